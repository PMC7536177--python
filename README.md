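# palmblink

Fluorophore blinking quantification and blinking-aware cluster detection for
PALM single-molecule localization maps.

Photoswitchable and photoactivatable fluorophores blink: one immobilized
molecule yields `N` detections spread over bursts (`t_on`) separated by dark
gaps (`t_off`, sometimes thousands of frames), so a PALM map of randomly
placed molecules shows tight clouds of localizations that mimic genuine
nanoclusters. `palmblink` is for microscopists who need to tell the two
apart. It provides:

* **Blink statistics extraction** — group probe localizations into
  per-molecule traces (UPGMA clustering cut at 200 nm), confirmed by
  co-localization with a second-channel platform label (affine chromatic
  correction, signal merging, 500 nm radius), and summarize the four
  blinking parameters `N`, `g`, `t_on`, `t_off`.
* **A synthetic ground-truth generator** for the calibration assay:
  per-molecule emission traces (geometric bursts/gap counts, heavy-tailed
  off-times), localization noise, a co-localized platform channel, and
  uniform background decoys.
* **Monte Carlo map simulation** — random or nanoclustered molecule maps
  (truncated-Gaussian clusters) overlaid with an empirical `N` distribution
  and localization noise.
* **Ripley's K classification** — the CSR-centered statistic
  `H(r) = sqrt(K(r)/pi) - r`, simulation envelopes (mean ± SD), and a
  three-way decision at the curve maximum: *not resolvable* / *borderline*
  / *resolvable*.

The central idea: a candidate map is never compared to naive randomness but
to simulations of random maps whose molecules blink like the actual
fluorophore. Clustering is only claimed when the map's Ripley curve escapes
that blinking-aware envelope.

## Worked example

Quantify blinking from a synthetic calibration field, then test whether a
clustered map is distinguishable from blinking alone:

```sh
# 1. synthetic two-channel calibration field (720 molecules, PS-CFP2-like)
palmblink simulate-traces --preset ps_cfp2_pfa --n-molecules 720 --seed 1 \
    --probe-out probe.csv --platform-out platform.csv --truth-out truth.csv

# 2. extract per-molecule blinking statistics
palmblink extract --probe probe.csv --platform platform.csv \
    --outlier-threshold 150 --out stats.json
# -> 721 molecules, mean N = 3.99, median t_off = 8 frames

# 3. simulate a clustered map with that fluorophore's blinking
palmblink simulate --stats stats.json --fraction 0.8 --cluster-radius 60 \
    --clusters-per-um2 20 --seed 2 --out clustered.csv
# -> 15750 molecules -> 62581 detections

# 4. Ripley curve of the map
palmblink ripley --in clustered.csv --out curve.csv
# -> H peaks at r = 60 nm
```

The extracted mean `N` of ~4 means each molecule was detected four times on
average — a map of such molecules contains ~4x more localizations than
molecules, and the detection step recovered the planted statistics from the
rendered field (the configured generator mean here realizes to 4.00 for
this seed). The clustered map's `H` peak location reflects the planted
60 nm cluster radius. Classifying that curve against an envelope of
`fraction 0` simulations with the same `stats.json` (`palmblink classify`,
or `assess` for the full decision flow on recorded maps with a YAML config)
returns `resolvable`; running step 3 with `--fraction 0` instead and
classifying returns `not_resolvable` even though its localization map
*also* shows clusters — all of them blinking artifacts.

Library use mirrors the CLI (`palmblink.extract_blink_stats`,
`palmblink.simulate_map`, `palmblink.build_envelope`, `palmblink.classify`,
`palmblink.assess_cell_map`, `palmblink.sensitivity_grid`); see
`docs/methods.md` for the model details and conventions.

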