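# Methods

## The problem

Photoactivated localization microscopy (PALM) reconstructs a molecular map
from single-fluorophore detections, but a fluorophore does not report its
molecule exactly once: after photoactivation it blinks, cycling between
emissive bursts and dark gaps before terminal bleaching. Each molecule thus
contributes a small cloud of `N` detections spread over the acquisition,
with gaps that can span thousands of frames. On a spatial map this
overcounting is indistinguishable from genuine nanoclustering by eye or by a
naive Ripley's K analysis. `palmblink` implements the two halves of the
remedy: (i) quantifying a fluorophore's blinking from a sparse calibration
field in which every probe is anchored to an immobile, independently labeled
platform molecule, and (ii) deciding, by Monte Carlo simulation of random
maps that blink the same way, whether a recorded map contains clustering
beyond what blinking alone produces.

## Blinking model and trace generator

A trace is parameterized by the number of off-gaps `g`, burst durations
`t_on` (frames, >= 1), and gap durations `t_off` (dark frames, >= 1); the
total detection count is structural, `N = sum(t_on)` over `g + 1` bursts.
The generator draws `g`, `t_on`, and `t_off` independently and schedules the
bursts from a random activation frame, truncating at the end of the
acquisition (10,000 frames by default). Truncated and never-activated
molecules are flagged and their fraction reported, never silently dropped.

Defaults:

* `g`: geometric on {0, 1, ...}; `t_on`: geometric on {1, 2, ...}.
* `t_off`: mixture of a short geometric body and a log-uniform tail on
  [200, 9000] frames with weight 0.08, reproducing the observed heavy tail
  of off-times that defeats simple gap-merging strategies.
* Activation: geometric decay from frame 0 with mean 500 frames
  (photoactivation concentrated at the start of the recording); background
  decoys are uniform in time and space, at a default rate of 1e-7
  detections per frame per um^2 — a handful of spurious detections per
  full acquisition, matching a clean supported-lipid-bilayer preparation.
* Localization precision `sigma_loc` (nm) is setup-specific and therefore a
  required parameter with no default.

The four measured marginals (N, g, t_on, t_off) of a real fluorophore
cannot in general be matched simultaneously by an independent-draw
generator, because `E[N] = (E[g] + 1) E[t_on]` is then forced. The presets
keep the measured `E[t_on]` and the measured mean N — the quantity all
downstream corrections divide by — and derive the gap-count mean as
`mean_N / mean_ton - 1`. For CAGE635 this reproduces the measured gap count
(6.57) almost exactly; for mEOS3.2 the derived value (2.43) is below the
measured 3.05, the price of the independence assumption. Off-time
short-body means (10, 3.5, 2.5 frames) were chosen in closed form so the
mixture median equals the measured median off-time (8, 3, 2 frames) at the
8% tail weight.

Two localization-noise conventions are implemented and kept distinct
because they differ measurably: `paper_literal` shifts a detection along a
uniform random direction by a signed Normal(0, sigma) distance (radial
error folded-normal, mean `sigma * sqrt(2/pi)`); `gaussian_xy` draws
independent per-axis errors (radial error Rayleigh, mean
`sigma * sqrt(pi/2)`). `paper_literal` is the default.

## Extraction pipeline

1. **Platform consolidation** — platform-channel detections are greedily
   chained in frame order onto the nearest open signal within one pixel
   (160 nm default) of its running mean and within 10,000 frames of its last
   member; the signal position is the member mean. Signals with a neighbor
   closer than 500 nm are discarded (both members of a close pair).
2. **Chromatic correction** — an affine transform (least squares on matched
   bead pairs, >= 3 non-collinear) maps the platform channel onto the probe
   channel.
3. **Probe grouping** — UPGMA (average-linkage) hierarchical clustering on
   Euclidean distance, dendrogram cut at 200 nm: clusters are the groups
   joined at linkage distance <= 200 nm. For scalability points are first
   split into connected components of the within-cut graph; average linkage
   is monotone and all inter-component distances exceed the cut, so the
   per-component result is provably identical to the global cut (and is
   verified against a brute-force implementation in the tests).
4. **Co-localization** — probe clusters are kept if a platform signal lies
   within 500 nm of the cluster center (member mean). This removes
   background decoys, which carry no platform partner, at the cost of a
   geometric leak-through of `1 - exp(-rho * pi * R^2)` for platform density
   rho.
5. **Outlier filter** — clusters with more than a condition-specific
   threshold of detections (100 / 150 / 600) are discarded and counted.
6. **Trace building** — a cluster's sorted frames are parsed into bursts
   and gaps. Convention: a burst ending at frame `f1` followed by one
   starting at `f2` has `t_off = f2 - f1 - 1` dark frames (so frames
   {1,2,7} give t_on = [2,1], t_off = [4]). Duplicate frames within one
   cluster are counted once with a warning.

Derived outputs: per-parameter histograms with mean/median summaries; the
normalized cumulative-detection curve (counts sorted ascending, cumulative
sum divided by total detections and multiplied by mean N, so the curve ends
at mean N and is the diagonal when every molecule is seen once); the
singleton detection share `p1 / mean_N`; and an MSD immobility check
(D from a linear fit `MSD = 4 D tau + offset` over the first 3 lags,
immobile means D < 1e-4 um^2/s).

## Map simulation

Scenario maps place `round(density x area)` molecules on the field
(15 x 15 um^2, 70 per um^2 defaults). Cluster centers are uniform;
clustered molecules (a configured fraction, distributed uniformly among
clusters) are offset by an isotropic Gaussian truncated radially at one
standard deviation (the "cluster radius"); remaining molecules are placed
uniformly outside the cluster discs by rejection. Counts are deterministic
rounds rather than Poisson draws to match fixed design densities and
reduce replicate variance (a Poisson mode exists behind a flag). Blinking
is overlaid by drawing per-molecule detection counts from an empirical N
histogram and jittering each detection by `sigma_loc`; detections displaced
beyond the field edge are kept, so candidate and reference maps share
identical edge behavior.

## Ripley classification

`K(r)` is estimated as `A / (n (n-1)) * #{ordered pairs with d <= r}` with
no edge correction, and normalized as `H(r) = sqrt(K/pi) - r`, which is
zero in expectation under complete spatial randomness at short range. The
uncorrected estimator acquires a deterministic negative bias at radii
approaching the field size; because candidate and reference are always
computed on identical geometry this bias cancels in every comparison, which
is why no correction is applied by default.

A reference envelope is the pointwise mean +/- SD of H over repeated
simulations (15 replicates for scenario comparisons, 10 for cell maps).
Classification happens at the radius where the candidate's mean H peaks:

* envelope vs envelope (k_sd = 1): **not resolvable** if each mean lies
  inside the other's interval; **resolvable** if the intervals are
  disjoint; **borderline** otherwise. The containment rule is conjunctive
  by default (a disjunctive variant is selectable).
* single recorded curve vs envelope: the candidate interval is zero-width,
  so the decision reduces to containment of the curve's peak value in the
  reference band and borderline is unattainable. A single draw compared to
  a null distribution needs a wider band than an envelope mean, so
  `assess_cell_map` defaults to k_sd = 2 (the conventional ~95% band);
  with k_sd = 1 a truly random map would be rejected ~1/3 of the time.

Cell-map assessment infers the molecular density from the map itself
(localizations / mean N / area), simulates random-with-blinking references
at that density on the same region, and classifies the map's own curve.
The sensitivity grid sweeps cluster radius, clustered fraction and cluster
density against a shared fraction-zero reference and reports a tidy table
of outcomes and peak heights.

## Numerical and scale choices

* All randomness flows through explicitly passed `numpy` generators or
  recorded per-replicate seeds; identical config + seed reproduces results
  bit for bit.
* Radius grid: 0-1000 nm in 20 nm steps; `H(0) = 0` by convention.
* Truncated-Gaussian and outside-cluster placement use vectorized rejection
  sampling; placement fails loudly if cluster discs (nearly) cover the
  field.
* The test suite exercises reduced problem sizes chosen to keep the full
  run in minutes while leaving verdicts statistically unambiguous: recovery
  runs use the measured per-condition molecule counts (720 / 166 / 491) over
  a few seeds; envelope checks use 5-15 replicates on 8-15 um fields; the
  CSR calibration uses 100 trials of 15-replicate envelopes at the default
  scenario scale.

## What the synthetic data does and does not show

The generator reproduces the *structure* of measured blinking (burst/gap
alternation, heavy-tailed off-times, activation concentrated early,
uniform background decoys, a co-localized quasi-static platform channel)
but idealizes everything optical: no point-spread function, photon
statistics, camera noise, drift, or detection failures, and molecules are
strictly immobile. Passing recovery tests therefore demonstrates that the
extraction pipeline is correct and unbiased under the stated blinking
model — not that any particular instrument achieves these conditions.
Distribution *shapes* beyond the matched moments (means, medians, tail
weight) are parametric conveniences, not measurements; analyses that
depend on full distribution shape should load measured histograms instead
of presets.

## Known limitations

* Independent-draw trace generation cannot match all four measured
  marginals at once (see above); correlations between burst count and
  burst length observed in real data are not modeled.
* Grouping by a fixed 200 nm cut fails for molecules closer than roughly
  the cut; crowded molecules are flagged in ground truth, and extraction
  from dense cell maps should always use platform-calibrated statistics,
  never statistics extracted from the dense map itself.
* The classification compares envelopes only at the candidate's peak
  radius; patterns that differ elsewhere while agreeing at the peak are
  not distinguished, and candidate/reference exchange symmetry holds only
  for the not-resolvable outcome.
* ~2% of detections are lost to acquisition-end truncation for the
  strongest blinker (long gap chains running past frame 10,000), which
  biases its recovered mean N slightly low; the truncated fraction is
  reported by the generator.
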