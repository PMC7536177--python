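"""Domain types for single-molecule blinking traces and the synthetic field generator.

A photoswitchable or photoactivatable fluorophore anchored to an immobile
platform does not emit continuously: after photoactivation it cycles between
emissive and dark states before terminal bleaching.  In a PALM acquisition of
``n_frames`` camera frames this produces a *trace* -- a set of frame indices in
which the molecule was detected -- characterized by four parameters:

* ``N``     total number of detections,
* ``g``     number of off-gaps interrupting the trace,
* ``t_on``  duration of each emission burst (frames),
* ``t_off`` duration of each dark gap (frames).

This module defines those types (:class:`Detection`, :class:`LocalizationTable`,
:class:`MoleculeTrace`, :class:`BlinkStats`) and a generative model that
inverts them: traces are sampled by drawing an activation frame, a gap count
``g`` and alternating burst/gap durations, so that ``N = sum(t_on)`` holds by
construction.  :func:`render_field` turns a set of traces placed on a 2-D
field into probe- and platform-channel localization tables with per-detection
localization noise and uniform background decoys, together with a ground-truth
map -- the synthetic stand-in for the supported-lipid-bilayer assay that the
downstream extraction pipeline is validated against.
"""

from __future__ import annotations

import enum
import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("palmblink")

__all__ = [
    "Channel",
    "Detection",
    "Rect",
    "LocalizationTable",
    "MoleculeTrace",
    "BlinkStats",
    "Constant",
    "Geometric",
    "Empirical",
    "OffTimeMixture",
    "TraceGeneratorConfig",
    "BLINK_PRESETS",
    "preset_config",
    "sample_trace",
    "sample_traces",
    "displace",
    "grid_positions",
    "render_field",
    "summarize",
]


class Channel(enum.Enum):
    """Color channel of a detection: the blinking probe or the platform label."""

    PROBE = "probe"
    PLATFORM = "platform"


@dataclass(frozen=True)
class Detection:
    """A single-molecule localization: frame index and position in nm."""

    frame: int
    x: float
    y: float
    channel: Channel = Channel.PROBE

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame must be >= 0, got {self.frame}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("detection coordinates must be finite")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in nm, origin at the lower-left corner."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("degenerate roi rectangle")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area_nm2(self) -> float:
        return self.width * self.height

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / 1e6

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)


@dataclass
class LocalizationTable:
    """Time-stamped 2-D detections of one color channel.

    ``df`` has columns ``frame`` (int), ``x`` and ``y`` (nm); row order is
    acquisition order.  ``roi`` is the imaged region in nm and ``pixel_size``
    the camera pixel pitch in nm (used only where a rule is stated in pixels).
    """

    df: pd.DataFrame
    n_frames: int
    roi: Rect
    pixel_size: float = 160.0
    channel: Channel = Channel.PROBE

    def __len__(self) -> int:
        return len(self.df)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of x/y coordinates in nm."""
        return self.df[["x", "y"]].to_numpy(dtype=float)

    @property
    def frames(self) -> np.ndarray:
        return self.df["frame"].to_numpy(dtype=int)

    def validate(self) -> None:
        if (self.df["frame"] < 0).any() or (self.df["frame"] >= self.n_frames).any():
            raise ValueError("frame indices outside [0, n_frames)")
        if not np.isfinite(self.positions).all():
            raise ValueError("non-finite coordinates")
        if len(self.df) and not self.roi.contains(
                self.df["x"].to_numpy(), self.df["y"].to_numpy()).all():
            raise ValueError("detections outside roi")

    @classmethod
    def from_detections(
        cls,
        detections: Iterable[Detection],
        n_frames: int,
        roi: Rect,
        pixel_size: float = 160.0,
        channel: Channel = Channel.PROBE,
    ) -> "LocalizationTable":
        rows = [(d.frame, d.x, d.y) for d in detections]
        df = pd.DataFrame(rows, columns=["frame", "x", "y"])
        if len(df) == 0:
            df = pd.DataFrame({"frame": pd.Series(dtype=int),
                               "x": pd.Series(dtype=float),
                               "y": pd.Series(dtype=float)})
        return cls(df=df, n_frames=n_frames, roi=roi,
                   pixel_size=pixel_size, channel=channel)


@dataclass
class MoleculeTrace:
    """One fluorophore's grouped detections with derived blinking parameters.

    Invariants: ``N == len(frames) == sum(t_on)``; ``g == len(t_off)`` and,
    for a non-empty trace, ``g == len(t_on) - 1``; all durations >= 1 frame.
    ``t_off`` counts *dark* frames: a burst ending at frame ``f1`` followed by
    one starting at ``f2`` has ``t_off = f2 - f1 - 1``.
    """

    molecule_id: int
    frames: np.ndarray  # sorted, unique, int
    position: tuple[float, float] | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        self.frames = np.unique(np.asarray(self.frames, dtype=int))

    @property
    def N(self) -> int:
        return len(self.frames)

    @property
    def t_on(self) -> list[int]:
        """Durations of consecutive-frame emission bursts."""
        if self.N == 0:
            return []
        breaks = np.flatnonzero(np.diff(self.frames) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [self.N - 1]))
        return list((self.frames[ends] - self.frames[starts] + 1).tolist())

    @property
    def t_off(self) -> list[int]:
        """Durations of dark gaps between bursts (number of dark frames)."""
        if self.N == 0:
            return []
        gaps = np.diff(self.frames)
        return list((gaps[gaps > 1] - 1).tolist())

    @property
    def g(self) -> int:
        return len(self.t_off)

    @property
    def first_frame(self) -> int:
        if self.N == 0:
            raise ValueError("empty trace has no first frame")
        return int(self.frames[0])

    def validate(self) -> None:
        t_on, t_off = self.t_on, self.t_off
        assert self.N == sum(t_on)
        if self.N >= 1:
            assert len(t_off) == len(t_on) - 1
        assert all(t >= 1 for t in t_on) and all(t >= 1 for t in t_off)
        # reconstruct frames from (first_frame, t_on, t_off) alternation
        if self.N:
            rebuilt = []
            f = self.first_frame
            for i, on in enumerate(t_on):
                rebuilt.extend(range(f, f + on))
                f += on
                if i < len(t_off):
                    f += t_off[i]
            assert np.array_equal(np.asarray(rebuilt), self.frames)


# ---------------------------------------------------------------------------
# Discrete duration/count distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constant:
    """Degenerate distribution: always ``value``."""

    value: int

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.value, dtype=int)

    def mean(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class Geometric:
    """Geometric distribution on ``{start, start+1, ...}`` with given mean.

    With ``start=1`` this is the standard number-of-trials geometric (burst
    durations); with ``start=0`` the number-of-failures variant (gap counts).
    """

    mean: float
    start: int = 1

    def __post_init__(self) -> None:
        if self.mean < self.start:
            raise ValueError(f"mean must be >= start ({self.start})")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.mean == self.start:
            return np.full(size, self.start, dtype=int)
        p = 1.0 / (self.mean - self.start + 1.0)
        return rng.geometric(p, size=size) - 1 + self.start


@dataclass(frozen=True)
class Empirical:
    """Integer-valued distribution given by an empirical histogram value -> mass."""

    hist: Mapping[int, float]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        values = np.fromiter(self.hist.keys(), dtype=int)
        weights = np.fromiter(self.hist.values(), dtype=float)
        if weights.sum() <= 0:
            raise ValueError("empirical histogram has zero mass")
        return rng.choice(values, size=size, p=weights / weights.sum())

    def mean(self) -> float:
        values = np.fromiter(self.hist.keys(), dtype=float)
        weights = np.fromiter(self.hist.values(), dtype=float)
        return float((values * weights).sum() / weights.sum())


@dataclass(frozen=True)
class OffTimeMixture:
    """Heavy-tailed off-time model: geometric body + log-uniform tail.

    Most dark gaps are short (geometric with mean ``short_mean``), but a small
    fraction ``tail_weight`` of off-times is drawn log-uniformly between
    ``tail_min`` and ``tail_max`` frames, emulating rare excursions into
    long-lived dark states that span hundreds to thousands of frames.
    """

    short_mean: float = 10.0
    tail_weight: float = 0.08
    tail_min: int = 200
    tail_max: int = 9000

    def __post_init__(self) -> None:
        if not (0.0 <= self.tail_weight <= 1.0):
            raise ValueError("tail_weight must be in [0, 1]")
        if self.short_mean < 1 or self.tail_min < 1 or self.tail_max < self.tail_min:
            raise ValueError("invalid off-time mixture parameters")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        out = rng.geometric(1.0 / self.short_mean, size=size)
        tail = rng.random(size) < self.tail_weight
        n_tail = int(tail.sum())
        if n_tail:
            u = rng.uniform(np.log(self.tail_min), np.log(self.tail_max), size=n_tail)
            out[tail] = np.rint(np.exp(u)).astype(int)
        return out

    def mean(self) -> float:
        tail_mean = (self.tail_max - self.tail_min) / math.log(self.tail_max / self.tail_min)
        return (1 - self.tail_weight) * self.short_mean + self.tail_weight * tail_mean


def _dist_mean(dist) -> float:
    if isinstance(dist, Geometric):
        return dist.mean
    return dist.mean()


# ---------------------------------------------------------------------------
# Generator configuration and fluorophore presets
# ---------------------------------------------------------------------------

@dataclass
class TraceGeneratorConfig:
    """Parameters of the synthetic trace/field generator.

    ``sigma_loc`` (localization precision, nm) has no universal value -- it
    depends on the optical setup -- and must be supplied explicitly.
    Activation defaults to a geometric decay from frame 0 with mean
    ``activation_mean`` frames, reflecting photoactivation concentrated at the
    start of the acquisition; background decoys appear uniformly in time.
    """

    sigma_loc: float
    n_frames: int = 10_000
    gap_count: object = field(default_factory=lambda: Geometric(mean=1.894, start=0))
    on_time: object = field(default_factory=lambda: Geometric(mean=1.41, start=1))
    off_time: object = field(default_factory=OffTimeMixture)
    activation: str = "geometric"  # or "uniform"
    activation_mean: float = 500.0
    displacement_mode: str = "paper_literal"  # or "gaussian_xy"
    decoy_rate: float = 1e-7  # detections per frame per um^2
    platform_offset_sigma: float = 20.0  # nm, per-molecule inter-channel offset
    platform_detections: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.decoy_rate < 0 or self.activation_mean < 0:
            raise ValueError("rates/means must be >= 0")
        if self.activation not in ("geometric", "uniform"):
            raise ValueError(f"unknown activation model {self.activation!r}")
        if self.displacement_mode not in ("paper_literal", "gaussian_xy"):
            raise ValueError(f"unknown displacement mode {self.displacement_mode!r}")


#: Blinking summaries of the characterized fluorophores (4% PFA, high power
#: density, 10,000 frames).  ``mean_n`` and ``mean_ton`` are the measured
#: means; the gap-count mean is derived as ``mean_n / mean_ton - 1`` so that
#: an independent-draw generator reproduces the measured mean N exactly;
#: ``toff_short_mean`` puts the off-time mixture median at the measured value.
BLINK_PRESETS: dict[str, dict] = {
    "ps_cfp2_pfa": dict(mean_n=4.08, mean_ton=1.41, median_toff=8,
                        toff_short_mean=10.0, n_molecules=720,
                        outlier_threshold=150),
    "meos32_pfa": dict(mean_n=6.48, mean_ton=1.89, median_toff=3,
                       toff_short_mean=3.5, n_molecules=166,
                       outlier_threshold=150),
    "cage635_pfa": dict(mean_n=27.09, mean_ton=3.58, median_toff=2,
                        toff_short_mean=2.5, n_molecules=491,
                        outlier_threshold=600),
}


def preset_config(name: str, sigma_loc: float, **overrides) -> TraceGeneratorConfig:
    """Build a :class:`TraceGeneratorConfig` for a characterized fluorophore."""
    try:
        p = BLINK_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(BLINK_PRESETS)}")
    cfg = TraceGeneratorConfig(
        sigma_loc=sigma_loc,
        gap_count=Geometric(mean=p["mean_n"] / p["mean_ton"] - 1.0, start=0),
        on_time=Geometric(mean=p["mean_ton"], start=1),
        off_time=OffTimeMixture(short_mean=p["toff_short_mean"]),
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Trace sampling
# ---------------------------------------------------------------------------

def _sample_activation(config: TraceGeneratorConfig, rng: np.random.Generator) -> int:
    if config.activation == "uniform":
        return int(rng.integers(0, config.n_frames))
    if config.activation_mean == 0:
        return 0
    p = 1.0 / (config.activation_mean + 1.0)
    return int(rng.geometric(p)) - 1


def sample_trace(
    config: TraceGeneratorConfig,
    rng: np.random.Generator,
    molecule_id: int = 0,
) -> MoleculeTrace:
    """Draw one blinking trace: activation frame, then alternating bursts/gaps.

    The schedule is truncated at the end of the acquisition; a molecule whose
    activation frame falls beyond ``n_frames`` yields an empty trace
    (``N == 0``, ``truncated=True``), mirroring molecules that are never
    detected.  ``N`` is the realized sum of burst durations.
    """
    a = _sample_activation(config, rng)
    if a >= config.n_frames:
        return MoleculeTrace(molecule_id=molecule_id, frames=np.empty(0, dtype=int),
                             truncated=True)
    g = int(config.gap_count.sample(rng, 1)[0])
    t_on = config.on_time.sample(rng, g + 1)
    t_off = config.off_time.sample(rng, g) if g else np.empty(0, dtype=int)

    frames: list[int] = []
    f = a
    truncated = False
    for i in range(g + 1):
        end = f + int(t_on[i])  # exclusive
        if end > config.n_frames:
            end = config.n_frames
            truncated = True
        frames.extend(range(f, end))
        if truncated:
            break
        f = end
        if i < g:
            f += int(t_off[i])
            if f >= config.n_frames:
                truncated = True
                break
    return MoleculeTrace(molecule_id=molecule_id,
                         frames=np.asarray(frames, dtype=int),
                         truncated=truncated)


def sample_traces(
    n: int, config: TraceGeneratorConfig, rng: np.random.Generator
) -> list[MoleculeTrace]:
    """Draw ``n`` independent traces with sequential molecule ids."""
    return [sample_trace(config, rng, molecule_id=i) for i in range(n)]


# ---------------------------------------------------------------------------
# Spatial rendering
# ---------------------------------------------------------------------------

def displace(
    points: np.ndarray, sigma: float, mode: str, rng: np.random.Generator
) -> np.ndarray:
    """Apply per-detection localization noise to (n, 2) positions.

    ``paper_literal``: shift each point along a uniformly random direction by
    a signed distance drawn from Normal(0, sigma); the radial displacement is
    then folded-normal with mean ``sigma * sqrt(2/pi)``.

    ``gaussian_xy``: independent Normal(0, sigma) per axis; the radial
    displacement is Rayleigh with mean ``sigma * sqrt(pi/2)``.
    """
    points = np.asarray(points, dtype=float)
    if sigma == 0 or len(points) == 0:
        return points.copy()
    n = len(points)
    if mode == "paper_literal":
        d = rng.normal(0.0, sigma, size=n)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        off = np.column_stack((d * np.cos(theta), d * np.sin(theta)))
    elif mode == "gaussian_xy":
        off = rng.normal(0.0, sigma, size=(n, 2))
    else:
        raise ValueError(f"unknown displacement mode {mode!r}")
    return points + off


def grid_positions(n: int, spacing_nm: float, roi_margin: float = 1000.0) -> tuple[np.ndarray, Rect]:
    """Regular square grid of ``n`` positions with the given spacing.

    Convenience for well-separated validation fields; returns positions and a
    bounding ROI with a margin on every side.
    """
    side = int(math.ceil(math.sqrt(n)))
    ij = np.indices((side, side)).reshape(2, -1).T[:n]
    pos = ij * spacing_nm + roi_margin
    extent = (side - 1) * spacing_nm + 2 * roi_margin
    return pos.astype(float), Rect(0.0, 0.0, extent, extent)


def render_field(
    traces: Sequence[MoleculeTrace],
    positions: np.ndarray,
    roi: Rect,
    config: TraceGeneratorConfig,
    rng: np.random.Generator,
    flag_distance: float = 400.0,
) -> tuple[LocalizationTable, LocalizationTable, pd.DataFrame]:
    """Render traces placed at ``positions`` into two-channel localization tables.

    Returns ``(probe, platform, truth)``: the probe table holds one noisy
    detection per trace frame plus uniform background decoys; the platform
    table holds a short quasi-static detection series per molecule (with a
    fixed per-molecule inter-channel offset); ``truth`` maps each probe row to
    its molecule id (``-1`` for decoys) and flags molecules with a neighbor
    closer than ``flag_distance`` (expected grouping failures).
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) != len(traces):
        raise ValueError("positions and traces length mismatch")
    if len(positions) and not roi.contains(positions[:, 0], positions[:, 1]).all():
        raise ValueError("molecule positions must lie within roi")

    frames_list, mol_xy, mol_ids = [], [], []
    for trace, pos in zip(traces, positions):
        if trace.N == 0:
            continue
        frames_list.append(trace.frames)
        mol_xy.append(np.broadcast_to(pos, (trace.N, 2)))
        mol_ids.append(np.full(trace.N, trace.molecule_id, dtype=int))
    if frames_list:
        probe_frames = np.concatenate(frames_list)
        probe_xy = displace(np.concatenate(mol_xy), config.sigma_loc,
                            config.displacement_mode, rng)
        probe_ids = np.concatenate(mol_ids)
    else:
        probe_frames = np.empty(0, dtype=int)
        probe_xy = np.empty((0, 2))
        probe_ids = np.empty(0, dtype=int)

    # uniform background decoys, uniform in time
    n_decoys = rng.poisson(config.decoy_rate * roi.area_um2 * config.n_frames)
    if n_decoys:
        dx = rng.uniform(roi.x0, roi.x1, size=n_decoys)
        dy = rng.uniform(roi.y0, roi.y1, size=n_decoys)
        df_frames = rng.integers(0, config.n_frames, size=n_decoys)
        probe_frames = np.concatenate((probe_frames, df_frames))
        probe_xy = np.vstack((probe_xy, np.column_stack((dx, dy))))
        probe_ids = np.concatenate((probe_ids, np.full(n_decoys, -1, dtype=int)))

    order = np.argsort(probe_frames, kind="stable")
    probe_df = pd.DataFrame({
        "frame": probe_frames[order].astype(int),
        "x": probe_xy[order, 0],
        "y": probe_xy[order, 1],
    })
    probe = LocalizationTable(df=probe_df, n_frames=config.n_frames, roi=roi,
                              channel=Channel.PROBE)

    # platform channel: quasi-static label per molecule, none for decoys
    plat_rows = []
    k = config.platform_detections
    plat_frames = np.linspace(0, config.n_frames - 1, k).astype(int)
    for trace, pos in zip(traces, positions):
        offset = rng.normal(0.0, config.platform_offset_sigma, size=2)
        base = pos + offset
        xy = displace(np.broadcast_to(base, (k, 2)), config.sigma_loc,
                      config.displacement_mode, rng)
        for f, (x, y) in zip(plat_frames, xy):
            plat_rows.append((int(f), x, y))
    plat_df = pd.DataFrame(plat_rows, columns=["frame", "x", "y"])
    if not plat_rows:
        plat_df = pd.DataFrame({"frame": pd.Series(dtype=int),
                                "x": pd.Series(dtype=float),
                                "y": pd.Series(dtype=float)})
    platform = LocalizationTable(df=plat_df, n_frames=config.n_frames, roi=roi,
                                 channel=Channel.PLATFORM)

    # ground truth: one row per probe detection, acquisition order
    truth = pd.DataFrame({
        "detection_row_id": np.arange(len(probe_df)),
        "molecule_id": probe_ids[order],
    })
    crowded_ids: set[int] = set()
    if len(positions) >= 2:
        from scipy.spatial import cKDTree

        tree = cKDTree(positions)
        for i, j in tree.query_pairs(flag_distance):
            crowded_ids.add(traces[i].molecule_id)
            crowded_ids.add(traces[j].molecule_id)
        if crowded_ids:
            logger.warning("%d molecules closer than %.0f nm (grouping may fail)",
                           len(crowded_ids), flag_distance)
    truth["crowded"] = truth["molecule_id"].isin(crowded_ids)
    return probe, platform, truth


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass
class BlinkStats:
    """Empirical blinking statistics of a set of molecule traces.

    Histograms map integer parameter values to counts; ``hist_N`` and
    ``hist_g`` sum to ``n_molecules``, ``hist_ton``/``hist_toff`` to the total
    number of bursts/gaps.  Summary scalars are statistics of the stored
    histograms.
    """

    hist_N: dict[int, int]
    hist_g: dict[int, int]
    hist_ton: dict[int, int]
    hist_toff: dict[int, int]
    mean_N: float
    mean_g: float
    mean_ton: float
    median_toff: float
    n_molecules: int
    condition_label: str = ""
    truncated_fraction: float = 0.0

    def validate(self) -> None:
        assert sum(self.hist_N.values()) == self.n_molecules
        assert sum(self.hist_g.values()) == self.n_molecules
        assert sum(self.hist_ton.values()) == sum(
            k * v for k, v in self.hist_g.items()) + self.n_molecules
        assert sum(self.hist_toff.values()) == sum(
            k * v for k, v in self.hist_g.items())
        assert math.isclose(self.mean_N, _hist_mean(self.hist_N), rel_tol=1e-12)
        assert math.isclose(self.mean_g, _hist_mean(self.hist_g), rel_tol=1e-12)
        assert math.isclose(self.mean_ton, _hist_mean(self.hist_ton), rel_tol=1e-12)
        if self.hist_toff:
            assert self.median_toff == _hist_median(self.hist_toff)

    def to_dict(self) -> dict:
        return {
            "hist_N": {str(k): v for k, v in sorted(self.hist_N.items())},
            "hist_g": {str(k): v for k, v in sorted(self.hist_g.items())},
            "hist_ton": {str(k): v for k, v in sorted(self.hist_ton.items())},
            "hist_toff": {str(k): v for k, v in sorted(self.hist_toff.items())},
            "mean_N": self.mean_N,
            "mean_g": self.mean_g,
            "mean_ton": self.mean_ton,
            "median_toff": self.median_toff,
            "n_molecules": self.n_molecules,
            "condition_label": self.condition_label,
            "truncated_fraction": self.truncated_fraction,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BlinkStats":
        def ih(h):
            return {int(k): int(v) for k, v in h.items()}

        return cls(hist_N=ih(d["hist_N"]), hist_g=ih(d["hist_g"]),
                   hist_ton=ih(d["hist_ton"]), hist_toff=ih(d["hist_toff"]),
                   mean_N=float(d["mean_N"]), mean_g=float(d["mean_g"]),
                   mean_ton=float(d["mean_ton"]),
                   median_toff=float(d["median_toff"]),
                   n_molecules=int(d["n_molecules"]),
                   condition_label=str(d.get("condition_label", "")),
                   truncated_fraction=float(d.get("truncated_fraction", 0.0)))


def _hist_mean(hist: Mapping[int, int]) -> float:
    total = sum(hist.values())
    return sum(k * v for k, v in hist.items()) / total if total else float("nan")


def _hist_median(hist: Mapping[int, int]) -> float:
    values = np.repeat(np.fromiter(hist.keys(), dtype=int),
                       np.fromiter(hist.values(), dtype=int))
    return float(np.median(values))


def summarize(traces: Sequence[MoleculeTrace], condition_label: str = "") -> BlinkStats:
    """Compute :class:`BlinkStats` over the non-empty traces.

    Empty traces (undetected molecules) are excluded but their fraction is
    reported via ``truncated_fraction`` together with mid-acquisition
    truncations, so losses are visible rather than silently absorbed.
    """
    nonempty = [t for t in traces if t.N > 0]
    if not nonempty:
        raise ValueError("no detectable molecules: all traces are empty")
    hist_N = Counter(t.N for t in nonempty)
    hist_g = Counter(t.g for t in nonempty)
    hist_ton = Counter()
    hist_toff = Counter()
    for t in nonempty:
        hist_ton.update(t.t_on)
        hist_toff.update(t.t_off)
    median_toff = _hist_median(hist_toff) if hist_toff else float("nan")
    truncated = sum(1 for t in traces if t.truncated)
    return BlinkStats(
        hist_N=dict(hist_N), hist_g=dict(hist_g),
        hist_ton=dict(hist_ton), hist_toff=dict(hist_toff),
        mean_N=_hist_mean(hist_N), mean_g=_hist_mean(hist_g),
        mean_ton=_hist_mean(hist_ton), median_toff=median_toff,
        n_molecules=len(nonempty), condition_label=condition_label,
        truncated_fraction=truncated / len(traces),
    )
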