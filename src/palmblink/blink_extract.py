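"""Per-molecule trace extraction from probe-channel localization tables.

An immobile blinking fluorophore produces a tight spatial cloud of
localizations, so detections are grouped purely by position: average-linkage
(UPGMA) hierarchical clustering on Euclidean distance, dendrogram cut at
200 nm.  Each cluster's frame set becomes a :class:`~palmblink.trace_model.
MoleculeTrace`; clusters with implausibly many detections are discarded as
outliers, and (optionally) only clusters co-localized with a platform signal
are kept.  The module also provides the normalized cumulative-detection
curve, the singleton detection-share relation, and an MSD-based immobility
check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .registration_coloc import (
    AffineTransform2D,
    PlatformSignal,
    colocalize,
    filter_isolated,
    merge_platform,
)
from .trace_model import BlinkStats, LocalizationTable, MoleculeTrace, summarize

logger = logging.getLogger("palmblink")

__all__ = [
    "ExtractionConfig",
    "CumulativeCurve",
    "cluster_localizations",
    "build_trace",
    "filter_outlier_clusters",
    "cumulative_curve",
    "detection_share_of_singletons",
    "msd_diffusion",
    "extract_blink_stats",
]


@dataclass
class ExtractionConfig:
    """Parameters of the grouping/extraction pipeline.

    ``cut_height``: dendrogram cut in nm (clusters are the groups joined at
    average-linkage distance <= cut).  ``outlier_threshold``: clusters with
    more than this many detections are discarded (condition dependent: 100,
    150 or 600 for the characterized fluorophores).  ``coloc_radius``:
    platform co-localization acceptance radius in nm.
    """

    cut_height: float = 200.0
    outlier_threshold: int = 150
    coloc_radius: float = 500.0
    min_nn: float = 500.0
    linkage_method: str = "average"  # UPGMA

    def __post_init__(self) -> None:
        if self.cut_height <= 0 or self.outlier_threshold <= 0:
            raise ValueError("cut_height and outlier_threshold must be > 0")


@dataclass
class CumulativeCurve:
    """Normalized cumulative sum of detections vs fraction of molecules.

    Molecules are sorted by ascending detection count; ``y`` is the running
    detection total normalized by the overall number of detections and scaled
    by the mean detection count, so the curve ends at ``max_y == mean_N`` and
    collapses onto the diagonal when every molecule is detected exactly once.
    """

    x: np.ndarray
    y: np.ndarray
    max_y: float

    def validate(self) -> None:
        assert np.all(np.diff(self.y) >= 0)
        assert np.isclose(self.y[-1], self.max_y)


def cluster_localizations(
    table: LocalizationTable, config: ExtractionConfig | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group detections into per-molecule clusters by UPGMA at the cut height.

    Returns ``(center, member_indices)`` pairs, where ``center`` is the mean
    position of the members and ``member_indices`` index rows of ``table``.
    Only spatial coordinates enter the clustering (never time).

    For scalability the points are first split into connected components of
    the "within cut distance" graph; average linkage is monotone and every
    inter-component distance exceeds the cut, so running UPGMA per component
    yields exactly the global dendrogram cut.
    """
    config = config or ExtractionConfig()
    pts = table.positions
    n = len(pts)
    if n == 0:
        return []
    if n == 1:
        return [(pts[0].copy(), np.array([0]))]

    tree = cKDTree(pts)
    pairs = tree.query_pairs(config.cut_height, output_type="ndarray")
    if len(pairs):
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, comp = connected_components(graph, directed=False)
    else:
        comp = np.arange(n)

    clusters: list[tuple[np.ndarray, np.ndarray]] = []
    for label in np.unique(comp):
        idx = np.flatnonzero(comp == label)
        if len(idx) <= 2:
            # a 2-point component is within the cut by construction
            clusters.append((pts[idx].mean(axis=0), idx))
            continue
        Z = linkage(pts[idx], method=config.linkage_method)
        flat = fcluster(Z, t=config.cut_height, criterion="distance")
        for sub in np.unique(flat):
            members = idx[flat == sub]
            clusters.append((pts[members].mean(axis=0), members))
    return clusters


def build_trace(
    frames: np.ndarray, molecule_id: int = 0, position: tuple[float, float] | None = None
) -> MoleculeTrace:
    """Turn a cluster's frame indices into a :class:`MoleculeTrace`.

    Consecutive-frame runs become bursts; a gap from a burst ending at ``f1``
    to the next starting at ``f2`` has ``t_off = f2 - f1 - 1`` dark frames.
    Duplicate frames within one cluster (two detections of one molecule in a
    single frame, a grouping error) are counted once with a warning.
    """
    frames = np.asarray(frames, dtype=int)
    if len(np.unique(frames)) != len(frames):
        warnings.warn(
            f"molecule {molecule_id}: duplicate frames within one cluster; "
            "counting each frame once", stacklevel=2)
    return MoleculeTrace(molecule_id=molecule_id, frames=frames, position=position)


def filter_outlier_clusters(
    traces: list[MoleculeTrace], threshold: int
) -> list[MoleculeTrace]:
    """Drop traces with more than ``threshold`` detections; report the count."""
    kept = [t for t in traces if t.N <= threshold]
    removed = len(traces) - len(kept)
    if removed:
        logger.info("outlier filter: removed %d/%d clusters with N > %d",
                    removed, len(traces), threshold)
    return kept


def cumulative_curve(stats: BlinkStats) -> CumulativeCurve:
    """Normalized cumulative sum of detections against fraction of molecules."""
    if stats.n_molecules < 1:
        raise ValueError("need at least one molecule")
    counts = np.repeat(
        np.fromiter(stats.hist_N.keys(), dtype=int),
        np.fromiter(stats.hist_N.values(), dtype=int),
    )
    counts.sort()
    m = len(counts)
    x = np.arange(1, m + 1) / m
    y = np.cumsum(counts) / counts.sum() * stats.mean_N
    return CumulativeCurve(x=x, y=y, max_y=stats.mean_N)


def detection_share_of_singletons(p1: float, mean_N: float) -> float:
    """Fraction of *all* detections contributed by molecules detected once.

    If a fraction ``p1`` of molecules is detected exactly once and the mean
    detection count is ``mean_N``, singletons contribute ``p1 * M`` of the
    ``mean_N * M`` total detections, i.e. a share of ``p1 / mean_N``.
    """
    if not (0.0 <= p1 <= 1.0):
        raise ValueError("p1 must be in [0, 1]")
    if mean_N < 1.0:
        raise ValueError("mean_N must be >= 1")
    return p1 / mean_N


def msd_diffusion(
    trajectory: np.ndarray, dt: float, n_lags: int = 3
) -> tuple[float, np.ndarray]:
    """Diffusion coefficient from a mean-square-displacement fit.

    ``trajectory`` is (n, 2) positions in nm at regular intervals ``dt``
    seconds.  The MSD is averaged over all pairs at each lag; a straight line
    ``MSD = 4 D tau + offset`` is fitted to the first ``n_lags`` lags, the
    offset absorbing the localization-error floor.  Returns ``D`` in um^2/s
    and the fitted MSD values (um^2).  Used to verify platform immobility
    (D below 1e-4 um^2/s).
    """
    traj = np.asarray(trajectory, dtype=float) / 1000.0  # nm -> um
    if len(traj) < 10:
        raise ValueError("need at least 10 positions for an MSD fit")
    lags = np.arange(1, n_lags + 1)
    msd = np.array([
        np.mean(np.sum((traj[lag:] - traj[:-lag]) ** 2, axis=1)) for lag in lags
    ])
    slope, _ = np.polyfit(lags * dt, msd, 1)
    return float(slope / 4.0), msd


def extract_blink_stats(
    probe: LocalizationTable,
    platform: LocalizationTable | None = None,
    config: ExtractionConfig | None = None,
    condition_label: str = "",
    chromatic_transform: AffineTransform2D | None = None,
) -> tuple[BlinkStats, list[MoleculeTrace]]:
    """Full extraction pipeline: cluster, co-localize, build traces, summarize.

    When a platform table is given, its detections are merged into signals,
    crowded signals are removed, and only probe clusters with a platform
    partner within the co-localization radius are analyzed.  A
    ``chromatic_transform`` (fitted platform -> probe from bead pairs) is
    applied to the consolidated platform positions before co-localization.
    Returns the blinking statistics and the retained per-molecule traces.
    """
    config = config or ExtractionConfig()
    clusters = cluster_localizations(probe, config)
    if platform is not None and len(platform):
        signals = merge_platform(platform)
        signals = filter_isolated(signals, min_nn=config.min_nn)
        if chromatic_transform is not None:
            corrected = chromatic_transform.apply(
                np.asarray([s.position for s in signals]))
            signals = [
                PlatformSignal(position=tuple(xy), n_merged=s.n_merged,
                               signal_id=s.signal_id)
                for s, xy in zip(signals, corrected)
            ]
        clusters, _ = colocalize(clusters, signals, radius=config.coloc_radius)
    frames_all = probe.frames
    traces = [
        build_trace(frames_all[m], molecule_id=i, position=tuple(c))
        for i, (c, m) in enumerate(clusters)
    ]
    traces = filter_outlier_clusters(traces, config.outlier_threshold)
    stats = summarize(traces, condition_label=condition_label)
    return stats, traces
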