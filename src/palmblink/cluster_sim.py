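"""Monte Carlo generator of random or clustered molecule maps with blinking.

Ground-truth molecule positions are laid out on a rectangular field either
completely at random or partly grouped into nanoclusters: cluster centers are
uniform on the field, members are drawn from an isotropic 2-D Gaussian
truncated radially at one standard deviation (the "cluster radius"), and the
remaining molecules are placed uniformly outside the cluster discs.  Blinking
overcounting is overlaid by drawing each molecule's detection count from an
empirical N distribution and jittering every detection by the localization
precision.  The resulting detection maps feed the Ripley's-K classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .trace_model import BlinkStats, Constant, Empirical, Rect, displace

logger = logging.getLogger("palmblink")

__all__ = [
    "ClusterScenario",
    "SimulatedMap",
    "place_molecules",
    "apply_blinking",
    "simulate_map",
    "density_from_map",
]

DEFAULT_ROI = Rect(0.0, 0.0, 15_000.0, 15_000.0)  # 15 x 15 um^2


@dataclass
class ClusterScenario:
    """Generative parameters of a (possibly clustered) molecule map.

    Densities are per um^2; ``cluster_radius`` is the standard deviation of
    the truncated Gaussian in nm; ``fraction_clustered`` is the share of
    molecules assigned to clusters.  ``n_source`` supplies per-molecule
    detection counts (``Constant(1)`` switches blinking off; an
    :class:`Empirical` histogram reproduces a measured fluorophore).
    Molecule and cluster counts are deterministic rounds of density x area.
    """

    sigma_loc: float
    roi: Rect = field(default_factory=lambda: DEFAULT_ROI)
    density: float = 70.0
    cluster_radius: float = 60.0
    clusters_per_um2: float = 20.0
    fraction_clustered: float = 0.0
    n_source: object = field(default_factory=lambda: Constant(1))
    displacement_mode: str = "paper_literal"
    poisson_counts: bool = False

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if not (0.0 <= self.fraction_clustered <= 1.0):
            raise ValueError("fraction_clustered must be in [0, 1]")
        if self.fraction_clustered > 0 and self.cluster_radius <= 0:
            raise ValueError("cluster_radius must be > 0 when molecules are clustered")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")

    @classmethod
    def from_stats(cls, stats: BlinkStats, **kwargs) -> "ClusterScenario":
        """Scenario whose N source is a measured blinking histogram."""
        return cls(n_source=Empirical(stats.hist_N), **kwargs)


@dataclass
class SimulatedMap:
    """Ground-truth molecules plus their blinking-overlaid detection map."""

    molecules: np.ndarray  # (n_mol, 2) nm
    in_cluster: np.ndarray  # bool per molecule
    detections: np.ndarray  # (n_det, 2) nm
    molecule_index: np.ndarray  # detection -> molecule row
    scenario: ClusterScenario


def _truncated_gaussian_offsets(
    n: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Isotropic 2-D Gaussian offsets rejected to radius <= sigma."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        need = n - filled
        # acceptance ~39%; oversample to keep iterations low
        cand = rng.normal(0.0, sigma, size=(int(need * 3) + 8, 2))
        ok = cand[np.hypot(cand[:, 0], cand[:, 1]) <= sigma]
        take = min(len(ok), need)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def place_molecules(
    scenario: ClusterScenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ground-truth molecule positions for a scenario.

    Returns ``(positions, in_cluster)``.  Cluster centers are uniform on the
    ROI; clustered molecules are distributed uniformly among clusters and
    offset by a radially truncated Gaussian; the rest are placed uniformly
    outside the union of cluster discs (rejection sampling).
    """
    area = scenario.roi.area_um2
    if scenario.poisson_counts:
        n_mol = int(rng.poisson(scenario.density * area))
        n_clusters = int(rng.poisson(scenario.clusters_per_um2 * area))
    else:
        n_mol = round(scenario.density * area)
        n_clusters = round(scenario.clusters_per_um2 * area)
    n_in = round(scenario.fraction_clustered * n_mol)
    if n_in > 0 and n_clusters == 0:
        raise ValueError("fraction_clustered > 0 requires at least one cluster")

    roi = scenario.roi
    centers = np.column_stack((
        rng.uniform(roi.x0, roi.x1, size=n_clusters),
        rng.uniform(roi.y0, roi.y1, size=n_clusters),
    ))

    parts = []
    if n_in:
        assign = rng.integers(0, n_clusters, size=n_in)
        offsets = _truncated_gaussian_offsets(n_in, scenario.cluster_radius, rng)
        parts.append(centers[assign] + offsets)
    n_out = n_mol - n_in
    if n_out:
        tree = cKDTree(centers) if n_clusters else None
        collected: list[np.ndarray] = []
        remaining = n_out
        for _ in range(1000):
            if remaining <= 0:
                break
            cand = np.column_stack((
                rng.uniform(roi.x0, roi.x1, size=remaining * 2 + 8),
                rng.uniform(roi.y0, roi.y1, size=remaining * 2 + 8),
            ))
            if tree is not None and scenario.fraction_clustered > 0:
                d, _i = tree.query(cand, k=1)
                cand = cand[d > scenario.cluster_radius]
            take = cand[:remaining]
            collected.append(take)
            remaining -= len(take)
        if remaining > 0:
            raise RuntimeError(
                "could not place molecules outside clusters; cluster discs "
                "cover (nearly) the whole field")
        parts.append(np.vstack(collected))
    positions = np.vstack(parts) if parts else np.empty((0, 2))
    in_cluster = np.zeros(n_mol, dtype=bool)
    in_cluster[:n_in] = True
    return positions, in_cluster


def apply_blinking(
    positions: np.ndarray,
    n_source,
    sigma_loc: float,
    mode: str = "paper_literal",
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Overlay blinking overcounting and localization noise on molecule positions.

    Each molecule's detection count is drawn from ``n_source``; every
    detection is the molecule position displaced by the localization noise
    model (see :func:`palmblink.trace_model.displace`).  Returns the
    detection coordinates and the index of the parent molecule per detection.
    """
    rng = rng if rng is not None else np.random.default_rng()
    positions = np.asarray(positions, dtype=float)
    n_mol = len(positions)
    counts = np.asarray(n_source.sample(rng, n_mol), dtype=int)
    idx = np.repeat(np.arange(n_mol), counts)
    detections = displace(positions[idx], sigma_loc, mode, rng)
    return detections, idx


def simulate_map(scenario: ClusterScenario, rng: np.random.Generator) -> SimulatedMap:
    """Draw a complete simulated localization map for a scenario.

    Detections displaced beyond the ROI are kept (no clipping), so edge
    behavior is identical between candidate and reference maps generated the
    same way.
    """
    positions, in_cluster = place_molecules(scenario, rng)
    detections, idx = apply_blinking(
        positions, scenario.n_source, scenario.sigma_loc,
        scenario.displacement_mode, rng)
    return SimulatedMap(molecules=positions, in_cluster=in_cluster,
                        detections=detections, molecule_index=idx,
                        scenario=scenario)


def density_from_map(n_localizations: int, mean_N: float, area_um2: float) -> float:
    """Molecular density (per um^2) implied by a localization map.

    Divides the localization count by the mean number of detections per
    molecule, then by the map area: blinking-corrected expression level.
    """
    if mean_N < 1.0:
        raise ValueError("mean_N must be >= 1")
    if area_um2 <= 0:
        raise ValueError("area must be > 0")
    return n_localizations / mean_N / area_um2
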