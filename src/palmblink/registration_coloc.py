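"""Two-channel registration, platform-signal consolidation and co-localization.

The blinking probe is identified by co-localization with a second, spectrally
distinct label on the same platform molecule.  That requires (i) correcting
the platform channel for chromatic aberration with an affine transform fitted
to matched bead coordinates, (ii) merging the platform label's repeated
detections into one mean position per molecule, (iii) discarding platform
signals with a close neighbor (ambiguous assignment), and (iv) keeping only
probe localization clusters with a platform signal within the co-localization
radius -- which removes background decoys that have no platform partner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .trace_model import LocalizationTable

logger = logging.getLogger("palmblink")

__all__ = [
    "AffineTransform2D",
    "PlatformSignal",
    "fit_affine",
    "merge_platform",
    "filter_isolated",
    "colocalize",
    "false_positive_fold_reduction",
]


@dataclass(frozen=True)
class AffineTransform2D:
    """Affine map ``x -> A @ x + b`` on nm coordinates."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float))
        if self.matrix.shape != (2, 2) or self.offset.shape != (2,):
            raise ValueError("matrix must be 2x2 and offset length 2")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("singular linear part")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.matrix.T + self.offset

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))


@dataclass
class PlatformSignal:
    """A consolidated platform-channel molecule: mean position over merged detections."""

    position: tuple[float, float]
    n_merged: int
    signal_id: int = -1

    def __post_init__(self) -> None:
        if self.n_merged < 1:
            raise ValueError("n_merged must be >= 1")


def fit_affine(src: np.ndarray, dst: np.ndarray) -> tuple[AffineTransform2D, dict]:
    """Least-squares affine transform mapping ``src`` bead positions onto ``dst``.

    Requires at least 3 non-collinear pairs.  Returns the transform together
    with a residual report (RMS, max and per-pair residuals in nm).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (n, 2) arrays")
    n = len(src)
    if n < 3:
        raise ValueError(f"need >= 3 matched pairs to fit an affine transform, got {n}")
    design = np.column_stack((src, np.ones(n)))
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("matched pairs are collinear; affine transform is degenerate")
    coeffs, *_ = np.linalg.lstsq(design, dst, rcond=None)
    transform = AffineTransform2D(matrix=coeffs[:2].T, offset=coeffs[2])
    residuals = np.linalg.norm(transform.apply(src) - dst, axis=1)
    report = {
        "n_pairs": n,
        "rms_residual_nm": float(np.sqrt(np.mean(residuals**2))),
        "max_residual_nm": float(residuals.max()),
        "residuals_nm": residuals.tolist(),
    }
    return transform, report


def merge_platform(
    table: LocalizationTable,
    max_gap: int = 10_000,
    max_disp: float | None = None,
) -> list[PlatformSignal]:
    """Greedily chain platform detections into quasi-static signals.

    Detections are visited in frame order; a detection joins the nearest open
    signal whose running-mean position is within ``max_disp`` (default: one
    camera pixel) and whose last member is within ``max_gap`` frames.
    Ties on distance are broken toward the lower signal id.  Each signal's
    position is the mean of its members.
    """
    if max_disp is None:
        max_disp = table.pixel_size
    frames = table.frames
    xy = table.positions
    order = np.argsort(frames, kind="stable")

    # open signals held in growable arrays; running mean = sum / count
    cap = 256
    sums = np.empty((cap, 2))
    counts = np.empty(cap, dtype=int)
    last = np.empty(cap, dtype=int)
    n_sig = 0
    for idx in order:
        f = int(frames[idx])
        p = xy[idx]
        best = -1
        if n_sig:
            means = sums[:n_sig] / counts[:n_sig, None]
            d = np.hypot(means[:, 0] - p[0], means[:, 1] - p[1])
            d[f - last[:n_sig] > max_gap] = np.inf
            cand = int(np.argmin(d))  # argmin keeps the lower id on exact ties
            if d[cand] <= max_disp:
                best = cand
        if best >= 0:
            sums[best] += p
            counts[best] += 1
            last[best] = f
        else:
            if n_sig == cap:
                cap *= 2
                sums = np.concatenate((sums, np.empty((n_sig, 2))))
                counts = np.concatenate((counts, np.empty(n_sig, dtype=int)))
                last = np.concatenate((last, np.empty(n_sig, dtype=int)))
            sums[n_sig] = p
            counts[n_sig] = 1
            last[n_sig] = f
            n_sig += 1
    return [
        PlatformSignal(position=(sums[i, 0] / counts[i], sums[i, 1] / counts[i]),
                       n_merged=int(counts[i]), signal_id=i)
        for i in range(n_sig)
    ]


def filter_isolated(
    signals: list[PlatformSignal], min_nn: float = 500.0
) -> list[PlatformSignal]:
    """Discard signals whose nearest neighbor is closer than ``min_nn`` nm.

    The rule is symmetric: both members of a close pair are removed.  A signal
    at exactly ``min_nn`` from its nearest neighbor is kept (the cut is on
    distances *smaller than* the threshold).
    """
    if len(signals) < 2:
        return list(signals)
    pos = np.asarray([s.position for s in signals])
    tree = cKDTree(pos)
    dists, _ = tree.query(pos, k=2)
    keep = dists[:, 1] >= min_nn
    return [s for s, k in zip(signals, keep) if k]


def colocalize(
    probe_clusters: list[tuple[np.ndarray, np.ndarray]],
    platform_signals: list[PlatformSignal],
    radius: float = 500.0,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], float]:
    """Retain probe clusters with a platform signal within ``radius`` of the center.

    ``probe_clusters`` is a list of ``(center, member_positions)`` pairs whose
    centers are the member means.  Returns the retained clusters and the
    retained fraction.  With no platform signals every cluster is rejected
    and a warning is emitted.
    """
    if not probe_clusters:
        return [], float("nan")
    if not platform_signals:
        logger.warning("no platform signals: rejecting all %d probe clusters",
                       len(probe_clusters))
        return [], 0.0
    centers = np.asarray([np.asarray(c, dtype=float) for c, _ in probe_clusters])
    tree = cKDTree(np.asarray([s.position for s in platform_signals]))
    dists, _ = tree.query(centers, k=1)
    keep = dists <= radius
    retained = [pc for pc, k in zip(probe_clusters, keep) if k]
    fraction = float(keep.mean())
    logger.info("colocalize: retained %d/%d clusters (%.1f%%) at radius %.0f nm",
                len(retained), len(probe_clusters), 100 * fraction, radius)
    return retained, fraction


def false_positive_fold_reduction(coloc_fraction: float) -> int:
    """Fold reduction in false positives achieved by the two-color protocol.

    If only a fraction ``f`` of channel-only control detections survive the
    co-localization filter, false positives are reduced ``round(1/f)``-fold.
    """
    if not (0.0 < coloc_fraction <= 1.0):
        raise ValueError("coloc_fraction must be in (0, 1]")
    return round(1.0 / coloc_fraction)
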