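"""Group-level resting-state network extraction from megPAC series.

Per-subject megPAC series are spatially smoothed (Gaussian, 7 mm FWHM),
z-scored per vertex, and concatenated over subjects. The Pearson correlation
matrix over an evenly distributed vertex subset is decomposed by SVD; the
first ten spatial modes are the RSNs. Full-resolution coupling-strength maps
are recovered by correlating every vertex's series with each mode's time
course and rescaling to [0, 1] (absolute value over map maximum), so the
"40 % of maximum" thresholds downstream are well defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .mesh import CorticalMesh

__all__ = [
    "ReductionPlan",
    "RSNSet",
    "smoothing_matrix",
    "smooth_series",
    "select_even_subset",
    "zscore_rows",
    "extract_rsns",
]

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class ReductionPlan:
    """Evenly distributed vertex subset used for the correlation SVD."""

    subset_indices: np.ndarray  # unique, sorted-free (FPS order)
    method: str
    k: int


@dataclass(frozen=True)
class RSNSet:
    """Ten spatial modes with coupling strength in [0, 1] per vertex."""

    modes: np.ndarray            # (n_modes, n_vertices) maps in [0, 1]
    singular_values: np.ndarray  # (n_modes,) non-increasing
    subset_used: ReductionPlan
    subset_modes: np.ndarray     # (k, n_modes) orthonormal subset vectors

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


# ---------------------------------------------------------------------------
# smoothing


def smoothing_matrix(mesh: CorticalMesh, fwhm_mm: float,
                     tol: float = 1e-12, max_iter: int = 10_000) -> np.ndarray:
    """Doubly stochastic Gaussian smoothing operator on the mesh.

    Gaussian kernel exp(-d^2 / (2 sigma^2)) with sigma = fwhm / 2.3548 over
    Euclidean inter-vertex distances, balanced by symmetric Sinkhorn scaling
    so that every row sums to 1 (spatially constant maps are preserved) and
    every column sums to 1 (the global mean of each time sample is preserved).
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm_mm / FWHM_TO_SIGMA
    d = mesh.vertex_distances()
    with np.errstate(under="ignore"):
        kernel = np.exp(-0.5 * (d / sigma) ** 2)
    u = np.ones(mesh.n_vertices)
    for _ in range(max_iter):
        ku = kernel @ u
        err = np.max(np.abs(u * ku - 1.0))
        if err < tol:
            break
        u = np.sqrt(u / ku)
    else:  # pragma: no cover
        warnings.warn("Sinkhorn balancing did not fully converge")
    w = kernel * np.outer(u, u)
    return w


def smooth_series(mesh: CorticalMesh, series: np.ndarray,
                  fwhm_mm: float = 7.0) -> np.ndarray:
    """Spatially smooth a (n_vertices, n_samples) series on the mesh."""
    series = np.asarray(series, float)
    if series.shape[0] != mesh.n_vertices:
        raise ValueError(
            f"series has {series.shape[0]} rows but mesh has "
            f"{mesh.n_vertices} vertices"
        )
    return smoothing_matrix(mesh, fwhm_mm) @ series


# ---------------------------------------------------------------------------
# even-source reduction


def select_even_subset(mesh: CorticalMesh, k: int,
                       start_vertex: int = 0) -> ReductionPlan:
    """Deterministic farthest-point sampling of ``k`` vertices.

    Starts at ``start_vertex`` and greedily adds the vertex farthest
    (Euclidean) from the current subset; ties break to the lowest index.
    """
    n = mesh.n_vertices
    if not 2 <= k <= n:
        raise ValueError(f"k = {k} outside [2, {n}]")
    coords = mesh.vertex_coords
    chosen = [int(start_vertex)]
    min_d = np.linalg.norm(coords - coords[start_vertex], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(min_d))
        chosen.append(nxt)
        d = np.linalg.norm(coords - coords[nxt], axis=1)
        min_d = np.minimum(min_d, d)
    return ReductionPlan(np.asarray(chosen, int), "farthest-point", k)


def subset_spread(mesh: CorticalMesh, plan: ReductionPlan) -> tuple[float, float]:
    """(covering radius, ideal uniform spacing sqrt(area / k)) in mm."""
    coords = mesh.vertex_coords
    sub = coords[plan.subset_indices]
    d = np.linalg.norm(coords[:, None, :] - sub[None, :, :], axis=2)
    covering = float(d.min(axis=1).max())
    ideal = float(np.sqrt(mesh.surface_area() / plan.k))
    return covering, ideal


# ---------------------------------------------------------------------------
# SVD network extraction


def zscore_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise z-score (population sd); zero-variance rows map to zeros."""
    x = np.asarray(x, float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    out = x - mu
    nz = sd[:, 0] > 0
    out[nz] /= sd[nz]
    out[~nz] = 0.0
    return out


def extract_rsns(series_by_subject: dict, plan: ReductionPlan,
                 n_modes: int = 10) -> RSNSet:
    """Group RSNs from per-subject megPAC series of one condition.

    Each subject's (n_vertices, n_samples) series is z-scored per vertex and
    the subjects are concatenated along time. The Pearson correlation matrix
    over the subset vertices is decomposed by SVD; full-resolution maps come
    from correlating every vertex with each subset mode's time course
    (back-projection), then |r| / max|r| per mode.
    """
    if not series_by_subject:
        raise ValueError("no subjects given")
    blocks = [zscore_rows(s) for s in series_by_subject.values()]
    n_v = blocks[0].shape[0]
    if any(b.shape[0] != n_v for b in blocks):
        raise ValueError("subjects disagree on vertex count")
    z = np.hstack(blocks)  # (V, T_total); rows zero-mean, unit (or zero) var
    t_tot = z.shape[1]
    sub = plan.subset_indices
    if t_tot < len(sub):
        warnings.warn(
            f"only {t_tot} time samples for {len(sub)} subset vertices: "
            "correlation matrix is rank deficient"
        )
    if n_modes > len(sub):
        raise ValueError("n_modes exceeds subset size")
    zs = z[sub]
    corr = (zs @ zs.T) / t_tot  # Pearson: rows are zero-mean, unit variance
    u, s, _ = np.linalg.svd(corr, hermitian=True)
    u = u[:, :n_modes]
    s = s[:n_modes]
    # deterministic sign: largest-magnitude component of each mode positive
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(n_modes)])
    flip[flip == 0] = 1.0
    u = u * flip

    tc = u.T @ zs  # (n_modes, T) mode time courses, zero mean
    tc_sd = tc.std(axis=1, keepdims=True)
    tc_n = np.divide(tc, tc_sd, out=np.zeros_like(tc), where=tc_sd > 0)
    r = (z @ tc_n.T) / t_tot  # (V, n_modes) correlations in [-1, 1]
    maps = np.abs(r.T)  # (n_modes, V)
    mx = maps.max(axis=1, keepdims=True)
    np.divide(maps, mx, out=maps, where=mx > 0)
    return RSNSet(maps, s, plan, u)
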