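"""Superposition, GROMOS-style clustering and sampling-convergence diagnostics.

Rigid-body superposition is the least-squares optimal rotation (Kabsch);
pairwise post-fit backbone RMSD feeds the neighbour-counting (GROMOS)
clustering whose largest-cluster centroid is the "most representative
structure" of an ensemble.  Convergence of sampling is judged from a standard
positional covariance analysis: projections of the trajectory onto the top
eigenvectors are compared with the half-cosine shapes expected for random
diffusion (Hess's cosine content); values near 1 indicate unconverged,
diffusion-like sampling, values near 0 sampling around an equilibrium.

No mass-weighting is applied to RMSD or covariance by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import BACKBONE_ATOMS, Ensemble, Frame


class DegenerateSelectionError(ValueError):
    """Fewer than 3 atoms, or a collinear selection: rotation is ill-posed."""


def backbone_indices(ensemble_or_frame: Ensemble | Frame) -> list[int]:
    """Indices of backbone atoms (N, CA, C, O) in the topology."""
    return [
        i
        for i, rec in enumerate(ensemble_or_frame.topology)
        if rec.name in BACKBONE_ATOMS
    ]


def _check_selection(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise DegenerateSelectionError("need >= 3 atoms for superposition")
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise DegenerateSelectionError("selection is collinear")


def kabsch_superpose(
    reference: Frame | np.ndarray,
    mobile: Frame | np.ndarray,
    selection: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference in the
    least-squares sense; the rotation is proper (det = +1) and ``rmsd`` is
    the post-fit value in nm over the selection.
    """
    xr = reference.coords if isinstance(reference, Frame) else np.asarray(reference, float)
    xm = mobile.coords if isinstance(mobile, Frame) else np.asarray(mobile, float)
    if selection is not None:
        sel = list(selection)
        xr, xm = xr[sel], xm[sel]
    if xr.shape != xm.shape:
        raise ValueError("selection does not map 1:1 between frames")
    _check_selection(xr)
    _check_selection(xm)
    cr = xr.mean(axis=0)
    cm = xm.mean(axis=0)
    rot, _ = Rotation.align_vectors(xr - cr, xm - cm)
    R = rot.as_matrix()
    t = cr - cm @ R.T
    fitted = xm @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - xr) ** 2, axis=1))))
    return R, t, rmsd


def superpose_coords(
    reference: np.ndarray, mobile: np.ndarray, selection: Sequence[int] | None = None
) -> np.ndarray:
    """Apply the optimal fit (computed on ``selection``) to all atoms."""
    R, t, _ = kabsch_superpose(reference, mobile, selection)
    return mobile @ R.T + t


def rmsd_series(
    ensemble: Ensemble,
    reference: Frame | np.ndarray | None = None,
    selection: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-frame post-fit RMSD (nm) against a reference frame.

    Defaults: reference = first frame; selection = backbone atoms (N, CA, C,
    O), the conventional choice for stability monitoring.
    """
    if selection is None:
        selection = backbone_indices(ensemble)
    if reference is None:
        reference = ensemble.frame(0)
    return np.array(
        [
            kabsch_superpose(reference, ensemble.frame(i), selection)[2]
            for i in range(ensemble.n_frames)
        ]
    )


def pairwise_rmsd(ensemble: Ensemble, selection: Sequence[int] | None = None) -> np.ndarray:
    """Symmetric matrix of post-fit RMSDs between all frame pairs."""
    if selection is None:
        selection = backbone_indices(ensemble)
    sel = list(selection)
    X = ensemble.coords[:, sel, :]
    n = ensemble.n_frames
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch_superpose(X[i], X[j])
            D[i, j] = D[j, i] = r
    return D


@dataclass(frozen=True)
class ClusterResult:
    """Neighbour-counting clustering of an ensemble at a fixed RMSD cutoff."""

    cutoff: float
    membership: tuple[int, ...]  # frame -> cluster id (0 = largest-first order)
    sizes: tuple[int, ...]  # descending
    centroids: tuple[int, ...]  # centroid frame index per cluster id

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def coverage(self) -> float:
        """Fraction of frames in the largest cluster."""
        return self.sizes[0] / len(self.membership)


def gromos_cluster(
    ensemble: Ensemble,
    cutoff: float = 0.2,
    selection: Sequence[int] | None = None,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterResult:
    """GROMOS neighbour-counting clustering under a pairwise-RMSD cutoff.

    Iteratively: the frame with the most neighbours within ``cutoff`` becomes
    a cluster centroid; it and its neighbours are removed; repeat.  Ties are
    broken toward the lowest frame index, making the result deterministic.
    Default cutoff 0.2 nm on backbone atoms.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    D = pairwise_rmsd(ensemble, selection) if rmsd_matrix is None else rmsd_matrix
    n = D.shape[0]
    neighbor = D < cutoff  # includes self on the diagonal (D=0)
    remaining = np.ones(n, dtype=bool)
    membership = np.full(n, -1, dtype=int)
    clusters: list[tuple[int, list[int]]] = []
    while remaining.any():
        counts = (neighbor & remaining).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(neighbor[center] & remaining)[0]
        clusters.append((center, members.tolist()))
        remaining[members] = False
    # Order clusters by size descending, then centroid index for determinism.
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    sizes = []
    centroids = []
    for cid, (center, members) in enumerate(clusters):
        sizes.append(len(members))
        centroids.append(center)
        for m in members:
            membership[m] = cid
    return ClusterResult(
        cutoff=float(cutoff),
        membership=tuple(int(m) for m in membership),
        sizes=tuple(sizes),
        centroids=tuple(centroids),
    )


def representative_structure(result: ClusterResult) -> tuple[int, float]:
    """Centroid frame of the largest cluster and its coverage fraction.

    Coverage lets the caller check the "more than half of the sampled
    conformations" condition explicitly.
    """
    if result.n_clusters < 1:
        raise ValueError("no clusters")
    return result.centroids[0], result.coverage


# ---------------------------------------------------------------------------
# Covariance analysis / cosine content
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovarianceResult:
    """Eigen-decomposition of the positional covariance of a fitted ensemble."""

    eigenvalues: np.ndarray  # descending, nm^2
    eigenvectors: np.ndarray  # (3N, n_modes), columns
    projections: np.ndarray  # (n_frames, n_modes)
    mean: np.ndarray  # (N, 3) mean structure after fitting
    fitted: np.ndarray  # (n_frames, N, 3) superposed selection coordinates


def covariance_modes(
    ensemble: Ensemble,
    selection: Sequence[int] | None = None,
    n_modes: int | None = None,
    superpose: bool = True,
) -> CovarianceResult:
    """Positional covariance analysis over a selection.

    Frames are superposed onto the ensemble mean with a single fit-to-mean
    iteration (fit to frame 0, recompute the mean, refit), then the 3N×3N
    covariance matrix is diagonalised.  Projections are the deviations of
    each fitted frame onto the eigenvectors, largest-variance mode first.
    ``superpose=False`` analyses raw coordinates (useful when the input is
    already aligned, or when internal motion must not be mixed with the
    compensating rigid-body component the fit introduces).
    """
    if selection is None:
        selection = backbone_indices(ensemble)
    sel = list(selection)
    X = ensemble.coords[:, sel, :]
    n_frames, n_atoms, _ = X.shape
    dof = 3 * n_atoms
    if n_modes is None:
        n_modes = min(dof, 10)
    if n_modes > dof:
        raise ValueError(f"n_modes {n_modes} > 3N = {dof}")
    if superpose:
        # One fit-to-mean iteration.
        fitted = np.array([superpose_coords(X[0], X[i]) for i in range(n_frames)])
        mean = fitted.mean(axis=0)
        fitted = np.array([superpose_coords(mean, fitted[i]) for i in range(n_frames)])
    else:
        fitted = X.copy()
    mean = fitted.mean(axis=0)
    dev = (fitted - mean).reshape(n_frames, dof)
    cov = (dev.T @ dev) / n_frames
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    proj = dev @ v[:, :n_modes]
    return CovarianceResult(
        eigenvalues=w,
        eigenvectors=v[:, :n_modes],
        projections=proj,
        mean=mean,
        fitted=fitted,
    )


def cosine_content(projection: np.ndarray, mode_index: int = 1) -> float:
    """Hess cosine content of one principal-component projection.

    Discrete form of ``c_i = (2/T) (∫ p(t) cos(iπt/T) dt)² / ∫ p(t)² dt``
    with trapezoidal integration on t = 0..T.  1 means the projection is a
    pure half-cosine of order ``i`` (the random-diffusion signature); 0 means
    no such component.  Bounded in [0, 1] by Cauchy–Schwarz.
    """
    p = np.asarray(projection, float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("projection must be a 1-D series of length >= 2")
    if mode_index < 1:
        raise ValueError("mode_index must be >= 1")
    denom_p2 = np.trapezoid(p * p, dx=1.0)
    if denom_p2 <= 0:
        raise ValueError("all-zero projection series: cosine content undefined")
    T = p.size - 1
    t = np.arange(p.size, dtype=float)
    c = np.cos(mode_index * np.pi * t / T)
    num = np.trapezoid(p * c, dx=1.0) ** 2
    return float((2.0 / T) * num / denom_p2)


@dataclass(frozen=True)
class ConvergenceReport:
    """Sampling-adequacy diagnostics for one ensemble window."""

    eigenvalues: np.ndarray
    projections: np.ndarray  # (n_frames, n_modes)
    cosine_contents: tuple[float, ...]
    rmsd: np.ndarray  # per-frame backbone RMSD vs the reference frame

    def to_dict(self) -> dict:
        return {
            "eigenvalues_nm2": [float(x) for x in self.eigenvalues],
            "cosine_contents": list(self.cosine_contents),
            "rmsd_nm": [float(x) for x in self.rmsd],
        }


def convergence_report(
    ensemble: Ensemble,
    selection: Sequence[int] | None = None,
    n_modes: int = 2,
) -> ConvergenceReport:
    """Covariance modes, cosine contents of the top projections, RMSD series."""
    if selection is None:
        selection = backbone_indices(ensemble)
    modes = covariance_modes(ensemble, selection, n_modes=n_modes)
    contents = []
    for i in range(min(n_modes, modes.projections.shape[1])):
        p = modes.projections[:, i]
        if np.allclose(p, 0.0):
            contents.append(0.0)  # frozen mode: no diffusion signature
        else:
            contents.append(cosine_content(p, i + 1))
    rmsd = rmsd_series(ensemble, selection=selection)
    return ConvergenceReport(
        eigenvalues=modes.eigenvalues,
        projections=modes.projections,
        cosine_contents=tuple(contents),
        rmsd=rmsd,
    )
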