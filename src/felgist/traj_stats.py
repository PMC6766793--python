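"""2D-RMSD matrices and principal component analysis of MD frames.

The superposition primitive is the least-squares optimal rigid fit
(Kabsch), restricted to proper rotations and with uniform weights —
appropriate for backbone-only selections. The all-against-all RMSD matrix
uses an independent best fit per frame pair. PCA aligns every frame to the
iteratively refined average structure on an alignment selection (typically
the protein backbone), then diagonalizes the covariance of the analysis
selection's 3N coordinates; analysing a ligand while aligning on the
backbone deliberately retains the ligand's translational and rotational
motion inside the site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .io_formats import Frame, Trajectory
from .selections import Selection

__all__ = ["Rmsd2D", "PcaResult", "kabsch_superpose", "rmsd2d", "pca"]


@dataclass
class Rmsd2D:
    matrix: np.ndarray   # (n_frames, n_frames), Å
    selection: str


@dataclass
class PcaResult:
    mean_structure: Frame
    eigenvalues: np.ndarray      # descending, Å²
    eigenvectors: np.ndarray     # (3N, n_components), orthonormal columns
    projections: np.ndarray      # (n_frames, n_components)


def _check_fit_input(mobile: np.ndarray, target: np.ndarray) -> None:
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must both be (n, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    for name, x in (("mobile", mobile), ("target", target)):
        rank = np.linalg.matrix_rank(x - x.mean(axis=0), tol=1e-8)
        if rank < 2:
            raise ValueError(f"{name} coordinates are collinear")


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``target`` in the
    least-squares sense; the rotation is proper (det = +1) and the RMSD is
    evaluated after the fit.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    _check_fit_input(mobile, target)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - R @ mc
    rmsd = float(rssd / np.sqrt(mobile.shape[0]))
    return R, t, rmsd


def _apply(R: np.ndarray, t: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def rmsd2d(traj: Trajectory, selection: Selection | None = None) -> Rmsd2D:
    """All-frames-against-all-frames RMSD with a pairwise best fit.

    Defaults to the protein backbone selection. The matrix is symmetric
    with a zero diagonal by construction.
    """
    sel = selection or Selection("backbone")
    idx = sel.indices(traj.atoms)
    if idx.size < 3:
        raise ValueError(f"selection {sel.expression!r} has fewer than 3 atoms")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    X = traj.coords[:, idx] - traj.coords[:, idx].mean(axis=1, keepdims=True)
    n = traj.n_frames
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, rssd = Rotation.align_vectors(X[i], X[j])
            m[i, j] = m[j, i] = rssd / np.sqrt(idx.size)
    return Rmsd2D(matrix=m, selection=sel.expression)


def pca(
    traj: Trajectory,
    selection: Selection,
    align_selection: Selection | None = None,
    n_components: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PcaResult:
    """Covariance-matrix PCA of the selected atoms after alignment to the
    iteratively refined average structure.

    The alignment transform is computed on ``align_selection`` (default:
    protein backbone) and applied to all atoms; iteration stops when the
    mean structure moves by less than ``tol`` Å (max per-atom displacement).
    """
    align_sel = align_selection or Selection("backbone")
    a_idx = align_sel.indices(traj.atoms)
    s_idx = selection.indices(traj.atoms)
    if a_idx.size < 3:
        raise ValueError("alignment selection needs at least 3 atoms")
    if s_idx.size == 0:
        raise ValueError("empty analysis selection")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")

    aligned = np.array(traj.coords, dtype=float, copy=True)
    mean = aligned.mean(axis=0)
    for it in range(max_iter):
        for f in range(traj.n_frames):
            R, t, _ = kabsch_superpose(aligned[f, a_idx], mean[a_idx])
            aligned[f] = _apply(R, t, aligned[f])
        new_mean = aligned.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    else:
        raise RuntimeError(
            f"average-structure alignment did not converge in {max_iter} "
            f"iterations (last mean shift {shift:.2e} Å)"
        )

    X = aligned[:, s_idx].reshape(traj.n_frames, -1)
    mu = X.mean(axis=0)
    cov = np.cov(X - mu, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if n_components is not None:
        evals, evecs = evals[:n_components], evecs[:, :n_components]
    projections = (X - mu) @ evecs
    return PcaResult(
        mean_structure=Frame(mean, frame_index=0, time_ps=0.0),
        eigenvalues=evals,
        eigenvectors=evecs,
        projections=projections,
    )
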