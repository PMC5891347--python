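"""Superposition, covariance construction, PCA, and free-energy projection.

The essential-dynamics workflow: every frame is rigidly superposed onto a
fixed reference over a Cα selection (Kabsch), the 3N×3N positional
covariance C = ⟨(R−⟨R⟩)(R−⟨R⟩)ᵀ⟩ is built over the selection (population
normalisation, divide by the number of frames), and its eigendecomposition
C = Σᵢ σᵢ pᵢ pᵢᵀ yields principal components ordered by descending variance.
Frame projections onto PCs give reaction coordinates whose histogrammed
density f is Boltzmann-inverted into a free-energy surface
A = −kT ln f + const.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from cypdyn.structio import Structure, Trajectory

#: Boltzmann constant in kcal/mol/K
KB_KCAL = 0.0019872


def thermal_energy(temperature: float) -> float:
    """kT in kcal/mol at a temperature in K (0.616 kcal/mol at 310 K)."""
    return KB_KCAL * temperature


@dataclass
class CovarianceModel:
    """Mean configuration, covariance, and (optionally) its eigensystem.

    ``mean`` is the 3N trajectory-average configuration (Å), ``matrix`` the
    3N×3N covariance (Ų). After :func:`eigendecompose`, ``components`` holds
    unit principal components as rows and ``variances`` their σᵢ in Ų,
    descending.
    """

    selection: np.ndarray
    mean: np.ndarray
    matrix: np.ndarray
    components: np.ndarray | None = None
    variances: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.selection)

    def msf_per_atom(self) -> np.ndarray:
        """Per-atom mean-square fluctuation (Ų) from the 3×3 diagonal blocks."""
        d = np.diag(self.matrix)
        return d.reshape(-1, 3).sum(axis=1)


@dataclass
class FreeEnergySurface:
    """Normalised projection density and its Boltzmann inversion.

    ``edges`` holds one bin-edge array per axis; ``density`` integrates to 1
    over the grid; ``energy`` is −kT ln f shifted so the lowest finite value
    is 0, with empty bins at +inf.
    """

    axes: tuple[int, ...]
    edges: list[np.ndarray]
    density: np.ndarray
    energy: np.ndarray
    kT: float

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of mobile onto reference.

    The optimal proper rotation is found over the selection atoms (all atoms
    if None) and applied to the full mobile coordinate set. Returns
    (rotation 3×3, translation 3-vector, transformed coords, selection RMSD);
    ``transformed = mobile @ rotation.T + translation``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise ValueError("superposition requires at least 3 selection atoms")
    msel = mobile[sel]
    rsel = reference[sel]
    mc = msel.mean(axis=0)
    rc = rsel.mean(axis=0)
    a = msel - mc
    b = rsel - rc
    s = np.linalg.svd(a, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("selection atoms are collinear; rotation is degenerate")
    rot, _ = Rotation.align_vectors(b, a)  # proper rotation, det=+1
    R = rot.as_matrix()
    t = rc - mc @ R.T
    transformed = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((transformed[sel] - rsel) ** 2, axis=1))))
    return R, t, transformed, rmsd


def align_trajectory(
    traj: Trajectory, reference: Structure, selection: np.ndarray
) -> Trajectory:
    """Superpose every frame onto the fixed reference over the selection.

    Single-pass alignment to the given reference (not iteratively onto the
    evolving mean). Errors from degenerate frames carry the frame index.
    """
    out = np.empty_like(traj.coords)
    ref = reference.coords
    for i, frame in enumerate(traj.coords):
        try:
            _, _, out[i], _ = kabsch_superpose(frame, ref, selection)
        except ValueError as exc:
            raise ValueError(f"alignment failed at frame {i}: {exc}") from exc
    return Trajectory(
        structure=traj.structure,
        coords=out,
        frame_interval_ps=traj.frame_interval_ps,
        production_length_ns=traj.production_length_ns,
        aligned=True,
    )


def compute_covariance(traj: Trajectory, selection: np.ndarray) -> CovarianceModel:
    """Population covariance of the 3N configuration vectors over frames."""
    if traj.n_frames < 2:
        raise ValueError("covariance requires at least 2 frames")
    X = traj.coords[:, selection, :].reshape(traj.n_frames, -1)
    mean = X.mean(axis=0)
    d = X - mean
    matrix = d.T @ d / traj.n_frames
    return CovarianceModel(selection=np.asarray(selection), mean=mean, matrix=matrix)


def eigendecompose(model: CovarianceModel) -> CovarianceModel:
    """Fill the model's principal components and variances, descending.

    Eigenvalues below −1e-8·trace are an error (the matrix is not a valid
    covariance); small negative values from round-off are clamped to 0. Each
    component's sign is fixed so its largest-magnitude entry is positive.
    """
    C = model.matrix
    if not np.allclose(C, C.T, atol=1e-8 * max(1.0, np.abs(C).max())):
        raise ValueError("covariance matrix is not symmetric")
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    trace = np.trace(C)
    if evals.min() < -1e-8 * max(trace, 1.0):
        raise ValueError(f"covariance has a significantly negative eigenvalue: {evals.min()}")
    evals = np.clip(evals, 0.0, None)
    comps = evecs.T
    for i in range(len(comps)):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    model.components = comps
    model.variances = evals
    return model


def project(
    traj: Trajectory, model: CovarianceModel, pcs: tuple[int, ...] = (0, 1)
) -> np.ndarray:
    """Per-frame scores along principal components (0-based indices).

    score_i(t) = p_i · (R(t) − ⟨R⟩). The trajectory must already be aligned
    to the same reference with the same selection the model was built from.
    Returns an array of shape (n_frames, len(pcs)) in Å.
    """
    if model.components is None:
        raise ValueError("model has no components; call eigendecompose first")
    if model.selection.max() >= traj.coords.shape[1]:
        raise ValueError(
            f"selection mismatch: model selection indexes atom {model.selection.max()}, "
            f"trajectory has {traj.coords.shape[1]} atoms"
        )
    X = traj.coords[:, model.selection, :].reshape(traj.n_frames, -1)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"selection mismatch: model expects dimension {model.mean.shape[0]}, "
            f"trajectory provides {X.shape[1]}"
        )
    return (X - model.mean) @ model.components[list(pcs)].T


def free_energy_surface(
    scores: np.ndarray,
    bins: int | tuple[int, ...] = 50,
    kT: float = thermal_energy(310.0),
    axes: tuple[int, ...] | None = None,
) -> FreeEnergySurface:
    """Boltzmann inversion of a 1-D or 2-D projection-score density.

    A = −kT ln f with the lowest finite value shifted to 0; bins with zero
    density get infinite energy (never a capped finite value).
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] < 1:
        raise ValueError("at least one score is required")
    ndim = scores.shape[1]
    if isinstance(bins, int):
        bins = (bins,) * ndim
    if any(b < 1 for b in bins):
        raise ValueError("bin counts must be positive")
    density, edges = np.histogramdd(scores, bins=bins, density=True)
    # histogramdd collapses degenerate ranges itself (identical scores land
    # in one occupied bin)
    with np.errstate(divide="ignore"):
        energy = -kT * np.log(density)
    finite = np.isfinite(energy)
    if finite.any():
        energy = energy - energy[finite].min()
    return FreeEnergySurface(
        axes=tuple(axes) if axes is not None else tuple(range(ndim)),
        edges=[np.asarray(e) for e in edges],
        density=density,
        energy=energy,
        kT=kT,
    )
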