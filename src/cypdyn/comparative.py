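"""Cross-system comparisons: distance-change maps, dynamic cross-correlation
maps, anticorrelation differences, and per-domain-aligned intradomain
correlations/fluctuations.

Dynamic cross-correlations use the standard convention
c_ij = ⟨ΔR_i·ΔR_j⟩ / (⟨ΔR_i²⟩⟨ΔR_j²⟩)^½ built from the 3×3 residue blocks of
the Cα covariance. Difference maps classify residue pairs whose mean Cα–Cα
distance or anticorrelation changed between two systems (e.g. wild type vs
a mutant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from cypdyn.descriptors import FluctuationProfile
from cypdyn.pca import CovarianceModel, align_trajectory, compute_covariance
from cypdyn.structio import Structure, Trajectory, select_calpha

# classification codes shared by both map types
DECREASE = -1   # distance decrease / more anticorrelated ("black"/"red" per map)
UNCLASSIFIED = 0
INCREASE = 1    # distance increase / less anticorrelated


@dataclass
class MeanDistanceMatrix:
    """Trajectory-averaged Cα–Cα distances d_ij (Å), symmetric, zero diagonal."""

    resids: np.ndarray
    matrix: np.ndarray


@dataclass
class CorrelationMatrix:
    """Normalised residue–residue cross-correlations in [−1, 1].

    Residues with zero positional variance get NaN rows/columns and are
    listed in ``undefined``.
    """

    resids: np.ndarray
    matrix: np.ndarray
    alignment: str = "global"
    undefined: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class DifferenceMap:
    """Signed residue-pair changes with a threshold classification.

    ``labels`` uses DECREASE (−1) / UNCLASSIFIED (0) / INCREASE (+1); for
    anticorrelation maps INCREASE means "less anticorrelated" and DECREASE
    "more anticorrelated". ``thresholds`` records the windows/margins used.
    """

    resids: np.ndarray
    delta: np.ndarray
    labels: np.ndarray
    thresholds: dict

    def pairs(self, label: int) -> list[tuple[int, int, float]]:
        """(res_i, res_j, delta) for classified pairs with i < j."""
        out = []
        n = len(self.resids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.labels[i, j] == label:
                    out.append((int(self.resids[i]), int(self.resids[j]),
                                float(self.delta[i, j])))
        return out


def mean_distance_matrix(traj: Trajectory, selection: np.ndarray) -> MeanDistanceMatrix:
    """Average the full Cα–Cα distance matrix over frames.

    Distances are rigid-motion invariant, so no alignment is required.
    """
    sel = np.asarray(selection)
    if sel.size == 0:
        raise ValueError("empty selection")
    if traj.n_frames < 1:
        raise ValueError("at least one frame is required")
    acc = np.zeros((len(sel), len(sel)))
    for frame in traj.coords:
        pts = frame[sel]
        acc += cdist(pts, pts)
    return MeanDistanceMatrix(
        resids=traj.structure.resids[sel].copy(),
        matrix=acc / traj.n_frames,
    )


def distance_change_map(
    mutant: MeanDistanceMatrix,
    wildtype: MeanDistanceMatrix,
    decrease_window: tuple[float, float] = (-10.0, -4.0),
    increase_window: tuple[float, float] = (4.0, 10.0),
    saturate: bool = False,
) -> DifferenceMap:
    """Classify residue-pair mean-distance changes Δ_ij = d_mut − d_wt.

    Pairs with Δ inside the decrease window (inclusive) are DECREASE, inside
    the increase window INCREASE, otherwise UNCLASSIFIED. With
    ``saturate=True`` the outer window edges act as saturation bounds
    (Δ < −10 still counts as a decrease, etc.); default is the strict
    windows exactly as printed.
    """
    if not np.array_equal(mutant.resids, wildtype.resids):
        raise ValueError("residue lists of the two systems differ")
    delta = mutant.matrix - wildtype.matrix
    lo_d, hi_d = decrease_window
    lo_i, hi_i = increase_window
    if saturate:
        dec = delta <= hi_d
        inc = delta >= lo_i
    else:
        dec = (delta >= lo_d) & (delta <= hi_d)
        inc = (delta >= lo_i) & (delta <= hi_i)
    labels = np.zeros(delta.shape, dtype=np.int8)
    labels[dec] = DECREASE
    labels[inc] = INCREASE
    np.fill_diagonal(labels, UNCLASSIFIED)
    return DifferenceMap(
        resids=mutant.resids.copy(),
        delta=delta,
        labels=labels,
        thresholds={
            "decrease_window": decrease_window,
            "increase_window": increase_window,
            "saturate": saturate,
        },
    )


def correlation_matrix(
    model: CovarianceModel, resids: np.ndarray, alignment: str = "global"
) -> CorrelationMatrix:
    """Normalised dynamic cross-correlation from a Cα covariance model.

    c_ij = trace(C_ij) / (trace(C_ii)·trace(C_jj))^½ over the 3×3 residue
    blocks — the 3-D vector-dot-product convention. Zero-variance residues
    are flagged and their rows/columns set to NaN.
    """
    n = model.n_atoms
    C = model.matrix.reshape(n, 3, n, 3)
    inner = np.einsum("ikjk->ij", C)  # ⟨ΔR_i · ΔR_j⟩
    msf = np.diag(inner).copy()
    undefined = np.flatnonzero(msf <= 1e-12 * max(float(msf.max()), 1e-300))
    denom = np.sqrt(np.outer(msf, msf))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = inner / denom
    corr[undefined, :] = np.nan
    corr[:, undefined] = np.nan
    return CorrelationMatrix(
        resids=np.asarray(resids).copy(),
        matrix=corr,
        alignment=alignment,
        undefined=undefined,
    )


def anticorrelation_difference_map(
    wildtype: CorrelationMatrix,
    mutant: CorrelationMatrix,
    anticorr_threshold: float = 0.1,
    margin: float = 0.05,
) -> DifferenceMap:
    """Changes in anticorrelated motion between two systems.

    Only pairs anticorrelated (c < −threshold) in at least one system are
    considered. A pair is INCREASE ("less anticorrelated") when
    c_mut − c_wt > margin and DECREASE ("more anticorrelated") when
    c_mut − c_wt < −margin.
    """
    if not np.array_equal(wildtype.resids, mutant.resids):
        raise ValueError("residue lists of the two systems differ")
    delta = mutant.matrix - wildtype.matrix
    considered = (wildtype.matrix < -anticorr_threshold) | (
        mutant.matrix < -anticorr_threshold
    )
    labels = np.zeros(delta.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        labels[considered & (delta > margin)] = INCREASE
        labels[considered & (delta < -margin)] = DECREASE
    np.fill_diagonal(labels, UNCLASSIFIED)
    return DifferenceMap(
        resids=wildtype.resids.copy(),
        delta=delta,
        labels=labels,
        thresholds={"anticorr_threshold": anticorr_threshold, "margin": margin},
    )


def intradomain_analysis(
    traj: Trajectory,
    domain_range: tuple[int, int],
    reference: Structure,
) -> tuple[CorrelationMatrix, FluctuationProfile]:
    """Domain-local correlations and fluctuations after per-domain alignment.

    Every frame is superposed onto the reference using only the domain's Cα
    atoms, the domain covariance is computed, and its diagonal yields the
    domain-aligned RMSF/B-factors. Rigid-body motion of the whole domain is
    removed, isolating internal dynamics.
    """
    from cypdyn.descriptors import rmsf as _rmsf

    sel = select_calpha(traj.structure, domain_range)
    aligned = align_trajectory(traj, reference, sel)
    model = compute_covariance(aligned, sel)
    corr = correlation_matrix(
        model, traj.structure.resids[sel], alignment=f"domain:{domain_range[0]}-{domain_range[1]}"
    )
    profile = _rmsf(aligned, sel, alignment=corr.alignment)
    return corr, profile
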