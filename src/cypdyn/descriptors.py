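"""Per-frame geometric descriptors of a two-domain trajectory.

Interdomain centroid distance, salt-bridge center-of-mass distance, helix
axes and interhelix angles, per-residue fluctuations (RMSF / B-factor), and
the coordination-shell radius — a per-residue compactness metric
R_g,i = (Σ_j R_ij² / n_i)^½ over neighbouring Cα atoms within a cutoff,
averaged over residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from cypdyn.structio import (
    ACID_OXYGENS,
    BASE_NITROGENS,
    Structure,
    StructureError,
    Trajectory,
    select_calpha,
)

#: B-factor per unit mean-square fluctuation: B = (8π²/3)·⟨ΔR²⟩
BFACTOR_PER_MSF = 8.0 * np.pi ** 2 / 3.0


@dataclass
class DescriptorSeries:
    """A named per-frame scalar with units and provenance."""

    name: str
    values: np.ndarray
    units: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"descriptor {self.name!r} contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FluctuationProfile:
    """Per-residue RMSF (Å) and B-factor (Ų), with alignment context."""

    resids: np.ndarray
    rmsf: np.ndarray
    alignment: str = "global"

    @property
    def bfactor(self) -> np.ndarray:
        return BFACTOR_PER_MSF * self.rmsf ** 2


@dataclass
class CoordinationShellProfile:
    """Per-residue coordination-shell radii and the protein average.

    Residues with no neighbour inside the cutoff have ``n_neighbors`` 0 and
    NaN radius; they are excluded from ``average``.
    """

    resids: np.ndarray
    n_neighbors: np.ndarray
    radius: np.ndarray
    cutoff: float

    @property
    def average(self) -> float:
        ok = self.n_neighbors > 0
        if not ok.any():
            return float("nan")
        return float(self.radius[ok].mean())


@dataclass
class HelixAxis:
    """Unit helix axis (dominant principal axis of the Cα cloud), N→C."""

    vector: np.ndarray
    anchor: np.ndarray
    name: str = ""


# ---------------------------------------------------------------------------
# Distances


def interdomain_distance(
    coords: np.ndarray, domain_a: np.ndarray, domain_b: np.ndarray
) -> float:
    """Distance between the unweighted centroids of two Cα index sets (Å)."""
    a = np.asarray(domain_a)
    b = np.asarray(domain_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both domains must contain at least one atom")
    return float(np.linalg.norm(coords[a].mean(axis=0) - coords[b].mean(axis=0)))


def interdomain_distance_series(
    traj: Trajectory,
    range_a: tuple[int, int],
    range_b: tuple[int, int],
) -> DescriptorSeries:
    """Per-frame interdomain centroid distance for two residue ranges."""
    ia = select_calpha(traj.structure, range_a)
    ib = select_calpha(traj.structure, range_b)
    ca = traj.coords[:, ia, :].mean(axis=1)
    cb = traj.coords[:, ib, :].mean(axis=1)
    values = np.linalg.norm(ca - cb, axis=1)
    return DescriptorSeries(
        name=f"interdomain_distance_{range_a[0]}-{range_a[1]}_vs_{range_b[0]}-{range_b[1]}",
        values=values,
        units="Å",
        provenance={"domain_a": range_a, "domain_b": range_b},
    )


def salt_bridge_distance(
    structure: Structure, coords: np.ndarray, acidic_resid: int, basic_resid: int
) -> float:
    """COM(side-chain O of acid) to COM(side-chain N of base) distance (Å).

    All-oxygen and all-nitrogen sets make the mass weighting uniform.
    """
    o_idx = np.flatnonzero(
        (structure.resids == acidic_resid) & np.isin(structure.atom_names, ACID_OXYGENS)
    )
    if o_idx.size == 0:
        raise StructureError(
            f"residue {acidic_resid} has no acidic side-chain oxygens "
            f"({'/'.join(ACID_OXYGENS)})"
        )
    n_idx = np.flatnonzero(
        (structure.resids == basic_resid) & np.isin(structure.atom_names, BASE_NITROGENS)
    )
    if n_idx.size == 0:
        raise StructureError(
            f"residue {basic_resid} has no basic side-chain nitrogens "
            f"({'/'.join(BASE_NITROGENS)})"
        )
    return float(np.linalg.norm(coords[o_idx].mean(axis=0) - coords[n_idx].mean(axis=0)))


def salt_bridge_series(
    traj: Trajectory, acidic_resid: int, basic_resid: int
) -> DescriptorSeries:
    """Per-frame salt-bridge COM distance for one (acid, base) pair."""
    values = np.array([
        salt_bridge_distance(traj.structure, frame, acidic_resid, basic_resid)
        for frame in traj.coords
    ])
    return DescriptorSeries(
        name=f"salt_bridge_{acidic_resid}-{basic_resid}",
        values=values,
        units="Å",
        provenance={"acidic": acidic_resid, "basic": basic_resid},
    )


# ---------------------------------------------------------------------------
# Helix axes and angles


def helix_axis(coords: np.ndarray, helix_ca: np.ndarray, name: str = "") -> HelixAxis:
    """Dominant principal axis of a helix's Cα cloud in one frame.

    PC1 of the 3×3 positional covariance, sign-fixed to point N→C (positive
    dot product with the first→last Cα vector). Warns when the first two
    principal variances are nearly equal (axis direction poorly defined).
    """
    helix_ca = np.asarray(helix_ca)
    if len(helix_ca) < 4:
        raise ValueError("helix axis requires at least 4 residues")
    pts = coords[helix_ca]
    center = pts.mean(axis=0)
    d = pts - center
    cov = d.T @ d / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[2] < 1e-12:
        raise ValueError("degenerate helix geometry: all Cα coincide")
    if evals[2] - evals[1] < 0.05 * evals[2]:
        warnings.warn(
            f"helix {name or '?'}: first two principal variances nearly equal; "
            "axis direction is ill-defined",
            stacklevel=2,
        )
    axis = evecs[:, 2]
    nc = pts[-1] - pts[0]
    if np.dot(axis, nc) < 0:
        axis = -axis
    return HelixAxis(vector=axis, anchor=center, name=name)


def interhelix_angle(a: HelixAxis, b: HelixAxis) -> float:
    """Angle between two helix axes in degrees, in [0, 180).

    Computed as θ = atan2(‖a×b‖, a·b), the numerically stable form of
    arccos of the dot product. Both axes must come from the same frame.
    """
    va = np.asarray(a.vector, dtype=float)
    vb = np.asarray(b.vector, dtype=float)
    if np.linalg.norm(va) < 1e-12 or np.linalg.norm(vb) < 1e-12:
        raise ValueError("helix axis has zero length")
    va = va / np.linalg.norm(va)
    vb = vb / np.linalg.norm(vb)
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(va, vb)), np.dot(va, vb))))


def interhelix_angle_series(
    traj: Trajectory,
    helix_a_range: tuple[int, int],
    helix_b_range: tuple[int, int],
    names: tuple[str, str] = ("a", "b"),
) -> DescriptorSeries:
    """Per-frame angle between two helices (axes taken from the same frame)."""
    ia = select_calpha(traj.structure, helix_a_range)
    ib = select_calpha(traj.structure, helix_b_range)
    values = np.array([
        interhelix_angle(
            helix_axis(frame, ia, names[0]), helix_axis(frame, ib, names[1])
        )
        for frame in traj.coords
    ])
    return DescriptorSeries(
        name=f"angle_{names[0]}-{names[1]}",
        values=values,
        units="degrees",
        provenance={"helix_a": helix_a_range, "helix_b": helix_b_range},
    )


# ---------------------------------------------------------------------------
# Fluctuations


def rmsf(traj: Trajectory, selection: np.ndarray, alignment: str = "global") -> FluctuationProfile:
    """Per-residue Cα RMSF over an aligned trajectory.

    RMSF_i = ⟨|R_i − ⟨R_i⟩|²⟩^½ in Å; the B-factor follows from
    B = (8π²/3)·RMSF². Warns if the trajectory is not flagged as aligned.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    if not traj.aligned:
        warnings.warn(
            "trajectory is not flagged as aligned; RMSF will mix internal and "
            "rigid-body motion",
            stacklevel=2,
        )
    sel = np.asarray(selection)
    pts = traj.coords[:, sel, :]
    mean = pts.mean(axis=0)
    msf = np.mean(np.sum((pts - mean) ** 2, axis=2), axis=0)
    return FluctuationProfile(
        resids=traj.structure.resids[sel].copy(),
        rmsf=np.sqrt(msf),
        alignment=alignment,
    )


def domain_average_bfactor(
    profile: FluctuationProfile, domain_range: tuple[int, int]
) -> float:
    """Arithmetic mean of per-residue RMSF (Å) over a domain.

    Note the convention: the quantity averaged is the fluctuation ⟨ΔR²⟩^½
    itself, not B — the form used for domain-average "B-factor" tables.
    """
    lo, hi = domain_range
    mask = (profile.resids >= lo) & (profile.resids <= hi)
    if not mask.any():
        raise ValueError(f"no residues in domain range {lo}-{hi}")
    return float(profile.rmsf[mask].mean())


# ---------------------------------------------------------------------------
# Coordination shell


def coordination_shell_radius(
    coords: np.ndarray,
    ca_indices: np.ndarray,
    resids: np.ndarray,
    cutoff: float,
) -> CoordinationShellProfile:
    """Coordination-shell radii of one coordinate set.

    For each residue i with Cα neighbours j ≠ i within the cutoff,
    R_g,i = (Σ_j R_ij² / n_i)^½; isolated residues are flagged (NaN) and
    excluded from the protein average.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca_indices = np.asarray(ca_indices)
    if len(ca_indices) < 2:
        raise ValueError("at least 2 residues are required")
    pts = coords[ca_indices]
    dist = cdist(pts, pts)
    np.fill_diagonal(dist, np.inf)
    within = dist <= cutoff
    n_nb = within.sum(axis=1)
    sq = np.where(within, dist ** 2, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        radius = np.sqrt(sq / n_nb)
    radius[n_nb == 0] = np.nan
    return CoordinationShellProfile(
        resids=np.asarray(resids)[ca_indices].copy(),
        n_neighbors=n_nb,
        radius=radius,
        cutoff=cutoff,
    )


def coordination_shell_profile(
    traj: Trajectory,
    selection: np.ndarray,
    cutoff: float,
    per_frame: bool = True,
) -> CoordinationShellProfile:
    """Trajectory coordination-shell profile.

    ``per_frame=True`` (default) computes radii per frame and averages them
    over frames; ``per_frame=False`` evaluates the mean structure instead.
    """
    sel = np.asarray(selection)
    resids = traj.structure.resids
    if not per_frame:
        return coordination_shell_radius(
            traj.coords.mean(axis=0), sel, resids, cutoff
        )
    acc_r = np.zeros(len(sel))
    acc_w = np.zeros(len(sel))
    acc_n = np.zeros(len(sel))
    for frame in traj.coords:
        prof = coordination_shell_radius(frame, sel, resids, cutoff)
        ok = prof.n_neighbors > 0
        acc_r[ok] += prof.radius[ok]
        acc_w += ok
        acc_n += prof.n_neighbors
    with np.errstate(invalid="ignore", divide="ignore"):
        radius = acc_r / acc_w
    radius[acc_w == 0] = np.nan
    return CoordinationShellProfile(
        resids=resids[sel].copy(),
        n_neighbors=(acc_n / traj.n_frames),
        radius=radius,
        cutoff=cutoff,
    )
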