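"""Synthetic two-domain Cα trajectories with known ground truth.

The generator emulates the statistical structure of a two-domain protein
whose interdomain distance switches between an "extended" and a "compact"
basin: a globular first domain, a flexible linker, and a second domain built
from ideal α-helices. Basin occupancy follows a two-state Markov chain, so
the stationary compact fraction p_ec/(p_ec+p_ce) is an exact recovery target
for downstream classifiers. Positional noise is isotropic iid Gaussian per
atom per frame (linker atoms scaled up), keeping every estimator's sampling
error analytic.

Proxy side-chain atoms provide salt-bridge geometry: an acidic residue gets
two O atoms at ±1.2 Å about a virtual centroid 2.5 Å off its Cα, a basic
residue one N atom 3.5 Å off its Cα, so center-of-mass distances have a
closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cypdyn.structio import Structure, Trajectory, select_calpha

# ideal alpha-helix geometry
HELIX_RISE = 1.5          # Å per residue along the axis
HELIX_RADIUS = 2.3        # Å
HELIX_TWIST = np.deg2rad(100.0)  # ~3.6 residues per turn

# proxy side-chain geometry (COM distances analytic by construction)
ACID_CENTROID_OFFSET = 2.5  # Å from Cα to the oxygen-pair centroid
ACID_O_SPACING = 1.2        # Å from centroid to each oxygen
BASE_N_OFFSET = 3.5         # Å from Cα to the nitrogen

CA_SPACING = 3.8  # Å, consecutive-residue Cα distance scale


@dataclass
class SyntheticSpec:
    """Parameters of the two-state generator.

    Defaults are wild-type-like study conditions: basins at 43.8 Å
    (extended) and 34.0 Å (compact) interdomain centroid distance, per-atom
    noise 1.5 Å, per-frame switch probabilities 0.003 (extended→compact) and
    0.007 (compact→extended) giving a 30% stationary compact fraction, and
    14 400 recorded frames (720 ns at 50 ps).
    """

    n_domain1: int = 60
    n_domain2: int = 60
    n_linker: int = 10
    n_helices: int = 2
    extended_distance: float = 43.8
    compact_distance: float = 34.0
    p_ec: float = 0.003
    p_ce: float = 0.007
    noise_sigma: float = 1.5
    linker_noise_scale: float = 3.0
    n_frames: int = 14400
    seed: int = 0
    start_state: str | None = None
    frame_interval_ps: float = 50.0
    acid_residues: tuple[int, ...] = ()   # default: two mid-linker residues
    base_residues: tuple[int, ...] = ()   # default: two first-helix residues

    def __post_init__(self) -> None:
        if min(self.n_domain1, self.n_domain2, self.n_linker) <= 0:
            raise ValueError("domain and linker lengths must be positive")
        if self.n_helices <= 0 or self.n_domain2 // self.n_helices < 4:
            raise ValueError("each helix needs at least 4 residues")
        if not (0.0 <= self.p_ec <= 1.0 and 0.0 <= self.p_ce <= 1.0):
            raise ValueError("switch probabilities must lie in [0, 1]")
        if self.extended_distance <= 0 or self.compact_distance <= 0:
            raise ValueError("basin distances must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.linker_noise_scale < 1.0:
            raise ValueError("linker_noise_scale must be >= 1")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.start_state not in (None, "extended", "compact"):
            raise ValueError("start_state must be 'extended', 'compact' or None")
        if not self.acid_residues:
            mid = self.linker_range[0] + self.n_linker // 2
            self.acid_residues = (mid - 1, mid)
        if not self.base_residues:
            h0 = self.helix_ranges["H1"]
            mid = (h0[0] + h0[1]) // 2
            self.base_residues = (mid, mid + 1)

    # --- residue bookkeeping (1-based, inclusive) ---

    @property
    def n_residues(self) -> int:
        return self.n_domain1 + self.n_linker + self.n_domain2

    @property
    def domain1_range(self) -> tuple[int, int]:
        return (1, self.n_domain1)

    @property
    def linker_range(self) -> tuple[int, int]:
        return (self.n_domain1 + 1, self.n_domain1 + self.n_linker)

    @property
    def domain2_range(self) -> tuple[int, int]:
        return (self.n_domain1 + self.n_linker + 1, self.n_residues)

    @property
    def helix_ranges(self) -> dict[str, tuple[int, int]]:
        """Domain-2 residues split evenly into ideal helices H1..Hk."""
        start = self.domain2_range[0]
        per = self.n_domain2 // self.n_helices
        out = {}
        for k in range(self.n_helices):
            lo = start + k * per
            hi = self.domain2_range[1] if k == self.n_helices - 1 else lo + per - 1
            out[f"H{k + 1}"] = (lo, hi)
        return out

    @property
    def salt_bridge_pairs(self) -> list[tuple[int, int]]:
        return [
            (a, b) for a, b in zip(self.acid_residues, self.base_residues)
        ]

    @property
    def stationary_compact_fraction(self) -> float:
        """Stationary compact occupancy of the 2-state Markov chain."""
        total = self.p_ec + self.p_ce
        if total == 0:
            return 0.0 if self.start_state != "compact" else 1.0
        return self.p_ec / total


@dataclass
class GroundTruth:
    """Per-frame basin labels and the exact basin geometries behind them."""

    labels: np.ndarray  # array of 'extended' / 'compact', length n_frames
    occupancies: dict[str, float]
    basin_references: dict[str, Structure]

    def __post_init__(self) -> None:
        total = sum(self.occupancies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("occupancies must sum to 1")


# ---------------------------------------------------------------------------
# Geometry builders


def _globular_cluster(n: int) -> np.ndarray:
    """n points on a cubic lattice inside a ball, CA_SPACING apart, centered."""
    r = 1
    while True:
        ax = np.arange(-r, r + 1)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(float)
        d2 = (pts ** 2).sum(axis=1)
        inside = pts[d2 <= r * r + 1e-9]
        if len(inside) >= n:
            order = np.lexsort((inside[:, 2], inside[:, 1], inside[:, 0],
                                (inside ** 2).sum(axis=1)))
            chosen = inside[order][:n] * CA_SPACING
            return chosen - chosen.mean(axis=0)
        r += 1


def ideal_helix(n: int, axis_origin: np.ndarray, direction: int = 1) -> np.ndarray:
    """Cα coordinates of an ideal right-handed α-helix starting at axis_origin.

    ``direction=-1`` runs the helix along −z via a proper 180° rotation about
    x (handedness preserved), for antiparallel bundle packing.
    """
    i = np.arange(n)
    pts = np.column_stack([
        HELIX_RADIUS * np.cos(HELIX_TWIST * i),
        HELIX_RADIUS * np.sin(HELIX_TWIST * i),
        HELIX_RISE * i,
    ])
    if direction == -1:
        pts[:, 1] *= -1
        pts[:, 2] *= -1
    return pts + np.asarray(axis_origin, dtype=float)


def _helix_bundle(spec: SyntheticSpec) -> np.ndarray:
    """Antiparallel bundle of ideal helices, one Cα row per domain-2 residue."""
    coords = []
    for k, (name, (lo, hi)) in enumerate(spec.helix_ranges.items()):
        n = hi - lo + 1
        direction = 1 if k % 2 == 0 else -1
        origin = np.array([0.0, 10.0 * k, 0.0 if direction == 1 else HELIX_RISE * (n - 1)])
        coords.append(ideal_helix(n, origin, direction))
    pts = np.vstack(coords)
    return pts - pts.mean(axis=0)


def build_toy_protein(spec: SyntheticSpec) -> Structure:
    """Build the Cα-plus-proxy reference structure in the extended basin.

    Domain 1 is a compact lattice cluster, the linker an interpolated strand,
    domain 2 an antiparallel bundle of ideal helices, with the interdomain
    centroid distance set to ``spec.extended_distance``. Deterministic: the
    geometry contains no random numbers (the seed only drives frame noise and
    basin switching).
    """
    d1 = _globular_cluster(spec.n_domain1)
    d2 = _helix_bundle(spec) + np.array([spec.extended_distance, 0.0, 0.0])

    resids, names, resnames, elements, coords = [], [], [], [], []
    acid = set(spec.acid_residues)
    base = set(spec.base_residues)

    # linker placed after domain2 exists: interpolate between the anchors
    a = d1[-1]
    b = d2[0]
    frac = (np.arange(1, spec.n_linker + 1)) / (spec.n_linker + 1)
    linker = a[None, :] + frac[:, None] * (b - a)[None, :]

    ca_by_resid = {}
    for block, rng in ((d1, spec.domain1_range), (linker, spec.linker_range),
                       (d2, spec.domain2_range)):
        for i, resid in enumerate(range(rng[0], rng[1] + 1)):
            ca_by_resid[resid] = block[i]

    y = np.array([0.0, 1.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    for resid in range(1, spec.n_residues + 1):
        ca = ca_by_resid[resid]
        if resid in acid:
            resname = "ASP"
        elif resid in base:
            resname = "LYS"
        else:
            resname = "GLY"
        resids.append(resid); names.append("CA"); resnames.append(resname)
        elements.append("C"); coords.append(ca)
        if resid in acid:
            centroid = ca + ACID_CENTROID_OFFSET * y
            for oname, s in (("OD1", 1.0), ("OD2", -1.0)):
                resids.append(resid); names.append(oname); resnames.append(resname)
                elements.append("O"); coords.append(centroid + s * ACID_O_SPACING * z)
        if resid in base:
            resids.append(resid); names.append("NZ"); resnames.append(resname)
            elements.append("N"); coords.append(ca + BASE_N_OFFSET * y)

    structure = Structure(
        atom_names=np.array(names),
        resids=np.array(resids),
        resnames=np.array(resnames),
        chains=np.full(len(names), "A"),
        elements=np.array(elements),
        coords=np.array(coords),
    )
    return make_basin(structure, spec.extended_distance,
                      spec.domain1_range, spec.domain2_range, spec.linker_range)


def make_basin(
    reference: Structure,
    target_distance: float,
    domain1_range: tuple[int, int],
    domain2_range: tuple[int, int],
    linker_range: tuple[int, int] | None = None,
) -> Structure:
    """Rigidly place domain 2 at a target interdomain centroid distance.

    Domain 2 (all atoms of its residues, proxies included) is translated
    along the centroid–centroid axis; linker Cα atoms are re-interpolated
    between the last domain-1 and first domain-2 Cα, with proxy atoms keeping
    their Cα-relative offsets. Domain 1 is untouched. If the structure is
    already at the target distance it is returned as an unchanged copy.
    """
    if target_distance <= 0:
        raise ValueError("target_distance must be positive")
    out = reference.copy()
    ca1 = select_calpha(out, domain1_range)
    ca2 = select_calpha(out, domain2_range)
    c1 = out.coords[ca1].mean(axis=0)
    c2 = out.coords[ca2].mean(axis=0)
    sep = c2 - c1
    current = float(np.linalg.norm(sep))
    if current < 1e-9:
        raise ValueError("domain centroids coincide; translation axis undefined")
    if abs(current - target_distance) < 1e-12:
        return out
    axis = sep / current
    shift = (target_distance - current) * axis

    in_dom2 = (out.resids >= domain2_range[0]) & (out.resids <= domain2_range[1])
    out.coords[in_dom2] += shift

    if linker_range is not None:
        a = out.coords[ca1[-1]]
        b = out.coords[ca2[0]]  # first domain-2 Cα, post-shift
        n_link = linker_range[1] - linker_range[0] + 1
        for k, resid in enumerate(range(linker_range[0], linker_range[1] + 1), start=1):
            in_res = out.resids == resid
            idx = np.flatnonzero(in_res)
            ca_idx = idx[out.atom_names[idx] == "CA"][0]
            old_ca = out.coords[ca_idx].copy()
            new_ca = a + (k / (n_link + 1)) * (b - a)
            out.coords[idx] += new_ca - old_ca
    return out


def generate_two_state_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Simulate a Markov-switching two-basin trajectory with Gaussian noise.

    Frame labels follow the 2-state chain (initial state drawn from the
    stationary distribution unless ``spec.start_state`` pins it); frame
    coordinates are the labelled basin reference plus iid Gaussian noise with
    per-atom σ = ``noise_sigma`` (linker residues scaled by
    ``linker_noise_scale``). Fully reproducible given ``spec.seed``.
    """
    if spec.p_ec + spec.p_ce == 0 and spec.start_state is None:
        raise ValueError(
            "p_ec = p_ce = 0 requires an explicit start_state (chain never moves)"
        )
    ref_ext = build_toy_protein(spec)
    ref_comp = make_basin(ref_ext, spec.compact_distance,
                          spec.domain1_range, spec.domain2_range, spec.linker_range)
    refs = np.stack([ref_ext.coords, ref_comp.coords])  # 0 = extended, 1 = compact

    rng = np.random.default_rng(spec.seed)
    states = np.empty(spec.n_frames, dtype=np.int8)
    if spec.start_state is not None:
        state = 1 if spec.start_state == "compact" else 0
    else:
        state = int(rng.random() < spec.stationary_compact_fraction)
    u = rng.random(spec.n_frames)
    for t in range(spec.n_frames):
        states[t] = state
        p_switch = spec.p_ec if state == 0 else spec.p_ce
        if u[t] < p_switch:
            state = 1 - state
    labels = np.where(states == 1, "compact", "extended")

    lo, hi = spec.linker_range
    in_linker = (ref_ext.resids >= lo) & (ref_ext.resids <= hi)
    sigma = np.full(ref_ext.n_atoms, spec.noise_sigma)
    sigma[in_linker] *= spec.linker_noise_scale

    coords = refs[states]
    if spec.noise_sigma > 0:
        coords = coords + rng.standard_normal(coords.shape) * sigma[None, :, None]
    else:
        coords = coords.copy()

    traj = Trajectory(
        structure=ref_ext,
        coords=coords,
        frame_interval_ps=spec.frame_interval_ps,
        production_length_ns=spec.n_frames * spec.frame_interval_ps / 1000.0,
    )
    frac_c = float(states.mean())
    truth = GroundTruth(
        labels=labels,
        occupancies={"extended": 1.0 - frac_c, "compact": frac_c},
        basin_references={"extended": ref_ext, "compact": ref_comp},
    )
    return traj, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write per-frame basin labels as a two-column TSV (frame, label)."""
    with open(path, "w") as fh:
        fh.write("frame\tlabel\n")
        for i, lab in enumerate(truth.labels):
            fh.write(f"{i}\t{lab}\n")
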