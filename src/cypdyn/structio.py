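"""Structure/trajectory I/O, atom selections, and the analysis configuration.

Coordinates are in Å throughout. Residue numbering is 1-based author (PDB)
numbering and all residue ranges are inclusive on both ends. PDB files are
parsed with biotite (first model only, altlocs resolved by occupancy); DCD
trajectories go through MDAnalysis coordinate readers/writers. Trajectory
time metadata (frame interval, production length) lives in the config, never
in binary headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: names of acidic side-chain oxygens / basic side-chain nitrogens used for
#: salt-bridge centers of mass
ACID_OXYGENS = ("OD1", "OD2", "OE1", "OE2")
BASE_NITROGENS = ("NZ", "NH1", "NH2", "NE", "ND1", "NE2")


class StructureError(ValueError):
    """Raised for malformed or inconsistent structural input."""


@dataclass
class Structure:
    """An atom table plus one coordinate set.

    Arrays are parallel over atoms: ``atom_names``, ``resids`` (1-based),
    ``resnames``, ``chains``, ``elements`` and ``coords`` with shape (n, 3).
    """

    atom_names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    elements: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        for name in ("atom_names", "resnames", "chains", "elements"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates in structure")
        n = len(self.coords)
        for name in ("atom_names", "resids", "resnames", "chains", "elements"):
            if len(getattr(self, name)) != n:
                raise StructureError(f"{name} length does not match coords")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def residue_span(self) -> tuple[int, int]:
        """Smallest and largest residue number present."""
        return int(self.resids.min()), int(self.resids.max())

    def copy(self) -> "Structure":
        return Structure(
            self.atom_names.copy(),
            self.resids.copy(),
            self.resnames.copy(),
            self.chains.copy(),
            self.elements.copy(),
            self.coords.copy(),
        )


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed atom table.

    ``coords`` has shape (n_frames, n_atoms, 3). ``frame_interval_ps`` and
    ``production_length_ns`` are bookkeeping metadata supplied by the config.
    ``aligned`` marks whether frames have been superposed onto a reference.
    """

    structure: Structure
    coords: np.ndarray
    frame_interval_ps: float | None = None
    production_length_ns: float | None = None
    aligned: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("trajectory coords must have shape (T, n, 3)")
        if self.coords.shape[1] != self.structure.n_atoms:
            raise StructureError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.structure.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def check_bookkeeping(self) -> None:
        """Verify frame count against the declared production length.

        Raises if both time fields are set and
        production_length_ns * 1000 / frame_interval_ps != n_frames.
        """
        if self.frame_interval_ps is None or self.production_length_ns is None:
            return
        expected = expected_frame_count(self.production_length_ns, self.frame_interval_ps)
        if expected != self.n_frames:
            raise StructureError(
                f"bookkeeping mismatch: {self.production_length_ns} ns at "
                f"{self.frame_interval_ps} ps/frame implies {expected} frames, "
                f"trajectory has {self.n_frames}"
            )


def expected_frame_count(production_length_ns: float, frame_interval_ps: float) -> int:
    """Number of frames implied by a production length and recording interval.

    720 ns recorded every 50 ps gives 14 400 frames. A non-integral ratio
    raises a warning via logging and is rounded to the nearest integer.
    """
    ratio = production_length_ns * 1000.0 / frame_interval_ps
    if abs(ratio - round(ratio)) > 1e-9:
        logger.warning(
            "production length %.6g ns is not an integer number of %.6g ps frames",
            production_length_ns, frame_interval_ps,
        )
    return int(round(ratio))


# ---------------------------------------------------------------------------
# PDB / DCD I/O


def _structure_from_atom_array(arr) -> Structure:
    import biotite.structure as struc  # local: keeps import cost off the hot path

    elements = np.asarray(arr.element)
    return Structure(
        atom_names=np.asarray(arr.atom_name),
        resids=np.asarray(arr.res_id, dtype=int),
        resnames=np.asarray(arr.res_name),
        chains=np.asarray(arr.chain_id),
        elements=elements,
        coords=np.asarray(arr.coord, dtype=float),
    )


def _atom_array_from_structure(structure: Structure, coords: np.ndarray):
    import biotite.structure as struc

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = structure.atom_names.astype("U6")
    arr.res_id = structure.resids
    arr.res_name = structure.resnames.astype("U5")
    arr.chain_id = structure.chains.astype("U4")
    arr.element = structure.elements.astype("U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def read_structure(path: str | Path) -> Structure:
    """Read the ATOM records of the first model of a PDB file.

    Altloc conflicts are resolved by highest occupancy, then first listed.
    HETATM records are dropped; a file with no ATOM records is an error.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises various parse errors
        raise StructureError(f"failed to parse PDB file {path}: {exc}") from exc
    arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise StructureError(f"no ATOM records in {path}")
    return _structure_from_atom_array(arr)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file."""
    from biotite.structure.io.pdb import PDBFile

    arr = _atom_array_from_structure(structure, structure.coords)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_trajectory(
    topology: Structure,
    path: str | Path,
    frame_interval_ps: float | None = None,
    production_length_ns: float | None = None,
) -> Trajectory:
    """Read a coordinate trajectory (DCD or multi-model PDB) over a topology.

    Frame order follows file order. Time metadata is taken from the
    arguments (normally sourced from the config), never from file headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    if path.suffix.lower() == ".dcd":
        coords = _read_dcd(path)
    else:
        coords = _read_multimodel_pdb(path)
    if coords.shape[1] != topology.n_atoms:
        raise StructureError(
            f"trajectory atom count mismatch: expected {topology.n_atoms} "
            f"(topology), found {coords.shape[1]} in {path}"
        )
    return Trajectory(
        structure=topology,
        coords=coords,
        frame_interval_ps=frame_interval_ps,
        production_length_ns=production_length_ns,
    )


def _read_dcd(path: Path) -> np.ndarray:
    from MDAnalysis.coordinates.DCD import DCDReader

    with DCDReader(str(path)) as reader:
        frames = [ts.positions.astype(float).copy() for ts in reader]
    if not frames:
        raise StructureError(f"no frames in DCD file {path}")
    return np.stack(frames)


def _read_multimodel_pdb(path: Path) -> np.ndarray:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(altloc="occupancy")
    stack = stack[..., ~stack.hetero]
    if stack.array_length() == 0:
        raise StructureError(f"no ATOM records in {path}")
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    return coords


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as DCD (``.dcd``) or multi-model PDB (otherwise)."""
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        _write_dcd(traj, path)
    else:
        _write_multimodel_pdb(traj, path)


def _write_dcd(traj: Trajectory, path: Path) -> None:
    import MDAnalysis as mda

    u = mda.Universe.empty(traj.structure.n_atoms, trajectory=True)
    with mda.coordinates.DCD.DCDWriter(str(path), n_atoms=traj.structure.n_atoms) as w:
        for frame in traj.coords:
            u.atoms.positions = frame
            w.write(u.atoms)


def _write_multimodel_pdb(traj: Trajectory, path: Path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arrays = [
        _atom_array_from_structure(traj.structure, frame) for frame in traj.coords
    ]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Selections


def select_calpha(structure: Structure, residue_range: tuple[int, int]) -> np.ndarray:
    """Indices of Cα atoms for residues in an inclusive range, residue order.

    Every residue of the range that is present in the structure must have a
    Cα atom; residues lacking one are reported in the error. An empty
    intersection between range and structure is also an error.
    """
    lo, hi = int(residue_range[0]), int(residue_range[1])
    if lo > hi:
        raise StructureError(f"empty residue range {lo}-{hi}")
    in_range = (structure.resids >= lo) & (structure.resids <= hi)
    if not in_range.any():
        raise StructureError(
            f"no atoms in residue range {lo}-{hi} "
            f"(structure spans {structure.residue_span[0]}-{structure.residue_span[1]})"
        )
    is_ca = structure.atom_names == "CA"
    present = np.unique(structure.resids[in_range])
    with_ca = np.unique(structure.resids[in_range & is_ca])
    missing = np.setdiff1d(present, with_ca)
    if missing.size:
        raise StructureError(
            "residues without a CA atom in range "
            f"{lo}-{hi}: {', '.join(map(str, missing))}"
        )
    idx = np.flatnonzero(in_range & is_ca)
    order = np.argsort(structure.resids[idx], kind="stable")
    return idx[order]


# ---------------------------------------------------------------------------
# Configuration

_CONFIG_DEFAULTS = {
    "temperature": 310.0,
    "frame_interval_ps": 50.0,
    "production_length_ns": 720.0,
    "n_runs": 8,
    "distance_bin_width": 0.5,
    "angle_bin_width": 2.0,
    "kde_bandwidth": None,  # None -> Silverman's rule
    "shell_cutoff": 10.0,
    "anticorr_threshold": 0.1,
    "correlation_margin": 0.05,
    "decrease_window": (-10.0, -4.0),
    "increase_window": (4.0, 10.0),
    "min_prominence": 0.05,
    "salt_bridge_formed_max": 4.5,
    "combined_pca": True,
}


@dataclass
class AnalysisConfig:
    """Validated analysis parameters: residue ranges and descriptor settings.

    ``domains``/``helices`` map names to inclusive 1-based residue ranges;
    ``salt_bridges`` lists (acidic resid, basic resid) pairs. Descriptor
    parameters carry the units stated in their names (Å, degrees, K).
    """

    domains: dict[str, tuple[int, int]]
    helices: dict[str, tuple[int, int]] = field(default_factory=dict)
    salt_bridges: list[tuple[int, int]] = field(default_factory=list)
    pca_residue_range: tuple[int, int] | None = None
    chain: str | None = None
    temperature: float = _CONFIG_DEFAULTS["temperature"]
    frame_interval_ps: float = _CONFIG_DEFAULTS["frame_interval_ps"]
    production_length_ns: float = _CONFIG_DEFAULTS["production_length_ns"]
    n_runs: int = _CONFIG_DEFAULTS["n_runs"]
    distance_bin_width: float = _CONFIG_DEFAULTS["distance_bin_width"]
    angle_bin_width: float = _CONFIG_DEFAULTS["angle_bin_width"]
    kde_bandwidth: float | None = _CONFIG_DEFAULTS["kde_bandwidth"]
    shell_cutoff: float = _CONFIG_DEFAULTS["shell_cutoff"]
    anticorr_threshold: float = _CONFIG_DEFAULTS["anticorr_threshold"]
    correlation_margin: float = _CONFIG_DEFAULTS["correlation_margin"]
    decrease_window: tuple[float, float] = _CONFIG_DEFAULTS["decrease_window"]
    increase_window: tuple[float, float] = _CONFIG_DEFAULTS["increase_window"]
    min_prominence: float = _CONFIG_DEFAULTS["min_prominence"]
    salt_bridge_formed_max: float = _CONFIG_DEFAULTS["salt_bridge_formed_max"]
    combined_pca: bool = _CONFIG_DEFAULTS["combined_pca"]
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, structure: Structure | None = None) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not self.domains:
            raise ValueError("at least one domain definition is required")
        ranges = {}
        for name, rng in {**self.domains, **self.helices}.items():
            lo, hi = int(rng[0]), int(rng[1])
            if lo > hi:
                raise ValueError(f"range for {name!r} is empty: {lo}-{hi}")
            ranges[name] = (lo, hi)
        dom_items = sorted(self.domains.items(), key=lambda kv: kv[1][0])
        for (na, (la, ha)), (nb, (lb, hb)) in zip(dom_items, dom_items[1:]):
            if lb <= ha:
                raise ValueError(f"domains {na!r} ({la}-{ha}) and {nb!r} ({lb}-{hb}) overlap")
        if structure is not None:
            span = structure.residue_span
            check = dict(ranges)
            if self.pca_residue_range is not None:
                check["pca_residue_range"] = tuple(self.pca_residue_range)
            for name, (lo, hi) in check.items():
                if lo < span[0] or hi > span[1]:
                    raise ValueError(
                        f"range for {name!r} ({lo}-{hi}) lies outside the "
                        f"structure's residue span {span[0]}-{span[1]}"
                    )
        # frame bookkeeping: non-integral ratio only warns (in expected_frame_count)
        expected_frame_count(self.production_length_ns, self.frame_interval_ps)

    @property
    def kT(self) -> float:
        """Thermal energy k·T in kcal/mol (k = 0.0019872 kcal/mol/K)."""
        return 0.0019872 * self.temperature

    @property
    def expected_frames(self) -> int:
        return expected_frame_count(self.production_length_ns, self.frame_interval_ps)

    @property
    def total_sampling_us(self) -> float:
        """Aggregate sampling across runs in μs (8 × 720 ns → 5.76 μs)."""
        return self.n_runs * self.production_length_ns / 1000.0


def default_config_path() -> Path:
    """Path to the packaged Cyp40 analysis configuration."""
    return Path(__file__).parent / "data" / "cyp40.yaml"


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load and validate a YAML analysis configuration.

    With no path, the packaged Cyp40 config is used. Every parameter that
    falls back to a default is logged at INFO level.
    """
    path = default_config_path() if path is None else Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    def _pair(v):
        return (int(v[0]), int(v[1]))

    domains = {k: _pair(v) for k, v in (raw.get("domains") or {}).items()}
    helices = {k: _pair(v) for k, v in (raw.get("helices") or {}).items()}
    bridges = [(int(a), int(b)) for a, b in (raw.get("salt_bridges") or [])]
    kwargs: dict = {}
    for key, default in _CONFIG_DEFAULTS.items():
        if key in raw:
            kwargs[key] = raw[key]
        else:
            kwargs[key] = default
            logger.info("config %s: using default %r", key, default)
    for win in ("decrease_window", "increase_window"):
        kwargs[win] = (float(kwargs[win][0]), float(kwargs[win][1]))
    pca_range = raw.get("pca_residue_range")
    return AnalysisConfig(
        domains=domains,
        helices=helices,
        salt_bridges=bridges,
        pca_residue_range=_pair(pca_range) if pca_range else None,
        chain=raw.get("chain"),
        synthetic=raw.get("synthetic") or {},
        **kwargs,
    )
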