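"""Structures, trajectories, domain maps and SAXS profiles.

Container types shared by the whole package plus readers/writers for the
plain-text formats it speaks: single- and multi-model PDB, XYZ frame
stacks, and 3-column SAXS profiles (q, I, sigma).  Residue numbering is
always taken verbatim from the input file (1-based), so residue labels in
reports match the labels used in the structural-biology literature for the
protein at hand (R19, K67, D97, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as _pdbio

__all__ = [
    "Structure",
    "Trajectory",
    "DomainMap",
    "SAXSProfile",
    "HingeflexError",
    "FormatError",
    "StructureError",
    "ParameterError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_saxs_profile",
    "write_saxs_profile",
    "residue_charge",
    "default_domain_map",
    "KB_KCAL_MOL_K",
]

#: Boltzmann constant in kcal/mol/K, shared by the Langevin generator and
#: the free-energy module.
KB_KCAL_MOL_K = 0.0019872


class HingeflexError(Exception):
    """Base class for all package errors."""


class FormatError(HingeflexError):
    """A file does not parse as the declared format."""


class StructureError(HingeflexError):
    """Topology/selection/grid mismatch between inputs."""


class ParameterError(HingeflexError):
    """A numeric parameter is outside its allowed range."""


# ---------------------------------------------------------------------------
# container types
# ---------------------------------------------------------------------------

_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971,
}


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "C"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    for two in ("SE",):
        if name.upper().startswith(two):
            return two
    return name[0].upper()


@dataclass(frozen=True)
class Structure:
    """Labeled coordinates of a single conformation.

    Attributes
    ----------
    atom_names, res_names : per-atom labels (PDB conventions).
    res_ids : 1-based residue numbers, non-decreasing within the chain.
    coords : (n_atoms, 3) float array, Angstrom.
    masses : per-atom masses, amu.
    chain_id : single chain identifier.
    radii : optional per-atom radii (Angstrom) used by SASA and the clash
        checks of the synthetic generator; ``None`` means "use a vdW table".
    """

    atom_names: tuple[str, ...]
    res_names: tuple[str, ...]
    res_ids: np.ndarray
    coords: np.ndarray
    masses: np.ndarray
    chain_id: str = "A"
    radii: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "res_ids", np.asarray(self.res_ids, dtype=int))
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        if self.radii is not None:
            object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coords must have shape (n_atoms, 3)")
        n = self.coords.shape[0]
        if n == 0:
            raise StructureError("a Structure needs at least one atom")
        if not (len(self.atom_names) == len(self.res_names) == len(self.res_ids)
                == len(self.masses) == n):
            raise StructureError("per-atom arrays have inconsistent lengths")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("coordinates must be finite")
        if np.any(np.diff(self.res_ids) < 0):
            raise StructureError("residue numbers must be non-decreasing")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def ca_indices(self) -> np.ndarray:
        """Indices of Cα atoms (the selection used by most analyses)."""
        return np.array([i for i, a in enumerate(self.atom_names)
                         if a.strip() == "CA"], dtype=int)

    def residue_indices(self, res_lo: int, res_hi: int) -> np.ndarray:
        """Atom indices whose residue number lies in [res_lo, res_hi]."""
        return np.nonzero((self.res_ids >= res_lo) & (self.res_ids <= res_hi))[0]

    def unique_residues(self) -> np.ndarray:
        return np.unique(self.res_ids)


@dataclass(frozen=True)
class Trajectory:
    """Ordered frames sharing one topology.

    ``timestep_ns`` is metadata only; every analysis in the package is
    frame-indexed.
    """

    topology: Structure
    frames: np.ndarray
    timestep_ns: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "frames", np.asarray(self.frames, dtype=float))
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise StructureError("a Trajectory needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"frames have {self.frames.shape[1]} atoms but the topology "
                f"has {self.topology.n_atoms}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class DomainMap:
    """Partition of the sequence into named domains and hinges.

    Ranges are inclusive residue-number intervals.  ``region_order`` fixes
    the row order of region-wise reports (domain I, hinge I-II, domain II,
    hinge II-III, domain III for the default three-domain map).
    """

    domains: dict[str, tuple[int, int]]
    hinges: dict[str, tuple[int, int]] = field(default_factory=dict)
    region_order: tuple[str, ...] = ()

    def __post_init__(self):
        regions = self.regions()
        spans = sorted(regions.values())
        for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
            if b_lo <= a_hi:
                raise StructureError(
                    f"overlapping regions: [{a_lo},{a_hi}] and [{b_lo},{b_hi}]")
        if not self.region_order:
            ordered = sorted(regions, key=lambda k: regions[k][0])
            object.__setattr__(self, "region_order", tuple(ordered))

    def regions(self) -> dict[str, tuple[int, int]]:
        merged = dict(self.domains)
        merged.update(self.hinges)
        return merged

    def region_residues(self, name: str) -> np.ndarray:
        lo, hi = self.regions()[name]
        return np.arange(lo, hi + 1)

    def all_residues(self) -> np.ndarray:
        return np.concatenate(
            [self.region_residues(r) for r in self.region_order])

    def domain_atom_indices(self, structure: Structure, name: str) -> np.ndarray:
        lo, hi = self.regions()[name]
        idx = structure.residue_indices(lo, hi)
        if idx.size == 0:
            raise StructureError(
                f"region {name!r} ([{lo},{hi}]) matches no atom of the structure")
        return idx


@dataclass(frozen=True)
class SAXSProfile:
    """Scattering intensities on a strictly increasing q-grid (1/Angstrom)."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "I", np.asarray(self.I, dtype=float))
        if self.sigma is not None:
            object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise StructureError("q and I must be 1-D arrays of equal length")
        if np.any(self.q < 0):
            raise StructureError("q must be non-negative")
        if np.any(np.diff(self.q) <= 0):
            raise StructureError("q must be strictly increasing")
        if not np.all(np.isfinite(self.I)):
            raise StructureError("intensities must be finite")
        if self.sigma is not None:
            if self.sigma.shape != self.q.shape:
                raise StructureError("sigma must match the q grid")
            if np.any(self.sigma <= 0):
                raise StructureError("sigma must be positive where present")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _structure_from_atom_array(arr: struc.AtomArray) -> Structure:
    atom_names = tuple(str(a) for a in arr.atom_name)
    res_names = tuple(str(r) for r in arr.res_name)
    elements = [str(e) if str(e) else _guess_element(a)
                for e, a in zip(arr.element, atom_names)]
    masses = np.array([_ELEMENT_MASS.get(e.upper(), 12.011) for e in elements])
    chain = str(arr.chain_id[0]) if len(arr.chain_id) else "A"
    return Structure(atom_names=atom_names, res_names=res_names,
                     res_ids=np.asarray(arr.res_id, dtype=int),
                     coords=np.asarray(arr.coord, dtype=float),
                     masses=masses, chain_id=chain)


def _atom_array_from_structure(s: Structure) -> struc.AtomArray:
    arr = struc.AtomArray(s.n_atoms)
    arr.coord = np.asarray(s.coords, dtype=np.float32)
    arr.chain_id = np.full(s.n_atoms, s.chain_id)
    arr.res_id = s.res_ids
    arr.res_name = np.array(s.res_names)
    arr.atom_name = np.array(s.atom_names)
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    arr.element = np.array([_guess_element(a) for a in s.atom_names])
    return arr


def _first_bad_pdb_line(path: str) -> int | None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    return lineno
    return None


def read_structure(path: str, format: str = "pdb") -> Structure:
    """Read a single-model structure file.

    Raises :class:`FormatError` (naming the offending line where it can be
    located) for malformed files, and a :class:`FormatError` pointing to
    :func:`read_trajectory` for multi-model files.
    """
    if format != "pdb":
        raise ParameterError(f"unsupported structure format {format!r}")
    try:
        pdb = _pdbio.PDBFile.read(path)
        n_models = pdb.get_model_count()
    except Exception as exc:
        bad = _first_bad_pdb_line(path)
        where = f" (line {bad})" if bad is not None else ""
        raise FormatError(f"{path}: not a parseable PDB file{where}: {exc}") from exc
    if n_models == 0:
        raise FormatError(f"{path}: no atoms found")
    if n_models > 1:
        raise FormatError(
            f"{path}: contains {n_models} MODEL records; use read_trajectory "
            "for multi-model files")
    try:
        arr = pdb.get_structure(model=1)
    except Exception as exc:
        bad = _first_bad_pdb_line(path)
        where = f" (line {bad})" if bad is not None else ""
        raise FormatError(f"{path}: malformed PDB record{where}: {exc}") from exc
    if arr.array_length() == 0:
        raise FormatError(f"{path}: no atoms found")
    return _structure_from_atom_array(arr)


def write_structure(structure: Structure, path: str) -> None:
    """Write a single-model PDB (coordinates at the format's 1e-3 A precision)."""
    pdb = _pdbio.PDBFile()
    pdb.set_structure(_atom_array_from_structure(structure))
    pdb.write(path)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _read_xyz_stack(path: str) -> tuple[list[str], np.ndarray]:
    """Read a concatenated-XYZ file into (atom labels, frames array)."""
    frames: list[np.ndarray] = []
    labels: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(
                f"{path}: expected an atom count at line {i + 1}") from exc
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise FormatError(
                f"{path}: frame {frame_idx} truncated (expected {n} atoms)")
        coords = np.empty((n, 3))
        frame_labels = []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: malformed XYZ line {i + 3 + j}")
            frame_labels.append(parts[0])
            coords[j] = [float(p) for p in parts[1:4]]
        if not labels:
            labels = frame_labels
        elif len(frame_labels) != len(labels):
            raise StructureError(
                f"{path}: frame {frame_idx} has {len(frame_labels)} atoms, "
                f"frame 0 has {len(labels)}")
        frames.append(coords)
        i += 2 + n
        frame_idx += 1
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return labels, np.stack(frames)


def read_trajectory(path: str, format: str = "pdb",
                    topology: Structure | None = None) -> Trajectory:
    """Read a multi-model PDB or an XYZ frame stack.

    The topology is taken from the first model when none is supplied; for
    XYZ input a topology is required to carry residue metadata (a bare
    carbon-chain topology is synthesised when omitted).
    """
    if format == "pdb":
        try:
            pdb = _pdbio.PDBFile.read(path)
            stack = pdb.get_structure()
        except Exception as exc:
            raise FormatError(f"{path}: not a parseable multi-model PDB: {exc}") from exc
        if stack.array_length() == 0:
            raise FormatError(f"{path}: no atoms found")
        first = _structure_from_atom_array(stack[0])
        topo = topology if topology is not None else first
        frames = np.asarray(stack.coord, dtype=float)
        if frames.shape[1] != topo.n_atoms:
            raise StructureError(
                f"{path}: frame 0 has {frames.shape[1]} atoms but the "
                f"topology has {topo.n_atoms}")
        return Trajectory(topology=topo, frames=frames)
    if format == "xyz":
        labels, frames = _read_xyz_stack(path)
        if topology is None:
            n = len(labels)
            topology = Structure(
                atom_names=tuple("CA" for _ in labels),
                res_names=tuple("GLY" for _ in labels),
                res_ids=np.arange(1, n + 1),
                coords=frames[0],
                masses=np.full(n, _ELEMENT_MASS["C"]))
        if frames.shape[1] != topology.n_atoms:
            raise StructureError(
                f"{path}: frames have {frames.shape[1]} atoms but the "
                f"topology has {topology.n_atoms}")
        return Trajectory(topology=topology, frames=frames)
    raise ParameterError(f"unsupported trajectory format {format!r}")


def write_trajectory(traj: Trajectory, path: str, format: str = "pdb") -> None:
    if format == "pdb":
        n = traj.n_frames
        template = _atom_array_from_structure(traj.topology)
        stack = struc.AtomArrayStack(n, traj.topology.n_atoms)
        for key in ("chain_id", "res_id", "res_name", "atom_name",
                    "hetero", "element"):
            stack.set_annotation(key, template.get_annotation(key))
        stack.coord = np.asarray(traj.frames, dtype=np.float32)
        pdb = _pdbio.PDBFile()
        pdb.set_structure(stack)
        pdb.write(path)
        return
    if format == "xyz":
        labels = [_guess_element(a) for a in traj.topology.atom_names]
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"{traj.topology.n_atoms}\nframe {f}\n")
                for lab, (x, y, z) in zip(labels, traj.frames[f]):
                    fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")
        return
    raise ParameterError(f"unsupported trajectory format {format!r}")


# ---------------------------------------------------------------------------
# SAXS profiles
# ---------------------------------------------------------------------------

def read_saxs_profile(path: str) -> SAXSProfile:
    """Read a 3-column (q, I[, sigma]) whitespace text file; '#' lines ignored."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: need at least q and I")
            try:
                rows.append([float(p) for p in parts[:3]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric field") from exc
    if not rows:
        raise FormatError(f"{path}: no data rows")
    have_sigma = all(len(r) == 3 for r in rows)
    q = np.array([r[0] for r in rows])
    inten = np.array([r[1] for r in rows])
    sigma = np.array([r[2] for r in rows]) if have_sigma else None
    return SAXSProfile(q=q, I=inten, sigma=sigma)


def write_saxs_profile(profile: SAXSProfile, path: str,
                       header: str = "q(1/A) I(q) sigma") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        for k in range(profile.q.size):
            if profile.sigma is not None:
                fh.write(f"{profile.q[k]:.6e} {profile.I[k]:.6e} "
                         f"{profile.sigma[k]:.6e}\n")
            else:
                fh.write(f"{profile.q[k]:.6e} {profile.I[k]:.6e}\n")


# ---------------------------------------------------------------------------
# residue charges and the default domain map
# ---------------------------------------------------------------------------

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Formal side-chain charge at physiological pH.  Histidine is neutral by
#: convention here (its majority protonation state at pH 7); terminal
#: charges are ignored because the charge-weighted SASA estimator is
#: residue-wise.
CHARGE_BY_RESNAME = {name: 0 for name in _STANDARD_AA}
CHARGE_BY_RESNAME.update({"LYS": 1, "ARG": 1, "ASP": -1, "GLU": -1})


def residue_charge(residue_name: str) -> int:
    """Formal side-chain charge of a standard 3-letter residue code."""
    key = residue_name.strip().upper()
    if key not in CHARGE_BY_RESNAME:
        raise LookupError(
            f"unknown residue code {residue_name!r}; valid codes: "
            + ", ".join(sorted(CHARGE_BY_RESNAME)))
    return CHARGE_BY_RESNAME[key]


def default_domain_map() -> DomainMap:
    """The three-domain SBDS partition with its two interdomain hinges.

    Domain I binds rRNA, domain II is the central hub, domain III packs
    against the GTPase; the hinge regions bracket the pivot residues D97
    and A170.
    """
    return DomainMap(
        domains={"I": (9, 95), "II": (107, 167), "III": (173, 236)},
        hinges={"I-II": (96, 106), "II-III": (168, 172)},
        region_order=("I", "I-II", "II", "II-III", "III"),
    )
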