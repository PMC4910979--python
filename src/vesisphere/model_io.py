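"""Domain model and file I/O for coarse-grained vesicle trajectories.

The package represents one time point as a :class:`VesicleFrame`: flat numpy
arrays of bead positions (nm) plus per-bead molecule, species and role labels.
A :class:`Trajectory` is a time-ordered list of frames with uniform spacing.
Coordinate files (GRO, PDB, XTC, multi-frame GRO) are read and written through
mdtraj, which is nm-native; a small declarative topology file supplies the
species/role information that coordinate formats do not carry.

Internal units are nm and ns everywhere. PDB coordinates (Angstrom on disk)
are converted on read by mdtraj.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import mdtraj as md
import mdtraj.core.element as _element
import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "BeadRecord",
    "VesicleFrame",
    "Trajectory",
    "Topology",
    "ParseError",
    "TopologyError",
    "TrajectoryError",
    "read_topology",
    "read_coordinates",
    "read_trajectory",
    "write_coordinates",
    "write_trajectory",
    "write_table",
    "read_config",
]


class ParseError(ValueError):
    """A coordinate or topology file did not parse under its format."""


class TopologyError(ValueError):
    """Topology information is missing, inconsistent, or contradicts a frame."""


class TrajectoryError(ValueError):
    """A trajectory violates the uniform-spacing / stable-ordering contract."""


class Role(str, Enum):
    """Function of a coarse-grained bead within its molecule."""

    HEADGROUP = "headgroup"
    TAIL = "tail"
    LINKER = "linker"
    PROTEIN_BACKBONE = "protein_backbone"
    PROTEIN_SIDECHAIN = "protein_sidechain"
    SOLVENT = "solvent"


LIPID_ROLES = frozenset({Role.HEADGROUP, Role.TAIL, Role.LINKER})
PROTEIN_ROLES = frozenset({Role.PROTEIN_BACKBONE, Role.PROTEIN_SIDECHAIN})


@dataclass(frozen=True)
class BeadRecord:
    """One coarse-grained bead: position in nm plus identity labels."""

    position: np.ndarray
    molecule_id: int
    species: str
    role: Role
    bead_name: str


@dataclass
class Topology:
    """Species/role assignments plus the trimer roster.

    ``bead_roles`` maps ``(species, bead_name_pattern)`` to a :class:`Role`;
    patterns use shell-style wildcards so e.g. ``("OMPF", "SC*")`` covers all
    sidechain beads. ``trimers`` maps a trimer id to the three molecule ids of
    its subunits.
    """

    bead_roles: dict[tuple[str, str], Role] = field(default_factory=dict)
    protein_species: set[str] = field(default_factory=set)
    solvent_species: set[str] = field(default_factory=set)
    trimers: dict[int, tuple[int, int, int]] = field(default_factory=dict)

    def role_of(self, species: str, bead_name: str) -> Role:
        if species in self.solvent_species:
            return Role.SOLVENT
        exact = self.bead_roles.get((species, bead_name))
        if exact is not None:
            return exact
        for (sp, pat), role in self.bead_roles.items():
            if sp == species and fnmatch.fnmatchcase(bead_name, pat):
                return role
        known = sorted({sp for sp, _ in self.bead_roles} | self.solvent_species)
        raise TopologyError(
            f"no role declared for bead {bead_name!r} of species {species!r}; "
            f"known species: {known}"
        )

    def validate_trimers(self) -> None:
        for tid, subunits in self.trimers.items():
            if len(subunits) != 3:
                raise TopologyError(
                    f"trimer {tid} has {len(subunits)} subunits; expected exactly 3"
                )


@dataclass
class VesicleFrame:
    """All beads of one trajectory frame, as flat per-bead arrays.

    positions are in nm; ``time`` in ns; ``box`` is a 3x3 cell matrix in nm
    (zeros when the source carries no box).
    """

    positions: np.ndarray  # (n, 3) float64, nm
    molecule_ids: np.ndarray  # (n,) int64
    species: np.ndarray  # (n,) str
    roles: np.ndarray  # (n,) str (Role values)
    bead_names: np.ndarray  # (n,) str
    time: float = 0.0
    box: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=np.int64)
        if self.molecule_ids.min(initial=0) < 0:
            raise ValueError("molecule_id must be >= 0")
        self.species = np.asarray(self.species, dtype=object)
        self.roles = np.asarray(
            [r.value if isinstance(r, Role) else str(r) for r in self.roles],
            dtype=object,
        )
        self.bead_names = np.asarray(self.bead_names, dtype=object)
        n = len(self.positions)
        for name in ("molecule_ids", "species", "roles", "bead_names"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match positions")
        if self.time < 0:
            raise ValueError("time must be >= 0")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def bead(self, i: int) -> BeadRecord:
        return BeadRecord(
            position=self.positions[i].copy(),
            molecule_id=int(self.molecule_ids[i]),
            species=str(self.species[i]),
            role=Role(self.roles[i]),
            bead_name=str(self.bead_names[i]),
        )

    # --- masks -----------------------------------------------------------
    def role_mask(self, roles: Iterable[Role | str]) -> np.ndarray:
        wanted = {Role(r).value for r in roles}
        return np.asarray([r in wanted for r in self.roles], dtype=bool)

    @property
    def lipid_mask(self) -> np.ndarray:
        return self.role_mask(LIPID_ROLES)

    @property
    def protein_mask(self) -> np.ndarray:
        return self.role_mask(PROTEIN_ROLES)

    @property
    def headgroup_mask(self) -> np.ndarray:
        return self.role_mask([Role.HEADGROUP])

    def species_mask(self, species: str | Iterable[str]) -> np.ndarray:
        wanted = {species} if isinstance(species, str) else set(species)
        return np.asarray([s in wanted for s in self.species], dtype=bool)

    # --- per-molecule reductions ----------------------------------------
    def lipid_molecule_ids(self) -> np.ndarray:
        """Sorted unique molecule ids of lipid molecules."""
        return np.unique(self.molecule_ids[self.lipid_mask])

    def molecule_com(self, molecule_id: int) -> np.ndarray:
        mask = self.molecule_ids == molecule_id
        if not mask.any():
            raise KeyError(f"molecule {molecule_id} not in frame")
        return self.positions[mask].mean(axis=0)

    def lipid_coms(self) -> tuple[np.ndarray, np.ndarray]:
        """(molecule_ids, COM positions) for every lipid molecule.

        Equal-mass beads: the centre of mass is the arithmetic mean.
        """
        mask = self.lipid_mask
        return _group_means(self.molecule_ids[mask], self.positions[mask])

    def lipid_species_table(self) -> dict[int, str]:
        mask = self.lipid_mask
        return dict(zip(self.molecule_ids[mask].tolist(), self.species[mask].tolist()))

    def validate(self) -> None:
        """Check frame invariants: every lipid molecule has >= 1 headgroup bead."""
        lipid_mols = set(self.lipid_molecule_ids().tolist())
        head_mols = set(self.molecule_ids[self.headgroup_mask].tolist())
        missing = sorted(lipid_mols - head_mols)
        if missing:
            raise TopologyError(
                f"lipid molecules without a headgroup bead: {missing[:10]}"
            )


def _group_means(ids: np.ndarray, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inverse = np.unique(ids, return_inverse=True)
    sums = np.zeros((len(uniq), 3))
    np.add.at(sums, inverse, positions)
    counts = np.bincount(inverse, minlength=len(uniq)).astype(float)
    return uniq, sums / counts[:, None]


@dataclass
class Trajectory:
    """Time-ordered frames with constant bead count/ordering and uniform dt (ns)."""

    frames: list[VesicleFrame]
    dt: float

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryError("trajectory has no frames")
        if self.dt <= 0 and len(self.frames) > 1:
            raise TrajectoryError("dt must be > 0")
        n0 = self.frames[0].n_beads
        names0 = self.frames[0].bead_names
        mols0 = self.frames[0].molecule_ids
        for k, fr in enumerate(self.frames[1:], start=1):
            if fr.n_beads != n0:
                raise TrajectoryError(
                    f"frame {k} has {fr.n_beads} beads, frame 0 has {n0}"
                )
            if not np.array_equal(fr.molecule_ids, mols0) or not np.array_equal(
                fr.bead_names, names0
            ):
                raise TrajectoryError(f"bead ordering changed at frame {k}")
        times = np.asarray([fr.time for fr in self.frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> VesicleFrame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.asarray([fr.time for fr in self.frames])


# ---------------------------------------------------------------------------
# topology file
# ---------------------------------------------------------------------------

def read_topology(path: str | Path) -> Topology:
    """Parse the declarative topology file.

    Line dialect (whitespace separated, ``#`` comments)::

        bead    <species> <bead_name_pattern> <role>
        protein <species>
        solvent <species> [<species> ...]
        trimer  <trimer_id> <mol_id> <mol_id> <mol_id>

    Roles are the :class:`Role` values (headgroup, tail, linker,
    protein_backbone, protein_sidechain, solvent).
    """
    top = Topology()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        kind = parts[0].lower()
        try:
            if kind == "bead":
                sp, name, role = parts[1], parts[2], Role(parts[3])
                top.bead_roles[(sp, name)] = role
            elif kind == "protein":
                top.protein_species.update(parts[1:])
            elif kind == "solvent":
                top.solvent_species.update(parts[1:])
            elif kind == "trimer":
                tid = int(parts[1])
                subunits = tuple(int(p) for p in parts[2:])
                if len(subunits) != 3:
                    raise TopologyError(
                        f"trimer {tid} declares {len(subunits)} subunits; expected 3"
                    )
                top.trimers[tid] = subunits  # type: ignore[assignment]
            else:
                raise ParseError(f"unknown directive {kind!r}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, (ParseError, TopologyError)):
                raise type(exc)(f"{path}:{lineno}: {exc}") from None
            raise ParseError(f"{path}:{lineno}: malformed line {line!r}: {exc}") from None
    top.validate_trimers()
    return top


# ---------------------------------------------------------------------------
# coordinate I/O (mdtraj-backed)
# ---------------------------------------------------------------------------

_FORMATS = {".gro": "GRO", ".pdb": "PDB", ".xtc": "XTC"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.upper()
    try:
        return _FORMATS[path.suffix.lower()]
    except KeyError:
        raise ParseError(f"cannot infer format from suffix {path.suffix!r}") from None


def _locate_gro_error(path: Path) -> str:
    """Best-effort line number for a malformed GRO record."""
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        return f"{path}: file too short for GRO"
    try:
        natoms = int(lines[1].strip())
    except ValueError:
        return f"{path}:2: atom count is not an integer"
    for lineno in range(3, min(3 + natoms, len(lines) + 1)):
        line = lines[lineno - 1]
        try:
            float(line[20:28]), float(line[28:36]), float(line[36:44])
        except (ValueError, IndexError):
            return f"{path}:{lineno}: malformed coordinate record {line!r}"
    return f"{path}: malformed GRO file"


def _frame_from_mdtraj(
    t: md.Trajectory, k: int, topology: Topology, skip_solvent: bool
) -> VesicleFrame:
    mdtop = t.topology
    n = mdtop.n_atoms
    mol_ids = np.empty(n, dtype=np.int64)
    species = np.empty(n, dtype=object)
    names = np.empty(n, dtype=object)
    for atom in mdtop.atoms:
        i = atom.index
        mol_ids[i] = atom.residue.resSeq
        species[i] = atom.residue.name
        names[i] = atom.name
    roles = np.array(
        [topology.role_of(species[i], names[i]).value for i in range(n)], dtype=object
    )
    keep = np.ones(n, dtype=bool)
    if skip_solvent:
        keep = roles != Role.SOLVENT.value
    box = t.unitcell_vectors[k] if t.unitcell_vectors is not None else np.zeros((3, 3))
    time = float(t.time[k]) if t.time is not None else 0.0
    return VesicleFrame(
        positions=np.asarray(t.xyz[k][keep], dtype=float),
        molecule_ids=mol_ids[keep],
        species=species[keep],
        roles=roles[keep],
        bead_names=names[keep],
        time=max(time, 0.0),
        box=np.asarray(box, dtype=float),
    )


def read_coordinates(
    path: str | Path,
    topology: Topology | str | Path,
    format: str | None = None,
    skip_solvent: bool = True,
) -> VesicleFrame:
    """Read a single coordinate frame (GRO or PDB) into a :class:`VesicleFrame`.

    PDB coordinates are converted from Angstrom to nm. Solvent beads are
    dropped by default; every analysis in the package operates on lipid and
    protein beads only.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt not in ("GRO", "PDB"):
        raise ParseError(f"read_coordinates supports GRO/PDB, not {fmt}")
    if not isinstance(topology, Topology):
        topology = read_topology(topology)
    try:
        t = md.load(str(path))
    except Exception as exc:
        if fmt == "GRO":
            raise ParseError(_locate_gro_error(path)) from exc
        raise ParseError(f"{path}: {exc}") from exc
    frame = _frame_from_mdtraj(t, 0, topology, skip_solvent)
    frame.validate()
    return frame


def read_trajectory(
    path: str | Path,
    topology: Topology | str | Path,
    format: str | None = None,
    top: str | Path | None = None,
    skip_solvent: bool = True,
    dt: float | None = None,
) -> Trajectory:
    """Read a multi-frame trajectory (XTC or multi-frame GRO).

    ``top`` (a GRO/PDB file) is required for XTC, which carries no atom
    labels. ``dt`` is inferred from stored frame times and must be uniform to
    within 1%; pass ``dt`` explicitly when the source stores no times.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not isinstance(topology, Topology):
        topology = read_topology(topology)
    chunks: list[md.Trajectory] = []
    try:
        if fmt == "XTC":
            if top is None:
                raise ParseError("XTC trajectories require a `top` coordinate file")
            for chunk in md.iterload(str(path), top=str(top), chunk=500):
                chunks.append(chunk)
        elif fmt == "GRO":
            chunks.append(md.load(str(path)))
        else:
            raise ParseError(f"read_trajectory supports XTC/multiGRO, not {fmt}")
    except ParseError:
        raise
    except Exception as exc:
        n_good = sum(c.n_frames for c in chunks)
        raise TrajectoryError(
            f"{path}: truncated or malformed after frame {n_good - 1} "
            f"(read {n_good} good frames): {exc}"
        ) from exc
    t = chunks[0] if len(chunks) == 1 else md.join(chunks)
    if fmt == "GRO":
        _check_gro_frame_ordering(path)
    frames = [_frame_from_mdtraj(t, k, topology, skip_solvent) for k in range(t.n_frames)]
    times = np.asarray([fr.time for fr in frames])
    if dt is None:
        diffs = np.diff(times)
        if len(diffs) == 0:
            dt = 0.0
        elif np.all(diffs <= 0):
            raise TrajectoryError(
                f"{path}: no usable frame times stored; pass dt explicitly"
            )
        else:
            dt = float(diffs.mean())
            if np.any(np.abs(diffs - dt) > 0.01 * dt):
                raise TrajectoryError(
                    f"{path}: frame spacing nonuniform beyond 1% (diffs {diffs})"
                )
    else:
        for k, fr in enumerate(frames):
            fr.time = k * dt
    frames[0].validate()
    return Trajectory(frames=frames, dt=float(dt))


def _check_gro_frame_ordering(path: Path) -> None:
    """Verify every frame of a multi-frame GRO lists beads in the same order."""
    lines = Path(path).read_text().splitlines()
    ref: list[str] | None = None
    i = 0
    frame_no = 0
    while i < len(lines) - 1:
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError:
            break
        ids = [line[:15] for line in lines[i + 2 : i + 2 + natoms]]
        if ref is None:
            ref = ids
        elif ids != ref:
            raise TrajectoryError(
                f"{path}: bead ordering changed at frame {frame_no} "
                "(residue/atom columns differ from frame 0)"
            )
        i += natoms + 3
        frame_no += 1


def _mdtraj_topology(frame: VesicleFrame) -> md.Topology:
    top = md.Topology()
    chain = top.add_chain()
    current: int | None = None
    res = None
    for i in range(frame.n_beads):
        mid = int(frame.molecule_ids[i])
        if mid != current:
            res = top.add_residue(str(frame.species[i]), chain, resSeq=mid)
            current = mid
        top.add_atom(str(frame.bead_names[i]), _element.virtual_site, res)
    return top


def _to_mdtraj(frames: Sequence[VesicleFrame]) -> md.Trajectory:
    xyz = np.stack([fr.positions for fr in frames]).astype(np.float32)
    t = md.Trajectory(
        xyz,
        _mdtraj_topology(frames[0]),
        time=np.asarray([fr.time for fr in frames]),
    )
    boxes = np.stack([fr.box for fr in frames])
    if np.any(boxes):
        t.unitcell_vectors = boxes.astype(np.float32)
    return t


def write_coordinates(frame: VesicleFrame, path: str | Path, format: str | None = None) -> None:
    """Write one frame as GRO (3-decimal nm) or PDB (Angstrom on disk)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    t = _to_mdtraj([frame])
    if fmt == "GRO":
        t.save_gro(str(path))
    elif fmt == "PDB":
        t.save_pdb(str(path))
        _restore_pdb_resnames(path, frame)
    else:
        raise ParseError(f"write_coordinates supports GRO/PDB, not {fmt}")


def _restore_pdb_resnames(path: Path, frame: VesicleFrame) -> None:
    """Re-widen residue names the PDB writer truncated to 3 characters.

    The PDB fixed format reserves 4 columns (18-21) for the residue name;
    species labels like POPE need all four.
    """
    out = []
    i = 0
    last = ""
    for line in path.read_text().splitlines(keepends=True):
        if line.startswith(("ATOM", "HETATM")) and i < frame.n_beads:
            last = f"{str(frame.species[i])[:4]:<4}"
            line = line[:17] + last + line[21:]
            i += 1
        elif line.startswith("TER") and len(line) >= 21 and last:
            line = line[:17] + last + line[21:]
        out.append(line)
    path.write_text("".join(out))


def write_trajectory(traj: Trajectory, path: str | Path, format: str | None = None) -> None:
    """Write a trajectory as multi-frame GRO or XTC.

    XTC stores coordinates and times only; pair it with a
    :func:`write_coordinates` GRO of frame 0 for the labels.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    t = _to_mdtraj(traj.frames)
    if fmt == "GRO":
        t.save_gro(str(path))
    elif fmt == "XTC":
        t.save_xtc(str(path))
    else:
        raise ParseError(f"write_trajectory supports GRO/XTC, not {fmt}")


# ---------------------------------------------------------------------------
# tabular output and flat config
# ---------------------------------------------------------------------------

def write_table(
    records: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write result rows as CSV with a header and full float precision.

    ``columns`` fixes the header (needed for an empty row set, which still
    produces a header-only file).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records), columns=columns)
    df.to_csv(path, index=False)


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` config file (``#`` comments allowed)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
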