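"""Structure and trajectory I/O.

Reads PDB structures and multi-model PDB trajectories into a lightweight
topology + coordinate-frames representation, and resolves named domain
selections (chain + residue intervals + atom-name filter) to atom index
sets.

All coordinates are stored internally in nanometres; the PDB boundary
converts from/to Angstrom (exact factor 10).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "DomainSpec",
    "StructureParseError",
    "EmptySelectionError",
    "read_structure",
    "read_trajectory",
    "select_domain",
    "write_trajectory",
]

logger = logging.getLogger(__name__)

ANGSTROM_PER_NM = 10.0

#: residue names treated as solvent/ions and dropped from HETATM records
_SOLVENT_RESNAMES = frozenset(
    {"HOH", "WAT", "SOL", "TIP", "TIP3", "TIP4", "NA", "CL", "K", "MG",
     "CA2", "ZN", "NA+", "CL-", "SO4", "PO4", "GOL", "EDO"}
)


class StructureParseError(ValueError):
    """A PDB record could not be parsed; the message names the line number."""


class EmptySelectionError(ValueError):
    """A domain selection matched no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """Identity metadata of one atom in the canonical atom order."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str = ""
    insertion_code: str = ""

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass(frozen=True)
class Topology:
    """Ordered atom metadata; the canonical order for every Frame."""

    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise ValueError("Topology requires at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def chain_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return tuple(seen)


@dataclass(frozen=True)
class Frame:
    """One coordinate snapshot (nm) bound to a topology's atom order."""

    time: float  # ns
    coordinates: np.ndarray  # (n_atoms, 3), nm

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coordinates must be (n, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates contain non-finite values")
        object.__setattr__(self, "coordinates", coords)


@dataclass(frozen=True)
class Trajectory:
    """An ordered sequence of frames sharing one topology."""

    topology: Topology
    frames: tuple[Frame, ...]

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("Trajectory requires at least one frame")
        n = self.topology.n_atoms
        for k, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {k}: {fr.coordinates.shape[0]} atoms, topology has {n}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def coordinate_array(self) -> np.ndarray:
        """Stack all frames into an (n_frames, n_atoms, 3) array."""
        return np.stack([fr.coordinates for fr in self.frames])

    def with_frames(self, frames: Sequence[Frame]) -> "Trajectory":
        return Trajectory(self.topology, tuple(frames))

    def strided(self, step: int) -> "Trajectory":
        """Keep every ``step``-th frame (step >= 1), starting at frame 0."""
        if step < 1:
            raise ValueError("stride step must be >= 1")
        return self.with_frames(self.frames[::step])


@dataclass(frozen=True)
class DomainSpec:
    """A named Cα selection: chain + inclusive residue intervals + atom filter."""

    name: str
    chain_id: str
    residue_intervals: tuple[tuple[int, int], ...]
    atom_filter: frozenset[str] = frozenset({"CA"})

    def __post_init__(self) -> None:
        intervals = tuple(
            (int(a), int(b)) for a, b in self.residue_intervals
        )
        for start, end in intervals:
            if start > end:
                raise ValueError(f"interval [{start}, {end}]: start > end")
        ordered = sorted(intervals)
        for (_, e0), (s1, _) in zip(ordered, ordered[1:]):
            if s1 <= e0:
                raise ValueError("residue intervals overlap")
        object.__setattr__(self, "residue_intervals", intervals)
        object.__setattr__(self, "atom_filter", frozenset(self.atom_filter))

    def contains_residue(self, resnum: int) -> bool:
        return any(s <= resnum <= e for s, e in self.residue_intervals)

    @classmethod
    def from_dict(cls, d: dict) -> "DomainSpec":
        return cls(
            name=d["name"],
            chain_id=d["chain_id"],
            residue_intervals=tuple(tuple(iv) for iv in d["residue_intervals"]),
            atom_filter=frozenset(d.get("atom_filter", ["CA"])),
        )


# ---------------------------------------------------------------------------
# PDB parsing (fixed-column ATOM/HETATM/MODEL/ENDMDL records)
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray, str, float]:
    """Parse one ATOM/HETATM line -> (record, xyz in Angstrom, altloc, occupancy)."""
    try:
        atom_name = line[12:16].strip()
        altloc = line[16:17].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21:22].strip()
        residue_number = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise StructureParseError(
            f"malformed PDB record at line {lineno}: {line.rstrip()!r} ({exc})"
        ) from exc
    if not atom_name:
        raise StructureParseError(f"empty atom name at line {lineno}")
    rec = AtomRecord(
        chain_id=chain_id,
        residue_number=residue_number,
        residue_name=residue_name,
        atom_name=atom_name,
        element=element,
        insertion_code=icode,
    )
    return rec, np.array([x, y, z]), altloc, occupancy


def _parse_time_remark(line: str) -> float | None:
    # convention used by write_trajectory: "REMARK 250 TIME_NS= <t>"
    if line.startswith("REMARK") and "TIME_NS=" in line:
        try:
            return float(line.split("TIME_NS=")[1].split()[0])
        except (ValueError, IndexError):
            return None
    return None


def _read_models(path: str | Path, include_hetatm: bool):
    """Yield (records, coords_A, time_or_None) per MODEL (or the whole file)."""
    path = Path(path)
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    # altLoc bookkeeping: (residue_key, atom_name) -> index into records
    best: dict[tuple, tuple[int, float]] = {}
    model_time: float | None = None
    in_model = False
    any_model = False

    def flush():
        nonlocal records, coords, best, model_time
        out = (tuple(records), np.array(coords).reshape(-1, 3), model_time)
        records, coords, best, model_time = [], [], {}, None
        return out

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag == "MODEL":
                if in_model and records:
                    yield flush()
                in_model = True
                any_model = True
            elif tag == "ENDMDL":
                in_model = False
                if records:
                    yield flush()
            elif tag in ("ATOM", "HETATM"):
                rec, xyz, altloc, occ = _parse_atom_line(line, lineno)
                if tag == "HETATM" and not include_hetatm:
                    continue
                if tag == "HETATM" and rec.residue_name in _SOLVENT_RESNAMES:
                    continue
                key = (rec.residue_key, rec.atom_name)
                if altloc and key in best:
                    idx, best_occ = best[key]
                    if occ > best_occ:  # strict: ties keep first encountered
                        records[idx] = rec
                        coords[idx] = xyz
                        best[key] = (idx, occ)
                    continue
                records.append(rec)
                coords.append(xyz)
                if altloc:
                    best[key] = (len(records) - 1, occ)
            else:
                t = _parse_time_remark(line)
                if t is not None:
                    model_time = t
    if records:
        yield flush()
    elif not any_model:
        raise StructureParseError(f"{path}: no ATOM records found")


def read_structure(
    path: str | Path,
    include_hetatm: bool = False,
) -> tuple[Topology, Frame]:
    """Read a PDB structure into a :class:`Topology` and one :class:`Frame`.

    Coordinates are converted Angstrom -> nm. Alternate locations are
    resolved to the highest-occupancy conformer (ties: first encountered).
    HETATM records are excluded unless ``include_hetatm`` is set; solvent
    and ion residues are always dropped.
    """
    models = list(_read_models(path, include_hetatm))
    if not models:
        raise StructureParseError(f"{path}: no ATOM records found")
    records, coords_ang, t = models[0]
    if len(records) == 0:
        raise EmptySelectionError(f"{path}: no atoms remain after filtering")
    topology = Topology(records)
    frame = Frame(time=t if t is not None else 0.0,
                  coordinates=coords_ang / ANGSTROM_PER_NM)
    return topology, frame


def read_trajectory(
    paths: str | Path | Sequence[str | Path],
    topology: Topology,
    dt: float = 0.04,
    include_hetatm: bool = False,
) -> Trajectory:
    """Read one or more multi-model PDB files into a :class:`Trajectory`.

    Frames are concatenated in file order. Per-frame times come from
    ``REMARK ... TIME_NS=`` lines where present; otherwise frame ``k``
    (1-based over the concatenation) is assigned time ``k * dt`` ns.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames: list[Frame] = []
    k = 0
    for path in paths:
        for records, coords_ang, t in _read_models(path, include_hetatm):
            k += 1
            if len(records) != topology.n_atoms:
                raise ValueError(
                    f"frame {k - 1} ({path}): {len(records)} atoms, "
                    f"topology has {topology.n_atoms}"
                )
            frames.append(
                Frame(time=t if t is not None else k * dt,
                      coordinates=coords_ang / ANGSTROM_PER_NM)
            )
    if not frames:
        raise StructureParseError("no frames read from input files")
    return Trajectory(topology, tuple(frames))


def select_domain(topology: Topology, spec: DomainSpec) -> np.ndarray:
    """Resolve a :class:`DomainSpec` to ordered atom indices.

    Order follows topology order. Residues missing from the structure
    inside a requested interval are skipped with a logged warning.
    An empty result raises :class:`EmptySelectionError` — a 0-atom
    domain is never silently accepted.
    """
    if spec.chain_id not in topology.chain_ids():
        raise EmptySelectionError(
            f"domain {spec.name!r}: chain {spec.chain_id!r} not in topology "
            f"(chains: {topology.chain_ids()})"
        )
    indices = [
        i
        for i, a in enumerate(topology.atoms)
        if a.chain_id == spec.chain_id
        and a.atom_name in spec.atom_filter
        and spec.contains_residue(a.residue_number)
    ]
    if not indices:
        raise EmptySelectionError(
            f"domain {spec.name!r}: selection matched no atoms"
        )
    found = {topology.atoms[i].residue_number for i in indices}
    requested = {
        r for s, e in spec.residue_intervals for r in range(s, e + 1)
    }
    missing = sorted(requested - found)
    if missing:
        logger.warning(
            "domain %r: %d residue(s) in requested intervals have no matching "
            "atom and were skipped: %s",
            spec.name, len(missing), missing,
        )
    return np.array(indices, dtype=np.intp)


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as a multi-model PDB (one MODEL per frame, nm -> A)."""
    path = Path(path)
    top = traj.topology
    with open(path, "w") as fh:
        for k, fr in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {k:>4d}\n")
            fh.write(f"REMARK 250 TIME_NS= {fr.time:.6f}\n")
            coords_ang = fr.coordinates * ANGSTROM_PER_NM
            for serial, (atom, xyz) in enumerate(zip(top.atoms, coords_ang), 1):
                name = atom.atom_name
                # PDB atom-name column convention: 1-3 char names start col 14
                name_field = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    "ATOM  {serial:>5d} {name:4s} {res:<3s} {chain:1s}"
                    "{resnum:>4d}{icode:1s}   "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
                    "          {elem:>2s}\n".format(
                        serial=serial % 100000,
                        name=name_field,
                        res=atom.residue_name,
                        chain=atom.chain_id or "A",
                        resnum=atom.residue_number,
                        icode=atom.insertion_code or " ",
                        x=xyz[0], y=xyz[1], z=xyz[2],
                        occ=1.0, b=0.0,
                        elem=atom.element or name[:1],
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


def read_trajectory_external(
    topology_source: str | Path,
    trajectory_paths: str | Path | Sequence[str | Path],
    dt: float = 0.04,
) -> Trajectory:
    """Read MD trajectory formats (XTC/TRR/DCD/multi-model PDB) via MDAnalysis.

    Optional convenience behind the same :class:`Trajectory` contract as
    :func:`read_trajectory`; requires the ``MDAnalysis`` package.
    Coordinates are converted Angstrom -> nm; frame times are taken from
    the file where present and positive, else assigned as k * dt.
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "read_trajectory_external requires the MDAnalysis package"
        ) from exc
    if isinstance(trajectory_paths, (str, Path)):
        trajectory_paths = [trajectory_paths]
    u = mda.Universe(str(topology_source), *[str(p) for p in trajectory_paths])
    records = []
    for atom in u.atoms:
        chain = getattr(atom, "chainID", "") or getattr(atom, "segid", "")
        records.append(
            AtomRecord(
                chain_id=str(chain).strip(),
                residue_number=int(atom.resid),
                residue_name=str(atom.resname).strip(),
                atom_name=str(atom.name).strip(),
                element=str(getattr(atom, "element", "") or "").strip(),
            )
        )
    topology = Topology(tuple(records))
    coords, raw_times = [], []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for ts in u.trajectory:
            raw_times.append(float(ts.time) / 1000.0)  # ps -> ns
            coords.append(ts.positions.astype(float) / ANGSTROM_PER_NM)
    # PDB and some readers fabricate times (frame index as ps); fall back
    # to k * dt whenever the file carries no genuine time information
    fabricated = any("no dt information" in str(w.message) for w in caught)
    times = np.asarray(raw_times)
    if fabricated or len(times) > 1 and not np.all(np.diff(times) > 0):
        times = (np.arange(len(coords)) + 1) * dt
    frames = tuple(
        Frame(time=t, coordinates=c) for t, c in zip(times, coords)
    )
    return Trajectory(topology, frames)


def residue_sequence(topology: Topology, chain_id: str) -> list[str]:
    """Three-letter residue names of a chain, in order, one per residue."""
    out: list[str] = []
    seen: set[tuple] = set()
    for a in topology.atoms:
        if a.chain_id != chain_id:
            continue
        if a.residue_key in seen:
            continue
        seen.add(a.residue_key)
        out.append(a.residue_name)
    return out
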