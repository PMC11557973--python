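"""System topology / trajectory data model and file I/O.

Internal units are Angstrom and nanoseconds throughout; GRO files (nm)
are converted on read by MDAnalysis. The "membrane" selection is all
atoms of lipid-role residues; solvent is read but excluded from every
distance computation downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROLE_PEPTIDE = "peptide"
ROLE_LIPID = "lipid"
ROLE_SOLVENT = "solvent"
ROLE_OTHER = "other"

#: residue names mapped to lipid species by default
DEFAULT_LIPID_NAMES: Mapping[str, str] = {"POPC": "POPC", "POPG": "POPG"}

DEFAULT_SOLVENT_NAMES = frozenset(
    {"SOL", "WAT", "HOH", "TIP3", "TIP3P", "TIP4", "SPC", "NA", "CL", "NA+", "CL-",
     "K", "K+", "SOD", "CLA", "POT", "ION"}
)

_AMINO_ACIDS = frozenset(
    {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD", "HSE",
     "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR",
     "VAL"}
)


class SystemInputError(ValueError):
    """Raised for malformed or inconsistent topology/trajectory input."""


@dataclass
class SystemTopology:
    """Per-atom annotation of one peptide + bilayer system.

    Arrays are indexed by atom; ``residue_names`` is indexed by the
    per-atom ``residue_index`` values (0-based, contiguous).
    """

    atom_names: np.ndarray          # (n_atoms,) str
    residue_index: np.ndarray       # (n_atoms,) int
    residue_names: np.ndarray       # (n_residues,) str
    roles: np.ndarray               # (n_atoms,) str, one of the ROLE_* values
    lipid_species: np.ndarray       # (n_atoms,) str, "" for non-lipid atoms

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for arr in (self.residue_index, self.roles, self.lipid_species):
            if len(arr) != n:
                raise SystemInputError("per-atom arrays must have equal length")
        pep = self.peptide_residues
        if len(pep) == 0:
            raise SystemInputError("no peptide residues found")
        if not np.array_equal(pep, np.arange(pep[0], pep[0] + len(pep))):
            raise SystemInputError("peptide residues must form one contiguous chain")
        bad = [
            str(self.residue_names[r])
            for r in np.unique(self.residue_index[self.roles == ROLE_LIPID])
            if self.lipid_species[self.residue_index == r][0] == ""
        ]
        if bad:
            raise SystemInputError(f"lipid residues without species label: {bad}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def peptide_atom_index(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ROLE_PEPTIDE)

    @property
    def membrane_atom_index(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ROLE_LIPID)

    @property
    def peptide_residues(self) -> np.ndarray:
        """Ordered residue indices of the peptide chain."""
        return np.unique(self.residue_index[self.roles == ROLE_PEPTIDE])

    @property
    def heavy(self) -> np.ndarray:
        """Heavy-atom mask inferred from atom names (leading H = hydrogen)."""
        out = np.empty(self.n_atoms, dtype=bool)
        for i, name in enumerate(self.atom_names):
            stripped = str(name).strip().lstrip("0123456789")
            out[i] = not stripped.upper().startswith("H")
        return out


@dataclass
class Trajectory:
    """Time-ordered coordinate frames for one system.

    coordinates: (n_frames, n_atoms, 3) in Angstrom
    boxes:       (n_frames, 3) orthorhombic box lengths in Angstrom
    times:       (n_frames,) timestamps in ns, uniformly spaced
    """

    coordinates: np.ndarray
    boxes: np.ndarray
    times: np.ndarray
    frame_interval: float

    _TIME_TOL = 1e-6  # ns

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise SystemInputError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.boxes.shape != (self.n_frames, 3):
            raise SystemInputError("boxes must have shape (n_frames, 3)")
        if self.times.shape != (self.n_frames,):
            raise SystemInputError("times must have one entry per frame")
        if self.n_frames > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise SystemInputError("timestamps must be strictly increasing")
            if np.any(np.abs(dt - self.frame_interval) > self._TIME_TOL):
                raise SystemInputError("timestamps must be uniformly spaced at frame_interval")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def total_time(self) -> float:
        """Total simulated time in ns (n_frames * frame_interval)."""
        return self.n_frames * self.frame_interval


def assign_roles(
    residue_names: Sequence[str],
    lipid_names: Mapping[str, str] = DEFAULT_LIPID_NAMES,
    solvent_names: Iterable[str] = DEFAULT_SOLVENT_NAMES,
) -> tuple[list[str], list[str]]:
    """Map residue names to (role, lipid_species) pairs.

    Defaults: POPC/POPG -> lipid, common water/ion names -> solvent,
    standard amino acids and PEP*-style residues -> peptide. Anything
    else is an error listing the offending names, so unknown lipids are
    never silently dropped from the membrane selection.
    """
    solvent = {s.upper() for s in solvent_names}
    lipids = {k.upper(): v for k, v in lipid_names.items()}
    roles, species, unknown = [], [], []
    for name in residue_names:
        key = str(name).strip().upper()
        if key in lipids:
            roles.append(ROLE_LIPID)
            species.append(lipids[key])
        elif key in solvent:
            roles.append(ROLE_SOLVENT)
            species.append("")
        elif key in _AMINO_ACIDS or key.startswith("PEP"):
            roles.append(ROLE_PEPTIDE)
            species.append("")
        else:
            unknown.append(key)
            roles.append(ROLE_OTHER)
            species.append("")
    if unknown:
        raise SystemInputError(
            "unclassifiable residue names (configure lipid/solvent maps): "
            + ", ".join(sorted(set(unknown)))
        )
    return roles, species


def load_system(
    topology_path: str | Path,
    trajectory_path: str | Path | None = None,
    *,
    lipid_names: Mapping[str, str] = DEFAULT_LIPID_NAMES,
    solvent_names: Iterable[str] = DEFAULT_SOLVENT_NAMES,
    frame_interval: float = 0.1,
) -> tuple[SystemTopology, Trajectory]:
    """Read a topology (GRO/PDB) and trajectory (multi-model PDB or XTC).

    MDAnalysis handles format parsing and unit conversion to Angstrom.
    ``frame_interval`` (ns) supplies the analysis time base, since
    multi-model PDB carries no timestamps.

    Raises SystemInputError on atom-count mismatch, missing peptide, or
    unclassifiable residue names.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise SystemInputError(f"topology file not found: {topology_path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is None:
            u = mda.Universe(str(topology_path))
        else:
            trajectory_path = Path(trajectory_path)
            if not trajectory_path.exists():
                raise SystemInputError(f"trajectory file not found: {trajectory_path}")
            try:
                u = mda.Universe(str(topology_path), str(trajectory_path))
            except (ValueError, OSError, EOFError) as exc:
                raise SystemInputError(
                    f"failed to combine {topology_path.name} with "
                    f"{trajectory_path.name}: {exc}"
                ) from exc

    res_names = [str(r) for r in u.residues.resnames]
    per_res_roles, per_res_species = assign_roles(res_names, lipid_names, solvent_names)

    resindex = u.atoms.resindices.astype(int)
    roles = np.array([per_res_roles[r] for r in resindex], dtype=object)
    species = np.array([per_res_species[r] for r in resindex], dtype=object)
    topology = SystemTopology(
        atom_names=np.array([str(n) for n in u.atoms.names], dtype=object),
        residue_index=resindex,
        residue_names=np.array(res_names, dtype=object),
        roles=roles,
        lipid_species=species,
    )

    # some trajectory dialects (multi-model PDB with one CRYST1) do not carry
    # per-frame boxes; fall back to the topology file's box
    fallback_box = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u_top = mda.Universe(str(topology_path))
        if u_top.dimensions is not None and np.all(u_top.dimensions[:3] > 0):
            fallback_box = np.array(u_top.dimensions[:3], dtype=float)

    n_frames = len(u.trajectory)
    coords = np.empty((n_frames, len(u.atoms), 3), dtype=float)
    boxes = np.empty((n_frames, 3), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frame_iter = enumerate(u.trajectory)
        while True:
            try:
                i, ts = next(frame_iter)
            except StopIteration:
                break
            except (ValueError, OSError, EOFError) as exc:
                raise SystemInputError(f"malformed trajectory frame: {exc}") from exc
            if ts.positions.shape[0] != topology.n_atoms:
                raise SystemInputError(
                    f"frame {i}: {ts.positions.shape[0]} coordinates for "
                    f"{topology.n_atoms} topology atoms"
                )
            coords[i] = ts.positions
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                boxes[i] = ts.dimensions[:3]
            elif fallback_box is not None:
                boxes[i] = fallback_box
            else:
                raise SystemInputError(f"frame {i}: missing or zero box dimensions")
    times = np.arange(n_frames) * frame_interval
    trajectory = Trajectory(coords, boxes, times, frame_interval)
    return topology, trajectory


def write_table(records, path: str | Path) -> None:
    """Write tabular output as a TSV with a header row.

    Floats are rendered at 6 significant digits; row order is taken as
    given (callers sort), so identical records produce byte-identical
    files. Empty record sets are an error rather than an empty file.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    if df.empty:
        raise SystemInputError("refusing to write an empty table")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
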