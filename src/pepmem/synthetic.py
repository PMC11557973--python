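"""Synthetic peptide-bilayer trajectories with known binding kinetics.

A two-state (bound/unbound) continuous-time Markov chain drives peptide
placement: in latent-bound frames a fixed fraction of peptide atoms is
set down within ``contact_depth`` of upper-leaflet lipid sites, in
latent-unbound frames the whole peptide is lifted well beyond the
contact cutoff plus ``unbound_margin``. Placement is purely geometric
(no forces); the point is to give every downstream stage a trajectory
whose correct classification is known exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from pepmem.systems import (
    ROLE_LIPID,
    ROLE_PEPTIDE,
    SystemInputError,
    SystemTopology,
    Trajectory,
    write_table,
)

#: raw contact cutoff (A) the emitted geometry is guaranteed against
CUTOFF_REF = 3.5


class SyntheticParamError(ValueError):
    """Raised for parameter combinations that cannot be emitted."""


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs for the generator; defaults mimic a 7-mer over 60 lipids."""

    n_residues: int = 7
    atoms_per_residue: int = 4
    n_lipids: int = 60
    popg_fraction: float = 0.0      # 0.30 for the anionic "prokaryotic" mix
    box: tuple[float, float, float] = (42.0, 42.0, 84.0)
    leaflet_z: float = 15.0
    k_on: float = 0.1               # per ns
    k_off: float = 0.1              # per ns
    frame_interval: float = 0.1     # ns
    n_frames: int = 2000
    contact_depth: float = 2.0      # A, bound-atom height above lipid sites
    unbound_margin: float = 10.0    # A, clearance beyond the contact cutoff
    jitter_sigma: float = 0.3       # A, Gaussian positional noise (clipped)
    bound_atom_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.popg_fraction <= 1.0:
            raise SyntheticParamError("popg_fraction must lie in [0, 1]")
        if self.k_on < 0 or self.k_off < 0:
            raise SyntheticParamError("rates must be non-negative")
        if min(self.box) <= 0 or self.leaflet_z <= 0 or self.frame_interval <= 0:
            raise SyntheticParamError("lengths and frame_interval must be positive")
        if self.n_frames < 1 or self.n_residues < 1 or self.atoms_per_residue < 1:
            raise SyntheticParamError("counts must be at least 1")
        if self.n_lipids < 2:
            raise SyntheticParamError("need at least one lipid per leaflet")
        if not 0 < self.contact_depth < CUTOFF_REF:
            raise SyntheticParamError(
                f"contact_depth must lie in (0, {CUTOFF_REF}) to guarantee raw contacts"
            )
        if not 0.0 < self.bound_atom_fraction <= 1.0:
            raise SyntheticParamError("bound_atom_fraction must lie in (0, 1]")

    @property
    def n_peptide_atoms(self) -> int:
        return self.n_residues * self.atoms_per_residue

    @property
    def n_popg(self) -> int:
        return round(self.n_lipids * self.popg_fraction)


@dataclass
class GroundTruth:
    """Latent state path underlying an emitted trajectory."""

    state_per_frame: np.ndarray                 # (n_frames,) int, 1 = bound
    dwell_segments: list[tuple[int, int, int]]  # (state, start, end) end exclusive
    stationary_occupancy: float

    def __post_init__(self) -> None:
        self.state_per_frame = np.asarray(self.state_per_frame, dtype=int)
        n = len(self.state_per_frame)
        pos = 0
        prev_state = None
        for state, start, end in self.dwell_segments:
            if start != pos or end <= start:
                raise ValueError("dwell segments must partition [0, n_frames)")
            if prev_state is not None and state == prev_state:
                raise ValueError("consecutive dwell segments must alternate state")
            prev_state = state
            pos = end
        if pos != n:
            raise ValueError("dwell segments must cover every frame")

    @property
    def n_frames(self) -> int:
        return len(self.state_per_frame)


def _run_length_segments(states: np.ndarray) -> list[tuple[int, int, int]]:
    segments: list[tuple[int, int, int]] = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            segments.append((int(states[start]), start, i))
            start = i
    return segments


def sample_state_path(
    params: SyntheticParams,
    initial_state: Optional[int] = None,
) -> GroundTruth:
    """Sample the latent bound/unbound path of the two-state chain.

    The continuous-time chain (exponential dwells with rates k_on out of
    unbound, k_off out of bound) is discretised by reading off the state
    at each frame boundary; dwells shorter than one frame interval may
    therefore be invisible. The initial state is drawn from the
    stationary distribution unless forced via ``initial_state``.
    """
    total_rate = params.k_on + params.k_off
    if total_rate <= 0:
        raise SyntheticParamError("degenerate chain: k_on + k_off must be positive")
    occupancy = params.k_on / total_rate
    rng = np.random.default_rng(params.seed)
    if initial_state is None:
        state = int(rng.random() < occupancy)
    else:
        state = int(initial_state)

    dt = params.frame_interval
    horizon = params.n_frames * dt
    states = np.empty(params.n_frames, dtype=int)
    t = 0.0
    frame = 0
    while frame < params.n_frames:
        rate = params.k_off if state == 1 else params.k_on
        dwell = math.inf if rate == 0 else rng.exponential(1.0 / rate)
        t_next = t + dwell
        # frames whose timestamp falls inside [t, t_next)
        last = params.n_frames if t_next >= horizon else int(math.ceil(t_next / dt - 1e-12))
        last = min(last, params.n_frames)
        if last > frame:
            states[frame:last] = state
            frame = last
        t = t_next
        state = 1 - state
    return GroundTruth(states, _run_length_segments(states), occupancy)


def _leaflet_grid(n_sites: int, box_x: float, box_y: float) -> np.ndarray:
    nx = int(math.ceil(math.sqrt(n_sites)))
    ny = int(math.ceil(n_sites / nx))
    sx, sy = box_x / nx, box_y / ny
    xy = [((i + 0.5) * sx, (j + 0.5) * sy) for j in range(ny) for i in range(nx)]
    return np.array(xy[:n_sites], dtype=float)


def build_topology(params: SyntheticParams) -> SystemTopology:
    """Peptide residues PEP1..PEPn (atoms_per_residue each) followed by
    single-atom POPC/POPG lipid residues, POPG share = round(n * f)."""
    atom_names, resindex, resnames, roles, species = [], [], [], [], []
    for r in range(params.n_residues):
        resnames.append(f"PEP{r + 1}")
        for a in range(params.atoms_per_residue):
            atom_names.append(f"C{a + 1}")
            resindex.append(r)
            roles.append(ROLE_PEPTIDE)
            species.append("")
    n_upper = (params.n_lipids + 1) // 2
    popg_upper = min(n_upper, round(n_upper * params.popg_fraction))
    popg_lower = params.n_popg - popg_upper
    if not 0 <= popg_lower <= params.n_lipids - n_upper:
        popg_lower = max(0, min(params.n_lipids - n_upper, popg_lower))
        popg_upper = params.n_popg - popg_lower
    leaflet_popg = [popg_upper, popg_lower]
    leaflet_n = [n_upper, params.n_lipids - n_upper]
    lipid_id = 0
    for leaflet in range(2):
        for k in range(leaflet_n[leaflet]):
            name = "POPG" if k < leaflet_popg[leaflet] else "POPC"
            resnames.append(name)
            atom_names.append("P")
            resindex.append(params.n_residues + lipid_id)
            roles.append(ROLE_LIPID)
            species.append(name)
            lipid_id += 1
    return SystemTopology(
        atom_names=np.array(atom_names, dtype=object),
        residue_index=np.array(resindex, dtype=int),
        residue_names=np.array(resnames, dtype=object),
        roles=np.array(roles, dtype=object),
        lipid_species=np.array(species, dtype=object),
    )


def emit_trajectory(
    params: SyntheticParams,
    truth: GroundTruth,
) -> tuple[SystemTopology, Trajectory]:
    """Turn a latent state path into coordinates.

    Guarantees, by construction and with jitter clipped accordingly:

    * latent bound: ceil(bound_atom_fraction * n_peptide_atoms) atoms sit
      within CUTOFF_REF of an upper-leaflet lipid atom (at ~contact_depth);
      the remaining atoms sit clear of the cutoff;
    * latent unbound: every peptide atom is farther than
      CUTOFF_REF + unbound_margin from every lipid atom.
    """
    if truth.n_frames != params.n_frames:
        raise SyntheticParamError("ground truth length does not match n_frames")
    topology = build_topology(params)
    bx, by, bz = params.box

    n_upper = (params.n_lipids + 1) // 2
    upper_xy = _leaflet_grid(n_upper, bx, by)
    lower_xy = _leaflet_grid(params.n_lipids - n_upper, bx, by)
    lipid_pos = np.concatenate(
        [
            np.column_stack([upper_xy, np.full(len(upper_xy), params.leaflet_z)]),
            np.column_stack([lower_xy, np.full(len(lower_xy), -params.leaflet_z)]),
        ]
    )

    n_pep = params.n_peptide_atoms
    n_contact = int(math.ceil(params.bound_atom_fraction * n_pep))
    # jitter clipped so a contact atom can never stray past CUTOFF_REF
    contact_clip = min(
        3.0 * params.jitter_sigma if params.jitter_sigma > 0 else 0.0,
        0.99 * (CUTOFF_REF - params.contact_depth) / math.sqrt(3.0),
    )
    loose_clip = min(3.0 * params.jitter_sigma, 2.0)
    detached_z = params.leaflet_z + CUTOFF_REF + 3.0 + loose_clip  # bound, non-contact atoms
    unbound_z = params.leaflet_z + CUTOFF_REF + params.unbound_margin + 2.0 * loose_clip + 0.5
    # the lower leaflet's periodic image sits bz above it; keep the lifted
    # peptide clear of that image too
    raw_span = (unbound_z + loose_clip) + params.leaflet_z + loose_clip
    if bz - raw_span <= CUTOFF_REF + params.unbound_margin:
        raise SyntheticParamError(
            "box z too small for the bilayer slab plus the unbound clearance "
            f"(need > {raw_span + CUTOFF_REF + params.unbound_margin:.1f} A)"
        )

    # rest pose for non-contact / unbound atoms: compact xy cluster mid-box
    rest_xy = np.column_stack(
        [
            bx / 2 + 1.5 * np.cos(2 * np.pi * np.arange(n_pep) / n_pep),
            by / 2 + 1.5 * np.sin(2 * np.pi * np.arange(n_pep) / n_pep),
        ]
    )

    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0xC0A7)))
    coords = np.empty((params.n_frames, topology.n_atoms, 3), dtype=float)
    n_lip = params.n_lipids
    for f in range(params.n_frames):
        frame = np.empty((topology.n_atoms, 3))
        lip_jit = np.clip(
            rng.normal(0.0, params.jitter_sigma, (n_lip, 3)), -loose_clip, loose_clip
        ) if params.jitter_sigma > 0 else 0.0
        frame[n_pep:] = lipid_pos + lip_jit
        if truth.state_per_frame[f] == 1:
            sites = rng.integers(0, n_upper, n_contact)
            jit = np.clip(
                rng.normal(0.0, params.jitter_sigma, (n_contact, 3)),
                -contact_clip, contact_clip,
            ) if params.jitter_sigma > 0 else 0.0
            anchor = frame[n_pep + sites]  # jittered lipid atoms, contact is exact
            frame[:n_contact] = anchor + jit
            frame[:n_contact, 2] = anchor[:, 2] + params.contact_depth + (
                jit[:, 2] if params.jitter_sigma > 0 else 0.0
            )
            rest = np.clip(
                rng.normal(0.0, params.jitter_sigma, (n_pep - n_contact, 3)),
                -loose_clip, loose_clip,
            ) if params.jitter_sigma > 0 else 0.0
            frame[n_contact:n_pep, :2] = rest_xy[n_contact:] + (
                rest[:, :2] if params.jitter_sigma > 0 else 0.0
            )
            frame[n_contact:n_pep, 2] = detached_z + (
                rest[:, 2] if params.jitter_sigma > 0 else 0.0
            )
        else:
            jit = np.clip(
                rng.normal(0.0, params.jitter_sigma, (n_pep, 3)),
                -loose_clip, loose_clip,
            ) if params.jitter_sigma > 0 else 0.0
            frame[:n_pep, :2] = rest_xy + (jit[:, :2] if params.jitter_sigma > 0 else 0.0)
            frame[:n_pep, 2] = unbound_z + (jit[:, 2] if params.jitter_sigma > 0 else 0.0)
        coords[f] = frame

    boxes = np.tile(np.array([bx, by, bz]), (params.n_frames, 1))
    times = np.arange(params.n_frames) * params.frame_interval
    return topology, Trajectory(coords, boxes, times, params.frame_interval)


def generate(params: SyntheticParams, initial_state: Optional[int] = None):
    """Convenience wrapper: sample a path and emit its trajectory."""
    truth = sample_state_path(params, initial_state=initial_state)
    topology, trajectory = emit_trajectory(params, truth)
    return topology, trajectory, truth


# ---------------------------------------------------------------------------
# file output


def _as_universe(topology: SystemTopology, trajectory: Trajectory):
    import warnings

    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n_res = topology.n_residues
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            topology.n_atoms,
            n_residues=n_res,
            atom_resindex=topology.residue_index,
            residue_segindex=np.zeros(n_res, dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [str(n) for n in topology.atom_names])
        u.add_TopologyAttr("resnames", [str(n) for n in topology.residue_names])
        u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
        dims = np.hstack(
            [trajectory.boxes, np.full((trajectory.n_frames, 3), 90.0)]
        ).astype(np.float32)
        u.load_new(
            trajectory.coordinates.astype(np.float32),
            format=MemoryReader,
            dimensions=dims,
        )
    return u


def write_topology(topology: SystemTopology, trajectory: Trajectory, path: str | Path) -> None:
    """Write the first frame as a GRO (or PDB) topology file."""
    import warnings

    u = _as_universe(topology, trajectory)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.trajectory[0]
        u.atoms.write(str(path))


def write_trajectory(topology: SystemTopology, trajectory: Trajectory, path: str | Path) -> None:
    """Write all frames (multi-model PDB, or XTC by extension)."""
    import warnings

    import MDAnalysis as mda

    u = _as_universe(topology, trajectory)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_ground_truth(truth: GroundTruth, frame_interval: float, path: str | Path) -> None:
    """TSV of (frame, time_ns, latent_state)."""
    import pandas as pd

    write_table(
        pd.DataFrame(
            {
                "frame": np.arange(truth.n_frames),
                "time_ns": np.arange(truth.n_frames) * frame_interval,
                "latent_state": truth.state_per_frame,
            }
        ),
        path,
    )
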