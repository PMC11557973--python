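"""Per-frame contact geometry and bound/unbound state segmentation.

Classification rule: an atom is in contact when its minimum distance to
any membrane atom is <= contact_cutoff (3.5 A, inclusive); a frame is
raw-bound when at least min_bound_fraction (30%) of the peptide atoms
are in contact; the peptide is assigned the bound state on maximal runs
of raw-bound frames lasting at least persistence_frames (50) frames.
All three thresholds are inclusive at the boundary.

Distances use the minimum-image convention in all three dimensions of
an orthorhombic box when ``use_pbc`` is on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from pepmem.systems import SystemTopology, Trajectory

_FRAC_TOL = 1e-12  # guards == comparisons of ratios against the 0.30 threshold


@dataclass(frozen=True)
class ClassifierParams:
    contact_cutoff: float = 3.5         # A
    min_bound_fraction: float = 0.30
    persistence_frames: int = 50
    use_pbc: bool = True
    heavy_atoms_only: bool = False
    symmetric_debounce: bool = False    # also absorb short raw-unbound gaps

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if not 0.0 < self.min_bound_fraction <= 1.0:
            raise ValueError("min_bound_fraction must lie in (0, 1]")
        if self.persistence_frames < 1:
            raise ValueError("persistence_frames must be at least 1")


@dataclass
class ContactSeries:
    """Per-frame contact summary for one trajectory."""

    bound_fraction: np.ndarray      # (n_frames,)
    residue_min_dist: np.ndarray    # (n_frames, n_peptide_residues) A
    raw_bound: np.ndarray           # (n_frames,) bool
    peptide_residues: np.ndarray    # residue indices of the columns

    @property
    def n_frames(self) -> int:
        return len(self.bound_fraction)


@dataclass
class BindingEvent:
    start: int          # frame, inclusive
    end: int            # frame, exclusive
    duration: float     # ns

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class StateTrack:
    """Persistence-filtered state assignment."""

    states: np.ndarray              # (n_frames,) bool, True = bound
    events: list[BindingEvent]
    frame_interval: float           # ns

    @property
    def n_frames(self) -> int:
        return len(self.states)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def t_bound(self) -> float:
        """Total bound time in ns."""
        return sum(e.duration for e in self.events)

    @property
    def t_loose(self) -> float:
        """Total unbound time in ns."""
        return self.n_frames * self.frame_interval - self.t_bound


def _selections(topology: SystemTopology, params: ClassifierParams):
    pep = topology.peptide_atom_index
    mem = topology.membrane_atom_index
    if params.heavy_atoms_only:
        heavy = topology.heavy
        pep = pep[heavy[pep]]
        mem = mem[heavy[mem]]
    if len(mem) == 0:
        raise ValueError("membrane selection is empty")
    if len(pep) == 0:
        raise ValueError("peptide selection is empty")
    return pep, mem


def _pair_distances(
    coords: np.ndarray,   # (..., n_pep, 3)
    mem: np.ndarray,      # (..., n_mem, 3)
    box: Optional[np.ndarray],
) -> np.ndarray:
    """All peptide-membrane atom pair distances, minimum image if box given."""
    delta = coords[..., :, None, :] - mem[..., None, :, :]
    if box is not None:
        delta -= box * np.round(delta / box)
    return np.sqrt((delta * delta).sum(axis=-1))


def min_distances(
    frame_coords: np.ndarray,
    box: np.ndarray,
    topology: SystemTopology,
    params: ClassifierParams = ClassifierParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum distance of each peptide atom, and of each residue, to the membrane.

    Returns ``(per_atom, per_residue)`` for a single frame. Distances are
    Euclidean minima over all membrane atoms, under the minimum-image
    convention when ``params.use_pbc`` is set.
    """
    pep, mem = _selections(topology, params)
    box = np.asarray(box, dtype=float)
    if params.use_pbc and np.any(box <= 0):
        raise ValueError("use_pbc requires positive box lengths")
    d = _pair_distances(
        np.asarray(frame_coords)[pep], np.asarray(frame_coords)[mem],
        box if params.use_pbc else None,
    )
    per_atom = d.min(axis=-1)
    residues = topology.peptide_residues
    res_of_atom = topology.residue_index[pep]
    per_residue = np.array([per_atom[res_of_atom == r].min() for r in residues])
    return per_atom, per_residue


def contact_series(
    trajectory: Trajectory,
    topology: SystemTopology,
    params: ClassifierParams = ClassifierParams(),
    chunk_frames: int = 256,
) -> ContactSeries:
    """Compute bound fractions, per-residue minimum distances and raw flags.

    Frames are processed in chunks so the (frames x pep x mem) distance
    tensor stays small.
    """
    pep, mem = _selections(topology, params)
    residues = topology.peptide_residues
    res_of_atom = topology.residue_index[pep]
    # residues with no atoms in the selection (all-H under heavy_atoms_only)
    # get NaN distance columns
    res_masks = [res_of_atom == r for r in residues]

    n_frames = trajectory.n_frames
    fraction = np.empty(n_frames)
    res_min = np.full((n_frames, len(residues)), np.nan)
    for lo in range(0, n_frames, chunk_frames):
        hi = min(lo + chunk_frames, n_frames)
        coords = trajectory.coordinates[lo:hi]
        box = trajectory.boxes[lo:hi, None, None, :] if params.use_pbc else None
        if params.use_pbc and np.any(trajectory.boxes[lo:hi] <= 0):
            raise ValueError("use_pbc requires positive box lengths")
        d = _pair_distances(coords[:, pep], coords[:, mem], box)
        per_atom = d.min(axis=-1)                       # (chunk, n_pep)
        in_contact = per_atom <= params.contact_cutoff
        fraction[lo:hi] = in_contact.sum(axis=1) / len(pep)
        for j, mask in enumerate(res_masks):
            if mask.any():
                res_min[lo:hi, j] = per_atom[:, mask].min(axis=1)
    raw = fraction >= params.min_bound_fraction - _FRAC_TOL
    return ContactSeries(fraction, res_min, raw, residues)


def _runs(flags: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of equal flag value as (start, end, value)."""
    out = []
    start = 0
    for i in range(1, len(flags) + 1):
        if i == len(flags) or flags[i] != flags[start]:
            out.append((start, i, bool(flags[start])))
            start = i
    return out


def segment_states(
    series: ContactSeries,
    params: ClassifierParams = ClassifierParams(),
    frame_interval: float = 0.1,
) -> StateTrack:
    """Persistence-filter raw flags into bound segments.

    A bound segment is a maximal run of raw-bound frames of length
    >= persistence_frames; every other frame is unbound. With
    ``symmetric_debounce`` raw-unbound gaps shorter than the persistence
    window that are flanked by raw-bound runs are absorbed first.
    """
    if series.n_frames == 0:
        raise ValueError("empty contact series")
    raw = series.raw_bound.astype(bool).copy()
    if params.symmetric_debounce:
        runs = _runs(raw)
        for k, (start, end, value) in enumerate(runs):
            if (
                not value
                and end - start < params.persistence_frames
                and 0 < k < len(runs) - 1
            ):
                raw[start:end] = True
    states = np.zeros(series.n_frames, dtype=bool)
    events: list[BindingEvent] = []
    for start, end, value in _runs(raw):
        if value and end - start >= params.persistence_frames:
            states[start:end] = True
            events.append(BindingEvent(start, end, (end - start) * frame_interval))
    return StateTrack(states, events, frame_interval)


@dataclass
class BoundFractionSample:
    """Bound fractions restricted to bound-state frames (Fig-4b-style)."""

    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.values)

    def summary(self) -> dict:
        if self.n == 0:
            return {"n": 0, "median": None, "q1": None, "q3": None}
        q1, med, q3 = np.percentile(self.values, [25, 50, 75])
        return {"n": self.n, "median": float(med), "q1": float(q1), "q3": float(q3)}


def bound_fraction_distribution(
    series: ContactSeries, track: StateTrack
) -> BoundFractionSample:
    """Per-frame bound fractions over frames assigned the bound state."""
    if series.n_frames != track.n_frames:
        raise ValueError("series and track cover different frame counts")
    return BoundFractionSample(series.bound_fraction[track.states])
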