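"""Contact profiling: per-residue and per-lipid-species counts, z-position.

A contact is one (peptide atom, lipid atom) pair within the cutoff in
one frame; the same 3.5 A cutoff as the binding criterion is used by
default but is configurable separately. A residue-lipid pair counting
mode (at most one contact per residue-lipid pair per frame) is available
via ``pair_mode="residue"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pepmem.contacts import ClassifierParams, _pair_distances, _selections
from pepmem.systems import SystemTopology, Trajectory


@dataclass
class ContactCounts:
    """Aggregated contact counts over a trajectory."""

    residue_counts: dict[int, int]      # peptide residue index -> count
    species_counts: dict[str, int]      # lipid species -> count
    total: int

    @property
    def species_percent(self) -> dict[str, float] | None:
        """Per-species share in percent, or None when nothing touched."""
        if self.total == 0:
            return None
        return {s: 100.0 * c / self.total for s, c in self.species_counts.items()}


def contact_counts(
    trajectory: Trajectory,
    topology: SystemTopology,
    params: ClassifierParams = ClassifierParams(),
    cutoff: float | None = None,
    pair_mode: str = "atom",
    chunk_frames: int = 256,
) -> ContactCounts:
    """Count peptide-membrane contacts per residue and per lipid species.

    ``pair_mode="atom"`` counts atom pairs; ``"residue"`` counts distinct
    (peptide residue, lipid residue) pairs per frame.
    """
    if pair_mode not in ("atom", "residue"):
        raise ValueError("pair_mode must be 'atom' or 'residue'")
    cutoff = params.contact_cutoff if cutoff is None else cutoff
    pep, mem = _selections(topology, params)
    residues = topology.peptide_residues
    pep_res = topology.residue_index[pep]
    mem_res = topology.residue_index[mem]
    mem_species = np.array([str(s) for s in topology.lipid_species[mem]])
    species_labels = sorted({str(s) for s in mem_species})

    res_counts = {int(r): 0 for r in residues}
    sp_counts = {s: 0 for s in species_labels}
    for lo in range(0, trajectory.n_frames, chunk_frames):
        hi = min(lo + chunk_frames, trajectory.n_frames)
        coords = trajectory.coordinates[lo:hi]
        box = trajectory.boxes[lo:hi, None, None, :] if params.use_pbc else None
        d = _pair_distances(coords[:, pep], coords[:, mem], box)
        touch = d <= cutoff                             # (chunk, n_pep, n_mem)
        if pair_mode == "residue":
            # collapse to (peptide residue, lipid residue) incidence per frame
            for f in range(touch.shape[0]):
                fi, fj = np.nonzero(touch[f])
                seen = set(zip(pep_res[fi].tolist(), mem_res[fj].tolist()))
                for rp, rl in seen:
                    res_counts[int(rp)] += 1
                    sp = str(topology.lipid_species[topology.residue_index == rl][0])
                    sp_counts[sp] += 1
        else:
            per_pair = touch.sum(axis=0)                # (n_pep, n_mem)
            for r in residues:
                res_counts[int(r)] += int(per_pair[pep_res == r].sum())
            for s in species_labels:
                sp_counts[s] += int(per_pair[:, mem_species == s].sum())
    total = sum(res_counts.values())
    if total != sum(sp_counts.values()):
        raise AssertionError("residue and species contact totals disagree")
    return ContactCounts(res_counts, sp_counts, total)


@dataclass
class ZPositionSeries:
    """Signed distance of a residue centroid from the membrane midplane."""

    residue: int
    values: np.ndarray      # (n_frames,) A

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0

    def histogram(self, bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.values, bins=bins)


def z_position(
    trajectory: Trajectory,
    topology: SystemTopology,
    residue: int,
) -> ZPositionSeries:
    """z of a peptide residue's atom centroid relative to the lipid midplane.

    The midplane is the mean z of all membrane atoms in each frame; the
    sign follows the box z axis (positive above the midplane).
    """
    if residue not in set(int(r) for r in topology.peptide_residues):
        raise ValueError(f"residue {residue} is not a peptide residue")
    atom_mask = topology.residue_index == residue
    mem = topology.membrane_atom_index
    centroid_z = trajectory.coordinates[:, atom_mask, 2].mean(axis=1)
    midplane_z = trajectory.coordinates[:, mem, 2].mean(axis=1)
    return ZPositionSeries(int(residue), centroid_z - midplane_z)
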