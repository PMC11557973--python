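from __future__ import annotations

import numpy as np
import pytest

from pepmem.contacts import ClassifierParams
from pepmem.synthetic import SyntheticParams, emit_trajectory, sample_state_path
from pepmem.systems import (
    ROLE_LIPID,
    ROLE_PEPTIDE,
    SystemTopology,
    Trajectory,
)


@pytest.fixture(scope="session")
def default_classifier() -> ClassifierParams:
    return ClassifierParams()


@pytest.fixture
def small_params() -> SyntheticParams:
    return SyntheticParams(n_frames=300, seed=7)


@pytest.fixture
def small_system(small_params):
    truth = sample_state_path(small_params)
    topology, trajectory = emit_trajectory(small_params, truth)
    return topology, trajectory, truth


def make_topology(n_pep_atoms: int, n_mem_atoms: int,
                  pep_atoms_per_residue: int = 1,
                  species: list[str] | None = None) -> SystemTopology:
    """Hand-built topology: peptide atoms first, then 1-atom lipid residues."""
    n_pep_res = -(-n_pep_atoms // pep_atoms_per_residue)
    if species is None:
        species = ["POPC"] * n_mem_atoms
    resindex = [min(i // pep_atoms_per_residue, n_pep_res - 1) for i in range(n_pep_atoms)]
    resindex += [n_pep_res + j for j in range(n_mem_atoms)]
    resnames = [f"PEP{r + 1}" for r in range(n_pep_res)] + list(species)
    return SystemTopology(
        atom_names=np.array(["C"] * n_pep_atoms + ["P"] * n_mem_atoms, dtype=object),
        residue_index=np.array(resindex, dtype=int),
        residue_names=np.array(resnames, dtype=object),
        roles=np.array([ROLE_PEPTIDE] * n_pep_atoms + [ROLE_LIPID] * n_mem_atoms,
                       dtype=object),
        lipid_species=np.array([""] * n_pep_atoms + list(species), dtype=object),
    )


def make_trajectory(coords: np.ndarray, box=(100.0, 100.0, 100.0),
                    frame_interval: float = 0.1) -> Trajectory:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[0]
    boxes = np.tile(np.asarray(box, dtype=float), (n, 1))
    return Trajectory(coords, boxes, np.arange(n) * frame_interval, frame_interval)


def random_small_system(rng: np.random.Generator,
                        max_atoms: int = 50, max_frames: int = 200):
    """Randomized tiny system for oracle-equivalence checks."""
    n_pep = int(rng.integers(2, min(20, max_atoms - 2) + 1))
    n_mem = int(rng.integers(2, max_atoms - n_pep + 1))
    n_frames = int(rng.integers(2, max_frames + 1))
    box = rng.uniform(8.0, 30.0, 3)
    coords = rng.uniform(0.0, 1.0, (n_frames, n_pep + n_mem, 3)) * box
    species = [str(s) for s in rng.choice(["POPC", "POPG"], n_mem)]
    topology = make_topology(n_pep, n_mem, species=species)
    trajectory = make_trajectory(coords, box)
    return topology, trajectory
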