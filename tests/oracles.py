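"""Independent brute-force reference implementations used only by tests.

These deliberately take a different computational route from the package:
minimum-image distances are found by explicitly scanning all 27 periodic
images with scipy's cdist, state segmentation by an explicit per-frame
run scan, and contact counts by per-frame pair enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.spatial.distance import cdist

SHIFTS = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)


def brute_min_image(pep: np.ndarray, mem: np.ndarray, box) -> np.ndarray:
    """(n_pep, n_mem) distance matrix via explicit 27-image scan."""
    box = np.asarray(box, dtype=float)
    best = np.full((len(pep), len(mem)), np.inf)
    for shift in SHIFTS:
        best = np.minimum(best, cdist(pep, mem + shift * box))
    return best


def brute_contact_stats(coords, boxes, pep_idx, mem_idx, cutoff, min_fraction,
                        use_pbc=True):
    """Per-frame (per_atom_min, fraction, raw_flag, pair_count_matrix sums)."""
    n_frames = coords.shape[0]
    per_atom = np.empty((n_frames, len(pep_idx)))
    fraction = np.empty(n_frames)
    pair_counts = np.zeros((len(pep_idx), len(mem_idx)), dtype=int)
    for f in range(n_frames):
        if use_pbc:
            d = brute_min_image(coords[f, pep_idx], coords[f, mem_idx], boxes[f])
        else:
            d = cdist(coords[f, pep_idx], coords[f, mem_idx])
        per_atom[f] = d.min(axis=1)
        fraction[f] = (per_atom[f] <= cutoff).sum() / len(pep_idx)
        pair_counts += d <= cutoff
    raw = fraction >= min_fraction - 1e-12
    return per_atom, fraction, raw, pair_counts


def brute_segments(raw: np.ndarray, persistence: int) -> list[tuple[int, int]]:
    """Bound segments [(start, end)) by an explicit frame-by-frame scan."""
    events = []
    run_start = None
    for i, flag in enumerate(list(raw) + [False]):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= persistence:
                events.append((run_start, i))
            run_start = None
    return events


def ctmc_transition_matrix(k_on: float, k_off: float, dt: float) -> np.ndarray:
    """Exact frame-to-frame transition matrix of the two-state chain.

    Rows/cols ordered (unbound, bound).
    """
    k = k_on + k_off
    f = k_on / k
    decay = math.exp(-k * dt)
    return np.array(
        [
            [1 - f + f * decay, f - f * decay],
            [(1 - f) * (1 - decay), f + (1 - f) * decay],
        ]
    )


def simulate_discrete_chain(k_on, k_off, dt, n_frames, rng, initial=None) -> np.ndarray:
    """Frame-by-frame simulation using the exact transition matrix."""
    P = ctmc_transition_matrix(k_on, k_off, dt)
    f = k_on / (k_on + k_off)
    state = int(rng.random() < f) if initial is None else int(initial)
    out = np.empty(n_frames, dtype=int)
    for i in range(n_frames):
        out[i] = state
        state = int(rng.random() < P[state, 1])
    return out


def normal_equation_ols(x: np.ndarray, y: np.ndarray):
    """Closed-form OLS via the normal equations: returns (intercept, slope)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[0]), float(beta[1])
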