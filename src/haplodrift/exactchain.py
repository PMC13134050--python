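"""Exact Markov-chain enumeration of the two-deme drift model at tiny Ne.

For constant deme sizes and no migration the haplogroup count is a finite
Markov chain whose transition probabilities are binomial; the joint
distribution of (east count, west count) after any number of generations
can therefore be computed exactly by matrix propagation.  This is an
independent route to the same quantities the Monte-Carlo simulator
estimates, usable as an oracle wherever the state space is small enough.

The timeline matches the simulator: the generation-0 CAP state is
``round(p0 * cap_ne)``; ``cap_generations - 1`` drift updates inside the
CAP; binomial split sampling at the split generation; then
``post_generations`` per-deme drift updates.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom

__all__ = [
    "wf_transition_matrix",
    "exact_joint_distribution",
    "exact_difference_probability",
    "total_variation",
]


def wf_transition_matrix(ne_now: int, ne_next: int) -> np.ndarray:
    """(ne_now+1, ne_next+1) matrix of Binomial(ne_next, i/ne_now) pmfs."""
    i = np.arange(ne_now + 1)[:, None]
    j = np.arange(ne_next + 1)[None, :]
    return binom.pmf(j, ne_next, i / ne_now)


def exact_joint_distribution(
    cap_ne: int,
    cap_generations: int,
    ne_east: int,
    ne_west: int,
    post_generations: int,
    p0: float = 0.5,
) -> np.ndarray:
    """Joint pmf of (east count, west count) after the post-split phase.

    Conditional on the CAP count at the split, the demes evolve
    independently; the joint distribution is the CAP-count mixture of the
    outer products of the per-deme conditional distributions.
    """
    cap_dist = np.zeros(cap_ne + 1)
    cap_dist[int(round(p0 * cap_ne))] = 1.0
    t_cap = wf_transition_matrix(cap_ne, cap_ne)
    for _ in range(cap_generations - 1):
        cap_dist = cap_dist @ t_cap

    split_east = wf_transition_matrix(cap_ne, ne_east)  # row c: Binom(ne_e, c/cap)
    split_west = wf_transition_matrix(cap_ne, ne_west)
    t_east = np.linalg.matrix_power(wf_transition_matrix(ne_east, ne_east), post_generations)
    t_west = np.linalg.matrix_power(wf_transition_matrix(ne_west, ne_west), post_generations)
    cond_east = split_east @ t_east  # row c: deme distribution after post phase
    cond_west = split_west @ t_west

    joint = np.einsum("c,ci,cj->ij", cap_dist, cond_east, cond_west)
    return joint


def exact_difference_probability(
    joint: np.ndarray, ne_east: int, ne_west: int, threshold: float = 0.5
) -> float:
    """P(east frequency - west frequency >= threshold) under a joint pmf."""
    fe = np.arange(ne_east + 1)[:, None] / ne_east
    fw = np.arange(ne_west + 1)[None, :] / ne_west
    return float(joint[(fe - fw) >= threshold].sum())


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total variation distance between two pmfs on the same support."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())
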