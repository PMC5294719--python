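"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (explicit
enumeration, scipy.linalg.expm, hand-built rate entries) and never calls the
package's pruning or spectral code paths, so agreement is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import scipy.linalg

from wgdomega.genetics import UNIVERSAL, is_transition


def oracle_rate_matrix(pi, kappa, omega, code=UNIVERSAL) -> np.ndarray:
    """GY-style generator built by explicit codon-pair loops, scaled to one
    expected substitution per codon per unit time."""
    n = code.n_states
    codons = code.sense_codons
    Q = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diffs = [k for k in range(3) if codons[i][k] != codons[j][k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            rate = pi[j]
            if is_transition(codons[i][k], codons[j][k]):
                rate *= kappa
            if code.codon_to_aa[codons[i]] != code.codon_to_aa[codons[j]]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    return Q / scale


def brute_force_loglik(alignment, tree, omega_of_class, kappa, pi, code=UNIVERSAL):
    """Fully independent exhaustive oracle: transition matrices from
    scipy.linalg.expm of the hand-built generator, summation by enumeration."""
    nodes = list(tree.postorder())
    root = nodes[-1]
    P = {}
    for n in nodes:
        if n is root:
            continue
        Q = oracle_rate_matrix(pi, kappa, omega_of_class[n.branch_class], code)
        P[id(n)] = scipy.linalg.expm(Q * float(n.length))
    return exhaustive_loglik_given_P(alignment, tree, P, pi, code)


def exhaustive_loglik_given_P(alignment, tree, P, pi, code=UNIVERSAL):
    """Exhaustive summation over all ancestral-state assignments.

    ``P`` maps ``id(node)`` to that branch's transition matrix.  The joint
    probability is enumerated on a full grid over the internal nodes
    (vectorised but exhaustive), then summed — no pruning recursion.
    """
    nodes = list(tree.postorder())
    root = nodes[-1]
    internal = [n for n in nodes if n.children]
    n_states = code.n_states
    grids = np.meshgrid(*([np.arange(n_states)] * len(internal)), indexing="ij")
    grid_of = {id(n): g for n, g in zip(internal, grids)}
    parent_of = {}
    for n in nodes:
        for c in n.children:
            parent_of[id(c)] = n

    total = 0.0
    for site in range(alignment.n_codons):
        joint = pi[grid_of[id(root)]].astype(float)
        for n in nodes:
            if n is root:
                continue
            pg = grid_of[id(parent_of[id(n)])]
            if n.children:
                joint = joint * P[id(n)][pg, grid_of[id(n)]]
            else:
                s = alignment.row(n.name)[site]
                if s < 0:  # missing: marginalise the leaf state
                    joint = joint * P[id(n)].sum(axis=1)[pg]
                else:
                    joint = joint * P[id(n)][pg, s]
        total += math.log(joint.sum())
    return total


def taylor_transition(Q: np.ndarray, t: float, terms: int = 10) -> np.ndarray:
    """Truncated Taylor series for exp(Qt)."""
    n = Q.shape[0]
    out = np.eye(n)
    term = np.eye(n)
    for k in range(1, terms):
        term = term @ (Q * t) / k
        out = out + term
    return out


def rank_sum_exact_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    x = list(map(float, x))
    y = list(map(float, y))
    combined = x + y
    n = len(x)
    order = sorted(range(len(combined)), key=lambda i: combined[i])
    # midranks
    ranks = [0.0] * len(combined)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and combined[order[j + 1]] == combined[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    obs = sum(ranks[:n])
    mean = n * (len(combined) + 1) / 2
    count = 0
    total = 0
    for subset in itertools.combinations(range(len(combined)), n):
        total += 1
        stat = sum(ranks[i] for i in subset)
        if abs(stat - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def fisher_exact_p(a, b, c, d) -> float:
    """Two-sided Fisher p by hypergeometric enumeration."""

    def table_prob(a_, b_, c_, d_):
        return (
            math.comb(a_ + b_, a_)
            * math.comb(c_ + d_, c_)
            / math.comb(a_ + b_ + c_ + d_, a_ + c_)
        )

    row1, col1 = a + b, a + c
    n = a + b + c + d
    p_obs = table_prob(a, b, c, d)
    p = 0.0
    for a_ in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        b_, c_ = row1 - a_, col1 - a_
        d_ = n - row1 - c_
        prob = table_prob(a_, b_, c_, d_)
        if prob <= p_obs * (1 + 1e-12):
            p += prob
    return p


def chi2_2x2_stat(a, b, c, d) -> float:
    """Textbook chi-square statistic on a 2x2 table, no correction."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())
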