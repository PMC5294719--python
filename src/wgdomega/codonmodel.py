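"""Goldman–Yang codon substitution model with branch-specific dN/dS.

The instantaneous rate between sense codons *i* and *j* that differ at exactly
one nucleotide position is

    q_ij  ∝  pi_j * kappa^{I[transition]} * omega^{I[nonsynonymous]}

and zero for multi-position changes.  ``kappa`` is the transition/transversion
rate ratio and ``omega`` the nonsynonymous/synonymous rate ratio (dN/dS).  The
matrix is rescaled so that one unit of branch length equals one expected
substitution per codon at equilibrium, making branch lengths comparable across
models that share the same frequencies.

Alignment log-likelihoods are computed by Felsenstein pruning over a rooted
tree whose branches carry classes (``0, a1, b1, a2, b2``); each class maps to
one omega.  Because the chain is reversible, transition probabilities and
their parameter derivatives come from the eigendecomposition of the
symmetrised generator, which also yields an analytic gradient of the
log-likelihood in all branch lengths, kappa, and the per-class omegas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .alignment import MISSING, CodonAlignment, CodonFrequencies
from .genetics import UNIVERSAL, GeneticCode

#: canonical branch-class order used throughout the package
CLASS_ORDER = ("0", "a1", "b1", "a2", "b2")

_ROW_SUM_TOL = 1e-10


@dataclass(frozen=True)
class CodonRateMatrix:
    """A scaled codon generator together with its parameters.

    ``Q`` has rows summing to zero and satisfies detailed balance
    ``pi_i q_ij = pi_j q_ji``; ``scale`` is the expected number of
    substitutions per codon per unit time after rescaling (always 1).
    """

    Q: np.ndarray
    kappa: float
    omega: float
    pi: np.ndarray
    code: GeneticCode = UNIVERSAL
    scale: float = 1.0


def _raw_rate_matrix(
    pi: np.ndarray, kappa: float, omega: float, code: GeneticCode
) -> tuple[np.ndarray, float]:
    """Unscaled GY-style generator and its equilibrium substitution rate."""
    single = code.single_step
    ts = code.transition_step
    syn = code.synonymous_step
    R = np.where(single, pi[None, :], 0.0)
    R = R * np.where(ts, kappa, 1.0) * np.where(single & ~syn, omega, 1.0)
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=1))
    s = -float(pi @ np.diag(R))
    return R, s


def build_rate_matrix(
    freqs: CodonFrequencies,
    kappa: float,
    omega: float,
    code: GeneticCode | None = None,
) -> CodonRateMatrix:
    """Build the scaled codon rate matrix for one (kappa, omega)."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    code = code or freqs.code
    R, s = _raw_rate_matrix(freqs.pi, kappa, omega, code)
    if s <= 0:
        raise ValueError("degenerate frequencies: zero expected substitution rate")
    return CodonRateMatrix(Q=R / s, kappa=kappa, omega=omega, pi=freqs.pi, code=code)


class SpectralGenerator:
    """Eigendecomposition of a reversible generator.

    Provides transition probabilities ``P(t) = exp(Qt)`` and directional
    derivatives of ``P(t)`` with respect to rate parameters via the
    Daleckii–Krein (Frechet) formula in the eigenbasis of the symmetrised
    generator ``S = D^{1/2} Q D^{-1/2}`` with ``D = diag(pi)``.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = Q
        self.pi = pi
        sq = np.sqrt(pi)
        S = (sq[:, None] * Q) / sq[None, :]
        S = 0.5 * (S + S.T)  # symmetric up to rounding
        lam, U = np.linalg.eigh(S)
        self.lam = lam
        self.A = U / sq[:, None]  # D^{-1/2} U
        self.B = U.T * sq[None, :]  # U^T D^{1/2}

    def transition(self, t: float) -> np.ndarray:
        """exp(Qt) with rows clipped/renormalised to exact stochasticity."""
        if t == 0.0:
            return np.eye(len(self.lam))
        P = (self.A * np.exp(self.lam * t)[None, :]) @ self.B
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def in_eigenbasis(self, M: np.ndarray) -> np.ndarray:
        """Conjugate a generator-space matrix into the eigenbasis: B M A."""
        return self.B @ M @ self.A

    def frechet_weights(self, t: float) -> np.ndarray:
        """Matrix F with F_ij = (e^{l_i t} - e^{l_j t}) / (l_i - l_j)."""
        lam = self.lam
        dl = lam[:, None] - lam[None, :]
        e = np.exp(lam * t)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (e[:, None] - e[None, :]) / dl
        near = np.abs(dl) < 1e-12
        F[near] = (t * e[None, :] * np.ones_like(dl))[near]
        return F


def transition_probability(Q: CodonRateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to one, entries in [0, 1].

    Uses the spectral route; falls back to scaling-and-squaring if the
    reconstruction is poorly conditioned.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    spec = SpectralGenerator(Q.Q, Q.pi)
    P = spec.transition(t)
    if not np.all(np.isfinite(P)) or np.abs(P.sum(axis=1) - 1).max() > _ROW_SUM_TOL:
        P = scipy.linalg.expm(Q.Q * t)
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------


class _ClassModel:
    """Spectral machinery for one branch class's (kappa, omega)."""

    def __init__(self, pi: np.ndarray, kappa: float, omega: float, code: GeneticCode):
        self.kappa = kappa
        self.omega = omega
        R, s = _raw_rate_matrix(pi, kappa, omega, code)
        self.Q = R / s
        self.spec = SpectralGenerator(self.Q, pi)
        # derivative matrices dQ/dkappa, dQ/domega of the *scaled* generator:
        # dQ = (dR - Q ds) / s where dR/dtheta keeps only theta-bearing entries.
        single = code.single_step
        ts = code.transition_step
        nonsyn = single & ~code.synonymous_step
        self._dQ = {}
        for name, mask, value in (("kappa", ts, kappa), ("omega", nonsyn, omega)):
            dR = np.where(mask, R / value, 0.0)
            np.fill_diagonal(dR, 0.0)
            np.fill_diagonal(dR, -dR.sum(axis=1))
            ds = -float(pi @ np.diag(dR))
            self._dQ[name] = (dR - self.Q * ds) / s
        self._V = {k: self.spec.in_eigenbasis(v) for k, v in self._dQ.items()}

    def V(self, name: str) -> np.ndarray:
        return self._V[name]


class PruningEngine:
    """Compiled likelihood evaluator for one alignment x labeled tree.

    The tree is flattened once (postorder node arrays, per-leaf partial
    matrices over compressed site patterns); every call then evaluates the
    log-likelihood — and optionally its gradient — for a vector of branch
    lengths, a shared kappa, and one omega per branch class present.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree,
        freqs: CodonFrequencies,
        code: GeneticCode | None = None,
    ):
        self.code = code or alignment.code
        self.freqs = freqs
        self.pi = freqs.pi
        n_states = self.code.n_states

        # -- flatten the tree in postorder -----------------------------------
        nodes = list(tree.postorder())
        self.nodes = nodes
        self.n_nodes = len(nodes)
        index = {id(n): i for i, n in enumerate(nodes)}
        self.children: list[list[int]] = [
            [index[id(c)] for c in n.children] for n in nodes
        ]
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        for i, n in enumerate(nodes):
            for c in self.children[i]:
                self.parent[c] = i
        self.root = self.n_nodes - 1

        classes = []
        for i, n in enumerate(nodes):
            if i == self.root:
                classes.append(None)
                continue
            if n.branch_class is None:
                raise ValueError(f"branch above node {n.name!r} has no class")
            classes.append(n.branch_class)
        self.classes_present: tuple[str, ...] = tuple(
            c for c in CLASS_ORDER if c in set(classes) - {None}
        )
        extra = set(classes) - {None} - set(CLASS_ORDER)
        if extra:
            raise ValueError(f"unknown branch classes {sorted(extra)}")
        cls_index = {c: k for k, c in enumerate(self.classes_present)}
        self.branch_class = np.array(
            [cls_index.get(c, -1) for c in classes], dtype=np.int64
        )
        self.tree_lengths = np.array(
            [0.0 if i == self.root else float(nodes[i].length or 0.0) for i in range(self.n_nodes)]
        )

        # -- site patterns ---------------------------------------------------
        leaf_rows = {}
        for i, n in enumerate(nodes):
            if not self.children[i]:
                if n.name not in alignment.taxa:
                    raise ValueError(f"leaf {n.name!r} has no sequence in the alignment")
                leaf_rows[i] = alignment.row(n.name)
        self.leaf_ids = sorted(leaf_rows)
        mat = np.stack([leaf_rows[i] for i in self.leaf_ids])  # (n_leaves, n_sites)
        patterns, weights = np.unique(mat, axis=1, return_counts=True)
        self.pattern_weights = weights.astype(float)
        self.n_patterns = patterns.shape[1]
        self.n_sites = mat.shape[1]

        self._leaf_partials = {}
        for r, i in enumerate(self.leaf_ids):
            L = np.zeros((n_states, self.n_patterns))
            states = patterns[r]
            miss = states == MISSING
            L[:, miss] = 1.0
            cols = np.nonzero(~miss)[0]
            L[states[cols], cols] = 1.0
            self._leaf_partials[i] = L

        self._class_cache: dict[tuple[float, float], _ClassModel] = {}

    # -- parameter plumbing --------------------------------------------------

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def branch_length_vector(self) -> np.ndarray:
        """Branch lengths read off the tree, in engine (postorder) order."""
        return self.tree_lengths[: self.n_branches].copy()

    def _class_model(self, kappa: float, omega: float) -> _ClassModel:
        key = (round(kappa, 14), round(omega, 14))
        model = self._class_cache.get(key)
        if model is None:
            model = _ClassModel(self.pi, kappa, omega, self.code)
            if len(self._class_cache) > 64:
                self._class_cache.clear()
            self._class_cache[key] = model
        return model

    def _omega_vector(self, omega_by_class) -> np.ndarray:
        if isinstance(omega_by_class, Mapping):
            try:
                return np.array(
                    [float(omega_by_class[c]) for c in self.classes_present]
                )
            except KeyError as exc:
                raise ValueError(f"no omega given for branch class {exc}") from exc
        om = np.asarray(omega_by_class, dtype=float)
        if om.shape != (len(self.classes_present),):
            raise ValueError(
                f"expected one omega per class {self.classes_present}, got {om.shape}"
            )
        return om

    # -- likelihood ----------------------------------------------------------

    def _forward(self, bl, kappa, omegas):
        """Postorder pass; returns (models, P, L, M, node_scale, scale_log, site_lik)."""
        models = [self._class_model(kappa, om) for om in omegas]
        P = [None] * self.n_nodes
        for i in range(self.n_branches):
            P[i] = models[self.branch_class[i]].spec.transition(bl[i])
        L = [None] * self.n_nodes
        M = [None] * self.n_nodes
        node_scale = [None] * self.n_nodes
        scale_log = np.zeros(self.n_patterns)
        for i in range(self.n_nodes):
            if not self.children[i]:
                L[i] = self._leaf_partials[i]
            else:
                prod = None
                for c in self.children[i]:
                    M[c] = P[c] @ L[c]
                    prod = M[c] if prod is None else prod * M[c]
                m = prod.max(axis=0)
                m[m <= 0] = 1.0
                node_scale[i] = m
                L[i] = prod / m
                scale_log += np.log(m)
        site_lik = self.pi @ L[self.root]
        return models, P, L, M, node_scale, scale_log, site_lik

    def loglik(self, branch_lengths, kappa: float, omega_by_class) -> float:
        """Alignment log-likelihood for the given parameters."""
        bl = np.asarray(branch_lengths, dtype=float)
        omegas = self._omega_vector(omega_by_class)
        *_, scale_log, site_lik = self._forward(bl, kappa, omegas)
        if np.any(site_lik <= 0) or not np.all(np.isfinite(site_lik)):
            return -np.inf
        return float(self.pattern_weights @ (np.log(site_lik) + scale_log))

    def loglik_grad(self, branch_lengths, kappa: float, omega_by_class):
        """Log-likelihood and its analytic gradient.

        Returns ``(ll, d_bl, d_kappa, d_omega)`` with ``d_bl`` over branches in
        engine order and ``d_omega`` over ``classes_present``.
        """
        bl = np.asarray(branch_lengths, dtype=float)
        omegas = self._omega_vector(omega_by_class)
        models, P, L, M, node_scale, scale_log, site_lik = self._forward(
            bl, kappa, omegas
        )
        if np.any(site_lik <= 0) or not np.all(np.isfinite(site_lik)):
            k = len(self.classes_present)
            return -np.inf, np.zeros(self.n_branches), 0.0, np.zeros(k)
        ll = float(self.pattern_weights @ (np.log(site_lik) + scale_log))
        w_over_l = self.pattern_weights / site_lik

        # preorder outer partials H_c for every branch (parent u -> child c):
        # H_c . M_c reproduces site_lik on the same scaling, so ratios of the
        # form H . dP . L / site_lik are scale-free.
        O = [None] * self.n_nodes
        O[self.root] = np.broadcast_to(self.pi[:, None], L[self.root].shape)
        H = [None] * self.n_nodes
        for i in range(self.n_nodes - 1, -1, -1):
            kids = self.children[i]
            if not kids:
                continue
            n_k = len(kids)
            # prefix/suffix sibling products, with the forward scaling divisor
            # of node i folded in once
            parent_side = O[i] / node_scale[i][None, :]
            if n_k == 1:
                sib = [parent_side]
            else:
                prefix = [parent_side]
                for c in kids[:-1]:
                    prefix.append(prefix[-1] * M[c])
                suffix = np.ones_like(parent_side)
                sib = [None] * n_k
                for k in range(n_k - 1, -1, -1):
                    sib[k] = prefix[k] * suffix
                    suffix = suffix * M[kids[k]]
            for k, c in enumerate(kids):
                H[c] = sib[k]
                O[c] = P[c].T @ H[c]

        d_bl = np.zeros(self.n_branches)
        d_kappa = 0.0
        d_omega = np.zeros(len(self.classes_present))
        for i in range(self.n_branches):
            model = models[self.branch_class[i]]
            spec = model.spec
            a = spec.A.T @ (H[i] * w_over_l[None, :])
            b = spec.B @ L[i]
            e = np.exp(spec.lam * bl[i])
            d_bl[i] = float((spec.lam * e) @ np.einsum("ip,ip->i", a, b))
            C = a @ b.T
            F = spec.frechet_weights(bl[i])
            CF = C * F
            d_kappa += float(np.sum(model.V("kappa") * CF))
            d_omega[self.branch_class[i]] += float(np.sum(model.V("omega") * CF))
        return ll, d_bl, d_kappa, d_omega


def log_likelihood(
    alignment: CodonAlignment,
    tree,
    omega_of_class: Mapping[str, float],
    kappa: float,
    freqs: CodonFrequencies,
    branch_lengths: Sequence[float] | None = None,
) -> float:
    """Pruning log-likelihood of a codon alignment on a class-labeled tree.

    Branch lengths default to those stored on the tree.  A single-leaf tree
    degenerates to the root prior: ``sum_sites log pi[observed]``.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    engine = PruningEngine(alignment, tree, freqs)
    bl = engine.branch_length_vector() if branch_lengths is None else branch_lengths
    return engine.loglik(bl, kappa, omega_of_class)
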