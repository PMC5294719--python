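"""Branch-partition dN/dS models, likelihood-ratio tests, and the R1–R4 cascade.

The statistical object is a codon branch model in which every branch class
(``0, a1, b1, a2, b2``) maps to one free omega parameter; a
:class:`BranchPartition` records that mapping.  Pairs of nested partitions
define the hypothesis tests used around a whole-genome duplication:

========  ====================================  =========================================
test      null                                  alternative
========  ====================================  =========================================
R1        one omega everywhere                  omega_0 vs omega_wgd (all post-WGD)
R2        R1 alternative                        omega_0 | omega_a1,b1 | omega_a2,b2
R3        R2 alternative                        omega_0 | omega_a1 | omega_b1 | omega_a2,b2
R4        R1 alternative                        omega_0 | omega_a1,a2 | omega_b1,b2
========  ====================================  =========================================

Each test adds exactly one free omega, so the likelihood-ratio statistic
``2(L1 - L0)`` is referred to a chi-square distribution with one degree of
freedom, rejecting at ``p < 0.05`` by default.

Fitting is joint maximum likelihood over kappa, the free omegas, and all
branch lengths, by bounded quasi-Newton (L-BFGS-B) on log-transformed
parameters with the analytic gradient from
:class:`~wgdomega.codonmodel.PruningEngine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .alignment import CodonAlignment, CodonFrequencies, estimate_codon_frequencies
from .codonmodel import CLASS_ORDER, PruningEngine
from .config import DEFAULT_OPTIONS, STRONG_PURIFYING_OMEGA, FitOptions


class OptimizerFailure(RuntimeError):
    """A likelihood optimisation produced an inconsistent result."""


# ---------------------------------------------------------------------------
# Partitions and hypothesis specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BranchPartition:
    """Mapping from branch classes to omega-parameter indices."""

    name: str
    class_to_param: Mapping[str, int]

    def __post_init__(self):
        mapping = dict(self.class_to_param)
        object.__setattr__(self, "class_to_param", mapping)
        if set(mapping) != set(CLASS_ORDER):
            raise ValueError(f"partition must map every class in {CLASS_ORDER}")
        indices = sorted(set(mapping.values()))
        if indices != list(range(len(indices))):
            raise ValueError("parameter indices must form 0..n-1 without gaps")

    @property
    def n_free_omegas(self) -> int:
        return len(set(self.class_to_param.values()))

    def is_nested_in(self, other: "BranchPartition") -> bool:
        """True if self is a coarsening of ``other`` (self nested in other)."""
        for c in CLASS_ORDER:
            for d in CLASS_ORDER:
                if (
                    other.class_to_param[c] == other.class_to_param[d]
                    and self.class_to_param[c] != self.class_to_param[d]
                ):
                    return False
        return True


_PARTITION_PRESETS: dict[str, dict[str, int]] = {
    "single": {"0": 0, "a1": 0, "b1": 0, "a2": 0, "b2": 0},
    "R1-alt": {"0": 0, "a1": 1, "b1": 1, "a2": 1, "b2": 1},
    "R2-alt": {"0": 0, "a1": 1, "b1": 1, "a2": 2, "b2": 2},
    "R3-alt": {"0": 0, "a1": 1, "b1": 2, "a2": 3, "b2": 3},
    "R4-alt": {"0": 0, "a1": 1, "b1": 2, "a2": 1, "b2": 2},
}
_PARTITION_ALIASES = {
    "R1-null": "single",
    "R2-null": "R1-alt",
    "R3-null": "R2-alt",
    "R4-null": "R1-alt",
}


def make_partition(name: str) -> BranchPartition:
    """Return a preset :class:`BranchPartition` by name.

    Known names: ``single`` (alias ``R1-null``), ``R1-alt`` (aliases
    ``R2-null``, ``R4-null``), ``R2-alt`` (alias ``R3-null``), ``R3-alt``,
    ``R4-alt``.
    """
    canonical = _PARTITION_ALIASES.get(name, name)
    if canonical not in _PARTITION_PRESETS:
        raise ValueError(f"unknown partition preset {name!r}")
    return BranchPartition(canonical, _PARTITION_PRESETS[canonical])


def custom_partition(name: str, class_to_param: Mapping[str, int]) -> BranchPartition:
    """A user-defined partition (e.g. the R2'/R3' variants)."""
    return BranchPartition(name, class_to_param)


@dataclass(frozen=True)
class HypothesisSpec:
    """A nested null/alternative partition pair."""

    name: str
    null_partition: BranchPartition
    alt_partition: BranchPartition
    df: int

    def __post_init__(self):
        if not self.null_partition.is_nested_in(self.alt_partition):
            raise ValueError(
                f"{self.name}: null partition is not nested in the alternative"
            )
        expected = self.alt_partition.n_free_omegas - self.null_partition.n_free_omegas
        if self.df != expected:
            raise ValueError(f"{self.name}: df must be {expected}")


_HYPOTHESES = {
    "R1": ("single", "R1-alt"),
    "R2": ("R1-alt", "R2-alt"),
    "R3": ("R2-alt", "R3-alt"),
    "R4": ("R1-alt", "R4-alt"),
}


def hypothesis(name: str) -> HypothesisSpec:
    """Preset hypothesis test R1/R2/R3/R4."""
    if name not in _HYPOTHESES:
        raise ValueError(f"unknown hypothesis {name!r}; use custom_hypothesis")
    null_name, alt_name = _HYPOTHESES[name]
    null, alt = make_partition(null_name), make_partition(alt_name)
    return HypothesisSpec(name, null, alt, alt.n_free_omegas - null.n_free_omegas)


def custom_hypothesis(
    name: str, null: BranchPartition, alt: BranchPartition
) -> HypothesisSpec:
    return HypothesisSpec(name, null, alt, alt.n_free_omegas - null.n_free_omegas)


# ---------------------------------------------------------------------------
# Model and results
# ---------------------------------------------------------------------------


class BranchOmegaModel:
    """Codon branch model for one orthogroup alignment on a labeled tree.

    Parameters
    ----------
    alignment : CodonAlignment
    tree : TreeNode
        Rooted tree with every non-root branch carrying a class.
    partition : BranchPartition or str
        Mapping of branch classes to free omegas (preset name accepted).
    freqs : CodonFrequencies, optional
        Defaults to frequencies estimated from the alignment under
        ``options.freq_mode``.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree,
        partition: BranchPartition | str = "single",
        freqs: CodonFrequencies | None = None,
        options: FitOptions = DEFAULT_OPTIONS,
    ):
        if isinstance(partition, str):
            partition = make_partition(partition)
        self.alignment = alignment
        self.tree = tree
        self.partition = partition
        self.options = options
        self.freqs = freqs or estimate_codon_frequencies(alignment, options.freq_mode)
        self.engine = PruningEngine(alignment, tree, self.freqs)

        # compress partition indices to the classes actually present
        present = self.engine.classes_present
        raw = [partition.class_to_param[c] for c in present]
        uniq = sorted(set(raw))
        remap = {p: k for k, p in enumerate(uniq)}
        self._class_param = np.array([remap[p] for p in raw])  # per present class
        self.n_free_omegas = len(uniq)
        #: present classes sharing each free omega, for reporting
        self.param_classes: list[tuple[str, ...]] = [
            tuple(c for c, p in zip(present, self._class_param) if p == k)
            for k in range(self.n_free_omegas)
        ]

    # -- parameter packing ---------------------------------------------------

    @property
    def n_params(self) -> int:
        return self.engine.n_branches + 1 + self.n_free_omegas

    def _unpack(self, x: np.ndarray):
        nb = self.engine.n_branches
        bl = np.exp(x[:nb])
        kappa = float(np.exp(x[nb]))
        omegas = np.exp(x[nb + 1 :])
        return bl, kappa, omegas

    def loglike(self, branch_lengths, kappa, omega_params) -> float:
        """Log-likelihood at explicit (natural-scale) parameter values."""
        om_class = np.asarray(omega_params)[self._class_param]
        return self.engine.loglik(branch_lengths, kappa, om_class)

    def _negloglike_grad(self, x: np.ndarray):
        bl, kappa, omegas = self._unpack(x)
        om_class = omegas[self._class_param]
        ll, d_bl, d_kappa, d_om_class = self.engine.loglik_grad(bl, kappa, om_class)
        if not np.isfinite(ll):
            return 1e300, np.zeros_like(x)
        d_om = np.zeros(self.n_free_omegas)
        np.add.at(d_om, self._class_param, d_om_class)
        # chain rule for log-parameters
        grad = np.concatenate([d_bl * bl, [d_kappa * kappa], d_om * omegas])
        return -ll, -grad

    def _bounds(self):
        o = self.options
        nb = self.engine.n_branches
        lo = np.concatenate(
            [
                np.full(nb, np.log(o.branch_length_bounds[0])),
                [np.log(o.kappa_bounds[0])],
                np.full(self.n_free_omegas, np.log(o.omega_bounds[0])),
            ]
        )
        hi = np.concatenate(
            [
                np.full(nb, np.log(o.branch_length_bounds[1])),
                [np.log(o.kappa_bounds[1])],
                np.full(self.n_free_omegas, np.log(o.omega_bounds[1])),
            ]
        )
        return lo, hi

    def _default_start(self) -> np.ndarray:
        o = self.options
        bl = self.engine.branch_length_vector()
        bl = np.where(bl > 0, bl, o.branch_length_init)
        x = np.concatenate(
            [np.log(bl), [np.log(o.kappa_init)], np.full(self.n_free_omegas, np.log(o.omega_init))]
        )
        lo, hi = self._bounds()
        return np.clip(x, lo, hi)

    def _start_from(self, start) -> np.ndarray:
        """Warm start from a nested fit's optimum (or explicit dict)."""
        if isinstance(start, BranchOmegaResults):
            if not start.model.partition.is_nested_in(self.partition):
                # fall back to its branch lengths/kappa, default omegas
                omegas = np.full(self.n_free_omegas, self.options.omega_init)
            else:
                omegas = np.array(
                    [
                        start.omega_by_class[classes[0]]
                        for classes in self.param_classes
                    ]
                )
            x = np.concatenate(
                [np.log(start.branch_lengths), [np.log(start.kappa)], np.log(omegas)]
            )
        elif isinstance(start, Mapping):
            bl = np.asarray(
                start.get("branch_lengths", self.engine.branch_length_vector())
            )
            bl = np.where(bl > 0, bl, self.options.branch_length_init)
            kappa = start.get("kappa", self.options.kappa_init)
            omegas = np.asarray(
                start.get("omegas", np.full(self.n_free_omegas, self.options.omega_init))
            )
            x = np.concatenate([np.log(bl), [np.log(kappa)], np.log(omegas)])
        else:
            raise TypeError("start must be BranchOmegaResults or a mapping")
        lo, hi = self._bounds()
        return np.clip(x, lo, hi)

    # -- fitting ---------------------------------------------------------------

    def fit(self, start=None, n_starts: int | None = None) -> "BranchOmegaResults":
        """Maximise the log-likelihood; returns the best of the configured starts.

        ``start`` may be the :class:`BranchOmegaResults` of a nested fit
        (warm start) or a mapping with ``branch_lengths``/``kappa``/``omegas``.
        Deterministic given ``options.seed``.
        """
        o = self.options
        if n_starts is None:
            n_starts = o.n_starts
        x0 = self._default_start() if start is None else self._start_from(start)
        lo, hi = self._bounds()
        rng = np.random.default_rng(o.seed)
        best = None
        n_iter = 0
        for k in range(max(1, n_starts)):
            xk = x0 if k == 0 else np.clip(x0 + rng.normal(0, 0.3, x0.shape), lo, hi)
            res = scipy.optimize.minimize(
                self._negloglike_grad,
                xk,
                jac=True,
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
                options={
                    "maxiter": o.max_iter,
                    "ftol": o.lnl_rel_tol,
                    "gtol": 1e-6,
                },
            )
            n_iter += res.nit
            if best is None or res.fun < best.fun:
                best = res
        bl, kappa, omegas = self._unpack(best.x)
        return BranchOmegaResults(
            model=self,
            llf=-float(best.fun),
            omega=omegas,
            kappa=kappa,
            branch_lengths=bl,
            converged=bool(best.success),
            n_iter=int(n_iter),
            message=str(best.message),
        )


@dataclass
class BranchOmegaResults:
    """Maximum-likelihood estimates for one branch partition.

    ``omega`` holds one estimate per free omega parameter;
    ``omega_by_class`` expands it to the branch classes present.
    """

    model: BranchOmegaModel
    llf: float
    omega: np.ndarray
    kappa: float
    branch_lengths: np.ndarray
    converged: bool
    n_iter: int
    message: str = ""

    @property
    def omega_by_class(self) -> dict[str, float]:
        present = self.model.engine.classes_present
        return {
            c: float(self.omega[self.model._class_param[i]])
            for i, c in enumerate(present)
        }

    @property
    def partition(self) -> BranchPartition:
        return self.model.partition

    @property
    def n_free_params(self) -> int:
        return self.model.n_params

    def lrt_against(self, null: "BranchOmegaResults", alpha=None) -> "TestResult":
        """Likelihood-ratio test with this fit as the alternative."""
        return likelihood_ratio_test(null, self, alpha=alpha)

    def summary(self) -> str:
        lines = [
            "Branch-omega model fit",
            "=" * 54,
            f"partition:        {self.partition.name}",
            f"log-likelihood:   {self.llf:.6f}",
            f"kappa:            {self.kappa:.4f}",
            f"free omegas:      {self.model.n_free_omegas}",
        ]
        for k, classes in enumerate(self.model.param_classes):
            lines.append(
                f"  omega[{','.join(classes)}] = {float(self.omega[k]):.4f}"
            )
        lines += [
            f"branch lengths:   {len(self.branch_lengths)} "
            f"(tree length {self.branch_lengths.sum():.4f})",
            f"converged:        {self.converged} ({self.n_iter} iterations)",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Likelihood-ratio test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    """One likelihood-ratio test between nested fits."""

    name: str
    lrt: float
    df: int
    p: float
    rejected: bool
    null_fit: BranchOmegaResults
    alt_fit: BranchOmegaResults


def likelihood_ratio_test(
    null_fit: BranchOmegaResults,
    alt_fit: BranchOmegaResults,
    df: int | None = None,
    alpha: float | None = None,
    name: str | None = None,
) -> TestResult:
    """LRT = 2(lnL_alt - lnL_null) against chi-square(df).

    ``df`` defaults to the difference in free omegas actually estimated.
    A statistic more negative than -1e-6 signals an optimiser failure (the
    models are nested, so the true statistic cannot be negative).
    """
    if alpha is None:
        alpha = null_fit.model.options.alpha
    if df is None:
        df = alt_fit.model.n_free_omegas - null_fit.model.n_free_omegas
    if df < 1:
        raise ValueError("alternative adds no free parameters on this tree")
    lrt = 2.0 * (alt_fit.llf - null_fit.llf)
    if lrt < -1e-6:
        raise OptimizerFailure(
            f"negative LRT {lrt:.3g}: refit the alternative from the null optimum"
        )
    lrt = max(lrt, 0.0)
    p = float(scipy.stats.chi2.sf(lrt, df))
    return TestResult(
        name=name or f"{null_fit.partition.name} vs {alt_fit.partition.name}",
        lrt=float(lrt),
        df=int(df),
        p=p,
        rejected=bool(p < alpha),
        null_fit=null_fit,
        alt_fit=alt_fit,
    )


# ---------------------------------------------------------------------------
# The hypothesis cascade
# ---------------------------------------------------------------------------


@dataclass
class OrthogroupVerdict:
    """Per-orthogroup outcome of the hypothesis cascade.

    Flags are derived solely from the stored test results: ``omega_change``
    (R1), ``accel_then_decel`` (R2), ``immediate_asymmetry`` (R3),
    ``clade_asymmetry`` (R4); ``strong_purifying`` marks a non-WGD omega
    below 0.02 in the R1 alternative fit, and ``slow_clade`` names the
    paralogous clade with the smaller omega when R4 rejects.
    """

    orthogroup_id: str
    tests: dict[str, TestResult]
    fits: dict[str, BranchOmegaResults]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def omega_change(self) -> bool:
        return "R1" in self.tests and self.tests["R1"].rejected

    @property
    def accel_then_decel(self) -> bool:
        return "R2" in self.tests and self.tests["R2"].rejected

    @property
    def immediate_asymmetry(self) -> bool:
        return "R3" in self.tests and self.tests["R3"].rejected

    @property
    def clade_asymmetry(self) -> bool:
        return "R4" in self.tests and self.tests["R4"].rejected

    @property
    def omega_nonwgd(self) -> float | None:
        fit = self.fits.get("R1-alt")
        return None if fit is None else fit.omega_by_class.get("0")

    @property
    def omega_wgd(self) -> float | None:
        fit = self.fits.get("R1-alt")
        if fit is None:
            return None
        for c in ("a1", "b1", "a2", "b2"):
            if c in fit.omega_by_class:
                return fit.omega_by_class[c]
        return None

    @property
    def strong_purifying(self) -> bool:
        om = self.omega_nonwgd
        return om is not None and om < STRONG_PURIFYING_OMEGA

    @property
    def slow_clade(self) -> str:
        if not self.clade_asymmetry:
            return "none"
        fit = self.tests["R4"].alt_fit
        om = fit.omega_by_class
        om_a = om.get("a1", om.get("a2"))
        om_b = om.get("b1", om.get("b2"))
        if om_a is None or om_b is None:
            return "none"
        return "A" if om_a < om_b else "B"

    def as_record(self) -> dict:
        rec = {
            "orthogroup": self.orthogroup_id,
            "omega_change": self.omega_change,
            "strong_purifying": self.strong_purifying,
            "accel_then_decel": self.accel_then_decel,
            "immediate_asymmetry": self.immediate_asymmetry,
            "clade_asymmetry": self.clade_asymmetry,
            "slow_clade": self.slow_clade,
            "omega_nonwgd": self.omega_nonwgd,
            "omega_wgd": self.omega_wgd,
        }
        for name, t in self.tests.items():
            rec[f"{name}_lrt"] = t.lrt
            rec[f"{name}_p"] = t.p
        return rec


def run_cascade(
    alignment: CodonAlignment,
    tree,
    tests: Sequence[str | HypothesisSpec] = ("R1", "R2", "R3", "R4"),
    alpha: float | None = None,
    options: FitOptions = DEFAULT_OPTIONS,
    orthogroup_id: str = "",
) -> OrthogroupVerdict:
    """Fit the nested hypothesis cascade on one orthogroup.

    Fits are cached by partition name and shared across tests (the R1
    alternative serves as the null of both R2 and R4); every alternative is
    warm-started from its null's optimum, which also guarantees a
    non-negative likelihood-ratio statistic.  Per-test failures are recorded
    rather than raised.
    """
    if alpha is None:
        alpha = options.alpha
    specs = [hypothesis(t) if isinstance(t, str) else t for t in tests]
    freqs = estimate_codon_frequencies(alignment, options.freq_mode)
    fits: dict[str, BranchOmegaResults] = {}
    results: dict[str, TestResult] = {}
    failures: dict[str, str] = {}

    def get_fit(partition: BranchPartition, warm: BranchOmegaResults | None):
        if partition.name in fits:
            return fits[partition.name]
        model = BranchOmegaModel(
            alignment, tree, partition, freqs=freqs, options=options
        )
        fit = model.fit(start=warm, n_starts=1 if warm is not None else None)
        fits[partition.name] = fit
        return fit

    for spec in specs:
        try:
            null_fit = get_fit(spec.null_partition, None)
            alt_fit = get_fit(spec.alt_partition, null_fit)
            if alt_fit.llf < null_fit.llf - 1e-6:
                # optimiser wandered: refit the alternative from the null
                model = alt_fit.model
                alt_fit = model.fit(start=null_fit, n_starts=1)
                fits[spec.alt_partition.name] = alt_fit
            results[spec.name] = likelihood_ratio_test(
                null_fit, alt_fit, alpha=alpha, name=spec.name
            )
        except (OptimizerFailure, ValueError) as exc:
            failures[spec.name] = str(exc)
    return OrthogroupVerdict(
        orthogroup_id=orthogroup_id, tests=results, fits=fits, failures=failures
    )


def verdicts_to_frame(verdicts: Sequence[OrthogroupVerdict]) -> pd.DataFrame:
    """Tabulate verdicts, one row per orthogroup."""
    return pd.DataFrame([v.as_record() for v in verdicts])


def tests_to_frame(verdicts: Sequence[OrthogroupVerdict]) -> pd.DataFrame:
    """Long-format results: one row per orthogroup x test, with both fits'
    log-likelihoods, the statistic, and the alternative's estimates."""
    rows = []
    for v in verdicts:
        for name, t in v.tests.items():
            row = {
                "orthogroup": v.orthogroup_id,
                "test": name,
                "lnL0": t.null_fit.llf,
                "lnL1": t.alt_fit.llf,
                "lrt": t.lrt,
                "df": t.df,
                "p": t.p,
                "rejected": t.rejected,
                "kappa": t.alt_fit.kappa,
            }
            for cls, om in t.alt_fit.omega_by_class.items():
                row[f"omega_{cls}"] = om
            rows.append(row)
    return pd.DataFrame(rows)
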