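"""Shared configuration for model fitting and hypothesis testing."""

from __future__ import annotations

from dataclasses import dataclass, replace

import yaml

#: dN/dS threshold below which the non-WGD branch class is called
#: "strong purifying selection"
STRONG_PURIFYING_OMEGA = 0.02


@dataclass(frozen=True)
class FitOptions:
    """Options governing maximum-likelihood fits and the test cascade.

    All optimisation runs on log-transformed parameters with the bounds
    below; ``n_starts`` counts total starts (the first from the default or
    warm start, the rest jittered), and ``seed`` fixes the jitter.
    """

    alpha: float = 0.05
    freq_mode: str = "F3x4"
    omega_bounds: tuple[float, float] = (1e-4, 10.0)
    kappa_bounds: tuple[float, float] = (0.01, 100.0)
    branch_length_bounds: tuple[float, float] = (1e-6, 50.0)
    lnl_rel_tol: float = 1e-7
    max_iter: int = 500
    n_starts: int = 2
    seed: int = 0
    #: apply Benjamini-Hochberg across a batch of orthogroups (off: raw p)
    bh_correction: bool = False
    omega_init: float = 0.2
    kappa_init: float = 2.0
    branch_length_init: float = 0.1

    def replace(self, **kw) -> "FitOptions":
        return replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: str) -> "FitOptions":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("omega_bounds", "kappa_bounds", "branch_length_bounds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


DEFAULT_OPTIONS = FitOptions()
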