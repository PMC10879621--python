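"""Two-step MR mediation and bidirectional MR.

The total effect c of an exposure on an outcome is decomposed into the
indirect effect a·b carried by a mediator (a: exposure→mediator,
b: mediator→outcome, each from its own MR fit) and the direct effect
c′ = c − a·b. The proportion mediated is a·b/c, with a delta-method
symmetric 95% CI. The two MR steps are treated as independent (separate,
non-overlapping source studies), so covariance terms are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedProportionError
from .estimators import METHODS, MREstimate, Z95
from .harmonize import harmonize
from .instruments import SelectionConfig, select_instruments
from .sumstats import LDMatrix

import pandas as pd


def _beta_se(effect) -> tuple[float, float]:
    if isinstance(effect, MREstimate):
        return effect.beta, effect.se
    beta, se = effect
    return float(beta), float(se)


@dataclass(frozen=True)
class MediationResult:
    """Decomposition of a total effect into mediated and direct components.

    All effects are on the additive (log/SD) scale. ``indirect + c_prime``
    equals ``c`` by construction.
    """

    a: float
    a_se: float
    b: float
    b_se: float
    c: float
    c_se: float
    indirect: float
    indirect_se: float
    c_prime: float
    c_prime_se: float
    proportion: float
    proportion_se: float
    proportion_ci: tuple[float, float]

    def as_row(self) -> dict:
        return {
            "a": self.a, "a_se": self.a_se, "b": self.b, "b_se": self.b_se,
            "c": self.c, "c_se": self.c_se,
            "indirect": self.indirect, "indirect_se": self.indirect_se,
            "c_prime": self.c_prime, "c_prime_se": self.c_prime_se,
            "proportion": self.proportion, "proportion_se": self.proportion_se,
            "proportion_ci_low": self.proportion_ci[0],
            "proportion_ci_high": self.proportion_ci[1],
        }


def two_step_mediation(a, b, c) -> MediationResult:
    """Product-of-coefficients decomposition with delta-method SEs.

    Parameters are (beta, se) pairs or :class:`MREstimate`s for the
    exposure→mediator (a), mediator→outcome (b) and total exposure→outcome
    (c) effects, all on a consistent additive scale.
    """
    a_b, a_se = _beta_se(a)
    b_b, b_se = _beta_se(b)
    c_b, c_se = _beta_se(c)
    for name, se in (("a", a_se), ("b", b_se), ("c", c_se)):
        if not se > 0:
            raise ValueError(f"se of {name} must be > 0")
    if c_b == 0:
        raise UndefinedProportionError("total effect c is 0; proportion undefined")

    indirect = a_b * b_b
    indirect_se = float(np.sqrt(b_b**2 * a_se**2 + a_b**2 * b_se**2))
    c_prime = c_b - indirect
    c_prime_se = float(np.sqrt(c_se**2 + indirect_se**2))
    proportion = indirect / c_b
    # delta-method se |p|·sqrt(se_i²/i² + se_c²/c²), written so that a zero
    # or underflowing product degrades gracefully to se_indirect/|c|
    prop_se = float(np.hypot(indirect_se / c_b, indirect * c_se / c_b**2))
    ci = (proportion - Z95 * prop_se, proportion + Z95 * prop_se)
    return MediationResult(a_b, a_se, b_b, b_se, c_b, c_se,
                           indirect, indirect_se, c_prime, c_prime_se,
                           proportion, prop_se, ci)


def bidirectional_mr(exposure_stats: pd.DataFrame, outcome_stats: pd.DataFrame,
                     ld: LDMatrix, config: SelectionConfig | None = None,
                     methods: tuple[str, ...] = ("ivw",), seed: int = 0,
                     n_boot: int = 1000,
                     reverse_config: SelectionConfig | None = None,
                     eaf_ambiguity: float = 0.08) -> dict[str, dict[str, MREstimate]]:
    """Run MR in both directions between two traits.

    Forward: instruments selected from ``exposure_stats``, effects taken on
    ``outcome_stats``. Reverse: instruments selected from ``outcome_stats``
    (optionally with its own :class:`SelectionConfig`), effects taken on
    ``exposure_stats``. Returns ``{"forward": {...}, "reverse": {...}}``
    keyed by method name.
    """
    config = config or SelectionConfig()
    reverse_config = reverse_config or config
    results: dict[str, dict[str, MREstimate]] = {}
    for label, exp, out, cfg in (
        ("forward", exposure_stats, outcome_stats, config),
        ("reverse", outcome_stats, exposure_stats, reverse_config),
    ):
        inst = select_instruments(exp, ld, cfg)
        table = harmonize(inst, out, eaf_ambiguity=eaf_ambiguity)
        results[label] = {m: METHODS[m](table, seed, n_boot) for m in methods}
    return results
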