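"""Agreement between AI and reference-reader TCFA calls.

Cohen's kappa with the Fleiss–Cohen–Everitt asymptotic standard error is
implemented directly (the formulas are short and this keeps an independent
cross-check against statsmodels possible in the test-suite); exact
binomial confidence intervals for the diagnostic proportions come from
statsmodels (Clopper–Pearson, with Wilson as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class Table2x2:
    """Paired binary calls cross-tabulated.

    ``a`` both positive, ``b`` AI-positive/reference-negative, ``c``
    AI-negative/reference-positive, ``d`` both negative. In diagnostic
    orientation rows are the test/exposure and columns the truth/outcome.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci95: Tuple[float, float]


def build_contingency(
    calls_ai: Sequence[bool], calls_ref: Sequence[bool]
) -> Table2x2:
    """Cross-tabulate paired AI and reference calls (same unit order)."""
    ai = np.asarray(calls_ai, dtype=bool)
    ref = np.asarray(calls_ref, dtype=bool)
    if ai.shape != ref.shape or ai.ndim != 1:
        raise ValueError("call vectors must be 1-D and of equal length")
    return Table2x2(
        a=int(np.count_nonzero(ai & ref)),
        b=int(np.count_nonzero(ai & ~ref)),
        c=int(np.count_nonzero(~ai & ref)),
        d=int(np.count_nonzero(~ai & ~ref)),
    )


def cohen_kappa(table: Table2x2, alpha: float = 0.05) -> KappaResult:
    """Cohen's kappa with asymptotic (Fleiss–Cohen–Everitt) 95% CI.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement
    p_o = (a + d)/n and chance agreement p_e from the marginals. Raises on
    degenerate marginals (p_e = 1), where kappa is undefined.
    """
    n = table.n
    p = table.as_array() / n
    po = p[0, 0] + p[1, 1]
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float(row @ col)
    if np.isclose(pe, 1.0):
        raise ZeroDivisionError("kappa undefined: chance agreement is 1")
    kappa = (po - pe) / (1 - pe)

    # Fleiss, Cohen & Everitt large-sample variance of kappa-hat
    term_a = sum(
        p[i, i] * ((1 - pe) - (col[i] + row[i]) * (1 - po)) ** 2 for i in range(2)
    )
    term_b = (1 - po) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(2)
        for j in range(2)
        if i != j
    )
    term_c = (po * pe - 2 * pe + po) ** 2
    var = (term_a + term_b - term_c) / (n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(1 - alpha / 2)
    return KappaResult(
        kappa=float(kappa), se=se, ci95=(float(kappa - z * se), float(kappa + z * se))
    )


def percent_agreement(table: Table2x2) -> Tuple[float, float, float]:
    """(concordant-positive, concordant-negative, overall) fractions."""
    n = table.n
    return table.a / n, table.d / n, (table.a + table.d) / n


def _proportion_ci(x: int, n: int, method: str, alpha: float) -> Tuple[float, float]:
    meth = {"clopper-pearson": "beta", "wilson": "wilson"}[method]
    lo, hi = proportion_confint(x, n, alpha=alpha, method=meth)
    return float(lo), float(hi)


def diagnostic_metrics(
    table: Table2x2,
    method: str = "clopper-pearson",
    alpha: float = 0.05,
) -> Dict[str, Optional[dict]]:
    """Sensitivity, specificity, PPV, NPV with exact binomial CIs.

    The table is read in diagnostic orientation: rows = test (positive on
    top), columns = truth (positive left). Metrics whose denominator is
    zero are reported as ``None`` with an explanation.
    """
    pairs = {
        "sensitivity": (table.a, table.a + table.c),
        "specificity": (table.d, table.b + table.d),
        "ppv": (table.a, table.a + table.b),
        "npv": (table.d, table.c + table.d),
    }
    out: Dict[str, Optional[dict]] = {}
    for name, (x, denom) in pairs.items():
        if denom == 0:
            out[name] = None
            continue
        lo, hi = _proportion_ci(x, denom, method, alpha)
        out[name] = {
            "estimate": x / denom,
            "ci95": (lo, hi),
            "numerator": x,
            "denominator": denom,
        }
    return out
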