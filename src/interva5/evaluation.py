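"""Agreement between CSMF tables: Lin's concordance correlation coefficient.

Lin's CCC measures how well paired measurements fall on the identity
line y = x, combining Pearson correlation (precision) with a penalty
for location and scale shift (accuracy):

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (x̄ - ȳ)^2)

with population (n-denominator) moments, matching the Stata ``concord``
convention. The 95% interval uses the Fisher z-transform with Lin's
asymptotic standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .population import CSMFTable, INDETERMINATE

__all__ = ["EvaluationError", "CCCEstimate", "concordance_correlation",
           "compare_csmf"]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class CCCEstimate:
    rho_c: float
    ci_low: float
    ci_high: float
    n: int

    def __str__(self) -> str:  # mirrors the usual reporting style
        return (f"CCC = {self.rho_c:.3f} (95% CI {self.ci_low:.3f} to "
                f"{self.ci_high:.3f}), n = {self.n}")


def concordance_correlation(x, y, alpha: float = 0.05) -> CCCEstimate:
    """Lin's concordance correlation coefficient with a Fisher-z interval.

    Moments use n denominators. Requires at least 3 pairs; two constant
    equal vectors leave the coefficient undefined (0/0) and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EvaluationError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise EvaluationError(f"need at least 3 paired points, got {n}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise EvaluationError("missing values in paired vectors")

    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()          # population (n) denominators
    sxy = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        raise EvaluationError("both vectors constant with equal means; "
                              "concordance undefined")
    rho_c = 2.0 * sxy / denom

    # Fisher z interval with Lin's standard error. Degenerate when the
    # fit is exactly the identity line (rho_c = +/-1): zero-width CI.
    if abs(rho_c) >= 1.0 - 1e-12 or vx == 0.0 or vy == 0.0:
        return CCCEstimate(float(rho_c), float(rho_c), float(rho_c), n)
    r = sxy / np.sqrt(vx * vy)
    u = (mx - my) / (vx * vy) ** 0.25
    r2, p2 = r ** 2, rho_c ** 2
    var_z = (1.0 / (n - 2)) * (
        (1 - r2) * p2 / ((1 - p2) * r2)
        + 2 * rho_c ** 3 * (1 - rho_c) * u ** 2 / (r * (1 - p2) ** 2)
        - rho_c ** 4 * u ** 4 / (2 * r2 * (1 - p2) ** 2)
    )
    se_z = float(np.sqrt(max(var_z, 0.0)))
    z = np.arctanh(rho_c)
    zcrit = float(norm.ppf(1.0 - alpha / 2.0))
    lo, hi = np.tanh(z - zcrit * se_z), np.tanh(z + zcrit * se_z)
    return CCCEstimate(float(rho_c), float(lo), float(hi), n)


def compare_csmf(a: CSMFTable, b: CSMFTable, stratum: str,
                 include_indeterminate: bool = True,
                 ) -> tuple[pd.DataFrame, CCCEstimate]:
    """Pair two tables' fractions over a stratum and compute the CCC.

    Pairs are built over causes with a value present in both tables for
    the stratum — near-axis rare causes are deliberately kept, taking
    the conservative view of concordance. The indeterminate row is a
    pair like any other unless excluded by flag.
    """
    if stratum not in a.strata or stratum not in b.strata:
        raise EvaluationError(f"stratum {stratum!r} missing from a table")
    ra, rb = a.stratum_row(stratum), b.stratum_row(stratum)
    shared = [c for c in ra.index if c in rb.index
              and not (pd.isna(ra[c]) or pd.isna(rb[c]))]
    if not include_indeterminate:
        shared = [c for c in shared if c != INDETERMINATE]
    if len(shared) < 3:
        raise EvaluationError(f"only {len(shared)} shared causes in stratum "
                              f"{stratum!r}; need at least 3")
    pairs = pd.DataFrame({"cause": shared,
                          "x": [float(ra[c]) for c in shared],
                          "y": [float(rb[c]) for c in shared]})
    pairs["abs_diff"] = (pairs["x"] - pairs["y"]).abs()
    est = concordance_correlation(pairs["x"].to_numpy(), pairs["y"].to_numpy())
    return pairs, est
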