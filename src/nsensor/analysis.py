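"""Correlation and trend analysis of sensor attributes.

Builds the per-stage and pooled ("overall") Pearson correlation tables
between sensor attributes (SN, biomass, NDVI) and agronomic targets
(lab leaf N, lab chlorophyll, grain yield), and fits polynomial trends
of attributes against applied N rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import STAGES
from .errors import RankDeficiencyError, UndefinedInputError, ValidationError

ATTRIBUTES = ("sn", "biomass", "ndvi")
TARGETS = ("lab_n", "lab_chl", "yield_t_ha")


@dataclass(frozen=True)
class CorrelationCell:
    """One entry of the correlation table.

    ``stage`` is a growth-stage token or ``"overall"`` (all stages
    pooled).  ``flagged`` marks cells that could not be computed
    (insufficient or degenerate data); their r/p are NaN.
    """

    attribute: str
    target: str
    stage: str
    r: float
    p_value: float
    n: int
    flagged: bool = False


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment r with its two-sided p-value.

    The p-value uses the t transform with n - 2 degrees of freedom.
    Raises for fewer than 3 points or a constant input.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D")
    if len(xa) < 3:
        raise ValidationError("need >= 3 points for a correlation")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedInputError("correlation undefined for a constant input")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def correlation_table(observations: pd.DataFrame) -> list[CorrelationCell]:
    """Attribute x target correlations per stage plus pooled rows.

    One cell per (attribute, target) for every stage present in the
    data and one more pooling raw observations across stages.  Cells
    with fewer than 3 usable rows or constant data are flagged rather
    than raising, so a partial table still comes back.
    """
    stages_present = [s for s in STAGES if s in set(observations["stage"])]
    stages_present += sorted(set(observations["stage"]) - set(STAGES))
    groups = [(s, observations[observations["stage"] == s]) for s in stages_present]
    groups.append(("overall", observations))
    cells: list[CorrelationCell] = []
    for attr in ATTRIBUTES:
        for target in TARGETS:
            for stage, sub in groups:
                pair = sub[[attr, target]].dropna()
                try:
                    r, p = pearson(pair[attr], pair[target])
                    cells.append(
                        CorrelationCell(attr, target, stage, r, p, len(pair))
                    )
                except ValidationError:
                    cells.append(
                        CorrelationCell(
                            attr, target, stage, math.nan, math.nan,
                            len(pair), flagged=True,
                        )
                    )
    return cells


def correlation_frame(observations: pd.DataFrame) -> pd.DataFrame:
    """Long-format DataFrame view of :func:`correlation_table`."""
    cells = correlation_table(observations)
    return pd.DataFrame(
        [
            {
                "attribute": c.attribute,
                "target": c.target,
                "stage": c.stage,
                "r": c.r,
                "p_value": c.p_value,
                "n": c.n,
                "flagged": c.flagged,
            }
            for c in cells
        ]
    )


def trend_fit(
    n_rates: Sequence[float],
    attribute_values: Sequence[float],
    degree: int = 2,
) -> tuple[np.ndarray, float]:
    """OLS polynomial trend of an attribute against applied N rate.

    Returns coefficients in ascending order (c0, c1, ..., c_degree) and
    the coefficient of determination R^2.  Requires at least degree + 1
    distinct N rates.
    """
    n = np.asarray(n_rates, dtype=float)
    y = np.asarray(attribute_values, dtype=float)
    if n.shape != y.shape or n.ndim != 1:
        raise ValidationError("n_rates and values must be equal-length 1-D")
    if degree < 0:
        raise ValidationError("degree must be >= 0")
    if len(np.unique(n)) < degree + 1:
        raise RankDeficiencyError(
            f"need >= {degree + 1} distinct N rates for degree {degree}"
        )
    coeffs = np.polynomial.polynomial.polyfit(n, y, deg=degree)
    fitted = np.polynomial.polynomial.polyval(n, coeffs)
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    # constant response carries no variance to explain; define R^2 = 0
    r2 = 0.0 if sst == 0 else 1.0 - sse / sst
    return coeffs, r2
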