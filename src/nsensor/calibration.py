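"""Stage-specific calibration fits.

Two ordinary least-squares models connect the meter and sensor worlds:

* the quadratic response of the SPAD sufficiency index to applied N,
  ``SI_SPAD = a0 + a1*Nrate + a2*Nrate**2`` — concave (a2 < 0) for any
  usable calibration, since adding N past the optimum cannot raise leaf
  chlorophyll;
* the linear bridge from the sensor sufficiency index to the SPAD one,
  ``SI_SPAD = b0 + b1*SI_sensor`` — with b1 > 0 (greener canopy, higher
  chlorophyll).

Fits are plain OLS on per-plot values.  Published coefficient sets for
the tillering and booting stages of wheat ship as named fixtures and are
stored verbatim; note the tillering set is on an implausible scale
(SI_SPAD of ~36 at 150 kg N/ha) and is retained for reference only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import RankDeficiencyError, ValidationError

STAGES = ("tillering", "booting", "ear_emergence")


@dataclass(frozen=True)
class QuadraticResponse:
    """Coefficients of SI_SPAD = a0 + a1*N + a2*N^2.

    Units: ``a0`` dimensionless, ``a1`` per (kg N/ha), ``a2`` per
    (kg N/ha)^2.  ``a2 < 0`` (concavity) is required before the model
    may be inverted for a recommendation; a non-concave fit is allowed
    to exist so it can be inspected, but produces a warning.
    """

    a0: float
    a1: float
    a2: float
    n_points: int | None = None
    r_squared: float | None = None

    def predict(self, n_rate):
        """Evaluate SI_SPAD at the given N rate(s)."""
        n = np.asarray(n_rate, dtype=float)
        out = self.a0 + self.a1 * n + self.a2 * n * n
        return float(out) if out.ndim == 0 else out

    @property
    def is_concave(self) -> bool:
        return self.a2 < 0


@dataclass(frozen=True)
class LinearSIMap:
    """Coefficients of the bridge SI_SPAD = b0 + b1*SI_sensor."""

    b0: float
    b1: float
    n_points: int | None = None
    r_squared: float | None = None

    def predict(self, si_sensor):
        s = np.asarray(si_sensor, dtype=float)
        out = self.b0 + self.b1 * s
        return float(out) if out.ndim == 0 else out

    def invert(self, si_spad):
        """SI_sensor for a given SI_SPAD (requires b1 != 0)."""
        if self.b1 == 0:
            raise ValidationError("cannot invert a flat SI map (b1 == 0)")
        s = np.asarray(si_spad, dtype=float)
        out = (s - self.b0) / self.b1
        return float(out) if out.ndim == 0 else out


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS coefficients and R^2 for a full-rank design matrix."""
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {design.shape[1]} parameters"
        )
    resid = y - design @ coef
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    # constant response carries no variance to explain; define R^2 = 0
    r2 = 0.0 if sst == 0 else 1.0 - sse / sst
    return coef, r2


def fit_quadratic_response(
    n_rates: Sequence[float], si_spad: Sequence[float]
) -> QuadraticResponse:
    """Fit the quadratic N-response of SI_SPAD by OLS.

    Requires at least three observations at three distinct N rates.
    Warns (does not raise) when the fitted curve is not concave; the
    hard check happens when the fit is used to derive an algorithm.
    """
    n = np.asarray(n_rates, dtype=float)
    y = np.asarray(si_spad, dtype=float)
    if n.shape != y.shape or n.ndim != 1:
        raise ValidationError("n_rates and si_spad must be equal-length 1-D")
    if len(n) < 3 or len(np.unique(n)) < 3:
        raise RankDeficiencyError(
            "need >= 3 observations at >= 3 distinct N rates for a quadratic"
        )
    design = np.column_stack([np.ones_like(n), n, n * n])
    (a0, a1, a2), r2 = _ols(design, y)
    if a2 >= 0:
        warnings.warn(
            f"fitted quadratic is not concave (a2 = {a2:.4g} >= 0); "
            "this calibration cannot be inverted for a recommendation",
            stacklevel=2,
        )
    return QuadraticResponse(
        a0=float(a0), a1=float(a1), a2=float(a2), n_points=len(n), r_squared=r2
    )


def fit_linear_si_map(
    si_sensor: Sequence[float], si_spad: Sequence[float]
) -> LinearSIMap:
    """Fit the linear SI_sensor -> SI_SPAD bridge by OLS.

    Requires at least two distinct sensor-SI values.  Warns when the
    slope is non-positive (sensor moving against the meter).
    """
    x = np.asarray(si_sensor, dtype=float)
    y = np.asarray(si_spad, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("si_sensor and si_spad must be equal-length 1-D")
    if len(x) < 2 or len(np.unique(x)) < 2:
        raise RankDeficiencyError(
            "need >= 2 observations at >= 2 distinct sensor SI values"
        )
    design = np.column_stack([np.ones_like(x), x])
    (b0, b1), r2 = _ols(design, y)
    if b1 <= 0:
        warnings.warn(
            f"fitted SI map slope is not positive (b1 = {b1:.4g}); "
            "this calibration cannot drive a recommendation",
            stacklevel=2,
        )
    return LinearSIMap(b0=float(b0), b1=float(b1), n_points=len(x), r_squared=r2)


#: Published stage calibrations for wheat, stored verbatim.  Keys are
#: canonical stage tokens; values are ((a0, a1, a2), (b0, b1)).
_PUBLISHED: dict[str, tuple[tuple[float, float, float], tuple[float, float]]] = {
    "tillering": ((-0.047, 0.2649, -0.00013), (-0.0056, 1.0461)),
    "booting": ((0.542, 0.003, -0.0006), (-0.608, 1.616)),
}


def published_coefficients(stage: str) -> tuple[QuadraticResponse, LinearSIMap]:
    """Published (quadratic, bridge) coefficient fixtures for a stage.

    Only tillering and booting calibrations were ever published for
    this sensor/crop combination; other stages raise.
    """
    try:
        (a, b) = _PUBLISHED[stage]
    except KeyError:
        raise ValidationError(
            f"no published calibration for stage {stage!r}; "
            f"available: {sorted(_PUBLISHED)}"
        ) from None
    quad = QuadraticResponse(a0=a[0], a1=a[1], a2=a[2])
    bridge = LinearSIMap(b0=b[0], b1=b[1])
    return quad, bridge
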