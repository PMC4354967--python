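"""N-recommendation algorithms: quadratic inversion, the parametric
square-root form, and the sensor-value lookup mode.

Inverting the concave response ``SI_SPAD = a0 + a1*N + a2*N**2`` gives
the N rate that produces a measured SI (ascending branch of the
parabola), the rate at the vertex ``Nrate_max = -a1 / (2*a2)`` that
maximizes SI, and the deficit between the two,

    N_app(SI_SPAD) = Nrate_max - Nrate(SI_SPAD)
                   = sqrt((SI_max - SI_SPAD) / |a2|).

Composing this with the linear bridge ``SI_SPAD = b0 + b1*SI_sensor``
collapses the whole chain into a two-constant field algorithm:

    N_app = R * sqrt(SI_R - SI_sensor),
    R = sqrt(-b1 / a2),
    SI_R = (4*a2*a0 - a1**2 - 4*a2*b0) / (4*a2*b1),

where SI_R is the sensor sufficiency index at which no N is needed.
Note the radical: R has units of kg N/ha per unit sqrt(SI), which is
what makes the published booting constant R = sqrt(1.616/0.0006) =
51.89 come out right.

The alternative recommendation mode maps raw sensor values (SN) to N
rates through a per-stage lookup table of (SN range -> rate) anchors,
with linear interpolation between the published ranges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

from .calibration import LinearSIMap, QuadraticResponse
from .errors import DerivationError, NonConcaveError, ValidationError

Provenance = Literal["derived", "published"]


def si_max(q: QuadraticResponse) -> float:
    """Maximum attainable SI_SPAD, at the vertex: a0 - a1^2/(4*a2)."""
    if q.a2 >= 0:
        raise NonConcaveError(f"response is not concave (a2 = {q.a2})")
    return q.a0 - q.a1 * q.a1 / (4.0 * q.a2)


def nrate_max(q: QuadraticResponse) -> float:
    """N rate at the vertex of the concave response, -a1/(2*a2).

    This is the rate that maximizes SI_SPAD; a usable calibration has
    it non-negative (warned otherwise, since a vertex at negative N
    means the response is decreasing over the whole trial range).
    """
    if q.a2 >= 0:
        raise NonConcaveError(f"response is not concave (a2 = {q.a2})")
    vertex = -q.a1 / (2.0 * q.a2)
    if vertex < 0:
        warnings.warn(
            f"vertex N rate is negative ({vertex:.4g} kg N/ha); "
            "calibration is decreasing over the trial range",
            stacklevel=2,
        )
    return vertex


def nrate_for_si(
    q: QuadraticResponse, si_spad: float, clamp: bool = True
) -> float:
    """N rate on the ascending branch that produces a given SI_SPAD.

    Solves the quadratic for N and returns the root at or below the
    vertex.  With ``clamp=True`` (default) the rate is clamped to
    [0, nrate_max]: an SI above the achievable maximum returns the
    vertex rate with a warning, and an SI below the zero-N response
    returns 0.  ``clamp=False`` returns the raw ascending-branch root
    (possibly negative), useful for algebraic checks.
    """
    if q.a2 >= 0:
        raise NonConcaveError(f"response is not concave (a2 = {q.a2})")
    vertex = -q.a1 / (2.0 * q.a2)
    disc = q.a1 * q.a1 - 4.0 * q.a2 * (q.a0 - si_spad)
    if disc < 0:
        warnings.warn(
            f"SI_SPAD {si_spad:.4g} exceeds the achievable maximum "
            f"{si_max(q):.4g}; returning the vertex rate",
            stacklevel=2,
        )
        return vertex
    # ascending branch: vertex - sqrt(disc)/(2|a2|); with a2 < 0 this is
    # (-a1 + sqrt(disc)) / (2*a2)
    rate = (-q.a1 + math.sqrt(disc)) / (2.0 * q.a2)
    if clamp:
        rate = min(max(rate, 0.0), vertex)
    return rate


def napp_from_si_spad(
    q: QuadraticResponse, si_spad: float, clamp: bool = True
) -> float:
    """N application rate: nrate_max - nrate_for_si(si_spad).

    Zero at (or above) the maximum SI; equals the full vertex rate for
    a plot sitting at the zero-N response (si_spad = a0).  Equivalent
    closed form: sqrt((SI_max - si_spad)/|a2|) for si_spad <= SI_max.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vertex = nrate_max(q)
        rate = nrate_for_si(q, si_spad, clamp=clamp)
    return vertex - rate


@dataclass(frozen=True)
class ParametricAlgorithm:
    """Deployable two-constant recommendation N_app = R*sqrt(SI_R - SI).

    ``R`` is in kg N/ha per unit sqrt(SI); ``SI_R`` is the sensor SI at
    which the recommendation reaches zero.  ``provenance`` records
    whether the constants were derived from a calibration fit or taken
    from a published algorithm.
    """

    R: float
    SI_R: float
    stage: str
    provenance: Provenance = "derived"

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValidationError(f"R must be positive, got {self.R}")


def derive_parametric(
    q: QuadraticResponse, m: LinearSIMap, stage: str
) -> ParametricAlgorithm:
    """Derive the parametric algorithm from a fitted calibration pair.

    Requires a concave quadratic (a2 < 0) and a positive bridge slope
    (b1 > 0).  SI_R below zero is physically suspect (the sensor could
    never report sufficiency) and is warned about.
    """
    if q.a2 >= 0 or m.b1 <= 0 or -m.b1 / q.a2 <= 0:
        raise DerivationError(
            f"cannot derive algorithm: requires a2 < 0 and b1 > 0, "
            f"got a2 = {q.a2}, b1 = {m.b1}"
        )
    r_const = math.sqrt(-m.b1 / q.a2)
    si_r = (4.0 * q.a2 * q.a0 - q.a1 * q.a1 - 4.0 * q.a2 * m.b0) / (
        4.0 * q.a2 * m.b1
    )
    if si_r <= 0:
        warnings.warn(
            f"derived SI_R is not positive ({si_r:.4g}); the algorithm "
            "would recommend N at every sensor reading",
            stacklevel=2,
        )
    return ParametricAlgorithm(R=r_const, SI_R=si_r, stage=stage)


def napp(alg: ParametricAlgorithm, si_sensor: float) -> float:
    """Recommended N rate R*sqrt(max(SI_R - SI_sensor, 0)) in kg N/ha.

    Zero at or above SI_R (the crop is sufficient), strictly decreasing
    in SI_sensor below it; never negative.
    """
    if si_sensor < 0:
        raise ValidationError(f"si_sensor must be >= 0, got {si_sensor}")
    deficit = alg.SI_R - si_sensor
    if deficit <= 0:
        return 0.0
    return alg.R * math.sqrt(deficit)


#: Published parametric algorithms per stage: (R, SI_R).
_PUBLISHED_ALG: dict[str, tuple[float, float]] = {
    "tillering": (87.17, 1.35),
    "booting": (51.89, 1.33),
}


def published_algorithm(stage: str) -> ParametricAlgorithm:
    """The published field algorithm for tillering or booting."""
    try:
        r_const, si_r = _PUBLISHED_ALG[stage]
    except KeyError:
        raise ValidationError(
            f"no published algorithm for stage {stage!r}; "
            f"available: {sorted(_PUBLISHED_ALG)}"
        ) from None
    return ParametricAlgorithm(
        R=r_const, SI_R=si_r, stage=stage, provenance="published"
    )


@dataclass(frozen=True)
class SNAnchor:
    """One lookup anchor: SN in [sn_low, sn_high] -> n_app kg N/ha."""

    sn_low: float
    sn_high: float
    n_app: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.sn_low + self.sn_high)


@dataclass(frozen=True)
class SNLookupTable:
    """Per-stage table mapping raw sensor values (SN) to N rates.

    Anchors must be sorted by SN, non-overlapping, with non-increasing
    rates (greener canopy needs less N).
    """

    stage: str
    anchors: tuple[SNAnchor, ...]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValidationError("SN lookup table must have >= 1 anchor")
        prev = None
        for a in self.anchors:
            if a.sn_high < a.sn_low:
                raise ValidationError(f"anchor range inverted: {a}")
            if prev is not None:
                if a.sn_low <= prev.sn_high:
                    raise ValidationError(
                        "anchor SN ranges must be sorted and non-overlapping"
                    )
                if a.n_app > prev.n_app:
                    raise ValidationError(
                        "n_app must be non-increasing as SN increases"
                    )
            prev = a


#: Published SN-value recommendation anchors per stage.
_PUBLISHED_SN: dict[str, tuple[tuple[float, float, float], ...]] = {
    "tillering": ((7.0, 11.0, 75.0), (33.1, 37.0, 45.0)),
    "booting": ((17.0, 24.0, 40.0), (76.1, 84.0, 25.0)),
}


def published_sn_table(stage: str) -> SNLookupTable:
    """Published SN -> N_app anchors for tillering or booting."""
    try:
        rows = _PUBLISHED_SN[stage]
    except KeyError:
        raise ValidationError(
            f"no published SN table for stage {stage!r}; "
            f"available: {sorted(_PUBLISHED_SN)}"
        ) from None
    return SNLookupTable(
        stage=stage, anchors=tuple(SNAnchor(*row) for row in rows)
    )


def recommend_from_sn(table: SNLookupTable, sn: float) -> float:
    """N rate for a raw sensor value by table lookup.

    Inside an anchor range the anchor's rate is returned exactly;
    between two ranges the rate is linearly interpolated between the
    flanking anchors' (range midpoint, rate) pairs; outside the table
    the nearest anchor's rate is returned with an extrapolation
    warning.
    """
    if sn < 0:
        raise ValidationError(f"sn must be >= 0, got {sn}")
    anchors = table.anchors
    for a in anchors:
        if a.sn_low <= sn <= a.sn_high:
            return a.n_app
    if sn < anchors[0].sn_low:
        warnings.warn(
            f"SN {sn} below the table range; extrapolating to the first "
            f"anchor rate {anchors[0].n_app} kg N/ha",
            stacklevel=2,
        )
        return anchors[0].n_app
    if sn > anchors[-1].sn_high:
        warnings.warn(
            f"SN {sn} above the table range; extrapolating to the last "
            f"anchor rate {anchors[-1].n_app} kg N/ha",
            stacklevel=2,
        )
        return anchors[-1].n_app
    for lo, hi in zip(anchors, anchors[1:]):
        if lo.sn_high < sn < hi.sn_low:
            frac = (sn - lo.midpoint) / (hi.midpoint - lo.midpoint)
            return lo.n_app + frac * (hi.n_app - lo.n_app)
    raise AssertionError("unreachable: sn not located in table")  # pragma: no cover


def recommend_series(
    table: SNLookupTable, sn_values: Sequence[float]
) -> list[float]:
    """Vector convenience wrapper over :func:`recommend_from_sn`."""
    return [recommend_from_sn(table, float(s)) for s in sn_values]
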