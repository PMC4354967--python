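"""Ground footprint of the rig-mounted canopy spectrometers.

The sensor rig carries two oblique-viewing lens pairs, one on each side
of the vehicle, so each pass scans two parallel strips of crop.  For a
rig of length ``d`` mounted at height ``h`` the inner and outer edges of
each scanned strip are linear in both dimensions:

    X1 = 0.5*d + 1.13*h        (inner edge of sensed strip)
    X2 = 0.5*d + 1.94*h        (outer edge of sensed strip)

so the strip width is ``y = X2 - X1 = 0.81*h`` per side.  The fraction
of crop area covered while driving is the total scanned width ``2*y``
divided by the total sensed span ``2*X2``.  With the standard rig
(d = 2.0 m, h = 1.6 m) this evaluates to about 32 % coverage.

The linear coefficients 1.13 and 1.94 are the tangents of the fixed lens
view angles; they are used verbatim rather than re-derived from angles.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: tan of the inner and outer lens view angles (dimensionless slopes).
INNER_SLOPE = 1.13
OUTER_SLOPE = 1.94


@dataclass(frozen=True)
class RigConfig:
    """Mounting configuration of the sensor rig.

    Parameters
    ----------
    rig_length_d:
        Length of the sensor rig in metres (default 2.0).
    mount_height_h:
        Mounting height above the canopy in metres (default 1.6).
    """

    rig_length_d: float = 2.0
    mount_height_h: float = 1.6

    def __post_init__(self) -> None:
        if not self.rig_length_d > 0:
            raise ValidationError(
                f"rig_length_d must be positive, got {self.rig_length_d}"
            )
        if self.mount_height_h < 0:
            raise ValidationError(
                f"mount_height_h must be non-negative, got {self.mount_height_h}"
            )


@dataclass(frozen=True)
class FootprintGeometry:
    """Scanned-strip coordinates (metres) and the coverage fraction.

    ``x1_inner``/``x2_outer`` are measured from the vehicle centre line;
    ``scanned_width_total`` and ``span_total`` count both sides.
    """

    x1_inner: float
    x2_outer: float
    strip_width_y: float
    scanned_width_total: float
    span_total: float
    coverage_fraction: float

    @property
    def coverage_percent(self) -> int:
        """Coverage as a whole percent (nearest integer)."""
        return round(self.coverage_fraction * 100)


def footprint(cfg: RigConfig) -> FootprintGeometry:
    """Compute the scanned footprint for a rig configuration.

    Returns the inner/outer strip edges, per-side strip width, the
    two-sided scanned width and span, and the coverage fraction
    ``2y / (2*X2) = 0.81*h / (0.5*d + 1.94*h)``.
    """
    d, h = cfg.rig_length_d, cfg.mount_height_h
    x1 = 0.5 * d + INNER_SLOPE * h
    x2 = 0.5 * d + OUTER_SLOPE * h
    y = x2 - x1
    scanned = 2.0 * y
    span = 2.0 * x2
    coverage = scanned / span if span > 0 else 0.0
    return FootprintGeometry(
        x1_inner=x1,
        x2_outer=x2,
        strip_width_y=y,
        scanned_width_total=scanned,
        span_total=span,
        coverage_fraction=coverage,
    )
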