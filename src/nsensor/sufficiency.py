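"""NDVI and sufficiency indices relative to a well-fertilized reference.

A sufficiency index (SI) is the ratio of a target plot's reading to the
same reading on a reference strip that is not nitrogen limited.  SI = 1
means the crop is N sufficient; SI < 1 means it is deficient, with more
N needed the smaller the SI.  Values above 1 (target greener than the
reference) are permitted and flagged, not clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .errors import EmptyReferenceError, UndefinedInputError, ValidationError

Basis = Literal["reflectance", "ndvi", "spad"]

#: SI above this default cap is flagged as suspicious (not clamped).
DEFAULT_SI_CAP = 2.0


@dataclass(frozen=True)
class ReflectancePair:
    """Red and near-infrared canopy reflectance (dimensionless, in (0, 1])."""

    red: float
    nir: float

    def __post_init__(self) -> None:
        if not (self.red > 0 and self.nir > 0):
            raise ValidationError(
                f"reflectances must be strictly positive, got red={self.red}, "
                f"nir={self.nir}"
            )


@dataclass(frozen=True)
class SufficiencyIndex:
    """A sufficiency index value with the basis it was computed on.

    ``flagged`` marks values above the configured cap — plausible field
    artefacts (e.g. a target plot greener than the reference strip by a
    wide margin) that deserve inspection but are not errors.
    """

    value: float
    basis: Basis
    flagged: bool = False

    def __float__(self) -> float:
        return self.value


def ndvi(pair: ReflectancePair) -> float:
    """Normalized difference vegetation index, (NIR - red)/(NIR + red).

    Always in [-1, 1]; antisymmetric under swapping the two bands.
    """
    total = pair.nir + pair.red
    if total == 0:
        raise UndefinedInputError("NDVI undefined: nir + red == 0")
    return (pair.nir - pair.red) / total


def sufficiency_index(
    target: float,
    reference: float,
    basis: Basis = "reflectance",
    cap: float = DEFAULT_SI_CAP,
) -> SufficiencyIndex:
    """SI = target / reference for any scalar canopy attribute.

    Parameters
    ----------
    target, reference:
        The target-plot and reference-strip readings on the same basis.
    basis:
        Which attribute the ratio is taken on (bookkeeping only).
    cap:
        Soft cap; SI above it is flagged, never altered.
    """
    if reference <= 0:
        raise ValidationError(
            f"reference must be strictly positive, got {reference}"
        )
    value = target / reference
    return SufficiencyIndex(value=value, basis=basis, flagged=value > cap)


def si_ndvi(
    target_ndvi: float, reference_ndvi: float, cap: float = DEFAULT_SI_CAP
) -> SufficiencyIndex:
    """Sensor sufficiency index on the NDVI basis (SI_sensor)."""
    return sufficiency_index(target_ndvi, reference_ndvi, basis="ndvi", cap=cap)


def reference_from_trial(
    observations: pd.DataFrame,
    stage: str,
    attribute: str = "ndvi",
    rule: str = "max_n_mean",
) -> float:
    """Reference value for one growth stage from trial observations.

    The default ``max_n_mean`` rule treats the plots at the highest
    applied N rate present at that stage as the well-fertilized
    reference strip and returns their mean ``attribute``.

    Raises
    ------
    EmptyReferenceError
        If no plot at the stage qualifies under the rule.
    """
    if rule != "max_n_mean":
        raise ValidationError(f"unknown reference rule: {rule!r}")
    at_stage = observations[observations["stage"] == stage]
    if at_stage.empty:
        raise EmptyReferenceError(f"no observations at stage {stage!r}")
    n_max = at_stage["n_rate"].max()
    ref_rows = at_stage[at_stage["n_rate"] == n_max]
    if ref_rows.empty:  # pragma: no cover - max() guarantees non-empty
        raise EmptyReferenceError(
            f"no reference plots at stage {stage!r} (N = {n_max})"
        )
    value = float(ref_rows[attribute].mean())
    if value <= 0:
        warnings.warn(
            f"non-positive reference {attribute} ({value:.4g}) at stage "
            f"{stage!r}; downstream SI values will be invalid",
            stacklevel=2,
        )
    return value
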