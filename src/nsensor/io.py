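"""Observation I/O, calibration artifacts and the end-to-end pipeline.

The observation table is a flat CSV with one row per plot x stage
(columns in :data:`~nsensor.trial_synth.OBS_COLUMNS`); unknown extra
columns are preserved on read but ignored.  Calibration results are
serialized as JSON artifacts that round-trip losslessly and carry
provenance (input hash, timestamp, options).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd

from . import algorithm as alg_mod
from . import calibration as cal_mod
from . import sufficiency as suf_mod
from .errors import ValidationError
from .trial_synth import OBS_COLUMNS

log = logging.getLogger("nsensor")

#: Accepted spellings for growth stages, mapped to canonical tokens.
#: Days-after-sowing and sensor growth-stage codes are accepted too.
STAGE_ALIASES = {
    "tillering": "tillering",
    "55das": "tillering",
    "28": "tillering",
    "booting": "booting",
    "85das": "booting",
    "36": "booting",
    "ear_emergence": "ear_emergence",
    "ear emergence": "ear_emergence",
    "115das": "ear_emergence",
    "50": "ear_emergence",
}

_NUMERIC_COLS = (
    "n_rate", "spad", "sn", "biomass", "ndvi", "lab_n", "lab_chl", "yield_t_ha",
)


@dataclass(frozen=True)
class PlotObservation:
    """One plot x stage record of the trial."""

    plot_id: str
    replicate: int
    stage: str
    n_rate: float
    spad: float
    sn: float
    biomass: float
    ndvi: float
    lab_n: float
    lab_chl: float
    yield_t_ha: float


def canonical_stage(token: str) -> str:
    """Canonical stage name for any accepted alias."""
    key = str(token).strip().lower()
    try:
        return STAGE_ALIASES[key]
    except KeyError:
        raise ValidationError(
            f"unrecognized growth stage {token!r}; accepted: "
            f"{sorted(set(STAGE_ALIASES.values()))} or their aliases"
        ) from None


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read and validate an observation CSV.

    Mandatory columns are checked by name, numeric columns are coerced
    with per-row diagnostics (row numbers count the header as line 1),
    stage tokens are canonicalized, and NDVI must lie in [-1, 1].
    Validation is fail-fast: the first problem raises with the rows
    involved.
    """
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"observation file {path} is missing mandatory column(s): "
            f"{', '.join(missing)}"
        )
    for col in _NUMERIC_COLS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])
            raise ValidationError(
                f"non-numeric value(s) in column {col!r} at row(s) {rows}"
            )
        df[col] = coerced
    df["stage"] = [canonical_stage(s) for s in df["stage"]]
    out_of_range = df.index[(df["ndvi"] < -1) | (df["ndvi"] > 1)]
    if len(out_of_range):
        rows = ", ".join(str(i + 2) for i in out_of_range[:5])
        raise ValidationError(
            f"ndvi outside [-1, 1] at row(s) {rows}"
        )
    return df


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    """Write an observation table as CSV with the canonical header."""
    cols = [c for c in OBS_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


def observations_to_records(df: pd.DataFrame) -> list[PlotObservation]:
    """Typed record view of an observation table."""
    fields = [f.name for f in dataclasses.fields(PlotObservation)]
    return [
        PlotObservation(**{k: row[k] for k in fields})
        for row in df.to_dict("records")
    ]


@dataclass(frozen=True)
class CalibrationArtifact:
    """A fitted stage calibration plus the algorithm derived from it.

    Round-trips losslessly through JSON; on load the derived constants
    are checked for consistency with the stored coefficients.
    """

    stage: str
    a0: float
    a1: float
    a2: float
    b0: float
    b1: float
    r_squared_quad: float | None
    r_squared_bridge: float | None
    n_quad: int | None
    n_bridge: int | None
    R: float
    SI_R: float
    provenance: dict[str, Any]

    def quadratic(self) -> cal_mod.QuadraticResponse:
        return cal_mod.QuadraticResponse(
            a0=self.a0, a1=self.a1, a2=self.a2,
            n_points=self.n_quad, r_squared=self.r_squared_quad,
        )

    def bridge(self) -> cal_mod.LinearSIMap:
        return cal_mod.LinearSIMap(
            b0=self.b0, b1=self.b1,
            n_points=self.n_bridge, r_squared=self.r_squared_bridge,
        )

    def parametric(self) -> alg_mod.ParametricAlgorithm:
        return alg_mod.ParametricAlgorithm(
            R=self.R, SI_R=self.SI_R, stage=self.stage, provenance="derived"
        )

    def to_json(self) -> str:
        return json.dumps(
            dataclasses.asdict(self), sort_keys=True, indent=2
        ) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "CalibrationArtifact":
        data = json.loads(text)
        artifact = cls(**data)
        derived = alg_mod.derive_parametric(
            artifact.quadratic(), artifact.bridge(), artifact.stage
        )
        for name, stored, recomputed in (
            ("R", artifact.R, derived.R),
            ("SI_R", artifact.SI_R, derived.SI_R),
        ):
            if abs(stored - recomputed) > 1e-9 * max(1.0, abs(recomputed)):
                raise ValidationError(
                    f"artifact {name} = {stored} inconsistent with its "
                    f"coefficients (expected {recomputed})"
                )
        return artifact

    @classmethod
    def read(cls, path: str | Path) -> "CalibrationArtifact":
        return cls.from_json(Path(path).read_text())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def calibrate_stage(
    observations: pd.DataFrame,
    stage: str,
    reference_rule: str = "max_n_mean",
    provenance: dict[str, Any] | None = None,
) -> tuple[CalibrationArtifact, pd.DataFrame]:
    """Fit both calibration models for one stage and derive the algorithm.

    Computes per-plot sufficiency indices against the stage's reference
    (mean SPAD / NDVI of the highest-N plots by default), fits the
    quadratic N response and the linear SI bridge, and packages the
    derived parametric algorithm as an artifact.  Also returns the
    stage's observations with ``si_spad`` / ``si_sensor`` columns
    attached.

    If the input already carries ``si_spad`` and ``si_sensor`` columns
    (e.g. normalized against a dedicated reference strip upstream) they
    are used as-is and no reference rule is applied.
    """
    stage = canonical_stage(stage)
    at_stage = observations[observations["stage"] == stage].copy()
    if at_stage.empty:
        raise ValidationError(f"no observations at stage {stage!r}")
    if {"si_spad", "si_sensor"} <= set(at_stage.columns):
        ref_spad = ref_ndvi = None
        log.info("stage %s: using precomputed SI columns", stage)
    else:
        ref_spad = suf_mod.reference_from_trial(
            observations, stage, attribute="spad", rule=reference_rule
        )
        ref_ndvi = suf_mod.reference_from_trial(
            observations, stage, attribute="ndvi", rule=reference_rule
        )
        at_stage["si_spad"] = at_stage["spad"] / ref_spad
        at_stage["si_sensor"] = at_stage["ndvi"] / ref_ndvi
    quad = cal_mod.fit_quadratic_response(at_stage["n_rate"], at_stage["si_spad"])
    bridge = cal_mod.fit_linear_si_map(at_stage["si_sensor"], at_stage["si_spad"])
    log.info(
        "stage %s: quadratic a=(%.6g, %.6g, %.6g) R2=%.4f; "
        "bridge b=(%.6g, %.6g) R2=%.4f",
        stage, quad.a0, quad.a1, quad.a2, quad.r_squared,
        bridge.b0, bridge.b1, bridge.r_squared,
    )
    parametric = alg_mod.derive_parametric(quad, bridge, stage)
    log.info("stage %s: derived R=%.4f SI_R=%.4f", stage, parametric.R,
             parametric.SI_R)
    prov = {
        "reference_rule": "precomputed" if ref_spad is None else reference_rule,
        "reference_spad": ref_spad,
        "reference_ndvi": ref_ndvi,
        **(provenance or {}),
    }
    artifact = CalibrationArtifact(
        stage=stage,
        a0=quad.a0, a1=quad.a1, a2=quad.a2,
        b0=bridge.b0, b1=bridge.b1,
        r_squared_quad=quad.r_squared, r_squared_bridge=bridge.r_squared,
        n_quad=quad.n_points, n_bridge=bridge.n_points,
        R=parametric.R, SI_R=parametric.SI_R,
        provenance=prov,
    )
    return artifact, at_stage


def recommend_algorithm(
    parametric: alg_mod.ParametricAlgorithm, with_si: pd.DataFrame
) -> pd.DataFrame:
    """Per-plot N recommendations from a parametric algorithm.

    Expects a frame with an ``si_sensor`` column.  Rates are reported
    to 0.1 kg N/ha; plots at or above SI_R get rate 0 and an
    ``at_sufficiency`` flag.
    """
    recs = []
    for row in with_si.to_dict("records"):
        si = float(row["si_sensor"])
        rate = alg_mod.napp(parametric, si) if si >= 0 else alg_mod.napp(parametric, 0.0)
        flags = []
        if si >= parametric.SI_R:
            flags.append("at_sufficiency")
        if si < 0:
            flags.append("negative_si_clamped")
        recs.append(
            {
                "plot_id": row["plot_id"],
                "replicate": row["replicate"],
                "stage": row["stage"],
                "si_sensor": si,
                "n_app_kg_ha": round(rate, 1),
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(recs)


def recommend_sn(observations: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Per-plot N recommendations by published SN-value lookup."""
    stage = canonical_stage(stage)
    table = alg_mod.published_sn_table(stage)
    at_stage = observations[observations["stage"] == stage]
    if at_stage.empty:
        raise ValidationError(f"no observations at stage {stage!r}")
    recs = []
    for row in at_stage.to_dict("records"):
        sn = float(row["sn"])
        flags = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            rate = alg_mod.recommend_from_sn(table, max(sn, 0.0))
        if sn < 0:
            flags.append("negative_sn_clamped")
        if caught:
            flags.append("extrapolated")
        elif not any(a.sn_low <= sn <= a.sn_high for a in table.anchors):
            flags.append("interpolated")
        recs.append(
            {
                "plot_id": row["plot_id"],
                "replicate": row["replicate"],
                "stage": stage,
                "sn": sn,
                "n_app_kg_ha": round(rate, 1),
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(recs)


def run_pipeline(
    obs: str | Path | pd.DataFrame,
    stage: str,
    mode: str = "algorithm",
    reference_rule: str = "max_n_mean",
    out_dir: str | Path | None = None,
) -> tuple[CalibrationArtifact | None, pd.DataFrame]:
    """End-to-end calibrate-and-recommend workflow for one stage.

    ``mode="algorithm"`` runs reference selection -> SI computation ->
    both OLS fits -> algorithm derivation -> per-plot recommendations,
    and returns the calibration artifact alongside the recommendation
    table.  ``mode="sn"`` skips calibration entirely and recommends by
    the published SN lookup (no SPAD or NDVI needed), returning
    ``None`` for the artifact.  With ``out_dir`` set, writes
    ``calibration_<stage>.json`` (algorithm mode) and
    ``recommendations_<stage>.csv``.
    """
    if isinstance(obs, (str, Path)):
        path = Path(obs)
        observations = read_observations(path)
        input_hash = _sha256(path)
        source = str(path)
    else:
        observations = obs.copy()
        observations["stage"] = [canonical_stage(s) for s in observations["stage"]]
        csv_bytes = observations.to_csv(index=False).encode()
        input_hash = hashlib.sha256(csv_bytes).hexdigest()
        source = "<in-memory>"
    stage = canonical_stage(stage)

    if mode == "sn":
        recs = recommend_sn(observations, stage)
        artifact = None
    elif mode == "algorithm":
        provenance = {
            "input": source,
            "input_sha256": input_hash,
            "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
            "mode": mode,
        }
        artifact, with_si = calibrate_stage(
            observations, stage, reference_rule=reference_rule,
            provenance=provenance,
        )
        recs = recommend_algorithm(artifact.parametric(), with_si)
    else:
        raise ValidationError(f"unknown mode {mode!r}; use 'algorithm' or 'sn'")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if artifact is not None:
            artifact.write(out / f"calibration_{stage}.json")
        recs.to_csv(out / f"recommendations_{stage}.csv", index=False)
        log.info("wrote outputs to %s", out)
    return artifact, recs
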