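"""Synthetic randomized-complete-block N-rate trial generator.

Emulates the field experiment the calibration chain assumes: six N
levels (0-150 kg N/ha), three replicate blocks, urea applied in a
50/25/25 basal/irrigation split, and canopy sensing at three wheat
growth stages (tillering, booting, ear emergence).

The generator works on the sufficiency-index scale and maps outward to
observable attributes, because the recommendation chain never consumes
raw spectra:

* a per-stage concave quadratic gives the true SPAD sufficiency index
  ``SI_SPAD`` at each N rate; the SPAD reading is ``reference_spad *
  SI_SPAD`` plus meter noise;
* the sensor sufficiency index comes from inverting the per-stage
  linear bridge, plus stage-specific sensor noise; NDVI is the sensor
  SI times the stage's reference-strip NDVI;
* sensor value (SN) and sensor biomass are affine in NDVI plus noise,
  on scales matching the ranges the instrument reports per stage;
* lab leaf N (% by weight) and lab chlorophyll (mg/g) are affine in the
  *true* SI plus stage-specific assay noise;
* instrument and assay outputs (SN, biomass, lab values, yield) are
  floored at zero, as the real devices report; the
  calibration-carrying channels (SPAD, NDVI) are never clipped, so
  noiseless coefficient recovery is exact even for truth parameters on
  an unphysical scale;
* grain yield (t/ha) is simulated once per plot as a quadratic-plateau
  in N plus a block effect, since each plot has a single harvest.

Stage-specific sensor and assay noise grow from tillering to ear
emergence, so sensor-attribute correlations with lab N, chlorophyll
and yield are strongest at tillering — the qualitative pattern observed
in the field.  At zero noise every attribute is an exact affine
transform of the common N signal, so all fits recover the generating
coefficients to machine precision.

Randomness is counter-based: every noise draw uses a fresh generator
keyed on (seed, replicate, N level, stage, attribute), so adding an
attribute never perturbs existing draws and output is independent of
loop order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import STAGES, LinearSIMap, QuadraticResponse
from .errors import ValidationError

#: Canonical observation-table columns, in writing order.
OBS_COLUMNS = (
    "plot_id",
    "replicate",
    "stage",
    "n_rate",
    "spad",
    "sn",
    "biomass",
    "ndvi",
    "lab_n",
    "lab_chl",
    "yield_t_ha",
)

# attribute codes for the counter-based noise keying
_C_BLOCK = 1
_C_YIELD = 2
_C_SI_SPAD = 3
_C_SI_SENSOR = 4
_C_SN = 5
_C_BIOMASS = 6
_C_LAB_N = 7
_C_LAB_CHL = 8


@dataclass(frozen=True)
class TrialDesign:
    """Layout of the randomized complete block trial."""

    n_levels: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    replicates: int = 3
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.n_levels)) < 3:
            raise ValidationError("need >= 3 distinct N levels")
        if self.replicates < 1:
            raise ValidationError("need >= 1 replicate")
        if any(n < 0 for n in self.n_levels):
            raise ValidationError("N levels must be non-negative")


@dataclass(frozen=True)
class DoseSchedule:
    """Urea split doses for one treatment, kg N/ha."""

    basal: float
    first_irrigation: float
    second_irrigation: float

    @property
    def total(self) -> float:
        return self.basal + self.first_irrigation + self.second_irrigation


def dose_schedule(total_n: float) -> DoseSchedule:
    """50 % basal, 25 % at each of the first two irrigations."""
    if total_n < 0:
        raise ValidationError(f"total N must be >= 0, got {total_n}")
    return DoseSchedule(
        basal=0.5 * total_n,
        first_irrigation=0.25 * total_n,
        second_irrigation=0.25 * total_n,
    )


@dataclass(frozen=True)
class StageNoise:
    """Gaussian noise standard deviations for one stage's attributes."""

    si_spad: float = 0.0
    si_sensor: float = 0.0
    sn: float = 0.0
    biomass: float = 0.0
    lab_n: float = 0.0
    lab_chl: float = 0.0


@dataclass(frozen=True)
class StageTruth:
    """Generating model for one growth stage.

    ``quad`` is the true SI_SPAD response to N, ``bridge`` the linear
    SI_sensor -> SI_SPAD map (inverted at generation time),
    ``reference_ndvi`` the reference-strip NDVI that scales sensor SI
    into NDVI, and the affine pairs place SN / biomass on instrument
    scales.
    """

    quad: QuadraticResponse
    bridge: LinearSIMap
    reference_ndvi: float
    sn_intercept: float
    sn_slope: float
    biomass_intercept: float
    biomass_slope: float
    noise: StageNoise = field(default_factory=StageNoise)


@dataclass(frozen=True)
class TruthParams:
    """Full generating parameter set for a synthetic trial."""

    stages: dict[str, StageTruth]
    reference_spad: float = 50.0
    lab_n_base: float = 1.2
    lab_n_gain: float = 2.0
    lab_chl_base: float = 0.8
    lab_chl_gain: float = 1.8
    yield_base: float = 2.2
    yield_gain: float = 3.5
    yield_n_opt: float = 150.0
    sigma_yield: float = 0.0
    block_sd: float = 0.0

    def with_noise(
        self,
        sigma_yield: float | None = None,
        block_sd: float | None = None,
        **stage_sigmas: float,
    ) -> "TruthParams":
        """Copy with noise levels replaced uniformly across stages.

        ``stage_sigmas`` keys are :class:`StageNoise` field names, e.g.
        ``with_noise(si_spad=0.02)``.
        """
        new_stages = {
            name: replace(st, noise=replace(st.noise, **stage_sigmas))
            for name, st in self.stages.items()
        }
        out = replace(self, stages=new_stages)
        if sigma_yield is not None:
            out = replace(out, sigma_yield=sigma_yield)
        if block_sd is not None:
            out = replace(out, block_sd=block_sd)
        return out


def _default_stage(
    a0: float,
    a2: float,
    bridge: tuple[float, float],
    reference_ndvi: float,
    sn_affine: tuple[float, float],
    noise: StageNoise,
) -> StageTruth:
    # vertex pinned at 150 kg N/ha (a1 = -300*a2) so every stage's SI is
    # affine in (N - 150)^2, the same signal the yield plateau follows
    a1 = -300.0 * a2
    return StageTruth(
        quad=QuadraticResponse(a0=a0, a1=a1, a2=a2),
        bridge=LinearSIMap(b0=bridge[0], b1=bridge[1]),
        reference_ndvi=reference_ndvi,
        sn_intercept=sn_affine[0],
        sn_slope=sn_affine[1],
        biomass_intercept=0.0,
        biomass_slope=80.0,
        noise=noise,
    )


def default_truth() -> TruthParams:
    """Realistic noisy generating parameters for the standard trial.

    SI responses are concave with the vertex at 150 kg N/ha and a
    deficiency contrast that narrows with crop age (zero-N SI 0.55 at
    tillering, 0.73 at ear emergence).  Sensor and assay noise increase
    with stage so that tillering shows the strongest sensor-lab and
    sensor-yield correlations.  SN scales per stage roughly match the
    instrument's reported ranges (about 7-37 at tillering, 17-84 at
    booting).
    """
    stages = {
        "tillering": _default_stage(
            a0=0.55,
            a2=-2.0e-5,
            bridge=(-0.0056, 1.0461),
            reference_ndvi=0.70,
            sn_affine=(-30.0, 100.0),
            noise=StageNoise(
                si_spad=0.02, si_sensor=0.010, sn=1.0, biomass=2.0,
                lab_n=0.12, lab_chl=0.15,
            ),
        ),
        "booting": _default_stage(
            a0=0.64,
            a2=-1.6e-5,
            bridge=(-0.608, 1.616),
            reference_ndvi=0.78,
            sn_affine=(-200.0, 366.0),
            noise=StageNoise(
                si_spad=0.02, si_sensor=0.030, sn=2.0, biomass=3.0,
                lab_n=0.28, lab_chl=0.30,
            ),
        ),
        "ear_emergence": _default_stage(
            a0=0.73,
            a2=-1.2e-5,
            bridge=(0.0, 1.0),
            reference_ndvi=0.80,
            sn_affine=(-110.0, 250.0),
            noise=StageNoise(
                si_spad=0.02, si_sensor=0.055, sn=2.5, biomass=4.0,
                lab_n=0.32, lab_chl=0.35,
            ),
        ),
    }
    return TruthParams(stages=stages, sigma_yield=0.25, block_sd=0.12)


def _paper_truth(stage: str) -> TruthParams:
    """Truth parameterized by a published coefficient set, noiseless.

    The published coefficients are applied to every stage so any stage
    subset recovers them.  They are kept verbatim, which puts some
    generated attributes outside physical instrument ranges (the
    published sets are on inconsistent scales); the generator warns but
    does not alter values, so fits recover the coefficients exactly.
    """
    from .calibration import published_coefficients

    quad, bridge = published_coefficients(stage)
    ref_ndvi = {"tillering": 0.70, "booting": 0.78}[stage]
    sn_affine = {"tillering": (-30.0, 100.0), "booting": (-200.0, 366.0)}[stage]
    st = StageTruth(
        quad=quad,
        bridge=bridge,
        reference_ndvi=ref_ndvi,
        sn_intercept=sn_affine[0],
        sn_slope=sn_affine[1],
        biomass_intercept=0.0,
        biomass_slope=80.0,
    )
    return TruthParams(stages={name: st for name in STAGES})


_PRESETS = {
    "default": default_truth,
    "paper_tillering": lambda: _paper_truth("tillering"),
    "paper_booting": lambda: _paper_truth("booting"),
}


def truth_presets(name: str) -> TruthParams:
    """Named generating-parameter presets.

    ``default`` is the realistic noisy trial; ``paper_tillering`` /
    ``paper_booting`` generate noiselessly from the published stage
    coefficient sets (useful for exact-recovery checks).
    """
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown truth preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return factory()


def _draw(seed: int, *key: int) -> float:
    """One standard-normal draw keyed on (seed, *key)."""
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])
    return float(rng.standard_normal())


def simulate_trial(
    design: TrialDesign, truth: TruthParams | None = None
) -> pd.DataFrame:
    """Generate one trial as a tidy observation table.

    Returns one row per plot x stage with the canonical columns
    (:data:`OBS_COLUMNS`).  Deterministic for a fixed ``design.seed``.
    SN, biomass, lab values and yield are floored at zero (instrument
    and assay floor); SPAD and NDVI are never clipped — the generator
    warns instead when the truth parameters put them outside physical
    range, so coefficient recovery from noiseless data stays exact.
    """
    truth = truth if truth is not None else default_truth()
    missing = [s for s in design.stages if s not in truth.stages]
    if missing:
        raise ValidationError(f"truth has no parameters for stages {missing}")
    seed = design.seed
    rows = []
    for rep in range(1, design.replicates + 1):
        block = truth.block_sd * _draw(seed, rep, 0, 0, _C_BLOCK)
        for li, n in enumerate(design.n_levels):
            frac = min(n, truth.yield_n_opt) / truth.yield_n_opt
            yield_signal = 1.0 - (1.0 - frac) ** 2
            yld = (
                truth.yield_base
                + truth.yield_gain * yield_signal
                + block
                + truth.sigma_yield * _draw(seed, rep, li, 0, _C_YIELD)
            )
            plot_id = f"R{rep}-N{li + 1}"
            for si_idx, stage in enumerate(design.stages):
                st = truth.stages[stage]
                si_true = st.quad.predict(float(n))
                si_spad = si_true + st.noise.si_spad * _draw(
                    seed, rep, li, si_idx + 1, _C_SI_SPAD
                )
                si_sensor = st.bridge.invert(si_true) + st.noise.si_sensor * _draw(
                    seed, rep, li, si_idx + 1, _C_SI_SENSOR
                )
                ndvi_val = st.reference_ndvi * si_sensor
                sn = (
                    st.sn_intercept
                    + st.sn_slope * ndvi_val
                    + st.noise.sn * _draw(seed, rep, li, si_idx + 1, _C_SN)
                )
                biomass = (
                    st.biomass_intercept
                    + st.biomass_slope * ndvi_val
                    + st.noise.biomass * _draw(seed, rep, li, si_idx + 1, _C_BIOMASS)
                )
                lab_n = (
                    truth.lab_n_base
                    + truth.lab_n_gain * si_true
                    + st.noise.lab_n * _draw(seed, rep, li, si_idx + 1, _C_LAB_N)
                )
                lab_chl = (
                    truth.lab_chl_base
                    + truth.lab_chl_gain * si_true
                    + st.noise.lab_chl * _draw(seed, rep, li, si_idx + 1, _C_LAB_CHL)
                )
                rows.append(
                    (
                        plot_id,
                        rep,
                        stage,
                        float(n),
                        truth.reference_spad * si_spad,
                        max(sn, 0.0),
                        max(biomass, 0.0),
                        ndvi_val,
                        max(lab_n, 0.0),
                        max(lab_chl, 0.0),
                        max(yld, 0.0),
                    )
                )
    df = pd.DataFrame(rows, columns=list(OBS_COLUMNS))
    if (df["ndvi"].abs() > 1).any() or (df["spad"] < 0).any():
        warnings.warn(
            "generated NDVI outside [-1, 1] or negative SPAD; the truth "
            "parameters are on an unphysical scale (calibration channels "
            "are kept verbatim, not clipped)",
            stacklevel=2,
        )
    return df


def attach_si(df: pd.DataFrame, truth: TruthParams) -> pd.DataFrame:
    """Add ``si_spad`` / ``si_sensor`` columns using the truth constants.

    Divides SPAD by the generating ``reference_spad`` and NDVI by each
    stage's generating ``reference_ndvi`` — the exact inverses of the
    generator's scaling, for calibration-recovery checks.  (A field
    pipeline estimates these references from the high-N plots instead.)
    """
    out = df.copy()
    out["si_spad"] = out["spad"] / truth.reference_spad
    ref_ndvi = out["stage"].map(
        {name: st.reference_ndvi for name, st in truth.stages.items()}
    )
    out["si_sensor"] = out["ndvi"] / ref_ndvi
    return out
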