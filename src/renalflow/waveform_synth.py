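"""Synthetic single-beat renal-artery Doppler velocity envelopes.

Every downstream stage (digitization, splitting, CNN training, evaluation)
is exercised on cohorts produced here, because the clinical duplex dataset
is private. The generator emulates the study's patient-paired design: each
synthetic patient contributes exactly two signals at the same arterial site —
one from the stenotic-kidney class and one contralateral-normal control — so
label balance is 50/50 by construction.

Waveform model
--------------
A beat is a piecewise curve over one cardiac cycle of length ``heart_period``:

* systolic upstroke on ``[0, accel_time]``: a raised-power sinusoid from
  ``edv`` up to ``psv``; the exponent ``peak_sharpness`` (>= 1) controls how
  rounded the peak is;
* after the peak: exponential relaxation back toward ``edv`` with time
  constant ``(heart_period - accel_time) / 4``, so the beat has essentially
  returned to its diastolic floor by the next cycle.

Two knobs reproduce both classical stenosis morphologies: a high-PSV jet at
the stenosis (``stenosis_jet``) and the blunted, delayed-upstroke
tardus-parvus waveform downstream of it (``tardus_parvus``). The ``normal``
regime sits below the classical PSV >= 180 cm/s stenosis criterion; the
stenosis-jet regime places the bulk of its PSV mass above it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import digitize
from .digitize import SITES, CalibratedTrace, ResampledSignal
from .errors import ConfigurationError, DataError

#: Female fraction matching the study cohort (101 of 198 patients).
FEMALE_FRACTION = 101 / 198

#: Time step used when rendering an analytic beat into discrete samples (s).
RENDER_DT = 0.002


@dataclass(frozen=True)
class WaveformParams:
    """Physiological parameters of one beat.

    psv, edv in cm/s; accel_time (systolic onset to peak) and heart_period
    in s; peak_sharpness unitless >= 1; noise_sd additive velocity noise SD
    in cm/s.
    """

    psv: float
    edv: float
    accel_time: float
    heart_period: float
    peak_sharpness: float = 2.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.psv > self.edv >= 0):
            raise ConfigurationError(f"require psv > edv >= 0, got psv={self.psv}, edv={self.edv}")
        if not (0 < self.accel_time < self.heart_period):
            raise ConfigurationError(
                f"require 0 < accel_time < heart_period, got {self.accel_time}, {self.heart_period}"
            )
        if self.peak_sharpness < 1:
            raise ConfigurationError("peak_sharpness must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class FieldDist:
    """Truncated normal sampling distribution for one parameter."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower < self.upper):
            raise ConfigurationError(f"infeasible bounds [{self.lower}, {self.upper}]")
        if self.sd < 0:
            raise ConfigurationError("sd must be >= 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            if not (self.lower <= self.mean <= self.upper):
                raise ConfigurationError("degenerate distribution mean outside bounds")
            return self.mean
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return float(stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, random_state=rng))


@dataclass(frozen=True)
class ClassRegime:
    """Per-class sampling distributions for :class:`WaveformParams`."""

    name: str
    psv: FieldDist
    edv: FieldDist
    accel_time: FieldDist
    heart_period: FieldDist
    peak_sharpness: FieldDist
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        # bounds must make psv > edv and accel_time < heart_period certain
        if self.edv.upper >= self.psv.lower:
            raise ConfigurationError(
                f"regime {self.name!r}: edv upper bound {self.edv.upper} must stay below "
                f"psv lower bound {self.psv.lower}"
            )
        if self.accel_time.upper >= self.heart_period.lower:
            raise ConfigurationError(
                f"regime {self.name!r}: accel_time bound overlaps heart_period bound"
            )


#: Contralateral-normal kidney: sharp systolic peak well below 180 cm/s.
NORMAL_REGIME = ClassRegime(
    name="normal",
    psv=FieldDist(90.0, 15.0, 50.0, 160.0),
    edv=FieldDist(25.0, 5.0, 5.0, 45.0),
    accel_time=FieldDist(0.05, 0.01, 0.02, 0.09),
    heart_period=FieldDist(0.86, 0.08, 0.5, 1.4),
    peak_sharpness=FieldDist(2.0, 0.3, 1.2, 3.0),
)

#: At-stenosis jet: elevated PSV (bulk of the mass >= 180 cm/s).
STENOSIS_JET_REGIME = ClassRegime(
    name="stenosis_jet",
    psv=FieldDist(220.0, 30.0, 150.0, 350.0),
    edv=FieldDist(60.0, 15.0, 20.0, 110.0),
    accel_time=FieldDist(0.05, 0.01, 0.02, 0.09),
    heart_period=FieldDist(0.86, 0.08, 0.5, 1.4),
    peak_sharpness=FieldDist(2.0, 0.3, 1.2, 3.0),
)

#: Downstream tardus-parvus: blunted peak, prolonged acceleration time.
TARDUS_PARVUS_REGIME = ClassRegime(
    name="tardus_parvus",
    psv=FieldDist(45.0, 10.0, 25.0, 90.0),
    edv=FieldDist(15.0, 4.0, 2.0, 24.0),
    accel_time=FieldDist(0.12, 0.02, 0.08, 0.25),
    heart_period=FieldDist(0.86, 0.08, 0.5, 1.4),
    peak_sharpness=FieldDist(1.3, 0.15, 1.0, 1.8),
)

_REGIMES = {r.name: r for r in (NORMAL_REGIME, STENOSIS_JET_REGIME, TARDUS_PARVUS_REGIME)}


def get_regime(name: str) -> ClassRegime:
    try:
        return _REGIMES[name]
    except KeyError:
        raise ConfigurationError(f"unknown regime {name!r}; choose from {sorted(_REGIMES)}") from None


@dataclass(frozen=True)
class SyntheticPatient:
    """One synthetic patient: an ARAS signal and a site-matched control."""

    patient_id: str
    site: str
    sex: str
    aras_signal: ResampledSignal
    control_signal: ResampledSignal

    def __post_init__(self) -> None:
        if self.aras_signal.label != "ARAS" or self.control_signal.label != "normal":
            raise DataError("patient signals must carry opposite labels (ARAS / normal)")
        if self.aras_signal.site != self.site or self.control_signal.site != self.site:
            raise DataError("both signals must share the patient's site")


def beat_envelope(params: WaveformParams, t) -> np.ndarray | float:
    """Noise-free velocity (cm/s) at time ``t`` (s) within one beat.

    Deterministic and continuous; v(0) = edv, the maximum equals psv at
    t = accel_time, the rise on [0, accel_time] is monotone, and the tail
    decays exponentially back toward edv.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr >= params.heart_period):
        raise ValueError(f"t must lie in [0, heart_period={params.heart_period})")
    amp = params.psv - params.edv
    tau = (params.heart_period - params.accel_time) / 4.0
    rise = params.edv + amp * np.sin(
        0.5 * np.pi * np.minimum(t_arr, params.accel_time) / params.accel_time
    ) ** params.peak_sharpness
    decay = params.edv + amp * np.exp(-(t_arr - params.accel_time) / tau)
    v = np.where(t_arr <= params.accel_time, rise, decay)
    return float(v) if np.isscalar(t) or t_arr.ndim == 0 else v


def sample_params(regime: ClassRegime, rng: np.random.Generator | int) -> WaveformParams:
    """Draw one parameter set from a regime's truncated distributions.

    ``rng`` may be a Generator or an integer seed; a fixed seed reproduces
    the same draw. The regime's bound structure guarantees the
    :class:`WaveformParams` invariants.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return WaveformParams(
        psv=regime.psv.sample(rng),
        edv=regime.edv.sample(rng),
        accel_time=regime.accel_time.sample(rng),
        heart_period=regime.heart_period.sample(rng),
        peak_sharpness=regime.peak_sharpness.sample(rng),
        noise_sd=regime.noise_sd,
    )


def render_beat(params: WaveformParams, rng: np.random.Generator | None = None) -> CalibratedTrace:
    """Render one beat into discrete (time, velocity) samples at 2 ms.

    Additive Gaussian velocity noise of SD ``params.noise_sd`` is applied
    sample-wise and clipped at 0 (velocity magnitudes cannot be negative).
    """
    times = np.arange(0.0, params.heart_period, RENDER_DT)
    v = np.asarray(beat_envelope(params, times), dtype=float)
    if params.noise_sd > 0:
        if rng is None:
            raise ConfigurationError("rng required when noise_sd > 0")
        v = v + rng.normal(0.0, params.noise_sd, size=v.shape)
    v = np.clip(v, 0.0, None)
    return CalibratedTrace(times=times, velocities=v)


def _make_signal(
    regime: ClassRegime, label: str, patient_id: str, site: str, rng: np.random.Generator
) -> ResampledSignal:
    params = sample_params(regime, rng)
    trace = render_beat(params, rng)
    return digitize.resample_to_grid(trace, label=label, patient_id=patient_id, site=site)


def generate_cohort(
    n_patients: int,
    aras_regime: ClassRegime = STENOSIS_JET_REGIME,
    seed: int = 0,
    normal_regime: ClassRegime = NORMAL_REGIME,
) -> list[SyntheticPatient]:
    """Generate a paired cohort: 2 signals per patient, one per class.

    All randomness flows from ``seed`` through a splittable seed sequence,
    one child stream per patient, so per-patient draws are order-independent.
    Sex is assigned at the study's female proportion with a deterministic
    count (``round(n * 101/198)`` females), shuffled across patients.
    """
    if n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_patients + 1)
    n_female = int(round(n_patients * FEMALE_FRACTION))
    sexes = np.array(["F"] * n_female + ["M"] * (n_patients - n_female))
    np.random.default_rng(children[-1]).shuffle(sexes)
    patients = []
    for i in range(n_patients):
        rng = np.random.default_rng(children[i])
        pid = f"P{i + 1:04d}"
        site = str(rng.choice(SITES))
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                site=site,
                sex=str(sexes[i]),
                aras_signal=_make_signal(aras_regime, "ARAS", pid, site, rng),
                control_signal=_make_signal(normal_regime, "normal", pid, site, rng),
            )
        )
    return patients


def cohort_signals(patients: list[SyntheticPatient]) -> list[ResampledSignal]:
    """Flatten a cohort into its 2·n signals (ARAS first within each patient)."""
    out: list[ResampledSignal] = []
    for p in patients:
        out.append(p.aras_signal)
        out.append(p.control_signal)
    return out


def cohort_metadata(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """Patient-level metadata table (patient_id, site, sex)."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "site": [p.site for p in patients],
            "sex": [p.sex for p in patients],
        }
    )


def demographics_summary(metadata: pd.DataFrame) -> dict:
    """Study-style bookkeeping: patient/signal counts and percent female."""
    n = len(metadata)
    n_female = int((metadata["sex"] == "F").sum())
    return {
        "n_patients": n,
        "n_signals": 2 * n,
        "n_female": n_female,
        "pct_female": round(100.0 * n_female / n, 1),
    }
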