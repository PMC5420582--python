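"""Synthetic medfly cohort generator with known ground truth.

Emulates the four-cohort study design (female/male x sugar-liquid/protein-
liquid, 30 flies per cohort, five fly cages plus one fly-free control cage
per humidity-preservation chamber):

* lifespans are Gompertz with cohort-specific means (days) and a common
  shape (hazard doubling rate), truncated at one day and rounded up;
* daily intake follows a smooth age profile per cohort — sucrose-fed females
  drink heavily in the first ~10 days then decline; sucrose-fed males dip in
  mid-life and resurge late; protein-fed females peak in mid-life (ages
  20-40); protein-fed males hold a constant moderate level — with optional
  multiplicative lognormal day-to-day noise;
* a female's daily egg count is Poisson (or negative-binomial) with mean
  given by the diet's Lorentzian surface evaluated at (age, that day's true
  intake);
* the raw capillary reading is true intake + the chamber's evaporation that
  day + Gaussian reading noise, so evaporation correction against the
  control channel recovers true intake in expectation.

Everything is driven by one integer seed; output is bit-for-bit reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special

from .records import CohortTable, ControlReading, Diet, FeedingRecord, Sex
from .surface import LorentzianParams

CohortKey = tuple[Sex, Diet]

COHORT_KEYS: tuple[CohortKey, ...] = (
    (Sex.F, Diet.SUGAR_LIQUID),
    (Sex.M, Diet.SUGAR_LIQUID),
    (Sex.F, Diet.PROTEIN_LIQUID),
    (Sex.M, Diet.PROTEIN_LIQUID),
)

#: Fitted egg-production surfaces used as simulation ground truth
#: (age at peak, intake at peak, amplitude, age half-width, intake half-width).
TRUE_PARAMS: dict[Diet, LorentzianParams] = {
    Diet.SUGAR_LIQUID: LorentzianParams(x0=32.0000, y0=0.6276, alpha=24.0087, beta=9.2432, gamma=0.2749),
    Diet.PROTEIN_LIQUID: LorentzianParams(x0=28.3359, y0=0.1258, alpha=14.8297, beta=12.7151, gamma=0.0725),
}

#: Cohort mean lifespans in days (Kaplan-Meier means of the four cohorts).
DEFAULT_MEAN_LIFESPAN: dict[CohortKey, float] = {
    (Sex.F, Diet.SUGAR_LIQUID): 38.935,
    (Sex.M, Diet.SUGAR_LIQUID): 50.833,
    (Sex.F, Diet.PROTEIN_LIQUID): 40.057,
    (Sex.M, Diet.PROTEIN_LIQUID): 75.037,
}


@dataclass(frozen=True)
class IntakeProfile:
    """Deterministic age profile of daily intake (intake units).

    level(t) = baseline
             + early_level * exp(-early_decline * t)          (youthful burst)
             + peak_level * exp(-((t - peak_age)/peak_width)^2 / 2)  (mid-life peak)
             + oscillation_amplitude * sin(2*pi*t / oscillation_period)
    """

    baseline: float
    early_level: float = 0.0
    early_decline: float = 0.1
    peak_age: float = 30.0
    peak_level: float = 0.0
    peak_width: float = 10.0
    oscillation_amplitude: float = 0.0
    oscillation_period: float = 7.0

    def level(self, days: np.ndarray) -> np.ndarray:
        t = np.asarray(days, dtype=float)
        out = (
            self.baseline
            + self.early_level * np.exp(-self.early_decline * t)
            + self.peak_level * np.exp(-0.5 * ((t - self.peak_age) / self.peak_width) ** 2)
            + self.oscillation_amplitude * np.sin(2 * np.pi * t / self.oscillation_period)
        )
        return np.maximum(out, 0.0)


DEFAULT_INTAKE_PROFILES: dict[CohortKey, IntakeProfile] = {
    # heavy sucrose drinking in the first ~10 days, then decline to a low plateau
    (Sex.F, Diet.SUGAR_LIQUID): IntakeProfile(baseline=0.12, early_level=0.50, early_decline=0.12),
    # early sucrose intake, mid-life dip, broad late-life resurgence with oscillation
    (Sex.M, Diet.SUGAR_LIQUID): IntakeProfile(
        baseline=0.12, early_level=0.35, early_decline=0.25,
        peak_age=60.0, peak_level=0.25, peak_width=25.0,
        oscillation_amplitude=0.03, oscillation_period=7.0,
    ),
    # unimodal protein peak in mid-life (ages 20-40), straddling the surface's y0
    (Sex.F, Diet.PROTEIN_LIQUID): IntakeProfile(
        baseline=0.06, peak_age=30.0, peak_level=0.10, peak_width=12.0,
    ),
    # constant moderate protein intake
    (Sex.M, Diet.PROTEIN_LIQUID): IntakeProfile(baseline=0.07),
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic four-cohort experiment."""

    n_per_cohort: int = 30
    seed: int = 0
    mean_lifespan: dict[CohortKey, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_LIFESPAN)
    )
    lifespan_shape: float = 0.1  # Gompertz hazard exponent, 1/days
    true_params: dict[Diet, LorentzianParams] = field(default_factory=lambda: dict(TRUE_PARAMS))
    egg_dispersion: float = math.inf  # negative-binomial size; inf = Poisson
    deterministic_eggs: bool = False  # record the surface mean itself (testing aid)
    intake_profile: dict[CohortKey, IntakeProfile] = field(
        default_factory=lambda: dict(DEFAULT_INTAKE_PROFILES)
    )
    intake_noise_sigma: float = 0.25  # lognormal sd of the multiplicative day noise
    evaporation_mean: float = 0.05  # volume units/day lost in the control capillary
    evaporation_sd: float = 0.01
    reading_noise_sd: float = 0.005  # meniscus reading error
    flies_per_hpc: int = 5

    def __post_init__(self) -> None:
        if self.n_per_cohort < 1:
            raise ValueError("n_per_cohort must be >= 1")
        for name in ("lifespan_shape", "egg_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _gompertz_scale_for_mean(mean: float, shape: float) -> float:
    """Baseline hazard ``a`` such that a Gompertz(a, b=shape) has the given mean.

    Survival S(t) = exp(-(a/b)(e^{bt} - 1)); integrating gives the closed form
    E[T] = e^{a/b} E1(a/b) / b with E1 the exponential integral.
    """

    def mean_of(log_x: float) -> float:
        x = math.exp(log_x)  # x = a / shape
        return float(math.exp(x) * special.exp1(x) / shape)

    sol = optimize.brentq(lambda lx: mean_of(lx) - mean, -34, 4.6, xtol=1e-13)
    return math.exp(sol) * shape


def simulate_death(config: SimulationConfig, sex: Sex, diet: Diet, rng: np.random.Generator) -> int:
    """Draw one lifespan (whole days >= 1) from the cohort's Gompertz law.

    ``lifespan_shape = inf`` is the degenerate zero-variance limit: every fly
    gets the configured mean (rounded up).
    """
    key = (sex, diet)
    if key not in config.mean_lifespan:
        raise KeyError(f"no mean lifespan configured for cohort {key}")
    m = config.mean_lifespan[key]
    if math.isinf(config.lifespan_shape):
        return max(1, math.ceil(m))
    b = config.lifespan_shape
    a = _gompertz_scale_for_mean(m, b)
    u = rng.uniform()
    t = math.log1p(-(b / a) * math.log(u)) / b  # inverse CDF
    return max(1, math.ceil(t))


def simulate_intake_trajectory(
    config: SimulationConfig, sex: Sex, diet: Diet, lifespan: int, rng: np.random.Generator
) -> np.ndarray:
    """Daily true intake over a fly's life: profile level x lognormal day noise."""
    if lifespan < 1:
        raise ValueError(f"lifespan must be >= 1, got {lifespan}")
    profile = config.intake_profile[(sex, diet)]
    days = np.arange(1, lifespan + 1)
    level = profile.level(days)
    if config.intake_noise_sigma > 0:
        s = config.intake_noise_sigma
        noise = rng.lognormal(mean=-0.5 * s**2, sigma=s, size=lifespan)  # mean-1 noise
        level = level * noise
    return level


def simulate_eggs(
    age: int,
    intake: float,
    params: LorentzianParams,
    dispersion: float,
    rng: np.random.Generator,
) -> int:
    """One day's egg count with conditional mean from the Lorentzian surface.

    Poisson when ``dispersion`` is infinite, else negative binomial with size
    ``dispersion`` (variance mu + mu^2/dispersion).
    """
    if age < 1 or intake < 0:
        raise ValueError(f"need age >= 1 and intake >= 0, got ({age}, {intake})")
    from .surface import lorentzian_eval

    mu = lorentzian_eval(params, age, intake)
    if math.isinf(dispersion):
        return int(rng.poisson(mu))
    p = dispersion / (dispersion + mu)
    return int(rng.negative_binomial(dispersion, p))


@dataclass
class SimulatedStudy:
    """Four simulated cohorts plus the ground truth that generated them."""

    cohorts: dict[CohortKey, CohortTable]
    true_intake: dict[str, np.ndarray]  # fly_id -> daily true intake
    true_params: dict[Diet, LorentzianParams]
    config: SimulationConfig

    def cohort(self, sex: Sex, diet: Diet) -> CohortTable:
        return self.cohorts[(sex, diet)]


def _cohort_label(sex: Sex, diet: Diet) -> str:
    return f"{sex.value}-{diet.value}"


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Simulate the full four-cohort study (records, controls, ground truth)."""
    rng = np.random.default_rng(config.seed)
    cohorts: dict[CohortKey, CohortTable] = {}
    true_intake: dict[str, np.ndarray] = {}
    for sex, diet in COHORT_KEYS:
        label = _cohort_label(sex, diet)
        n_hpc = math.ceil(config.n_per_cohort / config.flies_per_hpc)
        lifespans = [simulate_death(config, sex, diet, rng) for _ in range(config.n_per_cohort)]
        max_day = max(lifespans)
        # control channel: one evaporation series per chamber
        evap = {
            h: np.clip(
                rng.normal(config.evaporation_mean, config.evaporation_sd, size=max_day), 0, None
            )
            for h in range(n_hpc)
        }
        records: list[FeedingRecord] = []
        death_day: dict[str, int] = {}
        for i, lifespan in enumerate(lifespans):
            fly_id = f"{label}-{i + 1:03d}"
            hpc = i // config.flies_per_hpc
            hpc_id = f"{label}-HPC{hpc + 1}"
            intake = simulate_intake_trajectory(config, sex, diet, lifespan, rng)
            true_intake[fly_id] = intake
            raw = intake + evap[hpc][:lifespan]
            if config.reading_noise_sd > 0:
                raw = raw + rng.normal(0, config.reading_noise_sd, size=lifespan)
            raw = np.clip(raw, 0, None)
            death_day[fly_id] = lifespan
            for d in range(1, lifespan + 1):
                eggs = None
                if sex is Sex.F:
                    if config.deterministic_eggs:
                        from .surface import lorentzian_eval

                        eggs = float(
                            lorentzian_eval(config.true_params[diet], d, float(intake[d - 1]))
                        )
                    else:
                        eggs = simulate_eggs(
                            d, float(intake[d - 1]), config.true_params[diet],
                            config.egg_dispersion, rng,
                        )
                records.append(
                    FeedingRecord(
                        fly_id=fly_id, sex=sex, diet=diet, hpc_id=hpc_id,
                        age_day=d, raw_descent=float(raw[d - 1]), eggs=eggs, alive=True,
                    )
                )
        controls = [
            ControlReading(hpc_id=f"{label}-HPC{h + 1}", age_day=d, evaporation=float(evap[h][d - 1]))
            for h in range(n_hpc)
            for d in range(1, max_day + 1)
        ]
        table = CohortTable(records=records, controls=controls, death_day=death_day)
        table.validate()
        cohorts[(sex, diet)] = table
    return SimulatedStudy(
        cohorts=cohorts, true_intake=true_intake,
        true_params=dict(config.true_params), config=config,
    )


def noiseless_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Convenience: a config with all observation noise switched off."""
    cfg = SimulationConfig(
        seed=seed, intake_noise_sigma=0.0, reading_noise_sd=0.0, evaporation_sd=0.0,
        deterministic_eggs=True,
    )
    return replace(cfg, **overrides)
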