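"""Synthetic bobwhite cohorts, FCM time series and radioimmunoassay plates.

The generator is the exact generative direction of the hierarchical
random-coefficients model: per-bird coefficient vectors are drawn from
``Normal(mu_k, sigma_k^2)``, observations from the linear predictor under
the fixed design-coding rules plus Gaussian residual noise, truncated at
zero (concentrations cannot be negative).  Whether a bird yields a sample
in a given 4-hour window is independent Bernoulli ("defecation
probability"), emulating the realized ~25 samples per bird over the
144-hour study.  Default truths ship in ``data/true_params.yaml``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidConfigError
from .model import EFFECT_NAMES, TREATMENTS, build_design

#: Long-format sample table schema (one row per collected dropping).
SAMPLE_COLUMNS = (
    "bird_id", "age_class", "sex", "weight_g", "treatment", "window_index",
    "hours_since_start", "clock_time", "is_night", "fcm_pg_per_mg",
)

#: Plate table schema; role is one of B0, NSB, standard, dilution, unknown, control.
PLATE_COLUMNS = ("plate_id", "tube_id", "role", "series_id", "dose_or_dilution", "count")

AGE_CLASSES = ("adult", "juvenile")
SEXES = ("male", "female")


def load_default_truth() -> dict:
    """Read the shipped generating-truth config (mu/sigma per effect, residual SD)."""
    text = importlib.resources.files("quailfcm").joinpath(
        "data/true_params.yaml").read_text()
    return yaml.safe_load(text)


def _default_truth_arrays() -> tuple[np.ndarray, np.ndarray, float]:
    cfg = load_default_truth()
    mu = np.array([cfg["effects"][k]["mu"] for k in EFFECT_NAMES])
    sigma = np.array([cfg["effects"][k]["sigma"] for k in EFFECT_NAMES])
    return mu, sigma, float(cfg["residual_sd"])


@dataclass(frozen=True)
class BirdProfile:
    bird_id: str
    age_class: str
    sex: str
    weight_g: float


@dataclass
class GeneratorConfig:
    """Study-design and truth parameters for the synthetic cohort.

    Defaults reproduce the study conditions: four age-by-sex classes of
    six birds, weights uniform on 141-214 g, three sequential 48-hour
    treatments sampled every 4 hours starting at 09:00, night windows at
    21:00/01:00/05:00, and a 0.70 per-window defecation probability.
    """

    n_per_class: int = 6
    true_mu_k: np.ndarray = None          # (K,) population means, pg/mg
    true_sigma_k: np.ndarray = None       # (K,) among-bird SDs, pg/mg
    residual_sd: float = None             # pg/mg
    defecation_prob: float = 0.70
    window_hours: int = 4
    treatment_hours: int = 48
    start_clock: int = 9                  # hour of first collection
    night_windows: frozenset = frozenset({21, 1, 5})
    weight_range: tuple = (141.0, 214.0)
    seed: int = 0

    # RIA plate simulation
    n_plates: int = 17
    b0_count: float = 10_000.0
    nsb_count: float = 500.0
    standard_doses: tuple = (31.25, 62.5, 125.0, 250.0, 500.0)  # pg/mL
    curve_slope: float = -1.2             # logit units per ln(dose)
    curve_intercept: float = 4.0
    dilution_factors: tuple = (1.0, 0.5, 0.25, 0.125, 0.0625)
    n_dilution_series: int = 3
    sample_neat_doses: tuple = (400.0, 280.0, 180.0)  # pg/mL, one per series
    slope_offset: float = 0.0             # non-parallelism injected per series
    count_cv: float = 0.02                # multiplicative per-tube noise
    n_unknowns_per_plate: int = 3
    unknown_dose_range: tuple = (60.0, 350.0)
    control_dose: float = 150.0           # pg/mL, shared across plates

    def __post_init__(self):
        if self.true_mu_k is None or self.true_sigma_k is None or self.residual_sd is None:
            mu, sigma, rsd = _default_truth_arrays()
            if self.true_mu_k is None:
                self.true_mu_k = mu
            if self.true_sigma_k is None:
                self.true_sigma_k = sigma
            if self.residual_sd is None:
                self.residual_sd = rsd
        self.true_mu_k = np.asarray(self.true_mu_k, float)
        self.true_sigma_k = np.asarray(self.true_sigma_k, float)

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise InvalidConfigError("n_per_class must be >= 1")
        if len(self.true_mu_k) != len(self.true_sigma_k):
            raise InvalidConfigError("true_mu_k and true_sigma_k lengths differ")
        if len(self.true_mu_k) != len(EFFECT_NAMES):
            raise InvalidConfigError(
                f"expected {len(EFFECT_NAMES)} effects "
                f"({', '.join(EFFECT_NAMES)}), got {len(self.true_mu_k)}")
        if (self.true_sigma_k < 0).any() or self.residual_sd < 0:
            raise InvalidConfigError("SDs must be nonnegative")
        if not 0.0 <= self.defecation_prob <= 1.0:
            raise InvalidConfigError("defecation_prob must be in [0, 1]")
        if self.treatment_hours % self.window_hours != 0:
            raise InvalidConfigError("treatment_hours must be divisible by window_hours")
        if len(self.standard_doses) < 3:
            raise InvalidConfigError("need at least 3 standard doses")

    @property
    def windows_per_treatment(self) -> int:
        return self.treatment_hours // self.window_hours


def make_cohort(config: GeneratorConfig) -> list[BirdProfile]:
    """Balanced age-by-sex cohort with uniform weights; deterministic given seed."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.weight_range
    birds = []
    i = 0
    for age in AGE_CLASSES:
        for sex in SEXES:
            for _ in range(config.n_per_class):
                i += 1
                birds.append(BirdProfile(
                    bird_id=f"b{i:02d}", age_class=age, sex=sex,
                    weight_g=float(rng.uniform(lo, hi))))
    return birds


def _complete_table(cohort: list[BirdProfile], config: GeneratorConfig) -> pd.DataFrame:
    """All birds x all windows, fcm filled with zeros (design scaffold)."""
    W = config.windows_per_treatment
    rows = []
    for bird in cohort:
        for t_i, treatment in enumerate(TREATMENTS):
            for w in range(W):
                hours = t_i * config.treatment_hours + w * config.window_hours
                clock = (config.start_clock + hours) % 24
                rows.append((bird.bird_id, bird.age_class, bird.sex,
                             bird.weight_g, treatment, w, float(hours),
                             clock, clock in config.night_windows, 0.0))
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def simulate_fcm(cohort: list[BirdProfile], config: GeneratorConfig) -> pd.DataFrame:
    """Simulate the FCM time series for a cohort.

    Draws per-bird coefficients ``beta_{j,k} ~ Normal(true_mu_k,
    true_sigma_k^2)``, evaluates the linear predictor under the design
    coding of :func:`quailfcm.model.build_design`, adds Gaussian residual
    noise, truncates at zero and thins windows by the defecation
    probability.  Missing windows are absent rows.
    """
    if not cohort:
        raise InvalidConfigError("cohort is empty")
    config.validate()
    rng = np.random.default_rng([config.seed, 1])

    table = _complete_table(cohort, config)
    data = build_design(table)
    K = data.n_effects
    J = data.n_birds
    beta = config.true_mu_k + config.true_sigma_k * rng.standard_normal((J, K))
    linpred = np.einsum("ik,ik->i", data.X, beta[data.bird_index])
    noise = config.residual_sd * rng.standard_normal(len(table)) \
        if config.residual_sd > 0 else 0.0
    table = table.copy()
    table["fcm_pg_per_mg"] = np.maximum(0.0, linpred + noise)
    keep = rng.random(len(table)) < config.defecation_prob \
        if config.defecation_prob < 1.0 else np.ones(len(table), bool)
    return table.loc[keep].reset_index(drop=True)


# --------------------------------------------------------------------------
# RIA plate simulation

def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def simulate_ria_plates(config: GeneratorConfig) -> pd.DataFrame:
    """Synthetic competitive-RIA plates for the validation pipeline.

    Every plate carries duplicate B0 and NSB tubes, the standard series
    (linear in logit-binding vs ln-dose with the configured slope),
    duplicate unknowns and one shared control.  Plate 1 additionally
    carries ``n_dilution_series`` serial-dilution series whose slope is
    offset by ``slope_offset`` (0 gives exactly parallel lines).
    Counts get multiplicative Gaussian noise with CV ``count_cv``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    b0, nsb = config.b0_count, config.nsb_count
    span = b0 - nsb

    def noisy(x):
        if config.count_cv <= 0:
            return float(x)
        return float(x * (1.0 + config.count_cv * rng.standard_normal()))

    def count_at(dose, slope):
        p = _logistic(config.curve_intercept + slope * np.log(dose))
        return nsb + p * span

    rows = []
    tube = 0

    def add(plate, role, series, dose, count):
        nonlocal tube
        tube += 1
        rows.append((f"p{plate:02d}", f"t{tube:04d}", role, series,
                     float(dose), max(0.0, noisy(count))))

    for plate in range(1, config.n_plates + 1):
        for _ in range(2):
            add(plate, "B0", "", 0.0, b0)
            add(plate, "NSB", "", 0.0, nsb)
        for dose in config.standard_doses:
            add(plate, "standard", "std", dose, count_at(dose, config.curve_slope))
        if plate == 1:
            for s in range(config.n_dilution_series):
                neat = config.sample_neat_doses[s % len(config.sample_neat_doses)]
                slope = config.curve_slope + config.slope_offset
                for d in config.dilution_factors:
                    # recorded x is the dilution factor; ln(neat) folds into
                    # the intercept, so parallel series share the slope
                    p = _logistic(config.curve_intercept
                                  + slope * np.log(neat * d))
                    add(plate, "dilution", f"dil{s + 1}", d, nsb + p * span)
        for u in range(config.n_unknowns_per_plate):
            dose = rng.uniform(*config.unknown_dose_range)
            c = count_at(dose, config.curve_slope)
            sid = f"unk{plate:02d}_{u + 1}"
            add(plate, "unknown", sid, 0.0, c)
            add(plate, "unknown", sid, 0.0, c)
        add(plate, "control", "ctrl", 0.0,
            count_at(config.control_dose, config.curve_slope))
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)
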