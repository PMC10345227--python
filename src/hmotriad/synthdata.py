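"""Synthetic longitudinal mother-infant cohort generator.

Emulates the statistical structure of a breast-milk / infant-gut-microbiome /
cognition study: ~105 mother-infant dyads observed at 1-4 visits between 2.9
and 12 months of age, with

* eight human milk oligosaccharide (HMO) concentrations (mg/L) following
  lognormal age trends (3-FL, 3'-SL and A-tetra rising; 2'-FL, 6'-SL, LNT,
  LNnT and LNFP-I falling),
* A-tetrasaccharide detectable only in milk of blood-group-A "A-tetra+"
  mothers (~36/105), constant within mother,
* a sparse compositional gut microbiota (12 focal *Bifidobacterium* /
  *Bacteroides* species + remainder) drawn from an age-modulated Dirichlet,
* six Mullen Scales of Early Learning (MSEL) scores generated from a
  random-intercept linear model on standardized HMO / microbiota predictors,
  their products, and the adjusting covariates.

The generator returns the ground-truth coefficients and subject intercepts so
downstream selection and mixed-model stages can be validated by parameter
recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HMO_NAMES",
    "SPECIES_NAMES",
    "MSEL_OUTCOMES",
    "COVARIATE_NAMES",
    "ATETRA_LOD_MGL",
    "HMOTrend",
    "SpeciesParams",
    "GammaSpec",
    "OutcomeModel",
    "CohortConfig",
    "HMOProfile",
    "MicrobiotaProfile",
    "MSELScores",
    "DyadSample",
    "Cohort",
    "ConfigError",
    "default_config",
    "generate_cohort",
    "simulate_hmo",
    "simulate_microbiota",
    "simulate_msel",
]

# ---------------------------------------------------------------------------
# canonical names
# ---------------------------------------------------------------------------

#: The eight quantified HMOs, in fixed column order.
HMO_NAMES = ("2fl", "3fl", "3sl", "6sl", "lnt", "lnnt", "lnfp1", "atetra")

#: Twelve focal species (seven Bifidobacterium, five Bacteroides).
SPECIES_NAMES = (
    "bif_longum",
    "bif_bifidum",
    "bif_breve",
    "bif_pseudocatenulatum",
    "bif_kashiwanohense",
    "bif_catenulatum",
    "bif_unspecified",
    "b_vulgatus",
    "b_dorei",
    "b_fragilis",
    "b_uniformis",
    "b_ovatus",
)

#: Mullen outcomes: early-learning composite plus the five T-scored subdomains.
MSEL_OUTCOMES = (
    "composite",
    "gross_motor",
    "visual_reception",
    "fine_motor",
    "receptive_language",
    "expressive_language",
)

#: Adjusting-covariate design columns (treatment coding; references are
#: female / cesarean / below-graduate / site B / batch 2018).
COVARIATE_NAMES = (
    "sex_male",
    "delivery_vaginal",
    "edu_graduate",
    "site_a",
    "batch_2019",
    "batch_2020",
)

#: A-tetra limit of detection, mg/L.
ATETRA_LOD_MGL = 4.4


class ConfigError(ValueError):
    """Raised when a cohort configuration field is invalid."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HMOTrend:
    """Lognormal age model for one HMO.

    Concentration ~ exp(log(baseline_mgl) + slope_per_month * age + sigma*Z).
    ``atetra_log_offset`` is added to the log-mean for samples from A-tetra+
    mothers (used to give 3-FL its lower mean in the A-tetra+ group).
    """

    baseline_mgl: float
    slope_per_month: float
    sigma: float
    atetra_log_offset: float = 0.0


@dataclass(frozen=True)
class SpeciesParams:
    """Dirichlet weight and latent age slope for one species.

    The Dirichlet weight at age ``a`` is ``weight * exp(age_slope*(a - 8))``;
    centring at 8 months (the cohort mean age) keeps marginal means close to
    their calibration values while letting abundance drift with age.
    """

    weight: float
    age_slope: float = 0.0


@dataclass(frozen=True)
class GammaSpec:
    """One planted HMO x species interaction coefficient.

    ``stratum`` restricts the interaction to visits of one A-tetra stratum
    (``"atetra_pos"`` / ``"atetra_neg"``); ``None`` applies it everywhere.
    """

    hmo: str
    species: str
    coef: float
    stratum: str | None = None


@dataclass(frozen=True)
class OutcomeModel:
    """True fixed-effect model for one MSEL outcome (standardized scale)."""

    intercept: float = 50.0
    beta_cov: tuple[float, ...] = (0.0,) * 6  # order: COVARIATE_NAMES
    beta_hmo: tuple[float, ...] = (0.0,) * 8  # order: HMO_NAMES
    beta_mb: tuple[float, ...] = (0.0,) * 12  # order: SPECIES_NAMES
    gamma: tuple[GammaSpec, ...] = ()
    sigma_subject: float = 5.0
    sigma_resid: float = 7.0


def _default_hmo_trends() -> dict[str, HMOTrend]:
    # Baselines are medians at birth on the mg/L scale; slopes act on the log
    # scale per month. Calibrated so that cohort means over ages 2.9-12 months
    # sit near reported values: 3-FL ~1551 mg/L in the A-tetra- group and
    # ~1243 in the A-tetra+ group (log offset log(1243.26/1550.97)), 6'-SL
    # ~77 mg/L at 3-4 months falling to ~57 at 4-8 months.
    return {
        "2fl": HMOTrend(2200.0, -0.030, 0.50),
        "3fl": HMOTrend(1010.0, +0.040, 0.50,
                        atetra_log_offset=math.log(1243.26 / 1550.97)),
        "3sl": HMOTrend(100.0, +0.020, 0.40),
        "6sl": HMOTrend(106.0, -0.117, 0.40),
        "lnt": HMOTrend(550.0, -0.050, 0.50),
        "lnnt": HMOTrend(180.0, -0.060, 0.50),
        "lnfp1": HMOTrend(250.0, -0.040, 0.60),
        # for A-tetra+ mothers the draw is added to the LOD so detectability
        # is constant within mother; A-tetra- mothers have exactly 0
        "atetra": HMOTrend(25.0, +0.030, 0.60),
    }


def _default_species_params() -> dict[str, SpeciesParams]:
    # Weights = reported mean relative abundance x total concentration 1.3;
    # the small total concentration reproduces the sparse, high-dispersion
    # compositions typical of the infant gut (SD ~ 0.32 for Bif. longum).
    means = {
        "bif_longum": 0.38, "bif_bifidum": 0.09, "bif_breve": 0.09,
        "bif_pseudocatenulatum": 0.01, "bif_kashiwanohense": 0.01,
        "bif_catenulatum": 0.001, "bif_unspecified": 0.01,
        "b_vulgatus": 0.04, "b_dorei": 0.02, "b_fragilis": 0.03,
        "b_uniformis": 0.003, "b_ovatus": 0.01,
    }
    slopes = {"bif_longum": -0.05, "bif_breve": -0.05,
              "bif_catenulatum": +0.05, "b_vulgatus": +0.05}
    total = 1.3
    return {s: SpeciesParams(weight=means[s] * total,
                             age_slope=slopes.get(s, 0.0))
            for s in SPECIES_NAMES}


def _default_outcome_models() -> dict[str, OutcomeModel]:
    # Intercepts near reported cohort means; batch-year effects negative
    # (scores fell in later analysis years); all HMO/microbiota coefficients
    # null by default -- tests plant effects explicitly.
    batch = (0.0, 0.0, 0.0, 0.0, -3.0, -5.0)
    models = {}
    for name in MSEL_OUTCOMES:
        if name == "composite":
            models[name] = OutcomeModel(intercept=108.0, beta_cov=batch,
                                        sigma_subject=5.0, sigma_resid=11.0)
        else:
            models[name] = OutcomeModel(intercept=54.0, beta_cov=batch,
                                        sigma_subject=5.0, sigma_resid=7.0)
    return models


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort."""

    n_subjects: int = 105
    p_singleton: float = 60.0 / 105.0
    max_visits: int = 4
    #: probability weights over {2, ..., max_visits} for non-singleton
    #: subjects; None -> (0.60, 0.35, 0.05) when max_visits == 4 (calibrated
    #: so a 105-subject cohort totals ~170 visits), else uniform
    visit_weights: tuple[float, ...] | None = None
    age_range_months: tuple[float, float] = (2.9, 12.0)
    p_atetra_mother: float = 36.0 / 105.0
    # covariate marginals (reported cohort proportions)
    p_male: float = 0.38
    p_vaginal: float = 0.79
    p_graduate: float = 0.61
    p_site_a: float = 0.5
    p_batch: tuple[float, float, float] = (0.3, 0.4, 0.3)  # 2018/2019/2020
    hmo_trend_params: dict[str, HMOTrend] = field(
        default_factory=_default_hmo_trends)
    microbiota_params: dict[str, SpeciesParams] = field(
        default_factory=_default_species_params)
    outcome_models: dict[str, OutcomeModel] = field(
        default_factory=_default_outcome_models)
    derived_composite: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_singleton", "p_atetra_mother", "p_male", "p_vaginal",
                     "p_graduate", "p_site_a"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.max_visits < 1:
            raise ConfigError(f"max_visits must be >= 1, got {self.max_visits}")
        lo, hi = self.age_range_months
        if not (0.0 < lo < hi <= 12.0):
            raise ConfigError(
                f"age_range_months must satisfy 0 < lo < hi <= 12, got {(lo, hi)}")
        if abs(sum(self.p_batch) - 1.0) > 1e-9 or min(self.p_batch) < 0:
            raise ConfigError(f"p_batch must be a probability vector, got {self.p_batch}")
        if self.visit_weights is not None:
            w = self.visit_weights
            if len(w) != self.max_visits - 1 or min(w) < 0 or abs(sum(w) - 1.0) > 1e-9:
                raise ConfigError(
                    "visit_weights must be a probability vector over "
                    f"{{2..{self.max_visits}}}, got {w}")
        if set(self.hmo_trend_params) != set(HMO_NAMES):
            raise ConfigError("hmo_trend_params must cover exactly the eight HMOs")
        for h, t in self.hmo_trend_params.items():
            if t.baseline_mgl <= 0 or t.sigma < 0:
                raise ConfigError(f"hmo_trend_params[{h!r}] has invalid baseline/sigma")
        for s, p in self.microbiota_params.items():
            if p.weight <= 0:
                raise ConfigError(f"microbiota_params[{s!r}].weight must be > 0")
        for o, m in self.outcome_models.items():
            if o not in MSEL_OUTCOMES:
                raise ConfigError(f"unknown outcome {o!r} in outcome_models")
            if m.sigma_subject < 0 or m.sigma_resid < 0:
                raise ConfigError(f"outcome_models[{o!r}] has negative SD")
            if len(m.beta_cov) != len(COVARIATE_NAMES):
                raise ConfigError(f"outcome_models[{o!r}].beta_cov has wrong length")
            if len(m.beta_hmo) != len(HMO_NAMES):
                raise ConfigError(f"outcome_models[{o!r}].beta_hmo has wrong length")
            if len(m.beta_mb) != len(SPECIES_NAMES):
                raise ConfigError(f"outcome_models[{o!r}].beta_mb has wrong length")
            for g in m.gamma:
                if g.hmo not in HMO_NAMES or g.species not in SPECIES_NAMES:
                    raise ConfigError(
                        f"outcome_models[{o!r}] gamma refers to unknown pair "
                        f"({g.hmo!r}, {g.species!r})")
                if g.stratum not in (None, "atetra_pos", "atetra_neg"):
                    raise ConfigError(
                        f"outcome_models[{o!r}] gamma stratum {g.stratum!r} invalid")


def default_config(**overrides) -> CohortConfig:
    """The study-calibrated default configuration, with optional overrides."""
    return replace(CohortConfig(), **overrides)


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HMOProfile:
    """Concentrations in mg/L for the eight HMOs, keyed by HMO_NAMES."""

    concentrations: dict[str, float]

    def __post_init__(self):
        if set(self.concentrations) != set(HMO_NAMES):
            raise ValueError("HMOProfile must cover exactly the eight HMOs")
        for k, v in self.concentrations.items():
            if v < 0:
                raise ValueError(f"negative concentration for {k}: {v}")

    def __getitem__(self, name: str) -> float:
        return self.concentrations[name]


@dataclass(frozen=True)
class MicrobiotaProfile:
    """Relative abundances in [0, 1]; species + remainder sum to 1."""

    abundances: dict[str, float]  # keyed by SPECIES_NAMES
    remainder: float

    def __post_init__(self):
        vals = list(self.abundances.values()) + [self.remainder]
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("relative abundances must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("abundances + remainder must sum to 1")

    def __getitem__(self, name: str) -> float:
        return self.abundances[name]


@dataclass(frozen=True)
class MSELScores:
    composite: float
    gross_motor: float
    visual_reception: float
    fine_motor: float
    receptive_language: float
    expressive_language: float

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class DyadSample:
    """One mother-infant visit record."""

    subject_id: str
    visit_index: int
    age_months: float
    sex: str                  # male / female
    delivery: str             # vaginal / cesarean
    maternal_education: str   # graduate / below
    site: str                 # A / B
    batch_year: int           # 2018 / 2019 / 2020
    hmo: HMOProfile
    microbiota: MicrobiotaProfile
    msel: MSELScores


@dataclass
class Cohort:
    """A generated cohort: the visit records plus the generating truth.

    Behaves as a sequence of :class:`DyadSample`.  ``truth`` holds everything
    needed for recovery tests: the outcome models, per-subject random
    intercepts, and the standardization statistics the generator used when
    applying coefficients on the standardized scale.
    """

    samples: list[DyadSample]
    truth: dict

    def __iter__(self):
        return iter(self.samples)

    def __len__(self):
        return len(self.samples)

    def __getitem__(self, i):
        return self.samples[i]


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------


def simulate_hmo(age_months: float, atetra_mother: bool,
                 params: dict[str, HMOTrend],
                 rng: np.random.Generator) -> HMOProfile:
    """Draw one milk HMO profile at the given infant age.

    Each concentration is lognormal around an age-linear log-mean.  A-tetra
    is 0 mg/L (below detection) for A-tetra- mothers and ``LOD + lognormal``
    for A-tetra+ mothers, so detectability never flips within a mother.
    """
    if age_months < 0:
        raise ValueError(f"age_months must be non-negative, got {age_months}")
    conc: dict[str, float] = {}
    for name in HMO_NAMES:
        t = params[name]
        if name == "atetra":
            if not atetra_mother:
                conc[name] = 0.0
                continue
            mu = math.log(t.baseline_mgl) + t.slope_per_month * age_months
            conc[name] = ATETRA_LOD_MGL + float(
                rng.lognormal(mean=mu, sigma=t.sigma))
            continue
        mu = math.log(t.baseline_mgl) + t.slope_per_month * age_months
        if atetra_mother:
            mu += t.atetra_log_offset
        conc[name] = float(rng.lognormal(mean=mu, sigma=t.sigma))
    return HMOProfile(conc)


def simulate_microbiota(age_months: float, params: dict[str, SpeciesParams],
                        rng: np.random.Generator) -> MicrobiotaProfile:
    """Draw one gut composition from the age-modulated Dirichlet."""
    if age_months < 0:
        raise ValueError(f"age_months must be non-negative, got {age_months}")
    names = [s for s in SPECIES_NAMES if s in params]
    extra = sorted(set(params) - set(SPECIES_NAMES))
    names += extra
    alpha = np.array([
        params[s].weight * math.exp(params[s].age_slope * (age_months - 8.0))
        for s in names
    ])
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet concentration weights must be positive")
    # remainder bucket: everything outside the focal species; weight fixed so
    # focal means stay calibrated (1 - sum of focal mean fractions) * total
    alpha_rem = 0.326 * 1.3
    draw = rng.dirichlet(np.append(alpha, alpha_rem))
    abund = {s: float(v) for s, v in zip(names, draw[:-1])}
    return MicrobiotaProfile(abundances=abund, remainder=float(draw[-1]))


def simulate_msel(fixed_row: dict[str, float],
                  models: dict[str, OutcomeModel],
                  subject_intercepts: dict[str, float],
                  rng: np.random.Generator,
                  derived_composite: bool = False) -> MSELScores:
    """Generate the six MSEL scores for one visit.

    ``fixed_row`` maps covariate dummies (``COVARIATE_NAMES``), standardized
    HMO values (``z_<hmo>``), standardized abundances (``z_<species>``) and
    the visit's stratum flag (``atetra_pos``: 0/1) to values.  Each outcome is

        score = intercept + beta_cov'c + beta_hmo'z_H + beta_mb'z_M
                + sum_g gamma_g z_Hg z_Mg [stratum mask] + b_i + eps
    """
    missing_out = [o for o in MSEL_OUTCOMES if o not in models]
    if missing_out:
        raise ValueError(f"outcome models missing for {missing_out}")
    needed = list(COVARIATE_NAMES) + [f"z_{h}" for h in HMO_NAMES] + \
        [f"z_{s}" for s in SPECIES_NAMES] + ["atetra_pos"]
    missing = [k for k in needed if k not in fixed_row]
    if missing:
        raise ValueError(f"fixed_row missing predictors: {missing[:5]}...")

    cov = np.array([fixed_row[c] for c in COVARIATE_NAMES])
    zh = np.array([fixed_row[f"z_{h}"] for h in HMO_NAMES])
    zm = np.array([fixed_row[f"z_{s}"] for s in SPECIES_NAMES])
    is_pos = bool(fixed_row["atetra_pos"])

    scores: dict[str, float] = {}
    for name in MSEL_OUTCOMES:
        m = models[name]
        mu = m.intercept + float(cov @ np.asarray(m.beta_cov))
        mu += float(zh @ np.asarray(m.beta_hmo)) + float(zm @ np.asarray(m.beta_mb))
        for g in m.gamma:
            if g.stratum == "atetra_pos" and not is_pos:
                continue
            if g.stratum == "atetra_neg" and is_pos:
                continue
            mu += g.coef * fixed_row[f"z_{g.hmo}"] * fixed_row[f"z_{g.species}"]
        eps = float(rng.normal(0.0, m.sigma_resid)) if m.sigma_resid > 0 else 0.0
        scores[name] = mu + subject_intercepts.get(name, 0.0) + eps
    if derived_composite:
        subs = [scores[o] for o in ("visual_reception", "fine_motor",
                                    "receptive_language", "expressive_language")]
        scores["composite"] = 2.0 * float(np.mean(subs))
    return MSELScores(**scores)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def _standardize_col(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return np.zeros_like(x), mu, 0.0
    return (x - mu) / sd, mu, sd


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort (reproducible under ``config.seed``).

    Visit counts are 1 with probability ``p_singleton``, else uniform on
    {2, ..., max_visits}.  HMO and microbiota draws are made per visit, then
    standardized across the whole cohort, and the MSEL outcome models are
    applied on that standardized scale.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range_months

    if config.max_visits >= 2:
        if config.visit_weights is not None:
            vweights = np.asarray(config.visit_weights, dtype=float)
        elif config.max_visits == 4:
            vweights = np.array([0.60, 0.35, 0.05])
        else:
            vweights = np.full(config.max_visits - 1,
                               1.0 / (config.max_visits - 1))

    # ---- subjects -----------------------------------------------------
    rows = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:04d}"
        atetra = bool(rng.random() < config.p_atetra_mother)
        n_visits = 1
        if rng.random() >= config.p_singleton and config.max_visits >= 2:
            n_visits = 2 + int(rng.choice(config.max_visits - 1, p=vweights))
        ages = np.sort(rng.uniform(lo, hi, size=n_visits))
        sex = "male" if rng.random() < config.p_male else "female"
        delivery = "vaginal" if rng.random() < config.p_vaginal else "cesarean"
        edu = "graduate" if rng.random() < config.p_graduate else "below"
        site = "A" if rng.random() < config.p_site_a else "B"
        batch = int(rng.choice([2018, 2019, 2020], p=config.p_batch))
        for v, age in enumerate(ages, start=1):
            rows.append(dict(subject_id=sid, visit_index=v,
                             age_months=float(age), atetra_mother=atetra,
                             sex=sex, delivery=delivery,
                             maternal_education=edu, site=site,
                             batch_year=batch))

    # ---- milk and microbiota draws ------------------------------------
    hmos = [simulate_hmo(r["age_months"], r["atetra_mother"],
                         config.hmo_trend_params, rng) for r in rows]
    mbs = [simulate_microbiota(r["age_months"], config.microbiota_params, rng)
           for r in rows]

    # ---- standardization over the cohort ------------------------------
    std_stats: dict[str, tuple[float, float]] = {}
    zcols: dict[str, np.ndarray] = {}
    for h in HMO_NAMES:
        x = np.array([p[h] for p in hmos])
        z, mu, sd = _standardize_col(x)
        zcols[f"z_{h}"] = z
        std_stats[h] = (mu, sd)
    for s in SPECIES_NAMES:
        x = np.array([p[s] for p in mbs])
        z, mu, sd = _standardize_col(x)
        zcols[f"z_{s}"] = z
        std_stats[s] = (mu, sd)

    # ---- outcomes ------------------------------------------------------
    intercepts: dict[str, dict[str, float]] = {}
    for r in rows:
        sid = r["subject_id"]
        if sid not in intercepts:
            intercepts[sid] = {
                o: float(rng.normal(0.0, m.sigma_subject)) if m.sigma_subject > 0 else 0.0
                for o, m in config.outcome_models.items()
            }

    samples: list[DyadSample] = []
    for k, r in enumerate(rows):
        fixed = {
            "sex_male": 1.0 if r["sex"] == "male" else 0.0,
            "delivery_vaginal": 1.0 if r["delivery"] == "vaginal" else 0.0,
            "edu_graduate": 1.0 if r["maternal_education"] == "graduate" else 0.0,
            "site_a": 1.0 if r["site"] == "A" else 0.0,
            "batch_2019": 1.0 if r["batch_year"] == 2019 else 0.0,
            "batch_2020": 1.0 if r["batch_year"] == 2020 else 0.0,
            "atetra_pos": 1.0 if r["atetra_mother"] else 0.0,
        }
        for name, z in zcols.items():
            fixed[name] = float(z[k])
        msel = simulate_msel(fixed, config.outcome_models,
                             intercepts[r["subject_id"]], rng,
                             derived_composite=config.derived_composite)
        samples.append(DyadSample(
            subject_id=r["subject_id"], visit_index=r["visit_index"],
            age_months=r["age_months"], sex=r["sex"], delivery=r["delivery"],
            maternal_education=r["maternal_education"], site=r["site"],
            batch_year=r["batch_year"], hmo=hmos[k], microbiota=mbs[k],
            msel=msel))

    truth = {
        "outcome_models": config.outcome_models,
        "subject_intercepts": intercepts,
        "standardization": std_stats,
        "seed": config.seed,
    }
    return Cohort(samples=samples, truth=truth)
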