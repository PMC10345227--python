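"""End-to-end orchestration of the triad association analysis.

For each requested MSEL outcome and stratification the pipeline runs:

1. preparation — per-species double-MAD outlier handling, abundance-sum
   species filter, standardization of HMO and abundance predictors, optional
   age residualization, per-visit A-tetra detectability;
2. design construction with HMO x species interactions and hierarchy groups;
3. penalty selection by subject-level 10-fold CV, repeated with fresh fold
   randomizations, aggregated into per-group selection frequencies;
4. fallback to the all-main-effects model when no interaction is stable;
5. a random-intercept REML mixed model on the adjusting covariates plus the
   selected terms, reported as effect sizes, SEs and Wald p-values.

Results are collected into a :class:`~hmotriad.dataio.ResultsBundle` with
full provenance (seed, configuration hash, selection frequencies, fallback
flags, variance components).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .dataio import Dataset, ResultsBundle, config_hash, write_results
from .design import STRATIFICATIONS, ModelSpec, build_design, build_groups
from .grouplasso import stability_select
from .lmm import fit_lmm_reml, wald_tests
from .preprocess import (PreprocessConfig, OutlierReport, apply_outlier_policy,
                         filter_species, residualize_on_age, standardize)
from .synthdata import MSEL_OUTCOMES, COVARIATE_NAMES

logger = logging.getLogger("hmotriad")

__all__ = ["LassoSettings", "RunConfig", "PreparedData", "prepare",
           "run_analysis", "make_report"]


@dataclass(frozen=True)
class LassoSettings:
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    k_folds: int = 10
    reps: int = 200
    freq_cutoff: float = 0.5
    tol: float = 1e-8
    max_iter: int = 20_000


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full analysis run."""

    input_path: str | None = None
    simulate: object | None = None      # CohortConfig when simulating
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    lasso: LassoSettings = field(default_factory=LassoSettings)
    outcomes: tuple[str, ...] = MSEL_OUTCOMES
    stratifications: tuple[str, ...] = STRATIFICATIONS
    seed: int = 0

    def __post_init__(self):
        bad = set(self.outcomes) - set(MSEL_OUTCOMES)
        if bad:
            raise ValueError(f"unknown outcome(s) {sorted(bad)}")
        bad = set(self.stratifications) - set(STRATIFICATIONS)
        if bad:
            raise ValueError(f"unknown stratification(s) {sorted(bad)}")
        if self.input_path is None and self.simulate is None:
            raise ValueError("RunConfig needs an input_path or a simulate block")


@dataclass
class PreparedData:
    frame: pd.DataFrame
    retained_species: list[str]
    outlier_report: OutlierReport


def prepare(dataset: Dataset, config: PreprocessConfig | None = None) -> PreparedData:
    """Outlier handling, species filtering, standardization, covariate coding.

    Adds to the frame: covariate dummies (reference levels female / cesarean
    / below-graduate / site B / batch 2018), the per-visit ``atetra_pos``
    flag, and standardized (optionally age-residualized) ``z_`` predictor
    columns for the eight HMOs and every retained species.
    """
    config = config or PreprocessConfig()
    df = dataset.df.copy()

    report = OutlierReport()
    cleaned = {}
    for sp in dataset.species_names:
        col = f"ra_{sp}"
        vals = df[col].to_numpy(dtype=float)
        new, flags = apply_outlier_policy(vals, config.mad_threshold,
                                          config.outlier_policy)
        cleaned[sp] = new
        from .preprocess import _double_mad  # diagnostics for the report
        ok = ~np.isnan(vals)
        m, left, right = _double_mad(vals[ok])
        report.median[sp] = m
        report.left_mad[sp] = left
        report.right_mad[sp] = right
        report.flagged[sp] = [
            (df["subject_id"].iloc[i], int(df["visit_index"].iloc[i]))
            for i in np.flatnonzero(flags)]
        df[col] = new

    abundance = pd.DataFrame(cleaned)
    retained = filter_species(abundance, config.species_sum_threshold)
    logger.info("species filter: retained %d/%d species",
                len(retained), len(dataset.species_names))

    df["atetra_pos"] = (df["atetra_mgL"] > config.atetra_lod_mgl).astype(float)

    df["sex_male"] = (df["sex"] == "male").astype(float)
    df["delivery_vaginal"] = (df["delivery"] == "vaginal").astype(float)
    df["edu_graduate"] = (df["maternal_education"] == "graduate").astype(float)
    df["site_a"] = (df["site"] == "A").astype(float)
    df["batch_2019"] = (df["batch_year"] == 2019).astype(float)
    df["batch_2020"] = (df["batch_year"] == 2020).astype(float)

    ages = df["age_months"].to_numpy(dtype=float)
    for name in list(dataset.hmo_names):
        z = standardize(df[f"{name}_mgL"].to_numpy(dtype=float))
        if config.residualize_age:
            z = residualize_on_age(z, ages)
        df[f"z_{name}"] = z
    for sp in retained:
        z = standardize(df[f"ra_{sp}"].to_numpy(dtype=float))
        if config.residualize_age:
            z = residualize_on_age(z, ages)
        df[f"z_{sp}"] = z

    return PreparedData(frame=df, retained_species=retained,
                        outlier_report=report)


def _term_frequencies(design, stability) -> dict[str, float]:
    """Per-term stability frequency: mains from their singleton group,
    interactions from their triple group."""
    freq = {}
    for g, name in enumerate(stability.group_names):
        freq[name] = float(stability.frequencies[g])
    return freq


def _analyze_combination(prepared: PreparedData, outcome: str, strat: str,
                         lasso: LassoSettings, rng: np.random.Generator) -> dict:
    spec = ModelSpec(outcome=outcome, stratification=strat,
                     species_names=tuple(prepared.retained_species))
    design = build_design(prepared.frame, spec)
    structure = build_groups(design)
    t0 = time.perf_counter()
    stability = stability_select(
        design.X, design.y, structure, design.subject_ids,
        reps=lasso.reps, k=lasso.k_folds, rng=rng,
        freq_cutoff=lasso.freq_cutoff, n_lambdas=lasso.n_lambdas,
        lambda_min_ratio=lasso.lambda_min_ratio, tol=lasso.tol,
        max_iter=lasso.max_iter)
    logger.info("%s/%s: selection took %.1fs, fallback=%s", outcome, strat,
                time.perf_counter() - t0, stability.fallback_used)

    keep = sorted(set(int(j) for j, p in enumerate(design.penalized) if not p)
                  | {int(c) for g in stability.final_groups
                     for c in structure.group_columns[g]})
    X_sel = design.X[:, keep]
    names = [design.columns[j] for j in keep]
    roles = [design.roles[j] for j in keep]
    fit = fit_lmm_reml(X_sel, design.y, design.subject_ids, columns=names)
    table = wald_tests(fit, roles=roles)
    freqs = _term_frequencies(design, stability)
    table["selection_frequency"] = [freqs.get(t, np.nan) for t in table["term"]]

    return {
        "table": table,
        "selection_frequencies": freqs,
        "fallback_used": stability.fallback_used,
        "lambdas": stability.lambdas.tolist(),
        "sigma_b": float(np.sqrt(fit.sigma_b2)),
        "sigma_resid": float(np.sqrt(fit.sigma2)),
        "n_obs": fit.n_obs,
        "n_subjects": fit.n_subjects,
        "n_dropped_rows": len(design.dropped),
    }


def run_analysis(config: RunConfig, dataset: Dataset | None = None) -> ResultsBundle:
    """Run selection + mixed-model inference for every outcome x stratification.

    A failing combination is logged and skipped; the run raises only if every
    combination fails.  ``dataset`` may be passed directly (e.g. an in-memory
    simulated cohort); otherwise it is read from ``config.input_path`` or
    simulated from ``config.simulate``.
    """
    if dataset is None:
        if config.input_path is not None:
            from .dataio import read_dataset
            dataset = read_dataset(config.input_path)
        else:
            from .dataio import dataset_from_samples
            from .synthdata import generate_cohort
            dataset = dataset_from_samples(generate_cohort(config.simulate))

    prepared = prepare(dataset, config.preprocess)
    bundle = ResultsBundle(outcomes=tuple(config.outcomes),
                           stratifications=tuple(config.stratifications))
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.outcomes) * len(config.stratifications))
    errors = {}
    k = 0
    for outcome in config.outcomes:
        for strat in config.stratifications:
            rng = np.random.default_rng(children[k])
            k += 1
            try:
                bundle.results[(outcome, strat)] = _analyze_combination(
                    prepared, outcome, strat, config.lasso, rng)
            except Exception as exc:  # noqa: BLE001 - isolate combinations
                logger.error("%s/%s failed: %s", outcome, strat, exc)
                errors[(outcome, strat)] = str(exc)
    if not bundle.results:
        raise RuntimeError(f"all combinations failed: {errors}")

    cfg_dict = {
        "preprocess": dataclasses.asdict(config.preprocess),
        "lasso": dataclasses.asdict(config.lasso),
        "outcomes": list(config.outcomes),
        "stratifications": list(config.stratifications),
        "input_path": config.input_path,
        "seed": config.seed,
    }
    bundle.outcomes = tuple(o for o in config.outcomes
                            if any(o == oo for (oo, _) in bundle.results))
    bundle.stratifications = tuple(s for s in config.stratifications
                                   if any(s == ss_ for (_, ss_) in bundle.results))
    bundle.provenance = {
        "outlier_flags": prepared.outlier_report.to_frame().to_dict("records"),
        "seed": config.seed,
        "config_hash": config_hash(cfg_dict),
        "software_version": __version__,
        "retained_species": prepared.retained_species,
        "freq_cutoff": config.lasso.freq_cutoff,
        "reps": config.lasso.reps,
        "fold_assignment": "by_subject",
        "aggregation": "selection frequency >= cutoff over repetitions",
        "errors": {f"{o}/{s}": m for (o, s), m in errors.items()},
    }
    return bundle


def make_report(bundle: ResultsBundle, out_dir) -> list:
    """Write full result tables plus a significance summary.

    The summary lists every non-intercept term with p < 0.05, its outcome,
    stratification, role, effect size and sign — a tabular counterpart of a
    colored significance matrix.
    """
    from pathlib import Path
    paths = write_results(bundle, out_dir)
    flags = bundle.provenance.get("outlier_flags")
    if flags is not None:
        opath = Path(out_dir) / "outlier_report.tsv"
        pd.DataFrame(flags, columns=["variable", "row", "median",
                                     "left_mad", "right_mad"]
                     ).to_csv(opath, sep="\t", index=False)
        paths.append(opath)
    rows = []
    for (outcome, strat), entry in sorted(bundle.results.items()):
        t = entry["table"]
        sig = t[(t["p"] < 0.05) & (t["term"] != "intercept")]
        for _, r in sig.iterrows():
            rows.append(dict(outcome=outcome, stratification=strat,
                             term=r["term"], role=r["role"],
                             effect_size=r["effect_size"],
                             sign="+" if r["effect_size"] > 0 else "-",
                             p=r["p"]))
    summary = pd.DataFrame(
        rows, columns=["outcome", "stratification", "term", "role",
                       "effect_size", "sign", "p"])
    path = Path(out_dir) / "significance_summary.tsv"
    summary.to_csv(path, sep="\t", index=False)
    paths.append(path)
    return paths
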