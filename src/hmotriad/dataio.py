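"""Reading and writing cohort tables, configuration and results.

The on-disk cohort format is a long-format TSV with one row per mother-infant
visit: metadata columns, eight HMO concentration columns suffixed ``_mgL``,
relative-abundance columns prefixed ``ra_``, and six MSEL score columns
prefixed ``msel_``.  Missing values are empty cells ("NA" also accepted on
read).  Results are written as one TSV per outcome x stratification plus a
single provenance JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import (HMO_NAMES, MSEL_OUTCOMES, Cohort, DyadSample,
                        SPECIES_NAMES)

__all__ = ["Dataset", "ResultsBundle", "SchemaError",
           "dataset_from_samples", "read_dataset", "write_dataset",
           "write_results", "read_result_table"]

METADATA_COLUMNS = ("subject_id", "visit_index", "age_months", "sex",
                    "delivery", "maternal_education", "site", "batch_year")
HMO_COLUMNS = tuple(f"{h}_mgL" for h in HMO_NAMES)
MSEL_COLUMNS = tuple(f"msel_{o}" for o in MSEL_OUTCOMES)

RESULT_COLUMNS = ("term", "role", "effect_size", "se", "t", "p",
                  "selection_frequency")


class SchemaError(ValueError):
    """A required column is missing or a cell fails validation."""


@dataclass
class Dataset:
    """A cohort table plus column metadata.

    ``species_names`` are the bare species identifiers (``ra_`` prefix
    stripped); the remainder bucket ``ra_other``, when present, is carried in
    the frame but is not a species column.
    """

    df: pd.DataFrame
    hmo_names: tuple[str, ...] = HMO_NAMES
    species_names: tuple[str, ...] = ()

    def __post_init__(self):
        dup = self.df.duplicated(subset=["subject_id", "visit_index"])
        if dup.any():
            pair = self.df.loc[dup.idxmax(), ["subject_id", "visit_index"]]
            raise SchemaError(
                f"duplicate (subject_id, visit_index): {tuple(pair)}")
        if not self.species_names:
            raise SchemaError("dataset needs at least one species column")

    @property
    def species_columns(self) -> list[str]:
        return [f"ra_{s}" for s in self.species_names]

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()


def dataset_from_samples(samples) -> Dataset:
    """Build a :class:`Dataset` from generated :class:`DyadSample` records."""
    if isinstance(samples, Cohort):
        samples = samples.samples
    rows = []
    for s in samples:
        if not isinstance(s, DyadSample):
            raise TypeError(f"expected DyadSample, got {type(s).__name__}")
        row = dict(subject_id=s.subject_id, visit_index=s.visit_index,
                   age_months=s.age_months, sex=s.sex, delivery=s.delivery,
                   maternal_education=s.maternal_education, site=s.site,
                   batch_year=s.batch_year)
        for h in HMO_NAMES:
            row[f"{h}_mgL"] = s.hmo[h]
        for sp in SPECIES_NAMES:
            row[f"ra_{sp}"] = s.microbiota[sp]
        row["ra_other"] = s.microbiota.remainder
        for o in MSEL_OUTCOMES:
            row[f"msel_{o}"] = s.msel[o]
        rows.append(row)
    cols = (list(METADATA_COLUMNS) + list(HMO_COLUMNS)
            + [f"ra_{sp}" for sp in SPECIES_NAMES] + ["ra_other"]
            + list(MSEL_COLUMNS))
    df = pd.DataFrame(rows, columns=cols)
    return Dataset(df=df, species_names=SPECIES_NAMES)


def _validate_numeric(df: pd.DataFrame, col: str, lo=None, hi=None) -> pd.Series:
    raw = df[col]
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"column {col!r}: non-numeric value {raw.iloc[row]!r} at data row {row}")
    if lo is not None or hi is not None:
        out = num.dropna()
        if lo is not None and (out < lo).any():
            row = int(np.flatnonzero((num < lo).fillna(False))[0])
            raise SchemaError(
                f"column {col!r}: value {num.iloc[row]} at data row {row} "
                f"below {lo}")
        if hi is not None and (out > hi).any():
            row = int(np.flatnonzero((num > hi).fillna(False))[0])
            raise SchemaError(
                f"column {col!r}: value {num.iloc[row]} at data row {row} "
                f"above {hi}")
    return num


def read_dataset(path) -> Dataset:
    """Read and validate a cohort TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str},
                     na_values=["", "NA"], keep_default_na=False,
                     float_precision="round_trip")
    missing = [c for c in METADATA_COLUMNS + HMO_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    ra_cols = [c for c in df.columns if c.startswith("ra_") and c != "ra_other"]
    if not ra_cols:
        raise SchemaError("no species columns (prefix 'ra_') found")
    df["visit_index"] = _validate_numeric(df, "visit_index").astype("Int64")
    df["age_months"] = _validate_numeric(df, "age_months", lo=0.0)
    df["batch_year"] = _validate_numeric(df, "batch_year").astype("Int64")
    for c in HMO_COLUMNS:
        df[c] = _validate_numeric(df, c, lo=0.0)
    for c in ra_cols + (["ra_other"] if "ra_other" in df.columns else []):
        df[c] = _validate_numeric(df, c, lo=0.0, hi=1.0)
    for c in MSEL_COLUMNS:
        if c in df.columns:
            df[c] = _validate_numeric(df, c)
    species = tuple(c[len("ra_"):] for c in ra_cols)
    return Dataset(df=df, species_names=species)


def write_dataset(dataset: Dataset, path) -> None:
    """Write the cohort as UTF-8 TSV with a deterministic column order.

    Floats are serialized with ``repr``-faithful precision so a read/write
    round trip reproduces values exactly.
    """
    ordered = (list(METADATA_COLUMNS) + list(HMO_COLUMNS)
               + dataset.species_columns
               + (["ra_other"] if "ra_other" in dataset.df.columns else [])
               + [c for c in MSEL_COLUMNS if c in dataset.df.columns])
    extra = [c for c in dataset.df.columns if c not in ordered]
    dataset.df[ordered + extra].to_csv(path, sep="\t", index=False,
                                       encoding="utf-8", na_rep="")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class ResultsBundle:
    """Fitted results keyed by (outcome, stratification).

    Each entry is a dict with keys ``table`` (DataFrame with RESULT_COLUMNS),
    ``selection_frequencies`` (group name -> frequency), ``fallback_used``,
    ``sigma_b``, ``sigma_resid``, ``n_obs``, ``n_subjects``.
    """

    results: dict[tuple[str, str], dict] = field(default_factory=dict)
    outcomes: tuple[str, ...] = ()
    stratifications: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    def missing_combinations(self) -> list[tuple[str, str]]:
        return [(o, s) for o in self.outcomes for s in self.stratifications
                if (o, s) not in self.results]


def config_hash(config_obj) -> str:
    """Stable SHA-256 of a JSON-serializable configuration mapping."""
    blob = json.dumps(config_obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_results(bundle: ResultsBundle, out_dir) -> list[Path]:
    """Write one TSV per outcome x stratification plus ``provenance.json``."""
    missing = bundle.missing_combinations()
    if missing:
        raise ValueError(f"results bundle incomplete; missing {missing}")
    if not bundle.provenance.get("seed") and bundle.provenance.get("seed") != 0:
        raise ValueError("provenance must record the seed")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for (outcome, strat), entry in sorted(bundle.results.items()):
        table = entry["table"]
        bad = [c for c in RESULT_COLUMNS if c not in table.columns]
        if bad:
            raise ValueError(f"result table {outcome}/{strat} lacks {bad}")
        path = out / f"results_{outcome}_{strat}.tsv"
        table.loc[:, list(RESULT_COLUMNS)].to_csv(path, sep="\t", index=False)
        written.append(path)
    prov = dict(bundle.provenance)
    prov["combinations"] = [
        {"outcome": o, "stratification": s,
         "fallback_used": bool(bundle.results[(o, s)].get("fallback_used")),
         "sigma_b": bundle.results[(o, s)].get("sigma_b"),
         "sigma_resid": bundle.results[(o, s)].get("sigma_resid"),
         "n_obs": bundle.results[(o, s)].get("n_obs"),
         "n_subjects": bundle.results[(o, s)].get("n_subjects")}
        for (o, s) in sorted(bundle.results)]
    jpath = out / "provenance.json"
    jpath.write_text(json.dumps(prov, indent=2, sort_keys=True, default=str))
    written.append(jpath)
    return written


def read_result_table(path) -> pd.DataFrame:
    """Re-parse a written results TSV (round-trip helper)."""
    return pd.read_csv(path, sep="\t")
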