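"""Data preparation: outlier handling, species filtering, standardization.

Implements the preparation steps the association analysis assumes:

* double-MAD outlier scoring of per-species relative abundances (separate
  median absolute deviations below and above the median, suited to the
  skewed abundance distributions),
* retention of species whose relative abundance summed over all samples
  exceeds a threshold (default 1.0, strict inequality),
* z-standardization of HMO and abundance predictors over all included
  samples,
* optional residualization of predictors on infant age (ordinary least
  squares; MSEL T-scores are already age-normed and are left untouched),
* A-tetra detectability and secretor-status classification of milk samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import ATETRA_LOD_MGL, HMOProfile

__all__ = [
    "PreprocessConfig",
    "OutlierReport",
    "double_mad_scores",
    "flag_outliers",
    "apply_outlier_policy",
    "filter_species",
    "standardize",
    "residualize_on_age",
    "atetra_status",
    "classify_secretor",
]

#: 2'-FL/3-FL ratio above which milk is classified secretor-positive.
SECRETOR_RATIO_CUTOFF = 6.5827
#: 2'-FL concentration (mg/L) below which milk is classified non-secretor.
SECRETOR_2FL_CUTOFF_MGL = 15.0


@dataclass(frozen=True)
class PreprocessConfig:
    mad_threshold: float = 3.0
    species_sum_threshold: float = 1.0
    atetra_lod_mgl: float = ATETRA_LOD_MGL
    residualize_age: bool = True
    outlier_policy: str = "set_missing"  # set_missing | winsorize | keep

    def __post_init__(self):
        if self.mad_threshold <= 0:
            raise ValueError(f"mad_threshold must be > 0, got {self.mad_threshold}")
        if self.atetra_lod_mgl <= 0:
            raise ValueError(f"atetra_lod_mgl must be > 0, got {self.atetra_lod_mgl}")
        if self.outlier_policy not in ("set_missing", "winsorize", "keep"):
            raise ValueError(f"unknown outlier_policy {self.outlier_policy!r}")


@dataclass
class OutlierReport:
    """Per-variable double-MAD diagnostics and flagged row indices."""

    flagged: dict[str, list] = field(default_factory=dict)
    median: dict[str, float] = field(default_factory=dict)
    left_mad: dict[str, float] = field(default_factory=dict)
    right_mad: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var in self.median:
            for idx in self.flagged.get(var, []):
                rows.append(dict(variable=var, row=idx,
                                 median=self.median[var],
                                 left_mad=self.left_mad[var],
                                 right_mad=self.right_mad[var]))
        return pd.DataFrame(rows, columns=["variable", "row", "median",
                                           "left_mad", "right_mad"])


def _double_mad(x: np.ndarray) -> tuple[float, float, float]:
    m = float(np.median(x))
    # values equal to the median contribute to both sides, keeping each
    # side-MAD defined even in heavily tied series
    left = float(np.median(np.abs(x[x <= m] - m)))
    right = float(np.median(np.abs(x[x >= m] - m)))
    return m, left, right


def double_mad_scores(values) -> np.ndarray:
    """Asymmetric outlier scores: |x - median| / side-MAD.

    The side-MAD is the median absolute deviation computed over the values on
    the same side of the median as ``x`` (ties included on both sides).  The
    median itself scores 0; when a side-MAD is 0 any deviation on that side
    scores +inf.  Missing values score NaN.  No consistency constant is
    applied: scores are in raw MAD units.
    """
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 3:
        raise ValueError("double_mad_scores requires >= 3 non-missing values")
    m, left, right = _double_mad(x[ok])
    scores = np.full(x.shape, np.nan)
    dev = np.abs(x[ok] - m)
    side = np.where(x[ok] < m, left, right)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = dev / side
    s[dev == 0] = 0.0
    s[(side == 0) & (dev > 0)] = np.inf
    scores[ok] = s
    return scores


def flag_outliers(values, threshold: float = 3.0) -> np.ndarray:
    """Boolean mask of values whose double-MAD score exceeds ``threshold``."""
    scores = double_mad_scores(values)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(scores, nan=0.0) > threshold


def apply_outlier_policy(values, threshold: float = 3.0,
                         policy: str = "set_missing") -> tuple[np.ndarray, np.ndarray]:
    """Flag outliers and apply the configured policy.

    Returns ``(cleaned, flags)``.  Policies: ``set_missing`` replaces flagged
    values with NaN; ``winsorize`` clips them to median +/- threshold *
    side-MAD; ``keep`` leaves values untouched (flags still reported).
    """
    x = np.asarray(values, dtype=float).copy()
    flags = flag_outliers(x, threshold)
    if policy == "keep" or not flags.any():
        return x, flags
    if policy == "set_missing":
        x[flags] = np.nan
        return x, flags
    if policy == "winsorize":
        ok = ~np.isnan(x)
        m, left, right = _double_mad(np.asarray(values, dtype=float)[ok])
        lo, hi = m - threshold * left, m + threshold * right
        x[flags & (x < m)] = lo
        x[flags & (x > m)] = hi
        return x, flags
    raise ValueError(f"unknown outlier policy {policy!r}")


def filter_species(abundance: pd.DataFrame, sum_threshold: float = 1.0) -> list[str]:
    """Species whose abundance summed over all samples exceeds the threshold.

    The inequality is strict (a total of exactly ``sum_threshold`` drops the
    species); column order is preserved.  Missing values are ignored in the
    sums.
    """
    if abundance.shape[0] == 0 or abundance.shape[1] == 0:
        raise ValueError("abundance table must be non-empty")
    arr = abundance.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise ValueError("relative abundances must lie in [0, 1]")
    sums = np.nansum(arr, axis=0)
    return [c for c, s in zip(abundance.columns, sums) if s > sum_threshold]


def standardize(values) -> np.ndarray:
    """z-scores with mean 0 and sample SD 1 over the non-missing entries."""
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    vals = x[ok]
    if np.unique(vals).size < 2:
        raise ValueError("standardize requires >= 2 distinct non-missing values")
    mu = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    out = np.full(x.shape, np.nan)
    out[ok] = (vals - mu) / sd
    return out


def residualize_on_age(values, ages) -> np.ndarray:
    """Residuals of ``values`` after OLS on [1, age]; missing stays missing."""
    x = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if x.shape != a.shape:
        raise ValueError("values and ages must have the same length")
    ok = ~np.isnan(x) & ~np.isnan(a)
    if ok.sum() < 3:
        raise ValueError("residualize_on_age requires >= 3 paired values")
    if np.unique(a[ok]).size < 2:
        raise ValueError("ages are constant; age slope is not identifiable")
    A = np.column_stack([np.ones(ok.sum()), a[ok]])
    coef, *_ = np.linalg.lstsq(A, x[ok], rcond=None)
    out = np.full(x.shape, np.nan)
    out[ok] = x[ok] - A @ coef
    return out


def atetra_status(hmo, lod: float = ATETRA_LOD_MGL) -> str:
    """``"positive"`` iff the milk A-tetra concentration strictly exceeds the LOD."""
    conc = hmo["atetra"] if isinstance(hmo, (HMOProfile, dict, pd.Series)) else hmo
    if conc is None or (isinstance(conc, float) and np.isnan(conc)):
        raise ValueError("A-tetra concentration is missing")
    return "positive" if conc > lod else "negative"


def classify_secretor(hmo, rule: str = "ratio") -> str:
    """Classify maternal secretor status from milk 2'-FL (and 3-FL).

    ``rule="ratio"``: secretor iff 2'-FL/3-FL > 6.5827.
    ``rule="threshold"``: non-secretor iff 2'-FL < 15 mg/L.
    """
    fl2 = hmo["2fl"]
    if fl2 is None or np.isnan(fl2):
        raise ValueError("2'-FL concentration is missing")
    if rule == "ratio":
        fl3 = hmo["3fl"]
        if fl3 is None or np.isnan(fl3):
            raise ValueError("3'-FL concentration is missing")
        if fl3 == 0:
            raise ValueError("3-FL is 0; the 2'-FL/3-FL ratio rule is undefined")
        return "secretor" if fl2 / fl3 > SECRETOR_RATIO_CUTOFF else "non_secretor"
    if rule == "threshold":
        return "non_secretor" if fl2 < SECRETOR_2FL_CUTOFF_MGL else "secretor"
    raise ValueError(f"unknown secretor rule {rule!r}")
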