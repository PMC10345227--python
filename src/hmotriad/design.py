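"""Fixed-effects design construction for the three model families.

The association model regresses one MSEL score on adjusting covariates,
eight standardized HMO concentrations, the standardized relative abundances
of the retained species, and all HMO x species products:

    score = b0 + b1'covariates + b2'HMO + b3'MB + g'(HMO x MB) + e

Three variants are built: unstratified; A-tetra+ stratified, where HMO and
interaction columns are zero-masked on visits whose milk had undetectable
A-tetra and an I(A-tetra-) indicator is added; and the mirror-image A-tetra-
stratified model.  Zero-masking (rather than row dropping) keeps microbiota
main effects estimated from all infants, with the indicator absorbing the
stratum mean shift.

Penalized-group construction encodes the interaction hierarchy: each
interaction can only enter the model through a latent group that also
carries both of its parent main effects (latent overlapping group LASSO).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grouplasso import GroupStructure
from .synthdata import COVARIATE_NAMES, HMO_NAMES, MSEL_OUTCOMES

__all__ = ["ModelSpec", "DesignMatrix", "build_design", "build_groups"]

STRATIFICATIONS = ("unstratified", "atetra_pos", "atetra_neg")


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    stratification: str = "unstratified"
    hmo_names: tuple[str, ...] = HMO_NAMES
    species_names: tuple[str, ...] = ()
    covariates: tuple[str, ...] = COVARIATE_NAMES

    def __post_init__(self):
        if self.outcome not in MSEL_OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.stratification not in STRATIFICATIONS:
            raise ValueError(f"unknown stratification {self.stratification!r}")
        if not self.species_names:
            raise ValueError("ModelSpec requires at least one retained species")


@dataclass
class DesignMatrix:
    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    roles: list[str]  # intercept | covariate | hmo_main | mb_main | interaction | indicator
    subject_ids: np.ndarray
    penalized: np.ndarray  # bool per column
    spec: ModelSpec
    dropped: list[tuple] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.y.size

    def columns_with_role(self, role: str) -> list[int]:
        return [j for j, r in enumerate(self.roles) if r == role]


def build_design(prepared: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Assemble y and X from a prepared cohort frame.

    ``prepared`` must carry the covariate dummy columns, standardized
    predictors ``z_<hmo>`` / ``z_<species>``, the per-visit stratum flag
    ``atetra_pos`` (0/1), ``subject_id``, ``visit_index`` and the outcome
    column ``msel_<outcome>``.  Rows with a missing required value are
    excluded and recorded in ``dropped``.
    """
    ycol = f"msel_{spec.outcome}"
    needed = ([ycol, "subject_id", "visit_index", "atetra_pos"]
              + list(spec.covariates)
              + [f"z_{h}" for h in spec.hmo_names]
              + [f"z_{s}" for s in spec.species_names])
    missing_cols = [c for c in needed if c not in prepared.columns]
    if missing_cols:
        raise ValueError(f"prepared frame lacks columns {missing_cols}")

    in_stratum = np.ones(len(prepared), dtype=bool)
    pos = prepared["atetra_pos"].to_numpy(dtype=float) > 0.5
    if spec.stratification == "atetra_pos":
        in_stratum = pos
    elif spec.stratification == "atetra_neg":
        in_stratum = ~pos
    if spec.stratification != "unstratified" and not in_stratum.any():
        raise ValueError(f"stratum {spec.stratification!r} is empty")

    # required-value missingness: HMO values only matter where unmasked
    req = prepared[[ycol] + list(spec.covariates)
                   + [f"z_{s}" for s in spec.species_names]].isna().any(axis=1)
    hmo_na = prepared[[f"z_{h}" for h in spec.hmo_names]].isna().any(axis=1)
    req |= hmo_na & in_stratum
    keep = ~req.to_numpy()
    dropped = [tuple(t) for t in
               prepared.loc[~keep, ["subject_id", "visit_index"]].itertuples(index=False)]
    sub = prepared.loc[keep]
    in_stratum = in_stratum[keep]
    if spec.stratification != "unstratified" and not in_stratum.any():
        raise ValueError(
            f"stratum {spec.stratification!r} is empty after exclusions")

    n = len(sub)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    roles: list[str] = ["intercept"]
    for c in spec.covariates:
        cols.append(sub[c].to_numpy(dtype=float))
        names.append(c)
        roles.append("covariate")
    mask = in_stratum.astype(float)
    hmo_vals = {}
    for h in spec.hmo_names:
        v = sub[f"z_{h}"].to_numpy(dtype=float)
        if spec.stratification != "unstratified":
            v = np.where(in_stratum, v, 0.0)
        hmo_vals[h] = v
        cols.append(v)
        names.append(h)
        roles.append("hmo_main")
    mb_vals = {}
    for s in spec.species_names:
        v = sub[f"z_{s}"].to_numpy(dtype=float)
        mb_vals[s] = v
        cols.append(v)
        names.append(s)
        roles.append("mb_main")
    for h in spec.hmo_names:
        for s in spec.species_names:
            cols.append(hmo_vals[h] * mb_vals[s])
            names.append(f"{h}:{s}")
            roles.append("interaction")
    if spec.stratification == "atetra_pos":
        cols.append(1.0 - mask)  # I(A-tetra-)
        names.append("i_atetra_neg")
        roles.append("indicator")
    elif spec.stratification == "atetra_neg":
        cols.append(1.0 - mask)  # I(A-tetra+)
        names.append("i_atetra_pos")
        roles.append("indicator")

    X = np.column_stack(cols)
    penalized = np.array([r in ("hmo_main", "mb_main", "interaction")
                          for r in roles])
    return DesignMatrix(y=sub[ycol].to_numpy(dtype=float), X=X,
                        columns=names, roles=roles,
                        subject_ids=sub["subject_id"].to_numpy(),
                        penalized=penalized, spec=spec, dropped=dropped)


def build_groups(design: DesignMatrix) -> GroupStructure:
    """Latent-overlap penalized groups encoding the interaction hierarchy.

    One singleton group per HMO main, one per species main, and one triple
    {HMO_j, MB_k, HMO_j x MB_k} per interaction.  Group weight is
    sqrt(group size).  Intercept, covariates and the stratum indicator stay
    unpenalized.
    """
    colidx = {name: j for j, name in enumerate(design.columns)}
    unpen = [j for j, p in enumerate(design.penalized) if not p]

    groups: list[np.ndarray] = []
    names: list[str] = []
    kinds: list[str] = []
    for j, (name, role) in enumerate(zip(design.columns, design.roles)):
        if role == "hmo_main":
            groups.append(np.array([j]))
            names.append(name)
            kinds.append("hmo")
        elif role == "mb_main":
            groups.append(np.array([j]))
            names.append(name)
            kinds.append("mb")
    for j, (name, role) in enumerate(zip(design.columns, design.roles)):
        if role != "interaction":
            continue
        h, s = name.split(":")
        if h not in colidx or s not in colidx:
            raise ValueError(
                f"interaction {name!r} lacks parent main-effect column(s)")
        groups.append(np.array([colidx[h], colidx[s], j]))
        names.append(name)
        kinds.append("interaction")
    return GroupStructure(
        n_columns=len(design.columns),
        unpenalized_columns=np.array(unpen, dtype=int),
        group_columns=groups,
        group_names=names,
        group_kinds=kinds,
    )
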