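"""Longitudinal change-trait derivation.

With exactly two visits per subject, a per-subject growth-curve slope reduces
to the annualised difference (y2 - y1) / (t2 - t1); the raw difference is kept
as an alternative mode for replication-style analyses.  The derived trait is
adjusted for covariates by ordinary least squares and then rank-based
inverse-normal (Blom) transformed; familial correlation is handled downstream
by the genetic models, not here.  The pipeline order derive -> adjust ->
transform is fixed and recorded in the output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "derive_delta",
    "derive_delta_table",
    "adjust_covariates",
    "blom_transform",
    "derive_adjusted_trait",
    "AdjustedTrait",
]

DELTA_MODES = ("annualized_slope", "raw_difference")


def derive_delta(y1, y2, t1, t2, mode: str = "annualized_slope"):
    """Per-subject change in a trait between two visits.

    annualized_slope: (y2 - y1) / (t2 - t1), trait units per year.
    raw_difference:   y2 - y1.
    Accepts scalars or aligned arrays; a non-positive time gap is an error.
    """
    if mode not in DELTA_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {DELTA_MODES}")
    y1, y2 = np.asarray(y1, dtype=float), np.asarray(y2, dtype=float)
    t1, t2 = np.asarray(t1, dtype=float), np.asarray(t2, dtype=float)
    gap = t2 - t1
    if np.any(gap <= 0):
        raise ValueError("visit-2 time must exceed visit-1 time")
    diff = y2 - y1
    return diff / gap if mode == "annualized_slope" else diff


def derive_delta_table(pheno: pd.DataFrame, mode: str = "annualized_slope") -> pd.DataFrame:
    """Derive the change trait from a long-format two-visit table.

    ``pheno`` needs columns id, visit (1 or 2), trait, time; subjects missing
    either visit are dropped with a log entry.  Returns a frame indexed by id
    with column raw_slope.
    """
    wide = pheno.pivot(index="id", columns="visit", values=["trait", "time"])
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        logger.info("derive_delta: dropped %d subjects missing a visit", len(dropped))
    out = pd.DataFrame(index=complete.index)
    out["raw_slope"] = derive_delta(
        complete[("trait", 1)],
        complete[("trait", 2)],
        complete[("time", 1)],
        complete[("time", 2)],
        mode=mode,
    )
    out.attrs["mode"] = mode
    return out


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariates, with categorical columns expanded to
    indicator contrasts (first level dropped)."""
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        s = covariates[col]
        if s.nunique(dropna=False) <= 1:
            logger.info("covariate %r is constant; absorbed by the intercept", col)
            continue
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.extend(dummies[c] for c in dummies.columns)
        else:
            parts.append(s.astype(float))
    design = pd.concat(parts, axis=1)
    return design.to_numpy(dtype=float), list(design.columns)


def adjust_covariates(
    values: pd.Series, covariates: pd.DataFrame
) -> tuple[pd.Series, list[str]]:
    """OLS residuals of ``values`` on intercept + covariates.

    Subjects with any missing covariate are dropped (returned in the second
    element); a rank-deficient design raises, naming the collinear columns.
    Residuals have mean zero by construction.
    """
    covariates = covariates.loc[values.index]
    complete = covariates.dropna().index.intersection(values.dropna().index)
    dropped = sorted(set(values.index) - set(complete))
    if dropped:
        logger.info("adjust_covariates: dropped %d subjects with missing data", len(dropped))
    y = values.loc[complete].to_numpy(dtype=float)
    X, names = _design_matrix(covariates.loc[complete])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(resid, index=complete, name="adjusted"), dropped


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad, kept = [], []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(names[j])
    return bad


def blom_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    transformed_i = Phi^-1((r_i - 3/8) / (n + 1/4)) where r_i is the average
    rank of value i (ties share their average rank).  Raises when all values
    are identical, where the transform is degenerate.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-d array with n >= 2")
    if np.any(np.isnan(x)):
        raise ValueError("missing values not allowed in blom_transform")
    if np.ptp(x) == 0:
        raise ValueError("all values identical; transform degenerate")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


@dataclass
class AdjustedTrait:
    """Derived, adjusted and transformed change trait with provenance."""

    table: pd.DataFrame  # index id; columns raw_slope, adjusted, transformed
    mode: str
    covariates: list[str]
    n_dropped: int

    def metadata(self) -> dict:
        return {
            "mode": self.mode,
            "covariates": self.covariates,
            "n": int(len(self.table)),
            "n_dropped": int(self.n_dropped),
            "order": ["derive", "adjust", "transform"],
        }


def derive_adjusted_trait(
    pheno: pd.DataFrame,
    covariate_cols: list[str],
    mode: str = "annualized_slope",
    visit_for_covariates: int = 1,
) -> AdjustedTrait:
    """Full trait pipeline: derive the change, adjust, Blom-transform.

    Covariates are taken from the requested visit (baseline by default).
    The stage order is fixed; it is logged and recorded in the result.
    """
    logger.info("trait pipeline order: derive -> adjust -> transform (mode=%s)", mode)
    slopes = derive_delta_table(pheno, mode=mode)
    cov = (
        pheno.loc[pheno["visit"] == visit_for_covariates]
        .set_index("id")
        .reindex(slopes.index)[covariate_cols]
    )
    adjusted, dropped = adjust_covariates(slopes["raw_slope"], cov)
    transformed = blom_transform(adjusted.to_numpy())
    table = pd.DataFrame(
        {
            "raw_slope": slopes["raw_slope"].loc[adjusted.index],
            "adjusted": adjusted,
            "transformed": transformed,
        }
    )
    return AdjustedTrait(
        table=table, mode=mode, covariates=list(covariate_cols), n_dropped=len(dropped)
    )
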