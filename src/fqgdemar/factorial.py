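"""Per-probe statistics of the 2x2 (age x sex) factorial design.

All statistics are median-based and computed on the log2 scale, probe by
probe — there is no probe-set summarization anywhere in the pipeline. With
A+ = Older, A- = Younger, B+ = Women, B- = Men and M(cell) the median log2
intensity of a design cell:

* interaction effect = 0.5 * [(M(A+B+) + M(A-B-)) - (M(A+B-) + M(A-B+))],
  a half-contrast of medians measuring non-additivity of age and sex;
* super-ratio = Age Ratio(females) / Age Ratio(males)
              = (M(A+B+)/M(A-B+)) / (M(A+B-)/M(A-B-)),
  algebraically identical to Sex Ratio(Older)/Sex Ratio(Younger);
* Super-Ratio* maps super-ratios in (0, 1) to -1/SR so up- and
  down-regulated interactions live on symmetric, sign-coherent branches;
* Age Ratio# and Sex Ratio# are quotients of pooled-group medians (pooling
  ignores the other factor) — the "pure" factor effects.

A generic OLS fit of the bi-linear model mu + alpha*i + beta*j + gamma*i*j
is reported alongside; note the half-contrast of medians and the OLS gamma
are related but distinct quantities and are both kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, StudyDesign

__all__ = [
    "GroupMedians",
    "FactorialModelFit",
    "group_medians",
    "interaction_effect",
    "super_ratio",
    "transform_super_ratio",
    "fit_bilinear",
    "age_ratio_sharp",
    "sex_ratio_sharp",
    "effect_table",
]

CELLS = {"m_pp": (1, 1), "m_pm": (1, -1), "m_mp": (-1, 1), "m_mm": (-1, -1)}
_CELL_NAMES = {
    "m_pp": "A+B+ (Older Women)",
    "m_pm": "A+B- (Older Men)",
    "m_mp": "A-B+ (Younger Women)",
    "m_mm": "A-B- (Younger Men)",
}


@dataclass
class GroupMedians:
    """Per-probe median log2 intensity of each design cell."""

    table: pd.DataFrame  # columns m_pp, m_pm, m_mp, m_mm, indexed by probe


@dataclass
class FactorialModelFit:
    """Per-probe OLS coefficients of the bi-linear model."""

    table: pd.DataFrame  # columns mu, alpha, beta, gamma, residual_scale


def group_medians(matrix: ExpressionMatrix, design: StudyDesign) -> GroupMedians:
    """Median log2 intensity per probe in each of the four design cells."""
    cols = {}
    for name, (i, j) in CELLS.items():
        samples = design.samples_in_cell(i, j)
        if not samples:
            raise ValueError(f"design cell {_CELL_NAMES[name]} has no samples")
        cols[name] = np.median(matrix.values[samples].to_numpy(), axis=1)
    return GroupMedians(table=pd.DataFrame(cols, index=matrix.probe_ids))


def interaction_effect(gm: GroupMedians) -> pd.Series:
    """Half-contrast of cell medians; zero for exactly additive probes."""
    t = gm.table
    return 0.5 * ((t["m_pp"] + t["m_mm"]) - (t["m_pm"] + t["m_mp"])).rename(
        "interaction_effect"
    )


#: Minimum cell median (log2 units) for a probe to enter any ratio
#: statistic. A median at or below this level sits at the array detection
#: floor, where a ratio denominator is numerically meaningless; RMA-scale
#: log2 intensities of expressed probes lie well above 1.
MIN_RATIO_MEDIAN = 1.0


def super_ratio(gm: GroupMedians, min_median: float = MIN_RATIO_MEDIAN) -> pd.DataFrame:
    """Sex-corrected age effect: Age Ratio(females) / Age Ratio(males).

    Probes with any cell median at or below ``min_median`` cannot enter a
    ratio; they are flagged (``excluded`` = True) with NaN statistics rather
    than dropped.
    """
    t = gm.table
    valid = (t > min_median).all(axis=1)
    arf = pd.Series(np.nan, index=t.index, name="age_ratio_f")
    arm = pd.Series(np.nan, index=t.index, name="age_ratio_m")
    arf[valid] = t.loc[valid, "m_pp"] / t.loc[valid, "m_mp"]
    arm[valid] = t.loc[valid, "m_pm"] / t.loc[valid, "m_mm"]
    sr = (arf / arm).rename("super_ratio")
    return pd.DataFrame(
        {
            "age_ratio_f": arf,
            "age_ratio_m": arm,
            "super_ratio": sr,
            "excluded": ~valid,
        }
    )


def transform_super_ratio(sr):
    """Map super-ratios in (0, 1) to -1/SR; values >= 1 pass through.

    The transform is strictly monotone on each branch, so interactions and
    super-ratios keep the same sign. Accepts a scalar or an array/Series;
    NaNs propagate, non-positive values raise.
    """
    arr = np.asarray(sr, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(arr[~np.isnan(arr)] <= 0):
            raise ValueError("super-ratio must be positive")
        out = np.where(arr >= 1, arr, -1.0 / arr)
    if np.isscalar(sr) or np.ndim(sr) == 0:
        return float(out)
    if isinstance(sr, pd.Series):
        return pd.Series(out, index=sr.index, name="super_ratio_star")
    return out


def fit_bilinear(matrix: ExpressionMatrix, design: StudyDesign) -> FactorialModelFit:
    """Per-probe OLS of Y = mu + alpha*i + beta*j + gamma*i*j.

    One design matrix serves all probes, so the solve is a single batched
    least-squares call.
    """
    i = design.table["age_code"].to_numpy(dtype=float)
    j = design.table["sex_code"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(i), i, j, i * j])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient design: every cell of the 2x2 needs samples")
    Y = matrix.values[design.table["sample_id"].tolist()].to_numpy().T  # samples x probes
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = max(X.shape[0] - 4, 1)
    scale = np.sqrt((resid**2).sum(axis=0) / dof)
    table = pd.DataFrame(
        coef.T, index=matrix.probe_ids, columns=["mu", "alpha", "beta", "gamma"]
    )
    table["residual_scale"] = scale
    return FactorialModelFit(table=table)


def _pooled_ratio(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    code_col: str,
    name: str,
    min_median: float = MIN_RATIO_MEDIAN,
) -> pd.Series:
    pos = design.table.loc[design.table[code_col] == 1, "sample_id"].tolist()
    neg = design.table.loc[design.table[code_col] == -1, "sample_id"].tolist()
    if not pos or not neg:
        raise ValueError(f"both pooled groups for {name} must be non-empty")
    m_pos = np.median(matrix.values[pos].to_numpy(), axis=1)
    m_neg = np.median(matrix.values[neg].to_numpy(), axis=1)
    ok = (m_pos > min_median) & (m_neg > min_median)
    ratio = np.where(ok, m_pos / np.where(ok, m_neg, np.nan), np.nan)
    return pd.Series(ratio, index=matrix.probe_ids, name=name)


def age_ratio_sharp(matrix: ExpressionMatrix, design: StudyDesign) -> pd.Series:
    """Pooled Older / pooled Younger median of log2 signal, per probe.

    Values above 1 mean the probe is up-regulated in the Older group.
    """
    return _pooled_ratio(matrix, design, "age_code", "age_ratio_sharp")


def sex_ratio_sharp(matrix: ExpressionMatrix, design: StudyDesign) -> pd.Series:
    """Pooled Women / pooled Men median of log2 signal, per probe."""
    return _pooled_ratio(matrix, design, "sex_code", "sex_ratio_sharp")


def effect_table(matrix: ExpressionMatrix, design: StudyDesign) -> pd.DataFrame:
    """One wide per-probe table with every factorial statistic.

    Columns: gene, the four cell medians, interaction_effect, age_ratio_f/m,
    super_ratio, super_ratio_star, age_ratio_sharp, sex_ratio_sharp, the OLS
    coefficients, and the ratio-exclusion flag.
    """
    gm = group_medians(matrix, design)
    sr = super_ratio(gm)
    fit = fit_bilinear(matrix, design)
    star = pd.Series(np.nan, index=sr.index, name="super_ratio_star")
    ok = sr["super_ratio"].notna()
    star[ok] = transform_super_ratio(sr.loc[ok, "super_ratio"])
    out = pd.concat(
        [
            matrix.annotation.rename("gene"),
            gm.table,
            interaction_effect(gm),
            sr[["age_ratio_f", "age_ratio_m", "super_ratio"]],
            star,
            age_ratio_sharp(matrix, design),
            sex_ratio_sharp(matrix, design),
            fit.table,
            sr["excluded"],
        ],
        axis=1,
    )
    out.index.name = "probe_id"
    return out
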