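"""Post-fit GxE summaries along the environmental gradient.

The genetic variance at an environment x is the quadratic form z' G0 z with
z = (P0(x), P1(x)) = (1, x) — written ZGZ' when stacked over HEG levels.
These per-level variances are averaged within levels of each environmental
category (or within environmental groups), trimmed at +/-2 SD, and compared
with a one-way fixed-effects linear model (least-square means, overall
F-test, pairwise contrasts).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["zgz_gradient", "average_by_level", "trim_and_test"]


def zgz_gradient(
    g0: np.ndarray,
    gradient,
    residual_class_variances=None,
    sigma2_pe: float = 0.0,
    sigma2_cg: float = 0.0,
) -> pd.DataFrame:
    """Genetic variance and sire heritability at every HEG level.

    For each level with scaled covariate x, zgz = [1, x] G0 [1, x]'.  When
    the five residual-class variances are given, the level's heritability is
    h2 = 4 zgz / (zgz + sigma2_pe + sigma2_cg + sigma2_e(class of x)), with
    the residual variance taken from the level's gradient-quantile class.
    Negative quadratic forms (possible only if G0 is not PSD) are clamped to
    zero and flagged.
    """
    g0 = np.asarray(g0, dtype=float)
    if g0.shape != (2, 2):
        raise ValueError("G0 must be 2x2")
    if np.linalg.eigvalsh(g0).min() < -1e-10:
        warnings.warn("G0 is not positive semidefinite; negative variances clamped",
                      stacklevel=2)
    table = gradient.table if hasattr(gradient, "table") else gradient
    x = table["scaled_x"].to_numpy(dtype=float)
    zgz = g0[0, 0] + 2.0 * g0[0, 1] * x + g0[1, 1] * x * x
    clamped = zgz < 0
    zgz = np.clip(zgz, 0.0, None)
    out = pd.DataFrame({
        "heg_level": table["heg_level"].to_numpy(),
        "scaled_x": x,
        "zgz": zgz,
        "clamped": clamped,
    })
    if residual_class_variances is not None:
        rv = np.asarray(residual_class_variances, dtype=float)
        k = rv.size
        qs = np.quantile(x, np.arange(1, k) / k)
        cls = np.searchsorted(qs, x, side="left")
        sigma2_e = rv[cls]
        out["resid_class"] = cls
        out["sigma2_e"] = sigma2_e
        denom = zgz + sigma2_pe + sigma2_cg + sigma2_e
        out["h2_sire"] = np.clip(4.0 * zgz / denom, 0.0, 1.0)
    return out


def _level_map(env_assignment: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Map each HEG level to its grouping level (EC column name or 'EG')."""
    col = "eg_label" if grouping in ("EG", "eg", "eg_label") else grouping
    if col not in env_assignment.columns:
        raise ValueError(f"grouping column {col!r} absent from the assignment")
    if "heg_level" in env_assignment.columns:
        m = env_assignment[["heg_level", col]].drop_duplicates()
    else:
        cols = ["herd_id", "eg_label"] if col == "eg_label" else ["herd_id", "eg_label", col]
        m = env_assignment[cols].copy()
        m["heg_level"] = m["herd_id"].astype(str) + ":" + m["eg_label"].astype(str)
        m = m[["heg_level", col]]
    return m.rename(columns={col: "level"})


def average_by_level(grad_var: pd.DataFrame, env_assignment: pd.DataFrame,
                     grouping: str) -> pd.DataFrame:
    """Arithmetic mean of the per-HEG-level genetic variance within each
    level of the grouping (untrimmed)."""
    merged = grad_var.merge(_level_map(env_assignment, grouping), on="heg_level",
                            how="left")
    if merged["level"].isna().any():
        bad = merged.loc[merged["level"].isna(), "heg_level"].unique()[:5]
        raise ValueError(f"HEG levels without a grouping level: {bad}")
    out = merged.groupby("level", observed=True).agg(
        n=("zgz", "size"), mean_zgz=("zgz", "mean")
    ).reset_index()
    out.insert(0, "grouping", grouping)
    return out


def trim_and_test(grad_var: pd.DataFrame, env_assignment: pd.DataFrame,
                  grouping: str, sd_window: float = 2.0,
                  tukey: bool = False) -> dict:
    """Trim extreme ZGZ' estimates and test level differences with a GLM.

    Estimates outside mean +/- sd_window * SD (mean and SD over all HEG
    levels of the trait) are discarded; a one-way fixed-effects linear model
    of zgz on the grouping level then yields least-square means, the overall
    F-test and pairwise contrasts (unadjusted two-tailed p by default;
    Tukey HSD optionally).
    """
    merged = grad_var.merge(_level_map(env_assignment, grouping), on="heg_level",
                            how="left")
    v = merged["zgz"].to_numpy(dtype=float)
    mu, sd = v.mean(), v.std(ddof=1) if v.size > 1 else 0.0
    keep = np.abs(v - mu) <= sd_window * sd if sd > 0 else np.ones(v.size, bool)
    n_trimmed = int((~keep).sum())
    kept = merged[keep]

    counts = kept.groupby("level", observed=True).size()
    usable = counts[counts >= 2]
    result = {
        "grouping": grouping,
        "n_trimmed": n_trimmed,
        "trim_window": (float(mu - sd_window * sd), float(mu + sd_window * sd)),
        "lsm": None, "f_stat": float("nan"), "df": (0, 0),
        "p_overall": float("nan"), "pairwise": None, "skipped": False,
    }
    if len(usable) < 2:
        warnings.warn("fewer than 2 grouping levels with >= 2 retained estimates; "
                      "GLM test skipped", stacklevel=2)
        result["skipped"] = True
        lsm = kept.groupby("level", observed=True)["zgz"].mean().rename("lsm").reset_index()
        result["lsm"] = lsm
        return result

    sub = kept[kept["level"].isin(usable.index)].copy()
    y = sub["zgz"].to_numpy(dtype=float)
    codes, levels = pd.factorize(sub["level"], sort=True)
    X = np.zeros((len(y), len(levels)))
    X[np.arange(len(y)), codes] = 1.0  # cell-means coding: LSM = cell means
    fit = sm.OLS(y, X).fit()
    lsm_vals = fit.params
    # overall F: all level means equal
    k, n = len(levels), len(y)
    grand = y.mean()
    ssb = sum(((y[codes == i].mean() - grand) ** 2) * (codes == i).sum()
              for i in range(k))
    ssw = sum(((y[codes == i] - y[codes == i].mean()) ** 2).sum() for i in range(k))
    df1, df2 = k - 1, n - k
    msw = ssw / df2 if df2 > 0 else float("nan")
    f_stat = (ssb / df1) / msw if msw > 0 else float("inf")
    p_overall = float(stats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0

    rows = []
    if tukey:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        th = pairwise_tukeyhsd(y, np.asarray(levels)[codes])
        for (g1, g2), p, diff in zip(
            [(r[0], r[1]) for r in th.summary().data[1:]],
            th.pvalues, th.meandiffs,
        ):
            rows.append({"level_a": g1, "level_b": g2, "diff": float(diff),
                         "p": float(p)})
    else:
        for i in range(k):
            for j in range(i + 1, k):
                ni, nj = (codes == i).sum(), (codes == j).sum()
                diff = lsm_vals[i] - lsm_vals[j]
                se = np.sqrt(msw * (1.0 / ni + 1.0 / nj))
                t = diff / se if se > 0 else float("inf")
                p = 2.0 * float(stats.t.sf(abs(t), df2)) if se > 0 else 0.0
                rows.append({"level_a": levels[i], "level_b": levels[j],
                             "diff": float(diff), "t": float(t), "p": p})

    result.update({
        "lsm": pd.DataFrame({"level": levels, "n": [int((codes == i).sum()) for i in range(k)],
                             "lsm": lsm_vals}),
        "f_stat": float(f_stat), "df": (df1, df2), "p_overall": p_overall,
        "pairwise": pd.DataFrame(rows),
    })
    return result
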