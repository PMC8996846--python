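"""Two-step reaction-norm analysis of genotype-by-environment interaction.

Step 1 fits a single-trait (repeatability) animal model whose fixed
herd-environment-group (HEG) solutions define a continuous environmental
gradient.  Step 2 re-fits the data under a random-regression sire model in
which each sire carries an intercept (genetic merit in the average
environment) and a slope on the scaled gradient (environmental sensitivity,
the GxE term), with five residual-variance classes over the gradient.
Downstream helpers compute variance ratios, sire heritability, environment-
specific EBVs, accuracies and re-ranking diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mmecore import (
    GibbsConfig,
    ModelSpec,
    PosteriorSamples,
    RandomTerm,
    gibbs_sample,
    posterior_summary,
    residual_classes,
    scale_covariate,
)
import scipy.sparse as sp

from .pedigree import a_inverse, a_matrix

__all__ = [
    "EnvironmentGradient",
    "ReactionNormFit",
    "fit_step1",
    "fit_reaction_norm",
    "variance_ratios",
    "sire_h2",
    "ebv_at_environment",
    "ebv_accuracy",
    "compare_rankings",
]

N_RESIDUAL_CLASSES = 5


@dataclass
class EnvironmentGradient:
    """Estimated HEG gradient: one row per herd-environment level.

    `table` columns: heg_level, solution (trait units, contrast against the
    reference level), scaled_x in [-1, 1], n_records.  diagnostics holds the
    normality check of the solutions; components the step-1 variance
    summaries; h2 the step-1 animal-model heritability summary.
    """

    table: pd.DataFrame
    diagnostics: dict
    components: dict
    h2: dict

    def x_of(self, heg_level) -> float:
        row = self.table.loc[self.table["heg_level"] == heg_level, "scaled_x"]
        if row.empty:
            raise KeyError(f"unknown HEG level {heg_level!r}")
        return float(row.iloc[0])


@dataclass
class ReactionNormFit:
    """Posterior of the step-2 sire model.

    With GxE the sire term is a random regression with 2x2 covariance G0 =
    [[sigma2_G, cov], [cov, sigma2_GxE]]; without it, a single random sire
    intercept.  Residuals follow five gradient-quantile classes either way.
    """

    samples: PosteriorSamples
    with_gxe: bool
    dataset_kind: str
    gradient: EnvironmentGradient
    sire_ids: np.ndarray
    sire_term: str = "sire"

    @property
    def g0_chain(self) -> np.ndarray:
        if not self.with_gxe:
            raise ValueError("no G0 chain in a fit without the GxE term")
        return self.samples.g0_chains[self.sire_term]

    def sigma2_G_chain(self) -> np.ndarray:
        if self.with_gxe:
            return self.g0_chain[:, 0, 0]
        return self.samples.variance_chains[self.sire_term]

    def g0_mean(self) -> np.ndarray:
        return self.g0_chain.mean(axis=0)

    def component_chains(self) -> dict[str, np.ndarray]:
        """All variance chains entering sigma2_P, plus G0 entries."""
        out = {}
        vc = self.samples.variance_chains
        for key in vc:
            if key != self.sire_term:
                out[key] = vc[key]
        if self.with_gxe:
            out["sigma2_G"] = self.g0_chain[:, 0, 0]
            out["cov_G_GxE"] = self.g0_chain[:, 0, 1]
            out["sigma2_GxE"] = self.g0_chain[:, 1, 1]
        else:
            out["sigma2_G"] = vc[self.sire_term]
        out["residual_mean"] = self.samples.residual_mean_chain()
        return out

    def sigma2_P_chain(self) -> np.ndarray:
        ch = self.component_chains()
        total = ch["residual_mean"].copy()
        for key, c in ch.items():
            if key.startswith("residual"):
                continue
            if key == "cov_G_GxE":
                total = total + 2.0 * c
            else:
                total = total + c
        return total

    def sire_solution_chains(self) -> dict[str, np.ndarray]:
        """Chains of sire solutions: 'intercept' (k, n_sires) and, with GxE,
        'slope'."""
        info = self.samples.term_info(self.sire_term)
        chain = self.samples.locations(self.sire_term)
        nlev = info.n_levels
        out = {"intercept": chain[:, :nlev]}
        if self.with_gxe:
            out["slope"] = chain[:, nlev:2 * nlev]
        return out

    def ebv_table(self) -> pd.DataFrame:
        sol = self.sire_solution_chains()
        out = pd.DataFrame({
            "sire_id": self.sire_ids,
            "intercept": sol["intercept"].mean(axis=0),
            "intercept_sd": sol["intercept"].std(axis=0, ddof=1),
        })
        if self.with_gxe:
            out["slope"] = sol["slope"].mean(axis=0)
            out["slope_sd"] = sol["slope"].std(axis=0, ddof=1)
        return out


def _check_normality(solutions: np.ndarray) -> dict:
    out = {
        "skewness": float(stats.skew(solutions)),
        "kurtosis": float(stats.kurtosis(solutions)),
        "p_normal": float("nan"),
    }
    if solutions.size >= 8:
        out["p_normal"] = float(stats.normaltest(solutions).pvalue)
    return out


def fit_step1(
    data: pd.DataFrame,
    ped: pd.DataFrame,
    dataset_kind: str = "MT",
    config: GibbsConfig | None = None,
    fixed_class_terms: list[str] = ("parity",),
    response: str = "value",
    contemporary_column: str = "htd",
    verbose: bool = False,
) -> EnvironmentGradient:
    """Step 1: estimate the herd-environment gradient with an animal model.

    MT (test-day) data use a repeatability model with herd-test-day and
    permanent-environment random effects; FS (single-record) data use a
    herd-year-classifier contemporary group and no permanent environment.
    The fixed HEG solutions (posterior means, reference level at zero) are
    min-max scaled to [-1, 1] and returned as the environmental covariate,
    together with the step-1 variance components and animal heritability.
    """
    if dataset_kind not in ("MT", "FS"):
        raise ValueError("dataset_kind must be 'MT' or 'FS'")
    config = config or GibbsConfig()
    cg_name = "htd" if dataset_kind == "MT" else "hyc"
    random_terms = [RandomTerm(cg_name, contemporary_column, "iid")]
    if dataset_kind == "MT":
        random_terms.append(RandomTerm("pe", "animal_id", "iid"))
    random_terms.append(RandomTerm("animal", "animal_id", "pedigree"))

    model = ModelSpec(
        response=response,
        fixed_class_terms=["heg_level", *fixed_class_terms],
        random_terms=random_terms,
        residual_k=1,
    )
    ainv, ids = a_inverse(ped)
    samples = gibbs_sample(
        model, data, {"animal": (ainv, ids)}, config, verbose=verbose
    )

    info = samples.term_info("heg_level")
    means = samples.locations("heg_level").mean(axis=0)
    levels = samples.level_labels["heg_level"]
    # the reference (first) level was constrained to zero
    solutions = np.concatenate([[0.0], means])
    counts = data["heg_level"].value_counts()
    scaled = scale_covariate(solutions) if len(solutions) > 1 else np.zeros(1)
    table = pd.DataFrame({
        "heg_level": levels,
        "solution": solutions,
        "scaled_x": scaled,
        "n_records": [int(counts.get(l, 0)) for l in levels],
    })

    vc = samples.variance_chains
    sigma2_a = vc["animal"]
    denom = vc[cg_name] + sigma2_a + vc["residual"]
    if dataset_kind == "MT":
        denom = denom + vc["pe"]
    h2_chain = sigma2_a / denom

    components = {name: posterior_summary(c) for name, c in vc.items()}
    return EnvironmentGradient(
        table=table,
        diagnostics=_check_normality(solutions),
        components=components,
        h2=posterior_summary(h2_chain),
    )


def _sire_ancestor_pedigree(ped: pd.DataFrame, sires: np.ndarray) -> pd.DataFrame:
    """Restrict a pedigree to the given sires and all their ancestors."""
    parents = {
        int(a): (int(s), int(d))
        for a, s, d in zip(ped["animal_id"], ped["sire_id"], ped["dam_id"])
    }
    keep: set[int] = set()
    stack = [int(s) for s in sires]
    while stack:
        a = stack.pop()
        if a in keep or a not in parents:
            continue
        keep.add(a)
        for par in parents[a]:
            if par != 0:
                stack.append(par)
    sub = ped[ped["animal_id"].isin(keep)].copy()
    # parents outside the subset (e.g. unknown dams) become missing
    sub.loc[~sub["sire_id"].isin(keep), "sire_id"] = 0
    sub.loc[~sub["dam_id"].isin(keep), "dam_id"] = 0
    return sub


def fit_reaction_norm(
    data: pd.DataFrame,
    gradient: EnvironmentGradient,
    ped: pd.DataFrame,
    with_gxe: bool = True,
    dataset_kind: str = "MT",
    config: GibbsConfig | None = None,
    fixed_class_terms: list[str] = ("parity",),
    response: str = "value",
    contemporary_column: str = "htd",
    sire_structure: str = "pedigree",
    verbose: bool = False,
) -> ReactionNormFit:
    """Step 2: the random-regression sire model on the estimated gradient.

    The HEG class effect of step 1 is replaced by a fixed linear Legendre
    regression on the scaled gradient; each sire gets a random intercept and,
    with_gxe, a random slope with unstructured 2x2 covariance, pedigree-
    structured over the sire pedigree by default.  Residual variances follow
    five classes cut at record-level quantiles of the herd's HEG solution.
    """
    config = config or GibbsConfig()
    data = data.merge(
        gradient.table[["heg_level", "scaled_x", "solution"]], on="heg_level", how="left"
    )
    if data["scaled_x"].isna().any():
        missing = data.loc[data["scaled_x"].isna(), "heg_level"].unique()[:5]
        raise ValueError(f"records with HEG levels absent from the gradient: {missing}")
    data = data.rename(columns={"scaled_x": "env_x"})
    data["resid_class"] = residual_classes(
        data["solution"].to_numpy(), N_RESIDUAL_CLASSES
    )

    cg_name = "htd" if dataset_kind == "MT" else "hyc"
    random_terms = [RandomTerm(cg_name, contemporary_column, "iid")]
    if dataset_kind == "MT":
        # hierarchically centered on the sire reaction norm: a cow's records
        # share one herd (one covariate value), so her permanent-environment
        # effect and her sire's contribution are near-confounded and the
        # centered parameterization is required for the chain to mix; only
        # possible while each cow sits at a single gradient value
        per_cow = data.groupby("animal_id")[["sire_id", "env_x"]].nunique()
        center = None if (per_cow > 1).any().any() else "sire"
        random_terms.append(
            RandomTerm("pe", "animal_id", "iid", centered_on=center))
    if with_gxe:
        random_terms.append(RandomTerm(
            "sire", "sire_id", "random_regression",
            order=1, covariate_column="env_x", structure=sire_structure,
        ))
    else:
        kind = "pedigree" if sire_structure == "pedigree" else "iid"
        random_terms.append(RandomTerm("sire", "sire_id", kind))

    model = ModelSpec(
        response=response,
        fixed_class_terms=list(fixed_class_terms),
        fixed_covariates=[("env_x", 1)],
        random_terms=random_terms,
        residual_k=N_RESIDUAL_CLASSES,
        residual_class_column="resid_class",
    )

    rel = None
    if sire_structure == "pedigree":
        # relationship structure marginalized to the sires with daughters:
        # ancestors are integrated out (identical model, and the coefficient
        # covariance draw no longer carries data-free pedigree levels)
        data_sires = np.sort(data["sire_id"].unique())
        sire_ped = _sire_ancestor_pedigree(ped, data_sires)
        A, ids = a_matrix(sire_ped)
        pos = pd.Index(ids).get_indexer(data_sires)
        A_sub = A[np.ix_(pos, pos)]
        ainv = sp.csr_matrix(np.linalg.inv(A_sub))
        rel = {"sire": (ainv, np.asarray(data_sires))}

    samples = gibbs_sample(model, data, rel, config, verbose=verbose)
    sire_ids = samples.level_labels["sire"]
    no_daughter = [s for s in sire_ids if s not in set(data["sire_id"])]
    if no_daughter:
        warnings.warn(
            f"{len(no_daughter)} pedigree sires have no daughters with records; "
            "their solutions are pedigree predictions only",
            stacklevel=2,
        )
    return ReactionNormFit(
        samples=samples,
        with_gxe=with_gxe,
        dataset_kind=dataset_kind,
        gradient=gradient,
        sire_ids=np.asarray(sire_ids),
    )


def variance_ratios(fit: ReactionNormFit) -> dict:
    """Proportions of phenotypic variance: G/P, GxE/P, covGxE/P, sigma2_P.

    sigma2_P = sigma2_htd (or hyc) (+ sigma2_Pe) + sigma2_G + sigma2_GxE +
    2 cov(G, GxE) + mean residual variance; ratios are summarised chain-wise
    (posterior mean, SE, z, two-tailed p).
    """
    if not fit.with_gxe:
        raise ValueError("variance ratios of the GxE decomposition need a with-GxE fit")
    p_chain = fit.sigma2_P_chain()
    if p_chain.mean() <= 0:
        raise ValueError("invalid fit: non-positive phenotypic variance")
    g = fit.g0_chain
    return {
        "G_over_P": posterior_summary(g[:, 0, 0] / p_chain),
        "GxE_over_P": posterior_summary(g[:, 1, 1] / p_chain),
        "covGxE_over_P": posterior_summary(g[:, 0, 1] / p_chain),
        "sigma2_P": posterior_summary(p_chain),
    }


def sire_h2(fit: ReactionNormFit) -> dict:
    """Sire-model heritability h2 = 4 sigma2_G / sigma2_P (chain summary)."""
    p_chain = fit.sigma2_P_chain()
    if p_chain.mean() <= 0:
        raise ValueError("invalid fit: non-positive phenotypic variance")
    return posterior_summary(4.0 * fit.sigma2_G_chain() / p_chain)


def ebv_at_environment(fit: ReactionNormFit, sire, x: float) -> float:
    """Sire EBV at environment x: intercept + slope * P1(x) (slope 0 without GxE)."""
    if abs(x) > 1.0 + 1e-12:
        raise ValueError("environment x must lie in [-1, 1]")
    tab = fit.ebv_table().set_index("sire_id")
    if sire not in tab.index:
        raise KeyError(f"unknown sire {sire!r}")
    row = tab.loc[sire]
    if fit.with_gxe:
        return float(row["intercept"] + row["slope"] * x)
    return float(row["intercept"])


def ebv_accuracy(fit: ReactionNormFit, sire, pev_mode: str = "posterior_variance") -> dict:
    """EBV accuracy acc = sqrt(1 - PEV / sigma2_G), clamped to [0, 1].

    PEV is the posterior variance of the sire's intercept chain (the
    Bayesian prediction-error variance).  pev_mode='ebv_squared' evaluates
    the literal squared-EBV variant for comparison; it ties accuracy to EBV
    magnitude and is not recommended.
    """
    tab = fit.ebv_table().set_index("sire_id")
    if sire not in tab.index:
        raise KeyError(f"unknown sire {sire!r}")
    sigma2_g = float(fit.sigma2_G_chain().mean())
    if sigma2_g <= 0:
        return {"accuracy": float("nan"), "pev": float("nan"), "flag": "zero_sire_variance"}
    if pev_mode == "posterior_variance":
        pev = float(tab.loc[sire, "intercept_sd"] ** 2)
    elif pev_mode == "ebv_squared":
        pev = float(tab.loc[sire, "intercept"] ** 2)
    else:
        raise ValueError(f"unknown pev_mode {pev_mode!r}")
    ratio = pev / sigma2_g
    flag = "pev_exceeds_sire_variance" if ratio > 1.0 else None
    acc = float(np.sqrt(max(1.0 - ratio, 0.0)))
    return {"accuracy": acc, "pev": pev, "flag": flag}


def compare_rankings(ebvs_a: pd.Series, ebvs_b: pd.Series, top_k: int = 20) -> dict:
    """Spearman rank correlation and top-k turnover between two EBV sets.

    Operates on the intersection of the two sire sets; reports the rank
    correlation, the top-k overlap count, and which sires enter or leave the
    top k when moving from ranking A to ranking B.
    """
    ebvs_a, ebvs_b = pd.Series(ebvs_a), pd.Series(ebvs_b)
    common = ebvs_a.index.intersection(ebvs_b.index)
    if common.empty:
        raise ValueError("no sires in common between the two EBV sets")
    a, b = ebvs_a[common], ebvs_b[common]
    rho = float(stats.spearmanr(a, b).statistic) if len(common) > 1 else float("nan")
    k = min(top_k, len(common))
    top_a = set(a.sort_values(ascending=False).index[:k])
    top_b = set(b.sort_values(ascending=False).index[:k])
    return {
        "spearman_r": rho,
        "n_common": int(len(common)),
        "top_k": k,
        "top_k_overlap": len(top_a & top_b),
        "entered_top_k": sorted(top_b - top_a),
        "left_top_k": sorted(top_a - top_b),
    }
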