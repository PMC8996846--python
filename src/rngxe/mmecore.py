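"""Mixed-model core: model specification, design construction, and Gibbs sampling.

Implements single-trait Gaussian mixed models of the kind used in routine
genetic evaluation: class fixed effects, fixed covariate regressions on a
Legendre basis, IID and pedigree-structured random effects, random-regression
terms with an unstructured coefficient covariance, and residual variances that
are either homogeneous or heterogeneous over record classes.

Estimation is fully Bayesian via single-site Gibbs sampling with conjugate
full conditionals (normal for locations, scaled inverse chi-square for scalar
variances, inverse Wishart for the random-regression covariance), the scheme
used by the GIBBSF90 family of programs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from ._kernels import location_sweep, parent_block_update

__all__ = [
    "ModelSpec",
    "RandomTerm",
    "GibbsConfig",
    "PosteriorSamples",
    "scale_covariate",
    "legendre_basis",
    "residual_classes",
    "gibbs_sample",
    "posterior_summary",
]


# --------------------------------------------------------------------------
# Covariate machinery
# --------------------------------------------------------------------------

def scale_covariate(values: np.ndarray) -> np.ndarray:
    """Affine map of a covariate onto [-1, 1] (min -> -1, max -> +1).

    This is the standard random-regression convention: Legendre polynomials
    are orthogonal on [-1, 1], so environmental solutions are rescaled to
    that support before entering the basis.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = np.min(values), np.max(values)
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("covariate contains non-finite values")
    if hi == lo:
        raise ValueError("degenerate covariate: all values identical, cannot scale to [-1, 1]")
    return -1.0 + 2.0 * (values - lo) / (hi - lo)


def legendre_basis(x, order: int) -> np.ndarray:
    """Evaluate plain (unnormalized) Legendre polynomials P0..P_order at x.

    P0 = 1, P1 = x, and higher orders by the Bonnet recursion
    (n+1) P_{n+1} = (2n+1) x P_n - n P_{n-1}.  x must lie in [-1, 1].
    Returns shape (order+1,) for scalar x, (len(x), order+1) otherwise.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(np.abs(x_arr) > 1.0 + 1e-12):
        raise ValueError("Legendre basis requires x in [-1, 1]")
    out = np.empty((x_arr.size, order + 1))
    out[:, 0] = 1.0
    if order >= 1:
        out[:, 1] = x_arr
    for n in range(1, order):
        out[:, n + 1] = ((2 * n + 1) * x_arr * out[:, n] - n * out[:, n - 1]) / (n + 1)
    if np.isscalar(x) or np.ndim(x) == 0:
        return out[0]
    return out


def residual_classes(covariate_by_record: np.ndarray, k: int) -> np.ndarray:
    """Partition records into k residual-variance classes by covariate quantile.

    Class boundaries are the (1/k, ..., (k-1)/k) quantiles of the records'
    covariate values; a value exactly on a boundary goes to the lower class.
    Returns an int array of class indices in [0, k).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    v = np.asarray(covariate_by_record, dtype=float)
    if k == 1:
        return np.zeros(v.size, dtype=np.int64)
    n_distinct = np.unique(v).size
    if n_distinct < k:
        import warnings

        warnings.warn(
            f"only {n_distinct} distinct covariate values for {k} residual classes; "
            "classes will be merged",
            stacklevel=2,
        )
    qs = np.quantile(v, np.arange(1, k) / k)
    # side='left': a record equal to a boundary stays in the lower class
    return np.searchsorted(qs, v, side="left").astype(np.int64)


# --------------------------------------------------------------------------
# Model specification
# --------------------------------------------------------------------------

@dataclass
class RandomTerm:
    """One random term of a mixed model.

    kind is 'iid', 'pedigree', or 'random_regression'.  For 'pedigree' the
    precision structure is the relationship-matrix inverse supplied at fit
    time.  For 'random_regression', `order` Legendre coefficients beyond the
    intercept are fitted per level of `column` on `covariate_column`, with an
    unstructured (order+1)x(order+1) coefficient covariance; `structure`
    selects IID or pedigree-structured levels.
    """

    name: str
    column: str
    kind: str = "iid"
    order: int = 0
    covariate_column: str | None = None
    structure: str = "iid"  # for random_regression: 'iid' or 'pedigree'
    centered_on: str | None = None  # iid term centered on a parent random term

    def __post_init__(self):
        if self.kind not in ("iid", "pedigree", "random_regression"):
            raise ValueError(f"unknown random term kind: {self.kind}")
        if self.kind == "random_regression":
            if self.order < 1:
                raise ValueError("random_regression needs order >= 1")
            if self.covariate_column is None:
                raise ValueError("random_regression needs a covariate column")

    @property
    def n_coef(self) -> int:
        return self.order + 1 if self.kind == "random_regression" else 1


@dataclass
class ModelSpec:
    """Single-trait mixed-model specification.

    fixed_class_terms are fitted with reference-level (first level dropped)
    constraints against an explicit intercept; fixed_covariates are
    (column, basis order) pairs expanded on the plain Legendre basis with the
    constant term absorbed by the intercept.  residual_k = 1 means a
    homogeneous residual; residual_k > 1 requires a residual_class_column of
    precomputed class indices.
    """

    response: str
    fixed_class_terms: list[str] = field(default_factory=list)
    fixed_covariates: list[tuple[str, int]] = field(default_factory=list)
    random_terms: list[RandomTerm] = field(default_factory=list)
    residual_k: int = 1
    residual_class_column: str | None = None

    def validate(self, data: pd.DataFrame) -> None:
        cols = [self.response, *self.fixed_class_terms]
        cols += [c for c, _ in self.fixed_covariates]
        for t in self.random_terms:
            cols.append(t.column)
            if t.covariate_column:
                cols.append(t.covariate_column)
        if self.residual_k > 1:
            if self.residual_class_column is None:
                raise ValueError("residual_k > 1 requires residual_class_column")
            cols.append(self.residual_class_column)
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"model references missing columns: {missing}")
        if self.residual_k < 1:
            raise ValueError("residual_k must be >= 1")


@dataclass
class GibbsConfig:
    """Chain protocol: total iterations, burn-in discard, thinning interval."""

    n_iterations: int = 20000
    burn_in: int = 4000
    thin: int = 10
    seed: int = 0
    prior_df: float = -2.0       # scaled inv-chi2 df; -2 with scale 0 is flat on variances
    prior_scale: float = 0.0
    # inverse-Wishart prior for random-regression covariances: df = -(m+1)
    # with zero scale makes the prior density flat on the covariance matrix
    # (the same convention as the flat scalar-variance prior); a positive df
    # concentrates prior mass near zero and shrinks the GxE variance
    g0_prior_df: float = -3.0
    g0_prior_scale: float = 0.0

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


# --------------------------------------------------------------------------
# Design construction (internal)
# --------------------------------------------------------------------------

@dataclass
class _TermInfo:
    name: str
    kind: str            # 'fixed' | 'iid' | 'pedigree' | 'rr'
    offset: int          # first coefficient index in theta
    n_levels: int        # levels of the underlying factor
    n_coef: int          # coefficients per level (1 except rr)
    levels: np.ndarray | None = None  # level labels
    structure: str = "iid"            # rr only

    @property
    def size(self) -> int:
        return self.n_levels * self.n_coef

    @property
    def sl(self) -> slice:
        return slice(self.offset, self.offset + self.size)


class _Design:
    """Compiled design: CSC incidence arrays + term metadata for the sampler."""

    def __init__(self, model: ModelSpec, data: pd.DataFrame,
                 relationship_inverse: dict[str, tuple[sp.spmatrix, np.ndarray]] | None):
        model.validate(data)
        n = len(data)
        self.n = n
        self.y = data[model.response].to_numpy(dtype=float)
        rel = relationship_inverse or {}

        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        rec = np.arange(n, dtype=np.int64)

        self.terms: list[_TermInfo] = []
        p = 0

        def add_block(r, c, v):
            rows.append(np.asarray(r, dtype=np.int64))
            cols.append(np.asarray(c, dtype=np.int64))
            vals.append(np.asarray(v, dtype=float))

        # intercept
        self.terms.append(_TermInfo("(intercept)", "fixed", p, 1, 1))
        add_block(rec, np.full(n, p), np.ones(n))
        p += 1

        # fixed class effects: drop first level (reference constraint)
        for name in model.fixed_class_terms:
            codes, levels = pd.factorize(data[name], sort=True)
            if (codes < 0).any():
                raise ValueError(f"missing values in fixed term {name}")
            nlev = len(levels)
            if nlev < 1:
                raise ValueError(f"fixed term {name} has no levels")
            info = _TermInfo(name, "fixed", p, max(nlev - 1, 0), 1, levels=np.asarray(levels))
            self.terms.append(info)
            keep = codes > 0
            if info.size > 0:
                add_block(rec[keep], p + codes[keep] - 1, np.ones(int(keep.sum())))
            p += info.size

        # fixed covariate regressions, Legendre basis, constant term dropped
        for colname, order in model.fixed_covariates:
            x = data[colname].to_numpy(dtype=float)
            basis = legendre_basis(x, order)
            info = _TermInfo(f"cov({colname})", "fixed", p, order, 1)
            self.terms.append(info)
            for j in range(1, order + 1):
                add_block(rec, np.full(n, p + j - 1), basis[:, j])
            p += order

        # random terms
        self._rel_structs: dict[str, tuple[sp.spmatrix, np.ndarray]] = {}
        center_parents = {t.centered_on for t in model.random_terms if t.centered_on}
        unknown_parents = center_parents - {t.name for t in model.random_terms}
        if unknown_parents:
            raise ValueError(f"centered_on references unknown terms: {unknown_parents}")
        for t in model.random_terms:
            codes, levels = pd.factorize(data[t.column], sort=True)
            levels = np.asarray(levels)
            need_rel = t.kind == "pedigree" or (t.kind == "random_regression" and t.structure == "pedigree")
            if need_rel:
                if t.name not in rel and t.column not in rel:
                    raise ValueError(f"term {t.name!r} needs a relationship inverse")
                ainv, ids = rel.get(t.name, rel.get(t.column))
                ids = np.asarray(ids)
                pos = pd.Index(ids).get_indexer(levels)
                if (pos < 0).any():
                    missing = levels[pos < 0][:5]
                    raise ValueError(f"levels of {t.column} absent from relationship ids: {missing}")
                # all relationship ids become levels (ancestors without data included)
                levels = ids
                codes = pd.Index(ids).get_indexer(data[t.column])
            nlev = len(levels)
            kind = {"iid": "iid", "pedigree": "pedigree", "random_regression": "rr"}[t.kind]
            info = _TermInfo(t.name, kind, p, nlev, t.n_coef, levels=levels,
                             structure=t.structure if t.kind == "random_regression" else "iid")
            self.terms.append(info)
            if t.name in center_parents:
                pass  # enters only through the centered child's prior mean
            elif t.kind == "random_regression":
                xcov = data[t.covariate_column].to_numpy(dtype=float)
                basis = legendre_basis(xcov, t.order)
                for j in range(t.n_coef):
                    add_block(rec, p + j * nlev + codes, basis[:, j])
            else:
                add_block(rec, p + codes, np.ones(n))
            if need_rel:
                self._rel_structs[t.name] = (ainv, levels)
            p += info.size

        # hierarchical-centering maps: each child level (e.g. a cow) belongs
        # to one parent level (her sire) at one covariate value
        self.centering: list[dict] = []
        term_by_name = {t.name: t for t in model.random_terms}
        for t in model.random_terms:
            if not t.centered_on:
                continue
            if t.kind != "iid":
                raise ValueError("only IID terms can be centered on a parent term")
            parent = term_by_name[t.centered_on]
            child_info = self.term(t.name)
            parent_info = self.term(parent.name)
            grp_cols = [parent.column]
            if parent.kind == "random_regression":
                grp_cols.append(parent.covariate_column)
            grouped = data.groupby(t.column, sort=True)[grp_cols].nunique()
            if (grouped > 1).any().any():
                raise ValueError(
                    f"cannot center {t.name!r} on {parent.name!r}: parent level or "
                    "covariate varies within a child level"
                )
            firsts = data.groupby(t.column, sort=True)[grp_cols].first()
            firsts = firsts.loc[child_info.levels]
            ppos = pd.Index(parent_info.levels).get_indexer(firsts[parent.column])
            if (ppos < 0).any():
                raise ValueError("child level maps to unknown parent level")
            if parent.kind == "random_regression":
                xchild = firsts[parent.covariate_column].to_numpy(dtype=float)
            else:
                xchild = np.zeros(len(firsts))
            self.centering.append({
                "child": t.name, "parent": parent.name,
                "parent_of_child": ppos.astype(np.int64),
                "x_of_child": xchild,
            })

        self.p = p
        X = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, p),
        ).tocsc()
        X.sum_duplicates()
        self.X = X

        # residual classes
        if model.residual_k > 1:
            rc = data[model.residual_class_column].to_numpy(dtype=np.int64)
            if rc.min() < 0 or rc.max() >= model.residual_k:
                raise ValueError("residual class indices out of range")
            self.resid_class = rc
        else:
            self.resid_class = np.zeros(n, dtype=np.int64)
        self.residual_k = model.residual_k

        self._check_rank()

    def _check_rank(self):
        """Detect confounding among fixed-effect columns (cheap Gram check)."""
        fixed_cols = [t.sl for t in self.terms if t.kind == "fixed"]
        idx = np.concatenate([np.arange(s.start, s.stop) for s in fixed_cols])
        if idx.size == 0:
            return
        F = self.X[:, idx].toarray()
        gram = F.T @ F
        rank = np.linalg.matrix_rank(gram)
        if rank < idx.size:
            names = [t.name for t in self.terms if t.kind == "fixed"]
            raise ValueError(
                f"fixed-effect block is rank deficient ({rank} < {idx.size}); "
                f"confounded terms among {names}"
            )

    def term(self, name: str) -> _TermInfo:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


# --------------------------------------------------------------------------
# Posterior container and summaries
# --------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Retained Gibbs draws.

    variance_chains maps term name (or 'residual_class_<c>') to a (k,) chain;
    g0_chains maps random-regression term names to (k, m, m) covariance
    chains; location_chain is (k, p) over the full coefficient vector with
    term layout in `terms`.
    """

    variance_chains: dict[str, np.ndarray]
    g0_chains: dict[str, np.ndarray]
    location_chain: np.ndarray
    terms: list[_TermInfo]
    level_labels: dict[str, np.ndarray]
    n_retained: int

    def term_slice(self, name: str) -> slice:
        for t in self.terms:
            if t.name == name:
                return t.sl
        raise KeyError(name)

    def term_info(self, name: str) -> _TermInfo:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def locations(self, name: str) -> np.ndarray:
        """Retained chain for one term, shape (k, n_levels*n_coef)."""
        return self.location_chain[:, self.term_slice(name)]

    def export_chains_csv(self, path) -> None:
        """Write variance (and G0-entry) chains as CSV, one column per
        parameter, for external convergence diagnostics."""
        cols = dict(self.variance_chains)
        for name, g in self.g0_chains.items():
            m = g.shape[1]
            for a in range(m):
                for b in range(a, m):
                    cols[f"{name}_g0_{a}{b}"] = g[:, a, b]
        pd.DataFrame(cols).to_csv(path, index=False)

    def residual_mean_chain(self) -> np.ndarray:
        """Chain of the residual variance averaged over classes."""
        keys = sorted(k for k in self.variance_chains if k.startswith("residual_class_"))
        if not keys:
            return self.variance_chains["residual"]
        return np.mean([self.variance_chains[k] for k in keys], axis=0)


def posterior_summary(chain: np.ndarray) -> dict:
    """Posterior mean, SE, z-score and two-tailed normal p for one chain.

    Follows the convention of testing a variance-component (or ratio) chain
    against zero: z = posterior mean / posterior SD, p = 2(1 - Phi(|z|)).
    A zero-variance chain yields z and p of NaN with `degenerate=True`.
    Effective sample size (autocorrelation-based) is reported as a
    convergence diagnostic.
    """
    c = np.asarray(chain, dtype=float)
    if c.size == 0:
        raise ValueError("empty chain")
    mean = float(c.mean())
    se = float(c.std(ddof=1)) if c.size > 1 else 0.0
    if se == 0.0:
        return {"mean": mean, "se": 0.0, "z": math.nan, "p": math.nan,
                "ess": float(c.size), "degenerate": True}
    z = mean / se
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return {"mean": mean, "se": se, "z": z, "p": float(p),
            "ess": _ess(c), "degenerate": False}


def _ess(c: np.ndarray) -> float:
    """Initial-positive-sequence effective sample size."""
    n = c.size
    if n < 4:
        return float(n)
    d = c - c.mean()
    var = d @ d / n
    if var == 0:
        return float(n)
    acf_sum = 0.0
    for lag in range(1, n // 2):
        rho = (d[:-lag] @ d[lag:]) / (n * var)
        if rho <= 0.0:
            break
        acf_sum += rho
    return float(n / (1.0 + 2.0 * acf_sum))


# --------------------------------------------------------------------------
# Gibbs sampler
# --------------------------------------------------------------------------

def gibbs_sample(
    model: ModelSpec,
    data: pd.DataFrame,
    relationship_inverse: dict[str, tuple[sp.spmatrix, np.ndarray]] | None = None,
    config: GibbsConfig | None = None,
    fix_variances: dict[str, float] | None = None,
    start_variances: dict[str, float] | None = None,
    verbose: bool = False,
) -> PosteriorSamples:
    """Run the single-site Gibbs sampler for a Gaussian mixed model.

    relationship_inverse maps a random-term name (or its data column) to
    (A_inverse, ids): a sparse symmetric precision structure over `ids`, used
    for 'pedigree' terms and pedigree-structured random regressions.  Levels
    present in ids but absent from the data are carried as unobserved effects
    (they borrow information through the pedigree).

    fix_variances holds named variances fixed at the given values instead of
    sampling them ('residual' fixes all residual classes); this is the
    standard device for validating location full conditionals against GLS.

    The full conditionals are conjugate: normal single-site updates for every
    location coefficient (sweeping in index order with an updated residual
    vector), scaled inverse chi-square draws for scalar variances, an
    inverse-Wishart draw for each random-regression coefficient covariance,
    and per-class scaled inverse chi-square draws for residual variances.
    """
    config = config or GibbsConfig()
    design = _Design(model, data, relationship_inverse)
    rng = np.random.default_rng(config.seed)
    fix_variances = fix_variances or {}
    start_variances = start_variances or {}

    n, p = design.n, design.p
    X = design.X
    indptr = X.indptr.astype(np.int64)
    xrows = X.indices.astype(np.int64)
    xvals = X.data.astype(np.float64)

    # per-coefficient term bookkeeping for the kernel
    kind_code = np.zeros(p, dtype=np.int64)      # 0 fixed, 1 iid, 2 pedigree-structured
    var_index = np.full(p, -1, dtype=np.int64)   # scalar-variance slot per coefficient
    rr_term_of = np.full(p, -1, dtype=np.int64)
    rr_coef_of = np.zeros(p, dtype=np.int64)
    rr_level_of = np.zeros(p, dtype=np.int64)

    scalar_terms: list[_TermInfo] = []
    rr_terms: list[_TermInfo] = []
    # pedigree precision per structured term (shared across rr coefs)
    ainv_indptr_list, ainv_idx_list, ainv_val_list = [], [], []
    struct_id_of_term: dict[str, int] = {}

    def _register_struct(name: str, nlev: int) -> int:
        ainv, ids = design._rel_structs[name]
        if len(ids) != nlev:
            raise AssertionError("relationship ids / levels mismatch")
        A = sp.csr_matrix(ainv)
        ainv_indptr_list.append(A.indptr.astype(np.int64))
        ainv_idx_list.append(A.indices.astype(np.int64))
        ainv_val_list.append(A.data.astype(np.float64))
        struct_id_of_term[name] = len(ainv_indptr_list) - 1
        return struct_id_of_term[name]

    sv = 0
    for t in design.terms:
        if t.kind in ("iid", "pedigree"):
            scalar_terms.append(t)
            var_index[t.sl] = sv
            sv += 1
            if t.kind == "pedigree":
                sid = _register_struct(t.name, t.n_levels)
                kind_code[t.sl] = 2
                # map each coefficient to its pedigree row
                rr_term_of[t.sl] = -2 - sid  # negative coding: scalar pedigree term
                rr_level_of[t.sl] = np.arange(t.n_levels)
            else:
                kind_code[t.sl] = 1
        elif t.kind == "rr":
            rr_terms.append(t)

    struct_of_rr = np.full(len(rr_terms), -1, dtype=np.int64)
    for r_id, t in enumerate(rr_terms):
        if t.structure == "pedigree":
            struct_of_rr[r_id] = _register_struct(t.name, t.n_levels)
        idx = np.arange(t.size)
        rr_term_of[t.sl] = r_id
        rr_coef_of[t.sl] = idx // t.n_levels
        rr_level_of[t.sl] = idx % t.n_levels
        kind_code[t.sl] = 3

    # hierarchical-centering bookkeeping: parent coefficients leave the main
    # sweep (kind 4) and are redrawn blockwise from the child effects
    center_infos = []
    centered_children = {c["child"] for c in design.centering}
    centered_parents = {c["parent"] for c in design.centering}
    for centering in design.centering:
        child_info = design.term(centering["child"])
        parent_info = design.term(centering["parent"])
        kind_code[parent_info.sl] = 4
        order = np.argsort(centering["parent_of_child"], kind="stable")
        counts = np.bincount(centering["parent_of_child"],
                             minlength=parent_info.n_levels)
        cow_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        if parent_info.name in struct_id_of_term:
            sid = struct_id_of_term[parent_info.name]
            p_indptr = ainv_indptr_list[sid]
            p_idx = ainv_idx_list[sid]
            p_val = ainv_val_list[sid]
            has_ainv = True
        else:
            p_indptr = np.zeros(1, np.int64)
            p_idx = np.zeros(0, np.int64)
            p_val = np.zeros(0, np.float64)
            has_ainv = False
        center_infos.append({
            "child": child_info, "parent": parent_info,
            "parent_of_child": centering["parent_of_child"],
            "x_of_child": centering["x_of_child"],
            "cow_ptr": cow_ptr, "cow_idx": order.astype(np.int64),
            "has_ainv": has_ainv, "ainv": (p_indptr, p_idx, p_val),
        })

    if ainv_indptr_list:
        struct_ptr_offsets = np.cumsum([0] + [len(a) for a in ainv_indptr_list[:-1]])
        nz_offsets = np.cumsum([0] + [len(a) for a in ainv_idx_list[:-1]])
        ainv_indptr = np.concatenate(
            [a + off for a, off in zip(ainv_indptr_list, nz_offsets)]
        )
        struct_row_start = np.asarray(struct_ptr_offsets, dtype=np.int64)
        ainv_idx = np.concatenate(ainv_idx_list)
        ainv_val = np.concatenate(ainv_val_list)
    else:
        ainv_indptr = np.zeros(1, dtype=np.int64)
        struct_row_start = np.zeros(1, dtype=np.int64)
        ainv_idx = np.zeros(0, dtype=np.int64)
        ainv_val = np.zeros(0, dtype=np.float64)

    # rr layout arrays
    rr_offsets = np.asarray([t.offset for t in rr_terms], dtype=np.int64) if rr_terms else np.zeros(0, np.int64)
    rr_nlev = np.asarray([t.n_levels for t in rr_terms], dtype=np.int64) if rr_terms else np.zeros(0, np.int64)
    rr_ncoef = np.asarray([t.n_coef for t in rr_terms], dtype=np.int64) if rr_terms else np.zeros(0, np.int64)
    max_coef = int(rr_ncoef.max()) if rr_terms else 1
    g0_inv = np.zeros((max(len(rr_terms), 1), max_coef, max_coef))

    # state: theta starts at 0, so e = y
    theta = np.zeros(p)
    resid = design.y.copy()
    k_res = design.residual_k
    y_var = float(np.var(design.y)) or 1.0
    resid_var = np.full(k_res, start_variances.get("residual", y_var / 2.0))
    scalar_var = np.array(
        [start_variances.get(t.name, y_var / max(len(scalar_terms), 1) / 2.0) for t in scalar_terms]
    )
    g0 = np.zeros_like(g0_inv)
    for r_id, t in enumerate(rr_terms):
        m = t.n_coef
        g0[r_id, :m, :m] = np.eye(m) * start_variances.get(t.name, y_var / 10.0)
        g0_inv[r_id, :m, :m] = np.linalg.inv(g0[r_id, :m, :m])

    resid_class = design.resid_class
    class_counts = np.bincount(resid_class, minlength=k_res).astype(float)

    fixed_scalar = np.array([t.name in fix_variances for t in scalar_terms])
    for i, t in enumerate(scalar_terms):
        if fixed_scalar[i]:
            scalar_var[i] = fix_variances[t.name]
    fix_resid = "residual" in fix_variances
    if fix_resid:
        resid_var[:] = fix_variances["residual"]
    fixed_g0 = [t.name in fix_variances for t in rr_terms]
    for r_id, t in enumerate(rr_terms):
        if fixed_g0[r_id]:
            v = np.asarray(fix_variances[t.name], dtype=float)
            m = t.n_coef
            g0[r_id, :m, :m] = v if v.ndim == 2 else np.eye(m) * v
            g0_inv[r_id, :m, :m] = np.linalg.inv(g0[r_id, :m, :m])

    n_ret = config.n_retained
    var_chains = {t.name: np.empty(n_ret) for t in scalar_terms}
    if k_res == 1:
        var_chains["residual"] = np.empty(n_ret)
    else:
        for c in range(k_res):
            var_chains[f"residual_class_{c}"] = np.empty(n_ret)
    g0_chains = {t.name: np.empty((n_ret, t.n_coef, t.n_coef)) for t in rr_terms}
    loc_chain = np.empty((n_ret, p))

    nu0, s0 = config.prior_df, config.prior_scale
    prior_mean = np.zeros(p)

    def _refresh_prior_means():
        for ci in center_infos:
            pinfo, chinfo = ci["parent"], ci["child"]
            u0 = theta[pinfo.offset + ci["parent_of_child"]]
            pm = u0.copy()
            if pinfo.n_coef == 2:
                u1 = theta[pinfo.offset + pinfo.n_levels + ci["parent_of_child"]]
                pm += u1 * ci["x_of_child"]
            prior_mean[chinfo.sl] = pm

    ret = 0
    for it in range(config.n_iterations):
        rprec = 1.0 / resid_var[resid_class]
        z = rng.standard_normal(p)
        _refresh_prior_means()
        location_sweep(
            theta, resid, z, prior_mean,
            indptr, xrows, xvals, rprec,
            kind_code, var_index, scalar_var,
            rr_term_of, rr_coef_of, rr_level_of,
            rr_offsets, rr_nlev, g0_inv,
            struct_of_rr, struct_row_start, ainv_indptr, ainv_idx, ainv_val,
        )

        # blocked redraw of centering parents from the child effects
        for ci in center_infos:
            pinfo, chinfo = ci["parent"], ci["child"]
            m = pinfo.n_coef
            if pinfo.kind == "rr":
                r_id = next(i for i, t in enumerate(rr_terms) if t.name == pinfo.name)
                gi = np.ascontiguousarray(g0_inv[r_id, :2, :2])
                if m == 1:
                    gi = np.array([[g0_inv[r_id, 0, 0], 0.0], [0.0, 1.0]])
            else:
                sv_i = next(i for i, t in enumerate(scalar_terms) if t.name == pinfo.name)
                gi = np.array([[1.0 / scalar_var[sv_i], 0.0], [0.0, 1.0]])
            child_var = scalar_var[next(
                i for i, t in enumerate(scalar_terms) if t.name == chinfo.name)]
            zb = rng.standard_normal(pinfo.size)
            p_indptr, p_idx, p_val = ci["ainv"]
            parent_block_update(
                theta, zb,
                pinfo.offset, pinfo.n_levels, m,
                chinfo.offset, 0.0,
                ci["cow_ptr"], ci["cow_idx"], ci["x_of_child"],
                1.0 / child_var,
                gi,
                ci["has_ainv"], p_indptr, p_idx, p_val,
            )
        # group scale moves for centered parents: (U_t, G0) -> (c U_t, D G0 D)
        # evaluated against the child-effect likelihood; breaks the absorbing
        # random walk between a shrunken column and a small sampled variance
        for ci in center_infos:
            pinfo, chinfo = ci["parent"], ci["child"]
            if pinfo.kind == "rr":
                r_id = next(i for i, t in enumerate(rr_terms) if t.name == pinfo.name)
                if fixed_g0[r_id]:
                    continue
                nu0g = config.g0_prior_df
            else:
                sv_i = next(i for i, t in enumerate(scalar_terms) if t.name == pinfo.name)
                if fixed_scalar[sv_i]:
                    continue
                nu0g = nu0
            child_var = scalar_var[next(
                i for i, t in enumerate(scalar_terms) if t.name == chinfo.name)]
            m = pinfo.n_coef
            eta = theta[chinfo.sl]
            poc = ci["parent_of_child"]
            xch = ci["x_of_child"]
            pm_all = theta[pinfo.offset + poc].copy()
            if m == 2:
                pm_all = pm_all + theta[pinfo.offset + pinfo.n_levels + poc] * xch
            for tcoef in range(m):
                u_t = theta[pinfo.offset + tcoef * pinfo.n_levels + poc]
                w = u_t if tcoef == 0 else u_t * xch
                r_vec = eta - pm_all + w
                a_q = float(w @ w) / child_var
                b_q = float(w @ r_vec) / child_var
                if pinfo.kind == "rr":
                    t0_q = config.g0_prior_scale * g0_inv[r_id, tcoef, tcoef]
                else:
                    t0_q = 0.0

                def logf(c):
                    return (-(nu0g + 1.0) * np.log(c)
                            - 0.5 * a_q * c * c + b_q * c
                            - 0.5 * t0_q / (c * c))

                c_cur = 1.0
                for _ in range(2):
                    c_prop = float(np.exp(np.log(c_cur) + 0.6 * rng.standard_normal()))
                    if np.log(rng.random()) < (logf(c_prop) + np.log(c_prop)
                                               - logf(c_cur) - np.log(c_cur)):
                        c_cur = c_prop
                if c_cur != 1.0:
                    cols = slice(pinfo.offset + tcoef * pinfo.n_levels,
                                 pinfo.offset + (tcoef + 1) * pinfo.n_levels)
                    theta[cols] *= c_cur
                    pm_all = pm_all - w + c_cur * w
                    if pinfo.kind == "rr":
                        g0[r_id, tcoef, :m] *= c_cur
                        g0[r_id, :m, tcoef] *= c_cur
                        g0_inv[r_id, :m, :m] = np.linalg.inv(g0[r_id, :m, :m])
                    else:
                        scalar_var[sv_i] *= c_cur * c_cur
        if center_infos:
            _refresh_prior_means()

        # scalar variances
        for i, t in enumerate(scalar_terms):
            if fixed_scalar[i]:
                continue
            u = theta[t.sl]
            if t.name in centered_children:
                u = u - prior_mean[t.sl]
            if t.kind == "pedigree":
                sid = struct_id_of_term[t.name]
                ainv, _ = design._rel_structs[t.name]
                ss = float(u @ (ainv @ u))
            else:
                ss = float(u @ u)
            df = t.n_levels + nu0
            if df <= 0:
                df = t.n_levels
            scalar_var[i] = (ss + nu0 * s0 if nu0 > 0 else ss) / rng.chisquare(df)
            scalar_var[i] = max(scalar_var[i], 1e-12)

        # rr covariances
        for r_id, t in enumerate(rr_terms):
            if fixed_g0[r_id]:
                continue
            m = t.n_coef
            U = theta[t.sl].reshape(m, t.n_levels).T  # (nlev, m)
            if t.structure == "pedigree":
                ainv, _ = design._rel_structs[t.name]
                S = U.T @ (ainv @ U)
            else:
                S = U.T @ U
            scale = S + np.eye(m) * config.g0_prior_scale
            # floor keeps the draw proper when a term has very few levels
            df = max(t.n_levels + config.g0_prior_df, m + 0.5)
            newg = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
            newg = np.atleast_2d(newg)
            g0[r_id, :m, :m] = newg
            g0_inv[r_id, :m, :m] = np.linalg.inv(newg)

        # group scale moves on random-regression columns: a Metropolis step
        # on the transformation (U_t, G0) -> (c U_t, D G0 D) that breaks the
        # slow random walk between shrunken coefficients and a small sampled
        # covariance (the prior quadratic form is invariant, so the
        # conditional for c is cheap to evaluate)
        for r_id, t in enumerate(rr_terms):
            if fixed_g0[r_id] or t.name in centered_parents:
                continue
            m = t.n_coef
            for tcoef in range(m):
                cols = slice(t.offset + tcoef * t.n_levels,
                             t.offset + (tcoef + 1) * t.n_levels)
                w = X[:, cols] @ theta[cols]
                a_q = float(w * rprec @ w)
                r_vec = resid + w
                b_q = float(w * rprec @ r_vec)
                t0_q = config.g0_prior_scale * g0_inv[r_id, tcoef, tcoef]
                nu0g = config.g0_prior_df

                def logf(c):
                    return (-(nu0g + 1.0) * np.log(c)
                            - 0.5 * a_q * c * c + b_q * c
                            - 0.5 * t0_q / (c * c))

                c_cur = 1.0
                for _ in range(2):
                    c_prop = float(np.exp(np.log(c_cur) + 0.5 * rng.standard_normal()))
                    # include the log-scale proposal Jacobian c
                    if np.log(rng.random()) < (logf(c_prop) + np.log(c_prop)
                                               - logf(c_cur) - np.log(c_cur)):
                        c_cur = c_prop
                if c_cur != 1.0:
                    theta[cols] *= c_cur
                    resid[:] = r_vec - c_cur * w
                    g0[r_id, tcoef, :m] *= c_cur
                    g0[r_id, :m, tcoef] *= c_cur
                    g0_inv[r_id, :m, :m] = np.linalg.inv(g0[r_id, :m, :m])

        # residual variances per class
        if not fix_resid:
            if k_res == 1:
                ss = float(resid @ resid)
                resid_var[0] = ss / rng.chisquare(max(n + nu0, 1))
            else:
                ss_c = np.bincount(resid_class, weights=resid * resid, minlength=k_res)
                for c in range(k_res):
                    df = max(class_counts[c] + nu0, 1.0)
                    resid_var[c] = ss_c[c] / rng.chisquare(df)
            resid_var = np.maximum(resid_var, 1e-12)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and ret < n_ret:
            for i, t in enumerate(scalar_terms):
                var_chains[t.name][ret] = scalar_var[i]
            if k_res == 1:
                var_chains["residual"][ret] = resid_var[0]
            else:
                for c in range(k_res):
                    var_chains[f"residual_class_{c}"][ret] = resid_var[c]
            for r_id, t in enumerate(rr_terms):
                m = t.n_coef
                g0_chains[t.name][ret] = g0[r_id, :m, :m]
            loc_chain[ret] = theta
            ret += 1
        if verbose and (it + 1) % 1000 == 0:
            print(f"  gibbs iteration {it + 1}/{config.n_iterations}")

    labels = {t.name: t.levels for t in design.terms if t.levels is not None}
    return PosteriorSamples(
        variance_chains=var_chains,
        g0_chains=g0_chains,
        location_chain=loc_chain,
        terms=design.terms,
        level_labels=labels,
        n_retained=ret,
    )
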