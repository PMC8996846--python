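"""Synthetic herd-book generator with a known reaction-norm architecture.

Emulates the structure of a small dual-purpose cattle population recorded
across heterogeneous farm environments: herds carry four environmental
categories (geographical area, housing, feeding, summer pasture) whose joint
combination defines the environmental group; sires carry correlated
reaction-norm intercepts and slopes; cows contribute repeated test-day
records with herd-test-day, permanent-environment and class fixed effects;
and the residual variance changes over the environmental gradient.

Because the sire transmits half the additive value, the generator draws sire
effects on the transmitting-ability scale (variance = sire variance) and puts
the remaining within-family deviation, N(0, 3 sigma2_G) constant per cow, in
the cow (dams are unknown founders, so the animal-model Mendelian variance is
exactly 3/4 of the additive variance).  Under a sire model that deviation is
absorbed by the permanent-environment term; `sire_model_truth` reports the
components that are estimable in that parameterisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import a_matrix

__all__ = [
    "SimulationConfig",
    "TruePopulation",
    "EC_LEVELS",
    "scs_transform",
    "assign_environments",
    "simulate_population",
    "simulate_phenotypes",
    "simulate_dataset",
    "sire_model_truth",
    "write_tables",
]

# Environmental categories and their levels: area has three, the rest two.
EC_LEVELS: dict[str, tuple[str, ...]] = {
    "area": ("Plain", "Hill", "Mountain"),
    "housing": ("TS", "LH"),          # tie-stall vs loose housing
    "feeding": ("Trad", "TMR"),       # hay+concentrate vs total mixed ration
    "pasture": ("Yes", "No"),         # summer pasture practised
}


def n_possible_eg() -> int:
    """Number of possible environmental groups (product of EC level counts)."""
    out = 1
    for levels in EC_LEVELS.values():
        out *= len(levels)
    return out


def _default_ec_probabilities() -> dict:
    """Area-conditional EC tables: plain farms lean to loose housing, total
    mixed ration and no pasture; mountain farms to tie-stalls, traditional
    feeding and summer pasture; hills sit in between."""
    return {
        "area": {"Plain": 0.40, "Hill": 0.20, "Mountain": 0.40},
        "housing": {
            "Plain": {"TS": 0.25, "LH": 0.75},
            "Hill": {"TS": 0.50, "LH": 0.50},
            "Mountain": {"TS": 0.70, "LH": 0.30},
        },
        "feeding": {
            "Plain": {"Trad": 0.25, "TMR": 0.75},
            "Hill": {"Trad": 0.60, "TMR": 0.40},
            "Mountain": {"Trad": 0.85, "TMR": 0.15},
        },
        "pasture": {
            "Plain": {"Yes": 0.10, "No": 0.90},
            "Hill": {"Yes": 0.45, "No": 0.55},
            "Mountain": {"Yes": 0.75, "No": 0.25},
        },
    }


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic herd-book.

    Default sizes follow the desk-scale design used throughout the package
    tests: 60 herds, 100 sires, 10 daughters per sire, 8 test-day records
    per cow (about 8,000 records).  Default variance components are on the
    factor-score scale: G0 = [[0.06, 0.01], [0.01, 0.04]] for the sire
    (intercept, slope), permanent environment 0.1, herd-test-day 0.05, and
    five residual-class variances 0.8..1.2 increasing along the gradient.
    """

    n_herds: int = 60
    n_sires: int = 100
    daughters_per_sire: float = 10.0
    records_per_cow: float = 8.0
    ec_level_probabilities: dict = field(default_factory=_default_ec_probabilities)
    true_G0: np.ndarray = field(
        default_factory=lambda: np.array([[0.06, 0.01], [0.01, 0.04]])
    )
    sigma2_pe: float = 0.1
    sigma2_htd: float = 0.05
    sigma2_resid_classes: tuple = (0.8, 0.9, 1.0, 1.1, 1.2)
    heg_effect_range: tuple = (-1.0, 1.0)
    fixed_effect_tables: dict = field(
        default_factory=lambda: {"parity": {1: 0.0, 2: 0.15, 3: 0.20}}
    )
    seed: int = 0

    def __post_init__(self):
        self.true_G0 = np.asarray(self.true_G0, dtype=float)
        if self.true_G0.shape != (2, 2):
            raise ValueError("true_G0 must be 2x2")
        if not np.allclose(self.true_G0, self.true_G0.T):
            raise ValueError("true_G0 must be symmetric")
        eig = np.linalg.eigvalsh(self.true_G0)
        if eig.min() < -1e-10:
            raise ValueError("true_G0 must be positive semidefinite")
        if len(self.sigma2_resid_classes) != 5:
            raise ValueError("exactly 5 residual-class variances required")
        for v in (self.sigma2_pe, self.sigma2_htd, *self.sigma2_resid_classes):
            if v < 0:
                raise ValueError("variances must be non-negative")
        self._validate_probabilities()

    def _validate_probabilities(self):
        probs = self.ec_level_probabilities
        for ec, levels in EC_LEVELS.items():
            if ec not in probs:
                raise ValueError(f"missing probability table for EC {ec!r}")
            table = probs[ec]
            tables = [table] if not _is_conditional(table) else list(table.values())
            for t in tables:
                unknown = set(t) - set(levels)
                if unknown:
                    raise ValueError(f"unknown levels {unknown} for EC {ec!r}")
                total = sum(t.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"probabilities for EC {ec!r} sum to {total}, not 1"
                    )


def _is_conditional(table: dict) -> bool:
    return any(isinstance(v, dict) for v in table.values())


@dataclass
class TruePopulation:
    """Simulated truth: pedigree, sire reaction norms, herd environments."""

    pedigree: pd.DataFrame
    sire_effects: pd.DataFrame   # sire_id, intercept, slope
    herd_env: pd.DataFrame       # herd_id, env_effect, x_true, resid_class, EC, eg_label
    cows: pd.DataFrame           # animal_id, sire_id, herd_id, parity, pe, wf
    config: SimulationConfig


def scs_transform(scc) -> float | np.ndarray:
    """Somatic cell score: SCS = 3 + log2(SCC / 100,000 cells/mL).

    100,000 cells/mL maps to 3; each doubling of the count adds one point.
    """
    scc = np.asarray(scc, dtype=float)
    if np.any(scc <= 0):
        raise ValueError("somatic cell count must be > 0")
    out = 3.0 + np.log2(scc / 100_000.0)
    return float(out) if out.ndim == 0 else out


def assign_environments(herds, config: SimulationConfig) -> pd.DataFrame:
    """Draw one level per environmental category for each herd.

    Area is drawn from its marginal table; the other categories from tables
    optionally conditioned on area, which lets levels cluster the way real
    farming systems do.  The environmental-group label concatenates the four
    levels, e.g. ``Plain_LH_TMR_No``.
    """
    herds = list(herds)
    if not herds:
        raise ValueError("no herds to assign")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    probs = config.ec_level_probabilities

    def draw(table: dict, size: int) -> np.ndarray:
        levels = list(table)
        pvals = np.asarray([table[k] for k in levels], dtype=float)
        return rng.choice(levels, size=size, p=pvals)

    n = len(herds)
    out = pd.DataFrame({"herd_id": herds})
    out["area"] = draw(probs["area"], n)
    for ec in ("housing", "feeding", "pasture"):
        table = probs[ec]
        if _is_conditional(table):
            vals = np.empty(n, dtype=object)
            for area, sub in table.items():
                mask = (out["area"] == area).to_numpy()
                if mask.any():
                    vals[mask] = draw(sub, int(mask.sum()))
            out[ec] = vals
        else:
            out[ec] = draw(table, n)
    out["eg_label"] = (
        out["area"].astype(str) + "_" + out["housing"].astype(str)
        + "_" + out["feeding"].astype(str) + "_" + out["pasture"].astype(str)
    )
    return out


def _sire_pedigree(config: SimulationConfig, rng) -> pd.DataFrame:
    """Sires plus two known ancestral generations (grandparents are founders)."""
    n_s = config.n_sires
    n_f = max(n_s // 5, 2)   # founder males = founder females
    n_m = max(n_s // 3, 2)   # middle-generation parents of sires
    rows = []
    fm = list(range(1, n_f + 1))
    ff = list(range(n_f + 1, 2 * n_f + 1))
    for a in fm + ff:
        rows.append((a, 0, 0, "M" if a in fm else "F", "1998-01-01"))
    mm = list(range(2 * n_f + 1, 2 * n_f + n_m + 1))
    mf = list(range(2 * n_f + n_m + 1, 2 * n_f + 2 * n_m + 1))
    for a in mm + mf:
        rows.append((a, int(rng.choice(fm)), int(rng.choice(ff)),
                     "M" if a in mm else "F", "2002-01-01"))
    sire_start = 2 * n_f + 2 * n_m + 1
    sires = list(range(sire_start, sire_start + n_s))
    for a in sires:
        rows.append((a, int(rng.choice(mm)), int(rng.choice(mf)), "M", "2006-01-01"))
    ped = pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id", "sex", "birth_date"])
    ped.attrs["sire_ids"] = sires
    return ped


def simulate_population(config: SimulationConfig) -> TruePopulation:
    """Build the true population: pedigree, sire reaction norms, herd truth.

    Sire (intercept, slope) pairs are drawn jointly over the pedigree,
    vec(U) ~ N(0, true_G0 (x) A), so related sires have correlated reaction
    norms and a pedigree-structured sire model is correctly specified.  True
    herd effects are spread evenly over heg_effect_range and shuffled over
    herds; the simulation's environmental covariate is that effect min-max
    scaled to [-1, 1].
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    ped = _sire_pedigree(config, rng)
    sires = ped.attrs["sire_ids"]

    A, ids = a_matrix(ped)
    L = np.linalg.cholesky(A + 1e-10 * np.eye(len(ids)))
    eigval, eigvec = np.linalg.eigh(config.true_G0)
    g_half = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None))) @ eigvec.T
    U = L @ rng.standard_normal((len(ids), 2)) @ g_half.T  # rows ~ N(0, A (x) G0)
    upos = pd.Index(ids).get_indexer(sires)
    sire_effects = pd.DataFrame({
        "sire_id": sires,
        "intercept": U[upos, 0],
        "slope": U[upos, 1],
    })

    # herd environments: evenly spread true effects, shuffled over herds
    herd_ids = np.arange(1, config.n_herds + 1)
    lo, hi = config.heg_effect_range
    if config.n_herds > 1:
        effects = np.linspace(lo, hi, config.n_herds)
    else:
        effects = np.array([(lo + hi) / 2.0])
    rng.shuffle(effects)
    herd_env = pd.DataFrame({"herd_id": herd_ids, "env_effect": effects})
    if hi == lo:
        herd_env["x_true"] = 0.0
    else:
        herd_env["x_true"] = -1.0 + 2.0 * (herd_env["env_effect"] - lo) / (hi - lo)
    # residual class by quintile of the true herd effect
    ranks = herd_env["env_effect"].rank(method="first").to_numpy()
    herd_env["resid_class"] = np.minimum(
        ((ranks - 1) * 5 / len(ranks)).astype(int), 4
    )
    env = assign_environments(herd_env["herd_id"], config)
    herd_env = herd_env.merge(env, on="herd_id")

    # cows: daughters per sire ~ Poisson(mean), each cow in one random herd
    n_daughters = rng.poisson(config.daughters_per_sire, size=len(sires))
    n_daughters = np.maximum(n_daughters, 1)
    cow_sires = np.repeat(sires, n_daughters)
    n_cows = len(cow_sires)
    cow_ids = np.arange(ped["animal_id"].max() + 1, ped["animal_id"].max() + 1 + n_cows)
    cow_herds = rng.choice(herd_env["herd_id"].to_numpy(), size=n_cows)
    parities = list(config.fixed_effect_tables.get("parity", {1: 0.0}))
    sg = config.true_G0[0, 0]
    cows = pd.DataFrame({
        "animal_id": cow_ids,
        "sire_id": cow_sires,
        "herd_id": cow_herds,
        "parity": rng.choice(parities, size=n_cows),
        "pe": rng.normal(0.0, np.sqrt(config.sigma2_pe), size=n_cows),
        "wf": rng.normal(0.0, np.sqrt(3.0 * sg), size=n_cows),
    })
    cow_ped = pd.DataFrame({
        "animal_id": cow_ids, "sire_id": cow_sires, "dam_id": 0,
        "sex": "F", "birth_date": "2012-01-01",
    })
    full_ped = pd.concat([ped, cow_ped], ignore_index=True)
    full_ped.attrs["sire_ids"] = sires
    return TruePopulation(full_ped, sire_effects, herd_env, cows, config)


def simulate_phenotypes(population: TruePopulation, trait: str = "y") -> pd.DataFrame:
    """Draw test-day records for every cow of the population.

    Record count per cow is Poisson(records_per_cow) truncated at 1; test
    days are drawn from a per-herd pool so herd-test-day effects have
    realistic level sizes.  The record value composes the true herd effect,
    the herd-test-day effect, the parity fixed effect, the sire's reaction
    norm evaluated at the herd's true covariate, the cow's within-family and
    permanent-environment deviations, and a residual from the herd's
    residual-variance class.
    """
    cfg = population.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    cows = population.cows
    herd = population.herd_env.set_index("herd_id")
    sires = population.sire_effects.set_index("sire_id")

    n_rec = np.maximum(rng.poisson(cfg.records_per_cow, size=len(cows)), 1)
    rec_cow = np.repeat(np.arange(len(cows)), n_rec)
    n = len(rec_cow)
    n_dates = max(int(cfg.records_per_cow * 1.5), 4)
    dates = rng.integers(0, n_dates, size=n)

    herd_of = cows["herd_id"].to_numpy()[rec_cow]
    htd_key = herd_of * 1000 + dates
    uniq, htd_code = np.unique(htd_key, return_inverse=True)
    htd_effect = rng.normal(0.0, np.sqrt(cfg.sigma2_htd), size=len(uniq))[htd_code]

    parity = cows["parity"].to_numpy()[rec_cow]
    parity_table = cfg.fixed_effect_tables.get("parity", {})
    parity_eff = np.asarray([parity_table.get(p, 0.0) for p in parity])

    env_eff = herd["env_effect"].to_numpy()[herd.index.get_indexer(herd_of)]
    x_true = herd["x_true"].to_numpy()[herd.index.get_indexer(herd_of)]
    rclass = herd["resid_class"].to_numpy()[herd.index.get_indexer(herd_of)]

    sire_of = cows["sire_id"].to_numpy()[rec_cow]
    spos = sires.index.get_indexer(sire_of)
    s_int = sires["intercept"].to_numpy()[spos]
    s_slope = sires["slope"].to_numpy()[spos]

    resid_sd = np.sqrt(np.asarray(cfg.sigma2_resid_classes))[rclass]
    resid = rng.standard_normal(n) * resid_sd

    y = (
        env_eff + htd_effect + parity_eff
        + s_int + s_slope * x_true
        + cows["wf"].to_numpy()[rec_cow] + cows["pe"].to_numpy()[rec_cow]
        + resid
    )
    base = pd.Timestamp("2013-01-15")
    out = pd.DataFrame({
        "animal_id": cows["animal_id"].to_numpy()[rec_cow],
        "sire_id": sire_of,
        "herd_id": herd_of,
        "record_date": base + pd.to_timedelta(dates * 30, unit="D"),
        "htd": htd_key,
        "parity": parity,
        "trait": trait,
        "value": y,
    })
    out = out.merge(
        population.herd_env[["herd_id", "eg_label"]], on="herd_id", how="left"
    )
    out["heg_level"] = out["herd_id"].astype(str) + ":" + out["eg_label"]
    return out


def simulate_dataset(config: SimulationConfig, trait: str = "y"):
    """Convenience wrapper: population plus its phenotype table."""
    pop = simulate_population(config)
    return pop, simulate_phenotypes(pop, trait=trait)


def sire_model_truth(config: SimulationConfig) -> dict:
    """True values of the components estimable under the step-2 sire model.

    The cow's within-family deviation (variance 3 sigma2_G) is constant over
    her records and therefore indistinguishable from permanent environment in
    a sire model; the estimable Pe variance is sigma2_pe + 3 sigma2_G.
    """
    g = config.true_G0
    return {
        "sigma2_htd": config.sigma2_htd,
        "sigma2_pe": config.sigma2_pe + 3.0 * g[0, 0],
        "sigma2_G": g[0, 0],
        "cov_G_GxE": g[0, 1],
        "sigma2_GxE": g[1, 1],
        "sigma2_resid_classes": tuple(config.sigma2_resid_classes),
    }


def write_tables(population: TruePopulation, phenotypes: pd.DataFrame, outdir) -> dict:
    """Write the pedigree / phenotype / herd-environment CSV files."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "herd_environment": outdir / "herd_environment.csv",
    }
    population.pedigree.to_csv(paths["pedigree"], index=False)
    phenotypes.to_csv(paths["phenotypes"], index=False)
    cols = ["herd_id", "area", "housing", "feeding", "pasture", "eg_label"]
    population.herd_env[cols].to_csv(paths["herd_environment"], index=False)
    return {k: str(v) for k, v in paths.items()}
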