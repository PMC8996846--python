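"""Multivariate selection response across environments.

Implements the classical selection-index machinery: index weights
b = P^-1 G a, index standard deviation sigma_i = sqrt(b' P b), and the
response per generation R = (i / sigma_i) G b, reported per trait in trait
units and in phenotypic-standard-deviation units (R / sigma_P).  Environment
specificity enters through the G and P matrices, whose genetic variances for
reaction-norm traits are the averaged per-environment ZGZ' estimates;
performance-test traits keep fixed variances because they are recorded under
standardized station conditions with no GxE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionIndexSpec",
    "ResponseResult",
    "default_emphasis",
    "selection_intensity",
    "build_matrices",
    "economic_weights",
    "selection_response",
]


def default_emphasis(traits: list[str]) -> dict[str, float]:
    """Default relative emphasis: 0.65 to milk yields split 3:1 PY:FY, 0.20
    to the type factor scores split equally UC:MU, 0.15 to performance-test
    traits split 0.45 ADG : 0.55 FLxDP, and 0 to SCS."""
    table = {
        "PY": 0.65 * 3 / 4, "FY": 0.65 * 1 / 4,
        "UC": 0.20 / 2, "MU": 0.20 / 2,
        "ADG": 0.15 * 0.45, "FLxDP": 0.15 * 0.55,
        "SCS": 0.0,
    }
    return {t: table.get(t, 0.0) for t in traits}


@dataclass
class SelectionIndexSpec:
    """Traits, emphasis, intensity inputs and correlation structure.

    genetic_sd holds per-trait genetic SDs for the economic-weight product
    a_s = a * sigma_a.  r_a and r_P are genetic and phenotypic correlation
    matrices in trait order.  Per-environment variances for reaction-norm
    traits are supplied to `build_matrices`; fixed_variances maps
    performance-test traits to constant (sigma2_a, sigma2_P) pairs.
    """

    traits: list[str]
    relative_emphasis: dict[str, float] = None
    selected_proportion: float = 0.10
    genetic_sd: dict[str, float] = field(default_factory=dict)
    r_a: np.ndarray = None
    r_P: np.ndarray = None
    fixed_variances: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.relative_emphasis is None:
            self.relative_emphasis = default_emphasis(self.traits)
        if not 0.0 < self.selected_proportion < 1.0:
            raise ValueError("selected_proportion must be in (0, 1)")
        if any(v < 0 for v in self.relative_emphasis.values()):
            raise ValueError("relative emphasis entries must be >= 0")
        m = len(self.traits)
        for name in ("r_a", "r_P"):
            r = getattr(self, name)
            if r is None:
                r = np.eye(m)
                setattr(self, name, r)
            r = np.asarray(r, dtype=float)
            setattr(self, name, r)
            if r.shape != (m, m) or not np.allclose(r, r.T):
                raise ValueError(f"{name} must be a symmetric {m}x{m} matrix")
            if not np.allclose(np.diag(r), 1.0) or np.abs(r).max() > 1.0 + 1e-12:
                raise ValueError(f"{name} must have unit diagonal and |r| <= 1")


@dataclass
class ResponseResult:
    """Per-trait response for one environment level."""

    environment: str
    traits: list[str]
    b: np.ndarray          # index weights
    sigma_i: float         # index SD
    R: np.ndarray          # trait units per generation
    R_dsi: np.ndarray      # phenotypic-SD units

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "environment": self.environment, "trait": self.traits,
            "R": self.R, "R_dsi": self.R_dsi,
        })


def selection_intensity(p: float) -> float:
    """Standardized selection differential of truncation selection.

    i = phi(z) / p with z the upper-p quantile of the standard normal;
    p = 0.10 gives 1.755.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("selected proportion must be in (0, 1)")
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


def build_matrices(
    spec: SelectionIndexSpec,
    environment_level: str,
    genetic_variances: dict[str, float],
    phenotypic_variances: dict[str, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble environment-specific G and P matrices.

    Reaction-norm traits take their genetic variance from the environment's
    averaged ZGZ' estimate and their phenotypic variance from the summed
    components for that environment; traits in spec.fixed_variances
    (performance test) keep the same variances in every environment.
    Covariances follow sigma_12 = r_12 * sqrt(sigma2_1 * sigma2_2).
    """
    m = len(spec.traits)
    va = np.empty(m)
    vp = np.empty(m)
    for i, t in enumerate(spec.traits):
        if t in spec.fixed_variances:
            va[i], vp[i] = spec.fixed_variances[t]
        else:
            if t not in genetic_variances or t not in phenotypic_variances:
                raise ValueError(f"no variances for trait {t!r} in {environment_level!r}")
            va[i] = genetic_variances[t]
            vp[i] = phenotypic_variances[t]
    if np.any(va <= 0) or np.any(vp <= 0):
        raise ValueError("all trait variances must be > 0")
    sa, sp_ = np.sqrt(va), np.sqrt(vp)
    G = spec.r_a * np.outer(sa, sa)
    P = spec.r_P * np.outer(sp_, sp_)
    for name, M in (("G", G), ("P", P)):
        eig = np.linalg.eigvalsh(M)
        if eig.min() <= 0 and name == "P":
            raise ValueError(
                f"{name} matrix for {environment_level!r} is not positive definite "
                f"(min eigenvalue {eig.min():.3g})"
            )
    return G, P


def economic_weights(spec: SelectionIndexSpec) -> np.ndarray:
    """a_s = relative emphasis times genetic SD, per trait (SCS stays 0)."""
    out = np.empty(len(spec.traits))
    for i, t in enumerate(spec.traits):
        a = spec.relative_emphasis.get(t, 0.0)
        if a > 0 and t not in spec.genetic_sd:
            raise ValueError(f"trait {t!r} has emphasis but no genetic SD")
        out[i] = a * spec.genetic_sd.get(t, 1.0)
    return out


def selection_response(
    G: np.ndarray, P: np.ndarray, a_s: np.ndarray, intensity: float,
    environment: str = "", traits: list[str] | None = None,
) -> ResponseResult:
    """Response to one generation of index selection.

    b = P^-1 G a_s; sigma_i = sqrt(b' P b); R = (intensity / sigma_i) G b;
    R_dsi = R / sigma_P elementwise.  A null index (sigma_i = 0) is an error.
    """
    G, P = np.asarray(G, float), np.asarray(P, float)
    a_s = np.asarray(a_s, float)
    b = np.linalg.solve(P, G @ a_s)
    sigma_i2 = float(b @ P @ b)
    if sigma_i2 <= 0:
        raise ValueError("null selection index: sigma_i = 0, response undefined")
    sigma_i = np.sqrt(sigma_i2)
    R = (intensity / sigma_i) * (G @ b)
    R_dsi = R / np.sqrt(np.diag(P))
    if traits is None:
        traits = [f"trait_{i}" for i in range(len(R))]
    return ResponseResult(environment, list(traits), b, sigma_i, R, R_dsi)
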