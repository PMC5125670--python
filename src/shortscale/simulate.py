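"""Seeded generator for guessing-floored dichotomous item responses.

The generative model is a standardized one-factor (2PL-with-guessing) model:
person p answers item i correctly with probability

    P(x_pi = 1) = c + (1 - c) * F(a_i * theta_p - tau_i)

where theta ~ N(0, 1), c is the guessing floor (e.g. .25 for four-alternative
multiple choice), F is a probit (default) or logistic link, and the
discrimination a_i comes from the standardized loading lambda_i through the
usual identity a_i = lambda_i / sqrt(1 - lambda_i^2) (times 1.702 for the
logistic link).  The intercept tau_i is calibrated numerically so that the
*population* proportion correct equals the requested item difficulty — the
guessing floor breaks the closed form, hence root-finding on the marginal.

Covariates are drawn jointly multivariate-normal with theta at declared
trait correlations, mutually independent given theta unless a full covariate
correlation matrix is supplied.  A rank correlation between loadings and
easiness can be imposed by Iman-Conover-style reordering of the difficulty
targets, emulating the easy-item/high-loading confound seen in vocabulary
data, which is what makes greedy loading-maximizing selection go wrong.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .io import ItemResponseMatrix

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_responses",
    "make_ppvt_like_pool",
    "population_marginal",
]

#: marginal-calibration tolerance (absolute, on the proportion-correct scale)
CALIBRATION_TOL = 1e-6

# probabilist Gauss-Hermite rule for E_theta[...] under N(0,1)
_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(81)
_GH_W = _GH_W / _GH_W.sum()


def _resolve_spec(spec, n_items: int, rng: np.random.Generator, what: str) -> np.ndarray:
    """Turn a per-item array or a ("uniform"|"truncnorm", ...) tuple into values."""
    if isinstance(spec, tuple) and spec and isinstance(spec[0], str):
        kind = spec[0]
        if kind == "uniform":
            _, lo, hi = spec
            return rng.uniform(lo, hi, size=n_items)
        if kind == "truncnorm":
            _, loc, scale, lo, hi = spec
            a, b = (lo - loc) / scale, (hi - loc) / scale
            return stats.truncnorm.rvs(
                a, b, loc=loc, scale=scale, size=n_items, random_state=rng
            )
        raise ValueError(f"unknown {what} distribution {kind!r}")
    values = np.asarray(spec, float)
    if values.shape != (n_items,):
        raise ValueError(f"{what} must have one value per item ({n_items})")
    return values


@dataclass
class SimulationConfig:
    """Configuration of one synthetic item-response study."""

    n_persons: int
    n_items: int
    loading_spec: object
    difficulty_spec: object
    guessing: float = 0.25
    covariate_spec: Sequence[tuple[str, float]] = ()
    covariate_corr: np.ndarray | None = None
    loading_difficulty_corr: float | None = None
    link: str = "probit"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be positive")
        if self.n_items < 3:
            raise ValueError("at least 3 items are needed for a one-factor model")
        if not 0.0 <= self.guessing <= 1.0:
            raise ValueError("guessing must lie in [0, 1]")
        if self.link not in ("probit", "logistic"):
            raise ValueError("link must be 'probit' or 'logistic'")
        for name, rho in self.covariate_spec:
            if not -1.0 < rho < 1.0:
                raise ValueError(
                    f"covariate {name!r}: trait correlation must be in (-1, 1)"
                )
        if self.loading_difficulty_corr is not None and not (
            -1.0 < self.loading_difficulty_corr < 1.0
        ):
            raise ValueError("loading_difficulty_corr must be in (-1, 1)")
        # joint (theta, covariates) correlation matrix must be positive definite
        if self.covariate_spec:
            sigma = self.joint_covariance()
            if np.linalg.eigvalsh(sigma)[0] <= 1e-10:
                raise ValueError(
                    "covariate structure is not positive definite"
                )

    def joint_covariance(self) -> np.ndarray:
        """Correlation matrix of (theta, covariate_1, ..., covariate_q)."""
        rho = np.array([r for _, r in self.covariate_spec], float)
        q = len(rho)
        sigma = np.empty((q + 1, q + 1))
        sigma[0, 0] = 1.0
        sigma[0, 1:] = rho
        sigma[1:, 0] = rho
        if self.covariate_corr is not None:
            xx = np.asarray(self.covariate_corr, float)
            if xx.shape != (q, q):
                raise ValueError("covariate_corr must be q x q")
            sigma[1:, 1:] = xx
        else:
            sigma[1:, 1:] = np.outer(rho, rho)
            np.fill_diagonal(sigma[1:, 1:], 1.0)
        return sigma


@dataclass
class TruthRecord:
    """Ground truth exactly as used to generate one data set."""

    latent_traits: np.ndarray
    loadings: np.ndarray
    difficulties: np.ndarray
    guessing: float
    covariate_trait_corrs: dict[str, float]
    link: str
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "latent_traits": self.latent_traits.tolist(),
            "loadings": self.loadings.tolist(),
            "difficulties": self.difficulties.tolist(),
            "guessing": self.guessing,
            "covariate_trait_corrs": self.covariate_trait_corrs,
            "link": self.link,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        return cls(
            latent_traits=np.array(payload["latent_traits"]),
            loadings=np.array(payload["loadings"]),
            difficulties=np.array(payload["difficulties"]),
            guessing=payload["guessing"],
            covariate_trait_corrs=payload["covariate_trait_corrs"],
            link=payload["link"],
            seed=payload["seed"],
        )


def _link_cdf(z: np.ndarray, link: str) -> np.ndarray:
    return stats.norm.cdf(z) if link == "probit" else expit(z)


def _discrimination(lam: np.ndarray, link: str) -> np.ndarray:
    a = lam / np.sqrt(1.0 - lam**2)
    return a if link == "probit" else 1.702 * a


def population_marginal(a: float, tau: float, guessing: float, link: str) -> float:
    """E_theta[c + (1-c) F(a*theta - tau)] under theta ~ N(0, 1)."""
    f = _link_cdf(a * _GH_X - tau, link)
    return float(guessing + (1.0 - guessing) * np.dot(_GH_W, f))


def _calibrate_intercepts(
    a: np.ndarray, targets: np.ndarray, guessing: float, link: str, item_ids
) -> np.ndarray:
    taus = np.empty_like(a)
    for i, (ai, pi) in enumerate(zip(a, targets)):
        if not guessing < pi < 1.0:
            raise ValueError(
                f"item {item_ids[i]}: target difficulty {pi} is unattainable "
                f"with guessing floor {guessing}"
            )
        g = lambda t: population_marginal(ai, t, guessing, link) - pi
        taus[i] = optimize.brentq(g, -60.0, 60.0, xtol=1e-10)
        if abs(g(taus[i])) > CALIBRATION_TOL:
            raise ValueError(f"item {item_ids[i]}: marginal calibration failed")
    return taus


def _impose_rank_corr(
    loadings: np.ndarray, difficulties: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Reorder difficulty targets so rank-corr(loading, difficulty) ~= rho."""
    n = len(loadings)
    z_load = stats.norm.ppf((stats.rankdata(loadings) - 0.375) / (n + 0.25))
    score = rho * z_load + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    ranks = np.argsort(np.argsort(score))  # rank of each item's score
    return np.sort(difficulties)[ranks]


def simulate_responses(
    config: SimulationConfig,
) -> tuple[ItemResponseMatrix, pd.DataFrame, TruthRecord]:
    """Generate responses, covariates, and the ground-truth record.

    Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    loadings = _resolve_spec(config.loading_spec, config.n_items, rng, "loading_spec")
    difficulties = _resolve_spec(
        config.difficulty_spec, config.n_items, rng, "difficulty_spec"
    )
    if np.any(np.abs(loadings) >= 1):
        raise ValueError("standardized loadings must lie in (-1, 1)")
    if config.loading_difficulty_corr is not None:
        difficulties = _impose_rank_corr(
            loadings, difficulties, config.loading_difficulty_corr, rng
        )

    item_ids = tuple(f"item{i + 1:03d}" for i in range(config.n_items))
    cov_names = [name for name, _ in config.covariate_spec]

    # joint draw of (theta, covariates)
    if config.covariate_spec:
        sigma = config.joint_covariance()
        chol = np.linalg.cholesky(sigma)
        z = rng.standard_normal((config.n_persons, sigma.shape[0])) @ chol.T
        theta, cov_values = z[:, 0], z[:, 1:]
    else:
        theta = rng.standard_normal(config.n_persons)
        cov_values = np.empty((config.n_persons, 0))

    c = config.guessing
    if c >= 1.0:
        # degenerate floor: every response is correct regardless of theta
        responses = np.ones((config.n_persons, config.n_items), dtype=np.int8)
    else:
        if np.any(difficulties >= 1.0) or np.any(difficulties <= 0.0):
            raise ValueError("difficulty targets must lie strictly in (0, 1)")
        a = _discrimination(loadings, config.link)
        taus = _calibrate_intercepts(a, difficulties, c, config.link, item_ids)
        prob = c + (1.0 - c) * _link_cdf(theta[:, None] * a - taus, config.link)
        responses = (rng.random((config.n_persons, config.n_items)) < prob).astype(
            np.int8
        )

    data = ItemResponseMatrix(responses, item_ids)
    covariates = pd.DataFrame(cov_values, columns=cov_names)
    truth = TruthRecord(
        latent_traits=theta,
        loadings=loadings,
        difficulties=difficulties,
        guessing=c,
        covariate_trait_corrs=dict(config.covariate_spec),
        link=config.link,
        seed=config.seed,
    )
    return data, covariates, truth


# ---------------------------------------------------------------------------
# the 89-item vocabulary-test-like pool
# ---------------------------------------------------------------------------

#: convergent-to-discriminant covariate panel (name, trait correlation)
PPVT_COVARIATES: tuple[tuple[str, float], ...] = (
    ("reading_competence", 0.65),
    ("reading_speed", 0.50),
    ("math_competence", 0.55),
    ("reasoning", 0.45),
    ("perceptual_speed", 0.25),
    ("german_native", 0.30),
    ("interest_german", 0.15),
    ("motivation_german", 0.10),
    ("age", -0.10),
    ("sex", 0.02),
)


def make_ppvt_like_pool(seed: int, n_persons: int = 3000) -> SimulationConfig:
    """Configuration emulating an 89-item four-alternative vocabulary test.

    Standardized loadings span roughly -.03 to .81 with mean near .41;
    difficulty targets span roughly .28 to .98 with mean near .64 (targets
    below the .25 guessing floor are infeasible under the generative model
    and are excluded by construction).  A strong positive rank correlation
    (0.9) between loadings and easiness reproduces the confound that makes
    stepwise loading-maximizing selection favor easy items; its strength is
    calibrated so that the 15 highest-loading items are very easy on
    average, the defining feature of the instrument being emulated.  The
    covariate panel mixes
    strong convergent, moderate, and near-zero discriminant trait
    correlations.
    """
    rng = np.random.default_rng(seed)
    n_items = 89

    def trunc_quantiles(loc, scale, lo, hi):
        a, b = (lo - loc) / scale, (hi - loc) / scale
        q = (np.arange(n_items) + 0.5) / n_items
        return stats.truncnorm.ppf(q, a, b, loc=loc, scale=scale)

    loadings = trunc_quantiles(0.41, 0.20, -0.03, 0.81)
    difficulties = trunc_quantiles(0.64, 0.18, 0.28, 0.98)
    rng.shuffle(loadings)  # difficulty order is re-imposed against loadings

    return SimulationConfig(
        n_persons=n_persons,
        n_items=n_items,
        loading_spec=loadings,
        difficulty_spec=difficulties,
        guessing=0.25,
        covariate_spec=PPVT_COVARIATES,
        loading_difficulty_corr=0.9,
        link="probit",
        seed=seed,
    )
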