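"""Scoring of short forms against the long form on four criteria.

A candidate subset is judged on: (a) one-factor model fit (chi-square, CFI,
RMSEA), (b) reliability (McDonald's omega), (c) sensitivity (distribution of
item difficulties around the .625 optimum), and (d) validity preservation
(shifts in Pearson correlations between unit-weighted sum scores and the
covariate panel).  ``SubsetScorer`` precomputes everything that does not
depend on the subset — the full-pool tetrachoric matrix, item difficulties,
and the centered cross-product matrices needed for sum-score correlations and
regression R^2 — so that the metaheuristics can evaluate thousands of subsets
cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import cfa
from .io import ItemResponseMatrix
from .objectives import PheromoneComponents

__all__ = ["SubsetScorer", "ShortFormEvaluation", "evaluate_short_form", "compare_methods"]


class SubsetScorer:
    """Precomputed machinery to evaluate item subsets of one data set.

    Parameters
    ----------
    data : ItemResponseMatrix
    covariates : DataFrame or None
        Numeric persons x covariates table (may be empty).
    corr : CorrelationMatrix, optional
        Full-pool tetrachoric matrix; computed on demand when omitted.
    clamp_sens : bool
        Whether the sensitivity pheromone is floored at 0.
    """

    def __init__(
        self,
        data: ItemResponseMatrix,
        covariates: pd.DataFrame | None = None,
        corr: cfa.CorrelationMatrix | None = None,
        clamp_sens: bool = True,
    ) -> None:
        self.data = data
        self.covariates = (
            covariates if covariates is not None else pd.DataFrame(index=range(data.n_persons))
        )
        if len(self.covariates) != data.n_persons:
            raise ValueError("covariates must align with response-matrix rows")
        self.clamp_sens = clamp_sens
        self._corr = corr

        x = data.values.astype(float)
        self.difficulties = x.mean(axis=0)
        xc = x - self.difficulties
        self.item_cov = xc.T @ xc  # centered cross-products, items x items
        self.long_score = x.sum(axis=1)

        z = self.covariates.to_numpy(float)
        zc = z - z.mean(axis=0) if z.size else z
        self.cov_names = tuple(map(str, self.covariates.columns))
        self.item_cov_z = xc.T @ zc  # items x covariates
        self.cov_ss = (zc**2).sum(axis=0) if z.size else np.empty(0)
        # long-form sum-score correlations with each covariate
        total = self.item_cov_z.sum(axis=0)
        long_var = self.item_cov.sum()
        with np.errstate(invalid="ignore"):
            self.long_r = (
                total / np.sqrt(long_var * self.cov_ss) if z.size else np.empty(0)
            )
        self._fit_cache: dict[tuple[int, ...], cfa.CFAFit] = {}

    @property
    def corr(self) -> cfa.CorrelationMatrix:
        if self._corr is None:
            self._corr = cfa.tetrachoric_matrix(self.data)
        return self._corr

    # -- subset-level quantities ------------------------------------------

    def fit(self, indices: Sequence[int]) -> cfa.CFAFit:
        key = tuple(sorted(int(i) for i in indices))
        hit = self._fit_cache.get(key)
        if hit is None:
            hit = cfa.fit_one_factor(self.corr.subset(key), self.data.n_persons)
            self._fit_cache[key] = hit
        return hit

    def delta_r(self, indices: Sequence[int]) -> np.ndarray:
        """Signed shifts (short minus long) in sum-score/covariate correlations."""
        if not self.cov_names:
            return np.empty(0)
        idx = list(indices)
        num = self.item_cov_z[idx].sum(axis=0)
        var = self.item_cov[np.ix_(idx, idx)].sum()
        short_r = num / np.sqrt(var * self.cov_ss)
        return short_r - self.long_r

    def r_squared(self, indices: Sequence[int]) -> float:
        """R^2 of regressing the long-form total score on the subset's items.

        Computed from centered cross-products (intercept implicit); equals the
        OLS coefficient of determination.
        """
        idx = list(indices)
        g = self.item_cov[np.ix_(idx, idx)]
        b = self.item_cov.sum(axis=1)[idx]  # cov of items with long total
        sst = self.item_cov.sum()
        try:
            beta = np.linalg.solve(g, b)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(g, b, rcond=None)
        return float(np.clip(b @ beta / sst, 0.0, 1.0))

    def components(self, indices: Sequence[int]) -> PheromoneComponents:
        """Pheromone components of a subset (fit, reliability, sensitivity, validity)."""
        fit = self.fit(indices)
        if not fit.converged:
            raise cfa_nonconvergence(indices)
        dr = self.delta_r(indices)
        return PheromoneComponents.from_metrics(
            cfi=fit.cfi,
            rmsea=fit.rmsea,
            omega=fit.omega,
            mean_difficulty=float(self.difficulties[list(indices)].mean()),
            max_abs_delta_r=float(np.max(np.abs(dr))) if dr.size else 0.0,
            clamp_sens=self.clamp_sens,
        )

    def objective(self, indices: Sequence[int]) -> float:
        return self.components(indices).total


class NonConvergentFitError(RuntimeError):
    """Raised when the one-factor optimizer fails for a candidate subset."""

    def __init__(self, indices):
        super().__init__(f"one-factor fit did not converge for subset {tuple(indices)}")
        self.indices = tuple(indices)


def cfa_nonconvergence(indices) -> NonConvergentFitError:
    return NonConvergentFitError(indices)


@dataclass(frozen=True)
class ShortFormEvaluation:
    """One short form scored on all four criteria."""

    method: str
    k: int
    item_ids: tuple[str, ...]
    pool_item_ids: tuple[str, ...]
    cfa: cfa.CFAFit
    omega: float
    mean_difficulty: float
    difficulty_range: tuple[float, float]
    loading_summary: dict[str, float]
    delta_r: dict[str, float]
    max_abs_delta_r: float
    phi: PheromoneComponents


def evaluate_short_form(
    data: ItemResponseMatrix,
    covariates: pd.DataFrame | None,
    subset: Sequence[int],
    method: str = "",
    scorer: SubsetScorer | None = None,
) -> ShortFormEvaluation:
    """Fit and score one item subset against the long form.

    ``subset`` holds column indices into ``data``; pass ``scorer`` to reuse a
    precomputed tetrachoric matrix across evaluations.
    """
    if scorer is None:
        scorer = SubsetScorer(data, covariates)
    idx = sorted(int(i) for i in subset)
    if not idx or idx[0] < 0 or idx[-1] >= data.n_items:
        raise ValueError("subset indices out of range")
    fit = scorer.fit(idx)
    dr = scorer.delta_r(idx)
    diffs = scorer.difficulties[idx]
    lam = fit.loadings
    phi = scorer.components(idx)
    return ShortFormEvaluation(
        method=method,
        k=len(idx),
        item_ids=tuple(data.item_ids[i] for i in idx),
        pool_item_ids=data.item_ids,
        cfa=fit,
        omega=fit.omega,
        mean_difficulty=float(diffs.mean()),
        difficulty_range=(float(diffs.min()), float(diffs.max())),
        loading_summary={
            "min": float(lam.min()),
            "median": float(np.median(lam)),
            "mean": float(lam.mean()),
            "max": float(lam.max()),
        },
        delta_r={name: float(d) for name, d in zip(scorer.cov_names, dr)},
        max_abs_delta_r=float(np.max(np.abs(dr))) if dr.size else 0.0,
        phi=phi,
    )


#: conventional good-fit cutoffs for the comparison table
CFI_GOOD = 0.95
RMSEA_GOOD = 0.08


def compare_methods(
    evaluations: Sequence[ShortFormEvaluation],
    reference: ShortFormEvaluation,
) -> pd.DataFrame:
    """Comparison table: one row per short form plus the long-form reference.

    Columns: chi_square, df, cfi, rmsea, omega, mean_difficulty,
    max_abs_delta_r, and a ``good_fit`` flag (CFI >= .95 and RMSEA <= .08).
    """
    if not evaluations:
        raise ValueError("need at least one evaluation")
    pools = {e.pool_item_ids for e in (*evaluations, reference)}
    if len(pools) != 1:
        raise ValueError("evaluations come from different item pools")

    def row(e: ShortFormEvaluation) -> dict:
        return {
            "model": f"{e.method}|{e.k}" if e.method else str(e.k),
            "chi_square": round(e.cfa.chi_square, 2),
            "df": e.cfa.df,
            "cfi": round(e.cfa.cfi, 3),
            "rmsea": round(e.cfa.rmsea, 3),
            "omega": round(e.omega, 3),
            "mean_difficulty": round(e.mean_difficulty, 3),
            "max_abs_delta_r": round(e.max_abs_delta_r, 3),
            "good_fit": bool(e.cfa.cfi >= CFI_GOOD and e.cfa.rmsea <= RMSEA_GOOD),
        }

    frame = pd.DataFrame([row(e) for e in evaluations] + [row(reference)])
    return frame.reset_index(drop=True)


def plot_comparison(
    evaluations: Sequence[ShortFormEvaluation],
    reference: ShortFormEvaluation,
    out_dir,
) -> list:
    """Optional matplotlib figures: difficulty distributions and the dr matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    labels = [f"{e.method}|{e.k}" for e in evaluations] + [f"all|{reference.k}"]

    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    # difficulty distributions are summarized from the scored subsets
    ax.boxplot(
        [list(e.loading_summary.values()) for e in (*evaluations, reference)],
        tick_labels=labels,
    )
    ax.set_ylabel("factor loading (summary points)")
    fig.tight_layout()
    p = out_dir / "loadings.png"
    fig.savefig(p)
    plt.close(fig)
    written.append(p)

    dr = pd.DataFrame(
        {f"{e.method}|{e.k}": e.delta_r for e in evaluations}
    )
    fig, ax = plt.subplots(figsize=(2 + 1.2 * len(evaluations), 0.5 * max(len(dr), 2) + 2))
    im = ax.imshow(dr.to_numpy(), cmap="RdBu_r", vmin=-0.15, vmax=0.15, aspect="auto")
    ax.set_xticks(range(dr.shape[1]), dr.columns, rotation=45)
    ax.set_yticks(range(dr.shape[0]), dr.index)
    fig.colorbar(im, ax=ax, label="delta r (short - long)")
    fig.tight_layout()
    p = out_dir / "delta_r.png"
    fig.savefig(p)
    plt.close(fig)
    written.append(p)
    return written
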