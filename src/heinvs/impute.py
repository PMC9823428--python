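"""Multiple imputation of the trial panel and Rubin's-rules pooling.

The panel is imputed in wide format (one column per variable x timepoint)
with chained equations: each incomplete column is regressed on study arm,
the baseline value of the same variable, and the concurrent values of the
other variables.  Draws are predictive-mean-matching by default (robust to
the bounded, non-normal score margins) with Bayesian-normal draws behind a
flag.  Baseline columns must be complete — the study design examines every
subject before any dropout — so follow-up columns always condition on an
observed anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .records import COMPONENTS, TIMEPOINTS, TrialDataset, ValidationError
from .scoring import MAX_TOTAL, ReferenceTable

logger = logging.getLogger(__name__)


@dataclass
class ImputedSet:
    """m completed panels plus a description of how they were produced."""

    datasets: list[TrialDataset]
    method: str
    seed: int | None

    @property
    def m(self) -> int:
        return len(self.datasets)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of m (estimate, SE) pairs.

    ``variance = within + (1 + 1/m) * between``; degrees of freedom follow
    Barnard-Rubin when a complete-data df is supplied, otherwise the classic
    large-sample formula.
    """

    estimate: float
    se: float
    within: float
    between: float
    df: float
    m: int


def pool(
    estimates: Sequence[tuple[float, float]], dfcom: float | None = None
) -> PooledEstimate:
    """Combine per-imputation estimates and standard errors."""
    if len(estimates) < 2:
        raise ValidationError("pooling requires at least 2 estimates")
    est = np.asarray([e for e, _ in estimates], dtype=float)
    ses = np.asarray([s for _, s in estimates], dtype=float)
    if (ses <= 0).any():
        raise ValidationError("standard errors must be positive")
    m = len(est)
    qbar = est.mean()
    w = float((ses**2).mean())
    b = float(est.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = np.inf
    else:
        lam = (1.0 + 1.0 / m) * b / t
        df_old = (m - 1) / lam**2
        if dfcom is None or not np.isfinite(dfcom):
            df = df_old
        else:
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    return PooledEstimate(
        estimate=float(qbar), se=float(np.sqrt(t)), within=w, between=b, df=float(df), m=m
    )


def _score_bounds() -> dict[str, tuple[float, float]]:
    refs = ReferenceTable.default()
    bounds = {c: (0.0, refs[c].max_points) for c in COMPONENTS}
    bounds["hei_nvs_total"] = (0.0, MAX_TOTAL)
    return bounds


class ChainedEquationsImputer(BaseEstimator):
    """Multiple imputation by chained equations on the wide trial panel.

    Parameters
    ----------
    m : int
        Number of completed datasets (the primary analysis uses 50).
    method : {"pmm", "bayes"}
        Predictive-mean matching (default, donor pool ``k_pmm``) or
        Bayesian-normal draws via iterative regression imputation.
    k_pmm : int
        Donor-pool size for PMM.
    burn_in, n_between : int
        Chained-equation cycles before the first draw and between draws.
    clamp_scores : bool
        Clamp imputed component scores to [0, max] and the total to [0, 110].
    random_state : int or None
        Seed for all stochastic draws.
    """

    def __init__(
        self,
        m: int = 50,
        method: str = "pmm",
        k_pmm: int = 5,
        burn_in: int = 5,
        n_between: int = 3,
        clamp_scores: bool = True,
        random_state: int | None = None,
    ):
        self.m = m
        self.method = method
        self.k_pmm = k_pmm
        self.burn_in = burn_in
        self.n_between = n_between
        self.clamp_scores = clamp_scores
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit_transform(self, dataset: TrialDataset, y=None) -> ImputedSet:
        if self.m < 2:
            raise ValidationError("m must be >= 2")
        if self.method not in ("pmm", "bayes"):
            raise ValidationError(f"unknown method {self.method!r}")

        wide = dataset.to_wide()
        groups = dataset.groups()
        zero_obs = [c for c in wide.columns if wide[c].notna().sum() == 0]
        if zero_obs:
            raise ValidationError(f"variables with no observed values: {zero_obs}")
        base_cols = [c for c in wide.columns if c.endswith("__t0")]
        if wide[base_cols].isna().any().any():
            raise ValidationError("baseline (t0) values must be complete")

        if dataset.is_complete():
            out = [dataset.copy() for _ in range(self.m)]
            self.n_cells_imputed_ = 0
            return ImputedSet(out, self.method, self.random_state)

        seed = self.random_state
        sub_seeds = np.random.SeedSequence(seed).generate_state(self.m + 1) % (2**31)
        if self.method == "pmm":
            completed = self._run_pmm(wide, groups, int(sub_seeds[0]))
        else:
            completed = self._run_bayes(wide, groups, sub_seeds[1:])

        bounds = _score_bounds() if self.clamp_scores else {}
        datasets = []
        for df in completed:
            for col in df.columns:
                var = col.rsplit("__", 1)[0]
                if var in bounds:
                    lo, hi = bounds[var]
                    was_missing = wide[col].isna()
                    df.loc[was_missing, col] = df.loc[was_missing, col].clip(lo, hi)
            datasets.append(TrialDataset.from_wide(df, groups))
        self.n_cells_imputed_ = int(wide.isna().sum().sum())
        return ImputedSet(datasets, self.method, seed)

    # ------------------------------------------------------------------
    def _predictor_columns(self, col: str, columns: Sequence[str]) -> list[str]:
        """Imputation model for ``var__tp``: arm, baseline of the same
        variable, and the concurrent values of the other variables."""
        var, tp = col.rsplit("__", 1)
        preds = ["group_control", f"{var}__t0"]
        preds += [
            c
            for c in columns
            if c.endswith(f"__{tp}") and c.rsplit("__", 1)[0] != var
        ]
        return preds

    def _run_pmm(
        self, wide: pd.DataFrame, groups: pd.Series, seed: int
    ) -> list[pd.DataFrame]:
        """Chained equations with predictive-mean matching.

        One independent chain per imputation: start from random observed
        draws, cycle each incomplete column ``burn_in + n_between`` times.
        Per column: OLS on the observed rows, gaussian perturbation of the
        coefficients from their sampling distribution, then each missing
        cell receives the observed value of a donor drawn uniformly from
        the ``k_pmm`` nearest predicted means.
        """
        rng = np.random.default_rng(seed)
        cols = list(wide.columns)
        col_ix = {c: i for i, c in enumerate(cols)}
        arr0 = wide.to_numpy(dtype=float)
        group_control = (groups.reindex(wide.index) == "control").to_numpy(dtype=float)
        incomplete = [c for c in cols if wide[c].isna().any()]
        miss = {c: np.isnan(arr0[:, col_ix[c]]) for c in incomplete}
        pred_ix = {
            c: [col_ix[p] for p in self._predictor_columns(c, cols) if p != "group_control"]
            for c in incomplete
        }
        n_cycles = self.burn_in + self.n_between
        out = []
        for _ in range(self.m):
            arr = arr0.copy()
            for c in incomplete:  # initial fill: random observed donors
                j = col_ix[c]
                mis = miss[c]
                obs_vals = arr0[~mis, j]
                arr[mis, j] = rng.choice(obs_vals, size=int(mis.sum()), replace=True)
            for _cycle in range(n_cycles):
                for c in incomplete:
                    j = col_ix[c]
                    mis = miss[c]
                    X = np.column_stack(
                        [np.ones(len(arr)), group_control, arr[:, pred_ix[c]]]
                    )
                    y_obs = arr0[~mis, j]
                    X_obs = X[~mis]
                    beta, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
                    resid = y_obs - X_obs @ beta
                    dof = max(len(y_obs) - X.shape[1], 1)
                    sigma2 = float(resid @ resid) / dof
                    xtx = X_obs.T @ X_obs + 1e-8 * np.eye(X.shape[1])
                    cov = sigma2 * np.linalg.pinv(xtx)
                    # collinear predictors (e.g. a total alongside its
                    # components) can leave cov only PSD; draw via eigh
                    evals, evecs = np.linalg.eigh((cov + cov.T) / 2.0)
                    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
                    beta_star = beta + root @ rng.standard_normal(len(beta))
                    yhat_obs = X_obs @ beta
                    yhat_mis = X[mis] @ beta_star
                    # k nearest observed predicted means per missing cell
                    d = np.abs(yhat_mis[:, None] - yhat_obs[None, :])
                    k = min(self.k_pmm, d.shape[1])
                    donors = np.argpartition(d, k - 1, axis=1)[:, :k]
                    pick = donors[np.arange(len(yhat_mis)), rng.integers(0, k, len(yhat_mis))]
                    arr[mis, j] = y_obs[pick]
            out.append(pd.DataFrame(arr, index=wide.index, columns=cols))
        return out

    def _run_bayes(
        self, wide: pd.DataFrame, groups: pd.Series, seeds: np.ndarray
    ) -> list[pd.DataFrame]:
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer

        work = wide.copy()
        work["group_control"] = (groups.reindex(work.index) == "control").astype(float)
        out = []
        for s in seeds:
            imp = IterativeImputer(
                sample_posterior=True,
                max_iter=self.burn_in + self.n_between,
                random_state=int(s),
                keep_empty_features=True,
            )
            filled = imp.fit_transform(work.to_numpy(dtype=float))
            df = pd.DataFrame(filled, index=wide.index, columns=work.columns)
            out.append(df[list(wide.columns)].copy())
        return out


def impute(
    dataset: TrialDataset,
    m: int = 50,
    seed: int | None = None,
    method: str = "pmm",
    **kwargs,
) -> ImputedSet:
    """Functional wrapper over :class:`ChainedEquationsImputer`."""
    return ChainedEquationsImputer(
        m=m, method=method, random_state=seed, **kwargs
    ).fit_transform(dataset)
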