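"""Robust linear mixed model for the trial outcome and within-group effects.

Model: ``y_ij = b0 + sum_t b_t 1[time=t] + b_g 1[control]
+ sum_t b_tg 1[time=t] 1[control] + u_i + e_ij`` with a subject random
intercept.  Reference levels are baseline (t0) and the intervention arm,
so the eight fixed effects read exactly like the trial's coefficient
table: three time contrasts, a group main effect, three time-by-group
interactions, and the intercept.

The fit is robustified by iteratively reweighted generalized least
squares: Huber weights (tuning constant 1.345, 95% efficiency at the
normal) on conditional residuals scaled by a MAD estimate, with
moment-based robust updates of the residual and between-subject
variances.  With the tuning constant at infinity all weights are one and
the fit reduces to the exact maximum-likelihood solution (profiled over
the variance ratio), which is what an external ML mixed-model fitter
produces on the same data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .impute import ImputedSet, PooledEstimate, pool
from .records import TIMEPOINTS, TrialDataset, ValidationError

logger = logging.getLogger(__name__)

#: Fixed-effect names, in design-matrix order.
COEF_NAMES: tuple[str, ...] = (
    "Intercept",
    "t0-t1",
    "t0-t2",
    "t0-t3",
    "group_control",
    "t0-t1:group_control",
    "t0-t2:group_control",
    "t0-t3:group_control",
)

HUBER_C = 1.345
_MAD_SCALE = 1.4826


class ConvergenceError(RuntimeError):
    """IRLS failed to reach the coefficient tolerance; carries the trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class EffectSize:
    """Within-group standardized change (Cohen's d) with its 95% CI."""

    group: str
    interval: str
    d: float
    ci_low: float
    ci_high: float
    n: int

    @property
    def magnitude(self) -> str:
        """Conventional |d| reading: 0.2 small, 0.5 medium, 0.8 large."""
        a = abs(self.d)
        if a >= 0.8:
            return "large"
        if a >= 0.5:
            return "medium"
        if a >= 0.2:
            return "small"
        return "negligible"


def _extract(dataset: TrialDataset | pd.DataFrame, outcome: str) -> pd.DataFrame:
    df = dataset.data if isinstance(dataset, TrialDataset) else dataset
    sub = df[(df["variable"] == outcome) & df["value"].notna()]
    if sub.empty:
        raise ValidationError(f"outcome {outcome!r} has no observed values")
    return sub

def _design(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tp = sub["timepoint"].to_numpy()
    ctrl = (sub["group"] == "control").to_numpy(dtype=float)
    cols = [np.ones(len(sub))]
    cols += [(tp == t).astype(float) for t in TIMEPOINTS[1:]]
    cols.append(ctrl)
    cols += [(tp == t).astype(float) * ctrl for t in TIMEPOINTS[1:]]
    X = np.column_stack(cols)
    y = sub["value"].to_numpy(dtype=float)
    subjects, idx = np.unique(sub["subject_id"].to_numpy(), return_inverse=True)
    return X, y, idx


class _GLSWorkspace:
    """Per-subject sufficient statistics for the random-intercept GLS."""

    def __init__(self, X: np.ndarray, y: np.ndarray, idx: np.ndarray):
        self.X, self.y, self.idx = X, y, idx
        self.n, self.p = X.shape
        self.n_groups = int(idx.max()) + 1

    def solve(self, lam: float, w: np.ndarray):
        """GLS coefficients for V_i = sigma_e^2 (diag(1/w) + lam 11')."""
        X, y, idx = self.X, self.y, self.idx
        s = np.bincount(idx, weights=w, minlength=self.n_groups)
        shrink = lam / (1.0 + lam * s)
        Sx = np.zeros((self.n_groups, self.p))
        np.add.at(Sx, idx, X * w[:, None])
        Sy = np.bincount(idx, weights=w * y, minlength=self.n_groups)
        XtWX = X.T @ (X * w[:, None])
        XtWy = X.T @ (w * y)
        M = XtWX - Sx.T @ (Sx * shrink[:, None])
        v = XtWy - Sx.T @ (Sy * shrink)
        beta = np.linalg.solve(M, v)
        r = y - X @ beta
        Swr = np.bincount(idx, weights=w * r, minlength=self.n_groups)
        quad = float(np.sum(w * r * r) - np.sum(shrink * Swr**2))
        return beta, M, quad, s, Swr

    def profiled_nll(self, log_lam: float, w: np.ndarray) -> float:
        lam = math.exp(log_lam)
        _, _, quad, s, _ = self.solve(lam, w)
        sigma2 = max(quad / self.n, 1e-300)
        logdet = float(np.sum(np.log1p(lam * s)) - np.sum(np.log(w)))
        return 0.5 * (self.n * math.log(sigma2) + logdet + self.n)


def _ml_fit(ws: _GLSWorkspace, w: np.ndarray):
    """Maximum-likelihood fit profiled over the variance ratio lambda."""
    res = optimize.minimize_scalar(
        ws.profiled_nll, args=(w,), bounds=(-25.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = math.exp(res.x)
    # compare against the boundary (no random effect)
    if ws.profiled_nll(-40.0, w) < res.fun:
        lam = 0.0
    beta, M, quad, s, Swr = ws.solve(lam, w)
    sigma2_e = max(quad / ws.n, 1e-300)
    return beta, M, lam, sigma2_e


class RobustLinearMixedModel(BaseEstimator):
    """Huber-robust random-intercept model for a trial outcome.

    Parameters
    ----------
    huber_c : float
        Huber tuning constant on scaled conditional residuals; ``inf``
        disables robustification (all weights 1, exact ML fit).
    robust : bool
        Convenience switch; ``False`` is equivalent to ``huber_c=inf``.
    tol, max_iter : float, int
        IRLS stopping rule on the max absolute coefficient change.
    scale_update_iters : int
        Iterations during which the residual scale and variance components
        are re-estimated; they are then frozen so the coefficient
        iteration can contract to ``tol``.

    Fitted attributes: ``coef_``, ``se_``, ``pvalues_`` (Wald, normal
    approximation), ``weights_``, ``sigma_u_``, ``sigma_e_``, ``n_iter_``,
    ``converged_``, ``iteration_trace_``.
    """

    def __init__(
        self,
        huber_c: float = HUBER_C,
        robust: bool = True,
        tol: float = 1e-8,
        max_iter: int = 100,
        scale_update_iters: int = 20,
    ):
        self.huber_c = huber_c
        self.robust = robust
        self.tol = tol
        self.max_iter = max_iter
        self.scale_update_iters = scale_update_iters

    # ------------------------------------------------------------------
    def fit(
        self, dataset: TrialDataset | pd.DataFrame, outcome: str = "hei_nvs_total"
    ) -> "RobustLinearMixedModel":
        sub = _extract(dataset, outcome)
        if sub["timepoint"].nunique() < 2:
            raise ValidationError("outcome must be observed at >= 2 timepoints")
        per_group = sub.groupby("group")["subject_id"].nunique()
        if len(per_group) < 2 or (per_group < 2).any():
            raise ValidationError("need >= 2 subjects in each arm")
        X, y, idx = _design(sub)
        ws = _GLSWorkspace(X, y, idx)

        w = np.ones(ws.n)
        beta, M, lam, sigma2_e = _ml_fit(ws, w)
        trace: list[float] = []
        n_iter = 0
        converged = True

        c = self.huber_c if self.robust else math.inf
        if math.isfinite(c):
            sigma_e = math.sqrt(sigma2_e)
            converged = False
            for it in range(1, self.max_iter + 1):
                n_iter = it
                r = y - X @ beta
                s = np.bincount(idx, weights=w, minlength=ws.n_groups)
                Swr = np.bincount(idx, weights=w * r, minlength=ws.n_groups)
                u = lam * Swr / (1.0 + lam * s)  # random-intercept BLUPs
                e = r - u[idx]
                if it <= self.scale_update_iters:
                    mad = np.median(np.abs(e - np.median(e)))
                    if mad > 1e-12:
                        sigma_e = _MAD_SCALE * float(mad)
                    # moment-based robust between-subject variance
                    n_i = np.bincount(idx, minlength=ws.n_groups).astype(float)
                    ubar = np.bincount(idx, weights=r, minlength=ws.n_groups) / n_i
                    mad_u = np.median(np.abs(ubar - np.median(ubar)))
                    var_u = max(
                        (_MAD_SCALE * float(mad_u)) ** 2
                        - sigma_e**2 * float(np.mean(1.0 / n_i)),
                        0.0,
                    )
                    lam = var_u / sigma_e**2 if sigma_e > 0 else 0.0
                z = np.abs(e) / max(sigma_e, 1e-12)
                w = np.minimum(1.0, c / np.maximum(z, 1e-12))
                beta_new, M, quad, _, _ = ws.solve(lam, w)
                step = float(np.max(np.abs(beta_new - beta)))
                trace.append(step)
                beta = beta_new
                # tolerance is relative to the coefficient scale so that
                # large-intercept outcomes are not held to machine precision
                if step < self.tol * (1.0 + float(np.max(np.abs(beta)))):
                    converged = True
                    break
            if not converged:
                raise ConvergenceError(
                    f"IRLS did not converge in {self.max_iter} iterations "
                    f"(last step {trace[-1]:.3e})",
                    trace,
                )
            sigma2_e = sigma_e**2
        if lam < 1e-10:
            logger.warning(
                "between-subject variance is effectively zero; "
                "fit reduces to a fixed-effects model"
            )

        cov = sigma2_e * np.linalg.inv(M)
        se = np.sqrt(np.diag(cov))
        zstat = beta / se
        self.coef_ = pd.Series(beta, index=list(COEF_NAMES))
        self.se_ = pd.Series(se, index=list(COEF_NAMES))
        self.zvalues_ = pd.Series(zstat, index=list(COEF_NAMES))
        self.pvalues_ = pd.Series(
            2.0 * stats.norm.sf(np.abs(zstat)), index=list(COEF_NAMES)
        )
        self.cov_ = pd.DataFrame(cov, index=list(COEF_NAMES), columns=list(COEF_NAMES))
        self.weights_ = w
        self.sigma_e_ = math.sqrt(sigma2_e)
        self.sigma_u_ = math.sqrt(lam * sigma2_e)
        self.lambda_ = lam
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.iteration_trace_ = trace
        self.n_obs_ = ws.n
        self.n_subjects_ = ws.n_groups
        self.outcome_ = outcome
        return self

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, z, p."""
        return pd.DataFrame(
            {
                "coef": self.coef_,
                "se": self.se_,
                "z": self.zvalues_,
                "p": self.pvalues_,
            }
        )


def fit_robust_lmm(
    dataset: TrialDataset | pd.DataFrame,
    outcome: str = "hei_nvs_total",
    **kwargs,
) -> RobustLinearMixedModel:
    """Fit the robust random-intercept model; see the class for options."""
    return RobustLinearMixedModel(**kwargs).fit(dataset, outcome)


@dataclass
class PooledModelFit:
    """Rubin-pooled coefficient table across imputations."""

    coef: pd.Series
    se: pd.Series
    df: pd.Series
    pvalues: pd.Series
    m: int
    per_imputation: list[RobustLinearMixedModel]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "df": self.df, "p": self.pvalues}
        )


def fit_pooled(
    imputed: ImputedSet, outcome: str = "hei_nvs_total", **kwargs
) -> PooledModelFit:
    """Fit the robust model on every completed dataset and pool the results."""
    fits: list[RobustLinearMixedModel] = []
    failures = 0
    for k, ds in enumerate(imputed.datasets):
        try:
            fits.append(fit_robust_lmm(ds, outcome, **kwargs))
        except (ConvergenceError, ValidationError, np.linalg.LinAlgError) as exc:
            failures += 1
            logger.warning("fit on imputation %d failed: %s", k, exc)
    if failures > 0.2 * imputed.m:
        raise ValidationError(
            f"{failures}/{imputed.m} per-imputation fits failed; aborting"
        )
    names = list(COEF_NAMES)
    coefs, ses, dfs, ps = {}, {}, {}, {}
    for name in names:
        pooled = pool([(f.coef_[name], f.se_[name]) for f in fits])
        coefs[name] = pooled.estimate
        ses[name] = pooled.se
        dfs[name] = pooled.df
        tstat = pooled.estimate / pooled.se
        if np.isfinite(pooled.df):
            ps[name] = 2.0 * stats.t.sf(abs(tstat), pooled.df)
        else:
            ps[name] = 2.0 * stats.norm.sf(abs(tstat))
    return PooledModelFit(
        coef=pd.Series(coefs)[names],
        se=pd.Series(ses)[names],
        df=pd.Series(dfs)[names],
        pvalues=pd.Series(ps)[names],
        m=len(fits),
        per_imputation=fits,
    )


def _interval_endpoint(interval: str) -> str:
    """'t0-t2' -> 't2' (also accepts a bare endpoint like 't2')."""
    end = interval.split("-")[-1].strip()
    if end not in TIMEPOINTS[1:]:
        raise ValidationError(f"bad interval {interval!r}")
    return end


def cohens_d(
    dataset: TrialDataset | pd.DataFrame,
    group: str,
    interval: str,
    outcome: str = "hei_nvs_total",
) -> EffectSize:
    """Within-group standardized change ``d = mean(delta) / SD(delta)``.

    ``delta`` is the follow-up minus baseline value per subject; the CI is
    ``d +/- 1.96 * sqrt(1/n + d^2/(2n))``.
    """
    end = _interval_endpoint(interval)
    sub = _extract(dataset, outcome)
    sub = sub[sub["group"] == group]
    pivot = sub.pivot(index="subject_id", columns="timepoint", values="value")
    if "t0" not in pivot.columns or end not in pivot.columns:
        raise ValidationError(f"both t0 and {end} must be observed in group {group!r}")
    pair = pivot[["t0", end]].dropna()
    if len(pair) < 2:
        raise ValidationError("need >= 2 subjects with both endpoint values")
    delta = (pair[end] - pair["t0"]).to_numpy(dtype=float)
    sd = delta.std(ddof=1)
    if sd == 0:
        raise ValidationError("change scores are constant; d undefined")
    n = len(delta)
    d = float(delta.mean() / sd)
    half = 1.96 * math.sqrt(1.0 / n + d * d / (2.0 * n))
    return EffectSize(group, f"t0-{end}", d, d - half, d + half, n)


def pooled_cohens_d(
    imputed: ImputedSet, group: str, interval: str, outcome: str = "hei_nvs_total"
) -> EffectSize:
    """Rubin-pooled within-group effect size across imputations."""
    per = [cohens_d(ds, group, interval, outcome) for ds in imputed.datasets]
    n = per[0].n
    pairs = [(e.d, (e.ci_high - e.ci_low) / (2 * 1.96)) for e in per]
    pooled = pool(pairs)
    half = 1.96 * pooled.se
    return EffectSize(
        group, per[0].interval, pooled.estimate, pooled.estimate - half,
        pooled.estimate + half, n,
    )
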