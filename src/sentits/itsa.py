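"""Per-policy interrupted time series analysis (segmented regression).

For each policy j the merged sentiment rate is modelled over the window
running from the start of the series through the 30th point after the
(lagged) intervention date:

    rate_t = beta0 + beta1 * t + beta2 * level_t + beta3 * trend_t + e_t

where ``level_t`` switches from 0 to 1 at the first series point dated on
or after the intervention and ``trend_t`` counts 1, 2, 3, ... from that
point on.  beta2 is the immediate level change, beta3 the change in slope
per time point.  The model is first fit by OLS; if Ljung-Box diagnostics
find significant residual autocorrelation the regression is refit with
ARMA(p, q) errors (p, q <= 2, order chosen by AIC), falling back to OLS
with Newey-West (HAC) standard errors if the ARMA fit does not converge.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.stats.stattools import durbin_watson

from .types import PolicyEvent, SegmentedFit, SeriesPoint

logger = logging.getLogger(__name__)

OUTCOMES = ("support_rate", "blame_rate")
ARMA_CANDIDATES = tuple(
    (p, q) for p in range(3) for q in range(3) if (p, q) != (0, 0)
)


def build_design(
    series: Sequence[SeriesPoint],
    policy: PolicyEvent,
    outcome: str = "support_rate",
    post_points: int = 30,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Design matrix and response for one policy's segmented regression.

    Rows cover the series from its start through the ``post_points``-th
    point after the intervention (fewer if the series ends first); columns
    are [1, t, level, trend].  Returns (X, y, intervention_row).
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    if not series:
        raise ValueError("empty series")
    effect_date = policy.effect_date
    idx = next((i for i, p in enumerate(series) if p.date >= effect_date), None)
    if idx is None or idx == 0:
        raise ValueError(
            f"policy {policy.policy_id} intervention date {effect_date} "
            "falls outside the series"
        )
    if idx < 3:
        raise ValueError(
            f"policy {policy.policy_id}: fewer than 3 pre-intervention points"
        )
    n_post = len(series) - idx
    if n_post < 3:
        warnings.warn(
            f"policy {policy.policy_id}: post-intervention window truncated "
            f"to {n_post} points"
        )
    used = list(series[: idx + min(post_points, n_post)])
    t = np.array([p.t for p in used], dtype=float)
    level = np.array([1.0 if i >= idx else 0.0 for i in range(len(used))])
    trend = np.array(
        [float(i - idx + 1) if i >= idx else 0.0 for i in range(len(used))]
    )
    X = np.column_stack([np.ones(len(used)), t, level, trend])
    y = np.array([getattr(p, outcome) for p in used])
    return X, y, idx


def _select_arma_order(resid: np.ndarray) -> tuple[int, int]:
    """Rank candidate ARMA orders by BIC on the OLS residuals.

    BIC rather than AIC: at the window sizes involved (tens to a couple of
    hundred points) AIC routinely picks over-parameterized ARMA(2,2) models
    whose likelihood ridge defeats the optimizer, while BIC recovers the
    generating order.
    """
    best, best_ic = (1, 0), np.inf
    for order in ARMA_CANDIDATES:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.tsa.ARIMA(resid, order=(order[0], 0, order[1]),
                                   trend="n").fit()
            if np.isfinite(res.bic) and res.bic < best_ic:
                best, best_ic = order, res.bic
        except Exception:                                   # noqa: BLE001
            continue
    return best


def fit_segmented(
    series: Sequence[SeriesPoint],
    policy: PolicyEvent,
    outcome: str = "support_rate",
    post_points: int = 30,
    alpha: float = 0.05,
    error_mode: str = "auto",
) -> SegmentedFit:
    """Fit the segmented regression for one policy.

    ``error_mode`` is ``"auto"`` (refit with ARMA errors only when
    Ljung-Box, lags <= 10, flags residual autocorrelation at ``alpha``),
    ``"ols"`` (never refit) or ``"arma"`` (always refit).
    """
    if error_mode not in ("auto", "ols", "arma"):
        raise ValueError("error_mode must be auto, ols or arma")
    X, y, idx = build_design(series, policy, outcome, post_points)
    n = len(y)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"policy {policy.policy_id}: singular design matrix")
    ols = sm.OLS(y, X).fit()
    resid = ols.resid
    window = (int(X[0, 1]), int(X[-1, 1]))

    perfect = float(np.var(resid)) < 1e-24
    dw = float(durbin_watson(resid)) if not perfect else None
    lb_min_p = None
    if not perfect:
        lags = max(1, min(10, n // 3))
        lb = acorr_ljungbox(resid, lags=lags, return_df=True)
        lb_min_p = float(np.nanmin(lb["lb_pvalue"].to_numpy()))

    intervention_t = int(X[idx, 1])

    def _from_ols(res, model_name):
        return SegmentedFit(
            policy_id=policy.policy_id,
            policy_date=policy.promulgation_date,
            outcome=outcome,
            beta0=float(res.params[0]), beta1=float(res.params[1]),
            beta2=float(res.params[2]), beta3=float(res.params[3]),
            se=tuple(float(s) for s in res.bse[:4]),
            pvalues=tuple(float(p) for p in res.pvalues[:4]),
            window=window,
            n_points=n,
            error_model=model_name,
            intervention_t=intervention_t,
            durbin_watson=dw,
            ljung_box_min_p=lb_min_p,
        )

    want_arma = error_mode == "arma" or (
        error_mode == "auto" and lb_min_p is not None and lb_min_p < alpha
    )
    if not want_arma or perfect:
        return _from_ols(ols, "iid")

    order = _select_arma_order(resid)
    try:
        # scale design columns to comparable magnitude: the raw time column
        # (values up to a few hundred against coefficients of ~1e-3) breaks
        # the L-BFGS line search; estimates are rescaled back afterwards
        scale = np.abs(X).max(axis=0)
        scale[scale == 0] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = sm.tsa.SARIMAX(
                y, exog=X / scale, order=(order[0], 0, order[1]), trend="n",
                enforce_stationarity=True, enforce_invertibility=True,
            )
            res = mod.fit(disp=0)
        converged = bool(res.mle_retvals.get("converged", True))
        if not converged or not np.all(np.isfinite(res.bse[:4])):
            raise RuntimeError("ARMA-error fit did not converge")

        class _Rescaled:
            params = res.params[:4] / scale
            bse = res.bse[:4] / scale
            pvalues = res.pvalues[:4]

        fit = _from_ols(_Rescaled, f"ARMA({order[0]},{order[1]})")
        fit.arma_order = order
        return fit
    except Exception as exc:                                # noqa: BLE001
        logger.warning(
            "policy %d: ARMA-error refit failed (%s); falling back to OLS "
            "with HAC standard errors", policy.policy_id, exc,
        )
        maxlags = int(np.floor(4 * (n / 100.0) ** (2.0 / 9.0)))
        hac = sm.OLS(y, X).fit(cov_type="HAC", cov_kwds={"maxlags": max(1, maxlags)})
        return _from_ols(hac, "ols_hac")


def summarize_policies(
    series: Sequence[SeriesPoint],
    schedule: Sequence[PolicyEvent],
    outcome: str = "support_rate",
    post_points: int = 30,
    alpha: float = 0.05,
    error_mode: str = "auto",
) -> list[SegmentedFit]:
    """One segmented fit per policy (separate single-interruption models)."""
    fits = []
    for policy in schedule:
        fits.append(
            fit_segmented(series, policy, outcome, post_points, alpha, error_mode)
        )
    return fits


def fits_table(fits: Sequence[SegmentedFit]) -> pd.DataFrame:
    """Fit results in the published table layout:
    policy, policy date, beta1, P, beta2, P, beta3, P (3-decimal betas)."""
    rows = []
    for f in fits:
        _, p1, p2, p3 = f.pvalues
        rows.append(
            {
                "policy": f.policy_id,
                "policy_date": f.policy_date.isoformat(),
                "beta1": round(f.beta1, 3), "p_beta1": round(p1, 3) if p1 == p1 else np.nan,
                "beta2": round(f.beta2, 3), "p_beta2": round(p2, 3) if p2 == p2 else np.nan,
                "beta3": round(f.beta3, 3), "p_beta3": round(p3, 3) if p3 == p3 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def aggregate_fits(
    table: pd.DataFrame | Sequence[SegmentedFit],
    policy_ids: Sequence[int],
) -> dict[str, float]:
    """Aggregates over a stated policy range of a fit table.

    Reports both the sum and the mean of the level changes (beta2) and of
    the trend changes (beta3), each rounded to 3 decimals, since published
    summaries sometimes quote the one and sometimes the other.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(
            [{"policy": f.policy_id, "beta2": f.beta2, "beta3": f.beta3} for f in table]
        )
    sel = table[table["policy"].isin(list(policy_ids))]
    if sel.empty:
        raise ValueError("no fits in the requested policy range")
    return {
        "beta2_sum": round(float(sel["beta2"].sum()), 3),
        "beta2_mean": round(float(sel["beta2"].mean()), 3),
        "beta3_sum": round(float(sel["beta3"].sum()), 3),
        "beta3_mean": round(float(sel["beta3"].mean()), 3),
        "n_policies": int(len(sel)),
    }


def plot_fit(series: Sequence[SeriesPoint], fit: SegmentedFit, ax=None):
    """Observed rates with fitted pre/post trend lines and a dashed vertical
    line at the intervention point (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    t_all = np.array([p.t for p in series], dtype=float)
    y_all = np.array([getattr(p, fit.outcome) for p in series])
    ax.plot(t_all, y_all, ".", color="0.6", ms=4, label="observed")
    t0, t1 = fit.window
    tw = np.array([tt for tt in t_all if t0 <= tt <= t1])
    if fit.intervention_t is None:
        raise ValueError("fit has no recorded intervention point")
    post = tw >= fit.intervention_t
    pre_line = fit.beta0 + fit.beta1 * tw
    trend = np.cumsum(post) * post
    post_line = pre_line + fit.beta2 + fit.beta3 * trend
    ax.plot(tw[~post], pre_line[~post], "-", color="C0", label="pre trend")
    ax.plot(tw[post], post_line[post], "-", color="C3", label="post trend")
    ax.axvline(fit.intervention_t, ls="--", color="k", lw=1)
    ax.set_xlabel("time point t")
    ax.set_ylabel(fit.outcome)
    ax.legend(frameon=False)
    return ax
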