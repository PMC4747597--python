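"""Model comparison, posterior summaries, diagnostics and counterfactuals.

WAIC is computed in the variance form from the stored per-line
log-likelihood draws:

    lppd   = sum_i log( mean_s exp(l_is) )        (log-sum-exp stabilized)
    p_waic = sum_i Var_s(l_is)
    WAIC   = -2 (lppd - p_waic)

Lower WAIC means better predictive ability; the reported delta is
WAIC(spline model) - WAIC(linear baseline), so negative values favor the
nonlinear structural model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .model import BivariateDataset
from .sampler import PosteriorSamples
from .splines import KnotVector, basis_matrix

__all__ = [
    "FitSummary",
    "TrajectoryEstimate",
    "compute_waic",
    "delta_waic",
    "summarize_trajectory",
    "significance_call",
    "identifiability_diagnostic",
    "predict_edit",
    "recovery_metrics",
]


@dataclass
class FitSummary:
    """WAIC decomposition of one fit.

    ``mean_loglik`` is the posterior mean of the total log-likelihood over
    retained draws.
    """

    mean_loglik: float
    lppd: float
    p_waic: float
    waic: float
    lppd_lines: np.ndarray
    p_waic_lines: np.ndarray


@dataclass
class TrajectoryEstimate:
    """Posterior summary of the influence function on a trait-value grid."""

    grid: np.ndarray
    mean_L: np.ndarray
    q025_L: np.ndarray
    q975_L: np.ndarray


def compute_waic(samples: PosteriorSamples) -> FitSummary:
    """Variance-form WAIC from stored per-line log-likelihood draws."""
    ll = samples.loglik_lines
    S = ll.shape[0]
    if S < 2:
        raise ValueError("need at least 2 draws to compute WAIC")
    lppd_lines = logsumexp(ll, axis=0) - np.log(S)
    p_lines = ll.var(axis=0, ddof=1)
    lppd = float(lppd_lines.sum())
    p_waic = float(p_lines.sum())
    return FitSummary(
        mean_loglik=float(samples.loglik.mean()),
        lppd=lppd,
        p_waic=p_waic,
        waic=-2.0 * (lppd - p_waic),
        lppd_lines=lppd_lines,
        p_waic_lines=p_lines,
    )


def delta_waic(fit_nse: FitSummary, fit_olm: FitSummary) -> float:
    """WAIC(NSE) - WAIC(OLM); negative favors the nonlinear model."""
    return fit_nse.waic - fit_olm.waic


def summarize_trajectory(
    samples: PosteriorSamples,
    kv: KnotVector | None = None,
    grid_size: int = 101,
) -> TrajectoryEstimate:
    """Posterior mean and 2.5/97.5% quantiles of L(y) on a uniform grid
    spanning the observed trait range [y_min, y_max]."""
    if samples.weights is None:
        raise ValueError("trajectory summary requires spline-model samples")
    kv = kv or samples.kv
    grid = np.linspace(kv.y_min, kv.y_max, grid_size)
    if grid.min() < kv.lower or grid.max() > kv.upper:
        raise ValueError("grid extends outside the knot range")
    Bg = basis_matrix(kv, grid)  # (G, n_basis)
    draws = samples.weights @ Bg.T  # (S, G)
    return TrajectoryEstimate(
        grid=grid,
        mean_L=draws.mean(axis=0),
        q025_L=np.quantile(draws, 0.025, axis=0),
        q975_L=np.quantile(draws, 0.975, axis=0),
    )


def significance_call(effect_draws: np.ndarray) -> dict:
    """Posterior 95% interval significance of one effect.

    Non-significant iff 0 lies inside [q2.5%, q97.5%].  The reported scale
    is twice the allele-substitution coefficient (homozygous inbreds carry
    two copies); raw quantiles are returned alongside.
    """
    draws = np.asarray(effect_draws, float).ravel()
    if draws.size < 40:
        raise ValueError("need at least 40 draws for a quantile-based call")
    q025, q975 = np.quantile(draws, [0.025, 0.975])
    significant = not (q025 <= 0.0 <= q975)
    return {
        "significant": bool(significant),
        "q025": float(q025),
        "q975": float(q975),
        "mean": float(draws.mean()),
        "mean_x2": float(2.0 * draws.mean()),
        "q025_x2": float(2.0 * q025),
        "q975_x2": float(2.0 * q975),
    }


def identifiability_diagnostic(samples: PosteriorSamples) -> dict:
    """Pearson correlation of each weight chain with the residual-covariance chain.

    Strong negative correlations (approaching -1) flag the confounding of a
    constant influence with the residual covariance; weak correlations
    indicate the weights are identified.
    """
    if samples.weights is None:
        raise ValueError("diagnostic requires spline-model samples")
    r12 = samples.R[:, 0, 1]
    cors = np.full(samples.weights.shape[1], np.nan)
    if r12.std() > 0:
        for m in range(samples.weights.shape[1]):
            w = samples.weights[:, m]
            if w.std() > 0:
                cors[m] = np.corrcoef(w, r12)[0, 1]
    valid = cors[np.isfinite(cors)]
    return {
        "per_weight": cors,
        "mean": float(valid.mean()) if valid.size else float("nan"),
        "sd": float(valid.std(ddof=1)) if valid.size > 1 else float("nan"),
    }


def predict_edit(
    data: BivariateDataset,
    samples: PosteriorSamples,
    kv: KnotVector | None,
    line: str,
    column_changes: dict[str, float],
) -> dict:
    """Counterfactual gene-edit prediction for one line.

    ``column_changes`` maps design-column names to their new 0/1 values.
    Per retained draw: the phenology shift is dDH = dx_P' beta_P; the
    edited phenology phenotype is clamped into the knot range (the spline
    is undefined beyond it, flagged when clamping occurs); the influenced
    trait's deviation from the overall mean is then
    L(y_P') y_P' + x_A'' beta_A + u_A.
    """
    if line not in data.line_ids:
        raise ValueError(f"line {line!r} not in dataset")
    i = data.line_ids.index(line)
    known = set(data.X_P_cols) | set(data.X_A_cols)
    bad = set(column_changes) - known
    if bad:
        raise ValueError(f"edited columns absent from both designs: {sorted(bad)}")
    kv = kv if kv is not None else samples.kv
    x_P = data.X_P[i].copy()
    x_A = data.X_A[i].copy()
    for col, val in column_changes.items():
        if col in data.X_P_cols:
            x_P[data.X_P_cols.index(col)] = val
        if col in data.X_A_cols:
            x_A[data.X_A_cols.index(col)] = val
    dx_P = x_P - data.X_P[i]
    S = samples.n_draws
    d_dh = samples.beta_P @ dx_P  # (S,)
    y_new = data.y_P[i] + d_dh
    clamped = False
    if kv is not None:
        lo, hi = kv.lower, kv.upper
        clamped = bool(np.any(y_new < lo) or np.any(y_new > hi))
        y_new = np.clip(y_new, lo, hi)
    if samples.weights is not None:
        Bn = basis_matrix(kv, y_new)  # (S, n_basis)
        L_new = np.einsum("sb,sb->s", samples.weights, Bn)
    else:
        L_new = np.zeros(S)
    dev_A = L_new * y_new + samples.beta_A @ x_A + samples.u_A[:, i]

    def summ(v):
        return {
            "mean": float(np.mean(v)),
            "q025": float(np.quantile(v, 0.025)),
            "q975": float(np.quantile(v, 0.975)),
        }

    return {
        "delta_P": summ(d_dh),
        "L_new": summ(L_new),
        "deviation_A": summ(dev_A),
        "clamped": clamped,
    }


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def recovery_metrics(truth, samples: PosteriorSamples) -> dict:
    """Correlations between simulated truth and posterior means.

    Reported for the per-line influence L(y_P,i), the per-line polygenic
    effect on the influenced trait, and the influenced-trait major-gene
    coefficients (intercept excluded).  Zero-variance truth vectors yield
    NaN ("missing").
    """
    est_u_A = samples.u_A.mean(axis=0)
    est_beta_A = samples.beta_A.mean(axis=0)[1:]
    out = {
        "cor_u_A": _safe_corr(truth.u_A, est_u_A),
        "cor_beta_A": _safe_corr(truth.beta_A[1:], est_beta_A),
        "cor_L": float("nan"),
    }
    if samples.weights is not None and getattr(truth, "L_lines", None) is not None:
        Bd = basis_matrix(samples.kv, np.clip(
            truth.y_P_centered, samples.kv.lower, samples.kv.upper))
        est_L = Bd @ samples.weights.mean(axis=0)
        out["cor_L"] = _safe_corr(truth.L_lines, est_L)
    return out
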