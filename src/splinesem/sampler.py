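"""Metropolis-within-Gibbs sampler for the bivariate structural model.

Conjugate Gibbs draws handle the fixed effects (flat prior), polygenic
effects (MVN(0, G (x) K) prior), and the 2x2 covariance matrices G and R
(inverse-Wishart priors with 4 degrees of freedom and scale equal to half
the phenotypic covariance matrix, so the prior mean equals the scale).
For the Gibbs steps the influenced trait is represented by its working
response y_A - L(y_P) * y_P, which reduces the structural model to a
standard bivariate mixed model.

The spline weights P_m are non-conjugate and use a random-walk Metropolis
step with fixed proposal variance (default 0.04).  Because basis function m
vanishes outside its five defining knots, the likelihood ratio of a P_m
proposal only involves lines whose phenological phenotype falls inside that
support — the local-support shortcut.  The weight prior is the
second-difference random walk

    P_0, P_1 ~ N(0, 1000 sigma_P^2),
    P_m | P_{m-1}, P_{m-2} ~ N(2 P_{m-1} - P_{m-2}, sigma_P^2),  m >= 2,

and sigma_P^2 carries a weakly-informative proper scaled-inverse-chi-square
prior giving a conjugate Inv-chi^2 full conditional (see
:class:`PriorSpec` for why the improper 1/sigma^2 limit is unusable).

The constant component of the influence function is not identified by the
likelihood when the phenology design nests in the influenced design: a
level shift can be absorbed exactly by co-transforming beta_A, u_A, G and
R.  A generalized-Gibbs move samples along this invariance orbit from the
prior-induced Gaussian conditional (:func:`update_level`); the
zero-residual-covariance variant, which breaks the invariance, instead
uses a likelihood-conditional level sweep.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix, regularize
from .model import (
    BivariateDataset,
    ModelSpec,
    NSEParams,
    bvn_loglik,
    per_line_logliks,
)
from .splines import KnotVector, SplineWeights, build_knots, basis_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "MCMCConfig",
    "PriorSpec",
    "ChainState",
    "ChainWorkspace",
    "PosteriorSamples",
    "make_workspace",
    "update_beta",
    "update_u",
    "update_G",
    "update_R",
    "update_weight",
    "update_level",
    "update_sigma_p2",
    "log_weight_prior",
    "run_chain",
    "rinvwishart",
]


@dataclass
class MCMCConfig:
    """Chain settings.  Defaults are the full-scale analysis settings
    (1.1e6 iterations, 1e5 burn-in, thinning 100); :meth:`desk` gives a
    reduced configuration for interactive and simulation-study use."""

    n_iter: int = 1_100_000
    burn_in: int = 100_000
    thin: int = 100
    sigma_prop2: float = 0.04
    seed: int = 0
    log_every: int = 0  # 0 = no progress logging

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.sigma_prop2 <= 0:
            raise ValueError("sigma_prop2 must be positive")

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "MCMCConfig":
        kw.setdefault("n_iter", 50_000)
        kw.setdefault("burn_in", 5_000)
        kw.setdefault("thin", 10)
        return cls(seed=seed, **kw)

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PriorSpec:
    """Concrete prior hyperparameters.

    ``G_scale`` and ``R_scale`` are the inverse-Wishart scale matrices
    (half the phenotypic covariance of the two traits); with 4 degrees of
    freedom and p = 2 the prior expectation equals the scale matrix.
    Fixed effects carry an improper flat prior.
    """

    G_scale: np.ndarray
    R_scale: np.ndarray
    iw_df: int = 4
    weight_boundary_factor: float = 1000.0
    # weakly-informative proper scaled-inv-chi-square prior on sigma_P^2.
    # The improper 1/sigma^2 limit makes the posterior degenerate here:
    # when the data do not constrain the weights, E[sigma^2 | rest]
    # contracts geometrically and the chain collapses to sigma^2 -> 0,
    # freezing the influence function.  A unit prior degree of freedom
    # with a small scale keeps the prior diffuse while bounding the
    # contraction away from the degenerate point.
    sigmaP2_df: float = 1.0
    sigmaP2_scale: float = 0.01

    @classmethod
    def from_data(
        cls, data: BivariateDataset, zero_covariance: bool = False
    ) -> "PriorSpec":
        """Scale matrices from half the phenotypic covariance.

        For the zero-residual-covariance variant the off-diagonals are
        dropped: that variant attributes the inter-trait covariance to the
        influence term, so seeding the genetic-covariance prior with the
        full observed covariance would double-count exactly the signal the
        constraint exists to isolate (and center the G_12 prior an order
        of magnitude above any plausible genetic covariance).
        """
        pheno_cov = np.cov(np.column_stack([data.y_P, data.y_A]), rowvar=False)
        half = 0.5 * pheno_cov
        if zero_covariance:
            half = np.diag(np.diag(half))
        return cls(G_scale=half, R_scale=half.copy())


def _inv2(M: np.ndarray) -> np.ndarray:
    a, b, c, d = M[0, 0], M[0, 1], M[1, 0], M[1, 1]
    det = a * d - b * c
    if det <= 0:
        raise np.linalg.LinAlgError("2x2 matrix not positive definite")
    return np.array([[d, -b], [-c, a]]) / det


def rinvwishart(rng: np.random.Generator, df: float, S: np.ndarray) -> np.ndarray:
    """Draw from the 2x2 inverse-Wishart IW(df, S) via Bartlett decomposition."""
    if df <= 1:
        raise ValueError("df must exceed p - 1 = 1")
    Sinv = _inv2(S)
    l11 = np.sqrt(Sinv[0, 0])
    l21 = Sinv[1, 0] / l11
    l22 = np.sqrt(Sinv[1, 1] - l21 * l21)
    a11 = np.sqrt(rng.chisquare(df))
    a22 = np.sqrt(rng.chisquare(df - 1))
    a21 = rng.standard_normal()
    # lower factor of W ~ Wishart(df, Sinv)
    f11 = l11 * a11
    f21 = l21 * a11 + l22 * a21
    f22 = l22 * a22
    W = np.array(
        [[f11 * f11, f11 * f21], [f11 * f21, f21 * f21 + f22 * f22]]
    )
    return _inv2(W)


@dataclass
class ChainState:
    """Mutable parameter state of a running chain."""

    beta_P: np.ndarray
    beta_A: np.ndarray
    u_P: np.ndarray
    u_A: np.ndarray
    G: np.ndarray
    R: np.ndarray
    weights: np.ndarray | None
    sigma_P2: float = 1.0

    def params(self) -> NSEParams:
        spline = (
            None
            if self.weights is None
            else SplineWeights(self.weights.copy(), self.sigma_P2)
        )
        return NSEParams(
            self.beta_P.copy(),
            self.beta_A.copy(),
            self.u_P.copy(),
            self.u_A.copy(),
            self.G.copy(),
            self.R.copy(),
            spline,
        )


@dataclass
class ChainWorkspace:
    """Precomputed quantities reused every iteration."""

    spec: ModelSpec
    priors: PriorSpec
    kv: KnotVector | None
    B: np.ndarray | None          # (n, n_basis) basis at y_P
    support: list[np.ndarray] | None  # index arrays per basis
    Q: np.ndarray                 # eigenvectors of regularized K
    lam: np.ndarray               # eigenvalues of regularized K
    XtX_inv: dict[str, np.ndarray]
    XtX_inv_chol: dict[str, np.ndarray]
    jitter: float
    sigma_prop2: float = 0.04
    nested_designs: bool = True

    def influence(self, state: ChainState, y_P: np.ndarray) -> np.ndarray:
        """Current L(y_P) * y_P vector (zeros for the OLM)."""
        if state.weights is None:
            return np.zeros_like(y_P)
        return (self.B @ state.weights) * y_P


def make_workspace(
    data: BivariateDataset,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    kv: KnotVector | None = None,
) -> ChainWorkspace:
    """Factorize once: kinship eigendecomposition, design Gram inverses,
    spline basis at the observed phenological phenotypes."""
    priors = priors or PriorSpec.from_data(data, zero_covariance=spec.zero_rescov)
    km, jitter = regularize(KinshipMatrix(data.line_ids, data.K))
    lam, Q = np.linalg.eigh(km.K)
    if lam.min() <= 0:
        km, jitter = regularize(km, eps=abs(lam.min()) + 1e-8)
        lam, Q = np.linalg.eigh(km.K)
    XtX_inv, XtX_chol = {}, {}
    for trait, X in (("P", data.X_P), ("A", data.X_A)):
        XtX = X.T @ X
        try:
            XtX_inv[trait] = np.linalg.inv(XtX)
            np.linalg.cholesky(XtX_inv[trait])
        except np.linalg.LinAlgError:
            cols = data.X_P_cols if trait == "P" else data.X_A_cols
            raise np.linalg.LinAlgError(
                f"design matrix for trait {trait} rank deficient (columns {cols})"
            )
        XtX_chol[trait] = np.linalg.cholesky(XtX_inv[trait])
    B = support = None
    if spec.has_spline:
        if kv is None:
            kv = build_knots(data.y_P.min(), data.y_P.max(), spec.n_basis)
        B = basis_matrix(kv, data.y_P)
        support = [np.nonzero(B[:, m] != 0.0)[0] for m in range(kv.n_basis)]
    p_P = data.X_P.shape[1]
    nested = data.X_A.shape[1] >= p_P and np.array_equal(
        data.X_A[:, :p_P], data.X_P
    )
    return ChainWorkspace(
        spec, priors, kv, B, support, Q, lam, XtX_inv, XtX_chol, jitter,
        nested_designs=nested,
    )


def _working_A(data: BivariateDataset, state: ChainState, ws: ChainWorkspace):
    """Influenced-trait working response y_A - L(y_P) y_P."""
    return data.y_A - ws.influence(state, data.y_P)


def update_beta(
    data: BivariateDataset,
    state: ChainState,
    ws: ChainWorkspace,
    trait: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gibbs draw of one trait's fixed effects under the flat prior.

    Conditioning trait-on-trait: given the partner trait's residual e_s,
    the target trait's residual is N((R_ts/R_ss) e_s, R_tt - R_ts^2/R_ss),
    so the conditional of beta_t is normal around the OLS solution on the
    partner-adjusted working response.
    """
    z_A = _working_A(data, state, ws)
    R = state.R
    if trait == "P":
        X, u_t = data.X_P, state.u_P
        y_t = data.y_P
        e_s = z_A - data.X_A @ state.beta_A - state.u_A
        r_tt, r_ts, r_ss = R[0, 0], R[0, 1], R[1, 1]
    elif trait == "A":
        X, u_t = data.X_A, state.u_A
        y_t = z_A
        e_s = data.y_P - data.X_P @ state.beta_P - state.u_P
        r_tt, r_ts, r_ss = R[1, 1], R[0, 1], R[0, 0]
    else:
        raise ValueError("trait must be 'P' or 'A'")
    v = r_tt - r_ts**2 / r_ss
    w = y_t - u_t - (r_ts / r_ss) * e_s
    mean = ws.XtX_inv[trait] @ (X.T @ w)
    beta = mean + np.sqrt(v) * (
        ws.XtX_inv_chol[trait] @ rng.standard_normal(X.shape[1])
    )
    if trait == "P":
        state.beta_P = beta
    else:
        state.beta_A = beta
    return beta


def update_u(
    data: BivariateDataset,
    state: ChainState,
    ws: ChainWorkspace,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint Gibbs draw of the 2n polygenic effects.

    In the eigenbasis of K the 2n-dimensional conditional factorizes into n
    independent bivariate normals: for eigenvalue lam_j the prior precision
    is G^{-1}/lam_j and the data precision R^{-1}, acting on the rotated
    residual responses.
    """
    z_P = data.y_P - data.X_P @ state.beta_P
    z_A = _working_A(data, state, ws) - data.X_A @ state.beta_A
    Zt = ws.Q.T @ np.column_stack([z_P, z_A])  # (n, 2)
    Ginv = _inv2(state.G)
    Rinv = _inv2(state.R)
    lam = ws.lam
    a11 = Ginv[0, 0] / lam + Rinv[0, 0]
    a12 = Ginv[0, 1] / lam + Rinv[0, 1]
    a22 = Ginv[1, 1] / lam + Rinv[1, 1]
    det = a11 * a22 - a12 * a12
    c11, c12, c22 = a22 / det, -a12 / det, a11 / det
    b1 = Rinv[0, 0] * Zt[:, 0] + Rinv[0, 1] * Zt[:, 1]
    b2 = Rinv[1, 0] * Zt[:, 0] + Rinv[1, 1] * Zt[:, 1]
    m1 = c11 * b1 + c12 * b2
    m2 = c12 * b1 + c22 * b2
    l11 = np.sqrt(c11)
    l21 = c12 / l11
    l22 = np.sqrt(np.maximum(c22 - l21 * l21, 0.0))
    eps = rng.standard_normal((data.n_lines, 2))
    ut1 = m1 + l11 * eps[:, 0]
    ut2 = m2 + l21 * eps[:, 0] + l22 * eps[:, 1]
    u = ws.Q @ np.column_stack([ut1, ut2])
    state.u_P, state.u_A = u[:, 0], u[:, 1]
    return state.u_P, state.u_A


def update_G(
    state: ChainState, ws: ChainWorkspace, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Conjugate inverse-Wishart draw of the 2x2 genetic covariance:
    IW(df0 + n, S0 + U' K^{-1} U)."""
    Ut = ws.Q.T @ np.column_stack([state.u_P, state.u_A])
    M = (Ut / ws.lam[:, None]).T @ Ut
    S = ws.priors.G_scale + M
    state.G = rinvwishart(rng, ws.priors.iw_df + n, S)
    return state.G


def update_R(
    data: BivariateDataset,
    state: ChainState,
    ws: ChainWorkspace,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate draw of the residual covariance from IW(df0 + n, S0 + E'E).

    The zero-residual-covariance variant pins the off-diagonal at zero and
    draws each variance from its scaled-inverse-chi-square conditional
    (the p = 1 inverse-Wishart special case with the matching scale entry).
    """
    e_P = data.y_P - data.X_P @ state.beta_P - state.u_P
    e_A = _working_A(data, state, ws) - data.X_A @ state.beta_A - state.u_A
    n = data.n_lines
    df = ws.priors.iw_df + n
    if ws.spec.zero_rescov:
        s1 = ws.priors.R_scale[0, 0] + float(e_P @ e_P)
        s2 = ws.priors.R_scale[1, 1] + float(e_A @ e_A)
        state.R = np.diag([s1 / rng.chisquare(df), s2 / rng.chisquare(df)])
    else:
        E = np.column_stack([e_P, e_A])
        state.R = rinvwishart(rng, df, ws.priors.R_scale + E.T @ E)
    return state.R


def log_weight_prior(P: np.ndarray, sigma_P2: float, boundary_factor: float) -> float:
    """Unnormalized log prior kernel of the weight vector given sigma_P2."""
    lp = -(P[0] ** 2 + P[1] ** 2) / (2.0 * boundary_factor * sigma_P2)
    d = P[2:] - 2.0 * P[1:-1] + P[:-2]
    return float(lp - (d @ d) / (2.0 * sigma_P2))


def update_weight(
    data: BivariateDataset,
    state: ChainState,
    ws: ChainWorkspace,
    m: int,
    rng: np.random.Generator,
) -> bool:
    """Random-walk Metropolis step for spline weight m.

    The likelihood ratio runs only over lines inside the support of basis
    m; lines outside it have identical likelihood under both values.  The
    prior ratio uses every random-walk term in which P_m appears.
    """
    P = state.weights
    prop = P[m] + np.sqrt(ws.sigma_prop2) * rng.standard_normal()
    sup = ws.support[m]
    e_P = data.y_P[sup] - data.X_P[sup] @ state.beta_P - state.u_P[sup]
    infl = (ws.B[sup] @ P) * data.y_P[sup]
    e_A = data.y_A[sup] - infl - data.X_A[sup] @ state.beta_A - state.u_A[sup]
    delta = (prop - P[m]) * ws.B[sup, m] * data.y_P[sup]
    E_cur = np.column_stack([e_P, e_A])
    E_new = np.column_stack([e_P, e_A - delta])
    llr = float(bvn_loglik(E_new, state.R).sum() - bvn_loglik(E_cur, state.R).sum())
    P_new = P.copy()
    P_new[m] = prop
    bf = ws.priors.weight_boundary_factor
    lpr = log_weight_prior(P_new, state.sigma_P2, bf) - log_weight_prior(
        P, state.sigma_P2, bf
    )
    if np.log(rng.uniform()) < llr + lpr:
        state.weights = P_new
        return True
    return False


def update_level(
    data: BivariateDataset,
    state: ChainState,
    ws: ChainWorkspace,
    rng: np.random.Generator,
) -> float:
    """Generalized-Gibbs move along the exact level-invariance orbit.

    A constant shift delta of the influence function leaves the likelihood
    exactly unchanged once the other blocks are co-transformed::

        P     -> P + delta * 1
        beta_A -> beta_A - delta * beta_P   (phenology columns are nested
                                             in the influenced design)
        u_A   -> u_A - delta * u_P
        G, R  -> T G T',  T R T'   with  T = [[1, 0], [-delta, 1]]

    This is the recursive model's version of the constant-influence /
    residual-covariance confounding: the level of L is informed only by
    the priors.  Every Jacobian of the transformation is one, so the
    conditional density of delta along the orbit is the product of the
    prior kernels at the transformed values — quadratic in delta under
    the inverse-Wishart trace terms (the log-determinants are invariant)
    and the two boundary weight-prior terms, hence exactly Gaussian.
    Sampling delta from it and applying the transformation leaves the
    posterior invariant while jumping the otherwise frozen direction
    (Liu & Sabatti's generalized Gibbs on a group orbit).

    Under the zero-residual-covariance constraint (or non-nested designs)
    the invariance is broken — precisely why the constraint identifies a
    constant influence — and the level is instead moved by a
    fixed-direction Gibbs sweep whose conditional is Gaussian from the
    likelihood (quadratic in delta) plus the two boundary prior terms.
    """
    if ws.spec.zero_rescov or not ws.nested_designs:
        return _update_level_likelihood(data, state, ws, rng)
    prec = 0.0
    lin = 0.0
    for S, X in ((ws.priors.G_scale, state.G), (ws.priors.R_scale, state.R)):
        M = _inv2(X)
        prec += S[0, 0] * M[1, 1]
        lin += -(S[0, 0] * M[0, 1] + S[0, 1] * M[1, 1])
    bf = ws.priors.weight_boundary_factor
    P = state.weights
    prec += 2.0 / (bf * state.sigma_P2)
    lin += -(P[0] + P[1]) / (bf * state.sigma_P2)
    delta = lin / prec + rng.standard_normal() / np.sqrt(prec)
    T = np.array([[1.0, 0.0], [-delta, 1.0]])
    state.weights = P + delta
    p_shared = state.beta_P.size
    state.beta_A = state.beta_A.copy()
    state.beta_A[:p_shared] -= delta * state.beta_P
    state.u_A = state.u_A - delta * state.u_P
    state.G = T @ state.G @ T.T
    state.R = T @ state.R @ T.T
    return float(delta)


def _update_level_likelihood(
    data: BivariateDataset,
    state: ChainState,
    ws: ChainWorkspace,
    rng: np.random.Generator,
) -> float:
    """Fixed-direction Gibbs sweep P -> P + delta * 1 from the exact
    (likelihood x boundary-prior) Gaussian conditional of delta; used when
    the level is likelihood-identified."""
    P = state.weights
    y = data.y_P
    e_P = y - data.X_P @ state.beta_P - state.u_P
    e_A = data.y_A - (ws.B @ P) * y - data.X_A @ state.beta_A - state.u_A
    Rinv = _inv2(state.R)
    a = Rinv[1, 1] * float(y @ y)
    b = float(y @ (Rinv[0, 1] * e_P + Rinv[1, 1] * e_A))
    bf = ws.priors.weight_boundary_factor
    p0 = 2.0 / (bf * state.sigma_P2)
    prec = a + p0
    mean = (b - (P[0] + P[1]) / (bf * state.sigma_P2)) / prec
    delta = mean + rng.standard_normal() / np.sqrt(prec)
    state.weights = P + delta
    return float(delta)


def update_sigma_p2(
    state: ChainState, ws: ChainWorkspace, rng: np.random.Generator
) -> float:
    """Conjugate scaled-inverse-chi-square draw of the smoothness variance.

    Sufficient statistics: the second differences of the weights (variance
    sigma_P2 each) plus the two boundary terms P_0, P_1 (variance
    1000 sigma_P2 each); combined with the proper scaled-inv-chi-square
    prior the conditional is Inv-chi^2 with df = #terms + prior df and
    scale sum augmented by the prior scale contribution.
    """
    P = state.weights
    pr = ws.priors
    bf = pr.weight_boundary_factor
    d = P[2:] - 2.0 * P[1:-1] + P[:-2]
    ss = float(d @ d) + (P[0] ** 2 + P[1] ** 2) / bf
    if ss < 1e-12:
        logger.warning("degenerate weight statistics; scale floored")
        ss = 1e-12
    df = P.size + pr.sigmaP2_df
    state.sigma_P2 = (ss + pr.sigmaP2_df * pr.sigmaP2_scale) / rng.chisquare(df)
    return state.sigma_P2


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws of every parameter block.

    ``loglik_lines`` holds the per-line log-likelihood at each retained
    draw (the WAIC input); ``acceptance`` the Metropolis acceptance rate
    per weight index.
    """

    beta_P: np.ndarray
    beta_A: np.ndarray
    u_P: np.ndarray
    u_A: np.ndarray
    G: np.ndarray
    R: np.ndarray
    weights: np.ndarray | None
    sigma_P2: np.ndarray | None
    loglik: np.ndarray
    loglik_lines: np.ndarray
    acceptance: np.ndarray | None
    kv: KnotVector | None
    line_ids: list[str]
    manifest: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.loglik.shape[0]

    def mean_params(self) -> NSEParams:
        """Posterior-mean parameter state (weights included when present)."""
        spline = (
            None
            if self.weights is None
            else SplineWeights(self.weights.mean(axis=0), float(self.sigma_P2.mean()))
        )
        return NSEParams(
            self.beta_P.mean(axis=0),
            self.beta_A.mean(axis=0),
            self.u_P.mean(axis=0),
            self.u_A.mean(axis=0),
            self.G.mean(axis=0),
            self.R.mean(axis=0),
            spline,
        )

    def to_dir(self, out_dir) -> None:
        """One CSV per parameter block plus a JSON run manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        blocks = {
            "beta_P": self.beta_P,
            "beta_A": self.beta_A,
            "u_P": self.u_P,
            "u_A": self.u_A,
            "G": self.G.reshape(self.n_draws, 4),
            "R": self.R.reshape(self.n_draws, 4),
            "loglik": self.loglik[:, None],
            "loglik_lines": self.loglik_lines,
        }
        if self.weights is not None:
            blocks["weights"] = self.weights
            blocks["sigma_P2"] = self.sigma_P2[:, None]
        for name, arr in blocks.items():
            pd.DataFrame(arr).to_csv(out / f"{name}.csv", index=False,
                                     float_format="%.10g")
        man = dict(self.manifest)
        man["line_ids"] = self.line_ids
        man["knots"] = list(self.kv.knots) if self.kv is not None else None
        man["acceptance"] = (
            self.acceptance.tolist() if self.acceptance is not None else None
        )
        (out / "manifest.json").write_text(json.dumps(man, indent=2))

    @classmethod
    def from_dir(cls, out_dir) -> "PosteriorSamples":
        out = Path(out_dir)
        man = json.loads((out / "manifest.json").read_text())

        def rd(name):
            p = out / f"{name}.csv"
            if not p.exists():
                raise FileNotFoundError(f"missing posterior block {name} in {out}")
            return pd.read_csv(p).to_numpy(float)

        loglik = rd("loglik")[:, 0]
        S = loglik.shape[0]
        has_w = (out / "weights.csv").exists()
        kv = KnotVector(tuple(man["knots"])) if man.get("knots") else None
        acc = man.get("acceptance")
        return cls(
            beta_P=rd("beta_P"),
            beta_A=rd("beta_A"),
            u_P=rd("u_P"),
            u_A=rd("u_A"),
            G=rd("G").reshape(S, 2, 2),
            R=rd("R").reshape(S, 2, 2),
            weights=rd("weights") if has_w else None,
            sigma_P2=rd("sigma_P2")[:, 0] if has_w else None,
            loglik=loglik,
            loglik_lines=rd("loglik_lines"),
            acceptance=np.asarray(acc, float) if acc is not None else None,
            kv=kv,
            line_ids=[str(i) for i in man["line_ids"]],
            manifest={k: v for k, v in man.items()
                      if k not in ("line_ids", "knots", "acceptance")},
        )


def run_chain(
    data: BivariateDataset,
    spec: ModelSpec,
    config: MCMCConfig,
    priors: PriorSpec | None = None,
    kv: KnotVector | None = None,
) -> PosteriorSamples:
    """Run the full Metropolis-within-Gibbs chain.

    Initialization: beta = 0, u = 0, G and R at their prior scale matrices,
    P = 0, sigma_P2 = 1.  Update order per iteration: beta_P, beta_A, u,
    G, R, then (spline models) P_0..P_M sequentially and sigma_P2.  All
    randomness flows from a single generator seeded by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ws = make_workspace(data, spec, priors, kv)
    ws.sigma_prop2 = config.sigma_prop2
    priors = ws.priors
    n = data.n_lines
    R0 = priors.R_scale.copy()
    if spec.zero_rescov:
        R0 = np.diag(np.diag(R0))
    state = ChainState(
        beta_P=np.zeros(data.X_P.shape[1]),
        beta_A=np.zeros(data.X_A.shape[1]),
        u_P=np.zeros(n),
        u_A=np.zeros(n),
        G=priors.G_scale.copy(),
        R=R0,
        weights=np.zeros(spec.n_basis) if spec.has_spline else None,
        sigma_P2=1.0,
    )
    S = config.n_draws
    out = PosteriorSamples(
        beta_P=np.empty((S, state.beta_P.size)),
        beta_A=np.empty((S, state.beta_A.size)),
        u_P=np.empty((S, n)),
        u_A=np.empty((S, n)),
        G=np.empty((S, 2, 2)),
        R=np.empty((S, 2, 2)),
        weights=np.empty((S, spec.n_basis)) if spec.has_spline else None,
        sigma_P2=np.empty(S) if spec.has_spline else None,
        loglik=np.empty(S),
        loglik_lines=np.empty((S, n)),
        acceptance=np.zeros(spec.n_basis) if spec.has_spline else None,
        kv=ws.kv,
        line_ids=list(data.line_ids),
        manifest={
            "model": spec.kind.value,
            "n_basis": spec.n_basis if spec.has_spline else None,
            "n_iter": config.n_iter,
            "burn_in": config.burn_in,
            "thin": config.thin,
            "sigma_prop2": config.sigma_prop2,
            "seed": config.seed,
            "kinship_jitter": ws.jitter,
            "G_prior_scale": priors.G_scale.tolist(),
            "R_prior_scale": priors.R_scale.tolist(),
            "iw_df": priors.iw_df,
        },
    )
    keep = 0
    for it in range(config.n_iter):
        update_beta(data, state, ws, "P", rng)
        update_beta(data, state, ws, "A", rng)
        update_u(data, state, ws, rng)
        update_G(state, ws, rng, n)
        update_R(data, state, ws, rng)
        if spec.has_spline:
            for m in range(spec.n_basis):
                if update_weight(data, state, ws, m, rng):
                    out.acceptance[m] += 1.0
            update_level(data, state, ws, rng)
            update_sigma_p2(state, ws, rng)
        step = it + 1
        if step > config.burn_in and (step - config.burn_in) % config.thin == 0:
            ll = per_line_logliks(data, state.params(), ws.kv)
            if not np.all(np.isfinite(ll)):
                raise RuntimeError(
                    f"non-finite likelihood at iteration {step}; state: {state!r}"
                )
            out.beta_P[keep] = state.beta_P
            out.beta_A[keep] = state.beta_A
            out.u_P[keep] = state.u_P
            out.u_A[keep] = state.u_A
            out.G[keep] = state.G
            out.R[keep] = state.R
            if spec.has_spline:
                out.weights[keep] = state.weights
                out.sigma_P2[keep] = state.sigma_P2
            out.loglik_lines[keep] = ll
            out.loglik[keep] = ll.sum()
            keep += 1
        if config.log_every and step % config.log_every == 0:
            ll = per_line_logliks(data, state.params(), ws.kv).sum()
            acc = (
                "-"
                if out.acceptance is None
                else f"{out.acceptance.sum() / (step * spec.n_basis):.2f}"
            )
            logger.info("iter %d loglik %.2f acc %s", step, ll, acc)
    if out.acceptance is not None:
        out.acceptance /= config.n_iter
        out.manifest["acceptance_mean"] = float(out.acceptance.mean())
    return out
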