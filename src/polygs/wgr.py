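"""Whole-genome regression on allele dosages: five Bayesian models + GBLUP.

All marker models share the linear model ``y = 1 mu + X beta + eps``
with ``X`` the dosage incidence matrix (0..ploidy codes) and differ in
the prior on the marker effects:

* BRR — one common normal prior variance (scaled-inverse-chi-square
  hyperprior);
* BayesA — a per-marker prior variance, each scaled-inverse-chi-square;
* BayesB — per-marker spike-and-slab: point mass at zero with
  probability ``pi``, per-marker normal slab otherwise;
* BayesC — common-slab variant of BayesB;
* Bayesian LASSO — per-marker variance ``sigma2_e * tau2_j`` with
  ``tau2_j`` exponential, giving double-exponential shrinkage.

Posteriors come from a single-site Gibbs sampler (20,000 iterations,
2,000 burn-in by default).  GBLUP instead models individual genetic
values ``g ~ N(0, K* sigma2_g)`` on a (blended) relationship matrix and
is fitted by REML through the eigendecomposition of ``K*``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize

from polygs._sampler import gibbs_core
from polygs.dosage import DosageMatrix
from polygs.kinship import RelationshipMatrix

__all__ = [
    "WgrSpec",
    "WgrPosterior",
    "GblupFit",
    "fit_bayesian",
    "fit_gblup",
    "predict_gebv",
    "narrow_heritability",
    "MODEL_CODES",
]

MODEL_CODES = {"BRR": 0, "BA": 1, "BB": 2, "BC": 3, "BL": 4}
BAYESIAN_MODELS = tuple(MODEL_CODES)
ALL_MODELS = BAYESIAN_MODELS + ("GBLUP",)


@dataclass
class WgrSpec:
    """Model choice, prior hyperparameters and MCMC protocol.

    Scale parameters left ``None`` are set from the data so the prior
    modes split the phenotypic variance evenly between markers and
    residual (``r2 = 0.5``), following common Bayesian-regression
    software defaults.  ``pi`` is the spike (zero-effect) probability of
    BayesB/C.  The LASSO rate ``lambda2`` gets a Gamma hyperprior unless
    ``fix_lambda`` is set.
    """

    model: str = "GBLUP"
    df_beta: float = 5.0
    s_beta: float | None = None
    df_eps: float = 5.0
    s_eps: float | None = None
    pi: float = 0.5
    lambda2: float | None = None
    lambda_shape: float = 1.1
    lambda_rate: float | None = None
    fix_lambda: bool = False
    r2: float = 0.5
    iterations: int = 20_000
    burn_in: int = 2_000
    thin: int = 1
    seed: int = 0
    update_hyper: bool = True  # False freezes variance hyperparameters

    def __post_init__(self) -> None:
        if self.model not in ALL_MODELS:
            raise ValueError(f"model must be one of {ALL_MODELS}")
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        for name in ("df_beta", "df_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def fast(self, iterations: int = 4_000, burn_in: int = 1_000) -> "WgrSpec":
        """Desk-scale MCMC profile for testing and cross-validation."""
        return replace(self, iterations=iterations, burn_in=burn_in)


@dataclass
class WgrPosterior:
    """Posterior summaries of a Bayesian marker-effect fit."""

    spec: WgrSpec
    mu: float
    beta: pd.Series  # posterior mean per marker
    beta_sd: pd.Series
    inclusion: pd.Series  # posterior probability of the slab (1 where no spike)
    sigma2_eps: float
    sigma2_beta: float  # posterior mean of the (average) marker variance
    lambda2: float
    gebv: pd.Series  # X beta posterior mean per training individual
    n_samples: int
    markers: pd.Index = field(repr=False, default=None)


@dataclass
class GblupFit:
    """REML GBLUP fit on a relationship matrix."""

    sigma2_g: float
    sigma2_eps: float
    mu: float
    g: pd.Series  # BLUP genetic values, mean ~ 0
    loglik: float
    K: RelationshipMatrix = field(repr=False, default=None)
    converged: bool = True


def _default_scales(spec: WgrSpec, X: np.ndarray, y: np.ndarray) -> WgrSpec:
    vy = float(np.var(y))
    if vy <= 0:
        vy = 1.0
    msx = float(np.sum(np.var(X, axis=0)))
    if msx <= 0:
        msx = 1.0
    r2 = spec.r2
    s_eps = spec.s_eps
    if s_eps is None:
        s_eps = vy * (1.0 - r2) * (spec.df_eps + 2.0) / spec.df_eps
    s_beta = spec.s_beta
    if s_beta is None:
        denom = msx
        if spec.model in ("BB", "BC"):
            denom = msx * max(1.0 - spec.pi, 1e-3)  # variance concentrates in the slab
        s_beta = vy * r2 / denom * (spec.df_beta + 2.0) / spec.df_beta
    lambda2 = spec.lambda2
    lambda_rate = spec.lambda_rate
    if spec.model == "BL":
        if lambda2 is None:
            # prior mode at the rate implied by an even variance split
            lambda2 = 2.0 * (1.0 - r2) / r2 * msx
        if lambda_rate is None:
            lambda_rate = (spec.lambda_shape - 1.0) / lambda2 if spec.lambda_shape > 1 else 1e-4
    else:
        lambda2 = lambda2 or 1.0
        lambda_rate = lambda_rate or 1.0
    return replace(
        spec, s_beta=s_beta, s_eps=s_eps, lambda2=lambda2, lambda_rate=lambda_rate
    )


def fit_bayesian(
    spec: WgrSpec,
    X: DosageMatrix | np.ndarray,
    y: pd.Series | np.ndarray,
) -> WgrPosterior:
    """Gibbs-sample one of the five Bayesian marker-effect models."""
    if spec.model == "GBLUP":
        raise ValueError("use fit_gblup for the GBLUP model")
    if isinstance(X, DosageMatrix):
        markers = X.markers
        ids = X.individuals
        Xa = X.complete_array()
    else:
        Xa = np.asarray(X, dtype=float)
        markers = pd.Index([f"m{j}" for j in range(Xa.shape[1])], name="marker")
        ids = pd.Index([f"i{i}" for i in range(Xa.shape[0])], name="individual")
    if isinstance(y, pd.Series):
        y = y.reindex(ids)
        if y.isna().any():
            raise ValueError("y is missing values for some individuals")
        ya = y.to_numpy(dtype=float)
    else:
        ya = np.asarray(y, dtype=float)
    if len(ya) != Xa.shape[0]:
        raise ValueError("y length does not match X rows")
    if Xa.shape[0] < 2:
        raise ValueError("need at least two records")
    if not np.isfinite(ya).all():
        raise ValueError("y contains non-finite values")

    full = _default_scales(spec, Xa, ya)
    offset = float(ya.mean())
    yc = ya - offset  # centered; mu re-offset on output
    # column-centering decouples the intercept from the marker sweep;
    # beta is invariant, mu is re-expressed on the original scale below
    col_means = Xa.mean(axis=0)
    Xc = Xa - col_means

    (
        mu,
        beta_mean,
        beta_sq,
        pip,
        s2e,
        s2b,
        lam2,
        gebv,
        n_saved,
    ) = gibbs_core(
        np.ascontiguousarray(Xc),
        yc,
        MODEL_CODES[spec.model],
        full.iterations,
        full.burn_in,
        full.thin,
        full.df_beta,
        full.s_beta,
        full.df_eps,
        full.s_eps,
        full.pi if spec.model in ("BB", "BC") else 0.0,
        full.lambda2,
        full.lambda_shape,
        full.lambda_rate,
        (spec.model == "BL") and not full.fix_lambda,
        full.update_hyper,
        int(full.seed) % (2**31),
    )
    beta_var = np.clip(beta_sq - beta_mean**2, 0.0, None)
    shift = float(col_means @ beta_mean)
    return WgrPosterior(
        spec=full,
        mu=float(mu + offset - shift),
        beta=pd.Series(beta_mean, index=markers),
        beta_sd=pd.Series(np.sqrt(beta_var), index=markers),
        inclusion=pd.Series(pip, index=markers),
        sigma2_eps=float(s2e),
        sigma2_beta=float(s2b),
        lambda2=float(lam2),
        gebv=pd.Series(gebv + shift, index=ids, name="gebv"),
        n_samples=int(n_saved),
        markers=markers,
    )


def fit_gblup(
    K_star: RelationshipMatrix,
    y: pd.Series | np.ndarray,
    tol_pd: float = 1e-8,
) -> GblupFit:
    """REML GBLUP through the eigendecomposition of the relationship matrix.

    Profiles the residual variance out of the restricted likelihood of
    ``y = 1 mu + g + eps`` and optimizes over the variance ratio on a
    log scale; BLUPs are recovered on the eigenbasis.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(K_star.ids)
        if y.isna().any():
            raise ValueError("y is missing values for some individuals in K")
        ya = y.to_numpy(dtype=float)
    else:
        ya = np.asarray(y, dtype=float)
    n = K_star.n
    if len(ya) != n:
        raise ValueError("y length does not match K")
    s, U = np.linalg.eigh(K_star.values)
    if s.min() <= tol_pd * max(1.0, s.max()):
        raise ValueError(
            "relationship matrix is not positive definite; blend it with a "
            "pedigree matrix (kinship.blend) first"
        )
    yt = U.T @ ya
    xt = U.T @ np.ones(n)

    def neg2reml(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        d = gamma * s + 1.0
        xdx = float(np.sum(xt * xt / d))
        bhat = float(np.sum(xt * yt / d)) / xdx
        r = yt - xt * bhat
        rss = float(np.sum(r * r / d))
        sigma2_e = rss / (n - 1)
        return (
            (n - 1) * np.log(sigma2_e)
            + float(np.sum(np.log(d)))
            + np.log(xdx)
            + (n - 1)
        )

    res = optimize.minimize_scalar(
        neg2reml, bounds=(-14.0, 14.0), method="bounded",
        options={"xatol": 1e-10},
    )
    log_gamma = float(res.x)
    gamma = np.exp(log_gamma)
    d = gamma * s + 1.0
    xdx = float(np.sum(xt * xt / d))
    mu = float(np.sum(xt * yt / d)) / xdx
    r = yt - xt * mu
    sigma2_e = float(np.sum(r * r / d)) / (n - 1)
    sigma2_g = gamma * sigma2_e
    # g_hat = sigma2_g K V^-1 (y - mu) on the eigenbasis
    ghat = U @ (gamma * s / d * r)
    ll = -0.5 * (neg2reml(log_gamma) + (n - 1) * np.log(2.0 * np.pi) - (n - 1))
    return GblupFit(
        sigma2_g=sigma2_g,
        sigma2_eps=sigma2_e,
        mu=mu,
        g=pd.Series(ghat, index=K_star.ids, name="g"),
        loglik=float(ll),
        K=K_star,
        converged=bool(res.success),
    )


def predict_gebv(
    fit: WgrPosterior | GblupFit,
    X_new: DosageMatrix | np.ndarray | None = None,
    K_cross: np.ndarray | None = None,
) -> pd.Series | np.ndarray:
    """Genomic estimated breeding values for new individuals.

    Marker models: ``GEBV = X_new beta``.  GBLUP: ``GEBV = K_cross
    K_train^-1 g_train`` with ``K_cross`` the new-by-training block of
    the relationship matrix.
    """
    if isinstance(fit, WgrPosterior):
        if X_new is None:
            raise ValueError("marker-model prediction needs X_new")
        if isinstance(X_new, DosageMatrix):
            if not X_new.markers.equals(fit.markers):
                raise ValueError("marker panel mismatch between training and prediction")
            Xa = X_new.complete_array()
            ids = X_new.individuals
        else:
            Xa = np.asarray(X_new, dtype=float)
            if Xa.shape[1] != len(fit.beta):
                raise ValueError("marker panel mismatch between training and prediction")
            ids = None
        vals = Xa @ fit.beta.to_numpy()
        return pd.Series(vals, index=ids, name="gebv") if ids is not None else vals
    if K_cross is None:
        raise ValueError("GBLUP prediction needs K_cross")
    K_cross = np.asarray(K_cross, dtype=float)
    if K_cross.shape[1] != fit.K.n:
        raise ValueError("K_cross columns must match the training individuals")
    alpha = np.linalg.solve(fit.K.values, fit.g.to_numpy())
    return K_cross @ alpha


def narrow_heritability(fit: GblupFit) -> float:
    """h2 = sigma2_A / sigma2_P with sigma2_P = sigma2_g + sigma2_eps."""
    total = fit.sigma2_g + fit.sigma2_eps
    if total <= 0:
        raise ValueError("phenotypic variance is zero; h2 undefined")
    return fit.sigma2_g / total
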