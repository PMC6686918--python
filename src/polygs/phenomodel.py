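"""Stage-1 longitudinal phenotypic analysis.

Repeated harvest measurements from a split-plot randomized complete
block trial are modelled with the linear mixed model

    y_ijkl = mu + h_l + b_k(l) + p_j(l) + bp_kj(l) + t_il + e_ijkl

where ``h_l`` is the fixed harvest effect, ``b_k(l)`` / ``p_j(l)`` /
``bp_kj(l)`` are random block, whole-plot entry and block-by-entry
effects nested in harvests (iid with variances ``sigma2_b``,
``sigma2_p``, ``sigma2_bp``), and the plant term ``t_il`` splits into a
random genetic effect ``g_il`` for sexual offspring and a fixed clone
effect ``c_il`` for apomictic check cultivars.  Across harvests the
genetic effects follow ``g ~ N(0, G_L (x) I)`` and residuals
``e ~ N(0, R_L (x) I)`` for structured L x L matrices ``G_L`` and
``R_L`` chosen from a nine-structure vocabulary (identity, diagonal,
compound symmetry, first-order autoregressive and power models with
homogeneous or heterogeneous variances, and unstructured).

Estimation is restricted maximum likelihood by direct maximization over
the structure parameters; structure choice is hierarchical (genetic
first against an identity residual, then residual) using AIC and BIC
with a largest-difference tie-break when the two criteria disagree.
The fit exposes genotype BLUPs, their prediction-error variances, a
generalized (Cullis) heritability, and adjusted entry means — the
per-genotype marginal predictions across harvests that become the
response of stage-2 genomic prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "VcovStructure",
    "build_vcov",
    "PhenotypeTable",
    "LongitudinalFit",
    "HeritabilityEstimate",
    "fit_longitudinal",
    "select_vcov",
    "criterion_tiebreak",
    "generalized_heritability",
    "adjusted_entry_means",
]

STRUCTURES = ("ID", "DIAG", "CS", "CSHet", "AR1", "AR1Het", "Po", "PoHet", "US")

_EPS_RHO = 1e-4


# ---------------------------------------------------------------------------
# VCOV structures


@dataclass
class VcovStructure:
    """A parameterized L x L covariance structure.

    ``params`` holds realized parameter values (``sigma2``, ``rho``,
    ``sigmas`` — per-harvest variances — or ``matrix`` for US); leave it
    ``None`` to use the structure as a fitting template.  ``times``
    supplies harvest coordinates for the power (Po/PoHet) models and
    defaults to ``1..L``.
    """

    name: str
    L: int
    params: dict | None = None
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.name not in STRUCTURES:
            raise ValueError(f"unknown structure {self.name!r}; one of {STRUCTURES}")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.times is None:
            self.times = np.arange(1, self.L + 1, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != self.L:
                raise ValueError("times length must equal L")

    @property
    def n_params(self) -> int:
        L = self.L
        return {
            "ID": 1,
            "DIAG": L,
            "CS": 2,
            "CSHet": L + 1,
            "AR1": 2,
            "AR1Het": L + 1,
            "Po": 2,
            "PoHet": L + 1,
            "US": L * (L + 1) // 2,
        }[self.name]

    # -- free-parameter transform (unconstrained <-> natural) ----------------

    def _rho_bounds(self) -> tuple[float, float]:
        if self.name in ("CS", "CSHet"):
            # compound symmetry is PD for rho in (-1/(L-1), 1)
            lo = -1.0 / (self.L - 1) if self.L > 1 else -1.0
            return lo + _EPS_RHO, 1.0 - _EPS_RHO
        if self.name in ("Po", "PoHet"):
            # rho^|t-s| needs a positive base
            return _EPS_RHO, 1.0 - _EPS_RHO
        return -1.0 + _EPS_RHO, 1.0 - _EPS_RHO

    def pack(self) -> np.ndarray:
        """Natural parameters -> unconstrained optimizer vector."""
        p = self.params
        if p is None:
            raise ValueError("structure has no parameters to pack")
        name = self.name
        if name == "ID":
            return np.array([np.log(p["sigma2"])])
        if name == "DIAG":
            return np.log(np.asarray(p["sigmas"], dtype=float))
        if name in ("CS", "AR1", "Po"):
            return np.array([np.log(p["sigma2"]), self._z_from_rho(p["rho"])])
        if name in ("CSHet", "AR1Het", "PoHet"):
            return np.concatenate(
                [np.log(np.asarray(p["sigmas"], dtype=float)), [self._z_from_rho(p["rho"])]]
            )
        # US: log-Cholesky
        C = np.linalg.cholesky(np.asarray(p["matrix"], dtype=float))
        out = []
        for i in range(self.L):
            for j in range(i + 1):
                out.append(np.log(C[i, i]) if i == j else C[i, j])
        return np.asarray(out)

    def unpack(self, z: np.ndarray) -> "VcovStructure":
        """Unconstrained optimizer vector -> structure with natural params."""
        z = np.asarray(z, dtype=float)
        name = self.name
        if name == "ID":
            params = {"sigma2": float(np.exp(z[0]))}
        elif name == "DIAG":
            params = {"sigmas": np.exp(z)}
        elif name in ("CS", "AR1", "Po"):
            params = {"sigma2": float(np.exp(z[0])), "rho": self._rho_from_z(z[1])}
        elif name in ("CSHet", "AR1Het", "PoHet"):
            params = {"sigmas": np.exp(z[:-1]), "rho": self._rho_from_z(z[-1])}
        else:  # US
            C = np.zeros((self.L, self.L))
            k = 0
            for i in range(self.L):
                for j in range(i + 1):
                    C[i, j] = np.exp(z[k]) if i == j else z[k]
                    k += 1
            params = {"matrix": C @ C.T}
        return replace(self, params=params)

    def _z_from_rho(self, rho: float) -> float:
        lo, hi = self._rho_bounds()
        u = (np.clip(rho, lo + 1e-9, hi - 1e-9) - lo) / (hi - lo)
        return float(np.log(u / (1.0 - u)))

    def _rho_from_z(self, z: float) -> float:
        lo, hi = self._rho_bounds()
        return float(lo + (hi - lo) / (1.0 + np.exp(-z)))

    def initial_pack(self, var_scale: float) -> np.ndarray:
        """A neutral starting point at total variance ``var_scale``."""
        template = {
            "ID": {"sigma2": var_scale},
            "DIAG": {"sigmas": np.full(self.L, var_scale)},
            "CS": {"sigma2": var_scale, "rho": 0.3},
            "CSHet": {"sigmas": np.full(self.L, var_scale), "rho": 0.3},
            "AR1": {"sigma2": var_scale, "rho": 0.3},
            "AR1Het": {"sigmas": np.full(self.L, var_scale), "rho": 0.3},
            "Po": {"sigma2": var_scale, "rho": 0.5},
            "PoHet": {"sigmas": np.full(self.L, var_scale), "rho": 0.5},
            "US": {
                "matrix": var_scale * (0.7 * np.eye(self.L) + 0.3 * np.ones((self.L, self.L)))
            },
        }[self.name]
        return replace(self, params=template).pack()

    def at_boundary(self, tol: float = 1e-3) -> bool:
        """True when a correlation parameter sits at its admissible edge."""
        if self.params is None or "rho" not in self.params:
            return False
        lo, hi = self._rho_bounds()
        rho = self.params["rho"]
        return bool(rho <= lo + tol or rho >= hi - tol)


def build_vcov(structure: VcovStructure) -> np.ndarray:
    """Realize the L x L covariance matrix of a parameterized structure."""
    p = structure.params
    if p is None:
        raise ValueError("structure has no parameters")
    L, name = structure.L, structure.name
    if name == "ID":
        return p["sigma2"] * np.eye(L)
    if name == "DIAG":
        return np.diag(np.asarray(p["sigmas"], dtype=float))
    if name == "CS":
        rho = p["rho"]
        return p["sigma2"] * ((1.0 - rho) * np.eye(L) + rho * np.ones((L, L)))
    if name == "CSHet":
        s = np.sqrt(np.asarray(p["sigmas"], dtype=float))
        rho = p["rho"]
        corr = rho + (1.0 - rho) * np.eye(L)
        return np.outer(s, s) * corr
    lag = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :]).astype(float)
    tdiff = np.abs(structure.times[:, None] - structure.times[None, :])
    if name == "AR1":
        return p["sigma2"] * p["rho"] ** lag
    if name == "AR1Het":
        s = np.sqrt(np.asarray(p["sigmas"], dtype=float))
        return np.outer(s, s) * p["rho"] ** lag
    if name == "Po":
        return p["sigma2"] * p["rho"] ** tdiff
    if name == "PoHet":
        s = np.sqrt(np.asarray(p["sigmas"], dtype=float))
        return np.outer(s, s) * p["rho"] ** tdiff
    # US
    M = np.asarray(p["matrix"], dtype=float)
    if M.shape != (L, L):
        raise ValueError("US matrix has wrong shape")
    if not np.allclose(M, M.T):
        raise ValueError("US matrix must be symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("US matrix must be positive semi-definite")
    return M


# ---------------------------------------------------------------------------
# Phenotype container


REQUIRED_COLUMNS = ("plant", "parent", "block", "harvest", "is_check", "value")


@dataclass
class PhenotypeTable:
    """Long-format trial records: one row per plant x harvest observation.

    Columns: ``plant`` (plant id), ``parent`` (whole-plot entry: dam
    family for offspring, cultivar for checks), ``block``, ``harvest``
    (1..L), ``is_check`` (bool) and ``value``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        dup = self.data.duplicated(subset=["plant", "block", "harvest"])
        if dup.any():
            raise ValueError("duplicate (plant, block, harvest) records")

    @property
    def n_harvests(self) -> int:
        return int(self.data["harvest"].nunique())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PhenotypeTable":
        return cls(frame.copy())


# ---------------------------------------------------------------------------
# REML machinery


@dataclass
class _Design:
    y: np.ndarray
    X: np.ndarray  # fixed effects
    fixed_names: list
    B_block: np.ndarray  # Z Z' for block(harvest)
    B_parent: np.ndarray
    B_bp: np.ndarray
    plant_slices: list  # (slice, harvest codes, is_check) per plant, obs sorted
    plants: list  # genotype plant ids in slice order (checks excluded)
    harvest_levels: np.ndarray
    n_obs: int
    logdet_xtx: float


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((len(codes), n_levels))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _build_design(table: PhenotypeTable) -> _Design:
    df = table.data.sort_values(["is_check", "plant", "harvest"], kind="stable")
    df = df.reset_index(drop=True)
    y = df["value"].to_numpy(dtype=float)
    n = len(df)

    harvest_levels, h_codes = np.unique(df["harvest"].to_numpy(), return_inverse=True)
    L = len(harvest_levels)
    block_levels, b_codes = np.unique(df["block"].to_numpy(), return_inverse=True)
    parent_levels, p_codes = np.unique(df["parent"].to_numpy(), return_inverse=True)

    # fixed: intercept + harvest contrasts + check-cultivar x harvest cells
    X_cols = [np.ones(n)]
    fixed_names = ["mu"]
    for l in range(1, L):
        X_cols.append((h_codes == l).astype(float))
        fixed_names.append(f"harvest:{harvest_levels[l]}")
    is_check = df["is_check"].to_numpy(dtype=bool)
    check_levels = np.unique(df.loc[is_check, "parent"]) if is_check.any() else []
    for c in check_levels:
        for l in range(L):
            col = ((df["parent"].to_numpy() == c) & (h_codes == l) & is_check).astype(float)
            X_cols.append(col)
            fixed_names.append(f"check:{c}:h{harvest_levels[l]}")
    X = np.column_stack(X_cols)

    bh = b_codes * L + h_codes
    ph = p_codes * L + h_codes
    bph = (b_codes * len(parent_levels) + p_codes) * L + h_codes
    Zb = _dummies(bh, len(block_levels) * L)
    Zp = _dummies(ph, len(parent_levels) * L)
    Zbp = _dummies(bph, len(block_levels) * len(parent_levels) * L)

    plant_slices = []
    plants = []
    start = 0
    for plant, group in df.groupby("plant", sort=False):
        idx = group.index.to_numpy()
        if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
            raise AssertionError("plant rows not contiguous after sort")
        hcodes = h_codes[idx]
        check = bool(group["is_check"].iloc[0])
        plant_slices.append((slice(idx[0], idx[-1] + 1), hcodes, check))
        if not check:
            plants.append(plant)
        start = idx[-1] + 1
    if start != n:
        raise AssertionError("plant grouping does not cover all rows")

    sign, logdet_xtx = np.linalg.slogdet(X.T @ X)
    if sign <= 0:
        raise ValueError("singular fixed-effect design")

    return _Design(
        y=y,
        X=X,
        fixed_names=fixed_names,
        B_block=Zb @ Zb.T,
        B_parent=Zp @ Zp.T,
        B_bp=Zbp @ Zbp.T,
        plant_slices=plant_slices,
        plants=plants,
        harvest_levels=harvest_levels,
        n_obs=n,
        logdet_xtx=float(logdet_xtx),
    )


def _assemble_v(
    design: _Design,
    vc: np.ndarray,
    G_L: np.ndarray,
    R_L: np.ndarray,
) -> np.ndarray:
    s2b, s2p, s2bp = vc
    V = s2b * design.B_block + s2p * design.B_parent + s2bp * design.B_bp
    for sl, hcodes, check in design.plant_slices:
        block = R_L[np.ix_(hcodes, hcodes)].copy()
        if not check:
            block += G_L[np.ix_(hcodes, hcodes)]
        V[sl, sl] += block
    return V


def _reml_loglik(design: _Design, V: np.ndarray) -> tuple[float, dict]:
    """Restricted log-likelihood (with constants) and solver intermediates.

    Uses the profiled form  -1/2 [ (n-p) log 2pi + log|V| + log|X'V^-1 X|
    - log|X'X| + y'Py ], which equals the likelihood of any orthonormal
    set of error contrasts.
    """
    n, p = design.X.shape
    try:
        cf = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return -np.inf, {}
    logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
    Vi_y = cho_solve(cf, design.y, check_finite=False)
    Vi_X = cho_solve(cf, design.X, check_finite=False)
    XtViX = design.X.T @ Vi_X
    try:
        cfx = cho_factor(XtViX, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return -np.inf, {}
    logdet_xvx = 2.0 * np.log(np.diag(cfx[0])).sum()
    beta = cho_solve(cfx, design.X.T @ Vi_y, check_finite=False)
    Py = Vi_y - Vi_X @ beta
    quad = float(design.y @ Py)
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi)
        + logdet_v
        + logdet_xvx
        - design.logdet_xtx
        + quad
    )
    return float(ll), {"cf": cf, "Py": Py, "beta": beta, "cfx": cfx, "Vi_X": Vi_X}


@dataclass
class LongitudinalFit:
    """REML fit of the longitudinal trial model."""

    mu: float
    harvest_effects: pd.Series
    check_effects: pd.Series
    sigma2_block: float
    sigma2_parent: float
    sigma2_block_parent: float
    g_structure: VcovStructure
    r_structure: VcovStructure
    G_L: np.ndarray
    R_L: np.ndarray
    loglik: float
    n_par: int
    aic: float
    bic: float
    blups: pd.DataFrame  # genotype plants x harvests
    blup_mean: pd.Series  # harvest-mean genetic BLUP per genotype plant
    mean_comparison_pev: float  # average variance of pairwise BLUP differences
    sigma2_g_mean: float  # variance of the harvest-mean genetic value under G_L
    entry_means: pd.Series
    converged: bool
    boundary: bool
    n_obs: int
    message: str = ""

    @property
    def variance_components(self) -> dict:
        return {
            "sigma2_block": self.sigma2_block,
            "sigma2_parent": self.sigma2_parent,
            "sigma2_block_parent": self.sigma2_block_parent,
            "G_L": self.g_structure.params,
            "R_L": self.r_structure.params,
        }


@dataclass
class HeritabilityEstimate:
    """Generalized (Cullis) heritability H2 = 1 - PEV / (2 sigma2_G)."""

    h2: float
    pev: float
    sigma2_g: float
    flagged: bool = False
    message: str = ""


def fit_longitudinal(
    table: PhenotypeTable | pd.DataFrame,
    g_structure: VcovStructure,
    r_structure: VcovStructure,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_starts: int = 2,
) -> LongitudinalFit:
    """Fit the longitudinal trial model by REML.

    Optimizes the restricted likelihood over the block / whole-plot /
    interaction variances and the parameters of the genetic and residual
    structures on log-variance / transformed-correlation scales, then
    extracts fixed-effect estimates, genotype BLUPs and their
    prediction-error variances, information criteria and adjusted entry
    means.
    """
    if isinstance(table, pd.DataFrame):
        table = PhenotypeTable(table)
    design = _build_design(table)
    L = len(design.harvest_levels)
    if g_structure.L != L or r_structure.L != L:
        raise ValueError(f"structures must have L={L}")

    var_y = float(np.var(design.y)) or 1.0
    n_vc = 3

    def split(z):
        vc = np.exp(z[:n_vc])
        gs = g_structure.unpack(z[n_vc : n_vc + g_structure.n_params])
        rs = r_structure.unpack(z[n_vc + g_structure.n_params :])
        return vc, gs, rs

    def negll(z):
        vc, gs, rs = split(z)
        try:
            G_L = build_vcov(gs)
            R_L = build_vcov(rs)
        except (ValueError, np.linalg.LinAlgError):
            return np.inf
        V = _assemble_v(design, vc, G_L, R_L)
        ll, _ = _reml_loglik(design, V)
        return -ll if np.isfinite(ll) else np.inf

    starts = []
    base = np.concatenate(
        [
            np.log([var_y / 10, var_y / 10, var_y / 10]),
            g_structure.initial_pack(var_y / 3),
            r_structure.initial_pack(var_y / 3),
        ]
    )
    starts.append(base)
    if n_starts > 1:
        alt = np.concatenate(
            [
                np.log([var_y / 4, var_y / 4, var_y / 4]),
                g_structure.initial_pack(var_y),
                r_structure.initial_pack(var_y / 10),
            ]
        )
        starts.append(alt)

    best = None
    for z0 in starts[:n_starts]:
        res = optimize.minimize(
            negll,
            z0,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    converged = bool(np.isfinite(best.fun))

    vc, gs, rs = split(best.x)
    G_L = build_vcov(gs)
    R_L = build_vcov(rs)
    V = _assemble_v(design, vc, G_L, R_L)
    ll, aux = _reml_loglik(design, V)

    n_par = n_vc + g_structure.n_params + r_structure.n_params
    n_eff = design.n_obs - design.X.shape[1]
    aic = -2.0 * ll + 2.0 * n_par
    bic = -2.0 * ll + n_par * np.log(n_eff)

    # fixed effects
    beta = aux["beta"]
    mu = float(beta[0])
    h_eff = pd.Series(0.0, index=design.harvest_levels, name="harvest")
    c_eff = {}
    for name, b in zip(design.fixed_names, beta):
        if name.startswith("harvest:"):
            h_eff.loc[type(design.harvest_levels[0])(name.split(":", 1)[1])] = float(b)
        elif name.startswith("check:"):
            c_eff[name[len("check:"):]] = float(b)

    # genotype BLUPs:  u = (I (x) G_L) Z' P y, block diagonal per plant
    Py = aux["Py"]
    n_g = len(design.plants)
    blups = np.zeros((n_g, L))
    # rows of T = C D Z'  (C = harvest-mean contrast per genotype plant)
    T = np.zeros((n_g, design.n_obs))
    gmean_row = (np.ones(L) / L) @ G_L  # 1'G_L / L
    gi = 0
    for sl, hcodes, check in design.plant_slices:
        if check:
            continue
        Gsub = G_L[:, hcodes]  # L x n_l : D Z' block for this plant
        blups[gi] = Gsub @ Py[sl]
        T[gi, sl] = gmean_row[hcodes]
        gi += 1

    blup_mean = blups.mean(axis=1)
    # PEV of harvest-mean genetic predictions: C D C' - T P T'
    cdc = float(np.ones(L) @ G_L @ np.ones(L)) / L**2
    cf = aux["cf"]
    Vi_T = cho_solve(cf, T.T, check_finite=False)
    XtVi_T = aux["Vi_X"].T @ T.T
    cfx = aux["cfx"]
    PT = Vi_T - aux["Vi_X"] @ cho_solve(cfx, XtVi_T, check_finite=False)
    pev_m = cdc * np.eye(n_g) - T @ PT
    if n_g > 1:
        d = np.diag(pev_m)
        vd = d[:, None] + d[None, :] - 2.0 * pev_m
        mean_pev = float(vd.sum() / (n_g * (n_g - 1)))
    else:
        mean_pev = float(pev_m[0, 0])

    fixed_mean = mu + float(h_eff.mean())
    entry_means = pd.Series(fixed_mean + blup_mean, index=design.plants, name="entry_mean")

    boundary = gs.at_boundary() or rs.at_boundary() or (vc.min() < 1e-8 * var_y)

    return LongitudinalFit(
        mu=mu,
        harvest_effects=h_eff,
        check_effects=pd.Series(c_eff, dtype=float),
        sigma2_block=float(vc[0]),
        sigma2_parent=float(vc[1]),
        sigma2_block_parent=float(vc[2]),
        g_structure=gs,
        r_structure=rs,
        G_L=G_L,
        R_L=R_L,
        loglik=float(ll),
        n_par=n_par,
        aic=float(aic),
        bic=float(bic),
        blups=pd.DataFrame(blups, index=design.plants, columns=design.harvest_levels),
        blup_mean=pd.Series(blup_mean, index=design.plants),
        mean_comparison_pev=mean_pev,
        sigma2_g_mean=cdc,
        entry_means=entry_means,
        converged=converged,
        boundary=boundary,
        n_obs=design.n_obs,
        message=str(getattr(best, "message", "")),
    )


# ---------------------------------------------------------------------------
# Hierarchical structure selection


def criterion_tiebreak(
    aic: Sequence[float], bic: Sequence[float]
) -> tuple[int, dict]:
    """Pick a model by AIC and BIC with the largest-difference tie-break.

    When the AIC-best and BIC-best models differ, each criterion's
    difference between those two candidates is computed, and the
    criterion with the larger difference decides.
    """
    aic = np.asarray(aic, dtype=float)
    bic = np.asarray(bic, dtype=float)
    i_aic = int(np.nanargmin(aic))
    i_bic = int(np.nanargmin(bic))
    if i_aic == i_bic:
        return i_aic, {"agreement": True, "governing": "both"}
    d_aic = float(aic[i_bic] - aic[i_aic])
    d_bic = float(bic[i_aic] - bic[i_bic])
    governing = "BIC" if d_bic > d_aic else "AIC"
    chosen = i_bic if governing == "BIC" else i_aic
    return chosen, {
        "agreement": False,
        "aic_best": i_aic,
        "bic_best": i_bic,
        "aic_difference": d_aic,
        "bic_difference": d_bic,
        "governing": governing,
    }


def select_vcov(
    table: PhenotypeTable | pd.DataFrame,
    candidates: Sequence[VcovStructure],
    r_candidates: Sequence[VcovStructure] | None = None,
    **fit_kwargs,
) -> tuple[VcovStructure, VcovStructure, dict]:
    """Hierarchical choice of the genetic and residual structures.

    Step 1 fits every candidate genetic structure against an identity
    residual and picks the best; step 2 fixes that genetic structure and
    fits every candidate residual structure.  Within each step, models
    are ranked by AIC and BIC with :func:`criterion_tiebreak`.
    Returns the chosen structures (with fitted parameters) and a trace.
    """
    if not candidates:
        raise ValueError("no candidate structures")
    if isinstance(table, pd.DataFrame):
        table = PhenotypeTable(table)
    if r_candidates is None:
        r_candidates = candidates
    L = table.n_harvests
    identity = VcovStructure("ID", L)

    def run_step(g_list, r_list):
        fits, labels = [], []
        for gs in g_list:
            for rs in r_list:
                try:
                    fits.append(fit_longitudinal(table, gs, rs, **fit_kwargs))
                except (ValueError, np.linalg.LinAlgError) as exc:
                    warnings.warn(f"fit failed for {gs.name}/{rs.name}: {exc}")
                    fits.append(None)
                labels.append((gs.name, rs.name))
        ok = [i for i, f in enumerate(fits) if f is not None and np.isfinite(f.loglik)]
        if not ok:
            raise RuntimeError("all candidate fits failed")
        aic = [fits[i].aic if i in ok else np.nan for i in range(len(fits))]
        bic = [fits[i].bic if i in ok else np.nan for i in range(len(fits))]
        chosen, trace = criterion_tiebreak(aic, bic)
        table_rows = [
            {
                "g_structure": labels[i][0],
                "r_structure": labels[i][1],
                "loglik": fits[i].loglik if fits[i] else np.nan,
                "n_par": fits[i].n_par if fits[i] else np.nan,
                "aic": aic[i],
                "bic": bic[i],
            }
            for i in range(len(fits))
        ]
        return chosen, fits[chosen], {"models": table_rows, "tiebreak": trace}

    i1, fit1, trace1 = run_step(list(candidates), [identity])
    chosen_g = fit1.g_structure
    i2, fit2, trace2 = run_step([replace(chosen_g, params=None)], list(r_candidates))
    chosen_r = fit2.r_structure
    trace = {"step1_genetic": trace1, "step2_residual": trace2, "final_fit": fit2}
    return chosen_g, chosen_r, trace


def generalized_heritability(fit: LongitudinalFit) -> HeritabilityEstimate:
    """Cullis generalized heritability from a CS-genetic / ID-residual fit.

    H2 = 1 - PEV / (2 sigma2_G), where PEV is the average prediction
    error variance of pairwise genotype comparisons (on harvest-mean
    BLUPs) and sigma2_G the genetic variance.
    """
    if fit.g_structure.name not in ("CS", "ID"):
        raise ValueError("generalized heritability expects a CS (or ID) genetic structure")
    if fit.g_structure.name == "CS":
        sigma2_g = float(fit.g_structure.params["sigma2"])
    else:
        sigma2_g = float(fit.g_structure.params["sigma2"])
    if sigma2_g <= 0:
        return HeritabilityEstimate(np.nan, fit.mean_comparison_pev, sigma2_g, True, "zero genetic variance")
    h2 = 1.0 - fit.mean_comparison_pev / (2.0 * sigma2_g)
    flagged = False
    msg = ""
    if not 0.0 <= h2 <= 1.0:
        flagged = True
        msg = f"H2 {h2:.3f} outside [0, 1]; clipped"
        warnings.warn(msg)
        h2 = float(np.clip(h2, 0.0, 1.0))
    return HeritabilityEstimate(float(h2), fit.mean_comparison_pev, sigma2_g, flagged, msg)


def adjusted_entry_means(fit: LongitudinalFit) -> pd.Series:
    """Per-genotype marginal prediction across harvests.

    mean over harvests of (mu + h_l + g_il); check cultivars excluded.
    """
    return fit.entry_means.copy()
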