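"""Single-site Gibbs sampler core for the Bayesian marker-effect models.

The whole chain runs inside one function written in the numpy subset
numba can compile; when numba is importable the function is jitted,
otherwise the same code runs as plain Python.  Randomness comes from
the legacy ``np.random`` state seeded explicitly at entry (numba keeps
an internal copy of that generator), so a given seed is reproducible
within an installation.

Model codes: 0 = BRR, 1 = BayesA, 2 = BayesB, 3 = BayesC,
4 = Bayesian LASSO.  The spike of BayesB/C is an exact point mass at
zero handled through binary inclusion indicators; the Bayesian LASSO
follows the Park & Casella hierarchy with marker prior variance
``sigma2_e * tau2_j`` and ``tau2_j ~ Exp(lambda2 / 2)``.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _rand_invgauss(mu: float, lam: float) -> float:
    """Inverse-Gaussian draw (Michael-Schucany-Haas)."""
    nu = np.random.standard_normal()
    y = nu * nu
    x = mu + mu * mu * y / (2.0 * lam) - mu / (2.0 * lam) * np.sqrt(
        4.0 * mu * lam * y + mu * mu * y * y
    )
    if x <= 0.0:
        return mu * mu / 1e-10
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def gibbs_core(
    X,
    y,
    model,
    n_iter,
    burn_in,
    thin,
    df_beta,
    s_beta,
    df_eps,
    s_eps,
    pi_spike,
    lambda2,
    lambda_shape,
    lambda_rate,
    update_lambda,
    update_marker_var,
    seed,
):
    """Run the chain; returns posterior summaries.

    ``update_marker_var`` False freezes the marker and residual variance
    hyperparameters at their initial values (degenerate hyperpriors),
    which turns BRR into a fixed-variance ridge sampler for oracle
    checks.
    """
    np.random.seed(seed)
    n, p = X.shape
    xtx = np.zeros(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += X[i, j] * X[i, j]
        xtx[j] = acc

    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    beta = np.zeros(p)
    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu

    sigma2_e = s_eps
    sigma2_b = s_beta  # common (BRR, BC)
    sigma2_bj = np.full(p, s_beta)  # per marker (BA, BB)
    tau2 = np.full(p, s_beta / s_eps)  # BL: prior variance sigma2_e * tau2 starts at s_beta
    incl = np.ones(p, dtype=np.bool_)
    lam2 = lambda2

    n_saved = 0
    mu_sum = 0.0
    beta_sum = np.zeros(p)
    beta_sq = np.zeros(p)
    pip_sum = np.zeros(p)
    s2e_sum = 0.0
    s2b_sum = 0.0
    lam2_sum = 0.0
    gebv_sum = np.zeros(n)

    for it in range(n_iter):
        # intercept (flat prior)
        acc = 0.0
        for i in range(n):
            e[i] += mu
            acc += e[i]
        mu = acc / n + np.random.standard_normal() * np.sqrt(sigma2_e / n)
        for i in range(n):
            e[i] -= mu

        # marker sweep
        for j in range(p):
            if xtx[j] <= 0.0:
                beta[j] = 0.0
                continue
            b_old = beta[j]
            r = 0.0
            for i in range(n):
                r += X[i, j] * e[i]
            r += xtx[j] * b_old

            if model == 0:  # BRR
                var_j = sigma2_b
            elif model == 1:  # BayesA
                var_j = sigma2_bj[j]
            elif model == 2:  # BayesB
                var_j = sigma2_bj[j]
            elif model == 3:  # BayesC
                var_j = sigma2_b
            else:  # BL: prior var sigma2_e * tau2_j
                var_j = sigma2_e * tau2[j]

            draw = True
            if model == 2 or model == 3:
                # spike/slab indicator from the marginal likelihood of r
                v0 = xtx[j] * sigma2_e
                v1 = v0 + xtx[j] * xtx[j] * var_j
                log_bf = 0.5 * (np.log(v0 / v1) + r * r * (1.0 / v0 - 1.0 / v1))
                if pi_spike >= 1.0:
                    p_slab = 0.0
                elif pi_spike <= 0.0:
                    p_slab = 1.0
                else:
                    # odds = ((1-pi)/pi) * BF, stabilized in log space
                    log_odds = np.log((1.0 - pi_spike) / pi_spike) + log_bf
                    if log_odds > 35.0:
                        p_slab = 1.0
                    elif log_odds < -35.0:
                        p_slab = 0.0
                    else:
                        p_slab = 1.0 / (1.0 + np.exp(-log_odds))
                if np.random.random() < p_slab:
                    incl[j] = True
                else:
                    incl[j] = False
                    draw = False

            if draw:
                denom = xtx[j] + sigma2_e / var_j
                b_new = r / denom + np.random.standard_normal() * np.sqrt(
                    sigma2_e / denom
                )
            else:
                b_new = 0.0
            if b_new != b_old:
                diff = b_new - b_old
                for i in range(n):
                    e[i] -= X[i, j] * diff
            beta[j] = b_new

        # variance hyperparameters
        if update_marker_var:
            if model == 0:
                ssb = 0.0
                for j in range(p):
                    ssb += beta[j] * beta[j]
                sigma2_b = (ssb + df_beta * s_beta) / np.random.chisquare(df_beta + p)
            elif model == 1:
                for j in range(p):
                    sigma2_bj[j] = (beta[j] * beta[j] + df_beta * s_beta) / np.random.chisquare(
                        df_beta + 1
                    )
            elif model == 2:
                for j in range(p):
                    if incl[j]:
                        sigma2_bj[j] = (
                            beta[j] * beta[j] + df_beta * s_beta
                        ) / np.random.chisquare(df_beta + 1)
                    else:
                        sigma2_bj[j] = df_beta * s_beta / np.random.chisquare(df_beta)
            elif model == 3:
                ssb = 0.0
                m = 0
                for j in range(p):
                    if incl[j]:
                        ssb += beta[j] * beta[j]
                        m += 1
                sigma2_b = (ssb + df_beta * s_beta) / np.random.chisquare(df_beta + m)
            else:  # BL
                for j in range(p):
                    b2 = beta[j] * beta[j]
                    if b2 < 1e-12:
                        b2 = 1e-12
                    mu_ig = np.sqrt(lam2 * sigma2_e / b2)
                    inv_tau2 = _rand_invgauss(mu_ig, lam2)
                    tau2[j] = 1.0 / inv_tau2
                if update_lambda:
                    st = 0.0
                    for j in range(p):
                        st += tau2[j]
                    lam2 = np.random.gamma(lambda_shape + p, 1.0 / (lambda_rate + st / 2.0))

            # residual variance
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            if model == 4:
                extra = 0.0
                for j in range(p):
                    extra += beta[j] * beta[j] / tau2[j]
                sigma2_e = (sse + extra + df_eps * s_eps) / np.random.chisquare(
                    df_eps + n + p
                )
            else:
                sigma2_e = (sse + df_eps * s_eps) / np.random.chisquare(df_eps + n)

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_saved += 1
            mu_sum += mu
            s2e_sum += sigma2_e
            lam2_sum += lam2
            if model == 1 or model == 2:
                acc = 0.0
                for j in range(p):
                    acc += sigma2_bj[j]
                s2b_sum += acc / p
            elif model == 4:
                acc = 0.0
                for j in range(p):
                    acc += sigma2_e * tau2[j]
                s2b_sum += acc / p
            else:
                s2b_sum += sigma2_b
            for j in range(p):
                beta_sum[j] += beta[j]
                beta_sq[j] += beta[j] * beta[j]
                if incl[j]:
                    pip_sum[j] += 1.0
            for i in range(n):
                gebv_sum[i] += y[i] - e[i] - mu  # = (X beta)_i this iteration

    return (
        mu_sum / n_saved,
        beta_sum / n_saved,
        beta_sq / n_saved,
        pip_sum / n_saved,
        s2e_sum / n_saved,
        s2b_sum / n_saved,
        lam2_sum / n_saved,
        gebv_sum / n_saved,
        n_saved,
    )
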