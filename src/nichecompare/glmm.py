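"""Binomial logistic mixed model with crossed random intercepts.

Fits, by maximum likelihood with a Laplace approximation to the
random-effect integral, the model

    y_i ~ Binomial(n_i, p_i),   logit(p_i) = beta[niche(i)] + b[dog(i)] + c[day(i)]
    b_d ~ N(0, sigma_dog^2),    c_t ~ N(0, sigma_day^2)   (crossed, independent)

where y_i is a taxon's read count out of the sample total n_i.  Fixed
effects use cell-means (one logit mean per niche) so pairwise contrasts
are simple coefficient differences.  A weak Gaussian stabilising
penalty (sd 10 on the fixed effects) guards against separation when a
taxon is absent from a niche; its shrinkage is negligible whenever the
data carry any real information.

Internally the random effects are standardised (u = b/sigma) and the
design columns scaled by sigma, the penalised joint mode in (beta, u)
is found by Newton iterations with step halving, and the Laplace
criterion  l(theta) = logLik_pen(mode) - 1/2 log|H_uu|  is maximised
over (sigma_dog, sigma_day) by Nelder-Mead.  sigma = 0 is an interior
point of the |sigma| parametrisation, so boundary fits (zero variance)
are handled without special casing and reproduce an ordinary penalised
binomial regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

__all__ = ["GlmmFit", "GlmmDesign", "fit_binomial_glmm_arrays", "pairwise_contrasts"]

_BETA_PENALTY_SD = 10.0


@dataclass
class GlmmDesign:
    """Integer-coded design for one fit: niche, dog and day per sample."""

    niche_codes: np.ndarray  # values in 0..n_niches-1
    dog_codes: np.ndarray
    day_codes: np.ndarray
    niche_levels: list[str]

    def __post_init__(self) -> None:
        self.niche_codes = np.asarray(self.niche_codes, dtype=np.intp)
        self.dog_codes = np.asarray(self.dog_codes, dtype=np.intp)
        self.day_codes = np.asarray(self.day_codes, dtype=np.intp)

    @property
    def n_niches(self) -> int:
        return len(self.niche_levels)

    @property
    def n_dogs(self) -> int:
        return int(self.dog_codes.max()) + 1 if self.dog_codes.size else 0

    @property
    def n_days(self) -> int:
        return int(self.day_codes.max()) + 1 if self.day_codes.size else 0

    def matrix(self, niche_codes: np.ndarray | None = None) -> np.ndarray:
        """Dense [X | Z_dog | Z_day] indicator matrix (unscaled)."""
        nc = self.niche_codes if niche_codes is None else niche_codes
        n = nc.size
        p, q1, q2 = self.n_niches, self.n_dogs, self.n_days
        A = np.zeros((n, p + q1 + q2))
        rows = np.arange(n)
        A[rows, nc] = 1.0
        A[rows, p + self.dog_codes] = 1.0
        A[rows, p + q1 + self.day_codes] = 1.0
        return A


@dataclass
class GlmmFit:
    """Result of one mixed-model fit."""

    niche_levels: list[str]
    beta: np.ndarray            # per-niche logit means
    cov_beta: np.ndarray        # Wald covariance of beta (conditional on theta)
    var_dog: float
    var_day: float
    loglik: float               # Laplace objective at the optimum
    converged: bool
    u_dog: np.ndarray           # empirical-Bayes modes (original scale)
    u_day: np.ndarray

    @property
    def mean_proportions(self) -> np.ndarray:
        """Population-level fitted niche proportions (random effects at 0)."""
        return expit(self.beta)

    def mean_proportion_ci(self, level: float = 0.95) -> np.ndarray:
        z = norm.ppf(0.5 + level / 2)
        se = np.sqrt(np.diag(self.cov_beta))
        lo = expit(self.beta - z * se)
        hi = expit(self.beta + z * se)
        return np.column_stack([lo, hi])


def _penalized_state(eta: np.ndarray, y, n, coef, pen) -> float:
    # binomial loglik (no binom coefficient) minus quadratic penalty
    ll = float(np.dot(y, eta) - np.dot(n, np.logaddexp(0.0, eta)))
    return ll - 0.5 * float(np.dot(pen, coef * coef))


def _newton_mode(y, n, A, pen, coef0, max_iter=60, tol=1e-9):
    """Penalised joint mode in (beta, u) by damped Newton iterations."""
    coef = coef0.copy()
    eta = A @ coef
    f = _penalized_state(eta, y, n, coef, pen)
    for _ in range(max_iter):
        p = expit(eta)
        mu = n * p
        w = mu * (1.0 - p)
        g = A.T @ (y - mu) - pen * coef
        gmax = np.max(np.abs(g))
        H = (A.T * w) @ A
        H[np.diag_indices_from(H)] += pen + 1e-12
        try:
            c, low = cho_factor(H, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            H[np.diag_indices_from(H)] += 1e-6
            c, low = cho_factor(H, lower=True, check_finite=False)
        step = cho_solve((c, low), g, check_finite=False)
        t = 1.0
        for _half in range(30):
            new_coef = coef + t * step
            new_eta = A @ new_coef
            new_f = _penalized_state(new_eta, y, n, new_coef, pen)
            if new_f >= f - 1e-12:
                break
            t *= 0.5
        else:
            return coef, H, f, gmax < 1e-4
        moved = np.max(np.abs(t * step))
        coef, eta, f = new_coef, new_eta, new_f
        if gmax < tol * (1.0 + abs(f)) or moved < 1e-10:
            break
    # final Hessian at the mode
    p = expit(eta)
    w = n * p * (1.0 - p)
    H = (A.T * w) @ A
    H[np.diag_indices_from(H)] += pen + 1e-12
    g = A.T @ (y - n * p) - pen * coef
    return coef, H, f, np.max(np.abs(g)) < 1e-4 * (1.0 + abs(f))


def _laplace_objective(sig, y, n, design: GlmmDesign, A0, pen, coef_start):
    """Negative Laplace criterion at sigma = |sig| (for the outer optimiser)."""
    sd, st = abs(sig[0]), abs(sig[1])
    p, q1, q2 = design.n_niches, design.n_dogs, design.n_days
    scale = np.concatenate([np.ones(p), np.full(q1, sd), np.full(q2, st)])
    A = A0 * scale
    coef, H, f, ok = _newton_mode(y, n, A, pen, coef_start)
    Huu = H[p:, p:]
    sign, logdet = np.linalg.slogdet(Huu)
    if sign <= 0:
        return 1e10, coef, ok
    return -(f - 0.5 * logdet), coef, ok


def fit_binomial_glmm_arrays(
    y: np.ndarray,
    n: np.ndarray,
    design: GlmmDesign,
    sigma_start: tuple[float, float] = (0.3, 0.15),
    coef_start: np.ndarray | None = None,
    xatol: float = 0.02,
    maxfev: int = 80,
) -> GlmmFit:
    """Fit the crossed-intercept binomial GLMM for one taxon.

    ``y``/``n`` are the taxon count and total reads per sample; the
    design supplies niche/dog/day codes.  Raises if fewer than two
    niches are present or any total is nonpositive.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("all sample totals must be > 0")
    if np.unique(design.niche_codes).size < 2:
        raise ValueError("at least two niches are required")

    p, q1, q2 = design.n_niches, design.n_dogs, design.n_days
    pen = np.concatenate(
        [np.full(p, _BETA_PENALTY_SD**-2), np.ones(q1 + q2)]
    )
    A0 = design.matrix()

    if coef_start is None:
        coef_start = np.zeros(p + q1 + q2)
        # start fixed effects at empirical logits
        for g in range(p):
            mask = design.niche_codes == g
            if mask.any():
                ybar = (y[mask].sum() + 0.5) / (n[mask].sum() + 1.0)
                coef_start[g] = np.log(ybar / (1.0 - ybar))
    state = {"coef": coef_start.copy(), "ok": True}

    def obj(sig):
        val, coef, ok = _laplace_objective(sig, y, n, design, A0, pen, state["coef"])
        state["coef"] = coef
        state["ok"] = ok
        return val

    res = minimize(
        obj,
        x0=np.asarray(sigma_start, dtype=float),
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": 1e-3, "maxfev": maxfev},
    )
    sd, st = abs(res.x[0]), abs(res.x[1])

    # final refit at the optimum for coefficients and Wald covariance
    scale = np.concatenate([np.ones(p), np.full(q1, sd), np.full(q2, st)])
    A = A0 * scale
    coef, H, f, ok = _newton_mode(y, n, A, pen, state["coef"])
    Huu = H[p:, p:]
    sign, logdet = np.linalg.slogdet(Huu)
    loglik = f - 0.5 * logdet if sign > 0 else -np.inf
    cov = np.linalg.inv(H)
    return GlmmFit(
        niche_levels=list(design.niche_levels),
        beta=coef[:p].copy(),
        cov_beta=cov[:p, :p].copy(),
        var_dog=sd * sd,
        var_day=st * st,
        loglik=loglik,
        converged=bool(ok),
        u_dog=coef[p : p + q1] * sd,
        u_day=coef[p + q1 :] * st,
    )


_Z975 = 1.959963984540054


def pairwise_contrasts(fit: GlmmFit) -> list[dict]:
    """All pairwise niche contrasts: log-odds difference, OR, 95% CI, Wald z."""
    out = []
    p = len(fit.niche_levels)
    for i in range(p):
        for j in range(i + 1, p):
            est = fit.beta[i] - fit.beta[j]
            var = fit.cov_beta[i, i] + fit.cov_beta[j, j] - 2.0 * fit.cov_beta[i, j]
            se = float(np.sqrt(max(var, 1e-300)))
            z = est / se if se > 0 else 0.0
            zq = _Z975
            out.append(
                {
                    "niche_pair": (fit.niche_levels[i], fit.niche_levels[j]),
                    "log_odds_diff": float(est),
                    "se": se,
                    "wald_stat": float(z),
                    "odds_ratio": float(np.exp(est)),
                    "or_ci_low": float(np.exp(est - zq * se)),
                    "or_ci_high": float(np.exp(est + zq * se)),
                }
            )
    return out
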