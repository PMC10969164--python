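"""Bayesian standard curve: onset median regressed on population median.

Model, for reference registries i = 1..n of one sex:

    y_i ~ Normal(alpha + beta * x_i, 1 / tau)
    alpha ~ Normal(0, precision 1e-6)
    beta  ~ Normal(0, precision 1e-6)
    tau   ~ Gamma(shape 0.5, rate 0.01)

with y the median age at cancer onset and x the median age of the
population, both in years. The model is conditionally conjugate, so the
posterior is sampled by a block Gibbs sampler: (alpha, beta) jointly from
their bivariate normal full conditional given tau, then tau from its gamma
full conditional. The default run length mirrors the original analysis
(3 chains, 100,000 burn-in + 100,000 retained iterations); tests and
simulations use much shorter chains.

Alongside the parameter draws the sampler retains one posterior predictive
noise draw eps_d ~ Normal(0, 1/tau_d) per kept iteration, so predictive
intervals and predictive residual draws are deterministic functions of the
fitted curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from earlyonset.registry_io import MedianPair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the vague priors on intercept, slope and noise precision."""

    intercept_mean: float = 0.0
    intercept_precision: float = 1.0e-6
    slope_mean: float = 0.0
    slope_precision: float = 1.0e-6
    noise_precision_shape: float = 0.5
    noise_precision_rate: float = 0.01

    def __post_init__(self) -> None:
        if min(self.intercept_precision, self.slope_precision,
               self.noise_precision_shape, self.noise_precision_rate) <= 0:
            raise ValueError("precisions, shape and rate must be positive")


@dataclass(frozen=True)
class McmcSettings:
    """Chain configuration; defaults follow the original analysis's run length."""

    chains: int = 3
    burn_in: int = 100_000
    samples: int = 100_000
    seed: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.burn_in < 0:
            raise ValueError("burn-in must be nonnegative")
        if self.samples < 1:
            raise ValueError("need at least one retained sample")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def scaled(self, chains: int, burn_in: int, samples: int) -> "McmcSettings":
        return replace(self, chains=chains, burn_in=burn_in, samples=samples)


@dataclass
class StandardCurve:
    """Posterior draws of the standard-curve parameters for one sex.

    ``alpha``/``beta``/``tau`` have shape (chains, draws); ``eps`` holds the
    matched posterior predictive noise draws Normal(0, 1/tau).
    """

    alpha: np.ndarray
    beta: np.ndarray
    tau: np.ndarray
    eps: np.ndarray
    reference_ids: tuple[str, ...]
    sex: str
    x_ref: np.ndarray
    y_ref: np.ndarray
    priors: PriorSpec = field(default_factory=PriorSpec)
    settings: McmcSettings = field(default_factory=McmcSettings)

    def __post_init__(self) -> None:
        for arr in (self.alpha, self.beta, self.tau, self.eps):
            if arr.shape != self.alpha.shape:
                raise ValueError("draw arrays must share one (chains, draws) shape")
        if np.any(self.tau <= 0):
            raise ValueError("all noise-precision draws must be positive")

    @property
    def n_draws(self) -> int:
        return self.alpha.size

    @property
    def alpha_flat(self) -> np.ndarray:
        return self.alpha.reshape(-1)

    @property
    def beta_flat(self) -> np.ndarray:
        return self.beta.reshape(-1)

    @property
    def tau_flat(self) -> np.ndarray:
        return self.tau.reshape(-1)

    @property
    def eps_flat(self) -> np.ndarray:
        return self.eps.reshape(-1)

    @property
    def sigma_flat(self) -> np.ndarray:
        """Residual standard deviation draws, sigma = tau ** -0.5 (years)."""
        return self.tau_flat ** -0.5

    def summary(self) -> dict:
        """Posterior means and SDs of the three parameters."""
        out = {}
        for name, arr in (("alpha", self.alpha_flat), ("beta", self.beta_flat),
                          ("sigma", self.sigma_flat)):
            out[name] = {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1))}
        return out

    def draws_frame(self):
        """Draws as a tidy DataFrame (chain, draw, alpha, beta, tau) for audit export."""
        import pandas as pd

        chains, draws = self.alpha.shape
        idx = np.indices((chains, draws))
        return pd.DataFrame(
            {
                "chain": idx[0].reshape(-1),
                "draw": idx[1].reshape(-1),
                "alpha": self.alpha_flat,
                "beta": self.beta_flat,
                "tau": self.tau_flat,
            }
        )


@dataclass(frozen=True)
class PredictiveBand:
    """Equal-tailed posterior predictive bounds on a grid of population medians."""

    x_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95

    def __post_init__(self) -> None:
        if not np.all(self.lower < self.upper):
            raise ValueError("lower bound must lie below upper bound everywhere")

    def contains(self, x, y) -> np.ndarray:
        """Membership of points in the band, interpolating bounds along x."""
        lo = np.interp(x, self.x_grid, self.lower)
        hi = np.interp(x, self.x_grid, self.upper)
        return (np.asarray(y) >= lo) & (np.asarray(y) <= hi)


def _usable_xy(pairs: Sequence[MedianPair]) -> tuple[np.ndarray, np.ndarray, list[str], str]:
    usable = [p for p in pairs if p.y is not None]
    if len(usable) < 3:
        raise ValueError(
            f"need at least 3 pairs with a defined onset median, got {len(usable)}"
        )
    sexes = {p.sex for p in usable}
    if len(sexes) != 1:
        raise ValueError(f"reference pairs must be single-sex, got {sorted(sexes)}")
    x = np.array([p.x for p in usable], dtype=float)
    y = np.array([p.y for p in usable], dtype=float)
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("non-finite medians in reference pairs")
    return x, y, [p.unit_id for p in usable], sexes.pop()


def fit_standard_curve(
    pairs: Sequence[MedianPair],
    priors: PriorSpec | None = None,
    settings: McmcSettings | None = None,
    center: bool = False,
) -> StandardCurve:
    """Gibbs-sample the posterior of (alpha, beta, tau) on reference pairs.

    ``center`` fits on mean-centred x for better mixing and maps the
    intercept back to the raw scale afterwards; off by default so the
    intercept matches the raw-scale regression equations the method reports.
    Deterministic given ``settings.seed``.
    """
    priors = priors or PriorSpec()
    settings = settings or McmcSettings()
    x, y, ids, sex = _usable_xy(pairs)

    x_shift = x.mean() if center else 0.0
    xc = x - x_shift
    n = len(xc)
    X = np.column_stack([np.ones(n), xc])
    XtX = X.T @ X
    Xty = X.T @ y

    prior_prec = np.array([priors.intercept_precision, priors.slope_precision])
    prior_mean = np.array([priors.intercept_mean, priors.slope_mean])
    prec_mean = prior_prec * prior_mean
    a_post = priors.noise_precision_shape + n / 2.0

    rng = np.random.default_rng(settings.seed)
    C = settings.chains

    # overdispersed initialisation around the least-squares solution
    coef_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_var = max(float(np.mean((y - X @ coef_hat) ** 2)), 1e-8)
    coef = coef_hat[None, :] + rng.normal(0.0, 1.0, size=(C, 2)) * np.array(
        [max(abs(coef_hat[0]), 1.0) * 0.1, max(abs(coef_hat[1]), 0.1) * 0.5]
    )
    tau = 1.0 / (resid_var * np.exp(rng.normal(0.0, 0.5, size=C)))

    keep = settings.samples
    total = settings.burn_in + keep * settings.thin
    alpha_out = np.empty((C, keep))
    beta_out = np.empty((C, keep))
    tau_out = np.empty((C, keep))

    xx00, xx01, xx11 = XtX[0, 0], XtX[0, 1], XtX[1, 1]
    k = 0
    for it in range(total):
        # (alpha, beta) | tau : bivariate normal, explicit 2x2 algebra per chain
        a11 = prior_prec[0] + tau * xx00
        a12 = tau * xx01
        a22 = prior_prec[1] + tau * xx11
        det = a11 * a22 - a12 * a12
        b1 = prec_mean[0] + tau * Xty[0]
        b2 = prec_mean[1] + tau * Xty[1]
        m1 = (a22 * b1 - a12 * b2) / det
        m2 = (a11 * b2 - a12 * b1) / det
        # Cholesky of the covariance A^{-1}
        c11 = a22 / det
        c12 = -a12 / det
        c22 = a11 / det
        l11 = np.sqrt(c11)
        l21 = c12 / l11
        l22 = np.sqrt(c22 - l21 * l21)
        z = rng.standard_normal((2, C))
        coef[:, 0] = m1 + l11 * z[0]
        coef[:, 1] = m2 + l21 * z[0] + l22 * z[1]

        # tau | (alpha, beta) : gamma on the residual sum of squares
        resid = y[None, :] - coef[:, 0, None] - coef[:, 1, None] * xc[None, :]
        ssr = np.einsum("ij,ij->i", resid, resid)
        tau = rng.gamma(a_post, 1.0 / (priors.noise_precision_rate + 0.5 * ssr))

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            alpha_out[:, k] = coef[:, 0]
            beta_out[:, k] = coef[:, 1]
            tau_out[:, k] = tau
            k += 1

    eps = rng.standard_normal((C, keep)) / np.sqrt(tau_out)
    if center:
        alpha_out = alpha_out - beta_out * x_shift

    return StandardCurve(
        alpha=alpha_out,
        beta=beta_out,
        tau=tau_out,
        eps=eps,
        reference_ids=tuple(ids),
        sex=sex,
        x_ref=x,
        y_ref=y,
        priors=priors,
        settings=settings,
    )


def expected_onset(curve: StandardCurve, x) -> float | np.ndarray:
    """Posterior mean of alpha + beta*x: the expected onset median at x (years)."""
    a = float(curve.alpha_flat.mean())
    b = float(curve.beta_flat.mean())
    out = a + b * np.asarray(x, dtype=float)
    return float(out) if out.ndim == 0 else out


def predictive_interval(curve: StandardCurve, x_grid, level: float = 0.95) -> PredictiveBand:
    """Equal-tailed posterior predictive interval of a new onset median.

    Uses one predictive noise draw per retained posterior draw
    (y_rep = alpha_d + beta_d * x + eps_d), so the band is a deterministic
    function of the fitted curve.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    xg = np.atleast_1d(np.asarray(x_grid, dtype=float))
    y_rep = (
        curve.alpha_flat[None, :]
        + curve.beta_flat[None, :] * xg[:, None]
        + curve.eps_flat[None, :]
    )
    tail = (1.0 - level) / 2.0
    lower, upper = np.quantile(y_rep, [tail, 1.0 - tail], axis=1)
    return PredictiveBand(x_grid=xg, lower=lower, upper=upper, level=level)


def fit_r_squared(curve: StandardCurve, pairs: Sequence[MedianPair] | None = None) -> float | None:
    """Squared Pearson correlation between observed y and posterior-mean fit.

    Returns None (undefined) when the observed onset medians are constant.
    """
    if pairs is None:
        x, y = curve.x_ref, curve.y_ref
    else:
        x, y, _, _ = _usable_xy(pairs)
    fitted = expected_onset(curve, x)
    if np.std(y) == 0 or np.std(fitted) == 0:
        return None
    r = float(np.corrcoef(y, fitted)[0, 1])
    return r * r


def convergence_diagnostics(curve: StandardCurve) -> dict:
    """Split-R-hat and bulk effective sample size per parameter (via ArviZ).

    With a single chain R-hat is unavailable and only ESS is reported.
    Chains that are bit-identical to one another are flagged degenerate.
    """
    import arviz as az

    chains = curve.alpha.shape[0]
    degenerate = chains > 1 and (
        np.array_equal(curve.alpha[0], curve.alpha[1])
        and np.array_equal(curve.tau[0], curve.tau[1])
    )
    if degenerate:
        logger.warning("chains are identical: diagnostics are degenerate")

    out: dict = {"degenerate": bool(degenerate)}
    for name, arr in (("alpha", curve.alpha), ("beta", curve.beta), ("tau", curve.tau)):
        ess = float(az.ess(np.asarray(arr)))
        rhat = float(az.rhat(np.asarray(arr))) if chains >= 2 else None
        if rhat is not None and rhat > 1.01:
            logger.warning("R-hat for %s is %.4f (> 1.01)", name, rhat)
        out[name] = {"rhat": rhat, "ess": ess}
    return out
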