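"""RMA-style background correction for linear-scale intensities.

The observed signal on one array is modelled as S = X + Y with a true
(exponentially distributed) signal X ~ Exp(alpha) and additive normal optical
background Y ~ N(mu, sigma^2), X and Y independent.  Correction replaces each
observed s by the posterior mean E[X | S = s], which is strictly positive and
strictly increasing in s — the classic normal+exponential convolution used by
RMA.

With a = s - mu - sigma^2 * alpha and b = sigma,

    E[X | S = s] = a + b * (phi(a/b) - phi((s - a)/b))
                         / (Phi(a/b) + Phi((s - a)/b) - 1)

where phi/Phi are the standard normal pdf/cdf.  Note (s - a)/b =
(mu + sigma^2 alpha)/sigma is constant in s; the second terms only matter
when the background can plausibly push S below zero.

Parameters are estimated per array (background level is an array property)
from experimental features only.  The estimator is the method of moments on
the first three central moments of S:

    E S = mu + 1/alpha,  Var S = sigma^2 + 1/alpha^2,  E(S - ES)^3 = 2/alpha^3

so alpha = (2/m3)^(1/3), mu = mean - 1/alpha, sigma^2 = var - 1/alpha^2.
This is consistent under the model and recovers mu to within a couple of
intensity units at n ~ 1e5, where the more traditional density-mode estimate
is biased upward by the mode shift of the convolution (the mode of S sits at
mu + sigma*z* with z* solving sigma*alpha*Phi(z) = phi(z), ~1.7 sigma for
typical arrays).  When the sample skewness is non-positive or the implied
sigma^2 is negative — i.e. the data look normal with no visible exponential
component — the estimator falls back to the density-mode heuristic: mu = mode
of a Silverman-bandwidth Gaussian-kernel density estimate, sigma = RMS of the
deviations below the mode, alpha = 1/mean excess above the mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfcx, log_ndtr, ndtr

from .errors import EstimationError

_FLOOR = 2.0 ** -20  # positivity guarantee for corrected values


@dataclass(frozen=True)
class BgParams:
    """Parameters of the exponential-signal + normal-noise convolution."""

    alpha: float  # rate of the exponential signal component (1/intensity)
    mu: float     # mean of the normal background (intensity units)
    sigma: float  # SD of the normal background (intensity units)

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and np.isfinite(self.alpha)):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")


def _kde_mode(x: np.ndarray, n_grid: int = 16384) -> float:
    """Mode of a Gaussian-kernel density estimate, Silverman bandwidth.

    Binned + convolution evaluation (the R ``density()`` strategy), so it is
    cheap even for 1e5 points.
    """
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34) if q75 > q25 else sd
    if spread <= 0:
        raise EstimationError("degenerate data: no spread for density estimate")
    bw = 0.9 * spread * x.size ** (-0.2)
    lo, hi = x.min() - 3 * bw, x.max() + 3 * bw
    counts, edges = np.histogram(x, bins=n_grid, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    step = centers[1] - centers[0]
    half = max(1, int(np.ceil(4 * bw / step)))
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) * step / bw) ** 2)
    dens = np.convolve(counts.astype(float), kern, mode="same")
    return float(centers[np.argmax(dens)])


def _mode_based_params(x: np.ndarray) -> BgParams:
    """Density-mode fallback: mu = KDE mode, sigma from the left flank."""
    m = _kde_mode(x)
    below = x[x < m]
    above = x[x > m]
    if below.size < 2 or above.size < 2:
        raise EstimationError(
            "fewer than 2 points on one side of the density mode"
        )
    sigma = float(np.sqrt(np.sum((below - m) ** 2) / (below.size - 1)))
    alpha = float(1.0 / np.mean(above - m))
    if sigma <= 0 or not np.isfinite(alpha) or alpha <= 0:
        raise EstimationError("mode-based estimation produced invalid parameters")
    return BgParams(alpha=alpha, mu=m, sigma=sigma)


def estimate_bg_params(x) -> BgParams:
    """Estimate (alpha, mu, sigma) of the convolution model from intensities.

    Method of moments on mean/variance/skewness, with the density-mode
    heuristic as fallback for effectively unskewed data.  Raises
    :class:`EstimationError` for degenerate inputs (constant vectors, too few
    points).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 4:
        raise EstimationError(f"need at least 4 intensities, got {x.size}")
    if not np.isfinite(x).all():
        raise EstimationError("non-finite intensities")
    if np.ptp(x) == 0:
        raise EstimationError("constant intensity vector")
    mean = float(x.mean())
    c = x - mean
    m2 = float(np.mean(c ** 2))
    m3 = float(np.mean(c ** 3))
    if m3 > 0:
        alpha = (2.0 / m3) ** (1.0 / 3.0)
        s2 = m2 - 1.0 / alpha ** 2
        if s2 > 0:
            return BgParams(alpha=float(alpha), mu=mean - 1.0 / alpha,
                            sigma=float(np.sqrt(s2)))
    return _mode_based_params(x)


def _phi(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * z ** 2) / np.sqrt(2.0 * np.pi)


def _mills_inverse(z: np.ndarray) -> np.ndarray:
    """phi(z)/Phi(z), evaluated stably for arbitrarily negative z."""
    return np.sqrt(2.0 / np.pi) / erfcx(-z / np.sqrt(2.0))


def correct_background(x, p: BgParams) -> np.ndarray:
    """Posterior-mean background correction E[X | S = s] for each s in x.

    The posterior of X given S = s is N(a, sigma^2) truncated to [0, s], so
    the correction is the truncated-normal mean

        a + b * (phi(u) - phi(v)) / (Phi(u) - Phi(-v)),
        u = a/b,  v = (s - a)/b,  u + v = s/b.

    Evaluation is split by regime to stay accurate everywhere on the
    positive axis: for dim features (u <= 0, both Phi terms in the far left
    tail) the ratio is computed in log space with expm1 so the near-equal
    tails cancel analytically rather than in floating point; for bright
    features the direct form is benign.  Non-positive s lies outside the
    truncation interval; there the untruncated asymptote
    a + b*phi(u)/Phi(u) is used.  All outputs are floored at 2^-20, so the
    result is strictly positive and increasing over positive intensities.
    """
    s = np.asarray(x, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("non-finite intensities passed to correct_background")
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    a = s - p.mu - p.sigma ** 2 * p.alpha
    b = p.sigma
    u = a / b
    v = (s - a) / b  # == (mu + sigma^2 alpha)/sigma, constant in s
    out = np.empty_like(s)

    dim = (s > 0) & (u <= 0)
    if np.any(dim):
        ud = u[dim]
        # log phi(v) - log phi(u) = (u^2 - v^2)/2, written to avoid
        # cancellation for s near 0 where u ~ -v
        dphi = -(v[dim] - ud) * (s[dim] / b) / 2.0
        dPhi = log_ndtr(-v[dim]) - log_ndtr(ud)
        mills = np.exp(-0.5 * ud ** 2 - 0.5 * np.log(2 * np.pi)
                       - log_ndtr(ud))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = mills * np.expm1(dphi) / np.expm1(dPhi)
        out[dim] = a[dim] + b * ratio

    bright = (s > 0) & (u > 0)
    if np.any(bright):
        num = _phi(u[bright]) - _phi(v[bright])
        den = ndtr(u[bright]) - ndtr(-v[bright])
        out[bright] = a[bright] + b * num / den

    rest = s <= 0
    if np.any(rest):
        out[rest] = a[rest] + b * _mills_inverse(u[rest])

    bad = ~np.isfinite(out) | (out <= 0)
    if np.any(bad):
        out = np.where(bad, a + b * _mills_inverse(u), out)
    out = np.maximum(out, _FLOOR)
    return out[0] if scalar else out
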