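"""Cell-cycle phase fractions from DNA-content event lists.

DNA-content histograms (e.g. propidium-iodide flow cytometry exports) are
modelled as a three-component mixture: a Gaussian G0/G1 peak at mean mu, a
Gaussian G2/M peak constrained near 2*mu, and a Dean-Jett-Fox-style S-phase
component — narrow Gaussians whose means are spread uniformly between the two
peaks, which integrates to the closed form

    S(x) = [Phi((x - mu)/s) - Phi((x - r*mu)/s)] / (mu*(r - 1))

with shared coefficient of variation cv (s = cv*mu) and peak ratio r in
[1.8, 2.2].  Fractions are the maximum-likelihood mixture weights after
sub-G1 debris exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats
from sklearn.base import BaseEstimator

from .exceptions import FitConvergenceError, InsufficientDataError

logger = logging.getLogger(__name__)


def _softmax(logits):
    z = np.exp(logits - np.max(logits))
    return z / z.sum()


def _mixture_logpdf(x, mu, cv, r, weights):
    """Log-density of the G1 + S + G2/M mixture at events x."""
    sd1 = max(cv * mu, 1e-12)
    sd2 = max(cv * r * mu, 1e-12)
    w_g1, w_s, w_g2 = weights
    p_g1 = stats.norm.pdf(x, mu, sd1)
    p_g2 = stats.norm.pdf(x, r * mu, sd2)
    span = mu * (r - 1.0)
    p_s = (stats.norm.cdf((x - mu) / sd1) - stats.norm.cdf((x - r * mu) / sd1)) / span
    dens = w_g1 * p_g1 + w_s * p_s + w_g2 * p_g2
    return np.log(np.maximum(dens, 1e-300))


def _g1_peak_guess(x):
    """First prominent mode of the event histogram (the G1 peak)."""
    hist, edges = np.histogram(x, bins=128)
    smooth = np.convolve(hist, np.ones(5) / 5.0, mode="same")
    peaks, props = signal.find_peaks(smooth, height=0.25 * smooth.max())
    centers = (edges[:-1] + edges[1:]) / 2.0
    if len(peaks) == 0:
        return centers[np.argmax(smooth)]
    return centers[peaks[0]]


@dataclass(frozen=True)
class CellCycleFractions:
    """Phase percentages (sum to 100) with fit diagnostics."""

    pct_g1: float
    pct_s: float
    pct_g2m: float
    diagnostics: dict = field(default_factory=dict, compare=False)

    def as_array(self) -> np.ndarray:
        return np.array([self.pct_g1, self.pct_s, self.pct_g2m])


class CellCycleMixture(BaseEstimator):
    """Maximum-likelihood G1/S/G2M mixture fit to DNA-content events.

    Parameters
    ----------
    debris_cut : float
        Events below ``debris_cut`` times the G1 peak estimate are excluded
        as sub-G1 debris (default 0.5).
    upper_cut : float
        Events above ``upper_cut`` times the G1 peak estimate are excluded
        as aggregates (default 3.0).
    g2_ratio_bounds : (float, float)
        Allowed G2M/G1 mean ratio (default (1.8, 2.2)).
    cv_bounds : (float, float)
        Allowed coefficient of variation of the G1 peak.
    min_events : int
        Minimum events after gating (default 200).
    n_restarts : int
        Jittered re-initialisations tried on non-convergence.
    random_state : int
        Seed for restart jitter.

    Attributes
    ----------
    pct_g1_, pct_s_, pct_g2m_ : float
        Phase percentages (sum to 100).
    g1_mean_, g2_mean_, cv_ : float
        Fitted peak locations and CV.
    loglik_ : float
        Maximised log-likelihood.
    n_gated_ : int
        Events used after the debris/aggregate gates.
    """

    def __init__(self, debris_cut: float = 0.5, upper_cut: float = 3.0,
                 g2_ratio_bounds: tuple[float, float] = (1.8, 2.2),
                 cv_bounds: tuple[float, float] = (1e-4, 0.5),
                 min_events: int = 200, n_restarts: int = 4,
                 random_state: int = 0):
        self.debris_cut = debris_cut
        self.upper_cut = upper_cut
        self.g2_ratio_bounds = g2_ratio_bounds
        self.cv_bounds = cv_bounds
        self.min_events = min_events
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, events, y=None):
        x = np.asarray(events, dtype=float).ravel()
        x = x[np.isfinite(x) & (x > 0)]
        if x.size < self.min_events:
            raise InsufficientDataError(
                f"{x.size} positive events; need >= {self.min_events}")
        mu0 = _g1_peak_guess(x)
        gated = x[(x >= self.debris_cut * mu0) & (x <= self.upper_cut * mu0)]
        if gated.size < self.min_events:
            raise InsufficientDataError(
                f"{gated.size} events after debris gate; need >= {self.min_events}")
        self.n_gated_ = int(gated.size)
        self.n_debris_ = int(x.size - gated.size)

        # initial weights from coarse windows around mu0, 2*mu0 and in between
        w0 = np.array([
            np.mean(np.abs(gated - mu0) < 0.25 * mu0),
            np.mean((gated >= 1.25 * mu0) & (gated < 1.75 * mu0)),
            np.mean(np.abs(gated - 2 * mu0) < 0.25 * mu0),
        ])
        w0 = np.maximum(w0, 1e-3)
        w0 /= w0.sum()

        lo_cv, hi_cv = self.cv_bounds
        bounds = [
            (np.log(0.5 * mu0), np.log(1.5 * mu0)),   # log mu
            (np.log(lo_cv), np.log(hi_cv)),           # log cv
            self.g2_ratio_bounds,                     # r
            (-20.0, 20.0), (-20.0, 20.0),             # weight logits (g1, s)
        ]

        def nll(theta):
            mu, cv, r = np.exp(theta[0]), np.exp(theta[1]), theta[2]
            w = _softmax(np.array([theta[3], theta[4], 0.0]))
            return -np.sum(_mixture_logpdf(gated, mu, cv, r, w))

        sd0 = np.std(gated[np.abs(gated - mu0) < 0.25 * mu0])
        cv0 = np.clip(sd0 / mu0 if sd0 > 0 else 0.05, lo_cv * 2, hi_cv / 2)
        logits0 = np.log(np.maximum(w0 / w0[2], 1e-8))
        theta0 = np.array([np.log(mu0), np.log(cv0), 2.0,
                           logits0[0], logits0[1]])

        rng = np.random.default_rng(self.random_state)
        best, best_nll = None, np.inf
        last_message = ""
        for attempt in range(self.n_restarts + 1):
            start = theta0 if attempt == 0 else theta0 + rng.normal(
                0, [0.05, 0.3, 0.05, 1.0, 1.0])
            start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
            res = optimize.minimize(nll, start, method="L-BFGS-B", bounds=bounds)
            last_message = str(res.message)
            if res.fun < best_nll and np.isfinite(res.fun):
                best, best_nll = res, res.fun
        if best is None:
            raise FitConvergenceError(
                "cell-cycle mixture fit failed to converge",
                diagnostics={"message": last_message, "n_events": self.n_gated_})

        mu, cv, r = np.exp(best.x[0]), np.exp(best.x[1]), best.x[2]
        w = _softmax(np.array([best.x[3], best.x[4], 0.0]))
        self.g1_mean_ = float(mu)
        self.g2_mean_ = float(r * mu)
        self.cv_ = float(cv)
        self.pct_g1_, self.pct_s_, self.pct_g2m_ = (100.0 * w).tolist()
        self.loglik_ = float(-best_nll)
        self.converged_ = bool(best.success)
        return self

    def result_(self) -> CellCycleFractions:
        return CellCycleFractions(
            self.pct_g1_, self.pct_s_, self.pct_g2m_,
            diagnostics={
                "g1_mean": self.g1_mean_, "g2_mean": self.g2_mean_,
                "cv": self.cv_, "loglik": self.loglik_,
                "n_events": self.n_gated_, "n_debris": self.n_debris_,
                "converged": self.converged_,
            })


def estimate_fractions(events, **kwargs) -> CellCycleFractions:
    """Fit the phase mixture to an event list; see :class:`CellCycleMixture`."""
    return CellCycleMixture(**kwargs).fit(events).result_()


@dataclass(frozen=True)
class FractionShift:
    """Per-phase difference (b - a) in percentage points across replicates."""

    phase: str
    shift: float
    sd: float
    p_value: float | None
    significant: bool | None


def compare_fractions(a: list[CellCycleFractions], b: list[CellCycleFractions],
                      alpha: float = 0.05) -> list[FractionShift]:
    """Phase-fraction shifts between two replicate groups with t-tests.

    Reports mean(b) - mean(a) per phase in percentage points with the SD of
    the difference; with >= 2 replicates per arm a two-sample t-test is run
    and significance called at ``alpha``, otherwise significance is marked
    unavailable (None).
    """
    arr_a = np.array([f.as_array() for f in a])
    arr_b = np.array([f.as_array() for f in b])
    out = []
    for i, phase in enumerate(("g1", "s", "g2m")):
        xa, xb = arr_a[:, i], arr_b[:, i]
        shift = float(xb.mean() - xa.mean())
        sd = float(np.sqrt((xa.std(ddof=1) ** 2 if len(xa) > 1 else 0.0)
                           + (xb.std(ddof=1) ** 2 if len(xb) > 1 else 0.0)))
        if len(xa) >= 2 and len(xb) >= 2:
            if np.allclose(xa, xa[0]) and np.allclose(xb, xb[0]) and np.isclose(
                    xa[0], xb[0]):
                p = 1.0
            else:
                p = float(stats.ttest_ind(xb, xa).pvalue)
                if not np.isfinite(p):
                    p = 1.0
            out.append(FractionShift(phase, shift, sd, p, p < alpha))
        else:
            out.append(FractionShift(phase, shift, sd, None, None))
    return out
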