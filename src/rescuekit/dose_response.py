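"""Median-effect dose-response analysis and combination-index scoring.

Growth assays are normalised to percent-of-control, fitted with the
median-effect law

    fa / fu = (D / Dm)^m

where ``fa`` is the fraction of growth inhibited at dose ``D``, ``fu = 1 - fa``,
``Dm`` is the median-effect dose (the IC50 of the fit) and ``m`` is the shape
coefficient.  Antagonism between a drug and a rescuing modulator is scored with
the Loewe-additivity combination index

    CI = d1 / Dx1 + d2 / Dx2

evaluated at a chosen effect level, where ``Dxi`` is the single-agent dose of
agent *i* producing that effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateControlError,
    InsufficientDataError,
    ParameterError,
    UnfittableError,
)

logger = logging.getLogger(__name__)

#: Conventional Chou-scale classification bands: upper CI bound -> label.
#: CI below the first bound is synergy, above the last is strong antagonism.
DEFAULT_CI_BANDS: tuple[tuple[float, str], ...] = (
    (0.9, "synergy"),
    (1.1, "additive"),
    (3.3, "moderate antagonism"),
    (float("inf"), "strong antagonism"),
)


def normalize_growth(n_treated: float, n_control: float, n_background: float) -> float:
    """Percent cell growth relative to an untreated control.

    ``n_background`` is the cell count at the moment of drug addition; growth
    is the net increase of the treated wells over the net increase of the
    control wells, times 100.  May be negative (net cell loss) or exceed 100.
    """
    if n_control <= n_background:
        raise DegenerateControlError(
            f"control count {n_control} did not exceed background {n_background}"
        )
    return 100.0 * (n_treated - n_background) / (n_control - n_background)


def fraction_affected(dose, m: float, dm: float):
    """Fraction of the system inhibited at `dose` under the median-effect law."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        fa = 1.0 / (1.0 + (dm / dose) ** m)
    return np.where(dose == 0, 0.0, fa)


def ic50(dose: float, growth_pct: float, m: float) -> float:
    """Median-effect dose from one (dose, viability%) observation.

    Implements ``IC50 = D / (100/y - 1)^(1/m)``; ``y`` must lie strictly in
    (0, 100) and both ``D`` and ``m`` must be positive.
    """
    if not 0.0 < growth_pct < 100.0:
        raise ParameterError(f"growth_pct must be in (0, 100), got {growth_pct}")
    if dose <= 0 or m <= 0:
        raise ParameterError("dose and m must be positive")
    return dose / (100.0 / growth_pct - 1.0) ** (1.0 / m)


@dataclass(frozen=True)
class MedianEffectFit:
    """Result of a linearised median-effect fit."""

    m: float
    dm: float
    r: float
    n_points: int
    n_excluded: int = 0

    def dose_for_effect(self, effect_level: float) -> float:
        """Single-agent dose Dx producing `effect_level` percent inhibition."""
        if not 0.0 < effect_level < 100.0:
            raise ParameterError("effect_level must be in (0, 100)")
        fa = effect_level / 100.0
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)

    def growth_at(self, dose) -> np.ndarray:
        """Predicted growth percent at `dose`."""
        return 100.0 * (1.0 - fraction_affected(dose, self.m, self.dm))


class MedianEffectModel(BaseEstimator):
    """Least-squares median-effect model on the linearised (log-log) scale.

    Fits a straight line to log10(fa/fu) against log10(D); the slope is the
    shape coefficient ``m`` and the intercept yields the median-effect dose
    ``Dm = 10^(-intercept/m)``.

    Parameters
    ----------
    min_points : int
        Minimum number of distinct usable positive doses (default 3).
    average_replicates : bool
        Average growth over duplicate doses before fitting (default True).

    Attributes
    ----------
    m_ : float
        Fitted shape coefficient.
    dm_ : float
        Fitted median-effect dose, in the input dose units.
    r_ : float
        Pearson correlation of the linearised fit.
    n_points_ : int
        Distinct doses used.
    n_excluded_ : int
        Points dropped because growth fell outside (0, 100) or dose was 0.
    """

    def __init__(self, min_points: int = 3, average_replicates: bool = True):
        self.min_points = min_points
        self.average_replicates = average_replicates

    def fit(self, dose, growth_pct=None):
        """Fit from dose and growth-percent arrays (or a two-column frame)."""
        if growth_pct is None:
            frame = pd.DataFrame(dose)
            dose = frame["dose"].to_numpy(float)
            growth_pct = frame["growth_pct"].to_numpy(float)
        dose = np.asarray(dose, dtype=float)
        growth = np.asarray(growth_pct, dtype=float)
        if dose.shape != growth.shape:
            raise ParameterError("dose and growth arrays must align")
        if np.any(dose < 0) or not np.all(np.isfinite(growth)):
            raise ParameterError("doses must be >= 0 and growth values finite")

        if self.average_replicates:
            agg = pd.Series(growth).groupby(pd.Series(dose)).mean()
            dose, growth = agg.index.to_numpy(float), agg.to_numpy(float)

        usable = (dose > 0) & (growth > 0.0) & (growth < 100.0)
        n_excluded = int((~usable).sum())
        if n_excluded:
            logger.info("median-effect fit: excluded %d point(s) outside (0, 100)%% "
                        "growth or at zero dose", n_excluded)
        dose, growth = dose[usable], growth[usable]
        if len(np.unique(dose)) < self.min_points:
            raise InsufficientDataError(
                f"need >= {self.min_points} distinct positive doses with growth in "
                f"(0, 100), got {len(np.unique(dose))}"
            )

        fu = growth / 100.0
        x = np.log10(dose)
        y = np.log10((1.0 - fu) / fu)
        slope, intercept = np.polyfit(x, y, 1)
        if slope <= 0 or not np.isfinite(slope):
            raise UnfittableError(
                f"dose-effect slope {slope:.3g} is not positive; Dm undefined"
            )
        r = float(np.corrcoef(x, y)[0, 1]) if len(x) > 2 else 1.0
        self.m_ = float(slope)
        self.dm_ = float(10.0 ** (-intercept / slope))
        self.r_ = r
        self.n_points_ = int(len(x))
        self.n_excluded_ = n_excluded
        return self

    def result_(self) -> MedianEffectFit:
        return MedianEffectFit(self.m_, self.dm_, self.r_, self.n_points_,
                               self.n_excluded_)


def fit_median_effect(table, dose_col: str = "dose",
                      growth_col: str = "growth_pct") -> MedianEffectFit:
    """Fit the median-effect model to a dose-response table.

    `table` is a DataFrame with dose and growth-percent columns (replicates at
    the same dose are averaged), or a pair of array-likes.
    """
    if isinstance(table, pd.DataFrame):
        model = MedianEffectModel().fit(table[dose_col], table[growth_col])
    else:
        dose, growth = table
        model = MedianEffectModel().fit(dose, growth)
    return model.result_()


@dataclass(frozen=True)
class CombinationIndexResult:
    ci: float
    effect_level: float
    d1: float
    d2: float
    dx1: float
    dx2: float
    classification: str
    extrapolated: bool = False
    bands: tuple = field(default=DEFAULT_CI_BANDS, repr=False)


def classify_ci(ci: float, bands=DEFAULT_CI_BANDS) -> str:
    """Map a combination-index value onto its qualitative band."""
    if ci <= 0 or not np.isfinite(ci):
        raise ParameterError(f"CI must be positive and finite, got {ci}")
    for upper, label in bands:
        if ci < upper:
            return label
    return bands[-1][1]


def combination_index(fit1: MedianEffectFit, fit2: MedianEffectFit,
                      d1: float, d2: float, effect_level: float,
                      bands=DEFAULT_CI_BANDS,
                      fitted_effect_ranges=None) -> CombinationIndexResult:
    """Loewe combination index of two agents at a given percent inhibition.

    ``Dxi`` is each agent's single-agent dose for the effect level, obtained
    from its median-effect fit; CI = d1/Dx1 + d2/Dx2.  If
    `fitted_effect_ranges` (two (lo, hi) percent-inhibition tuples) is given
    and the effect level lies outside both, an extrapolation warning is logged
    and flagged on the result rather than raised.
    """
    dx1 = fit1.dose_for_effect(effect_level)
    dx2 = fit2.dose_for_effect(effect_level)
    ci = d1 / dx1 + d2 / dx2
    extrapolated = False
    if fitted_effect_ranges is not None:
        (lo1, hi1), (lo2, hi2) = fitted_effect_ranges
        if not (lo1 <= effect_level <= hi1) and not (lo2 <= effect_level <= hi2):
            extrapolated = True
            logger.warning("effect level %.1f%% lies outside both single-agent "
                           "fit ranges; CI is an extrapolation", effect_level)
    return CombinationIndexResult(
        ci=float(ci), effect_level=float(effect_level), d1=float(d1),
        d2=float(d2), dx1=float(dx1), dx2=float(dx2),
        classification=classify_ci(ci, bands), extrapolated=extrapolated,
        bands=tuple(bands),
    )
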