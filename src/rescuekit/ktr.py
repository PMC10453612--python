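"""Single-cell kinase-translocation-reporter (KTR) quantification.

A KTR shuttles from the nucleus to the cytoplasm when phosphorylated by its
kinase, so per-cell kinase activity is read out as the ratio of median
reporter fluorescence in a cytoplasmic ring to that in the nucleus (the C/N
ratio).  The pipeline is: illumination correction, two-class Otsu segmentation
of the nuclear stain, a fixed-width cytoplasm ring extended from each nucleus
(contested pixels go to the nearest nucleus), per-cell median intensities, and
artifact filtering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import clear_border as _clear_border

from .exceptions import ParameterError

logger = logging.getLogger(__name__)


def correct_illumination(image: np.ndarray, sigma: float | None = None) -> np.ndarray:
    """Flatten smooth illumination variation across a field.

    The illumination field is estimated by large-kernel Gaussian smoothing
    (sigma defaults to one eighth of the smaller image dimension) of the
    background only: bright sparse structures (nuclei, cells) are masked out
    with a fine-binned Otsu threshold and the smoothing is renormalised over
    the remaining pixels, so the estimate interpolates the background under
    the cells instead of bulging around them.  The image is divided by the
    estimate and rescaled so the global median is preserved.  Falls back to
    the uncorrected image with a warning if the estimate reaches zero
    anywhere.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("expected a 2-D image")
    if sigma is None:
        sigma = min(image.shape) / 8.0
    if image.min() < image.max():
        background = image <= threshold_otsu(image, nbins=4096)
    else:
        background = np.ones(image.shape, dtype=bool)
    weight = background.astype(float)
    num = gaussian(image * weight, sigma=sigma, mode="nearest",
                   preserve_range=True)
    den = gaussian(weight, sigma=sigma, mode="nearest", preserve_range=True)
    est = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-9)
    if np.any(est <= 0):
        logger.warning("illumination estimate hits zero; returning image uncorrected")
        return image.copy()
    corrected = image / est
    med = np.median(corrected)
    if med > 0:
        corrected *= np.median(image) / med
    return corrected


def segment_nuclei(nuclear_channel: np.ndarray, min_area: int = 50,
                   max_area: int = 5000, clear_border: bool = False) -> np.ndarray:
    """Label nuclei by global two-class Otsu thresholding.

    Connected components (8-connectivity) of the above-threshold foreground
    are labelled; components outside [min_area, max_area] pixels are removed
    and labels compacted.  A uniform image (Otsu undefined) yields an empty
    mask with a warning.
    """
    img = np.asarray(nuclear_channel, dtype=float)
    if img.min() == img.max():
        logger.warning("uniform nuclear channel: Otsu threshold undefined, "
                       "returning empty mask")
        return np.zeros(img.shape, dtype=np.int32)
    # fine histogram binning: with a dim background and bright sparse nuclei
    # the default 256 bins put the whole background mode in one bin and the
    # returned threshold lands inside the background noise band
    mask = img > threshold_otsu(img, nbins=4096)
    labels = cc_label(mask, connectivity=2)
    if clear_border:
        labels = _clear_border(labels)
    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < min_area) | (areas > max_area))
    labels[np.isin(labels, bad[bad > 0])] = 0
    # compact label ids to 1..n
    kept = np.unique(labels)
    remap = np.zeros(kept.max() + 1 if kept.size else 1, dtype=np.int32)
    remap[kept] = np.arange(len(kept))
    return remap[labels]


def extend_cytoplasm(nuclei: np.ndarray, width: int = 10) -> np.ndarray:
    """Cytoplasm rings: each nucleus dilated by `width` pixels, minus nuclei.

    Pixels reachable from more than one nucleus are assigned to the nearest
    one (Euclidean distance transform), so rings never overlap nuclei or each
    other.
    """
    if width <= 0:
        raise ParameterError("ring width must be positive")
    nuclei = np.asarray(nuclei)
    background = nuclei == 0
    dist, (iy, ix) = ndimage.distance_transform_edt(background, return_indices=True)
    rings = np.where(background & (dist <= width), nuclei[iy, ix], 0)
    return rings.astype(nuclei.dtype, copy=False)


def measure_ktr(nuclei: np.ndarray, rings: np.ndarray,
                reporter_channel: np.ndarray,
                saturation_level: float | None = None) -> pd.DataFrame:
    """Per-cell median nuclear/ring reporter intensities and C/N ratio.

    Returns one row per label with centroid, areas, medians, ``cn_ratio``,
    the fraction of saturated pixels over nucleus plus ring, and QC flags
    (``flag_saturated`` is informational here; thresholds are applied by
    :func:`remove_artifacts`).  Cells whose nuclear median is zero get a NaN
    ratio and ``flag_zero_nuc``.
    """
    reporter = np.asarray(reporter_channel, dtype=float)
    if saturation_level is None:
        if np.issubdtype(np.asarray(reporter_channel).dtype, np.integer):
            saturation_level = float(np.iinfo(np.asarray(reporter_channel).dtype).max)
        else:
            saturation_level = float("inf")
    ids = np.unique(nuclei)
    ids = ids[ids > 0]
    rows = []
    for k in ids:
        nuc_px = reporter[nuclei == k]
        ring_px = reporter[rings == k]
        cy, cx = ndimage.center_of_mass(nuclei == k)
        med_nuc = float(np.median(nuc_px)) if nuc_px.size else np.nan
        med_cyt = float(np.median(ring_px)) if ring_px.size else np.nan
        all_px = np.concatenate([nuc_px, ring_px]) if ring_px.size else nuc_px
        sat_frac = float(np.mean(all_px >= saturation_level)) if all_px.size else 0.0
        zero_nuc = not (med_nuc and np.isfinite(med_nuc)) or med_nuc <= 0
        rows.append({
            "cell": int(k), "y": cy, "x": cx,
            "nucleus_area": int(nuc_px.size), "ring_area": int(ring_px.size),
            "median_nuc": med_nuc, "median_cyt": med_cyt,
            "cn_ratio": np.nan if zero_nuc else med_cyt / med_nuc,
            "sat_frac": sat_frac,
            "flag_zero_nuc": bool(zero_nuc),
        })
    cols = ["cell", "y", "x", "nucleus_area", "ring_area", "median_nuc",
            "median_cyt", "cn_ratio", "sat_frac", "flag_zero_nuc"]
    return pd.DataFrame(rows, columns=cols)


def remove_artifacts(measurements: pd.DataFrame,
                     max_sat_frac: float = 0.01,
                     area_bounds: tuple[float, float] = (50, 5000),
                     ratio_bounds: tuple[float, float] = (0.05, 20.0)) -> pd.DataFrame:
    """Drop cells failing saturation, nucleus-area or C/N-ratio gates.

    Cells with a saturated-pixel fraction above ``max_sat_frac``, a nucleus
    area outside ``area_bounds``, an undefined ratio, or a ratio outside
    ``ratio_bounds`` are removed; counts are logged per gate.
    """
    m = measurements
    if m.empty:
        return m.copy()
    sat = m["sat_frac"] > max_sat_frac
    area = ~m["nucleus_area"].between(*area_bounds)
    bad_ratio = m["flag_zero_nuc"] | ~m["cn_ratio"].between(*ratio_bounds)
    drop = sat | area | bad_ratio
    logger.info("artifact removal: %d saturated, %d area-gated, %d ratio-gated "
                "of %d cells", int(sat.sum()), int(area.sum()),
                int(bad_ratio.sum()), len(m))
    kept = m.loc[~drop].copy()
    if kept.empty:
        logger.warning("all %d cells removed as artifacts", len(m))
    return kept


def quantify_field(nuclear: np.ndarray, reporter: np.ndarray,
                   ring_width: int = 10, correct: bool = True,
                   saturation_level: float | None = None,
                   min_area: int = 50, max_area: int = 5000) -> pd.DataFrame:
    """Full single-field pipeline: correct, segment, extend, measure.

    Saturation flags are computed on the raw reporter channel (illumination
    correction rescales intensities, which would hide clipped pixels).
    """
    nuc_img = correct_illumination(nuclear) if correct else np.asarray(nuclear, float)
    rep_img = correct_illumination(reporter) if correct else np.asarray(reporter, float)
    nuclei = segment_nuclei(nuc_img, min_area=min_area, max_area=max_area)
    rings = extend_cytoplasm(nuclei, width=ring_width)
    meas = measure_ktr(nuclei, rings, rep_img, saturation_level=float("inf"))
    raw = measure_ktr(nuclei, rings, reporter, saturation_level=saturation_level)
    meas["sat_frac"] = raw["sat_frac"].to_numpy()
    return meas


def summarize_condition(measurements: pd.DataFrame,
                        condition_col: str = "condition",
                        replicate_col: str = "replicate",
                        normalize_to: str | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate medians and per-condition summaries of C/N ratios.

    Returns ``(per_replicate, per_condition)``: per replicate the median and
    IQR of single-cell ratios; per condition the mean of replicate medians
    with its SD (0 for a single replicate).  With ``normalize_to`` set, adds a
    column of condition means divided by the reference condition's mean.
    """
    m = measurements.dropna(subset=["cn_ratio"])
    per_rep = (
        m.groupby([condition_col, replicate_col])["cn_ratio"]
        .agg(median="median",
             iqr=lambda s: float(np.subtract(*np.percentile(s, [75, 25]))),
             n_cells="size")
        .reset_index()
    )
    per_cond = (
        per_rep.groupby(condition_col)["median"]
        .agg(mean_of_medians="mean", sd_of_medians="std", n_replicates="size")
        .reset_index()
    )
    per_cond["sd_of_medians"] = per_cond["sd_of_medians"].fillna(0.0)
    if normalize_to is not None:
        ref = per_cond.loc[per_cond[condition_col] == normalize_to,
                           "mean_of_medians"]
        if ref.empty:
            raise ParameterError(f"reference condition {normalize_to!r} not found")
        per_cond["normalized"] = per_cond["mean_of_medians"] / float(ref.iloc[0])
    return per_rep, per_cond
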