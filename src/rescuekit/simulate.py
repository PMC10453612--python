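"""Synthetic-data generators with recorded ground truth.

Every downstream stage of the pipeline (dose-response fitting, reporter-image
quantification, DNA-content deconvolution, differential expression, pathway
scoring) can be exercised on data generated here, where the planted parameters
are known exactly.  The generators emulate the statistical structure of a
serum/ligand drug-rescue experiment on an EGFR-driven cell line:

* growth tables drawn from the median-effect law, with an optional rescuing
  modulator that attenuates the effective drug dose;
* two-channel fluorescence fields (nuclear stain + kinase translocation
  reporter) with planted per-cell cytoplasm/nucleus ratios, an optional linear
  illumination gradient, and saturated artifact blobs;
* DNA-content event lists with Gaussian G1 and G2/M peaks (G2/M at twice the
  G1 mean), a broadened S-phase plateau between them, and sub-G1 debris;
* negative-binomial count matrices over six conditions (control, serum, EGF,
  drug, drug+serum, drug+EGF) in replicate, with planted drug-responsive gene
  classes of which a designated fraction is "rescued" (returned to the control
  mean) in the combined conditions.

All randomness flows from the integer ``seed`` carried by each spec; fixing it
reproduces every artifact bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import fraction_affected
from .exceptions import GenerationError, ParameterError

CONDITIONS = ("control", "serum", "egf", "drug", "drug_serum", "drug_egf")


# ---------------------------------------------------------------------------
# dose-response tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthSimSpec:
    """Median-effect growth simulation with a dose-attenuating modulator.

    ``rescue_strength`` in [0, 1] scales how strongly a modulator level of 1
    attenuates the effective drug dose: D_eff = D * (1 - rescue_strength * L).
    ``noise_sd`` is the SD of multiplicative Gaussian noise on growth percent.
    """

    #: eight-point geometric dose ladder spanning 50-1600 around Dm = 300,
    #: covering growth from ~97% down to ~3% without the flat extremes where
    #: the linearised fit loses information
    m: float = 2.0
    dm: float = 300.0
    doses: tuple[float, ...] = (50.0, 82.0, 134.6, 220.8, 362.3, 594.4,
                                975.2, 1600.0)
    noise_sd: float = 0.02
    rescue_strength: float = 0.5
    modulator_levels: tuple[float, ...] = (0.0,)
    n_reps: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.dm <= 0:
            raise ParameterError("Dm must be positive")
        if any(d < 0 for d in self.doses):
            raise ParameterError("doses must be >= 0")
        if not 0.0 <= self.rescue_strength <= 1.0:
            raise ParameterError("rescue_strength must lie in [0, 1]")
        if self.noise_sd < 0 or self.n_reps < 1:
            raise ParameterError("noise_sd must be >= 0 and n_reps >= 1")


def gen_dose_response(spec: GrowthSimSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a growth table; returns (table, ground-truth dict).

    Growth percent is 100 * (1 - fa(D_eff)) times multiplicative noise, where
    fa is the median-effect fraction affected and D_eff the attenuated dose.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for level in spec.modulator_levels:
        atten = 1.0 - spec.rescue_strength * level
        for rep in range(spec.n_reps):
            d_eff = np.asarray(spec.doses, float) * atten
            growth = 100.0 * (1.0 - fraction_affected(d_eff, spec.m, spec.dm))
            if spec.noise_sd > 0:
                growth = growth * (1.0 + rng.normal(0.0, spec.noise_sd, growth.shape))
            for dose, y in zip(spec.doses, growth):
                rows.append((dose, level, y, rep))
    table = pd.DataFrame(rows, columns=["dose", "modulator_level",
                                        "growth_pct", "replicate"])
    truth = {"m": spec.m, "dm": spec.dm, "rescue_strength": spec.rescue_strength}
    return table, truth


# ---------------------------------------------------------------------------
# reporter-image fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSimSpec:
    """Two-channel field: nuclear disks plus a reporter with a planted
    cytoplasm/nucleus intensity ratio.

    ``illumination_gradient`` is the fractional intensity slope across the
    field width (0.3 means the multiplicative gain runs from 0.7 to 1.3).
    ``n_artifacts`` saturated blobs are each planted on top of a distinct
    cell, so the affected cells are known exactly.
    """

    field_size: tuple[int, int] = (512, 512)
    n_cells: int = 50
    nucleus_radius: int = 8
    cytoplasm_width: int = 12
    true_cn_ratio: float = 2.5
    nucleus_intensity: float = 1000.0
    background: float = 100.0
    illumination_gradient: float = 0.0
    noise_sd: float = 0.01
    n_artifacts: int = 0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0 or self.nucleus_radius <= 0 or self.cytoplasm_width <= 0:
            raise ParameterError("cell geometry parameters must be positive")
        if self.true_cn_ratio <= 0 or self.background < 0:
            raise ParameterError("intensities must be positive")
        if self.n_artifacts > self.n_cells:
            raise ParameterError("cannot plant more artifacts than cells")

    @property
    def saturation_level(self) -> int:
        return 2 ** self.bit_depth - 1


def _place_centers(rng, shape, n, min_dist, margin, max_tries=20000):
    """Rejection-sample non-overlapping disk centers."""
    h, w = shape
    if n == 0:
        return np.empty((0, 2))
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"placed only {len(centers)}/{n} cells after {max_tries} tries; "
                "reduce n_cells or the field is too small"
            )
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_dist ** 2 for cy, cx in centers):
            centers.append((y, x))
    return np.asarray(centers)


def gen_ktr_field(spec: ImageSimSpec) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate one field; returns (nuclear, reporter, truth table).

    Nuclei are uniform disks in the nuclear channel; in the reporter channel
    each nucleus has intensity ``c`` and is surrounded by a cytoplasm annulus
    of intensity ``c * true_cn_ratio``.  Cells are placed so that annuli never
    touch (margin of at least twice the cytoplasm width between nucleus
    edges).  The truth table records centers, the planted ratio, and which
    cells carry a saturated artifact blob.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size
    r_nuc, r_cyt = spec.nucleus_radius, spec.nucleus_radius + spec.cytoplasm_width
    nuclear = np.full((h, w), spec.background, float)
    reporter = np.full((h, w), spec.background, float)

    if spec.n_cells > 0:
        # annuli stay disjoint (4 px slack); nucleus-edge margin is then
        # 2*cytoplasm_width + 4, comfortably over twice the measurement ring
        centers = _place_centers(
            rng, (h, w), spec.n_cells,
            min_dist=2 * r_cyt + 4,
            margin=r_cyt + 2,
        )
    else:
        centers = np.empty((0, 2))

    yy, xx = np.mgrid[0:h, 0:w]
    c_nuc = spec.nucleus_intensity
    for cy, cx in centers:
        dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nucleus = dist2 <= r_nuc ** 2
        annulus = (dist2 <= r_cyt ** 2) & ~nucleus
        nuclear[nucleus] = 3.0 * c_nuc
        reporter[nucleus] = c_nuc
        reporter[annulus] = c_nuc * spec.true_cn_ratio

    if spec.illumination_gradient != 0.0 and w > 1:
        gain = 1.0 + spec.illumination_gradient * (2.0 * xx / (w - 1) - 1.0)
        nuclear *= gain
        reporter *= gain

    if spec.noise_sd > 0:
        nuclear *= 1.0 + rng.normal(0.0, spec.noise_sd, nuclear.shape)
        reporter *= 1.0 + rng.normal(0.0, spec.noise_sd, reporter.shape)

    artifact_cells = np.zeros(len(centers), dtype=bool)
    if spec.n_artifacts > 0:
        hit = rng.choice(len(centers), size=spec.n_artifacts, replace=False)
        artifact_cells[hit] = True
        for idx in hit:
            cy, cx = centers[idx]
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= 4.0 ** 2
            reporter[blob] = spec.saturation_level

    sat = spec.saturation_level
    nuclear = np.clip(np.rint(nuclear), 0, sat).astype(np.uint16)
    reporter = np.clip(np.rint(reporter), 0, sat).astype(np.uint16)

    truth = pd.DataFrame({
        "cell": np.arange(1, len(centers) + 1),
        "y": centers[:, 0] if len(centers) else np.array([]),
        "x": centers[:, 1] if len(centers) else np.array([]),
        "true_cn_ratio": spec.true_cn_ratio,
        "artifact": artifact_cells,
    })
    return nuclear, reporter, truth


# ---------------------------------------------------------------------------
# DNA-content histograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleSimSpec:
    """DNA-content event list with planted cell-cycle phase fractions.

    G1 events are Gaussian around ``g1_mean`` with coefficient of variation
    ``cv``; G2/M events sit at exactly twice the G1 mean with the same CV;
    S-phase events are a plateau of narrow Gaussians whose means are uniform
    between the two peaks (a Dean-Jett-Fox-style broadened component).
    ``debris_frac`` of all events are sub-G1 debris, drawn below the G1 peak
    and excluded from the phase fractions.
    """

    n_events: int = 10_000
    f_g1: float = 0.6
    f_s: float = 0.25
    f_g2m: float = 0.15
    g1_mean: float = 100.0
    cv: float = 0.05
    debris_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        fracs = (self.f_g1, self.f_s, self.f_g2m)
        if any(f < 0 or f > 1 for f in fracs):
            raise ParameterError("phase fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ParameterError(f"phase fractions must sum to 1, got {sum(fracs)}")
        if not 0.0 <= self.debris_frac < 1.0:
            raise ParameterError("debris_frac must lie in [0, 1)")
        if self.g1_mean <= 0 or self.cv < 0 or self.n_events < 0:
            raise ParameterError("g1_mean > 0, cv >= 0 and n_events >= 0 required")


def gen_dna_histogram(spec: CycleSimSpec) -> tuple[np.ndarray, dict]:
    """Simulate a per-event DNA-content intensity list; returns (events, truth)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    if n == 0:
        return np.array([]), {"f_g1": spec.f_g1, "f_s": spec.f_s,
                              "f_g2m": spec.f_g2m, "g1_mean": spec.g1_mean}
    n_debris = rng.binomial(n, spec.debris_frac)
    n_phase = n - n_debris
    phase = rng.choice(3, size=n_phase, p=[spec.f_g1, spec.f_s, spec.f_g2m])
    mu1, mu2 = spec.g1_mean, 2.0 * spec.g1_mean
    sd = spec.cv * mu1
    events = np.empty(n_phase)
    g1, s, g2 = phase == 0, phase == 1, phase == 2
    events[g1] = rng.normal(mu1, sd, g1.sum())
    events[g2] = rng.normal(mu2, 2.0 * sd, g2.sum())
    # S phase: narrow Gaussians with means spread uniformly between the peaks
    events[s] = rng.uniform(mu1, mu2, s.sum()) + rng.normal(0.0, sd, s.sum())
    debris = rng.uniform(0.05 * mu1, 0.45 * mu1, n_debris)
    events = np.concatenate([events, debris])
    rng.shuffle(events)
    events = np.clip(events, 0.0, None)
    truth = {"f_g1": spec.f_g1, "f_s": spec.f_s, "f_g2m": spec.f_g2m,
             "g1_mean": spec.g1_mean, "cv": spec.cv,
             "debris_frac": spec.debris_frac}
    return events, truth


# ---------------------------------------------------------------------------
# RNA-seq count matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountsSimSpec:
    """Negative-binomial count matrix over the six-condition rescue design.

    Baseline gene means are log-uniform over ``mean_range``.  ``n_drug_down``
    and ``n_drug_up`` genes are shifted by -/+ ``effect_log2fc`` in the drug
    condition; in each combined condition the designated ``rescued_fraction``
    of those genes returns to the control mean, the rest keep the drug shift.
    Dispersion is a single global constant by default; pass an array of length
    ``n_genes`` for per-gene dispersions.
    """

    n_genes: int = 2000
    conditions: tuple[str, ...] = CONDITIONS
    n_reps: int = 3
    mean_range: tuple[float, float] = (20.0, 2000.0)
    dispersion: float | np.ndarray = 0.05
    n_drug_down: int = 100
    n_drug_up: int = 100
    effect_log2fc: float = 2.0
    rescued_fraction_serum: float = 0.75
    rescued_fraction_egf: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 2:
            raise ParameterError("n_reps must be >= 2")
        if self.n_drug_down + self.n_drug_up > self.n_genes:
            raise ParameterError("planted gene classes exceed n_genes")
        if self.effect_log2fc <= 1.0 and (self.n_drug_down or self.n_drug_up):
            raise ParameterError("planted |log2FC| must exceed the calling "
                                 "threshold of 1")
        for f in (self.rescued_fraction_serum, self.rescued_fraction_egf):
            if not 0.0 <= f <= 1.0:
                raise ParameterError("rescued fractions must lie in [0, 1]")


def _nb_draw(rng, mean, dispersion):
    """NB(mean, dispersion) with var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, float)
    disp = np.broadcast_to(np.asarray(dispersion, float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = disp < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        size = 1.0 / disp[~tiny]
        p = size / (size + mean[~tiny])
        out[~tiny] = rng.negative_binomial(size, p)
    return out


def gen_counts(spec: CountsSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate counts; returns (counts genes x samples, design, gene truth).

    The truth table carries each gene's class (``null`` / ``drug_down`` /
    ``drug_up``) and, for planted genes, whether it is rescued under each
    combined condition.
    """
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"gene{i:05d}" for i in range(spec.n_genes)])
    base = np.exp(rng.uniform(np.log(spec.mean_range[0]),
                              np.log(spec.mean_range[1]), spec.n_genes))

    planted = rng.choice(spec.n_genes, spec.n_drug_down + spec.n_drug_up,
                         replace=False)
    down, up = planted[:spec.n_drug_down], planted[spec.n_drug_down:]
    gene_class = np.full(spec.n_genes, "null", dtype=object)
    gene_class[down] = "drug_down"
    gene_class[up] = "drug_up"

    shift = np.ones(spec.n_genes)
    shift[down] = 2.0 ** -spec.effect_log2fc
    shift[up] = 2.0 ** spec.effect_log2fc

    def rescued_mask(fraction):
        mask = np.zeros(spec.n_genes, dtype=bool)
        k = int(round(fraction * len(planted)))
        if k:
            mask[rng.choice(planted, k, replace=False)] = True
        return mask

    resc_serum = rescued_mask(spec.rescued_fraction_serum)
    resc_egf = rescued_mask(spec.rescued_fraction_egf)

    cond_means = {
        "control": base,
        "serum": base,
        "egf": base,
        "drug": base * shift,
        "drug_serum": np.where(resc_serum, base, base * shift),
        "drug_egf": np.where(resc_egf, base, base * shift),
    }

    columns, data = [], []
    for cond in spec.conditions:
        for rep in range(1, spec.n_reps + 1):
            columns.append(f"{cond}_{rep}")
            data.append(_nb_draw(rng, cond_means[cond], spec.dispersion))
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    counts.index.name = "gene"

    design = pd.DataFrame({
        "sample": columns,
        "condition": [c.rsplit("_", 1)[0] for c in columns],
        "replicate": [int(c.rsplit("_", 1)[1]) for c in columns],
    }).set_index("sample")

    truth = pd.DataFrame({
        "gene": genes,
        "class": gene_class,
        "base_mean": base,
        "rescued_serum": resc_serum & (gene_class != "null"),
        "rescued_egf": resc_egf & (gene_class != "null"),
    }).set_index("gene")
    return counts, design, truth
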