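# Methods

This note documents the models behind each rescuekit stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions taken where the underlying experimental conventions
leave the design open.

## Dose response and combination index

Growth percent is the background-subtracted treated count over the
background-subtracted control count, times 100. It may be negative (net cell
loss) or exceed 100; a control that did not grow past the background raises an
error rather than returning a sign-flipped value.

The median-effect model `fa/fu = (D/Dm)^m` is fitted by ordinary least
squares on the linearised form `log10(fa/fu) = m·log10(D) − m·log10(Dm)`,
with `fa = 1 − y/100`. Conventions:

* log base 10 throughout; replicate growth values at the same dose are
  averaged before fitting;
* points with growth ≤ 0% or ≥ 100% carry no information on the logit scale
  and are excluded (the count is logged and reported on the fit);
* at least 3 distinct positive usable doses are required; a non-positive
  slope (e.g. a flat 50% table) is unfittable and raises.

The linearisation is exact on noise-free model data, so the fit recovers
(m, Dm) to machine precision there; with multiplicative noise the extreme
ends of the curve (growth near 0 or 100) dominate the error, which is why the
synthetic generator's default ladder spans doses giving roughly 3–97% growth.

The combination index follows Loewe additivity: `CI = d1/Dx1 + d2/Dx2` with
`Dxi = Dmi · (fa/(1−fa))^(1/mi)` at the chosen effect level. A fixed-level
rescuing modulator (serum, EGF) enters as agent 2 through its own titration
fit, and the CI is evaluated at the observed combined effect level, exposed
as an explicit parameter. Classification bands follow the conventional Chou
scale — < 0.9 synergy, 0.9–1.1 additive, 1.1–3.3 moderate antagonism, > 3.3
strong antagonism — and are configurable. An effect level outside both
single-agent fit ranges flags the result as extrapolated (warning, not
error). Self-combination under Loewe partitioning is exactly 1 at every
effect level; this is asserted in the test suite.

## KTR image quantification

Per-cell kinase activity is the ratio of the median reporter intensity over a
cytoplasm ring to the median over the nucleus. Pipeline decisions:

* **Illumination correction** divides by a smooth illumination estimate and
  rescales to preserve the global median. The estimate is a Gaussian
  smoothing (sigma = min(h, w)/8) restricted to background pixels via
  normalized convolution: bright sparse structures are masked with a
  fine-binned Otsu threshold first, because smoothing them into the estimate
  biases the corrected background unevenly across the field. A flat image is
  returned unchanged; an estimate that reaches zero anywhere falls back to
  the uncorrected image with a warning.
* **Segmentation** is global two-class Otsu on the corrected nuclear channel
  with 4096 histogram bins — with a dim background and bright sparse nuclei
  the default 256 bins collapse the entire background mode into one bin and
  the threshold lands inside the background noise. Connected components use
  8-connectivity; components outside [50, 5000] px are removed (configurable;
  the bounds suit the synthetic scale of ~8 px nuclear radius at 10×-like
  sampling).
* **Cytoplasm** is a ring obtained by dilating each nucleus 10 px (the
  field-standard extension width; configurable). Contested pixels go to the
  nearest nucleus via the Euclidean distance transform, so rings never
  overlap nuclei or each other.
* **Measurement** records median nucleus and ring intensities, their ratio,
  and QC fields. Saturation is assessed on the *raw* reporter channel (the
  declared bit depth's top value), since correction rescales intensities and
  would hide clipped pixels. A zero nuclear median makes the ratio undefined;
  the cell is flagged and excluded from summaries.
* **Artifact removal** drops cells with a saturated-pixel fraction above 1%,
  a nucleus area outside the configured bounds, or a C/N ratio outside
  [0.05, 20]. These defaults are declared, not inferred from any published
  criterion, and every removal is counted in the log.
* **Summaries** take the median and IQR of single-cell ratios per replicate,
  then the mean ± SD of replicate medians per condition, optionally
  normalised to a no-drug reference condition.

The C/N ratio is invariant under any positive scaling of the reporter
channel, and — because nucleus and ring are adjacent — largely insensitive to
smooth illumination gradients even before correction; the pipeline recovers
planted ratios exactly on flat noise-free fields and within ±5% under a 30%
linear gradient.

## Cell-cycle deconvolution

DNA-content events are modelled as a three-component mixture: Gaussian G1 at
mean μ with coefficient of variation cv, Gaussian G2/M at r·μ with the same
cv (r constrained to [1.8, 2.2]), and an S-phase component formed by narrow
Gaussians whose means are uniform between the two peaks, which integrates to
the closed form `S(x) = [Φ((x−μ)/σ) − Φ((x−rμ)/σ)] / (μ(r−1))`. This
Dean–Jett–Fox-style shape was chosen because instrument-software gating
strategies are generally unpublished; it is the simplest model whose weights
are the phase fractions.

Fitting is by maximum likelihood (L-BFGS-B) over (log μ, log cv, r, two
weight logits), with the weights a softmax — fractions are non-negative and
sum to exactly 100%. Initialisation takes μ from the first prominent
histogram mode and the weights from coarse windows around μ, 2μ and the span
between; non-convergence triggers seeded jittered restarts (4 by default).
Events below 0.5× the G1 peak estimate are excluded as debris and events
above 3× as aggregates, both configurable; at least 200 events must remain.
cv is bounded in [1e-4, 0.5], which lets degenerate two-delta histograms
collapse to their point masses while keeping the likelihood finite.

Fractions are invariant to uniform rescaling of the intensity axis (μ is
free). Condition comparisons report per-phase shifts in percentage points
across replicates with a two-sample t-test at p < 0.05; with a single
replicate per arm the shift is reported and significance marked unavailable.

## Differential expression

The caller is self-contained and deliberately simple; it is not a
re-implementation of any published estimator, and the downstream core-set and
overlap machinery accepts externally produced DEG tables (gene, log2fc,
padj) interchangeably.

* **Normalisation**: median-of-ratios size factors against the geometric-mean
  reference over genes expressed in all samples.
* **Filter**: genes with total count < 10 across the contrasted samples are
  excluded (count logged); the threshold is a declared default.
* **Dispersion**: per-gene method of moments on the pooled within-group
  variability, floored at 0.01, then stabilised by a parametric trend
  `a0 + a1/μ` fitted across genes: each gene's final dispersion is the
  maximum of its own estimate and the trend, so no gene is tested with less
  variability than the ensemble suggests.
* **Test**: by default a likelihood-ratio test — per-group NB means (Newton
  MLE with size-factor offsets, fixed dispersion) against a common mean,
  referred to χ²(1). A delta-method Wald z statistic is available as an
  option. The LRT was made the default after simulation showed the Wald
  normal approximation understates far-tail p-values with three replicates
  per arm, inflating the family-wise null discovery rate when ~2000 genes
  are screened; the LRT restores calibration with no measurable power cost.
* **Calling**: BH adjustment, then `is_deg = (padj < 0.05) & (|log2FC| > 1)`,
  both thresholds configurable.

On simulated nulls (2000 genes, 3 vs 3) the mean false-discovery proportion
stays within Monte-Carlo error of 0.05, and planted |log2FC| = 2 genes are
detected with ≥ 90% power at moderate-to-high counts — both are asserted in
the test suite.

**Core gene groups.** The core set for a drug/modulator pair is the genes
flagged in the drug-only contrast and not flagged in the drug+modulator
contrast (both against the same control, same gene universe); the restored
fraction is the core size over the drug DEG count, as a percent. The measured
restored fraction slightly exceeds the planted rescue fraction by (1 −
power) times the non-rescued share — a non-rescued gene that escapes
detection in the combined contrast counts as restored — which at ≥ 95% power
keeps the bias under ~1.5 points.

**Permutation overlap test.** For 2 or 3 gene sets, each iteration draws an
equally sized uniform sample without replacement from each set's universe and
records the intersection size; `p = (# null ≥ observed)/n_iter` with no +1
correction, and a p of exactly 0 is annotated as `< 1/n_iter`. Universes
default to the genes passing the expression filter in each contrast. On
uniform universes this null is exactly hypergeometric, which the tests use as
a closed-form oracle.

## Pathway activation levels

Profiles are normalised gene-wise to case-to-normal ratios: each sample's
value over the gene's geometric mean across all samples in the dataset.
Genes zero everywhere are excluded; genes with some zeros get a pseudocount
of 1 added to the whole row (logged). A pathway is scored only when at least
10 weighted members are present in the profile. The score is

    PAL = K · Σ_g ARR_g · log10(CNR_g) / Σ_g |ARR_g|,   K = 100,

a weighted mean of signed log-ratios. Both K and the log base are
configurable so outputs can be matched to other conventions of the same
family. PAL is zero at unit CNR, flips sign under CNR inversion, ignores
neutral (ARR = 0) members, and shifts by K·log10(c) when all members of an
all-activator pathway are scaled by c. Group comparisons use a two-sample
t-test on per-sample PALs with BH adjustment across pathways; the test choice
is declared, not derived from any published convention.

Pathway files are GMT, with an optional `gene|weight` dialect for ARR
weights; plain GMT reads as all-activator. No pathway database ships with the
package — users supply their own gene sets.

## Synthetic generators: what they emulate, and what they do not

The generators reproduce the *statistical* structure of a rescue experiment —
six conditions (control, serum, EGF, drug, drug+serum, drug+EGF) in
triplicate, NB counts with planted drug-responsive genes of which designated
fractions are rescued per modulator; reporter fields with planted C/N ratios,
optional linear illumination gradients and saturated artifact blobs planted
on known cells; DNA histograms with planted phase fractions and sub-G1
debris; growth tables from the median-effect law with rescue modelled as
effective-dose attenuation `D_eff = D(1 − ρ·level)`.

Deliberate simplifications: rescue-by-attenuation is a monotone stand-in (it
creates the antagonistic CI > 1 structure but is not a mechanistic claim —
in particular the bell-shaped dual action of EGF is not modelled);
donor-to-donor serum variability is a single scalar; NB dispersion is a
global constant by default (per-gene arrays are accepted); nuclei are
uniform disks placed with disjoint cytoplasm annuli, so segmentation is never
confronted with touching nuclei (watershed splitting is out of scope); image
noise is multiplicative Gaussian, not Poisson photon statistics. Passing
tests therefore demonstrate correctness of the estimators under the stated
models and graceful behaviour at their edges — not robustness to every
pathology of real microscopy or sequencing data.

Default problem sizes (50 cells/field, 10 fields for image validation,
10,000 events per histogram, 2000 genes × 18 samples, 1000–10,000
permutation iterations, 20–50 seeds for repeated-recovery checks) were
chosen so each recovery estimate's Monte-Carlo error is small relative to the
tolerance it is checked against, while a full validation run completes in
about a minute on one core.

All generators draw every random quantity from a single integer seed
(`numpy.random.default_rng`); regenerating with the same spec is
bit-identical, and the demo orchestrator derives all stage seeds from one
config seed.

## Known limitations

* The DE caller omits shrinkage priors on fold changes, outlier handling and
  independent filtering; its exact DEG counts will not match heavier
  published estimators, which is why the core-set machinery is
  caller-agnostic.
* The cell-cycle mixture assumes a single G1 population; aneuploid or
  multi-population histograms need a richer model.
* The median-effect fit weights all usable points equally on the logit
  scale; very noisy extreme-effect points can still leverage the fit when a
  dose ladder extends far beyond the informative range.
* FCS binary flow-cytometry files and time-lapse imaging are not read; CSV
  event exports and endpoint fields are the supported inputs.
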