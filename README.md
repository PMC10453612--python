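# rescuekit

Quantitative toolkit for measuring how serum or growth-factor ligands rescue
cancer cells from growth inhibition by targeted drugs — the analysis side of a
rescue experiment on an EGFR-driven cell line (e.g. A431 squamous carcinoma
treated with cetuximab or erlotinib in the presence of human serum or EGF).
It is aimed at wet-lab groups and computational biologists who have the raw
readouts of such an experiment (cell counts, reporter microscopy, DNA-content
flow cytometry, RNA-seq counts) and want the downstream numbers: IC50s and
antagonism scores, single-cell kinase activity, cell-cycle shifts, rescued
gene fractions, and pathway activation levels.

Every stage has a matching synthetic-data generator with recorded ground
truth, so the whole pipeline can be exercised and validated without any
external data.

## What it computes

**Dose response.** Growth is normalised as
`100 · (n_treated − n_background) / (n_control − n_background)` and fitted
with the median-effect law `fa/fu = (D/Dm)^m` on the linearised scale
(log₁₀(fa/fu) vs log₁₀ D); `Dm` is the IC50 and
`IC50 = D / (100/y − 1)^(1/m)` from any single observation. Drug–modulator
antagonism is scored with the Loewe combination index
`CI = d₁/Dx₁ + d₂/Dx₂` at a chosen effect level (CI < 0.9 synergy, ~1
additive, > 1.1 antagonism).

**KTR imaging.** Kinase activity per cell is the ratio of median reporter
fluorescence in a 10-pixel cytoplasm ring to that in the nucleus (C/N ratio),
after illumination correction, two-class Otsu nuclear segmentation, and
artifact removal.

**Cell cycle.** G0/G1, S and G2/M fractions are maximum-likelihood weights of
a Gaussian G1 peak, a Gaussian G2/M peak constrained near twice the G1 mean,
and a Dean–Jett–Fox-style broadened S component, after sub-G1 debris
exclusion.

**Differential expression and core gene groups.** A self-contained
negative-binomial test (median-of-ratios size factors, trend-stabilised
dispersions, likelihood-ratio statistic) calls DEGs at BH-adjusted p < 0.05
and |log2FC| > 1. A drug's *core gene group* is the set of its DEGs that
become non-differential when the rescuing modulator is co-applied; overlap
significance between gene sets uses a permutation null (uniform equally-sized
draws from each universe; p = fraction of null intersections ≥ observed).

**Pathway activation levels.** Expression is normalised to case-to-normal
ratios (CNR, each gene over its geometric mean across samples) and each
pathway with ≥ 10 members scored as
`PAL = 100 · Σ ARR_g · log₁₀(CNR_g) / Σ |ARR_g|`, where ARR is the
activator(+)/repressor(−) role weight.

## Worked example

Run the end-to-end synthetic demonstration (generates dose tables, reporter
fields, DNA histograms and count matrices, then analyses all of them):

```bash
rescuekit demo --seed 1 --outdir demo_out
```

`demo_out/report.json` compares every recovered quantity to its planted
truth. With seed 1 the key numbers are:

| stage | planted | recovered |
|---|---|---|
| median-effect fit | m = 2, Dm = 300 | m = 2.008, Dm = 302.2 |
| combination index (drug + modulator) | antagonistic by construction | CI = 4.57, "strong antagonism" |
| KTR C/N ratio, control / drug | 2.5 / 1.0 | 2.509 / 1.003 |
| normalised drug ERK activity | 0.40 | 0.3997 |
| G1 shift under drug | +20 points | +20.8 ± 1.6, p = 2.2e-05 |
| DEGs under drug | 200 planted | 199 called |
| restored fraction, drug + serum | 75% | 75.4% |
| restored fraction, drug + EGF | 100% | 100% |
| top differential pathway | planted suppressed set | ranked first, padj = 3.4e-04 |

The same stages are available individually (`rescuekit dose fit`,
`rescuekit ktr --nuclear-glob ... --reporter-glob ...`, `rescuekit cycle fit`,
`rescuekit degs call|core|overlap`, `rescuekit pal`), and as a library:

```python
import rescuekit as rk

table, truth = rk.gen_dose_response(rk.GrowthSimSpec(m=2, dm=300, seed=1))
fit = rk.fit_median_effect(table)          # fit.m, fit.dm, fit.r
counts, design, gene_truth = rk.gen_counts(rk.CountsSimSpec(seed=5))
degs = rk.call_degs(counts, design, ("drug", "control"))
core = rk.core_gene_set(degs, rk.call_degs(counts, design,
                                           ("drug_serum", "control")))
print(core.restored_fraction_pct)
```

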