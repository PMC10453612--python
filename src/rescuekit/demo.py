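"""End-to-end synthetic demonstration run.

Generates a full synthetic rescue experiment (dose tables, reporter fields,
DNA histograms, count matrices), runs every analysis stage, and writes a JSON
report comparing each recovered quantity to its planted truth.  All randomness
derives from the single config seed, so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cell_cycle, degs, dose_response, io, ktr, pal, simulate
from .exceptions import RescueKitError

logger = logging.getLogger(__name__)

STAGES = ("dose", "imaging", "cycle", "degs", "pal")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and sizes for the demonstration run.

    Defaults follow the analysis conventions used throughout the package:
    significance at BH-adjusted p < 0.05, DEGs at |log2FC| > 1, 1000
    permutation iterations, a 10-pixel cytoplasm ring, and a 10-gene pathway
    eligibility minimum.
    """

    seed: int = 0
    outdir: str = "demo_out"
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    n_iter: int = 1000
    ring_width: int = 10
    min_pathway_genes: int = 10
    skip: tuple[str, ...] = ()
    # synthetic experiment sizes (kept modest so a demo run stays quick)
    n_cells_per_field: int = 30
    n_fields_per_replicate: int = 1
    n_cycle_events: int = 4000
    n_genes: int = 2000

    def __post_init__(self):
        unknown = set(self.skip) - set(STAGES)
        if unknown:
            raise RescueKitError(f"unknown stage(s) to skip: {sorted(unknown)}")


class StageError(RescueKitError):
    """A demo stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _seed(config: RunConfig, offset: int) -> int:
    return (config.seed * 1000 + offset) % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_dose(config: RunConfig, outdir: Path) -> dict:
    truth_m, truth_dm, rescue = 2.0, 300.0, 0.5
    drug_spec = simulate.GrowthSimSpec(
        m=truth_m, dm=truth_dm, noise_sd=0.02, rescue_strength=rescue,
        modulator_levels=(0.0, 1.0), n_reps=3, seed=_seed(config, 1))
    table, _ = simulate.gen_dose_response(drug_spec)
    io.write_dose_table(table, outdir / "dose_response.csv")

    fit_drug = dose_response.fit_median_effect(
        table[table.modulator_level == 0.0])

    # modulator's own titration as agent 2 (its own dose units; level 1 = Dm)
    mod_spec = simulate.GrowthSimSpec(
        m=1.5, dm=5.0, doses=(0.5, 1.0, 2.0, 4.0, 8.0, 16.0), noise_sd=0.02,
        rescue_strength=0.0, n_reps=3, seed=_seed(config, 2))
    mod_table, _ = simulate.gen_dose_response(mod_spec)
    fit_mod = dose_response.fit_median_effect(mod_table)

    # combination point: drug at its Dm with the modulator at level 1
    d1, d2 = truth_dm, 5.0
    fa_combo = dose_response.fraction_affected(
        d1 * (1.0 - rescue), truth_m, truth_dm)
    ci = dose_response.combination_index(
        fit_drug, fit_mod, d1=d1, d2=d2, effect_level=100.0 * float(fa_combo))

    ic50_hat = dose_response.ic50(
        float(table.dose.iloc[5]),
        float(fit_drug.growth_at(table.dose.iloc[5])), fit_drug.m)
    return {
        "fit": {"m": fit_drug.m, "dm": fit_drug.dm, "r": fit_drug.r,
                "n_points": fit_drug.n_points},
        "planted": {"m": truth_m, "dm": truth_dm},
        "ic50_from_fitted_curve": ic50_hat,
        "combination_index": {
            "ci": ci.ci, "effect_level_pct": ci.effect_level,
            "classification": ci.classification,
            "dx1": ci.dx1, "dx2": ci.dx2,
        },
    }


def _stage_imaging(config: RunConfig, outdir: Path) -> dict:
    planted = {"control": 2.5, "drug": 1.0}
    frames = []
    for c_idx, (cond, ratio) in enumerate(sorted(planted.items())):
        for rep in range(1, 4):
            for f_idx in range(config.n_fields_per_replicate):
                spec = simulate.ImageSimSpec(
                    n_cells=config.n_cells_per_field, true_cn_ratio=ratio,
                    illumination_gradient=0.2, n_artifacts=2,
                    seed=_seed(config, 100 + 10 * c_idx + 3 * rep + f_idx))
                nuclear, reporter, _truth = simulate.gen_ktr_field(spec)
                meas = ktr.quantify_field(nuclear, reporter,
                                          ring_width=config.ring_width)
                meas = ktr.remove_artifacts(meas)
                meas["condition"] = cond
                meas["replicate"] = rep
                frames.append(meas)
    all_meas = pd.concat(frames, ignore_index=True)
    all_meas.to_csv(outdir / "ktr_cells.tsv", sep="\t", index=False)
    per_rep, per_cond = ktr.summarize_condition(all_meas,
                                                normalize_to="control")
    per_cond.to_csv(outdir / "ktr_summary.tsv", sep="\t", index=False)
    as_dict = per_cond.set_index("condition").to_dict(orient="index")
    return {
        "planted_cn_ratio": planted,
        "recovered": {c: d["mean_of_medians"] for c, d in as_dict.items()},
        "normalized_drug_activity": as_dict["drug"]["normalized"],
        "n_cells_measured": int(len(all_meas)),
    }


def _stage_cycle(config: RunConfig, outdir: Path) -> dict:
    planted = {"control": (0.60, 0.25, 0.15), "drug": (0.80, 0.12, 0.08)}
    fits: dict[str, list] = {}
    for c_idx, (cond, (g1, s, g2m)) in enumerate(sorted(planted.items())):
        fits[cond] = []
        for rep in range(3):
            spec = simulate.CycleSimSpec(
                n_events=config.n_cycle_events, f_g1=g1, f_s=s, f_g2m=g2m,
                debris_frac=0.05, seed=_seed(config, 200 + 10 * c_idx + rep))
            events, _ = simulate.gen_dna_histogram(spec)
            fits[cond].append(cell_cycle.estimate_fractions(events))
    shifts = cell_cycle.compare_fractions(fits["control"], fits["drug"],
                                          alpha=config.alpha)
    return {
        "planted_fractions": {c: list(v) for c, v in planted.items()},
        "recovered_mean_pct": {
            c: np.mean([f.as_array() for f in fs], axis=0).tolist()
            for c, fs in fits.items()},
        "g1_shift_points": {
            "shift": shifts[0].shift, "sd": shifts[0].sd,
            "p_value": shifts[0].p_value, "significant": shifts[0].significant},
    }


def _stage_degs(config: RunConfig, outdir: Path) -> dict:
    spec = simulate.CountsSimSpec(
        n_genes=config.n_genes, rescued_fraction_serum=0.75,
        rescued_fraction_egf=1.0, seed=_seed(config, 300))
    counts, design, truth = simulate.gen_counts(spec)
    io.write_counts(counts, outdir / "counts.tsv")
    io.write_design(design, outdir / "design.tsv")
    truth.to_csv(outdir / "gene_truth.tsv", sep="\t")

    tables = {}
    for cond in ("drug", "drug_serum", "drug_egf"):
        tables[cond] = degs.call_degs(
            counts, design, (cond, "control"), alpha=config.alpha,
            lfc_threshold=config.lfc_threshold)
        tables[cond].to_csv(outdir / f"degs_{cond}_vs_control.tsv", sep="\t")

    cores = {
        mod: degs.core_gene_set(tables["drug"], tables[f"drug_{mod}"],
                                drug="drug", modulator=mod)
        for mod in ("serum", "egf")
    }

    universe = tables["drug"].index[tables["drug"].pvalue.notna()]
    detected_up = set(tables["drug"].index[tables["drug"].direction == "up"])
    planted_up = set(truth.index[truth["class"] == "drug_up"]) & set(universe)
    overlap = degs.permutation_overlap_test(
        [detected_up, planted_up], [universe, universe],
        n_iter=config.n_iter, seed=_seed(config, 301))

    return {
        "n_degs_drug": int(tables["drug"].is_deg.sum()),
        "planted_degs": int(spec.n_drug_down + spec.n_drug_up),
        "restored_fraction_pct": {
            mod: cores[mod].restored_fraction_pct for mod in cores},
        "planted_rescued_fraction_pct": {"serum": 75.0, "egf": 100.0},
        "core_sizes": {mod: {"up": cores[mod].n_up, "down": cores[mod].n_down}
                       for mod in cores},
        "detected_vs_planted_up_overlap": {
            "observed": overlap.observed, "p_value": overlap.p_value,
            "p_annotation": overlap.p_annotation},
    }


def _stage_pal(config: RunConfig, outdir: Path) -> dict:
    spec = simulate.CountsSimSpec(
        n_genes=config.n_genes, seed=_seed(config, 300))  # same data as degs
    counts, design, truth = simulate.gen_counts(spec)
    sf = degs.size_factors(counts)
    cnr = pal.geometric_mean_normalize(counts / sf)

    rng = np.random.default_rng(_seed(config, 400))
    down_genes = truth.index[truth["class"] == "drug_down"][:30].tolist()
    pathways = [pal.Pathway("planted_drug_suppressed",
                            {g: 1.0 for g in down_genes})]
    null_pool = truth.index[truth["class"] == "null"].to_numpy()
    for i in range(20):
        members = rng.choice(null_pool, size=15, replace=False)
        pathways.append(pal.Pathway(f"null_pathway_{i:02d}",
                                    {g: 1.0 for g in members}))

    mat = pal.score_pathways(pathways, cnr,
                             min_genes=config.min_pathway_genes)
    comparison = pal.compare_pal_groups(
        mat, design["condition"], group_a="control", group_b="drug")
    comparison.to_csv(outdir / "pal_comparison.tsv", sep="\t")
    top = comparison.index[0]
    return {
        "n_pathways_scored": int(len(mat)),
        "top_pathway": str(top),
        "top_pathway_pal_diff": float(comparison["pal_diff"].iloc[0]),
        "top_pathway_padj": float(comparison["padj"].iloc[0]),
        "planted_pathway_is_top": bool(top == "planted_drug_suppressed"),
    }


_STAGE_FUNCS = {"dose": _stage_dose, "imaging": _stage_imaging,
                "cycle": _stage_cycle, "degs": _stage_degs, "pal": _stage_pal}


def run_demo(config: RunConfig | None = None) -> dict:
    """Run every (non-skipped) stage and write ``report.json`` to the outdir."""
    config = config or RunConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}
    for stage in STAGES:
        if stage in config.skip:
            logger.info("skipping stage %s", stage)
            continue
        try:
            report["stages"][stage] = _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:  # noqa: BLE001 - re-tagged with the stage
            raise StageError(stage, exc) from exc
        logger.info("stage %s done", stage)
    io.write_json(report, outdir / "report.json")
    return report
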