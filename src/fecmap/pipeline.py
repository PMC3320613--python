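"""End-to-end orchestration: the synthetic study replay.

``run_study_replay`` regenerates the whole study design from scratch with
a single seed — 12 RILs genotyped at ~102 SNPs on three chromosomes, two
larval diets, a chromosome-2R QTL at 35% of among-line variance, one
failing and one complementing deficiency scenario, an effective RNAi
scenario, and qPCR plates at the study's observed effect sizes — runs
every analysis stage at its standard settings (50 imputations, 3 cM grid,
permutation threshold), and writes a plain-text report comparing each
recovered quantity with its generator truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import complementation as comp
from . import fecundity, qpcr, qtl, simulate
from .genmap import default_ril_map

logger = logging.getLogger(__name__)

REPLAY_QTL = simulate.QTLSpec(
    chrom="2",
    position_cm=72.0,
    variance_fraction=0.35,
    additive_effect_by_environment={"yeast_0.2": 0.7, "yeast_0.6": 1.3},
)

QPCR_SCENARIOS = {
    # (gene, tissue, group pair): true log2 fold change of group2 vs group1
    ("Drip", "head", ("high", "low")): -2.7,
    ("Drip", "head", ("control", "RNAi")): -1.75,
    ("Crz", "head", ("high", "low")): -12.0,
    ("pale", "head", ("high", "low")): 0.5,
}


def _check(label, recovered, truth, tol, lines):
    status = "pass" if abs(recovered - truth) <= tol else "FAIL"
    lines.append(
        f"  [{status}] {label}: recovered {recovered:.3f} vs truth {truth:.3f} "
        f"(tolerance {tol:g})"
    )
    return status == "pass"


def run_study_replay(
    seed: int,
    outdir,
    n_lines: int = 12,
    n_markers: int = 102,
    n_imputations: int = 50,
    step_cm: float = 3.0,
    n_perm: int = 1000,
    n_boot: int = 1000,
) -> dict:
    """Run every stage on freshly simulated data; returns a results dict
    and writes all artifacts plus ``report.txt`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seeds = {k: int(rng.integers(2**31 - 1)) for k in
             ("genotypes", "fecundity", "scan", "comp", "rnai", "qpcr")}
    config = {"seed": seed, "n_lines": n_lines, "n_markers": n_markers,
              "n_imputations": n_imputations, "step_cm": step_cm, "n_perm": n_perm}
    config_hash = hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]
    logger.info("replay config %s seeds %s hash %s", config, seeds, config_hash)
    report = [f"fecmap replay (seed={seed}, config hash {config_hash})", ""]
    results = {"config": config, "seeds": seeds}

    # --- stage 1: RIL panel and fecundity assay -------------------------
    gmap = default_ril_map(n_markers)
    genotypes = simulate.simulate_ril_genotypes(gmap, n_lines, seeds["genotypes"])
    gmap.to_csv(outdir / "map.csv")
    genotypes.to_csv(outdir / "genotypes.csv")

    config_fec = simulate.FecundityGeneratorConfig()
    eggs = simulate.simulate_fecundity(genotypes, REPLAY_QTL, config_fec, seeds["fecundity"])
    eggs.to_csv(outdir / "eggcounts.tsv", sep="\t", index=False)

    totals = fecundity.line_totals(eggs)
    totals.to_csv(outdir / "totals.tsv", sep="\t", index=False)

    # --- stage 2: genome scan ------------------------------------------
    profile = qtl.scan_pipeline(
        genotypes, totals, n_imputations=n_imputations, step_cm=step_cm,
        n_perm=n_perm, seed=seeds["scan"],
    )
    profile.table.to_csv(outdir / "lod_profile.tsv", sep="\t", index=False)
    peak = profile.peak()
    interval = qtl.lod_support_interval(profile)
    ve = qtl.variance_explained(profile)
    with open(outdir / "qtl.json", "w") as fh:
        json.dump(
            {"peak_chrom": str(peak["chrom"]), "peak_cm": float(peak["cm"]),
             "max_lod": float(peak["lod"]), "threshold": profile.threshold,
             "variance_explained_pct": ve, "support_interval": interval},
            fh, indent=2, default=str,
        )
    report.append("QTL scan (12 RILs, ~102 markers, 50 imputations, 3 cM grid):")
    report.append(
        f"  peak on chromosome {peak['chrom']} at {peak['cm']:.1f} cM "
        f"(truth: chromosome {REPLAY_QTL.chrom} at {REPLAY_QTL.position_cm:.1f} cM)"
    )
    sig = profile.threshold is not None and peak["lod"] > profile.threshold
    report.append(
        f"  max LOD {peak['lod']:.2f} vs 95% permutation threshold "
        f"{profile.threshold:.2f} -> {'significant' if sig else 'not significant'}"
    )
    checks = []
    checks.append(_check("variance explained at peak (%)", ve,
                         100 * REPLAY_QTL.variance_fraction, 15.0, report))
    chrom_ok = str(peak["chrom"]) == str(REPLAY_QTL.chrom)
    report.append(f"  [{'pass' if chrom_ok else 'FAIL'}] peak localizes to the true chromosome")
    checks.append(chrom_ok)
    results["qtl"] = {"peak_chrom": str(peak["chrom"]), "peak_cm": float(peak["cm"]),
                      "max_lod": float(peak["lod"]), "threshold": profile.threshold,
                      "ve_pct": ve, "significant": bool(sig)}
    report.append("")

    # --- stage 3: complementation --------------------------------------
    comp_config = simulate.FecundityGeneratorConfig(n_vials=5, n_flies=1)
    scenarios = {
        "failing_deficiency": {"A/Bal": 300.0, "B/Bal": 300.0, "A/Def": 300.0, "B/Def": 180.0},
        "complementing_deficiency": {c: 300.0 for c in ("A/Bal", "B/Bal", "A/Def", "B/Def")},
    }
    comp_rows = []
    report.append("Quantitative complementation (likelihood-ratio contrasts):")
    for i, (label, class_totals) in enumerate(scenarios.items()):
        recs = simulate.simulate_complementation(class_totals, comp_config, seeds["comp"] + i)
        res = comp.fit_contrast_model(recs, comp.default_complementation_design(),
                                      n_boot=n_boot, seed=seeds["comp"] + i)
        expected = "fails_to_complement" if label.startswith("failing") else "complements"
        ok = res.call == expected
        checks.append(ok)
        report.append(f"  [{'pass' if ok else 'FAIL'}] {label}: called {res.call}")
        for _, row in res.contrasts.iterrows():
            comp_rows.append((label, row["name"], row["estimate"], row["lrt"],
                              row["p_value"], res.call))
        results[label] = {"call": res.call,
                          "contrasts": res.contrasts.to_dict("records")}
    report.append("")

    # --- stage 4: RNAi fecundity effect --------------------------------
    rnai_truth_pct = 20.0
    control_total = 300.0
    rnai_config = simulate.FecundityGeneratorConfig(n_vials=30, n_flies=1)
    rnai_recs = simulate.simulate_complementation(
        {"control": control_total, "RNAi": control_total * (1 - rnai_truth_pct / 100)},
        rnai_config, seeds["rnai"],
    )
    rnai_res = comp.fit_contrast_model(rnai_recs, comp.default_rnai_design(),
                                       n_boot=n_boot, seed=seeds["rnai"])
    t_ctrl = rnai_res.class_totals["control"].total_eggs
    t_rnai = rnai_res.class_totals["RNAi"].total_eggs
    pct = 100 * (1 - t_rnai / t_ctrl)
    report.append("RNAi knock-down (control vs RNAi):")
    checks.append(_check("fecundity reduction (%)", pct, rnai_truth_pct, 10.0, report))
    ok = rnai_res.call == "rnai_reduces"
    checks.append(ok)
    report.append(f"  [{'pass' if ok else 'FAIL'}] RNAi effect called: {rnai_res.call}")
    results["rnai"] = {"call": rnai_res.call, "pct_reduction": pct}
    for _, row in rnai_res.contrasts.iterrows():
        comp_rows.append(("rnai", row["name"], row["estimate"], row["lrt"],
                          row["p_value"], rnai_res.call))
    pd.DataFrame(
        comp_rows,
        columns=["scenario", "contrast", "estimate", "lrt", "p_value", "call"],
    ).to_csv(outdir / "complementation_report.tsv", sep="\t", index=False)
    report.append("")

    # --- stage 5: qPCR -------------------------------------------------
    report.append("qPCR fold changes (delta-delta-Ct, permutation inference):")
    fc_rows = []
    qpcr_tables = []
    for i, ((gene, tissue, groups), truth) in enumerate(QPCR_SCENARIOS.items()):
        cts = simulate.simulate_qpcr(truth, seed=seeds["qpcr"] + i, groups=groups,
                                     target_gene=gene, tissue=tissue)
        qpcr_tables.append(cts)
        est = qpcr.permutation_inference(cts, gene, comparison=groups,
                                         tissue=tissue, seed=seeds["qpcr"] + i)
        label = f"{gene} ({tissue}, {groups[1]} vs {groups[0]})"
        checks.append(_check(f"log2 fold change, {label}", est.log2_fc, truth, 0.75, report))
        fc_rows.append((gene, tissue, f"{groups[1]}_vs_{groups[0]}", est.log2_fc,
                        est.ci_low, est.ci_high, est.p_value,
                        "exact" if est.exact else "monte-carlo"))
        results[f"qpcr_{gene}_{groups[1]}"] = {"log2_fc": est.log2_fc, "p": est.p_value}
    pd.concat(qpcr_tables).to_csv(outdir / "qpcr.csv", index=False)
    pd.DataFrame(
        fc_rows,
        columns=["gene", "tissue", "comparison", "log2_fc", "ci_low", "ci_high",
                 "p", "method"],
    ).to_csv(outdir / "foldchanges.tsv", sep="\t", index=False)

    report.append("")
    n_pass = sum(checks)
    report.append(f"{n_pass}/{len(checks)} checks passed.")
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    results["n_checks"] = len(checks)
    results["n_passed"] = int(n_pass)
    return results
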