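#!/usr/bin/env python
"""Differential abundance/occupancy and the enhanced-TE program.

Reads the simulated counts from results/data/, runs both per-assay NB Wald
tests, applies the published classification rule (RNA unchanged at
|log2FC| <= 2; occupancy up at p < 0.01 and log2FC > 0.5), and confirms the
classification with the NB GLM condition-by-assay interaction test.  Writes
tables under results/te/ and a classification scatter under
results/figures/.
"""

import argparse
from pathlib import Path

import numpy as np

from riboshift import io as rio
from riboshift.plots import te_scatter
from riboshift.te import (
    TEThresholds,
    classify_te,
    differential_abundance,
    estimate_dispersion,
    glm_te_interaction,
)

parser = argparse.ArgumentParser()
parser.add_argument("--datadir", type=Path, default=Path("results/data"))
parser.add_argument("--outdir", type=Path, default=Path("results/te"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

rna = rio.read_count_experiment(args.datadir / "rna_counts.tsv",
                                args.datadir / "lengths.tsv",
                                args.datadir / "design.tsv", "rna")
ribo = rio.read_count_experiment(args.datadir / "ribo_counts.tsv",
                                 args.datadir / "lengths.tsv",
                                 args.datadir / "design.tsv", "ribo")
truth = rio.read_table(args.datadir / "truth_te.tsv")

disp_rna = estimate_dispersion(rna.counts, rna.condition_of_library)
disp_ribo = estimate_dispersion(ribo.counts, ribo.condition_of_library)
res_rna = differential_abundance(rna, disp_rna)
res_ribo = differential_abundance(ribo, disp_ribo)
thresholds = TEThresholds()
classes = classify_te(res_rna, res_ribo, thresholds)
inter = glm_te_interaction(rna, ribo, 0.5 * (disp_rna + disp_ribo))

rio.write_table(res_rna, args.outdir / "differential_rna.tsv")
rio.write_table(res_ribo, args.outdir / "differential_ribo.tsv")
rio.write_table(classes, args.outdir / "te_classification.tsv")
rio.write_table(inter, args.outdir / "te_interaction.tsv")

planted = set(truth.loc[truth["planted_class"] == "te_up", "transcript_id"])
enhanced = set(classes.loc[classes["enhanced_te"], "transcript_id"])
n_rna_changed = (classes["rna_status"] != "unchanged").sum()
n_occ_up = (classes["occupancy_status"] == "up").sum()
print(f"RNA abundance changed (|log2FC| > {thresholds.rna_abs_log2fc}): "
      f"{n_rna_changed} / {len(classes)} "
      f"({100 * n_rna_changed / len(classes):.1f}%)")
print(f"occupancy up (p < {thresholds.ribo_p}, log2FC > "
      f"{thresholds.ribo_abs_log2fc}): {n_occ_up}")
print(f"enhanced-TE transcripts: {len(enhanced)}; "
      f"{len(enhanced & planted)} of {len(planted)} planted recovered, "
      f"{len(enhanced - planted)} outside the planted program")

mean_planted = inter.set_index("transcript_id").loc[sorted(planted),
                                                    "delta_te_log2"].mean()
sig = inter[(inter["fdr"] < 0.05) & (inter["delta_te_log2"] > 0)]
print(f"GLM interaction confirmation: mean interaction coefficient over the "
      f"planted program {mean_planted:.3f} (planted value 1.0); "
      f"{len(sig)} individual transcript(s) reach FDR < 0.05 — per-transcript "
      f"power is low at 3 replicates, the confirmation is at the program level")

figdir = Path("results/figures")
figdir.mkdir(parents=True, exist_ok=True)
te_scatter(res_rna["log2fc"].to_numpy(), res_ribo["log2fc"].to_numpy(),
           classes["enhanced_te"].to_numpy(), figdir / "te_classification.png",
           thresholds=thresholds)
print(f"scatter written to {figdir / 'te_classification.png'}")
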