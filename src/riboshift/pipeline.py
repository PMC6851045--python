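"""End-to-end orchestration: simulate -> TE analysis -> enrichment, plus the
bisulfite screen and amplicon clone analysis, driven by a single YAML config
with one global seed fanned out per stage.

The stage-seed derivation is ``SeedSequence([seed, stage_index])`` reduced
modulo 2**31, with fixed stage indices (0 counts, 1 pileup, 2 clones,
3 gene sets), so toggling stages on or off never changes the data another
stage sees.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import bisulfite as bs
from . import enrichment as enr
from . import io as rio
from . import simulate as sim
from . import te as te_mod

__all__ = ["default_config", "load_config", "run_pipeline", "stage_seed"]

_STAGE_INDEX = {"te_sim": 0, "bs_sim": 1, "clone_sim": 2, "gene_sets": 3}

_SCHEMA = {
    "outdir": None,
    "seed": None,
    "stages": {"simulate", "te", "bsrna", "clones", "enrichment"},
    "simulate": {"te_sim", "bs_sim", "clone_sim", "gene_sets"},
    "te": {"pseudocount", "shrinkage", "min_base_mean", "deficient_arm", "thresholds"},
    "bsrna": {"high_threshold", "min_coverage", "call_condition",
              "conversion_control_sites"},
    "clones": {"min_clones", "mode", "amplicon_length", "target_methylation",
               "background_methylation", "n_clones", "sequencing_error_rate"},
    "enrichment": {"fdr", "min_set_size", "max_set_size"},
    "inputs": {"rna_counts", "ribo_counts", "lengths", "design", "pileup",
               "clones_fasta", "amplicon_fasta", "gmt"},
}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    ss = np.random.SeedSequence([int(seed), _STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0] % 2**31)


def default_config(outdir, seed: int = 0) -> dict:
    """A small self-contained demo configuration: simulate everything, run
    every stage.  Sizes are reduced so the demo completes in seconds."""
    return {
        "outdir": str(outdir),
        "seed": int(seed),
        "stages": {"simulate": True, "te": True, "bsrna": True,
                   "clones": True, "enrichment": True},
        "simulate": {
            "te_sim": {"n_transcripts": 400, "frac_rna_de": 0.02,
                       "frac_te_up": 0.05},
            "bs_sim": {"n_sites": 200, "planted_site_index": 101},
            "gene_sets": {"n_null_sets": 10, "set_size": 20,
                          "planted_set_fraction": 0.6},
        },
        "te": {"pseudocount": 0.5, "shrinkage": 0.8, "min_base_mean": 1.0,
               "deficient_arm": None,
               "thresholds": {"rna_abs_log2fc": 2.0, "ribo_abs_log2fc": 0.5,
                              "ribo_p": 0.01}},
        "bsrna": {"high_threshold": 0.9, "min_coverage": 30,
                  "call_condition": "NSUN5",
                  "conversion_control_sites": list(range(1, 51))},
        "clones": {"min_clones": 8, "mode": "all_c", "amplicon_length": 120,
                   "target_methylation": 0.9, "background_methylation": 0.05,
                   "n_clones": 8, "sequencing_error_rate": 0.0},
        "enrichment": {"fdr": 0.05, "min_set_size": 5, "max_set_size": 2000},
    }


def _validate(config: dict) -> None:
    unknown = set(config) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, allowed in _SCHEMA.items():
        if allowed is None or key not in config:
            continue
        section = config[key]
        if not isinstance(section, dict):
            raise ValueError(f"config section {key!r} must be a mapping")
        extra = set(section) - allowed
        if extra:
            raise ValueError(f"unknown keys in config section {key!r}: {sorted(extra)}")
    for path_key in ("outdir",):
        if path_key not in config:
            raise ValueError(f"config must declare {path_key!r}")


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    _validate(config)
    return config


def _simulate_stage(config, outdir, summary):
    seed = int(config.get("seed", 0))
    simcfg = config.get("simulate", {})

    te_kwargs = dict(simcfg.get("te_sim", {}))
    te_kwargs.setdefault("seed", stage_seed(seed, "te_sim"))
    te_cfg = sim.TESimConfig(**te_kwargs)
    rna, ribo, truth = sim.simulate_te_experiment(te_cfg)
    rio.write_counts_tsv(rna, outdir / "rna_counts.tsv", outdir / "lengths.tsv")
    rio.write_counts_tsv(ribo, outdir / "ribo_counts.tsv")
    rio.write_design_tsv({"rna": rna, "ribo": ribo}, outdir / "design.tsv")
    rio.write_table(truth, outdir / "truth_te.tsv")

    bs_kwargs = dict(simcfg.get("bs_sim", {}))
    bs_kwargs.setdefault("seed", stage_seed(seed, "bs_sim"))
    bs_cfg = sim.BsSimConfig(**bs_kwargs)
    pileup = sim.simulate_bsrna_pileup(bs_cfg)
    rio.write_pileup_tsv(pileup, outdir / "pileup.tsv")

    clone_section = config.get("clones", {})
    clone_seed = stage_seed(seed, "clone_sim")
    rng = np.random.default_rng(clone_seed)
    length = int(clone_section.get("amplicon_length", 120))
    amplicon = "".join(rng.choice(list("ACGT"), length))
    mode = clone_section.get("mode", "all_c")
    positions = bs.queried_cytosines(amplicon, mode)
    profile = np.full(len(positions), float(clone_section.get("background_methylation", 0.05)))
    target = int(np.argmin(np.abs(np.asarray(positions) - length / 2)))
    profile[target] = float(clone_section.get("target_methylation", 0.9))
    clone_cfg = sim.CloneSimConfig(
        amplicon_sequence=amplicon,
        per_site_methylation=tuple(profile),
        cytosine_mode=mode,
        n_clones=int(clone_section.get("n_clones", 8)),
        sequencing_error_rate=float(clone_section.get("sequencing_error_rate", 0.0)),
        seed=clone_seed,
    )
    records, clone_truth = sim.simulate_clones(clone_cfg)
    rio.write_fasta(records, outdir / "clones.fasta")
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    rio.write_fasta([SeqRecord(Seq(amplicon), id="amplicon", description="")],
                    outdir / "amplicon.fasta")
    rio.write_table(clone_truth, outdir / "truth_clones.tsv")

    gs_kwargs = dict(simcfg.get("gene_sets", {}))
    gs_kwargs.setdefault("seed", stage_seed(seed, "gene_sets"))
    sets = sim.simulate_gene_sets(truth, **gs_kwargs)
    enr.write_gmt(sets, outdir / "gene_sets.gmt")

    summary["simulate"] = {
        "seeds": {name: stage_seed(seed, name) for name in _STAGE_INDEX},
        "n_transcripts": int(te_cfg.n_transcripts),
        "n_sites": int(bs_cfg.n_sites),
        "n_clones": int(clone_cfg.n_clones),
    }


def _input_path(config, outdir, key, default_name):
    inputs = config.get("inputs", {})
    if key in inputs:
        return Path(inputs[key])
    return outdir / default_name


def _te_stage(config, outdir, summary):
    te_cfg = config.get("te", {})
    pc = float(te_cfg.get("pseudocount", 0.5))
    shrink = float(te_cfg.get("shrinkage", 0.5))
    min_mean = float(te_cfg.get("min_base_mean", 1.0))
    thresholds = te_mod.TEThresholds(**te_cfg.get("thresholds", {}))

    rna = rio.read_count_experiment(
        _input_path(config, outdir, "rna_counts", "rna_counts.tsv"),
        _input_path(config, outdir, "lengths", "lengths.tsv"),
        _input_path(config, outdir, "design", "design.tsv"), "rna")
    ribo = rio.read_count_experiment(
        _input_path(config, outdir, "ribo_counts", "ribo_counts.tsv"),
        _input_path(config, outdir, "lengths", "lengths.tsv"),
        _input_path(config, outdir, "design", "design.tsv"), "ribo")

    sf_rna = te_mod.estimate_size_factors(rna.counts)
    sf_ribo = te_mod.estimate_size_factors(ribo.counts)
    mean_rna = (rna.counts / sf_rna).mean(axis=1)
    mean_ribo = (ribo.counts / sf_ribo).mean(axis=1)
    keep = (mean_rna >= min_mean) | (mean_ribo >= min_mean)
    n_filtered = int((~keep).sum())

    def _subset(exp, mask):
        return te_mod.CountExperiment(exp.transcript_ids[mask], exp.lengths_bp[mask],
                                      exp.counts[mask], exp.library_labels,
                                      exp.condition_of_library)

    rna_f, ribo_f = _subset(rna, keep), _subset(ribo, keep)
    disp_rna = te_mod.estimate_dispersion(rna_f.counts, rna_f.condition_of_library,
                                          shrinkage=shrink)
    disp_ribo = te_mod.estimate_dispersion(ribo_f.counts, ribo_f.condition_of_library,
                                           shrinkage=shrink)
    res_rna = te_mod.differential_abundance(rna_f, disp_rna, pseudocount=pc)
    res_ribo = te_mod.differential_abundance(ribo_f, disp_ribo, pseudocount=pc)
    classes = te_mod.classify_te(res_rna, res_ribo, thresholds)

    deficient = te_cfg.get("deficient_arm")
    cond_a, cond_b = rna.conditions
    if deficient is None or deficient == cond_b:
        enhanced_def = classes["enhanced_te"]
    elif deficient == cond_a:
        # fold changes are B vs A: enhanced TE in the reference arm shows as
        # occupancy down with RNA unchanged
        enhanced_def = ((classes["rna_status"] == "unchanged")
                        & (classes["occupancy_status"] == "down"))
    else:
        raise ValueError(f"deficient_arm {deficient!r} is not a condition label")
    classes = classes.assign(enhanced_te_deficient_arm=enhanced_def)

    disp_combined = 0.5 * (disp_rna + disp_ribo)
    interaction = te_mod.glm_te_interaction(rna_f, ribo_f, disp_combined,
                                            pseudocount=pc)

    rio.write_table(res_rna, outdir / "differential_rna.tsv",
                    f"NB Wald test, log2fc = {cond_b} vs {cond_a}, pseudocount {pc}")
    rio.write_table(res_ribo, outdir / "differential_ribo.tsv",
                    f"NB Wald test, log2fc = {cond_b} vs {cond_a}, pseudocount {pc}")
    rio.write_table(classes, outdir / "te_classification.tsv",
                    f"thresholds: |rna log2fc| > {thresholds.rna_abs_log2fc}, "
                    f"ribo p < {thresholds.ribo_p} and |log2fc| > {thresholds.ribo_abs_log2fc}")
    rio.write_table(interaction, outdir / "te_interaction.tsv",
                    "NB GLM condition:assay interaction (log2 TE change)")

    summary["te"] = {
        "n_tested": int(keep.sum()),
        "n_low_count_filtered": n_filtered,
        "thresholds": {"rna_abs_log2fc": thresholds.rna_abs_log2fc,
                       "ribo_abs_log2fc": thresholds.ribo_abs_log2fc,
                       "ribo_p": thresholds.ribo_p},
        "class_counts": {
            "rna_up": int((classes["rna_status"] == "up").sum()),
            "rna_down": int((classes["rna_status"] == "down").sum()),
            "occupancy_up": int((classes["occupancy_status"] == "up").sum()),
            "occupancy_down": int((classes["occupancy_status"] == "down").sum()),
            "enhanced_te": int(classes["enhanced_te"].sum()),
            "enhanced_te_deficient_arm": int(classes["enhanced_te_deficient_arm"].sum()),
        },
    }
    return classes


def _bsrna_stage(config, outdir, summary):
    cfg = config.get("bsrna", {})
    pileup = rio.read_pileup_tsv(_input_path(config, outdir, "pileup", "pileup.tsv"))
    conditions = list(dict.fromkeys(pileup["condition"]))
    call_condition = cfg.get("call_condition", conditions[-1])

    controls = cfg.get("conversion_control_sites")
    efficiency = None
    if controls:
        efficiency = bs.estimate_conversion_efficiency(pileup, controls)

    hits = bs.call_high_methylation_sites(
        pileup, call_condition,
        threshold=float(cfg.get("high_threshold", 0.9)),
        min_coverage=int(cfg.get("min_coverage", 30)),
        conversion_efficiency=efficiency)

    cond_a, cond_b = conditions[0], conditions[-1]
    mat_a = bs.site_level_matrix(pileup, cond_a, efficiency)
    mat_b = bs.site_level_matrix(pileup, cond_b, efficiency)
    sites = mat_a.index.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tests = bs.moderated_t_site_test(mat_a.to_numpy(),
                                         mat_b.loc[sites].to_numpy(),
                                         sites=sites)

    rio.write_table(hits, outdir / "high_methylation_sites.tsv",
                    f"pooled level in {call_condition} strictly > "
                    f"{cfg.get('high_threshold', 0.9)}; 1-based sites")
    rio.write_table(tests, outdir / "site_tests.tsv",
                    f"empirical-Bayes moderated t, {cond_b} vs {cond_a}; 1-based sites")

    summary["bsrna"] = {
        "conversion_efficiency": None if efficiency is None else float(efficiency),
        "call_condition": call_condition,
        "n_high_sites": int(len(hits)),
        "high_sites": [int(s) for s in hits["site"]],
        "top_site_by_p": (int(tests.loc[tests["p_value"].idxmin(), "site"])
                          if tests["p_value"].notna().any() else None),
    }


def _clones_stage(config, outdir, summary):
    cfg = config.get("clones", {})
    clones = rio.read_fasta(_input_path(config, outdir, "clones_fasta", "clones.fasta"))
    amplicon = rio.read_fasta(_input_path(config, outdir, "amplicon_fasta",
                                          "amplicon.fasta"))[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix = bs.clone_analysis(clones, str(amplicon.seq),
                                   mode=cfg.get("mode", "all_c"),
                                   min_clones=int(cfg.get("min_clones", 8)))
    freq = pd.DataFrame({"position": matrix.positions,
                         "frequency": matrix.per_position_frequency.to_numpy()})
    rio.write_table(freq, outdir / "clone_frequencies.tsv",
                    "per-position methylation frequency (ambiguous calls excluded)")
    (outdir / "clone_lollipop.txt").write_text(bs.render_lollipop(matrix) + "\n")
    summary["clones"] = {
        "n_clones": len(matrix.clone_ids),
        "n_positions": len(matrix.positions),
        "max_frequency": float(np.nanmax(matrix.per_position_frequency.to_numpy())),
    }


def _enrichment_stage(config, outdir, summary, classes):
    cfg = config.get("enrichment", {})
    collection = enr.read_gmt(_input_path(config, outdir, "gmt", "gene_sets.gmt"),
                              normalize_case=False)
    if classes is None:
        classes = rio.read_table(outdir / "te_classification.tsv")
    universe = classes["transcript_id"]
    query_col = ("enhanced_te_deficient_arm"
                 if "enhanced_te_deficient_arm" in classes else "enhanced_te")
    query = classes.loc[classes[query_col].astype(bool), "transcript_id"]
    fdr_cut = float(cfg.get("fdr", 0.05))
    if len(query) == 0:
        summary["enrichment"] = {"n_query": 0, "n_sets_tested": 0, "significant_sets": []}
        return
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = enr.hypergeometric_enrichment(
            query, collection, universe,
            min_set_size=int(cfg.get("min_set_size", 5)),
            max_set_size=int(cfg.get("max_set_size", 2000)))
    rio.write_table(result, outdir / "enrichment.tsv",
                    f"hypergeometric over-representation; FDR cutoff {fdr_cut}")
    summary["enrichment"] = {
        "n_query": int(len(query)),
        "n_sets_tested": int(len(result)),
        "significant_sets": result.loc[result["fdr"] < fdr_cut, "set_name"].tolist(),
    }


def run_pipeline(config: dict) -> dict:
    """Run the configured stages; returns (and writes) the run summary."""
    _validate(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", {})
    summary = {"version": __version__, "seed": int(config.get("seed", 0)),
               "stages_run": [k for k, v in stages.items() if v]}

    classes = None
    try:
        if stages.get("simulate"):
            _simulate_stage(config, outdir, summary)
        if stages.get("te"):
            classes = _te_stage(config, outdir, summary)
        if stages.get("bsrna"):
            _bsrna_stage(config, outdir, summary)
        if stages.get("clones"):
            _clones_stage(config, outdir, summary)
        if stages.get("enrichment"):
            _enrichment_stage(config, outdir, summary, classes)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    (outdir / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
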