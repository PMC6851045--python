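#!/usr/bin/env python
"""Generate the synthetic study data set.

Emulates the two-condition perturbation design (empty-vector vs
NSUN5-restored) at the default study conditions: paired RNA-seq/Ribo-seq
counts for 2000 transcripts with 3 replicates per condition (2% planted
transcriptional changes, 5% planted enhanced-TE program at +1 log2),
a 1000-site bisulfite pileup with one planted high-methylation site, clone
sequences for a methylated and an unmethylated sample, and gene sets
containing the planted program.  Everything is written under results/data/.
"""

import argparse
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from riboshift import io as rio
from riboshift.bisulfite import queried_cytosines
from riboshift.enrichment import write_gmt
from riboshift.pipeline import stage_seed
from riboshift.simulate import (
    BsSimConfig,
    CloneSimConfig,
    TESimConfig,
    simulate_bsrna_pileup,
    simulate_clones,
    simulate_gene_sets,
    simulate_te_experiment,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--outdir", type=Path, default=Path("results/data"))
args = parser.parse_args()
out = args.outdir
out.mkdir(parents=True, exist_ok=True)

te_cfg = TESimConfig(seed=stage_seed(args.seed, "te_sim"))
rna, ribo, truth = simulate_te_experiment(te_cfg)
rio.write_counts_tsv(rna, out / "rna_counts.tsv", out / "lengths.tsv")
rio.write_counts_tsv(ribo, out / "ribo_counts.tsv")
rio.write_design_tsv({"rna": rna, "ribo": ribo}, out / "design.tsv")
rio.write_table(truth, out / "truth_te.tsv")
print(f"counts: {te_cfg.n_transcripts} transcripts x "
      f"{rna.n_libraries} libraries per assay; "
      f"{(truth['planted_class'] == 'rna_de').sum()} planted RNA-DE, "
      f"{(truth['planted_class'] == 'te_up').sum()} planted enhanced-TE")

bs_cfg = BsSimConfig(seed=stage_seed(args.seed, "bs_sim"))
pileup = simulate_bsrna_pileup(bs_cfg)
rio.write_pileup_tsv(pileup, out / "pileup.tsv")
print(f"bisulfite pileup: {bs_cfg.n_sites} sites, planted site "
      f"{bs_cfg.planted_site_index} at "
      f"{bs_cfg.planted_methylation_by_condition} (EV, NSUN5)")

# clone sets for an NSUN5-expressing sample (target cytosine methylated)
# and a silenced sample (target unmethylated)
rng = np.random.default_rng(stage_seed(args.seed, "clone_sim"))
amplicon = "".join(rng.choice(list("ACGT"), 120))
positions = queried_cytosines(amplicon, "all_c")
target = positions[len(positions) // 2]
for label, target_m in (("expressing", 0.95), ("silenced", 0.05)):
    profile = np.full(len(positions), 0.03)
    profile[positions.index(target)] = target_m
    records, clone_truth = simulate_clones(CloneSimConfig(
        amplicon, tuple(profile), n_clones=8,
        seed=stage_seed(args.seed, "clone_sim") + (0 if label == "expressing" else 1)))
    rio.write_fasta(records, out / f"clones_{label}.fasta")
    rio.write_table(clone_truth, out / f"truth_clones_{label}.tsv")
rio.write_fasta([SeqRecord(Seq(amplicon), id="amplicon", description="")],
                out / "amplicon.fasta")
print(f"clones: 8 per sample, target cytosine at amplicon position {target}")

sets = simulate_gene_sets(truth, n_null_sets=20, set_size=50,
                          planted_set_fraction=0.8,
                          seed=stage_seed(args.seed, "gene_sets"))
write_gmt(sets, out / "gene_sets.gmt")
print(f"gene sets: {len(sets)} (1 planted program + 20 null)")
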