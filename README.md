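# riboshift

Analysis of translational reprogramming and rRNA cytosine methylation in a
two-condition perturbation design, motivated by the loss of the
5-methylcytosine RNA methyltransferase NSUN5 in glioma: cells silencing
NSUN5 lose methylation of a single 28S rRNA cytosine (C3782), globally
restrain protein synthesis, and yet translate a specific set of
stress-adaptation mRNAs more efficiently.  `riboshift` implements the
computational core needed to detect that program from sequencing data:

* **Differential RNA abundance and ribosome occupancy** from paired
  RNA-seq/Ribo-seq count matrices, with a per-transcript negative-binomial
  GLM: counts `y_gj ~ NB(s_j·m_gc, α_g)` with median-of-ratios size factors
  `s_j`, method-of-moments dispersions `α_g` shrunk toward a mean–dispersion
  trend, and Wald tests on the condition coefficient.
* **The enhanced-TE classification**: a transcript shows enhanced
  translational efficiency when its RNA abundance is unchanged
  (|log2FC| ≤ 2) while its ribosome occupancy is up (p < 0.01 and
  log2FC > 0.5).  RPKM and TE = Ribo-RPKM / RNA-RPKM matrices are also
  provided.
* **A GLM confirmation**: the NB interaction model
  `condition + assay + condition:assay` on stacked RNA/Ribo counts, whose
  interaction coefficient is the log2 change in translational efficiency.
* **Bisulfite methylation analysis**: per-cytosine methylation levels from
  bsRNA-seq pileups, conversion-efficiency correction
  `m = (observed − (1−e))/e`, calling of sites exceeding 90% methylation,
  and differential site methylation by an empirical-Bayes moderated t-test
  (limma-style variance shrinkage, prior fitted by log-variance moment
  matching with trigamma inversion).
* **Amplicon clone analysis**: per-clone × per-cytosine methylation calls
  from Sanger-sequenced bisulfite clones, with text lollipop renderings.
* **Gene-set over-representation** of the enhanced-TE program by the
  upper-tail hypergeometric test with BH FDR.
* **A synthetic-data generator** reproducing the statistical structure of
  the design (planted transcriptional changes, a planted enhanced-TE
  program, a planted high-methylation site) with ground-truth tables, so
  every stage is testable end to end.

## Worked example

The `analysis/` directory is a numbered narrative over the library
(`src/riboshift/`).  Step 01 simulates the study conditions (2000
transcripts, 3 replicates per condition, 2% planted transcriptional
changes, a 5% planted enhanced-TE program at +1 log2, dispersion 0.1, and a
1000-site bisulfite pileup with one planted site at 0.95 vs 0.05):

```bash
python analysis/01_simulate_data.py --seed 0
python analysis/02_te_analysis.py
python analysis/03_bsrna_screen.py
python analysis/04_clone_bisulfite.py
python analysis/05_enrichment.py
```

Step 02 prints:

```
RNA abundance changed (|log2FC| > 2.0): 40 / 2000 (2.0%)
occupancy up (p < 0.01, log2FC > 0.5): 72
enhanced-TE transcripts: 51; 45 of 100 planted recovered, 6 outside the planted program
GLM interaction confirmation: mean interaction coefficient over the planted
program 0.892 (planted value 1.0); ...
```

i.e. the classifier recovers the planted program at high specificity, and
the interaction coefficient averages close to the planted +1 log2 shift
(per-transcript significance is power-limited at 3 replicates — see
`docs/methods.md`).  Step 03 prints:

```
conversion efficiency from 100 control sites: 0.9708
sites over 90% corrected methylation in the NSUN5 condition: [501] (levels [0.946])
moderated t: top differential site 501 (EV 0.010 -> NSUN5 0.948, p = 7.72e-34, ...)
```

recovering exactly the planted high-methylation site, and step 05 reports
the planted gene set as the only over-represented one
(`k=20/50, fold=15.69, FDR=1.24e-19`).

The same stages are available as a pipeline with a single YAML config and
one global seed:

```bash
riboshift run --outdir results/demo --seed 0     # bundled demo config
riboshift te --rna rna.tsv --ribo ribo.tsv --lengths len.tsv --design design.tsv --outdir out/
```

Subcommands: `simulate`, `te`, `bsrna`, `clones`, `enrich`, `run`.

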