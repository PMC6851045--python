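"""Synthetic-data generators with ground truth.

Emulates the statistical structure of a two-condition glioma perturbation
experiment (empty-vector vs NSUN5-restored) measured by paired RNA-seq and
Ribo-seq, by transcriptome-wide bisulfite RNA sequencing, and by amplicon
bisulfite clone sequencing:

* replicated negative-binomial count matrices with a small transcriptionally
  differential fraction and a larger planted program of transcripts whose
  ribosome occupancy shifts with no RNA change (enhanced TE);
* per-cytosine bisulfite pileups with one planted high-methylation site
  (the C3782 analogue) on a low-methylation background with imperfect
  bisulfite conversion;
* single-molecule clone sequences of a bisulfite-converted amplicon.

Every generator is deterministic given its config seed and returns a ground
truth table for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bisulfite import queried_cytosines
from .te import CountExperiment

__all__ = [
    "TESimConfig",
    "BsSimConfig",
    "CloneSimConfig",
    "simulate_te_experiment",
    "simulate_bsrna_pileup",
    "simulate_clones",
    "simulate_gene_sets",
]


@dataclass(frozen=True)
class TESimConfig:
    """Parameters of the paired RNA-seq/Ribo-seq count simulation.

    Defaults emulate the benchmark design: ~2% of transcripts
    transcriptionally differential (split between up and down), a larger 5%
    planted program with a +1 log2 shift in ribosome occupancy only, three
    replicates per condition, and a shared NB dispersion of 0.1.  Effects are
    applied to the second condition (the perturbed arm).
    """

    n_transcripts: int = 2000
    n_reps_per_condition: int = 3
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    length_range_bp: tuple = (300, 10_000)
    dispersion: float = 0.1
    lib_size_range: tuple = (800_000, 1_200_000)
    frac_rna_de: float = 0.02
    rna_de_log2fc: float = 3.0
    frac_te_up: float = 0.05
    te_log2fc: float = 1.0
    condition_labels: tuple = ("EV", "NSUN5")
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_rna_de", "frac_te_up"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_rna_de + self.frac_te_up > 1:
            raise ValueError("planted fractions must be disjoint: "
                             "frac_rna_de + frac_te_up <= 1")
        if np.any(np.asarray(self.dispersion) <= 0):
            raise ValueError("dispersion must be positive")
        if self.n_transcripts < 1 or self.n_reps_per_condition < 1:
            raise ValueError("n_transcripts and n_reps_per_condition must be positive")
        if self.baseline_log2_sd <= 0:
            raise ValueError("baseline_log2_sd must be positive")


def _nb_draw(rng, mean, alpha):
    """NB(mean, var = mean + alpha mean^2) via numpy's (n, p) parametrization."""
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(np.maximum(n, 1e-12), np.clip(p, 1e-12, 1.0))


def simulate_te_experiment(config: TESimConfig):
    """Simulate paired RNA-seq and Ribo-seq count experiments.

    Planted-set sizes are floor(fraction * n_transcripts); membership is the
    first blocks of a seeded permutation, so the truth is reproducible.
    Transcriptionally differential transcripts shift both assays by
    ``rna_de_log2fc`` with a random sign; enhanced-TE transcripts shift the
    Ribo assay only, by ``te_log2fc``.  Counts scale linearly with transcript
    length (log-uniform lengths), so RPKM normalization is consequential.

    Returns ``(rna, ribo, truth)`` where ``truth`` has one row per
    transcript: transcript_id, true_rna_log2fc, true_te_log2fc,
    planted_class in {null, rna_de, te_up}.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_transcripts
    n = config.n_reps_per_condition

    lengths = np.exp(rng.uniform(np.log(config.length_range_bp[0]),
                                 np.log(config.length_range_bp[1]), g))
    lengths = np.round(lengths).astype(int)
    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, g)
    baseline = baseline * lengths / 1e3

    perm = rng.permutation(g)
    n_rna = int(np.floor(config.frac_rna_de * g))
    n_te = int(np.floor(config.frac_te_up * g))
    rna_idx = perm[:n_rna]
    te_idx = perm[n_rna:n_rna + n_te]

    true_rna = np.zeros(g)
    true_rna[rna_idx] = rng.choice([-1.0, 1.0], size=n_rna) * config.rna_de_log2fc
    true_te = np.zeros(g)
    true_te[te_idx] = config.te_log2fc

    planted = np.array(["null"] * g, dtype=object)
    planted[rna_idx] = "rna_de"
    planted[te_idx] = "te_up"

    alpha = np.broadcast_to(np.asarray(config.dispersion, dtype=float), (g,))
    cond_a, cond_b = config.condition_labels
    condition = [cond_a] * n + [cond_b] * n
    is_b = np.array([0.0] * n + [1.0] * n)

    experiments = {}
    for assay in ("rna", "ribo"):
        lib_sizes = rng.integers(config.lib_size_range[0],
                                 config.lib_size_range[1] + 1, 2 * n)
        sf = lib_sizes / np.exp(np.mean(np.log(lib_sizes)))
        lfc = true_rna + (true_te if assay == "ribo" else 0.0)
        mean = (baseline[:, None] * sf[None, :]
                * 2.0 ** (lfc[:, None] * is_b[None, :]))
        counts = _nb_draw(rng, mean, alpha[:, None])
        experiments[assay] = CountExperiment(
            transcript_ids=np.array([f"T{i:05d}" for i in range(g)], dtype=object),
            lengths_bp=lengths,
            counts=counts,
            library_labels=[f"{assay}_{c}_{r + 1}" for c in config.condition_labels
                            for r in range(n)],
            condition_of_library=list(condition),
        )

    truth = pd.DataFrame({
        "transcript_id": [f"T{i:05d}" for i in range(g)],
        "true_rna_log2fc": true_rna,
        "true_te_log2fc": true_te,
        "planted_class": planted,
    })
    return experiments["rna"], experiments["ribo"], truth


@dataclass(frozen=True)
class BsSimConfig:
    """Parameters of the bisulfite RNA-seq pileup simulation.

    One planted site carries condition-specific methylation (low in the
    deficient arm, high after restoration, emulating the C3782 screen); all
    other sites sit at a common low background.  The observed unconverted
    count is Binomial(coverage, m + (1-m) * conversion_failure_rate):
    conversion failure creates false methylated signal only.
    """

    n_sites: int = 1000
    n_reps_per_condition: int = 3
    coverage_mean: float = 100.0
    background_methylation: float = 0.02
    planted_site_index: int = 501
    planted_methylation_by_condition: tuple = (0.05, 0.95)
    conversion_failure_rate: float = 0.01
    condition_labels: tuple = ("EV", "NSUN5")
    reference_name: str = "28S"
    seed: int = 0

    def __post_init__(self):
        for name in ("background_methylation", "conversion_failure_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for m in self.planted_methylation_by_condition:
            if not 0 <= m <= 1:
                raise ValueError("planted methylation proportions must lie in [0, 1]")
        if not 1 <= self.planted_site_index <= self.n_sites:
            raise ValueError("planted_site_index must lie in [1, n_sites]")
        if self.n_sites < 1 or self.n_reps_per_condition < 1 or self.coverage_mean <= 0:
            raise ValueError("n_sites, n_reps_per_condition, coverage_mean must be positive")


def simulate_bsrna_pileup(config: BsSimConfig) -> pd.DataFrame:
    """Simulate a per-cytosine bisulfite pileup table.

    Returns one row per site x library with columns reference, site (1-based),
    library, condition, coverage (Poisson around ``coverage_mean``) and
    unconverted count.
    """
    rng = np.random.default_rng(config.seed)
    sites = np.arange(1, config.n_sites + 1)
    rows = []
    for cond, planted_m in zip(config.condition_labels,
                               config.planted_methylation_by_condition):
        m = np.full(config.n_sites, config.background_methylation)
        m[config.planted_site_index - 1] = planted_m
        p_obs = m + (1.0 - m) * config.conversion_failure_rate
        for rep in range(config.n_reps_per_condition):
            coverage = rng.poisson(config.coverage_mean, config.n_sites)
            unconverted = rng.binomial(coverage, p_obs)
            rows.append(pd.DataFrame({
                "reference": config.reference_name,
                "site": sites,
                "library": f"{cond}_{rep + 1}",
                "condition": cond,
                "coverage": coverage,
                "unconverted": unconverted,
            }))
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class CloneSimConfig:
    """Parameters of the amplicon bisulfite clone simulation.

    Each clone is an independent molecule: every queried cytosine is
    methylated (retains C) with its own probability, unmethylated cytosines
    and non-queried cytosines read T, and an optional per-base sequencing
    error substitutes a random other base.
    """

    amplicon_sequence: str
    per_site_methylation: tuple
    cytosine_mode: str = "all_c"
    n_clones: int = 8
    sequencing_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.amplicon_sequence:
            raise ValueError("amplicon sequence must be non-empty")
        positions = queried_cytosines(self.amplicon_sequence, self.cytosine_mode)
        if not positions:
            raise ValueError("amplicon contains no queried cytosine under this mode")
        if len(self.per_site_methylation) != len(positions):
            raise ValueError(
                f"per_site_methylation has {len(self.per_site_methylation)} entries "
                f"but the amplicon has {len(positions)} queried cytosines")
        for m in self.per_site_methylation:
            if not 0 <= m <= 1:
                raise ValueError("methylation probabilities must lie in [0, 1]")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if not 0 <= self.sequencing_error_rate <= 1:
            raise ValueError("sequencing_error_rate must lie in [0, 1]")


def simulate_clones(config: CloneSimConfig):
    """Simulate bisulfite-converted clone sequences.

    Returns ``(records, truth)``: a list of Bio.SeqRecord of amplicon length
    and a truth table (position, true_frequency) of the per-site Bernoulli
    means.
    """
    rng = np.random.default_rng(config.seed)
    ref = config.amplicon_sequence.upper().replace("U", "T")
    positions = queried_cytosines(ref, config.cytosine_mode)
    m = np.asarray(config.per_site_methylation, dtype=float)
    bases = np.array(list("ACGT"))

    records = []
    for k in range(config.n_clones):
        seq = list(ref)
        # non-queried cytosines always convert
        for i, ch in enumerate(seq):
            if ch == "C" and (i + 1) not in positions:
                seq[i] = "T"
        methylated = rng.random(len(positions)) < m
        for pos, is_m in zip(positions, methylated):
            seq[pos - 1] = "C" if is_m else "T"
        if config.sequencing_error_rate > 0:
            errs = np.flatnonzero(rng.random(len(seq)) < config.sequencing_error_rate)
            for i in errs:
                seq[i] = rng.choice(bases[bases != seq[i]])
        records.append(SeqRecord(Seq("".join(seq)), id=f"clone_{k + 1}", description=""))

    truth = pd.DataFrame({"position": positions, "true_frequency": m})
    return records, truth


def simulate_gene_sets(truth: pd.DataFrame, n_null_sets: int = 20,
                       set_size: int = 50, planted_set_fraction: float = 0.8,
                       seed: int = 0) -> dict:
    """Gene sets for over-representation testing against a simulated truth
    table: one set enriched in the planted enhanced-TE program (a fraction of
    its members drawn from te_up transcripts) plus random null sets."""
    rng = np.random.default_rng(seed)
    universe = truth["transcript_id"].to_numpy()
    te_up = truth.loc[truth["planted_class"] == "te_up", "transcript_id"].to_numpy()
    other = truth.loc[truth["planted_class"] != "te_up", "transcript_id"].to_numpy()

    n_planted = min(int(np.floor(planted_set_fraction * set_size)), len(te_up))
    members = list(rng.choice(te_up, n_planted, replace=False))
    members += list(rng.choice(other, set_size - n_planted, replace=False))
    sets = {"PLANTED_TE_PROGRAM": set(members)}
    for k in range(n_null_sets):
        sets[f"NULL_SET_{k + 1:02d}"] = set(rng.choice(universe, set_size, replace=False))
    return sets
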