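"""Plain-text table and sequence I/O.

Counts travel as TSV with transcripts as rows and libraries as columns, a
companion length TSV, and a design TSV (library, assay, condition).  Pileups
are long-format TSV (reference, site, library, condition, coverage,
unconverted; sites 1-based).  Sequences use FASTA via Biopython.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .te import CountExperiment

FLOAT_FORMAT = "%.10g"


def write_counts_tsv(experiment: CountExperiment, counts_path, lengths_path=None) -> None:
    df = pd.DataFrame(experiment.counts, index=experiment.transcript_ids,
                      columns=experiment.library_labels)
    df.index.name = "transcript_id"
    df.to_csv(counts_path, sep="\t")
    if lengths_path is not None:
        pd.DataFrame({"transcript_id": experiment.transcript_ids,
                      "length_bp": experiment.lengths_bp}).to_csv(
            lengths_path, sep="\t", index=False)


def write_design_tsv(experiments: dict, path) -> None:
    """``experiments`` maps assay name -> CountExperiment."""
    rows = []
    for assay, exp in experiments.items():
        for lib, cond in zip(exp.library_labels, exp.condition_of_library):
            rows.append({"library": lib, "assay": assay, "condition": cond})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_count_experiment(counts_path, lengths_path, design_path,
                          assay: str) -> CountExperiment:
    counts = pd.read_csv(counts_path, sep="\t", index_col="transcript_id")
    lengths = pd.read_csv(lengths_path, sep="\t").set_index("transcript_id")
    design = pd.read_csv(design_path, sep="\t")
    design = design[design["assay"] == assay]
    libs = [l for l in counts.columns if l in set(design["library"])]
    cond_of = design.set_index("library")["condition"]
    return CountExperiment(
        transcript_ids=counts.index.to_numpy(dtype=object),
        lengths_bp=lengths.loc[counts.index, "length_bp"].to_numpy(),
        counts=counts[libs].to_numpy(),
        library_labels=libs,
        condition_of_library=[cond_of[l] for l in libs],
    )


def write_pileup_tsv(pileup: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# site coordinates are 1-based on the named reference\n")
        pileup.to_csv(fh, sep="\t", index=False)


def read_pileup_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list:
    return list(SeqIO.parse(str(path), "fasta"))


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
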