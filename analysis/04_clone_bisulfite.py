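#!/usr/bin/env python
"""Amplicon bisulfite clone analysis of the two simulated samples.

Scores each sample's eight cloned molecules against the amplicon reference
(C = methylated, T = unmethylated), prints the per-clone lollipop rendering
and per-position frequencies, and writes tables under results/clones/.
"""

import argparse
from pathlib import Path

from riboshift import io as rio
from riboshift.bisulfite import clone_analysis, render_lollipop

parser = argparse.ArgumentParser()
parser.add_argument("--datadir", type=Path, default=Path("results/data"))
parser.add_argument("--outdir", type=Path, default=Path("results/clones"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

amplicon = str(rio.read_fasta(args.datadir / "amplicon.fasta")[0].seq)
for label in ("expressing", "silenced"):
    clones = rio.read_fasta(args.datadir / f"clones_{label}.fasta")
    matrix = clone_analysis(clones, amplicon, mode="all_c")
    text = render_lollipop(matrix)
    (args.outdir / f"lollipop_{label}.txt").write_text(text + "\n")
    freq = matrix.per_position_frequency
    rio.write_table(freq.rename("frequency").rename_axis("position").reset_index(),
                    args.outdir / f"frequencies_{label}.tsv")
    print(f"== {label} sample ({len(matrix.clone_ids)} clones, "
          f"{len(matrix.positions)} queried cytosines) ==")
    print(text)
    top = freq.idxmax()
    print(f"most methylated position: {top} at {freq.loc[top]:.2f}\n")
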