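#!/usr/bin/env python
"""Quantify glycopeptides: proteome scaling, >=5-PSM filter, per-channel
medians, the four between-group ratios, and normalized glycosylation.

Reads results/glyco_psms.tsv and results/proteome_psms.tsv; writes
results/quant.tsv (glycopeptides) and results/proteins.tsv.
"""

import argparse
import pathlib

import pandas as pd

from glycosite import quant


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", default="results")
    args = ap.parse_args()

    res = pathlib.Path(args.results)
    glyco_psms = pd.read_csv(res / "glyco_psms.tsv", sep="\t",
                             dtype={c: float for c in quant.STUDY_CHANNELS})
    proteome_psms = pd.read_csv(res / "proteome_psms.tsv", sep="\t")

    factors = quant.proteome_scaling_factors(proteome_psms)
    print("proteome scaling factors:",
          {c: round(factors[c], 3) for c in quant.STUDY_CHANNELS})

    protein_ratios = quant.protein_quant(quant.apply_scaling(proteome_psms, factors))
    qtable = quant.aggregate_glycopeptides(quant.apply_scaling(glyco_psms, factors))
    dropped = glyco_psms.groupby(["peptide", "site"]).size().lt(quant.MIN_PSM).sum()
    qtable = quant.add_normalized_glycosylation(qtable, protein_ratios)

    qtable.to_csv(res / "quant.tsv", sep="\t", index=False)
    protein_ratios.to_csv(res / "proteins.tsv", sep="\t", index=False)
    print(f"{len(qtable)} glycopeptides quantified (>= {quant.MIN_PSM} PSMs; "
          f"{dropped} keys dropped), {len(protein_ratios)} proteins")
    up = (qtable.ICC_ICCP >= 2).sum()
    print(f"{up} glycopeptides with >= twofold ICC/ICC-paracancer ratio")


if __name__ == "__main__":
    main()
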