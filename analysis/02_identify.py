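#!/usr/bin/env python
"""Identify intact glycopeptides and proteome PSMs from the simulated runs.

Reads results/study/, runs the paired-scan search with dual-level 1% FDR,
and writes the accepted glycopeptide PSM table and the proteome PSM table
under results/.
"""

import argparse
import glob
import pathlib

from glycosite import identify, quant, seqdb, spectra


def find_run(stem, directory):
    hits = sorted(glob.glob(str(directory / f"{stem}.*")))
    if not hits:
        raise SystemExit(f"no {stem} run found in {directory}; run 01_simulate.py first")
    return hits[0]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    study_dir = pathlib.Path(args.study)
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    fasta = seqdb.read_fasta(study_dir / "proteome.fasta")
    space = seqdb.build_search_space(fasta)
    print(f"search space: {len(space.glyco)} sequon-bearing candidates "
          f"(targets+decoys), {len(space.proteome)} total")

    index = identify.GlycanIndex()
    glyco_run = spectra.read_run(find_run("glyco_run", study_dir))
    pairs = spectra.pair_spectra(glyco_run)
    psms = identify.search_run(pairs, space, index)
    accepted, pep_fdr, gly_fdr = identify.accept_psms(psms)
    print(f"{len(pairs)} spectrum pairs -> {len(psms)} PSMs -> "
          f"{len(accepted)} accepted at 1% dual-level FDR "
          f"(peptide threshold {pep_fdr.threshold:.2f}, "
          f"glycan threshold {gly_fdr.threshold:.3f})")

    quant.glyco_psm_table(accepted).to_csv(out / "glyco_psms.tsv", sep="\t", index=False)

    proteome_run = spectra.read_run(find_run("proteome_run", study_dir))
    proteome_psms = identify.identify_proteome(proteome_run, space)
    quant.proteome_psm_table(proteome_psms).to_csv(
        out / "proteome_psms.tsv", sep="\t", index=False
    )
    print(f"proteome: {len(proteome_run)} MS2 scans -> {len(proteome_psms)} PSMs")


if __name__ == "__main__":
    main()
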