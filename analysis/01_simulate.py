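#!/usr/bin/env python
"""Generate the synthetic four-channel TMT glycoproteomics study.

Writes the protein FASTA, the proteome and glycoproteome MS2 runs (internal
JSON format; pass --mzml for mzML) and the ground-truth manifest under
results/study/.
"""

import argparse
import pathlib

from glycosite import seqdb, spectra, synth


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/study")
    ap.add_argument("--n-glycopeptides", type=int, default=200)
    ap.add_argument("--mzml", action="store_true", help="write mzML instead of JSON")
    ap.add_argument("--no-noise", action="store_true")
    args = ap.parse_args()

    design = synth.StudyDesign(n_glycopeptides=args.n_glycopeptides, noise=not args.no_noise)
    study = synth.generate_study(design, seed=args.seed)

    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    ext = "mzML" if args.mzml else "json"
    seqdb.write_fasta(study.fasta, out / "proteome.fasta")
    spectra.write_run(study.proteome_run, out / f"proteome_run.{ext}")
    spectra.write_run(study.glyco_run, out / f"glyco_run.{ext}")
    manifest = study.manifest
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    study.protein_truth.to_csv(out / "protein_truth.tsv", sep="\t", index=False)

    n_lac = int((manifest["class"] == "lacdinac").sum())
    print(f"wrote {out}/: {len(study.fasta)} proteins, "
          f"{len(study.glyco_run)} glyco MS2 scans "
          f"({len(manifest)} glycopeptides, {n_lac} LacdiNAc-class), "
          f"{len(study.proteome_run)} proteome MS2 scans")
    print(f"PSM replication: min {manifest.psm_count.min()}, "
          f"median {int(manifest.psm_count.median())}")


if __name__ == "__main__":
    main()
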