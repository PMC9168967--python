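# glycosite

Branch-resolved, site-specific N-glycoproteomics from dual-energy HCD
MS/MS, with TMT quantification and differential glycosylation analysis.

## The problem

Intrahepatic cholangiocarcinoma (ICC) and hepatocellular carcinoma (HCC)
are the two major primary liver cancers and are hard to tell apart, yet
they demand different treatment. Protein N-glycosylation changes with
tumorigenesis, and *structural* features of site-specific glycans — core
fucosylation, bisecting GlcNAc, and in particular the uncommon LacdiNAc
(GalNAcβ1-4GlcNAc) antenna motif — carry tumor-type information that a
composition-only readout misses: a LacdiNAc-bearing glycan has the same
monosaccharide composition as isomers built from LacNAc (Galβ1-4GlcNAc)
branches plus a bisecting or truncated GlcNAc.

This package implements the quantitative analysis for that problem as a
tested, reusable pipeline:

- **Glycan model** (`glycosite.glyco`): glycans as one of four core motifs
  (HexNAc2Hex3, optionally +Fuc and/or +bisecting GlcNAc) plus a multiset
  of antenna motifs from a 12-motif library; canonical text encoding;
  exhaustive structure enumeration per composition; theoretical B (oxonium)
  and Y ions.
- **Search space** (`glycosite.seqdb`): tryptic digestion (≤2 missed
  cleavages), N-X-S/T sequon detection (X ≠ P), TMT/carbamidomethyl
  masses, pseudo-reverse decoys.
- **Spectra** (`glycosite.spectra`): mzML and an internal JSON run format,
  low/high collision-energy scan pairing, the two-of-top-ten oxonium
  prescreen, TMT reporter extraction.
- **Identification** (`glycosite.identify`): peptide from the high-energy
  scan (b/y ions, 20 ppm), glycan from the low-energy scan (Y-ion core
  ladder + B-ion branch evidence), assembly under 10 ppm precursor-mass
  closure, and 1% FDR independently at the peptide and glycan levels. A
  LacdiNAc branch is accepted only when a HexNAc2-containing B ion
  (*m/z* 407.17, 698.26 or its fucosyl analogue) is matched.
- **Quantification** (`glycosite.quant`): proteome-derived per-channel
  scaling factors, ≥5-PSM filter, per-channel medians, the four
  between-group ratios (ICC/ICCP, HCC/HCCP, ICC/HCC, ICCP/HCCP), and
  normalized glycosylation (glycopeptide ratio ÷ protein ratio).
- **Differential analysis** (`glycosite.diff`): twofold-cutoff
  categorization into common / tumor-specific / protein-level-only /
  opposite / unchanged classes, structural feature frequencies, PCA and
  hierarchical-clustering exports.
- **Synthetic data** (`glycosite.synth`): a ground-truthed generator for
  four-channel TMT studies (129C = HCC paracancer, 130C = ICC paracancer,
  130N = HCC tumor, 131 = ICC tumor) with a LacdiNAc class elevated two-
  to five-fold in the ICC channel, so every stage is testable by recovery
  against a manifest.

## Worked example

The numbered scripts under `analysis/` run the full study:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_identify.py
python analysis/03_quantify.py
python analysis/04_differential.py
```

which prints (seed 1):

```
wrote results/study/: 127 proteins, 2758 glyco MS2 scans (200 glycopeptides, 26 LacdiNAc-class), 381 proteome MS2 scans
1379 spectrum pairs -> 1379 PSMs -> 1379 accepted at 1% dual-level FDR (peptide threshold 33.60, glycan threshold 0.844)
proteome scaling factors: {'129C': 1.012, '130C': 1.019, '130N': 1.003, '131': 0.967}
200 glycopeptides quantified (>= 5 PSMs; 0 keys dropped), 127 proteins
64 glycopeptides with >= twofold ICC/ICC-paracancer ratio
category counts: {'unchanged': 108, 'icc_specific_up': 39, 'protein_level_only': 21, 'common_up': 16, 'common_down': 7, 'hcc_specific_up': 7, 'hcc_specific_down': 1, 'opposite': 1}
LacdiNAc share of ICC-specific-up glycopeptides: 61.5%
PCA explained variance: [0.703, 0.289, 0.009, 0.0]
```

Reading: every simulated spectrum pair was identified, all 200 designed
glycopeptides pass the ≥5-PSM quantification filter, the scaling factors
are near 1 (balanced loading), 39 glycopeptides are specifically elevated
in the ICC tumor channel, and the LacdiNAc-class glycopeptides dominate
that category while never appearing in the HCC-specific one. The ICC
channel separates from the other three channels in the PCA export.

As a small API example, the diagnostic oxonium ions that identify a
sialylated LacdiNAc branch:

```python
>>> from glycosite import glyco
>>> [round(glyco.oxonium_mz(glyco.parse_composition(t)), 2)
...  for t in ("N2", "N1S1", "N2S1")]
[407.17, 495.18, 698.26]
>>> s = glyco.parse_structure("CF|LacNAc,LacdiNAc-S")  # N5H4F1S1
>>> glyco.classify_features(s).has_lacdinac
True
```

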