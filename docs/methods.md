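# Methods

## Glycan model

An N-glycan is a rooted tree assembled from a **core motif** and a multiset
of **branch (antenna) motifs**.

Cores (composition in the N/H/F/S convention, N = HexNAc, H = Hex,
F = Fuc, S = NeuAc):

| kind | composition | note |
|---|---|---|
| plain | N2H3 | trimannosyl-chitobiose core |
| core_fucosylated | N2H3F1 | Fuc on the innermost GlcNAc |
| bisecting | N3H3 | bisecting GlcNAc on the β-mannose |
| fucosylated_bisecting | N3H3F1 | both |

Branches are linear residue chains ordered root→terminus with optional
terminal decorations (NeuAc capping, antenna Fuc). The default library
(`src/glycosite/branch_library.yaml`, editable without code change) holds
12 motifs in four families: GlcNAc (±Fuc), LacNAc = HexNAc–Hex
(±NeuAc/±Fuc), LacdiNAc = HexNAc–HexNAc (±NeuAc or ±Fuc), and
mannose-family Hex motifs (Man, Man–Man, terminal Gal). Linkage
annotations (α2-6, β1-4 …) are carried as documentation only; HCD MS/MS
cannot resolve them and they are never used in matching.

Caps: ≤4 non-mannose antennae, ≤6 branches total, and Fuc/NeuAc counts
effectively ≤3 through the library. These bound the enumeration to the
ranges seen in tissue glycoproteomics.

Monoisotopic residue masses (Da): Hex 162.052824, HexNAc 203.079373,
Fuc 146.057909, NeuAc 291.095417; proton 1.007276; water 18.010565.
With these, the protonated HexNAc2, HexNAc1NeuAc1 and HexNAc2NeuAc1
oxonium ions compute to 407.17, 495.18 and 698.26 at two decimals.

**Canonical encoding.** `CODE|motif,motif,...` with core codes C / CF /
CB / CFB and branch names sorted lexicographically, so the encoding is
invariant under branch permutation and usable as a set key.

**Fragment chemistry.** B (oxonium) ions retain the non-reducing end:
for every branch, all chain suffixes crossed with decoration subsets, plus
the single-residue oxonium of every residue type present. Y ions retain
the peptide plus a connected, terminally pruned glycan remnant: the core
ladder (peptide, +N1, +N2, +N2H1…N2H3, Fuc-shifted variants when
core-fucosylated, +bisecting GlcNAc states) and the full core combined
with every per-branch pruning option (absent, chain prefixes, full chain
± decorations).

## Identification

Input is a pair of MS2 scans per precursor: low collision energy (glycan
B/Y ions) and high collision energy (peptide b/y ions, TMT reporters).
Pairing is greedy nearest-in-retention-time with equal charge and 10 ppm
precursor agreement. Pairs must show ≥2 oxonium ions among the 10 most
intense low-energy peaks (20 ppm) before search.

Peptide candidates come from tryptic digestion (cleave after K/R, not
before P, ≤2 missed cleavages, length 6–45, mass 600–6000 Da) of the
FASTA, restricted to sequon-bearing peptides, and are admitted for a
spectrum when precursor − peptide mass leaves a remainder matching some
enumerable glycan composition within 10 ppm. Modifications:
carbamidomethyl-C (+57.021464) and TMT (+229.162932, N-terminus and — by
default, switchable — every lysine) static; oxidation/acetylation deltas
are supported but not used by the generator.

**Scoring (surrogate).** The original software's internal formulas are not
public, so this package defines and documents its own:

- *Peptide score* = −log10 of the hypergeometric tail probability of
  observing k matched b/y ions given the peak count and a fixed bin budget
  (2000). Ties break by smaller precursor error, then sequence.
- *Glycan score* = 0.5 × (matched fraction of theoretical B+Y ions)
  + 0.5 × (fraction of low-energy fragment intensity explained)
  + 0.1 × (fraction of branches whose intact B ion is matched).
  All terms are monotone: removing a matched peak never raises the score.
  The two complementary terms make the score discriminative in both
  directions — a candidate with extra unmatched theoretical ions loses on
  the first term, a candidate that fails to explain observed fragment
  intensity loses on the second.

**Branch-evidence gates.** A multiset containing a LacdiNAc-family motif
is scored only if a HexNAc2-containing B ion (HexNAc≥2, Hex=0) is matched;
a LacNAc-family motif requires a HexNAc1Hex1-containing B ion or its
sialyl/fucosyl extension. This is what discriminates LacdiNAc from its
composition-isomers.

**Assembly.** For every composition within 10 ppm of the remainder, every
enumerated structure (and its decoy counterpart) is scored against the
low-energy scan; the best-scoring hypothesis wins, with deterministic
tie-breaks (target before decoy, then lexicographic canonical string).
Composition closure |peptide + glycan − precursor| ≤ 10 ppm is enforced on
the result.

**Spectral indistinguishability.** Some assemblies produce identical
theoretical ion sets — e.g. a bisecting core with two LacNAc antennae vs
a plain core with a truncated GlcNAc antenna plus two LacNAc antennae, or
any Man↔terminal-Gal swap. No scorer can separate these from one spectrum;
the engine resolves such ties deterministically, and the core codes are
chosen so the bisecting-core reading wins over the truncated-antenna
reading. `infer_core` therefore only decides the fucosylation axis on its
own (a pep+HexNAc3Hex3 Y ion is equally consistent with a bisecting core
or a GlcNAc stub) and reports bisecting evidence for the assembly stage to
use. The synthetic panel contains only structures that are the canonical
representative of their indistinguishability class.

**FDR.** Two independent target–decoy competitions at 1%:

- *Peptide level*: pseudo-reverse decoys (C-terminal residue fixed). For
  the sequon-restricted glycopeptide space the sequon triplet is also held
  in place, so decoys stay inside the searched space and provide genuine
  competition — plain reversal would destroy nearly every sequon and
  leave the glyco search effectively decoy-free.
- *Glycan level*: decoy structural hypotheses built by shifting every
  branch-derived fragment mass by +17.0027 Da per motif (precursor and
  composition unchanged, so mass closure still holds). This implements
  the decoy-spectra idea with a deterministic, seedable construction.

The threshold at each level is the smallest score with
(#decoys ≥ s)/(#targets ≥ s) ≤ 0.01; accepted identifications are targets
passing both levels. Module-level confidence is surfaced as per-branch /
per-core evidence lists rather than a calibrated probability (the
calibration recipe of the original tool is not public).

## Quantification

Reporter intensities (channels 129C/130C/130N/131 at the published
10-plex reporter masses, ±0.003 m/z window) are scaled by global
per-channel factors computed from the proteome run:
factor(c) = mean(totals)/total(c), so scaled proteome totals are equal.
Glycopeptides need ≥5 PSMs; each channel's abundance is the median over
PSMs (missing reporters are excluded, not zero-imputed); ratios are taken
between group channels (ICC = 131, ICCP = 130C, HCC = 130N, HCCP = 129C).
Protein abundance is the median over that protein's non-glyco PSMs
(median chosen over sum; switchable). Normalized glycosylation divides
each glycopeptide ratio by its protein's matching ratio; glycopeptides on
unquantified proteins pass through flagged `protein-unquantified`.

The design is pooled (one channel per group), so no per-patient variance
exists and none is claimed: "changed" means a twofold ratio, not a test
statistic.

## Categorization

With cutoff c = 2, the decision tree applies in order:

1. ICCP/HCCP outside [1/c, c] → `paracancer_differs` (comparisons between
   tumors are only meaningful when the baselines agree);
2. every tumor/paracancer ratio that is outside the band has its
   normalized-glycosylation ratio inside → `protein_level_only`;
3. both tumor ratios ≥ c → `common_up`; both ≤ 1/c → `common_down`;
4. both outside in opposite directions → `opposite`;
5. exactly one outside → the corresponding `icc_specific_*` /
   `hcc_specific_*` label; with `require_cross_tumor=True` the label
   additionally demands ICC/HCC outside the band (the stricter selection
   used when listing tumor-type-specific glycopeptides; off by default);
6. otherwise `unchanged`.

Labels are exhaustive and mutually exclusive; inverting all four ratios
mirrors every directional label (property-tested).

PCA operates on log2 channel profiles (channels as observations, full SVD,
deterministic up to sign); clustering is agglomerative with Euclidean
distance and average linkage (complete linkage is a common alternative;
average is the package default, switchable).

## Synthetic study design

The generator emulates a four-channel TMT liver-tissue study:

- 200 glycopeptides on ~67 glycoproteins (3 per protein) plus 60 filler
  proteins; peptides are 9–14 residues with exactly one planted sequon;
  a known LacdiNAc-bearing reference glycopeptide is planted for
  regression tests.
- Base abundance log-normal (ln-mean 13, ln-sd 1 — intensities around
  4×10⁵ with a realistic dynamic range). Class mixture: 13% LacdiNAc
  class (96% of which are elevated 2–5× in the ICC channel, none in HCC),
  8% common-up, 4% common-down, 8% ICC-up, 4% HCC-up, 6% pure
  protein-expression shifts (2–4×, both directions), remainder unchanged.
  Paracancer channels differ only by a log2-σ = 0.15 jitter.
- PSM replication 5 + Poisson(2) per glycopeptide, so every designed
  glycopeptide is quantifiable under the ≥5-PSM filter.
- Noise model: 2 ppm precursor and 3 ppm fragment m/z jitter,
  multiplicative log-normal reporter noise (σ = 0.1), Poisson(30) uniform
  noise peaks per low-energy scan, and the HexNAc secondary fragment
  series (126.055/138.055/168.066/186.076) that accompanies every real
  N-glycan HCD spectrum.
- The proteome run uses a moderate abundance spread (ln-σ 0.5) and
  balanced protein shifts so that bulk channel totals are dominated by the
  unchanged majority — the property that makes total-intensity
  normalization valid in deep (thousands-of-proteins) proteome data, here
  reproduced at a ~130-protein scale chosen to keep the full pipeline
  runnable in seconds.
- Optional decoy spikes: a fraction of spectrum pairs generated from
  shuffled peptides absent from the database, labelled in the manifest so
  the empirical FDR of the accepted set is measurable.

Everything is driven by one `numpy` Generator seeded from the study seed;
outputs are byte-identical across runs.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: chromatographic elution and co-isolation
interference, isotope envelopes, missing fragment ions (every theoretical
ion of the true structure is present, noise aside), variable modifications,
non-tryptic background, and glycans outside the 12-motif library. Recovery
rates on this generator are upper bounds on real-data performance; the
pipeline's contracts (FDR control, gate soundness, ratio arithmetic) are
what the tests establish.

## Numerical choices and degenerate inputs

- Tolerances: 10 ppm precursor, 20 ppm fragment, ±0.003 m/z reporters.
- Matching uses binary search on sorted peak arrays; deterministic
  tie-breaks everywhere (score, then target-before-decoy, then canonical
  string; peptides by score, precursor error, sequence).
- Empty candidate sets, compositions smaller than any core, and spectra
  failing the oxonium screen produce no-match results, not errors; zero
  proteome channel totals, negative composition counts, NaN clustering
  inputs and constant PCA matrices raise.
- Peptides with two sequons are assigned to the first sequon and flagged
  ambiguous (fragment ions cannot localize the site when both sequons lie
  on the same backbone fragments for most ions).
- I and L are distinct characters internally; they are mass-identical, so
  candidate ranking breaks such ties lexicographically.

## Known limitations

- The 12-motif library is a documented reconstruction; real branch
  diversity (polyLacNAc, antennary arrangements beyond linear chains) is
  out of scope.
- Glycosidic linkage and anomericity are never determined.
- The glycan decoy construction is a surrogate; absolute glycan-level FDR
  estimates inherit its assumptions (the empirical-FDR test with spiked
  spectra is the ground-truth check).
- O-glycans, open modification search, and chimeric spectra are out of
  scope.
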