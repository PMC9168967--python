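"""Ground-truthed synthetic proteome + glycoproteome runs.

Emulates the study's acquisition: TMT-labelled tryptic peptides, a
four-channel design (129C = HCC paracancer, 130C = ICC paracancer,
130N = HCC tumor, 131 = ICC tumor), and for every glycopeptide precursor a
pair of HCD MS2 scans — the high-energy scan carrying peptide b/y ions,
Y0/Y1 stubs and the TMT reporter region, the low-energy scan carrying the
glycan B and Y ions.  Every generated quantity is recorded in a ground-truth
manifest so each downstream stage can be tested by recovery.

The default design mirrors the study's statistical structure: LacdiNAc-class
glycopeptides elevated two- to five-fold in the ICC channel (96% of the
class) with no change in HCC, a twofold-change backbone of common and
tumor-specific alterations, paracancer channels within twofold of each
other, >= 5 PSMs per glycopeptide, and multiplicative log-normal reporter
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import glyco, seqdb
from .glyco import PROTON, GlycanStructure, default_library, parse_structure
from .spectra import (
    Ms2Spectrum,
    SpectrumPair,
    STUDY_CHANNELS,
    TMT10_REPORTER_MZ,
)

CHANNEL_GROUP = {"129C": "HCCP", "130C": "ICCP", "130N": "HCC", "131": "ICC"}
GROUP_CHANNEL = {g: c for c, g in CHANNEL_GROUP.items()}

# Curated structure panel: (canonical structure, class tag).  Every entry is
# the deterministic winner of its spectral-indistinguishability class under
# the identification engine's tie-break, so noise-free recovery is exact.
DEFAULT_PANEL: tuple[tuple[str, str], ...] = (
    ("plain|Man2", "other"),  # Man5
    ("plain|Man,Man2", "other"),  # Man6
    ("plain|Man,Man,Man2", "other"),  # Man7
    ("plain|LacNAc,LacNAc", "other"),  # A2G2
    ("plain|LacNAc,LacNAc-S", "other"),
    ("plain|LacNAc-S,LacNAc-S", "other"),
    ("core_fucosylated|LacNAc,LacNAc", "other"),  # N4H5F1, Fig-2F composition
    ("core_fucosylated|LacNAc,LacNAc-S", "other"),
    ("core_fucosylated|LacNAc-S,LacNAc-S", "other"),
    ("plain|LacNAc-F,LacNAc-S", "other"),  # antenna fucose
    ("bisecting|LacNAc,LacNAc", "other"),
    ("bisecting|LacNAc,LacNAc-S", "other"),
    ("fucosylated_bisecting|LacNAc,LacNAc", "other"),
    ("plain|GlcNAc-F,LacNAc", "other"),  # truncated fucosylated antenna
    ("plain|LacNAc,LacNAc,LacNAc-S", "other"),  # tri-antennary
    ("plain|LacNAc,LacNAc,LacNAc-S,LacNAc-S", "other"),  # tetra-antennary
    ("plain|LacNAc-S,Man2", "other"),  # hybrid
    ("core_fucosylated|LacNAc,LacdiNAc-S", "lacdinac"),  # N5H4F1S1, Fig-2E
    ("plain|LacNAc,LacdiNAc", "lacdinac"),  # N5H4
    ("plain|LacNAc-S,LacdiNAc-S", "lacdinac"),
    ("bisecting|LacNAc,LacdiNAc-S", "lacdinac"),
    ("core_fucosylated|LacNAc-S,LacdiNAc", "lacdinac"),
    ("plain|LacNAc,LacdiNAc-F", "lacdinac"),
)

FIG2E_PEPTIDE = "ITDIENGSLANIPR"  # single sequon at the N of "NGS"


@dataclass
class StudyDesign:
    """Parameters of the synthetic study; the seed fully determines output."""

    n_glycopeptides: int = 200
    n_filler_proteins: int = 60
    glycopeptides_per_protein: int = 3
    proteome_psms_per_protein: int = 3
    # proteome abundance spread is kept moderate so that, as in deep
    # proteome data, bulk channel totals are dominated by the unchanged
    # majority rather than by a few high-abundance outliers
    proteome_log_sigma: float = 0.5
    channels: tuple[str, ...] = STUDY_CHANNELS
    # log-normal base abundance of a glycopeptide (natural-log scale)
    base_log_mean: float = 13.0
    base_log_sigma: float = 1.0
    # class mixture (fractions of glycopeptides; remainder unchanged)
    frac_lacdinac: float = 0.13  # ~26/200, mirroring the quantified LacdiNAc set
    frac_common_up: float = 0.08
    frac_common_down: float = 0.04
    frac_icc_up: float = 0.08
    frac_hcc_up: float = 0.04
    frac_protein_shift: float = 0.06
    lacdinac_elevated_frac: float = 0.96  # share of LacdiNAc class elevated in ICC
    lacdinac_fold_range: tuple[float, float] = (2.0, 5.0)
    tumor_fold_range: tuple[float, float] = (2.0, 8.0)
    paracancer_log2_sigma: float = 0.15  # ICCP/HCCP spread, well inside twofold
    # PSM replication: psm_min + Poisson(psm_extra_mean)
    psm_min: int = 5
    psm_extra_mean: float = 2.0
    # instrument/noise model
    noise: bool = True
    reporter_sigma: float = 0.1  # multiplicative log-normal sigma
    precursor_jitter_ppm: float = 2.0
    fragment_jitter_ppm: float = 3.0
    noise_peaks_mean: float = 30.0
    noise_intensity_mean: float = 60.0
    precursor_charge: int = 3
    channel_loading: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in STUDY_CHANNELS}
    )
    decoy_spike_frac: float = 0.0
    plant_fig2e_peptide: bool = True
    panel: tuple[tuple[str, str], ...] = DEFAULT_PANEL

    def without_noise(self) -> "StudyDesign":
        return replace(self, noise=False)


@dataclass
class GlycopeptideTruth:
    gp_id: str
    protein_id: str
    peptide: str
    site: int  # protein coordinate of the glycosylated N
    structure: GlycanStructure
    cls: str
    abundance: dict[str, float]  # true per-channel abundance (pre-loading)
    protein_ratio: dict[str, float]  # protein-level group factors
    psm_count: int = 0
    scan_ids: list[int] = field(default_factory=list)
    is_spike: bool = False


@dataclass
class SynthStudy:
    fasta: list[tuple[str, str]]
    proteome_run: list[Ms2Spectrum]
    glyco_run: list[Ms2Spectrum]
    manifest: pd.DataFrame
    truths: list[GlycopeptideTruth]
    protein_truth: pd.DataFrame  # per-protein true group factors
    design: StudyDesign


# ---------------------------------------------------------------------------
# Sequence generation

_PEP_ALPHABET = "ACDEFGHILQSTVWY"  # no K/R/P/N/M: cleavage, sequon, mods controlled


def _random_peptide(rng: np.random.Generator, with_sequon: bool) -> str:
    n = int(rng.integers(8, 14))
    seq = list(rng.choice(list(_PEP_ALPHABET), size=n))
    if with_sequon:
        pos = int(rng.integers(1, n - 3))
        seq[pos] = "N"
        x = seq[pos + 1]
        if x == "P":  # alphabet excludes P, defensive
            seq[pos + 1] = "A"
        seq[pos + 2] = "S" if rng.random() < 0.5 else "T"
    seq.append("K" if rng.random() < 0.5 else "R")
    return "".join(seq)


def generate_proteome(
    n_proteins: int,
    seed: int,
    peptides_per_protein: int = 6,
    sequons_per_protein: int = 1,
    plant_fig2e: bool = False,
) -> list[tuple[str, str]]:
    """Random protein FASTA entries with planted N-X-S/T sequons."""
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_proteins):
        parts = []
        for j in range(peptides_per_protein):
            parts.append(_random_peptide(rng, with_sequon=j < sequons_per_protein))
        if plant_fig2e and i == 0:
            parts.insert(1, FIG2E_PEPTIDE)
        entries.append((f"SYN{i:04d}", "".join(parts)))
    return entries


# ---------------------------------------------------------------------------
# Spectrum simulation


def _jitter(rng: np.random.Generator, mz: np.ndarray, ppm: float) -> np.ndarray:
    if ppm <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, ppm * 1e-6, size=len(mz)))


def simulate_pair(
    peptide: str,
    structure: GlycanStructure,
    channel_abundance: dict[str, float],
    design: StudyDesign,
    rng: np.random.Generator,
    scan_base: int,
    rt: float,
) -> SpectrumPair:
    """One low/high HCD scan pair for a glycopeptide precursor."""
    pep_mass = seqdb.peptide_neutral_mass(peptide)
    glycan_mass = glyco.composition_mass(structure.composition)
    z = design.precursor_charge
    prec_mz = (pep_mass + glycan_mass + z * PROTON) / z
    if design.noise:
        prec_mz *= 1.0 + rng.normal(0.0, design.precursor_jitter_ppm * 1e-6)

    frag_ppm = design.fragment_jitter_ppm if design.noise else 0.0

    # high-energy scan: peptide backbone ions + Y0/Y1 stubs + reporters
    by = np.array([mz for _, _, mz in seqdb.b_y_ions(peptide)])
    stubs = np.array(
        [
            (pep_mass + extra + zz * PROTON) / zz
            for extra in (0.0, glyco.RESIDUE_MASS["HexNAc"])
            for zz in (1, 2)
        ]
    )
    hi_mz = [_jitter(rng, by, frag_ppm), _jitter(rng, stubs, frag_ppm)]
    hi_int = [
        400.0 * (0.5 + 0.5 * rng.random(len(by))),
        300.0 * (0.5 + 0.5 * rng.random(len(stubs))),
    ]
    for ch in design.channels:
        inten = channel_abundance[ch] * design.channel_loading.get(ch, 1.0)
        if design.noise and design.reporter_sigma > 0:
            inten *= float(np.exp(rng.normal(0.0, design.reporter_sigma)))
        hi_mz.append(np.array([TMT10_REPORTER_MZ[ch]]))
        hi_int.append(np.array([inten]))

    # low-energy scan: glycan B ions and Y ions, plus the HexNAc secondary
    # fragment series (water/cross-ring losses of the 204.087 oxonium) that
    # accompanies every N-glycan spectrum
    hexnac_satellites = np.array([126.055, 138.055, 168.066, 186.076])
    b_mz = np.array([mz for _, mz in glyco.theoretical_B_ions(structure)])
    b_mz = np.concatenate([hexnac_satellites, b_mz])
    y_charges = (1, 2) if z >= 3 else (1,)
    y_mz = np.array(
        [mz for _, _, mz in glyco.theoretical_Y_ions(structure, pep_mass, y_charges)]
    )
    lo_mz = [_jitter(rng, b_mz, frag_ppm), _jitter(rng, y_mz, frag_ppm)]
    lo_int = [
        800.0 * (0.5 + 0.5 * rng.random(len(b_mz))),
        300.0 * (0.5 + 0.5 * rng.random(len(y_mz))),
    ]
    if design.noise and design.noise_peaks_mean > 0:
        n_noise = int(rng.poisson(design.noise_peaks_mean))
        lo_mz.append(rng.uniform(150.0, prec_mz * z, size=n_noise))
        lo_int.append(rng.exponential(design.noise_intensity_mean, size=n_noise))

    low = Ms2Spectrum(
        scan_id=scan_base,
        precursor_mz=prec_mz,
        precursor_charge=z,
        energy="low",
        mz=np.concatenate(lo_mz),
        intensity=np.concatenate(lo_int),
        rt=rt,
    )
    high = Ms2Spectrum(
        scan_id=scan_base + 1,
        precursor_mz=prec_mz,
        precursor_charge=z,
        energy="high",
        mz=np.concatenate(hi_mz),
        intensity=np.concatenate(hi_int),
        rt=rt + 0.5,
    )
    return SpectrumPair(low=low, high=high)


def _simulate_proteome_psm(
    peptide: str,
    channel_abundance: dict[str, float],
    design: StudyDesign,
    rng: np.random.Generator,
    scan_id: int,
    rt: float,
) -> Ms2Spectrum:
    pep_mass = seqdb.peptide_neutral_mass(peptide)
    z = 2
    prec_mz = (pep_mass + z * PROTON) / z
    if design.noise:
        prec_mz *= 1.0 + rng.normal(0.0, design.precursor_jitter_ppm * 1e-6)
    frag_ppm = design.fragment_jitter_ppm if design.noise else 0.0
    by = np.array([mz for _, _, mz in seqdb.b_y_ions(peptide)])
    mzs = [_jitter(rng, by, frag_ppm)]
    ints = [400.0 * (0.5 + 0.5 * rng.random(len(by)))]
    for ch in design.channels:
        inten = channel_abundance[ch] * design.channel_loading.get(ch, 1.0)
        if design.noise and design.reporter_sigma > 0:
            inten *= float(np.exp(rng.normal(0.0, design.reporter_sigma)))
        mzs.append(np.array([TMT10_REPORTER_MZ[ch]]))
        ints.append(np.array([inten]))
    return Ms2Spectrum(
        scan_id=scan_id,
        precursor_mz=prec_mz,
        precursor_charge=z,
        energy="high",
        mz=np.concatenate(mzs),
        intensity=np.concatenate(ints),
        rt=rt,
    )


# ---------------------------------------------------------------------------
# Study generation


def _class_assignments(design: StudyDesign, rng: np.random.Generator) -> list[str]:
    n = design.n_glycopeptides
    classes = []
    for cls, frac in (
        ("lacdinac", design.frac_lacdinac),
        ("common_up", design.frac_common_up),
        ("common_down", design.frac_common_down),
        ("icc_up", design.frac_icc_up),
        ("hcc_up", design.frac_hcc_up),
        ("protein_shift", design.frac_protein_shift),
    ):
        classes += [cls] * int(round(frac * n))
    classes += ["unchanged"] * (n - len(classes))
    return classes[:n]


def _group_factors(cls: str, design: StudyDesign, rng: np.random.Generator) -> dict[str, float]:
    """True glycosylation-level group factors relative to HCCP."""
    lo, hi = design.tumor_fold_range
    f = {"HCCP": 1.0}
    f["ICCP"] = float(2.0 ** rng.normal(0.0, design.paracancer_log2_sigma))
    icc = hcc = 1.0
    if cls == "lacdinac":
        if rng.random() < design.lacdinac_elevated_frac:
            icc = float(rng.uniform(*design.lacdinac_fold_range))
    elif cls == "common_up":
        icc = float(rng.uniform(lo, hi))
        hcc = float(rng.uniform(lo, hi))
    elif cls == "common_down":
        icc = 1.0 / float(rng.uniform(lo, hi))
        hcc = 1.0 / float(rng.uniform(lo, hi))
    elif cls == "icc_up":
        icc = float(rng.uniform(lo, hi))
    elif cls == "hcc_up":
        hcc = float(rng.uniform(lo, hi))
    f["ICC"] = f["ICCP"] * icc
    f["HCC"] = hcc
    return f


def generate_study(design: StudyDesign, seed: int = 1) -> SynthStudy:
    """Full synthetic study: FASTA, proteome run, glycoproteome run, manifest."""
    rng = np.random.default_rng(seed)
    n_glycoproteins = -(-design.n_glycopeptides // design.glycopeptides_per_protein)

    # -- sequences: glycopeptides (unique, single sequon) and host proteins
    glyco_peptides: list[str] = []
    seen = set()
    if design.plant_fig2e_peptide:
        glyco_peptides.append(FIG2E_PEPTIDE)
        seen.add(FIG2E_PEPTIDE)
    while len(glyco_peptides) < design.n_glycopeptides:
        pep = _random_peptide(rng, with_sequon=True)
        if pep not in seen:
            seen.add(pep)
            glyco_peptides.append(pep)

    fasta = []
    pep_location: dict[str, tuple[str, int]] = {}  # peptide -> (protein, start)
    for i in range(n_glycoproteins):
        chunk = glyco_peptides[
            i * design.glycopeptides_per_protein : (i + 1) * design.glycopeptides_per_protein
        ]
        parts, pos = [], 0
        for pep in chunk:
            filler = _random_peptide(rng, with_sequon=False)
            parts.append(filler)
            pos += len(filler)
            pep_location[pep] = (f"GP{i:04d}", pos + 1)
            parts.append(pep)
            pos += len(pep)
        fasta.append((f"GP{i:04d}", "".join(parts)))
    for i in range(design.n_filler_proteins):
        parts = [_random_peptide(rng, with_sequon=False) for _ in range(6)]
        fasta.append((f"FILL{i:04d}", "".join(parts)))

    # -- true abundances
    classes = _class_assignments(design, rng)
    rng.shuffle(classes)
    protein_factor: dict[str, dict[str, float]] = {}
    for acc, _ in fasta:
        protein_factor[acc] = {g: 1.0 for g in CHANNEL_GROUP.values()}

    truths: list[GlycopeptideTruth] = []
    for gp_idx, (pep, cls) in enumerate(zip(glyco_peptides, classes)):
        prot, start = pep_location[pep]
        if cls == "protein_shift" and all(
            v == 1.0 for v in protein_factor[prot].values()
        ):
            # protein-expression-level change, up or down, with no
            # glycosylation-level change on top of it
            shift = float(rng.uniform(2.0, 4.0))
            protein_factor[prot]["ICC"] = shift if rng.random() < 0.5 else 1.0 / shift
        site_off = seqdb.find_sequons(pep, 1)[0] - 1
        canonical, tag = design.panel[int(rng.integers(0, len(design.panel)))]
        if cls == "lacdinac":
            lacd = [p for p in design.panel if p[1] == "lacdinac"]
            canonical, tag = lacd[int(rng.integers(0, len(lacd)))]
        elif tag == "lacdinac":
            others = [p for p in design.panel if p[1] != "lacdinac"]
            canonical, tag = others[int(rng.integers(0, len(others)))]
        gfac = _group_factors(cls, design, rng)
        base = float(np.exp(rng.normal(design.base_log_mean, design.base_log_sigma)))
        abundance = {
            ch: base * gfac[CHANNEL_GROUP[ch]] * protein_factor[prot][CHANNEL_GROUP[ch]]
            for ch in design.channels
        }
        truths.append(
            GlycopeptideTruth(
                gp_id=f"gp{gp_idx:04d}",
                protein_id=prot,
                peptide=pep,
                site=start + site_off,
                structure=parse_structure(canonical),
                cls=cls if tag != "lacdinac" else "lacdinac",
                abundance=abundance,
                protein_ratio=dict(protein_factor[prot]),
            )
        )

    # -- glycoproteome run
    glyco_run: list[Ms2Spectrum] = []
    scan_id, rt = 1, 0.0
    for t in truths:
        t.psm_count = design.psm_min + int(rng.poisson(design.psm_extra_mean))
        for _ in range(t.psm_count):
            pair = simulate_pair(
                t.peptide, t.structure, t.abundance, design, rng, scan_id, rt
            )
            t.scan_ids.append(pair.low.scan_id)
            glyco_run += [pair.low, pair.high]
            scan_id += 2
            rt += 2.0
    # decoy spikes: shuffled peptides absent from the database
    n_spikes = int(round(design.decoy_spike_frac * sum(t.psm_count for t in truths)))
    spike_scans = []
    for k in range(n_spikes):
        t = truths[int(rng.integers(0, len(truths)))]
        core = list(t.peptide[:-1])
        rng.shuffle(core)
        spike_pep = "".join(core) + t.peptide[-1]
        pair = simulate_pair(
            spike_pep, t.structure, t.abundance, design, rng, scan_id, rt
        )
        spike_scans.append(pair.low.scan_id)
        glyco_run += [pair.low, pair.high]
        scan_id += 2
        rt += 2.0

    # -- proteome run: non-glyco PSMs for scaling factors and protein quant
    proteome_run: list[Ms2Spectrum] = []
    pscan, prt = 1, 0.0
    for acc, seq in fasta:
        peps = [
            c.sequence
            for c in seqdb.digest(acc, seq, max_missed=0, min_length=6, max_length=45)
            if not c.sequon_positions
        ]
        if not peps:
            continue
        base = float(np.exp(rng.normal(design.base_log_mean, design.proteome_log_sigma)))
        abundance = {
            ch: base * protein_factor[acc][CHANNEL_GROUP[ch]] for ch in design.channels
        }
        for _ in range(design.proteome_psms_per_protein):
            pep = peps[int(rng.integers(0, len(peps)))]
            proteome_run.append(
                _simulate_proteome_psm(pep, abundance, design, rng, pscan, prt)
            )
            pscan += 1
            prt += 2.0

    manifest = pd.DataFrame(
        {
            "gp_id": [t.gp_id for t in truths],
            "protein_id": [t.protein_id for t in truths],
            "peptide": [t.peptide for t in truths],
            "site": [t.site for t in truths],
            "structure": [t.structure.canonical for t in truths],
            "composition": [t.structure.composition.serialize() for t in truths],
            "class": [t.cls for t in truths],
            "psm_count": [t.psm_count for t in truths],
            "scan_ids": [";".join(map(str, t.scan_ids)) for t in truths],
            **{
                f"abund_{ch}": [t.abundance[ch] for t in truths]
                for ch in design.channels
            },
            "true_ICC_ICCP": [
                t.abundance[GROUP_CHANNEL["ICC"]] / t.abundance[GROUP_CHANNEL["ICCP"]]
                for t in truths
            ],
            "true_HCC_HCCP": [
                t.abundance[GROUP_CHANNEL["HCC"]] / t.abundance[GROUP_CHANNEL["HCCP"]]
                for t in truths
            ],
            "true_ICC_HCC": [
                t.abundance[GROUP_CHANNEL["ICC"]] / t.abundance[GROUP_CHANNEL["HCC"]]
                for t in truths
            ],
            "true_ICCP_HCCP": [
                t.abundance[GROUP_CHANNEL["ICCP"]] / t.abundance[GROUP_CHANNEL["HCCP"]]
                for t in truths
            ],
        }
    )
    manifest.attrs["spike_scan_ids"] = spike_scans
    protein_truth = pd.DataFrame(
        [
            {"protein_id": acc, **{f"factor_{g}": v for g, v in fac.items()}}
            for acc, fac in protein_factor.items()
        ]
    )
    return SynthStudy(
        fasta=fasta,
        proteome_run=proteome_run,
        glyco_run=glyco_run,
        manifest=manifest,
        truths=truths,
        protein_truth=protein_truth,
        design=design,
    )
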