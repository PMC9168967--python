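"""Intact glycopeptide identification from paired dual-energy MS2 scans.

The peptide backbone is read from the high-energy scan (b/y ions at 20 ppm),
the glycan from the low-energy scan: the core kind from Y-ion ladders
(peptide, +HexNAc, +HexNAc2, +trimannosyl core, with Fuc- and
bisecting-GlcNAc-shifted variants), branches from B-ion evidence.  Candidate
structures are assembled under the precursor-mass closure constraint
(|peptide + glycan - precursor| <= 10 ppm) and scored; the highest score is
the reported identification, and FDR is controlled at 1% independently at
the peptide level (pseudo-reverse decoy peptides) and the glycan level
(mass-shifted decoy structural hypotheses).

A LacdiNAc-family branch is only ever accepted when a HexNAc2-containing
B ion (HexNAc2, HexNAc2Sia1 or HexNAc2Fuc1) is matched; a LacNAc-family
branch requires a HexNAc1Hex1-containing B ion or a sialyl/fucosyl
extension of it.

Scoring is a surrogate for the original glycan-structure search engine's
internal formulas: the peptide score is the -log10 hypergeometric tail
probability of the observed b/y matches, and the glycan score combines the
matched fraction of theoretical B+Y ions, the fraction of fragment
intensity explained, and a diagnostic-ion bonus per confirmed branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats

from . import glyco, seqdb
from .glyco import Composition, GlycanStructure, default_library
from .seqdb import PeptideCandidate, SearchSpace
from .spectra import (
    Ms2Spectrum,
    ReporterVector,
    SpectrumPair,
    extract_reporters,
    oxonium_screen,
)

GLYCAN_DECOY_SHIFT = 17.0027  # Da added per branch motif in decoy hypotheses

PRECURSOR_TOL_PPM = 10.0
FRAGMENT_TOL_PPM = 20.0


@dataclass
class SearchParams:
    precursor_tol_ppm: float = PRECURSOR_TOL_PPM
    fragment_tol_ppm: float = FRAGMENT_TOL_PPM
    oxonium_min_matches: int = 2
    oxonium_top_n: int = 10
    hypergeom_bins: int = 2000
    diag_bonus: float = 0.1


@dataclass
class GlycopeptidePSM:
    pair_id: str
    peptide: PeptideCandidate
    site: int  # protein coordinate of assigned sequon N
    site_ambiguous: bool
    structure: GlycanStructure
    peptide_score: float
    glycan_score: float
    branch_evidence: dict[str, list[float]]  # motif name -> matched B m/z
    core_evidence: list[float]  # matched core-ladder Y m/z
    precursor_error_ppm: float
    peptide_is_decoy: bool
    glycan_is_decoy: bool
    reporters: ReporterVector = field(default_factory=ReporterVector)


@dataclass
class FdrResult:
    level: str  # "peptide" | "glycan"
    threshold: float
    n_accepted: int
    estimated_fdr: float


class NoDecoysError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Peak matching


def _match_ppm(spectrum_mz: np.ndarray, theo_mz: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Boolean mask: theoretical m/z with a spectrum peak within tol_ppm."""
    if len(spectrum_mz) == 0 or len(theo_mz) == 0:
        return np.zeros(len(theo_mz), dtype=bool)
    idx = np.searchsorted(spectrum_mz, theo_mz)
    best = np.full(len(theo_mz), np.inf)
    for off in (-1, 0):
        j = np.clip(idx + off, 0, len(spectrum_mz) - 1)
        best = np.minimum(best, np.abs(spectrum_mz[j] - theo_mz))
    return best / theo_mz * 1e6 <= tol_ppm


def _matched_peak_indices(
    spectrum_mz: np.ndarray, theo_mz: np.ndarray, tol_ppm: float
) -> set[int]:
    """Indices of spectrum peaks matched by at least one theoretical ion."""
    out: set[int] = set()
    idx = np.searchsorted(spectrum_mz, theo_mz)
    for k, t in enumerate(theo_mz):
        for off in (-1, 0):
            j = min(max(idx[k] + off, 0), len(spectrum_mz) - 1)
            if abs(spectrum_mz[j] - t) / t * 1e6 <= tol_ppm:
                out.add(int(j))
    return out


# ---------------------------------------------------------------------------
# Peptide matching (high-energy scan)


@dataclass
class PeptideMatch:
    candidate: PeptideCandidate
    score: float
    n_matched: int
    precursor_error_ppm: float


def score_peptide(
    spectrum: Ms2Spectrum, sequence: str, params: SearchParams, _cache: dict = {}
) -> tuple[float, int]:
    """-log10 hypergeometric tail probability of the b/y ion matches."""
    theo = _cache.get(sequence)
    if theo is None:
        theo = np.array([mz for _, _, mz in seqdb.b_y_ions(sequence)])
        if len(_cache) > 50000:
            _cache.clear()
        _cache[sequence] = theo
    matched = int(_match_ppm(spectrum.mz, theo, params.fragment_tol_ppm).sum())
    M = params.hypergeom_bins
    n_peaks = min(len(spectrum.mz), M)
    n_theo = min(len(theo), M)
    if matched == 0:
        return 0.0, 0
    p = stats.hypergeom.sf(matched - 1, M, n_peaks, n_theo)
    return float(-np.log10(max(p, 1e-300))), matched


def match_peptide(
    pair: SpectrumPair,
    candidates: list[PeptideCandidate],
    glycan_masses: np.ndarray,
    params: SearchParams,
) -> list[PeptideMatch]:
    """Rank candidates whose mass leaves a glycan-explainable remainder."""
    prec = pair.precursor_neutral_mass
    tol = prec * params.precursor_tol_ppm * 1e-6
    cand_masses = np.array([c.neutral_mass for c in candidates])
    remainders = prec - cand_masses
    j = np.searchsorted(glycan_masses, remainders)
    err = np.minimum(
        np.abs(glycan_masses[np.clip(j - 1, 0, len(glycan_masses) - 1)] - remainders),
        np.abs(glycan_masses[np.clip(j, 0, len(glycan_masses) - 1)] - remainders),
    )
    viable = np.flatnonzero((remainders > 0) & (err <= tol))
    matches = []
    for k in viable:
        cand = candidates[k]
        score, n = score_peptide(pair.high, cand.sequence, params)
        if n == 0:
            continue
        matches.append(PeptideMatch(cand, score, n, err[k] / prec * 1e6))
    matches.sort(key=lambda m: (-m.score, m.precursor_error_ppm, m.candidate.sequence))
    return matches


# ---------------------------------------------------------------------------
# Glycan structure index and scoring


class GlycanIndex:
    """All library structures up to the antenna caps, grouped by composition."""

    def __init__(self, library=None, max_residues: int = 26):
        self.library = library or default_library()
        by_comp: dict[Composition, list[GlycanStructure]] = {}
        seen: set[str] = set()
        for kind in glyco.CORE_KINDS:
            core_comp = glyco.core_composition(kind)
            budget = Composition(
                max_residues, max_residues, max_residues, max_residues
            )
            residual_cap = budget - core_comp
            motifs = sorted(self.library, key=lambda m: m.name)
            for multiset in self._multisets(motifs, residual_cap):
                s = GlycanStructure(kind, multiset)
                if s.canonical in seen:
                    continue
                comp = s.composition
                if comp.total() > max_residues:
                    continue
                seen.add(s.canonical)
                by_comp.setdefault(comp, []).append(s)
        for structures in by_comp.values():
            structures.sort(key=lambda s: s.canonical)
        self.by_comp = by_comp
        self.comps = sorted(by_comp, key=glyco.composition_mass)
        self.masses = np.array([glyco.composition_mass(c) for c in self.comps])

    @staticmethod
    def _multisets(motifs, cap):
        def rec(start, chosen, n_ant, remaining):
            yield tuple(chosen)
            if len(chosen) >= glyco.MAX_BRANCHES:
                return
            for i in range(start, len(motifs)):
                m = motifs[i]
                nxt = remaining - m.composition
                if not nxt.is_nonnegative():
                    continue
                ant = n_ant + (m.family != "Mannose")
                if ant > glyco.MAX_NON_MANNOSE_ANTENNAE:
                    continue
                chosen.append(m)
                yield from rec(i, chosen, ant, nxt)
                chosen.pop()

        yield from rec(0, [], 0, cap)

    def comps_near(self, mass: float, tol: float) -> list[Composition]:
        lo = np.searchsorted(self.masses, mass - tol, side="left")
        hi = np.searchsorted(self.masses, mass + tol, side="right")
        return self.comps[lo:hi]


@lru_cache(maxsize=200000)
def _structure_ion_cache(canonical: str, decoy: bool) -> tuple:
    """(B compositions, B m/z, Y retained compositions, Y glycan masses)."""
    s = glyco.parse_structure(canonical)
    shift = GLYCAN_DECOY_SHIFT if decoy else 0.0
    b = glyco.theoretical_B_ions(s, mass_shift_per_branch=shift)
    b_comps = tuple(c for c, _ in b)
    b_mz = np.array([mz for _, mz in b])
    # Y ions via a unit peptide mass; the true peptide mass is added later
    y = glyco.theoretical_Y_ions(s, 1.0, (1,), mass_shift_per_branch=shift)
    y_comps = tuple(c for c, _, _ in y)
    y_gmass = np.array([mz - 1.0 - glyco.PROTON for _, _, mz in y])
    return b_comps, b_mz, y_comps, y_gmass


@dataclass
class GlycanMatch:
    structure: GlycanStructure
    score: float
    is_decoy: bool
    branch_evidence: dict[str, list[float]]
    core_evidence: list[float]
    n_matched: int
    n_theoretical: int


def score_structure(
    low: Ms2Spectrum,
    structure: GlycanStructure,
    peptide_mass: float,
    params: SearchParams,
    y_charges: tuple[int, ...] = (1, 2),
    decoy: bool = False,
) -> GlycanMatch | None:
    """Score one structural hypothesis against the low-energy scan.

    Returns None when a branch-evidence gate fails (e.g. LacdiNAc proposed
    without a matched HexNAc2-containing B ion).
    """
    b_comps, b_mz, y_comps, y_gmass = _structure_ion_cache(structure.canonical, decoy)
    y_mz = np.concatenate(
        [(peptide_mass + y_gmass + z * glyco.PROTON) / z for z in y_charges]
    )
    theo = np.concatenate([b_mz, y_mz])
    mask = _match_ppm(low.mz, theo, params.fragment_tol_ppm)
    b_mask = mask[: len(b_mz)]
    y_mask = mask[len(b_mz):].reshape(len(y_charges), -1).any(axis=0)

    matched_b = [c for c, ok in zip(b_comps, b_mask) if ok]
    # branch-evidence gates on diagnostic B ions
    families = {m.family for m in structure.branches}
    if "LacdiNAc" in families and not any(
        c.hexnac >= 2 and c.hex == 0 for c in matched_b
    ):
        return None
    if "LacNAc" in families and not any(
        c.hexnac >= 1 and c.hex >= 1 for c in matched_b
    ):
        return None

    n_theo = len(b_mz) + len(y_mask)
    n_matched = int(b_mask.sum()) + int(y_mask.sum())
    if n_matched == 0:
        return None
    frac = n_matched / n_theo

    peak_idx = _matched_peak_indices(low.mz, theo[mask], params.fragment_tol_ppm)
    total_int = float(low.intensity.sum())
    explained = (
        float(low.intensity[sorted(peak_idx)].sum()) / total_int if total_int else 0.0
    )

    branch_evidence: dict[str, list[float]] = {}
    confirmed = 0
    for m in structure.branches:
        intact = m.composition
        hits = [
            float(mz)
            for c, mz, ok in zip(b_comps, b_mz, b_mask)
            if ok and c == intact
        ]
        sub = [
            float(mz)
            for c, mz, ok in zip(b_comps, b_mz, b_mask)
            if ok and (intact - c).is_nonnegative() and c.total() > 0
        ]
        branch_evidence[m.name] = sub
        confirmed += bool(hits)
    diag = confirmed / len(structure.branches) if structure.branches else 1.0

    core_ladder = {
        Composition(),
        Composition(1, 0, 0, 0),
        Composition(2, 0, 0, 0),
        Composition(2, 1, 0, 0),
        Composition(2, 2, 0, 0),
        Composition(2, 3, 0, 0),
        Composition(2, 3, 1, 0),
        Composition(3, 3, 0, 0),
        Composition(3, 3, 1, 0),
    }
    core_evidence = [
        float((peptide_mass + gm + glyco.PROTON))
        for c, gm, ok in zip(y_comps, y_gmass, y_mask)
        if ok and c in core_ladder
    ]

    score = 0.5 * frac + 0.5 * explained + params.diag_bonus * diag
    return GlycanMatch(
        structure=structure,
        score=score,
        is_decoy=decoy,
        branch_evidence=branch_evidence,
        core_evidence=core_evidence,
        n_matched=n_matched,
        n_theoretical=n_theo,
    )


def infer_core(
    low: Ms2Spectrum,
    peptide_mass: float,
    params: SearchParams | None = None,
    y_charges: tuple[int, ...] = (1, 2),
) -> tuple[str | None, dict[str, list[float]]]:
    """Best-supported core kind from Y-ion ladder evidence.

    Tests peptide / +HexNAc / +HexNAc2 / +core ladders plus Fuc-shifted
    (core fucose) and +HexNAc-on-core (bisecting) variants; core fucose
    requires a Fuc-shifted Y ion at the fragment tolerance.

    Only the fucosylation axis is decided here: a pep+HexNAc3Hex3 ion is
    equally consistent with a bisecting core or with a truncated GlcNAc
    antenna on a plain core, so bisecting evidence is reported but the
    bisecting/plain decision is left to full structure assembly, which sees
    the branch ions too.
    """
    params = params or SearchParams()
    ladder = [
        Composition(),
        Composition(1, 0, 0, 0),
        Composition(2, 0, 0, 0),
        Composition(2, 1, 0, 0),
        Composition(2, 2, 0, 0),
        Composition(2, 3, 0, 0),
    ]
    variants = {
        "plain": ladder,
        "core_fucosylated": [c + Composition(0, 0, 1, 0) for c in ladder[1:]],
        "bisecting": [Composition(3, 3, 0, 0)],
        "fucosylated_bisecting": [Composition(3, 3, 1, 0)],
    }
    evidence = {}
    for kind, comps in variants.items():
        theo = np.concatenate(
            [
                (peptide_mass + np.array([c.mass for c in comps]) + z * glyco.PROTON) / z
                for z in y_charges
            ]
        )
        mask = _match_ppm(low.mz, theo, params.fragment_tol_ppm)
        evidence[kind] = sorted(float(t) for t, ok in zip(theo, mask) if ok)
    if not evidence["plain"]:
        return None, evidence
    kind = "core_fucosylated" if evidence["core_fucosylated"] else "plain"
    return kind, evidence


def infer_branches(
    low: Ms2Spectrum,
    residual: Composition,
    peptide_mass: float,
    core_kind: str,
    params: SearchParams | None = None,
    library=None,
) -> list[GlycanMatch]:
    """Score all branch multisets from the library summing to ``residual``."""
    params = params or SearchParams()
    library = library or default_library()
    if not residual.is_nonnegative():
        raise ValueError("residual composition must be non-negative")
    matches = []
    motifs = sorted(library, key=lambda m: m.name)
    for multiset in glyco._branch_multisets(residual, motifs):
        s = GlycanStructure(core_kind, multiset)
        m = score_structure(low, s, peptide_mass, params)
        if m is not None:
            matches.append(m)
    matches.sort(key=lambda m: (-m.score, m.structure.canonical))
    return matches


# ---------------------------------------------------------------------------
# Full search


def assemble_and_score(
    pair: SpectrumPair,
    pep_match: PeptideMatch,
    index: GlycanIndex,
    params: SearchParams,
) -> GlycopeptidePSM | None:
    """Best glycan structure (target or decoy hypothesis) for one pair."""
    prec = pair.precursor_neutral_mass
    remainder = prec - pep_match.candidate.neutral_mass
    tol = prec * params.precursor_tol_ppm * 1e-6
    y_charges = (1, 2) if pair.low.precursor_charge >= 3 else (1,)
    best: GlycanMatch | None = None
    for comp in index.comps_near(remainder, tol):
        for s in index.by_comp[comp]:
            for decoy in (False, True):
                m = score_structure(
                    pair.low, s, pep_match.candidate.neutral_mass, params,
                    y_charges, decoy,
                )
                if m is None:
                    continue
                # higher score wins; at equal score prefer target over decoy,
                # then the lexicographically smallest canonical string
                if (
                    best is None
                    or m.score > best.score
                    or (
                        m.score == best.score
                        and (m.is_decoy, m.structure.canonical)
                        < (best.is_decoy, best.structure.canonical)
                    )
                ):
                    best = m
    if best is None:
        return None
    sequons = pep_match.candidate.sequon_positions
    glycan_mass = glyco.composition_mass(best.structure.composition)
    err_ppm = (pep_match.candidate.neutral_mass + glycan_mass - prec) / prec * 1e6
    if abs(err_ppm) > params.precursor_tol_ppm and not best.is_decoy:
        return None
    return GlycopeptidePSM(
        pair_id=pair.pair_id,
        peptide=pep_match.candidate,
        site=sequons[0],
        site_ambiguous=len(sequons) > 1,
        structure=best.structure,
        peptide_score=pep_match.score,
        glycan_score=best.score,
        branch_evidence=best.branch_evidence,
        core_evidence=best.core_evidence,
        precursor_error_ppm=err_ppm,
        peptide_is_decoy=pep_match.candidate.is_decoy,
        glycan_is_decoy=best.is_decoy,
        reporters=extract_reporters(pair.high),
    )


def search_pair(
    pair: SpectrumPair,
    space: SearchSpace,
    index: GlycanIndex,
    params: SearchParams | None = None,
) -> GlycopeptidePSM | None:
    params = params or SearchParams()
    ok, _ = oxonium_screen(
        pair.low, params.oxonium_min_matches, params.oxonium_top_n,
        params.fragment_tol_ppm,
    )
    if not ok:
        return None
    pep_matches = match_peptide(pair, space.glyco, index.masses, params)
    if not pep_matches:
        return None
    return assemble_and_score(pair, pep_matches[0], index, params)


def search_run(
    pairs: list[SpectrumPair],
    space: SearchSpace,
    index: GlycanIndex | None = None,
    params: SearchParams | None = None,
) -> list[GlycopeptidePSM]:
    index = index or GlycanIndex()
    params = params or SearchParams()
    psms = []
    for pair in pairs:
        psm = search_pair(pair, space, index, params)
        if psm is not None:
            psms.append(psm)
    return psms


# ---------------------------------------------------------------------------
# FDR


def fdr_threshold(
    scores: np.ndarray,
    is_decoy: np.ndarray,
    alpha: float,
    require_decoys: bool = False,
) -> tuple[float, float]:
    """Smallest score cutoff with (#decoy >= s) / (#target >= s) <= alpha.

    With zero decoy hits the estimate is 0 everywhere and every target is
    accepted; ``require_decoys`` instead raises, for callers whose inputs
    should always contain decoy competition.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if require_decoys and not is_decoy.any():
        raise NoDecoysError("no decoys present; FDR is not estimable")
    if not is_decoy.any():
        return float(scores.min()), 0.0
    best = (np.inf, 0.0)
    for s in np.unique(scores):
        targets = int(((scores >= s) & ~is_decoy).sum())
        decoys = int(((scores >= s) & is_decoy).sum())
        if targets == 0:
            continue
        fdr = decoys / targets
        if fdr <= alpha and s < best[0]:
            best = (s, fdr)
    if not np.isfinite(best[0]):
        # no cutoff achieves alpha: accept nothing (threshold above max)
        return float(scores.max()) + 1.0, 0.0
    return float(best[0]), float(best[1])


def fdr_filter(
    psms: list[GlycopeptidePSM], level: str, alpha: float = 0.01
) -> tuple[FdrResult, list[GlycopeptidePSM]]:
    if level == "peptide":
        scores = np.array([p.peptide_score for p in psms])
        decoy = np.array([p.peptide_is_decoy for p in psms])
    elif level == "glycan":
        scores = np.array([p.glycan_score for p in psms])
        decoy = np.array([p.glycan_is_decoy for p in psms])
    else:
        raise ValueError(f"unknown FDR level {level!r}")
    thr, est = fdr_threshold(scores, decoy, alpha)
    accepted = [
        p for p, s, d in zip(psms, scores, decoy) if s >= thr and not d
    ]
    return FdrResult(level, thr, len(accepted), est), accepted


def accept_psms(
    psms: list[GlycopeptidePSM], alpha: float = 0.01
) -> tuple[list[GlycopeptidePSM], FdrResult, FdrResult]:
    """Targets passing both peptide- and glycan-level 1% FDR."""
    pep_res, pep_ok = fdr_filter(psms, "peptide", alpha)
    gly_res, _ = fdr_filter(psms, "glycan", alpha)
    accepted = [
        p
        for p in pep_ok
        if p.glycan_score >= gly_res.threshold and not p.glycan_is_decoy
    ]
    return accepted, pep_res, gly_res


# ---------------------------------------------------------------------------
# Proteome (non-glyco) identification for scaling factors / protein quant


@dataclass
class ProteomePSM:
    scan_id: int
    peptide: PeptideCandidate
    score: float
    is_decoy: bool
    reporters: ReporterVector


def identify_proteome(
    run: list[Ms2Spectrum],
    space: SearchSpace,
    params: SearchParams | None = None,
    alpha: float = 0.01,
) -> list[ProteomePSM]:
    params = params or SearchParams()
    by_mass = sorted(space.proteome, key=lambda c: c.neutral_mass)
    masses = np.array([c.neutral_mass for c in by_mass])
    psms = []
    for spec in run:
        prec = spec.precursor_neutral_mass
        tol = prec * params.precursor_tol_ppm * 1e-6
        lo = np.searchsorted(masses, prec - tol, side="left")
        hi = np.searchsorted(masses, prec + tol, side="right")
        best = None
        for cand in by_mass[lo:hi]:
            score, n = score_peptide(spec, cand.sequence, params)
            if n == 0:
                continue
            key = (-score, abs(cand.neutral_mass - prec), cand.sequence)
            if best is None or key < best[0]:
                best = (key, cand, score)
        if best is not None:
            psms.append(
                ProteomePSM(
                    scan_id=spec.scan_id,
                    peptide=best[1],
                    score=best[2],
                    is_decoy=best[1].is_decoy,
                    reporters=extract_reporters(spec),
                )
            )
    if not psms or not any(p.is_decoy for p in psms):
        return psms
    thr, _ = fdr_threshold(
        np.array([p.score for p in psms]), np.array([p.is_decoy for p in psms]), alpha
    )
    return [p for p in psms if p.score >= thr and not p.is_decoy]
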