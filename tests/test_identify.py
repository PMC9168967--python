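"""Glycopeptide identification engine: matching, assembly, scoring, FDR."""

import numpy as np
import pytest

from glycosite import glyco, identify, seqdb, spectra, synth
from glycosite.identify import (
    FdrResult,
    GlycanIndex,
    SearchParams,
    fdr_filter,
    fdr_threshold,
    infer_branches,
    infer_core,
    match_peptide,
    score_structure,
    search_pair,
)


@pytest.fixture(scope="module")
def noise_free_setup(glycan_index):
    study = synth.generate_study(
        synth.StudyDesign(n_glycopeptides=12, noise=False), seed=11
    )
    space = seqdb.build_search_space(study.fasta)
    pairs = spectra.pair_spectra(study.glyco_run)
    by_low = {p.low.scan_id: p for p in pairs}
    return study, space, by_low


def simulate_single(peptide, canonical, seed=0, noise=False):
    design = synth.StudyDesign(noise=noise)
    rng = np.random.default_rng(seed)
    st = glyco.parse_structure(canonical)
    return synth.simulate_pair(
        peptide, st, {c: 500.0 for c in design.channels}, design, rng, 1, 0.0
    )


def make_candidate(peptide):
    return seqdb.PeptideCandidate(
        "P1", peptide, 1, len(peptide), 0, seqdb.find_sequons(peptide, 1),
        neutral_mass=seqdb.peptide_neutral_mass(peptide),
    )


class TestMatchPeptide:
    def test_noise_free_pair_top_ranked_is_true_peptide(self, noise_free_setup, glycan_index):
        study, space, by_low = noise_free_setup
        t = study.truths[0]
        pair = by_low[t.scan_ids[0]]
        matches = match_peptide(pair, space.glyco, glycan_index.masses, SearchParams())
        assert matches[0].candidate.sequence == t.peptide
        assert not matches[0].candidate.is_decoy

    def test_spectrum_without_fragment_matches_gives_no_match(self, glycan_index):
        pair = simulate_single("LATNFSDAVSK", "C|LacNAc,LacNAc")
        empty = spectra.Ms2Spectrum(
            pair.high.scan_id, pair.high.precursor_mz, pair.high.precursor_charge,
            "high", np.array([333.3]), np.array([1.0]),
        )
        pair = spectra.SpectrumPair(low=pair.low, high=empty)
        cands = [make_candidate("LATNFSDAVSK")]
        assert match_peptide(pair, cands, glycan_index.masses, SearchParams()) == []

    def test_equal_scores_broken_deterministically(self, glycan_index):
        pair = simulate_single("LATNFSDAVSK", "C|LacNAc,LacNAc")
        # two identical-mass candidates (I/L swap) tie on every ion
        cands = [make_candidate("LATNFSDAVSK"), make_candidate("IATNFSDAVSK")]
        m = match_peptide(pair, cands, glycan_index.masses, SearchParams())
        assert [x.candidate.sequence for x in m[:2]] == ["IATNFSDAVSK", "LATNFSDAVSK"]


class TestInferCore:
    @pytest.mark.parametrize(
        "canonical,expected",
        [
            ("C|Man2", "plain"),
            ("CF|LacNAc,LacNAc", "core_fucosylated"),
            ("CB|LacNAc,LacNAc", "plain"),  # bisecting left to assembly
            ("CFB|LacNAc,LacNAc", "core_fucosylated"),
        ],
    )
    def test_noise_free_fucosylation_axis_recovered(self, canonical, expected):
        pep = "LATNFSDAVSK"
        pair = simulate_single(pep, canonical)
        kind, evidence = infer_core(pair.low, seqdb.peptide_neutral_mass(pep))
        assert kind == expected
        if "F" in canonical.split("|")[0]:
            assert evidence["core_fucosylated"]  # Fuc-shifted Y ion cited
        if "B" in canonical.split("|")[0]:
            assert evidence["bisecting"]  # bisect-shifted Y ion reported

    def test_bisecting_core_recovered_by_full_assembly(self, glycan_index):
        pep = "LATNFSDAVSK"
        pair = simulate_single(pep, "CB|LacNAc,LacNAc")
        pm = identify.PeptideMatch(make_candidate(pep), 10.0, 10, 0.0)
        psm = identify.assemble_and_score(pair, pm, glycan_index, SearchParams())
        assert psm.structure.core == "bisecting"

    def test_ladder_absent_returns_none(self):
        s = spectra.Ms2Spectrum(1, 1000.0, 3, "low", np.array([204.087]), np.array([1.0]))
        kind, _ = infer_core(s, 1500.0)
        assert kind is None


class TestInferBranches:
    def test_diagnostic_b_ions_select_sialylated_lacdinac_plus_lacnac(self):
        low = spectra.Ms2Spectrum(
            1, 1000.0, 3, "low",
            np.array([204.087, 366.140, 407.166, 495.182, 698.261]),
            np.full(5, 100.0),
        )
        m = infer_branches(
            low, glyco.parse_composition("N3H1S1"), 1500.0, "plain"
        )
        names = sorted(x.name for x in m[0].structure.branches)
        assert names == ["LacNAc", "LacdiNAc-S"]

    def test_empty_residual_gives_bare_assembly(self):
        low = spectra.Ms2Spectrum(1, 1000.0, 3, "low", np.array([204.087]), np.array([1.0]))
        m = infer_branches(low, glyco.Composition(), 1500.0, "plain")
        assert len(m) == 1 and m[0].structure.branches == ()

    def test_isomeric_residual_without_407_prefers_lacdinac_free_multiset(self):
        # N3H1 residual: LacdiNAc-bearing readings are gated out without the
        # HexNAc2 B ion; a GlcNAc/LacNAc reading survives
        low = spectra.Ms2Spectrum(
            1, 1000.0, 3, "low",
            np.array([163.060, 204.087, 366.140]),
            np.full(3, 100.0),
        )
        m = infer_branches(low, glyco.parse_composition("N3H1"), 1500.0, "plain")
        assert m
        assert all(
            all(b.family != "LacdiNAc" for b in x.structure.branches) for x in m
        )


class TestIsomerDiscrimination:
    PEP = "LATNFSDAVSK"
    # paired isomer fixtures: same composition, LacdiNAc-bearing vs
    # bisecting/truncated LacNAc assemblies
    PAIRS = [
        ("C|LacNAc,LacdiNAc", "CB|GlcNAc,LacNAc"),  # N5H4
        ("CB|LacNAc,LacdiNAc-S", "CB|GlcNAc,GlcNAc,LacNAc-S"),  # N6H4S1
    ]

    @pytest.mark.parametrize("lacdinac_can,other_can", PAIRS)
    def test_zero_cross_assignments_noise_free(
        self, glycan_index, lacdinac_can, other_can
    ):
        params = SearchParams()
        for truth in (lacdinac_can, other_can):
            pair = simulate_single(self.PEP, truth)
            pm = identify.PeptideMatch(make_candidate(self.PEP), 10.0, 10, 0.0)
            psm = identify.assemble_and_score(pair, pm, glycan_index, params)
            assert psm is not None
            assert psm.structure.canonical == truth

    def test_lacdinac_assignment_cites_hexnac2_b_ion(self, glycan_index):
        pair = simulate_single(self.PEP, "C|LacNAc,LacdiNAc")
        pm = identify.PeptideMatch(make_candidate(self.PEP), 10.0, 10, 0.0)
        psm = identify.assemble_and_score(pair, pm, glycan_index, SearchParams())
        ev = psm.branch_evidence["LacdiNAc"]
        assert any(abs(mz - 407.166) < 0.01 for mz in ev)


class TestScoring:
    def test_removing_matched_ion_never_increases_score(self):
        pep = "LATNFSDAVSK"
        pair = simulate_single(pep, "CF|LacNAc,LacdiNAc-S")
        st = glyco.parse_structure("CF|LacNAc,LacdiNAc-S")
        pep_mass = seqdb.peptide_neutral_mass(pep)
        params = SearchParams()
        full = score_structure(pair.low, st, pep_mass, params)
        theo = np.array([mz for _, mz in glyco.theoretical_B_ions(st)])
        theo = np.concatenate([
            theo,
            [mz for _, _, mz in glyco.theoretical_Y_ions(st, pep_mass, (1, 2))],
        ])
        matched_peaks = [
            i
            for i, mz in enumerate(pair.low.mz)
            if np.min(np.abs(theo - mz)) / mz * 1e6 <= params.fragment_tol_ppm
        ]
        assert matched_peaks
        for drop in matched_peaks:
            low = spectra.Ms2Spectrum(
                1, pair.low.precursor_mz, 3, "low",
                np.delete(pair.low.mz, drop), np.delete(pair.low.intensity, drop),
            )
            reduced = score_structure(low, st, pep_mass, params)
            if reduced is not None:
                assert reduced.score <= full.score + 1e-12

    def test_composition_closure_on_accepted_psms(self, noise_free_setup, glycan_index):
        study, space, by_low = noise_free_setup
        pairs = list(by_low.values())
        psms = identify.search_run(pairs, space, glycan_index)
        assert psms
        for p in psms:
            total = p.peptide.neutral_mass + glyco.composition_mass(
                p.structure.composition
            )
            pair = by_low[int(p.pair_id.split("/")[0])]
            err = abs(total - pair.precursor_neutral_mass) / total * 1e6
            assert err <= 10.0

    def test_oxonium_failed_pair_never_searched(self, glycan_index):
        low = spectra.Ms2Spectrum(
            1, 1000.0, 3, "low", np.array([500.0, 600.0]), np.array([9.0, 9.0])
        )
        high = spectra.Ms2Spectrum(2, 1000.0, 3, "high", np.array([500.0]), np.array([9.0]))
        pair = spectra.SpectrumPair(low=low, high=high)
        space = seqdb.SearchSpace(glyco=[make_candidate("LATNFSDAVSK")], proteome=[])
        assert search_pair(pair, space, glycan_index) is None


class TestFdr:
    def test_separated_scores_accept_all_targets(self):
        scores = np.array([10.0] * 20 + [1.0] * 20)
        decoy = np.array([False] * 20 + [True] * 20)
        thr, est = fdr_threshold(scores, decoy, 0.01)
        assert 1.0 < thr <= 10.0
        assert est == 0.0

    def brute_force_threshold(self, scores, decoy, alpha):
        candidates = []
        for s in sorted(set(scores)):
            t = sum(1 for x, d in zip(scores, decoy) if x >= s and not d)
            dcount = sum(1 for x, d in zip(scores, decoy) if x >= s and d)
            if t and dcount / t <= alpha:
                candidates.append(s)
        return min(candidates) if candidates else max(scores) + 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_threshold_equals_brute_force_cutoff_scan(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.exponential(5.0, 300), 2)
        decoy = rng.random(300) < 0.3
        for alpha in (0.01, 0.05, 0.2):
            thr, _ = fdr_threshold(scores, decoy, alpha)
            assert thr == self.brute_force_threshold(scores, decoy, alpha)

    def test_no_decoys_raises_when_required(self):
        with pytest.raises(identify.NoDecoysError):
            fdr_threshold(np.array([1.0]), np.array([False]), 0.01, require_decoys=True)

    def test_filter_reports_level_and_estimate(self, noise_free_setup, glycan_index):
        study, space, by_low = noise_free_setup
        psms = identify.search_run(list(by_low.values()), space, glycan_index)
        res, accepted = fdr_filter(psms, "peptide", 0.01)
        assert isinstance(res, FdrResult)
        assert res.estimated_fdr <= 0.01
        assert all(not p.peptide_is_decoy for p in accepted)
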