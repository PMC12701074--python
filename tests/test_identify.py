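"""Identification pipeline: digestion, signature-pair detection, MS3 and
stepped-HCD matching, FDR estimation and linkage aggregation."""

import math

import numpy as np
import pytest

from kcxlink.chemistry import (
    ModifiedPeptide,
    fragment_ladder,
    get_linker,
    mz_to_neutral,
    neutral_to_mz,
    remnants_for,
)
from kcxlink.identify import (
    CAM,
    CrossLinkSpectrumMatch,
    PeptideSpectrumMatch,
    Tolerances,
    collapse_to_unique_linkages,
    detect_signature_pairs,
    digest,
    estimate_fdr,
    match_ms3,
    reproducibility_filter,
    search_ms2_stepped_hcd,
    search_msn,
)
from kcxlink.spectra import Run, Spectrum
from kcxlink.synthetic import (
    SimulationConfig,
    simulate_msn_run,
    simulate_proteome,
)

SIA = get_linker("SIA")


class TestDigest:
    def test_tryptic_peptides_with_missed_cleavages(self):
        index = digest(
            {"P": "AKRC"}, missed_cleavages=1, length_range=(1, 50), decoy_mode=None
        )
        seqs = {e.sequence for e in index.entries}
        assert {"AK", "R", "C", "AKR", "RC"} <= seqs
        assert "AKRC" not in seqs  # needs 2 missed cleavages

    def test_no_cleavage_before_proline(self):
        index = digest(
            {"P": "AKPGR"}, missed_cleavages=0, length_range=(1, 50), decoy_mode=None
        )
        assert {e.sequence for e in index.entries} == {"AKPGR"}

    def test_decoy_reverses_keeping_terminus(self):
        index = digest({"P": "MSAKAYEHR"}, length_range=(5, 50))
        decoys = {e.sequence for e in index.entries if e.is_decoy}
        # full-protein reversal keeping the C-terminal residue, re-digested
        assert "HEYAKASMR" in decoys

    def test_empty_database_raises(self):
        with pytest.raises(ValueError):
            digest({})

    def test_invalid_residues_skip_protein_with_warning(self):
        with pytest.warns(UserWarning, match="non-standard"):
            index = digest(
                {"BAD": "AXXKBZR", "GOOD": "GRSAKAYEHR"}, length_range=(5, 50)
            )
        assert all("BAD" not in e.protein_ids for e in index.entries)

    def test_linkable_lysine_must_be_internal_or_protein_cterm(self):
        index = digest(
            {"P": "GGGKAAAK"}, missed_cleavages=1, length_range=(1, 50), decoy_mode=None
        )
        by_seq = {e.sequence: e for e in index.entries}
        assert by_seq["GGGK"].k_sites == ()  # cleaved C-terminal K: not linkable
        assert by_seq["AAAK"].k_sites == (4,)  # protein C-terminus: linkable
        assert by_seq["GGGKAAAK"].k_sites == (4, 8)

    def test_coordinates_are_exact_substrings(self):
        proteins = {"P1": "MSAKAYEHRGGLADVCAHER"}
        index = digest(proteins, length_range=(5, 50))
        for e in index.entries:
            if e.is_decoy:
                continue
            for pid, start in e.locations:
                assert proteins[pid][start - 1 : start - 1 + len(e.sequence)] == e.sequence


def _fig2b_spectrum(extra_peaks=(), precursor=(529.2494, 4)):
    mz = sorted([547.2418, 511.2581, *extra_peaks])
    return Spectrum(
        scan_id=1,
        ms_level=2,
        mz=np.array(mz),
        intensity=np.full(len(mz), 100.0),
        precursor_mz=precursor[0],
        precursor_charge=precursor[1],
    )


class TestSignaturePairs:
    def test_worked_example_pair_recovered(self):
        pairs = detect_signature_pairs(_fig2b_spectrum(), SIA)
        assert len(pairs) == 1
        p = pairs[0]
        assert {round(p.alpha_mz, 4), round(p.beta_mz, 4)} == {547.2418, 511.2581}
        assert p.alpha_charge == 2 and p.beta_charge == 2
        assert abs(p.ppm_error) < 10

    def test_removing_one_member_gives_no_pair(self):
        spec = Spectrum(
            scan_id=1,
            ms_level=2,
            mz=np.array([511.2581]),
            intensity=np.array([100.0]),
            precursor_mz=529.2494,
            precursor_charge=4,
        )
        assert detect_signature_pairs(spec, SIA) == []

    def test_alpha_t_corroboration_assigns_orientation(self):
        # add the dehydrated alpha fragment at alpha_S - H2O/2 (2+)
        spec = _fig2b_spectrum(extra_peaks=(547.2418 - 18.010565 / 2,))
        pairs = detect_signature_pairs(spec, SIA)
        assigned = [p for p in pairs if p.alpha_assigned]
        assert assigned
        assert abs(assigned[0].alpha_mz - 547.2418) < 1e-3

    def test_matches_brute_force_on_random_spectrum(self):
        rng = np.random.default_rng(7)
        mz = np.sort(rng.uniform(200, 1900, size=200))
        spec = Spectrum(
            scan_id=1,
            ms_level=2,
            mz=mz,
            intensity=np.ones(200),
            precursor_mz=700.0,
            precursor_charge=5,
        )
        tol = Tolerances()
        got = detect_signature_pairs(spec, SIA, tol)
        # independent all-pairs scan over every charge hypothesis
        z = 5
        M = mz_to_neutral(700.0, z)
        tol_da = M * tol.ms2_ppm * 1e-6
        expected = set()
        for i in range(len(mz)):
            for j in range(len(mz)):
                if i == j:
                    continue
                for za in range(1, z):
                    for zb in range(1, z):
                        if za + zb > z:
                            continue
                        na = za * (mz[i] - 1.007276)
                        nb = zb * (mz[j] - 1.007276)
                        if abs(na + nb - M) <= tol_da:
                            expected.add(
                                tuple(sorted([(i, za), (j, zb)]))
                            )
        got_keys = set()
        for p in got:
            ia = int(np.searchsorted(mz, p.alpha_mz))
            ib = int(np.searchsorted(mz, p.beta_mz))
            got_keys.add(tuple(sorted([(ia, p.alpha_charge), (ib, p.beta_charge)])))
        assert got_keys == expected

    def test_tightening_tolerance_never_adds_pairs(self):
        rng = np.random.default_rng(3)
        mz = np.sort(rng.uniform(200, 1900, size=150))
        spec = Spectrum(
            scan_id=1,
            ms_level=2,
            mz=mz,
            intensity=np.ones(150),
            precursor_mz=650.0,
            precursor_charge=4,
        )
        counts = [
            len(detect_signature_pairs(spec, SIA, Tolerances(ms2_ppm=ppm)))
            for ppm in (100.0, 50.0, 20.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)


def _ms3_of(peptide: ModifiedPeptide, charge: int, parent=1, scan=2):
    ions = fragment_ladder(peptide, ("b", "y"), max_charge=min(2, charge))
    mzs = np.array(sorted(ion.mz for ion in ions))
    sel = neutral_to_mz(peptide.neutral_mass, charge)
    return Spectrum(
        scan_id=scan,
        ms_level=3,
        mz=mzs,
        intensity=np.full(mzs.size, 50.0),
        precursor_mz=sel,
        precursor_charge=charge,
        parent_scan=parent,
        selected_mz=sel,
    )


class TestMatchMs3:
    def test_noiseless_self_consistency_is_rank_one_with_all_ions(self):
        proteins = {"P1": "GRSAKAYEHRGG"}
        index = digest(proteins, length_range=(5, 50))
        rem = remnants_for(SIA)
        target = ModifiedPeptide("SAKAYEHR", mods=((3, rem.alpha_S_mod),))
        psms = match_ms3(_ms3_of(target, 2), index, SIA)
        assert psms
        top = psms[0]
        assert top.peptide.sequence == "SAKAYEHR"
        assert top.remnant == "alpha_S"
        assert top.site == 3
        assert top.matched == top.total

    def test_peptide_absent_from_index_gives_no_candidates(self):
        index = digest({"P1": "MGGLLLVVVAAR"}, length_range=(5, 50))
        rem = remnants_for(SIA)
        target = ModifiedPeptide("SAKAYEHR", mods=((3, rem.alpha_S_mod),))
        assert match_ms3(_ms3_of(target, 2), index, SIA) == []

    def test_isobaric_candidates_tie_broken_lexicographically(self):
        proteins = {"P1": "GAKYSR", "P2": "AGKYSR"}  # same composition
        index = digest(proteins, length_range=(5, 50), decoy_mode=None)
        rem = remnants_for(SIA)
        prec = neutral_to_mz(
            ModifiedPeptide("GAKYSR", mods=((3, rem.alpha_S_mod),)).neutral_mass, 1
        )
        spec = Spectrum(
            scan_id=9,
            ms_level=3,
            mz=np.array([175.119]),  # y1 only: shared by both candidates
            intensity=np.array([10.0]),
            precursor_mz=prec,
            precursor_charge=1,
            parent_scan=1,
            selected_mz=prec,
        )
        psms = [p for p in match_ms3(spec, index, SIA) if p.remnant == "alpha_S"]
        assert len(psms) == 2
        assert psms[0].score == psms[1].score
        assert psms[0].peptide.sequence == "AGKYSR"  # lexicographic tie-break


def _tiny_config(**kw):
    defaults = dict(seed=11, n_proteins=8, n_crosslinks=4, protein_length=(120, 200))
    defaults.update(kw)
    return SimulationConfig(**defaults)


def _truth_keys(links):
    return {l.key for l in links}


def _found_keys(csms):
    keys = set()
    for c in csms:
        a_pid, a_start = c.alpha.peptide.locations[0]
        b_pid, b_start = c.beta.peptide.locations[0]
        keys.add((a_pid, a_start + c.alpha.site - 1, b_pid, b_start + c.beta.site - 1))
    return keys


class TestIntegrateMsn:
    def test_planted_links_give_tt_csms(self):
        cfg = _tiny_config()
        proteins, links = simulate_proteome(cfg)
        run, _ = simulate_msn_run(cfg, proteins, links)
        index = digest(proteins)
        csms = search_msn(run, index, SIA)
        two_sided = [c for c in csms if not c.single_sided]
        assert _truth_keys(links) <= _found_keys(two_sided)
        assert all(c.decoy_class == "TT" for c in two_sided)

    def test_beta_only_ms3_yields_single_sided_flag(self):
        cfg = _tiny_config(n_crosslinks=1)
        proteins, links = simulate_proteome(cfg)
        run, prov = simulate_msn_run(cfg, proteins, links)
        link = links[0]
        rem = remnants_for(SIA)
        alpha_neutral = (
            ModifiedPeptide(
                link.alpha_seq,
                mods=tuple((i + 1, "carbamidomethyl") for i, c in enumerate(link.alpha_seq) if c == "C"),
            ).neutral_mass
            + rem.alpha_S_mod
        )
        kept = [
            s
            for s in run.spectra
            if s.ms_level != 3
            or abs(mz_to_neutral(s.selected_mz, s.precursor_charge) - alpha_neutral) > 2.0
            and abs(mz_to_neutral(s.selected_mz, s.precursor_charge) - (alpha_neutral - 18.010565)) > 2.0
        ]
        pruned = Run(spectra=kept, linker=run.linker, replicate=run.replicate)
        csms = search_msn(pruned, digest(proteins), SIA)
        assert csms
        assert all(c.single_sided for c in csms)

    def test_perturbed_precursor_fails_mass_integration(self):
        cfg = _tiny_config(n_crosslinks=2)
        proteins, links = simulate_proteome(cfg)
        run, _ = simulate_msn_run(cfg, proteins, links)
        shifted = []
        for s in run.spectra:
            if s.ms_level == 2:
                s = Spectrum(
                    scan_id=s.scan_id,
                    ms_level=2,
                    mz=s.mz,
                    intensity=s.intensity,
                    precursor_mz=s.precursor_mz + 0.5,  # far beyond 10 ppm
                    precursor_charge=s.precursor_charge,
                )
            shifted.append(s)
        bad = Run(spectra=shifted, linker=run.linker, replicate=run.replicate)
        assert [c for c in search_msn(bad, digest(proteins), SIA) if not c.single_sided] == []


class TestSteppedHcd:
    def test_planted_spectrum_ranks_planted_pair_first(self):
        cfg = _tiny_config(mode="ms2", n_crosslinks=3)
        proteins, links = simulate_proteome(cfg)
        run, prov = simulate_msn_run(cfg, proteins, links)
        index = digest(proteins)
        for ms2 in run.by_level(2):
            link = prov[ms2.scan_id]
            ranked = search_ms2_stepped_hcd(ms2, index, SIA)
            assert ranked
            top = ranked[0]
            assert top.alpha.peptide.sequence == link.alpha_seq
            assert top.beta.peptide.sequence == link.beta_seq
            assert top.alpha.site == link.alpha_site
            assert top.beta.site == link.beta_site

    def test_candidates_match_brute_force_double_loop(self):
        cfg = _tiny_config(mode="ms2", n_crosslinks=2, n_proteins=6)
        proteins, links = simulate_proteome(cfg)
        run, _ = simulate_msn_run(cfg, proteins, links)
        index = digest(proteins)
        tol = Tolerances()
        rem = remnants_for(SIA)
        ms2 = run.by_level(2)[0]
        got = {
            (c.alpha.peptide.sequence, c.beta.peptide.sequence)
            for c in search_ms2_stepped_hcd(ms2, index, SIA, use_signature_constraint=False)
        }
        M = mz_to_neutral(ms2.precursor_mz, ms2.precursor_charge)
        expected = set()
        for a in index.entries:
            if not a.k_sites:
                continue
            for b in index.entries:
                if not b.c_sites:
                    continue
                theo = a.mass_all_cam + b.mass_all_cam - CAM + rem.intact_ox_addition
                if abs((M - theo) / theo * 1e6) <= tol.precursor_ppm:
                    expected.add((a.sequence, b.sequence))
        assert got == expected

    def test_unmatchable_precursor_gives_empty_list(self):
        index = digest({"P1": "GRSAKAYEHRGGLADVCAHER"}, length_range=(5, 50))
        spec = Spectrum(
            scan_id=1,
            ms_level=2,
            mz=np.array([300.0, 400.0]),
            intensity=np.array([1.0, 1.0]),
            precursor_mz=100.0,
            precursor_charge=4,
        )
        assert search_ms2_stepped_hcd(spec, index, SIA) == []


def _fake_csm(score, cls, scan=0):
    entry_kw = dict(
        locations=(("P", 1),),
        missed_cleavages=0,
        k_sites=(2,),
        c_sites=(),
        shared_with_target=False,
    )
    from kcxlink.identify import IndexedPeptide

    a = IndexedPeptide(sequence="AKAR", is_decoy=cls[0] == "D", **entry_kw)
    b_kw = dict(entry_kw, k_sites=(), c_sites=(2,))
    b = IndexedPeptide(sequence="ACAR", is_decoy=cls[1] == "D", **b_kw)
    pa = PeptideSpectrumMatch(scan, a, 2, "alpha_S", score / 2, 3, 6, 0.1)
    pb = PeptideSpectrumMatch(scan, b, 2, "beta_A", score / 2, 3, 6, 0.1)
    return CrossLinkSpectrumMatch(scan, pa, pb, score, 0.1, "SIA", "rep1", "msn")


class TestFdr:
    def test_direct_arithmetic_one_td_in_hundred(self):
        csms = [_fake_csm(10.0, "TT", i) for i in range(100)] + [_fake_csm(5.0, "TD", 100)]
        result = estimate_fdr(csms)
        # at the loosest threshold: (1 TD - 0 DD) / 100 TT = 1%
        assert math.isclose(result.qvalues.max(), 0.01, abs_tol=1e-12)

    def test_all_decoys_caps_at_one(self):
        csms = [_fake_csm(5.0, "TD", i) for i in range(10)]
        result = estimate_fdr(csms)
        assert result.qvalues.max() == 1.0

    def test_qvalues_monotone_in_score(self):
        rng = np.random.default_rng(1)
        csms = [
            _fake_csm(float(rng.uniform(0, 20)), rng.choice(["TT", "TT", "TT", "TD", "DD"]), i)
            for i in range(200)
        ]
        result = estimate_fdr(csms)
        order = np.argsort(-result.scores)
        q = result.qvalues[order]
        assert np.all(np.diff(q) >= -1e-12)

    def test_dd_corrects_td_count(self):
        csms = (
            [_fake_csm(10.0, "TT", i) for i in range(50)]
            + [_fake_csm(9.0, "TD", 50)]
            + [_fake_csm(8.0, "DD", 51)]
        )
        result = estimate_fdr(csms)
        # TD and DD cancel: (1 - 1)/50 = 0
        assert result.qvalues.min() == 0.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            estimate_fdr([])

    def test_search_without_decoys_is_undefined(self):
        with pytest.raises(ValueError, match="without decoys"):
            estimate_fdr([_fake_csm(10.0, "TT")], decoys_searched=False)


class TestLinkageAggregation:
    def test_same_residues_collapse_with_support_two(self):
        proteins = {"P": "GRSAKAYEHRGGLADVCAHER"}
        csms = []
        index = digest(proteins, length_range=(5, 50), decoy_mode=None)
        by_seq = {e.sequence: e for e in index.entries}
        a, b = by_seq["SAKAYEHR"], by_seq["GGLADVCAHER"]
        for scan in (1, 2):
            pa = PeptideSpectrumMatch(scan, a, 3, "alpha_S", 10.0, 5, 10, 0.1)
            pb = PeptideSpectrumMatch(scan, b, 7, "beta_A", 10.0, 5, 10, 0.1)
            csms.append(CrossLinkSpectrumMatch(scan, pa, pb, 20.0, 0.1, "SIA", "rep1", "msn"))
        links = collapse_to_unique_linkages(csms, proteins)
        assert len(links) == 1
        link = links[0]
        assert link.csm_count == 2
        assert link.is_intra
        assert proteins["P"][link.residue_k - 1] == "K"
        assert proteins["P"][link.residue_c - 1] == "C"

    def test_shared_peptide_sets_ambiguity_flag(self):
        proteins = {"P1": "GRSAKAYEHRGG", "P2": "GRSAKAYEHRTT", "P3": "LADVCAHER"}
        index = digest(proteins, length_range=(5, 50), decoy_mode=None)
        by_seq = {e.sequence: e for e in index.entries}
        shared = by_seq["SAKAYEHR"]
        assert len(shared.locations) == 2
        pa = PeptideSpectrumMatch(1, shared, 3, "alpha_S", 10.0, 5, 10, 0.1)
        pb = PeptideSpectrumMatch(1, by_seq["LADVCAHER"], 5, "beta_A", 10.0, 5, 10, 0.1)
        csm = CrossLinkSpectrumMatch(1, pa, pb, 20.0, 0.1, "SIA", "rep1", "msn")
        (link,) = collapse_to_unique_linkages([csm], proteins)
        assert link.ambiguous
        assert set(link.protein_a_candidates) == {"P1", "P2"}

    def test_corrupt_mapping_raises(self):
        proteins = {"P": "GRSAKAYEHRGGLADVCAHER"}
        index = digest(proteins, length_range=(5, 50), decoy_mode=None)
        by_seq = {e.sequence: e for e in index.entries}
        pa = PeptideSpectrumMatch(1, by_seq["SAKAYEHR"], 2, "alpha_S", 10.0, 5, 10, 0.1)
        pb = PeptideSpectrumMatch(1, by_seq["GGLADVCAHER"], 7, "beta_A", 10.0, 5, 10, 0.1)
        csm = CrossLinkSpectrumMatch(1, pa, pb, 20.0, 0.1, "SIA", "rep1", "msn")
        with pytest.raises(ValueError, match="corruption"):
            collapse_to_unique_linkages([csm], proteins)


class TestReproducibilityFilter:
    def _link(self, support):
        from kcxlink.identify import UniqueLinkage

        return UniqueLinkage("A", 3, "B", 5, False, support=dict.fromkeys(support, 1))

    def test_two_replicates_same_linker_kept(self):
        link = self._link([("SIA", "rep1"), ("SIA", "rep2")])
        assert reproducibility_filter([link]) == [link]

    def test_single_replicates_of_different_linkers_dropped(self):
        link = self._link([("SIA", "rep1"), ("SBAP", "rep1")])
        assert reproducibility_filter([link]) == []

    def test_min_one_is_identity(self):
        links = [self._link([("SIA", "rep1")]), self._link([("SBAP", "rep2")])]
        assert reproducibility_filter(links, min_replicates=1) == links
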