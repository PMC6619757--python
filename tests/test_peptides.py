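"""Peptide mapping: digestion rules, fragment arithmetic, search and FDR
behaviour, coverage, apex quantification and glycopeptide detection."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from mamkit import masschem as mc
from mamkit import peptides as pep
from mamkit.containers import RawRun, RawSpectrum

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestDigest:
    def test_no_cleavage_before_proline(self):
        seqs = [p.sequence for p in pep.digest("AKRPGKR", 0)]
        assert seqs == ["AK", "RPGK", "R"]

    def test_one_missed_cleavage_adds_joined_peptides(self):
        seqs = {p.sequence for p in pep.digest("AKRPGKR", 1)}
        assert seqs == {"AK", "RPGK", "R", "AKRPGK", "RPGKR"}

    def test_no_cut_sites_whole_sequence(self):
        out = pep.digest("MNQSTV", 0)
        assert len(out) == 1 and out[0].sequence == "MNQSTV"

    @given(seq=st.text(AA, min_size=1, max_size=60))
    @hyp_settings(deadline=None, max_examples=60)
    def test_zero_missed_digest_partitions_chain(self, seq):
        zero = [p for p in pep.digest(seq, 0) if p.missed_cleavages == 0]
        assert "".join(p.sequence for p in zero) == seq
        spans = [(p.start, p.end) for p in zero]
        assert spans == sorted(spans)


class TestFragments:
    def test_b1_of_glycine(self):
        ions = dict(pep.theoretical_fragments("GAS", charges=(1,)))
        assert ions["b1^1"] == pytest.approx(58.0287, abs=1e-3)

    def test_b_y_pairs_sum_to_precursor_mass(self):
        seq = "EEQYNSTYR"
        mass = mc.chain_mass(seq)
        ions = dict(pep.theoretical_fragments(seq, charges=(1,)))
        for i in range(1, len(seq)):
            total = (ions[f"b{i}^1"] - mc.PROTON) + (ions[f"y{len(seq)-i}^1"]
                                                     - mc.PROTON)
            assert total == pytest.approx(mass, abs=1e-6)

    def test_nterm_pyroglu_shifts_b_not_y(self):
        seq = "QVQLQESGPGLVK"
        spec = mc.MODIFICATIONS["Gln->pyro-Glu"]
        plain = dict(pep.theoretical_fragments(seq, charges=(1,)))
        modded = dict(pep.theoretical_fragments(seq, ((spec, 0),), charges=(1,)))
        for i in range(1, len(seq)):
            assert modded[f"b{i}^1"] - plain[f"b{i}^1"] == pytest.approx(
                -17.0266, abs=1e-3)
            assert modded[f"y{len(seq)-i}^1"] == pytest.approx(
                plain[f"y{len(seq)-i}^1"], abs=1e-9)

    def test_mod_on_wrong_residue_rejected(self):
        spec = mc.MODIFICATIONS["Deamidated"]
        with pytest.raises(ValueError):
            pep.theoretical_fragments("GAS", ((spec, 2),))


def spectrum_for(form: pep.PeptideForm, charge=2, scan_id=1, rt=100.0):
    """Noiseless MS2 built from the form's own theoretical ladder."""
    mzs = np.array(sorted(mz for _, mz in pep.theoretical_fragments(
        form.peptide.sequence, form.mods)))
    return RawSpectrum(scan_id, 2, rt, mzs, np.full(len(mzs), 100.0),
                       precursor_mz=mc.mz_from_mass(form.mass(), charge),
                       precursor_charge=charge)


class TestSearch:
    CHAINS = {"light": "EIVLTQSPGTKAAAGSGTDFTLTISK",
              "heavy": "QVQLQESGPGLVKAPELLGGPSVFLK"}

    def test_noiseless_spectrum_scores_one(self):
        target = pep.digest(self.CHAINS["heavy"], 0, "heavy")[0]
        form = pep.PeptideForm(target)
        run = RawRun(spectra=[spectrum_for(form)])
        psms = pep.search(run, self.CHAINS)
        assert len(psms) == 1
        best = psms[0]
        assert best.form.peptide.sequence == target.sequence
        assert not best.decoy
        assert best.score == pytest.approx(1.0)

    def test_decoy_scores_below_target_on_real_spectrum(self):
        target = pep.digest(self.CHAINS["light"], 0, "light")[0]
        form = pep.PeptideForm(target)
        run = RawRun(spectra=[spectrum_for(form)])
        forms = pep.build_form_database(self.CHAINS, [], with_decoys=True)
        decoys = [f for f in forms if f.decoy
                  and len(f.peptide.sequence) == len(target.sequence)]
        spec_mz = np.sort(run.spectra[0].mz)
        target_score = 1.0
        for d in decoys:
            theo = np.array([m for _, m in pep.theoretical_fragments(
                d.peptide.sequence, d.mods)])
            score = pep._matched_count(theo, spec_mz, 0.02) / len(theo)
            assert score < target_score

    def test_empty_run_empty_result(self):
        assert pep.search(RawRun(), self.CHAINS) == []


class TestFdrFilter:
    def make(self, score, decoy):
        form = pep.PeptideForm(pep.PeptideSpec("AK", "decoy_x" if decoy else "x",
                                               1, 2, 0), decoy=decoy)
        return pep.PeptideSpectrumMatch(form, 1, 0.0, 100.0, 2, score, 1, 1)

    def as_list(self, psms):
        out = pep.PSMList(psms)
        out.decoys_searched = True
        return out

    def test_no_decoys_above_threshold_q_zero(self):
        psms = self.as_list([self.make(0.9, False), self.make(0.8, False),
                             self.make(0.1, True)])
        accepted = pep.fdr_filter(psms, q_max=0.05)
        assert [p.score for p in accepted] == [0.9, 0.8]
        assert all(p.q_value == 0.0 for p in accepted)

    def test_one_decoy_ten_targets_q_is_point_one(self):
        psms = self.as_list([self.make(0.5 + i / 100, False) for i in range(10)]
                            + [self.make(0.99, True)])
        pep.fdr_filter(psms, q_max=1.0)
        worst = min(psms, key=lambda p: p.score)
        assert worst.q_value == pytest.approx(0.1)

    def test_all_decoys_outscore_targets_empty(self):
        psms = self.as_list([self.make(0.9, True), self.make(0.8, True),
                             self.make(0.1, False)])
        assert pep.fdr_filter(psms, q_max=0.05) == []

    def test_no_decoys_searched_rejected(self):
        psms = pep.PSMList([self.make(0.9, False)])
        psms.decoys_searched = False
        with pytest.raises(ValueError):
            pep.fdr_filter(psms)


class TestCoverage:
    def test_partial_and_full_and_empty(self):
        chain = "A" * 100
        spans = [pep.PeptideSpec("A" * 50, "c", 1, 50, 0),
                 pep.PeptideSpec("A" * 48, "c", 51, 98, 0)]
        psms = [pep.PeptideSpectrumMatch(pep.PeptideForm(s), 1, 0.0, 1.0, 2,
                                         1.0, 1, 1) for s in spans]
        assert pep.sequence_coverage(psms, chain, "c") == pytest.approx(98.0)
        full = psms + [pep.PeptideSpectrumMatch(
            pep.PeptideForm(pep.PeptideSpec("AA", "c", 99, 100, 0)),
            1, 0.0, 1.0, 2, 1.0, 1, 1)]
        assert pep.sequence_coverage(full, chain, "c") == pytest.approx(100.0)
        assert pep.sequence_coverage([], chain, "c") == 0.0


class TestModificationQuant:
    def test_pyroglu_fractions_recovered(self, peptide_analysis, model):
        per_form = peptide_analysis["per_form"]
        heavy = pep.base_peptide_fraction(per_form, "heavy", 1, "Gln->pyro-Glu")
        light = pep.base_peptide_fraction(per_form, "light", 1, "Glu->pyro-Glu")
        assert heavy * 100 == pytest.approx(model.heavy_pyroglu_fraction * 100,
                                            abs=2.0)
        assert light * 100 == pytest.approx(model.light_pyroglu_fraction * 100,
                                            abs=2.0)

    def test_site_mod_fraction_recovered(self, peptide_analysis, model, digest_run):
        site = model.ptm_sites[0]  # heavy-chain NG deamidation hot spot
        per_form = peptide_analysis["per_form"]
        sel = per_form[(per_form.chain == site.chain)
                       & (per_form.start <= site.position)
                       & (per_form.end >= site.position)
                       & (per_form.start > 1)]
        base_starts = sorted(set(sel.start))
        assert base_starts, "hot-spot peptide was not identified"
        frac = pep.base_peptide_fraction(per_form, site.chain, base_starts[0],
                                         "Deamidated")
        assert frac * 100 == pytest.approx(site.fraction * 100, abs=3.0)

    def test_report_abundances_within_bounds(self, peptide_analysis):
        for row in peptide_analysis["modification_report"]:
            assert 0.0 <= row.relative_abundance <= 100.0
            assert row.n_modified_peptides >= 1


class TestGlycopeptides:
    def test_sequon_detection(self):
        assert pep.has_sequon("EEQYNSTYR")
        assert not pep.has_sequon("EEQYNPTYR")  # proline blocks the sequon
        assert not pep.has_sequon("EEQYASTYR")

    def test_precursor_arithmetic_matches_simulator(self, digest_run):
        theo = (mc.chain_mass("EEQYNSTYR") + mc.glycan_mass(mc.glycan("G0F"))
                + 2 * mc.PROTON) / 2
        assert theo == pytest.approx(1317.527, abs=1e-3)
        simulated = digest_run.truth["glycopeptide_precursors"]["G0F/2+"]
        assert abs(theo - simulated) < 1e-3

    def test_detected_glycoforms_on_sequon_peptide(self, peptide_analysis):
        quant = peptide_analysis["glycopeptide_quant"]
        assert set(quant.glycan) >= {"G0F", "G1F"}
        assert all("N" in s for s in quant.peptide)
        assert quant.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_scans_without_oxonium_not_assigned(self, digest_run, model):
        digest_peps = [p for p in pep.digest(model.heavy_chain, 1, "heavy")
                       if len(p.sequence) >= 2]
        assignments, _ = pep.detect_glycopeptides(digest_run, digest_peps,
                                                  [mc.glycan("G0F")])
        marker_scans = {s.scan_id for s in digest_run.ms2()
                        if len(s.mz) and np.any(np.abs(s.mz - mc.OXONIUM_HEXNAC) <= 0.02)}
        assert assignments
        assert all(a.scan_id in marker_scans for a in assignments)

    def test_empty_library_rejected(self, digest_run):
        with pytest.raises(ValueError):
            pep.detect_glycopeptides(digest_run, [], [])
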