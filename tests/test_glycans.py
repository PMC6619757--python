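"""Free-glycan identification: composition enumeration vs a brute-force
oracle, oxonium prefiltering, fragment confirmation, XIC isomer counting and
relative quantification."""

import itertools

import numpy as np
import pytest

from mamkit import glycans as gly
from mamkit import masschem as mc
from mamkit.containers import RawRun, RawSpectrum


def brute_force_compositions(target, settings):
    """Independent nested-loop lattice scan (the enumeration oracle)."""
    mono = {n: mc.TABLE.sugar_mass(n)
            for n in ("Hex", "HexNAc", "dHex", "NeuAc", "NeuGc")}
    tol = target * settings.ppm * 1e-6
    out = set()
    for h, n, f, s, g in itertools.product(
            range(settings.max_hex + 1), range(settings.max_hexnac + 1),
            range(settings.max_dhex + 1), range(settings.max_neuac + 1),
            range(settings.max_neugc + 1)):
        mass = (h * mono["Hex"] + n * mono["HexNAc"] + f * mono["dHex"]
                + s * mono["NeuAc"] + g * mono["NeuGc"] + mc.WATER_MONO)
        if abs(mass - target) <= tol:
            out.add((h, n, f, s, g))
    return out


class TestEnumerateCompositions:
    def test_g0f_free_mass_found(self):
        hits = gly.enumerate_compositions(1462.5444)
        labels = [c.label for c, _ in hits]
        assert "G0F" in labels

    def test_single_hexose(self):
        hits = gly.enumerate_compositions(180.0634)
        assert hits[0][0].counts == (1, 0, 0, 0, 0)

    def test_mass_without_composition_empty(self):
        assert gly.enumerate_compositions(100.0) == []

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            gly.enumerate_compositions(0.0)

    def test_matches_brute_force_oracle_on_random_masses(self):
        settings = gly.CompositionSearchSettings()
        rng = np.random.default_rng(2019)
        for target in rng.uniform(500.0, 3500.0, 100):
            ours = {c.counts for c, _ in gly.enumerate_compositions(target, settings)}
            assert ours == brute_force_compositions(target, settings)

    def test_tightening_ppm_never_adds_compositions(self):
        rng = np.random.default_rng(7)
        for target in rng.uniform(500.0, 3500.0, 25):
            wide = {c.counts for c, _ in gly.enumerate_compositions(
                target, gly.CompositionSearchSettings(ppm=10.0))}
            tight = {c.counts for c, _ in gly.enumerate_compositions(
                target, gly.CompositionSearchSettings(ppm=2.0))}
            assert tight <= wide

    def test_results_sorted_by_abs_ppm(self):
        hits = gly.enumerate_compositions(1462.60, gly.CompositionSearchSettings(ppm=80))
        errs = [abs(p) for _, p in hits]
        assert errs == sorted(errs)


def ms2(mzs, scan_id=1, pmz=None, z=None):
    arr = np.sort(np.asarray(mzs, dtype=float))
    return RawSpectrum(scan_id, 2, 60.0, arr, np.full(len(arr), 50.0),
                       precursor_mz=pmz, precursor_charge=z)


class TestOxoniumPrefilter:
    def test_marker_scan_retained_with_labels(self):
        run = RawRun(spectra=[ms2([204.0867, 500.0]), ms2([400.0, 500.0], 2)])
        kept = gly.oxonium_prefilter(run)
        assert len(kept) == 1
        scan, hits = kept[0]
        assert scan.scan_id == 1 and hits == ("HexNAc+",)

    def test_sialic_marker_flagged(self):
        run = RawRun(spectra=[ms2([292.1027])])
        _, hits = gly.oxonium_prefilter(run)[0]
        assert hits == ("NeuAc+",)


class TestConfirmByFragments:
    def test_own_fragments_fully_matched(self):
        comp = mc.glycan("G0F")
        ions = sorted({round(m, 4) for _, m in gly.fragment_ions(comp)})
        scan = ms2(ions)
        assert gly.confirm_by_fragments(scan, comp) == len(ions)

    def test_fucosylated_candidate_scores_lower_on_afucosylated_spectrum(self):
        # the fucosylated ladder is a superset: same matches, lower fraction
        g0 = mc.glycan("G0")
        g0f = mc.glycan("G0F")
        scan = ms2(sorted({round(m, 4) for _, m in gly.fragment_ions(g0)}))
        _, frac_g0 = gly.fragment_match_stats(scan, g0)
        _, frac_g0f = gly.fragment_match_stats(scan, g0f)
        assert frac_g0f < frac_g0 == 1.0

    def test_empty_scan_zero(self):
        assert gly.confirm_by_fragments(ms2([]), mc.glycan("G0F")) == 0


class TestXic:
    def run_with_elution(self, mz, apex_times, width=6.0, height=1000.0):
        spectra = []
        times = np.arange(0.0, 400.0, 2.0)
        for i, t in enumerate(times):
            inten = sum(height * np.exp(-0.5 * ((t - a) / width) ** 2)
                        for a in apex_times)
            if inten > 1.0:
                spectra.append(RawSpectrum(i + 1, 1, t, np.array([mz]),
                                           np.array([inten])))
            else:
                spectra.append(RawSpectrum(i + 1, 1, t, np.empty(0), np.empty(0)))
        return RawRun(spectra=spectra)

    def test_two_elution_peaks_counted_as_two_isomers(self):
        run = self.run_with_elution(732.28, [100.0, 200.0])
        assert gly.xic(run, 732.28).isomer_count == 2

    def test_four_offsets_counted_as_four(self):
        run = self.run_with_elution(941.35, [80.0, 140.0, 200.0, 260.0])
        assert gly.xic(run, 941.35).isomer_count == 4

    def test_flat_chromatogram_empty(self):
        run = self.run_with_elution(732.28, [])
        chrom = gly.xic(run, 732.28)
        assert chrom.isomer_count == 0 and chrom.peak_areas == []

    def test_areas_scale_with_intensity(self):
        a = gly.xic(self.run_with_elution(732.28, [100.0], height=1000.0), 732.28)
        b = gly.xic(self.run_with_elution(732.28, [100.0], height=3000.0), 732.28)
        assert b.total_area == pytest.approx(3 * a.total_area, rel=1e-3)


class TestRelativeQuant:
    def assignment(self, name, area, isomers=1):
        return gly.GlycanAssignment(mc.glycan(name), 732.0, 2, 0.0, 5, area,
                                    isomers)

    def test_normalization_example(self):
        table = gly.relative_glycan_quant(
            [self.assignment("G0F", 73.0), self.assignment("G1F", 18.0),
             self.assignment("G2F", 9.0)])
        pcts = dict(zip(table.composition, table.percent))
        assert pcts["G0F"] == pytest.approx(73.0)
        assert table.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_composition_100(self):
        table = gly.relative_glycan_quant([self.assignment("G0F", 1.0)])
        assert table.percent.iloc[0] == pytest.approx(100.0)

    def test_charge_states_pooled_per_composition(self):
        a2 = self.assignment("G0F", 60.0)
        a3 = gly.GlycanAssignment(mc.glycan("G0F"), 488.3, 3, 0.0, 5, 40.0, 1)
        table = gly.relative_glycan_quant([a2, a3])
        assert len(table) == 1 and table.area.iloc[0] == pytest.approx(100.0)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            gly.relative_glycan_quant([self.assignment("G0F", 0.0)])

    def test_isomer_count_validated(self):
        with pytest.raises(ValueError):
            gly.GlycanAssignment(mc.glycan("G0F"), 732.0, 2, 0.0, 5, 1.0, 0)


class TestEndToEnd:
    def test_identified_set_matches_simulated_truth(self, glycan_run,
                                                    glycan_analysis):
        truth = {e["composition"]: e for e in glycan_run.truth["profile"]}
        quant = glycan_analysis["quant"]
        assert set(quant.composition) == set(truth)
        for _, row in quant.iterrows():
            assert row.percent == pytest.approx(
                truth[row.composition]["fraction"] * 100, abs=3.0)

    def test_isomer_counts_match_truth(self, glycan_run, glycan_analysis):
        truth = {e["composition"]: e["isomers"]
                 for e in glycan_run.truth["profile"]}
        quant = glycan_analysis["quant"]
        for _, row in quant.iterrows():
            assert row.isomers == truth[row.composition]

    def test_quant_invariant_to_global_scaling(self, glycan_run):
        scaled = RawRun(name="scaled", truth=glycan_run.truth)
        for s in glycan_run.spectra:
            scaled.spectra.append(RawSpectrum(
                s.scan_id, s.ms_level, s.rt, s.mz, s.intensity * 13.7,
                s.precursor_mz, s.precursor_charge))
        from mamkit import pipeline as pipe
        q1 = pipe.analyze_glycan_level(glycan_run)["quant"]
        q2 = pipe.analyze_glycan_level(scaled)["quant"]
        merged = q1.merge(q2, on="composition", suffixes=("_a", "_b"))
        assert np.allclose(merged.percent_a, merged.percent_b, atol=1e-6)
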