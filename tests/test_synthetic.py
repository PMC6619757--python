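"""Synthetic-run generator: seed determinism, model validation, construction
invariants, and the ground-truth sidecar every recovery test relies on."""

from dataclasses import replace

import numpy as np
import pytest

from mamkit import masschem as mc
from mamkit import synthetic as syn


def runs_identical(a, b):
    if len(a) != len(b):
        return False
    for x, y in zip(a.spectra, b.spectra):
        if (x.ms_level != y.ms_level or x.rt != y.rt
                or not np.array_equal(x.mz, y.mz)
                or not np.array_equal(x.intensity, y.intensity)
                or x.precursor_mz != y.precursor_mz):
            return False
    return True


class TestModelValidation:
    def test_default_model_embeds_sequon_peptide(self, model):
        assert "EEQYNSTYR" in model.heavy_chain
        assert model.heavy_chain[model.glycosite - 1] == "N"
        assert model.heavy_chain[0] == "Q" and model.light_chain[0] == "E"

    def test_profile_fractions_sum_to_one(self, model):
        assert sum(f for _, f in model.glycan_profile) == pytest.approx(1.0,
                                                                        abs=1e-9)

    def test_bad_profile_rejected(self, model):
        with pytest.raises(ValueError, match="sum"):
            replace(model, glycan_profile=((mc.glycan("G0F"), 0.5),))

    def test_fraction_out_of_range_rejected(self, model):
        with pytest.raises(ValueError):
            replace(model, heavy_pyroglu_fraction=1.5)

    def test_glycosite_must_be_asparagine(self, model):
        with pytest.raises(ValueError, match="must be N"):
            replace(model, glycosite=1)  # heavy chain starts with Q

    def test_empty_profile_untreated_run_rejected(self, model):
        bare = replace(model, glycan_profile=())
        with pytest.raises(ValueError):
            syn.simulate_intact_run(bare, syn.intact_settings())
        syn.simulate_intact_run(bare, syn.intact_settings(n_scans=2),
                                pngase_treated=True)  # treated run is fine


class TestDeterminism:
    def test_intact_byte_identical_under_seed(self, model):
        s = syn.intact_settings(seed=99, n_scans=5)
        assert runs_identical(syn.simulate_intact_run(model, s),
                              syn.simulate_intact_run(model, s))

    def test_different_seed_differs(self, model):
        a = syn.simulate_intact_run(model, syn.intact_settings(seed=1, n_scans=5))
        b = syn.simulate_intact_run(model, syn.intact_settings(seed=2, n_scans=5))
        assert not runs_identical(a, b)

    def test_digest_byte_identical_under_seed(self, model):
        s = syn.digest_settings(seed=99, run_length_s=120.0)
        assert runs_identical(syn.simulate_digest_run(model, s),
                              syn.simulate_digest_run(model, s))

    def test_glycan_byte_identical_under_seed(self):
        s = syn.glycan_settings(seed=99, run_length_s=150.0)
        assert runs_identical(syn.simulate_glycan_run(settings=s),
                              syn.simulate_glycan_run(settings=s))


class TestIntactConstruction:
    def test_noiseless_sticks_on_charge_grid(self, model):
        s = syn.intact_settings(noise_level=0.0, n_noise_peaks=0, jitter=0.0,
                                n_scans=1)
        run = syn.simulate_intact_run(model, s)
        masses = [sp["mass"] for sp in run.truth["species"]]
        scan = run.spectra[0]
        for mz in scan.mz:
            ok = any(abs(mc.mz_from_mass(m, z) - mz) < 1e-9
                     for m in masses for z in range(30, 80))
            assert ok, f"stick {mz} not on any species' charge grid"

    def test_truth_groups_cover_unordered_pairs(self, model):
        run = syn.simulate_intact_run(model, syn.intact_settings(n_scans=2))
        groups = set(run.truth["groups"])
        assert {"G0F/G0F", "G0F/G1F", "G1F/G1F"} <= groups
        assert run.truth["base_group"] == "G0F/G0F"

    def test_pngase_collapses_heterogeneity(self, model):
        before = syn.simulate_intact_run(model, syn.intact_settings(n_scans=2))
        after = syn.simulate_intact_run(model, syn.intact_settings(n_scans=2),
                                        pngase_treated=True)
        assert len(after.truth["groups"]) < len(before.truth["groups"])
        shift = (before.truth["base_cluster_apex"]
                 - after.truth["base_cluster_apex"])
        two_g0f = 2 * (mc.glycan("G0F").residue_mass("average")
                       - mc.MODIFICATIONS["Deamidated"].delta_avg)
        assert shift == pytest.approx(two_g0f, abs=2.0)


class TestReducedConstruction:
    def test_light_chain_unaffected_by_pngase(self, model):
        s = syn.reduced_settings(n_scans=2)
        before = syn.simulate_reduced_run(model, s)
        after = syn.simulate_reduced_run(model, s, pngase_treated=True)
        assert before.truth["light_cluster_mass"] == pytest.approx(
            after.truth["light_cluster_mass"], abs=1e-9)

    def test_heavy_shift_is_one_g0f(self, model):
        s = syn.reduced_settings(n_scans=2)
        before = syn.simulate_reduced_run(model, s)
        after = syn.simulate_reduced_run(model, s, pngase_treated=True)
        shift = (before.truth["base_heavy_cluster_apex"]
                 - after.truth["base_heavy_cluster_apex"])
        one_g0f = (mc.glycan("G0F").residue_mass("average")
                   - mc.MODIFICATIONS["Deamidated"].delta_avg)
        assert shift == pytest.approx(one_g0f, abs=1.0)

    def test_zero_width_envelope_single_charge(self, model):
        s = syn.reduced_settings(charge_sigma=1e-6, noise_level=0.0,
                                 n_noise_peaks=0, jitter=0.0, n_scans=1)
        run = syn.simulate_reduced_run(
            replace(model, formic_adduct_fraction=0.0,
                    heavy_pyroglu_fraction=1.0, light_pyroglu_fraction=0.0,
                    glycan_profile=((mc.glycan("G0F"), 1.0),)), s)
        assert len(run.spectra[0].mz) == 2  # one stick per chain


class TestDigestConstruction:
    def test_truth_form_fractions_sum_to_one(self, digest_run):
        for entry in digest_run.truth["peptides"].values():
            assert sum(entry["forms"].values()) == pytest.approx(1.0, abs=1e-6)

    def test_glycopeptide_ms2_contains_hexnac_oxonium(self, digest_run):
        gp_mzs = set(round(v, 3) for v in
                     digest_run.truth["glycopeptide_precursors"].values())
        flagged = 0
        for scan in digest_run.ms2():
            if scan.precursor_mz is not None and round(scan.precursor_mz, 3) in gp_mzs:
                flagged += 1
                assert np.any(np.abs(scan.mz - mc.OXONIUM_HEXNAC) <= 0.02)
        assert flagged > 0

    def test_ida_respects_charge_filter_and_threshold(self, model):
        s = syn.digest_settings(seed=3, run_length_s=600.0)
        run = syn.simulate_digest_run(model, s)
        for scan in run.ms2():
            assert s.ida_charge_min <= scan.precursor_charge <= s.ida_charge_max

    def test_clean_ms2_is_pure_by_ladder(self, model):
        from mamkit import peptides as pep
        bare = replace(model, ptm_sites=(), heavy_pyroglu_fraction=0.0,
                       light_pyroglu_fraction=0.0, glycosite=0,
                       formic_adduct_fraction=0.0)
        s = syn.digest_settings(seed=4, noise_level=0.0)
        run = syn.simulate_digest_run(bare, s)
        checked = 0
        for scan in run.ms2()[:20]:
            neutral = mc.mass_from_mz(scan.precursor_mz, scan.precursor_charge)
            # find the simulated peptide by mass among all digest forms
            match = None
            for chain in ("heavy", "light"):
                for p in pep.digest(bare.chain(chain), 1, chain):
                    if len(p.sequence) < 2:
                        continue
                    cam = mc.MODIFICATIONS["Carbamidomethyl"]
                    mods = [(cam, 1)] * p.sequence.count("C")
                    if abs(mc.chain_mass(p.sequence, "mono", mods) - neutral) < 0.01:
                        match = (p, mods)
                if match:
                    break
            assert match is not None
            p, mods = match
            theo = np.array([m for _, m in pep.theoretical_fragments(
                p.sequence, tuple((spec, i + 1) for i, a in enumerate(p.sequence)
                                  if a == "C" for spec in [cam]))])
            significant = scan.mz[scan.intensity > 1e-3 * scan.intensity.max()]
            for mz in significant:
                assert np.min(np.abs(theo - mz)) < 0.02
            checked += 1
        assert checked > 0


class TestGlycanRunConstruction:
    def test_default_profile_normalized_with_14_compositions(self):
        profile = syn.default_glycan_profile()
        assert len(profile) == 14
        assert sum(f for _, f, _ in profile) == pytest.approx(1.0, abs=1e-9)

    def test_bad_isomer_count_rejected(self):
        profile = [(mc.glycan("G0F"), 1.0, 0)]
        with pytest.raises(ValueError):
            syn.simulate_glycan_run(profile, syn.glycan_settings())

    def test_unnormalized_profile_rejected(self):
        profile = [(mc.glycan("G0F"), 0.7, 1)]
        with pytest.raises(ValueError):
            syn.simulate_glycan_run(profile, syn.glycan_settings())

    def test_g0f_precursor_at_expected_mz(self, glycan_run):
        truth = {e["composition"]: e for e in glycan_run.truth["profile"]}
        assert truth["G0F"]["precursor_2plus"] == pytest.approx(732.2795,
                                                                abs=1e-3)

    def test_single_composition_quantifies_to_100(self):
        from mamkit import pipeline as pipe
        run = syn.simulate_glycan_run([(mc.glycan("G0F"), 1.0, 2)],
                                      syn.glycan_settings(seed=8,
                                                          run_length_s=300.0))
        quant = pipe.analyze_glycan_level(run)["quant"]
        assert len(quant) == 1
        assert quant.percent.iloc[0] == pytest.approx(100.0)
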