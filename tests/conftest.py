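"""Shared fixtures: the default IgG model and one simulated+analysed run per
characterization level (session-scoped; several tests interrogate each)."""

import pytest

from mamkit import pipeline as pipe
from mamkit import synthetic as syn


@pytest.fixture(scope="session")
def model():
    return syn.IgGModel.default()


@pytest.fixture(scope="session")
def intact_runs(model):
    before = syn.simulate_intact_run(model, syn.intact_settings(seed=11))
    after = syn.simulate_intact_run(model, syn.intact_settings(seed=12),
                                    pngase_treated=True)
    return before, after


@pytest.fixture(scope="session")
def intact_analysis(model, intact_runs):
    before, after = intact_runs
    return pipe.analyze_protein_level(before, after, model.light_chain,
                                      model.heavy_chain, pipe.DEFAULT_LIBRARY,
                                      "intact")


@pytest.fixture(scope="session")
def reduced_runs(model):
    before = syn.simulate_reduced_run(model, syn.reduced_settings(seed=13))
    after = syn.simulate_reduced_run(model, syn.reduced_settings(seed=14),
                                     pngase_treated=True)
    return before, after


@pytest.fixture(scope="session")
def reduced_analysis(model, reduced_runs):
    before, after = reduced_runs
    return pipe.analyze_reduced_level(before, after, model.light_chain,
                                      model.heavy_chain, pipe.DEFAULT_LIBRARY,
                                      rel_min=0.1, quant_threshold_pct=0.1)


@pytest.fixture(scope="session")
def digest_run(model):
    return syn.simulate_digest_run(model, syn.digest_settings(seed=15))


@pytest.fixture(scope="session")
def peptide_analysis(model, digest_run):
    return pipe.analyze_peptide_level(digest_run, model.light_chain,
                                      model.heavy_chain, pipe.DEFAULT_LIBRARY)


@pytest.fixture(scope="session")
def glycan_run():
    return syn.simulate_glycan_run(settings=syn.glycan_settings(seed=16))


@pytest.fixture(scope="session")
def glycan_analysis(glycan_run):
    return pipe.analyze_glycan_level(glycan_run)
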