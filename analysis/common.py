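"""Shared plumbing for the numbered analysis drivers.

Simulated runs are cached as TSV peak lists under scratch/runs/ (regenerated
when missing); result tables go to results/.  Seeds are fixed here so every
driver operates on the same virtual experiment.
"""

from pathlib import Path

from mamkit import io as mio
from mamkit import synthetic as syn

ROOT = Path(__file__).resolve().parent.parent
RUNS = ROOT / "scratch" / "runs"
RESULTS = ROOT / "results"

SEED = 2019

MAKERS = {
    "intact": lambda m: syn.simulate_intact_run(m, syn.intact_settings(SEED)),
    "intact_pngase": lambda m: syn.simulate_intact_run(
        m, syn.intact_settings(SEED + 1), pngase_treated=True),
    "reduced": lambda m: syn.simulate_reduced_run(m, syn.reduced_settings(SEED + 2)),
    "reduced_pngase": lambda m: syn.simulate_reduced_run(
        m, syn.reduced_settings(SEED + 3), pngase_treated=True),
    "digest": lambda m: syn.simulate_digest_run(m, syn.digest_settings(SEED + 4)),
    "glycans": lambda m: syn.simulate_glycan_run(
        settings=syn.glycan_settings(SEED + 5)),
}


def get_model():
    return syn.IgGModel.default()


def get_run(name: str):
    """Load the cached run, simulating and caching it first if needed."""
    RUNS.mkdir(parents=True, exist_ok=True)
    path = RUNS / f"{name}.tsv"
    if not path.exists():
        run = MAKERS[name](get_model())
        mio.write_tsv(run, path)
        return run
    return mio.read_tsv(path)


def results_dir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
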