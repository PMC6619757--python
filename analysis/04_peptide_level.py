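#!/usr/bin/env python
"""Level 3: peptide mapping.

Searches the tryptic IDA run against the two chains (plus pseudo-reversed
decoys), accepts identifications at q <= 0.05, reports chain coverage, the
modification table with apex-intensity relative abundances, terminal
pyroglutamate fractions, and oxonium-filtered glycopeptides.
"""

import common
import pandas as pd
from mamkit import peptides as pep
from mamkit import pipeline as pipe


def main():
    model = common.get_model()
    run = common.get_run("digest")
    res = pipe.analyze_peptide_level(run, model.light_chain,
                                     model.heavy_chain, pipe.DEFAULT_LIBRARY)

    print(f"{len(res['psms'])} PSMs, {len(res['accepted'])} accepted at q<=0.05")
    for chain, cov in res["coverage"].items():
        print(f"{chain} chain sequence coverage: {cov:.1f}%")

    per_form = res["per_form"]
    heavy = pep.base_peptide_fraction(per_form, "heavy", 1, "Gln->pyro-Glu")
    light = pep.base_peptide_fraction(per_form, "light", 1, "Glu->pyro-Glu")
    print(f"\nheavy N-terminal pyroGlu: {100 * heavy:.1f}% "
          f"(light N-terminus {100 * (1 - light):.1f}% unmodified)")

    mods = pd.DataFrame([{"modification": r.modification,
                          "n_modified_peptides": r.n_modified_peptides,
                          "relative_abundance_pct": round(r.relative_abundance, 2)}
                         for r in res["modification_report"]])
    print("\nmodification table:")
    print(mods.to_string(index=False))

    gp = res["glycopeptide_quant"]
    print("\nglycopeptides (XIC-area %):")
    print(gp.to_string(index=False))

    out_dir = common.results_dir()
    mods.to_csv(out_dir / "modifications.csv", index=False)
    gp.to_csv(out_dir / "glycopeptides.csv", index=False)
    print(f"\nwrote {out_dir / 'modifications.csv'} and "
          f"{out_dir / 'glycopeptides.csv'}")


if __name__ == "__main__":
    main()
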