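#!/usr/bin/env python
"""Level 4: released N-glycan analysis.

Identifies free glycans on the PGC-style run by oxonium prefiltering,
10 ppm composition enumeration and B/Y fragment confirmation, then counts
chromatographic isomers and quantifies compositions by XIC peak areas.
"""

import common
from mamkit import pipeline as pipe


def main():
    run = common.get_run("glycans")
    res = pipe.analyze_glycan_level(run)
    quant = res["quant"]
    print(f"{len(quant)} glycan compositions identified "
          f"({int(quant.isomers.sum())} chromatographic peaks):")
    print(quant.to_string(index=False))

    out = common.results_dir() / "free_glycans.csv"
    quant.to_csv(out, index=False)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
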