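#!/usr/bin/env python
"""Generate the six synthetic LC-MS(/MS) runs the study analyses.

One virtual IgG1 (bundled synthetic chain pair, single Fc N-glycosite with a
G0F/G1F/G2F profile of 78.1/21.7/0.3%, 95% heavy-chain N-terminal pyroGlu)
measured at four levels: intact and PNGase-treated TOF-MS, reduced chains
with and without PNGase, a tryptic-digest IDA run, and a released-glycan
PGC-style run with a 14-composition profile.  Runs are cached under
scratch/runs/ as diffable TSV peak lists with ground-truth sidecars.
"""

import common


def main():
    for name in common.MAKERS:
        run = common.get_run(name)
        ms2 = len(run.ms2())
        print(f"{name:16s} {len(run):5d} scans ({ms2} MS2) -> "
              f"scratch/runs/{name}.tsv")
    print("\nGround truth for each run is in the matching .truth.json sidecar.")


if __name__ == "__main__":
    main()
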