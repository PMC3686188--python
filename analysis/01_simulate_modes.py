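#!/usr/bin/env python
"""Simulate one dataset per geographic speciation mode.

Generates a 15-tip chronogram and evolved species ranges for the
allopatric, sympatric, and peripatric worlds (shared topology, one seed),
plus a forward DEC coding, and writes each dataset under
``results/sim/<mode>/`` in the same formats the analysis commands read.
"""

from pathlib import Path

from rangearc.pipeline import run_simulate

SEED = 1
OUT = Path("results/sim")


def main():
    for mode in ("allopatric", "sympatric", "peripatric"):
        out_dir = OUT / mode
        res = run_simulate(mode, n_tips=15, seed=SEED, out_dir=out_dir)
        n_zero = sum(
            1 for rec in res["truth"]["split_truth"].values()
            if rec["sympatry_at_split"] < 1e-9
        )
        print(
            f"{mode}: 15 tips, 14 splits, {n_zero} splits with zero initial "
            f"overlap -> {out_dir}"
        )
    print("Same seed everywhere: the three trees are identical; only the "
          "range geometries differ.")


if __name__ == "__main__":
    main()
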