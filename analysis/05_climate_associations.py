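#!/usr/bin/env python
"""Association of community phylogenetic structure with climate: Spearman
correlations of NRI against the 21 bioclimatic factors and the LGM
anomalies per habitat group, PLS regression of NRI on climate, and
per-group NRI / PD / richness comparisons.

Requires the outputs of steps 03 and 04.  Writes results/assoc.csv,
results/pls.csv, results/group_stats.csv, results/group_pairwise.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from phylostruct.pipeline import run_associate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    paths = run_associate(
        args.outdir / "nri.csv",
        args.outdir / "pd_sr.csv",
        args.data / "climate.csv",
        args.outdir / "groups.csv",
        args.outdir,
        seed=args.seed,
    )
    stats = pd.read_csv(paths["group_stats"], comment="#")
    print("per-habitat medians and NRI-vs-zero tests:")
    print(stats.to_string(index=False))
    assoc = pd.read_csv(paths["assoc"], comment="#")
    strong = assoc[assoc["p"] < 0.01]
    print(f"\n{len(strong)} NRI-climate correlations with p < .01; "
          "strongest five by |rho|:")
    print(
        strong.reindex(strong["rho"].abs().sort_values(ascending=False).index)
        .head(5).to_string(index=False)
    )
    pls = pd.read_csv(paths["pls"], comment="#")
    print("\nPLS: NRI variance explained by 3 components per group:")
    for _, r in pls.iterrows():
        if not r.get("skipped", False):
            print(f"  {r['group']:>4}: {100 * r['r2y_cum_3']:.2f}% "
                  f"(n={int(r['n'])})")


if __name__ == "__main__":
    main()
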