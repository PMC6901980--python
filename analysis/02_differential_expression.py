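#!/usr/bin/env python
"""Per-gene fold changes and DEG calls for both conditions, plus overlap.

For each condition: fold change = mean log expression difference
(treatment - control), pooled-variance t-test, BH q-values, and the DEG
rule q <= 0.05 & |beta| >= 0.41 (natural-log 1.5-fold bound).  Then the
DEG overlap and fold-change concordance between the two conditions.

At this mild planted effect (ln 2) with n = 5, per-gene calling has little
power — the point the module statistics address in the next step.
"""

import json
from pathlib import Path

from toxmod import call_degs, compute_fold_changes, deg_overlap, read_expression

DATA = Path("results/data")
OUT = Path("results")
CONDITIONS = ["liver_24h_vivo", "hepatocyte_24h_vitro"]


def main() -> None:
    tables = {}
    for cond in CONDITIONS:
        matrix = read_expression(DATA / f"{cond}_matrix.tsv",
                                 DATA / f"{cond}_metadata.tsv")
        fct = compute_fold_changes(matrix, cond)
        degs = call_degs(fct)
        degs.reset_index().to_csv(OUT / f"{cond}_degs.tsv", sep="\t",
                                  index=False, float_format="%.10g")
        tables[cond] = degs
        print(f"{cond}: {int(degs['is_deg'].sum())} DEGs of {len(degs)} genes "
              f"(q<=0.05, |beta|>=0.41); min q = {degs['q'].min():.3g}")
    overlap = deg_overlap(tables[CONDITIONS[0]], tables[CONDITIONS[1]])
    summary = {
        "n_intersection": overlap.n_intersection,
        "n_a_only": overlap.n_a_only,
        "n_b_only": overlap.n_b_only,
        "fc_r_squared": overlap.r_squared,
        "fc_slope": overlap.slope,
    }
    with (OUT / "deg_overlap.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    print(f"DEG overlap: {summary}")


if __name__ == "__main__":
    main()
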