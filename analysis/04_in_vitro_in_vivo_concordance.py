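#!/usr/bin/env python
"""Correlate module activation between the in vivo and in vitro conditions.

The squared Pearson correlation of the 11 modules' AAFC z-scores across
the two conditions is the desk-scale analogue of in vitro - in vivo
concordance; the slope is reported because R^2 is sign-blind.
"""

import json
from pathlib import Path

import pandas as pd

from toxmod import ActivationResult, correlate_conditions, rank_modules

OUT = Path("results")
CONDITIONS = ["liver_24h_vivo", "hepatocyte_24h_vitro"]


def _load(cond: str):
    df = pd.read_csv(OUT / f"{cond}_aafc_scores.tsv", sep="\t")
    results = [
        ActivationResult(
            set_name=r["set_name"], score=r["score"], p_perm=r["p_perm"],
            p_plain=r["p_perm"], z=r["z"], p_fisher=r["p_fisher"],
            n_measured=int(r["n_measured"]), n_set=int(r["n_set"]),
        )
        for _, r in df.iterrows()
    ]
    return rank_modules(results, condition_id=cond)


def main() -> None:
    corr = correlate_conditions(_load(CONDITIONS[0]), _load(CONDITIONS[1]))
    with (OUT / "concordance.json").open("w") as fh:
        json.dump({"condition_a": corr.condition_a, "condition_b": corr.condition_b,
                   "n_shared": corr.n_shared, "r_squared": corr.r_squared,
                   "slope": corr.slope}, fh, indent=2, sort_keys=True)
    print(f"module z-score concordance over {corr.n_shared} shared modules: "
          f"R^2 = {corr.r_squared:.3f}, slope = {corr.slope:.3f}")


if __name__ == "__main__":
    main()
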