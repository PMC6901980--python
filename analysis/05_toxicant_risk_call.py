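#!/usr/bin/env python
"""Aggregate over conditions by maximum score and call fibrosis risk.

Each module keeps the row from whichever condition maximized its
activation score; the compound is flagged high-risk when the fibrosis
module is significantly activated (p < 0.01) in that maximized table.
"""

import json
from pathlib import Path

import pandas as pd

from toxmod import ActivationResult, classify_risk, max_over_conditions

OUT = Path("results")
CONDITIONS = ["liver_24h_vivo", "hepatocyte_24h_vitro"]


def _load(cond: str):
    df = pd.read_csv(OUT / f"{cond}_aafc_scores.tsv", sep="\t")
    return [
        ActivationResult(
            set_name=r["set_name"], score=r["score"], p_perm=r["p_perm"],
            p_plain=r["p_perm"], z=r["z"], p_fisher=r["p_fisher"],
            n_measured=int(r["n_measured"]), n_set=int(r["n_set"]),
            condition_id=cond,
        )
        for _, r in df.iterrows()
    ]


def main() -> None:
    maxed = max_over_conditions({c: _load(c) for c in CONDITIONS})
    call = classify_risk(maxed, "fibrosis", alpha=0.01, compound_id="thioacetamide_like")
    with (OUT / "risk_call.json").open("w") as fh:
        json.dump({"compound_id": call.compound_id, "target_module": call.target_module,
                   "max_score_condition": call.max_score_condition,
                   "max_z": call.max_z, "p_perm": call.p_perm,
                   "call": call.call}, fh, indent=2, sort_keys=True)
    print(f"{call.compound_id}: {call.call} - fibrosis max score in "
          f"{call.max_score_condition} (z={call.max_z:.2f}, p={call.p_perm:.4g})")


if __name__ == "__main__":
    main()
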