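#!/usr/bin/env python
"""Simulate a paired toxicant study: one in vivo tissue, one in vitro model.

Both conditions share the same 2,000-gene universe and the same 11 liver
injury modules, with the fibrosis module planted at a 2-fold effect
(delta = ln 2) split half up / half down — the mixed-direction regime a
signed statistic cannot see.  The other ten modules are inactive decoys.
Cohorts are n = 5 treatment vs n = 5 control with Gaussian log-scale noise
(sd 0.5); the two conditions get independent noise, emulating independent
experiments on the same biology.

Writes matrix/metadata TSVs, the module GMT, and the planted truth under
results/data/.
"""

import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from toxmod import make_planted_config, simulate_experiment, write_expression, write_gmt

OUT = Path("results/data")
SEED = 7
MODULES = [
    "fibrosis", "single_cell_necrosis", "cellular_infiltration",
    "bile_duct_hyperplasia", "hypertrophy", "glycogen_depletion",
    "vacuolization", "microgranuloma", "mitotic_figures",
    "anisonucleosis", "peroxisome_proliferation",
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    effect_sizes = [np.log(2.0)] + [0.0] * (len(MODULES) - 1)
    # one shared universe and module collection; only the noise differs
    base_cfg, gsc = make_planted_config(
        n_genes=2000, module_sizes=[20] * len(MODULES),
        effect_sizes=effect_sizes, seed=SEED, names=MODULES,
        direction_mix=0.5, condition_id="liver_24h_vivo",
    )
    for condition, seed in (("liver_24h_vivo", SEED), ("hepatocyte_24h_vitro", SEED + 1000)):
        cfg = replace(base_cfg, seed=seed, condition_id=condition)
        matrix, truth = simulate_experiment(cfg)
        write_expression(matrix, OUT / f"{condition}_matrix.tsv",
                         OUT / f"{condition}_metadata.tsv")
        if condition.endswith("vivo"):
            write_gmt(gsc, OUT / "injury_modules.gmt")
        with (OUT / f"{condition}_truth.json").open("w") as fh:
            json.dump({"module_active": truth.module_active,
                       "module_delta": truth.module_delta}, fh, indent=2, sort_keys=True)
        n_shift = int((truth.log_fc != 0).sum())
        print(f"{condition}: 2000 genes x 10 samples, planted fibrosis "
              f"delta=ln2 on {n_shift} genes (half up, half down)")
    print(f"inputs written to {OUT}/")


if __name__ == "__main__":
    main()
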