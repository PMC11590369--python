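#!/usr/bin/env python
"""Reduced-scale validation summary of the whole stack.

Runs small versions of the calibration and recovery experiments (the full
versions live in the test suite and scripts/acceptance.py) and prints one
table: likelihood-oracle error, stepping-stone error, node-age HPD
coverage, DEC recovery, stochastic-mapping consistency.
"""

import json
from pathlib import Path

from morphoclock import experiments

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = {}
    mk = experiments.mk_oracle_error(seed=11, n_cases=50)
    rows["mk_pruning_max_abs_error"] = mk["max_abs_error"]
    ss = experiments.stepping_stone_toy(seed=1, n_steps=10, n_samples=2000)
    rows["stepping_stone_abs_error"] = ss["abs_error"]
    cov = experiments.node_age_coverage(seed=177, n_replicates=5, n_generations=15_000)
    rows["node_age_hpd95_coverage"] = cov["coverage"]
    rec = experiments.dec_recovery(seed=300, n_replicates=5)
    rows["dec_dispersal_median"] = rec["median_d"]
    rows["dec_extirpation_median"] = rec["median_e"]
    sm = experiments.simmap_consistency(seed=9, n_histories=2000)
    rows["simmap_max_abs_freq_deviation"] = sm["max_abs_deviation"]
    for k, v in rows.items():
        print(f"{k:36s} {v:.6g}")
    with open(OUT / "validation_summary.json", "w") as fh:
        json.dump(rows, fh, indent=2)
    print("wrote results/validation_summary.json")


if __name__ == "__main__":
    main()
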