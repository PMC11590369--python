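#!/usr/bin/env python
"""Derive the informative lognormal prior on the base clock rate.

The construction divides the median non-clock tree height in expected
substitutions by the median of the root-age prior.  With the study's
numbers (height 16.6429, root median 37.6 Ma) the ratio is 0.4426 and the
prior mean on the log scale is -0.8150; the same chain is repeated for the
synthetic dataset from step 01.
"""

import json
from pathlib import Path

import numpy as np

from morphoclock import io_formats
from morphoclock.clock_models import derive_clock_rate_prior, effective_lengths
from morphoclock.tree_priors import RootCalibration

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    mean_log, sd_log = derive_clock_rate_prior(16.6429, 37.6, 1.5)
    print(f"study numbers: ratio {16.6429 / 37.6:.4f}, mean_log {mean_log:.4f}, sd {sd_log}")

    out = {"study": {"ratio": 16.6429 / 37.6, "mean_log": mean_log, "sd_log": sd_log}}
    tree_path = DATA / "true_tree.nwk"
    if tree_path.exists():
        tree = io_formats.read_tree(tree_path)
        # non-clock stand-in: median root-to-extant-tip path in substitutions
        # under the generating base rate
        eff = effective_lengths(tree, 0.4426)
        depths = []
        for i in tree.tip_indices:
            v, tot = int(i), 0.0
            if tree.ages[int(i)] > 1e-9:
                continue
            while tree.parent[v] >= 0:
                tot += eff[v]
                v = int(tree.parent[v])
            depths.append(tot)
        cal = RootCalibration(34.0, 41.2)
        root_median = cal.offset + np.log(2.0) / cal.rate
        height = float(np.median(depths))
        m, s = derive_clock_rate_prior(height, root_median, 1.5)
        print(f"synthetic: height {height:.3f} subst / root median {root_median:.1f} Ma "
              f"-> mean_log {m:.4f}")
        out["synthetic"] = {"height_subst": height, "root_median": root_median, "mean_log": m}
    OUT.mkdir(exist_ok=True)
    with open(OUT / "clock_prior.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print("wrote results/clock_prior.json")


if __name__ == "__main__":
    main()
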