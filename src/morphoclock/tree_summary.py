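"""Posterior tree summarization: consensus topologies, clade supports,
median node ages and highest-posterior-density intervals.

Majority-rule consensus keeps clades above frequency 0.5; the maximum
compatible ("allcompat") consensus then greedily adds the remaining clades
in descending frequency whenever compatible, giving a fully resolved
summary when the sample allows one.  Node ages on the consensus are
medians over the samples that contain the clade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import TimeTree

__all__ = ["ConsensusTree", "consensus", "hpd", "mrca_age_summary"]


def hpd(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        warnings.warn("fewer than 2 samples; HPD is degenerate", stacklevel=2)
        v = float(x[0]) if n else float("nan")
        return (v, v)
    m = int(np.ceil(mass * n))
    m = min(max(m, 1), n)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return (float(x[i]), float(x[i + m - 1]))


def _clade_sets(tree: TimeTree) -> dict[frozenset[str], float]:
    """Clade -> node age for every clade (including tips) in a tree."""
    return {
        clade: float(tree.ages[v]) for clade, v in tree.bipartitions().items()
    }


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a.isdisjoint(b) or a <= b or b <= a


@dataclass
class ConsensusTree:
    """Summary tree with per-clade posterior support and age summaries."""

    tree: TimeTree
    clade_support: dict[frozenset[str], float] = field(default_factory=dict)
    clade_age_median: dict[frozenset[str], float] = field(default_factory=dict)
    clade_age_hpd: dict[frozenset[str], tuple[float, float]] = field(
        default_factory=dict
    )
    tip_age_median: dict[str, float] = field(default_factory=dict)
    tip_age_hpd: dict[str, tuple[float, float]] = field(default_factory=dict)

    def node_table(self) -> pd.DataFrame:
        rows = []
        for clade, pp in sorted(
            self.clade_support.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
        ):
            lo, hi = self.clade_age_hpd[clade]
            rows.append(
                {
                    "clade": "|".join(sorted(clade)),
                    "size": len(clade),
                    "posterior": pp,
                    "age_median": self.clade_age_median[clade],
                    "age_hpd_lower": lo,
                    "age_hpd_upper": hi,
                }
            )
        return pd.DataFrame(rows)

    def annotated_newick(self) -> str:
        t = self.tree
        clades = t.bipartitions()
        node_clade = {v: c for c, v in clades.items()}

        def render(v: int) -> str:
            if t.is_tip(v):
                lab = t.labels[v]
                meta = ""
                if lab in self.tip_age_hpd:
                    lo, hi = self.tip_age_hpd[lab]
                    meta = (
                        f"[&age_median={self.tip_age_median[lab]:.6g},"
                        f"age_hpd={{{lo:.6g},{hi:.6g}}}]"
                    )
                core = lab + meta
            else:
                inner = ",".join(render(c) for c in t.children[v])
                clade = node_clade[v]
                lo, hi = self.clade_age_hpd[clade]
                core = (
                    f"({inner})[&pp={self.clade_support[clade]:.4g},"
                    f"age_median={self.clade_age_median[clade]:.6g},"
                    f"age_hpd={{{lo:.6g},{hi:.6g}}}]"
                )
            p = t.parent[v]
            if p < 0:
                return core
            return f"{core}:{max(t.ages[p] - t.ages[v], 0.0):.6g}"

        return render(t.root) + ";"


def _build_tree_from_clades(
    clade_list: list[frozenset[str]],
    taxa: list[str],
    ages: dict[frozenset[str], float],
    tip_ages: dict[str, float],
) -> TimeTree:
    """Assemble a TimeTree from a nested, compatible clade collection."""
    full = frozenset(taxa)
    clades = sorted(set(clade_list) | {full}, key=lambda c: (-len(c), sorted(c)))
    labels = list(taxa) + ["" for _ in clades]
    n_tip = len(taxa)
    parent = np.full(n_tip + len(clades), -1, dtype=np.int64)
    node_ages = np.zeros(n_tip + len(clades))
    clade_index = {c: n_tip + i for i, c in enumerate(clades)}
    for i, c in enumerate(clades):
        node_ages[n_tip + i] = ages[c]
        if c == full:
            continue
        # parent = smallest clade strictly containing c
        best = full
        for other in clades:
            if c < other and len(other) < len(best):
                best = other
        parent[n_tip + i] = clade_index[best]
    for i, t in enumerate(taxa):
        node_ages[i] = tip_ages.get(t, 0.0)
        singleton = frozenset([t])
        best = full
        for other in clades:
            if singleton < other and len(other) < len(best):
                best = other
        parent[i] = clade_index[best]
    # enforce parent-older-than-child monotonicity (medians over different
    # sample subsets can cross); bump parents up where needed
    tree = TimeTree(parent, node_ages, labels, validate=False)
    for v in tree.postorder():
        p = int(tree.parent[v])
        if p >= 0 and tree.ages[p] < tree.ages[v]:
            tree.ages[p] = tree.ages[v]
    tree.validate()
    return tree


def consensus(trees: list[TimeTree], mode: str = "majrule") -> ConsensusTree:
    """Majority-rule or maximum-compatible consensus of a posterior sample."""
    if not trees:
        raise ValueError("need at least one tree")
    if mode not in ("majrule", "allcompat"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    taxa = sorted(trees[0].tip_labels)
    full = frozenset(taxa)
    for t in trees[1:]:
        if frozenset(t.tip_labels) != full:
            raise ValueError("taxon sets differ across trees")

    ages_by_clade: dict[frozenset[str], list[float]] = {}
    for t in trees:
        for clade, age in _clade_sets(t).items():
            ages_by_clade.setdefault(clade, []).append(age)
    n = len(trees)
    freq = {c: len(v) / n for c, v in ages_by_clade.items() if len(c) > 1}

    kept = [c for c, f in freq.items() if f > 0.5 and c != full]
    if mode == "allcompat":
        rest = sorted(
            (c for c, f in freq.items() if f <= 0.5 and c != full),
            key=lambda c: (-freq[c], sorted(c)),  # ties: lexicographic encoding
        )
        for c in rest:
            if all(_compatible(c, k) for k in kept):
                kept.append(c)
    # majority-rule splits are pairwise compatible by construction
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            assert _compatible(a, b), "incompatible splits in consensus"

    summary_clades = kept + [full]
    med = {c: float(np.median(ages_by_clade[c])) for c in summary_clades}
    hpds = {c: hpd(ages_by_clade[c]) if len(ages_by_clade[c]) > 1 else (med[c], med[c]) for c in summary_clades}
    tip_ages_samples: dict[str, list[float]] = {t: [] for t in taxa}
    for t in trees:
        for lab in taxa:
            tip_ages_samples[lab].append(float(t.ages[t.tip_index(lab)]))
    tip_med = {lab: float(np.median(v)) for lab, v in tip_ages_samples.items()}
    tip_hpd = {
        lab: hpd(v) if len(v) > 1 else (tip_med[lab], tip_med[lab])
        for lab, v in tip_ages_samples.items()
    }
    tree = _build_tree_from_clades(summary_clades, taxa, med, tip_med)
    support = {c: freq.get(c, 1.0) for c in summary_clades}
    support[full] = 1.0
    return ConsensusTree(tree, support, med, hpds, tip_med, tip_hpd)


def mrca_age_summary(
    trees: list[TimeTree], taxa: list[str], mass: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Median and HPD of the MRCA age of a clade over a posterior sample.

    The MRCA is located per sampled tree whether or not the clade is
    monophyletic in that tree.
    """
    ages = [float(t.ages[t.mrca(taxa)]) for t in trees]
    if len(ages) == 1:
        return ages[0], (ages[0], ages[0])
    return float(np.median(ages)), hpd(ages, mass)
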