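"""Rooted time trees with node ages in Ma and sampled-ancestor fossils.

The tree is binary everywhere except that a sampled ancestor is represented
as a fossil tip attached by a zero-length branch (its age equals its
parent's age).  Ages are the primary state; branch durations are always
derived from them so the two can never drift apart.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["TimeTree", "TreeValidationError"]

_AGE_TOL = 1e-9


class TreeValidationError(ValueError):
    """A tree violates an age/topology invariant."""


class TimeTree:
    """Rooted binary tree with node ages (Ma before present).

    Parameters
    ----------
    parent:
        Integer array, ``parent[i]`` is the parent index of node ``i`` and
        ``-1`` for the root.
    ages:
        Float array of node ages in Ma before present (extant tips at 0).
    labels:
        Per-node label; internal nodes may have empty labels, tip labels
        must be unique and non-empty.
    sampled_ancestor:
        Boolean per node; only fossil tips may carry the flag, and a flagged
        tip must sit at its parent's age (zero-length attachment).
    calibrations:
        Mapping ``tip label -> (min_age, max_age)`` for fossil tips whose
        age is a free parameter constrained to a stratigraphic window.
    """

    def __init__(
        self,
        parent: Sequence[int],
        ages: Sequence[float],
        labels: Sequence[str],
        sampled_ancestor: Sequence[bool] | None = None,
        calibrations: dict[str, tuple[float, float]] | None = None,
        validate: bool = True,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64).copy()
        self.ages = np.asarray(ages, dtype=float).copy()
        self.labels = list(labels)
        n = self.n_nodes
        if sampled_ancestor is None:
            sampled_ancestor = np.zeros(n, dtype=bool)
        self.sampled_ancestor = np.asarray(sampled_ancestor, dtype=bool).copy()
        self.calibrations = dict(calibrations or {})
        self._children: list[list[int]] | None = None
        self._postorder: np.ndarray | None = None
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeValidationError(f"tree has {len(roots)} roots")
        return int(roots[0])

    def invalidate(self) -> None:
        """Drop cached traversals after an in-place topology change."""
        self._children = None
        self._postorder = None

    @property
    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    def is_tip(self, i: int) -> bool:
        return len(self.children[i]) == 0

    @property
    def tip_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if self.is_tip(i)])

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    def tip_index(self, label: str) -> int:
        for i in self.tip_indices:
            if self.labels[i] == label:
                return int(i)
        raise KeyError(f"no tip labelled {label!r}")

    def postorder(self) -> np.ndarray:
        """Node indices, every child before its parent."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            seen = []
            while stack:
                v = stack.pop()
                seen.append(v)
                stack.extend(self.children[v])
            self._postorder = np.array(seen[::-1], dtype=np.int64)
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    def branch_durations(self) -> np.ndarray:
        """Duration (Ma) of the branch above each node; 0 at the root."""
        d = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        d[has_parent] = self.ages[self.parent[has_parent]] - self.ages[has_parent]
        return d

    def tree_length(self) -> float:
        return float(self.branch_durations().sum())

    def mrca(self, tips: Iterable[str]) -> int:
        idx = [self.tip_index(t) for t in tips]
        paths = []
        for i in idx:
            path = set()
            while i >= 0:
                path.add(i)
                i = int(self.parent[i])
            paths.append(path)
        common = set.intersection(*paths)
        return min(common, key=lambda v: self.ages[v])

    def bipartitions(self) -> dict[frozenset[str], int]:
        """Map each non-trivial clade (as a tip-label set) to its node."""
        below: dict[int, frozenset[str]] = {}
        out: dict[frozenset[str], int] = {}
        for v in self.postorder():
            v = int(v)
            if self.is_tip(v):
                below[v] = frozenset([self.labels[v]])
            else:
                s = frozenset().union(*(below[c] for c in self.children[v]))
                below[v] = s
                out[s] = v
        return out

    # ------------------------------------------------------------------
    # validation / copying
    # ------------------------------------------------------------------
    def validate(self) -> None:
        n = self.n_nodes
        if len(self.ages) != n or len(self.labels) != n:
            raise TreeValidationError("parent/ages/labels length mismatch")
        if np.any(self.ages < -_AGE_TOL):
            raise TreeValidationError("negative node age")
        root = self.root  # also checks uniqueness
        for i in range(n):
            p = int(self.parent[i])
            if p < 0:
                continue
            gap = self.ages[p] - self.ages[i]
            if gap < -_AGE_TOL:
                raise TreeValidationError(
                    f"node {i} ({self.labels[i]!r}) older than its parent"
                )
            if self.sampled_ancestor[i]:
                if not self.is_tip(i):
                    raise TreeValidationError("sampled-ancestor flag on internal node")
                if abs(gap) > _AGE_TOL:
                    raise TreeValidationError(
                        f"sampled ancestor {self.labels[i]!r} not at its parent's age"
                    )
            elif self.is_tip(i) and abs(gap) <= _AGE_TOL and self.ages[i] > _AGE_TOL:
                # zero-length fossil attachment without the flag is suspect but
                # legal right after parsing; io_formats sets the flag.
                pass
        tips = self.tip_labels
        if len(set(tips)) != len(tips):
            raise TreeValidationError("duplicate tip labels")
        for lab, (lo, hi) in self.calibrations.items():
            if lo >= hi:
                raise TreeValidationError(f"calibration for {lab!r} has min >= max")
        # connectivity: every node must reach the root
        for i in range(n):
            seen = 0
            j = i
            while j >= 0 and seen <= n:
                j = int(self.parent[j])
                seen += 1
            if seen > n:
                raise TreeValidationError("cycle in parent pointers")
        _ = root

    def prune_to(self, labels: Iterable[str]) -> "TimeTree":
        """Subtree spanned by the given tips, suppressing degree-1 nodes.

        Node ages are preserved; a sampled ancestor whose attachment node is
        suppressed becomes an ordinary fossil tip (its flag is re-derived
        from the zero-length condition).  Calibrations are filtered to the
        kept tips.
        """
        keep = {self.tip_index(l) for l in labels}
        if not keep:
            raise ValueError("cannot prune to an empty taxon set")
        cnt = np.zeros(self.n_nodes, dtype=int)
        for v in self.postorder():
            v = int(v)
            if self.is_tip(v):
                cnt[v] = 1 if v in keep else 0
            else:
                cnt[v] = sum(cnt[c] for c in self.children[v])

        parent: list[int] = []
        ages: list[float] = []
        new_labels: list[str] = []

        def build(v: int, parent_idx: int) -> None:
            kids_kept = [c for c in self.children[v] if cnt[c] > 0]
            while not self.is_tip(v) and len(kids_kept) == 1:
                v = kids_kept[0]
                kids_kept = [c for c in self.children[v] if cnt[c] > 0]
            idx = len(parent)
            parent.append(parent_idx)
            ages.append(float(self.ages[v]))
            new_labels.append(self.labels[v])
            for c in kids_kept:
                build(c, idx)

        # new root: walk down while only one lineage retains kept tips
        root = self.root
        while cnt[root] > 0 and not self.is_tip(root):
            kept = [c for c in self.children[root] if cnt[c] > 0]
            if len(kept) != 1:
                break
            root = kept[0]
        build(root, -1)
        tree = TimeTree(
            parent,
            ages,
            new_labels,
            calibrations={
                k: v for k, v in self.calibrations.items() if k in set(new_labels)
            },
            validate=False,
        )
        # re-derive SA flags from the zero-length condition
        for i in tree.tip_indices:
            i = int(i)
            p = int(tree.parent[i])
            tree.sampled_ancestor[i] = (
                p >= 0
                and tree.ages[i] > _AGE_TOL
                and abs(tree.ages[p] - tree.ages[i]) <= _AGE_TOL
            )
        tree.validate()
        return tree

    def copy(self) -> "TimeTree":
        return TimeTree(
            self.parent,
            self.ages,
            list(self.labels),
            self.sampled_ancestor,
            dict(self.calibrations),
            validate=False,
        )

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def from_parent_ages(cls, parent, ages, labels, **kw) -> "TimeTree":
        return cls(parent, ages, labels, **kw)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree {self.n_tips} tips, root age {self.ages[self.root]:.3g} Ma>"
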