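"""Generators for synthetic datasets with known truth.

Everything the tip-dating pipeline consumes can be simulated here: a
fossilized birth-death tree with extinct tips and sampled ancestors, a
variable-only discrete character matrix evolved under Mk + gamma with
branch-rate variation from a chosen clock model, and geographic ranges
evolved under DEC with epoch-wise connectivity.  Each simulator takes an
explicit seed and the combined truth manifest suffices to re-simulate
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .biogeo_dec import DECModel, cladogenetic_splits, enumerate_ranges
from .clock_models import BranchRates, sample_branch_rates
from .io_formats import CharacterMatrix, ConnectivityModel, MUROID_AREAS, RangeTable
from .mk_model import discrete_gamma_rates, mk_transition_matrix
from .tree_priors import FBDParams
from .trees import TimeTree

__all__ = [
    "TruthManifest",
    "simulate_fbd_tree",
    "simulate_characters",
    "simulate_ranges",
    "study_connectivity",
    "STATE_COUNT_MIXTURE",
]

#: Mixture over per-character state counts used for fixture matrices
#: (binary-dominated, as in real morphological matrices).
STATE_COUNT_MIXTURE = {2: 0.60, 3: 0.25, 4: 0.10, 5: 0.05}

_ZERO_TOL = 1e-9


@dataclass
class TruthManifest:
    """Everything needed to re-simulate a dataset bit-identically."""

    seed: int
    root_age: float
    fbd: dict = field(default_factory=dict)
    clock: dict = field(default_factory=dict)
    alpha: float = 1.0
    dec: dict = field(default_factory=dict)
    true_node_ages: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


# ----------------------------------------------------------------------
# FBD trees
# ----------------------------------------------------------------------
class _Lineage:
    __slots__ = ("start", "end", "children", "extant", "fossils")

    def __init__(self, start: float):
        self.start = start
        self.end: float | None = None
        self.children: list["_Lineage"] = []
        self.extant = False
        self.fossils: list[float] = []


class _TooManyLineages(RuntimeError):
    """Forward simulation exceeded the lineage budget (tree far too big)."""


def _simulate_lineage(start: float, lam, mu, psi, rng, budget: list[int]) -> _Lineage:
    """Forward birth-death-fossilization of one lineage from age ``start``."""
    budget[0] -= 1
    if budget[0] <= 0:
        raise _TooManyLineages
    lin = _Lineage(start)
    total = lam + mu
    t = start
    while True:
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        nxt = t - wait
        if nxt <= 0.0:
            lin.end = 0.0
            lin.extant = True
            break
        if rng.random() < lam / total:
            lin.end = nxt
            lin.children = [
                _simulate_lineage(nxt, lam, mu, psi, rng, budget),
                _simulate_lineage(nxt, lam, mu, psi, rng, budget),
            ]
            break
        lin.end = nxt
        break  # extinction
    if psi > 0:
        span = lin.start - lin.end
        n_f = rng.poisson(psi * span)
        lin.fossils = sorted(
            (lin.end + rng.random(n_f) * span).tolist(), reverse=True
        )
    return lin


def _sample_structure(lin: _Lineage, rho: float, rng) -> dict | None:
    """Prune to the sampled tree, expressed as a nested node structure."""
    kids = [
        s for c in lin.children if (s := _sample_structure(c, rho, rng)) is not None
    ]
    if lin.children:
        if len(kids) == 2:
            desc = {"age": lin.end, "kind": "birth", "children": kids}
        elif len(kids) == 1:
            desc = kids[0]
        else:
            desc = None
    else:
        desc = (
            {"age": 0.0, "kind": "extant", "children": []}
            if lin.extant and rng.random() < rho
            else None
        )
    fossils = sorted(lin.fossils)  # youngest first
    if desc is None:
        if not fossils:
            return None
        desc = {"age": fossils[0], "kind": "fossil", "children": []}
        fossils = fossils[1:]
    for z in fossils:  # older fossils become sampled ancestors
        desc = {
            "age": z,
            "kind": "birth",
            "children": [{"age": z, "kind": "sa", "children": []}, desc],
        }
    return desc


def _structure_to_tree(
    struct: dict, rng, calibration_window=(0.2, 1.5)
) -> TimeTree:
    parent: list[int] = []
    ages: list[float] = []
    labels: list[str] = []
    sa: list[bool] = []
    calibrations: dict[str, tuple[float, float]] = {}
    counters = {"extant": 0, "fossil": 0}

    def add(node: dict, parent_idx: int) -> int:
        idx = len(parent)
        parent.append(parent_idx)
        ages.append(float(node["age"]))
        kind = node["kind"]
        if kind in ("extant",):
            counters["extant"] += 1
            labels.append(f"t{counters['extant']}")
            sa.append(False)
        elif kind in ("fossil", "sa"):
            counters["fossil"] += 1
            lab = f"f{counters['fossil']}"
            labels.append(lab)
            sa.append(kind == "sa")
            lo_w, hi_w = calibration_window
            below = rng.uniform(lo_w, hi_w)
            above = rng.uniform(lo_w, hi_w)
            calibrations[lab] = (
                max(0.0, node["age"] - below),
                node["age"] + above,
            )
        else:
            labels.append("")
            sa.append(False)
        for c in node["children"]:
            add(c, idx)
        return idx

    add(struct, -1)
    return TimeTree(parent, ages, labels, sa, calibrations)


def simulate_fbd_tree(
    params: FBDParams,
    root_age: float,
    seed: int,
    min_tips: int = 3,
    max_tips: int | None = None,
    max_tries: int = 1000,
    max_lineages: int = 50_000,
) -> tuple[TimeTree, TruthManifest]:
    """Simulate a sampled FBD tree conditioned on its root (crown) age.

    Forward birth-death with Poisson fossilization runs from two crown
    lineages; extant tips are subsampled at rho, fossils on lineages with
    sampled descendants become sampled ancestors, and the attempt is
    rejected unless both crown lineages leave samples (matching the
    survival conditioning of the density).
    """
    lam, mu, psi = params.rates
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        try:
            budget = [max_lineages]
            left = _simulate_lineage(root_age, lam, mu, psi, rng, budget)
            right = _simulate_lineage(root_age, lam, mu, psi, rng, budget)
        except _TooManyLineages:
            continue
        sl = _sample_structure(left, params.rho, rng)
        sr = _sample_structure(right, params.rho, rng)
        if sl is None or sr is None:
            continue
        struct = {"age": root_age, "kind": "birth", "children": [sl, sr]}
        tree = _structure_to_tree(struct, rng)
        if tree.n_tips < min_tips:
            continue
        if max_tips is not None and tree.n_tips > max_tips:
            continue
        manifest = TruthManifest(
            seed=seed,
            root_age=root_age,
            fbd=dataclasses.asdict(params),
            true_node_ages={
                "|".join(sorted(clade)): float(tree.ages[v])
                for clade, v in tree.bipartitions().items()
                if len(clade) > 1
            },
        )
        return tree, manifest
    raise RuntimeError(
        f"no acceptable FBD tree in {max_tries} attempts (total extinction "
        "or tip-count bounds too tight)"
    )


# ----------------------------------------------------------------------
# characters
# ----------------------------------------------------------------------
def _draw_state_counts(n_chars: int, rng) -> list[int]:
    ks = sorted(STATE_COUNT_MIXTURE)
    probs = np.array([STATE_COUNT_MIXTURE[k] for k in ks])
    return [int(k) for k in rng.choice(ks, size=n_chars, p=probs / probs.sum())]


def simulate_characters(
    tree: TimeTree,
    eff_lengths: np.ndarray,
    alpha: float,
    n_chars: int,
    seed: int,
    state_counts: list[int] | None = None,
    variable_only: bool = True,
    n_categories: int = 4,
    missing_prob: float = 0.0,
    max_rejects: int = 10_000,
) -> CharacterMatrix:
    """Evolve discrete characters down a tree with given effective lengths.

    Root states are uniform; each character draws one of the discrete-gamma
    rate multipliers (the inference model's own mixture).  Under
    variable-only coding, constant characters are rejected and re-simulated,
    which reproduces the ascertainment the Mk(v) correction undoes.
    """
    rng = np.random.default_rng(seed)
    if state_counts is None:
        state_counts = _draw_state_counts(n_chars, rng)
    if len(state_counts) != n_chars:
        raise ValueError("state_counts length must equal n_chars")
    if variable_only and np.all(np.asarray(eff_lengths) <= _ZERO_TOL):
        raise ValueError(
            "all effective lengths are zero: every character is constant, "
            "variable-only rejection cannot terminate"
        )
    gamma_rates = discrete_gamma_rates(alpha, n_categories)
    tip_idx = [int(i) for i in tree.tip_indices]
    order = tree.preorder()
    columns: list[dict[int, frozenset[int]]] = []
    rejects = 0
    for j in range(n_chars):
        k = state_counts[j]
        while True:
            rate = float(gamma_rates[rng.integers(n_categories)])
            states = np.zeros(tree.n_nodes, dtype=int)
            for v in order:
                v = int(v)
                p = int(tree.parent[v])
                if p < 0:
                    states[v] = rng.integers(k)
                    continue
                t = eff_lengths[v] * rate
                P = mk_transition_matrix(k, float(t))
                states[v] = rng.choice(k, p=P[states[p]])
            col = {}
            for i in tip_idx:
                if missing_prob > 0 and rng.random() < missing_prob:
                    col[i] = frozenset(range(k))
                else:
                    col[i] = frozenset([int(states[i])])
            # constant iff one state is compatible with every (masked) tip
            shared = frozenset(range(k))
            for cell in col.values():
                shared &= cell
            if variable_only and shared:
                rejects += 1
                if rejects > max_rejects:
                    raise RuntimeError(
                        "variable-only rejection loop exceeded its cap; "
                        "branch lengths may be degenerate"
                    )
                continue
            break
        columns.append(col)
    taxa = [tree.labels[i] for i in tip_idx]
    chars = [[columns[j][i] for j in range(n_chars)] for i in tip_idx]
    coding = "variable" if variable_only else "all"
    return CharacterMatrix(taxa, chars, list(state_counts), coding=coding)


# ----------------------------------------------------------------------
# geographic ranges
# ----------------------------------------------------------------------
def _gillespie_branch(
    R: frozenset[int],
    age_start: float,
    age_end: float,
    model: DECModel,
    rng,
) -> frozenset[int]:
    """Anagenetic DEC simulation from age_start down to age_end."""
    conn = model.connectivity
    a = age_start
    while a > age_end + _ZERO_TOL and R:
        m = conn.at_age(a)
        # epoch floor for the current age
        floor = age_end
        if a > conn.epochs[0][0]:  # older than all epochs: oldest extends
            floor = max(age_end, conn.epochs[0][1])
        else:
            for start, end, _ in conn.epochs:
                if end <= a <= start:
                    floor = max(age_end, end)
                    break
        events: list[tuple[float, str, int]] = []
        for b in range(len(model.areas)):
            if b in R or len(R) >= model.max_range_size:
                continue
            rate = model.d * sum(m[x, b] for x in R)
            if rate > 0:
                events.append((rate, "gain", b))
        for x in R:
            events.append((model.e, "loss", x))
        total = sum(r for r, *_ in events)
        if total <= 0:
            a = floor
            if a <= age_end + _ZERO_TOL:
                break
            a -= _ZERO_TOL * 2  # step into the next epoch
            continue
        wait = rng.exponential(1.0 / total)
        if a - wait < floor:
            a = floor
            if abs(a - age_end) <= _ZERO_TOL:
                break
            a -= _ZERO_TOL * 2
            continue
        a -= wait
        pick = rng.random() * total
        acc = 0.0
        for rate, kind, area in events:
            acc += rate
            if pick <= acc:
                R = R | {area} if kind == "gain" else R - {area}
                break
    return R


def simulate_ranges(
    tree: TimeTree,
    model: DECModel,
    seed: int,
    max_tries: int = 100,
) -> tuple[RangeTable, dict[int, frozenset[int]]]:
    """Evolve geographic ranges down the tree under DEC.

    The root range is drawn from the model's root prior; cladogenetic
    scenarios are drawn uniformly at internal nodes; anagenesis is exact
    Gillespie simulation respecting epoch connectivity.  Lineages that hit
    the empty range are recorded extinct and their tips dropped (with a
    warning); if every tip goes extinct the simulation restarts.
    """
    space = model.space()
    rng = np.random.default_rng(seed)

    def connected(R: frozenset[int], m: np.ndarray) -> bool:
        if len(R) <= 1:
            return True
        nodes = sorted(R)
        seen = {nodes[0]}
        frontier = [nodes[0]]
        while frontier:
            a = frontier.pop()
            for b in nodes:
                if b not in seen and (m[a, b] or m[b, a]):
                    seen.add(b)
                    frontier.append(b)
        return len(seen) == len(R)

    root_conn = model.connectivity.at_age(float(tree.ages[tree.root]))
    # root ranges must be internally connected under the connectivity of
    # the root's epoch, otherwise unreachable-by-dispersal ranges leak in
    admissible = [s for s in space.states if s and connected(s, root_conn)]
    for _ in range(max_tries):
        node_range: dict[int, frozenset[int]] = {}
        root = tree.root
        node_range[root] = admissible[rng.integers(len(admissible))]
        ok = True
        for v in tree.preorder():
            v = int(v)
            kids = tree.children[v]
            if not kids:
                continue
            R = node_range[v]
            if not R:
                for c in kids:
                    node_range[c] = frozenset()
                continue
            splits = cladogenetic_splits(space, R, model.wide_vicariance)
            l, r = splits[rng.integers(len(splits))]
            starts = [l, r] if len(kids) == 2 else [R] * len(kids)
            for c, start in zip(kids, starts):
                node_range[c] = _gillespie_branch(
                    start, float(tree.ages[v]), float(tree.ages[c]), model, rng
                )
        presence = {}
        extinct = []
        for i in tree.tip_indices:
            i = int(i)
            R = node_range[i]
            if not R:
                extinct.append(tree.labels[i])
                continue
            vec = np.zeros(len(model.areas), dtype=int)
            for a in R:
                vec[a] = 1
            presence[tree.labels[i]] = vec
        if not presence:
            continue
        if extinct:
            warnings.warn(
                f"{len(extinct)} lineages hit the empty range and were "
                f"dropped: {extinct}",
                stacklevel=2,
            )
        return RangeTable(list(model.areas), presence), node_range
    raise RuntimeError(f"all lineages extinct in every one of {max_tries} tries")


def study_connectivity(areas=MUROID_AREAS) -> ConnectivityModel:
    """A documented 3-epoch connectivity stand-in over the 13 areas.

    The oldest epoch (45-30 Ma) isolates sub-Saharan Africa (EA, SA) and
    South East Asia from the Palearctic core; the middle epoch (30-15 Ma)
    opens the Arabian corridor; the youngest epoch (15-0 Ma) connects all
    geographically adjacent areas.  This is a synthetic paleogeography for
    fixtures, not a reconstruction.
    """
    areas = list(areas)
    n = len(areas)
    ix = {a: i for i, a in enumerate(areas)}
    adjacency = [
        ("SWE", "CE"), ("CE", "GR"), ("GR", "AC"), ("AC", "WCA"),
        ("AC", "AR"), ("WCA", "SCA"), ("WCA", "RU"), ("SCA", "ECA"),
        ("ECA", "RU"), ("ECA", "SEA"), ("SCA", "SEA"), ("AR", "NA"),
        ("AR", "EA"), ("NA", "SWE"), ("NA", "EA"), ("EA", "SA"),
        ("CE", "RU"), ("AC", "RU"), ("SCA", "AR"), ("GR", "NA"),
    ]

    def matrix(closed_pairs=()):
        m = np.eye(n, dtype=int)
        closed = {frozenset(p) for p in closed_pairs}
        for a, b in adjacency:
            if frozenset((a, b)) in closed:
                continue
            m[ix[a], ix[b]] = m[ix[b], ix[a]] = 1
        return m

    old_closed = [
        ("AR", "EA"), ("NA", "EA"), ("EA", "SA"), ("ECA", "SEA"),
        ("SCA", "SEA"), ("AR", "NA"), ("SCA", "AR"),
    ]
    mid_closed = [("ECA", "SEA"), ("SCA", "SEA")]
    return ConnectivityModel(
        areas,
        [
            (45.0, 30.0, matrix(old_closed)),
            (30.0, 15.0, matrix(mid_closed)),
            (15.0, 0.0, matrix()),
        ],
    )
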