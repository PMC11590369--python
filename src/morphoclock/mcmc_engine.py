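"""Metropolis-Hastings sampler for tip-dated morphological-clock analyses.

The state is a dated tree (node ages, fossil tip ages, sampled-ancestor
flags, topology), per-branch clock rates and the scalar parameters
(base clock rate c, clock variance nu, gamma shape alpha, FBD net
diversification / turnover / fossil-sampling probability).  Proposals are
standard scale/slide moves plus a dated narrow exchange and a
reversible-jump sampled-ancestor toggle.  The likelihood can be switched
off (prior sampling) or raised to a power beta (power posteriors for
stepping-stone sampling).

Convergence diagnostics follow tip-dating practice: average standard
deviation of split frequencies across runs (ASDSF), Gelman-Rubin potential
scale reduction (PSRF) and autocorrelation-time effective sample size
(ESS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clock_models import (
    BranchRates,
    ClockConfig,
    _lognormal_logpdf,
    branch_rate_log_prior,
    effective_lengths,
    sample_branch_rates,
)
from .io_formats import CharacterMatrix
from .mk_model import MkLikelihood
from .tree_priors import FBDParams, RootCalibration, fbd_log_density, root_age_log_prior, tip_age_log_prior
from .trees import TimeTree

__all__ = [
    "MCMCConfig",
    "ChainState",
    "Trace",
    "run_mcmc",
    "asdsf",
    "psrf",
    "ess",
]

_ZERO_TOL = 1e-9


@dataclass
class MCMCConfig:
    """Settings for one sampler run (priors, moves, power)."""

    clock: ClockConfig = field(default_factory=ClockConfig)
    root_calibration: RootCalibration | None = None
    rho: float = 1.0
    net_div_prior_mean: float = 1.0
    alpha_prior_mean: float = 1.0
    nu_prior_mean: float = 1.0
    n_categories: int = 4
    use_likelihood: bool = True
    likelihood_power: float = 1.0
    sample_topology: bool = True
    sample_tip_ages: bool = True
    sample_sampled_ancestors: bool = True
    condition_on_survival: bool = True
    scale_times_weight: float = 2.0
    #: Hold the FBD parameters fixed (no d/r/s moves). Used for age-focused
    #: calibration studies: the FBD tree density is not normalized over tip
    #: counts, so sampling (d, r, s) at a fixed taxon set tilts the
    #: node-age prior away from the generating process.
    fixed_fbd: "FBDParams | None" = None
    #: With the FBD density detached the target over (d, r, s) and ages is
    #: exactly the stated independent priors — used to validate proposal
    #: machinery against Exp(1)/U(0,1)/uniform-window marginals, which the
    #: FBD term would otherwise tilt at a fixed taxon set.
    include_fbd_density: bool = True


@dataclass
class ChainState:
    """Current MCMC state with its cached log-posterior decomposition."""

    tree: TimeTree
    rates: BranchRates
    base_rate: float
    nu: float
    alpha: float
    fbd: FBDParams
    components: dict[str, float] = field(default_factory=dict)

    @property
    def log_posterior(self) -> float:
        return float(sum(self.components.values()))

    def audit(self, engine: "_Engine", tol: float = 1e-8) -> None:
        """Recompute every component from scratch; raise on drift."""
        fresh = engine.compute_components(self)
        for key, val in fresh.items():
            if not np.isclose(val, self.components[key], atol=tol, rtol=0):
                raise RuntimeError(
                    f"posterior component {key!r} drifted: cached "
                    f"{self.components[key]!r} vs fresh {val!r}"
                )


@dataclass
class Trace:
    """Sampled scalar parameters plus tree samples from one run."""

    params: dict[str, list[float]]
    trees: list[TimeTree]
    iterations: list[int]
    seed: int
    run_id: str
    acceptance: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.params)
        df.insert(0, "iteration", self.iterations)
        return df

    def burned(self, fraction: float = 0.25) -> "Trace":
        cut = int(len(self.iterations) * fraction)
        return Trace(
            {k: v[cut:] for k, v in self.params.items()},
            self.trees[cut:],
            self.iterations[cut:],
            self.seed,
            self.run_id,
            self.acceptance,
        )


class _Engine:
    """Posterior evaluation shared by all moves."""

    def __init__(self, matrix: CharacterMatrix | None, tree: TimeTree, cfg: MCMCConfig):
        self.cfg = cfg
        self.mk = (
            MkLikelihood(tree, matrix, cfg.n_categories)
            if (matrix is not None and cfg.use_likelihood)
            else None
        )

    # -- component computations -------------------------------------
    def log_likelihood(self, st: ChainState) -> float:
        if self.mk is None or self.cfg.likelihood_power == 0.0:
            return 0.0
        eff = effective_lengths(st.tree, st.base_rate, st.rates)
        lnl = self.mk.log_likelihood(st.tree, eff, st.alpha)
        return self.cfg.likelihood_power * lnl

    def compute_components(
        self, st: ChainState, keys: tuple[str, ...] | None = None
    ) -> dict[str, float]:
        cfg = self.cfg
        want = set(keys) if keys is not None else None
        comp: dict[str, float] = {}

        def need(name: str) -> bool:
            return want is None or name in want

        if need("lnL"):
            comp["lnL"] = self.log_likelihood(st)
        if need("fbd"):
            comp["fbd"] = (
                fbd_log_density(
                    st.tree, st.fbd, condition_on_survival=cfg.condition_on_survival
                )
                if cfg.include_fbd_density
                else 0.0
            )
        if need("root_prior"):
            comp["root_prior"] = (
                root_age_log_prior(st.tree.ages[st.tree.root], cfg.root_calibration)
                if cfg.root_calibration is not None
                else 0.0
            )
        if need("tip_prior"):
            comp["tip_prior"] = tip_age_log_prior(st.tree)
        if need("rates_prior"):
            comp["rates_prior"] = branch_rate_log_prior(
                cfg.clock.model, st.rates, st.nu, st.tree
            )
        if need("c_prior"):
            comp["c_prior"] = float(
                _lognormal_logpdf(
                    st.base_rate,
                    cfg.clock.base_rate_prior_mean_log,
                    cfg.clock.base_rate_prior_sd_log,
                )
            )
        if need("alpha_prior"):
            comp["alpha_prior"] = float(
                -st.alpha / cfg.alpha_prior_mean - np.log(cfg.alpha_prior_mean)
            )
        if need("nu_prior"):
            comp["nu_prior"] = float(
                -st.nu / cfg.nu_prior_mean - np.log(cfg.nu_prior_mean)
            )
        if need("fbd_param_prior"):
            # d ~ Exp(mean); r, s ~ U(0,1) contribute a constant
            comp["fbd_param_prior"] = float(
                -st.fbd.net_diversification / cfg.net_div_prior_mean
                - np.log(cfg.net_div_prior_mean)
            )
        return comp

    def refresh(self, st: ChainState, keys: tuple[str, ...] | None = None) -> None:
        fresh = self.compute_components(st, keys)
        if keys is None:
            st.components = fresh
        else:
            st.components.update(fresh)


def _tk02_multipliers(tree: TimeTree, node_rates: np.ndarray) -> np.ndarray:
    mult = np.ones(tree.n_nodes)
    for v in range(tree.n_nodes):
        p = int(tree.parent[v])
        if p >= 0:
            mult[v] = 0.5 * (node_rates[p] + node_rates[v])
    return mult


def _gamma_logpdf_scalar(x: float, shape: float, rate: float) -> float:
    from scipy.special import gammaln

    return (
        shape * np.log(rate) - float(gammaln(shape))
        + (shape - 1.0) * np.log(x) - rate * x
    )


def _propose_scale(value: float, rng, lam: float = 0.6) -> tuple[float, float]:
    """Multiplier proposal; returns (new value, log Hastings ratio)."""
    factor = np.exp(lam * (rng.random() - 0.5))
    return value * factor, float(np.log(factor))


def run_mcmc(
    matrix: CharacterMatrix | None,
    start_tree: TimeTree,
    config: MCMCConfig,
    n_generations: int,
    seed: int,
    sample_every: int = 50,
    run_id: str = "run1",
    audit_every: int = 0,
) -> Trace:
    """Sample the joint posterior (or prior, with the likelihood off).

    Returns a :class:`Trace` with scalar parameters and tree samples taken
    every ``sample_every`` generations.  A fixed seed gives a bit-identical
    trace.  ``audit_every`` > 0 re-derives the cached posterior
    decomposition from scratch periodically and raises on drift.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    tree = start_tree.copy()
    engine = _Engine(matrix, tree, cfg)

    # initial state: draw rates from the clock prior, scalars at prior means
    nu0 = cfg.clock.variance
    rates = sample_branch_rates(cfg.clock.model, tree, nu0, rng)
    if cfg.clock.model == "TK02":
        rates = BranchRates(
            _tk02_multipliers(tree, rates.node_rates), node_rates=rates.node_rates
        )
    st = ChainState(
        tree=tree,
        rates=rates,
        base_rate=float(np.exp(cfg.clock.base_rate_prior_mean_log)),
        nu=nu0,
        alpha=1.0,
        fbd=(
            cfg.fixed_fbd
            if cfg.fixed_fbd is not None
            else FBDParams(0.5, 0.3, 0.3, cfg.rho)
        ),
    )
    engine.refresh(st)
    if not np.isfinite(st.log_posterior):
        raise ValueError("starting state has zero posterior density")

    fossil_tips = [
        int(i)
        for i in tree.tip_indices
        if tree.labels[int(i)] in tree.calibrations
    ]
    internal = [
        v for v in range(tree.n_nodes) if not tree.is_tip(v)
    ]

    # move weights scale with the number of parameters each class updates,
    # so per-parameter update rates stay comparable as trees grow
    weighted: list[tuple[str, float]] = [
        ("c", 1.0), ("alpha", 1.0),
        ("node_age", max(len(internal) - 1, 1) / 2.0), ("root_age", 1.0),
    ]
    if cfg.fixed_fbd is None:
        weighted += [("d", 1.0), ("r", 1.0), ("s", 1.0)]
    if cfg.scale_times_weight > 0:
        weighted.append(("scale_times", cfg.scale_times_weight))
    if len(internal) > 1:
        weighted.append(("subtree_scale", max(len(internal) - 1, 1) / 3.0))
    if cfg.clock.model != "strict":
        weighted += [("nu", 1.0), ("branch_rate", tree.n_nodes / 2.0)]
    if cfg.sample_tip_ages and fossil_tips:
        weighted.append(("tip_age", len(fossil_tips) / 2.0))
    if cfg.sample_sampled_ancestors and fossil_tips:
        weighted.append(("sa_toggle", len(fossil_tips) / 4.0))
    if cfg.sample_topology and len(internal) > 1:
        weighted.append(("topology", max(len(internal) - 1, 1) / 2.0))
    moves = [m for m, _ in weighted]
    move_probs = np.array([w for _, w in weighted])
    move_probs = move_probs / move_probs.sum()
    move_cdf = np.cumsum(move_probs)

    params_log: dict[str, list[float]] = {
        k: []
        for k in (
            "lnL", "log_posterior", "root_age", "tree_length", "base_rate",
            "nu", "alpha", "net_diversification", "turnover",
            "fossil_sampling", "n_sampled_ancestors",
        )
    }
    trees_out: list[TimeTree] = []
    iters: list[int] = []
    accept: dict[str, list[int]] = {m: [0, 0] for m in moves}

    _TREE_KEYS = ("lnL", "fbd", "root_prior", "tip_prior", "rates_prior")
    _MOVE_KEYS = {
        "c": ("lnL", "c_prior"),
        "alpha": ("lnL", "alpha_prior"),
        "nu": ("rates_prior", "nu_prior"),
        "d": ("fbd", "fbd_param_prior"),
        "r": ("fbd",),
        "s": ("fbd",),
        "node_age": _TREE_KEYS,
        "root_age": _TREE_KEYS,
        "scale_times": _TREE_KEYS + ("c_prior",),
        "subtree_scale": _TREE_KEYS,
        "tip_age": _TREE_KEYS,
        "sa_toggle": _TREE_KEYS,
        "topology": _TREE_KEYS,
        "branch_rate": ("lnL", "rates_prior"),
    }

    def try_accept(move, new_state, log_hastings, keys=None):
        accept[move][1] += 1
        new_state.components = dict(st_holder[0].components)
        engine.refresh(new_state, keys if keys is not None else _MOVE_KEYS[move])
        delta = new_state.log_posterior - st_holder[0].log_posterior
        if np.isfinite(delta) and np.log(rng.random()) < delta + log_hastings:
            accept[move][0] += 1
            return new_state
        return st_holder[0]

    st_holder = [st]

    def attempt():
        st = st_holder[0]
        move = moves[int(np.searchsorted(move_cdf, rng.random()))]
        tree = st.tree

        if move in ("c", "alpha", "nu", "d"):
            new = ChainState(tree, st.rates, st.base_rate, st.nu, st.alpha, st.fbd)
            if move == "c":
                new.base_rate, lh = _propose_scale(st.base_rate, rng)
            elif move == "alpha":
                new.alpha, lh = _propose_scale(st.alpha, rng)
                if new.alpha > 300.0:  # gamma numerically flat beyond this
                    new.alpha = 300.0
            elif move == "nu":
                new.nu, lh = _propose_scale(st.nu, rng)
            else:
                if rng.random() < 0.3:
                    # independence draw from the Exp prior: mixes the
                    # near-zero tail a multiplier random walk crawls through
                    nd = float(rng.exponential(cfg.net_div_prior_mean))
                    lh = (nd - st.fbd.net_diversification) / cfg.net_div_prior_mean
                else:
                    nd, lh = _propose_scale(st.fbd.net_diversification, rng)
                new.fbd = FBDParams(
                    nd, st.fbd.turnover, st.fbd.fossil_sampling, st.fbd.rho
                )
            st_holder[0] = try_accept(move, new, lh)

        elif move in ("r", "s"):
            cur = st.fbd.turnover if move == "r" else st.fbd.fossil_sampling
            if rng.random() < 0.3:
                prop = rng.random()  # independence draw from the U(0,1) prior
            else:
                prop = (cur + 0.2 * (rng.random() - 0.5)) % 1.0  # symmetric wrap
            try:
                fbd = (
                    FBDParams(st.fbd.net_diversification, prop, st.fbd.fossil_sampling, st.fbd.rho)
                    if move == "r"
                    else FBDParams(st.fbd.net_diversification, st.fbd.turnover, prop, st.fbd.rho)
                )
            except ValueError:
                return
            new = ChainState(tree, st.rates, st.base_rate, st.nu, st.alpha, fbd)
            st_holder[0] = try_accept(move, new, 0.0)

        elif move == "node_age":
            v = internal[rng.integers(len(internal))]
            t2 = tree.copy()
            p = int(t2.parent[v])
            kids = t2.children[v]
            sa_kids = [c for c in kids if t2.sampled_ancestor[c]]
            lo = max(
                (t2.ages[c] for c in kids if not t2.sampled_ancestor[c]),
                default=0.0,
            )
            hi = t2.ages[p] if p >= 0 else None
            for c in sa_kids:
                if t2.labels[c] in t2.calibrations:
                    clo, chi = t2.calibrations[t2.labels[c]]
                    lo = max(lo, clo)
                    hi = chi if hi is None else min(hi, chi)
            if p < 0:
                # root move handled separately
                return
            if hi - lo <= _ZERO_TOL:
                return
            new_age = lo + rng.random() * (hi - lo)
            t2.ages[v] = new_age
            for c in sa_kids:
                t2.ages[c] = new_age
            new = ChainState(t2, st.rates, st.base_rate, st.nu, st.alpha, st.fbd)
            st_holder[0] = try_accept(move, new, 0.0)

        elif move == "root_age":
            t2 = tree.copy()
            root = t2.root
            kids = t2.children[root]
            sa_kids = [c for c in kids if t2.sampled_ancestor[c]]
            lo = max(
                (t2.ages[c] for c in kids if not t2.sampled_ancestor[c]),
                default=0.0,
            )
            hi = None
            for c in sa_kids:
                if t2.labels[c] in t2.calibrations:
                    clo, chi = t2.calibrations[t2.labels[c]]
                    lo = max(lo, clo)
                    hi = chi if hi is None else min(hi, chi)
            excess = t2.ages[root] - lo
            if excess <= _ZERO_TOL:
                return
            new_excess, lh = _propose_scale(excess, rng)
            new_age = lo + new_excess
            if hi is not None and new_age > hi:
                return
            t2.ages[root] = new_age
            for c in sa_kids:
                t2.ages[c] = new_age
            new = ChainState(t2, st.rates, st.base_rate, st.nu, st.alpha, st.fbd)
            st_holder[0] = try_accept(move, new, lh)

        elif move == "tip_age":
            f = fossil_tips[rng.integers(len(fossil_tips))]
            if tree.sampled_ancestor[f]:
                return
            lo, hi = tree.calibrations[tree.labels[f]]
            hi = min(hi, tree.ages[int(tree.parent[f])])
            if hi - lo <= _ZERO_TOL:
                return
            t2 = tree.copy()
            t2.ages[f] = lo + rng.random() * (hi - lo)
            new = ChainState(t2, st.rates, st.base_rate, st.nu, st.alpha, st.fbd)
            st_holder[0] = try_accept(move, new, 0.0)

        elif move == "sa_toggle":
            f = fossil_tips[rng.integers(len(fossil_tips))]
            p = int(tree.parent[f])
            lo, hi = tree.calibrations[tree.labels[f]]
            page = tree.ages[p]
            w = min(hi, page) - lo
            if w <= _ZERO_TOL:
                return
            t2 = tree.copy()
            if not tree.sampled_ancestor[f]:
                if not (lo <= page <= hi):
                    return
                t2.ages[f] = page
                t2.sampled_ancestor[f] = True
                lh = -np.log(w)  # reverse draws the age back from U(lo, min(hi, page))
            else:
                t2.sampled_ancestor[f] = False
                t2.ages[f] = lo + rng.random() * w
                lh = np.log(w)
            new = ChainState(t2, st.rates, st.base_rate, st.nu, st.alpha, st.fbd)
            st_holder[0] = try_accept(move, new, lh)

        elif move == "topology":
            cand = [v for v in internal if tree.parent[v] >= 0]
            if not cand:
                return
            p = cand[rng.integers(len(cand))]
            g = int(tree.parent[p])
            sibs = [c for c in tree.children[g] if c != p]
            kids = tree.children[p]
            if len(sibs) != 1 or len(kids) != 2:
                return
            c_node = sibs[0]
            b = kids[rng.integers(2)]
            involved = [p, g, c_node, b]
            if any(tree.sampled_ancestor[x] for x in involved):
                return
            if any(
                tree.sampled_ancestor[ch]
                for x in (p, g)
                for ch in tree.children[x]
            ):
                return
            if tree.ages[c_node] >= tree.ages[p]:
                return
            t2 = tree.copy()
            t2.parent[b] = g
            t2.parent[c_node] = p
            t2.invalidate()
            new = ChainState(t2, st.rates, st.base_rate, st.nu, st.alpha, st.fbd)
            st_holder[0] = try_accept(move, new, 0.0)

        elif move == "scale_times":
            # ridge move: scale every internal age by f and divide the base
            # rate by f, leaving effective lengths nearly invariant;
            # Jacobian of (ages, c) -> (f*ages, c/f) gives (n_int - 1) ln f
            f = float(np.exp(0.15 * (rng.random() - 0.5)))
            t2 = tree.copy()
            n_scaled = 0
            for v in internal:
                t2.ages[v] *= f
                n_scaled += 1
            for i in fossil_tips:
                if t2.sampled_ancestor[i]:
                    t2.ages[i] = t2.ages[int(t2.parent[i])]
            dur = t2.branch_durations()
            if np.any(dur < -_ZERO_TOL):
                return  # a fossil tip ended up older than its parent
            new = ChainState(
                t2, st.rates, st.base_rate / f, st.nu, st.alpha, st.fbd
            )
            lh = (n_scaled - 1) * np.log(f)
            st_holder[0] = try_accept(move, new, lh)

        elif move == "subtree_scale":
            # scale every internal age inside one subtree; loosens packed
            # deep nodes that single-age slides random-walk through slowly
            cand = [v for v in internal if tree.parent[v] >= 0]
            if not cand:
                return
            v = cand[rng.integers(len(cand))]
            f = float(np.exp(0.25 * (rng.random() - 0.5)))
            t2 = tree.copy()
            stack = [v]
            scaled = []
            while stack:
                u = stack.pop()
                if not t2.is_tip(u):
                    t2.ages[u] *= f
                    scaled.append(u)
                    stack.extend(t2.children[u])
                elif t2.sampled_ancestor[u]:
                    t2.ages[u] = t2.ages[int(t2.parent[u])] * 1.0
            for u in scaled:
                for ch in t2.children[u]:
                    if t2.sampled_ancestor[ch]:
                        t2.ages[ch] = t2.ages[u]
            if t2.ages[v] >= t2.ages[int(t2.parent[v])]:
                return
            dur = t2.branch_durations()
            if np.any(dur < -_ZERO_TOL):
                return
            new = ChainState(t2, st.rates, st.base_rate, st.nu, st.alpha, st.fbd)
            st_holder[0] = try_accept(move, new, len(scaled) * np.log(f))

        elif move == "branch_rate":
            v = int(rng.integers(tree.n_nodes))
            dur = tree.branch_durations()
            from_prior = rng.random() < 0.4
            if cfg.clock.model == "TK02":
                # the root node rate is fixed at 1: it is confounded with
                # the base clock rate and carries no prior term
                if v == tree.root:
                    return
                nr = st.rates.node_rates.copy()
                if from_prior and dur[v] > _ZERO_TOL:
                    # draw from the prior conditional on the parent rate;
                    # the proposal density cancels that prior factor, so
                    # acceptance hinges on children terms and likelihood
                    p = int(tree.parent[v])
                    var = st.nu * dur[v]
                    old, newv = nr[v], nr[p] * float(
                        np.exp(rng.normal(-var / 2.0, np.sqrt(var)))
                    )
                    nr[v] = newv
                    mlog = np.log(nr[p]) - var / 2.0
                    lh = float(
                        _lognormal_logpdf(old, mlog, np.sqrt(var))
                        - _lognormal_logpdf(newv, mlog, np.sqrt(var))
                    )
                else:
                    nr[v], lh = _propose_scale(nr[v], rng)
                new_rates = BranchRates(
                    _tk02_multipliers(tree, nr), node_rates=nr
                )
            else:
                if v == tree.root or dur[v] <= _ZERO_TOL:
                    return
                mult = st.rates.multipliers.copy()
                if from_prior:
                    old = mult[v]
                    if cfg.clock.model == "ILN":
                        newv = float(rng.lognormal(-st.nu / 2.0, np.sqrt(st.nu)))
                        lh = float(
                            _lognormal_logpdf(old, -st.nu / 2.0, np.sqrt(st.nu))
                            - _lognormal_logpdf(newv, -st.nu / 2.0, np.sqrt(st.nu))
                        )
                    elif cfg.clock.model == "IGR":
                        shape = 1.0 / st.nu
                        newv = float(rng.gamma(shape, st.nu))
                        lh = float(
                            _gamma_logpdf_scalar(old, shape, shape)
                            - _gamma_logpdf_scalar(newv, shape, shape)
                        )
                    else:  # WN
                        shape = dur[v] / st.nu
                        newv = float(rng.gamma(shape, 1.0 / shape))
                        lh = float(
                            _gamma_logpdf_scalar(old, shape, shape)
                            - _gamma_logpdf_scalar(newv, shape, shape)
                        )
                    mult[v] = newv
                else:
                    mult[v], lh = _propose_scale(mult[v], rng)
                new_rates = BranchRates(mult)
            new = ChainState(tree, new_rates, st.base_rate, st.nu, st.alpha, st.fbd)
            st_holder[0] = try_accept(move, new, lh)

    for it in range(1, n_generations + 1):
        attempt()

        if audit_every and it % audit_every == 0:
            st_holder[0].audit(engine)

        if it % sample_every == 0:
            s = st_holder[0]
            params_log["lnL"].append(s.components["lnL"])
            params_log["log_posterior"].append(s.log_posterior)
            params_log["root_age"].append(float(s.tree.ages[s.tree.root]))
            params_log["tree_length"].append(s.tree.tree_length())
            params_log["base_rate"].append(s.base_rate)
            params_log["nu"].append(s.nu)
            params_log["alpha"].append(s.alpha)
            params_log["net_diversification"].append(s.fbd.net_diversification)
            params_log["turnover"].append(s.fbd.turnover)
            params_log["fossil_sampling"].append(s.fbd.fossil_sampling)
            params_log["n_sampled_ancestors"].append(
                float(s.tree.sampled_ancestor.sum())
            )
            for lab in s.tree.calibrations:
                key = f"age_{lab}"
                params_log.setdefault(key, []).append(
                    float(s.tree.ages[s.tree.tip_index(lab)])
                )
            trees_out.append(s.tree.copy())
            iters.append(it)

    zero_accept = [
        m for m, (acc, tot) in accept.items() if tot > 20 and acc == 0
    ]
    if zero_accept:
        warnings.warn(
            f"proposal classes with zero acceptance: {zero_accept}", stacklevel=2
        )
    return Trace(
        params_log,
        trees_out,
        iters,
        seed,
        run_id,
        {m: (a, t) for m, (a, t) in accept.items()},
    )


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------
def _split_frequencies(trees: list[TimeTree]) -> dict[frozenset[str], float]:
    counts: dict[frozenset[str], int] = {}
    if not trees:
        return {}
    all_taxa = frozenset(trees[0].tip_labels)
    for t in trees:
        for clade in t.bipartitions():
            if clade != all_taxa and len(clade) > 1:
                counts[clade] = counts.get(clade, 0) + 1
    return {c: n / len(trees) for c, n in counts.items()}


def asdsf(tree_samples: list[list[TimeTree]], min_freq: float = 0.10) -> float:
    """Average across-run standard deviation of split frequencies.

    Splits qualify if their frequency reaches ``min_freq`` in at least one
    run; the standard deviation uses the n-1 convention.
    """
    if len(tree_samples) < 2:
        raise ValueError("ASDSF needs at least two independent runs")
    freqs = [_split_frequencies(ts) for ts in tree_samples]
    splits = set().union(*(f.keys() for f in freqs))
    qualifying = [
        s for s in splits if max(f.get(s, 0.0) for f in freqs) >= min_freq
    ]
    if not qualifying:
        warnings.warn("no splits reach min_freq; ASDSF reported as 0", stacklevel=2)
        return 0.0
    sds = [
        float(np.std([f.get(s, 0.0) for f in freqs], ddof=1)) for s in qualifying
    ]
    return float(np.mean(sds))


def psrf(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    ``chains`` is (n_chains, n_samples).  A zero-variance parameter is
    reported as 1 with a warning.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2:
        raise ValueError("PSRF needs at least two chains")
    w = chains.var(axis=1, ddof=1).mean()
    if w <= 0:
        warnings.warn("zero within-chain variance; PSRF reported as 1", stacklevel=2)
        return 1.0
    b_over_n = chains.mean(axis=1).var(ddof=1)
    v_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(v_hat / w))


def ess(series: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        return float(n)
    xc = x - x.mean()
    if np.all(xc == 0):
        warnings.warn("zero-variance series; ESS reported as n", stacklevel=2)
        return float(n)
    f = np.fft.rfft(xc, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n] / n
    rho = acov / acov[0]
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(n / max(tau, 1e-12))
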