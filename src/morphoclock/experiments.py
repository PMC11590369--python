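"""Reusable validation experiments over the whole stack.

These are the study-style computations the analysis drivers, the test
suite and the acceptance script share: simulation-based calibration of
node-age HPDs, prior-sampling checks, the stepping-stone toy model with a
closed-form marginal, DEC parameter recovery, stochastic-mapping
consistency, and small brute-force oracles.  Every function takes an
explicit seed and returns plain dictionaries of numbers.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
from scipy import stats
from scipy.linalg import expm

from .biogeo_dec import DECModel, cladogenetic_splits, dec_log_likelihood, fit_dec
from .char_mapping import node_state_posteriors, sample_history, select_model
from .clock_models import (
    BranchRates,
    ClockConfig,
    effective_lengths,
    sample_branch_rates,
)
from .io_formats import RangeTable
from .mcmc_engine import MCMCConfig, _tk02_multipliers, run_mcmc
from .mk_model import character_log_likelihood, discrete_gamma_rates
from .model_selection import beta_schedule, stepping_stone
from .synthetic_data import simulate_characters, simulate_fbd_tree, simulate_ranges
from .tree_priors import FBDParams, RootCalibration
from .tree_summary import hpd
from .trees import TimeTree

__all__ = [
    "node_age_coverage",
    "prior_sampling_ks",
    "stepping_stone_toy",
    "dec_recovery",
    "dec_oracle_error",
    "mk_oracle_error",
    "simmap_consistency",
    "two_run_asdsf",
]


# ----------------------------------------------------------------------
# simulation-based calibration of the dating machinery
# ----------------------------------------------------------------------
def node_age_coverage(
    seed: int = 177,
    n_replicates: int = 20,
    n_taxa: tuple[int, int] = (16, 26),
    n_chars: int = 100,
    clock_model: str = "ILN",
    n_generations: int = 25_000,
    hpd_mass: float = 0.95,
    max_seconds: float | None = None,
) -> dict:
    """Fraction of true node ages inside posterior HPD intervals.

    Each replicate draws a tip-dated FBD tree (root age from its
    offset-exponential calibration; fixed diversification parameters shared
    by generator and sampler, since the FBD density is not normalized over
    tip counts), clock parameters from their priors, evolves a
    variable-only character matrix, and re-infers node ages by MCMC with
    the topology held at truth.
    """
    import time

    rng = np.random.default_rng(seed)
    cal = RootCalibration(34.0, 41.2)
    fbd_true = FBDParams(0.12, 0.5, 0.5, 1.0)
    inside = total = 0
    done = 0
    t0 = time.time()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while done < n_replicates:
            if max_seconds is not None and time.time() - t0 > max_seconds:
                break
            root_age = cal.offset + rng.exponential(1.0 / cal.rate)
            try:
                tree, _ = simulate_fbd_tree(
                    fbd_true, root_age, seed=int(rng.integers(2**31 - 1)),
                    min_tips=n_taxa[0], max_tips=n_taxa[1],
                    max_tries=200, max_lineages=3000,
                )
            except RuntimeError:
                continue
            c = float(np.exp(np.log(0.4426) + 0.5 * rng.normal()))
            alpha = float(rng.exponential(1.0))
            nu = float(rng.exponential(0.1))
            sub_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
            br = sample_branch_rates(clock_model, tree, nu, sub_rng)
            if clock_model == "TK02":
                br = BranchRates(
                    _tk02_multipliers(tree, br.node_rates), node_rates=br.node_rates
                )
            eff = effective_lengths(tree, c, br)
            try:
                matrix = simulate_characters(
                    tree, eff, alpha, n_chars,
                    seed=int(rng.integers(2**31 - 1)), max_rejects=3000,
                )
            except RuntimeError:
                continue
            cfg = MCMCConfig(
                clock=ClockConfig(
                    model=clock_model,
                    base_rate_prior_mean_log=float(np.log(0.4426)),
                    base_rate_prior_sd_log=0.5,
                    variance=0.1,
                ),
                nu_prior_mean=0.1,
                root_calibration=cal,
                sample_topology=False,
                fixed_fbd=fbd_true,
            )
            trace = run_mcmc(
                matrix, tree, cfg, n_generations,
                seed=int(rng.integers(2**31 - 1)), sample_every=25,
            )
            trees = trace.trees[len(trace.trees) // 4 :]
            for clade, v in tree.bipartitions().items():
                if len(clade) <= 1:
                    continue
                ages = [t.ages[t.bipartitions()[clade]] for t in trees]
                lo, hi = hpd(ages, hpd_mass)
                total += 1
                inside += lo - 1e-9 <= tree.ages[v] <= hi + 1e-9
            done += 1
    return {
        "coverage": inside / max(total, 1),
        "n_nodes": total,
        "n_replicates": done,
    }


def prior_sampling_ks(seed: int = 5, n_generations: int = 150_000) -> dict:
    """KS p-values of prior-only MCMC marginals against the stated priors.

    Uses a hand-built tree whose focal fossil's window cannot collide with
    its parent, and detaches the FBD density so the target over
    (net diversification, turnover, fossil sampling, tip age) is exactly
    Exp(1) x U(0,1) x U(0,1) x U(window).
    """
    tree = TimeTree(
        [-1, 0, 0, 1, 1],
        [37.0, 25.0, 0.0, 11.0, 21.0],
        ["", "", "e1", "f1", "f2"],
        calibrations={"f1": (10.0, 12.0), "f2": (20.0, 22.0)},
    )
    cfg = MCMCConfig(
        clock=ClockConfig(model="strict"),
        root_calibration=RootCalibration(34.0, 41.2),
        use_likelihood=False,
        include_fbd_density=False,
        sample_sampled_ancestors=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trace = run_mcmc(None, tree, cfg, n_generations, seed=seed, sample_every=100)
    burn = 150
    d = np.array(trace.params["net_diversification"])[burn:]
    r = np.array(trace.params["turnover"])[burn:]
    s = np.array(trace.params["fossil_sampling"])[burn:]
    a = np.array(trace.params["age_f1"])[burn:]
    return {
        "net_diversification_exp1": float(stats.kstest(d, "expon").pvalue),
        "turnover_uniform": float(stats.kstest(r, "uniform").pvalue),
        "fossil_sampling_uniform": float(stats.kstest(s, "uniform").pvalue),
        "tip_age_uniform": float(
            stats.kstest(a, "uniform", args=(10.0, 2.0)).pvalue
        ),
    }


# ----------------------------------------------------------------------
# stepping-stone toy with analytic marginal
# ----------------------------------------------------------------------
def stepping_stone_toy(
    seed: int = 1,
    n_steps: int = 10,
    n_samples: int = 10_000,
    n_data: int = 20,
    prior_var: float = 4.0,
) -> dict:
    """Stepping stone on a conjugate normal-normal model vs the closed-form
    marginal likelihood (exact iid power-posterior samples per step)."""
    rng = np.random.default_rng(seed)
    data = rng.normal(1.3, 1.0, size=n_data)
    sigma2 = 1.0
    xbar = float(data.mean())

    def sample_lnl(beta, rng_):
        prec = 1.0 / prior_var + beta * n_data / sigma2
        var = 1.0 / prec
        mean = var * (beta * n_data * xbar / sigma2)
        theta = rng_.normal(mean, np.sqrt(var), size=n_samples)
        return (
            -0.5 * n_data * np.log(2 * np.pi * sigma2)
            - 0.5 * ((data[:, None] - theta[None, :]) ** 2).sum(axis=0) / sigma2
        )

    est, se = stepping_stone(sample_lnl, beta_schedule(n_steps), rng)
    cov = np.full((n_data, n_data), prior_var) + np.eye(n_data) * sigma2
    sign, logdet = np.linalg.slogdet(cov)
    analytic = float(
        -0.5 * n_data * np.log(2 * np.pi)
        - 0.5 * logdet
        - 0.5 * data @ np.linalg.solve(cov, data)
    )
    return {
        "estimate": est,
        "analytic": analytic,
        "mc_se": se,
        "abs_error": abs(est - analytic),
    }


# ----------------------------------------------------------------------
# DEC recovery and oracle
# ----------------------------------------------------------------------
_DEC_RECOVERY_CACHE: dict[tuple, dict] = {}


def dec_recovery(
    seed: int = 300,
    n_replicates: int = 20,
    d_true: float = 0.1,
    e_true: float = 0.05,
    n_areas: int = 5,
    tip_window: tuple[int, int] = (90, 130),
) -> dict:
    """ML recovery of DEC (d, e) from ranges simulated on ~100-tip trees.

    Range-extinct lineages are pruned before fitting (they are
    unobservable), which conditions the data on survival; dispersal is
    well recovered, extirpation collapses toward zero (the documented DEC
    identifiability failure) — both medians are reported.
    """
    key = (seed, n_replicates, d_true, e_true, n_areas, tip_window)
    if key in _DEC_RECOVERY_CACHE:
        return dict(_DEC_RECOVERY_CACHE[key])
    areas = [f"A{i + 1}" for i in range(n_areas)]
    rng = np.random.default_rng(seed)
    ds, es = [], []
    rep = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while rep < n_replicates:
            try:
                tree, _ = simulate_fbd_tree(
                    FBDParams(0.4, 0.1, 0.0, 1.0), 10.0,
                    seed=int(rng.integers(2**31 - 1)),
                    min_tips=tip_window[0], max_tips=tip_window[1],
                    max_tries=200, max_lineages=5000,
                )
            except RuntimeError:
                continue
            model = DECModel(areas, d_true, e_true, n_areas)
            try:
                table, _ = simulate_ranges(
                    tree, model, seed=int(rng.integers(2**31 - 1))
                )
            except RuntimeError:
                continue
            surv = tree.prune_to(table.presence.keys())
            if surv.n_tips < 10:
                continue
            fitted = fit_dec(surv, table, DECModel(areas, 0.01, 0.01, n_areas))
            ds.append(fitted.d)
            es.append(fitted.e)
            rep += 1
    out = {
        "median_d": float(np.median(ds)),
        "median_e": float(np.median(es)),
        "d_true": d_true,
        "e_true": e_true,
        "n_replicates": rep,
    }
    _DEC_RECOVERY_CACHE[key] = dict(out)
    return out


def _propagator_by_squaring(Q, t, n_doublings=22):
    P = np.eye(Q.shape[0]) + Q * (t / 2.0**n_doublings)
    for _ in range(n_doublings):
        P = P @ P
    return P


def dec_oracle_error(seed: int = 7, n_cases: int = 4) -> dict:
    """Max |pruning - brute force| over random 3-taxon DEC toys.

    The brute force sums over every internal range assignment and
    cladogenetic scenario with discretized (repeated-squaring) propagators.
    """
    from .biogeo_dec import dec_rate_matrix, enumerate_ranges

    tree = TimeTree([-1, 0, 0, 1, 1], [2.0, 1.0, 0.0, 0.0, 0.0], ["", "", "C", "A", "B"])
    areas = ["X", "Y", "Z"]
    rng = np.random.default_rng(seed)
    space = enumerate_ranges(3, 2)
    worst = 0.0
    for _ in range(n_cases):
        pres = {}
        for lab in "ABC":
            size = int(rng.integers(1, 3))
            vec = np.zeros(3, dtype=int)
            vec[rng.choice(3, size=size, replace=False)] = 1
            pres[lab] = vec
        ranges = RangeTable(areas, pres)
        model = DECModel(areas, 0.15, 0.08, 2)
        mine = dec_log_likelihood(tree, ranges, model)
        # brute force
        Q = dec_rate_matrix(space, model.d, model.e, np.ones((3, 3), int))
        P = {
            v: _propagator_by_squaring(
                Q, float(tree.ages[int(tree.parent[v])] - tree.ages[v])
            )
            for v in range(tree.n_nodes)
            if tree.parent[v] >= 0
        }
        tips = {
            int(v): space.index[ranges.area_set(tree.labels[int(v)])]
            for v in tree.tip_indices
        }
        prior = np.zeros(space.n_states)
        prior[1:] = 1.0 / (space.n_states - 1)
        internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
        total = 0.0
        for assign in product(range(1, space.n_states), repeat=len(internals)):
            st = dict(zip(internals, assign))
            p = prior[st[tree.root]]
            for v in internals:
                kids = tree.children[v]
                splits = cladogenetic_splits(space, space.states[st[v]])
                acc = 0.0
                for l, r_ in splits:
                    term = 1.0
                    for child, start in zip(kids, (l, r_)):
                        end = tips[child] if tree.is_tip(child) else st[child]
                        term *= P[child][space.index[start], end]
                    acc += term
                p *= acc / len(splits)
            total += p
        worst = max(worst, abs(mine - float(np.log(total))))
    return {"max_abs_error": worst, "n_cases": n_cases}


# ----------------------------------------------------------------------
# Mk pruning oracle
# ----------------------------------------------------------------------
def _random_dated_tree(n_tips, rng):
    parent = [-1]
    ages = [float(rng.uniform(1.0, 3.0))]
    labels = [""]
    frontier = [0]
    while len(frontier) < n_tips:
        v = frontier.pop(int(rng.integers(len(frontier))))
        for _ in range(2):
            idx = len(parent)
            parent.append(v)
            ages.append(float(rng.uniform(0.0, ages[v])))
            labels.append("")
            frontier.append(idx)
    for i, v in enumerate(frontier):
        labels[v] = f"T{i}"
        if rng.random() < 0.7:
            ages[v] = 0.0
    return TimeTree(parent, ages, labels)


def mk_oracle_error(seed: int = 11, n_cases: int = 200) -> dict:
    """Max |pruning - enumeration| over random small Mk likelihoods."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        k = int(rng.choice([2, 3, 4]))
        tree = _random_dated_tree(int(rng.integers(3, 7)), rng)
        eff = np.abs(rng.normal(0.3, 0.3, tree.n_nodes))
        col = {}
        for i in tree.tip_indices:
            size = 1 if rng.random() < 0.8 else 2
            col[tree.labels[int(i)]] = frozenset(
                rng.choice(k, size=min(size, k), replace=False).tolist()
            )
        rates = discrete_gamma_rates(float(rng.uniform(0.3, 2.0)), 3)
        mine = character_log_likelihood(tree, eff, col, k, rates)
        # enumeration with expm propagators
        Qm = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(Qm, -1.0)
        internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
        total = 0.0
        for r in rates:
            P = {v: expm(Qm * eff[v] * r) for v in range(tree.n_nodes)}
            for assign in product(range(k), repeat=len(internals)):
                st = dict(zip(internals, assign))
                p = 1.0 / k
                for v in range(tree.n_nodes):
                    par = int(tree.parent[v])
                    if par < 0:
                        continue
                    if tree.is_tip(v):
                        p *= sum(P[v][st[par], s] for s in col[tree.labels[v]])
                    else:
                        p *= P[v][st[par], st[v]]
                total += p
        ref = float(np.log(total / len(rates)))
        worst = max(worst, abs(mine - ref))
    return {"max_abs_error": worst, "n_cases": n_cases}


# ----------------------------------------------------------------------
# stochastic mapping consistency
# ----------------------------------------------------------------------
def simmap_consistency(seed: int = 9, n_histories: int = 10_000) -> dict:
    """Max deviation of sampled node-state frequencies from marginals."""
    tree = TimeTree(
        [-1, 0, 0, 1, 1, 2, 2, 5, 5],
        [10.0, 6.0, 7.0, 0.0, 0.0, 4.0, 0.0, 0.0, 0.0],
        ["", "", "", "A", "B", "", "C", "D", "E"],
    )
    column = {
        "A": frozenset([0]), "B": frozenset([0]),
        "C": frozenset([1]), "D": frozenset([1]), "E": frozenset([1]),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit, aics = select_model(tree, column, k=2)
        post = node_state_posteriors(tree, column, fit)
        hists = sample_history(tree, column, fit, n_histories, seed=seed)
    worst = 0.0
    for v in range(tree.n_nodes):
        freq0 = float(np.mean([h.node_states[v] == 0 for h in hists]))
        worst = max(worst, abs(freq0 - float(post[v][0])))
    return {
        "max_abs_deviation": worst,
        "n_histories": n_histories,
        "chosen_model": fit.model,
        "aic": aics,
    }


# ----------------------------------------------------------------------
# convergence diagnostics on a synthetic dating run
# ----------------------------------------------------------------------
def two_run_asdsf(
    seed: int = 21, n_generations: int = 30_000, n_chars: int = 60
) -> dict:
    """ASDSF between two independent dating runs on one synthetic dataset."""
    from .mcmc_engine import asdsf, ess

    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tree, _ = simulate_fbd_tree(
            FBDParams(0.05, 0.5, 0.3, 1.0), 37.6,
            seed=int(rng.integers(2**31 - 1)), min_tips=12, max_tips=20,
        )
        eff = effective_lengths(tree, 0.4426)
        matrix = simulate_characters(
            tree, eff, 1.0, n_chars, seed=int(rng.integers(2**31 - 1))
        )
        cfg = MCMCConfig(
            clock=ClockConfig(model="strict"),
            root_calibration=RootCalibration(34.0, 41.2),
        )
        traces = [
            run_mcmc(
                matrix, tree, cfg, n_generations,
                seed=int(rng.integers(2**31 - 1)), sample_every=30,
                run_id=f"run{i + 1}",
            ).burned(0.25)
            for i in range(2)
        ]
        value = asdsf([t.trees for t in traces])
        ess_root = float(
            sum(ess(np.array(t.params["root_age"])) for t in traces)
        )
    return {"asdsf": value, "ess_root_age": ess_root, "n_runs": 2}
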