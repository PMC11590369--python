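"""Branch-rate (relaxed clock) models for the morphological clock.

Five models map a base clock rate c (substitutions per Ma) and per-branch
multipliers to effective branch lengths:

* ``strict`` — all multipliers 1;
* ``ILN``   — independent lognormal multipliers with real-space mean 1
  (mean_log = -nu/2, var_log = nu);
* ``IGR``   — independent gamma multipliers, mean 1, variance nu;
* ``WN``    — white noise: gamma multipliers, mean 1, variance nu/duration;
* ``TK02``  — autocorrelated lognormal node rates: the child node's
  (relative) rate is lognormal around its parent's with log-variance
  nu * branch duration, and a branch's multiplier is the arithmetic mean
  of its endpoint rates.

The base-rate prior follows the informative construction used for
morphological clocks: median tree height in substitutions from a non-clock
run divided by the median root age, log-transformed, with a broad sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .trees import TimeTree

__all__ = [
    "CLOCK_MODELS",
    "ClockConfig",
    "BranchRates",
    "derive_clock_rate_prior",
    "sample_branch_rates",
    "branch_rate_log_prior",
    "effective_lengths",
]

CLOCK_MODELS = ("strict", "TK02", "ILN", "IGR", "WN")

_ZERO_TOL = 1e-12


@dataclass
class ClockConfig:
    """Clock-model choice plus the priors on its parameters."""

    model: str = "ILN"
    base_rate: float = 0.4426
    base_rate_prior_mean_log: float = float(np.log(0.4426))
    base_rate_prior_sd_log: float = 1.5
    variance: float = 0.1  # nu
    variance_prior_mean: float = 1.0  # exponential hyperprior mean

    def __post_init__(self) -> None:
        if self.model not in CLOCK_MODELS:
            raise ValueError(f"unknown clock model {self.model!r}")
        if self.base_rate <= 0 or self.base_rate_prior_sd_log <= 0:
            raise ValueError("base rate and its prior sd must be positive")
        if self.variance <= 0:
            raise ValueError("clock variance must be positive")


@dataclass
class BranchRates:
    """Per-branch positive multipliers (indexed by child node); TK02 also
    carries the per-node relative rates that the multipliers average."""

    multipliers: np.ndarray
    node_rates: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        if np.any(self.multipliers < 0):
            raise ValueError("branch-rate multipliers must be positive")

    @classmethod
    def strict(cls, n_nodes: int) -> "BranchRates":
        return cls(np.ones(n_nodes))


def derive_clock_rate_prior(
    tree_height_subst: float, root_age: float, sd_log: float = 1.5
) -> tuple[float, float]:
    """Lognormal prior parameters for the base clock rate.

    mean_log = ln(median tree height in substitutions / median root age);
    sd_log is passed through unchanged.
    """
    if tree_height_subst <= 0 or root_age <= 0:
        raise ValueError("tree height and root age must be positive")
    if sd_log <= 0:
        raise ValueError("sd_log must be positive")
    return float(np.log(tree_height_subst / root_age)), float(sd_log)


def _lognormal_logpdf(x, mean_log, sd_log):
    x = np.asarray(x, dtype=float)
    z = (np.log(x) - mean_log) / sd_log
    return -np.log(x * sd_log) - 0.5 * np.log(2.0 * np.pi) - 0.5 * z * z


def _gamma_logpdf(x, shape, rate):
    x = np.asarray(x, dtype=float)
    return (
        shape * np.log(rate)
        - gammaln(shape)
        + (shape - 1.0) * np.log(x)
        - rate * x
    )


def sample_branch_rates(
    model: str,
    tree: TimeTree,
    nu: float,
    rng: np.random.Generator,
) -> BranchRates:
    """Draw branch-rate multipliers from a clock model's prior.

    Sampled-ancestor attachment branches (zero duration) inherit rate 1 /
    the parent's node rate; they contribute nothing to effective length.
    """
    n = tree.n_nodes
    dur = tree.branch_durations()
    if model == "strict":
        return BranchRates.strict(n)
    if model == "ILN":
        sd = np.sqrt(nu)
        r = rng.lognormal(mean=-nu / 2.0, sigma=sd, size=n)
        r[tree.root] = 1.0
        return BranchRates(r)
    if model == "IGR":
        r = rng.gamma(shape=1.0 / nu, scale=nu, size=n)
        r[tree.root] = 1.0
        return BranchRates(r)
    if model == "WN":
        r = np.ones(n)
        for v in range(n):
            if v == tree.root or dur[v] <= _ZERO_TOL:
                continue
            shape = dur[v] / nu
            r[v] = rng.gamma(shape=shape, scale=1.0 / shape)
        return BranchRates(r)
    if model == "TK02":
        node_rates = np.ones(n)
        mult = np.ones(n)
        for v in tree.preorder():
            v = int(v)
            p = int(tree.parent[v])
            if p < 0:
                node_rates[v] = 1.0
                continue
            if dur[v] <= _ZERO_TOL:
                node_rates[v] = node_rates[p]
                mult[v] = node_rates[p]
                continue
            var = nu * dur[v]
            node_rates[v] = node_rates[p] * np.exp(
                rng.normal(-var / 2.0, np.sqrt(var))
            )
            mult[v] = 0.5 * (node_rates[p] + node_rates[v])
        return BranchRates(mult, node_rates=node_rates)
    raise ValueError(f"unknown clock model {model!r}")


def branch_rate_log_prior(
    model: str, rates: BranchRates, nu: float, tree: TimeTree
) -> float:
    """Log prior density of a set of branch rates under a clock model.

    Zero-duration (sampled-ancestor) branches are skipped: their rate is
    inherited and carries no density term.
    """
    dur = tree.branch_durations()
    root = tree.root
    r = rates.multipliers
    if model == "strict":
        if not np.allclose(r, 1.0):
            return -np.inf
        return 0.0
    mask = dur > _ZERO_TOL
    mask[root] = False
    if model == "TK02":
        if rates.node_rates is None:
            raise ValueError("TK02 prior needs node rates")
        nr = rates.node_rates
        par = tree.parent[mask]
        var = nu * dur[mask]
        vals = _lognormal_logpdf(
            nr[mask], np.log(nr[par]) - var / 2.0, np.sqrt(var)
        )
        return float(vals.sum())
    if model == "ILN":
        vals = _lognormal_logpdf(r[mask], -nu / 2.0, np.sqrt(nu))
    elif model == "IGR":
        vals = _gamma_logpdf(r[mask], 1.0 / nu, 1.0 / nu)
    elif model == "WN":
        shape = dur[mask] / nu
        vals = _gamma_logpdf(r[mask], shape, shape)
    else:
        raise ValueError(f"unknown clock model {model!r}")
    return float(vals.sum())


def effective_lengths(
    tree: TimeTree, base_rate: float, rates: BranchRates | None = None
) -> np.ndarray:
    """Expected substitutions on the branch above each node:
    duration x base rate x multiplier (zero on sampled-ancestor branches)."""
    dur = tree.branch_durations()
    mult = np.ones(tree.n_nodes) if rates is None else rates.multipliers
    out = dur * base_rate * mult
    out[dur <= _ZERO_TOL] = 0.0
    return out
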