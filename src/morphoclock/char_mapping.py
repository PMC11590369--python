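"""Stochastic character mapping on a fixed dated tree.

For each discrete character a continuous-time Markov chain is fitted by
maximum likelihood under one of three constraint classes — equal rates
(ER), symmetric (SYM) or all-rates-different (ARD) — the best class is
chosen by AIC, marginal ancestral-state posteriors are computed by an
up-down pruning pass (states called only above a 50% threshold), and full
histories are drawn by sampling node states backward and then
endpoint-conditioned paths along branches by uniformization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .trees import TimeTree

__all__ = [
    "CtmcFit",
    "MappedHistory",
    "fit_ctmc",
    "select_model",
    "node_state_posteriors",
    "call_states",
    "sample_history",
]

_MODELS = ("ER", "SYM", "ARD")
_ZERO_TOL = 1e-12


@dataclass
class CtmcFit:
    model: str
    Q: np.ndarray
    log_likelihood: float
    n_params: int
    root_prior: np.ndarray

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood


@dataclass
class MappedHistory:
    """One sampled character history: node states plus per-branch segments
    (state, dwell time) ordered from the parent end down to the child."""

    node_states: dict[int, int]
    branch_segments: dict[int, list[tuple[int, float]]] = field(default_factory=dict)

    def n_changes(self) -> int:
        total = 0
        for segs in self.branch_segments.values():
            total += max(len(segs) - 1, 0)
        return total


def _n_free(model: str, k: int) -> int:
    if model == "ER":
        return 1
    if model == "SYM":
        return k * (k - 1) // 2
    if model == "ARD":
        return k * (k - 1)
    raise ValueError(f"unknown model {model!r}")


def _build_q(model: str, k: int, params: np.ndarray) -> np.ndarray:
    Q = np.zeros((k, k))
    if model == "ER":
        Q[:] = params[0]
    elif model == "SYM":
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):
                Q[i, j] = Q[j, i] = params[idx]
                idx += 1
    else:  # ARD
        idx = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = params[idx]
                    idx += 1
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _stationary(Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _tip_partials(tree: TimeTree, column: dict[str, frozenset[int]], k: int):
    parts = {}
    for i in tree.tip_indices:
        lab = tree.labels[int(i)]
        if lab not in column:
            raise KeyError(f"taxon {lab!r} missing from character data")
        v = np.zeros(k)
        for s in column[lab]:
            v[s] = 1.0
        parts[int(i)] = v
    return parts


def _pruning(tree: TimeTree, Q: np.ndarray, tipdata, root_prior):
    """Return (lnL, per-node downward partials, per-branch P matrices)."""
    k = Q.shape[0]
    dur = tree.branch_durations()
    P = {}
    partial = {}
    scale = 0.0
    for v in tree.postorder():
        v = int(v)
        kids = tree.children[v]
        if not kids:
            partial[v] = tipdata[v].copy()
        else:
            acc = np.ones(k)
            for c in kids:
                P[c] = expm(Q * dur[c]) if dur[c] > _ZERO_TOL else np.eye(k)
                acc = acc * (P[c] @ partial[c])
            partial[v] = acc
        s = partial[v].max()
        if s <= 0:
            return -np.inf, partial, P
        partial[v] /= s
        scale += np.log(s)
    lik = float(root_prior @ partial[tree.root])
    if lik <= 0:
        return -np.inf, partial, P
    return float(np.log(lik) + scale), partial, P


def _char_loglik(tree, column, k, model, log_params, root: str):
    Q = _build_q(model, k, np.exp(log_params))
    prior = _stationary(Q) if root == "stationary" else np.full(k, 1.0 / k)
    tipdata = _tip_partials(tree, column, k)
    lnl, _, _ = _pruning(tree, Q, tipdata, prior)
    return lnl


def fit_ctmc(
    tree: TimeTree,
    column: dict[str, frozenset[int]],
    model: str = "ER",
    k: int | None = None,
    root_prior: str = "stationary",
) -> CtmcFit:
    """Maximum-likelihood CTMC fit for one character under ER/SYM/ARD.

    Rates are per Ma on the dated tree.  A character whose observed states
    collapse to one is flagged: its ML rate sits at the zero boundary.
    """
    observed = frozenset().union(*column.values())
    if k is None:
        k = max(observed) + 1
    if len(observed) < 2:
        warnings.warn("constant character: ML rate at the zero boundary", stacklevel=2)
    n_free = _n_free(model, k)
    # initial rate: parsimony-flavored changes per unit tree length
    base = max(len(observed) - 1, 1) / max(tree.tree_length(), 1e-6)
    best = None
    for start_scale in (1.0, 0.2):
        x0 = np.full(n_free, np.log(base * start_scale))
        res = minimize(
            lambda x: -_char_loglik(tree, column, k, model, x, root_prior),
            x0,
            method="L-BFGS-B",
            bounds=[(-18.0, 8.0)] * n_free,
        )
        if best is None or res.fun < best.fun:
            best = res
    Q = _build_q(model, k, np.exp(best.x))
    prior = _stationary(Q) if root_prior == "stationary" else np.full(k, 1.0 / k)
    return CtmcFit(model, Q, float(-best.fun), n_free, prior)


def select_model(
    tree: TimeTree,
    column: dict[str, frozenset[int]],
    k: int | None = None,
    models: tuple[str, ...] = _MODELS,
    root_prior: str = "stationary",
) -> tuple[CtmcFit, dict[str, float]]:
    """Fit all requested models; return the AIC-best fit and the AIC table.

    Ties prefer the simpler model (ER < SYM < ARD); a SYM/ARD fit that
    fails to produce a finite likelihood falls back to ER with a warning.
    """
    fits: dict[str, CtmcFit] = {}
    for m in models:
        try:
            fit = fit_ctmc(tree, column, m, k=k, root_prior=root_prior)
            if not np.isfinite(fit.log_likelihood):
                raise ArithmeticError("non-finite likelihood")
            fits[m] = fit
        except Exception as exc:  # noqa: BLE001 - fallback is the contract
            warnings.warn(
                f"{m} fit misbehaved ({exc}); falling back to ER", stacklevel=2
            )
    if not fits:
        raise ArithmeticError("no CTMC model could be fitted")
    aics = {m: f.aic for m, f in fits.items()}
    order = {m: i for i, m in enumerate(_MODELS)}
    best = min(fits, key=lambda m: (round(aics[m], 9), order[m]))
    return fits[best], aics


def node_state_posteriors(
    tree: TimeTree, column: dict[str, frozenset[int]], fit: CtmcFit
) -> dict[int, np.ndarray]:
    """Marginal ancestral-state probabilities at every node (up-down pass)."""
    k = fit.Q.shape[0]
    tipdata = _tip_partials(tree, column, k)
    lnl, partial, P = _pruning(tree, fit.Q, tipdata, fit.root_prior)
    if not np.isfinite(lnl):
        raise ArithmeticError("character has zero likelihood under the fit")
    up: dict[int, np.ndarray] = {tree.root: fit.root_prior.copy()}
    for v in tree.preorder():
        v = int(v)
        for c in tree.children[v]:
            sib = np.ones(k)
            for o in tree.children[v]:
                if o != c:
                    sib = sib * (P[o] @ partial[o])
            msg = up[v] * sib
            up[c] = msg @ P[c]
    out = {}
    for v in range(tree.n_nodes):
        m = up[v] * partial[v]
        out[v] = m / m.sum()
    return out


def call_states(
    posteriors: dict[int, np.ndarray], threshold: float = 0.5
) -> dict[int, int | str]:
    """Call the state whose posterior strictly exceeds the threshold,
    otherwise "uncertain"."""
    calls: dict[int, int | str] = {}
    for v, p in posteriors.items():
        i = int(np.argmax(p))
        calls[v] = i if p[i] > threshold else "uncertain"
    return calls


def histories_to_text(histories: list[MappedHistory], path) -> None:
    """Write sampled histories as a segment-list text file.

    One line per branch per history: ``history<TAB>branch<TAB>
    state:dwell,state:dwell,...`` ordered from the parent end down.
    """
    lines = ["history\tbranch\tsegments"]
    for h_idx, h in enumerate(histories):
        for branch, segs in sorted(h.branch_segments.items()):
            body = ",".join(f"{s}:{d:.6g}" for s, d in segs)
            lines.append(f"{h_idx}\t{branch}\t{body}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def _sample_dtmc_bridge(R_pows, a, b, n, rng):
    """Path of a DTMC bridge a -> b in n steps given cached powers of R."""
    states = [a]
    cur = a
    for step in range(1, n + 1):
        rem = n - step
        w = R_pows[1][cur] * R_pows[rem][:, b]
        w = np.clip(w, 0.0, None)
        tot = w.sum()
        if tot <= 0:
            raise ArithmeticError("DTMC bridge has no support")
        cur = int(rng.choice(len(w), p=w / tot))
        states.append(cur)
    return states


def _sample_path(Q, a, b, t, rng, max_jumps=10_000):
    """Endpoint-conditioned CTMC path by uniformization; returns segments."""
    k = Q.shape[0]
    if t <= _ZERO_TOL:
        if a != b:
            raise ArithmeticError("zero-length branch with differing endpoints")
        return [(a, 0.0)]
    mu = float(max(-Q.diagonal().min(), 1e-12))
    R = np.eye(k) + Q / mu
    Pab = expm(Q * t)[a, b]
    if Pab <= 0:
        raise ArithmeticError("endpoint pair has zero probability")
    # N | a -> b: e^{-mu t}(mu t)^n / n! * [R^n]_ab / Pab
    R_pows = [np.eye(k)]
    u = rng.random()
    log_pois = -mu * t
    cum = 0.0
    n = 0
    while True:
        if n >= len(R_pows):
            R_pows.append(R_pows[-1] @ R)
        cum += np.exp(log_pois) * R_pows[n][a, b] / Pab
        if u <= cum or n > max_jumps:
            break
        n += 1
        log_pois += np.log(mu * t) - np.log(n)
    if n > max_jumps:
        raise ArithmeticError("uniformization jump cap exceeded")
    while len(R_pows) <= n:
        R_pows.append(R_pows[-1] @ R)
    states = _sample_dtmc_bridge(R_pows, a, b, n, rng) if n > 0 else [a]
    times = np.sort(rng.random(n)) * t
    # collapse virtual (self) jumps into dwell segments
    segments: list[tuple[int, float]] = []
    cur_state = states[0]
    seg_start = 0.0
    for i in range(1, len(states)):
        if states[i] != cur_state:
            segments.append((cur_state, times[i - 1] - seg_start))
            seg_start = times[i - 1]
            cur_state = states[i]
    segments.append((cur_state, t - seg_start))
    return segments


def sample_history(
    tree: TimeTree,
    column: dict[str, frozenset[int]],
    fit: CtmcFit,
    n: int,
    seed: int,
) -> list[MappedHistory]:
    """Draw ``n`` full stochastic character maps consistent with the tips.

    Node states are sampled backward from the conditional distributions of
    the pruning pass; branch histories are endpoint-conditioned CTMC paths.
    """
    if n < 1:
        raise ValueError("need n >= 1 histories")
    rng = np.random.default_rng(seed)
    k = fit.Q.shape[0]
    tipdata = _tip_partials(tree, column, k)
    lnl, partial, P = _pruning(tree, fit.Q, tipdata, fit.root_prior)
    if not np.isfinite(lnl):
        raise ArithmeticError("character has zero likelihood under the fit")
    dur = tree.branch_durations()
    out = []
    for _ in range(n):
        node_states: dict[int, int] = {}
        for v in tree.preorder():
            v = int(v)
            p = int(tree.parent[v])
            if p < 0:
                w = fit.root_prior * partial[v]
            else:
                w = P[v][node_states[p]] * partial[v]
            w = np.clip(w, 0.0, None)
            node_states[v] = int(rng.choice(k, p=w / w.sum()))
        segs: dict[int, list[tuple[int, float]]] = {}
        for v in range(tree.n_nodes):
            p = int(tree.parent[v])
            if p < 0:
                continue
            try:
                segs[v] = _sample_path(
                    fit.Q, node_states[p], node_states[v], float(dur[v]), rng
                )
            except ArithmeticError as exc:
                raise ArithmeticError(f"path sampling failed on branch {v}: {exc}")
        out.append(MappedHistory(node_states, segs))
    return out
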