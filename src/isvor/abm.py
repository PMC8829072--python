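"""Discrete-time Monte-Carlo simulation of the five ISVOR roles on a graph.

Each step is synchronous: every node's next role is computed from the
time-t configuration and all updates are applied at once.  Within a node,
candidate transitions are evaluated as a sequence of Bernoulli trials with
short-circuit ("first success wins"): contact-driven trials come first, in
uniformly random order over the node's contact-trial multiset, and
spontaneous trials follow in a documented fixed order.

Two contact semantics are supported (``AbmConfig.contact_mode``):

``aggregate`` (default)
    Each contact-driven transition receives ONE Bernoulli trial at its
    nominal probability when the node has at least one qualifying
    neighbor.  This reads the per-step rates as per-individual
    probabilities conditional on contact ("when in contact with a
    spreader, an ignorant becomes a spreader with probability alpha") and
    keeps compound per-step probabilities on the scale the rates imply
    regardless of degree.

``per_contact``
    One independent trial per qualifying neighbor contact, so expected
    per-step transition counts scale with degree, mirroring the
    degree-multiplied mass-action terms of the mean-field system.  At mean
    degree 10 and rates around 0.5 the compound probabilities saturate
    toward 1, which suppresses the variation and oyster compartments; this
    mode exists for the mean-field correspondence (where rates are
    rescaled by 1/degree) and for sensitivity checks.

Per-node rules (role codes I=0, S=1, V=2, O=3, R=4):

I : alpha trial(s) from S-neighbors -> S and lam trial(s) from
    V-neighbors -> V, in random order (with epsilon enabled, an
    epsilon -> R trial precedes each alpha trial within its contact).
S : mu1 trial(s) from non-I neighbors -> R and eta trial(s) from
    V-neighbors -> V (random order); then spontaneous
    Bernoulli(gamma) -> V, then Bernoulli(xi1) -> O.
V : mu2 trial(s) from non-I neighbors -> R; then spontaneous
    Bernoulli(xi2) -> O.
O : spontaneous Bernoulli(theta) -> R (contact-driven theta trial(s)
    from non-I neighbors in ``theta_mode="contact"``), then
    Bernoulli(beta1) -> S, then Bernoulli(beta2) -> V.
R : absorbing.

Because contact trials are exchangeable, the first success among them is of
a given type with probability (successes of that type) / (total successes).
The vectorized sampler below exploits this: it draws per-type success
counts (binomial over contacts, or a single indicator trial in aggregate
mode) and then a categorical winner — an exact sampling of the
sequential-trial semantics, at O(edges) cost per step via sparse adjacency
mat-vecs.  :func:`exact_one_step` independently enumerates the per-trial
outcome space on tiny graphs and serves as the test oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Literal, Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .networks import Graph, NetworkSpec
from .params import IsvorParams
from .trajectory import ISVOR_COLUMNS, Trajectory

__all__ = [
    "ROLE_CODES",
    "ROLE_NAMES",
    "AbmConfig",
    "RoleAssignment",
    "TRANSITION_TYPES",
    "initialize",
    "step",
    "run",
    "RunResult",
    "ensemble",
    "exact_one_step",
]

ROLE_NAMES: tuple[str, ...] = ISVOR_COLUMNS  # ("I","S","V","O","R")
ROLE_CODES: dict[str, int] = {r: i for i, r in enumerate(ROLE_NAMES)}
_I, _S, _V, _O, _R = range(5)

TRANSITION_TYPES: tuple[str, ...] = (
    "I>S", "I>V", "I>R",
    "S>V", "S>O", "S>R",
    "V>O", "V>R",
    "O>S", "O>V", "O>R",
)


@dataclass(frozen=True)
class AbmConfig:
    """Configuration of one agent-based run.

    ``params.k`` is ignored: contacts come from the graph.  ``init_spreaders``
    is either a count of uniformly placed initial spreaders or an explicit
    node list; everyone else starts ignorant.
    """

    params: IsvorParams = field(default_factory=IsvorParams)
    init_spreaders: int | tuple[int, ...] = 1
    include_epsilon: bool = False
    contact_mode: Literal["aggregate", "per_contact"] = "aggregate"
    theta_mode: Literal["spontaneous", "contact"] = "spontaneous"
    lambda_mode: Literal["contact_with_V", "fraction_of_infections"] = (
        "contact_with_V"
    )
    t_max: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_mode not in ("aggregate", "per_contact"):
            raise ParameterError(f"unknown contact_mode {self.contact_mode!r}")
        if self.theta_mode not in ("spontaneous", "contact"):
            raise ParameterError(f"unknown theta_mode {self.theta_mode!r}")
        if self.lambda_mode not in ("contact_with_V", "fraction_of_infections"):
            raise ParameterError(f"unknown lambda_mode {self.lambda_mode!r}")
        if self.t_max < 1:
            raise ParameterError("t_max must be >= 1")
        if isinstance(self.init_spreaders, int):
            if self.init_spreaders < 1:
                raise ParameterError("init_spreaders must be >= 1")
        else:
            object.__setattr__(self, "init_spreaders",
                               tuple(int(i) for i in self.init_spreaders))
            if len(self.init_spreaders) < 1:
                raise ParameterError("init_spreaders list must be non-empty")


@dataclass
class RoleAssignment:
    """Role of every node at one time step."""

    roles: np.ndarray  # int8 array of role codes, length n_nodes
    step: int = 0

    def __post_init__(self) -> None:
        self.roles = np.asarray(self.roles, dtype=np.int8)
        if self.roles.ndim != 1:
            raise ParameterError("roles must be a 1-D sequence")
        if self.roles.min(initial=0) < 0 or self.roles.max(initial=0) > 4:
            raise ParameterError("role codes must be in 0..4 (I,S,V,O,R)")

    def counts(self) -> np.ndarray:
        """Integer count of each role; sums to n_nodes exactly."""
        return np.bincount(self.roles, minlength=5)

    def densities(self) -> np.ndarray:
        return self.counts() / self.roles.size


def initialize(
    g: Graph, cfg: AbmConfig, rng: np.random.Generator | None = None
) -> RoleAssignment:
    """All nodes ignorant except the initial spreaders."""
    roles = np.zeros(g.n_nodes, dtype=np.int8)
    if isinstance(cfg.init_spreaders, tuple):
        nodes = np.asarray(cfg.init_spreaders, dtype=np.int64)
        if nodes.size >= g.n_nodes:
            raise ParameterError("init_spreaders must leave at least one ignorant")
        if nodes.min() < 0 or nodes.max() >= g.n_nodes:
            raise ParameterError("init spreader id outside node range")
    else:
        if cfg.init_spreaders >= g.n_nodes:
            raise ParameterError("init_spreaders must leave at least one ignorant")
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        nodes = rng.choice(g.n_nodes, size=cfg.init_spreaders, replace=False)
    roles[nodes] = _S
    return RoleAssignment(roles, step=0)


def _categorical_winner(
    rng: np.random.Generator, counts: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Given per-type success counts (arrays of equal length), return
    (any_success mask, winner type index) with P(type) = count/total."""
    stacked = np.stack(counts, axis=0).astype(float)
    total = stacked.sum(axis=0)
    any_succ = total > 0
    winner = np.zeros(total.shape, dtype=np.int64)
    if np.any(any_succ):
        probs = stacked[:, any_succ] / total[any_succ]
        u = rng.random(int(any_succ.sum()))
        # guard against cumulative rounding putting u past the last bin
        winner[any_succ] = np.minimum(
            (np.cumsum(probs, axis=0) < u).sum(axis=0), len(counts) - 1
        )
    return any_succ, winner


def step(
    g: Graph,
    assignment: RoleAssignment,
    cfg: AbmConfig,
    rng: np.random.Generator,
) -> tuple[RoleAssignment, dict[str, int]]:
    """One synchronous update; returns the new assignment and the realized
    transition counts (keys from :data:`TRANSITION_TYPES`)."""
    p = cfg.params
    roles = assignment.roles
    n = roles.size
    adj = g.adjacency()

    is_s = (roles == _S).astype(np.int64)
    is_v = (roles == _V).astype(np.int64)
    non_i = (roles != _I).astype(np.int64)
    n_s = adj @ is_s      # S-neighbors of every node
    n_v = adj @ is_v      # V-neighbors
    n_ni = adj @ non_i    # non-ignorant neighbors
    if cfg.contact_mode == "aggregate":
        # one trial per transition type given >=1 qualifying neighbor:
        # clamping the contact counts to {0, 1} turns every binomial draw
        # below into a single Bernoulli trial
        n_s = np.minimum(n_s, 1)
        n_v = np.minimum(n_v, 1)
        n_ni = np.minimum(n_ni, 1)

    new_roles = roles.copy()

    # --- Ignorant nodes -----------------------------------------------
    mask = roles == _I
    if np.any(mask):
        ns, nv = n_s[mask], n_v[mask]
        eps = p.epsilon if cfg.include_epsilon else 0.0
        r_cnt = rng.binomial(ns, eps) if eps > 0 else np.zeros_like(ns)
        s_cnt = rng.binomial(ns - r_cnt, p.alpha)
        if cfg.lambda_mode == "contact_with_V":
            v_cnt = rng.binomial(nv, p.lam)
            any_succ, winner = _categorical_winner(rng, [r_cnt, s_cnt, v_cnt])
            outcome = np.array([_R, _S, _V], dtype=np.int8)[winner]
        else:  # fraction_of_infections: I->S conversions flip to V w.p. lam
            any_succ, winner = _categorical_winner(rng, [r_cnt, s_cnt])
            outcome = np.array([_R, _S], dtype=np.int8)[winner]
            became_s = any_succ & (outcome == _S)
            flips = rng.random(outcome.size) < p.lam
            outcome[became_s & flips] = _V
        idx = np.flatnonzero(mask)[any_succ]
        new_roles[idx] = outcome[any_succ]

    # --- Spreader nodes -----------------------------------------------
    mask = roles == _S
    if np.any(mask):
        m = int(mask.sum())
        r_cnt = rng.binomial(n_ni[mask], p.mu1)
        v_cnt = rng.binomial(n_v[mask], p.eta)
        any_succ, winner = _categorical_winner(rng, [r_cnt, v_cnt])
        outcome = np.where(winner == 0, _R, _V).astype(np.int8)
        # spontaneous sequence for contact-quiet nodes: gamma -> V, xi1 -> O
        quiet = ~any_succ
        to_v = quiet & (rng.random(m) < p.gamma)
        to_o = quiet & ~to_v & (rng.random(m) < p.xi1)
        nxt = roles[mask].copy()
        nxt[any_succ] = outcome[any_succ]
        nxt[to_v] = _V
        nxt[to_o] = _O
        new_roles[mask] = nxt

    # --- Variation nodes ----------------------------------------------
    mask = roles == _V
    if np.any(mask):
        m = int(mask.sum())
        to_r = rng.binomial(n_ni[mask], p.mu2) > 0
        to_o = ~to_r & (rng.random(m) < p.xi2)
        nxt = roles[mask].copy()
        nxt[to_r] = _R
        nxt[to_o] = _O
        new_roles[mask] = nxt

    # --- Oyster nodes ---------------------------------------------------
    mask = roles == _O
    if np.any(mask):
        m = int(mask.sum())
        if cfg.theta_mode == "spontaneous":
            to_r = rng.random(m) < p.theta
        else:  # one theta trial per non-ignorant neighbor
            to_r = rng.binomial(n_ni[mask], p.theta) > 0
        to_s = ~to_r & (rng.random(m) < p.beta1)
        to_v = ~to_r & ~to_s & (rng.random(m) < p.beta2)
        nxt = roles[mask].copy()
        nxt[to_r] = _R
        nxt[to_s] = _S
        nxt[to_v] = _V
        new_roles[mask] = nxt

    log = _transition_counts(roles, new_roles)
    return RoleAssignment(new_roles, step=assignment.step + 1), log


def _transition_counts(old: np.ndarray, new: np.ndarray) -> dict[str, int]:
    moved = old != new
    pairs = old[moved].astype(np.int64) * 5 + new[moved]
    counts = np.bincount(pairs, minlength=25)
    return {
        t: int(counts[ROLE_CODES[t[0]] * 5 + ROLE_CODES[t[2]]])
        for t in TRANSITION_TYPES
    }


@dataclass
class RunResult:
    """A single seeded run: density trajectory, per-step transition counts,
    and the final role assignment."""

    trajectory: Trajectory
    transitions: list[dict[str, int]]
    final_assignment: RoleAssignment

    @property
    def absorbed(self) -> bool:
        c = self.final_assignment.counts()
        return int(c[_S] + c[_V] + c[_O]) == 0


def run(
    g: Graph,
    cfg: AbmConfig,
    rng: np.random.Generator | None = None,
) -> RunResult:
    """Simulate until ``t_max`` steps or until the absorbing set (no
    spreaders, variations or oysters) is reached, whichever is first."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    assignment = initialize(g, cfg, rng)
    dens = [assignment.densities()]
    logs: list[dict[str, int]] = []
    for _ in range(cfg.t_max):
        counts = assignment.counts()
        if counts[_S] + counts[_V] + counts[_O] == 0:
            break
        assignment, log = step(g, assignment, cfg, rng)
        dens.append(assignment.densities())
        logs.append(log)
    traj = Trajectory(
        np.arange(len(dens), dtype=float),
        np.asarray(dens),
        ISVOR_COLUMNS,
        {"model": "isvor_abm", "n_nodes": g.n_nodes,
         "params": cfg.params.as_dict(), "t_max": cfg.t_max,
         "theta_mode": cfg.theta_mode, "lambda_mode": cfg.lambda_mode,
         "graph": dict(g.provenance)},
    )
    return RunResult(traj, logs, assignment)


def _pad_to(traj: Trajectory, length: int) -> np.ndarray:
    """Extend a run's density matrix to ``length`` rows by repeating the
    absorbing final row."""
    d = traj.data
    if d.shape[0] >= length:
        return d[:length]
    pad = np.repeat(d[-1][None, :], length - d.shape[0], axis=0)
    return np.vstack([d, pad])


def ensemble(
    g: Graph | NetworkSpec,
    cfg: AbmConfig,
    reps: int,
    return_runs: bool = False,
) -> Trajectory | tuple[Trajectory, list[RunResult]]:
    """Mean trajectory with pointwise standard errors over ``reps``
    independent runs.

    With a :class:`NetworkSpec`, a fresh graph is generated per rep; with a
    concrete :class:`Graph` the instance is shared.  Per-rep RNG streams are
    spawned from ``cfg.seed`` via ``numpy.random.SeedSequence`` so the
    ensemble is reproducible and reps are independent.  Runs shorter than
    the longest are padded with their absorbing values.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(reps)
    results: list[RunResult] = []
    for child in children:
        rng = np.random.default_rng(child)
        if isinstance(g, NetworkSpec):
            graph_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            graph = g.realize(graph_seed)
        else:
            graph = g
        results.append(run(graph, cfg, rng))
    length = max(len(r.trajectory) for r in results)
    stack = np.stack([_pad_to(r.trajectory, length) for r in results])
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else np.zeros_like(mean)
    traj = Trajectory(
        np.arange(length, dtype=float), mean, ISVOR_COLUMNS,
        {"model": "isvor_abm_ensemble", "reps": reps, "seed": cfg.seed,
         "params": cfg.params.as_dict(),
         "network": g.provenance if isinstance(g, Graph) else vars(g).copy()},
        stderr=se,
    )
    if return_runs:
        return traj, results
    return traj


# ---------------------------------------------------------------------------
# Exact one-step oracle (tiny graphs)

def _first_success_distribution(
    trials: list[tuple[float, int]]
) -> dict[int | None, float]:
    """Distribution of the type of the first success when the given
    (success probability, type) trials are performed in uniformly random
    order.  Enumerates every success/failure pattern explicitly; the first
    success in a uniform ordering is uniform over the realized successes.
    Returns a mapping type -> probability, with None for "no success"."""
    out: dict[int | None, float] = {}
    for pattern in itertools.product([0, 1], repeat=len(trials)):
        prob = 1.0
        succ: list[int] = []
        for hit, (q, typ) in zip(pattern, trials):
            prob *= q if hit else (1.0 - q)
            if hit:
                succ.append(typ)
        if prob == 0.0:
            continue
        if not succ:
            out[None] = out.get(None, 0.0) + prob
        else:
            total = len(succ)
            for typ in set(succ):
                share = succ.count(typ) / total
                out[typ] = out.get(typ, 0.0) + prob * share
    return out


def _sequential(probs: list[tuple[float, int]], stay: int) -> dict[int, float]:
    """Short-circuit sequence of spontaneous Bernoulli trials."""
    out: dict[int, float] = {}
    remaining = 1.0
    for q, typ in probs:
        out[typ] = out.get(typ, 0.0) + remaining * q
        remaining *= 1.0 - q
    out[stay] = out.get(stay, 0.0) + remaining
    return out


def _node_distribution(
    node: int, roles: np.ndarray, neighbors: np.ndarray, cfg: AbmConfig
) -> dict[int, float]:
    """Exact next-role distribution of one node given the configuration."""
    p = cfg.params
    role = roles[node]
    nb_roles = roles[neighbors]
    aggregate = cfg.contact_mode == "aggregate"

    def clamp(c: int) -> int:
        return min(c, 1) if aggregate else c

    n_ni_contacts = clamp(int(np.sum(nb_roles != _I)))
    n_v_contacts = clamp(int(np.sum(nb_roles == _V)))

    if role == _R:
        return {_R: 1.0}

    if role == _I:
        eps = p.epsilon if cfg.include_epsilon else 0.0
        return _ignorant_distribution(
            clamp(int(np.sum(nb_roles == _S))), n_v_contacts,
            p, eps, cfg.lambda_mode == "contact_with_V",
        )

    if role == _S:
        trials: list[tuple[float, int]] = (
            [(p.mu1, _R)] * n_ni_contacts + [(p.eta, _V)] * n_v_contacts
        )
        first = _first_success_distribution(trials)
        out: dict[int, float] = {}
        for typ, q in first.items():
            if typ is None:
                tail = _sequential([(p.gamma, _V), (p.xi1, _O)], stay=_S)
                for t2, q2 in tail.items():
                    out[t2] = out.get(t2, 0.0) + q * q2
            else:
                out[typ] = out.get(typ, 0.0) + q
        return out

    if role == _V:
        p_r = 1.0 - (1.0 - p.mu2) ** n_ni_contacts
        out = {_R: p_r}
        tail = _sequential([(p.xi2, _O)], stay=_V)
        for t2, q2 in tail.items():
            out[t2] = out.get(t2, 0.0) + (1.0 - p_r) * q2
        return {t: q for t, q in out.items() if q > 0}

    # role == _O
    if cfg.theta_mode == "spontaneous":
        return _sequential(
            [(p.theta, _R), (p.beta1, _S), (p.beta2, _V)], stay=_O
        )
    p_r = 1.0 - (1.0 - p.theta) ** n_ni_contacts
    out = {_R: p_r}
    tail = _sequential([(p.beta1, _S), (p.beta2, _V)], stay=_O)
    for t2, q2 in tail.items():
        out[t2] = out.get(t2, 0.0) + (1.0 - p_r) * q2
    return {t: q for t, q in out.items() if q > 0}


def _ignorant_distribution(
    s_contacts: int, v_contacts: int,
    p: IsvorParams, eps: float, contact_v: bool,
) -> dict[int, float]:
    """Enumerate every S-contact (three-way: R / S / nothing) and V-contact
    (two-way: V / nothing) outcome of an ignorant node and average the
    first-success type over uniform contact orderings."""
    if not contact_v:
        v_contacts = 0
    lam_redirect = 0.0 if contact_v else p.lam

    out: dict[int, float] = {}
    s_outcomes = [(_R, eps), (_S, (1 - eps) * p.alpha),
                  (None, (1 - eps) * (1 - p.alpha))]
    v_outcomes = [(_V, p.lam), (None, 1 - p.lam)]
    for s_pat in itertools.product(s_outcomes, repeat=s_contacts):
        for v_pat in itertools.product(v_outcomes, repeat=v_contacts):
            prob = 1.0
            succ: list[int] = []
            for typ, q in (*s_pat, *v_pat):
                prob *= q
                if typ is not None:
                    succ.append(typ)
            if prob == 0.0:
                continue
            if not succ:
                out[_I] = out.get(_I, 0.0) + prob
                continue
            total = len(succ)
            for typ in set(succ):
                share = succ.count(typ) / total
                if typ == _S and lam_redirect > 0:
                    out[_S] = out.get(_S, 0.0) + prob * share * (1 - lam_redirect)
                    out[_V] = out.get(_V, 0.0) + prob * share * lam_redirect
                else:
                    out[typ] = out.get(typ, 0.0) + prob * share
    return out


def exact_one_step(
    g: Graph, assignment: RoleAssignment, cfg: AbmConfig
) -> dict[tuple[int, ...], float]:
    """Exact distribution over next-step role assignments.

    Only feasible on tiny graphs (``n_nodes <= 8``).  Under synchronous
    updating the nodes' next roles are conditionally independent given the
    current configuration, so the joint law is the product of the per-node
    marginals, each obtained by enumerating its Bernoulli trial outcomes.
    """
    if g.n_nodes > 8:
        raise ParameterError("exact_one_step supports at most 8 nodes")
    roles = assignment.roles
    adj = g.adjacency()
    marginals = []
    for node in range(g.n_nodes):
        neighbors = adj.indices[adj.indptr[node]:adj.indptr[node + 1]]
        marginals.append(_node_distribution(node, roles, neighbors, cfg))
    out: dict[tuple[int, ...], float] = {}
    for combo in itertools.product(*(m.items() for m in marginals)):
        prob = 1.0
        key = []
        for typ, q in combo:
            prob *= q
            key.append(typ)
        if prob > 0:
            out[tuple(key)] = out.get(tuple(key), 0.0) + prob
    return out
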