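"""Comparator rumor models: network SIR, SEIR, and Twin-SIR.

These share the agent-based machinery of :mod:`isvor.abm` — synchronous
updates, one Bernoulli trial per qualifying contact, first success wins —
so that differences from the five-role model are attributable to model
structure, not to simulation semantics.

The SIR comparator is fully specified by the study settings (infection
``alpha`` per contact with an infected neighbor, spontaneous recovery
``mu1``).  SEIR and Twin-SIR rate values are standard reconstructions, not
study-given numbers: the incubation (E -> I) probability defaults to 0.5,
the dispeller conversion probability defaults to ``alpha``, and the
dispeller enters 2 steps after the rumor — at the study rates the rumor
peaks within about 5 steps, so a later dispeller could not suppress the
peak at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import ParameterError
from .networks import Graph, NetworkSpec
from .trajectory import Trajectory

__all__ = [
    "BaselineParams",
    "run_sir",
    "run_seir",
    "run_twin_sir",
    "baseline_ensemble",
]


@dataclass(frozen=True)
class BaselineParams:
    """Rates of the comparator models (all per-step probabilities).

    ``incubation`` is SEIR-only; the ``dispeller_*`` fields are
    Twin-SIR-only.  ``dispeller_conversion=None`` means "same as alpha" and
    ``dispeller_recovery=None`` means "same as mu1".
    """

    model: Literal["sir", "seir", "twin_sir"] = "sir"
    alpha: float = 0.5
    mu1: float = 0.5
    contact_mode: Literal["aggregate", "per_contact"] = "aggregate"
    incubation: float = 0.5
    dispeller_conversion: float | None = None
    dispeller_recovery: float | None = None
    dispeller_delay: int | None = 2
    dispeller_init: int = 1

    def __post_init__(self) -> None:
        if self.model not in ("sir", "seir", "twin_sir"):
            raise ParameterError(f"unknown baseline model {self.model!r}")
        if self.contact_mode not in ("aggregate", "per_contact"):
            raise ParameterError(f"unknown contact_mode {self.contact_mode!r}")
        for name in ("alpha", "mu1", "incubation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v!r} outside [0, 1]")
        for name in ("dispeller_conversion", "dispeller_recovery"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v!r} outside [0, 1]")

    @property
    def conversion(self) -> float:
        return self.alpha if self.dispeller_conversion is None else self.dispeller_conversion

    @property
    def dispeller_mu(self) -> float:
        return self.mu1 if self.dispeller_recovery is None else self.dispeller_recovery


def _init_roles(
    g: Graph, init: int | Sequence[int], infected_code: int,
    rng: np.random.Generator,
) -> np.ndarray:
    roles = np.zeros(g.n_nodes, dtype=np.int8)
    if isinstance(init, (int, np.integer)):
        if not (1 <= init < g.n_nodes):
            raise ParameterError("init count must be in [1, n_nodes)")
        nodes = rng.choice(g.n_nodes, size=int(init), replace=False)
    else:
        nodes = np.asarray(list(init), dtype=np.int64)
        if nodes.min() < 0 or nodes.max() >= g.n_nodes:
            raise ParameterError("init node id outside node range")
    roles[nodes] = infected_code
    return roles


def _finish(dens: list[np.ndarray], columns: tuple[str, ...],
            meta: dict) -> Trajectory:
    return Trajectory(np.arange(len(dens), dtype=float), np.asarray(dens),
                      columns, meta)


def run_sir(
    g: Graph,
    p: BaselineParams,
    init: int | Sequence[int] = 1,
    t_max: int = 100,
    seed: int | np.random.Generator = 0,
) -> Trajectory:
    """Network SIR: S -> I per infected contact (alpha); I -> R
    spontaneously (mu1).  Stops early once no infected remain."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S, I, R = 0, 1, 2
    roles = _init_roles(g, init, I, rng)
    adj = g.adjacency()
    dens = [np.bincount(roles, minlength=3) / g.n_nodes]
    for _ in range(t_max):
        if not np.any(roles == I):
            break
        n_inf = adj @ (roles == I).astype(np.int64)
        if p.contact_mode == "aggregate":
            n_inf = np.minimum(n_inf, 1)
        new = roles.copy()
        sus = roles == S
        hit = rng.binomial(n_inf[sus], p.alpha) > 0
        new[np.flatnonzero(sus)[hit]] = I
        inf = roles == I
        rec = rng.random(int(inf.sum())) < p.mu1
        new[np.flatnonzero(inf)[rec]] = R
        roles = new
        dens.append(np.bincount(roles, minlength=3) / g.n_nodes)
    return _finish(dens, ("S", "I", "R"),
                   {"model": "sir", "alpha": p.alpha, "mu1": p.mu1,
                    "n_nodes": g.n_nodes})


def run_seir(
    g: Graph,
    p: BaselineParams,
    init: int | Sequence[int] = 1,
    t_max: int = 100,
    seed: int | np.random.Generator = 0,
) -> Trajectory:
    """Network SEIR: S -> E per infected contact (alpha), E -> I
    spontaneously (incubation), I -> R spontaneously (mu1)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S, E, I, R = 0, 1, 2, 3
    roles = _init_roles(g, init, I, rng)
    adj = g.adjacency()
    dens = [np.bincount(roles, minlength=4) / g.n_nodes]
    for _ in range(t_max):
        if not np.any((roles == I) | (roles == E)):
            break
        n_inf = adj @ (roles == I).astype(np.int64)
        if p.contact_mode == "aggregate":
            n_inf = np.minimum(n_inf, 1)
        new = roles.copy()
        sus = roles == S
        hit = rng.binomial(n_inf[sus], p.alpha) > 0
        new[np.flatnonzero(sus)[hit]] = E
        exp = roles == E
        prog = rng.random(int(exp.sum())) < p.incubation
        new[np.flatnonzero(exp)[prog]] = I
        inf = roles == I
        rec = rng.random(int(inf.sum())) < p.mu1
        new[np.flatnonzero(inf)[rec]] = R
        roles = new
        dens.append(np.bincount(roles, minlength=4) / g.n_nodes)
    return _finish(dens, ("S", "E", "I", "R"),
                   {"model": "seir", "alpha": p.alpha, "mu1": p.mu1,
                    "incubation": p.incubation, "n_nodes": g.n_nodes})


def run_twin_sir(
    g: Graph,
    p: BaselineParams,
    init: int | Sequence[int] = 1,
    t_max: int = 100,
    seed: int | np.random.Generator = 0,
) -> Trajectory:
    """Twin-SIR with a competing rumor dispeller.

    Roles: susceptible, S1 (rumor spreader), S2 (dispeller), R.
    Susceptibles convert per contact to S1 (alpha) or S2 (conversion),
    first contact success wins; an S2 contact converts S1 to S2; both
    spreader types decay spontaneously to R.  ``dispeller_delay`` steps
    after the start, ``dispeller_init`` random non-S1 nodes become S2
    (``dispeller_delay=None`` disables the dispeller entirely, which
    reduces the model to plain SIR and is delegated to :func:`run_sir`).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if p.dispeller_delay is None:
        sir = run_sir(g, p, init, t_max, rng)
        return Trajectory(
            sir.times,
            np.column_stack([sir["S"], sir["I"], np.zeros(len(sir)), sir["R"]]),
            ("S", "S1", "S2", "R"),
            {**sir.metadata, "model": "twin_sir", "dispeller": "absent"},
        )
    SUS, S1, S2, R = 0, 1, 2, 3
    conv, mu2 = p.conversion, p.dispeller_mu
    roles = _init_roles(g, init, S1, rng)
    adj = g.adjacency()
    dens = [np.bincount(roles, minlength=4) / g.n_nodes]
    for t in range(t_max):
        if t == p.dispeller_delay:
            candidates = np.flatnonzero(roles == SUS)
            if candidates.size:
                chosen = rng.choice(
                    candidates,
                    size=min(p.dispeller_init, candidates.size),
                    replace=False,
                )
                roles[chosen] = S2
                dens[-1] = np.bincount(roles, minlength=4) / g.n_nodes
        if not np.any((roles == S1) | (roles == S2)):
            break
        n_s1 = adj @ (roles == S1).astype(np.int64)
        n_s2 = adj @ (roles == S2).astype(np.int64)
        if p.contact_mode == "aggregate":
            n_s1 = np.minimum(n_s1, 1)
            n_s2 = np.minimum(n_s2, 1)
        new = roles.copy()
        sus = roles == SUS
        a = rng.binomial(n_s1[sus], p.alpha)
        b = rng.binomial(n_s2[sus], conv)
        tot = a + b
        hit = tot > 0
        u = rng.random(int(hit.sum()))
        to_s2 = u < (b[hit] / np.maximum(tot[hit], 1))
        idx = np.flatnonzero(sus)[hit]
        new[idx] = np.where(to_s2, S2, S1)
        s1 = roles == S1
        converted = rng.binomial(n_s2[s1], conv) > 0
        decayed = rng.random(int(s1.sum())) < p.mu1
        nxt = roles[s1].copy()
        nxt[converted] = S2           # contact conversion precedes decay
        nxt[~converted & decayed] = R
        new[s1] = nxt
        s2 = roles == S2
        rec = rng.random(int(s2.sum())) < mu2
        new[np.flatnonzero(s2)[rec]] = R
        roles = new
        dens.append(np.bincount(roles, minlength=4) / g.n_nodes)
    return _finish(dens, ("S", "S1", "S2", "R"),
                   {"model": "twin_sir", "alpha": p.alpha, "mu1": p.mu1,
                    "conversion": conv, "dispeller_delay": p.dispeller_delay,
                    "n_nodes": g.n_nodes})


_RUNNERS = {"sir": run_sir, "seir": run_seir, "twin_sir": run_twin_sir}


def baseline_ensemble(
    g: Graph | NetworkSpec,
    p: BaselineParams,
    init: int | Sequence[int] = 1,
    t_max: int = 100,
    reps: int = 50,
    seed: int = 0,
) -> Trajectory:
    """Mean trajectory over ``reps`` seeded runs of the chosen baseline;
    fresh graph per rep when given a :class:`NetworkSpec`."""
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    runner = _RUNNERS[p.model]
    root = np.random.SeedSequence(seed)
    trajs: list[Trajectory] = []
    for child in root.spawn(reps):
        rng = np.random.default_rng(child)
        if isinstance(g, NetworkSpec):
            gs = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            graph = g.realize(gs)
        else:
            graph = g
        trajs.append(runner(graph, p, init, t_max, rng))
    length = max(len(t) for t in trajs)
    def pad(d: np.ndarray) -> np.ndarray:
        if d.shape[0] >= length:
            return d[:length]
        return np.vstack([d, np.repeat(d[-1][None], length - d.shape[0], axis=0)])
    stack = np.stack([pad(t.data) for t in trajs])
    mean = stack.mean(axis=0)
    se = (stack.std(axis=0, ddof=1) / np.sqrt(reps)
          if reps > 1 else np.zeros_like(mean))
    return Trajectory(np.arange(length, dtype=float), mean, trajs[0].columns,
                      {"model": f"{p.model}_ensemble", "reps": reps,
                       "seed": seed}, stderr=se)
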