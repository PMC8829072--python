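"""Scripted simulation experiments: peak statistics, parameter sweeps,
and the packaged figure-level study designs.

The headline statistic of the study is the diffuser peak
``max_t {S(t) + V(t)}`` — the maximum density of individuals actively
circulating any rumor version.  Sweeps couple grid values with common
random numbers: within a sweep, rep r uses the identical graph, initial
spreader placement and RNG stream for every grid value, so parameter
effects are not confounded by sampling noise and paired per-rep tests are
valid.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import abm
from .abm import AbmConfig
from .baselines import BaselineParams, baseline_ensemble
from .errors import ParameterError
from .networks import Graph, NetworkSpec
from .params import IsvorParams
from .trajectory import ISVOR_COLUMNS, Trajectory

__all__ = [
    "peak_diffuser",
    "run_sweep",
    "SweepResult",
    "intervention_comparison",
    "InterventionReport",
    "reproduce",
    "FIGURE_IDS",
]

FIGURE_IDS = ("fig3", "fig4", "fig5_7", "fig8_10", "fig11")


def peak_diffuser(traj: Trajectory) -> tuple[float, float]:
    """Maximum of S(t) + V(t) and the earliest time attaining it."""
    if len(traj) == 0:
        raise ParameterError("empty trajectory")
    sv = traj["S"] + traj["V"]
    i = int(np.argmax(sv))  # argmax returns the first maximizer
    return float(sv[i]), float(traj.times[i])


def _peak(series: np.ndarray, times: np.ndarray) -> tuple[float, float]:
    i = int(np.argmax(series))
    return float(series[i]), float(times[i])


@dataclass
class SweepResult:
    """Outcome of a one-parameter sweep under common random numbers.

    ``per_rep`` maps summary name -> array of shape (len(grid), reps) so
    paired per-rep comparisons across grid values are possible;
    ``summary`` is the per-grid-value mean of each statistic.
    """

    param: str
    grid: tuple[float, ...]
    ensembles: dict[float, Trajectory]
    per_rep: dict[str, np.ndarray]
    summary: pd.DataFrame
    reps: int
    seed: int
    family: str

    def tidy(self) -> pd.DataFrame:
        """Long-format ensemble means: param, param_value, t, I..R."""
        frames = []
        for value, traj in self.ensembles.items():
            df = traj.to_dataframe()
            df.insert(0, "param_value", value)
            df.insert(0, "param", self.param)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


_SUMMARY_KEYS = ("peak_diffuser", "peak_time", "peak_V", "peak_V_time",
                 "peak_O", "final_R", "final_I")


def _run_summaries(traj: Trajectory) -> dict[str, float]:
    pv, pt = peak_diffuser(traj)
    vpk, vt = _peak(traj["V"], traj.times)
    opk, _ = _peak(traj["O"], traj.times)
    return {
        "peak_diffuser": pv, "peak_time": pt, "peak_V": vpk,
        "peak_V_time": vt, "peak_O": opk,
        "final_R": float(traj["R"][-1]), "final_I": float(traj["I"][-1]),
    }


def run_sweep(
    spec: NetworkSpec | Graph,
    base: AbmConfig,
    param: str,
    grid: Sequence[float],
    reps: int = 50,
    fresh_graph_per_rep: bool = True,
) -> SweepResult:
    """Ensemble runs for each value of ``param`` over ``grid``.

    Rep r shares its graph instance, initial spreader placement, and RNG
    seed across all grid values (common random numbers).  With
    ``fresh_graph_per_rep=False`` a single graph instance (seeded from the
    base seed) is pinned for every rep.
    """
    if param not in IsvorParams().probability_fields:
        raise ParameterError(
            f"{param!r} is not a sweepable probability parameter"
        )
    grid = tuple(float(v) for v in grid)
    root = np.random.SeedSequence(base.seed)
    children = root.spawn(reps)

    # realize the per-rep substrate and initial condition once; run seeds
    # are derived non-destructively so every grid value replays the same
    # per-rep stream
    graphs: list[Graph] = []
    inits: list[tuple[int, ...]] = []
    run_seeds: list[int] = []
    pinned: Graph | None = None
    if isinstance(spec, Graph):
        pinned = spec
    elif not fresh_graph_per_rep:
        pinned = spec.realize(int(root.generate_state(1, dtype=np.uint32)[0] % 2**31))
    for child in children:
        words = child.generate_state(2, dtype=np.uint32)
        if pinned is not None:
            g = pinned
        else:
            g = spec.realize(int(words[0] % (2**31)))  # type: ignore[union-attr]
        graphs.append(g)
        run_seeds.append(int(words[1]))
        init_rng = np.random.default_rng(child)
        if isinstance(base.init_spreaders, tuple):
            nodes = base.init_spreaders
        else:
            nodes = tuple(
                int(i) for i in init_rng.choice(
                    g.n_nodes, size=base.init_spreaders, replace=False
                )
            )
        inits.append(nodes)

    ensembles: dict[float, Trajectory] = {}
    per_rep = {k: np.empty((len(grid), reps)) for k in _SUMMARY_KEYS}
    rows = []
    for gi, value in enumerate(grid):
        cfg = dataclasses.replace(
            base, params=base.params.replace(**{param: value})
        )
        trajs: list[Trajectory] = []
        for r in range(reps):
            run_cfg = dataclasses.replace(cfg, init_spreaders=inits[r])
            rng = np.random.default_rng(run_seeds[r])
            res = abm.run(graphs[r], run_cfg, rng)
            trajs.append(res.trajectory)
            for k, v in _run_summaries(res.trajectory).items():
                per_rep[k][gi, r] = v
        length = max(len(t) for t in trajs)
        stack = np.stack([abm._pad_to(t, length) for t in trajs])
        mean_traj = Trajectory(
            np.arange(length, dtype=float), stack.mean(axis=0), ISVOR_COLUMNS,
            {"model": "isvor_abm_ensemble", "reps": reps, param: value},
            stderr=(stack.std(axis=0, ddof=1) / np.sqrt(reps)
                    if reps > 1 else None),
        )
        ensembles[value] = mean_traj
        rows.append({"param": param, "param_value": value,
                     **{k: float(per_rep[k][gi].mean()) for k in _SUMMARY_KEYS}})
    family = (spec.provenance.get("generator", "graph")
              if isinstance(spec, Graph) else spec.family)
    return SweepResult(param, grid, ensembles, per_rep,
                       pd.DataFrame(rows), reps, base.seed, family)


@dataclass(frozen=True)
class InterventionReport:
    """Peak reduction achieved by raising mu2 vs raising xi2 over the same
    grid, with paired bootstrap confidence intervals."""

    grid: tuple[float, float]
    delta_mu2: float
    delta_xi2: float
    ci_mu2: tuple[float, float]
    ci_xi2: tuple[float, float]
    better: str  # "xi2", "mu2", or "tie"

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _bootstrap_ci(
    deltas: np.ndarray, rng: np.random.Generator,
    n_boot: int = 2000, level: float = 0.95,
) -> tuple[float, float]:
    idx = rng.integers(0, deltas.size, size=(n_boot, deltas.size))
    means = deltas[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def intervention_comparison(
    spec: NetworkSpec | Graph,
    base: AbmConfig,
    grid: Sequence[float] = (0.1, 0.5),
    reps: int = 50,
) -> InterventionReport:
    """Compare the two interventions on the diffuser peak.

    Raising the variation's silencing probability xi2 from the low to the
    high grid value is compared against raising its immunization
    probability mu2 over the same range, with common random numbers shared
    between both sweeps.  ``delta_*`` is the mean per-rep peak reduction
    (low minus high); positive means the intervention lowered the peak.
    """
    grid = tuple(float(v) for v in grid)
    lo, hi = grid[0], grid[-1]
    sweep_mu2 = run_sweep(spec, base, "mu2", (lo, hi), reps)
    sweep_xi2 = run_sweep(spec, base, "xi2", (lo, hi), reps)
    d_mu2 = sweep_mu2.per_rep["peak_diffuser"][0] - sweep_mu2.per_rep["peak_diffuser"][-1]
    d_xi2 = sweep_xi2.per_rep["peak_diffuser"][0] - sweep_xi2.per_rep["peak_diffuser"][-1]
    rng = np.random.default_rng(np.random.SeedSequence((base.seed, 0xB007)))
    ci_mu2 = _bootstrap_ci(d_mu2, rng)
    ci_xi2 = _bootstrap_ci(d_xi2, rng)
    dm, dx = float(d_mu2.mean()), float(d_xi2.mean())
    better = "tie" if dm == dx else ("xi2" if dx > dm else "mu2")
    return InterventionReport((lo, hi), dm, dx, ci_mu2, ci_xi2, better)


# ---------------------------------------------------------------------------
# Packaged figure-level experiments

def _scales(scale: str) -> tuple[int, int]:
    if scale == "full":
        return 2000, 50
    if scale == "ci":
        return 300, 10
    raise ParameterError(f"unknown scale {scale!r}; expected 'full' or 'ci'")


def _specs(n: int) -> dict[str, NetworkSpec]:
    return {
        "ws": NetworkSpec("ws", n=n, ws_k=10, ws_p=0.4),
        "ba": NetworkSpec("ba", n=n, ba_m=5),
    }


def reproduce(
    figure_id: str,
    out_dir: str | Path,
    scale: str = "ci",
    seed: int = 0,
    plot: bool = False,
) -> dict[str, Any]:
    """Run one of the packaged experiment designs and write its outputs.

    ``fig3``: role densities at default rates on WS and BA.
    ``fig4``: SIR / SEIR / Twin-SIR / ISVOR ensembles on BA at matched rates.
    ``fig5_7`` / ``fig8_10``: mu2 / xi2 sweep over {0.1, 0.3, 0.5}, both
    families.  ``fig11``: alpha sweep over {0.1, 0.3, 0.5} on BA.

    ``scale="full"`` uses 2000 nodes and 50 reps; ``"ci"`` 300 nodes and
    10 reps.  Returns the manifest (also written as ``manifest.json``).
    """
    if figure_id not in FIGURE_IDS:
        raise ParameterError(
            f"unknown figure id {figure_id!r}; expected one of {FIGURE_IDS}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n, reps = _scales(scale)
    specs = _specs(n)
    base = AbmConfig(params=IsvorParams(), seed=seed, t_max=100)
    files: list[str] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        files.append(name)

    if figure_id == "fig3":
        trajs = {}
        for fam, spec in specs.items():
            traj = abm.ensemble(spec, base, reps)
            trajs[fam] = traj
            save(traj.to_dataframe(), f"fig3_{fam}.csv")
        if plot:
            _plot_roles(trajs, out / "fig3.png", files)
    elif figure_id == "fig4":
        spec = specs["ba"]
        bp = BaselineParams(alpha=0.5, mu1=0.5)
        runs = {
            "sir": baseline_ensemble(spec, dataclasses.replace(bp, model="sir"),
                                     1, base.t_max, reps, seed),
            "seir": baseline_ensemble(spec, dataclasses.replace(bp, model="seir"),
                                      1, base.t_max, reps, seed),
            "twin_sir": baseline_ensemble(
                spec, dataclasses.replace(bp, model="twin_sir"),
                1, base.t_max, reps, seed),
            "isvor": abm.ensemble(spec, base, reps),
        }
        for name, traj in runs.items():
            save(traj.to_dataframe(), f"fig4_{name}.csv")
        if plot:
            _plot_roles(runs, out / "fig4.png", files)
    elif figure_id in ("fig5_7", "fig8_10"):
        param = "mu2" if figure_id == "fig5_7" else "xi2"
        tidies, summaries = [], []
        for fam, spec in specs.items():
            sweep = run_sweep(spec, base, param, (0.1, 0.3, 0.5), reps)
            t = sweep.tidy()
            t.insert(0, "family", fam)
            tidies.append(t)
            s = sweep.summary.copy()
            s.insert(0, "family", fam)
            summaries.append(s)
        save(pd.concat(tidies, ignore_index=True), f"{figure_id}_{param}_tidy.csv")
        save(pd.concat(summaries, ignore_index=True), f"{figure_id}_{param}_summary.csv")
    elif figure_id == "fig11":
        sweep = run_sweep(specs["ba"], base, "alpha", (0.1, 0.3, 0.5), reps)
        save(sweep.tidy(), "fig11_alpha_tidy.csv")
        save(sweep.summary, "fig11_alpha_summary.csv")

    manifest = {
        "figure_id": figure_id, "scale": scale, "n_nodes": n, "reps": reps,
        "seed": seed, "params": IsvorParams().as_dict(), "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _plot_roles(trajs: dict[str, Trajectory], path: Path,
                files: list[str]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(trajs), figsize=(5 * len(trajs), 4),
                             squeeze=False)
    for ax, (name, traj) in zip(axes[0], trajs.items()):
        for col in traj.columns:
            ax.plot(traj.times, traj[col], label=col)
        ax.set_title(name)
        ax.set_xlabel("step")
        ax.set_ylabel("density")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    files.append(path.name)
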