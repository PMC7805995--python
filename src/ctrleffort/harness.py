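"""Scenario wiring: STIM / SENS / TORQUE control-effort runs end to end.

A scenario names which loop signals are discretized:

* ``STIM``   — the muscle stimulations (controller output, range [0, 1]);
* ``SENS``   — the proprioceptive sensor signals entering the controller,
  ranges taken from an undiscretized reference run;
* ``TORQUE`` — the torque commands of the technical twin (fixed range for
  pointing, reference-run range for the periodic task).

``run_scenario`` runs the undiscretized reference, builds the simulation
constraint ``P(r)``, minimizes the information cost with the three-phase
pattern search, re-simulates at the optimum to score the empirical control
effort, and packages everything into a serializable report.  The module
also provides the brute-force enumeration oracle and seeded synthetic
constraint problems used to validate the optimizer.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .codec import (
    DiscretizedTrace,
    ResolutionVector,
    SignalSpec,
    bits_per_second,
    info_empirical,
    info_uniform,
)
from .criteria import (
    PeriodicCriterion,
    PointingCriterion,
    estimate_reference_speed,
    periodic_P,
    pointing_P,
)
from .optimize import ConstraintCache, EffortResult, minimize_effort
from .plants import (
    PlantConfig,
    SimResult,
    build_periodic_torque_config,
    default_periodic_config,
    default_pointing_config,
    extract_reference_ranges,
    simulate,
)

__all__ = [
    "ScenarioConfig",
    "RunReport",
    "run_scenario",
    "brute_force_effort",
    "generate_fixtures",
    "separable_problem",
    "weighted_sum_problem",
    "random_separable_problems",
    "random_weighted_sum_problems",
]

SCENARIOS = ("STIM", "SENS", "TORQUE")


# ---------------------------------------------------------------------------
# scenario configuration

@dataclass(frozen=True)
class ScenarioConfig:
    """One control-effort measurement: task x scenario x optimizer settings."""

    scenario: str                      # STIM | SENS | TORQUE
    task: str = "pointing"             # pointing | periodic
    seed: int = 0
    delay: Optional[float] = None      # override the plant's sensor delay
    n_init: int = 2 ** 16              # initial amplitude resolution
    m_init: Optional[int] = None       # default: one sample per controller tick
    use_phase3: Optional[bool] = None  # default: off for pointing, on for periodic
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.task not in ("pointing", "periodic"):
            raise ValueError("task must be 'pointing' or 'periodic'")

    @property
    def plant_kind(self) -> str:
        return "torque" if self.scenario == "TORQUE" else "muscle"


@dataclass
class RunReport:
    """Everything one scenario run produced, round-trippable to JSON."""

    config: ScenarioConfig
    signal_names: list[str]
    signal_specs: list[SignalSpec]
    effort: EffortResult
    I_min_bits: Optional[float]
    I_min_rate: Optional[float]        # bit/s over the evaluation window
    I_uniform_rate: float
    window_T: float
    reference_summary: dict
    histograms: dict[str, list[int]]
    version: str = __version__

    def to_dict(self) -> dict:
        e = self.effort
        return {
            "version": self.version,
            "config": dataclasses.asdict(self.config),
            "signals": [dataclasses.asdict(s) for s in self.signal_specs],
            "r_init": list(e.r_init.as_flat()),
            "r_opt": list(e.r_opt.as_flat()),
            "I_init_bits": e.I_init,
            "I_uniform_opt_bits": e.I_uniform_opt,
            "I_uniform_opt_rate": self.I_uniform_rate,
            "I_min_bits": self.I_min_bits,
            "I_min_rate": self.I_min_rate,
            "delta_I_opt_bits": e.delta_I_opt,
            "stage_costs_bits": e.stage_costs,
            "constraint_evals": e.constraint_evals,
            "window_T": self.window_T,
            "reference_summary": self.reference_summary,
            "histograms": self.histograms,
            "seed": self.config.seed,
        }

    def poll_log_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(rec) for rec in self.effort.poll_log]
        for row in rows:
            row["r"] = ",".join(str(v) for v in row["r"])
        return pd.DataFrame(rows)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = f"{self.config.task}_{self.config.scenario}"
        with open(out / f"{tag}_report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        self.poll_log_frame().to_csv(out / f"{tag}_poll_log.csv", index=False)


# ---------------------------------------------------------------------------
# building the pieces of a scenario

def _plant_config(cfg: ScenarioConfig) -> PlantConfig:
    if cfg.task == "pointing":
        return default_pointing_config(cfg.plant_kind, delay=cfg.delay)
    if cfg.plant_kind == "muscle":
        return default_periodic_config("muscle", delay=cfg.delay)
    muscle_ref = simulate(default_periodic_config("muscle"), seed=cfg.seed)
    return build_periodic_torque_config(muscle_ref, delay=cfg.delay)


def _discretized_names(cfg: ScenarioConfig, plant: PlantConfig) -> list[str]:
    if cfg.scenario == "SENS":
        return list(plant.sensor_names)
    return list(plant.output_names)   # STIM and TORQUE: controller outputs


def _signal_specs(
    cfg: ScenarioConfig, plant: PlantConfig, reference: SimResult
) -> list[SignalSpec]:
    _, win_len = plant.window
    names = _discretized_names(cfg, plant)
    if cfg.scenario == "STIM":
        return [SignalSpec(name=n, u_min=0.0, u_max=1.0, T=win_len,
                           role="controller-output") for n in names]
    if cfg.scenario == "TORQUE" and cfg.task == "pointing":
        return [SignalSpec(name=n, u_min=-20.0, u_max=20.0, T=win_len,
                           role="controller-output") for n in names]
    role = "controller-input" if cfg.scenario == "SENS" else "controller-output"
    return extract_reference_ranges(reference, names, role=role)


def _candidate_seed(master_seed: int, r: ResolutionVector, k: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([master_seed, k, *r.as_flat()])


def _run_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


class _Scenario:
    """Callable plumbing shared by the constraint and the final re-simulation."""

    def __init__(self, cfg: ScenarioConfig):
        self.cfg = cfg
        self.plant = _plant_config(cfg)
        self.names = _discretized_names(cfg, self.plant)
        self.win_start, self.win_len = self.plant.window

        self.reference = self._reference_run()
        self.specs = _signal_specs(cfg, self.plant, self.reference)

        if cfg.task == "pointing":
            gx, gy = self.reference.goal_xy()
            self.criterion = PointingCriterion(x_goal=gx, y_goal=gy)
            if pointing_P(self._pointing_runs(None), self.criterion) > 0:
                raise RuntimeError(
                    "reference configuration does not achieve the task")
        else:
            t = self.reference.times
            mask = t >= self.win_start - 1e-12
            ref_speed = estimate_reference_speed(
                t[mask], self.reference.x_hat[mask])
            cycle = 1.0 / self.plant.periodic.freq
            self.criterion = PeriodicCriterion(
                ref_speed=ref_speed, T=self.plant.T_total, window_s=cycle)
            ref_checked = self._periodic_run(None)
            if periodic_P(ref_checked, self.criterion) > 0:
                raise RuntimeError(
                    "reference configuration does not achieve the task")

    # -- runs ---------------------------------------------------------------
    def _reference_run(self) -> SimResult:
        ss = _candidate_seed(self.cfg.seed, ResolutionVector(((1, 1),)), 0)
        return simulate(self.plant, seed=_run_seed(ss))

    def _discretization(self, r: Optional[ResolutionVector]):
        if r is None:
            return None
        return {name: (spec, n, m)
                for name, spec, (n, m) in zip(self.names, self.specs, r.pairs)}

    def _pointing_runs(self, r: Optional[ResolutionVector]) -> list[SimResult]:
        disc = self._discretization(r)
        key = r if r is not None else ResolutionVector(((1, 1),))
        runs = []
        for k in range(self.criterion.repeats):
            ss = _candidate_seed(self.cfg.seed, key, k)
            runs.append(simulate(self.plant, discretization=disc,
                                 scenario=self.cfg.scenario if r is not None else None,
                                 seed=_run_seed(ss)))
        return runs

    def _periodic_run(self, r: Optional[ResolutionVector]) -> SimResult:
        disc = self._discretization(r)
        monitor = self.criterion.make_monitor(self.win_start, self.plant.dt)
        return simulate(self.plant, discretization=disc,
                        scenario=self.cfg.scenario if r is not None else None,
                        seed=self.cfg.seed, abort=monitor)

    # -- optimizer interfaces ----------------------------------------------
    def constraint(self, r: ResolutionVector) -> float:
        if self.cfg.task == "pointing":
            return pointing_P(self._pointing_runs(r), self.criterion)
        return periodic_P(self._periodic_run(r), self.criterion)

    def traces_at(self, r: ResolutionVector) -> dict[str, DiscretizedTrace]:
        if self.cfg.task == "pointing":
            return self._pointing_runs(r)[0].traces
        return self._periodic_run(r).traces

    def empirical_info(self, r: ResolutionVector) -> float:
        return info_empirical(self.traces_at(r).values())

    def r_init(self) -> ResolutionVector:
        n_ticks = int(round(self.win_len / self.plant.tick))
        m0 = self.cfg.m_init if self.cfg.m_init is not None else n_ticks
        return ResolutionVector(tuple((self.cfg.n_init, m0)
                                      for _ in self.names))

    def reference_summary(self) -> dict:
        ref = self.reference
        out = {"t_stop": ref.t_stop, "stop_reason": ref.stop_reason}
        if self.cfg.task == "pointing":
            out.update(x_end=ref.x_end, y_end=ref.y_end, dq_end=ref.dq_end,
                       x_goal=self.criterion.x_goal, y_goal=self.criterion.y_goal)
        else:
            out.update(ref_speed=self.criterion.ref_speed,
                       torque_limit=(self.plant.torque_ctrl.limit
                                     if self.plant.plant == "torque" else None))
        return out


def run_scenario(cfg: ScenarioConfig) -> RunReport:
    """Measure the control effort of one scenario end to end."""
    sc = _Scenario(cfg)
    use_phase3 = (cfg.use_phase3 if cfg.use_phase3 is not None
                  else cfg.task == "periodic")
    effort = minimize_effort(
        sc.constraint, sc.r_init(),
        use_phase3=use_phase3,
        empirical_fn=sc.empirical_info,
        seed=cfg.seed,
    )
    traces = sc.traces_at(effort.r_opt)
    histograms = {
        name: np.bincount(tr.symbols, minlength=tr.n + 1)[1:].tolist()
        for name, tr in traces.items()
    }
    report = RunReport(
        config=cfg,
        signal_names=sc.names,
        signal_specs=sc.specs,
        effort=effort,
        I_min_bits=effort.I_min,
        I_min_rate=(bits_per_second(effort.I_min, sc.win_len)
                    if effort.I_min is not None else None),
        I_uniform_rate=bits_per_second(effort.I_uniform_opt, sc.win_len),
        window_T=sc.win_len,
        reference_summary=sc.reference_summary(),
        histograms=histograms,
    )
    if cfg.out_dir is not None:
        report.write(cfg.out_dir)
    return report


# ---------------------------------------------------------------------------
# brute-force oracle

def brute_force_effort(
    constraint: Callable[[ResolutionVector], float],
    bounds: Sequence[tuple[int, int]],
    cost_fn: Callable[[ResolutionVector], float] = info_uniform,
    grid_cap: int = 10 ** 6,
    cache: Optional[ConstraintCache] = None,
) -> tuple[ResolutionVector, float, int]:
    """Exhaustive enumeration in increasing-cost order.

    ``bounds`` gives inclusive (lo, hi) per flat entry.  The first feasible
    point visited is the global constrained minimum of the monotone cost.
    Returns ``(argmin, cost, constraint evaluations)``.
    """
    sizes = [hi - lo + 1 for lo, hi in bounds]
    if any(s < 1 for s in sizes):
        raise ValueError("empty bounds")
    total = math.prod(sizes)
    if total > grid_cap:
        raise ValueError(
            f"grid of {total} points exceeds cap {grid_cap}; shrink bounds")
    if cache is None:
        cache = ConstraintCache(constraint)
    # enumerate the grid and its costs vectorized; build vectors lazily
    axes = [np.arange(lo, hi + 1) for lo, hi in bounds]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, len(bounds))
    if cost_fn is info_uniform:
        costs = (grid[:, 1::2] * np.log2(grid[:, 0::2])).sum(axis=1)
    else:
        costs = np.array([cost_fn(ResolutionVector.from_flat(f)) for f in grid])
    order = np.lexsort(tuple(grid[:, c] for c in range(len(bounds) - 1, -1, -1))
                       + (costs,))
    n_evals = 0
    for idx in order:
        r = ResolutionVector.from_flat(grid[idx])
        _, ok, cached, _ = cache.evaluate(r)
        if not cached:
            n_evals += 1
        if ok:
            return r, float(costs[idx]), n_evals
    raise ValueError("no feasible point in bounds")


# ---------------------------------------------------------------------------
# synthetic constraint problems (optimizer validation)

@dataclass(frozen=True)
class SyntheticProblem:
    """A monotone Boolean constraint with a known brute-force setting."""

    kind: str                       # "separable" | "weighted-sum"
    thresholds: tuple[int, ...]     # separable: feasible iff r >= thresholds
    weights: tuple[float, ...]      # weighted-sum: feasible iff w . r >= c
    c: float
    r_init: tuple[int, ...]

    def constraint(self, r: ResolutionVector) -> float:
        flat = r.as_flat()
        if self.kind == "separable":
            ok = all(x >= t for x, t in zip(flat, self.thresholds))
        else:
            ok = sum(w * x for w, x in zip(self.weights, flat)) >= self.c
        return 0.0 if ok else 1.0

    def bounds(self) -> list[tuple[int, int]]:
        return [(1, x) for x in self.r_init]


def separable_problem(thresholds: Sequence[int],
                      r_init: Sequence[int]) -> SyntheticProblem:
    """Feasible iff every entry meets its threshold; argmin is the threshold."""
    return SyntheticProblem(kind="separable",
                            thresholds=tuple(int(t) for t in thresholds),
                            weights=(), c=0.0,
                            r_init=tuple(int(x) for x in r_init))


def weighted_sum_problem(weights: Sequence[float], c: float,
                         r_init: Sequence[int]) -> SyntheticProblem:
    """Feasible iff the weighted entry sum reaches ``c`` (non-separable)."""
    return SyntheticProblem(kind="weighted-sum", thresholds=(),
                            weights=tuple(float(w) for w in weights), c=float(c),
                            r_init=tuple(int(x) for x in r_init))


def random_separable_problems(
    n_problems: int, seed: int, max_signals: int = 3, max_threshold: int = 16,
    r_init_value: int = 64,
) -> list[SyntheticProblem]:
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_problems):
        n_sig = int(rng.integers(1, max_signals + 1))
        thresholds = rng.integers(1, max_threshold + 1, size=2 * n_sig)
        out.append(separable_problem(thresholds, [r_init_value] * 2 * n_sig))
    return out


def random_weighted_sum_problems(
    n_problems: int, seed: int, n_signals: int = 2, r_init_value: int = 16,
) -> list[SyntheticProblem]:
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_problems):
        dim = 2 * n_signals
        w = rng.uniform(0.5, 2.0, size=dim)
        # Plane placed above the zero-cost region (all n=1, m maxed) so that
        # amplitude resolution genuinely trades against time resolution, and
        # close below the resolution box: feasibility requires near-maximal
        # total resolution with mild exchange between signals.  Descent with
        # downward polls cannot traverse far along a deep feasibility plane
        # (a documented limitation), so instances live in the regime the
        # local neighborhood sweep is built to polish.
        lo = float(w[0::2].sum() + w[1::2].sum() * r_init_value)
        hi = float(w.sum() * r_init_value)
        c = lo + float(rng.uniform(0.93, 0.99)) * (hi - lo)
        out.append(weighted_sum_problem(w, c, [r_init_value] * dim))
    return out


# ---------------------------------------------------------------------------
# fixture bundle

def generate_fixtures(seed: int, out_dir) -> dict:
    """Write the reproducible fixture bundle used by the tests.

    Contents: summaries of the undiscretized pointing and periodic
    reference runs, a manifest of synthetic constraint problems with their
    brute-force optima, small signal CSVs for codec round-trips, and a
    deliberately infeasible-at-start scenario configuration.  Identical
    seeds produce byte-identical bundles.
    """
    from .codec import write_signal_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    summaries = {}
    for plant_kind in ("muscle", "torque"):
        ref = simulate(default_pointing_config(plant_kind), seed=seed)
        summaries[f"pointing_{plant_kind}"] = {
            "x_end": ref.x_end, "y_end": ref.y_end, "dq_end": ref.dq_end,
            "t_stop": ref.t_stop, "stop_reason": ref.stop_reason,
        }
    ref_per = simulate(default_periodic_config("muscle"), seed=seed)
    summaries["periodic_muscle"] = {
        "t_stop": ref_per.t_stop, "stop_reason": ref_per.stop_reason,
        "x_hat_end": float(ref_per.x_hat[-1]),
        "y_hat_min": float(ref_per.y_hat.min()),
    }

    problems = []
    for i, prob in enumerate(random_separable_problems(
            10, seed, max_signals=2, max_threshold=12, r_init_value=16)):
        argmin, cost, _ = brute_force_effort(prob.constraint, prob.bounds(),
                                             grid_cap=10 ** 8)
        problems.append({
            "index": i, "kind": prob.kind,
            "thresholds": list(prob.thresholds),
            "r_init": list(prob.r_init),
            "argmin": list(argmin.as_flat()), "cost_bits": cost,
        })

    rng = np.random.default_rng(seed)
    times = np.round(np.arange(0.0, 1.0, 0.01), 6)
    write_signal_csv(out / "codec_signals.csv", times, {
        "ramp": times / times[-1],
        "noise": np.round(rng.normal(0.0, 1.0, size=times.size), 9),
    })

    manifest = {
        "seed": seed,
        "reference_runs": summaries,
        "separable_problems": problems,
        "infeasible_start_scenario": {
            "task": "pointing", "scenario": "STIM",
            "note": "r_init forced to all-ones fails the pointing criterion",
            "r_init_flat": [1, 1, 1, 1],
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
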