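"""Three-phase pattern search for the control-effort problem.

Minimizes the cheap, monotone information cost ``I(r)`` over integer
resolution vectors subject to an expensive Boolean performance constraint
``P(r) <= 0`` (a closed-loop simulation that either achieves the movement or
does not).  The search descends from a feasible high-resolution initial
guess in three phases:

1. parallel bisection — one all-ones pattern vector shrinks every entry at
   once with an adaptive mesh, locating a first rough feasibility knee in
   few constraint evaluations;
2. coordinate pattern search — unit-vector polls with mesh adaptation,
   plus an augmented "go back by half" pattern built from the most recent
   successful direction to escape single-coordinate local minima;
3. local neighborhood sweep — all direction vectors with one, two or three
   simultaneous unit decrements at fixed mesh 1, which also yields the
   discreteness error bound ``delta_I_opt`` (the largest cost drop any
   single-entry decrement could still buy).

The cost is always evaluated first and the constraint is skipped whenever a
candidate cannot improve on the incumbent; constraint outcomes are memoized
on the integer vector.  Stochastic constraints must own their averaging and
seeding so the optimizer can treat them as deterministic.

The phase mechanics here are reconstructed from prose; choices that were
genuinely open (initial mesh sizes, first-improvement sweep order,
single-last-direction augmented set, ties rounding toward the cheaper
candidate) are interpretation, flagged where made.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .codec import ResolutionVector, info_uniform

__all__ = [
    "MeshVector",
    "EvaluationRecord",
    "EffortResult",
    "ConstraintCache",
    "poll",
    "phase1_bisection",
    "phase2_pattern",
    "phase3_neighborhood",
    "minimize_effort",
    "InfeasibleStartError",
]

CostFn = Callable[[ResolutionVector], float]
ConstraintFn = Callable[[ResolutionVector], float]


class InfeasibleStartError(ValueError):
    """The initial guess must satisfy the performance constraint."""


@dataclass
class MeshVector:
    """Positive per-entry step scaling for polling; halved / doubled adaptively."""

    values: list[float]

    def __post_init__(self) -> None:
        self.values = [float(v) for v in self.values]
        if any(v <= 0 for v in self.values):
            raise ValueError("mesh entries must be positive")

    def scale(self, factor: float) -> None:
        self.values = [v * factor for v in self.values]

    def all_below_one(self) -> bool:
        return all(v < 1.0 for v in self.values)

    def copy(self) -> "MeshVector":
        return MeshVector(list(self.values))


@dataclass
class EvaluationRecord:
    """One polled candidate: what it cost, and what the constraint said."""

    r: tuple[int, ...]          # flat (n1, m1, n2, m2, ...)
    cost: float
    outcome: str                # "feasible" | "infeasible" | "skipped-by-cost"
    phase: str
    poll_index: int
    cached: bool = False
    constraint_value: Optional[float] = None
    wall_time: float = 0.0
    note: str = ""


@dataclass
class EffortResult:
    """Outcome of a control-effort minimization."""

    r_opt: ResolutionVector
    I_uniform_opt: float
    delta_I_opt: float
    I_min: Optional[float]                  # empirical (entropy) information, if computed
    r_init: ResolutionVector
    I_init: float
    stage_costs: dict[str, float]           # I after each phase that ran
    constraint_evals: dict[str, int]        # true constraint calls per phase
    poll_log: list[EvaluationRecord]
    seed: Optional[int] = None

    @property
    def total_constraint_evals(self) -> int:
        return sum(self.constraint_evals.values())


class ConstraintCache:
    """Memoizes constraint outcomes keyed on the flat integer vector.

    Stochastic constraints are cached too: the same candidate always maps to
    the same (averaged) outcome, which keeps the descent consistent.
    """

    def __init__(self, constraint: ConstraintFn):
        self._constraint = constraint
        self._store: dict[tuple[int, ...], tuple[float, bool]] = {}
        self.n_calls = 0

    def __contains__(self, r: ResolutionVector) -> bool:
        return r.as_flat() in self._store

    def evaluate(self, r: ResolutionVector) -> tuple[float, bool, bool, str]:
        """Return ``(P value, feasible, was_cached, note)``.

        A constraint that raises is recorded as infeasible: a crashed
        simulation is a failed movement.
        """
        key = r.as_flat()
        if key in self._store:
            value, ok = self._store[key]
            return value, ok, True, ""
        self.n_calls += 1
        note = ""
        try:
            value = float(self._constraint(r))
        except Exception as exc:  # noqa: BLE001 - by contract
            value = math.inf
            note = f"constraint raised: {exc!r}"
        ok = value <= 0.0
        self._store[key] = (value, ok)
        return value, ok, False, note


def _round_down_ties(x: float) -> int:
    # nearest integer, exact ties toward the smaller value (cheaper candidate)
    return int(math.ceil(x - 0.5))


def poll(
    r: ResolutionVector, mesh: MeshVector, d: Sequence[float]
) -> ResolutionVector:
    """Candidate ``r - mesh ⊙ d``, rounded to integers and clamped at 1.

    Entries where ``d`` is zero are untouched; non-integer results round to
    the nearest integer with ties toward the smaller resolution (the search
    direction is downward).
    """
    flat = r.as_flat()
    out = []
    for x, mv, dl in zip(flat, mesh.values, d):
        if dl == 0:
            out.append(x)
        else:
            out.append(max(1, _round_down_ties(x - mv * dl)))
    return ResolutionVector.from_flat(out)


class _Search:
    """Shared state threaded through the three phases."""

    def __init__(self, cost_fn: CostFn, cache: ConstraintCache,
                 incumbent: ResolutionVector):
        self.cost_fn = cost_fn
        self.cache = cache
        self.incumbent = incumbent
        self.incumbent_cost = cost_fn(incumbent)
        self.log: list[EvaluationRecord] = []
        self.evals_per_phase: dict[str, int] = {}
        self._poll_index = 0

    def try_candidate(self, candidate: ResolutionVector, phase: str) -> bool:
        """Cheap-first evaluation; returns True if the candidate was accepted.

        A candidate must be strictly cheaper than the incumbent, except for
        the degenerate cost ties created by ``n_i = 1`` entries (where
        ``m_i`` no longer affects the cost): an equal-cost candidate that is
        elementwise no larger and strictly smaller somewhere is still worth
        evaluating, so the search settles on the smallest resolution vector
        among cost ties.
        """
        self._poll_index += 1
        t0 = time.perf_counter()
        cost = self.cost_fn(candidate)
        tie_dominates = (
            cost == self.incumbent_cost
            and candidate.as_flat() != self.incumbent.as_flat()
            and all(c <= i for c, i in zip(candidate.as_flat(),
                                           self.incumbent.as_flat()))
        )
        if cost >= self.incumbent_cost and not tie_dominates:
            self.log.append(EvaluationRecord(
                r=candidate.as_flat(), cost=cost, outcome="skipped-by-cost",
                phase=phase, poll_index=self._poll_index,
                wall_time=time.perf_counter() - t0))
            return False
        value, ok, cached, note = self.cache.evaluate(candidate)
        if not cached:
            self.evals_per_phase[phase] = self.evals_per_phase.get(phase, 0) + 1
        self.log.append(EvaluationRecord(
            r=candidate.as_flat(), cost=cost,
            outcome="feasible" if ok else "infeasible", phase=phase,
            poll_index=self._poll_index, cached=cached,
            constraint_value=value, wall_time=time.perf_counter() - t0,
            note=note))
        if ok:
            self.incumbent = candidate
            self.incumbent_cost = cost
            return True
        return False


def phase1_bisection(
    search: _Search, max_iter: int = 10_000
) -> ResolutionVector:
    """Parallel bisection on all entries with the all-ones pattern.

    Mesh starts at ``(r_init - 1)/2`` elementwise (midpoint toward the
    all-ones floor), doubles on a feasible poll, halves on an infeasible
    one, and the phase stops once every mesh entry is below 1.
    """
    r = search.incumbent
    mesh = MeshVector([max((x - 1) / 2.0, 0.5) for x in r.as_flat()])
    ones = [1.0] * len(r)
    for _ in range(max_iter):
        if mesh.all_below_one():
            break
        candidate = poll(search.incumbent, mesh, ones)
        if search.try_candidate(candidate, "phase1"):
            mesh.scale(2.0)
        else:
            mesh.scale(0.5)
    return search.incumbent


def _augmented_pattern(dim: int, last_success: int) -> list[list[float]]:
    """The "go back by half" pattern built from the last successful direction.

    Every base unit vector receives an extra -0.5 in the previously
    successful entry (which, with the downward poll ``r - m ⊙ d``, moves that
    entry back up by half a mesh step); the previously successful entry's own
    vector becomes a bare half step (+0.5).
    """
    out = []
    for l in range(dim):
        if l == last_success:
            d = [0.0] * dim
            d[l] = 0.5
        else:
            d = [0.0] * dim
            d[l] = 1.0
            d[last_success] = -0.5
        out.append(d)
    return out


def phase2_pattern(
    search: _Search, max_iter: int = 100_000
) -> ResolutionVector:
    """Coordinate pattern search with augmented escape vectors.

    Polls the ``2 N_u`` unit vectors in fixed index order with
    first-improvement acceptance; after a whole failed base sweep it polls
    the augmented set built from the most recent successful direction.  The
    mesh doubles on any success and halves when the full sweep (base plus
    augmented) fails; the phase ends when that happens with every mesh entry
    already below 1.
    """
    dim = len(search.incumbent)
    mesh = MeshVector([max(1.0, x / 4.0) for x in search.incumbent.as_flat()])
    last_success: Optional[int] = None
    for _ in range(max_iter):
        improved = False
        for l in range(dim):
            d = [0.0] * dim
            d[l] = 1.0
            candidate = poll(search.incumbent, mesh, d)
            if search.try_candidate(candidate, "phase2"):
                last_success = l
                improved = True
                break
        if not improved and last_success is not None:
            for d in _augmented_pattern(dim, last_success):
                candidate = poll(search.incumbent, mesh, d)
                if search.try_candidate(candidate, "phase2"):
                    improved = True
                    break
        if improved:
            mesh.scale(2.0)
        else:
            if mesh.all_below_one():
                break
            mesh.scale(0.5)
    return search.incumbent


def delta_I_single_decrements(
    cost_fn: CostFn, r_opt: ResolutionVector
) -> float:
    """Discreteness error: max cost drop over feasible single-entry decrements.

    Entries already at 1 are excluded (a decrement would leave the domain).
    """
    flat = list(r_opt.as_flat())
    best = 0.0
    base = cost_fn(r_opt)
    for l, x in enumerate(flat):
        if x <= 1:
            continue
        down = list(flat)
        down[l] = x - 1
        drop = base - cost_fn(ResolutionVector.from_flat(down))
        best = max(best, drop)
    return best


def phase3_neighborhood(
    search: _Search, max_combo_entries: int = 3, max_iter: int = 100_000
) -> ResolutionVector:
    """Systematic sweep of all 1-3 entry simultaneous unit decrements.

    The mesh is fixed at all-ones; any feasible strictly cheaper point is
    accepted and the sweep restarts from it.
    """
    dim = len(search.incumbent)
    mesh = MeshVector([1.0] * dim)
    directions: list[list[float]] = []
    for k in range(1, min(max_combo_entries, dim) + 1):
        for idx in itertools.combinations(range(dim), k):
            d = [0.0] * dim
            for i in idx:
                d[i] = 1.0
            directions.append(d)
    for _ in range(max_iter):
        improved = False
        for d in directions:
            candidate = poll(search.incumbent, mesh, d)
            if search.try_candidate(candidate, "phase3"):
                improved = True
                break
        if not improved:
            break
    return search.incumbent


def minimize_effort(
    constraint: ConstraintFn,
    r_init: ResolutionVector,
    cost_fn: CostFn = info_uniform,
    *,
    use_phase1: bool = True,
    use_phase2: bool = True,
    use_phase3: bool = True,
    empirical_fn: Optional[Callable[[ResolutionVector], float]] = None,
    cache: Optional[ConstraintCache] = None,
    seed: Optional[int] = None,
) -> EffortResult:
    """Run phases 1 → 2 → 3 from a feasible high-resolution initial guess.

    ``constraint`` returns ``P(r)`` (feasible iff <= 0); a stochastic
    constraint must do its own run-averaging and seeding so identical
    candidates give identical outcomes.  ``empirical_fn``, if given, is
    called once on the optimum to compute the entropy-based control effort
    ``I_min`` (e.g. by re-simulating and scoring the recorded symbol
    sequences); otherwise ``I_min`` is left unset.
    """
    if cache is None:
        cache = ConstraintCache(constraint)
    value, ok, cached, note = cache.evaluate(r_init)
    if not ok:
        raise InfeasibleStartError(
            "initial guess must satisfy the performance constraint "
            f"(P(r_init) = {value}{'; ' + note if note else ''})"
        )
    search = _Search(cost_fn, cache, r_init)
    if not cached:
        search.evals_per_phase["init"] = 1
    search.log.append(EvaluationRecord(
        r=r_init.as_flat(), cost=search.incumbent_cost, outcome="feasible",
        phase="init", poll_index=0, cached=cached, constraint_value=value))

    stage_costs: dict[str, float] = {"I0": search.incumbent_cost}
    if use_phase1:
        phase1_bisection(search)
        stage_costs["I1"] = search.incumbent_cost
    if use_phase2:
        phase2_pattern(search)
        stage_costs["I2"] = search.incumbent_cost
    if use_phase3:
        phase3_neighborhood(search)
        stage_costs["I3"] = search.incumbent_cost

    r_opt = search.incumbent
    delta = delta_I_single_decrements(cost_fn, r_opt)
    I_min = empirical_fn(r_opt) if empirical_fn is not None else None
    return EffortResult(
        r_opt=r_opt,
        I_uniform_opt=search.incumbent_cost,
        delta_I_opt=delta,
        I_min=I_min,
        r_init=r_init,
        I_init=cost_fn(r_init),
        stage_costs=stage_costs,
        constraint_evals=dict(search.evals_per_phase),
        poll_log=search.log,
        seed=seed,
    )
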