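"""MAP inference over a ground model.

The most probable alignment maximizes the weighted sum of satisfied ground
formulas.  After dropping constants (groundings whose truth does not depend
on the hidden atoms), the objective over the candidate selection x is

    sum_c sigma_c * x_c                      (prior)
  + sum_(i,j,w) w * x_i * x_j               (stability conjunctions, w <= 0)
  - sum_(a,c,w) w * x_a * (1 - x_c)         (propagation implications, w >= 0)

subject to the hard at-most-one and mutual-exclusion constraints.  This is
compiled to a mixed-integer linear program and solved exactly with HiGHS
(:func:`scipy.optimize.milp`):

* conjunction products use an auxiliary y with y >= x_i + x_j - 1; because
  the weight is non-positive the optimizer presses y to its lower bound, so
  y may stay continuous in [0, 1] and is integral at any optimum;
* implication penalties use an auxiliary p >= x_a - x_c with objective
  -w * p; the optimizer presses p down to max(0, x_a - x_c).

Both transformations preserve the argmax exactly.  An exhaustive oracle
(:func:`brute_force_map`) provides ground truth on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .grounding import GroundModel, Key
from .ontology import Alignment, Correspondence

__all__ = [
    "MapSolution",
    "objective_value",
    "solve_map_ilp",
    "brute_force_map",
    "extract_alignment",
    "export_lp",
]

Status = Literal["optimal", "feasible", "error"]


@dataclass
class MapSolution:
    """Selected candidate keys plus the achieved objective value."""

    selected: frozenset[Key]
    objective: float
    status: Status = "optimal"
    solver_message: str = ""


def objective_value(model: GroundModel, selected: Iterable[Key]) -> float:
    """Recompute the MAP objective of a selection from scratch."""
    chosen = set(selected)
    unknown = chosen - set(model.variables)
    if unknown:
        raise KeyError(f"selection references unknown variables: {sorted(unknown)}")
    total = sum(model.prior_terms[key] for key in chosen)
    for sc in model.soft_conjunctions:
        if sc.var_i in chosen and sc.var_j in chosen:
            total += sc.weight
    for si in model.soft_implications:
        if si.antecedent in chosen and si.consequent not in chosen:
            total -= si.weight
    return total


def _hard_feasible(model: GroundModel, chosen: set[Key]) -> bool:
    for hc in model.hard_constraints:
        if sum(1 for key in hc.variables if key in chosen) > 1:
            return False
    return True


def solve_map_ilp(model: GroundModel, time_limit: float = 300.0) -> MapSolution:
    """Exact MAP via mixed-integer linear programming (HiGHS backend).

    Within the time limit HiGHS proves optimality; on timeout the best
    incumbent is returned with status ``"feasible"``.  The all-zero
    selection is always feasible, so the program is never infeasible.
    """
    model.validate()
    keys = sorted(model.variables)
    if not keys:
        return MapSolution(frozenset(), 0.0, "optimal")
    index = {key: i for i, key in enumerate(keys)}
    n = len(keys)
    n_conj = len(model.soft_conjunctions)
    n_impl = len(model.soft_implications)
    n_total = n + n_conj + n_impl

    # maximize => minimize the negation
    cost = np.zeros(n_total)
    for key, sigma in model.prior_terms.items():
        cost[index[key]] = -sigma
    for k, sc in enumerate(model.soft_conjunctions):
        cost[n + k] = -sc.weight  # weight <= 0 so this entry is >= 0
    for k, si in enumerate(model.soft_implications):
        cost[n + n_conj + k] = si.weight

    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    lower: list[float] = []
    upper: list[float] = []
    r = 0

    def add_row(entries: list[tuple[int, float]], lo: float, hi: float) -> None:
        nonlocal r
        for j, v in entries:
            rows.append(r)
            cols.append(j)
            data.append(v)
        lower.append(lo)
        upper.append(hi)
        r += 1

    for hc in model.hard_constraints:
        add_row([(index[key], 1.0) for key in hc.variables], -np.inf, 1.0)
    for k, sc in enumerate(model.soft_conjunctions):
        # y >= x_i + x_j - 1  <=>  x_i + x_j - y <= 1
        add_row([(index[sc.var_i], 1.0), (index[sc.var_j], 1.0), (n + k, -1.0)], -np.inf, 1.0)
    for k, si in enumerate(model.soft_implications):
        # p >= x_a - x_c  <=>  x_a - x_c - p <= 0
        add_row(
            [(index[si.antecedent], 1.0), (index[si.consequent], -1.0), (n + n_conj + k, -1.0)],
            -np.inf,
            0.0,
        )

    integrality = np.zeros(n_total)
    integrality[:n] = 1  # auxiliaries integral at optimum by construction
    bounds = Bounds(np.zeros(n_total), np.ones(n_total))
    constraints = []
    if r:
        matrix = csr_matrix((data, (rows, cols)), shape=(r, n_total))
        constraints.append(LinearConstraint(matrix, np.array(lower), np.array(upper)))

    res = milp(
        c=cost,
        constraints=constraints,
        integrality=integrality,
        bounds=bounds,
        options={"time_limit": time_limit},
    )
    if res.x is None:
        return MapSolution(frozenset(), 0.0, "error", res.message or "solver failed")
    chosen = frozenset(key for key, i in index.items() if res.x[i] > 0.5)
    status: Status = "optimal" if res.status == 0 else "feasible"
    # report the exactly recomputed objective, not the solver's float
    return MapSolution(chosen, objective_value(model, chosen), status, res.message or "")


BRUTE_FORCE_LIMIT = 20


def brute_force_map(model: GroundModel) -> MapSolution:
    """Exhaustive MAP oracle: enumerate every subset of candidates.

    Refuses instances above :data:`BRUTE_FORCE_LIMIT` variables.  Ties break
    toward the lexicographically smallest sorted selection, making the
    oracle fully deterministic.
    """
    model.validate()
    keys = sorted(model.variables)
    if len(keys) > BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"brute force limited to {BRUTE_FORCE_LIMIT} variables, got {len(keys)}"
        )
    best_sel: tuple[Key, ...] = ()
    best_obj = 0.0  # empty selection
    for size in range(1, len(keys) + 1):
        for combo in combinations(keys, size):
            chosen = set(combo)
            if not _hard_feasible(model, chosen):
                continue
            obj = objective_value(model, chosen)
            if obj > best_obj or (obj == best_obj and combo < best_sel):
                best_obj, best_sel = obj, combo
    return MapSolution(frozenset(best_sel), best_obj, "optimal")


def extract_alignment(model: GroundModel, sol: MapSolution) -> Alignment:
    """One equivalence correspondence per selected candidate, sigma as confidence."""
    if sol.status == "error":
        raise ValueError(f"cannot extract alignment from failed solve: {sol.solver_message}")
    corrs = {
        Correspondence(key[0], key[1], model.variables[key].sigma)
        for key in sorted(sol.selected)
    }
    return Alignment(corrs)


def export_lp(model: GroundModel, path) -> None:
    """Write the compiled program in CPLEX LP text format for debugging."""
    keys = sorted(model.variables)
    index = {key: i for i, key in enumerate(keys)}
    lines = ["Maximize", " obj:"]
    terms = [f" + {model.prior_terms[key]} x{index[key]}" for key in keys]
    for k, sc in enumerate(model.soft_conjunctions):
        terms.append(f" - {-sc.weight} y{k}")
    for k, si in enumerate(model.soft_implications):
        terms.append(f" - {si.weight} p{k}")
    lines.append("  " + "".join(terms))
    lines.append("Subject To")
    r = 0
    for hc in model.hard_constraints:
        expr = " + ".join(f"x{index[key]}" for key in hc.variables)
        lines.append(f" c{r}: {expr} <= 1")
        r += 1
    for k, sc in enumerate(model.soft_conjunctions):
        lines.append(f" c{r}: x{index[sc.var_i]} + x{index[sc.var_j]} - y{k} <= 1")
        r += 1
    for k, si in enumerate(model.soft_implications):
        lines.append(f" c{r}: x{index[si.antecedent]} - x{index[si.consequent]} - p{k} <= 0")
        r += 1
    lines.append("Bounds")
    for k in range(len(model.soft_conjunctions)):
        lines.append(f" 0 <= y{k} <= 1")
    for k in range(len(model.soft_implications)):
        lines.append(f" 0 <= p{k} <= 1")
    lines.append("Binaries")
    lines.append(" " + " ".join(f"x{i}" for i in range(len(keys))))
    lines.append("End")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
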