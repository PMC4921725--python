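"""End-to-end matching: candidates -> grounding -> MAP -> alignment."""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from .grounding import GroundModel, MatchConfig, ground_model
from .inference import MapSolution, extract_alignment, solve_map_ilp
from .ontology import Alignment, Ontology
from .similarity import Candidate, generate_candidates

__all__ = ["RunReport", "match_ontologies"]


@dataclass
class RunReport:
    """Sizes, solver outcome and wall time per pipeline stage."""

    config: MatchConfig
    n_candidates: int = 0
    n_hard_constraints: int = 0
    n_soft_conjunctions: int = 0
    n_soft_implications: int = 0
    solver_status: str = ""
    objective: float = 0.0
    alignment_size: int = 0
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def lines(self) -> list[str]:
        return [
            f"tau={self.config.tau} enabled={'+'.join(sorted(self.config.enabled))}",
            f"candidates={self.n_candidates}",
            f"hard_constraints={self.n_hard_constraints}",
            f"soft_conjunctions={self.n_soft_conjunctions}",
            f"soft_implications={self.n_soft_implications}",
            f"solver_status={self.solver_status} objective={self.objective:.6f}",
            f"alignment_size={self.alignment_size}",
        ]


def match_ontologies(
    o1: Ontology,
    o2: Ontology,
    cfg: MatchConfig | None = None,
    time_limit: float = 300.0,
) -> tuple[Alignment, RunReport, GroundModel, MapSolution, list[Candidate]]:
    """Run the three matcher stages and return all intermediate artifacts."""
    cfg = cfg or MatchConfig()
    report = RunReport(config=cfg)

    t0 = time.perf_counter()
    candidates = generate_candidates(o1, o2, cfg.tau)
    report.stage_seconds["candidates"] = time.perf_counter() - t0
    report.n_candidates = len(candidates)

    t0 = time.perf_counter()
    model = ground_model(o1, o2, candidates, cfg)
    report.stage_seconds["grounding"] = time.perf_counter() - t0
    report.n_hard_constraints = len(model.hard_constraints)
    report.n_soft_conjunctions = len(model.soft_conjunctions)
    report.n_soft_implications = len(model.soft_implications)

    t0 = time.perf_counter()
    sol = solve_map_ilp(model, time_limit=time_limit)
    report.stage_seconds["inference"] = time.perf_counter() - t0
    report.solver_status = sol.status
    report.objective = sol.objective

    alignment = extract_alignment(model, sol)
    report.alignment_size = len(alignment)
    return alignment, report, model, sol, candidates
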