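"""Greedy allocation of a fixed screen budget across subgroups.

Each subgroup has a constant per-screen (or per-patient) benefit score,
so total benefit is linear in the number of screens assigned and the
greedy rule — saturate subgroups in descending score order, skipping
scores at or below the worthwhileness threshold ``T`` — is exactly
optimal under the budget and subgroup-size box constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["AllocationInput", "AllocationResult", "rank_subgroups", "allocate_screens"]


@dataclass(frozen=True)
class AllocationInput:
    """Scores, sizes, budget and threshold for one allocation run.

    ``scores`` maps subgroup key -> benefit per screen (days) or per
    patient (years); ``mode`` records which units the caller used.
    ``threshold`` is the minimal gain T above which screening a group
    is considered worthwhile (strict: a score equal to T does not
    qualify).
    """

    scores: dict
    sizes: dict
    budget: int
    threshold: float = 0.0
    mode: str = "per_screen"

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValueError("budget must be >= 0")
        if set(self.scores) != set(self.sizes):
            raise ValueError("scores and sizes must cover the same subgroups")
        if any(s < 0 for s in self.sizes.values()):
            raise ValueError("sizes must be >= 0")
        if self.mode not in ("per_screen", "per_patient"):
            raise ValueError("mode must be 'per_screen' or 'per_patient'")


@dataclass(frozen=True)
class AllocationResult:
    """Screens assigned per subgroup, in allocation (rank) order."""

    assignments: tuple  # ((key, screens), ...) in rank order
    total_screens: int
    total_benefit: float
    mode: str = "per_screen"


def rank_subgroups(scores: dict, sizes: dict | None = None) -> list:
    """Subgroup keys in descending score order.

    Ties break deterministically by larger size, then lexicographic
    key, so repeated runs produce identical reports.
    """
    sizes = sizes or {}
    return sorted(
        scores,
        key=lambda k: (-scores[k], -sizes.get(k, 0), str(k)),
    )


def allocate_screens(inp: AllocationInput) -> AllocationResult:
    """Greedy saturating allocation.

    Walk subgroups in rank order; assign min(remaining budget, group
    size) screens to each group whose score strictly exceeds the
    threshold; stop when the budget is exhausted or the next score
    falls to or below the threshold.
    """
    order = rank_subgroups(inp.scores, inp.sizes)
    remaining = inp.budget
    assignments: list[tuple] = []
    total_benefit = 0.0
    for key in order:
        if remaining <= 0 or inp.scores[key] <= inp.threshold:
            break
        n = min(remaining, int(inp.sizes[key]))
        if n > 0:
            assignments.append((key, n))
            total_benefit += n * inp.scores[key]
            remaining -= n
    return AllocationResult(
        assignments=tuple(assignments),
        total_screens=inp.budget - remaining,
        total_benefit=total_benefit,
        mode=inp.mode,
    )
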