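"""Post-hoc classification of category cells and recruitment counting.

Roles are derived from winner statistics on clean, noise-free probes
with learning disabled, never from inspecting the weights directly:

* a cell that wins the feedforward sweep for *every* variant of a
  category is that category's **overall** cell (it encodes the shared
  structure);
* a cell that wins the feedback sweep for *exactly one* variant is that
  variant's **subcategory** cell (it encodes the variant's deviation
  from the category average);
* a cell never selected by the winner-take-all rule during training is
  **unused** -- spare representational capacity.

Assignments that do not fit this scheme (e.g. a cell winning the
feedback sweep for several variants) are reported as ambiguous rather
than silently resolved.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model_core import ModelParams, ModelState
from .stimuli import StimulusSet
from .training import TrainingTrace, probe_step

__all__ = ["CellRole", "CellRoles", "classify_cells", "count_recruited", "weight_energy"]


@dataclasses.dataclass(frozen=True)
class CellRole:
    cell: int
    role: str  # "overall" | "subcategory" | "unused" | "other"
    category: str | None = None
    variant: int | None = None


@dataclasses.dataclass
class CellRoles:
    """Role assignment per cell, plus the raw probe winners behind it."""

    roles: tuple[CellRole, ...]
    ff_winners: dict[tuple[str, int], int]  # (category, variant) -> cell
    fb_winners: dict[tuple[str, int], int]
    ambiguities: tuple[str, ...]

    def by_role(self, role: str) -> list[CellRole]:
        return [r for r in self.roles if r.role == role]

    def overall_cells(self) -> dict[str, int]:
        return {r.category: r.cell for r in self.by_role("overall")}

    def subcategory_cells(self, category: str | None = None) -> dict[tuple[str, int], int]:
        return {
            (r.category, r.variant): r.cell
            for r in self.by_role("subcategory")
            if category is None or r.category == category
        }

    def n_unused(self) -> int:
        return len(self.by_role("unused"))

    def summary(self) -> str:
        lines = []
        for r in self.roles:
            tag = f" {r.category}" if r.category else ""
            tag += f" variant {r.variant}" if r.variant else ""
            lines.append(f"cell {r.cell}: {r.role}{tag}")
        for a in self.ambiguities:
            lines.append(f"ambiguous: {a}")
        return "\n".join(lines)


def classify_cells(
    state: ModelState,
    stimulus_sets: tuple[StimulusSet, ...] | StimulusSet,
    params: ModelParams,
    used: np.ndarray | None = None,
) -> CellRoles:
    """Probe each clean variant (twice, without learning) and assign roles.

    The double probe guards the stability of the feedback-winner
    assignment; since probing never adapts weights, a disagreement
    between the two probes would indicate a non-deterministic sweep and
    is reported as ambiguous.
    """
    if isinstance(stimulus_sets, StimulusSet):
        stimulus_sets = (stimulus_sets,)
    used = state.used if used is None else np.asarray(used, dtype=bool)

    ff_winners: dict[tuple[str, int], int] = {}
    fb_winners: dict[tuple[str, int], int] = {}
    ambiguities: list[str] = []
    for st in stimulus_sets:
        for variant in (1, 2, 3, 4):
            s = st.variant(variant).flatten()
            key = (st.category_label, variant)
            first = [probe_step(state, s, params) for _ in range(2)]
            (ff_a, fb_a), (ff_b, fb_b) = first
            if ff_a.winner != ff_b.winner or fb_a.winner != fb_b.winner:
                ambiguities.append(f"unstable probe winners for {key}")
            ff_winners[key] = ff_a.winner
            fb_winners[key] = fb_a.winner

    overall: dict[str, int] = {}
    for st in stimulus_sets:
        cat = st.category_label
        winners = {ff_winners[(cat, v)] for v in (1, 2, 3, 4)}
        if len(winners) == 1:
            overall[cat] = winners.pop()
        else:
            ambiguities.append(
                f"no single feedforward winner for category {cat}: cells {sorted(winners)}"
            )

    fb_counts: dict[int, list[tuple[str, int]]] = {}
    for key, cell in fb_winners.items():
        fb_counts.setdefault(cell, []).append(key)
    subcat: dict[int, tuple[str, int]] = {}
    for cell, keys in fb_counts.items():
        if len(keys) == 1 and cell not in overall.values():
            subcat[cell] = keys[0]
        elif len(keys) > 1 and cell not in overall.values():
            ambiguities.append(f"cell {cell} wins the feedback sweep for several variants: {sorted(keys)}")

    roles: list[CellRole] = []
    for cell in range(state.n_cells):
        if not used[cell]:
            roles.append(CellRole(cell, "unused"))
        elif cell in overall.values():
            cat = next(c for c, k in overall.items() if k == cell)
            roles.append(CellRole(cell, "overall", category=cat))
        elif cell in subcat:
            cat, variant = subcat[cell]
            roles.append(CellRole(cell, "subcategory", category=cat, variant=variant))
        else:
            roles.append(CellRole(cell, "other"))
    return CellRoles(
        roles=tuple(roles),
        ff_winners=ff_winners,
        fb_winners=fb_winners,
        ambiguities=tuple(ambiguities),
    )


def count_recruited(trace: TrainingTrace) -> int:
    """Number of distinct cells ever selected by the winner-take-all rule."""
    winners: set[int] = set()
    for rec in trace.records:
        winners.add(rec.ff_winner)
        winners.add(rec.fb_winner)
    return len(winners)


def weight_energy(w: np.ndarray) -> float:
    """Squared Euclidean norm of a weight vector."""
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("weight vector must be finite")
    return float(w @ w)
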