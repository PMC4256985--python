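"""Winner-gated Hebbian weight adaptation.

Only the category cell selected by the winner-take-all rule adapts, and
it adapts two complementary weight sets at once:

* **instar** (receptive field, fan-in): an Oja-type rule whose forgetting
  term scales with the squared postsynaptic activation,

      dw_in = eta_in * g_v * (g_u - g_v * w_in),

  which bounds weight growth; in the isolated linear-response regime the
  rule converges to a unit-energy weight vector.

* **outstar** (projective field, fan-out): a gated steepest-descent rule
  whose forgetting term is the weight itself,

      dw_out = eta_out * g_v * (g_u - w_out),

  driving the fan-out row toward the average layer-2 activity presented
  while the cell wins -- the cell's prediction of its expected input.

Updates are discrete Euler steps, one per stimulus presentation, with
the learning rate as step size.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model_core import ModelParams, ModelState, SweepResult

__all__ = ["LearningEvent", "update_instar", "update_outstar", "apply_learning"]


@dataclasses.dataclass(frozen=True)
class LearningEvent:
    """Record of one winner-gated adaptation."""

    step: int
    sweep: str  # "feedforward" | "feedback"
    winner: int
    delta_w_in: float  # Euclidean norm of the fan-in column change
    delta_w_out: float  # Euclidean norm of the fan-out row change
    first_use: bool  # True when this selection recruited the cell


def _check_eta(eta: float) -> None:
    if eta < 0:
        raise ValueError(f"learning rate must be non-negative, got {eta}")


def update_instar(w_col: np.ndarray, g_u: np.ndarray, g_v_k: float, eta_in: float) -> np.ndarray:
    """One instar step on the winner's fan-in column.

    The continuous rule can transiently push small weights negative at a
    finite step size, so the result is clamped at zero.
    """
    _check_eta(eta_in)
    w = np.asarray(w_col, dtype=float)
    updated = w + eta_in * g_v_k * (np.asarray(g_u, dtype=float) - g_v_k * w)
    return np.maximum(updated, 0.0)


def update_outstar(w_row: np.ndarray, g_u: np.ndarray, g_v_k: float, eta_out: float) -> np.ndarray:
    """One outstar step on the winner's fan-out row.

    For ``eta_out * g_v_k <= 1`` this is a convex combination of the old
    row and the presented activity, so non-negativity is preserved.
    """
    _check_eta(eta_out)
    w = np.asarray(w_row, dtype=float)
    return w + eta_out * g_v_k * (np.asarray(g_u, dtype=float) - w)


def apply_learning(
    state: ModelState,
    sweep: SweepResult,
    params: ModelParams,
    step: int = 0,
    sweep_kind: str = "feedforward",
) -> tuple[ModelState, LearningEvent]:
    """Adapt the sweep winner's fan-in column and fan-out row in place.

    All other weights are left bit-identical; the winner's ``used`` flag
    is set.  Returns the (mutated) state together with a LearningEvent
    describing the update.
    """
    k = sweep.winner
    g_v_k = float(sweep.g_v[k])
    new_col = update_instar(state.w_in[:, k], sweep.g_u, g_v_k, params.eta_in)
    new_row = update_outstar(state.w_out[k, :], sweep.g_u, g_v_k, params.eta_out)
    delta_in = float(np.linalg.norm(new_col - state.w_in[:, k]))
    delta_out = float(np.linalg.norm(new_row - state.w_out[k, :]))
    state.w_in[:, k] = new_col
    state.w_out[k, :] = new_row
    first_use = not bool(state.used[k])
    state.used[k] = True
    event = LearningEvent(
        step=step,
        sweep=sweep_kind,
        winner=k,
        delta_w_in=delta_in,
        delta_w_out=delta_out,
        first_use=first_use,
    )
    return state, event
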