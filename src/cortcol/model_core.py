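"""Steady-state activation dynamics of the three-stage columnar cascade.

Every model column is a cascade of (I) linear input filtering, (II)
multiplicative modulation by re-entrant feedback, and (III) divisive pool
normalization (shunting inhibition).  Layer 2 mirrors the input field
one-to-one (identity filter, rectified-linear transfer); layer 3 holds M
category cells (learned fan-in filter, logistic transfer) competing
through a winner-take-all rule.

The continuous-time shunting equations are simulated at their steady
state: with drive ``b_j`` the normalized activity solves the coupled
fixed point

    x_j = beta * b_j / (alpha + q_j),     q_j = gain * sum_k g(x_k),

found by damped fixed-point iteration.  Feedback enters layer 2 only by
scaling the stimulus drive, ``s_j * (1 + lambda * res_j)``, where ``res``
is the rectified difference between the current layer-2 activity and the
winning cell's projective-field prediction.  Because the feedback is a
gain on the feedforward drive, a zero stimulus pixel yields zero output
no matter how strong the feedback -- the gating asymmetry the
architecture is built around.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelParams",
    "ModelState",
    "SweepResult",
    "ConvergenceError",
    "linear_filter",
    "modulate",
    "transfer_u",
    "transfer_v",
    "pool_normalize",
    "layer2_response",
    "layer3_response",
    "wta",
    "residual_template",
    "init_state",
]


class ConvergenceError(RuntimeError):
    """Raised when the damped fixed-point iteration fails to converge."""


@dataclasses.dataclass
class ModelParams:
    """All dynamics and learning constants.

    Printed experiment values: ``kappa_log`` = 0.0075, ``mu_log`` = 700
    (800 for the slowed-down blocked experiment), ``lam`` = 2**5,
    ``eta_in`` = ``eta_out`` = 2**-4 (2**-5 slowed down), weight init
    N(0.75, 0.1) (N(0.5, 0.1) slowed down), stimulus noise sigma = 0.05.

    The shunting constants and the pool kernel are calibration choices
    (see docs/methods.md): decay and input scale are 1, the pool kernel
    is uniform all-to-all, ``q = pool_gain * sum(g(x))``, with a layer-2
    gain small enough that a clean feedforward stimulus keeps roughly its
    input scale (so the logistic midpoint ``mu_log`` = 700 sits at about
    half the ~1400 squared-pixel energy of a stimulus) yet large enough
    that residual-amplified activity is renormalized instead of growing
    linearly with the feedback gain.
    """

    # shunting dynamics, layer 2 (passive decay / input scale)
    alpha_u: float = 1.0
    beta_u: float = 1.1
    # shunting dynamics, layer 3
    alpha_v: float = 1.0
    beta_v: float = 1.0
    # layer-3 logistic transfer
    kappa_log: float = 0.0075
    mu_log: float = 700.0
    # feedback gain on the residual template
    lam: float = 2.0**5
    # uniform pool-kernel couplings Lambda_jk
    pool_gain_l2: float = 1.0e-3
    pool_gain_l3: float = 0.01
    # learning rates (instar / outstar)
    eta_in: float = 2.0**-4
    eta_out: float = 2.0**-4
    # weight initialization N(init_mu, init_sigma), clamped at 0
    init_mu: float = 0.75
    init_sigma: float = 0.1
    # fixed-point solver controls
    fp_tol: float = 1e-8
    fp_max_iter: int = 500
    fp_damping: float = 0.5

    def validate(self) -> None:
        for name in ("alpha_u", "beta_u", "alpha_v", "beta_v", "kappa_log"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("lam", "pool_gain_l2", "pool_gain_l3", "eta_in", "eta_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.fp_damping <= 1):
            raise ValueError("fp_damping must be in (0, 1]")


@dataclasses.dataclass
class ModelState:
    """Adaptive weights of the layer-2 <-> layer-3 bipartite graph.

    ``w_in`` (N x M) holds the receptive (fan-in) field of each category
    cell in its columns; ``w_out`` (M x N) the projective (fan-out) field
    in its rows; ``used[k]`` records whether cell k was ever selected by
    the winner-take-all rule during training.
    """

    w_in: np.ndarray
    w_out: np.ndarray
    used: np.ndarray

    def __post_init__(self) -> None:
        if self.w_in.ndim != 2 or self.w_out.ndim != 2:
            raise ValueError("weight matrices must be 2-D")
        n, m = self.w_in.shape
        if self.w_out.shape != (m, n):
            raise ValueError(
                f"w_out shape {self.w_out.shape} inconsistent with w_in {self.w_in.shape}"
            )
        if self.used.shape != (m,):
            raise ValueError("used flags must have one entry per category cell")
        if not (np.all(np.isfinite(self.w_in)) and np.all(np.isfinite(self.w_out))):
            raise ValueError("weights must be finite")
        if (self.w_in < 0).any() or (self.w_out < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[0]

    @property
    def n_cells(self) -> int:
        return self.w_in.shape[1]

    def copy(self) -> "ModelState":
        return ModelState(self.w_in.copy(), self.w_out.copy(), self.used.copy())


@dataclasses.dataclass
class SweepResult:
    """Activities of one sweep: layer-2 output, layer-3 response, winner."""

    g_u: np.ndarray
    v_raw: np.ndarray
    g_v: np.ndarray
    winner: int
    res_templ: np.ndarray | None = None  # None for a pure feedforward sweep


def init_state(n_inputs: int, n_cells: int, params: ModelParams, rng: np.random.Generator) -> ModelState:
    """Draw both weight matrices from N(init_mu, init_sigma), clamped at 0."""
    w_in = rng.normal(params.init_mu, params.init_sigma, size=(n_inputs, n_cells))
    w_out = rng.normal(params.init_mu, params.init_sigma, size=(n_cells, n_inputs))
    return ModelState(
        np.maximum(w_in, 0.0),
        np.maximum(w_out, 0.0),
        np.zeros(n_cells, dtype=bool),
    )


# ---------------------------------------------------------------------------
# cascade stages


def linear_filter(inputs: np.ndarray, weights: np.ndarray) -> float:
    """Stage I: weighted sum r = sum_j K_j * s_j of the input to a cell."""
    inputs = np.asarray(inputs, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if inputs.shape != weights.shape:
        raise ValueError(f"length mismatch: inputs {inputs.shape} vs weights {weights.shape}")
    return float(inputs @ weights)


def modulate(r: float, net_fb: float) -> float:
    """Stage II: multiplicative feedback, r * (1 + net_fb).

    The feedforward signal gates the feedback: r = 0 yields 0 for any
    feedback strength, and net_fb = 0 leaves r unchanged.
    """
    if r < 0 or net_fb < 0:
        raise ValueError("modulate expects non-negative r and net_fb")
    return r * (1.0 + net_fb)


def transfer_u(u: np.ndarray) -> np.ndarray:
    """Layer-2 firing rate: linear with rectification, [u]^+ = max(u, 0)."""
    return np.maximum(np.asarray(u, dtype=float), 0.0)


def transfer_v(v: np.ndarray, kappa_log: float, mu_log: float) -> np.ndarray:
    """Layer-3 firing rate: logistic 1 / (1 + exp(kappa * (mu - v)))."""
    if kappa_log <= 0:
        raise ValueError("kappa_log must be > 0")
    return expit(kappa_log * (np.asarray(v, dtype=float) - mu_log))


def pool_normalize(
    raw: np.ndarray,
    alpha: float,
    beta: float,
    pool_gain: float,
    transfer: Callable[[np.ndarray], np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 500,
    damping: float = 0.5,
) -> np.ndarray:
    """Stage III: steady state of divisive mutual inhibition within a pool.

    Solves ``x_j = beta * raw_j / (alpha + q_j)`` with the uniform pool
    ``q_j = pool_gain * sum_k transfer(x_k)`` (the pool sum includes the
    target cell itself) by damped fixed-point iteration.  The result is
    elementwise non-negative and bounded by ``beta * raw / alpha``.
    """
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError("pool_normalize expects non-negative raw responses")
    x = beta * raw / alpha
    if pool_gain == 0.0:
        return x
    scale = max(1.0, float(np.max(x, initial=0.0)))
    for _ in range(max_iter):
        q = pool_gain * float(np.sum(transfer(x)))
        x_new = beta * raw / (alpha + q)
        residual = float(np.max(np.abs(x_new - x), initial=0.0))
        x = (1.0 - damping) * x + damping * x_new
        if residual <= tol * scale:
            return x
    raise ConvergenceError(
        f"pool normalization did not converge within {max_iter} iterations "
        f"(last residual {residual:.3e}, tolerance {tol * scale:.3e})"
    )


def layer2_response(s: np.ndarray, res: np.ndarray | None, params: ModelParams) -> np.ndarray:
    """Steady-state layer-2 activity g_u for stimulus ``s`` and residual ``res``.

    The drive is ``beta_u * s_j * (1 + lam * res_j)``; with ``res`` absent
    (or ``lam`` = 0) this is the pure feedforward sweep.
    """
    s = np.asarray(s, dtype=float)
    if res is None:
        drive = s
    else:
        res = np.asarray(res, dtype=float)
        if res.shape != s.shape:
            raise ValueError(f"residual shape {res.shape} does not match stimulus {s.shape}")
        if (res < 0).any():
            raise ValueError("residual template must be non-negative")
        drive = s * (1.0 + params.lam * res)
    u = pool_normalize(
        drive,
        params.alpha_u,
        params.beta_u,
        params.pool_gain_l2,
        transfer_u,
        tol=params.fp_tol,
        max_iter=params.fp_max_iter,
        damping=params.fp_damping,
    )
    return transfer_u(u)


def layer3_response(
    g_u: np.ndarray, w_in: np.ndarray, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state layer-3 response (v_raw, g_v) to layer-2 activity.

    Stage I correlates g_u with every cell's fan-in column of ``w_in``;
    stage III renormalizes within the pool of all M category cells; the
    logistic transfer maps potentials into (0, 1).
    """
    g_u = np.asarray(g_u, dtype=float)
    if w_in.shape[0] != g_u.shape[0]:
        raise ValueError(f"w_in shape {w_in.shape} inconsistent with g_u length {g_u.shape[0]}")
    r = g_u @ w_in
    v = pool_normalize(
        r,
        params.alpha_v,
        params.beta_v,
        params.pool_gain_l3,
        lambda x: transfer_v(x, params.kappa_log, params.mu_log),
        tol=params.fp_tol,
        max_iter=params.fp_max_iter,
        damping=params.fp_damping,
    )
    return v, transfer_v(v, params.kappa_log, params.mu_log)


def wta(g_v: np.ndarray) -> int:
    """Winner-take-all: index of the maximally active cell (ties: lowest)."""
    g_v = np.asarray(g_v)
    if g_v.size == 0:
        raise ValueError("wta requires a non-empty activity vector")
    return int(np.argmax(g_v))


def residual_template(g_u: np.ndarray, w_out_winner: np.ndarray) -> np.ndarray:
    """Rectified difference between layer-2 activity and the winner's prediction.

    ``res_j = [g_u(u_j) - w_kj_out]^+`` with k the winning category cell;
    the overshoot (prediction above activity) is clipped to zero.
    """
    g_u = np.asarray(g_u, dtype=float)
    w_out_winner = np.asarray(w_out_winner, dtype=float)
    if g_u.shape != w_out_winner.shape:
        raise ValueError(
            f"shape mismatch: g_u {g_u.shape} vs w_out row {w_out_winner.shape}"
        )
    if (g_u < 0).any() or (w_out_winner < 0).any():
        raise ValueError("residual_template expects non-negative inputs")
    return np.maximum(g_u - w_out_winner, 0.0)
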