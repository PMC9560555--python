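"""Mean-field ODE systems and their integration.

State layout is always ``y = (r, v, s, K, Q)``:

* ``r``  population firing rate,
* ``v``  mean membrane potential,
* ``s``  mean synaptic activation,
* ``K``  slow external input (oscillating around ``eta_bar``),
* ``Q``  slow-input velocity.

In *fast time* t the system reads

    r' = Delta/pi + 2 r v + Gamma_tilde s
    v' = v^2 - pi^2 r^2 + J_tilde s + K
    s' = (-s + r)/tau_s
    K' = eps Q
    Q' = -eps (K - eta_bar)

and in *slow time* tau = eps*t the population equations acquire the
1/eps prefactor while (K, Q) become an undamped unit-frequency oscillator.
Both parametrisations are exposed by :func:`extended_rhs` through the
``time_scale`` flag; they describe the same orbits.

The quadratic rate term uses the pi^2 r^2 convention of the generalised
mean field; the critical-manifold module relies on exactly this form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import MeanFieldParams, MultiPopParams

__all__ = [
    "Trajectory",
    "extended_rhs",
    "multipop_rhs",
    "make_rhs",
    "make_multipop_rhs",
    "integrate_trajectory",
    "equilibrium_state",
]

STATE_COLUMNS = ("r", "v", "s", "K", "Q")


@dataclass
class Trajectory:
    """Time-ordered solution of one of the mean-field systems.

    ``states`` has one row per time point, columns ``(r, v, s, K, Q)`` (or
    the 3p+2 multi-population layout).  ``metadata`` echoes parameters and
    solver settings so a run can be reproduced from its output alone.
    """

    times: np.ndarray
    states: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape[0] != self.times.size:
            raise ValueError("states length must equal times length")

    @property
    def r(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def v(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def s(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def K(self) -> np.ndarray:
        return self.states[:, -2]

    @property
    def Q(self) -> np.ndarray:
        return self.states[:, -1]

    def to_frame(self):
        """Tabular view with columns t,r,v,s,K,Q (single population)."""
        import pandas as pd

        if self.states.shape[1] != 5:
            raise ValueError("to_frame supports the single-population layout")
        return pd.DataFrame(
            {"t": self.times, **{c: self.states[:, i] for i, c in enumerate(STATE_COLUMNS)}}
        )

    def write_csv(self, path, sidecar: bool = True) -> None:
        """Write the trajectory as CSV plus a JSON parameter sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {k: _jsonable(v) for k, v in self.metadata.items()}
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if hasattr(v, "__dict__") and not isinstance(v, type):
        return {k: _jsonable(x) for k, x in vars(v).items()}
    return v


def extended_rhs(
    state: Sequence[float],
    params: MeanFieldParams,
    epsilon: float,
    t: float = 0.0,
    time_scale: str = "slow",
) -> np.ndarray:
    """Right-hand side of the forced mean field in state (r, v, s, K, Q).

    ``time_scale='slow'`` returns the derivative with respect to the slow
    time (population equations divided by eps); ``'fast'`` returns the
    fast-time form.  The forcing oscillator is autonomous, so ``t`` is
    accepted only for solver compatibility.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    if time_scale not in ("slow", "fast"):
        raise ValueError(f"time_scale must be 'slow' or 'fast', got {time_scale!r}")
    r, v, s, K, Q = state
    gt = params.gamma_tilde
    jt = params.j_tilde
    dr = params.delta / math.pi + 2.0 * r * v + gt * s
    dv = v * v - math.pi**2 * r * r + jt * s + K
    ds = (-s + r) / params.tau_s
    dK = Q
    dQ = -(K - params.eta_bar)
    if time_scale == "slow":
        return np.array([dr / epsilon, dv / epsilon, ds / epsilon, dK, dQ])
    return np.array([dr, dv, ds, epsilon * dK, epsilon * dQ])


def multipop_rhs(
    states: Sequence[Sequence[float]],
    params: MultiPopParams,
    epsilon: float,
    time_scale: str = "slow",
) -> np.ndarray:
    """Derivatives for p coupled populations plus the shared (K, Q) pair.

    ``states`` is a sequence of p triples (r_i, v_i, s_i) followed by the
    pair (K, Q), or equivalently a flat vector of length 3p+2.  Population
    ``forced_index`` receives K in its voltage equation and its eta_bar is
    carried by K; all other populations keep eta_bar_i as a constant drive.
    Cross-coupling enters as sum_j J_tilde_ij s_j.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    p = params.n_pop
    y = np.asarray(states, dtype=float).ravel()
    if y.size != 3 * p + 2:
        raise ValueError(f"expected state of length {3 * p + 2}, got {y.size}")
    r = y[0 : 3 * p : 3]
    v = y[1 : 3 * p : 3]
    s = y[2 : 3 * p : 3]
    K, Q = y[-2], y[-1]
    J = np.asarray(params.coupling, dtype=float)
    syn = J @ s
    out = np.empty_like(y)
    for i, pop in enumerate(params.populations):
        eta = 0.0 if i == params.forced_index else pop.eta_bar
        forced = K if i == params.forced_index else 0.0
        dr = pop.delta / math.pi + 2.0 * r[i] * v[i] + pop.gamma_tilde * s[i]
        dv = v[i] * v[i] - math.pi**2 * r[i] * r[i] + eta + syn[i] + forced
        ds = (-s[i] + r[i]) / pop.tau_s
        out[3 * i : 3 * i + 3] = (dr, dv, ds)
    eta_k = params.populations[params.forced_index].eta_bar
    if time_scale == "slow":
        out[: 3 * p] /= epsilon
        out[-2], out[-1] = Q, -(K - eta_k)
    else:
        out[-2], out[-1] = epsilon * Q, -epsilon * (K - eta_k)
    return out


def make_rhs(
    params: MeanFieldParams, epsilon: float, time_scale: str = "fast"
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Close extended_rhs over parameters in solve_ivp's f(t, y) signature."""
    return lambda t, y: extended_rhs(y, params, epsilon, t, time_scale=time_scale)


def make_multipop_rhs(
    params: MultiPopParams, epsilon: float, time_scale: str = "fast"
) -> Callable[[float, np.ndarray], np.ndarray]:
    return lambda t, y: multipop_rhs(y, params, epsilon, time_scale=time_scale)


def integrate_trajectory(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    initial_state: Sequence[float],
    t_span: tuple[float, float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    t_eval: np.ndarray | None = None,
    max_step: float = np.inf,
    metadata: dict | None = None,
) -> Trajectory:
    """Adaptive-step integration of a mean-field right-hand side.

    The default solver is stiff-capable (the synaptic relaxation time can
    be as small as 0.002 while the forcing period is hundreds of time
    units).  Solver failures raise RuntimeError carrying the last valid
    state so the caller can diagnose where the step size underflowed.
    """
    y0 = np.asarray(initial_state, dtype=float)
    if not (t_span[1] > t_span[0]):
        raise ValueError(f"degenerate t_span {t_span}")
    sol = solve_ivp(
        rhs,
        t_span,
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        max_step=max_step,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1]!r}: {sol.message}; "
            f"last state {sol.y[:, -1]!r}"
        )
    meta = {
        "rtol": rtol,
        "atol": atol,
        "method": method,
        "t_span": tuple(t_span),
        "initial_state": y0.tolist(),
    }
    if metadata:
        meta.update(metadata)
    return Trajectory(sol.t, sol.y.T, meta)


def equilibrium_state(
    params: MeanFieldParams, v: float, forcing_amplitude: float = 0.0
) -> np.ndarray:
    """Exact fast-subsystem equilibrium on the critical manifold at voltage v.

    Returns (r, v, s, K, Q) with r = s = -(Delta/pi)/(2v + Gamma_tilde),
    K = -psi(v) and Q = forcing_amplitude, i.e. a point from which the
    forced system starts on the branch passing through v.
    """
    from .geometry import CriticalManifold

    man = CriticalManifold(params)
    r = man.rate(v)
    return np.array([r, v, r, -man.psi(v), forcing_amplitude])
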