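"""Canonical excitability experiments at each scale.

These functions wire the simulators, the manifold geometry and the
classification machinery into the standard experiments: locating the
canard-mediated bursting threshold of a single self-coupled cell, of the
mean field, of a dense network, and of a sparse network, plus the
amplitude sweeps that trace the continuous routes to bursting.

Default parameter sets follow the study conditions:

* bistable cell: eta1 = -0.2, J = 6, tau_s = 0.3, eps = 0.01 (threshold
  bracket printed as [0.20318, 0.20319]);
* tonic cell: eta1 = 0.5, J = 6, tau_s = 0.3, eps = 0.1 (bursting
  reported between A = 0.83 and A = 0.8892, measured on t in [0, 70]);
* mean field / dense network: Delta = 1, J = 15, tau_s = 0.002,
  eps = 0.05, eta_bar = -15.1 (bistable) or +5 (tonic), Vt = 100 = -Vr;
* routes to bursting: tau_s = 0.02, eta_bar in {-6.5, -5, -3.5, -2};
* sparse network: M-scaled coefficients J = 1, tau_s = 0.015,
  Delta_gamma = 0.3, eps = 0.1, eta_bar = -0.5, Delta = 1e-4, with the
  amplitude coefficient swept near 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CriticalManifold
from .meanfield import Trajectory, integrate_trajectory, make_rhs
from .microscale import (
    NetworkParams,
    SpikeRecord,
    simulate_dense_network,
    simulate_theta_cell,
    theta_rest_angle,
)
from .params import MeanFieldParams, SlowForcing
from .routes import (
    BranchPoint,
    OrbitClass,
    canard_dwell_time,
    classify_orbit,
    find_threshold,
    s_norm,
)

__all__ = [
    "CellExperiment",
    "bistable_cell_spikes",
    "bistable_cell_threshold",
    "tonic_cell_spike_count",
    "tonic_cell_threshold",
    "meanfield_orbit",
    "meanfield_reaches_up",
    "meanfield_threshold",
    "network_reaches_up",
    "network_trajectory",
    "trajectory_from_trace",
]


@dataclass(frozen=True)
class CellExperiment:
    """Single self-coupled cell setup (theta form, literal increment 1)."""

    eta: float
    j_syn: float = 6.0
    tau_s: float = 0.3
    epsilon: float = 0.01
    spike_increment: float = 1.0


BISTABLE_CELL = CellExperiment(eta=-0.2, epsilon=0.01)
TONIC_CELL = CellExperiment(eta=0.5, epsilon=0.1)


def bistable_cell_spikes(
    amplitude: float, exp: CellExperiment = BISTABLE_CELL, horizon_fraction: float = 0.6
) -> SpikeRecord:
    """Forced response of the bistable cell from its quiescent state.

    The cell starts at the rest phase of the unforced system (s = 0) and
    is integrated over ``horizon_fraction`` of a forcing period, past the
    first passage of the fold at K = 0.
    """
    forcing = SlowForcing(amplitude, exp.epsilon)
    theta0 = theta_rest_angle(exp.eta)
    rec, _ = simulate_theta_cell(
        exp.eta,
        exp.j_syn,
        exp.tau_s,
        forcing,
        (0.0, horizon_fraction * forcing.period),
        theta0=theta0,
        s0=0.0,
        spike_increment=exp.spike_increment,
        rtol=1e-8,
        atol=1e-10,
    )
    return rec


def bistable_cell_threshold(
    tol: float = 1e-6,
    bracket: tuple[float, float] = (0.15, 0.25),
    exp: CellExperiment = BISTABLE_CELL,
) -> tuple[float, tuple[float, float]]:
    """Canard threshold of the bistable cell by amplitude bisection.

    Below threshold the orbit is down-down (no spike: a subthreshold
    oscillation that hugs the unstable branch and falls back); above, it
    is down-up (the cell emits at least one spike after the fold
    passage).  The predicate is the presence of any spike.
    """
    classify = lambda A: len(bistable_cell_spikes(A, exp)) > 0
    return find_threshold(classify, *bracket, tol=tol)


def tonic_cell_spike_count(
    amplitude: float,
    exp: CellExperiment = TONIC_CELL,
    window: tuple[float, float] = (0.0, 70.0),
    return_snorm: bool = False,
):
    """Spike count (and optionally ||s||) of the tonic cell on the window.

    The cell starts at the voltage symmetry point (theta = 0, i.e. V = 0)
    with s = 0 and is measured over the same transient window the branch
    diagrams use, t in [0, 70].
    """
    forcing = SlowForcing(amplitude, exp.epsilon)
    rec, trace = simulate_theta_cell(
        exp.eta,
        exp.j_syn,
        exp.tau_s,
        forcing,
        window,
        theta0=0.0,
        s0=0.0,
        spike_increment=exp.spike_increment,
        rtol=1e-10,
        atol=1e-12,
        record=return_snorm,
    )
    if return_snorm:
        t, _, s = trace
        return len(rec), s_norm(t, s, window)
    return len(rec)


def tonic_cell_threshold(
    tol: float = 1e-5,
    bracket: tuple[float, float] = (0.7, 1.0),
    exp: CellExperiment = TONIC_CELL,
) -> tuple[float, tuple[float, float]]:
    """Up-to-down bursting threshold of the tonic cell.

    Across the canard explosion the orbit grows a canard-extended spike
    during the descending half of the forcing cycle; the bisection
    predicate is the change of the spike count on t in [0, 70] relative
    to the lower bracket end.
    """
    n_ref = tonic_cell_spike_count(bracket[0], exp)
    classify = lambda A: tonic_cell_spike_count(A, exp) != n_ref
    return find_threshold(classify, *bracket, tol=tol)


# ---------------------------------------------------------------------------
# mean field
# ---------------------------------------------------------------------------

MF_BISTABLE = MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-15.1, tau_s=0.002)
MF_TONIC = MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=5.0, tau_s=0.002)
MF_ROUTES = {
    "I": MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-6.5, tau_s=0.02),
    "II": MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-5.0, tau_s=0.02),
    "III": MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-3.5, tau_s=0.02),
    "IV": MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-2.0, tau_s=0.02),
}


def meanfield_orbit(
    params: MeanFieldParams,
    amplitude: float,
    epsilon: float = 0.05,
    start_sheet: str = "lower",
    n_periods: float = 1.0,
    n_eval: int = 4000,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Forced mean-field orbit started on an attracting branch at K = eta_bar.

    The initial state is the frozen-system equilibrium on ``start_sheet``
    at the distribution centre, with the forcing switched on at phase
    zero (K rising).  Integrated in fast time with a stiff-capable
    solver.
    """
    man = CriticalManifold(params)
    v0 = man.branch_voltage(params.eta_bar, start_sheet)
    r0 = float(man.rate(v0))
    forcing = SlowForcing(amplitude, epsilon)
    y0 = np.array([r0, v0, r0, params.eta_bar, amplitude])
    t_end = n_periods * forcing.period
    return integrate_trajectory(
        make_rhs(params, epsilon, time_scale="fast"),
        y0,
        (0.0, t_end),
        rtol=rtol,
        atol=atol,
        t_eval=np.linspace(0.0, t_end, n_eval),
        metadata={"params": params, "amplitude": amplitude, "epsilon": epsilon,
                  "start_sheet": start_sheet},
    )


def meanfield_reaches_up(
    params: MeanFieldParams, amplitude: float, epsilon: float = 0.05,
    horizon_fraction: float = 0.55,
) -> bool:
    """Down-up predicate: does the orbit reach the upper sheet after the
    first fold passage?  (max rate exceeds the upper-fold rate.)"""
    man = CriticalManifold(params)
    folds = man.folds()
    r_up = float(man.rate(folds[0].v_star))
    traj = meanfield_orbit(
        params, amplitude, epsilon, "lower", n_periods=horizon_fraction, n_eval=2000
    )
    return bool(traj.r.max() > r_up)


def meanfield_threshold(
    params: MeanFieldParams = MF_BISTABLE,
    epsilon: float = 0.05,
    bracket: tuple[float, float] | None = None,
    tol: float = 1e-4,
) -> tuple[float, tuple[float, float]]:
    """Bisected down-up canard threshold of the mean field.

    The default bracket spans +-10% of the singular estimate
    eta_-(fold) - eta_bar (the amplitude at which K first touches the
    lower fold).
    """
    if bracket is None:
        man = CriticalManifold(params)
        a0 = man.folds()[1].eta_fold - params.eta_bar
        bracket = (0.9 * a0, 1.15 * a0)
    classify = lambda A: meanfield_reaches_up(params, A, epsilon)
    return find_threshold(classify, *bracket, tol=tol)


# ---------------------------------------------------------------------------
# dense network
# ---------------------------------------------------------------------------


def _network_params(
    n_neurons: int, seed: int, params: MeanFieldParams, dt: float
) -> NetworkParams:
    return NetworkParams(
        n_neurons=n_neurons,
        j_syn=params.j_syn,
        tau_s=params.tau_s,
        eta_bar=params.eta_bar,
        delta=params.delta,
        seed=seed,
        dt=dt,
        increment_convention="one_over_N_tau",
    )


def network_trajectory(
    params: MeanFieldParams,
    amplitude: float,
    n_neurons: int,
    seed: int,
    epsilon: float = 0.05,
    horizon_fraction: float = 0.55,
    dt: float = 2e-4,
    window_dt: float = 0.15,
    burn_in: float = 5.0,
    currents: str = "sampled",
) -> tuple[Trajectory, SpikeRecord]:
    """Dense-network orbit in mean-field coordinates.

    Each neuron starts at its own rest voltage for the unforced drive
    (tonic outliers at the rotation midpoint V = 0), the synapse at the
    mean-field equilibrium; a short unforced burn-in then relaxes the
    network to its stationary asynchronous state before the forcing
    switches on.  The trace's median voltage and windowed rate are
    assembled with the analytic (K, Q) forcing into a trajectory
    comparable against the mean field and the critical manifold.

    ``currents``: "sampled" draws the background currents from the seeded
    Lorentzian; "quantile" uses the deterministic Lorentzian quantile
    grid (the variance-controlled protocol for mean-field comparisons).
    """
    from .microscale import lorentzian_quantiles

    man = CriticalManifold(params)
    v0 = man.branch_voltage(params.eta_bar, "lower")
    r0 = float(man.rate(v0))
    net = _network_params(n_neurons, seed, params, dt)
    if currents == "quantile":
        etas = lorentzian_quantiles(params.eta_bar, params.delta, n_neurons)
        net = NetworkParams(
            n_neurons=n_neurons, j_syn=params.j_syn, tau_s=params.tau_s,
            eta_values=tuple(etas), dt=dt,
            increment_convention="one_over_N_tau",
        )
    elif currents != "sampled":
        raise ValueError(f"currents must be 'sampled' or 'quantile', got {currents!r}")
    etas = net.currents()
    d0 = etas + params.j_syn * r0
    V0 = np.where(d0 < 0, -np.sqrt(np.clip(-d0, 0.0, None)), 0.0)
    forcing = SlowForcing(amplitude, epsilon)
    t_end = horizon_fraction * forcing.period
    rec, trace = simulate_dense_network(
        net, forcing, (V0, r0), (0.0, t_end), window_dt=window_dt,
        burn_in=burn_in,
    )
    traj = trajectory_from_trace(
        trace.times, trace.mean_v, trace.inst_rate, trace.mean_s,
        params.eta_bar, forcing,
    )
    return traj, rec


def trajectory_from_trace(
    times: np.ndarray,
    v: np.ndarray,
    rate: np.ndarray,
    s: np.ndarray,
    eta_bar: float,
    forcing: SlowForcing,
) -> Trajectory:
    """Assemble a (r, v, s, K, Q) trajectory from network observables."""
    K = eta_bar + forcing.amplitude * np.sin(forcing.epsilon * times)
    Q = forcing.amplitude * np.cos(forcing.epsilon * times)
    states = np.column_stack([rate, v, s, K, Q])
    return Trajectory(times, states, {"eta_bar": eta_bar, "amplitude": forcing.amplitude})


def network_reaches_up(
    params: MeanFieldParams,
    amplitude: float,
    n_neurons: int,
    seed: int,
    epsilon: float = 0.05,
    dt: float = 2e-4,
) -> bool:
    """Down-up predicate for the dense network (windowed rate crosses the
    upper-fold rate after the fold passage)."""
    man = CriticalManifold(params)
    r_up = float(man.rate(man.folds()[0].v_star))
    traj, _ = network_trajectory(
        params, amplitude, n_neurons, seed, epsilon, dt=dt
    )
    return bool(traj.r.max() > r_up)


# ---------------------------------------------------------------------------
# branch points (used by amplitude sweeps at every scale)
# ---------------------------------------------------------------------------


def meanfield_branch_point(
    params: MeanFieldParams,
    amplitude: float,
    epsilon: float = 0.05,
    start_sheet: str = "lower",
    s_window: tuple[float, float] | None = None,
) -> BranchPoint:
    """One amplitude-sweep point: run two forcing periods, classify the
    entrained (second) cycle, measure delta_r over it and the canard dwell."""
    from .routes import classify_orbit as _classify, delta_r as _delta_r

    man = CriticalManifold(params)
    traj = meanfield_orbit(
        params, amplitude, epsilon, start_sheet, n_periods=2.0, n_eval=6000
    )
    period = SlowForcing(amplitude, epsilon).period
    oc = _classify(traj, man, period)
    dr = _delta_r(traj, period)
    if s_window is None:
        s_window = (period, 2 * period)
    sn = s_norm(traj.times, traj.s, s_window)
    dwell = canard_dwell_time(traj, man, epsilon)
    return BranchPoint(amplitude, sn, dr, oc, dwell)
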