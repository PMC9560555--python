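"""Microscale QIF simulators: single theta cells and dense all-to-all networks.

The network model is N quadratic integrate-and-fire neurons

    V_i' = V_i^2 + eta_i + I(t) + (J/N) sum_j s_j,     s_i' = -s_i/tau_s,

with heterogeneous background currents eta_i drawn from a Lorentzian
(Cauchy) distribution, slow sinusoidal forcing I(t) = A sin(eps t), and a
finite threshold/reset Vt = -Vr standing in for the blow-up/reset at
+-infinity.  When V_i crosses Vt it is reset to Vr and every synapse is
incremented.  Two increment conventions are supported:

* ``one_over_N`` -- the literal per-spike increment 1/N;
* ``one_over_N_tau`` -- 1/(N tau_s), under which the population-mean
  synapse obeys the relaxation law tau_s <s>' = -<s> + rate that the
  mean-field reduction assumes.

For N = 1 the singularity-free theta form V = tan(theta/2),

    theta' = 1 - cos(theta) + (1 + cos(theta)) * (eta + I + J s),

is integrated adaptively with root-resolved spike times (a spike is the
upward crossing of theta = pi, where V blows up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy.integrate import solve_ivp

from .params import SlowForcing

__all__ = [
    "NetworkParams",
    "SpikeRecord",
    "PopulationTrace",
    "sample_lorentzian",
    "lorentzian_quantiles",
    "simulate_theta_cell",
    "simulate_dense_network",
    "population_observables",
    "theta_rest_angle",
]


def sample_lorentzian(eta_bar: float, delta: float, n: int, seed) -> np.ndarray:
    """n Cauchy(eta_bar, delta) draws by the inverse CDF.

    eta = eta_bar + delta * tan(pi*(u - 1/2)) with u uniform on (0, 1);
    delta = 0 degenerates to a point mass at eta_bar.  ``seed`` may be an
    integer or a ``numpy.random.Generator``.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(n)
    return eta_bar + delta * np.tan(np.pi * (u - 0.5))


def lorentzian_quantiles(eta_bar: float, delta: float, n: int) -> np.ndarray:
    """Deterministic Lorentzian quantile grid.

    eta_i = eta_bar + delta * tan(pi/2 * (2i - n - 1)/(n + 1)), i = 1..n:
    the evenly spaced quantiles of Cauchy(eta_bar, delta).  The standard
    variance-control protocol for comparing finite networks against
    their mean-field limit — it removes the (infinite-variance)
    realization noise of sampled heavy-tailed currents while keeping the
    same limiting distribution.
    """
    i = np.arange(1, n + 1)
    return eta_bar + delta * np.tan(np.pi / 2 * (2 * i - n - 1) / (n + 1))


@dataclass(frozen=True)
class NetworkParams:
    """Dense-network configuration.

    ``eta_values`` may be given explicitly (length N) or left None, in
    which case currents are sampled from Cauchy(eta_bar, delta) with
    ``seed``.  ``increment_convention`` selects the per-spike synaptic
    increment (see module docstring).
    """

    n_neurons: int
    j_syn: float
    tau_s: float
    eta_bar: float = 0.0
    delta: float = 0.0
    eta_values: tuple[float, ...] | None = None
    seed: int = 0
    v_threshold: float = 100.0
    v_reset: float = -100.0
    dt: float = 1e-4
    increment_convention: str = "one_over_N"

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not (self.v_threshold > 0 > self.v_reset):
            raise ValueError("need v_threshold > 0 > v_reset")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")
        if self.eta_values is not None and len(self.eta_values) != self.n_neurons:
            raise ValueError("eta_values length must equal n_neurons")
        if self.increment_convention not in ("one_over_N", "one_over_N_tau"):
            raise ValueError(
                f"unknown increment_convention {self.increment_convention!r}"
            )

    def currents(self) -> np.ndarray:
        if self.eta_values is not None:
            return np.asarray(self.eta_values, dtype=float)
        return sample_lorentzian(self.eta_bar, self.delta, self.n_neurons, self.seed)

    @property
    def spike_increment(self) -> float:
        u = 1.0 / self.n_neurons
        if self.increment_convention == "one_over_N_tau":
            u /= self.tau_s
        return u


@dataclass
class SpikeRecord:
    """Spike events as parallel (time, neuron-id) arrays, time-sorted."""

    times: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.times.shape != self.ids.shape:
            raise ValueError("times and ids must have equal length")

    def __len__(self) -> int:
        return self.times.size

    def write_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.ids]),
            fmt=("%.9g", "%d"),
            delimiter="\t",
            header="time\tneuron_id",
            comments="",
        )


@dataclass
class PopulationTrace:
    """Population observables sampled on a regular time grid.

    ``inst_rate`` is the sliding-window estimate: spikes per neuron per
    unit time in [t, t + window).  ``mean_v`` uses the configured central
    estimator (median by default; Cauchy-tailed voltage marginals make the
    arithmetic mean noisy).
    """

    times: np.ndarray
    mean_v: np.ndarray
    mean_s: np.ndarray
    inst_rate: np.ndarray
    window_dt: float = 0.15
    estimator: str = "median"

    def write_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "t": self.times,
                "median_v" if self.estimator == "median" else "mean_v": self.mean_v,
                "mean_s": self.mean_s,
                "rate": self.inst_rate,
            }
        ).to_csv(path, index=False)


def theta_rest_angle(drive: float) -> float:
    """Stable rest phase of the theta equation under constant drive < 0.

    The rest voltage is V = -sqrt(-drive); returns 2*atan(V).  Raises for
    drive >= 0 (no rest state: the cell is tonic).
    """
    if drive >= 0:
        raise ValueError("no rest state for non-negative drive")
    return 2.0 * math.atan(-math.sqrt(-drive))


def simulate_theta_cell(
    eta: float,
    j_syn: float,
    tau_s: float,
    forcing: SlowForcing,
    t_span: tuple[float, float],
    theta0: float = 0.0,
    s0: float = 0.0,
    spike_increment: float = 1.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    record: bool = False,
    max_step: float = np.inf,
) -> tuple[SpikeRecord, tuple[np.ndarray, np.ndarray, np.ndarray] | None]:
    """Self-coupled single theta cell under slow sinusoidal forcing.

    Spike times are resolved by the solver's event location at theta = pi
    (upward crossing); at each spike the phase is wrapped by -2*pi (exact
    on the circle) and the synapse incremented by ``spike_increment`` (the
    literal single-cell convention is 1, i.e. 1/N with N = 1).

    Returns the spike record and, when ``record`` is true, the sampled
    (t, theta, s) trace.
    """
    A, eps = forcing.amplitude, forcing.epsilon

    def rhs(t, y):
        th, s = y
        drive = eta + A * math.sin(eps * t) + j_syn * s
        return (1.0 - math.cos(th) + (1.0 + math.cos(th)) * drive, -s / tau_s)

    def spike(t, y):
        return y[0] - math.pi

    spike.terminal = True
    spike.direction = 1

    t0, t_end = t_span
    y = np.array([theta0, s0], dtype=float)
    spikes: list[float] = []
    ts_parts, th_parts, s_parts = [], [], []
    while t0 < t_end:
        sol = solve_ivp(
            rhs,
            (t0, t_end),
            y,
            events=spike,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            max_step=max_step,
        )
        if record:
            ts_parts.append(sol.t)
            th_parts.append(sol.y[0])
            s_parts.append(sol.y[1])
        if sol.t_events[0].size:
            t0 = float(sol.t_events[0][0])
            spikes.append(t0)
            y = sol.y_events[0][0].copy()
            y[0] -= 2.0 * math.pi
            y[1] += spike_increment
        else:
            break
    rec = SpikeRecord(np.array(spikes), np.zeros(len(spikes), dtype=np.int64))
    if record:
        trace = (
            np.concatenate(ts_parts),
            np.concatenate(th_parts),
            np.concatenate(s_parts),
        )
        return rec, trace
    return rec, None


def simulate_dense_network(
    params: NetworkParams,
    forcing: SlowForcing,
    init: tuple[np.ndarray | float, np.ndarray | float],
    t_span: tuple[float, float],
    window_dt: float = 0.15,
    n_record: int = 1000,
    estimator: str = "median",
    burn_in: float = 0.0,
) -> tuple[SpikeRecord, PopulationTrace]:
    """Fixed-step (forward-Euler) simulation of the dense QIF network.

    At the end of each step every neuron at or above threshold is reset to
    Vr, one spike per such neuron is recorded at the step time, and all
    synapses are incremented by (number of spikes) x increment;
    simultaneous spikes accumulate.  The all-to-all coupling reduces to
    the population-mean synapse, so a step costs O(N).

    ``init`` is (V0, s0), scalars broadcast over neurons.  When
    ``burn_in`` > 0 the network is first relaxed for that long with the
    forcing off (A = 0), unrecorded, so the forced run starts from the
    stationary asynchronous state.  The trace is sampled at ~``n_record``
    points; the rate is a trailing-window count over ``window_dt``.
    """
    N = params.n_neurons
    etas = params.currents()
    V = np.broadcast_to(np.asarray(init[0], dtype=float), (N,)).copy()
    s = np.broadcast_to(np.asarray(init[1], dtype=float), (N,)).copy()
    dt = params.dt
    t0, t_end = t_span
    n_steps = int(round((t_end - t0) / dt))
    if burn_in > 0:
        kick_b = params.spike_increment
        for k in range(int(round(burn_in / dt))):
            drive = etas + params.j_syn * s.mean()
            V += dt * (V * V + drive)
            s -= dt * s / params.tau_s
            fired = V >= params.v_threshold
            n_f = int(np.count_nonzero(fired))
            if n_f:
                V[fired] = params.v_reset
                s += n_f * kick_b
    kick = params.spike_increment
    J = params.j_syn
    A, eps = forcing.amplitude, forcing.epsilon
    Vt, Vr = params.v_threshold, params.v_reset
    est = np.median if estimator == "median" else np.mean

    rec_every = max(1, n_steps // n_record)
    wsteps = max(1, int(round(window_dt / dt)))
    win_buf = np.zeros(wsteps, dtype=np.int64)
    win_sum = 0
    wi = 0

    spk_t: list[float] = []
    spk_i: list[np.ndarray] = []
    ts, mv, ms, rr = [], [], [], []

    for k in range(n_steps):
        t = t0 + k * dt
        drive = etas + (A * math.sin(eps * t) + J * s.mean())
        V += dt * (V * V + drive)
        s -= dt * s / params.tau_s
        fired = V >= Vt
        n_f = int(np.count_nonzero(fired))
        if n_f:
            ids = np.nonzero(fired)[0]
            V[ids] = Vr
            s += n_f * kick
            spk_t.append(t + dt)
            spk_i.append(ids)
        win_sum += n_f - win_buf[wi]
        win_buf[wi] = n_f
        wi = (wi + 1) % wsteps
        if k % rec_every == 0:
            ts.append(t + dt)
            mv.append(est(V))
            ms.append(s.mean())
            rr.append(win_sum / (N * wsteps * dt))
        if not np.all(np.isfinite(V)):
            bad = int(np.nonzero(~np.isfinite(V))[0][0])
            raise RuntimeError(
                f"non-finite voltage at t={t + dt:.6g} (neuron {bad})"
            )

    if spk_t:
        times = np.concatenate(
            [np.full(len(i), tt) for tt, i in zip(spk_t, spk_i)]
        )
        ids = np.concatenate(spk_i)
    else:
        times = np.empty(0)
        ids = np.empty(0, dtype=np.int64)
    rec = SpikeRecord(times, ids)
    trace = PopulationTrace(
        np.asarray(ts), np.asarray(mv), np.asarray(ms), np.asarray(rr),
        window_dt=wsteps * dt, estimator=estimator,
    )
    return rec, trace


def population_observables(
    spikes: SpikeRecord,
    n_neurons: int,
    t_span: tuple[float, float],
    window_dt: float = 0.15,
    voltages: tuple[np.ndarray, np.ndarray] | None = None,
    estimator: str = "median",
) -> PopulationTrace:
    """Population trace recomputed from a spike record.

    ``inst_rate(t)`` is (spike count in [t, t + window_dt)) / (N * window_dt);
    an empty record gives a zero rate everywhere.  ``voltages`` may supply
    (times, per-time voltage snapshots) from which the central estimate is
    taken; otherwise mean_v is NaN.
    """
    if window_dt <= 0:
        raise ValueError("window_dt must be > 0")
    t0, t_end = t_span
    edges = np.arange(t0, t_end + window_dt, window_dt)
    counts, _ = np.histogram(spikes.times, bins=edges)
    rate = counts / (n_neurons * window_dt)
    centres = edges[:-1]
    if voltages is not None:
        vt, vsnap = voltages
        est = np.median if estimator == "median" else np.mean
        per_t = np.asarray([est(row) for row in np.atleast_2d(vsnap)])
        mean_v = np.interp(centres, vt, per_t)
    else:
        mean_v = np.full_like(centres, np.nan, dtype=float)
    return PopulationTrace(
        centres, mean_v, np.zeros_like(centres), rate,
        window_dt=window_dt, estimator=estimator,
    )
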