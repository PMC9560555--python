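"""Sparse QIF networks with Cauchy-distributed in-degrees, and their
heuristic mean field.

The network is

    V_i' = V_i^2 + eta_i + I(t) + (J/sqrt(M)) sum_j W_ij s_j,
    tau_s s_i' = -s_i,

where W is a binary sparse matrix: row i holds gamma_i ones in randomly
selected columns (the presynaptic sources of neuron i), and the in-degree
gamma_i = floor(k_i) * chi_[0, 2M](k_i) comes from a Cauchy candidate
k_i ~ Cauchy(M, Delta_gamma * sqrt(M)); candidates outside [0, 2M] yield
degree zero (the literal indicator rule; resampling is available by flag).

Scaling profile.  The sparsity parameter M enters the model through four
exponents, all configurable via :class:`ScalingProfile` (exponent e means
a factor M**e): background currents Cauchy(eta_bar*M^a, Delta*M^a),
forcing amplitude A_bar*M^b, per-link coupling J*M^c, degree HWHM
Delta_gamma*M^d.  The default (a, b, c, d) = (1/2, 1/2, -1/2, 1/2) is the
unique assignment under which the heuristic mean field

    eps r. = sqrt(M)*Delta/pi + 2 r v + J*Delta_gamma*s/pi
    eps v. = v^2 + sqrt(M) (K + J s) - pi^2 r^2
    eps s. = (-s + r)/tau_s,          K around eta_bar, amplitude A_bar

is the consistent large-N description: it is exactly the generalised
single-population mean field with effective parameters

    Delta_eff = sqrt(M) Delta,   eta_bar_eff = sqrt(M) eta_bar,
    A_eff = sqrt(M) A_bar,       J_eff = sqrt(M) J,
    Gamma_tilde_eff = J Delta_gamma / pi,

so the whole critical-manifold/canard machinery applies unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .meanfield import extended_rhs
from .microscale import PopulationTrace, SpikeRecord
from .params import MeanFieldParams, SlowForcing

__all__ = [
    "ScalingProfile",
    "SparseParams",
    "SparseConnectivity",
    "sample_degrees",
    "build_connectivity",
    "simulate_sparse_network",
    "heuristic_meanfield_rhs",
    "heuristic_equivalent",
]


@dataclass(frozen=True)
class ScalingProfile:
    """Exponent placement of the sparsity parameter M (factor M**exponent)."""

    current: float = 0.5
    forcing: float = 0.5
    coupling: float = -0.5
    degree: float = 0.5


@dataclass(frozen=True)
class SparseParams:
    """Sparse-network configuration in *coefficient* units.

    ``eta_bar``, ``delta``, ``amp_coeff`` are the M-independent
    coefficients; the simulator applies the scaling profile, e.g. currents
    are Cauchy(eta_bar * M^a, delta * M^a).
    """

    n_neurons: int
    m_links: int
    j_syn: float
    degree_hwhm_coeff: float  # Delta_gamma
    eta_bar: float
    delta: float
    tau_s: float
    amp_coeff: float  # A_bar
    epsilon: float
    seed: int = 0
    v_threshold: float = 100.0
    v_reset: float = -100.0
    dt: float = 1e-4
    scaling_profile: ScalingProfile = field(default_factory=ScalingProfile)
    resample_out_of_range: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.m_links <= self.n_neurons):
            raise ValueError("need 1 <= m_links <= n_neurons")
        if self.degree_hwhm_coeff < 0 or self.delta < 0:
            raise ValueError("HWHM coefficients must be >= 0")
        if self.tau_s <= 0 or self.dt <= 0 or self.epsilon <= 0:
            raise ValueError("tau_s, dt, epsilon must be > 0")


def sample_degrees(
    m_links: int,
    degree_hwhm_coeff: float,
    n: int,
    seed,
    degree_exponent: float = 0.5,
    resample_out_of_range: bool = False,
) -> np.ndarray:
    """In-degrees gamma_i from the truncated-Cauchy rule.

    Candidates k_i ~ Cauchy(M, Delta_gamma * M**degree_exponent); a
    candidate inside [0, 2M] is rounded down to an integer, one outside
    gives degree 0 (or is redrawn when ``resample_out_of_range``).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hwhm = degree_hwhm_coeff * m_links**degree_exponent
    M = m_links

    def draw(k):
        u = rng.random(k)
        return M + hwhm * np.tan(np.pi * (u - 0.5))

    k = draw(n)
    if resample_out_of_range:
        bad = (k < 0) | (k > 2 * M)
        while np.any(bad):
            k[bad] = draw(int(bad.sum()))
            bad = (k < 0) | (k > 2 * M)
    inside = (k >= 0) & (k <= 2 * M)
    return np.where(inside, np.floor(k), 0.0).astype(np.int64)


@dataclass
class SparseConnectivity:
    """Binary sparse adjacency stored as per-row source lists.

    ``sources[i]`` are the gamma_i distinct presynaptic neurons of neuron
    i (self-loops excluded).  ``targets_of[j]`` is the transpose view used
    by the simulator to push spike increments to postsynaptic drives.
    """

    n: int
    degrees: np.ndarray
    sources: list[np.ndarray]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.degrees = np.asarray(self.degrees, dtype=np.int64)
        for i, row in enumerate(self.sources):
            if len(row) != self.degrees[i]:
                raise ValueError(f"row {i} length != degree")
            if len(np.unique(row)) != len(row):
                raise ValueError(f"row {i} has duplicated sources")

    @property
    def targets_of(self) -> list[np.ndarray]:
        if not hasattr(self, "_targets"):
            buckets: list[list[int]] = [[] for _ in range(self.n)]
            for i, row in enumerate(self.sources):
                for j in row:
                    buckets[j].append(i)
            self._targets = [np.asarray(b, dtype=np.int64) for b in buckets]
        return self._targets

    def write(self, path) -> None:
        """Row-index text format: header line `N M? seed`, then one
        whitespace-separated source list per row (blank line = degree 0)."""
        with open(path, "w") as fh:
            fh.write(f"# n={self.n} seed={self.seed}\n")
            for row in self.sources:
                fh.write(" ".join(map(str, row)) + "\n")


def build_connectivity(degrees: np.ndarray, n: int, seed) -> SparseConnectivity:
    """Adjacency with row i containing degrees[i] random distinct sources.

    Sources are drawn uniformly without replacement from the other n-1
    neurons (no self-loops).
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    if np.any(degrees > n - 1):
        raise ValueError("degree exceeds n-1 (cannot avoid self-loops)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows: list[np.ndarray] = []
    others = np.arange(n - 1)
    for i in range(n):
        g = int(degrees[i])
        pick = rng.choice(n - 1, size=g, replace=False) if g else np.empty(0, dtype=np.int64)
        # map [0, n-2] onto [0, n-1] \ {i}
        pick = np.where(pick >= i, pick + 1, pick)
        rows.append(np.sort(pick).astype(np.int64))
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return SparseConnectivity(n, degrees, rows, seed_val)


def simulate_sparse_network(
    params: SparseParams,
    connectivity: SparseConnectivity,
    init: tuple[np.ndarray | float, np.ndarray | float],
    t_span: tuple[float, float],
    eta_values: np.ndarray | None = None,
    window_dt: float = 0.15,
    n_record: int = 1000,
    estimator: str = "median",
    burn_in: float = 0.0,
) -> tuple[SpikeRecord, PopulationTrace]:
    """Fixed-step simulation of the sparse network.

    Same stepping/reset machinery as the dense simulator, but the
    per-neuron synaptic drive u_i = w * sum_j W_ij s_j is maintained
    incrementally: all s_j share the same exponential decay, so u decays
    by the same per-step factor and spike kicks are pushed along the
    spiking neurons' target lists.  The connectivity object is reusable
    across runs (amplitude sweeps hold W fixed).

    Per-spike synaptic increment is 1/tau_s, under which the
    population-mean synapse obeys tau_s <s>' = -<s> + rate.
    """
    N = params.n_neurons
    if connectivity.n != N:
        raise ValueError("connectivity size does not match params")
    prof = params.scaling_profile
    M = params.m_links
    if eta_values is None:
        rng = np.random.default_rng(params.seed)
        scale = M**prof.current
        u = rng.random(N)
        eta_values = params.eta_bar * scale + params.delta * scale * np.tan(
            np.pi * (u - 0.5)
        )
    A = params.amp_coeff * M**prof.forcing
    w_link = params.j_syn * M**prof.coupling
    kick = 1.0 / params.tau_s
    targets = connectivity.targets_of

    dt, eps = params.dt, params.epsilon
    Vt, Vr = params.v_threshold, params.v_reset
    t0, t_end = t_span
    n_steps = int(round((t_end - t0) / dt))
    V = np.broadcast_to(np.asarray(init[0], dtype=float), (N,)).copy()
    s = np.broadcast_to(np.asarray(init[1], dtype=float), (N,)).copy()
    drive_syn = np.zeros(N)
    for i in range(N):  # initial consistency with s
        if connectivity.degrees[i]:
            drive_syn[i] = w_link * s[connectivity.sources[i]].sum()
    decay = 1.0 - dt / params.tau_s
    est = np.median if estimator == "median" else np.mean

    if burn_in > 0:  # relax to the stationary state with the forcing off
        for k in range(int(round(burn_in / dt))):
            V += dt * (V * V + eta_values + drive_syn)
            s *= decay
            drive_syn *= decay
            fired = V >= Vt
            if np.any(fired):
                ids = np.nonzero(fired)[0]
                V[ids] = Vr
                s[ids] += kick
                wk = w_link * kick
                for j in ids:
                    tg = targets[j]
                    if tg.size:
                        drive_syn[tg] += wk

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
        ext = A * math.sin(eps * t)
        V += dt * (V * V + eta_values + ext + drive_syn)
        s *= decay
        drive_syn *= decay
        fired = V >= Vt
        n_f = int(np.count_nonzero(fired))
        if n_f:
            ids = np.nonzero(fired)[0]
            V[ids] = Vr
            s[ids] += kick
            wk = w_link * kick
            for j in ids:
                tg = targets[j]
                if tg.size:
                    drive_syn[tg] += wk
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
            raise RuntimeError(f"non-finite voltage at t={t + dt:.6g} (neuron {bad})")

    if spk_t:
        times = np.concatenate([np.full(len(i), tt) for tt, i in zip(spk_t, spk_i)])
        ids = np.concatenate(spk_i)
    else:
        times = np.empty(0)
        ids = np.empty(0, dtype=np.int64)
    trace = PopulationTrace(
        np.asarray(ts), np.asarray(mv), np.asarray(ms), np.asarray(rr),
        window_dt=wsteps * dt, estimator=estimator,
    )
    return SpikeRecord(times, ids), trace


def heuristic_equivalent(params: SparseParams) -> tuple[MeanFieldParams, SlowForcing]:
    """Effective single-population parameters of the heuristic mean field.

    Returns (MeanFieldParams, SlowForcing) such that the generalised
    mean-field right-hand side with these parameters equals
    :func:`heuristic_meanfield_rhs`: Delta, eta_bar and the forcing
    amplitude are scaled by M**current-exponent, the synaptic strength by
    the same factor (via gamma_coupling trickery we instead pass
    j_syn = sqrt(M) J and encode Gamma_tilde = J*Delta_gamma/pi through
    ``gamma_coupling = pi * Gamma_tilde``).
    """
    prof = params.scaling_profile
    scale = params.m_links**prof.current
    gamma_tilde = params.j_syn * params.degree_hwhm_coeff / math.pi
    mf = MeanFieldParams(
        delta=params.delta * scale,
        j_syn=params.j_syn * scale,
        eta_bar=params.eta_bar * scale,
        tau_s=params.tau_s,
        gamma_coupling=math.pi * gamma_tilde,
    )
    forcing = SlowForcing(params.amp_coeff * scale, params.epsilon)
    return mf, forcing


def heuristic_meanfield_rhs(
    state, params: SparseParams, epsilon: float | None = None,
    t: float = 0.0, time_scale: str = "slow",
):
    """Right-hand side of the heuristic sparse mean field in (r, v, s, K, Q).

    K oscillates around the coefficient eta_bar with amplitude amp_coeff;
    the sparsity prefactor sqrt(M) multiplies (K + J s) in the voltage
    equation and Delta/pi in the rate equation, and the degree
    heterogeneity adds J*Delta_gamma*s/pi to the rate equation.
    Implemented by delegation to the generalised mean field under the
    effective-parameter map (see :func:`heuristic_equivalent`); state K is
    rescaled on the way in/out so callers work in coefficient units.
    """
    if epsilon is None:
        epsilon = params.epsilon
    mf, _ = heuristic_equivalent(params)
    scale = params.m_links**params.scaling_profile.current
    r, v, s, K, Q = state
    out = extended_rhs(
        (r, v, s, K * scale, Q * scale), mf, epsilon, t, time_scale=time_scale
    )
    out[3] /= scale
    out[4] /= scale
    return out
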