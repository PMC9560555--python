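"""Parameter containers shared across the mean-field and geometry modules.

The central object is :class:`MeanFieldParams`, which describes the
Montbrio-Pazo-Roxin (MPR) firing-rate/mean-voltage reduction of an
all-to-all QIF network with Lorentzian-distributed background currents,
together with the generalised coupling extensions (coupling heterogeneity
``Gamma``, electrical coupling ``g``, spike asymmetry ``a``).  The
generalisation enters the dynamics only through the two effective
coefficients

    Gamma_tilde = Gamma/pi - g        (rate equation, multiplies s)
    J_tilde     = J + g*ln(a)         (voltage equation, multiplies s)

so every analysis downstream is written in terms of ``gamma_tilde`` and
``j_tilde``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace


def effective_coefficients(
    gamma_coupling: float, g_elec: float, a_spike: float
) -> tuple[float, float]:
    """Effective coefficients of the generalised mean field.

    Returns ``(gamma_tilde, j_offset)`` where ``gamma_tilde = Gamma/pi - g``
    and ``j_offset = g*ln(a)``, so that the effective synaptic strength is
    ``J_tilde = J + j_offset``.

    Raises
    ------
    ValueError
        If ``a_spike <= 0`` (the spike-asymmetry parameter enters through
        its logarithm).
    """
    if a_spike <= 0:
        raise ValueError(f"a_spike must be positive, got {a_spike}")
    return gamma_coupling / math.pi - g_elec, g_elec * math.log(a_spike)


@dataclass(frozen=True)
class MeanFieldParams:
    """Parameters of the (generalised) MPR mean field.

    Attributes
    ----------
    delta : float
        HWHM of the Lorentzian background-current distribution (current units).
    j_syn : float
        Chemical synaptic coupling strength J.
    eta_bar : float
        Centre of the background-current distribution.
    tau_s : float
        Synaptic time constant (time units).
    gamma_coupling : float
        HWHM of the coupling-strength distribution (Gamma); 0 turns the
        extension off.
    g_elec : float
        Electrical (gap-junction) coupling strength; 0 turns it off.
    a_spike : float
        Spike-asymmetry parameter; 1 turns it off.
    """

    delta: float = 1.0
    j_syn: float = 15.0
    eta_bar: float = 0.0
    tau_s: float = 0.02
    gamma_coupling: float = 0.0
    g_elec: float = 0.0
    a_spike: float = 1.0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.tau_s <= 0:
            raise ValueError(f"tau_s must be > 0, got {self.tau_s}")
        if self.a_spike <= 0:
            raise ValueError(f"a_spike must be > 0, got {self.a_spike}")
        gt, off = effective_coefficients(
            self.gamma_coupling, self.g_elec, self.a_spike
        )
        if not (math.isfinite(gt) and math.isfinite(off)):
            raise ValueError("effective coefficients are not finite")

    @property
    def gamma_tilde(self) -> float:
        return effective_coefficients(
            self.gamma_coupling, self.g_elec, self.a_spike
        )[0]

    @property
    def j_tilde(self) -> float:
        return self.j_syn + effective_coefficients(
            self.gamma_coupling, self.g_elec, self.a_spike
        )[1]

    def with_eta_bar(self, eta_bar: float) -> "MeanFieldParams":
        return replace(self, eta_bar=eta_bar)


@dataclass(frozen=True)
class SlowForcing:
    """Slow sinusoidal forcing ``I(t) = A*sin(eps*t)``.

    The forcing is represented by the harmonic pair (K, Q) with
    ``K(t) = eta_bar + A*sin(eps*t)`` and ``Q(t) = A*cos(eps*t)``; the pair
    obeys ``K' = eps*Q``, ``Q' = -eps*(K - eta_bar)`` so that
    ``(K - eta_bar)^2 + Q^2 = A^2`` is conserved exactly.  The initial phase
    is fixed: ``K(0) = eta_bar``, ``Q(0) = A`` (the input starts at zero and
    increasing).
    """

    amplitude: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")

    @property
    def period(self) -> float:
        """Forcing period in fast-time units, 2*pi/eps."""
        return 2.0 * math.pi / self.epsilon

    def current(self, t) -> float:
        """The external input I(t) = A*sin(eps*t) (fast time)."""
        import numpy as np

        return self.amplitude * np.sin(self.epsilon * np.asarray(t))


@dataclass(frozen=True)
class MultiPopParams:
    """p synaptically coupled populations, one of which is slowly forced.

    ``coupling[i][j]`` is the effective synaptic strength J_tilde_ij with
    which population j's synaptic output drives population i's voltage
    equation.  Only population ``forced_index`` receives the slow input K;
    by the same convention as the single-population system, the forced
    population's baseline eta_bar is carried by K (it oscillates around
    eta_bar_k) and is therefore excluded from that population's intrinsic
    drive, while unforced populations keep their eta_bar in the voltage
    equation.
    """

    populations: tuple[MeanFieldParams, ...]
    coupling: tuple[tuple[float, ...], ...]
    forced_index: int = 0
    forcing: SlowForcing = field(default_factory=lambda: SlowForcing(0.0, 0.05))

    def __post_init__(self) -> None:
        p = len(self.populations)
        if p < 1:
            raise ValueError("need at least one population")
        if len(self.coupling) != p or any(len(row) != p for row in self.coupling):
            raise ValueError(
                f"coupling must be {p}x{p}, got "
                f"{len(self.coupling)}x{len(self.coupling[0]) if self.coupling else 0}"
            )
        if not (0 <= self.forced_index < p):
            raise ValueError(f"forced_index {self.forced_index} out of range for p={p}")

    @property
    def n_pop(self) -> int:
        return len(self.populations)
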