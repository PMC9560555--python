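"""Orbit classification, branch measures, canard dwell times and
threshold location by amplitude bisection.

The vocabulary: within one forcing cycle an orbit occupies a *down* phase
(quiescent / lower-sheet tracking) and/or an *up* phase (tonic firing /
upper-sheet tracking).  Composing the phase before and after the fold
passage gives the four transition labels down-down, down-up, up-up,
up-down; *bursting* orbits are those containing both phases in one cycle
(down-up or up-down), non-bursting ones stay on a single sheet.  The
onset of bursting under amplitude variation is mediated by canard
solutions that track the repelling middle sheet; the transition is
continuous but exponentially sharp (a canard explosion), so in practice
it is located by bisection on a discrete classification predicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .geometry import CriticalManifold
from .meanfield import Trajectory

__all__ = [
    "OrbitClass",
    "BranchPoint",
    "s_norm",
    "delta_r",
    "classify_orbit",
    "classify_meanfield_cycle",
    "canard_dwell_time",
    "find_threshold",
    "amplitude_sweep",
]

LABELS = ("down-down", "down-up", "up-up", "up-down", "unclassified")


@dataclass(frozen=True)
class OrbitClass:
    """Transition label of one forcing cycle plus the raw phase sequence."""

    value: str
    phases: tuple[str, ...] = ()

    @property
    def bursting(self) -> bool:
        """True when the cycle contains both a down and an up phase."""
        return self.value in ("down-up", "up-down")


@dataclass(frozen=True)
class BranchPoint:
    """One point of an amplitude-sweep branch."""

    amplitude: float
    s_norm: float
    delta_r: float
    orbit_class: OrbitClass
    dwell: float = 0.0


def s_norm(times: np.ndarray, s: np.ndarray, window: tuple[float, float] = (0.0, 70.0)) -> float:
    """Trapezoidal integral of s(t) over ``window``.

    Raises when the window is not contained in the sampled span.
    """
    t0, t1 = window
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise ValueError(
            f"window {window} outside trajectory span ({times[0]}, {times[-1]})"
        )
    m = (times >= t0) & (times <= t1)
    return float(np.trapezoid(s[m], times[m]))


def delta_r(
    traj: Trajectory, period: float, transient: float | None = None
) -> float:
    """max(r) - min(r) over exactly one forcing period after the transient.

    ``transient`` defaults to one forcing period.
    """
    if transient is None:
        transient = period
    t0 = traj.times[0] + transient
    t1 = t0 + period
    if t1 > traj.times[-1] + 1e-9:
        raise ValueError(
            f"trajectory span {traj.times[-1]} too short for transient+period {t1}"
        )
    m = (traj.times >= t0) & (traj.times <= t1)
    r = traj.r[m]
    return float(r.max() - r.min())


def _phase_sequence(
    v: np.ndarray, r: np.ndarray, manifold: CriticalManifold
) -> list[str]:
    """Collapse per-sample sheet tracking into a down/up phase sequence."""
    folds = manifold.folds()
    if not folds:
        raise ValueError("orbit classification requires a folded manifold")
    fp, fm = folds[0], folds[1]
    r_up = manifold.rate(fp.v_star)
    lab = np.full(v.shape, "", dtype=object)
    lab[(v < fm.v_star) & (r < manifold.rate(fm.v_star) * 1.5)] = "down"
    lab[(v > fp.v_star) | (r > r_up)] = "up"
    seq: list[str] = []
    for x in lab:
        if x and (not seq or seq[-1] != x):
            seq.append(str(x))
    return seq


def classify_meanfield_cycle(
    traj: Trajectory,
    manifold: CriticalManifold,
    cycle: tuple[float, float] | None = None,
) -> OrbitClass:
    """Label one forcing cycle of a mean-field trajectory.

    The phase at each sample follows the sheet the state tracks: *down*
    when v is below the lower fold voltage (and the rate below the
    lower-fold rate), *up* when v is above the upper fold voltage or the
    rate exceeds the upper-fold rate.  The first two distinct phases in
    the cycle give the transition label (a fully developed bursting
    cycle down-up-down keeps its first transition, down-up); a single
    phase doubles up (down-down / up-up); the raw sequence is kept in
    label; no identified phase is "unclassified".
    """
    if cycle is not None:
        m = (traj.times >= cycle[0]) & (traj.times <= cycle[1])
        v, r = traj.v[m], traj.r[m]
    else:
        v, r = traj.v, traj.r
    seq = _phase_sequence(v, r, manifold)
    if not seq:
        return OrbitClass("unclassified", ())
    if len(seq) == 1:
        return OrbitClass(f"{seq[0]}-{seq[0]}", tuple(seq))
    return OrbitClass(f"{seq[0]}-{seq[1]}", tuple(seq))


def classify_orbit(
    traj: Trajectory,
    manifold: CriticalManifold,
    period: float,
    transient: float | None = None,
) -> OrbitClass:
    """Label the post-transient forcing cycle of a mean-field trajectory.

    ``transient`` defaults to one forcing period (entrained measurement);
    pass 0 to classify the first cycle (transient response).
    """
    if transient is None:
        transient = period
    t0 = traj.times[0] + transient
    return classify_meanfield_cycle(traj, manifold, (t0, t0 + period))


def canard_dwell_time(
    traj: Trajectory,
    manifold: CriticalManifold,
    epsilon: float,
    tube_radius: float | None = None,
) -> float:
    """Slow time spent inside a tube around the repelling sheet.

    The repelling sheet is {(v, K): K = -psi(v), psi'(v) > 0 between the
    folds}; the dwell is the total time with |K + psi(v)| < radius and v
    strictly between the fold voltages, converted to slow-time units
    (times eps when the trajectory is parametrised by fast time).

    The default radius is 0.25 * |eta_- - eta_+|: for eps > 0 a canard
    tracks the repelling *slow manifold*, which is displaced O(eps) from
    S0, so the tube must be wide enough to contain that displacement
    while still excluding the fast jumps (which pass several fold-span
    units away from the sheet).
    """
    folds = manifold.folds()
    if not folds:
        raise ValueError("dwell time requires a folded manifold")
    fp, fm = folds[0], folds[1]
    if tube_radius is None:
        tube_radius = 0.25 * abs(fm.eta_fold - fp.eta_fold)
    v, K, t = traj.v, traj.K, traj.times
    inside = (v > fm.v_star) & (v < fp.v_star)
    vv = np.clip(v, fm.v_star + 1e-12, fp.v_star - 1e-12)
    near = np.abs(K + np.asarray(manifold.psi(vv))) < tube_radius
    mask = inside & near
    if not mask.any():
        return 0.0
    dt = np.diff(t)
    occ = 0.5 * (mask[1:].astype(float) + mask[:-1].astype(float))
    return float(np.sum(dt * occ) * epsilon)


def find_threshold(
    classify: Callable[[float], object],
    a_low: float,
    a_high: float,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[float, tuple[float, float]]:
    """Bisection on the forcing amplitude against a classification predicate.

    ``classify(A)`` may return any comparable label; the bracket must
    yield two different labels.  Randomness (currents, connectivity,
    initial noise) must be frozen by the caller across the sweep.
    Returns (midpoint, bracket) once the bracket width is below ``tol``.
    """
    c_low = classify(a_low)
    c_high = classify(a_high)
    if c_low == c_high:
        raise ValueError(
            f"same class at both bracket ends: {c_low!r} at {a_low} and {a_high}"
        )
    lo, hi = float(a_low), float(a_high)
    it = 0
    while hi - lo > tol and it < max_iter:
        mid = 0.5 * (lo + hi)
        if classify(mid) == c_low:
            lo = mid
        else:
            hi = mid
        it += 1
    return 0.5 * (lo + hi), (lo, hi)


def amplitude_sweep(
    run: Callable[[float], BranchPoint],
    amplitudes: Sequence[float],
    vertical_fraction: float = 0.5,
    vertical_span: float = 1e-3,
) -> tuple[list[BranchPoint], dict]:
    """Evaluate a solution branch over sorted amplitudes.

    ``run(A)`` must hold every random element fixed.  The summary flags a
    quasi-vertical (canard-explosion) segment when either branch measure
    changes by more than ``vertical_fraction`` of its sweep range within
    an amplitude interval shorter than ``vertical_span`` times the sweep
    span.
    """
    amplitudes = list(amplitudes)
    if any(b < a for a, b in zip(amplitudes, amplitudes[1:])):
        raise ValueError("amplitudes must be sorted ascending")
    points = [run(float(a)) for a in amplitudes]
    span = amplitudes[-1] - amplitudes[0] if len(amplitudes) > 1 else 0.0
    summary: dict = {"quasi_vertical": False, "interval": None, "measure": None}
    for measure in ("delta_r", "s_norm"):
        vals = np.array([getattr(p, measure) for p in points], dtype=float)
        if measure == "s_norm":
            vals = np.where(vals > 0, 1.0 / np.where(vals > 0, vals, 1.0), np.nan)
        finite = vals[np.isfinite(vals)]
        if finite.size < 2 or span <= 0:
            continue
        rng_v = finite.max() - finite.min()
        if rng_v <= 0:
            continue
        for i in range(len(points) - 1):
            da = amplitudes[i + 1] - amplitudes[i]
            dv = abs(vals[i + 1] - vals[i])
            if not np.isfinite(dv):
                continue
            if da < vertical_span * span and dv > vertical_fraction * rng_v:
                summary = {
                    "quasi_vertical": True,
                    "interval": (amplitudes[i], amplitudes[i + 1]),
                    "measure": measure,
                }
                break
        if summary["quasi_vertical"]:
            break
    return points, summary
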