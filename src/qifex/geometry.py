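"""Slow-fast geometry of the mean field: critical manifold, folds, folded
singularities, singular canards and routes-to-bursting regions.

Freezing the slow forcing (eps -> 0) reduces the fast population equations
to algebraic constraints.  With the pi^2 r^2 convention these are

    s = r = -(Delta/pi) / (2v + Gamma_tilde),      0 = K + psi(v),

where

    psi(v) = v^2 - pi^2 r(v)^2 + J_tilde r(v).

The constraint surface S0 (the critical manifold) is S-shaped whenever
psi' has two real roots v* (the folds F+ and F-, with fold input values
eta_f = -psi(v*)).  The slow flow on S0, projected to (v, Q) and rescaled
by -psi'(v) (the desingularised reduced system, DRS)

    v' = Q,      Q' = -psi'(v) (eta_bar + psi(v)),

turns each fold point with Q = 0 into an ordinary equilibrium whose
linearisation has zero trace and eigenvalues +-sqrt(a) with

    a = -psi''(v*) (eta_bar + psi(v*)) = -psi''(v*) (eta_bar - eta_f).

a > 0 gives a folded saddle (true and faux singular canards exist);
a < 0 a folded centre (no canards, discontinuous transition).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .params import MeanFieldParams, MultiPopParams

__all__ = [
    "CriticalManifold",
    "FoldPoint",
    "FoldedSingularity",
    "RegionLabel",
    "equilibrium_rate",
    "find_folds",
    "classify_folded_singularity",
    "drs_flow",
    "singular_canard",
    "region_classify",
    "MultiPopManifold",
]


def equilibrium_rate(v: float, delta: float, gamma_tilde: float = 0.0):
    """Equilibrium rate r(v) = -(Delta/pi)/(2v + Gamma_tilde).

    Defined away from the singular line 2v + Gamma_tilde = 0; positive on
    the manifold domain v < -Gamma_tilde/2 (for Delta > 0).
    """
    den = 2.0 * np.asarray(v, dtype=float) + gamma_tilde
    if np.any(den == 0):
        raise ValueError("v lies on the singular line 2v + gamma_tilde = 0")
    return -(delta / math.pi) / den


@dataclass(frozen=True)
class FoldPoint:
    """A fold of the critical manifold: root of psi'.

    ``label`` is "F+" for the fold bordering the upper (high-rate,
    less-negative-voltage) sheet and "F-" for the one bordering the lower
    sheet.  ``eta_fold`` is the input value at the fold, -psi(v_star).
    """

    v_star: float
    eta_fold: float
    label: str


@dataclass(frozen=True)
class FoldedSingularity:
    """A fold point together with its DRS classification at a given eta_bar.

    ``lambda_sq`` is the squared eigenvalue a = -psi''(v*)(eta_bar - eta_f);
    the DRS Jacobian at the singularity is [[0, 1], [a, 0]] (zero trace),
    so the eigenvalues are +-sqrt(a): a real pair for a folded saddle,
    an imaginary pair for a folded centre.
    """

    fold: FoldPoint
    eta_bar: float
    lambda_sq: float
    classification: str  # "folded-saddle" | "folded-centre" | "degenerate"

    @property
    def eigenvalues(self) -> tuple[complex, complex]:
        lam = np.sqrt(complex(self.lambda_sq))
        return (lam, -lam)


@dataclass(frozen=True)
class RegionLabel:
    """Route-to-bursting region of eta_bar relative to the fold inputs.

    I   : eta_bar < eta_plus           (down-to-up route only)
    II  : eta_plus < eta_bar < eta_0   (down-to-up; upper branch folds back)
    III : eta_0 < eta_bar < eta_minus  (up-to-down; lower branch folds back)
    IV  : eta_bar > eta_minus          (up-to-down route only)

    with eta_0 = (eta_plus + eta_minus)/2.
    """

    value: str
    boundaries: tuple[float, float, float]  # (eta_plus, eta_0, eta_minus)


class CriticalManifold:
    """The constraint surface S0 of the frozen-forcing mean field.

    Provides psi and its analytic first and second derivatives on the
    domain v < -Gamma_tilde/2 where the equilibrium rate is positive, plus
    fold finding and sheet tests.  By construction psi satisfies the
    equilibrium identity: substituting (r(v), v, s=r(v), K=-psi(v)) into
    the fast part of the mean-field right-hand side gives zero.
    """

    def __init__(self, params: MeanFieldParams):
        self.params = params
        self._gt = params.gamma_tilde
        self._jt = params.j_tilde

    @property
    def v_max(self) -> float:
        """Right edge of the manifold domain (exclusive)."""
        return -self._gt / 2.0

    def _check_domain(self, v) -> None:
        if np.any(np.asarray(v) >= self.v_max):
            raise ValueError(
                f"v must be < {self.v_max} (manifold domain), got {v}"
            )

    def rate(self, v):
        """Equilibrium rate r(v) on the manifold."""
        self._check_domain(v)
        return equilibrium_rate(v, self.params.delta, self._gt)

    def psi(self, v):
        """psi(v) = v^2 - pi^2 r(v)^2 + J_tilde r(v); K = -psi on S0."""
        self._check_domain(v)
        v = np.asarray(v, dtype=float)
        r = equilibrium_rate(v, self.params.delta, self._gt)
        return v * v - math.pi**2 * r * r + self._jt * r

    def psi_prime(self, v):
        self._check_domain(v)
        v = np.asarray(v, dtype=float)
        d = self.params.delta / math.pi
        u = 1.0 / (2.0 * v + self._gt)
        r = -d * u
        rp = 2.0 * d * u * u
        return 2.0 * v - 2.0 * math.pi**2 * r * rp + self._jt * rp

    def psi_second(self, v):
        self._check_domain(v)
        v = np.asarray(v, dtype=float)
        d = self.params.delta / math.pi
        u = 1.0 / (2.0 * v + self._gt)
        r = -d * u
        rp = 2.0 * d * u * u
        rpp = -8.0 * d * u * u * u
        return 2.0 - 2.0 * math.pi**2 * (rp * rp + r * rpp) + self._jt * rpp

    # -- folds -----------------------------------------------------------

    def folds(
        self, v_lo: float = -1e3, v_margin: float = 1e-6, n_grid: int = 10_000
    ) -> list[FoldPoint]:
        """All folds (roots of psi') in the domain, ordered F+ then F-.

        Roots are isolated by a sign-change scan on a log-spaced grid in
        (v_lo, v_max - v_margin) and polished by bisection; psi' diverges
        at both ends of the domain, so brackets are guaranteed when folds
        exist.  The grid is refined automatically (up to 3 times) if the
        scan finds an odd or >2 number of sign changes.
        """
        hi = self.v_max - v_margin
        for attempt in range(4):
            n = n_grid * (4**attempt)
            # log-spaced offsets below the domain edge
            offs = np.logspace(
                math.log10(v_margin), math.log10(hi - v_lo + v_margin), n
            )
            vs = hi - offs + v_margin  # from near the edge down to v_lo
            vs = vs[::-1]  # increasing
            f = self.psi_prime(vs)
            idx = np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]
            if len(idx) in (0, 2):
                break
        else:
            raise RuntimeError("could not isolate fold roots by grid refinement")
        roots = [
            brentq(lambda x: float(self.psi_prime(x)), vs[i], vs[i + 1], xtol=1e-12)
            for i in idx
        ]
        roots.sort()  # most negative first (F-), least negative last (F+)
        if not roots:
            return []
        fm, fp = roots[0], roots[-1]
        return [
            FoldPoint(fp, float(-self.psi(fp)), "F+"),
            FoldPoint(fm, float(-self.psi(fm)), "F-"),
        ]

    # -- sheets ----------------------------------------------------------

    def sheet(self, v) -> np.ndarray:
        """Sheet membership: -1 lower, 0 repelling (middle), +1 upper.

        The middle sheet is where psi' > 0 between the folds; the two
        attracting sheets have psi' < 0.  Without folds everything is one
        attracting sheet (-1).
        """
        v = np.atleast_1d(np.asarray(v, dtype=float))
        folds = self.folds()
        out = np.full(v.shape, -1, dtype=int)
        if folds:
            fp, fm = folds[0].v_star, folds[1].v_star
            out[v > fp] = 1
            out[(v > fm) & (v <= fp)] = 0
        return out

    def branch_voltage(self, eta: float, sheet: str) -> float:
        """Voltage of the equilibrium at input K = eta on a given sheet.

        ``sheet`` is "lower", "middle" or "upper".  Raises ValueError when
        the requested sheet does not exist at that input.
        """
        folds = self.folds()
        if not folds:
            if sheet != "lower":
                raise ValueError("unfolded manifold has a single (lower) sheet")
            lo = -max(10.0, 2 * math.sqrt(abs(eta) + 1.0))
            while eta + self.psi(lo) < 0:
                lo *= 2
            return brentq(lambda v: float(eta + self.psi(v)), lo, self.v_max - 1e-9)
        fp, fm = folds[0], folds[1]
        g = lambda v: float(eta + self.psi(v))
        if sheet == "lower":
            if eta >= fm.eta_fold:
                raise ValueError(
                    f"no lower-sheet equilibrium at eta={eta} (fold at {fm.eta_fold})"
                )
            lo = min(fm.v_star * 2, -2 * math.sqrt(abs(eta) + 1.0))
            while g(lo) < 0:
                lo *= 2
            return brentq(g, lo, fm.v_star)
        if sheet == "middle":
            if not (fp.eta_fold < eta < fm.eta_fold):
                raise ValueError(f"no middle-sheet equilibrium at eta={eta}")
            return brentq(g, fm.v_star, fp.v_star)
        if sheet == "upper":
            if eta <= fp.eta_fold:
                raise ValueError(
                    f"no upper-sheet equilibrium at eta={eta} (fold at {fp.eta_fold})"
                )
            scale = 1e-6
            while g(self.v_max - scale) > 0:
                scale *= 0.1
                if scale < 1e-15:
                    raise RuntimeError("failed to bracket upper-sheet root")
            return brentq(g, fp.v_star, self.v_max - scale)
        raise ValueError(f"unknown sheet {sheet!r}")

    def sample(self, n: int = 400, v_lo: float | None = None) -> np.ndarray:
        """Sample (v, r, K) along S0 for plotting/serialisation."""
        folds = self.folds()
        if v_lo is None:
            v_lo = 4 * folds[1].v_star if folds else -10.0
        vs = np.linspace(v_lo, self.v_max - 1e-3, n)
        return np.column_stack([vs, self.rate(vs), -self.psi(vs)])


def find_folds(params: MeanFieldParams, **kw) -> list[FoldPoint]:
    """Folds of the critical manifold of ``params`` (length 0 or 2)."""
    return CriticalManifold(params).folds(**kw)


def classify_folded_singularity(
    fold: FoldPoint, eta_bar: float, params: MeanFieldParams, tol: float = 1e-12
) -> FoldedSingularity:
    """Classify the folded singularity on ``fold`` at distribution centre eta_bar.

    Computes a = -psi''(v*)(eta_bar - eta_fold) and labels the singularity
    folded-saddle (a > 0), folded-centre (a < 0) or degenerate (|a| <= tol,
    which happens exactly when eta_bar sits on the fold value).
    """
    man = CriticalManifold(params)
    if abs(float(man.psi_prime(fold.v_star))) > 1e-8:
        raise ValueError(f"fold.v_star={fold.v_star} is not a root of psi'")
    a = float(-man.psi_second(fold.v_star) * (eta_bar - fold.eta_fold))
    if abs(a) <= tol:
        cls = "degenerate"
    elif a > 0:
        cls = "folded-saddle"
    else:
        cls = "folded-centre"
    return FoldedSingularity(fold, eta_bar, a, cls)


def drs_flow(v, Q, params: MeanFieldParams, eta_bar: float | None = None):
    """Vector field of the desingularised reduced system (DRS).

    v' = Q,  Q' = -psi'(v) (eta_bar + psi(v)).  Note the time-orientation
    subtlety: the DRS flow matches the reduced slow flow on the attracting
    sheets (psi' < 0) but runs backwards on the repelling sheet (psi' > 0).
    """
    if eta_bar is None:
        eta_bar = params.eta_bar
    man = CriticalManifold(params)
    return np.asarray(Q, dtype=float), -man.psi_prime(v) * (eta_bar + man.psi(v))


@dataclass
class CanardSegment:
    """One DRS orbit segment lifted to (K, Q, v) via K = -psi(v)."""

    kind: str  # "true" or "faux"
    v: np.ndarray
    Q: np.ndarray
    K: np.ndarray
    sheets: np.ndarray  # -1 / 0 / +1 per sample


def singular_canard(
    singularity: FoldedSingularity,
    params: MeanFieldParams,
    delta_ev: float = 1e-4,
    t_max: float = 5.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> dict[str, CanardSegment]:
    """True and faux singular canards through a folded saddle.

    Integrates the DRS forward and backward from the saddle displaced by
    +-delta_ev along each eigenvector and stitches the branches that cross
    between sheets.  The *true* canard is the orbit passing from an
    attracting sheet to the repelling (middle) sheet in the reduced flow's
    own time; because the DRS reverses time on the repelling sheet, it is
    the DRS *stable* eigendirection that carries the true canard.

    Raises ValueError for a folded centre (no canards exist there).
    """
    if singularity.classification != "folded-saddle":
        raise ValueError("no canards at a folded centre")
    eta_bar = singularity.eta_bar
    man = CriticalManifold(params)
    v_star = singularity.fold.v_star
    lam = math.sqrt(singularity.lambda_sq)

    def rhs(t, y):
        dv, dQ = drs_flow(y[0], y[1], params, eta_bar)
        return [float(dv), float(dQ)]

    v_dom_hi = man.v_max - 1e-9

    def run(y0, sign):
        stop = lambda t, y: y[0] - v_dom_hi
        stop.terminal = True
        sol = solve_ivp(
            rhs,
            (0.0, sign * t_max),
            y0,
            rtol=rtol,
            atol=atol,
            events=stop,
            max_step=t_max / 50.0,
        )
        return sol.t, sol.y

    segments: dict[str, CanardSegment] = {}
    # Eigenvectors of [[0,1],[a,0]]: (1, +-sqrt(a)).  Unstable: +lam.
    for kind, slope in (("faux", lam), ("true", -lam)):
        vs_parts, qs_parts = [], []
        for disp in (-1.0, 1.0):
            y0 = np.array([v_star + disp * delta_ev, disp * delta_ev * slope])
            # grow outwards: along the unstable direction forward in time,
            # along the stable one backward.
            sign = 1.0 if kind == "faux" else -1.0
            t, y = run(y0, sign)
            vs_parts.append(y[0])
            qs_parts.append(y[1])
        v_all = np.concatenate([vs_parts[0][::-1], [v_star], vs_parts[1]])
        q_all = np.concatenate([qs_parts[0][::-1], [0.0], qs_parts[1]])
        segments[kind] = CanardSegment(
            kind, v_all, q_all, -np.asarray(man.psi(v_all)), man.sheet(v_all)
        )
    return segments


def region_classify(eta_bar: float, params: MeanFieldParams) -> RegionLabel:
    """Locate eta_bar among the four routes-to-bursting regions.

    Boundary ties report the higher-index region with a warning (so the
    classification is deterministic).  Raises if the manifold has no folds.
    """
    folds = find_folds(params)
    if not folds:
        raise ValueError("no bursting-route regions without folds")
    eta_p, eta_m = folds[0].eta_fold, folds[1].eta_fold
    eta_0 = 0.5 * (eta_p + eta_m)
    bounds = (eta_p, eta_0, eta_m)
    for b in bounds:
        if eta_bar == b:
            warnings.warn(
                f"eta_bar={eta_bar} sits exactly on a region boundary; "
                "reporting the higher-index region",
                stacklevel=2,
            )
    if eta_bar < eta_p:
        return RegionLabel("I", bounds)
    if eta_bar < eta_0:
        return RegionLabel("II", bounds)
    if eta_bar < eta_m:
        return RegionLabel("III", bounds)
    return RegionLabel("IV", bounds)


# ---------------------------------------------------------------------------
# p populations
# ---------------------------------------------------------------------------


class MultiPopManifold:
    """Critical manifold of the p-population mean field.

    The constraints are Psi_i(v_1..v_p) + K delta_ik = 0 with

        Psi_i = v_i^2 - pi^2 r_i(v_i)^2 + eta_i + sum_j Jt_ij r_j(v_j),

    where r_i(v) = -(Delta_i/pi)/(2v + Gamma_tilde_i), eta_i = eta_bar_i
    for unforced populations and 0 for the forced one (its baseline is
    carried by K).  Given the forced population's voltage v_k, the p-1
    unforced constraints are solved numerically for the other voltages and
    K = -Psi_k closes the system, parametrising S0 by v_k exactly as the
    single-population manifold is parametrised by v.
    """

    def __init__(self, params: MultiPopParams):
        self.params = params
        self.k = params.forced_index
        self._J = np.asarray(params.coupling, dtype=float)

    def _rate(self, i: int, v: float) -> float:
        p = self.params.populations[i]
        return equilibrium_rate(v, p.delta, p.gamma_tilde)

    def psi_i(self, i: int, vs: Sequence[float]) -> float:
        """Constraint value Psi_i at voltages vs (length p)."""
        p = self.params.populations[i]
        r_i = self._rate(i, vs[i])
        eta = 0.0 if i == self.k else p.eta_bar
        syn = sum(
            self._J[i, j] * self._rate(j, vs[j])
            for j in range(self.params.n_pop)
        )
        return vs[i] ** 2 - math.pi**2 * r_i**2 + eta + syn

    def solve(
        self,
        v_k: float,
        bracket: tuple[float, float] = (-60.0, -1e-6),
        x0: Sequence[float] | None = None,
    ) -> tuple[np.ndarray, float]:
        """Full equilibrium (v_1..v_p, K) given the forced voltage v_k.

        For a single unforced population the constraint is solved by
        bracketed root finding on ``bracket``; for more, by a damped
        Newton iteration (scipy.optimize.root) started from ``x0`` or the
        bracket midpoint.  Raises if no root lies in the bracket.
        """
        p = self.params.n_pop
        others = [i for i in range(p) if i != self.k]
        vs = np.empty(p)
        vs[self.k] = v_k
        if others:
            if len(others) == 1:
                i = others[0]

                def g(x):
                    vv = vs.copy()
                    vv[i] = x
                    return self.psi_i(i, vv)

                a, b = bracket
                fa, fb = g(a), g(b)
                if fa * fb > 0:
                    raise ValueError(
                        f"no root of Psi_{i} in bracket {bracket}: "
                        f"g({a})={fa:.3g}, g({b})={fb:.3g}"
                    )
                vs[i] = brentq(g, a, b, xtol=1e-12)
            else:

                def G(x):
                    vv = vs.copy()
                    vv[others] = x
                    return [self.psi_i(i, vv) for i in others]

                start = (
                    np.asarray(x0, dtype=float)
                    if x0 is not None
                    else np.full(len(others), 0.5 * (bracket[0] + bracket[1]))
                )
                res = root(G, start, tol=1e-12)
                if not res.success:
                    raise ValueError(
                        f"unforced constraints did not converge in bracket "
                        f"{bracket}: {res.message}"
                    )
                vs[others] = res.x
        K = -self.psi_i(self.k, vs)
        return vs, float(K)

    def fold_condition(self, v_k: float, h: float = 1e-6, **kw) -> float:
        """Total derivative d(Psi_k)/d(v_k) along the solved family.

        Central finite difference with relative step ``h``; the sign
        convention mirrors the single-population psi' (the fold set is its
        zero set), since K(v_k) = -Psi_k(v_k) on the manifold.
        """
        step = h * max(1.0, abs(v_k))
        _, K_plus = self.solve(v_k + step, **kw)
        _, K_minus = self.solve(v_k - step, **kw)
        # K = -Psi_k, so dPsi_k/dv_k = -(dK/dv_k)
        return float(-(K_plus - K_minus) / (2.0 * step))
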