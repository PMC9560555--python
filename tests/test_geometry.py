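"""Critical manifold, folds, folded singularities, canards and regions."""

import math

import numpy as np
import pytest

from qifex.geometry import (
    CriticalManifold,
    MultiPopManifold,
    classify_folded_singularity,
    drs_flow,
    equilibrium_rate,
    find_folds,
    region_classify,
    singular_canard,
)
from qifex.params import MeanFieldParams, MultiPopParams


class TestEquilibriumRate:
    @pytest.mark.parametrize(
        "v,delta,gt,expect",
        [
            (-1.0 / (2 * math.pi), 1.0, 0.0, 1.0),
            (-1.0, 1.0, 0.0, 1.0 / (2 * math.pi)),
            (-1.5, 1.0, 2.0, 1.0 / math.pi),
        ],
    )
    def test_closed_form(self, v, delta, gt, expect):
        assert equilibrium_rate(v, delta, gt) == pytest.approx(expect, rel=1e-12)

    def test_singular_line_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_rate(0.0, 1.0, 0.0)


class TestPsi:
    def test_heterogeneity_off_gives_parabola(self):
        man = CriticalManifold(MeanFieldParams(delta=0.0, j_syn=7.0, tau_s=1.0))
        assert float(man.psi(-2.0)) == pytest.approx(4.0)

    def test_closed_form_value(self):
        man = CriticalManifold(MeanFieldParams(delta=1.0, j_syn=15.0, tau_s=1.0))
        # v=-1: 1 - 1/4 + 15/(2 pi)
        assert float(man.psi(-1.0)) == pytest.approx(0.75 + 15.0 / (2 * math.pi), rel=1e-12)

    def test_derivatives_match_finite_differences(self):
        man = CriticalManifold(MeanFieldParams(delta=1.0, j_syn=15.0, tau_s=1.0))
        vs = np.linspace(-3.0, -0.1, 100)
        h = 1e-6
        fd1 = (np.asarray(man.psi(vs + h)) - np.asarray(man.psi(vs - h))) / (2 * h)
        np.testing.assert_allclose(np.asarray(man.psi_prime(vs)), fd1, atol=1e-5)
        h2 = 1e-4  # larger step: the 2nd difference amplifies roundoff by h^-2
        fd2 = (
            np.asarray(man.psi(vs + h2))
            - 2 * np.asarray(man.psi(vs))
            + np.asarray(man.psi(vs - h2))
        ) / h2**2
        np.testing.assert_allclose(
            np.asarray(man.psi_second(vs)), fd2, rtol=1e-5, atol=1e-3
        )

    def test_domain_error(self):
        man = CriticalManifold(MeanFieldParams(delta=1.0, j_syn=15.0, tau_s=1.0))
        with pytest.raises(ValueError):
            man.psi(0.5)


class TestFolds:
    def test_standard_set_has_two_ordered_folds(self):
        folds = find_folds(MeanFieldParams(delta=1.0, j_syn=15.0, tau_s=1.0))
        assert [f.label for f in folds] == ["F+", "F-"]
        fp, fm = folds
        assert fp.eta_fold < fm.eta_fold < 0.0
        # brute-force verified locations
        assert fp.v_star == pytest.approx(-0.2111, abs=2e-4)
        assert fm.v_star == pytest.approx(-0.9790, abs=2e-4)

    def test_uncoupled_manifold_has_no_folds(self):
        assert find_folds(MeanFieldParams(delta=1.0, j_syn=0.0, tau_s=1.0)) == []

    def test_folds_are_roots_of_psi_prime(self):
        p = MeanFieldParams(delta=1.0, j_syn=15.0, tau_s=1.0)
        man = CriticalManifold(p)
        for f in man.folds():
            assert abs(float(man.psi_prime(f.v_star))) < 1e-9

    @pytest.mark.parametrize("j_syn", [0.0, 2.0, 5.0, 10.0, 15.0, 40.0])
    @pytest.mark.parametrize("delta", [0.3, 1.0, 2.5])
    def test_fold_count_is_zero_or_two(self, j_syn, delta):
        folds = find_folds(MeanFieldParams(delta=delta, j_syn=j_syn, tau_s=1.0))
        assert len(folds) in (0, 2)


@pytest.fixture(scope="module")
def folded_setup():
    p = MeanFieldParams(delta=1.0, j_syn=15.0, tau_s=1.0)
    return p, find_folds(p)


class TestFoldedSingularities:

    def test_bistable_centre_gives_two_folded_saddles(self, folded_setup):
        p, folds = folded_setup
        kinds = {
            f.label: classify_folded_singularity(f, -5.0, p).classification
            for f in folds
        }
        assert kinds == {"F+": "folded-saddle", "F-": "folded-saddle"}

    def test_tonic_centre_gives_saddle_and_centre(self, folded_setup):
        p, folds = folded_setup
        kinds = {
            f.label: classify_folded_singularity(f, 5.0, p).classification
            for f in folds
        }
        assert kinds == {"F+": "folded-saddle", "F-": "folded-centre"}

    def test_degenerate_exactly_on_fold_value(self, folded_setup):
        p, folds = folded_setup
        c = classify_folded_singularity(folds[0], folds[0].eta_fold, p)
        assert c.classification == "degenerate"
        assert c.lambda_sq == pytest.approx(0.0, abs=1e-12)

    def test_classification_flips_at_fold_value(self, folded_setup):
        """Sweeping eta_bar through eta_f flips saddle <-> centre within 1e-6."""
        p, folds = folded_setup
        for f in folds:
            below = classify_folded_singularity(f, f.eta_fold - 1e-6, p)
            above = classify_folded_singularity(f, f.eta_fold + 1e-6, p)
            assert {below.classification, above.classification} == {
                "folded-saddle",
                "folded-centre",
            }

    def test_eigenvalues_are_plus_minus_sqrt(self, folded_setup):
        p, folds = folded_setup
        c = classify_folded_singularity(folds[0], -5.0, p)
        lam = c.eigenvalues
        assert lam[0] == -lam[1]
        assert (lam[0] ** 2).real == pytest.approx(c.lambda_sq)


class TestDRS:
    def test_fold_point_is_equilibrium(self):
        p = MeanFieldParams(delta=1.0, j_syn=15.0, tau_s=1.0)
        for f in find_folds(p):
            dv, dQ = drs_flow(f.v_star, 0.0, p, -5.0)
            assert float(dv) == 0.0
            assert float(dQ) == pytest.approx(0.0, abs=1e-8)

    def test_jacobian_structure_zero_trace(self):
        """Numerical Jacobian of the DRS at the singularity is [[0,1],[a,0]]."""
        p = MeanFieldParams(delta=1.0, j_syn=15.0, tau_s=1.0)
        f = find_folds(p)[1]
        eta_bar = -15.1
        a = classify_folded_singularity(f, eta_bar, p).lambda_sq
        h = 1e-7
        J = np.zeros((2, 2))
        for j, dy in enumerate(np.eye(2) * h):
            plus = np.array(drs_flow(f.v_star + dy[0], 0.0 + dy[1], p, eta_bar), dtype=float)
            minus = np.array(drs_flow(f.v_star - dy[0], 0.0 - dy[1], p, eta_bar), dtype=float)
            J[:, j] = (plus - minus) / (2 * h)
        assert J[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert J[1, 1] == pytest.approx(0.0, abs=1e-6)
        assert J[0, 1] == pytest.approx(1.0)
        assert J[1, 0] == pytest.approx(a, rel=1e-4)

    def test_true_canard_crosses_onto_repelling_sheet(self):
        """The singular canard through the F- saddle straddles the fold,
        passing from the lower attracting sheet to the repelling one."""
        p = MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-15.1, tau_s=1.0)
        f = find_folds(p)[1]
        sing = classify_folded_singularity(f, p.eta_bar, p)
        assert sing.classification == "folded-saddle"
        segs = singular_canard(sing, p)
        true = segs["true"]
        assert true.v.min() < f.v_star < true.v.max()
        assert (true.sheets == 0).any() and (true.sheets == -1).any()

    def test_canard_orbit_stable_under_smaller_displacement(self):
        p = MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-15.1, tau_s=1.0)
        f = find_folds(p)[1]
        sing = classify_folded_singularity(f, p.eta_bar, p)
        a = singular_canard(sing, p, delta_ev=1e-4, t_max=1.0)["true"]
        b = singular_canard(sing, p, delta_ev=5e-5, t_max=1.0)["true"]
        # compare Q at shared v values on the repelling side
        vs = np.linspace(f.v_star + 0.05, min(a.v.max(), b.v.max()) - 0.01, 10)
        qa = np.interp(vs, a.v, a.Q)
        qb = np.interp(vs, b.v, b.Q)
        np.testing.assert_allclose(qa, qb, rtol=1e-2, atol=1e-3)

    def test_folded_centre_has_no_canards(self):
        p = MeanFieldParams(delta=1.0, j_syn=15.0, tau_s=1.0)
        f = find_folds(p)[1]
        centre = classify_folded_singularity(f, 5.0, p)
        with pytest.raises(ValueError):
            singular_canard(centre, p)


class TestRegions:
    @pytest.mark.parametrize(
        "eta_bar,region",
        [(-6.5, "I"), (-5.0, "II"), (-3.5, "III"), (-2.0, "IV")],
    )
    def test_reference_values(self, eta_bar, region):
        p = MeanFieldParams(delta=1.0, j_syn=15.0, tau_s=1.0)
        assert region_classify(eta_bar, p).value == region

    def test_boundary_tie_reports_higher_region_with_warning(self):
        p = MeanFieldParams(delta=1.0, j_syn=15.0, tau_s=1.0)
        eta_0 = region_classify(-5.0, p).boundaries[1]
        with pytest.warns(UserWarning):
            lab = region_classify(eta_0, p)
        assert lab.value == "III"

    def test_unfolded_manifold_rejected(self):
        with pytest.raises(ValueError):
            region_classify(-1.0, MeanFieldParams(delta=1.0, j_syn=0.0, tau_s=1.0))


class TestMultiPopManifold:
    def test_single_population_matches_psi(self):
        p = MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-15.1, tau_s=0.02)
        mp = MultiPopParams(populations=(p,), coupling=((p.j_tilde,),))
        mm = MultiPopManifold(mp)
        man = CriticalManifold(p)
        for v in np.linspace(-4.0, -0.1, 25):
            vs, K = mm.solve(v)
            assert K == pytest.approx(-float(man.psi(v)), abs=1e-10)

    def test_decoupled_pair_forced_population_keeps_its_folds(self):
        p = MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-15.1, tau_s=0.02)
        q = MeanFieldParams(delta=0.5, j_syn=4.0, eta_bar=-2.0, tau_s=0.02)
        mp = MultiPopParams(
            populations=(p, q),
            coupling=((p.j_tilde, 0.0), (0.0, q.j_tilde)),
            forced_index=0,
        )
        mm = MultiPopManifold(mp)
        man = CriticalManifold(p)
        folds = man.folds()
        for f in folds:
            # K(v) = -psi(v) along the solved family, so the fold condition
            # vanishes exactly where psi' does
            assert mm.fold_condition(f.v_star) == pytest.approx(0.0, abs=1e-4)
        vs, K = mm.solve(folds[0].v_star)
        assert K == pytest.approx(folds[0].eta_fold, abs=1e-8)

    def test_symmetric_pair_has_symmetric_solution(self):
        p = MeanFieldParams(delta=1.0, j_syn=10.0, eta_bar=-6.0, tau_s=0.02)
        mp = MultiPopParams(
            populations=(p, p),
            coupling=((3.0, 3.0), (3.0, 3.0)),
            forced_index=0,
        )
        mm = MultiPopManifold(mp)
        # at v_k chosen as the unforced population's self-consistent root the
        # solution is exchange-symmetric: plugging v1 = v2 satisfies both
        from scipy.optimize import brentq

        g = lambda v: mm.psi_i(1, (v, v))
        v_sym = brentq(g, -10.0, -0.2)
        vs, K = mm.solve(v_sym, bracket=(-10.0, -0.2))
        assert vs[1] == pytest.approx(v_sym, abs=1e-9)

    def test_missing_root_reports_bracket(self):
        p = MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-15.1, tau_s=0.02)
        q = MeanFieldParams(delta=1.0, j_syn=1.0, eta_bar=50.0, tau_s=0.02)
        mp = MultiPopParams(
            populations=(p, q), coupling=((0.0, 0.0), (0.0, 0.0)), forced_index=0
        )
        mm = MultiPopManifold(mp)
        with pytest.raises(ValueError, match="bracket"):
            mm.solve(-1.0, bracket=(-5.0, -0.5))
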