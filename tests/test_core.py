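"""Divergence entropy, RD, the M profile, the K scan and fragment status."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fodm.core import (
    KGrid,
    UndefinedRDError,
    analyze_unit,
    fragment_status,
    kl_divergence,
    m_profile,
    optimize_k,
    rd,
    rd_kopt,
)
from fodm.hydro_field import (
    HydroProfile,
    fit_gaussian,
    theoretical_profile,
    uniform_profile,
)

from conftest import make_atoms


def profile(values, role="O"):
    values = np.asarray(values, dtype=float)
    return HydroProfile(role, values / values.sum(), list(range(len(values))))


positive_profiles = st.lists(
    st.floats(min_value=1e-3, max_value=1.0), min_size=2, max_size=30
)


class TestKLDivergence:
    def test_identity_is_zero(self):
        P = profile([0.2, 0.3, 0.5])
        assert kl_divergence(P, P) == 0.0

    def test_two_term_closed_form(self):
        """P=(1/2,1/2) vs Q=(1/4,3/4): analytically 1 - log2(3)/2 bits."""
        val = kl_divergence(profile([0.5, 0.5]), profile([0.25, 0.75], "T"))
        assert val == pytest.approx(1.0 - 0.5 * math.log2(3.0), abs=1e-12)

    def test_point_mass_against_fair_coin(self):
        P = HydroProfile("O", np.array([1.0, 0.0]), [0, 1])
        assert kl_divergence(P, profile([0.5, 0.5], "T")) == \
            pytest.approx(1.0, abs=1e-12)

    def test_zero_q_on_support_raises(self):
        P = profile([0.5, 0.5])
        Q = HydroProfile("T", np.array([1.0, 0.0]), [0, 1])
        with pytest.raises(ValueError, match="infinite"):
            kl_divergence(P, Q)

    @settings(deadline=None, max_examples=100)
    @given(positive_profiles, st.data())
    def test_gibbs_inequality(self, raw, data):
        """D_KL >= 0, equal to 0 iff the distributions coincide."""
        P = profile(raw)
        other = data.draw(st.lists(
            st.floats(min_value=1e-3, max_value=1.0),
            min_size=len(raw), max_size=len(raw)))
        Q = profile(other, "T")
        d = kl_divergence(P, Q)
        assert d >= 0.0
        if np.allclose(P.values, Q.values, rtol=0, atol=1e-15):
            assert d == pytest.approx(0.0, abs=1e-12)
        elif not np.allclose(P.values, Q.values, rtol=0, atol=1e-9):
            assert d > 0.0


class TestRD:
    def test_o_equals_t(self):
        T = profile([0.5, 0.3, 0.2], "T")
        O = profile([0.5, 0.3, 0.2], "O")
        R = uniform_profile(3)
        assert rd(O, T, R) == 0.0

    def test_o_equals_r(self):
        T = profile([0.5, 0.3, 0.2], "T")
        R = uniform_profile(3)
        O = profile([1.0, 1.0, 1.0], "O")
        assert rd(O, T, R) == 1.0

    def test_matches_ratio_of_divergences(self, rng):
        O = profile(rng.uniform(0.1, 1, 10), "O")
        T = profile(rng.uniform(0.1, 1, 10), "T")
        R = uniform_profile(10)
        expected = kl_divergence(O, T) / (
            kl_divergence(O, T) + kl_divergence(O, R))
        assert rd(O, T, R) == pytest.approx(expected, rel=1e-12)

    def test_base_invariance(self, rng):
        """Bits or nats: both divergences rescale, the ratio does not."""
        O = profile(rng.uniform(0.1, 1, 15), "O")
        T = profile(rng.uniform(0.1, 1, 15), "T")
        R = uniform_profile(15)
        assert rd(O, T, R, base=2.0) == pytest.approx(
            rd(O, T, R, base=math.e), rel=1e-12)

    def test_undefined_when_all_equal(self):
        U = uniform_profile(4)
        O = profile([1, 1, 1, 1], "O")
        T = profile([1, 1, 1, 1], "T")
        with pytest.raises(UndefinedRDError):
            rd(O, T, U)


class TestMProfile:
    def test_k_zero_reproduces_t(self, rng):
        T = profile(rng.uniform(0.1, 1, 12), "T")
        M = m_profile(T, 0.0)
        np.testing.assert_allclose(M.values, T.values, atol=1e-15)

    def test_large_k_inverts_the_maximum(self, rng):
        """Strong environment: the T maximum becomes the M minimum."""
        T = profile(rng.uniform(0.1, 1, 12), "T")
        M = m_profile(T, 50.0)
        assert np.argmin(M.values) == np.argmax(T.values)

    def test_flat_t_degenerates_to_t(self):
        T = profile([1, 1, 1, 1], "T")
        M = m_profile(T, 2.0)
        np.testing.assert_allclose(M.values, T.values, atol=1e-15)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            m_profile(profile([1, 2, 3], "T"), -0.1)

    def test_manual_three_residue_construction(self):
        """Hand-computed M for T=(0.5,0.3,0.2), K=1."""
        T = profile([0.5, 0.3, 0.2], "T")
        # complement (0, .2, .3), inner-normalised (0, .4, .6)
        # M_raw = (.5, .7, .8), sum 2 -> (.25, .35, .40)
        M = m_profile(T, 1.0)
        np.testing.assert_allclose(M.values, [0.25, 0.35, 0.40], atol=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(positive_profiles,
           st.floats(min_value=0.0, max_value=5.0))
    def test_sums_to_one(self, raw, K):
        M = m_profile(profile(raw, "T"), K)
        assert abs(M.values.sum() - 1.0) <= 1e-9

    def test_continuity_in_k(self, rng):
        T = profile(rng.uniform(0.1, 1, 20), "T")
        deltas = [np.abs(m_profile(T, k + 1e-4).values
                         - m_profile(T, k).values).sum()
                  for k in (0.0, 0.5, 1.7, 4.0)]
        assert max(deltas) < 1e-3


class TestOptimizeK:
    def test_o_equals_t_gives_zero(self, rng):
        T = profile(rng.uniform(0.1, 1, 10), "T")
        O = HydroProfile("O", T.values.copy(), list(T.residue_ids))
        k_opt, curve = optimize_k(O, T)
        assert k_opt == 0.0
        assert curve.dkl_values[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k_star", [0.5, 1.5, 2.5, 4.0])
    def test_self_consistency_recovers_k(self, rng, k_star):
        """O manufactured as M(K*) puts the scan minimum at K* exactly."""
        T = profile(rng.uniform(0.05, 1, 25), "T")
        O = HydroProfile("O", m_profile(T, k_star).values,
                         list(T.residue_ids))
        k_opt, curve = optimize_k(O, T)
        assert k_opt == pytest.approx(k_star, abs=1e-9)
        assert curve.dkl_values.min() == pytest.approx(0.0, abs=1e-12)

    def test_equals_brute_force_grid_minimum(self, rng):
        O = profile(rng.uniform(0.1, 1, 15), "O")
        T = profile(rng.uniform(0.1, 1, 15), "T")
        grid = KGrid(0.0, 3.0, 0.1)
        k_opt, curve = optimize_k(O, T, grid)
        brute = {float(k): kl_divergence(O, m_profile(T, float(k)))
                 for k in grid.points()}
        best = min(brute, key=lambda k: (brute[k], k))
        assert k_opt == best
        np.testing.assert_allclose(curve.dkl_values,
                                   [brute[float(k)] for k in grid.points()],
                                   atol=1e-12)

    def test_tie_breaks_toward_smallest_k(self):
        """A flat T makes every M(K) identical: the tie resolves to K=0."""
        T = profile([1, 1, 1, 1], "T")
        O = profile([2, 1, 1, 1], "O")
        k_opt, _ = optimize_k(O, T)
        assert k_opt == 0.0

    def test_grid_points_are_exact_multiples(self):
        pts = KGrid(0.0, 5.0, 0.1).points()
        assert len(pts) == 51
        assert 2.5 in pts and 0.1 in pts


class TestRDKopt:
    def test_o_equals_t(self, rng):
        T = profile(rng.uniform(0.1, 1, 8), "T")
        O = HydroProfile("O", T.values.copy(), list(T.residue_ids))
        M = m_profile(T, 1.0)
        assert rd_kopt(O, T, M) == 0.0

    def test_half_when_m_opt_is_t(self, rng):
        """K_opt = 0 makes M_opt = T, so the ratio is exactly 1/2."""
        O = profile(rng.uniform(0.1, 1, 8), "O")
        T = profile(rng.uniform(0.1, 1, 8), "T")
        M = m_profile(T, 0.0)
        assert rd_kopt(O, T, M) == pytest.approx(0.5, rel=1e-12)

    def test_matches_divergence_composition(self, rng):
        O = profile(rng.uniform(0.1, 1, 12), "O")
        T = profile(rng.uniform(0.1, 1, 12), "T")
        M = m_profile(T, 1.3)
        expected = kl_divergence(O, T) / (
            kl_divergence(O, T) + kl_divergence(O, M))
        assert rd_kopt(O, T, M) == pytest.approx(expected, rel=1e-12)


class TestFragmentStatus:
    @pytest.fixture
    def unit(self, rng):
        pts = rng.normal(size=(40, 3)) * [7, 5, 4]
        atoms = make_atoms(pts)
        h = rng.uniform(0.05, 1.0, size=40)
        return atoms, fit_gaussian(atoms), h

    def test_whole_unit_fragment_equals_unit_result(self, unit):
        atoms, fld, h = unit
        whole, _, _ = analyze_unit(atoms, fld, hydrophobicity=h)
        frag = fragment_status(atoms, fld, hydrophobicity=h,
                               fragment=(1, 40))
        assert frag.rd == pytest.approx(whole.rd, rel=1e-12)
        assert frag.k_opt == whole.k_opt
        assert frag.rd_kopt == pytest.approx(whole.rd_kopt, rel=1e-12)

    def test_fragment_rd_zero_when_o_matches_t(self, rng):
        """If O is proportional to T on the fragment, fragment RD = 0."""
        pts = rng.normal(size=(30, 3)) * [6, 5, 4]
        atoms = make_atoms(pts)
        fld = fit_gaussian(atoms)
        T = theoretical_profile(fld, atoms)
        # restriction of an O proportional to T stays proportional on the
        # fragment after renormalisation, hence fragment RD = 0

        mask = np.array([5 <= rid.number <= 20
                         for rid in atoms.residue_ids])
        t_frag = T.values[mask] / T.values[mask].sum()
        O = HydroProfile("O", t_frag, [r for r, m in
                                       zip(atoms.residue_ids, mask) if m])
        Tf = HydroProfile("T", t_frag.copy(), list(O.residue_ids))
        R = uniform_profile(Tf.n, list(O.residue_ids))
        assert rd(O, Tf, R) == 0.0

    def test_uses_fragment_local_t_max(self, unit):
        """The complement in M must vanish at the fragment's own T peak."""
        atoms, fld, h = unit
        t_raw = fld.density(atoms.positions)
        mask = np.array([10 <= rid.number <= 25
                         for rid in atoms.residue_ids])
        t_frag = t_raw[mask] / t_raw[mask].sum()
        T = HydroProfile("T", t_frag,
                         [r for r, m in zip(atoms.residue_ids, mask) if m])
        M = m_profile(T, 1.0, t_max=float(t_frag.max()))
        # at the fragment-local maximum the inverted term contributes 0
        peak = int(np.argmax(t_frag))
        raw_peak = t_frag[peak]  # + 1.0 * 0
        comp = t_frag.max() - t_frag
        m_raw = t_frag + comp / comp.sum()
        assert M.values[peak] == pytest.approx(raw_peak / m_raw.sum(),
                                               rel=1e-12)

    def test_too_small_fragment_rejected(self, unit):
        atoms, fld, h = unit
        with pytest.raises(ValueError, match="need >= 2"):
            fragment_status(atoms, fld, hydrophobicity=h, fragment=(3, 3))

    def test_terminal_fragment_runs(self, unit):
        atoms, fld, h = unit
        res = fragment_status(atoms, fld, hydrophobicity=h,
                              fragment=(30, 40))
        assert 0.0 <= res.rd <= 1.0
        assert res.n_residues == 11
        assert res.fragment_label == "30-40"
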