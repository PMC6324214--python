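"""Regulatory kernels: shifted Hill, microRNA silencing, splicing partition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emtcircuits.kinetics import (
    ConfigurationError,
    HillRegulation,
    KineticParameterSet,
    MicroRNASilencing,
    mirna_bound_fraction,
    mirna_modulation,
    shifted_hill,
    splicing_partition,
)

finite_levels = st.floats(min_value=0.0, max_value=1e9)
thresholds = st.floats(min_value=1e-3, max_value=1e7)
coefficients = st.integers(min_value=1, max_value=8)
folds = st.floats(min_value=1e-3, max_value=1e3)


class TestShiftedHill:
    def test_basal_midpoint_saturation(self):
        reg = HillRegulation(threshold=100.0, coefficient=4, fold_change=3.0)
        assert shifted_hill(0.0, reg) == 1.0
        assert shifted_hill(100.0, reg) == pytest.approx(2.0)  # (1+lam)/2
        reg = HillRegulation(threshold=50.0, coefficient=2, fold_change=0.1)
        assert shifted_hill(1e12, reg) == pytest.approx(0.1)

    def test_domain_errors(self):
        reg = HillRegulation(100.0, 2, 2.0)
        with pytest.raises(ValueError):
            shifted_hill(-1.0, reg)
        with pytest.raises(ConfigurationError):
            HillRegulation(threshold=-5.0, coefficient=2, fold_change=2.0)

    @given(X=finite_levels, X0=thresholds, n=coefficients, lam=folds)
    @settings(deadline=None, max_examples=200)
    def test_bounded_between_one_and_fold(self, X, X0, n, lam):
        h = float(shifted_hill(X, HillRegulation(X0, n, lam)))
        assert min(1.0, lam) - 1e-12 <= h <= max(1.0, lam) + 1e-12

    @given(X0=thresholds, n=coefficients, lam=folds,
           r=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=200)
    def test_reciprocal_fold_and_input_inversion_symmetry(self, X0, n, lam, r):
        """H(X0/r; lam) == lam * H(X0*r; 1/lam): swapping lam -> 1/lam while
        inverting the input about the threshold is an exact symmetry."""
        lhs = float(shifted_hill(X0 / r, HillRegulation(X0, n, lam)))
        rhs = lam * float(shifted_hill(X0 * r, HillRegulation(X0, n, 1.0 / lam)))
        assert lhs == pytest.approx(rhs, rel=1e-9)

    @given(X0=thresholds, n=coefficients, lam=folds)
    @settings(deadline=None, max_examples=100)
    def test_monotone(self, X0, n, lam):
        reg = HillRegulation(X0, n, lam)
        xs = np.geomspace(1e-3 * X0, 1e3 * X0, 64)
        hs = shifted_hill(xs, reg)
        diffs = np.diff(hs)
        assert np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12)


def _silencing(n_sites=6, mu0=10_000.0):
    l = (1.0, 0.6, 0.3, 0.1, 0.05, 0.05, 0.05)[: n_sites + 1]
    gm = (0.0, 0.04, 0.2, 1.0, 1.0, 1.0, 1.0)[: n_sites + 1]
    gu = (0.0, 0.005, 0.05, 0.5, 0.5, 0.5, 0.5)[: n_sites + 1]
    return MicroRNASilencing(mu0=mu0, n_sites=n_sites, l=l, gamma_m=gm, gamma_mu=gu)


class TestMicroRNASilencing:
    def test_nothing_bound_at_zero(self):
        M = mirna_bound_fraction(0.0, _silencing())
        assert M[0] == 1.0 and np.all(M[1:] == 0.0)

    def test_binomial_at_threshold_two_sites(self):
        sil = MicroRNASilencing(mu0=100.0, n_sites=2, l=(1.0, 0.5, 0.2),
                                gamma_m=(0.0, 0.1, 0.2), gamma_mu=(0.0, 0.1, 0.2))
        M = mirna_bound_fraction(100.0, sil)
        assert M == pytest.approx([0.25, 0.5, 0.25])

    @given(mu=finite_levels, mu0=st.floats(min_value=1.0, max_value=1e6),
           n=st.integers(min_value=1, max_value=6))
    @settings(deadline=None, max_examples=200)
    def test_occupancies_normalized(self, mu, mu0, n):
        sil = _silencing(n_sites=n, mu0=mu0)
        M = mirna_bound_fraction(mu, sil)
        assert np.all(M >= 0)
        assert float(M.sum()) == pytest.approx(1.0, abs=1e-12)

    def test_modulation_at_zero(self):
        L, Ym, Ymu = mirna_modulation(0.0, _silencing())
        assert (L, Ym, Ymu) == (1.0, 0.0, 0.0)

    def test_silencing_disabled(self):
        sil = MicroRNASilencing(mu0=50.0, n_sites=3, l=(1.0, 1.0, 1.0, 1.0),
                                gamma_m=(0.0,) * 4, gamma_mu=(0.0,) * 4)
        for mu in (0.0, 10.0, 50.0, 1e6):
            L, Ym, _ = mirna_modulation(mu, sil)
            assert L == pytest.approx(1.0) and Ym == 0.0

    def test_modulation_matches_term_by_term_sums_at_threshold(self):
        """Direct python-float summation over occupancies reproduces L/Ym/Ymu."""
        sil = _silencing()
        mu = sil.mu0
        p = mu / (sil.mu0 + mu)
        M = [math.comb(6, i) * p**i * (1 - p) ** (6 - i) for i in range(7)]
        L_ref = sum(li * Mi for li, Mi in zip(sil.l, M))
        Ym_ref = sum(gi * Mi for gi, Mi in zip(sil.gamma_m, M))
        Ymu_ref = sum(i * gi * Mi for i, (gi, Mi) in enumerate(zip(sil.gamma_mu, M)))
        L, Ym, Ymu = mirna_modulation(mu, sil)
        assert L == pytest.approx(L_ref, rel=1e-12)
        assert Ym == pytest.approx(Ym_ref, rel=1e-12)
        assert Ymu == pytest.approx(Ymu_ref, rel=1e-12)

    def test_monotone_in_mirna(self):
        sil = _silencing()
        mus = np.geomspace(1.0, 1e6, 50)
        L, Ym, Ymu = mirna_modulation(mus, sil)
        assert np.all(np.diff(L) <= 1e-12)
        assert np.all(np.diff(Ym) >= -1e-12)
        assert np.all(np.diff(Ymu) >= -1e-12)

    def test_shape_constraints_enforced(self):
        with pytest.raises(ConfigurationError):
            MicroRNASilencing(mu0=10.0, n_sites=2, l=(0.9, 0.5, 0.2),
                              gamma_m=(0.0, 0.1, 0.2), gamma_mu=(0.0, 0.1, 0.2))
        with pytest.raises(ConfigurationError):
            MicroRNASilencing(mu0=10.0, n_sites=2, l=(1.0, 0.5),
                              gamma_m=(0.0, 0.1, 0.2), gamma_mu=(0.0, 0.1, 0.2))


class TestSplicing:
    @given(E1=finite_levels, g_C=st.floats(min_value=1e-3, max_value=1e4),
           X0=thresholds, n=coefficients)
    @settings(deadline=None, max_examples=200)
    def test_total_production_conserved(self, E1, g_C, X0, n):
        rs, rv = splicing_partition(E1, g_C, X0, n)
        assert rs >= 0 and rv >= 0
        assert float(rs + rv) == pytest.approx(g_C, rel=1e-12)

    def test_limits_and_midpoint(self):
        rs, rv = splicing_partition(0.0, 90.0, 60.0, 2)
        assert rv == 0.0 and rs == pytest.approx(90.0)  # no ESRP1: all CD44s
        rs, rv = splicing_partition(60.0, 90.0, 60.0, 2)
        assert rs == pytest.approx(45.0) and rv == pytest.approx(45.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            splicing_partition(-1.0, 90.0, 60.0, 2)


class TestParameterFiles:
    def test_bit_exact_round_trip(self, tmp_path, extended_params):
        path = tmp_path / "p.params"
        extended_params.to_file(path)
        back = KineticParameterSet.from_file(path)
        assert back == extended_params

    def test_missing_parameter_reported_by_name(self, extended_params):
        with pytest.raises(ConfigurationError, match="h_Z_E1_X0"):
            _ = KineticParameterSet({})["h_Z_E1_X0"]

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.params"
        path.write_text("g_X 1.0 extra\n")
        with pytest.raises(ConfigurationError, match="bad.params:1"):
            KineticParameterSet.from_file(path)
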