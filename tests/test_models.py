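"""Unit and property tests of the model right-hand sides and knockouts."""

import numpy as np
import pytest

import hpaxis as h
from hpaxis.models import KNOCKOUT_NAMES, apply_knockout, get_model
from hpaxis.params import FREE_PARAM_NAMES, STATE_NAMES

from conftest import random_params, random_state
from oracle_rhs import rhs_extended_oracle, rhs_parsimonious_oracle


class TestMembraneComplexes:
    def test_zero_receptor_gives_zero_complex(self, default_params):
        x = np.ones(15)
        x[6] = 0.0  # CRHR
        c = h.membrane_complexes(x, default_params)
        assert c["CRHR_CRH"] == 0.0

    def test_cooperative_square_law(self, default_params):
        x = np.ones(15)
        x[0] = 3.0
        c1 = h.membrane_complexes(x, default_params)
        x2 = x.copy()
        x2[0] = 6.0
        c2 = h.membrane_complexes(x2, default_params)
        assert c2["GPCR_COR2"] == pytest.approx(4.0 * c1["GPCR_COR2"], rel=1e-12)

    def test_closure_arithmetic(self, default_params):
        p = default_params.replace(kCRC=6.0)
        x = np.ones(15)
        x[6], x[1] = 2.0, 3.0
        assert h.membrane_complexes(x, p)["CRHR_CRH"] == pytest.approx(1.0)

    def test_negative_input_rejected(self, default_params):
        x = np.ones(15)
        x[0] = -1.0
        with pytest.raises(ValueError):
            h.membrane_complexes(x, default_params)


class TestDimerFlux:
    def test_no_free_species_no_flux(self, default_params):
        assert h.dimer_flux_F(5.0, 0.0, 0.0, default_params) == 0.0
        # import term vanishes without free cortisol
        assert h.dimer_flux_F(5.0, 0.0, 3.0, default_params) == 0.0

    def test_zero_at_transport_equilibrium(self, default_params):
        p = default_params
        C = G = 1.0
        D_cyt = C**2 * G**2 / p.kappa
        D_nu = p.k2in * D_cyt / (p.k_bar * p.k2ex)
        assert h.dimer_flux_F(D_nu, C, G, p) == pytest.approx(0.0, abs=1e-15)

    def test_unit_point_matches_closed_form(self, unit_params):
        # all constants 1, k_bar = 1/2, C = G = 1, D_nu = 4:
        # F = (1*1*2/1) * (0.5*1*4 - 1*1) = 2.0
        assert h.dimer_flux_F(4.0, 1.0, 1.0, unit_params) == pytest.approx(2.0)

    def test_single_sign_change_along_dnu_ray(self, default_params, rng):
        C, G = 0.7, 2.3
        D = np.linspace(0.0, 50.0, 2000)
        F = np.array([h.dimer_flux_F(d, C, G, default_params) for d in D])
        signs = np.sign(F[np.abs(F) > 0])
        assert np.sum(np.diff(signs) != 0) == 1
        assert F[0] < 0 and F[-1] > 0  # import first, export dominates later

    def test_nonfinite_rejected(self, default_params):
        with pytest.raises(ValueError):
            h.dimer_flux_F(np.nan, 1.0, 1.0, default_params)


class TestRhsExtended:
    def test_gpcr_balance_zero(self, default_params, rng):
        x = random_state(rng)
        x[5] = default_params.v2 / default_params.d6
        dx = h.rhs_extended(0.0, x, default_params, 0.3)
        assert dx[5] == pytest.approx(0.0, abs=1e-14)

    def test_empty_system_fixed_point(self, zero_production_params):
        dx = h.rhs_extended(0.0, np.zeros(15), zero_production_params, 0.0)
        assert np.allclose(dx, 0.0, atol=1e-290)

    def test_matches_symbolic_oracle_on_random_draws(self, rng):
        """The implementation agrees with an independently coded symbolic
        evaluation of the full system on 100 random (state, params, stress)
        draws to 1e-10 relative."""
        for _ in range(100):
            p = random_params(rng)
            x = random_state(rng)
            stress = float(10 ** rng.uniform(-2, 0.5))
            got = h.rhs_extended(0.0, x, p, stress)
            want = np.array(rhs_extended_oracle(x, p.to_dict(), stress))
            scale = np.maximum(np.abs(want), 1e-30)
            assert np.max(np.abs(got - want) / scale) < 1e-10

    def test_flux_enters_cor_in_and_gr_identically(self, rng):
        """Eqs for COR_in and GR share one F evaluation: subtracting the
        non-flux terms leaves identical remainders."""
        for _ in range(20):
            p = random_params(rng)
            x = random_state(rng)
            dx = h.rhs_extended(0.0, x, p, 0.2)
            F_from_cor = dx[3] - (p.kdiff1 * (x[0] - x[3]) - p.d4 * x[3])
            F_from_gr = dx[7] - (p.ktl2 * x[10] - p.d8 * x[7])
            assert F_from_cor == pytest.approx(F_from_gr, rel=1e-9, abs=1e-12)
            assert F_from_cor == pytest.approx(
                h.dimer_flux_F(x[8], x[3], x[7], p), rel=1e-9, abs=1e-12
            )

    def test_dimension_and_domain_errors(self, default_params):
        with pytest.raises(ValueError):
            h.rhs_extended(0.0, np.ones(14), default_params, 0.1)
        with pytest.raises(ValueError):
            h.rhs_extended(0.0, np.ones(15), default_params, -0.1)


class TestRhsParsimonious:
    def test_crh_balance(self):
        p = h.ParsimoniousParams()
        x = np.array([p.kc / p.kcd, 0.5, 0.5, 0.0])
        dx = h.rhs_parsimonious(0.0, x, p, 0.0)
        assert dx[0] == pytest.approx(0.0, abs=1e-14)

    def test_gr_balance_without_complex(self):
        p = h.ParsimoniousParams()
        x = np.array([1.0, 1.0, p.kcr / p.krd, 0.0])
        dx = h.rhs_parsimonious(0.0, x, p, 0.0)
        assert dx[2] == pytest.approx(0.0, abs=1e-14)

    def test_cor_balance(self):
        p = h.ParsimoniousParams(ko=1.0, kod=1.0)
        x = np.array([1.0, 1.0, 1.0, 1.0])
        dx = h.rhs_parsimonious(0.0, x, p, 0.0)
        assert dx[3] == pytest.approx(0.0)

    def test_matches_symbolic_oracle(self, rng):
        p = h.ParsimoniousParams()
        for _ in range(30):
            kw = {k: v * 10 ** rng.uniform(-0.5, 0.5) for k, v in p.to_dict().items()}
            q = h.ParsimoniousParams(**kw)
            x = 10 ** rng.uniform(-2, 1, 4)
            stress = float(rng.uniform(0, 2))
            got = h.rhs_parsimonious(0.0, x, q, stress)
            want = np.array(rhs_parsimonious_oracle(x, q.to_dict(), stress))
            assert np.allclose(got, want, rtol=1e-12, atol=1e-15)


class TestKnockouts:
    def test_unknown_name_lists_valid(self, default_params):
        with pytest.raises(ValueError, match="gpcr_pathway"):
            h.KnockoutSpec("nonsense")

    def test_gpcr_knockout_release_denominator(self, default_params, rng):
        """With the GPCR complex forced to zero, the release term reduces
        to the pure CRHR form K4 + CRHR_CRH."""
        variant = apply_knockout("gpcr_pathway", default_params)
        p = default_params
        x = random_state(rng)
        dx = variant.rhs(0.0, x, p, 0.1)
        R = x[6] * x[1] / p.kCRC
        release = p.k1ex * R * x[4] / (p.K4 + R)
        assert dx[2] == pytest.approx(release - p.d3 * x[2], rel=1e-12)
        assert dx[5] == 0.0  # receptor ODE removed

    def test_crh_genomic_knockout_decouples_tfs(self, default_params, rng):
        variant = apply_knockout("crh_genomic_feedback", default_params)
        x = random_state(rng)
        vals = []
        for crh in (0.1, 1.0, 10.0):
            x2 = x.copy()
            x2[1] = crh
            vals.append(variant.rhs(0.0, x2, default_params, 0.1)[11])
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)
        assert vals[1] == pytest.approx(vals[2], rel=1e-12)

    def test_gr_loop_knockout_removes_v8_term(self, default_params, rng):
        variant = apply_knockout("gr_autocatalytic_loop", default_params)
        p = default_params
        x = random_state(rng)
        dx = variant.rhs(0.0, x, p, 0.1)
        expected = -p.ktrs2 * x[14] + p.v7 - p.d15 * x[14]
        assert dx[14] == pytest.approx(expected, rel=1e-12)

    def test_removed_terms_recorded(self, default_params):
        for name in KNOCKOUT_NAMES:
            v = apply_knockout(name, default_params)
            assert v.removed_terms
            assert v.n_states == 15

    def test_get_model_aliases(self):
        assert get_model("extended-gpcr").name == "extended-gpcr_pathway"
        assert get_model("extended").n_states == 15
        assert get_model("parsimonious").n_states == 4
        with pytest.raises(ValueError):
            get_model("bogus")
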