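"""Circuit ODE right-hand side, integration, steady states and units."""

import dataclasses

import numpy as np
import pytest

from comrs import (
    CircuitState,
    Scenario,
    concentration_to_molecules,
    derivatives,
    molecules_to_concentration,
    simulate,
    steady_state,
)
from comrs.params import SPECIES, CircuitParameters, DegradationLaw


def zero_production(params):
    return params.replace(k_R=0.0, k_S0=0.0, k_S=0.0, k_X=0.0, k_D0=0.0, k_DX=0.0)


class TestDerivatives:
    def test_absorbing_state(self, deg_params):
        """All-zero state with zero basal production stays at rest."""
        p = zero_production(deg_params)
        assert np.allclose(derivatives(CircuitState(), p), 0.0)

    def test_michaelis_menten_half_saturation(self, deg_params):
        """At substrate = K_m the degradation flux is exactly k_cat*deg/2."""
        law = deg_params.degradation
        d = 7.0
        state = CircuitState(xip_intra=law.K_m, deg=d)
        with_deg = derivatives(state, deg_params)
        without = derivatives(state, deg_params.replace(k_cat=0.0))
        flux = without[SPECIES.index("xip_intra")] - with_deg[SPECIES.index("xip_intra")]
        assert flux == pytest.approx(law.k_cat * d / 2.0, rel=1e-12)

    def test_kcat_only_touches_target_pool(self, deg_params):
        """Turning catalysis on changes only the degradation target's rate."""
        state = CircuitState(
            comR_free=500.0, comS_intra=10.0, xip_extra=5.0, xip_intra=3.0,
            complex_RX=20.0, comX=40.0, deg=6.0,
        )
        on = derivatives(state, deg_params)
        off = derivatives(state, deg_params.replace(k_cat=0.0))
        diff = np.nonzero(~np.isclose(on, off))[0]
        assert list(diff) == [SPECIES.index("xip_intra")]

    def test_negative_state_rejected(self, deg_params):
        with pytest.raises(ValueError, match="negative"):
            derivatives(CircuitState(comR_free=-1.0), deg_params)

    @pytest.mark.parametrize("target", ["comS_intra", "both"])
    def test_target_pool_selection(self, deg_params, target):
        p = deg_params.replace(target_pool=target)
        state = CircuitState(comS_intra=5.0, xip_intra=5.0, deg=4.0)
        on = derivatives(state, p)
        off = derivatives(state, p.replace(k_cat=0.0))
        touched = {SPECIES[i] for i in np.nonzero(~np.isclose(on, off))[0]}
        expected = {"comS_intra"} if target == "comS_intra" else {"comS_intra", "xip_intra"}
        assert touched == expected


class TestDegradationLaw:
    def test_monotone_and_bounded(self):
        """Flux is 0 at 0, increases with substrate, and saturates below k_cat*deg."""
        law = DegradationLaw(k_cat=3.0, K_m=10.0)
        xs = np.linspace(0.0, 1e4, 200)
        v = np.array([law.rate(2.0, x) for x in xs])
        assert v[0] == 0.0
        assert np.all(np.diff(v) > 0)
        assert np.all(v <= 3.0 * 2.0)


class TestSimulate:
    def test_null_scenario_is_constant(self, deg_params, basal_state):
        """From the basal fixed point the unforced trajectory does not move."""
        traj = simulate(Scenario(kind="null"), deg_params, horizon=300.0, dt=5.0,
                        y0=basal_state)
        ref = basal_state.as_array()
        scale = np.maximum(np.abs(ref), 1.0)
        assert np.all(np.abs(traj.values - ref) / scale < 1e-5)

    def test_trajectory_nonnegative(self, induction_traj):
        assert induction_traj.values.min() >= 0.0

    def test_nonnegativity_random_parameter_sets(self, deg_params, rng):
        """Trajectories stay non-negative across 100 random valid parameter sets."""
        names = ["k_R", "k_S0", "k_S", "k_X", "k_D0", "k_DX",
                 "K_S", "K_X", "K_D", "k_on", "k_off", "k_exp", "k_imp"]
        for _ in range(100):
            changes = {
                n: getattr(deg_params, n) * float(rng.lognormal(0.0, 0.5))
                for n in names
            }
            changes["k_cat"] = deg_params.degradation.k_cat * float(rng.lognormal(0, 0.5))
            changes["K_m"] = deg_params.degradation.K_m * float(rng.lognormal(0, 0.5))
            p = deg_params.replace(**changes)
            traj = simulate(Scenario(kind="comR_overexpression", comR_fold=8.5),
                            p, horizon=150.0, dt=10.0)
            assert traj.values.min() >= -1e-10

    def test_deg_player_deletion_equals_kcat_zero(self, deg_params, basal_state):
        """Deleting the deg species matches k_cat = k_D0 = k_DX = 0.

        The deleted-player model is a six-species system integrated
        independently here, without going through the package's RHS.
        """
        from scipy.integrate import solve_ivp

        p = deg_params.replace(k_cat=0.0, k_D0=0.0, k_DX=0.0)
        y0 = dataclasses.replace(basal_state, deg=0.0)
        sc = Scenario(kind="comR_overexpression", comR_fold=8.5)
        t_full = simulate(sc, p, horizon=300.0, dt=5.0, y0=y0)

        d = p.delta

        def rhs6(t, y):
            R, S, Xe, Xi, C, X = y
            hill = lambda x, K, n: 0.0 if x <= 0 else (x / K) ** n / (1 + (x / K) ** n)
            fold = 8.5 if t >= 0.0 else 1.0
            bind, unbind = p.k_on * R * Xi, p.k_off * C
            return [
                p.k_R * fold - bind + unbind - d["comR_free"] * R,
                p.k_S0 + p.k_S * hill(C, p.K_S, p.n_S) - p.k_exp * S - d["comS_intra"] * S,
                p.k_exp * S - p.k_imp * Xe - d["xip_extra"] * Xe,
                p.k_imp * Xe - bind + unbind - d["xip_intra"] * Xi,
                bind - unbind - d["complex_RX"] * C,
                p.k_X * hill(C, p.K_X, p.n_X) - d["comX"] * X,
            ]

        keep = [i for i, s in enumerate(SPECIES) if s != "deg"]
        sol = solve_ivp(rhs6, (0.0, 300.0), y0.as_array()[keep], method="LSODA",
                        t_eval=t_full.time, rtol=1e-10, atol=1e-12)
        scale = np.maximum(np.abs(sol.y.T), 1e-3)
        assert np.all(np.abs(t_full.values[:, keep] - sol.y.T) / scale < 1e-5)
        assert np.all(t_full.species("deg") == 0.0)

    def test_saturation_bound_along_trajectory(self, deg_params, induction_traj):
        """Instantaneous degradation flux never exceeds k_cat * deg(t)."""
        law = deg_params.degradation
        xi = induction_traj.species("xip_intra")
        deg = induction_traj.species("deg")
        flux = np.array([law.rate(d, x) for d, x in zip(deg, xi)])
        assert np.all(flux <= law.k_cat * deg + 1e-12)

    def test_comR_mass_bookkeeping(self, deg_params):
        """With ComR production and decay off, free ComR + complex is conserved."""
        delta = dict(deg_params.delta)
        delta["comR_free"] = 0.0
        delta["complex_RX"] = 0.0
        p = deg_params.replace(k_R=0.0, delta=delta)
        y0 = CircuitState(comR_free=800.0, xip_extra=500.0, deg=5.0)
        traj = simulate(Scenario(kind="null"), p, horizon=400.0, dt=5.0, y0=y0)
        total = traj.species("comR_free") + traj.species("complex_RX")
        assert np.all(np.abs(total - 800.0) / 800.0 < 1e-6)

    def test_tolerance_robustness(self, deg_params, basal_state):
        """Tightening solver tolerances 10-fold moves summaries by < 0.1%."""
        sc = Scenario(kind="comR_overexpression", comR_fold=8.5)
        a = simulate(sc, deg_params, horizon=600.0, dt=2.0, y0=basal_state)
        b = simulate(sc, deg_params, horizon=600.0, dt=2.0, y0=basal_state,
                     rtol=1e-9, atol=1e-11)
        for summary in (
            lambda t: t.species("comX")[-1],
            lambda t: t.species("xip_intra").max(),
            lambda t: t.time[np.argmax(t.species("comX") >= 75.0)],
        ):
            assert summary(a) == pytest.approx(summary(b), rel=1e-3)


class TestSteadyState:
    def test_zero_production_gives_zero_state(self, deg_params):
        ss = steady_state(zero_production(deg_params))
        assert np.allclose(ss.as_array(), 0.0, atol=1e-9)

    def test_matches_long_integration(self, deg_params, basal_state):
        """Root-polished fixed point agrees with a 10,000-min integration."""
        traj = simulate(Scenario(kind="null"), deg_params, horizon=10_000.0,
                        dt=500.0, y0=CircuitState(comR_free=100.0, deg=1.0))
        end = traj.final_state().as_array()
        ss = basal_state.as_array()
        scale = np.maximum(np.abs(ss), 1e-3)
        assert np.all(np.abs(end - ss) / scale < 1e-3)

    def test_residual_is_small(self, deg_params, basal_state):
        assert np.linalg.norm(derivatives(basal_state, deg_params)) < 1e-6


class TestUnitConversion:
    def test_zero_molecules_is_zero_nM(self, deg_params):
        assert molecules_to_concentration(0.0, deg_params, "intracellular") == 0.0

    def test_single_molecule_in_1p66_fL(self, deg_params):
        """1 molecule in a 1.66 fL cell is ~1 nM (Avogadro arithmetic)."""
        p = deg_params.replace(cell_volume=1.66e-15)
        expected = 1.0 / (6.02214076e23 * 1.66e-15) * 1e9
        got = molecules_to_concentration(1.0, p, "intracellular")
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.0, rel=1e-2)

    @pytest.mark.parametrize("compartment", ["intracellular", "extracellular"])
    def test_round_trip_identity(self, deg_params, compartment, rng):
        n = rng.uniform(0.0, 1e5, size=20)
        back = concentration_to_molecules(
            molecules_to_concentration(n, deg_params, compartment),
            deg_params, compartment,
        )
        assert np.allclose(back, n, rtol=1e-12)

    def test_bad_conversion_factors_rejected(self, deg_params):
        with pytest.raises(ValueError):
            deg_params.replace(cell_volume=0.0)
        with pytest.raises(ValueError):
            deg_params.replace(culture_density=-1.0)


class TestParameterIO:
    def test_yaml_json_round_trip(self, deg_params, tmp_path):
        for name in ("p.yaml", "p.json"):
            path = tmp_path / name
            deg_params.save(path)
            loaded = CircuitParameters.load(path)
            assert loaded == deg_params

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CircuitParameters(k_R=-1.0)
        with pytest.raises(ValueError):
            CircuitParameters(n_S=0.5)
        with pytest.raises(ValueError):
            DegradationLaw(target_pool="nonsense")
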