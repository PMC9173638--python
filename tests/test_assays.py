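"""Degradation-assay normalisation, EC50 fitting, turnover and screening."""

import numpy as np
import pytest

from comrs.assays import (
    REFERENCE_PEPF_GRADIENT_NM,
    DoseResponseDataset,
    InhibitionFit,
    apparent_turnover,
    efficiency_ratio,
    fit_inhibition,
    inhibition_model,
    normalize_to_control,
    screen_signal_loss,
    substrate_enzyme_ratio,
)
from comrs.synth import SyntheticSpec, gen_dose_response


def make_dataset(top=100.0, bottom=0.0, ec50=0.22, hill_slope=1.0,
                 noise_cv=0.0, replicates=1, seed=0):
    return gen_dose_response(
        {"top": top, "bottom": bottom, "ec50": ec50, "hill_slope": hill_slope},
        spec=SyntheticSpec(noise_cv=noise_cv, replicates=replicates, seed=seed),
    )


class TestNormalize:
    def test_controls_average_to_100(self, rng):
        raw = rng.uniform(50.0, 150.0, size=8)
        out = normalize_to_control(raw, [0, 1, 2])
        assert np.mean(out[[0, 1, 2]]) == pytest.approx(100.0)

    def test_zero_treated_wells(self):
        out = normalize_to_control([10.0, 10.0, 0.0, 0.0], [0, 1])
        assert out[2] == out[3] == 0.0

    def test_matches_elementwise_oracle(self, rng):
        raw = rng.uniform(1.0, 1000.0, size=12)
        ctrl = [3, 7]
        expected = [v * 100.0 / ((raw[3] + raw[7]) / 2.0) for v in raw]
        assert np.allclose(normalize_to_control(raw, ctrl), expected)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            normalize_to_control([0.0, 0.0, 5.0], [0, 1])


class TestInhibitionModel:
    def test_half_signal_at_ec50(self):
        """The four-parameter curve equals (top+bottom)/2 exactly at EC50."""
        for t, b, ec50, hs in [(100, 0, 0.22, 1.0), (93, 7, 3.06, 1.7)]:
            assert inhibition_model(ec50, t, b, ec50, hs) == pytest.approx((t + b) / 2)

    def test_top_at_zero_enzyme(self):
        assert inhibition_model(0.0, 100.0, 5.0, 0.3, 1.2) == 100.0


class TestFitInhibition:
    def test_noise_free_recovery_at_printed_concentrations(self):
        """Self-consistency on the 11-point PepF gradient: parameters back
        to 4 significant figures."""
        ds = make_dataset(top=100.0, bottom=0.0, ec50=0.22, hill_slope=1.0)
        assert list(np.unique(ds.enzyme_nM)) == sorted(REFERENCE_PEPF_GRADIENT_NM)
        fit = fit_inhibition(ds)
        assert fit.converged
        assert fit.ec50 == pytest.approx(0.22, rel=1e-4)
        assert fit.hill_slope == pytest.approx(1.0, rel=1e-4)
        assert fit.top == pytest.approx(100.0, rel=1e-4)
        assert abs(fit.bottom) < 1e-3

    def test_recovery_study_5pct_noise(self):
        """Over 100 seeded datasets (5% noise, truth EC50 in [0.02, 20] nM):
        median relative error < 10% and ±3 SE coverage >= 90%."""
        draw = np.random.default_rng(123)
        errs, covered = [], 0
        for seed in range(100):
            ec50 = float(np.exp(draw.uniform(np.log(0.02), np.log(20.0))))
            ds = make_dataset(ec50=ec50, noise_cv=0.05, replicates=3, seed=seed)
            fit = fit_inhibition(ds)
            errs.append(abs(fit.ec50 - ec50) / ec50)
            if fit.se_ec50 is not None and abs(fit.ec50 - ec50) <= 3 * fit.se_ec50:
                covered += 1
        assert np.median(errs) < 0.10
        assert covered >= 90

    def test_scale_equivariance(self):
        """Rescaling enzyme concentrations by c rescales EC50 by c and leaves
        the Hill slope unchanged."""
        ds = make_dataset(ec50=0.5, hill_slope=1.4, noise_cv=0.02, seed=5,
                          replicates=2)
        fit1 = fit_inhibition(ds)
        scaled = DoseResponseDataset(
            enzyme_nM=ds.enzyme_nM * 37.0, signal_pct=ds.signal_pct,
            replicate=ds.replicate,
        )
        fit2 = fit_inhibition(scaled)
        assert fit2.ec50 == pytest.approx(fit1.ec50 * 37.0, rel=1e-6)
        assert fit2.hill_slope == pytest.approx(fit1.hill_slope, rel=1e-6)

    def test_fixed_hill_slope_option(self):
        ds = make_dataset(hill_slope=1.0)
        fit = fit_inhibition(ds, fix_hill_slope=1.0)
        assert fit.hill_slope == 1.0
        assert fit.se_hill_slope is None
        assert fit.ec50 == pytest.approx(0.22, rel=1e-4)

    def test_non_monotone_data_warns(self):
        x = np.array(REFERENCE_PEPF_GRADIENT_NM)
        y = inhibition_model(x, 100.0, 0.0, 0.22, 1.0)
        y[-1] = 160.0  # strong rise at the top dose
        with pytest.warns(UserWarning, match="decreasing"):
            fit = fit_inhibition(DoseResponseDataset(enzyme_nM=x, signal_pct=y))
        assert fit.monotone_warning

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            DoseResponseDataset(
                enzyme_nM=[0.0, 1.0, 2.0], signal_pct=[100.0, 60.0, 30.0]
            )

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            InhibitionFit(top=50.0, bottom=60.0, ec50=1.0, hill_slope=1.0,
                          se_top=None, se_bottom=None, se_ec50=None,
                          se_hill_slope=None, rss=0.0, converged=True)
        with pytest.raises(ValueError):
            InhibitionFit(top=100.0, bottom=0.0, ec50=-1.0, hill_slope=1.0,
                          se_top=None, se_bottom=None, se_ec50=None,
                          se_hill_slope=None, rss=0.0, converged=True)


class TestAssayArithmetic:
    def test_reference_turnover_numbers(self):
        """500 nM substrate, 0.2 nM EC50, 4 h: 2,500-fold ratio and an
        apparent turnover of ~0.2 per second (0.17 exactly)."""
        assert substrate_enzyme_ratio(0.2, 500.0) == pytest.approx(2500.0)
        k = apparent_turnover(0.2, 500.0, 240.0)
        assert k == pytest.approx(2500.0 / (240.0 * 60.0), rel=1e-12)
        assert 0.1 < k < 0.25  # "~0.2 s^-1"

    def test_turnover_inverse_in_time(self):
        assert apparent_turnover(0.2, 500.0, 480.0) == pytest.approx(
            apparent_turnover(0.2, 500.0, 240.0) / 2.0
        )

    def test_unit_inputs(self):
        assert substrate_enzyme_ratio(1.0, 1.0) == 1.0
        assert apparent_turnover(1.0, 1.0, 10.0) == pytest.approx(1.0 / 600.0)

    def test_efficiency_ratio_sve_vs_ssa(self):
        """EC50 3.06 nM over ~0.2 nM: ~15-fold less efficient degradation."""
        ratio = efficiency_ratio(3.06, 0.2)
        assert ratio == pytest.approx(15.3)

    def test_efficiency_ratio_reciprocity(self):
        assert efficiency_ratio(3.06, 0.2) * efficiency_ratio(0.2, 3.06) == \
            pytest.approx(1.0)
        assert efficiency_ratio(2.0, 2.0) == 1.0

    def test_signal_loss(self):
        assert screen_signal_loss(200.0, 200.0) == 0.0
        assert screen_signal_loss(200.0, 0.0) == 100.0
        assert screen_signal_loss(200.0, 50.0) == 75.0
        assert screen_signal_loss(100.0, 150.0) == 0.0  # clipped
        with pytest.raises(ValueError):
            screen_signal_loss(0.0, 10.0)
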