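import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metalscreen.errors import DegenerateControlError, InputError
from metalscreen.registry import load_lead_compounds
from metalscreen.screening_analytics import (
    DoseSeries,
    binarize_activity,
    call_mic,
    classify_toxicity,
    dilution_grid,
    ec_at,
    fit_4pl,
    four_pl,
    percent_of_control,
    round_conc,
    round_half_away,
    therapeutic_index,
)
from metalscreen.synthetic_data import sim_dose_response


class TestDilutionGrid:
    def test_crude_grid(self):
        assert dilution_grid(50, 2, 7) == [50, 25, 12.5, 6.25, 3.13, 1.56, 0.78, 0.39]

    def test_pure_grid_lowest(self):
        grid = dilution_grid(100, 2, 11)
        assert len(grid) == 12
        assert grid[-1] == pytest.approx(0.049)
        assert grid[-4] == pytest.approx(0.39)

    def test_zero_steps(self):
        assert dilution_grid(7.5, 2, 0) == [7.5]

    def test_invalid_params(self):
        for args in ((0, 2, 3), (10, 1, 3), (10, 2, -1)):
            with pytest.raises(InputError):
                dilution_grid(*args)

    def test_rounding_convention(self):
        assert round_conc(3.125) == 3.13
        assert round_conc(1.5625) == 1.56
        assert round_conc(0.78125) == 0.78
        assert round_conc(0.390625) == 0.39
        assert round_conc(0.1953125) == 0.2
        assert round_conc(0.048828125) == 0.049


class TestPercentOfControl:
    def test_endpoints(self):
        assert percent_of_control(1.0, 1.0, 0.1) == 100.0
        assert percent_of_control(0.1, 1.0, 0.1) == 0.0
        assert percent_of_control(0.55, 1.0, 0.1) == pytest.approx(50.0)

    def test_clipped_below_zero(self):
        assert percent_of_control(0.05, 1.0, 0.1) == 0.0

    def test_degenerate_controls(self):
        with pytest.raises(DegenerateControlError):
            percent_of_control(0.5, 0.1, 0.1)


def series(grid, responses):
    return DoseSeries(tuple(grid), tuple(responses))


class TestCallMic:
    GRID = (50, 25, 12.5, 6.25, 3.13, 1.56, 0.78, 0.39)

    def test_example_from_rule(self):
        mic = call_mic(series(self.GRID, [0, 0, 0, 0, 80, 95, 99, 100]), 10)
        assert mic.value == 6.25 and not mic.censored

    def test_all_growth_censored(self):
        mic = call_mic(series(self.GRID, [100] * 8), 10)
        assert mic.censored and mic.value is None
        assert mic.render() == "-"

    def test_non_monotone_highest_block(self):
        # inhibited at 50, growth at 25, inhibited again below: call 50
        mic = call_mic(series(self.GRID, [0, 50, 0, 0, 0, 0, 0, 0]), 10)
        assert mic.value == 50

    def test_fully_inhibited(self):
        mic = call_mic(series(self.GRID, [0] * 8), 10)
        assert mic.value == 0.39

    def test_monotonicity_property(self):
        base = [100, 100, 100, 0, 0, 100, 100, 100]
        mic1 = call_mic(series(self.GRID, base), 10)
        assert mic1.censored
        more = [0, 0, 0, 0, 0, 100, 100, 100]
        mic2 = call_mic(series(self.GRID, more), 10)
        assert mic2.value == 3.13

    @given(st.lists(st.floats(0, 100), min_size=8, max_size=8))
    def test_extra_inhibition_never_raises_mic(self, growth):
        mic_a = call_mic(series(self.GRID, growth), 10)
        stronger = [0.0] + growth[1:]
        mic_b = call_mic(series(self.GRID, stronger), 10)
        if not mic_a.censored:
            assert not mic_b.censored and mic_b.value <= mic_a.value

    def test_grid_validation(self):
        with pytest.raises(InputError):
            DoseSeries((1.0, 2.0), (0.0, 0.0))  # increasing grid
        with pytest.raises(InputError):
            DoseSeries((2.0, -1.0), (0.0, 0.0))


class TestBinarizeActivity:
    def test_cutoff_boundary(self):
        GRID = (50, 25, 12.5, 6.25)
        mic_625 = call_mic(series(GRID, [0, 0, 0, 0]), 10)
        assert mic_625.value == 6.25
        assert binarize_activity(mic_625) == 1

    def test_above_cutoff(self):
        GRID = (50, 25, 12.5, 6.25)
        mic = call_mic(series(GRID, [0, 0, 0, 90]), 10)
        assert mic.value == 12.5
        assert binarize_activity(mic) == 0

    def test_censored_inactive(self):
        mic = call_mic(series((50, 25), [100, 100]), 10)
        assert binarize_activity(mic) == 0


class TestClassifyToxicity:
    def test_toxic_below_50(self):
        assert classify_toxicity(45.0)  # e.g. 45 ± 7% viability

    def test_boundary_strict(self):
        assert not classify_toxicity(50.0)

    def test_not_toxic(self):
        assert not classify_toxicity(100.0)


class TestFourPL:
    def test_noiseless_recovery(self):
        s, _ = sim_dose_response(10.0, hill=1.0, bottom=0, top=100, noise_sd=0.0)
        fit = fit_4pl(s.concentrations, s.responses)
        assert fit.converged
        assert fit.ec50 == pytest.approx(10.0, rel=0.01)

    def test_hc10_analytic(self):
        # f(c) = 100 / (1 + (50/c)) = 10  =>  c = 50/9
        s, _ = sim_dose_response(50.0, hill=1.0, bottom=0, top=100,
                                 n_points=10, noise_sd=0.0)
        fit = fit_4pl(s.concentrations, s.responses)
        assert ec_at(fit, 10.0) == pytest.approx(50.0 / 9.0, rel=1e-3)
        assert ec_at(fit, 10.0) == pytest.approx(5.56, abs=0.005)

    def test_decreasing_viability_curve(self):
        conc = np.array([100 / 2**k for k in range(10)])
        resp = four_pl(conc, 5.0, 95.0, -1.5, 12.0)
        fit = fit_4pl(conc, resp)
        assert fit.converged and fit.bottom < fit.top
        assert ec_at(fit, 50.0) == pytest.approx(
            12.0 * ((95 - 5) / (50 - 5) - 1) ** (1 / 1.5), rel=1e-3
        )

    def test_flat_response_fails(self):
        conc = [100, 50, 25, 12.5, 6.25]
        fit = fit_4pl(conc, [100.0] * 5)
        assert not fit.converged and math.isnan(fit.ec50)

    def test_too_few_points_fails(self):
        fit = fit_4pl([10, 5, 2.5], [90, 50, 10])
        assert not fit.converged

    def test_recovery_study_median_error(self):
        # 100 simulated curves, hill in [0.5, 3], 5% noise
        rng = np.random.default_rng(12345)
        errors = []
        for i in range(100):
            ec50 = float(rng.uniform(2, 50))
            hill = float(rng.uniform(0.5, 3.0))
            s, _ = sim_dose_response(ec50, hill=hill, bottom=0, top=100,
                                     n_points=10, noise_sd=5.0, seed=1000 + i)
            fit = fit_4pl(s.concentrations, s.responses)
            if fit.converged:
                errors.append(abs(fit.ec50 - ec50) / ec50)
            else:
                errors.append(1.0)
        assert np.median(errors) < 0.10


class TestTherapeuticIndex:
    def test_rounding_half_away(self):
        assert round_half_away(36.5) == 37
        assert round_half_away(30.51) == 31
        assert round_half_away(2.49) == 2
        assert round_half_away(-2.5) == -3

    def test_single_mic_single_ti(self):
        ti = therapeutic_index(12.4, 73.0, 0.39)
        assert ti.ti_lo == ti.ti_hi == 32
        assert ti.render() == "32"

    def test_censored_hc10(self):
        ti = therapeutic_index(38.5, math.inf, 0.39, 0.78)
        assert (ti.ti_lo, ti.ti_hi) == (49, 99)
        assert ti.render() == "49–99"

    def test_equal_cc50_and_mic(self):
        ti = therapeutic_index(6.25, None, 6.25)
        assert ti.ti_lo == ti.ti_hi == 1

    def test_printed_lead_table_reproduced(self):
        expected = {
            "Re(CO)3(M1Y1)": "32",
            "Re(CO)3(M20Y3)": "11–21",
            "IrCN(M12Y1)": "19–37",
            "IrCN(M8Y4)": "49–99",
            "Mn(CO)3(M19Y1)": "15–31",
            "Mn(CO)3(M22Y1)": "2–4",
        }
        df = load_lead_compounds()
        assert len(df) == 6
        for r in df.itertuples():
            ti = therapeutic_index(r.cc50_um, r.hc10_um, r.mic_lo_um, r.mic_hi_um)
            assert ti.render() == expected[r.compound_id], r.compound_id

    def test_grid_value_not_exact_power(self):
        # 11.9 / 0.39 -> 31 whereas 11.9 / 0.390625 would round to 30:
        # reported grid values, not exact powers, enter the arithmetic
        assert therapeutic_index(11.9, None, 0.39).ti_hi == 31
        assert round_half_away(11.9 / 0.390625) == 30

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            therapeutic_index(-1.0, None, 0.39)
        with pytest.raises(InputError):
            therapeutic_index(10.0, None, 0.78, 0.39)
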