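import numpy as np
import pytest

import metalscreen as ms
from metalscreen import registry
from metalscreen.errors import InputError, UndefinedConversionError
from metalscreen.formula import ElementalFormula
from metalscreen.lcms_pipeline import (
    ChromPeak,
    ChromatographyRun,
    PipelineParams,
    characterize_library,
    characterize_run,
    conversion_percent,
    detect_peaks,
    extract_eic,
    library_summary,
    load_run,
    match_target,
    save_run,
)
from metalscreen.synthetic_data import SimTarget, sim_chromatogram

F = ElementalFormula.from_hill


def gaussian_trace(areas, rts, sd=0.05, t_end=10.0, hz=2.0, noise_sd=0.0, seed=0):
    t = np.arange(0.0, t_end, 1.0 / (hz * 60.0))
    y = np.zeros_like(t)
    for a, mu in zip(areas, rts):
        y += a * np.exp(-0.5 * ((t - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    if noise_sd:
        y += np.random.default_rng(seed).normal(0, noise_sd, t.shape)
    return t, y


class TestDetectPeaks:
    def test_single_gaussian(self):
        t, y = gaussian_trace([10.0], [5.0])
        peaks = detect_peaks(t, y)
        assert len(peaks) == 1
        p = peaks[0]
        step = t[1] - t[0]
        assert p.apex_rt == pytest.approx(5.0, abs=step)
        # trapezoidal area vs the closed-form Gaussian area (the parameter)
        assert p.area == pytest.approx(10.0, rel=0.01)

    def test_area_ratio_three_to_one(self):
        t, y = gaussian_trace([9.0, 3.0], [3.0, 7.0])
        peaks = sorted(detect_peaks(t, y), key=lambda p: p.apex_rt)
        assert len(peaks) == 2
        assert peaks[0].area / peaks[1].area == pytest.approx(3.0, rel=0.02)

    def test_flat_noise_only(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0, 10, 1200)
        y = rng.normal(0.0, 1.0, t.shape)
        assert detect_peaks(t, y) == []

    def test_too_short(self):
        with pytest.raises(InputError):
            detect_peaks(np.array([0, 1, 2]), np.array([0.0, 1.0, 0.0]))

    def test_peak_invariants(self):
        t, y = gaussian_trace([5.0, 2.0], [2.0, 6.0], noise_sd=0.05, seed=3)
        for p in detect_peaks(t, y):
            assert p.start < p.apex_rt <= p.end
            assert p.area >= 0


class TestExtractEic:
    def _run(self, scans, times=None):
        times = times if times is not None else np.arange(len(scans), dtype=float)
        return ChromatographyRun(
            uv_times=np.linspace(0, 1, 10),
            uv_signal=np.zeros(10),
            ms_times=times,
            ms_scans=scans,
        )

    def test_single_centroid_passthrough(self):
        intensities = [10.0, 50.0, 10.0]
        scans = [(np.array([500.0]), np.array([i])) for i in intensities]
        _, eic = extract_eic(self._run(scans), 500.0, tol=0.5)
        assert list(eic) == intensities

    def test_absent_target(self):
        scans = [(np.array([400.0]), np.array([10.0]))] * 3
        _, eic = extract_eic(self._run(scans), 500.0, tol=0.5)
        assert np.all(eic == 0)

    def test_tolerance_window_sums(self):
        scans = [(np.array([499.7, 500.2, 501.0]), np.array([1.0, 2.0, 4.0]))]
        _, eic = extract_eic(self._run(scans), 500.0, tol=0.5)
        assert eic[0] == 3.0

    def test_invalid_tol(self):
        with pytest.raises(InputError):
            extract_eic(self._run([(np.array([1.0]), np.array([1.0]))]), 500.0, tol=0)


def peak(rt, area=1.0):
    return ChromPeak(apex_rt=rt, start=rt - 0.1, end=rt + 0.1, area=area, height=1.0)


class TestMatchTarget:
    def test_nearest_within_tol(self):
        matches = match_target([peak(5.02)], [peak(5.00), peak(7.10)], rt_tol=0.2)
        assert matches[0][1].apex_rt == 5.00
        assert matches[0][2] == set()

    def test_not_found(self):
        matches = match_target([peak(5.0)], [peak(7.1)], rt_tol=0.2)
        assert matches[0][1] is None
        assert "not-found" in matches[0][2]

    def test_tie_broken_by_area(self):
        uv = [peak(4.95, area=1.0), peak(5.05, area=3.0)]
        matches = match_target([peak(5.0)], uv, rt_tol=0.2)
        assert matches[0][1].area == 3.0
        assert "multiple-candidates" in matches[0][2]


class TestConversionPercent:
    def test_single_matched_peak(self):
        p = peak(5.0, area=42.0)
        res = conversion_percent([p], [p])
        assert res.conversion_pct == 100.0

    def test_fraction(self):
        matched = peak(5.0, area=75.0)
        other = peak(7.0, area=25.0)
        res = conversion_percent([matched, other], [matched])
        assert res.conversion_pct == 75.0

    def test_aggregate_two_species(self):
        m1, m2 = peak(4.0, area=40.0), peak(5.5, area=20.0)
        other = peak(7.0, area=40.0)
        res = conversion_percent([m1, m2, other], [m1, m2], mode="aggregate")
        assert res.conversion_pct == 60.0

    def test_duplicate_matched_counted_once(self):
        p = peak(5.0, area=50.0)
        other = peak(7.0, area=50.0)
        res = conversion_percent([p, other], [p, p], mode="aggregate")
        assert res.conversion_pct == 50.0

    def test_normalized_total_excludes_unidentified(self):
        m = peak(5.0, area=30.0)
        unidentified = peak(7.0, area=70.0)
        res = conversion_percent(
            [m, unidentified], [m], mode="normalized-total", identified=[m]
        )
        assert res.conversion_pct == 100.0

    def test_zero_total_area(self):
        with pytest.raises(UndefinedConversionError):
            conversion_percent([], [])

    def test_empty_match_flags_not_found(self):
        res = conversion_percent([peak(5.0, area=1.0)], [])
        assert res.conversion_pct == 0.0
        assert "not-found" in res.flags

    def test_monotone_in_matched_area(self):
        other = peak(7.0, area=50.0)
        prev = -1.0
        for a in (10.0, 25.0, 50.0):
            res = conversion_percent([peak(5.0, area=a), other], [peak(5.0, area=a)])
            assert res.conversion_pct > prev
            prev = res.conversion_pct


@pytest.fixture(scope="module")
def rucy_complex(scaffold_map, t4p_ligands):
    lig = next(l for l in t4p_ligands if l.id == "M8Y1")
    return ms.assemble_complexes([lig], [scaffold_map["RuCy"]])[0]


class TestEndToEnd:
    def test_noiseless_round_trip(self, rucy_complex):
        tgt = SimTarget(rucy_complex.formula, 1, rt=5.0, fraction=0.75)
        run, _ = sim_chromatogram([tgt], noise_sd=0.0, seed=0)
        res = characterize_run(run, rucy_complex)
        assert res.conversion_pct == pytest.approx(75.0, abs=0.05)
        assert res.rt_reported == pytest.approx(5.0, abs=0.02)

    def test_uniform_uv_scaling_invariance(self, rucy_complex):
        tgt = SimTarget(rucy_complex.formula, 1, rt=5.0, fraction=0.6)
        run, _ = sim_chromatogram([tgt], noise_sd=0.0, seed=0)
        scaled = ChromatographyRun(
            uv_times=run.uv_times, uv_signal=run.uv_signal * 37.0,
            ms_times=run.ms_times, ms_scans=run.ms_scans,
        )
        a = characterize_run(run, rucy_complex).conversion_pct
        b = characterize_run(scaled, rucy_complex).conversion_pct
        assert a == pytest.approx(b, abs=1e-9)

    def test_noise_convergence(self, rucy_complex):
        tgt = SimTarget(rucy_complex.formula, 1, rt=5.0, fraction=0.6)
        errors = []
        for noise in (2.0, 0.5, 0.0):
            run, _ = sim_chromatogram([tgt], noise_sd=noise, seed=11)
            res = characterize_run(run, rucy_complex)
            errors.append(abs(res.conversion_pct - 60.0))
        assert errors[-1] < 0.05
        assert errors[-1] <= errors[0] + 0.5

    def test_characterize_library_known_truth(self, rucy_complex, scaffold_map,
                                              t4p_ligands):
        rng = np.random.default_rng(7)
        specs = ms.assemble_complexes(t4p_ligands[:12], [scaffold_map["RuCy"]])
        truths, runs = {}, {}
        for i, spec in enumerate(specs):
            frac = float(rng.uniform(0.3, 1.0))
            truths[spec.id] = 100 * frac
            run, _ = sim_chromatogram(
                [SimTarget(spec.formula, 1, rt=4.0, fraction=frac)],
                noise_sd=0.3, seed=100 + i, compound_id=spec.id,
            )
            runs[spec.id] = run
        table = characterize_library(runs, specs)
        assert len(table) == 12
        errs = [abs(r.conversion_pct - truths[r.compound_id])
                for r in table.itertuples()]
        assert all(e < 2.0 for e in errs)
        assert abs(np.mean([r.conversion_pct for r in table.itertuples()])
                   - np.mean(list(truths.values()))) < 1.0

    def test_missing_run_reported_absent(self, rucy_complex):
        table = characterize_library({}, [rucy_complex])
        assert len(table) == 1
        assert table.iloc[0]["flags"] == "missing-run"
        assert np.isnan(table.iloc[0]["conversion_pct"])

    def test_summary_formatting(self):
        import pandas as pd

        table = pd.DataFrame({"conversion_pct": [100.0, 100.0, 100.0]})
        mean, sd, rendered = library_summary(table)
        assert (mean, sd) == (100.0, 0.0)
        assert rendered == "100 ± 0%"

        table = pd.DataFrame({"conversion_pct": [59.0, 91.0]})
        assert library_summary(table)[2] == "75 ± 16%"


class TestFileDialect:
    def test_round_trip(self, tmp_path, rucy_complex):
        tgt = SimTarget(rucy_complex.formula, 1, rt=5.0, fraction=0.5)
        run, _ = sim_chromatogram([tgt], noise_sd=0.2, seed=9)
        uv, msf = str(tmp_path / "x.uv.csv"), str(tmp_path / "x.ms.csv")
        save_run(run, uv, msf)
        back = load_run(uv, msf)
        assert np.allclose(back.uv_times, run.uv_times)
        assert np.allclose(back.uv_signal, run.uv_signal)
        nonempty = [i for i, (mz, _) in enumerate(run.ms_scans) if len(mz)]
        assert len(back.ms_times) == len(nonempty)
        res_a = characterize_run(run, rucy_complex)
        res_b = characterize_run(back, rucy_complex)
        assert res_a.conversion_pct == pytest.approx(res_b.conversion_pct, abs=1e-9)
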