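"""Automated library characterization from UV + MS chromatograms.

For each compound: build the expected target ion(s), extract their ion
chromatograms from the MS scans, find the co-eluting UV peak at 254 nm,
integrate it and report conversion% as matched UV area over total UV area
(with per-scaffold variants: adduct aggregation and renormalization over
MS-identified peaks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedConversionError
from .library_design import ComplexSpec
from .mass_iso import IonSpecies, expected_ions, isotope_pattern

ConversionMode = Literal["area-percent", "aggregate", "normalized-total"]


@dataclass
class ChromatographyRun:
    """One LC-MS run: a UV trace plus centroided MS scans."""

    uv_times: np.ndarray          # min, strictly increasing
    uv_signal: np.ndarray         # mAU at 254 nm
    ms_times: np.ndarray          # min, strictly increasing
    ms_scans: list[tuple[np.ndarray, np.ndarray]]  # per scan (mz, intensity)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.uv_times = np.asarray(self.uv_times, dtype=float)
        self.uv_signal = np.asarray(self.uv_signal, dtype=float)
        self.ms_times = np.asarray(self.ms_times, dtype=float)
        for t in (self.uv_times, self.ms_times):
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise InputError("times must be strictly increasing")
        if len(self.ms_scans) != self.ms_times.size:
            raise InputError("one scan per MS time point required")


@dataclass(frozen=True)
class ChromPeak:
    apex_rt: float
    start: float
    end: float
    area: float    # trapezoidal, above local linear baseline
    height: float

    def __post_init__(self):
        if not (self.start < self.apex_rt <= self.end):
            raise InputError("peak bounds must bracket the apex")


@dataclass
class ConversionResult:
    compound_id: str
    matched_species: list[tuple[str, float]]  # (species label, apex rt)
    rt_reported: float | None
    conversion_pct: float
    mode: ConversionMode
    flags: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(y, kernel, mode="same")


def detect_peaks(
    times: np.ndarray,
    signal: np.ndarray,
    smooth_window: int = 5,
    noise_k: float = 5.0,
    min_height_frac: float = 0.01,
) -> list[ChromPeak]:
    """Find peaks in a 1-D trace.

    Moving-average smoothing; candidate apexes are local maxima above both
    (baseline median + noise_k x robust noise SD) and min_height_frac x
    global max. Bounds run to the flanking local minima or the baseline
    crossing, whichever comes first; area is the trapezoidal integral above a
    straight line drawn between the bound points.
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if times.size < 5:
        raise InputError("trace too short for peak detection (need >= 5 points)")
    smoothed = _moving_average(signal, smooth_window)
    baseline = float(np.median(smoothed))
    noise = 1.4826 * float(np.median(np.abs(smoothed - baseline)))
    threshold = max(baseline + noise_k * max(noise, 1e-12),
                    min_height_frac * float(smoothed.max()))

    from scipy.signal import find_peaks as _fp

    apex_idx, _ = _fp(smoothed, height=threshold)
    peaks: list[ChromPeak] = []
    for i in apex_idx:
        lo = i
        while lo > 0 and smoothed[lo - 1] < smoothed[lo] and smoothed[lo - 1] > baseline:
            lo -= 1
        hi = i
        n = smoothed.size
        while hi < n - 1 and smoothed[hi + 1] < smoothed[hi] and smoothed[hi + 1] > baseline:
            hi += 1
        if lo == i or hi == i:
            continue
        seg_t = times[lo : hi + 1]
        seg_y = signal[lo : hi + 1]
        base = np.interp(seg_t, [seg_t[0], seg_t[-1]], [seg_y[0], seg_y[-1]])
        area = float(np.trapezoid(np.clip(seg_y - base, 0.0, None), seg_t))
        peaks.append(
            ChromPeak(
                apex_rt=float(times[i]),
                start=float(times[lo]),
                end=float(times[hi]),
                area=max(area, 0.0),
                height=float(signal[i]),
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# EIC extraction and UV matching
# ---------------------------------------------------------------------------


def extract_eic(
    run: ChromatographyRun, target_mz: float, tol: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-scan summed centroid intensity within |m/z - target| <= tol."""
    if tol <= 0:
        raise InputError("m/z tolerance must be positive")
    intensity = np.zeros(run.ms_times.size)
    for k, (mz, inten) in enumerate(run.ms_scans):
        mask = np.abs(np.asarray(mz) - target_mz) <= tol
        if mask.any():
            intensity[k] = float(np.asarray(inten)[mask].sum())
    return run.ms_times, intensity


def match_target(
    eic_peaks: Sequence[ChromPeak],
    uv_peaks: Sequence[ChromPeak],
    rt_tol: float = 0.1,
) -> list[tuple[ChromPeak, ChromPeak | None, set[str]]]:
    """Pair each EIC peak with the nearest UV apex within rt_tol.

    Ties (two UV apexes equidistant within 1e-9 min) go to the larger UV
    area and set the ``multiple-candidates`` flag; no UV peak within
    tolerance sets ``not-found``.
    """
    if rt_tol <= 0:
        raise InputError("rt tolerance must be positive")
    out = []
    for ep in eic_peaks:
        flags: set[str] = set()
        candidates = [(abs(up.apex_rt - ep.apex_rt), up) for up in uv_peaks]
        candidates = [(d, up) for d, up in candidates if d <= rt_tol]
        if not candidates:
            out.append((ep, None, {"not-found"}))
            continue
        dmin = min(d for d, _ in candidates)
        best = [up for d, up in candidates if abs(d - dmin) <= 1e-9]
        if len(best) > 1:
            flags.add("multiple-candidates")
        chosen = max(best, key=lambda up: up.area)
        out.append((ep, chosen, flags))
    return out


def conversion_percent(
    uv_peaks: Sequence[ChromPeak],
    matched: Sequence[ChromPeak],
    mode: ConversionMode = "area-percent",
    identified: Sequence[ChromPeak] | None = None,
    compound_id: str = "",
    matched_species: Sequence[tuple[str, float]] = (),
) -> ConversionResult:
    """Conversion% = 100 x matched UV area / total UV area.

    ``aggregate`` sums areas over several matched species (adduct + parent)
    before dividing; ``normalized-total`` divides by the area of
    MS-identified peaks only (``identified``) instead of all UV peaks.
    Duplicate ChromPeak objects in ``matched`` are counted once.
    """
    # dedupe by identity so a UV peak matched by two species counts once
    seen: list[ChromPeak] = []
    for p in matched:
        if not any(p is q for q in seen):
            seen.append(p)
    matched_area = sum(p.area for p in seen)
    if mode == "normalized-total":
        denom_peaks = identified if identified is not None else seen
    else:
        denom_peaks = uv_peaks
    total = sum(p.area for p in denom_peaks)
    if total <= 0:
        raise UndefinedConversionError("total UV peak area is zero")
    pct = float(np.clip(100.0 * matched_area / total, 0.0, 100.0))
    flags: set[str] = set()
    rt = None
    if seen:
        rt = max(seen, key=lambda p: p.area).apex_rt
    else:
        flags.add("not-found")
        pct = 0.0
    return ConversionResult(
        compound_id=compound_id,
        matched_species=list(matched_species),
        rt_reported=rt,
        conversion_pct=pct,
        mode=mode,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# library-level characterization
# ---------------------------------------------------------------------------


@dataclass
class PipelineParams:
    mz_tol: float = 0.5            # ion-trap scale
    rt_tol: float = 0.1            # min
    smooth_window: int = 5
    noise_k: float = 5.0
    min_height_frac: float = 0.01  # UV peaks below this fraction of max ignored
    mode: ConversionMode = "area-percent"


def characterize_run(
    run: ChromatographyRun,
    spec: ComplexSpec,
    params: PipelineParams | None = None,
    species: Sequence[IonSpecies] | None = None,
) -> ConversionResult:
    """Characterize one compound: detect its target ion(s) and integrate UV."""
    params = params or PipelineParams()
    if species is None:
        species = expected_ions(spec)
    uv_peaks = detect_peaks(
        run.uv_times, run.uv_signal,
        smooth_window=params.smooth_window,
        noise_k=params.noise_k,
        min_height_frac=params.min_height_frac,
    )
    matched: list[ChromPeak] = []
    labels: list[tuple[str, float]] = []
    flags: set[str] = set()
    for sp in species:
        pattern = isotope_pattern(sp.formula(spec.formula), z=sp.charge)
        t, eic = extract_eic(run, pattern.base_peak_mz, tol=params.mz_tol)
        if not np.any(eic > 0):
            continue
        try:
            eic_peaks = detect_peaks(t, eic, smooth_window=1,
                                     noise_k=params.noise_k, min_height_frac=0.05)
        except InputError:
            continue
        for _, uv_peak, f in match_target(eic_peaks, uv_peaks, rt_tol=params.rt_tol):
            flags |= f
            if uv_peak is not None:
                matched.append(uv_peak)
                labels.append((sp.label, uv_peak.apex_rt))
    mode = params.mode
    identified = matched if mode == "normalized-total" else None
    try:
        result = conversion_percent(
            uv_peaks, matched, mode=mode, identified=identified,
            compound_id=spec.id, matched_species=labels,
        )
    except UndefinedConversionError:
        result = ConversionResult(spec.id, labels, None, 0.0, mode, {"not-found"})
    result.flags |= flags
    return result


def characterize_library(
    runs: Mapping[str, ChromatographyRun],
    specs: Sequence[ComplexSpec],
    params: PipelineParams | None = None,
) -> pd.DataFrame:
    """Per-compound characterization table; missing runs become absent rows."""
    rows = []
    for spec in specs:
        run = runs.get(spec.id)
        if run is None:
            rows.append({"compound_id": spec.id, "rt_min": np.nan,
                         "conversion_pct": np.nan, "species": "",
                         "flags": "missing-run"})
            continue
        res = characterize_run(run, spec, params)
        rows.append({
            "compound_id": spec.id,
            "rt_min": res.rt_reported if res.rt_reported is not None else np.nan,
            "conversion_pct": res.conversion_pct,
            "species": ";".join(lbl for lbl, _ in res.matched_species),
            "flags": ";".join(sorted(res.flags)),
        })
    return pd.DataFrame(rows)


def library_summary(table: pd.DataFrame) -> tuple[float, float, str]:
    """Mean +/- SD conversion over characterized compounds, plus the
    integer-percent rendering used in library reporting (e.g. ``"75 ± 16%"``)."""
    vals = table["conversion_pct"].dropna().to_numpy()
    if vals.size == 0:
        raise InputError("no characterized compounds")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    return mean, sd, f"{round(mean):.0f} ± {round(sd):.0f}%"


# ---------------------------------------------------------------------------
# file dialect
# ---------------------------------------------------------------------------


def load_run(uv_csv: str, ms_csv: str, **metadata) -> ChromatographyRun:
    """Read the two-file tabular dialect: ``*.uv.csv`` (time_min, a254) and
    ``*.ms.csv`` (scan_time_min, mz, intensity; long format)."""
    uv = pd.read_csv(uv_csv)
    ms = pd.read_csv(ms_csv)
    times = []
    scans = []
    for t, grp in ms.groupby("scan_time_min", sort=True):
        times.append(float(t))
        scans.append((grp["mz"].to_numpy(float), grp["intensity"].to_numpy(float)))
    return ChromatographyRun(
        uv_times=uv["time_min"].to_numpy(float),
        uv_signal=uv["a254"].to_numpy(float),
        ms_times=np.asarray(times),
        ms_scans=scans,
        metadata=metadata,
    )


def save_run(run: ChromatographyRun, uv_csv: str, ms_csv: str) -> None:
    pd.DataFrame({"time_min": run.uv_times, "a254": run.uv_signal}).to_csv(
        uv_csv, index=False
    )
    rows = []
    for t, (mz, inten) in zip(run.ms_times, run.ms_scans):
        for m, i in zip(mz, inten):
            rows.append((t, m, i))
    pd.DataFrame(rows, columns=["scan_time_min", "mz", "intensity"]).to_csv(
        ms_csv, index=False
    )
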