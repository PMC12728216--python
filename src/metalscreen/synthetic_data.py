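"""Seeded generators for every input the pipeline consumes.

Each generator returns its dataset together with a :class:`TruthRecord`
holding the ground-truth parameters, so round-trip tests (and users) can
check recovery without external data. All randomness flows through a
``numpy`` generator seeded from the ``seed`` argument; same seed, same data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .formula import ElementalFormula
from .lcms_pipeline import ChromatographyRun
from .mass_iso import isotope_pattern
from .screening_analytics import DoseSeries, PlateRead, four_pl


@dataclass
class TruthRecord:
    kind: str
    seed: int
    parameters: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# chromatograms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimTarget:
    """One species to place in a simulated run."""

    formula: ElementalFormula
    charge: int
    rt: float        # min
    fraction: float  # of total UV area, in [0, 1]
    label: str = "M+"


def _gaussian(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def sim_chromatogram(
    targets: Sequence[SimTarget],
    noise_sd: float = 0.0,
    seed: int = 0,
    t_end: float = 10.0,
    uv_hz: float = 2.0,
    ms_hz: float = 1.0,
    peak_sd: float = 0.05,
    impurity_rt: float = 8.0,
    total_uv_area: float = 100.0,
    ms_scale: float = 1e5,
    compound_id: str = "sim",
) -> tuple[ChromatographyRun, TruthRecord]:
    """Simulate one LC-MS run.

    The UV trace is a sum of Gaussian peaks whose areas are proportional to
    the target fractions, plus an impurity peak absorbing the remaining
    fraction, on a baseline with additive Gaussian noise. MS scans carry each
    species' isotope envelope around its retention time with Poisson-like
    intensity noise.
    """
    fractions = [t.fraction for t in targets]
    if any(f < 0 for f in fractions) or sum(fractions) > 1 + 1e-9:
        raise InputError("fractions must be >= 0 and sum to <= 1")
    rng = np.random.default_rng(seed)
    warnings = []
    rts = [t.rt for t in targets] + ([impurity_rt] if sum(fractions) < 1 - 1e-9 else [])
    for i, a in enumerate(rts):
        for b in rts[i + 1:]:
            if abs(a - b) < 4 * peak_sd:
                warnings.append(f"co-elution: peaks at {a:.3f} and {b:.3f} min")

    uv_times = np.arange(0.0, t_end, 1.0 / (uv_hz * 60.0))  # times in min
    uv = np.zeros_like(uv_times)
    for tg in targets:
        uv += total_uv_area * tg.fraction * _gaussian(uv_times, tg.rt, peak_sd)
    rest = 1.0 - sum(fractions)
    if rest > 1e-9:
        uv += total_uv_area * rest * _gaussian(uv_times, impurity_rt, peak_sd)
    if noise_sd > 0:
        uv = uv + rng.normal(0.0, noise_sd, uv.shape)

    ms_times = np.arange(0.0, t_end, 1.0 / (ms_hz * 60.0))
    scans = []
    patterns = [isotope_pattern(tg.formula, z=tg.charge) for tg in targets]
    for t in ms_times:
        mzs: list[float] = []
        intens: list[float] = []
        for tg, pat in zip(targets, patterns):
            amp = np.exp(-0.5 * ((t - tg.rt) / peak_sd) ** 2)
            if amp < 1e-6:
                continue
            for mz, rel in pat.peaks:
                expected = ms_scale * amp * rel / 100.0 * max(tg.fraction, 0.05)
                if noise_sd > 0:
                    observed = float(rng.poisson(expected))
                else:
                    observed = expected
                if observed > 0:
                    mzs.append(mz)
                    intens.append(observed)
        order = np.argsort(mzs)
        scans.append((np.asarray(mzs)[order], np.asarray(intens)[order]))

    run = ChromatographyRun(
        uv_times=uv_times, uv_signal=uv, ms_times=ms_times, ms_scans=scans,
        metadata={"compound_id": compound_id},
    )
    truth = TruthRecord(
        kind="chromatogram",
        seed=seed,
        parameters={
            "compound_id": compound_id,
            "targets": [
                {"formula": tg.formula.to_hill(), "charge": tg.charge,
                 "rt": tg.rt, "fraction": tg.fraction, "label": tg.label}
                for tg in targets
            ],
            "conversion_pct": 100.0 * sum(fractions),
            "noise_sd": noise_sd,
            "peak_sd": peak_sd,
        },
        warnings=warnings,
    )
    return run, truth


# ---------------------------------------------------------------------------
# MIC plates
# ---------------------------------------------------------------------------


def growth_fraction(conc: float, true_mic: float, steepness: float = 9.0) -> float:
    """Logistic growth model: ~100% below the MIC, ~0% at and above it, with
    a transition one dilution step wide centred half a step below the MIC."""
    x = np.log2(conc) - (np.log2(true_mic) - 0.5)
    return float(100.0 / (1.0 + np.exp(steepness * x)))


def sim_mic_plate(
    true_mics: Mapping[str, float],
    grid: Sequence[float],
    noise_sd: float = 2.0,
    seed: int = 0,
    plate_id: str = "simplate",
    blank_signal: float = 0.05,
    ctrl_signal: float = 1.0,
) -> tuple[PlateRead, TruthRecord]:
    """One 8 x 12 OD600 plate: up to 8 compounds (one per row), the dilution
    grid across the leading columns, growth controls in column 11 and blanks
    in column 12. ``noise_sd`` is in percent-of-control units."""
    ids = list(true_mics)
    if len(ids) > 8:
        raise InputError("at most 8 compounds per plate")
    if len(grid) > 10:
        raise InputError("dilution grid longer than available columns")
    rng = np.random.default_rng(seed)
    span = ctrl_signal - blank_signal
    g = np.zeros((8, 12))
    g[:, 10] = ctrl_signal
    g[:, 11] = blank_signal
    for r, cid in enumerate(ids):
        for k, conc in enumerate(grid):
            frac = growth_fraction(conc, true_mics[cid])
            noisy = frac + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            g[r, k] = blank_signal + max(noisy, 0.0) / 100.0 * span
    if noise_sd > 0:
        g[:, 10] += rng.normal(0.0, noise_sd / 100.0 * span, 8)
        g[:, 11] += rng.normal(0.0, noise_sd / 100.0 * span / 4, 8)
    g = np.clip(g, 0.0, None)
    rows = "ABCDEFGH"
    plate = PlateRead(
        plate_id=plate_id,
        grid=g,
        channel="OD600",
        growth_ctrl_wells=tuple(f"{r}11" for r in rows),
        blank_wells=tuple(f"{r}12" for r in rows),
        layout={"rows": {rows[i]: cid for i, cid in enumerate(ids)},
                "concentrations": list(grid)},
    )
    truth = TruthRecord(
        kind="mic_plate", seed=seed,
        parameters={"true_mics": dict(true_mics), "grid": list(grid),
                    "noise_sd": noise_sd},
    )
    return plate, truth


# ---------------------------------------------------------------------------
# dose-response curves
# ---------------------------------------------------------------------------


def sim_dose_response(
    true_ec50: float,
    hill: float = 1.0,
    bottom: float = 0.0,
    top: float = 100.0,
    n_points: int = 8,
    start: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DoseSeries, TruthRecord]:
    """Sample a 4PL curve on a 2-fold dilution grid with Gaussian noise.

    ``noise_sd`` is in response units (% of control); for relative noise pass
    e.g. ``0.05 * (top - bottom)``.
    """
    rng = np.random.default_rng(seed)
    if start is None:
        start = true_ec50 * 16.0
    conc = np.array([start / 2.0**k for k in range(n_points)])
    resp = four_pl(conc, bottom, top, hill, true_ec50)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, resp.shape)
    series = DoseSeries(concentrations=tuple(conc), responses=tuple(resp))
    truth = TruthRecord(
        kind="dose_response", seed=seed,
        parameters={"ec50": true_ec50, "hill": hill, "bottom": bottom,
                    "top": top, "noise_sd": noise_sd, "n_points": n_points},
    )
    return series, truth


# ---------------------------------------------------------------------------
# binary activity datasets
# ---------------------------------------------------------------------------


def sim_activity_dataset(
    n: int,
    rule: Mapping[int, float],
    label_noise: float = 0.0,
    seed: int = 0,
    n_bits: int = 598,
    density: float = 0.25,
    causal_density: float | None = None,
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray, TruthRecord]:
    """Bernoulli bit matrix with labels from a linear rule on causal bits.

    label = 1 iff sum_b rule[b] * X[:, b] > threshold (default: half the
    smallest positive single-bit weight, i.e. any causal bit activates),
    then flipped with probability ``label_noise``. ``density`` sets the
    background bit density; ``causal_density`` (default: same) the density of
    the causal bits — a sparse background with denser causal bits yields a
    cleanly separable dataset.
    """
    rng = np.random.default_rng(seed)
    X = (rng.random((n, n_bits)) < density).astype(np.int8)
    if causal_density is not None:
        for b in rule:
            X[:, b] = (rng.random(n) < causal_density).astype(np.int8)
    score = np.zeros(n)
    for b, w in rule.items():
        score += w * X[:, b]
    if threshold is None:
        threshold = 0.5 * min(abs(w) for w in rule.values())
    y = (score > threshold).astype(int)
    flipped = rng.random(n) < label_noise
    y = np.where(flipped, 1 - y, y)
    truth = TruthRecord(
        kind="activity_dataset", seed=seed,
        parameters={"n": n, "rule": {str(k): v for k, v in rule.items()},
                    "threshold": threshold, "label_noise": label_noise,
                    "density": density, "n_bits": n_bits,
                    "n_flipped": int(flipped.sum())},
    )
    return X, y, truth
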