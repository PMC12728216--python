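"""Plate-based screening analytics.

Covers the broth-microdilution workflow (2-fold dilution grids, % of
control, MIC calling with a highest-contiguous-block rule), single-dose
toxicity classification, four-parameter-logistic dose-response fitting
(CC50, HC10/HC50) and therapeutic-index computation.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateControlError, InputError

#: growth fraction (% of control) at or below which a well counts as fully
#: inhibited; the operational definition of "complete inhibition"
DEFAULT_INHIBITION_THRESHOLD = 10.0

#: MIC cutoff for the binary activity label used by the SAR model
ACTIVITY_CUTOFF_UM = 6.25

#: single-dose viability below which a compound is labelled toxic
TOXICITY_THRESHOLD_PCT = 50.0


def round_conc(c: float) -> float:
    """Reporting convention for dilution-grid concentrations.

    Values >= 1 round to 3 significant figures (12.5, 6.25, 3.13, 1.56);
    values < 1 round to 2 significant figures (0.78, 0.39, 0.20, 0.049) —
    the convention used in the printed grids.
    """
    if c <= 0:
        raise InputError("concentration must be positive")
    sig = 3 if c >= 1 else 2
    # half-up (not banker's) rounding so 3.125 -> 3.13 as printed
    exponent = math.floor(math.log10(c))
    q = decimal.Decimal(1).scaleb(exponent - sig + 1)
    return float(decimal.Decimal(repr(c)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def dilution_grid(start: float, factor: float = 2.0, n_steps: int = 7) -> list[float]:
    """Serial-dilution grid [start, start/factor, ...] of length n_steps + 1,
    rounded per :func:`round_conc`."""
    if start <= 0 or factor <= 1 or n_steps < 0:
        raise InputError("need start > 0, factor > 1, n_steps >= 0")
    return [round_conc(start / factor**k) for k in range(n_steps + 1)]


def percent_of_control(signal: float, growth_ctrl_mean: float, blank_mean: float) -> float:
    """100 x (signal - blank) / (ctrl - blank), clipped below at 0."""
    if growth_ctrl_mean <= blank_mean:
        raise DegenerateControlError("growth control does not exceed blank")
    return max(0.0, 100.0 * (signal - blank_mean) / (growth_ctrl_mean - blank_mean))


@dataclass(frozen=True)
class DoseSeries:
    """Responses (% of control) on a strictly decreasing concentration grid."""

    concentrations: tuple[float, ...]  # uM, strictly decreasing
    responses: tuple[float, ...]
    replicates: int = 1

    def __post_init__(self):
        if len(self.concentrations) != len(self.responses):
            raise InputError("concentrations and responses differ in length")
        c = np.asarray(self.concentrations)
        if np.any(c <= 0):
            raise InputError("concentrations must be positive")
        if c.size > 1 and not np.all(np.diff(c) < 0):
            raise InputError("concentrations must be strictly decreasing")


@dataclass(frozen=True)
class MICResult:
    value: float | None           # uM; None when censored
    censored: bool
    grid: tuple[float, ...]
    threshold: float

    def render(self) -> str:
        return "-" if self.censored else f"{self.value:g}"


def call_mic(series: DoseSeries, inhibit_threshold: float = DEFAULT_INHIBITION_THRESHOLD) -> MICResult:
    """MIC = lowest concentration of the contiguous fully-inhibited block that
    extends to the top of the grid.

    A well is inhibited when growth <= threshold; any growth at a higher
    concentration breaks the block (so a non-monotone series inhibited at
    50, growing at 25 and inhibited again at 12.5 is called at 50). No
    inhibited block at the top -> censored (rendered ``-``).
    """
    mic = None
    for c, g in zip(series.concentrations, series.responses):  # high -> low
        if g <= inhibit_threshold:
            mic = c
        else:
            break
    return MICResult(
        value=mic,
        censored=mic is None,
        grid=series.concentrations,
        threshold=inhibit_threshold,
    )


def binarize_activity(mic: MICResult, cutoff: float = ACTIVITY_CUTOFF_UM) -> int:
    """1 iff the MIC is uncensored and <= cutoff, else 0."""
    return int((not mic.censored) and mic.value <= cutoff)


def classify_toxicity(viability_pct_at_50um: float,
                      threshold: float = TOXICITY_THRESHOLD_PCT) -> bool:
    """Toxic iff single-dose viability is strictly below the threshold."""
    if viability_pct_at_50um < 0:
        raise InputError("viability cannot be negative")
    return viability_pct_at_50um < threshold


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------


@dataclass
class FourPLFit:
    bottom: float
    top: float
    hill: float
    ec50: float
    rss: float
    converged: bool


def four_pl(c: np.ndarray, bottom: float, top: float, hill: float, ec50: float) -> np.ndarray:
    """resp = bottom + (top - bottom) / (1 + (ec50 / c) ** hill).

    hill > 0 gives a response rising with concentration, hill < 0 falling.
    """
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / c) ** hill)


def fit_4pl(conc: Sequence[float], resp: Sequence[float]) -> FourPLFit:
    """Least-squares 4PL fit.

    Initialization: bottom/top from the response extremes, ec50 at the
    geometric mean of the concentration range, hill +/-1 depending on the
    response direction. Flat responses or failed optimizations return
    ``converged=False`` with nan parameters.
    """
    c = np.asarray(conc, dtype=float)
    r = np.asarray(resp, dtype=float)
    if np.unique(c).size < 4:
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, math.nan, False)
    span = float(r.max() - r.min())
    if span < 1e-9 * max(1.0, abs(float(r.max()))):
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, math.nan, False)
    rising = float(np.corrcoef(np.log(c), r)[0, 1]) >= 0
    hill0 = 1.0 if rising else -1.0
    p0 = [float(r.min()), float(r.max()), hill0,
          float(np.exp(np.mean(np.log(c))))]
    lo = [-np.inf, -np.inf, 0.05 if rising else -20.0, c.min() / 1e4]
    hi = [np.inf, np.inf, 20.0 if rising else -0.05, c.max() * 1e4]
    try:
        popt, _ = curve_fit(four_pl, c, r, p0=p0, bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError):
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, math.nan, False)
    bottom, top, hill, ec50 = (float(v) for v in popt)
    if bottom > top:  # canonical orientation: bottom < top, hill sign flips
        bottom, top, hill = top, bottom, -hill
    rss = float(np.sum((four_pl(c, bottom, top, hill, ec50) - r) ** 2))
    return FourPLFit(bottom, top, hill, ec50, rss, True)


def ec_at(fit: FourPLFit, p: float) -> float:
    """Invert the fitted curve at response level ``p`` (same units).

    For a normalized lysis curve (bottom 0, top 100, hill 1, ec50 = HC50)
    ec_at(fit, 10) is the HC10.
    """
    if not fit.converged:
        raise InputError("cannot invert a failed fit")
    if not (min(fit.bottom, fit.top) < p < max(fit.bottom, fit.top)):
        raise InputError(f"response level {p} outside fitted range")
    q = (fit.top - fit.bottom) / (p - fit.bottom) - 1.0
    if q <= 0:
        raise InputError("response level not reachable on this branch")
    return float(fit.ec50 * q ** (-1.0 / fit.hill))


# ---------------------------------------------------------------------------
# therapeutic index
# ---------------------------------------------------------------------------


def round_half_away(x: float) -> int:
    """Round to nearest integer with halves away from zero (36.5 -> 37)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class TIResult:
    ti_lo: int
    ti_hi: int
    numerator: float
    mic_lo: float
    mic_hi: float

    def render(self) -> str:
        return str(self.ti_lo) if self.ti_lo == self.ti_hi else f"{self.ti_lo}–{self.ti_hi}"


def therapeutic_index(
    cc50: float,
    hc10: float | None,
    mic_lo: float,
    mic_hi: float | None = None,
) -> TIResult:
    """TI = min(CC50, HC10) / MIC, rounded half away from zero.

    A censored HC10 (None or +inf) drops out of the numerator. An MIC range
    [mic_lo, mic_hi] yields a TI range [numerator/mic_hi, numerator/mic_lo];
    a single MIC yields a single TI.
    """
    if cc50 <= 0 or mic_lo <= 0:
        raise InputError("CC50 and MIC must be positive")
    if mic_hi is None:
        mic_hi = mic_lo
    if mic_hi < mic_lo:
        raise InputError("mic_hi must be >= mic_lo")
    numerator = cc50 if hc10 is None or math.isinf(hc10) else min(cc50, hc10)
    return TIResult(
        ti_lo=round_half_away(numerator / mic_hi),
        ti_hi=round_half_away(numerator / mic_lo),
        numerator=numerator,
        mic_lo=mic_lo,
        mic_hi=mic_hi,
    )


# ---------------------------------------------------------------------------
# plate container
# ---------------------------------------------------------------------------


@dataclass
class PlateRead:
    """8 x 12 plate of signals plus designated control wells."""

    plate_id: str
    grid: np.ndarray  # shape (8, 12)
    channel: str = "OD600"
    growth_ctrl_wells: tuple[str, ...] = ()
    blank_wells: tuple[str, ...] = ()
    layout: dict = field(default_factory=dict)  # e.g. row -> compound id

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (8, 12):
            raise InputError("plate grid must be 8 x 12")
        if np.any(self.grid < 0):
            raise InputError("signals must be non-negative")

    @staticmethod
    def well_index(well: str) -> tuple[int, int]:
        row = ord(well[0].upper()) - ord("A")
        col = int(well[1:]) - 1
        if not (0 <= row < 8 and 0 <= col < 12):
            raise InputError(f"invalid well {well!r}")
        return row, col

    def value(self, well: str) -> float:
        r, c = self.well_index(well)
        return float(self.grid[r, c])

    def control_means(self) -> tuple[float, float]:
        if not self.growth_ctrl_wells or not self.blank_wells:
            raise DegenerateControlError("control wells not designated")
        g = float(np.mean([self.value(w) for w in self.growth_ctrl_wells]))
        b = float(np.mean([self.value(w) for w in self.blank_wells]))
        return g, b

    def dose_series(self, row: str, concentrations: Sequence[float]) -> DoseSeries:
        """Interpret the first len(concentrations) wells of a row as a
        dilution series, normalized to % of control."""
        g, b = self.control_means()
        r, _ = self.well_index(f"{row}1")
        resp = tuple(
            percent_of_control(float(self.grid[r, k]), g, b)
            for k in range(len(concentrations))
        )
        return DoseSeries(concentrations=tuple(concentrations), responses=resp)
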