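"""Endpoint summaries of transfer-hydrogenation kinetic traces and
solution-stability checks.

Two assay channels are summarized: a fluorescence product-formation assay
(delta_fl = final - initial reading) and an absorbance consumption assay
(delta_abs = maximum - final reading). Hit thresholds follow the screen
definitions: fluorescence hit at delta_fl > 15000 (strict) and total
conversion at delta_abs >= 2.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InputError

FLUORESCENCE_HIT_THRESHOLD = 15000.0
TOTAL_CONVERSION_ABS = 2.0


@dataclass
class KineticTrace:
    times: np.ndarray     # min, increasing
    signals: np.ndarray   # fluorescence (arb. units) or absorbance (A.U.)
    channel: dict = field(default_factory=dict)  # e.g. {"lambda_ex": 350, ...}

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.size < 2:
            raise InputError("kinetic trace needs at least 2 points")
        if not np.all(np.diff(self.times) > 0):
            raise InputError("times must be increasing")


@dataclass(frozen=True)
class KineticSummary:
    compound_id: str
    delta_fl: float | None = None
    delta_abs: float | None = None
    fluorescence_hit: bool = False
    total_conversion: bool = False


def average_traces(traces: Sequence[KineticTrace]) -> KineticTrace:
    """Point-wise mean of replicate traces (must share the time axis)."""
    if not traces:
        raise InputError("no traces to average")
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise InputError("replicate traces must share their time axis")
    return KineticTrace(
        times=t0.copy(),
        signals=np.mean([tr.signals for tr in traces], axis=0),
        channel=dict(traces[0].channel),
    )


def delta_fluorescence(trace: KineticTrace) -> float:
    """Final minus initial reading (may be negative)."""
    return float(trace.signals[-1] - trace.signals[0])


def delta_absorbance(trace: KineticTrace) -> float:
    """Global maximum minus final reading (>= 0 by construction)."""
    return float(trace.signals.max() - trace.signals[-1])


def flag_hits(
    summaries: Sequence[KineticSummary],
    fl_threshold: float = FLUORESCENCE_HIT_THRESHOLD,
    abs_total: float = TOTAL_CONVERSION_ABS,
) -> list[KineticSummary]:
    """Re-flag summaries: fluorescence hit iff delta_fl > fl_threshold
    (strict), total conversion iff delta_abs >= abs_total."""
    out = []
    for s in summaries:
        out.append(
            KineticSummary(
                compound_id=s.compound_id,
                delta_fl=s.delta_fl,
                delta_abs=s.delta_abs,
                fluorescence_hit=s.delta_fl is not None and s.delta_fl > fl_threshold,
                total_conversion=s.delta_abs is not None and s.delta_abs >= abs_total,
            )
        )
    return out


def summarize(
    compound_id: str,
    fl_trace: KineticTrace | None = None,
    abs_trace: KineticTrace | None = None,
) -> KineticSummary:
    s = KineticSummary(
        compound_id=compound_id,
        delta_fl=delta_fluorescence(fl_trace) if fl_trace is not None else None,
        delta_abs=delta_absorbance(abs_trace) if abs_trace is not None else None,
    )
    return flag_hits([s])[0]


def stability_change(
    spectrum_t0: Sequence[tuple[float, float]],
    spectrum_t_end: Sequence[tuple[float, float]],
    lambda_ref: float = 320.0,
) -> float:
    """Percent absorbance change at the reference wavelength between two
    spectra (lists of (wavelength nm, absorbance)); <10% counts as stable."""

    def at(spec: Sequence[tuple[float, float]]) -> float:
        wl = np.asarray([p[0] for p in spec], dtype=float)
        ab = np.asarray([p[1] for p in spec], dtype=float)
        order = np.argsort(wl)
        wl, ab = wl[order], ab[order]
        if not (wl[0] <= lambda_ref <= wl[-1]):
            raise InputError(f"spectrum does not cover {lambda_ref} nm")
        return float(np.interp(lambda_ref, wl, ab))

    a0 = at(spectrum_t0)
    a1 = at(spectrum_t_end)
    if a0 == 0:
        raise InputError("reference absorbance at t0 is zero")
    return 100.0 * abs(a1 - a0) / a0
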