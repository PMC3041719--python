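"""Rate-dependent electrical cycle: intervals, waveform, mechanical triggers.

The simulator is paced by a fixed-rate artificial pacemaker.  Each cardiac
cycle's electrical intervals (P duration, PR, QRS, QT) are second-order
polynomials of the cycle length RR = 60/HR, so the electrical cycle
compresses realistically as the rate rises: the QT interval shortens, the
diastolic fraction of the cycle shrinks.  The interval set drives two
consumers:

* a synthesized single-lead ECG waveform (unscaled, display/teaching only),
  assembled from smooth parametric fragments time-scaled to the intervals;
* the mechanical trigger schedule — atrial and ventricular contraction
  onsets and systolic durations — obtained by shifting the electrical
  events by a fixed electromechanical delay.

The diastolic heart fraction DHF = 1 − (delay + QT)/RR is the fraction of
the cycle spent in mechanical diastole; it falls from ~0.66 at 40 min^-1 to
~0.35 at 160 min^-1 and is the quantity that limits ventricular filling
(and, physiologically, myocardial perfusion) at high rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigError, TimingError

Coefficients = Mapping[str, tuple[float, float, float]]

#: Interval quadratics X(rr) = a + b·rr + c·rr² (seconds), anchored to
#: textbook resting values at rr = 1 s (QT 0.40 s, PR 0.16 s, QRS 0.09 s,
#: P 0.09 s) with the rate dependence concentrated in QT.
DEFAULT_COEFFICIENTS: Coefficients = {
    "p_dur": (0.07, 0.02, 0.0),
    "pr": (0.10, 0.06, 0.0),
    "qrs": (0.09, 0.0, 0.0),
    "qt": (0.086667, 0.402222, -0.088889),
}

HR_MIN, HR_MAX = 40.0, 160.0

#: repolarization tail of QT excluded from mechanical systole
SYSTOLE_QT_FRACTION = 0.9
#: atrial mechanical systole lasts twice the P-wave duration
ATRIAL_SYSTOLE_P_FACTOR = 2.0


@dataclass(frozen=True)
class EcgTiming:
    """One cycle's interval set (all in seconds; dhf dimensionless)."""

    rr: float
    p_dur: float
    pr: float      # P onset to QRS onset
    qrs: float
    qt: float      # QRS onset to T end
    dhf: float     # diastolic heart fraction of the cycle

    def check(self) -> "EcgTiming":
        ok = (0 < self.p_dur < self.pr < self.rr
              and 0 < self.qrs < self.qt < self.rr
              and 0 < self.dhf < 1
              and self.pr + self.qt < self.rr)
        if not ok:
            raise ConfigError(f"inconsistent ECG timing: {self}")
        return self


@dataclass(frozen=True)
class TriggerSchedule:
    """Mechanical onsets/durations within the cycle (seconds from P onset)."""

    atrial_onset: float
    ventricular_onset: float
    systolic_duration_atrial: float
    systolic_duration_ventricular: float


def _poly(coeffs: tuple[float, float, float], rr: float) -> float:
    a, b, c = coeffs
    return a + b * rr + c * rr * rr


def timing_for_rate(hr: float,
                    coeffs: Coefficients = DEFAULT_COEFFICIENTS,
                    electromechanical_delay: float = 0.02) -> EcgTiming:
    """Interval set for a heart rate in [40, 160] min^-1.

    ``rr = 60/hr``; each interval is its quadratic evaluated at rr; the
    diastolic heart fraction is measured against mechanical systole:
    ``dhf = 1 − (delay + qt)/rr``.
    """
    if not (HR_MIN <= hr <= HR_MAX):
        raise ValueError(f"hr={hr} outside [{HR_MIN:g}, {HR_MAX:g}] min^-1")
    rr = 60.0 / hr
    p_dur = _poly(coeffs["p_dur"], rr)
    pr = _poly(coeffs["pr"], rr)
    qrs = _poly(coeffs["qrs"], rr)
    qt = _poly(coeffs["qt"], rr)
    dhf = 1.0 - (electromechanical_delay + qt) / rr
    return EcgTiming(rr=rr, p_dur=p_dur, pr=pr, qrs=qrs, qt=qt, dhf=dhf).check()


def validate_coefficients(coeffs: Coefficients,
                          electromechanical_delay: float = 0.02) -> Coefficients:
    """Reject coefficient tables that break any timing invariant.

    Evaluated over the whole supported grid hr = 40..160 min^-1 in steps of
    1 so that a bad table fails at load time, not mid-simulation.
    """
    missing = {"p_dur", "pr", "qrs", "qt"} - set(coeffs)
    if missing:
        raise ConfigError(f"missing ECG coefficient entries: {sorted(missing)}")
    for hr in range(int(HR_MIN), int(HR_MAX) + 1):
        try:
            timing_for_rate(float(hr), coeffs, electromechanical_delay)
        except ConfigError as exc:
            raise ConfigError(f"ECG coefficients invalid at hr={hr}: {exc}") from exc
    return coeffs


def trigger_schedule(timing: EcgTiming, delay: float) -> TriggerSchedule:
    """Mechanical trigger times: electrical events shifted by ``delay``.

    Ventricular systole covers 90 % of QT (the last 10 % is repolarization
    without pressure generation); atrial systole lasts twice the P duration,
    so the atrial kick completes shortly after ventricular onset.
    """
    if delay < 0:
        raise ValueError("electromechanical delay must be >= 0")
    sched = TriggerSchedule(
        atrial_onset=delay,
        ventricular_onset=timing.pr + delay,
        systolic_duration_atrial=ATRIAL_SYSTOLE_P_FACTOR * timing.p_dur,
        systolic_duration_ventricular=SYSTOLE_QT_FRACTION * timing.qt,
    )
    if sched.ventricular_onset + sched.systolic_duration_ventricular >= timing.rr:
        raise TimingError(
            f"ventricular systole ends at "
            f"{sched.ventricular_onset + sched.systolic_duration_ventricular:.3f} s, "
            f"past the cycle end {timing.rr:.3f} s")
    return sched


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

#: fixed fragment amplitudes (arbitrary units; the output is unscaled)
P_AMPLITUDE = 0.15
T_AMPLITUDE = 0.30
QRS_AMPLITUDES = (-0.10, 1.0, -0.20)   # Q, R, S lobes
QRS_LOBE_FRACTIONS = (0.2, 0.5, 0.3)   # of the QRS duration
T_QT_FRACTION = 0.45                   # T-wave width as a fraction of QT


def _hump(tau: np.ndarray, width: float, amplitude: float) -> np.ndarray:
    """Smooth unimodal raised-cosine bump on [0, width], zero outside."""
    out = np.zeros_like(tau)
    inside = (tau >= 0.0) & (tau <= width)
    out[inside] = amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau[inside] / width))
    return out


def _qrs(tau: np.ndarray, width: float) -> np.ndarray:
    """Triphasic QRS: three half-sine lobes (Q down, R up, S down)."""
    out = np.zeros_like(tau)
    start = 0.0
    for amp, frac in zip(QRS_AMPLITUDES, QRS_LOBE_FRACTIONS):
        w = frac * width
        inside = (tau >= start) & (tau <= start + w)
        out[inside] += amp * np.sin(np.pi * (tau[inside] - start) / w)
        start += w
    return out


def waveform(timing: EcgTiming, t: np.ndarray) -> np.ndarray:
    """Evaluate the synthesized ECG at times ``t`` within one cycle.

    P occupies [0, p_dur], QRS [pr, pr+qrs], the T wave ends at pr+qt; the
    baseline is exactly zero elsewhere.  Fragment shapes are fixed and only
    time-scaled to the interval durations.
    """
    t = np.asarray(t, dtype=float) % timing.rr
    t_width = T_QT_FRACTION * timing.qt
    t_start = timing.pr + timing.qt - t_width
    return (_hump(t, timing.p_dur, P_AMPLITUDE)
            + _qrs(t - timing.pr, timing.qrs)
            + _hump(t - t_start, t_width, T_AMPLITUDE))


def synthesize_cycle(timing: EcgTiming, resolution: float = 0.001):
    """One full cycle of (time, amplitude) samples at the given resolution.

    Returns a pair of numpy arrays ``(time_s, ecg_au)`` covering
    [0, rr) at step ``resolution`` (must be ≤ 1 ms).
    """
    if resolution > 0.001 + 1e-12:
        raise ValueError("ECG resolution must be <= 1 ms")
    n = int(round(timing.rr / resolution))
    t = np.arange(n) * resolution
    return t, waveform(timing, t)
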