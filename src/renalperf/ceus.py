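"""Contrast-enhanced ultrasound time-intensity-curve (TIC) parameterization.

For each ROI curve the seven standard bolus perfusion parameters are
computed from the raw samples:

* PI  -- peak intensity: curve maximum minus the pre-rise baseline.
* WiR -- wash-in rate: OLS slope of the ascending samples whose
  baseline-subtracted intensity lies between 10% and 85% of PI.
* WoR -- wash-out rate: OLS slope of the descending samples between 85%
  and 40% of PI (negative).
* TI / TO -- times where the ascending / descending regression lines cross
  the baseline level (x-intercepts of the baseline-subtracted lines).
* TTP -- time of peak enhancement from injection (t = 0).
* RT = TTP - TI (rise time), FT = TO - TTP (fall time).
* AUC -- trapezoidal area of the baseline-subtracted curve from TI to TO.

Intensity-related parameters (PI, WiR, AUC) reflect blood volume;
time-related parameters (TTP, RT, FT) reflect blood velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import InvalidInputError, TimeIntensityCurve

_EPS = 1e-12


@dataclass
class TICParameters:
    """The seven perfusion parameters plus the two regression intercepts."""

    pi: float
    wir: float
    wor: float
    ti: float
    to: float
    rt: float
    ft: float
    ttp: float
    auc: float
    baseline: float
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "PI": self.pi, "WiR": self.wir, "WoR": self.wor, "TI": self.ti,
            "TO": self.to, "RT": self.rt, "FT": self.ft, "TTP": self.ttp,
            "AUC": self.auc,
        }


def average_roi_tics(tics: list[TimeIntensityCurve],
                     roi_class: str | None = None) -> TimeIntensityCurve:
    """Pointwise mean of same-grid ROI curves (3 cortical / 2 medullary ROIs
    in the standard layout; other counts are averaged with a warning)."""
    if not tics:
        raise InvalidInputError("no curves to average")
    t0 = tics[0].time
    for tic in tics[1:]:
        if tic.time.shape != t0.shape or not np.allclose(tic.time, t0):
            raise InvalidInputError("curves must share the time grid")
    cls = roi_class or tics[0].roi_class
    expected = {"cortex": 3, "medulla": 2}.get(cls)
    if expected is not None and len(tics) != expected:
        warnings.warn(f"{cls} average from {len(tics)} curves "
                      f"(standard layout uses {expected})", stacklevel=2)
    mean = np.mean([tic.intensity for tic in tics], axis=0)
    return TimeIntensityCurve(time=t0, intensity=mean, roi_class=cls,
                              baseline_window=tics[0].baseline_window)


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and intercept of y = a + b t by ordinary least squares."""
    b, a = np.polyfit(t, y, 1)
    return float(b), float(a)


def tic_parameters(tic: TimeIntensityCurve, smooth: bool = False,
                   auc_baseline_subtracted: bool = True,
                   wir_band_mode: str = "fraction-of-peak") -> TICParameters:
    """Compute the TIC perfusion parameters from a sampled curve.

    The ascending regression band selects pre-peak samples with
    baseline-subtracted intensity in [0.10*PI, 0.85*PI] (the
    fraction-of-peak reading of "10% above baseline"); pass
    ``wir_band_mode='above-baseline'`` for the literal 1.10 x baseline lower
    edge.  Peak ties break to the earliest sample.  ``smooth`` applies an
    optional 3-sample moving average before analysis (off by default).
    """
    t = tic.time
    y = np.asarray(tic.intensity, dtype=float)
    if smooth:
        y = np.convolve(y, np.ones(3) / 3, mode="same")
    baseline = float(np.mean(y[: tic.baseline_window]))
    z = y - baseline

    flags: list[str] = []
    ipk = int(np.argmax(z))  # argmax returns the earliest maximal sample
    pi = float(z[ipk])
    ttp = float(t[ipk])
    if pi <= 0:
        raise InvalidInputError("curve has no enhancement above baseline")

    if wir_band_mode == "above-baseline":
        lo_asc = 0.10 * baseline
    else:
        lo_asc = 0.10 * pi
    asc = (np.arange(t.size) <= ipk) & (z >= lo_asc - _EPS) & (z <= 0.85 * pi + _EPS)
    desc = (np.arange(t.size) > ipk) & (z >= 0.40 * pi - _EPS) & (z <= 0.85 * pi + _EPS)
    if asc.sum() < 2 or desc.sum() < 2:
        flags.append("empty-regression-band")
        nan = float("nan")
        return TICParameters(pi=pi, wir=nan, wor=nan, ti=nan, to=nan, rt=nan,
                             ft=nan, ttp=ttp, auc=nan, baseline=baseline,
                             flags=tuple(flags))

    wir, a_in = _ols_line(t[asc], z[asc])
    wor, a_out = _ols_line(t[desc], z[desc])
    ti = -a_in / wir
    to = -a_out / wor
    if to > t[-1]:
        flags.append("TO-extrapolated")

    auc = _auc(t, z if auc_baseline_subtracted else y, ti, to)
    return TICParameters(pi=pi, wir=wir, wor=wor, ti=ti, to=to,
                         rt=ttp - ti, ft=to - ttp, ttp=ttp, auc=auc,
                         baseline=baseline, flags=tuple(flags))


def _auc(t: np.ndarray, z: np.ndarray, ti: float, to: float) -> float:
    """Trapezoidal integral of the sampled curve between TI and TO, with
    linear interpolation at both endpoints (clipped to the record)."""
    lo = max(ti, float(t[0]))
    hi = min(to, float(t[-1]))
    if hi <= lo:
        return 0.0
    grid = t[(t > lo) & (t < hi)]
    tt = np.concatenate(([lo], grid, [hi]))
    zz = np.interp(tt, t, z)
    return float(np.trapezoid(zz, tt))
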