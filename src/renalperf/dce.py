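"""Dynamic contrast-enhanced MRI analysis.

Covers signal-to-concentration conversion, arterial-input-function (AIF)
modeling and extraction with configurable aortic ROI placement, and four
renal plasma-flow analyses operating on ROI-level curves:

* MS   -- maximum slope: F_p = max dC_t/dt / max c_a.
* MF   -- model-free: regularized discrete deconvolution of the tissue
  curve by the AIF; F_p = max of the impulse-response function.
* C2UM -- two-compartment uptake model: plasma compartment plus an
  irreversible trapping compartment (tubular uptake),
      v_p dc_p/dt = F_p c_a - (F_p + F_t) c_p,   dC_u/dt = F_t c_p.
* C2FM -- two-compartment filtration model: the tubular compartment drains,
      v_t dc_t/dt = F_t (c_p - c_t),
  with mean tubular transit time T_t = v_t / F_t.

Flows are in mL/min/100 mL of tissue, volume fractions in mL/100 mL.
Derived RBF converts plasma flow to whole-blood flow per tissue mass,
RBF = F_p / ((1 - Hct) * rho), with hematocrit Hct and tissue density rho.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .types import AIFCurve, DynamicSeries, InvalidInputError

PK_MODELS = ("MS", "MF", "C2UM", "C2FM")

#: default AIF placement tags -> (delay s, dispersion s); the reference
#: placement (25 mm cranial of the renal artery) carries no extra delay.
DEFAULT_PLACEMENTS: dict[str, tuple[float, float]] = {
    "Cr25": (0.0, 0.0),
    "Cr12": (0.5, 0.5),
    "Ca": (1.0, 1.0),
    "AD": (1.5, 2.0),
}


# ---------------------------------------------------------------------------
# signal -> concentration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SPGRConstants:
    """Spoiled-gradient-echo sequence constants for full conversion."""

    t10: float = 1.4       # precontrast T1, s
    r1: float = 3.6        # relaxivity, 1/mM/s
    tr: float = 0.0048     # repetition time, s
    flip_deg: float = 17.0


def spgr_signal(c: np.ndarray, m0: float, const: SPGRConstants) -> np.ndarray:
    """Forward SPGR signal for concentration ``c`` (mM)."""
    r1 = 1.0 / const.t10 + const.r1 * np.asarray(c, dtype=float)
    e1 = np.exp(-const.tr * r1)
    a = np.radians(const.flip_deg)
    return m0 * np.sin(a) * (1 - e1) / (1 - np.cos(a) * e1)


def signal_to_concentration(series: DynamicSeries, mode: str = "linear",
                            scale: float = 1.0,
                            spgr: SPGRConstants | None = None) -> np.ndarray:
    """Convert a dynamic signal to tracer concentration.

    linear mode: C = scale * (S - S0) / S0 with S0 the baseline mean
    (relative enhancement).  spgr mode: exact inversion of the
    spoiled-gradient-echo signal equation using ``spgr`` constants, with M0
    calibrated from the baseline.
    """
    s = series.data
    nb = series.baseline_frames
    if nb < 3 or nb >= s.shape[0]:
        raise InvalidInputError("baseline window must have >= 3 frames and precede the bolus")
    s0 = s[:nb].mean(axis=0)
    if np.any(s0 <= 0):
        raise InvalidInputError("baseline mean must be positive")
    if mode == "linear":
        return scale * (s - s0) / s0
    if mode == "spgr":
        const = spgr or SPGRConstants()
        a = np.radians(const.flip_deg)
        e10 = np.exp(-const.tr / const.t10)
        m0 = s0 * (1 - np.cos(a) * e10) / (np.sin(a) * (1 - e10))
        y = np.clip(s / (m0 * np.sin(a)), 1e-9, None)
        e1 = np.clip((1 - y) / (1 - np.cos(a) * y), 1e-9, 1 - 1e-9)
        r1 = -np.log(e1) / const.tr
        return (r1 - 1.0 / const.t10) / const.r1
    raise InvalidInputError(f"unknown conversion mode {mode!r}")


# ---------------------------------------------------------------------------
# AIF modeling and extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaVariateAIF:
    """Gamma-variate bolus with a dispersed recirculation shoulder.

    The first pass peaks at ``t0 + tp`` with amplitude ``amplitude``; the
    shoulder is a fraction of the first pass delayed and widened.
    """

    amplitude: float = 5.0   # peak concentration, mM
    t0: float = 12.0         # bolus arrival, s
    alpha: float = 2.5       # shape
    tp: float = 6.0          # time-to-peak after arrival, s
    recirc_frac: float = 0.12
    recirc_delay: float = 22.0
    recirc_width: float = 3.0  # widening factor on tp

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)

        def gv(tt, t0, tp):
            x = np.clip((tt - t0) / tp, 0.0, None)
            return x**self.alpha * np.exp(self.alpha * (1.0 - x))

        c = gv(t, self.t0, self.tp)
        c = c + self.recirc_frac * gv(t, self.t0 + self.recirc_delay,
                                      self.tp * self.recirc_width)
        return self.amplitude * c


def apply_placement(aif: AIFCurve, delay: float, dispersion: float,
                    placement: str) -> AIFCurve:
    """Delay and disperse a reference AIF to emulate a downstream/upstream
    aortic ROI placement.

    The curve is shifted by ``delay`` seconds (grid-aligned by linear
    interpolation) and convolved with a normalized exponential kernel of
    time constant ``dispersion`` seconds (no kernel when 0).
    """
    t = aif.time
    c = np.interp(t - delay, t, aif.concentration, left=0.0)
    if dispersion > 0:
        dt = float(t[1] - t[0])
        k = np.exp(-np.arange(t.size) * dt / dispersion)
        k /= k.sum()
        c = np.convolve(c, k)[: t.size]
    return AIFCurve(time=t, concentration=c, placement=placement)


@dataclass(frozen=True)
class AIFRoi:
    """Rectangular aortic ROI: center in pixels, physical size in mm."""

    center: tuple[float, float]      # (y, x) px
    size_mm: tuple[float, float] = (10.0, 4.4)
    placement: str = "Cr25"


def extract_aif(series: DynamicSeries, roi: AIFRoi,
                pixel_spacing: tuple[float, float] = (1.0, 1.0),
                mode: str = "linear", scale: float = 1.0,
                spgr: SPGRConstants | None = None) -> AIFCurve:
    """Mean ROI signal per frame converted to concentration.

    ``series`` must be an image-form dynamic series (n_t, ny, nx).
    """
    if series.data.ndim != 3:
        raise InvalidInputError("extract_aif needs an image-form dynamic series")
    ny, nx = series.data.shape[1:]
    hy = max(1, int(round(roi.size_mm[0] / pixel_spacing[0]))) / 2.0
    hx = max(1, int(round(roi.size_mm[1] / pixel_spacing[1]))) / 2.0
    y0, y1 = int(np.floor(roi.center[0] - hy + 0.5)), int(np.floor(roi.center[0] + hy + 0.5))
    x0, x1 = int(np.floor(roi.center[1] - hx + 0.5)), int(np.floor(roi.center[1] + hx + 0.5))
    y1, x1 = max(y1, y0 + 1), max(x1, x0 + 1)
    if y0 < 0 or x0 < 0 or y1 > ny or x1 > nx:
        raise InvalidInputError("AIF ROI extends beyond the image")
    curve = series.data[:, y0:y1, x0:x1].mean(axis=(1, 2))
    conc = signal_to_concentration(
        DynamicSeries(time=series.time, data=curve,
                      baseline_frames=series.baseline_frames),
        mode=mode, scale=scale, spgr=spgr)
    return AIFCurve(time=series.time, concentration=conc, placement=roi.placement)


# ---------------------------------------------------------------------------
# pharmacokinetic forward models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PKParams:
    """Two-compartment parameters: flows mL/min/100 mL, volumes mL/100 mL."""

    fp: float = 120.0   # plasma flow
    vp: float = 30.0    # plasma volume fraction
    ft: float = 0.0     # tubular (filtration) flow, the Ktrans analogue
    tt: float = 60.0    # tubular mean transit time, s (C2FM only)

    def __post_init__(self) -> None:
        if self.fp <= 0 or not (0 < self.vp < 100):
            raise InvalidInputError("require F_p > 0 and 0 < v_p < 100")
        if self.ft < 0 or self.tt <= 0:
            raise InvalidInputError("require F_t >= 0 and T_t > 0")


def pk_irf(model: str, params: PKParams, t: np.ndarray) -> np.ndarray:
    """Tissue impulse-response function h(t) (units 1/s) so that
    C_t = dt * (c_a (x) h)."""
    t = np.asarray(t, dtype=float)
    fp = params.fp / 6000.0
    ft = params.ft / 6000.0
    vp = params.vp / 100.0
    tp = vp / (fp + ft)
    ep = np.exp(-t / tp)
    if model in ("C2UM",):
        e = ft / (fp + ft)
        return fp * (ep + e * (1.0 - ep))
    if model == "C2FM":
        if params.ft == 0:
            return fp * ep
        tt = params.tt
        if abs(1.0 / tp - 1.0 / tt) < 1e-12:
            tub = (ft * fp / vp) * t * ep
        else:
            tub = (ft * fp / vp) * (np.exp(-t / tt) - ep) / (1.0 / tp - 1.0 / tt)
        return fp * ep + tub
    if model == "1C":
        return fp * np.exp(-t * fp / vp)
    raise InvalidInputError(f"unknown PK model {model!r}")


def pk_forward(model: str, params: PKParams, aif: AIFCurve) -> np.ndarray:
    """Tissue concentration curve: discrete convolution of the AIF with the
    model IRF on the AIF's uniform grid (rectangle rule, C_t(0) = 0 for a
    causal AIF)."""
    t = aif.time
    dt = float(t[1] - t[0])
    h = pk_irf(model if model != "C2UM" else "C2UM", params, t - t[0])
    return dt * np.convolve(aif.concentration, h)[: t.size]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class PKResults:
    """Fit result for one (tissue curve, AIF, model) combination."""

    model: str
    fp: float
    vp: float = float("nan")
    ft: float = float("nan")
    tt: float = float("nan")
    rbf: float = float("nan")
    sse: float = float("nan")
    r_squared: float = float("nan")
    converged: bool = True
    message: str = ""
    irf: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def extraction_fraction(self) -> float:
        if np.isnan(self.ft):
            return float("nan")
        return self.ft / (self.fp + self.ft)

    def summary(self) -> str:
        lines = [f"PK fit [{self.model}]",
                 f"  F_p  = {self.fp:10.3f} mL/min/100 mL",
                 f"  RBF  = {self.rbf:10.3f} mL/100 g/min"]
        if not np.isnan(self.vp):
            lines.append(f"  v_p  = {self.vp:10.3f} mL/100 mL")
        if not np.isnan(self.ft):
            lines.append(f"  F_t  = {self.ft:10.3f} mL/min/100 mL")
        if self.model == "C2FM":
            lines.append(f"  T_t  = {self.tt:10.3f} s")
        lines.append(f"  R^2  = {self.r_squared:.6f}  converged={self.converged}")
        return "\n".join(lines)


def _smoothed_slope(y: np.ndarray, dt: float, window: int = 3) -> np.ndarray:
    """Finite-difference slope after a centered moving-average smooth."""
    if window > 1:
        k = np.ones(window) / window
        y = np.convolve(y, k, mode="same")
    return np.gradient(y, dt)


class PKModel:
    """Renal plasma-flow model for an ROI tissue curve against an AIF.

    Parameters
    ----------
    ct : tissue concentration curve on the AIF grid (array or DynamicSeries
        already converted to concentration).
    aif : AIFCurve on the same uniform grid.
    model : one of "MS", "MF", "C2UM", "C2FM".
    hematocrit, density : constants for the F_p -> RBF conversion.
    """

    def __init__(self, ct, aif: AIFCurve, model: str = "C2UM",
                 hematocrit: float = 0.45, density: float = 1.05):
        if model not in PK_MODELS:
            raise InvalidInputError(f"unknown PK model {model!r}")
        ct_arr = ct.data if isinstance(ct, DynamicSeries) else np.asarray(ct, dtype=float)
        if ct_arr.shape != aif.time.shape:
            raise InvalidInputError("tissue curve and AIF must share the grid")
        if np.max(aif.concentration) <= 0:
            raise InvalidInputError("AIF has no positive peak")
        self.ct = ct_arr
        self.aif = aif
        self.model = model
        self.hematocrit = hematocrit
        self.density = density

    def _to_rbf(self, fp: float) -> float:
        return fp / ((1.0 - self.hematocrit) * self.density)

    # -- estimators ---------------------------------------------------------
    def fit(self, **kw) -> PKResults:
        if self.model == "MS":
            res = self._fit_ms(**kw)
        elif self.model == "MF":
            res = self._fit_mf(**kw)
        else:
            res = self._fit_c2(**kw)
        res.rbf = self._to_rbf(res.fp)
        return res

    def _fit_ms(self, slope_window: int = 3) -> PKResults:
        dt = float(self.aif.time[1] - self.aif.time[0])
        slope = _smoothed_slope(self.ct, dt, window=slope_window)
        fp = float(np.max(slope) / np.max(self.aif.concentration)) * 6000.0
        return PKResults(model="MS", fp=fp)

    def _fit_mf(self, regularization: str = "tikhonov",
                lam: float | None = None, statistic: str = "max",
                selection: str = "gcv") -> PKResults:
        """Regularized discrete deconvolution; F_p = max (or late plateau)
        of the impulse-response function.

        The Tikhonov parameter is chosen by generalized cross-validation by
        default (``selection='lcurve'`` for the L-curve corner); ``lam``
        fixes it explicitly (relative to the largest singular value)."""
        t = self.aif.time
        n = t.size
        dt = float(t[1] - t[0])
        ca = self.aif.concentration
        A = dt * np.tril(
            np.array([[ca[i - j] if i >= j else 0.0 for j in range(n)]
                      for i in range(n)]))
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
        beta = U.T @ self.ct
        if regularization == "tsvd":
            k = int(np.sum(s > (lam if lam is not None else 1e-3) * s[0]))
            h = Vt[:k].T @ (beta[:k] / s[:k])
            lam_used = float(s[k - 1] / s[0])
        else:
            if lam is not None:
                lam_used = lam * s[0]
            elif selection == "lcurve":
                lam_used = _lcurve_lambda(s, beta)
            else:
                lam_used = _gcv_lambda(s, beta, n)
            f = s / (s**2 + lam_used**2)
            h = Vt.T @ (f * beta)
        if statistic == "plateau":
            # late-time plateau of the IRF (uptake-dominated tissues)
            fp_frac = float(np.median(h[n // 2:]))
        else:
            fp_frac = float(np.max(h))
        resid = A @ h - self.ct
        return PKResults(model="MF", fp=fp_frac * 6000.0, sse=float(resid @ resid),
                         r_squared=_r2(self.ct, A @ h), irf=h,
                         extras={"lambda": lam_used})

    def _fit_c2(self, n_starts: int = 5, xtol: float = 1e-10) -> PKResults:
        """Trust-region nonlinear least squares with multi-start
        initialization from log-spaced plasma transit times."""
        model = self.model
        ms = self._fit_ms()
        fp0 = max(ms.fp, 10.0)
        best = None
        tps = np.geomspace(2.0, 40.0, n_starts)
        for tp in tps:
            ft0 = 0.2 * fp0
            vp0 = tp * (fp0 + ft0) / 60.0  # v_p giving this plasma transit time
            vp0 = min(max(vp0, 1.0), 80.0)
            if model == "C2UM":
                x0 = np.log([fp0, vp0, ft0])
            else:
                x0 = np.log([fp0, vp0, ft0, 60.0])

            def resid(x):
                p = np.exp(x)
                try:
                    params = PKParams(fp=p[0], vp=min(p[1], 99.0), ft=p[2],
                                      tt=p[3] if p.size > 3 else 60.0)
                except InvalidInputError:
                    return np.full(self.ct.size, 1e6)
                return pk_forward(model, params, self.aif) - self.ct

            try:
                sol = least_squares(resid, x0, method="trf", xtol=xtol,
                                    ftol=1e-12, gtol=1e-12, max_nfev=400)
            except Exception:  # pragma: no cover - defensive
                continue
            sse = float(2 * sol.cost)
            if best is None or sse < best[0]:
                best = (sse, sol)
        if best is None:
            return PKResults(model=model, fp=float("nan"), converged=False,
                             message="all starts failed")
        sse, sol = best
        p = np.exp(sol.x)
        params = PKParams(fp=p[0], vp=min(p[1], 99.0), ft=p[2],
                          tt=p[3] if p.size > 3 else float("nan"))
        fitted = pk_forward(model, params, self.aif)
        return PKResults(model=model, fp=params.fp, vp=params.vp, ft=params.ft,
                         tt=params.tt if model == "C2FM" else float("nan"),
                         sse=sse, r_squared=_r2(self.ct, fitted),
                         converged=bool(sol.success), message=sol.message)


def _gcv_lambda(s: np.ndarray, beta: np.ndarray, n: int) -> float:
    """Generalized cross-validation: minimize ||r_lam||^2/n over
    (1 - tr(influence)/n)^2 on a log-spaced lambda grid."""
    lams = s[0] * np.logspace(-6, 0, 60)
    best_lam, best_g = lams[0], np.inf
    for lam in lams:
        f = s**2 / (s**2 + lam**2)
        r = beta * (1 - f)
        g = (float(r @ r) / n) / (1 - f.sum() / n) ** 2
        if g < best_g:
            best_g, best_lam = g, lam
    return float(best_lam)


def _lcurve_lambda(s: np.ndarray, beta: np.ndarray) -> float:
    """L-curve corner: lambda maximizing the curvature of
    (log residual norm, log solution norm) over a log-spaced grid."""
    lams = s[0] * np.logspace(-7, 0, 40)
    rho = np.empty(lams.size)
    eta = np.empty(lams.size)
    for i, lam in enumerate(lams):
        f = s / (s**2 + lam**2)
        x = f * beta
        r = beta * (1 - s * f)
        rho[i] = np.log(max(float(r @ r), 1e-300))
        eta[i] = np.log(max(float(x @ x), 1e-300))
    d1r, d1e = np.gradient(rho), np.gradient(eta)
    d2r, d2e = np.gradient(d1r), np.gradient(d1e)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (d1r * d2e - d2r * d1e) / (d1r**2 + d1e**2) ** 1.5
    kappa[~np.isfinite(kappa)] = -np.inf
    return float(lams[int(np.argmax(kappa))])


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_pk(ct, aif: AIFCurve, model: str, **kw) -> PKResults:
    """Fit one of the four plasma-flow analyses; see :class:`PKModel`."""
    fit_kw = {k: kw.pop(k) for k in list(kw)
              if k in ("slope_window", "regularization", "lam", "statistic",
                       "n_starts", "xtol")}
    return PKModel(ct, aif, model=model, **kw).fit(**fit_kw)
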