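"""Core in-memory containers shared across the pipeline.

All images are 2D single-slice arrays (row = y, column = x) on an
isotropic-or-not pixel grid with physical spacing in millimetres.  The
anatomical convention throughout the package is that the cranial pole of
the kidney points toward +y and the caudal pole toward -y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidGeometryError(ValueError):
    """A mask geometry request produced an empty, fragmented or edge-touching mask."""


class InvalidMaskError(ValueError):
    """A mask violates a precondition (disconnected, too small, ...)."""


class AmbiguousAxisError(ValueError):
    """A nearly circular mask has no usable long axis and no pole hint."""


class InvalidInputError(ValueError):
    """Generic invalid-input error for quantification routines."""


@dataclass(frozen=True)
class KidneyMask:
    """Binary parenchyma region on a pixel grid.

    Parameters
    ----------
    grid : (ny, nx) bool array
        True inside the parenchyma.
    pixel_spacing : (dy, dx) in mm.
    side : "left" or "right".
    pole_axis_hint : optional unit vector (dy, dx) pointing cranial->caudal,
        i.e. toward the caudal pole.
    """

    grid: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    side: str = "left"
    pole_axis_hint: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", g)
        if g.ndim != 2:
            raise InvalidMaskError("mask grid must be 2D")

    @property
    def n_pixels(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.grid)


@dataclass(frozen=True)
class ParametricMap:
    """Per-pixel quantitative values tied to a mask.

    ``values`` is a full-grid float array; pixels outside the mask are not
    meaningful (conventionally 0 or nan).  ``kind`` is one of
    {"RBF", "R2*", "S0", "PW", "M0"}; units follow the kind
    (mL/100 g/min for RBF, 1/s for R2*, a.u. otherwise).
    """

    values: np.ndarray
    mask: KidneyMask
    kind: str = "RBF"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != self.mask.grid.shape:
            raise InvalidInputError("map and mask shapes differ")
        # nan inside the mask marks invalid voxels; infinities are rejected
        if np.any(np.isinf(v[self.mask.grid])):
            raise InvalidInputError("map has infinite values inside the mask")

    def masked(self) -> np.ndarray:
        """Values at mask pixels, 1D."""
        return self.values[self.mask.grid]


@dataclass(frozen=True)
class RegionLabelMap:
    """Integer partition of a mask into regions (0 outside the mask).

    scheme "TLCO-12": ids 1..12, 1 = outermost layer, 12 = innermost.
    scheme "TEO-10": ids 1..10, 1 = caudal pole, 10 = cranial pole.
    """

    labels: np.ndarray
    mask: KidneyMask
    scheme: str
    n_regions: int
    warnings: tuple[str, ...] = ()

    def region_ids(self) -> np.ndarray:
        return np.arange(1, self.n_regions + 1)

    def region_pixels(self, region_id: int) -> np.ndarray:
        return self.labels == region_id


@dataclass(frozen=True)
class TimeIntensityCurve:
    """Sampled (linearized) intensity vs time for one ultrasound ROI.

    time is in seconds with 0 = contrast injection; baseline_window is the
    number of initial pre-rise samples used to estimate the baseline.
    """

    time: np.ndarray
    intensity: np.ndarray
    roi_class: str = "cortex"
    baseline_window: int = 5

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", y)
        if t.shape != y.shape or t.ndim != 1:
            raise InvalidInputError("time and intensity must be 1D of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("time must be strictly increasing")

    @property
    def baseline(self) -> float:
        return float(np.mean(self.intensity[: self.baseline_window]))


@dataclass(frozen=True)
class AIFCurve:
    """Arterial input function: tracer concentration vs time in the aorta.

    placement tags follow the study layout: Cr25 / Cr12 (25 and 12 mm
    cranial to the right renal artery), Ca (caudal to the celiac and
    cranial mesenteric arteries), AD (12 mm caudal to the renal artery).
    """

    time: np.ndarray
    concentration: np.ndarray
    placement: str = "Cr25"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.concentration, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "concentration", c)
        if t.shape != c.shape:
            raise InvalidInputError("time and concentration shapes differ")

    @property
    def peak_value(self) -> float:
        return float(np.max(self.concentration))

    @property
    def peak_time(self) -> float:
        return float(self.time[int(np.argmax(self.concentration))])


@dataclass(frozen=True)
class MultiEchoSeries:
    """Stack of gradient-echo magnitude images, one per echo time."""

    echoes: np.ndarray  # (n_echoes, ny, nx)
    echo_times: np.ndarray  # seconds, strictly increasing
    mask: KidneyMask

    def __post_init__(self) -> None:
        e = np.asarray(self.echoes, dtype=float)
        te = np.asarray(self.echo_times, dtype=float)
        object.__setattr__(self, "echoes", e)
        object.__setattr__(self, "echo_times", te)
        if e.ndim != 3 or e.shape[0] != te.size:
            raise InvalidInputError("echoes must be (n_echoes, ny, nx) matching echo_times")
        if te.size < 3:
            raise InvalidInputError("need at least 3 echoes")
        if not np.all(np.diff(te) > 0):
            raise InvalidInputError("echo times must be strictly increasing")
        if np.any(e < 0):
            raise InvalidInputError("magnitude data must be non-negative")


@dataclass(frozen=True)
class DynamicSeries:
    """Dynamic contrast series, either ROI-mean signal or an image stack.

    data is (n_t,) for an ROI curve or (n_t, ny, nx) for an image series on
    a uniform time grid.  ``baseline_frames`` precontrast frames define the
    enhancement baseline.
    """

    time: np.ndarray
    data: np.ndarray
    baseline_frames: int = 5

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "data", d)
        if d.shape[0] != t.size:
            raise InvalidInputError("time axis mismatch")
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6) or dt[0] <= 0:
                raise InvalidInputError("time grid must be uniform and increasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class RegionalSummary:
    """Per-region mean/SD of a parametric map plus cortex/medulla/whole aggregates.

    ``per_region`` maps region id -> (mean, sd, n_pixels); empty regions are
    recorded as missing (nan, nan, 0), never silently zero.  ``aggregates``
    maps {"cortex", "medulla", "whole"} -> (mean, sd, n_pixels) for the
    TLCO scheme.
    """

    scheme: str
    kind: str
    per_region: dict[int, tuple[float, float, int]] = field(default_factory=dict)
    aggregates: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    missing_regions: tuple[int, ...] = ()

    def mean(self, key: int | str) -> float:
        if isinstance(key, str):
            return self.aggregates[key][0]
        return self.per_region[key][0]
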