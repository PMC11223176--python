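"""Synthetic phantom cohort emulating a dopamine-vs-saline crossover study.

Generates, for each of n_subjects x 2 treatments x 2 kidney sides, a
phantom kidney mask with cortico-medullary ground truth and the four
measurement modalities:

* a 12-echo gradient-echo magnitude stack (mono-exponential decay, Rician
  noise applied to the real/imaginary channels before magnitude),
* FAIR-style ASL control / label / M0 images for two consecutive runs, in
  which the control-label difference encodes RBF exactly through the
  inverse of the pulsed-ASL quantification model,
* an ROI-level dynamic contrast series with a gamma-variate population AIF
  whose aortic ROI placement adds configurable delay and dispersion,
* cortical and medullary contrast-ultrasound time-intensity curves
  (gamma-variate bolus on a baseline, multiplicative noise).

Default regional truth values are the published canine TLCO regional
means under saline and low-dose dopamine; under dopamine the ground-truth
RBF rises and R2* falls.  All randomness derives from one master seed via
numpy SeedSequence spawning, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .asl import ASLParams
from .dce import (DEFAULT_PLACEMENTS, GammaVariateAIF, PKParams, apply_placement,
                  pk_forward)
from .regions import CORTEX_LAYERS, MEDULLA_LAYERS, tlco_labels, teo_labels
from .types import (AIFCurve, DynamicSeries, InvalidGeometryError,
                    InvalidInputError, KidneyMask, MultiEchoSeries,
                    ParametricMap, RegionLabelMap, TimeIntensityCurve)

#: Canine TLCO regional reference values (mean, SD): RBF in mL/100 g/min,
#: R2* in 1/s, for saline (control) and low-dose dopamine infusion.
REGIONAL_REFERENCE: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "dopamine": {
        "cortex": {"RBF": (409.87, 113.25), "R2*": (27.86, 6.01)},
        "medulla": {"RBF": (177.46, 34.48), "R2*": (17.94, 3.93)},
        "whole": {"RBF": (279.79, 134.63), "R2*": (21.90, 6.73)},
    },
    "control": {
        "cortex": {"RBF": (338.72, 87.43), "R2*": (28.58, 4.26)},
        "medulla": {"RBF": (156.63, 39.13), "R2*": (20.77, 5.43)},
        "whole": {"RBF": (232.21, 105.69), "R2*": (24.09, 6.85)},
    },
}


@dataclass(frozen=True)
class MaskGeometry:
    """Superellipse phantom kidney with an optional medial (hilar) notch.

    The long (pole) axis runs along +y (cranial) by convention.
    ``jitter`` scales seed-driven randomization of the semi-axes (fractional)
    and rotation (degrees = 20 * jitter) so each phantom subject differs.
    """

    grid_shape: tuple[int, int] = (96, 96)
    semi_major: float = 30.0   # along the pole axis, px
    semi_minor: float = 15.0
    exponent: float = 2.0
    concavity: float = 0.0     # 0..1, depth of the hilar notch
    rotation_deg: float = 0.0
    jitter: float = 0.0


@dataclass(frozen=True)
class CEUSBolusTruth:
    """Parametric bolus for a CEUS ROI class: gamma-variate on a baseline."""

    baseline: float = 5.0
    amplitude: float = 20.0   # peak enhancement above baseline, a.u.
    t0: float = 8.0           # enhancement onset, s
    alpha: float = 2.5
    tp: float = 10.0          # rise time onset->peak, s

    def __call__(self, t: np.ndarray) -> np.ndarray:
        x = np.clip((np.asarray(t, dtype=float) - self.t0) / self.tp, 0.0, None)
        return self.baseline + self.amplitude * x**self.alpha * np.exp(
            self.alpha * (1.0 - x))


@dataclass(frozen=True)
class StudyConfig:
    """Study conditions for the synthetic cohort."""

    n_subjects: int = 8
    treatments: tuple[str, str] = ("control", "dopamine")
    sides: tuple[str, str] = ("left", "right")
    master_seed: int = 20240620

    # ground truth: absolute cortex/medulla values per treatment
    regional_truth: dict = field(
        default_factory=lambda: {
            t: {r: {k: REGIONAL_REFERENCE[t][r][k][0] for k in ("RBF", "R2*")}
                for r in ("cortex", "medulla")}
            for t in ("control", "dopamine")})

    # biological variability (latent, multiplicative on RBF / additive on R2*)
    subject_cv_rbf: float = 0.15
    subject_sd_r2s: float = 2.0
    subject_coupling: float = -0.7   # corr(subject RBF factor, subject R2* shift)
    side_cv_rbf: float = 0.05
    side_sd_r2s: float = 0.5
    visit_cv_rbf: float = 0.04
    visit_sd_r2s: float = 0.8

    # acquisition
    echo_times: tuple = tuple(np.round(np.arange(1, 13) * 4.2e-3, 6))
    s0: float = 1000.0
    m0: float = 1000.0
    bold_noise_sd: float = 15.0
    asl_noise_sd: float = 5.0
    asl_params: ASLParams = field(default_factory=ASLParams)
    n_asl_runs: int = 2

    dce_dt: float = 1.5
    dce_n_frames: int = 80
    dce_baseline_frames: int = 8
    dce_noise_sd: float = 0.02
    aif: GammaVariateAIF = field(default_factory=GammaVariateAIF)
    aif_placements: dict = field(default_factory=lambda: dict(DEFAULT_PLACEMENTS))
    pk_truth: dict = field(default_factory=lambda: {
        "control": PKParams(fp=134.0, vp=30.0, ft=30.0, tt=60.0),
        "dopamine": PKParams(fp=161.5, vp=30.0, ft=30.0, tt=60.0),
    })
    dce_truth_model: str = "C2FM"

    ceus_dt: float = 0.5
    ceus_duration: float = 90.0
    ceus_noise_cv: float = 0.15
    ceus_truth: dict = field(default_factory=lambda: {
        "cortex": CEUSBolusTruth(baseline=5.0, amplitude=20.0, t0=8.0, tp=10.0),
        "medulla": CEUSBolusTruth(baseline=4.0, amplitude=10.0, t0=10.0, tp=14.0),
    })
    ceus_dopamine_amplitude_factor: float = 1.10

    geometry: MaskGeometry = field(default_factory=lambda: MaskGeometry(
        semi_major=28.0, semi_minor=14.0, concavity=0.25, jitter=1.0))
    modalities: tuple = ("asl", "bold", "dce", "ceus")

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidInputError("n_subjects must be >= 1")
        te = np.asarray(self.echo_times)
        if not np.all(np.diff(te) > 0):
            raise InvalidInputError("echo times must be strictly increasing")
        for name in ("bold_noise_sd", "asl_noise_sd", "dce_noise_sd", "ceus_noise_cv"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        for t, regions_ in self.regional_truth.items():
            for r, vals in regions_.items():
                if vals["RBF"] <= 0 or vals["R2*"] <= 0:
                    raise InvalidInputError("regional truth must be positive")

    @property
    def dce_time(self) -> np.ndarray:
        return np.arange(self.dce_n_frames) * self.dce_dt

    @property
    def ceus_time(self) -> np.ndarray:
        return np.arange(0.0, self.ceus_duration + 1e-9, self.ceus_dt)


def _dataset_seed(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

def generate_kidney_mask(geometry: MaskGeometry, seed: int = 0,
                         side: str = "left") -> KidneyMask:
    """Superellipse kidney phantom; deterministic given (geometry, seed).

    The caudal pole points toward -y; ``pole_axis_hint`` is set accordingly
    (co-rotated with the mask).
    """
    rng = np.random.default_rng(seed)
    a = geometry.semi_major * (1 + 0.10 * geometry.jitter * rng.uniform(-1, 1))
    b = geometry.semi_minor * (1 + 0.10 * geometry.jitter * rng.uniform(-1, 1))
    rot = np.radians(geometry.rotation_deg
                     + 20.0 * geometry.jitter * rng.uniform(-1, 1))
    ny, nx = geometry.grid_shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    dy, dx = yy - cy, xx - cx
    # rotate into the kidney frame: u along the pole axis (+y), v lateral
    u = np.cos(rot) * dy + np.sin(rot) * dx
    v = -np.sin(rot) * dy + np.cos(rot) * dx
    n = geometry.exponent
    grid = (np.abs(u / a) ** n + np.abs(v / b) ** n) < 1.0
    if geometry.concavity > 0:
        # hilar notch on the medial side (+v for left kidney, -v for right)
        sgn = 1.0 if side == "left" else -1.0
        notch = ((u / (0.45 * a)) ** 2
                 + ((v - sgn * b) / (geometry.concavity * b * 1.6)) ** 2) < 1.0
        grid &= ~notch
    if not grid.any():
        raise InvalidGeometryError("geometry produced an empty mask")
    lab, ncomp = ndimage.label(grid)
    if ncomp > 1:  # keep the largest component if the notch split the mask
        sizes = ndimage.sum(grid, lab, index=np.arange(1, ncomp + 1))
        grid = lab == (1 + int(np.argmax(sizes)))
    if grid.sum() < 200:
        raise InvalidGeometryError("mask smaller than 200 pixels")
    border = np.zeros_like(grid)
    border[:2, :] = border[-2:, :] = border[:, :2] = border[:, -2:] = True
    if (grid & border).any():
        raise InvalidGeometryError("mask touches the grid edge (margin < 2 px)")
    hint = (-float(np.cos(rot)), -float(np.sin(rot)))  # caudal = rotated -y
    return KidneyMask(grid=grid, side=side, pole_axis_hint=hint)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Simulation truth for one (subject, treatment, side) kidney."""

    rbf_map: ParametricMap
    r2s_map: ParametricMap
    s0_map: ParametricMap
    m0_map: ParametricMap
    pk_params: PKParams
    tic_truth: dict[str, CEUSBolusTruth]
    labels_tlco: RegionLabelMap
    labels_teo: RegionLabelMap
    region_values: dict[str, dict[str, float]]  # cortex/medulla -> kind -> value


def _layer_profile(cortex: float, medulla: float, n_layers: int = 12) -> np.ndarray:
    """Per-layer truth values: layers 1-3 cortical, 4-7 a linear
    cortico-medullary transition, 8-12 medullary."""
    prof = np.empty(n_layers)
    prof[:3] = cortex
    prof[3:7] = cortex + (medulla - cortex) * np.array([0.2, 0.4, 0.6, 0.8])
    prof[7:] = medulla
    return prof


def build_truth_maps(mask: KidneyMask, labels: RegionLabelMap,
                     cortex_rbf: float, medulla_rbf: float,
                     cortex_r2s: float, medulla_r2s: float,
                     s0: float, m0: float) -> tuple[ParametricMap, ParametricMap,
                                                    ParametricMap, ParametricMap]:
    rbf_prof = _layer_profile(cortex_rbf, medulla_rbf, labels.n_regions)
    r2s_prof = _layer_profile(cortex_r2s, medulla_r2s, labels.n_regions)
    rbf = np.zeros(mask.grid.shape)
    r2s = np.zeros(mask.grid.shape)
    for rid in labels.region_ids():
        sel = labels.labels == rid
        rbf[sel] = rbf_prof[rid - 1]
        r2s[sel] = r2s_prof[rid - 1]
    s0_map = np.where(mask.grid, s0, 0.0)
    m0_map = np.where(mask.grid, m0, 0.0)
    return (ParametricMap(rbf, mask, "RBF"), ParametricMap(r2s, mask, "R2*"),
            ParametricMap(s0_map, mask, "S0"), ParametricMap(m0_map, mask, "M0"))


# ---------------------------------------------------------------------------
# modality simulators
# ---------------------------------------------------------------------------

def simulate_multiecho(r2s_map: ParametricMap, s0_map: ParametricMap,
                       echo_times, noise_sd: float, seed) -> MultiEchoSeries:
    """Mono-exponential decay per pixel plus Rician magnitude noise
    (Gaussian noise of the given SD on the real and imaginary channels)."""
    te = np.asarray(echo_times, dtype=float)
    if not np.all(np.diff(te) > 0):
        raise InvalidInputError("echo times must be strictly increasing")
    mask = r2s_map.mask
    if s0_map.mask.grid.shape != mask.grid.shape:
        raise InvalidInputError("maps must share the mask")
    if np.any(s0_map.values[mask.grid] <= 0):
        raise InvalidInputError("S0 must be positive inside the mask")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signal = s0_map.values[None] * np.exp(-r2s_map.values[None] * te[:, None, None])
    signal *= mask.grid[None]
    if noise_sd > 0:
        re = signal + rng.normal(0.0, noise_sd, signal.shape)
        im = rng.normal(0.0, noise_sd, signal.shape)
        signal = np.hypot(re, im)
    return MultiEchoSeries(echoes=signal, echo_times=te, mask=mask)


def simulate_asl_pair(rbf_map: ParametricMap, m0_map: ParametricMap,
                      asl_params: ASLParams, noise_sd: float, seed,
                      n_runs: int = 2) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Control/label/M0 images for ``n_runs`` consecutive scans.

    The noiseless control-label difference inverts the quantification model
    exactly: dM = RBF * M0 / scale.  Gaussian noise of the given SD is added
    independently to every image of every run.
    Returns (control, label, m0) with control/label shaped (n_runs, ny, nx).
    """
    if np.any(rbf_map.values[rbf_map.mask.grid] < 0):
        raise InvalidInputError("RBF must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m0 = m0_map.values
    dm = rbf_map.values * m0 / asl_params.scale
    shape = (n_runs,) + m0.shape
    control = np.broadcast_to(m0 + dm / 2.0, shape).copy()
    label = np.broadcast_to(m0 - dm / 2.0, shape).copy()
    m0_img = m0.copy()
    if noise_sd > 0:
        control += rng.normal(0.0, noise_sd, shape)
        label += rng.normal(0.0, noise_sd, shape)
        m0_img = m0_img + rng.normal(0.0, noise_sd, m0.shape)
    return control, label, m0_img


@dataclass
class DCESimulation:
    tissue: DynamicSeries
    aif: AIFCurve            # at the requested placement
    aif_reference: AIFCurve  # un-delayed population AIF
    placements: dict[str, AIFCurve] = field(default_factory=dict)


def simulate_dce(pk_truth: PKParams, aif_params: GammaVariateAIF,
                 time_grid, placement: str, noise_sd: float, seed,
                 model: str = "C2FM",
                 placements_map: dict | None = None) -> DCESimulation:
    """ROI-level tissue curve: the chosen model's response to the placed AIF
    plus Gaussian noise; the un-delayed reference AIF is returned alongside,
    as are the AIF curves at every configured placement."""
    t = np.asarray(time_grid, dtype=float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0]) or dt[0] <= 0:
        raise InvalidInputError("time grid must be uniform and increasing")
    pmap = placements_map or DEFAULT_PLACEMENTS
    if placement not in pmap:
        raise InvalidInputError(f"unknown AIF placement {placement!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = AIFCurve(time=t, concentration=aif_params(t), placement="reference")
    placed_all = {tag: apply_placement(ref, d, disp, tag)
                  for tag, (d, disp) in pmap.items()}
    placed = placed_all[placement]
    ct = pk_forward(model, pk_truth, placed)
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, ct.shape)
    tissue = DynamicSeries(time=t, data=ct, baseline_frames=max(3, int(
        np.searchsorted(t, aif_params.t0) // 2)))
    return DCESimulation(tissue=tissue, aif=placed, aif_reference=ref,
                         placements=placed_all)


def simulate_ceus_tic(tic_truth: CEUSBolusTruth, time_grid, noise_cv: float,
                      seed, roi_class: str = "cortex") -> TimeIntensityCurve:
    """Gamma-variate bolus on a baseline with multiplicative Gaussian noise
    (CV-parameterized); deterministic given the seed."""
    t = np.asarray(time_grid, dtype=float)
    if not (t[0] <= tic_truth.t0 + tic_truth.tp <= t[-1]):
        raise InvalidInputError("bolus peak must lie inside the recording window")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = tic_truth(t)
    if noise_cv > 0:
        y = np.clip(y * (1.0 + noise_cv * rng.normal(0.0, 1.0, y.shape)), 0.0, None)
    nb = max(3, int(np.floor(tic_truth.t0 / (t[1] - t[0]) / 2)))
    return TimeIntensityCurve(time=t, intensity=y, roi_class=roi_class,
                              baseline_window=nb)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class KidneyDataset:
    """Everything simulated for one (subject, treatment, side) kidney."""

    subject: int
    treatment: str
    side: str
    mask: KidneyMask
    truth: GroundTruth
    asl: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    bold: MultiEchoSeries | None = None
    dce: DCESimulation | None = None
    ceus: dict[str, list[TimeIntensityCurve]] | None = None

    @property
    def key(self) -> str:
        return f"dog{self.subject:02d}_{self.treatment}_{self.side}"


@dataclass
class SyntheticStudy:
    config: StudyConfig
    datasets: list[KidneyDataset]

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)


def generate_cohort(config: StudyConfig) -> SyntheticStudy:
    """Generate the full phantom cohort (n_subjects x treatments x sides)."""
    datasets: list[KidneyDataset] = []
    n_roi = {"cortex": 3, "medulla": 2}
    for s in range(config.n_subjects):
        rng_subj = _dataset_seed(config.master_seed, s, 999)
        z1, z2 = rng_subj.normal(size=2)
        rho = config.subject_coupling
        subj_rbf = 1.0 + config.subject_cv_rbf * z1
        subj_r2s = config.subject_sd_r2s * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        for ti, treatment in enumerate(config.treatments):
            for si, side in enumerate(config.sides):
                rng_bio = _dataset_seed(config.master_seed, s, ti, si, 0)
                mask_seed = int(_dataset_seed(config.master_seed, s, 500 + si)
                                .integers(0, 2**31 - 1))
                mask = generate_kidney_mask(config.geometry, seed=mask_seed,
                                            side=side)
                labels_tlco = tlco_labels(mask)
                labels_teo = teo_labels(mask)

                side_rbf = 1.0 + config.side_cv_rbf * float(
                    _dataset_seed(config.master_seed, s, 600 + si).normal())
                side_r2s = config.side_sd_r2s * float(
                    _dataset_seed(config.master_seed, s, 700 + si).normal())
                visit_rbf = 1.0 + config.visit_cv_rbf * float(rng_bio.normal())
                visit_r2s = config.visit_sd_r2s * float(rng_bio.normal())

                truth_t = config.regional_truth[treatment]
                f_rbf = max(subj_rbf * side_rbf * visit_rbf, 0.05)
                d_r2s = subj_r2s + side_r2s + visit_r2s
                region_values = {
                    r: {"RBF": truth_t[r]["RBF"] * f_rbf,
                        "R2*": max(truth_t[r]["R2*"] + d_r2s, 0.5)}
                    for r in ("cortex", "medulla")}
                rbf_map, r2s_map, s0_map, m0_map = build_truth_maps(
                    mask, labels_tlco,
                    region_values["cortex"]["RBF"], region_values["medulla"]["RBF"],
                    region_values["cortex"]["R2*"], region_values["medulla"]["R2*"],
                    config.s0, config.m0)

                pk_base = config.pk_truth[treatment]
                pk = replace(pk_base, fp=pk_base.fp * f_rbf)
                amp_factor = (config.ceus_dopamine_amplitude_factor
                              if treatment == "dopamine" else 1.0)
                tic_truth = {
                    cls: replace(base, amplitude=base.amplitude * amp_factor * f_rbf)
                    for cls, base in config.ceus_truth.items()}

                truth = GroundTruth(rbf_map=rbf_map, r2s_map=r2s_map,
                                    s0_map=s0_map, m0_map=m0_map, pk_params=pk,
                                    tic_truth=tic_truth, labels_tlco=labels_tlco,
                                    labels_teo=labels_teo,
                                    region_values=region_values)
                ds = KidneyDataset(subject=s, treatment=treatment, side=side,
                                   mask=mask, truth=truth)

                if "asl" in config.modalities:
                    ds.asl = simulate_asl_pair(
                        rbf_map, m0_map, config.asl_params, config.asl_noise_sd,
                        _dataset_seed(config.master_seed, s, ti, si, 1),
                        n_runs=config.n_asl_runs)
                if "bold" in config.modalities:
                    ds.bold = simulate_multiecho(
                        r2s_map, s0_map, config.echo_times, config.bold_noise_sd,
                        _dataset_seed(config.master_seed, s, ti, si, 2))
                if "dce" in config.modalities:
                    ds.dce = simulate_dce(
                        pk, config.aif, config.dce_time, "Cr25",
                        config.dce_noise_sd,
                        _dataset_seed(config.master_seed, s, ti, si, 3),
                        model=config.dce_truth_model,
                        placements_map=config.aif_placements)
                if "ceus" in config.modalities:
                    rng_c = _dataset_seed(config.master_seed, s, ti, si, 4)
                    ds.ceus = {
                        cls: [simulate_ceus_tic(tic_truth[cls], config.ceus_time,
                                                config.ceus_noise_cv, rng_c,
                                                roi_class=cls)
                              for _ in range(n_roi[cls])]
                        for cls in ("cortex", "medulla")}
                datasets.append(ds)
    return SyntheticStudy(config=config, datasets=datasets)
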