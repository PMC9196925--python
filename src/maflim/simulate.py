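"""Synthetic maFLIM dermoscopy data generator.

Generates multispectral time-resolved fluorescence image stacks with the
statistical structure the downstream analysis assumes: per-pixel
biexponential decays convolved with a per-channel instrument response,
two spatial regions per image (a central lesion disc and its surround) with
distinct decay parameters, channel-dependent intensities, baseline offsets,
configurable noise, optional saturation/hair artifacts, and patient-grouped
benign/malignant cohorts with class-dependent parameter shifts.

The default cohort layout mirrors the clinical study conditions this
pipeline was designed for: 30 patients contributing 60 lesions with a
41 benign / 19 malignant imbalance, each patient's lesions sharing one
diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import (
    BENIGN,
    CHANNELS,
    MALIGNANT,
    AcquisitionConfig,
    InstrumentResponse,
    TimeResolvedImage,
)
from .decay import discrete_reconvolve, multiexp_conv_gauss, multiexp_fir

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class DecayParams:
    """Biexponential decay parameters of one region in one channel.

    ``alpha_fast`` is the unitless weight of the fast component (the slow
    weight is ``1 - alpha_fast``); lifetimes are in ns; ``intensity`` is the
    photon-scale amplitude applied to the whole decay (arbitrary units).
    """

    alpha_fast: float
    tau_fast: float
    tau_slow: float
    intensity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_fast <= 1.0:
            raise ValueError("alpha_fast must lie in [0, 1]")
        if not 0.0 < self.tau_fast <= self.tau_slow:
            raise ValueError("need 0 < tau_fast <= tau_slow")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


class RegionDecayParams(dict):
    """Mapping of emission channel -> :class:`DecayParams` for one region."""

    def __init__(self, by_channel: Mapping[int, DecayParams]):
        super().__init__(by_channel)
        missing = set(CHANNELS) - set(self)
        if missing:
            raise ValueError(f"missing channels: {sorted(missing)}")

    def shifted(self, deltas: Mapping[str, float]) -> "RegionDecayParams":
        """Return a copy with named parameter offsets applied.

        Keys are ``"<param>"`` (all channels) or ``"<param>_<channel>"``
        (one channel), with param one of ``alpha_fast``, ``tau_fast``,
        ``tau_slow``, ``intensity`` (additive) or ``intensity_frac``
        (multiplicative).  Results are clipped back into the physical domain
        (weights in [0, 1], positive ordered lifetimes).
        """
        vals = {
            ch: {
                "alpha_fast": p.alpha_fast,
                "tau_fast": p.tau_fast,
                "tau_slow": p.tau_slow,
                "intensity": p.intensity,
            }
            for ch, p in self.items()
        }
        for key, delta in deltas.items():
            name, chans = _parse_param_key(key)
            for ch in chans:
                if name == "intensity_frac":
                    vals[ch]["intensity"] *= 1.0 + delta
                else:
                    vals[ch][name] += delta
        out = {}
        for ch, v in vals.items():
            a = float(np.clip(v["alpha_fast"], 0.0, 1.0))
            tf = max(v["tau_fast"], 0.05)
            ts = max(v["tau_slow"], tf)
            out[ch] = DecayParams(a, tf, ts, max(v["intensity"], 0.0))
        return RegionDecayParams(out)


def _parse_param_key(key: str) -> tuple[str, tuple[int, ...]]:
    parts = key.rsplit("_", 1)
    if len(parts) == 2 and parts[1].isdigit():
        ch = int(parts[1])
        if ch not in CHANNELS:
            raise KeyError(f"unknown channel in parameter key {key!r}")
        return parts[0], (ch,)
    return key, CHANNELS


@dataclass
class SceneSpec:
    """One synthetic lesion image: geometry, decay parameters, noise, artifacts.

    ``noise_model`` is ``("gaussian", snr_db)``, ``("poisson", peak_counts)``
    or ``None``; Gaussian noise is scaled per pixel so that
    ``20*log10(peak / sigma)`` equals the requested SNR.
    """

    region1_params: RegionDecayParams  # lesion
    region2_params: RegionDecayParams  # surround
    noise_model: tuple[str, float] | None = ("gaussian", 25.0)
    offset: float = 100.0
    saturated_fraction: float = 0.0
    hair_rows: tuple[int, ...] = ()
    adc_max: float = 4095.0
    lesion_mask: np.ndarray | None = None
    lesion_area_frac: float = 0.3
    seed: int = 0

    def resolve_mask(self, rows: int, cols: int) -> np.ndarray:
        """Lesion-region boolean map; default is a centred disc."""
        if self.lesion_mask is not None:
            m = np.asarray(self.lesion_mask, dtype=bool)
            if m.shape != (rows, cols):
                raise ValueError("lesion_mask shape must match the pixel grid")
            return m
        return disc_mask(rows, cols, self.lesion_area_frac)


@dataclass(frozen=True)
class CohortSpec:
    """Patient-grouped lesion cohort with class-dependent parameter shifts.

    ``effect`` holds per-class offsets applied to the lesion region of every
    malignant lesion; ``inter_patient_sd`` holds the standard deviations of
    per-patient random offsets, applied identically to both regions of all of
    a patient's lesions (so global region-difference features reflect the
    class effect, not the patient).
    """

    lesions_per_patient: tuple[int, ...]
    patient_labels: tuple[str, ...]
    effect: Mapping[str, float] = field(default_factory=dict)
    inter_patient_sd: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lesions_per_patient) != len(self.patient_labels):
            raise ValueError("one label per patient is required")
        if sum(self.lesions_per_patient) <= 0:
            raise ValueError("cohort must contain at least one lesion")
        bad = set(self.patient_labels) - {BENIGN, MALIGNANT}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def n_patients(self) -> int:
        return len(self.patient_labels)

    @property
    def n_lesions(self) -> int:
        return int(sum(self.lesions_per_patient))


@dataclass
class SimulatedLesion:
    lesion_id: str
    patient_id: str
    label: str
    image: TimeResolvedImage


# ---------------------------------------------------------------------------
# geometry


def disc_mask(rows: int, cols: int, area_frac: float = 0.3) -> np.ndarray:
    """Centred disc covering ``area_frac`` of the field of view."""
    radius = np.sqrt(area_frac * rows * cols / np.pi)
    r = np.arange(rows)[:, None] - (rows - 1) / 2.0
    c = np.arange(cols)[None, :] - (cols - 1) / 2.0
    return r * r + c * c <= radius * radius


# ---------------------------------------------------------------------------
# IRF


def generate_irf(
    config: AcquisitionConfig,
    fwhm_ns: float | Sequence[float] = 1.0,
    t0_ns: float | Sequence[float] = 4.0,
) -> InstrumentResponse:
    """Per-channel unit-area Gaussian excitation pulses on the config time base.

    ``fwhm_ns`` and ``t0_ns`` may be scalars (shared) or one value per
    channel.  A near-zero FWHM degenerates to a single-sample impulse of
    height ``1/dt`` (discrete delta), so convolution with it is the identity.
    Raises if the pulse would be truncated by the acquisition window.
    """
    fwhms = _per_channel(fwhm_ns, config)
    t0s = _per_channel(t0_ns, config)
    t = config.time_ns
    dt = config.dt
    channels: dict[int, np.ndarray] = {}
    params: dict[int, tuple[float, float]] = {}
    for ch, fwhm, t0 in zip(config.channels, fwhms, t0s):
        if fwhm < 0:
            raise ValueError("fwhm_ns must be non-negative")
        if not 0.0 <= t0 <= t[-1]:
            raise ValueError("t0_ns must lie within the channel time window")
        sigma = fwhm * _FWHM_TO_SIGMA
        if sigma < 1e-6 * dt:
            u = np.zeros_like(t)
            u[int(round(t0 / dt))] = 1.0 / dt
            sigma = 0.0
        else:
            u = np.exp(-((t - t0) ** 2) / (2 * sigma * sigma)) / (
                sigma * np.sqrt(2 * np.pi)
            )
            if u[-1] > 1e-9 * u.max():
                raise ValueError(
                    "IRF pulse truncated by the window end; reduce t0 or fwhm"
                )
        channels[ch] = u
        params[ch] = (float(fwhm), float(t0))
    return InstrumentResponse(channels=channels, dt=dt, gaussian_params=params)


def _per_channel(value, config: AcquisitionConfig) -> tuple[float, ...]:
    if np.isscalar(value):
        return tuple(float(value) for _ in config.channels)
    vals = tuple(float(v) for v in value)
    if len(vals) != len(config.channels):
        raise ValueError("need one value per channel")
    return vals


# ---------------------------------------------------------------------------
# forward model


def clean_decay(
    params: DecayParams,
    irf: InstrumentResponse,
    channel: int,
    config: AcquisitionConfig,
) -> np.ndarray:
    """Noiseless measured decay of one region in one channel.

    Uses the exact continuous-time Gaussian-IRF convolution when the IRF is
    parametric, otherwise a trapezoid-rule discrete reconvolution with the
    IRF samples.
    """
    t = config.time_ns
    w = np.array([params.alpha_fast, 1.0 - params.alpha_fast])
    taus = np.array([params.tau_fast, params.tau_slow])
    if irf.gaussian_params is not None and channel in irf.gaussian_params:
        fwhm, t0 = irf.gaussian_params[channel]
        sigma = fwhm * _FWHM_TO_SIGMA
        shape = multiexp_conv_gauss(t, w, taus, sigma, t0)
    else:
        shape = discrete_reconvolve(irf.channels[channel], multiexp_fir(t, w, taus), config.dt)
    return params.intensity * shape


def generate_lesion_image(
    scene: SceneSpec,
    config: AcquisitionConfig,
    irf: InstrumentResponse,
) -> TimeResolvedImage:
    """Render one synthetic maFLIM image from a scene specification.

    Per pixel and channel the decay is the region's noiseless model plus a
    constant baseline offset and the configured noise; saturated-artifact
    pixels are railed at the ADC maximum; everything is clipped to the ADC
    range.  Deterministic given ``scene.seed``.
    """
    rows, cols = config.rows, config.cols
    lesion = scene.resolve_mask(rows, cols)
    rng = np.random.default_rng(scene.seed)
    for region in (scene.region1_params, scene.region2_params):
        for p in region.values():
            for v in (p.alpha_fast, p.tau_fast, p.tau_slow, p.intensity):
                if not np.isfinite(v):
                    raise ValueError("non-finite decay parameter")

    n_sat = int(round(scene.saturated_fraction * rows * cols))
    sat_idx = (
        rng.choice(rows * cols, size=n_sat, replace=False) if n_sat else np.array([], int)
    )

    channels: dict[int, np.ndarray] = {}
    for ch in config.channels:
        trace1 = clean_decay(scene.region1_params[ch], irf, ch, config)
        trace2 = clean_decay(scene.region2_params[ch], irf, ch, config)
        cube = np.where(lesion[..., None], trace1[None, None, :], trace2[None, None, :])
        cube = np.ascontiguousarray(cube, dtype=float)
        for r in scene.hair_rows:
            cube[r, :, :] *= 0.25  # dark stripe from a hair across the FOV
        peak = cube.max(axis=-1, keepdims=True)
        cube = cube + scene.offset
        if scene.noise_model is not None:
            kind, level = scene.noise_model
            if kind == "gaussian":
                sigma = peak / 10.0 ** (level / 20.0)
                cube = cube + rng.standard_normal(cube.shape) * sigma
            elif kind == "poisson":
                scale = level / max(float(peak.max()), 1e-12)
                cube = rng.poisson(np.maximum(cube * scale, 0.0)).astype(float) / scale
            else:
                raise ValueError(f"unknown noise model {kind!r}")
        if n_sat:
            flat = cube.reshape(rows * cols, -1)
            flat[sat_idx] = scene.adc_max
        cube = np.clip(cube, 0.0, scene.adc_max)
        channels[ch] = cube
    return TimeResolvedImage(
        channels=channels,
        dt=config.dt,
        adc_max=scene.adc_max,
        meta={"lesion_mask": lesion, "seed": scene.seed},
    )


def generate_cohort(
    cohort: CohortSpec,
    scene_template: SceneSpec,
    config: AcquisitionConfig,
    irf: InstrumentResponse,
) -> list[SimulatedLesion]:
    """Render a patient-grouped cohort of synthetic lesion images.

    Per-patient random offsets (``inter_patient_sd``) are drawn once per
    patient and applied identically to both regions of all that patient's
    lesions; the class ``effect`` offsets are applied to the lesion region of
    malignant lesions only.  Deterministic given ``cohort.seed``.
    """
    rng = np.random.default_rng(cohort.seed)
    lesions: list[SimulatedLesion] = []
    idx = 0
    for p_idx, (label, n_les) in enumerate(
        zip(cohort.patient_labels, cohort.lesions_per_patient)
    ):
        patient_id = f"P{p_idx:02d}"
        patient_offsets = {
            key: float(rng.normal(0.0, sd)) for key, sd in cohort.inter_patient_sd.items()
        }
        for _ in range(n_les):
            r1 = scene_template.region1_params.shifted(patient_offsets)
            r2 = scene_template.region2_params.shifted(patient_offsets)
            if label == MALIGNANT:
                r1 = r1.shifted(cohort.effect)
            scene = replace(
                scene_template,
                region1_params=r1,
                region2_params=r2,
                seed=int(rng.integers(2**31)),
            )
            image = generate_lesion_image(scene, config, irf)
            lesions.append(SimulatedLesion(f"L{idx:03d}", patient_id, label, image))
            idx += 1
    return lesions


# ---------------------------------------------------------------------------
# study-condition defaults
#
# Decay parameters are chosen in the range reported for skin endogenous
# fluorophores (collagen in the 390 nm band, NADH at 452 nm, FAD at 500 nm):
# sub-ns fast components, slow components of a few ns, fast-weight around
# 0.6-0.75.  The malignant effect shifts exactly the parameters that the
# clinical analysis found most discriminant (tau_fast/alpha_fast at 452 nm,
# tau_slow/alpha_fast at 390 nm, alpha_fast at 500 nm).


def default_surround_params() -> RegionDecayParams:
    return RegionDecayParams(
        {
            390: DecayParams(0.60, 0.90, 4.50, 500.0),
            452: DecayParams(0.70, 0.70, 3.80, 700.0),
            500: DecayParams(0.65, 0.80, 3.50, 600.0),
        }
    )


def default_lesion_params() -> RegionDecayParams:
    return RegionDecayParams(
        {
            390: DecayParams(0.68, 0.85, 5.00, 450.0),
            452: DecayParams(0.75, 0.60, 4.20, 560.0),
            500: DecayParams(0.70, 0.75, 3.90, 660.0),
        }
    )


def default_effect() -> dict[str, float]:
    """Malignant-versus-benign shifts of the lesion-region decay parameters."""
    return {
        "tau_fast_452": -0.20,
        "alpha_fast_452": +0.08,
        "tau_slow_390": +0.60,
        "alpha_fast_390": +0.06,
        "alpha_fast_500": +0.05,
    }


def strong_effect() -> dict[str, float]:
    """A large, well-separated class effect for recovery experiments."""
    return {
        "tau_fast_452": -0.35,
        "alpha_fast_452": +0.15,
        "tau_slow_390": +1.20,
        "alpha_fast_390": +0.12,
        "alpha_fast_500": +0.10,
    }


def default_inter_patient_sd() -> dict[str, float]:
    return {
        "tau_fast": 0.04,
        "tau_slow": 0.15,
        "alpha_fast": 0.02,
        "intensity_frac": 0.08,
    }


def default_scene(seed: int = 0, snr_db: float = 25.0) -> SceneSpec:
    return SceneSpec(
        region1_params=default_lesion_params(),
        region2_params=default_surround_params(),
        noise_model=("gaussian", snr_db),
        seed=seed,
    )


def default_irf(config: AcquisitionConfig) -> InstrumentResponse:
    """Study-default IRF: 1 ns FWHM pulses, arrival staggered per channel.

    The stagger (one sample between adjacent channels) reflects differing
    detection path delays and keeps the concatenated IRF spectrum non-zero at
    every harmonic (identical per-channel pulses would null every harmonic
    not divisible by three by segment symmetry).
    """
    return generate_irf(config, fwhm_ns=1.0, t0_ns=(4.0, 4.4, 4.8))


def cohort_spec_like_study(
    effect: Mapping[str, float] | None = None,
    inter_patient_sd: Mapping[str, float] | None = None,
    seed: int = 0,
) -> CohortSpec:
    """Cohort layout matching the study: 30 patients, 60 lesions, 41/19 split.

    Benign: 2 patients x 5 lesions plus 15 patients sharing 31 lesions;
    malignant: 2 patients x 3, 5 patients x 1, and 6 patients sharing 8.
    """
    benign = [5, 5, 3] + [2] * 14
    malignant = [3, 3] + [1] * 5 + [2, 2, 1, 1, 1, 1]
    return CohortSpec(
        lesions_per_patient=tuple(benign + malignant),
        patient_labels=tuple([BENIGN] * len(benign) + [MALIGNANT] * len(malignant)),
        effect=dict(default_effect() if effect is None else effect),
        inter_patient_sd=dict(
            default_inter_patient_sd() if inter_patient_sd is None else inter_patient_sd
        ),
        seed=seed,
    )
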