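"""Frequency-domain (phasor) maFLIM features.

Instead of iterative time-domain reconvolution, the instrument response is
removed by a single division in the frequency domain: with Y and U the DFTs
of the concatenated three-channel decay and IRF, the normalised fluorescence
frequency response is

    P(w) = Y(w) U(0) / (U(w) Y(0)),

evaluated at the first nine harmonics of the 3*M-point spectrum.  Each pixel
maps to a phasor point (G, S) = (Re P, Im P) per harmonic; a bivariate
Gaussian is fitted to each clustered region's point cloud and four scalar
features compare the two regions: the distance between means, the difference
of covariance determinants ("spread"), the acute angle between major axes,
and the difference of major/minor eigenvalue ratios ("symmetry").  Nine
harmonics x four features = 36 global features per image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AcquisitionConfig,
    ConcatenatedImage,
    InstrumentResponse,
    RegionMasks,
    harmonic_label,
)
from .preprocess import concat_irf

__all__ = [
    "PHASOR_POOL",
    "normalize_concat",
    "harmonic_frequencies",
    "frequency_deconvolve",
    "fit_phasor_gaussian",
    "phasor_pair_features",
    "extract_phasor_pool",
]

N_HARMONICS = 9
_FEATURE_KINDS = ("distance", "spread", "angle", "symmetry")

#: Canonical phasor-pool feature names (36), labelled on the nominal
#: 5.6 MHz harmonic grid as printed in the study tables.
PHASOR_POOL: tuple[str, ...] = tuple(
    f"{kind}_{harmonic_label(k)}MHz"
    for k in range(1, N_HARMONICS + 1)
    for kind in _FEATURE_KINDS
)


def normalize_concat(signal: np.ndarray) -> np.ndarray:
    """Scale concatenated decays to unit sum along the time axis.

    Zero- or negative-sum pixels are returned as NaN (flagged invalid).
    Note the DC division in the frequency-domain deconvolution makes P
    invariant to this scaling; normalisation is kept for numerical hygiene
    and for parity with the preprocessing convention.
    """
    signal = np.asarray(signal, dtype=float)
    total = signal.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = signal / total
    return np.where(total > 0, out, np.nan)


def harmonic_frequencies(
    config: AcquisitionConfig, n_harmonics: int = N_HARMONICS
) -> np.ndarray:
    """First ``n`` harmonic frequencies (Hz) of the concatenated spectrum.

    The frequency resolution is ``sampling_rate / (3 M)`` (5.59 MHz for
    2.5 GHz and M = 149); harmonics are its integer multiples and all nine
    stay within the ~60 MHz fluorescence bandwidth.
    """
    df = config.sampling_rate / (3 * config.n_samples_per_channel)
    return df * np.arange(1, n_harmonics + 1)


def frequency_deconvolve(
    concat_signal: np.ndarray,
    concat_irf_trace: np.ndarray,
    n_harmonics: int = N_HARMONICS,
    rel_tol: float = 1e-9,
) -> np.ndarray:
    """Normalised frequency response P at the first ``n`` harmonic bins.

    ``concat_signal`` has time on the last axis (length 3*M, matching the
    IRF trace).  Raises when the IRF spectrum is numerically zero at a
    requested harmonic (ill-posed division).  Returns complex values with
    the imaginary part sign-flipped so that S = Im P is positive for decays
    (phasor convention).
    """
    y = np.asarray(concat_signal, dtype=float)
    u = np.asarray(concat_irf_trace, dtype=float)
    if y.shape[-1] != len(u):
        raise ValueError("signal and IRF concatenations differ in length")
    k = np.arange(n_harmonics + 1)
    U = np.fft.rfft(u)[k]
    if np.any(np.abs(U[1:]) < rel_tol * np.abs(U[0])):
        bad = k[1:][np.abs(U[1:]) < rel_tol * np.abs(U[0])]
        raise ValueError(
            f"IRF spectrum vanishes at harmonic(s) {bad.tolist()}: "
            "deconvolution is ill-posed (identical per-channel IRFs null "
            "every harmonic not divisible by 3)"
        )
    Y = np.fft.rfft(y, axis=-1)[..., k]
    P = Y[..., 1:] * U[0] / (U[1:] * Y[..., :1])
    return np.conj(P)  # (G, S) with S >= 0 for causal decays


def fit_phasor_gaussian(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood bivariate Gaussian fit of a phasor point cloud.

    ``points`` is (n, 2) with columns (G, S); returns the sample mean and the
    maximum-likelihood (1/n) covariance matrix.  Requires at least three
    points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be of shape (n, 2)")
    if len(pts) < 3:
        raise ValueError("need at least three phasor points")
    mean = pts.mean(axis=0)
    centred = pts - mean
    cov = centred.T @ centred / len(pts)
    return mean, cov


def _major_minor(cov: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(leading eigenvector, leading eigenvalue, trailing eigenvalue)."""
    vals, vecs = np.linalg.eigh(cov)
    return vecs[:, 1], float(vals[1]), float(vals[0])


def phasor_pair_features(
    mean1: np.ndarray,
    cov1: np.ndarray,
    mean2: np.ndarray,
    cov2: np.ndarray,
    spread_mode: str = "determinant",
) -> tuple[float, float, float, float]:
    """(distance, spread, angle, symmetry) comparing two phasor Gaussians.

    distance: Euclidean norm of the mean difference.
    spread:   |det(cov1) - det(cov2)| (``spread_mode="determinant"``, the
              covariance determinant being the distribution's spread
              measure) or the Frobenius norm of cov1 - cov2
              (``spread_mode="frobenius"``).
    angle:    acute angle in degrees between the leading eigenvectors.
    symmetry: |s1 - s2| with s = (major eigenvalue)/(minor eigenvalue) >= 1;
              NaN when a minor eigenvalue is numerically zero.
    All four are symmetric under swapping the two regions.
    """
    mean1 = np.asarray(mean1, float)
    mean2 = np.asarray(mean2, float)
    distance = float(np.linalg.norm(mean1 - mean2))
    if spread_mode == "determinant":
        spread = float(abs(np.linalg.det(cov1) - np.linalg.det(cov2)))
    elif spread_mode == "frobenius":
        spread = float(np.linalg.norm(np.asarray(cov1) - np.asarray(cov2), "fro"))
    else:
        raise ValueError("spread_mode must be 'determinant' or 'frobenius'")
    v1, l1_max, l1_min = _major_minor(np.asarray(cov1, float))
    v2, l2_max, l2_min = _major_minor(np.asarray(cov2, float))
    # point-like clouds (covariances at float-rounding scale): no shape to compare
    if max(abs(l1_max), abs(l2_max)) < 1e-18:
        return distance, spread, 0.0, 0.0
    cosang = np.clip(abs(float(v1 @ v2)), 0.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    if l1_max < 1e-18 or l2_max < 1e-18:
        return distance, spread, float("nan"), float("nan")
    if l1_min <= 1e-12 * l1_max or l2_min <= 1e-12 * l2_max:
        symmetry = float("nan")  # a degenerate (line) cloud has no axis ratio
    else:
        symmetry = float(abs(l1_max / l1_min - l2_max / l2_min))
    return distance, spread, angle, symmetry


def phasor_histogram(
    points: np.ndarray,
    bins: int = 64,
    extent: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 0.6),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of a phasor point cloud (for plotting/export).

    Returns (counts, G edges, S edges); the Gaussian fits themselves use the
    raw points, binning is visualisation only.
    """
    pts = np.asarray(points, dtype=float)
    g0, g1, s0, s1 = extent
    return np.histogram2d(pts[:, 0], pts[:, 1], bins=bins,
                          range=[[g0, g1], [s0, s1]])


@dataclass
class PhasorDistribution:
    """One region's phasor cloud and Gaussian fit at one harmonic."""

    frequency_hz: float
    points: np.ndarray
    mean: np.ndarray
    cov: np.ndarray


def extract_phasor_pool(
    concat: ConcatenatedImage,
    irf: InstrumentResponse,
    masks: RegionMasks,
    config: AcquisitionConfig,
    n_harmonics: int = N_HARMONICS,
    spread_mode: str = "determinant",
    return_distributions: bool = False,
):
    """The 36 phasor global features of one preprocessed image.

    Phasor points are computed per valid pixel from the concatenated,
    offset-subtracted decays; each clustered region's cloud is fitted by a
    bivariate Gaussian at each of the nine harmonics and the four pairwise
    features are emitted under names ``{kind}_{frequency}MHz``.
    """
    u = concat_irf(irf, concat.segment_length)
    valid = masks.valid
    signals = concat.data[valid]
    phasors = frequency_deconvolve(signals, u, n_harmonics=n_harmonics)
    in_r1 = masks.region1[valid]
    in_r2 = masks.region2[valid]
    freqs = harmonic_frequencies(config, n_harmonics)
    features: dict[str, float] = {}
    dists: list[tuple[PhasorDistribution, PhasorDistribution]] = []
    for k in range(n_harmonics):
        pts = np.column_stack([phasors[:, k].real, phasors[:, k].imag])
        p1, p2 = pts[in_r1], pts[in_r2]
        m1, c1 = fit_phasor_gaussian(p1)
        m2, c2 = fit_phasor_gaussian(p2)
        d, sp, ang, sym = phasor_pair_features(m1, c1, m2, c2, spread_mode=spread_mode)
        label = harmonic_label(k + 1)
        features[f"distance_{label}MHz"] = d
        features[f"spread_{label}MHz"] = sp
        features[f"angle_{label}MHz"] = ang
        features[f"symmetry_{label}MHz"] = sym
        if return_distributions:
            dists.append(
                (
                    PhasorDistribution(freqs[k], p1, m1, c1),
                    PhasorDistribution(freqs[k], p2, m2, c2),
                )
            )
    ordered = {name: features[name] for name in PHASOR_POOL[: 4 * n_harmonics]}
    if return_distributions:
        return ordered, dists
    return ordered
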