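"""Pixel- and image-level preprocessing of maFLIM decay cubes.

Pipeline order: baseline-offset subtraction -> 5x5 spatial averaging ->
saturation/SNR masking -> tail zero-padding and channel concatenation ->
two-cluster K-means segmentation of the valid pixels into region-1/region-2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from sklearn.cluster import KMeans

from .core import ConcatenatedImage, InstrumentResponse, RegionMasks, TimeResolvedImage

__all__ = [
    "subtract_offset",
    "subtract_offset_image",
    "spatial_average",
    "estimate_snr",
    "mask_pixels",
    "pad_and_concatenate",
    "concat_irf",
    "cluster_regions",
    "preprocess_image",
    "ProcessedImage",
]


def subtract_offset(decay: np.ndarray, n_edge: int = 5) -> np.ndarray:
    """Remove the baseline by a joint straight-line fit to both signal ends.

    A least-squares line through the first and last ``n_edge`` time points
    (jointly) is evaluated over the full time vector and subtracted.  Works on
    any array whose last axis is time.
    """
    decay = np.asarray(decay, dtype=float)
    n = decay.shape[-1]
    if n < 2 * n_edge:
        raise ValueError("decay must have at least 2*n_edge samples")
    idx = np.concatenate([np.arange(n_edge), np.arange(n - n_edge, n)])
    # joint LS line through the edge samples, vectorised over leading axes
    x = idx.astype(float)
    xm = x.mean()
    y = decay[..., idx]
    ym = y.mean(axis=-1, keepdims=True)
    denom = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym), axis=-1, keepdims=True) / denom
    intercept = ym - slope * xm
    t_full = np.arange(n, dtype=float)
    return decay - (slope * t_full + intercept)


def subtract_offset_image(image: TimeResolvedImage, n_edge: int = 5) -> TimeResolvedImage:
    """Per-channel baseline removal over a whole image."""
    out = image.copy()
    out.channels = {c: subtract_offset(a, n_edge) for c, a in image.channels.items()}
    return out


def spatial_average(image: TimeResolvedImage, order: int = 5) -> TimeResolvedImage:
    """Box-filter every time sample over an ``order x order`` neighbourhood.

    At image borders the mean is taken over the in-bounds neighbours only
    (renormalised box filter), avoiding artificial darkening of the edge.
    """
    if order % 2 == 0 or order < 1:
        raise ValueError("averaging order must be odd and >= 1")
    if order == 1:
        return image.copy()
    out = image.copy()
    rows, cols = image.shape
    ones = np.ones((rows, cols))
    counts = uniform_filter(ones, size=order, mode="constant", cval=0.0)
    new = {}
    for c, cube in image.channels.items():
        summed = uniform_filter(cube, size=(order, order, 1), mode="constant", cval=0.0)
        new[c] = summed / counts[..., None]
    out.channels = new
    return out


def _smooth3(cube: np.ndarray) -> np.ndarray:
    """3-sample moving average along time (edges averaged over 2 samples)."""
    out = cube.copy()
    out[..., 1:-1] = (cube[..., :-2] + cube[..., 1:-1] + cube[..., 2:]) / 3.0
    out[..., 0] = (cube[..., 0] + cube[..., 1]) / 2.0
    out[..., -1] = (cube[..., -2] + cube[..., -1]) / 2.0
    return out


def estimate_snr(
    image: TimeResolvedImage,
    n_head: int = 6,
    n_tail: int = 10,
) -> np.ndarray:
    """Per-pixel SNR in dB: decay peak over baseline noise standard deviation.

    Computed on the channel with the largest peak at each pixel, from the
    offset-subtracted decay: the noise level is the standard deviation of the
    signal-free samples at both ends of the trace (the pre-pulse head and the
    fully-decayed tail); the peak is taken after a light 3-sample smoothing
    so it is not dominated by the noise maximum.  Returns ``-inf`` where the
    peak is not positive.
    """
    peaks = []
    noises = []
    for cube in image.channels.values():
        peaks.append(_smooth3(cube).max(axis=-1))
        edges = np.concatenate([cube[..., :n_head], cube[..., -n_tail:]], axis=-1)
        noises.append(edges.std(axis=-1, ddof=1))
    peaks = np.stack(peaks, axis=0)
    noises = np.stack(noises, axis=0)
    best = np.argmax(peaks, axis=0)
    r, c = np.indices(best.shape)
    peak = peaks[best, r, c]
    noise = noises[best, r, c]
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = 20.0 * np.log10(peak / noise)
    snr = np.where(peak > 0, snr, -np.inf)
    return np.where(np.isnan(snr), np.inf, snr)  # zero noise, positive peak


def mask_pixels(
    image: TimeResolvedImage,
    snr_db_min: float = 15.0,
    adc_max: float | None = None,
    raw: TimeResolvedImage | None = None,
) -> np.ndarray:
    """Valid-pixel mask: not saturated in any channel and SNR above threshold.

    Saturation is tested on ``raw`` (the unprocessed cube) when provided,
    since offset subtraction and averaging blur the railed-ADC signature;
    the SNR test uses ``image`` as given.
    """
    valid = estimate_snr(image) >= snr_db_min
    if adc_max is None:
        adc_max = image.adc_max if raw is None else raw.adc_max
    if adc_max is not None:
        src = raw if raw is not None else image
        for cube in src.channels.values():
            valid &= ~(cube >= adc_max).any(axis=-1)
    return valid


def pad_and_concatenate(image: TimeResolvedImage) -> ConcatenatedImage:
    """Zero-pad each channel's tail to the longest length M and concatenate.

    Channels are laid end to end in ascending band order (390, 452, 500);
    padding at the tail preserves the rising-edge alignment with the IRF.
    """
    order = image.channel_order
    M = max(image.channels[c].shape[-1] for c in order)
    segs = []
    for c in order:
        cube = image.channels[c]
        pad = M - cube.shape[-1]
        if pad:
            width = [(0, 0)] * (cube.ndim - 1) + [(0, pad)]
            cube = np.pad(cube, width)
        segs.append(cube)
    return ConcatenatedImage(
        data=np.concatenate(segs, axis=-1),
        dt=image.dt,
        segment_length=M,
        channel_order=order,
    )


def concat_irf(irf: InstrumentResponse, segment_length: int | None = None) -> np.ndarray:
    """Tail-pad each channel IRF to M samples and concatenate in band order.

    Shares the padding/concatenation path of the signal branch; raises if the
    IRF is longer than the requested segment length.
    """
    order = tuple(sorted(irf.channels))
    M = segment_length if segment_length is not None else irf.n_samples
    if irf.n_samples > M:
        raise ValueError("IRF longer than the signal segment length")
    image = TimeResolvedImage(
        channels={c: np.pad(irf.channels[c], (0, M - irf.n_samples))[None, None, :]
                  for c in order},
        dt=irf.dt,
    )
    return pad_and_concatenate(image).data[0, 0]


def cluster_regions(
    concat: ConcatenatedImage,
    valid: np.ndarray,
    seed: int = 0,
    n_init: int = 10,
) -> RegionMasks:
    """Two-cluster K-means on the valid pixels' concatenated decays.

    The concatenated decay is the per-pixel feature vector, so all three
    emission channels inform the segmentation simultaneously.  Cluster
    numbering is arbitrary; downstream features are invariant to it.
    """
    valid = np.asarray(valid, dtype=bool)
    vectors = concat.data[valid]
    if len(vectors) < 2:
        raise ValueError("need at least two valid pixels to cluster")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    labels = km.fit_predict(vectors)
    if len(np.unique(labels)) < 2:
        raise ValueError(
            "degenerate clustering: all valid pixels fell in one cluster "
            f"(inertia={km.inertia_:.3g}); the image may lack two regions"
        )
    region1 = np.zeros_like(valid)
    region2 = np.zeros_like(valid)
    region1[valid] = labels == 0
    region2[valid] = labels == 1
    return RegionMasks(valid=valid, region1=region1, region2=region2)


@dataclass
class ProcessedImage:
    """Bundle of the preprocessing outputs consumed by feature extraction."""

    image: TimeResolvedImage       # offset-subtracted, spatially averaged
    concat: ConcatenatedImage
    masks: RegionMasks
    snr_db: np.ndarray


def preprocess_image(
    image: TimeResolvedImage,
    n_edge: int = 5,
    order: int = 5,
    snr_db_min: float = 15.0,
    seed: int = 0,
) -> ProcessedImage:
    """Run the full preprocessing chain on one maFLIM image."""
    sub = subtract_offset_image(image, n_edge=n_edge)
    avg = spatial_average(sub, order=order)
    valid = mask_pixels(avg, snr_db_min=snr_db_min, raw=image)
    concat = pad_and_concatenate(avg)
    masks = cluster_regions(concat, valid, seed=seed)
    return ProcessedImage(image=avg, concat=concat, masks=masks, snr_db=estimate_snr(avg))
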