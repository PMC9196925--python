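"""HDF5 dataset and CSV manifest storage for synthetic maFLIM cohorts.

Layout: ``/lesions/<id>/channel_<band>`` holds each 3-D decay cube with
``patient_id``/``label`` attributes on the lesion group; ``/irf/channel_<band>``
holds the per-channel IRF traces (with Gaussian pulse parameters as
attributes when known); acquisition settings are root attributes; ``/meta``
is a (lesion_id, patient_id, label) table mirrored by a CSV manifest.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import AcquisitionConfig, InstrumentResponse, TimeResolvedImage
from .simulate import SimulatedLesion


def save_cohort(
    path: str | Path,
    lesions: list[SimulatedLesion],
    irf: InstrumentResponse,
    config: AcquisitionConfig,
    manifest_path: str | Path | None = None,
) -> None:
    """Write a cohort, its IRF and acquisition settings to one HDF5 file."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for key in ("rows", "cols", "dt", "n_samples_per_channel",
                    "sampling_rate", "pixel_rate"):
            f.attrs[key] = getattr(config, key)
        f.attrs["channels"] = list(config.channels)
        g_irf = f.create_group("irf")
        for ch, trace in irf.channels.items():
            d = g_irf.create_dataset(f"channel_{ch}", data=trace)
            if irf.gaussian_params and ch in irf.gaussian_params:
                d.attrs["fwhm_ns"], d.attrs["t0_ns"] = irf.gaussian_params[ch]
        g_les = f.create_group("lesions")
        for les in lesions:
            g = g_les.create_group(les.lesion_id)
            g.attrs["patient_id"] = les.patient_id
            g.attrs["label"] = les.label
            if les.image.adc_max is not None:
                g.attrs["adc_max"] = les.image.adc_max
            for ch, cube in les.image.channels.items():
                g.create_dataset(f"channel_{ch}", data=cube, compression="gzip")
        meta = np.array(
            [(l.lesion_id, l.patient_id, l.label) for l in lesions],
            dtype=[("lesion_id", "S16"), ("patient_id", "S16"), ("label", "S16")],
        )
        f.create_dataset("meta", data=meta)
    if manifest_path is not None:
        manifest(lesions).to_csv(manifest_path, index=False)


def save_masks(path: str | Path, lesion_id: str, masks) -> None:
    """Store a lesion's validity and region masks next to its decay cubes."""
    with h5py.File(path, "a") as f:
        g = f[f"lesions/{lesion_id}"]
        for name in ("valid", "region1", "region2"):
            if name in g:
                del g[name]
            g.create_dataset(name, data=getattr(masks, name))


def load_masks(path: str | Path, lesion_id: str):
    from .core import RegionMasks

    with h5py.File(path, "r") as f:
        g = f[f"lesions/{lesion_id}"]
        return RegionMasks(
            valid=g["valid"][()].astype(bool),
            region1=g["region1"][()].astype(bool),
            region2=g["region2"][()].astype(bool),
        )


def manifest(lesions: list[SimulatedLesion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"lesion_id": l.lesion_id, "patient_id": l.patient_id, "label": l.label}
            for l in lesions
        ]
    )


def load_cohort(
    path: str | Path,
) -> tuple[list[SimulatedLesion], InstrumentResponse, AcquisitionConfig]:
    """Read back a cohort written by :func:`save_cohort`."""
    with h5py.File(path, "r") as f:
        config = AcquisitionConfig(
            rows=int(f.attrs["rows"]),
            cols=int(f.attrs["cols"]),
            dt=float(f.attrs["dt"]),
            n_samples_per_channel=int(f.attrs["n_samples_per_channel"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            pixel_rate=float(f.attrs["pixel_rate"]),
            channels=tuple(int(c) for c in f.attrs["channels"]),
        )
        irf_channels, gaussians = {}, {}
        for name, d in f["irf"].items():
            ch = int(name.split("_")[1])
            irf_channels[ch] = d[()]
            if "fwhm_ns" in d.attrs:
                gaussians[ch] = (float(d.attrs["fwhm_ns"]), float(d.attrs["t0_ns"]))
        irf = InstrumentResponse(
            channels=irf_channels,
            dt=config.dt,
            gaussian_params=gaussians or None,
        )
        lesions = []
        for lesion_id in sorted(f["lesions"]):
            g = f["lesions"][lesion_id]
            channels = {
                int(name.split("_")[1]): d[()]
                for name, d in g.items()
            }
            image = TimeResolvedImage(
                channels=channels,
                dt=config.dt,
                adc_max=float(g.attrs["adc_max"]) if "adc_max" in g.attrs else None,
            )
            lesions.append(
                SimulatedLesion(
                    lesion_id=lesion_id,
                    patient_id=str(g.attrs["patient_id"]),
                    label=str(g.attrs["label"]),
                    image=image,
                )
            )
    return lesions, irf, config
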