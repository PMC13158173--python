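"""HDF5 / CSV containers for channel data, images, AC maps and echo trains.

Every file carries unit attributes and provenance (seed, config hash)
where available; readers validate the schema and name missing datasets.
"""

from __future__ import annotations

import hashlib
import json

import h5py
import numpy as np
import pandas as pd

from .attenuation import ACMap
from .beamforming import BeamformedImage
from .pdff import EchoTrain
from .rf_simulator import ChannelData, PhantomSpec, ProbeGeometry


class SchemaError(KeyError):
    """A container is missing required datasets."""


def _require(h5, names, path):
    missing = [n for n in names if n not in h5]
    if missing:
        raise SchemaError(f"{path}: missing required dataset(s)/group(s): {missing}")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_probe(group: h5py.Group, probe: ProbeGeometry) -> None:
    for k, v in probe.__dict__.items():
        group.attrs[k] = v


def _read_probe(group: h5py.Group) -> ProbeGeometry:
    return ProbeGeometry(
        n_elements=int(group.attrs["n_elements"]),
        pitch_um=float(group.attrs["pitch_um"]),
        element_width_um=float(group.attrs["element_width_um"]),
        center_frequency_mhz=float(group.attrs["center_frequency_mhz"]),
        sampling_frequency_mhz=float(group.attrs["sampling_frequency_mhz"]),
        fractional_bandwidth=float(group.attrs["fractional_bandwidth"]),
    )


def write_channel_data(path: str, data: ChannelData) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("rf", data=data.rf)
        d.attrs["units"] = "pressure-proportional amplitude"
        t = f.create_dataset("time_axis", data=data.time_axis_us)
        t.attrs["units"] = "us"
        _write_probe(f.create_group("probe"), data.probe)
        for k, v in data.meta.items():
            f.attrs[k] = v
        if data.truth is not None:
            g = f.create_group("phantom_truth")
            g.create_dataset("x_axis_cm", data=data.truth.x_axis_cm)
            g.create_dataset("z_axis_cm", data=data.truth.z_axis_cm)
            g.create_dataset("alpha0_map", data=data.truth.alpha0_map)
            g["alpha0_map"].attrs["units"] = "Np/(cm.MHz)"
            g.create_dataset("echogenicity_map", data=data.truth.echogenicity_map)
            g.attrs["sound_speed_m_s"] = data.truth.sound_speed_m_s
            g.attrs["scatterer_density"] = data.truth.scatterer_density


def read_channel_data(path: str) -> ChannelData:
    with h5py.File(path, "r") as f:
        _require(f, ["rf", "time_axis", "probe"], path)
        probe = _read_probe(f["probe"])
        truth = None
        if "phantom_truth" in f:
            g = f["phantom_truth"]
            truth = PhantomSpec(
                x_axis_cm=g["x_axis_cm"][:],
                z_axis_cm=g["z_axis_cm"][:],
                alpha0_map=g["alpha0_map"][:],
                echogenicity_map=g["echogenicity_map"][:],
                sound_speed_m_s=float(g.attrs["sound_speed_m_s"]),
                scatterer_density=float(g.attrs["scatterer_density"]),
            )
        return ChannelData(
            rf=f["rf"][:],
            time_axis_us=f["time_axis"][:],
            probe=probe,
            truth=truth,
            meta=dict(f.attrs),
        )


def write_beamformed_image(path: str, image: BeamformedImage) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("beamformed", data=image.s)
        d.attrs["units"] = "beamformed RF amplitude"
        f.create_dataset("x_axis", data=image.x_axis_cm).attrs["units"] = "cm"
        f.create_dataset("z_axis", data=image.z_axis_cm).attrs["units"] = "cm"
        f.attrs["sound_speed_m_s"] = image.sound_speed_m_s
        _write_probe(f.create_group("probe"), image.probe)
        for k, v in (image.meta or {}).items():
            f.attrs[k] = v


def read_beamformed_image(path: str) -> BeamformedImage:
    with h5py.File(path, "r") as f:
        _require(f, ["beamformed", "x_axis", "z_axis", "probe"], path)
        return BeamformedImage(
            s=f["beamformed"][:],
            x_axis_cm=f["x_axis"][:],
            z_axis_cm=f["z_axis"][:],
            sound_speed_m_s=float(f.attrs["sound_speed_m_s"]),
            probe=_read_probe(f["probe"]),
            meta={k: v for k, v in f.attrs.items() if k != "sound_speed_m_s"},
        )


def write_acmap(path: str, acmap: ACMap) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("alpha0_map", data=acmap.alpha0)
        d.attrs["units"] = "Np/(cm.MHz)"
        f.create_dataset("x_centers", data=acmap.x_centers_cm).attrs["units"] = "cm"
        f.create_dataset("z_centers", data=acmap.z_centers_cm).attrs["units"] = "cm"
        f.create_dataset("fit_r2", data=acmap.fit_r2)
        f.attrs["pixel_size_lambda"] = acmap.pixel_size_lambda
        f.attrs["overlap"] = acmap.overlap
        f.attrs["depth_range_cm"] = acmap.depth_range_cm


def read_acmap(path: str) -> ACMap:
    with h5py.File(path, "r") as f:
        _require(f, ["alpha0_map", "x_centers", "z_centers", "fit_r2"], path)
        return ACMap(
            alpha0=f["alpha0_map"][:],
            x_centers_cm=f["x_centers"][:],
            z_centers_cm=f["z_centers"][:],
            pixel_size_lambda=float(f.attrs["pixel_size_lambda"]),
            overlap=float(f.attrs["overlap"]),
            depth_range_cm=tuple(f.attrs["depth_range_cm"]),
            fit_r2=f["fit_r2"][:],
        )


def acmap_to_csv(path: str, acmap: ACMap) -> None:
    """Long-format CSV export: one row per map pixel (x, z, alpha0, r2)."""
    xx, zz = np.meshgrid(acmap.x_centers_cm, acmap.z_centers_cm, indexing="ij")
    df = pd.DataFrame(
        {
            "x_cm": xx.ravel(),
            "z_cm": zz.ravel(),
            "alpha0": acmap.alpha0.ravel(),
            "r2": acmap.fit_r2.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.8g")


def read_acmap_csv(path: str, pixel_size_lambda=np.nan, overlap=0.0,
                   depth_range_cm=(np.nan, np.nan)) -> ACMap:
    df = pd.read_csv(path)
    x = np.unique(df["x_cm"].to_numpy())
    z = np.unique(df["z_cm"].to_numpy())
    shape = (x.size, z.size)
    order = np.lexsort((df["z_cm"], df["x_cm"]))
    return ACMap(
        alpha0=df["alpha0"].to_numpy()[order].reshape(shape),
        x_centers_cm=x,
        z_centers_cm=z,
        pixel_size_lambda=pixel_size_lambda,
        overlap=overlap,
        depth_range_cm=depth_range_cm,
        fit_r2=df["r2"].to_numpy()[order].reshape(shape),
    )


def write_echo_train(path: str, train: EchoTrain) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=train.signals)
        f.create_dataset("TEs", data=train.tes_ms).attrs["units"] = "ms"
        f.attrs["field_strength_t"] = train.field_strength_t
        for k, v in train.meta.items():
            f.attrs[k] = v


def read_echo_train(path: str) -> EchoTrain:
    with h5py.File(path, "r") as f:
        _require(f, ["signals", "TEs"], path)
        return EchoTrain(
            tes_ms=f["TEs"][:],
            signals=f["signals"][:],
            field_strength_t=float(f.attrs.get("field_strength_t", 3.0)),
            meta={k: v for k, v in f.attrs.items() if k != "field_strength_t"},
        )


def read_mask(path: str, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a binary ROI mask from a CSV grid (0/1) or a PNG (0/255)."""
    if str(path).lower().endswith(".png"):
        from PIL import Image  # optional dependency, only for PNG masks

        arr = np.asarray(Image.open(path).convert("L"))
        mask = arr > 127
    else:
        mask = np.loadtxt(path, delimiter=",") > 0.5
    if shape is not None and mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} does not match expected {shape}")
    return mask
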