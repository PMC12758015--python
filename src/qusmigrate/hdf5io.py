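"""HDF5 containers for frames, patch sets, and transfer functions.

Frame files hold ``frames`` (n x axial x lateral) and ``labels`` datasets
with acquisition metadata and serialized machine/phantom profiles as
attributes, next to a JSON manifest string. Patch and transfer-function files
mirror the in-memory dataclasses field by field.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .preprocess import PatchSet
from .rf_sim import MachineProfile, PhantomProfile, RFFrame, profile_from_json, profile_to_json
from .transfer_function import DepthGrid, TransferFunction

__all__ = [
    "save_frames",
    "load_frames",
    "save_patchset",
    "load_patchset",
    "save_transfer_function",
    "load_transfer_function",
]


def save_frames(
    path: str | Path,
    frames: list[RFFrame],
    labels: np.ndarray | None = None,
    machine: MachineProfile | None = None,
    phantoms: list[PhantomProfile] | None = None,
    manifest: dict | None = None,
) -> None:
    f0 = frames[0]
    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=np.stack([f.samples for f in frames]))
        if labels is not None:
            h5.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))
        h5.attrs["sampling_rate"] = f0.sampling_rate
        h5.attrs["axial_spacing"] = f0.axial_spacing
        h5.attrs["lateral_pitch"] = f0.lateral_pitch
        h5.attrs["machine_ids"] = json.dumps([f.machine_id for f in frames])
        h5.attrs["phantom_ids"] = json.dumps([f.phantom_id for f in frames])
        if machine is not None:
            h5.attrs["machine_profile"] = profile_to_json(machine)
        if phantoms is not None:
            h5.attrs["phantom_profiles"] = json.dumps([profile_to_json(p) for p in phantoms])
        h5.attrs["manifest"] = json.dumps(manifest or {})


def load_frames(path: str | Path) -> tuple[list[RFFrame], np.ndarray | None, dict]:
    with h5py.File(path, "r") as h5:
        data = h5["frames"][()]
        labels = h5["labels"][()] if "labels" in h5 else None
        machine_ids = json.loads(h5.attrs["machine_ids"])
        phantom_ids = json.loads(h5.attrs["phantom_ids"])
        meta = {
            "sampling_rate": float(h5.attrs["sampling_rate"]),
            "axial_spacing": float(h5.attrs["axial_spacing"]),
            "lateral_pitch": float(h5.attrs["lateral_pitch"]),
            "manifest": json.loads(h5.attrs.get("manifest", "{}")),
        }
        if "machine_profile" in h5.attrs:
            meta["machine_profile"] = profile_from_json(h5.attrs["machine_profile"])
        if "phantom_profiles" in h5.attrs:
            meta["phantom_profiles"] = [
                profile_from_json(s) for s in json.loads(h5.attrs["phantom_profiles"])
            ]
    frames = [
        RFFrame(
            samples=data[i],
            sampling_rate=meta["sampling_rate"],
            axial_spacing=meta["axial_spacing"],
            lateral_pitch=meta["lateral_pitch"],
            machine_id=machine_ids[i],
            phantom_id=phantom_ids[i],
            frame_index=i,
        )
        for i in range(len(data))
    ]
    return frames, labels, meta


def save_patchset(path: str | Path, ps: PatchSet) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("patches", data=ps.patches)
        h5.create_dataset("coords", data=ps.coords)
        if ps.labels is not None:
            h5.create_dataset("labels", data=np.asarray(ps.labels, dtype=np.int64))
        h5.attrs["provenance"] = ps.provenance
        h5.attrs["sampling_rate"] = ps.sampling_rate
        h5.attrs["axial_spacing"] = ps.axial_spacing


def load_patchset(path: str | Path) -> PatchSet:
    with h5py.File(path, "r") as h5:
        return PatchSet(
            patches=h5["patches"][()],
            coords=h5["coords"][()],
            labels=h5["labels"][()] if "labels" in h5 else None,
            provenance=str(h5.attrs["provenance"]),
            sampling_rate=float(h5.attrs["sampling_rate"]),
            axial_spacing=float(h5.attrs["axial_spacing"]),
        )


def save_transfer_function(path: str | Path, tf: TransferFunction, provenance: dict | None = None) -> None:
    with h5py.File(path, "w") as h5:
        for name in ("gamma_raw", "gamma_wiener", "snr", "band_mask", "freq_grid", "depth_centers"):
            h5.create_dataset(name, data=getattr(tf, name))
        h5.attrs["window_length"] = tf.grid.window_length
        h5.attrs["window_overlap"] = tf.grid.window_overlap
        h5.attrs["start_offset"] = tf.grid.start_offset
        h5.attrs["window_taper"] = tf.grid.window_taper
        h5.attrs["sampling_rate"] = tf.sampling_rate
        h5.attrs["axial_spacing"] = tf.axial_spacing
        h5.attrs["provenance"] = json.dumps(provenance or {})


def load_transfer_function(path: str | Path) -> TransferFunction:
    with h5py.File(path, "r") as h5:
        grid = DepthGrid(
            window_length=int(h5.attrs["window_length"]),
            window_overlap=float(h5.attrs["window_overlap"]),
            start_offset=int(h5.attrs["start_offset"]),
            window_taper=str(h5.attrs["window_taper"]),
        )
        return TransferFunction(
            gamma_raw=h5["gamma_raw"][()],
            gamma_wiener=h5["gamma_wiener"][()],
            snr=h5["snr"][()],
            band_mask=h5["band_mask"][()].astype(bool),
            freq_grid=h5["freq_grid"][()],
            depth_centers=h5["depth_centers"][()],
            grid=grid,
            sampling_rate=float(h5.attrs["sampling_rate"]),
            axial_spacing=float(h5.attrs["axial_spacing"]),
        )
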