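"""HDF5 container for session recordings.

Schema (format tag ``laminargc-session/1``):

* datasets: ``lfp`` (trial x channel x sample, float64, µV), optional
  ``baseline`` and ``mua_envelope``, ``condition`` (per-trial label),
  ``probe_of_channel`` (per-channel area), ``channel_position``
  (per-channel position in spacing units).
* root attributes: ``format``, ``fs``, ``spacing_um``, ``epoch_alignment``,
  ``referencing``, ``seed`` and, for synthetic sessions, the generator
  configuration serialized as JSON in ``ground_truth``.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .session import BipolarRecording, SessionRecording
from .synthetic import GeneratorConfig

FORMAT_TAG = "laminargc-session/1"


def save_session(path, rec: SessionRecording) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = FORMAT_TAG
        f.attrs["fs"] = rec.fs
        f.attrs["spacing_um"] = rec.spacing_um
        f.attrs["epoch_alignment"] = rec.epoch_alignment
        f.attrs["referencing"] = rec.referencing
        if rec.seed is not None:
            f.attrs["seed"] = int(rec.seed)
        if isinstance(rec.ground_truth, GeneratorConfig):
            f.attrs["ground_truth"] = json.dumps(rec.ground_truth.to_dict())
        f.create_dataset("lfp", data=rec.lfp)
        f.create_dataset("condition", data=rec.condition.astype("S8"))
        f.create_dataset("probe_of_channel", data=rec.probe_of_channel.astype("S8"))
        f.create_dataset("channel_position", data=rec.channel_position)
        if rec.baseline is not None:
            f.create_dataset("baseline", data=rec.baseline)
        if rec.mua_envelope is not None:
            f.create_dataset("mua_envelope", data=rec.mua_envelope)


def load_session(path) -> SessionRecording:
    with h5py.File(path, "r") as f:
        tag = f.attrs.get("format", "")
        if tag != FORMAT_TAG:
            raise ValueError(f"unrecognized container format {tag!r}")
        gt = None
        if "ground_truth" in f.attrs:
            gt = GeneratorConfig.from_dict(json.loads(f.attrs["ground_truth"]))
        cls = (BipolarRecording if f.attrs["referencing"] == "bipolar"
               else SessionRecording)
        return cls(
            lfp=f["lfp"][()],
            fs=float(f.attrs["fs"]),
            probe_of_channel=f["probe_of_channel"][()].astype("U8"),
            condition=f["condition"][()].astype("U8"),
            spacing_um=float(f.attrs["spacing_um"]),
            epoch_alignment=str(f.attrs["epoch_alignment"]),
            referencing=str(f.attrs["referencing"]),
            channel_position=f["channel_position"][()],
            baseline=f["baseline"][()] if "baseline" in f else None,
            mua_envelope=f["mua_envelope"][()] if "mua_envelope" in f else None,
            ground_truth=gt,
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
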