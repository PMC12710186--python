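"""Recording container and on-disk formats.

Recordings travel either as delimited text (one column per channel, one
header line) with a small YAML sidecar holding the sampling rate and
labels, or as an HDF5 container with the same information in attributes.
Burst annotations and labeled-segment manifests are written as TSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml


@dataclasses.dataclass
class LFPRecording:
    """Multichannel LFP time series.

    samples: array of shape (n_channels, n_samples), arbitrary units.
    sampling_rate: Hz.
    channel_labels: one label per channel.
    session_id: free-text identifier for provenance.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    session_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None
        return self.samples[idx]


def write_recording_h5(recording: LFPRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("samples", data=recording.samples)
        dset.attrs["fs"] = float(recording.sampling_rate)
        dset.attrs["labels"] = [str(c) for c in recording.channel_labels]
        dset.attrs["session_id"] = recording.session_id


def read_recording_h5(path: str | Path) -> LFPRecording:
    with h5py.File(path, "r") as f:
        dset = f["samples"]
        return LFPRecording(
            samples=dset[()],
            sampling_rate=float(dset.attrs["fs"]),
            channel_labels=[str(c) for c in dset.attrs["labels"]],
            session_id=str(dset.attrs.get("session_id", "")),
        )


def write_recording_text(recording: LFPRecording, path: str | Path) -> None:
    """One column per channel with a header line; YAML sidecar for metadata."""
    path = Path(path)
    df = pd.DataFrame(recording.samples.T, columns=recording.channel_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    meta = {
        "sampling_rate": float(recording.sampling_rate),
        "channel_labels": list(recording.channel_labels),
        "session_id": recording.session_id,
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))


def read_recording_text(path: str | Path, sampling_rate: float | None = None) -> LFPRecording:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".yaml")
    session_id = ""
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        sampling_rate = meta.get("sampling_rate", sampling_rate)
        session_id = meta.get("session_id", "")
    if sampling_rate is None:
        raise ValueError("sampling_rate required when no sidecar metadata is present")
    return LFPRecording(
        samples=df.to_numpy().T,
        sampling_rate=float(sampling_rate),
        channel_labels=[str(c) for c in df.columns],
        session_id=session_id,
    )
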