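"""Epoched-EEG container and its HDF5 on-disk layout.

The on-disk layout is one HDF5 file per participant:

* dataset ``data`` — float array, epochs x channels x samples (microvolts)
* dataset ``trial_result`` — int array, one code per epoch
* attributes ``sample_rate`` (Hz) and ``channel_labels`` (10-20 names)

Trial-result codes index the four N-back trial outcomes:
0 = target-correct, 1 = target-incorrect, 2 = nontarget-correct,
3 = nontarget-incorrect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

TRIAL_RESULT_CODES: dict[int, str] = {
    0: "target_correct",
    1: "target_incorrect",
    2: "nontarget_correct",
    3: "nontarget_incorrect",
}

FRONTAL_ELECTRODES: tuple[str, ...] = (
    "F7", "F8", "F5", "F6", "F3", "F4", "F1", "F2", "Fz",
)


@dataclass
class EpochedEEG:
    """Per-participant epoched EEG with per-epoch trial-result labels."""

    data: np.ndarray  # epochs x channels x samples, microvolts
    sample_rate: float  # Hz
    channel_labels: tuple[str, ...]
    trial_result: np.ndarray = field(default=None)  # int codes, one per epoch

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be epochs x channels x samples, got shape {self.data.shape}"
            )
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[1]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.trial_result is None:
            self.trial_result = np.zeros(self.data.shape[0], dtype=int)
        self.trial_result = np.asarray(self.trial_result, dtype=int)
        if self.trial_result.shape != (self.data.shape[0],):
            raise ValueError("trial_result must have one code per epoch")
        bad = set(np.unique(self.trial_result)) - set(TRIAL_RESULT_CODES)
        if bad:
            raise ValueError(f"unknown trial-result codes: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def write_eeg_h5(eeg: EpochedEEG, path) -> None:
    """Write an :class:`EpochedEEG` to the package HDF5 layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=eeg.data)
        f.create_dataset("trial_result", data=eeg.trial_result)
        f.attrs["sample_rate"] = float(eeg.sample_rate)
        f.attrs["channel_labels"] = list(eeg.channel_labels)


def read_eeg_h5(path) -> EpochedEEG:
    """Read an :class:`EpochedEEG` from the package HDF5 layout."""
    with h5py.File(path, "r") as f:
        labels = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in f.attrs["channel_labels"]
        ]
        return EpochedEEG(
            data=f["data"][...],
            sample_rate=float(f.attrs["sample_rate"]),
            channel_labels=tuple(labels),
            trial_result=f["trial_result"][...],
        )
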