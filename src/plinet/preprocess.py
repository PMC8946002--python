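"""Band-pass filtering, epoch segmentation, artifact screening, selection.

The continuous recording is filtered before segmentation (confining filter
transients to the recording ends), cut into non-overlapping fixed-length
epochs from sample 0, screened with three simple rules standing in for
visual artifact inspection (absolute amplitude, flat line, variance
outlier), and reduced to the configured number of clean epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .types import BandDefinition, ConfigurationError, EEGRecording


class InsufficientEpochsError(RuntimeError):
    """Fewer clean epochs than requested."""


@dataclass
class EpochSet:
    """Fixed-length non-overlapping segments of one band-filtered recording."""

    band: BandDefinition
    channel_labels: list[str]
    fs: float
    epochs: np.ndarray              # (n_epochs, n_channels, epoch_len)
    source_offsets: np.ndarray      # start sample of each epoch
    flags: list[list[str]] = field(default_factory=list)  # artifact annotations

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.source_offsets = np.asarray(self.source_offsets, dtype=int)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, epoch_len)")
        if len(self.source_offsets) != self.epochs.shape[0]:
            raise ValueError("one offset per epoch required")
        d = np.diff(self.source_offsets)
        if np.any(d < self.epochs.shape[2]):
            raise ValueError("offsets must increase by at least the epoch length")
        if not self.flags:
            self.flags = [[] for _ in range(self.epochs.shape[0])]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[2]

    def clean_indices(self) -> np.ndarray:
        return np.array(
            [k for k, f in enumerate(self.flags) if not f], dtype=int
        )


def band_filter(rec: EEGRecording, band: BandDefinition, order: int = 4,
                ) -> EEGRecording:
    """Zero-phase Butterworth band-pass of the continuous recording.

    A 4th-order filter applied forward and backward (8th-order magnitude
    response, zero phase) — phase distortion would bias any phase-based
    connectivity estimate downstream.
    """
    band.check_nyquist(rec.fs)
    sos = signal.butter(order, [band.lo, band.hi], btype="bandpass",
                        fs=rec.fs, output="sos")
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=1))


def segment_epochs(rec: EEGRecording, epoch_len: int,
                   band: BandDefinition | None = None) -> EpochSet:
    """Cut into floor(n/epoch_len) contiguous epochs starting at sample 0."""
    if epoch_len < 2:
        raise ConfigurationError("epoch_len must be >= 2")
    n = rec.n_samples
    if n < epoch_len:
        raise ConfigurationError(
            f"recording of {n} samples shorter than one epoch ({epoch_len})"
        )
    k = n // epoch_len
    offsets = np.arange(k) * epoch_len
    epochs = rec.data[:, :k * epoch_len].reshape(rec.n_channels, k, epoch_len)
    epochs = np.transpose(epochs, (1, 0, 2))
    return EpochSet(
        band=band or BandDefinition("broadband", 1e-6, rec.fs / 2 * 0.999),
        channel_labels=list(rec.channel_labels),
        fs=rec.fs,
        epochs=epochs,
        source_offsets=offsets,
    )


def flag_artifacts(es: EpochSet, amp_uv: float = 100.0, flat_eps: float = 0.1,
                   var_z: float = 5.0) -> EpochSet:
    """Annotate epochs violating amplitude, flat-line or variance rules.

    An epoch is flagged if any channel exceeds ``amp_uv`` in absolute
    amplitude, any channel's peak-to-peak falls below ``flat_eps`` (flat
    line / detached electrode), or any channel's variance is more than
    ``var_z`` standard deviations above that channel's mean variance
    across epochs. Flags accumulate; existing flags are preserved.
    """
    if amp_uv <= 0 or flat_eps <= 0 or var_z <= 0:
        raise ConfigurationError("artifact thresholds must be positive")
    X = es.epochs  # (E, C, T)
    flags = [list(f) for f in es.flags]

    over = np.abs(X).max(axis=2) > amp_uv            # (E, C)
    ptp = X.max(axis=2) - X.min(axis=2)
    flat = ptp < flat_eps
    var = X.var(axis=2)                               # (E, C)
    mu, sd = var.mean(axis=0), var.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (var - mu) / sd, 0.0)
    noisy = z > var_z

    for k in range(es.n_epochs):
        if over[k].any() and "amplitude" not in flags[k]:
            flags[k].append("amplitude")
        if flat[k].any() and "flat" not in flags[k]:
            flags[k].append("flat")
        if noisy[k].any() and "variance" not in flags[k]:
            flags[k].append("variance")
    return replace(es, flags=flags)


def select_epochs(es: EpochSet, n: int, policy: str = "first",
                  seed: int | None = None) -> EpochSet:
    """Keep exactly ``n`` unflagged epochs.

    ``first`` takes the earliest by source offset; ``random`` draws a
    seed-deterministic sample (kept in temporal order).
    """
    clean = es.clean_indices()
    if len(clean) < n:
        raise InsufficientEpochsError(
            f"only {len(clean)} clean epochs available, {n} requested"
        )
    if policy == "first":
        keep = clean[:n]
    elif policy == "random":
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(clean, size=n, replace=False))
    else:
        raise ConfigurationError(f"unknown selection policy {policy!r}")
    return replace(
        es,
        epochs=es.epochs[keep],
        source_offsets=es.source_offsets[keep],
        flags=[[] for _ in keep],
    )
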