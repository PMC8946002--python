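"""Phase lag index (PLI) functional connectivity.

PLI between channels i and j is the absolute time-average of the sign of
their wrapped instantaneous phase difference,

    PLI_ij = | < sign( wrap(phi_i(t) - phi_j(t)) ) >_t |,

with the difference wrapped into (-pi, pi] and sign(0) contributing 0.
PLI is 0 for consistently zero-lag (volume-conducted) synchrony and 1 when
the sign of the lag is constant and nonzero, and it ignores amplitudes
entirely. Phases come from the analytic signal (Hilbert transform) of each
already band-filtered epoch; per-epoch PLI matrices are averaged
element-wise across the selected epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import EpochSet
from .types import BandDefinition


@dataclass
class ConnectivityMatrix:
    """Symmetric per-band PLI matrix over channels, entries in [0, 1]."""

    band: BandDefinition
    channels: list[str]
    W: np.ndarray
    n_epochs_aggregated: int = 1

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        n = len(self.channels)
        if W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n}, got {W.shape}")
        if not np.allclose(W, W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("W diagonal must be exactly zero")
        if W.min() < 0 or W.max() > 1:
            raise ValueError("PLI entries must lie in [0, 1]")
        self.W = W


def instantaneous_phase(epoch: np.ndarray) -> np.ndarray:
    """Per-channel analytic-signal phase in (-pi, pi] of one epoch."""
    epoch = np.asarray(epoch, dtype=float)
    if np.any(epoch.std(axis=-1) == 0):
        bad = np.nonzero(epoch.std(axis=-1) == 0)[0]
        raise ValueError(
            f"constant channel(s) {bad.tolist()}: instantaneous phase undefined"
        )
    return np.angle(hilbert(epoch, axis=-1))


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(x), 2 * np.pi)


def pli_epoch(phases: np.ndarray) -> np.ndarray:
    """PLI matrix of one epoch from its (channels x samples) phases.

    sign(0) counts as 0, keeping the denominator fixed at the sample
    count; the diagonal is exactly zero and the matrix symmetric.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 2 or phases.shape[1] < 2:
        raise ValueError("phases must be (channels x samples) with >= 2 samples")
    n = phases.shape[0]
    iu, ju = np.triu_indices(n, 1)
    d = phases[iu] - phases[ju]  # in (-2*pi, 2*pi) for angles in (-pi, pi]
    # sign of the difference wrapped into (-pi, pi]: flip the raw sign
    # outside (-pi, pi]; d <= -pi wraps to (0, pi] hence +1, d > pi to
    # (-pi, 0) hence -1; sign(0) stays 0.
    s = np.where(d > np.pi, -1.0, np.where(d <= -np.pi, 1.0, np.sign(d)))
    vals = np.abs(s.mean(axis=-1))
    W = np.zeros((n, n))
    W[iu, ju] = vals
    return W + W.T


def aggregate_pli(per_epoch: list[np.ndarray], band: BandDefinition,
                  channels: list[str]) -> ConnectivityMatrix:
    """Element-wise mean of per-epoch PLI matrices."""
    if not per_epoch:
        raise ValueError("need at least one epoch matrix")
    shapes = {m.shape for m in per_epoch}
    if len(shapes) != 1:
        raise ValueError(f"epoch matrices differ in shape: {shapes}")
    W = np.mean(np.stack(per_epoch), axis=0)
    return ConnectivityMatrix(band, list(channels), W, len(per_epoch))


def epoch_plis(es: EpochSet) -> list[np.ndarray]:
    """Per-epoch PLI matrices of an epoch set."""
    return [pli_epoch(instantaneous_phase(ep)) for ep in es.epochs]


def connectivity_from_epochs(es: EpochSet) -> ConnectivityMatrix:
    """Epoch-averaged PLI matrix of a selected epoch set."""
    return aggregate_pli(epoch_plis(es), es.band, es.channel_labels)


def mean_pli(W: np.ndarray) -> float:
    """Mean of the off-diagonal upper-triangle entries (whole-network PLI)."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if n < 2:
        raise ValueError("mean PLI needs at least 2 channels")
    iu = np.triu_indices(n, 1)
    return float(W[iu].mean())
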