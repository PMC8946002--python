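"""Synthetic EEG and cohorts with known phase-coupling ground truth.

The signal model is a phase-mixture oscillator rather than full Kuramoto
dynamics: every channel is a unit-amplitude sinusoid at the band's center
frequency whose instantaneous phase is, sample by sample, either a copy of
its driver channel's phase plus a fixed lag (with probability equal to the
coupling strength) or an independent random-walk phase. The time fraction
spent tracking the driver is therefore the phase-locking strength itself,
which makes the phase lag index of a pair analytically predictable: a pair
coupled at strength c has PLI close to c, exactly 1 at c = 1, and 0 in
expectation at c = 0. White noise and 1/f (pink) background are added on
top of the oscillation.

Cohorts are generated by drawing a per-subject coupling scale from a
group-specific distribution (an additive shift separates the groups),
synthesising EEG per subject, and planting a monotone association between
one true network measure and one behavioral score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .types import (
    AnalysisConfig,
    BandDefinition,
    CohortTable,
    ConfigurationError,
    EEGRecording,
    MEASURE_NAMES,
    MONTAGE_1020_21,
)

#: Default step SD of the independent random-walk phase, rad/sample.
#: Decorrelates uncoupled channels well within one 1024-sample epoch.
PHASE_WALK_SD = 0.1


@dataclass
class CouplingSpec:
    """Pairwise phase-coupling specification for one simulated recording.

    ``coupling`` is a symmetric matrix with zero diagonal and entries in
    [0, 1]: the probability per sample that the higher-indexed channel of
    the pair tracks the lower-indexed one. ``lag`` is the fixed phase lag
    (radians) imposed while tracking — a scalar applied to every pair, or
    an (n, n) matrix giving the lag channel j uses when tracking channel
    i as ``lag[i, j]``. The default pi/4 sits well away from the
    phase-lag-index blind spots at 0 and pi; distinct per-pair lags keep
    channels that track a common driver from locking at zero lag with
    each other (which would null their mutual PLI).
    """

    n_channels: int
    band: BandDefinition
    coupling: np.ndarray
    lag: float | np.ndarray = math.pi / 4
    noise_sd: float = 0.2          # white noise, uV
    pink_noise_weight: float = 0.1  # amplitude of 1/f background, uV
    track_block_samples: int = 256  # coherence block of the tracking mixture
    seed: int = 0

    def __post_init__(self) -> None:
        C = np.asarray(self.coupling, dtype=float)
        if C.shape != (self.n_channels, self.n_channels):
            raise ConfigurationError(
                f"coupling must be {self.n_channels}x{self.n_channels}, got {C.shape}"
            )
        if not np.allclose(C, C.T):
            raise ConfigurationError("coupling matrix must be symmetric")
        if np.any(np.diag(C) != 0):
            raise ConfigurationError("coupling diagonal must be zero")
        if C.min() < 0 or C.max() > 1:
            raise ConfigurationError("coupling entries must lie in [0, 1]")
        L = np.asarray(self.lag, dtype=float)
        if L.ndim not in (0, 2) or (L.ndim == 2 and L.shape != C.shape):
            raise ConfigurationError("lag must be scalar or an (n, n) matrix")
        if np.any(L <= -math.pi) or np.any(L > math.pi):
            raise ConfigurationError("lag must lie in (-pi, pi]")
        self.coupling = C

    def lag_of(self, i: int, j: int) -> float:
        L = np.asarray(self.lag, dtype=float)
        return float(L) if L.ndim == 0 else float(L[i, j])


def uniform_coupling(n_channels: int, band: BandDefinition, strength: float,
                     **kw) -> CouplingSpec:
    """All-to-all coupling at a single strength (zero diagonal)."""
    C = np.full((n_channels, n_channels), float(strength))
    np.fill_diagonal(C, 0.0)
    return CouplingSpec(n_channels, band, C, **kw)


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white noise, unit SD."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    shape[0] = 0.0
    pink = np.fft.irfft(spec * shape, n=n, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def simulate_eeg(spec: CouplingSpec, duration_s: float, fs: float) -> EEGRecording:
    """Synthesize one multichannel recording from a coupling specification.

    Deterministic given ``spec.seed``. Each channel j > 0 with any coupling
    takes its driver to be the lowest-indexed channel i < j with the
    largest coupling[i, j]; channel phases are built in index order so
    coupled groups share a common phase process.
    """
    spec.band.check_nyquist(fs)
    if fs < 2 * spec.band.hi:
        raise ConfigurationError("fs must be at least twice the band's upper edge")
    n = int(round(duration_s * fs))
    if n < 2:
        raise ConfigurationError("duration too short")
    rng = np.random.default_rng(spec.seed)
    nch = spec.n_channels
    omega = 2 * math.pi * spec.band.center / fs

    t = np.arange(n)
    carrier = omega * t
    # Independent random-walk phase per channel around the carrier.
    walk = np.cumsum(rng.normal(0.0, PHASE_WALK_SD, size=(nch, n)), axis=1)
    own = carrier[None, :] + walk + rng.uniform(0, 2 * math.pi, size=(nch, 1))

    phases = np.empty((nch, n))
    for j in range(nch):
        c_col = spec.coupling[:j, j] if j > 0 else np.empty(0)
        if j == 0 or c_col.size == 0 or c_col.max() == 0:
            phases[j] = own[j]
            continue
        i = int(np.argmax(c_col))  # lowest index wins ties via argmax
        c = float(c_col[i])
        lag = spec.lag_of(i, j)
        if c >= 1.0:
            phases[j] = phases[i] + lag
        else:
            # Tracking state is drawn per coherence block, not per sample: a
            # narrowband filter averages over ~fs/bandwidth samples, so
            # sample-wise switching would wash the mixture out downstream.
            blk = max(1, int(spec.track_block_samples))
            n_blocks = -(-n // blk)
            track = np.repeat(rng.random(n_blocks) < c, blk)[:n]
            phases[j] = np.where(track, phases[i] + lag, own[j])

    data = np.sin(phases)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    if spec.pink_noise_weight > 0:
        data = data + spec.pink_noise_weight * _pink_noise(rng, nch, n)

    labels = (MONTAGE_1020_21[:nch] if nch <= len(MONTAGE_1020_21)
              else [f"ch{k:02d}" for k in range(nch)])
    return EEGRecording(labels, float(fs), data)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Effect:
    """Planted monotone link: score = intercept + slope * measure + noise.

    Either give ``noise_sd`` directly, or give ``rho_target`` to have the
    noise SD calibrated against the realized between-subject spread of
    the true measure so the population Spearman correlation between
    measure and score equals the target.
    """

    covariate: str
    slope: float
    noise_sd: float | None = None
    intercept: float = 0.0
    rho_target: float | None = None

    def __post_init__(self) -> None:
        if (self.noise_sd is None) == (self.rho_target is None):
            raise ConfigurationError(
                "give exactly one of noise_sd or rho_target"
            )


@dataclass
class CohortSpec:
    """Design of a synthetic two-group cohort.

    Group sizes default to the study design (15 agPPA vs 7 PPAOS). The
    per-subject mean coupling scale is Gaussian within group; a positive
    ``group_coupling_shift`` raises group A (agPPA) above group B.
    ``effect`` maps a network-measure name to the planted association with
    one behavioral score.

    The default coupling scale (0.6 +/- 0.15) keeps the cohort on the
    monotone rising branch of the PLI estimator's response: at 8 epochs x
    1024 samples the estimator has a positive small-sample bias floor
    (about 0.36 for uncoupled narrowband channels) and its response to
    weak partial coupling is non-monotone below a scale of roughly 0.35,
    while the between-subject spread of 0.15 keeps the planted
    between-subject differences well above the estimator's sampling
    noise.
    """

    n_per_group: tuple[int, int] = (15, 7)
    effect: dict[str, Effect] = field(default_factory=dict)
    group_coupling_shift: float = 0.05
    coupling_mean: float = 0.6
    coupling_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 1:
            raise ConfigurationError("each group needs at least one subject")
        for name, eff in self.effect.items():
            if name not in MEASURE_NAMES:
                raise ConfigurationError(f"unknown measure name {name!r} in effect")
            if eff.noise_sd is not None and eff.noise_sd < 0:
                raise ConfigurationError("effect noise_sd must be >= 0")


def spearman_attenuation_noise(slope: float, sigma_measure: float,
                               rho_target: float) -> float:
    """Noise SD giving a population Spearman rho_target for a Gaussian measure.

    For bivariate Gaussian data Spearman's rho relates to Pearson's r by
    rho = (6/pi) * asin(r/2); inverting gives the Pearson target, and the
    additive-noise SD follows from the signal-to-noise decomposition.
    """
    if not 0 < rho_target < 1:
        raise ConfigurationError("rho_target must lie in (0, 1)")
    r = 2 * math.sin(math.pi * rho_target / 6)
    return abs(slope) * sigma_measure * math.sqrt(1.0 / r**2 - 1.0)


def planted_cohort_spec(
    rho_target: float = 0.8,
    measure: str = "pli_mean",
    covariate: str = "ASRS3",
    n_per_group: tuple[int, int] = (15, 7),
    seed: int = 0,
    **kw,
) -> CohortSpec:
    """Cohort spec with a planted Spearman association of given strength.

    The slope and intercept map the expected range of the measure into the
    covariate's scale; the noise SD is calibrated at generation time so
    the population Spearman correlation between the true measure and the
    score is ``rho_target``.
    """
    spec = CohortSpec(n_per_group=n_per_group, seed=seed, **kw)
    spec.effect = {
        measure: Effect(covariate, slope=50.0, intercept=5.0,
                        rho_target=rho_target)
    }
    return spec


# Group-typical behavioral medians used as nuisance-score centers
# (agPPA, PPAOS); scores not carrying the planted effect are drawn around
# these and clipped to their valid ranges.
_SCORE_CENTERS = {
    "age": (69.0, 74.0, 6.0),
    "disease_duration": (4.1, 2.0, 1.5),
    "MoCA": (21.0, 27.0, 3.0),
    "MDS_UPDRS_III": (15.0, 12.0, 5.0),
    "ASRS3": (21.0, 16.0, 6.0),
    "NAT": (5.0, 9.0, 1.5),
    "WAB_AQ": (88.8, 97.9, 4.0),
    "aphasia_severity": (1.5, 0.0, 0.7),
    "AOS_severity": (2.0, 2.0, 0.8),
}

from .types import SCORE_RANGES  # noqa: E402  (kept near its use)


def _template(rng: np.random.Generator, nch: int) -> np.ndarray:
    """Fixed heterogeneous, hub-dominated coupling pattern.

    Channel 0 acts as a common driver (think of a dominant posterior
    alpha generator): its couplings are drawn above every other pair's,
    so all channels track the hub and every channel pair shares coupled
    time, spreading the coupling signal across the whole matrix rather
    than a spanning tree of pairs.
    """
    B = rng.uniform(0.3, 0.7, size=(nch, nch))
    B = (B + B.T) / 2
    B[0, :] = B[:, 0] = rng.uniform(0.75, 1.0, size=nch)
    np.fill_diagonal(B, 0.0)
    return B


def true_measure(name: str, coupling: np.ndarray,
                 config: AnalysisConfig | None = None) -> float:
    """Ground-truth network measure computed on the coupling matrix itself."""
    config = config or AnalysisConfig()
    if name == "pli_mean":
        n = coupling.shape[0]
        iu = np.triu_indices(n, 1)
        return float(coupling[iu].mean())
    return float(
        _metrics.compute_measures(
            coupling,
            n_surrogates=config.n_surrogates,
            seed=config.surrogate_seed,
        ).as_dict()[name]
    )


def simulate_cohort(
    spec: CohortSpec,
    analysis: AnalysisConfig | None = None,
    band: BandDefinition | None = None,
    fs: float = 256.0,
    duration_s: float | None = None,
    n_channels: int = 21,
    noise_sd: float = 0.2,
    pink_noise_weight: float = 0.1,
) -> tuple[dict[str, EEGRecording], CohortTable, pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns ``(recordings, cohort, truth)`` where ``recordings`` maps
    subject id to its EEG, ``cohort`` carries group labels and behavioral
    scores, and ``truth`` holds the per-subject coupling scale and the
    ground-truth value of every measure named in ``spec.effect`` (plus
    ``pli_mean``), for recovery tests.

    The recording is long enough for ``analysis.n_epochs`` epochs plus one
    spare, rounded up to a whole second so the EDF writer accepts it.
    """
    analysis = analysis or AnalysisConfig()
    band = band or analysis.bands[1]  # alpha1 by default
    if duration_s is None:
        need = (analysis.n_epochs + 1) * analysis.epoch_len_samples
        duration_s = math.ceil(need / fs)
    rng = np.random.default_rng(spec.seed)
    B = _template(rng, n_channels)
    # Distinct per-channel tracking lags in (pi/6, pi/2): direct pairs keep a
    # nonzero lag and channels sharing a driver differ by a nonzero lag too.
    lag_vals = rng.uniform(math.pi / 6, math.pi / 2, size=n_channels)
    lag_mat = np.tile(lag_vals, (n_channels, 1))

    n_a, n_b = spec.n_per_group
    groups = ["agPPA"] * n_a + ["PPAOS"] * n_b
    half = spec.group_coupling_shift / 2
    means = [spec.coupling_mean + half] * n_a + [spec.coupling_mean - half] * n_b

    recordings: dict[str, EEGRecording] = {}
    rows = []
    truth_rows = []
    truth_names = sorted(set(spec.effect) | {"pli_mean"})
    for k, (g, mu) in enumerate(zip(groups, means)):
        sid = f"S{k + 1:03d}"
        scale = float(np.clip(rng.normal(mu, spec.coupling_sd), 0.02, 0.98))
        coupling = np.clip(scale * B, 0.0, 1.0)
        cspec = CouplingSpec(
            n_channels, band, coupling, lag=lag_mat,
            noise_sd=noise_sd, pink_noise_weight=pink_noise_weight,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        recordings[sid] = simulate_eeg(cspec, duration_s, fs)

        truths = {name: true_measure(name, coupling, analysis)
                  for name in truth_names}
        truth_rows.append({"id": sid, "group": g, "coupling_scale": scale, **truths})

        row: dict[str, object] = {"id": sid, "group": g}
        gi = 0 if g == "agPPA" else 1
        for col, (m_a, m_b, sd) in _SCORE_CENTERS.items():
            center = (m_a, m_b)[gi]
            lo, hi = SCORE_RANGES[col]
            val = rng.normal(center, sd)
            row[col] = float(np.clip(val, lo if lo is not None else -np.inf,
                                     hi if hi is not None else np.inf))
        rows.append(row)

    truth = pd.DataFrame(truth_rows)
    df = pd.DataFrame(rows)
    # Planted effects: noise calibrated against the realized spread of the
    # true measure when a target Spearman correlation was requested.
    for name, eff in spec.effect.items():
        vals = truth[name].to_numpy()
        if eff.noise_sd is not None:
            noise_sd = eff.noise_sd
        else:
            sigma = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            noise_sd = (spearman_attenuation_noise(eff.slope, sigma,
                                                   eff.rho_target)
                        if sigma > 0 else 0.0)
        noise = rng.normal(0.0, noise_sd, size=len(vals)) if noise_sd > 0 else 0.0
        score = eff.intercept + eff.slope * vals + noise
        lo, hi = SCORE_RANGES[eff.covariate]
        df[eff.covariate] = np.clip(score,
                                    lo if lo is not None else -np.inf,
                                    hi if hi is not None else np.inf)

    cohort = CohortTable(df)
    return recordings, cohort, truth
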