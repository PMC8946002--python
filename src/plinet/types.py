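"""Shared domain types for the EEG network pipeline.

The pipeline analyses resting-state scalp EEG recorded on the standard
10-20 montage (21 channels, 256 Hz in the study design this package
follows), band-limited to theta and lower/upper alpha, and summarised per
subject by nine network measures: mean phase lag index, normalized weighted
clustering coefficient (gamma), normalized characteristic path length
(lambda), weighted degree divergence (kappa_w), modularity, and four
minimum-spanning-tree measures (maximum betweenness, diameter,
eccentricity, leaf fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
import yaml

#: Standard 10-20 labels for the 21-channel clinical montage.
MONTAGE_1020_21 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2", "A1", "A2",
]

GROUP_LABELS = ("agPPA", "PPAOS")

#: Behavioral score columns and their valid (inclusive) ranges; None = unbounded.
SCORE_RANGES: dict[str, tuple[float | None, float | None]] = {
    "age": (0.0, None),
    "disease_duration": (0.0, None),
    "MoCA": (0.0, 30.0),
    "MDS_UPDRS_III": (0.0, 81.0),
    "ASRS3": (0.0, 52.0),
    "NAT": (0.0, 10.0),
    "WAB_AQ": (0.0, 100.0),
    "aphasia_severity": (0.0, 4.0),
    "AOS_severity": (0.0, 4.0),
}

#: Covariates entering the correlation grid (six columns of the report).
CORRELATION_COVARIATES = [
    "age", "disease_duration", "MoCA", "MDS_UPDRS_III", "ASRS3", "WAB_AQ",
]

#: Canonical order of the nine per-subject network measures.
MEASURE_NAMES = [
    "pli_mean", "gamma", "lambda_", "kappa_w", "modularity",
    "mst_bc_max", "mst_diameter", "mst_eccentricity", "mst_leaf",
]


class FormatError(ValueError):
    """Raised when an external file violates its declared format."""


class ConfigurationError(ValueError):
    """Raised when required configuration (e.g. sampling rate) is missing."""


@dataclass
class EEGRecording:
    """Multichannel EEG time series.

    Parameters
    ----------
    channel_labels : sequence of str
        Unique electrode labels in recording order.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    reference : str
        Reference electrode label, or ``"average"`` / ``"as_recorded"``.
    """

    channel_labels: list[str]
    fs: float
    data: np.ndarray
    reference: str = "as_recorded"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = list(self.channel_labels)
        if self.data.ndim != 2:
            raise FormatError(
                f"data must be 2-D (channels x samples), got {self.data.ndim}-D"
            )
        if len(self.channel_labels) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise FormatError("channel labels must be unique")
        if not self.fs > 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        return replace(self, data=data)


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band given by its passband corners in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ConfigurationError(
                f"band {self.name!r}: need 0 < lo < hi, got ({self.lo}, {self.hi})"
            )

    def check_nyquist(self, fs: float) -> None:
        if self.hi >= fs / 2:
            raise ConfigurationError(
                f"band {self.name!r} upper edge {self.hi} Hz >= Nyquist {fs / 2} Hz"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


#: The three study bands: theta and the two alpha sub-bands.
DEFAULT_BANDS = [
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 13.0),
]


class CohortTable:
    """Typed per-subject cohort table (diagnosis group + behavioral scores).

    Wraps a :class:`pandas.DataFrame` with one row per subject, validating
    id uniqueness, the closed group-label set and score ranges on
    construction. Missing scores are permitted and stored as NaN.
    """

    REQUIRED = ["id", "group"]

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"cohort table missing required column {col!r}")
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].tolist()
            raise FormatError(f"duplicate subject ids: {dup}")
        bad = set(df["group"]) - set(GROUP_LABELS)
        if bad:
            raise FormatError(
                f"unknown group labels {sorted(bad)}; allowed: {GROUP_LABELS}"
            )
        for col, (lo, hi) in SCORE_RANGES.items():
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="coerce")
            vals = df[col].dropna()
            if lo is not None and (vals < lo).any():
                raise FormatError(f"{col}: value below {lo}")
            if hi is not None and (vals > hi).any():
                raise FormatError(f"{col}: value above {hi}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()

    def group_of(self, subject_id: str) -> str:
        row = self.df.loc[self.df["id"] == subject_id]
        if row.empty:
            raise KeyError(f"unknown subject id {subject_id!r}")
        return row["group"].iloc[0]

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.df["group"] == g).sum()) for g in GROUP_LABELS}


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full pipeline with study defaults.

    Defaults follow the study design: 1024-sample epochs, 8 artifact-free
    epochs per subject, theta/alpha1/alpha2 bands, a 0.1 PLI threshold for
    network-map exports, and 50 weight-shuffle surrogates for the
    gamma/lambda normalization.
    """

    bands: list[BandDefinition] = field(default_factory=lambda: list(DEFAULT_BANDS))
    epoch_len_samples: int = 1024
    n_epochs: int = 8
    amp_uv: float = 100.0       # absolute amplitude artifact threshold, uV
    flat_eps: float = 0.1       # flat-line peak-to-peak threshold, uV
    var_z: float = 5.0          # per-channel variance z-score threshold
    n_surrogates: int = 50
    surrogate_seed: int = 0
    modularity_seed: int = 0
    viz_threshold: float = 0.1  # PLI threshold for network-map export
    epoch_policy: str = "first"  # {"first", "random"}
    metric_mode: str = "per_epoch"  # {"per_epoch", "aggregate"}
    band_collapse: str = "mean"  # group tests: {"mean", "pool"} across bands
    alpha: float = 0.05
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if self.epoch_len_samples < 2:
            raise ConfigurationError("epoch_len_samples must be >= 2")
        if self.n_epochs < 1:
            raise ConfigurationError("n_epochs must be >= 1")
        if not 0 <= self.viz_threshold <= 1:
            raise ConfigurationError("viz_threshold must lie in [0, 1]")
        if self.metric_mode not in ("per_epoch", "aggregate"):
            raise ConfigurationError(f"unknown metric_mode {self.metric_mode!r}")
        if self.band_collapse not in ("mean", "pool"):
            raise ConfigurationError(f"unknown band_collapse {self.band_collapse!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        bands = raw.pop("bands", None)
        cfg = cls(**raw)
        if bands is not None:
            cfg.bands = [BandDefinition(**b) for b in bands]
        return cfg

    def to_yaml(self, path) -> None:
        raw = {
            k: v for k, v in self.__dict__.items() if k != "bands"
        }
        raw["bands"] = [
            {"name": b.name, "lo": b.lo, "hi": b.hi} for b in self.bands
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class NetworkMeasures:
    """The nine per-subject, per-band network summary scalars."""

    pli_mean: float
    gamma: float
    lambda_: float
    kappa_w: float
    modularity: float
    mst_bc_max: float
    mst_diameter: float
    mst_eccentricity: float
    mst_leaf: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MEASURE_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "NetworkMeasures":
        return cls(**{name: d[name] for name in MEASURE_NAMES})


def measures_frame(
    per_subject: dict[str, dict[str, NetworkMeasures]],
) -> pd.DataFrame:
    """Flatten {subject -> {band -> NetworkMeasures}} into a long DataFrame.

    Returns columns: id, band, measure, value.
    """
    rows = []
    for sid, by_band in per_subject.items():
        for band, nm in by_band.items():
            for name, value in nm.as_dict().items():
                rows.append({"id": sid, "band": band, "measure": name, "value": value})
    return pd.DataFrame(rows, columns=["id", "band", "measure", "value"])
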