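"""Readers and writers for recordings, cohorts, result tables and networks.

Formats
-------
- EEG: EDF (16-bit European Data Format) or plain numeric CSV with one
  column per channel and a single header row of channel labels. CSV
  carries no sampling rate, so ``fs`` comes from an argument or a
  ``<path>.fs`` sidecar file.
- Cohort: CSV with the documented column names (see
  :class:`plinet.types.CohortTable`).
- Results: TSV with fixed column order, so runs diff cleanly.
- Networks: GraphML (``.graphml``) or a plain tab-separated edge list.

EDF is written by a small built-in writer (1-second records, symmetric
16-bit quantization) and read back through :mod:`mne`, which keeps the
two directions of the round trip independent of each other.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    CohortTable,
    ConfigurationError,
    EEGRecording,
    FormatError,
    MEASURE_NAMES,
    NetworkMeasures,
)

log = logging.getLogger(__name__)

_EDF_DIG_MAX = 32767  # symmetric digital range keeps 0 uV exactly representable


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def read_recording(path, format: str | None = None, fs: float | None = None,
                   ) -> EEGRecording:
    """Read an EEG recording from EDF or CSV.

    Parameters
    ----------
    path : path-like
    format : {"edf", "csv"}, optional
        Inferred from the file extension when omitted.
    fs : float, optional
        Sampling rate for CSV input; ignored for EDF (taken from the
        header). When omitted for CSV, a ``<path>.fs`` sidecar file is
        consulted.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "edf":
        return _read_edf(path)
    if format == "csv":
        return _read_csv(path, fs)
    raise ConfigurationError(f"unknown recording format {format!r}")


def write_recording(rec: EEGRecording, path, format: str | None = None) -> None:
    """Write a recording as EDF or CSV (CSV gets an ``.fs`` sidecar)."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "edf":
        _write_edf(rec, path)
    elif format == "csv":
        pd.DataFrame(rec.data.T, columns=rec.channel_labels).to_csv(
            path, index=False, float_format="%.8g"
        )
        Path(str(path) + ".fs").write_text(f"{rec.fs:.10g}\n")
    else:
        raise ConfigurationError(f"unknown recording format {format!r}")


def _read_csv(path: Path, fs: float | None) -> EEGRecording:
    if fs is None:
        sidecar = Path(str(path) + ".fs")
        if sidecar.exists():
            fs = float(sidecar.read_text().strip())
        else:
            raise ConfigurationError(
                f"CSV recording {path} needs a sampling rate: pass fs= or "
                f"provide a {sidecar.name} sidecar"
            )
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged or non-numeric CSV (NaN after parse)")
    data = df.to_numpy(dtype=float).T
    return EEGRecording(list(df.columns), float(fs), data)


def _read_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return EEGRecording(list(raw.ch_names), float(raw.info["sfreq"]), data_uv)


def _edf_num(x: float, width: int) -> bytes:
    """Format a number into EDF's fixed-width ASCII field."""
    s = f"{x:.6g}"
    if len(s) > width:
        s = f"{x:.3g}"
    if len(s) > width:
        raise FormatError(f"value {x} does not fit EDF field width {width}")
    return s.ljust(width).encode("ascii")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF writer: 1-second records, one 16-bit stream per channel.

    Requires the sampling rate to be an integer and the recording length a
    whole number of seconds (the simulator always emits such recordings).
    Physical units are microvolts.
    """
    fs = rec.fs
    if not float(fs).is_integer():
        raise ConfigurationError(f"EDF writer needs integer fs, got {fs}")
    fs = int(fs)
    if rec.n_samples % fs != 0:
        raise FormatError(
            f"EDF writer needs whole-second recordings: {rec.n_samples} samples "
            f"at {fs} Hz"
        )
    n_records = rec.n_samples // fs
    ns = rec.n_channels

    # Symmetric physical range per channel; slight headroom so the observed
    # extreme is never clipped by the rounding of the printed range.
    amps = np.maximum(np.abs(rec.data).max(axis=1), 1e-9) * 1.0005
    amps = np.array([float(f"{a:.6g}") for a in amps])
    scales = amps / _EDF_DIG_MAX

    hdr = b""
    hdr += b"0".ljust(8)
    hdr += b"X".ljust(80)                      # patient id
    hdr += b"Startdate X".ljust(80)            # recording id
    hdr += b"01.01.00"                         # start date
    hdr += b"00.00.00"                         # start time
    hdr += str(256 * (ns + 1)).ljust(8).encode()
    hdr += b" " * 44
    hdr += str(n_records).ljust(8).encode()
    hdr += b"1".ljust(8)                       # record duration, seconds
    hdr += str(ns).ljust(4).encode()

    def field(values, width):
        return b"".join(v.ljust(width).encode("ascii")[:width] for v in values)

    labels = [f"EEG {c}" for c in rec.channel_labels]
    hdr += field(labels, 16)
    hdr += field([""] * ns, 80)                               # transducer
    hdr += field(["uV"] * ns, 8)
    hdr += b"".join(_edf_num(-a, 8) for a in amps)            # phys min
    hdr += b"".join(_edf_num(+a, 8) for a in amps)            # phys max
    hdr += field([str(-_EDF_DIG_MAX)] * ns, 8)                # dig min
    hdr += field([str(_EDF_DIG_MAX)] * ns, 8)                 # dig max
    hdr += field([""] * ns, 80)                               # prefiltering
    hdr += field([str(fs)] * ns, 8)                           # samples/record
    hdr += field([""] * ns, 32)
    assert len(hdr) == 256 * (ns + 1)

    dig = np.round(rec.data / scales[:, None]).astype(np.int64)
    dig = np.clip(dig, -_EDF_DIG_MAX, _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            block = dig[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())  # channel-sequential within each record


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def read_cohort(path) -> CohortTable:
    """Read and validate a cohort CSV (blank cells become missing values)."""
    df = pd.read_csv(path, dtype={"id": str})
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Measure tables
# ---------------------------------------------------------------------------

_TABLE_COLS = [
    "band", "measure",
    "agPPA_median", "agPPA_q1", "agPPA_q3",
    "PPAOS_median", "PPAOS_q1", "PPAOS_q3",
    "all_median", "all_q1", "all_q3",
]


def measure_table(
    measures: dict[str, dict[str, NetworkMeasures]],
    cohort: CohortTable,
) -> pd.DataFrame:
    """Median (Q1, Q3) of each measure x band per group and overall.

    ``measures`` maps subject id -> band name -> :class:`NetworkMeasures`.
    The output always has (#bands x 9) rows regardless of cohort size.
    """
    unknown = set(measures) - set(cohort.ids)
    if unknown:
        raise KeyError(f"subjects absent from cohort: {sorted(unknown)}")
    bands: list[str] = []
    for by_band in measures.values():
        for b in by_band:
            if b not in bands:
                bands.append(b)
    group_ids = {
        g: [s for s in measures if cohort.group_of(s) == g]
        for g in ("agPPA", "PPAOS")
    }
    group_ids["all"] = list(measures)

    rows = []
    for band in bands:
        for name in MEASURE_NAMES:
            row: dict[str, object] = {"band": band, "measure": name}
            for g, ids in group_ids.items():
                vals = np.array([
                    getattr(measures[s][band], name)
                    for s in ids if band in measures[s]
                ])
                if vals.size:
                    row[f"{g}_median"] = float(np.median(vals))
                    row[f"{g}_q1"] = float(np.percentile(vals, 25))
                    row[f"{g}_q3"] = float(np.percentile(vals, 75))
                else:
                    row[f"{g}_median"] = row[f"{g}_q1"] = row[f"{g}_q3"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows, columns=_TABLE_COLS)


def write_measure_table(
    measures: dict[str, dict[str, NetworkMeasures]],
    cohort: CohortTable,
    path,
) -> pd.DataFrame:
    table = measure_table(measures, cohort)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return table


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def threshold_graph(W: np.ndarray, labels: list[str], threshold: float) -> nx.Graph:
    """Graph with all channels as nodes and edges strictly above threshold."""
    if not 0 <= threshold <= 1:
        raise ConfigurationError(f"threshold must lie in [0, 1], got {threshold}")
    W = np.asarray(W, float)
    G = nx.Graph()
    G.add_nodes_from(labels)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > threshold:
                G.add_edge(labels[i], labels[j], weight=float(W[i, j]))
    return G


def export_network_map(W: np.ndarray, labels: list[str], threshold: float,
                       path) -> nx.Graph:
    """Write the thresholded connectivity graph (isolated nodes kept).

    ``.graphml`` extension selects GraphML; anything else gets a
    tab-separated edge list with a header line.
    """
    W = np.asarray(W, float)
    if not np.allclose(W, W.T):
        raise FormatError("connectivity matrix must be symmetric")
    G = threshold_graph(W, labels, threshold)
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(G, path)
    else:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, d in sorted(G.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']:.6g}\n")
    return G
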