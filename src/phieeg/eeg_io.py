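"""Reading, selecting and epoching preprocessed EEG recordings.

Recordings are consumed already preprocessed (bandpass-filtered,
re-referenced, artifact-cleaned); no signal conditioning happens here.
Two on-disk formats are supported: EEGLAB ``.set`` (read through mne, as
distributed in BIDS-EEG layouts) and a plain-matrix CSV exchange format —
one header row of channel labels, one row per sample, amplitudes in µV —
used by the synthetic-data generator and the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical 10–20 montage of the 19-channel clinical layout.
MONTAGE_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
]

# Modern-name synonyms mapped back to the classical temporal labels.
_SYNONYMS = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}
_CANONICAL = {name.lower(): name for name in MONTAGE_1020}
_CANONICAL.update({k.lower(): v for k, v in _SYNONYMS.items()})


def normalize_label(label: str) -> str:
    """Map a channel label to canonical 10–20 capitalization (Fp1, Fz, ...).

    T7/T8/P7/P8 are translated to their classical synonyms T3/T4/T5/T6.
    Labels outside the 19-channel montage are returned stripped but
    otherwise untouched.
    """
    return _CANONICAL.get(label.strip().lower(), label.strip())


@dataclass
class EEGRecording:
    """One subject's channel-labelled amplitude matrix in µV.

    ``data`` has shape (n_channels, n_samples); row *i* is the channel
    named ``channels[i]``.
    """

    subject_id: str
    sampling_rate: float
    channels: list[str]
    data: np.ndarray
    group: str | None = None
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) matrix")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"duplicate channel labels: {self.channels}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.data.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Amplitude sequence of one channel; raises KeyError if absent."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording {self.subject_id!r}") from None
        return self.data[idx]


@dataclass(frozen=True)
class ElectrodePair:
    """Unordered pair of distinct channel labels (Fp1-Fp2 == Fp2-Fp1)."""

    label_a: str
    label_b: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "label_a", normalize_label(self.label_a))
        object.__setattr__(self, "label_b", normalize_label(self.label_b))
        if self.label_a == self.label_b:
            raise ValueError(f"electrode pair needs two distinct channels, got {self.label_a!r} twice")

    @classmethod
    def parse(cls, text: str) -> "ElectrodePair":
        """Parse 'Fp1-Fp2' style identifiers."""
        parts = text.split("-")
        if len(parts) != 2:
            raise ValueError(f"cannot parse electrode pair {text!r}")
        return cls(parts[0], parts[1])

    @property
    def name(self) -> str:
        return f"{self.label_a}-{self.label_b}"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElectrodePair):
            return NotImplemented
        return {self.label_a, self.label_b} == {other.label_a, other.label_b}

    def __hash__(self) -> int:
        return hash(frozenset((self.label_a, self.label_b)))

    def __str__(self) -> str:
        return self.name


def load_recording(path: str | Path, format: str = "plain_matrix", subject_id: str | None = None) -> EEGRecording:
    """Load one EEG recording from disk.

    Parameters
    ----------
    path
        File location.
    format
        ``"plain_matrix"`` (CSV, header row of channel labels, µV) or
        ``"eeglab_set"`` (EEGLAB ``.set``, read via mne; volts are
        converted to µV).
    subject_id
        Overrides the identifier derived from the file stem.
    """
    path = Path(path)
    sid = subject_id if subject_id is not None else path.stem
    if format == "plain_matrix":
        return _load_plain_matrix(path, sid)
    if format == "eeglab_set":
        return _load_eeglab(path, sid)
    raise ValueError(f"unknown recording format {format!r}")


def _load_plain_matrix(path: Path, subject_id: str) -> EEGRecording:
    # pandas renames duplicated header fields, so check the raw header first
    with open(path) as fh:
        raw_header = [c.strip() for c in fh.readline().strip().split(",")]
    if len(set(raw_header)) != len(raw_header):
        raise ValueError(f"{path}: duplicated channel label in header {raw_header}")
    df = pd.read_csv(path)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"{path}: empty plain-matrix file")
    cols = list(df.columns)
    rate = None
    # Optional leading time column: 'time' in seconds or 'sample' index.
    if cols[0].lower() in ("time", "t", "sample", "index"):
        if cols[0].lower() in ("time", "t") and len(df) > 1:
            dt = float(df.iloc[1, 0]) - float(df.iloc[0, 0])
            if dt > 0:
                rate = 1.0 / dt
        df = df.iloc[:, 1:]
        cols = cols[1:]
    if rate is None:
        rate = _read_rate_sidecar(path)
    labels = [normalize_label(c) for c in cols]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicated channel label after normalization: {labels}")
    return EEGRecording(
        subject_id=subject_id,
        sampling_rate=rate,
        channels=labels,
        data=df.to_numpy(dtype=float).T,
    )


def _read_rate_sidecar(path: Path) -> float:
    """Sampling rate from '<stem>.rate' sidecar (Hz, one number); 500 Hz default."""
    sidecar = path.with_suffix(".rate")
    if sidecar.exists():
        return float(sidecar.read_text().strip())
    warnings.warn(f"{path}: no sampling-rate metadata, assuming 500 Hz", stacklevel=3)
    return 500.0


def _load_eeglab(path: Path, subject_id: str) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_eeglab(path, preload=True, verbose="error")
    labels = [normalize_label(ch) for ch in raw.ch_names]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicated channel label after normalization")
    data = raw.get_data() * 1e6  # mne stores volts; analysis runs in µV
    return EEGRecording(
        subject_id=subject_id,
        sampling_rate=float(raw.info["sfreq"]),
        channels=labels,
        data=data,
    )


def write_recording(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording in the plain-matrix CSV format plus a rate sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channels)
    df.to_csv(path, index=False, float_format="%.6f")
    path.with_suffix(".rate").write_text(f"{rec.sampling_rate:g}\n")


def select_channels(rec: EEGRecording, labels: list[str]) -> EEGRecording:
    """Restrict a recording to ``labels``, in the requested order."""
    wanted = [normalize_label(lb) for lb in labels]
    missing = [lb for lb in wanted if lb not in rec.channels]
    if missing:
        raise KeyError(f"channel(s) {missing} not present in recording {rec.subject_id!r}")
    idx = [rec.channels.index(lb) for lb in wanted]
    return replace(rec, channels=wanted, data=rec.data[idx])


def first_epoch(rec: EEGRecording, duration: float = 60.0) -> EEGRecording:
    """First ``duration`` seconds of the recording, anchored at sample 0.

    The analysis partitions each recording into fixed-length epochs and
    uses only the first; the epoch start is sample 0 of the preprocessed
    timeline.
    """
    n = int(np.floor(duration * rec.sampling_rate))
    if rec.n_samples < n:
        raise ValueError(
            f"recording {rec.subject_id!r} is {rec.duration:.2f} s long, "
            f"shorter than the requested {duration:g} s epoch"
        )
    if rec.n_samples == n:
        return rec
    return replace(rec, data=rec.data[:, :n])


def load_demographics(path: str | Path) -> pd.DataFrame:
    """Demographics sidecar CSV: columns subject_id, group, age, sex.

    Group labels are upper-cased (AD/FTD/HC); sex is normalized to
    'male'/'female' from common encodings (m/f, M/F, 1/0).
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "group", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: demographics table missing columns {sorted(missing)}")
    df = df.copy()
    df["group"] = df["group"].astype(str).str.upper().str.strip()
    sex_map = {"male": "male", "m": "male", "1": "male", "female": "female", "f": "female", "0": "female"}
    norm = df["sex"].astype(str).str.lower().str.strip().map(sex_map)
    if norm.isna().any():
        bad = df.loc[norm.isna(), "sex"].unique().tolist()
        raise ValueError(f"{path}: unrecognized sex value(s) {bad}")
    df["sex"] = norm
    df["age"] = df["age"].astype(float)
    return df.set_index("subject_id", drop=False)
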