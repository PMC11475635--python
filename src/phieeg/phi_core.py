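"""PHI: summed bidirectional mutual information between binned EEG amplitudes.

An electrode pair is treated as a two-part system.  Each channel's
amplitude trace is discretized by rounding to 10-µV bins; every rounded
amplitude is a state, and state probabilities are the relative
frequencies observed over the analysis epoch (plug-in estimates, no
smoothing or bias correction).  The mutual information of the pair is
then

    MI(A; B) = H(A) + H(B) - H(A, B)        [bits, log base 2]

and PHI is the sum of MI taken in both directions (A as source, then B
as source).  With empirical distributions on both sides the two
directional terms coincide, so PHI = 2·MI; both terms are nevertheless
computed and reported separately, and their equality is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eeg_io import EEGRecording, ElectrodePair

#: The 13 default-mode-network electrode pairs analysed by default.
DEFAULT_PAIRS: list[ElectrodePair] = [
    ElectrodePair(*p)
    for p in [
        ("Fp1", "Fp2"), ("Fp2", "F4"), ("F3", "F4"), ("Fp2", "F8"), ("Fp2", "T4"),
        ("F7", "F8"), ("T5", "P3"), ("T3", "P3"), ("O1", "O2"), ("T3", "T5"),
        ("T4", "T6"), ("T4", "P4"), ("T6", "P4"),
    ]
]

DEFAULT_BIN_WIDTH = 10.0  # µV


@dataclass(frozen=True)
class DiscretizedSignal:
    """Integer bin-index sequence after amplitude binning.

    ``states[i]`` is the index of the bin (multiples of ``bin_width``)
    containing sample i, so state k represents the amplitude k·bin_width.
    """

    states: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", np.asarray(self.states, dtype=np.int64))
        if self.states.ndim != 1 or self.states.size < 1:
            raise ValueError("states must be a non-empty 1-D sequence")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def n(self) -> int:
        return self.states.size


@dataclass(frozen=True)
class PhiResult:
    """PHI for one electrode pair: both directional MI terms and their sum."""

    pair: ElectrodePair
    mi_ab: float  # bits, A as source
    mi_ba: float  # bits, B as source
    phi: float    # mi_ab + mi_ba

    def __post_init__(self) -> None:
        if abs(self.phi - (self.mi_ab + self.mi_ba)) > 1e-12:
            raise ValueError("phi must equal mi_ab + mi_ba")


def discretize(signal: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH) -> DiscretizedSignal:
    """Round amplitudes to the nearest multiple of ``bin_width``.

    The bin index is ⌊x / bin_width + 0.5⌋ — half-way values round toward
    +∞.  With the default 10-µV width, 5.0 µV maps to bin 1 (10 µV) and
    −17.0 µV maps to bin −2 (−20 µV).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D amplitude sequence")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite amplitudes")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    states = np.floor(x / bin_width + 0.5).astype(np.int64)
    return DiscretizedSignal(states=states, bin_width=bin_width)


def _as_states(x: DiscretizedSignal | np.ndarray) -> np.ndarray:
    if isinstance(x, DiscretizedSignal):
        return x.states
    arr = np.asarray(x)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("state sequence must be non-empty and 1-D")
    return arr


def entropy(x: DiscretizedSignal | np.ndarray) -> float:
    """Plug-in Shannon entropy (bits) of the empirical state distribution."""
    states = _as_states(x)
    _, counts = np.unique(states, return_counts=True)
    p = counts / states.size
    return float(-(p * np.log2(p)).sum())


def joint_entropy(x: DiscretizedSignal | np.ndarray, y: DiscretizedSignal | np.ndarray) -> float:
    """Plug-in joint entropy (bits) of time-paired states.

    Samples are paired by time stamp, so both sequences must have equal
    length.
    """
    sx, sy = _as_states(x), _as_states(y)
    if sx.size != sy.size:
        raise ValueError(f"cannot pair sequences of lengths {sx.size} and {sy.size}")
    pairs = np.column_stack([sx, sy])
    _, counts = np.unique(pairs, axis=0, return_counts=True)
    p = counts / sx.size
    return float(-(p * np.log2(p)).sum())


def mutual_information(x: DiscretizedSignal | np.ndarray, y: DiscretizedSignal | np.ndarray) -> float:
    """Plug-in mutual information MI = H(x) + H(y) − H(x, y), in bits.

    Clipped at 0 to absorb floating-point round-off; the plug-in estimate
    is non-negative in exact arithmetic.
    """
    mi = entropy(x) + entropy(y) - joint_entropy(x, y)
    return max(mi, 0.0)


def phi(x: np.ndarray, y: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH,
        pair: ElectrodePair | None = None) -> PhiResult:
    """PHI of two amplitude sequences: bidirectional binned MI, summed.

    Both directions use the empirical (observed) state distributions, so
    the directional terms are equal and PHI = 2·MI; the symmetry is
    asserted to 1e−9.
    """
    dx = discretize(x, bin_width)
    dy = discretize(y, bin_width)
    mi_ab = mutual_information(dx, dy)  # A as source
    mi_ba = mutual_information(dy, dx)  # B as source
    assert abs(mi_ab - mi_ba) < 1e-9
    if pair is None:
        pair = ElectrodePair("A", "B")
    return PhiResult(pair=pair, mi_ab=mi_ab, mi_ba=mi_ba, phi=mi_ab + mi_ba)


def phi_matrix(rec: EEGRecording, pairs: list[ElectrodePair] | None = None,
               bin_width: float = DEFAULT_BIN_WIDTH) -> list[PhiResult]:
    """PHI for every requested electrode pair of one recording.

    ``pairs`` defaults to the 13 default-mode-network pairs; order is
    preserved in the output.  The recording is expected to be the
    analysis epoch already (see :func:`phieeg.eeg_io.first_epoch`).
    """
    if pairs is None:
        pairs = DEFAULT_PAIRS
    # Discretize each referenced channel once.
    needed = {lb for p in pairs for lb in (p.label_a, p.label_b)}
    binned = {lb: discretize(rec.channel(lb), bin_width) for lb in needed}
    results = []
    for p in pairs:
        dx, dy = binned[p.label_a], binned[p.label_b]
        mi_ab = mutual_information(dx, dy)
        mi_ba = mutual_information(dy, dx)
        results.append(PhiResult(pair=p, mi_ab=mi_ab, mi_ba=mi_ba, phi=mi_ab + mi_ba))
    return results
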