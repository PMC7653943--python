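"""Respiratory, cardiac and dual gate assignment for time-sampled signals.

Respiratory gating is amplitude based: the range of the (valid) lung-volume
signal is split into ``r`` bins of equal height and each sample is labelled
by the bin its amplitude falls in.  Cardiac gating is phase based: each
R-to-R interval of the ECG is split into ``p`` bins of equal duration.  A
dual gate is the intersection of one respiratory and one cardiac bin.

Gate indices are 1-based; the sentinel ``REJECTED`` (-1) marks samples that
carry no gate (invalid spirometry, or times outside any full cardiac cycle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptySignalError,
    InputError,
    InsufficientTriggersError,
    InvalidGateCountError,
)

__all__ = [
    "REJECTED",
    "RespSignal",
    "CardiacSignal",
    "DualGateLabel",
    "assign_resp_amplitude",
    "assign_card_phase",
    "cardiac_phase_fraction",
    "combine_dual",
    "rejected_fraction",
    "read_resp_signal",
    "write_resp_signal",
    "read_rpeaks",
    "write_rpeaks",
    "write_labels",
    "read_labels",
]

#: gate index sentinel for samples excluded from gating
REJECTED = -1


@dataclass(frozen=True)
class RespSignal:
    """A sampled lung-volume (or surrogate amplitude) trace.

    ``amplitude`` units are arbitrary but must be consistent; ``valid``
    flags samples the acquisition system accepted.
    """

    times: np.ndarray
    amplitude: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        if not (t.shape == a.shape == v.shape) or t.ndim != 1:
            raise InputError("times, amplitude and valid must be equal-length 1-D")
        if t.size and not (np.diff(t) > 0).all():
            raise InputError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitude", a)
        object.__setattr__(self, "valid", v)


@dataclass(frozen=True)
class CardiacSignal:
    """ECG trigger times (R-peaks), strictly increasing, in seconds."""

    rpeak_times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.rpeak_times, dtype=float)
        if t.ndim != 1:
            raise InputError("rpeak_times must be 1-D")
        if t.size and not (np.diff(t) > 0).all():
            raise InputError("R-peak times must be strictly increasing")
        object.__setattr__(self, "rpeak_times", t)


@dataclass(frozen=True)
class DualGateLabel:
    """A (respiratory, cardiac) gate pair; REJECTED components mark rejection."""

    resp_index: int
    card_index: int

    @property
    def rejected(self) -> bool:
        return self.resp_index == REJECTED or self.card_index == REJECTED


def _check_gates(n: int, name: str) -> int:
    if int(n) != n or n < 1:
        raise InvalidGateCountError(f"{name} must be an integer >= 1, got {n!r}")
    return int(n)


def assign_resp_amplitude(signal: RespSignal, r: int) -> np.ndarray:
    """Label each sample with its equal-height amplitude bin in [1, r].

    The bin edges span the [min, max] amplitude of the *valid* samples.
    Samples exactly on an interior edge go to the higher bin; the maximum
    goes to bin r.  Invalid samples get REJECTED.
    """
    r = _check_gates(r, "r")
    valid = signal.valid
    if not valid.any():
        raise EmptySignalError("no valid samples in the respiratory signal")
    a = signal.amplitude
    lo = a[valid].min()
    hi = a[valid].max()
    gates = np.full(a.shape, REJECTED, dtype=int)
    if hi == lo:
        # degenerate flat signal: a single motion state, everything in gate 1
        gates[valid] = 1
        return gates
    width = (hi - lo) / r
    idx = np.floor((a - lo) / width).astype(int) + 1
    np.clip(idx, 1, r, out=idx)
    gates[valid] = idx[valid]
    return gates


def assign_card_phase(
    signal: CardiacSignal, p: int, times: Sequence[float]
) -> np.ndarray:
    """Label each time with its equal-duration phase bin within its RR interval.

    A time t in [R_i, R_{i+1}) gets gate floor(p (t - R_i) / RR_i) + 1;
    times before the first or at/after the last R-peak are REJECTED.
    """
    p = _check_gates(p, "p")
    peaks = signal.rpeak_times
    if peaks.size < 2:
        raise InsufficientTriggersError("need at least two R-peaks")
    frac = cardiac_phase_fraction(signal, times)
    gates = np.full(frac.shape, REJECTED, dtype=int)
    inside = np.isfinite(frac)
    idx = np.floor(p * frac[inside]).astype(int) + 1
    np.clip(idx, 1, p, out=idx)
    gates[inside] = idx
    return gates


def cardiac_phase_fraction(
    signal: CardiacSignal, times: Sequence[float]
) -> np.ndarray:
    """Phase fraction in [0, 1) within the enclosing RR interval, NaN outside."""
    peaks = signal.rpeak_times
    if peaks.size < 2:
        raise InsufficientTriggersError("need at least two R-peaks")
    t = np.asarray(times, dtype=float)
    i = np.searchsorted(peaks, t, side="right") - 1
    frac = np.full(t.shape, np.nan)
    inside = (i >= 0) & (i < peaks.size - 1)
    ii = i[inside]
    frac[inside] = (t[inside] - peaks[ii]) / (peaks[ii + 1] - peaks[ii])
    return frac


def combine_dual(
    resp_idx: Sequence[int], card_idx: Sequence[int]
) -> list[DualGateLabel]:
    """Pair respiratory and cardiac labels; rejection in either rejects both."""
    resp = np.asarray(resp_idx, dtype=int)
    card = np.asarray(card_idx, dtype=int)
    if resp.shape != card.shape:
        raise InputError("respiratory and cardiac label series differ in length")
    labels = []
    for ri, ci in zip(resp, card):
        if ri == REJECTED or ci == REJECTED:
            labels.append(DualGateLabel(REJECTED, REJECTED))
        else:
            labels.append(DualGateLabel(int(ri), int(ci)))
    return labels


def rejected_fraction(labels: Sequence[DualGateLabel]) -> float:
    """Percentage of samples rejected from gating."""
    labels = list(labels)
    if not labels:
        raise InputError("empty label series")
    n_rej = sum(1 for lab in labels if lab.rejected)
    return 100.0 * n_rej / len(labels)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------


def write_resp_signal(path, signal: RespSignal) -> None:
    pd.DataFrame(
        {
            "time_s": signal.times,
            "amplitude": signal.amplitude,
            "valid": signal.valid.astype(int),
        }
    ).to_csv(path, index=False)


def read_resp_signal(path) -> RespSignal:
    df = pd.read_csv(path)
    for col in ("time_s", "amplitude", "valid"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return RespSignal(
        times=df["time_s"].to_numpy(float),
        amplitude=df["amplitude"].to_numpy(float),
        valid=df["valid"].to_numpy(bool),
    )


def write_rpeaks(path, signal: CardiacSignal) -> None:
    pd.DataFrame({"rpeak_time_s": signal.rpeak_times}).to_csv(path, index=False)


def read_rpeaks(path) -> CardiacSignal:
    df = pd.read_csv(path)
    if "rpeak_time_s" not in df.columns:
        raise InputError(f"{path}: missing column 'rpeak_time_s'")
    return CardiacSignal(rpeak_times=df["rpeak_time_s"].to_numpy(float))


def write_labels(path, times, labels: Sequence[DualGateLabel]) -> None:
    pd.DataFrame(
        {
            "time_s": np.asarray(times, dtype=float),
            "resp_gate": [lab.resp_index for lab in labels],
            "card_gate": [lab.card_index for lab in labels],
        }
    ).to_csv(path, index=False)


def read_labels(path) -> tuple[np.ndarray, list[DualGateLabel]]:
    df = pd.read_csv(path)
    for col in ("time_s", "resp_gate", "card_gate"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    labels = combine_dual(
        df["resp_gate"].to_numpy(int), df["card_gate"].to_numpy(int)
    )
    return df["time_s"].to_numpy(float), labels
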