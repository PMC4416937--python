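"""Preprocessing chain for raw motor-imagery recordings.

Channel subset over the motor cortex, 8-30 Hz band-pass (5th-order
Butterworth by default), cue-relative segment extraction and per-channel
mean removal.  Filtering is causal (forward-only) by default, matching
an online system; zero-phase two-pass filtering is available via
``zero_phase=True``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal

from .epochs import EpochSet, EpochSetError

__all__ = [
    "PreprocessConfig",
    "select_channels",
    "bandpass_filter",
    "extract_segment",
]


@dataclasses.dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``band`` is the pass band in Hz, ``segment`` the cue-relative crop
    window in seconds (half-open, ``[start, end)`` after rounding to
    samples).
    """

    channel_subset: list | None = None
    band: tuple[float, float] = (8.0, 30.0)
    filter_order: int = 5
    segment: tuple[float, float] = (0.5, 2.0)
    exclude_rejected: bool = True
    zero_phase: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError(f"band must satisfy 0 < low < high, got {self.band}")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.segment[0] >= self.segment[1]:
            raise ValueError("segment start must precede end")


def select_channels(es: EpochSet, subset: Sequence) -> EpochSet:
    """Restrict epochs to ``subset`` (names or 0-based indices), in order."""
    if es.channel_names is None:
        raise EpochSetError("epoch set has no channel names")
    idx: list[int] = []
    seen: set[int] = set()
    for ch in subset:
        if isinstance(ch, (int, np.integer)):
            i = int(ch)
            if not 0 <= i < es.n_channels:
                raise EpochSetError(f"channel index {i} out of range")
        else:
            matches = [j for j, n in enumerate(es.channel_names) if n == ch]
            if not matches:
                raise EpochSetError(f"unknown channel {ch!r}")
            if len(matches) > 1:
                raise EpochSetError(f"channel name {ch!r} is ambiguous")
            i = matches[0]
        if i in seen:
            raise EpochSetError(f"duplicate channel request: {ch!r}")
        seen.add(i)
        idx.append(i)
    return EpochSet(
        epochs=[e[idx, :].copy() for e in es.epochs],
        labels=es.labels.copy(),
        channel_names=[es.channel_names[i] for i in idx],
        sample_rate=es.sample_rate,
        n_classes=es.n_classes,
    )


def _design_bandpass(cfg: PreprocessConfig, fs: float):
    lo, hi = cfg.band
    nyq = fs / 2.0
    if hi >= nyq:
        raise EpochSetError(
            f"band {cfg.band} infeasible at sample rate {fs} Hz (Nyquist {nyq})"
        )
    return signal.butter(cfg.filter_order, [lo, hi], btype="bandpass", fs=fs,
                         output="sos")


def bandpass_filter(es: EpochSet, cfg: PreprocessConfig | None = None) -> EpochSet:
    """Band-pass each channel of each epoch independently.

    DC lies in the stop band, so output is approximately zero-mean.
    """
    cfg = cfg or PreprocessConfig()
    if es.sample_rate is None:
        raise EpochSetError("sample_rate required for filtering")
    sos = _design_bandpass(cfg, es.sample_rate)
    filt = signal.sosfiltfilt if cfg.zero_phase else signal.sosfilt
    out = [np.asarray(filt(sos, e, axis=1)) for e in es.epochs]
    return EpochSet(
        epochs=out,
        labels=es.labels.copy(),
        channel_names=list(es.channel_names) if es.channel_names else None,
        sample_rate=es.sample_rate,
        n_classes=es.n_classes,
    )


def extract_segment(
    es: EpochSet,
    cue_sample: Sequence[int] | int,
    cfg: PreprocessConfig | None = None,
) -> EpochSet:
    """Crop each epoch to the cue-relative window and remove channel means.

    The window is ``[cue + round(start*fs), cue + round(end*fs))`` with
    0-based sample indexing; the per-channel mean is subtracted after
    cropping so the zero-mean invariant holds exactly.
    """
    cfg = cfg or PreprocessConfig()
    if es.sample_rate is None:
        raise EpochSetError("sample_rate required for segment extraction")
    fs = es.sample_rate
    cues = (
        np.full(es.n_epochs, int(cue_sample), dtype=int)
        if np.isscalar(cue_sample)
        else np.asarray(cue_sample, dtype=int)
    )
    if len(cues) != es.n_epochs:
        raise EpochSetError("one cue sample per epoch required")
    off0 = int(round(cfg.segment[0] * fs))
    off1 = int(round(cfg.segment[1] * fs))
    out = []
    for i, (e, cue) in enumerate(zip(es.epochs, cues)):
        a, b = cue + off0, cue + off1
        if a < 0 or b > e.shape[1]:
            raise EpochSetError(
                f"segment window [{a}, {b}) exceeds epoch {i} bounds "
                f"(T={e.shape[1]})"
            )
        seg = e[:, a:b].copy()
        seg -= seg.mean(axis=1, keepdims=True)
        out.append(seg)
    return EpochSet(
        epochs=out,
        labels=es.labels.copy(),
        channel_names=list(es.channel_names) if es.channel_names else None,
        sample_rate=es.sample_rate,
        n_classes=es.n_classes,
    )
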