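"""Labeled epoch container and its plain-text on-disk format.

An *epoch* is one trial of multichannel data: an ``N x T`` real matrix
(``N`` channels, ``T`` samples) with an integer class label in ``1..C``.
The :class:`EpochSet` is the universal input to every other module.

On disk an epoch set is a directory holding a ``manifest.txt`` of
``key=value`` lines plus one tab-delimited matrix file per epoch
(rows = channels).  The format is deliberately plain text: the data sets
at this scale are tiny and diffability matters.
"""

from __future__ import annotations

import dataclasses
import os
import re
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["EpochSet", "write_epochset", "read_epochset", "EpochSetError"]

MANIFEST_NAME = "manifest.txt"
_EPOCH_FILE_RE = re.compile(r"epoch_(\d+)_class(\d+)\.txt$")

# Zero-mean tolerance, relative to the per-channel standard deviation.
ZERO_MEAN_RTOL = 1e-8


class EpochSetError(ValueError):
    """Raised on malformed epoch sets or on-disk containers."""


@dataclasses.dataclass
class EpochSet:
    """Ordered collection of labeled N x T epochs.

    Parameters
    ----------
    epochs
        List of 2-D float arrays, all with the same channel count ``N``.
    labels
        Integer class id in ``1..n_classes`` per epoch.
    channel_names
        Optional channel names; placeholders ``ch1..chN`` if omitted.
    sample_rate
        Sampling rate in Hz; only required by the preprocessing chain.
    n_classes
        Number of classes ``C``; defaults to ``max(labels)``.
    """

    epochs: list[np.ndarray]
    labels: np.ndarray
    channel_names: list[str] | None = None
    sample_rate: float | None = None
    n_classes: int | None = None

    def __post_init__(self) -> None:
        self.epochs = [np.asarray(e, dtype=float) for e in self.epochs]
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.epochs) != len(self.labels):
            raise EpochSetError(
                f"{len(self.epochs)} epochs but {len(self.labels)} labels"
            )
        for i, e in enumerate(self.epochs):
            if e.ndim != 2:
                raise EpochSetError(f"epoch {i} is not a 2-D matrix")
        if self.epochs:
            n = self.epochs[0].shape[0]
            for i, e in enumerate(self.epochs):
                if e.shape[0] != n:
                    raise EpochSetError(
                        f"epoch {i} has {e.shape[0]} channels, expected {n}"
                    )
        if self.n_classes is None:
            self.n_classes = int(self.labels.max()) if len(self.labels) else 0
        if len(self.labels) and (
            self.labels.min() < 1 or self.labels.max() > self.n_classes
        ):
            raise EpochSetError(
                f"labels must lie in 1..{self.n_classes}, "
                f"got range [{self.labels.min()}, {self.labels.max()}]"
            )
        if self.channel_names is None and self.epochs:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]

    # -- basic accessors -------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def n_channels(self) -> int:
        return self.epochs[0].shape[0] if self.epochs else 0

    @property
    def n_samples(self) -> int | None:
        """Common sample count, or None if epochs have ragged lengths."""
        if not self.epochs:
            return None
        ts = {e.shape[1] for e in self.epochs}
        return ts.pop() if len(ts) == 1 else None

    def class_indices(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)

    def validate_zero_mean(self, rtol: float = ZERO_MEAN_RTOL) -> None:
        """Check the per-channel zero-mean invariant required downstream."""
        for i, e in enumerate(self.epochs):
            mu = e.mean(axis=1)
            sd = e.std(axis=1)
            scale = np.where(sd > 0, sd, 1.0)
            if np.any(np.abs(mu) > rtol * scale + 1e-300):
                raise EpochSetError(
                    f"epoch {i} is not zero-mean per channel "
                    f"(max |mean|/sd = {np.max(np.abs(mu) / scale):.3g})"
                )

    def validate_training(self) -> None:
        """Require every class 1..C to be represented."""
        present = set(np.unique(self.labels).tolist())
        missing = sorted(set(range(1, (self.n_classes or 0) + 1)) - present)
        if missing:
            raise EpochSetError(f"classes {missing} have no epochs")

    def subset(self, idx: Sequence[int]) -> "EpochSet":
        idx = list(idx)
        return EpochSet(
            epochs=[self.epochs[i].copy() for i in idx],
            labels=self.labels[idx].copy(),
            channel_names=list(self.channel_names) if self.channel_names else None,
            sample_rate=self.sample_rate,
            n_classes=self.n_classes,
        )


def write_epochset(es: EpochSet, path: str | os.PathLike) -> None:
    """Write an epoch set to ``path`` as a manifest plus per-epoch files.

    Refuses to write ragged epoch sets (all epochs must share ``T``);
    values round-trip at full double precision.
    """
    if es.n_epochs and es.n_samples is None:
        lengths = sorted({e.shape[1] for e in es.epochs})
        raise EpochSetError(
            f"inconsistent epoch shapes: sample counts {lengths}; refusing to write"
        )
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lines = [
        f"n_channels={es.n_channels}",
        f"n_samples={es.n_samples or 0}",
        f"n_epochs={es.n_epochs}",
        f"n_classes={es.n_classes}",
        f"sample_rate={'' if es.sample_rate is None else repr(float(es.sample_rate))}",
        f"channel_names={','.join(es.channel_names or [])}",
    ]
    (path / MANIFEST_NAME).write_text("\n".join(lines) + "\n")
    width = max(4, len(str(max(es.n_epochs - 1, 0))))
    for i, (e, lab) in enumerate(zip(es.epochs, es.labels)):
        fname = path / f"epoch_{i:0{width}d}_class{int(lab)}.txt"
        np.savetxt(fname, e, fmt="%.17g", delimiter="\t")


def _parse_manifest(text: str, path: Path) -> dict[str, str]:
    kv: dict[str, str] = {}
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if "=" not in ln:
            raise EpochSetError(f"malformed manifest line in {path}: {ln!r}")
        k, v = ln.split("=", 1)
        kv[k.strip()] = v.strip()
    return kv


def read_epochset(path: str | os.PathLike) -> EpochSet:
    """Read an epoch set written by :func:`write_epochset`.

    Epochs are returned in manifest (index) order; shape and label-range
    violations are reported naming the first offending file.
    """
    path = Path(path)
    manifest = path / MANIFEST_NAME
    if not manifest.is_file():
        raise EpochSetError(f"missing manifest: {manifest}")
    kv = _parse_manifest(manifest.read_text(), manifest)
    try:
        n_channels = int(kv["n_channels"])
        n_epochs = int(kv["n_epochs"])
        n_classes = int(kv["n_classes"])
    except KeyError as exc:
        raise EpochSetError(f"manifest missing key {exc} in {manifest}") from exc
    sample_rate = float(kv["sample_rate"]) if kv.get("sample_rate") else None
    names = kv.get("channel_names", "")
    channel_names = names.split(",") if names else None

    files: dict[int, tuple[Path, int]] = {}
    for p in sorted(path.iterdir()):
        m = _EPOCH_FILE_RE.search(p.name)
        if m:
            files[int(m.group(1))] = (p, int(m.group(2)))
    if sorted(files) != list(range(n_epochs)):
        raise EpochSetError(
            f"manifest declares {n_epochs} epochs but found indices "
            f"{sorted(files)} in {path}"
        )
    epochs, labels = [], []
    for i in range(n_epochs):
        p, lab = files[i]
        mat = np.loadtxt(p, ndmin=2)
        if mat.shape[0] != n_channels:
            raise EpochSetError(
                f"shape mismatch in {p.name}: {mat.shape[0]} rows, "
                f"manifest says {n_channels} channels"
            )
        if not 1 <= lab <= n_classes:
            raise EpochSetError(
                f"label {lab} in {p.name} outside 1..{n_classes}"
            )
        epochs.append(mat)
        labels.append(lab)
    return EpochSet(
        epochs=epochs,
        labels=np.array(labels, dtype=int),
        channel_names=channel_names,
        sample_rate=sample_rate,
        n_classes=n_classes,
    )
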