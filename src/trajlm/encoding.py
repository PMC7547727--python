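"""Spatial discretization of a 1-D order-parameter series into characters.

A scalar series is mapped onto ``N`` equal-width bins spanning its range;
each sample becomes an integer label (a "character"), optionally one-hot
encoded, and each label decodes back to the bin midpoint (its representative
value).  Bins are half-open ``[edge_i, edge_{i+1})`` except the last, which
is closed; out-of-range values clamp to the end bins so encoding is total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DiscretizationScheme",
    "LabelSeries",
    "fit_scheme",
    "encode",
    "decode",
    "one_hot",
    "write_labels",
    "read_labels",
]

DEFAULT_N_LABELS = 32  # model-potential default; 20 used for alanine
                       # dipeptide and 34 for force-spectroscopy data


@dataclass(frozen=True)
class DiscretizationScheme:
    """N equal-width bins on [lo, hi] with midpoint representative values."""

    n_labels: int
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.n_labels < 2:
            raise ValueError("n_labels must be >= 2")
        if not self.lo < self.hi:
            raise ValueError(f"degenerate range: lo={self.lo} must be < hi={self.hi}")

    @property
    def bin_width(self) -> float:
        return (self.hi - self.lo) / self.n_labels

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_labels + 1)

    @property
    def representative_values(self) -> np.ndarray:
        return self.lo + (np.arange(self.n_labels) + 0.5) * self.bin_width


@dataclass(frozen=True)
class LabelSeries:
    """Integer character sequence together with its bin geometry."""

    labels: np.ndarray
    scheme: DiscretizationScheme

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.size and (labels.min() < 0 or labels.max() >= self.scheme.n_labels):
            raise ValueError("labels out of range for scheme")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)


def fit_scheme(series, n_labels: int = DEFAULT_N_LABELS) -> DiscretizationScheme:
    """Fit equal-width bins to the observed range of a series."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot fit a scheme to an empty series")
    if not np.all(np.isfinite(series)):
        bad = int(np.flatnonzero(~np.isfinite(series))[0])
        raise ValueError(f"non-finite value in series at index {bad}")
    lo, hi = float(series.min()), float(series.max())
    if lo == hi:
        raise ValueError(f"degenerate range: series is constant at {lo}")
    return DiscretizationScheme(n_labels=int(n_labels), lo=lo, hi=hi)


def encode(series, scheme: DiscretizationScheme) -> LabelSeries:
    """Map each value to its bin index; out-of-range values clamp."""
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        bad = int(np.flatnonzero(~np.isfinite(series))[0])
        raise ValueError(f"non-finite value in series at index {bad}")
    idx = np.floor((series - scheme.lo) / scheme.bin_width).astype(np.int64)
    idx = np.clip(idx, 0, scheme.n_labels - 1)  # clamp + closed last bin
    return LabelSeries(labels=idx, scheme=scheme)


def decode(labels: LabelSeries) -> np.ndarray:
    """Replace each label by its bin-midpoint representative value."""
    if len(labels) == 0:
        return np.empty(0)
    return labels.scheme.representative_values[labels.labels]


def one_hot(labels, n_labels: int) -> np.ndarray:
    """(T, N) binary matrix with a single 1 per row."""
    labels = np.asarray(labels.labels if isinstance(labels, LabelSeries) else labels,
                        dtype=np.int64)
    if labels.size and (labels.min() < 0 or labels.max() >= n_labels):
        raise ValueError("label out of range for one-hot encoding")
    out = np.zeros((labels.size, n_labels), dtype=np.int64)
    out[np.arange(labels.size), labels] = 1
    return out


# -- label file I/O ---------------------------------------------------------
# One integer per line, plus a JSON sidecar manifest recording the bin
# geometry so decoding is reproducible.

def write_labels(ls: LabelSeries, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, ls.labels, fmt="%d")
    manifest = {"n_labels": ls.scheme.n_labels, "lo": ls.scheme.lo, "hi": ls.scheme.hi}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest))


def read_labels(path: str | Path) -> LabelSeries:
    path = Path(path)
    labels = np.atleast_1d(np.loadtxt(path, dtype=np.int64))
    manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    scheme = DiscretizationScheme(
        n_labels=int(manifest["n_labels"]), lo=float(manifest["lo"]),
        hi=float(manifest["hi"]),
    )
    return LabelSeries(labels=labels, scheme=scheme)
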