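"""Trial-aligned bivariate spike-count samples and their on-disk format.

A :class:`CountPairSample` holds ``n`` simultaneously observed spike-count
pairs from two neurons, optionally tagged with a stimulus label per trial
(needed by the mutual-information variant of the test).  The text format is
whitespace/tab-delimited, one trial per row: ``x  y  [stimulus]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, LabelingError

__all__ = ["CountPairSample", "read_count_pairs", "write_count_pairs"]


@dataclass(frozen=True)
class CountPairSample:
    """n observed (x, y) nonnegative integer count pairs, optionally labelled."""

    xs: np.ndarray
    ys: np.ndarray
    stimulus_labels: np.ndarray | None = None

    def __post_init__(self):
        xs = np.asarray(self.xs, dtype=np.int64)
        ys = np.asarray(self.ys, dtype=np.int64)
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "ys", ys)
        if xs.ndim != 1 or xs.shape != ys.shape:
            raise InvalidParameterError("xs and ys must be 1-D of equal length")
        if xs.size < 1:
            raise InvalidParameterError("a sample needs at least one pair")
        if (xs < 0).any() or (ys < 0).any():
            raise InvalidParameterError("spike counts must be nonnegative")
        if self.stimulus_labels is not None:
            labels = np.asarray(self.stimulus_labels)
            if labels.shape != xs.shape:
                raise LabelingError("stimulus_labels must align with pairs")
            object.__setattr__(self, "stimulus_labels", labels)

    @property
    def n(self) -> int:
        return int(self.xs.size)

    @property
    def labelled(self) -> bool:
        return self.stimulus_labels is not None

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[int, int]],
                   labels: Sequence | None = None) -> "CountPairSample":
        arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        return cls(arr[:, 0], arr[:, 1],
                   None if labels is None else np.asarray(labels))

    def subset(self, mask: np.ndarray) -> "CountPairSample":
        labels = None if self.stimulus_labels is None else self.stimulus_labels[mask]
        return CountPairSample(self.xs[mask], self.ys[mask], labels)

    def by_stimulus(self) -> dict:
        """Split the sample into per-stimulus sub-samples (labels required)."""
        if self.stimulus_labels is None:
            raise LabelingError("sample carries no stimulus labels")
        out = {}
        for lab in np.unique(self.stimulus_labels):
            out[lab] = self.subset(self.stimulus_labels == lab)
        return out

    def sample_statistics(self) -> tuple[float, float, float]:
        """Plug-in estimates (mean_x, mean_y, pearson_r); r = 0 if degenerate."""
        mx = float(self.xs.mean())
        my = float(self.ys.mean())
        vx = float(self.xs.var())
        vy = float(self.ys.var())
        if vx <= 0.0 or vy <= 0.0:
            r = 0.0
        else:
            r = float(((self.xs - mx) * (self.ys - my)).mean() / np.sqrt(vx * vy))
        return mx, my, r


def read_count_pairs(path: str | Path) -> CountPairSample:
    """Read a delimited count-pair file (columns x, y[, stimulus])."""
    df = pd.read_csv(path, sep=r"\s+|,|;", engine="python", comment="#",
                     header=None)
    if df.shape[1] < 2:
        raise InvalidParameterError(
            f"{path}: expected at least two columns, got {df.shape[1]}")
    labels = df.iloc[:, 2].to_numpy() if df.shape[1] >= 3 else None
    return CountPairSample(df.iloc[:, 0].to_numpy(dtype=np.int64),
                           df.iloc[:, 1].to_numpy(dtype=np.int64), labels)


def write_count_pairs(sample: CountPairSample, path: str | Path) -> None:
    cols = {"x": sample.xs, "y": sample.ys}
    if sample.stimulus_labels is not None:
        cols["stimulus"] = sample.stimulus_labels
    pd.DataFrame(cols).to_csv(path, sep="\t", header=False, index=False)
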