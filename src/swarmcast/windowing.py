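"""Sliding-window extraction of (history, horizon) training samples."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from swarmcast.errors import SeriesTooShortError
from swarmcast.panel import AsirPanel


@dataclass(frozen=True)
class WindowedDataset:
    """Paired (window, horizon) tensors cut from a panel.

    inputs : (N, w, S) — each sample is the w years ending at anchor year t.
    targets : (N, h, S) — the h years following the anchor.
    anchor_years : length-N, strictly increasing; window covers
        [t-w+1, t], target covers [t+1, t+h].
    """

    inputs: np.ndarray
    targets: np.ndarray
    anchor_years: tuple[int, ...]
    w: int
    h: int

    def __post_init__(self):
        n = len(self.anchor_years)
        assert self.inputs.shape[0] == n and self.targets.shape[0] == n
        assert self.inputs.shape[1] == self.w and self.targets.shape[1] == self.h

    def __len__(self) -> int:
        return len(self.anchor_years)

    @property
    def n_strata(self) -> int:
        return self.inputs.shape[2]

    def subset(self, idx) -> "WindowedDataset":
        idx = np.asarray(idx)
        return WindowedDataset(
            inputs=self.inputs[idx],
            targets=self.targets[idx],
            anchor_years=tuple(np.asarray(self.anchor_years)[idx].tolist()),
            w=self.w,
            h=self.h,
        )


def make_windows(panel: AsirPanel, w: int, h: int) -> WindowedDataset:
    """All N = T - w - h + 1 multivariate windows, in chronological order.

    Values are copies: mutating the dataset does not alter the panel.
    """
    if w < 1 or h < 1:
        raise ValueError("w and h must be positive")
    T, S = panel.shape
    if T < w + h:
        raise SeriesTooShortError(
            f"series of length {T} too short for w={w}, h={h}; need at least {w + h} years"
        )
    n = T - w - h + 1
    inputs = np.empty((n, w, S))
    targets = np.empty((n, h, S))
    anchors = []
    for k in range(n):
        start = k  # window rows [k, k+w), targets [k+w, k+w+h)
        inputs[k] = panel.values[start : start + w]
        targets[k] = panel.values[start + w : start + w + h]
        anchors.append(panel.years[start + w - 1])
    return WindowedDataset(
        inputs=inputs, targets=targets, anchor_years=tuple(anchors), w=w, h=h
    )


def count_samples(T: int, S: int, w: int, h: int) -> tuple[int, int]:
    """Window count and the per-subsequence ("paper-style") sample count.

    Returns ``(windows, paper_style)`` where ``windows = T - w - h + 1`` is
    the number of multivariate windows and ``paper_style = windows * S``
    counts each window-subsequence pair separately (the convention some
    reports use when quoting training-sample totals).
    """
    if T < w + h:
        raise SeriesTooShortError(
            f"series of length {T} too short for w={w}, h={h}; need at least {w + h} years"
        )
    windows = T - w - h + 1
    return windows, windows * S
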