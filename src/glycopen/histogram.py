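"""Delta-mass frequency distribution and predominant-mass calling.

Open-search delta masses are binned in 0.1 Da increments over [300, 2000)
and the most populated bins are called as predominant modification masses,
refined to the median of their member deltas. Because glycan heterogeneity
within a prokaryotic proteome is typically low, a genuine glycan produces a
sharp, highly populated bin against a diffuse background of false wildcard
deltas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class DeltaHistogram:
    """Left-closed fixed-width binning of wildcard delta masses."""

    lo: float
    hi: float
    width: float
    counts: np.ndarray
    members: list[np.ndarray]  # per-bin member delta values

    @property
    def edges(self) -> np.ndarray:
        return self.lo + self.width * np.arange(len(self.counts) + 1)

    @property
    def n_binned(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.edges[:-1],
                "bin_hi": self.edges[1:],
                "count": self.counts,
            }
        )


def build_histogram(
    deltas: Sequence[float],
    width: float = 0.1,
    lo: float = 300.0,
    hi: float = 2000.0,
) -> DeltaHistogram:
    """Bin delta masses; a delta d falls in bin floor((d - lo)/width).

    Deltas outside [lo, hi) and zero deltas (unmodified PSMs) are ignored.
    Accepts raw delta values or PSM objects/DataFrames via ``deltas_of``.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    values = np.asarray(list(deltas), dtype=float)
    values = values[(values >= lo) & (values < hi) & (values != 0.0)]
    n_bins = int(np.ceil((hi - lo) / width))
    idx = np.floor((values - lo) / width).astype(int)
    counts = np.bincount(idx, minlength=n_bins).astype(np.int64)
    order = np.argsort(idx, kind="stable")
    members: list[np.ndarray] = [np.empty(0)] * n_bins
    if len(values):
        sorted_idx = idx[order]
        sorted_vals = values[order]
        starts = np.searchsorted(sorted_idx, np.arange(n_bins), side="left")
        ends = np.searchsorted(sorted_idx, np.arange(n_bins), side="right")
        members = [sorted_vals[a:b] for a, b in zip(starts, ends)]
    return DeltaHistogram(lo, hi, width, counts, members)


def deltas_of(psms) -> list[float]:
    """Extract delta masses from PSM objects or a PSM DataFrame."""
    if isinstance(psms, pd.DataFrame):
        return psms["delta"].tolist()
    return [p.delta for p in psms]


def default_min_count(hist: DeltaHistogram) -> int:
    """max(5, 3x the expected per-bin count under a uniform background)."""
    n_bins = len(hist.counts)
    expected = hist.n_binned / n_bins if n_bins else 0.0
    return max(5, int(np.ceil(3.0 * expected)))


def predominant_masses(
    hist: DeltaHistogram,
    top_k: int = 2,
    min_count: int | None = None,
) -> list[tuple[float, int]]:
    """The top-k predominant modification masses as (refined mass, count).

    Bins are ranked by count (ties: lower mass first) and reported when they
    hold at least ``min_count`` deltas; the refined mass is the median of the
    member deltas rounded to 2 dp. Adjacent qualifying bins whose medians
    differ by less than one bin width are merged into a single call (a mass
    split across a bin edge by measurement error).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if min_count is None:
        min_count = default_min_count(hist)

    qualifying = [i for i in range(len(hist.counts)) if hist.counts[i] >= min_count]
    # Merge runs of adjacent qualifying bins with near-identical medians.
    groups: list[list[int]] = []
    for i in qualifying:
        if (
            groups
            and groups[-1][-1] == i - 1
            and abs(np.median(hist.members[i]) - np.median(hist.members[groups[-1][-1]]))
            < hist.width
        ):
            groups[-1].append(i)
        else:
            groups.append([i])

    calls = []
    for group in groups:
        member_values = np.concatenate([hist.members[i] for i in group])
        refined = float(np.round(np.median(member_values), 2))
        calls.append((refined, int(len(member_values))))
    calls.sort(key=lambda c: (-c[1], c[0]))
    return calls[:top_k]
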