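"""Nonoverlapping-window GC and depth tracks.

Tracks are plain pandas DataFrames with columns
``scaffold, start, end, full`` plus ``gc`` and/or ``depth_<platform>``
columns; ``full`` marks windows of exactly the nominal size (the trailing
partial window is kept but flagged). GC is (G+C)/(A+C+G+T) with N excluded
from the denominator, and an all-N window carries a missing value rather
than 0 so gap windows never drag medians. Depth follows samtools-bedcov
semantics: the sum of per-base depth over the window divided by the window
span.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ScaffoldSet

__all__ = ["gc_windows", "depth_windows", "median_window_stat", "merge_tracks",
           "read_bedgraph", "write_track"]


def _window_bounds(length: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, length, window)
    ends = np.minimum(starts + window, length)
    return starts, ends


def gc_windows(scaffolds: ScaffoldSet, window: int = 10_000) -> pd.DataFrame:
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for name, seq in scaffolds.items():
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
        starts, ends = _window_bounds(len(seq), window)
        gc_sums = np.add.reduceat(is_gc.astype(np.int64), starts) if len(arr) else []
        acgt_sums = np.add.reduceat(is_acgt.astype(np.int64), starts) if len(arr) else []
        for s, e, g, a in zip(starts, ends, gc_sums, acgt_sums):
            gc = g / a if a > 0 else np.nan
            rows.append((name, int(s), int(e), e - s == window, gc))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "full", "gc"])


def depth_windows(
    per_base_depth: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    window: int = 10_000,
    value_col: str = "depth",
    out_col: str = "depth",
) -> pd.DataFrame:
    """Window-average depth from a bedGraph-style table.

    ``per_base_depth`` needs columns scaffold, start, end and a value column;
    each row asserts a constant per-base depth over [start, end). Window
    depth = (sum of per-base depth in window) / (window span), so the result
    is invariant to how the input intervals are chunked.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    unknown = set(per_base_depth["scaffold"]) - set(scaffold_lengths)
    if unknown:
        raise ValueError(f"depth track references unknown scaffolds: {sorted(unknown)}")
    if (per_base_depth[value_col] < 0).any():
        raise ValueError("depth values must be >= 0")
    sums: dict[str, np.ndarray] = {
        name: np.zeros(int(np.ceil(L / window)) if L else 0)
        for name, L in scaffold_lengths.items()
    }
    for scaf, s, e, v in per_base_depth[["scaffold", "start", "end", value_col]].itertuples(
        index=False
    ):
        acc = sums[scaf]
        w0, w1 = int(s) // window, (int(e) - 1) // window
        for w in range(w0, w1 + 1):
            lo, hi = max(int(s), w * window), min(int(e), (w + 1) * window)
            acc[w] += v * (hi - lo)
    rows = []
    for name, L in scaffold_lengths.items():
        starts, ends = _window_bounds(L, window)
        for i, (s, e) in enumerate(zip(starts, ends)):
            rows.append((name, int(s), int(e), e - s == window, sums[name][i] / (e - s)))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "full", out_col])


def median_window_stat(track: pd.DataFrame, scaffold: str, field: str) -> float:
    """Lower-median of a window statistic over one scaffold (NaNs dropped)."""
    vals = track.loc[track["scaffold"] == scaffold, field].dropna().sort_values()
    if len(vals) == 0:
        raise ValueError(f"no non-missing {field!r} windows on {scaffold!r}")
    return float(vals.iloc[(len(vals) - 1) // 2])


def merge_tracks(*tracks: pd.DataFrame) -> pd.DataFrame:
    """Outer-join tracks on the shared (scaffold, start, end, full) grid."""
    out = tracks[0]
    for t in tracks[1:]:
        out = out.merge(t, on=["scaffold", "start", "end", "full"], how="outer")
    return out.sort_values(["scaffold", "start"]).reset_index(drop=True)


def read_bedgraph(path: str | Path, value_col: str = "depth") -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#",
        names=["scaffold", "start", "end", value_col],
    )


def write_track(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format="%.6g")
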