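"""Fixed-step signal tracks (FPKM coverage and ChIP/input ratios).

Coverage is normalized as fragments per kilobase of window per million
mapped fragments (FPKM), computed on fixed windows (default 10 kb).  Ratio
tracks are defined only where the denominator is positive; undefined windows
propagate as NaN, never as 0, so unmappable regions do not masquerade as
depletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SignalTrack", "coverage_track", "ratio_track", "write_bedgraph", "read_bedgraph"]


@dataclass
class SignalTrack:
    """Uniform-step signal on one chromosome.

    ``values[k]`` covers ``[k*step, (k+1)*step)``; ``kind`` is ``coverage``
    (non-negative) or ``ratio`` (NaN where undefined).
    """

    chrom: str
    step: int
    values: np.ndarray
    kind: str = "coverage"

    def __len__(self) -> int:
        return len(self.values)

    def mean_over(self, start: int, end: int) -> float:
        """Mean value over [start, end) bp, NaN-aware."""
        k0, k1 = start // self.step, -(-end // self.step)
        window = self.values[k0:k1]
        return float(np.nanmean(window)) if len(window) else float("nan")


def coverage_track(
    fragments: pd.DataFrame,
    window: int = 10_000,
    chrom_length: int | None = None,
    total_fragments: int | None = None,
    chrom: str = "chr1",
) -> SignalTrack:
    """FPKM coverage: fragments overlapping each window / (kb × millions mapped).

    ``fragments`` needs ``start``/``end`` columns (bp, half-open).  A fragment
    spanning several windows is counted in each window it overlaps.
    ``total_fragments`` defaults to the number of fragments supplied (i.e.
    they are the full mapped library).
    """
    if len(fragments) == 0:
        raise ValueError("zero mapped fragments")
    total = total_fragments if total_fragments is not None else len(fragments)
    if total <= 0:
        raise ValueError("zero mapped fragments")
    starts = fragments["start"].to_numpy(dtype=np.int64)
    ends = fragments["end"].to_numpy(dtype=np.int64)
    if chrom_length is None:
        chrom_length = int(ends.max())
    n_win = -(-chrom_length // window)
    counts = np.zeros(n_win)
    w0 = starts // window
    w1 = np.minimum((ends - 1) // window, n_win - 1)
    # overlap count via difference array over the window range of each fragment
    np.add.at(counts, w0, 1.0)
    tail = w1 + 1
    np.subtract.at(counts, tail[tail < n_win], 1.0)
    counts = np.cumsum(counts)
    fpkm = counts / (window / 1000.0) / (total / 1e6)
    return SignalTrack(chrom=chrom, step=window, values=fpkm, kind="coverage")


def ratio_track(chip: SignalTrack, input_: SignalTrack) -> SignalTrack:
    """Per-window chip/input ratio, NaN where the input is 0."""
    if chip.step != input_.step or len(chip) != len(input_):
        raise ValueError("chip and input tracks must share windows")
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(input_.values > 0, chip.values / input_.values, np.nan)
    return SignalTrack(chrom=chip.chrom, step=chip.step, values=vals, kind="ratio")


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for k, v in enumerate(track.values):
            if np.isnan(v):
                continue
            fh.write(f"{track.chrom}\t{k * track.step}\t{(k + 1) * track.step}\t{v:g}\n")


def read_bedgraph(path, step: int) -> SignalTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    if df.empty:
        raise ValueError(f"empty bedGraph {path}")
    chrom = df["chrom"].iloc[0]
    n_win = int(df["end"].max()) // step
    vals = np.full(n_win, np.nan)
    idx = df["start"].to_numpy() // step
    vals[idx] = df["value"].to_numpy(dtype=float)
    return SignalTrack(chrom=chrom, step=step, values=vals, kind="coverage")
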