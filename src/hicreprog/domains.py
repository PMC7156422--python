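"""TAD boundaries, directionality, aggregate TAD maps, RTI and region rules.

Boundary calling follows the insulation-score method: slide a square of side
``square_size`` (default 1 Mb) along the diagonal, average the contacts
crossing each bin, log2-normalize by the chromosome-wide mean, and call
boundaries where the delta vector (difference of mean insulation over
``delta_span`` flanks) crosses zero downward with a peak-to-trough amplitude
of at least ``noise_threshold`` (defaults 1 Mb / 200 kb / 0.25).

The relative TAD intensity (RTI) quantifies TAD strength: within the
neighborhood that exactly embeds a TAD, each distance row contributes the
ratio median(I_in)/median(I_out) of contact frequencies with both ends vs
exactly one end inside the TAD; the RTI is the median of the row ratios.
A uniform matrix has RTI 1, and stronger TADs have larger RTI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .tracks import SignalTrack

__all__ = [
    "InsulationTrack",
    "BoundarySet",
    "insulation_score",
    "call_boundaries",
    "tads_from_boundaries",
    "directionality_index",
    "profile_at_anchors",
    "feature_density_at_anchors",
    "rescale_aggregate",
    "aggregate_difference",
    "relative_tad_intensity",
    "mark_tads_by_signal",
    "classify_reprogramming",
    "relative_boundary_distance",
    "assign_regions",
]


@dataclass
class InsulationTrack:
    """Per-bin insulation score (log2 of the normalized crossing-contact mean)
    and its delta vector, with the calling parameters recorded."""

    chrom: str
    resolution: int
    insulation: np.ndarray  # NaN where the square does not fit
    delta: np.ndarray
    square_size: int
    delta_span: int
    noise_threshold: float


@dataclass
class BoundarySet:
    """Called TAD boundaries: DataFrame with columns ``bin, strength``."""

    chrom: str
    resolution: int
    n_bins: int
    table: pd.DataFrame

    @property
    def bins(self) -> np.ndarray:
        return self.table["bin"].to_numpy()

    def positions_bp(self) -> np.ndarray:
        """Boundary positions as bin midpoints in bp."""
        return (self.bins + 0.5) * self.resolution


def insulation_score(
    m: ContactMatrix,
    square_size: int = 1_000_000,
    delta_span: int = 200_000,
    noise_threshold: float = 0.25,
) -> InsulationTrack:
    """Insulation score of a single-chromosome (balanced) matrix.

    For bin b the raw score is the mean contact frequency of the
    ``square_size`` × ``square_size`` square immediately straddling b
    (rows b-w..b-1, columns b+1..b+w, w bins per Mb of ``square_size``),
    masked bins excluded.  The reported insulation is
    log2(raw / chromosome-wide mean of raw); the delta vector is the mean
    insulation over the upstream ``delta_span`` window minus the downstream
    one, so boundaries (insulation minima) are downward zero crossings.
    """
    if len(m.chromosomes) != 1:
        raise ValueError("insulation_score works per chromosome")
    n = m.n_bins
    w = max(1, int(round(square_size / m.resolution)))
    dw = max(1, int(round(delta_span / m.resolution)))
    if n < 2 * w + 1:
        raise ValueError("chromosome shorter than twice the insulation square")
    ok = ~m.mask
    raw = np.full(n, np.nan)
    for b in range(w, n - w):
        rows = slice(b - w, b)
        cols = slice(b + 1, b + 1 + w)
        sq = m.values[rows, cols]
        keep = np.outer(ok[rows], ok[cols])
        if keep.sum() < 0.5 * w * w:
            continue
        raw[b] = sq[keep].mean()
    finite = np.isfinite(raw) & (raw > 0)
    if not finite.any():
        raise ValueError("no defined insulation squares")
    chrom_mean = raw[finite].mean()
    ins = np.full(n, np.nan)
    ins[finite] = np.log2(raw[finite] / chrom_mean)
    delta = np.full(n, np.nan)
    for b in range(n):
        left = ins[max(0, b - dw): b]
        right = ins[b + 1: b + 1 + dw]
        if len(left) < dw or len(right) < dw:
            continue
        if np.isnan(left).all() or np.isnan(right).all():
            continue
        delta[b] = np.nanmean(left) - np.nanmean(right)
    return InsulationTrack(
        chrom=m.chromosomes[0],
        resolution=m.resolution,
        insulation=ins,
        delta=delta,
        square_size=square_size,
        delta_span=delta_span,
        noise_threshold=noise_threshold,
    )


def call_boundaries(t: InsulationTrack) -> BoundarySet:
    """Boundaries at downward zero crossings of the delta vector.

    The boundary strength is the difference between the local delta maximum
    before the crossing and the local minimum after it (searched within the
    contiguous sign runs around the crossing); a boundary is called when the
    strength is at least the noise threshold.  The boundary bin is whichever
    side of the crossing has the lower insulation.
    """
    delta, ins = t.delta, t.insulation
    n = len(delta)
    rows = []
    for i in range(n - 1):
        if not (np.isfinite(delta[i]) and np.isfinite(delta[i + 1])):
            continue
        if not (delta[i] > 0 >= delta[i + 1]):
            continue
        j = i
        peak = delta[i]
        while j - 1 >= 0 and np.isfinite(delta[j - 1]) and delta[j - 1] > 0:
            j -= 1
            peak = max(peak, delta[j])
        j = i + 1
        trough = delta[i + 1]
        while j + 1 < n and np.isfinite(delta[j + 1]) and delta[j + 1] <= 0:
            j += 1
            trough = min(trough, delta[j])
        strength = peak - trough
        if strength >= t.noise_threshold:
            a, b = i, i + 1
            if np.isfinite(ins[a]) and np.isfinite(ins[b]):
                bnd = a if ins[a] <= ins[b] else b
            else:
                bnd = a
            rows.append((bnd, float(strength)))
    table = pd.DataFrame(rows, columns=["bin", "strength"])
    return BoundarySet(chrom=t.chrom, resolution=t.resolution, n_bins=n, table=table)


def tads_from_boundaries(b: BoundarySet) -> pd.DataFrame:
    """TADs as intervals between consecutive boundaries.

    Chromosome ends close the terminal TADs, so k boundaries give k+1 TADs
    partitioning the chromosome.  Returns a frame with columns
    ``chrom, start, end, start_bin, end_bin`` (bp coordinates half-open).
    """
    edges = np.concatenate([[0], np.sort(b.bins), [b.n_bins]])
    edges = np.unique(edges)
    rows = []
    for s, e in zip(edges[:-1], edges[1:]):
        rows.append(
            (b.chrom, int(s) * b.resolution, int(e) * b.resolution, int(s), int(e))
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "start_bin", "end_bin"])


def directionality_index(m: ContactMatrix, window: int = 2_000_000) -> np.ndarray:
    """Directionality index per bin.

    A is the contact sum to the upstream ``window``, B downstream;
    with E = (A+B)/2, DI = sign(B-A) * ((A-E)^2/E + (B-E)^2/E); DI = 0
    where A = B.  NaN where the full window does not fit.
    """
    if len(m.chromosomes) != 1:
        raise ValueError("directionality_index works per chromosome")
    n = m.n_bins
    w = int(round(window / m.resolution))
    if w >= n:
        raise ValueError("window larger than chromosome")
    di = np.full(n, np.nan)
    for b in range(w, n - w):
        a = float(m.values[b, b - w: b].sum())
        bb = float(m.values[b, b + 1: b + 1 + w].sum())
        e = (a + bb) / 2.0
        if e == 0 or a == bb:
            di[b] = 0.0
            continue
        di[b] = np.sign(bb - a) * ((a - e) ** 2 / e + (bb - e) ** 2 / e)
    return di


def profile_at_anchors(
    values: np.ndarray, step: int, anchors_bp: np.ndarray, flank: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean meta-profile of a stepped track around anchor positions.

    Returns (offsets_bp, mean_profile); offsets run from -flank to +flank in
    ``step`` increments.  Anchors whose window exits the track are dropped;
    an empty usable set is an error.
    """
    vals = np.asarray(values, dtype=float)
    k = int(round(flank / step))
    offsets = np.arange(-k, k + 1)
    rows = []
    for a in np.asarray(anchors_bp):
        c = int(a // step)
        if c - k < 0 or c + k >= len(vals):
            continue
        rows.append(vals[c - k: c + k + 1])
    if not rows:
        raise ValueError("no usable anchors (all windows exit the track)")
    prof = np.nanmean(np.vstack(rows), axis=0)
    return offsets * step, prof


def feature_density_at_anchors(
    positions_bp: np.ndarray,
    anchors_bp: np.ndarray,
    flank: int,
    window: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean count of point features per ``window`` around anchors."""
    pos = np.sort(np.asarray(positions_bp, dtype=float))
    k = int(round(flank / window))
    offsets = np.arange(-k, k) * window  # window left edges relative to anchor
    counts = np.zeros((len(anchors_bp), len(offsets)))
    for i, a in enumerate(np.asarray(anchors_bp)):
        lefts = a + offsets
        counts[i] = np.searchsorted(pos, lefts + window) - np.searchsorted(pos, lefts)
    if counts.size == 0:
        raise ValueError("no usable anchors")
    return offsets + window // 2, counts.mean(axis=0)


def rescale_aggregate(
    m: ContactMatrix,
    tads: pd.DataFrame,
    flank_frac: float = 0.5,
    n_grid_tad: int = 20,
) -> np.ndarray:
    """Average TAD neighborhood after rescaling every TAD to a common grid.

    Each TAD plus flanks of ``flank_frac`` × TAD length on both sides is
    resampled onto a fixed grid by area-weighted block averaging (the TAD
    body occupies ``n_grid_tad`` grid cells), grids are averaged across
    TADs, and the aggregate is divided by its mean so every stage has an
    equal matrix sum.  TADs of 3 bins or fewer, or whose flanked span exits
    the chromosome, are skipped.
    """
    if len(m.chromosomes) != 1:
        raise ValueError("rescale_aggregate works per chromosome")
    res = m.resolution
    n = m.n_bins
    gf = int(round(n_grid_tad * flank_frac))
    g = n_grid_tad + 2 * gf
    acc = np.zeros((g, g))
    used = 0
    for _, tad in tads.iterrows():
        s_bin = int(tad["start"]) / res
        e_bin = int(tad["end"]) / res
        length = e_bin - s_bin
        if length <= 3:
            continue
        flank = flank_frac * length
        lo, hi = s_bin - flank, e_bin + flank
        if lo < 0 or hi > n:
            continue
        # area-weighted resampling matrix W: grid cell x source bin overlap
        cell_edges = np.linspace(lo, hi, g + 1)
        k0, k1 = int(np.floor(lo)), int(np.ceil(hi))
        src = np.arange(k0, k1)
        W = np.zeros((g, len(src)))
        for gi in range(g):
            a, b = cell_edges[gi], cell_edges[gi + 1]
            ov = np.minimum(b, src + 1) - np.maximum(a, src)
            W[gi] = np.clip(ov, 0, None)
        W /= W.sum(axis=1, keepdims=True)
        sub = m.values[k0:k1, k0:k1]
        acc += W @ sub @ W.T
        used += 1
    if used == 0:
        raise ValueError("no usable TADs (need length > 3 bins within the chromosome)")
    agg = acc / used
    mean = agg.mean()
    if mean > 0:
        agg = agg / mean
    return agg


def aggregate_difference(agg_late: np.ndarray, agg_early: np.ndarray) -> np.ndarray:
    """Entrywise late-minus-early difference of two aggregate TAD maps."""
    if agg_late.shape != agg_early.shape:
        raise ValueError("aggregate grids must match")
    return agg_late - agg_early


def relative_tad_intensity(
    m: ContactMatrix, start_bin: int, end_bin: int
) -> float:
    """Relative TAD intensity of the TAD spanning [start_bin, end_bin).

    For each separation d = 1..L-1 (L the TAD length in bins), I_in collects
    frequencies of pairs with both ends inside the TAD and I_out those with
    exactly one end inside and the other within one TAD length of the TAD;
    the row ratio is median(I_in)/median(I_out) and the RTI is the median of
    row ratios.  Rows with an empty class or a zero outside-median are
    skipped; all rows skipped is an error.  Masked bins are excluded.
    """
    L = end_bin - start_bin
    if L < 3:
        raise ValueError("TAD must span at least 3 bins")
    n = m.n_bins
    ok = ~m.mask
    inside = np.zeros(n, dtype=bool)
    inside[start_bin:end_bin] = True
    near = np.zeros(n, dtype=bool)
    near[max(0, start_bin - L): start_bin] = True
    near[end_bin: min(n, end_bin + L)] = True
    ratios = []
    for d in range(1, L):
        i = np.arange(0, n - d)
        j = i + d
        keep = ok[i] & ok[j]
        both_in = inside[i] & inside[j] & keep
        one_in = (inside[i] ^ inside[j]) & (near[i] | near[j]) & keep
        if not both_in.any() or not one_in.any():
            continue
        med_in = float(np.median(m.values[i[both_in], j[both_in]]))
        med_out = float(np.median(m.values[i[one_in], j[one_in]]))
        if med_out == 0:
            continue
        ratios.append(med_in / med_out)
    if not ratios:
        raise ValueError("all RTI rows skipped (no usable pairs)")
    return float(np.median(ratios))


def mark_tads_by_signal(
    tads: pd.DataFrame, chip: SignalTrack, input_: SignalTrack
) -> np.ndarray:
    """Flag TADs whose length-normalized ChIP coverage exceeds the input.

    Both coverages are averaged per bp over the TAD (the tracks are already
    depth-normalized per million mapped fragments); a TAD is marked iff its
    ChIP signal is strictly higher than its input signal.
    """
    if np.nansum(chip.values) == 0 or np.nansum(input_.values) == 0:
        raise ValueError("zero-depth track")
    flags = np.zeros(len(tads), dtype=bool)
    for k, (_, tad) in enumerate(tads.iterrows()):
        c = chip.mean_over(int(tad["start"]), int(tad["end"]))
        i = input_.mean_over(int(tad["start"]), int(tad["end"]))
        flags[k] = c > i
    return flags


def classify_reprogramming(
    rti_scnt: float | np.ndarray,
    rti_ref: float | np.ndarray,
    ratio_thresh: float = 1.2,
) -> np.ndarray:
    """'unreprogrammed' where the RTI exceeds the reference by more than
    ``ratio_thresh``-fold, else 'reprogrammed'.

    A TAD that stays substantially stronger in the nuclear-transfer embryo
    than in the fertilization-derived reference has resisted the removal of
    donor-cell structure.  No standard numeric cutoff exists for this
    comparison; 1.2 is this package's default and is configurable.
    """
    scnt = np.asarray(rti_scnt, dtype=float)
    ref = np.asarray(rti_ref, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference RTI must be positive")
    out = np.where(scnt / ref > ratio_thresh, "unreprogrammed", "reprogrammed")
    return out if out.shape else out[()]


def relative_boundary_distance(
    region: tuple[float, float], boundaries_bp: np.ndarray
) -> float:
    """Relative distance Dmin/Dtad of a region to its TAD boundaries.

    Dmin is the distance of the region midpoint to the nearest boundary and
    Dtad the distance between the flanking (upstream, downstream) boundaries;
    the ratio lies in [0, 0.5] (0 on a boundary, 0.5 at the TAD center).
    The midpoint must lie between two boundaries.
    """
    b = np.sort(np.asarray(boundaries_bp, dtype=float))
    mid = (region[0] + region[1]) / 2.0
    idx = np.searchsorted(b, mid)
    if idx == 0 or idx == len(b):
        if len(b) and mid == b[0 if idx == 0 else -1]:
            pass  # exactly on a terminal boundary: Dmin = 0
        else:
            raise ValueError("region midpoint outside any TAD")
    if idx == 0:
        return 0.0
    if idx == len(b):
        return 0.0
    up, down = b[idx - 1], b[idx]
    dmin = min(mid - up, down - mid)
    dtad = down - up
    return float(dmin / dtad)


def assign_regions(
    regions: pd.DataFrame,
    features: pd.DataFrame,
    f: float = 0.5,
    mode: str = "either",
) -> pd.DataFrame:
    """Assign regions to features by fractional overlap.

    With ``mode='either'`` (the ``intersectBed -f 0.5 -r -e`` semantics), a
    region is assigned to a feature when the overlap covers at least
    fraction ``f`` of the region *or* of the feature; ``mode='both'``
    requires both fractions.  Inputs are BED-like frames with ``start`` and
    ``end`` columns (and an optional ``chrom`` that must match when present
    in both).  Returns one row per (region, feature) assignment with the
    overlap length; regions can match several features.
    """
    if mode not in ("either", "both"):
        raise ValueError("mode must be 'either' or 'both'")
    rows = []
    r_chrom = regions["chrom"] if "chrom" in regions else None
    f_chrom = features["chrom"] if "chrom" in features else None
    for ri, reg in regions.iterrows():
        rs, re_ = float(reg["start"]), float(reg["end"])
        rlen = re_ - rs
        for fi, feat in features.iterrows():
            if r_chrom is not None and f_chrom is not None:
                if reg["chrom"] != feat["chrom"]:
                    continue
            fs, fe = float(feat["start"]), float(feat["end"])
            ov = min(re_, fe) - max(rs, fs)
            if ov <= 0:
                continue
            frac_r = ov / rlen if rlen > 0 else 1.0
            flen = fe - fs
            frac_f = ov / flen if flen > 0 else 1.0
            hit = (
                (frac_r >= f or frac_f >= f)
                if mode == "either"
                else (frac_r >= f and frac_f >= f)
            )
            if hit:
                rows.append((ri, fi, ov))
    return pd.DataFrame(rows, columns=["region_idx", "feature_idx", "overlap"])
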