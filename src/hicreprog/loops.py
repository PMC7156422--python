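"""Significant-interaction calling, super-enhancers, and virtual 4C.

Interaction significance follows the binomial/FDR scheme of distance-aware
Hi-C callers: the expected contact probability of a bin pair is estimated
from the smoothed empirical decay of the same matrix (mean count per pair
within 0.05 log10 distance bins, 3-bin moving average), each observed count
is tested against Binomial(N, p_d) with N the total tested contact count,
and Benjamini–Hochberg correction yields q-values (significant at q < 0.01).
A second pass re-estimates the expectation after removing first-pass
significant outliers so planted or biological hot pairs do not inflate their
own expectation.

Super-enhancers are called ROSE-style: promoter-overlapping peaks are
removed, the remainder stitched within a window (default 20 kb), stitched
entities ranked by aggregate signal, and the cutoff placed where the slope
of the scaled rank–signal curve reaches 1 (the hockey-stick elbow).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .contacts import ContactMatrix
from .decay import LOG_BIN_STEP

__all__ = [
    "call_significant_interactions",
    "stitch_peaks",
    "call_super_enhancers",
    "fragment_interaction_region",
    "make_promoters",
    "classify_interaction",
    "virtual_4c",
]


def _expected_probability(
    counts: np.ndarray, s: np.ndarray, keep: np.ndarray
) -> np.ndarray:
    """Per-pair expected contact probability from the smoothed decay.

    ``s`` are pair separations (bp); counts/keep select which pairs enter
    the estimation.  Returns the probability for every pair in ``s``.
    """
    b = np.floor(np.log10(s) / LOG_BIN_STEP + 1e-9).astype(int)
    b0 = b.min()
    nb = b.max() - b0 + 1
    mass = np.bincount(b[keep] - b0, weights=counts[keep], minlength=nb)
    npairs = np.bincount(b[keep] - b0, minlength=nb).astype(float)
    with np.errstate(invalid="ignore"):
        mean_per_pair = np.where(npairs > 0, mass / npairs, np.nan)
    # 3-bin moving average over occupied bins
    occ = np.isfinite(mean_per_pair)
    vals = mean_per_pair[occ]
    if len(vals) >= 3:
        sm = np.convolve(vals, np.ones(3) / 3, mode="same")
        sm[0] = vals[:2].mean()
        sm[-1] = vals[-2:].mean()
    else:
        sm = vals
    smoothed = mean_per_pair.copy()
    smoothed[occ] = sm
    # pairs in unoccupied bins inherit the nearest occupied bin
    if (~occ).any():
        occ_idx = np.flatnonzero(occ)
        nearest = occ_idx[
            np.clip(np.searchsorted(occ_idx, np.flatnonzero(~occ)), 0, len(occ_idx) - 1)
        ]
        smoothed[~occ] = smoothed[nearest]
    total = counts[keep].sum()
    if total <= 0:
        raise ValueError("insufficient pairs for expectation estimation")
    return smoothed[b - b0] / total


def call_significant_interactions(
    m: ContactMatrix,
    min_dist: int = 200_000,
    max_dist: int = 20_000_000,
    q_thresh: float = 0.01,
    passes: int = 2,
) -> pd.DataFrame:
    """Binomial test of every cis bin pair against the distance expectation.

    Tests pairs with separation in [min_dist, max_dist], per chromosome but
    pooled for FDR control.  Returns a frame with columns
    ``chrom, bin_i, bin_j, distance, observed, expected_p, p, q, significant``
    (bin indices are chromosome-local).
    """
    frames = []
    for chrom in m.chromosomes:
        sub = m.cis(chrom)
        n = sub.n_bins
        iu = np.triu_indices(n, k=1)
        s = (iu[1] - iu[0]).astype(float) * m.resolution
        sel = (s >= min_dist) & (s <= max_dist)
        ok = ~sub.mask
        sel &= ok[iu[0]] & ok[iu[1]]
        if not sel.any():
            continue
        i, j = iu[0][sel], iu[1][sel]
        counts = sub.values[i, j]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_i": i,
                    "bin_j": j,
                    "distance": s[sel],
                    "observed": counts,
                }
            )
        )
    if not frames:
        raise ValueError("no testable cis pairs in the distance range")
    calls = pd.concat(frames, ignore_index=True)

    keep = np.ones(len(calls), dtype=bool)
    for _ in range(max(1, passes)):
        probs = np.empty(len(calls))
        n_tot = np.empty(len(calls))
        for chrom, grp in calls.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            probs[idx] = _expected_probability(
                grp["observed"].to_numpy(dtype=float),
                grp["distance"].to_numpy(),
                keep[idx],
            )
            n_tot[idx] = grp["observed"].to_numpy(dtype=float)[keep[idx]].sum()
        k = calls["observed"].to_numpy()
        # P[X >= k] under Binomial(N, p); k = 0 gives p-value 1
        pvals = stats.binom.sf(k - 1, np.round(n_tot).astype(np.int64), np.clip(probs, 0, 1))
        pvals = np.clip(pvals, 0.0, 1.0)
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        keep = ~(qvals < q_thresh)  # drop significant outliers, re-estimate
    calls["expected_p"] = probs
    calls["p"] = pvals
    calls["q"] = qvals
    calls["significant"] = qvals < q_thresh
    return calls


def stitch_peaks(peaks: pd.DataFrame, stitch: int = 20_000) -> pd.DataFrame:
    """Merge peaks whose gap is at most ``stitch`` bp; sum their signal."""
    if len(peaks) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "signal", "n_constituents"])
    df = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    rows = []
    cur = None
    for _, pk in df.iterrows():
        if (
            cur is not None
            and pk["chrom"] == cur["chrom"]
            and pk["start"] - cur["end"] <= stitch
        ):
            cur["end"] = max(cur["end"], pk["end"])
            cur["signal"] += pk["signal"]
            cur["n_constituents"] += 1
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "chrom": pk["chrom"],
                "start": pk["start"],
                "end": pk["end"],
                "signal": float(pk["signal"]),
                "n_constituents": 1,
            }
    rows.append(cur)
    return pd.DataFrame(rows)


def call_super_enhancers(
    peaks: pd.DataFrame,
    promoters: pd.DataFrame,
    stitch: int = 20_000,
) -> pd.DataFrame:
    """ROSE-style super-enhancer calling from a ranked peak set.

    Peaks overlapping any promoter are excluded, the rest are stitched
    within ``stitch`` bp and ranked by aggregate signal; the hockey-stick
    cutoff is the point of the scaled rank–signal curve where the tangent
    slope is 1 (argmin of y_scaled - x_scaled on the convex ascending
    curve), and entities with signal above the cutoff are returned.
    """
    if len(peaks) == 0:
        raise ValueError("no peaks supplied")
    drop = np.zeros(len(peaks), dtype=bool)
    pk_start = peaks["start"].to_numpy()
    pk_end = peaks["end"].to_numpy()
    for _, pr in promoters.iterrows():
        drop |= (pk_start < pr["end"]) & (pk_end > pr["start"])
    kept = peaks.loc[~drop]
    entities = stitch_peaks(kept, stitch=stitch)
    if len(entities) < 3:
        raise ValueError("fewer than 3 stitched entities; cutoff not estimable")
    sig = np.sort(entities["signal"].to_numpy())
    x = np.arange(len(sig)) / (len(sig) - 1)
    y = sig / sig.max()
    cut_idx = int(np.argmin(y - x))
    threshold = sig[cut_idx]
    supers = entities[entities["signal"] > threshold].reset_index(drop=True)
    supers.attrs["signal_cutoff"] = float(threshold)
    return supers


def fragment_interaction_region(
    read_pos: int, restriction_sites: np.ndarray, strand: str = "+", min_len: int = 500
) -> tuple[int, int]:
    """Interaction region of a read 5' end, bounded by its restriction site.

    The region spans from the read 5' end to the restriction site that
    terminates its fragment in the read direction; regions shorter than
    ``min_len`` (default 500 bp) are replaced by the ``min_len`` window
    extending back from the site.
    """
    sites = np.asarray(restriction_sites)
    if len(sites) == 0:
        raise ValueError("no restriction sites supplied")
    if strand == "+":
        idx = int(np.searchsorted(sites, read_pos, side="left"))
        if idx == len(sites):
            raise ValueError("read position beyond the last restriction site")
        site = int(sites[idx])
        if site - read_pos < min_len:
            return site - min_len, site
        return int(read_pos), site
    idx = int(np.searchsorted(sites, read_pos, side="right")) - 1
    if idx < 0:
        raise ValueError("read position before the first restriction site")
    site = int(sites[idx])
    if read_pos - site < min_len:
        return site, site + min_len
    return site, int(read_pos)


def make_promoters(tss: pd.DataFrame, flank: int = 1000) -> pd.DataFrame:
    """Promoters as TSS ± ``flank`` (strand-aware TSS, 0-based half-open).

    ``tss`` needs columns ``chrom, pos`` and optionally ``strand`` (the TSS
    position is assumed to already be the strand-correct transcription
    start).
    """
    return pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": np.maximum(0, tss["pos"] - flank),
            "end": tss["pos"] + flank,
        }
    )


def _covered_fraction(region: tuple[float, float], intervals: pd.DataFrame) -> float:
    """Fraction of the region covered by the union of intervals."""
    s, e = region
    if e <= s:
        return 0.0
    segs = []
    for _, iv in intervals.iterrows():
        a, b = max(s, iv["start"]), min(e, iv["end"])
        if b > a:
            segs.append((a, b))
    if not segs:
        return 0.0
    segs.sort()
    covered = 0.0
    cur_a, cur_b = segs[0]
    for a, b in segs[1:]:
        if a > cur_b:
            covered += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    covered += cur_b - cur_a
    return covered / (e - s)


def classify_interaction(
    region1: tuple[float, float],
    region2: tuple[float, float],
    super_enhancers: pd.DataFrame,
    promoters: pd.DataFrame,
    min_frac: float = 0.5,
) -> str:
    """SE–P / P–P / other classification of a significant interaction.

    SE–P: one region has at least ``min_frac`` of its length inside a
    super-enhancer and the partner at least ``min_frac`` inside a promoter
    (symmetric in region order).  P–P: both regions promoter-covered.
    Anything else: other.
    """
    se1 = _covered_fraction(region1, super_enhancers) >= min_frac
    se2 = _covered_fraction(region2, super_enhancers) >= min_frac
    pr1 = _covered_fraction(region1, promoters) >= min_frac
    pr2 = _covered_fraction(region2, promoters) >= min_frac
    if (se1 and pr2) or (se2 and pr1):
        return "SE-P"
    if pr1 and pr2:
        return "P-P"
    return "other"


def virtual_4c(m: ContactMatrix, anchor_bin: int) -> np.ndarray:
    """The anchor bin's row of frequencies as a one-vs-all profile."""
    if not (0 <= anchor_bin < m.n_bins):
        raise ValueError("anchor outside matrix")
    if m.mask[anchor_bin]:
        raise ValueError("anchor bin is masked")
    return m.values[anchor_bin].copy()
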