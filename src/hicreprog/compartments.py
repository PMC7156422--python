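"""A/B compartment calling and compartment-level statistics.

Compartments are called per chromosome from the leading eigenvector (PC1) of
the Pearson correlation matrix of the observed/expected (O/E) contact map —
the convention behind the plaid correlation heatmaps of compartment figures.
The eigenvector sign is arbitrary, so it is oriented against an external
activity track (TSS density or an active-mark ratio): the sign is chosen so
bins above the track median have positive mean PC1, making A (PC1 > 0) the
active compartment.

Compartment segregation is quantified as the ratio of mean A–B interaction
frequency to mean within-compartment (A–A or B–B) frequency, restricted to
distance strata where both pair classes are represented — removing the
confound that A–B pairs sit at larger separations.  Lower ratio = stronger
segregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .contacts import ContactMatrix

__all__ = [
    "CompartmentProfile",
    "observed_expected",
    "compartment_pc1",
    "pc1_reproducibility",
    "segregation_ratio",
    "call_switches",
    "cluster_pc1_trajectories",
    "signal_in_compartments",
]


@dataclass
class CompartmentProfile:
    """Per-bin PC1 values and A/B labels for one chromosome.

    ``pc1`` is NaN at masked bins; ``labels`` holds 'A' (PC1 > 0),
    'B' (PC1 < 0) or '' where undefined.
    """

    chrom: str
    resolution: int
    pc1: np.ndarray
    labels: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.pc1)


def observed_expected(m: ContactMatrix) -> np.ndarray:
    """Divide each entry by the mean of its distance stratum (diagonal).

    Expects a single-chromosome (typically ICE-balanced) matrix.  Masked
    bins and strata with zero mean are NaN in the output.
    """
    if len(m.chromosomes) != 1:
        raise ValueError("observed_expected works per chromosome")
    n = m.n_bins
    ok = ~m.mask
    oe = np.full((n, n), np.nan)
    for d in range(0, n):
        diag = np.diagonal(m.values, offset=d)
        keep = ok[: n - d] & ok[d:]
        if not keep.any():
            continue
        mean = diag[keep].mean()
        if mean <= 0:
            continue
        row = np.arange(n - d)[keep]
        oe[row, row + d] = diag[keep] / mean
        oe[row + d, row] = oe[row, row + d]
    return oe


def compartment_pc1(
    m: ContactMatrix, orientation_track: np.ndarray | None = None
) -> CompartmentProfile:
    """PC1 of the correlation matrix of O/E, oriented by an activity track.

    ``orientation_track`` gives one value per bin (e.g. TSS density or an
    H3K4me3/input ratio); after orientation, bins above its median have
    positive mean PC1 and are labeled A.  Without a track the sign is left
    as returned by the eigendecomposition.
    """
    oe = observed_expected(m)
    good = np.isfinite(oe).sum(axis=1) > 0
    idx = np.flatnonzero(good)
    if idx.size < 10:
        raise ValueError("fewer than 10 unmasked bins; correlation degenerate")
    sub = oe[np.ix_(idx, idx)]
    # column means over defined entries so residual NaNs do not poison corrcoef
    col_mean = np.nanmean(sub, axis=0)
    inds = np.where(np.isfinite(sub), sub, np.broadcast_to(col_mean, sub.shape))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(inds)
    corr = np.nan_to_num(corr, nan=0.0)
    w, v = np.linalg.eigh(corr)
    lead = v[:, -1] * np.sqrt(max(w[-1], 0.0))
    pc1 = np.full(m.n_bins, np.nan)
    pc1[idx] = lead
    if orientation_track is not None:
        track = np.asarray(orientation_track, dtype=float)
        if track.shape != (m.n_bins,):
            raise ValueError("orientation track length must equal n_bins")
        med = np.nanmedian(track[idx])
        defined = np.isfinite(pc1)
        hi = (track >= med) & defined
        lo = (track < med) & defined
        if hi.any() and lo.any():
            if np.nanmean(pc1[hi]) < np.nanmean(pc1[lo]):
                pc1 = -pc1
        elif hi.any() and np.nanmean(pc1[hi]) < 0:
            pc1 = -pc1
    labels = np.where(
        np.isfinite(pc1) & (pc1 > 0), "A", np.where(np.isfinite(pc1) & (pc1 < 0), "B", "")
    )
    return CompartmentProfile(
        chrom=m.chromosomes[0], resolution=m.resolution, pc1=pc1, labels=labels
    )


def pc1_reproducibility(p1: CompartmentProfile, p2: CompartmentProfile) -> float:
    """Pearson correlation of two PC1 profiles over mutually defined bins."""
    if len(p1.pc1) != len(p2.pc1):
        raise ValueError("profiles must share bins")
    both = p1.defined & p2.defined
    if both.sum() < 3:
        raise ValueError("fewer than 3 shared defined bins")
    r, _ = stats.pearsonr(p1.pc1[both], p2.pc1[both])
    return float(r)


def segregation_ratio(
    m: ContactMatrix, p: CompartmentProfile, min_pairs_per_stratum: int = 10
) -> float:
    """Mean A–B frequency / mean within-compartment frequency, distance-matched.

    Only distance strata with at least ``min_pairs_per_stratum`` pairs in
    *both* classes contribute; each qualifying stratum yields the ratio of
    its class mean frequencies and the result is the unweighted mean of
    stratum ratios (pooling masses across strata would re-introduce the
    distance confound the stratification removes, since A–B pairs sit at
    larger separations).  Lower values mean stronger compartment
    segregation (0 = no A–B contact at all; 1 = no segregation).
    """
    if len(m.chromosomes) != 1:
        raise ValueError("segregation_ratio works per chromosome")
    lab = p.labels
    is_a, is_b = lab == "A", lab == "B"
    if not is_a.any() or not is_b.any():
        raise ValueError("both compartment classes must be present")
    n = m.n_bins
    ratios = []
    for d in range(1, n):
        diag = np.diagonal(m.values, offset=d)
        a1, a2 = is_a[: n - d], is_a[d:]
        b1, b2 = is_b[: n - d], is_b[d:]
        cross = (a1 & b2) | (b1 & a2)
        same = (a1 & a2) | (b1 & b2)
        if cross.sum() < min_pairs_per_stratum or same.sum() < min_pairs_per_stratum:
            continue
        within_mean = diag[same].mean()
        if within_mean <= 0:
            continue
        ratios.append(diag[cross].mean() / within_mean)
    if not ratios:
        raise ValueError("no qualifying distance strata")
    return float(np.mean(ratios))


def call_switches(
    p_start: CompartmentProfile,
    p_end: CompartmentProfile,
    delta_min: float = 1.0,
    exclude_chroms: tuple[str, ...] = ("chrX",),
) -> pd.DataFrame:
    """Compartment switches between two stages.

    A bin switches when its PC1 changes sign and |ΔPC1| > ``delta_min``;
    consecutive switching bins with the same direction merge into maximal
    runs.  Returns a BED-like frame with columns
    ``chrom, start, end, direction`` (direction 'A->B' or 'B->A').
    The X chromosome is excluded by default, matching the convention of
    excluding the dosage-compensated chromosome from differential calls.
    """
    if len(p_start.pc1) != len(p_end.pc1):
        raise ValueError("profiles must share bins")
    cols = ["chrom", "start", "end", "direction"]
    if p_start.chrom in exclude_chroms:
        return pd.DataFrame(columns=cols)
    both = p_start.defined & p_end.defined
    sign_change = np.sign(p_start.pc1) * np.sign(p_end.pc1) < 0
    big = np.abs(p_end.pc1 - p_start.pc1) > delta_min
    hit = both & sign_change & big
    direction = np.where(p_start.pc1 > 0, "A->B", "B->A")
    rows = []
    i, n = 0, len(hit)
    res = p_start.resolution
    while i < n:
        if not hit[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hit[j + 1] and direction[j + 1] == direction[i]:
            j += 1
        rows.append((p_start.chrom, i * res, (j + 1) * res, direction[i]))
        i = j + 1
    return pd.DataFrame(rows, columns=cols)


def cluster_pc1_trajectories(
    pc1_by_stage: np.ndarray, k: int = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """K-means over per-bin PC1 trajectories across stages.

    ``pc1_by_stage`` is (n_bins, n_stages); rows containing NaN are dropped
    from clustering and labeled -1.  Returns (labels, cluster_means) with
    deterministic output for a fixed seed.
    """
    X = np.asarray(pc1_by_stage, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need per-bin PC1 across >= 2 stages")
    ok = np.isfinite(X).all(axis=1)
    rows = X[ok]
    if len(np.unique(rows, axis=0)) < k:
        raise ValueError(f"fewer than k={k} distinct trajectories")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    fit_labels = km.fit_predict(rows)
    labels = np.full(X.shape[0], -1)
    labels[ok] = fit_labels
    return labels, km.cluster_centers_


def signal_in_compartments(
    track: np.ndarray, p: CompartmentProfile, bin_lengths: np.ndarray | None = None
) -> dict[str, float]:
    """Length-weighted mean track signal over A bins and over B bins."""
    t = np.asarray(track, dtype=float)
    if t.shape != p.pc1.shape:
        raise ValueError("track must have one value per bin")
    w = (
        np.ones_like(t)
        if bin_lengths is None
        else np.asarray(bin_lengths, dtype=float)
    )
    out = {}
    for lab in ("A", "B"):
        sel = (p.labels == lab) & np.isfinite(t)
        if not sel.any():
            raise ValueError(f"no defined bins in compartment {lab}")
        out[lab] = float(np.average(t[sel], weights=w[sel]))
    return out
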