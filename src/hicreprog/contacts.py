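"""Contact-data containers and normalization.

The central object is :class:`ContactMatrix`: a per-genome binned, symmetric
contact matrix with a companion bin table (0-based half-open BED coordinates).
Matrices are held dense — the analyses in this package run on single
chromosomes at 40 kb–1 Mb resolution, where a dense array of a few thousand
bins is both faster and simpler than sparse bookkeeping.  The on-disk form is
the HiC-Pro-style triplet (``bin1 bin2 count``) plus a ``_abs.bed`` bin table,
which is sparse.

Normalization follows the standard Hi-C pipeline: iterative correction (ICE)
equalizes bin marginals to remove coverage bias, and depth scaling multiplies
the matrix to a common total (default 1e8) so samples sequenced to different
depths are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ContactList",
    "ContactMatrix",
    "make_bins",
    "read_valid_pairs",
    "bin_contacts",
    "ice_normalize",
    "scale_to_depth",
    "read_matrix",
    "write_matrix",
]


PAIR_COLUMNS = ["read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


@dataclass
class ContactList:
    """Valid contact pairs, canonically ordered.

    ``records`` has columns ``chrom1, pos1, strand1, chrom2, pos2, strand2``
    with ``(chrom1, pos1) <= (chrom2, pos2)`` for every row.  Strands are
    preserved but unused downstream.
    """

    records: pd.DataFrame
    n_malformed: int = 0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def is_cis(self) -> np.ndarray:
        return (self.records["chrom1"] == self.records["chrom2"]).to_numpy()


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix with its bin table.

    Parameters
    ----------
    bins
        DataFrame with columns ``chrom, start, end``; the row index is the
        bin id (strictly increasing, genome-wide).
    values
        Dense symmetric ``(n, n)`` array of counts (raw) or frequencies
        (after normalization).  The main diagonal is zero by convention
        (self-ligation removed upstream).
    resolution
        Bin size in bp (terminal bins may be shorter).
    normalization
        One of ``raw | iced | iced_scaled``.
    mask
        Boolean array marking filtered (low-coverage) bins; masked rows and
        columns carry no signal and are excluded from means downstream.
    """

    bins: pd.DataFrame
    values: np.ndarray
    resolution: int
    normalization: str = "raw"
    mask: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        n = len(self.bins)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} bins"
            )
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    @property
    def total(self) -> float:
        """Total interaction mass, counting each unordered pair once."""
        return float(np.triu(self.values).sum())

    def cis(self, chrom: str) -> "ContactMatrix":
        """Single-chromosome sub-matrix (shares no memory with the parent)."""
        sel = (self.bins["chrom"] == chrom).to_numpy()
        if not sel.any():
            raise KeyError(f"chromosome {chrom!r} not in bin table")
        idx = np.flatnonzero(sel)
        sub = self.bins.iloc[idx].reset_index(drop=True)
        return ContactMatrix(
            bins=sub,
            values=self.values[np.ix_(idx, idx)].copy(),
            resolution=self.resolution,
            normalization=self.normalization,
            mask=self.mask[idx].copy(),
            converged=self.converged,
        )

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            bins=self.bins.copy(),
            values=self.values.copy(),
            resolution=self.resolution,
            normalization=self.normalization,
            mask=self.mask.copy(),
            converged=self.converged,
        )


def make_bins(chromsizes: dict[str, int], bin_size: int) -> pd.DataFrame:
    """Tile chromosomes into fixed-size bins (terminal bins may be short)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    frames = []
    for chrom, length in chromsizes.items():
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    bins = pd.concat(frames, ignore_index=True)
    return bins


def read_valid_pairs(path) -> ContactList:
    """Read a HiC-Pro-style validPairs file (tab-separated, >= 7 columns).

    Malformed lines (too few fields, non-integer positions) are counted and
    skipped with a warning; an input yielding zero valid records is an error.
    """
    rows = []
    n_malformed = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                n_malformed += 1
                continue
            try:
                pos1, pos2 = int(parts[2]), int(parts[5])
            except ValueError:
                n_malformed += 1
                continue
            if pos1 < 0 or pos2 < 0:
                n_malformed += 1
                continue
            rows.append((parts[1], pos1, parts[3], parts[4], pos2, parts[6]))
    if not rows:
        raise ValueError(f"zero valid records in {path}")
    if n_malformed:
        warnings.warn(f"{n_malformed} malformed line(s) skipped in {path}")
    df = pd.DataFrame(
        rows, columns=["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
    )
    # canonical ordering: (chrom1, pos1) <= (chrom2, pos2)
    flip = (df["chrom2"] < df["chrom1"]) | (
        (df["chrom2"] == df["chrom1"]) & (df["pos2"] < df["pos1"])
    )
    if flip.any():
        f = flip.to_numpy()
        c1, p1, s1 = (df.loc[f, c].to_numpy() for c in ("chrom1", "pos1", "strand1"))
        df.loc[f, ["chrom1", "pos1", "strand1"]] = df.loc[
            f, ["chrom2", "pos2", "strand2"]
        ].to_numpy()
        df.loc[f, "chrom2"] = c1
        df.loc[f, "pos2"] = p1
        df.loc[f, "strand2"] = s1
    return ContactList(records=df, n_malformed=n_malformed)


def bin_contacts(
    contacts: ContactList,
    bin_size: int,
    chromsizes: dict[str, int] | None = None,
) -> ContactMatrix:
    """Aggregate contact pairs into a raw binned matrix.

    The bin of a position is ``floor(pos / bin_size)``.  When ``chromsizes``
    is omitted, each chromosome length is inferred as ``max(pos) + 1``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    df = contacts.records
    if chromsizes is None:
        lengths: dict[str, int] = {}
        for col_c, col_p in (("chrom1", "pos1"), ("chrom2", "pos2")):
            grp = df.groupby(col_c)[col_p].max()
            for chrom, mx in grp.items():
                lengths[chrom] = max(lengths.get(chrom, 0), int(mx) + 1)
        chromsizes = dict(sorted(lengths.items()))
    else:
        for col_c, col_p in (("chrom1", "pos1"), ("chrom2", "pos2")):
            for chrom, mx in df.groupby(col_c)[col_p].max().items():
                if chrom not in chromsizes:
                    raise ValueError(f"chromosome {chrom!r} not in chromsizes")
                if int(mx) >= chromsizes[chrom]:
                    raise ValueError(
                        f"position {int(mx)} beyond declared length of {chrom!r}"
                    )
    bins = make_bins(chromsizes, bin_size)
    offsets = {}
    for chrom in chromsizes:
        offsets[chrom] = int((bins["chrom"] == chrom).to_numpy().argmax())
    n = len(bins)
    b1 = (
        df["chrom1"].map(offsets).to_numpy() + (df["pos1"] // bin_size).to_numpy()
    ).astype(np.intp)
    b2 = (
        df["chrom2"].map(offsets).to_numpy() + (df["pos2"] // bin_size).to_numpy()
    ).astype(np.intp)
    lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
    values = np.zeros((n, n))
    np.add.at(values, (lo, hi), 1.0)
    values = values + values.T - np.diag(np.diag(values))
    return ContactMatrix(bins=bins, values=values, resolution=bin_size)


def ice_normalize(
    m: ContactMatrix,
    max_iter: int = 300,
    tol: float = 1e-8,
    filter_percentile: float = 2.0,
) -> ContactMatrix:
    """Iterative correction: balance the matrix so bin marginals are equal.

    Bins whose raw marginal is strictly below the ``filter_percentile``-th
    percentile of nonzero marginals (and all zero-marginal bins) are masked
    before balancing — a guard against sparse-coverage artifacts.  The
    balanced matrix is rescaled so its mean over unmasked cells equals the
    pre-balancing mean.  Convergence is declared when the coefficient of
    variation of unmasked marginals drops below ``tol``; non-convergence is
    reported via a warning and ``converged=False`` on the result.
    """
    if m.normalization != "raw":
        raise ValueError("ice_normalize expects a raw matrix")
    W = m.values.astype(float).copy()
    marg = W.sum(axis=1)
    if not np.any(marg > 0):
        raise ValueError("all-zero matrix cannot be balanced")
    mask = marg == 0
    nonzero = marg[~mask]
    if filter_percentile > 0 and nonzero.size:
        cut = np.percentile(nonzero, filter_percentile)
        mask |= marg < cut
    mask |= m.mask
    W[mask, :] = 0.0
    W[:, mask] = 0.0
    pre_mean = W[np.ix_(~mask, ~mask)].mean() if (~mask).any() else 0.0

    converged = False
    for _ in range(max_iter):
        s = W.sum(axis=1)
        sm = s[~mask]
        mean = sm.mean()
        if mean == 0:
            raise ValueError("matrix became all-zero during balancing")
        cv = sm.std() / mean
        if cv < tol:
            converged = True
            break
        sn = s / mean
        sn[mask] = 1.0
        W /= np.outer(sn, sn)
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iter} iterations (cv={cv:.3g}); "
            "returning partial result"
        )
    post_mean = W[np.ix_(~mask, ~mask)].mean()
    if post_mean > 0:
        W *= pre_mean / post_mean
    return ContactMatrix(
        bins=m.bins.copy(),
        values=W,
        resolution=m.resolution,
        normalization="iced",
        mask=mask,
        converged=converged,
    )


def scale_to_depth(m: ContactMatrix, target: float = 1e8) -> ContactMatrix:
    """Multiply the matrix so its total (pairs counted once) equals ``target``."""
    total = m.total
    if total <= 0:
        raise ValueError("zero-total matrix cannot be depth-scaled")
    out = m.copy()
    out.values = out.values * (target / total)
    out.normalization = (
        "iced_scaled" if m.normalization in ("iced", "iced_scaled") else m.normalization
    )
    return out


def write_matrix(m: ContactMatrix, path_matrix, path_bins) -> None:
    """Write a triplet matrix (upper triangle, 1 decimal-preserving float or int)
    and the bin table as a BED with a fourth ``bin_id`` column."""
    iu = np.triu_indices(m.n_bins)
    vals = m.values[iu]
    nz = vals != 0
    trip = pd.DataFrame(
        {"bin1": iu[0][nz], "bin2": iu[1][nz], "count": vals[nz]}
    )
    trip.to_csv(path_matrix, sep="\t", header=False, index=False)
    bed = m.bins.copy()
    bed["bin_id"] = bed.index
    bed.to_csv(path_bins, sep="\t", header=False, index=False)


def read_matrix(path_matrix, path_bins, resolution: int | None = None) -> ContactMatrix:
    """Read a triplet matrix + bin-table BED written by :func:`write_matrix`.

    Upper-triangle-only input is symmetrized; a triplet referencing a bin id
    absent from the bin table is an error naming the id.
    """
    bins = pd.read_csv(
        path_bins,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "bin_id"],
    )
    bins = bins.sort_values("bin_id").reset_index(drop=True)
    if not (bins["bin_id"].to_numpy() == np.arange(len(bins))).all():
        raise ValueError("bin_id column must be 0..n-1 without gaps")
    n = len(bins)
    if resolution is None:
        resolution = int((bins["end"] - bins["start"]).max())
    trip = pd.read_csv(
        path_matrix, sep="\t", header=None, names=["bin1", "bin2", "count"]
    )
    values = np.zeros((n, n))
    b1 = trip["bin1"].to_numpy(dtype=np.intp)
    b2 = trip["bin2"].to_numpy(dtype=np.intp)
    for b in (b1, b2):
        bad = (b < 0) | (b >= n)
        if bad.any():
            raise ValueError(f"unknown bin_id {int(b[bad][0])} in triplet matrix")
    values[b1, b2] = trip["count"].to_numpy(dtype=float)
    lower = values.T.copy()
    np.fill_diagonal(lower, 0.0)
    sym = np.where(values != 0, values, lower)
    sym = np.maximum(sym, sym.T)  # symmetrize; duplicates must agree
    return ContactMatrix(
        bins=bins[["chrom", "start", "end"]],
        values=sym,
        resolution=resolution,
    )
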