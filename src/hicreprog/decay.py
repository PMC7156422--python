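"""Contact-probability distance decay, P(s), and chromatin-state calls.

P(s) is computed the way it is plotted in the Hi-C literature on early
embryos: genomic separations are placed into log10 bins of width 0.05, the
interaction mass per bin is divided by the total so the raw curve sums to 1,
and the curve is optionally divided by a unit-normalized s^-1 reference
(the fractal-globule expectation) to expose deviations such as the abrupt
metaphase fall-off.

Two reference scalings anchor state classification: interphase chromatin
follows P(s) ~ s^-1 (fractal globule), condensed metaphase chromatin follows
P(s) ~ s^-0.5 up to a fall-off scale — near 10 Mb for mitotic metaphase and
near 4 Mb for meiosis-II (MII) metaphase — beyond which contacts vanish.

Note on slopes: the per-log-bin *mass* of an s^alpha map scales as
s^(alpha+1) (bin width and pair availability both grow with s), so
:func:`fit_decay_exponent` divides the mass by the number of locus pairs per
bin to obtain the mean per-pair contact frequency, whose log-log slope is
alpha itself.  The curve also stores the s^-1-weighted pair mass per bin so
the reference normalization uses the exact same geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import ContactList, ContactMatrix

__all__ = [
    "PsCurve",
    "StateCall",
    "contact_probability",
    "normalize_ps_by_reference",
    "fit_decay_exponent",
    "detect_falloff",
    "classify_chromatin_state",
    "distance_class_fractions",
    "trans_fraction",
]

LOG_BIN_STEP = 0.05


@dataclass
class PsCurve:
    """Contact probability vs genomic distance in log10 bins of width 0.05.

    ``edges`` are left log10-bp edges (multiples of 0.05); ``values`` is the
    unit-sum probability per bin when ``normalized`` is False, or the
    s^-1-normalized ratio otherwise.  ``n_pairs`` counts the locus pairs per
    bin (None when the geometry is unknown); ``ref_mass`` is the
    unnormalized s^-1-weighted pair mass per bin used as the reference.
    """

    edges: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray | None = None
    ref_mass: np.ndarray | None = None
    normalized: bool = False

    @property
    def centers_bp(self) -> np.ndarray:
        """Geometric bin centers in bp."""
        return 10 ** (self.edges + LOG_BIN_STEP / 2)


def _log_bin_index(s: np.ndarray) -> np.ndarray:
    return np.floor(np.log10(s) / LOG_BIN_STEP + 1e-9).astype(int)


def contact_probability(
    data: ContactMatrix | ContactList, min_dist_bins: int = 2
) -> PsCurve:
    """Raw P(s): interaction mass per 0.05 log10 distance bin / total mass.

    For a :class:`ContactMatrix`, distances are bin separations (cis only,
    every chromosome pooled) and the per-bin locus-pair counts are recorded;
    separations below ``min_dist_bins`` are dropped to suppress self-ligation
    artifacts near the diagonal.  For a :class:`ContactList`, distances are
    base-pair separations of cis pairs and pair availability is approximated
    as continuous (proportional to bin width in s).
    """
    if isinstance(data, ContactMatrix):
        masses: dict[int, float] = {}
        pairs: dict[int, float] = {}
        refs: dict[int, float] = {}
        any_cis = False
        for chrom in data.chromosomes:
            sub = data.cis(chrom)
            n = sub.n_bins
            ok = ~sub.mask
            for d in range(min_dist_bins, n):
                diag = np.diagonal(sub.values, offset=d)
                keep = ok[:-d] & ok[d:]
                if not keep.any():
                    continue
                any_cis = True
                s = d * data.resolution
                b = int(_log_bin_index(np.array([s]))[0])
                masses[b] = masses.get(b, 0.0) + float(diag[keep].sum())
                np_d = int(keep.sum())
                pairs[b] = pairs.get(b, 0.0) + np_d
                refs[b] = refs.get(b, 0.0) + np_d / s
        if not any_cis:
            raise ValueError("no intra-chromosomal contacts")
        bins_idx = np.array(sorted(pairs))
        mass = np.array([masses.get(b, 0.0) for b in bins_idx])
        n_pairs = np.array([pairs[b] for b in bins_idx])
        ref = np.array([refs[b] for b in bins_idx])
    else:
        df = data.records
        cis = df["chrom1"] == df["chrom2"]
        s = (df.loc[cis, "pos2"] - df.loc[cis, "pos1"]).to_numpy(dtype=float)
        s = s[s > 0]
        if s.size == 0:
            raise ValueError("no intra-chromosomal contacts")
        b = _log_bin_index(s)
        bins_idx = np.arange(b.min(), b.max() + 1)
        mass = np.bincount(b - b.min(), minlength=len(bins_idx)).astype(float)
        occupied = mass > 0
        bins_idx, mass = bins_idx[occupied], mass[occupied]
        left = 10 ** (bins_idx * LOG_BIN_STEP)
        right = 10 ** ((bins_idx + 1) * LOG_BIN_STEP)
        n_pairs = right - left  # continuous pair availability ∝ bin width
        ref = np.log(right / left)  # ∫ s^-1 ds over the bin
    total = mass.sum()
    if total <= 0:
        raise ValueError("no intra-chromosomal contacts")
    return PsCurve(
        edges=bins_idx * LOG_BIN_STEP,
        values=mass / total,
        n_pairs=n_pairs,
        ref_mass=ref,
        normalized=False,
    )


def normalize_ps_by_reference(c: PsCurve) -> PsCurve:
    """Divide P(s) by the unit-normalized s^-1 reference over the same bins."""
    if c.normalized:
        raise ValueError("curve is already s^-1-normalized")
    if c.ref_mass is None:
        raise ValueError("curve carries no reference geometry")
    ref = c.ref_mass / c.ref_mass.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(ref > 0, c.values / ref, np.nan)
    return PsCurve(
        edges=c.edges.copy(),
        values=vals,
        n_pairs=None if c.n_pairs is None else c.n_pairs.copy(),
        ref_mass=c.ref_mass.copy(),
        normalized=True,
    )


def fit_decay_exponent(c: PsCurve, s_min: float = 5e5, s_max: float = 3e6) -> float:
    """Least-squares log-log slope of the decay over [s_min, s_max].

    On a raw curve the mass per bin is first converted to mean per-pair
    contact frequency, so the fitted slope estimates the generative exponent
    alpha directly.  On an s^-1-normalized curve the stored ratio is fitted
    as-is (a flat normalized curve fits slope 0).
    """
    centers = c.centers_bp
    sel = (centers >= s_min) & (centers <= s_max) & (c.values > 0)
    sel &= np.isfinite(c.values)
    if sel.sum() < 5:
        raise ValueError(
            f"need >= 5 occupied bins in [{s_min:g}, {s_max:g}] bp, have {int(sel.sum())}"
        )
    y = c.values[sel]
    if not c.normalized:
        if c.n_pairs is None:
            raise ValueError("raw curve carries no pair counts")
        y = y / c.n_pairs[sel]
    slope = np.polyfit(np.log10(centers[sel]), np.log10(y), 1)[0]
    return float(slope)


def detect_falloff(
    c: PsCurve, s_max: float | None = None, smooth: int = 3
) -> float | None:
    """Fall-off scale: distance at the maximum of the normalized curve.

    The s^-1-normalized curve of a metaphase-like map rises as s^(alpha+1)
    and collapses past the cutoff, so its maximum marks the fall-off.  The
    curve is smoothed with a ``smooth``-bin moving average first; a maximum
    at the window edge means no interior fall-off (None).  Ties break to the
    smallest distance.  Returns the geometric center (bp) of the peak bin.
    """
    if not c.normalized:
        raise ValueError("detect_falloff expects an s^-1-normalized curve")
    centers = c.centers_bp
    sel = np.isfinite(c.values)
    if s_max is not None:
        sel &= centers <= s_max
    if sel.sum() == 0:
        raise ValueError("empty curve")
    v = c.values[sel]
    ctr = centers[sel]
    if v.size >= smooth:
        kernel = np.ones(smooth) / smooth
        sm = np.convolve(v, kernel, mode="same")
        # fix edge cells where the kernel hangs over
        half = smooth // 2
        for k in range(half):
            sm[k] = v[: k + half + 1].mean()
            sm[-(k + 1)] = v[-(k + half + 1):].mean()
    else:
        sm = v
    imax = int(np.argmax(sm))  # argmax takes the first (smallest s) on ties
    if imax == 0 or imax == len(sm) - 1:
        return None
    return float(ctr[imax])


@dataclass
class StateCall:
    """Chromatin-state label with the evidence behind it."""

    label: str  # interphase | mitotic_metaphase | MII_metaphase
    exponent: float
    falloff: float | None


def classify_chromatin_state(
    c: PsCurve,
    fit_window: tuple[float, float] = (5e5, 3e6),
    falloff_search_max: float = 3e7,
    mii_mitotic_threshold: float = 6e6,
) -> StateCall:
    """Interphase vs mitotic-metaphase vs MII-metaphase from a raw P(s) curve.

    Rule: a map is metaphase-like when its fitted exponent over the
    ``fit_window`` (default 0.5–3 Mb, inside both fall-off scales) is closer
    to the metaphase reference -0.5 than to the fractal-globule reference -1
    *and* an interior fall-off is detected in the normalized curve; a
    fall-off at or below 6 Mb (log-midpoint of the 4 and 10 Mb anchors)
    labels MII metaphase, above it mitotic metaphase.  Otherwise interphase.
    """
    if c.normalized:
        raise ValueError("classification starts from a raw curve")
    centers = c.centers_bp
    if centers.min() > fit_window[0] or centers.max() < 2e7:
        raise ValueError("curve must cover the fit window and reach 20 Mb")
    expo = fit_decay_exponent(c, *fit_window)
    falloff = detect_falloff(normalize_ps_by_reference(c), s_max=falloff_search_max)
    metaphase_like = abs(expo - (-0.5)) < abs(expo - (-1.0)) and falloff is not None
    if metaphase_like:
        label = (
            "MII_metaphase" if falloff <= mii_mitotic_threshold else "mitotic_metaphase"
        )
    else:
        label = "interphase"
    return StateCall(label=label, exponent=expo, falloff=falloff)


def distance_class_fractions(m: ContactMatrix) -> dict[str, float]:
    """Fractions of cis interaction mass by separation class.

    Classes ``<1 Mb``, ``1–10 Mb`` and ``>10 Mb`` partition the cis mass
    (they sum to 1); ``>20 Mb`` is reported separately as a sub-class of
    ``>10 Mb``.
    """
    short = mid = long_ = xlong = total = 0.0
    for chrom in m.chromosomes:
        sub = m.cis(chrom)
        n = sub.n_bins
        for d in range(1, n):
            s = d * m.resolution
            mass = float(np.diagonal(sub.values, offset=d).sum())
            total += mass
            if s < 1e6:
                short += mass
            elif s < 1e7:
                mid += mass
            else:
                long_ += mass
                if s > 2e7:
                    xlong += mass
    if total == 0:
        return {"lt_1Mb": 0.0, "1_10Mb": 0.0, "gt_10Mb": 0.0, "gt_20Mb": 0.0}
    return {
        "lt_1Mb": short / total,
        "1_10Mb": mid / total,
        "gt_10Mb": long_ / total,
        "gt_20Mb": xlong / total,
    }


def trans_fraction(data: ContactMatrix | ContactList) -> float:
    """Fraction of interaction mass between different chromosomes."""
    if isinstance(data, ContactMatrix):
        total = m_total = 0.0
        chrom = data.bins["chrom"].to_numpy()
        iu = np.triu_indices(data.n_bins, k=1)
        vals = data.values[iu]
        cis = chrom[iu[0]] == chrom[iu[1]]
        total = float(vals.sum())
        if total == 0:
            return 0.0
        return float(vals[~cis].sum()) / total
    cis = data.is_cis
    if len(data) == 0:
        return 0.0
    return float((~cis).sum()) / len(data)
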