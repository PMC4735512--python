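"""4C-seq viewpoint-track quantification around a Polycomb Hox domain.

The signal unit is the restriction fragment of a 4-cutter digest; read
counts per fragment per (condition, replicate) measure contact frequency
with the viewpoint.  The pipeline:

* normalize every sample to a common total inside a fixed genomic region
  spanning the assayed domain;
* smooth with a running mean of three fragments (fragment space, truncated
  at the ends);
* exclude fragments within 5 kb of the viewpoint;
* average replicates, divide perturbed conditions by the control and
  subtract 1 so gains are positive and losses negative;
* summarize the ratio in "near" vs "far" sub-regions of the domain
  (two-sample two-tailed t-test with an Anderson-Darling normality check
  and an exact rank-sum fallback);
* tile the domain into 200-bp windows, flag windows whose contact rate
  changed by more than 50%, and compare flagged vs unchanged windows by
  their distance to the nearest protein-binding peak centre;
* for externally called significant-contact intervals, count overlapping
  restriction fragments, split contacts into domain neighbourhood (<=2 Mb
  from the domain border) vs distal, and compute the fraction overlapping
  at least one binding peak.

Coordinates are 0-based half-open internally; BED-style interval inputs are
consumed as is, and the genome-browser style 1-based region strings of the
default scheme are converted on construction.  All interval tests use the
any-overlap rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FragmentTrack",
    "RegionScheme",
    "DEFAULT_SCHEME",
    "normalize_track",
    "smooth_running_mean",
    "mask_viewpoint",
    "ratio_minus_one",
    "near_far_summary",
    "flag_changed_windows",
    "distance_to_nearest_peak",
    "contacts_to_fragment_counts",
    "partition_contacts",
    "peak_overlap_fraction",
    "peak_centres",
]

NORMALIZATION_TOTAL = 1e6


@dataclass
class FragmentTrack:
    """Sorted, non-overlapping restriction fragments with per-sample counts.

    ``fragments`` has columns chrom/start/end (0-based half-open);
    ``counts`` maps sample name -> float array aligned to the fragments.
    ``mask`` marks fragments excluded from statistics (e.g. near the
    viewpoint).
    """

    fragments: pd.DataFrame
    counts: dict[str, np.ndarray]
    mask: np.ndarray | None = None
    signed: bool = False  # derived ratio tracks may hold negative values

    def __post_init__(self) -> None:
        frag = self.fragments.reset_index(drop=True)
        if not (frag["end"] > frag["start"]).all():
            raise ValueError("fragments must have positive length")
        if not frag["start"].is_monotonic_increasing:
            raise ValueError("fragments must be sorted by start")
        if (frag["start"].to_numpy()[1:] < frag["end"].to_numpy()[:-1]).any():
            raise ValueError("fragments must be non-overlapping")
        self.fragments = frag
        self.counts = {k: np.asarray(v, dtype=float) for k, v in self.counts.items()}
        for k, v in self.counts.items():
            if len(v) != len(frag):
                raise ValueError(f"sample {k!r} count length mismatch")
            if not self.signed and (v < 0).any():
                raise ValueError(f"sample {k!r} has negative counts")
        if self.mask is None:
            self.mask = np.zeros(len(frag), dtype=bool)

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def starts(self) -> np.ndarray:
        return self.fragments["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.fragments["end"].to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    def same_fragment_map(self, other: "FragmentTrack") -> bool:
        return (
            len(self) == len(other)
            and (self.starts == other.starts).all()
            and (self.ends == other.ends).all()
        )

    def replace_counts(
        self, counts: dict[str, np.ndarray], signed: bool | None = None
    ) -> "FragmentTrack":
        return FragmentTrack(
            self.fragments.copy(), counts, self.mask.copy(),
            self.signed if signed is None else signed,
        )


@dataclass
class RegionScheme:
    """Genomic landmarks of the assayed domain (0-based half-open).

    Defaults follow the Drosophila Bithorax-Complex on chr3R: the
    normalization window spanning the complex, the near/far boundary used
    for the Abd-B/Fab-6 viewpoints, the complex bounds, and a 2-Mb
    neighbourhood margin.
    """

    chrom: str = "chr3R"
    normalization_region: tuple[int, int] = (12367358, 12885749)
    viewpoint: tuple[int, int] = (12723000, 12724000)
    near_far_boundary: int = 12681221  # iab3/iab4 boundary (Abd-B, Fab-6)
    bxc_bounds: tuple[int, int] = (12480478, 12821577)
    neighbourhood_margin: int = 2_000_000
    viewpoint_margin: int = 5_000

    # The Ubx viewpoint uses the start of the bxd non-coding transcript.
    UBX_BOUNDARY = 12598910

    def __post_init__(self) -> None:
        lo, hi = self.bxc_bounds
        if not lo <= self.near_far_boundary <= hi:
            raise ValueError("near/far boundary must fall inside the domain bounds")
        if self.neighbourhood_margin <= 0 or self.viewpoint_margin <= 0:
            raise ValueError("margins must be positive")


DEFAULT_SCHEME = RegionScheme()


def _overlaps(starts, ends, lo, hi) -> np.ndarray:
    """Any-overlap of [start, end) fragments with the window [lo, hi)."""
    return (np.asarray(starts) < hi) & (np.asarray(ends) > lo)


def normalize_track(track: FragmentTrack, scheme: RegionScheme = DEFAULT_SCHEME,
                    total: float = NORMALIZATION_TOTAL) -> FragmentTrack:
    """Scale each sample so its reads inside the normalization region sum to
    a common constant; within-sample relative values are untouched."""
    lo, hi = scheme.normalization_region
    inside = _overlaps(track.starts, track.ends, lo, hi)
    out = {}
    for name, vals in track.counts.items():
        region_sum = float(vals[inside].sum())
        if region_sum <= 0:
            raise ValueError(f"sample {name!r} has no reads in the normalization region")
        out[name] = vals * (total / region_sum)
    return track.replace_counts(out)


def smooth_running_mean(track: FragmentTrack, window: int = 3) -> FragmentTrack:
    """Running mean over ``window`` fragments (fragment space, not bp);
    truncated windows at the track ends."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    out = {}
    for name, vals in track.counts.items():
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        n = len(vals)
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        out[name] = (csum[hi] - csum[lo]) / (hi - lo)
    return track.replace_counts(out)


def mask_viewpoint(track: FragmentTrack, scheme: RegionScheme = DEFAULT_SCHEME,
                   margin_bp: int | None = None) -> FragmentTrack:
    """Flag fragments overlapping viewpoint +/- margin as excluded
    (any-overlap rule) from all downstream statistics."""
    margin = scheme.viewpoint_margin if margin_bp is None else margin_bp
    lo = scheme.viewpoint[0] - margin
    hi = scheme.viewpoint[1] + margin
    new = track.replace_counts(track.counts)
    new.mask = track.mask | _overlaps(track.starts, track.ends, lo, hi)
    return new


def ratio_minus_one(test: FragmentTrack, control: FragmentTrack) -> FragmentTrack:
    """Per fragment (test/control) - 1, replicate-averaged per track.

    Output carries one sample ``"ratio"``; fragments where the control is
    zero are flagged in the mask (undefined, not +/-inf).
    """
    if not test.same_fragment_map(control):
        raise ValueError("tracks must share an identical fragment map")
    t = np.mean(list(test.counts.values()), axis=0)
    c = np.mean(list(control.counts.values()), axis=0)
    undefined = c == 0
    ratio = np.full(len(t), np.nan)
    np.divide(t, c, out=ratio, where=~undefined)
    out = test.replace_counts(
        {"ratio": np.where(undefined, 0.0, ratio - 1.0)}, signed=True
    )
    out.counts["ratio"][undefined] = np.nan
    out.mask = test.mask | control.mask | undefined
    return out


def _normality_ok(*groups) -> bool:
    for g in groups:
        if len(g) < 8:  # Anderson-Darling needs a reasonable sample
            continue
        res = stats.anderson(np.asarray(g), dist="norm")
        # significance_level is [15, 10, 5, 2.5, 1] %; use the 5% critical value
        crit = res.critical_values[list(res.significance_level).index(5.0)]
        if res.statistic > crit:
            return False
    return True


def near_far_summary(
    ratio_tracks: dict[str, FragmentTrack],
    scheme: RegionScheme = DEFAULT_SCHEME,
    boundaries: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean ratio in near vs far sub-regions of the domain per viewpoint,
    with a near-vs-far two-tailed two-sample t-test.

    ``ratio_tracks`` maps viewpoint name -> ratio track (from
    :func:`ratio_minus_one`).  ``boundaries`` optionally overrides the
    near/far boundary per viewpoint.  Normality is checked per group by
    Anderson-Darling; on violation an exact two-sample rank-sum test
    (Mann-Whitney U) replaces the t-test.
    """
    rows = []
    lo, hi = scheme.bxc_bounds
    vp_mid = 0.5 * (scheme.viewpoint[0] + scheme.viewpoint[1])
    for name, track in ratio_tracks.items():
        boundary = (boundaries or {}).get(name, scheme.near_far_boundary)
        vals = track.counts["ratio"]
        keep = ~track.mask & np.isfinite(vals)
        mid = track.midpoints
        in_domain = keep & (mid >= lo) & (mid < hi)
        # "near" is the viewpoint's own side of the boundary
        vp_side = mid >= boundary if vp_mid >= boundary else mid < boundary
        near = vals[in_domain & vp_side]
        far = vals[in_domain & ~vp_side]
        if len(near) == 0 or len(far) == 0:
            raise ValueError(f"viewpoint {name!r}: a region has no retained fragments")
        if len(near) < 2 or len(far) < 2:
            p, test_used = np.nan, "skipped (degenerate group)"
        elif _normality_ok(near, far):
            # Welch variant: near/far groups differ in size and count depth
            p = float(stats.ttest_ind(near, far, equal_var=False).pvalue)
            test_used = "t-test"
        else:
            p = float(stats.mannwhitneyu(near, far, alternative="two-sided").pvalue)
            test_used = "rank-sum"
        for region, group in (("near", near), ("far", far)):
            rows.append(
                {
                    "viewpoint": name,
                    "region": region,
                    "mean_ratio": float(np.mean(group)),
                    "n_fragments": len(group),
                    "p_near_vs_far": p,
                    "test": test_used,
                }
            )
    return pd.DataFrame(rows)


def flag_changed_windows(
    test: FragmentTrack,
    control: FragmentTrack,
    scheme: RegionScheme = DEFAULT_SCHEME,
    window_bp: int = 200,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Tile the domain into disjoint windows and flag contact-rate changes.

    Per window, the replicate-averaged test/control ratio (mean over
    fragments overlapping the window) is classified as ``decreased`` when
    ratio < (1 - threshold), ``increased`` when ratio > (1 + threshold),
    else ``unchanged``.  Windows with no defined ratio are dropped.
    """
    if not test.same_fragment_map(control):
        raise ValueError("tracks must share an identical fragment map")
    t = np.mean(list(test.counts.values()), axis=0)
    c = np.mean(list(control.counts.values()), axis=0)
    keep = ~(test.mask | control.mask) & (c > 0)
    ratio = np.full(len(t), np.nan)
    np.divide(t, c, out=ratio, where=keep)
    lo, hi = scheme.bxc_bounds
    edges = np.arange(lo, hi + window_bp, window_bp)
    rows = []
    starts, ends = test.starts, test.ends
    for wlo, whi in zip(edges[:-1], edges[1:]):
        sel = _overlaps(starts, ends, wlo, whi) & keep & np.isfinite(ratio)
        if not sel.any():
            continue
        r = float(np.mean(ratio[sel]))
        if r < 1.0 - threshold:
            flag = "decreased"
        elif r > 1.0 + threshold:
            flag = "increased"
        else:
            flag = "unchanged"
        rows.append(
            {"start": int(wlo), "end": int(min(whi, hi)), "midpoint": 0.5 * (wlo + min(whi, hi)),
             "ratio": r, "flag": flag}
        )
    return pd.DataFrame(rows)


def peak_centres(peaks: pd.DataFrame) -> np.ndarray:
    """Peak centres as interval midpoints (BED semantics)."""
    return 0.5 * (peaks["start"].to_numpy(float) + peaks["end"].to_numpy(float))


def distance_to_nearest_peak(
    windows: pd.DataFrame, peaks: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance (bp) from each window midpoint to the nearest peak centre,
    and a changed-vs-unchanged group comparison.

    Returns (windows with a ``distance_bp`` column, summary frame with the
    mean distance per flag group and the two-tailed t-test p-value between
    changed and unchanged windows).
    """
    if len(peaks) == 0:
        raise ValueError("peak set is empty")
    centres = np.sort(peak_centres(peaks))
    mids = windows["midpoint"].to_numpy(float)
    pos = np.searchsorted(centres, mids)
    left = centres[np.clip(pos - 1, 0, len(centres) - 1)]
    right = centres[np.clip(pos, 0, len(centres) - 1)]
    dist = np.minimum(np.abs(mids - left), np.abs(mids - right))
    out = windows.copy()
    out["distance_bp"] = dist
    changed = out[out["flag"] != "unchanged"]["distance_bp"].to_numpy()
    unchanged = out[out["flag"] == "unchanged"]["distance_bp"].to_numpy()
    if len(changed) >= 2 and len(unchanged) >= 2:
        p = float(stats.ttest_ind(changed, unchanged).pvalue)
    else:
        p = np.nan
    summary = (
        out.groupby("flag")["distance_bp"].agg(["mean", "count"]).reset_index()
    )
    summary["p_changed_vs_unchanged"] = p
    return out, summary


def contacts_to_fragment_counts(
    contacts: pd.DataFrame, fragments: pd.DataFrame
) -> pd.DataFrame:
    """Number of restriction fragments overlapping each contact interval
    (any-overlap), via sorted-interval search."""
    fr = fragments.sort_values("start").reset_index(drop=True)
    starts = fr["start"].to_numpy()
    ends = fr["end"].to_numpy()
    out = contacts.copy().reset_index(drop=True)
    n_frag = np.zeros(len(out), dtype=np.int64)
    for i, (lo, hi) in enumerate(zip(out["start"], out["end"])):
        # fragments with start < hi and end > lo
        first = int(np.searchsorted(ends, lo, side="right"))
        last = int(np.searchsorted(starts, hi, side="left"))
        n_frag[i] = max(last - first, 0)
    out["n_fragments"] = n_frag
    return out


def partition_contacts(
    contacts: pd.DataFrame, scheme: RegionScheme = DEFAULT_SCHEME
) -> dict[str, pd.DataFrame]:
    """Split contacts outside the domain into neighbourhood (<= margin from
    the domain border) vs distal (> margin); contacts inside the domain are
    excluded from the partition."""
    lo, hi = scheme.bxc_bounds
    starts = contacts["start"].to_numpy(float)
    ends = contacts["end"].to_numpy(float)
    inside = _overlaps(starts, ends, lo, hi)
    dist = np.where(ends <= lo, lo - ends, np.where(starts >= hi, starts - hi, 0.0))
    near = ~inside & (dist <= scheme.neighbourhood_margin)
    far = ~inside & (dist > scheme.neighbourhood_margin)
    return {
        "neighbourhood": contacts[near].reset_index(drop=True),
        "distal": contacts[far].reset_index(drop=True),
        "inside": contacts[inside].reset_index(drop=True),
    }


def peak_overlap_fraction(contacts: pd.DataFrame, peaks: pd.DataFrame) -> float:
    """Fraction of contact intervals overlapping at least one peak
    (any-overlap; chromosome-aware when both frames carry ``chrom``)."""
    if len(contacts) == 0:
        raise ValueError("contact set is empty")
    if len(peaks) == 0:
        return 0.0
    by_chrom = "chrom" in contacts.columns and "chrom" in peaks.columns
    hit = np.zeros(len(contacts), dtype=bool)
    contacts = contacts.reset_index(drop=True)
    chroms = contacts["chrom"].unique() if by_chrom else [None]
    for chrom in chroms:
        if by_chrom:
            cmask = (contacts["chrom"] == chrom).to_numpy()
            pk = peaks[peaks["chrom"] == chrom]
        else:
            cmask = np.ones(len(contacts), dtype=bool)
            pk = peaks
        if not len(pk):
            continue
        pk = pk.sort_values("start")
        ps = pk["start"].to_numpy()
        pe = pk["end"].to_numpy()
        order = np.argsort(pe)
        pe_sorted = pe[order]
        ps_by_end = ps[order]
        cs = contacts.loc[cmask, "start"].to_numpy()
        ce = contacts.loc[cmask, "end"].to_numpy()
        sub_hit = np.zeros(len(cs), dtype=bool)
        for i, (lo, hi) in enumerate(zip(cs, ce)):
            first = int(np.searchsorted(pe_sorted, lo, side="right"))
            sub_hit[i] = bool((ps_by_end[first:] < hi).any())
        hit[cmask] = sub_hit
    return float(hit.mean())
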