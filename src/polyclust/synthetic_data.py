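"""Seeded generators with planted ground truth for every analysis stage.

The localization generator emulates a 2D STORM field of view of one nucleus:
clusters with log-uniform diameters spanning the ~30 nm resolution limit up
to several hundred nm, molecule counts growing with the third power of
diameter, a geometric number of switching events (localizations) per
molecule, Gaussian localization jitter, and uniform background events.  The
4C generator emulates a viewpoint track over a 4-cutter restriction map of a
chr3R-like chromosome: power-law distance decay from the viewpoint,
enrichment at planted binding peaks, negative-binomial replicate noise, and
an optional planted depletion of a far sub-region in the test condition.

Every generator is fully deterministic under its seed, and the returned
truth records carry everything needed to score downstream recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fourc_analysis import DEFAULT_SCHEME, FragmentTrack, RegionScheme
from .storm_clusters import LocalizationTable

__all__ = [
    "LocGenParams",
    "FourCGenParams",
    "gen_localizations",
    "gen_two_channel",
    "gen_fragment_map",
    "gen_4c_tracks",
    "gen_contacts",
]


# ---------------------------------------------------------------------------
# STORM localizations
# ---------------------------------------------------------------------------

@dataclass
class LocGenParams:
    """Planted-cluster nucleus model.

    ``molecule_density`` scales molecules per cluster as
    ``density * (d / d_min)**3`` so a resolution-limit cluster holds a
    single molecule.  ``locs_per_molecule`` is the mean of the geometric
    switching-event count.  ``background`` is the number of uniform
    background localizations over the nucleus.
    """

    nucleus_diameter: float = 6000.0   # nm
    n_clusters: int = 150
    diameter_range: tuple[float, float] = (30.0, 700.0)
    molecule_density: float = 1.0
    locs_per_molecule: float = 3.0
    jitter_sigma: float = 10.0         # nm
    background: int = 300
    shared_fraction: float = 0.5       # two-channel generator only
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        for name in ("nucleus_diameter", "molecule_density", "locs_per_molecule",
                     "jitter_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.diameter_range[0] <= 0 or self.diameter_range[1] < self.diameter_range[0]:
            raise ValueError("invalid diameter_range")


def _place_clusters(params: LocGenParams, rng: np.random.Generator) -> pd.DataFrame:
    """Plant cluster centres and diameters, avoiding overlaps best-effort."""
    lo, hi = params.diameter_range
    diam = np.exp(rng.uniform(np.log(lo), np.log(hi), size=params.n_clusters))
    diam = np.sort(diam)[::-1]  # place large clusters first
    radius = params.nucleus_diameter / 2.0
    cx = np.empty(params.n_clusters)
    cy = np.empty(params.n_clusters)
    for i in range(params.n_clusters):
        for _ in range(200):
            r = radius * np.sqrt(rng.random())
            th = rng.uniform(0, 2 * np.pi)
            x, y = r * np.cos(th), r * np.sin(th)
            if i == 0:
                break
            sep = np.hypot(cx[:i] - x, cy[:i] - y)
            if (sep > 0.5 * (diam[:i] + diam[i]) + 100.0).all():
                break
        cx[i], cy[i] = x, y
    molecules = np.maximum(
        1, np.round(params.molecule_density * (diam / lo) ** 3).astype(int)
    )
    return pd.DataFrame(
        {"cluster_id": np.arange(params.n_clusters), "x": cx, "y": cy,
         "diameter": diam, "n_molecules": molecules}
    )


def _emit_cluster(
    x0: float, y0: float, diameter: float, n_molecules: int,
    params: LocGenParams, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    r = 0.5 * diameter * np.sqrt(rng.random(n_molecules))
    th = rng.uniform(0, 2 * np.pi, n_molecules)
    mx = x0 + r * np.cos(th)
    my = y0 + r * np.sin(th)
    blinks = rng.geometric(1.0 / params.locs_per_molecule, size=n_molecules)
    x = np.repeat(mx, blinks) + rng.normal(0, params.jitter_sigma, int(blinks.sum()))
    y = np.repeat(my, blinks) + rng.normal(0, params.jitter_sigma, int(blinks.sum()))
    return x, y


def _background(params: LocGenParams, rng: np.random.Generator, n: int):
    radius = params.nucleus_diameter / 2.0
    r = radius * np.sqrt(rng.random(n))
    th = rng.uniform(0, 2 * np.pi, n)
    return r * np.cos(th), r * np.sin(th)


def gen_localizations(params: LocGenParams) -> tuple[LocalizationTable, dict]:
    """One-channel nucleus with planted clusters plus uniform background."""
    rng = np.random.default_rng(params.seed)
    truth_clusters = _place_clusters(params, rng)
    xs, ys, labels = [], [], []
    loc_counts = np.zeros(len(truth_clusters), dtype=int)
    for row in truth_clusters.itertuples():
        x, y = _emit_cluster(row.x, row.y, row.diameter, row.n_molecules, params, rng)
        xs.append(x)
        ys.append(y)
        loc_counts[row.cluster_id] = len(x)
    bx, by = _background(params, rng, params.background)
    xs.append(bx)
    ys.append(by)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    table = LocalizationTable(
        x, y, np.full(len(x), "A"), np.full(len(x), "cell0")
    )
    truth_clusters = truth_clusters.assign(n_localizations=loc_counts)
    w = loc_counts.astype(float)
    order = np.argsort(truth_clusters["diameter"].to_numpy())
    cum = np.cumsum(w[order])
    wmed = float(truth_clusters["diameter"].to_numpy()[order][
        min(int(np.searchsorted(cum, 0.5 * w.sum())), len(w) - 1)
    ])
    truth = {
        "clusters": truth_clusters,
        "weighted_median_diameter": wmed,
        "n_above_30nm": int((truth_clusters["diameter"] > 30.0).sum()),
    }
    return table, truth


def gen_two_channel(params: LocGenParams) -> tuple[LocalizationTable, LocalizationTable, dict]:
    """Two channels sharing a planted fraction of clusters.

    A shared cluster emits molecules in both channels; an exclusive cluster
    emits in only one.  The truth records, per channel, the planted fraction
    of cluster localizations lying in shared clusters.
    """
    rng = np.random.default_rng(params.seed)
    clusters = _place_clusters(params, rng)
    n = len(clusters)
    shared = rng.random(n) < params.shared_fraction
    exclusive_channel = rng.integers(0, 2, size=n)  # 0 -> A, 1 -> B
    data = {"A": ([], []), "B": ([], [])}
    loc_in_shared = {"A": 0, "B": 0}
    loc_total = {"A": 0, "B": 0}
    for i, row in enumerate(clusters.itertuples()):
        targets = ("A", "B") if shared[i] else (("A",) if exclusive_channel[i] == 0 else ("B",))
        for ch in targets:
            x, y = _emit_cluster(row.x, row.y, row.diameter, row.n_molecules, params, rng)
            data[ch][0].append(x)
            data[ch][1].append(y)
            loc_total[ch] += len(x)
            if shared[i]:
                loc_in_shared[ch] += len(x)
    tables = {}
    for ch in ("A", "B"):
        bx, by = _background(params, rng, params.background)
        x = np.concatenate(data[ch][0] + [bx])
        y = np.concatenate(data[ch][1] + [by])
        tables[ch] = LocalizationTable(x, y, np.full(len(x), ch), np.full(len(x), "cell0"))
    truth = {
        "shared_mask": shared,
        "planted_fraction_a": loc_in_shared["A"] / max(loc_total["A"], 1),
        "planted_fraction_b": loc_in_shared["B"] / max(loc_total["B"], 1),
        "clusters": clusters,
    }
    return tables["A"], tables["B"], truth


# ---------------------------------------------------------------------------
# 4C tracks
# ---------------------------------------------------------------------------

@dataclass
class FourCGenParams:
    """Synthetic viewpoint-track model on a chr3R-like chromosome.

    Expected fragment counts decay as (distance + decay_offset)**(-exponent)
    from the viewpoint, are multiplied by ``peak_enrichment`` inside planted
    peaks, and by ``depletion_factor`` inside ``depleted_region`` for the
    test condition.  Replicates draw negative-binomial counts with
    dispersion ``nb_size`` (variance mu + mu^2/size).
    """

    chrom_length: int = 27_905_053     # dm3 chr3R
    mean_fragment_length: float = 256.0  # NlaIII 4-cutter
    viewpoint: tuple[int, int] = DEFAULT_SCHEME.viewpoint
    decay_exponent: float = 1.3
    decay_offset: float = 1000.0
    total_reads: float = 3e7
    nb_size: float = 30.0
    n_peaks: int = 40
    peak_width: int = 1500
    peak_enrichment: float = 3.0
    depletion_factor: float = 1.0
    depleted_region: tuple[int, int] | None = None
    # plant the contact loss around peak centres instead of one region
    deplete_around_peaks: bool = False
    peak_depletion_halfwidth: int = 2000
    conditions: tuple[str, ...] = ("S2", "PhML")
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if not 0.0 < self.depletion_factor <= 1.0:
            raise ValueError("depletion_factor must be in (0, 1]")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")


def gen_fragment_map(params: FourCGenParams) -> pd.DataFrame:
    """Contiguous restriction fragments tiling the chromosome.

    Lengths are geometric with the given mean (the spacing law of a random
    4-cutter site); the last fragment is clipped so total length is
    conserved exactly.
    """
    rng = np.random.default_rng(params.seed)
    n_guess = int(params.chrom_length / params.mean_fragment_length * 1.2) + 10
    lengths = rng.geometric(1.0 / params.mean_fragment_length, size=n_guess)
    ends = np.cumsum(lengths)
    k = int(np.searchsorted(ends, params.chrom_length))
    ends = np.concatenate([ends[:k], [params.chrom_length]])
    starts = np.concatenate([[0], ends[:-1]])
    return pd.DataFrame(
        {"chrom": DEFAULT_SCHEME.chrom, "start": starts.astype(np.int64),
         "end": ends.astype(np.int64)}
    )


def _plant_peaks(params: FourCGenParams, rng: np.random.Generator,
                 scheme: RegionScheme) -> pd.DataFrame:
    """Peaks across the domain and its flanks (sorted, in-bounds)."""
    lo, hi = scheme.bxc_bounds
    if hi > params.chrom_length:  # domain off this (short) chromosome
        lo, hi = 0, params.chrom_length
    span_lo = max(0, lo - scheme.neighbourhood_margin)
    span_hi = min(params.chrom_length, hi + scheme.neighbourhood_margin)
    n_in = params.n_peaks // 2
    centres_in = rng.uniform(lo, hi, n_in)
    centres_out = rng.uniform(span_lo, span_hi, params.n_peaks - n_in)
    centres = np.sort(np.concatenate([centres_in, centres_out]))
    half = params.peak_width // 2
    return pd.DataFrame(
        {"chrom": scheme.chrom,
         "start": np.maximum(0, centres - half).astype(np.int64),
         "end": np.minimum(params.chrom_length, centres + half).astype(np.int64)}
    )


def gen_4c_tracks(
    params: FourCGenParams, scheme: RegionScheme = DEFAULT_SCHEME
) -> tuple[FragmentTrack, dict]:
    """Fragment track with per-(condition, replicate) counts plus truth.

    Sample names are ``"{condition}_rep{r}"``.  The first condition is the
    control and is never depleted.
    """
    rng = np.random.default_rng(params.seed)
    fragments = gen_fragment_map(params)
    mids = 0.5 * (fragments["start"].to_numpy() + fragments["end"].to_numpy())
    vp_mid = 0.5 * (params.viewpoint[0] + params.viewpoint[1])
    dist = np.abs(mids - vp_mid)
    mu = np.power(dist + params.decay_offset, -params.decay_exponent)

    peaks = _plant_peaks(params, rng, scheme)
    in_peak = np.zeros(len(fragments), dtype=bool)
    for s, e in zip(peaks["start"], peaks["end"]):
        in_peak |= (fragments["start"].to_numpy() < e) & (fragments["end"].to_numpy() > s)
    mu = np.where(in_peak, mu * params.peak_enrichment, mu)
    mu *= params.total_reads / mu.sum()

    counts: dict[str, np.ndarray] = {}
    if params.deplete_around_peaks:
        lo, hi = scheme.bxc_bounds
        centres = 0.5 * (peaks["start"].to_numpy() + peaks["end"].to_numpy())
        centres = centres[(centres >= lo) & (centres < hi)]
        half = params.peak_depletion_halfwidth
        depleted = np.zeros(len(fragments), dtype=bool)
        for c in centres:
            depleted |= (mids >= c - half) & (mids < c + half)
    else:
        dep_lo, dep_hi = params.depleted_region or (0, 0)
        depleted = (mids >= dep_lo) & (mids < dep_hi)
    for ci, cond in enumerate(params.conditions):
        mu_c = mu.copy()
        if ci > 0 and params.depletion_factor < 1.0:
            mu_c = np.where(depleted, mu_c * params.depletion_factor, mu_c)
        for r in range(params.n_replicates):
            # NB as gamma-Poisson mixture with shape nb_size, mean mu_c
            lam = rng.gamma(params.nb_size, mu_c / params.nb_size)
            counts[f"{cond}_rep{r + 1}"] = rng.poisson(lam).astype(float)
    track = FragmentTrack(fragments, counts)
    truth = {
        "peaks": peaks,
        "depleted_mask": depleted,
        "depletion_factor": params.depletion_factor,
        "depleted_region": params.depleted_region,
        "expected_far_ratio_minus_one": params.depletion_factor - 1.0,
    }
    return track, truth


def gen_contacts(
    peaks: pd.DataFrame,
    n_contacts: int,
    on_peak_fraction: float,
    seed: int,
    chrom_length: int = 27_905_053,
    contact_length: int = 4000,
    scheme: RegionScheme = DEFAULT_SCHEME,
) -> tuple[pd.DataFrame, dict]:
    """Significant-contact intervals with a planted fraction centred on peaks.

    Off-peak contacts are rejection-sampled away from every peak so the
    planted overlap fraction is exact by construction.
    """
    rng = np.random.default_rng(seed)
    n_on = int(round(on_peak_fraction * n_contacts))
    rows = []
    centres = 0.5 * (peaks["start"].to_numpy(float) + peaks["end"].to_numpy(float))
    half = contact_length // 2
    chosen = rng.choice(len(peaks), size=n_on, replace=True) if n_on else []
    for idx in chosen:
        c = centres[idx] + rng.integers(-half // 2, half // 2 + 1)
        rows.append((max(0, int(c) - half), min(chrom_length, int(c) + half)))
    ps = peaks["start"].to_numpy()
    pe = peaks["end"].to_numpy()
    while len(rows) < n_contacts:
        c = int(rng.integers(half, chrom_length - half))
        lo, hi = c - half, c + half
        if not ((ps < hi) & (pe > lo)).any():
            rows.append((lo, hi))
    rng.shuffle(rows)
    contacts = pd.DataFrame(rows, columns=["start", "end"])
    contacts.insert(0, "chrom", scheme.chrom)
    truth = {"planted_fraction": n_on / n_contacts if n_contacts else 0.0}
    return contacts, truth
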