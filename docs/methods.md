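# Methods

`polyclust` implements three linked analyses around Polycomb group (PcG)
protein clustering in *Drosophila* nuclei: a lattice "strings and binders"
chromatin polymer simulator with Polyhomeotic (Ph)-like binders, the
cluster-calling and colocalization algorithm for STORM single-molecule
localization data, and the 4C-seq viewpoint contact quantification used
around the Bithorax-Complex (BX-C).  A seeded synthetic-data module plants
known structure for every stage so the pipelines can be scored against
ground truth without any external download.

## Chromatin polymer model

The chromatin fibre is a self-avoiding chain of beads on the simple cubic
lattice (unit bonds).  Conformations evolve by the pivot algorithm — a
random non-identity octahedral symmetry applied to one chain arm — with a
single-bead local displacement as fallback when the pivot is geometrically
rejected.  Local moves follow a relaxed bond-fluctuation dialect: the
displaced bead keeps its bonds within length {1, √2}.  Excluded volume is
exact site exclusion.  The chain is initialized as a straight rod and
equilibrated by `3 × n_nodes` accepted pivot moves; the pivot algorithm
decorrelates global observables within a handful of accepted moves, and the
binderless chain reproduces self-avoiding-walk scaling of the end-to-end
distance (log–log slope ≈ 0.59, checked in the tests).

Each bead is a genomic site with a fixed affinity `A ~ Uniform[0, 1]`,
modelling the spectrum of weak to strong PcG recruitment sites.  Ph
molecules are a well-mixed reservoir (mean-field: no explicit diffusion).
Association at a bead is mass action with surface multiplicity: a bead with
`k` residents whose SAM interaction surfaces are free makes `k + 1`
independent association attempts per sweep, each succeeding with
probability `k_a · A · f`, where `f` is the free-pool fraction of the
species.  Bound molecules dissociate independently with probability `k_d`.
Occupancy per bead saturates at `n_max = 15` copies (the spreading limit)
unless the variant lifts the cap.  Because exogenous wild-type Ph is the
same molecule as endogenous Ph, the wild-type variants draw both on one
shared free pool; the mutant (Ph-ML) variants keep a separate pool.

Every binder carries one bridging surface.  Bond formation is an encounter
event between beads: each pair of beads within `neighbor_radius = √3` in
3D (chain-adjacent beads excluded — bridges are long-range contacts) whose
sides both hold a free surface forms one new bond with probability
`k_join` per sweep, between uniformly chosen free-surface binders.  The
encounter rate is therefore set by polymer geometry while the surfaces cap
the bonds two clusters can share at the size of the smaller cluster (a
cluster of `n` molecules can bind at most `n` members of a partner
cluster).  Bonds break with probability `k_break`, when a partner
dissociates, or when a polymer move pulls the beads beyond the radius;
such moves cost `E_bond` per broken bond and pass through a Metropolis
filter (energies in kT; temperature is absorbed into `E_bond`).

A cluster is a maximal set of bound binders connected by co-occupancy of a
bead or by bridge bonds.  Diameters follow volume scaling,
`d = scale · n^(1/3)` with `scale = 30` length units (a single molecule
sits at the imaging resolution limit).  Snapshots are taken every
`snapshot_every` sweeps after a 50% burn-in; readouts are the cluster
count, the plain and molecule-weighted median cluster diameter (weighting
parallels how imaging weights clusters by localizations), and the contact
frequency: per unordered bead pair, the fraction of snapshots with at
least one bridge between them, averaged over pairs of beads that were
each occupied at least once.

### Model variants

* `baseline` / `wt_limited` — exogenous wild-type Ph, spreading capped.
* `wt_unlimited` — wild-type Ph, no spreading cap.
* `weak_binding_ML` — Ph-ML as a destabilized binder: `k_d` is 10× the
  endogenous value unless set explicitly.
* `capping_ML` — Ph-ML carries no bridging surface; on joining a cluster
  it occupies (caps) the surface of one resident wild-type Ph, displacing
  any bond held through it.  A cluster whose wild-type members are all
  capped accepts no further members of either type; a lone Ph-ML founds a
  closed cluster.  Departure of a capper frees the surface.

### Parameters and study conditions

The kinetic constants of the real system are unknown; the package defaults
(`k_a_endog = 0.02`, `k_d_endog = 0.002`, `k_join = 0.1`, `k_break = 0.01`,
`E_bond = 1.0`, 400 beads, 5000 sweeps, 50 iterations) are declared
reference values for exploratory runs.  The qualitative claims are judged
under a documented scaled-down protocol chosen so all five behaviors are
resolvable within a short run: 300 beads, 800 endogenous Ph,
`k_a = 0.4`, `k_d = 0.08` (so occupancy relaxes in ~12 sweeps),
`k_join = 0.1`, `k_break = 0.2`, `E_bond = 1.5`, 500 sweeps, 20
independent iterations, snapshots every 20 sweeps after burn-in.  The
endogenous load is chosen deep enough that the strongest sites are
saturated/condensed at baseline — the regime the wild-type comparison
depends on.  Mutant sweeps span 0–2× the endogenous count (the capping
collapse requires enough Ph-ML to cap all clusters); wild-type sweeps span
0–1.25× (total Ph up to ~2.2× control, matching the at-least-twofold
overexpression of the cell lines).  Trends are judged by one-sided
Mann–Whitney tests across iterations at α = 0.05.

Under these conditions the five documented behaviors hold: the
weak-binding variant's weighted median cluster size rises slightly then
plateaus; the capping variant's rises then falls sharply; capping
suppresses contact frequency far more than weak binding; unlimited
spreading grows cluster size without increasing contact frequency; limited
spreading grows cluster number and contact frequency with only modest size
change.

## STORM cluster analysis

Localizations (switching events, nm) are rasterized into square half-open
bins (origin at the minimum coordinate; boundary points go to the
higher-index bin).  The bin edge adapts to per-cell density,
`15 nm · (cohort mean / cell count)^½`, clamped to [10, 30] nm.  Any
8-connected set of non-empty bins is a cluster, including isolated single
bins.  Cluster diameter is the equivalent-square edge
`bin_size · √n_bins` (the estimator is a convention; equivalent-circle
differs by a constant ~1.13 factor, so absolute medians depend on this
choice and only planted-truth recovery is asserted).  Size distributions
weight clusters by localization count; the weighted median is the smallest
diameter reaching half the cumulative weight.

Colocalization uses fixed 15-nm bins on a grid shared by both channels,
calls clusters per channel, excludes single-bin clusters (below the ~30 nm
resolution limit), and marks a cluster colocalized when at least one of
its bins is also claimed by an above-resolution cluster of the other
channel; the reported fraction is localizations in colocalized clusters
over localizations in all multi-bin clusters.  Robustness to sampling
density is scored by a random 50/50 split of events and the two-sample KS
distance between the half-data weighted diameter distributions (values
well under 0.15 indicate saturation).

## 4C-seq quantification

Restriction-fragment read counts per (condition, replicate) are normalized
to a common total (10⁶) inside a fixed region spanning the BX-C
(chr3R:12,367,359–12,885,749, 1-based; stored 0-based half-open), smoothed
by a running mean of three fragments (truncated at the ends), and
fragments within 5 kb of the viewpoint are excluded (any-overlap rule).
Replicates are averaged, perturbed conditions are divided by the control,
and 1 is subtracted so gains are positive.  Near/far means are taken on
either side of a regulatory boundary (iab-3/iab-4 at chr3R:12,681,222 for
the Abd-B/Fab-6 viewpoints; the bxd start at chr3R:12,598,911 for Ubx)
within the BX-C bounds (chr3R:12,480,479–12,821,577), with "near" the
viewpoint's side.  The near-vs-far comparison is a two-tailed two-sample
t-test in the Welch variant — the two groups differ in size and coverage
depth, and the Welch form keeps the null calibrated — preceded by an
Anderson–Darling normality check with a Mann–Whitney fallback.  The
statistics are computed on unsmoothed ratios: the running mean correlates
neighbouring fragments and would understate the standard error; smoothing
is applied only to the exported display tracks.

The BX-C is tiled into disjoint 200-bp windows; a window is "decreased"
when the replicate-averaged test/control ratio falls below 0.5 and
"increased" above 1.5 (the stated >50% reduction rule, mirrored for
gains).  Window midpoints are scored by distance to the nearest
binding-peak centre (peak = interval midpoint; all peaks are candidates
regardless of height) and changed vs unchanged windows are compared by a
two-tailed t-test.  Externally called significant-contact intervals are
converted to overlapping restriction-fragment counts, partitioned into
BX-C neighbourhood (≤2 Mb from the domain border) vs distal (>2 Mb), and
scored for the fraction overlapping at least one peak — all with
any-overlap (BEDtools-style) semantics, strands ignored.

## Synthetic data

The localization generator plants clusters in a 6-µm nuclear disc:
log-uniform diameters over [30, 700] nm, molecules per cluster
`(d/30)³` (volume scaling), a geometric number of switching events per
molecule (mean 3, the simplest memoryless blinking model), Gaussian
localization jitter (σ = 10 nm), and 300 uniform background events.
Cluster placement rejects overlaps best-effort (100 nm margin).  The
two-channel generator emits a planted fraction of clusters in both
channels.  It does not emulate drift, chromatic offsets, or structured
background, so recovery results speak to the clustering arithmetic, not to
microscope artifacts.

The 4C generator tiles a chr3R-sized chromosome (27.9 Mb) with
geometric-length fragments (mean 256 bp, the spacing of a random 4-cutter),
decays expected counts as `(distance + 1 kb)^-1.3` from the viewpoint,
triples them inside planted peaks, scales a designated far region by the
depletion factor in the test condition, and draws negative-binomial
replicate counts (size 30).  Coverage (3×10⁷ expected reads) and
dispersion are set so the ratio bias of low-coverage fragments stays well
inside the ±0.1 recovery band and the near/far test is calibrated (its
p-value is uniform over null seeds).  Planted-contact intervals place a
chosen fraction exactly on peaks and rejection-sample the rest away from
all peaks, so the planted overlap fraction is exact.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere; 1-based genome-browser
  style inputs are converted on construction.
* Running-mean ends use truncated windows; normalization constant 10⁶ is
  arbitrary (ratios are scale-free).
* Capping ties (which resident Ph loses its surface) break uniformly at
  random; dissociation of a capper restores the surface.
* Iteration `i` of a simulation seeds its generator with `seed + i`, so
  replicates are independently reproducible.
* Degenerate inputs fail loudly: empty trajectories, empty peak or contact
  sets, channels without multi-bin clusters, and zero in-region reads all
  raise instead of returning silent zeros.

## Known limitations

* The simulator is a lattice mean-field model: no explicit diffusion,
  nucleosome structure, or epigenetic state; kinetic constants are not
  fitted to data and readouts are in model units.
* Cluster diameters (imaging and simulation) depend on the stated
  estimator conventions; absolute nanometre medians are not comparable to
  published values without matching those conventions.
* The 4C module consumes externally called significant-contact intervals;
  it does not reimplement the window-significance caller, read alignment
  or peak calling.
* Analysis is 2D for STORM (matching the thin optical section) and
  single-chromosome for 4C.
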