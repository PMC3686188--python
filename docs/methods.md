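# Methods

## Range geometry

Ranges are polygonal geometries in a planar equal-area frame with km
units; areas are km².  Input must already be projected — the package does
no spherical geometry or reprojection, so absolute areas depend on the
caller's projection while the sympatry and symmetry indexes, being ratios,
do not.  GeoJSON features sharing a `taxon_id` are unioned (separately
digitized subspecies polygons stay mergeable for lumping analyses);
invalid or zero-area geometries are rejected at load.

A grid representation provides a brute-force oracle: a cell of side *h*
with origin (0,0) is occupied iff its center lies inside the polygon.
Cell counting agrees with polygonal areas to within 2% at the documented
oracle resolution of *h* = 1/200 of the smaller geometry's bounding-box
side.  The error of the cell-center rule scales like
perimeter·*h*/(2·area), so thin slivers need proportionally finer grids;
coarse grids can over- or under-estimate (a 10×10 km square can occupy a
single 400 km² cell).

## Indexes and regressions

Node sympatry = clade-range overlap / smaller clade range; symmetry =
smaller clade range / summed clade ranges; the species-level variant
averages (and maximizes) pairwise overlap proportions over **cross-clade**
tip pairs only, because within-clade pairs do not date from the node's
divergence.  Proportions are arcsine-square-root transformed by default
(`arcsin √p`, the variance-stabilizing choice; a plain `arcsin p` variant
is available), with symmetry doubled first so both transforms span
[0, π/2].  Regressions use untransformed age in Ma.

The linear fit is OLS with t-tests on slope and intercept.  The
three-parameter logistic `y = a/(1 + b·e^(−c·Age))` is fitted by
Levenberg–Marquardt on log-parameters (enforcing a, b, c > 0):
a₀ = 1.05·max(y); c₀ from the slope of `log((a₀−y)/y)` on age where
defined; b₀ solved from the youngest point; plus 20 seeded restarts
jittering the start by factors U(0.5, 2).  r² is 1 − SSres/SStot, clipped
to [0, 1].  Constant responses (or sigmoids collapsing to c ≈ 0) return a
flagged non-converged fit rather than raising.  Model choice reports both
r² (primary criterion) and Gaussian AIC = n·ln(SSres/n) + 2(k+1).
Zero-sympatry points are never dropped or log-transformed: the cluster of
zeros at young ages *is* the allopatric signal.

Taxonomic lumping maps tips to groups; each group must be a clade, is
pruned to a single tip at the group's crown, and carries the union of the
member ranges.  Clade-level sympatry at nodes above the lump is exactly
unchanged (the union of unions is the same union); species-level mean/max
sympatry generally changes because the pair set and pair ranges change.
Groups spanning the two daughter clades of a retained node are rejected.

## Dated trees

Chronograms must be rooted, strictly bifurcating, and ultrametric within a
relative tolerance of 1e-6 of tree height (configurable; chronogram
round-off motivates the slack).  Node ages are root-to-tip heights; tips
sit at age 0.  The root node is included in the regression table by
default and excluded with `--no-include-root`; both conventions exist in
the ARC literature and the point count changes the residual df, so the
choice is surfaced rather than fixed.

## DEC model

States are the nonempty subsets of the area set (15 states for 4 areas),
ordered by size then lexicographically.  Anagenesis: dispersal adds one
area at rate d·|S| (every occupied area is an equal-weight source; no
adjacency matrix or time stratification); local extinction removes one
area at rate e, except that single-area ranges have no extinction exit —
the empty range is excluded from the state space entirely, a simplification
of full DEC's lineage-extinction bookkeeping.  Cladogenesis scenarios for
a multi-area range S are vicariance ({a}, S−{a}) and subset speciation
({a}, S) for each a ∈ S, each in both daughter orders, deduplicated (for
|S| = 2 the two vicariance choices coincide, giving 6 scenarios, not 8)
and uniformly weighted; single-area ranges duplicate identically.

The likelihood is Felsenstein pruning with dense `expm(Q·t)` per branch and
the scenario sum at each node; the root sums over a configurable prior
(uniform by default).  An exhaustive-enumeration oracle (explicit sum over
every joint assignment of node states and scenarios) verifies the pruning
implementation to 1e-10 relative on trees of ≤ 4 tips and ≤ 3 areas.
Rates are fitted by screening a log-spaced 3×3 grid of starts plus
(0.01, 0.01) and running L-BFGS-B in log-rate space from the best start,
bounded to [1e-8, 10]/Myr; directions that are likelihood-flat to 1e-9 are
snapped to the boundary and flagged (`at_bound`), e.g. when every tip
shares one area and d is unidentified.  Ancestral splits are marginal: an
outside (preorder) pass gives, for every node and scenario, the likelihood
of the whole data with that scenario at that node, normalized per node;
ties are broken by canonical state order and flagged.

**Known limitation.**  Because the empty range is excluded, very high
(d, e) pairs mimic an instantly equilibrating process without paying any
survival penalty, and on small stylized datasets this saturated ridge can
out-score the low-rate basin (on the packaged fixture the ML sits at
d ≈ 0.59, e ≈ 1.57/Myr and the per-node scenario distribution flattens
toward uniform).  The qualitative reconstruction (a Himalayan-region root)
is stable, and is much sharper at modest fixed rates; exact numerical
agreement with other DEC implementations, which condition on survival
differently, is not claimed.

## Synthetic data

The generator emulates a continental-scale radiation with known truth.

- **Trees**: pure-birth (Yule) forward simulation conditioned on the tip
  count, rate 0.4/Myr per lineage by default — with 15 tips this puts root
  ages mostly at 5–12 Ma, the scale of the accentor chronogram.
- **Root range**: a 1000×1000 km square (10⁶ km²).
- **Splits**: allopatric — line bisection through the centroid at a random
  angle (overlap exactly 0); sympatric — two copies jittered by < 5% of
  the diameter (initial sympatry ≥ 0.9); peripatric — a line-cut
  peripheral fragment holding `peripheral_fraction` (default 0.1) of the
  area.  Allopatric/peripatric daughters are pushed apart by 0.1× the
  root-range radius so young splits start with a gap.
- **Branch dynamics**: each branch draws a uniform direction and shifts
  the centroid `drift_rate·Δt` km along it (default 50 km/Myr), a
  persistent per-lineage range shift under which sister separation grows
  roughly linearly with divergence time; area receives a multiplicative
  lognormal jitter (sd 0.02·√Δt in log-area); and ranges expand by a
  buffer of `contact_rate·Δt·r₀` km (r₀ = root-range radius), the
  secondary-contact dynamic that lets separated daughters regain overlap
  at roughly `contact_rate` of the smaller range per Myr and lets small
  isolates catch up in area.
- **Study conditions** (`mode_config`): allopatric and peripatric worlds
  use contact_rate = 0.05/Myr; the sympatric world uses 0 — its daughters
  are born in contact, there is no gap for secondary contact to close, and
  overlap there is reshaped by drift alone.
- **DEC histories**: root state drawn from the prior, Gillespie simulation
  of Q along branches, cladogenetic inheritance sampled uniformly from the
  scenario table.

Every stochastic operation requires an explicit seed; there is no global
RNG state, and identical seeds give byte-identical outputs.

What the generator does **not** emulate: realistic coastline/topography
(ranges are rectangles and their buffered/cut descendants — irrelevant to
ratio-based indexes), habitat or climate dependence, species interactions,
extinction of whole lineages, and any calibrated post-split range dynamic:
`contact_rate` is an artifact construct for producing secondary-contact
patterns, not an estimate of any real-world quantity.  Passing the
mode-recovery checks therefore shows the inference chain is internally
consistent under its own generative assumptions, not that real radiations
obey them.

## The packaged fixture

A 15-tip accentor-like dataset: 13 species plus a second subspecies each
for the alpine accentor and the black-throated accentor.  Node ages are
the published point estimates (root 7.31 Ma); the one unprinted age (the
node joining the Himalayan endemic *strophiata* to the
*fulvescens*/*koslowi* pair) is interpolated at 1.30 Ma between its
neighbours (1.69 and 0.91).  Tip area codings over W/C/H/E follow the
published regional occurrence statements.  The ranges are **synthetic,
non-authoritative** stylized rectangles laid out in four 1000-km area
blocks consistent with the codings; they reproduce the qualitative ARC
pattern but carry no information about real accentor distributions, and
no absolute area or overlap computed from them should be quoted.

## Problem sizes and numerics

Default analyses run in seconds: the verification studies use 200
replicates for logistic recovery, 20 seeded replicates for DEC rate
recovery at 50 tips, 20 replicates per mode for the inference checks, and
a 4-tree × 3-area-set × 9-rate-grid sweep for the likelihood oracle —
sizes chosen so the whole battery stays interactive while keeping binomial
success bounds (≥ 17/20, ≥ 90%/200) meaningful.  Outputs are written with
6 significant digits; likelihood comparisons use relative tolerances
(1e-10 for the pruning oracle); ultrametricity and proportion-range checks
use absolute slack of ~1e-12 to absorb float round-off.
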