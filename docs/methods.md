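# Methods

## Scope and model structure

`helistroke` models the prehospital pathway of suspected large-vessel
occlusion (LVO) stroke in an intermediate-density country as four
deterministic time chains plus a stochastic fleet-capacity layer:

1. **Geography** (`region`): a planar synthetic country with municipalities,
   stroke centers and helicopter bases.
2. **Travel laws** (`travel`): closed-form ground and air travel times.
3. **Time chains** (`timechain`): component-wise onset-to-needle (IVT) and
   onset-to-groin (EVT) times for drip-and-ship and bypass, each with and
   without a helicopter.
4. **Fleet DES** (`fleet`): a discrete-event simulation of helicopter
   availability under Poisson mission streams.
5. **Statistics** (`stats`, `runner`): median/IQR tables, rank statistics,
   number-needed-to-fly, time-saved rasters, and orchestration.

All coordinates are planar kilometres with Euclidean distances. At a
country scale of a few hundred kilometres the difference to geodesic
computation is far below the minute-level resolution of the delay data, and
the planar frame removes any map-projection dependency.

## Synthetic geography

The default `RegionSpec` encodes the Danish setting: 43,000 km², 98
municipalities, 5.8 M inhabitants, 7 primary stroke centers (PSC), 3
full-time comprehensive centers (CSC), one hybrid center that is a CSC in
working hours and a PSC otherwise, and 4 helicopter bases. Municipal
territories are the Voronoi cells of uniformly seeded centroids, clipped to
a rectangular outline (aspect ratio 1.45) by mirroring the seeds across the
edges, so the cells tile the rectangle exactly.

Population is assigned by a three-bucket scheme that enforces the
intermediate-density definition by construction: the smallest-area cells
become *urban* (density > 1,500/km², 30% of the population), the next
smallest the *middle* band (300–1,500/km², 40%), the remaining large cells
*rural* (< 300/km², 30%). Within a bucket, lognormal weights (σ = 0.6)
create size heterogeneity and a bisection water-fill keeps every cell
inside its density band while the bucket hits its population share. With
30%/30% rural and urban shares, both stay strictly below the 50% thresholds
for every seed (asserted over a 100-seed panel in the tests). Infeasible
specs (too few cells for a mix) fall back to area-proportional allocation
with a logged warning; the density guarantee then no longer applies.
Islands without bridge connections are not generated — the reference
dispatch-pattern analysis excluded them because air transport is their only
option.

Full-time CSCs occupy the most populous municipalities (these are the urban
bucket by construction), the hybrid the next most populous; PSCs are chosen
greedily max-min-distance from existing hospitals among the more populous
half, and bases greedily max-min over all centroids, giving the dispersed
base layout the fleet needs. Stroke-code demand is
`population × base_rate × (1 + gradient × d/dmax)` with `d` the centroid
distance to the nearest specialized center, reproducing the empirically
observed pattern of higher per-capita stroke-code incidence far from the
CSCs. Defaults `base_rate = 0.004`/person/year and `gradient = 0.5` give a
national total of ~26,000 codes/year, of the order of the Danish
stroke-code volume; the magnitude matters only through the DES demand
calibration below.

## Travel laws and calibration

Ground time is `distance × detour_factor / base_speed × period_multiplier`;
defaults 80 km/h, detour 1.3, multipliers 1.0 except 1.1 in the afternoon
peak. These defaults put the synthetic national median scene→PSC time near
the observed ~26 min and scene→CSC near ~50 min; they are configuration
values, not fitted quantities, and can be recalibrated for other regions.
Air time is straight-line distance at 240 km/h, inclusive of take-off and
landing. The observed "CSC trips get ~8 min slower off-hours" effect is
emergent: the hybrid center drops out of nighttime CSC lookups, pushing
border addresses to a farther full-time CSC, rather than being a hard-coded
constant.

Facility lookup minimizes travel time with ties broken by lowest facility
id. The specialized-hospital-services (SHS) set — used for DES destinations,
catchment cutoffs and the helicopter-viability rule — is the three
full-time CSCs plus the hybrid around the clock, since trauma/PCI/EVT
co-locate there; only *stroke-role* lookups are period-dependent.

## Time chains

The `DelayTable` holds the eleven registry-median components listed in the
README. Two deliberate reproductions of the source arithmetic:

* the ground chain adds ambulance dispatch (1) *and* response (8) while the
  28-min call-to-air floor is response + on-scene only (8 + 20); the two
  are not harmonized;
* scene departure by air is `max(helicopter arrival, 28) + 11` — loading
  does not overlap the preparation floor (the conservative reading of the
  "minimum 28 min, then load" composition).

The helicopter-viability rule excludes addresses with ground-to-SHS time
strictly below the cutoff (default 28 min); at exactly the cutoff the
helicopter is allowed. The guideline bypass rule is strict as well: bypass
iff `ground(CSC) − ground(PSC) < 15`.

Treatment-time summaries pool all four periods and restrict to address ×
period combinations whose nearest stroke facility acts as a PSC in that
period, i.e. the PSC-catchment population for whom the strategy choice is
real. Totals are kept in real minutes; rounding happens only in reports.

## Fleet discrete-event simulation

Requests seize the nearest base (by distance from the scene) holding an
idle, in-service helicopter; ties go to the lowest base id. Availability
(default 0.90) is an independent per-dispatch Bernoulli refusal: a refused
unit stays blocked *for that request*, which keeps the event loop free of
livelock and approximates weather as memoryless. Draws are indexed by
(request, base, helicopter slot) so configurations differing only in fleet
size share their randomness; together with per-municipality keyed mission
streams (the SMALL-zone stream is an exact subset of the LARGE-zone stream
for a shared seed) this makes zone and fleet comparisons paired. Queue
discipline is FIFO; at equal timestamps releases are processed before
arrivals and arrivals before rejection timeouts, so a patient whose
helicopter frees exactly at the 60-min mark is served. *Queued* (wait >
15 min) and *rejected* (wait reaching 60 min) overlap: every rejected
patient was queued first.

Service time is either the fixed 165-min average mission, a computed
dispatch + legs + 15-min handover sum, or exponential (validation mode).
With thresholds disabled, full availability and exponential service the
engine is exactly M/M/c; the test suite checks its mean wait against the
Erlang-C closed form within 3 batch-means standard errors at 10⁵ arrivals.

Because the true per-municipality demand magnitude is not public, the sweep
calibrates a demand multiplier so the LARGE-zone request rate equals the
observed fleet tempo of 2.8 missions per helicopter-day (non-stroke
missions default to half of that, 1.4 per base-day, delivered in proportion
to the eligible population share). Under this tempo the four-base fleet is
lightly loaded and rejected fractions are in the low percent range —
substantially below the published 20–24%, which was driven by a larger
(supplement-only) demand figure; the package reports the orderings and the
capacity effect of a second helicopter, not those percentages. Default
sweep sizes are 1,000 replicates of a 28-day horizon; the shipped examples
and acceptance script use 100–200 replicates, which already give
sub-percent Monte-Carlo error on the reported means.

## Statistics

Quartiles use linear interpolation between order statistics (type 7); the
source never states its rule. Wilcoxon signed-rank drops zero differences,
uses the exact distribution for n ≤ 25 without ties and the
tie-corrected normal approximation otherwise; Spearman is the Pearson
correlation of mid-ranks. Both are delegated to scipy behind the module
surface and verified against enumeration/brute-force oracles in the tests.
Number needed to fly is `floor(1/|Δp|)` with a 10⁻⁹ epsilon so exact
reciprocals survive binary floating point; it is symmetric in its
arguments. Time-saved rasters evaluate two chains on cell centres inside
the outline; cells outside are NaN (NODATA in the ASCII-grid export).

## Reproducibility

One master seed is split into named streams (`region`, `addresses`,
`demand`, `missions`, `des`, `dispatch`) via numpy `SeedSequence` spawn
keys with a fixed name→index map; replicate and per-municipality seeds
derive from those. Every CSV carries a provenance header (package version,
config hash, master seed) and reruns are byte-identical. All spawned
integer seeds stay below 2³¹.

## What the synthetic data does and does not show

The generator reproduces the *structural* features that drive the
strategy comparison: an intermediate-density settlement mix, CSCs in the
population centres, dispersed bases, demand growing with distance from the
CSCs. It does not reproduce Denmark's actual coastline, road network,
island topology or true municipal demand, so passing tests establish the
model's internal logic and qualitative conclusions (the treatment-time
ordering, the sign of the dispatch correlation, fleet-capacity behaviour)
— not the exact published medians, which depend on the real geography.
Deterministic worked examples (112-min needle time at a 26-min PSC trip,
the 28-min air floor, NNF = 33) are exact by construction. Known further
limitations: no refuelling, crew duty cycles, rendezvous transports,
multi-patient missions, triage-scale error, or cost-effectiveness.
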