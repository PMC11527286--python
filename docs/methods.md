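# Methods

This note documents the models implemented in `clockmorph`, the parameter
choices that matter, the numerical conventions, and what the synthetic-data
generators do and do not emulate.

## Morphometry

### Input model

A brain is a set of traced neurons (rooted trees of 3-D sample points in
SWC convention, µm) plus landmarks that SWC cannot carry: the POI (where
the sLNv bundle crosses the lLNv/optic-tract projections), optionally the
main branching point (BP), the midline abscissa, and an optic-tract
polyline. Landmarks live in a JSON sidecar per brain so the SWC files stay
standard-conformant.

All distances and intersections are computed in the x–y plane. Traces are
assumed to come from maximum-intensity projections, so z carries no
measurement information; it is stored for fidelity and excluded from every
length. The frame convention is y increasing dorsally and the midline the
vertical line `x = midline_x`.

### The six measures

1. **Total projection length** — for each sLNv, the geodesic along the
   trace from the node nearest the POI to each terminal; the maximum over
   terminals is reported ("end of the dorsal termini" = the longest path).
   Any path is truncated at its first crossing of the midline, with linear
   interpolation to the exact crossing point.
2. **Length to BP** — geodesic from the node nearest the POI to the node
   nearest the BP, measured on the sLNv trace with the longest total
   cable. If no BP is annotated it is auto-detected (below).
3. **Ventral defasciculation** — modified Sholl count over 6 concentric
   circles, 25 µm apart, centered at the POI, target class sLNv.
4. **Dorsal termini branching** — 8 circles × 12.5 µm at the BP (adult) or
   6 × 12.5 µm (larval stage).
5. **lLNv defasciculation** — the ventral POI circles applied to lLNv
   traces.
6. **Optic-tract contact** — true when any post-BP sLNv segment approaches
   the lLNv traces (or the optic-tract polyline when no lLNv is traced)
   within a tolerance (default 2 µm, roughly axon-diameter scale) while
   heading ventrally (y decreasing) at the approach. "Post-BP" is the
   flood-fill of the trace from the BP node away from the POI.

### Sholl counting rules

Counts are *circle intersections*, not neurites. For each trace edge and
each circle the analytic segment–circle solution is used with a strict
transversal rule:

* a point at distance exactly r belongs to the interior (`≤ r` = inside);
* exactly one endpoint inside → 1 crossing;
* both endpoints outside but the interior of the segment dips strictly
  inside (closest-approach parameter in the open interval, minimum distance
  `< r`) → 2 crossings (a chord through the annulus counts both);
* otherwise 0. Both endpoints inside can never produce a crossing because
  a disk is convex.

These conventions make grazing contacts count 0 or 2 deterministically and
the integer counts stable under ±10⁻⁶ µm vertex perturbations, which the
test suite checks. The analytic counter is validated against an
independent dense-sampling oracle (sign changes of the distance along
2048 samples per ~2 µm edge, i.e. ~1 nm resolution) with exact integer
equality on hundreds of random bundles.

### BP auto-detection

Walking distal-ward from the node nearest the POI (on the longest sLNv
trace), the BP is the first node with at least two outgoing subtrees each
of total cable length ≥ 10 µm. The floor skips micro-spurs so the detected
point is the main ramification where the stereotypical dorsal arborization
begins; it is configurable. The start node itself is never a candidate
(re-rooting makes its soma-side neighbour look like a child). When a BP is
annotated in the landmarks it always takes precedence.

One input convention deserves a note: for larval brains the dorsal circles
are centered at the BP, as for adults, even though the two length measures
are anchored at the POI — the two anchors are deliberately distinct.

## Synthetic morphology generator

Each "genotype" is a parameter set (`MorphGenParams`). The four sLNvs
share a common spine — a waypoint polyline from the soma region through the
POI toward the dorsal brain, resampled at 2 µm arc-length steps. A single
dorsal arbor skeleton (≥ 2 branches, Poisson-distributed count,
exponential lengths, gently meandering headings) is drawn per brain at the
BP; each neuron receives a jittered copy re-anchored at its own BP
position. Per-neuron defasciculation is a *lateral Gaussian random walk*
(offsets accumulate along the path rather than being redrawn i.i.d.), so
bundles diverge smoothly the way real axons defasciculate; the walk is
frozen before `defasciculation_onset` (a fraction of the spine's arc
length). Misrouted neurons (Bernoulli per neuron) grow a deviant ventral
extension from the dorsal terminus straight to a random point on the optic
tract. lLNvs run along the optic-tract polyline with small fixed jitter.

Defaults place the POI at the origin, the BP at 160 µm geodesic from the
POI — beyond the outermost ventral circle at 150 µm, so control ventral
counts never see the arbor — and the midline at x = 110 µm. The documented
presets are:

* `CONTROL_ADULT` — sd 0.4 µm/step, onset 0.7 (spreading begins only
  around the BP, i.e. controls stay fasciculated through the ventral
  brain), BP at 160 µm. Ventral Sholl sits at the deterministic 4-neuron
  floor of 28 (each neuron crosses each of the 6 circles once going
  dorsally, plus one soma-side crossing of the innermost circle).
* `DEFASCICULATED_ADULT` — sd 1.5, onset 0.05, BP at 110 µm: the bundle
  spreads from the ventral brain and the BP proximalizes.
* `MISROUTED_ADULT` — misrouting probability 1 with ventral/optic-tract
  targets (the hyperextension phenotype).
* `CONTROL_L3` — larval scale (half-size waypoints, BP at 60 µm, no
  lLNvs).

Cohort seeding is counter-based: each brain's RNG derives from
(seed, crc32(genotype), index), so generation order is irrelevant and
cohorts are exactly reproducible.

What the generator does **not** emulate: no biophysical growth-cone
dynamics, no image noise or tracing error, no registration differences
between brains, no left/right asymmetries. Passing effect-recovery tests
therefore show that the *measurement and statistics layers* recover
programmed geometric differences — not that the generator reproduces real
biological variance structure.

## Activity model and rhythm analysis

### Generator

Counts per bin are Poisson with rate
`λ(t) = base · (1 + a·g(φ(t))) / (1 + a·ḡ)`, where `g` is a bimodal
template (two wrapped-Gaussian bumps at the morning and evening peak
phases, default 0.5 h and 11.5 h after lights-on, width 1.5 h) and `ḡ` its
cycle mean. The normalisation keeps the cycle-mean rate equal to the
baseline whatever the amplitude, decoupling rhythm strength from total
activity. During LD the phase φ is locked to the 24 h zeitgeber; at the
LD→DD transition it continues from the entrained phase but advances at
24/period_h — entrainment is modelled as phase-locking only, with no
lights-on startle or masking transients (a deliberate simplification).
Arrhythmic flies (the first ⌈fraction·n⌉ indices) are homogeneous Poisson
at the baseline. The default protocol is 5 days 12:12 LD then 8 days DD at
1-min bins; per-fly RNG streams derive from (seed, genotype, index).

### χ²-periodogram

The DD slice (days 1–7 by default) at 30-min analysis bins is folded at
every integer bin period P from ⌈14 h⌉ to ⌊34 h⌋ and scored with the
Sokolove–Bushell statistic `Qp = Σ_h n_h (M_h − M)² / s²` (population
variance in the denominator). Partial final cycles are kept through
unequal column counts n_h rather than truncating data. The significance
line is the χ² quantile at 1 − α with P − 1 degrees of freedom, α = 0.01
per period with no multiple-testing correction across periods (standard
periodogram practice). A constant series has s² = 0 and is rejected as
degenerate; a series shorter than two full cycles at the longest period is
rejected as too short.

Analytic sanity anchors, both tested: a noise-free square wave folded at
its true period gives Qp = N exactly (zero within-column variance), and Qp
agrees with an independently coded direct evaluation of the formula to
10⁻⁹ relative on random Poisson series.

### Classification

Candidate peaks are local maxima of Qp (one-sided at the window edges)
that exceed the significance line. The predominant peak maximises the
*rhythmic power* Qp − significance; the fly is rhythmic iff that power is
at least the threshold (default 10 Qp units). The commercial tool this
mirrors does not publish its exact peak-finding or threshold semantics, so
both are explicit and configurable here; "power ≥ 10 above the
significance line" is the interpretation adopted. Summaries report
`% rhythmicity` rounded half-up to 2 decimals (matching published-table
conventions, e.g. 1/32 → 3.13), and period/power mean ± SEM (n−1) over
rhythmic flies only, SEM omitted when fewer than two are rhythmic.

At the defaults the classifier's false-positive rate on 200
homogeneous-Poisson flies is ~1% and its recovery of a programmed 24 h
rhythm (amplitude 2, 8 days DD) is ~100% with period error below the
30-min bin resolution; both are recomputed by the acceptance script.

## DAM2 I/O

The 42-column DAM2 dialect is used: reading index, date, time, a status
integer, six device fields, then 32 channel counts. Readings with
status ≠ 1 are dropped (monitor-error semantics — not zeroed) and interior
gaps are zero-filled on the regular grid with a logged count. The light
schedule is supplied externally; the monitor's light-sensor column is not
trusted. Population activity profiles average within fly across the
selected LD days first, then across flies, so flies with unequal missing
bins contribute equally; SEM uses n−1 across flies.

## PER quantification

Per-cell inputs are mean ROI intensities (nuclear, optional cytoplasmic,
background). "Normalisation to background" is implemented as the ratio
nuclear/background; since ratio-vs-subtraction is a genuine convention
ambiguity, a subtraction variant is provided under an explicit option. The
nuclear/cytoplasmic ratio serves subcellular-localisation time courses.
The unit of analysis is the brain: per-cell statistics are averaged within
(brain, cluster, timepoint) before any group test, so n counts brains, not
cells — mirroring the "each dot is one brain" convention used for
morphometry.

## Statistics workflow

Every group is screened with the D'Agostino–Pearson omnibus test at
α = 0.05 (the screen's α is a package choice; the routed tests' α is the
caller's). The omnibus test is undefined below n = 8; smaller groups must
be routed explicitly via `gate_override` (the pipeline falls back to the
nonparametric branch automatically). Routing: 2 groups → t-test
(parametric) or Mann–Whitney; ≥ 3 groups → one-way ANOVA + Tukey HSD or
Kruskal–Wallis + Dunn. Dunn's post hoc uses rank-sum z statistics with tie
correction and Bonferroni family adjustment by default (Holm available) —
the family correction used by the original point-and-click workflows is
not specified, so the most conservative common default is taken.
Fisher's exact test reports the two-sided p (summing hypergeometric
probabilities ≤ the observed table's) with the conditional-MLE odds ratio.
Two-way ANOVA uses Type II sums of squares and requires ≥ 2 replicates per
cell, naming offending cells.

Monte-Carlo calibration (1000 null replicates per routed test, recomputed
by the acceptance script) puts each test's empirical type-I error within
two points of the nominal 5%.

## Problem sizes and numerical choices

The test and acceptance runs use sizes chosen to make every check sharp
but cheap on one CPU: 200 random bundles for the Sholl oracle
(100 in the acceptance script), 2048 samples/edge for the dense oracle,
200 null + 50 rhythmic flies for classifier calibration, cohorts of 15
brains per genotype for effect recovery, and 1000 replicates per
statistical calibration. Qp oracle equality is asserted at 10⁻⁹ relative;
Sholl equality is exact-integer. Geodesic symmetry holds to float
summation order (asserted at 10⁻¹² relative).

## Known limitations

* Morphometry is strictly 2-D; crossing counts cannot distinguish true
  branches from overlaps that a 3-D analysis would separate.
* The misrouting model grows a single straight deviant extension; real
  misrouted axons wander.
* LD masking, startle responses, sleep structure and temperature cycles
  are out of scope of the activity generator.
* Periodogram period resolution equals the analysis bin (30 min); no
  interpolation between candidate periods is attempted.
* The rhythmicity threshold semantics ("power ≥ 10") follow a documented
  interpretation of an unpublished commercial rule and are configurable.
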