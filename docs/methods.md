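# Methods

## Scope and state

The simulator models a tumour and its surrounding tissue as a grid of
independent voxels at fixed cell density µ (default 10⁶ cells/mm³, a
standard packing estimate for soft tissue). Each voxel carries four
populations whose sum equals the voxel capacity after every hourly step:

* tumour cells, resolved over the cell cycle (24 one-hour compartments:
  14 G1, 6 S, 3 G2, 1 M) plus a quiescent G0 pool;
* normal cells, the filler population;
* capillary cells, whose share of capacity (the vascular fraction *vf*)
  proxies the local oxygen supply;
* dead cells awaiting resorption.

There is no inter-voxel transport: no cell migration, no oxygen
diffusion between voxels, no boundary growth into empty voxels. This
keeps every voxel an independent dynamical system, which the engine
exploits by evolving all voxels as arrays and by collapsing voxels with
identical initial composition into weighted equivalence classes (exact
in expectation mode; stochastic grids always keep one row per voxel so
that draws stay independent).

## Oxygenation

Oxygen enters only through a per-voxel pO₂ probability histogram,
selected by vf class (< 1, < 3, < 4, < 5, < 8, ≥ 8%). Every
oxygen-dependent quantity is the histogram expectation of the
corresponding kernel, evaluated at bin midpoints — a deterministic
quadrature replacing per-cell pO₂ sampling. The shipped histograms are
lognormals (log-sd 0.6) truncated to [0, 100] mmHg in 1-mmHg bins with
medians (0.25, 0.6, 1.2, 2.5, 8, 45) mmHg per class. The shapes are a
**calibration input**, not measured ground truth: published
vf-conditioned oxygenation patterns are only available graphically, so
the medians of the five hypoxic classes were fitted to reproduce
published dose-response benchmarks on the virtual tumour (below), and
the top class jointly with the G2→M checkpoint probability to reproduce
published untreated phase kinetics. Users can replace the whole table
from a TSV file (`bin_id`, `pO2_mmHg`, `probability`). Imposed breathing
conditions (carbogen vs reduced oxygen) are emulated by forcing every
voxel onto the top or bottom class.

Reoxygenation is emergent, not prescribed: killing tumour cells feeds
the dead pool, resorption frees capacity, replacement raises the
capillary share, the voxel moves into a better-oxygenated vf class.

## Radiation survival

Tumour survival after a fraction of dose *d* uses the linear-quadratic
form evaluated at an oxygen-scaled effective dose m·d·OER(pO₂), with
OER(pO₂) = (m·pO₂ + k)/(pO₂ + k) ∈ [1, m]:

SF(d, pO₂) = exp(−α·m·d·OER − β·(m·d·OER)²),  m = 3, k = 3 mmHg.

Two points deserve emphasis.

First, the convention. The textbook OER construction divides the dose by
the enhancement at full oxygenation (effective dose d·OER/m, recovering
plain LQ for oxic cells); this package instead multiplies (effective
dose m·d·OER), so even anoxic cells see a three-fold dose scaling. Both
share the essential hypoxia ordering — hypoxic cells always survive
better than oxic ones — but differ by an overall ~3–9× factor in log
kill. The multiplicative grouping is the package default because it is
the only convention under which a centimetre-scale tumour (~10¹⁰ cells)
reaches 50% control probability within clinically printed total doses of
15–25 Gy, which is the dose-response regime this model family reports;
under the textbook convention the same tumour would need ≳85 Gy. The
textbook construction remains available via
`RadiobiologyParams(oer_convention="effective_dose")`.

Second, phase weighting. Cell-cycle-dependent radiosensitivity
multiplies α by a per-phase weight (defaults G0 0.85, G1 1.0, S 0.7,
G2 1.2, M 1.3 — S-phase resistance, G2/M sensitivity, mild quiescent
protection). By default the quadratic term uses the squared weight, i.e.
the whole LQ exponent is evaluated with the weighted α. Weighting α only
(`weight_beta=False`) is supported, but then the m²β OER² term dominates
the per-fraction kill, and because that term scales as 1/n at fixed
total dose it rewards protocols with fewer, larger fractions so strongly
that the repopulation differences between schedules become invisible in
the TCD50s.

Normal and capillary cells follow the unweighted, oxygen-independent
exp(−α_n d − β_n d²) with α_n = 0.15 Gy⁻¹, β_n = 0.05 Gy⁻² (α/β = 3 Gy,
the classic late-responding-tissue choice; no published value exists for
this model family, and capillary radiosensitivity is likewise not
published, so capillaries share the normal-tissue response).

## Cell cycle, checkpoints, arrest

Progression is a synchronous hourly shift through the compartments. Two
checkpoints gate it:

* **G1→S** passes with the oxygen-gated proliferation factor
  PF(pO₂) = C·exp(−exp(−B·(pO₂ − M))) (C = 1, B = 0.075 mmHg⁻¹,
  M = 26.3 mmHg; PF(M) = C/e at the inflection). Failures enter G0 and
  re-attempt hourly with the same rule — quiescence is a reversible,
  oxygen-controlled state, with no death in G0.
* **G2→M** passes with a constant probability p₂ = 0.26 outside the
  post-irradiation arrest window. Failures **wait in the last G2
  compartment** and retry; this queueing is what produces G2
  accumulation. (Routing G2 failures to quiescence instead would make a
  checkpoint block *empty* G2, inverting the post-irradiation G2 peak.)

Each fraction forces the G2→M pass probability to zero for 8 h, chosen
so the post-irradiation G2 excess peaks and then relaxes on the ~10 h
scale that published phase-kinetics time courses show.

Mitosis doubles cells into the first G1 compartment; the extra copies
displace normal cells, never below zero. Repopulation multiplies the
whole tumour pool by exp(ln2·dt/T_p) per step, T_p switching from
1200 h to 120 h two weeks after the first fraction (accelerated
repopulation); the newborn cells are injected into the first G1
compartment and also displace normal cells.

The constant p₂ < 1 and the top-class histogram median are the two
knobs calibrated against the published untreated 24-h phase benchmark
(G1/S/G2/M 68.44/20.04/8.77/2.75 → 68.58/16.44/12.22/2.75%): the S
decrease and G2 increase over 24 h require exactly the partial G2
bottleneck that p₂ ≈ 0.26 provides, and the well-oxygenated G1→S pass
rate E[PF] ≈ 0.66 sets the S-phase inflow. The calibrated model
reproduces the benchmark row to within 0.5 percentage points for S and
G2 and 2.3 points for G1.

## Schedules and dose sweeps

Fraction times are day-based with a fixed 72 h untreated lead-in:
standard (25 × 2 Gy, weekdays, 5 weeks), accelerated 6-days-a-week
(24 × 2 Gy, 4 weeks; the fraction count is an explicit override since
the regimen is also quoted with 25), continuous daily (25 × 2 Gy) and
CHART (36 × 1.5 Gy, 3/day at exactly 6 h spacing, 12 consecutive days).
TCP dose sweeps rescale every per-fraction dose by total/nominal while
keeping the timing fixed; TCD50 values depend on this choice, so it is
stated prominently. Simulations run to 24 h after the last fraction.
TCP is exp(−E[N]) in expectation mode; TCD50 interpolates the isotonic
TCP curve linearly in logit between the bracketing grid doses, after an
adaptive 0.5 Gy refinement pass around the crossing.

## Execution modes and numerical choices

* **expectation** (default): all transitions propagate means; fully
  deterministic, used for regression tests and TCP curves.
* **stochastic**: integer counts; checkpoint and survival draws use the
  exact binomial below 30 cells and a rounded, clipped normal
  approximation above; fractional growth terms draw binomially. All
  transfers are integer, so voxel capacity is conserved to the cell by
  construction; the engine raises if any hourly commit violates it. In
  expectation mode the normal population absorbs the floating-point
  residual (the filler role it plays in the replacement rule).

Replacement of resorbed dead cells splits 96.4/3.6 between normal and
capillary cells with largest-remainder rounding (ties to normal).
Tumour growth may displace normal cells but not capillary cells.
Angiogenesis (capillary doubling time 612 h) runs only in voxels whose
histogram-mean pO₂ is below 10 mmHg — the threshold is configurable
since only the qualitative trigger ("hypoxia may induce angiogenesis")
is established.

## The virtual tumour and what the tests show

The synthetic generator produces a spherical lesion (default 3 cm
diameter, 2 mm voxels, intensity 1 inside, zero background; a radial
Gaussian profile is available). It emulates only the gross geometry of
a PET-visible lesion: real tracer images carry heterogeneous uptake,
noise, partial-volume blur at the rim and non-zero background, none of
which the generator reproduces. Tests passing on the virtual tumour
therefore validate the dynamics and the analysis pipeline, not
image-specific behaviour; conclusions about real scans require real
volumes (the seeding and rendering paths accept NIfTI directly).

Benchmark problem sizes are a 3 cm tumour (≈1 800 active voxels,
1.15 × 10¹⁰ cells) for dose-response work and a 16³ grid for
conservation checks; both complete full five-week courses in seconds in
expectation mode.

On this tumour the calibrated model yields TCD50s of 18.99 (PP), 19.61
(CP), 19.70 (SP) and 18.99 Gy (DP) against published simulated-tumour
values of 17.7, 17.9, 20.1 and 23.4 Gy. Three of the four fall within
~10% of print and all four within 20%. The published *ordering* places
the 6-day-a-week accelerated schedule (DP) above the five-week standard
one; this the model cannot reproduce under any calibration explored: at
equal total dose DP delivers slightly larger fractions (more quadratic
kill) over less overall time (less repopulation) than SP, so every
mechanism in the model makes DP need less dose than SP, not 3.3 Gy
more. The discrepancy is documented rather than fitted away.

## Known limitations

* Histogram shapes, phase weights and checkpoint probabilities are
  calibration inputs; alternative choices matching the same benchmarks
  exist.
* The multiplicative OER convention makes well-oxygenated kill per Gy
  far larger than classic in-vitro survival data; it should be read as
  the convention of this model family, not as a general-purpose LQ
  implementation (the textbook convention is one switch away).
* No inter-voxel physics (diffusion, invasion, vascular remodelling
  beyond the scalar vf), no sublethal-damage repair kinetics between
  closely spaced fractions (full repair is implicit in applying the LQ
  per fraction), no normal-tissue complication modelling.
* The Poisson TCP uses the expected survivor count; for very
  heterogeneous grids the stochastic empirical mode is the reference
  (the two agree within sampling error on benchmark cases).
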