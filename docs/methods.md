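# Methods

`chromarch` implements the computational pipeline for studying how
heterochromatin-protein-mediated interactions shape 3D genome organisation
in early fly embryos: Hi-C compartment analytics, a block-copolymer nuclear
model with a heterochromatin-loss transform, and inverse inference of
bead-bead interaction energies.  This note records the models, estimators,
numerical choices and their rationale.

## Contact-map analytics

**Balancing.** `balance()` performs standard iterative correction (ICE):
raw counts are symmetrically rescaled until every unmasked row sums to the
same value (relative tolerance `tol = 1e-5`, up to 200 iterations).  Bins
with fewer than `min_nnz = 10` non-zero entries are masked.  A `none`
method passes raw counts through with the same masking; it is the
appropriate treatment for synthetic maps whose per-bin coverage is uniform
by construction, because iterative correction cannot distinguish planted
per-bin signal differences (e.g. a selective B-B contact depletion) from
technical coverage bias and partially absorbs them (we measure a planted
20 % B-weakening as 11-7 % after ICE on such maps).  On real data,
coverage bias is real and ICE remains the default.

**Distance decay.** `decay_curve()` averages the balanced signal over
log-spaced separation bins (8 per decade), normalises the curve to unit
area over its populated bins (the normalisation of contact-probability
curves is a convention; unit area makes curves from differently sized
regions comparable), and reports the least-squares slope of
log10 P versus log10 s inside the fit range, by default 100 kb to
10 Mb — compartment-scale separations above the TAD regime.

**Compartment score.** Per chromosome/arm: observed/expected (each
diagonal divided by its unmasked mean), Pearson correlation matrix,
leading eigenvector.  The eigenvector sign is arbitrary, so scores are
oriented against a user-supplied reference (gene density or active-mark
coverage on real data; the generator's ground truth in tests); positive
means the active A compartment.  Degenerate inputs (uniform maps) yield
undefined scores with a warning rather than an error.

**Saddle and compartment strength.** Bins are ranked by compartment score
into `n_quantiles = 50` quantiles (ties broken by a fixed pseudo-random
permutation — positional tie-breaking would concentrate corner quantiles
at one end of an arm and bias which separations they sample).  O/E values
are pooled per quantile pair *stratified by genomic separation*: the cell
value is the mean over separations of the per-separation mean.  Corner
strengths (`corner_fraction = 0.2` of quantiles at each extreme) are then
averaged over the strata in which **all three** corner classes (A-A, B-B,
A-B) are populated.  This two-step estimator makes the corner ratios
exactly independent of distance-decay composition: on a no-noise synthetic
map with same-type enrichment c the measured overall strength is c to
machine precision, and a planted B-B multiplier moves strength_B = BB/AB
by exactly that factor while strength_A = AA/AB stays put.  A naive pooled
mean does not have this property because different corner cells sample
different separation mixtures.  `strength_overall = sqrt(AA*BB)/AB`.
Distance filters (`min_separation` of 0, 500 kb, 3 Mb) exclude short-range
pairs to show that compartment signal is not TAD leakage.

**Insulation.** Mean balanced signal in the w x w square spanning the w
bins before and the w bins from each position (window 100 kb at 10-kb
bins, the fly TAD scale), log2-relative to the region median.  With this
convention a domain edge that starts at bin i has its unique insulation
minimum at i.  Boundaries are local minima with prominence >= 0.1 log2
units (`scipy.signal.find_peaks`).

## Synthetic data

`make_map` draws counts from Poisson(E) with
E_ij ∝ depth · max(|i-j|, 1)^gamma · m_ij, where m_ij is c for same-type
pairs (additionally x beta if both B, x1.5c for pericentromeric C-C pairs)
and 1 otherwise; optional TAD blocks multiply within-domain expectations.
A no-noise mode returns E itself for exact oracle checks.  Compartment
profiles default to *aperiodic* random block lengths (uniform in
[block/2, 2 block), seeded separately from the count noise so paired
conditions share the profile): a strictly periodic checkerboard places
same-type and cross-type pairs at disjoint separations modulo the period,
which no separation-stratified statistic can deconvolve.  Real compartment
blocks are irregular, so the aperiodic default is also the more faithful
one.  `paired_condition_maps` emulates the knockdown comparison: a shared
profile, a decay-exponent shift (milder decay) and a B-B multiplier
beta < 1, with RNG streams split from one seed.

`make_tables` plants peaks with midpoints inside the intended category
(pericentromeric block, arm-B bin, arm-A bin), so classification and
compartment assignment recover the planted counts exactly.  Widths are
log-normal (sigma = 0.5) rescaled so each category's *sample median*
equals its target exactly (default 730 bp for arm-B peaks, broader
2 kb in the pericentromere, 500 bp for arm-A); the B count is forced odd
so the median is a single order statistic.  What these generators do not
emulate: mappability and coverage bias, re-ligation artefacts, repeat
sequence content, inter-chromosomal contacts.  Passing tests therefore
demonstrate estimator correctness on the assumed statistical structure,
not robustness to every real-data artefact.

## The copolymer nuclear model

Chromosomes are bead-spring chains of types A/B (compartments, 10-kb
beads in the genome template; 40-kb in region templates) and C
(pericentromere/telomere), confined in a cylinder sized to packing
fraction 0.1 with height = 3 radius.  Potentials (kT units, sigma = one
bead diameter): harmonic bonds k = 50 kT/sigma^2 at rest length 1 sigma
with hard limits [0.7, 1.3] sigma enforced at proposal time (a finitely
extensible bond; guarantees every sampled conformation respects the
limits); soft-core repulsion U = eps_rep (1 - r^2/sigma^2) for r < sigma,
cap eps_rep = 4 kT (penetrable enough to keep single-bead Monte Carlo
mobile, hard enough that the free chain swells to the self-avoiding
exponent); square-well attraction of depth epsilon_tt' for
sigma <= r < 1.5 sigma; C beads gain -eps_surf within 1 sigma of the
apical cap (top disc).  Sampling is single-bead Metropolis displacement
MC with the step size auto-tuned during equilibration to an acceptance
of 0.3-0.6; equilibrium ensemble statistics, not dynamics, are the object
of comparison.  Identical (seed, config) gives bit-identical ensembles.

**Initial state.** Bounded runs start Rabl-like: chains anchored in a
tight apical bundle (anchor radius <= 1.5 sigma) with centromere blocks
at the cap and both arms serpentining toward the base.  This reflects
the post-mitotic configuration; the scientific question is whether the
interactions *retain* it.  The wild-type energies do; the mutant
transform (C-C and C-surface attractions scaled by c_factor, default
0.2, all other energies untouched) loses it.  Unbounded (free-space)
runs start from seeded self-avoiding growth walks.

**Calibrated wild-type energies.** AA = 0.1, BB = 0.5, CC = 1.5,
AB = AC = BC = 0.05, eps_surf_C = 3.0 kT, chosen by the shipped
`calibrate_energies` grid search so that (i) arms show measurable
compartmentalisation (strength ~ 2), and (ii) the apical chromocenter is
retained over the simulated window even when centromere/telomere blocks
are halved.  Weaker C parameters (e.g. CC = 0.6, surf = 1.0) let the
control lose the Rabl state, which erases the control/mutant contrast.

**Observables** (`rabl_statistics`): mean inter-chromosomal C-C distance,
and the same restricted to centromeric C beads (internal C runs) —
telomeric C beads sit at the chain ends inside the arm mass and never
re-cluster at desk scale, so they dilute the chromocenter signal; mean
distance between matched arm coordinates of different chromosomes (the
alignment-sensitive part of inter-arm distance — in the Rabl state arms
run in parallel so matched coordinates sit at similar heights); the
share of C-to-arm contacts among all distal contacts (the observable of
a depth-normalised contact map: when C-C contacts are lost, remaining
classes gain share), excluding chain-local pairs (separation <= 20
beads), whose contacts are topology-dominated; and intra-arm compartment
strength from the arm-averaged contact submatrix (all arms share the
A/B pattern, so averaging them gives one low-noise estimate).

At the default template, all mutant directions (C de-clustering, reduced
arm alignment, increased C-to-arm contact share) and the < 10 % bound on
the intra-arm strength change hold with four pooled seeds, verified on
disjoint seed groups.  When the C blocks are halved or doubled, the
de-clustering directions remain robust, but the alignment and
contact-share contrasts lose significance within the desk-scale window:
with 2-bead telomeres the control has little Rabl alignment left to
lose, and small pinned blocks hold the chromocenter only marginally.
These are finite-size limitations of the scaled-down template, not of
the transform.

**Desk scale.** The default genome template is 4 chromosomes x 280 beads
(two 130-bead arms, 10-bead centromere, 5-bead telomeres); runs use
~12-16 k sweeps with 3 pooled seeds per condition.  These sizes give
stable directional contrasts in a few CPU-minutes each; the full
10-kb-genome model is cluster-scale and out of desk scope.

**Phase sweep.** `sweep_energies` scales all pair attractions (or only
B-B) by each multiplier and reports the P(s) exponent and saddle strength
of the simulated map against the known bead types.  The region base
table (AA = 0.72, BB = 0.96, AB = 0.64 kT on a 90-bead chain with four
large blocks) sits in the dense-globule regime where increasing all
attractions compacts the chain, saturates contacts and *mixes*
compartments: the exponent rises and the measured strength falls
monotonically across multipliers 0.5-1.5.  At weaker bases the opposite
(segregation-dominated) branch appears and strength grows with
attraction; both regimes are physical, and the dense branch is the one
consistent with the experimental sweep behaviour this models.

## Inverse energy inference

Damped iterative Boltzmann inversion on a region chain: simulate with the
current per-pair energies, compare simulated contact probabilities with
the target, update E_ij by alpha kT log((p_sim + d)/(p_exp + d)) capped
at +-0.5 kT per round (alpha = 0.5), diagonal and bonded neighbours
excluded (bond-dominated).  Targets are scaled to probability units by
matching the first off-diagonal (bonded neighbours are in near-certain
contact).  The floor d is half the smallest non-zero target probability
but never below 8 / (samples per round): below the sampling resolution a
chance contact would otherwise ratchet a no-information pair by the full
cap.  Pairs below sampling support on both sides shrink toward zero (the
prior) instead of updating.  Iteration stops at Spearman correlation
r >= 0.9 (pairs |i-j| >= 2), or — usually earlier — when the two maps
agree within binomial sampling noise (median |z| <= 1.5 with the target
assumed sampled at the round's depth): past that point further rounds
only absorb sampling noise into the energies, which is what used to break
the fixed-point property.  The returned matrix averages the last 8-15
visited rounds (near the fixed point E fluctuates around its stationary
value) and is box-smoothed over (i, j) neighbourhoods (radius 1-2):
per-pair inversion at finite sampling is ill-conditioned and energies at
this scale vary smoothly, so local averaging is the natural
regularisation.  A constant shift of all E_ij is a near-gauge freedom
(it trades against overall compaction), so class summaries are reported
both raw and mean-centred.

Desk-scale validation: on a 60-bead chain with planted block energies
(E_AA = -0.25, E_AB = -0.1, E_BB = -0.4 kT) the pipeline reaches
Pearson(planted, inferred) ~ 0.75 over non-bonded pairs and recovers the
class-mean ordering with class means within ~0.03 kT of the planted
values.

## Known limitations

- Single-bead moves equilibrate large-scale conformation slowly;
  directional control/mutant contrasts are measured over a fixed
  simulated window from the common Rabl start, which is the biologically
  posed comparison but not an infinite-time equilibrium statement.
- The free-chain self-avoiding-walk check pools ~50-100 short
  independent runs (the global coil decorrelates slowly within a run, so
  replicas, not run length, set the effective sample size) and fits
  separations 6-40 on a 64-bead chain; the effective exponent there is
  0.57-0.60, consistent with nu ~ 0.588 at finite size.
- Interval operations are in-memory and suited to ~10^5 intervals, not
  whole-genome base-pair resolution data.
- The inverse problem's uniqueness is not addressed; reported energies
  are one regularised solution.
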