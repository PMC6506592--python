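# Methods

This note documents the models implemented in `larvorigin`, the parameter
defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical conventions that matter for reproducing results.

## Study system and scales

The package emulates a connectivity study of Caribbean spiny lobster:
postlarvae (pueruli) settling at two Florida Keys sites — Big Munson in the
lower Keys (24.617°N, 81.387°W) and Long Key in the middle Keys (24.803°N,
80.84°W) — sampled on the seventh day of each lunar month, against adult
samples from 15 locations across Florida and the wider Caribbean.  The
reference scales are 14 microsatellite loci, adult sample sizes
40, 49, 16, 39, 50, 119, 77, 49, 54, 48, 22, 36, 102, 49, 49 (total 799),
and ~2030 postlarvae over 24 months (~45 per site-month; 50 were targeted
per lunar month in the field).  All counts are configurable; tests and the
demo configuration run reduced versions (e.g. 4 populations × 30 adults)
purely to keep runs short — the statistical machinery is identical at any
scale.

## Synthetic genotypes (the truth channel)

**Drift model.** Population allele frequencies follow Balding–Nichols: for
a locus with ancestral frequency vector p and a population at differentiation
F, the population's vector is Dirichlet(p·(1−F)/F), giving E[p_i] = p_i and
Var[p_i] = F·p_i(1−p_i) — i.e. FST = F by construction.  This was chosen
because the target quantity downstream is Weir–Cockerham θ; any generative
model with the right first two moments would do, and Balding–Nichols is the
standard choice.  F = 0 copies the ancestral vector exactly.  Default
ancestral vectors are symmetric-Dirichlet draws over 8–12 alleles per locus,
a realistic allelic richness for lobster microsatellites.

**Adults** are Hardy–Weinberg draws (two independent gametes per locus).
**Postlarvae** draw a source population from a per-month mixture; with
probability `prop_parent_sampled` the true parent is a uniformly chosen
genotyped adult of that population, one allele per locus transmitted
uniformly from the parent's two and the other gamete drawn from the
population frequencies.  Otherwise both gametes are population draws and
the parent is recorded as unsampled.  Parent sex is ignored throughout: the
assignment is single-parent, so dam/sire distinction adds nothing.

**Typing noise.** Per genotype cell, independently: missing with
`missing_rate` (default 0.02), else replaced by a random Hardy–Weinberg
genotype with `error_rate` (default 0.01).  Whole-genotype replacement was
chosen (rather than per-allele dropout or stutter) because it is exactly the
error process the assignment likelihood's ε-mixture models, which keeps the
generator and the likelihood consistent.  Null alleles and allelic dropout
are *not* generated; the Brookfield-1 estimator is provided for data QC, not
exercised by the generator.

**What passing tests show.** Recovery results on these data demonstrate the
estimators are correct under their own assumptions (HWE within populations,
independent loci, unlinked neutral markers, error = ε-mixture).  Real
microsatellite data violate these in known ways — null alleles, stutter,
family structure within cohorts (siblings from one large female), linkage —
so field performance will be somewhat worse than the synthetic recovery
rates; the tests validate the machinery, not the field error budget.

## Diversity statistics

Per locus: observed heterozygosity Ho; unbiased expected heterozygosity
He = (2n/(2n−1))(1−Σp²) (Nei's small-sample correction, matching the
convention of the standard microsatellite toolchain); polymorphic
information content PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j², computed as
1 − s₂ − (s₂² − s₄); rarefied allelic richness
AR(g) = Σ_i [1 − C(N−N_i, g)/C(N, g)]; and the Brookfield-1 null-allele
estimate r = (He−Ho)/(1+He) floored at zero.

**HWE exact test.** A seeded Monte-Carlo exact test: the statistic is the
Levene conditional probability of the genotype array given the allele
counts; the null is sampled by randomly re-pairing the observed allele
multiset, and p = (1 + #{perm ≤ obs})/(n_perm + 1).  Because re-pairing
preserves allele counts, only the variable part h·ln2 − Σ ln(n_ij!) is
compared, with a 1e-12 tie tolerance on the log scale.  This is a simpler,
seed-deterministic substitute for the full Guo–Thompson chain; for the
sample sizes used here it is adequate (null p-values are uniform to a KS
test in the suite).

## Weir–Cockerham θ

Multi-allelic, multi-locus θ uses the 1984 variance components: per locus
and allele, a (among populations), b (among individuals within populations),
c (within individuals) from sample sizes n_i, allele frequencies p_i and
allele-specific heterozygote frequencies h_i; θ = Σa / Σ(a+b+c), the ratio
of sums over alleles and loci.  Loci with fewer than two populations typed,
n̄ ≤ 1 or n_c ≤ 0 are skipped and reported.  Negative θ (small-sample) is
reported as computed, never truncated.  Permutation p-values shuffle
individuals between the two groups; p = (1 + #{θ_perm ≥ θ_obs})/(n_perm+1).

## DAPC

The design matrix codes each allele as a 0/1/2 count column; missing
genotypes are mean-imputed *in this matrix only* (all other statistics
exclude missing data).  Columns are centred and scaled, reduced by PCA —
by default the smallest number of components explaining ≥90% of variance,
overridable — then k-means (10 seeded restarts) is run for k = 1..k_max and
k selected by BIC(k) = n·ln(WSS_k/n) + k·ln(n), ties broken toward the
smallest k.  Linear discriminant analysis on the retained components and
selected clusters yields up to k−1 discriminant functions.

A caution on this BIC: its fit term scales linearly with n while the
penalty scales with ln n, so the selected k is *not* invariant under
replicating the data set (doubling every individual can move the optimum to
a larger k), and for very large n it drifts toward k_max.  It is used here
because it is the de-facto standard for genotype clustering; treat the BIC
profile, not the single argmin, as the result.

## Parentage assignment

Per locus, with reference allele frequencies p (pooled over all genotyped
adults by default; per-population frequencies are available but off by
default since the pooled choice matches calibrating and scoring against the
same candidate pool):

* transition T(g_o | g_p): the parent transmits each of its two alleles
  with probability ½; the untransmitted gamete is a Hardy–Weinberg draw;
  unordered-genotype probabilities are summed over consistent assignments.
* LOD term = ln[((1−ε)T + ε·P(g_o)) / P(g_o)], P(g_o) = p² or 2pq.
  T = 0 marks a Mendelian mismatch; with ε > 0 the term is finite (ln ε),
  with ε = 0 the −∞ term is excluded from the sum and kept only as mismatch
  bookkeeping.  Alleles absent from the reference frequencies get a floor
  frequency 1/(2·N_pool + 1) (1e-3 when model frequencies without gene
  counts are supplied).

Loci missing in either genotype are skipped; the pair score carries the
LOD sum, the number of loci compared, and the mismatch count.

**Critical-LOD calibration.** Monte-Carlo, fully vectorised: each of
`n_sim_offspring` (default 10,000) trials draws a true parent from the
pooled frequencies, creates an offspring by Mendelian transmission, and
scores it against `n_candidates` (default 98) unrelated Hardy–Weinberg
genotypes, the true parent replacing one candidate with probability
`prop_sampled` (default 0.016, the estimated fraction of candidate mothers
actually sampled).  ε-mistyping is applied to every genotype.
confidence(t) = fraction of trials with best LOD ≥ t whose best candidate
is the true parent, smoothed to be non-decreasing by a cumulative maximum;
the critical LOD is the smallest point on a 0.1-step grid reaching the
confidence level (default 0.95).  If no threshold reaches it, calibration
fails loudly with the curve attached.  The curve thresholds raw best-LOD,
not a best-minus-second-best (Delta) statistic; Delta is out of scope.

**Acceptance filters.** Best LOD ≥ critical LOD, loci compared ≥ 10
("more than 10" is read as ≥10 by default; a `strict_gt` switch gives ≥11),
mismatches ≤ 2, and no exact LOD tie between distinct candidates.  Rejected
postlarvae carry a reason code (few_loci, many_mismatches, low_lod, tie).

**Weighted source statistic.** Per settlement site and source population,
percent = 100·count/N_site and weighted = 100·count/(N_adult·N_site); the
per-population total is the sum of the weighted values over sites.  The
division by adult sample size corrects for unequal sampling effort across
candidate populations; the statistic is a relative connectivity index, not
an absolute migration rate.

## Backward Lagrangian tracker

Kinematics: first-order Euler on a spherical earth, 111,320 m per degree
with a cos(lat) zonal correction (the Ichthyop-compatible convention);
default dt = 1800 s, positions recorded daily.  Velocity interpolation is
bilinear in lon/lat, linear in time, nearest-level in depth; land-masked
stencil nodes are excluded by renormalising the bilinear weights over water
nodes, and an all-land stencil beaches the particle.  Beached and exited
particles freeze at their last water position (freezing was preferred to
reflection for auditability: a frozen particle's last position is its
answer).  Positions poleward of ±89.4° are rejected.

Depth is prescribed, not advected: an ontogenetic vertical migration
schedule maps larval age to depth in contiguous half-open bands (default a
flat 5 m, the release depth; the cited field schedule is not published, so
it is configuration-driven).  In backward runs the particle is oldest at
the settlement end, so age = duration − elapsed backward time and the bands
apply in reverse along the trajectory.

Reference run geometry: square settlement polygons centred on the printed
site coordinates (64 km² at the basin scale, 25 km² at the local scale),
10,000 particles per polygon released at 5 m, monthly releases, 196 days of
dispersal with a 152-day pre-competency period.  Pre-competency gates
settlement in forward runs; backward runs record the competency window but
do not gate (the fixed 196-day horizon is the only constraint, since the
gating convention for backward runs is not documented).  Origin accounting
classifies terminal positions into named region polygons (first match in
declared order; boundary counts as inside) and averages percentages over
release polygons and events.

Euler error is first-order: in a solid-body rotation of angular velocity ω
the radius grows by ≈ T·ω²·dt/2 over integration time T, e.g. 0.3% for a
60-day gyre tracked 30 days at dt = 1800 s — within the 1% budget used in
the tests.  Halve dt to halve the drift.

## Pipeline and determinism

One root seed drives everything; each component derives a child seed by
SHA-256 hashing a fixed label, so stages re-run in isolation reproduce
their in-pipeline streams.  Stage outputs are written before the next stage
starts; the run report (JSON + text) carries SHA-256 digests of every
output and is byte-identical across reruns of the same config and seed.
The method comparison joins per-region genetic weighted totals with
dispersal origin percentages and reports Spearman rank concordance computed
by the explicit average-rank formula (ties share mean ranks).

## Known limitations

* No mutation model, linkage, or selection in the generator; no sibship or
  parent-pair analysis (parent–offspring vs full-sibling pairs are not
  distinguishable from single-parent LOD alone).
* Null alleles and stutter are estimated (Brookfield) but not simulated.
* The tracker has no turbulent diffusion, mortality, growth, or vertical
  advection; fields are analytic stand-ins, not ocean reanalyses.
* The k-means BIC caveat above: cluster counts on large datasets should be
  read from the whole profile.
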