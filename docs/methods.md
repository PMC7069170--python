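# Methods

## Model

Per-cell tract length at a microsatellite locus is modelled as normal:
N(μ₁, σ₁²) in normal cells, N(μ₂, σ₂²) in tumor cells.  A sequenced
tumor sample with purity p ∈ [0, 1] yields length observations from the
mixture density f = (1 − p)·f₁ + p·f₂.  MSI is declared when μ₂
differs significantly from μ₁.  Three estimation problems follow:
purity, the tumor component for short tracts, and the tumor component
for long tracts.

### Purity from SNV read counts

Each candidate site carries a latent joint genotype
(G_N, G_T) ∈ {AA, AB, BB}² with multinomial prior μ_G.  Alt-read
counts are binomial in both samples; the normal-sample success
probability depends on G_N through the canonical alt fractions
v(AA) = ε, v(AB) = ½, v(BB) = 1 − ε (ε = 0.01, the sequencing-noise
alt fraction), while the mixed sample uses the purity-weighted blend
q(G_N, G_T; p) = (1 − p)·v(G_N) + p·v(G_T).  An EM over the latent
genotypes maximizes the observed-data likelihood in (μ_G, μ_p); the
M-step for μ_p is an exact bounded 1-D maximization, so the
log-likelihood is non-decreasing by construction and is asserted so at
every iteration.

Two design choices deserve note.  First, the genotype support is
restricted to the germline diagonal plus the heterozygous-somatic state
(AA, AB): a het-somatic site at purity p and a hom-somatic site at
purity p/2 generate *identical* mixed-sample alt-count distributions,
so admitting (AA, BB) would make p unidentifiable; the site filter's
heterozygous-somatic contract resolves the ambiguity, and the
responsibilities still span (and sum to one over) all nine states.
Second, a per-site Gaussian purity deviation is not part of the EM
objective; the shared mean purity enters the binomial directly, and the
spread of per-site purity estimates over somatic responsibilities is
reported descriptively as λ_p⁻¹.  When the somatic responsibility mass
vanishes the purity M-step is flat; the estimate is then pinned to 0
(no tumor signal).

Site filtering keeps records with normal-sample alt fraction ≤ 0.02
(non-germline) and mixed-sample alt fraction ≥ 0.05 (detectable
signal).  At p = 0.1 the signal floor truncates the binomial left tail
and biases p̂ upward by about +0.02 — visible, documented, and well
inside the ±0.05 recovery envelope.

### Short tracts: fixed-proportion mixture MLE

Reads spanning both flanks of a tract measure its length exactly
(lengths are measured in bases; the tract is located on the read at the
detected breakpoint and extended by its period).  With (p, μ₁, σ₁)
known — μ₁, σ₁ from the paired normal sample by single-component MLE —
the tumor parameters maximize the mixture likelihood.  Maximization is
an EM with the mixing weight frozen at p and component 1 frozen at the
normal fit; only (μ₂, σ₂) update from responsibilities
(Δloglik < 1e-8 or 300 iterations).  Because the shift direction is
unknown, the fit starts from both the top and the bottom ⌈pN⌉ order
statistics and keeps the higher-likelihood solution.  σ̂₂ is floored at
0.5 bp and flagged when the component degenerates.

On discretized length data (integer lengths; the simulator's seven-bin
protocol concentrates each population on ≤ 7 support points) the
fixed-weight EM can lock the tumor component onto one or two support
points at low purity, reporting a near-zero σ̂₂ with absurd confidence.
The calling layer therefore treats a fitted tumor SD below half the
germline SD as collapsed and substitutes the normal-sample dispersion
as the reported scale (instability broadens dispersion, if anything).
The estimator itself is left untouched so that it remains the exact
mixture MLE.

### Long tracts: coverage fixed point over a window sweep

No read spans a long tract, so length is inferred from coverage.  A
window WIN-bk of length L_Win (initial 5 000 bp) is centered on the
breakpoint b; pairs are classified by mate placement — C (both mates in
the window flanks), T (both inside the tract), O (one flank, one
tract), S (one flank, one breakpoint-spanning), SO (one tract or both,
spanning) — with spanning membership taking precedence over containment
so spanning bases are counted once.  L_aln is the total number of
S-read bases inside the tract.  Then

    C   = [2·(NUM_C + NUM_T + NUM_O + NUM_S + NUM_SO)·L_read + L_aln] / L,
    L″  = [(2·NUM_T + NUM_O + NUM_SO)·L_read + L_aln] / C,

with L = L′ + L_Win, iterated from L′ = 0 until |L″ − L′| ≤ δ,
δ = L′/100 + 1.  The printed convergence criterion compares L″ to
L = L′ + L_Win, which can never come within δ of L″ once the window
exceeds the tract; successive-iterate comparison is the standard
fixed-point test and respects the same δ.  Since the pair counts do not
depend on L′, the iteration is the affine map
L ← TB·(L + W)/SB (TB = tract evidence, SB = window bases), a
contraction with limit W·TB/(SB − TB) ≈ the mean planted tract length;
convergence is geometric and typically takes < 10 iterations.

The window grows by 1 000 bp for 30 sweeps (5 000…34 000 bp), giving
≥ 30 length estimates L_set whose mean and variance define the
mixed-sample model (Shapiro–Wilk normality is reported and logged, not
fatal; regions with fewer than 20 converged sweeps are reported N/A).
The tumor component follows from the moment equations
μ₂ = (μ − (1 − p)μ₁)/p and σ₂² = (σ² − (1 − p)σ₁²)/p, with a 1 bp²
floor (flagged) when the variance difference is non-positive.  The
sweep variance reflects estimator noise, not the population σ₂; the
z-test is therefore the default state test, as the method's small-n
behaviour of a t-test would demand sample sizes the sweep cannot
provide.

### State call

z = (μ̂₂ − μ̂₁)/√(σ̂₁²/n₁ + σ̂₂²/n₂), two-sided normal p-value, MSI iff
p < α = 0.05 (strict).  For short tracts the effective counts are the
expected component occupancies of the mixed length set, n₁ = (1 − p)·N
and n₂ = p·N; for long tracts both n's equal the sweep count.  The
occupancy choice understates Var(μ̂₂) at low purity (the Fisher
information of the fixed-weight mixture near the null gives
Var(μ̂₂) ≈ σ²/(p²N), not σ²/(pN)), so the statistic is over-dispersed
at p ≈ 0.1; this raises low-purity sensitivity above nominal and is
the documented trade-off of the simple occupancy convention.

## Candidate-region discovery

The reference scan reports every maximal tandem tract with minimal
period ≤ 6 and length ≥ 12 bp (= 2k, the shortest tract the read-level
rule can confirm).  Read-level detection scans each
breakpoint-spanning read from its first base and fires at the first
offset whose k-mer (k = 6) reappears at a shift d ≤ k, with the
periodic run required to extend ≥ 2k bases — without the run-length
requirement, chance shifted 6-mer matches in flanking sequence (≈ 14 %
of 100-bp reads) dominate the vote, and because flanks are shared
across overlapping reads the false votes concentrate on specific wrong
positions.  Shifts up to k are tried because adjacent non-overlapping
k-mers are equal only when the period divides k, which would make 4 bp
and 5 bp units undetectable.  Units are canonicalized to the smallest
rotation of their primitive core (a unit folds only when it is an exact
integer repetition of a shorter core).  SB-reads are clustered by
single-linkage on mapping position (same cluster iff connected by gaps
< L_max = 50 kb); each cluster votes (modal breakpoint, modal canonical
unit), with votes spread evenly across the cluster (a head slice would
over-sample the left edge).  A region is short-class when ≥ 10 reads
fully span it, else long-class.

## Simulator

The generator plants, per locus and population, seven haplotype classes
at μ + kσ (k = −3…3) with copy counts round(coverage × probability),
probabilities 1/6/24/38/24/6/1 % (rounding half away from zero so 50×
keeps its ±3σ copies).  Each copy is sequenced to ~1× over its
neighbourhood with Poisson pair counts, fragment length N(400, 40²) bp,
and error-free reads carrying truth alignments (an optional uniform
substitution rate exists).  Mixing keeps each tumor pair with
probability p and each normal pair with 1 − p, preserving total
coverage.  Truth-aligned emission encodes each mate as
flank/tract/spanning relative to its donor tract; the tract is treated
as an insertion at the breakpoint, so tract and spanning reads anchor
at b — the idealized version of what a clipped alignment would report.

Deliberate idealizations, and hence what passing tests do *not* show
about real data: no sequencing errors or quality strings by default, no
mapping ambiguity or aligner artifacts, single-breakpoint
(uninterrupted) repeats only, strand-consistent reads, and loci spaced
65 kb apart so analysis windows and SB-read clusters of neighbours
never interact.  The two reference bases flanking each insertion are
chosen outside the unit's alphabet where possible, so the planted
length is the measurable truth; generated units use ≤ 3 distinct bases
to keep that patch always possible.

Defaults that define the study conditions: σ = max(2, 0.1·μ) for both
populations (not stated by the evaluation protocol; gives overlapping
but separable distributions at the published effect sizes); short-locus
truth draws the repeat-unit length with weights
0.35/0.30/0.15/0.10/0.05/0.05 for 1…6 bp (mono- and di-nucleotide
repeats dominate real catalogs) and shifts the tumor mean by exactly
one unit, insertion or deletion — the canonical minimal slippage event
and the hardest realistic case; long-locus truth draws means uniformly
on 500–5 000 bp for the coverage grid.  Insert size defaults to
400 ± 40 bp.  All randomness flows from one seed through
`numpy.random.SeedSequence` spawning; identical seeds give
byte-identical outputs.

## Problem sizes

The shipped experiments run at desk scale: per-locus neighbourhoods
(~36 kb for long-tract analysis, ~3 kb for short) on a virtual
reference rather than a 10 Mb contig, 30 loci for the fixed panels, and
one replicate per cell of the 10 × 3 coverage grid (the test suite and
the acceptance script each complete the grid in about half a minute).
Replicate counts appear in each test; the short-tract recall checks
average six simulations per purity, and length-recovery checks average
five replicates per planted length because the window sweep reuses the
same tract reads in every window, leaving tract-coverage counting noise
(relative SD ≈ 6–8 % at 500 bp, 100×) that only replication averages
out.

## Numerical choices and degenerate inputs

EM tolerances: purity 1e-6 on the log-likelihood (max 500 iterations),
mixture MLE 1e-8 (max 300); fixed point max 100 iterations, after which
the region is flagged non-converged and reported N/A (scored as a miss
in evaluation).  Floors: σ̂₂ ≥ 0.5 bp (short), σ² ≥ 1 bp² (sweep and
moment deconvolution), all flagged.  Consensus ties break toward the
smaller breakpoint, then the lexicographically smaller unit.  Zero
tract evidence converges to length 0 and the region is N/A.  Binomial
logs are clipped at 1e-12 from both ends.

## Evaluation

A call is correct when the canonical units match, the called breakpoint
is within ±10 bp (inclusive) of truth, and the true tumor mean lies in
the reported (μ̂₂ − 3σ̂₂, μ̂₂ + 3σ̂₂) band.  In full mode a positive is
an MSI call; duplicate positives on one locus score the closest and
count the rest as false positives, and a positive failing the band is a
false positive while its locus counts as a false negative.  Detection
mode (purity-free length recovery) treats every converged estimate as a
positive and every planted locus as a target.  State-only mode scores
the per-locus MSI flag with unresolved loci counting 0.  The five
metrics use the standard formulas, with Gain = (TP − FP)/(TP + FN);
undefined ratios are NaN except MCC, which reports 0 on a degenerate
table.  Note that with all-MSI truth (TN = 0) and misses double-counted
as FP + FN, MCC reduces to −FP/(TP + FP) = −(1 − precision): large
negative MCC alongside high precision/recall is an artifact of this
table shape, not a contradiction.

## Known limitations

The purity model ignores copy-number variation and assumes a shared
purity across sites.  The z-test occupancy convention over-rejects at
low purity (see above).  Long-tract σ₂ estimates are sweep-noise
driven and should not be read as population dispersions.  Interrupted
or compound repeats, reverse-complement unit folding, and tracts beyond
50 kb are out of scope.  On real BAMs, SB-read identification uses a
simple soft-clip heuristic (≥ 10 clipped bases) that is no substitute
for indel-aware realignment.
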