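# Methods

This note documents the models behind `mmscreen`, the defaults and why they
were chosen, the numerical choices that matter, and what the synthetic-data
tests do and do not establish about real screens.

## Barcodes and decoding (`codec`)

A barcode is an ordered word of `n_bits` binary values; bit *i* reports
whether FISH target *i* is expressed.  Bits are ordered round-major,
colour-minor (bit = `n_colors * round + colour`); the convention is
arbitrary and only has to be consistent between encoder and decoder.
Codebooks are sampled **uniformly without replacement** from the full
2^n_bits word space: the physical process of bottlenecking a saturated
combinatorial pool is modelled as uniform subsampling, which makes the
nearest-neighbour geometry analytically predictable — the probability that
a barcode has a neighbour within distance *d* follows the Poissonised
Hamming-ball bound `P(min ≤ d) ≈ 1 − exp(−(N−1)·B(d)/2^n)` with
`B(d) = Σ_{k≤d} C(n,k)`, which the test suite checks against simulation.
At N = 120,000 and n = 30 the lower quartile of nearest-neighbour distances
is 3 bits.

The per-bit FISH misread probability defaults to a symmetric 0.002.  This
is a simulation knob, not a measurement: it was chosen so that the raw
whole-barcode error (1 − 0.998³⁰ ≈ 5.8 % of readouts carry ≥ 1 flipped bit)
is large enough to exercise error correction while nearest-neighbour
decoding still lands in the > 99.8 %-correct regime a working platform
reports.  Decoding assigns the unique nearest codebook entry by Herring
distance; ties are always reported as ambiguous (never silently broken) and
count as errors in accuracy metrics.  An exact-match policy and a maximum-
radius policy are provided because real pipelines differ in how aggressive
their correction is.  The decoding benchmark short-circuits words that are
exact codebook members (they are their own unique nearest neighbour, since
entries are distinct); this is purely an optimisation and the full scan
path is unit-tested.

Each bit maps to one of two 20-nt readout sites.  Site pairs are sampled
randomly subject to a within-pair Hamming separation ≥ 10 nt, so one bit of
Herring distance costs ≥ 10 nt of sequence distance and whole barcodes at
Herring distance 3–4 differ by > 30 nt — the margin that makes per-read
barcode calling robust at 10 %/base read error.

## Guide library (`design`)

Mismatch series follow the consecutive-erosion rule: member 0 is the
perfect-match 20-nt guide; member *i* additionally mutates the base just 3'
of the previous mutation, so member *i* mismatches at exactly the *i*
5'-most positions (11 guides per target site).  The identity of each
substituted base is a genuinely open design choice; the default is the
transversion map A↔C, G↔T applied at every position, which is deterministic
and never re-creates the original base.  Control guides fail screening iff
any window of the candidate or its reverse complement matches a reference
with a run of ≥ 8 consecutive bases ("less than 8 bp of complementarity").

Bottlenecking assigns each of `n_clones` clones one guide uniformly at
random and a unique barcode, making barcodes-per-guide Binomial and, at
screen scale, Poisson: 134,000 clones over 29,738 guides gives a mean of
134000/29738 ≈ 4.51 barcodes per guide and a predicted e^(−4.51) ≈ 1.1 %
of guides lost, both verified in tests.

## Read consensus (`consensus`)

The read simulator defaults to **substitution-only noise at 10 %/base**,
uniform over the three alternative bases.  This is a deliberate
idealisation of nanopore noise — real long-read errors are indel-rich and
locally correlated — chosen so the consensus machinery can be analysed
with clean binomial arithmetic.  Optional insertion/deletion rates exist;
reads whose length changed are re-anchored per site by banded edit distance
(edlib, infix mode, band 5) before classification.

Barcode calling classifies each 20-nt read segment as the closer site
variant and requires a distance margin ≥ 2 between the two variants; any
ambiguous site, or a decode tie, leaves the read unassigned.  Variant
calling over a barcode group takes the strict per-position majority base at
each discriminating position; a tie at any position, or a base pattern
matching no variant, is a no-call, and no-calls count as errors in every
accuracy figure (conservative).  At depth 20 and 10 %/base error the
probability that a wrong base wins a majority at one position is far below
10⁻⁴, so 2-bp variant calls exceed 99.8 % accuracy; the depth-accuracy
curve uses a monotone protocol (lower depths are prefixes of the same
simulated reads) so it is non-decreasing up to Monte-Carlo noise.

## Lineage simulator (`lineage`)

Each trench holds one retained mother cell.  Between frames the cell
elongates exponentially at the current growth rate λ (doublings/h); it
divides when length reaches `L_birth + Δ` — **adder** control, with the
increment Δ drawn per cycle with CV 0.1 and the septum placed at a
Normal(0.5, σ_s) fraction truncated to (0.2, 0.8).  Threshold crossings are
solved exactly inside the frame interval, so with all noise switched off
interdivision times are analytic (τ = 1/λ at the adder fixed point where
birth length equals Δ).  Division times, mother length and kept-daughter
length are recorded alongside the frame grid so extraction can be tested
against exact values.

Defaults describe a fast-growing rod: λ = 1.5 dbl/h, width 1.0 µm, adder
increment 3.0 µm, septum SD 0.04, reporter intensity 1000 a.u., frames
every 10 min for 10 h with induction at 2 h, multiplicative measurement
noise CV 0.03 on length, width and intensity.  These are round numbers in
the physiological range of rich-medium *E. coli* and are configurable.

Knockdown strength maps from mismatch count through a logistic in
(10 − n_mm), midpoint 5, scale 1.5 — a stand-in for the graded titration a
mismatch series produces; the real strength-vs-mismatch curve is
gene-specific and not modelled.  After induction each parameter relaxes
exponentially from baseline toward `baseline + strength·(target −
baseline)` with timescale `response_h / strength`, so stronger guides act
both deeper and faster.  This first-order form is a modelling convenience:
the simulator makes no claim about real knockdown kinetics, only that
responses are graded, delayed and monotone.  Growth arrest is modelled as a
zero growth-rate target; lysis morphology is not emulated.  Width follows a
mean-reverting relaxation toward its (possibly shifting) target.

What the simulator does **not** emulate: images (and hence segmentation or
tracking errors), nucleoid signals, cell filamentation morphology beyond
length, chip-position gradients (an optional static trench bias can be
injected by the caller to exercise rescaling), crosstalk between trenches,
and death by lysis.  Tests that pass on these data therefore validate the
statistical machinery, not the upstream image pipeline of a real screen.

## Phenotyping statistics (`phenotypes`)

Six parameters per lineage: L, W and I per frame; λ per frame pair as
`(log2 L(t+Δt) − log2 L(t))/Δt` within an interdivision interval (pairs
spanning a division are dropped); τ between consecutive divisions; and
septum error `L_s = |L_daughter − L_mother/2| / L_mother` at each division.
The L_s formula is one concrete reading of "septum-placement error
normalised by cell length"; it is zero at a perfect midcell division and
dimensionless.

Baseline rescaling divides each trench's **measured** quantities (L, W, I)
by that trench's pre-induction mean.  Growth rate, interdivision time and
septum error are deliberately left on their natural scales: static optical
or geometric trench biases act multiplicatively on measured lengths and
intensities, and λ, τ, L_s are ratios or time differences already invariant
to them (dividing a per-trench τ by a baseline estimated from the one or
two pre-induction division intervals would only inject estimator noise, and
degenerates exactly when a trench has a single pre-induction interval).
Growth filtering drops trenches with no pre-induction window (< 3 frames),
no pre-induction division, or a pre-induction growth rate more than 3
robust SDs (1.4826·MAD) from the chip median; thresholds are package
choices and configurable.

Per-sgRNA aggregation takes lineage means in a window (default 5–8 h after
induction), the **median** across lineages as the point estimate, and a
bootstrap over lineages (default 1000 draws) for the SEM.  Quality requires
strictly more than 7 lineages and CV_SEM = SEM/|estimate| < 0.2 on every
defined parameter.  Volcano calls use the Mann–Whitney U test of an sgRNA's
lineage means against pooled control lineage means, Benjamini–Hochberg
correction across sgRNAs within each parameter, an effect size expressed in
SDs of the control-sgRNA estimate distribution, and an inclusive ≥ 2 SD
effect threshold at FDR 0.05.  The choice of test and of BH are package
decisions; any test producing exchangeable p-values under the null would
serve.

Spherocylinder geometry converts (L, W) to volume
`V = π(W/2)²(L − W) + (4/3)π(W/2)³`, with midcell perimeter πW and
cross-section π(W/2)².

## Dynamic-phenotype clustering (`clustering`)

The experiment is binned into 20 equal windows; per window and parameter,
an sgRNA's Z-score is its mean minus the mean of control-sgRNA window
means, over the SD of those control means.  Windows where fewer than two
control sgRNAs have data cannot define a null scale and contribute Z = 0 (no
evidence); a genuinely zero control SD raises an error.  The weak-phenotype
filter keeps an sgRNA iff max |Z| **strictly** exceeds 1 over all 6 × 20
entries; the absolute value is used so strong negative phenotypes are
retained.

Soft-DTW uses squared-Euclidean local costs summed across the six channels
and the soft-minimum recursion with smoothing γ (default 1.0; γ → 0
recovers exact DTW, verified against a brute-force path-enumeration oracle
at small lengths).  Distances feed a k-nearest-neighbour graph (default
k = 15) with local-scaling affinities `exp(−d/σ_i)`, σ_i the median
distance to the k neighbours — the median rather than the k-th distance so
that a bandwidth straddling a cluster boundary does not inflate
cross-cluster affinities.  Leiden community detection optimises
RB-configuration modularity at resolution 2 (the default used for screen-
scale data) and is seed-deterministic.  Note that resolution 2 targets
communities well below ~15 points; stability analyses of small demo
datasets should recluster at resolution 1, as the test suite does.

Jackknife stability drops 10 % of points per resample (default 50
resamples), reclusters, and matches each original cluster (restricted to
retained points) to its best-overlapping resampled cluster by Jaccard
|A∩B|/|A∪B|, also reporting recall |A∩B|/|A|; a cluster entirely removed by
the drop scores 0 in that resample.  Genes are assigned to the cluster
containing the plurality of their sgRNAs, with all tied clusters assigned
on exact ties (two for a two-way tie).

## Growth-law models (`growthlaws`)

The kinetic model is a first-order description of (p)ppGpp ("g") control by
the RelA/SpoT pair.  Ribosomes are active with probability
`f_active = k_i/(k_i + k_ref)`; the elongating pool `f_active · φ_R` splits
between a dwelling state (uncharged A-site, mean time τ_d) and a
translocating state (mean time τ_t) in ratio τ_d : τ_t.  RelA synthesises g
in proportion to the dwelling pool R_D (coefficient α); SpoT degrades it in
proportion to the translocating pool R_T (coefficient β) and contributes a
small basal synthesis flux σ.  Allocation follows a Hill response
`φ_R = φ_max/(1 + (g/g₀)^h)` and growth is
`λ = c_λ · f_active · φ_R · (1 − q_eff)/(τ_d + τ_t)`.

Under single-amino-acid limitation, ribosomes queue behind the hungry
codon; queued ribosomes are stalled with a charged A-site and are counted
in R_T (they stimulate degradation, not RelA).  Queuing is itself
suppressed by (p)ppGpp — high alarmone levels throttle initiation and
dissolve queues — via `q_eff = q · queue_g0/(queue_g0 + g)`.  This feedback
is what reconciles the two genotype phenotypes with one parameter set: in
the wild type, basal g (≈ 0.17 in model units) keeps q_eff small, the dwell
term dominates and tRNA-charging limitation raises g (classical
size–growth scaling); in the ΔrelA background g collapses to the basal
σ-supported level (≈ 0.003), queues form, R_T grows, g falls further and
the scaling inverts.  A fixed queued fraction cannot do both: with the
elongating pool normalised, whatever share RelA's sensor gains SpoT's loses,
so the masking requires a genotype-dependent realised queue, which the
g-suppression supplies mechanistically.

Default constants (k_i = 1, k_ref = 0.25, τ_d = 0.25, τ_t = 0.75, α = 1,
β = 2, σ = 0.001, φ_max = 0.55, g₀ = 0.4, h = 1, c_λ = 4, queue_g0 = 0.02)
are in arbitrary model units scaled so the unperturbed state grows at
≈ 1.5 dbl/h with φ_R ≈ 0.39.  σ is kept three orders below the RelA flux so
that initiation perturbations leave g within 1 % (the model-level statement
of initiation insensitivity: with σ → 0 and q = 0 the fixed point is the
closed form g* = (α/β)(τ_d/τ_t), independent of k_i); h = 1 keeps the
allocation response sensitive at the low g of the ΔrelA background, where a
steeper Hill response would flatten all ΔrelA scans numerically.  Genotypes:
ΔrelA sets α = 0; ΔrelAΔspoT pins g = 0 and φ_R = φ_max, collapsing every
scan to a flat line.  The steady state is solved by damped fixed-point
iteration on g (tolerance 10⁻¹⁰, cap 10⁴ iterations) and is verified against
long-time integration of the rate equations.

Perturbation axes map knockdown classes onto parameters: capture (τ_d·m),
translocation (τ_t·m), initiation (k_i/m), single-AA (mild dwell increase
τ_d·(1+0.3(m−1)) plus queuing propensity q = 0.5(1−1/m)), multi-AA (τ_d·m,
no queuing) and stalk (τ_d, τ_t · m with k_i/m).  The resulting φ_R-vs-λ
slopes reproduce the three observed growth-law variants: positive
(capture), negative (translocation), flat (initiation, stalk), plus the
ΔrelA single-AA inversion and its wild-type masking.

The size model composes three linear pieces: division on accumulating a
fixed amount of division proteins in the sector not repressed by (p)ppGpp
gives `V = V₀/(1 − φ_C)`; linearity of the repressed sector in the ribosome
sector gives `φ_C = a₁φ_R + b₁`; and a linear ribosome growth law
`φ_R = a₂λ + b₂` yields the negative hyperbola `V = A/(1 − kλ)` with
`k = a₁a₂/(1 − b₁ − a₁b₂)` — checked symbolically in tests.  Only composite
constants are identifiable, so whether the division-protein fraction is a
fixed share of the non-repressed sector or an absolute constant is left
open (fixed share assumed).

Hyperbolic fitting is **exactly** linear least squares in 1/V-space
(`1/V = u − wλ`, A = 1/u, k = w/u), with RSS reported in V-space for
comparability with the exponential alternative fitted on ln V.  The joint
fit shares u across perturbation classes with one slope per class — 3 free
parameters for two classes — and reads the flat-class trendline as the
common level V = 1/u at λ = 0.  The "shared-u" reading of the intersection
is one of two defensible interpretations; it is the only three-parameter
one, and the alternative (anchoring at a wild-type reference growth rate)
can be emulated by shifting λ before fitting.  Confidence intervals come
from a residual bootstrap (default 2000 draws): residuals in 1/V-space are
resampled within class, the model refit, and percentile intervals taken for
u, each w and each derived k; coverage at 2 % multiplicative noise is
verified to sit in the 90–99 % band.  Scaling classification regresses
log2(length) on λ and applies the ±0.2 slope thresholds, requiring ≥ 3
points and at least one point below 0.9 dbl/h — without slow points a line
through fast-growth data cannot distinguish the classes.

β–κ diagnostics tabulate each class's ribosome-law slope β = a₂ against its
volume-law constant κ = k; classes generated from one sector model with a
common intercept share κ/β = a₁/(1 − b₁ − a₁b₂) exactly.  The perimeter
correction refits the joint model with V normalised by midcell perimeter
(πW) and by cross-section (π(W/2)²), comparing scale-invariant relative RSS
(RSS/ΣV²) so a constant width reproduces the raw fit identically.

## Pipeline (`pipeline`)

Stage seeds derive from the global seed by hashing `(seed, stage name)`
(blake2s, reduced below 2³¹), so stages are independently reproducible and
rerunning a config regenerates byte-identical tables, verified through a
SHA-256 manifest.  All artifacts are tab-delimited text plus a JSON config
and manifest.  The demo configuration (6 genes × 6 mismatch levels + 12
controls, 8 trenches per guide) runs in well under a minute on one CPU;
problem sizes were chosen so examples and tests stay at desk scale while
the acceptance script runs the codebook, decoding, consensus and bottleneck
benchmarks at full published scale (120,000 barcodes, 100,000 trials,
10,000 read groups, 134,000 clones).

## Known limitations

- All validation is against the package's own generative models; agreement
  demonstrates internal consistency of the statistics, not performance on
  real microscopy or sequencing data.
- The read-error model's substitution-only default understates the
  difficulty of real nanopore consensus; the indel path is exercised but
  not benchmarked at scale.
- Knockdown response kinetics (first-order relaxation, logistic
  strength-vs-mismatch map) are stand-ins; per-gene response shapes are not
  modelled.
- The kinetic model is a minimal pool model: no explicit tRNA charging
  dynamics, no mRNA competition, and queuing enters through a single
  phenomenological suppression constant.
- Leiden at resolution 2 fragments datasets much smaller than the screen
  scale it is meant for; small-sample stability work should lower the
  resolution.
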