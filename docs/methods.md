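# Methods

## Sequence statistics

All diversity statistics operate on an rCRS-coordinate view of an aligned
FASTA. Coordinates are 1-based inclusive positions on the 16569-bp
revised Cambridge Reference Sequence throughout; if the alignment contains
the reference as a row, columns are mapped through it and columns where
the reference is gapped (insertions relative to rCRS) carry no coordinate
and are dropped when a mask is applied.

Two masks ship as presets. The `noncoding` preset is the control region,
intervals 1–576 and 16024–16569, minus positions 303–315, 522–523,
16180–16193 and 16519, which are unalignable homopolymer/indel tracts:
1092 retained positions. The `coding` preset is the positional union of
the 13 protein-coding gene intervals of the standard rCRS annotation; the
genes cover 11395 bp of sequence but overlap by 54 bp (ATP8/ATP6 46,
ATP6/COX3 1, ND4L/ND4 7), so the union holds 11341 positions. ND6 lies on
the light strand; strand is irrelevant for per-column statistics, so no
reverse complementation is needed at mask level.

**Missing data: complete deletion.** Any column containing a gap or an
ambiguous base in any sequence of the analyzed group is removed before
statistics are computed, and the per-group analyzed length *L* is logged.
This is the default of the classic desktop tools for mitochondrial
diversity tables and explains why per-group *L* falls below the nominal
mask size. Published per-group summaries are internally consistent with
*L* ≈ 1020–1090 under the 1092-position mask, which is what this scheme
produces for groups with a handful of low-coverage members.

**Statistics.** With *n* sequences and *L* analyzed columns:

* *S* counts columns with more than one nucleotide state; a triallelic
  column counts once (this is the *S* that enters Watterson's estimator).
* θ<sub>w</sub> = *S*/(*a*₁*L*), *a*₁ = Σ<sub>i=1</sub><sup>n−1</sup> 1/*i*.
* π = (total pairwise differences)/(C(*n*,2)·*L*), computed per column
  from base counts. Its SD is √(*b*₁π/*L* + *b*₂π²) — the Nei (1987)
  total-variance estimator combining sampling and stochastic
  (evolutionary) variance. Published tables built with other tools may
  print a different variance flavor; this column should be compared only
  to order of magnitude across implementations (it is reported, never
  tested against, downstream).
* Tajima's *D* = (*k* − *S*/*a*₁)/√(*e*₁*S* + *e*₂*S*(*S*−1)) with *k*
  the mean pairwise difference count and the 1989 constants *a*₁, *a*₂,
  *b*₁, *b*₂, *c*₁, *c*₂, *e*₁, *e*₂. *D* is reported as NA (NaN), never
  0, when *S* = 0 or *n* < 4.
* Significance of *D* uses the beta-distribution approximation of the
  null: *D* is assumed to range over (*D*min, *D*max) =
  ((2/*n* − 1/*a*₁)/√*e*₂, ((*n*+1)/2*n* − 1/*a*₁)/√*e*₂) following a
  scaled beta with mean 0 and variance 1; a value outside the central 95%
  of that distribution is flagged. This is deterministic and reproduces
  the starring pattern of published tables across *n* = 4…104; a
  coalescent-simulation null could be substituted but would make the
  binary call seed-dependent.

**Recomputation from published summaries.** A published row
(*n*, *S*, θ<sub>w</sub>, π) is overdetermined: *L* is recoverable from
θ<sub>w</sub> = *S*/(*a*₁*L*), and π·C(*n*,2)·*L* must be an integer
count of pairwise differences. `published.reconstruct_tajima_row` rounds
both and recomputes *D* and its significance; on the shipped reference
rows this reproduces the printed *D* to all five printed decimals for
most site groups and to < 0.05 for all, which is the package's
sequence-free consistency check against published values (the underlying
sequences are archived in a public nucleotide database and can be run
through the same pipeline via `haplodrift stats` when available locally).

**Fisher's exact test.** The region × haplogroup table (individuals not
in the two focal haplogroups are excluded first) is tested by full
enumeration of the hypergeometric support with exact binomial
coefficients; the two-sided *P* sums all tables whose probability does
not exceed the observed one (relative guard 1+1e-7 against float ties).
Any zero margin yields *P* = 1 with a degeneracy warning.

**Isotope mixing.** The marine dietary fraction is linear two-endmember
mixing between collagen δ¹³C endmembers −22.6‰ (terrestrial) and −10.9‰
(marine), clipped to [0,1], carrying a ±5% margin and the regional
reservoir correction ΔR = −98 ± 37 y for downstream calibration (the
calibration itself is out of scope).

## Drift simulation

Haploid Wright–Fisher, two haplogroups tracked as the count of the focal
one. Scenario defaults are the study conditions: 1000 generations at 25
years each (generation 0 = 25000 years ago), a common ancestral
population (CAP) of constant *N*ₑ ∈ {1000, 5000, 10000} for the first 100
generations, initial frequency 0.5, an east/west split at generation 100
with ratios 0.1…0.9, checkpoints every 100 generations from 400 to 900,
1000 trials, threshold 0.5 on the directional difference
f<sub>east</sub> − f<sub>west</sub> (inclusive ≥; ties are measure-zero
except at very small *N*ₑ).

Timeline: the generation-0 state is the initial count; drift updates run
at generations 1…99; at generation 100 each deme's initial count is drawn
Binomial(deme *N*ₑ, f<sub>CAP</sub>) from the final CAP frequency — the
split event itself contributes drift (a deterministic-rounding split is a
one-line switch away but is not the default because it would understate
founder sampling). Thereafter each deme updates as
Binomial(*N*ₑ(t), count/*N*ₑ(t−1)).

**Ne trajectories.** Post-split sizes follow per-deme four-parameter
logistic curves *N*(t) = *A* + (*K*−*A*)/(1+e^(−r(t−t₀))) — "sigmoid" is
read as logistic, the conventional monotone growth form — fitted by
`scipy.optimize.curve_fit` with deterministic initialization (floor/
ceiling at the anchor extremes, midpoint by interpolation at half range,
rate from the steepest inter-anchor slope; near-constant anchors short-
circuit to a flat curve). Curve evaluations are rounded to the nearest
integer and floored at 2. Fitted curves need not pass exactly through
the split sizes; the mismatch against cap·ratio is logged rather than
forced. When no curves are supplied, post-split sizes are constant at the
split of the CAP size — this is the configuration used in grid sweeps,
because the archaeological per-phase census numbers behind any particular
published trajectory are user input, not shipped data (a documented
one-tenth census-to-effective scaling flag is applied to whatever anchors
are given).

**Migration.** Symmetric simultaneous exchange every *g* generations
(events at t > split with (t−split) mod g = 0, applied after that
generation's drift update): each deme emits round(*m*·*N*ₑ) individuals
whose haplogroup composition is Binomial(migrants, f<sub>source</sub>)
from pre-migration frequencies, truncated to compositions actually
available in the source deme (active only at very small *N*ₑ); counts and
deme sizes update on both sides, conserving individuals. Migrant counts
are integers, so small *m*·*N*ₑ rounds to zero — the effective pressure
is *m*/*g* jointly, which is the axis along which the probability *P*
responds. The default rate grid is {0, 0.1%, 1%} with intervals
{1, 10, 100}; an alternative preset `figure3` ships with rates
{0, 0.01%, 0.1%} because published descriptions of the design differ
between the two sets; both are selectable and logged.

**Reproducibility.** One master seed; grid cells derive independent
substreams via `SeedSequence([master, cap_ne, ratio·1000, rate·10⁶,
effective_interval])`, where the interval is normalized to 1 at rate 0 so
a dead parameter cannot change results; cells are therefore reproducible
independently of sweep order. The engine is vectorized over trials
(per-generation binomial draws on count arrays).

**Exact-chain oracle.** For constant deme sizes and no migration the
model is a finite Markov chain; `exactchain` propagates the exact joint
distribution of (east, west) counts through the same timeline
(CAP matrix powers, binomial split kernel, per-deme powers, mixed over
the CAP count). The Monte-Carlo engine is tested against it at CAP 6,
3:3 split, 20 post-split generations: total-variation distance < 0.01 at
10⁵ trials.

## Synthetic data

The coalescent generator draws Kingman coalescence times (Exp with rate
C(k,2) on the 2N-scaled clock), places Poisson(θ/2 × branch length)
mutations per branch, and assigns each mutation its own uniformly chosen
unused column (infinite sites; exhausting *L* is an error instructing a
larger *L*, never silent recurrent mutation, so *S* equals the mutation
count and expectations are unambiguous: E[*S*] = θ·*a*₁, E[π·*L*] = θ).
It is constant-size and non-recombining by design — it tests the
statistics, not demography; consequently passing tests say nothing about
robustness to recombination (absent in mtDNA anyway), recurrent mutation
at hypervariable sites, or postmortem damage, all of which real
control-region data contain. msprime serves as an optional independent
cross-check of the generator in the test suite, never as the
implementation.

Haplogroup tables are per-region Bernoulli draws at configurable focal-
haplogroup frequencies. Sigmoid anchors are the truth curve evaluated at
the six cultural-phase boundary generations (16500/11300/7100/5400/4400/
3200/2400 years ago → generations 340–904 at 25 y/gen, origin 25000 ya)
times mean-one lognormal noise of a given CV.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale Monte-Carlo sizes
chosen to make the tested expectations sharp at 3-standard-error
tolerances: 200 trials/cell × 3 seeds for grid trend orderings, 1000
trials/cell for the full factorial grid, 10⁵ trials for exact-chain
agreement, 2000 coalescent replicates for estimator recovery, 10⁴ trials
for fixation/heterozygosity checks. Tolerances: π vs brute-force pairwise
counting at machine precision; Tajima's *D* vs an independent
symbol-by-symbol evaluation at 1e-9; Fisher *P* vs closed-form
hypergeometric tails at 1e-12; published *D* recomputation at ±0.05
(printed-precision rounding of the inputs propagates at about this
scale); θ<sub>w</sub>/π self-consistency at ±2% (analyzed-length
ambiguity of published rows).

## Known limitations

* The model has exactly two demes, no selection, no mutation between
  haplogroups, no age structure; it addresses haplogroup frequencies,
  not sequence evolution.
* The SD-of-π column is estimator-dependent across tools and is not a
  comparable quantity beyond order of magnitude.
* Region membership (east/west under a named boundary) is input data;
  the package does no geography.
* Radiocarbon calibration (IntCal/Marine mixing, OxCal) is out of scope;
  only the marine-fraction step is provided.
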