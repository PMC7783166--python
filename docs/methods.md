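# Methods

## Stop-context extraction

For each protein-coding gene we take the spliced CDS (longest CDS where
several transcripts are annotated; ties broken by smallest transcript
id) and build a 130-nt termination window: 30 nt of upstream CDS, the
primary stop at +1..+3, and 97 nt of genomic sequence 3′ of the stop
(+4..+100). A gene is retained only if

* its 3′ intergenic distance is **strictly** greater than 100 bp
  (distance from the base after the stop, in transcription direction,
  to the nearest boundary of any other annotated gene on either strand,
  or to the contig end);
* the CDS length is a multiple of 3 and the terminal codon is
  TAA/TGA/TAG, with no other in-frame stop after the initiator;
* the window lies entirely on the contig and contains only A/C/G/T
  (N is accepted in contigs but disqualifies a context).

Each rejected gene is counted under exactly one reason, using a fixed
precedence (short-intergenic → length → no-valid-stop → internal-stop →
truncated-context → non-ACGT). The retained *set* is independent of
rule order — each rule is a pure predicate of the gene — and a test
asserts this against independently evaluated predicates. The intergenic
rule is measured from the CDS stop end; annotated 3′-UTR ends are not
used (UTR annotation quality varies too much across genomes). Note that
with the default 100-bp intergenic threshold a retained gene can never
have a truncated downstream window (the intergenic distance lower-bounds
the distance to the contig edge), so `truncated-context` only fires
when the threshold is lowered below 97 bp.

HEGs and LEGs are the top and bottom quartiles of protein abundance
(both of size ⌊n/4⌋; ties broken by abundance then gene id); a species
enters the comparison only with ≥ 400 abundance-annotated genes.

## Enrichment statistics

**Per-site nucleotide enrichment.** For each window site and nucleotide
X, the HEG count of X is compared to (genome-wide frequency of X at
that site) × |HEG| by a 1-df Pearson chi-square on the two-cell split
[count, n − count], without continuity correction, flagged at p < 0.05
before multiple-testing correction. The two-cell (per-nucleotide) form
is used rather than a four-cell per-site test so that enrichment and
depletion are attributed to individual bases. Upstream (coding-side)
sites are reported but should be read as context only: amino-acid-level
selection confounds nucleotide-level interpretation there. A
calibration test draws HEG-sized replicate sets *with replacement* from
the gene pool and checks that ~5% of cells are flagged; with-replacement
sampling realises the independent-draws null the chi-square assumes
(a without-replacement quartile subsample is hypergeometric and tests
conservatively at ≈ 0.024 through the finite-population correction).

**ASC detection and nulls.** Codon position n (1..6) of a 3′-UTR holds
an ASC iff UTR[3(n−1)..3n) ∈ {TAA, TGA, TAG}. Two observed statistics
are kept: *any-ASC* (a stop at position n) and *first-ASC* (the first
downstream in-frame stop is at n), because the analytic null is
explicitly a first-occurrence law while the simulation null naturally
yields per-position occupancy. The pairing is fixed: geometric null ↔
first-ASC, dinucleotide simulation ↔ any-ASC; both profiles are
emitted.

* *Geometric (degrading-frequency) null*: P(first ASC at n) =
  p(1−p)^(n−1), with p the pooled fraction of the 32 in-frame UTR
  triplets that are stops, pooled across genes (a per-gene p would be
  noisy at 32 triplets/gene). The law integrates to 1 over all
  positions; truncation to +1..+6 leaves exactly (1−p)⁶ unassigned.
* *Dinucleotide-controlled null*: a first-order Markov chain fitted to
  the observed 97-nt UTRs (transition rows exactly empirical; source
  states never observed fall back to a uniform row so simulation cannot
  deadlock), initial base drawn from the empirical +4 marginal, 10,000
  simulated UTRs by default. The first base is conditioned on the +4
  marginal rather than the stop's last base because codon +1 lies
  wholly inside the UTR, so cross-boundary dinucleotides cannot affect
  ASC positions. Simulation is seeded; a fixed seed reproduces the
  expected-frequency vector bit for bit, and run seeds are recorded in
  output manifests.

**Scores and calls.** PES = (Observed − Expected)/Expected per
position; the genome score is the unweighted mean PES over +1..+6. A
genome is called ASC-enriched when some position shows a raw excess
with chi-square p < 0.05/6. Under this threshold the chance probability
of no significant position is (1 − 0.05/6)⁶ ≈ 0.951, and ≈ 0.049 of
null genomes are expected to fire; the calibration test reproduces this
at the few-hundred-genes-per-genome scale implied by the ≥ 400-gene
species-inclusion threshold (500 genes per replicate genome). At that
scale the binomial right-skew of per-position counts makes the
one-sided (excess + significance) exceedance approximately the full
per-test α, so the ≈ 4.9% family-wise rate holds; at much larger gene
counts the raw-excess clause asymptotically halves each per-test rate
and the empirical family-wise rate drifts down toward ≈ 2.5%.

**TAA scores.** TAA usage at a position is TAA/(TAA+TGA+TAG) among
stop triplets there. The TAA enrichment score compares primary-site
usage to the unweighted mean usage over downstream positions +1..+6
(positions with no stop triplet are dropped with a warning); TAA
disparity is f_HEG(TAA)/f_LEG(TAA).

## Substitution profiles from ortholog triplets

Alignments follow the soft-masking convention (CDS uppercase, 3′-UTR
lowercase; MAFFT preserves case), which is how the reader locates each
row's terminal stop. A triplet passes filtering iff every row's
ungapped CDS is a multiple of 3 with no premature stop and a
TAA/TGA/TAG terminus, all three stops are identical and occupy the same
columns, and no gap occurs within 30 columns either side of the stop.
The ancestor at a column is the outgroup base when it matches at least
one ingroup, else the site is unresolved; this is provably equivalent
to unique-minimum-change labeling on the ((in1,in2),out) topology
(tested over all 64 columns). Substitutions are counted on both ingroup
lineages and divided by 2 × (genes resolved at that site), giving a
per-lineage rate; columns where parsimony is unresolved drop out of
both numerator and denominator at that site. A column where the
outgroup matches one ingroup while the other differs counts a single
substitution (the parsimony minimum). Per-lineage normalisation is a
documented choice — the absolute scale of published per-gene profiles
is not recoverable anyway — and label-swapping the ingroups leaves the
profile unchanged.

## Comparative machinery

N̂e = π/4µ. PGLS: with V the Brownian covariance of the timetree
(V_ij = shared root-to-MRCA path length), Pagel's λ multiplies the
off-diagonal entries. For a candidate λ, β̂ is the GLS estimate under
V(λ) (Cholesky whitening), σ² is profiled out, and λ maximises the
profile log-likelihood over [0,1] via a 0.01 grid followed by bounded
refinement to 1e-6 (the likelihood can be multimodal near the bounds;
the grid stage guards against a local trap). ML is the default; REML is
available. Coefficient p-values use t with n − k df (k including the
intercept); r² is computed on the whitened model against the
whitened intercept-only fit, and the adjusted r² uses the usual
small-sample correction, hence can be negative. Likelihood-ratio
statistics against λ = 0 and λ = 1 use a 1-df chi-square (boundary
conservatism not corrected — the same convention as common comparative
packages). Non-ultrametric trees are accepted with a warning. Ne enters
regressions as given; a log transform is left to the caller (the trait
tables emitted by the simulator carry both `ne` and `log_ne`).

Exact tests: binomial tails via the exact distribution (two-sided by
summing outcomes no more probable than observed); Fisher's 2×2 by the
hypergeometric probability-mass rule (for the published 4/7-vs-1/13
table the one- and two-sided values coincide). Both are cross-checked
in tests against brute-force enumeration oracles. Wilcoxon signed-rank
and Spearman correlations are library-backed with a type-I calibration
test.

## Synthetic data: what it emulates, and what it does not

`GenomeSimConfig` builds one gene per contig: ATG-initiated CDS of
uniform non-stop codons, a stop drawn with P(TAA) =
sigmoid(logit(p₀) + β·z) where z is the standard-normal log abundance
(log-normal(0,1) ppm — only ranks matter for quartiles), and a
3′ region sampled from a first-order Markov chain (default: i.i.d.
bases at the target GC, so each downstream codon position is a stop
with probability 3/64 at GC 0.5). An optional injection overwrites the
triplet at one codon position with a uniformly drawn stop with
probability e, leaving the Markov structure elsewhere intact; the
default test setting e ≈ 0.021 corresponds to a ≈ 40% first-ASC excess
at +1 once the inflated pooled p is accounted for (closed forms in
`expected_any_asc`/`expected_pes`). A per-gene rejection plan builds
single-fault genes for each reachable filter, so the extraction report
must equal the recorded truth exactly. Genes are placed on either
strand with equal probability.

`TripletSimConfig` evolves a root CDS+UTR independently along two
ingroup lineages and one (root-to-tip) outgroup lineage under
Jukes–Cantor with per-site rate multipliers (default: a V-shaped
profile, constraint strongest at the frozen stop and relaxing over
10 codons each side — the qualitative shape real termination regions
show). Event counts per site/lineage are recorded as truth.
Jukes–Cantor keeps expectations analytic: tests validate the parsimony
pipeline against an exact enumeration over the 64 column outcomes
rather than the small-t approximation, since outgroup misresolution
inflates naive expectations even at modest divergence.

`ComparativeSimConfig` simulates a pure-birth tree (tip branches
extended by one waiting-time draw so the present falls strictly between
speciations — otherwise the covariance matrix is singular), Brownian
log(Ne), and a response a + b·log(Ne) + noise with covariance
σ²V(λ_true), plus Bernoulli cellularity.

What the generators deliberately do **not** emulate: real genome size
and architecture (multi-gene contigs, isoforms, introns beyond the
multi-part CDS representation), indels in ortholog alignments, codon-
level selection, or realistic trait error in π and µ. Passing tests
therefore demonstrate that the *machinery* is correct and calibrated
under known structure, not that any biological claim holds for a given
real genome.

## Problem sizes and numerical choices

Default validation scales: 400–5,000 genes per synthetic genome
(hundreds of retained genes matches the species-inclusion threshold the
HEG/LEG analysis assumes), 10,000 null simulants, 500–2,000 ortholog
triplets, 25–50 species × 500 replicate trees for PGLS recovery, and
1,000 replicate genomes for the family-wise calibration. Chi-square
tests are uncorrected Pearson (two-cell, 1 df) throughout; a zero
expected count with zero observed scores 0; a zero global frequency
with a nonzero observation floors the expectation at 0.5 counts with a
warning. Degenerate cases are defined explicitly: SFD is 0 when a stop
is absent from both sets (+∞ when absent only from LEGs), equal-
abundance partitions fall back to a deterministic id-ordered split with
a warning, and a dinucleotide null is refused without a seed.
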