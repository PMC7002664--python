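# Methods

This note documents the models, estimators and design choices behind
`riboscreen`, and what its synthetic screens do and do not establish about
real data.

## Read counting

Variants are identified purely by anchor matching: the amplicon layout is
`flank_5p + spacer + body + spacer + flank_3p`, where the body is the
sub-library template with its randomized (`N`) positions filled. The
compiled matcher requires every constant base exactly and captures the
randomized positions with `[ACGT]` classes; the concatenated captures (5'→3'
across disjoint N-runs) form the motif key. Rationale for exact matching: a
single substitution in a randomized position would silently convert one
variant into another, so tolerating mismatches in constant regions while
motif positions stay error-prone buys little accuracy; reads with damaged
anchors are simply dropped (unassigned) and counted in the per-sample match
statistics. Matching is attempted anywhere in the read (amplicons can start
mid-read), leftmost hit first, on the sense strand and then the reverse
complement (`strand_mode="both"`, the default, since amplicon library prep
is not strand-preserving). Base qualities are ignored; reads shorter than
the shortest amplicon are gated out.

Sub-library disambiguation is resolved at compile time: two templates whose
wildcard amplicons are position-wise compatible (equal length, every
position equal or `N`) could both explain some concrete read, and such a
design is rejected with `AmbiguityError`. With `allow_ambiguous=True` the
matcher instead tests all sub-libraries per read and books multi-hits into
an `ambiguous` bin. The spike-in sequence is checked against every
sub-library pattern for the same reason. Per sample the invariant
`assigned + unassigned + ambiguous = total` is asserted.

The bundled designs (`builtin_design`) carry the real primer binding sites
(`CATTGCAGCGTATTCCCAGTCC` / `GCCTGGTGAAATTGTTATCCGCT`), `(CAAA)₃` spacers
and the randomized-position layouts and complexities of the published
screens (4⁷ = 16,384; 4⁶ = 4,096; nine Twister sub-libraries totalling
18,432); their fixed ribozyme/aptamer bodies are synthetic placeholders.

## Normalization and differential abundance

**Spike-in size factors.** The spike-in control is present at constant
input in every sample, so its counts define the per-sample scale:
`factor_s = spike_s / geomean(spike)`. Counts are divided by these factors;
the geometric-mean centring makes the factors multiplicatively neutral.
Library-size (CPM) factors are available as a fallback for spike-free data
(`use_spike=False`). Spike normalization — rather than total-count
normalization — is essential here because an effective ligand shifts the
abundance of many variants at once.

**Dispersion.** Counts are modelled NB with variance μ + φμ². The common
dispersion is a pooled method-of-moments estimate over all variants and
replicate groups, φ = max(0, Σ(s² − m) / Σ m²) (within-group sample means
and variances), which is accurate and essentially unbiased at the scale of
thousands of variants. Per-variant estimates are shrunk toward the common
value with weight w = n_prior / (n_prior + df), df the variant's
within-group degrees of freedom; n_prior defaults to 10 (a weakly
informative prior comparable to common empirical-Bayes practice).

**Exact test.** For each variant and dose, the treated group sum is
compared with the control group sum conditionally on their total. Because a
sum of n iid NB(μ, φ) variables is NB(nμ, φ/n), the conditional law of the
group-A sum given the total depends only on (n_A, n_B, φ, total) — a
negative hypergeometric — and the two-sided p-value is the total
conditional probability of all splits at most as probable as the observed
one (the Poisson/binomial conditional test is the φ→0 limit; an observed
modal split gives p = 1). Normalized counts are rounded to integers before
summing; this quantile-free simplification is the point where p-values can
deviate numerically from pipelines that pseudo-equalize library sizes
instead. Computation is in log space (gammaln) with a 1e−9 log-space tie
tolerance so that theoretically tied splits (e.g. mirror splits at equal
group sizes) are never dropped by floating-point rounding.

**Fold changes and FDR.** log₂FC is computed on group-mean spike-normalized
CPM with a 0.5 pseudocount (bounds fold changes for zero counts, standard
prior-count practice). Benjamini–Hochberg adjustment is applied across
variants within each dose contrast separately — each contrast is its own
multiple-testing family, as each volcano panel is read on its own. The
whole table is deterministic; no RNG enters the analysis modules.

## Hit selection

Defaults follow the stricter of the published screens' criteria:
|log₂FC| ≥ 0.6 and FDR ≤ 0.01 at the selection dose (default: highest),
with direction `on` (induced), `off` (repressed) or `both`.
*Dose-dependency* is formalized as: the sign of log₂FC is identical at all
doses where |log₂FC| exceeds the tolerance, and |log₂FC| never drops by
more than the tolerance (0.1 log₂ units by default) between consecutive
doses. This is a deliberately literal, reproducible version of a rule the
original screens applied qualitatively; note that for responses that
saturate below the top dose it behaves like a coin flip on noise of
comparable size (see Limitations). The *pi-score*, log₂FC · (−log₁₀ p),
is offered as an alternative ranking that demotes low-abundance variants
whose fold changes are large but unsupported. Hits with motif AT-fraction
> 0.7 are flagged (not removed) because AT-rich communication modules tend
to disrupt the intended secondary structure. `select_hits_union` merges
per-dose hit lists and drops duplicate variants keeping the best rank,
mirroring how published hit lists were assembled; a negative list (criteria
failures) supports false-positive spot checks.

## Sequence-space characterization

Distances between equal-length motifs are normalized Hamming distances
(mismatches / length). Clustering is average-linkage (UPGMA) on these
distances — the linkage is our choice; the original tooling did not name
one — with the tree cut so that clusters share **strictly more than** the
identity threshold (default 0.75): cut height = (1 − identity) − ε. Each
cluster is summarized as a PWM (per-position base probabilities, optional
pseudocount, default 0 so logos describe the observed hits) with
information content IC_j = 2 + Σ_b p_jb log₂ p_jb bits ∈ [0, 2].

The single-mutation network connects significant motifs at Hamming
distance exactly 1 (built per sub-library; O(n·L) via (L−1)-mer wildcard
indexing). Communities are Girvan–Newman: iteratively remove the
maximum-edge-betweenness edge (ties broken lexicographically for
determinism) and return the partition with maximal modularity along the
removal path, seeded with the connected components. Edgeless graphs
decompose into singletons. Per-community mean log₂FC summarizes
within-family effect direction.

## Synthetic screen generator

The generator encodes the ligand–cleavage mechanism as a Hill response on
the log scale: `log₂ r(d) = log₂ r₀ + Δ · dʰ/(dʰ + EC50ʰ)`, with r₀ the
basal relative expression (library abundance and constitutive ribozyme
activity folded into one number), Δ the maximal log₂ response (positive =
ON-switch, negative = OFF-switch, 0 = null variant), and h = 1 (1:1
aptamer–ligand binding). Defaults mirror the screens' layout: doses
(0, 30, 100, 300) µM × 8 replicates, 154 bp reads.

Chosen-once generator parameters, with rationale:

- **basal abundance spread**: log-normal, sd 0.75 log₂ units — a
  synthesized, QC'd oligo library is fairly uniform (≈4-fold 10–90%
  range);
- **EC50**: log-uniform in [30, 100] µM — published cellular riboswitch
  dose–responses are graded across a 30–300 µM series and approach
  saturation at the top dose (75–91% of Δ realized here);
- **per-sample depth factor**: log-normal, sd 0.3 log₂ units, shared by
  all variants *and* the spike-in — this is the
  transfection-efficiency/depth variation that spike normalization exists
  to remove; the spike-in's residual noise is Poisson (a high-abundance
  constant-input control), its expected share 2% of reads;
- **counting noise**: NB with φ = 0.05 (var = μ + φμ²) per variant;
- **sequencing errors**: substitution-only at rate e (default 0), applied
  per base after strand choice; no indels, since anchor-based counting
  makes the substitution channel the relevant one;
- **GC bias**: optional 2^(−β·GC(motif)) abundance multiplier (β = 0 by
  default) for exercising the QC detector.

Randomness derives from a single seed via per-sample `SeedSequence`
substreams, so any one sample can be regenerated stably. At e = 0 the
emitted FASTQ re-counts to the simulated matrix exactly (tested); at e > 0
the assigned fraction follows (1−e)^(number of fixed positions).

**What the generator does not emulate:** PCR amplification bias and
duplicate structure, quality-score degradation, indels, adapter read-through,
cross-sample index hopping, and any correlation between a motif's sequence
and its true switching behavior. Passing recovery tests therefore
demonstrates the statistical machinery under the stated noise model, not
robustness to every artifact of real sequencing data.

## Problem sizes used in tests

The test suite and the acceptance script run the full analysis at the
screens' replicate/dose layout with 4,096-variant libraries and 2×10⁵
reads per sample at the counts level, and exercise the FASTQ path on
smaller libraries (64–1,024 variants, 10³–10⁵ reads); these sizes give
per-variant counts in the same regime as the real screens (tens of counts
per sample) while keeping the whole suite fast.

## Known limitations

- The exact test conditions on rounded spike-normalized totals; with very
  small size factors the rounding can cost a fraction of a count.
- Recovery of 2-fold (|Δ| = 1) switches at sub-average abundance is
  marginal at 2×10⁵ reads/sample under FDR ≤ 0.01 — the BH cut with ~20
  alternatives among 4,096 variants demands p ≈ 5×10⁻⁵ while such
  variants deliver p ≈ 10⁻⁴–10⁻² even at the true dispersion; measured
  pooled sensitivity for |Δ| ∈ [1, 2.5] is ≈ 0.85–0.9 with empirical
  FDR ≤ 0.1. Deeper sequencing or looser FDR raise it.
- The dose-dependency rule penalizes saturating responses whose top-dose
  increments are smaller than the log₂FC noise; its tolerance (0.1) is of
  the same order as that noise at φ = 0.05, n = 8.
- Hierarchical clustering at >75% identity on short motifs (5–9 nt) is
  coarse: one mismatch in a 6-mer is already 83% identity.
- Girvan–Newman maximizes modularity only along its removal path; on
  graphs without clear block structure the partition need not be the
  global modularity optimum.
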