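# Methods

This note documents the models, conventions and numerical choices behind
`dgetag`, and what the synthetic-data experiments do and do not demonstrate.

## Tag model

DGE tag profiling represents each transcript by 21-nt tags anchored at CATG
(NlaIII) restriction sites; the MmeI digestion step fixes the tag length at
CATG + 17 nt.  The reference ("virtual") tag library enumerates **all** CATG
+ 17 nt windows of every reference transcript, including overlapping CATG
occurrences.  Windows containing an undetermined base (N) are skipped rather
than wildcarded — an N cannot define a reference tag, and wildcarding would
silently create ambiguity.

Conventions:

- **Sense strand only** by default.  Unigene/EST references are oriented
  transcripts and the polyT bead capture reads the mRNA 3′ end; antisense
  scanning is available behind a flag (`include_antisense`) for unoriented
  references.
- **Coordinates** are 0-based offsets of the CATG start; intervals are
  half-open.
- **Resolution policy.**  A perfect hit strictly governs: 1-mismatch
  neighbours are consulted only when the query is absent from the index.
  The single tolerated mismatch (SNP tolerance between varieties) is
  confined to the 17-nt variable region; the CATG anchor is the restriction
  site that defines the read and must match exactly, so a read not starting
  with CATG is unmapped by construction.  At the governing level a tag is
  credited to a gene only when exactly one gene carries it; otherwise it is
  ambiguous and its whole count is discarded (no fractional allocation, and
  no tie-breaking among 1-mismatch genes).  Resolution is strictly per-tag:
  one tag's fate never depends on another tag's hits.

## Cleaning filters

Five filters run in a fixed order — adaptor, empty, ambiguous base, length,
copy number < 2 — and a read matching several classes is charged to the
first applicable one, which makes the filter statistics deterministic and
read conservation exact (`raw = clean + Σ removed`).

The adaptor rule is configuration, not a published fact: a read *contains*
the adaptor when the adaptor's first k nt (k = 8 by default) occur as an
exact substring.  A match at position 0 means there is no tag content in
front of the adaptor, so the read is classed *empty*; a match at position
> 0 is an adaptor-contaminated tag.  The copy-number filter is applied per
library, after exact-sequence aggregation and before mapping; the singleton
statistic therefore counts reads whose tag occurred exactly once.

Saturation curves subsample clean reads **without replacement through one
shared permutation**, so the subsamples are nested and every per-seed curve
is monotone.  A gene counts as detected from ≥ 1 unambiguously mapped tag.
Copy-number distribution percentages are shares of total clean tags
(copies), with distinct-tag counts reported alongside.

## Differential expression

Counts are normalized to tags per million clean tags (TPM,
`count/N × 10⁶`); this is a pure library-size normalization (the historical
SAGE "TPM"), not the length-aware modern TPM.  The log₂ ratio is computed
on TPM; when totals differ this differs from a raw-count ratio, which is why
the choice is stated here.  A zero count is floored at 0.5 tags *for the
ratio only* (configurable), keeping the ratio finite; the test always uses
the raw integers.

The Audic–Claverie statistic conditions on the count in one library with a
flat prior on the unknown rate, giving the negative-binomial-form
conditional `p(k|x) = C(x+k, k) q^k (1-q)^(x+1)`, `q = N₂/(N₁+N₂)`.  Tails
are summed term-by-term in log space with log-gamma starting values and
ratio updates; the upper tail is entered only at or above the conditional
mode, where terms decrease and summation stops once a term falls 45 nats
below the running peak (remaining mass < 10⁻¹⁹ of the sum).  Overflow is
impossible by construction.  The two-sided p-value doubles the
direction-selected, point-included tail and caps at 1.

Two documented consequences of this construction:

- **Exchange asymmetry.**  Because the distribution is conditioned on one
  library, swapping the libraries does not algebraically preserve the
  point-included two-sided p-value (e.g. x=0, y=1 at equal totals gives 1.0
  one way and 0.5 the other).  Equal-count pairs are exactly symmetric, the
  log ratio negates exactly, decisions flip in practice, and the p-values
  agree within a discreteness-bounded factor; the tests assert exactly
  these properties.
- **Mild conservatism.**  As a discrete exact-style test with the observed
  point included in the doubled tail, the null rate of `p < 0.05` sits
  slightly below nominal (≈ 0.046 at per-gene means of ~100 counts in the
  null simulations below) rather than exactly at 0.05.

Multiple testing uses Benjamini–Hochberg over the genes with x + y > 0;
all-zero genes are untestable and excluded from the family so they cannot
dilute the adjustment.  Calls require FDR < 0.001 and |log₂ ratio| ≥ 1
(both thresholds configurable; defaults as stated).  Genotype contrasts
reuse the same machinery with the two genotypes' libraries as reference and
treatment at matching time points.

The Venn decomposition partitions the union of DE genes at two time points
into eight disjoint classes by per-gene case analysis of the two calls.

## GO enrichment

Upper-tail hypergeometric test per term against the background universe,
which defaults to the full tag-mapped reference gene set (configurable to
the tested-gene set).  The float path uses the survival function of the
hypergeometric distribution; an `exact=True` path sums the tail in rational
arithmetic, for which complement identities hold exactly.  BH adjustment is
applied within each GO namespace when namespaces are supplied, otherwise
over all tested terms; a term is enriched when p < 0.01 and FDR < 0.05.
Annotations are used as given — no ancestor closure is assumed — with
`propagate_annotations` available as explicit pre-processing over a
term-parent table.

## Synthetic data: what it emulates, and what it does not

The generator emulates: transcripts that all host ≥ 1 valid CATG site
(random uniform base composition, lengths 200–600 nt by default); planted
two-condition differential structure (a fraction of genes, split evenly
up/down, scaled by 2^±lfc and renormalized — note renormalization imparts a
small opposite shift to null genes); multinomial tag sampling at stated
depths; the 3′-most-site rule of the bead-capture chemistry (an optional
`leaky_site_rate` emits non-3′ tags to create multi-site and ambiguous
cases — its default of 0 is a free choice, not a measured quantity);
independent per-base substitution errors; and the four junk-read classes,
mutually exclusive per read with exact multinomial accounting, so
`informative + junk = depth` always.

It does **not** model: base-quality scores (only N presence), PCR
duplication, positional error profiles, adaptor sequencing errors,
reference redundancy (real unigene collections contain many near-identical
entries, which is the dominant source of ambiguous tags in real data), or
transcript-length biases.  Passing tests therefore demonstrate the
*correctness of the algorithms and their accounting*, and the *operating
characteristics of the test under clean multinomial sampling* — not the
mapping rates or DEG counts of any real library.

Default study conditions: per-gene abundances are log-normal (σ = 1)
normalized to a probability vector, a realistic right-skewed profile.  The
calibration simulations (null and planted-signal) instead use flat
abundance across 2,000 genes at 2×10⁵ clean tags per library — chosen so
the tests isolate the DE test's behaviour from abundance skew and every
gene sits at baseline 500 TPM, comfortably inside the regime the recovery
check targets (baseline TPM ≥ 100, |log₂FC| = 2, 10 % DE genes).  Under
these conditions measured sensitivity is ≈ 1.0 and empirical FDR ≈ 0 over
20 seeds; the per-simulation null `p < 0.05` rate lies within its binomial
sampling band, with the small systematic deficit described above.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds from the single run seed via `SeedSequence([seed, stage])`,
and all output tables are sorted and written with fixed float formatting,
so one config + seed reproduces byte-identical artifacts.  The bundled demo
uses 200 genes × 6 libraries × 20,000 reads and finishes in seconds; the
calibration simulations use 2,000 genes × 2×10⁵ tags × 20 seeds.  These
sizes were chosen as the smallest at which mapping rates, calibration and
power stabilize; all are parameters, and larger runs only cost time.

## Known limitations

- One library per condition, as in the original design: the AC test models
  sampling noise only, not biological replication or overdispersion — with
  replicates a dispersion-aware model (e.g. a negative-binomial GLM) should
  be preferred.
- The 1-mismatch neighbourhood search is exhaustive (51 neighbours per
  tag), which is exact but means mapping cost grows with distinct-tag
  count; for real-scale libraries (~10⁷ reads, ~10⁵ distinct tags) this is
  still only ~5×10⁶ dictionary probes.
- Genome (intron-containing) references and spliced mapping are out of
  scope; the index is defined on transcript sequences.
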