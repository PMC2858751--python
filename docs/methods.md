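# Methods

## The detection model

The screen treats a 3'-biased expression array as an ordered set of
genomic reporters.  Its unit of inference is a *probe-set pair*: the
primary probe set (annotated to a transcript, target most 3' in transcript
orientation) and the single nearest probe set strictly downstream on the
same strand.  The underlying generative assumption is simple: if both
probe sets report the same transcript, their log2 expression profiles
across a diverse tissue compendium differ only by a consistent intensity
offset (labeling efficiency decays with distance from the polyA tail), so
their Pearson correlation is high; if the downstream probe set reports
noise or an independent transcription unit, the correlation is near the
null.  Calls are therefore gated on three things: unique mappability,
above-noise expression of both members, and correlation above a cutoff.

Conventions that the rest of the package inherits:

* Coordinates are 0-based half-open (BED).  A feature's 3' coordinate is
  `end` on `+` and `start` on `-`; downstream means increasing coordinates
  on `+` and decreasing on `-`.
* "Strictly downstream" compares the candidate's 5'-most edge with the
  primary target's 3' coordinate; overlapping or abutting targets never
  qualify, so pair distances are positive.
* Only the *nearest* downstream probe set is evaluated.  If it fails the
  annotation condition the transcript yields no pair; the screen does not
  skip to the next one.  An unannotated probe set belonging to an
  undiscovered downstream gene is exactly the confusable case, and
  skipping past an annotated blocker would re-admit it.
* "Annotated" means a non-empty entry in the probe-set → transcript table.
  An optional overlap mode (`annotate_by_overlap`) additionally treats a
  same-strand overlap with any transcript span as annotation, for datasets
  whose annotation table is stale relative to the gene models.
* All ties (equal 3' coordinates, equal distances) break on the
  lexicographically smallest id, so outputs are deterministic.
* Genes whose transcripts disagree on chromosome or strand are skipped
  with a diagnostic rather than silently resolved.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `expression_threshold` | 6 | log2 signal | a probe set is "above noise" iff it strictly exceeds this in ≥ 1 array (raw signal > 64; roughly the array-wide median) |
| `correlation_cutoff` | 0.6 | Pearson r | strict lower bound for calling co-expression |
| `motif_max_region_len` | 1000 | bp | only extension regions strictly shorter enter motif/conservation characterization (limits spliced-out introns) |
| `n_random_sets` | 100 | sets | matched random region sets per pool in the conservation comparison |
| `n_random_pairs` | 100000 | draws | random-pair null sample size (an exhaustive mode enumerates all pairs when feasible) |

Both thresholds are strict inequalities.  The noise filter is applied over
the entire matrix, not per tissue; the correlation test is one-sided
(r > cutoff, not |r|).

## False-positive rates

*Random-pair null.*  Unordered pairs of above-noise rows are drawn
uniformly (a row never pairs with itself; distinct draws may repeat a
pair), and the null rate is the fraction with r above the cutoff.  The
draw count is configurable because a stable tail estimate needs many
draws; the exhaustive mode is the oracle on small matrices.  Zero-variance
rows are excluded (their correlation is undefined) with a logged count.

*Cross-chromosome null.*  For one probe set, its correlation with every
uniquely-mapping probe set on other chromosomes is computed exhaustively;
under the assumption that no transcript spans two chromosomes, the
fraction above the cutoff is a per-probe-set false-positive rate.  No
noise filter is applied to the comparison rows by default; both
eligibility rules are explicit switches.

`expected_false_positives(n, q) = floor(n·q)` converts a rate into an
expected count of false calls among `n` predictions.

*Rescue pairs.*  Pairs where only the downstream member passes the noise
filter (the primary may sit far from the true 3' end and suffer the
labeling gradient) are computed by the same machinery but reported
separately and never merged into the main predictions — their expression
evidence is one-sided and noisier.

## Conservation comparison

The extension region runs from the annotated 3' end to the far (3'-most)
edge of the extended probe target, so it includes the inter-probe gap plus
the probe target; a `span_mode="near"` switch stops at the proximal edge
instead.  Region conservation is the mean per-base score, with bases
absent from the track contributing 0 (phastCons emits nothing for
unalignable bases; absence-as-zero is the conservative choice).

"Same amount of sequence" is implemented as per-region length matching:
each random set contains, for every prediction region of length L, one
uniformly placed sub-interval of length L from the pool (pool intervals
weighted by their number of valid start positions), so set totals match
the prediction total exactly.  The Z-statistic is
`(ext_mean − mean(intergenic set means)) / sd(intergenic set means)` with
the n−1 sample standard deviation, and p is the one-sided upper-tail
normal probability, clamped to the smallest positive float so it stays in
(0, 1] when the geometry makes it underflow.  A constant track (sd = 0) is
an error, not a silent infinity.  Set-level summaries quoted from the
count tables use percentile confidence intervals.

## Motif grammar and seed sites

Patterns are whitespace-separated elements: IUPAC words with parenthesised
alternations, bounded gaps `a...b` (or `a.b`), bounded single-symbol
repeats `X{a,b}`, and a trailing `[s,i,d]` mismatch triple (substitutions,
insertions, deletions) applying only to the word it follows.  T and U are
equivalent; an `N` in the scanned sequence matches only a pattern `N`.
Scanning reports one hit per matching start position, using the
shortest-gap assignment; overlapping hits at distinct starts each count.
The matcher is a backtracking enumerator over element spans; with the
built-in patterns' budgets this is exact and fast, and tests pin it
against an independent brute-force enumerator.

Seed sites follow the canonical hierarchy: a perfect reverse-complement
match to seed positions 2–8 followed by A is an 8mer and is counted only
as such; without the A it is a 7mer-m8; a match to positions 2–7 followed
by A (and not embedded in an 8mer) is a 7mer-A1.  Context scoring and
conservation weighting of sites are out of scope.

Tag confirmation accepts any same-strand tag whose 3' coordinate falls on
the extended probe target or downstream of it.  The unbounded rule is the
method's definition; because a genome-wide tag library will often have
*some* unrelated downstream tag on the same strand, the function takes an
optional `max_downstream` window (the acceptance measurements use 10 kb)
so only local polyadenylation evidence is credited.

## The synthetic generator

`utrx.simulate` emulates the structure of a multi-tissue 3'-array
compendium: 22 tissues with 3–5 replicates trimmed to 70 arrays; genes
laid out on 4 synthetic chromosomes in fixed-size slots, each with an
annotated transcript, a primary probe target in its 3'UTR, and either a
planted extension (unannotated probe target 200–900 bp downstream) or an
unannotated intergenic decoy probe set; a small set of multi-mapping probe
sets exercises the mappability filter.

Expression is `baseline + tissue effect + noise` per probe set, all in
log2 units (baseline ~ N(8, 1), tissue effect sd 1.5, replicate noise sd
0.4).  Planted pairs share the latent tissue effect and receive private
jitter whose variance is solved from the target pair correlation
(default 0.9), plus a consistent intensity shift between members —
correlation is planted through a shared latent factor rather than profile
copying, so the random-pair null keeps a realistic non-degenerate tail.
Decoys draw independent tissue effects.  Conservation scores are i.i.d.
clipped normals per base around class means: known 3'UTR 0.233,
intergenic 0.124, planted extensions 0.26 (sd 0.1).  Sequences are
uniform random nucleotides; a mammalian polyA element instance is planted
near the extension 3' end with probability `motif_plant_rate` (default
0.7, roughly the fraction of mammalian 3' ends carrying the hexamer), and
3'-end tags are emitted at extension ends for `tag_fraction` (default
0.4) of extension genes.  All randomness derives from a single seed
through three spawned streams (geometry, expression, track/sequence), so
bundles are byte-identical given a seed and structural counts are
seed-independent.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: probe-level hybridization physics and GC
effects, spatial autocorrelation of conservation, realistic base
composition and repeat structure, tissue-restricted extensions (the
planted correlation holds across all tissues), annotation errors, and
cross-hybridization.  The planted geometry is also clean: extensions
never overlap neighboring genes, and decoys are genuinely independent.

## Problem sizes and numerical choices

Default experiments use 200 genes × 70 arrays; null estimates use
20k–50k draws; the conservation comparison uses 100 matched sets per
pool.  These sizes make every quantity stable to well under the decision
margins used in the tests while keeping the whole suite fast.  Pearson
correlations are computed on centered, unit-norm rows (vectorized dot
products); values are clipped to [−1, 1] against rounding.  Zero-variance
profiles raise an explicit undefined-correlation error wherever a single
correlation is requested and are excluded, with a logged count, from bulk
screens and nulls.

## Known limitations

Adjacent, co-regulated but distinct transcription units can produce
correlated pairs that are not extensions; the cross-chromosome null does
not capture this shared-regulation failure mode (neither does the
random-pair null), so rates from both are lower bounds on the true error.
Tissue-restricted extensions are invisible to a compendium-wide
correlation.  The screen evaluates only the nearest downstream probe set,
so extensions reported only by a farther probe set are missed.  Motif
counts are not discriminative between 3'UTR and intergenic sequence (by
design of the negative control, and empirically), so they characterize
rather than validate predictions.
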