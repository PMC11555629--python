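# Methods

## Scoring model

The unit of analysis is a curated sample pair: one intersexual (transitional)
gonad transcriptome and one ovary transcriptome from the same species,
quantified as TPM. For transcript *t* and pair *p*,

    IO-ratio(t, p) = log2(TPM_I(t, p) + c) − log2(TPM_O(t, p) + c)

with pseudocount c = 0.01 TPM. The pseudocount keeps ratios finite at zero
expression and makes (0, 0) map to exactly 0; its side effect is to shrink
ratios of very low-expressed transcripts toward 0 (at baseline 0.1 TPM the
adjustment is ~10% of the signal), which slightly attenuates the pooled
ratio SD relative to the noise actually simulated.

A pair is labelled *upregulated* iff IO-ratio > log2(F), *downregulated* iff
IO-ratio < −log2(F), otherwise *unchanged*, with fold cutoff F = 5. Both
inequalities are strict: a ratio exactly at ±log2(F) is unchanged. Per
species, IO-score(t) = #up − #down over that species' pairs, so
|IO-score| ≤ pair count, and a transcript must move in the *same direction
in most pairs* to score high — single outlier pairs contribute at most ±1.
Ratios are always computed pair by pair as manifested; replicate ovaries are
never averaged before ratioing, and expression values are never compared
across pairs or across studies. That is the design's defence against batch
effects: every comparison is internal to one experiment.

The `ratio_sd_diagnostic` reports, per species, the mean and sample SD
(ddof = 1, matching R's `sd()`) of all IO-ratios pooled over transcripts and
pairs, plus `fold_at_2sd = 2^(2·SD)`. A fold-at-2SD near F means the cutoff
sits at the edge of the species' natural ratio dispersion. Pooling includes
all transcripts by default; an option drops transcripts whose ratio is zero
in every pair, since the field has no agreed convention on whether
never-expressed transcripts belong in the dispersion estimate.

## Orthology

Species are linked to one designated hub species by reciprocal best hits
(RBH) computed from 12-column tabular homology-search output (the
BLAST/Diamond outfmt-6 dialect). Hits with e-value > 1e-3 are dropped at
parse time, so both search directions see the same filtered universe —
equivalent to passing the cutoff to the search itself. Per query the best
subject is chosen by max bitscore; ties break by lower e-value, then longer
alignment, then lexicographically smallest subject id, and multiple HSPs for
one (query, subject) are first collapsed to the max-bitscore one. The
hierarchy is a deterministic convention of this package (search tools do not
document one); tests verify it against exhaustive enumeration. Self-hits are
excluded defensively. An RBH map is 1:1 by construction and asserted on
every output.

Consolidation produces one group per hub protein id; a group is *common* iff
it has an RBH member in every non-hub species. Only common groups are
scored: a gene missing from any species cannot receive contributions from
all of them, so including it would bias totals toward well-annotated
lineages. A hub protein with no transcript in the hub expression data drops
its group (with a logged count); a non-hub member without expression data
contributes 0 and flags the group, keeping totals comparable.

## Aggregation and calling

The total IO-score of a common gene is the sum of its members' per-species
IO-scores, so |total| ≤ total pair count N. The calling threshold is
`ceil(fraction · N)` with fraction = 0.2 — for the 31-pair default design,
ceil(6.2) = 7 — applied symmetrically as ±threshold with the **boundary
inclusive** (a total of exactly ±7 is called). Two readings of a
"20% beyond the extremes" rule are possible; only fraction-of-maximum with
ceiling maps 31 pairs to 7, and boundary inclusion is required for the rule
to be usable at all when totals sit exactly at the cutoff. The ceiling is
computed as `ceil(round(fraction·N, 9))` to protect exact multiples from
float artifacts (0.2 × 10 must give 2, not 3).

Records are ranked by descending total (ties by hub id, 1-based).
`composition_table` emits the signed per-species breakdown in long format,
with a `single_species` flag marking genes whose entire total comes from one
species — such calls rest on a single study design and deserve scrutiny.
`annotate` joins reference-annotation symbols by highest alignment score
(ties to the lexicographically smallest reference id, logged) and reports
the unmapped count.

## Synthetic data generator

`ioscore.simulate` emulates the statistical structure the scoring assumes,
not any particular sequencing artefact. Defaults define the study shape:
7 species, per-species pair counts (4, 2, 2, 6, 2, 12, 3) totalling 31,
5000 orthologs, non-hub retention probability 0.9, 1% of orthologs planted
up and 1% down at 25-fold, log-normal baselines (log2-TPM ~ N(3, 2)), log2
noise SD 0.25, dropout probability 0.02, 100 paralog decoys per species.

Per (transcript, pair): ovary log2-TPM ~ N(baseline_log2_mean,
baseline_log2_sd); intersexual log2-TPM = ovary + s·log2(effect_fold) +
N(0, noise_sd) with s ∈ {+1, −1, 0} by planted class. Noise is attached to
the intersexual member so a pair's IO-ratio is exactly
N(s·log2(effect_fold), noise_sd) before pseudocount and dropout — the
quantity the scoring thresholds act on. Dropout zeroes individual TPM
entries independently; zeroing the intersexual member of a planted-up pair
flips its label to down, which is the main error mode the recovery tests
exercise. TPMs are deliberately not renormalised to sum to 1e6 per sample:
scoring consumes ratios only and renormalisation would couple transcripts.
Planted class is constant across species (the shared-regulation premise).

Hit tables: each retained ortholog gets mutual top hits (bitscore uniform on
[250, 500], identical in both directions, e-value ≤ 1e-3). Decoys attach to
retained orthologs at strictly below 0.9× the true bitscore, so best hits
are unambiguous; a configurable fraction of decoys instead become the best
hit of a hub protein that has *no* retained partner in that species (best in
one direction only), exercising the reciprocity check without ever
displacing a true pair. Consequently brute-force RBH on generated tables
recovers exactly the planted pairs at any breaking fraction; the tests
assert this at fraction 0 and 1.

Determinism: one master seed; per-species and per-stage substreams are
spawned via `numpy.random.SeedSequence([seed, stage, species])`. Identical
config ⇒ byte-identical bundle files (floats are written at fixed
precision: TPM %.6f, bitscore %.1f, e-value %.2e).

What the generator does **not** model: library-size or batch effects beyond
the log-normal noise, isoform structure, correlated dropout,
count-mean–variance relationships, many-to-many paralogy, or reads and
alignments of any kind. Passing tests therefore demonstrate that the
pipeline's logic is correct and that the scoring recovers clean planted
signal of the stated magnitude; they do not certify performance on real
quantifier output, where effect sizes are heterogeneous and orthology errors
correlate with expression.

## Evaluation choices

Planted-recovery precision and recall are computed against the planted truth
restricted to the common-ortholog universe: with retention 0.9 over six
non-hub species only ~53% of planted genes are common, and — exactly as in a
real study — genes outside the candidate universe cannot be called, so they
are out of denominator by design. Null-control runs use the same shape with
no planted effects; at noise SD 0.25 a false call requires ≥ 7 net
dropout-flipped pairs in one gene, which is vanishingly rare, and the
observed null call rate is ~0.

Problem sizes used by the test suite and `scripts/acceptance.py` (5000
orthologs, 10 recovery/null seeds in tests, 5 in the script, 100
random-instance oracle comparisons at ≤ 40 proteins a side) were chosen so a
full run completes in well under a minute while keeping binomial/Monte-Carlo
standard errors far inside the asserted margins.

## Limitations

- Orthology is 1:1 RBH only; lineage-specific duplications are represented
  at most by one member and paralog interference is modelled only as decoys.
- The 20%-of-maximum threshold rule presumes pair counts comparable to the
  default design; with very few pairs the derived threshold collapses to 1
  and calls become single-pair driven (`derive_total_threshold` floors at 1).
- The SD diagnostic is descriptive: the pipeline never re-derives the fold
  cutoff from data; users should inspect `sd_diagnostic.tsv` and override
  `fold_threshold` deliberately if their data's dispersion warrants it.
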