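# Methods

This note documents the procedures implemented in `neopept`, the defaults
they use, the synthetic world the fixture generator emulates, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Consensus call set

The union of three per-caller VCFs is keyed on (chromosome, position) after
minimal-representation normalization (shared suffix trimmed, then shared
prefix; multi-allelic records split). Identical (ref, alt) calls accumulate
supporters. Where callers disagree at one coordinate, an allele is kept iff
its supporters are a strict majority of the distinct callers reporting
there; with no strict majority the whole coordinate is rejected. Note that
under this formulation an uncontested allele (one reporting caller) is
always kept, which preserves union semantics.

Somatic status is tumor-only presence; germline evidence from **any** caller
makes a variant a germline SNP (conservative for somatic status). Calls seen
only in the germline sample are flagged and are linked-SNP candidates only
if phased. High confidence = called by MuTect alone or by ≥ 2 of the 3
callers. Germline SNPs sharing both the phase set and the haplotype index of
a retained somatic variant (phased genotype separators plus PS tags, tumor
sample) are attached as linked SNPs and **inherit retention** from their
partner — the caller-support rule is deliberately not applied to them
independently, since a phased germline SNP is typically a high-quality call
and its retention only modifies the context of an already-retained mutation.
Unphased variants are never linked.

Full left-alignment of indels against the reference genome is not performed;
trim-based normalization is sufficient to make equality well-defined across
callers that pad indel alleles differently. Coordinates are 0-based
half-open internally, 1-based in all I/O.

## Contexts and the customized proteome

One context per mutation, on the gene's canonical transcript (longest CDS,
ties broken lexicographically — isoform-level behavior is not otherwise
specified by the procedure this reimplements). Transcripts with CDS length
not divisible by 3, or with internal stops, are flagged incomplete and
excluded. For a missense SNV the novel residue is centered in a
31-mer (`context_flank` = 15); contexts truncate, never pad, at protein
termini. Non-synonymous linked-SNP edits falling inside the window are
applied to the mutant sequence (the wild-type sequence keeps reference
residues), so downstream peptides reflect the actual tumor haplotype.
Synonymous and stop-gain effects yield no vaccine candidates.

Frameshift contexts (`indel_contexts`, **off by default**, matching the
procedure as published) emit the 24 reference residues immediately upstream
of the first altered residue, fewer near the N-terminus, followed by the
novel ORF translation up to (not including) the first stop; an immediate
stop leaves an upstream-only context flagged `truncated_orf`.

The customized proteome FASTA emits every reference protein once and, for
each affected transcript, one additional entry with the full mutant sequence
and a pipe-delimited header suffix listing its substitutions
(`>tid|gene|p.Lys2Arg;p.Lys8Asn`). The header convention is this package's
own. With zero variants the output is byte-identical to the reference
proteome. The intended downstream MS search settings (unspecific digestion,
8–25 aa peptides, 5% peptide FDR, no protein FDR) are recorded here as
metadata; the search itself is out of scope. MS-identified peptides can be
flagged `mutant` (occurs in a mutant protein, spans a mutated residue, and
is absent from the reference proteome), `wt`, or `unmapped`.

## Binding scores and calibration

Candidates are all class I 9–12-mer and class II 12–19-mer windows whose
span covers the somatic residue (windows covering only linked-SNP edits are
excluded by default; `include_linked_only_windows` enables them). Scoring is
pluggable:

- **External tables** (`load_external_scores`): TSV of peptide, allele,
  score, %Rank (p-value optional, defaulted to %Rank/100), for use with
  published predictor output. Unmatched candidates are flagged unscored and
  excluded from binder calls.
- **Built-in PWM scorer**: class I sums per-position weights from a
  length-matched matrix; class II takes the best 9-mer core under a single
  core matrix. Raw scores are calibrated per (allele, length) against
  decoys: N = 100,000 peptides drawn i.i.d. from uniform residue
  frequencies with a fixed seed (`decoy_seed` = 42), %Rank = 100 × fraction
  of decoys scoring ≥ the query. p-value := %Rank/100 — the simplest mapping
  consistent with reporting both quantities, and an honest label for what a
  percentile against random peptides is. The real mixture-model predictors
  this stands in for are deliberately not reimplemented.

Binder call: %Rank strictly below 5 for ≥ 1 allele (`rank_cutoff`,
`rank_strict`; the strict form follows the formulation in the published
methods over the `≤` that appears elsewhere), **or** the peptide's wild-type
form is an exact ligand-database match.

## Filters and hotspot overlap

- **Expression**: gene-level 90th-percentile TPM in the target tissue,
  linear interpolation between order statistics (a convention had to be
  fixed; the source tables give no method). Strictly below 1 TPM drops the
  mutation. Genes absent from the table are retained with a missing-
  expression flag: absence of evidence is not evidence of absence.
- **Wild-type identity**: a mutant peptide occurring verbatim anywhere in a
  reference proteome is removed (exact substring scan). Only the mutant
  sequence matters.
- **Hypermutated genes**: more than `hypermutated_max` = 3 somatic mutations
  in one gene drops them all as likely false positives. The published
  procedure gives no number; 3 is a placeholder an operator should review.
- **Underrepresentation**: mutations whose source protein has ligand-
  database coverage below `coverage_threshold` can be dropped; the default
  threshold 0 keeps the filter inert because no quantitative criterion is
  published.
- **Hotspot overlap** per HLA class, over the wild-type forms of a
  mutation's candidates: EXACT (equals a database ligand), INCLUDED (proper
  substring of a ligand, or properly contains one), PARTIAL (positional
  overlap ≥ 5 residues with a ligand mapped to the same protein), else NONE.
  INCLUDED/PARTIAL are this package's operationalization of the reported
  categories and are configurable. An EXACT match promotes a mutation as a
  ranking tie-break only, never as a filter.

These mutation-level filters commute (each tests an independent predicate),
which the acceptance suite verifies.

## Long-peptide design and ranking

Over all contiguous windows of the context, the design maximizes the number
of fully contained predicted binders; among maxima the shortest window wins,
then the leftmost. There is no length cap beyond the context itself: for a
≤ 31-residue SNV context the whole context contains every binder, so the
optimum reduces to the hull of the binder spans. For long frameshift
contexts an optional `max_length` restricts the window (e.g. to a
synthesizable length), which can force the optimizer to choose the larger of
two distant binder clusters. The implementation is vectorized over the
O(L²) windows and is checked against an independent exhaustive enumerator on
1,000 random instances.

Ranking keys, in order: minimum class I p-value ascending (designs with no
scored class I binder sort last); total binder count descending; represented
alleles (class I + II) descending; EXACT hotspot match first; genomic
coordinate ascending as the final deterministic tie-break, making the order
total. The top 10 designs (configurable) form the report. "# predicted
peptides" counts unique binder sequences pooled over classes; the allele
columns count distinct passing alleles per class.

## The synthetic world

`neopept.fixtures.generate_cohort` writes a byte-deterministic bundle per
seed. Defaults emulate the smallest of the three published patients: **23
non-synonymous somatic mutations**, a low-mutational-load tumor, pancreas as
the target tissue, 20 single-exon plus-strand genes of 120–260 residues on
one chromosome (multi-exon/minus-strand geometry is exercised in unit tests;
`minus_strand_fraction` exists for the generator), two class I and one
class II allotype, 20% of ordinary mutations carrying a phase-linked
germline SNP within ±10 codons, ~120 ligand-database entries, and uniform
background residue frequencies (the simplest null for decoy calibration).

Planted structure, all recorded in `truth.json`:

- supporter profiles cycling over MuTect-alone, two-caller and three-caller
  combinations, plus two single-non-MuTect-caller calls (excluded by the
  high-confidence rule), one 2-vs-1 caller conflict (majority keeps the
  pair's allele) and one 1-vs-1 conflict (coordinate rejected);
- four epitope-planted mutations: allele motifs carry anchor residues
  (weight 0.8 in a row-normalized PWM, near-uniform jittered background
  rows) and each planted Pro→Leu substitution completes the position-2
  anchor of a class I 9-mer whose remaining anchors pre-exist in the
  germline protein, plus a class II core centered on the mutation. The
  designated best mutation matches all four class I anchors; other planted
  binders only two, so its %Rank is strictly minimal — verified against the
  generated decoy distribution at build time (generation fails otherwise
  rather than silently shipping a broken invariant);
- traps: one planted binder in a gene with p90 TPM < 1 (expression filter),
  five mutations in one gene (hypermutated filter), and one planted mutant
  9-mer copied into an unrelated protein so the wild-type-identity filter
  must remove exactly that candidate;
- deliberate ligand-database entries: the best mutation's wild-type 9-mer
  (class I EXACT) and 14-mer (class II EXACT), and a same-protein ligand
  with ≥ 5-residue positional overlap for another mutation (PARTIAL).

What a green end-to-end test establishes: the merge rule, high-confidence
selection, phase linking, context construction, decoy-calibrated binder
calling, every filter, and the ranking recover the planted truth exactly,
including the engineered rank-1 mutation. What it does not establish:
predictive accuracy of the PWM stand-in against real predictors, behavior on
real caller idiosyncrasies (the VCFs are clean), multi-exon coordinate
arithmetic at pipeline scale, or performance at human-proteome scale (the
wild-type-identity scan is a naive substring search, adequate for ~10⁴–10⁵
residues of reference proteome).

Because percentile ranks of random peptides are uniform, unplanted mutations
also acquire occasional sub-5% windows — a realistic property of a
permissive %Rank cutoff; the planted best's four-anchor margin (measured
p ≈ 10⁻⁴ tail vs ~10⁻² for chance minima over a mutation's windows) is what
makes rank-1 recovery stable across bundle seeds.

## Numerical and degenerate-input choices

- %Rank uses `searchsorted` on the sorted decoy scores with ties counted as
  ≥ (a score equal to decoys shares their rank); a score above all decoys
  gets %Rank 0 and p-value 0.
- Decoy RNGs derive from `(decoy_seed, allele_index)` so calibration is
  reproducible per allele and independent of the bundle seed.
- Contexts shorter than a class's minimum peptide length yield an empty
  candidate list with a warning; mutations with zero binders carry no design
  and are excluded from ranking.
- Candidates containing non-standard residues are dropped with a warning;
  MS peptides with non-standard residues are `unmapped`.
- Duplicate external-score rows with conflicting values abort loading;
  exact duplicates are tolerated.
- Fewer designs than `top_n` returns all with a warning; `top_n = 0` returns
  an empty report.

## Known limitations

- The PWM + decoy scorer is a transparent stand-in, not a reimplementation
  of mixture-deconvolution predictors; absolute %Rank values are only
  meaningful relative to its own decoy model.
- The wild-type-identity and hotspot scans are exact but naive (O(n·m));
  fine at fixture scale, would want an index at proteome scale.
- Indel handling covers frameshift/inframe classification and frameshift
  contexts on plus- and minus-strand single-CDS transcripts; complex
  multi-exon indels spanning splice boundaries are out of scope.
- Splice-site, UTR and regulatory effect annotation is out of scope (the
  upstream annotator this replaces covers them).
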