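# neopept

Neoantigen prioritization and long vaccine-peptide design from multi-caller
somatic variant calls.

Personalized cancer vaccines target *neoantigens*: peptides created by
tumor-specific somatic mutations, absent from the normal proteome, and
presentable by the patient's HLA class I and II molecules. In low-mutational-
load tumors (such as pancreatic ductal adenocarcinoma, with a few dozen
non-synonymous mutations per patient) every candidate counts, so the
selection pipeline has to squeeze reliable calls out of noisy inputs and
pack as many predicted epitopes as possible into a handful of synthesizable
long peptides. `neopept` implements that in-silico core for bioinformaticians
building or evaluating such pipelines:

1. **Consensus variant calling.** Per-caller VCFs (HaplotypeCaller, MuTect,
   VarScan-style, consumed as files) are merged into a non-redundant union.
   Conflicting calls at one coordinate are resolved by simple majority of the
   reporting callers; no majority rejects the coordinate. Somatic status is
   tumor-only presence. *High-confidence* calls are those made by MuTect
   alone or by at least two callers; germline SNPs phased onto the same
   haplotype as a somatic mutation ride along as linked SNPs.
2. **Mutant contexts.** Each missense mutation is mapped onto its gene's
   canonical transcript and the novel residue is centered in a 31-mer
   (15 residues either side, truncated at protein termini), with amino-acid
   changes from non-synonymous linked SNPs applied inside the window.
   Frameshift contexts (24 unaltered upstream residues + the novel ORF) are
   available behind a flag, off by default. The same machinery emits a
   customized proteome FASTA for proteogenomic MS searches and flags
   MS-identified peptides as mutant/wt/unmapped.
3. **Binding prediction.** All class I 9–12-mers and class II 12–19-mers
   spanning the mutation are scored per allele. Scores come from a pluggable
   source: external predictor score tables, or the built-in position-weight-
   matrix scorer whose raw scores are converted to percentile ranks (%Rank)
   against a seeded decoy distribution of 100,000 random peptides; the
   reported p-value is %Rank/100. A peptide is a predicted binder when
   %Rank < 5 for at least one allele, or when its wild-type form is an exact
   match in a ligand database of MS-observed HLA peptides.
4. **Prioritization filters.** Mutations in genes not expressed in the
   target tissue (90th-percentile TPM < 1) are excluded, as are mutations in
   hypermutated genes; mutant peptides occurring verbatim anywhere in the
   reference proteome are removed. Overlap of the wild-type forms with
   ligand-database presentation hotspots is classified
   EXACT > INCLUDED > PARTIAL > NONE per HLA class.
5. **Long-peptide design.** For each surviving mutation the designer picks
   the shortest contiguous context window containing the maximum number of
   fully contained predicted binders, ranks designs by the minimum class I
   p-value (then binder count, allele count, EXACT hotspot match, genomic
   coordinate) and reports the top 10.

A seeded synthetic-fixture generator (`neopept.fixtures`) builds complete
toy input bundles — genome + GFF3, three caller VCFs with planted
concordance/discordance and phasing, expression table, ligand database, PWM
motifs — together with a ground-truth table of expected outcomes, including
an engineered rank-1 mutation.

## Worked example

```
$ neopept make-fixtures --seed 1 -o demo/inputs
bundle with 23 somatic mutations -> demo/inputs
$ neopept run-all -c demo/inputs/config.yaml -o demo/out
{
 "consensus_variants": 32,
 "high_confidence": 23,
 "somatic_contexts": 21,
 "retained_after_filters": 15,
 "designs": 15,
 "reported": 10
}
```

32 merged variants (23 somatic + phased/unphased germline SNPs; one planted
1-vs-1 caller conflict is rejected); 21 of the somatic calls satisfy the
high-confidence rule (two single-non-MuTect-caller calls do not); one
mutation falls in a non-expressed gene and five in a hypermutated gene,
leaving 15. The first rows of `demo/out/report.tsv` (columns abridged):

```
Rank  Chromosome_position  Gene     Expression_TPM_p90  Mutation     Driver_status  Long_peptide_sequence          ipMSDB_HLA-I  Lowest_HLA-I_pval  N_predicted_peptides
1     1_385                GENE001  47.273              p.Pro112Leu  Driver         MTCQSSVENTWELCLAGVEVHVPGWATPG  EXACT         0                  67
2     1_5577               GENE010  52.172              p.Val23Leu                  DMDGFGVRWLFVAIDRNVPE                         0.00084            7
3     1_10348              GENE016  55.814              p.Glu141Ala                 QWQGHVYSHKAGQEEWYWNC           INCLUDED      0.00138            5
```

Rank 1 is the fixture's engineered best mutation: its Pro→Leu substitution
completes every anchor of the planted class I motif (p-value 0, i.e. above
all 100,000 decoys), its wild-type 9-mer was planted in the ligand database
(EXACT), and the designed 29-mer packs 67 predicted binder peptides around
the mutation.

The library API mirrors the stages (`neopept.variants`, `.annotate`,
`.binding`, `.prioritize`, `.design`, `.pipeline.run_pipeline`); CLI
subcommands `merge-variants`, `build-contexts`, `build-db`, `predict`,
`report`, `make-fixtures`, `run-all` wrap them thinly.

## Acceptance script

`scripts/acceptance.py` recomputes the pipeline's fixed context-geometry
constants from scratch by generating seeded synthetic transcripts and
running the package's annotation machinery: the mutant-context length for an
interior missense SNV, and the number of unaltered upstream residues ahead
of the novel open reading frame in a frameshift context (indel option
enabled).

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model, parameter defaults, numerical choices
and known limitations.
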