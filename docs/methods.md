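# Methods

## The inheritance model

`pedvar` assumes a fully penetrant autosomal recessive trait at a single
biallelic locus.  Under that model the genotype of every cohort member is
determined (or bounded) by its analysis role:

- **obligate carrier parent** — an unaffected parent of an affected
  offspring must carry exactly one copy of the causal allele: state `het`;
- **affected case** — must be `hom_alt`;
- **unaffected sibling** — anything but `hom_alt` (carriers are allowed;
  the constraint is deliberately *not* `{het}`);
- **unrelated control** — from a population where the allele is absent:
  `hom_ref`.

A variant is a candidate when every role-constrained sample satisfies its
constraint (`segregation.matches_model`).  Roles are derived from a PED
pedigree plus the sequencing design (`pedigree.assign_roles`): sequenced
affected individuals become cases, both of their parents carriers, and
sequenced unaffected full siblings of a sequenced case become unaffected
siblings.  Controls may be external to the pedigree but must not belong to
a case family.

**Missing genotypes.**  The default policy is `strict`: a missing call
fails every constraint, which is conservative for candidate discovery (a
true causal variant is expected to be confidently called in all 15
samples).  The `permissive` policy lets a missing call satisfy only the
`not_hom_alt` constraint — the one constraint that a missing call cannot
contradict "upward".  Neither policy is asserted to be what any particular
upstream caller does; both are exposed.

**Phase** is ignored throughout: all constraints are zygosity constraints.

## Variant representation

Coordinates are 1-based inclusive, matching VCF.  Before filtering,
multiallelic rows are split into biallelic records (calls to a foreign
alternate allele become missing, so they can never be mistaken for
reference) and indels are normalized to the parsimonious left-aligned
representation (shared trailing bases trimmed with leftward reference
extension, then shared leading bases trimmed down to the single VCF anchor
base).  Normalization is idempotent and preserves the implied haplotype;
both properties are tested against direct string surgery.

**Display names.**  Candidate indels are rendered in an HGVS-style form
that matches field practice for reverse-strand genes: the deletion is
placed at its 3'-most equivalent position on the *forward* strand, while
the deleted base letter is reported on the gene's *coding* strand.  For the
study deletion (VCF `12:62282766 AC>A` in a reverse-strand gene) this
yields `62282767delG`.  Strict HGVS would shift 3' on the coding strand
instead; the hybrid is intentional and documented in `variants.py`.

## Consequence annotation

The CDS is assembled from GFF3 CDS segments (reverse-complemented,
descending order for strand `-`) and translated with the standard genetic
code; translation stops at the first stop codon, which is not counted as a
residue.  Classes: `synonymous`, `missense`, `stop_gain`, `frameshift`
(indel length not divisible by 3 inside the CDS), `inframe_indel`, and the
non-coding tags `intronic` / `five_prime` / `three_prime` / `intergenic`
computed from the gene geometry.  Edits spanning a CDS/exon junction are
rejected as unsupported rather than guessed.

Conventions for truncating variants:

- *first affected codon* = codon of the first coding base that differs
  between the alleles in coding orientation, after normalization;
- *protein length* counts translated residues only, so a protein "reduced
  to N residues" has its stop at codon index N+1;
- *novel residues* of a frameshift = `mut_protein_length −
  first_affected_codon`, the aberrant residues carboxy-terminal of the
  frameshift codon.  The frameshift codon itself is usually altered too;
  it is reported separately rather than folded into the count.  This is
  the convention under which a frameshift at codon 333 stopping after
  residue 366 has 33 novel residues;
- *exon indices* are transcript-order (exon 1 is 5'-most on the coding
  strand), which is what "a premature stop in exon 12" means for a
  reverse-strand gene;
- *domain impact*: a domain is `lost` if the truncated protein ends before
  it starts, `truncated_partial` if it ends inside it, else `retained`.

## The packaged study cohort

`pedvar.studycase` ships the study pedigree (27 individuals: 9 founder
parents and 18 offspring in 5 litters, 8 affected, with the dam of litter
5 being an unaffected offspring of litter 1) and the 12 + 3 sequencing
design as packaged PED/TSV data, plus the four candidate variant sites
with their published forward-strand alleles.

The gene model behind the consequence numbers is a **synthetic stand-in**:
the public transcript annotation is not bundled, so
`synthetic_study_gene()` engineers — deterministically, from a fixed
internal seed — a reverse-strand 24-exon gene at the real genomic span
whose coding sequence satisfies, simultaneously:

- 877 translated residues (2634-bp CDS including the stop);
- CDS base 998 (codon 333, base 2) at forward position 62,282,767, with a
  coding-strand `G` there and alleles arranged so the VCF record
  `62282766 AC>A` is already normalized and unambiguous;
- codon 346 = `AAC` with its third base at forward position 62,282,727
  (the synonymous `AAC>AAT` site; its 40-bp spacing from the deletion in
  the same exon is what fixes the deletion to codon-333 base 2);
- a stop-free shifted reading frame from codon 333 through mutant codon
  366, terminating at mutant codon 367, whose first base falls in
  transcript exon 12;
- a 3' UTR in exon 24 covering the two non-coding candidate sites.

Exon boundaries, intron sizes, UTR lengths and all non-constrained
sequence are synthetic.  Consequence *arithmetic* computed on this model
(codon indices, protein lengths, novel-residue and exon-of-stop numbers)
is exact by construction; anything depending on the true exon coordinates
(e.g. which intron a new variant would fall in) is not meaningful on it.
In this synthetic geometry the two non-coding candidate sites are tagged
`three_prime`: they lie at the genomic low end of a reverse-strand gene,
i.e. its 3' side.

## The synthetic cohort generator

`simulate.SimConfig` defaults encode the study conditions: 3 nuclear
families (2 founder parents, 1 affected + 1 unaffected offspring) plus 3
unrelated controls — 15 samples; a 24-exon reverse-strand gene with an
877-codon CDS in a 100-kb reference; a 1-bp coding deletion planted at
codon 333; 3 fully linked private variants within 50 kb of the causal site
inside the gene (emulating a private haplotype block); 80 unlinked
background SNVs at allele frequency 0.2; genotyping error rate 0.

Mechanics, all driven by one `numpy` Generator seeded from `SimConfig.seed`
(identical configs give byte-identical output bundles):

- the CDS is random codons (ATG start, stop end, internally stop-free);
  the target codon is kept non-homopolymeric so the planted deletion
  always has a normalized placement inside it;
- gene drop: founder parents are `het` at the causal site, each offspring
  draws one allele per parent, and each litter is resampled until its
  genotypes match the recorded affection pattern under full penetrance
  (a bounded-attempts guard turns impossible founder configurations into
  an error);
- linked-block variants copy the causal genotype map exactly (complete
  linkage, private to the case families); background variants draw founder
  alleles independently at the configured frequency and are transmitted by
  the same gene-drop rule, independently per site (no linkage among
  background variants);
- optional genotyping error replaces each genotype, independently with the
  configured probability, by a uniformly chosen different zygosity state;
  the truth channel keeps the error-free genotypes.

What the generator does **not** emulate: read-level evidence (depths,
qualities, strand bias), linkage disequilibrium among background variants,
recombination within the private block, population structure, de novo
mutation, reduced penetrance.  A passing recovery test therefore shows the
filter logic is correct under the stated model, not that it is robust to
real call-set artefacts beyond the simple genotype-error model.

## Numerical and design choices

- `max_gap` for single-linkage clustering defaults to 100 kb; the study
  candidates (gaps 1,134 / 51,753 / 39 bp) form one cluster at that
  setting, and the parameter is exposed everywhere.
- No quality or depth thresholds are applied by default; a user predicate
  hook on the filter accepts arbitrary pre-filters.
- Report rows are sorted by (chrom, pos) with a fixed column order, and
  nothing in the pipeline path draws randomness, so identical inputs give
  byte-identical reports.
- Problem sizes used by the shipped checks: the full default cohort
  (15 samples, 84 variant records) for end-to-end runs; 100 seeded cohorts
  for the recovery rate; 10,000 gene drops for the Mendelian 1:2:1
  chi-square check; 500 random sequences for the translation oracle.
- The `fixture` CLI emits the study bundle in slice-local coordinates
  (120-kb window; offset recorded in `info.json`) so the emitted FASTA
  stays small and the bundle is directly runnable; library code uses
  absolute coordinates via an offset window accessor.

## Known limitations

- One transcript per gene is annotated per run (no multi-transcript
  prioritization); overlapping genes each get a report row through their
  own model only via the first listed gene id.
- Structural and symbolic alleles are rejected, not interpreted.
- Edits spanning splice junctions are unsupported by design.
- The recessive preset is the only inheritance model; dominant, X-linked
  and compound-heterozygous patterns are out of scope.
- Region tags for positions inside a gene but outside the modelled
  transcript follow the supplied annotation's geometry; with a different
  transcript model the non-coding tags could differ.
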