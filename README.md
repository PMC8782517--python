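# pedvar

Pedigree-aware variant filtering and coding-consequence annotation for
Mendelian recessive disease mapping in small family cohorts — the analysis
pattern used to map a 1-bp *HACE1* deletion causing hereditary cerebellar
ataxia in the Norwegian elkhound black.

## The problem

A fully penetrant autosomal recessive trait in a handful of nuclear families
imposes a hard genotype pattern at the causal site of a multi-sample call
set:

| analysis role            | required genotype state      |
| ------------------------ | ---------------------------- |
| obligate carrier parent  | heterozygous (0/1)           |
| affected case            | homozygous alternate (1/1)   |
| unaffected sibling       | not homozygous alternate     |
| unrelated control        | homozygous reference (0/0)   |

With three case trios, three sequenced healthy littermates and three
unrelated controls, a whole-genome call set restricted to gene regions
collapses to a few closely linked private variants on the shared causal
haplotype.  `pedvar` implements this filter and the downstream molecular
interpretation:

- **pedigree model** — PED IO, litter structure, role assignment from the
  sequencing design, validation (cycles, parental sex, missing parents);
- **variant IO** — multi-sample VCF read/write (pysam), multiallelic
  splitting, parsimonious left-aligned indel normalization, and HGVS-style
  display names (deletion positioned at the 3'-most forward-strand
  placement, base letter reported on the gene's coding strand, e.g.
  `62282767delG` for the VCF record `12:62282766 AC>A` in a reverse-strand
  gene);
- **segregation filter** — genotype-state matching against the recessive
  model with strict or permissive missing-genotype policy, gene-region
  restriction, and single-linkage clustering of linked candidates;
- **consequence annotation** — CDS assembly from GFF3 + FASTA on either
  strand, genomic↔CDS projection, standard-code translation, classification
  (synonymous / missense / frameshift / stop-gain / in-frame indel /
  non-coding), frameshift arithmetic (first affected codon, novel residues,
  premature stop codon and its exon) and protein-domain impact
  (retained / truncated / lost);
- **synthetic cohorts** — a seeded generator producing complete
  FASTA/GFF3/PED/VCF bundles with a planted causal variant, a linked private
  block, background variants and optional genotyping error, plus a truth
  channel for recovery testing.

The package also ships the study cohort as a fixture: the five-litter
pedigree (18 offspring, 8 affected, with the dam of litter 5 herself an
offspring of litter 1), the four CFA12 candidate sites, and a synthetic
stand-in for the *HACE1* transcript engineered to the published gene facts
(24 exons, reverse strand, 877-residue protein; deletion at codon 333 in
exon 11 → frameshift, 33 novel residues, premature stop in exon 12,
truncation to 366 residues, loss of the catalytic HECT domain).

## Worked example

Simulate a cohort (3 families × 4 + 3 controls, 24-exon reverse-strand
gene, causal 1-bp deletion at codon 333, 3 linked private variants, 80
background variants at allele frequency 0.2) and run the pipeline:

```sh
$ pedvar simulate --seed 42 --out cohort
wrote cohort bundle to /tmp/demo/cohort
causal variant: {'chrom': '1', 'pos': 79956, 'ref': 'CA', 'alt': 'C'}

$ pedvar run --vcf cohort/cohort.vcf --ped cohort/cohort.ped \
    --roles cohort/roles.tsv --gff3 cohort/genes.gff3 \
    --fasta cohort/reference.fa --out results
 cluster chrom   pos ref alt        name    gene   region consequence                                                                                         protein_effect
       1     1 61966   A   C  1:61966T>G simgene  exon 24    missense                                                                                  missense at codon 847
       1     1 72178   G   A  1:72178C>T simgene intronic    intronic                                                                                                      -
       1     1 79956  CA   C 1:79957delT simgene  exon 10  frameshift frameshift at codon 333; protein 877->343 aa; 10 novel residues; premature stop at codon 344 (exon 10)
       1     1 89164   G   A  1:89164C>T simgene intronic    intronic                                                                                                      -
report: results/report.tsv
```

Of 84 input variants, exactly the planted causal deletion and its three
linked private variants survive the recessive filter; they form one cluster,
and the causal record is classified as a frameshift at the target codon.
(A genotype-summary column, identical for all four rows here —
`carrier_parents:het=6;cases:hom_alt=3;siblings:het=3;controls:hom_ref=3`
— is elided above for width.)

The packaged study fixture runs the same way:

```sh
pedvar fixture --out fix
pedvar run --vcf fix/cohort.vcf --ped fix/cohort.ped --roles fix/roles.tsv \
    --gff3 fix/genes.gff3 --fasta fix/reference.fa \
    --domains fix/domains.tsv --out study_results
```

which reports one cluster of four candidates: two non-coding sites, the
synonymous exon-11 SNV, and the frameshift deletion
(`12:62282767delG`, protein 877→366 aa, 33 novel residues, premature stop
in exon 12, `HECT=lost`).

Other subcommands: `pedvar filter` (candidate VCF + TSV only) and
`pedvar annotate` (consequence TSV for an arbitrary VCF).

## Layout

```
src/pedvar/
  pedigree.py     PED IO, roles, validation
  variants.py     VCF IO, normalization, HGVS-style names
  segregation.py  recessive-model filter, gene restriction, clustering
  genes.py        GFF3 gene models, CDS assembly, coordinate maps
  consequence.py  translation, consequence classes, domain impact
  simulate.py     seeded synthetic cohort generator
  studycase.py    packaged study cohort + synthetic study transcript
  pipeline.py     end-to-end orchestration and reporting
  cli.py          `pedvar` command-line interface
```

See `docs/methods.md` for the model, conventions and limitations.
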