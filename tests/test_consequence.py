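"""CDS assembly, coordinate projection, translation and consequence calls."""

import random

import pytest

from pedvar.consequence import (
    ConsequenceClass,
    DomainAnnotation,
    apply_variant_to_cds,
    classify_consequence,
    domain_impact,
    project_variant,
    translate,
)
from pedvar.genes import CodingMap, GeneModel, build_cds, load_gene_models, write_gff3
from pedvar.reference import WindowReference, revcomp, write_fasta
from pedvar.variants import UnsupportedVariantError, VariantRecord
from conftest import TOY_CDS, make_toy_gene

# independent codon-table oracle (hand-written, not derived from Biopython)
_ORACLE_TABLE = {}
_BASES = "TCAG"
_AAS = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(
    (a, b, c) for a in _BASES for b in _BASES for c in _BASES
):
    _ORACLE_TABLE[_a + _b + _c] = _AAS[_i]


def oracle_translate(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = _ORACLE_TABLE[seq[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


class TestBuildCds:
    def test_forward_is_plain_concatenation(self, toy_forward):
        model, ref = toy_forward
        cds, _ = build_cds(model, ref)
        concat = "".join(ref.fetch("t", s, e) for s, e in model.cds_segments)
        assert cds == concat == TOY_CDS

    def test_reverse_equals_string_surgery_oracle(self, toy_reverse):
        model, ref = toy_reverse
        cds, _ = build_cds(model, ref)
        concat = "".join(ref.fetch("t", s, e) for s, e in model.cds_segments)
        assert cds == revcomp(concat) == TOY_CDS

    def test_strand_involution(self, toy_reverse):
        # declaring the same segments '+' and reverse-complementing equals
        # the '-' assembly
        model, ref = toy_reverse
        as_plus = GeneModel(
            gene_id="toy", transcript_id="toy-plus", chrom="t", strand="+",
            exons=list(model.exons), cds_segments=list(model.cds_segments),
        )
        with pytest.warns(UserWarning):  # '+' reading is not a clean ORF
            plus_cds, _ = build_cds(as_plus, ref)
        minus_cds, _ = build_cds(model, ref)
        assert minus_cds == revcomp(plus_cds)

    def test_flags_non_multiple_of_three(self, toy_forward):
        model, ref = toy_forward
        bad = GeneModel(
            gene_id="toy", transcript_id="toy-bad", chrom="t", strand="+",
            exons=list(model.exons),
            cds_segments=[(s, e - 1 if (s, e) == model.cds_segments[-1] else e)
                          for s, e in model.cds_segments],
        )
        with pytest.warns(UserWarning, match="divisible"):
            build_cds(bad, ref)
        assert bad.flagged


class TestCodingMap:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_bijective(self, strand):
        model, _ = make_toy_gene(strand)
        cmap = CodingMap(model)
        genomic = [cmap.genomic_pos(i) for i in range(1, len(cmap) + 1)]
        assert len(set(genomic)) == len(cmap)
        for i, g in enumerate(genomic, 1):
            assert cmap.cds_pos("t", g) == i

    def test_reverse_cds1_is_greatest_genomic(self, toy_reverse):
        model, _ = toy_reverse
        cmap = CodingMap(model)
        all_cds_bases = [p for s, e in model.cds_segments for p in range(s, e + 1)]
        assert cmap.genomic_pos(1) == max(all_cds_bases)


class TestGff3RoundTrip:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_write_then_load(self, tmp_path, strand):
        model, ref = make_toy_gene(strand)
        gff = write_gff3([model], tmp_path / "toy.gff3",
                         sequence_regions={"t": (1, len(ref.seq))})
        fasta = write_fasta({"t": ref.seq}, tmp_path / "toy.fa")
        models, fref = load_gene_models(gff, fasta)
        assert len(models) == 1
        loaded = models[0]
        assert loaded.strand == strand
        assert loaded.exons == model.exons
        assert loaded.cds_segments == model.cds_segments
        cds, _ = build_cds(loaded, fref)
        assert cds == TOY_CDS


class TestTranslate:
    def test_minimal(self):
        assert translate("ATGTAA") == "M"

    def test_trailing_partial_codon_ignored(self):
        assert translate("ATGGATTA") == translate("ATGGAT") == "MD"

    def test_matches_codon_table_oracle(self):
        rng = random.Random(0)
        for _ in range(500):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 120)))
            assert translate(seq) == oracle_translate(seq)


class TestProjectVariant:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_every_cds_position_matches_enumeration(self, strand):
        model, ref = make_toy_gene(strand)
        cds, cmap = build_cds(model, ref)
        for cds_pos in range(1, len(cds) + 1):
            g = cmap.genomic_pos(cds_pos)
            base = ref.fetch("t", g, g)
            alt = "A" if base != "A" else "G"
            proj = project_variant(VariantRecord("t", g, base, (alt,)), cmap)
            assert proj.region == "cds"
            assert proj.cds_pos == cds_pos
            assert proj.codon_index == (cds_pos + 2) // 3

    def test_intronic(self, toy_forward):
        model, ref = toy_forward
        cmap = CodingMap(model)
        pos = model.exons[0][1] + 2  # inside intron 1
        base = ref.fetch("t", pos, pos)
        proj = project_variant(
            VariantRecord("t", pos, base, ("A" if base != "A" else "C",)), cmap
        )
        assert proj.region == "intronic"

    def test_chrom_mismatch_is_intergenic(self, toy_forward):
        model, _ = toy_forward
        cmap = CodingMap(model)
        proj = project_variant(VariantRecord("other", 5, "A", ("G",)), cmap)
        assert proj.region == "intergenic"


class TestApplyVariant:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_snvs_match_string_surgery(self, strand):
        model, ref = make_toy_gene(strand)
        cds, cmap = build_cds(model, ref)
        rng = random.Random(4)
        for _ in range(50):
            cds_pos = rng.randint(1, len(cds))
            g = cmap.genomic_pos(cds_pos)
            fwd_ref = ref.fetch("t", g, g)
            fwd_alt = rng.choice([b for b in "ACGT" if b != fwd_ref])
            rec = VariantRecord("t", g, fwd_ref, (fwd_alt,))
            mutant = apply_variant_to_cds(cds, cmap, rec)
            coding_alt = fwd_alt if strand == "+" else revcomp(fwd_alt)
            expected = cds[: cds_pos - 1] + coding_alt + cds[cds_pos:]
            assert mutant == expected

    def test_intronic_edit_returns_cds_unchanged(self, toy_forward):
        model, ref = toy_forward
        cds, cmap = build_cds(model, ref)
        pos = model.exons[0][1] + 2
        base = ref.fetch("t", pos, pos)
        rec = VariantRecord("t", pos, base, ("A" if base != "A" else "C",))
        assert apply_variant_to_cds(cds, cmap, rec) == cds

    def test_junction_spanning_edit_unsupported(self, toy_forward):
        model, ref = toy_forward
        cds, cmap = build_cds(model, ref)
        end = model.exons[0][1]
        ref_seq = ref.fetch("t", end, end + 1)  # last exon base + first intron base
        rec = VariantRecord("t", end, ref_seq, (ref_seq[0],))
        with pytest.raises(UnsupportedVariantError, match="junction"):
            apply_variant_to_cds(cds, cmap, rec)


class TestClassifyConsequence:
    def test_snv_to_stop_is_stop_gain(self, toy_forward):
        model, ref = toy_forward
        # codon 2 GAT -> TAT? need a stop: GAT -> TAG impossible in one base;
        # codon 3 TAC -> TAA (C->A at cds position 9)
        cds, cmap = build_cds(model, ref)
        g = cmap.genomic_pos(9)
        rec = VariantRecord("t", g, "C", ("A",))
        cons = classify_consequence(model, ref, rec)
        assert cons.consequence_class is ConsequenceClass.STOP_GAIN
        assert cons.mut_protein_length == 2
        assert cons.stop_codon_index == 3
        # oracle: direct translation of the edited CDS
        assert translate(cds[:8] + "A" + cds[9:]) == "MD"

    def test_synonymous_snv(self, toy_reverse):
        model, ref = toy_reverse
        cds, cmap = build_cds(model, ref)
        # codon 2 GAT -> GAC is still Asp; cds position 6 T>C, reverse strand
        g = cmap.genomic_pos(6)
        fwd_ref = ref.fetch("t", g, g)
        rec = VariantRecord("t", g, fwd_ref, (revcomp("C"),))
        cons = classify_consequence(model, ref, rec)
        assert cons.consequence_class is ConsequenceClass.SYNONYMOUS
        assert cons.wt_protein_length == cons.mut_protein_length == 6

    def test_inframe_deletion_is_not_frameshift(self, toy_forward):
        model, ref = toy_forward
        cds, cmap = build_cds(model, ref)
        # delete codon 2 (cds 4-6) entirely: anchor at cds 3, ref spans 3-6
        g_anchor = cmap.genomic_pos(3)
        ref_seq = ref.fetch("t", g_anchor, g_anchor + 3)
        rec = VariantRecord("t", g_anchor, ref_seq, (ref_seq[0],))
        cons = classify_consequence(model, ref, rec)
        assert cons.consequence_class is not ConsequenceClass.FRAMESHIFT
        assert cons.consequence_class is ConsequenceClass.INFRAME_INDEL
        assert cons.mut_protein_length == cons.wt_protein_length - 1

    def test_frameshift_invariants_on_random_deletions(self, toy_forward):
        model, ref = toy_forward
        cds, cmap = build_cds(model, ref)
        rng = random.Random(11)
        seen_frameshift = False
        for _ in range(40):
            cds_pos = rng.randint(2, len(cds) - 1)
            g = cmap.genomic_pos(cds_pos)
            if cmap.cds_pos("t", g - 1) is None or cmap.cds_pos("t", g + 1) is None:
                continue
            anchor = ref.fetch("t", g - 1, g - 1)
            rec = VariantRecord(
                "t", g - 1, anchor + ref.fetch("t", g, g), (anchor,)
            )
            try:
                cons = classify_consequence(model, ref, rec)
            except UnsupportedVariantError:
                continue
            if cons.consequence_class is not ConsequenceClass.FRAMESHIFT:
                continue
            seen_frameshift = True
            assert (
                cons.wt_protein_length
                - cons.mut_protein_length
                + (cons.novel_residue_count or 0)
                >= 0
            )
            if cons.stop_codon_index is not None:
                assert cons.mut_protein_length == cons.stop_codon_index - 1
                assert cons.first_affected_codon <= cons.stop_codon_index
                assert (cons.novel_residue_count or 0) <= cons.mut_protein_length
        assert seen_frameshift

    def test_noncoding_classes(self, toy_forward):
        model, ref = toy_forward
        pos = model.exons[0][1] + 2
        base = ref.fetch("t", pos, pos)
        cons = classify_consequence(
            model, ref, VariantRecord("t", pos, base, ("A" if base != "A" else "C",))
        )
        assert cons.consequence_class is ConsequenceClass.INTRONIC
        assert cons.wt_protein_length == cons.mut_protein_length == 6


class TestDomainImpact:
    def test_random_pairs_match_interval_oracle(self):
        rng = random.Random(2)
        wt = 877
        for _ in range(1000):
            mut = rng.randint(0, wt)
            start = rng.randint(1, wt)
            end = rng.randint(start, wt)
            cons_stub = type(
                "C", (), {"wt_protein_length": wt, "mut_protein_length": mut}
            )()
            got = domain_impact(
                cons_stub, DomainAnnotation("p", [("d", start, end)])
            )["d"]
            if start > mut:
                assert got == "lost"
            elif end > mut:
                assert got == "truncated_partial"
            else:
                assert got == "retained"

    def test_full_length_protein_retains_all(self):
        cons_stub = type(
            "C", (), {"wt_protein_length": 100, "mut_protein_length": 100}
        )()
        ann = DomainAnnotation("p", [("a", 1, 50), ("b", 51, 100)])
        assert set(domain_impact(cons_stub, ann).values()) == {"retained"}

    def test_out_of_bounds_domain_is_error(self):
        cons_stub = type(
            "C", (), {"wt_protein_length": 100, "mut_protein_length": 50}
        )()
        with pytest.raises(ValueError, match="exceed"):
            domain_impact(cons_stub, DomainAnnotation("p", [("d", 10, 101)]))
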