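"""Genotype states, model matching, filtering, gene restriction, clustering."""

import itertools
import random

import pytest

from pedvar.pedigree import Role, RoleAssignment
from pedvar.segregation import (
    NOT_HOM_ALT,
    CandidateVariant,
    GenotypeState,
    SegregationModel,
    cluster_linked,
    genotype_state,
    matches_model,
    restrict_to_genes,
    segregation_filter,
)
from pedvar.simulate import SimConfig, simulate_cohort
from pedvar.variants import Genotype, VariantError, VariantRecord

S = GenotypeState
STATE_GT = {
    S.HOM_REF: Genotype((0, 0)),
    S.HET: Genotype((0, 1)),
    S.HOM_ALT: Genotype((1, 1)),
    S.MISSING: Genotype.missing(),
}
ROLES4 = RoleAssignment(
    {
        "parent": Role.OBLIGATE_CARRIER_PARENT,
        "case": Role.AFFECTED_CASE,
        "sib": Role.UNAFFECTED_SIBLING,
        "ctrl": Role.UNRELATED_CONTROL,
    }
)


def record_for(states: dict[str, GenotypeState]) -> VariantRecord:
    return VariantRecord(
        "1", 100, "A", ("G",), {s: STATE_GT[st] for s, st in states.items()}
    )


class TestGenotypeState:
    def test_enumeration_oracle(self):
        # all 9 ordered diploid genotypes over {0, 1, .}
        for a, b in itertools.product([0, 1, None], repeat=2):
            got = genotype_state(Genotype((a, b)))
            if a is None or b is None:
                expected = S.MISSING
            elif a == b == 0:
                expected = S.HOM_REF
            elif a == b == 1:
                expected = S.HOM_ALT
            else:
                expected = S.HET
            assert got is expected

    def test_phase_insensitive(self):
        assert genotype_state(Genotype((1, 0))) is S.HET
        assert genotype_state(Genotype((0, 1))) is S.HET


class TestMatchesModel:
    def test_causal_pattern_matches(self):
        rec = record_for(
            {"parent": S.HET, "case": S.HOM_ALT, "sib": S.HET, "ctrl": S.HOM_REF}
        )
        assert matches_model(rec, ROLES4, SegregationModel.autosomal_recessive())

    def test_het_case_fails(self):
        rec = record_for(
            {"parent": S.HET, "case": S.HET, "sib": S.HET, "ctrl": S.HOM_REF}
        )
        assert not matches_model(rec, ROLES4, SegregationModel.autosomal_recessive())

    @pytest.mark.parametrize("policy", ["strict", "permissive"])
    def test_exhaustive_state_vectors_match_set_oracle(self, policy):
        # brute-force set-membership oracle over all 4^4 state vectors of a
        # reduced one-sample-per-role cohort
        model = SegregationModel.autosomal_recessive(policy)
        allowed = {
            "parent": {S.HET},
            "case": {S.HOM_ALT},
            "sib": {S.HOM_REF, S.HET},
            "ctrl": {S.HOM_REF},
        }
        if policy == "permissive":
            allowed = {
                k: (v | {S.MISSING} if v >= NOT_HOM_ALT else v)
                for k, v in allowed.items()
            }
        samples = list(ROLES4.roles)
        for vector in itertools.product(list(S), repeat=4):
            states = dict(zip(samples, vector))
            expected = all(states[s] in allowed[s] for s in samples)
            assert matches_model(record_for(states), ROLES4, model) == expected

    def test_absent_constrained_sample_is_error(self):
        rec = VariantRecord("1", 1, "A", ("G",), {"parent": Genotype((0, 1))})
        with pytest.raises(VariantError, match="absent"):
            matches_model(rec, ROLES4, SegregationModel.autosomal_recessive())

    def test_strict_missing_excludes(self):
        rec = record_for(
            {"parent": S.MISSING, "case": S.HOM_ALT, "sib": S.HET, "ctrl": S.HOM_REF}
        )
        assert not matches_model(rec, ROLES4, SegregationModel.autosomal_recessive())


def random_pattern_records(seed: int, n: int = 40) -> list[VariantRecord]:
    rng = random.Random(seed)
    out = []
    for i in range(n):
        states = {s: rng.choice(list(S)) for s in ROLES4.roles}
        rec = record_for(states)
        rec.pos = 10 * (i + 1)
        out.append(rec)
    return out


class TestSegregationFilter:
    def test_output_is_subset_and_idempotent(self):
        model = SegregationModel.autosomal_recessive()
        records = random_pattern_records(1)
        once = segregation_filter(records, ROLES4, model)
        assert [c.record for c in once] == [
            r for r in records if matches_model(r, ROLES4, model)
        ]
        twice = segregation_filter([c.record for c in once], ROLES4, model)
        assert [c.record for c in twice] == [c.record for c in once]

    def test_empty_input(self):
        assert segregation_filter([], ROLES4, SegregationModel.autosomal_recessive()) == []

    def test_sample_column_permutation_invariance(self):
        model = SegregationModel.autosomal_recessive()
        for seed in range(10):
            records = random_pattern_records(seed)
            baseline = [c.pos for c in segregation_filter(records, ROLES4, model)]
            rng = random.Random(seed)
            shuffled = []
            for rec in records:
                keys = list(rec.genotypes)
                rng.shuffle(keys)
                shuffled.append(
                    VariantRecord(
                        rec.chrom, rec.pos, rec.ref, rec.alts,
                        {k: rec.genotypes[k] for k in keys},
                    )
                )
            assert [c.pos for c in segregation_filter(shuffled, ROLES4, model)] == baseline

    def test_relaxing_sibling_constraint_is_monotone(self):
        strictm = SegregationModel.autosomal_recessive()
        relaxed = SegregationModel(
            name="autosomal_recessive",
            constraints={
                **strictm.constraints,
                Role.UNAFFECTED_SIBLING: frozenset(
                    {S.HOM_REF, S.HET, S.HOM_ALT}
                ),
            },
        )
        for seed in range(5):
            records = random_pattern_records(seed)
            narrow = {c.pos for c in segregation_filter(records, ROLES4, strictm)}
            wide = {c.pos for c in segregation_filter(records, ROLES4, relaxed)}
            assert narrow <= wide

    def test_user_predicate_hook(self):
        model = SegregationModel.autosomal_recessive()
        records = random_pattern_records(2)
        kept = segregation_filter(records, ROLES4, model, predicate=lambda r: r.pos > 200)
        assert all(c.pos > 200 for c in kept)

    def test_planted_variant_recovered(self, default_cohort):
        sim = default_cohort
        cands = segregation_filter(
            sim.records, sim.roles, SegregationModel.autosomal_recessive()
        )
        assert sim.truth["causal"]["pos"] in {c.pos for c in cands}

    def test_recovery_degrades_with_genotype_error(self):
        model = SegregationModel.autosomal_recessive()
        clean = errored = 0
        n = 40
        for seed in range(n):
            sim0 = simulate_cohort(SimConfig(seed=seed, n_background=5))
            sim1 = simulate_cohort(
                SimConfig(seed=seed, n_background=5, genotype_error_rate=0.05)
            )
            for sim, bump in ((sim0, "clean"), (sim1, "err")):
                cands = segregation_filter(sim.records, sim.roles, model)
                hit = sim.truth["causal"]["pos"] in {c.pos for c in cands}
                if bump == "clean":
                    clean += hit
                else:
                    errored += hit
        assert clean == n
        assert errored < n


class _Span:
    def __init__(self, gene_id, chrom, start, end):
        self.gene_id, self.chrom = gene_id, chrom
        self.gene_start, self.gene_end = start, end


def _cand(chrom: str, pos: int) -> CandidateVariant:
    return CandidateVariant(record=VariantRecord(chrom, pos, "A", ("G",)))


class TestRestrictToGenes:
    def test_study_gene_span_retains_candidate(self, study_gene):
        model, _ = study_gene
        kept = restrict_to_genes([_cand("12", 62282766)], [model])
        assert len(kept) == 1 and kept[0].gene_ids == ["HACE1"]

    def test_boundary_exclusion(self, study_gene):
        model, _ = study_gene
        assert restrict_to_genes([_cand("12", model.gene_start - 1)], [model]) == []
        assert restrict_to_genes([_cand("12", model.gene_end + 1)], [model]) == []
        assert len(restrict_to_genes([_cand("12", model.gene_start)], [model])) == 1

    def test_fuzzed_intervals_match_naive_scan(self):
        rng = random.Random(5)
        for _ in range(20):
            genes = [
                _Span(f"g{i}", "1", s, s + rng.randint(0, 500))
                for i, s in enumerate(rng.sample(range(1, 10_000), 8))
            ]
            cands = [_cand("1", rng.randint(1, 11_000)) for _ in range(50)]
            got = {c.pos for c in restrict_to_genes(cands, genes)}
            expected = {
                c.pos
                for c in cands
                if any(g.gene_start <= c.pos <= g.gene_end for g in genes)
            }
            assert got == expected


class TestClusterLinked:
    def test_study_positions_form_one_cluster(self):
        # gaps between consecutive sites: 1134, 51753, 39 — all within 100 kb
        cands = [_cand("12", p) for p in (62229840, 62230974, 62282727, 62282766)]
        clusters = cluster_linked(cands, max_gap=100_000)
        assert len(clusters) == 1
        assert len(clusters[0]) == 4
        assert clusters[0].span == (62229840, 62282766)

    def test_singleton(self):
        clusters = cluster_linked([_cand("1", 5)], max_gap=10)
        assert len(clusters) == 1 and len(clusters[0]) == 1

    def test_gap_boundary(self):
        a, b = _cand("1", 100), _cand("1", 201)
        assert len(cluster_linked([a, b], max_gap=101)) == 1
        assert len(cluster_linked([a, b], max_gap=100)) == 2

    def test_chromosome_change_breaks_cluster(self):
        clusters = cluster_linked([_cand("1", 100), _cand("2", 101)], max_gap=1000)
        assert len(clusters) == 2
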