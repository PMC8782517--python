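"""Recessive-model segregation filtering, gene restriction and clustering.

The filter keeps variants whose cohort genotype pattern is consistent with a
fully penetrant autosomal recessive trait: obligate carrier parents are
heterozygous, affected cases homozygous for the alternate allele, unaffected
siblings anything but homozygous alternate, and unrelated controls homozygous
reference.  With three case trios plus sequenced siblings and three controls
this pattern is stringent enough to reduce a whole-genome call set to a
handful of linked private variants around the causal site.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .pedigree import Role, RoleAssignment
from .variants import Genotype, VariantRecord, VariantError


class GenotypeState(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


# pseudo-state used only in model constraints
NOT_HOM_ALT = frozenset({GenotypeState.HOM_REF, GenotypeState.HET})


def genotype_state(genotype: Genotype) -> GenotypeState:
    """Collapse a diploid genotype to its zygosity state, phase-insensitive.

    Any missing allele makes the whole genotype missing; after multiallelic
    splitting this also covers calls to a foreign alternate allele.
    """
    if genotype.is_missing:
        return GenotypeState.MISSING
    n_alt = sum(1 for a in genotype.alleles if a != 0)
    if n_alt == 0:
        return GenotypeState.HOM_REF
    if n_alt == len(genotype.alleles):
        return GenotypeState.HOM_ALT
    return GenotypeState.HET


@dataclass(frozen=True)
class SegregationModel:
    """Map from analysis role to the set of genotype states it may show.

    ``missing_policy`` controls how a missing genotype in a constrained
    sample is judged: ``strict`` fails every constraint (conservative, the
    default); ``permissive`` lets a missing call satisfy only constraints
    that already allow every non-hom-alt state (i.e. ``not_hom_alt``).
    """

    name: str
    constraints: dict[Role, frozenset[GenotypeState]]
    missing_policy: str = "strict"

    def __post_init__(self) -> None:
        if self.missing_policy not in ("strict", "permissive"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")

    @classmethod
    def autosomal_recessive(cls, missing_policy: str = "strict") -> "SegregationModel":
        return cls(
            name="autosomal_recessive",
            constraints={
                Role.OBLIGATE_CARRIER_PARENT: frozenset({GenotypeState.HET}),
                Role.AFFECTED_CASE: frozenset({GenotypeState.HOM_ALT}),
                Role.UNAFFECTED_SIBLING: NOT_HOM_ALT,
                Role.UNRELATED_CONTROL: frozenset({GenotypeState.HOM_REF}),
            },
            missing_policy=missing_policy,
        )

    def allows(self, role: Role, state: GenotypeState) -> bool:
        allowed = self.constraints.get(role)
        if allowed is None:
            return True
        if state is GenotypeState.MISSING:
            return self.missing_policy == "permissive" and allowed >= NOT_HOM_ALT
        return state in allowed


@dataclass
class CandidateVariant:
    """A variant passing the segregation filter, with its per-sample states."""

    record: VariantRecord
    matched_states: dict[str, GenotypeState] = field(default_factory=dict)
    gene_ids: list[str] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.record.chrom

    @property
    def pos(self) -> int:
        return self.record.pos


@dataclass
class VariantCluster:
    chrom: str
    members: list[CandidateVariant]

    @property
    def span(self) -> tuple[int, int]:
        return self.members[0].pos, self.members[-1].pos

    def __len__(self) -> int:
        return len(self.members)


def matches_model(
    record: VariantRecord,
    roles: RoleAssignment,
    model: SegregationModel,
) -> bool:
    """True iff every role-constrained sample's genotype state is allowed.

    Every constrained sample must be present in the record's genotype map;
    an absent sample is a hard error rather than silently unconstrained.
    """
    for sample in roles.constrained_samples():
        role = roles[sample]
        if role not in model.constraints:
            continue
        if sample not in record.genotypes:
            raise VariantError(
                f"sample {sample!r} (role {role.value}) absent from record "
                f"{record.chrom}:{record.pos}"
            )
        if not model.allows(role, genotype_state(record.genotypes[sample])):
            return False
    return True


def segregation_filter(
    records: Iterable[VariantRecord],
    roles: RoleAssignment,
    model: SegregationModel,
    predicate: Callable[[VariantRecord], bool] | None = None,
) -> list[CandidateVariant]:
    """Select the records matching the segregation model, preserving order.

    ``predicate`` is an optional user hook (e.g. a quality/depth filter)
    applied before the genotype-pattern test; no quality thresholds are
    applied by default.
    """
    out: list[CandidateVariant] = []
    for rec in records:
        if predicate is not None and not predicate(rec):
            continue
        if matches_model(rec, roles, model):
            out.append(
                CandidateVariant(
                    record=rec,
                    matched_states={
                        s: genotype_state(rec.genotypes[s])
                        for s in roles.constrained_samples()
                    },
                )
            )
    return out


def restrict_to_genes(
    candidates: Sequence[CandidateVariant],
    gene_models: Sequence,
) -> list[CandidateVariant]:
    """Keep candidates whose position falls inside any gene's [start, end].

    Gene models need ``chrom``, ``gene_start``, ``gene_end`` and ``gene_id``
    attributes (1-based inclusive span).  Overlapping gene ids are attached
    to each retained candidate.
    """
    out = []
    for cand in candidates:
        hits = [
            g.gene_id
            for g in gene_models
            if g.chrom == cand.chrom and g.gene_start <= cand.pos <= g.gene_end
        ]
        if hits:
            cand.gene_ids = hits
            out.append(cand)
    return out


def cluster_linked(
    candidates: Sequence[CandidateVariant],
    max_gap: int = 100_000,
) -> list[VariantCluster]:
    """Single-linkage chaining of candidates along the genome.

    A new cluster starts when the chromosome changes or the gap to the
    previous candidate exceeds ``max_gap`` base pairs.
    """
    ordered = sorted(candidates, key=lambda c: (c.chrom, c.pos))
    clusters: list[VariantCluster] = []
    for cand in ordered:
        if (
            clusters
            and clusters[-1].chrom == cand.chrom
            and cand.pos - clusters[-1].members[-1].pos <= max_gap
        ):
            clusters[-1].members.append(cand)
        else:
            clusters.append(VariantCluster(chrom=cand.chrom, members=[cand]))
    return clusters
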