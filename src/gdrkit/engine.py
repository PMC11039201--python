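"""Allelic-requirement satisfaction and variant prioritization.

Given an individual's qualifying variants in a curated gene, the engine
decides whether the curation's allelic requirement is met: one qualifying
allele satisfies a monoallelic (dominant) requirement; a biallelic
(recessive) requirement needs a homozygote or a trans compound heterozygote,
a single heterozygote being only a candidate ("a second contributory variant
or alternative cause should be sought"); X-linked recessive disease manifests
if hemizygous in males or biallelic in females, a single heterozygous female
being a carrier; Y-linked and mitochondrial requirements check the obvious
chromosome contexts; PAR requirements additionally require the variant to
fall in a pseudoautosomal interval and then count copies autosomally.

Inheritance qualifiers annotate (and in one case downgrade) the decision:
"requires heterozygosity" downgrades hemizygous-male satisfaction, imprinting
direction is checked against parental origin, "typically de novo" and
sex-limited expression add supportive/cautionary flags, and penetrance /
onset / anticipation qualifiers are purely informational.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .annotate import AnnotatedVariant, annotate_variants, read_variants
from .curation import GeneDiseaseCuration
from .matrix import ConsequenceMatrix, DEFAULT_SUGGESTION_THRESHOLD, default_matrix
from .terms import Vocabulary, build_vocabulary
from .transcripts import TranscriptModel

__all__ = [
    "PARConfig",
    "SampleContext",
    "GenotypeObservation",
    "RequirementDecision",
    "QualifyingVariant",
    "qualifying_variants",
    "evaluate_requirement",
    "apply_qualifiers",
    "prioritize",
    "RATIONALE_CODES",
]

# The fixed set of rationale codes a decision may carry.
RATIONALE_CODES = frozenset(
    {
        "no_qualifying_variants",
        "monoallelic_satisfied",
        "hemizygous_satisfies",
        "homozygous_satisfies_biallelic",
        "single_het_recessive",
        "possible_compound_het_phase_unknown",
        "compound_het_trans",
        "cis_pair_single_allele",
        "het_carrier_only",
        "karyotype_incompatible",
        "unknown_karyotype",
        "not_in_par",
        "mitochondrial_variant",
        "homozygous_under_dominant",
        "consequences_inferred_from_known_classes",
        "no_transcript_model",
        "non_mendelian_requirement",
    }
)

_STATUS_ORDER = {"unsatisfied": 0, "candidate_partial": 1, "satisfied": 2}


@dataclass(frozen=True)
class PARConfig:
    """Pseudoautosomal intervals (0-based half-open), X and Y only."""

    genome_build_label: str
    par_intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for chrom, start, end in self.par_intervals:
            if _norm_chrom(chrom) not in ("X", "Y"):
                raise ValueError(f"PAR interval on non-sex chromosome {chrom!r}")
            if not 0 <= start < end:
                raise ValueError(f"bad PAR interval ({chrom}, {start}, {end})")

    def contains(self, chromosome: str, position_1based: int) -> bool:
        c = _norm_chrom(chromosome)
        p0 = position_1based - 1
        return any(
            _norm_chrom(chrom) == c and start <= p0 < end
            for chrom, start, end in self.par_intervals
        )

    @classmethod
    def from_bed(cls, path, genome_build_label: str = "custom") -> "PARConfig":
        intervals = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, *_ = line.split("\t")
            intervals.append((chrom, int(start), int(end)))
        return cls(genome_build_label, tuple(intervals))

    @classmethod
    def default_grch38(cls) -> "PARConfig":
        path = resources.files("gdrkit.data").joinpath("par_grch38.bed")
        with resources.as_file(path) as p:
            return cls.from_bed(p, genome_build_label="GRCh38")


def _norm_chrom(chrom: str) -> str:
    c = chrom.removeprefix("chr").upper()
    return "MT" if c in ("M", "MT") else c


@dataclass(frozen=True)
class SampleContext:
    sample_id: str
    sex_karyotype: str = "unknown"  # XX | XY | unknown
    trio_available: bool = False
    par_config: Optional[PARConfig] = None

    def __post_init__(self) -> None:
        if self.sex_karyotype not in ("XX", "XY", "unknown"):
            raise ValueError(f"sex_karyotype must be XX, XY or unknown, got {self.sex_karyotype!r}")

    @property
    def par(self) -> PARConfig:
        return self.par_config or PARConfig.default_grch38()


@dataclass(frozen=True)
class GenotypeObservation:
    """One qualifying variant observation in the curated gene."""

    annotated_variant: Optional[AnnotatedVariant]
    zygosity: str  # heterozygous | homozygous_alt | hemizygous
    chromosome: str = ""
    position: int = 0
    phase_set: Optional[str] = None
    haplotype: Optional[int] = None
    parental_origin: Optional[str] = None
    de_novo_status: Optional[str] = None
    heteroplasmy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("heterozygous", "homozygous_alt", "hemizygous"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")

    @classmethod
    def from_annotated(cls, av: AnnotatedVariant) -> "GenotypeObservation":
        v = av.variant
        return cls(
            annotated_variant=av,
            zygosity=v.zygosity,
            chromosome=v.chromosome,
            position=v.position,
            phase_set=v.phase_set,
            haplotype=v.haplotype,
            parental_origin=v.parental_origin,
            de_novo_status=v.de_novo_status,
            heteroplasmy=v.heteroplasmy,
        )

    @property
    def label(self) -> str:
        if self.annotated_variant is not None:
            v = self.annotated_variant.variant
            return f"{v.chromosome}:{v.position}:{v.ref}>{v.alt}"
        return f"{self.chromosome}:{self.position}"


@dataclass(frozen=True)
class RequirementDecision:
    status: str  # satisfied | candidate_partial | unsatisfied
    rationale_codes: tuple[str, ...]
    contributing_variants: tuple[GenotypeObservation, ...] = ()
    qualifier_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in _STATUS_ORDER:
            raise ValueError(f"bad status {self.status!r}")
        bad = [c for c in self.rationale_codes if c not in RATIONALE_CODES]
        if bad:
            raise ValueError(f"unknown rationale code(s) {bad}")
        if self.status == "satisfied" and not self.contributing_variants:
            raise ValueError("a satisfied decision must name contributing variants")


@dataclass(frozen=True)
class QualifyingVariant:
    annotated_variant: AnnotatedVariant
    matched_consequence: str
    score: int


def qualifying_variants(
    annotated_variants: Iterable[AnnotatedVariant],
    curation: GeneDiseaseCuration,
    matrix: ConsequenceMatrix,
    threshold: int = DEFAULT_SUGGESTION_THRESHOLD,
) -> list[QualifyingVariant]:
    """Keep variants whose consequence profile reaches >= ``threshold`` for at
    least one consequence the curation asserts; record the best match."""
    asserted = sorted(curation.disease_associated_consequences)
    if not asserted:
        raise ValueError(
            "curation asserts no disease-associated consequences; derive them "
            "with infer_consequences over known_pathogenic_variant_classes"
        )
    out = []
    for av in annotated_variants:
        hits = [(av.consequence_profile[c], c) for c in asserted if av.consequence_profile[c] >= threshold]
        if hits:
            score, consequence = max(hits)
            out.append(QualifyingVariant(av, consequence, score))
    return out


# -- phase resolution ----------------------------------------------------------

def _pair_phase(a: GenotypeObservation, b: GenotypeObservation) -> str:
    """trans | cis | unknown for a pair of heterozygous observations."""
    if a.phase_set is not None and a.phase_set == b.phase_set:
        if a.haplotype is not None and b.haplotype is not None:
            return "trans" if a.haplotype != b.haplotype else "cis"
    if a.parental_origin in ("maternal", "paternal") and b.parental_origin in ("maternal", "paternal"):
        return "trans" if a.parental_origin != b.parental_origin else "cis"
    return "unknown"


def _biallelic_from_hets(
    hets: Sequence[GenotypeObservation], phase_override: Optional[str]
) -> tuple[str, list[str], tuple[GenotypeObservation, ...]]:
    """Decide a biallelic requirement from >= 1 distinct single-allele
    observations (no homozygote present)."""
    if len(hets) == 1:
        return "candidate_partial", ["single_het_recessive"], tuple(hets)
    phases = {pair: _pair_phase(*pair) for pair in combinations(hets, 2)}
    if phase_override in ("trans", "cis") and len(hets) == 2:
        phases = {pair: phase_override for pair in phases}
    trans_pairs = [pair for pair, ph in phases.items() if ph == "trans"]
    if trans_pairs:
        return "satisfied", ["compound_het_trans"], tuple(trans_pairs[0])
    if phases and all(ph == "cis" for ph in phases.values()):
        # all variants on one haplotype: a single affected allele
        return "candidate_partial", ["cis_pair_single_allele"], tuple(hets)
    return "candidate_partial", ["possible_compound_het_phase_unknown"], tuple(hets)


def evaluate_requirement(
    observations: Iterable[GenotypeObservation],
    requirement_token: str,
    sample_context: SampleContext,
    phase_info: Optional[str] = None,
    vocabulary: Optional[Vocabulary] = None,
) -> RequirementDecision:
    """Decide satisfied / candidate_partial / unsatisfied for one requirement.

    ``phase_info`` optionally overrides phase for a heterozygous pair
    ("trans" or "cis"). Requirement/karyotype impossibilities (a Y-linked
    requirement in an XX individual) yield an unsatisfied decision with a
    rationale, never an exception. With an unknown karyotype, requirements
    whose outcome depends on it are capped at candidate_partial.
    """
    vocab = vocabulary or build_vocabulary()
    requirement = vocab.lookup(requirement_token)
    obs = list(observations)
    token = requirement.token
    karyotype = sample_context.sex_karyotype

    if not obs and token != "monoallelic_Y_hemizygous":
        return RequirementDecision("unsatisfied", ("no_qualifying_variants",))

    def split(items):
        homs = [o for o in items if o.zygosity == "homozygous_alt"]
        hets = [o for o in items if o.zygosity == "heterozygous"]
        hemis = [o for o in items if o.zygosity == "hemizygous"]
        return homs, hets, hemis

    if token in ("monoallelic_autosomal",):
        return RequirementDecision("satisfied", ("monoallelic_satisfied",), tuple(obs))

    if token == "biallelic_autosomal":
        homs, hets, hemis = split(obs)
        if homs:
            return RequirementDecision("satisfied", ("homozygous_satisfies_biallelic",), tuple(homs))
        status, codes, contributing = _biallelic_from_hets(hets + hemis, phase_info)
        return RequirementDecision(status, tuple(codes), contributing)

    if token == "monoallelic_X_heterozygous":
        homs, hets, hemis = split(obs)
        codes = ["monoallelic_satisfied"]
        if hemis and not hets and not homs:
            codes = ["hemizygous_satisfies"]
        if homs and karyotype == "XX":
            codes.append("homozygous_under_dominant")
        return RequirementDecision("satisfied", tuple(codes), tuple(obs))

    if token == "monoallelic_X_hemizygous":
        homs, hets, hemis = split(obs)
        if karyotype == "XY":
            carriers = hemis or homs or hets  # any observed allele is effectively hemizygous in XY
            return RequirementDecision("satisfied", ("hemizygous_satisfies",), tuple(carriers))
        if karyotype == "XX":
            if homs:
                return RequirementDecision("satisfied", ("homozygous_satisfies_biallelic",), tuple(homs))
            if len(hets) >= 2:
                status, codes, contributing = _biallelic_from_hets(hets, phase_info)
                return RequirementDecision(status, tuple(codes), contributing)
            return RequirementDecision("unsatisfied", ("het_carrier_only",), tuple(hets))
        return RequirementDecision("candidate_partial", ("unknown_karyotype",), tuple(obs))

    if token == "monoallelic_Y_hemizygous":
        y_obs = [o for o in obs if _norm_chrom(o.chromosome) == "Y" or not o.chromosome]
        if karyotype == "XX":
            return RequirementDecision("unsatisfied", ("karyotype_incompatible",))
        if not y_obs:
            return RequirementDecision("unsatisfied", ("no_qualifying_variants",))
        if karyotype == "XY":
            return RequirementDecision("satisfied", ("hemizygous_satisfies",), tuple(y_obs))
        return RequirementDecision("candidate_partial", ("unknown_karyotype",), tuple(y_obs))

    if token == "mitochondrial":
        flags = tuple(
            f"heteroplasmy={o.heteroplasmy:g}" for o in obs if o.heteroplasmy is not None
        )
        return RequirementDecision("satisfied", ("mitochondrial_variant",), tuple(obs), flags)

    if token in ("monoallelic_PAR", "biallelic_PAR"):
        par = sample_context.par
        inside = [o for o in obs if not o.chromosome or par.contains(o.chromosome, o.position)]
        codes_extra = ["not_in_par"] if len(inside) < len(obs) else []
        if not inside:
            return RequirementDecision("unsatisfied", tuple(["no_qualifying_variants"] + codes_extra))
        if token == "monoallelic_PAR":
            return RequirementDecision(
                "satisfied", tuple(["monoallelic_satisfied"] + codes_extra), tuple(inside)
            )
        homs, hets, hemis = split(inside)
        if homs:
            return RequirementDecision(
                "satisfied", tuple(["homozygous_satisfies_biallelic"] + codes_extra), tuple(homs)
            )
        status, codes, contributing = _biallelic_from_hets(hets + hemis, phase_info)
        return RequirementDecision(status, tuple(codes + codes_extra), contributing)

    # Non-Mendelian and anything else representable but without filtering semantics
    return RequirementDecision("unsatisfied", ("non_mendelian_requirement",))


# -- qualifier application -----------------------------------------------------

def apply_qualifiers(
    decision: RequirementDecision,
    qualifiers: Iterable[str],
    observations: Iterable[GenotypeObservation],
    sample_context: SampleContext,
    vocabulary: Optional[Vocabulary] = None,
) -> RequirementDecision:
    """Attach qualifier flags; "requires heterozygosity" may downgrade.

    Penetrance, onset, anticipation, mosaicism and contiguous-gene qualifiers
    never change satisfaction — they annotate.
    """
    vocab = vocabulary or build_vocabulary()
    obs = list(observations)
    flags: list[str] = list(decision.qualifier_flags)
    status = decision.status
    curies = {vocab.lookup_qualifier(q).curie for q in qualifiers}

    if "HP:0034343" in curies:  # requires heterozygosity
        hemizygous_only = (
            decision.contributing_variants
            and all(o.zygosity == "hemizygous" for o in decision.contributing_variants)
        )
        if status == "satisfied" and hemizygous_only and sample_context.sex_karyotype == "XY":
            status = "candidate_partial"
            flags.append("requires_heterozygosity:hemizygous_males_seldom_manifest")

    imprint_direction = None
    if "HP:0012275" in curies:  # maternal imprinting: expressed copy is paternal
        imprint_direction = "maternal"
    elif "HP:0012274" in curies:  # paternal imprinting: expressed copy is maternal
        imprint_direction = "paternal"
    if imprint_direction is not None:
        origins = {o.parental_origin for o in obs}
        if imprint_direction in origins:
            flags.append("imprinting:origin_inconsistent_with_imprinting")
        elif origins - {None, "unknown"}:
            flags.append("imprinting:origin_consistent")
        else:
            flags.append("imprinting:origin_unknown")
    elif "HP:0034338" in curies:
        flags.append("imprinting:direction_unspecified")

    if "HP:0025352" in curies:  # typically de novo
        statuses = {o.de_novo_status for o in obs}
        if "confirmed" in statuses:
            flags.append("de_novo:confirmed_supportive")
        elif "inherited" in statuses:
            flags.append("de_novo:inherited_caution")
        else:
            flags.append("de_novo:status_unknown")

    if "HP:0001475" in curies and sample_context.sex_karyotype == "XX":
        flags.append("sex_limited:not_expected_to_manifest")
    if "HP:0034344" in curies and sample_context.sex_karyotype == "XY":
        flags.append("sex_limited:not_expected_to_manifest")

    informational = {
        "HP:0001442": "somatic_mosaicism_typical",
        "HP:0003829": "incomplete_penetrance",
        "HP:4000159": "moderate_penetrance",
        "HP:4000158": "high_penetrance",
        "HP:0034950": "complete_penetrance",
        "HP:0034857": "highly_variable_onset",
        "HP:0003831": "age_related_onset",
        "HP:0003743": "anticipation",
        "HP:0001466": "contiguous_gene_syndrome",
        "HP:0001470": "sex_limited_expression",
    }
    for curie, tag in informational.items():
        if curie in curies:
            flags.append(f"info:{tag}")

    return replace(decision, status=status, qualifier_flags=tuple(flags))


# -- end-to-end prioritization -------------------------------------------------

REPORT_COLUMNS = [
    "sample",
    "gene",
    "disease",
    "allelic_requirement",
    "variant",
    "class",
    "nmd_flag",
    "matched_consequence",
    "score",
    "status",
    "rationale_codes",
    "qualifier_flags",
]


def prioritize(
    vcf_path,
    curations: Sequence[GeneDiseaseCuration],
    transcripts: Sequence[TranscriptModel],
    sample_context: SampleContext,
    matrix: Optional[ConsequenceMatrix] = None,
    threshold: int = DEFAULT_SUGGESTION_THRESHOLD,
    vocabulary: Optional[Vocabulary] = None,
) -> pd.DataFrame:
    """Run the full pipeline: annotate a sample's VCF against each curated
    gene-disease pair and report the requirement decision per pair.

    The same variant set may satisfy one pair and not another — e.g. a
    hemizygous X variant satisfies both an X-linked-recessive and an
    X-linked-dominant curation on the gene, while a single heterozygous
    variant in an XX individual satisfies only the dominant one.
    """
    matrix = matrix or default_matrix()
    vocab = vocabulary or build_vocabulary()
    variants = read_variants(vcf_path, sample_context.sample_id) if not isinstance(vcf_path, list) else vcf_path

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_symbol, []).append(tx)

    rows: list[dict] = []
    for curation in sorted(curations, key=lambda c: (c.gene_symbol, c.disease_label)):
        base = {
            "sample": sample_context.sample_id,
            "gene": curation.gene_symbol,
            "disease": curation.disease_label,
            "allelic_requirement": curation.allelic_requirement,
        }
        gene_txs = by_gene.get(curation.gene_symbol)
        if not gene_txs:
            rows.append(
                {**base, "variant": "", "class": "", "nmd_flag": "", "matched_consequence": "",
                 "score": "", "status": "no transcript model", "rationale_codes": "no_transcript_model",
                 "qualifier_flags": ""}
            )
            continue

        annotated = annotate_variants(variants, gene_txs, matrix)
        extra_codes: list[str] = []
        cur = curation
        if not cur.disease_associated_consequences and cur.known_pathogenic_variant_classes:
            profile = matrix.infer_consequences(sorted(cur.known_pathogenic_variant_classes))
            cur = cur.with_consequences([c for c, v in profile.items() if v >= threshold])
            extra_codes.append("consequences_inferred_from_known_classes")
        qualifying = (
            qualifying_variants(annotated, cur, matrix, threshold)
            if cur.disease_associated_consequences
            else []
        )
        observations = [GenotypeObservation.from_annotated(q.annotated_variant) for q in qualifying]
        decision = evaluate_requirement(
            observations, cur.allelic_requirement, sample_context, vocabulary=vocab
        )
        if extra_codes:
            decision = replace(
                decision, rationale_codes=tuple(list(decision.rationale_codes) + extra_codes)
            )
        decision = apply_qualifiers(decision, curation.qualifiers, observations, sample_context, vocab)

        common = {
            "status": decision.status,
            "rationale_codes": ";".join(decision.rationale_codes),
            "qualifier_flags": ";".join(decision.qualifier_flags),
        }
        if qualifying:
            for q in sorted(qualifying, key=lambda q: (q.annotated_variant.variant.position, q.annotated_variant.variant.alt)):
                v = q.annotated_variant.variant
                rows.append(
                    {**base, **common,
                     "variant": f"{v.chromosome}:{v.position}:{v.ref}>{v.alt}",
                     "class": q.annotated_variant.variant_class.name,
                     "nmd_flag": q.annotated_variant.nmd_flag,
                     "matched_consequence": q.matched_consequence,
                     "score": q.score}
                )
        else:
            rows.append(
                {**base, **common, "variant": "", "class": "", "nmd_flag": "",
                 "matched_consequence": "", "score": ""}
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
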