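from itertools import combinations_with_replacement

import pytest

from gdrkit import (
    GenotypeObservation,
    PARConfig,
    RequirementDecision,
    SampleContext,
    Variant,
    VariantRecipe,
    apply_qualifiers,
    evaluate_requirement,
    exemplar_curations,
    prioritize,
    qualifying_variants,
    synth_transcript,
    synth_variants,
)
from gdrkit.engine import RATIONALE_CODES, _STATUS_ORDER

from oracles import requirement_oracle

TOKENS = (
    "monoallelic_autosomal",
    "biallelic_autosomal",
    "monoallelic_X_heterozygous",
    "monoallelic_X_hemizygous",
    "monoallelic_Y_hemizygous",
    "mitochondrial",
    "monoallelic_PAR",
    "biallelic_PAR",
)
KARYOTYPES = ("XX", "XY", "unknown")
ZYGOSITIES = ("heterozygous", "homozygous_alt", "hemizygous")

_TOKEN_LOCUS = {
    "monoallelic_autosomal": ("chr1", 1000),
    "biallelic_autosomal": ("chr1", 1000),
    "monoallelic_X_heterozygous": ("chrX", 50_000_000),
    "monoallelic_X_hemizygous": ("chrX", 50_000_000),
    "monoallelic_Y_hemizygous": ("chrY", 10_000_000),
    "mitochondrial": ("chrMT", 5000),
    "monoallelic_PAR": ("chrX", 20_000),
    "biallelic_PAR": ("chrX", 20_000),
}

PAR = PARConfig.default_grch38()


def _obs(token, zygosities, **kw):
    chrom, pos = _TOKEN_LOCUS[token]
    return [
        GenotypeObservation(None, z, chromosome=chrom, position=pos + i, **kw)
        for i, z in enumerate(zygosities)
    ]


def _context(karyotype, sample="S1"):
    return SampleContext(sample_id=sample, sex_karyotype=karyotype, par_config=PAR)


def _grid():
    for token in TOKENS:
        for karyotype in KARYOTYPES:
            for size in range(4):
                for zygs in combinations_with_replacement(ZYGOSITIES, size):
                    yield token, karyotype, zygs


# -- oracle equivalence ----------------------------------------------------------

def test_engine_matches_brute_force_oracle(vocab):
    n = 0
    for token, karyotype, zygs in _grid():
        decision = evaluate_requirement(
            _obs(token, zygs), token, _context(karyotype), vocabulary=vocab
        )
        expected = requirement_oracle(token, karyotype, zygs)
        assert decision.status == expected, (
            f"{token} / {karyotype} / {zygs}: engine {decision.status}, oracle {expected} "
            f"(codes {decision.rationale_codes})"
        )
        n += 1
    assert n == len(TOKENS) * len(KARYOTYPES) * 20  # 480 cases


def test_adding_an_observation_never_lowers_status(vocab):
    for token, karyotype, zygs in _grid():
        if len(zygs) == 3:
            continue
        base = evaluate_requirement(
            _obs(token, zygs), token, _context(karyotype), vocabulary=vocab
        )
        for extra in ZYGOSITIES:
            grown = evaluate_requirement(
                _obs(token, zygs + (extra,)), token, _context(karyotype), vocabulary=vocab
            )
            assert _STATUS_ORDER[grown.status] >= _STATUS_ORDER[base.status], (
                f"{token} / {karyotype}: {zygs} -> +{extra} lowered "
                f"{base.status} to {grown.status}"
            )


def test_all_emitted_rationale_codes_are_known(vocab):
    for token, karyotype, zygs in _grid():
        decision = evaluate_requirement(
            _obs(token, zygs), token, _context(karyotype), vocabulary=vocab
        )
        assert set(decision.rationale_codes) <= RATIONALE_CODES


# -- phase resolution ------------------------------------------------------------

def _het_pair(token="biallelic_autosomal", **pair_kw):
    chrom, pos = _TOKEN_LOCUS[token]
    a = GenotypeObservation(None, "heterozygous", chromosome=chrom, position=pos,
                            **{k: v[0] for k, v in pair_kw.items()})
    b = GenotypeObservation(None, "heterozygous", chromosome=chrom, position=pos + 10,
                            **{k: v[1] for k, v in pair_kw.items()})
    return [a, b]


def test_trans_compound_het_satisfies_biallelic(vocab):
    obs = _het_pair(phase_set=("7", "7"), haplotype=(0, 1))
    decision = evaluate_requirement(obs, "biallelic_autosomal", _context("XX"), vocabulary=vocab)
    assert decision.status == "satisfied"
    assert "compound_het_trans" in decision.rationale_codes
    assert len(decision.contributing_variants) == 2


def test_cis_pair_is_a_single_affected_allele(vocab):
    obs = _het_pair(phase_set=("7", "7"), haplotype=(1, 1))
    decision = evaluate_requirement(obs, "biallelic_autosomal", _context("XX"), vocabulary=vocab)
    assert decision.status == "candidate_partial"
    assert "cis_pair_single_allele" in decision.rationale_codes


def test_parental_origin_resolves_phase(vocab):
    trans = _het_pair(parental_origin=("maternal", "paternal"))
    decision = evaluate_requirement(trans, "biallelic_autosomal", _context("XX"), vocabulary=vocab)
    assert decision.status == "satisfied"
    cis = _het_pair(parental_origin=("maternal", "maternal"))
    decision = evaluate_requirement(cis, "biallelic_autosomal", _context("XX"), vocabulary=vocab)
    assert decision.status == "candidate_partial"
    assert "cis_pair_single_allele" in decision.rationale_codes


def test_phase_unknown_pair_is_candidate(vocab):
    obs = _het_pair()
    decision = evaluate_requirement(obs, "biallelic_autosomal", _context("XX"), vocabulary=vocab)
    assert decision.status == "candidate_partial"
    assert "possible_compound_het_phase_unknown" in decision.rationale_codes


def test_phase_info_override(vocab):
    obs = _het_pair()
    as_trans = evaluate_requirement(
        obs, "biallelic_autosomal", _context("XX"), phase_info="trans", vocabulary=vocab
    )
    assert as_trans.status == "satisfied"
    as_cis = evaluate_requirement(
        obs, "biallelic_autosomal", _context("XX"), phase_info="cis", vocabulary=vocab
    )
    assert as_cis.status == "candidate_partial"
    assert "cis_pair_single_allele" in as_cis.rationale_codes


def test_xx_compound_het_can_satisfy_x_linked_recessive(vocab):
    token = "monoallelic_X_hemizygous"
    chrom, pos = _TOKEN_LOCUS[token]
    obs = [
        GenotypeObservation(None, "heterozygous", chromosome=chrom, position=pos,
                            phase_set="3", haplotype=0),
        GenotypeObservation(None, "heterozygous", chromosome=chrom, position=pos + 10,
                            phase_set="3", haplotype=1),
    ]
    decision = evaluate_requirement(obs, token, _context("XX"), vocabulary=vocab)
    assert decision.status == "satisfied"
    assert "compound_het_trans" in decision.rationale_codes


# -- PAR handling ----------------------------------------------------------------

def test_default_par_intervals_boundaries():
    assert PAR.contains("chrX", 10_001)       # first base of PAR1 (0-based 10000)
    assert not PAR.contains("chrX", 10_000)
    assert PAR.contains("chrX", 2_781_479)
    assert not PAR.contains("chrX", 2_781_480)
    assert PAR.contains("X", 20_000)          # chr-prefix insensitive
    assert PAR.contains("chrY", 56_887_903)   # PAR2 on Y
    assert not PAR.contains("chr1", 20_000)


def test_par_requirement_ignores_non_par_observations(vocab):
    outside = GenotypeObservation(None, "heterozygous", chromosome="chrX", position=50_000_000)
    decision = evaluate_requirement([outside], "monoallelic_PAR", _context("XX"), vocabulary=vocab)
    assert decision.status == "unsatisfied"
    assert "not_in_par" in decision.rationale_codes
    inside = GenotypeObservation(None, "heterozygous", chromosome="chrX", position=20_000)
    decision = evaluate_requirement(
        [outside, inside], "monoallelic_PAR", _context("XX"), vocabulary=vocab
    )
    assert decision.status == "satisfied"
    assert "not_in_par" in decision.rationale_codes  # notes the discarded observation


def test_par_config_validation():
    with pytest.raises(ValueError):
        PARConfig("bad", (("chr7", 0, 100),))
    with pytest.raises(ValueError):
        PARConfig("bad", (("chrX", 100, 100),))


def test_par_config_from_bed(tmp_path):
    bed = tmp_path / "par.bed"
    bed.write_text("# comment\nchrX\t100\t200\tPAR1\nchrY\t100\t200\n")
    par = PARConfig.from_bed(bed)
    assert par.contains("chrX", 101) and not par.contains("chrX", 100)
    assert par.contains("chrY", 200) and not par.contains("chrY", 201)


# -- decision / context objects --------------------------------------------------

def test_requirement_decision_invariants():
    with pytest.raises(ValueError):
        RequirementDecision("satisfied", ("monoallelic_satisfied",))  # no contributing variants
    with pytest.raises(ValueError):
        RequirementDecision("unsatisfied", ("made_up_code",))
    with pytest.raises(ValueError):
        RequirementDecision("perhaps", ())


def test_sample_context_validates_karyotype():
    with pytest.raises(ValueError):
        SampleContext("S1", sex_karyotype="XYY")


def test_mitochondrial_decision_carries_heteroplasmy(vocab):
    obs = [GenotypeObservation(None, "hemizygous", chromosome="chrMT", position=5000,
                               heteroplasmy=0.62)]
    decision = evaluate_requirement(obs, "mitochondrial", _context("XX"), vocabulary=vocab)
    assert decision.status == "satisfied"
    assert "heteroplasmy=0.62" in decision.qualifier_flags


# -- qualifier application -------------------------------------------------------

def _hemi_satisfied():
    obs = GenotypeObservation(None, "hemizygous", chromosome="chrX", position=50_000_000)
    return RequirementDecision("satisfied", ("hemizygous_satisfies",), (obs,)), [obs]


def test_requires_heterozygosity_downgrades_hemizygous_male(vocab):
    decision, obs = _hemi_satisfied()
    out = apply_qualifiers(decision, ["HP:0034343"], obs, _context("XY"), vocab)
    assert out.status == "candidate_partial"
    assert any(f.startswith("requires_heterozygosity") for f in out.qualifier_flags)


def test_requires_heterozygosity_leaves_heterozygotes_alone(vocab):
    obs = [GenotypeObservation(None, "heterozygous", chromosome="chrX", position=50_000_000)]
    decision = RequirementDecision("satisfied", ("monoallelic_satisfied",), tuple(obs))
    out = apply_qualifiers(decision, ["HP:0034343"], obs, _context("XX"), vocab)
    assert out.status == "satisfied"


def test_imprinting_direction_checked_against_origin(vocab):
    obs = [GenotypeObservation(None, "heterozygous", chromosome="chr1", position=1000,
                               parental_origin="maternal")]
    decision = RequirementDecision("satisfied", ("monoallelic_satisfied",), tuple(obs))
    # maternally imprinted: the maternal copy is silenced, a maternal-origin
    # variant is inconsistent with the disease model
    out = apply_qualifiers(decision, ["HP:0012275"], obs, _context("XX"), vocab)
    assert "imprinting:origin_inconsistent_with_imprinting" in out.qualifier_flags
    out = apply_qualifiers(decision, ["HP:0012274"], obs, _context("XX"), vocab)
    assert "imprinting:origin_consistent" in out.qualifier_flags
    no_origin = [GenotypeObservation(None, "heterozygous", chromosome="chr1", position=1000)]
    out = apply_qualifiers(decision, ["HP:0012275"], no_origin, _context("XX"), vocab)
    assert "imprinting:origin_unknown" in out.qualifier_flags
    out = apply_qualifiers(decision, ["HP:0034338"], obs, _context("XX"), vocab)
    assert "imprinting:direction_unspecified" in out.qualifier_flags


def test_de_novo_and_sex_limited_flags(vocab):
    obs = [GenotypeObservation(None, "heterozygous", chromosome="chr1", position=1000,
                               de_novo_status="confirmed")]
    decision = RequirementDecision("satisfied", ("monoallelic_satisfied",), tuple(obs))
    out = apply_qualifiers(decision, ["HP:0025352"], obs, _context("XX"), vocab)
    assert "de_novo:confirmed_supportive" in out.qualifier_flags
    out = apply_qualifiers(decision, ["HP:0001475"], obs, _context("XX"), vocab)  # male-limited
    assert "sex_limited:not_expected_to_manifest" in out.qualifier_flags
    out = apply_qualifiers(decision, ["HP:0001475"], obs, _context("XY"), vocab)
    assert "sex_limited:not_expected_to_manifest" not in out.qualifier_flags


def test_informational_qualifiers_never_change_status(vocab):
    obs = [GenotypeObservation(None, "heterozygous", chromosome="chr1", position=1000)]
    decision = RequirementDecision("satisfied", ("monoallelic_satisfied",), tuple(obs))
    out = apply_qualifiers(
        decision,
        ["HP:0003829", "HP:4000158", "HP:0003831", "HP:0003743", "HP:0001442", "HP:0001466"],
        obs, _context("XX"), vocab,
    )
    assert out.status == "satisfied"
    assert {"info:incomplete_penetrance", "info:high_penetrance", "info:age_related_onset",
            "info:anticipation", "info:somatic_mosaicism_typical",
            "info:contiguous_gene_syndrome"} <= set(out.qualifier_flags)


# -- qualifying variants ---------------------------------------------------------

@pytest.fixture(scope="module")
def annotated_hand_variants(matrix, hand_tx):
    from gdrkit import annotate_variants

    variants = [
        Variant("chrT", 46, "C", "T"),   # stop_gained|NMD_escaping
        Variant("chrT", 21, "C", "T"),   # missense
        Variant("chrT", 51, "T", "C"),   # synonymous
    ]
    return annotate_variants(variants, [hand_tx], matrix)


def test_qualifying_variants_filters_by_asserted_consequences(annotated_hand_variants, matrix):
    from gdrkit import GeneDiseaseCuration

    curation = GeneDiseaseCuration(
        "HAND1", "toy disease", "monoallelic_autosomal",
        disease_associated_consequences=frozenset({"altered gene product sequence"}),
    )
    hits = qualifying_variants(annotated_hand_variants, curation, matrix)
    positions = {q.annotated_variant.variant.position for q in hits}
    assert 21 in positions       # missense scores 5 for altered sequence
    assert 51 not in positions   # synonymous does not
    for q in hits:
        assert q.matched_consequence == "altered gene product sequence"
        assert q.score >= 4


def test_qualifying_variants_requires_asserted_consequences(annotated_hand_variants, matrix):
    from gdrkit import GeneDiseaseCuration

    curation = GeneDiseaseCuration("HAND1", "toy disease", "monoallelic_autosomal")
    with pytest.raises(ValueError, match="infer_consequences"):
        qualifying_variants(annotated_hand_variants, curation, matrix)


def test_raising_threshold_shrinks_qualifying_set(annotated_hand_variants, matrix):
    from gdrkit import GeneDiseaseCuration

    curation = GeneDiseaseCuration(
        "HAND1", "toy disease", "monoallelic_autosomal",
        disease_associated_consequences=frozenset(
            {"altered gene product sequence", "decreased gene product level"}
        ),
    )
    keys = {
        t: {q.annotated_variant.variant.key
            for q in qualifying_variants(annotated_hand_variants, curation, matrix, t)}
        for t in (2, 3, 4, 5)
    }
    assert keys[5] <= keys[4] <= keys[3] <= keys[2]


# -- end-to-end prioritization ---------------------------------------------------

@pytest.fixture(scope="module")
def toyx_setup(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("toyx")
    tx = synth_transcript(n_exons=3, seed=21, chromosome="chrX", gene_symbol="TOYX")
    curations = [c for c in exemplar_curations() if c.gene_symbol == "TOYX"]
    assert {c.allelic_requirement for c in curations} == {
        "monoallelic_X_hemizygous", "monoallelic_X_heterozygous",
    }
    return tmp, tx, curations


def _run_scenario(tmp, tx, curations, zygosity, karyotype, name):
    recipe = VariantRecipe(
        counts={"stop_gained|NMD_triggering": 1}, seed=5, zygosities=(zygosity,)
    )
    vcf = tmp / f"{name}.vcf"
    synth_variants(tx, recipe, out_path=vcf, sample=name)
    context = SampleContext(sample_id=name, sex_karyotype=karyotype, par_config=PAR)
    report = prioritize(vcf, curations, [tx], context)
    return {
        row["allelic_requirement"]: row["status"] for _, row in report.iterrows()
    }


def test_dual_phenotype_x_gene_scenario(toyx_setup):
    tmp, tx, curations = toyx_setup
    # the same hemizygous PTC variant in an XY individual satisfies both the
    # X-linked-recessive and the X-linked-dominant curation on the gene
    male = _run_scenario(tmp, tx, curations, "hemizygous", "XY", "MALE1")
    assert male["monoallelic_X_hemizygous"] == "satisfied"
    assert male["monoallelic_X_heterozygous"] == "satisfied"
    # a single heterozygous variant in an XX individual satisfies only the
    # heterozygous (dominant) curation
    female = _run_scenario(tmp, tx, curations, "heterozygous", "XX", "FEMALE1")
    assert female["monoallelic_X_hemizygous"] == "unsatisfied"
    assert female["monoallelic_X_heterozygous"] == "satisfied"


def test_prioritize_reports_missing_transcript_and_inferred_consequences(toyx_setup, vocab):
    from gdrkit import GeneDiseaseCuration

    tmp, tx, curations = toyx_setup
    recipe = VariantRecipe(counts={"stop_gained|NMD_triggering": 1}, seed=5,
                           zygosities=("heterozygous",))
    vcf = tmp / "extra.vcf"
    synth_variants(tx, recipe, out_path=vcf, sample="S9")
    extra = [
        GeneDiseaseCuration("NOGENE", "orphan disease", "monoallelic_autosomal",
                            disease_associated_consequences=frozenset({"absent gene product"})),
        GeneDiseaseCuration(
            "TOYX", "classes-only curation", "monoallelic_X_heterozygous",
            known_pathogenic_variant_classes=frozenset({"stop_gained|NMD_triggering"}),
        ),
    ]
    context = SampleContext(sample_id="S9", sex_karyotype="XX", par_config=PAR)
    report = prioritize(vcf, extra, [tx], context, vocabulary=vocab)
    by_gene = {row["gene"]: row for _, row in report.iterrows()}
    assert by_gene["NOGENE"]["rationale_codes"] == "no_transcript_model"
    toyx_row = by_gene["TOYX"]
    assert "consequences_inferred_from_known_classes" in toyx_row["rationale_codes"]
    assert toyx_row["status"] == "satisfied"


def test_prioritize_report_is_deterministic(toyx_setup):
    tmp, tx, curations = toyx_setup
    first = _run_scenario(tmp, tx, curations, "hemizygous", "XY", "REP1")
    second = _run_scenario(tmp, tx, curations, "hemizygous", "XY", "REP1")
    assert first == second
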