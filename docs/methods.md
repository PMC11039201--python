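# Methods

This document records the model implemented by gdrkit, the parameters and
defaults it bakes in, and the reasoning behind the choices that were ours to
make. The controlled vocabulary (requirement/inheritance pairs, qualifier
terms, the six consequence terms, and the text-anchored matrix cells) follows
the published harmonized terminology for Mendelian gene–disease
relationships; everything labeled a *design choice* below is this package's.

## 1. Vocabulary

Eight allelic-requirement tokens are paired one-to-one with Mendelian
inheritance terms; both members of a pair share one HPO identifier (the
requirement spelling is the "allelic requirement" synonym of the inheritance
term):

| requirement token | inheritance term | HPO |
| --- | --- | --- |
| `monoallelic_autosomal` | Autosomal Dominant | HP:0000006 |
| `biallelic_autosomal` | Autosomal Recessive | HP:0000007 |
| `monoallelic_X_heterozygous` | X-linked Dominant | HP:0001423 |
| `monoallelic_X_hemizygous` | X-linked Recessive | HP:0001419 |
| `monoallelic_Y_hemizygous` | Y-linked | HP:0001450 |
| `mitochondrial` | Mitochondrial | HP:0001427 |
| `monoallelic_PAR` | PAR dominant | HP:0034340 |
| `biallelic_PAR` | PAR recessive | HP:0034341 |

Seventeen inheritance-qualifier terms (eleven parents, six children) cover
mosaicism, de novo tendency, penetrance (complete / incomplete, with moderate
and high bands), onset variability, imprinting (with maternal/paternal
children), anticipation, requires-heterozygosity, sex-limited expression
(male/female children), and contiguous-gene syndromes. Validation rejects
co-assertion of contradictory qualifiers (complete vs incomplete penetrance,
maternal vs paternal imprinting, male- vs female-limited, moderate vs high
penetrance).

## 2. Consequence hierarchy and likelihood matrix

The six high-level disease-associated consequences are SO terms arranged in a
small hierarchy: *altered gene product level* (SO:0002314) with children
*decreased* (SO:0002316, itself parent of *absent*, SO:0002317) and
*increased* (SO:0002315); *altered gene product sequence* (SO:0002318); and
*functionally normal* (SO:0002219). Broader SO nodes (sequence_variant,
functional_effect_variant, functionally_abnormal, function_uncertain_variant)
are modeled as hierarchy nodes but are not matrix columns.

**Base class set (design choice, documented derivation).** The matrix rows
start from the classic 33-term Ensembl VEP consequence vocabulary in severity
order. Thirteen terms carry no row because they are flags or catch-alls
rather than variant classes (`NMD_transcript_variant`,
`coding_sequence_variant`, `non_coding_transcript_variant`,
`incomplete_terminal_codon_variant`), structural-amplification classes
(`transcript_amplification`, `TFBS_*`, `regulatory_region_ablation/
amplification`, `feature_elongation/truncation`), or subsumed locations
(`downstream_gene_variant`, `intergenic_variant`). That leaves 20 base rows;
`stop_gained` and `frameshift_variant` are each split into `|NMD_triggering`
and `|NMD_escaping` rows (a degraded transcript lowers product level; an
escaping PTC yields a truncated, sequence-altered product), giving **22
rows × 6 columns**.

**Scale.** Every cell is an ordinal likelihood 1–5 (almost never, unlikely,
possible, probable, almost always). The default threshold for "this class
plausibly produces this consequence" is **4 (probable)**.

**Cell provenance.** Cells fixed by the published text are tagged
`paper_text` (e.g. NMD-triggering stop_gained scores 5 for both *decreased*
and *absent*; missense scores 5 for *altered sequence*; synonymous scores 5
for *functionally normal* and 1 for *altered sequence*). All remaining cells
are authored defaults tagged `expert_default`, chosen to satisfy the
hierarchy-monotonicity invariant (for every row: altered level ≥
max(decreased, increased), decreased ≥ absent), which `validate()` enforces
for any user-supplied matrix as well.

**Operations.** `infer_consequences` is the element-wise maximum over the
observed classes' rows (monotone under adding classes; empty input gives an
empty profile). `suggest_classes` returns the classes, disjoint from the
input, that score ≥ threshold for at least one consequence that itself
reaches ≥ threshold in the inferred profile, sorted by severity.

## 3. Variant classification and NMD

Classification is from first principles rather than by wrapping an external
annotator: the edit is applied to the chromosome sequence (exon and CDS
coordinates downstream of the edit shift by the length difference), alleles
are normalized (shared prefix/suffix trimming, left-alignment of pure indels
against the reference), the edited CDS is retranslated, and candidate terms
are collected — splice donor/acceptor (intronic ±1,2), splice region
(intronic positions 3–8 plus the 3 exonic bases flanking each junction),
UTR/intron location, and the coding outcome (synonymous, missense, stop
gained/lost, start lost, in-frame indel, frameshift). The reported class is
the most severe candidate under the VEP severity ranking. For frameshifts the
edited transcript is scanned in frame from the CDS start for the first stop,
which may lie beyond the original CDS; a PTC class with no in-transcript stop
is necessarily NMD-escaping.

**NMD rule (design choice among published variants of the rule).** A
premature termination codon *escapes* NMD when (a) the transcript is
single-exon, (b) the PTC lies in the final exon, or (c) the first base of
the PTC lies within the last 50 nt upstream of the final exon–exon junction,
boundary inclusive (exactly 50 nt upstream still escapes); otherwise it
*triggers* NMD. A start-proximal escape clause (PTC within the first 150
coding nt) exists in the literature but is **off by default**
(`assess_nmd(..., start_proximal_escape=True)` enables it): it is the less
consistently replicated part of the rule and enabling it by default would
silently down-weight bona fide early PTCs.

VEP-style `CSQ` consequence strings are also accepted
(`parse_vep_consequences`): the most severe recognized term wins; inputs with
only unrecognized terms map to `function_uncertain_variant` with a warning.

## 4. Requirement engine

Qualifying variants are those whose consequence profile reaches the threshold
for at least one consequence asserted by the curation. The decision per
curation is `satisfied`, `candidate_partial`, or `unsatisfied`, always with
machine-readable rationale codes:

- monoallelic requirements: any qualifying variant satisfies.
- biallelic requirements: a homozygote satisfies; two heterozygotes satisfy
  iff some pair is in *trans* (resolved from shared phase sets + haplotype
  indexes, or from parental origins); a single heterozygote is
  `candidate_partial` (a second contributory variant or alternative cause
  should be sought); a pair confirmed in *cis* is `candidate_partial` with
  code `cis_pair_single_allele` — **design choice**: the two variants form one
  affected allele, which is exactly the single-heterozygote state, so grading
  it below a single het would break monotonicity (adding an observation could
  then lower the decision).
- X-linked recessive (`monoallelic_X_hemizygous`): satisfied hemizygous in XY;
  in XX, satisfied if homozygous or trans-compound-heterozygous, while a
  single heterozygote is `unsatisfied` with code `het_carrier_only`; with an
  unknown karyotype the decision is capped at `candidate_partial`
  (**design choice**: never assert satisfaction that depends on an
  unverified karyotype).
- Y-linked: incompatible with an XX karyotype (`karyotype_incompatible`).
- PAR requirements: observations outside the bundled GRCh38 pseudoautosomal
  intervals (BED, 0-based half-open; a custom BED can be supplied) are
  discarded with code `not_in_par`; the remainder is counted autosomally.

Qualifiers then annotate the decision and in one case downgrade it:
"requires heterozygosity" lowers a satisfaction supported only by hemizygous
variants in an XY individual to `candidate_partial` (such disorders manifest
in the functionally mosaic heterozygous state); imprinting direction is
cross-checked against parental origin (a maternal-origin variant in a
maternally imprinted gene is flagged inconsistent — the expressed copy is the
paternal one); de novo and sex-limited qualifiers add supportive or
cautionary flags; penetrance/onset/anticipation/mosaicism/contiguous
qualifiers are purely informational.

## 5. Fixtures and problem sizes

All test data is generated, seeded, and kilobase-scale (a pure function of
arguments + seed; no downloads): toy transcripts with ATG…stop CDS, no
internal in-frame stop, and canonical GT..AG introns, on either strand;
recipe-driven variant sets in which every emitted variant is verified to
re-classify to its requested class (including the NMD qualifier) before being
written to VCF 4.2; and 18 exemplar curations — published gene examples
(MYH7, KCNQ1, FBN1, EFNB1, DMPK, DHH, NF1, CYP1B1, IRF6, C9orf72, RYR1,
CACNA1S) plus synthetic stand-ins (marked `synthetic` in their provenance
field) for contexts without a published exemplar (Y-linked, mitochondrial,
PAR, and the dual-phenotype X-linked scenario), so that every requirement
token is exercised.

Generated sequences are random DNA, not a real genome: splice-site and NMD
logic depend only on transcript geometry, and coding logic only on codon
structure, so toy scale (3 × 150 nt exons by default) exercises every code
path the engine has. Limits: no repeats/homology, uniform base composition,
SNVs and ≤ 3-nt indels only — sufficient for the implemented classifier,
unsuitable for benchmarking aligners or callers.

## 6. Verification

The test suite checks the engine against *independent* oracles implemented
from the rule statements rather than the code: a 480-case brute-force truth
table for requirement satisfaction (8 tokens × 3 karyotypes × all genotype
multisets of size ≤ 3), an exhaustive per-position NMD scan on three
transcripts computing junctions directly from exon intervals (including the
50-nt boundary), strand-symmetry checks (mirrored minus-strand transcripts
classify identically), property-based tests (inference monotonicity,
suggestion order-invariance and disjointness, normalization preserving the
edited sequence, decision monotonicity under added observations), and frozen
hand-computed classifications on a fully worked 102-bp transcript.
`scripts/acceptance.py --seed N --out results.json` re-runs the headline
checks end to end.

## 7. Interface conventions

The API is plain functions over frozen dataclasses (plus thin `click` CLI
wrappers); it does not adopt a fit/predict estimator shape because nothing
here is estimated from data — the matrix is authored knowledge and the engine
is a rule system, so there is no training step for `fit` to perform.
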