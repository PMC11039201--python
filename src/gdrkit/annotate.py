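"""Variant-class assignment, NMD assessment and VCF input.

Variants are classified from first principles against a transcript model:
the edit is applied to the reference, the edited CDS is translated, and the
outcome (premature stop, frameshift, in-frame change, amino-acid change,
silent change, splice-site disruption, UTR/intronic location) determines the
SO variant class. Premature termination codons are then assessed for
nonsense-mediated decay: a PTC escapes NMD when the transcript has a single
exon, when it lies in the final exon, or when it lies within the last 50 nt
upstream of the final exon-exon junction (boundary inclusive); it triggers
NMD otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from .matrix import (
    NMD_SPLIT_CLASSES,
    SEVERITY_RANK,
    VEP_BASE_CLASSES,
    ConsequenceMatrix,
    VariantClass,
)
from .transcripts import TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "AnnotatedVariant",
    "ClassificationResult",
    "classify_variant",
    "assess_nmd",
    "parse_vep_consequences",
    "VepParse",
    "read_variants",
    "annotate_variants",
    "normalize_allele",
]

NMD_ESCAPE_WINDOW_NT = 50  # junction-proximal escape window
FUNCTION_UNCERTAIN = "function_uncertain_variant"


@dataclass(frozen=True)
class Variant:
    """One variant call for one sample (VCF conventions: 1-based position)."""

    chromosome: str
    position: int
    ref: str
    alt: str
    sample: Optional[str] = None
    genotype: tuple[int, ...] = (0, 1)  # allele indexes; length 1 = haploid call
    phased: bool = False
    phase_set: Optional[str] = None
    haplotype: Optional[int] = None  # index of the haplotype carrying the alt, if phased
    parental_origin: Optional[str] = None  # maternal | paternal | unknown
    de_novo_status: Optional[str] = None  # confirmed | inherited | unknown
    heteroplasmy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def zygosity(self) -> str:
        alts = sum(1 for a in self.genotype if a > 0)
        if len(self.genotype) == 1:
            return "hemizygous" if alts else "reference"
        if alts == 0:
            return "reference"
        if alts == len(self.genotype):
            return "homozygous_alt"
        return "heterozygous"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of first-principles classification against one transcript."""

    variant_class: Optional[VariantClass]  # None when the variant misses the transcript
    transcript_id: str
    ptc_tx_position: Optional[int] = None  # first base of the termination codon (edited transcript coords)
    detail: tuple[str, ...] = ()  # all candidate terms, most severe first
    outside: bool = False

    @property
    def base_term(self) -> Optional[str]:
        return self.variant_class.base_so_term if self.variant_class else None


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: Variant
    variant_class: VariantClass
    nmd_flag: str  # triggering | escaping | not_applicable
    consequence_profile: dict[str, int]
    transcript_id: Optional[str] = None
    ptc_tx_position: Optional[int] = None
    detail: tuple[str, ...] = ()


def normalize_allele(pos: int, ref: str, alt: str, seq: str) -> tuple[int, str, str]:
    """Trim shared prefix/suffix and left-align pure indels.

    Returns (pos, ref, alt) where an empty ref means insertion before ``pos``
    and an empty alt a deletion starting at ``pos``.
    """
    # trim shared suffix
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    # left-align pure indels against the reference
    if ref == "" and alt:
        while pos > 1 and seq[pos - 2] == alt[-1]:
            alt = seq[pos - 2] + alt[:-1]
            pos -= 1
    elif alt == "" and ref:
        while pos > 1 and seq[pos - 2] == ref[-1]:
            ref = seq[pos - 2] + ref[:-1]
            pos -= 1
    return pos, ref, alt


def _translate(seq: str) -> str:
    usable = seq[: len(seq) // 3 * 3]
    if not usable:
        return ""
    return str(Seq(usable).translate())


def _splice_site_positions(transcript: TranscriptModel):
    """Genomic position sets: donor (+1,+2), acceptor (-1,-2), splice region
    (intronic 3-8 from either intron end; 3 exonic bases flanking each
    junction)."""
    donor: set[int] = set()
    acceptor: set[int] = set()
    region: set[int] = set()
    for (istart, iend) in transcript.introns:
        if transcript.strand == "+":
            d5, a3 = istart, iend  # transcript-5' intron end is genomic start
        else:
            d5, a3 = iend, istart
        step = 1 if transcript.strand == "+" else -1
        donor.update({d5, d5 + step})
        acceptor.update({a3, a3 - step})
        # intronic splice region: positions 3..8 from each intron end
        for k in range(2, 8):
            p_d = d5 + step * k
            p_a = a3 - step * k
            if istart <= p_d <= iend:
                region.add(p_d)
            if istart <= p_a <= iend:
                region.add(p_a)
        # exonic splice region: 3 exonic bases adjacent to each junction
        if transcript.strand == "+":
            region.update({istart - 3, istart - 2, istart - 1})
            region.update({iend + 1, iend + 2, iend + 3})
        else:
            region.update({iend + 1, iend + 2, iend + 3})
            region.update({istart - 3, istart - 2, istart - 1})
    return donor, acceptor, region


def classify_variant(
    variant: Variant, transcript: TranscriptModel
) -> ClassificationResult:
    """Assign an SO variant class by translating the edited CDS.

    SNVs and small indels only. Returns a no-overlap result when the variant
    falls outside the transcript footprint; raises on reference mismatch.
    For PTC-producing classes the transcript coordinate of the first base of
    the premature termination codon is returned alongside the class.
    """
    if variant.chromosome != transcript.chromosome:
        return ClassificationResult(None, transcript.transcript_id, outside=True)

    seq = transcript.chrom_seq
    if seq[variant.position - 1 : variant.position - 1 + len(variant.ref)] != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chromosome}:{variant.position}: "
            f"expected {seq[variant.position - 1 : variant.position - 1 + len(variant.ref)]!r}, "
            f"got {variant.ref!r}"
        )

    pos, ref, alt = normalize_allele(variant.position, variant.ref, variant.alt, seq)
    if ref:
        affected = set(range(pos, pos + len(ref)))
    else:  # insertion between pos-1 and pos
        affected = {pos - 1, pos}

    span_start, span_end = transcript.span
    if not any(span_start <= p <= span_end for p in affected):
        return ClassificationResult(None, transcript.transcript_id, outside=True)

    donor, acceptor, splice_region = _splice_site_positions(transcript)
    candidates: list[str] = []
    if affected & donor:
        candidates.append("splice_donor_variant")
    if affected & acceptor:
        candidates.append("splice_acceptor_variant")
    if affected & splice_region and not (affected & (donor | acceptor)):
        candidates.append("splice_region_variant")

    exonic_tx = [transcript.tx_position(p) for p in affected]
    exonic_tx = [t for t in exonic_tx if t is not None]
    ptc_tx: Optional[int] = None
    edited: Optional[TranscriptModel] = None

    if not exonic_tx:
        if not (candidates and {"splice_donor_variant", "splice_acceptor_variant"} & set(candidates)):
            if "splice_region_variant" not in candidates:
                candidates.append("intron_variant")
    else:
        cstart, cend = transcript.cds_tx_interval
        if all(t < cstart for t in exonic_tx):
            candidates.append("5_prime_UTR_variant")
        elif all(t > cend for t in exonic_tx):
            candidates.append("3_prime_UTR_variant")
        else:
            coding_class, ptc_tx, edited = _classify_coding(transcript, pos, ref, alt)
            candidates.append(coding_class)

    candidates = sorted(set(candidates), key=lambda t: SEVERITY_RANK[t])
    best = candidates[0]

    if best in NMD_SPLIT_CLASSES and ptc_tx is not None:
        nmd = assess_nmd(ptc_tx, edited or transcript)
        vc = VariantClass(best, nmd)
    else:
        if best not in NMD_SPLIT_CLASSES:
            ptc_tx = None
        vc = VariantClass(best)
        if best in NMD_SPLIT_CLASSES:
            # PTC-producing class but no in-transcript stop found: the ribosome
            # reads through the annotated 3' end, necessarily NMD-escaping.
            vc = VariantClass(best, "escaping")
    return ClassificationResult(vc, transcript.transcript_id, ptc_tx, tuple(candidates))


def _classify_coding(
    transcript: TranscriptModel, pos: int, ref: str, alt: str
) -> tuple[str, Optional[int], TranscriptModel]:
    """Classify an edit overlapping the CDS; returns (base term, PTC transcript
    position on the edited transcript or None, edited transcript)."""
    edited = transcript.apply_edit(pos, ref, alt)
    orig_cds = transcript.cds_sequence
    new_cds = edited.cds_sequence
    delta = len(new_cds) - len(orig_cds)
    e_cstart, _ = edited.cds_tx_interval

    if delta % 3 != 0:
        # frameshift: scan the edited transcript in frame from the CDS start
        # for the first in-frame stop (may lie beyond the original CDS end)
        tail = edited.spliced_sequence[e_cstart - 1 :]
        protein = _translate(tail)
        stop_idx = protein.find("*")
        ptc = e_cstart + 3 * stop_idx if stop_idx != -1 else None
        return "frameshift_variant", ptc, edited

    orig_protein = _translate(orig_cds)
    new_protein = _translate(new_cds)

    if new_cds[:3] != orig_cds[:3] and new_cds[:3] != "ATG" and orig_cds[:3] == "ATG":
        return "start_lost", None, edited

    internal_stop = new_protein.find("*")
    has_internal_stop = 0 <= internal_stop < len(new_protein) - 1 or (
        internal_stop != -1 and not new_protein.endswith("*")
    )

    if delta == 0:
        if new_protein == orig_protein:
            return "synonymous_variant", None, edited
        diffs = [i for i, (a, b) in enumerate(zip(orig_protein, new_protein)) if a != b]
        i = diffs[0]
        if new_protein[i] == "*" and i < len(orig_protein) - 1:
            return "stop_gained", e_cstart + 3 * i, edited
        if orig_protein[i] == "*" and new_protein[i] != "*":
            return "stop_lost", None, edited
        return "missense_variant", None, edited

    # in-frame indel
    if has_internal_stop and "*" not in orig_protein[:-1]:
        return "stop_gained", e_cstart + 3 * internal_stop, edited
    if orig_protein.endswith("*") and not new_protein.endswith("*"):
        return "stop_lost", None, edited
    if delta > 0:
        return "inframe_insertion", None, edited
    return "inframe_deletion", None, edited


def assess_nmd(
    ptc_tx_position: int,
    transcript: TranscriptModel,
    start_proximal_escape: bool = False,
) -> str:
    """Assess whether a PTC triggers or escapes nonsense-mediated decay.

    Escaping if (a) the transcript is single-exon, (b) the PTC lies in the
    final exon, or (c) it lies within the last ``NMD_ESCAPE_WINDOW_NT`` (50)
    nucleotides upstream of the final exon-exon junction — a PTC whose first
    base sits exactly 50 nt upstream of the junction escapes. Optionally a
    start-proximal escape clause (PTC within the first 150 coding nt) can be
    enabled; it is off by default.
    """
    cstart, _ = transcript.cds_tx_interval
    if ptc_tx_position < cstart or ptc_tx_position > transcript.length:
        raise ValueError(
            f"PTC position {ptc_tx_position} outside the coding span "
            f"[{cstart}, {transcript.length}]"
        )
    if start_proximal_escape and ptc_tx_position - cstart < 150:
        return "escaping"
    junctions = transcript.junction_tx_positions
    if not junctions:  # single exon
        return "escaping"
    final_junction = junctions[-1]
    if ptc_tx_position > final_junction:  # within the last exon
        return "escaping"
    return "escaping" if final_junction - ptc_tx_position <= NMD_ESCAPE_WINDOW_NT else "triggering"


# -- VEP-style annotation parsing ---------------------------------------------

@dataclass(frozen=True)
class VepParse:
    variant_class: Optional[VariantClass]  # None => function uncertain
    unrecognized: tuple[str, ...] = ()

    @property
    def is_function_uncertain(self) -> bool:
        return self.variant_class is None

    @property
    def term(self) -> str:
        return self.variant_class.name if self.variant_class else FUNCTION_UNCERTAIN


def parse_vep_consequences(
    annotation_text: str, severity_order: Optional[Sequence[str]] = None
) -> VepParse:
    """Pick the most severe recognized SO term from an ampersand-separated
    VEP CSQ consequence list. NMD-qualified spellings
    (``stop_gained|NMD_triggering``) are accepted. An input with only
    unrecognized terms maps to function-uncertain with a warning.
    """
    if not annotation_text or not annotation_text.strip():
        raise ValueError("empty consequence annotation")
    order = list(severity_order) if severity_order is not None else list(VEP_BASE_CLASSES)
    rank = {t: i for i, t in enumerate(order)}
    recognized: list[VariantClass] = []
    unknown: list[str] = []
    for raw in annotation_text.split("&"):
        term = raw.strip()
        if not term:
            continue
        try:
            vc = VariantClass.parse(term)
        except ValueError:
            unknown.append(term)
            continue
        if vc.base_so_term in rank:
            recognized.append(vc)
        else:
            unknown.append(term)
    if not recognized:
        warnings.warn(
            f"no recognized consequence term in {annotation_text!r}; "
            "mapping to function_uncertain",
            stacklevel=2,
        )
        return VepParse(None, tuple(unknown))
    best = min(recognized, key=lambda vc: (rank[vc.base_so_term], vc.nmd_qualifier == "escaping"))
    return VepParse(best, tuple(unknown))


# -- VCF input ----------------------------------------------------------------

def read_variants(vcf_path, sample: Optional[str] = None) -> list[Variant]:
    """Read one sample's calls from a VCF 4.x file (plain or bgzipped).

    Genotypes decode per VCF convention: ``0/1`` heterozygous, ``1/1``
    homozygous-alt, single-index ``1`` hemizygous. Phased separators are kept
    via ``phase_set`` (FORMAT/PS when present, else the record's phased flag
    keyed by contig). No-calls (``./.``) are skipped with a log message.
    Optional toolkit INFO keys: ``PO`` (parental origin), ``DN`` (de novo
    status), ``HF`` (heteroplasmy fraction).
    """
    import pysam

    out: list[Variant] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        if sample is None:
            if len(samples) != 1:
                raise ValueError(f"sample must be named; VCF has samples {samples}")
            sample = samples[0]
        if sample not in samples:
            raise ValueError(f"sample {sample!r} not in VCF (has {samples})")
        for rec in vcf:
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or all(a is None for a in gt):
                logger.info("skipping no-call at %s:%s", rec.chrom, rec.pos)
                continue
            alleles = tuple(a for a in gt if a is not None)
            if not any(a > 0 for a in alleles):
                continue  # homozygous reference: nothing observed
            alt_index = next(a for a in alleles if a > 0)
            alt = rec.alts[alt_index - 1]
            phased = bool(getattr(call, "phased", False))
            ps = call.get("PS")
            haplotype = None
            if phased and len(alleles) > 1:
                haplotype = next(i for i, a in enumerate(alleles) if a > 0)
            def info_get(key, rec=rec):
                try:  # pysam raises on keys absent from the VCF header
                    return rec.info.get(key)
                except (KeyError, ValueError):
                    return None

            hf = info_get("HF")
            out.append(
                Variant(
                    chromosome=rec.chrom,
                    position=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    sample=sample,
                    genotype=alleles,
                    phased=phased,
                    phase_set=str(ps) if ps is not None else None,
                    haplotype=haplotype,
                    parental_origin=info_get("PO"),
                    de_novo_status=info_get("DN"),
                    heteroplasmy=float(hf) if hf is not None else None,
                )
            )
    return out


def annotate_variants(
    variants: Iterable[Variant],
    transcripts: Iterable[TranscriptModel],
    matrix: ConsequenceMatrix,
) -> list[AnnotatedVariant]:
    """Classify each variant against the transcripts it overlaps and attach
    the matrix consequence profile (most severe class across transcripts)."""
    transcripts = list(transcripts)
    out = []
    for variant in variants:
        results = []
        for tx in transcripts:
            res = classify_variant(variant, tx)
            if res.variant_class is not None:
                results.append(res)
        if not results:
            continue
        best = min(results, key=lambda r: r.variant_class.severity_rank)
        vc = best.variant_class
        profile = matrix.row_profile(vc) if vc.name in matrix.rows else matrix.row_profile(vc.base_so_term)
        out.append(
            AnnotatedVariant(
                variant=variant,
                variant_class=vc,
                nmd_flag=vc.nmd_qualifier,
                consequence_profile=profile,
                transcript_id=best.transcript_id,
                ptc_tx_position=best.ptc_tx_position,
                detail=best.detail,
            )
        )
    return out
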