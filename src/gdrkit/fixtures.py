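"""Deterministic generators for toy transcripts, recipe-driven variant sets
and exemplar gene-disease curations.

Everything here is a pure function of its arguments plus a seed, so the rest
of the toolkit is testable without downloads. Reference sequences are
seed-generated, not a real genome. Exemplar curations are built from
published gene examples (MYH7, KCNQ1, EFNB1, ...); records for requirement
contexts with no published exemplar (Y-linked, mitochondrial, PAR) are
synthetic and labeled as such in their provenance field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .annotate import Variant, classify_variant
from .curation import GeneDiseaseCuration
from .matrix import VariantClass
from .transcripts import TranscriptModel, reverse_complement

__all__ = [
    "VariantRecipe",
    "synth_transcript",
    "synth_variants",
    "exemplar_curations",
    "write_fasta",
    "write_gff3",
    "write_vcf",
]

_STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"

_ZYGOSITY_GT = {
    "heterozygous": "0/1",
    "homozygous_alt": "1/1",
    "hemizygous": "1",
}


@dataclass(frozen=True)
class VariantRecipe:
    """Requested variant-class counts, a seed, and a per-variant zygosity plan.

    ``zygosities`` applies to the generated variants in deterministic order
    (classes sorted by name, then generation order); missing entries default
    to heterozygous.
    """

    counts: dict[str, int]
    seed: int = 0
    zygosities: Optional[tuple[str, ...]] = None


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _random_cds(rng: np.random.Generator, length: int) -> str:
    if length % 3 != 0 or length < 9:
        raise ValueError(f"CDS length must be a multiple of 3 and >= 9, got {length}")
    codons = ["ATG"]
    for _ in range(length // 3 - 2):
        while True:
            codon = _random_seq(rng, 3)
            if codon not in _STOP_CODONS:
                break
        codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def synth_transcript(
    n_exons: int = 3,
    exon_lengths: Optional[Sequence[int]] = None,
    intron_lengths: Optional[Sequence[int]] = None,
    utr5: int = 30,
    utr3: int = 30,
    strand: str = "+",
    seed: int = 0,
    chromosome: str = "chr1",
    gene_symbol: str = "TOY1",
    transcript_id: Optional[str] = None,
    flank: int = 100,
) -> TranscriptModel:
    """Generate a reproducible toy transcript with a translatable CDS.

    The CDS starts ATG, ends with a stop codon and contains no internal
    in-frame stop. Introns carry canonical GT..AG splice dinucleotides.
    """
    rng = np.random.default_rng(seed)
    if exon_lengths is None:
        exon_lengths = [150] * n_exons
    if len(exon_lengths) != n_exons:
        raise ValueError("exon_lengths must have n_exons entries")
    if intron_lengths is None:
        intron_lengths = [80] * (n_exons - 1)
    if len(intron_lengths) != n_exons - 1:
        raise ValueError("intron_lengths must have n_exons - 1 entries")
    if any(l <= 0 for l in exon_lengths) or any(l < 20 for l in intron_lengths):
        raise ValueError("exon lengths must be positive and introns >= 20 nt")
    total_exonic = int(sum(exon_lengths))
    cds_len = total_exonic - utr5 - utr3
    if cds_len < 9 or cds_len % 3 != 0:
        raise ValueError(
            f"infeasible geometry: CDS length {cds_len} (exonic {total_exonic} "
            f"minus UTRs {utr5}+{utr3}) must be >= 9 and divisible by 3"
        )

    spliced = _random_seq(rng, utr5) + _random_cds(rng, cds_len) + _random_seq(rng, utr3)

    # split spliced sequence into exons, interleave introns (assembly = transcript orientation)
    exon_seqs = []
    offset = 0
    for length in exon_lengths:
        exon_seqs.append(spliced[offset : offset + length])
        offset += length
    intron_seqs = ["GT" + _random_seq(rng, l - 4) + "AG" for l in intron_lengths]

    assembly = _random_seq(rng, flank)
    exon_asm: list[tuple[int, int]] = []  # 1-based inclusive in assembly space
    for i, ex in enumerate(exon_seqs):
        start = len(assembly) + 1
        assembly += ex
        exon_asm.append((start, len(assembly)))
        if i < len(intron_seqs):
            assembly += intron_seqs[i]
    assembly += _random_seq(rng, flank)

    def tx_to_asm(tx_pos: int) -> int:
        remaining = tx_pos
        for (s, e) in exon_asm:
            length = e - s + 1
            if remaining <= length:
                return s + remaining - 1
            remaining -= length
        raise ValueError(f"transcript position {tx_pos} beyond transcript")

    cds_asm = (tx_to_asm(utr5 + 1), tx_to_asm(utr5 + cds_len))

    if strand == "+":
        chrom_seq = assembly
        exons = tuple(exon_asm)
        cds_start, cds_end = cds_asm
    elif strand == "-":
        L = len(assembly)
        chrom_seq = reverse_complement(assembly)
        exons = tuple(sorted((L - e + 1, L - s + 1) for s, e in exon_asm))
        cds_start, cds_end = L - cds_asm[1] + 1, L - cds_asm[0] + 1
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")

    model = TranscriptModel(
        transcript_id=transcript_id or f"{gene_symbol}-tx1",
        gene_symbol=gene_symbol,
        chromosome=chromosome,
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        chrom_seq=chrom_seq,
    )
    cds = model.cds_sequence
    assert cds.startswith("ATG") and cds[-3:] in _STOP_CODONS and len(cds) % 3 == 0
    return model


# -- recipe-driven variant synthesis -------------------------------------------

def _tx_to_genomic(transcript: TranscriptModel, tx_pos: int) -> int:
    remaining = tx_pos
    exons = transcript.exons if transcript.strand == "+" else tuple(reversed(transcript.exons))
    for (s, e) in exons:
        length = e - s + 1
        if remaining <= length:
            return s + remaining - 1 if transcript.strand == "+" else e - remaining + 1
        remaining -= length
    raise ValueError(f"transcript position {tx_pos} beyond transcript length {transcript.length}")


def _substitution_candidates(transcript: TranscriptModel, tx_positions: Iterable[int]):
    seq = transcript.chrom_seq
    for tx_pos in tx_positions:
        g = _tx_to_genomic(transcript, tx_pos)
        ref = seq[g - 1]
        for alt in _BASES:
            if alt != ref:
                yield (g, ref, alt)


def _candidate_edits(transcript: TranscriptModel, target: VariantClass):
    """Yield candidate (genomic_pos, ref, alt) edits plausibly producing the
    target class; each is verified by classification before acceptance."""
    seq = transcript.chrom_seq
    cstart, cend = transcript.cds_tx_interval
    base = target.base_so_term

    if base in ("missense_variant", "synonymous_variant", "stop_gained", "stop_lost", "start_lost"):
        if base == "start_lost":
            positions = range(cstart, cstart + 3)
        elif base == "stop_lost":
            positions = range(cend - 2, cend + 1)
        else:
            positions = range(cstart + 3, cend - 2)
        yield from _substitution_candidates(transcript, positions)
    elif base in ("5_prime_UTR_variant",):
        yield from _substitution_candidates(transcript, range(1, cstart))
    elif base in ("3_prime_UTR_variant",):
        yield from _substitution_candidates(transcript, range(cend + 1, transcript.length + 1))
    elif base in ("splice_donor_variant", "splice_acceptor_variant", "splice_region_variant", "intron_variant"):
        if not transcript.introns:
            return
        for (istart, iend) in transcript.introns:
            for g in range(istart, iend + 1):
                ref = seq[g - 1]
                for alt in _BASES:
                    if alt != ref:
                        yield (g, ref, alt)
    elif base == "frameshift_variant":
        for tx_pos in range(cstart + 3, cend - 3):
            g = _tx_to_genomic(transcript, tx_pos)
            anchor = seq[g - 2]
            # 1-bp deletion (anchored VCF style)
            yield (g - 1, anchor + seq[g - 1], anchor)
            # 1-bp insertion
            yield (g - 1, anchor, anchor + "A")
    elif base in ("inframe_deletion", "inframe_insertion"):
        for tx_pos in range(cstart + 3, cend - 5, 3):
            g = _tx_to_genomic(transcript, tx_pos)
            anchor = seq[g - 2]
            if base == "inframe_deletion":
                yield (g - 1, anchor + seq[g - 1 : g + 2], anchor)
            else:
                yield (g - 1, anchor, anchor + "GCT")
    else:
        return


def synth_variants(
    transcript: TranscriptModel,
    recipe: VariantRecipe,
    out_path=None,
    sample: str = "S1",
) -> list[Variant]:
    """Generate variants matching the recipe's class counts; optionally write
    them as a VCF. Every emitted variant is verified to reclassify to its
    requested class (including the NMD qualifier when requested)."""
    rng = np.random.default_rng(recipe.seed)
    variants: list[Variant] = []
    used_positions: set[int] = set()
    zygosities = list(recipe.zygosities or ())

    order_index = 0
    for name in sorted(recipe.counts):
        count = recipe.counts[name]
        target = VariantClass.parse(name)
        candidates = list(_candidate_edits(transcript, target))
        if not candidates:
            raise ValueError(
                f"class {name!r} is not producible on transcript "
                f"{transcript.transcript_id} (e.g. splice classes need introns)"
            )
        rng.shuffle(candidates)
        accepted = 0
        for (pos, ref, alt) in candidates:
            if accepted == count:
                break
            if pos in used_positions:
                continue
            zygosity = (
                zygosities[order_index] if order_index < len(zygosities) else "heterozygous"
            )
            gt = (0, 1) if zygosity == "heterozygous" else (1, 1) if zygosity == "homozygous_alt" else (1,)
            variant = Variant(
                chromosome=transcript.chromosome, position=pos, ref=ref, alt=alt,
                sample=sample, genotype=gt,
            )
            result = classify_variant(variant, transcript)
            if result.variant_class is None:
                continue
            matches = (
                result.variant_class.name == target.name
                if target.nmd_qualifier != "not_applicable"
                else result.variant_class.base_so_term == target.base_so_term
            )
            if matches:
                variants.append(variant)
                used_positions.add(pos)
                accepted += 1
                order_index += 1
        if accepted < count:
            raise ValueError(
                f"could not generate {count} variants of class {name!r} on "
                f"transcript {transcript.transcript_id} (found {accepted})"
            )
    variants.sort(key=lambda v: v.position)
    if out_path is not None:
        write_vcf(variants, out_path, transcript.chromosome, len(transcript.chrom_seq), sample)
    return variants


def write_vcf(
    variants: Sequence[Variant], path, chromosome: str, chrom_length: int, sample: str = "S1"
) -> None:
    """Write variants as plain VCF 4.2 with one sample column."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chromosome},length={chrom_length}>",
        '##INFO=<ID=PO,Number=1,Type=String,Description="Parental origin of the alt allele">',
        '##INFO=<ID=DN,Number=1,Type=String,Description="De novo status">',
        '##INFO=<ID=HF,Number=1,Type=Float,Description="Heteroplasmy fraction">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for v in sorted(variants, key=lambda v: (v.chromosome, v.position, v.alt)):
        info_parts = []
        if v.parental_origin:
            info_parts.append(f"PO={v.parental_origin}")
        if v.de_novo_status:
            info_parts.append(f"DN={v.de_novo_status}")
        if v.heteroplasmy is not None:
            info_parts.append(f"HF={v.heteroplasmy:g}")
        info = ";".join(info_parts) or "."
        sep = "|" if v.phased else "/"
        gt = sep.join(str(a) for a in v.genotype)
        fmt, values = "GT", gt
        if v.phase_set is not None:
            fmt, values = "GT:PS", f"{gt}:{v.phase_set}"
        lines.append(
            f"{v.chromosome}\t{v.position}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\t{fmt}\t{values}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(transcripts: Sequence[TranscriptModel], path) -> None:
    seen: dict[str, str] = {}
    for tx in transcripts:
        seen.setdefault(tx.chromosome, tx.chrom_seq)
    with open(path, "w") as fh:
        for chrom, seq in seen.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_gff3(transcripts: Sequence[TranscriptModel], path) -> None:
    lines = ["##gff-version 3"]
    for tx in transcripts:
        s, e = tx.span
        gid = f"gene-{tx.gene_symbol}"
        lines.append(
            f"{tx.chromosome}\tgdrkit\tgene\t{s}\t{e}\t.\t{tx.strand}\t.\tID={gid};Name={tx.gene_symbol}"
        )
        lines.append(
            f"{tx.chromosome}\tgdrkit\tmRNA\t{s}\t{e}\t.\t{tx.strand}\t.\t"
            f"ID={tx.transcript_id};Parent={gid};gene_name={tx.gene_symbol}"
        )
        for i, (xs, xe) in enumerate(tx.exons, 1):
            lines.append(
                f"{tx.chromosome}\tgdrkit\texon\t{xs}\t{xe}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id}-exon{i};Parent={tx.transcript_id}"
            )
        for (xs, xe) in tx.exons:
            cs, ce = max(xs, tx.cds_start), min(xe, tx.cds_end)
            if cs <= ce:
                lines.append(
                    f"{tx.chromosome}\tgdrkit\tCDS\t{cs}\t{ce}\t.\t{tx.strand}\t0\t"
                    f"ID={tx.transcript_id}-cds;Parent={tx.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


# -- exemplar curations ---------------------------------------------------------

def exemplar_curations() -> list[GeneDiseaseCuration]:
    """Bundled gene-disease curation exemplars.

    Published examples cover the autosomal and X-linked requirement tokens and
    the qualifier vocabulary; Y-linked, mitochondrial and pseudoautosomal
    records (and the dual-phenotype X gene) are synthetic stand-ins, marked
    ``synthetic`` in their provenance. Every allelic-requirement token is
    exercised at least once.
    """
    C = GeneDiseaseCuration
    fs = frozenset
    return [
        C("MYH7", "hypertrophic cardiomyopathy", "monoallelic_autosomal",
          qualifiers=fs({"HP:0003831"}),
          disease_associated_consequences=fs({"altered gene product sequence"}),
          known_pathogenic_variant_classes=fs({"missense_variant"}),
          mechanism_note="requires an abnormal gene product; not haploinsufficient (PTCs not pathogenic)",
          provenance="published example"),
        C("KCNQ1", "short QT syndrome", "monoallelic_autosomal",
          disease_associated_consequences=fs({"altered gene product sequence"}),
          known_pathogenic_variant_classes=fs({"missense_variant"}),
          mechanism_note="gain of function; evidence derives from a single recurrent missense variant p.(Val141Met)",
          provenance="published example"),
        C("FBN1", "Marfan syndrome", "monoallelic_autosomal",
          disease_associated_consequences=fs({"altered gene product sequence", "decreased gene product level"}),
          known_pathogenic_variant_classes=fs({"missense_variant", "stop_gained|NMD_triggering", "frameshift_variant|NMD_triggering"}),
          provenance="published example"),
        C("EFNB1", "craniofrontonasal dysplasia", "monoallelic_X_heterozygous",
          qualifiers=fs({"HP:0034343"}),
          disease_associated_consequences=fs({"altered gene product sequence", "decreased gene product level"}),
          known_pathogenic_variant_classes=fs({"missense_variant", "stop_gained|NMD_triggering"}),
          mechanism_note="cellular interference: most severe in the heterozygous (functionally mosaic) state",
          provenance="published example"),
        C("DMPK", "myotonic dystrophy type 1", "monoallelic_autosomal",
          qualifiers=fs({"HP:0003743"}),
          disease_associated_consequences=fs({"altered gene product sequence"}),
          mechanism_note="triplet repeat expansion (toxic RNA); anticipation across generations",
          provenance="published example"),
        C("DHH", "46,XY gonadal dysgenesis", "biallelic_autosomal",
          qualifiers=fs({"HP:0001475"}),
          disease_associated_consequences=fs({"decreased gene product level", "absent gene product"}),
          known_pathogenic_variant_classes=fs({"stop_gained|NMD_triggering", "missense_variant"}),
          mechanism_note="manifests only in XY males; XX females phenotypically normal",
          provenance="published example"),
        C("NF1", "neurofibromatosis type 1", "monoallelic_autosomal",
          qualifiers=fs({"HP:0034950"}),
          disease_associated_consequences=fs({"decreased gene product level", "absent gene product", "altered gene product sequence"}),
          known_pathogenic_variant_classes=fs({"stop_gained|NMD_triggering", "frameshift_variant|NMD_triggering", "splice_donor_variant", "missense_variant"}),
          provenance="published example"),
        C("CYP1B1", "primary congenital glaucoma", "biallelic_autosomal",
          qualifiers=fs({"HP:0003829", "HP:4000158"}),
          disease_associated_consequences=fs({"decreased gene product level", "absent gene product", "altered gene product sequence"}),
          known_pathogenic_variant_classes=fs({"missense_variant", "stop_gained|NMD_triggering", "frameshift_variant|NMD_triggering"}),
          mechanism_note="approximately 90% penetrance",
          provenance="published example"),
        C("IRF6", "Van der Woude syndrome", "monoallelic_autosomal",
          qualifiers=fs({"HP:0003829", "HP:4000158"}),
          disease_associated_consequences=fs({"decreased gene product level", "altered gene product sequence"}),
          known_pathogenic_variant_classes=fs({"missense_variant", "stop_gained|NMD_triggering"}),
          mechanism_note="cleft lip and/or palate; penetrance estimated at 80%",
          provenance="published example"),
        C("C9orf72", "frontotemporal dementia and/or ALS", "monoallelic_autosomal",
          qualifiers=fs({"HP:0003829", "HP:4000159", "HP:0003831"}),
          disease_associated_consequences=fs({"altered gene product level"}),
          mechanism_note="repeat expansion; approximately 50% penetrance",
          provenance="published example"),
        C("RYR1", "malignant hyperthermia susceptibility", "monoallelic_autosomal",
          disease_associated_consequences=fs({"altered gene product sequence"}),
          known_pathogenic_variant_classes=fs({"missense_variant"}),
          mechanism_note="mechanism (dominant negative vs haploinsufficiency) unclear",
          provenance="published example"),
        C("CACNA1S", "malignant hyperthermia susceptibility", "monoallelic_autosomal",
          disease_associated_consequences=fs({"altered gene product sequence"}),
          known_pathogenic_variant_classes=fs({"missense_variant"}),
          mechanism_note="mechanism (dominant negative vs haploinsufficiency) unclear",
          provenance="published example"),
        # Hypothetical dual-phenotype X-linked gene: hemizygous/biallelic variation
        # causes congenital heart disease; heterozygous variation causes
        # late-onset cardiomyopathy. Distinct curations, distinct filtering.
        C("TOYX", "congenital heart disease (toy)", "monoallelic_X_hemizygous",
          disease_associated_consequences=fs({"decreased gene product level", "absent gene product"}),
          known_pathogenic_variant_classes=fs({"stop_gained|NMD_triggering", "frameshift_variant|NMD_triggering"}),
          provenance="synthetic (dual-phenotype scenario)"),
        C("TOYX", "dilated cardiomyopathy (toy)", "monoallelic_X_heterozygous",
          qualifiers=fs({"HP:0003831"}),
          disease_associated_consequences=fs({"decreased gene product level", "absent gene product"}),
          known_pathogenic_variant_classes=fs({"stop_gained|NMD_triggering"}),
          provenance="synthetic (dual-phenotype scenario)"),
        C("TOYY", "toy Y-linked spermatogenic failure", "monoallelic_Y_hemizygous",
          disease_associated_consequences=fs({"absent gene product", "decreased gene product level"}),
          known_pathogenic_variant_classes=fs({"stop_gained|NMD_triggering"}),
          provenance="synthetic"),
        C("TOYMT", "toy mitochondrial encephalomyopathy", "mitochondrial",
          disease_associated_consequences=fs({"altered gene product sequence"}),
          known_pathogenic_variant_classes=fs({"missense_variant"}),
          provenance="synthetic"),
        C("TOYPAR1", "toy PAR dominant skeletal dysplasia", "monoallelic_PAR",
          disease_associated_consequences=fs({"decreased gene product level", "absent gene product"}),
          known_pathogenic_variant_classes=fs({"stop_gained|NMD_triggering", "frameshift_variant|NMD_triggering"}),
          provenance="synthetic"),
        C("TOYPAR2", "toy PAR recessive dysplasia", "biallelic_PAR",
          disease_associated_consequences=fs({"decreased gene product level", "absent gene product"}),
          known_pathogenic_variant_classes=fs({"stop_gained|NMD_triggering"}),
          provenance="synthetic"),
    ]
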