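"""Transcript models: exon/CDS structure plus reference sequence.

Coordinates follow the usual conventions: genomic and transcript positions
are 1-based inclusive (VCF-style); internal interval arithmetic is 0-based
half-open. Exons are stored in genomic order; transcript orientation follows
``strand``. The model carries the reference sequence of its chromosome (toy
chromosomes here are kilobase-scale), which makes variant application and
CDS translation self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

__all__ = ["TranscriptModel", "transcript_from_json", "transcripts_from_json", "transcripts_from_gff3"]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_symbol: str
    chromosome: str
    strand: str  # + | -
    exons: tuple[tuple[int, int], ...]  # genomic, 1-based inclusive, sorted
    cds_start: int  # genomic, 1-based; cds_start <= cds_end regardless of strand
    cds_end: int
    chrom_seq: str  # reference sequence of the chromosome

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        exons = self.exons
        if not exons:
            raise ValueError("transcript must have at least one exon")
        for (s, e) in exons:
            if not 1 <= s <= e <= len(self.chrom_seq):
                raise ValueError(f"exon ({s}, {e}) outside chromosome of length {len(self.chrom_seq)}")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError("exons must be non-overlapping and sorted")
        if not (self.cds_start <= self.cds_end):
            raise ValueError("cds_start must be <= cds_end (genomic)")
        for pos in (self.cds_start, self.cds_end):
            if self.tx_position(pos) is None:
                raise ValueError(f"CDS bound {pos} does not fall inside an exon")

    # -- basic geometry ------------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        lengths = tuple(e - s + 1 for s, e in self.exons)
        return lengths if self.strand == "+" else lengths[::-1]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    def tx_position(self, genomic_pos: int) -> Optional[int]:
        """Map a genomic position to a 1-based transcript coordinate.

        Returns None for intronic or out-of-transcript positions.
        """
        offset = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= genomic_pos <= e:
                    return offset + (genomic_pos - s) + 1
                offset += e - s + 1
        else:
            for s, e in reversed(self.exons):
                if s <= genomic_pos <= e:
                    return offset + (e - genomic_pos) + 1
                offset += e - s + 1
        return None

    # -- sequence ------------------------------------------------------------

    @property
    def spliced_sequence(self) -> str:
        parts = [self.chrom_seq[s - 1 : e] for s, e in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)

    @property
    def cds_tx_interval(self) -> tuple[int, int]:
        """CDS span in transcript coordinates (1-based inclusive)."""
        a = self.tx_position(self.cds_start)
        b = self.tx_position(self.cds_end)
        assert a is not None and b is not None
        return (a, b) if a <= b else (b, a)

    @property
    def cds_sequence(self) -> str:
        a, b = self.cds_tx_interval
        return self.spliced_sequence[a - 1 : b]

    @property
    def junction_tx_positions(self) -> tuple[int, ...]:
        """Transcript coordinates of the last base of each exon but the last
        (the exon-exon junctions, in transcript orientation)."""
        out = []
        running = 0
        for length in self.exon_lengths[:-1]:
            running += length
            out.append(running)
        return tuple(out)

    # -- editing -------------------------------------------------------------

    def apply_edit(self, pos: int, ref: str, alt: str) -> "TranscriptModel":
        """Return the transcript model over the chromosome with ``ref`` at
        genomic ``pos`` replaced by ``alt``; exon and CDS coordinates
        downstream of the edit shift by the length difference.

        The edit must match the reference; edits are expected to lie within a
        single exon or intron (fixture-scale variants).
        """
        if self.chrom_seq[pos - 1 : pos - 1 + len(ref)] != ref:
            raise ValueError(
                f"reference mismatch at {self.chromosome}:{pos}: expected "
                f"{self.chrom_seq[pos - 1 : pos - 1 + len(ref)]!r}, got {ref!r}"
            )
        delta = len(alt) - len(ref)
        new_seq = self.chrom_seq[: pos - 1] + alt + self.chrom_seq[pos - 1 + len(ref) :]
        edit_end = pos + len(ref)  # first genomic position after the edit

        def shift(coord: int) -> int:
            return coord + delta if coord >= edit_end else coord

        new_exons = tuple((shift(s), shift(e)) for s, e in self.exons)
        return replace(
            self,
            chrom_seq=new_seq,
            exons=new_exons,
            cds_start=shift(self.cds_start),
            cds_end=shift(self.cds_end),
        )

    # -- serialization -------------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "id": self.transcript_id,
            "gene": self.gene_symbol,
            "chrom": self.chromosome,
            "strand": self.strand,
            "exons": [list(e) for e in self.exons],
            "cds_start": self.cds_start,
            "cds_end": self.cds_end,
            "sequence": self.chrom_seq,
        }


def transcript_from_json(data: dict) -> TranscriptModel:
    """Build a model from the minimal JSON form
    ``{id, gene, chrom, strand, exons, cds_start, cds_end, sequence}`` where
    ``sequence`` is the chromosome reference sequence."""
    return TranscriptModel(
        transcript_id=data["id"],
        gene_symbol=data.get("gene", data["id"]),
        chromosome=data["chrom"],
        strand=data["strand"],
        exons=tuple(tuple(e) for e in data["exons"]),
        cds_start=data["cds_start"],
        cds_end=data["cds_end"],
        chrom_seq=data["sequence"],
    )


def transcripts_from_json(path) -> list[TranscriptModel]:
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    return [transcript_from_json(d) for d in payload]


def transcripts_from_gff3(gff_path, fasta_path) -> list[TranscriptModel]:
    """Load transcript models from GFF3 (mRNA/exon/CDS features) plus a
    reference FASTA."""
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
    )
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    chrom_cache: dict[str, str] = {}
    models = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not exons or not cds:
            continue
        chrom = mrna.seqid
        if chrom not in chrom_cache:
            chrom_cache[chrom] = str(fasta[chrom][:])
        gene = mrna.attributes.get("gene_name", mrna.attributes.get("gene", [mrna.id]))[0]
        models.append(
            TranscriptModel(
                transcript_id=mrna.id,
                gene_symbol=gene,
                chromosome=chrom,
                strand=mrna.strand,
                exons=tuple(exons),
                cds_start=cds[0][0],
                cds_end=cds[-1][1],
                chrom_seq=chrom_cache[chrom],
            )
        )
    return models
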