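"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected outcomes from first principles
(explicit case enumeration, explicit junction lists) without calling the
implementation they check.
"""

from __future__ import annotations


def nmd_oracle(ptc_tx_position: int, exons, strand: str) -> str:
    """Rule-scan NMD oracle from an explicit junction list.

    Recomputes exon lengths in transcript orientation directly from the
    genomic exon intervals and applies: single exon -> escaping; PTC in last
    exon -> escaping; PTC <= 50 nt upstream of the final junction -> escaping;
    else triggering.
    """
    lengths = [e - s + 1 for s, e in exons]
    if strand == "-":
        lengths = lengths[::-1]
    if len(lengths) == 1:
        return "escaping"
    junctions = []
    total = 0
    for L in lengths[:-1]:
        total += L
        junctions.append(total)
    last_junction = junctions[-1]
    if ptc_tx_position > last_junction:
        return "escaping"
    if last_junction - ptc_tx_position <= 50:
        return "escaping"
    return "triggering"


def requirement_oracle(token: str, karyotype: str, zygosities, in_par=None) -> str:
    """Truth-table oracle for requirement satisfaction (status only).

    ``zygosities`` is the multiset of qualifying observations
    (heterozygous / homozygous_alt / hemizygous); phase is unknown.
    ``in_par`` optionally marks, per observation, whether it falls in a
    pseudoautosomal interval (defaults to all inside for PAR requirements).
    """
    zygs = list(zygosities)
    if token in ("monoallelic_PAR", "biallelic_PAR"):
        flags = list(in_par) if in_par is not None else [True] * len(zygs)
        zygs = [z for z, ok in zip(zygs, flags) if ok]
    n = len(zygs)
    n_hom = zygs.count("homozygous_alt")
    n_single = zygs.count("heterozygous") + zygs.count("hemizygous")
    n_het = zygs.count("heterozygous")

    if token == "monoallelic_autosomal" or token == "monoallelic_PAR":
        return "satisfied" if n else "unsatisfied"

    if token == "biallelic_autosomal" or token == "biallelic_PAR":
        if n_hom:
            return "satisfied"
        if n_single >= 2:
            return "candidate_partial"  # possible compound het, phase unknown
        if n_single == 1:
            return "candidate_partial"  # second contributory variant sought
        return "unsatisfied"

    if token == "monoallelic_X_heterozygous":
        return "satisfied" if n else "unsatisfied"

    if token == "monoallelic_X_hemizygous":
        if n == 0:
            return "unsatisfied"
        if karyotype == "XY":
            return "satisfied"
        if karyotype == "XX":
            if n_hom:
                return "satisfied"
            if n_het >= 2:
                return "candidate_partial"
            return "unsatisfied"  # single het female: carrier
        return "candidate_partial"  # unknown karyotype: conservative

    if token == "monoallelic_Y_hemizygous":
        if karyotype == "XX":
            return "unsatisfied"
        if n == 0:
            return "unsatisfied"
        return "satisfied" if karyotype == "XY" else "candidate_partial"

    if token == "mitochondrial":
        return "satisfied" if n else "unsatisfied"

    raise ValueError(f"oracle does not model {token}")
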