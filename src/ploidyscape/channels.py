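"""Canonical mutation-channel schemas.

SBS96: single-base substitutions on the pyrimidine strand, stratified by the
5' and 3' flanking bases — 6 substitution types x 4 x 4 contexts. ID83: small
insertions/deletions stratified by type, size, homopolymer/repeat context and
microhomology. Label strings and row order follow the COSMIC conventions
(``A[C>A]A`` ...; ``1:Del:C:0`` ...).
"""

from __future__ import annotations

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def _sbs96_labels() -> list[str]:
    labels = []
    for sub in SUBSTITUTIONS:
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return labels


def _id83_labels() -> list[str]:
    labels = []
    # 1-bp deletions / insertions in homopolymer context
    for kind in ("Del", "Ins"):
        for base in ("C", "T"):
            for k in range(6):
                labels.append(f"1:{kind}:{base}:{k}")
    # >=2-bp deletions / insertions in tandem-repeat context
    for kind in ("Del", "Ins"):
        for size in (2, 3, 4, 5):
            for k in range(6):
                labels.append(f"{size}:{kind}:R:{k}")
    # deletions with flanking microhomology
    for size, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        for mh in range(1, max_mh + 1):
            labels.append(f"{size}:Del:M:{mh}")
    return labels


SBS96_LABELS: tuple[str, ...] = tuple(_sbs96_labels())
ID83_LABELS: tuple[str, ...] = tuple(_id83_labels())

SBS96_INDEX = {lab: i for i, lab in enumerate(SBS96_LABELS)}
ID83_INDEX = {lab: i for i, lab in enumerate(ID83_LABELS)}

assert len(SBS96_LABELS) == 96
assert len(ID83_LABELS) == 83


def sbs_label(five: str, ref: str, alt: str, three: str) -> str:
    """Canonical SBS96 label for a substitution with its trinucleotide context.

    Purine-reference variants are mapped to the reverse-complement
    pyrimidine-strand representation.
    """
    five, ref, alt, three = five.upper(), ref.upper(), alt.upper(), three.upper()
    if ref in ("A", "G"):
        five, three = COMPLEMENT[three], COMPLEMENT[five]
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{five}[{ref}>{alt}]{three}"
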