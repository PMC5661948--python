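"""Design internally tagged protein variants.

A design places a peptide tag (typically a TEV protease recognition site)
after a chosen residue, optionally deleting the residues that follow the
insertion point and/or re-appending a duplicated run of upstream residues
after the tag.  Every design is reversible: removing the tag and the
duplication and restoring the deleted span recovers the original protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .io_formats import ProteinRecord

__all__ = [
    "TEV_MIN", "TEV_EXT", "TEV_FLANKED", "TEV_CORE", "TAG_LIBRARY",
    "TagDesign", "design_insertion", "original_context",
    "back_translate", "translate", "extension_length",
    "ECOLI_PREFERRED_CODONS",
]

#: TEV protease recognition core ENLYFQ↓ (cleavage before the following G/S).
TEV_CORE = "ENLYFQ"
#: Minimal TEV-tag: the canonical recognition heptapeptide.
TEV_MIN = "ENLYFQG"
#: Minimal tag extended by five C-terminal residues from a natural TEV
#: polyprotein junction; substantially improves cleavage of internal tags.
TEV_EXT = "ENLYFQGESLFK"
#: Extended tag with additional N/C flanking residues for rigid contexts.
TEV_FLANKED = "PPKNENLYFQGESLFKGP"

TAG_LIBRARY: Mapping[str, str] = {
    "min": TEV_MIN,
    "ext": TEV_EXT,
    "flanked": TEV_FLANKED,
}

#: Highest-usage codon per amino acid in E. coli K-12 (configurable default).
ECOLI_PREFERRED_CODONS: Mapping[str, str] = {
    "A": "GCG", "R": "CGC", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}


@dataclass(frozen=True)
class TagDesign:
    """An insertion recipe and the resulting variant sequence.

    ``after_pos`` is the residue after which the tag is placed (1-based).
    ``delete_span`` is the removed residue range (starts at after_pos + 1);
    ``duplicate_span`` is an upstream range re-appended after the tag.
    ``context`` renders the junction with 3-residue flanks, the inserted
    residues between ``**`` markers.
    """

    target: ProteinRecord
    after_pos: int
    tag: str
    delete_span: tuple[int, int] | None
    duplicate_span: tuple[int, int] | None
    variant_sequence: str
    context: str

    @property
    def deleted_length(self) -> int:
        if self.delete_span is None:
            return 0
        return self.delete_span[1] - self.delete_span[0] + 1

    @property
    def duplicated_length(self) -> int:
        if self.duplicate_span is None:
            return 0
        return self.duplicate_span[1] - self.duplicate_span[0] + 1

    def revert(self) -> str:
        """Reconstruct the original target sequence from the variant."""
        seq = self.variant_sequence
        ins_len = len(self.tag) + self.duplicated_length
        head = seq[: self.after_pos]
        tail = seq[self.after_pos + ins_len :]
        deleted = ""
        if self.delete_span is not None:
            d1, d2 = self.delete_span
            deleted = self.target.sequence[d1 - 1 : d2]
        return head + deleted + tail


def design_insertion(target: ProteinRecord, after_pos: int, tag: str,
                     delete_len: int = 0,
                     duplicate_span: tuple[int, int] | None = None) -> TagDesign:
    """Insert ``tag`` after residue ``after_pos``, optionally deleting the
    ``delete_len`` residues that follow and/or re-appending
    ``duplicate_span`` (an upstream range ending at or before after_pos)
    after the tag."""
    seq = target.sequence
    L = target.length
    if not 1 <= after_pos <= L:
        raise ValueError(f"after_pos {after_pos} outside 1..{L}")
    if delete_len < 0 or after_pos + delete_len > L:
        raise ValueError(f"delete_len {delete_len} extends past the C-terminus")
    dup = ""
    if duplicate_span is not None:
        u1, u2 = duplicate_span
        if not (1 <= u1 <= u2 <= after_pos):
            raise ValueError(f"duplicate_span {duplicate_span} not within [1, after_pos]")
        dup = seq[u1 - 1 : u2]
    insert = tag + dup
    variant = seq[:after_pos] + insert + seq[after_pos + delete_len :]

    flank_n = seq[max(0, after_pos - 3) : after_pos]
    flank_c = seq[after_pos + delete_len : after_pos + delete_len + 3]
    context = f"{flank_n}**{insert}**{flank_c}"

    delete_span = (after_pos + 1, after_pos + delete_len) if delete_len else None
    return TagDesign(target=target, after_pos=after_pos, tag=tag,
                     delete_span=delete_span, duplicate_span=duplicate_span,
                     variant_sequence=variant, context=context)


def original_context(target: ProteinRecord, after_pos: int,
                     delete_len: int = 0) -> str:
    """Render the unmodified junction the same way designs are rendered.

    With a deletion, the deleted residues appear between ``**``; without
    one, the six residues around the insertion point are shown.
    """
    seq = target.sequence
    if delete_len:
        flank_n = seq[max(0, after_pos - 3) : after_pos]
        deleted = seq[after_pos : after_pos + delete_len]
        flank_c = seq[after_pos + delete_len : after_pos + delete_len + 3]
        return f"{flank_n}**{deleted}**{flank_c}"
    return seq[max(0, after_pos - 3) : after_pos + 3]


_STANDARD_TRANSLATION = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}


def back_translate(peptide: str,
                   codon_table: Mapping[str, str] = ECOLI_PREFERRED_CODONS) -> str:
    """Encode a peptide as DNA using one codon per residue (3 nt each)."""
    out = []
    for res in peptide.upper():
        if res not in codon_table:
            raise ValueError(f"no codon for residue {res!r}")
        out.append(codon_table[res])
    return "".join(out)


def translate(dna: str) -> str:
    """Translate an in-frame coding DNA string (no stop codons expected)."""
    if len(dna) % 3:
        raise ValueError("DNA length is not a multiple of 3")
    dna = dna.upper()
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        if codon not in _STANDARD_TRANSLATION:
            raise ValueError(f"untranslatable codon {codon!r}")
        out.append(_STANDARD_TRANSLATION[codon])
    return "".join(out)


def extension_length(tag_a: str, tag_b: str) -> int:
    """Number of residues by which ``tag_b`` extends ``tag_a`` (a prefix)."""
    if not tag_b.startswith(tag_a):
        raise ValueError(f"{tag_a!r} is not a prefix of {tag_b!r}")
    return len(tag_b) - len(tag_a)
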