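"""Reference tag-insertion designs for the six E. coli study proteins.

``ADK_ECOLI_SEQUENCE`` is the full adenylate kinase sequence (UniProtKB
P69441, 214 residues).  For the remaining proteins no full sequence is
bundled; ``scaffold_targets()`` builds SYNTHETIC scaffold records that carry
the documented residues at their true positions (the regions each design
touches) on an alanine backbone of the protein's nominal length.  Context
strings produced on a scaffold are exact wherever the real residues are
present, which covers every design in ``DESIGNS``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import ProteinRecord
from .tag_design import TEV_EXT, TEV_FLANKED, TEV_MIN

__all__ = ["ADK_ECOLI_SEQUENCE", "ReferenceDesign", "DESIGNS",
           "scaffold_targets", "design_targets"]

ADK_ECOLI_SEQUENCE = (
    "MRIILLGAPGAGKGTQAQFIMEKYGIPQISTGDMLRAAVKSGSELGKQAKDIMDAGKLVT"
    "DELVIALVKERIAQEDCRNGFLLDGFPRTIPQADAMKEAGINVDYVLEFDVPDELIVDRI"
    "VGRRVHAPSGRVYHVKFNPPKVEGKDDVTGEELTTRKDDQEETVRKRLVEYHQMTAPLIG"
    "YYSKEAEAGNTKYAKVDGTKPVAEVRADLEKILG"
)

# Residue fragments (1-based start -> residues) documented for the other
# study proteins, and each protein's nominal length.  Everything outside the
# fragments in a scaffold is alanine filler: synthetic, NOT the real protein.
_SCAFFOLD_FRAGMENTS: dict[str, tuple[int, dict[int, str]]] = {
    "TpiA": (255, {53: "EAEGSH", 67: "DLNLSGA", 128: "GETEAENEAGKTE",
                   151: "LKTQGA"}),
    "GpsA": (339, {47: "DRCNAAFLPDVPFPDTL", 97: "PLMRPD", 130: "DQIPLA",
                   267: "LGQGMD"}),
    "AtpA": (513, {121: "LDHDGE"}),
    "AtpD": (460, {99: "KGEIGE"}),
}


@dataclass(frozen=True)
class ReferenceDesign:
    """One published tag-insertion recipe and its expected junction strings."""

    name: str
    protein: str
    after_pos: int
    tag: str
    delete_len: int = 0
    duplicate_span: tuple[int, int] | None = None
    expected_context: str = ""
    expected_original: str = ""


DESIGNS: tuple[ReferenceDesign, ...] = (
    # --- Adk, plasmid insertions ---
    ReferenceDesign("AdkD76.1", "Adk", 76, TEV_MIN, delete_len=5,
                 expected_context="QED**ENLYFQG**LLD",
                 expected_original="QED**CRNGF**LLD"),
    ReferenceDesign("AdkA93", "Adk", 93, TEV_MIN, delete_len=2,
                 expected_context="PQA**ENLYFQG**MKE",
                 expected_original="PQA**DA**MKE"),
    ReferenceDesign("AdkK97", "Adk", 97, TEV_MIN,
                 expected_context="AMK**ENLYFQG**EAG",
                 expected_original="AMKEAG"),
    ReferenceDesign("AdkA99.1", "Adk", 99, TEV_MIN, duplicate_span=(96, 99),
                 expected_context="KEA**ENLYFQGMKEA**GIN",
                 expected_original="KEAGIN"),
    ReferenceDesign("AdkA99.2", "Adk", 99, TEV_MIN, duplicate_span=(94, 99),
                 expected_context="KEA**ENLYFQGDAMKEA**GIN",
                 expected_original="KEAGIN"),
    ReferenceDesign("AdkP140", "Adk", 140, TEV_MIN, delete_len=8,
                 expected_context="NPP**ENLYFQG**TGE",
                 expected_original="NPP**KVEGKDDV**TGE"),
    ReferenceDesign("AdkA186", "Adk", 186, TEV_MIN, delete_len=3,
                 expected_context="KEA**ENLYFQG**NTK",
                 expected_original="KEA**EAG**NTK"),
    # --- Adk, chromosomal / extended-tag variants ---
    ReferenceDesign("AdkD76.2", "Adk", 76, TEV_MIN,
                 expected_context="QED**ENLYFQG**CRN",
                 expected_original="QEDCRN"),
    ReferenceDesign("AdkD76.3", "Adk", 76, TEV_EXT,
                 expected_context="QED**ENLYFQGESLFK**CRN",
                 expected_original="QEDCRN"),
    ReferenceDesign("AdkD76.4", "Adk", 76, "ENLYFQGESLFKGG",
                 expected_context="QED**ENLYFQGESLFKGG**CRN",
                 expected_original="QEDCRN"),
    # --- TpiA ---
    ReferenceDesign("TpiAE55.GSH1", "TpiA", 55, "GGSGENLYFQGSGGS",
                 expected_context="EAE**GGSGENLYFQGSGGS**GSH",
                 expected_original="EAEGSH"),
    ReferenceDesign("TpiAE55.GSH2", "TpiA", 55, "GCLGESENLYFQGDERKNK",
                 expected_context="EAE**GCLGESENLYFQGDERKNK**GSH",
                 expected_original="EAEGSH"),
    ReferenceDesign("TpiAE55.GSH3", "TpiA", 55, "GCLPTTENLYFQSGTVKNK",
                 expected_context="EAE**GCLPTTENLYFQSGTVKNK**GSH",
                 expected_original="EAEGSH"),
    ReferenceDesign("TpiAN69", "TpiA", 69, TEV_MIN,
                 expected_context="DLN**ENLYFQG**LSG",
                 expected_original="DLNLSG"),
    ReferenceDesign("TpiAL70", "TpiA", 70, TEV_FLANKED,
                 expected_context="LNL**PPKNENLYFQGESLFKGP**SGA",
                 expected_original="LNLSGA"),
    ReferenceDesign("TpiAT130.KTE1", "TpiA", 130, "ENLYFQGGSG", delete_len=7,
                 expected_context="GET**ENLYFQGGSG**KTE",
                 expected_original="GET**EAENEAG**KTE"),
    ReferenceDesign("TpiAT130.KTE2", "TpiA", 130, "GGSENLYFQGGSG", delete_len=7,
                 expected_context="GET**GGSENLYFQGGSG**KTE",
                 expected_original="GET**EAENEAG**KTE"),
    ReferenceDesign("TpiAT153", "TpiA", 153, "DYDIPTTENLYFQSGTVDAGAD",
                 expected_context="LKT**DYDIPTTENLYFQSGTVDAGAD**QGA",
                 expected_original="LKTQGA"),
    # --- GpsA ---
    ReferenceDesign("GpsAC49", "GpsA", 49, TEV_MIN, delete_len=9,
                 expected_context="DRC**ENLYFQG**FPD",
                 expected_original="DRC**NAAFLPDVP**FPD"),
    ReferenceDesign("GpsAP60", "GpsA", 60, TEV_MIN, duplicate_span=(57, 60),
                 expected_context="PFP**ENLYFQGVPFP**DTL",
                 expected_original="PFPDTL"),
    ReferenceDesign("GpsAM99", "GpsA", 99, "PTTENLYFQGCLG",
                 expected_context="PLM**PTTENLYFQGCLG**RPD",
                 expected_original="PLMRPD"),
    ReferenceDesign("GpsAI132", "GpsA", 132, "PTTENLYFQGCLG",
                 expected_context="DQI**PTTENLYFQGCLG**PLA",
                 expected_original="DQIPLA"),
    ReferenceDesign("GpsAQ269", "GpsA", 269, "PTTENLYFQGGTV",
                 expected_context="LGQ**PTTENLYFQGGTV**GMD",
                 expected_original="LGQGMD"),
    # --- ATP synthase subunits ---
    ReferenceDesign("AtpAH123", "AtpA", 123, TEV_MIN,
                 expected_context="LDH**ENLYFQG**DGE",
                 expected_original="LDHDGE"),
    ReferenceDesign("AtpDE101", "AtpD", 101, TEV_MIN,
                 expected_context="KGE**ENLYFQG**IGE",
                 expected_original="KGEIGE"),
)


def scaffold_targets() -> dict[str, ProteinRecord]:
    """Synthetic scaffold records for TpiA, GpsA, AtpA, AtpD (see module
    docstring): real residues only at the documented fragments."""
    out: dict[str, ProteinRecord] = {}
    for name, (length, fragments) in _SCAFFOLD_FRAGMENTS.items():
        seq = ["A"] * length
        for start, frag in fragments.items():
            seq[start - 1 : start - 1 + len(frag)] = list(frag)
        out[name] = ProteinRecord(name, "".join(seq))
    return out


def design_targets() -> dict[str, ProteinRecord]:
    """All reference design targets: real Adk plus the synthetic scaffolds."""
    targets = {"Adk": ProteinRecord("Adk", ADK_ECOLI_SEQUENCE)}
    targets.update(scaffold_targets())
    return targets
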