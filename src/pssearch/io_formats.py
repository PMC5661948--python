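"""Readers and writers for the formats the permissive-stretch workflow touches.

All coordinates are normalized on read to the internal convention: 1-based
inclusive residue positions. BED output is the single 0-based, half-open
surface.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

__all__ = [
    "ProteinRecord",
    "AlignedFamily",
    "HspRecord",
    "ResidueProfile",
    "FormatError",
    "MAX_ASA_SANDER_ROST",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_hsps",
    "read_profile",
    "rsa_from_asa",
    "read_stretches",
    "write_stretches",
    "read_known_sites",
]

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUES = AA20 | {"X"}

#: Maximum accessible surface areas (Å²) per residue, Sander & Rost (1994).
#: Used to normalize DSSP-style absolute surface areas into RSA fractions.
MAX_ASA_SANDER_ROST: Mapping[str, float] = {
    "A": 106.0, "R": 248.0, "N": 157.0, "D": 163.0, "C": 135.0,
    "Q": 198.0, "E": 194.0, "G": 84.0, "H": 184.0, "I": 169.0,
    "L": 164.0, "K": 205.0, "M": 188.0, "F": 197.0, "P": 136.0,
    "S": 130.0, "T": 142.0, "W": 227.0, "Y": 222.0, "V": 142.0,
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence: canonical residues plus X, no gap characters."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"record {self.id!r} contains invalid residue(s): {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedFamily:
    """A multiple sequence alignment keyed by sequence id, query included.

    Rows hold residues and ``-`` gap characters; every row has the same
    column count.  De-gapping any row yields a valid :class:`ProteinRecord`.
    """

    query_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if self.query_id not in self.rows:
            raise FormatError(f"query {self.query_id!r} absent from alignment")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment rows: lengths {sorted(lengths)}")
        for rid, row in self.rows.items():
            ProteinRecord(rid, row.replace("-", ""))

    @property
    def column_count(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def query_row(self) -> str:
        return self.rows[self.query_id]

    @property
    def query_length(self) -> int:
        return len(self.query_row) - self.query_row.count("-")


@dataclass(frozen=True)
class HspRecord:
    """One BLAST-style high-scoring pair (local pairwise alignment segment).

    ``qstart``/``qend`` are 1-based inclusive query residue coordinates;
    ``identity`` is a fraction in [0, 1].
    """

    query_id: str
    subject_id: str
    qstart: int
    qend: int
    qseq: str
    sseq: str
    evalue: float
    identity: float

    def __post_init__(self) -> None:
        if len(self.qseq) != len(self.sseq):
            raise FormatError(
                f"HSP {self.query_id}/{self.subject_id}: qseq and sseq lengths differ"
            )
        if not self.qseq or self.qseq[0] == "-" or self.qseq[-1] == "-":
            raise FormatError(
                f"HSP {self.query_id}/{self.subject_id}: qseq begins or ends with a gap"
            )
        if not self.sseq or self.sseq[0] == "-" or self.sseq[-1] == "-":
            raise FormatError(
                f"HSP {self.query_id}/{self.subject_id}: sseq begins or ends with a gap"
            )
        n_res = len(self.qseq) - self.qseq.count("-")
        if n_res != self.qend - self.qstart + 1:
            raise FormatError(
                f"HSP {self.query_id}/{self.subject_id}: de-gapped qseq length {n_res} "
                f"inconsistent with qstart={self.qstart}, qend={self.qend}"
            )
        if self.evalue < 0:
            raise FormatError("negative e-value")
        if not 0.0 <= self.identity <= 1.0:
            raise FormatError(f"identity {self.identity} outside [0,1]")

    @property
    def aligned_columns(self) -> int:
        return len(self.qseq)


@dataclass
class ResidueProfile:
    """Per-residue RSA and secondary-structure annotation for one protein.

    ``rsa`` is a float array in [0, 1] with NaN for missing residues.
    ``ss_probs`` is an (L, 3) array of (helix, strand, coil) probabilities
    (rows of NaN where unknown); hard labels are represented as degenerate
    one-hot rows.  ``source`` is ``"predicted"`` or ``"structure"``.
    """

    protein_id: str
    rsa: np.ndarray
    ss_probs: np.ndarray | None = None
    source: str = "predicted"

    def __post_init__(self) -> None:
        self.rsa = np.asarray(self.rsa, dtype=float)
        finite = self.rsa[np.isfinite(self.rsa)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise FormatError(f"profile {self.protein_id!r}: RSA outside [0,1]")
        if self.ss_probs is not None:
            self.ss_probs = np.asarray(self.ss_probs, dtype=float)
            if self.ss_probs.shape != (len(self.rsa), 3):
                raise FormatError(
                    f"profile {self.protein_id!r}: ss_probs shape "
                    f"{self.ss_probs.shape} does not match length {len(self.rsa)}"
                )
            rows = self.ss_probs[np.all(np.isfinite(self.ss_probs), axis=1)]
            if rows.size:
                if rows.min() < 0:
                    raise FormatError("negative secondary-structure probability")
                if np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-6):
                    raise FormatError(
                        f"profile {self.protein_id!r}: ss probabilities do not sum to 1"
                    )
        if self.source not in ("predicted", "structure"):
            raise FormatError(f"unknown profile source {self.source!r}")

    @property
    def length(self) -> int:
        return int(len(self.rsa))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA; order preserved, sequences upper-cased, ids unique."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, format: str = "aligned-fasta",
                   query_id: str | None = None) -> AlignedFamily:
    """Read an MSA (aligned FASTA or Clustal) into an :class:`AlignedFamily`.

    ``query_id`` defaults to the first row. Rows must be equal length; the
    query must be present.
    """
    fmt = {"aligned-fasta": "fasta", "clustal": "clustal"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    rows = {rec.id: str(rec.seq).upper() for rec in aln}
    if len(rows) != len(aln):
        raise FormatError(f"{path}: duplicate row ids in alignment")
    if query_id is None:
        query_id = aln[0].id
    if query_id not in rows:
        raise FormatError(f"{path}: query {query_id!r} not among alignment rows")
    return AlignedFamily(query_id=query_id, rows=rows)


# ---------------------------------------------------------------------------
# HSP tables
# ---------------------------------------------------------------------------

_HSP_COLUMNS = ["qseqid", "sseqid", "pident", "evalue", "qstart", "qend", "qseq", "sseq"]


def read_hsps(path: str | Path) -> list[HspRecord]:
    """Read BLAST-style tabular HSPs.

    Expected tab-separated columns: qseqid, sseqid, pident, evalue, qstart,
    qend, qseq, sseq (a header row naming them is optional).  Percent
    identity is converted to a fraction.
    """
    records: list[HspRecord] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() == "qseqid":
                continue
            if len(row) != len(_HSP_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_HSP_COLUMNS)} columns, got {len(row)}"
                )
            try:
                rec = HspRecord(
                    query_id=row[0].strip(),
                    subject_id=row[1].strip(),
                    identity=float(row[2]) / 100.0,
                    evalue=float(row[3]),
                    qstart=int(row[4]),
                    qend=int(row[5]),
                    qseq=row[6].strip().upper(),
                    sseq=row[7].strip().upper(),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_hsps(records: Iterable[HspRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HSP_COLUMNS)
        for r in records:
            writer.writerow([
                r.query_id, r.subject_id, f"{r.identity * 100.0:.2f}",
                f"{r.evalue:.3g}", r.qstart, r.qend, r.qseq, r.sseq,
            ])


# ---------------------------------------------------------------------------
# Residue profiles
# ---------------------------------------------------------------------------

def _parse_optional_float(token: str) -> float:
    token = token.strip()
    if token in ("", "NA", "NaN", "nan", "."):
        return float("nan")
    return float(token)


def read_profile(path: str | Path, dialect: str = "tsv",
                 protein_id: str | None = None) -> ResidueProfile:
    """Read a per-residue RSA / secondary-structure profile.

    ``dialect="tsv"``: tab-separated with header, columns ``position``,
    optional ``aa``, ``rsa``, and optionally ``p_helix``, ``p_strand``,
    ``p_coil``.  ``dialect="netsurfp"``: the classic whitespace-column
    NetSurfP text layout (class, aa, name, position, RSA, ASA, z-fit,
    p_helix, p_strand, p_coil; ``#`` comment lines ignored).

    Positions must be contiguous from 1; RSA values outside [0, 1] are
    rejected; missing values are allowed (NaN).
    """
    if dialect == "tsv":
        return _read_profile_tsv(path, protein_id)
    if dialect == "netsurfp":
        return _read_profile_netsurfp(path, protein_id)
    raise ValueError(f"unknown profile dialect {dialect!r}")


def _check_positions(positions: list[int], path: str | Path) -> None:
    expected = list(range(1, len(positions) + 1))
    if positions != expected:
        raise FormatError(f"{path}: residue numbering is not contiguous from 1")


def _read_profile_tsv(path: str | Path, protein_id: str | None) -> ResidueProfile:
    positions: list[int] = []
    rsa: list[float] = []
    probs: list[tuple[float, float, float]] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "rsa" not in reader.fieldnames:
            raise FormatError(f"{path}: missing header with an 'rsa' column")
        has_ss = all(c in reader.fieldnames for c in ("p_helix", "p_strand", "p_coil"))
        for lineno, row in enumerate(reader, start=2):
            positions.append(int(row["position"]))
            rsa.append(_parse_optional_float(row["rsa"]))
            if has_ss:
                probs.append(tuple(_parse_optional_float(row[c])
                                   for c in ("p_helix", "p_strand", "p_coil")))
    _check_positions(positions, path)
    ss = np.array(probs) if probs else None
    pid = protein_id or Path(path).stem
    return ResidueProfile(protein_id=pid, rsa=np.array(rsa), ss_probs=ss)


def _read_profile_netsurfp(path: str | Path, protein_id: str | None) -> ResidueProfile:
    positions: list[int] = []
    rsa: list[float] = []
    probs: list[tuple[float, float, float]] = []
    pid = protein_id
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 10:
                raise FormatError(f"{path}:{lineno}: expected 10 whitespace columns")
            if pid is None:
                pid = parts[2]
            positions.append(int(parts[3]))
            rsa.append(_parse_optional_float(parts[4]))
            probs.append((float(parts[7]), float(parts[8]), float(parts[9])))
    if not positions:
        raise FormatError(f"{path}: no residue rows found")
    _check_positions(positions, path)
    return ResidueProfile(protein_id=pid or Path(path).stem,
                          rsa=np.array(rsa), ss_probs=np.array(probs))


def read_asa_tsv(path: str | Path, max_asa: Mapping[str, float] = MAX_ASA_SANDER_ROST,
                 protein_id: str | None = None) -> ResidueProfile:
    """Read a DSSP-derived per-residue ASA table (TSV: position, aa, asa,
    optional ss label column H/E/C) and convert to a structure-source profile."""
    positions: list[int] = []
    rsa: list[float] = []
    probs: list[tuple[float, float, float]] = []
    onehot = {"H": (1.0, 0.0, 0.0), "E": (0.0, 1.0, 0.0), "C": (0.0, 0.0, 1.0)}
    nan3 = (float("nan"),) * 3
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "asa" not in reader.fieldnames:
            raise FormatError(f"{path}: missing header with an 'asa' column")
        for row in reader:
            positions.append(int(row["position"]))
            asa_tok = row["asa"].strip()
            if asa_tok in ("", "NA", "NaN", "."):
                rsa.append(float("nan"))
            else:
                rsa.append(rsa_from_asa(float(asa_tok), row["aa"].strip().upper(), max_asa))
            label = (row.get("ss") or "").strip().upper()
            probs.append(onehot.get(label, nan3))
    _check_positions(positions, path)
    return ResidueProfile(protein_id=protein_id or Path(path).stem,
                          rsa=np.array(rsa), ss_probs=np.array(probs),
                          source="structure")


def rsa_from_asa(asa: float, residue: str,
                 max_asa: Mapping[str, float] = MAX_ASA_SANDER_ROST) -> float:
    """Convert an absolute surface area (Å²) to an RSA fraction.

    Normalizes by the residue's maximum exposure and clips to 1.0 (observed
    ASAs occasionally exceed the reference maxima).
    """
    if asa < 0:
        raise ValueError(f"negative ASA {asa}")
    residue = residue.upper()
    if residue not in max_asa:
        raise ValueError(f"no maximum-ASA constant for residue {residue!r}")
    return min(1.0, asa / max_asa[residue])


# ---------------------------------------------------------------------------
# Stretch tables (TSV internal 1-based inclusive; BED 0-based half-open)
# ---------------------------------------------------------------------------

def write_stretches(stretches: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write permissive stretches as TSV (1-based inclusive) or BED.

    BED conversion: internal [s, e] → chromStart s−1, chromEnd e.
    """
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["protein_id", "label", "start", "end"])
            for st in stretches:
                writer.writerow([st.protein_id, st.label, st.s, st.e])
    elif format == "bed":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for st in stretches:
                writer.writerow([st.protein_id, st.s - 1, st.e, st.label])
    else:
        raise ValueError(f"unknown stretch output format {format!r}")


def read_stretches(path: str | Path) -> list:
    """Read a stretches TSV written by :func:`write_stretches`."""
    from .pss_core import PermissiveStretch  # deferred: avoid import cycle

    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(PermissiveStretch(
                protein_id=row["protein_id"], s=int(row["start"]),
                e=int(row["end"]), members=(), label=row["label"],
            ))
    return out


def read_known_sites(path: str | Path) -> list:
    """Read a known-sites TSV: protein_id, position, class."""
    from .pss_core import KnownSite

    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(KnownSite(protein_id=row["protein_id"],
                                 position=int(row["position"]),
                                 klass=row["class"]))
    return out
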