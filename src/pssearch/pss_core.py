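"""Detect indel evidence in alignments and merge it into permissive stretches.

A permissive stretch (PS) is a contiguous region of a query protein that is
likely to tolerate insertion of extra residues.  The evidence unit is an
indel seen against a homolog: a gap in the query row (the homolog carries
extra residues) or a gap in the homolog row (the homolog lacks residues the
query has).  Each indel is recorded as the closed interval of query residues
[s, e] spanning the gap plus its two flanking residues; stretches are the
connected components of the union of these intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import AlignedFamily, HspRecord

__all__ = [
    "GapInterval",
    "PermissiveStretch",
    "KnownSite",
    "SiteMapping",
    "INSERTION",
    "DELETION",
    "gap_set",
    "scan_alignment",
    "filter_hits",
    "merge_connected",
    "detect_stretches",
    "map_known_sites",
]

INSERTION = "insertion_in_homolog"
DELETION = "deletion_in_homolog"


@dataclass(frozen=True)
class GapInterval:
    """One indel's evidence interval on the query, flanks included.

    An insertion in a homolog falls between two adjacent query residues, so
    its interval is exactly [s, s+1]; a deletion of query residues i..j spans
    [i−1, j+1] (gap length + 2).
    """

    protein_id: str
    s: int
    e: int
    kind: str
    support: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.s < self.e:
            raise ValueError(f"invalid interval [{self.s}, {self.e}]")
        if self.kind not in (INSERTION, DELETION):
            raise ValueError(f"unknown gap kind {self.kind!r}")
        if self.kind == INSERTION and self.e != self.s + 1:
            raise ValueError("insertion intervals must span exactly two residues")
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass(frozen=True)
class PermissiveStretch:
    """A merged run of indel evidence: the method's central output.

    [s, e] is the min/max over member intervals; stretches of one protein
    are pairwise disjoint and labelled with Roman numerals from the
    N-terminus.
    """

    protein_id: str
    s: int
    e: int
    members: tuple[GapInterval, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.s < self.e:
            raise ValueError(f"invalid stretch [{self.s}, {self.e}]")

    @property
    def span(self) -> int:
        """Span length e − s (number of insertion sites covered)."""
        return self.e - self.s

    def __contains__(self, position: int) -> bool:
        return self.s <= position <= self.e


PERMISSIVE_CLASSES = ("permissive", "semi_permissive", "non_permissive")


@dataclass(frozen=True)
class KnownSite:
    """An experimentally characterized insertion site ("after residue k")."""

    protein_id: str
    position: int
    klass: str = "permissive"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("site position must be >= 1")
        if self.klass not in PERMISSIVE_CLASSES:
            raise ValueError(f"unknown site class {self.klass!r}")


@dataclass(frozen=True)
class SiteMapping:
    """How a known site relates to the detected stretches.

    ``direct``: inside a stretch; ``scattered``: within the window of one;
    ``unmapped``: farther than the window from every stretch.
    """

    site: KnownSite
    category: str
    nearest_stretch: PermissiveStretch | None
    distance: int | None
    same_ss_element: bool | None = None


def _roman(n: int) -> str:
    numerals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
                (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
                (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


# ---------------------------------------------------------------------------
# Gap extraction
# ---------------------------------------------------------------------------

def _gap_runs(aligned: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as [start, end) column index pairs."""
    runs = []
    i = 0
    n = len(aligned)
    while i < n:
        if aligned[i] == "-":
            j = i
            while j < n and aligned[j] == "-":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def gap_set(hsp: HspRecord) -> list[GapInterval]:
    """Extract the indel intervals g(p, i) of one HSP, in absolute query
    coordinates.

    A gap run in the query row between query residues i and i+1 yields the
    insertion interval [i, i+1]; a gap run in the subject row aligned to
    query residues i..j yields the deletion interval [i−1, j+1].  Intervals
    whose flank would fall outside [qstart, qend] are discarded.
    """
    # query residue index (absolute) at or before each column
    qpos = []  # absolute position of the query residue in this column, or None
    pos = hsp.qstart - 1
    for ch in hsp.qseq:
        if ch == "-":
            qpos.append(None)
        else:
            pos += 1
            qpos.append(pos)

    out: list[GapInterval] = []
    for c0, c1 in _gap_runs(hsp.qseq):
        # c0 > 0 and c1 < len by the no-terminal-gap invariant
        left = qpos[c0 - 1]
        out.append(GapInterval(hsp.query_id, left, left + 1, INSERTION))
    for c0, c1 in _gap_runs(hsp.sseq):
        covered = [qpos[c] for c in range(c0, c1) if qpos[c] is not None]
        if not covered:
            continue
        i, j = covered[0], covered[-1]
        if i - 1 < hsp.qstart or j + 1 > hsp.qend:
            continue
        out.append(GapInterval(hsp.query_id, i - 1, j + 1, DELETION))
    out.sort(key=lambda g: (g.s, g.e))
    return out


def scan_alignment(family: AlignedFamily, min_support: int = 1) -> list[GapInterval]:
    """Extract indel intervals from an MSA, in query (de-gapped) numbering.

    Query-row gap runs with at least ``min_support`` homologs carrying a
    residue yield insertion intervals between the flanking query residues.
    Per-homolog gap runs aligned to query residues i..j, gapped in at least
    ``min_support`` rows over the full run, yield deletion intervals
    [i−1, j+1].  Runs touching an alignment terminus, or whose flank would
    fall outside the query, are discarded (treated as missing data, not
    indels).
    """
    query = family.query_row
    ncols = family.column_count
    length = family.query_length
    homologs = {rid: row for rid, row in family.rows.items() if rid != family.query_id}

    # query residue number at each column (None on query gaps)
    qpos: list[int | None] = []
    pos = 0
    for ch in query:
        if ch == "-":
            qpos.append(None)
        else:
            pos += 1
            qpos.append(pos)

    out: list[GapInterval] = []

    # insertions: gap runs in the query row
    for c0, c1 in _gap_runs(query):
        if c0 == 0 or c1 == ncols:
            continue  # terminal run: no flank on one side
        support = sum(1 for row in homologs.values()
                      if any(row[c] != "-" for c in range(c0, c1)))
        if support < min_support or support == 0:
            continue
        left = qpos[c0 - 1]
        out.append(GapInterval(family.query_id, left, left + 1, INSERTION, support))

    # deletions: gap runs in homolog rows
    seen: dict[tuple[int, int], int] = {}
    for rid, row in homologs.items():
        for c0, c1 in _gap_runs(row):
            if c0 == 0 or c1 == ncols:
                continue  # terminal gap = missing data
            covered = [qpos[c] for c in range(c0, c1) if qpos[c] is not None]
            if not covered:
                continue
            i, j = covered[0], covered[-1]
            if i - 1 < 1 or j + 1 > length:
                continue
            support = sum(1 for other in homologs.values()
                          if all(other[c] == "-" for c in range(c0, c1)))
            key = (i - 1, j + 1)
            seen[key] = max(seen.get(key, 0), support)
    for (s, e), support in seen.items():
        if support >= min_support:
            out.append(GapInterval(family.query_id, s, e, DELETION, support))

    # dedupe identical insertion intervals produced by distinct runs
    uniq: dict[tuple[int, int, str], GapInterval] = {}
    for g in out:
        key = (g.s, g.e, g.kind)
        if key not in uniq or g.support > uniq[key].support:
            uniq[key] = g
    return sorted(uniq.values(), key=lambda g: (g.s, g.e, g.kind))


# ---------------------------------------------------------------------------
# Hit filtering (homolog-search hygiene)
# ---------------------------------------------------------------------------

def filter_hits(hits: Mapping[str, Sequence[HspRecord]], query_len: int,
                evalue_max: float = 0.001, min_coverage: float = 0.8,
                min_identity: float = 0.3) -> dict[str, list[HspRecord]]:
    """Retain homolog hits that are confident, near-full-length, and gapped.

    Per hit (subject): HSPs at or above ``evalue_max`` are dropped; the hit
    is retained iff the union of its remaining HSPs' query ranges covers at
    least ``min_coverage`` of the query, aggregate identity (identical
    positions over aligned columns, summed across HSPs) is at least
    ``min_identity``, and at least one HSP contains an indel.
    """
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    retained: dict[str, list[HspRecord]] = {}
    for subject, hsps in hits.items():
        good = [h for h in hsps if h.evalue < evalue_max]
        if not good:
            continue
        covered: set[int] = set()
        for h in good:
            covered.update(range(h.qstart, h.qend + 1))
        if len(covered) < min_coverage * query_len:
            continue
        cols = sum(h.aligned_columns for h in good)
        ident = sum(h.identity * h.aligned_columns for h in good)
        if cols == 0 or ident / cols < min_identity:
            continue
        if not any(gap_set(h) for h in good):
            continue
        retained[subject] = list(good)
    return retained


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_connected(intervals: Iterable[GapInterval]) -> list[PermissiveStretch]:
    """Merge indel intervals into stretches: connected components of the
    union of their residue sets.

    Two intervals belong to the same stretch iff they share at least one
    residue; adjacent-but-disjoint intervals do not merge.  Output is sorted
    N→C and labelled with Roman numerals.
    """
    intervals = list(intervals)
    if not intervals:
        return []
    pids = {g.protein_id for g in intervals}
    if len(pids) != 1:
        raise ValueError(f"intervals from multiple proteins: {sorted(pids)}")
    pid = pids.pop()

    ordered = sorted(intervals, key=lambda g: (g.s, g.e))
    components: list[list[GapInterval]] = [[ordered[0]]]
    cur_end = ordered[0].e
    for g in ordered[1:]:
        if g.s <= cur_end:  # shares a residue with the growing component
            components[-1].append(g)
            cur_end = max(cur_end, g.e)
        else:
            components.append([g])
            cur_end = g.e
    return [
        PermissiveStretch(
            protein_id=pid,
            s=min(g.s for g in comp),
            e=max(g.e for g in comp),
            members=tuple(comp),
            label=_roman(idx),
        )
        for idx, comp in enumerate(components, start=1)
    ]


def detect_stretches(hsps: Sequence[HspRecord], query_len: int,
                     evalue_max: float = 0.001, min_coverage: float = 0.8,
                     min_identity: float = 0.3) -> list[PermissiveStretch]:
    """Full HSP pipeline: filter hits, extract gap sets, merge into stretches.

    All HSPs must share one query.  Returns [] when no hit survives the
    filters.
    """
    if not hsps:
        return []
    queries = {h.query_id for h in hsps}
    if len(queries) != 1:
        raise ValueError(f"HSPs from multiple queries: {sorted(queries)}")
    by_subject: dict[str, list[HspRecord]] = {}
    for h in hsps:
        by_subject.setdefault(h.subject_id, []).append(h)
    retained = filter_hits(by_subject, query_len, evalue_max=evalue_max,
                           min_coverage=min_coverage, min_identity=min_identity)
    intervals: list[GapInterval] = []
    for subject_hsps in retained.values():
        for h in subject_hsps:
            intervals.extend(gap_set(h))
    return merge_connected(intervals)


# ---------------------------------------------------------------------------
# Known-site mapping
# ---------------------------------------------------------------------------

def _distance_to(position: int, stretch: PermissiveStretch) -> int:
    if position < stretch.s:
        return stretch.s - position
    if position > stretch.e:
        return position - stretch.e
    return 0


def map_known_sites(sites: Sequence[KnownSite],
                    stretches: Sequence[PermissiveStretch],
                    window: int = 5,
                    ss_labels: Sequence[str] | None = None,
                    protein_length: int | None = None) -> list[SiteMapping]:
    """Classify known insertion sites against detected stretches.

    ``direct``: the site falls inside a stretch; ``scattered``: within
    ``window`` residues of the nearest stretch boundary; else ``unmapped``.
    With ``ss_labels`` (per-residue H/E/C strings), ``same_ss_element``
    reports whether the site and the nearest stretch share one maximal run
    of identical labels.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    length = protein_length or (len(ss_labels) if ss_labels else None)
    out: list[SiteMapping] = []
    for site in sites:
        if length is not None and site.position > length:
            raise ValueError(
                f"site position {site.position} outside protein of length {length}"
            )
        relevant = [st for st in stretches if st.protein_id == site.protein_id]
        if not relevant:
            out.append(SiteMapping(site, "unmapped", None, None))
            continue
        nearest = min(relevant, key=lambda st: _distance_to(site.position, st))
        dist = _distance_to(site.position, nearest)
        if dist == 0:
            category = "direct"
        elif dist <= window:
            category = "scattered"
        else:
            category = "unmapped"
        same_ss = None
        if ss_labels is not None:
            same_ss = _same_ss_element(site.position, nearest, ss_labels)
        out.append(SiteMapping(site, category, nearest, dist, same_ss))
    return out


def _same_ss_element(position: int, stretch: PermissiveStretch,
                     ss_labels: Sequence[str]) -> bool:
    """True iff the maximal run of identical SS labels containing the site
    overlaps the stretch."""
    idx = position - 1
    if not 0 <= idx < len(ss_labels):
        raise ValueError(f"position {position} outside SS label track")
    label = ss_labels[idx]
    lo = idx
    while lo > 0 and ss_labels[lo - 1] == label:
        lo -= 1
    hi = idx
    while hi + 1 < len(ss_labels) and ss_labels[hi + 1] == label:
        hi += 1
    # run covers residues lo+1 .. hi+1 (1-based)
    return not (hi + 1 < stretch.s or lo + 1 > stretch.e)
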