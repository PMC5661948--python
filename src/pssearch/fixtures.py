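"""Synthetic input generators with the statistical structure the method
assumes: homolog families with implanted indel regions, residue profiles
where loops are more exposed than the core, and HSP sets derived from the
true alignment.

Families are built *by construction* — the true alignment is assembled
directly from the implanted events, no aligner involved — so detector tests
measure the detector, not aligner behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import AlignedFamily, HspRecord, ProteinRecord, ResidueProfile
from .pss_core import DELETION, INSERTION, GapInterval

__all__ = ["IndelRegion", "FamilySpec", "ProfileSpec",
           "simulate_family", "simulate_profile", "simulate_hsps"]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class IndelRegion:
    """A length-variable region: each homolog receives an insertion or a
    deletion of 1..max_len residues anchored at ``position``."""

    position: int
    max_len: int
    kind: str = "either"  # either | insertion | deletion

    def __post_init__(self) -> None:
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.kind not in ("either", "insertion", "deletion"):
            raise ValueError(f"unknown region kind {self.kind!r}")


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for a simulated homolog family.

    Defaults mirror the study conditions: six homologs (the workflow wants
    more than five) and a substitution rate of 0.35, placing pairwise
    identity in the 30–70% band where gap detection is informative.
    """

    ancestor_length: int = 200
    n_homologs: int = 6
    indel_regions: tuple[IndelRegion, ...] = ()
    substitution_rate: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestor_length < 4:
            raise ValueError("ancestor too short")
        if self.n_homologs < 1:
            raise ValueError("need at least one homolog")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0,1]")
        regions = tuple(
            r if isinstance(r, IndelRegion) else IndelRegion(*r)
            for r in self.indel_regions
        )
        object.__setattr__(self, "indel_regions", regions)
        prev_extent = 0
        for r in sorted(regions, key=lambda r: r.position):
            if r.position < 2 or r.position + r.max_len > self.ancestor_length - 1:
                raise ValueError(
                    f"region at {r.position} (max_len {r.max_len}) too close to a terminus"
                )
            if r.position - 1 <= prev_extent:
                raise ValueError("indel regions overlap or touch")
            prev_extent = r.position + r.max_len
        self._check_query_coverage()

    def _check_query_coverage(self) -> None:
        total = sum(r.max_len for r in self.indel_regions)
        if total >= self.ancestor_length:
            raise ValueError("indel regions exceed the sequence")


@dataclass(frozen=True)
class ProfileSpec:
    """Recipe for a synthetic residue profile: exposed coil loops
    (``rsa_loop_mean``) on a buried non-loop background (``rsa_core_mean``).

    Defaults (0.8 loop / 0.2 core, sd 0.05) give the clear loop-exposure
    contrast the enrichment test is designed to detect.
    """

    length: int = 200
    loop_regions: tuple[tuple[int, int], ...] = ()
    rsa_loop_mean: float = 0.8
    rsa_core_mean: float = 0.2
    rsa_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for m in (self.rsa_loop_mean, self.rsa_core_mean):
            if not 0.0 <= m <= 1.0:
                raise ValueError("RSA means must be in [0,1]")
        if self.rsa_sd < 0:
            raise ValueError("rsa_sd must be non-negative")
        for s, e in self.loop_regions:
            if not 1 <= s <= e <= self.length:
                raise ValueError(f"loop region [{s},{e}] outside sequence")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def simulate_family(spec: FamilySpec,
                    query_id: str = "query") -> tuple[AlignedFamily, list[GapInterval]]:
    """Simulate a homolog family with implanted indels; returns the true
    alignment and the ground-truth evidence intervals (flanks included)."""
    rng = np.random.default_rng(spec.seed)
    L = spec.ancestor_length
    ancestor = _random_sequence(rng, L)

    # per homolog: residue at each ancestor position ('-' when deleted) and
    # inserted runs keyed by the position they follow
    names = [f"hom{i + 1}" for i in range(spec.n_homologs)]
    residues: dict[str, list[str]] = {}
    inserts: dict[str, dict[int, str]] = {name: {} for name in names}
    truth: list[GapInterval] = []

    for name in names:
        row = list(ancestor)
        # substitutions outside the indel regions
        protected = set()
        for r in spec.indel_regions:
            protected.update(range(r.position, r.position + r.max_len + 1))
        for k in range(L):
            if (k + 1) not in protected and rng.random() < spec.substitution_rate:
                choices = [a for a in _AA if a != row[k]]
                row[k] = choices[rng.integers(len(choices))]
        for r in spec.indel_regions:
            kind = r.kind
            if kind == "either":
                kind = "insertion" if rng.random() < 0.5 else "deletion"
            ell = int(rng.integers(1, r.max_len + 1))
            if kind == "deletion":
                for k in range(r.position, r.position + ell):
                    row[k - 1] = "-"
                truth.append(GapInterval(query_id, r.position - 1,
                                         r.position + ell, DELETION))
            else:
                inserts[name][r.position] = _random_sequence(rng, ell)
                truth.append(GapInterval(query_id, r.position,
                                         r.position + 1, INSERTION))
        residues[name] = row

    # assemble the true MSA column by column
    cols: dict[str, list[str]] = {query_id: []}
    for name in names:
        cols[name] = []
    for k in range(1, L + 1):
        cols[query_id].append(ancestor[k - 1])
        for name in names:
            cols[name].append(residues[name][k - 1])
        width = max((len(inserts[n].get(k, "")) for n in names), default=0)
        if width:
            cols[query_id].append("-" * width)
            for name in names:
                ins = inserts[name].get(k, "")
                cols[name].append(ins + "-" * (width - len(ins)))

    rows = {rid: "".join(chars) for rid, chars in cols.items()}
    family = AlignedFamily(query_id=query_id, rows=rows)
    truth.sort(key=lambda g: (g.s, g.e))
    return family, truth


def simulate_profile(spec: ProfileSpec, protein_id: str = "query") -> ResidueProfile:
    """Synthetic residue profile: clipped-normal RSA around the loop or core
    mean, coil labels inside loops and helix elsewhere."""
    rng = np.random.default_rng(spec.seed)
    in_loop = np.zeros(spec.length, dtype=bool)
    for s, e in spec.loop_regions:
        in_loop[s - 1 : e] = True
    means = np.where(in_loop, spec.rsa_loop_mean, spec.rsa_core_mean)
    rsa = means + (rng.normal(0.0, spec.rsa_sd, spec.length) if spec.rsa_sd else 0.0)
    rsa = np.clip(rsa, 0.0, 1.0)
    ss = np.zeros((spec.length, 3))
    ss[in_loop, 2] = 1.0   # coil
    ss[~in_loop, 0] = 1.0  # helix
    return ResidueProfile(protein_id=protein_id, rsa=rsa, ss_probs=ss)


def simulate_hsps(family: AlignedFamily, fragment_coverage: float = 1.0,
                  evalue_range: tuple[float, float] = (1e-30, 1e-6),
                  seed: int = 0) -> list[HspRecord]:
    """Derive one pairwise HSP per homolog from the true alignment.

    Each homolog is trimmed to a random local window covering
    ``fragment_coverage`` of the query; gap content is inherited from the
    family, identities are computed from the pair, and e-values are drawn
    log-uniformly from ``evalue_range``.
    """
    if not 0.0 < fragment_coverage <= 1.0:
        raise ValueError("fragment_coverage must be in (0,1]")
    rng = np.random.default_rng(seed)
    query = family.query_row
    Lq = family.query_length
    # column index of each query residue (1-based residue -> column)
    res_col = [c for c, ch in enumerate(query) if ch != "-"]

    n_res = max(2, round(fragment_coverage * Lq))
    lo_e, hi_e = np.log10(evalue_range[0]), np.log10(evalue_range[1])

    out: list[HspRecord] = []
    for rid, row in family.rows.items():
        if rid == family.query_id:
            continue
        start_res = int(rng.integers(1, Lq - n_res + 2))
        end_res = start_res + n_res - 1
        c0, c1 = res_col[start_res - 1], res_col[end_res - 1]
        qseq, sseq = [], []
        for c in range(c0, c1 + 1):
            if query[c] == "-" and row[c] == "-":
                continue
            qseq.append(query[c])
            sseq.append(row[c])
        # trim so neither aligned string starts/ends with a gap
        qstart, qend = start_res, end_res
        while qseq and (qseq[0] == "-" or sseq[0] == "-"):
            if qseq[0] != "-":
                qstart += 1
            qseq.pop(0)
            sseq.pop(0)
        while qseq and (qseq[-1] == "-" or sseq[-1] == "-"):
            if qseq[-1] != "-":
                qend -= 1
            qseq.pop()
            sseq.pop()
        if len(qseq) < 2:
            continue
        ident = sum(a == b for a, b in zip(qseq, sseq) if a != "-" and b != "-")
        evalue = float(10 ** rng.uniform(lo_e, hi_e))
        out.append(HspRecord(
            query_id=family.query_id, subject_id=rid,
            qstart=qstart, qend=qend,
            qseq="".join(qseq), sseq="".join(sseq),
            evalue=evalue, identity=ident / len(qseq),
        ))
    return out
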