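"""Score stretches by surface accessibility and secondary-structure context.

An insertion *site* is the junction between two adjacent residues (or a
terminus).  Its accessibility is the geometric mean of the flanking residue
RSAs; a stretch's accessibility is the maximum site RSA over the stretch.
Predicted and crystal-derived profiles are compared by distance correlation,
with secondary-structure labels embedded as three mutually equidistant
points in the plane so that label disagreement is metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import ResidueProfile
from .pss_core import PermissiveStretch

__all__ = [
    "SS_LABELS",
    "SS_EMBEDDING",
    "StretchScore",
    "UndefinedRsaError",
    "site_rsa",
    "site_rsa_track",
    "stretch_rsa",
    "ss_label",
    "ss_labels_of",
    "loop_length_at",
    "distance_correlation",
    "compare_profiles",
    "score_stretch",
]

SS_LABELS = ("helix", "strand", "coil")

#: Planar embedding of (helix, strand, coil): vertices of a unit equilateral
#: triangle, so all pairwise label distances equal 1.
SS_EMBEDDING: dict[str, tuple[float, float]] = {
    "helix": (0.0, 0.0),
    "strand": (1.0, 0.0),
    "coil": (0.5, math.sqrt(3.0) / 2.0),
}

# tie-break preference when probabilities are equal (least-committal first)
_TIE_ORDER = {"coil": 0, "helix": 1, "strand": 2}


class UndefinedRsaError(ValueError):
    """A required residue RSA is missing from the profile."""

    def __init__(self, protein_id: str, residues: list[int]):
        self.residues = residues
        super().__init__(
            f"profile {protein_id!r}: RSA missing at residue(s) {residues}"
        )


@dataclass(frozen=True)
class StretchScore:
    """Accessibility and structural context of one stretch."""

    stretch: PermissiveStretch
    rsa: float
    best_site: int
    ss_context: str | None = None
    loop_length: int | None = None


# ---------------------------------------------------------------------------
# Site and stretch RSA
# ---------------------------------------------------------------------------

def site_rsa(profile: ResidueProfile, i: int) -> float:
    """RSA of insertion site ``i`` (0 ≤ i ≤ L).

    Interior site i lies between residues i and i+1 and scores
    √(RSA(i)·RSA(i+1)); the terminal sites 0 and L take the RSA of the first
    and last residue, respectively.
    """
    L = profile.length
    if not 0 <= i <= L:
        raise ValueError(f"site index {i} outside 0..{L}")
    rsa = profile.rsa
    if i == 0:
        needed = [1]
    elif i == L:
        needed = [L]
    else:
        needed = [i, i + 1]
    vals = [rsa[k - 1] for k in needed]
    missing = [k for k, v in zip(needed, vals) if not np.isfinite(v)]
    if missing:
        raise UndefinedRsaError(profile.protein_id, missing)
    if len(vals) == 1:
        return float(vals[0])
    return float(math.sqrt(vals[0] * vals[1]))


def site_rsa_track(profile: ResidueProfile) -> np.ndarray:
    """Vector of interior-site RSAs: entry k (0-based) is site k+1, i.e.
    √(RSA(k+1)·RSA(k+2)).  NaN where a flanking residue is missing.

    Length L−1; used to score many stretch placements quickly.
    """
    r = profile.rsa
    return np.sqrt(r[:-1] * r[1:])


def stretch_rsa(profile: ResidueProfile, stretch: PermissiveStretch) -> float:
    """Stretch accessibility: max site RSA over sites s..e−1."""
    score, _ = _best_site(profile, stretch)
    return score


def _best_site(profile: ResidueProfile, stretch: PermissiveStretch) -> tuple[float, int]:
    if stretch.e > profile.length:
        raise ValueError(
            f"stretch [{stretch.s},{stretch.e}] outside profile of length {profile.length}"
        )
    track = site_rsa_track(profile)
    window = track[stretch.s - 1 : stretch.e - 1]
    if np.isnan(window).any():
        missing = sorted({
            k for i in range(stretch.s, stretch.e)
            for k in (i, i + 1) if not np.isfinite(profile.rsa[k - 1])
        })
        raise UndefinedRsaError(profile.protein_id, missing)
    k = int(np.argmax(window))
    return float(window[k]), stretch.s + k


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def ss_label(probs) -> str:
    """Hard label for one (helix, strand, coil) probability triple.

    Ties are broken coil > helix > strand.
    """
    p = np.asarray(probs, dtype=float)
    if p.shape != (3,):
        raise ValueError("expected a (helix, strand, coil) triple")
    best = max(SS_LABELS, key=lambda lab: (p[SS_LABELS.index(lab)], -_TIE_ORDER[lab]))
    return best


def ss_labels_of(profile: ResidueProfile) -> list[str | None]:
    """Per-residue hard labels for a profile (None where unknown)."""
    if profile.ss_probs is None:
        return [None] * profile.length
    out: list[str | None] = []
    for row in profile.ss_probs:
        out.append(ss_label(row) if np.all(np.isfinite(row)) else None)
    return out


def loop_length_at(labels, position: int) -> int | None:
    """Length of the maximal coil run containing ``position`` (1-based);
    None when the residue is not coil."""
    idx = position - 1
    if not 0 <= idx < len(labels):
        raise ValueError(f"position {position} outside label track")
    if labels[idx] != "coil":
        return None
    lo = idx
    while lo > 0 and labels[lo - 1] == "coil":
        lo -= 1
    hi = idx
    while hi + 1 < len(labels) and labels[hi + 1] == "coil":
        hi += 1
    return hi - lo + 1


def score_stretch(profile: ResidueProfile, stretch: PermissiveStretch) -> StretchScore:
    """Full per-stretch report: max site RSA, its site, SS context, and the
    loop length at the best site (when coil)."""
    score, best = _best_site(profile, stretch)
    labels = ss_labels_of(profile)
    context = None
    loop_len = None
    if profile.ss_probs is not None:
        window = labels[stretch.s - 1 : stretch.e]
        context = "".join({"helix": "H", "strand": "E", "coil": "C"}.get(l, "?")
                          for l in window)
        if labels[best - 1] == "coil":
            loop_len = loop_length_at(labels, best)
    return StretchScore(stretch=stretch, rsa=score, best_site=best,
                        ss_context=context, loop_length=loop_len)


# ---------------------------------------------------------------------------
# Distance correlation
# ---------------------------------------------------------------------------

def _as_points(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError("expected a vector or a 2-D array of points")
    return a


def distance_correlation(x, y) -> float:
    """Sample distance correlation between paired samples in Euclidean space.

    Computed from double-centered pairwise distance matrices; returns a value
    in [0, 1], with 0 when either sample has zero distance variance (the
    declared degenerate rule for constant inputs).
    """
    X = _as_points(x)
    Y = _as_points(y)
    if len(X) != len(Y):
        raise ValueError(f"length mismatch: {len(X)} vs {len(Y)}")
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 paired observations")

    def centered(Z: np.ndarray) -> np.ndarray:
        d = np.sqrt(((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2))
        return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()

    A = centered(X)
    B = centered(Y)
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    denom = math.sqrt(dvar_x * dvar_y) if dvar_x > 0 and dvar_y > 0 else 0.0
    if denom <= 0:
        return 0.0
    val = dcov2 / denom
    # numerical guard: dcov2 can dip infinitesimally below 0
    return float(math.sqrt(max(val, 0.0)))


def compare_profiles(predicted: ResidueProfile,
                     structural: ResidueProfile) -> tuple[float, float]:
    """Distance correlations between a predicted and a structure-derived
    profile of one protein: (rsa_dcor, ss_dcor).

    Residues unresolved in either profile are excluded pairwise (per
    measure).  SS labels are compared in the equidistant planar embedding.
    """
    if predicted.length != structural.length:
        raise ValueError("profiles cover different residue counts")

    mask = np.isfinite(predicted.rsa) & np.isfinite(structural.rsa)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 residues shared between profiles (RSA)")
    rsa_dcor = distance_correlation(predicted.rsa[mask], structural.rsa[mask])

    if predicted.ss_probs is None or structural.ss_probs is None:
        return rsa_dcor, float("nan")  # no SS track to compare
    lp = ss_labels_of(predicted)
    ls = ss_labels_of(structural)
    pairs = [(a, b) for a, b in zip(lp, ls) if a is not None and b is not None]
    if len(pairs) < 2:
        raise ValueError("fewer than 2 residues shared between profiles (SS)")
    P = np.array([SS_EMBEDDING[a] for a, _ in pairs])
    S = np.array([SS_EMBEDDING[b] for _, b in pairs])
    ss_dcor = distance_correlation(P, S)
    return rsa_dcor, ss_dcor
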