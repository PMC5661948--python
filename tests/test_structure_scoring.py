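import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pssearch.io_formats import ResidueProfile
from pssearch.pss_core import PermissiveStretch
from pssearch.structure_scoring import (
    SS_EMBEDDING, UndefinedRsaError, compare_profiles, distance_correlation,
    loop_length_at, score_stretch, site_rsa, ss_label, ss_labels_of,
    stretch_rsa,
)


def profile(rsa, ss=None):
    return ResidueProfile("p", np.asarray(rsa, dtype=float), ss)


class TestSiteRsa:
    def test_interior_geometric_mean(self, simple_profile):
        assert site_rsa(simple_profile, 2) == pytest.approx(math.sqrt(0.4 * 0.9))

    def test_equal_neighbors_idempotent(self):
        assert site_rsa(profile([0.3, 0.3]), 1) == pytest.approx(0.3)

    def test_terminal_sites_take_end_residues(self):
        p = profile([0.7, 0.2, 0.5])
        assert site_rsa(p, 0) == pytest.approx(0.7)
        assert site_rsa(p, 3) == pytest.approx(0.5)

    def test_missing_rsa_signals_undefined(self):
        p = profile([0.2, float("nan"), 0.5])
        with pytest.raises(UndefinedRsaError) as exc:
            site_rsa(p, 1)
        assert exc.value.residues == [2]

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, derandomize=True)
    def test_never_exceeds_larger_neighbor(self, a, b):
        assert site_rsa(profile([a, b]), 1) <= max(a, b) + 1e-12


class TestStretchRsa:
    def test_two_site_max(self):
        p = profile([0.1, 0.4, 0.9, 0.2])
        st_ = PermissiveStretch("p", 2, 4)
        assert stretch_rsa(p, st_) == pytest.approx(0.6)

    def test_single_pair_stretch(self):
        p = profile([0.1, 0.4, 0.9, 0.2])
        assert stretch_rsa(p, PermissiveStretch("p", 3, 4)) == pytest.approx(
            math.sqrt(0.9 * 0.2))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            L = int(rng.integers(5, 30))
            p = profile(rng.uniform(0, 1, L))
            s = int(rng.integers(1, L))
            e = int(rng.integers(s + 1, L + 1))
            brute = max(math.sqrt(p.rsa[i - 1] * p.rsa[i]) for i in range(s, e))
            assert stretch_rsa(p, PermissiveStretch("p", s, e)) == pytest.approx(brute)

    def test_monotone_in_residue_rsa(self):
        rsa = [0.1, 0.4, 0.3, 0.2, 0.5]
        base = stretch_rsa(profile(rsa), PermissiveStretch("p", 2, 4))
        rsa[2] = 0.9
        assert stretch_rsa(profile(rsa), PermissiveStretch("p", 2, 4)) >= base

    def test_missing_residues_listed(self):
        p = profile([0.1, float("nan"), 0.3, 0.2])
        with pytest.raises(UndefinedRsaError) as exc:
            stretch_rsa(p, PermissiveStretch("p", 1, 3))
        assert 2 in exc.value.residues


class TestSsLabels:
    @pytest.mark.parametrize("probs,expected", [
        ((0.1, 0.2, 0.7), "coil"),
        ((0.8, 0.1, 0.1), "helix"),
        ((0.1, 0.8, 0.1), "strand"),
        ((0.5, 0.5, 0.0), "helix"),          # tie: helix beats strand
        ((1 / 3, 1 / 3, 1 / 3), "coil"),     # tie: coil beats both
        ((0.0, 0.5, 0.5), "coil"),
    ])
    def test_argmax_with_declared_tie_break(self, probs, expected):
        assert ss_label(probs) == expected

    def test_loop_length_at(self):
        labels = ["helix", "helix", "coil", "coil", "coil", "helix"]
        assert loop_length_at(labels, 4) == 3
        assert loop_length_at(labels, 1) is None
        assert loop_length_at(["coil"] * 8, 5) == 8
        with pytest.raises(ValueError):
            loop_length_at(labels, 7)

    def test_embedding_is_equilateral(self):
        pts = list(SS_EMBEDDING.values())
        dists = {round(math.dist(a, b), 12) for a, b in itertools.combinations(pts, 2)}
        assert dists == {1.0}

    def test_score_stretch_reports_context_and_loop(self, simple_profile):
        sc = score_stretch(simple_profile, PermissiveStretch("p", 4, 6))
        assert sc.ss_context == "CCC"
        assert sc.best_site == 5  # sqrt(0.8*0.7) beats sqrt(0.2*0.8)
        assert sc.loop_length == 3


def brute_dcor(X, Y):
    """Independent double-centering implementation (naive loops)."""
    X = np.atleast_2d(np.asarray(X, float).T).T if np.asarray(X).ndim == 1 else np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(X)
    a = np.zeros((n, n))
    b = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a[i, j] = np.linalg.norm(X[i] - X[j])
            b[i, j] = np.linalg.norm(Y[i] - Y[j])
    A = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
    B = b - b.mean(0) - b.mean(1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    vx, vy = (A * A).mean(), (B * B).mean()
    if vx <= 0 or vy <= 0:
        return 0.0
    return math.sqrt(max(dcov2 / math.sqrt(vx * vy), 0.0))


class TestDistanceCorrelation:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert distance_correlation(x, x) == pytest.approx(1.0)

    def test_constant_argument_returns_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert distance_correlation(x, np.ones(3)) == 0.0

    def test_four_point_case_matches_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        assert distance_correlation(x, y) == pytest.approx(brute_dcor(x, y))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            d1 = int(rng.integers(1, 3))
            d2 = int(rng.integers(1, 3))
            X = rng.normal(size=(n, d1))
            Y = rng.normal(size=(n, d2))
            assert distance_correlation(X, Y) == pytest.approx(brute_dcor(X, Y))

    def test_symmetry_translation_scale_invariance_and_range(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            d = distance_correlation(x, y)
            assert 0.0 <= d <= 1.0
            assert distance_correlation(y, x) == pytest.approx(d)
            assert distance_correlation(3.7 * x + 2.0, y) == pytest.approx(d)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            distance_correlation(np.ones(3), np.ones(4))


class TestCompareProfiles:
    def test_identical_profiles_give_unity(self):
        rng = np.random.default_rng(3)
        rsa = rng.uniform(0, 1, 30)
        ss = np.tile([0.2, 0.3, 0.5], (30, 1))
        ss[:10] = [0.7, 0.2, 0.1]
        a = ResidueProfile("p", rsa, ss)
        b = ResidueProfile("p", rsa.copy(), ss.copy(), source="structure")
        assert compare_profiles(a, b) == pytest.approx((1.0, 1.0))

    def test_missing_structural_residues_excluded_pairwise(self):
        rng = np.random.default_rng(4)
        rsa = rng.uniform(0, 1, 40)
        struct = rsa.copy()
        struct[::3] = np.nan  # ~30% unresolved
        a = ResidueProfile("p", rsa)
        b = ResidueProfile("p", struct, source="structure")
        rsa_dcor, ss_dcor = compare_profiles(a, b)
        assert math.isnan(ss_dcor)  # neither profile carries an SS track
        mask = np.isfinite(struct)
        assert rsa_dcor == pytest.approx(
            distance_correlation(rsa[mask], struct[mask]))

    def test_compare_profiles_needs_shared_residues(self):
        a = ResidueProfile("p", np.array([0.1, 0.2, 0.3]))
        b = ResidueProfile("p", np.array([np.nan, np.nan, 0.3]),
                           source="structure")
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_profiles(a, b)

    def test_ss_dcor_uses_embedding(self):
        # identical hard labels -> ss_dcor 1 even when probabilities differ
        ss_a = np.tile([0.6, 0.3, 0.1], (20, 1))
        ss_a[10:] = [0.1, 0.2, 0.7]
        ss_b = np.tile([0.9, 0.05, 0.05], (20, 1))
        ss_b[10:] = [0.0, 0.0, 1.0]
        rsa = np.linspace(0, 1, 20)
        a = ResidueProfile("p", rsa, ss_a)
        b = ResidueProfile("p", rsa, ss_b, source="structure")
        _, ss_dcor = compare_profiles(a, b)
        assert ss_dcor == pytest.approx(1.0)

    def test_compare_profiles_ss_only_missing(self):
        labels = ss_labels_of(ResidueProfile("p", np.zeros(3)))
        assert labels == [None, None, None]
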