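"""Triplet scoring: oracle equivalence, additivity, ranking, backbone report."""

import numpy as np
import pytest

from orisite.aa_profiles import build_profiles, default_profiles
from orisite.flexibility import wcn
from orisite.orientation import CandidatePoint
from orisite.scoring import (
    ResidueScore,
    accumulate_scores_bruteforce,
    accumulate_scores_fast,
    backbone_report,
    rank_residues,
    score_triplet,
)

from conftest import make_structure, random_structure


def _points_for(structure, rng, n_points=2, max_n=12):
    """Random candidate points over the structure's vector-bearing residues."""
    vec_idx = [i for i, r in enumerate(structure.residues)
               if r.has_sidechain_vector]
    pts = []
    for _ in range(n_points):
        n = int(rng.integers(3, min(max_n, len(vec_idx)) + 1))
        chosen = sorted(rng.choice(vec_idx, size=n, replace=False))
        pts.append(CandidatePoint(
            position=rng.uniform(0, 25, 3),
            surrounding=[int(i) for i in chosen],
            thetas=np.zeros(n),
            mean_theta=0.0,
        ))
    return pts


class TestScoreTriplet:
    def test_all_zero(self):
        assert score_triplet((0, 0, 0), (0, 0, 0)) == (0.0, 0.0, 0.0)

    def test_uniform_zw(self):
        assert score_triplet((1, 1, 1), (0, 0, 0)) == pytest.approx((2, 2, 2))

    def test_asymmetric_zw(self):
        assert score_triplet((3, 0, 0), (0, 0, 0)) == pytest.approx((4, 1, 1))


class TestBruteForceCombinatorics:
    @pytest.fixture
    def structure(self, rng):
        # ensure at least 6 vector-bearing residues
        while True:
            st = random_structure(rng, n=14)
            if sum(r.has_sidechain_vector for r in st.residues) >= 6:
                return st

    def test_single_triplet_point(self, structure, rng):
        pts = _points_for(structure, rng, n_points=1)
        pts[0].surrounding = pts[0].surrounding[:3]
        flex = wcn(structure)
        scores = accumulate_scores_bruteforce(pts, structure, flex,
                                              default_profiles())
        counted = {s.residue_index: s.triplet_count for s in scores}
        for i in pts[0].surrounding:
            assert counted[i] == 1  # C(3,3) = 1, each member scored once
        assert sum(counted.values()) == 3

    def test_five_surrounding_membership_count(self, structure, rng):
        pts = _points_for(structure, rng, n_points=1)
        vec_idx = [i for i, r in enumerate(structure.residues)
                   if r.has_sidechain_vector]
        pts[0].surrounding = vec_idx[:5]
        scores = accumulate_scores_bruteforce(pts, structure, wcn(structure),
                                              default_profiles())
        counts = {s.residue_index: s.triplet_count for s in scores}
        for i in vec_idx[:5]:
            assert counts[i] == 6  # each residue in C(4,2) of the 10 triplets

    def test_memberships_add_across_points(self, structure, rng):
        vec_idx = [i for i, r in enumerate(structure.residues)
                   if r.has_sidechain_vector]
        shared = vec_idx[0]
        p1 = CandidatePoint(np.zeros(3), [shared] + vec_idx[1:3],
                            np.zeros(3), 0.0)
        p2 = CandidatePoint(np.ones(3), [shared] + vec_idx[3:5],
                            np.zeros(3), 0.0)
        scores = accumulate_scores_bruteforce([p1, p2], structure,
                                              wcn(structure), default_profiles())
        counts = {s.residue_index: s.triplet_count for s in scores}
        assert counts[shared] == 2


class TestOracleEquivalence:
    def test_fast_equals_bruteforce_on_many_random_fixtures(self):
        """The closed-form accumulation reproduces explicit triplet
        enumeration to |ΔS| < 1e-9 on 120 randomized fixtures."""
        profiles = default_profiles()
        worst = 0.0
        n_cases = 0
        for seed in range(120):
            rng = np.random.default_rng(1000 + seed)
            st = random_structure(rng, n=int(rng.integers(10, 18)))
            if sum(r.has_sidechain_vector for r in st.residues) < 4:
                continue
            pts = _points_for(st, rng, n_points=int(rng.integers(1, 4)))
            flex = wcn(st)
            brute = {s.residue_index: s for s in
                     accumulate_scores_bruteforce(pts, st, flex, profiles)}
            fast = {s.residue_index: s for s in
                    accumulate_scores_fast(pts, st, flex, profiles)}
            assert brute.keys() == fast.keys()
            for i in brute:
                worst = max(worst, abs(brute[i].S - fast[i].S))
                assert brute[i].triplet_count == fast[i].triplet_count
                assert brute[i].z_a_sum == pytest.approx(fast[i].z_a_sum,
                                                         abs=1e-9)
            n_cases += 1
        assert n_cases >= 100
        assert worst < 1e-9

    def test_empty_candidate_list(self, rng):
        st = random_structure(rng, n=10)
        for s in accumulate_scores_fast([], st, wcn(st), default_profiles()):
            assert s.S == 0.0 and s.triplet_count == 0


def test_score_additivity_over_disjoint_point_sets(rng):
    """Scoring the union of two candidate sets equals the per-residue sum of
    scoring them separately, once the a-value normalization is shared."""
    st = random_structure(rng, n=16)
    if sum(r.has_sidechain_vector for r in st.residues) < 6:
        st = random_structure(rng, n=20)
    flex = wcn(st)
    pts = _points_for(st, rng, n_points=4)
    # an all-ALA profile zeroes every a value, so z^a is degenerate (0) in
    # every subset and scores reduce to the strictly additive WCN terms
    zero_profiles = build_profiles([["ALA", "ALA"]])
    union = {s.residue_index: s.S for s in
             accumulate_scores_fast(pts, st, flex, zero_profiles)}
    part1 = {s.residue_index: s.S for s in
             accumulate_scores_fast(pts[:2], st, flex, zero_profiles)}
    part2 = {s.residue_index: s.S for s in
             accumulate_scores_fast(pts[2:], st, flex, zero_profiles)}
    for i in union:
        assert union[i] == pytest.approx(part1[i] + part2[i], abs=1e-9)


class TestRankResidues:
    def _scores(self, structure, values):
        out = []
        for i, v in enumerate(values):
            rs = ResidueScore(residue_index=i, S=v)
            rs.triplet_count = 1
            out.append(rs)
        return out

    def test_descending_order(self):
        st = make_structure([("A", i, "", "ASP", (6.0 * i, 0, 0),
                              (6.0 * i + 1, 0, 0)) for i in (1, 2, 3)])
        ranked = rank_residues(self._scores(st, [3.0, 1.0, 2.0]), st)
        assert [st.residues[r.residue_index].seq_num for r in ranked] == [1, 3, 2]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_tie_breaks_by_identity(self):
        st = make_structure([("A", 10, "", "ASP", (0, 0, 0), (1, 0, 0)),
                             ("A", 7, "", "GLU", (8, 0, 0), (9, 0, 0))])
        ranked = rank_residues(self._scores(st, [5.0, 5.0]), st)
        assert [st.residues[r.residue_index].seq_num for r in ranked] == [7, 10]

    def test_unscored_residues_rank_last_in_identity_order(self):
        st = make_structure([("A", i, "", "ASP", (6.0 * i, 0, 0),
                              (6.0 * i + 1, 0, 0)) for i in (1, 2, 3)])
        scores = self._scores(st, [-5.0, 0.0, 0.0])
        scores[1].triplet_count = 0
        scores[2].triplet_count = 0
        ranked = rank_residues(scores, st)
        # scored residue first even with negative S; rest by identity
        assert [st.residues[r.residue_index].seq_num for r in ranked] == [1, 2, 3]

    def test_fused_score_used_when_requested(self):
        st = make_structure([("A", 1, "", "ASP", (0, 0, 0), (1, 0, 0)),
                             ("A", 2, "", "GLU", (8, 0, 0), (9, 0, 0))])
        scores = self._scores(st, [2.0, 1.0])
        scores[0].S_prime = 0.5
        scores[1].S_prime = 3.0
        ranked = rank_residues(scores, st, use_fused=True)
        assert [st.residues[r.residue_index].seq_num for r in ranked] == [2, 1]


class TestBackboneReport:
    def test_backbone_types_only(self, rng):
        st = make_structure([
            ("A", 1, "", "GLY", (0, 0, 0), None),
            ("A", 2, "", "ASP", (6, 0, 0), (7, 0, 0)),
            ("A", 3, "", "PRO", (12, 0, 0), None),
        ])
        rep = backbone_report(st, wcn(st), default_profiles())
        assert list(rep["aa"]) == ["GLY", "PRO"]
        assert "ASP" not in set(rep["aa"])

    def test_empty_structure_empty_report(self):
        st = make_structure([("A", 1, "", "ASP", (0, 0, 0), (1, 0, 0)),
                             ("A", 2, "", "GLU", (7, 0, 0), (8, 0, 0)),
                             ("A", 3, "", "HIS", (18, 0, 0), (19, 0, 0))])
        rep = backbone_report(st, wcn(st), default_profiles())
        assert len(rep) == 0
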