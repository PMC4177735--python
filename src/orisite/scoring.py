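"""Triplet enumeration, feature scoring and residue ranking.

Every surviving candidate point contributes one feature score to each member
of each triplet (unordered 3-subset) of its surrounding residues.  For a
triplet n = {j, y, z} the member j receives

    S_incr = w_n + z^w_j + z^a_j

where w_n is the mean normalized WCN of the triplet, z^w_j the residue's own
normalized WCN, and z^a_j the normalized amino-acid combination score
a_j = p_x^y + p_x^z (x = type of j).  a-values are z-normalized over the
multiset of ALL triplet-membership a values of the protein (population
statistics), computed in a first pass.  A residue's total score S is the sum
of its increments over every triplet of every candidate point that contains
it; residues are ranked by S descending.

Enumerating C(N,3) triplets for 27,000 grid points is infeasible naively, so
the production path (:func:`accumulate_scores_fast`) uses closed forms for
the per-point sums; :func:`accumulate_scores_bruteforce` is the reference
oracle and must agree to 1e-9.

Closed forms per point with surrounding set R, N = |R|, T = Σ_{m∈R} z^w_m,
q_j = Σ_{m∈R∖{j}} p_{x(j)}^{x(m)}, q2_j the same sum of squared entries:

    Σ_{triplets ∋ j} (w_n + z^w_j) = (4/3)·C(N-1,2)·z^w_j + (N-2)/3·(T - z^w_j)
    Σ_{triplets ∋ j} a_j          = (N-2)·q_j
    Σ_{triplets ∋ j} a_j²         = (N-3)·q2_j + q_j²

(the last feeds the exact population mean/SD of the a multiset without
enumeration; each point contributes N·C(N-1,2) membership values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .aa_profiles import ProfileSet
from .flexibility import FlexibilityProfile
from .orientation import CandidatePoint
from .structure_io import AA_INDEX, SIDECHAIN_VECTOR_ATOMS, Structure

logger = logging.getLogger(__name__)


@dataclass
class ResidueScore:
    """Accumulated score of one residue across all candidate points."""

    residue_index: int
    S: float = 0.0
    triplet_count: int = 0
    z_w: float = 0.0
    z_a_sum: float = 0.0
    z_c: float | None = None
    S_prime: float | None = None
    rank: int | None = None

    @property
    def mean_z_a(self) -> float:
        return self.z_a_sum / self.triplet_count if self.triplet_count else 0.0


def score_triplet(
    z_w: tuple[float, float, float],
    z_a: tuple[float, float, float],
) -> tuple[float, float, float]:
    """Feature scores a single triplet hands to its three members.

    ``z_w``/``z_a`` hold each member's normalized WCN and combination score;
    member j receives mean(z_w) + z_w[j] + z_a[j].
    """
    w_n = sum(z_w) / 3.0
    return tuple(w_n + z_w[k] + z_a[k] for k in range(3))


def _init_scores(structure: Structure, flex: FlexibilityProfile) -> dict[int, ResidueScore]:
    scores: dict[int, ResidueScore] = {}
    for idx, res in enumerate(structure.residues):
        if res.has_sidechain_vector:
            scores[idx] = ResidueScore(residue_index=idx, z_w=float(flex.z[idx]))
    return scores


def accumulate_scores_bruteforce(
    candidates: list[CandidatePoint],
    structure: Structure,
    flex: FlexibilityProfile,
    profiles: ProfileSet,
) -> list[ResidueScore]:
    """Reference oracle: enumerate every triplet of every point explicitly.

    Two passes — first collect the full multiset of a values to fix the
    normalization, then score.  Quadratic-ish and meant for small inputs and
    for validating :func:`accumulate_scores_fast`.
    """
    scores = _init_scores(structure, flex)
    aa_idx = {i: AA_INDEX[structure.residues[i].aa] for i in scores}
    P = profiles.p

    a_values: list[float] = []
    for pt in candidates:
        for j, y, z in combinations(pt.surrounding, 3):
            xj, xy, xz = aa_idx[j], aa_idx[y], aa_idx[z]
            a_values.append(P[xj, xy] + P[xj, xz])
            a_values.append(P[xy, xj] + P[xy, xz])
            a_values.append(P[xz, xj] + P[xz, xy])
    if a_values:
        arr = np.asarray(a_values)
        a_mean = float(arr.mean())
        a_sd = float(arr.std())
    else:
        a_mean, a_sd = 0.0, 0.0

    def z_a(a: float) -> float:
        return (a - a_mean) / a_sd if a_sd > 0 else 0.0

    for pt in candidates:
        for trip in combinations(pt.surrounding, 3):
            zw = tuple(float(flex.z[i]) for i in trip)
            xs = tuple(aa_idx[i] for i in trip)
            za = (
                z_a(P[xs[0], xs[1]] + P[xs[0], xs[2]]),
                z_a(P[xs[1], xs[0]] + P[xs[1], xs[2]]),
                z_a(P[xs[2], xs[0]] + P[xs[2], xs[1]]),
            )
            incr = score_triplet(zw, za)
            for k, i in enumerate(trip):
                rs = scores[i]
                rs.S += incr[k]
                rs.triplet_count += 1
                rs.z_a_sum += za[k]
    return list(scores.values())


def accumulate_scores_fast(
    candidates: list[CandidatePoint],
    structure: Structure,
    flex: FlexibilityProfile,
    profiles: ProfileSet,
) -> list[ResidueScore]:
    """Closed-form accumulation; equals the brute-force oracle to 1e-9."""
    scores = _init_scores(structure, flex)
    P = profiles.p
    types = np.array(
        [AA_INDEX[r.aa] for r in structure.residues], dtype=np.intp
    )
    zw_all = np.asarray(flex.z, dtype=float)

    # pass 1: exact population mean/SD of the a-value multiset
    total_n = 0
    total_sum = 0.0
    total_sumsq = 0.0
    per_point: list[tuple[np.ndarray, np.ndarray, int]] = []  # (idx, q, N)
    for pt in candidates:
        idx = np.asarray(pt.surrounding, dtype=np.intp)
        N = idx.size
        t = types[idx]
        sub = P[np.ix_(t, t)]                       # (N, N) pairwise p_x^y
        diag = np.diagonal(sub)
        q = sub.sum(axis=1) - diag
        q2 = (sub**2).sum(axis=1) - diag**2
        c_pairs = comb(N - 1, 2)
        total_n += N * c_pairs
        total_sum += (N - 2) * q.sum()
        total_sumsq += ((N - 3) * q2 + q**2).sum()
        per_point.append((idx, q, N))
    if total_n:
        a_mean = total_sum / total_n
        var = max(total_sumsq / total_n - a_mean**2, 0.0)
        a_sd = float(np.sqrt(var))
    else:
        a_mean, a_sd = 0.0, 0.0

    # pass 2: per-residue accumulation
    S = np.zeros(len(structure.residues))
    za_sum = np.zeros(len(structure.residues))
    counts = np.zeros(len(structure.residues), dtype=np.int64)
    for idx, q, N in per_point:
        c_pairs = comb(N - 1, 2)
        zw = zw_all[idx]
        T = zw.sum()
        wcn_part = (4.0 / 3.0) * c_pairs * zw + ((N - 2) / 3.0) * (T - zw)
        if a_sd > 0:
            comb_part = ((N - 2) * q - c_pairs * a_mean) / a_sd
        else:
            comb_part = np.zeros_like(q)
        np.add.at(S, idx, wcn_part + comb_part)
        np.add.at(za_sum, idx, comb_part)
        np.add.at(counts, idx, c_pairs)
    for i, rs in scores.items():
        rs.S = float(S[i])
        rs.z_a_sum = float(za_sum[i])
        rs.triplet_count = int(counts[i])
    logger.info("scored %d candidate points, %d triplet memberships",
                len(candidates), total_n)
    return list(scores.values())


def rank_residues(
    scores: list[ResidueScore],
    structure: Structure,
    use_fused: bool = False,
) -> list[ResidueScore]:
    """Rank residues descending by S (or S′ when fused).

    Ties break by residue identity (chain, number, insertion code)
    ascending.  Residues that entered no triplet keep S = 0 and are listed
    after every scored residue, in identity order.  Ranks 1..n are written
    back onto the returned (sorted) list.
    """
    def identity(rs: ResidueScore):
        return structure.residues[rs.residue_index].identity

    def sort_key(rs: ResidueScore):
        val = rs.S_prime if (use_fused and rs.S_prime is not None) else rs.S
        scored = rs.triplet_count > 0
        return (0 if scored else 1, -val if scored else 0.0, identity(rs))

    ordered = sorted(scores, key=sort_key)
    for i, rs in enumerate(ordered, start=1):
        rs.rank = i
    return ordered


def backbone_report(
    structure: Structure,
    flex: FlexibilityProfile,
    profiles: ProfileSet,
) -> pd.DataFrame:
    """Auxiliary table for the eight backbone-functional amino-acid types.

    These types carry no side-chain vector and are never ranked; about 5% of
    catalytic residues belong to them, so their flexibility z-score and best
    pairwise profile affinity (max over partner types of p_x^y) are reported
    for manual inspection.
    """
    rows = []
    for idx, res in enumerate(structure.residues):
        if res.aa in SIDECHAIN_VECTOR_ATOMS:
            continue
        rows.append(
            {
                "chain": res.chain_id,
                "resnum": res.seq_num,
                "icode": res.icode,
                "aa": res.aa,
                "z_wcn": float(flex.z[idx]),
                "best_profile_affinity": float(profiles.row(res.aa).max()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chain", "resnum", "icode", "aa", "z_wcn", "best_profile_affinity"],
    )
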