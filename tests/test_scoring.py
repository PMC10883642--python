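"""Desirability scoring, the weighted final score and constraint scores."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from latentmol.errors import (
    EmptyObjectives,
    InvalidSmarts,
    NegativeWeight,
)
from latentmol.scoring import (
    Objective,
    desirability,
    final_score,
    score_molecule,
    similarity_objective,
    similarity_score,
    substructure_objective,
    substructure_score,
    tanimoto_similarity,
)


def _obj(opt, rec, **kw):
    return Objective("x", evaluator=lambda m: 0.0, optimal_range=opt,
                     recommended_range=rec, **kw)


class TestDesirability:
    def test_one_inside_optimal(self):
        o = _obj((2, 4), (0, 6))
        assert desirability(3.0, o) == 1.0
        assert desirability(2.0, o) == 1.0  # closed boundary
        assert desirability(4.0, o) == 1.0

    def test_zero_outside_recommended(self):
        o = _obj((2, 4), (0, 6))
        assert desirability(-1.0, o) == 0.0
        assert desirability(7.0, o) == 0.0
        assert desirability(0.0, o) == 0.0  # recommended boundary attains 0
        assert desirability(6.0, o) == 0.0

    def test_linear_shoulder(self):
        o = _obj((2, 4), (0, 6))
        assert desirability(1.0, o) == pytest.approx(0.5)
        assert desirability(5.0, o) == pytest.approx(0.5)
        assert 0.0 < desirability(0.5, o) < 1.0

    def test_one_sided_ramp(self):
        o = _obj((0.67, math.inf), (0.3, math.inf))
        assert desirability(0.8, o) == 1.0
        assert desirability(0.3, o) == 0.0
        assert desirability(0.485, o) == pytest.approx(0.5)

    def test_non_finite_scores_zero_with_warning(self):
        o = _obj((2, 4), (0, 6))
        with pytest.warns(UserWarning):
            assert desirability(float("nan"), o) == 0.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_monotone_from_optimal(self, seed):
        """Desirability never increases as the value moves away from the
        optimal interval on either side."""
        rng = np.random.default_rng(seed)
        LO, lo, hi, HI = np.sort(rng.uniform(-10, 10, 4))
        if not (LO < lo <= hi < HI):
            return
        o = _obj((lo, hi), (LO, HI))
        left = np.sort(rng.uniform(LO - 1, lo, 8))
        vals = [desirability(v, o) for v in left]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
        right = np.sort(rng.uniform(hi, HI + 1, 8))
        vals = [desirability(v, o) for v in right]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestFinalScore:
    def test_hand_examples(self):
        assert final_score([1, 0], [1, 1]) == pytest.approx(0.5)
        assert final_score([1, 0], [2, 1]) == pytest.approx(2 / 3)
        assert final_score([0.7], [5.0]) == pytest.approx(0.7)

    def test_matches_hand_oracle_on_random_draws(self):
        """1000 random (S, W) draws against an explicitly summed weighted
        mean, to 1e-12."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            j = int(rng.integers(1, 9))
            S = rng.uniform(0, 1, j)
            W = rng.uniform(1e-3, 10, j)
            num = 0.0
            den = 0.0
            for s, w in zip(S, W):
                num += s * w
                den += w
            assert abs(final_score(S, W) - num / den) < 1e-12

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        S = rng.uniform(0, 1, 5)
        W = rng.uniform(0.1, 3, 5)
        for c in [1e-6, 0.5, 3.0, 1e6]:
            assert final_score(S, c * W) == pytest.approx(
                final_score(S, W), abs=1e-12
            )

    def test_errors(self):
        with pytest.raises(EmptyObjectives):
            final_score([], [])
        with pytest.raises(NegativeWeight):
            final_score([0.5], [-1.0])


class TestTanimoto:
    def test_self_similarity(self):
        assert tanimoto_similarity("c1ccccc1CCO", "c1ccccc1CCO") == 1.0

    def test_disjoint(self):
        assert tanimoto_similarity("C", "N") == 0.0

    def test_symmetric(self):
        a, b = "CCOc1ccccc1", "CCN"
        assert tanimoto_similarity(a, b) == tanimoto_similarity(b, a)

    def test_agrees_with_bit_set_brute_force(self, corpus200):
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        rng = np.random.default_rng(5)
        smiles = [r.canonical_smiles for r in corpus200]
        for _ in range(50):
            a, b = rng.choice(smiles, 2)
            fa = set(gen.GetFingerprint(Chem.MolFromSmiles(a)).GetOnBits())
            fb = set(gen.GetFingerprint(Chem.MolFromSmiles(b)).GetOnBits())
            expected = len(fa & fb) / len(fa | fb) if fa | fb else 1.0
            assert tanimoto_similarity(a, b) == pytest.approx(expected,
                                                              abs=1e-12)


class TestSimilarityScore:
    def test_identical_is_one(self):
        assert similarity_score("CCO", "CCO", 0.4) == 1.0

    def test_linear_ramp(self):
        # construct a pair, then check the ramp formula at its similarity
        t = tanimoto_similarity("CCCCCCO", "CCCCCCN")
        assert 0 < t < 0.4 or t >= 0.4
        threshold = min(0.95, t * 2)
        expected = 1.0 if t >= threshold else t / threshold
        assert similarity_score("CCCCCCO", "CCCCCCN", threshold) == (
            pytest.approx(expected)
        )

    def test_boundary_attains_one(self):
        t = tanimoto_similarity("CCO", "CCN")
        assert similarity_score("CCO", "CCN", t) == 1.0

    def test_strict_mode(self):
        t = tanimoto_similarity("CCO", "c1ccccc1")
        assert similarity_score("CCO", "c1ccccc1", min(0.9, t + 0.1),
                                strict=True) == 0.0


SUBSTRUCTURE_PANEL = [
    ("CC(=O)Nc1ccccc1", "C(=O)N", 1),   # anilide amide
    ("c1ccccc1", "C(=O)N", 0),
    ("CCO", "[OX2H]", 1),               # hydroxyl
    ("CCOC", "[OX2H]", 0),              # ether has no O-H
    ("c1ccccc1", "c1ccccc1", 1),        # self-match
    ("C1CCCCC1", "c1ccccc1", 0),        # saturated ring is not aromatic
    ("CCN", "[NX3]", 1),
    ("CC#N", "[NX3]", 0),               # nitrile N is not trivalent amine
    ("CCCl", "[Cl]", 1),
    ("CCBr", "[Cl]", 0),
    ("CC(=O)O", "C(=O)[OX2H1]", 1),     # carboxylic acid
    ("CC(=O)OC", "C(=O)[OX2H1]", 0),    # ester
    ("c1ccncc1", "n", 1),               # aromatic nitrogen
    ("c1ccccc1", "n", 0),
    ("C=CC", "C=C", 1),
    ("CCC", "C=C", 0),
    ("CC(C)C", "[CX4H0]", 0),           # isobutane has no quaternary carbon
    ("C1CCOC1", "[OX2r5]", 1),          # ring oxygen in 5-ring
    ("CCOCC", "[OX2r5]", 0),
    ("CC#N", "C#N", 1),
]


class TestSubstructure:
    @pytest.mark.parametrize("smiles,smarts,expected", SUBSTRUCTURE_PANEL)
    def test_panel(self, smiles, smarts, expected):
        assert substructure_score(smiles, smarts) == expected

    def test_own_smiles_matches(self):
        for s in ["CCO", "CC(N)=O", "c1ccncc1"]:
            assert substructure_score(s, s) == 1

    def test_invalid_smarts(self):
        with pytest.raises(InvalidSmarts):
            substructure_score("CCO", "[[[")


class TestScoreMolecule:
    def _slogp_objective(self, opt, rec, weight=1.0):
        from latentmol.properties import compute_builtin

        return Objective("SlogP", lambda m: compute_builtin(m, "SlogP"),
                         optimal_range=opt, recommended_range=rec,
                         weight=weight)

    def test_all_optimal_gives_one(self):
        objs = [self._slogp_objective((-10, 10), (-20, 20)),
                substructure_objective("[OX2H]", hard=False)]
        rep = score_molecule("CCO", objs)
        assert rep.F == 1.0
        assert rep.scaled_scores == [1.0, 1.0]

    def test_all_outside_gives_zero(self):
        objs = [self._slogp_objective((100, 200), (99, 201))]
        rep = score_molecule("CCO", objs)
        assert rep.F == 0.0

    def test_weighted_mix(self):
        objs = [
            Objective("a", lambda m: 0.0, optimal_range=(-1, 1),
                      recommended_range=(-2, 2), weight=1.0),
            Objective("b", lambda m: 0.5, scorer=lambda v: v, weight=3.0),
        ]
        rep = score_molecule("CCO", objs)
        assert rep.F == pytest.approx(0.625)

    def test_invalid_molecule_scores_zero(self):
        from latentmol.chem_io import MoleculeRecord

        bad = MoleculeRecord.from_smiles("xx((")
        rep = score_molecule(bad, [_obj((0, 1), (0, 1))])
        assert rep.F == 0.0

    def test_deterministic(self):
        objs = [self._slogp_objective((-1, 2), (-3, 5)),
                similarity_objective("CCO", threshold=0.5)]
        a = score_molecule("CCCO", objs)
        b = score_molecule("CCCO", objs)
        assert a.raw_values == b.raw_values
        assert a.F == b.F

    def test_hard_constraint_zeroes_final_score(self):
        objs = [self._slogp_objective((-10, 10), (-20, 20)),
                substructure_objective("C(=O)N", hard=True)]
        rep = score_molecule("CCO", objs)  # no amide
        assert rep.constraint_violated
        assert rep.F == 0.0

    def test_report_final_score_recomputable(self):
        objs = [self._slogp_objective((-1, 2), (-3, 5), weight=2.0),
                similarity_objective("CCO", threshold=0.5, weight=0.5)]
        rep = score_molecule("CCCCO", objs)
        assert rep.F == pytest.approx(
            final_score(rep.scaled_scores, rep.weights), abs=1e-12
        )
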