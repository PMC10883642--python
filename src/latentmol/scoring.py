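"""Multi-objective desirability scoring.

Each objective rescales a raw property value into a desirability
S in [0, 1]: exactly 1 inside the closed optimal range, 0 outside the
recommended range, and a linear ramp on the shoulders in between (the
simplest monotone choice; swap ``desirability`` to change it).  The
final score is the weight-normalized mean

    F = sum_i(S_i * W_i) / sum_i(W_i)

so F is invariant under uniform rescaling of the weights.  Similarity to
a reference molecule (ECFP4-equivalent Morgan fingerprints, radius 2,
2048 bits, Tanimoto metric) and SMARTS substructure presence enter the
same weighted mean as constraint objectives, optionally in hard mode
where a violated constraint forces F to 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import MoleculeRecord
from .errors import (
    EmptyObjectives,
    InvalidSmarts,
    InvalidSmiles,
    NegativeWeight,
)

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _as_mol(molecule) -> Chem.Mol:
    if isinstance(molecule, Chem.Mol):
        return molecule
    if isinstance(molecule, MoleculeRecord):
        return molecule.mol()
    mol = Chem.MolFromSmiles(molecule)
    if mol is None:
        raise InvalidSmiles(f"cannot parse SMILES: {molecule!r}")
    return mol


@dataclass
class Objective:
    """One scored property or constraint.

    ``evaluator`` maps a molecule to a raw value; ``scorer`` maps the raw
    value to S in [0, 1] (default: desirability against the ranges).
    ``hard=True`` marks a strict constraint: S = 0 then zeroes the whole
    final score.  One-sided objectives use infinite bounds; the
    recommended range must contain the optimal range.
    """

    name: str
    evaluator: Callable[[Chem.Mol], float]
    optimal_range: tuple[float, float] = (-math.inf, math.inf)
    recommended_range: tuple[float, float] = (-math.inf, math.inf)
    weight: float = 1.0
    scorer: Callable[[float], float] | None = None
    hard: bool = False

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise NegativeWeight(f"objective {self.name!r}: weight must be > 0")
        lo, hi = self.optimal_range
        LO, HI = self.recommended_range
        if not (LO <= lo <= hi <= HI):
            raise ValueError(
                f"objective {self.name!r}: recommended range must contain "
                f"optimal range"
            )

    def score(self, value: float) -> float:
        if self.scorer is not None:
            return self.scorer(value)
        return desirability(value, self)


def desirability(value: float, objective: Objective) -> float:
    """Piecewise-linear desirability of a raw value.

    1 inside the closed optimal range, 0 at or beyond the recommended
    boundary, and a strictly-interior linear ramp on each shoulder.
    Non-finite values score 0 with a warning.
    """
    if not math.isfinite(value):
        warnings.warn(
            f"non-finite value for objective {objective.name!r} scored as 0"
        )
        return 0.0
    lo, hi = objective.optimal_range
    LO, HI = objective.recommended_range
    if lo <= value <= hi:
        return 1.0
    if value < lo:
        # an infinite recommended bound with a finite optimal bound has no
        # finite shoulder to ramp over; score 0 (degenerate configuration)
        if value <= LO or math.isinf(LO):
            return 0.0
        return (value - LO) / (lo - LO)
    if value >= HI or math.isinf(HI):
        return 0.0
    return (HI - value) / (HI - hi)


def final_score(scores: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted arithmetic mean of desirabilities (the final score F)."""
    if len(scores) == 0 or len(weights) == 0:
        raise EmptyObjectives("final_score needs at least one objective")
    if len(scores) != len(weights):
        raise ValueError("scores and weights must have equal length")
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise NegativeWeight("all weights must be > 0")
    s = np.asarray(scores, dtype=float)
    return float((s * w).sum() / w.sum())


def tanimoto_similarity(molecule_a, molecule_b) -> float:
    """Tanimoto coefficient on 2048-bit radius-2 Morgan fingerprints
    (the ECFP4-equivalent circular fingerprint)."""
    fa = _MORGAN.GetFingerprint(_as_mol(molecule_a))
    fb = _MORGAN.GetFingerprint(_as_mol(molecule_b))
    return DataStructs.TanimotoSimilarity(fa, fb)


def similarity_score(
    candidate, reference, similarity_threshold: float, strict: bool = False
) -> float:
    """Similarity constraint score.

    1 when the Tanimoto similarity reaches the threshold; otherwise a
    linear ramp down to 0 at similarity 0 (soft mode, the default, so
    the constraint composes with the weighted mean) or exactly 0
    (strict-filter mode).
    """
    if not (0.0 < similarity_threshold <= 1.0):
        raise ValueError("similarity_threshold must be in (0, 1]")
    t = tanimoto_similarity(candidate, reference)
    if t >= similarity_threshold:
        return 1.0
    return 0.0 if strict else t / similarity_threshold


def substructure_score(candidate, motif: str) -> int:
    """1 iff the candidate contains at least one match of the SMARTS motif."""
    pattern = Chem.MolFromSmarts(motif)
    if pattern is None:
        raise InvalidSmarts(f"cannot parse SMARTS: {motif!r}")
    return int(_as_mol(candidate).HasSubstructMatch(pattern))


def similarity_objective(
    reference, threshold: float = 0.4, weight: float = 1.0,
    strict: bool = False, name: str = "similarity",
) -> Objective:
    """Similarity-to-reference constraint as a weighted objective."""
    ref_mol = _as_mol(reference)

    def evaluator(mol: Chem.Mol) -> float:
        return tanimoto_similarity(mol, ref_mol)

    def scorer(t: float) -> float:
        if t >= threshold:
            return 1.0
        return 0.0 if strict else t / threshold

    return Objective(name=name, evaluator=evaluator, scorer=scorer,
                     weight=weight, hard=strict)


def substructure_objective(
    motif: str, weight: float = 1.0, hard: bool = True,
    name: str = "substructure",
) -> Objective:
    """Bioactive-motif constraint as a weighted objective (hard by default:
    a molecule missing the motif scores F = 0)."""
    pattern = Chem.MolFromSmarts(motif)
    if pattern is None:
        raise InvalidSmarts(f"cannot parse SMARTS: {motif!r}")

    def evaluator(mol: Chem.Mol) -> float:
        return float(mol.HasSubstructMatch(pattern))

    return Objective(name=name, evaluator=evaluator, scorer=float,
                     weight=weight, hard=hard)


@dataclass
class ScoreReport:
    """Per-objective raw values, desirabilities and the final score."""

    names: list[str] = field(default_factory=list)
    raw_values: list[float] = field(default_factory=list)
    scaled_scores: list[float] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)
    F: float = 0.0
    constraint_violated: bool = False

    @property
    def n_objectives(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict:
        d = {}
        for n, r, s in zip(self.names, self.raw_values, self.scaled_scores):
            d[n] = r
            d[f"{n}_score"] = s
        d["final_score"] = self.F
        return d


def score_molecule(molecule, objectives: Sequence[Objective]) -> ScoreReport:
    """Evaluate every objective on one molecule and aggregate to F.

    An invalid molecule scores F = 0 with empty per-objective entries.
    A hard constraint scoring 0 marks the report as violated and forces
    F = 0 while per-objective values are still reported.
    """
    if len(objectives) == 0:
        raise EmptyObjectives("score_molecule needs at least one objective")
    if isinstance(molecule, MoleculeRecord) and not molecule.valid:
        return ScoreReport(F=0.0)
    try:
        mol = _as_mol(molecule)
    except InvalidSmiles:
        return ScoreReport(F=0.0)
    report = ScoreReport()
    violated = False
    for obj in objectives:
        raw = float(obj.evaluator(mol))
        s = float(obj.score(raw))
        if obj.hard and s == 0.0:
            violated = True
        report.names.append(obj.name)
        report.raw_values.append(raw)
        report.scaled_scores.append(s)
        report.weights.append(obj.weight)
    report.constraint_violated = violated
    report.F = 0.0 if violated else final_score(
        report.scaled_scores, report.weights
    )
    return report
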