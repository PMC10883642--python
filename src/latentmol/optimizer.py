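"""Multi-objective particle swarm optimization over the latent space.

A swarm of particles moves through the 512-dimensional tanh-bounded
latent space.  Each particle i carries a position x_i and velocity v_i;
after every iteration the velocity blends inertia, attraction to the
particle's own historical best x_i_best and attraction to the swarm's
historical best x_best:

    v_i <- w * v_i + c1 * r1 * (x_i_best - x_i) + c2 * r2 * (x_best - x_i)
    x_i <- x_i + v_i

with r1, r2 drawn independently per particle per step from Uniform(0, 1).
Positions are clipped back to [-1, 1] componentwise (the decoder was only
ever trained on tanh-range vectors) and velocities are capped at 1.0 per
component.  The inertia weight decays linearly from ``w`` to ``w_end``
over the run unless held constant.

The objective surface is the desirability final score of the molecule a
position decodes to; positions with no valid decode score 0.  Scored
property values always describe the *re-encoded decoded molecule*, never
the raw particle position, so every reported score belongs to a
realizable structure (raw-position scoring is available as a test hook
by passing an analytic objective directly to :func:`run_pso`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chem_io import LATENT_DIM, MoleculeRecord, canonicalize
from .errors import DimensionError, InvalidSmiles, NonFiniteScore
from .scoring import Objective, ScoreReport, score_molecule, tanimoto_similarity
from .translator import Seq2SeqTranslator


@dataclass
class PSOConfig:
    """Swarm constants and run sizes.

    ``w`` decays linearly to ``w_end`` across iterations unless
    ``constant_inertia``; c1/c2 are the cognitive and social weights.
    Each of the ``restarts`` cycles reseeds its jitter and uniform draws
    from a child seed of ``seed``, so a full run is reproducible from the
    config alone.
    """

    w: float = 0.9
    w_end: float = 0.4
    constant_inertia: bool = False
    c1: float = 2.0
    c2: float = 2.0
    swarm_size: int = 100
    iterations: int = 50
    restarts: int = 100
    top_k: int = 10
    init_jitter_sd: float = 0.1
    position_clip: bool = True
    velocity_cap: float = 1.0
    beam_width: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.w, self.w_end, self.c1, self.c2) < 0:
            raise ValueError("w, w_end, c1, c2 must be >= 0")
        if self.swarm_size < 1 or self.iterations < 1 or self.restarts < 1:
            raise ValueError("swarm_size, iterations, restarts must be >= 1")

    def inertia_at(self, k: int) -> float:
        """Inertia weight at iteration k (0-based)."""
        if self.constant_inertia or self.iterations <= 1:
            return self.w
        frac = k / (self.iterations - 1)
        return self.w + (self.w_end - self.w) * min(frac, 1.0)


@dataclass
class Particle:
    """Single-particle view of the swarm state."""

    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_score: float


@dataclass
class Swarm:
    """Vectorized swarm state: row i of each array is particle i."""

    positions: np.ndarray       # (S, D)
    velocities: np.ndarray      # (S, D)
    best_positions: np.ndarray  # (S, D)
    best_scores: np.ndarray     # (S,)
    global_best_position: np.ndarray  # (D,)
    global_best_score: float
    iteration: int = 0

    @property
    def particles(self) -> list[Particle]:
        return [
            Particle(self.positions[i], self.velocities[i],
                     self.best_positions[i], float(self.best_scores[i]))
            for i in range(len(self.best_scores))
        ]


ObjectiveFn = Callable[[np.ndarray], np.ndarray]
"""Maps positions (S, D) to finite scores (S,)."""


def _check_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise NonFiniteScore("objective returned a non-finite score")
    return scores


def init_swarm(
    seed_position: np.ndarray,
    config: PSOConfig,
    rng: np.random.Generator,
    f: ObjectiveFn,
) -> Swarm:
    """Swarm initialized at the encoder output.

    The first particle sits exactly at ``seed_position``; the remaining
    swarm_size - 1 particles add isotropic Gaussian jitter (sd
    ``init_jitter_sd``), clipped to [-1, 1].  Velocities start at zero
    and personal/global bests come from the initial evaluation.
    """
    x0 = np.asarray(seed_position, dtype=np.float64).reshape(-1)
    D = x0.shape[0]
    S = config.swarm_size
    positions = np.tile(x0, (S, 1))
    if S > 1 and config.init_jitter_sd > 0:
        positions[1:] += rng.normal(0.0, config.init_jitter_sd,
                                    size=(S - 1, D))
    if config.position_clip:
        np.clip(positions, -1.0, 1.0, out=positions)
    scores = _check_scores(f(positions))
    best = int(np.argmax(scores))
    return Swarm(
        positions=positions,
        velocities=np.zeros((S, D)),
        best_positions=positions.copy(),
        best_scores=scores.copy(),
        global_best_position=positions[best].copy(),
        global_best_score=float(scores[best]),
    )


def pso_step(
    swarm: Swarm,
    config: PSOConfig,
    f: ObjectiveFn,
    rng: np.random.Generator,
    inertia: float | None = None,
) -> Swarm:
    """One velocity/position update followed by re-evaluation (in place).

    Personal bests replace only on strictly greater scores (equal scores
    keep the earlier best, for stability), and likewise the global best.
    """
    w = config.inertia_at(swarm.iteration) if inertia is None else inertia
    S = swarm.positions.shape[0]
    r1 = rng.random((S, 1))
    r2 = rng.random((S, 1))
    v = (
        w * swarm.velocities
        + config.c1 * r1 * (swarm.best_positions - swarm.positions)
        + config.c2 * r2 * (swarm.global_best_position[None, :] - swarm.positions)
    )
    if config.velocity_cap > 0:
        np.clip(v, -config.velocity_cap, config.velocity_cap, out=v)
    x = swarm.positions + v
    if config.position_clip:
        np.clip(x, -1.0, 1.0, out=x)
    swarm.velocities = v
    swarm.positions = x
    scores = _check_scores(f(x))
    improved = scores > swarm.best_scores
    swarm.best_positions[improved] = x[improved]
    swarm.best_scores[improved] = scores[improved]
    best = int(np.argmax(swarm.best_scores))
    if swarm.best_scores[best] > swarm.global_best_score:
        swarm.global_best_score = float(swarm.best_scores[best])
        swarm.global_best_position = swarm.best_positions[best].copy()
    swarm.iteration += 1
    return swarm


def run_pso(
    f: ObjectiveFn,
    seed_position: np.ndarray,
    config: PSOConfig,
    rng: np.random.Generator,
    callback: Callable[[int, Swarm], None] | None = None,
) -> tuple[Swarm, list[float]]:
    """Run one swarm for ``config.iterations`` steps from a seed position.

    Returns the final swarm and the per-iteration trajectory of the
    swarm-best score (non-decreasing by construction).  ``callback`` is
    invoked after each step; this is also the raw-position test hook for
    analytic objectives.
    """
    swarm = init_swarm(seed_position, config, rng, f)
    trajectory = [swarm.global_best_score]
    for k in range(config.iterations):
        pso_step(swarm, config, f, rng)
        trajectory.append(swarm.global_best_score)
        if callback is not None:
            callback(k, swarm)
    return swarm, trajectory


# ---------------------------------------------------------------------------
# Decode-and-score evaluation
# ---------------------------------------------------------------------------

def evaluate_position(
    z: np.ndarray,
    model: Seq2SeqTranslator,
    objectives: Sequence[Objective],
    beam_width: int = 1,
) -> tuple[MoleculeRecord | None, ScoreReport]:
    """Decode one latent position and score the decoded molecule.

    The top-ranked valid beam candidate is canonicalized and scored; a
    position with no valid decode returns (None, report with F = 0)
    rather than raising — syntactically broken decodes are an expected
    feature of arbitrary latent points.
    """
    z = np.asarray(z, dtype=np.float64).reshape(-1)
    if z.shape[0] != model.config.bottleneck_dim:
        raise DimensionError(
            f"latent vector has {z.shape[0]} components, expected "
            f"{model.config.bottleneck_dim}"
        )
    results = model.decode(z, beam_width=beam_width)
    for smiles, _, valid in results:
        if valid:
            record = MoleculeRecord.from_smiles(smiles)
            return record, score_molecule(record, objectives)
    return None, ScoreReport(F=0.0)


class _DecodeScorer:
    """Batched decode-and-score objective with caching.

    Greedy (width-1) decoding runs the whole swarm through the decoder
    in one batch; wider beams fall back to per-particle beam search.
    Scores are cached per canonical SMILES so each unique molecule is
    evaluated once per run.
    """

    def __init__(self, model, objectives, beam_width):
        self.model = model
        self.objectives = objectives
        self.beam_width = beam_width
        self.score_cache: dict[str, ScoreReport] = {}
        self.new_molecules: dict[str, ScoreReport] = {}

    def _canonical(self, raw_smiles: str) -> str | None:
        if not raw_smiles:
            return None
        try:
            return canonicalize(raw_smiles)
        except InvalidSmiles:
            return None

    def _score(self, canon: str) -> ScoreReport:
        report = self.score_cache.get(canon)
        if report is None:
            report = score_molecule(MoleculeRecord.from_smiles(canon),
                                    self.objectives)
            self.score_cache[canon] = report
        return report

    def __call__(self, positions: np.ndarray) -> np.ndarray:
        if self.beam_width == 1:
            raw = self.model.greedy_decode_batch(positions)
        else:
            raw = []
            for z in positions:
                results = self.model.decode(z, beam_width=self.beam_width)
                chosen = next((r[0] for r in results if r[2]),
                              results[0][0] if results else "")
                raw.append(chosen)
        scores = np.zeros(len(raw))
        for i, smi in enumerate(raw):
            canon = self._canonical(smi)
            if canon is None:
                continue
            report = self._score(canon)
            scores[i] = report.F
            if not report.constraint_violated:
                self.new_molecules.setdefault(canon, report)
        return scores


@dataclass
class OptimizedMolecule:
    """One unique optimized molecule with its score report."""

    smiles: str
    report: ScoreReport
    similarity_to_seed: float

    @property
    def F(self) -> float:
        return self.report.F


@dataclass
class OptimizationResult:
    """Ranked unique optimized molecules plus the optimization trace.

    Ranking is final score descending, ties broken by similarity to the
    seed descending, then lexicographic SMILES.  ``trajectory`` has one
    row per (restart, iteration) with the swarm-best score and the mean
    per-objective raw values of that iteration's decoded molecules.
    """

    seed: MoleculeRecord
    seed_report: ScoreReport
    molecules: list[OptimizedMolecule] = field(default_factory=list)
    trajectory: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rank, m in enumerate(self.molecules, start=1):
            row = {"rank": rank, "smiles": m.smiles,
                   "similarity_to_seed": m.similarity_to_seed}
            row.update(m.report.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def optimize(
    seed_smiles: str,
    objectives: Sequence[Objective],
    config: PSOConfig,
    model: Seq2SeqTranslator,
) -> OptimizationResult:
    """Full optimization run: ``restarts`` independent swarms of
    ``iterations`` steps each, seeded at the encoding of ``seed_smiles``.

    Every iteration's newly decoded valid molecules are ranked by final
    score and the top ``top_k`` retained; results are merged across
    restarts and deduplicated by canonical SMILES, keeping each
    molecule's best report.  Fully deterministic for a fixed config seed
    and fixed model weights.
    """
    if len(objectives) == 0:
        raise ValueError("optimize needs at least one objective")
    seed_record = MoleculeRecord.from_smiles(seed_smiles)
    if not seed_record.valid:
        raise InvalidSmiles(f"cannot parse seed SMILES: {seed_smiles!r}")
    seed_report = score_molecule(seed_record, objectives)
    seed_z = model.encode([seed_record.canonical_smiles])[0]

    master = np.random.default_rng(config.seed)
    restart_seeds = master.integers(0, 2**31, size=config.restarts)
    scorer = _DecodeScorer(model, objectives, config.beam_width)
    collected: dict[str, ScoreReport] = {}
    traj_rows: list[dict] = []

    for restart, rseed in enumerate(restart_seeds):
        rng = np.random.default_rng(int(rseed))
        scorer.new_molecules = {}
        swarm = init_swarm(seed_z, config, rng, scorer)
        _collect(collected, scorer.new_molecules, config.top_k)
        _log_row(traj_rows, restart, 0, swarm, scorer.new_molecules, objectives)
        for k in range(config.iterations):
            scorer.new_molecules = {}
            pso_step(swarm, config, scorer, rng)
            _collect(collected, scorer.new_molecules, config.top_k)
            _log_row(traj_rows, restart, k + 1, swarm, scorer.new_molecules,
                     objectives)

    molecules = [
        OptimizedMolecule(
            smiles=smi,
            report=rep,
            similarity_to_seed=tanimoto_similarity(smi, seed_record),
        )
        for smi, rep in collected.items()
    ]
    molecules.sort(key=lambda m: (-m.F, -m.similarity_to_seed, m.smiles))
    return OptimizationResult(
        seed=seed_record,
        seed_report=seed_report,
        molecules=molecules,
        trajectory=pd.DataFrame(traj_rows),
    )


def _collect(collected: dict, new: dict[str, ScoreReport], top_k: int) -> None:
    """Merge this iteration's top-k new molecules into the result pool,
    keeping the best report per canonical SMILES."""
    ranked = sorted(new.items(), key=lambda kv: (-kv[1].F, kv[0]))[:top_k]
    for smi, rep in ranked:
        prev = collected.get(smi)
        if prev is None or rep.F > prev.F:
            collected[smi] = rep


def _log_row(rows, restart, iteration, swarm, new, objectives) -> None:
    row = {
        "restart": restart,
        "iteration": iteration,
        "best_F": swarm.global_best_score,
        "n_new_molecules": len(new),
    }
    if new:
        reports = list(new.values())
        for j, obj in enumerate(objectives):
            vals = [r.raw_values[j] for r in reports if r.raw_values]
            row[f"mean_{obj.name}"] = float(np.mean(vals)) if vals else np.nan
    rows.append(row)
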