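"""The generational loop: selection, elitism, crossover, mutation.

The engine minimises fitness (negative is better).  Selection maps the raw
— typically negative — fitnesses to rank-based weights (weight ∝ 1/√rank),
the conventional companion of stochastic-uniform sampling: sign-safe and
scale-free.  Elites are carried unchanged and, with a deterministic scorer,
not re-scored, which makes the best-fitness trace non-increasing; a config
flag re-scores everyone each generation to mimic a stochastic docking
backend.  Crossover and mutation are independent per-slot probabilities.

Every generation is checkpointed with the RNG state, so a killed run
restarts bit-for-bit identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .fitness_engine import FitnessRecord, PenaltyBreakdown
from .genetic_operators import OperatorConfig, crossover, mutate
from .molgraph import ChromosomeError, MoleculeGraph, parse_smiles, write_smiles

logger = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "GenerationRecord",
    "RunHistory",
    "CheckpointError",
    "select_parents",
    "next_generation",
    "run_ga",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT = "smilesga-checkpoint"
CHECKPOINT_VERSION = 1


@dataclass
class GAConfig:
    """Generational-loop parameters (defaults follow the usual GA-toolbox
    conventions for this method: 100 generations, 10% elitism, both rates
    high at 0.8).

    ``tol_con`` is accepted for config compatibility but inert: constraints
    enter the fitness as penalties, no nonlinear constraint solver is used.
    """

    generations: int = 100
    elite_fraction: float = 0.1
    crossover_rate: float = 0.8
    mutation_rate: float = 0.8
    selection: str = "stochastic_uniform"
    stall_gen_limit: int = 100
    tol_fun: float = 0.02
    tol_con: float = 0.01
    reevaluate_elites: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("elite_fraction", "crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")
        if self.selection not in ("stochastic_uniform", "roulette", "tournament"):
            raise ValueError(f"unknown selection method {self.selection!r}")
        if self.generations < 0 or self.stall_gen_limit < 1:
            raise ValueError("generations must be >= 0 and stall_gen_limit >= 1")


@dataclass(frozen=True)
class GenerationRecord:
    """Snapshot of one generation; ``rng_state`` is the generator state
    *after* this generation was produced and evaluated, i.e. the state with
    which the next generation will be produced (restart anchor)."""

    generation: int
    records: tuple[FitnessRecord, ...]
    best_fitness: float
    mean_fitness: float
    rng_state: dict

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(r.chromosome for r in self.records)


@dataclass
class RunHistory:
    """Ordered generation snapshots plus the run configuration."""

    ga_config: GAConfig
    records: list[GenerationRecord] = field(default_factory=list)
    scorer_identity: str = ""

    @property
    def generations_run(self) -> int:
        return len(self.records)

    def best_trace(self) -> list[float]:
        return [g.best_fitness for g in self.records]

    def mean_trace(self) -> list[float]:
        return [g.mean_fitness for g in self.records]


class CheckpointError(RuntimeError):
    """Corrupt or incompatible checkpoint file."""


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def _rank_weights(fitnesses: Sequence[float]) -> np.ndarray:
    """Rank-based selection weights, 1/sqrt(rank), with tied fitnesses
    sharing the average weight of their rank span (so identical individuals
    are selected equally often)."""
    order = sorted(range(len(fitnesses)), key=lambda i: fitnesses[i])
    raw = 1.0 / np.sqrt(np.arange(1, len(fitnesses) + 1))
    weights = np.empty(len(fitnesses))
    pos = 0
    while pos < len(order):
        end = pos
        while end < len(order) and fitnesses[order[end]] == fitnesses[order[pos]]:
            end += 1
        shared = raw[pos:end].mean()
        for idx in order[pos:end]:
            weights[idx] = shared
        pos = end
    return weights


def select_parents(
    fitnesses: Sequence[float],
    n: int,
    method: str,
    rng: np.random.Generator,
) -> list[int]:
    """Select ``n`` parent indices from an evaluated population.

    stochastic_uniform lays the rank weights on a line and samples with one
    uniform start and equal steps; roulette draws independently from the
    same weights; tournament plays k=2 fitness duels.  A population where
    every fitness is the failure sentinel 0 falls back to uniform random
    selection with a warning.
    """
    if n == 0:
        return []
    if not fitnesses:
        raise ValueError("cannot select from an empty population")
    m = len(fitnesses)
    if all(f == 0.0 for f in fitnesses):
        logger.warning("all-failure population: falling back to uniform selection")
        return [int(i) for i in rng.integers(0, m, size=n)]

    if method == "tournament":
        out = []
        for _ in range(n):
            a, b = int(rng.integers(0, m)), int(rng.integers(0, m))
            out.append(a if fitnesses[a] <= fitnesses[b] else b)
        return out

    weights = _rank_weights(fitnesses)
    probs = weights / weights.sum()
    if method == "roulette":
        return [int(i) for i in rng.choice(m, size=n, p=probs)]
    if method == "stochastic_uniform":
        cum = np.cumsum(weights)
        total = cum[-1]
        step = total / n
        start = rng.uniform(0.0, step)
        pointers = start + step * np.arange(n)
        picks = np.searchsorted(cum, pointers, side="right")
        picks = np.minimum(picks, m - 1)
        out = [int(i) for i in picks]
        rng.shuffle(out)
        return out
    raise ValueError(f"unknown selection method {method!r}")


# ---------------------------------------------------------------------------
# Generation step
# ---------------------------------------------------------------------------

EvalFn = Callable[[Sequence[str]], list[FitnessRecord]]


def next_generation(
    population: Sequence[FitnessRecord],
    operator_config: OperatorConfig,
    evaluate: EvalFn,
    ga_config: GAConfig,
    rng: np.random.Generator,
) -> list[FitnessRecord]:
    """Produce and evaluate the next population of the same size.

    The elite (best ``round(elite_fraction x size)``) is copied unchanged;
    every remaining slot is filled from two selected parents with the
    crossover-then-mutation pipeline applied at the configured independent
    rates.
    """
    size = len(population)
    n_elite = int(round(ga_config.elite_fraction * size))
    order = sorted(range(size), key=lambda i: population[i].fitness)
    elites = [population[i] for i in order[:n_elite]]

    fitnesses = [r.fitness for r in population]
    cache: dict[str, Optional[MoleculeGraph]] = {}

    def parsed(text: str) -> Optional[MoleculeGraph]:
        if text not in cache:
            try:
                cache[text] = parse_smiles(text, operator_config.molecular)
            except ChromosomeError:
                cache[text] = None
        return cache[text]

    children: list[str] = []
    for _slot in range(size - n_elite):
        ia, ib = select_parents(fitnesses, 2, ga_config.selection, rng)
        ga, gb = parsed(population[ia].chromosome), parsed(population[ib].chromosome)
        child: Optional[MoleculeGraph] = ga
        if rng.uniform() < ga_config.crossover_rate and ga is not None and gb is not None:
            child = crossover(ga, gb, operator_config, rng)[0]
        if rng.uniform() < ga_config.mutation_rate and child is not None:
            child = mutate(child, operator_config, rng)
        children.append(
            write_smiles(child) if child is not None else population[ia].chromosome
        )

    evaluated = evaluate(children)
    new_pop = elites + evaluated
    if ga_config.reevaluate_elites:
        new_pop = evaluate([r.chromosome for r in new_pop])
    assert len(new_pop) == size
    return new_pop


# ---------------------------------------------------------------------------
# Run loop with checkpointing
# ---------------------------------------------------------------------------


def _snapshot(generation: int, records: Sequence[FitnessRecord], rng) -> GenerationRecord:
    fitnesses = [r.fitness for r in records]
    return GenerationRecord(
        generation=generation,
        records=tuple(records),
        best_fitness=min(fitnesses),
        mean_fitness=float(np.mean(fitnesses)),
        rng_state=rng.bit_generator.state,
    )


def run_ga(
    initial_population: Sequence[str] | str | Path,
    operator_config: OperatorConfig,
    ga_config: GAConfig,
    evaluate: EvalFn,
    checkpoint_path: Optional[str | Path] = None,
    resume_from: Optional[RunHistory] = None,
    scorer_identity: str = "",
) -> RunHistory:
    """Run the full generational loop.

    ``initial_population`` is a list of SMILES chromosomes or a path to a
    one-SMILES-per-line file (``#`` comments allowed).  The loop stops when
    ``generations`` are exhausted or the best fitness has improved by less
    than ``tol_fun`` over ``stall_gen_limit`` consecutive generations.  A
    checkpoint (including RNG state) is written every generation when
    ``checkpoint_path`` is given; ``resume_from`` continues a loaded history
    identically to the uninterrupted run.
    """
    if resume_from is not None:
        history = resume_from
        if not history.records:
            raise ValueError("cannot resume from an empty history")
        rng = np.random.default_rng()
        rng.bit_generator.state = history.records[-1].rng_state
        population = list(history.records[-1].records)
        start_gen = history.records[-1].generation + 1
        ga_config = history.ga_config
    else:
        if isinstance(initial_population, (str, Path)):
            lines = Path(initial_population).read_text().splitlines()
            chromosomes = [
                ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")
            ]
        else:
            chromosomes = list(initial_population)
        if not chromosomes:
            raise ValueError("initial population is empty")
        rng = np.random.default_rng(ga_config.seed)
        population = evaluate(chromosomes)
        history = RunHistory(ga_config=ga_config, scorer_identity=scorer_identity)
        history.records.append(_snapshot(0, population, rng))
        start_gen = 1
        if checkpoint_path is not None:
            save_checkpoint(history, checkpoint_path)

    best_so_far = min(g.best_fitness for g in history.records)
    last_improvement = max(
        (g.generation for g in history.records
         if g.best_fitness <= best_so_far),
        default=0,
    )

    for gen in range(start_gen, ga_config.generations + 1):
        population = next_generation(
            population, operator_config, evaluate, ga_config, rng
        )
        snap = _snapshot(gen, population, rng)
        history.records.append(snap)
        logger.info(
            "generation %d: best %.4f mean %.4f",
            gen, snap.best_fitness, snap.mean_fitness,
        )
        if snap.best_fitness < best_so_far - ga_config.tol_fun:
            best_so_far = snap.best_fitness
            last_improvement = gen
        if checkpoint_path is not None:
            save_checkpoint(history, checkpoint_path)
        if gen - last_improvement >= ga_config.stall_gen_limit:
            logger.info("stall limit reached at generation %d", gen)
            break
    return history


# ---------------------------------------------------------------------------
# Checkpoint serialisation (versioned JSON)
# ---------------------------------------------------------------------------


def _record_to_dict(r: FitnessRecord) -> dict:
    return {
        "chromosome": r.chromosome,
        "fitness": r.fitness,
        "failure": r.failure,
        "best_stereoisomer": r.best_stereoisomer,
        "best_score": r.best_score,
        "penalties": dataclasses.asdict(r.penalties),
        "failure_reason": r.failure_reason,
    }


def _record_from_dict(d: dict) -> FitnessRecord:
    return FitnessRecord(
        chromosome=d["chromosome"],
        fitness=d["fitness"],
        failure=d["failure"],
        best_stereoisomer=d["best_stereoisomer"],
        best_score=d["best_score"],
        penalties=PenaltyBreakdown(**d["penalties"]),
        failure_reason=d.get("failure_reason", ""),
    )


def _jsonify_state(state) -> dict:
    def conv(x):
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, np.ndarray):
            return {"__ndarray__": x.tolist(), "dtype": str(x.dtype)}
        if isinstance(x, (np.integer,)):
            return int(x)
        return x

    return conv(state)


def _restore_state(state) -> dict:
    def conv(x):
        if isinstance(x, dict):
            if "__ndarray__" in x:
                return np.array(x["__ndarray__"], dtype=x["dtype"])
            return {k: conv(v) for k, v in x.items()}
        return x

    return conv(state)


def save_checkpoint(history: RunHistory, path: str | Path) -> None:
    """Write a versioned, lossless JSON checkpoint (atomic replace)."""
    payload = {
        "format": CHECKPOINT_FORMAT,
        "version": CHECKPOINT_VERSION,
        "ga_config": dataclasses.asdict(history.ga_config),
        "scorer_identity": history.scorer_identity,
        "generations": [
            {
                "generation": g.generation,
                "records": [_record_to_dict(r) for r in g.records],
                "best_fitness": g.best_fitness,
                "mean_fitness": g.mean_fitness,
                "rng_state": _jsonify_state(g.rng_state),
            }
            for g in history.records
        ],
    }
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(payload, sort_keys=True))
    tmp.replace(path)


def load_checkpoint(path: str | Path) -> RunHistory:
    """Load a checkpoint; truncated files or version mismatches raise
    :class:`CheckpointError` (never silently reinterpreted)."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise CheckpointError(f"corrupt checkpoint {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != CHECKPOINT_FORMAT:
        raise CheckpointError(f"{path} is not a {CHECKPOINT_FORMAT} file")
    if payload.get("version") != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"checkpoint version {payload.get('version')} != supported {CHECKPOINT_VERSION}"
        )
    try:
        history = RunHistory(
            ga_config=GAConfig(**payload["ga_config"]),
            scorer_identity=payload.get("scorer_identity", ""),
        )
        for g in payload["generations"]:
            history.records.append(
                GenerationRecord(
                    generation=g["generation"],
                    records=tuple(_record_from_dict(r) for r in g["records"]),
                    best_fitness=g["best_fitness"],
                    mean_fitness=g["mean_fitness"],
                    rng_state=_restore_state(g["rng_state"]),
                )
            )
    except (KeyError, TypeError) as exc:
        raise CheckpointError(f"corrupt checkpoint {path}: {exc}") from exc
    return history
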