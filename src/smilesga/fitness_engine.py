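"""Fitness evaluation: stereo expansion, pluggable scoring, penalties.

A chromosome's fitness is ``-(best pose score over its stereoisomers) +
(sum of penalties)``; *negative is better* because the GA minimises, and a
chromosome that cannot be parsed or scored at all receives the failure
sentinel fitness 0 exactly (it is eventually ejected by selection).  Note
the documented sharp edge: the sentinel 0 can be *better* than a valid
positive fitness when penalties exceed the score; this is kept as-is, with
no clamping.

Scoring is a contract (:class:`ScorerContract`): the shipped backends are a
deterministic surrogate binding site (:class:`SyntheticSiteScorer`) and a
file-based replay scorer; an external docking engine plugs in behind the
same contract and is out of scope here.
"""

from __future__ import annotations

import logging
import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence

import networkx as nx
from networkx.algorithms import isomorphism

from .molgraph import (
    ChromosomeError,
    DEFAULT_MOLECULAR_CONFIG,
    MolecularConfig,
    MoleculeGraph,
    PropertyProfile,
    StereoAssignment,
    ATOMIC_MASSES,
    canonical_key,
    compute_properties,
    enumerate_stereoisomers,
    parse_smiles,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ADMEConfig",
    "InteractionReport",
    "ScoreResult",
    "ScorerContract",
    "SyntheticSiteScorer",
    "ReplayScorer",
    "ForbiddenPattern",
    "ConstraintConfig",
    "PenaltyBreakdown",
    "FitnessRecord",
    "lipinski_penalty",
    "substructure_penalty",
    "hbond_requirement_penalty",
    "localization_penalty",
    "evaluate_fitness",
]

PROFILE_KEYS = ("heavy_atoms", "hbd", "hba", "n_rings", "rotatable_dihedrals")


@dataclass(frozen=True)
class ADMEConfig:
    """Rule-of-5 style limits and penalty coefficients.

    ``mode``: "None" (no ADME term), "SoftLipinski" (penalty proportional to
    the violation) or "HardLipinski" (flat penalty per violated rule).  In
    soft mode the default penalty is *relative*: coefficient x
    max(0, (x - limit)/limit), keeping penalties commensurate with scores of
    order 10-100; set ``relative_soft=False`` for the raw (x - limit) x
    coefficient form.  The log K_ow rule only applies when a profile carries
    a user-supplied value.
    """

    mode: str = "None"
    max_mass: float = 500.0
    max_donor: int = 5
    max_acceptor: int = 10
    max_rotatable_dihedrals: int = 7
    max_log_kow: float = 5.0
    penalty_mass: float = 4.0
    penalty_donor: float = 10.0
    penalty_acceptor: float = 10.0
    penalty_dihedrals: float = 10.0
    penalty_log_kow: float = 10.0
    hard_violation_penalty: float = 20.0
    relative_soft: bool = True

    def __post_init__(self):
        if self.mode not in ("None", "SoftLipinski", "HardLipinski"):
            raise ValueError(f"unknown ADME mode {self.mode!r}")
        for name in ("max_mass", "max_donor", "max_acceptor",
                     "max_rotatable_dihedrals", "max_log_kow"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("penalty_mass", "penalty_donor", "penalty_acceptor",
                     "penalty_dihedrals", "penalty_log_kow", "hard_violation_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class InteractionReport:
    """Scorer-supplied interaction details for one scored pose.

    ``hydrogen_bonds`` pairs an opaque residue label (matched exactly
    against constraint specs) with the ligand atom index involved;
    ``pose_coordinates`` (per heavy atom, Å) and ``contacts`` are optional.
    """

    hydrogen_bonds: tuple[tuple[str, int], ...] = ()
    pose_coordinates: Optional[tuple[tuple[float, float, float], ...]] = None
    contacts: tuple[str, ...] = ()


@dataclass(frozen=True)
class ScoreResult:
    """Outcome of scoring one stereoisomer: ``score`` is None when the
    scorer found no pose (distinct from a pose of score 0)."""

    score: Optional[float]
    report: InteractionReport = field(default_factory=InteractionReport)


class ScorerContract(Protocol):
    """Binding-site scoring backend: higher score = stronger predicted
    binding; ``deterministic`` tells the GA whether elite re-scoring and the
    monotone-best assertion are meaningful."""

    identity: str
    deterministic: bool

    def score(
        self,
        graph: MoleculeGraph,
        stereo: StereoAssignment,
        profile: PropertyProfile,
    ) -> ScoreResult: ...


@dataclass
class SyntheticSiteScorer:
    """Deterministic surrogate binding site.

    Scores a molecule by how closely its property profile matches a target
    profile ``t`` over (heavy_atoms, hbd, hba, n_rings,
    rotatable_dihedrals): ``score = max(0, s_max - sum_i w_i |p_i - t_i|)``.
    A stand-in for a docking engine that makes the whole GA loop exercisable
    and exactly reproducible.  ``report_residues`` lists residue labels the
    scorer reports as hydrogen-bonded whenever the ligand has at least one
    donor or acceptor (synthetic interaction records for constraint hooks).
    """

    target: dict[str, float]
    weights: dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in PROFILE_KEYS}
    )
    s_max: float = 100.0
    identity: str = "synthetic-site"
    deterministic: bool = True
    report_residues: tuple[str, ...] = ()

    def __post_init__(self):
        if self.s_max <= 0:
            raise ValueError("s_max must be positive")
        unknown = set(self.target) - set(PROFILE_KEYS)
        unknown |= set(self.weights) - set(PROFILE_KEYS)
        if unknown:
            raise ValueError(f"unknown profile keys {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")

    def score(
        self,
        graph: MoleculeGraph,
        stereo: StereoAssignment,
        profile: PropertyProfile,
    ) -> ScoreResult:
        dist = sum(
            self.weights.get(k, 0.0) * abs(getattr(profile, k) - t)
            for k, t in self.target.items()
        )
        hbonds: tuple[tuple[str, int], ...] = ()
        if self.report_residues and (profile.hbd + profile.hba) > 0:
            atom = next(
                (i for i, el in enumerate(graph.elements) if el in ("N", "O")), 0
            )
            hbonds = tuple((res, atom) for res in self.report_residues)
        return ScoreResult(
            score=max(0.0, self.s_max - dist),
            report=InteractionReport(hydrogen_bonds=hbonds),
        )


class ReplayScorer:
    """Replays precomputed scores from a TSV of
    ``canonical key <tab> stereoisomer index <tab> score``.

    Missing entries are reported as scoring failures (no pose found).
    Used for integration tests and for re-examining external docking runs.
    """

    def __init__(self, table: dict[tuple[str, int], float], identity: str = "replay"):
        self.table = dict(table)
        self.identity = identity
        self.deterministic = True

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReplayScorer":
        table: dict[tuple[str, int], float] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            table[(parts[0], int(parts[1]))] = float(parts[2])
        return cls(table, identity=f"replay:{path}")

    def score(
        self,
        graph: MoleculeGraph,
        stereo: StereoAssignment,
        profile: PropertyProfile,
    ) -> ScoreResult:
        key = canonical_key(graph)
        val = self.table.get((key, stereo.index))
        return ScoreResult(score=val)


# ---------------------------------------------------------------------------
# Penalties
# ---------------------------------------------------------------------------


def lipinski_penalty(profile: PropertyProfile, config: ADMEConfig) -> float:
    """ADME penalty for one property profile under the configured mode.

    Rules checked: molecular mass, H-bond donors, acceptors, rotatable
    dihedrals, and — only when the profile carries one — log K_ow.
    """
    if config.mode == "None":
        return 0.0
    rules = [
        (profile.molecular_mass, config.max_mass, config.penalty_mass),
        (profile.hbd, config.max_donor, config.penalty_donor),
        (profile.hba, config.max_acceptor, config.penalty_acceptor),
        (profile.rotatable_dihedrals, config.max_rotatable_dihedrals,
         config.penalty_dihedrals),
    ]
    if profile.log_kow is not None:
        rules.append((profile.log_kow, config.max_log_kow, config.penalty_log_kow))

    if config.mode == "HardLipinski":
        return config.hard_violation_penalty * sum(1 for x, lim, _ in rules if x > lim)
    total = 0.0
    for x, lim, coeff in rules:
        excess = max(0.0, x - lim)
        total += coeff * (excess / lim if config.relative_soft else excess)
    return total


@dataclass(frozen=True)
class ForbiddenPattern:
    """A forbidden substructure given as a SMILES-like pattern string.

    ``terminal_atoms`` lists pattern atom indices (parse order) that must
    map onto branch end-points of the molecule (heavy-degree 1); patterns
    without the flag match anywhere.
    """

    smiles: str
    terminal_atoms: tuple[int, ...] = ()
    name: str = ""


# Hydrolytically unstable motifs used as the default forbidden set: enol
# ether C=C-O-C, thioenolate C=C-S at a branch end, and the acetal-like
# O-C-O.
DEFAULT_FORBIDDEN = (
    ForbiddenPattern("C=COC", name="enol_ether"),
    ForbiddenPattern("C=CS", terminal_atoms=(2,), name="thioenolate"),
    ForbiddenPattern("OCO", name="acetal_OCO"),
)


def _pattern_matches(graph: MoleculeGraph, pattern: ForbiddenPattern) -> int:
    pat = parse_smiles(pattern.smiles, graph.config)
    gm = isomorphism.GraphMatcher(
        graph.to_networkx(),
        pat.to_networkx(),
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    seen: set[frozenset] = set()
    for mapping in gm.subgraph_monomorphisms_iter():
        inv = {p: m for m, p in mapping.items()}
        if any(graph.heavy_degree(inv[t]) != 1 for t in pattern.terminal_atoms):
            continue
        edges = frozenset(
            frozenset((inv[a], inv[b])) for a, b in pat.to_networkx().edges()
        )
        seen.add(edges)
    return len(seen)


def substructure_penalty(
    graph: MoleculeGraph,
    patterns: Sequence[ForbiddenPattern],
    per_match_penalty: float,
) -> float:
    """``per_match_penalty`` x (number of distinct forbidden-substructure
    embeddings, counted by bond set so pattern automorphisms do not double
    count)."""
    return per_match_penalty * sum(_pattern_matches(graph, p) for p in patterns)


def hbond_requirement_penalty(
    report: InteractionReport,
    required_residues: Sequence[str],
    penalty_each: float,
) -> float:
    """Penalty for every required residue with no hydrogen-bond record; an
    empty report counts as zero hydrogen bonds."""
    bonded = {res for res, _atom in report.hydrogen_bonds}
    return penalty_each * sum(1 for r in required_residues if r not in bonded)


def localization_penalty(
    report: InteractionReport,
    anchors: Sequence[tuple[float, float, float]],
    radius: float,
    penalty: float,
) -> float:
    """Penalty unless every anchor point has some ligand heavy atom within
    ``radius`` Å (all-anchors-covered semantics).  Inactive (0, with a
    logged warning) when the report carries no pose coordinates."""
    if not anchors:
        return 0.0
    if report.pose_coordinates is None:
        logger.warning("localization constraint inactive: no pose coordinates in report")
        return 0.0
    for ax, ay, az in anchors:
        if not any(
            math.dist((ax, ay, az), xyz) <= radius for xyz in report.pose_coordinates
        ):
            return penalty
    return 0.0


@dataclass
class ConstraintConfig:
    """Constraint hooks applied on top of the ADME term."""

    forbidden: tuple[ForbiddenPattern, ...] = ()
    substructure_penalty_each: float = 20.0
    required_hbond_residues: tuple[str, ...] = ()
    hbond_penalty_each: float = 20.0
    localization_anchors: tuple[tuple[float, float, float], ...] = ()
    localization_radius: float = 5.0
    localization_penalty_value: float = 20.0


@dataclass(frozen=True)
class PenaltyBreakdown:
    adme: float = 0.0
    substructure: float = 0.0
    hbond_requirement: float = 0.0
    localization: float = 0.0

    @property
    def total(self) -> float:
        return self.adme + self.substructure + self.hbond_requirement + self.localization


@dataclass(frozen=True)
class FitnessRecord:
    """Evaluated chromosome.

    ``failure`` implies ``fitness == 0.0`` exactly; otherwise
    ``fitness == -best_score + penalties.total``.
    """

    chromosome: str
    fitness: float
    failure: bool = False
    best_stereoisomer: Optional[int] = None
    best_score: Optional[float] = None
    penalties: PenaltyBreakdown = field(default_factory=PenaltyBreakdown)
    failure_reason: str = ""


def _write_work_products(
    ligand_dir: Path,
    mol_idx: int,
    chromosome: str,
    results: list[ScoreResult],
) -> None:
    mol_dir = ligand_dir / f"mol_{mol_idx:03d}"
    mol_dir.mkdir(parents=True, exist_ok=True)
    (mol_dir / "chromosome.smi").write_text(chromosome + "\n")
    for s_idx, res in enumerate(results):
        sdir = mol_dir / f"stereo_{s_idx:03d}"
        sdir.mkdir(exist_ok=True)
        (sdir / "score.txt").write_text(
            "FAILED\n" if res.score is None else f"{res.score:.6f}\n"
        )
        lines = [f"{res_label}\t{atom}" for res_label, atom in res.report.hydrogen_bonds]
        (sdir / "hbonds.txt").write_text("\n".join(lines) + ("\n" if lines else ""))


def evaluate_fitness(
    chromosomes: Sequence[str],
    scorer: ScorerContract,
    molecular_config: MolecularConfig = DEFAULT_MOLECULAR_CONFIG,
    adme_config: Optional[ADMEConfig] = None,
    constraints: Optional[ConstraintConfig] = None,
    max_stereoisomers: Optional[int] = None,
    masses: Optional[dict[str, float]] = None,
    log_kow: Optional[dict[str, float]] = None,
    ligand_dir: Optional[str | Path] = None,
) -> list[FitnessRecord]:
    """Evaluate a batch of SMILES chromosomes.

    Per chromosome: parse -> enumerate stereoisomers (up to the cap) ->
    score each -> best score -> fitness = -best + penalties.  Individual
    parse or scoring failures yield a sentinel record (fitness 0) and never
    abort the batch.  ``log_kow`` optionally maps chromosome text to a
    user-supplied partition coefficient.  When ``ligand_dir`` is given, a
    per-molecule directory tree with per-stereoisomer subdirectories is
    deleted and recreated on each call.
    """
    adme = adme_config or ADMEConfig()
    cap = max_stereoisomers or molecular_config.max_stereoisomers
    work_dir: Optional[Path] = None
    if ligand_dir is not None:
        work_dir = Path(ligand_dir)
        if work_dir.exists():
            for old in sorted(work_dir.glob("mol_*")):
                shutil.rmtree(old)
        work_dir.mkdir(parents=True, exist_ok=True)

    records: list[FitnessRecord] = []
    for m_idx, text in enumerate(chromosomes):
        try:
            graph = parse_smiles(text, molecular_config)
        except ChromosomeError as exc:
            records.append(
                FitnessRecord(text, 0.0, failure=True, failure_reason=str(exc))
            )
            continue

        kow = log_kow.get(text) if log_kow else None
        profile = compute_properties(graph, masses=masses, log_kow=kow)
        stereo_list = enumerate_stereoisomers(graph, cap=cap)
        results: list[ScoreResult] = []
        for stereo in stereo_list:
            try:
                results.append(scorer.score(graph, stereo, profile))
            except Exception as exc:  # scorer crash == no pose, keep going
                logger.warning("scorer %s failed on %s: %s", scorer.identity, text, exc)
                results.append(ScoreResult(score=None))

        if work_dir is not None:
            _write_work_products(work_dir, m_idx, text, results)

        scored = [(r.score, k) for k, r in enumerate(results) if r.score is not None]
        if not scored:
            records.append(
                FitnessRecord(text, 0.0, failure=True, failure_reason="no pose found")
            )
            continue
        best_score, best_idx = max(scored)
        best_report = results[best_idx].report

        cons = constraints or ConstraintConfig()
        breakdown = PenaltyBreakdown(
            adme=lipinski_penalty(profile, adme),
            substructure=substructure_penalty(
                graph, cons.forbidden, cons.substructure_penalty_each
            ),
            hbond_requirement=hbond_requirement_penalty(
                best_report, cons.required_hbond_residues, cons.hbond_penalty_each
            ),
            localization=localization_penalty(
                best_report,
                cons.localization_anchors,
                cons.localization_radius,
                cons.localization_penalty_value,
            ),
        )
        records.append(
            FitnessRecord(
                chromosome=text,
                fitness=-best_score + breakdown.total,
                best_stereoisomer=best_idx,
                best_score=best_score,
                penalties=breakdown,
            )
        )
    return records
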