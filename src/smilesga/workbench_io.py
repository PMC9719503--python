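"""Run configuration, population files, and post-processing reports.

The run configuration is a YAML file with five optional blocks — paths,
ga, molecular, adme, scorer, constraints — every parameter defaulted to
the method's standard values when omitted.  Unknown keys are rejected and
all problems in a file are reported at once.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import yaml

from .fitness_engine import (
    ADMEConfig,
    ConstraintConfig,
    FitnessRecord,
    ForbiddenPattern,
    ReplayScorer,
    ScorerContract,
    SyntheticSiteScorer,
    PROFILE_KEYS,
)
from .ga_engine import GAConfig, RunHistory
from .genetic_operators import (
    DEFAULT_INTER_BOND_DISTANCE,
    MutationKind,
    OperatorConfig,
)
from .molgraph import (
    ATOMIC_MASSES,
    ChromosomeError,
    MolecularConfig,
    compute_properties,
    canonical_key,
    parse_smiles,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "dump_config",
    "build_scorer",
    "load_population",
    "generate_report",
    "write_report",
    "save_fitness_plot",
]


class ConfigError(ValueError):
    """Invalid run configuration; message lists every problem found."""


@dataclass
class RunConfig:
    """Fully-defaulted, validated configuration set for one run."""

    ligand_dir: Optional[str] = None
    initial_population: Optional[str] = None
    checkpoint_out: Optional[str] = None
    ga: GAConfig = field(default_factory=GAConfig)
    operators: OperatorConfig = field(default_factory=OperatorConfig)
    adme: ADMEConfig = field(default_factory=ADMEConfig)
    constraints: ConstraintConfig = field(default_factory=ConstraintConfig)
    masses: dict[str, float] = field(default_factory=lambda: dict(ATOMIC_MASSES))
    scorer_descriptor: Optional[dict] = None

    @property
    def molecular(self) -> MolecularConfig:
        return self.operators.molecular


_TOP_KEYS = {"paths", "ga", "molecular", "adme", "scorer", "constraints"}
_PATH_KEYS = {"ligand_dir", "initial_population", "checkpoint_out"}
_GA_KEYS = {
    "generations", "elite_fraction", "crossover_rate", "mutation_rate",
    "selection", "stall_gen_limit", "tol_fun", "tol_con",
    "reevaluate_elites", "seed",
}
_MOL_KEYS = {
    "atom_type", "atom_val", "unnorm_percent_atom", "unnorm_mut_probability",
    "max_tries", "min_heavy_atoms", "cutoff_bond_percentage",
    "inter_bond_distance", "max_stereoisomers",
}
_ADME_KEYS = {
    "ADME_Penalty_Type", "max_mass_ADME", "max_donor_ADME", "max_acceptor_ADME",
    "max_rotatable_dihedrals", "max_log_kow", "penalty_mass", "penalty_donor",
    "penalty_acceptor", "penalty_dihedrals", "penalty_log_kow",
    "hard_violation_penalty", "atomic_daltons", "relative_soft",
}
_SCORER_KEYS = {"type", "target", "weights", "s_max", "report_residues", "table",
                "command", "receptor_conf", "parameters"}
_CONSTRAINT_KEYS = {
    "forbidden_substructures", "substructure_penalty",
    "required_hbond_residues", "hbond_penalty", "localization",
}


def _check_unknown(block: dict, allowed: set, where: str, problems: list[str]) -> None:
    for key in block:
        if key not in allowed:
            problems.append(f"{where}: unknown key {key!r}")


def load_config(path: str | Path | None = None, data: Optional[dict] = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Either ``path`` or an already-parsed ``data`` dict may be given; an
    empty file yields all defaults.  Raises :class:`ConfigError` listing
    *all* problems at once.
    """
    if data is None:
        raw = Path(path).read_text() if path is not None else ""
        data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigError("top level of the config must be a mapping")

    problems: list[str] = []
    _check_unknown(data, _TOP_KEYS, "config", problems)

    paths = data.get("paths") or {}
    _check_unknown(paths, _PATH_KEYS, "paths", problems)

    ga_block = dict(data.get("ga") or {})
    _check_unknown(ga_block, _GA_KEYS, "ga", problems)
    ga = GAConfig()
    try:
        ga = GAConfig(**{k: v for k, v in ga_block.items() if k in _GA_KEYS})
    except (TypeError, ValueError) as exc:
        problems.append(f"ga: {exc}")

    mol_block = dict(data.get("molecular") or {})
    _check_unknown(mol_block, _MOL_KEYS, "molecular", problems)
    operators = OperatorConfig()
    try:
        operators = _build_operator_config(mol_block, problems)
    except (TypeError, ValueError) as exc:
        problems.append(f"molecular: {exc}")

    adme_block = dict(data.get("adme") or {})
    _check_unknown(adme_block, _ADME_KEYS, "adme", problems)
    masses = dict(ATOMIC_MASSES)
    if "atomic_daltons" in adme_block:
        table = adme_block.pop("atomic_daltons")
        if not isinstance(table, dict):
            problems.append("adme.atomic_daltons: must be a mapping element -> Daltons")
        else:
            masses.update({str(k): float(v) for k, v in table.items()})
    rename = {
        "ADME_Penalty_Type": "mode",
        "max_mass_ADME": "max_mass",
        "max_donor_ADME": "max_donor",
        "max_acceptor_ADME": "max_acceptor",
    }
    adme = ADMEConfig()
    try:
        adme = ADMEConfig(**{rename.get(k, k): v for k, v in adme_block.items()})
    except (TypeError, ValueError) as exc:
        problems.append(f"adme: {exc}")

    scorer_block = data.get("scorer")
    if scorer_block is not None:
        if not isinstance(scorer_block, dict):
            problems.append("scorer: must be a mapping")
            scorer_block = None
        else:
            _check_unknown(scorer_block, _SCORER_KEYS, "scorer", problems)
            if scorer_block.get("type") not in ("synthetic", "replay", "external"):
                problems.append(
                    "scorer.type must be one of synthetic | replay | external"
                )

    cons_block = dict(data.get("constraints") or {})
    _check_unknown(cons_block, _CONSTRAINT_KEYS, "constraints", problems)
    constraints = ConstraintConfig()
    try:
        constraints = _build_constraints(cons_block)
    except (TypeError, ValueError, KeyError) as exc:
        problems.append(f"constraints: {exc}")

    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))

    return RunConfig(
        ligand_dir=paths.get("ligand_dir"),
        initial_population=paths.get("initial_population"),
        checkpoint_out=paths.get("checkpoint_out"),
        ga=ga,
        operators=operators,
        adme=adme,
        constraints=constraints,
        masses=masses,
        scorer_descriptor=dict(scorer_block) if scorer_block else None,
    )


def _build_operator_config(block: dict, problems: list[str]) -> OperatorConfig:
    molecular = MolecularConfig()
    if "atom_type" in block or "atom_val" in block:
        types = tuple(block.get("atom_type", "CNOPSF"))
        vals = block.get("atom_val", [4, 3, 2, 3, 2, 1])
        if len(types) != len(vals):
            raise ValueError("atom_type and atom_val lengths differ")
        valences = {t: int(v) for t, v in zip(types, vals)}
        input_val = {t: (v,) for t, v in valences.items()}
        if "S" in input_val:
            input_val["S"] = tuple(sorted({valences["S"], 4, 6}))
        molecular = MolecularConfig(
            atom_types=types,
            atom_valences=valences,
            input_valences=input_val,
            max_stereoisomers=int(block.get("max_stereoisomers", 512)),
        )
    elif "max_stereoisomers" in block:
        molecular = MolecularConfig(max_stereoisomers=int(block["max_stereoisomers"]))

    mut_weights = {kind: 1.0 for kind in MutationKind}
    for name, w in (block.get("unnorm_mut_probability") or {}).items():
        try:
            mut_weights[MutationKind(name)] = float(w)
        except ValueError:
            problems.append(f"molecular.unnorm_mut_probability: unknown mutation {name!r}")

    atom_weights = {el: 1.0 for el in molecular.atom_types}
    pa = block.get("unnorm_percent_atom")
    if isinstance(pa, dict):
        for el, w in pa.items():
            if el not in atom_weights:
                problems.append(f"molecular.unnorm_percent_atom: unknown element {el!r}")
            else:
                atom_weights[el] = float(w)
    elif isinstance(pa, (list, tuple)):
        if len(pa) != len(molecular.atom_types):
            raise ValueError("unnorm_percent_atom list length != alphabet size")
        atom_weights = {el: float(w) for el, w in zip(molecular.atom_types, pa)}

    distances = dict(DEFAULT_INTER_BOND_DISTANCE)
    for pair, d in (block.get("inter_bond_distance") or {}).items():
        if len(pair) != 2:
            problems.append(f"molecular.inter_bond_distance: bad pair key {pair!r}")
        else:
            distances[frozenset(pair)] = float(d)

    return OperatorConfig(
        molecular=molecular,
        unnorm_mut_probability=mut_weights,
        unnorm_percent_atom=atom_weights,
        max_tries=int(block.get("max_tries", 20)),
        min_heavy_atoms=int(block.get("min_heavy_atoms", 10)),
        cutoff_bond_percentage=float(block.get("cutoff_bond_percentage", 1.10)),
        inter_bond_distance=distances,
    )


def _build_constraints(block: dict) -> ConstraintConfig:
    forbidden = []
    for item in block.get("forbidden_substructures") or []:
        if isinstance(item, str):
            forbidden.append(ForbiddenPattern(item))
        else:
            forbidden.append(
                ForbiddenPattern(
                    smiles=item["smiles"],
                    terminal_atoms=tuple(item.get("terminal_atoms", ())),
                    name=item.get("name", ""),
                )
            )
    loc = block.get("localization") or {}
    return ConstraintConfig(
        forbidden=tuple(forbidden),
        substructure_penalty_each=float(block.get("substructure_penalty", 20.0)),
        required_hbond_residues=tuple(block.get("required_hbond_residues") or ()),
        hbond_penalty_each=float(block.get("hbond_penalty", 20.0)),
        localization_anchors=tuple(tuple(a) for a in loc.get("anchors", ())),
        localization_radius=float(loc.get("radius", 5.0)),
        localization_penalty_value=float(loc.get("penalty", 20.0)),
    )


def dump_config(config: RunConfig) -> dict:
    """Normalised, fully-defaulted dict form of a RunConfig (the round-trip
    companion of :func:`load_config`)."""
    return {
        "paths": {
            "ligand_dir": config.ligand_dir,
            "initial_population": config.initial_population,
            "checkpoint_out": config.checkpoint_out,
        },
        "ga": dataclasses.asdict(config.ga),
        "molecular": {
            "atom_type": "".join(config.molecular.atom_types),
            "atom_val": [config.molecular.atom_valences[t] for t in config.molecular.atom_types],
            "unnorm_percent_atom": dict(config.operators.unnorm_percent_atom),
            "unnorm_mut_probability": {
                k.value: v for k, v in config.operators.unnorm_mut_probability.items()
            },
            "max_tries": config.operators.max_tries,
            "min_heavy_atoms": config.operators.min_heavy_atoms,
            "cutoff_bond_percentage": config.operators.cutoff_bond_percentage,
            "max_stereoisomers": config.molecular.max_stereoisomers,
            "inter_bond_distance": {
                ("".join(sorted(p)) if len(p) == 2 else 2 * next(iter(p))): d
                for p, d in config.operators.inter_bond_distance.items()
            },
        },
        "adme": {
            "ADME_Penalty_Type": config.adme.mode,
            "max_mass_ADME": config.adme.max_mass,
            "max_donor_ADME": config.adme.max_donor,
            "max_acceptor_ADME": config.adme.max_acceptor,
            "max_rotatable_dihedrals": config.adme.max_rotatable_dihedrals,
            "max_log_kow": config.adme.max_log_kow,
            "penalty_mass": config.adme.penalty_mass,
            "penalty_donor": config.adme.penalty_donor,
            "penalty_acceptor": config.adme.penalty_acceptor,
            "penalty_dihedrals": config.adme.penalty_dihedrals,
            "penalty_log_kow": config.adme.penalty_log_kow,
            "hard_violation_penalty": config.adme.hard_violation_penalty,
            "relative_soft": config.adme.relative_soft,
            "atomic_daltons": dict(config.masses),
        },
        "scorer": dict(config.scorer_descriptor) if config.scorer_descriptor else None,
        "constraints": {
            "forbidden_substructures": [
                {"smiles": p.smiles, "terminal_atoms": list(p.terminal_atoms), "name": p.name}
                for p in config.constraints.forbidden
            ],
            "substructure_penalty": config.constraints.substructure_penalty_each,
            "required_hbond_residues": list(config.constraints.required_hbond_residues),
            "hbond_penalty": config.constraints.hbond_penalty_each,
            "localization": {
                "anchors": [list(a) for a in config.constraints.localization_anchors],
                "radius": config.constraints.localization_radius,
                "penalty": config.constraints.localization_penalty_value,
            },
        },
    }


def build_scorer(config: RunConfig) -> ScorerContract:
    """Instantiate the scoring backend from the config's descriptor."""
    desc = config.scorer_descriptor
    if not desc:
        raise ConfigError("no scorer configured (scorer block missing)")
    kind = desc.get("type")
    if kind == "synthetic":
        target = desc.get("target")
        if not target:
            raise ConfigError("synthetic scorer requires a target profile")
        return SyntheticSiteScorer(
            target={k: float(v) for k, v in target.items()},
            weights={k: float(v) for k, v in (desc.get("weights")
                     or {k: 1.0 for k in PROFILE_KEYS}).items()},
            s_max=float(desc.get("s_max", 100.0)),
            report_residues=tuple(desc.get("report_residues", ())),
        )
    if kind == "replay":
        if "table" not in desc:
            raise ConfigError("replay scorer requires a table path")
        return ReplayScorer.from_tsv(desc["table"])
    if kind == "external":
        raise ConfigError(
            "external docking adapters are descriptor pass-through only; "
            "no engine is bundled with this package"
        )
    raise ConfigError(f"unknown scorer type {kind!r}")


# ---------------------------------------------------------------------------
# Population files
# ---------------------------------------------------------------------------


def load_population(
    path: str | Path, molecular_config: Optional[MolecularConfig] = None
) -> list[str]:
    """Read a one-SMILES-per-line population file (# comments allowed).

    Every line must parse and validate; any invalid line raises a
    ``ValueError`` naming its line number.  The population size is the
    number of valid lines.
    """
    cfg = molecular_config or MolecularConfig()
    chromosomes: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        try:
            parse_smiles(text, cfg)
        except ChromosomeError as exc:
            raise ValueError(f"{path}:{lineno}: invalid chromosome {text!r}: {exc}")
        chromosomes.append(text)
    if not chromosomes:
        raise ValueError(f"{path}: population file contains no molecules")
    return chromosomes


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "canonical_key", "smiles", "best_fitness", "first_seen_generation",
    "heavy_atoms", "molecular_mass", "hbd", "hba", "rotatable_dihedrals",
    "n_rings",
)


def generate_report(history: RunHistory) -> list[dict[str, Any]]:
    """Sorted-unique molecule report over a run history.

    The union of all generations is deduplicated by canonical key keeping
    the best (lowest) fitness and the generation where the key first
    appeared; rows are sorted by fitness ascending (best first).
    Chromosomes that never parsed (failure sentinels for malformed text)
    are skipped with a warning.
    """
    best: dict[str, dict[str, Any]] = {}
    for gen in history.records:
        for rec in gen.records:
            try:
                graph = parse_smiles(rec.chromosome)
            except ChromosomeError:
                logger.warning("skipping unparseable chromosome %r", rec.chromosome)
                continue
            key = canonical_key(graph)
            if key not in best:
                profile = compute_properties(graph)
                best[key] = {
                    "canonical_key": key,
                    "smiles": rec.chromosome,
                    "best_fitness": rec.fitness,
                    "first_seen_generation": gen.generation,
                    "heavy_atoms": profile.heavy_atoms,
                    "molecular_mass": round(profile.molecular_mass, 3),
                    "hbd": profile.hbd,
                    "hba": profile.hba,
                    "rotatable_dihedrals": profile.rotatable_dihedrals,
                    "n_rings": profile.n_rings,
                }
            elif rec.fitness < best[key]["best_fitness"]:
                best[key]["best_fitness"] = rec.fitness
    return sorted(best.values(), key=lambda r: (r["best_fitness"], r["canonical_key"]))


def write_report(rows: Sequence[dict[str, Any]], path: str | Path) -> None:
    """Write a report as TSV with a header line."""
    lines = ["\t".join(REPORT_COLUMNS)]
    for row in rows:
        lines.append("\t".join(str(row[c]) for c in REPORT_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def save_fitness_plot(history: RunHistory, path: str | Path) -> None:
    """Optional static best/mean fitness trace plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gens = [g.generation for g in history.records]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(gens, history.best_trace(), label="best")
    ax.plot(gens, history.mean_trace(), label="mean")
    ax.set_xlabel("generation")
    ax.set_ylabel("fitness (lower is better)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
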