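"""Synthetic worlds with planted ground truth.

A toy world is a self-consistent triple of (characterized-protein database,
pathway registry, proteomes) plus a Truth record of the categories the
annotation pipeline should recover. Per compound, one complete pathway is
planted: each step gets a characterized exemplar, and each genome gets a
proteome member at a controlled percent identity to that exemplar.
Scenarios vary per (genome, compound):

* ``complete``  — every step planted well above the high-confidence
  identity threshold: expected category high (2);
* ``medium``    — one step planted between the medium and high identity
  thresholds: expected category medium (1);
* ``missing``   — one step absent from the proteome: expected low (0);
* ``demoted``   — one step's candidate is an exact copy of an
  other-function decoy protein (itself ~50% identical to the step's
  exemplar), so the candidate out-scores against the decoy and is demoted
  from high to medium: expected category medium (1).

Sequences are i.i.d. uniform over the 20 amino acids (reproducibility over
realism) and mutation is substitution-only by default, so planted identity
is controlled to about +/-0.02 and coverage stays near 1.0. Identity levels
are kept at least 0.05 from every classification threshold so that Truth
is unambiguous. Identical specs produce byte-identical outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .curated import CuratedDB, CuratedProtein
from .rules import PathwayDef, Rule, StepDef, resolve_imports, serialize_pathway

__all__ = [
    "WorldSpec",
    "Truth",
    "ToyWorld",
    "random_protein",
    "mutate_to_identity",
    "make_toy_world",
    "write_world",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
SCENARIOS = ("complete", "medium", "missing", "demoted")
EXPECTED_CATEGORY = {"complete": 2, "medium": 1, "missing": 0, "demoted": 1}


@dataclass
class WorldSpec:
    """Study conditions for a synthetic world."""

    n_compounds: int = 5
    steps_per_pathway: tuple[int, int] = (2, 4)
    n_alternatives: tuple[int, int] = (1, 2)
    family_identity_levels: tuple[float, ...] = (0.90, 0.35)
    decoy_families: int = 2
    proteome_size: int = 25
    n_genomes: int = 3
    protein_length: int = 250
    seed: int = 0

    def __post_init__(self):
        if any(not 0.0 < x <= 1.0 for x in self.family_identity_levels):
            raise ValueError("identity levels must be in (0, 1]")
        if self.n_compounds < 1 or self.n_genomes < 1:
            raise ValueError("need at least one compound and one genome")

    @property
    def high_level(self) -> float:
        levels = [x for x in self.family_identity_levels if x >= 0.45]
        if not levels:
            raise ValueError(
                "contradictory spec: no identity level safely above the "
                "high-confidence threshold (need one >= 0.45)"
            )
        return max(levels)

    @property
    def medium_level(self) -> float:
        levels = [x for x in self.family_identity_levels if 0.30 <= x < 0.40]
        if not levels:
            raise ValueError(
                "contradictory spec: no identity level in the medium band "
                "[0.30, 0.40) for the 'medium' scenario"
            )
        return levels[0]


@dataclass
class Truth:
    """What the pipeline should find, per (genome, compound) and per step."""

    expected: dict[tuple[str, str], int] = field(default_factory=dict)
    scenario: dict[tuple[str, str], str] = field(default_factory=dict)
    planted: dict[tuple[str, str, str], tuple[str, float] | None] = field(
        default_factory=dict
    )


@dataclass
class ToyWorld:
    spec: WorldSpec
    db: CuratedDB
    registry: dict[str, PathwayDef]
    proteomes: dict[str, list[tuple[str, str]]]
    truth: Truth


def random_protein(length: int, seed: int) -> str:
    """i.i.d. uniform amino-acid sequence; deterministic per seed."""
    if length < 30:
        raise ValueError(f"length must be >= 30, got {length}")
    rng = random.Random(seed)
    return "".join(rng.choice(AA20) for _ in range(length))


def mutate_to_identity(
    seq: str, target: float, seed: int, *, indels: bool = False
) -> str:
    """Substitute positions so global identity to ``seq`` is ~``target``.

    Substitution-only by default (coverage stays ~1.0); with ``indels`` a
    short terminal deletion is added to exercise coverage clauses.
    """
    if not 0.2 < target <= 1.0:
        raise ValueError(f"target identity must be in (0.2, 1.0]: {target}")
    rng = random.Random(seed)
    chars = list(seq)
    n_sub = round((1.0 - target) * len(chars))
    for pos in rng.sample(range(len(chars)), n_sub):
        chars[pos] = rng.choice([a for a in AA20 if a != chars[pos]])
    if indels:
        cut = max(1, len(chars) // 10)
        chars = chars[:-cut]
    return "".join(chars)


def _plant_steps(spec: WorldSpec, rng: random.Random, cid: str, db: CuratedDB):
    """Create one compound's pathway: a planted main alternative plus
    optional never-planted extra alternatives."""
    n_steps = rng.randint(*spec.steps_per_pathway)
    main_steps = []
    pathway = PathwayDef(compound_id=cid)
    for j in range(n_steps):
        sid = f"{cid}_s{j}"
        pid = f"cur_{sid}"
        seq = random_protein(spec.protein_length, rng.randrange(2**31))
        kind = "transporter" if j == 0 else "enzyme"
        db[pid] = CuratedProtein(
            protein_id=pid, sequence=seq, source="synthetic",
            description=f"{kind} for step {sid}", step_ids=[sid],
        )
        pathway.steps[sid] = StepDef(step_id=sid, kind=kind, curated_ids=[pid])
        main_steps.append(sid)
    alternatives = [list(main_steps)]
    n_alt = rng.randint(*spec.n_alternatives)
    for k in range(1, n_alt):
        alt_steps = []
        for m in range(rng.randint(1, 2)):
            sid = f"{cid}_alt{k}_s{m}"
            pid = f"cur_{sid}"
            seq = random_protein(spec.protein_length, rng.randrange(2**31))
            db[pid] = CuratedProtein(
                protein_id=pid, sequence=seq, source="synthetic",
                description=f"enzyme for step {sid}", step_ids=[sid],
            )
            pathway.steps[sid] = StepDef(step_id=sid, kind="enzyme", curated_ids=[pid])
            alt_steps.append(sid)
        alternatives.append(alt_steps)
    pathway.rules["all"] = Rule(rule_id="all", alternatives=alternatives)
    pathway.entry_rule = "all"
    pathway.validate()
    return pathway, main_steps


def make_toy_world(spec: WorldSpec) -> ToyWorld:
    """Generate a world with planted pathways and known expected categories."""
    rng = random.Random(spec.seed)
    hi, med = spec.high_level, spec.medium_level

    db = CuratedDB()
    registry: dict[str, PathwayDef] = {}
    main_steps: dict[str, list[str]] = {}
    for i in range(spec.n_compounds):
        cid = f"c{i}"
        registry[cid], main_steps[cid] = _plant_steps(spec, rng, cid, db)
    resolve_imports(registry)

    # other-function decoys, each ~50% identical to one planted step exemplar
    decoy_for_step: dict[str, str] = {}
    first_steps = [main_steps[f"c{i}"][0] for i in range(spec.n_compounds)]
    for j in range(spec.decoy_families):
        sid = first_steps[j % len(first_steps)]
        pid = f"decoy{j}"
        exemplar = db[f"cur_{sid}"].sequence
        db[pid] = CuratedProtein(
            protein_id=pid,
            sequence=mutate_to_identity(exemplar, 0.50, rng.randrange(2**31)),
            source="synthetic",
            description=f"other-function paralog of {sid}",
        )
        decoy_for_step.setdefault(sid, pid)

    truth = Truth()
    proteomes: dict[str, list[tuple[str, str]]] = {}
    for k in range(spec.n_genomes):
        gid = f"g{k}"
        proteome: list[tuple[str, str]] = []
        for i, cid in enumerate(sorted(registry)):
            steps = main_steps[cid]
            scenario = SCENARIOS[(i + k) % len(SCENARIOS)]
            if scenario == "demoted" and not any(s in decoy_for_step for s in steps):
                scenario = "medium"
            affected = steps[(i + k) % len(steps)]
            if scenario == "demoted":
                affected = next(s for s in steps if s in decoy_for_step)
            for sid in steps:
                exemplar = db[f"cur_{sid}"].sequence
                pid = f"{gid}_{sid}"
                if sid == affected and scenario == "missing":
                    truth.planted[(gid, cid, sid)] = None
                    continue
                if sid == affected and scenario == "medium":
                    seq, level = mutate_to_identity(
                        exemplar, med, rng.randrange(2**31)
                    ), med
                elif sid == affected and scenario == "demoted":
                    seq, level = db[decoy_for_step[sid]].sequence, 0.50
                else:
                    seq, level = mutate_to_identity(
                        exemplar, hi, rng.randrange(2**31)
                    ), hi
                proteome.append((pid, seq))
                truth.planted[(gid, cid, sid)] = (pid, level)
            truth.expected[(gid, cid)] = EXPECTED_CATEGORY[scenario]
            truth.scenario[(gid, cid)] = scenario
        while len(proteome) < spec.proteome_size:
            pid = f"{gid}_fill{len(proteome)}"
            proteome.append(
                (pid, random_protein(spec.protein_length, rng.randrange(2**31)))
            )
        proteomes[gid] = proteome
    return ToyWorld(spec=spec, db=db, registry=registry, proteomes=proteomes, truth=truth)


def write_world(world: ToyWorld, outdir: str | Path) -> None:
    """Write the world as FASTA + TSV + pathway dialect (byte-deterministic)."""
    out = Path(outdir)
    (out / "pathways").mkdir(parents=True, exist_ok=True)
    (out / "genomes").mkdir(exist_ok=True)
    with open(out / "curated.faa", "w") as fh:
        for pid in sorted(world.db):
            fh.write(f">{pid}\n{world.db[pid].sequence}\n")
    with open(out / "curated.tsv", "w") as fh:
        fh.write("protein_id\tsource\tdescription\tstep_ids\tis_complex\n")
        for pid in sorted(world.db):
            p = world.db[pid]
            fh.write(
                f"{pid}\t{p.source}\t{p.description}\t"
                f"{','.join(p.step_ids)}\t{int(p.is_complex)}\n"
            )
    for cid in sorted(world.registry):
        (out / "pathways" / f"{cid}.txt").write_text(
            serialize_pathway(world.registry[cid])
        )
    for gid in sorted(world.proteomes):
        with open(out / "genomes" / f"{gid}.faa", "w") as fh:
            for pid, seq in world.proteomes[gid]:
                fh.write(f">{pid}\n{seq}\n")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("genome\tcompound\texpected_category\tscenario\n")
        for (gid, cid) in sorted(world.truth.expected):
            fh.write(
                f"{gid}\t{cid}\t{world.truth.expected[(gid, cid)]}\t"
                f"{world.truth.scenario[(gid, cid)]}\n"
            )
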