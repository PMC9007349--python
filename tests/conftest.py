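import random

import pyhmmer
import pytest

from pathcall.fixtures import mutate_to_identity, random_protein
from pathcall.rules import PathwayDef, Rule, StepDef


def make_random_pathway(rng: random.Random, max_steps: int = 12) -> PathwayDef:
    """Random acyclic rule tree: steps s0..sk, rules r0..rm built in
    topological order so every reference points at a step or an earlier
    rule; <= 3 alternatives per rule, 1-3 requirements per alternative."""
    n_steps = rng.randint(1, max_steps)
    pw = PathwayDef(compound_id="rand")
    for i in range(n_steps):
        sid = f"s{i}"
        pw.steps[sid] = StepDef(step_id=sid, curated_ids=["p"])
    n_rules = rng.randint(1, 5)
    for j in range(n_rules):
        pool = list(pw.steps) + [f"r{k}" for k in range(j)]
        alternatives = []
        for _ in range(rng.randint(1, 3)):
            alternatives.append(
                [rng.choice(pool) for _ in range(rng.randint(1, 3))]
            )
        pw.rules[f"r{j}"] = Rule(rule_id=f"r{j}", alternatives=alternatives)
    pw.entry_rule = f"r{n_rules - 1}"
    return pw


def make_enumerable_pathway(rng: random.Random, max_steps: int = 12,
                            max_paths: int = 2000) -> PathwayDef:
    """Random tree small enough for the brute-force enumeration oracle."""
    from pathcall.rules import count_paths

    while True:
        pw = make_random_pathway(rng, max_steps)
        if count_paths(pw) <= max_paths:
            return pw


def build_hmm(base_seed: int, n: int = 8, length: int = 120,
              ident: float = 0.85, name: bytes = b"fam") -> pyhmmer.plan7.HMM:
    """Profile HMM built from an MSA of mutated copies of one random
    sequence (gap-free, so model length equals sequence length)."""
    alphabet = pyhmmer.easel.Alphabet.amino()
    base = random_protein(length, seed=base_seed)
    seqs = [mutate_to_identity(base, ident, seed=base_seed * 100 + i) for i in range(n)]
    msa = pyhmmer.easel.TextMSA(
        name=name,
        sequences=[
            pyhmmer.easel.TextSequence(name=f"m{i}".encode(), sequence=s)
            for i, s in enumerate(seqs)
        ],
    )
    builder = pyhmmer.plan7.Builder(alphabet)
    background = pyhmmer.plan7.Background(alphabet)
    hmm, _, _ = builder.build_msa(msa.digitize(alphabet), background)
    return hmm


@pytest.fixture(scope="session")
def toy_world():
    from pathcall.fixtures import WorldSpec, make_toy_world

    return make_toy_world(WorldSpec(seed=1))
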