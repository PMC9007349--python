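"""Pathway definitions: steps, alternate rules, imports, and path expansion.

A pathway describes how a compound can be taken up and catabolized. Each
*step* is one required function (an enzyme, a transporter, or one subunit of
a multi-subunit complex) backed by characterized proteins and/or profile
HMMs. A *rule* is an OR-of-alternatives, where each alternative is an
AND-list of steps and/or sub-rules; the *entry rule* defines utilization of
the compound. A *path* is one full expansion of the entry rule into a set of
steps.

The on-disk dialect is line-oriented UTF-8 text::

    compound glucose
    # steps carry their evidence sources
    step glk kind=enzyme curated=P1,P2 hmm=TIGR001 ignore=P9
    step pts kind=transporter curated=P3
    rule upper: glk | pts
    rule all: upper lower
    entry all
    import fructose:lower

Spaces separate AND-ed requirements; ``|`` separates alternatives. Steps or
rules defined in another pathway can be imported so that a definition is
recorded in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "StepDef",
    "Rule",
    "Path",
    "PathwayDef",
    "PathwayError",
    "PathwaySyntaxError",
    "CyclicRuleError",
    "ExpansionLimitError",
    "parse_pathway_file",
    "serialize_pathway",
    "resolve_imports",
    "enumerate_paths",
    "count_paths",
]

DEFAULT_EXPANSION_BOUND = 10_000


class PathwayError(ValueError):
    """Invalid pathway content (semantic errors)."""


class PathwaySyntaxError(PathwayError):
    """Malformed dialect text; message carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class CyclicRuleError(PathwayError):
    """Rule references form a cycle."""


class ExpansionLimitError(PathwayError):
    """Full path expansion would exceed the configured bound."""


@dataclass
class StepDef:
    """One required function in a pathway.

    ``curated_ids`` are identifiers of experimentally characterized proteins
    known to perform the step; ``hmm_ids`` are profile-HMM identifiers;
    ``ignore_ids`` are characterized proteins whose similarity to a candidate
    must not be counted as evidence of a conflicting function (typically
    close paralogs acting on a slightly different substrate).
    """

    step_id: str
    description: str = ""
    kind: str = "enzyme"  # "enzyme" or "transporter"
    curated_ids: list[str] = field(default_factory=list)
    hmm_ids: list[str] = field(default_factory=list)
    ignore_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.kind not in ("enzyme", "transporter"):
            raise PathwayError(f"step {self.step_id}: unknown kind {self.kind!r}")
        if not self.curated_ids and not self.hmm_ids:
            raise PathwayError(
                f"step {self.step_id}: needs at least one curated protein or HMM"
            )
        overlap = set(self.ignore_ids) & set(self.curated_ids)
        if overlap:
            raise PathwayError(
                f"step {self.step_id}: ignore list overlaps curated ids: {sorted(overlap)}"
            )


@dataclass
class Rule:
    """OR-of-alternatives; each alternative is an AND-list of step/rule ids."""

    rule_id: str
    alternatives: list[list[str]]


@dataclass(frozen=True)
class Path:
    """One expansion of the entry rule; duplicate step ids are collapsed."""

    step_ids: tuple[str, ...]

    def __post_init__(self):
        if not self.step_ids:
            raise PathwayError("empty path")

    @property
    def step_set(self) -> frozenset[str]:
        return frozenset(self.step_ids)


@dataclass
class PathwayDef:
    """A compound's full definition: steps, rules, entry rule, imports."""

    compound_id: str
    steps: dict[str, StepDef] = field(default_factory=dict)
    rules: dict[str, Rule] = field(default_factory=dict)
    entry_rule: str | None = None
    imports: list[tuple[str, str]] = field(default_factory=list)
    frozen: bool = False

    # -- lookup helpers -------------------------------------------------
    def has_id(self, name: str) -> bool:
        return name in self.steps or name in self.rules

    def pending_import_ids(self) -> set[str]:
        return {item for _, item in self.imports}

    def validate(self, allow_pending_imports: bool = False) -> None:
        """Check internal consistency; imports may be unresolved if allowed."""
        dup = set(self.steps) & set(self.rules)
        if dup:
            raise PathwayError(f"{self.compound_id}: ids used as both step and rule: {sorted(dup)}")
        for step in self.steps.values():
            step.validate()
        pending = self.pending_import_ids() if allow_pending_imports else set()
        for rule in self.rules.values():
            for alt in rule.alternatives:
                for req in alt:
                    if not self.has_id(req) and req not in pending:
                        raise PathwayError(
                            f"{self.compound_id}: rule {rule.rule_id} references "
                            f"undeclared id {req!r}"
                        )
        if self.entry_rule is None:
            raise PathwayError(f"{self.compound_id}: no entry rule declared")
        if self.entry_rule not in self.rules and self.entry_rule not in pending:
            raise PathwayError(
                f"{self.compound_id}: entry rule {self.entry_rule!r} is not defined"
            )
        if not (allow_pending_imports and pending):
            self._check_rule_acyclic()

    def _check_rule_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color: dict[str, int] = {}

        def visit(rid: str, stack: list[str]) -> None:
            color[rid] = GRAY
            rule = self.rules[rid]
            for alt in rule.alternatives:
                for req in alt:
                    if req in self.rules:
                        c = color.get(req, WHITE)
                        if c == GRAY:
                            cycle = stack[stack.index(req):] if req in stack else [rid, req]
                            raise CyclicRuleError(
                                f"{self.compound_id}: cyclic rule references: "
                                + " -> ".join(cycle + [req])
                            )
                        if c == WHITE:
                            visit(req, stack + [req])
            color[rid] = BLACK

        for rid in self.rules:
            if color.get(rid, WHITE) == WHITE:
                visit(rid, [rid])


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------

def _parse_list(value: str) -> list[str]:
    return [x for x in value.split(",") if x]


def parse_pathway_file(text: str) -> PathwayDef:
    """Parse dialect text into a :class:`PathwayDef`.

    The returned object is validated except for ids that a pending
    ``import`` line promises to supply; call :func:`resolve_imports` on the
    full registry to materialize those.
    """
    pathway = PathwayDef(compound_id="")
    seen_compound = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        kw = fields[0]
        if kw == "compound":
            if len(fields) != 2:
                raise PathwaySyntaxError("expected: compound <id>", lineno)
            if seen_compound:
                raise PathwaySyntaxError("duplicate compound line", lineno)
            pathway.compound_id = fields[1]
            seen_compound = True
        elif kw == "step":
            if len(fields) < 2:
                raise PathwaySyntaxError("expected: step <id> [key=value ...]", lineno)
            step_id = fields[1]
            if step_id in pathway.steps:
                raise PathwaySyntaxError(f"duplicate step id {step_id!r}", lineno)
            step = StepDef(step_id=step_id)
            for kv in fields[2:]:
                if "=" not in kv:
                    raise PathwaySyntaxError(f"expected key=value, got {kv!r}", lineno)
                key, value = kv.split("=", 1)
                if key == "kind":
                    step.kind = value
                elif key == "curated":
                    step.curated_ids = _parse_list(value)
                elif key == "hmm":
                    step.hmm_ids = _parse_list(value)
                elif key == "ignore":
                    step.ignore_ids = _parse_list(value)
                elif key == "desc":
                    step.description = value.replace("_", " ")
                else:
                    raise PathwaySyntaxError(f"unknown step attribute {key!r}", lineno)
            pathway.steps[step_id] = step
        elif kw == "rule":
            # rule <id>: req req | req ...
            rest = line[len("rule"):].strip()
            if ":" not in rest:
                raise PathwaySyntaxError("expected: rule <id>: <requirements>", lineno)
            rule_id, body = rest.split(":", 1)
            rule_id = rule_id.strip()
            if not rule_id or " " in rule_id:
                raise PathwaySyntaxError(f"bad rule id {rule_id!r}", lineno)
            if rule_id in pathway.rules:
                raise PathwaySyntaxError(f"duplicate rule id {rule_id!r}", lineno)
            alternatives = []
            for alt_text in body.split("|"):
                reqs = alt_text.split()
                if not reqs:
                    raise PathwaySyntaxError("empty alternative", lineno)
                alternatives.append(reqs)
            pathway.rules[rule_id] = Rule(rule_id=rule_id, alternatives=alternatives)
        elif kw == "entry":
            if len(fields) != 2:
                raise PathwaySyntaxError("expected: entry <rule_id>", lineno)
            pathway.entry_rule = fields[1]
        elif kw == "import":
            if len(fields) != 2 or ":" not in fields[1]:
                raise PathwaySyntaxError("expected: import <compound>:<id>", lineno)
            source, item = fields[1].split(":", 1)
            pathway.imports.append((source, item))
        else:
            raise PathwaySyntaxError(f"unknown keyword {kw!r}", lineno)
    if not seen_compound:
        raise PathwayError("missing compound line")
    pathway.validate(allow_pending_imports=True)
    return pathway


def serialize_pathway(pathway: PathwayDef) -> str:
    """Render a PathwayDef back into dialect text (parses to an equal object)."""
    lines = [f"compound {pathway.compound_id}"]
    imported = pathway.pending_import_ids()
    for source, item in pathway.imports:
        lines.append(f"import {source}:{item}")
    for step in pathway.steps.values():
        if step.step_id in imported:
            continue
        parts = [f"step {step.step_id}", f"kind={step.kind}"]
        if step.curated_ids:
            parts.append("curated=" + ",".join(step.curated_ids))
        if step.hmm_ids:
            parts.append("hmm=" + ",".join(step.hmm_ids))
        if step.ignore_ids:
            parts.append("ignore=" + ",".join(step.ignore_ids))
        if step.description:
            parts.append("desc=" + step.description.replace(" ", "_"))
        lines.append(" ".join(parts))
    for rule in pathway.rules.values():
        if rule.rule_id in imported:
            continue
        body = " | ".join(" ".join(alt) for alt in rule.alternatives)
        lines.append(f"rule {rule.rule_id}: {body}")
    if pathway.entry_rule is not None:
        lines.append(f"entry {pathway.entry_rule}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# import resolution
# ---------------------------------------------------------------------------

def resolve_imports(registry: dict[str, PathwayDef]) -> dict[str, PathwayDef]:
    """Materialize every import by reference and freeze the registry.

    Imported steps/rules are shared objects: an edit to the source definition
    made before resolution is visible in every importer. Imports may chain
    across pathways (A imports an item that B itself imports) as long as no
    single item ultimately depends on itself. Resolution is idempotent.
    """
    # item-level dependency resolution: (compound, item) -> (source, item)
    pending: dict[tuple[str, str], tuple[str, str]] = {}
    for cid, pw in registry.items():
        for source, item in pw.imports:
            if source not in registry:
                raise PathwayError(
                    f"{cid}: import from missing pathway {source!r}"
                )
            if not pw.has_id(item):
                pending[(cid, item)] = (source, item)

    def available(key: tuple[str, str]) -> bool:
        cid, item = key
        return registry[cid].has_id(item)

    while pending:
        progressed = []
        for key, (source, item) in pending.items():
            if available((source, item)):
                cid, local_item = key
                src_pw = registry[source]
                if item in src_pw.steps:
                    registry[cid].steps[local_item] = src_pw.steps[item]
                else:
                    registry[cid].rules[local_item] = src_pw.rules[item]
                progressed.append(key)
        if not progressed:
            cyc = sorted(f"{c}:{i}" for c, i in pending)
            raise PathwayError(f"unresolvable import cycle among: {', '.join(cyc)}")
        for key in progressed:
            del pending[key]

    for pw in registry.values():
        pw.validate(allow_pending_imports=False)
        pw.frozen = True
    return registry


# ---------------------------------------------------------------------------
# path expansion (the solver's oracle)
# ---------------------------------------------------------------------------

def count_paths(pathway: PathwayDef, rule_id: str | None = None) -> int:
    """Number of expansions of a rule (product over AND, sum over OR)."""
    rule_id = pathway.entry_rule if rule_id is None else rule_id
    pathway._check_rule_acyclic()

    memo: dict[str, int] = {}

    def count(rid: str) -> int:
        if rid in pathway.steps:
            return 1
        if rid in memo:
            return memo[rid]
        total = 0
        for alt in pathway.rules[rid].alternatives:
            prod = 1
            for req in alt:
                prod *= count(req)
            total += prod
        memo[rid] = total
        return total

    return count(rule_id)


def enumerate_paths(
    pathway: PathwayDef, bound: int = DEFAULT_EXPANSION_BOUND
) -> list[Path]:
    """Expand the entry rule into every path, in definition order, depth-first.

    Each alternative contributes the cross-product of its requirements'
    expansions; duplicate step ids within one path collapse (a shared gene
    product is one step). Raises :class:`ExpansionLimitError` when the number
    of expansions exceeds ``bound`` — use the solver for such pathways.
    """
    if pathway.entry_rule is None:
        raise PathwayError(f"{pathway.compound_id}: no entry rule")
    n = count_paths(pathway)
    if n > bound:
        raise ExpansionLimitError(
            f"{pathway.compound_id}: {n} expansions exceed bound {bound}; "
            "use the best-path solver instead of full enumeration"
        )

    memo: dict[str, list[tuple[str, ...]]] = {}

    def expand(rid: str) -> list[tuple[str, ...]]:
        if rid in pathway.steps:
            return [(rid,)]
        if rid in memo:
            return memo[rid]
        out: list[tuple[str, ...]] = []
        for alt in pathway.rules[rid].alternatives:
            partial: list[tuple[str, ...]] = [()]
            for req in alt:
                sub = expand(req)
                partial = [p + s for p in partial for s in sub]
            out.extend(partial)
        memo[rid] = out
        return out

    paths = []
    for steps in expand(pathway.entry_rule):
        seen: list[str] = []
        for sid in steps:
            if sid not in seen:
                seen.append(sid)
        paths.append(Path(step_ids=tuple(seen)))
    return paths


def copy_pathway(pathway: PathwayDef) -> PathwayDef:
    """Deep-enough copy for safe mutation (steps copied, not shared)."""
    return PathwayDef(
        compound_id=pathway.compound_id,
        steps={k: replace(v, curated_ids=list(v.curated_ids),
                          hmm_ids=list(v.hmm_ids), ignore_ids=list(v.ignore_ids))
               for k, v in pathway.steps.items()},
        rules={k: Rule(k, [list(a) for a in v.alternatives])
               for k, v in pathway.rules.items()},
        entry_rule=pathway.entry_rule,
        imports=list(pathway.imports),
    )
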