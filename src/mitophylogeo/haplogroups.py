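"""Haplogroup tree handling, classification and phylogeographic screening.

The tree is a rooted haplogroup phylogeny in which every branch carries the
variants that define its child node relative to the parent (PhyloTree
style).  A node's *cumulative state* is the parent state edited by the
branch's defining variants, with ``@``-prefixed back mutations reverting
the site to its rCRS state.

Classification scores a haplotype against every node by the symmetric
average of path recall and profile precision and reports the ranked list;
the top hit carries the private variants the path does not explain.  New
sub-haplogroups are proposed by the rule used when extending the reference
phylogeny: at least two distinct genomes sharing at least one derived
variant at a mutationally stable position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .nomenclature import (
    BACK_MUTATION,
    HaplotypeProfile,
    MitoVariant,
    NomenclatureError,
    parse_motif,
    parse_variant_token,
    PHYLOGENY_HOTSPOTS,
    POLYC_515_524,
    POLYC_AROUND_310,
)


@dataclass
class HaploNode:
    """One named haplogroup with the variants defining it from its parent."""

    name: str
    defining_variants: list[MitoVariant] = field(default_factory=list)
    children: list["HaploNode"] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    def walk(self) -> Iterable[tuple["HaploNode", int]]:
        """Yield (node, depth) over the subtree, preorder."""
        stack = [(self, 0)]
        while stack:
            node, depth = stack.pop()
            yield node, depth
            for child in reversed(node.children):
                stack.append((child, depth + 1))

    def find(self, name: str) -> "HaploNode | None":
        for node, _ in self.walk():
            if node.name == name:
                return node
        return None

    def descendant_names(self, name: str) -> set[str]:
        """Names of ``name`` and all its descendants; empty set if absent."""
        start = self.find(name)
        if start is None:
            return set()
        return {node.name for node, _ in start.walk()}


def load_tree(tree_text: str) -> HaploNode:
    """Load a haplogroup tree from indented text, one node per line.

    Format: ``name: v1,v2`` with child nodes indented more deeply than
    their parent (any consistent indentation).  The first line is the root.
    """
    root: HaploNode | None = None
    stack: list[tuple[int, HaploNode]] = []
    names: set[str] = set()
    for lineno, raw in enumerate(tree_text.splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        indent = len(raw) - len(raw.lstrip())
        line = raw.strip()
        name, _, spec = line.partition(":")
        name = name.strip()
        if not name:
            raise ValueError(f"line {lineno}: node without a name")
        if name in names:
            raise ValueError(f"line {lineno}: duplicate node name {name!r}")
        names.add(name)
        variants = [
            parse_variant_token(tok.strip())
            for tok in spec.split(",")
            if tok.strip()
        ]
        node = HaploNode(name=name, defining_variants=variants)
        while stack and stack[-1][0] >= indent:
            stack.pop()
        if not stack:
            if root is not None:
                raise ValueError(f"line {lineno}: second root {name!r}")
            root = node
        else:
            stack[-1][1].children.append(node)
        stack.append((indent, node))
    if root is None:
        raise ValueError("empty tree text")
    return root


def _apply_edit(state: dict[tuple[int, int], MitoVariant], v: MitoVariant) -> None:
    """Edit a cumulative state by one defining variant (back mutations revert)."""
    if v.kind == BACK_MUTATION:
        state.pop((v.position, 0), None)
    else:
        state[v.site] = v


def cumulative_states(tree: HaploNode) -> dict[str, dict[tuple[int, int], MitoVariant]]:
    """Per-node cumulative variant state (site -> variant) from the root path."""
    states: dict[str, dict[tuple[int, int], MitoVariant]] = {}

    def rec(node: HaploNode, state: dict[tuple[int, int], MitoVariant]) -> None:
        state = dict(state)
        for v in node.defining_variants:
            _apply_edit(state, v)
        states[node.name] = state
        for child in node.children:
            rec(child, state)

    rec(tree, {})
    return states


def node_state_profile(tree: HaploNode, name: str) -> HaplotypeProfile:
    """The cumulative state of a node as a haplotype profile."""
    states = cumulative_states(tree)
    if name not in states:
        raise KeyError(f"node {name!r} not in tree")
    return HaplotypeProfile(
        sample_id=name, variants=tuple(sorted(states[name].values(), key=lambda v: v.site))
    )


def _node_depths(tree: HaploNode) -> dict[str, int]:
    return {node.name: depth for node, depth in tree.walk()}


def _same_state(a: MitoVariant, b: MitoVariant) -> bool:
    """Two variants denote the same derived state at the same site."""
    if a.site != b.site or a.kind != b.kind:
        return False
    return a.alt == b.alt


@dataclass(frozen=True)
class Classification:
    sample_id: str
    best_node: str
    score: float
    matched: tuple[MitoVariant, ...]
    missing: tuple[MitoVariant, ...]
    private: tuple[MitoVariant, ...]


def classify(profile: HaplotypeProfile, tree: HaploNode) -> list[Classification]:
    """Rank every tree node against a (phylogeny-filtered) profile.

    Score = mean of (|E∩P|/|E|) and (|E∩P|/|P|) where E is the node's
    cumulative state restricted to the profile's covered range and P the
    profile's variants.  An expected variant countered by an observed
    ``@`` token counts as missing.  Empty E or P contributes 1 to its
    term (a root with no expectations neither matches nor contradicts).
    Ties prefer the deeper node, then the lexicographically smaller name.
    """
    if tree is None:
        raise ValueError("empty tree")
    states = cumulative_states(tree)
    depths = _node_depths(tree)

    observed: dict[tuple[int, int], MitoVariant] = {}
    reverted: set[int] = set()
    for v in profile.variants:
        if v.kind == BACK_MUTATION:
            reverted.add(v.position)
        else:
            observed[v.site] = v
    informative = [v for v in profile.variants if v.kind != BACK_MUTATION]

    results: list[Classification] = []
    for name, state in states.items():
        expected = [
            v for v in state.values() if profile.covers(v.position)
        ]
        matched: list[MitoVariant] = []
        missing: list[MitoVariant] = []
        for e in expected:
            obs = observed.get(e.site)
            if e.position in reverted and e.insert_index == 0:
                missing.append(e)
            elif obs is not None and _same_state(e, obs):
                matched.append(e)
            else:
                missing.append(e)
        n_e = len(expected)
        n_p = len(informative)
        n_m = len(matched)
        recall = n_m / n_e if n_e else 1.0
        precision = n_m / n_p if n_p else 1.0
        score = 0.5 * (recall + precision)
        expected_sites = {e.site for e in expected}
        private = tuple(v for v in informative if v.site not in expected_sites)
        results.append(
            Classification(
                sample_id=profile.sample_id,
                best_node=name,
                score=score,
                matched=tuple(matched),
                missing=tuple(missing),
                private=private,
            )
        )
    results.sort(key=lambda c: (-c.score, -depths[c.best_node], c.best_node))
    return results


# ---------------------------------------------------------------------------
# Sub-haplogroup discovery

#: default mutationally unstable positions: the hotspot trio plus poly-C tracts
DEFAULT_UNSTABLE: frozenset[int] = frozenset(
    set(PHYLOGENY_HOTSPOTS)
    | set(range(POLYC_515_524[0], POLYC_515_524[1] + 1))
    | set(range(POLYC_AROUND_310[0], POLYC_AROUND_310[1] + 1))
    | {16189, 16193}
)


def default_stable_positions() -> set[int]:
    """All rCRS positions minus the bundled hotspot/poly-C set."""
    from .nomenclature import MT_LENGTH

    return set(range(1, MT_LENGTH + 1)) - DEFAULT_UNSTABLE


def _next_child_name(parent: str, taken: set[str]) -> str:
    """PhyloTree-style child naming: append a digit after a letter, a letter
    after a digit."""
    if parent and parent[-1].isdigit():
        alphabet = "abcdefghijklmnopqrstuvwxyz"
        for ch in alphabet:
            if parent + ch not in taken:
                taken.add(parent + ch)
                return parent + ch
    i = 1
    while f"{parent}{i}" in taken:
        i += 1
    taken.add(f"{parent}{i}")
    return f"{parent}{i}"


def derived_variants(
    member: HaplotypeProfile, parent_state: HaplotypeProfile
) -> set[MitoVariant]:
    """Variants of ``member`` not present in ``parent_state`` (same site+allele)."""
    parent = {v.site: v for v in parent_state.variants}
    out = set()
    for v in member.variants:
        if v.kind == BACK_MUTATION:
            if v.position in {s[0] for s in parent}:
                out.add(v)
            continue
        p = parent.get(v.site)
        if p is None or not _same_state(p, v):
            out.add(v)
    return out


def discover_subclades(
    members: Sequence[HaplotypeProfile],
    parent_state: HaplotypeProfile,
    stable_positions: set[int] | None = None,
    parent_name: str = "new",
) -> list[HaploNode]:
    """Propose child clades: maximal sets of >=2 distinct genomes sharing >=1
    derived variant at a stable position.  Nested proposals are allowed and
    returned as nested nodes."""
    if stable_positions is None:
        stable_positions = default_stable_positions()
    if len(members) < 2:
        return []

    by_variant: dict[MitoVariant, frozenset[str]] = {}
    for m in members:
        for v in derived_variants(m, parent_state):
            if v.position in stable_positions and v.kind != BACK_MUTATION:
                by_variant.setdefault(v, frozenset())
                by_variant[v] |= {m.sample_id}

    # group defining variants by identical member sets
    groups: dict[frozenset[str], list[MitoVariant]] = {}
    for v, ids in by_variant.items():
        if len(ids) >= 2:
            groups.setdefault(ids, []).append(v)

    if not groups:
        return []

    # order by size descending so parents come before nested children
    ordered = sorted(
        groups.items(),
        key=lambda kv: (-len(kv[0]), sorted(v.render() for v in kv[1])[0]),
    )
    taken: set[str] = {parent_name}
    proposals: list[tuple[frozenset[str], HaploNode]] = []
    roots: list[HaploNode] = []
    for ids, variants in ordered:
        variants = sorted(variants, key=lambda v: v.site)
        host: tuple[frozenset[str], HaploNode] | None = None
        for pids, pnode in proposals:
            if ids < pids:
                host = (pids, pnode)  # strict subset -> nest inside
        if host is None:
            name = _next_child_name(parent_name, taken)
            node = HaploNode(name=name, defining_variants=variants)
            node.annotations["members"] = sorted(ids)
            roots.append(node)
        else:
            name = _next_child_name(host[1].name, taken)
            node = HaploNode(name=name, defining_variants=variants)
            node.annotations["members"] = sorted(ids)
            host[1].children.append(node)
        proposals.append((ids, node))
    return roots


# ---------------------------------------------------------------------------
# Motif database search

@dataclass(frozen=True)
class MotifRecord:
    profile: HaplotypeProfile
    population: str
    region: str
    source: str = ""


@dataclass
class MotifDatabase:
    """Control-region motif database restricted to a declared range."""

    records: list[MotifRecord]
    range: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.range
        for r in self.records:
            for v in r.profile.variants:
                if not lo <= v.position <= hi:
                    raise ValueError(
                        f"record {r.profile.sample_id!r} has variant "
                        f"{v.render()} outside database range {self.range}"
                    )

    @classmethod
    def from_tsv(cls, path: str, range_: tuple[int, int]) -> "MotifDatabase":
        from .nomenclature import restrict_range

        records = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                motif = parts[0]
                pop = parts[1] if len(parts) > 1 else ""
                region = parts[2] if len(parts) > 2 else ""
                source = parts[3] if len(parts) > 3 else ""
                prof = restrict_range(parse_motif(motif), *range_)
                records.append(MotifRecord(prof, pop, region, source))
        return cls(records=records, range=range_)


def _query_states(query_tokens: Sequence[str]) -> dict[tuple[int, int], set[str]]:
    """Per-site admissible derived states; '/'-separated tokens give
    alternatives (``A16318T/A16318C``)."""
    states: dict[tuple[int, int], set[str]] = {}
    for tok in query_tokens:
        alts = [parse_variant_token(t) for t in tok.split("/")]
        site = alts[0].site
        if any(a.site != site for a in alts):
            raise NomenclatureError(f"alternatives in {tok!r} name different sites")
        states.setdefault(site, set()).update(
            f"{a.kind}:{a.alt}" for a in alts
        )
    return states


def _difference_steps(
    query: dict[tuple[int, int], set[str]],
    record: HaplotypeProfile,
) -> int:
    """Mutational steps between a query state and a record: one per site
    present on one side only or carrying a non-matching allele."""
    rec_state = {v.site: f"{v.kind}:{v.alt}" for v in record.variants}
    steps = 0
    for site, allowed in query.items():
        got = rec_state.get(site)
        if got is None or got not in allowed:
            steps += 1
    for site in rec_state:
        if site not in query:
            steps += 1
    return steps


@dataclass(frozen=True)
class MotifMatch:
    record: MotifRecord
    steps: int


def motif_search(
    query: HaplotypeProfile | Sequence[str],
    db: MotifDatabase,
    max_steps: int = 0,
) -> tuple[list[MotifMatch], dict[str, int]]:
    """Search the database at 0 (exact) or 1 mutational step.

    ``query`` is a profile or a token list which may carry per-site
    alternative alleles (``A16318T/A16318C``).  Returns the matches at
    exactly ``max_steps`` steps and per-region tallies.
    """
    if max_steps not in (0, 1):
        raise ValueError("max_steps must be 0 or 1")
    if isinstance(query, HaplotypeProfile):
        if query.covered_range != ((db.range[0], db.range[1]),) and query.covered_range != (
            (1, 16569),
        ):
            raise ValueError(
                f"query range {query.covered_range} does not cover database "
                f"range {db.range}"
            )
        tokens = query.tokens()
    else:
        tokens = tuple(query)
    qstate = _query_states(tokens)
    for (pos, _), _s in qstate.items():
        if not db.range[0] <= pos <= db.range[1]:
            raise ValueError(f"query variant at {pos} outside database range {db.range}")
    matches = [
        MotifMatch(record=r, steps=_difference_steps(qstate, r.profile))
        for r in db.records
    ]
    hits = [m for m in matches if m.steps == max_steps]
    tallies: dict[str, int] = {}
    for m in hits:
        tallies[m.record.region] = tallies.get(m.record.region, 0) + 1
    return hits, tallies


# ---------------------------------------------------------------------------
# Geographic flagging and the ancestry component

def flag_clade_origin(
    node: HaploNode,
    member_regions: Mapping[str, int],
    home_region: str,
    threshold: float = 0.5,
) -> str:
    """Region holding >= threshold of the clade's non-home members, else
    'unresolved'."""
    counts = {r: c for r, c in member_regions.items() if r != home_region and c > 0}
    total = sum(counts.values())
    if total == 0:
        return "unresolved"
    best_region, best = max(sorted(counts.items()), key=lambda kv: kv[1])
    if best / total >= threshold:
        return best_region
    return "unresolved"


def ancestry_component(
    classifications: Sequence[Classification],
    flagged_nodes: set[str],
    tree: HaploNode | None = None,
) -> float:
    """Percentage of samples classified to a flagged node or a descendant."""
    if not classifications:
        raise ValueError("no classified samples")
    flagged = set(flagged_nodes)
    if tree is not None:
        for name in flagged_nodes:
            flagged |= tree.descendant_names(name)
    hits = sum(1 for c in classifications if c.best_node in flagged)
    return 100.0 * hits / len(classifications)
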