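"""Synthetic mitogenome data with known truth.

Everything the other modules consume can be generated here: haplotypes
evolved down a haplogroup tree under a Poisson molecular clock, structured
populations with chosen haplogroup frequencies, an admixed study
population carrying a known fraction of source-region lineages, motif
databases, and multi-sample VCF fixtures that round-trip through the
nomenclature converter.

The sequence backdrop is a *synthetic* 16,569-bp reference (seeded
constant, overridden wherever a variant token names its rCRS base); it
stands in for the real rCRS so fixtures stay programmatic.  The clock is
calibrated on mutations at stable positions only — hotspot hits are
generated as an additional process so that exclusion filters have
something to remove without biasing the dating clock.

All randomness flows from the single ``seed`` in :class:`SimulationConfig`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dating import CladeGenealogy, GenealogyNode
from .haplogroups import HaploNode, cumulative_states, load_tree
from .nomenclature import (
    DELETION,
    INSERTION,
    MT_LENGTH,
    HaplotypeProfile,
    MitoVariant,
    render_motif,
)
from .haplogroups import DEFAULT_UNSTABLE

_REFERENCE_SEED = 16569  # fixed: the synthetic reference is a constant

PURINE_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def toy_tree() -> HaploNode:
    """The bundled toy haplogroup tree (see ``data/toy_tree.txt``)."""
    text = (
        importlib.resources.files("mitophylogeo")
        .joinpath("data/toy_tree.txt")
        .read_text()
    )
    return load_tree(text)


_REF_BACKDROP: np.ndarray | None = None


def synthetic_reference(profiles: Iterable[HaplotypeProfile] = ()) -> np.ndarray:
    """A deterministic synthetic base per rCRS coordinate (index 1..16569).

    Bases named as ``ref`` by any supplied variant override the random
    backdrop; conflicting ref claims at one position raise.
    """
    global _REF_BACKDROP
    if _REF_BACKDROP is None:
        rng = np.random.default_rng(_REFERENCE_SEED)
        _REF_BACKDROP = rng.choice(list("ACGT"), size=MT_LENGTH + 1)
    bases = _REF_BACKDROP.copy()
    claims: dict[int, str] = {}
    for p in profiles:
        for v in p.variants:
            if v.ref:
                prev = claims.get(v.position)
                if prev is not None and prev != v.ref:
                    raise ValueError(
                        f"conflicting reference bases {prev}/{v.ref} at {v.position}"
                    )
                claims[v.position] = v.ref
    for pos, base in claims.items():
        bases[pos] = base
    return bases


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    region: str
    haplogroup_freqs: dict[str, float]
    size: int

    def __post_init__(self) -> None:
        total = sum(self.haplogroup_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies for {self.label!r} sum to {total}, not 1")


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the study design being emulated: 110 samples in the
    admixed population, an 8.2% source-region fraction, the
    whole-mitogenome clock of one mutation per 3,624 years, and Yule
    genealogies (real clades are not stars).
    """

    seed: int = 0
    tree: HaploNode | None = None
    years_per_mutation: float = 3624.0
    clade_age_years: float = 8000.0
    n_samples: int = 110
    topology: str = "yule"          # "yule" or "star"
    hotspot_rate: float = 0.15      # hotspot hits per stable-clock mutation
    admixture_fraction: float = 0.082
    populations: list[PopulationSpec] = field(default_factory=list)
    hvs1_only: bool = False

    def __post_init__(self) -> None:
        if self.topology not in ("yule", "star"):
            raise ValueError("topology must be 'yule' or 'star'")
        if not 0.0 <= self.admixture_fraction <= 1.0:
            raise ValueError("admixture_fraction must be in [0, 1]")


_STABLE_POSITIONS = np.array(
    sorted(set(range(1, MT_LENGTH + 1)) - set(DEFAULT_UNSTABLE)), dtype=int
)
_HOTSPOT_POSITIONS = np.array(sorted(DEFAULT_UNSTABLE), dtype=int)
# within the hotspot set, the three classical positions are 50x more mutable
_HOTSPOT_WEIGHTS = np.where(
    np.isin(_HOTSPOT_POSITIONS, (16182, 16183, 16519)), 50.0, 1.0
)
_HOTSPOT_WEIGHTS = _HOTSPOT_WEIGHTS / _HOTSPOT_WEIGHTS.sum()


def _draw_allele(ref: str, rng: np.random.Generator) -> str:
    """Transitions dominate mtDNA substitution; 94:6 against transversions."""
    if rng.random() < 0.94:
        return PURINE_PARTNER[ref]
    others = [b for b in "ACGT" if b != ref and b != PURINE_PARTNER[ref]]
    return others[rng.integers(len(others))]


def _substitution_variant(pos: int, ref: str, alt: str) -> MitoVariant:
    from .nomenclature import _substitution_kind

    return MitoVariant(position=pos, ref=ref, alt=alt, kind=_substitution_kind(ref, alt))


def _yule_split_depths(n: int, age: float, rng: np.random.Generator) -> np.ndarray:
    """Depths of the n-1 splits of a Yule genealogy conditioned to depth
    ``age``: exponential inter-split waits rescaled to the total depth."""
    waits = np.array([rng.exponential(1.0 / k) for k in range(1, n)])
    tail = rng.exponential(1.0 / n)  # time spent with n lineages before today
    cum = np.concatenate(([0.0], np.cumsum(waits)[:-1])) if n > 1 else np.array([0.0])
    total = waits.sum() + tail
    return cum / total * age


def simulate_clade(
    cfg: SimulationConfig,
    root_state: HaplotypeProfile | None = None,
    sample_prefix: str = "s",
    rng: np.random.Generator | None = None,
) -> tuple[CladeGenealogy, list[HaplotypeProfile]]:
    """Evolve ``cfg.n_samples`` haplotypes down a clade of the configured age.

    Branch mutation counts in the returned genealogy cover stable-position
    mutations only (the quantity the calibrated clock counts); leaf
    profiles additionally carry hotspot hits so exclusion filters are
    exercised.  Deterministic given the seed.
    """
    if cfg.clade_age_years < 0 or cfg.years_per_mutation <= 0:
        raise ValueError("need non-negative age and positive clock rate")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    if n < 1:
        raise ValueError("need at least one sample")
    reference = synthetic_reference([root_state] if root_state else [])
    root_variants: dict[int, MitoVariant] = (
        {v.position: v for v in root_state.variants} if root_state else {}
    )

    # --- topology: list of (start_depth, node); leaves end at cfg.clade_age_years
    root = GenealogyNode(sample_id="root")
    if cfg.topology == "star" or n == 1:
        starts = {id(root): 0.0}
        active = []
        for i in range(n):
            child = GenealogyNode(sample_id=f"{sample_prefix}{i}")
            root.children.append(child)
            starts[id(child)] = 0.0
            active.append(child)
    else:
        depths = _yule_split_depths(n, cfg.clade_age_years, rng)
        starts = {id(root): 0.0}
        active = [root]
        for d in depths:  # n-1 splits; the first (depth 0) splits the root
            idx = rng.integers(len(active))
            node = active.pop(int(idx))
            left, right = GenealogyNode(), GenealogyNode()
            node.children = [left, right]
            starts[id(left)] = starts[id(right)] = float(d)
            active.extend([left, right])
        for i, leaf in enumerate(active):
            leaf.sample_id = f"{sample_prefix}{i}"

    # --- mutations along branches
    mu = 1.0 / cfg.years_per_mutation
    profiles: list[HaplotypeProfile] = []

    def evolve(node: GenealogyNode, state: dict[int, MitoVariant], depth: float) -> None:
        if node is not root:
            duration = (
                cfg.clade_age_years - depth if node.is_leaf
                else starts[id(node.children[0])] - depth
            )
            duration = max(duration, 0.0)
            m_stable = rng.poisson(duration * mu)
            m_hot = rng.poisson(duration * mu * cfg.hotspot_rate)
            node.mutations = int(m_stable)
            state = dict(state)
            for pos in rng.choice(_STABLE_POSITIONS, size=m_stable, replace=False if m_stable <= len(_STABLE_POSITIONS) else True):
                _mutate(state, int(pos))
            for pos in rng.choice(_HOTSPOT_POSITIONS, size=m_hot, p=_HOTSPOT_WEIGHTS):
                _mutate(state, int(pos))
        if node.is_leaf and node is not root:
            profiles.append(
                HaplotypeProfile(
                    sample_id=node.sample_id,
                    variants=tuple(sorted(state.values(), key=lambda v: v.site)),
                )
            )
        else:
            for c in node.children:
                child_depth = starts[id(c)]
                evolve(c, state, child_depth)

    def _mutate(state: dict[int, MitoVariant], pos: int) -> None:
        ref = str(reference[pos])
        if pos in state:
            # recurrent hit reverts the site to the reference state
            del state[pos]
        else:
            state[pos] = _substitution_variant(pos, ref, _draw_allele(ref, rng))

    evolve(root, dict(root_variants), 0.0)
    # leaves were appended in traversal order; sort by sample id for stability
    profiles.sort(key=lambda p: (len(p.sample_id), p.sample_id))
    return CladeGenealogy(root=root), profiles


# ---------------------------------------------------------------------------
# Structured / admixed populations

def default_study_populations() -> tuple[list[PopulationSpec], set[str], str]:
    """The synthetic study design: a local (study-region) haplogroup pool, a
    source-region pool, and the set of source-diagnostic clades."""
    local = {"H": 0.42, "HV": 0.08, "J": 0.12, "T2": 0.18, "U": 0.14, "L1b1a": 0.06}
    source = {
        "HV9c": 0.18, "U7a4a1a": 0.20, "J1d6": 0.14, "J1b1a3a": 0.12,
        "T2d2a": 0.12, "T2n1": 0.10, "H92": 0.08, "H97": 0.06,
    }
    flagged = set(source)
    specs = [
        PopulationSpec("study", "Europe", local, 110),
        PopulationSpec("source", "Near East", source, 60),
    ]
    return specs, flagged, "source"


def simulate_haplotype_for(
    name: str,
    states: Mapping[str, Mapping],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str,
    private_age_years: float = 1500.0,
) -> HaplotypeProfile:
    """One haplotype of haplogroup ``name``: the node's cumulative state plus
    a small Poisson load of private stable-position mutations."""
    state = {v.position: v for v in states[name].values()}
    reference = synthetic_reference()
    m = rng.poisson(private_age_years / cfg.years_per_mutation)
    for pos in rng.choice(_STABLE_POSITIONS, size=m, replace=False):
        pos = int(pos)
        if pos in state:
            del state[pos]
        else:
            ref = str(reference[pos])
            state[pos] = _substitution_variant(pos, ref, _draw_allele(ref, rng))
    return HaplotypeProfile(
        sample_id=sample_id, variants=tuple(sorted(state.values(), key=lambda v: v.site))
    )


def simulate_admixed_study(cfg: SimulationConfig):
    """An admixed study population: each sample draws its haplogroup from the
    source-region pool with probability ``admixture_fraction``, otherwise
    from the local pool.  Returns the population and per-sample truth
    labels ("local" / "source")."""
    from .popgen import PopulationSet

    rng = np.random.default_rng(cfg.seed)
    tree = cfg.tree if cfg.tree is not None else toy_tree()
    states = cumulative_states(tree)
    if cfg.populations:
        if len(cfg.populations) < 2:
            raise ValueError("need a local and a source population spec")
        local_spec, source_spec = cfg.populations[0], cfg.populations[1]
    else:
        specs, _flagged, _src = default_study_populations()
        local_spec, source_spec = specs

    for spec in (local_spec, source_spec):
        missing = [h for h in spec.haplogroup_freqs if h not in states]
        if missing:
            raise ValueError(f"haplogroups {missing} not in the tree")

    def draw_from(spec: PopulationSpec) -> str:
        names = sorted(spec.haplogroup_freqs)
        probs = np.array([spec.haplogroup_freqs[h] for h in names])
        return names[rng.choice(len(names), p=probs)]

    profiles = []
    truth = []
    for i in range(cfg.n_samples):
        is_source = rng.random() < cfg.admixture_fraction
        hg = draw_from(source_spec if is_source else local_spec)
        profiles.append(
            simulate_haplotype_for(hg, states, cfg, rng, sample_id=f"tus{i:03d}")
        )
        truth.append("source" if is_source else "local")
    pop = PopulationSet(label=local_spec.label, profiles=profiles, region=local_spec.region)
    return pop, truth


# ---------------------------------------------------------------------------
# Fixture writers

def write_fixture_vcf(profiles: Sequence[HaplotypeProfile], path: str) -> None:
    """Write profiles as a multi-sample VCF v4.2 on a synthetic rCRS-length
    contig.  Round-trips exactly through ``vcf_to_profile``."""
    import pysam

    reference = synthetic_reference(profiles)
    header = pysam.VariantHeader()
    header.add_line("##source=mitophylogeo-synthetic")
    header.add_line(f"##contig=<ID=chrM,length={MT_LENGTH}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for p in profiles:
        header.add_sample(p.sample_id)

    # one record per distinct variant state
    carriers: dict[tuple, set[str]] = {}
    variant_of: dict[tuple, MitoVariant] = {}
    for p in profiles:
        for v in p.variants:
            if v.kind == "back_mutation":
                raise ValueError(
                    "back-mutation tokens describe tree edits, not sample "
                    "states, and cannot be written to VCF"
                )
            key = (v.position, v.insert_index, v.kind, v.alt)
            carriers.setdefault(key, set()).add(p.sample_id)
            variant_of[key] = v

    records = []
    for key, v in variant_of.items():
        if v.kind == DELETION:
            anchor = v.position - 1
            if anchor < 1:
                raise ValueError("cannot anchor a deletion at position 1")
            ref = str(reference[anchor]) + (v.ref or str(reference[v.position]))
            alt = str(reference[anchor])
            pos = anchor
        elif v.kind == INSERTION:
            ref = str(reference[v.position])
            alt = ref + v.alt
            pos = v.position
        else:
            ref = v.ref or str(reference[v.position])
            alt = v.alt
            pos = v.position
        records.append((pos, ref, alt, carriers[key]))
    records.sort(key=lambda r: (r[0], r[1], r[2]))

    with pysam.VariantFile(path, "w", header=header) as out:
        for pos, ref, alt, who in records:
            rec = out.new_record(
                contig="chrM", start=pos - 1, stop=pos - 1 + len(ref),
                alleles=(ref, alt),
            )
            for p in profiles:
                rec.samples[p.sample_id]["GT"] = (1,) if p.sample_id in who else (0,)
            out.write(rec)


def write_motif_db(
    entries: Sequence[tuple[HaplotypeProfile, str, str, str]], path: str
) -> None:
    """Write a motif database TSV: motif, population, region, source."""
    with open(path, "w") as fh:
        for profile, pop, region, source in entries:
            fh.write(f"{render_motif(profile)}\t{pop}\t{region}\t{source}\n")
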