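"""mtDNA variant nomenclature relative to the rCRS.

Variants are named in the convention used throughout the forensic and
phylogeographic mtDNA literature (EMPOP / PhyloTree style): 1-based rCRS
coordinates, transitions written ``A73G``, transversions distinguished only
by their base chemistry, deletions ``15322d``, insertions anchored to the
preceding rCRS position ``309.1C``, and back mutations (reversion of an
ancestrally mutated site to its rCRS state) prefixed with ``@``.

Two token dialects are accepted by :func:`parse_variant_token`:

* the full EMPOP form carrying the reference base (``T6248C``);
* the tree-figure shorthand without it (``16311`` for a transition,
  ``16318C`` where a trailing base marks a transversion).

Both render back to the form they were parsed from, so parse/render is an
exact round trip.
"""

from __future__ import annotations

import re
import sys
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

MT_LENGTH = 16569
"""Length of the revised Cambridge Reference Sequence in base pairs."""

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
NUCLEOTIDES = frozenset("ACGT")

#: kinds of variant
TRANSITION = "transition"
TRANSVERSION = "transversion"
INSERTION = "insertion"
DELETION = "deletion"
BACK_MUTATION = "back_mutation"


class NomenclatureError(ValueError):
    """A variant token or profile violates the mtDNA nomenclature rules."""


_TOKEN_RE = re.compile(
    r"""^(?P<back>@)?
         (?:
            (?P<ins_ref>[ACGT])?(?P<ins_pos>\d+)\.(?P<ins_idx>\d+)(?P<ins_alt>[ACGT]+)
          | (?P<del_ref>[ACGT])?(?P<del_pos>\d+)d
          | (?P<sub_ref>[ACGT])?(?P<sub_pos>\d+)(?P<sub_alt>[ACGT])?
         )$""",
    re.VERBOSE,
)


@dataclass(frozen=True, order=True)
class MitoVariant:
    """One difference from the rCRS.

    ``ref``/``alt`` may be empty in the shorthand dialect; ``insert_index``
    is 0 except for insertions, where it numbers the inserted position
    after the anchor (``309.1C`` has ``insert_index == 1``).
    """

    position: int
    ref: str = ""
    alt: str = ""
    kind: str = TRANSITION
    insert_index: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise NomenclatureError(
                f"position {self.position} outside rCRS coordinates 1..{MT_LENGTH}"
            )
        if self.kind not in (TRANSITION, TRANSVERSION, INSERTION, DELETION, BACK_MUTATION):
            raise NomenclatureError(f"unknown variant kind {self.kind!r}")
        if self.kind == INSERTION and self.insert_index < 1:
            raise NomenclatureError("insertions need insert_index >= 1")
        if self.kind != INSERTION and self.insert_index != 0:
            raise NomenclatureError("insert_index must be 0 for non-insertions")

    @property
    def site(self) -> tuple[int, int]:
        """The (position, insert_index) slot this variant occupies."""
        return (self.position, self.insert_index)

    @property
    def is_indel(self) -> bool:
        return self.kind in (INSERTION, DELETION)

    def render(self) -> str:
        prefix = "@" if self.kind == BACK_MUTATION else ""
        if self.kind == INSERTION:
            return f"{prefix}{self.ref}{self.position}.{self.insert_index}{self.alt}"
        if self.kind == DELETION:
            return f"{prefix}{self.ref}{self.position}d"
        return f"{prefix}{self.ref}{self.position}{self.alt}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def _substitution_kind(ref: str, alt: str) -> str:
    """Transition iff ref and alt are both purines or both pyrimidines."""
    if ref and alt:
        if {ref, alt} <= PURINES or {ref, alt} <= PYRIMIDINES:
            return TRANSITION
        return TRANSVERSION
    if alt and not ref:
        # figure shorthand: a trailing base flags a transversion,
        # plain numbers are transitions
        return TRANSVERSION
    return TRANSITION


def parse_variant_token(token: str) -> MitoVariant:
    """Parse one nomenclature token into a :class:`MitoVariant`.

    Raises :class:`NomenclatureError` naming the token on malformed input
    or out-of-range positions.
    """
    m = _TOKEN_RE.match(token.strip())
    if m is None or not token.strip():
        raise NomenclatureError(f"malformed variant token {token!r}")
    back = bool(m.group("back"))
    if m.group("ins_pos") is not None:
        var = MitoVariant(
            position=int(m.group("ins_pos")),
            ref=m.group("ins_ref") or "",
            alt=m.group("ins_alt"),
            kind=BACK_MUTATION if back else INSERTION,
            insert_index=0 if back else int(m.group("ins_idx")),
        )
        if back:
            raise NomenclatureError(
                f"back-mutation of an insertion is written @<pos> not {token!r}"
            )
        return var
    if m.group("del_pos") is not None:
        if back:
            raise NomenclatureError(
                f"back-mutation of a deletion is written @<pos> not {token!r}"
            )
        return MitoVariant(
            position=int(m.group("del_pos")),
            ref=m.group("del_ref") or "",
            alt="",
            kind=DELETION,
        )
    pos = int(m.group("sub_pos"))
    ref = m.group("sub_ref") or ""
    alt = m.group("sub_alt") or ""
    if back:
        return MitoVariant(position=pos, ref=ref, alt=alt, kind=BACK_MUTATION)
    if not alt and not ref:
        # bare number: transition in figure shorthand
        return MitoVariant(position=pos, kind=TRANSITION)
    if not alt and ref:
        raise NomenclatureError(f"substitution token {token!r} lacks a derived base")
    return MitoVariant(position=pos, ref=ref, alt=alt, kind=_substitution_kind(ref, alt))


def parse_motif(motif: str, sample_id: str = "") -> "HaplotypeProfile":
    """Parse a hyphen-joined motif string like ``A73G-T152C-...``."""
    motif = motif.strip()
    if not motif:
        return HaplotypeProfile(sample_id=sample_id, variants=())
    variants = [parse_variant_token(t) for t in motif.split("-")]
    return HaplotypeProfile(sample_id=sample_id, variants=tuple(variants))


FULL_RANGE: tuple[tuple[int, int], ...] = ((1, MT_LENGTH),)


@dataclass(frozen=True)
class HaplotypeProfile:
    """One sample's differences from the rCRS over a covered range."""

    sample_id: str
    variants: tuple[MitoVariant, ...]
    covered_range: tuple[tuple[int, int], ...] = FULL_RANGE

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.variants, key=lambda v: v.site))
        object.__setattr__(self, "variants", ordered)
        seen: set[tuple[int, int]] = set()
        for v in ordered:
            if v.site in seen:
                raise NomenclatureError(
                    f"profile {self.sample_id!r}: two variants at site {v.site}"
                )
            seen.add(v.site)
            if not self.covers(v.position):
                raise NomenclatureError(
                    f"profile {self.sample_id!r}: variant {v.render()} outside "
                    f"covered range {self.covered_range}"
                )

    def covers(self, position: int) -> bool:
        return any(lo <= position <= hi for lo, hi in self.covered_range)

    @property
    def length_covered(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.covered_range)

    def tokens(self) -> tuple[str, ...]:
        return tuple(v.render() for v in self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


def render_motif(profile: HaplotypeProfile) -> str:
    """Hyphen-joined tokens in ascending position order."""
    return "-".join(profile.tokens())


# ---------------------------------------------------------------------------
# Exclusion policies

PHYLOGENY_HOTSPOTS = frozenset({16182, 16183, 16519})
DIVERSITY_DROP_TOKENS = frozenset({"16182C", "16183C"})
POLYC_515_524 = (515, 524)
POLYC_AROUND_310 = (302, 316)
INSERTION_HOTSPOT_16193 = 16193


@dataclass(frozen=True)
class ExclusionPolicy:
    """Which variants to ignore for a given analysis context.

    The ``phylogeny`` context removes the classical hotspot positions
    16182/16183/16519, indels in the 515-524 repeat, insertions at 16193
    and the poly-C variation around position 310 (implemented as indels
    and C-tract substitutions within 302-316).  The ``diversity`` context
    removes only the length-heteroplasmy-associated states 16182C/16183C
    near position 16189.
    """

    context: str
    drop_positions: frozenset[int] = frozenset()
    drop_tokens: frozenset[str] = frozenset()
    drop_ranges: tuple[tuple[int, int], ...] = ()

    def excludes(self, v: MitoVariant) -> bool:
        if v.position in self.drop_positions:
            return True
        token = v.render().lstrip("@")
        bare = f"{v.position}{v.alt}" if v.kind not in (INSERTION, DELETION) else token
        if token in self.drop_tokens or bare in self.drop_tokens:
            return True
        for lo, hi in self.drop_ranges:
            if lo <= v.position <= hi:
                if v.is_indel:
                    return True
                if (lo, hi) == POLYC_AROUND_310 and "C" in (v.ref, v.alt):
                    return True
        if self.context == "phylogeny" and v.kind == INSERTION and v.position == INSERTION_HOTSPOT_16193:
            return True
        return False


def phylogeny_policy() -> ExclusionPolicy:
    return ExclusionPolicy(
        context="phylogeny",
        drop_positions=PHYLOGENY_HOTSPOTS,
        drop_ranges=(POLYC_515_524, POLYC_AROUND_310),
    )


def diversity_policy() -> ExclusionPolicy:
    return ExclusionPolicy(context="diversity", drop_tokens=DIVERSITY_DROP_TOKENS)


def get_policy(name: str) -> ExclusionPolicy | None:
    if name == "phylogeny":
        return phylogeny_policy()
    if name == "diversity":
        return diversity_policy()
    if name in ("none", ""):
        return None
    raise ValueError(f"unknown exclusion context {name!r}")


def apply_exclusions(profile: HaplotypeProfile, policy: ExclusionPolicy | None) -> HaplotypeProfile:
    """Return a copy of ``profile`` with the policy's variants removed."""
    if policy is None:
        return profile
    kept = tuple(v for v in profile.variants if not policy.excludes(v))
    if kept == profile.variants:
        return profile
    return replace(profile, variants=kept)


def restrict_range(profile: HaplotypeProfile, lo: int, hi: int) -> HaplotypeProfile:
    """Keep only variants with lo <= position <= hi; covered_range becomes [lo, hi]."""
    if lo > hi:
        raise ValueError(f"inverted range {lo}..{hi}")
    if not (1 <= lo <= MT_LENGTH and 1 <= hi <= MT_LENGTH):
        raise ValueError(f"range {lo}..{hi} outside 1..{MT_LENGTH}")
    kept = tuple(v for v in profile.variants if lo <= v.position <= hi)
    return HaplotypeProfile(
        sample_id=profile.sample_id, variants=kept, covered_range=((lo, hi),)
    )


# ---------------------------------------------------------------------------
# VCF conversion

def _decompose_record(pos: int, ref: str, alt: str) -> list[MitoVariant]:
    """Express one VCF REF/ALT pair in mtDNA nomenclature.

    Left-aligned VCF indels map to the anchored convention: a deletion of k
    bases after anchor p becomes ``<p+1>d .. <p+k>d``; an insertion after p
    becomes ``<p>.1<bases>``.
    """
    out: list[MitoVariant] = []
    if len(ref) == len(alt):
        for i, (r, a) in enumerate(zip(ref, alt)):
            if r != a:
                out.append(
                    MitoVariant(position=pos + i, ref=r, alt=a, kind=_substitution_kind(r, a))
                )
        return out
    # trim the shared leading anchor
    shared = 0
    while shared < min(len(ref), len(alt)) and ref[shared] == alt[shared]:
        shared += 1
    if len(ref) > len(alt):
        if alt[:shared] != ref[:shared] or shared < len(alt):
            raise NomenclatureError(
                f"unsupported complex allele {ref}>{alt} at {pos}; decompose first"
            )
        # deletions are written per deleted position without the base
        # ("15322d"), the usual EMPOP rendering
        for i in range(len(ref) - shared):
            out.append(MitoVariant(position=pos + shared + i, ref="", alt="", kind=DELETION))
    else:
        if shared < len(ref):
            raise NomenclatureError(
                f"unsupported complex allele {ref}>{alt} at {pos}; decompose first"
            )
        anchor = pos + len(ref) - 1
        out.append(
            MitoVariant(
                position=anchor, ref="", alt=alt[shared:], kind=INSERTION, insert_index=1
            )
        )
    return out


def _pick_allele(genotype: Sequence[int | None], sample_id: str, pos: int) -> int:
    """Resolve a genotype to one allele index (major allele on ambiguity)."""
    alleles = [a for a in genotype if a is not None]
    if not alleles:
        return 0
    distinct = set(alleles)
    if len(distinct) > 1:
        counts: dict[int, int] = {}
        for a in alleles:
            counts[a] = counts.get(a, 0) + 1
        best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
        print(
            f"warning: heteroplasmic genotype for {sample_id} at {pos}; "
            f"taking allele {best}",
            file=sys.stderr,
        )
        return best
    return distinct.pop()


def vcf_to_profile(vcf_path: str, sample_id: str) -> HaplotypeProfile:
    """Convert one sample's mtDNA VCF calls into a :class:`HaplotypeProfile`.

    The VCF must be aligned to the rCRS (a declared mtDNA contig of length
    16569 is checked when the header carries one).  Heteroplasmic genotypes
    resolve to the major allele with a warning.
    """
    import pysam

    variants: list[MitoVariant] = []
    with pysam.VariantFile(vcf_path) as vcf:
        for contig in vcf.header.contigs.values():
            if contig.length is not None and contig.length != MT_LENGTH:
                raise NomenclatureError(
                    f"contig {contig.name} has length {contig.length}, "
                    f"expected rCRS length {MT_LENGTH}"
                )
        if sample_id not in vcf.header.samples:
            raise KeyError(f"sample {sample_id!r} not in VCF {vcf_path}")
        for rec in vcf:
            call = rec.samples[sample_id]
            idx = _pick_allele(call.allele_indices or (), sample_id, rec.pos)
            if idx == 0 or rec.alts is None:
                continue
            alt = rec.alts[idx - 1]
            variants.extend(_decompose_record(rec.pos, rec.ref, alt))
    return HaplotypeProfile(sample_id=sample_id, variants=tuple(sorted(variants, key=lambda v: v.site)))


def write_haplotype_table(profiles: Iterable[HaplotypeProfile], path: str) -> None:
    """Write the one-line-per-sample table: sample_id TAB motif."""
    with open(path, "w") as fh:
        for p in profiles:
            fh.write(f"{p.sample_id}\t{render_motif(p)}\n")


def read_haplotype_table(path: str) -> list[HaplotypeProfile]:
    profiles = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            sid, motif = parts[0], parts[1] if len(parts) > 1 else ""
            profiles.append(parse_motif(motif, sample_id=sid))
    return profiles
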