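import numpy as np
import pytest

from mitophylogeo.haplogroups import load_tree
from mitophylogeo.nomenclature import HaplotypeProfile, MitoVariant, _substitution_kind

HV9C_TREE = """\
root:
  HV9: T16311C
    HV9c: T6248C,@16311
      HV9c1: G5471A
"""

U7A4_TREE = """\
U7a4: T146C,T16126C
  U7a4a: C16148T
    U7a4a1: T195C,T6221C
      U7a4a1a: A16318C
        U7a4a1a1: C8574T
          U7a4a1a1a: G16213A
      U7a4a1b: T143C,C12063T,A15322G
"""


@pytest.fixture
def hv9c_tree():
    return load_tree(HV9C_TREE)


@pytest.fixture
def u7a4_tree():
    return load_tree(U7A4_TREE)


def random_profile(rng: np.random.Generator, n: int = 8, sample_id: str = "x") -> HaplotypeProfile:
    """A random substitution-only haplotype profile."""
    positions = rng.choice(np.arange(1, 16570), size=n, replace=False)
    variants = []
    for pos in sorted(int(p) for p in positions):
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        variants.append(
            MitoVariant(position=pos, ref=str(ref), alt=str(alt), kind=_substitution_kind(ref, alt))
        )
    return HaplotypeProfile(sample_id=sample_id, variants=tuple(variants))
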