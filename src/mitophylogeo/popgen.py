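"""Population-level summary statistics over mtDNA haplotypes.

Distances between haplotypes are raw counts of differing sites (the
"pairwise difference" molecular distance), computed over the shared covered
range after range restriction and the diversity exclusion filter have been
applied upstream.  On top of that distance the module provides:

* haplotype diversity (HD), nucleotide diversity (pi) and the mean number
  of pairwise differences (M), with the exact relation M = pi * L;
* pairwise Phi_ST from a two-level AMOVA on squared distances, with the
  Excoffier variance-component estimators and an optional clamp of
  negative estimates to zero;
* classical (metric) multidimensional scaling of a distance matrix with
  per-dimension variance fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .nomenclature import HaplotypeProfile, render_motif


@dataclass
class PopulationSet:
    """A labelled collection of haplotypes sharing a covered range."""

    label: str
    profiles: list[HaplotypeProfile]
    region: str = ""

    def __post_init__(self) -> None:
        ranges = {p.covered_range for p in self.profiles}
        if len(ranges) > 1:
            raise ValueError(
                f"population {self.label!r} mixes covered ranges {ranges}"
            )

    @property
    def n(self) -> int:
        return len(self.profiles)

    @property
    def length_covered(self) -> int:
        if not self.profiles:
            raise ValueError("empty population")
        return self.profiles[0].length_covered


def haplotype_distance(a: HaplotypeProfile, b: HaplotypeProfile) -> int:
    """Number of sites at which two haplotypes differ (same site with a
    different derived allele counts once)."""
    sa = {v.site: (v.kind, v.alt) for v in a.variants}
    sb = {v.site: (v.kind, v.alt) for v in b.variants}
    d = 0
    for site, state in sa.items():
        if sb.get(site) != state:
            d += 1
    for site in sb:
        if site not in sa:
            d += 1
    return d


def distance_matrix_of(profiles: Sequence[HaplotypeProfile]) -> np.ndarray:
    n = len(profiles)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = haplotype_distance(profiles[i], profiles[j])
    return d


@dataclass(frozen=True)
class DiversityReport:
    HD: float
    pi: float
    M: float
    n: int
    L: int


def diversity(pop: PopulationSet) -> DiversityReport:
    """HD, pi and M for one population.

    HD = n/(n-1) * (1 - sum p_k^2) over haplotype frequencies;
    M = mean pairwise difference count; pi = M / L over the covered length.
    """
    n = pop.n
    if n < 2:
        raise ValueError("diversity needs at least 2 haplotypes")
    keys: dict[str, int] = {}
    for p in pop.profiles:
        k = render_motif(p)
        keys[k] = keys.get(k, 0) + 1
    freqs = np.array(list(keys.values()), dtype=float) / n
    hd = n / (n - 1) * (1.0 - float(np.sum(freqs**2)))
    d = distance_matrix_of(pop.profiles)
    m = float(d[np.triu_indices(n, k=1)].mean()) if n > 1 else 0.0
    L = pop.length_covered
    return DiversityReport(HD=hd, pi=m / L, M=m, n=n, L=L)


# ---------------------------------------------------------------------------
# Phi_ST (two-population AMOVA on pairwise differences)

def pairwise_phist(
    a: PopulationSet, b: PopulationSet, clamp_negative: bool = True
) -> float:
    """Phi_ST between two populations from the AMOVA variance components.

    With N = n_a + n_b and squared pairwise distances d^2:
    SS_total = sum over all pairs d^2 / N (each unordered pair once),
    SS_within the analogous within-population sums over n_pop,
    sigma2_within = SS_within / (N - 2),
    sigma2_among = (SS_among/(P-1) - sigma2_within) / n' with
    n' = (N - (n_a^2 + n_b^2)/N) / (P - 1), P = 2.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("each population needs at least 2 haplotypes")
    if a.profiles[0].covered_range != b.profiles[0].covered_range:
        raise ValueError("populations cover different ranges")
    profiles = a.profiles + b.profiles
    n_a, n_b = a.n, b.n
    N = n_a + n_b
    d = distance_matrix_of(profiles)
    d2 = d**2

    def ss(block: np.ndarray, size: int) -> float:
        iu = np.triu_indices(block.shape[0], k=1)
        return float(block[iu].sum()) / size

    ss_total = ss(d2, N)
    ss_within = ss(d2[:n_a, :n_a], n_a) + ss(d2[n_a:, n_a:], n_b)
    ss_among = ss_total - ss_within
    P = 2
    sigma2_within = ss_within / (N - P)
    n_prime = (N - (n_a**2 + n_b**2) / N) / (P - 1)
    sigma2_among = (ss_among / (P - 1) - sigma2_within) / n_prime
    denom = sigma2_among + sigma2_within
    if denom <= 0:
        return 0.0
    phist = sigma2_among / denom
    if clamp_negative and phist < 0:
        return 0.0
    return float(phist)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in parts[1:]])
        return cls(labels=header, values=np.array(rows))


def fst_matrix(
    pops: Sequence[PopulationSet], clamp_negative: bool = True
) -> DistanceMatrix:
    """All pairwise Phi_ST values as a symmetric zero-diagonal matrix."""
    labels = [p.label for p in pops]
    if len(set(labels)) != len(labels):
        raise ValueError("population labels must be unique")
    n = len(pops)
    values = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        values[i, j] = values[j, i] = pairwise_phist(
            pops[i], pops[j], clamp_negative=clamp_negative
        )
    return DistanceMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# Classical MDS

@dataclass
class MDSResult:
    labels: list[str]
    coordinates: np.ndarray          # (n_labels, k)
    eigenvalues: np.ndarray          # all, descending
    variance_fraction: np.ndarray    # per retained dimension


def classical_mds(d: DistanceMatrix, k: int = 2) -> MDSResult:
    """Classical (Torgerson) scaling: eigendecomposition of the
    double-centred squared-distance matrix.

    Coordinates are the top-k eigenvectors scaled by sqrt(eigenvalue);
    variance fractions are eigenvalues over the sum of positive
    eigenvalues.  Signs are fixed so each dimension's first nonzero
    loading is positive.
    """
    n = len(d.labels)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < {n}")
    D2 = d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    pos_sum = float(eigval[eigval > 1e-12].sum())
    coords = np.zeros((n, k))
    fractions = np.zeros(k)
    for j in range(k):
        lam = eigval[j]
        if lam > 1e-12:
            axis = eigvec[:, j] * np.sqrt(lam)
            nz = np.flatnonzero(np.abs(axis) > 1e-12)
            if nz.size and axis[nz[0]] < 0:
                axis = -axis
            coords[:, j] = axis
            if pos_sum > 0:
                fractions[j] = lam / pos_sum
    if pos_sum == 0:
        import warnings

        warnings.warn("all eigenvalues are zero; variance fractions undefined")
    return MDSResult(
        labels=list(d.labels),
        coordinates=coords,
        eigenvalues=eigval,
        variance_fraction=fractions,
    )
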