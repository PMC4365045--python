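# Methods

This note documents the models and procedures implemented in
`mitophylogeo`, the parameter choices that matter, what the synthetic-data
generator does and does not emulate, and the numerical details a user
re-deriving our results would need.

## Variant nomenclature and filtering

All coordinates are 1-based rCRS positions (1..16569); there is no 0-based
interface anywhere. Two token dialects are parsed: the full EMPOP form
with the reference base (`T6248C`) and the tree-figure shorthand without
it (`16311` = transition, `16318C` = transversion, per the convention that
a trailing base letter marks a transversion). Both render back to exactly
the form they were parsed from, so parse∘render is the identity on
well-formed input (property-tested on 1000 random profiles).

VCF conversion maps left-aligned records into the anchored mtDNA
convention: a deletion of k bases after anchor p becomes `p+1 d … p+k d`
(one `d` token per deleted position, written without the base, the usual
EMPOP rendering), and an insertion after p becomes `p.1<bases>`. We fix
this dialect deliberately — community practice varies on 3'-realignment
of indels in homopolymer tracts, and the anchored left-aligned form is
reproducible without reference to surrounding context. Heteroplasmic
genotypes resolve to the major allele with a warning (configurable at the
call site); point and length heteroplasmies play no further role.

Two exclusion contexts are bundled:

* **phylogeny** — positions 16182, 16183, 16519; indels within 515–524;
  insertions at 16193; and the poly-C variation around position 310,
  implemented as indels plus C-tract substitutions within 302–316. The
  310 region is not enumerated in the sources this follows, so the
  302–316 interval is our fixed rendering of standard poly-C treatment.
* **diversity** — the length-heteroplasmy-associated states 16182C and
  16183C only. Position 16189 itself is retained: only the two C states
  adjacent to it are canonical length-heteroplasmy artefacts.

## Haplogroup classification

The tree is a rooted phylogeny whose branches carry defining variants; a
node's cumulative state is its root path's edits with `@` back mutations
reverting sites. Classification scores every node as the mean of path
recall |E∩P|/|E| and profile precision |E∩P|/|P| (a symmetric
Kulczynski-type index), with E restricted to the profile's covered range.
Conventions: an empty E or P contributes 1 to its term (so a bare root
neither matches nor contradicts); an expected variant countered by an
observed `@` token counts as missing, not private; ties prefer the deeper
node, then the lexicographically smaller name — matching the practice of
reporting the most derived defensible label. The full ranked list is
returned; no manual-curation layer is emulated.

Sub-haplogroup discovery proposes a child clade for every maximal set of
≥2 distinct genomes sharing ≥1 derived variant (relative to the parent
state) at a mutationally stable position; proposals whose member sets nest
become nested nodes, and names follow the PhyloTree letter/digit
alternation. "Stable" means: not in the bundled unstable set (the three
classical hotspots, the 515–524 and 302–316 poly-C tracts, 16189, 16193).
A finer per-position rate table can be passed in instead.

Motif database search matches a query state against records on a shared
range at 0 steps (exact) or exactly 1 step (one variant added, absent, or
with a substituted allele); queries may carry per-site alternative alleles
(`A16318T/A16318C`), which match either state. Clade-origin flagging
returns the region holding ≥50% (configurable) of the clade's non-home
members; the ancestry component is the percentage of samples whose best
node is a flagged clade or one of its descendants.

## Clade dating

ρ is the mean mutational distance from the clade root over sampled
members; its heuristic standard error is σ² = Σ_b m_b (n_b/n)², the
branch counts weighted by squared subtended-sample fractions. Given the
genealogy's topology this is an unbiased estimator of Var(ρ): writing
ρ = Σ_b m_b·n_b/n, each branch's Poisson count variance enters weighted
by the squared fraction of samples it subtends. Ages are ρ·(years/mutation) with a symmetric ρ±1.96σ interval floored
at zero years.

Clocks are explicit constants, never inferred: the default
`soares-complete` clock is one mutation per 3,624 years for complete
mitogenomes (the purifying-selection-corrected whole-molecule rate in
standard use); `hvs1-transitions` is the classical control-region
transition clock of 20,180 years per transition for HVS-I-only
genealogies. The time-dependence of the corrected rate is *not*
re-implemented; the correction is absorbed into the constant, which is a
documented limitation for clades far from the calibration range.

The ML alternative assumes a strict clock on the given rooted topology:
leaves at time 0, node ages maximising Σ_b [m_b log(μΔt_b) − μΔt_b].
Internal node ages are parametrised as fractions of their parent's age
(guaranteeing order constraints) and optimised with L-BFGS-B from a
deterministic ρ-based starting point; the root age is then profiled with
a bounded scalar optimiser. The 95% interval is the profile-likelihood
set within 1.92 log-units of the maximum, bracketed by bisection. The
all-zero-count genealogy returns age 0 with the likelihood-only upper
bound 1.92/(μn).

**Calibration caveat.** On star genealogies the ρ±1.96σ interval attains
nominal coverage (95.8% measured over 500 replicates). On Yule
genealogies of the same age it covers the truth in only ~87% of
replicates: σ correctly estimates the sd of ρ (rms σ 0.898 vs empirical
sd 0.908 over 800 replicates), but shared internal branches make the
distribution of ρ right-skewed, and the symmetric normal-form interval is
anti-conservative — the documented behaviour of ρ-based confidence
intervals on structured genealogies. Users dating non-star clades should
treat the ρ CI as optimistic and prefer the ML profile interval.

## Population statistics

Haplotype distance is the raw count of differing sites (one per site, a
shared-site allele difference counting once); no substitution model is
applied, matching the default "pairwise difference" molecular distance of
the standard AMOVA implementation. Diversity over a population of n
haplotypes on a shared covered length L: HD = n/(n−1)(1−Σp_k²), M = mean
pairwise distance, π = M/L, so π·L = M holds exactly by construction.

Pairwise ΦST uses the two-level AMOVA variance decomposition on squared
distances: SS terms as Σd²/(group size) over unordered pairs,
σ²_within = SS_within/(N−2), σ²_among = (SS_among − σ²_within)/n′ with
n′ = (N − (n_a²+n_b²)/N), and ΦST = σ²_among/(σ²_among+σ²_within).
Negative estimates clamp to 0 by default (disable with
`clamp_negative=False`) so the matrix remains a valid distance input for
scaling; both clamped and raw modes are exposed because published
matrices differ in this respect.

Classical MDS double-centres the squared-distance matrix,
B = −½·J·D²·J, takes the top-k eigenpairs, scales eigenvectors by √λ and
reports λ_j/Σ_{λ>0}λ as the variance fraction per dimension. Signs follow
a deterministic convention (first nonzero loading positive); dimensions
with non-positive eigenvalues get zero coordinates and fractions. The
implementation is cross-checked in the tests against an independent
principal-coordinates implementation (scikit-bio) to 1e−8.

## Frequency surfaces

Distances are great-circle (haversine, R = 6371 km): the regions of
interest span tens of degrees of longitude, where planar approximations
distort. The empirical variogram bins half squared value differences by
pair distance; models (spherical or exponential, the exponential using
the effective-range convention γ(range) ≈ 0.95·sill) are fitted by least
squares weighted by √(pair count), with the nugget fixable at 0.
Ordinary kriging solves, per grid cell, the (n+1)-dimensional system with
the unit-sum Lagrange constraint, via one LU factorisation of the sample
matrix reused across cells. With a zero nugget the predictor is exact at
sample sites (asserted to 1e−10), and weight sums are tracked and
reported (max |Σw−1| over the grid). Frequency predictions are clipped to
[0,1] only at the reporting layer (`GeoSurface.clipped`), never inside
the solver. Duplicate sample locations fail by default (singular system)
with an opt-in ~1 m jitter.

## Synthetic data: what it emulates, and what it does not

The generator stands in for a real resequencing cohort. Its defaults are
the study conditions of the analysis this package replicates: 110 samples
in the admixed study population, a source-region admixture fraction of
0.082, the 3,624 yr/mutation whole-molecule clock, Yule genealogies (real
clades are not stars; a star switch exists for calibration tests), and a
clade age of 8,000 years where one is needed.

Haplotypes evolve down a branching genealogy conditioned to a fixed root
age (exponential inter-split waits rescaled to the target depth, a random
lineage splitting each time). Mutation counts on each branch are
Poisson(duration/3,624) at stable positions drawn uniformly; recurrent
hits revert the site. Hotspot variation is generated as a *separate*
additive Poisson stream (default 0.15 hotspot hits per clock mutation,
with the three classical hotspots 50× more mutable than the rest of the
unstable set): the calibrated clock thus counts exactly the mutations
that survive the phylogeny filter, mirroring practice — hotspots are
excluded before dating — while still giving the exclusion machinery
something to remove. Genealogy branch counts are therefore stable-position
counts; leaf profiles carry both streams.

The sequence backdrop is a synthetic 16,569-bp reference (fixed-seed
random bases, overridden wherever a variant token names its reference
base). It is *not* the rCRS sequence; it exists so that VCF fixtures have
consistent REF/ALT columns and round-trip exactly. Consequences: base
composition, codon structure, the true hotspot spectrum, heteroplasmy,
and sequencing error are not emulated, and indels are not simulated
(indel handling is exercised by targeted token-level fixtures). Passing
tests therefore demonstrate the correctness of the statistical machinery
and bookkeeping on data with known truth — not robustness to
caller-specific VCF quirks or to real mutational rate heterogeneity
beyond the bundled hotspot set.

The admixed-study generator draws each sample's haplogroup from the
source pool with probability 0.082 and otherwise from the local pool,
then adds a small private-mutation load (default 1,500 years' worth) on
top of the haplogroup's cumulative state. The bundled toy tree (31 nodes)
uses published defining motifs for the clades it shares with the real
mtDNA phylogeny and synthetic variants elsewhere; it is a test harness,
not a PhyloTree substitute. All randomness flows from the single
configured seed.

## Problem sizes

The validation suite and the acceptance script use: 500 replicate clades
of 15 leaves for dating calibration (clade sizes in the replicated study
run ~9–27 members, so 15 is representative), 200 replicate studies of 110
samples for end-to-end admixture recovery, 12–16 geographic sites on
15–20-point grids for kriging, and populations of ~24 haplotypes for
ΦST/MDS. These sizes give Monte-Carlo standard errors well inside the
assertion tolerances while keeping a full run in the low minutes on one
CPU.

## Known limitations

* ρ confidence intervals are anti-conservative on non-star genealogies
  (see the calibration caveat above); this is a property of the
  estimator, not of the implementation.
* The ML dater assumes the given topology and branch counts are correct;
  it does not integrate over genealogical uncertainty and does not use
  outgroups (the root is taken as given).
* Clock constants are fixed inputs; no rate time-dependence, site
  heterogeneity or relaxed clock.
* ΦST supports two populations per comparison (pairwise matrices of any
  size); no multi-group AMOVA, no permutation significance testing.
* Kriging is univariate ordinary kriging on a lon/lat grid without map
  projection; no co-kriging, no anisotropy.
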