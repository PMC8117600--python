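# Methods

## Standardization pipeline

A molecule enters as a raw SMILES string and passes through: parse →
largest fragment (salt stripping) → neutralization → stereochemistry
removal → canonicalization → Bemis–Murcko scaffold extraction → property
and substructure filters. Unparseable strings are an expected outcome
(generators emit them) and map to an invalid marker rather than an error.

One canonical dialect — RDKit canonical SMILES with stereochemistry
removed — is used for every string comparison in the package: uniqueness,
novelty, recovery, blocklist matching. Mixing dialects (or leaving
stereochemistry in some sets) silently breaks all cross-set counts, so the
dialect is fixed at the lowest level and tested for idempotence.

Neutralization adds or removes protons on charged atoms matched by the
standard pattern `[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]`:
positive centres carrying at least one hydrogen are deprotonated, negative
centres not adjacent to a compensating positive centre are protonated.
Quaternary nitrogens (no removable proton) and internally compensated
zwitterion pairs are left unchanged, and the heavy-atom skeleton is never
modified. The operation is idempotent.

Filters and defaults: molecular weight 250–350 Da, ≤ 8 rotatable bonds,
logP ≤ 3.5, elements ⊆ {C, N, S, O, F, Cl, Br, H}, no ring larger than 8
atoms, PAINS alerts (RDKit filter catalog), and a small configurable
medicinal-chemistry SMARTS alert list (reactive/unstable groups: azo,
acyl halides, epoxides, nitro, isocyanates, …). The logP rule uses the
Crippen estimator; curations built on XlogP will disagree near the 3.5
boundary, a deliberate trade of fidelity for a reproducible open
implementation. The verdict names every failed rule, so downstream audits
can distinguish a weight failure from an alert hit.

## Similarity substrate

Binary Morgan fingerprints, radius 2 folded to 1024 bits, everywhere. A
fingerprint set is a boolean matrix, and all pairwise similarity is
computed as integer matrix products (|A∩B| = A·Bᵀ), which keeps the @1k
workloads (10⁶ pairs) in tens of milliseconds. Tanimoto similarity of two
all-zero fingerprints is defined as 1.0: they encode the same empty
feature set, and the choice avoids 0/0. The only molecule that produces an
all-zero fingerprint in practice is the empty pseudo-scaffold of acyclic
molecules, where "all acyclic molecules share one scaffold" is exactly the
intended semantics.

## Sphere-exclusion diversity

The leader algorithm scans fingerprints in input order; a molecule is
picked as a centroid iff its Tanimoto distance to every previously picked
centroid is strictly greater than the sphere radius. Strictness at the
boundary is enforced with a 1e-9 epsilon: Tanimoto distances on 1024-bit
vectors are rationals whose floating-point images can straddle the radius
in either direction, and adjacent attainable distance values differ by far
more than 1e-9, so the epsilon resolves representation noise without ever
reordering true comparisons.

SEDiv = picks / evaluated set. The metric is defined on the
valid-and-unique subset of a sample; duplicates are a property of the
sample (and lower the value toward 1/N), which the run tracker exploits —
but the function itself evaluates whatever it is given, so the degenerate
1/N case is reachable and tested. When a subsample size k is configured
(default 1000, the @1k convention) and the input exceeds k, a seeded
uniform subset is evaluated and the result records the evaluated size,
the subsample flag and the seed.

Sphere radius defaults: 0.65 distance for molecules, 0.2 for scaffolds.
0.65 is the radius at which co-membership of a sphere broadly predicts
shared bioactivity class, which is what gives SEDiv its reading as "the
minimum fraction of the set needed to explain its bioactivity-relevant
diversity". Internal diversity is 1 − mean of the full pairwise
similarity matrix *including the diagonal*, so an all-identical set scores
exactly 0; the diagonal convention is stated because the alternative
(excluding it) changes small-set values materially.

Clustering reuses the same picks: every molecule is assigned to its
nearest centroid by Tanimoto distance, ties broken toward the
earliest-picked centroid (argmax over centroids in pick order). Cluster
sizes therefore always sum to the input size, and every molecule is within
the radius of some centroid or is itself a centroid.

Scaffold metrics: uniqueness = |unique scaffold strings| / |records|;
scaffold diversity = SEDiv over fingerprints of the unique scaffolds at
the 0.2 scaffold radius. The latter definition is this package's declared
convention for "scaffold diversity".

## Generative metrics and the run tracker

validity = valid/total, uniqueness = unique/valid, novelty =
novel/unique, each absent when its denominator is zero; the counts are
nested by construction. Recovery probability is exact canonical-string
matching of a sample's valid-and-unique molecules against canonicalized
active/inactive reference sets, one probability per independent sample;
active bias is mean P(active) / mean P(inactive) on unrounded
probabilities, and fold change is the bias ratio against a baseline
report. A zero inactive probability with non-zero active probability
yields an infinite bias with an explicit flag rather than an exception.

Analogue coverage uses an inclusive threshold (Tanimoto ≥ 0.4): the
generated-side fraction counts molecules with at least one reference
analogue, the reference-side fraction counts references with at least one
generated analogue. The two sides answer different questions (analogue
mass vs breadth of coverage) and deliberately travel together.

The run tracker consumes an ordered (step, batch) stream and reports at
every multiple of `every` (default 100 steps) on the molecules accumulated
since the previous report — per-interval, not cumulative, so a late-run
collapse is visible rather than averaged away; a `cumulative` flag offers
the alternative. Each report carries validity/uniqueness/novelty plus
SEDiv, internal diversity, scaffold uniqueness/diversity and (optionally)
mean single-nearest-neighbour similarity to a reference set, all computed
on the interval's valid-unique molecules subsampled to the configured @k
with the recorded seed.

## Retrospective classification and overlap analysis

Docking scores: lower is better; a threshold t predicts active iff score
≤ t (inclusive — lowering t is the stricter criterion). The sweep
computes confusion counts per threshold, accuracy with the standard
denominator TP+FP+TN+FN, precision and recall (absent, not zero, when
undefined), and the best-accuracy threshold with ties broken toward the
most stringent threshold. Recall is monotone in t by construction.

Cluster overlap pools named fingerprint sets in dataset order, clusters
the pool (sphere exclusion + nearest centroid; no subsampling), then flags
each cluster for every dataset contributing ≥ 1 member. Venn-region counts
partition the clusters by exact membership pattern and sum to the cluster
total. The pooled order is fixed so results are reproducible; renaming
datasets permutes but never changes the counts.

Score distributions are compared with Welch's unequal-variance t-test,
one-tailed, and Bonferroni adjustment (adjusted p = min(1, m·p)) for a
declared family size m. Welch-plus-Bonferroni is the conservative choice
for unequal-variance score samples compared several ways; the method name
travels in the result object. Two constant, equal samples leave t
undefined and are flagged degenerate.

## SIFt collapse and deltas

A raw SIFt row is nine non-exclusive bits per residue: any contact,
backbone, sidechain, polar, hydrophobic, HB acceptor, HB donor, aromatic,
charged. Collapse precedence: charged+HB donor → charged_hbd; charged+HB
acceptor → charged_hba; HB donor → hbd; HB acceptor → hba; charged;
aromatic; hydrophobic; polar; any location-only pattern → contact_only;
all-zero → none. Donor outranks acceptor when both HB bits are set — the
hierarchy groups "donor/acceptor" jointly, so this tie-break is a
convention of this package, not an externally fixed rule. The collapse is
total over all 512 patterns (enumerated in tests). Backbone/sidechain
carry location rather than chemistry and never influence the type.

Frequencies are per-residue fractions of molecules per exclusive type
(rows sum to 1 including `none`); deltas against a baseline are absolute
frequency differences (percentage points), flagged at ±10 points
inclusive, with a `relative` mode for ratio changes where the baseline is
non-zero. A 1e-12 tolerance keeps the inclusive flag boundary robust to
float subtraction.

## Synthetic data: what it emulates and what it does not

The scaffold-series library generator crosses 8 curated template cores
(one substituent slot each) with ~150 small substituents. The pools were
curated so that under Morgan(2, 1024) Tanimoto similarity every pair of
molecules sharing a core is within the 0.65-distance sphere (min
intra-series similarity ≈ 0.47) and molecules from different cores are
beyond it (max cross-series similarity ≈ 0.34). A library of k cores
therefore has SEDiv exactly k/n by construction, which is what makes the
design-recovery tests exact rather than statistical. Decorations are
sampled with a seeded permutation and deduplicated on canonical SMILES;
identical spec + seed reproduces the library byte for byte.

The score generator draws labelled Gaussians; its default moments
(actives −7.45 ± 1.01, baseline generator −6.17 ± 1.02, docking-optimized
generator −8.05 ± 0.95) are realistic values for a dopamine-receptor
docking campaign and are parameterization, not ground truth. Real docking
score distributions are heavier-tailed than Gaussians, so tail-sensitive
quantities (precision at stringent thresholds) run a few points optimistic
relative to empirical data.

The SIFt generator draws independent Bernoulli bits per cell; real
interaction bits are strongly correlated (a hydrogen bond implies a
contact), so it exercises the counting and collapse machinery, not
chemical realism.

The run-stream generator emulates a training generator. The stable
profile samples every batch uniformly from the full library; the
collapsing profile linearly shrinks the number of scaffold series sampled
from (8 down to 2 across the run), so per-interval uniqueness and SEDiv
decline monotonically in expectation — the overfitting signature of an
agent that resamples known high-reward molecules. The construction makes
the decline a guarantee rather than a tendency, which is what the dynamics
tests need; the trade-off is that the SEDiv decline is modest in absolute
terms (the metric's level is set by series count over evaluated-set size),
while the uniqueness decline is large. Passing these tests shows the
tracker recovers engineered dynamics; it does not show how a particular
real generator behaves.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for interactive runs: oracle
cross-checks use ≤ 30 random 64-bit fingerprints per set (hundreds of
sets), design-recovery libraries 300–500 molecules, sweeps 4–15k scores,
and tracked streams 300 steps × 64 molecules with reports every 100 steps;
the retrospective sweep in the acceptance script uses 4613 actives vs
10,000 inactives, mirroring a realistic class imbalance. All randomness
flows through explicit integer seeds (numpy default_rng); there is no
hidden global state.

Known limitations: the medicinal-chemistry alert list is a small stand-in
for proprietary curations; Crippen logP differs from XlogP near the filter
boundary; SEDiv at @1k has subsampling noise of roughly ±0.01 for
mid-range values, so single-run comparisons below that resolution are not
meaningful; and the collapse tie-break (donor over
acceptor) is a convention that downstream consumers comparing against
other SIFt tooling should be aware of.
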