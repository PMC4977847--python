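# Methods

## Duplex model

`mirx.hybridize` scores one contiguous, purely intermolecular duplex between
a miRNA (5′→3′) and a target region read antiparallel. The structure space
is all non-crossing pairings over the six admissible pair types (A:U, U:A,
C:G, G:C, G:U, U:G); there are no multiloops and no intramolecular
structure, matching the hybridization-only model of duplex-prediction tools.
The energy of a structure is

ΔG = Σ stack(pᵢ, pᵢ₊₁) + Σ bulge(ℓ) + Σ loop(ℓ₁, ℓ₂) + 2 × end,

with a Turner-style nearest-neighbor stack table (Watson–Crick stacks −0.93
to −3.42 kcal/mol, G:U-containing stacks −0.40 to −2.51), linear penalties
bulge(ℓ) = 3.8 + 0.5ℓ and loop(ℓ₁, ℓ₂) = 4.0 + 0.3(ℓ₁+ℓ₂) kcal/mol, and a
helix-end penalty of 0.45 kcal/mol per duplex end. The table lives in a
versioned YAML file (`mirx/data/energy_v1.yaml`) and is enforced to respect
the 180° rotation symmetry stack(p, q) = stack(rot q, rot p); values can be
swapped without code changes. The table is a self-contained simplification:
bit-exact agreement with any external folding tool is a non-goal, and no
coaxial, dangling-end or loop-asymmetry terms are modeled.

The minimum is found by a dynamic program over cells (i, j) = "the 3′-most
miRNA pair is miRNA i with target j", numba-compiled, with full traceback.
Between consecutive pairs a gap of (a, b) unpaired bases scores as a stack
(0,0), bulge (one-sided) or internal loop (two-sided); caps on bulge length
and loop side length are pruned inside the DP. `duplex_mfe` with `caps=None`
searches the unconstrained space and is checked exactly (|Δ| < 1e−9)
against `mirx.reference.enumerate_duplex_mfe`, an explicit recursion over
all admissible pairings. A single base pair scores 2 × end = +0.9 kcal/mol,
so isolated pairs are never reported as hits; sequences with no admissible
pair return an infinite-energy sentinel rather than raising.

`scan_transcript` runs one DP over the whole region instead of literal
40-nt sliding windows: every target position is a candidate 5′ anchor, and
overlapping candidates are reduced to local minima (lowest MFE wins, ties
to the leftmost site), which is the windowed procedure's overlap rule
without its redundant recomputation. When no profile caps are given the
scan bounds the search at 15 nt per bulge and per loop side — wider than
any biologically sensible duplex gap and wider than the plant caps — so the
"uncapped" human profile remains tractable. Only sites below `report_max`
(default −10 kcal/mol in the pipeline, 0 in the API) are materialized.

Coordinates are 0-based half-open on the region; seed terminology uses
1-based miRNA positions. The seed rule requires miRNA positions 2–8 (7 nt)
each Watson–Crick paired — G:U wobble does not count — to contiguous target
bases. This is the canonical reading of a "first two to eight bases" perfect
core match; tolerating wobble in the seed would be a one-line change in
`seed_match`.

## Empirical p-values

The p-value of a hit is P(ΔG_null ≤ ΔG_hit) under a minimum-Gumbel law,
CDF 1 − exp(−exp((x − μ)/β)), fitted by the method of moments
(β = √(6·Var)/π floored at 1e−6, μ = mean + γβ) to the best duplex energies
of ≥ 100 dinucleotide-preserving shuffles (Altschul–Erickson Euler-path
shuffle) of 40-nt windows sampled uniformly from the scanned regions. Each
miRNA gets its own calibration with a seed derived from the run seed.
Gumbel is the standard asymptotic family for extremes of alignment-like
scores; the pooled best-of-window null is not exactly Gumbel, so a single
calibration's uniformity error (KS sup-distance) is typically 0.03–0.09 at
n = 500. The adequacy check therefore pools fresh null scores across all 25
calibrations (20 each, n = 500), where the KS distance sits at 0.02–0.07
across run seeds. An all-equal null (e.g. homopolymer windows) degenerates
to a step function at μ via the β floor; a null with no admissible pairing
at all raises `CalibrationError`.

## Screening and validation

`FilterProfile` holds the cascade thresholds: ΔG ≤ −25 kcal/mol (the
stability range of authentic miRNA:target pairs; the bound is inclusive),
p ≤ 0.05 (the p cutoff default is a configurable choice with no canonical
value), a required perfect seed, and — in the
plant profile only — internal loop ≤ 5 nt per side and bulge ≤ 9 nt,
measured on the traceback pairing rather than re-derived from energies.
Hits without a calibrated p-value are not filtered on p. Filtering is
idempotent and monotone (relaxing any threshold yields a superset).

Ranking within one miRNA is by p ascending, then ΔG ascending, then gene
id / region / site start as a deterministic tie-break (p and ΔG carry the biological meaning; the remaining keys exist only to
make ranks a total order). Three-level validation checks each known (miRNA, gene, region)
triple for presence in the input mRNA set, among primary predictions in the
validated region, and among post-screen targets, attaching the per-miRNA
rank of surviving hits; `in_refined ⇒ in_primary ⇒ in_mrna_set` is enforced
on every record. Ranks are per miRNA (not pooled across miRNAs), so a target's rank is always relative to the other predictions of the
same miRNA.

## Network weighting and modules

The interaction graph is undirected and simple (duplicate edges collapsed,
self-loops dropped). The default weighting iterates B ← A·B from B₀ = 1.
Iterating the raw adjacency diverges whenever the spectral radius exceeds
1, so the total is renormalized to N after every multiplication — power
iteration, whose fixed point is the Perron eigenvector of A scaled to sum
N. Convergence is declared when max|ΔB| < tol (default 0.005); the
iteration count depends on the spectral gap of the graph and is reported,
not asserted. A standard
damped PageRank (d = 0.85, dangling mass redistributed uniformly, same
sum-N scale) is available as `mode="damped"` and is cross-checked against
networkx's implementation in the tests. Degenerate cases: a graph with no
edges is returned at its initial weights; isolated nodes in a graph that
has edges end at weight 0 in the eigenvector mode and retain the teleport
share in the damped mode.

Bridges are the top-k weights (k = 15), ties broken by degree then id.
Deleting them leaves connected components; components with ≥ 3 members
become modules `M1, M2, …` (ordered by size, then lexicographically
smallest member) and smaller ones are reported as residue rather than
silently dropped — tiny fragments left over after hub deletion are
uninformative for enrichment, and the threshold is explicit and
configurable. Each module also records its *central* bridges:
the deleted genes adjacent to any member in the original graph.

## Enrichment, slim grouping, similarity, tissue tiers

Per-module over-representation uses the upper-tail hypergeometric
P(X ≥ k | N, K, n) with the complete network as background N. Annotations
are propagated up is_a ancestors before testing (true-path rule;
switchable, since it changes the counts). Benjamini–Hochberg runs within
each module across all background-annotated terms, and findings with
adjusted p < 0.1 are reported. Only over-representation is tested. Slim
grouping maps each term to every generic category reachable via is_a
(a slim term maps to itself; unreachable terms land in an explicit
`unclassified` bucket), and cross-species functional similarity is the
Jaccard and overlap coefficient of two category support sets.

Tissue tiers over the eight tissues (brain, heart, kidney, liver, lung,
spleen, stomach, small intestine): expressed means value > 1.0 (detection
threshold, arbitrary units of the input matrix); ubiquitous = expressed in
≥ 7 of 8; specific = exactly 1; high = 2–6 tissues with cross-tissue
z-score > 1. Both thresholds are invented plumbing (the study names the
three levels without formulas) and are exposed in the config. Genes
expressed in 2–6 tissues at a flat level have max z ≤ 1 by arithmetic and
fall into `unclassified`; the tier definition presumes a peaked profile.

## Synthetic data: what it does and does not emulate

Each generator is a pure function of (config, seed) with per-generator RNG
streams, and emits a truth table sufficient to score its downstream stage.

* **Sequences** — uniform random RNA (25 miRNAs × 21 nt; 30 genes with one
  CDS and one 3′UTR of 200–400 nt). Planted sites are exact reverse
  complements with controlled corruptions: one seed base flipped to a
  non-pairing, non-wobble base (position 5); one non-seed Watson–Crick pair
  converted to G:U; or 3/10 random nucleotides inserted mid-site as a
  target bulge. The two bulge sites are assigned to the most GC-rich of the
  otherwise unplanted miRNAs so the bulged duplex stays well below −25
  kcal/mol and only the structural caps separate the plant and human
  profiles. Background composition is uniform; real UTRs are biased and
  repetitive, so false-positive rates on real data will differ.
* **Network** — 11 Erdős–Rényi blocks (p = 0.10 plus a random Hamiltonian
  cycle that guarantees within-module connectivity) over 531 genes, wired
  only through 15 bridge hubs of degree ~48 spread across all modules;
  ~2,440 edges in total — the default scale of the shipped study. No direct inter-module or bridge–bridge edges
  exist, so deleting the true bridges yields exactly 11 components; real
  interaction networks have overlapping communities and noisy hubs.
* **Annotations** — a three-rank acyclic ontology (8 generic roots = the
  slim set, 24 mid terms, 48 leaves, 1–2 parents each); 1–4 background
  terms per gene; planted terms annotate 80 % of one module's genes against
  a 5 % background rate.
* **Expression** — tiers sampled at 30/30/30/10 % (ubiquitous / high /
  specific / silent); ubiquitous genes at 4–8 units in all tissues,
  specific at 6–10 in one, high-tier with one dominant tissue (9–11) plus
  1–5 moderate ones (2.5–4), which keeps max z > 1 for any breadth 2–6;
  Gaussian noise σ = 0.3, clipped at zero.

Passing the planted-recovery tests shows the pipeline recovers signal that
is present by construction under realistic scales and mild noise; it says
nothing about sensitivity/specificity on real sequence composition, real
network topology, or real annotation bias.

## Problem sizes and runtime

The shipped study runs 25 miRNAs × 60 regions with 200-shuffle
calibrations (~6 s), the full network/enrichment/tissue stages (~2 s), the
500-case enumeration cross-check (~15 s) and 200 null enrichment modules
(~5 s); the whole test suite completes in well under a minute after JIT
warm-up, and `scripts/acceptance.py` in under a minute.

## Known limitations

* The energy model omits loop asymmetry, coaxial stacking, dangling ends
  and temperature dependence; energies are comparable within this model
  only.
* One duplex per site: multi-site cooperativity and target-site
  accessibility are out of scope.
* The Gumbel calibration is approximate (see above); p-values are
  screening scores, not literal tail probabilities.
* The eigenvector weighting assumes a connected, non-bipartite graph for a
  unique fixed point; on disconnected graphs mass concentrates on the
  dominant component (isolated nodes go to 0 by convention).
* BH is applied within each module; a batch mode across modules would give
  different adjusted values.
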