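# mirx

Cross-kingdom miRNA target analysis: seed-anchored duplex prediction,
validated-target ranking, PageRank bridge-gene module decomposition, and
per-module GO enrichment — exercised end to end on synthetic data with
planted, recoverable structure.

Diet-derived plant miRNAs have been reported in mammalian serum, raising the
question of which human transcripts a plant miRNA could plausibly repress.
`mirx` implements the computational core of that analysis for researchers in
systems biology and small-RNA bioinformatics who want a self-contained,
testable pipeline rather than a chain of web services:

1. **hybridize** — for each miRNA *m* and transcript region *t* (CDS or
   3′UTR), find the minimum-free-energy intermolecular duplex
   ΔG(m:t) = Σ stacks + Σ bulge/loop penalties + end penalties over all
   non-crossing antiparallel pairings (nearest-neighbor model, dynamic
   programming with traceback). Each hit's energy is converted to an
   empirical p-value P(ΔG_null ≤ ΔG) under a minimum-Gumbel law fitted to
   best-hit energies of dinucleotide-preserving shuffles.
2. **screen** — a filter cascade: perfect Watson–Crick seed (miRNA bases
   2–8), ΔG ≤ −25 kcal/mol, p ≤ p_max, and (plant profile) internal loops ≤ 5
   nt per side and bulges ≤ 9 nt. Surviving targets are ranked per miRNA by
   p-value, then ΔG; a three-level harness checks known targets at the mRNA /
   primary-prediction / post-screen levels and reports their ranks.
3. **netcore** — an undirected gene interaction graph is weighted by
   iterating B ← A·B from B₀ = 1 with the total renormalized to N each step
   (power iteration; the converged B is the principal eigenvector of the
   adjacency matrix A), stopping when max|ΔB| < 0.005. The top-15 weighted
   "bridge" genes are deleted and the remaining connected components become
   modules. Standard damped PageRank (d = 0.85) is available behind a flag.
4. **enrich** — each module is tested against the whole network as
   background with the upper-tail hypergeometric test
   P(X ≥ k | N, K, n), Benjamini–Hochberg adjusted within the module
   (findings at adjusted p < 0.1); enriched terms are grouped into generic
   (slim) GO categories by is_a transitive closure, and two species'
   category sets are compared by Jaccard / overlap coefficients. An
   8-tissue expression matrix is classified into ubiquitous (housekeeping),
   highly-expressed and tissue-specific tiers.
5. **synthgen** — generators for every input, with planted structure at a
   realistic study scale (25 × 21-nt miRNAs, ~531 module genes in 11 modules wired
   through 15 bridge hubs with ~2,444 edges, planted enriched terms,
   planted expression tiers) and truth tables for scoring recovery.

## Worked example

Scan a transcript region for a 21-nt miRNA:

```python
from mirx import MiRNA, TranscriptRegion, scan_transcript, reverse_complement

background = ("ACGUGUCCAAGGUUCACGAGGAAACCUUGGACGUGAGCCAUGGCAACUGUAGGCACCAUC"
              "AAUCCGUAUGCCAACGGUGGAUACGAUCGGAUCCAGGAAACGGCUAAGCUUACGGGAAUC")
mir = MiRNA("ath-miR-like", "UGACAGAAGAGAGUGAGCACA")
seq = background[:47] + reverse_complement(mir.seq) + background[47:]
region = TranscriptRegion("SPL-like", "AT0G00001", "CDS", seq)

for h in scan_transcript(mir, region, report_max=-25.0):
    print(h.target_start, h.target_end, round(h.mfe, 2))
    print(h.pairing.replace("&", "\n"))
```

```
47 68 -42.87
UGACAGAAGAGAGUGAGCACA
|||||||||||||||||||||
ACUGUCUUCUCUCACUCGUGU
```

The planted site is recovered at its offset (47), as a contiguous 21-pair
helix at −42.87 kcal/mol — far below the −25 kcal/mol stability cutoff
expected of authentic miRNA:target pairs.

The whole pipeline runs from one command on a synthetic study:

```bash
mirx run-all --out demo --seed 42
```

which prints the stage summary (also written to `demo/run/summary.json`):

```json
{
  "frac_top50": 1.0,
  "n_bridges": 15,
  "n_edges": 2469,
  "n_enriched_terms": 16,
  "n_in_top10": 10,
  "n_mirnas": 25,
  "n_modules": 11,
  "n_nodes": 546,
  "n_primary_hits": 4106,
  "n_refined_hits": 13,
  "n_validated": 10,
  ...
}
```

Reading: of 4,106 primary duplex predictions, 13 survive the plant-profile
screen — exactly the 10 clean planted sites, the two non-seed G:U wobble
sites and the 3-nt-bulge site; every planted "validated" target ranks in its
miRNA's top 10 (`frac_top50 = 1.0`); the 546-gene network decomposes into
the 11 planted modules after deleting the 15 recovered bridges, and the
planted GO terms are among the 16 enriched findings. Individual stages are
also exposed as subcommands (`mirx hybridize`, `screen`, `validate`,
`network`, `enrich`, `similarity`, `tissues`, `synth`).

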