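"""Synthetic inputs with planted, recoverable structure.

Every pipeline stage has a generator that emulates its real-world input at
a realistic study scale: 25 miRNAs of 21 nt; transcripts carrying planted
complementary sites with controlled corruptions (seed mismatch, G:U wobble,
bulge); an interaction network of ~531 module genes in 11 dense modules
connected only through 15 high-degree bridge hubs (~2444 edges); an acyclic
synthetic ontology with planted enriched terms; and an 8-tissue expression
matrix with planted ubiquitous / high / tissue-specific tiers.  Each
generator is a pure function of its config and seed, and emits a truth table
sufficient to score the downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .energy import BASES, RNA_COMPLEMENT, WATSON_CRICK, reverse_complement
from .enrich import GOAnnotation, Ontology, TISSUES
from .hybridize import MiRNA, TranscriptRegion
from .netcore import GeneNetwork, build_graph

# per-generator RNG stream ids (spawned off the config seed)
_STREAM = {"mirnas": 1, "transcripts": 2, "network": 3, "annotations": 4,
           "expression": 5}


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=cfg_seed, spawn_key=(_STREAM[stream],)))


@dataclass(frozen=True)
class PlantedSite:
    """One planted miRNA complement in a transcript region."""

    mirna_idx: int
    gene_idx: int
    region: str  # CDS | UTR3
    corruption: str = "none"  # none | seed_mismatch | wobble | bulge
    bulge_len: int = 0


@dataclass(frozen=True)
class NetworkConfig:
    n_modules: int = 11
    total_module_genes: int = 531
    n_bridges: int = 15
    intra_p: float = 0.10
    bridge_degree: int = 48


@dataclass(frozen=True)
class AnnotationConfig:
    n_roots: int = 8     # generic (slim) categories
    n_mid: int = 24
    n_leaf: int = 48
    max_anns_per_gene: int = 4
    n_planted_modules: int = 3
    planted_frac: float = 0.8
    background_rate: float = 0.05


@dataclass(frozen=True)
class ExpressionConfig:
    tier_probs: tuple = (("ubiquitous", 0.3), ("high", 0.3),
                         ("specific", 0.3), ("not_expressed", 0.1))
    noise_sd: float = 0.3


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 42
    n_mirnas: int = 25
    mirna_len: int = 21
    n_transcripts: int = 30
    region_len_range: tuple = (200, 400)
    planted_sites: Optional[tuple] = None  # default plan if None
    network: NetworkConfig = field(default_factory=NetworkConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def sites(self, mirnas: Optional[Sequence[MiRNA]] = None) -> tuple:
        return self.planted_sites if self.planted_sites is not None \
            else default_planted_sites(self.n_mirnas, self.n_transcripts,
                                       mirnas)


def default_planted_sites(n_mirnas: int = 25, n_transcripts: int = 30,
                          mirnas: Optional[Sequence[MiRNA]] = None) -> tuple:
    """The standard planted-site plan: ten clean sites (alternating CDS and
    3'UTR), five seed-mismatch sites, two non-seed G:U wobbles, one modest
    3-nt bulge and one 10-nt bulge (the plant/human cap discriminator).

    When the miRNA sequences are available, the two bulge sites go to the
    most GC-rich of the otherwise unplanted miRNAs, so that the bulged
    duplex stays well below the -25 kcal/mol stability cutoff and only the
    structural caps separate the plant and human profiles.
    """
    plan = []
    for i in range(10):
        plan.append(PlantedSite(i, i, "CDS" if i % 2 == 0 else "UTR3"))
    for i in range(10, 15):
        plan.append(PlantedSite(i, i, "UTR3", "seed_mismatch"))
    for i in range(15, 17):
        plan.append(PlantedSite(i, i, "CDS", "wobble"))
    b3, b10 = 17, 18
    if mirnas is not None and n_mirnas > 18:
        free = list(range(17, min(n_mirnas, len(mirnas))))
        by_gc = sorted(free, key=lambda i: (
            -sum(b in "GC" for b in mirnas[i].seq), i))
        if len(by_gc) >= 2:
            b10, b3 = by_gc[0], by_gc[1]
    plan.append(PlantedSite(b3, 17, "UTR3", "bulge", bulge_len=3))
    plan.append(PlantedSite(b10, 18, "CDS", "bulge", bulge_len=10))
    return tuple(p for p in plan
                 if p.mirna_idx < n_mirnas and p.gene_idx < n_transcripts)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, size=length))


def gen_mirnas(cfg: SynthConfig) -> list[MiRNA]:
    """Uniform random miRNAs, reproducible from the config seed."""
    rng = _rng(cfg.seed, "mirnas")
    return [MiRNA(id=f"syn-miR-{i + 1:03d}", seq=random_rna(rng, cfg.mirna_len))
            for i in range(cfg.n_mirnas)]


def _corrupt_site(site: str, mirna_seq: str, spec: PlantedSite,
                  rng: np.random.Generator) -> str:
    """Apply the requested corruption to a perfect reverse-complement site.

    Site position ``len(site)-1-p`` faces miRNA position ``p`` (0-based).
    """
    L = len(site)
    if spec.corruption == "none":
        return site
    if spec.corruption == "seed_mismatch":
        p = 4  # miRNA position 5 (1-based), inside the 2-8 seed
        t = L - 1 - p
        mb = mirna_seq[p]
        # any base that neither Watson-Crick- nor wobble-pairs the seed base
        choices = [b for b in BASES
                   if mb + b not in WATSON_CRICK and mb + b not in ("GU", "UG")]
        return site[:t] + choices[rng.integers(len(choices))] + site[t + 1:]
    if spec.corruption == "wobble":
        # any position strictly outside the 2-8 seed, central ones first
        for p in list(range(9, len(mirna_seq))) + [8, 0]:
            mb = mirna_seq[p]
            if mb in "GU":
                t = L - 1 - p
                return site[:t] + ("U" if mb == "G" else "G") + site[t + 1:]
        raise ValueError("miRNA has no G/U outside the seed; cannot plant a "
                         "wobble site")
    if spec.corruption == "bulge":
        cut = L - 1 - 10  # between the pairs facing miRNA positions 10 and 11
        insert = random_rna(rng, spec.bulge_len)
        return site[:cut + 1] + insert + site[cut + 1:]
    raise ValueError(f"unknown corruption {spec.corruption!r}")


def gen_transcripts_with_sites(cfg: SynthConfig, mirnas: Sequence[MiRNA]
                               ) -> tuple[list[TranscriptRegion], pd.DataFrame]:
    """Random transcripts (one CDS + one 3'UTR region per gene) with planted
    sites; returns the regions and the truth table."""
    rng = _rng(cfg.seed, "transcripts")
    sites = cfg.sites(mirnas)
    for s in sites:
        if s.mirna_idx >= len(mirnas):
            raise ValueError(f"planted site references miRNA {s.mirna_idx} "
                             "beyond the generated set")
    by_slot: dict[tuple, list[PlantedSite]] = {}
    for s in sites:
        by_slot.setdefault((s.gene_idx, s.region), []).append(s)
    lo, hi = cfg.region_len_range
    regions: list[TranscriptRegion] = []
    rows = []
    for gi in range(cfg.n_transcripts):
        gene = f"TG{gi:03d}"
        acc = f"SYNT{gi:05d}"
        for region in ("CDS", "UTR3"):
            seq = random_rna(rng, int(rng.integers(lo, hi + 1)))
            cursor = 0
            for spec in by_slot.get((gi, region), []):
                mir = mirnas[spec.mirna_idx]
                site = _corrupt_site(reverse_complement(mir.seq), mir.seq,
                                     spec, rng)
                if cursor + len(site) > len(seq):
                    raise ValueError(f"planted sites overflow region "
                                     f"{gene}/{region}")
                off = int(rng.integers(cursor,
                                       len(seq) - len(site) + 1))
                seq = seq[:off] + site + seq[off + len(site):]
                cursor = off + len(site)
                rows.append({"mirna_id": mir.id, "gene_id": gene,
                             "region": region, "offset": off,
                             "site_len": len(site),
                             "corruption": spec.corruption,
                             "bulge_len": spec.bulge_len})
            regions.append(TranscriptRegion(gene_id=gene, accession=acc,
                                            region=region, seq=seq))
    truth = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "region",
                                        "offset", "site_len", "corruption",
                                        "bulge_len"])
    return regions, truth


def validated_targets(truth: pd.DataFrame) -> list[tuple]:
    """The planted clean sites, as a validated-target list."""
    clean = truth[truth["corruption"] == "none"]
    return list(clean[["mirna_id", "gene_id", "region"]].itertuples(
        index=False, name=None))


def gen_network(cfg: SynthConfig) -> tuple[GeneNetwork, dict]:
    """Planted module/bridge network.

    Each module is a dense Erdos-Renyi block on a guaranteed-connecting
    random cycle; there are no direct inter-module (or bridge-bridge) edges,
    so deleting the bridges yields exactly ``n_modules`` components.  Every
    bridge connects to all modules with ``bridge_degree`` edges in total,
    far above the intra-module degrees.
    """
    nc = cfg.network
    if nc.n_modules < 2:
        raise ValueError("need at least two modules")
    rng = _rng(cfg.seed, "network")
    base = nc.total_module_genes // nc.n_modules
    sizes = [base + (1 if i < nc.total_module_genes % nc.n_modules else 0)
             for i in range(nc.n_modules)]
    gene_iter = iter(f"G{i + 1:04d}" for i in range(nc.total_module_genes))
    modules = [[next(gene_iter) for _ in range(s)] for s in sizes]
    bridges = [f"G{nc.total_module_genes + i + 1:04d}"
               for i in range(nc.n_bridges)]
    edges = set()
    for members in modules:
        order = list(rng.permutation(members))
        for a, b in zip(order, order[1:] + order[:1]):  # connectivity cycle
            edges.add((min(a, b), max(a, b)))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < nc.intra_p:
                    a, b = members[i], members[j]
                    edges.add((min(a, b), max(a, b)))
    quota = nc.bridge_degree // nc.n_modules
    for br in bridges:
        extra_mods = set(rng.choice(nc.n_modules,
                                    size=nc.bridge_degree % nc.n_modules,
                                    replace=False).tolist())
        for mi, members in enumerate(modules):
            take = quota + (1 if mi in extra_mods else 0)
            for g in rng.choice(members, size=min(take, len(members)),
                                replace=False):
                edges.add((min(br, g), max(br, g)))
    net = build_graph(sorted(edges))
    truth = {
        "modules": [sorted(m) for m in modules],
        "module_of": {g: mi for mi, m in enumerate(modules) for g in m},
        "bridges": bridges,
    }
    return net, truth


def gen_annotations(cfg: SynthConfig, network_truth: dict
                    ) -> tuple[GOAnnotation, list[str], pd.DataFrame]:
    """Synthetic acyclic ontology + annotations with planted enriched terms.

    Returns (annotation, slim list, planted-term truth table).  The ontology
    has three ranks (roots = generic slim categories, mid terms, leaves), so
    acyclicity holds by construction.  Planted terms annotate
    ``planted_frac`` of one module's genes against a low background rate.
    """
    ac = cfg.annotation
    rng = _rng(cfg.seed, "annotations")
    roots = [f"SGO:R{i + 1:02d}" for i in range(ac.n_roots)]
    mids = [f"SGO:M{i + 1:02d}" for i in range(ac.n_mid)]
    leaves = [f"SGO:L{i + 1:02d}" for i in range(ac.n_leaf)]
    n_planted = min(ac.n_planted_modules, len(network_truth["modules"]))
    planted_terms = [f"SGO:P{i + 1:02d}" for i in range(n_planted)]
    terms = {t: {"name": f"synthetic process {t[4:]}",
                 "namespace": "biological_process"}
             for t in roots + mids + leaves + planted_terms}
    parents: dict[str, list[str]] = {t: [] for t in terms}
    for t in mids:
        ps = rng.choice(len(roots), size=int(rng.integers(1, 3)),
                        replace=False)
        parents[t] = [roots[p] for p in ps]
    for t in leaves + planted_terms:
        ps = rng.choice(len(mids), size=int(rng.integers(1, 3)),
                        replace=False)
        parents[t] = [mids[p] for p in ps]
    ontology = Ontology(terms, parents)

    genes = sorted(set(network_truth["module_of"])
                   | set(network_truth["bridges"]))
    pool = mids + leaves
    gene2terms: dict[str, set] = {}
    for g in genes:
        n_ann = int(rng.integers(1, ac.max_anns_per_gene + 1))
        picks = rng.choice(len(pool), size=n_ann, replace=False)
        gene2terms[g] = {pool[p] for p in picks}
    rows = []
    for mi, term in enumerate(planted_terms):
        members = network_truth["modules"][mi]
        n_hit = max(1, int(round(ac.planted_frac * len(members))))
        hit = rng.choice(members, size=n_hit, replace=False)
        for g in hit:
            gene2terms[g].add(term)
        for g in genes:
            if g not in set(members) and rng.random() < ac.background_rate:
                gene2terms[g].add(term)
        rows.append({"module_index": mi, "term_id": term,
                     "n_annotated_in_module": n_hit,
                     "module_size": len(members)})
    truth = pd.DataFrame(rows, columns=["module_index", "term_id",
                                        "n_annotated_in_module",
                                        "module_size"])
    return GOAnnotation(gene2terms, ontology), roots, truth


def gen_expression(cfg: SynthConfig, genes: Sequence[str]
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """8-tissue expression matrix with planted tier labels.

    Ubiquitous genes sit at a moderate level in all tissues; tissue-specific
    genes are high in exactly one; high-tier genes have a peaked profile
    (one dominant tissue plus 1-5 moderately expressed ones), which keeps
    their cross-tissue z-score above 1 for any breadth in 2-6.
    """
    ec = cfg.expression
    rng = _rng(cfg.seed, "expression")
    tiers, probs = zip(*ec.tier_probs)
    labels = [tiers[i] for i in
              rng.choice(len(tiers), size=len(genes), p=np.asarray(probs))]
    mat = np.zeros((len(genes), len(TISSUES)))
    for gi, tier in enumerate(labels):
        if tier == "ubiquitous":
            mat[gi] = rng.uniform(4.0, 8.0, size=len(TISSUES))
        elif tier == "specific":
            t = rng.integers(len(TISSUES))
            mat[gi, t] = rng.uniform(6.0, 10.0)
        elif tier == "high":
            k = int(rng.integers(2, 7))
            ts = rng.choice(len(TISSUES), size=k, replace=False)
            mat[gi, ts[0]] = rng.uniform(9.0, 11.0)  # dominant tissue
            mat[gi, ts[1:]] = rng.uniform(2.5, 4.0, size=k - 1)
    if ec.noise_sd > 0:
        mat = mat + rng.normal(0.0, ec.noise_sd, size=mat.shape)
    mat = np.clip(mat, 0.0, None)
    expr = pd.DataFrame(mat, index=list(genes), columns=list(TISSUES))
    return expr, pd.Series(labels, index=list(genes), name="tier")
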