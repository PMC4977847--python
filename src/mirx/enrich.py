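"""Per-module GO enrichment, slim grouping, cross-species similarity and
tissue-expression tiers.

Each module is tested for over-represented terms against the whole network as
background with an upper-tail hypergeometric test; Benjamini-Hochberg adjusts
p-values within the module and terms with adjusted p below 0.1 are reported.
Enriched terms are grouped into generic (slim) categories by is_a transitive
closure, and functional similarity between two species' category sets is the
overlap of those generic categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

UNCLASSIFIED = "unclassified"

#: The eight tissues tracked for expression tiers.
TISSUES = ("brain", "heart", "kidney", "liver", "lung", "spleen", "stomach",
           "small_intestine")


class Ontology:
    """A term table plus acyclic is_a parent graph."""

    def __init__(self, terms: Mapping[str, dict],
                 parents: Mapping[str, Iterable[str]]):
        self.terms = dict(terms)  # id -> {"name":..., "namespace":...}
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in parents.items():
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("is_a graph contains a cycle")
        self._g = g

    def __contains__(self, term):
        return term in self._g

    def ancestors(self, term: str) -> set:
        """All terms reachable from ``term`` along is_a (term excluded)."""
        return nx.descendants(self._g, term)

    def name(self, term: str) -> str:
        return self.terms.get(term, {}).get("name", term)


@dataclass
class GOAnnotation:
    """gene -> set of term ids, tied to an ontology."""

    gene2terms: dict
    ontology: Ontology

    def __post_init__(self):
        missing = {t for ts in self.gene2terms.values() for t in ts
                   if t not in self.ontology}
        if missing:
            raise ValueError(f"annotated terms missing from the term table: "
                             f"{sorted(missing)[:5]}")

    def propagated(self) -> "GOAnnotation":
        """True-path propagation: annotate every is_a ancestor as well."""
        out = {g: set(ts) for g, ts in self.gene2terms.items()}
        for g, ts in out.items():
            extra = set()
            for t in ts:
                extra |= self.ontology.ancestors(t)
            ts |= extra
        return GOAnnotation(out, self.ontology)


@dataclass(frozen=True)
class EnrichmentResult:
    module_id: str
    term_id: str
    k: int       # module genes with the term
    n: int       # module size
    K: int       # background genes with the term
    N_bg: int    # background size
    p_raw: float
    p_adj: Optional[float] = None

    def __post_init__(self):
        if not 0 <= self.k <= min(self.n, self.K):
            raise ValueError("inconsistent counts k > min(n, K)")


def hypergeom_enrich(module_genes, term: str, annotation: GOAnnotation,
                     background_genes, module_id: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric P(X >= k) for one term in one module."""
    module = set(module_genes)
    background = set(background_genes)
    if not module <= background:
        raise ValueError("module genes must be a subset of the background")
    with_term = {g for g in background
                 if term in annotation.gene2terms.get(g, ())}
    k = len(module & with_term)
    K = len(with_term)
    if K == 0:
        if k > 0:
            raise ValueError(f"term {term} absent from background but "
                             "present in module")
        p = 1.0
    else:
        p = float(hypergeom.sf(k - 1, len(background), K, len(module)))
    return EnrichmentResult(module_id=module_id, term_id=term, k=k,
                            n=len(module), K=K, N_bg=len(background),
                            p_raw=min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def enrich_module(module, annotation: GOAnnotation, background,
                  alpha: float = 0.1, propagate: bool = True,
                  module_id: Optional[str] = None) -> list[EnrichmentResult]:
    """Test every background-annotated term in one module; BH within the
    module; return findings with adjusted p < alpha, sorted by adjusted p.

    ``module`` may be a :class:`~mirx.netcore.Module` or a gene iterable.
    """
    if hasattr(module, "member_genes"):
        module_genes = set(module.member_genes)
        module_id = module_id or module.module_id
    else:
        module_genes = set(module)
        module_id = module_id or "module"
    if not module_genes:
        return []
    ann = annotation.propagated() if propagate else annotation
    background = set(background)
    counts: dict[str, int] = {}
    for g in background:
        for t in ann.gene2terms.get(g, ()):
            counts[t] = counts.get(t, 0) + 1
    terms = sorted(counts)
    if not terms:
        return []
    results = [hypergeom_enrich(module_genes, t, ann, background, module_id)
               for t in terms]
    adj = bh_adjust([r.p_raw for r in results])
    out = [EnrichmentResult(**{**r.__dict__, "p_adj": a})
           for r, a in zip(results, adj) if a < alpha]
    out.sort(key=lambda r: (r.p_adj, r.p_raw, r.term_id))
    return out


@dataclass
class SlimMapping:
    """term -> set of generic (slim) categories via is_a transitive closure."""

    mapping: dict = field(default_factory=dict)

    def categories(self) -> list[str]:
        """Multiset of slim categories over all mapped terms."""
        out = []
        for cats in self.mapping.values():
            out.extend(sorted(cats))
        return out


def map_to_slim(terms: Iterable[str], slim_list: Iterable[str],
                ontology: Ontology) -> SlimMapping:
    """Map each term to every slim ancestor (a slim term maps to itself);
    terms with no slim ancestor land in the 'unclassified' bucket."""
    slim = set(slim_list)
    missing = slim - set(ontology.terms)
    if missing:
        raise ValueError(f"slim terms not in ontology: {sorted(missing)}")
    mapping = {}
    for t in terms:
        reach = ({t} | ontology.ancestors(t)) & slim
        mapping[t] = reach if reach else {UNCLASSIFIED}
    return SlimMapping(mapping)


def functional_similarity(cats_a: Iterable[str],
                          cats_b: Iterable[str]) -> dict:
    """Overlap of two generic-category collections (support sets)."""
    a, b = set(cats_a) - {UNCLASSIFIED}, set(cats_b) - {UNCLASSIFIED}
    if not a and not b:
        warnings.warn("both category sets empty; similarity undefined, "
                      "returning 0", stacklevel=2)
        return {"jaccard": 0.0, "overlap_coef": 0.0, "shared": set()}
    shared = a & b
    union = a | b
    return {
        "jaccard": len(shared) / len(union) if union else 0.0,
        "overlap_coef": len(shared) / min(len(a), len(b)) if a and b else 0.0,
        "shared": shared,
    }


def classify_tissue_levels(expr: pd.DataFrame, detect_thresh: float = 1.0,
                           z_thresh: float = 1.0) -> pd.DataFrame:
    """Three-tier expression classification (genes x tissues input).

    A gene counts as expressed in a tissue when its value exceeds
    ``detect_thresh``.  Tiers: 'ubiquitous' when expressed in >= 7 of 8
    tissues (housekeeping), 'specific' when expressed in exactly one,
    'high' when expressed in 2-6 tissues with a cross-tissue z-score above
    ``z_thresh``; all-undetected genes are 'not_expressed', the remainder
    'unclassified'.  Returns a frame with columns level / tissues.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two tissues")
    if (expr.values < 0).any() or not np.isfinite(expr.values).all():
        raise ValueError("expression values must be finite and non-negative")
    vals = expr.values.astype(float)
    detected = vals > detect_thresh
    n_expr = detected.sum(axis=1)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (vals - mean) / np.maximum(sd, 1e-12), 0.0)
    max_z = z.max(axis=1)
    ubi_cut = min(7, expr.shape[1] - 1)
    levels, tissues = [], []
    for gi in range(expr.shape[0]):
        expressed = [expr.columns[t] for t in range(expr.shape[1])
                     if detected[gi, t]]
        if n_expr[gi] == 0:
            levels.append("not_expressed")
            tissues.append("")
        elif n_expr[gi] >= ubi_cut:
            levels.append("ubiquitous")
            tissues.append(",".join(expressed))
        elif n_expr[gi] == 1:
            levels.append("specific")
            tissues.append(expressed[0])
        elif 2 <= n_expr[gi] <= 6 and max_z[gi] > z_thresh:
            levels.append("high")
            tissues.append(",".join(expressed))
        else:
            levels.append("unclassified")
            tissues.append(",".join(expressed))
    return pd.DataFrame({"level": levels, "tissues": tissues},
                        index=expr.index)
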