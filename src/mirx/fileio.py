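"""Readers and writers for the pipeline's plain-text formats.

All tabular files are UTF-8, tab-separated with a header row, LF endings and
'.' for missing values, so reruns diff bit-exactly.  FASTA goes through
Biopython; ontologies are minimal OBO (is_a only) parsed with obonet.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import obonet
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrich import GOAnnotation, Ontology
from .hybridize import DuplexHit, MiRNA, TranscriptRegion
from .screen import ValidationRecord

MISSING = "."

_REGION_ALIASES = {"CDS": "CDS", "UTR3": "UTR3", "3UTR": "UTR3",
                   "3'UTR": "UTR3"}


def _normalize_rna(seq: str) -> str:
    return str(seq).upper().replace("T", "U")


def read_fasta(path) -> list[tuple[str, str, str]]:
    """Parse FASTA into (id, description, normalized RNA seq) records.

    DNA input (T, lowercase) is normalized to uppercase RNA.  Duplicate ids
    and empty records are errors.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = _normalize_rna(rec.seq)
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        records.append((rec.id, rec.description, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def _desc_tags(description: str) -> dict:
    tags = {}
    for tok in description.split()[1:]:
        if "=" in tok:
            key, val = tok.split("=", 1)
            tags[key] = val
    return tags


def read_mirnas(path) -> list[MiRNA]:
    return [MiRNA(id=rid, seq=seq) for rid, _, seq in read_fasta(path)]


def read_regions(path, default_region: Optional[str] = None
                 ) -> list[TranscriptRegion]:
    """Read transcript regions; region read from a ' region=CDS|3UTR' tag in
    the description line, else ``default_region``."""
    out = []
    for rid, desc, seq in read_fasta(path):
        tags = _desc_tags(desc)
        raw = tags.get("region", default_region)
        if raw is None:
            raise ValueError(f"record {rid!r} has no region= tag and no "
                             "default region was given")
        region = _REGION_ALIASES.get(raw.upper())
        if region is None:
            raise ValueError(f"record {rid!r}: unknown region {raw!r}")
        out.append(TranscriptRegion(gene_id=rid,
                                    accession=tags.get("accession", rid),
                                    region=region, seq=seq))
    return out


def write_mirnas(mirnas: Sequence[MiRNA], path) -> None:
    SeqIO.write([SeqRecord(Seq(m.seq), id=m.id, description="")
                 for m in mirnas], path, "fasta")


def write_regions(regions: Sequence[TranscriptRegion], path) -> None:
    recs = []
    for i, r in enumerate(regions):
        recs.append(SeqRecord(
            Seq(r.seq), id=f"{r.gene_id}.{r.region}",
            description=f"region={r.region} accession={r.accession} "
                        f"gene={r.gene_id}"))
    SeqIO.write(recs, path, "fasta")


def read_regions_synth(path) -> list[TranscriptRegion]:
    """Read regions written by :func:`write_regions` (gene= tag carries the
    gene id; the record id suffixes the region for uniqueness)."""
    out = []
    for rid, desc, seq in read_fasta(path):
        tags = _desc_tags(desc)
        region = _REGION_ALIASES[tags["region"].upper()]
        out.append(TranscriptRegion(gene_id=tags.get("gene", rid),
                                    accession=tags.get("accession", rid),
                                    region=region, seq=seq))
    return out


# ---------------------------------------------------------------------------
# tabular formats

def _fmt(x) -> str:
    if x is None:
        return MISSING
    if isinstance(x, float):
        if math.isnan(x):
            return MISSING
        return format(x, ".6g")
    return str(x)


def _write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


HIT_COLUMNS = ("mirna_id", "gene_id", "region", "start", "end", "mfe",
               "pvalue", "rank", "pairs", "pairing")


def write_hits_tsv(hits: Sequence[DuplexHit], path) -> None:
    rows = []
    for h in hits:
        pairs = ";".join(f"{i}:{j}" for i, j in h.pairs)
        rows.append((h.mirna_id, h.gene_id, h.region, h.target_start,
                     h.target_end, h.mfe, h.pvalue, h.rank,
                     f"{pairs}|{h.pair_symbols}", h.pairing))
    _write_tsv(path, HIT_COLUMNS, rows)


def read_hits_tsv(path) -> list[DuplexHit]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    hits = []
    for row in df.itertuples(index=False):
        pair_field, symbols = row.pairs.split("|", 1)
        pairs = tuple(tuple(int(x) for x in p.split(":"))
                      for p in pair_field.split(";"))
        hits.append(DuplexHit(
            mirna_id=row.mirna_id, gene_id=row.gene_id, region=row.region,
            target_start=int(row.start), target_end=int(row.end),
            mfe=float(row.mfe),
            pvalue=None if row.pvalue == MISSING else float(row.pvalue),
            rank=None if row.rank == MISSING else int(row.rank),
            pairs=pairs, pair_symbols=symbols, pairing=row.pairing))
    return hits


def write_edges_tsv(edges: Iterable[tuple], path) -> None:
    _write_tsv(path, ("gene_a", "gene_b"), sorted(map(tuple, edges)))


def read_edges_tsv(path) -> list[tuple]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"empty edge list {path}")
    return [tuple(r) for r in df.itertuples(index=False)]


def write_annotations_tsv(gene2terms: dict, path) -> None:
    rows = [(g, t) for g in sorted(gene2terms)
            for t in sorted(gene2terms[g])]
    _write_tsv(path, ("gene_id", "term_id"), rows)


def read_annotations_tsv(path, ontology: Ontology) -> GOAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    g2t: dict[str, set] = {}
    for row in df.itertuples(index=False):
        g2t.setdefault(row.gene_id, set()).add(row.term_id)
    return GOAnnotation(g2t, ontology)


def write_obo(ontology: Ontology, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("format-version: 1.2\nontology: sgo\n")
        for term in sorted(ontology.terms):
            meta = ontology.terms[term]
            fh.write(f"\n[Term]\nid: {term}\nname: {meta.get('name', term)}\n")
            if meta.get("namespace"):
                fh.write(f"namespace: {meta['namespace']}\n")
            for parent in sorted(ontology._g.successors(term)):
                fh.write(f"is_a: {parent} ! {ontology.name(parent)}\n")


def read_obo(path) -> Ontology:
    graph = obonet.read_obo(path)
    terms = {}
    parents: dict[str, list] = {}
    for node, data in graph.nodes(data=True):
        terms[node] = {"name": data.get("name", node),
                       "namespace": data.get("namespace", "")}
        parents[node] = []
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].append(parent)
    return Ontology(terms, parents)


def write_slim_list(slim: Sequence[str], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for t in slim:
            fh.write(t + "\n")


def read_slim_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g",
                lineterminator="\n")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_validated_tsv(validated: Iterable[tuple], path) -> None:
    _write_tsv(path, ("mirna_id", "gene_id", "region"), validated)


def read_validated_tsv(path) -> list[tuple]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [tuple(r) for r in df.itertuples(index=False)]


def write_validation_report(records: Sequence[ValidationRecord], path) -> None:
    """Serialize three-level validation records in the rank-report shape:
    gene, region, mRNA Y/N, primary Y/N, refined Y/N, rank."""
    rows = [(r.mirna_id, r.gene_id, r.region_validated,
             "Y" if r.in_mrna_set else "N",
             "Y" if r.in_primary else "N",
             "Y" if r.in_refined else "N",
             r.rank) for r in records]
    _write_tsv(path, ("mirna_id", "gene_id", "region", "in_mrna",
                      "primary", "refined", "rank"), rows)
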