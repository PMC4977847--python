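"""Filter cascade, per-miRNA target ranking and three-level validation.

The screening thresholds encode the biology of functional sites: hybrids must be at least as
stable as authentic miRNA-target pairs (MFE <= -25 kcal/mol), carry a perfect
Watson-Crick seed (miRNA bases 2-8), and - in the plant profile - keep
internal loops within 5 nt per side and bulges within 9 nt.  Surviving
targets are ranked per miRNA by p-value, then MFE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .hybridize import DuplexHit, seed_match


@dataclass(frozen=True)
class FilterProfile:
    """Screening thresholds for one species mode."""

    mfe_max: float = -25.0
    p_max: float = 0.05
    require_seed: bool = True
    max_loop: Optional[int] = None
    max_bulge: Optional[int] = None
    top_k_rank: Optional[int] = 50

    def __post_init__(self):
        if self.mfe_max >= 0:
            raise ValueError("mfe_max must be negative")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must lie in (0, 1]")


#: Arabidopsis mode: loop/bulge caps 5 and 9 nt.
PLANT_PROFILE = FilterProfile(max_loop=5, max_bulge=9)
#: Human mode: no structural caps.
HUMAN_PROFILE = FilterProfile()

PROFILES = {"plant": PLANT_PROFILE, "human": HUMAN_PROFILE}


def measure_gaps(pairs) -> tuple[int, int]:
    """(longest bulge, longest internal-loop side) in a traceback pairing."""
    max_bulge = 0
    max_loop_side = 0
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        a = i1 - i0 - 1
        b = j0 - j1 - 1
        if a and b:
            max_loop_side = max(max_loop_side, a, b)
        elif a or b:
            max_bulge = max(max_bulge, a + b)
    return max_bulge, max_loop_side


def apply_filters(hits: Iterable[DuplexHit],
                  profile: FilterProfile) -> list[DuplexHit]:
    """Retain hits passing every active threshold; input order preserved.

    Hits without a calibrated p-value are not filtered on p.
    """
    kept = []
    for h in hits:
        if h.mfe > profile.mfe_max:
            continue
        if h.pvalue is not None and h.pvalue > profile.p_max:
            continue
        if profile.require_seed and not seed_match(None, h):
            continue
        bulge, loop_side = measure_gaps(h.pairs)
        if profile.max_bulge is not None and bulge > profile.max_bulge:
            continue
        if profile.max_loop is not None and loop_side > profile.max_loop:
            continue
        kept.append(h)
    return kept


def rank_targets(hits: Sequence[DuplexHit]) -> list[DuplexHit]:
    """1-based ranks for one miRNA's hits: p ascending, then MFE ascending,
    then gene id (and site coordinates) as the deterministic tie-break."""
    ordered = sorted(hits, key=lambda h: (
        h.pvalue if h.pvalue is not None else 1.0, h.mfe, h.gene_id,
        h.region, h.target_start))
    return [replace(h, rank=r) for r, h in enumerate(ordered, start=1)]


@dataclass(frozen=True)
class ValidationRecord:
    """Outcome of the three-level check for one validated miRNA-target pair."""

    mirna_id: str
    gene_id: str
    region_validated: str
    in_mrna_set: bool
    in_primary: bool
    in_refined: bool
    rank: Optional[int]

    def __post_init__(self):
        if self.in_refined and not self.in_primary:
            raise ValueError("in_refined implies in_primary")
        if self.in_primary and not self.in_mrna_set:
            raise ValueError("in_primary implies in_mrna_set")
        if (self.rank is not None) != self.in_refined:
            raise ValueError("rank is defined iff in_refined")


def validate_three_level(validated: Sequence[tuple], mrna_set,
                         primary_hits: Sequence[DuplexHit],
                         refined_hits: Sequence[DuplexHit]
                         ) -> list[ValidationRecord]:
    """Check each validated (miRNA, gene, region) triple at three levels:
    present in the input mRNA set, recovered among primary predictions, and
    surviving the screen - with its per-miRNA rank among refined targets."""
    mrna_set = set(mrna_set)
    primary_idx = {(h.mirna_id, h.gene_id, h.region) for h in primary_hits}
    refined_idx = {(h.mirna_id, h.gene_id, h.region) for h in refined_hits}
    by_mirna: dict[str, list[DuplexHit]] = {}
    for h in refined_hits:
        by_mirna.setdefault(h.mirna_id, []).append(h)
    rank_idx: dict[tuple, int] = {}
    for mid, hs in by_mirna.items():
        for h in rank_targets(hs):
            key = (mid, h.gene_id, h.region)
            if key not in rank_idx or h.rank < rank_idx[key]:
                rank_idx[key] = h.rank
    records = []
    for mid, gid, region in validated:
        in_mrna = gid in mrna_set
        in_primary = in_mrna and (mid, gid, region) in primary_idx
        in_refined = in_primary and (mid, gid, region) in refined_idx
        records.append(ValidationRecord(
            mirna_id=mid, gene_id=gid, region_validated=region,
            in_mrna_set=in_mrna, in_primary=in_primary,
            in_refined=in_refined,
            rank=rank_idx[(mid, gid, region)] if in_refined else None))
    return records


def validation_summary(records: Sequence[ValidationRecord]) -> dict:
    """Counts of validated targets recovered within the per-miRNA top ranks."""
    n = len(records)
    ranks = [r.rank for r in records if r.rank is not None]
    summary = {
        "n_validated": n,
        "n_in_top10": sum(1 for r in ranks if r <= 10),
        "n_in_top50": sum(1 for r in ranks if r <= 50),
    }
    summary["frac_top50"] = summary["n_in_top50"] / n if n else math.nan
    return summary
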