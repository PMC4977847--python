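"""Seed-anchored miRNA-transcript hybridization prediction.

Finds minimum-free-energy intermolecular duplexes between a miRNA and
transcript regions (CDS or 3'UTR), reports candidate sites with their
traceback pairing, and calibrates an empirical extreme-value p-value for hit
energies against dinucleotide-preserving shuffles of the scanned sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from ._duplex_kernel import INF, duplex_dp
from .energy import (BASE_CODE, EnergyModel, WATSON_CRICK,
                     default_energy_model, encode)

#: Hard structural bound used while scanning when no profile caps are given.
SCAN_BULGE_CAP = 15
SCAN_LOOP_CAP = 15
#: 1-based inclusive miRNA seed span ("first two to eight bases").
SEED_START, SEED_END = 2, 8

EULER_GAMMA = 0.5772156649015329

Region = Literal["CDS", "UTR3"]


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3' over {A, C, G, U}."""

    id: str
    seq: str

    def __post_init__(self):
        if len(self.seq) < 9:
            raise ValueError(f"miRNA {self.id}: length {len(self.seq)} < 9, "
                             "seed span 2-8 would not exist")
        bad = set(self.seq) - set("ACGU")
        if bad:
            raise ValueError(f"miRNA {self.id}: non-RNA characters {bad}")


@dataclass(frozen=True)
class TranscriptRegion:
    """One labelled region (CDS or 3'UTR) of a transcript, 5'->3'."""

    gene_id: str
    accession: str
    region: Region
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"{self.gene_id}/{self.region}: empty sequence")
        if self.region not in ("CDS", "UTR3"):
            raise ValueError(f"{self.gene_id}: unknown region {self.region!r}")
        bad = set(self.seq) - set("ACGU")
        if bad:
            raise ValueError(f"{self.gene_id}: non-RNA characters {bad}")


@dataclass(frozen=True)
class DuplexHit:
    """One predicted miRNA:site duplex.

    ``pairs`` lists (miRNA index, target index) base pairs, miRNA index
    ascending / target index descending (antiparallel).  ``pair_symbols`` has
    one character per pair: '|' Watson-Crick, ':' G:U wobble.  ``pairing`` is
    a rendered three-line alignment with lines joined by '&'.
    Coordinates are 0-based half-open on the region sequence.
    """

    mirna_id: str
    gene_id: str
    region: Region
    target_start: int
    target_end: int
    mfe: float
    pairs: tuple
    pair_symbols: str
    pairing: str
    pvalue: Optional[float] = None
    rank: Optional[int] = None


class CalibrationError(RuntimeError):
    """Raised when a null calibration cannot be fitted."""


def _caps_to_ints(caps, default_bulge, default_loop, m, n):
    if caps is None:
        return default_bulge, default_loop
    mb = caps.get("max_bulge")
    ml = caps.get("max_loop")
    big = m + n  # effectively uncapped
    return (big if mb is None else int(mb)), (big if ml is None else int(ml))


def _run_dp(mirna_seq: str, target_seq: str, model: EnergyModel,
            max_bulge: int, max_loop: int):
    return duplex_dp(encode(mirna_seq), encode(target_seq), model.pair_index,
                     model.stack, model.bulge_base, model.bulge_slope,
                     model.loop_base, model.loop_slope,
                     model.helix_end_penalty, max_bulge, max_loop)


def _traceback(bt, i, j):
    pairs = []
    while i >= 0:
        pairs.append((i, j))
        i, j = int(bt[i, j, 0]), int(bt[i, j, 1])
    pairs.reverse()
    return tuple(pairs)


def pair_symbol(mb: str, tb: str) -> str:
    return "|" if mb + tb in WATSON_CRICK else ":"


def render_pairing(mirna_seq: str, target_seq: str, pairs) -> str:
    """Render a duplex as miRNA 5'->3' / match line / target 3'->5'.

    Lines are joined with '&' so the structure fits one TSV field.
    """
    top, mid, bot = [], [], []
    for k, (i, j) in enumerate(pairs):
        if k:
            i0, j0 = pairs[k - 1]
            mgap = mirna_seq[i0 + 1:i]
            tgap = target_seq[j + 1:j0][::-1]  # displayed 3'->5'
            width = max(len(mgap), len(tgap))
            top.append(mgap.ljust(width, "-"))
            bot.append(tgap.ljust(width, "-"))
            mid.append(" " * width)
        top.append(mirna_seq[i])
        bot.append(target_seq[j])
        mid.append(pair_symbol(mirna_seq[i], target_seq[j]))
    return "&".join(("".join(top), "".join(mid), "".join(bot)))


def duplex_mfe(mirna, window: str, model: Optional[EnergyModel] = None,
               caps: Optional[dict] = None):
    """Minimum free energy of any admissible duplex in ``window``.

    Returns ``(mfe, pairing)``; ``(math.inf, "")`` when no base pair can
    form ("no hit" sentinel).  ``caps`` may bound bulge / internal-loop-side
    lengths; ``None`` means unconstrained.
    """
    seq = mirna.seq if isinstance(mirna, MiRNA) else mirna
    if not seq or not window:
        raise ValueError("empty sequence")
    model = model or default_energy_model()
    m, n = len(seq), len(window)
    mb, ml = _caps_to_ints(caps, m + n, m + n, m, n)
    E, bt = _run_dp(seq, window, model, mb, ml)
    close = E + model.helix_end_penalty
    i, j = np.unravel_index(np.argmin(close), close.shape)
    if close[i, j] >= INF * 0.5:
        return math.inf, ""
    pairs = _traceback(bt, int(i), int(j))
    return float(close[i, j]), render_pairing(seq, window, pairs)


def scan_transcript(mirna: MiRNA, region: TranscriptRegion,
                    model: Optional[EnergyModel] = None,
                    caps: Optional[dict] = None, stride: int = 1,
                    report_max: float = 0.0) -> list[DuplexHit]:
    """Scan a transcript region and return candidate sites.

    One dynamic program covers the whole region; every target position is a
    candidate 5' anchor for a site (``stride`` subsamples anchors).
    Overlapping candidates are reduced to local minima: a hit is retained iff
    no overlapping hit has lower MFE (ties go to the leftmost).  Hits are
    returned sorted by MFE ascending.  Only sites with mfe < ``report_max``
    (default 0) are reported.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    model = model or default_energy_model()
    seq = region.seq
    if len(seq) < len(mirna.seq):
        return []
    mb, ml = _caps_to_ints(caps, SCAN_BULGE_CAP, SCAN_LOOP_CAP,
                           len(mirna.seq), len(seq))
    E, bt = _run_dp(mirna.seq, seq, model, mb, ml)
    close = E + model.helix_end_penalty
    best_i = np.argmin(close, axis=0)
    best_e = close[best_i, np.arange(len(seq))]
    cands = []
    for j in range(0, len(seq), stride):
        if best_e[j] < report_max:
            pairs = _traceback(bt, int(best_i[j]), j)
            cands.append((float(best_e[j]), j, pairs))
    cands.sort(key=lambda c: (c[0], c[1]))
    taken: list[tuple[int, int]] = []
    hits = []
    for mfe, start, pairs in cands:
        end = pairs[0][1] + 1  # first pair holds the largest target index
        if any(start < e and end > s for s, e in taken):
            continue
        taken.append((start, end))
        symbols = "".join(pair_symbol(mirna.seq[i], seq[j]) for i, j in pairs)
        hits.append(DuplexHit(
            mirna_id=mirna.id, gene_id=region.gene_id, region=region.region,
            target_start=start, target_end=end, mfe=mfe, pairs=pairs,
            pair_symbols=symbols,
            pairing=render_pairing(mirna.seq, seq, pairs)))
    hits.sort(key=lambda h: (h.mfe, h.target_start))
    return hits


def seed_match(mirna, hit: DuplexHit) -> bool:
    """True iff miRNA bases 2-8 are all Watson-Crick paired to contiguous
    target nucleotides.  G:U wobble does not count inside the seed."""
    by_i = {i: (j, s) for (i, j), s in zip(hit.pairs, hit.pair_symbols)}
    prev_j = None
    for i in range(SEED_START - 1, SEED_END):  # 0-based indices 1..7
        if i not in by_i:
            return False
        j, sym = by_i[i]
        if sym != "|":
            return False
        if prev_j is not None and j != prev_j - 1:
            return False
        prev_j = j
    return True


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson doublet-preserving shuffle.

    Produces a uniform random sequence with exactly the original
    dinucleotide (and hence mononucleotide) counts.
    """
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    verts = list(edges)
    last = seq[-1]
    for _ in range(2000):
        # pick a random terminal edge for every vertex except the sink and
        # accept if they form a tree into the sink (Euler-path condition)
        last_edge = {}
        for v in verts:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        ok = True
        for v in last_edge:
            seen = {v}
            u = v
            while u != last:
                u = last_edge.get(u)
                if u is None or u in seen:
                    ok = False
                    break
                seen.add(u)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - rejection loop essentially always succeeds
        return seq
    rest = {}
    for v in verts:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        rest[v] = pool
    out = [seq[0]]
    ptr = {v: 0 for v in verts}
    v = seq[0]
    for _ in range(len(seq) - 1):
        nxt = rest[v][ptr[v]]
        ptr[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


@dataclass(frozen=True)
class NullCalibration:
    """Minimum-Gumbel fit to best duplex MFEs of shuffled windows."""

    mirna_id: str
    mu: float
    beta: float
    n_shuffles: int
    shuffle_seed: int

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("Gumbel scale must be positive")


def null_scores(mirna: MiRNA, regions: Sequence[TranscriptRegion],
                model: Optional[EnergyModel] = None, n: int = 200,
                seed: int = 0, window: int = 40) -> np.ndarray:
    """Best duplex MFEs of ``n`` dinucleotide-preserving window shuffles.

    Windows of ``window`` nt are sampled uniformly from the scanned regions;
    shuffles with no admissible pairing are dropped.
    """
    model = model or default_energy_model()
    rng = np.random.default_rng(seed)
    slots = [(ri, off) for ri, r in enumerate(regions)
             for off in range(0, max(1, len(r.seq) - window + 1))]
    if not slots:
        raise CalibrationError("no scannable windows in regions")
    scores = []
    for _ in range(n):
        ri, off = slots[rng.integers(len(slots))]
        win = regions[ri].seq[off:off + window]
        shuf = dinucleotide_shuffle(win, rng)
        mfe, _ = duplex_mfe(mirna, shuf, model,
                            caps={"max_bulge": SCAN_BULGE_CAP,
                                  "max_loop": SCAN_LOOP_CAP})
        if math.isfinite(mfe):
            scores.append(mfe)
    return np.asarray(scores)


def calibrate_null(mirna: MiRNA, regions: Sequence[TranscriptRegion],
                   model: Optional[EnergyModel] = None,
                   n_shuffles: int = 200, seed: int = 0,
                   window: int = 40) -> NullCalibration:
    """Fit the null MFE distribution from dinucleotide-preserving shuffles.

    The best (lowest) duplex MFE per shuffled window is collected and a
    Gumbel (minimum) law is fitted by the method of moments.
    """
    if n_shuffles < 100:
        raise ValueError("need n_shuffles >= 100 for a stable fit")
    arr = null_scores(mirna, regions, model, n=n_shuffles, seed=seed,
                      window=window)
    if arr.size == 0:
        raise CalibrationError(f"{mirna.id}: no admissible duplex in any "
                               "shuffled window")
    beta = max(float(np.sqrt(6.0 * arr.var()) / math.pi), 1e-6)
    mu = float(arr.mean() + EULER_GAMMA * beta)
    return NullCalibration(mirna_id=mirna.id, mu=mu, beta=beta,
                           n_shuffles=n_shuffles, shuffle_seed=seed)


def hit_pvalue(hit, calib: NullCalibration) -> float:
    """P(null MFE <= observed MFE) under the fitted minimum-Gumbel."""
    mfe = hit.mfe if isinstance(hit, DuplexHit) else float(hit)
    z = (mfe - calib.mu) / calib.beta
    if z > 700.0:
        return 1.0
    p = -math.expm1(-math.exp(z))
    return min(max(p, 0.0), 1.0)


def assign_pvalues(hits: Iterable[DuplexHit],
                   calib: NullCalibration) -> list[DuplexHit]:
    return [replace(h, pvalue=hit_pvalue(h, calib)) for h in hits]
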