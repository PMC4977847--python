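"""Nearest-neighbor energy model for intermolecular RNA duplexes.

The model scores one contiguous antiparallel duplex between a miRNA (5'->3')
and a target window (read 3'->5'): stacked base pairs contribute tabulated
stacking free energies; unpaired stretches on one side (bulges) or both sides
(internal loops) pay length-linear penalties; each helix end pays a fixed
terminal penalty.  Parameters live in a versioned YAML file shipped with the
package so the table can be swapped without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

#: Base encoding shared by the DP kernel and the reference enumerator.
BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
BASES = "ACGU"

#: Allowed pair types, indexed; (miRNA base, target base).
PAIR_ORDER = ("AU", "UA", "CG", "GC", "GU", "UG")
RNA_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
WATSON_CRICK = frozenset({"AU", "UA", "CG", "GC"})

DEFAULT_PARAMS = "energy_v1.yaml"


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string to int8 codes (A=0, C=1, G=2, U=3)."""
    try:
        return np.array([BASE_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"non-RNA base {exc} in sequence {seq!r}") from None


def reverse_complement(seq: str) -> str:
    return "".join(RNA_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class EnergyModel:
    """Duplex energy parameters (kcal/mol).

    Attributes
    ----------
    pair_index : (4, 4) int array; allowed-pair index or -1.
    stack : (6, 6) float array; stack[p, q] is the energy of pair type ``p``
        stacked 5'->3' (on the miRNA strand) onto pair type ``q``.
    bulge_base, bulge_slope : linear bulge penalty ``base + slope * len``.
    loop_base, loop_slope : internal-loop penalty ``base + slope * (l1+l2)``.
    helix_end_penalty : terminal penalty applied once per duplex end.
    """

    stack: np.ndarray
    bulge_base: float
    bulge_slope: float
    loop_base: float
    loop_slope: float
    helix_end_penalty: float
    version: int = 1
    pair_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        idx = np.full((4, 4), -1, dtype=np.int8)
        for k, pq in enumerate(PAIR_ORDER):
            idx[BASE_CODE[pq[0]], BASE_CODE[pq[1]]] = k
        object.__setattr__(self, "pair_index", idx)
        wc = [PAIR_ORDER.index(p) for p in WATSON_CRICK]
        if not (self.stack[np.ix_(wc, wc)] < 0).all():
            raise ValueError("all Watson-Crick stack energies must be negative")
        if min(self.bulge_base, self.bulge_slope, self.loop_base,
               self.loop_slope) < 0:
            raise ValueError("loop/bulge penalties must be non-negative")

    def bulge_penalty(self, length: int) -> float:
        return self.bulge_base + self.bulge_slope * length

    def internal_loop_penalty(self, len1: int, len2: int) -> float:
        return self.loop_base + self.loop_slope * (len1 + len2)


def load_energy_model(path=None) -> EnergyModel:
    """Load an :class:`EnergyModel` from YAML (package default if no path)."""
    if path is None:
        text = resources.files("mirx.data").joinpath(DEFAULT_PARAMS).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    stack = np.zeros((6, 6))
    for key, val in raw["stack_energies"].items():
        p, q = key.split("/")
        stack[PAIR_ORDER.index(p), PAIR_ORDER.index(q)] = float(val)
    return EnergyModel(
        stack=stack,
        bulge_base=float(raw["bulge_penalty"]["base"]),
        bulge_slope=float(raw["bulge_penalty"]["slope"]),
        loop_base=float(raw["internal_loop_penalty"]["base"]),
        loop_slope=float(raw["internal_loop_penalty"]["slope"]),
        helix_end_penalty=float(raw["helix_end_penalty"]),
        version=int(raw.get("version", 1)),
    )


_DEFAULT_MODEL = None


def default_energy_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_energy_model()
    return _DEFAULT_MODEL
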