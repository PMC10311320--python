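"""Packed-bit support vectors and stratified contingency counting.

The miner spends essentially all of its time computing pattern supports
(which samples carry a meta-marker) and turning them into the per-stratum
margins of a 2x2xC contingency table.  Supports are therefore kept as
packed bit vectors: sample ``i`` is bit ``i``, OR-composition of two
supports is a single bitwise union, and counting is a population count.

Internally a :class:`SampleBitset` wraps an arbitrary-precision integer,
which Python stores as a sequence of machine words; ``int.bit_count`` and
the bitwise operators run over whole words at C speed.  The ``words``
property exposes the canonical 64-bit-word view (padding bits zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SampleBitset",
    "StratumMasks",
    "StratifiedCounts",
    "binarize_marker",
    "or_support",
    "stratified_counts",
    "DOMINANT",
    "RECESSIVE",
]

DOMINANT = "dominant"
RECESSIVE = "recessive"


class SampleBitset:
    """A set of samples, stored as a packed bit vector of length ``n``."""

    __slots__ = ("n", "value")

    def __init__(self, n: int, value: int = 0):
        if n < 0:
            raise ValueError("sample count must be non-negative")
        self.n = n
        # mask away anything beyond bit n-1 so padding is always zero
        self.value = value & ((1 << n) - 1)

    @classmethod
    def from_indicators(cls, indicators: Iterable[int]) -> "SampleBitset":
        bits = np.asarray(list(indicators), dtype=bool)
        n = bits.size
        # little-endian bit packing: sample i -> bit i
        packed = np.packbits(bits, bitorder="little")
        return cls(n, int.from_bytes(packed.tobytes(), "little"))

    @property
    def n_words(self) -> int:
        return (self.n + 63) // 64

    @property
    def words(self) -> np.ndarray:
        """The bitset as ceil(n/64) little-endian uint64 words."""
        raw = self.value.to_bytes(self.n_words * 8, "little")
        return np.frombuffer(raw, dtype="<u8").copy()

    def popcount(self) -> int:
        return self.value.bit_count()

    def to_indicators(self) -> np.ndarray:
        raw = np.frombuffer(
            self.value.to_bytes(self.n_words * 8, "little"), dtype=np.uint8
        )
        return np.unpackbits(raw, bitorder="little")[: self.n].astype(np.int8)

    def __or__(self, other: "SampleBitset") -> "SampleBitset":
        if self.n != other.n:
            raise ValueError("bitset size mismatch: %d vs %d" % (self.n, other.n))
        return SampleBitset(self.n, self.value | other.value)

    def __and__(self, other: "SampleBitset") -> "SampleBitset":
        if self.n != other.n:
            raise ValueError("bitset size mismatch: %d vs %d" % (self.n, other.n))
        return SampleBitset(self.n, self.value & other.value)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SampleBitset)
            and self.n == other.n
            and self.value == other.value
        )

    def __hash__(self) -> int:
        return hash((self.n, self.value))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SampleBitset(n={self.n}, popcount={self.popcount()})"


def binarize_marker(genotype_row: Sequence[int], encoding: str) -> SampleBitset:
    """Binarize one marker row of additive genotypes into a support bitset.

    ``dominant``: carrier of at least one minor allele (value >= 1).
    ``recessive``: homozygous for the minor allele (value == 2).
    On already-binary input (no 2s) the dominant encoding reproduces the row.
    """
    row = np.asarray(genotype_row)
    if encoding == DOMINANT:
        return SampleBitset.from_indicators(row >= 1)
    if encoding == RECESSIVE:
        return SampleBitset.from_indicators(row == 2)
    raise ValueError(f"unknown encoding {encoding!r}")


def or_support(a: SampleBitset, b: SampleBitset) -> SampleBitset:
    """Union of two supports (a child meta-marker covers either parent's carriers)."""
    return a | b


class StratumMasks:
    """Per-covariate-class membership and case masks.

    Holds, for each stratum j, the bitset of its members and of its cases,
    together with the fixed CMH margins n_j (stratum size) and n1_j (cases),
    plus precomputed coefficients reused by the test statistic:
    ``ratio[j] = n1_j/n_j`` and ``var_coef[j] = n1_j(n_j-n1_j)/(n_j^2(n_j-1))``.
    """

    __slots__ = (
        "n",
        "C",
        "members",
        "cases",
        "n_per",
        "n1_per",
        "ratio",
        "var_coef",
        "cases_all",
    )

    def __init__(self, y: Sequence[int], c: Sequence[int]):
        y = np.asarray(y, dtype=np.int8)
        c = np.asarray(c, dtype=np.int64)
        if y.shape != c.shape:
            raise ValueError("labels and covariates differ in length")
        self.n = int(y.size)
        self.C = int(c.max()) + 1 if c.size else 0
        self.members = []
        self.cases = []
        self.n_per = []
        self.n1_per = []
        self.ratio = []
        self.var_coef = []
        for j in range(self.C):
            in_j = c == j
            if not in_j.any():
                raise ValueError(f"covariate class {j} is empty")
            memb = SampleBitset.from_indicators(in_j)
            case = SampleBitset.from_indicators(in_j & (y == 1))
            nj = memb.popcount()
            n1j = case.popcount()
            self.members.append(memb)
            self.cases.append(case)
            self.n_per.append(nj)
            self.n1_per.append(n1j)
            self.ratio.append(n1j / nj)
            self.var_coef.append(
                n1j * (nj - n1j) / (nj * nj * (nj - 1)) if nj > 1 else 0.0
            )
        self.cases_all = SampleBitset.from_indicators(y == 1)

    def __repr__(self) -> str:  # pragma: no cover
        return f"StratumMasks(n={self.n}, C={self.C}, n1={self.n1_per})"


@dataclass(frozen=True)
class StratifiedCounts:
    """Pattern margins of the 2x2xC table: x_j carriers, a_j carrier-cases."""

    x: tuple
    a: tuple
    masks: StratumMasks

    def __post_init__(self):
        for j, (xj, aj) in enumerate(zip(self.x, self.a)):
            nj = self.masks.n_per[j]
            n1j = self.masks.n1_per[j]
            if not (0 <= xj <= nj):
                raise ValueError(f"x[{j}]={xj} outside [0, {nj}]")
            if not (max(0, xj - (nj - n1j)) <= aj <= min(xj, n1j)):
                raise ValueError(f"a[{j}]={aj} infeasible for margins")


def stratified_counts(support: SampleBitset, masks: StratumMasks) -> StratifiedCounts:
    """Count pattern carriers (x_j) and carrier-cases (a_j) per stratum."""
    x = tuple((support & m).popcount() for m in masks.members)
    a = tuple((support & m).popcount() for m in masks.cases)
    return StratifiedCounts(x=x, a=a, masks=masks)
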