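"""Structural model of polychlorinated biphenyl (PCB) congeners.

A PCB is a biphenyl scaffold carrying 1-10 chlorines.  Each phenyl ring is
described by the set of chlorinated carbons in {2, 3, 4, 5, 6}; carbon 1 is
the ring-ring bond and cannot carry a chlorine.  Positions 2 and 6 are
*ortho*, 3 and 5 are *meta*, and 4 is *para* relative to that bond.  A
congener is written in chlorophenyl-ring notation, e.g. ``"2345-245"`` for
2,2',3,4,4',5,5'-heptachlorobiphenyl.

Two physical symmetries make distinct substitution strings describe the same
molecule: each ring may be flipped (2<->6, 3<->5) and the two rings may be
swapped.  The resulting symmetry group has order 8, and reducing the
2^5 x 2^5 = 1024 raw substitution patterns modulo this group (and dropping
the unchlorinated pattern) yields the classical set of 209 congeners.

This module provides canonicalization, parsing, enumeration, positional
(ortho/meta/para) accounting, flanking context of individual chlorines, and
single-step dechlorination products -- the structural substrate for all
dechlorination statistics downstream.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "BIPHENYL",
    "Congener",
    "CongenerError",
    "CongenerParseError",
    "DechlorChannel",
    "RingPattern",
    "congener_table",
    "enumerate_congeners",
    "flank_context",
    "parse_congener",
    "positional_counts",
    "single_dechlorination_products",
]

#: Terminal node label for fully dechlorinated biphenyl (not a congener).
BIPHENYL = "biphenyl"

_FLIP = {2: 6, 3: 5, 4: 4, 5: 3, 6: 2}
#: Ring-carbon adjacency among chlorinable positions (carbon 1 is the bond).
_NEIGHBORS = {2: (3,), 3: (2, 4), 4: (3, 5), 5: (4, 6), 6: (5,)}
POSITION_CLASS = {2: "ortho", 3: "meta", 4: "para", 5: "meta", 6: "ortho"}
HOMOLOG_NAMES = {
    1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta",
    6: "hexa", 7: "hepta", 8: "octa", 9: "nona", 10: "deca",
}


class CongenerError(ValueError):
    """Invalid congener structure or operation on one."""


class CongenerParseError(CongenerError):
    """Malformed chlorophenyl-ring notation label."""


@dataclass(frozen=True)
class RingPattern:
    """Chlorine substitution pattern of one phenyl ring."""

    positions: frozenset[int]

    def __post_init__(self) -> None:
        if not self.positions <= {2, 3, 4, 5, 6}:
            bad = sorted(self.positions - {2, 3, 4, 5, 6})
            raise CongenerError(f"invalid ring positions: {bad}")

    def flip(self) -> "RingPattern":
        """Mirror the ring about the 1-4 axis (2<->6, 3<->5)."""
        return RingPattern(frozenset(_FLIP[p] for p in self.positions))

    def canonical(self) -> "RingPattern":
        """Flip-minimal representative (lexicographically smaller string)."""
        flipped = self.flip()
        return self if self.digits() <= flipped.digits() else flipped

    def digits(self) -> str:
        """Sorted digit run, ``"0"`` for the unsubstituted ring."""
        return "".join(str(p) for p in sorted(self.positions)) or "0"

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class Congener:
    """A PCB congener in canonical form.  Construct via :func:`make_congener`
    or :func:`parse_congener`; direct construction skips canonicalization."""

    ring_a: RingPattern
    ring_b: RingPattern

    @property
    def label(self) -> str:
        return f"{self.ring_a.digits()}-{self.ring_b.digits()}"

    @property
    def n_cl(self) -> int:
        return len(self.ring_a) + len(self.ring_b)

    @property
    def n_ortho(self) -> int:
        return sum(1 for r in (self.ring_a, self.ring_b)
                   for p in r.positions if POSITION_CLASS[p] == "ortho")

    @property
    def n_meta(self) -> int:
        return sum(1 for r in (self.ring_a, self.ring_b)
                   for p in r.positions if POSITION_CLASS[p] == "meta")

    @property
    def n_para(self) -> int:
        return sum(1 for r in (self.ring_a, self.ring_b)
                   for p in r.positions if POSITION_CLASS[p] == "para")

    @property
    def homolog(self) -> str:
        return HOMOLOG_NAMES[self.n_cl]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _ring_sort_key(ring: RingPattern) -> tuple[bool, str]:
    # Unsubstituted ring always renders second ("245-0", not "0-245").
    return (len(ring) == 0, ring.digits())


def make_congener(ring_a: RingPattern, ring_b: RingPattern) -> Congener:
    """Canonicalize a ring pair into a :class:`Congener`.

    Canonical form: each ring flip-minimized, then the ring with the
    lexicographically smaller digit string first (an empty ring always
    second).  Idempotent, and constant on each orbit of the order-8
    symmetry group generated by {flip ring_a, flip ring_b, swap rings}.
    """
    if len(ring_a) + len(ring_b) == 0:
        raise CongenerError(
            "unchlorinated biphenyl is not a congener; use BIPHENYL sentinel")
    a, b = sorted((ring_a.canonical(), ring_b.canonical()), key=_ring_sort_key)
    return Congener(a, b)


def _parse_ring(token: str, label: str) -> RingPattern:
    if token in ("", "0"):
        return RingPattern(frozenset())
    positions: set[int] = set()
    for ch in token:
        if ch not in "23456":
            raise CongenerParseError(
                f"invalid position {ch!r} in ring {token!r} of label {label!r}"
                " (chlorinable positions are 2-6)")
        p = int(ch)
        if p in positions:
            raise CongenerParseError(
                f"repeated position {ch!r} in ring {token!r} of label {label!r}")
        positions.add(p)
    return RingPattern(frozenset(positions))


@functools.lru_cache(maxsize=8192)
def parse_congener(label: str) -> Congener:
    """Parse a chlorophenyl-ring-notation label into a canonical Congener.

    Accepts ``"2345-245"``-style labels; the unsubstituted ring may be
    written ``"0"``, left empty (``"245-"``), or omitted entirely
    (``"245"``).  Ring order and within-ring orientation are irrelevant:
    ``"245-25"`` and ``"52-542"`` parse to the same congener.
    """
    if not isinstance(label, str) or not label.strip():
        raise CongenerParseError(f"empty or non-string label: {label!r}")
    tokens = label.strip().split("-")
    if len(tokens) > 2:
        raise CongenerParseError(
            f"label {label!r} has {len(tokens)} ring tokens; at most 2 allowed")
    if len(tokens) == 1:
        tokens = [tokens[0], "0"]
    ring_a = _parse_ring(tokens[0], label)
    ring_b = _parse_ring(tokens[1], label)
    if len(ring_a) + len(ring_b) == 0:
        raise CongenerParseError(
            f"label {label!r} has no chlorines; biphenyl is not a congener")
    return make_congener(ring_a, ring_b)


@functools.lru_cache(maxsize=1)
def enumerate_congeners() -> tuple[Congener, ...]:
    """All 209 PCB congeners, canonical and deterministically ordered.

    Brute force over the 1024 ring-pair substitution patterns, deduplicated
    by canonical form, minus the zero-chlorine pattern; ordered by chlorine
    count then label.
    """
    seen: set[Congener] = set()
    subsets = [frozenset(c) for n in range(6)
               for c in itertools.combinations((2, 3, 4, 5, 6), n)]
    for pa in subsets:
        for pb in subsets:
            if pa or pb:
                seen.add(make_congener(RingPattern(pa), RingPattern(pb)))
    return tuple(sorted(seen, key=lambda c: (c.n_cl, c.label)))


def positional_counts(c: Congener) -> tuple[int, int, int]:
    """(n_ortho, n_meta, n_para) chlorine counts; they sum to ``n_cl``."""
    return (c.n_ortho, c.n_meta, c.n_para)


def _flank_of(ring: RingPattern, position: int) -> str:
    n_flanking = sum(1 for q in _NEIGHBORS[position] if q in ring.positions)
    return ("unflanked", "singly-flanked", "doubly-flanked")[n_flanking]


def flank_context(c: Congener, ring: str, position: int) -> str:
    """Flanking context of the chlorine at `position` on ring ``"a"``/``"b"``.

    A chlorine is flanked by each chlorinated adjacent ring carbon
    (adjacency 2-3, 3-4, 4-5, 5-6; ortho positions have a single
    chlorinable neighbor).  Raises :class:`CongenerError` if the position
    does not carry a chlorine.
    """
    if ring not in ("a", "b"):
        raise CongenerError(f"ring must be 'a' or 'b', got {ring!r}")
    rp = c.ring_a if ring == "a" else c.ring_b
    if position not in rp.positions:
        raise CongenerError(
            f"position {position} of ring {ring!r} in {c.label} is not chlorinated")
    return _flank_of(rp, position)


@dataclass(frozen=True)
class DechlorChannel:
    """One symmetry-distinct single-dechlorination channel of a congener.

    ``product`` is ``None`` when the parent is mono-chlorinated and the
    product is the terminal (fully dechlorinated) biphenyl.  ``multiplicity``
    counts the symmetry-equivalent chlorines feeding this channel; kinetic
    rates scale with it.
    """

    product: Congener | None
    position_class: str  # ortho / meta / para
    flank: str           # unflanked / singly-flanked / doubly-flanked
    multiplicity: int

    @property
    def product_label(self) -> str:
        return BIPHENYL if self.product is None else self.product.label


def single_dechlorination_products(c: Congener) -> tuple[DechlorChannel, ...]:
    """All single-chlorine-removal channels of a congener, symmetry-merged.

    One raw channel exists per chlorine; channels whose (canonical product,
    position class, flanking context) coincide are merged with their
    multiplicity summed, so the total multiplicity equals ``n_cl``.
    Deterministic ordering by (product label, position class, flank).
    """
    merged: dict[tuple[str, str, str], tuple[Congener | None, int]] = {}
    for ring_name, ring, other in (("a", c.ring_a, c.ring_b),
                                   ("b", c.ring_b, c.ring_a)):
        for pos in ring.positions:
            reduced = RingPattern(ring.positions - {pos})
            if len(reduced) + len(other) == 0:
                product: Congener | None = None
                key_label = BIPHENYL
            else:
                product = make_congener(reduced, other)
                key_label = product.label
            key = (key_label, POSITION_CLASS[pos], _flank_of(ring, pos))
            prev = merged.get(key)
            merged[key] = (product, (prev[1] if prev else 0) + 1)
    channels = [
        DechlorChannel(product=prod, position_class=k[1], flank=k[2],
                       multiplicity=mult)
        for k, (prod, mult) in merged.items()
    ]
    return tuple(sorted(channels,
                        key=lambda ch: (ch.product_label, ch.position_class,
                                        ch.flank)))


def congener_table() -> pd.DataFrame:
    """The 209-congener list as a DataFrame
    (label, n_cl, n_ortho, n_meta, n_para, homolog)."""
    rows = [(c.label, c.n_cl, c.n_ortho, c.n_meta, c.n_para, c.homolog)
            for c in enumerate_congeners()]
    return pd.DataFrame(
        rows, columns=["label", "n_cl", "n_ortho", "n_meta", "n_para", "homolog"])
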