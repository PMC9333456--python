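"""Canonical strand-packing templates for the 8-stranded C2 beta-sandwich.

A C2 domain is two four-stranded antiparallel sheets packed face to face.
Each template lists, per sheet, the spatial (left-to-right) order of the
strands by their 1-based sequence ordinal.  The Type-I arrangement is the
synaptotagmin-like connectivity; Type-II is its single-step circular
permutation (Type-I strand k occupies the slot of Type-II strand k-1, with
strand 1 wrapping to strand 8).  In the Type-II arrangement strands 1 and 2
are sheet neighbours, so the beta1-2 connection is a hairpin at the pocket
apex -- the structural reading of "loop 1" for Type-II domains.

Templates are data, not code: the pairing sets derived from them are what
the topology classifier matches against.
"""

from __future__ import annotations

TYPE_I = "Type-I"
TYPE_II = "Type-II"
AMBIGUOUS = "ambiguous"

#: Spatial strand order per sheet, strands named by sequence ordinal 1..8.
TEMPLATE_SHEETS: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {
    TYPE_I: ((4, 1, 8, 5), (3, 2, 7, 6)),
    TYPE_II: ((3, 8, 7, 4), (2, 1, 6, 5)),
}


def permutation_offset(topology: str) -> int:
    return {TYPE_I: 0, TYPE_II: 1}[topology]


def template_for_offset(offset: int) -> str:
    return {0: TYPE_I, 1: TYPE_II}[offset % 2]


def template_pairs(topology: str) -> frozenset[frozenset[int]]:
    """Unordered sheet-neighbour pairs implied by a template."""
    pairs = set()
    for sheet in TEMPLATE_SHEETS[topology]:
        for a, b in zip(sheet, sheet[1:]):
            pairs.add(frozenset((a, b)))
    return frozenset(pairs)


def circular_permute(ordinals: frozenset[frozenset[int]],
                     step: int = 1) -> frozenset[frozenset[int]]:
    """Shift every strand ordinal by ``step`` (cyclic over 1..8)."""
    return frozenset(
        frozenset((a - 1 + step) % 8 + 1 for a in pair) for pair in ordinals
    )
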