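"""Monophyly checks on externally built trees and 16S-style nucleotide utilities.

Tree construction itself happens outside this package (any ML program that
writes newick); here a clade claim is verified against the tree. On an
unrooted tree a leaf set is monophyletic iff it is exactly one side of some
edge's bipartition; on a rooted tree it must be exactly the leaf set of
some node's subtree.

The nucleotide utilities support identity sanity checks between 16S rRNA
sequences: plain percent identity and the Kimura 2-parameter distance
``d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))`` with transitions ``P`` and
transversions ``Q`` counted over pairwise-complete (non-gap, non-N) columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import dendropy

from .core_genome import _make_aligner, pairwise_identity
from .seqio import GAP, parse_newick

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """K2P distance undefined: substitution fractions at/beyond saturation."""


@dataclass(frozen=True)
class Bipartition:
    side_a: frozenset[str]
    side_b: frozenset[str]

    def __post_init__(self) -> None:
        if not self.side_a or not self.side_b:
            raise ValueError("both sides of a bipartition must be non-empty")
        if self.side_a & self.side_b:
            raise ValueError("bipartition sides must be disjoint")


class MonophylyResult(NamedTuple):
    monophyletic: bool
    witness: Bipartition | None      # the separating edge's bipartition
    intruding: frozenset[str]        # foreign leaves inside the best edge
    excluded: frozenset[str]         # queried taxa outside the best edge


def _ensure_tree(tree) -> dendropy.Tree:
    if isinstance(tree, str):
        return parse_newick(tree)
    return tree


def edge_bipartitions(tree) -> list[Bipartition]:
    """Non-trivial bipartitions induced by the internal edges of a tree."""
    tree = _ensure_tree(tree)
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = leaves - below
        if len(below) < 2 or len(other) < 2:
            continue
        out.append(Bipartition(below, other))
    return out


def is_monophyletic(tree, taxa) -> MonophylyResult:
    """Do the taxa form a clade in the tree?

    Unrooted trees use the edge-bipartition definition (either side of an
    edge may equal the taxa); rooted trees require a subtree. On failure,
    the result reports intruding/excluded leaves relative to the edge whose
    split best matches the query.
    """
    tree = _ensure_tree(tree)
    taxa = frozenset(taxa)
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    missing = taxa - leaves
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    if not taxa:
        raise ValueError("empty taxon set")
    if taxa == leaves or len(taxa) == 1:
        return MonophylyResult(True, None, frozenset(), frozenset())

    rooted = bool(tree.is_rooted)
    best_side, best_score = None, None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sides = [below] if rooted else [below, leaves - below]
        for side in sides:
            if side == taxa:
                witness = Bipartition(side, leaves - side) if leaves - side \
                    else None
                return MonophylyResult(True, witness, frozenset(), frozenset())
            score = len(side ^ taxa)
            if best_score is None or score < best_score:
                best_side, best_score = side, score
    intruding = frozenset(best_side - taxa) if best_side else frozenset()
    excluded = frozenset(taxa - best_side) if best_side else frozenset()
    return MonophylyResult(False, None, intruding, excluded)


# ---------------------------------------------------------------------------
# Nucleotide utilities

def _aligned_pair(a: str, b: str, aligned: bool) -> tuple[str, str]:
    a, b = a.upper(), b.upper()
    if aligned:
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        return a, b
    aligner = _make_aligner("global")
    aln = aligner.align(a.replace(GAP, ""), b.replace(GAP, ""))[0]
    return str(aln[0]), str(aln[1])


class K2PResult(NamedTuple):
    distance: float
    P: float  # transition proportion
    Q: float  # transversion proportion
    compared: int


def k2p_distance(a: str, b: str, aligned: bool = True) -> K2PResult:
    """Kimura 2-parameter distance in substitutions/site, with (P, Q).

    Gap and ``N`` columns are excluded from the denominator (pairwise
    deletion). Raises :class:`SaturationError` when ``1 - 2P - Q <= 0`` or
    ``1 - 2Q <= 0``.
    """
    sa, sb = _aligned_pair(a, b, aligned)
    compared = transitions = transversions = 0
    for x, y in zip(sa, sb):
        if x not in "ACGT" or y not in "ACGT":
            continue
        compared += 1
        if x == y:
            continue
        same_class = ({x, y} <= PURINES) or ({x, y} <= PYRIMIDINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if compared == 0:
        raise ValueError("K2P undefined: zero compared columns")
    P = transitions / compared
    Q = transversions / compared
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P saturated: 1-2P-Q={w1:.4f}, 1-2Q={w2:.4f}")
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(d, P, Q, compared)


def percent_identity_nt(a: str, b: str, aligned: bool = True) -> float:
    """Percent identity over compared (non-gap, non-N) columns."""
    sa, sb = _aligned_pair(a, b, aligned)
    res = pairwise_identity(sa, sb, mode="aligned")
    return 100.0 * res.fraction
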