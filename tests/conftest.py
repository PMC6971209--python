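import numpy as np
import pytest

from cladesig.seqio import GAP, AlignedRow, Alignment, CladeMap, SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n: int) -> str:
    return "".join(AA[i] for i in rng.integers(len(AA), size=n))


def with_gap(seq: str, span: tuple[int, int]) -> str:
    """Replace the 1-based closed span with gap characters."""
    s, e = span
    return seq[:s - 1] + GAP * (e - s + 1) + seq[e:]


def two_clade_map(n_in: int = 4, n_out: int = 4,
                  max_ingroup_absent: int | None = None) -> CladeMap:
    assignment = {f"in{i}": "X" for i in range(1, n_in + 1)}
    assignment.update({f"out{i}": "Y" for i in range(1, n_out + 1)})
    return CladeMap(assignment, frozenset({"X"}), frozenset({"Y"}),
                    max_ingroup_absent)


def signature_case(rng, length: int = 120, span: tuple[int, int] = (60, 61),
                   kind: str = "deletion", n_in: int = 4, n_out: int = 4,
                   in_spans=None, extra_out_gapped: int = 0):
    """A toy family alignment with a clean clade-splitting gap pattern.

    Deletion: ingroup rows gapped over ``span`` (per-row override via
    ``in_spans``); insertion: outgroup rows gapped. ``extra_out_gapped``
    additionally gaps that many outgroup rows (deletion exceptions).
    """
    base = random_protein(rng, length)
    rows = []
    for k in range(1, n_in + 1):
        seq = base
        if kind == "deletion":
            seq = with_gap(base, in_spans[k - 1] if in_spans else span)
        rows.append(AlignedRow(f"in{k}|P", f"in{k}", seq))
    for k in range(1, n_out + 1):
        seq = base
        if kind == "insertion" or k <= extra_out_gapped:
            seq = with_gap(base, span)
        rows.append(AlignedRow(f"out{k}|P", f"out{k}", seq))
    return Alignment(rows), two_clade_map(n_in, n_out)


def pool_from_alignment(aln: Alignment) -> list[SequenceRecord]:
    return [SequenceRecord(r.id, r.genome, r.seq.replace(GAP, ""))
            for r in aln.rows]


# ---------------------------------------------------------------------------
# Independent oracles

def oracle_greedy_partition(records, id_threshold, len_threshold,
                            identity_fn) -> list[frozenset]:
    """Brute-force restatement of the greedy clustering rule: length-sorted
    records join the first cluster whose seed they match above both
    thresholds. Shares only the pairwise-identity primitive with the
    implementation under test."""
    ordered = sorted(records, key=lambda r: (-len(r.residues), r.id))
    seeds, groups = [], []
    for rec in ordered:
        for seed, group in zip(seeds, groups):
            la, lb = len(rec.residues), len(seed.residues)
            if min(la, lb) / max(la, lb) <= len_threshold:
                continue
            if identity_fn(rec, seed) > id_threshold:
                group.append(rec.id)
                break
        else:
            seeds.append(rec)
            groups.append([rec.id])
    return [frozenset(g) for g in groups]


def random_tree_newick(rng, n_leaves: int) -> str:
    """Random topology by iterative joining; labels L1..Ln."""
    nodes = [f"L{i}" for i in range(1, n_leaves + 1)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return "(" + ",".join(nodes) + ");"


def oracle_monophyletic(newick: str, taxa: set[str]) -> bool:
    """Unrooted monophyly by edge removal on a graph built straight from the
    newick string (independent of the tree library)."""
    import itertools

    counter = itertools.count()
    edges, leaves = [], {}

    def parse(s, lo, hi):
        node = next(counter)
        if s[lo] != "(":
            leaves[node] = s[lo:hi]
            return node
        depth, start = 0, lo + 1
        for k in range(lo, hi):
            ch = s[k]
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth == 0:
                    child = parse(s, start, k)
                    edges.append((node, child))
            elif ch == "," and depth == 1:
                child = parse(s, start, k)
                edges.append((node, child))
                start = k + 1
        return node

    body = newick.strip().rstrip(";")
    parse(body, 0, len(body))
    all_leaves = set(leaves.values())
    if taxa == all_leaves or len(taxa) == 1:
        return True
    for drop in range(len(edges)):
        adj = {}
        for k, (a, b) in enumerate(edges):
            if k == drop:
                continue
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        a0 = edges[drop][0]
        seen = {a0}
        stack = [a0]
        while stack:
            n = stack.pop()
            for m in adj.get(n, []):
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        side = {leaves[n] for n in seen if n in leaves}
        if taxa in (side, all_leaves - side):
            return True
    return False
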