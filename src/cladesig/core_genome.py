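"""Greedy protein-family clustering, core-family selection, and supermatrix assembly.

The clustering emulates the conventional length-sorted greedy strategy used
for core-genome selection: records are processed longest-first and join the
first existing cluster whose representative they match above an identity
threshold (default >50%) and a length-ratio threshold (default >50%); the
seed of each cluster is its representative. Identity between unaligned
sequences is computed on a standard global alignment (match +1, mismatch 0,
linear gap -1) with gap and ambiguity columns excluded from the denominator.

A simple star-progressive multiple aligner and a gap-fraction column trimmer
are provided so the whole pipeline runs at desk scale with no external
aligner; an external-aligner command may be substituted upstream by writing
aligned FASTA and reading it back through :mod:`cladesig.seqio`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from Bio import Align

from .seqio import GAP, AlignedRow, Alignment, SequenceRecord, alphabet_set

logger = logging.getLogger(__name__)

_AMBIG = {"X", "N"}


class IdentityResult(NamedTuple):
    fraction: float
    identical: int
    compared: int


def _make_aligner(mode: str = "global", match: float = 1.0,
                  mismatch: float = 0.0, gap: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def _residues(x) -> str:
    return x.residues if isinstance(x, SequenceRecord) else str(x)


def pairwise_identity(a, b, mode: str = "global",
                      match: float = 1.0, mismatch: float = 0.0,
                      gap: float = -1.0) -> IdentityResult:
    """Fraction of identical residue pairs over compared columns.

    ``mode='aligned'`` takes two equal-length gapped strings; ``mode='global'``
    first builds a global alignment of the two gap-free sequences. Columns
    where either symbol is a gap or an ambiguity code (X/N) are excluded from
    the ``compared`` denominator. Zero compared columns is an error
    (identity undefined).
    """
    sa, sb = _residues(a), _residues(b)
    if mode == "aligned":
        if len(sa) != len(sb):
            raise ValueError("aligned mode requires equal-length strings")
        pairs = zip(sa, sb)
    elif mode == "global":
        aligner = _make_aligner("global", match, mismatch, gap)
        aln = aligner.align(sa, sb)[0]
        pairs = zip(str(aln[0]), str(aln[1]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    identical = compared = 0
    for x, y in pairs:
        if x == GAP or y == GAP or x in _AMBIG or y in _AMBIG:
            continue
        compared += 1
        if x == y:
            identical += 1
    if compared == 0:
        raise ValueError("identity undefined: zero compared columns")
    return IdentityResult(identical / compared, identical, compared)


@dataclass
class ProteinFamily:
    """A cluster of homologous proteins; the representative is the seed
    (longest member, ties broken by lexicographic id)."""

    family_id: str
    members: list[SequenceRecord]
    representative: str  # member id

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("family must be non-empty")

    @property
    def genomes(self) -> set[str]:
        return {m.genome for m in self.members}

    @property
    def representative_record(self) -> SequenceRecord:
        for m in self.members:
            if m.id == self.representative:
                return m
        raise KeyError(self.representative)


def greedy_cluster(records: Sequence[SequenceRecord],
                   id_threshold: float = 0.5,
                   len_threshold: float = 0.5) -> list[ProteinFamily]:
    """Cluster proteins greedily by identity to cluster representatives.

    Records are sorted by decreasing length (ties by lexicographic id); each
    joins the first cluster whose representative it matches with identity
    strictly above ``id_threshold`` and length ratio (short/long) strictly
    above ``len_threshold``, else it seeds a new cluster. Deterministic for
    a given input set.
    """
    if not records:
        raise ValueError("no records to cluster")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[SequenceRecord] = []
    members: list[list[SequenceRecord]] = []
    for rec in ordered:
        placed = False
        for i, rep in enumerate(reps):
            ratio = min(len(rec), len(rep)) / max(len(rec), len(rep))
            if ratio <= len_threshold:
                continue
            ident = pairwise_identity(rec, rep).fraction
            if ident > id_threshold:
                members[i].append(rec)
                placed = True
                break
        if not placed:
            reps.append(rec)
            members.append([rec])
    return [
        ProteinFamily(f"F{i:04d}", mem, rep.id)
        for i, (rep, mem) in enumerate(zip(reps, members), 1)
    ]


def resolve_paralogs(family: ProteinFamily) -> ProteinFamily:
    """Keep one member per genome: the one most similar to the representative.

    Ties break by lexicographic id; the representative itself is always
    retained. Dropped paralogs are logged.
    """
    rep = family.representative_record
    by_genome: dict[str, list[SequenceRecord]] = {}
    for m in family.members:
        by_genome.setdefault(m.genome, []).append(m)
    kept: list[SequenceRecord] = []
    for genome, group in by_genome.items():
        if len(group) == 1:
            kept.append(group[0])
            continue
        if rep.genome == genome:
            best = rep
        else:
            best = max(group, key=lambda m: (pairwise_identity(m, rep).fraction, m.id)
                       if m.id != rep.id else (2.0, m.id))
        for m in group:
            if m is not best:
                logger.info("family %s: dropping paralog %s from genome %s",
                            family.family_id, m.id, genome)
        kept.append(best)
    kept.sort(key=lambda m: [x.id for x in family.members].index(m.id))
    return ProteinFamily(family.family_id, kept, family.representative)


def select_core(families: Iterable[ProteinFamily], genomes: Iterable[str],
                min_presence: float = 0.8) -> list[ProteinFamily]:
    """Keep paralog-resolved families present in >= ceil(min_presence * |genomes|)
    distinct genomes."""
    genomes = set(genomes)
    if not genomes:
        raise ValueError("empty genome set")
    need = math.ceil(min_presence * len(genomes))
    out = []
    for fam in families:
        fam = resolve_paralogs(fam)
        if len(fam.genomes & genomes) >= need:
            out.append(fam)
    return out


# ---------------------------------------------------------------------------
# Progressive (star) multiple alignment

def _pairwise_rows(center: str, other: str) -> tuple[str, str]:
    aligner = _make_aligner("global")
    aln = aligner.align(center, other)[0]
    return str(aln[0]), str(aln[1])


def _insertion_profile(gapped_center: str) -> list[int]:
    """ins[i] = gap run length in the gapped center before consuming its i-th
    residue (i = number of residues consumed; the final slot is trailing)."""
    n_res = len(gapped_center.replace(GAP, ""))
    ins = [0] * (n_res + 1)
    consumed = 0
    for ch in gapped_center:
        if ch == GAP:
            ins[consumed] += 1
        else:
            consumed += 1
    return ins


def align_progressive(records: Sequence[SequenceRecord]) -> Alignment:
    """Star-progressive multiple alignment around the longest sequence.

    Every sequence is globally aligned to the center; gaps opened in the
    center are merged across the pairwise alignments ("once a gap, always a
    gap"). Adequate for the conserved families this package targets; not a
    substitute for a profile aligner on divergent data.
    """
    if not records:
        raise ValueError("nothing to align")
    if len(records) == 1:
        r = records[0]
        return Alignment([AlignedRow(r.id, r.genome, r.residues)])
    center_idx = min(range(len(records)),
                     key=lambda i: (-len(records[i]), records[i].id))
    center = records[center_idx]
    n_res = len(center)

    pairs: dict[int, tuple[str, str]] = {}
    master_ins = [0] * (n_res + 1)
    for i, rec in enumerate(records):
        if i == center_idx:
            continue
        gc, go = _pairwise_rows(center.residues, rec.residues)
        pairs[i] = (gc, go)
        for slot, k in enumerate(_insertion_profile(gc)):
            master_ins[slot] = max(master_ins[slot], k)

    def center_row() -> str:
        out = []
        for slot in range(n_res + 1):
            out.append(GAP * master_ins[slot])
            if slot < n_res:
                out.append(center.residues[slot])
        return "".join(out)

    def other_row(gc: str, go: str) -> str:
        # split go into per-slot chunks following the gapped center
        chunks: list[str] = [""] * (n_res + 1)
        aligned_to: list[str] = [""] * n_res
        consumed = 0
        for c_ch, o_ch in zip(gc, go):
            if c_ch == GAP:
                chunks[consumed] += o_ch
            else:
                aligned_to[consumed] = o_ch
                consumed += 1
        out = []
        for slot in range(n_res + 1):
            pad = master_ins[slot] - len(chunks[slot])
            out.append(GAP * pad + chunks[slot])
            if slot < n_res:
                out.append(aligned_to[slot])
        return "".join(out)

    rows = []
    for i, rec in enumerate(records):
        if i == center_idx:
            rows.append(AlignedRow(rec.id, rec.genome, center_row()))
        else:
            rows.append(AlignedRow(rec.id, rec.genome, other_row(*pairs[i])))
    return Alignment(rows)


# ---------------------------------------------------------------------------
# Trimming and concatenation

def trim_alignment(aln: Alignment, max_gap_fraction: float = 0.5,
                   min_conservation: float = 0.0) -> tuple[Alignment, list[int]]:
    """Drop columns with gap fraction > ``max_gap_fraction`` or whose
    majority-residue frequency (over all rows) < ``min_conservation``.

    Returns the trimmed alignment and the kept columns (original 1-based
    indices) for coordinate back-translation.
    """
    n_rows = aln.n_rows
    kept: list[int] = []
    for col in range(1, aln.n_cols + 1):
        chars = aln.column(col)
        n_gap = chars.count(GAP)
        if n_gap / n_rows > max_gap_fraction:
            continue
        residues = [c for c in chars if c != GAP]
        if not residues:
            continue
        majority = max(residues.count(c) for c in set(residues))
        if majority / n_rows < min_conservation:
            continue
        kept.append(col)
    if not kept:
        raise ValueError("trimming removed every column")
    rows = [
        AlignedRow(r.id, r.genome, "".join(r.seq[c - 1] for c in kept))
        for r in aln.rows
    ]
    return Alignment(rows, top_index=aln.top_index), kept


@dataclass
class Supermatrix:
    """Concatenated per-family alignments over a fixed genome list.

    ``partitions`` tiles ``[1, n_cols]`` with closed ranges, one per family;
    genomes missing a family carry an all-gap block there.
    """

    alignment: Alignment  # one row per genome, row id == genome label
    partitions: list[tuple[str, int, int]]


def concatenate(family_alignments: Sequence[tuple[str, Alignment]],
                genomes: Sequence[str]) -> Supermatrix:
    """Concatenate family alignments into a supermatrix over ``genomes``.

    Each alignment's rows map to genomes via their genome labels; a genome
    appearing twice in one family is an error (resolve paralogs first).
    """
    if not family_alignments:
        raise ValueError("no family alignments to concatenate")
    if not genomes:
        raise ValueError("empty genome list")
    blocks: dict[str, list[str]] = {g: [] for g in genomes}
    partitions: list[tuple[str, int, int]] = []
    start = 1
    for fam_id, aln in family_alignments:
        seen: dict[str, str] = {}
        for row in aln.rows:
            if row.genome in seen:
                raise ValueError(
                    f"family {fam_id}: genome {row.genome!r} appears twice")
            seen[row.genome] = row.seq
        width = aln.n_cols
        for g in genomes:
            blocks[g].append(seen.get(g, GAP * width))
        partitions.append((fam_id, start, start + width - 1))
        start += width
    rows = [AlignedRow(g, g, "".join(blocks[g])) for g in genomes]
    return Supermatrix(Alignment(rows), partitions)


def supermatrix_slice(sm: Supermatrix, genome: str, family_id: str) -> str:
    """De-gapped sequence of ``genome`` within one partition (empty if absent)."""
    for fam, start, end in sm.partitions:
        if fam == family_id:
            row = sm.alignment.row_by_genome(genome)
            return row.seq[start - 1:end].replace(GAP, "")
    raise KeyError(family_id)
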