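"""Readers/writers for FASTA, aligned FASTA, newick, and the clade-map config.

Coordinate conventions used throughout the package
--------------------------------------------------
* Alignment columns and sequence positions are **1-based**; all ranges are
  **closed intervals** (a range ``159-209`` includes both endpoints).
* The gap character is ``'-'`` and appears only inside :class:`Alignment`
  rows; :class:`SequenceRecord` residues are always gap-free.
* Ambiguity codes (``X`` for amino acids, ``N`` for nucleotides) are legal
  residues but are never counted as matches by any comparison in the package.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import yaml

GAP = "-"
AA_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
NT_RESIDUES = frozenset("ACGT")
AMBIGUOUS = {"aa": "X", "nt": "N"}


class ParseError(ValueError):
    """Malformed input file (FASTA, newick, or clade map)."""


def alphabet_set(alphabet: str) -> frozenset[str]:
    """Return the legal residue set (ambiguity code included) for ``aa``/``nt``."""
    if alphabet == "aa":
        return AA_RESIDUES | {"X"}
    if alphabet == "nt":
        return NT_RESIDUES | {"N"}
    raise ValueError(f"unknown alphabet {alphabet!r}; expected 'aa' or 'nt'")


@dataclass
class SequenceRecord:
    """One named, gap-free amino-acid or nucleotide sequence.

    ``genome`` carries the source-genome label used for clade assignment;
    by default it is the stem of the FASTA file the record came from.
    """

    id: str
    genome: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignedRow:
    id: str
    genome: str
    seq: str


@dataclass
class Alignment:
    """A column-indexed multiple sequence alignment.

    ``top_index`` designates the reference ("top") row used for window
    coordinates and dash-identity rendering.
    """

    rows: list[AlignedRow]
    top_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        n = len(self.rows[0].seq)
        for r in self.rows:
            if len(r.seq) != n:
                raise ValueError(
                    f"row {r.id!r} has length {len(r.seq)}, expected {n}"
                )
        if not 0 <= self.top_index < len(self.rows):
            raise ValueError("top_index out of range")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0].seq)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col``, top to bottom."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} outside [1, {self.n_cols}]")
        return "".join(r.seq[col - 1] for r in self.rows)

    def degapped(self, row_index: int) -> str:
        return self.rows[row_index].seq.replace(GAP, "")

    def residue_columns(self, row_index: int) -> list[int]:
        """1-based columns at which the row carries a residue (non-gap)."""
        return [i + 1 for i, ch in enumerate(self.rows[row_index].seq) if ch != GAP]

    def position_of_column(self, row_index: int, col: int) -> int:
        """1-based ungapped position of the residue at/preceding ``col``.

        Returns the number of residues of the row in columns ``1..col``;
        0 if the row has no residue at or before ``col``.
        """
        return sum(1 for ch in self.rows[row_index].seq[:col] if ch != GAP)

    def row_by_genome(self, genome: str) -> AlignedRow:
        for r in self.rows:
            if r.genome == genome:
                return r
        raise KeyError(genome)


@dataclass
class CladeMap:
    """Genome-to-clade assignment plus the ingroup/outgroup partition for a scan.

    ``max_ingroup_absent`` bounds how many ingroup genomes may lack a homolog
    in a scanned family before the family is skipped; ``None`` means
    unlimited (absences are still reported on each candidate).
    """

    assignment: dict[str, str]
    ingroup: frozenset[str]
    outgroup: frozenset[str]
    max_ingroup_absent: int | None = None

    def __post_init__(self) -> None:
        self.ingroup = frozenset(self.ingroup)
        self.outgroup = frozenset(self.outgroup)
        if not self.ingroup:
            raise ValueError("ingroup must be non-empty")
        if not self.outgroup:
            raise ValueError("outgroup must be non-empty")
        overlap = self.ingroup & self.outgroup
        if overlap:
            raise ValueError(f"clades in both ingroup and outgroup: {sorted(overlap)}")
        known = set(self.assignment.values())
        missing = (self.ingroup | self.outgroup) - known
        if missing:
            raise ValueError(f"ingroup/outgroup clades with no genomes: {sorted(missing)}")

    def clade(self, genome: str) -> str | None:
        return self.assignment.get(genome)

    def role(self, genome: str) -> str | None:
        """``'ingroup'`` / ``'outgroup'`` / ``None`` for the genome's scan role."""
        clade = self.assignment.get(genome)
        if clade is None:
            return None
        if clade in self.ingroup:
            return "ingroup"
        if clade in self.outgroup:
            return "outgroup"
        return None

    @property
    def genomes(self) -> set[str]:
        return set(self.assignment)

    def ingroup_genomes(self) -> set[str]:
        return {g for g, c in self.assignment.items() if c in self.ingroup}

    def outgroup_genomes(self) -> set[str]:
        return {g for g, c in self.assignment.items() if c in self.outgroup}

    def with_scan(
        self,
        ingroup: set[str],
        outgroup: set[str] | None = None,
        max_ingroup_absent: int | None = None,
    ) -> "CladeMap":
        """A copy re-partitioned for a different scan (same assignment)."""
        ingroup = set(ingroup)
        if outgroup is None:
            outgroup = set(self.assignment.values()) - ingroup
        return CladeMap(dict(self.assignment), frozenset(ingroup), frozenset(outgroup),
                        max_ingroup_absent)


# ---------------------------------------------------------------------------
# FASTA

def _iter_fasta(handle) -> list[tuple[str, str]]:
    header = None
    chunks: list[str] = []
    out: list[tuple[str, str]] = []
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n").rstrip("\r")
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                out.append((header, "".join(chunks)))
            header = line[1:].strip()
            if not header:
                raise ParseError(f"empty FASTA header at line {lineno}")
            chunks = []
        else:
            if header is None:
                raise ParseError(f"sequence data before first header at line {lineno}")
            chunks.append(line.strip())
    if header is not None:
        out.append((header, "".join(chunks)))
    return out


def _validate_residues(seq: str, record_id: str, alphabet: str, allow_gap: bool) -> str:
    legal = alphabet_set(alphabet)
    if allow_gap:
        legal = legal | {GAP}
    seq = seq.upper()
    for pos, ch in enumerate(seq, 1):
        if ch not in legal:
            raise ParseError(
                f"record {record_id!r}: illegal {alphabet} residue {ch!r} at position {pos}"
            )
    return seq


def _genome_from_header(header: str, path, genome: str | None,
                        genome_delimiter: str | None, genome_field: int) -> str:
    if genome is not None:
        return genome
    if genome_delimiter is not None:
        parts = header.split(genome_delimiter)
        if len(parts) > genome_field:
            return parts[genome_field].strip()
        raise ParseError(
            f"header {header!r} has no field {genome_field} under delimiter "
            f"{genome_delimiter!r}"
        )
    if path is None:
        return header.split()[0]
    return Path(path).stem


def read_fasta(
    path,
    alphabet: str = "aa",
    genome: str | None = None,
    genome_delimiter: str | None = None,
    genome_field: int = 1,
) -> list[SequenceRecord]:
    """Read an (unaligned) FASTA file into :class:`SequenceRecord` objects.

    The genome label is, in order of precedence: the explicit ``genome``
    argument; the ``genome_field``-th token of the header split on
    ``genome_delimiter``; the file stem (one proteome file per genome).
    Residues outside the declared alphabet (case-folded, ``X``/``N``
    allowed) raise :class:`ParseError` naming the record and position.
    """
    opened = isinstance(path, (str, Path))
    handle = open(path) if opened else path
    try:
        raw = _iter_fasta(handle)
    finally:
        if opened:
            handle.close()
    records = []
    for header, seq in raw:
        rid = header.split()[0]
        desc = header[len(rid):].strip()
        seq = _validate_residues(seq, rid, alphabet, allow_gap=False)
        if not seq:
            raise ParseError(f"record {rid!r} has an empty sequence")
        g = _genome_from_header(header, path if opened else None, genome,
                                genome_delimiter, genome_field)
        records.append(SequenceRecord(rid, g, seq, desc))
    return records


def read_alignment_fasta(path, alphabet: str = "aa", top: str | None = None,
                         **kwargs) -> Alignment:
    """Read an aligned FASTA (gap char ``-``) into an :class:`Alignment`.

    ``top`` selects the reference row by record id (default: first row).
    """
    opened = isinstance(path, (str, Path))
    handle = open(path) if opened else path
    try:
        raw = _iter_fasta(handle)
    finally:
        if opened:
            handle.close()
    if not raw:
        raise ParseError("alignment FASTA contains no records")
    rows = []
    for header, seq in raw:
        rid = header.split()[0]
        seq = _validate_residues(seq, rid, alphabet, allow_gap=True)
        g = _genome_from_header(header, path if opened else None,
                                kwargs.get("genome"), kwargs.get("genome_delimiter"),
                                kwargs.get("genome_field", 1))
        rows.append(AlignedRow(rid, g, seq))
    top_index = 0
    if top is not None:
        ids = [r.id for r in rows]
        if top not in ids:
            raise ParseError(f"top row {top!r} not present in alignment")
        top_index = ids.index(top)
    return Alignment(rows, top_index=top_index)


def write_fasta(records, path, width: int = 70) -> None:
    """Write records as FASTA; headers are ``>id description``."""
    opened = isinstance(path, (str, Path))
    handle = open(path, "w") if opened else path
    try:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i:i + width] + "\n")
    finally:
        if opened:
            handle.close()


def write_alignment_fasta(aln: Alignment, path, width: int = 70) -> None:
    opened = isinstance(path, (str, Path))
    handle = open(path, "w") if opened else path
    try:
        for row in aln.rows:
            handle.write(f">{row.id}\n")
            for i in range(0, len(row.seq), width):
                handle.write(row.seq[i:i + width] + "\n")
    finally:
        if opened:
            handle.close()


# ---------------------------------------------------------------------------
# Newick

def parse_newick(text: str) -> dendropy.Tree:
    """Parse one newick tree; leaf labels must be unique.

    Rootedness follows the ``[&R]``/``[&U]`` hint when present; otherwise
    the tree is treated as unrooted (the common convention for trees built
    by ML programs).
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            rooting="default-unrooted",
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ParseError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"duplicate leaf labels: {dups}")
    return tree


def read_newick(path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree, path=None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Clade map config (YAML; JSON is a YAML subset)

_CLADE_MAP_KEYS = {"clades", "ingroup", "outgroup", "max_ingroup_absent"}


def read_clade_map(path) -> CladeMap:
    """Read a clade-map config with keys ``clades``, ``ingroup``, ``outgroup``,
    ``max_ingroup_absent``.

    ``outgroup`` defaults to every clade not in the ingroup. A genome listed
    in two clades, an empty ingroup, or an unknown top-level key is an error.
    """
    if isinstance(path, (str, Path)):
        data = yaml.safe_load(Path(path).read_text())
    else:
        data = yaml.safe_load(path)
    if not isinstance(data, dict):
        raise ParseError("clade map must be a mapping")
    unknown = set(data) - _CLADE_MAP_KEYS
    if unknown:
        raise ParseError(f"unknown clade-map keys: {sorted(unknown)}")
    clades = data.get("clades")
    if not isinstance(clades, dict) or not clades:
        raise ParseError("clade map needs a non-empty 'clades' mapping")
    assignment: dict[str, str] = {}
    for clade, genomes in clades.items():
        if not isinstance(genomes, (list, tuple)):
            raise ParseError(f"clade {clade!r} must list its genomes")
        for g in genomes:
            g = str(g)
            if g in assignment:
                raise ParseError(
                    f"genome {g!r} assigned to both {assignment[g]!r} and {clade!r}"
                )
            assignment[g] = str(clade)
    ingroup = data.get("ingroup") or []
    if not ingroup:
        raise ParseError("clade map must declare a non-empty ingroup")
    ingroup = {str(c) for c in ingroup}
    outgroup = data.get("outgroup")
    if outgroup is None:
        outgroup = set(clades) - ingroup
    else:
        outgroup = {str(c) for c in outgroup}
    bad = (ingroup | outgroup) - set(map(str, clades))
    if bad:
        raise ParseError(f"ingroup/outgroup references unknown clades: {sorted(bad)}")
    try:
        return CladeMap(assignment, frozenset(ingroup), frozenset(outgroup),
                        data.get("max_ingroup_absent"))
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def write_clade_map(cm: CladeMap, path) -> None:
    clades: dict[str, list[str]] = {}
    for g, c in sorted(cm.assignment.items()):
        clades.setdefault(c, []).append(g)
    data = {
        "clades": clades,
        "ingroup": sorted(cm.ingroup),
        "outgroup": sorted(cm.outgroup),
    }
    if cm.max_ingroup_absent is not None:
        data["max_ingroup_absent"] = cm.max_ingroup_absent
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
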