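"""Plain-text signature excerpts with dash-identity masking.

The display convention: the reference (top) sequence is printed in full;
every other row prints ``'-'`` where its residue is identical to the top
row's residue in that column, the literal residue where it differs, and a
blank at alignment gaps. The indel region is delimited with ``'|'`` box
markers, ingroup rows are listed before outgroup rows, and the excerpt's
position range on the ungapped top sequence heads the block. Dash-masking
is invertible given the top row, so the excerpt is a lossless view of the
underlying alignment slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .csi_finder import CSIRecord
from .seqio import GAP, Alignment, CladeMap

BLANK = " "


@dataclass
class SignatureBlock:
    title: str
    column_header: str                       # e.g. "159-209"
    rows: list[tuple[str, str, str, str]]    # (group, species, accession, masked seq)
    box: tuple[int, int]                     # 1-based closed columns within excerpt
    n_ingroup: int = 0

    def __post_init__(self) -> None:
        widths = {len(r[3]) for r in self.rows}
        if len(widths) != 1:
            raise ValueError("masked rows must share one length")
        w = widths.pop()
        if not (1 <= self.box[0] <= self.box[1] <= w):
            raise ValueError("box outside excerpt")

    def text(self) -> str:
        """Monospace rendering with the indel region boxed by '|'."""
        b1, b2 = self.box

        def boxed(seq: str) -> str:
            return seq[:b1 - 1] + "|" + seq[b1 - 1:b2] + "|" + seq[b2:]

        name_w = max((len(r[1]) for r in self.rows), default=10) + 2
        acc_w = max((len(r[2]) for r in self.rows), default=8) + 2
        grp_w = max((len(r[0]) for r in self.rows), default=5) + 2
        lines = [self.title, f"{'':{grp_w + name_w + acc_w}}{self.column_header}"]
        for k, (group, species, acc, seq) in enumerate(self.rows):
            if k == self.n_ingroup and self.n_ingroup:
                lines.append("")
            lines.append(f"{group:<{grp_w}}{species:<{name_w}}{acc:<{acc_w}}{boxed(seq)}")
        return "\n".join(lines) + "\n"


def mask_row(row_seq: str, top_seq: str) -> str:
    """Dash-identity masking of one aligned row against the top row."""
    out = []
    for ch, t in zip(row_seq, top_seq):
        if ch == GAP:
            out.append(BLANK)
        elif ch == t:
            out.append("-")
        else:
            out.append(ch)
    return "".join(out)


def unmask_row(masked: str, top_seq: str) -> str:
    """Invert :func:`mask_row` given the unmasked top row."""
    out = []
    for ch, t in zip(masked, top_seq):
        if ch == BLANK:
            out.append(GAP)
        elif ch == "-":
            out.append(t)
        else:
            out.append(ch)
    return "".join(out)


def render_signature(aln: Alignment, csi: CSIRecord, groups: CladeMap,
                     order: list[str] | None = None,
                     metadata: dict[str, tuple[str, str]] | None = None,
                     title: str | None = None) -> SignatureBlock:
    """Build the signature excerpt for one CSI.

    ``metadata`` optionally maps genome label to ``(species name, accession)``
    for display; genomes fall back to their labels. ``order`` lists clade
    labels controlling row-group order within ingroup and outgroup.
    """
    if csi.window_cols is None:
        raise ValueError("CSI has no query window; run extract_query_window first")
    c1, c2 = csi.window_cols
    if not (1 <= c1 <= c2 <= aln.n_cols):
        raise ValueError("CSI window outside alignment")
    s, e = csi.indel_cols
    top = aln.top_index
    top_seq = aln.rows[top].seq[c1 - 1:c2]
    metadata = metadata or {}

    def display(genome: str, rid: str) -> tuple[str, str]:
        species, acc = metadata.get(genome, (genome, rid))
        return species, acc

    def group_key(i: int) -> tuple:
        clade = groups.clade(aln.rows[i].genome) or ""
        pos = order.index(clade) if order and clade in order else len(order or [])
        return (pos, clade, i)

    present = [i for i in range(aln.n_rows) if set(aln.rows[i].seq) != {GAP}]
    in_rows = [i for i in present if groups.role(aln.rows[i].genome) == "ingroup"]
    out_rows = [i for i in present if groups.role(aln.rows[i].genome) == "outgroup"]
    if top in in_rows:
        in_rows.remove(top)
        in_rows = [top] + sorted(in_rows, key=group_key)
        out_rows = sorted(out_rows, key=group_key)
    elif top in out_rows:
        # unusual but legal: keep the top row first overall
        out_rows.remove(top)
        in_rows = sorted(in_rows, key=group_key)
        out_rows = [top] + sorted(out_rows, key=group_key)

    rows: list[tuple[str, str, str, str]] = []
    ordered = in_rows + out_rows
    for i in ordered:
        r = aln.rows[i]
        seq = r.seq[c1 - 1:c2]
        masked = seq if i == ordered[0] else mask_row(seq, top_seq)
        species, acc = display(r.genome, r.id)
        rows.append((groups.clade(r.genome) or "", species, acc, masked))

    block_title = title or (
        f"{csi.protein}: {csi.indel_size} aa "
        f"{'ins' if csi.indel_type == 'insertion' else 'del'} "
        f"specific for {csi.specificity_group or '+'.join(sorted(groups.ingroup))}"
    )
    header = (f"{csi.window_start}-{csi.window_end}"
              if csi.window_start is not None else f"cols {c1}-{c2}")
    return SignatureBlock(
        title=block_title, column_header=header, rows=rows,
        box=(s - c1 + 1, e - c1 + 1), n_ingroup=len(in_rows),
    )


def block_presence_pattern(block: SignatureBlock, aln_rows_order=None) -> dict[str, bool]:
    """Re-derive the per-row indel presence/absence pattern from a rendered block.

    A row 'carries the gap state' iff its boxed region is entirely blank
    (non-top rows) / entirely gap (top row). Used to verify that rendering
    preserves what the scanner reported.
    """
    b1, b2 = block.box
    pattern = {}
    for k, (_, species, acc, masked) in enumerate(block.rows):
        region = masked[b1 - 1:b2]
        if k == 0:
            gapped = set(region) <= {GAP}
        else:
            gapped = set(region) <= {BLANK}
        pattern[acc] = gapped
    return pattern
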