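"""Detection of conserved signature indels (CSIs) exclusively shared by a clade.

A CSI is an insertion or deletion of fixed length, located in a conserved
region of a protein, whose presence/absence pattern separates a designated
ingroup from all outgroup homologs. The scan works on a multiple sequence
alignment per protein family:

1. :func:`find_shared_gaps` — every maximal run of gap columns whose
   gapped-row set splits ingroup from outgroup becomes a candidate. Polarity
   is assigned from the outgroup state: an ingroup-only gap is a deletion in
   the ingroup, an outgroup-only gap is an insertion in the ingroup.
2. :func:`check_flanks` — both sides of the gap run must show at least
   ``min_flank_conserved`` conserved columns within a ``flank_window`` of
   the neighbouring reference-row residues.
3. :func:`extract_query_window` — a 40–100 residue window of the reference
   (top) row spanning the indel and its conserved flanks, reported in
   1-based ungapped coordinates of the top sequence.
4. :func:`assess_specificity` — the window is compared against an ordered
   pool of homologs (a stand-in for ranked database search hits); the CSI is
   *exclusive* only if every non-ingroup pool member lacks the indel and the
   ingroup members share it, within the configured allowances.

Group sharing with a small number of outgroup exceptions is reported as
``exceptions(k)`` rather than silently dropped, so borderline signatures
remain auditable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core_genome import _make_aligner
from .seqio import GAP, Alignment, CladeMap, SequenceRecord

logger = logging.getLogger(__name__)

_AMBIG = {"X", "N"}


@dataclass
class ScanParams:
    """Tunables of the CSI scan.

    min_flank_conserved : conserved columns required on *each* side of the
        gap run (accepted working range 4–5; default 5).
    flank_window : how many neighbouring reference-residue columns are
        examined per side (accepted 40–50; default 50).
    conservation_rule : ``'strict'`` (every compared row identical) or
        ``'majority'`` (modal residue frequency >= ``majority_fraction``).
    max_outgroup_exceptions : outgroup homologs allowed to share the indel
        while the CSI still counts as exclusive (default 0).
    report_outgroup_exceptions : patterns with up to this many outgroup
        exceptions are still emitted (status ``exceptions(k)``) for audit.
    min_ingroup_coverage : fraction of ingroup homologs (among those present)
        that must share the indel ("most or all"; default 0.8).
    allow_length_range : accept indels whose length varies across the
        sharing group, reported as a length range.
    top_n_pool : only the first N pool entries are examined (ranked-hit
        convention; accepted 500–1000, default 1000).
    """

    min_flank_conserved: int = 5
    flank_window: int = 50
    conservation_rule: str = "strict"
    majority_fraction: float = 0.8
    max_outgroup_exceptions: int = 0
    report_outgroup_exceptions: int = 2
    min_ingroup_coverage: float = 0.8
    allow_length_range: bool = False
    top_n_pool: int = 1000
    window_min_len: int = 40
    window_max_len: int = 100

    def __post_init__(self) -> None:
        if self.min_flank_conserved < 1 or self.flank_window < 1:
            raise ValueError("flank parameters must be positive")
        if self.top_n_pool < 1:
            raise ValueError("top_n_pool must be >= 1")
        if self.conservation_rule not in ("strict", "majority"):
            raise ValueError("conservation_rule must be 'strict' or 'majority'")
        if not 0 < self.min_ingroup_coverage <= 1:
            raise ValueError("min_ingroup_coverage must be in (0, 1]")
        if self.window_min_len > self.window_max_len:
            raise ValueError("window_min_len must be <= window_max_len")


@dataclass
class CSIRecord:
    """One candidate / confirmed signature indel."""

    protein: str                       # family or protein identifier
    indel_type: str                    # 'insertion' | 'deletion' (ingroup-relative)
    length_min: int
    length_max: int
    indel_cols: tuple[int, int]        # 1-based closed alignment-column run
    sharing: dict[str, bool] = field(default_factory=dict)  # genome -> has indel
    ingroup_absent: int = 0
    outgroup_exceptions: int = 0
    ingroup_missing_indel: int = 0
    status: str = "candidate"          # candidate | rejected | exclusive |
                                       # exceptions(k) | undetermined
    reason: str | None = None
    flank_report: dict | None = None
    window_start: int | None = None    # 1-based on ungapped top row
    window_end: int | None = None
    window_cols: tuple[int, int] | None = None
    window_seq: str | None = None
    flags: list[str] = field(default_factory=list)
    specificity: dict | None = None
    specificity_group: str | None = None

    @property
    def is_exclusive(self) -> bool:
        return self.status == "exclusive"

    @property
    def indel_size(self) -> str:
        if self.length_min == self.length_max:
            return str(self.length_min)
        return f"{self.length_min}-{self.length_max}"


# ---------------------------------------------------------------------------
# Stage 1: shared gap patterns

def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal 1-based closed runs of gap characters in an aligned row."""
    runs = []
    start = None
    for i, ch in enumerate(seq, 1):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def _classify_rows(aln: Alignment, clades: CladeMap):
    """Split alignment rows into present ingroup/outgroup indices.

    All-gap rows count as missing homologs. Rows whose genome has no scan
    role are an error: the scan contract requires every aligned genome to be
    covered by the clade map.
    """
    in_rows, out_rows = [], []
    absent_ingroup = 0
    unassigned = []
    for i, row in enumerate(aln.rows):
        role = clades.role(row.genome)
        if role is None:
            unassigned.append(row.genome)
            continue
        if set(row.seq) == {GAP}:
            if role == "ingroup":
                absent_ingroup += 1
            continue
        (in_rows if role == "ingroup" else out_rows).append(i)
    if unassigned:
        raise ValueError(f"alignment genomes without scan role: {sorted(set(unassigned))}")
    return in_rows, out_rows, absent_ingroup


def find_shared_gaps(aln: Alignment, clades: CladeMap,
                     p: ScanParams | None = None) -> list[CSIRecord]:
    """Candidate CSIs from gap-column runs that split ingroup from outgroup.

    Overlapping per-row gap runs are merged into one candidate region. A
    region qualifies as a *deletion in the ingroup* when the gapped rows are
    (most or all of) the ingroup with at most the reporting allowance of
    outgroup rows, and as an *insertion in the ingroup* in the mirrored
    case. The fixed-length rule requires every sharing row to carry the same
    gap run; length variation is a rejection unless ``allow_length_range``.
    """
    p = p or ScanParams()
    in_rows, out_rows, _ = _classify_rows(aln, clades)
    if not out_rows:
        raise ValueError("alignment has no outgroup rows; polarity undefined")
    if not in_rows:
        return []
    # missing homologs: ingroup genomes with no (or an all-gap) row
    ingroup_absent = len(clades.ingroup_genomes()
                         - {aln.rows[i].genome for i in in_rows})
    if (clades.max_ingroup_absent is not None
            and ingroup_absent > clades.max_ingroup_absent):
        raise ValueError(
            f"{ingroup_absent} ingroup genomes lack a homolog "
            f"(max_ingroup_absent={clades.max_ingroup_absent})")

    scanned = in_rows + out_rows
    runs_by_row = {i: _gap_runs(aln.rows[i].seq) for i in scanned}
    all_runs = sorted(
        (start, end, i) for i, runs in runs_by_row.items() for start, end in runs
    )
    # merge overlapping runs into clusters
    clusters: list[list[tuple[int, int, int]]] = []
    cur_end = -1
    for start, end, i in all_runs:
        if clusters and start <= cur_end:
            clusters[-1].append((start, end, i))
            cur_end = max(cur_end, end)
        else:
            clusters.append([(start, end, i)])
            cur_end = end
    allow_k = max(p.max_outgroup_exceptions, p.report_outgroup_exceptions)
    in_set, out_set = set(in_rows), set(out_rows)
    records: list[CSIRecord] = []
    for cluster in clusters:
        span = (min(s for s, _, _ in cluster), max(e for _, e, _ in cluster))
        if span == (1, aln.n_cols):
            continue
        gapped = {i for _, _, i in cluster}
        gapped_in = gapped & in_set
        gapped_out = gapped & out_set
        n_in, n_out = len(in_set), len(out_set)

        indel_type = None
        if gapped_in and len(gapped_in) >= p.min_ingroup_coverage * n_in:
            # candidate deletion in ingroup: outgroup rows gapped are exceptions
            if len(gapped_out) <= allow_k:
                indel_type = "deletion"
                sharing_rows = gapped
                exceptions = len(gapped_out)
                missing_in = n_in - len(gapped_in)
        if indel_type is None:
            ungapped_in = in_set - gapped
            ungapped_out = out_set - gapped
            if (gapped_out and len(gapped_out) >= n_out - allow_k
                    and len(ungapped_in) >= p.min_ingroup_coverage * n_in):
                # insertion in ingroup: gap marks the rows *lacking* the insert
                indel_type = "insertion"
                sharing_rows = (in_set | out_set) - gapped
                exceptions = len(ungapped_out)
                missing_in = len(gapped_in)
        if indel_type is None:
            continue

        # fixed-length rule over the rows that actually carry the gap state
        gap_state_rows = gapped_in | gapped_out if indel_type == "deletion" else gapped
        cluster_runs = [(s, e) for s, e, i in cluster if i in gap_state_rows]
        lengths = sorted({e - s + 1 for s, e in cluster_runs})
        distinct = sorted(set(cluster_runs))
        rec = CSIRecord(
            protein="", indel_type=indel_type,
            length_min=lengths[0], length_max=lengths[-1],
            indel_cols=span,
            sharing={aln.rows[i].genome: (i in sharing_rows) for i in scanned},
            ingroup_absent=ingroup_absent,
            outgroup_exceptions=exceptions,
            ingroup_missing_indel=missing_in,
        )
        if len(distinct) > 1 and not p.allow_length_range:
            rec.status, rec.reason = "rejected", "length_mismatch"
        records.append(rec)
    records.sort(key=lambda r: r.indel_cols)
    return records


# ---------------------------------------------------------------------------
# Stage 2: flank conservation

def _column_conserved(aln: Alignment, col: int, rows: Sequence[int],
                      p: ScanParams) -> bool:
    chars = [aln.rows[i].seq[col - 1] for i in rows]
    informative = [c for c in chars if c != GAP and c not in _AMBIG]
    if p.conservation_rule == "strict":
        return len(informative) == len(chars) and len(set(informative)) == 1
    if not informative:
        return False
    modal = max(informative.count(c) for c in set(informative))
    return modal / len(chars) >= p.majority_fraction


def check_flanks(candidate: CSIRecord, aln: Alignment,
                 p: ScanParams | None = None) -> tuple[dict, bool]:
    """Count conserved columns on each side of the gap run; both sides must
    reach ``min_flank_conserved``.

    The flank window is measured in alignment columns at which the top row
    carries a residue; conservation is assessed across *all* compared rows
    (ingroup and outgroup homologs present). A side with fewer candidate
    columns than ``min_flank_conserved`` fails with reason ``edge_truncated``.
    Updates and returns the candidate's ``flank_report`` and pass flag.
    """
    p = p or ScanParams()
    s, e = candidate.indel_cols
    if not (1 <= s <= e <= aln.n_cols):
        raise ValueError("candidate columns outside alignment")
    rows = [i for i in range(aln.n_rows) if set(aln.rows[i].seq) != {GAP}]
    top = aln.top_index

    def side(cols: Iterable[int]) -> tuple[int, int]:
        examined = conserved = 0
        for col in cols:
            if aln.rows[top].seq[col - 1] == GAP:
                continue
            examined += 1
            if _column_conserved(aln, col, rows, p):
                conserved += 1
            if examined == p.flank_window:
                break
        return conserved, examined

    left_cons, left_exam = side(range(s - 1, 0, -1))
    right_cons, right_exam = side(range(e + 1, aln.n_cols + 1))
    report = {
        "left_conserved": left_cons, "left_examined": left_exam,
        "right_conserved": right_cons, "right_examined": right_exam,
    }
    passed = left_cons >= p.min_flank_conserved and right_cons >= p.min_flank_conserved
    reason = None
    if not passed:
        if (left_exam < p.min_flank_conserved
                or right_exam < p.min_flank_conserved):
            reason = "edge_truncated"
        else:
            reason = "flank_not_conserved"
    candidate.flank_report = report
    if not passed and candidate.status != "rejected":
        candidate.status, candidate.reason = "rejected", reason
    return report, passed


# ---------------------------------------------------------------------------
# Stage 3: query window

def extract_query_window(candidate: CSIRecord, aln: Alignment,
                         min_len: int = 40, max_len: int = 100,
                         flank_pad: int = 5) -> CSIRecord:
    """A top-row window spanning the indel plus conserved context.

    The window is centred on the gap run and expanded symmetrically until it
    holds at least ``min_len`` ungapped top-row residues (and at least
    ``flank_pad`` residues beyond the indel on each side), capped at
    ``max_len``. Coordinates are 1-based on the ungapped top sequence and
    stored as ``window_start``/``window_end``. A top sequence shorter than
    ``min_len`` yields the whole sequence with a ``short_protein`` flag.
    """
    s, e = candidate.indel_cols
    top = aln.top_index
    res_cols = aln.residue_columns(top)
    n_res = len(res_cols)
    if n_res == 0:
        raise ValueError("top row has no residues")
    inner_idx = [k for k, col in enumerate(res_cols) if s <= col <= e]
    m = len(inner_idx)
    if inner_idx:
        left_edge, right_edge = inner_idx[0], inner_idx[-1]
    else:
        # deletion in the top row: anchor between the flanking residues
        right_edge = next((k for k, col in enumerate(res_cols) if col > e), n_res)
        left_edge = right_edge - 1
    target = min(max_len, max(min_len, m + 2 * flank_pad))
    lo = max(left_edge, 0)
    hi = min(right_edge, n_res - 1)
    if lo > hi:  # empty interior at sequence edge
        lo, hi = max(0, min(left_edge, n_res - 1)), min(max(right_edge, 0), n_res - 1)

    def total() -> int:
        return hi - lo + 1

    while total() < target and (lo > 0 or hi < n_res - 1):
        left_taken = left_edge - lo
        right_taken = hi - right_edge
        if lo > 0 and (left_taken <= right_taken or hi == n_res - 1):
            lo -= 1
        else:
            hi += 1
    if n_res < min_len:
        candidate.flags.append("short_protein")
    if m > max_len:
        candidate.flags.append("long_indel")
    candidate.window_start = lo + 1
    candidate.window_end = hi + 1
    c1 = min(res_cols[lo], s)
    c2 = max(res_cols[hi], e)
    candidate.window_cols = (c1, c2)
    candidate.window_seq = aln.rows[top].seq[c1 - 1:c2].replace(GAP, "")
    return candidate


# ---------------------------------------------------------------------------
# Stage 4: specificity against a homolog pool

def _window_variant(aln: Alignment, row_index: int, cols: tuple[int, int]) -> str:
    c1, c2 = cols
    return aln.rows[row_index].seq[c1 - 1:c2].replace(GAP, "")


def _call_indel_state(hit_seq: str, ingroup_ref: str, outgroup_ref: str,
                      aligner=None) -> bool:
    """True iff the hit looks like the ingroup (indel-bearing) window state.

    Each hit is locally aligned to both reference windows (match +1,
    mismatch 0, gap -1); it shares the indel iff it scores strictly higher
    against the ingroup-state reference. Ties are called as lacking the
    indel, the conservative direction for exclusivity.
    """
    aligner = aligner or _make_aligner("local")
    s_in = aligner.score(hit_seq, ingroup_ref)
    s_out = aligner.score(hit_seq, outgroup_ref)
    return s_in > s_out


def assess_specificity(candidate: CSIRecord, aln: Alignment, clades: CladeMap,
                       pool: Sequence[SequenceRecord],
                       p: ScanParams | None = None) -> CSIRecord:
    """Final exclusivity call against an ordered homolog pool.

    Only the first ``top_n_pool`` entries are examined (pool order stands in
    for database-search ranking). Pool genomes map to scan roles through the
    clade map; a genome unknown to the map counts as non-ingroup, matching
    the treatment of unrelated database hits. Status becomes ``exclusive``
    when at most ``max_outgroup_exceptions`` non-ingroup hits share the
    indel and the sharing fraction among ingroup hits reaches
    ``min_ingroup_coverage``; an empty pool (or one without ingroup hits)
    is ``undetermined``.
    """
    p = p or ScanParams()
    if candidate.window_cols is None:
        raise ValueError("candidate has no query window; run extract_query_window")
    if not pool:
        candidate.status = "undetermined"
        candidate.reason = "empty_pool"
        return candidate

    in_ref_row = out_ref_row = None
    order = [aln.top_index] + [i for i in range(aln.n_rows) if i != aln.top_index]
    for i in order:
        g = aln.rows[i].genome
        if g not in candidate.sharing:
            continue
        role = clades.role(g)
        if in_ref_row is None and role == "ingroup" and candidate.sharing[g]:
            in_ref_row = i
        if out_ref_row is None and role == "outgroup" and not candidate.sharing[g]:
            out_ref_row = i
    if in_ref_row is None or out_ref_row is None:
        candidate.status = "undetermined"
        candidate.reason = "no_reference_state"
        return candidate
    in_ref = _window_variant(aln, in_ref_row, candidate.window_cols)
    out_ref = _window_variant(aln, out_ref_row, candidate.window_cols)

    n_in = n_out = share_in = share_out = 0
    aligner = _make_aligner("local")
    for hit in pool[:p.top_n_pool]:
        clade = clades.clade(hit.genome)
        is_ingroup = clade in clades.ingroup
        shares = _call_indel_state(hit.residues, in_ref, out_ref, aligner)
        if is_ingroup:
            n_in += 1
            share_in += shares
        else:
            n_out += 1
            share_out += shares
    candidate.specificity = {
        "pool_examined": min(len(pool), p.top_n_pool),
        "ingroup_hits": n_in, "ingroup_sharing": share_in,
        "outgroup_hits": n_out, "outgroup_sharing": share_out,
    }
    if n_in == 0:
        candidate.status, candidate.reason = "undetermined", "no_ingroup_hits"
    elif share_out > p.max_outgroup_exceptions:
        candidate.status, candidate.reason = f"exceptions({share_out})", None
    elif share_in < p.min_ingroup_coverage * n_in:
        candidate.status, candidate.reason = "rejected", "ingroup_coverage"
    else:
        candidate.status, candidate.reason = "exclusive", None
    candidate.outgroup_exceptions = max(candidate.outgroup_exceptions, share_out)
    return candidate


# ---------------------------------------------------------------------------
# Pipeline

def scan_pipeline(families, clades: CladeMap, pools=None,
                  p: ScanParams | None = None) -> list[CSIRecord]:
    """Run the full scan over a set of family alignments.

    ``families``: iterable of ``(family_id, Alignment)`` (or a dict).
    ``pools``: optional dict ``family_id -> ordered homolog pool``; when a
    family has no pool its alignment-level exclusivity stands (pattern with
    zero outgroup exceptions -> exclusive) and specificity is marked
    unassessed. Per-family failures are logged and the scan continues.
    """
    p = p or ScanParams()
    if isinstance(families, dict):
        families = families.items()
    group_label = "+".join(sorted(clades.ingroup))
    out: list[CSIRecord] = []
    for fam_id, aln in families:
        try:
            candidates = find_shared_gaps(aln, clades, p)
        except ValueError as exc:
            logger.warning("family %s skipped: %s", fam_id, exc)
            continue
        for cand in candidates:
            cand.protein = fam_id
            cand.specificity_group = group_label
            if cand.status == "rejected":
                out.append(cand)
                continue
            _, ok = check_flanks(cand, aln, p)
            if not ok:
                out.append(cand)
                continue
            extract_query_window(cand, aln, p.window_min_len, p.window_max_len)
            pool = (pools or {}).get(fam_id)
            if pool is not None:
                assess_specificity(cand, aln, clades, pool, p)
            else:
                k = cand.outgroup_exceptions
                if k > p.max_outgroup_exceptions:
                    cand.status = f"exceptions({k})"
                else:
                    cand.status = "exclusive"
                cand.flags.append("specificity_not_assessed")
            out.append(cand)
    return out


def records_to_table(records: Sequence[CSIRecord]) -> pd.DataFrame:
    """TSV-ready summary table (one row per candidate/CSI)."""
    rows = []
    for r in records:
        rows.append({
            "protein": r.protein,
            "indel_type": r.indel_type,
            "indel_size": r.indel_size,
            "indel_position": (f"{r.window_start}-{r.window_end}"
                               if r.window_start is not None else "NA"),
            "alignment_cols": f"{r.indel_cols[0]}-{r.indel_cols[1]}",
            "specificity": r.specificity_group or "NA",
            "status": r.status,
            "reason": r.reason or "",
            "ingroup_absent": r.ingroup_absent,
            "outgroup_exceptions": r.outgroup_exceptions,
            "flags": ";".join(r.flags),
        })
    return pd.DataFrame(rows, columns=[
        "protein", "indel_type", "indel_size", "indel_position",
        "alignment_cols", "specificity", "status", "reason",
        "ingroup_absent", "outgroup_exceptions", "flags",
    ])
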