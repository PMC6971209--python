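"""Clade-structured synthetic proteomes with planted, truth-tracked indels.

The generator realizes the evolutionary premise the signature-indel logic
assumes: an indel arises once on the ancestral branch of a clade and is
vertically inherited by every descendant. Evolution runs down a two-tier
hierarchy (root -> clade ancestor -> genome) with independent per-site
substitutions at each tier; a full birth-death tree is deliberately not
simulated, which keeps every emitted coordinate exactly derivable. Each
planted event carries conserved flanking blocks that are substitution-immune
by construction, so flank-conservation behaviour is testable at any noise
level. Families can be dropped per genome with a configurable probability to
emulate missing homologs.

All randomness flows through one :class:`numpy.random.Generator` seeded from
the config, so a given config yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core_genome import pairwise_identity
from .csi_finder import CSIRecord, ScanParams, scan_pipeline
from .seqio import (GAP, AlignedRow, Alignment, CladeMap, SequenceRecord,
                    write_alignment_fasta, write_clade_map, write_fasta)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
OUTGROUP = "outgroup"


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class PlantedEvent:
    """One indel planted on a clade's ancestral branch.

    ``position`` is a 1-based root coordinate: a deletion removes root
    residues ``position .. position+length-1``; an insertion adds ``length``
    residues immediately after root residue ``position``. ``flank_width``
    root residues on each side are substitution-immune.
    """

    family: int            # 0-based family index
    clade: str
    kind: str              # 'insertion' | 'deletion'
    length: int
    position: int
    flank_width: int = 50

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ConfigError(f"unknown indel kind {self.kind!r}")
        if self.length < 1:
            raise ConfigError("indel length must be >= 1")
        if self.flank_width < 1:
            raise ConfigError("flank width must be >= 1")

    def footprint(self) -> tuple[int, int]:
        """Root-coordinate closed span covered by the event plus its flanks."""
        if self.kind == "deletion":
            return (self.position - self.flank_width,
                    self.position + self.length + self.flank_width - 1)
        return (self.position - self.flank_width + 1,
                self.position + self.flank_width)

    def conserved_positions(self) -> set[int]:
        if self.kind == "deletion":
            left = range(self.position - self.flank_width, self.position)
            right = range(self.position + self.length,
                          self.position + self.length + self.flank_width)
        else:
            left = range(self.position - self.flank_width + 1, self.position + 1)
            right = range(self.position + 1, self.position + self.flank_width + 1)
        return set(left) | set(right)


@dataclass
class SimulationConfig:
    """Study conditions for the planted-indel benchmark.

    Defaults describe the reference condition used throughout the test
    battery: 3 ingroup clades of 4 genomes plus 4 outgroup genomes, 50
    families of 200-400 residues, 10 planted events with lengths spanning
    1-11 residues, and no substitution noise. ``subst_prob_clade`` /
    ``subst_prob_genome`` are per-site substitution probabilities on the
    root->ancestor and ancestor->genome branch tiers respectively.
    """

    n_clades: int = 3
    genomes_per_clade: int = 4
    n_outgroup_genomes: int = 4
    n_families: int = 50
    family_length_range: tuple[int, int] = (200, 400)
    subst_prob_clade: float = 0.0
    subst_prob_genome: float = 0.0
    family_absence_prob: float = 0.0
    planted_events: list[PlantedEvent] | None = None
    n_default_events: int = 10
    default_event_lengths: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 11)
    default_flank_width: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.subst_prob_clade, self.subst_prob_genome,
                  self.family_absence_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        lo, hi = self.family_length_range
        if lo < 1 or hi < lo:
            raise ConfigError("invalid family_length_range")
        if min(self.n_clades, self.genomes_per_clade, self.n_outgroup_genomes,
               self.n_families) < 1:
            raise ConfigError("counts must be positive")

    @property
    def clade_names(self) -> list[str]:
        return [f"clade{i:02d}" for i in range(1, self.n_clades + 1)]


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one planted event, in emitted-sequence coordinates.

    ``window_start``/``window_end`` are 1-based closed positions on the
    indel-bearing clade's ungapped sequence: the inserted residues for an
    insertion, the two junction residues for a deletion.
    """

    family_id: str
    clade: str
    kind: str
    length: int
    window_start: int
    window_end: int
    root_position: int


@dataclass
class FamilyData:
    family_id: str
    root: str
    alignment: Alignment            # the true alignment over present genomes
    records: dict[str, SequenceRecord]   # genome -> emitted (gap-free) record
    events: list[PlantedEvent]
    conserved_root_positions: set[int]


@dataclass
class Dataset:
    config: SimulationConfig
    clade_names: list[str]          # ingroup clades (outgroup listed separately)
    genomes_by_clade: dict[str, list[str]]
    clade_map: CladeMap
    families: dict[str, FamilyData]
    truth: list[TruthRow]

    def clade_map_for(self, clade: str,
                      max_ingroup_absent: int | None = None) -> CladeMap:
        """Scan partition with ``clade`` as ingroup and everything else outgroup."""
        return self.clade_map.with_scan({clade}, max_ingroup_absent=max_ingroup_absent)

    def proteome(self, genome: str) -> list[SequenceRecord]:
        return [fam.records[genome] for fam in self.families.values()
                if genome in fam.records]

    @property
    def genomes(self) -> list[str]:
        return [g for c in [*self.clade_names, OUTGROUP]
                for g in self.genomes_by_clade[c]]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        (outdir / "genomes").mkdir(parents=True, exist_ok=True)
        (outdir / "alignments").mkdir(exist_ok=True)
        for g in self.genomes:
            write_fasta(self.proteome(g), outdir / "genomes" / f"{g}.faa")
        for fid, fam in self.families.items():
            write_alignment_fasta(fam.alignment, outdir / "alignments" / f"{fid}.afa")
        write_clade_map(self.clade_map, outdir / "clade_map.yaml")
        truth_table(self).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def truth_table(dataset: Dataset) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.family_id, t.clade, t.kind, t.length, t.window_start, t.window_end,
          t.root_position) for t in dataset.truth],
        columns=["family_id", "clade", "kind", "length",
                 "window_start", "window_end", "root_position"],
    )


# ---------------------------------------------------------------------------
# Generation

def _default_events(cfg: SimulationConfig, fam_lengths: np.ndarray,
                    rng: np.random.Generator) -> list[PlantedEvent]:
    n = min(cfg.n_default_events, cfg.n_families)  # at most one event per family
    fams = sorted(int(i) for i in
                  rng.choice(cfg.n_families, size=n, replace=False))
    lengths = list(cfg.default_event_lengths)
    if len(lengths) < n:
        raise ConfigError("not enough default event lengths")
    events = []
    w = cfg.default_flank_width
    for k, fam in enumerate(fams):
        clade = cfg.clade_names[k % cfg.n_clades]
        kind = "deletion" if k % 2 else "insertion"
        L = lengths[k]
        root_len = int(fam_lengths[fam])
        if kind == "deletion":
            lo, hi = w + 1, root_len - L - w + 1
        else:
            lo, hi = w, root_len - w
        if hi < lo:
            raise ConfigError(
                f"family {fam} too short ({root_len}) for event length {L} "
                f"with flank width {w}")
        pos = int(rng.integers(lo, hi + 1))
        events.append(PlantedEvent(fam, clade, kind, L, pos, w))
    return events


def _validate_events(events: list[PlantedEvent], fam_lengths: np.ndarray,
                     clades: list[str]) -> None:
    by_family: dict[int, list[PlantedEvent]] = {}
    for ev in events:
        if not 0 <= ev.family < len(fam_lengths):
            raise ConfigError(f"event family index {ev.family} out of range")
        if ev.clade not in clades:
            raise ConfigError(f"event clade {ev.clade!r} is not an ingroup clade")
        lo, hi = ev.footprint()
        if lo < 1 or hi > int(fam_lengths[ev.family]):
            raise ConfigError(
                f"event at root position {ev.position} (family {ev.family}) "
                "leaves no room for its conserved flanks")
        by_family.setdefault(ev.family, []).append(ev)
    for fam, evs in by_family.items():
        evs = sorted(evs, key=lambda e: e.position)
        for a, b in zip(evs, evs[1:]):
            if a.footprint()[1] >= b.footprint()[0]:
                raise ConfigError(
                    f"family {fam}: planted events at positions "
                    f"{a.position} and {b.position} overlap each other's "
                    "conserved flanks")


def _mutate(chars: list[str | None], mutable: np.ndarray, prob: float,
            rng: np.random.Generator) -> list[str | None]:
    """Per-site substitution of a gapped character list (None = gap)."""
    out = list(chars)
    if prob <= 0.0:
        return out
    hits = np.nonzero(mutable & (rng.random(len(chars)) < prob))[0]
    for i in hits:
        old = out[i]
        choices = AA20.replace(old, "")
        out[i] = choices[int(rng.integers(len(choices)))]
    return out


def generate_dataset(cfg: SimulationConfig | None = None) -> Dataset:
    """Generate per-genome proteomes, true alignments, clade map, and truth table."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    clades = cfg.clade_names
    all_clades = [*clades, OUTGROUP]
    genomes_by_clade = {
        c: [f"{c}_g{j}" for j in range(1, cfg.genomes_per_clade + 1)]
        for c in clades
    }
    genomes_by_clade[OUTGROUP] = [f"out_g{j}"
                                  for j in range(1, cfg.n_outgroup_genomes + 1)]
    assignment = {g: c for c in all_clades for g in genomes_by_clade[c]}
    clade_map = CladeMap(assignment, frozenset(clades), frozenset({OUTGROUP}))

    lo, hi = cfg.family_length_range
    fam_lengths = rng.integers(lo, hi + 1, size=cfg.n_families)
    events = cfg.planted_events
    if events is None:
        events = _default_events(cfg, fam_lengths, rng)
    _validate_events(events, fam_lengths, clades)
    events_by_family: dict[int, list[PlantedEvent]] = {}
    for ev in events:
        events_by_family.setdefault(ev.family, []).append(ev)

    families: dict[str, FamilyData] = {}
    truth: list[TruthRow] = []
    for f in range(cfg.n_families):
        fid = f"F{f + 1:04d}"
        root_len = int(fam_lengths[f])
        root = "".join(AA20[i] for i in rng.integers(len(AA20), size=root_len))
        fam_events = sorted(events_by_family.get(f, []), key=lambda e: e.position)
        conserved = set()
        for ev in fam_events:
            conserved |= ev.conserved_positions()
        ins_residues = {
            ev: "".join(AA20[i] for i in rng.integers(len(AA20), size=ev.length))
            for ev in fam_events if ev.kind == "insertion"
        }

        # column template: root positions interleaved with insertion blocks
        cols: list[tuple] = []
        for i in range(1, root_len + 1):
            cols.append(("root", i))
            for ev in fam_events:
                if ev.kind == "insertion" and ev.position == i:
                    for j in range(ev.length):
                        cols.append(("ins", ev, j))
        n_cols = len(cols)
        del_clade_at = {}
        for ev in fam_events:
            if ev.kind == "deletion":
                for i in range(ev.position, ev.position + ev.length):
                    del_clade_at[i] = ev.clade
        mutable = np.array(
            [c[0] == "ins" or c[1] not in conserved for c in cols], dtype=bool)

        ancestors: dict[str, list[str | None]] = {}
        for clade in all_clades:
            chars: list[str | None] = []
            for c in cols:
                if c[0] == "root":
                    i = c[1]
                    chars.append(None if del_clade_at.get(i) == clade else root[i - 1])
                else:
                    _, ev, j = c
                    chars.append(ins_residues[ev][j] if ev.clade == clade else None)
            present = np.array([ch is not None for ch in chars])
            ancestors[clade] = _mutate(chars, mutable & present,
                                       cfg.subst_prob_clade, rng)

        rows: list[AlignedRow] = []
        records: dict[str, SequenceRecord] = {}
        for clade in all_clades:
            anc = ancestors[clade]
            present_mask = np.array([ch is not None for ch in anc])
            for genome in genomes_by_clade[clade]:
                if rng.random() < cfg.family_absence_prob:
                    continue
                chars = _mutate(anc, mutable & present_mask,
                                cfg.subst_prob_genome, rng)
                seq = "".join(ch if ch is not None else GAP for ch in chars)
                rid = f"{genome}|{fid}"
                rows.append(AlignedRow(rid, genome, seq))
                records[genome] = SequenceRecord(
                    rid, genome, seq.replace(GAP, ""),
                    description=f"family {fid} (simulated)")
        if not rows:
            continue
        alignment = Alignment(rows)
        families[fid] = FamilyData(fid, root, alignment, records,
                                   fam_events, conserved)

        # truth coordinates on the indel-bearing clade's ungapped sequence
        for ev in fam_events:
            anc = ancestors[ev.clade]
            pos = 0
            first = last = None
            for c, ch in zip(cols, anc):
                if ch is None:
                    continue
                pos += 1
                if ev.kind == "insertion" and c[0] == "ins" and c[1] is ev:
                    if first is None:
                        first = pos
                    last = pos
                elif (ev.kind == "deletion" and c[0] == "root"
                        and c[1] == ev.position - 1):
                    first, last = pos, pos + 1
            truth.append(TruthRow(fid, ev.clade, ev.kind, ev.length,
                                  first, last, ev.position))

    return Dataset(cfg, clades, genomes_by_clade, clade_map, families, truth)


# ---------------------------------------------------------------------------
# Specificity pools and benchmark helpers

def make_specificity_pool(dataset: Dataset, family_id: str,
                          extra_decoys: int = 0,
                          decoy_subst_prob: float = 0.1,
                          seed: int | None = None) -> list[SequenceRecord]:
    """Ordered homolog pool for one family (stand-in for ranked search hits).

    The pool holds every emitted homolog of the family plus ``extra_decoys``
    further outgroup-derived variants, ordered by global-alignment identity
    to the family representative (longest member, ties by id), descending;
    ties break lexicographically by record id, so the representative itself
    comes first.
    """
    fam = dataset.families[family_id]
    fam_index = list(dataset.families).index(family_id)
    rng = np.random.default_rng(
        [dataset.config.seed, 9001, fam_index] if seed is None else seed)
    pool = list(fam.records.values())
    sources = [fam.records[g] for g in dataset.genomes_by_clade[OUTGROUP]
               if g in fam.records]
    for k in range(extra_decoys):
        src = sources[k % len(sources)]
        chars = list(src.residues)
        hits = np.nonzero(rng.random(len(chars)) < decoy_subst_prob)[0]
        for i in hits:
            choices = AA20.replace(chars[i], "")
            chars[i] = choices[int(rng.integers(len(choices)))]
        pool.append(SequenceRecord(f"decoy{k:03d}|{family_id}", src.genome,
                                   "".join(chars), "synthetic decoy homolog"))
    rep = sorted(fam.records.values(), key=lambda r: (-len(r), r.id))[0]
    scored = [(pairwise_identity(rec, rep).fraction, rec) for rec in pool]
    scored.sort(key=lambda t: (-t[0], t[1].id))
    return [rec for _, rec in scored]


def scan_dataset(dataset: Dataset, params: ScanParams | None = None,
                 clades: list[str] | None = None,
                 with_pools: bool = True,
                 extra_decoys: int = 0) -> list[CSIRecord]:
    """Run the full CSI scan once per ingroup clade and pool the records."""
    params = params or ScanParams()
    out: list[CSIRecord] = []
    pools = None
    if with_pools:
        pools = {fid: make_specificity_pool(dataset, fid, extra_decoys)
                 for fid in dataset.families}
    for clade in clades or dataset.clade_names:
        cm = dataset.clade_map_for(clade)
        fams = [(fid, fam.alignment) for fid, fam in dataset.families.items()]
        out.extend(scan_pipeline(fams, cm, pools, params))
    return out


def score_scan(records: list[CSIRecord], truth: list[TruthRow]) -> dict:
    """Precision/recall of exclusive CSIs against the planted truth table.

    A record matches a truth row when family, target clade, polarity agree
    and the planted length falls within the record's reported length range.
    Precision is 1.0 when nothing exclusive was reported (no false
    positives); recall is 1.0 for an empty truth table.
    """
    exclusive = [r for r in records if r.is_exclusive]
    matched_truth: set[int] = set()
    n_matched_records = 0
    for r in exclusive:
        hit = None
        for k, t in enumerate(truth):
            if (t.family_id == r.protein and t.clade == r.specificity_group
                    and t.kind == r.indel_type
                    and r.length_min <= t.length <= r.length_max):
                hit = k
                break
        if hit is not None:
            matched_truth.add(hit)
            n_matched_records += 1
    precision = 1.0 if not exclusive else n_matched_records / len(exclusive)
    recall = 1.0 if not truth else len(matched_truth) / len(truth)
    return {
        "n_exclusive": len(exclusive),
        "n_truth": len(truth),
        "precision": precision,
        "recall": recall,
    }
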