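"""Pairwise average amino acid identity (AAI) over a concatenated core alignment.

AAI between two genomes is the percentage of identical residues over the
alignment columns where both rows carry an unambiguous residue (gap and X
columns excluded pairwise). Per-clade summaries report the mean and sample
standard deviation of within-clade pair values; a clade contributing a
single pair has no defined SD and a single-genome clade has no defined mean
(serialized as ``NA``).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_genome import Supermatrix
from .seqio import GAP, Alignment, CladeMap


@dataclass
class AAIMatrix:
    genomes: list[str]
    values: np.ndarray          # percentages in [0, 100]; NaN = undefined
    compared_counts: np.ndarray  # compared-column counts per pair

    def value(self, a: str, b: str) -> float:
        i, j = self.genomes.index(a), self.genomes.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genomes, columns=self.genomes)

    def to_tsv(self, path) -> None:
        df = self.to_dataframe().round(4)
        df.to_csv(path, sep="\t", na_rep="NA", index_label="genome")


@dataclass
class CladeAAISummary:
    clade: str
    n_pairs: int
    mean: float  # NaN when n_pairs == 0
    sd: float    # NaN when n_pairs < 2

    @property
    def mean_defined(self) -> bool:
        return not np.isnan(self.mean)

    @property
    def sd_defined(self) -> bool:
        return not np.isnan(self.sd)


def compute_aai(matrix: Supermatrix | Alignment) -> AAIMatrix:
    """AAI percentage matrix over all genome pairs of a supermatrix.

    Pairs with zero comparable columns get value NaN with a warning.
    """
    aln = matrix.alignment if isinstance(matrix, Supermatrix) else matrix
    genomes = [r.genome for r in aln.rows]
    if len(genomes) != len(set(genomes)):
        raise ValueError("duplicate genome rows in supermatrix")
    n = len(genomes)
    if n < 2:
        raise ValueError("AAI needs at least 2 genomes")
    arrs = [np.frombuffer(r.seq.encode("ascii"), dtype="S1") for r in aln.rows]
    valid = [ (a != GAP.encode()) & (a != b"X") & (a != b"N") for a in arrs]
    values = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    np.fill_diagonal(values, 100.0)
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        compared = int(both.sum())
        counts[i, j] = counts[j, i] = compared
        if compared == 0:
            warnings.warn(
                f"no comparable columns between {genomes[i]!r} and {genomes[j]!r}; "
                "AAI undefined", stacklevel=2)
            continue
        identical = int((arrs[i][both] == arrs[j][both]).sum())
        values[i, j] = values[j, i] = 100.0 * identical / compared
    return AAIMatrix(genomes, values, counts)


def clade_aai_summary(m: AAIMatrix, clades: CladeMap) -> list[CladeAAISummary]:
    """Mean and sample SD of within-clade AAI values, one summary per clade.

    Every genome in the matrix must be assigned a clade. Cross-clade pairs
    are excluded; single-pair clades have undefined SD (mirroring published
    AAI-matrix summaries where a lone pair admits no deviation estimate).
    """
    unassigned = [g for g in m.genomes if clades.clade(g) is None]
    if unassigned:
        raise ValueError(f"genomes without clade assignment: {unassigned}")
    by_clade: dict[str, list[int]] = {}
    for idx, g in enumerate(m.genomes):
        by_clade.setdefault(clades.clade(g), []).append(idx)
    out = []
    for clade in sorted(by_clade):
        idxs = by_clade[clade]
        vals = [m.values[i, j] for i, j in itertools.combinations(idxs, 2)
                if not np.isnan(m.values[i, j])]
        n_pairs = len(vals)
        mean = float(np.mean(vals)) if n_pairs >= 1 else float("nan")
        sd = float(np.std(vals, ddof=1)) if n_pairs >= 2 else float("nan")
        out.append(CladeAAISummary(clade, n_pairs, mean, sd))
    return out


def summaries_to_tsv(summaries: list[CladeAAISummary], path) -> None:
    df = pd.DataFrame(
        [(s.clade, s.n_pairs, s.mean, s.sd) for s in summaries],
        columns=["clade", "n_pairs", "mean", "sd"],
    ).round(4)
    df.to_csv(path, sep="\t", na_rep="NA", index=False)
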