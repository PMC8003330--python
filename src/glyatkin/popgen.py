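"""Haplotype diversity statistics: segregating sites, pairwise diversity,
Tajima's D, and haplotype-frequency tabulation.

Statistics are computed on an alignment of equal-length haplotype
sequences (any residue alphabet).  Columns containing a gap or missing
symbol are removed before anything is counted (complete deletion).  The
per-site diversity pi is the plain mean pairwise difference per retained
position with no sample-size correction, and distinct haplotypes are
equally weighted in S, k, pi and D; observation counts only enter the
frequency tabulation.

Tajima's D contrasts the diversity-based estimate of the population
mutation parameter (k, mean pairwise differences) with the
segregating-sites-based one (S / a1).  Strongly negative values indicate
an excess of rare variants relative to neutral expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from os import PathLike

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import ValidationError

__all__ = [
    "GAP_CHARS",
    "HaplotypeAlignment",
    "TajimaStats",
    "segregating_sites",
    "pairwise_diversity",
    "tajimas_d",
    "tajimas_d_from_summary",
    "haplotype_frequencies",
    "write_stats_report",
]

#: Symbols treated as gap / missing data (their columns are deleted).
GAP_CHARS = frozenset("-.?*")


@dataclass
class HaplotypeAlignment:
    """Equal-length haplotype sequences with optional observation counts."""

    ids: list[str]
    sequences: list[str]
    counts: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValidationError("ids and sequences differ in length")
        if len(self.sequences) < 2:
            raise ValidationError("alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValidationError(
                f"sequences are not aligned (lengths {sorted(lengths)})"
            )
        if next(iter(lengths)) == 0:
            raise ValidationError("alignment has zero columns")
        self.sequences = [s.upper() for s in self.sequences]
        for s in self.sequences:
            bad = set(s) - set("ABCDEFGHIJKLMNOPQRSTUVWXYZ") - GAP_CHARS
            if bad:
                raise ValidationError(f"invalid residue symbols {sorted(bad)}")
        if self.counts is not None:
            if len(self.counts) != len(self.ids):
                raise ValidationError("counts and ids differ in length")
            if any(c < 1 for c in self.counts):
                raise ValidationError("counts must be >= 1")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0])

    def _matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences])

    def retained_matrix(self) -> np.ndarray:
        """Character matrix after complete deletion of gap/missing columns."""
        mat = self._matrix()
        gap_mask = np.isin(mat, list(GAP_CHARS)).any(axis=0)
        kept = mat[:, ~gap_mask]
        if kept.shape[1] == 0:
            raise ValidationError("no columns remain after gap deletion")
        return kept

    @classmethod
    def from_fasta(cls, path: str | PathLike) -> "HaplotypeAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValidationError(f"no sequences found in {path}")
        return cls(ids=[r.id for r in records],
                   sequences=[str(r.seq) for r in records])

    def to_fasta(self, path: str | PathLike) -> None:
        records = [SeqRecord(Seq(s), id=i, description="")
                   for i, s in zip(self.ids, self.sequences)]
        SeqIO.write(records, str(path), "fasta")


def segregating_sites(aln: HaplotypeAlignment) -> int:
    """Number of retained columns with >= 2 distinct residues.

    Multi-allelic columns count once.
    """
    kept = aln.retained_matrix()
    return int(sum(len(set(col)) > 1 for col in kept.T))


def pairwise_diversity(aln: HaplotypeAlignment) -> tuple[float, float]:
    """Mean pairwise differences k and per-site diversity pi = k / L.

    k averages the Hamming distance over all n(n-1)/2 unordered sequence
    pairs on the retained columns; any mismatch counts as one difference.
    """
    kept = aln.retained_matrix()
    n, L = kept.shape
    # per column: number of differing pairs = (n^2 - sum of class sizes^2)/2
    total_diff_pairs = 0.0
    for col in kept.T:
        _, counts = np.unique(col, return_counts=True)
        total_diff_pairs += (n * n - np.sum(counts.astype(float) ** 2)) / 2.0
    n_pairs = n * (n - 1) / 2.0
    k = total_diff_pairs / n_pairs
    return float(k), float(k / L)


@dataclass(frozen=True)
class TajimaStats:
    """Tajima's D with every intermediate coefficient, for auditability.

    ``D`` is NaN when S = 0 (the statistic is undefined, not zero).
    """

    n: int
    L: int | None
    S: int
    k: float
    pi: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    theta_w: float
    D: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.D)


def tajimas_d_from_summary(n: int, S: int, k: float,
                           L: int | None = None) -> TajimaStats:
    """Tajima's D from summary quantities alone.

    Parameters are the number of sequences ``n`` (>= 4), the number of
    segregating sites ``S``, and the mean pairwise differences ``k`` (per
    sequence pair, not per site).  ``L`` is only used to report pi = k/L.

    Coefficients (i runs 1..n-1):
        a1 = sum 1/i                 a2 = sum 1/i^2
        b1 = (n+1) / (3(n-1))        b2 = 2(n^2+n+3) / (9n(n-1))
        c1 = b1 - 1/a1               c2 = b2 - (n+2)/(a1 n) + a2/a1^2
        e1 = c1/a1                   e2 = c2 / (a1^2 + a2)
        D  = (k - S/a1) / sqrt(e1 S + e2 S(S-1))
    """
    if n < 4:
        raise ValidationError(f"Tajima's D needs n >= 4 sequences, got {n}")
    if S < 0:
        raise ValidationError("S must be >= 0")
    if k < 0:
        raise ValidationError("k must be >= 0")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    theta_w = S / a1
    if S == 0:
        D = math.nan  # undefined: no variation to test
    else:
        D = (k - theta_w) / math.sqrt(e1 * S + e2 * S * (S - 1))
    pi = k / L if L else math.nan
    return TajimaStats(n=n, L=L, S=S, k=k, pi=pi, a1=a1, a2=a2, b1=b1, b2=b2,
                       c1=c1, c2=c2, e1=e1, e2=e2, theta_w=theta_w, D=D)


def tajimas_d(aln: HaplotypeAlignment) -> TajimaStats:
    """Tajima's D computed from an alignment (complete gap deletion)."""
    S = segregating_sites(aln)
    k, _ = pairwise_diversity(aln)
    L = aln.retained_matrix().shape[1]
    return tajimas_d_from_summary(aln.n, S, k, L=L)


def haplotype_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Tabulate haplotype counts and frequencies, per population and overall.

    ``table`` needs a ``haplotype`` column; ``population`` and ``count``
    columns are optional (count defaults to 1 per row).  The result has one
    row per (population, haplotype), plus an ``ALL`` population pooling
    everything, sorted by descending frequency within each population.
    """
    if table is None or len(table) == 0:
        raise ValidationError("haplotype table is empty")
    if "haplotype" not in table.columns:
        raise ValidationError("haplotype table needs a 'haplotype' column")
    df = table.copy()
    haps = df["haplotype"].astype(str)
    lengths = haps.str.len().unique()
    if len(lengths) > 1:
        raise ValidationError(
            f"ragged haplotype strings (lengths {sorted(lengths)})"
        )
    df["haplotype"] = haps
    if "count" not in df.columns:
        df["count"] = 1
    if (df["count"] < 0).any():
        raise ValidationError("counts must be >= 0")
    if "population" not in df.columns:
        df["population"] = "ALL"
        pooled = df
    else:
        df["population"] = df["population"].astype(str)
        pooled = pd.concat(
            [df, df.assign(population="ALL")], ignore_index=True
        )
    grouped = (pooled.groupby(["population", "haplotype"], sort=False)
               ["count"].sum().reset_index())
    totals = grouped.groupby("population")["count"].transform("sum")
    grouped["frequency"] = grouped["count"] / totals
    grouped = grouped.sort_values(
        ["population", "frequency", "haplotype"],
        ascending=[True, False, True], kind="mergesort",
    ).reset_index(drop=True)
    return grouped


def write_stats_report(stats: TajimaStats, path: str | PathLike,
                       label: str = "alignment") -> None:
    """Write a one-row TSV mirroring the summary-statistics table layout
    (m, S, pi, D) followed by the intermediate coefficients."""
    row = {
        "label": label, "m": stats.n, "L": stats.L, "S": stats.S,
        "k": stats.k, "pi": stats.pi, "theta_w": stats.theta_w, "D": stats.D,
        "a1": stats.a1, "a2": stats.a2, "b1": stats.b1, "b2": stats.b2,
        "c1": stats.c1, "c2": stats.c2, "e1": stats.e1, "e2": stats.e2,
    }
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)
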