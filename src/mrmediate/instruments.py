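"""Instrument selection: p-value thresholding, greedy LD clumping, F-statistic filtering.

The selection cascade mirrors standard two-sample MR practice: keep variants
associated with the exposure at p < 1e-5, prune to approximate linkage
equilibrium (r² < 0.001 within 10,000 kb), and drop weak instruments (F ≤ 10,
with F approximated per SNP as (beta/se)²).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gwas_io import SummaryStatTable


@dataclass
class LDMatrix:
    """Squared-correlation matrix over a SNP panel.

    Symmetric, unit diagonal, entries in [0, 1]. ``chrom``/``pos`` are optional
    per-SNP coordinates (clumping takes coordinates from the stats table).
    """

    snp_ids: list[str]
    r2: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValidationError(f"r2 matrix shape {self.r2.shape} != ({k}, {k})")
        if not np.allclose(self.r2, self.r2.T):
            raise ValidationError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValidationError("r2 matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValidationError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, snp_a: str, snp_b: str) -> float:
        try:
            return float(self.r2[self._index[snp_a], self._index[snp_b]])
        except KeyError as exc:
            raise ValidationError(f"SNP {exc.args[0]!r} absent from LD matrix") from None

    def contains(self, snp: str) -> bool:
        return snp in self._index

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame, snp_ids: list[str]) -> "LDMatrix":
        """Build from a long table with columns snp_a, snp_b, r2; unlisted
        pairs are r²=0."""
        k = len(snp_ids)
        idx = {s: i for i, s in enumerate(snp_ids)}
        m = np.zeros((k, k))
        np.fill_diagonal(m, 1.0)
        for _, row in pairs.iterrows():
            a, b = row["snp_a"], row["snp_b"]
            if a in idx and b in idx:
                m[idx[a], idx[b]] = m[idx[b], idx[a]] = float(row["r2"])
        return cls(snp_ids, m)


def load_ld(path: str | Path, snp_ids: list[str] | None = None) -> LDMatrix:
    """Load an LD matrix from TSV.

    Two dialects are accepted:

    * pair list with header ``snp_a  snp_b  r2`` (requires ``snp_ids`` for the
      full panel; unlisted pairs get r²=0);
    * square matrix whose header row is ``snp_id`` followed by the SNP ids and
      whose first column repeats the ids.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:3] == ["snp_a", "snp_b", "r2"]:
        pairs = pd.read_csv(path, sep="\t")
        if snp_ids is None:
            snp_ids = sorted(set(pairs["snp_a"]) | set(pairs["snp_b"]))
        return LDMatrix.from_pairs(pairs, snp_ids)
    if header[0] != "snp_id":
        raise ValidationError(
            f"{path}: unrecognized LD format (expected 'snp_a/snp_b/r2' or square 'snp_id ...')"
        )
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = list(df.columns)
    if list(df.index) != ids:
        raise ValidationError(f"{path}: square LD matrix rows and columns disagree")
    return LDMatrix(ids, df.to_numpy(dtype=float))


def write_ld(ld: LDMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids)
    df.index.name = "snp_id"
    df.to_csv(Path(path), sep="\t")


def select_by_pvalue(table: SummaryStatTable, p_threshold: float = 1e-5) -> SummaryStatTable:
    """Keep records with pval strictly below the threshold, order preserved."""
    return table.subset(table.df["pval"] < p_threshold)


def _chrom_sort_key(c: str):
    try:
        return (0, int(c))
    except (TypeError, ValueError):
        return (1, str(c))


def ld_clump(
    table: SummaryStatTable,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> SummaryStatTable:
    """Greedy LD clumping.

    Repeatedly take the remaining SNP with the smallest p-value (ties broken by
    chrom, pos) as an index and remove every remaining SNP on the same
    chromosome within ``window_kb`` (closed interval, index position ±
    window_kb·1000 bp) whose r² with the index is >= ``r2_threshold``. The
    retained set is returned in genomic order.

    Raises
    ------
    ValidationError
        If any table SNP is absent from the LD matrix.
    """
    df = table.df
    for sid in df["snp_id"]:
        if not ld.contains(sid):
            raise ValidationError(f"SNP {sid!r} absent from LD matrix")
    order = sorted(
        df.index,
        key=lambda i: (df.at[i, "pval"], _chrom_sort_key(df.at[i, "chrom"]), df.at[i, "pos"]),
    )
    window_bp = window_kb * 1000
    alive = set(order)
    kept: list[int] = []
    for i in order:
        if i not in alive:
            continue
        kept.append(i)
        alive.discard(i)
        ci, pi, si = df.at[i, "chrom"], df.at[i, "pos"], df.at[i, "snp_id"]
        for j in list(alive):
            if df.at[j, "chrom"] != ci:
                continue
            if abs(int(df.at[j, "pos"]) - int(pi)) > window_bp:
                continue
            if ld.lookup(si, df.at[j, "snp_id"]) >= r2_threshold:
                alive.discard(j)
    kept_sorted = sorted(
        kept, key=lambda i: (_chrom_sort_key(df.at[i, "chrom"]), df.at[i, "pos"])
    )
    return SummaryStatTable(
        table.trait_id, table.trait_type, df.loc[kept_sorted].reset_index(drop=True)
    )


def f_statistic(beta, se):
    """Per-SNP instrument-strength F statistic, (beta/se)².

    Accepts scalars or arrays; raises ValidationError unless all se > 0.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValidationError("f_statistic requires se > 0")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def filter_weak_instruments(
    table: SummaryStatTable, f_min: float = 10.0
) -> tuple[SummaryStatTable, pd.DataFrame]:
    """Keep SNPs with F strictly greater than ``f_min``.

    Returns the filtered table and a per-SNP report (snp_id, f_stat, kept).
    """
    if len(table) == 0:
        report = pd.DataFrame(columns=["snp_id", "f_stat", "kept"])
        return table, report
    f = f_statistic(table.df["beta"].to_numpy(), table.df["se"].to_numpy())
    f = np.atleast_1d(f)
    report = pd.DataFrame(
        {"snp_id": table.df["snp_id"].to_numpy(), "f_stat": f, "kept": f > f_min}
    )
    return table.subset(pd.Series(f > f_min, index=table.df.index)), report
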