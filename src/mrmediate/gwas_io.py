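"""Reading, writing, validation and allele harmonization of GWAS summary statistics.

Tables are tab-separated with GWAS-SSF-like column names::

    snp_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

``eaf`` and ``n`` may be missing ("NA"). Betas are per effect-allele copy, in
SD units for continuous traits and log-odds for binary traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInstrumentsError, ValidationError

CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]
#: columns whose values must always be present and parseable
REQUIRED_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
]
OPTIONAL_COLUMNS = ["eaf", "n"]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: A/T and C/G variants: strand cannot be resolved from alleles alone
PALINDROMIC_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})


@dataclass
class SummaryStatTable:
    """Per-SNP association records for one trait.

    ``df`` holds one row per SNP in the canonical column order; ``snp_id`` is
    unique within a table.
    """

    trait_id: str
    trait_type: str  # "continuous" | "binary"
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(
                f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def subset(self, mask) -> "SummaryStatTable":
        return SummaryStatTable(
            self.trait_id, self.trait_type, self.df.loc[mask].reset_index(drop=True)
        )


@dataclass
class HarmonizedInstruments:
    """Allele-aligned paired effect estimates for an (exposure, outcome) pair.

    Outcome betas are oriented to the exposure effect allele. ``dropped`` lists
    (snp_id, reason) for every exposure instrument not retained, with reason in
    {allele_mismatch, palindromic_ambiguous, missing_in_outcome}.
    """

    pair_id: tuple[str, str]
    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)
    outcome_type: str = "continuous"

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        snp_ids: Sequence[str] | None = None,
        pair_id: tuple[str, str] = ("exposure", "outcome"),
        outcome_type: str = "continuous",
    ) -> "HarmonizedInstruments":
        beta_exp = np.asarray(beta_exp, dtype=float)
        se_exp = np.asarray(se_exp, dtype=float)
        beta_out = np.asarray(beta_out, dtype=float)
        se_out = np.asarray(se_out, dtype=float)
        if not (len(beta_exp) == len(se_exp) == len(beta_out) == len(se_out)):
            raise ValidationError("effect/SE arrays must have equal length")
        if snp_ids is None:
            snp_ids = [f"snp{i}" for i in range(len(beta_exp))]
        return cls(
            pair_id=pair_id,
            snp_ids=list(snp_ids),
            beta_exp=beta_exp,
            se_exp=se_exp,
            beta_out=beta_out,
            se_out=se_out,
            outcome_type=outcome_type,
        )

    def drop_index(self, idx) -> "HarmonizedInstruments":
        """Return a copy without the instruments at positions ``idx``."""
        idx = np.atleast_1d(idx)
        keep = np.ones(self.n_snp, dtype=bool)
        keep[idx] = False
        return HarmonizedInstruments(
            pair_id=self.pair_id,
            snp_ids=[s for s, k in zip(self.snp_ids, keep) if k],
            beta_exp=self.beta_exp[keep],
            se_exp=self.se_exp[keep],
            beta_out=self.beta_out[keep],
            se_out=self.se_out[keep],
            dropped=list(self.dropped),
            outcome_type=self.outcome_type,
        )


def _coerce_numeric(df: pd.DataFrame, col: str, problems: list[str]) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    for i in df.index[bad]:
        problems.append(f"row {i + 1}, field {col}: unparseable value {raw[i]!r}")
    return out


def _validate_rows(df: pd.DataFrame) -> None:
    problems: list[str] = []
    for i, row in df.iterrows():
        rownum = i + 1  # 1-based data-row numbering
        for col in REQUIRED_COLUMNS:
            if pd.isna(row[col]):
                problems.append(f"row {rownum}, field {col}: missing value")
        ea, oa = row["effect_allele"], row["other_allele"]
        if isinstance(ea, str) and ea not in VALID_ALLELES:
            problems.append(f"row {rownum}, field effect_allele: invalid allele {ea!r}")
        if isinstance(oa, str) and oa not in VALID_ALLELES:
            problems.append(f"row {rownum}, field other_allele: invalid allele {oa!r}")
        if ea in VALID_ALLELES and oa in VALID_ALLELES and ea == oa:
            problems.append(f"row {rownum}: effect_allele equals other_allele ({ea})")
        if pd.notna(row["se"]) and not row["se"] > 0:
            problems.append(f"row {rownum}, field se: must be > 0, got {row['se']}")
        if pd.notna(row["pval"]) and not (0 < row["pval"] <= 1):
            problems.append(f"row {rownum}, field pval: must be in (0,1], got {row['pval']}")
        if pd.notna(row["eaf"]) and not (0 < row["eaf"] < 1):
            problems.append(f"row {rownum}, field eaf: must be in (0,1), got {row['eaf']}")
        if pd.notna(row["pos"]) and row["pos"] < 1:
            problems.append(f"row {rownum}, field pos: must be >= 1, got {row['pos']}")
        if pd.notna(row["n"]) and row["n"] < 1:
            problems.append(f"row {rownum}, field n: must be positive, got {row['n']}")
    if problems:
        raise ValidationError("invalid summary statistics:\n" + "\n".join(problems))


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait_id: str | None = None,
    sep: str = "\t",
) -> SummaryStatTable:
    """Read a delimited summary-statistics table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Optional ``{canonical_name: file_column_name}`` mapping for files whose
        headers differ from the canonical dialect.
    trait_type
        ``"continuous"`` or ``"binary"`` (binary betas are log-odds).
    trait_id
        Defaults to the file stem.

    Raises
    ------
    ConfigurationError
        If a required column is absent.
    ValidationError
        If any row has an unparseable or contract-violating field; the message
        names every offending row and field.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, na_values=["NA"], keep_default_na=False)
    column_map = dict(column_map or {})
    rename = {}
    missing = []
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical in REQUIRED_COLUMNS:
            missing.append(source)
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    df = raw.rename(columns=rename)
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[CANONICAL_COLUMNS].copy()

    problems: list[str] = []
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = _coerce_numeric(df, col, problems)
    if problems:
        raise ValidationError(f"{path}: unparseable fields:\n" + "\n".join(problems))
    df["pos"] = df["pos"].astype("Int64")
    df["n"] = df["n"].astype("Int64")
    _validate_rows(df)

    if df["snp_id"].duplicated().any():
        dups = sorted(df.loc[df["snp_id"].duplicated(), "snp_id"].unique())
        warnings.warn(
            f"{path}: duplicate snp_id(s) {dups}; keeping lowest-p record of each",
            stacklevel=2,
        )
        # stable sort keeps input order among ties; lowest p wins
        df = (
            df.sort_values("pval", kind="stable")
            .drop_duplicates("snp_id", keep="first")
            .sort_index()
        )
    df = df.reset_index(drop=True)
    return SummaryStatTable(trait_id or path.stem, trait_type, df)


def write_summary_stats(table: SummaryStatTable, path: str | Path) -> None:
    """Write a table as TSV in canonical column order; missing values as "NA".

    Floats are written at full precision so a read-back reproduces the table
    exactly.
    """
    df = table.df[CANONICAL_COLUMNS].copy()
    df.to_csv(Path(path), sep="\t", index=False, na_rep="NA")


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in PALINDROMIC_PAIRS


def harmonize(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedInstruments:
    """Align outcome effects to the exposure effect allele.

    Matching order per SNP: direct allele match, swapped (sign flip + eaf
    complement), then strand-complemented versions of both. Palindromic (A/T,
    C/G) SNPs are kept only when both allele frequencies are available, both
    fall outside ``0.5 ± palindrome_eaf_window``, and they agree on which
    allele is the minor one after alignment; otherwise they are dropped as
    ``palindromic_ambiguous``.

    Raises
    ------
    EmptyInstrumentsError
        If no SNP survives harmonization.
    """
    out_idx = outcome.df.set_index("snp_id")
    retained_rows = []
    dropped: list[tuple[str, str]] = []
    lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window

    for _, erow in exposure.df.iterrows():
        sid = erow["snp_id"]
        if sid not in out_idx.index:
            dropped.append((sid, "missing_in_outcome"))
            continue
        orow = out_idx.loc[sid]
        ea, oa = erow["effect_allele"], erow["other_allele"]
        ea2, oa2 = orow["effect_allele"], orow["other_allele"]
        beta_out = float(orow["beta"])
        eaf_out = orow["eaf"]

        if _is_palindromic(ea, oa):
            if {ea2, oa2} != {ea, oa}:
                dropped.append((sid, "allele_mismatch"))
                continue
            eaf_exp = erow["eaf"]
            if pd.isna(eaf_exp) or pd.isna(eaf_out):
                dropped.append((sid, "palindromic_ambiguous"))
                continue
            if not (eaf_exp < lo or eaf_exp > hi) or not (eaf_out < lo or eaf_out > hi):
                dropped.append((sid, "palindromic_ambiguous"))
                continue
            if (ea2, oa2) == (oa, ea):  # nominal swap
                beta_out = -beta_out
                eaf_out = 1.0 - float(eaf_out)
            # strand check: after nominal alignment the frequencies must agree
            if (eaf_exp < 0.5) != (eaf_out < 0.5):
                dropped.append((sid, "palindromic_ambiguous"))
                continue
        else:
            if (ea2, oa2) == (ea, oa):
                pass
            elif (ea2, oa2) == (oa, ea):
                beta_out = -beta_out
            else:
                cea2 = COMPLEMENT.get(ea2, "?")
                coa2 = COMPLEMENT.get(oa2, "?")
                if (cea2, coa2) == (ea, oa):
                    pass
                elif (cea2, coa2) == (oa, ea):
                    beta_out = -beta_out
                else:
                    dropped.append((sid, "allele_mismatch"))
                    continue
        retained_rows.append(
            (sid, float(erow["beta"]), float(erow["se"]), beta_out, float(orow["se"]))
        )

    if not retained_rows:
        raise EmptyInstrumentsError(
            f"no SNPs could be harmonized between {exposure.trait_id} and {outcome.trait_id}"
        )
    sids, bx, sx, by, sy = zip(*retained_rows)
    return HarmonizedInstruments(
        pair_id=(exposure.trait_id, outcome.trait_id),
        snp_ids=list(sids),
        beta_exp=np.array(bx),
        se_exp=np.array(sx),
        beta_out=np.array(by),
        se_out=np.array(sy),
        dropped=dropped,
        outcome_type=outcome.trait_type,
    )


def make_table(
    trait_id: str,
    trait_type: str = "continuous",
    **columns,
) -> SummaryStatTable:
    """Build a SummaryStatTable from keyword arrays; unspecified optional
    columns are filled with NA, chrom/pos with placeholders. Convenience for
    tests and simulation."""
    n = len(columns["snp_id"])
    defaults = {
        "chrom": ["1"] * n,
        "pos": list(range(1, n + 1)),
        "effect_allele": ["A"] * n,
        "other_allele": ["G"] * n,
        "eaf": [np.nan] * n,
        "n": [pd.NA] * n,
    }
    data = {c: columns.get(c, defaults.get(c)) for c in CANONICAL_COLUMNS}
    df = pd.DataFrame(data)
    df["pos"] = df["pos"].astype("Int64")
    df["n"] = df["n"].astype("Int64")
    return SummaryStatTable(trait_id, trait_type, df)
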