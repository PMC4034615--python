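"""Count-table data model and tabular IO.

The central container is :class:`CountTable`: a samples x OTUs matrix of
nonnegative integer read counts together with per-sample categorical
factors (host species, reef bank, treatment, ...).  Zeros are data — under
the Poisson-lognormal model an absent OTU may simply be undersampled — so
reshaping never drops zero cells.

Two tab-separated dialects are supported:

* ``wide``: one row per sample; first column the sample id, then the factor
  columns, then one integer column per OTU.
* ``long``: one row per (otu, sample) cell with columns
  ``otu_id  sample_id  count  <factor columns...>``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountTable", "read_counts", "write_counts", "to_long", "from_long"]

_LONG_FIXED_COLS = ("otu_id", "sample_id", "count")


@dataclass
class CountTable:
    """Samples x OTUs integer counts plus per-sample factor levels.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one integer column per OTU.
    factors
        DataFrame indexed by sample id with one string column per factor.
        May be empty (zero columns) but must cover every sample.
    """

    counts: pd.DataFrame
    factors: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.factors is None:
            self.factors = pd.DataFrame(index=self.counts.index)
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere(~np.isfinite(arr) | (arr != np.floor(arr)))[0]
                raise ValueError(
                    f"non-integer count at sample {c.index[bad[0]]!r}, "
                    f"OTU {c.columns[bad[1]]!r}"
                )
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if arr.size and arr.min() < 0:
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {c.index[bad[0]]!r}, "
                f"OTU {c.columns[bad[1]]!r}"
            )
        if not self.factors.index.equals(c.index):
            missing = c.index.difference(self.factors.index).tolist()
            extra = self.factors.index.difference(c.index).tolist()
            raise ValueError(
                f"factor table does not match samples (missing {missing}, extra {extra})"
            )
        if self.factors.isna().any().any():
            raise ValueError("every sample needs a level for every declared factor")
        self.factors = self.factors.astype(str) if self.factors.shape[1] else self.factors

    # -- convenience --------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors.columns)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def subset(self, samples=None, otus=None) -> "CountTable":
        """Return a new table restricted to the given ids (order preserved)."""
        c = self.counts
        f = self.factors
        if samples is not None:
            samples = list(samples)
            c = c.loc[samples]
            f = f.loc[samples]
        if otus is not None:
            c = c[list(otus)]
        return CountTable(c.copy(), f.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and list(self.counts.columns) == list(other.counts.columns)
            and self.factors.equals(other.factors)
        )

    def __repr__(self) -> str:
        return (
            f"CountTable({len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs, "
            f"factors={self.factor_names})"
        )


def to_long(table: CountTable) -> pd.DataFrame:
    """Melt a :class:`CountTable` to long format, keeping explicit zeros.

    Returns a DataFrame with columns ``otu_id, sample_id, count`` followed by
    one column per factor; exactly ``n_samples * n_otus`` rows.
    """
    long = (
        table.counts.reset_index(names="sample_id")
        .melt(id_vars="sample_id", var_name="otu_id", value_name="count")
    )
    long = long[["otu_id", "sample_id", "count"]]
    if table.factor_names:
        fac = table.factors.reset_index(names="sample_id")
        long = long.merge(fac, on="sample_id", how="left")
    # deterministic order: OTU-major, samples as in the table
    long["_s"] = pd.Categorical(long["sample_id"], categories=table.sample_ids, ordered=True)
    long["_o"] = pd.Categorical(long["otu_id"], categories=table.otu_ids, ordered=True)
    long = long.sort_values(["_o", "_s"], kind="stable").drop(columns=["_s", "_o"])
    return long.reset_index(drop=True)


def from_long(long: pd.DataFrame) -> CountTable:
    """Aggregate a long-format frame back into a :class:`CountTable`.

    Inverse of :func:`to_long`; the first appearance order of sample and OTU
    ids in the frame fixes the output ordering.
    """
    for col in _LONG_FIXED_COLS:
        if col not in long.columns:
            raise ValueError(f"long table missing required column {col!r}")
    sample_order = list(pd.unique(long["sample_id"]))
    otu_order = list(pd.unique(long["otu_id"]))
    wide = long.pivot_table(
        index="sample_id", columns="otu_id", values="count", aggfunc="sum", fill_value=np.nan
    )
    if wide.isna().any().any():
        raise ValueError("long table does not cover every (otu, sample) cell")
    wide = wide.loc[sample_order, otu_order]
    wide.index.name = None
    wide.columns.name = None
    factor_cols = [c for c in long.columns if c not in _LONG_FIXED_COLS]
    fac = (
        long[["sample_id", *factor_cols]].drop_duplicates().set_index("sample_id")
        if factor_cols
        else pd.DataFrame(index=pd.Index(sample_order))
    )
    if fac.index.has_duplicates:
        raise ValueError("inconsistent factor levels for a sample in long table")
    fac = fac.loc[sample_order]
    fac.index.name = None
    return CountTable(wide.astype(np.int64), fac)


def _detect_factor_columns(df: pd.DataFrame) -> list[str]:
    """Leading non-count columns after the sample id are taken as factors."""
    factors: list[str] = []
    for col in df.columns:
        ser = pd.to_numeric(df[col], errors="coerce")
        is_count = ser.notna().all() and (ser == ser.round()).all()
        if is_count:
            break
        factors.append(col)
    return factors


def read_counts(path, format: str = "wide_tsv", factor_columns=None) -> CountTable:
    """Read a count table from ``wide_tsv`` or ``long_tsv``.

    ``factor_columns`` names the metadata columns; when ``None`` the leading
    non-integer columns (after the sample id for wide tables) are used.
    Raises ``ValueError`` on negative or non-integer counts, naming the
    offending row/column.
    """
    if format not in ("wide_tsv", "long_tsv"):
        raise ValueError(f"unknown format {format!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if format == "long_tsv":
        for col in _LONG_FIXED_COLS:
            if col not in df.columns:
                raise ValueError(f"long table missing required column {col!r}")
        df["count"] = _parse_count_column(df["count"], "count")
        return from_long(df)

    sample_col = df.columns[0]
    body = df.set_index(sample_col)
    body.index.name = None
    if body.index.has_duplicates:
        dups = body.index[body.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if factor_columns is None:
        factor_columns = _detect_factor_columns(body)
    factor_columns = list(factor_columns)
    otu_cols = [c for c in body.columns if c not in factor_columns]
    counts = pd.DataFrame(
        {col: _parse_count_column(body[col], col) for col in otu_cols},
        index=body.index,
    )[otu_cols]
    return CountTable(counts, body[factor_columns].copy())


def _parse_count_column(ser: pd.Series, name: str) -> pd.Series:
    num = pd.to_numeric(ser, errors="coerce")
    if num.isna().any():
        row = ser.index[num.isna()][0]
        raise ValueError(f"malformed count {ser[row]!r} at row {row!r}, column {name!r}")
    if (num != num.round()).any():
        row = ser.index[num != num.round()][0]
        raise ValueError(f"non-integer count {ser[row]!r} at row {row!r}, column {name!r}")
    if (num < 0).any():
        row = ser.index[num < 0][0]
        raise ValueError(f"negative count at row {row!r}, column {name!r}")
    return num.astype(np.int64)


def write_counts(table: CountTable, path, format: str = "wide_tsv") -> None:
    """Write a table so that :func:`read_counts` round-trips it exactly."""
    if format == "wide_tsv":
        out = pd.concat([table.factors, table.counts], axis=1)
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, sep="\t", index=False)
    elif format == "long_tsv":
        to_long(table).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def counts_to_string(table: CountTable, format: str = "wide_tsv") -> str:
    buf = io.StringIO()
    write_counts(table, buf, format=format)
    return buf.getvalue()
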