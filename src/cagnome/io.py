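"""Readers and writers for expression matrices, sample tables, and result tables.

All on-disk formats are plain tab-delimited text.  The expression loader
additionally understands the GEO series-matrix dialect, in which the numeric
block is delimited by ``!series_matrix_table_begin`` / ``!series_matrix_table_end``
lines and sample identifiers may be double-quoted.

Matrices are assumed to be already normalised on the log2 scale (gcRMA-like
output); no transformation is applied on load.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path]

#: CAG length of the shortest fully-penetrant HD allele.  Longer-allele
#: lengths of 36 and above are labelled HD; 35 and below are controls.
HD_CAG_THRESHOLD = 36

GROUP_HD = "HD"
GROUP_CONTROL = "control"


class DataFormatError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A probes x samples matrix of log2-scale expression values.

    Parameters
    ----------
    frame
        DataFrame with probe IDs as the index and sample IDs as columns.
        Values must be finite floats; duplicate probe or sample IDs are
        rejected.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.frame.index
        cols = self.frame.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate probe IDs: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate sample IDs: {dup}")
        try:
            values = self.frame.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise DataFormatError(f"non-numeric expression value: {exc}") from exc
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise DataFormatError(
                f"non-finite expression value at probe {idx[i]!r}, sample {cols[j]!r}"
            )
        self.frame = self.frame.astype(float)
        self.frame.index = self.frame.index.astype(str)
        self.frame.columns = self.frame.columns.astype(str)
        self.frame.index.name = "probe_id"

    @property
    def probe_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def reordered(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        """Return a copy with columns in the given sample order."""
        return ExpressionMatrix(self.frame.loc[:, list(sample_ids)].copy())

    def to_tsv(self, path: PathLike) -> None:
        self.frame.to_csv(path, sep="\t")


def _extract_series_matrix_block(text: str) -> str:
    lines = text.splitlines()
    try:
        start = next(
            i for i, ln in enumerate(lines)
            if ln.strip().lower() == "!series_matrix_table_begin"
        )
        end = next(
            i for i, ln in enumerate(lines)
            if ln.strip().lower() == "!series_matrix_table_end"
        )
    except StopIteration:
        raise DataFormatError(
            "series_matrix file lacks !series_matrix_table_begin/end markers"
        ) from None
    block = lines[start + 1:end]
    return "\n".join(ln.replace('"', "") for ln in block)


def read_expression_matrix(path: PathLike, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a probes x samples expression matrix.

    Parameters
    ----------
    path
        Input file.  First column holds probe IDs, header row holds sample IDs.
    dialect
        ``"tsv"`` for a plain tab-delimited matrix or ``"series_matrix"`` for
        the GEO series-matrix dialect (metadata lines starting with ``!`` are
        ignored and quoted IDs are unquoted).
    """
    path = Path(path)
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    elif dialect == "series_matrix":
        block = _extract_series_matrix_block(path.read_text())
        frame = pd.read_csv(_io.StringIO(block), sep="\t", index_col=0, dtype={0: str})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    # locate non-numeric cells before the dataclass check so the error carries
    # row/column coordinates
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            probe = frame.index[bad.to_numpy().nonzero()[0][0]]
            raise DataFormatError(
                f"non-numeric value in column {col!r}, probe {probe!r}: "
                f"{frame.loc[probe, col]!r}"
            )
        frame[col] = coerced
    if frame.isna().any().any():
        raise DataFormatError("missing expression values are not allowed")
    return ExpressionMatrix(frame)


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------

def infer_group(cag_long: int) -> str:
    """HD/control label implied by the longer-allele CAG length."""
    return GROUP_HD if cag_long >= HD_CAG_THRESHOLD else GROUP_CONTROL


@dataclass
class SampleTable:
    """Per-sample CAG genotypes and HD/control labels.

    The underlying frame has columns ``sample_id``, ``cag_long``, ``cag_short``,
    ``group`` and optionally ``subject_id``.  Group labels must be consistent
    with the CAG rule: HD iff the longer allele is >35 CAGs.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        required = {"sample_id", "cag_long", "cag_short"}
        missing = required - set(df.columns)
        if missing:
            raise DataFormatError(f"sample table missing columns: {sorted(missing)}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise DataFormatError(f"duplicate sample IDs: {dup}")
        for col in ("cag_long", "cag_short"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
            if (df[col] <= 0).any():
                raise DataFormatError(f"{col} must be a positive CAG count")
        bad = df["cag_long"] < df["cag_short"]
        if bad.any():
            sid = df.loc[bad, "sample_id"].iloc[0]
            raise DataFormatError(
                f"sample {sid!r}: cag_long < cag_short"
            )
        inferred = df["cag_long"].map(infer_group)
        if "group" in df.columns and df["group"].notna().all():
            df["group"] = df["group"].astype(str)
            unknown = ~df["group"].isin([GROUP_HD, GROUP_CONTROL])
            if unknown.any():
                raise DataFormatError(
                    f"unknown group labels: {df.loc[unknown, 'group'].unique().tolist()}"
                )
            clash = df["group"] != inferred
            if clash.any():
                sid = df.loc[clash, "sample_id"].iloc[0]
                raise DataFormatError(
                    f"sample {sid!r}: explicit group {df.loc[clash, 'group'].iloc[0]!r} "
                    f"contradicts CAG length {df.loc[clash, 'cag_long'].iloc[0]}"
                )
        else:
            df["group"] = inferred
        if "subject_id" not in df.columns:
            df["subject_id"] = df["sample_id"]
        df["subject_id"] = df["subject_id"].astype(str)
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def cag_long(self) -> pd.Series:
        return self.frame.set_index("sample_id")["cag_long"]

    @property
    def groups(self) -> pd.Series:
        return self.frame.set_index("sample_id")["group"]

    def ids_in_group(self, group: str) -> list[str]:
        return self.frame.loc[self.frame["group"] == group, "sample_id"].tolist()

    @property
    def n_hd(self) -> int:
        return int((self.frame["group"] == GROUP_HD).sum())

    @property
    def n_control(self) -> int:
        return int((self.frame["group"] == GROUP_CONTROL).sum())

    def to_tsv(self, path: PathLike) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def read_sample_table(path: PathLike) -> SampleTable:
    """Read a tab-delimited sample table; group labels are inferred from
    ``cag_long`` when absent, and checked against it when present."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return SampleTable(frame)


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

@dataclass
class ProbeAnnotation:
    """Probe set -> gene mapping (GPL570-style export).

    One row per probe; a gene symbol may map to several probes.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        required = {"probe_id", "gene_symbol"}
        missing = required - set(df.columns)
        if missing:
            raise DataFormatError(f"annotation missing columns: {sorted(missing)}")
        for col in ("probe_id", "gene_symbol", "gene_name", "entrez_id"):
            if col not in df.columns:
                df[col] = ""
            df[col] = df[col].fillna("").astype(str)
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
            raise DataFormatError(f"duplicate probe IDs in annotation: {dup}")
        self.frame = df.reset_index(drop=True)


def read_probe_annotation(path: PathLike) -> ProbeAnnotation:
    return ProbeAnnotation(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# results tables and alignment
# ---------------------------------------------------------------------------

def write_results_table(table: pd.DataFrame, path: PathLike) -> None:
    """Write a result table (association statistics, power-curve points, ...)
    as tab-delimited text at full float precision so it round-trips losslessly."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    table.to_csv(path, sep="\t", index=False)


def read_results_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def align(expr: ExpressionMatrix, samples: SampleTable) -> ExpressionMatrix:
    """Align matrix columns to the sample table by sample_id.

    Samples present on one side but not the other are a hard error: silently
    intersecting would corrupt the HD/control group counts downstream.
    """
    matrix_ids = set(expr.sample_ids)
    table_ids = set(samples.sample_ids)
    if matrix_ids != table_ids:
        only_matrix = sorted(matrix_ids - table_ids)
        only_table = sorted(table_ids - matrix_ids)
        raise DataFormatError(
            "expression matrix and sample table disagree on samples: "
            f"matrix-only={only_matrix} table-only={only_table}"
        )
    return expr.reordered(samples.sample_ids)
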