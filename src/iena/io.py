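"""Reading, validating and writing the pipeline's tabular artifacts.

The universal currency is the :class:`OTUTable`: a samples × OTUs abundance
matrix, either raw counts or per-sample relative abundances (compositions).
Sample metadata carries the longitudinal design: which subject and time point
each sample belongs to, which samples form the baseline reference group, and
the (optional) clinical outcome label used for evaluation.

Tables are plain TSV/CSV.  The QIIME "classic" dialect (first header token
``#OTU ID``, OTUs in rows) is auto-detected and transposed on load, so files
exported by common 16S workflows work without flags.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "SampleMetadata",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "to_relative_abundance",
    "read_tsv",
    "write_tsv",
]

#: Sum tolerance used to recognise an already-normalised (relative) table.
_RELATIVE_TOL = 1e-6
#: Row-sum tolerance guaranteed by :func:`to_relative_abundance`.
_CLOSURE_TOL = 1e-9

OUTCOMES = ("Sx", "Asx", "unknown")


@dataclass
class OTUTable:
    """Samples × OTUs abundance matrix.

    Parameters
    ----------
    data
        DataFrame with sample ids as the index and OTU ids as columns.
        Entries must be finite and non-negative.
    mode
        ``"counts"`` for raw abundances, ``"relative"`` for compositions
        (every row sums to 1 within ``1e-9``).
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"mode must be 'counts' or 'relative', got {self.mode!r}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("empty OTU table")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate OTU id: {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric abundance value in OTU table")
        if not np.isfinite(values).all():
            raise ValueError("non-finite abundance value in OTU table")
        if (values < 0).any():
            raise ValueError("negative abundance value in OTU table")
        if self.mode == "relative":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > _CLOSURE_TOL
            if bad.any():
                sid = self.data.index[np.nonzero(bad)[0][0]]
                raise ValueError(
                    f"relative-mode row {sid!r} sums to {sums[bad][0]:.12g}, not 1"
                )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def otu_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def subset_otus(self, otu_ids) -> "OTUTable":
        """Column subset preserving sample rows and mode flag.

        Note: subsetting a relative table yields rows that no longer close to
        1; the result therefore reverts to ``counts`` mode semantics only if
        requested by the caller — here we keep values untouched and trust the
        downstream statistics, which never renormalise.
        """
        sub = self.data.loc[:, list(otu_ids)]
        out = OTUTable.__new__(OTUTable)
        out.data = sub
        out.mode = self.mode if sub.shape[1] == self.data.shape[1] else "counts"
        return out


@dataclass
class SampleMetadata:
    """Per-sample design information for a longitudinal cohort.

    One row per sample: ``subject_id``, integer ``time_point`` (sortable;
    negative study days are allowed), ``is_reference`` flag marking baseline
    samples, and an ``outcome`` label in {Sx, Asx, unknown}.
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject_id", "time_point", "is_reference")

    def __post_init__(self) -> None:
        df = self.frame
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        if "outcome" not in df.columns:
            df = df.assign(outcome="unknown")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample id in metadata: {dup!r}")
        bad = set(df["outcome"]) - set(OUTCOMES)
        if bad:
            raise ValueError(f"unknown outcome label(s): {sorted(bad)}; expected {OUTCOMES}")
        df = df.copy()
        df["time_point"] = df["time_point"].astype(int)
        df["is_reference"] = _coerce_bool(df["is_reference"])
        if not df["is_reference"].any():
            raise ValueError("no reference samples (is_reference all false)")
        if int(df["is_reference"].sum()) < 2:
            raise ValueError("at least 2 reference samples are required to estimate an SD")
        pairs = df[["subject_id", "time_point"]]
        if pairs.duplicated().any():
            sub, tp = pairs[pairs.duplicated()].iloc[0]
            raise ValueError(f"duplicate (subject_id, time_point) pair: ({sub!r}, {tp})")
        self.frame = df

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    def validate_against(self, table: OTUTable) -> None:
        """Every table sample must have exactly one metadata row."""
        missing = table.sample_ids.difference(self.frame.index)
        if len(missing):
            raise ValueError(f"sample {missing[0]!r} present in OTU table but missing from metadata")

    def reference_ids(self) -> pd.Index:
        return self.frame.index[self.frame["is_reference"]]

    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.frame["subject_id"]))

    def subject_samples(self, subject_id: str, include_reference: bool = False) -> pd.DataFrame:
        """Rows for one subject ordered by time point."""
        rows = self.frame[self.frame["subject_id"] == subject_id]
        if not include_reference:
            rows = rows[~rows["is_reference"]]
        return rows.sort_values("time_point")


def _coerce_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False, "t": True, "f": False}
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise ValueError(f"cannot interpret is_reference value {bad!r} as boolean")
    return out.astype(bool)


def read_otu_table(path, orientation: str = "auto") -> OTUTable:
    """Read an OTU abundance table from TSV/CSV.

    ``orientation`` is ``samples_in_rows``, ``otus_in_rows``, or ``auto``.
    Auto-detection: a first header token ``#OTU ID`` marks the QIIME-classic
    dialect (OTUs in rows) and the matrix is transposed on load.  A table
    whose rows already sum to 1 (±1e-6) is flagged ``relative``, otherwise
    ``counts``.
    """
    path = Path(path)
    text = path.read_text()
    # QIIME classic: optional comment line, then a header starting "#OTU ID"
    lines = text.splitlines()
    header_idx = 0
    if lines and lines[0].startswith("#") and not lines[0].startswith("#OTU ID"):
        if len(lines) > 1 and lines[1].startswith("#OTU ID"):
            header_idx = 1
    qiime = bool(lines) and lines[header_idx].startswith("#OTU ID")
    if orientation == "auto":
        orientation = "otus_in_rows" if qiime else "samples_in_rows"
    elif orientation not in ("samples_in_rows", "otus_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")

    sep = "\t" if "\t" in lines[header_idx] else "," if lines else "\t"
    header_ids = lines[header_idx].split(sep)[1:]
    dup = pd.Index(header_ids)
    if dup.has_duplicates:
        raise ValueError(f"duplicate id in header: {dup[dup.duplicated()][0]!r}")
    body = "\n".join(lines[header_idx:])
    df = pd.read_csv(_io.StringIO(body), sep=sep, index_col=0, dtype=str,
                     keep_default_na=False, na_filter=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty table in {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric abundance in {path}: {exc}") from None
    if orientation == "otus_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    df.columns = df.columns.astype(str)
    df.columns.name = None

    sums = df.to_numpy().sum(axis=1)
    mode = "relative" if np.all(np.abs(sums - 1.0) <= _RELATIVE_TOL) else "counts"
    return OTUTable(df, mode=mode)


def write_otu_table(table: OTUTable, path, orientation: str = "samples_in_rows") -> None:
    """Write a table as TSV with 12 significant digits (round-trip stable)."""
    df = table.data if orientation == "samples_in_rows" else table.data.T
    if orientation == "otus_in_rows":
        df = df.copy()
        df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_metadata(path) -> SampleMetadata:
    """Read sample metadata TSV (columns: sample_id, subject_id, time_point,
    is_reference, optional outcome)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("metadata missing required column 'sample_id'")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


def to_relative_abundance(table: OTUTable) -> OTUTable:
    """Close each sample row to sum 1 (compositional normalisation).

    Idempotent; preserves the zero pattern exactly.  An all-zero row cannot
    be normalised and raises with the offending sample id.
    """
    if table.mode == "relative":
        return table
    values = table.data.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    zero = sums == 0
    if zero.any():
        sid = table.sample_ids[np.nonzero(zero)[0][0]]
        raise ValueError(f"cannot normalise all-zero sample row {sid!r}")
    rel = values / sums[:, None]
    df = pd.DataFrame(rel, index=table.sample_ids, columns=table.otu_ids)
    return OTUTable(df, mode="relative")


def read_tsv(path) -> pd.DataFrame:
    """Read a pipeline artifact TSV (networks, markers, scores)."""
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a pipeline artifact TSV with 12 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
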