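"""Readers, writers and grouping logic for the tabular formats the pipeline touches.

In-memory containers follow pandas idiom:

* expression matrix  -- ``pd.DataFrame`` of log2 intensities, rows indexed by
  probe id, columns by sample id;
* response annotation -- ``pd.Series`` mapping sample id to one of the ordered
  clinical response categories (CR, nCR, VGPR, PR, SD);
* probe annotation   -- ``pd.DataFrame`` indexed by probe id with columns
  ``gene``, ``chromosome``, ``cytoband`` and optional 1-based inclusive
  ``start``/``end``;
* segment table      -- ``pd.DataFrame`` with columns ``sample_id``, ``chrom``,
  ``start``, ``end``, ``event`` (1-based inclusive coordinates, events from
  the closed vocabulary gain / loss / LOH).

All genomic coordinates are kept 1-based inclusive internally (the SEG
convention); BED input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

RESPONSE_CATEGORIES = ("CR", "nCR", "VGPR", "PR", "SD")
SEGMENT_EVENTS = ("gain", "loss", "LOH")

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "event"]


class ParseError(ValueError):
    """A file violated its declared format."""


class ValidationError(ValueError):
    """An in-memory table violated a structural invariant."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants: unique ids, finite values."""
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate probe ids: {dupes[:5]}")
    if matrix.columns.has_duplicates:
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("expression matrix contains non-numeric values")
    if not np.isfinite(values).all():
        bad = int((~np.isfinite(values)).sum())
        raise ValidationError(f"expression matrix contains {bad} non-finite values")
    return matrix


def read_expression(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a probe x sample log2 expression matrix from TSV or GCT 1.2.

    TSV dialect: first column holds probe ids, header row holds sample ids.
    GCT 1.2: ``#1.2`` version line, ``nrows<TAB>ncols`` dimension line, then a
    header ``Name  Description  <samples...>``.
    """
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ParseError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise ParseError(f"{path}: malformed GCT dimension line")
            nrows, ncols = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        if "Description" in df.columns:
            df = df.drop(columns="Description")
        if df.shape != (nrows, ncols):
            raise ParseError(
                f"{path}: GCT dimension line declares {nrows}x{ncols} "
                f"but body is {df.shape[0]}x{df.shape[1]}"
            )
    else:
        raise ValueError(f"unknown expression format {format!r}")
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        raise ParseError(f"{path}: non-numeric expression column(s) {non_numeric}")
    return validate_expression(df.astype(float))


def write_expression(matrix: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        matrix.to_csv(path, sep="\t", index_label="probe_id")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
            body = matrix.copy()
            body.insert(0, "Description", matrix.index)
            body.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_response_annotation(path: str | Path) -> pd.Series:
    """Read a CSV with columns ``sample_id,response`` into a Series."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "response"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    bad = sorted(set(df["response"]) - set(RESPONSE_CATEGORIES))
    if bad:
        raise ParseError(
            f"{path}: unknown response categor{'y' if len(bad) == 1 else 'ies'} {bad}; "
            f"allowed: {list(RESPONSE_CATEGORIES)}"
        )
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    return pd.Series(df["response"].to_numpy(), index=df["sample_id"], name="response")


def write_response_annotation(annotation: pd.Series, path: str | Path) -> None:
    annotation.rename_axis("sample_id").rename("response").to_csv(path)


def read_probe_annotation(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a probe annotation table (CSV or TSV, sniffed by extension).

    Required columns: ``probe_id``, ``gene``, ``chromosome``, ``cytoband``;
    optional 1-based inclusive ``start`` / ``end``.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    required = {"probe_id", "gene", "chromosome", "cytoband"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    df = df.set_index("probe_id")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate probe ids")
    return df


def write_probe_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.rename_axis("probe_id").to_csv(path)


# ---------------------------------------------------------------------------
# copy-number segments
# ---------------------------------------------------------------------------

def validate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SEGMENT_COLUMNS if c not in segments.columns]
    if missing:
        raise ValidationError(f"segment table missing column(s) {missing}")
    bad_events = sorted(set(segments["event"]) - set(SEGMENT_EVENTS))
    if bad_events:
        raise ValidationError(
            f"unknown segment event(s) {bad_events}; allowed: {list(SEGMENT_EVENTS)}"
        )
    inverted = segments["start"] > segments["end"]
    if inverted.any():
        row = segments[inverted].iloc[0]
        raise ValidationError(
            f"segment with start > end for sample {row['sample_id']} "
            f"({row['chrom']}:{row['start']}-{row['end']})"
        )
    return segments


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a SEG-like TSV with columns sample_id, chrom, start, end, event."""
    df = pd.read_csv(path, sep="\t")
    df = validate_segments(df)
    return df[SEGMENT_COLUMNS].astype(
        {"sample_id": str, "chrom": str, "start": int, "end": int, "event": str}
    )


def write_segments(segments: pd.DataFrame, path: str | Path) -> None:
    validate_segments(segments)
    segments[SEGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3 region list, converting 0-based half-open to 1-based inclusive."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        comment="#",
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    if (df["start"] > df["end"]).any():
        raise ParseError(f"{path}: BED record with zero or negative length")
    return df


def align_samples(
    matrix: pd.DataFrame, annotation: pd.Series, case_insensitive: bool = False
) -> pd.DataFrame:
    """Check every expression sample has a response category; return the
    matrix with columns renamed to the annotation's ids.

    Matching is exact by default; ``case_insensitive=True`` folds case on
    both sides before comparing.
    """
    if case_insensitive:
        lookup = {str(s).lower(): s for s in annotation.index}
        mapping, missing = {}, []
        for col in matrix.columns:
            target = lookup.get(str(col).lower())
            if target is None:
                missing.append(col)
            else:
                mapping[col] = target
    else:
        missing = [c for c in matrix.columns if c not in annotation.index]
        mapping = {}
    if missing:
        raise ValidationError(f"samples without a response category: {missing[:5]}")
    return matrix.rename(columns=mapping) if mapping else matrix


# ---------------------------------------------------------------------------
# binary response contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinaryContrast:
    """A two-group comparison derived from the ordinal response annotation.

    ``positive`` holds the samples of the class of interest (e.g. CR) and
    ``negative`` the comparison class (e.g. PR/SD pooled).
    """

    positive: tuple[str, ...]
    negative: tuple[str, ...]
    name_positive: str = "positive"
    name_negative: str = "negative"

    def __post_init__(self) -> None:
        if not self.positive or not self.negative:
            raise ValidationError("contrast sides must be non-empty")
        if set(self.positive) & set(self.negative):
            raise ValidationError("contrast sides overlap")

    @property
    def n_positive(self) -> int:
        return len(self.positive)

    @property
    def n_negative(self) -> int:
        return len(self.negative)

    @property
    def samples(self) -> tuple[str, ...]:
        return self.positive + self.negative

    def labels(self) -> np.ndarray:
        """0/1 vector over ``self.samples`` (1 = positive class)."""
        return np.r_[np.ones(self.n_positive, dtype=int), np.zeros(self.n_negative, dtype=int)]


def make_contrast(
    annotation: pd.Series,
    positive_categories: set[str] | list[str] | tuple[str, ...],
    negative_categories: set[str] | list[str] | tuple[str, ...],
) -> BinaryContrast:
    """Partition samples into a binary contrast by response category.

    Example: ``{CR}`` vs ``{PR, SD}`` yields the study's most opposite
    response classes; ``{CR}`` vs ``{nCR, VGPR, PR, SD}`` the CR-vs-rest
    split used for classifier training.
    """
    pos_cats, neg_cats = set(positive_categories), set(negative_categories)
    if pos_cats & neg_cats:
        raise ValidationError(f"category sets overlap: {sorted(pos_cats & neg_cats)}")
    unknown = (pos_cats | neg_cats) - set(RESPONSE_CATEGORIES)
    if unknown:
        raise ValidationError(f"unknown response categories {sorted(unknown)}")
    positive = tuple(annotation.index[annotation.isin(pos_cats)])
    negative = tuple(annotation.index[annotation.isin(neg_cats)])
    if not positive or not negative:
        raise ValidationError(
            f"empty contrast side: {sorted(pos_cats)} has {len(positive)} samples, "
            f"{sorted(neg_cats)} has {len(negative)}"
        )
    return BinaryContrast(
        positive=positive,
        negative=negative,
        name_positive="/".join(sorted(pos_cats, key=RESPONSE_CATEGORIES.index)),
        name_negative="/".join(sorted(neg_cats, key=RESPONSE_CATEGORIES.index)),
    )
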