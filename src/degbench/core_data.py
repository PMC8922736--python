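"""Count-matrix and condition-label data model plus file dialects.

The central container is :class:`CountMatrix`, a dense gene-by-sample matrix of
non-negative integer read counts with unique gene and sample identifiers.
Two-condition designs are described by :class:`ConditionLabels`; the split of a
matrix ``M`` into per-condition matrices ``X`` and ``Y`` is performed by
:func:`split_by_condition`, aligning samples by identifier rather than by
position so that label files (including permuted ones) are unambiguous.

Supported on-disk dialects: plain TSV (header row of sample ids, first column
gene ids), GCT 1.2, and matrix-market triplets with sidecar id lists.
Comment lines starting with ``#`` are treated as metadata and skipped on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "AlignmentError",
    "ConditionLabels",
    "CountMatrix",
    "ParseError",
    "ValidationError",
    "read_count_matrix",
    "read_labels",
    "split_by_condition",
    "write_count_matrix",
    "write_labels",
]


class ParseError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """An in-memory object violates a structural invariant."""


class AlignmentError(ValueError):
    """Two objects that must share sample identifiers do not."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Gene-by-sample matrix of non-negative integer read counts.

    Parameters
    ----------
    gene_ids
        Unique row identifiers.
    sample_ids
        Unique column identifiers.
    counts
        Integer array of shape ``(len(gene_ids), len(sample_ids))`` with all
        entries >= 0.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D array")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(np.asarray(counts, dtype=float))
            if not np.array_equal(rounded, counts):
                raise ValidationError("counts must be integers")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        self.counts = counts

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        """Per-sample total read counts."""
        return self.counts.sum(axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        """Column subset (and reordering) by sample identifier."""
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise AlignmentError(f"unknown sample ids: {missing}")
        cols = [index[s] for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, cols])

    def select_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        """Row subset (and reordering) by gene identifier."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise AlignmentError(f"unknown gene ids: {missing}")
        rows = [index[g] for g in gene_ids]
        return CountMatrix(list(gene_ids), list(self.sample_ids), self.counts[rows, :])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ConditionLabels:
    """Two-condition sample labels aligned to a count matrix by sample id.

    Exactly two distinct levels must be present, each with at least two
    samples. ``level_order`` fixes which level plays the role of condition 1
    (the fold-change denominator); by default levels are ordered
    lexicographically.
    """

    sample_ids: list[str]
    labels: list[str]
    level_order: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(c) for c in self.labels]
        if len(self.sample_ids) != len(self.labels):
            raise ValidationError("sample_ids and labels must have equal length")
        _check_unique(self.sample_ids, "sample")
        levels = sorted(set(self.labels))
        if len(levels) != 2:
            raise ValidationError(
                f"expected exactly two conditions, found {len(levels)}: {levels}"
            )
        for lev in levels:
            n = self.labels.count(lev)
            if n < 2:
                raise ValidationError(
                    f"condition {lev!r} has only {n} sample(s); need at least 2"
                )
        if self.level_order is not None:
            order = tuple(str(x) for x in self.level_order)
            if sorted(order) != levels:
                raise ValidationError(
                    f"level_order {order} does not match observed levels {levels}"
                )
            self.level_order = order
        else:
            self.level_order = (levels[0], levels[1])

    @property
    def levels(self) -> tuple[str, str]:
        assert self.level_order is not None
        return self.level_order

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_of(self, level: str) -> list[str]:
        """Sample ids of one condition, in stored order."""
        return [s for s, c in zip(self.sample_ids, self.labels) if c == level]

    def group_sizes(self) -> tuple[int, int]:
        a, b = self.levels
        return len(self.samples_of(a)), len(self.samples_of(b))

    def with_labels(self, labels: Sequence[str]) -> "ConditionLabels":
        """Same samples, new label assignment (used for permutations)."""
        return ConditionLabels(list(self.sample_ids), list(labels), self.level_order)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FORMATS = ("tsv", "gct", "mtx-triplet")


def _metadata_lines(metadata: Mapping[str, object] | None) -> list[str]:
    if not metadata:
        return []
    return [f"# {k}={v}" for k, v in metadata.items()]


def _coerce_counts(df: pd.DataFrame, path: str) -> np.ndarray:
    values = df.to_numpy()
    try:
        arr = np.asarray(values, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric count entries") from exc
    if not np.isfinite(arr).all():
        raise ParseError(f"{path}: non-finite count entries")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ParseError(
            f"{path}: negative count for gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if not np.array_equal(arr, np.rint(arr)):
        i, j = np.argwhere(arr != np.rint(arr))[0]
        raise ParseError(
            f"{path}: non-integer count for gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return arr.astype(np.int64)


def _read_tsv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    counts = _coerce_counts(df, str(path))
    try:
        return CountMatrix(list(df.index), list(df.columns), counts)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _read_gct(path: Path) -> CountMatrix:
    with open(path, "rt", encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ParseError(f"{path}: line 1 must be the GCT version tag '#1.2'")
        dims = fh.readline().strip().split("\t")
        if len(dims) < 2:
            raise ParseError(f"{path}: line 2 must hold row and column counts")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise ParseError(f"{path}: non-integer dimensions on line 2") from exc
        body = pd.read_csv(fh, sep="\t", dtype=str)
    if list(body.columns[:2]) != ["Name", "Description"]:
        raise ParseError(f"{path}: line 3 must start with 'Name\\tDescription'")
    if body.shape[0] != n_rows or body.shape[1] - 2 != n_cols:
        raise ParseError(
            f"{path}: declared dimensions {n_rows}x{n_cols} disagree with body "
            f"{body.shape[0]}x{body.shape[1] - 2}"
        )
    data = body.set_index("Name").drop(columns="Description")
    counts = _coerce_counts(data, str(path))
    try:
        return CountMatrix(list(data.index), list(data.columns), counts)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("") if path.suffix == ".mtx" else path
    return Path(str(base) + ".genes.txt"), Path(str(base) + ".samples.txt")


def _read_mtx(path: Path) -> CountMatrix:
    gene_file, sample_file = _sidecar_paths(path)
    for f in (gene_file, sample_file):
        if not f.exists():
            raise ParseError(f"{path}: missing sidecar id list {f}")
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:  # scipy raises bare ValueError on malformed files
        raise ParseError(f"{path}: {exc}") from exc
    arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    genes = gene_file.read_text(encoding="utf-8").splitlines()
    samples = sample_file.read_text(encoding="utf-8").splitlines()
    df = pd.DataFrame(arr, index=genes, columns=samples)
    counts = _coerce_counts(df, str(path))
    try:
        return CountMatrix(genes, samples, counts)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_count_matrix(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from ``path`` in one of the supported dialects.

    Parameters
    ----------
    path
        Input file. The ``mtx-triplet`` dialect additionally expects sidecar
        files ``<stem>.genes.txt`` and ``<stem>.samples.txt`` with one
        identifier per line.
    format
        One of ``tsv``, ``gct``, ``mtx-triplet``.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "gct":
        return _read_gct(path)
    return _read_mtx(path)


def write_count_matrix(
    matrix: CountMatrix,
    path: str | Path,
    format: str = "tsv",
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write ``matrix`` to ``path`` in the named dialect.

    TSV output may carry a ``#``-prefixed key=value metadata block before the
    header (skipped on read). GCT 1.2 writes an empty Description column.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "tsv":
        with open(path, "wt", encoding="utf-8") as fh:
            for line in _metadata_lines(metadata):
                fh.write(line + "\n")
            matrix.to_dataframe().to_csv(fh, sep="\t", index_label="gene_id")
    elif format == "gct":
        df = matrix.to_dataframe()
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            out = df.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        gene_file, sample_file = _sidecar_paths(path)
        sparse = scipy.sparse.coo_matrix(matrix.counts)
        buf = io.BytesIO()
        scipy.io.mmwrite(buf, sparse, field="integer")
        path.write_bytes(buf.getvalue())
        gene_file.write_text("\n".join(matrix.gene_ids) + "\n", encoding="utf-8")
        sample_file.write_text("\n".join(matrix.sample_ids) + "\n", encoding="utf-8")


def read_labels(path: str | Path, level_order: tuple[str, str] | None = None) -> ConditionLabels:
    """Read a two-column (sample_id, condition) TSV into :class:`ConditionLabels`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (sample_id, condition)")
    sample_ids = list(df.iloc[:, 0])
    labels = list(df.iloc[:, 1])
    levels = sorted(set(labels))
    if len(levels) > 2:
        raise ValidationError(
            f"{path}: more than two conditions: {levels}"
        )
    return ConditionLabels(sample_ids, labels, level_order)


def write_labels(
    labels: ConditionLabels,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for line in _metadata_lines(metadata):
            fh.write(line + "\n")
        fh.write("sample_id\tcondition\n")
        for s, c in zip(labels.sample_ids, labels.labels):
            fh.write(f"{s}\t{c}\n")


def split_by_condition(
    matrix: CountMatrix, labels: ConditionLabels
) -> tuple[CountMatrix, CountMatrix]:
    """Split ``matrix`` into per-condition matrices ``(X, Y)``.

    ``X`` holds the columns of the first level of ``labels.levels`` and ``Y``
    the second, each keeping the original within-condition column order of
    ``matrix``. Alignment is by sample id; the label row order is irrelevant.
    """
    if set(matrix.sample_ids) != set(labels.sample_ids):
        only_m = sorted(set(matrix.sample_ids) - set(labels.sample_ids))
        only_c = sorted(set(labels.sample_ids) - set(matrix.sample_ids))
        raise AlignmentError(
            f"sample ids do not match; only in matrix: {only_m}, only in labels: {only_c}"
        )
    level1, level2 = labels.levels
    by_sample = dict(zip(labels.sample_ids, labels.labels))
    x_ids = [s for s in matrix.sample_ids if by_sample[s] == level1]
    y_ids = [s for s in matrix.sample_ids if by_sample[s] == level2]
    return matrix.select_samples(x_ids), matrix.select_samples(y_ids)
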