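"""Reading, writing, aggregation and normalization of count matrices.

Count matrices follow the sequencing convention: rows are entities
(genes, mature miRNAs, ...), columns are samples.  Two on-disk dialects
are supported: a plain TSV with a header row of sample ids and a first
column of entity ids, and Matrix Market (``.mtx``) with sidecar
``<stem>.rows.txt`` / ``<stem>.cols.txt`` id files.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GroupAssignment",
    "ExpressionMatrix",
    "ParseError",
    "ValidationError",
    "read_count_matrix",
    "write_count_matrix",
    "read_group_assignment",
    "write_group_assignment",
    "aggregate_isoform_quantification",
    "normalize",
]


class ParseError(ValueError):
    """A file could not be interpreted in the declared dialect."""


class ValidationError(ValueError):
    """Parsed data violates a count-matrix or grouping invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class CountMatrix:
    """Raw read counts ``R_igs`` for m entities across all samples.

    Attributes
    ----------
    counts : ndarray of shape (m, n_samples)
        Nonnegative integral read counts.
    entity_ids, sample_ids : ndarray of str
        Unique row / column identifiers.
    """

    counts: np.ndarray
    entity_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.entity_ids = np.asarray(self.entity_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D entity x sample array")
        m, s = self.counts.shape
        if m != len(self.entity_ids) or s != len(self.sample_ids):
            raise ValidationError("counts shape does not match id lengths")
        _check_unique(self.entity_ids, "entity ids")
        _check_unique(self.sample_ids, "sample ids")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at entity {self.entity_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(self.counts != np.floor(self.counts)):
            i, j = np.argwhere(self.counts != np.floor(self.counts))[0]
            raise ValidationError(
                f"non-integer count at entity {self.entity_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_entities(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_totals(self) -> np.ndarray:
        """Per-sample sequencing depths ``R_gs`` (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.entity_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), df.index.to_numpy(), df.columns.to_numpy())


@dataclass
class GroupAssignment:
    """Partition of samples into n groups (replicates, cancer types, ...)."""

    group_of: dict = field(default_factory=dict)

    @property
    def labels(self) -> list:
        """Group labels in deterministic (sorted) order."""
        return sorted(set(self.group_of.values()), key=str)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def group_sizes(self) -> dict:
        sizes: dict = {}
        for g in self.group_of.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def codes(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Integer group index (into :attr:`labels`) per sample, in order."""
        index = {g: k for k, g in enumerate(self.labels)}
        missing = [s for s in sample_ids if s not in self.group_of]
        if missing:
            raise ValidationError(f"samples without group assignment: {missing[:5]}")
        return np.array([index[self.group_of[s]] for s in sample_ids], dtype=int)

    def members(self, label) -> list:
        return [s for s, g in self.group_of.items() if g == label]

    @classmethod
    def from_labels(cls, sample_ids: Sequence[str], labels: Sequence) -> "GroupAssignment":
        if len(sample_ids) != len(labels):
            raise ValidationError("sample_ids and labels differ in length")
        return cls(dict(zip(sample_ids, labels)))


@dataclass
class ExpressionMatrix:
    """Depth-normalized expression values, as fractions or reads per million."""

    values: np.ndarray
    entity_ids: np.ndarray
    sample_ids: np.ndarray
    units: str = "fraction"
    zero_total_samples: np.ndarray = None  # bool per sample, flagged not dropped

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.entity_ids = np.asarray(self.entity_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.units not in ("fraction", "RPM"):
            raise ValidationError(f"unknown units {self.units!r}")
        if self.zero_total_samples is None:
            self.zero_total_samples = np.zeros(self.values.shape[1], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.sample_ids)


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.rows.txt"), Path(f"{stem}.cols.txt")


def _infer_dialect(path: Path) -> str:
    return "matrix-market" if path.suffix.lower() == ".mtx" else "tsv"


def read_count_matrix(path, dialect: str | None = None) -> CountMatrix:
    """Read a validated :class:`CountMatrix` from ``path``.

    Parameters
    ----------
    path : str or Path
    dialect : {"tsv", "matrix-market"}, optional
        Inferred from the filename extension when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas error variety
            raise ParseError(f"{path}: {exc}") from exc
        values = np.empty(df.shape, dtype=float)
        for i, (eid, row) in enumerate(df.iterrows()):
            for j, cell in enumerate(row):
                try:
                    values[i, j] = float(cell)
                except (TypeError, ValueError) as exc:
                    # +2: one header line, one-based numbering
                    raise ParseError(
                        f"{path}: line {i + 2}: cell {cell!r} is not a number"
                    ) from exc
        return CountMatrix(values, df.index.to_numpy(), df.columns.astype(str).to_numpy())
    if dialect == "matrix-market":
        rows_path, cols_path = _sidecar_paths(path)
        for p in (rows_path, cols_path):
            if not p.exists():
                raise ParseError(f"missing sidecar id file {p}")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
        counts = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        entity_ids = rows_path.read_text().split()
        sample_ids = cols_path.read_text().split()
        return CountMatrix(counts, np.array(entity_ids), np.array(sample_ids))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_count_matrix(cm: CountMatrix, path, dialect: str | None = None) -> None:
    """Write ``cm`` in the given dialect (inverse of :func:`read_count_matrix`)."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "tsv":
        cm.to_frame().astype(int).to_csv(path, sep="\t", index_label="entity_id")
    elif dialect == "matrix-market":
        rows_path, cols_path = _sidecar_paths(path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(cm.counts.astype(int)))
        rows_path.write_text("\n".join(map(str, cm.entity_ids)) + "\n")
        cols_path.write_text("\n".join(map(str, cm.sample_ids)) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_group_assignment(path, cm: CountMatrix | None = None) -> GroupAssignment:
    """Read a two-column (sample_id, group) TSV.

    When ``cm`` is given, every sample of the matrix must be assigned;
    extra table rows are ignored with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns")
    # tolerate a header line
    if df.iloc[0, 0].lower() in ("sample", "sample_id"):
        df = df.iloc[1:]
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if cm is not None:
        missing = [s for s in cm.sample_ids if s not in mapping]
        if missing:
            raise ValidationError(f"samples missing from group table: {missing}")
        extra = sorted(set(mapping) - set(cm.sample_ids))
        if extra:
            warnings.warn(f"ignoring {len(extra)} samples absent from count matrix")
            mapping = {s: mapping[s] for s in cm.sample_ids}
    return GroupAssignment(mapping)


def write_group_assignment(groups: GroupAssignment, path) -> None:
    with open(path, "w") as fh:
        for s, g in groups.group_of.items():
            fh.write(f"{s}\t{g}\n")


# TCGA-style isoform quantification aggregation -----------------------------

_REGION_COLUMN_CANDIDATES = ("miRNA_region", "mirna_region")
_COUNT_COLUMN_CANDIDATES = ("read_count", "reads")


def aggregate_isoform_quantification(
    files: Iterable, id_pattern: str = r"MIMAT\d+"
) -> CountMatrix:
    """Aggregate per-isoform quantification files to mature-miRNA counts.

    Each file is one sample (column).  Every line whose region annotation
    matches ``id_pattern`` (a mature-miRNA accession) contributes its read
    count to that accession; counts for the same accession within a file are
    summed, including reads from different genomic regions coding the same
    mature miRNA.  Lines without a matching accession (precursors, unannotated
    regions) are dropped.
    """
    pattern = re.compile(id_pattern)
    per_file: dict[str, dict[str, float]] = {}
    for f in files:
        f = Path(f)
        sample_id = f.stem
        df = pd.read_csv(f, sep="\t", dtype=str)
        region_col = next((c for c in _REGION_COLUMN_CANDIDATES if c in df.columns), None)
        count_col = next((c for c in _COUNT_COLUMN_CANDIDATES if c in df.columns), None)
        if region_col is None or count_col is None:
            raise ParseError(
                f"{f}: need region ({_REGION_COLUMN_CANDIDATES}) and count "
                f"({_COUNT_COLUMN_CANDIDATES}) columns, got {list(df.columns)}"
            )
        sums: dict[str, float] = {}
        for region, count in zip(df[region_col], df[count_col]):
            match = pattern.search(str(region))
            if match is None:
                continue
            sums[match.group(0)] = sums.get(match.group(0), 0.0) + float(count)
        if not sums:
            logger.warning("%s: no mature-miRNA lines; column will be all zeros", f)
        per_file[sample_id] = sums
    entities = sorted({acc for sums in per_file.values() for acc in sums})
    counts = np.zeros((len(entities), len(per_file)))
    eidx = {acc: i for i, acc in enumerate(entities)}
    for j, (sample_id, sums) in enumerate(per_file.items()):
        for acc, c in sums.items():
            counts[eidx[acc], j] = c
    return CountMatrix(counts, np.array(entities, dtype=object), np.array(list(per_file), dtype=object))


def normalize(cm: CountMatrix, units: str = "fraction") -> ExpressionMatrix:
    """Maximum-likelihood expression: fractions ``R_igs/R_gs`` or RPM.

    Samples with zero total reads yield an all-zero column and are flagged
    in :attr:`ExpressionMatrix.zero_total_samples` rather than dropped.
    """
    if units not in ("fraction", "RPM"):
        raise ValueError(f"unknown units {units!r}")
    totals = cm.sample_totals
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    values = cm.counts / safe
    if units == "RPM":
        values = values * 1e6
    values[:, zero] = 0.0
    if zero.any():
        logger.warning("%d samples have zero total reads", int(zero.sum()))
    return ExpressionMatrix(values, cm.entity_ids, cm.sample_ids, units, zero)
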