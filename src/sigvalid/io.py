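"""Readers, writers and gene matching for expression matrices and signatures.

Expression matrices are genes-in-rows, samples-in-columns (the dominant
convention for delimited expression files and GCT); the PCA engine transposes
internally so that samples are the statistical observations.

Values are expected on a log2 scale; no normalization is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, MatchError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SignatureTable",
    "GeneMatch",
    "read_expression",
    "write_expression",
    "read_signature",
    "write_signature",
    "match_genes",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples grid of log2 expression values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by unique gene (or probeset) identifiers, columns by
        unique sample identifiers. Must be fully numeric with no missing
        entries.
    base_gene_ids : list of str, optional
        The pre-disambiguation identifier for each row. When the reader
        encounters duplicated gene ids it keeps every row and appends
        deterministic ``.1``, ``.2``, ... suffixes; this field remembers the
        original id so signature matching can still find all copies. Defaults
        to the row index itself.
    """

    data: pd.DataFrame
    base_gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids after disambiguation: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if self.data.shape[0] < 2:
            raise FormatError("expression matrix needs at least 2 genes")
        if self.data.shape[1] < 3:
            raise FormatError("expression matrix needs at least 3 samples")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            raise FormatError("expression matrix contains missing/non-finite values")
        if self.base_gene_ids is None:
            self.base_gene_ids = [str(g) for g in self.data.index]
        elif len(self.base_gene_ids) != self.data.shape[0]:
            raise FormatError("base_gene_ids length does not match row count")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SignatureTable:
    """An ordered list of (gene id, reference value) pairs.

    Reference values carry each gene's direction (-1/+1, e.g. male/female
    specific genes) or a continuous weight (e.g. a training-dataset PC1
    loading). They are compared against the fitted PC1 loadings by the
    transferability statistic; they never re-weight expression values.
    """

    entries: list[tuple[str, float]]
    name: str = "signature"

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise FormatError(f"signature '{self.name}' is empty")
        self.entries = [(str(g), float(v)) for g, v in self.entries]
        ids = [g for g, _ in self.entries]
        seen: set[str] = set()
        dups = sorted({g for g in ids if g in seen or seen.add(g)})  # type: ignore[func-returns-value]
        if dups:
            raise FormatError(f"duplicate gene ids in signature '{self.name}': {dups}")
        vals = np.array([v for _, v in self.entries], dtype=float)
        if not np.isfinite(vals).all():
            raise FormatError(f"non-finite reference value in signature '{self.name}'")
        if np.unique(vals).size < 2:
            raise FormatError(
                f"constant reference values in signature '{self.name}': "
                "transferability is undefined for a constant reference"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def reference_values(self) -> np.ndarray:
        return np.array([v for _, v in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GeneMatch:
    """Result of matching a signature against the rows of a matrix.

    ``matched_gene_ids`` enumerates matrix rows in matrix order (suffixed
    duplicates of one signature gene each appear, inheriting its reference
    value), while ``n_matched`` counts the *distinct* signature genes found —
    the quantity the match-fraction check and the paper-style "k of n present"
    bookkeeping refer to.
    """

    matched_gene_ids: list[str]
    matched_reference: np.ndarray
    n_signature: int
    n_matched: int

    @property
    def fraction(self) -> float:
        return self.n_matched / self.n_signature

    @property
    def n_rows(self) -> int:
        return len(self.matched_gene_ids)


def _dedupe_index(ids: list[str]) -> tuple[list[str], list[str], dict[str, int]]:
    """Suffix duplicated ids deterministically; return (new ids, base ids, dup counts)."""
    counts: dict[str, int] = {}
    for g in ids:
        counts[g] = counts.get(g, 0) + 1
    dup_counts = {g: c for g, c in counts.items() if c > 1}
    if not dup_counts:
        return ids, list(ids), {}
    running: dict[str, int] = {}
    new_ids = []
    for g in ids:
        if counts[g] > 1:
            running[g] = running.get(g, 0) + 1
            new_ids.append(f"{g}.{running[g]}")
        else:
            new_ids.append(g)
    return new_ids, list(ids), dup_counts


def read_expression(
    path: str | Path,
    format: str = "tsv",
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV, or GCT 1.2.

    For TSV/CSV the first column holds gene ids and the remaining columns one
    sample each. GCT 1.2 files carry a ``#1.2`` version line, a dimensions
    line, and NAME/Description columns; Description is dropped.

    Missing or non-numeric cells are an error unless ``impute_missing`` is
    set, in which case they are replaced by the per-gene mean (logged).
    Duplicated gene ids are all retained with ``.1``, ``.2``, ... suffixes.
    """
    path = Path(path)
    format = format.lower()
    if format not in {"tsv", "csv", "gct"}:
        raise FormatError(f"unknown expression format: {format!r}")
    if not path.exists():
        raise FormatError(f"no such file: {path}")

    if format == "gct":
        raw, ids = _read_gct(path)
    else:
        sep = "\t" if format == "tsv" else ","
        try:
            raw = pd.read_csv(path, sep=sep, header=0, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas error detail
            raise FormatError(f"could not parse {path}: {exc}") from exc
        if raw.shape[1] < 4:
            raise FormatError(
                f"{path}: fewer than 3 sample columns (got {raw.shape[1] - 1})"
            )
        ids = [str(g) for g in raw.iloc[:, 0]]
        raw = raw.iloc[:, 1:]

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    n_missing = int(numeric.isna().to_numpy().sum())
    if n_missing:
        if not impute_missing:
            raise FormatError(
                f"{path}: {n_missing} missing or non-numeric cells "
                "(pass impute_missing=True to apply per-gene mean imputation)"
            )
        row_means = numeric.mean(axis=1)
        numeric = numeric.apply(lambda col: col.fillna(row_means))
        logger.warning("%s: imputed %d cells with per-gene means", path, n_missing)

    new_ids, base_ids, dup_counts = _dedupe_index(ids)
    if dup_counts:
        logger.info(
            "%s: %d duplicated gene ids suffixed (%s)",
            path,
            len(dup_counts),
            ", ".join(sorted(dup_counts)[:5]),
        )
    numeric.index = pd.Index(new_ids)
    matrix = ExpressionMatrix(numeric, base_gene_ids=base_ids)
    logger.info(
        "loaded %s: %d genes x %d samples (%d duplicate ids suffixed)",
        path,
        matrix.n_genes,
        matrix.n_samples,
        len(dup_counts),
    )
    return matrix


def _read_gct(path: Path) -> tuple[pd.DataFrame, list[str]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 4 or not lines[0].startswith("#1.2"):
        raise FormatError(f"{path}: not a GCT 1.2 file (missing '#1.2' header)")
    dims = lines[1].split("\t")
    try:
        n_rows, n_cols = int(dims[0]), int(dims[1])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed GCT dimensions line") from exc
    header = lines[2].split("\t")
    if len(header) < 2 or header[0].upper() != "NAME":
        raise FormatError(f"{path}: malformed GCT column header")
    sample_ids = header[2:]
    if len(sample_ids) != n_cols:
        raise FormatError(
            f"{path}: column count mismatch (header says {n_cols}, "
            f"found {len(sample_ids)})"
        )
    body = [ln.split("\t") for ln in lines[3:] if ln.strip() != ""]
    if len(body) != n_rows:
        raise FormatError(
            f"{path}: row count mismatch (header says {n_rows}, found {len(body)})"
        )
    ids = [row[0] for row in body]
    values = pd.DataFrame(
        [row[2 : 2 + n_cols] for row in body], columns=sample_ids, dtype=str
    )
    return values, ids


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    """Write an ExpressionMatrix as TSV, CSV, or GCT 1.2."""
    path = Path(path)
    format = format.lower()
    if format in {"tsv", "csv"}:
        sep = "\t" if format == "tsv" else ","
        out = matrix.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep=sep, float_format="%.10g")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            fh.write("NAME\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
            for gid, base, row in zip(
                matrix.gene_ids, matrix.base_gene_ids, matrix.values
            ):
                vals = "\t".join(f"{v:.10g}" for v in row)
                fh.write(f"{gid}\t{base}\t{vals}\n")
    else:
        raise FormatError(f"unknown expression format: {format!r}")


def read_signature(path: str | Path, name: str | None = None) -> SignatureTable:
    """Read a two-column ``gene_id<TAB>reference_value`` signature file.

    Lines starting with ``#`` are comments; a single header line is tolerated
    (detected by a non-numeric second field on the first data line).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    entries: list[tuple[str, float]] = []
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected two columns (gene_id, reference_value)"
                )
            gid, raw_val = fields[0].strip(), fields[1].strip()
            try:
                val = float(raw_val)
            except ValueError:
                if first_data_line:
                    first_data_line = False
                    continue  # header line
                raise FormatError(
                    f"{path}:{lineno}: non-numeric reference value {raw_val!r}"
                ) from None
            if not np.isfinite(val):
                raise FormatError(f"{path}:{lineno}: non-finite reference value")
            entries.append((gid, val))
            first_data_line = False
    return SignatureTable(entries, name=name or path.stem)


def write_signature(signature: SignatureTable, path: str | Path) -> None:
    """Write a SignatureTable as two-column TSV with a comment header."""
    with open(path, "w") as fh:
        fh.write(f"# signature: {signature.name}\n")
        fh.write("gene_id\treference_value\n")
        for gid, val in signature.entries:
            fh.write(f"{gid}\t{val:.10g}\n")


def match_genes(
    matrix: ExpressionMatrix,
    signature: SignatureTable,
    min_fraction: float = 0.5,
) -> GeneMatch:
    """Match signature genes to matrix rows by exact, case-sensitive id.

    Suffixed duplicate rows of a signature gene all match and each inherits
    the gene's reference value. Matched rows follow matrix row order. An
    error is raised when fewer than 3 distinct signature genes are found or
    when the matched fraction falls below ``min_fraction``.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    ref_by_gene = dict(signature.entries)
    matched_ids: list[str] = []
    matched_ref: list[float] = []
    matched_genes: set[str] = set()
    for row_id, base_id in zip(matrix.gene_ids, matrix.base_gene_ids):
        if base_id in ref_by_gene:
            matched_ids.append(row_id)
            matched_ref.append(ref_by_gene[base_id])
            matched_genes.add(base_id)
    n_matched = len(matched_genes)
    n_signature = len(signature)
    if n_matched == 0:
        raise MatchError(
            f"signature '{signature.name}' shares no genes with the matrix"
        )
    if n_matched < 3:
        raise MatchError(
            f"signature '{signature.name}' too small after matching "
            f"({n_matched} of {n_signature} genes found)"
        )
    fraction = n_matched / n_signature
    if fraction < min_fraction:
        raise MatchError(
            f"signature '{signature.name}': matched fraction {fraction:.3f} "
            f"({n_matched}/{n_signature}) below min_fraction={min_fraction}"
        )
    logger.info(
        "matched %d/%d genes (%.1f%%) of signature '%s' to %d matrix rows",
        n_matched,
        n_signature,
        100 * fraction,
        signature.name,
        len(matched_ids),
    )
    return GeneMatch(
        matched_gene_ids=matched_ids,
        matched_reference=np.array(matched_ref, dtype=float),
        n_signature=n_signature,
        n_matched=n_matched,
    )
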