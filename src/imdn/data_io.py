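"""Readers, writers and matrix builders for association, similarity and expression data.

All on-disk formats share one dialect: tab-separated values, UTF-8, ``#``
comment lines.  Identifiers are normalized (lower-cased, whitespace-stripped)
on ingest, so "hsa-miR-21" and "HSA-MIR-21" name the same miRNA.  Output
ordering is always lexicographic in the normalized IDs, which makes every
matrix written by this module reproducible byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "AssociationMatrix",
    "WeightMatrix",
    "ExpressionTable",
    "normalize_id",
    "read_association_list",
    "write_association_list",
    "merge_association_lists",
    "association_from_pairs",
    "read_expression_table",
    "write_expression_table",
    "build_weight_matrix",
    "read_matrix",
    "read_similarity_matrix",
    "write_matrix",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the file and line."""


def normalize_id(raw: str) -> str:
    """Canonical identifier form: stripped and lower-cased.

    Lower-casing unifies capitalization variants of the same gene symbol
    (e.g. the "hsa-miR-x" / "hsa-mir-x" precursor-vs-mature spelling split).
    """
    return raw.strip().lower()


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary miRNA x disease adjacency matrix.

    ``R[u, i] == 1`` iff miRNA ``mirna_ids[u]`` has a verified association
    with disease ``disease_ids[i]``.  Both axes are sorted lexicographically
    and free of duplicates.
    """

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    R: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError(
                f"R has shape {R.shape}, expected "
                f"({len(self.mirna_ids)}, {len(self.disease_ids)})"
            )
        if not np.isin(R, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be exactly 0 or 1")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        object.__setattr__(self, "R", R)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_positives(self) -> int:
        return int(self.R.sum())

    def mirna_index(self, mirna_id: str) -> int:
        return self.mirna_ids.index(normalize_id(mirna_id))

    def disease_index(self, disease_id: str) -> int:
        return self.disease_ids.index(normalize_id(disease_id))

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (u, i) with R[u, i] == 1, in row-major order."""
        return [tuple(p) for p in np.argwhere(self.R == 1)]


@dataclass(frozen=True)
class WeightMatrix:
    """Per-pair confidence weights for the factorization loss.

    ``W[u, i] == 1`` wherever the association is known (``R == 1``); where it
    is unknown the entry carries the min-max-scaled expression value in
    ``[0, 1]``.  ``background`` stores the expression-derived weight for
    *every* cell, i.e. the weight a cell would carry if its association were
    unknown — leave-one-out evaluation uses it to down-weight a held-out
    positive back to its unobserved state.
    """

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    W: np.ndarray
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError("weight matrix shape does not match ID axes")
        if not np.isfinite(W).all():
            raise ValueError("weight matrix contains non-finite entries")
        if (W < 0).any() or (W > 1).any():
            raise ValueError("weight matrix entries must lie in [0, 1]")
        object.__setattr__(self, "W", W)
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != W.shape:
                raise ValueError("background weights shape mismatch")
            object.__setattr__(self, "background", bg)


@dataclass(frozen=True)
class ExpressionTable:
    """miRNA expression records: (mirna_id, optional disease_id, value).

    Values are non-negative and finite, in arbitrary units; min-max scaling
    happens later when the weight matrix is built.  ``disease_id`` is NaN/None
    for per-miRNA records.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        required = {"mirna_id", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"expression table needs columns {sorted(required)}")
        if "disease_id" not in df.columns:
            df["disease_id"] = pd.NA
        df["mirna_id"] = df["mirna_id"].map(normalize_id)
        df["disease_id"] = df["disease_id"].map(
            lambda x: normalize_id(x) if isinstance(x, str) else pd.NA
        )
        df["value"] = pd.to_numeric(df["value"])
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if (df["value"] < 0).any():
            raise ValueError("expression values must be non-negative")
        if df.duplicated(subset=["mirna_id", "disease_id"]).any():
            raise ValueError("duplicate (miRNA, disease) expression keys")
        object.__setattr__(self, "df", df[["mirna_id", "disease_id", "value"]])

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str | None, float]]
    ) -> "ExpressionTable":
        rows = [
            {"mirna_id": m, "disease_id": d if d is not None else pd.NA, "value": v}
            for m, d, v in records
        ]
        return cls(pd.DataFrame(rows, columns=["mirna_id", "disease_id", "value"]))

    def per_mirna(self) -> dict[str, float]:
        """Mean value per miRNA (collapses per-pair records if present)."""
        return self.df.groupby("mirna_id")["value"].mean().to_dict()

    def per_pair(self) -> dict[tuple[str, str], float]:
        sub = self.df.dropna(subset=["disease_id"])
        return {
            (m, d): v
            for m, d, v in zip(sub["mirna_id"], sub["disease_id"], sub["value"])
        }


# ---------------------------------------------------------------------------
# association lists
# ---------------------------------------------------------------------------


def _parse_pairs(path: Path, delimiter: str) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    n_data_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split(delimiter)
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"{path}:{lineno}: expected at least two fields "
                    f"(miRNA-ID, disease-ID), got {stripped!r}"
                )
            n_data_lines += 1
            pairs.add((normalize_id(fields[0]), normalize_id(fields[1])))
    if n_data_lines == 0:
        raise ParseError(f"{path}: no association records found")
    return pairs


def association_from_pairs(pairs: Iterable[tuple[str, str]]) -> AssociationMatrix:
    """Build the binary adjacency from normalized (miRNA, disease) pairs."""
    pair_set = {(normalize_id(m), normalize_id(d)) for m, d in pairs}
    if not pair_set:
        raise ValueError("cannot build an association matrix from zero pairs")
    mirna_ids = tuple(sorted({m for m, _ in pair_set}))
    disease_ids = tuple(sorted({d for _, d in pair_set}))
    m_index = {m: u for u, m in enumerate(mirna_ids)}
    d_index = {d: i for i, d in enumerate(disease_ids)}
    R = np.zeros((len(mirna_ids), len(disease_ids)))
    for m, d in pair_set:
        R[m_index[m], d_index[d]] = 1.0
    return AssociationMatrix(mirna_ids, disease_ids, R)


def read_association_list(path: str | Path, delimiter: str = "\t") -> AssociationMatrix:
    """Read one edge-list file into a binary adjacency matrix.

    Duplicate lines collapse to a single 1-entry; IDs are normalized and
    sorted so the matrix layout is deterministic.
    """
    return association_from_pairs(_parse_pairs(Path(path), delimiter))


def merge_association_lists(
    paths: Sequence[str | Path], delimiter: str = "\t"
) -> AssociationMatrix:
    """Union of several edge lists after ID normalization.

    Mirrors merging curated association databases: duplicates within and
    across sources collapse, and the axes cover the union of all IDs.
    """
    if not paths:
        raise ValueError("merge requires at least one path")
    all_pairs: set[tuple[str, str]] = set()
    for p in paths:
        all_pairs |= _parse_pairs(Path(p), delimiter)
    return association_from_pairs(all_pairs)


def write_association_list(assoc: AssociationMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# mirna_id\tdisease_id\n")
        for u, i in assoc.positive_pairs():
            fh.write(f"{assoc.mirna_ids[u]}\t{assoc.disease_ids[i]}\n")


# ---------------------------------------------------------------------------
# expression and weights
# ---------------------------------------------------------------------------


def read_expression_table(path: str | Path, delimiter: str = "\t") -> ExpressionTable:
    """Read expression records; 2 columns = per-miRNA, 3 = per-pair."""
    path = Path(path)
    records: list[tuple[str, str | None, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split(delimiter)
            try:
                if len(fields) == 2:
                    records.append((fields[0], None, float(fields[1])))
                elif len(fields) >= 3:
                    disease = fields[1].strip() or None
                    records.append((fields[0], disease, float(fields[2])))
                else:
                    raise ValueError("too few fields")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no expression records found")
    return ExpressionTable.from_records(records)


def write_expression_table(expr: ExpressionTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# mirna_id\tdisease_id\tvalue\n")
        for _, row in expr.df.iterrows():
            d = row["disease_id"]
            d_str = d if isinstance(d, str) else ""
            fh.write(f"{row['mirna_id']}\t{d_str}\t{row['value']!r}\n")


def build_weight_matrix(
    assoc: AssociationMatrix,
    expr: ExpressionTable,
    mode: Literal["per_mirna", "per_pair"] = "per_mirna",
) -> WeightMatrix:
    """Expression-derived confidence weights for every miRNA-disease cell.

    Expression values are min-max scaled to [0, 1] over all provided values
    (one global scaling).  Known associations keep weight 1; unknown cells
    get the scaled value — the full row value in ``per_mirna`` mode, the
    pair-specific value in ``per_pair`` mode.  miRNAs without expression fall
    back to weight 1 (fully observed) with a logged warning, so missing
    expression degrades gracefully to plain weighted matrix factorization.
    """
    values = expr.df["value"].to_numpy(dtype=float)
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        raise ValueError(
            "all expression values are identical: min-max scaling is undefined; "
            "use a constant weight matrix (np.ones_like(R)) instead"
        )

    def scale(v: float) -> float:
        return (v - vmin) / (vmax - vmin)

    nm, nd = assoc.R.shape
    background = np.ones((nm, nd))
    if mode == "per_mirna":
        by_mirna = expr.per_mirna()
        missing = [m for m in assoc.mirna_ids if m not in by_mirna]
        if missing:
            logger.warning(
                "no expression for %d miRNA(s) (e.g. %s); using weight 1.0",
                len(missing),
                missing[0],
            )
        for u, m in enumerate(assoc.mirna_ids):
            if m in by_mirna:
                background[u, :] = scale(by_mirna[m])
    elif mode == "per_pair":
        by_pair = expr.per_pair()
        by_mirna = expr.per_mirna()
        for u, m in enumerate(assoc.mirna_ids):
            for i, d in enumerate(assoc.disease_ids):
                if (m, d) in by_pair:
                    background[u, i] = scale(by_pair[(m, d)])
                elif m in by_mirna:
                    background[u, i] = scale(by_mirna[m])
    else:
        raise ValueError(f"unknown weight mode {mode!r}")

    extra = set(expr.df["mirna_id"]) - set(assoc.mirna_ids)
    if extra:
        logger.warning(
            "dropping expression for %d miRNA(s) absent from the association "
            "matrix (e.g. %s)",
            len(extra),
            sorted(extra)[0],
        )
    W = np.where(assoc.R == 1, 1.0, background)
    return WeightMatrix(assoc.mirna_ids, assoc.disease_ids, W, background=background)


# ---------------------------------------------------------------------------
# generic labelled matrices
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Read a TSV matrix with an ID header row and ID first column."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, comment="#", float_precision="round_trip"
    )
    row_ids = tuple(normalize_id(str(r)) for r in df.index)
    col_ids = tuple(normalize_id(str(c)) for c in df.columns)
    return row_ids, col_ids, df.to_numpy(dtype=float)


def read_association_matrix(path: str | Path) -> AssociationMatrix:
    """Read a binary adjacency in matrix form (keeps isolated IDs, which an
    edge list cannot represent)."""
    row_ids, col_ids, values = read_matrix(path)
    return AssociationMatrix(row_ids, col_ids, values)


def read_similarity_matrix(path: str | Path, kind: str = "functional"):
    """Read a square miRNA similarity matrix (ID header row and column).

    Rejects non-square inputs, NaN entries, and asymmetries beyond 1e-8;
    small numerical asymmetry is symmetrized away.
    """
    from .similarity import SimilarityMatrix

    row_ids, col_ids, values = read_matrix(path)
    if values.shape[0] != values.shape[1] or row_ids != col_ids:
        raise ValueError(f"{path}: similarity matrix must be square with matching IDs")
    if np.isnan(values).any():
        raise ValueError(f"{path}: similarity matrix contains NaN entries")
    if kind != "row_normalized":  # row-normalized matrices are not symmetric
        if np.abs(values - values.T).max(initial=0.0) > 1e-8:
            raise ValueError(
                f"{path}: similarity matrix is asymmetric beyond 1e-8"
            )
        values = 0.5 * (values + values.T)
    return SimilarityMatrix(row_ids, values, kind=kind)


def write_matrix(obj, path: str | Path) -> None:
    """Write any labelled matrix (association, weight or similarity) as TSV.

    Floats are written with ``repr`` (shortest round-tripping form), so
    read(write(x)) reproduces x exactly.
    """
    if isinstance(obj, AssociationMatrix):
        row_ids, col_ids, values = obj.mirna_ids, obj.disease_ids, obj.R
    elif isinstance(obj, WeightMatrix):
        row_ids, col_ids, values = obj.mirna_ids, obj.disease_ids, obj.W
    else:  # SimilarityMatrix or any duck-typed labelled square matrix
        row_ids, col_ids, values = obj.mirna_ids, obj.mirna_ids, obj.values
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(col_ids) + "\n")
        for rid, row in zip(row_ids, values):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
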