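"""Binary disease-microbe association datasets and their file formats.

The central object is :class:`AssociationDataset`: a labeled 0/1 adjacency
matrix ``A`` with diseases as rows and microbes as columns, so ``A[i, j] = 1``
iff disease ``i`` has a curated association with microbe ``j``.  Row ``i`` of
``A`` is the interaction profile of disease ``i``; column ``j`` is the
interaction profile of microbe ``j``.  Two plain-text formats are supported: a
two-column pair list (one known association per row, the layout of an HMDAD
export) and a dense labeled 0/1 matrix.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationDataset",
    "read_pair_list",
    "read_dense_matrix",
    "write_pair_list",
    "write_dense_matrix",
    "write_ranked_scores",
]


@dataclass(frozen=True)
class AssociationDataset:
    """Labeled binary disease x microbe adjacency matrix.

    Parameters
    ----------
    disease_ids
        Ordered unique disease identifiers (matrix rows).
    microbe_ids
        Ordered unique microbe identifiers (matrix columns).
    A
        Binary matrix of shape ``(nd, nm)``; entries are 0 or 1.
    """

    disease_ids: tuple[str, ...]
    microbe_ids: tuple[str, ...]
    A: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        object.__setattr__(self, "microbe_ids", tuple(self.microbe_ids))
        A = np.asarray(self.A)
        if A.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("association matrix must contain only 0/1 entries")
        A = A.astype(np.int8)
        A.setflags(write=False)
        object.__setattr__(self, "A", A)
        nd, nm = A.shape
        if nd < 1 or nm < 1:
            raise ValueError("dataset needs at least one disease and one microbe")
        if len(self.disease_ids) != nd or len(self.microbe_ids) != nm:
            raise ValueError("label count does not match matrix shape")
        if len(set(self.disease_ids)) != nd:
            raise ValueError("duplicate disease identifiers")
        if len(set(self.microbe_ids)) != nm:
            raise ValueError("duplicate microbe identifiers")

    @property
    def nd(self) -> int:
        return self.A.shape[0]

    @property
    def nm(self) -> int:
        return self.A.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def positives(self) -> list[tuple[int, int]]:
        """Known-association index pairs ``(row, col)`` in row-major order."""
        rows, cols = np.nonzero(self.A)
        return list(zip(rows.tolist(), cols.tolist()))

    def with_matrix(self, A: np.ndarray) -> "AssociationDataset":
        """Same labels, different (equally shaped) matrix."""
        return AssociationDataset(self.disease_ids, self.microbe_ids, A)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationDataset):
            return NotImplemented
        return (
            self.disease_ids == other.disease_ids
            and self.microbe_ids == other.microbe_ids
            and np.array_equal(self.A, other.A)
        )


def _ensure_text(stream: IO[str] | str) -> IO[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def read_pair_list(
    stream: IO[str] | str,
    delimiter: str = "\t",
    header: bool = False,
) -> AssociationDataset:
    """Read a (disease, microbe) pair list into a dataset.

    Each non-empty row must hold at least two non-empty fields: disease ID and
    microbe ID.  Exact-duplicate pairs (after whitespace trimming) collapse to
    a single matrix entry; the number removed is logged.  Row and column order
    is first-appearance order, so the result is deterministic.
    """
    handle = _ensure_text(stream)
    diseases: dict[str, int] = {}
    microbes: dict[str, int] = {}
    pairs: dict[tuple[str, str], None] = {}
    n_rows = 0
    for lineno, raw in enumerate(handle, start=1):
        if header and lineno == 1:
            continue
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(delimiter)]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(
                f"malformed pair-list row at line {lineno}: need two non-empty "
                f"fields, got {line!r}"
            )
        d, m = fields[0], fields[1]
        n_rows += 1
        diseases.setdefault(d, len(diseases))
        microbes.setdefault(m, len(microbes))
        pairs.setdefault((d, m))
    if n_rows == 0:
        raise ValueError("no associations in input")
    A = np.zeros((len(diseases), len(microbes)), dtype=np.int8)
    for d, m in pairs:
        A[diseases[d], microbes[m]] = 1
    logger.info(
        "read %d association rows, %d unique (%d duplicates removed): %d diseases x %d microbes",
        n_rows, len(pairs), n_rows - len(pairs), len(diseases), len(microbes),
    )
    return AssociationDataset(tuple(diseases), tuple(microbes), A)


def read_dense_matrix(stream: IO[str] | str, delimiter: str = ",") -> AssociationDataset:
    """Read a dense labeled 0/1 matrix (first row microbe IDs, first column disease IDs)."""
    handle = _ensure_text(stream)
    rows = [row for row in csv.reader(handle, delimiter=delimiter) if row]
    if len(rows) < 2:
        raise ValueError("dense matrix needs a header row and at least one body row")
    microbe_ids = [c.strip() for c in rows[0][1:]]
    if not microbe_ids:
        raise ValueError("dense matrix header holds no microbe identifiers")
    disease_ids: list[str] = []
    body = np.zeros((len(rows) - 1, len(microbe_ids)), dtype=np.int8)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(microbe_ids) + 1:
            raise ValueError(
                f"ragged row for disease {row[0]!r}: expected "
                f"{len(microbe_ids) + 1} cells, got {len(row)}"
            )
        disease_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            value = cell.strip()
            if value not in ("0", "1"):
                raise ValueError(
                    f"non-binary cell {value!r} at disease {row[0].strip()!r}, "
                    f"microbe {microbe_ids[j]!r}"
                )
            body[i, j] = int(value)
    return AssociationDataset(tuple(disease_ids), tuple(microbe_ids), body)


def write_pair_list(dataset: AssociationDataset, stream: IO[str], delimiter: str = "\t") -> int:
    """Write the known associations as a pair list; returns the row count."""
    n = 0
    for i, j in dataset.positives():
        stream.write(f"{dataset.disease_ids[i]}{delimiter}{dataset.microbe_ids[j]}\n")
        n += 1
    return n


def write_dense_matrix(dataset: AssociationDataset, stream: IO[str], delimiter: str = ",") -> None:
    """Write the dense labeled matrix; round-trips through :func:`read_dense_matrix`."""
    stream.write(delimiter.join(["", *dataset.microbe_ids]) + "\n")
    for i, d in enumerate(dataset.disease_ids):
        cells = (str(int(v)) for v in dataset.A[i])
        stream.write(delimiter.join([d, *cells]) + "\n")


def write_ranked_scores(
    scores: np.ndarray,
    dataset: AssociationDataset,
    stream: IO[str],
    mask_known: bool = False,
    top_n: int | None = None,
) -> int:
    """Write ``rank<TAB>disease<TAB>microbe<TAB>score`` rows, best first.

    Ties share a rank (competition ranking) and are ordered secondarily by
    microbe then disease identifier so output is deterministic.  With
    ``mask_known`` the pairs already present in the training matrix are
    dropped: only novel candidates are ranked.
    """
    values = np.asarray(scores, dtype=float)
    if values.shape != dataset.A.shape:
        raise ValueError(
            f"score shape {values.shape} does not match dataset shape {dataset.A.shape}"
        )
    entries: list[tuple[float, str, str]] = []
    for i in range(dataset.nd):
        for j in range(dataset.nm):
            if mask_known and dataset.A[i, j] == 1:
                continue
            entries.append((values[i, j], dataset.disease_ids[i], dataset.microbe_ids[j]))
    entries.sort(key=lambda e: (-e[0], e[2], e[1]))
    if top_n is not None:
        entries = entries[:top_n]
    all_scores = np.array([e[0] for e in entries])
    n = 0
    for score, disease, microbe in entries:
        rank = int(np.sum(all_scores > score)) + 1  # competition ranking
        stream.write(f"{rank}\t{disease}\t{microbe}\t{score:.6g}\n")
        n += 1
    return n
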