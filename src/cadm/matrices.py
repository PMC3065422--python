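"""Distance-matrix containers.

A :class:`DistanceMatrix` is a square, symmetric, zero-diagonal matrix of
non-negative pairwise distances over a set of labelled taxa. A
:class:`DistanceMatrixSet` is an ordered collection of such matrices over the
*same* taxa, stored in one canonical (sorted-label) order so that row/column
``i`` refers to the same taxon in every member — the input object of the
congruence test.

The plain-text interchange format is PHYLIP-flavoured: a first line with the
taxon count ``m``, then ``m`` whitespace-delimited rows ``label d1 ... dm``
(square) or ``label d1 ... d(i-1)`` (lower triangle); both dialects are
auto-detected on read.
"""

from __future__ import annotations

import io
from collections.abc import Sequence
from pathlib import Path

import numpy as np

__all__ = [
    "DistanceMatrix",
    "DistanceMatrixSet",
    "read_distance_matrix",
    "write_distance_matrix",
]

#: Absolute tolerance for declaring a matrix symmetric.
SYMMETRY_TOL = 1e-9

#: Smallest taxon set accepted (below this the test is degenerate).
MIN_TAXA = 4


class DistanceMatrix:
    """Square symmetric distance matrix with taxon labels.

    Parameters
    ----------
    values : (m, m) array_like
        Pairwise distances; must be symmetric within ``1e-9``, have an exactly
        zero diagonal after validation, and contain only finite, non-negative
        entries.
    labels : sequence of str
        One taxon identifier per row, unique. Rows/columns are reordered into
        canonical sorted-label order on construction.
    """

    __slots__ = ("labels", "values")

    def __init__(self, values, labels: Sequence[str]):
        values = np.asarray(values, dtype=float)
        labels = [str(x) for x in labels]
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"distance matrix must be square, got shape {values.shape}")
        m = values.shape[0]
        if len(labels) != m:
            raise ValueError(f"{len(labels)} labels for a {m}x{m} matrix")
        if len(set(labels)) != m:
            raise ValueError("duplicate taxon labels")
        if m < MIN_TAXA:
            raise ValueError(f"need at least {MIN_TAXA} taxa, got {m}")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite distances")
        asym = np.max(np.abs(values - values.T)) if m else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix not symmetric: max |d_ij - d_ji| = {asym:g}")
        if np.any(np.abs(np.diag(values)) > SYMMETRY_TOL):
            raise ValueError("diagonal must be zero")
        if np.any(values < -SYMMETRY_TOL):
            raise ValueError("negative distances")
        # canonicalize: symmetrize exactly, zero the diagonal, sort labels
        values = np.clip((values + values.T) / 2.0, 0.0, None)
        np.fill_diagonal(values, 0.0)
        order = np.argsort(np.asarray(labels, dtype=object))
        self.labels: tuple[str, ...] = tuple(labels[i] for i in order)
        self.values: np.ndarray = values[np.ix_(order, order)]
        self.values.flags.writeable = False

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_distances(self) -> int:
        """Number of unfolded pairwise distances, m(m-1)/2."""
        m = self.n_taxa
        return m * (m - 1) // 2

    def condensed(self) -> np.ndarray:
        """Upper off-diagonal distances, row-major over i < j (canonical order)."""
        iu, ju = np.triu_indices(self.n_taxa, k=1)
        return self.values[iu, ju]

    def permuted(self, perm: Sequence[int]) -> "DistanceMatrix":
        """Relabel taxa: taxon at position ``i`` takes the label previously at
        ``perm[i]`` (rows and columns permuted simultaneously)."""
        perm = np.asarray(perm)
        if sorted(perm.tolist()) != list(range(self.n_taxa)):
            raise ValueError("not a permutation of 0..m-1")
        vals = self.values[np.ix_(perm, perm)]
        return DistanceMatrix(vals, self.labels)

    def __repr__(self) -> str:
        return f"DistanceMatrix({self.n_taxa} taxa)"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DistanceMatrix)
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )


class DistanceMatrixSet:
    """Ordered collection of distance matrices over one shared taxon set."""

    __slots__ = ("matrices", "names")

    def __init__(self, matrices: Sequence[DistanceMatrix], names: Sequence[str] | None = None):
        matrices = list(matrices)
        if len(matrices) < 2:
            raise ValueError("need at least 2 matrices")
        ref = matrices[0].labels
        for k, dm in enumerate(matrices[1:], start=2):
            if dm.labels != ref:
                missing = set(ref) ^ set(dm.labels)
                if missing:
                    raise ValueError(
                        f"matrix {k} has a different taxon set; symmetric difference: "
                        f"{sorted(missing)}"
                    )
                raise ValueError(f"matrix {k} label order mismatch")  # pragma: no cover
        if names is None:
            names = [f"matrix_{k}" for k in range(1, len(matrices) + 1)]
        if len(names) != len(matrices):
            raise ValueError("one name per matrix required")
        self.matrices: tuple[DistanceMatrix, ...] = tuple(matrices)
        self.names: tuple[str, ...] = tuple(names)

    @property
    def n_matrices(self) -> int:
        return len(self.matrices)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.matrices[0].labels

    @property
    def n_taxa(self) -> int:
        return self.matrices[0].n_taxa

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)

    def __getitem__(self, k) -> DistanceMatrix:
        return self.matrices[k]

    def __repr__(self) -> str:
        return f"DistanceMatrixSet(p={self.n_matrices}, m={self.n_taxa} taxa)"


def read_distance_matrix(source) -> DistanceMatrix:
    """Read a distance matrix from a path, file object or string.

    Accepts the square and the lower-triangular dialect; which one is present
    is detected from the number of values on each row.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if isinstance(source, Path) or "\n" not in text:
            try:
                if Path(text).exists():
                    text = Path(text).read_text()
            except OSError:
                pass
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty distance-matrix file")
    try:
        m = int(lines[0].split()[0])
    except ValueError as exc:
        raise ValueError("first line must contain the taxon count") from exc
    if len(lines) - 1 < m:
        raise ValueError(f"expected {m} taxon rows, found {len(lines) - 1}")
    labels: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1 : m + 1]:
        parts = ln.split()
        labels.append(parts[0])
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"non-numeric distance in row {parts[0]!r}") from exc
    counts = [len(r) for r in rows]
    if counts == [m] * m:
        values = np.array(rows)
    elif counts == list(range(m)):
        values = np.zeros((m, m))
        for i, r in enumerate(rows):
            values[i, :i] = r
            values[:i, i] = r
    else:
        raise ValueError(
            "rows are neither square (m values each) nor lower-triangular "
            f"(0..m-1 values); got row lengths {counts}"
        )
    return DistanceMatrix(values, labels)


def write_distance_matrix(dm: DistanceMatrix, target=None, *, triangular: bool = False) -> str:
    """Serialize to the plain-text format; returns the text, optionally writing
    it to ``target`` (path or file object)."""
    buf = io.StringIO()
    buf.write(f"{dm.n_taxa}\n")
    width = max(len(s) for s in dm.labels)
    for i, lab in enumerate(dm.labels):
        stop = i if triangular else dm.n_taxa
        row = " ".join(format(v, ".17g") for v in dm.values[i, :stop])
        buf.write(f"{lab:<{width}} {row}".rstrip() + "\n")
    text = buf.getvalue()
    if target is not None:
        if hasattr(target, "write"):
            target.write(text)
        else:
            Path(target).write_text(text)
    return text
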