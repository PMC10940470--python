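"""Edge-list I/O and labeled pair-dataset assembly.

The central object is the binary association matrix ``Y`` (lncRNAs in rows,
diseases in columns) built from a two-column edge list.  Training data for
the classifiers are (lncRNA, disease) pairs: every observed association is a
positive, and negatives are drawn at random from the unobserved cells
(presumed-negative sampling, the standard choice for positive-unlabeled
association data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "AssociationMatrix",
    "LabeledDataset",
    "load_association_edges",
    "write_association_edges",
    "assemble_dataset",
]

_HEADER_HINTS = ("lnc", "disease", "dis_", "rna")


@dataclass
class AssociationMatrix:
    """Binary lncRNA-disease incidence matrix with stable identifier order.

    Attributes
    ----------
    lnc_ids : list of str
        Unique lncRNA identifiers, one per row, in first-appearance order.
    dis_ids : list of str
        Unique disease identifiers, one per column, in first-appearance order.
    Y : ndarray of shape (n, m)
        Entry ``Y[i, j]`` is 1 if lncRNA ``i`` is associated with disease
        ``j``, else 0.
    """

    lnc_ids: list[str]
    dis_ids: list[str]
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        if self.Y.ndim != 2:
            raise ValueError("Y must be a 2-D matrix")
        n, m = self.Y.shape
        if n < 1 or m < 1:
            raise ValueError("association matrix must be at least 1x1")
        if len(self.lnc_ids) != n or len(self.dis_ids) != m:
            raise ValueError("identifier lists must match matrix shape")
        if len(set(self.lnc_ids)) != n or len(set(self.dis_ids)) != m:
            raise ValueError("identifiers must be unique within each axis")
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        if not self.Y.any():
            raise ValueError("association matrix contains no associations")
        self.Y = self.Y.astype(np.int8)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def m(self) -> int:
        return self.Y.shape[1]

    def positive_pairs(self) -> np.ndarray:
        """Row-major (row, col) indices of all observed associations."""
        return np.argwhere(self.Y == 1)

    def negative_pairs(self) -> np.ndarray:
        """Row-major (row, col) indices of all unobserved cells."""
        return np.argwhere(self.Y == 0)


@dataclass
class LabeledDataset:
    """Pair feature matrix with binary labels and pair provenance.

    ``X`` has one row per (lncRNA, disease) pair; the feature width ``d``
    splits as ``d = a + b`` into the lncRNA and disease halves.
    """

    X: np.ndarray
    y: np.ndarray
    pairs: np.ndarray  # (p, 2) int array of (row, col)
    a: int = field(default=0)
    b: int = field(default=0)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int8)
        self.pairs = np.asarray(self.pairs, dtype=int)
        p = self.X.shape[0]
        if not (len(self.y) == p and len(self.pairs) == p):
            raise ValueError("X, y and pairs must have equal length")
        if len({tuple(pr) for pr in self.pairs.tolist()}) != p:
            raise ValueError("pairs must be unique")
        if self.a == 0 and self.b == 0:
            self.a = self.X.shape[1] // 2
            self.b = self.X.shape[1] - self.a
        if self.a + self.b != self.X.shape[1]:
            raise ValueError("a + b must equal the feature width d")

    @property
    def p(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_arrays(cls, X, y) -> "LabeledDataset":
        """Build a dataset from bare arrays, inventing pair provenance."""
        X = np.asarray(X, dtype=float)
        pairs = np.column_stack([np.arange(len(X)), np.zeros(len(X), int)])
        return cls(X=X, y=np.asarray(y), pairs=pairs)


def _looks_like_header(fields: Sequence[str]) -> bool:
    joined = " ".join(fields[:2]).lower()
    return any(h in joined for h in _HEADER_HINTS) and not any(
        c.isdigit() for c in joined
    )


def load_association_edges(
    path: str | Path, delimiter: str = "\t", header: str = "auto"
) -> AssociationMatrix:
    """Read a two-column (lncRNA_id, disease_id) edge list into a matrix.

    Rows and columns are ordered by first appearance in the file.  Lines
    starting with ``#`` are comments; duplicate edges collapse to a single
    association with a warning.

    Parameters
    ----------
    path : path-like
        UTF-8 text file, one association per line.
    delimiter : str
        Field separator (tab by default; pass ``","`` for CSV).
    header : {"auto", "none", "present"}
        Whether the first non-comment line is a column header.  ``"auto"``
        skips it when the first two fields look like column names.
    """
    path = Path(path)
    lnc_ids: list[str] = []
    dis_ids: list[str] = []
    lnc_index: dict[str, int] = {}
    dis_index: dict[str, int] = {}
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    n_dup = 0
    first_data_line = True

    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [f.strip() for f in line.split(delimiter)]
            if first_data_line:
                first_data_line = False
                if header == "present" or (
                    header == "auto" and _looks_like_header(parts)
                ):
                    continue
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}: malformed line {lineno}: expected at least two "
                    f"{delimiter!r}-delimited fields"
                )
            lnc, dis = parts[0], parts[1]
            if lnc not in lnc_index:
                lnc_index[lnc] = len(lnc_ids)
                lnc_ids.append(lnc)
            if dis not in dis_index:
                dis_index[dis] = len(dis_ids)
                dis_ids.append(dis)
            edge = (lnc_index[lnc], dis_index[dis])
            if edge in seen:
                n_dup += 1
                continue
            seen.add(edge)
            edges.append(edge)

    if not edges:
        raise ValueError(f"{path}: no associations found")
    if n_dup:
        warnings.warn(
            f"{path}: {n_dup} duplicate edge(s) collapsed", stacklevel=2
        )

    Y = np.zeros((len(lnc_ids), len(dis_ids)), dtype=np.int8)
    rows, cols = zip(*edges)
    Y[list(rows), list(cols)] = 1
    return AssociationMatrix(lnc_ids=lnc_ids, dis_ids=dis_ids, Y=Y)


def write_association_edges(
    am: AssociationMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write the matrix back to an edge list that round-trips exactly.

    Edges are emitted in an order that re-introduces lncRNAs and diseases in
    the matrix's identifier order, so ``load_association_edges`` on the
    output reproduces the identical matrix and orderings.
    """
    n, m = am.Y.shape
    remaining = {tuple(e) for e in np.argwhere(am.Y == 1).tolist()}
    out: list[tuple[int, int]] = []
    lnc_in = np.zeros(n, bool)
    dis_in = np.zeros(m, bool)
    next_l, next_d = 0, 0

    def _advance():
        nonlocal next_l, next_d
        while next_l < n and lnc_in[next_l]:
            next_l += 1
        while next_d < m and dis_in[next_d]:
            next_d += 1

    while remaining:
        _advance()
        # flush edges between already-introduced entities first (always safe)
        safe = sorted(e for e in remaining if lnc_in[e[0]] and dis_in[e[1]])
        if safe:
            for e in safe:
                remaining.discard(e)
            out.extend(safe)
            continue
        # introduce the next entity in order via an edge touching it
        cand = None
        if next_l < n:
            opts = sorted(
                e for e in remaining if e[0] == next_l and dis_in[e[1]]
            )
            if opts:
                cand = opts[0]
        if cand is None and next_d < m:
            opts = sorted(
                e for e in remaining if e[1] == next_d and lnc_in[e[0]]
            )
            if opts:
                cand = opts[0]
        if cand is None and next_l < n and next_d < m:
            if (next_l, next_d) in remaining:
                cand = (next_l, next_d)
        if cand is None:
            # orderings not realizable from any edge sequence; fall back
            cand = sorted(remaining)[0]
        remaining.discard(cand)
        out.append(cand)
        lnc_in[cand[0]] = True
        dis_in[cand[1]] = True

    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# lncRNA_id{delimiter}disease_id\n")
        for i, j in out:
            fh.write(f"{am.lnc_ids[i]}{delimiter}{am.dis_ids[j]}\n")


FeatureProvider = Callable[[np.ndarray], np.ndarray]


def _pair_matrix(features, pairs: np.ndarray) -> np.ndarray:
    if hasattr(features, "pair_matrix"):
        return features.pair_matrix(pairs)
    return np.asarray([features(int(r), int(c)) for r, c in pairs], dtype=float)


def assemble_dataset(
    am: AssociationMatrix,
    features,
    mode: str = "balanced",
    neg_ratio: float = 1.0,
    seed: int = 0,
) -> LabeledDataset:
    """Assemble a labeled pair dataset from the association matrix.

    Parameters
    ----------
    am : AssociationMatrix
    features
        Either a ``PairFeaturizer`` (anything with a ``pair_matrix(pairs)``
        method) or a callable ``f(row, col) -> vector``.
    mode : {"balanced", "all_pairs"}
        ``all_pairs`` emits one sample per matrix cell (p = n*m).
        ``balanced`` keeps every positive and samples
        ``floor(neg_ratio * #positives)`` unobserved cells uniformly without
        replacement as negatives.
    neg_ratio : float
        Negatives per positive under ``balanced``; must be > 0.
    seed : int
        Drives both negative sampling and the final deterministic shuffle.
    """
    rng = np.random.default_rng(seed)
    pos = am.positive_pairs()
    if mode == "all_pairs":
        rows, cols = np.unravel_index(np.arange(am.n * am.m), (am.n, am.m))
        pairs = np.column_stack([rows, cols])
    elif mode == "balanced":
        if neg_ratio <= 0:
            raise ValueError("neg_ratio must be positive")
        zeros = am.negative_pairs()
        k = int(np.floor(neg_ratio * len(pos)))
        if k > len(zeros):
            raise ValueError(
                f"requested {k} negatives but only {len(zeros)} zero cells"
            )
        idx = rng.choice(len(zeros), size=k, replace=False)
        pairs = np.vstack([pos, zeros[idx]])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    order = rng.permutation(len(pairs))
    pairs = pairs[order]
    y = am.Y[pairs[:, 0], pairs[:, 1]]
    X = _pair_matrix(features, pairs)
    return LabeledDataset(X=X, y=y, pairs=pairs)


def write_dataset_scores(
    am: AssociationMatrix,
    pairs: np.ndarray,
    labels: np.ndarray,
    path: str | Path,
    scores: np.ndarray | None = None,
    delimiter: str = "\t",
) -> None:
    """Export pairs (and optional scores) as TSV [lnc, disease, label, score]."""
    with Path(path).open("w", encoding="utf-8") as fh:
        head = ["lncRNA_id", "disease_id", "label"]
        if scores is not None:
            head.append("score")
        fh.write("# " + delimiter.join(head) + "\n")
        for k, (i, j) in enumerate(np.asarray(pairs, int)):
            row = [am.lnc_ids[i], am.dis_ids[j], str(int(labels[k]))]
            if scores is not None:
                row.append(f"{scores[k]:.6g}")
            fh.write(delimiter.join(row) + "\n")
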