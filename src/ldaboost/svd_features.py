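"""Truncated-SVD pair features.

The association matrix ``Y`` is factorized as ``Y = U S V^T`` and truncated
to the ``e`` largest singular values.  Row ``i`` of the left block then
embeds lncRNA ``i`` and row ``j`` of the right block embeds disease ``j``;
a pair is represented by the concatenation of the two embeddings, a vector
of width ``d = 2e`` (default e = 32, d = 64).

With ``sqrt_sigma`` scaling the singular values are split symmetrically
between the two factors, so the inner product of a lncRNA and a disease
feature approximates the corresponding matrix entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SVDFactorization",
    "svd_factorize",
    "entity_features",
    "pair_features",
    "PairFeaturizer",
]


@dataclass
class SVDFactorization:
    """Rank-``e`` truncated SVD of an association matrix.

    ``U_e`` (n x e) and ``V_e`` (m x e) have orthonormal columns; ``sigma``
    is non-increasing.  Column signs are fixed so the largest-magnitude entry
    of each ``U_e`` column is positive, making the factorization
    bit-reproducible.
    """

    U_e: np.ndarray
    sigma: np.ndarray
    V_e: np.ndarray
    e: int

    @property
    def n(self) -> int:
        return self.U_e.shape[0]

    @property
    def m(self) -> int:
        return self.V_e.shape[0]

    def reconstruction(self) -> np.ndarray:
        """Best rank-``e`` approximation of the input matrix."""
        return (self.U_e * self.sigma) @ self.V_e.T


def svd_factorize(am_or_matrix, e: int) -> SVDFactorization:
    """Truncated SVD of the association matrix at rank ``e``.

    Parameters
    ----------
    am_or_matrix : AssociationMatrix or ndarray
        Binary (or masked) association matrix.
    e : int
        Truncation rank, ``1 <= e <= min(n, m)``.  If the matrix has rank
        below ``e`` the trailing singular values are zero and the
        corresponding features vanish under ``sqrt_sigma`` scaling, keeping
        the feature width fixed.

    Raises
    ------
    ValueError
        If ``e`` is out of range or the matrix is all-zero.
    """
    Y = np.asarray(getattr(am_or_matrix, "Y", am_or_matrix), dtype=float)
    n, m = Y.shape
    if not 1 <= e <= min(n, m):
        raise ValueError(f"e={e} out of range [1, {min(n, m)}]")
    if not Y.any():
        raise ValueError("all-zero matrix has no informative factors")

    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    U_e = U[:, :e].copy()
    sigma = s[:e].copy()
    V_e = Vt[:e].T.copy()

    # sign convention: largest-|entry| of each U column positive (first on tie)
    for k in range(e):
        idx = int(np.argmax(np.abs(U_e[:, k])))
        if U_e[idx, k] < 0:
            U_e[:, k] *= -1
            V_e[:, k] *= -1
    return SVDFactorization(U_e=U_e, sigma=sigma, V_e=V_e, e=e)


def _scaled_block(f: SVDFactorization, axis: str, scaling: str) -> np.ndarray:
    if axis == "lncrna":
        block = f.U_e
    elif axis == "disease":
        block = f.V_e
    else:
        raise ValueError(f"unknown axis {axis!r}")
    if scaling == "raw":
        return block
    if scaling == "sqrt_sigma":
        return block * np.sqrt(f.sigma)
    raise ValueError(f"unknown scaling {scaling!r}")


def entity_features(
    f: SVDFactorization, axis: str, index: int, scaling: str = "sqrt_sigma"
) -> np.ndarray:
    """Length-``e`` embedding of one lncRNA or disease.

    ``raw`` returns the row of the singular-vector block; ``sqrt_sigma``
    multiplies it elementwise by ``sqrt(sigma)`` so that
    ``dot(lnc_i, dis_j) ~ y_ij``.
    """
    block = _scaled_block(f, axis, scaling)
    if not 0 <= index < block.shape[0]:
        raise IndexError(f"{axis} index {index} out of bounds")
    return block[index].copy()


def pair_features(
    f: SVDFactorization, row: int, col: int, scaling: str = "sqrt_sigma"
) -> np.ndarray:
    """Concatenated [lncRNA || disease] pair feature of width ``d = 2e``."""
    return np.concatenate(
        [
            entity_features(f, "lncrna", row, scaling),
            entity_features(f, "disease", col, scaling),
        ]
    )


class PairFeaturizer:
    """Vectorized pair-feature provider over a fixed factorization.

    Precomputes the scaled entity blocks once; ``pair_matrix`` then gathers
    features for an array of (row, col) pairs in one shot.
    """

    def __init__(self, f: SVDFactorization, scaling: str = "sqrt_sigma"):
        self.factorization = f
        self.scaling = scaling
        self._L = _scaled_block(f, "lncrna", scaling)
        self._D = _scaled_block(f, "disease", scaling)

    @property
    def d(self) -> int:
        return self._L.shape[1] + self._D.shape[1]

    def __call__(self, row: int, col: int) -> np.ndarray:
        return np.concatenate([self._L[row], self._D[col]])

    def pair_matrix(self, pairs: np.ndarray) -> np.ndarray:
        pairs = np.asarray(pairs, dtype=int)
        return np.hstack([self._L[pairs[:, 0]], self._D[pairs[:, 1]]])


def export_entity_features(
    f: SVDFactorization,
    axis: str,
    ids: list[str],
    path: str | Path,
    scaling: str = "sqrt_sigma",
    delimiter: str = "\t",
) -> None:
    """Write one entity axis' feature matrix as TSV with an identifier column."""
    block = _scaled_block(f, axis, scaling)
    with Path(path).open("w", encoding="utf-8") as fh:
        cols = delimiter.join(f"f{k}" for k in range(block.shape[1]))
        fh.write(f"# id{delimiter}{cols}\n")
        for name, row in zip(ids, block):
            vals = delimiter.join(f"{v:.8g}" for v in row)
            fh.write(f"{name}{delimiter}{vals}\n")
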