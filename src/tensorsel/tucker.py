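"""Mode-n unfolding and economy higher-order SVD (Tucker decomposition).

The HOSVD factor for mode *m* holds the left singular vectors of the
mode-*m* unfolding, ordered by decreasing singular value; the core is the
tensor contracted with the factor transposes on every mode.  Conventions
fixed here and used throughout the package:

* unfolding column order: the remaining modes vary with the lower-numbered
  mode fastest (Fortran order over the remaining axes), so
  ``fold(unfold(x, m), m, x.shape) == x`` bit-for-bit;
* sign canonicalization: each factor column is flipped so its
  largest-magnitude entry is positive (the core absorbs the flip);
* economy ranks: mode *m* keeps ``min(dim_m, prod(other dims))`` columns —
  the remaining columns of a full square factor pair with an all-zero core
  and carry no information.
"""

from __future__ import annotations

from typing import Optional, Sequence

import h5py
import numpy as np

from .datatypes import OmicsTensor, TuckerModel

__all__ = [
    "unfold",
    "fold",
    "hosvd",
    "reconstruct",
    "mode_multiply",
    "economy_ranks",
    "save_model",
    "load_model",
    "HOSVD",
]

# Above this row/column ratio the mode factor is computed from the Gram
# matrix of the smaller side (eigendecomposition of A^T A) instead of a
# direct SVD of the tall unfolding.
_GRAM_RATIO = 10


def _values(tensor) -> np.ndarray:
    x = tensor.values if isinstance(tensor, OmicsTensor) else np.asarray(tensor, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"expected a 3-mode tensor, got ndim={x.ndim}")
    if not np.all(np.isfinite(x)):
        raise ValueError("tensor contains non-finite values")
    return x


def unfold(tensor, mode: int) -> np.ndarray:
    """Matricize a 3-mode tensor along ``mode`` (1, 2 or 3).

    Returns an array of shape ``(dim_mode, prod(other dims))``; among the
    remaining modes the lower-numbered one varies fastest along columns.
    """
    x = _values(tensor)
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode!r}")
    a = np.moveaxis(x, mode - 1, 0)
    return a.reshape(a.shape[0], -1, order="F")


def fold(matrix: np.ndarray, mode: int, shape: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given 3-mode ``shape``."""
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode!r}")
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError("shape must have three entries")
    rest = [shape[m] for m in range(3) if m != mode - 1]
    a = np.asarray(matrix).reshape([shape[mode - 1]] + rest, order="F")
    return np.moveaxis(a, 0, mode - 1)


def mode_multiply(x: np.ndarray, mat: np.ndarray, mode: int) -> np.ndarray:
    """Multiply ``mat`` onto ``x`` along ``mode``: new dim_mode = mat.shape[0]."""
    x = np.asarray(x, dtype=float)
    new_shape = list(x.shape)
    new_shape[mode - 1] = mat.shape[0]
    return fold(mat @ unfold(x, mode), mode, new_shape)


def economy_ranks(shape: Sequence[int]) -> tuple[int, int, int]:
    """Maximal informative rank per mode: min(dim_m, prod(other dims))."""
    n, m, k = shape
    return (min(n, m * k), min(m, n * k), min(k, n * m))


def _complete_orthonormal(u: np.ndarray, rank: int) -> np.ndarray:
    """Deterministically extend ``u`` (orthonormal columns) to ``rank`` columns."""
    n, r = u.shape
    if r >= rank:
        return u[:, :rank]
    basis = [u]
    have = r
    for j in range(n):
        if have >= rank:
            break
        e = np.zeros(n)
        e[j] = 1.0
        for b in basis:
            e -= b @ (b.T @ e)
        nrm = np.linalg.norm(e)
        if nrm > 1e-8:
            basis.append((e / nrm)[:, None])
            have += 1
    return np.hstack(basis)[:, :rank]


def _mode_factor(a: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Leading ``rank`` left singular vectors (and values) of unfolding ``a``."""
    n, p = a.shape
    if n > _GRAM_RATIO * p:
        # Gram trick: eigendecompose the small p x p product, recover U = A V / s.
        g = a.T @ a
        w, v = np.linalg.eigh(g)
        order = np.argsort(w, kind="stable")[::-1]
        w = np.clip(w[order], 0.0, None)
        v = v[:, order]
        s = np.sqrt(w)
        tol = max(n, p) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        keep = s > tol
        u = np.zeros((n, int(keep.sum())))
        if keep.any():
            u = a @ (v[:, keep] / s[keep])
        u = _complete_orthonormal(u, rank)
        return u, s[:rank]
    u, s, _ = np.linalg.svd(a, full_matrices=False)
    return u[:, :rank], s[:rank]


def _canonicalize_sign(u: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|entry| element is positive."""
    u = u.copy()
    for c in range(u.shape[1]):
        col = u[:, c]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            u[:, c] = -col
    return u


def hosvd(tensor, ranks: Optional[Sequence[int]] = None) -> TuckerModel:
    """Economy HOSVD of a 3-mode tensor.

    Parameters
    ----------
    tensor : 3-mode ndarray or :class:`OmicsTensor`.
    ranks : optional (R1, R2, R3); defaults to the economy ranks.  Each
        requested rank must not exceed its economy bound.

    Returns
    -------
    TuckerModel with sign-canonicalized orthonormal factors and the core
    ``G = x ×1 U1^T ×2 U2^T ×3 U3^T``.
    """
    x = _values(tensor)
    bounds = economy_ranks(x.shape)
    if ranks is None:
        ranks = bounds
    else:
        ranks = tuple(int(r) for r in ranks)
        if len(ranks) != 3:
            raise ValueError("ranks must have three entries")
        for m, (r, b) in enumerate(zip(ranks, bounds)):
            if not 1 <= r <= b:
                raise ValueError(
                    f"rank {r} for mode {m + 1} outside the economy bound [1, {b}]"
                )
    factors = []
    for mode in (1, 2, 3):
        u, _ = _mode_factor(unfold(x, mode), ranks[mode - 1])
        factors.append(_canonicalize_sign(u))
    core = x
    for mode, u in zip((1, 2, 3), factors):
        core = mode_multiply(core, u.T, mode)
    return TuckerModel(core=core, factors=tuple(factors))


def reconstruct(model: TuckerModel) -> np.ndarray:
    """Evaluate the Tucker sum ``sum_l G(l1,l2,l3) u1 u2 u3`` as a dense tensor."""
    x = model.core
    for mode, u in zip((1, 2, 3), model.factors):
        x = mode_multiply(x, u, mode)
    return x


def save_model(model: TuckerModel, path, ids: Optional[dict] = None) -> None:
    """Serialize a TuckerModel (and optional per-mode id lists) to HDF5."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("core", data=model.core)
        for m, f in enumerate(model.factors, start=1):
            h5.create_dataset(f"factor{m}", data=f)
        if ids:
            grp = h5.create_group("ids")
            for key, vals in ids.items():
                grp.create_dataset(key, data=np.array([str(v) for v in vals], dtype="S"))


def load_model(path) -> tuple[TuckerModel, dict]:
    with h5py.File(path, "r") as h5:
        core = h5["core"][()]
        factors = tuple(h5[f"factor{m}"][()] for m in (1, 2, 3))
        ids = {}
        if "ids" in h5:
            for key in h5["ids"]:
                ids[key] = [v.decode() for v in h5["ids"][key][()]]
    return TuckerModel(core=core, factors=factors), ids


class HOSVD:
    """Higher-order SVD as a scikit-learn-style estimator.

    Parameters
    ----------
    ranks : optional (R1, R2, R3) truncation; None keeps economy ranks.

    Attributes (after :meth:`fit`)
    ------------------------------
    core_ : ndarray, the (R1, R2, R3) core tensor.
    factors_ : tuple of three orthonormal factor matrices.
    ranks_ : the realized ranks.
    """

    def __init__(self, ranks: Optional[Sequence[int]] = None):
        self.ranks = ranks

    def get_params(self, deep: bool = True) -> dict:
        return {"ranks": self.ranks}

    def set_params(self, **params) -> "HOSVD":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "HOSVD":
        model = hosvd(X, ranks=self.ranks)
        self.model_ = model
        self.core_ = model.core
        self.factors_ = model.factors
        self.ranks_ = model.ranks
        return self

    def inverse_transform(self) -> np.ndarray:
        """Reconstruct the (possibly truncated) tensor from the fitted model."""
        if not hasattr(self, "model_"):
            raise AttributeError("HOSVD instance is not fitted yet")
        return reconstruct(self.model_)
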