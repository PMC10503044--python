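"""Core data containers for tensor-based unsupervised feature extraction.

Naming follows the multilinear-algebra convention: a three-mode tensor
``x[i, j, k]`` holds the value of feature *i* for replicate/sample *j*
under condition/omics-layer *k*; singular-vector components along each
mode are numbered 1-based (``l1``, ``l2``, ``l3``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


def _as_id_list(ids: Sequence, n: int, what: str) -> list[str]:
    out = [str(x) for x in ids]
    if len(out) != n:
        raise ValueError(f"{what}: expected {n} identifiers, got {len(out)}")
    if len(set(out)) != len(out):
        raise ValueError(f"{what}: identifiers contain duplicates")
    return out


@dataclass
class SampleDesign:
    """Mapping of tensor sample modes to an experimental design.

    Parameters
    ----------
    replicate_labels : labels over the mode-2 (replicate/subject) index j.
    condition_levels : ordered labels over the mode-3 index k.  Order is
        meaningful: it defines the ordinal scale used by monotonicity
        scoring (e.g. tumor stages i < ii < iii < iv).
    """

    replicate_labels: list
    condition_levels: list

    def __post_init__(self) -> None:
        self.replicate_labels = list(self.replicate_labels)
        self.condition_levels = list(self.condition_levels)
        if len(self.condition_levels) < 1:
            raise ValueError("condition_levels must be non-empty")

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_labels)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_levels)

    def condition_codes(self) -> np.ndarray:
        """Ordinal codes 0..K-1 in the declared level order."""
        return np.arange(len(self.condition_levels), dtype=float)


@dataclass
class OmicsTensor:
    """A three-mode numeric array with per-mode identifiers.

    ``values[i, j, k]`` is the measurement of feature ``feature_ids[i]``
    for ``mode2_ids[j]`` (replicate or subject) at ``mode3_ids[k]``
    (condition, tissue or omics layer).
    """

    values: np.ndarray
    feature_ids: list
    mode2_ids: list
    mode3_ids: list
    design: Optional[SampleDesign] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be a 3-mode array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        n, m, k = self.values.shape
        self.feature_ids = _as_id_list(self.feature_ids, n, "feature_ids")
        self.mode2_ids = _as_id_list(self.mode2_ids, m, "mode2_ids")
        self.mode3_ids = _as_id_list(self.mode3_ids, k, "mode3_ids")
        if self.design is not None:
            if self.design.n_replicates != m or self.design.n_conditions != k:
                raise ValueError(
                    "design dimensions (%d replicates x %d conditions) do not match "
                    "tensor shape %s" % (self.design.n_replicates, self.design.n_conditions, (n, m, k))
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class TuckerModel:
    """Tucker/HOSVD decomposition: core tensor plus one orthonormal factor per mode.

    ``core[l1-1, l2-1, l3-1]`` weights the rank-one term
    ``u1[:, l1-1] (x) u2[:, l2-1] (x) u3[:, l3-1]``.
    """

    core: np.ndarray
    factors: tuple[np.ndarray, np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        self.core = np.asarray(self.core, dtype=float)
        self.factors = tuple(np.asarray(f, dtype=float) for f in self.factors)
        if self.core.ndim != 3 or len(self.factors) != 3:
            raise ValueError("TuckerModel requires a 3-mode core and three factors")
        for m, f in enumerate(self.factors):
            if f.ndim != 2 or f.shape[1] != self.core.shape[m]:
                raise ValueError(
                    f"factor for mode {m + 1} has shape {f.shape}, "
                    f"incompatible with core shape {self.core.shape}"
                )

    @property
    def ranks(self) -> tuple[int, int, int]:
        return self.core.shape

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(f.shape[0] for f in self.factors)


@dataclass
class NullFit:
    """Fitted Gaussian null for a vector of component scores."""

    sigma: float
    p_values: np.ndarray
    adjusted_p: np.ndarray
    selected: np.ndarray
    threshold: float
    histogram: tuple[np.ndarray, np.ndarray]  # (bin edges, counts of 1 - P)
    objective_value: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.adjusted_p = np.asarray(self.adjusted_p, dtype=float)
        self.selected = np.asarray(self.selected, dtype=bool)


@dataclass
class SelectionResult:
    """Outcome of a single-tensor feature-selection run (1-based component indices)."""

    l1: int
    l2: int
    l3: int
    constancy_scores: np.ndarray
    monotonicity_scores: np.ndarray
    core_slice: np.ndarray
    feature_table: pd.DataFrame
    null_fit: NullFit = field(repr=False, default=None)

    @property
    def selected_ids(self) -> list[str]:
        t = self.feature_table
        return list(t.loc[t["selected"], "feature_id"])


@dataclass
class MultiomicsSet:
    """K feature-by-sample matrices sharing one sample axis."""

    layers: list[np.ndarray]
    layer_names: list
    sample_ids: list
    feature_ids: list  # list of per-layer id lists

    def __post_init__(self) -> None:
        self.layers = [np.asarray(x, dtype=float) for x in self.layers]
        if not self.layers:
            raise ValueError("at least one omics layer is required")
        m = len(self.sample_ids)
        self.sample_ids = _as_id_list(self.sample_ids, m, "sample_ids")
        self.layer_names = [str(x) for x in self.layer_names]
        if len(self.layer_names) != len(self.layers):
            raise ValueError("layer_names length does not match number of layers")
        if len(self.feature_ids) != len(self.layers):
            raise ValueError("feature_ids must provide one id list per layer")
        fixed = []
        for name, x, ids in zip(self.layer_names, self.layers, self.feature_ids):
            if x.ndim != 2:
                raise ValueError(f"layer '{name}' is not a matrix")
            if x.shape[1] != m:
                raise ValueError(
                    f"layer '{name}' has {x.shape[1]} sample columns, expected {m}"
                )
            if x.shape[0] < 1:
                raise ValueError(f"layer '{name}' has no features")
            if not np.all(np.isfinite(x)):
                raise ValueError(f"layer '{name}' contains non-finite values")
            fixed.append(_as_id_list(ids, x.shape[0], f"feature_ids[{name}]"))
        self.feature_ids = fixed

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class GramTensor:
    """Sample-by-sample inner-product matrices, one symmetric PSD slice per layer."""

    values: np.ndarray  # shape (M, M, K)
    sample_ids: list
    layer_names: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("GramTensor values must have shape (M, M, K)")


@dataclass
class ProjectedScores:
    """Per-layer feature scores obtained by back-projecting a sample component."""

    scores: list[np.ndarray]
    layer_names: list

    def __getitem__(self, i: int) -> np.ndarray:
        return self.scores[i]
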