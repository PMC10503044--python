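"""Multiomics feature selection via the shared-sample Gram tensor.

K omics layers measured on the same M samples are integrated without ever
decomposing the (huge) feature axis: each layer's feature dimension is
contracted away into an M x M sample Gram matrix,

    x[j, j', k] = sum_i  x_k[i, j] * x_k[i, j'],

and HOSVD is applied to the resulting M x M x K tensor.  The sample
component that tracks the labels of interest is then back-projected into
each layer's feature space (u_feat = X_k^T-free product X_k u_sample), and
each layer's projected scores go through the SD-optimized Gaussian null
independently.  Nothing larger than max(M^2 K, max_k N_k M) entries is
materialized — that memory saving is the reason for the Gram construction.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import nullmodel
from .datatypes import GramTensor, MultiomicsSet, ProjectedScores, TuckerModel
from .tucker import hosvd

__all__ = [
    "build_gram_tensor",
    "hosvd_gram",
    "choose_label_vector",
    "project_features",
    "run_multiomics",
    "center_layers",
    "MultiomicsSelector",
]

logger = logging.getLogger(__name__)


def center_layers(omics: MultiomicsSet) -> MultiomicsSet:
    """Center every feature row across samples, layer by layer."""
    centered = [x - x.mean(axis=1, keepdims=True) for x in omics.layers]
    return MultiomicsSet(
        layers=centered,
        layer_names=list(omics.layer_names),
        sample_ids=list(omics.sample_ids),
        feature_ids=[list(ids) for ids in omics.feature_ids],
    )


def build_gram_tensor(omics: MultiomicsSet, center: bool = True) -> GramTensor:
    """Contract each layer's feature axis into a sample-by-sample Gram slice.

    With ``center=True`` (default) feature rows are mean-centered first, so
    each slice is M times the sample covariance contribution of that layer;
    uncentered Grams are dominated by mean structure.
    """
    work = center_layers(omics) if center else omics
    m = omics.n_samples
    values = np.empty((m, m, omics.n_layers))
    for k, x in enumerate(work.layers):
        slab = x.T @ x
        values[:, :, k] = 0.5 * (slab + slab.T)  # exact symmetry despite fp noise
    return GramTensor(
        values=values,
        sample_ids=list(omics.sample_ids),
        layer_names=list(omics.layer_names),
    )


def hosvd_gram(gram: GramTensor) -> TuckerModel:
    """HOSVD of the Gram tensor; mode-1 and mode-2 factors agree up to sign.

    Slice symmetry makes the mode-1 and mode-2 unfoldings transposes of one
    another, so their left singular vectors span the same subspace; this is
    checked numerically for well-separated leading components.
    """
    model = hosvd(gram.values)
    u1, u2 = model.factors[0], model.factors[1]
    s = np.linalg.norm(
        model.core.reshape(model.core.shape[0], -1), axis=1
    )  # mode-1 slice norms = mode-1 singular values
    for c in range(min(u1.shape[1], u2.shape[1])):
        gap_ok = s[c] > 0 and (c + 1 >= s.size or (s[c] - s[c + 1]) > 1e-6 * s[0]) and (
            c == 0 or (s[c - 1] - s[c]) > 1e-6 * s[0]
        )
        if gap_ok and not np.allclose(np.abs(u1[:, c]), np.abs(u2[:, c]), atol=1e-6):
            warnings.warn(
                f"mode-1/mode-2 factor mismatch at component {c + 1}; "
                "the Gram tensor slices may not be symmetric",
                stacklevel=2,
            )
    return model


def _label_codes(labels) -> tuple[np.ndarray, bool]:
    """Numeric codes for ordinal/categorical labels; True if two-class."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "ifu":
        codes = arr.astype(float)
    else:
        seen: dict = {}
        codes = np.empty(arr.size, dtype=float)
        for i, v in enumerate(arr.ravel()):
            codes[i] = seen.setdefault(v, len(seen))
    return codes, np.unique(codes).size == 2


def choose_label_vector(
    model: TuckerModel,
    labels,
    override: Optional[int] = None,
) -> tuple[int, np.ndarray]:
    """Pick the mode-1 sample component most associated with the labels.

    Association is |Spearman| for ordinal labels and the absolute
    point-biserial correlation for two-class labels.  Returns the 1-based
    component index and the per-component score vector.
    """
    u1 = model.factors[0]
    codes, two_class = _label_codes(labels)
    if codes.size != u1.shape[0]:
        raise ValueError(f"{codes.size} labels for {u1.shape[0]} samples")
    if np.unique(codes).size < 2:
        raise ValueError("labels must have at least 2 distinct values")
    scores = np.zeros(u1.shape[1])
    for c in range(u1.shape[1]):
        col = u1[:, c]
        if np.unique(col).size < 2:
            continue
        if two_class:
            scores[c] = abs(stats.pearsonr(col, codes).statistic)
        else:
            scores[c] = abs(stats.spearmanr(col, codes).statistic)
    if override is not None:
        l1 = int(override)
        if not 1 <= l1 <= u1.shape[1]:
            raise ValueError(f"override l1={l1} out of range 1..{u1.shape[1]}")
    else:
        l1 = int(np.argmax(scores)) + 1
    logger.info("label-association scores per sample component: %s",
                np.array2string(scores, precision=3))
    logger.info("chosen sample component l1=%d%s",
                l1, " (override)" if override is not None else "")
    return l1, scores


def project_features(omics: MultiomicsSet, label_vector) -> ProjectedScores:
    """Back-project a sample component into each layer's feature space: X_k @ u."""
    u = np.asarray(label_vector, dtype=float).ravel()
    if u.size != omics.n_samples:
        raise ValueError(
            f"label vector length {u.size} != number of samples {omics.n_samples}"
        )
    return ProjectedScores(
        scores=[x @ u for x in omics.layers],
        layer_names=list(omics.layer_names),
    )


def run_multiomics(
    omics: MultiomicsSet,
    labels,
    threshold: float = nullmodel.DEFAULT_THRESHOLD,
    override: Optional[int] = None,
    center: bool = True,
    **null_kwargs,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Full multiomics selection; returns per-layer feature tables and a manifest.

    The null SD is optimized per layer: projected-score scales differ by
    orders of magnitude between layers of different size, and the selection
    rule is scale-dependent within each layer.
    """
    work = center_layers(omics) if center else omics
    gram = build_gram_tensor(work, center=False)
    model = hosvd_gram(gram)
    l1, assoc = choose_label_vector(model, labels, override)
    projected = project_features(work, model.factors[0][:, l1 - 1])
    tables: dict[str, pd.DataFrame] = {}
    sigmas: dict[str, float] = {}
    for name, ids, scores in zip(omics.layer_names, omics.feature_ids, projected.scores):
        fit = nullmodel.fit_null(scores, threshold=threshold, **null_kwargs)
        tables[name] = nullmodel._feature_table(ids, scores, fit)
        sigmas[name] = fit.sigma
        logger.info("layer %s: sigma=%.6g, %d/%d features selected",
                    name, fit.sigma, int(fit.selected.sum()), len(ids))
    manifest = {
        "chosen_component": l1,
        "association_scores": assoc.tolist(),
        "sigma_per_layer": sigmas,
        "center": center,
        "threshold": threshold,
    }
    return tables, manifest


class MultiomicsSelector:
    """Sklearn-style estimator for shared-sample multiomics feature selection.

    Parameters
    ----------
    threshold : per-layer BH-adjusted P cutoff (default 0.01).
    component : fix the 1-based sample component instead of scoring labels.
    center : mean-center feature rows before the Gram contraction.

    Attributes (after :meth:`fit`)
    ------------------------------
    component_ : chosen sample component (1-based).
    tables_ : dict layer name -> feature table.
    sigmas_ : dict layer name -> optimized null SD.
    supports_ : dict layer name -> boolean mask in input feature order.
    """

    def __init__(
        self,
        threshold: float = nullmodel.DEFAULT_THRESHOLD,
        component: Optional[int] = None,
        center: bool = True,
        bins: int = nullmodel.DEFAULT_BINS,
        tail_fraction: float = nullmodel.DEFAULT_TAIL_FRACTION,
        sigma_bracket: Sequence[float] = nullmodel.DEFAULT_SIGMA_BRACKET,
    ):
        self.threshold = threshold
        self.component = component
        self.center = center
        self.bins = bins
        self.tail_fraction = tail_fraction
        self.sigma_bracket = sigma_bracket

    def get_params(self, deep: bool = True) -> dict:
        return {
            "threshold": self.threshold,
            "component": self.component,
            "center": self.center,
            "bins": self.bins,
            "tail_fraction": self.tail_fraction,
            "sigma_bracket": self.sigma_bracket,
        }

    def set_params(self, **params) -> "MultiomicsSelector":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, omics: MultiomicsSet, labels) -> "MultiomicsSelector":
        tables, manifest = run_multiomics(
            omics,
            labels,
            threshold=self.threshold,
            override=self.component,
            center=self.center,
            bins=self.bins,
            tail_fraction=self.tail_fraction,
            sigma_bracket=self.sigma_bracket,
        )
        self.tables_ = tables
        self.manifest_ = manifest
        self.component_ = manifest["chosen_component"]
        self.sigmas_ = manifest["sigma_per_layer"]
        self.supports_ = {}
        for name, ids in zip(omics.layer_names, omics.feature_ids):
            t = tables[name].set_index("feature_id")
            self.supports_[name] = t.loc[[str(i) for i in ids], "selected"].to_numpy()
        return self
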