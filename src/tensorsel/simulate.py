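"""Synthetic data with the statistical structure the method assumes.

Two generators with known ground truth:

* a replicate x condition expression tensor where a subset of features
  carries a linear trend over the ordered conditions, identical across
  replicates, on top of per-feature baselines and Gaussian noise;
* a shared-sample multiomics set where planted features in every layer
  load on one label-aligned sample factor.

Gaussian noise is the default because the selection null is Gaussian; a
log-normal count-like option exercises the pipeline off its assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datatypes import MultiomicsSet, OmicsTensor, SampleDesign

__all__ = ["SyntheticSpec", "make_deg_tensor", "make_multiomics_set", "default_labels"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic generators.

    Tensor path: ``n_features x n_replicates x n_conditions`` with
    ``n_planted`` trend-carrying features; ``effect_size`` is the per-step
    trend amplitude in units of the noise SD.  Multiomics path:
    ``layer_sizes`` feature counts over ``n_samples`` shared samples with
    ``n_levels`` ordered label classes and ``layer_planted`` signal
    features per layer (default: 10% of each layer).
    """

    n_features: int = 1000
    n_replicates: int = 9
    n_conditions: int = 4
    n_planted: int = 100
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    distribution: str = "gaussian"  # or "lognormal"
    # multiomics
    layer_sizes: Sequence[int] = (500, 300, 200)
    n_samples: int = 60
    n_levels: int = 4
    layer_planted: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if self.n_planted > self.n_features:
            raise ValueError("n_planted cannot exceed n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.distribution not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.layer_planted is not None and len(self.layer_planted) != len(self.layer_sizes):
            raise ValueError("layer_planted must match layer_sizes in length")

    def planted_per_layer(self) -> list[int]:
        if self.layer_planted is not None:
            return [int(p) for p in self.layer_planted]
        return [max(1, n // 10) for n in self.layer_sizes]


def make_deg_tensor(spec: SyntheticSpec) -> tuple[OmicsTensor, np.ndarray]:
    """Generate a feature x replicate x condition tensor with planted trends.

    ``x[i, j, k] = baseline_i + planted_i * effect_size * trend(k) + noise``
    with ``trend(k) = k - (K - 1)/2`` (centered, unit step), identical
    across replicates j.  Returns the tensor and the planted boolean mask.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, k = spec.n_features, spec.n_replicates, spec.n_conditions
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
    planted = np.zeros(n, dtype=bool)
    planted[rng.choice(n, size=spec.n_planted, replace=False)] = True
    trend = np.arange(k, dtype=float) - (k - 1) / 2.0
    signal = spec.effect_size * spec.noise_sd * np.outer(planted.astype(float), trend)
    x = baseline[:, None, None] + signal[:, None, :] + rng.normal(
        0.0, spec.noise_sd, size=(n, m, k)
    )
    if spec.distribution == "lognormal":
        x = np.exp(x * 0.2)  # count-like positive skew, trend preserved in log space
    tensor = OmicsTensor(
        values=x,
        feature_ids=[f"gene_{i}" for i in range(n)],
        mode2_ids=[f"rep_{j}" for j in range(m)],
        mode3_ids=[f"cond_{c}" for c in range(k)],
        design=SampleDesign(
            replicate_labels=[f"rep_{j}" for j in range(m)],
            condition_levels=[f"cond_{c}" for c in range(k)],
        ),
    )
    return tensor, planted


def default_labels(spec: SyntheticSpec) -> np.ndarray:
    """Ordered integer labels 0..n_levels-1 spread evenly over the samples."""
    return np.repeat(
        np.arange(spec.n_levels), int(np.ceil(spec.n_samples / spec.n_levels))
    )[: spec.n_samples].astype(float)


def make_multiomics_set(
    spec: SyntheticSpec, labels: Optional[np.ndarray] = None
) -> tuple[MultiomicsSet, list[np.ndarray], np.ndarray]:
    """Generate K shared-sample layers with label-aligned planted features.

    Every planted feature loads on the same standardized label factor
    ``s_j`` with amplitude ``effect_size * noise_sd``; null features are
    pure noise.  Returns the set, per-layer truth masks, and the labels.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if labels is None:
        labels = default_labels(spec)
    labels = np.asarray(labels, dtype=float)
    if labels.size != spec.n_samples:
        raise ValueError(f"{labels.size} labels for {spec.n_samples} samples")
    s = labels - labels.mean()
    sd = s.std()
    if sd > 0:
        s = s / sd
    layers, masks, ids = [], [], []
    for li, (n_k, n_sig) in enumerate(zip(spec.layer_sizes, spec.planted_per_layer())):
        mask = np.zeros(n_k, dtype=bool)
        mask[rng.choice(n_k, size=n_sig, replace=False)] = True
        x = rng.normal(0.0, spec.noise_sd, size=(n_k, spec.n_samples))
        x[mask] += spec.effect_size * spec.noise_sd * s[None, :]
        layers.append(x)
        masks.append(mask)
        ids.append([f"layer{li}_feat_{i}" for i in range(n_k)])
    omics = MultiomicsSet(
        layers=layers,
        layer_names=[f"omics_{li}" for li in range(len(layers))],
        sample_ids=[f"sample_{j}" for j in range(spec.n_samples)],
        feature_ids=ids,
    )
    return omics, masks, labels
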