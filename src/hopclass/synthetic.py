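"""Seeded generators for class-structured expression data.

The generator emulates the regimes the classifier is meant for: a handful of
classes with strongly unbalanced disjoint gene signatures (a few dozen up to
nearly a thousand genes), cohorts of a few dozen to a few hundred samples,
and log2-ratio values in which a sample's own signature genes are shifted up
and all other signature genes are shifted down.  Two corruption dials are
provided: Gaussian noise around the class means and a per-gene sign-flip
probability; flip_prob = 0 gives trivially recoverable samples and
flip_prob = 0.5 removes all class signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SignatureSet, random_patterns

__all__ = [
    "SyntheticSpec",
    "make_signatures",
    "simulate_expression",
    "simulate_mixture",
    "class_mean_profile",
    "random_patterns",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults describe a three-class problem with signature sizes spanning the
    unbalanced range the classifier targets (19 to 956 genes) and a clear
    but noisy class signal: signature genes are shifted by ±1.5 log2 units
    (about a 2.8-fold change) around noise of standard deviation 0.5.
    """

    n_classes: int = 3
    signature_sizes: tuple[int, ...] = (19, 300, 956)
    n_noise_genes: int = 100
    samples_per_class: tuple[int, ...] = (8, 8, 8)
    effect: float = 1.5
    sigma: float = 0.5
    flip_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if len(self.signature_sizes) != self.n_classes:
            raise ValueError("signature_sizes must have one entry per class")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class must have one entry per class")
        if any(s < 1 for s in self.signature_sizes):
            raise ValueError("signature sizes must be positive")
        if any(s < 0 for s in self.samples_per_class):
            raise ValueError("sample counts must be non-negative")
        if self.effect <= 0:
            raise ValueError("effect must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.flip_prob <= 0.5:
            raise ValueError("flip_prob must lie in [0, 0.5]")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be non-negative")

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(f"class_{k + 1}" for k in range(self.n_classes))


def make_signatures(spec: SyntheticSpec) -> SignatureSet:
    """Disjoint gene signatures with the requested sizes.

    Gene names are deterministic functions of the spec, so the same spec
    always yields the same signature set.
    """
    genes_by_class = {}
    for k, (label, size) in enumerate(zip(spec.class_labels, spec.signature_sizes)):
        genes_by_class[label] = tuple(f"SIG{k + 1}_{j:04d}" for j in range(size))
    return SignatureSet(classes=spec.class_labels, genes_by_class=genes_by_class)


def _gene_universe(spec: SyntheticSpec, signatures: SignatureSet) -> list[str]:
    genes = [g for c in signatures.classes for g in signatures.genes_by_class[c]]
    genes += [f"NOISE_{j:04d}" for j in range(spec.n_noise_genes)]
    return genes


def class_mean_profile(
    spec: SyntheticSpec, signatures: SignatureSet, cls: str
) -> pd.Series:
    """Expected log2-ratio per gene for a pure sample of one class."""
    genes = _gene_universe(spec, signatures)
    mean = pd.Series(0.0, index=genes)
    for c in signatures.classes:
        shift = spec.effect if c == cls else -spec.effect
        mean.loc[list(signatures.genes_by_class[c])] = shift
    return mean


def _finish_matrix(
    means: np.ndarray,
    genes: list[str],
    sample_ids: list[str],
    n_signature_genes: int,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    values = rng.normal(loc=means, scale=spec.sigma)
    if spec.flip_prob > 0:
        flips = rng.random((n_signature_genes, values.shape[1])) < spec.flip_prob
        values[:n_signature_genes][flips] *= -1.0
    return pd.DataFrame(values, index=genes, columns=sample_ids)


def simulate_expression(
    spec: SyntheticSpec,
    signatures: SignatureSet,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a labelled cohort of log2-ratio profiles.

    For a sample of class c, its own signature genes are drawn from
    Normal(+effect, sigma), every other signature gene from
    Normal(-effect, sigma) and noise genes from Normal(0, sigma); each
    signature gene's value is then sign-flipped with probability flip_prob.
    Returns the genes x samples matrix and the true labels.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    genes = _gene_universe(spec, signatures)
    n_sig = sum(len(signatures.genes_by_class[c]) for c in signatures.classes)
    mean_by_class = {
        c: class_mean_profile(spec, signatures, c).to_numpy()
        for c in signatures.classes
    }
    sample_ids: list[str] = []
    labels: list[str] = []
    columns: list[np.ndarray] = []
    idx = 0
    for cls, n_samples in zip(spec.class_labels, spec.samples_per_class):
        for _ in range(n_samples):
            sample_ids.append(f"sample_{idx:03d}")
            labels.append(cls)
            columns.append(mean_by_class[cls])
            idx += 1
    means = np.column_stack(columns) if columns else np.empty((len(genes), 0))
    matrix = _finish_matrix(means, genes, sample_ids, n_sig, spec, rng)
    return matrix, pd.Series(labels, index=sample_ids, name="true_class")


def simulate_mixture(
    spec: SyntheticSpec,
    signatures: SignatureSet,
    weights: dict[str, float],
    n_samples: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Samples whose per-gene expectation is a convex combination of classes.

    ``weights`` maps class labels to non-negative mixing weights summing to
    one; a 60/40 mixture of two classes has per-gene mean
    0.6 mu_1 + 0.4 mu_2.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    w = np.array([weights.get(c, 0.0) for c in signatures.classes])
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("mixture weights must be non-negative and sum to 1")
    genes = _gene_universe(spec, signatures)
    n_sig = sum(len(signatures.genes_by_class[c]) for c in signatures.classes)
    mean = np.zeros(len(genes))
    for c, wc in zip(signatures.classes, w):
        if wc > 0:
            mean += wc * class_mean_profile(spec, signatures, c).to_numpy()
    sample_ids = [f"mix_{j:03d}" for j in range(n_samples)]
    means = np.repeat(mean[:, None], n_samples, axis=1)
    return _finish_matrix(means, genes, sample_ids, n_sig, spec, rng)
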