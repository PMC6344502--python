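"""Per-sample classification confidence.

The energy of the network at a sample's initial (binarized, un-pruned) state
measures its distance from the stored class attractors.  A null distribution
is built by reshuffling the sample's expression values across the signature
genes and re-classifying each permutation; permutations converging to the
sample's own class contribute their initial energies to the null, and the
lower tail of that distribution gives an empirical p-value.  p-values across
a run are converted to q-values with the Benjamini-Hochberg step-up rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core import HopeConfig, TemplateBank, energy
from . import core

__all__ = [
    "NullRecord",
    "initial_energy",
    "permutation_null",
    "empirical_pvalue",
    "bh_fdr",
]


@dataclass(frozen=True)
class NullRecord:
    """One permutation of a sample: its convergence class and initial energy.

    Records with ``converged_class = None`` are kept for bookkeeping but are
    excluded from the null distribution.
    """

    index: int
    converged_class: str | None
    energy_initial: float


def initial_energy(
    values: np.ndarray,
    bank: TemplateBank,
    weights: np.ndarray,
    ratio_mode: str = "precomputed_log2ratio",
    reference: np.ndarray | None = None,
) -> float:
    """Energy of the full binarized state, -1/2 x0' W x0.

    Computed on the complete signature gene set (no subsampling), so it is a
    deterministic function of the sample.
    """
    from .classify import _aligned_values, binarize_sample

    v = _aligned_values(values, bank)
    state = binarize_sample(v, ratio_mode, reference)
    if bank.class_of_gene is not None:
        return core.block_energy(bank, state.x)
    return energy(weights, state.x)


def permutation_null(
    values: np.ndarray,
    bank: TemplateBank,
    weights: np.ndarray,
    signatures,
    config: HopeConfig,
    rng: np.random.Generator,
    reference: np.ndarray | None = None,
) -> list[NullRecord]:
    """Classify uniformly reshuffled copies of one sample.

    Each permutation rearranges the sample's expression values across the
    filtered signature genes (a multiset-preserving shuffle), then runs the
    full subsampling/vote pipeline with ``config.m_null`` replicas and
    records the convergence class together with the permuted sample's
    full-state initial energy.
    """
    from .classify import UNCLASSIFIED, _aligned_values, classify_sample

    v = _aligned_values(values, bank)
    finite = v[np.isfinite(v)]
    if finite.size and np.unique(finite).size <= 1:
        warnings.warn(
            "constant-valued sample: permutation null is degenerate", stacklevel=2
        )
    null_config = replace(config, replicas=config.m_null)
    records: list[NullRecord] = []
    for b in range(config.n_permutations):
        perm = rng.permutation(v)
        primary, _, _ = classify_sample(
            perm, bank, weights, signatures, null_config, rng, reference
        )
        e = initial_energy(perm, bank, weights, config.ratio_mode, reference)
        records.append(
            NullRecord(
                index=b,
                converged_class=None if primary == UNCLASSIFIED else primary,
                energy_initial=e,
            )
        )
    return records


def empirical_pvalue(
    e_obs: float,
    null: list[NullRecord],
    target_class: str,
    rng: np.random.Generator | None = None,
) -> tuple[float, int]:
    """Lower-tail empirical p-value of the observed initial energy.

    Only null records that converged to ``target_class`` are retained (count
    k).  Stored attractors are energy minima, so a low initial energy means
    the sample sits close to its class attractor; the p-value is the add-one
    lower-tail rank p = (1 + #{E_null <= E_obs}) / (1 + k).

    Binarized states make the energy a discrete statistic, so exact ties
    between the observed and null energies are common rather than
    negligible.  When ``rng`` is given, the observation's rank within its
    tie group is drawn uniformly (the randomized-rank construction that
    keeps permutation p-values exactly uniform under the null); without an
    ``rng`` every tied null counts as below the observation, which is
    deterministic but conservative.  An empty null (k = 0) yields p = 1
    with a low-confidence warning.
    """
    retained = np.asarray(
        [r.energy_initial for r in null if r.converged_class == target_class]
    )
    k = len(retained)
    if k == 0:
        warnings.warn(
            f"no permutation converged to class {target_class!r}; "
            "p-value set to 1 (low confidence)",
            stacklevel=2,
        )
        return 1.0, 0
    tol = 1e-9 * max(1.0, abs(e_obs))
    ties = int(np.sum(np.abs(retained - e_obs) <= tol))
    less = int(np.sum(retained < e_obs - tol))
    if rng is None or ties == 0:
        b = less + ties
    else:
        b = less + int(rng.integers(0, ties + 1))
    return (1.0 + b) / (1.0 + k), k


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
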