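"""Sample-facing classification pipeline.

Preprocessing (restriction to signature genes, binarization of log2 ratios),
per-replica signature subsampling against the size cutoff gamma, plurality
vote over M replicas, and the secondary-class call obtained by deleting the
winning signature and re-running on the reduced network.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    HopeConfig,
    NetworkState,
    ReplicaOutcome,
    SignatureSet,
    TemplateBank,
    build_template_bank,
    evolve_to_class,
    hebb_weights_hope,
)

__all__ = [
    "UNCLASSIFIED",
    "SampleClassification",
    "filter_to_signature_genes",
    "binarize_sample",
    "gamma_select",
    "classify_sample",
    "secondary_class",
    "classify_dataset",
]

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


@dataclass
class SampleClassification:
    """Per-sample output of the full pipeline.

    ``vote_fractions`` covers every class plus ``"none"`` (replicas that did
    not converge) and sums to one.  ``p_value`` / ``fdr`` are None for
    unclassified samples, which carry no confidence statement.
    """

    sample_id: str
    primary_class: str
    vote_fractions: dict[str, float]
    secondary_class: str | None
    energy_initial: float
    p_value: float | None
    fdr: float | None
    n_null_retained: int | None


def filter_to_signature_genes(
    expr: pd.DataFrame, signatures: SignatureSet, bank: TemplateBank | None = None
) -> pd.DataFrame:
    """Restrict an expression matrix to the union of the signature genes.

    Rows are reordered to the template-bank gene index; signature genes
    absent from the matrix are retained as missing rows (they binarize to 0).
    A class with no gene present at all in the matrix is an error.
    """
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers in expression matrix: {dups[:10]}")
    if bank is None:
        bank = build_template_bank(signatures)
    present = set(expr.index)
    for cls in signatures.classes:
        genes = signatures.genes_by_class[cls]
        covered = sum(g in present for g in genes)
        if covered == 0:
            raise ValueError(
                f"class {cls!r}: none of its {len(genes)} signature genes "
                "are present in the expression matrix"
            )
        logger.info(
            "signature coverage %s: %d/%d genes present", cls, covered, len(genes)
        )
    return expr.reindex(list(bank.gene_index))


def binarize_sample(
    values: np.ndarray | pd.Series,
    ratio_mode: str = "precomputed_log2ratio",
    reference: np.ndarray | pd.Series | None = None,
) -> NetworkState:
    """Binarize one sample's expression values into a ternary initial state.

    ``precomputed_log2ratio``: x_i = sign(value_i).  ``gene_median_log2ratio``:
    x_i = sign(value_i - reference_i) where the reference is each gene's
    cohort median.  Missing values, exact zeros and exact reference ties all
    map to 0 (the gene is absent from the dynamics).
    """
    v = np.asarray(values, dtype=float)
    if ratio_mode == "gene_median_log2ratio":
        if reference is None:
            raise ValueError(
                "gene_median_log2ratio requires a per-gene cohort reference"
            )
        v = v - np.asarray(reference, dtype=float)
    elif ratio_mode != "precomputed_log2ratio":
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    x = np.sign(v)
    x[~np.isfinite(v)] = 0.0
    return NetworkState.from_vector(x.astype(np.int8))


def gamma_select(
    signatures: SignatureSet, gamma: int, rng: np.random.Generator
) -> dict[str, tuple[str, ...]]:
    """Per-class retained gene subsets under the signature-size cutoff.

    Classes with at most ``gamma`` genes keep their full signature; larger
    classes get a fresh uniform subset of exactly ``gamma`` genes drawn
    without replacement (original gene order is preserved within the subset).
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    retained: dict[str, tuple[str, ...]] = {}
    for cls in signatures.classes:
        genes = signatures.genes_by_class[cls]
        if len(genes) <= gamma:
            retained[cls] = genes
        else:
            keep = np.sort(rng.choice(len(genes), size=gamma, replace=False))
            retained[cls] = tuple(genes[k] for k in keep)
    return retained


def _aligned_values(
    values: np.ndarray | pd.Series, bank: TemplateBank
) -> np.ndarray:
    if isinstance(values, pd.Series):
        values = values.reindex(list(bank.gene_index))
    v = np.asarray(values, dtype=float)
    if v.shape != (bank.n_genes,):
        raise ValueError(
            f"expected {bank.n_genes} values aligned to the gene index, "
            f"got shape {v.shape}"
        )
    return v


def classify_sample(
    values: np.ndarray | pd.Series,
    bank: TemplateBank,
    weights: np.ndarray,
    signatures: SignatureSet,
    config: HopeConfig,
    rng: np.random.Generator,
    reference: np.ndarray | pd.Series | None = None,
) -> tuple[str, dict[str, float], list[ReplicaOutcome]]:
    """Classify one sample by plurality vote over M subsampling replicas.

    Each replica draws fresh gamma subsets, zeroes the unselected genes in
    the binarized state and evolves the result to a class attractor.  Votes
    are tallied over the classes plus "none"; the plurality winner is the
    primary class, while a winning "none" or an exact tie between classes
    yields ``"unclassified"``.
    """
    v = _aligned_values(values, bank)
    if reference is not None:
        reference = _aligned_values(reference, bank)
    full_state = binarize_sample(v, config.ratio_mode, reference)
    labels = list(bank.classes) + ["none"]
    if not full_state.active0.any():
        warnings.warn("all-zero initial state; sample is unclassified", stacklevel=2)
        votes = {lab: 0.0 for lab in labels}
        votes["none"] = 1.0
        return UNCLASSIFIED, votes, []

    needs_subsampling = any(
        len(signatures.genes_by_class[c]) > config.gamma for c in signatures.classes
    )
    counts: Counter[str] = Counter()
    outcomes: list[ReplicaOutcome] = []
    for _ in range(config.replicas):
        if needs_subsampling:
            kept = gamma_select(signatures, config.gamma, rng)
            mask = np.zeros(bank.n_genes, dtype=bool)
            for genes in kept.values():
                mask[[bank.positions[g] for g in genes]] = True
            x0 = np.where(mask, full_state.x, 0).astype(np.int8)
            state = NetworkState.from_vector(x0)
        else:
            state = NetworkState.from_vector(full_state.x)
        outcome = evolve_to_class(state, bank, weights, config, rng)
        counts[outcome.converged_class or "none"] += 1
        outcomes.append(outcome)

    m = config.replicas
    vote_fractions = {lab: counts.get(lab, 0) / m for lab in labels}
    top_count = max(counts.values())
    top_labels = [lab for lab, c in counts.items() if c == top_count]
    if len(top_labels) == 1 and top_labels[0] != "none":
        primary = top_labels[0]
    else:
        primary = UNCLASSIFIED
    return primary, vote_fractions, outcomes


def secondary_class(
    values: np.ndarray | pd.Series,
    signatures: SignatureSet,
    primary: str,
    config: HopeConfig,
    rng: np.random.Generator,
    reference: np.ndarray | pd.Series | None = None,
) -> str | None:
    """Second-best class: delete the winning signature and re-run.

    Only defined for multi-class problems (p >= 3) and for samples with a
    real primary class.  The reduced problem drops both the primary class
    and all of its genes, so the network shrinks to N - N_primary units.
    """
    if primary == UNCLASSIFIED:
        raise ValueError("secondary class is undefined for unclassified samples")
    if signatures.n_classes < 3:
        raise ValueError(
            "secondary class requires a multi-class problem (p >= 3)"
        )
    reduced = signatures.drop_class(primary)
    bank2 = build_template_bank(reduced)
    weights2 = hebb_weights_hope(bank2)
    if isinstance(values, pd.Series):
        v2: np.ndarray | pd.Series = values
    else:
        # align positional values of the original bank onto the reduced index
        bank_full = build_template_bank(signatures)
        v2 = pd.Series(np.asarray(values, dtype=float), index=list(bank_full.gene_index))
    if reference is not None and not isinstance(reference, pd.Series):
        bank_full = build_template_bank(signatures)
        reference = pd.Series(
            np.asarray(reference, dtype=float), index=list(bank_full.gene_index)
        )
    second, _, _ = classify_sample(
        v2, bank2, weights2, reduced, config, rng, reference
    )
    return None if second == UNCLASSIFIED else second


def _sample_rng_streams(
    seed: int, sample_id: str, n_streams: int = 3
) -> list[np.random.Generator]:
    """Per-sample child generators derived from the master seed.

    The child entropy mixes the master seed with a CRC32 digest of the sample
    identifier, so a sample's stream does not depend on its position in the
    matrix (removing other samples cannot change its call).
    """
    digest = zlib.crc32(sample_id.encode("utf-8"))
    ss = np.random.SeedSequence([seed % (2**31), digest])
    return [np.random.default_rng(child) for child in ss.spawn(n_streams)]


def classify_dataset(
    expr: pd.DataFrame,
    signatures: SignatureSet,
    config: HopeConfig,
    compute_fdr: bool = True,
    compute_secondary: bool = True,
) -> list[SampleClassification]:
    """Classify every sample of an expression matrix independently.

    Samples are processed one at a time with seed streams derived from the
    sample identifier, preserving the single-sample guarantee (a sample's
    call does not depend on which other samples are present, except through
    the per-gene cohort median when ``gene_median_log2ratio`` is active).
    p-values come from the energy permutation null of the significance
    module; the Benjamini-Hochberg FDR is computed across the classified
    samples of the run.
    """
    from . import significance

    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dups[:10]}")
    bank = build_template_bank(signatures)
    weights = hebb_weights_hope(bank)
    filtered = filter_to_signature_genes(expr, signatures, bank)
    reference = None
    if config.ratio_mode == "gene_median_log2ratio":
        if filtered.shape[1] < 2:
            raise ValueError(
                "gene_median_log2ratio requires a multi-sample cohort"
            )
        reference = filtered.median(axis=1, skipna=True).to_numpy()

    results: list[SampleClassification] = []
    for sample_id in filtered.columns:
        rng_cls, rng_null, rng_sec = _sample_rng_streams(config.seed, str(sample_id))
        values = filtered[sample_id].to_numpy(dtype=float)
        try:
            primary, votes, _ = classify_sample(
                values, bank, weights, signatures, config, rng_cls, reference
            )
            e0 = significance.initial_energy(
                values, bank, weights, config.ratio_mode, reference
            )
            p_value = None
            n_retained = None
            second = None
            if primary != UNCLASSIFIED:
                if compute_fdr and config.n_permutations > 0:
                    null = significance.permutation_null(
                        values, bank, weights, signatures, config, rng_null, reference
                    )
                    p_value, n_retained = significance.empirical_pvalue(
                        e0, null, primary, rng_null
                    )
                if compute_secondary and signatures.n_classes >= 3:
                    second = secondary_class(
                        pd.Series(values, index=list(bank.gene_index)),
                        signatures,
                        primary,
                        config,
                        rng_sec,
                        reference,
                    )
        except Exception as exc:  # annotate failures with the sample id
            raise type(exc)(f"sample {sample_id!r}: {exc}") from exc
        results.append(
            SampleClassification(
                sample_id=str(sample_id),
                primary_class=primary,
                vote_fractions=votes,
                secondary_class=second,
                energy_initial=e0,
                p_value=p_value,
                fdr=None,
                n_null_retained=n_retained,
            )
        )

    from .significance import bh_fdr

    classified = [r for r in results if r.p_value is not None]
    if classified:
        qs = bh_fdr([r.p_value for r in classified])
        for rec, q in zip(classified, qs):
            rec.fdr = float(q)
    return results
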