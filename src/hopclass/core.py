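"""Attractor-network machinery for signature-based class prediction.

A set of gene signatures (one per class) is stored in a Hopfield network as
class templates: ±1 vectors over the union of the signature genes, +1 on the
genes of the class's own signature.  Samples are classified by evolving their
binarized expression state towards one of the stored attractors.

Two weight constructions are provided: the classical Hebb rule, kept here as
an oracle and for storage-capacity simulations, and a modified Hebb rule
tailored to mutually non-overlapping signatures, which yields a binary weight
matrix (+p/N within a class, -p/N across classes).  The dynamics comes in two
flavours as well: the classical asynchronous sign rule on ±1 states, and an
asymmetric, diluted variant on {-1, 0, +1} states in which a unit that would
flip from +1 to -1 is instead eliminated (set to 0) permanently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erfc

__all__ = [
    "SignatureOverlapWarning",
    "SignatureSet",
    "TemplateBank",
    "NetworkState",
    "ReplicaOutcome",
    "HopeConfig",
    "CapacityEstimate",
    "build_template_bank",
    "hebb_weights_classic",
    "hebb_weights_hope",
    "local_field",
    "class_sum_local_field",
    "energy",
    "block_energy",
    "async_sweep_classic",
    "classic_fixed_point",
    "async_sweep_asymmetric",
    "match_fraction",
    "evolve_to_class",
    "estimate_capacity",
    "random_patterns",
    "bit_error_probability",
    "perfect_recall_probability",
    "minimal_stable_size",
]


class SignatureOverlapWarning(UserWarning):
    """A gene belongs to more than one class signature."""


RATIO_MODES = ("precomputed_log2ratio", "gene_median_log2ratio")


@dataclass(frozen=True)
class SignatureSet:
    """Named classes, each with an ordered gene list.

    Parameters
    ----------
    classes : tuple of str
        Ordered class labels (at least two).
    genes_by_class : mapping
        For each class, the ordered tuple of gene identifiers.  Duplicates
        within one class are forbidden; genes shared across classes are
        permitted but flagged downstream.
    """

    classes: tuple[str, ...]
    genes_by_class: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError(
                f"at least two classes are required, got {len(self.classes)}"
            )
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class labels")
        if set(self.classes) != set(self.genes_by_class):
            raise ValueError("classes and genes_by_class keys disagree")
        for cls in self.classes:
            genes = self.genes_by_class[cls]
            if len(genes) == 0:
                raise ValueError(f"class {cls!r} has an empty gene signature")
            if any(not isinstance(g, str) or not g for g in genes):
                raise ValueError(f"class {cls!r} contains an empty gene identifier")
            if len(set(genes)) != len(genes):
                dups = sorted({g for g in genes if list(genes).count(g) > 1})
                raise ValueError(f"class {cls!r} lists duplicate genes: {dups}")

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Sequence[str]]) -> "SignatureSet":
        return cls(
            classes=tuple(mapping),
            genes_by_class={c: tuple(g) for c, g in mapping.items()},
        )

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def sizes(self) -> dict[str, int]:
        """Signature size N_mu per class."""
        return {c: len(self.genes_by_class[c]) for c in self.classes}

    def overlapping_genes(self) -> set[str]:
        seen: set[str] = set()
        shared: set[str] = set()
        for cls in self.classes:
            for g in self.genes_by_class[cls]:
                if g in seen:
                    shared.add(g)
                seen.add(g)
        return shared

    def drop_class(self, name: str) -> "SignatureSet":
        """Remove a class and all of its genes (used for the secondary call).

        Genes of the dropped class are also removed from any other class that
        shares them; a remaining class emptied by the removal is an error.
        """
        if name not in self.classes:
            raise KeyError(name)
        if self.n_classes - 1 < 2:
            raise ValueError("dropping a class would leave fewer than two classes")
        dropped = set(self.genes_by_class[name])
        remaining: dict[str, tuple[str, ...]] = {}
        for cls in self.classes:
            if cls == name:
                continue
            kept = tuple(g for g in self.genes_by_class[cls] if g not in dropped)
            if not kept:
                raise ValueError(
                    f"removing class {name!r} empties the signature of {cls!r}"
                )
            remaining[cls] = kept
        return SignatureSet(classes=tuple(remaining), genes_by_class=remaining)


@dataclass(frozen=True, eq=False)
class TemplateBank:
    """Union gene index and the ±1 class templates stored in the network.

    ``templates`` is a (p, N) int8 array whose row mu is the template of
    class mu: +1 where the gene belongs to that class's signature, -1
    elsewhere.  ``membership`` is the corresponding boolean mask.
    """

    gene_index: tuple[str, ...]
    classes: tuple[str, ...]
    templates: np.ndarray
    membership: np.ndarray
    positions: Mapping[str, int] = field(repr=False)

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def has_overlap(self) -> bool:
        return bool((self.membership.sum(axis=0) > 1).any())

    @property
    def class_of_gene(self) -> np.ndarray | None:
        """Class index per gene, or None when signatures overlap."""
        if self.has_overlap:
            return None
        return self.membership.argmax(axis=0)


def build_template_bank(signatures: SignatureSet) -> TemplateBank:
    """Construct the union gene index and the ±1 templates.

    The gene index concatenates the class gene lists in class order,
    deduplicating while preserving the first occurrence.  For mutually
    non-overlapping signatures N = sum of the signature sizes.
    """
    index: list[str] = []
    positions: dict[str, int] = {}
    for cls in signatures.classes:
        for g in signatures.genes_by_class[cls]:
            if g not in positions:
                positions[g] = len(index)
                index.append(g)
    shared = signatures.overlapping_genes()
    if shared:
        warnings.warn(
            f"{len(shared)} gene(s) shared across signatures: "
            f"{sorted(shared)[:5]}{'...' if len(shared) > 5 else ''}",
            SignatureOverlapWarning,
            stacklevel=2,
        )
    n = len(index)
    p = signatures.n_classes
    membership = np.zeros((p, n), dtype=bool)
    for mu, cls in enumerate(signatures.classes):
        for g in signatures.genes_by_class[cls]:
            membership[mu, positions[g]] = True
    templates = np.where(membership, 1, -1).astype(np.int8)
    return TemplateBank(
        gene_index=tuple(index),
        classes=signatures.classes,
        templates=templates,
        membership=membership,
        positions=positions,
    )


def hebb_weights_classic(patterns: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Classical Hebb rule W_ij = (1/N) sum_mu xi_i^mu xi_j^mu, zero diagonal."""
    pat = np.asarray(patterns, dtype=float)
    if pat.ndim == 1:
        pat = pat[None, :]
    if pat.ndim != 2 or pat.shape[0] < 1:
        raise ValueError("patterns must be a non-empty list of equal-length vectors")
    if not np.all(np.isin(pat, (-1.0, 1.0))):
        raise ValueError("patterns must be ±1 vectors")
    n = pat.shape[1]
    w = pat.T @ pat / n
    np.fill_diagonal(w, 0.0)
    return w


def hebb_weights_hope(bank: TemplateBank) -> np.ndarray:
    """Modified Hebb rule W_ij = (p/2N)(sum_mu xi_i^mu xi_j^mu + 2 - p).

    For non-overlapping signatures this is a binary matrix: +p/N when genes
    i and j belong to the same class, -p/N otherwise.  The diagonal is forced
    to zero (no self-interaction).
    """
    pat = bank.templates.astype(float)
    p, n = pat.shape
    w = (p / (2.0 * n)) * (pat.T @ pat + 2.0 - p)
    np.fill_diagonal(w, 0.0)
    return w


def local_field(weights: np.ndarray, x: np.ndarray, i: int) -> float:
    """Dense local field h_i = sum_j W_ij x_j."""
    return float(weights[i] @ np.asarray(x, dtype=float))


def class_sum_local_field(
    bank: TemplateBank, x: np.ndarray, i: int, class_sums: np.ndarray | None = None
) -> float:
    """Local field via per-class running sums (non-overlapping signatures).

    With the block weights (+p/N same class, -p/N otherwise) the field of gene
    i in class c reduces to h_i = (p/N) (2 S_c - S_tot - x_i) where S_c is the
    sum of the states of class c's genes.  Equal to the dense dot product to
    within 1e-12.
    """
    cls = bank.class_of_gene
    if cls is None:
        raise ValueError("class-sum shortcut requires non-overlapping signatures")
    xf = np.asarray(x, dtype=float)
    if class_sums is None:
        class_sums = np.bincount(cls, weights=xf, minlength=bank.n_classes)
    p, n = bank.n_classes, bank.n_genes
    return float(p / n * (2.0 * class_sums[cls[i]] - class_sums.sum() - xf[i]))


def energy(weights: np.ndarray, x: np.ndarray) -> float:
    """Network energy E = -1/2 sum_ij W_ij x_i x_j (Lyapunov function)."""
    xf = np.asarray(x, dtype=float)
    return float(-0.5 * xf @ weights @ xf)


def block_energy(bank: TemplateBank, x: np.ndarray) -> float:
    """Energy under the modified Hebb weights via class sums, O(N).

    Valid for non-overlapping signatures; agrees with :func:`energy` on the
    dense matrix to floating-point accuracy.
    """
    cls = bank.class_of_gene
    if cls is None:
        raise ValueError("block energy requires non-overlapping signatures")
    xf = np.asarray(x, dtype=float)
    p, n = bank.n_classes, bank.n_genes
    s_cls = np.bincount(cls, weights=xf, minlength=p)
    q_cls = np.bincount(cls, weights=xf * xf, minlength=p)
    s_tot, q_tot = s_cls.sum(), q_cls.sum()
    quad = (p / n) * (2.0 * ((s_cls**2 - q_cls).sum()) - (s_tot**2 - q_tot))
    return float(-0.5 * quad)


@dataclass
class NetworkState:
    """Ternary network state with bookkeeping of the initially active genes.

    ``active0`` records the genes with non-zero state at t = 0 (after
    binarization and signature subsampling); it is the denominator of the
    convergence criterion.  ``eliminated`` counts dynamic +1 -> 0 events.
    """

    x: np.ndarray
    active0: np.ndarray
    eliminated: int = 0

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "NetworkState":
        xi = np.asarray(x)
        if not np.all(np.isin(xi, (-1, 0, 1))):
            raise ValueError("state entries must be in {-1, 0, +1}")
        xi = xi.astype(np.int8)
        return cls(x=xi, active0=xi != 0, eliminated=0)


@dataclass(frozen=True)
class ReplicaOutcome:
    """Result of one asymmetric evolution of a (possibly subsampled) sample."""

    converged_class: str | None
    match_fraction: float
    sweeps: int
    energy_initial: float
    energy_final: float
    eliminated: int


@dataclass(frozen=True)
class HopeConfig:
    """Run configuration.

    Parameters
    ----------
    gamma : int
        Per-class cap on the signature size; oversized signatures are
        randomly subsampled to ``gamma`` genes in each replica (default 200).
    replicas : int
        Number M of subsampling replicas whose convergence classes are
        combined by plurality vote (default 100).
    match_threshold : float
        Fraction of the initially active genes that must match a template for
        convergence (default 0.95).
    n_permutations : int
        Permutations of the sample's expression values used for the
        energy-based null (default 1000).
    null_replicas : int or None
        Replicas used when classifying each permuted sample; defaults to
        ``replicas``.
    max_sweeps : int
        Cap on asynchronous sweeps per evolution; the asymmetric dynamics
        cannot cycle, so this is a safety net only.
    seed : int
        Master seed; every random choice in a run derives from it.
    ratio_mode : str
        ``precomputed_log2ratio`` (values are already log2 ratios) or
        ``gene_median_log2ratio`` (values are compared to each gene's cohort
        median).
    """

    gamma: int = 200
    replicas: int = 100
    match_threshold: float = 0.95
    n_permutations: int = 1000
    null_replicas: int | None = None
    max_sweeps: int = 100
    seed: int = 0
    ratio_mode: str = "precomputed_log2ratio"

    def __post_init__(self) -> None:
        if self.gamma < 1 or self.replicas < 1 or self.max_sweeps < 1:
            raise ValueError("gamma, replicas and max_sweeps must be >= 1")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        if self.null_replicas is not None and self.null_replicas < 1:
            raise ValueError("null_replicas must be >= 1")
        if not 0.0 < self.match_threshold <= 1.0:
            raise ValueError("match_threshold must lie in (0, 1]")
        if self.ratio_mode not in RATIO_MODES:
            raise ValueError(f"ratio_mode must be one of {RATIO_MODES}")

    @property
    def m_null(self) -> int:
        return self.null_replicas if self.null_replicas is not None else self.replicas


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def async_sweep_classic(
    x: np.ndarray, weights: np.ndarray, order: Sequence[int]
) -> np.ndarray:
    """One asynchronous sweep of the classical sign rule x_i <- sign(h_i).

    Nodes are visited in ``order``; a zero field leaves the node unchanged.
    The energy is non-increasing across the sweep (Lyapunov property).
    """
    out = np.asarray(x, dtype=float).copy()
    for i in order:
        h = weights[i] @ out
        if h > 0:
            out[i] = 1.0
        elif h < 0:
            out[i] = -1.0
    return out


def classic_fixed_point(
    x: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
    max_sweeps: int = 100,
) -> tuple[np.ndarray, int]:
    """Iterate classical asynchronous sweeps to a fixed point.

    Returns the fixed point and the number of sweeps performed.  Each sweep
    uses a fresh uniformly random visiting order.
    """
    n = len(x)
    cur = np.asarray(x, dtype=float).copy()
    for sweep in range(1, max_sweeps + 1):
        nxt = async_sweep_classic(cur, weights, rng.permutation(n))
        if np.array_equal(nxt, cur):
            return cur, sweep
        cur = nxt
    return cur, max_sweeps


def async_sweep_asymmetric(
    state: NetworkState, weights: np.ndarray, order: Sequence[int]
) -> NetworkState:
    """One sweep of the asymmetric diluted rule.

    For each visited node i with x_i != 0: a -1 node with positive field
    switches to +1; a +1 node with negative field is eliminated (set to 0,
    permanently); a zero field leaves the node unchanged.  Nodes at 0 are
    never revived.
    """
    x = state.x.astype(float).copy()
    eliminated = state.eliminated
    for i in order:
        xi = x[i]
        if xi == 0.0:
            continue
        h = weights[i] @ x
        if xi < 0.0 and h > 0.0:
            x[i] = 1.0
        elif xi > 0.0 and h < 0.0:
            x[i] = 0.0
            eliminated += 1
    return NetworkState(
        x=x.astype(np.int8), active0=state.active0.copy(), eliminated=eliminated
    )


def match_fraction(
    x: np.ndarray, template: np.ndarray, denominator_mask: np.ndarray
) -> float:
    """Fraction of the masked genes whose state equals the template value.

    The mask is the set of genes active at t = 0; genes eliminated during the
    evolution are at 0 and therefore count as mismatches.
    """
    mask = np.asarray(denominator_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty denominator: no genes active at t = 0")
    return float(np.mean(np.asarray(x)[mask] == np.asarray(template)[mask]))


def evolve_to_class(
    state0: NetworkState,
    bank: TemplateBank,
    weights: np.ndarray,
    config: HopeConfig,
    rng: np.random.Generator,
) -> ReplicaOutcome:
    """Evolve a ternary initial state towards one of the stored templates.

    Runs asymmetric asynchronous sweeps (fresh random order per sweep, at most
    ``config.max_sweeps``).  After each sweep the match fraction against every
    template is evaluated over the genes active at t = 0; the first class
    reaching ``config.match_threshold`` wins.  If two templates qualify after
    the same sweep the higher match fraction wins and an exact tie yields no
    class.  Non-convergence (no class qualifies before the state stabilises)
    is a valid outcome with ``converged_class = None``.
    """
    active0 = state0.active0
    if not active0.any():
        return ReplicaOutcome(None, 0.0, 0, 0.0, 0.0, 0)

    cls_of = bank.class_of_gene
    fast = cls_of is not None
    x = state0.x.astype(np.int8).copy()
    p, n = bank.n_classes, bank.n_genes
    scale = p / n
    if fast:
        e_initial = block_energy(bank, x)
        class_sums = np.bincount(cls_of, weights=x.astype(float), minlength=p)
        s = class_sums.tolist()
        s_tot = float(class_sums.sum())
    else:
        e_initial = energy(weights, x)

    eliminated = state0.eliminated
    converged: str | None = None
    best_fraction = 0.0
    sweeps_done = 0
    templates_active = bank.templates[:, active0]

    for sweep in range(1, config.max_sweeps + 1):
        sweeps_done = sweep
        idx = np.flatnonzero(x != 0)
        rng.shuffle(idx)
        changed = False
        for i in idx:
            xi = int(x[i])
            if xi == 0:
                continue
            if fast:
                c = cls_of[i]
                h = scale * (2.0 * s[c] - s_tot - xi)
            else:
                h = float(weights[i] @ x)
            if xi == -1 and h > 0.0:
                x[i] = 1
                changed = True
                if fast:
                    s[c] += 2.0
                    s_tot += 2.0
            elif xi == 1 and h < 0.0:
                x[i] = 0
                eliminated += 1
                changed = True
                if fast:
                    s[c] -= 1.0
                    s_tot -= 1.0
        fractions = (templates_active == x[active0]).mean(axis=1)
        best_fraction = float(fractions.max())
        qualifying = fractions >= config.match_threshold
        if qualifying.any():
            top = np.flatnonzero(qualifying & (fractions == best_fraction))
            converged = bank.classes[top[0]] if len(top) == 1 else None
            break
        if not changed:
            break

    e_final = block_energy(bank, x) if fast else energy(weights, x)
    return ReplicaOutcome(
        converged_class=converged,
        match_fraction=best_fraction,
        sweeps=sweeps_done,
        energy_initial=e_initial,
        energy_final=e_final,
        eliminated=eliminated,
    )


# ---------------------------------------------------------------------------
# storage capacity of the classical network
# ---------------------------------------------------------------------------


def random_patterns(n: int, p: int, rng: np.random.Generator) -> np.ndarray:
    """p random uncorrelated ±1 patterns of length n, as a (p, n) int8 array."""
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    return (rng.integers(0, 2, size=(p, n)) * 2 - 1).astype(np.int8)


@dataclass(frozen=True)
class CapacityEstimate:
    """Outcome of a storage-capacity simulation."""

    critical_ratio: float | None
    stderr: float
    retrieved_fraction: dict[float, float]
    n: int
    trials: int


def _retrieve_fraction(
    patterns: np.ndarray,
    rng: np.random.Generator,
    overlap_threshold: float,
    max_sweeps: int,
) -> float:
    """Fraction of stored patterns retrieved when the dynamics starts at them.

    All p retrieval runs share the Hebb weights, so they are evolved in a
    batch: per visited node the fields of every run are obtained from the
    running pattern overlaps, h_i = (sum_mu xi_i^mu m_mu - p x_i) / N, which
    avoids materialising the N x N weight matrix.
    """
    pat = patterns.astype(float)
    p, n = pat.shape
    states = pat.copy()  # run r starts at pattern r
    overlaps = states @ pat.T  # (runs, p), maintained incrementally
    for _ in range(max_sweeps):
        changed = False
        for i in rng.permutation(n):
            col = pat[:, i]
            h = overlaps @ col - p * states[:, i]
            new = np.where(h > 0, 1.0, np.where(h < 0, -1.0, states[:, i]))
            delta = new - states[:, i]
            moved = delta != 0.0
            if moved.any():
                changed = True
                overlaps[moved] += np.outer(delta[moved], col)
                states[:, i] = new
        if not changed:
            break
    final_overlap = np.diag(overlaps) / n
    return float(np.mean(final_overlap >= overlap_threshold))


def estimate_capacity(
    n: int,
    ratios: Sequence[float],
    trials: int,
    rng: np.random.Generator,
    overlap_threshold: float = 0.95,
    retrieved_threshold: float = 0.5,
    max_sweeps: int = 100,
) -> CapacityEstimate:
    """Estimate the critical storage ratio p_c/N of the classical network.

    For each ratio, ``round(ratio * n)`` random uncorrelated ±1 patterns are
    stored with the classical Hebb rule; the dynamics is started at each
    stored pattern and run to a fixed point, and a pattern counts as
    retrieved when its final overlap is at least ``overlap_threshold``.  The
    critical ratio is the smallest one at which the mean retrieved fraction
    drops below ``retrieved_threshold``; the Monte-Carlo standard error of
    that fraction across trials is reported alongside.
    """
    if n < 100:
        raise ValueError("capacity estimation requires n >= 100")
    ratios = sorted(float(r) for r in ratios)
    means: dict[float, float] = {}
    per_trial: dict[float, np.ndarray] = {}
    for ratio in ratios:
        p = max(1, round(ratio * n))
        fracs = np.empty(trials)
        for t in range(trials):
            patterns = random_patterns(n, p, rng)
            fracs[t] = _retrieve_fraction(patterns, rng, overlap_threshold, max_sweeps)
        means[ratio] = float(fracs.mean())
        per_trial[ratio] = fracs
    critical = None
    stderr = float("nan")
    for ratio in ratios:
        if means[ratio] < retrieved_threshold:
            critical = ratio
            stderr = float(per_trial[ratio].std(ddof=1) / math.sqrt(trials))
            break
    return CapacityEstimate(
        critical_ratio=critical,
        stderr=stderr,
        retrieved_fraction=means,
        n=n,
        trials=trials,
    )


# ---------------------------------------------------------------------------
# analytic storage bound for the signature network
# ---------------------------------------------------------------------------


def bit_error_probability(n: int, p: int) -> float:
    """Probability that any single bit of a stored pattern is unstable.

    P_error = 1/2 [1 - erf(sqrt(N / 2p))] for N units storing p patterns.
    """
    return float(0.5 * erfc(math.sqrt(n / (2.0 * p))))


def perfect_recall_probability(n: int, p: int) -> float:
    """Probability of error-free recall of an N-bit pattern, (1 - P_error)^N."""
    return float((1.0 - bit_error_probability(n, p)) ** n)


def minimal_stable_size(p: int, max_iter: int = 500, tol: float = 1e-12) -> int:
    """Smallest integer N satisfying the storage bound N > p ln(Np / 0.0002 pi).

    The bound guarantees error-free recall with probability above 0.99 and
    drives the choice of the signature-size cutoff: the effective network
    size N(gamma) must stay above this threshold.  Solved by fixed-point
    iteration of N <- p ln(Np / 0.0002 pi) followed by an integer scan.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    const = 0.0002 * math.pi

    def rhs(x: float) -> float:
        return p * math.log(p * x / const)

    x = 10.0 * p
    for _ in range(max_iter):
        nxt = rhs(x)
        if abs(nxt - x) < tol:
            break
        x = nxt
    n = max(1, int(math.floor(x)))
    while not n > rhs(n):
        n += 1
    while n > 1 and (n - 1) > rhs(n - 1):
        n -= 1
    return n
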