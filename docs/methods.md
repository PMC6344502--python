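# Methods

## Model

`hopclass` treats class prediction as attractor retrieval. The union of the
per-class gene signatures defines a fully connected network of N gene-nodes;
each class μ is a stored pattern ξ^μ ∈ {−1,+1}^N with +1 exactly on the
genes of its own signature. Weights follow a modified Hebb rule,

    W_ij = (p / 2N) (Σ_μ ξ_i^μ ξ_j^μ + 2 − p),   W_ii = 0,

which for mutually disjoint signatures reduces to the binary block matrix
W_ij = +p/N when i and j share a class and −p/N otherwise. The classical
Hebb rule W_ij = (1/N) Σ_μ ξ_i^μ ξ_j^μ and the classical ±1 sign dynamics
are also implemented; they serve as the correctness anchor (energy descent,
pattern completion, storage capacity) rather than as the classifier.

A sample is binarized gene-wise to x_i⁰ = sign(log2ratio) ∈ {−1, 0, +1}
(0 for absent, missing or exactly-zero values) and evolved asynchronously:
each sweep visits every non-zero node once in a fresh uniformly random
order and applies the **asymmetric diluted rule** — a −1 node with positive
local field becomes +1, while a +1 node with negative field is eliminated
(set to 0 permanently) instead of being flipped to −1. Elimination is the
model's noise control: a spuriously up-regulated gene is silenced rather
than counted as evidence against its class. Zero nodes never re-enter the
dynamics, which therefore cannot cycle (each node moves at most
−1 → +1 → 0) and always stabilises.

Convergence is declared when at least `match_threshold` (default 95 %) of
the genes active at t = 0 equal a template; eliminated genes count as
mismatches, so an input that loses more than 5 % of its active genes can no
longer converge and comes out unclassified — ambiguity is reported, not
resolved silently. Convergence is tested once per sweep. If two templates
qualify after the same sweep the higher match wins; an exact tie is
returned as no convergence.

### Template stability

Under the block weights, an off-class gene of class c sitting at −1 in
template μ feels the field (p/N)(N + 1 − 2N_c − 2N_μ). Templates are
therefore exact fixed points of the asymmetric dynamics only when

    2 (N_c + N_μ) ≥ N + 1   for every class pair (μ, c),

which holds for any two-class problem and for near-balanced three-class
problems, but fails for balanced problems with p ≥ 4 and for strongly
unbalanced size vectors (a mid-sized class gets pumped up when the rest of
the network is far more negative than it is). This is exactly the imbalance
pathology the Γ cutoff is meant to suppress: subsampling every signature
larger than Γ makes the *active* size vector close to (min(N_μ, Γ))_μ,
which satisfies the condition in the regimes the tool targets (e.g. sizes
19/300/956 at Γ = 200 give active sizes 19/200/200). The fixed-point
property tests are scoped to layouts satisfying the condition; outside it
the dynamics still runs and the 95 % criterion converts template
instability into explicit "unclassified" calls.

## Parameters

| parameter | default | meaning and rationale |
|---|---|---|
| `gamma` | 200 | per-class cap on signature size (genes). Balances unbalanced signatures while keeping the effective network size well above the analytic storage bound below. Oversized signatures are subsampled fresh per replica, without replacement. |
| `replicas` (M) | 100 | subsampling replicas combined by plurality vote over classes ∪ {none}. Results are insensitive to M once M ≫ 1; when every signature is under Γ the replicas share one initial state and M is irrelevant. |
| `match_threshold` | 0.95 | fraction of initially active genes that must match a template. |
| `n_permutations` | 1000 | reshuffles of the sample's values across the signature genes for the energy null. |
| `null_replicas` | = M | replicas used when classifying each reshuffle; small values (5–10) are adequate because only the convergence class is needed. |
| `max_sweeps` | 100 | safety cap; the asymmetric dynamics stabilises long before this. |
| `ratio_mode` | `precomputed_log2ratio` | values are already log2 ratios (two-channel arrays, pre-processed data). `gene_median_log2ratio` subtracts each gene's cohort median first (single-channel intensities, RNA-seq), at the cost of a mild cross-sample dependence through the median. |
| `seed` | 0 | master seed. Per-sample streams are derived from (seed, CRC32(sample id)), so a sample's call never depends on which other samples are present. |

The storage bound motivating Γ: in a Hebb network the probability that a
single bit of a stored pattern is unstable is
P_error = ½[1 − erf(√(N/2p))], so error-free recall of an N-bit pattern has
probability (1 − P_error)^N. Requiring this to stay above 0.99 leads to
N > p·ln(Np/0.0002π); solved by fixed-point iteration this gives minimal
sizes N = 51 at p = 4 and N = 82 at p = 6 (the package computes both, see
`scripts/acceptance.py`), hence a Γ of a few hundred keeps N(Γ) comfortably
above the bound for realistic class counts.

## Confidence: the energy permutation null

The energy E = −½ x⁰ᵀ W x⁰ of the **full, un-pruned** binarized state is a
deterministic proxy for the sample's distance from the stored attractors
(templates are energy minima). Each of the `n_permutations` reshuffles of
the sample's values across the filtered signature genes is classified with
the full pipeline; reshuffles converging to the sample's own class form the
null (count k), and the p-value is the add-one lower-tail rank
(1 + #{E_null ≤ E_obs}) / (1 + k).

Two numerical points deserve emphasis:

- **Ties are structural, not incidental.** Binarized states make the
  energy a function of a few per-class integer counts, so a substantial
  fraction of retained null energies can tie with the observation exactly.
  Counting every tied reshuffle as ≤ E_obs inflates the p-value (measured
  mean ≈ 0.62 in a controlled exchangeability experiment where 0.5 is
  guaranteed). The pipeline therefore uses the standard randomized-rank
  construction — the observation's rank within its tie group is drawn
  uniformly from the sample's seeded stream — which restores exact
  uniformity under exchangeable (class-signal-free) inputs (measured mean
  0.501, KS 0.05). `empirical_pvalue` without an RNG falls back to the
  deterministic conservative count; with continuous energies the two
  coincide.
- **An empty null is reported, not patched.** Reshuffles of a strongly
  class-structured sample essentially never reproduce a class-like pattern,
  so k = 0 is common for unambiguous samples; the p-value is then 1 with a
  low-confidence flag. The permutation confidence is informative exactly
  where it matters — borderline samples whose reshuffles do populate the
  null. Reshuffles that fail to classify are dropped (k shrinks); they are
  not redrawn.

p-values are converted to q-values with the Benjamini–Hochberg step-up
(via statsmodels) across the classified samples of one run; unclassified
samples carry no p-value and do not enter the family.

The secondary class repeats the whole procedure after deleting the winning
class and all of its genes (the network shrinks to N − N_primary); it is
defined only for p ≥ 3.

## Synthetic data

The generator emulates the regimes the classifier targets: p = 2–5 classes
with disjoint signatures of 19–956 genes, cohorts of a dozen to a few
hundred samples. For a sample of class c, own-signature genes are drawn
from Normal(+effect, σ), all other signature genes from Normal(−effect, σ),
and non-signature noise genes from Normal(0, σ); each signature gene's
value is sign-flipped with probability `flip_prob`. Defaults: p = 3, sizes
(19, 300, 956), effect = 1.5 log2 units, σ = 0.5, flip_prob = 0 — a clear
but noisy signal in a realistically unbalanced layout. `flip_prob` is the
corruption dial: 0 gives trivially recoverable samples, 0.5 removes the
class signal entirely. Mixture samples take per-gene means as convex
combinations of class profiles.

What the generator does **not** emulate: platform-specific artefacts
(probe effects, count dispersion of RNA-seq), gene–gene correlation within
signatures, batch structure, and overlapping signatures. Passing tests on
this generator therefore demonstrate the algorithmic properties
(retrieval, vote stability, calibration of the permutation null under
exchangeable inputs) — not field performance on any particular platform.

The p-value calibration check uses a two-class, 3+3-gene signature set
with flip_prob = 0.5: noise inputs must occasionally classify for p-values
to exist at all, and under the 95 % criterion the noise classification
rate decays extremely fast with signature size (≈ 22 % at 3+3 genes,
< 2 % at 10+10). Small signatures are the only regime where the
calibration statement is testable at reasonable cost.

## Problem sizes used by the checks

The storage-capacity simulation runs at N = 500 with 20 network
realisations per ratio over p/N = 0.10–0.18; the calibration check uses
900 noise samples (≈ 200 of which classify) with 200 permutations and
M = M_null = 10; the clean-cohort recovery check uses 24 samples at the
default signature sizes with M = 20. These sizes were chosen to make each
statistical statement testable with comfortable Monte-Carlo margins.

## Known limitations

- **Finite-size storage capacity.** The thermodynamic-limit capacity of
  the classical Hebb network is p_c/N ≈ 0.138, and the simulator's
  retrieved fraction degrades around that load; but the 50 %-retrieval
  crossing measured by starting the zero-temperature dynamics *at* the
  stored pattern sits visibly above it at accessible sizes (≈ 0.17 at
  N = 500, ≈ 0.16 at N = 1000, drifting down with N), because finite
  networks retain metastable remnant minima above the thermodynamic
  transition. The simulator reports the honest finite-N crossing.
- Templates of strongly unbalanced or many-class problems are not fixed
  points before Γ balancing (see the stability condition above); with an
  ill-chosen Γ the dynamics can drain small-class samples into larger
  classes' basins and return unclassified.
- The energy null is empty (k = 0) for unambiguous samples; their FDR is
  reported as 1/low-confidence rather than extrapolated.
- A six-gene toy network cannot express a 95 % criterion (one elimination
  already costs 1/6); sub-20-gene problems need a correspondingly coarser
  `match_threshold`.
- Overlapping signatures are accepted (the general Hebb form is used and a
  warning is emitted) but the fast class-sum field path and the block-form
  identities require disjoint signatures; overlap falls back to dense
  arithmetic and is outside the tested regime.
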