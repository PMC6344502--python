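"""Network machinery: templates, weights, energy, dynamics, capacity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hopclass.core import (
    HopeConfig,
    NetworkState,
    SignatureOverlapWarning,
    SignatureSet,
    async_sweep_asymmetric,
    async_sweep_classic,
    block_energy,
    build_template_bank,
    class_sum_local_field,
    classic_fixed_point,
    energy,
    estimate_capacity,
    evolve_to_class,
    hebb_weights_classic,
    hebb_weights_hope,
    local_field,
    match_fraction,
    minimal_stable_size,
    perfect_recall_probability,
    random_patterns,
)
from conftest import random_disjoint_signatures


# ---------------------------------------------------------------------------
# signatures and templates
# ---------------------------------------------------------------------------


class TestTemplateBank:
    def test_membership_rule(self, two_class_signatures):
        bank = build_template_bank(two_class_signatures)
        assert bank.n_genes == 6
        np.testing.assert_array_equal(bank.templates[0], [1, 1, 1, -1, -1, -1])
        np.testing.assert_array_equal(bank.templates[1], -bank.templates[0])

    def test_shared_gene_appears_once_with_warning(self):
        sigs = SignatureSet.from_dict({"A": ["g1", "g2"], "B": ["g2", "g3"]})
        with pytest.warns(SignatureOverlapWarning):
            bank = build_template_bank(sigs)
        assert bank.gene_index == ("g1", "g2", "g3")
        i = bank.positions["g2"]
        assert bank.templates[0][i] == 1 and bank.templates[1][i] == 1
        assert bank.has_overlap

    def test_unbalanced_sizes_sum(self):
        sigs = SignatureSet.from_dict(
            {
                "small": [f"s{i}" for i in range(19)],
                "large": [f"l{i}" for i in range(956)],
            }
        )
        bank = build_template_bank(sigs)
        assert bank.n_genes == 975

    @pytest.mark.parametrize(
        "mapping,message",
        [
            ({"A": ["g1"]}, "two classes"),
            ({"A": [], "B": ["g1"]}, "empty"),
            ({"A": ["g1", "g1"], "B": ["g2"]}, "duplicate"),
        ],
    )
    def test_invalid_signatures_rejected(self, mapping, message):
        with pytest.raises(ValueError, match=message):
            SignatureSet.from_dict(mapping)

    def test_drop_class_removes_label_and_genes(self, three_class_signatures):
        reduced = three_class_signatures.drop_class("alpha")
        assert reduced.classes == ("beta", "gamma")
        assert "a0" not in {g for c in reduced.classes for g in reduced.genes_by_class[c]}


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------


def brute_force_classic(patterns):
    pat = np.asarray(patterns, dtype=float)
    p, n = pat.shape
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                w[i, j] = sum(pat[mu, i] * pat[mu, j] for mu in range(p)) / n
    return w


def block_form_weights(bank):
    """±p/N shortcut for non-overlapping signatures (oracle)."""
    cls = bank.class_of_gene
    p, n = bank.n_classes, bank.n_genes
    w = np.where(cls[:, None] == cls[None, :], p / n, -p / n)
    np.fill_diagonal(w, 0.0)
    return w


class TestHebbWeights:
    def test_single_pattern_entries(self):
        rng = np.random.default_rng(0)
        xi = random_patterns(8, 1, rng)[0]
        w = hebb_weights_classic([xi])
        for i, j in [(0, 3), (2, 7), (4, 5)]:
            assert w[i, j] == pytest.approx(xi[i] * xi[j] / 8)

    def test_classic_matches_brute_force(self):
        rng = np.random.default_rng(1)
        pats = random_patterns(6, 3, rng)
        np.testing.assert_allclose(
            hebb_weights_classic(pats), brute_force_classic(pats), atol=1e-15
        )

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        for p in (1, 4):
            w = hebb_weights_classic(random_patterns(10, p, rng))
            np.testing.assert_allclose(w, w.T)
            assert np.all(np.diag(w) == 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hebb_weights_classic([np.ones(3), np.ones(4)])

    def test_modified_rule_block_values(self):
        sigs = SignatureSet.from_dict(
            {f"c{k}": [f"g{k}{j}" for j in range(3)] for k in range(3)}
        )
        bank = build_template_bank(sigs)
        w = hebb_weights_hope(bank)
        assert w[0, 1] == pytest.approx(1 / 3)  # same class, p/N = 3/9
        assert w[0, 4] == pytest.approx(-1 / 3)  # different classes

    def test_two_class_entries(self, two_class_bank):
        w = hebb_weights_hope(two_class_bank)
        off = w[~np.eye(6, dtype=bool)]
        assert np.all(np.isclose(off, 1 / 3) | np.isclose(off, -1 / 3))

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_general_form_equals_block_form(self, seed):
        sigs = random_disjoint_signatures(np.random.default_rng(seed))
        bank = build_template_bank(sigs)
        np.testing.assert_allclose(
            hebb_weights_hope(bank), block_form_weights(bank), atol=1e-14
        )


# ---------------------------------------------------------------------------
# fields and energy
# ---------------------------------------------------------------------------


class TestFieldsAndEnergy:
    def test_template_field_positive_on_own_class(self, two_class_bank, two_class_weights):
        x = two_class_bank.templates[0].astype(float)
        p, n = 2, 6
        for i in range(3):
            assert local_field(two_class_weights, x, i) == pytest.approx(
                p / n * (n - 1)
            )

    def test_zero_state_zero_field(self, two_class_weights):
        x = np.zeros(6)
        assert all(local_field(two_class_weights, x, i) == 0 for i in range(6))

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_class_sum_shortcut_equals_dense(self, seed):
        rng = np.random.default_rng(seed)
        sigs = random_disjoint_signatures(rng)
        bank = build_template_bank(sigs)
        w = hebb_weights_hope(bank)
        x = rng.integers(-1, 2, size=bank.n_genes).astype(float)
        for i in range(bank.n_genes):
            assert class_sum_local_field(bank, x, i) == pytest.approx(
                local_field(w, x, i), abs=1e-12
            )

    def test_zero_state_zero_energy(self, two_class_weights):
        assert energy(two_class_weights, np.zeros(6)) == 0.0

    def test_template_energy_brute_force(self, two_class_bank, two_class_weights):
        # E = -1/2 sum_ij W_ij x_i x_j evaluated by explicit double loop
        x = two_class_bank.templates[0].astype(float)
        e = -0.5 * sum(
            two_class_weights[i, j] * x[i] * x[j]
            for i in range(6)
            for j in range(6)
        )
        assert e == pytest.approx(-5.0)  # -(p/2)(N-1)
        assert energy(two_class_weights, x) == pytest.approx(e)

    def test_energy_sign_symmetry(self, two_class_weights):
        rng = np.random.default_rng(3)
        x = rng.integers(-1, 2, size=6).astype(float)
        assert energy(two_class_weights, x) == pytest.approx(
            energy(two_class_weights, -x)
        )

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_block_energy_equals_dense(self, seed):
        rng = np.random.default_rng(seed)
        sigs = random_disjoint_signatures(rng)
        bank = build_template_bank(sigs)
        w = hebb_weights_hope(bank)
        x = rng.integers(-1, 2, size=bank.n_genes)
        assert block_energy(bank, x) == pytest.approx(energy(w, x), abs=1e-10)


# ---------------------------------------------------------------------------
# classical dynamics
# ---------------------------------------------------------------------------


class TestClassicDynamics:
    def test_stored_pattern_is_fixed_point(self):
        rng = np.random.default_rng(4)
        xi = random_patterns(20, 1, rng)[0].astype(float)
        w = hebb_weights_classic([xi])
        out = async_sweep_classic(xi, w, rng.permutation(20))
        np.testing.assert_array_equal(out, xi)

    def test_corrupted_pattern_restored(self):
        rng = np.random.default_rng(5)
        xi = random_patterns(50, 1, rng)[0].astype(float)
        w = hebb_weights_classic([xi])
        noisy = xi.copy()
        flip = rng.choice(50, size=5, replace=False)
        noisy[flip] *= -1
        restored, _ = classic_fixed_point(noisy, w, rng)
        np.testing.assert_array_equal(restored, xi)

    def test_energy_never_increases(self):
        rng = np.random.default_rng(6)
        pats = random_patterns(30, 3, rng)
        w = hebb_weights_classic(pats)
        for _ in range(5):
            x = random_patterns(30, 1, rng)[0].astype(float)
            for _ in range(4):
                e_before = energy(w, x)
                x = async_sweep_classic(x, w, rng.permutation(30))
                assert energy(w, x) <= e_before + 1e-9


# ---------------------------------------------------------------------------
# asymmetric diluted dynamics
# ---------------------------------------------------------------------------


class TestAsymmetricDynamics:
    def test_template_is_fixed_point(self, two_class_bank, two_class_weights):
        state = NetworkState.from_vector(two_class_bank.templates[0])
        rng = np.random.default_rng(7)
        out = async_sweep_asymmetric(state, two_class_weights, rng.permutation(6))
        np.testing.assert_array_equal(out.x, state.x)
        assert out.eliminated == 0

    def test_zero_nodes_never_revive(self, two_class_bank, two_class_weights):
        x = two_class_bank.templates[0].copy()
        x[1] = 0
        state = NetworkState.from_vector(x)
        rng = np.random.default_rng(8)
        for _ in range(3):
            state = async_sweep_asymmetric(
                state, two_class_weights, rng.permutation(6)
            )
            assert state.x[1] == 0

    def test_elimination_bookkeeping(self, two_class_bank, two_class_weights):
        # one up-gene in the losing class is eliminated, not flipped to -1
        x = np.array([1, 1, 1, 1, -1, -1], dtype=np.int8)
        state = NetworkState.from_vector(x)
        out = async_sweep_asymmetric(state, two_class_weights, list(range(6)))
        assert out.x[3] == 0
        assert out.eliminated == 1
        assert -1 not in np.sign(out.x[3:4])


class TestMatchFraction:
    def test_exact_match(self, two_class_bank):
        t = two_class_bank.templates[0]
        assert match_fraction(t, t, np.ones(6, bool)) == 1.0

    def test_one_elimination_in_twenty(self):
        template = np.ones(20, dtype=np.int8)
        state = template.copy()
        state[0] = 0
        assert match_fraction(state, template, np.ones(20, bool)) == pytest.approx(0.95)

    def test_orthogonal_state_low_match(self, two_class_bank):
        t0, t1 = two_class_bank.templates
        assert match_fraction(t1, t0, np.ones(6, bool)) == 0.0

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError, match="empty denominator"):
            match_fraction(np.ones(3), np.ones(3), np.zeros(3, bool))


class TestEvolveToClass:
    def test_template_converges_immediately(self, two_class_bank, two_class_weights):
        state = NetworkState.from_vector(two_class_bank.templates[1])
        out = evolve_to_class(
            state, two_class_bank, two_class_weights, HopeConfig(), np.random.default_rng(9)
        )
        assert out.converged_class == "B"
        assert out.match_fraction == 1.0
        assert out.sweeps <= 1
        assert out.energy_initial == pytest.approx(-5.0)

    def test_small_network_toy_all_orders(self, two_class_bank, two_class_weights):
        """Six-gene toy: (+1,+1,-1 | -1,-1,+1) settles on class A.

        The lone up-gene of class B is always eliminated, capping the match
        at 5/6, so the convergence threshold is set to the granularity a
        six-gene network supports.  Every one of the 720 asynchronous orders
        gives the same answer.
        """
        x0 = np.array([1, 1, -1, -1, -1, 1], dtype=np.int8)
        config = HopeConfig(match_threshold=0.8)
        for order in itertools.permutations(range(6)):
            state = NetworkState.from_vector(x0)
            while True:
                nxt = async_sweep_asymmetric(state, two_class_weights, list(order))
                if np.array_equal(nxt.x, state.x):
                    break
                state = nxt
            fr_a = match_fraction(
                state.x, two_class_bank.templates[0], state.active0
            )
            fr_b = match_fraction(
                state.x, two_class_bank.templates[1], state.active0
            )
            assert fr_a >= config.match_threshold
            assert fr_a == pytest.approx(5 / 6)
            assert fr_b < config.match_threshold

    def test_ambiguous_input_returns_none(self):
        # three spurious up-genes in the losing class: eliminations exceed
        # the 5% budget, so no template reaches the 95% criterion
        sigs = SignatureSet.from_dict(
            {"A": [f"a{i}" for i in range(10)], "B": [f"b{i}" for i in range(10)]}
        )
        bank = build_template_bank(sigs)
        w = hebb_weights_hope(bank)
        x = bank.templates[0].copy()
        x[[10, 11, 12]] = 1
        out = evolve_to_class(
            NetworkState.from_vector(x), bank, w, HopeConfig(), np.random.default_rng(10)
        )
        assert out.converged_class is None
        assert out.eliminated >= 3

    def test_all_zero_state_degenerate(self, two_class_bank, two_class_weights):
        out = evolve_to_class(
            NetworkState.from_vector(np.zeros(6, dtype=np.int8)),
            two_class_bank,
            two_class_weights,
            HopeConfig(),
            np.random.default_rng(11),
        )
        assert out.converged_class is None


# ---------------------------------------------------------------------------
# storage capacity and the analytic bound
# ---------------------------------------------------------------------------


class TestCapacity:
    def test_single_pattern_always_retrieved(self):
        rng = np.random.default_rng(12)
        est = estimate_capacity(100, [0.005], trials=3, rng=rng)
        assert est.retrieved_fraction[0.005] == 1.0

    def test_retrieval_decreases_with_load(self):
        rng = np.random.default_rng(13)
        est = estimate_capacity(150, [0.05, 0.25], trials=3, rng=rng)
        assert est.retrieved_fraction[0.05] > 0.9
        assert est.retrieved_fraction[0.25] < est.retrieved_fraction[0.05]

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            estimate_capacity(50, [0.1], 2, np.random.default_rng(0))


class TestStorageBound:
    def test_minimal_size_is_fixed_point_boundary(self):
        import math

        for p in (2, 4, 6):
            n = minimal_stable_size(p)
            bound = lambda m: p * math.log(p * m / (0.0002 * math.pi))
            assert n > bound(n)
            assert not (n - 1) > bound(n - 1)

    def test_recall_probability_decreases_with_load(self):
        assert perfect_recall_probability(80, 2) > perfect_recall_probability(80, 6)
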