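"""Randomization procedures: conditional probabilities, generation, enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from randeval.procedures import (
    ConfigurationError,
    EnumerationLimitError,
    FeasibilityError,
    ProcedureSpec,
    enumerate_sequences,
    generate_sequence,
    generate_sequences,
    imbalance_bound,
    next_allocation_prob,
    sequence_probability,
)
from randeval.sequences import AllocationSequence, imbalance_profile


def seq(labels: str) -> AllocationSequence:
    return AllocationSequence.from_labels(labels)


# a representative spec of each procedure family, with an N they all accept
ALL_SPECS = [
    ProcedureSpec.cr(),
    ProcedureSpec.rar(),
    ProcedureSpec.pbr(2),
    ProcedureSpec.bsd(2),
    ProcedureSpec.mp(2),
    ProcedureSpec.mp(2, terminal_balance=False),
    ProcedureSpec.ebc(2 / 3),
    ProcedureSpec.chen(2, 2 / 3),
    ProcedureSpec.ud(1, 1),
]


class TestNextAllocationProb:
    @pytest.mark.parametrize(
        "spec, history, n, expected",
        [
            (ProcedureSpec.cr(), "", 8, 0.5),
            (ProcedureSpec.cr(), "EEEE", 8, 0.5),
            (ProcedureSpec.bsd(1), "E", 8, 0.0),  # forced C at |D| = a
            (ProcedureSpec.bsd(1), "EC", 8, 0.5),
            (ProcedureSpec.bsd(3), "EE", 8, 0.5),
            # urn: one initial ball per arm, one C ball added after drawing E
            (ProcedureSpec.ud(1, 1), "E", 8, 1 / 3),
            (ProcedureSpec.ud(0, 1), "", 8, 0.5),  # empty urn -> fair coin
            (ProcedureSpec.ud(0, 0), "EC", 8, 0.5),  # degenerate urn -> fair coin
            (ProcedureSpec.ebc(2 / 3), "E", 8, 1 / 3),
            (ProcedureSpec.ebc(2 / 3), "C", 8, 2 / 3),
            (ProcedureSpec.ebc(2 / 3), "EC", 8, 0.5),
            (ProcedureSpec.chen(2, 2 / 3), "EE", 8, 0.0),  # forced at MTI
            (ProcedureSpec.chen(2, 2 / 3), "E", 8, 1 / 3),  # biased coin inside MTI
            (ProcedureSpec.rar(), "", 4, 0.5),
            (ProcedureSpec.rar(), "EE", 4, 0.0),  # E allocations exhausted
            (ProcedureSpec.rar(), "EC", 4, 0.5),
            (ProcedureSpec.pbr(2), "E", 4, 0.0),  # within-block forcing
            (ProcedureSpec.pbr(2), "EC", 4, 0.5),  # fresh block
            (ProcedureSpec.mp(1), "", 4, 0.5),
        ],
    )
    def test_examples(self, spec, history, n, expected):
        assert next_allocation_prob(spec, history, n) == pytest.approx(expected, abs=1e-12)

    def test_infeasible_prefix_raises(self):
        with pytest.raises(FeasibilityError):
            next_allocation_prob(ProcedureSpec.rar(), "EEE", 4, )
        with pytest.raises(FeasibilityError):
            next_allocation_prob(ProcedureSpec.bsd(1), "EE", 8)
        with pytest.raises(FeasibilityError):
            next_allocation_prob(ProcedureSpec.mp(1), "EE", 4)

    def test_exhausted_history_raises(self):
        with pytest.raises(ValueError):
            next_allocation_prob(ProcedureSpec.cr(), "ECEC", 4)


class TestMaximalProcedure:
    """MP sampled via exact dynamic-programming path counts."""

    def brute_force(self, n, a, terminal_balance):
        """All admissible sequences under MTI a (and optional terminal balance)."""
        admissible = []
        for bits in itertools.product((0, 1), repeat=n):
            d = np.cumsum(2 * np.asarray(bits) - 1)
            if np.abs(d).max() <= a and (not terminal_balance or d[-1] == 0):
                admissible.append(bits)
        return admissible

    @pytest.mark.parametrize("n, a, tb", [(4, 1, True), (4, 2, True), (6, 2, True), (6, 1, False), (6, 3, False)])
    def test_uniform_over_admissible(self, n, a, tb):
        expected = self.brute_force(n, a, tb)
        got = enumerate_sequences(ProcedureSpec.mp(a, terminal_balance=tb), n)
        assert {tuple(s.assignments) for s, _ in got} == set(expected)
        for _, p in got:
            assert p == pytest.approx(1.0 / len(expected), abs=1e-12)

    def test_mti_one_n4(self):
        # MTI 1 with terminal balance: D(2k) forced 0, so 4 admissible sequences
        got = enumerate_sequences(ProcedureSpec.mp(1), 4)
        labels = sorted(str(s) for s, _ in got)
        assert labels == ["CECE", "CEEC", "ECCE", "ECEC"]


class TestSequenceProbability:
    @pytest.mark.parametrize(
        "spec, labels, expected",
        [
            (ProcedureSpec.rar(), "EECC", 1 / 6),  # (2/4)(1/3)(1)(1)
            (ProcedureSpec.ebc(2 / 3), "ECE", 1 / 6),  # (1/2)(2/3)(1/2)
            (ProcedureSpec.bsd(1), "EECC", 0.0),  # prefix EE violates MTI
            (ProcedureSpec.cr(), "ECCE", 1 / 16),
            (ProcedureSpec.ud(1, 1), "EC", (1 / 2) * (2 / 3)),
        ],
    )
    def test_examples(self, spec, labels, expected):
        assert sequence_probability(spec, labels) == pytest.approx(expected, abs=1e-12)

    def test_rar_uniform_over_balanced(self):
        # every balanced sequence has probability 1/C(N, N/2)
        pairs = enumerate_sequences(ProcedureSpec.rar(), 4)
        assert len(pairs) == 6
        for s, p in pairs:
            assert p == pytest.approx(1 / 6, abs=1e-12)
            assert s.n_e == 2


class TestEnumeration:
    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.label)
    def test_probabilities_sum_to_one(self, spec):
        pairs = enumerate_sequences(spec, 6)
        total = sum(p for _, p in pairs)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_cr_counts(self):
        assert len(enumerate_sequences(ProcedureSpec.cr(), 3)) == 8
        pairs = enumerate_sequences(ProcedureSpec.pbr(2), 4)
        assert len(pairs) == 4
        assert all(p == pytest.approx(0.25) for _, p in pairs)

    def test_limit_guard(self):
        with pytest.raises(EnumerationLimitError):
            enumerate_sequences(ProcedureSpec.cr(), 25)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.label)
    def test_matches_empirical_frequencies(self, spec):
        """Exact sequence probabilities agree with sampled frequencies."""
        n, r = 6, 100_000
        pairs = enumerate_sequences(spec, n)
        rng = np.random.default_rng(2024)
        draws = generate_sequences(spec, n, r, rng)
        keys = draws @ (1 << np.arange(n))
        counts = np.bincount(keys, minlength=2**n)
        seen = set()
        for s, p in pairs:
            key = int(s.assignments @ (1 << np.arange(n)))
            seen.add(key)
            se = np.sqrt(p * (1 - p) / r)
            assert abs(counts[key] / r - p) <= 4 * se + 1e-12
        # no probability mass outside the enumerated support
        assert counts[[k for k in range(2**n) if k not in seen]].sum() == 0


class TestGenerationInvariants:
    @pytest.mark.parametrize(
        "spec", [ProcedureSpec.bsd(2), ProcedureSpec.chen(2, 0.7), ProcedureSpec.mp(2)],
        ids=lambda s: s.label,
    )
    def test_mti_never_exceeded(self, spec):
        rng = np.random.default_rng(5)
        tm = generate_sequences(spec, 12, 20_000, rng)
        d = np.cumsum(2 * tm - 1, axis=1)
        assert np.abs(d).max() <= 2

    @pytest.mark.parametrize(
        "spec", [ProcedureSpec.rar(), ProcedureSpec.pbr(4), ProcedureSpec.mp(3)],
        ids=lambda s: s.label,
    )
    def test_terminal_balance(self, spec):
        rng = np.random.default_rng(6)
        tm = generate_sequences(spec, 12, 20_000, rng)
        assert (tm.sum(axis=1) == 6).all()

    def test_pbr_block_balance(self):
        rng = np.random.default_rng(7)
        tm = generate_sequences(ProcedureSpec.pbr(2), 8, 5_000, rng)
        cum = np.cumsum(tm, axis=1)
        for block_end, target in [(2, 1), (4, 2), (6, 3), (8, 4)]:
            assert (cum[:, block_end - 1] == target).all()

    def test_reproducible_given_seed(self):
        a = generate_sequences(ProcedureSpec.ud(1, 2), 10, 50, np.random.default_rng(42))
        b = generate_sequences(ProcedureSpec.ud(1, 2), 10, 50, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_generate_single(self):
        s = generate_sequence(ProcedureSpec.rar(), 8, np.random.default_rng(0))
        assert s.n == 8 and s.n_e == 4


class TestReductions:
    def test_ebc_half_and_degenerate_urn_reduce_to_cr(self):
        for spec in (ProcedureSpec.ebc(0.5), ProcedureSpec.ud(3, 0)):
            for labels in ("", "E", "EE", "ECC", "EECCE"):
                assert next_allocation_prob(spec, labels, 8) == 0.5

    def test_pbr_full_block_is_rar(self):
        n = 6
        rar = dict(
            (tuple(s.assignments), p) for s, p in enumerate_sequences(ProcedureSpec.rar(), n)
        )
        pbr = dict(
            (tuple(s.assignments), p) for s, p in enumerate_sequences(ProcedureSpec.pbr(n), n)
        )
        assert rar.keys() == pbr.keys()
        for key in rar:
            assert rar[key] == pytest.approx(pbr[key], abs=1e-12)


class TestValidation:
    def test_configuration_errors(self):
        with pytest.raises(ConfigurationError):
            ProcedureSpec.pbr(3)  # odd block size
        with pytest.raises(ConfigurationError):
            ProcedureSpec("CR", mti=2)  # parameter not taken
        with pytest.raises(ConfigurationError):
            ProcedureSpec("PBR")  # missing block size
        with pytest.raises(ConfigurationError):
            ProcedureSpec.ebc(0.3)  # coin below 1/2
        with pytest.raises(ConfigurationError):
            generate_sequences(ProcedureSpec.pbr(4), 6, 1, np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            generate_sequences(ProcedureSpec.rar(), 7, 1, np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            generate_sequences(ProcedureSpec.mp(2), 7, 1, np.random.default_rng(0))

    def test_mp_without_terminal_balance_allows_odd_n(self):
        tm = generate_sequences(
            ProcedureSpec.mp(2, terminal_balance=False), 7, 500, np.random.default_rng(1)
        )
        assert np.abs(np.cumsum(2 * tm - 1, axis=1)).max() <= 2

    def test_from_params_aliases(self):
        assert ProcedureSpec.from_params("pbr", b=4) == ProcedureSpec.pbr(4)
        assert ProcedureSpec.from_params("CHEN", a=2, p=0.67) == ProcedureSpec.chen(2, 0.67)
        assert ProcedureSpec.from_params("UD", alpha=1, beta=2) == ProcedureSpec.ud(1, 2)

    def test_imbalance_bound(self):
        assert imbalance_bound(ProcedureSpec.bsd(3), 20) == 3
        assert imbalance_bound(ProcedureSpec.pbr(4), 20) == 2
        assert imbalance_bound(ProcedureSpec.rar(), 20) == 10
        assert imbalance_bound(ProcedureSpec.cr(), 20) == 20


class TestImbalanceProfile:
    @pytest.mark.parametrize(
        "labels, profile",
        [("ECEC", [1, 0, 1, 0]), ("EEEE", [1, 2, 3, 4]), ("CCEE", [-1, -2, -1, 0])],
    )
    def test_examples(self, labels, profile):
        assert list(seq(labels).imbalance_profile()) == profile

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_steps_of_one(self, bits):
        d = imbalance_profile(bits)
        steps = np.diff(np.concatenate(([0], d)))
        assert set(np.abs(steps)) == {1}
        assert d[-1] == 2 * sum(bits) - len(bits)
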