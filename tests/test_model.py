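"""PPM-C count tables, escape cascade code lengths, updates, serialization."""

import math
from collections import Counter
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from ppmadl import ESC, Missing, PPMActivityModel, train
from ppmadl.model import _context_total

TIME_SYMS = "abcdef"
LOC_SYMS = "ghijkl"
ACT_SYMS = "mnopqr"


def triplet_strategy(max_size=200):
    one = st.tuples(
        st.sampled_from(TIME_SYMS), st.sampled_from(LOC_SYMS), st.sampled_from(ACT_SYMS)
    )
    return st.lists(one, max_size=max_size)


def brute_force_tables(triplets):
    """Independent tally of all context counts, written without the model code."""
    order2, t_l, l_a, order0 = {}, {}, {}, Counter()
    for t, l, a in triplets:
        order2.setdefault((t, l), Counter())[a] += 1
        t_l.setdefault(t, Counter())[l] += 1
        l_a.setdefault(l, Counter())[a] += 1
        for s in (t, l, a):
            order0[s] += 1
    return order2, t_l, l_a, order0


class TestCountTables:
    """The five-triplet hand example must reproduce every published table cell."""

    @pytest.mark.parametrize(
        "context,symbol,count,prob",
        [
            (("a", "c"), "t", 2, Fraction(2, 3)),
            (("i", "c"), "k", 1, Fraction(1, 2)),
            (("i", "o"), "n", 1, Fraction(1, 2)),
            (("i", "v"), "e", 1, Fraction(1, 2)),
        ],
    )
    def test_order2_cells(self, example_model, context, symbol, count, prob):
        assert example_model.order2_[context][symbol] == count
        assert example_model.prob(2, context, symbol) == prob

    @pytest.mark.parametrize(
        "context,expected",
        [
            ("a", {"c": (2, Fraction(2, 3))}),
            ("i", {"c": (1, Fraction(1, 6)), "o": (1, Fraction(1, 6)), "v": (1, Fraction(1, 6))}),
            ("c", {"k": (1, Fraction(1, 5)), "t": (2, Fraction(2, 5))}),
            ("o", {"n": (1, Fraction(1, 2))}),
            ("v", {"e": (1, Fraction(1, 2))}),
        ],
    )
    def test_order1_cells(self, example_model, context, expected):
        for symbol, (count, prob) in expected.items():
            assert example_model.prob(1, context, symbol) == prob
        table = (
            example_model.time_location_.get(context)
            or example_model.location_activity_[context]
        )
        assert {s: c for s, c in table.items()} == {
            s: c for s, (c, _) in expected.items()
        }

    @pytest.mark.parametrize(
        "context,esc_prob",
        [
            (("a", "c"), Fraction(1, 3)),
            (("i", "c"), Fraction(1, 2)),
            ("a", Fraction(1, 3)),
            ("i", Fraction(3, 6)),
            ("c", Fraction(2, 5)),
        ],
    )
    def test_escape_probabilities(self, example_model, context, esc_prob):
        order = 2 if isinstance(context, tuple) else 1
        assert example_model.prob(order, context, ESC) == esc_prob

    def test_order0_denominator_is_occurrences_plus_distinct(self, example_model):
        # 15 symbol occurrences + 9 distinct symbols
        assert _context_total(example_model.order0_) == 24
        assert example_model.prob(0, None, ESC) == Fraction(9, 24)
        assert example_model.prob(0, None, "c") == Fraction(3, 24)
        assert example_model.prob(0, None, "a") == Fraction(2, 24)
        assert example_model.prob(0, None, "k") == Fraction(1, 24)

    def test_alphabet(self, example_model):
        assert example_model.alphabet_ == frozenset("activeonk")

    def test_empty_training_allowed(self):
        m = PPMActivityModel().fit([])
        assert len(m.alphabet_) == 0 and m.n_triplets_ == 0

    @settings(deadline=None, max_examples=100)
    @given(triplet_strategy())
    def test_counts_match_brute_force_oracle(self, triplets):
        m = train(triplets)
        o2, tl, la, o0 = brute_force_tables(triplets)
        assert m.order2_ == o2
        assert m.time_location_ == tl
        assert m.location_activity_ == la
        assert m.order0_ == o0

    @settings(deadline=None, max_examples=60)
    @given(triplet_strategy(max_size=120))
    def test_ppmc_escape_law_and_normalization(self, triplets):
        """In every context: esc count = distinct successors; probs sum to 1."""
        m = train(triplets)
        contexts = (
            [(2, ctx, c) for ctx, c in m.order2_.items()]
            + [(1, ctx, c) for ctx, c in m.time_location_.items()]
            + [(1, ctx, c) for ctx, c in m.location_activity_.items()]
        )
        if triplets:
            contexts.append((0, None, m.order0_))
        for order, ctx, counter in contexts:
            assert m.prob(order, ctx, ESC) == Fraction(
                len(counter), _context_total(counter)
            )
            total = sum(
                (m.prob(order, ctx, s) for s in counter), m.prob(order, ctx, ESC)
            )
            assert total == 1


class TestProb:
    def test_unknown_context_signals_not_raises(self, example_model):
        assert example_model.prob(2, ("z", "z"), "t") is Missing.CONTEXT
        assert example_model.prob(1, "z", "t") is Missing.CONTEXT

    def test_absent_symbol_in_existing_context_is_not_zero(self, example_model):
        assert example_model.prob(2, ("a", "c"), "k") is Missing.SYMBOL
        assert example_model.prob(1, "o", "e") is Missing.SYMBOL

    def test_invalid_order_rejected(self, example_model):
        with pytest.raises(ValueError, match="order"):
            example_model.prob(3, ("a", "c"), "t")


class TestUniformBits:
    def test_worked_example_alphabet(self, example_model):
        assert round(example_model.uniform_bits(), 2) == 9.51

    @pytest.mark.parametrize(
        "triplets,bits",
        [([("a", "a", "a")], 0.0), ([("a", "b", "a")], 3.0)],
    )
    def test_small_alphabets(self, triplets, bits):
        assert train(triplets).uniform_bits() == pytest.approx(bits)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            PPMActivityModel().fit([]).uniform_bits()


class TestCodeLength:
    @pytest.mark.parametrize(
        "triplet,bits",
        [
            # hand-derived through the escape cascade (escapes cost 0 bits):
            (("a", "c", "k"), 2.91),  # order-1 a→c (2/3) and c→k (1/5)
            (("a", "v", "e"), 4.58),  # v→e (1/2) and order-0 P(a)=1/12
            (("s", "o", "n"), 2.42),  # o→n (1/2) and order-0 P(esc)=9/24
            (("i", "c", "n"), 7.17),  # i→c (1/6) and order-0 P(n)=1/24
            (("a", "c", "t"), 1.17),  # full match: P(t|ac)=2/3 and a→c (2/3)
        ],
    )
    def test_cascade_scenarios(self, example_model, triplet, bits):
        assert round(example_model.code_length(triplet).total_bits, 2) == bits

    def test_breakdown_factors_for_order2_miss(self, example_model):
        steps = example_model.code_length(("a", "c", "k")).steps
        assert [(s.order, s.probability) for s in steps] == [
            (1, Fraction(2, 3)),
            (1, Fraction(1, 5)),
        ]

    def test_breakdown_uses_escape_for_unseen_symbol(self, example_model):
        steps = example_model.code_length(("s", "o", "n")).steps
        assert steps[-1].symbol is ESC and steps[-1].probability == Fraction(9, 24)

    def test_total_bits_is_neg_log_of_factor_product(self, example_model):
        cb = example_model.code_length(("i", "c", "n"))
        assert cb.total_bits == pytest.approx(-math.log2(float(cb.probability)))

    @settings(deadline=None, max_examples=60)
    @given(
        triplet_strategy(max_size=60),
        st.tuples(
            st.sampled_from(TIME_SYMS + "Z"),
            st.sampled_from(LOC_SYMS + "Z"),
            st.sampled_from(ACT_SYMS + "Z"),
        ),
    )
    def test_finite_and_positive_for_any_query(self, triplets, query):
        """Any printable triplet is codable against a nonempty model."""
        m = train(triplets + [("a", "g", "m")])
        bits = m.code_length(query).total_bits
        assert math.isfinite(bits) and bits > 0


class TestUpdateCounts:
    def test_empty_update_is_identity(self, example_model):
        before = example_model.to_json()
        assert example_model.partial_fit([]).to_json() == before

    def test_update_equals_batch_retrain(self, example, example_model):
        updated = example_model.partial_fit([("a", "c", "k")])
        batch = train(list(example.training) + [("a", "c", "k")])
        assert updated.equals(batch)
        assert updated.time_location_["a"]["c"] == 3
        assert updated.location_activity_["c"]["k"] == 2

    @settings(deadline=None, max_examples=60)
    @given(triplet_strategy(max_size=30), st.integers(0, 30))
    def test_path_independence(self, triplets, cut):
        """Any train/update split of a stream yields the identical model."""
        cut = min(cut, len(triplets))
        split = PPMActivityModel().fit(triplets[:cut]).partial_fit(triplets[cut:])
        whole = train(triplets)
        assert split.equals(whole)
        assert split.training_triplets_ == whole.training_triplets_


class TestSerialization:
    def test_worked_example_roundtrip(self, example_model):
        restored = PPMActivityModel.from_json(example_model.to_json())
        assert restored.equals(example_model)
        assert restored.training_triplets_ == example_model.training_triplets_
        assert restored.to_json() == example_model.to_json()

    def test_empty_model_roundtrip(self):
        m = PPMActivityModel().fit([])
        assert PPMActivityModel.from_json(m.to_json()).equals(m)

    def test_store_training_false_roundtrip(self, example):
        m = PPMActivityModel(store_training=False).fit(example.training)
        restored = PPMActivityModel.from_json(m.to_json())
        assert restored.training_triplets_ is None and restored.equals(m)

    @pytest.mark.parametrize(
        "payload",
        [
            "not json at all",
            "{}",
            '{"format": "something-else", "version": 1}',
            '{"format": "ppmadl-model", "version": 99}',
            '{"format": "ppmadl-model", "version": 1, "store_training": true}',
        ],
    )
    def test_malformed_payloads_rejected(self, payload):
        with pytest.raises(ValueError):
            PPMActivityModel.from_json(payload)

    @settings(deadline=None, max_examples=100)
    @given(triplet_strategy(max_size=80))
    def test_random_model_roundtrip(self, triplets):
        m = train(triplets)
        assert PPMActivityModel.from_json(m.to_json()).equals(m)


class TestSklearnCompat:
    def test_get_set_params(self):
        m = PPMActivityModel()
        assert m.get_params() == {"store_training": True}
        m.set_params(store_training=False)
        assert m.store_training is False

    def test_unfitted_queries_raise(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            PPMActivityModel().code_length(("a", "b", "c"))

    def test_invalid_triplets_rejected(self):
        with pytest.raises(ValueError, match="triplet 0"):
            PPMActivityModel().fit([("ab", "c", "d")])
        with pytest.raises(ValueError, match="triplet 1"):
            PPMActivityModel().fit(["act", ("a", "b")])
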