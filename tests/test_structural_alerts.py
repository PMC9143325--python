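import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ditptox.featurization import FeatureBlock
from ditptox.structural_alerts import (
    AlertError,
    fragment_frequency,
    information_gain,
    mine_alerts,
)


def brute_force_ig(frag, y):
    """First-principles entropy from the 2x2 contingency counts."""
    import math

    def ent(counts):
        n = sum(counts)
        if n == 0:
            return 0.0
        out = 0.0
        for c in counts:
            if c:
                out -= (c / n) * math.log2(c / n)
        return out

    n = len(y)
    n11 = sum(1 for f, t in zip(frag, y) if f == 1 and t == 1)
    n10 = sum(1 for f, t in zip(frag, y) if f == 1 and t == 0)
    n01 = sum(1 for f, t in zip(frag, y) if f == 0 and t == 1)
    n00 = sum(1 for f, t in zip(frag, y) if f == 0 and t == 0)
    total = ent([n11 + n01, n10 + n00])
    cond = (n11 + n10) / n * ent([n11, n10]) + (n01 + n00) / n * ent([n01, n00])
    return total - cond


def _block(matrix):
    m = np.asarray(matrix, dtype=float)
    return FeatureBlock(
        "FRAG", "binary", m, [f"frag_{j}" for j in range(m.shape[1])],
        [f"r{i}" for i in range(m.shape[0])],
    )


class TestInformationGain:
    def test_ubiquitous_fragment_zero_gain(self):
        y = np.array([1, 0, 1, 0, 1])
        assert information_gain(np.ones(5), y) == 0.0

    def test_fragment_equal_to_labels_full_entropy(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        ig = information_gain(y.copy(), y)
        p = y.mean()
        ent = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
        assert ig == pytest.approx(ent)

    def test_hand_computed_twenty_compounds(self):
        # 8 toxicants of 20; fragment hits 6 toxicants and 2 non-toxicants
        y = np.array([1] * 8 + [0] * 12)
        frag = np.array([1] * 6 + [0] * 2 + [1] * 2 + [0] * 10)
        assert information_gain(frag, y) == pytest.approx(0.2565, abs=5e-4)

    def test_matches_brute_force_on_random_columns(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        for _ in range(1000):
            frag = rng.integers(0, 2, 60)
            assert information_gain(frag, y) == pytest.approx(
                brute_force_ig(frag, y), abs=1e-12
            )

    @given(st.integers(0, 2**20 - 1))
    def test_bit_inversion_symmetry(self, pattern):
        frag = np.array([(pattern >> i) & 1 for i in range(20)])
        y = np.array([1] * 8 + [0] * 12)
        assert information_gain(frag, y) == pytest.approx(
            information_gain(1 - frag, y), abs=1e-12
        )

    def test_length_mismatch_errors(self):
        with pytest.raises(AlertError, match="length"):
            information_gain([1, 0], [1, 0, 1])


class TestFragmentFrequency:
    def test_ubiquitous_fragment_is_one(self):
        assert fragment_frequency(8, 20, 20, 8) == 1.0

    def test_hand_arithmetic(self):
        assert fragment_frequency(6, 20, 8, 8) == pytest.approx(1.875)

    def test_absent_from_positives_is_zero(self):
        assert fragment_frequency(0, 20, 5, 8) == 0.0

    def test_zero_denominator_errors(self):
        with pytest.raises(AlertError):
            fragment_frequency(1, 20, 0, 8)

    def test_strictly_increasing_in_positive_count(self):
        vals = [fragment_frequency(k, 50, 10, 20) for k in range(11)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_weighted_frequencies_conserve(self, rng):
        # freq_P * nP/n + freq_N * nN/n == 1 for every fragment
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        frag = rng.integers(0, 2, 40)
        frag[:2] = 1
        n, n_p = 40, int(y.sum())
        n_ft = int(frag.sum())
        n_fp = int(frag[y == 1].sum())
        freq_p = fragment_frequency(n_fp, n, n_ft, n_p)
        freq_n = fragment_frequency(n_ft - n_fp, n, n_ft, n - n_p)
        assert freq_p * n_p / n + freq_n * (n - n_p) / n == pytest.approx(1.0)


class TestMineAlerts:
    def test_planted_alert_ranked_first(self, rng):
        n = 200
        y = np.array([1] * 80 + [0] * 120)
        noise = rng.integers(0, 2, (n, 200)) * (rng.random((n, 200)) < 0.25)
        planted = np.zeros(n)
        hot = rng.choice(80, 40, replace=False)  # 40 of 80 toxicants
        cold = 80 + rng.choice(120, 10, replace=False)  # 10 of 120 others
        planted[hot] = 1
        planted[cold] = 1
        block = _block(np.column_stack([noise, planted]))
        report = mine_alerts(block, y)
        assert report.alerts[0].fragment_id == "frag_200"
        # brute-force check: no column has higher IG
        igs = [information_gain(block.matrix[:, j], y) for j in range(201)]
        assert np.argmax(igs) == 200

    def test_occurrence_filter_strictly_more_than_six(self):
        y = np.array([1] * 10 + [0] * 10)
        six = np.array([1] * 6 + [0] * 14)     # exactly 6: excluded
        seven = np.array([1] * 7 + [0] * 13)   # 7: included
        block = _block(np.column_stack([six, seven]))
        ids = [a.fragment_id for a in mine_alerts(block, y).alerts]
        assert ids == ["frag_1"]

    def test_all_zero_column_excluded(self):
        y = np.array([1] * 10 + [0] * 10)
        block = _block(np.zeros((20, 3)))
        assert mine_alerts(block, y).alerts == []

    def test_negative_enrichment_excluded(self):
        y = np.array([1] * 10 + [0] * 10)
        neg_frag = np.array([0] * 10 + [1] * 10)  # only in non-toxicants
        report = mine_alerts(_block(neg_frag.reshape(-1, 1)), y)
        assert report.alerts == []
        assert report.all_stats[0].freq_P == 0.0

    def test_ranking_and_dataframe(self, rng):
        y = np.array([1] * 50 + [0] * 50)
        strong = np.array([1] * 40 + [0] * 10 + [1] * 5 + [0] * 45)
        weak = np.array([1] * 20 + [0] * 30 + [1] * 10 + [0] * 40)
        block = _block(np.column_stack([weak, strong]))
        report = mine_alerts(block, y)
        assert [a.fragment_id for a in report.alerts] == ["frag_1", "frag_0"]
        df = report.to_dataframe()
        assert list(df["fragment_id"]) == ["frag_1", "frag_0"]
        assert (df["freq_P"] > df["freq_N"]).all()

    def test_single_class_errors(self):
        with pytest.raises(AlertError, match="both classes"):
            mine_alerts(_block(np.ones((5, 2))), np.ones(5))
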