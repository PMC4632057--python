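"""clr transform, correlation statistics, and the detection-threshold test."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from venomconcord.concordance import (
    close,
    clr,
    concordance,
    detection_threshold_analysis,
    pearson_with_ci,
    spearman,
)

# integer-valued raw abundances keep distinct components distinct through
# closure and log (adversarial 1-ulp near-ties would break rank comparisons
# for floating-point reasons unrelated to the mathematics)
compositions = st.lists(
    st.integers(min_value=1, max_value=10**6).map(float), min_size=2, max_size=40
).map(lambda v: close(v))


class TestCloseAndClr:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ((2, 2), (0.5, 0.5)),
            ((1, 1, 2), (0.25, 0.25, 0.5)),
        ],
    )
    def test_closure(self, raw, expected):
        assert close(raw) == pytest.approx(expected)

    def test_zeros_rejected(self):
        with pytest.raises(ValueError):
            close((0, 1))
        with pytest.raises(ValueError):
            close((0, 0))
        with pytest.raises(ValueError):
            clr((0.0, 1.0))

    def test_uniform_maps_to_zero(self):
        assert clr(np.full(4, 0.25)) == pytest.approx(np.zeros(4), abs=1e-12)

    @pytest.mark.parametrize(
        "x, expected",
        [
            ((0.8, 0.2), (0.6931, -0.6931)),
            ((0.5, 0.25, 0.25), (0.4621, -0.2310, -0.2310)),
        ],
    )
    def test_reference_values(self, x, expected):
        assert clr(x) == pytest.approx(expected, abs=5e-4)

    @given(x=compositions)
    @settings(max_examples=300, derandomize=True)
    def test_components_sum_to_zero(self, x):
        assert abs(clr(x).sum()) < 1e-9

    def test_agrees_with_skbio(self):
        from skbio.stats.composition import clr as skbio_clr

        rng = np.random.default_rng(2)
        for _ in range(50):
            x = close(rng.dirichlet(np.full(rng.integers(2, 30), 0.7)) + 1e-9)
            assert clr(x) == pytest.approx(np.asarray(skbio_clr(x)), abs=1e-10)

    def test_clr_is_shifted_log(self):
        # clr subtracts a per-vector constant from the logs, so Pearson r on
        # clr pairs equals Pearson r on log pairs exactly
        rng = np.random.default_rng(3)
        x = close(rng.lognormal(0, 1, 30))
        y = close(rng.lognormal(0, 1, 30))
        r_clr = stats.pearsonr(clr(x), clr(y)).statistic
        r_log = stats.pearsonr(np.log(x), np.log(y)).statistic
        assert abs(r_clr - r_log) < 1e-12


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman([1, 2, 3, 4], [10, 20, 40, 80]) == 1.0
        assert spearman([1, 2, 3, 4], [5, 4, 3, 1]) == -1.0

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1, 2, 3])

    @given(
        p=compositions.filter(lambda x: len(x) >= 3),
        data=st.data(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_clr_preserves_rank_correlation(self, p, data):
        q = close(
            data.draw(
                st.lists(
                    st.integers(min_value=1, max_value=10**6).map(float),
                    min_size=len(p),
                    max_size=len(p),
                )
            )
        )
        if np.ptp(p) == 0 or np.ptp(q) == 0:
            return
        assert spearman(clr(p), clr(q)) == spearman(p, q)


def correlated_pair(r: float, n: int, seed: int = 0):
    """Vectors whose sample Pearson correlation is exactly r (Gram-Schmidt)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    e = e - e.mean()
    e -= x * (e @ x) / (x @ x)
    e /= e.std()
    return x, r * x + math.sqrt(1 - r * r) * e


class TestPearsonCI:
    def test_identical_vectors_degenerate(self):
        a = np.array([1.0, 2.0, 5.0, 9.0])
        r, ci = pearson_with_ci(a, a)
        assert r == 1.0 and ci == (1.0, 1.0)

    def test_fisher_z_closed_form(self):
        x, y = correlated_pair(0.74, 25, seed=1)
        r, ci = pearson_with_ci(x, y)
        assert r == pytest.approx(0.74, abs=1e-12)
        z, half = math.atanh(0.74), 1.959964 / math.sqrt(22)
        assert ci == pytest.approx((math.tanh(z - half), math.tanh(z + half)), abs=1e-6)
        assert ci == pytest.approx((0.487, 0.878), abs=1e-3)

    def test_null_ci_symmetric(self):
        x, y = correlated_pair(0.0, 400, seed=2)
        r, ci = pearson_with_ci(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert ci[0] == pytest.approx(-ci[1], abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci([1, 2, 3], [1, 2, 3])


class TestConcordance:
    def test_proportional_layers_are_perfectly_concordant(self):
        tpm = {f"t{i}": float(v) for i, v in enumerate([5, 50, 500, 20, 1])}
        fmol = {k: 3.7 * v for k, v in tpm.items()}
        res = concordance(tpm, fmol)
        assert res.spearman_rho == pytest.approx(1.0, abs=1e-12)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.n == 5

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        tpm = {f"t{i}": float(v) for i, v in enumerate(rng.lognormal(0, 1, 30))}
        fmol = {f"t{i}": float(v) for i, v in enumerate(rng.lognormal(0, 1, 30))}
        a = concordance(tpm, fmol)
        b = concordance({k: v * 1e6 for k, v in tpm.items()}, fmol)
        assert a.pearson_r == pytest.approx(b.pearson_r, rel=1e-12)
        assert a.spearman_rho == b.spearman_rho

    def test_restricts_to_shared_ids_and_recloses(self):
        rng = np.random.default_rng(5)
        ids = [f"t{i}" for i in range(20)]
        tpm = {i: float(v) for i, v in zip(ids, rng.lognormal(0, 1, 20))}
        fmol = {i: float(v) for i, v in zip(ids[:12], rng.lognormal(0, 1, 12))}
        res = concordance(tpm, fmol)
        assert res.n == 12 and set(res.matched_ids) == set(ids[:12])
        # identical to computing on the pre-restricted subcomposition
        sub = concordance({i: tpm[i] for i in ids[:12]}, fmol)
        assert res.pearson_r == pytest.approx(sub.pearson_r, rel=1e-12)

    def test_too_few_shared_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            concordance({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})

    def test_independent_layers_near_zero(self):
        rng = np.random.default_rng(6)
        tpm = {f"t{i}": float(v) for i, v in enumerate(rng.lognormal(0, 1, 400))}
        fmol = {f"t{i}": float(v) for i, v in enumerate(rng.lognormal(0, 1, 400))}
        assert abs(concordance(tpm, fmol).spearman_rho) < 0.15


class TestDetectionThreshold:
    def _tpm(self, n=50, seed=7):
        rng = np.random.default_rng(seed)
        vals = np.sort(rng.lognormal(3, 1.5, n))[::-1]  # descending
        return {f"t{i}": float(v) for i, v in enumerate(vals)}

    def test_bottom_five_undetected(self):
        tpm = self._tpm()
        detected = set(list(tpm)[:-5])
        res = detection_threshold_analysis(tpm, detected)
        assert res.rank_sum_p < 0.01
        assert res.all_top_k_detected
        assert res.rank_most_expressed_undetected == 46
        assert res.n_undetected == 5

    def test_all_detected_skips_test(self):
        tpm = self._tpm()
        res = detection_threshold_analysis(tpm, set(tpm))
        assert res.rank_sum_p is None
        assert res.all_top_k_detected
        assert res.n_undetected == 0

    def test_detected_must_be_subset(self):
        with pytest.raises(ValueError, match="not in abundance"):
            detection_threshold_analysis(self._tpm(), {"bogus"})

    def test_random_detection_gives_uniform_pvalues(self):
        # detection independent of abundance: the one-sided test should not
        # fire more often than its level
        rng = np.random.default_rng(8)
        tpm = self._tpm(60)
        ids = list(tpm)
        hits = 0
        n_seeds = 300
        for _ in range(n_seeds):
            detected = set(rng.choice(ids, size=30, replace=False))
            p = detection_threshold_analysis(tpm, detected).rank_sum_p
            hits += p < 0.05
        assert 0.005 <= hits / n_seeds <= 0.12
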