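import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from angiomir import (
    ValidationError,
    correlate_methylation,
    correlate_with_genes,
    correlate_with_score,
    spearman,
)


def oracle_spearman(x, y):
    """Independent oracle: explicit mid-rank computation + hand Pearson."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0  # average of 1-based ranks i+1..j
            i = j
        return ranks

    rx, ry = midranks(x), midranks(y)
    cx, cy = rx - rx.mean(), ry - ry.mean()
    return float(cx @ cy / np.sqrt((cx @ cx) * (cy @ cy)))


class TestSpearman:
    def test_perfect_antimonotone(self):
        res = spearman([1, 2, 3, 4], [10, 7, 5, 1])
        assert res.rho == pytest.approx(-1.0)

    def test_hand_example_rho_half(self):
        assert spearman([1, 2, 3], [1, 3, 2]).rho == pytest.approx(0.5)

    def test_constant_vector_flagged_not_nan_silently(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert not res.ok
        assert res.reason == "constant input"

    def test_incomplete_pairs_removed(self):
        res = spearman([1, 2, np.nan, 4], [4, 3, 2, 1])
        assert res.n == 3
        assert res.rho == pytest.approx(-1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert spearman(x, y).rho == pytest.approx(spearman(y, x).rho)

    def test_agreement_with_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            x = rng.integers(0, 6, n).astype(float)  # ties likely
            y = rng.normal(size=n)
            if np.all(x == x[0]):
                continue
            assert spearman(x, y).rho == pytest.approx(oracle_spearman(x, y), abs=1e-12)

    def test_p_value_matches_t_approximation(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = spearman(x, y)
        t = res.rho * np.sqrt((res.n - 2) / (1 - res.rho**2))
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), res.n - 2), rel=1e-9)

    def test_exact_permutation_p_matches_enumeration_tail(self):
        x, y = [1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 1.0, 4.0, 3.0, 5.0]
        res = spearman(x, y, exact=True)
        # enumeration over 5! rank permutations
        from itertools import permutations

        obs = oracle_spearman(x, y)
        hits = sum(
            abs(oracle_spearman(x, list(p))) >= abs(obs) - 1e-12
            for p in permutations(y)
        )
        assert res.p_value == pytest.approx(hits / 120)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariance_under_strictly_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert spearman(np.exp(x), y).rho == pytest.approx(spearman(x, y).rho)


class TestCorrelateWithScore:
    def _cohort_frames(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(30)]
        score = pd.Series(rng.normal(size=30), index=samples)
        expr = pd.DataFrame(
            {
                "miR-pos": score.to_numpy(),                  # identical to score
                "miR-neg": -score.to_numpy(),                 # exact negative
                "miR-noise": rng.normal(size=30),
            },
            index=samples,
        ).T
        return expr, score

    def test_ranking_most_negative_first(self):
        expr, score = self._cohort_frames()
        out = correlate_with_score(expr, score)
        assert out["mirna"].iloc[0] == "miR-neg"
        assert out["rho"].iloc[0] == pytest.approx(-1.0)
        assert out["mirna"].iloc[-1] == "miR-pos"
        assert out["rho"].iloc[-1] == pytest.approx(1.0)

    def test_exact_copies_tie_broken_lexicographically(self):
        expr, score = self._cohort_frames()
        dup = pd.concat([expr, expr.loc[["miR-neg"]].rename(index={"miR-neg": "miR-aaa"})])
        out = correlate_with_score(dup, score)
        assert out["mirna"].tolist()[:2] == ["miR-aaa", "miR-neg"]

    def test_no_shared_samples_is_error(self):
        expr, score = self._cohort_frames()
        score.index = [f"other{i}" for i in range(30)]
        with pytest.raises(ValidationError, match="shared"):
            correlate_with_score(expr, score)


class TestCorrelateWithGenes:
    def test_exact_negative_gene_top_ranked(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(20)]
        mirna = pd.Series(rng.normal(size=20), index=samples)
        mrna = pd.DataFrame(
            {"gNeg": -mirna.to_numpy(), "gNoise": rng.normal(size=20)}, index=samples
        ).T
        out = correlate_with_genes(mirna, mrna, ["gNeg", "gNoise"])
        assert out["gene"].iloc[0] == "gNeg"
        assert out["rho"].iloc[0] == pytest.approx(-1.0)

    def test_empty_gene_list_gives_empty_result(self):
        mirna = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        mrna = pd.DataFrame([[1, 2, 3]], index=["g"], columns=["a", "b", "c"])
        out = correlate_with_genes(mirna, mrna, [])
        assert len(out) == 0


class TestCorrelateTracks:
    def test_monotone_transform_gives_rho_minus_one(self):
        samples = [f"s{i}" for i in range(10)]
        expr = pd.Series(np.linspace(-2, 2, 10), index=samples)
        beta = 1 / (1 + np.exp(expr.to_numpy()))  # inverse-logit(-expression)
        tracks = pd.DataFrame([beta], index=["probe1"], columns=samples)
        res, skipped = correlate_methylation(expr, tracks)
        assert res["rho"].iloc[0] == pytest.approx(-1.0)
        assert len(skipped) == 0

    def test_probe_with_two_samples_skipped_with_reason(self):
        samples = ["a", "b", "c", "d"]
        expr = pd.Series([1.0, 2.0, 3.0, 4.0], index=samples)
        tracks = pd.DataFrame(
            [[0.1, 0.2, np.nan, np.nan], [0.1, 0.2, 0.3, 0.4]],
            index=["probe_short", "probe_full"],
            columns=samples,
        )
        res, skipped = correlate_methylation(expr, tracks)
        assert skipped["feature"].tolist() == ["probe_short"]
        assert "2 complete pairs" in skipped["reason"].iloc[0]
        assert res["feature"].tolist() == ["probe_full"]


def test_planted_methylation_probe_detected_across_seeds():
    """Probes whose beta rises with latent activity anti-correlate with the
    planted miRNA (p < 0.01) in at least 90 of 100 seeds at n=300."""
    from angiomir.synthetic import CohortConfig, PlantedMirna, generate_cohort

    hits = 0
    for seed in range(100):
        cfg = CohortConfig(
            n_samples=300,
            n_null_mirnas=0,
            planted_mirnas=(PlantedMirna("miR-planted", gamma=0.8, baseline=8.0),),
            mirna_mode="gaussian",
            seed=seed,
        )
        cohort = generate_cohort(cfg)
        res, _ = correlate_methylation(
            cohort.mirna_expr.loc["miR-planted"], cohort.methylation
        )
        probe = res.set_index("feature").iloc[0]
        first = res.set_index("feature").loc["cg_probe_01"]
        hits += bool(first["rho"] < 0 and first["p_value"] < 0.01)
    assert hits >= 90
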