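"""Encoding, transforms, LOOCV machinery and evaluation statistics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression

import multikin as mk
from multikin.ml import (
    FEATURE_NAMES,
    N_FEATURES,
    correlation_table,
    log_square,
)
from multikin.types import TokenCapacityError


class TestTransforms:
    @pytest.mark.parametrize("x,expected", [(1.0, 0.0), (np.e**2, 4.0)])
    def test_log_square(self, x, expected):
        assert log_square(x) == pytest.approx(expected, rel=1e-12)

    def test_inverse_on_submolar_branch(self):
        kd = np.array([1e-9, 1e-6, 1e-3])
        np.testing.assert_allclose(mk.inverse_log_square(log_square(kd)), kd,
                                   rtol=1e-12)


class TestPrepareResponses:
    def _table(self):
        return pd.DataFrame({
            "id": ["a", "b", "c", "d"],
            "valency": [2, 2, 2, 4],
            "epitope_seq": ["FSIVG", "FSIVG", "FSIVG", "FSIVGS"],
            "tokens": ["", "", "", "J"],
            "kd_M": [1e-9, 2e-9, 9e-9, 5e-8],
            "k_on": [1e5, 1e5, 1e5, 2e5],
            "k_off": [1e-4, 2e-4, 9e-4, 1e-2],
        })

    def test_duplicates_collapse_to_median(self):
        prep = mk.prepare_responses(self._table())
        assert len(prep) == 2
        row = prep[prep["valency"] == 2].iloc[0]
        assert row["kd_M"] == 2e-9  # median of {1, 2, 9} nM

    def test_transform_columns_appended(self):
        prep = mk.prepare_responses(self._table())
        np.testing.assert_allclose(prep["kd_logsq"], log_square(prep["kd_M"]))
        np.testing.assert_allclose(prep["koff_logsq"], log_square(prep["k_off"]))

    def test_missing_responses_dropped(self):
        t = self._table()
        t.loc[3, "k_off"] = np.nan
        assert (mk.prepare_responses(t)["valency"] == 4).sum() == 0

    def test_empty_after_filtering_rejected(self):
        t = self._table()
        t["kd_M"] = np.nan
        with pytest.raises(ValueError):
            mk.prepare_responses(t)


class TestEncodeAac:
    def test_single_letter(self):
        v = mk.encode_aac("AA")
        assert v[mk.AA_ALPHABET.index("A")] == 1.0 and v.sum() == 1.0

    def test_core_motif_fractions(self):
        v = mk.encode_aac("FSIVG")
        for aa in "FSIVG":
            assert v[mk.AA_ALPHABET.index(aa)] == pytest.approx(0.2)

    def test_uniform_fractions(self):
        np.testing.assert_allclose(sorted(mk.encode_aac("ACDE"))[-4:], 0.25)

    def test_noncanonical_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            mk.encode_aac("FSXVG")

    @pytest.mark.parametrize("seq", ["FSIVG", "ADFSIVGSP", "W", "ACDEFGHIK"])
    def test_sums_to_one(self, seq):
        assert mk.encode_aac(seq).sum() == pytest.approx(1.0, rel=1e-12)


class TestEncodeLinker:
    def test_empty_all_gaps(self):
        np.testing.assert_array_equal(mk.encode_linker(""), np.zeros(14))

    def test_single_linker(self):
        v = mk.encode_linker("J")
        np.testing.assert_array_equal(v, [1, 0] + [0] * 12)

    def test_concatenation(self):
        v = mk.encode_linker("JOJ")
        np.testing.assert_array_equal(v, [1, 0, 0, 1, 1, 0] + [0] * 8)

    def test_capacity_error(self):
        with pytest.raises(TokenCapacityError):
            mk.encode_linker("JOJOJOJO")

    def test_bits_pairwise_exclusive(self):
        for tok in ("", "J", "O", "JOJOJOJ", "OOJOO"):
            v = mk.encode_linker(tok)
            assert np.all(v[::2] * v[1::2] == 0)


class TestBuildMatrix:
    def _responses(self, n=6):
        seqs = ["FSIVG", "FSIVGS", "DFSIVGS", "FSIVGSP", "ADFSIVG", "FSIVGSK"][:n]
        return pd.DataFrame({
            "id": [f"p{i}" for i in range(n)],
            "valency": [2, 2, 4, 4, 8, 8][:n],
            "epitope_seq": seqs,
            "tokens": ["", "O", "J", "OJ", "JJ", "OJO"][:n],
            "kd_M": np.logspace(-6, -8, n),
            "k_on": np.logspace(4, 6, n),
            "k_off": np.full(n, 1e-3),
            "kd_logsq": log_square(np.logspace(-6, -8, n)),
            "koff_logsq": np.full(n, log_square(1e-3)),
        })

    def test_34_features_before_removal(self):
        enc = mk.build_matrix(self._responses())
        assert enc.X_full.shape == (6, N_FEATURES) and N_FEATURES == 34
        assert len(FEATURE_NAMES) == 34

    def test_paper_scale_shape(self):
        r = pd.concat([self._responses()] * 14, ignore_index=True).head(79)
        r["id"] = [f"q{i}" for i in range(79)]
        assert mk.build_matrix(r).X_full.shape == (79, 34)

    def test_absent_residue_column_removed(self):
        enc = mk.build_matrix(self._responses())
        assert "aac_W" not in enc.kept_feature_names

    def test_duplicate_row_leaves_mask_unchanged(self):
        r = self._responses()
        enc = mk.build_matrix(r)
        r2 = pd.concat([r, r.iloc[[0]]], ignore_index=True)
        enc2 = mk.build_matrix(r2)
        np.testing.assert_array_equal(enc.kept_mask, enc2.kept_mask)

    def test_all_constant_rejected(self):
        r = self._responses()
        r["epitope_seq"] = "FSIVG"
        r["tokens"] = ""
        with pytest.raises(ValueError, match="zero variance"):
            mk.build_matrix(r)

    def test_aac_rows_sum_to_one(self):
        enc = mk.build_matrix(self._responses())
        np.testing.assert_allclose(enc.X_full[:, :20].sum(axis=1), 1.0)


class TestStatistics:
    def test_r_squared_examples(self):
        y = np.array([1.0, 2.0, 3.0])
        assert mk.r_squared(y, y) == 1.0
        assert mk.r_squared(y, np.full(3, y.mean())) == 0.0
        assert mk.r_squared(y, [1.0, 2.0, 4.0]) == 0.5

    def test_pearson_examples(self):
        x = np.arange(10.0)
        assert mk.pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert mk.pearson_r(x, -x) == pytest.approx(-1.0)

    def test_pearson_independent_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert abs(mk.pearson_r(x, y)) < 0.05

    def test_bootstrap_perfect_predictions_collapse(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        point, lo, hi = mk.bootstrap_ci(y, y, seed=0)
        assert (point, lo, hi) == (1.0, 1.0, 1.0)

    def test_bootstrap_resample_count(self):
        calls = []

        def counting_stat(y, yhat):
            calls.append(1)
            return 0.0

        mk.bootstrap_ci(np.ones(5), np.ones(5), statistic=counting_stat,
                        n_boot=1000, seed=0)
        assert len(calls) == 1000 + 1  # 1000 resamples + the point estimate

    def test_bootstrap_width_shrinks_with_n(self):
        rng = np.random.default_rng(1)
        widths = []
        for n in (10, 1000):
            x = rng.normal(size=n)
            y = x + 0.3 * rng.normal(size=n)
            _, lo, hi = mk.bootstrap_ci(x, y, seed=2, n_boot=300)
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestLoocv:
    def _enc(self, n=12, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        seqs = [("FSIVG" + "SPKRE" * 2)[: 5 + i % 5] for i in range(n)]
        toks = [("OJ" * 3)[: i % 6] for i in range(n)]
        X_cols = [np.concatenate([mk.encode_aac(s), mk.encode_linker(t)])
                  for s, t in zip(seqs, toks)]
        lens = np.array([len(s) for s in seqs], dtype=float)
        resp = pd.DataFrame({
            "id": [f"p{i:02d}" for i in range(n)],
            "valency": [2, 4, 8] * (n // 3),
            "epitope_seq": seqs,
            "tokens": toks,
            "kd_M": np.exp(-lens),
            "k_on": lens,
            "k_off": np.full(n, 1e-3),
            "kd_logsq": lens**2,
            "koff_logsq": np.full(n, 1.0),
            "target_lin": lens + noise * rng.normal(size=n),
        })
        return mk.build_matrix(resp)

    @staticmethod
    def _linear_factory(seed):
        return LinearRegression

    def test_linear_signal_linear_baseline(self):
        """A response linear in one feature is recovered by an
        identity-capable baseline model."""
        enc = self._enc()
        rep = mk.loocv_predict(enc, "target_lin", seed=0, n_boot=50,
                               model_factory=LinearRegression)
        assert rep.r2_total >= 0.9

    def test_noise_response_scores_poorly(self):
        rng = np.random.default_rng(3)
        enc = self._enc()
        enc.responses["pure_noise"] = rng.normal(size=len(enc.ids))
        rep = mk.loocv_predict(enc, "pure_noise", seed=0, n_boot=50)
        assert rep.r2_total < 0.2

    def test_order_invariance(self):
        enc = self._enc()
        rep1 = mk.loocv_predict(enc, "kd_logsq", seed=0, n_boot=10)
        perm = np.random.default_rng(0).permutation(len(enc.ids))
        enc_p = mk.build_matrix(enc.responses.iloc[perm].reset_index(drop=True))
        rep2 = mk.loocv_predict(enc_p, "kd_logsq", seed=0, n_boot=10)
        assert rep1.ids == rep2.ids
        np.testing.assert_array_equal(rep1.yhat, rep2.yhat)

    def test_no_leakage_of_held_out_response(self):
        """An extreme outlier response is not reproduced for its own fold."""
        enc = self._enc()
        y = enc.responses["kd_logsq"].copy()
        y.iloc[0] = 1e6
        enc.responses["spiked"] = y
        rep = mk.loocv_predict(enc, "spiked", seed=0, n_boot=10)
        spiked_pred = rep.yhat[rep.ids.index("p00")]
        assert spiked_pred < 1e5  # nowhere near the leaked value

    def test_too_few_peptides_rejected(self):
        enc = self._enc(n=12)
        small = mk.build_matrix(enc.responses.head(2))
        with pytest.raises(ValueError):
            mk.loocv_predict(small, "kd_logsq")

    def test_unknown_response_rejected(self):
        with pytest.raises(KeyError):
            mk.loocv_predict(self._enc(), "nope")


class TestCorrelationTable:
    def test_per_group_pearson(self):
        df = pd.DataFrame({
            "valency": [2] * 5 + [4] * 5,
            "assoc_level": list(range(5)) * 2,
            "kd_M": list(range(5)) + list(range(5, 0, -1)),
            "k_off": [1.0] * 10,
            "k_on": list(range(10)),
        })
        tab = correlation_table(df)
        kd2 = tab[(tab["valency"] == 2) & (tab["pair"] == "assoc_level~kd_M")]
        kd4 = tab[(tab["valency"] == 4) & (tab["pair"] == "assoc_level~kd_M")]
        assert kd2["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert kd4["pearson_r"].iloc[0] == pytest.approx(-1.0)
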