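import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbcorrect import (
    MBCModel,
    MutationDataset,
    MutationRecord,
    build_design_matrix,
    encode_mutation,
    fit,
    get_scale,
)
from mbcorrect.core import ridge_solve
from mbcorrect.errors import (
    EmptyInputError,
    IncompleteRecordError,
    InvalidResidueError,
    SingularSystemError,
)
from mbcorrect.scales import AA_INDEX, AMINO_ACIDS

aa_strategy = st.sampled_from(AMINO_ACIDS)


def _record(wt, mut, ddg=None, score=None, rid="r"):
    return MutationRecord(record_id=rid, wt_aa=wt, mut_aa=mut,
                          ddg_exp=ddg, score_delta=score)


class TestEncoding:
    def test_single_substitution(self):
        o = encode_mutation("A", "V")
        assert o[AA_INDEX["A"]] == -1 and o[AA_INDEX["V"]] == 1
        assert np.count_nonzero(o) == 2

    def test_identity_is_zero_vector(self):
        assert not encode_mutation("L", "L").any()

    def test_antisymmetric_and_zero_sum_all_pairs(self):
        for w, m in itertools.product(AMINO_ACIDS, repeat=2):
            o = encode_mutation(w, m)
            assert o.sum() == 0
            np.testing.assert_array_equal(o, -encode_mutation(m, w))

    def test_noncanonical_rejected(self):
        with pytest.raises(InvalidResidueError):
            encode_mutation("A", "X")


class TestDesignMatrix:
    @pytest.fixture
    def five_records(self):
        pairs = [("A", "V"), ("L", "P"), ("G", "W"), ("K", "E"), ("F", "Y")]
        return MutationDataset(records=[
            _record(w, m, ddg=0.1 * i, score=0.2 * i, rid=f"r{i}")
            for i, (w, m) in enumerate(pairs)
        ])

    def test_dd_has_21_columns(self, five_records):
        dm = build_design_matrix(five_records, "dd")
        assert dm.X.shape == (5, 21)
        np.testing.assert_allclose(dm.X[:, 0], [0.0, 0.2, 0.4, 0.6, 0.8])

    def test_only_has_20_columns_no_score(self, five_records):
        dm = build_design_matrix(five_records, "only")
        assert dm.X.shape == (5, 20)
        assert set(np.unique(dm.X)) <= {-1.0, 0.0, 1.0}

    def test_rose_row_is_score_and_scale_delta(self):
        rose = get_scale("rose")
        ds = MutationDataset(records=[_record("A", "V", ddg=1.0, score=0.4)])
        dm = build_design_matrix(ds, "rose", scale=rose)
        assert dm.X.shape == (1, 2)
        np.testing.assert_allclose(dm.X[0], [0.4, rose["V"] - rose["A"]])

    def test_missing_score_lists_offenders(self):
        ds = MutationDataset(records=[
            _record("A", "V", ddg=1.0, score=0.4, rid="good"),
            _record("L", "P", ddg=2.0, rid="bad"),
        ])
        with pytest.raises(IncompleteRecordError) as err:
            build_design_matrix(ds, "dd")
        assert "bad" in err.value.record_ids

    def test_only_mode_ignores_missing_scores(self):
        ds = MutationDataset(records=[_record("A", "V", ddg=1.0)])
        assert build_design_matrix(ds, "only").X.shape == (1, 20)


class TestRidgeSolve:
    def test_ols_interpolates_square_full_rank(self, rng):
        X = rng.normal(size=(6, 6))
        y = rng.normal(size=6)
        beta = ridge_solve(X, y, 0.0)
        np.testing.assert_allclose(X @ beta, y, atol=1e-8)

    def test_huge_penalty_shrinks_to_zero(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        beta = ridge_solve(X, y, 1e12)
        assert np.max(np.abs(beta)) < 1e-6

    def test_rank_deficient_without_penalty_raises(self, rng):
        col = rng.normal(size=10)
        X = np.column_stack([col, col])  # identical columns
        with pytest.raises(SingularSystemError, match="lambda"):
            ridge_solve(X, col, 0.0)

    def test_rank_deficient_with_penalty_ok(self, rng):
        col = rng.normal(size=10)
        X = np.column_stack([col, col])
        beta = ridge_solve(X, col, 1.0)
        # symmetric problem: penalty splits the weight equally
        assert beta[0] == pytest.approx(beta[1])

    def test_matches_numerical_minimizer(self, rng):
        import scipy.optimize

        X = rng.normal(size=(50, 21))
        y = rng.normal(size=50)
        lam = 1.0
        beta = ridge_solve(X, y, lam)

        def residuals(b):
            return np.concatenate([y - X @ b, np.sqrt(lam) * b])

        sol = scipy.optimize.least_squares(
            residuals, np.zeros(21), xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        assert np.max(np.abs(beta - sol.x)) < 1e-6


class TestFit:
    def test_recovers_planted_coefficients_noise_free(self, rng):
        # y built exactly as 0.8*dS + sum a*_i O_i; fitted coefficients
        # must match up to the shared-constant gauge freedom
        a_true = rng.normal(size=20)
        a0_true = 0.8
        pairs = list(itertools.permutations(AMINO_ACIDS, 2))
        records = []
        for i, (w, m) in enumerate(pairs):
            s = rng.normal()
            y = a0_true * s + a_true[AA_INDEX[m]] - a_true[AA_INDEX[w]]
            records.append(_record(w, m, ddg=y, score=s, rid=f"r{i}"))
        model = fit(MutationDataset(records=records), mode="dd", lam=1e-8)
        assert model.a0 == pytest.approx(a0_true, abs=1e-4)
        np.testing.assert_allclose(
            model.a - model.a.mean(), a_true - a_true.mean(), atol=1e-4
        )

    def test_rose_mode_exact_linear_recovery(self):
        rose = get_scale("rose")
        pairs = [("A", "V"), ("L", "P"), ("G", "W"), ("K", "E")]
        records = [
            _record(w, m, ddg=2.0 * (rose[m] - rose[w]), score=float(i - 2), rid=f"r{i}")
            for i, (w, m) in enumerate(pairs)
        ]
        model = fit(MutationDataset(records=records), mode="rose", lam=0.0)
        assert model.a1 == pytest.approx(2.0, abs=1e-6)
        assert model.a0 == pytest.approx(0.0, abs=1e-6)
        assert model.scale_name == "rose"

    def test_empty_dataset_rejected(self):
        with pytest.raises(EmptyInputError):
            fit(MutationDataset(), mode="dd")

    def test_underdetermined_ols_rejected(self):
        ds = MutationDataset(records=[_record("A", "V", ddg=1.0, score=0.4)])
        with pytest.raises(SingularSystemError):
            fit(ds, mode="dd", lam=0.0, augment=False)

    def test_augmentation_invariance_no_intercept(self, rng):
        # with no intercept the ridge fit on D equals the fit on D plus
        # its antisymmetric complement
        pairs = list(itertools.permutations(AMINO_ACIDS, 2))[:100]
        records = [
            _record(w, m, ddg=float(rng.normal()), score=float(rng.normal()), rid=f"r{i}")
            for i, (w, m) in enumerate(pairs)
        ]
        ds = MutationDataset(records=records)
        plain = fit(ds, mode="dd", lam=1.0, augment=False)
        augmented = fit(ds, mode="dd", lam=1.0, augment=True)
        assert abs(plain.a0 - augmented.a0) < 1e-8
        np.testing.assert_allclose(plain.a, augmented.a, atol=1e-8)
        assert augmented.fit_meta["n"] == 2 * plain.fit_meta["n"]


class TestPredict:
    def test_pure_score_model_returns_score_delta(self, tiny_dataset):
        model = MBCModel(mode="dd", a0=1.0, a=np.zeros(20))
        np.testing.assert_allclose(
            model.predict(tiny_dataset),
            [r.score_delta for r in tiny_dataset],
        )

    def test_only_mode_identity_mutation_is_zero(self):
        model = MBCModel(mode="only", a=np.arange(20.0))
        ds = MutationDataset(records=[_record("L", "L")])
        assert model.predict(ds)[0] == 0.0

    def test_prediction_order_matches_records(self, tiny_dataset):
        model = MBCModel(mode="only", a=np.arange(20.0))
        pred = model.predict(tiny_dataset)
        for p, r in zip(pred, tiny_dataset):
            assert p == model.predict_record(r)

    def test_mode_field_mismatch(self):
        model = MBCModel(mode="dd", a0=1.0, a=np.zeros(20))
        ds = MutationDataset(records=[_record("A", "V", ddg=1.0)])  # no score
        with pytest.raises(IncompleteRecordError):
            model.predict(ds)

    @settings(derandomize=True, max_examples=100)
    @given(
        wt=aa_strategy, mut=aa_strategy,
        score=st.floats(-10, 10),
        seed=st.integers(0, 2**20),
        mode=st.sampled_from(["dd", "rose", "only"]),
    )
    def test_antisymmetry_any_model(self, wt, mut, score, seed, mode):
        """Reversing a mutation negates the prediction, for every mode."""
        rng = np.random.default_rng(seed)
        if mode == "dd":
            model = MBCModel(mode="dd", a0=rng.normal(), a=rng.normal(size=20))
        elif mode == "only":
            model = MBCModel(mode="only", a=rng.normal(size=20))
        else:
            model = MBCModel(mode="rose", a0=rng.normal(), a1=rng.normal(),
                             scale_name="rose")
        rec = _record(wt, mut, ddg=1.0, score=score)
        direct = model.predict_record(rec)
        inverse = model.predict_record(rec.complement())
        assert abs(direct + inverse) <= 1e-10

    @settings(derandomize=True, max_examples=50)
    @given(c=st.floats(-100, 100), seed=st.integers(0, 2**20))
    def test_gauge_freedom(self, c, seed):
        """Adding a constant to all residue coefficients changes nothing."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=20)
        model = MBCModel(mode="dd", a0=0.7, a=a)
        shifted = MBCModel(mode="dd", a0=0.7, a=a + c)
        ds = MutationDataset(records=[
            _record(w, m, score=float(rng.normal()), rid=f"r{i}")
            for i, (w, m) in enumerate([("A", "V"), ("W", "G"), ("K", "K")])
        ])
        np.testing.assert_allclose(
            model.predict(ds), shifted.predict(ds), atol=1e-12
        )
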