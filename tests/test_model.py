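"""Feature assembly and the regression stack."""

import numpy as np
import pandas as pd
import pytest

from ddgdyn import fixtures, model as mdl
from ddgdyn.structure_io import MultiMutation, MutationSpec
from conftest import transformed_structure


@pytest.fixture(scope="module")
def helix():
    s, _ = fixtures.make_helix(16, seed=5)
    return s


def spec_for(structure, index, mut=None):
    res = structure.residues()[index]
    if mut is None:
        mut = "A" if res.one_letter != "A" else "V"
    return MutationSpec(chain=res.chain_id, wt=res.one_letter,
                        position=res.residue_seq, mut=mut)


class TestFeaturizeSingle:
    def test_length_and_block_arithmetic(self, helix):
        fv = mdl.featurize_single(helix, spec_for(helix, 7))
        assert len(fv) == 216 + 4 + 2 + 3 + 1 == 226
        assert list(fv.index) == mdl.feature_names()

    def test_bit_identical_determinism(self, helix):
        f = mdl.Featurizer()
        a = f.featurize_single(helix, spec_for(helix, 7))
        b = f.featurize_single(helix, spec_for(helix, 7))
        assert (a.to_numpy() == b.to_numpy()).all()

    def test_rigid_body_invariance(self, helix):
        """Every feature block is invariant under rotation + translation."""
        moved = transformed_structure(helix)
        a = mdl.featurize_single(helix, spec_for(helix, 7))
        b = mdl.featurize_single(moved, spec_for(moved, 7))
        sig = [c for c in a.index if c.startswith("sig_")]
        assert (a[sig].to_numpy() == b[sig].to_numpy()).all()  # integer counts
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-6,
                                   atol=1e-9)

    def test_site_errors_propagate(self, helix):
        from ddgdyn.structure_io import SiteNotFoundError
        bad = MutationSpec(chain="A", wt="A", position=999, mut="V")
        with pytest.raises(SiteNotFoundError):
            mdl.featurize_single(helix, bad)


class TestFeaturizeMulti:
    def test_aggregation_rule(self, helix):
        f = mdl.Featurizer()
        s1, s2 = spec_for(helix, 5), spec_for(helix, 9)
        a = f.featurize_single(helix, s1)
        b = f.featurize_single(helix, s2)
        multi = f.featurize_multi(helix, MultiMutation(specs=(s1, s2)))
        assert len(multi) == len(a) + 1
        assert multi["n_sites"] == 2.0
        # counts summed, intensities averaged
        sig = [c for c in a.index if c.startswith("sig_")]
        np.testing.assert_allclose(multi[sig], a[sig] + b[sig])
        assert multi["rsa"] == pytest.approx((a["rsa"] + b["rsa"]) / 2)
        assert multi["sub_dvolume"] == pytest.approx(
            a["sub_dvolume"] + b["sub_dvolume"])

    def test_site_order_invariance(self, helix):
        f = mdl.Featurizer()
        s1, s2, s3 = (spec_for(helix, i) for i in (4, 8, 12))
        ab = f.featurize_multi(helix, MultiMutation(specs=(s1, s2, s3)))
        ba = f.featurize_multi(helix, MultiMutation(specs=(s3, s1, s2)))
        assert (ab.to_numpy() == ba.to_numpy()).all()


def _toy_data(rng, n=60, p=8):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"f{i}" for i in range(p)])
    y = 2.0 * X["f0"].to_numpy() + rng.normal(scale=0.05, size=n)
    return X, y


class TestTrain:
    def test_planted_signal_training_fit(self, rng):
        X, y = _toy_data(rng, n=120)
        m = mdl.train(X, y, seed=0)
        r = np.corrcoef(m.predict_frame(X), y)[0, 1]
        assert r >= 0.95

    def test_seed_determinism(self, rng):
        X, y = _toy_data(rng)
        probe = X.iloc[:10]
        p1 = mdl.train(X, y, seed=7).predict_frame(probe)
        p2 = mdl.train(X, y, seed=7).predict_frame(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_constant_target(self, rng):
        X, _ = _toy_data(rng)
        y = np.full(len(X), 1.5)
        m = mdl.train(X, y, seed=0)
        np.testing.assert_allclose(m.predict_frame(X), 1.5, atol=1e-12)

    def test_nan_features_rejected_naming_column(self, rng):
        X, y = _toy_data(rng)
        X.loc[3, "f2"] = np.nan
        with pytest.raises(ValueError, match="f2"):
            mdl.train(X, y)

    def test_minimum_records(self, rng):
        X, y = _toy_data(rng, n=10)
        with pytest.raises(ValueError):
            mdl.train(X, y)


class TestGreedySelect:
    def test_planted_feature_selected_first(self, rng):
        """One informative column among permuted-noise columns wins step 1."""
        X, y = _toy_data(rng, n=100, p=6)
        for c in X.columns[1:]:
            X[c] = rng.permutation(X[c].to_numpy())
        selected, scores = mdl.greedy_select(X, y, k_folds=3, max_features=3,
                                             seed=0)
        assert selected[0] == "f0"

    def test_max_features_one(self, rng):
        X, y = _toy_data(rng)
        selected, scores = mdl.greedy_select(X, y, k_folds=3, max_features=1,
                                             seed=0)
        assert len(selected) == 1 and len(scores) == 1

    def test_kfolds_validation(self, rng):
        X, y = _toy_data(rng)
        with pytest.raises(ValueError):
            mdl.greedy_select(X, y, k_folds=1)


class TestPredict:
    def test_config_hash_guard(self, rng):
        X, y = _toy_data(rng)
        m = mdl.train(X, y, config_hash="abc")
        with pytest.raises(ValueError, match="mismatch"):
            mdl.predict(m, X.iloc[0], config_hash="xyz")

    def test_prediction_within_training_range(self, rng):
        X, y = _toy_data(rng, n=100)
        m = mdl.train(X, y, seed=0)
        probe = X.iloc[0] * 50.0  # far outside the training cloud
        ddg, label = mdl.predict(m, probe)
        assert y.min() <= ddg <= y.max()
        assert label in ("stabilizing", "destabilizing")

    def test_heldout_recovery_low_noise(self, rng):
        X, y = _toy_data(rng, n=200)
        m = mdl.train(X.iloc[:150], y[:150], seed=0)
        pred = m.predict_frame(X.iloc[150:])
        assert np.corrcoef(pred, y[150:])[0, 1] >= 0.9


class TestCrossValidate:
    def test_leave_one_out_on_20(self, rng):
        X, y = _toy_data(rng, n=20)
        out = mdl.cross_validate(X, y, k=20, seed=0, n_trees=25)
        assert len(out["predictions"]) == 20

    def test_fold_determinism_and_pooled_count(self, rng):
        X, y = _toy_data(rng, n=60)
        a = mdl.cross_validate(X, y, k=5, seed=3, n_trees=25)
        b = mdl.cross_validate(X, y, k=5, seed=3, n_trees=25)
        np.testing.assert_array_equal(a["predictions"], b["predictions"])
        assert a["pooled"].n == 60


class TestPersistence:
    def test_save_load_predict_bit_identical(self, rng, tmp_path):
        X, y = _toy_data(rng)
        m = mdl.train(X, y, seed=1, config_hash="h1")
        path = tmp_path / "model.joblib"
        mdl.save_model(m, path)
        m2 = mdl.load_model(path)
        assert m2.config_hash == "h1"
        np.testing.assert_array_equal(m.predict_frame(X), m2.predict_frame(X))


class TestReverseFeaturization:
    def test_reverse_uses_same_environment_swapped_direction(self, helix):
        f = mdl.Featurizer()
        fwd_spec = spec_for(helix, 6)
        rev_spec = MutationSpec(chain=fwd_spec.chain, wt=fwd_spec.mut,
                                position=fwd_spec.position, mut=fwd_spec.wt)
        fwd = f.featurize_single(helix, fwd_spec)
        rev = f.featurize_single(helix, rev_spec, reverse=True)
        sig = [c for c in fwd.index if c.startswith("sig_")]
        assert (fwd[sig].to_numpy() == rev[sig].to_numpy()).all()
        assert rev["sub_dvolume"] == -fwd["sub_dvolume"]
        assert rev["sub_dhydro"] == -fwd["sub_dhydro"]
        assert rev["rsa"] == fwd["rsa"]
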