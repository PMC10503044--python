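"""Gram-tensor construction, decomposition, back-projection and selection."""

import numpy as np
import pytest

from tensorsel.datatypes import MultiomicsSet
from tensorsel.multiomics import (
    MultiomicsSelector,
    build_gram_tensor,
    center_layers,
    choose_label_vector,
    hosvd_gram,
    project_features,
    run_multiomics,
)
from tensorsel.nullmodel import fit_null
from tensorsel.simulate import SyntheticSpec, default_labels, make_multiomics_set

from oracles import f1_score, gram_loops, project_loops


def make_set(layers, names=None):
    m = layers[0].shape[1]
    return MultiomicsSet(
        layers=layers,
        layer_names=names or [f"L{k}" for k in range(len(layers))],
        sample_ids=[f"s{j}" for j in range(m)],
        feature_ids=[[f"L{k}_f{i}" for i in range(x.shape[0])] for k, x in enumerate(layers)],
    )


class TestGramTensor:
    def test_single_feature_row_gives_outer_product(self):
        v = np.array([1.0, -2.0, 3.0])
        gram = build_gram_tensor(make_set([v[None, :]]), center=False)
        np.testing.assert_allclose(gram.values[:, :, 0], np.outer(v, v))
        assert np.linalg.matrix_rank(gram.values[:, :, 0]) == 1

    def test_symmetry_exact(self, rng):
        gram = build_gram_tensor(make_set([rng.normal(size=(20, 8))]), center=True)
        np.testing.assert_array_equal(gram.values, gram.values.transpose(1, 0, 2))

    def test_matches_triple_loop_oracle(self, rng):
        layers = [rng.normal(size=(n, 10)) for n in (50, 30, 20)]
        gram = build_gram_tensor(make_set(layers), center=False)
        np.testing.assert_allclose(gram.values, gram_loops(layers), atol=1e-12)

    def test_slices_positive_semidefinite(self, rng):
        layers = [rng.normal(size=(n, 12)) for n in (40, 25)]
        gram = build_gram_tensor(make_set(layers), center=True)
        for k in range(gram.values.shape[2]):
            eigvals = np.linalg.eigvalsh(gram.values[:, :, k])
            assert eigvals.min() >= -1e-10

    def test_mismatched_sample_counts_rejected(self, rng):
        with pytest.raises(ValueError, match="bad_layer"):
            MultiomicsSet(
                layers=[rng.normal(size=(5, 8)), rng.normal(size=(5, 7))],
                layer_names=["ok_layer", "bad_layer"],
                sample_ids=[f"s{j}" for j in range(8)],
                feature_ids=[[f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)]],
            )


class TestHosvdGram:
    def test_single_layer_factors_match_eigenvectors(self, rng):
        x = rng.normal(size=(40, 9))
        gram = build_gram_tensor(make_set([x]), center=False)
        model = hosvd_gram(gram)
        w, v = np.linalg.eigh(gram.values[:, :, 0])
        order = np.argsort(w)[::-1]
        v = v[:, order]
        for c in range(9):
            dot = abs(float(model.factors[0][:, c] @ v[:, c]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_zero_layers_give_zero_core(self):
        gram = build_gram_tensor(make_set([np.zeros((6, 5))]), center=False)
        model = hosvd_gram(gram)
        assert np.all(model.core == 0)

    def test_mode1_mode2_factor_magnitudes_agree(self, rng):
        layers = [rng.normal(size=(n, 10)) for n in (30, 20, 15)]
        model = hosvd_gram(build_gram_tensor(make_set(layers)))
        u1, u2 = model.factors[0], model.factors[1]
        for c in range(3):  # leading, well-separated components
            np.testing.assert_allclose(np.abs(u1[:, c]), np.abs(u2[:, c]), atol=1e-8)


class TestLabelVector:
    def test_planted_ordinal_component_found(self):
        spec = SyntheticSpec(layer_sizes=(300, 200), n_samples=48, seed=12)
        omics, _, labels = make_multiomics_set(spec)
        model = hosvd_gram(build_gram_tensor(omics))
        l1, scores = choose_label_vector(model, labels)
        # the planted label factor dominates the centered Gram: component 1
        assert l1 == int(np.argmax(scores)) + 1
        assert scores[l1 - 1] >= 0.9

    def test_two_class_indicator_column_wins_with_score_one(self):
        from tensorsel.datatypes import TuckerModel

        labels = np.array([0, 0, 0, 1, 1, 1])
        indicator = np.array([-1.0, -1, -1, 1, 1, 1]) / np.sqrt(6)
        u1 = np.linalg.qr(
            np.column_stack([indicator, np.random.default_rng(3).normal(size=(6, 2))])
        )[0]
        core = np.zeros((3, 3, 1))
        core[0, 0, 0] = 1.0
        model = TuckerModel(core=core, factors=(u1, u1.copy(), np.eye(1)))
        l1, scores = choose_label_vector(model, labels)
        assert l1 == 1
        assert scores[0] == pytest.approx(1.0, abs=1e-10)

    def test_override_honored(self):
        spec = SyntheticSpec(layer_sizes=(100,), n_samples=24, seed=1)
        omics, _, labels = make_multiomics_set(spec)
        model = hosvd_gram(build_gram_tensor(omics))
        l1, _ = choose_label_vector(model, labels, override=5)
        assert l1 == 5
        with pytest.raises(ValueError, match="out of range"):
            choose_label_vector(model, labels, override=999)


class TestProjection:
    def test_unit_vector_selects_sample_column(self, rng):
        layers = [rng.normal(size=(n, 6)) for n in (10, 7)]
        e1 = np.zeros(6)
        e1[0] = 1.0
        proj = project_features(make_set(layers), e1)
        for x, p in zip(layers, proj.scores):
            np.testing.assert_array_equal(p, x[:, 0])

    def test_zero_vector_gives_zero_scores(self, rng):
        proj = project_features(make_set([rng.normal(size=(8, 5))]), np.zeros(5))
        assert np.all(proj.scores[0] == 0)

    def test_matches_double_loop_oracle(self, rng):
        layers = [rng.normal(size=(n, 9)) for n in (25, 15)]
        u = rng.normal(size=9)
        proj = project_features(make_set(layers), u)
        for x, p in zip(layers, proj.scores):
            np.testing.assert_allclose(p, project_loops(x, u), atol=1e-12)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            project_features(make_set([rng.normal(size=(8, 5))]), np.zeros(6))


class TestRunMultiomics:
    def test_single_layer_gram_route_agrees_with_direct_svd_route(self):
        spec = SyntheticSpec(layer_sizes=(400,), n_samples=40, effect_size=3.0, seed=6)
        omics, masks, labels = make_multiomics_set(spec)
        tables, manifest = run_multiomics(omics, labels)
        l1 = manifest["chosen_component"]
        # direct route: left singular vector of the centered layer
        x = omics.layers[0] - omics.layers[0].mean(axis=1, keepdims=True)
        u_svd, s, vt = np.linalg.svd(x, full_matrices=False)
        direct_scores = u_svd[:, l1 - 1]
        gram_table = tables[omics.layer_names[0]].set_index("feature_id")
        gram_scores = gram_table.loc[omics.feature_ids[0], "score_u"].to_numpy()
        # proportional up to sign
        cs = gram_scores / np.linalg.norm(gram_scores)
        ds = direct_scores / np.linalg.norm(direct_scores)
        assert min(np.abs(cs - ds).max(), np.abs(cs + ds).max()) <= 1e-8
        direct_fit = fit_null(direct_scores)
        direct_sel = {
            fid for fid, s_ in zip(omics.feature_ids[0], direct_fit.selected) if s_
        }
        gram_sel = set(gram_table.index[gram_table["selected"]])
        assert gram_sel == direct_sel

    def test_three_layer_planted_recovery(self):
        omics, masks, labels = make_multiomics_set(SyntheticSpec())
        sel = MultiomicsSelector().fit(omics, labels)
        for name, mask in zip(omics.layer_names, masks):
            assert f1_score(sel.supports_[name], mask) >= 0.85

    def test_pure_null_layers_select_almost_nothing(self):
        omics, _, labels = make_multiomics_set(SyntheticSpec(effect_size=0.0, seed=7))
        sel = MultiomicsSelector().fit(omics, labels)
        for name in omics.layer_names:
            assert sel.supports_[name].mean() <= 0.005

    def test_sign_flip_of_label_vector_preserves_selection(self):
        spec = SyntheticSpec(layer_sizes=(200, 150), n_samples=36, seed=9)
        omics, _, labels = make_multiomics_set(spec)
        work = center_layers(omics)
        model = hosvd_gram(build_gram_tensor(work, center=False))
        l1, _ = choose_label_vector(model, labels)
        u = model.factors[0][:, l1 - 1]
        for x in work.layers:
            fit_pos = fit_null(x @ u)
            fit_neg = fit_null(x @ -u)
            np.testing.assert_allclose(fit_neg.p_values, fit_pos.p_values, atol=1e-12)
            np.testing.assert_array_equal(fit_neg.selected, fit_pos.selected)

    def test_memory_contract_shapes(self):
        # nothing bigger than max(M^2 K, max_k N_k M) is materialized: the
        # Gram tensor itself and the per-layer score vectors are the largest
        # objects the pipeline creates
        spec = SyntheticSpec(layer_sizes=(300, 200), n_samples=20, seed=2)
        omics, _, labels = make_multiomics_set(spec)
        gram = build_gram_tensor(omics)
        m, k = omics.n_samples, omics.n_layers
        bound = max(m * m * k, max(x.shape[0] for x in omics.layers) * m)
        assert gram.values.size <= bound
        proj = project_features(omics, np.ones(m))
        assert all(p.size <= bound for p in proj.scores)
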