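import numpy as np
import pytest
from scipy import stats

from kirbind import prediction
from kirbind.classifiers import MODEL_IDS
from kirbind.prediction import (
    degranulation_correlation,
    export_beta_csv,
    import_beta_csv,
    load_bundle,
    mutation_delta,
    percentile_of,
    predict,
    predict_genotype,
    reciprocity_analysis,
    save_bundle,
    train_bundle,
)
from kirbind.sequences import UNKNOWN


@pytest.fixture(scope="module")
def bundle(planted):
    return train_bundle(planted["panel"], planted["log"], planted["labels"])


class TestTrainBundle:
    def test_eleven_models_with_expected_ids(self, bundle):
        assert tuple(bundle.models) == MODEL_IDS

    def test_all_models_carry_betas(self, bundle):
        for model in bundle.models.values():
            assert model.betas is not None
            assert len(model.betas) == len(bundle.feature_labels)


class TestPredict:
    def test_training_allele_scores_match_projection_route(self, planted, bundle):
        from kirbind import dimred
        from kirbind.sequences import build_region_mask, one_hot_encode

        panel = planted["panel"]
        region = build_region_mask("helices", len(panel[0]))
        encoded = one_hot_encode(panel, region)
        proj = dimred.fit_pca(
            encoded.matrix.astype(float), K=7, feature_labels=encoded.feature_labels
        )
        coords = dimred.project(proj, encoded.matrix.astype(float))
        model = bundle.models["overall_binder"]
        for i in (0, 13, 50):
            report = predict(bundle, panel[i])
            via_w = float(coords[i] @ model.w + model.b)
            assert report.scores["overall_binder"] == pytest.approx(via_w, abs=1e-8)

    def test_all_unknown_sequence_scores_intercept(self, bundle):
        seq = UNKNOWN * bundle.sequence_length
        report = predict(bundle, seq)
        for model_id, model in bundle.models.items():
            assert report.scores[model_id] == pytest.approx(model.intercept)
        masked_positions = {p for p, _ in bundle.feature_labels}
        assert report.n_ignored_positions == len(masked_positions)

    def test_max_reference_allele_is_percentile_100(self, planted, bundle):
        scores = {
            s.name: predict(bundle, s).scores["overall_binder"]
            for s in planted["panel"]
        }
        best = max(scores, key=scores.get)
        seq = next(s for s in planted["panel"] if s.name == best)
        assert predict(bundle, seq).percentiles["overall_binder"] == 100.0

    def test_length_mismatch_raises(self, bundle):
        with pytest.raises(ValueError, match="length"):
            predict(bundle, "RA")

    def test_percentile_stable_under_duplicated_reference(self, planted, bundle):
        seq = planted["panel"][5]
        before = predict(bundle, seq).percentiles
        doubled = {
            k: np.sort(np.concatenate([v, v]))
            for k, v in bundle.reference_scores.items()
        }
        original = bundle.reference_scores
        bundle.reference_scores = doubled
        try:
            after = predict(bundle, seq).percentiles
        finally:
            bundle.reference_scores = original
        for model_id in before:
            assert after[model_id] == pytest.approx(before[model_id])

    def test_percentile_midpoint_option(self):
        ref = np.array([1.0, 2.0, 2.0, 3.0])
        assert percentile_of(ref, 2.0, ties="upper") == 75.0
        assert percentile_of(ref, 2.0, ties="midpoint") == 50.0


class TestPredictGenotype:
    def test_homozygote_equals_single_model(self, planted, bundle):
        seq = planted["panel"][0]
        single = predict(bundle, seq).scores["005"]
        assert predict_genotype(bundle, seq, ["005", "005"]) == pytest.approx(single)

    def test_heterozygote_average_and_permutation(self, planted, bundle):
        seq = planted["panel"][1]
        rep = predict(bundle, seq)
        expected = (rep.scores["001"] + rep.scores["015"]) / 2
        assert predict_genotype(bundle, seq, ["001", "015"]) == pytest.approx(expected)
        assert predict_genotype(bundle, seq, ["015", "001"]) == pytest.approx(expected)

    def test_unknown_allotype_raises(self, planted, bundle):
        with pytest.raises(ValueError, match="no per-allotype model"):
            predict_genotype(bundle, planted["panel"][0], ["077"])


class TestMutationDelta:
    def test_antisymmetry_exact_for_every_model(self, planted, bundle):
        seq = planted["panel"][0]
        pos = bundle.feature_labels[0][0]
        src = seq.residues[pos - 1]
        dst = next(r for p, r in bundle.feature_labels if p == pos and r != src)
        fwd = mutation_delta(bundle, seq, (pos, src, dst))
        mutant = seq.residues[: pos - 1] + dst + seq.residues[pos:]
        rev = mutation_delta(bundle, mutant, (pos, dst, src))
        for model_id in bundle.models:
            assert fwd[model_id] == pytest.approx(-rev[model_id], abs=1e-12)

    def test_delta_equals_beta_difference(self, planted, bundle):
        seq = planted["panel"][2]
        labels = bundle.feature_labels
        pos = labels[0][0]
        src = seq.residues[pos - 1]
        dst = next(r for p, r in labels if p == pos and r != src)
        deltas = mutation_delta(bundle, seq, (pos, src, dst))
        for model_id, model in bundle.models.items():
            beta = {(p, r): v for (p, r), v in zip(labels, model.betas)}
            expected = beta.get((pos, dst), 0.0) - beta.get((pos, src), 0.0)
            assert deltas[model_id] == pytest.approx(expected, abs=1e-10)

    def test_zero_beta_position_zero_delta(self, planted, bundle):
        # a position outside the helices mask has no features at all
        seq = planted["panel"][0]
        masked = {p for p, _ in bundle.feature_labels}
        pos = next(p for p in range(1, len(seq) + 1) if p not in masked)
        src = seq.residues[pos - 1]
        dst = "A" if src != "A" else "C"
        deltas = mutation_delta(bundle, seq, (pos, src, dst))
        assert all(v == 0.0 for v in deltas.values())

    def test_wrong_wildtype_residue_raises(self, planted, bundle):
        seq = planted["panel"][0]
        bad = "A" if seq.residues[0] != "A" else "C"
        with pytest.raises(ValueError, match="expected"):
            mutation_delta(bundle, seq, (1, bad, "G"))


class TestReciprocity:
    def test_linear_model_puts_points_on_diagonal(self, rng):
        direct = rng.normal(size=10)
        pairs = [(d, -d) for d in direct]  # inverse effect is exactly opposite
        out = reciprocity_analysis(pairs)
        assert np.allclose(out["x"], out["y"])
        assert out["correlation"] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        pairs = list(zip(rng.normal(size=50), rng.normal(size=50)))
        assert abs(reciprocity_analysis(pairs)["correlation"]) < 0.3

    def test_sign_flip_negates_correlation(self, rng):
        pairs = [(x, -0.8 * x + 0.1 * e) for x, e in
                 zip(rng.normal(size=30), rng.normal(size=30))]
        fwd = reciprocity_analysis(pairs)["correlation"]
        rev = reciprocity_analysis([(x, -y) for x, y in pairs])["correlation"]
        assert fwd == pytest.approx(-rev)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError, match="3"):
            reciprocity_analysis([(1.0, 2.0)])


class TestDegranulationCorrelation:
    def test_monotone_decreasing_gives_minus_one(self):
        scores = np.array([0.1, 0.5, 1.2, 3.0])
        degran = 100.0 * np.exp(-scores)
        out = degranulation_correlation(scores, degran, 100.0)
        assert out["rho"] == pytest.approx(-1.0)

    def test_matches_rank_formula_with_ties(self, rng):
        scores = np.round(rng.normal(size=15), 1)
        degran = np.exp(rng.normal(size=15))
        out = degranulation_correlation(scores, degran, 1.0)
        ra = stats.rankdata(scores)
        rb = stats.rankdata(np.log(degran))
        manual = np.corrcoef(ra, rb)[0, 1]
        assert out["rho"] == pytest.approx(manual)

    def test_baseline_scaling_invariance(self, rng):
        scores = rng.normal(size=12)
        degran = np.exp(rng.normal(size=12))
        a = degranulation_correlation(scores, degran, 50.0)
        b = degranulation_correlation(scores, degran, 500.0)
        assert a["rho"] == pytest.approx(b["rho"])

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            degranulation_correlation([1.0, 1.0, 1.0], [2.0, 3.0, 4.0], 1.0)

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(ValueError, match="positive"):
            degranulation_correlation([1.0, 2.0], [2.0, 3.0], 0.0)


class TestSerialization:
    def test_beta_csv_round_trip_scores(self, tmp_path, planted, bundle):
        path = tmp_path / "betas.csv"
        export_beta_csv(bundle, path)
        back = import_beta_csv(path, sequence_length=bundle.sequence_length)
        for seq in planted["panel"][:20]:
            a = predict(bundle, seq).scores
            b = predict(back, seq).scores
            for model_id in a:
                assert abs(a[model_id] - b[model_id]) <= 1e-10

    def test_full_bundle_round_trip(self, tmp_path, planted, bundle):
        beta, meta = tmp_path / "betas.csv", tmp_path / "bundle.json"
        save_bundle(bundle, beta, meta)
        back = load_bundle(beta, meta)
        seq = planted["panel"][0]
        assert predict(back, seq).percentiles == pytest.approx(
            predict(bundle, seq).percentiles
        )
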