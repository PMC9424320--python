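"""Fingerprints, feature building, classifiers, direct score, top-k."""

import numpy as np
import pytest

from pathranker.errors import ArgumentError, FeatureError, ScoringError, TrainingError
from pathranker.records import PathwayRecord, ReactionRecord, Species
from pathranker.scoring import (
    FP_BITS,
    FeatureVector,
    GlobalScoreClassifier,
    build_features,
    direct_score,
    global_score,
    reaction_fingerprint,
    species_fingerprint,
    topk_recovery,
    train_global_classifier,
)
from pathranker.synth import FixtureSpec, make_pathway_set


class TestFingerprints:
    def test_additivity_over_participants(self, simple_pathway):
        r = simple_pathway.reactions[0]
        total = reaction_fingerprint(r, simple_pathway.species)
        by_hand = sum(
            (species_fingerprint(simple_pathway.species[sid])
             for sid in list(r.reactants) + list(r.products)),
            start=np.zeros(FP_BITS, dtype=np.int64),
        )
        assert np.array_equal(total, by_hand)
        assert total.shape == (FP_BITS,)

    def test_empty_substrate_side_gives_product_fingerprint(self):
        r = ReactionRecord(id="r", reactants={}, products={"T": 1})
        species = {"T": Species(id="T", smiles="CCO")}
        assert np.array_equal(
            reaction_fingerprint(r, species), species_fingerprint(species["T"])
        )

    def test_smiles_permutation_invariance(self):
        # same molecule (1-propanol) written from either end
        a = species_fingerprint(Species(id="x", smiles="CCCO"))
        b = species_fingerprint(Species(id="y", smiles="OCCC"))
        assert np.array_equal(a, b)

    def test_structureless_species_is_a_feature_error(self):
        r = ReactionRecord(id="r", reactants={"X": 1}, products={"T": 1})
        species = {"X": Species(id="X"), "T": Species(id="T", smiles="C")}
        with pytest.raises(FeatureError, match="X"):
            reaction_fingerprint(r, species)


class TestFeatures:
    def test_reaction_permutation_gives_identical_vectors(self, toy_chassis, simple_pathway):
        simple_pathway.properties.update({"pathway_dg": -3.0, "target_flux": 1.5})
        fv1 = build_features(simple_pathway, toy_chassis)
        flipped = PathwayRecord(
            id="flipped",
            reactions=list(reversed(simple_pathway.reactions)),
            target_id=simple_pathway.target_id,
            species=simple_pathway.species,
            properties=dict(simple_pathway.properties),
        )
        fv2 = build_features(flipped, toy_chassis)
        assert np.array_equal(fv1.to_array(), fv2.to_array())

    def test_single_reaction_availability_is_its_rule_score(self, toy_chassis):
        p = PathwayRecord(
            id="p",
            reactions=[
                ReactionRecord(id="r", reactants={"A": 1}, products={"T": 1},
                               rule_score=0.73)
            ],
            target_id="T",
            species={"A": Species(id="A", smiles="C"), "T": Species(id="T", smiles="CC")},
        )
        fv = build_features(p, toy_chassis)
        assert fv.availability_mean == pytest.approx(0.73)
        assert fv.n_reactions == 1

    def test_missing_dg_imputed_with_flag(self, toy_chassis, simple_pathway):
        fv = build_features(simple_pathway, toy_chassis)
        assert fv.pathway_dg == 0.0
        assert fv.dg_missing and fv.flux_missing
        simple_pathway.properties["pathway_dg"] = -8.0
        fv2 = build_features(simple_pathway, toy_chassis)
        assert not fv2.dg_missing

    def test_vector_layout_matches_column_names(self, toy_chassis, simple_pathway):
        fv = build_features(simple_pathway, toy_chassis)
        assert len(fv.to_array()) == len(FeatureVector.column_names())


@pytest.fixture(scope="module")
def separable_features(toy_chassis):
    spec = FixtureSpec(seed=11, n_pathways=120, positive_fraction=0.3,
                       effect_size=3.0)
    return [
        (build_features(p, toy_chassis), label)
        for p, label in make_pathway_set(spec, toy_chassis)
    ]


class TestClassifier:
    def test_high_accuracy_on_separable_labels(self, separable_features):
        _, metrics = train_global_classifier(separable_features, seed=42)
        assert metrics["cv_accuracy"] >= 0.9

    def test_single_class_is_a_training_error(self, separable_features):
        positives = [(fv, 1) for fv, lab in separable_features if lab == 1]
        with pytest.raises(TrainingError):
            train_global_classifier(positives)

    def test_training_positive_scores_above_half(self, separable_features):
        model, _ = train_global_classifier(separable_features, seed=42)
        fv_pos = next(fv for fv, lab in separable_features if lab == 1)
        assert global_score(model, fv_pos).value > 0.5

    def test_scores_bounded_and_deterministic(self, separable_features):
        model, _ = train_global_classifier(separable_features, seed=42)
        for fv, _ in separable_features[:10]:
            s1 = global_score(model, fv).value
            s2 = global_score(model, fv).value
            assert 0.0 <= s1 <= 1.0
            assert s1 == s2

    def test_dimensionality_mismatch_is_a_scoring_error(self, separable_features):
        model, _ = train_global_classifier(separable_features, seed=42)
        with pytest.raises(ScoringError):
            model.predict_proba(np.zeros((1, 7)))

    def test_sklearn_estimator_contract(self):
        clf = GlobalScoreClassifier(n_estimators=5)
        params = clf.get_params()
        assert params["max_depth"] == 1000
        assert params["learning_rate"] == pytest.approx(0.3)
        clf.set_params(n_estimators=7)
        assert clf.get_params()["n_estimators"] == 7
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        y = (X[:, 0] > 0).astype(int)
        proba = clf.fit(X, y).predict_proba(X)
        assert proba.shape == (40, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_accuracy_grows_with_planted_effect(self, toy_chassis):
        accs = []
        for effect in (0.0, 1.0, 4.0):
            spec = FixtureSpec(seed=17, n_pathways=120, positive_fraction=0.3,
                               effect_size=effect)
            feats = [
                (build_features(p, toy_chassis), label)
                for p, label in make_pathway_set(spec, toy_chassis)
            ]
            _, metrics = train_global_classifier(feats, seed=42)
            accs.append(metrics["cv_accuracy"])
        assert accs[0] <= accs[1] <= accs[2]
        assert accs[2] >= 0.95


class TestDirectScore:
    def _pathway(self, pid, n_reactions, dg, avail, flux):
        reactions = [
            ReactionRecord(
                id=f"{pid}_r{j}",
                reactants={f"{pid}_s{j}": 1},
                products={f"{pid}_s{j + 1}": 1},
                rule_score=avail,
            )
            for j in range(n_reactions)
        ]
        species = {
            f"{pid}_s{j}": Species(id=f"{pid}_s{j}") for j in range(n_reactions + 1)
        }
        p = PathwayRecord(
            id=pid, reactions=reactions, target_id=f"{pid}_s{n_reactions}",
            species=species,
        )
        p.properties.update({"pathway_dg": dg, "target_flux": flux})
        return p

    def test_identical_candidates_score_equally(self):
        cands = [self._pathway(f"p{i}", 2, -10, 0.5, 1.0) for i in range(3)]
        scores = direct_score(cands)
        assert len({s.value for s in scores}) == 1

    def test_dominating_candidate_is_strictly_maximal(self):
        dominator = self._pathway("dom", 1, -50, 0.9, 5.0)
        others = [
            self._pathway("o1", 3, -10, 0.5, 1.0),
            self._pathway("o2", 2, -20, 0.7, 2.0),
        ]
        scores = direct_score([dominator] + others)
        assert scores[0].value > max(s.value for s in scores[1:])

    def test_two_candidate_hand_computation(self):
        c1 = self._pathway("c1", 2, -10.0, 0.8, 2.0)
        c2 = self._pathway("c2", 4, -5.0, 0.4, 1.0)
        s1, s2 = direct_score([c1, c2])
        # c1 wins every normalised axis (value 1), c2 loses every one (value 0)
        assert s1.components == pytest.approx((0.5, 1.0, 1.0, 1.0))
        assert s2.components == pytest.approx((0.25, 0.0, 0.0, 0.0))
        assert s1.value == pytest.approx(3.5)
        assert s2.value == pytest.approx(0.25)
        assert c1.properties["direct_score"] == pytest.approx(3.5)

    def test_invariant_to_affine_flux_rescaling(self):
        base = [
            self._pathway("p1", 2, -10, 0.8, 1.0),
            self._pathway("p2", 2, -20, 0.6, 2.0),
            self._pathway("p3", 3, -30, 0.4, 3.0),
        ]
        rescaled = [
            self._pathway("q1", 2, -10, 0.8, 1.0 * 7 + 3),
            self._pathway("q2", 2, -20, 0.6, 2.0 * 7 + 3),
            self._pathway("q3", 3, -30, 0.4, 3.0 * 7 + 3),
        ]
        v1 = [s.value for s in direct_score(base)]
        v2 = [s.value for s in direct_score(rescaled)]
        assert v1 == pytest.approx(v2)

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ArgumentError):
            direct_score([])


class TestTopkRecovery:
    def test_unique_maximum_recovered_at_k1(self):
        scored = [("g", 0.9, True), ("g", 0.5, False), ("g", 0.1, False)]
        assert topk_recovery(scored, 1) == 1.0

    def test_k_at_least_group_size_always_recovers(self):
        scored = [("g", s, ref) for s, ref in [(0.1, True), (0.5, False), (0.9, False)]]
        assert topk_recovery(scored, 3) == 1.0
        assert topk_recovery(scored, 50) == 1.0

    def test_reference_outside_topk_not_recovered(self):
        scored = [("g", 0.1, True), ("g", 0.5, False), ("g", 0.9, False)]
        assert topk_recovery(scored, 2) == 0.0

    def test_ties_share_rank(self):
        scored = [("g", 0.9, False), ("g", 0.9, True), ("g", 0.5, False)]
        assert topk_recovery(scored, 1) == 1.0

    def test_fraction_over_groups(self):
        scored = [
            ("g1", 0.9, True), ("g1", 0.5, False),
            ("g2", 0.1, True), ("g2", 0.5, False), ("g2", 0.9, False),
            ("g3", 0.4, False),  # no reference: excluded from the denominator
        ]
        assert topk_recovery(scored, 1) == pytest.approx(0.5)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(23)
        scored = []
        for g in range(8):
            n = int(rng.integers(3, 12))
            ref_idx = int(rng.integers(n))
            for i in range(n):
                scored.append((f"g{g}", float(rng.random()), i == ref_idx))
        values = [topk_recovery(scored, k) for k in range(1, 13)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))

    def test_k_below_one_rejected(self):
        with pytest.raises(ArgumentError):
            topk_recovery([("g", 0.5, True)], 0)
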