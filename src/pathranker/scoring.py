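"""Pathway scoring: features, learned global score, direct score, top-k recovery.

A candidate pathway is summarised by pathway-level features (chassis taxon
id, pathway ΔG, fraction-of-reaction target flux) and reaction-level features
aggregated order-free over its reactions (elementwise sum of 4096-position
Morgan count fingerprints, mean enzyme-availability score, sum of reaction
ΔGs, reaction count). A reaction's fingerprint is the elementwise sum of its
substrates' and products' circular fingerprints (radius 2, count-folded).

The global score is the positive-class probability of a gradient-boosted
tree classifier (maximum tree depth 1000, shrinkage 0.3, other
hyperparameters at library defaults) trained on labelled pathway collections
and evaluated by stratified 4-fold cross-validation at a 0.5 threshold.

The direct score needs no training: it is the sum of four [0,1] components —
inverse pathway length, negated min-max-normalised ΔG, normalised mean
availability, normalised target flux — where normalisation is across the
candidate set sharing one (target, chassis) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .errors import ArgumentError, FeatureError, ScoringError, TrainingError
from .records import ChassisModel, PathwayRecord, ReactionRecord, Species

FP_BITS = 4096
FP_RADIUS = 2
SCORE_THRESHOLD = 0.5
DEFAULT_SEED = 42


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

def _mol_of(sp: Species):
    from rdkit import Chem

    mol = None
    if sp.smiles:
        mol = Chem.MolFromSmiles(sp.smiles)
    if mol is None and sp.inchi:
        mol = Chem.MolFromInchi(sp.inchi)
    return mol


def species_fingerprint(sp: Species) -> np.ndarray:
    """Morgan count fingerprint (radius 2) folded to 4096 positions."""
    from rdkit.Chem import rdFingerprintGenerator

    mol = _mol_of(sp)
    if mol is None:
        raise FeatureError(f"species {sp.id!r} has no usable structure")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=FP_RADIUS, fpSize=FP_BITS
    )
    fp = gen.GetCountFingerprint(mol)
    vec = np.zeros(FP_BITS, dtype=np.int64)
    for idx, count in fp.GetNonzeroElements().items():
        vec[idx] = count
    return vec


def reaction_fingerprint(
    r: ReactionRecord, species: Mapping[str, Species]
) -> np.ndarray:
    """Fingerprint(reaction) = Fingerprint(substrates) + Fingerprint(products),
    elementwise over all participating species."""
    vec = np.zeros(FP_BITS, dtype=np.int64)
    for sid in list(r.reactants) + list(r.products):
        sp = species.get(sid)
        if sp is None:
            raise FeatureError(f"species {sid!r} missing from pathway species map")
        vec += species_fingerprint(sp)
    return vec


# ---------------------------------------------------------------------------
# Feature vectors
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """Classifier input for one pathway.

    Missing pathway ΔG or flux is imputed with 0 and flagged, so pathways
    with unresolved species remain scoreable.
    """

    taxon_id: int
    pathway_dg: float
    target_flux: float
    reaction_fp_agg: np.ndarray
    availability_mean: float
    reaction_dg_sum: float
    n_reactions: int
    dg_missing: bool = False
    flux_missing: bool = False

    def __post_init__(self) -> None:
        if len(self.reaction_fp_agg) != FP_BITS:
            raise FeatureError(
                f"fingerprint length {len(self.reaction_fp_agg)} != {FP_BITS}"
            )
        if not 0.0 <= self.availability_mean <= 1.0:
            raise FeatureError(
                f"availability_mean {self.availability_mean} not in [0,1]"
            )

    def to_array(self) -> np.ndarray:
        head = np.array(
            [
                float(self.taxon_id),
                self.pathway_dg,
                self.target_flux,
                self.availability_mean,
                self.reaction_dg_sum,
                float(self.n_reactions),
                float(self.dg_missing),
                float(self.flux_missing),
            ]
        )
        return np.concatenate([head, self.reaction_fp_agg.astype(float)])

    @staticmethod
    def column_names() -> list[str]:
        head = [
            "taxon_id",
            "pathway_dg",
            "target_flux",
            "availability_mean",
            "reaction_dg_sum",
            "n_reactions",
            "dg_missing",
            "flux_missing",
        ]
        return head + [f"fp{i}" for i in range(FP_BITS)]


def build_features(p: PathwayRecord, chassis: ChassisModel) -> FeatureVector:
    """Aggregate pathway- and reaction-level features, order-free."""
    dg = p.properties.get("pathway_dg")
    flux = p.properties.get("target_flux")
    fp = np.zeros(FP_BITS, dtype=np.int64)
    for r in p.reactions:
        fp += reaction_fingerprint(r, p.species)
    scores = [r.rule_score for r in p.reactions if r.rule_score is not None]
    dgs = [r.dg_prime for r in p.reactions if r.dg_prime is not None]
    return FeatureVector(
        taxon_id=chassis.taxon_id,
        pathway_dg=float(dg) if dg is not None else 0.0,
        target_flux=float(flux) if flux is not None else 0.0,
        reaction_fp_agg=fp,
        availability_mean=float(np.mean(scores)) if scores else 0.0,
        reaction_dg_sum=float(np.sum(dgs)) if dgs else 0.0,
        n_reactions=len(p.reactions),
        dg_missing=dg is None,
        flux_missing=flux is None,
    )


# ---------------------------------------------------------------------------
# Learned global score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlobalScore:
    """Positive-class probability that a pathway is valid/engineerable."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ScoringError(f"global score {self.value} not in [0,1]")


class GlobalScoreClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted tree classifier over pathway feature vectors.

    sklearn-compatible estimator wrapping XGBoost with the scoring defaults:
    maximum tree depth 1000 and shrinkage (learning rate) 0.3; everything
    else at library defaults.

    Parameters
    ----------
    max_depth : int, default 1000
    learning_rate : float, default 0.3
    n_estimators : int, default 100
    random_state : int, default 42
    """

    def __init__(
        self,
        max_depth: int = 1000,
        learning_rate: float = 0.3,
        n_estimators: int = 100,
        random_state: int = DEFAULT_SEED,
    ):
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        import xgboost as xgb

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise TrainingError("training labels contain a single class")
        self.n_features_in_ = X.shape[1]
        self._booster = xgb.XGBClassifier(
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            n_estimators=self.n_estimators,
            random_state=self.random_state,
            n_jobs=1,
            eval_metric="logloss",
        )
        self._booster.fit(X, y)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "_booster")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ScoringError(
                f"feature dimensionality {X.shape[1]} != trained {self.n_features_in_}"
            )
        return self._booster.predict_proba(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] > SCORE_THRESHOLD).astype(int)]


def train_global_classifier(
    labeled: Sequence[tuple[FeatureVector, int]],
    params: dict | None = None,
    seed: int = DEFAULT_SEED,
    n_folds: int = 4,
) -> tuple[GlobalScoreClassifier, dict]:
    """Train the global scorer and report stratified CV metrics.

    Returns the model fitted on all data and a dict with ``cv_accuracy`` and
    ``cv_fpr`` (pooled over folds, threshold 0.5).

    Raises
    ------
    TrainingError
        If only one class is present.
    """
    if not labeled:
        raise TrainingError("empty training set")
    X = np.vstack([fv.to_array() for fv, _ in labeled])
    y = np.array([int(lab) for _, lab in labeled])
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")

    params = dict(params or {})
    params.setdefault("random_state", seed)
    model = GlobalScoreClassifier(**params)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        fold = GlobalScoreClassifier(**params)
        fold.fit(X[train_idx], y[train_idx])
        proba = fold.predict_proba(X[test_idx])[:, 1]
        pred = (proba > SCORE_THRESHOLD).astype(int)
        truth = y[test_idx]
        accs.append(float(np.mean(pred == truth)))
        tp += int(np.sum((pred == 1) & (truth == 1)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
        tn += int(np.sum((pred == 0) & (truth == 0)))
        fn += int(np.sum((pred == 0) & (truth == 1)))

    model.fit(X, y)
    metrics = {
        "cv_accuracy": float(np.mean(accs)),
        "cv_fpr": (fp / (fp + tn)) if (fp + tn) else 0.0,
        "n_folds": n_folds,
    }
    return model, metrics


def global_score(
    model: GlobalScoreClassifier, features: FeatureVector | PathwayRecord,
    chassis: ChassisModel | None = None,
) -> GlobalScore:
    """Positive-class probability for one pathway (stored in its properties
    when a PathwayRecord is given)."""
    record = None
    if isinstance(features, PathwayRecord):
        if chassis is None:
            raise ScoringError("scoring a PathwayRecord needs the chassis model")
        record = features
        features = build_features(features, chassis)
    proba = model.predict_proba(features.to_array()[None, :])[0, 1]
    score = GlobalScore(value=float(proba))
    if record is not None:
        record.properties["global_score"] = score.value
    return score


# ---------------------------------------------------------------------------
# Direct score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectScore:
    """Sum of four normalised components in [0,1] each."""

    value: float
    components: tuple[float, float, float, float]  # (inv_length, neg_norm_dg, norm_availability, norm_flux)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi - lo < 1e-12:
        return np.full(len(values), 0.5)
    return (values - lo) / (hi - lo)


def direct_score(candidates: Sequence[PathwayRecord]) -> list[DirectScore]:
    """Direct (non-learned) scores across one candidate set.

    Components per candidate: 1/n_reactions; min-max of the negated pathway
    ΔG; min-max of the mean availability score; min-max of the target flux.
    Missing ΔG or flux enters normalisation as 0. The score is stored in each
    pathway's ``properties['direct_score']``.

    Raises
    ------
    ArgumentError
        On an empty candidate list.
    """
    if not candidates:
        raise ArgumentError("empty candidate list")
    neg_dg = np.array(
        [-float(p.properties.get("pathway_dg", 0.0)) for p in candidates]
    )
    avail = np.array(
        [
            float(
                np.mean(
                    [r.rule_score for r in p.reactions if r.rule_score is not None]
                    or [0.0]
                )
            )
            for p in candidates
        ]
    )
    flux = np.array(
        [float(p.properties.get("target_flux", 0.0)) for p in candidates]
    )
    neg_dg_n = _minmax(neg_dg)
    avail_n = _minmax(avail)
    flux_n = _minmax(flux)

    out = []
    for i, p in enumerate(candidates):
        comps = (
            1.0 / len(p.reactions),
            float(neg_dg_n[i]),
            float(avail_n[i]),
            float(flux_n[i]),
        )
        score = DirectScore(value=float(sum(comps)), components=comps)
        p.properties["direct_score"] = score.value
        out.append(score)
    return out


# ---------------------------------------------------------------------------
# Top-k recovery
# ---------------------------------------------------------------------------

def topk_recovery(
    scored: Sequence[tuple[object, float, bool]], k: int
) -> float:
    """Fraction of (target, chassis) groups whose reference pathway scores
    within the k highest distinct scores of the group (ties share rank).

    ``scored`` items are ``(pathway_or_group_key, score, is_reference)``;
    a :class:`PathwayRecord` groups by ``(target_id, chassis_id property)``,
    any other first element is used as the group key directly.

    Raises
    ------
    ArgumentError
        If ``k < 1``.
    """
    if k < 1:
        raise ArgumentError(f"k must be >= 1, got {k}")

    groups: dict[object, list[tuple[float, bool]]] = {}
    for item, score, is_ref in scored:
        if isinstance(item, PathwayRecord):
            key = (item.target_id, item.properties.get("chassis_id"))
        else:
            key = item
        groups.setdefault(key, []).append((float(score), bool(is_ref)))

    n_groups = 0
    n_recovered = 0
    for members in groups.values():
        ref_scores = [s for s, is_ref in members if is_ref]
        if not ref_scores:
            continue
        n_groups += 1
        distinct = sorted({s for s, _ in members}, reverse=True)
        threshold = distinct[min(k, len(distinct)) - 1]
        if max(ref_scores) >= threshold:
            n_recovered += 1
    if n_groups == 0:
        return 0.0
    return n_recovered / n_groups
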