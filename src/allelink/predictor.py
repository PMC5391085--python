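"""Random Forest rescue of untestable variant-gene pairs.

Pairs whose allelic imbalance could be observed form the training data:
pairs imbalanced on both sides with matching direction are the true class,
testable pairs failing those tests the control class.  Ten Random Forest
classifiers come from a 5-fold stratified cross-validation repeated twice
(each pair is held out exactly twice); every classifier then votes on the
untestable pairs — those with no usable heterozygote — and a pair is called
positive when more than 5 of the 10 classifiers support it.

Each forest uses 1000 trees, mtry = floor(sqrt(#features)), terminal nodes
grown to minimum size 1.  The subpanel experiment repeats the whole
procedure on random sample subsets (2, 5, 10 or 20 samples, 10 resamplings)
to measure how panel size affects prediction stability, and rescue calls
from a subpanel are validated by re-testing them on the full panel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .features import FeatureMatrix, FeatureSpec, build_feature_matrix, pair_id
from .imbalance import ImbalanceConfig
from .pairing import (CONTROL_PAIR, TRUE_PAIR, UNTESTABLE, AllelicPair,
                      build_pairs)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 1000
    folds: int = 5
    repetitions: int = 2
    vote_threshold: int = 5  # positive iff votes strictly greater
    seed: int = 0

    @property
    def ensemble_size(self) -> int:
        return self.folds * self.repetitions

    @staticmethod
    def mtry(n_features: int) -> int:
        """Default mtry: floor of the square root of the feature count."""
        return max(1, math.floor(math.sqrt(n_features)))


@dataclass
class EnsembleResult:
    classifiers: list[RandomForestClassifier]
    fold_assignments: list[np.ndarray]   # held-out index array per classifier
    cv_scores: list[float]               # held-out AUC per classifier
    feature_names: list[str]
    votes: dict[str, int] = field(default_factory=dict)
    positives: set[str] = field(default_factory=set)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.cv_scores))


def partition_cases(pairs: Sequence[AllelicPair]
                    ) -> tuple[list[AllelicPair], list[AllelicPair], list[AllelicPair]]:
    """Split pairs into (true, control, untestable) by their labels."""
    true_set = [p for p in pairs if p.label == TRUE_PAIR]
    control_set = [p for p in pairs if p.label == CONTROL_PAIR]
    untestable_set = [p for p in pairs if p.label == UNTESTABLE]
    return true_set, control_set, untestable_set


def train_ensemble(X: FeatureMatrix, y: Sequence[int],
                   cfg: ForestConfig = ForestConfig()) -> EnsembleResult:
    """Train the 10-classifier ensemble by stratified 5-fold x 2 CV.

    Each classifier is fit on its fold complement and scored by AUC on its
    held-out fold; every pair is held out exactly twice.  Deterministic
    under ``cfg.seed``.
    """
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("train_ensemble needs both classes present")
    counts = np.bincount(y)
    if counts[counts > 0].min() < cfg.folds:
        raise ValueError(
            f"minority class has {counts[counts > 0].min()} members; "
            f"stratified {cfg.folds}-fold CV needs at least {cfg.folds}")
    values = X.values
    splitter = RepeatedStratifiedKFold(n_splits=cfg.folds,
                                       n_repeats=cfg.repetitions,
                                       random_state=cfg.seed)
    classifiers, folds, scores = [], [], []
    for i, (train_idx, test_idx) in enumerate(splitter.split(values, y)):
        clf = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_features="sqrt",
            min_samples_leaf=1,
            random_state=cfg.seed * 1000 + i,
            n_jobs=1,
        )
        clf.fit(values[train_idx], y[train_idx])
        scores.append(float(roc_auc_score(
            y[test_idx], clf.predict_proba(values[test_idx])[:, 1])))
        classifiers.append(clf)
        folds.append(test_idx)
    return EnsembleResult(classifiers, folds, scores, X.feature_names)


def rescue_untestable(ensemble: EnsembleResult, X_untestable: FeatureMatrix,
                      cfg: ForestConfig = ForestConfig()) -> EnsembleResult:
    """Vote every classifier on the untestable pairs; positive iff votes > 5."""
    if X_untestable.feature_names != ensemble.feature_names:
        raise ValueError("feature columns do not match the trained ensemble")
    values = X_untestable.values
    votes = np.zeros(len(values), dtype=int)
    for clf in ensemble.classifiers:
        votes += (clf.predict(values) == 1).astype(int)
    ensemble.votes = dict(zip(X_untestable.pair_ids, votes.tolist()))
    ensemble.positives = {pid for pid, v in ensemble.votes.items()
                          if v > cfg.vote_threshold}
    return ensemble


# ---------------------------------------------------------------------------
# Subpanel experiments and rescue validation
# ---------------------------------------------------------------------------

@dataclass
class MappingInputs:
    """Everything needed to run pairing + features on a sample panel."""

    tags: list
    ld_expansion: dict
    peaks: list
    interactions: list
    genes: list
    panel: "object"
    counts: list
    imbalance_cfg: ImbalanceConfig
    feature_specs: list[FeatureSpec]
    tracks: dict
    go_sets: dict
    affinity: dict

    def restrict_samples(self, samples: Sequence[str]) -> "MappingInputs":
        sub_panel = self.panel.subset_samples(list(samples))
        keep = set(samples)
        sub_counts = [c for c in self.counts if c.sample in keep]
        return replace(self, panel=sub_panel, counts=sub_counts)

    def build(self) -> list[AllelicPair]:
        return build_pairs(self.tags, self.ld_expansion, self.peaks,
                           self.interactions, self.genes, self.panel,
                           self.counts, self.imbalance_cfg, with_ld=False)

    def feature_matrix(self, pairs: Sequence[AllelicPair]) -> FeatureMatrix:
        snps = {s.id: s for s in self.panel.snps}
        genes = {g.gene_id: g for g in self.genes}
        return build_feature_matrix(pairs, self.feature_specs, self.tracks,
                                    self.go_sets, self.affinity, snps, genes)


@dataclass
class SubpanelRun:
    samples: list[str]
    ensemble: EnsembleResult | None
    n_true: int
    n_control: int
    n_untestable: int
    failure: str | None = None


def train_and_rescue(inputs: MappingInputs,
                     cfg: ForestConfig) -> SubpanelRun:
    """Pair, partition, train and vote on one (sub)panel."""
    pairs = inputs.build()
    true_set, control_set, untestable_set = partition_cases(pairs)
    run = SubpanelRun(list(inputs.panel.samples), None,
                      len(true_set), len(control_set), len(untestable_set))
    labelled = true_set + control_set
    if not labelled:
        run.failure = "no testable pairs"
        return run
    X = inputs.feature_matrix(labelled)
    y = [1] * len(true_set) + [0] * len(control_set)
    try:
        ensemble = train_ensemble(X, y, cfg)
    except ValueError as exc:
        run.failure = str(exc)
        return run
    if untestable_set:
        rescue_untestable(ensemble, inputs.feature_matrix(untestable_set), cfg)
    run.ensemble = ensemble
    return run


def subsample_experiment(inputs: MappingInputs, k: int, n_reps: int = 10,
                         seed: int = 0,
                         cfg: ForestConfig = ForestConfig()) -> list[SubpanelRun]:
    """Repeat training on random k-sample subpanels of the full panel."""
    all_samples = list(inputs.panel.samples)
    if k > len(all_samples):
        raise ValueError(f"k={k} exceeds panel size {len(all_samples)}")
    rng = np.random.default_rng(seed)
    runs = []
    for rep in range(n_reps):
        chosen = sorted(rng.choice(all_samples, size=k, replace=False).tolist())
        sub_cfg = replace(cfg, seed=cfg.seed * 100 + rep + 1)
        runs.append(train_and_rescue(inputs.restrict_samples(chosen), sub_cfg))
    return runs


@dataclass(frozen=True)
class RescueValidation:
    n_predicted: int
    n_tested: int
    n_confirmed: int

    @property
    def percentage(self) -> float:
        """Confirmed / tested, in percent; NaN when nothing was testable."""
        if self.n_tested == 0:
            return float("nan")
        return 100.0 * self.n_confirmed / self.n_tested


def validate_rescue(positive_ids: set[str],
                    full_panel_pairs: Sequence[AllelicPair]) -> RescueValidation:
    """Check subpanel rescue calls against the full panel's imbalance tests.

    A positive call is "tested" when the full panel makes the pair testable
    and "confirmed" when the full panel labels it allele-specific (both
    sides imbalanced with matching direction).
    """
    by_id = {pair_id(p): p for p in full_panel_pairs}
    tested = confirmed = 0
    for pid in positive_ids:
        p = by_id.get(pid)
        if p is None or p.label == UNTESTABLE:
            continue
        tested += 1
        if p.label == TRUE_PAIR:
            confirmed += 1
    return RescueValidation(len(positive_ids), tested, confirmed)
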