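"""Decision fusion of SVM experts and low-level channel fusion.

Three fusion configurations are supported:

* single_layer_multi_view — e.g. three experts trained on pressure,
  altitude and velocity descriptors tapped at one layer;
* multi_layer_single_view — three experts on one view at three layers;
* multi_layer_multi_view — e.g. nine experts, three views x three layers.

Decision fusion is a hard majority vote over per-subject class decisions;
every configuration uses an odd expert count, so no tie rule is needed.
Low-level fusion instead combines information before feature extraction:
the three hybrid views are placed in the three input channels of a single
image, features are extracted once, and a single expert is trained.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .deep_features import (
    DEFAULT_CHANNEL_ORDER,
    ExtractorConfig,
    FeatureVector,
    compose_channels,
    extract_features,
)
from .expert_classifier import (
    AD,
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    HC,
    EvalResult,
    SamplingPlan,
    _split_ids,
    aggregate,
    confusion_from_decisions,
    run_expert_protocol,
    train_expert,
)

logger = logging.getLogger("spiralad")

FUSION_MODES = (
    "single_layer_multi_view",
    "multi_layer_single_view",
    "multi_layer_multi_view",
    "low_level",
)


class FusionConfigError(ValueError):
    """Invalid fusion scheme (even expert count, missing features, ...)."""


@dataclass(frozen=True)
class FusionScheme:
    """A fusion configuration: expert (view, layer) pairs plus a mode."""

    experts: tuple[tuple[str, str], ...]
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in FUSION_MODES:
            raise FusionConfigError(f"mode must be one of {FUSION_MODES}")
        object.__setattr__(self, "experts", tuple((v, l) for v, l in self.experts))
        if self.mode != "low_level" and len(self.experts) % 2 == 0:
            raise FusionConfigError(
                f"decision fusion requires an odd expert count, got {len(self.experts)}"
            )


def majority_vote(decisions: Sequence[str]) -> str:
    """The class with strictly more votes among an odd number of experts."""
    if len(decisions) % 2 == 0:
        raise FusionConfigError("majority vote requires an odd number of decisions")
    counts = Counter(decisions)
    winner, n = counts.most_common(1)[0]
    if n <= len(decisions) / 2:
        raise FusionConfigError(f"no strict majority in {dict(counts)}")
    return winner


class FeatureStore:
    """Per-(view, layer) feature matrices keyed by subject, with labels."""

    def __init__(self, labels: Mapping[str, str]):
        self.labels = dict(labels)
        self._sets: dict[tuple[str, str], dict[str, np.ndarray]] = {}

    def add(self, vectors: Sequence[FeatureVector]) -> None:
        for v in vectors:
            self._sets.setdefault((v.view, v.layer), {})[v.subject_id] = v.values

    def get(self, view: str, layer: str) -> dict[str, np.ndarray]:
        key = (view, layer)
        if key not in self._sets:
            raise FusionConfigError(
                f"no features stored for view={view!r} layer={layer!r}; "
                f"available: {sorted(self._sets)}"
            )
        missing = set(self.labels) - set(self._sets[key])
        if missing:
            raise FusionConfigError(
                f"features for ({view}, {layer}) missing subjects: {sorted(missing)[:5]}"
            )
        return self._sets[key]

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._sets)


def run_decision_fusion(
    scheme: FusionScheme,
    plan: SamplingPlan,
    store: FeatureStore,
    c_grid: Sequence = DEFAULT_C_GRID,
    gamma_grid: Sequence = DEFAULT_GAMMA_GRID,
    return_details: bool = False,
):
    """Majority-vote fusion of experts sharing one sampling plan.

    Per repetition, every (view, layer) expert is trained and tested
    independently on the same subject split (and the same CV fold seed, so
    decisions align subject-by-subject); the fused per-subject decision is
    the majority vote. Returns the fused EvalResult, plus per-expert
    EvalResults and the per-repetition decision matrices when
    ``return_details`` is set.
    """
    if scheme.mode == "low_level":
        raise FusionConfigError("low_level schemes go through run_low_level_fusion")
    expert_feats = {pair: store.get(*pair) for pair in scheme.experts}
    hc_ids = sorted(s for s, l in store.labels.items() if l == HC)
    ad_ids = sorted(s for s, l in store.labels.items() if l == AD)
    fused_counts = []
    per_expert_counts: dict[tuple[str, str], list] = {p: [] for p in scheme.experts}
    decision_log = []
    for rep in plan.repetitions:
        train_ids, train_y, test_ids, test_y = _split_ids(rep, hc_ids, ad_ids)
        decisions = np.empty((len(scheme.experts), len(test_ids)), dtype=object)
        for k, pair in enumerate(scheme.experts):
            feats = expert_feats[pair]
            X_train = np.stack([feats[s] for s in train_ids])
            X_test = np.stack([feats[s] for s in test_ids])
            model = train_expert(
                X_train, train_y, c_grid, gamma_grid,
                cv_seed=rep.cv_seed, view=pair[0], layer=pair[1],
            )
            decisions[k] = model.predict(X_test)
            per_expert_counts[pair].append(confusion_from_decisions(decisions[k], test_y))
        fused = [majority_vote(list(decisions[:, j])) for j in range(len(test_ids))]
        fused_counts.append(confusion_from_decisions(fused, test_y))
        decision_log.append({"test_ids": test_ids, "test_labels": test_y, "decisions": decisions})
    result = aggregate(fused_counts)
    if return_details:
        per_expert = {p: aggregate(cs) for p, cs in per_expert_counts.items()}
        return result, per_expert, decision_log
    return result


def run_low_level_fusion(
    views: Mapping[str, Mapping[str, "GrayImage"]],
    plan: SamplingPlan,
    layer: str,
    labels: Mapping[str, str],
    extractor: ExtractorConfig = ExtractorConfig(),
    order: Sequence[str] = DEFAULT_CHANNEL_ORDER,
    c_grid: Sequence = DEFAULT_C_GRID,
    gamma_grid: Sequence = DEFAULT_GAMMA_GRID,
) -> EvalResult:
    """Channel-fuse three hybrid views, extract once, train one expert.

    ``views`` maps view name -> {subject_id: GrayImage} for the three views
    in ``order``. Each subject's views are stacked into one 3-channel image,
    features are extracted at ``layer``, and a single SVM expert runs under
    the standard protocol.
    """
    missing = [v for v in order if v not in views]
    if missing:
        raise FusionConfigError(f"low-level fusion missing rendered views: {missing}")
    features: dict[str, np.ndarray] = {}
    for sid in labels:
        try:
            imgs = [views[v][sid] for v in order]
        except KeyError as exc:
            raise FusionConfigError(f"subject {sid!r} missing from view {exc}") from exc
        composite = compose_channels(imgs, order)
        features[sid] = extract_features(
            composite, layer, extractor, subject_id=sid, view="composite"
        ).values
    return run_expert_protocol(
        features, dict(labels), plan, c_grid, gamma_grid, view="composite", layer=layer
    )
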