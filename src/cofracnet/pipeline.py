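"""End-to-end orchestration: from elution matrices to condition networks.

Ties the stages together: profile cleaning and Gaussian deconvolution, pair
feature computation over the candidate universe, reference-calibrated naive
Bayes scoring, running precision, and the 50%-precision network cut.  Also
provides planted-truth evaluation helpers for synthetic experiments.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .chromatograms import (
    CoFractionationDataset,
    clean_profile,
    fit_gaussians,
)
from .errors import ProfileFitError
from .inference import (
    InteractionNetwork,
    Pair,
    ReferenceComplexSet,
    ScoredInteraction,
    build_network,
    compute_pair_features,
    label_pairs,
    precision_curve,
    score_pairs,
)

__all__ = ["InferenceResult", "infer_network", "network_precision"]

log = logging.getLogger(__name__)


@dataclass
class InferenceResult:
    """Output of one condition's network inference."""

    network: InteractionNetwork
    ranked: list[ScoredInteraction]
    n_candidates: int
    n_labeled: int
    skipped_proteins: list[str]


def infer_network(
    dataset: CoFractionationDataset,
    reference: ReferenceComplexSet,
    *,
    min_consecutive: int = 5,
    max_components: int = 5,
    min_cooccurring: int = 5,
    n_folds: int = 10,
    precision_threshold: float = 0.5,
    seed: int = 0,
) -> InferenceResult:
    """Infer one condition's interaction network from its elution profiles.

    Profiles are cleaned and deconvolved; proteins whose profiles cannot be
    fitted (too few observed fractions) are skipped.  Candidate pairs are all
    pairs with at least ``min_cooccurring`` mutually observed fractions and
    defined correlations; they are scored by reference-calibrated naive Bayes
    with complex-level cross-validation and the network is cut at the largest
    rank whose running precision meets ``precision_threshold``.
    """
    cleaned, fits, skipped = {}, {}, []
    for pid in dataset.protein_ids:
        prof = dataset.profiles[pid]
        cl = clean_profile(prof, min_consecutive)
        try:
            fits[pid] = fit_gaussians(cl, max_components=max_components)
        except ProfileFitError:
            skipped.append(pid)
            continue
        cleaned[pid] = cl
    if skipped:
        log.info(
            "%s: %d/%d profiles unusable after cleaning",
            dataset.condition,
            len(skipped),
            len(dataset.profiles),
        )

    usable = sorted(cleaned)
    features = {}
    for a, b in itertools.combinations(usable, 2):
        pa, pb = dataset.profiles[a], dataset.profiles[b]
        mutual = int((~np.isnan(pa.values) & ~np.isnan(pb.values)).sum())
        if mutual < min_cooccurring:
            continue
        feats = compute_pair_features(
            pa,
            pb,
            fits[a],
            fits[b],
            cleaned_a=cleaned[a],
            cleaned_b=cleaned[b],
            min_consecutive=min_consecutive,
        )
        if not (np.isfinite(feats.pearson_raw) and np.isfinite(feats.pearson_cleaned)):
            continue
        features[(a, b)] = feats

    labels = label_pairs(features.keys(), reference)
    ranked = score_pairs(
        features, labels, n_folds=n_folds, seed=seed, reference=reference
    )
    ranked = precision_curve(ranked)
    network = build_network(
        ranked, precision_threshold=precision_threshold, condition=dataset.condition
    )
    n_labeled = sum(1 for v in labels.values() if v != "unknown")
    return InferenceResult(
        network=network,
        ranked=ranked,
        n_candidates=len(features),
        n_labeled=n_labeled,
        skipped_proteins=skipped,
    )


def network_precision(network: InteractionNetwork, true_pairs) -> float:
    """Fraction of network edges that are planted co-complex pairs."""
    if not network.edges:
        return float("nan")
    truth = set(true_pairs)
    return sum(1 for e in network.edges if e in truth) / network.n_edges
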