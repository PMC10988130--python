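"""Co-elution pair scoring, precision calibration, and network construction.

The core inference step of co-fractionation interactomics: candidate protein
pairs are scored for co-elution with a Gaussian naive Bayes classifier trained
on pairs labeled true-positive (co-occurring in a reference complex catalogue,
e.g. CORUM) or false-positive (both proteins catalogued but never co-complexed).
Running precision — TP / (TP + FP) among labeled interactions of equal or
higher score — is then computed down the ranking and the network is cut at the
largest rank still achieving the chosen precision (50% by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np
from sklearn.naive_bayes import GaussianNB

from .chromatograms import ElutionProfile, GaussianComponent, clean_profile
from .errors import CalibrationError

__all__ = [
    "Pair",
    "canonical_pair",
    "ReferenceComplexSet",
    "PairFeatures",
    "ScoredInteraction",
    "InteractionNetwork",
    "label_pairs",
    "compute_pair_features",
    "score_pairs",
    "precision_curve",
    "build_network",
]

Pair = tuple[str, str]

TP, FP, UNKNOWN = "TP", "FP", "unknown"


def canonical_pair(a: str, b: str) -> Pair:
    """Unordered pair in canonical (lexicographic) order."""
    if a == b:
        raise ValueError(f"self-pair {a!r} is not a valid interaction")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class ReferenceComplexSet:
    """A catalogue of named protein complexes inducing TP/FP pair labels.

    ``tp_pairs`` are unordered pairs co-occurring in at least one complex;
    ``fp_pairs`` are pairs whose members both appear in the catalogue but never
    in the same complex.  The two sets are disjoint by construction.
    """

    complexes: dict[str, frozenset[str]]

    @classmethod
    def from_complexes(cls, complexes: dict[str, set[str] | frozenset[str]]):
        """Build a reference set, dropping complexes of size < 2."""
        kept = {
            cid: frozenset(members)
            for cid, members in complexes.items()
            if len(set(members)) >= 2
        }
        return cls(complexes=kept)

    @cached_property
    def proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.complexes.values():
            out |= members
        return frozenset(out)

    @cached_property
    def tp_pairs(self) -> frozenset[Pair]:
        pairs: set[Pair] = set()
        for members in self.complexes.values():
            for a, b in itertools.combinations(sorted(members), 2):
                pairs.add((a, b))
        return frozenset(pairs)

    @cached_property
    def fp_pairs(self) -> frozenset[Pair]:
        prots = sorted(self.proteins)
        tp = self.tp_pairs
        return frozenset(
            p for p in itertools.combinations(prots, 2) if p not in tp
        )

    def label(self, pair: Pair) -> str:
        if pair in self.tp_pairs:
            return TP
        if pair[0] in self.proteins and pair[1] in self.proteins:
            return FP
        return UNKNOWN

    def complexes_of(self, protein: str) -> list[str]:
        return sorted(
            cid for cid, members in self.complexes.items() if protein in members
        )


def label_pairs(
    pairs, reference: ReferenceComplexSet
) -> dict[Pair, str]:
    """Label each unordered pair TP / FP / unknown against the reference."""
    if not reference.complexes:
        raise CalibrationError("reference complex set is empty")
    return {canonical_pair(*p): reference.label(canonical_pair(*p)) for p in pairs}


@dataclass(frozen=True)
class PairFeatures:
    """Co-elution evidence for one protein pair in one condition.

    pearson_raw / pearson_cleaned
        Pearson correlation over mutually observed fractions of the raw and
        cleaned profiles (NaN when fewer than 2 mutual fractions or a profile
        is constant).
    euclidean_distance
        Euclidean distance between the L2-normalized profiles on mutually
        observed fractions.
    co_apex_distance
        Minimum distance (in fractions) between fitted Gaussian peak centers of
        the two proteins; NaN when either deconvolution is unavailable.
    n_cooccurring
        Number of fractions where both proteins were observed.
    """

    pearson_raw: float
    pearson_cleaned: float
    euclidean_distance: float
    co_apex_distance: float
    n_cooccurring: int

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.pearson_raw,
                self.pearson_cleaned,
                self.euclidean_distance,
                self.co_apex_distance,
                float(self.n_cooccurring),
            ]
        )


FEATURE_NAMES = (
    "pearson_raw",
    "pearson_cleaned",
    "euclidean_distance",
    "co_apex_distance",
    "n_cooccurring",
)


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    if u.size < 2 or np.std(u) == 0 or np.std(v) == 0:
        return float("nan")
    return float(np.corrcoef(u, v)[0, 1])


def compute_pair_features(
    a: ElutionProfile,
    b: ElutionProfile,
    fits_a: list[GaussianComponent] | None = None,
    fits_b: list[GaussianComponent] | None = None,
    *,
    cleaned_a: ElutionProfile | None = None,
    cleaned_b: ElutionProfile | None = None,
    min_consecutive: int = 5,
) -> PairFeatures:
    """Compute co-elution features on the mutually observed fractions.

    ``cleaned_a`` / ``cleaned_b`` may be supplied to avoid re-cleaning profiles
    when features are computed for many pairs.
    """
    if a.n_fractions != b.n_fractions:
        raise ValueError(
            f"profile lengths differ: {a.n_fractions} vs {b.n_fractions}"
        )
    va, vb = a.values, b.values
    mutual = ~np.isnan(va) & ~np.isnan(vb)
    n_co = int(mutual.sum())
    pearson_raw = _pearson(va[mutual], vb[mutual])

    if cleaned_a is None:
        cleaned_a = clean_profile(a, min_consecutive)
    if cleaned_b is None:
        cleaned_b = clean_profile(b, min_consecutive)
    ca, cb = cleaned_a.values, cleaned_b.values
    cmutual = ~np.isnan(ca) & ~np.isnan(cb)
    pearson_cleaned = _pearson(ca[cmutual], cb[cmutual])

    u, v = va[mutual], vb[mutual]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if n_co == 0 or nu == 0 or nv == 0:
        euclid = float("nan")
    else:
        euclid = float(np.linalg.norm(u / nu - v / nv))

    if fits_a and fits_b:
        co_apex = min(
            abs(ga.center - gb.center) for ga in fits_a for gb in fits_b
        )
    else:
        co_apex = float("nan")

    return PairFeatures(
        pearson_raw=pearson_raw,
        pearson_cleaned=pearson_cleaned,
        euclidean_distance=euclid,
        co_apex_distance=float(co_apex),
        n_cooccurring=n_co,
    )


@dataclass(frozen=True)
class ScoredInteraction:
    """A ranked candidate interaction: pair, classifier posterior, reference label."""

    pair: Pair
    score: float
    label: str = UNKNOWN
    running_precision: float | None = None


def _log_odds(model: GaussianNB, X: np.ndarray) -> np.ndarray:
    """Naive-Bayes log odds of the TP class: finer-grained than the posterior.

    The posterior saturates at 1.0 in double precision for strongly separated
    pairs, which would leave the top of the ranking ordered by ties; the log
    odds is a strictly monotone transform of the posterior without that loss
    of resolution.
    """
    jll = np.zeros((X.shape[0], 2))
    for k in range(2):
        jll[:, k] = np.log(model.class_prior_[k]) - 0.5 * np.sum(
            np.log(2.0 * np.pi * model.var_[k])
            + (X - model.theta_[k]) ** 2 / model.var_[k],
            axis=1,
        )
    tp = int(np.where(model.classes_ == 1)[0][0])
    return jll[:, tp] - jll[:, 1 - tp]


def _feature_matrix(features: dict[Pair, PairFeatures], pairs: list[Pair]) -> np.ndarray:
    X = np.array([features[p].as_vector() for p in pairs])
    # Median-impute missing feature values (e.g. co-apex when a fit is absent)
    for j in range(X.shape[1]):
        col = X[:, j]
        bad = ~np.isfinite(col)
        if bad.any():
            finite = col[~bad]
            col[bad] = float(np.median(finite)) if finite.size else 0.0
    return X


def score_pairs(
    features: dict[Pair, PairFeatures],
    labels: dict[Pair, str],
    n_folds: int = 10,
    seed: int = 0,
    reference: ReferenceComplexSet | None = None,
) -> list[ScoredInteraction]:
    """Posterior probability of true interaction for every candidate pair.

    A Gaussian naive Bayes classifier is trained on the labeled (TP/FP) pairs.
    When ``reference`` is given, cross-validation folds are formed over
    reference *complexes* rather than pairs, so that pairs from one complex
    never score themselves: each labeled pair is scored by the fold model whose
    held-out fold contains its (lexicographically first) involved complex.
    Unknown pairs are scored by the model trained on all labeled pairs.
    ``n_folds <= 1`` disables cross-validation (full model for all pairs).

    Output is sorted by descending score with ties broken by pair identity,
    making the ranking a pure function of the inputs and the seed.
    """
    pairs = sorted(features)
    labeled = [p for p in pairs if labels.get(p, UNKNOWN) in (TP, FP)]
    if not labeled:
        raise CalibrationError("no TP/FP labeled pairs available for calibration")
    X = _feature_matrix(features, pairs)
    index = {p: i for i, p in enumerate(pairs)}
    y = np.array([1 if labels[p] == TP else 0 for p in labeled])
    Xl = X[[index[p] for p in labeled]]
    if len(set(y.tolist())) < 2:
        raise CalibrationError("calibration requires both TP and FP labeled pairs")

    full = GaussianNB().fit(Xl, y)
    log_odds = _log_odds(full, X)

    if n_folds > 1:
        rng = np.random.default_rng(seed)
        if reference is not None:
            cids = sorted(reference.complexes)
            if len(cids) < n_folds:
                raise CalibrationError(
                    f"complex-level cross-validation needs at least {n_folds} "
                    f"reference complexes, got {len(cids)}"
                )
            perm = rng.permutation(len(cids))
            fold_of_cid = {cid: int(perm[i]) % n_folds for i, cid in enumerate(cids)}

            def pair_fold(p: Pair) -> int:
                a, b = p
                ca = set(reference.complexes_of(a))
                cb = set(reference.complexes_of(b))
                involved = (ca & cb) if labels[p] == TP else (ca | cb)
                return fold_of_cid[min(involved)]

            folds = np.array([pair_fold(p) for p in labeled])
        else:
            perm = rng.permutation(len(labeled))
            folds = perm % n_folds

        for f in np.unique(folds):
            train = folds != f
            if len(set(y[train].tolist())) < 2:
                continue  # degenerate fold: keep full-model scores
            model = GaussianNB().fit(Xl[train], y[train])
            held = [labeled[i] for i in np.where(folds == f)[0]]
            idx = [index[p] for p in held]
            log_odds[idx] = _log_odds(model, X[idx])

    posterior = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
    order = {p: float(log_odds[index[p]]) for p in pairs}
    ranked = [
        ScoredInteraction(
            pair=p, score=float(posterior[index[p]]), label=labels.get(p, UNKNOWN)
        )
        for p in pairs
    ]
    ranked.sort(key=lambda s: (-order[s.pair], s.pair))
    return ranked


def precision_curve(ranked: list[ScoredInteraction]) -> list[ScoredInteraction]:
    """Fill running precision down a score-sorted ranking.

    At each rank, precision is #TP / (#TP + #FP) among *labeled* pairs of equal
    or higher score; unknown pairs inherit the precision at their rank.  Ranks
    before the first labeled pair carry precision 1 by convention, so the
    precision threshold is a total function of the ranking.
    """
    for prev, cur in zip(ranked, ranked[1:]):
        if cur.score > prev.score:
            raise ValueError("ranking is not sorted by descending score")
    out: list[ScoredInteraction] = []
    tp = fp = 0
    prec = 1.0
    for si in ranked:
        if si.label == TP:
            tp += 1
        elif si.label == FP:
            fp += 1
        if tp + fp:
            prec = tp / (tp + fp)
        out.append(replace(si, running_precision=prec))
    return out


@dataclass(frozen=True)
class InteractionNetwork:
    """A thresholded, simple, undirected interaction network for one condition."""

    condition: str
    edges: frozenset[Pair]

    @classmethod
    def from_edges(cls, edges, condition: str = "") -> "InteractionNetwork":
        canon = frozenset(canonical_pair(*e) for e in edges)
        return cls(condition=condition, edges=canon)

    @cached_property
    def nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return frozenset(out)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_networkx(self):
        """Export as a networkx.Graph (nodes incident to >= 1 edge only)."""
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g


def build_network(
    ranked: list[ScoredInteraction],
    precision_threshold: float = 0.5,
    condition: str = "",
) -> InteractionNetwork:
    """Cut the ranking at the target precision and emit the network.

    The cut is at the *largest* rank K whose running precision still meets the
    threshold (running precision is non-monotone, so this yields the largest
    network achieving it).  Pairs labeled FP against the reference are excluded
    from the emitted edge set even when they rank above the cut.
    """
    if not 0 < precision_threshold <= 1:
        raise ValueError(
            f"precision_threshold must be in (0, 1], got {precision_threshold}"
        )
    edges: list[Pair] = []
    K = 0
    for i, si in enumerate(ranked, start=1):
        if si.running_precision is None:
            raise ValueError("running precision not filled; call precision_curve first")
        if si.running_precision >= precision_threshold:
            K = i
    for si in ranked[:K]:
        if si.label != FP:
            edges.append(si.pair)
    return InteractionNetwork.from_edges(edges, condition=condition)
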