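"""Degree-preserving rewiring nulls and annotation-based network statistics.

The biological coherence of an inferred interactome is assessed by comparing
annotation sharing between interacting pairs to the same statistic on randomly
rewired networks.  Rewiring uses repeated double-edge swaps with rejection,
which preserves every node's degree exactly while randomizing who interacts
with whom — the standard null for topology-dependent statistics.

The same null drives the differential test: for each annotation term, the
difference in within-term edge counts between two condition networks is
compared to its distribution over pairs of independently rewired networks,
yielding a z-score, a normal-approximation p-value and a Benjamini–Hochberg
q-value per term.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedStatisticError
from .inference import InteractionNetwork

__all__ = [
    "AnnotationSet",
    "RewiringNullResult",
    "TermEnrichmentRecord",
    "EnrichmentMapEdge",
    "LogOdds",
    "rewire",
    "sharing_proportion",
    "permutation_test",
    "differential_term_enrichment",
    "content_log_odds",
    "enrichment_map",
]

ASPECTS = (
    "biological_process",
    "molecular_function",
    "cellular_component",
    "disease",
    "domain",
)


@dataclass
class AnnotationSet:
    """Protein → term annotations for one aspect (GO category, disease, or domain).

    For the ``domain`` aspect, ``domain_pairs`` lists unordered pairs of domain
    identifiers known to physically interact in resolved 3D structures; an edge
    is then "supported" when any domain of one endpoint pairs with any domain
    of the other.
    """

    aspect: str
    annotations: dict[str, set[str]] = field(default_factory=dict)
    domain_pairs: set[frozenset[str]] | None = None

    def __post_init__(self) -> None:
        if self.aspect not in ASPECTS:
            raise ValueError(f"unknown annotation aspect {self.aspect!r}")
        if self.domain_pairs is not None and self.aspect != "domain":
            raise ValueError("domain_pairs are only valid for the 'domain' aspect")

    def terms(self, protein: str) -> set[str]:
        return self.annotations.get(protein, set())

    def annotated(self, protein: str) -> bool:
        return bool(self.annotations.get(protein))


@dataclass(frozen=True)
class RewiringNullResult:
    """A permutation statistic against the rewired-network null.

    ``empirical_p = (1 + #{null >= observed}) / (1 + N)``; ``z`` is the
    standardized observed value against the null mean/sd (NaN when the null is
    degenerate with zero spread).
    """

    statistic_name: str
    observed: float
    null_samples: tuple[float, ...]
    empirical_p: float
    z: float


def _edge_shares(u: str, v: str, ann: AnnotationSet) -> bool:
    tu, tv = ann.terms(u), ann.terms(v)
    if ann.aspect == "domain" and ann.domain_pairs is not None:
        return any(
            frozenset((du, dv)) in ann.domain_pairs for du in tu for dv in tv
        )
    return bool(tu & tv)


def rewire(
    network: InteractionNetwork, n_swap_factor: float = 10, seed: int = 0
) -> InteractionNetwork:
    """Randomize a simple network by attempted double-edge swaps.

    Performs ``ceil(n_swap_factor * |E|)`` swap attempts; each attempt picks two
    distinct edges (u,v), (x,y) and a random reconnection (u-x, v-y) or
    (u-y, v-x), rejecting any swap that would create a self-loop or duplicate
    edge.  The degree sequence is preserved exactly.  Deterministic given seed.
    """
    edges = sorted(network.edges)
    m = len(edges)
    if m < 2:
        return InteractionNetwork(condition=network.condition, edges=network.edges)
    n_attempts = math.ceil(n_swap_factor * m)
    rng = np.random.default_rng(seed)
    ii = rng.integers(0, m, n_attempts).tolist()
    jj = rng.integers(0, m, n_attempts).tolist()
    ss = rng.integers(0, 2, n_attempts).tolist()
    edge_set = set(edges)
    for i, j, s in zip(ii, jj, ss):
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if s:
            c, d = d, c
        # proposed new edges: (a, c) and (b, d)
        if a == c or b == d:
            continue
        e1 = (a, c) if a < c else (c, a)
        e2 = (b, d) if b < d else (d, b)
        if e1 == e2 or e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
    return InteractionNetwork(condition=network.condition, edges=frozenset(edge_set))


def sharing_proportion(
    network: InteractionNetwork,
    ann: AnnotationSet,
    *,
    annotated_only: bool = True,
) -> float:
    """Fraction of interacting pairs sharing at least one annotation term.

    By default only edges whose two endpoints each carry >= 1 annotation enter
    the denominator (unannotated proteins are uninformative); pass
    ``annotated_only=False`` to divide by all edges instead.  For the domain
    aspect an edge counts when any cross-endpoint domain pair is a known
    physically interacting pair.

    Raises
    ------
    UndefinedStatisticError
        If no edge is eligible.
    """
    eligible = shared = 0
    for u, v in network.edges:
        if annotated_only and not (ann.annotated(u) and ann.annotated(v)):
            continue
        eligible += 1
        if _edge_shares(u, v, ann):
            shared += 1
    if eligible == 0:
        raise UndefinedStatisticError(
            f"no eligible edges for aspect {ann.aspect!r}: sharing proportion undefined"
        )
    return shared / eligible


def _null_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def permutation_test(
    network: InteractionNetwork,
    ann: AnnotationSet,
    n_null: int = 100,
    seed: int = 0,
    n_swap_factor: float = 10,
    annotated_only: bool = True,
) -> RewiringNullResult:
    """Annotation-sharing enrichment against the degree-preserving null.

    The observed sharing proportion is compared to the same statistic on
    ``n_null`` independently rewired copies of the network; the one-sided
    empirical p-value is ``(1 + #{null >= observed}) / (1 + n_null)``.
    """
    if not network.edges:
        raise UndefinedStatisticError("cannot permutation-test an empty network")
    observed = sharing_proportion(network, ann, annotated_only=annotated_only)
    seeds = _null_seeds(seed, n_null)
    null = []
    for s in seeds:
        rewired = rewire(network, n_swap_factor=n_swap_factor, seed=int(s))
        null.append(
            sharing_proportion(rewired, ann, annotated_only=annotated_only)
        )
    null_arr = np.array(null)
    empirical_p = (1 + int((null_arr >= observed).sum())) / (1 + n_null)
    sd = float(null_arr.std(ddof=1)) if n_null > 1 else 0.0
    z = (observed - float(null_arr.mean())) / sd if sd > 0 else float("nan")
    return RewiringNullResult(
        statistic_name=f"sharing_proportion[{ann.aspect}]",
        observed=observed,
        null_samples=tuple(null),
        empirical_p=empirical_p,
        z=z,
    )


@dataclass(frozen=True)
class LogOdds:
    """Log odds ratio of term annotation between two node sets, with its z-score."""

    log_odds: float
    z: float


def content_log_odds(
    a: InteractionNetwork, b: InteractionNetwork, ann: AnnotationSet
) -> dict[str, LogOdds]:
    """Per-term log odds of annotation among nodes of a vs nodes of b.

    Uses the standard 2x2 asymptotic z = log-OR / SE with the Haldane–Anscombe
    0.5 correction applied to all cells whenever any cell is zero.
    """
    nodes_a, nodes_b = a.nodes, b.nodes
    terms: set[str] = set()
    for p in nodes_a | nodes_b:
        terms |= ann.terms(p)
    out: dict[str, LogOdds] = {}
    na, nb = len(nodes_a), len(nodes_b)
    for t in sorted(terms):
        ka = sum(1 for p in nodes_a if t in ann.terms(p))
        kb = sum(1 for p in nodes_b if t in ann.terms(p))
        cells = [ka, na - ka, kb, nb - kb]
        if 0 in cells:
            cells = [c + 0.5 for c in cells]
        x11, x12, x21, x22 = cells
        log_or = math.log((x11 * x22) / (x12 * x21))
        se = math.sqrt(1 / x11 + 1 / x12 + 1 / x21 + 1 / x22)
        out[t] = LogOdds(log_odds=log_or, z=log_or / se)
    return out


@dataclass(frozen=True)
class TermEnrichmentRecord:
    """Differential within-term connectivity of one annotation term.

    ``delta = n_edges_a - n_edges_b`` is the observed difference in edges whose
    both endpoints carry the term; ``z`` standardizes it against rewired-pair
    nulls, ``p`` is the two-sided normal-approximation p-value and ``q`` its BH
    adjustment.  ``direction`` reports which network the term's interactions
    are enriched in.
    """

    term: str
    n_edges_a: int
    n_edges_b: int
    delta: int
    z: float
    p: float
    q: float
    direction: str
    content_log_odds_z: float
    significant: bool


def _term_edge_counts(
    network: InteractionNetwork, term_proteins: dict[str, set[str]]
) -> dict[str, int]:
    counts = dict.fromkeys(term_proteins, 0)
    membership: dict[str, set[str]] = {}
    for t, prots in term_proteins.items():
        for p in prots:
            membership.setdefault(p, set()).add(t)
    for u, v in network.edges:
        shared = membership.get(u, set()) & membership.get(v, set())
        for t in shared:
            counts[t] += 1
    return counts


def differential_term_enrichment(
    a: InteractionNetwork,
    b: InteractionNetwork,
    ann: AnnotationSet,
    n_null: int = 100,
    fdr: float = 0.10,
    min_annotated: int = 3,
    seed: int = 0,
    n_swap_factor: float = 10,
    max_annotated_fraction: float = 0.5,
) -> list[TermEnrichmentRecord]:
    """Per-term differential connectivity between two condition networks.

    For each term annotating at least ``min_annotated`` network proteins (and
    at most ``max_annotated_fraction`` of them, excluding near-universal root
    terms), the observed within-term edge-count difference is standardized
    against ``n_null`` pairs of independently rewired networks.  Terms with
    ``q < fdr`` are flagged significant.
    """
    if not a.edges or not b.edges:
        raise UndefinedStatisticError("both networks must be non-empty")
    nodes = a.nodes | b.nodes
    n_nodes = len(nodes)
    term_proteins: dict[str, set[str]] = {}
    for p in nodes:
        for t in ann.terms(p):
            term_proteins.setdefault(t, set()).add(p)
    eligible = {
        t: prots
        for t, prots in term_proteins.items()
        if min_annotated <= len(prots) <= max_annotated_fraction * n_nodes
    }
    if not eligible:
        return []
    terms = sorted(eligible)

    obs_a = _term_edge_counts(a, eligible)
    obs_b = _term_edge_counts(b, eligible)
    deltas = {t: obs_a[t] - obs_b[t] for t in terms}

    seeds = _null_seeds(seed, 2 * n_null)
    null = np.zeros((n_null, len(terms)))
    for i in range(n_null):
        ra = rewire(a, n_swap_factor=n_swap_factor, seed=int(seeds[2 * i]))
        rb = rewire(b, n_swap_factor=n_swap_factor, seed=int(seeds[2 * i + 1]))
        ca = _term_edge_counts(ra, eligible)
        cb = _term_edge_counts(rb, eligible)
        null[i] = [ca[t] - cb[t] for t in terms]

    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    zs, ps = [], []
    for k, t in enumerate(terms):
        d = deltas[t]
        if sd[k] > 0:
            z = (d - mean[k]) / sd[k]
        else:
            z = 0.0 if d == mean[k] else math.copysign(float("inf"), d - mean[k])
        p = float(2 * norm.sf(abs(z))) if math.isfinite(z) else 0.0
        zs.append(z)
        ps.append(p)
    qs = multipletests(ps, method="fdr_bh")[1]
    lodds = content_log_odds(a, b, ann)

    records = []
    for k, t in enumerate(terms):
        d = deltas[t]
        direction = "enriched_in_a" if d > 0 else ("enriched_in_b" if d < 0 else "none")
        records.append(
            TermEnrichmentRecord(
                term=t,
                n_edges_a=obs_a[t],
                n_edges_b=obs_b[t],
                delta=d,
                z=float(zs[k]),
                p=float(ps[k]),
                q=float(qs[k]),
                direction=direction,
                content_log_odds_z=lodds[t].z if t in lodds else float("nan"),
                significant=bool(qs[k] < fdr),
            )
        )
    records.sort(key=lambda r: (r.q, r.p, r.term))
    return records


@dataclass(frozen=True)
class EnrichmentMapEdge:
    """Overlap edge between two significant terms in an enrichment map."""

    term_a: str
    term_b: str
    jaccard: float


def enrichment_map(
    records: list[TermEnrichmentRecord],
    ann: AnnotationSet,
    jaccard_cutoff: float = 0.33,
    nodes: frozenset[str] | None = None,
) -> list[EnrichmentMapEdge]:
    """Edges between significant terms whose annotated protein sets overlap.

    Jaccard similarity is computed over annotated proteins, restricted to
    ``nodes`` (typically the aggregate network's proteins) when given.  Term
    pairs at or above the cutoff are emitted.
    """
    if not records:
        raise ValueError("no enrichment records supplied")
    sig = [r.term for r in records if r.significant]
    prot_sets: dict[str, set[str]] = {}
    for t in sig:
        s = {p for p, terms in ann.annotations.items() if t in terms}
        if nodes is not None:
            s &= set(nodes)
        prot_sets[t] = s
    edges = []
    for ta, tb in itertools.combinations(sorted(sig), 2):
        pa, pb = prot_sets[ta], prot_sets[tb]
        union = pa | pb
        if not union:
            continue
        j = len(pa & pb) / len(union)
        if j >= jaccard_cutoff:
            edges.append(EnrichmentMapEdge(term_a=ta, term_b=tb, jaccard=j))
    return edges
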