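"""Synthetic two-condition co-fractionation data with planted ground truth.

Emulates a differential SEC co-fractionation experiment: proteins are grouped
into planted complexes whose members share a Gaussian elution peak (large
assemblies elute in early fractions), each protein additionally carries a
monomer peak at a later fraction, and a configurable fraction of complexes is
"rearranged" between the two conditions — either dissolving entirely or
shifting its shared peak by several fractions, mimicking complex disruption
upon pathway inhibition.  Multiplicative log-normal noise and intensity-
dependent dropout mimic label-free MS quantitation.

Every generator is a pure function of its configuration and seed, and returns
the planted truth (complex membership, co-complex pairs, annotation terms and
IP fold changes) so downstream inference can be scored against a known answer.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatograms import CoFractionationDataset, ElutionProfile
from .errors import ConfigError
from .inference import Pair, ReferenceComplexSet
from .ipdiff import GROUPS, AbundanceTable
from .rewiring import AnnotationSet

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_cofractionation",
    "generate_annotations",
    "generate_ip_table",
    "generate_reference",
]

CONDITIONS = ("inhibited", "uninhibited")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design for the synthetic co-fractionation experiment.

    Defaults describe a desk-scale version of a two-condition SEC experiment:
    40 fractions, 200 proteins of which ~90 sit in 20 complexes of 3-6
    subunits, 20% multiplicative noise, 10% missing measurements, and a
    reference catalogue covering 80% of the planted complexes plus decoys.
    """

    n_proteins: int = 200
    n_fractions: int = 40
    n_complexes: int = 20
    complex_size_range: tuple[int, int] = (3, 6)
    rearranged_fraction: float = 0.5
    peak_sigma_range: tuple[float, float] = (0.8, 1.8)
    noise_cv: float = 0.2
    dropout_rate: float = 0.1
    reference_coverage: float = 0.8
    n_decoy_complexes: int = 30
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_proteins", "n_fractions", "n_complexes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        lo, hi = self.complex_size_range
        if lo < 2 or hi < lo:
            raise ConfigError(
                "complex_size_range must satisfy 2 <= min <= max"
            )
        for name in ("rearranged_fraction", "dropout_rate", "reference_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        slo, shi = self.peak_sigma_range
        if not (slo > 0 and shi >= slo):
            raise ConfigError("peak_sigma_range must satisfy 0 < min <= max")
        if self.noise_cv < 0:
            raise ConfigError(f"noise_cv must be non-negative, got {self.noise_cv}")
        if self.n_decoy_complexes < 0:
            raise ConfigError("n_decoy_complexes must be non-negative")
        if self.n_complexes * hi > self.n_proteins:
            raise ConfigError(
                "n_proteins too small: n_complexes complexes of up to "
                f"{hi} members need at most {self.n_complexes * hi} proteins"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic experiment."""

    proteins: list[str]
    planted_complexes: dict[str, dict[str, frozenset[str]]]  # condition -> cid -> members
    true_cocomplex_pairs: dict[str, frozenset[Pair]]  # condition -> pairs
    rearranged_complexes: dict[str, str]  # cid -> "dissolved" | "shifted"
    complex_centers: dict[str, dict[str, float]]  # condition -> cid -> peak center
    annotation_truth: dict[str, set[str]] = field(default_factory=dict)
    ip_truth: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0


def _pairs_of(members) -> set[Pair]:
    return set(itertools.combinations(sorted(members), 2))


def generate_cofractionation(
    config: SyntheticConfig,
) -> tuple[CoFractionationDataset, CoFractionationDataset, SyntheticTruth]:
    """Generate (inhibited, uninhibited) datasets plus the planted truth.

    Complex members in a condition share a common Gaussian peak center
    (per-protein jitter < 1 fraction); every protein also has a protein-
    specific monomer peak at a later fraction than its complex peak (smaller
    apparent mass elutes later).  Rearranged complexes either dissolve in the
    inhibited condition (members become monomer-only) or shift their shared
    center by at least 5 fractions, chosen 50/50.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, nf = config.n_proteins, config.n_fractions
    proteins = [f"P{i:04d}" for i in range(1, n + 1)]

    # --- complex membership (disjoint, sampled from a shuffled pool) ---
    lo, hi = config.complex_size_range
    sizes = rng.integers(lo, hi + 1, config.n_complexes)
    pool = rng.permutation(n)
    members: dict[str, frozenset[str]] = {}
    cursor = 0
    for k, size in enumerate(sizes):
        cid = f"CPX{k + 1:03d}"
        members[cid] = frozenset(proteins[i] for i in pool[cursor : cursor + size])
        cursor += int(size)
    cids = sorted(members)
    in_complex = {p: cid for cid, ms in members.items() for p in ms}

    # --- peak geometry ---
    # Complexes are placed across the column's separating range the way an
    # SEC-resolvable complex set elutes: spread out rather than piled up, with
    # per-complex jitter; assignment of positions to complexes is random.
    # Complex members carry most of their mass in the shared complex peak, as
    # protein correlation profiling assumes: their monomer peak is small
    # (~30% of the complex amplitude) and sits at a later fraction (smaller
    # apparent mass).  Proteins outside the planted complexes belong to
    # unmodelled assemblies of their own: they carry two peaks of comparable
    # amplitude at independent positions, so a chance coincidence in a single
    # peak cannot mimic the profile agreement of a co-complex pair.
    complex_hi = 0.6 * nf
    grid = np.linspace(4.0, complex_hi, len(cids))
    grid = grid + rng.uniform(-0.4, 0.4, len(cids))
    order = rng.permutation(len(cids))
    centers = {cid: float(grid[order[k]]) for k, cid in enumerate(cids)}
    complex_sigma = {cid: float(s) for cid, s in zip(cids, rng.uniform(*config.peak_sigma_range, len(cids)))}
    jitter = {p: float(j) for p, j in zip(proteins, rng.uniform(-0.25, 0.25, n))}
    monomer_sigma = {p: float(s) for p, s in zip(proteins, rng.uniform(*config.peak_sigma_range, n))}
    complex_amp = {p: float(a) for p, a in zip(proteins, rng.lognormal(math.log(10.0), 0.4, n))}
    monomer_center, monomer_amp = {}, {}
    minor_center, minor_amp, minor_sigma = {}, {}, {}
    dissolved_split = {}
    mono_lo = 0.5 * nf
    peak_lo, peak_hi = 5.0, 0.95 * nf

    def _separated_center(other: float) -> float:
        # a protein's two assemblies differ in size: keep its peaks apart
        for _ in range(100):
            c = float(rng.uniform(peak_lo, peak_hi))
            if abs(c - other) >= 6.0:
                return c
        return peak_lo if other > 0.5 * (peak_lo + peak_hi) else peak_hi

    for p in proteins:
        cid = in_complex.get(p)
        minor_sigma[p] = float(rng.uniform(*config.peak_sigma_range))
        if cid is None:
            monomer_center[p] = float(rng.uniform(peak_lo, peak_hi))
            monomer_amp[p] = float(rng.lognormal(math.log(10.0), 0.4))
            minor_center[p] = _separated_center(monomer_center[p])
            minor_amp[p] = monomer_amp[p] * float(rng.lognormal(math.log(0.7), 0.3))
        else:
            lo_p = max(centers[cid] + 5.0, mono_lo)
            monomer_center[p] = float(rng.uniform(lo_p, peak_hi))
            monomer_amp[p] = complex_amp[p] * float(rng.lognormal(math.log(0.3), 0.3))
            minor_center[p] = _separated_center(monomer_center[p])
            minor_amp[p] = complex_amp[p] * float(rng.lognormal(math.log(0.7), 0.3))
            dissolved_split[p] = float(rng.uniform(0.4, 0.7))

    # --- rearrangement between conditions ---
    n_re = int(round(config.rearranged_fraction * config.n_complexes))
    re_idx = rng.choice(len(cids), size=n_re, replace=False) if n_re else np.array([], int)
    modes = rng.integers(0, 2, n_re)
    rearranged: dict[str, str] = {}
    centers_inh = dict(centers)
    for idx, mode in zip(re_idx, modes):
        cid = cids[int(idx)]
        if mode == 0:
            rearranged[cid] = "dissolved"
            del centers_inh[cid]
        else:
            rearranged[cid] = "shifted"
            delta = 5.0 + float(rng.uniform(0.0, 3.0))
            c = centers[cid]
            centers_inh[cid] = float(c - delta if c - delta >= 2.0 else c + delta)

    condition_centers = {"inhibited": centers_inh, "uninhibited": dict(centers)}

    # --- signal matrices ---
    x = np.arange(1, nf + 1, dtype=float)

    def gauss(amp: float, c: float, s: float) -> np.ndarray:
        return amp * np.exp(-0.5 * ((x - c) / s) ** 2)

    signal = {}
    for cond in CONDITIONS:
        mat = np.zeros((n, nf))
        ccent = condition_centers[cond]
        for i, p in enumerate(proteins):
            cid = in_complex.get(p)
            if cid is not None and cid in ccent:
                mat[i] = gauss(complex_amp[p], ccent[cid] + jitter[p], complex_sigma[cid])
                mat[i] += gauss(monomer_amp[p], monomer_center[p], monomer_sigma[p])
            elif cid is not None:
                # dissolved complex: the member's mass redistributes into two
                # comparable peaks (monomer plus an unmodelled sub-assembly)
                total = complex_amp[p] + monomer_amp[p]
                u = dissolved_split[p]
                mat[i] = gauss(total * u, monomer_center[p], monomer_sigma[p])
                mat[i] += gauss(total * (1 - u), minor_center[p], minor_sigma[p])
            else:
                mat[i] = gauss(monomer_amp[p], monomer_center[p], monomer_sigma[p])
                mat[i] += gauss(minor_amp[p], minor_center[p], minor_sigma[p])
        signal[cond] = mat

    # --- multiplicative noise and intensity-dependent dropout ---
    datasets = {}
    for cond in CONDITIONS:
        mat = signal[cond].copy()
        if config.noise_cv > 0:
            sln = math.sqrt(math.log(1.0 + config.noise_cv**2))
            mat *= rng.lognormal(-0.5 * sln**2, sln, mat.shape)
        if config.dropout_rate > 0:
            q25 = float(np.quantile(mat, 0.25))
            r = config.dropout_rate
            r_low = min(1.5 * r, 1.0)
            r_high = (r - 0.25 * r_low) / 0.75
            rate = np.where(mat < q25, r_low, r_high)
            mat[rng.random(mat.shape) < rate] = np.nan
        profiles = {
            p: ElutionProfile(protein_id=p, condition=cond, values=mat[i])
            for i, p in enumerate(proteins)
        }
        datasets[cond] = CoFractionationDataset(
            condition=cond, profiles=profiles, n_fractions=nf
        )

    # --- planted IP fold changes (used by generate_ip_table) ---
    n_ip = max(10, n // 10)
    ip_idx = rng.choice(n, size=min(n_ip, n), replace=False)
    fc_u = rng.uniform(1.0, 4.0, len(ip_idx))
    altered = rng.random(len(ip_idx)) < 0.5
    fc_shift = rng.uniform(-2.0, 1.0, len(ip_idx))
    ip_truth: dict[str, dict[str, float]] = {}
    for j, i in enumerate(ip_idx):
        p = proteins[int(i)]
        fu = float(fc_u[j])
        fi = fu + float(fc_shift[j]) if altered[j] else fu
        ip_truth[p] = {
            "bait_vs_ctrl_inhibited": fi,
            "bait_vs_ctrl_uninhibited": fu,
        }

    planted = {
        "uninhibited": dict(members),
        "inhibited": {
            cid: ms
            for cid, ms in members.items()
            if rearranged.get(cid) != "dissolved"
        },
    }
    pairs = {
        cond: frozenset(
            pair for ms in planted[cond].values() for pair in _pairs_of(ms)
        )
        for cond in CONDITIONS
    }
    truth = SyntheticTruth(
        proteins=proteins,
        planted_complexes=planted,
        true_cocomplex_pairs=pairs,
        rearranged_complexes=rearranged,
        complex_centers=condition_centers,
        ip_truth=ip_truth,
        seed=config.seed,
    )
    return datasets["inhibited"], datasets["uninhibited"], truth


def generate_annotations(
    truth: SyntheticTruth,
    terms_per_complex: int = 2,
    background_terms: int = 20,
    seed: int = 0,
    aspect: str = "biological_process",
    background_prob: float = 0.05,
) -> AnnotationSet:
    """Annotation terms correlated with planted complex membership.

    Each planted complex contributes ``terms_per_complex`` terms carried by all
    its members (so co-complex pairs always share a term); ``background_terms``
    additional terms are assigned to random proteins independently of the
    complex structure.  Updates ``truth.annotation_truth`` in place.
    """
    if not truth.proteins:
        raise ConfigError("truth is empty: no proteins to annotate")
    rng = np.random.default_rng(seed)
    annotations: dict[str, set[str]] = {}
    all_complexes = truth.planted_complexes["uninhibited"]
    for cid in sorted(all_complexes):
        for j in range(terms_per_complex):
            term = f"T:{cid}:{j + 1}"
            for p in all_complexes[cid]:
                annotations.setdefault(p, set()).add(term)
    for k in range(background_terms):
        term = f"T:BG:{k + 1:03d}"
        hits = rng.random(len(truth.proteins)) < background_prob
        for p, h in zip(truth.proteins, hits):
            if h:
                annotations.setdefault(p, set()).add(term)
    truth.annotation_truth = {p: set(t) for p, t in annotations.items()}
    return AnnotationSet(aspect=aspect, annotations=annotations)


def generate_ip_table(
    truth: SyntheticTruth,
    n_replicates: int = 6,
    noise_sd_log2: float = 0.25,
    seed: int = 0,
) -> AbundanceTable:
    """Log-normal IP replicate intensities with planted bait-binding fold changes.

    Four groups (bait/control × inhibited/uninhibited); control group means are
    each protein's base abundance, bait means are shifted by the planted log2
    fold change for that condition, and replicates add N(0, noise_sd_log2)
    noise on the log2 scale — so group-mean log2 differences recover the
    planted fold changes in expectation.
    """
    if n_replicates < 2:
        raise ConfigError(
            f"n_replicates must be >= 2 for a t-test, got {n_replicates}"
        )
    rng = np.random.default_rng(seed)
    proteins = truth.proteins
    base = rng.normal(20.0, 2.0, len(proteins))
    rows = []
    for i, p in enumerate(proteins):
        fc = truth.ip_truth.get(p, {})
        means = {
            "ctrl_inhibited": base[i],
            "ctrl_uninhibited": base[i],
            "bait_inhibited": base[i] + fc.get("bait_vs_ctrl_inhibited", 0.0),
            "bait_uninhibited": base[i] + fc.get("bait_vs_ctrl_uninhibited", 0.0),
        }
        for group in GROUPS:
            noise = rng.normal(0.0, noise_sd_log2, n_replicates) if noise_sd_log2 > 0 else np.zeros(n_replicates)
            for r in range(n_replicates):
                rows.append(
                    {
                        "protein_id": p,
                        "group": group,
                        "replicate": r + 1,
                        "intensity": float(2.0 ** (means[group] + noise[r])),
                    }
                )
    return AbundanceTable(data=pd.DataFrame(rows))


def generate_reference(
    truth: SyntheticTruth,
    coverage: float = 0.8,
    n_decoys: int = 30,
    seed: int = 0,
) -> ReferenceComplexSet:
    """Reference complex catalogue partially overlapping the planted truth.

    A ``coverage`` fraction of the planted complexes (original membership) is
    included under new identifiers, plus ``n_decoys`` decoy complexes whose
    members are drawn at random from the whole proteome — catalogued complexes
    that do not co-elute in this system, as real catalogues contain.  This
    keeps calibration labels distinct from the planted truth (no circular
    evaluation) and extends the catalogue's protein universe beyond the
    detectably co-eluting complexes, so the false-positive labels sample the
    chance co-elution population the classifier must rank down.
    """
    rng = np.random.default_rng(seed)
    all_complexes = truth.planted_complexes["uninhibited"]
    cids = sorted(all_complexes)
    n_keep = int(round(coverage * len(cids)))
    keep = sorted(rng.choice(len(cids), size=n_keep, replace=False).tolist())
    complexes: dict[str, frozenset[str]] = {
        f"REF{k + 1:03d}": all_complexes[cids[i]] for k, i in enumerate(keep)
    }
    pool = truth.proteins
    sizes = [len(all_complexes[c]) for c in cids]
    for d in range(n_decoys):
        size = int(rng.choice(sizes))
        picked = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
        complexes[f"DECOY{d + 1:03d}"] = frozenset(pool[i] for i in picked)
    return ReferenceComplexSet.from_complexes(complexes)
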