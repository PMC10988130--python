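"""Readers and writers for the pipeline's tabular formats.

All formats are UTF-8 TSV with '.' decimals; missing values are empty cells or
``NA``.  Every file written by the package begins with commented header lines
(``# key=value``) recording the tool version, a hash of the configuration and
the seed, so outputs are self-describing; readers skip ``#`` lines.

Formats
-------
matrix
    ``protein_id`` then fraction columns in elution order (1-based).
complexes
    Two columns: complex id, semicolon-separated member ids.
annotations
    GAF-lite: ``protein_id  aspect  term_id`` (one term per row).
interactions
    ``protein_a  protein_b  score  running_precision  label  condition``.
ip table
    Long format: ``protein_id  group  replicate  intensity``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chromatograms import CoFractionationDataset, ElutionProfile
from .errors import ConfigError, ParseError
from .inference import (
    InteractionNetwork,
    ReferenceComplexSet,
    ScoredInteraction,
    canonical_pair,
)
from .ipdiff import AbundanceTable, DifferentialAbundanceRecord
from .network import DifferentialNetworkSummary
from .rewiring import (
    ASPECTS,
    AnnotationSet,
    EnrichmentMapEdge,
    RewiringNullResult,
    TermEnrichmentRecord,
)

__all__ = [
    "PipelineConfig",
    "load_config",
    "config_hash",
    "read_matrix",
    "write_matrix",
    "read_complexes",
    "write_complexes",
    "read_annotations",
    "write_annotations",
    "read_domain_pairs",
    "read_interactions",
    "write_interactions",
    "read_network",
    "write_ip_table",
    "read_ip_table",
    "write_summary",
    "write_null_results",
    "write_enrichment",
    "write_enrichment_map",
    "write_records",
    "write_truth",
]

NA_VALUES = ("", "NA")


def _fmt(v: float) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "NA"
    return format(v, ".6g")


def config_hash(obj) -> str:
    """Short stable hash of any YAML-serializable configuration object."""
    dump = yaml.safe_dump(obj, sort_keys=True)
    return hashlib.sha1(dump.encode()).hexdigest()[:12]


def _header(seed: int | None = None, cfg_hash: str | None = None, **extra) -> str:
    fields = {"tool": f"cofracnet {__version__}"}
    if cfg_hash is not None:
        fields["config_hash"] = cfg_hash
    if seed is not None:
        fields["seed"] = seed
    fields.update(extra)
    return "".join(f"# {k}={v}\n" for k, v in fields.items())


# --------------------------------------------------------------------------
# protein x fraction matrices


def write_matrix(
    dataset: CoFractionationDataset,
    path,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(seed, cfg_hash, condition=dataset.condition,
                         fraction_axis="1-based, ordered by elution time"))
        cols = "\t".join(f"fraction_{i}" for i in range(1, dataset.n_fractions + 1))
        fh.write(f"protein_id\t{cols}\n")
        for pid in dataset.protein_ids:
            vals = "\t".join(_fmt(v) for v in dataset.profiles[pid].values)
            fh.write(f"{pid}\t{vals}\n")


def read_matrix(path, condition: str | None = None) -> CoFractionationDataset:
    """Parse a protein-by-fraction TSV into a dataset.

    Raises :class:`ParseError` (with the line number) on a malformed header,
    duplicate protein ids, or negative abundances.
    """
    path = Path(path)
    profiles: dict[str, ElutionProfile] = {}
    n_fractions = None
    header_condition = ""
    with path.open() as fh:
        lineno = 0
        header_seen = False
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n")
            if line.startswith("#"):
                if "condition=" in line:
                    header_condition = line.split("condition=", 1)[1].strip()
                continue
            if not line.strip():
                continue
            cells = line.split("\t")
            if not header_seen:
                if cells[0] != "protein_id" or len(cells) < 2:
                    raise ParseError(
                        f"{path}:{lineno}: header must start with 'protein_id' "
                        "followed by fraction columns"
                    )
                n_fractions = len(cells) - 1
                header_seen = True
                continue
            pid = cells[0]
            if pid in profiles:
                raise ParseError(f"{path}:{lineno}: duplicate protein_id {pid!r}")
            if len(cells) - 1 != n_fractions:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_fractions} fraction values, "
                    f"got {len(cells) - 1}"
                )
            values = []
            for j, cell in enumerate(cells[1:], start=1):
                if cell in NA_VALUES:
                    values.append(np.nan)
                    continue
                try:
                    v = float(cell)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric value {cell!r} "
                        f"in fraction column {j}"
                    ) from exc
                if v < 0:
                    raise ParseError(
                        f"{path}:{lineno}: negative abundance {v} for {pid!r}"
                    )
                values.append(v)
            cond = condition if condition is not None else header_condition
            profiles[pid] = ElutionProfile(
                protein_id=pid, condition=cond, values=np.array(values)
            )
    if n_fractions is None:
        raise ParseError(f"{path}: empty matrix file")
    return CoFractionationDataset(
        condition=condition if condition is not None else header_condition,
        profiles=profiles,
        n_fractions=n_fractions,
    )


# --------------------------------------------------------------------------
# reference complexes


def write_complexes(
    reference: ReferenceComplexSet, path, seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(seed, cfg_hash))
        fh.write("complex_id\tmembers\n")
        for cid in sorted(reference.complexes):
            fh.write(f"{cid}\t{';'.join(sorted(reference.complexes[cid]))}\n")


def read_complexes(path) -> ReferenceComplexSet:
    """Parse a two-column complex catalogue (id, ';'-separated members).

    Complexes of size >= 2 are retained; singletons are dropped with a warning
    since they induce no pair labels.
    """
    import logging

    path = Path(path)
    complexes: dict[str, set[str]] = {}
    with path.open() as fh:
        lineno = 0
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n")
            if line.startswith("#") or not line.strip():
                continue
            cells = line.split("\t")
            if cells[0] == "complex_id":
                continue
            if len(cells) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            members = {m for m in cells[1].split(";") if m}
            if len(members) < 2:
                logging.getLogger(__name__).warning(
                    "%s:%d: singleton complex %r dropped", path, lineno, cells[0]
                )
                continue
            complexes[cells[0]] = members
    if not complexes:
        raise ParseError(f"{path}: no complexes of size >= 2 found")
    return ReferenceComplexSet.from_complexes(complexes)


# --------------------------------------------------------------------------
# annotations (GAF-lite) and domain pairs


def write_annotations(
    sets: dict[str, AnnotationSet] | AnnotationSet, path,
    seed: int | None = None, cfg_hash: str | None = None,
) -> None:
    if isinstance(sets, AnnotationSet):
        sets = {sets.aspect: sets}
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(seed, cfg_hash))
        fh.write("protein_id\taspect\tterm_id\n")
        for aspect in sorted(sets):
            ann = sets[aspect]
            for p in sorted(ann.annotations):
                for t in sorted(ann.annotations[p]):
                    fh.write(f"{p}\t{aspect}\t{t}\n")


def read_annotations(path) -> dict[str, AnnotationSet]:
    """Parse a GAF-lite TSV into one AnnotationSet per aspect."""
    path = Path(path)
    by_aspect: dict[str, dict[str, set[str]]] = {}
    with path.open() as fh:
        lineno = 0
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n")
            if line.startswith("#") or not line.strip():
                continue
            cells = line.split("\t")
            if cells[0] == "protein_id":
                continue
            if len(cells) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected three columns (protein, aspect, term)"
                )
            protein, aspect, term = cells
            if aspect not in ASPECTS:
                raise ParseError(f"{path}:{lineno}: unknown aspect {aspect!r}")
            by_aspect.setdefault(aspect, {}).setdefault(protein, set()).add(term)
    return {
        aspect: AnnotationSet(aspect=aspect, annotations=annots)
        for aspect, annots in by_aspect.items()
    }


def read_domain_pairs(path) -> set[frozenset[str]]:
    """Two-column TSV of domain identifiers known to physically interact."""
    path = Path(path)
    pairs: set[frozenset[str]] = set()
    with path.open() as fh:
        lineno = 0
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n")
            if line.startswith("#") or not line.strip():
                continue
            cells = line.split("\t")
            if cells[0] in ("domain_a", "domain_1"):
                continue
            if len(cells) != 2:
                raise ParseError(f"{path}:{lineno}: expected two domain columns")
            pairs.add(frozenset(cells))
    return pairs


# --------------------------------------------------------------------------
# interactions / networks


def write_interactions(
    ranked: list[ScoredInteraction], condition: str, path,
    seed: int | None = None, cfg_hash: str | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(seed, cfg_hash, condition=condition))
        fh.write(
            "protein_a\tprotein_b\tscore\trunning_precision\tlabel\tcondition\n"
        )
        for si in ranked:
            a, b = si.pair
            fh.write(
                f"{a}\t{b}\t{_fmt(si.score)}\t{_fmt(si.running_precision)}\t"
                f"{si.label}\t{condition}\n"
            )


def read_interactions(path) -> list[ScoredInteraction]:
    path = Path(path)
    out = []
    with path.open() as fh:
        lineno = 0
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n")
            if line.startswith("#") or not line.strip():
                continue
            cells = line.split("\t")
            if cells[0] == "protein_a":
                continue
            if len(cells) != 6:
                raise ParseError(f"{path}:{lineno}: expected six columns")
            a, b, score, rp, label, _cond = cells
            out.append(
                ScoredInteraction(
                    pair=canonical_pair(a, b),
                    score=float(score),
                    label=label,
                    running_precision=None if rp == "NA" else float(rp),
                )
            )
    return out


def read_network(path, condition: str = "") -> InteractionNetwork:
    ranked = read_interactions(path)
    return InteractionNetwork.from_edges([si.pair for si in ranked], condition)


# --------------------------------------------------------------------------
# IP tables and differential records


def write_ip_table(
    table: AbundanceTable, path, seed: int | None = None, cfg_hash: str | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(seed, cfg_hash))
        fh.write("protein_id\tgroup\treplicate\tintensity\n")
        df = table.data.sort_values(["protein_id", "group", "replicate"])
        for _, row in df.iterrows():
            fh.write(
                f"{row['protein_id']}\t{row['group']}\t{row['replicate']}\t"
                f"{_fmt(row['intensity'])}\n"
            )


def read_ip_table(path) -> AbundanceTable:
    df = pd.read_csv(
        path, sep="\t", comment="#", na_values=list(NA_VALUES), keep_default_na=False
    )
    if (df["intensity"].dropna() < 0).any():
        raise ParseError(f"{path}: negative intensities are not allowed")
    return AbundanceTable(data=df)


def write_records(
    records: list[DifferentialAbundanceRecord], path,
    seed: int | None = None, cfg_hash: str | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(seed, cfg_hash))
        fh.write("protein\tcomparison\tlog2fc\tp\tq\n")
        for r in records:
            fh.write(
                f"{r.protein}\t{r.comparison}\t{_fmt(r.log2fc)}\t{_fmt(r.p)}\t{_fmt(r.q)}\n"
            )


# --------------------------------------------------------------------------
# summaries and enrichment outputs


def write_summary(
    summary: DifferentialNetworkSummary, path,
    seed: int | None = None, cfg_hash: str | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(seed, cfg_hash))
        fh.write("metric\tvalue\n")
        for k, v in asdict(summary).items():
            val = f"{v:.1f}" if k == "pct_unique" else v
            fh.write(f"{k}\t{val}\n")


def write_null_results(
    results: list[RewiringNullResult], path,
    seed: int | None = None, cfg_hash: str | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(seed, cfg_hash))
        fh.write("statistic\tobserved\tnull_mean\tnull_sd\tempirical_p\tz\tn_null\n")
        for r in results:
            null = np.array(r.null_samples)
            fh.write(
                f"{r.statistic_name}\t{_fmt(r.observed)}\t{_fmt(null.mean())}\t"
                f"{_fmt(null.std(ddof=1) if null.size > 1 else 0.0)}\t"
                f"{_fmt(r.empirical_p)}\t{_fmt(r.z)}\t{null.size}\n"
            )


def write_enrichment(
    records: list[TermEnrichmentRecord], path,
    seed: int | None = None, cfg_hash: str | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(seed, cfg_hash))
        fh.write(
            "term\tn_edges_a\tn_edges_b\tdelta\tz\tp\tq\tdirection\t"
            "content_log_odds_z\tsignificant\n"
        )
        for r in records:
            fh.write(
                f"{r.term}\t{r.n_edges_a}\t{r.n_edges_b}\t{r.delta}\t{_fmt(r.z)}\t"
                f"{_fmt(r.p)}\t{_fmt(r.q)}\t{r.direction}\t"
                f"{_fmt(r.content_log_odds_z)}\t{int(r.significant)}\n"
            )


def write_enrichment_map(
    edges: list[EnrichmentMapEdge], path,
    seed: int | None = None, cfg_hash: str | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(seed, cfg_hash))
        fh.write("term_a\tterm_b\tjaccard\n")
        for e in edges:
            fh.write(f"{e.term_a}\t{e.term_b}\t{_fmt(e.jaccard)}\n")


def write_truth(truth, path, seed: int | None = None, cfg_hash: str | None = None) -> None:
    """Serialize a SyntheticTruth to JSON (sets become sorted lists)."""
    path = Path(path)
    payload = {
        "proteins": truth.proteins,
        "planted_complexes": {
            cond: {cid: sorted(ms) for cid, ms in by_cid.items()}
            for cond, by_cid in truth.planted_complexes.items()
        },
        "true_cocomplex_pairs": {
            cond: sorted(list(p) for p in pairs)
            for cond, pairs in truth.true_cocomplex_pairs.items()
        },
        "rearranged_complexes": truth.rearranged_complexes,
        "complex_centers": truth.complex_centers,
        "annotation_truth": {p: sorted(t) for p, t in truth.annotation_truth.items()},
        "ip_truth": truth.ip_truth,
        "seed": truth.seed,
    }
    with path.open("w") as fh:
        fh.write(_header(seed, cfg_hash))
        json.dump(payload, fh, indent=1)
        fh.write("\n")


# --------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Stage parameters and paths for a full pipeline run.

    All thresholds are validated against their documented ranges; the seed is
    mandatory because scoring, rewiring and simulation are stochastic.
    """

    seed: int = 0
    output_dir: str = "cofracnet_out"
    verbosity: int = 1
    # input paths (optional; the simulate stage fills them in)
    matrix_inhibited: str | None = None
    matrix_uninhibited: str | None = None
    complexes: str | None = None
    annotations: str | None = None
    ip_table: str | None = None
    # stage parameters
    min_consecutive: int = 5
    max_components: int = 5
    min_cooccurring: int = 5
    n_folds: int = 10
    precision_threshold: float = 0.5
    n_null: int = 100
    fdr: float = 0.10
    lfc_min: float = 0.58
    q_max: float = 0.05
    jaccard_cutoff: float = 0.33
    min_quantified: int = 3
    # simulation parameters (used by simulate / run-all)
    simulate: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.precision_threshold <= 1:
            raise ConfigError(
                f"precision_threshold must be in (0, 1], got {self.precision_threshold}"
            )
        for name in ("fdr", "q_max"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if not 0 <= self.jaccard_cutoff <= 1:
            raise ConfigError(
                f"jaccard_cutoff must be in [0, 1], got {self.jaccard_cutoff}"
            )
        if self.lfc_min < 0:
            raise ConfigError(f"lfc_min must be non-negative, got {self.lfc_min}")
        for name in ("min_consecutive", "max_components", "min_cooccurring",
                     "n_folds", "n_null", "min_quantified"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")

    def hash(self) -> str:
        return config_hash(asdict(self))


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown configuration keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
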