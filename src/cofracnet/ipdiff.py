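"""Differential abundance analysis for bait immunoprecipitation (IP) data.

A bait protein (e.g. the NF-κB subunit RELA) is immunoprecipitated alongside a
nonspecific IgG control in two conditions, with several biological replicates
per group.  Interactors are the proteins enriched in bait over control
(Log2FC > 0.58, q < 0.05 by default), and between-condition comparison of the
bait pulldowns identifies interactions gained or lost upon treatment.

Fold changes are differences of group means of log2 intensities; p-values come
from a two-sample Student's t-test on the log2 values, and q-values from
Benjamini–Hochberg adjustment across all tested proteins.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError

__all__ = [
    "GROUPS",
    "AbundanceTable",
    "DifferentialAbundanceRecord",
    "differential_test",
    "call_interactors",
    "compare_conditions",
    "load_rela_ip_example",
]

log = logging.getLogger(__name__)

#: The four IP groups: bait and IgG control in each condition.
GROUPS = ("bait_inhibited", "ctrl_inhibited", "bait_uninhibited", "ctrl_uninhibited")


@dataclass
class AbundanceTable:
    """Long-format protein × replicate intensities for the four IP groups.

    ``data`` columns: ``protein_id``, ``group``, ``replicate``, ``intensity``.
    Intensities are non-negative; missing measurements are absent rows or NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"protein_id", "group", "replicate", "intensity"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"abundance table missing columns: {sorted(missing)}")
        bad = set(self.data["group"].unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def proteins(self) -> list[str]:
        return sorted(self.data["protein_id"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    def group_values(self, protein: str, group: str) -> np.ndarray:
        sel = self.data[
            (self.data["protein_id"] == protein) & (self.data["group"] == group)
        ]
        vals = sel["intensity"].to_numpy(dtype=float)
        return vals[~np.isnan(vals)]

    def group_matrix(self, group: str) -> pd.DataFrame:
        """Proteins × replicates intensity matrix for one group."""
        sel = self.data[self.data["group"] == group]
        return sel.pivot_table(
            index="protein_id", columns="replicate", values="intensity", aggfunc="first"
        )


@dataclass(frozen=True)
class DifferentialAbundanceRecord:
    """One protein's differential abundance in one comparison."""

    protein: str
    comparison: str
    log2fc: float
    p: float
    q: float


def differential_test(
    table: AbundanceTable,
    group_a: str,
    group_b: str,
    min_quantified: int = 3,
    equal_var: bool = True,
) -> list[DifferentialAbundanceRecord]:
    """Two-sample t-test of log2 intensities, group_a vs group_b, per protein.

    Proteins quantified in fewer than ``min_quantified`` replicates of either
    group are excluded (and logged).  ``log2fc`` is the difference of group
    means of log2 intensities; set ``equal_var=False`` for a Welch test.
    Degenerate zero-variance comparisons yield p = 1 when the means are equal
    and p = 0 otherwise.
    """
    for g in (group_a, group_b):
        if g not in set(table.data["group"].unique()):
            raise ValueError(f"group {g!r} absent from abundance table")
    comparison = f"{group_a}_vs_{group_b}"
    mat_a = table.group_matrix(group_a)
    mat_b = table.group_matrix(group_b)
    tested, log2fcs, pvals, dropped = [], [], [], []
    for protein in sorted(set(mat_a.index) | set(mat_b.index)):
        xa = mat_a.loc[protein].dropna().to_numpy() if protein in mat_a.index else np.array([])
        xb = mat_b.loc[protein].dropna().to_numpy() if protein in mat_b.index else np.array([])
        xa, xb = xa[xa > 0], xb[xb > 0]
        if len(xa) < min_quantified or len(xb) < min_quantified:
            dropped.append(protein)
            continue
        la, lb = np.log2(xa), np.log2(xb)
        fc = float(la.mean() - lb.mean())
        if la.std(ddof=1) == 0 and lb.std(ddof=1) == 0:
            p = 1.0 if fc == 0 else 0.0
        else:
            p = float(stats.ttest_ind(la, lb, equal_var=equal_var).pvalue)
        tested.append(protein)
        log2fcs.append(fc)
        pvals.append(p)
    if dropped:
        log.info(
            "differential_test %s: %d proteins below min_quantified=%d dropped: %s",
            comparison,
            len(dropped),
            min_quantified,
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    if not tested:
        return []
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return [
        DifferentialAbundanceRecord(
            protein=prot, comparison=comparison, log2fc=fc, p=p, q=float(q)
        )
        for prot, fc, p, q in zip(tested, log2fcs, pvals, qvals)
    ]


def call_interactors(
    records: list[DifferentialAbundanceRecord],
    lfc_min: float = 0.58,
    q_max: float = 0.05,
) -> set[str]:
    """Bait interactors: proteins with log2fc > lfc_min and q < q_max (strict)."""
    return {r.protein for r in records if r.log2fc > lfc_min and r.q < q_max}


def compare_conditions(
    records: list[DifferentialAbundanceRecord],
    lfc_min: float = 0.58,
    q_max: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Interactors gained (up) and lost (down) between conditions.

    Applied to the between-condition bait comparison: ``up`` holds proteins
    with log2fc > lfc_min, ``down`` those with log2fc < -lfc_min, both at
    q < q_max (all strict inequalities).
    """
    up = {r.protein for r in records if r.log2fc > lfc_min and r.q < q_max}
    down = {r.protein for r in records if r.log2fc < -lfc_min and r.q < q_max}
    return up, down


_EXAMPLE_COMPARISONS = {
    "inhibited_bait_vs_ctrl": ("log2fc_inh_vs_ctrl", "q_inh_vs_ctrl"),
    "uninhibited_bait_vs_ctrl": ("log2fc_uninh_vs_ctrl", "q_uninh_vs_ctrl"),
    "inhibited_vs_uninhibited_bait": ("log2fc_inh_vs_uninh", "q_inh_vs_uninh"),
}


def load_rela_ip_example() -> dict[str, list[DifferentialAbundanceRecord]]:
    """Packaged RELA co-IP example: differential abundance of RELA interactors.

    A curated table of RELA immunoprecipitation results from MCF-7 breast
    cancer cells with and without NF-κB inhibition: per protein, log2 fold
    change and q-value for bait-vs-IgG in each condition and for the
    between-condition bait comparison.  Returns one record list per comparison,
    keyed ``inhibited_bait_vs_ctrl``, ``uninhibited_bait_vs_ctrl`` and
    ``inhibited_vs_uninhibited_bait``.
    """
    ref = importlib.resources.files("cofracnet.data") / "rela_ip_differential.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, list[DifferentialAbundanceRecord]] = {}
    for comparison, (fc_col, q_col) in _EXAMPLE_COMPARISONS.items():
        out[comparison] = [
            DifferentialAbundanceRecord(
                protein=row["gene"],
                comparison=comparison,
                log2fc=float(row[fc_col]),
                p=float("nan"),  # source table reports adjusted values only
                q=float(row[q_col]),
            )
            for _, row in df.iterrows()
        ]
    return out


def validate_replicates(table: AbundanceTable, n_min: int = 2) -> None:
    """Raise ConfigError unless every present group has >= n_min replicates."""
    counts = table.data.groupby("group")["replicate"].nunique()
    low = counts[counts < n_min]
    if not low.empty:
        raise ConfigError(
            f"n_replicates: groups with fewer than {n_min} replicates: "
            f"{dict(low)} (t-test undefined)"
        )
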