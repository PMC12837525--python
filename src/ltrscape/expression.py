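"""Expression contrasts between SPE- and SYN-resident genes.

Genes are assigned to the species-specific (SPE) or species-syntenic
(SYN) region class holding the majority (> 50%) of their SPE+SYN overlap
bases; genes overlapping neither class are excluded, and exact ties are
flagged ambiguous and excluded as well.  Per developmental stage (and
optionally per pathway gene set) expression is compared between the two
groups with a two-sample t test on log2(x+1) values — Welch's
unequal-variance variant by default, with the pooled-variance Student
form available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import RegionSet
from .errors import ContractError, InputError, ParameterError


@dataclass
class ContrastResult:
    stage: str
    gene_set: str
    n_spe: int
    n_syn: int
    t: float
    p: float
    mean_diff: float  # SPE - SYN on the transformed scale

    @property
    def significance(self) -> str:
        if self.p < 0.001:
            return "***"
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return "ns"


def _overlap_bases(starts, ends, s, e) -> int:
    lo = np.searchsorted(ends, s, side="right")
    hi = np.searchsorted(starts, e, side="left")
    total = 0
    for i in range(lo, hi):
        total += min(e, ends[i]) - max(s, starts[i])
    return int(total)


def assign_region_class(genes: pd.DataFrame, regions: RegionSet) -> pd.DataFrame:
    """Per-gene SPE/SYN assignment by majority overlap.

    Returns columns gene_id, cls in {SPE, SYN, ambiguous, none},
    spe_overlap_bp, syn_overlap_bp.  ``none`` means no overlap with either
    class; ``ambiguous`` an exact bp tie (neither side holds > 50% of the
    combined overlap).
    """
    rows = []
    for g in genes.itertuples():
        bp = {}
        for cls in ("SPE", "SYN"):
            arrays = regions.class_arrays(cls, g.scaffold)
            bp[cls] = (
                _overlap_bases(arrays[0], arrays[1], g.start, g.end)
                if arrays is not None
                else 0
            )
        total = bp["SPE"] + bp["SYN"]
        if total == 0:
            cls = "none"
        elif bp["SPE"] * 2 > total:
            cls = "SPE"
        elif bp["SYN"] * 2 > total:
            cls = "SYN"
        else:
            cls = "ambiguous"
        rows.append(
            dict(gene_id=g.gene_id, cls=cls,
                 spe_overlap_bp=bp["SPE"], syn_overlap_bp=bp["SYN"])
        )
    return pd.DataFrame(rows, columns=["gene_id", "cls", "spe_overlap_bp", "syn_overlap_bp"])


def _transform(values: np.ndarray, transform: str) -> np.ndarray:
    if (values < 0).any():
        raise InputError("expression values must be non-negative")
    if transform == "log2p1":
        return np.log2(values + 1.0)
    if transform == "none":
        return values.astype(float)
    raise ParameterError(f"unknown transform {transform!r}")


def contrast(
    expression: pd.DataFrame,
    assignment: pd.DataFrame,
    stage: str,
    gene_set: Optional[set] = None,
    gene_set_label: str = "all",
    test: str = "welch",
    transform: str = "log2p1",
) -> ContrastResult:
    """Two-group expression test for one stage.

    ``expression`` has a gene_id column plus one column per stage;
    ``assignment`` is the output of :func:`assign_region_class`.  Both
    groups must contain at least 2 genes.
    """
    if test not in ("welch", "student"):
        raise ParameterError(f"unknown test {test!r}; use welch or student")
    if stage not in expression.columns:
        raise InputError(f"stage column {stage!r} not in expression table")
    merged = expression.merge(assignment[["gene_id", "cls"]], on="gene_id")
    if gene_set is not None:
        merged = merged[merged["gene_id"].isin(gene_set)]
    groups = {}
    for cls in ("SPE", "SYN"):
        vals = merged.loc[merged["cls"] == cls, stage].to_numpy()
        if len(vals) < 2:
            raise ContractError(
                f"group {cls} has {len(vals)} genes (< 2) for stage {stage!r}, "
                f"set {gene_set_label!r}"
            )
        groups[cls] = _transform(vals, transform)
    res = stats.ttest_ind(groups["SPE"], groups["SYN"], equal_var=(test == "student"))
    t = float(res.statistic)
    p = float(res.pvalue)
    diff = float(groups["SPE"].mean() - groups["SYN"].mean())
    if np.isnan(t):  # both groups constant: t degenerates
        if diff == 0:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(diff)) * float("inf"), 0.0
    return ContrastResult(
        stage=stage, gene_set=gene_set_label,
        n_spe=len(groups["SPE"]), n_syn=len(groups["SYN"]),
        t=t, p=p, mean_diff=diff,
    )


def contrast_all(
    expression: pd.DataFrame,
    assignment: pd.DataFrame,
    gene_sets: Optional[dict] = None,
    test: str = "welch",
    transform: str = "log2p1",
) -> pd.DataFrame:
    """Contrasts for every stage column and gene set; tidy table output."""
    stages = [c for c in expression.columns if c != "gene_id"]
    sets = {"all": None}
    if gene_sets:
        sets.update(gene_sets)
    rows = []
    for label, members in sets.items():
        for stage in stages:
            r = contrast(
                expression, assignment, stage,
                gene_set=members, gene_set_label=label,
                test=test, transform=transform,
            )
            rows.append(
                dict(stage=r.stage, gene_set=r.gene_set, n_spe=r.n_spe,
                     n_syn=r.n_syn, t=r.t, p=r.p, mean_diff=r.mean_diff,
                     significance=r.significance)
            )
    return pd.DataFrame(rows)
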