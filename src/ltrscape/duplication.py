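"""Tandem/proximal gene-duplication calls and pseudogene filtering.

A homologous gene pair on the same chromosome is a tandem duplication
(TD) when the genes are physically adjacent (0 intervening genes in the
positional ranking) and a proximal duplication (PD) when separated by 1
to 10 genes; anything farther apart, or on different scaffolds, is
neither.  Pseudogene candidates from an upstream detection pipeline are
kept only when amino-acid identity to the parent gene exceeds 30% and the
parent alignment covers more than 50% of the pseudogene — both strict
inequalities.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError


def rank_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Assign per-scaffold positional ranks 1..n.

    Genes are ordered by start, ties broken by end and then gene_id, so a
    shuffled input yields the identical ranking.
    """
    need = {"gene_id", "scaffold", "start", "end"}
    if not need.issubset(genes.columns):
        raise InputError(f"gene table needs columns {sorted(need)}")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise InputError(f"duplicate gene_id {dup!r}")
    out = genes.sort_values(
        ["scaffold", "start", "end", "gene_id"], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = out.groupby("scaffold", sort=False).cumcount() + 1
    return out


def classify_duplications(
    pairs: pd.DataFrame,
    ranked_genes: pd.DataFrame,
    max_proximal: int = 10,
) -> pd.DataFrame:
    """TD/PD/none calls for homologous gene pairs.

    ``intervening = |rank_a - rank_b| - 1`` on a shared scaffold; TD means
    0 intervening, PD means 1..``max_proximal``; cross-scaffold pairs are
    ``none``.  The call is symmetric in pair order.
    """
    if max_proximal < 1:
        raise ParameterError("max_proximal must be >= 1")
    if "rank" not in ranked_genes.columns:
        ranked_genes = rank_genes(ranked_genes)
    info = ranked_genes.set_index("gene_id")[["scaffold", "rank"]]
    rows = []
    for rec in pairs.itertuples():
        for g in (rec.gene_a, rec.gene_b):
            if g not in info.index:
                raise InputError(f"unknown gene id {g!r} in pair list")
        sa, ra = info.loc[rec.gene_a]
        sb, rb = info.loc[rec.gene_b]
        if sa != sb:
            dup_type, intervening = "none", None
        else:
            intervening = abs(int(ra) - int(rb)) - 1
            if intervening == 0:
                dup_type = "TD"
            elif 1 <= intervening <= max_proximal:
                dup_type = "PD"
            else:
                dup_type = "none"
        rows.append(
            dict(gene_a=rec.gene_a, gene_b=rec.gene_b,
                 type=dup_type, intervening=intervening)
        )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "type", "intervening"])


def filter_pseudogenes(
    candidates: pd.DataFrame,
    min_identity: float = 30.0,
    min_coverage: float = 50.0,
) -> pd.DataFrame:
    """Keep candidates with identity > 30% and parent coverage > 50%.

    Both thresholds are strict (greater-than); candidates exactly at a
    threshold are removed.  Percentages must be populated for every row.
    """
    for col in ("identity", "parent_coverage"):
        if col not in candidates.columns:
            raise InputError(f"pseudogene table lacks column {col!r}")
        if candidates[col].isna().any():
            raise InputError(f"pseudogene table has missing {col!r} values")
        vals = candidates[col]
        if ((vals < 0) | (vals > 100)).any():
            raise InputError(f"{col!r} values must be percentages in [0, 100]")
    keep = (candidates["identity"] > min_identity) & (
        candidates["parent_coverage"] > min_coverage
    )
    return candidates[keep].reset_index(drop=True)


def nearest_ltr_context(
    genes: pd.DataFrame,
    ltr_loci: pd.DataFrame,
    window: int,
) -> pd.DataFrame:
    """LTR elements within ``window`` bp of each gene.

    Position classes are gene-orientation aware: for a minus-strand gene
    the upstream side is the right flank.  Distances are 0 for overlap and
    signed relative to gene orientation otherwise (negative upstream,
    positive downstream).
    """
    if window < 0:
        raise ParameterError("window must be >= 0")
    by_scaffold = dict(tuple(ltr_loci.groupby("scaffold", sort=False)))
    rows = []
    for g in genes.itertuples():
        sub = by_scaffold.get(g.scaffold)
        if sub is None:
            continue
        for l in sub.itertuples():
            if l.start < g.end and l.end > g.start:
                cls, dist = "overlapping", 0
            elif l.end <= g.start:
                gap = g.start - l.end
                if gap > window:
                    continue
                cls = "upstream" if g.strand != "-" else "downstream"
                dist = -gap if cls == "upstream" else gap
            else:
                gap = l.start - g.end
                if gap > window:
                    continue
                cls = "downstream" if g.strand != "-" else "upstream"
                dist = -gap if cls == "upstream" else gap
            rows.append(
                dict(
                    gene_id=g.gene_id, element_id=l.element_id,
                    position=cls, distance=dist,
                )
            )
    return pd.DataFrame(rows, columns=["gene_id", "element_id", "position", "distance"])
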