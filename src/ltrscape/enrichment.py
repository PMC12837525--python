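"""Overlap of LTR intervals with structural-variation region classes.

Whole-genome comparison of related species partitions each assembly into
inversion regions (INV), species-specific regions (SPE) and
species-syntenic regions (SYN).  This module counts how many LTR
intervals overlap each class, compares the observed count against a
randomization null (same number of intervals, same length multiset,
placed uniformly with scaffolds weighted by length), and reports the
per-class base-pair coverage by species-specific LTRs.

Empirical p-values use the +1 correction, p = (1 + #{null >= obs}) /
(n_perm + 1) for enrichment (<= for depletion), so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ParameterError

KNOWN_CLASSES = ("INV", "SPE", "SYN")


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/abutting-free intervals per scaffold (half-open)."""
    out = []
    for name, grp in df.groupby("scaffold", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # strict: half-open abutment does not merge
                cur_e = max(cur_e, e)
            else:
                out.append((name, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((name, cur_s, cur_e))
    return pd.DataFrame(out, columns=["scaffold", "start", "end"])


class RegionSet:
    """Labeled genomic intervals (INV/SPE/SYN plus any other classes).

    Within each class, overlapping intervals are merged on load; classes
    are evaluated independently, so cross-class overlaps are preserved.
    """

    def __init__(self, records: pd.DataFrame):
        need = {"scaffold", "start", "end", "cls"}
        if not need.issubset(records.columns):
            raise ParameterError(f"region table needs columns {sorted(need)}")
        pieces = []
        for cls, grp in records.groupby("cls", sort=True):
            merged = merge_intervals(grp)
            merged["cls"] = cls
            pieces.append(merged)
        self.records = (
            pd.concat(pieces, ignore_index=True)
            if pieces
            else pd.DataFrame(columns=["scaffold", "start", "end", "cls"])
        )
        self._arrays = {}
        for (cls, name), grp in self.records.groupby(["cls", "scaffold"], sort=True):
            grp = grp.sort_values("start")
            self._arrays[(cls, name)] = (
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
            )

    @property
    def classes(self) -> list:
        return sorted(self.records["cls"].unique())

    def class_arrays(self, cls: str, scaffold: str):
        return self._arrays.get((cls, scaffold))

    def class_bases(self, cls: str) -> int:
        sub = self.records[self.records["cls"] == cls]
        return int((sub["end"] - sub["start"]).sum())

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["scaffold", "start", "end", "cls"], usecols=[0, 1, 2, 3],
        )
        return cls(df)


@dataclass
class OverlapTest:
    cls: str
    observed: int
    null_samples: np.ndarray
    n_perm: int
    seed: int
    z_score: Optional[float]
    p_enrich: float
    p_deplete: float


def overlap_count(intervals: pd.DataFrame, regions: RegionSet, cls: str) -> int:
    """Number of intervals overlapping >= 1 bp with any region of ``cls``."""
    if cls not in regions.classes:
        raise ParameterError(f"unknown region class {cls!r}; have {regions.classes}")
    total = 0
    for name, grp in intervals.groupby("scaffold", sort=False):
        arrays = regions.class_arrays(cls, name)
        if arrays is None:
            continue
        starts, ends = arrays
        s = grp["start"].to_numpy(np.int64)
        e = grp["end"].to_numpy(np.int64)
        # regions are sorted and disjoint: the only candidate is the one
        # with the largest start < interval end
        idx = np.searchsorted(starts, e, side="left") - 1
        ok = (idx >= 0) & (ends[np.clip(idx, 0, None)] > s)
        total += int(ok.sum())
    return total


def randomize_intervals(
    intervals: pd.DataFrame, scaffold_lengths: dict, seed
) -> pd.DataFrame:
    """Uniform re-placement preserving the interval length multiset.

    Each interval keeps its length and is dropped uniformly on a scaffold
    chosen with probability proportional to scaffold length among the
    scaffolds it fits in; intervals may overlap each other, mirroring
    shuffle-style randomization.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(scaffold_lengths)
    L = np.array([scaffold_lengths[n] for n in names], dtype=np.int64)
    lens = (intervals["end"] - intervals["start"]).to_numpy(np.int64)
    if len(lens) and lens.max() > L.max():
        raise CapacityError(
            f"an interval of length {int(lens.max())} fits no scaffold "
            f"(longest is {int(L.max())})"
        )
    # weight matrix: scaffold length where the interval fits, else 0
    w = np.where(lens[:, None] <= L[None, :], L[None, :].astype(float), 0.0)
    w /= w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1)
    pick = (rng.random(len(lens))[:, None] < cum).argmax(axis=1)
    span = L[pick] - lens + 1
    starts = np.floor(rng.random(len(lens)) * span).astype(np.int64)
    return pd.DataFrame(
        {
            "scaffold": [names[i] for i in pick],
            "start": starts,
            "end": starts + lens,
        }
    )


def permutation_enrichment(
    intervals: pd.DataFrame,
    regions: RegionSet,
    cls: str,
    scaffold_lengths: dict,
    n_perm: int = 1000,
    seed=0,
) -> OverlapTest:
    """Permutation test of interval-region overlap for one class.

    The observed overlap count is compared with ``n_perm`` randomized
    placements; z = (obs - mean(null)) / sd(null) (undefined when the null
    is degenerate), with +1-corrected empirical p-values for enrichment
    and depletion.
    """
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99 for a meaningful empirical p")
    rng = np.random.default_rng(seed)
    obs = overlap_count(intervals, regions, cls)
    null = np.empty(n_perm, dtype=np.int64)
    for k in range(n_perm):
        null[k] = overlap_count(
            randomize_intervals(intervals, scaffold_lengths, rng), regions, cls
        )
    sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    z = (obs - float(null.mean())) / sd if sd > 0 else None
    p_enrich = (1 + int((null >= obs).sum())) / (n_perm + 1)
    p_deplete = (1 + int((null <= obs).sum())) / (n_perm + 1)
    return OverlapTest(
        cls=cls, observed=obs, null_samples=null, n_perm=n_perm, seed=seed,
        z_score=z, p_enrich=p_enrich, p_deplete=p_deplete,
    )


def enrichment_table(
    intervals: pd.DataFrame,
    regions: RegionSet,
    scaffold_lengths: dict,
    classes: Optional[Sequence[str]] = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed / mean-null / z / p per region class."""
    classes = list(classes) if classes is not None else regions.classes
    rows = []
    for k, cls in enumerate(classes):
        t = permutation_enrichment(
            intervals, regions, cls, scaffold_lengths, n_perm=n_perm, seed=seed + k
        )
        rows.append(
            dict(
                cls=cls, observed=t.observed, null_mean=float(t.null_samples.mean()),
                null_sd=float(t.null_samples.std(ddof=1)), z=t.z_score,
                p_enrich=t.p_enrich, p_deplete=t.p_deplete, n_perm=n_perm,
            )
        )
    return pd.DataFrame(rows)


def _covered_bases(starts, ends, q_starts, q_ends) -> int:
    """Bases of the disjoint sorted regions covered by the query union."""
    total = 0
    for qs, qe in zip(q_starts, q_ends):
        lo = np.searchsorted(ends, qs, side="right")
        hi = np.searchsorted(starts, qe, side="left")
        for i in range(lo, hi):
            total += min(qe, ends[i]) - max(qs, starts[i])
    return total


def class_coverage(
    regions: RegionSet,
    ltr_intervals: pd.DataFrame,
    label_column: Optional[str] = None,
) -> pd.DataFrame:
    """Percent of each class's bases covered by >= 1 LTR interval.

    Coverage is a base-pair union (overlapping LTRs do not double count),
    reported to three decimals.  With ``label_column`` (e.g. superfamily)
    a per-label breakdown is appended.  Classes with zero total bases get
    NaN percent.
    """
    groups = [("all", ltr_intervals)]
    if label_column is not None:
        groups += [
            (str(lab), grp) for lab, grp in ltr_intervals.groupby(label_column, sort=True)
        ]
    rows = []
    for cls in regions.classes:
        total = regions.class_bases(cls)
        for lab, grp in groups:
            merged = merge_intervals(grp)
            covered = 0
            for name, g in merged.groupby("scaffold", sort=False):
                arrays = regions.class_arrays(cls, name)
                if arrays is None:
                    continue
                covered += _covered_bases(
                    arrays[0], arrays[1],
                    g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64),
                )
            pct = round(100.0 * covered / total, 3) if total else float("nan")
            rows.append(
                dict(cls=cls, label=lab, class_bases=total,
                     covered_bases=covered, percent=pct)
            )
    return pd.DataFrame(rows)
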