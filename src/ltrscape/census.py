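"""LTR-RT life-cycle census: solo / truncated / intact classification.

Intact elements (both LTRs plus the internal Gag-Pol domain) are taken
from the input annotation.  Their LTR sequences are then used as queries
in a seed-and-extend homology search over the genome; hits that do not
fall inside an annotated intact element are candidate free-standing LTRs.
Each candidate's flanks are searched for homology to the family's internal
domain: no internal homology on either side means a solo LTR (the product
of intra-element LTR-LTR recombination), homology on exactly one side
means a truncated element, and homology on both sides flags an overlap
with an intact structure that the caller must reconcile.

From the classified loci the module computes the birth/death summary
statistics: the counts I (intact), S (solo), T (truncated), the ratios
S:I, T:I, (S+T):I and the total S+T+I, per-family ratios with the
proportion of families whose S:I exceeds 3 (a high-elimination flag), and
a scaffold-length stabilization scan that picks the smallest assembly-
length filter after which S:I stops moving.

The homology search uses gapless X-drop extension from exact word seeds:
within-family LTR divergence at the identity floor used here (default
80%) is substitution-dominated, and a gapless model keeps the search
exactly checkable against an exhaustive alignment oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import encode, kmer_codes, revcomp
from .errors import ContractError, ParameterError

_UNDEFINED = float("nan")


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass
class LtrLocus:
    """One LTR-RT occurrence with an assigned life-cycle status."""

    element_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    family: str
    superfamily: str = "unknown"
    status: str = "unassigned"  # intact | solo | truncated | intact-overlap
    ltr5_interval: Optional[tuple] = None
    ltr3_interval: Optional[tuple] = None
    internal_interval: Optional[tuple] = None


@dataclass
class HomologyHit:
    query_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    identity: float
    aligned_length: int
    score: int = 0


@dataclass
class SearchParams:
    min_identity: float = 0.8
    min_length: int = 100
    word_size: int = 11
    xdrop: int = 30
    match: int = 1
    mismatch: int = -2

    def validate(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ParameterError("min_identity must be in (0, 1]")
        if self.word_size < 4:
            raise ParameterError("word_size must be >= 4")
        if self.min_length < self.word_size:
            raise ParameterError("min_length must be >= word_size")
        if self.xdrop <= 0 or self.match <= 0 or self.mismatch >= 0:
            raise ParameterError("xdrop/match must be positive, mismatch negative")


@dataclass
class CensusTable:
    """Genome-wide I/S/T counts and the derived ratio statistics.

    Ratios are kept at full precision; ``format_ratio`` renders the
    two-decimal half-up form used in printed tables.  When I == 0 the
    ratios are NaN sentinels and ``ratios_defined`` is False.
    """

    I: int
    S: int
    T: int
    min_scaffold_length: int = 0
    filtered_I: Optional[int] = None
    filtered_S: Optional[int] = None
    filtered_T: Optional[int] = None

    @property
    def STI(self) -> int:
        return self.I + self.S + self.T

    @property
    def ratios_defined(self) -> bool:
        return self.I > 0

    @property
    def S_over_I(self) -> float:
        return self.S / self.I if self.I else _UNDEFINED

    @property
    def T_over_I(self) -> float:
        return self.T / self.I if self.I else _UNDEFINED

    @property
    def ST_over_I(self) -> float:
        return (self.S + self.T) / self.I if self.I else _UNDEFINED

    @classmethod
    def from_counts(cls, I: int, S: int, T: int, **kw) -> "CensusTable":
        if min(I, S, T) < 0:
            raise ParameterError("counts must be non-negative")
        return cls(I=I, S=S, T=T, **kw)

    def filtered(self) -> "CensusTable":
        """The census restricted to scaffolds passing the length filter."""
        if self.filtered_I is None:
            return self
        return CensusTable.from_counts(self.filtered_I, self.filtered_S, self.filtered_T)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                level="all", I=self.I, S=self.S, T=self.T, STI=self.STI,
                S_over_I=self.S_over_I, T_over_I=self.T_over_I,
                ST_over_I=self.ST_over_I,
            )
        ]
        if self.filtered_I is not None:
            f = self.filtered()
            rows.append(
                dict(
                    level=f"scaffold>={self.min_scaffold_length}",
                    I=f.I, S=f.S, T=f.T, STI=f.STI,
                    S_over_I=f.S_over_I, T_over_I=f.T_over_I,
                    ST_over_I=f.ST_over_I,
                )
            )
        return pd.DataFrame(rows)


def format_ratio(x: float, decimals: int = 2) -> str:
    """Half-up decimal rendering (printed-table convention for ratios)."""
    if np.isnan(x):
        return "NA"
    scale = 10**decimals
    return f"{np.floor(x * scale + 0.5) / scale:.{decimals}f}"


def format_percent_truncated(x: float, decimals: int = 2) -> str:
    """Truncated (floor) percent rendering, as printed for family proportions."""
    if np.isnan(x):
        return "NA"
    scale = 10**decimals
    return f"{np.floor(x * scale) / scale:.{decimals}f}"


@dataclass
class FamilyCensus:
    family_id: str
    I: int
    S: int
    T: int

    @property
    def S_over_I(self) -> float:
        return self.S / self.I if self.I else float("inf") if self.S else 0.0

    @property
    def high_elimination(self) -> bool:
        # families with I == 0 but surviving solos/truncations represent
        # complete elimination: ratio treated as +inf > 3
        return self.S_over_I > 3


@dataclass
class FamilySummary:
    n_families: int
    n_high: int

    @property
    def proportion_high(self) -> float:
        """Percent of families with S:I > 3 (full precision)."""
        return 100.0 * self.n_high / self.n_families if self.n_families else _UNDEFINED

    @property
    def proportion_high_str(self) -> str:
        return format_percent_truncated(self.proportion_high)


@dataclass
class StabilityScan:
    thresholds: list
    ratio_at_threshold: list
    selected_threshold: int
    tolerance: float
    stable: bool
    truncated_at: Optional[int] = None  # grid point where I hit 0, if any


# ---------------------------------------------------------------------------
# seed-and-extend homology search
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact-word index over a set of scaffolds for seed lookup."""

    def __init__(self, scaffolds: dict, word_size: int = 11):
        self.word_size = word_size
        self.scaffolds = scaffolds
        self.codes = {name: encode(seq) for name, seq in scaffolds.items()}
        self._sorted = {}
        for name, codes in self.codes.items():
            words = kmer_codes(codes, word_size)
            order = np.argsort(words, kind="stable")
            self._sorted[name] = (words[order], order.astype(np.int64))

    def positions(self, name: str, word: int) -> np.ndarray:
        words, order = self._sorted[name]
        lo = np.searchsorted(words, word, side="left")
        hi = np.searchsorted(words, word, side="right")
        return order[lo:hi]


def _extend_gapless(q: np.ndarray, s: np.ndarray, qi: int, si: int, params: SearchParams):
    """X-drop gapless extension of a seed; returns (q0, q1, matches, score).

    The seed word starting at (qi, si) is extended left and right along the
    diagonal; each direction stops once the running score drops ``xdrop``
    below its maximum, and the best-scoring extent is kept.
    """
    w = len(q)
    # right extension from end of word
    best_r, score, r = 0, 0, 0
    qstart, sstart = qi, si
    n_right = min(w - qi, len(s) - si)
    matches_right = 0
    best_mr = 0
    for k in range(n_right):
        score += params.match if q[qi + k] == s[si + k] else params.mismatch
        if q[qi + k] == s[si + k]:
            matches_right += 1
        if score > best_r:
            best_r, r, best_mr = score, k + 1, matches_right
        elif best_r - score > params.xdrop:
            break
    # left extension from before the word
    best_l, score, l = 0, 0, 0
    n_left = min(qi, si)
    matches_left = 0
    best_ml = 0
    for k in range(1, n_left + 1):
        score += params.match if q[qi - k] == s[si - k] else params.mismatch
        if q[qi - k] == s[si - k]:
            matches_left += 1
        if score > best_l:
            best_l, l, best_ml = score, k, matches_left
        elif best_l - score > params.xdrop:
            break
    return qstart - l, qstart - l + (l + r), best_ml + best_mr, best_l + best_r


def search_homology(
    query: str,
    subject,
    params: Optional[SearchParams] = None,
    query_id: str = "query",
) -> list:
    """Find local homologies of ``query`` in the subject scaffolds.

    ``subject`` is a dict of scaffold sequences or a prebuilt
    :class:`GenomeIndex`.  Both strands are searched; overlapping hits on
    the same scaffold and strand are merged keeping the higher-identity
    extent.  Every returned :class:`HomologyHit` satisfies
    ``identity >= min_identity`` and ``aligned_length >= min_length``.
    """
    params = params or SearchParams()
    params.validate()
    if len(query) < params.word_size:
        raise ParameterError(
            f"query length {len(query)} < word_size {params.word_size}"
        )
    if not isinstance(subject, GenomeIndex):
        subject = GenomeIndex(subject, params.word_size)
    elif subject.word_size != params.word_size:
        raise ParameterError("index word_size does not match search params")

    hits = []
    for strand in "+-":
        qseq = query if strand == "+" else revcomp(query)
        qcodes = encode(qseq)
        qwords = kmer_codes(qcodes, params.word_size)
        for name, scodes in subject.codes.items():
            seen_diag = {}
            for qi in range(len(qwords)):
                w = int(qwords[qi])
                if w < 0:
                    continue
                for si in subject.positions(name, w):
                    diag = int(si) - qi
                    prev_end = seen_diag.get(diag, -1)
                    if si < prev_end:
                        continue  # already inside an extension on this diagonal
                    q0, q1, matches, score = _extend_gapless(
                        qcodes, scodes, qi, int(si), params
                    )
                    alen = q1 - q0
                    sub_start = q0 + diag
                    seen_diag[diag] = sub_start + alen
                    if alen < params.min_length:
                        continue
                    ident = matches / alen
                    if ident < params.min_identity:
                        continue
                    hits.append(
                        HomologyHit(
                            query_id=query_id, scaffold=name, start=sub_start,
                            end=sub_start + alen,
                            strand=strand, identity=ident, aligned_length=alen,
                            score=score,
                        )
                    )
    return merge_hits(hits)


def merge_hits(hits: Sequence[HomologyHit]) -> list:
    """Merge overlapping same-scaffold/strand hits, keeping the best extent."""
    out = []
    keyed = sorted(hits, key=lambda h: (h.scaffold, h.strand, h.start, h.end))
    for h in keyed:
        if out:
            p = out[-1]
            if p.scaffold == h.scaffold and p.strand == h.strand and h.start < p.end:
                if (h.identity, h.aligned_length) > (p.identity, p.aligned_length):
                    out[-1] = h
                continue
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def default_flank_window(internal_length: int, cap: int = 15_000) -> int:
    """1.5x the internal reference length, capped (displaced-domain reach)."""
    return int(min(1.5 * internal_length, cap))


def classify_locus(
    hit: HomologyHit,
    internal_reference: str,
    scaffolds: dict,
    flank_window: Optional[int] = None,
    params: Optional[SearchParams] = None,
) -> str:
    """Assign solo / truncated / intact-overlap from flanking homology.

    The windows upstream and downstream of the hit are searched for
    homology to the internal (Gag-Pol) reference.  Neither side -> solo;
    exactly one side -> truncated; both sides -> ``intact-overlap`` for
    the caller to reconcile with the intact annotation (never dropped
    here).  Windows are clipped at scaffold ends.
    """
    if flank_window is None:
        flank_window = default_flank_window(len(internal_reference))
    if flank_window <= 0:
        raise ParameterError("flank_window must be > 0")
    params = params or SearchParams()
    seq = scaffolds[hit.scaffold]
    up = seq[max(0, hit.start - flank_window) : hit.start]
    down = seq[hit.end : hit.end + flank_window]
    has = []
    for flank in (up, down):
        if len(flank) < params.word_size:
            has.append(False)
            continue
        found = search_homology(internal_reference, {"flank": flank}, params)
        has.append(bool(found))
    up_hit, down_hit = has
    if up_hit and down_hit:
        return "intact-overlap"
    if up_hit or down_hit:
        return "truncated"
    return "solo"


def _overlaps_any(hit: HomologyHit, intervals_by_scaffold: dict) -> bool:
    spans = intervals_by_scaffold.get(hit.scaffold)
    if spans is None:
        return False
    starts, ends = spans
    i = int(np.searchsorted(starts, hit.end, side="left")) - 1
    return i >= 0 and ends[i] > hit.start


def classify_genome(
    scaffolds: dict,
    intact_annotation: pd.DataFrame,
    params: Optional[SearchParams] = None,
    flank_window: Optional[int] = None,
):
    """Full census classification of a genome.

    ``intact_annotation`` holds part rows (element_id, scaffold, start,
    end, strand, family, superfamily, part in {LTR5, internal, LTR3}) for
    the intact elements.  Per family, the first intact element contributes
    the LTR and internal reference sequences; the LTR reference is
    searched genome-wide, hits overlapping any annotated intact element
    span are excluded (they are the intacts' own LTRs), and the remainder
    are classified by flanking internal homology.

    Returns ``(loci, unreconciled)``: classified :class:`LtrLocus` records
    (intact loci from the annotation plus solo/truncated calls), and hits
    classified intact-overlap that matched no annotated intact element.
    """
    params = params or SearchParams()
    index = GenomeIndex(scaffolds, params.word_size)

    def part_seq(row):
        s = scaffolds[row.scaffold][row.start : row.end]
        return revcomp(s) if row.strand == "-" else s

    # intact spans per scaffold for exclusion
    spans = {}
    intact_loci = []
    if len(intact_annotation):
        grouped = intact_annotation.groupby("element_id", sort=True)
        bounds = []
        for eid, grp in grouped:
            lo, hi = int(grp["start"].min()), int(grp["end"].max())
            row0 = grp.iloc[0]
            bounds.append((row0.scaffold, lo, hi))
            parts = {r.part: (int(r.start), int(r.end)) for r in grp.itertuples()}
            intact_loci.append(
                LtrLocus(
                    element_id=str(eid), scaffold=row0.scaffold, start=lo, end=hi,
                    strand=row0.strand, family=row0.family,
                    superfamily=getattr(row0, "superfamily", "unknown"),
                    status="intact",
                    ltr5_interval=parts.get("LTR5"),
                    ltr3_interval=parts.get("LTR3"),
                    internal_interval=parts.get("internal"),
                )
            )
        df = pd.DataFrame(bounds, columns=["scaffold", "lo", "hi"])
        for name, grp in df.groupby("scaffold"):
            grp = grp.sort_values("lo")
            spans[name] = (grp["lo"].to_numpy(), grp["hi"].to_numpy())

    # family references from the first intact element of each family
    refs = {}
    if len(intact_annotation):
        for (fam,), grp in intact_annotation.groupby(["family"], sort=True):
            first = grp[grp["element_id"] == grp["element_id"].iloc[0]]
            by_part = {r.part: r for r in first.itertuples()}
            if "LTR5" not in by_part or "internal" not in by_part:
                raise ContractError(f"family {fam} lacks LTR5/internal parts")
            refs[fam] = dict(
                ltr=part_seq(by_part["LTR5"]),
                internal=part_seq(by_part["internal"]),
                superfamily=getattr(first.iloc[0], "superfamily", "unknown"),
            )

    candidate_hits = []
    for fam in sorted(refs):
        for h in search_homology(refs[fam]["ltr"], index, params, query_id=fam):
            if not _overlaps_any(h, spans):
                candidate_hits.append((fam, h))
    # de-duplicate across families: keep the best-identity hit per interval
    candidate_hits.sort(key=lambda t: (t[1].scaffold, t[1].start, t[1].end))
    deduped = []
    for fam, h in candidate_hits:
        if deduped:
            pf, p = deduped[-1]
            if p.scaffold == h.scaffold and h.start < p.end:
                if (h.identity, h.aligned_length) > (p.identity, p.aligned_length):
                    deduped[-1] = (fam, h)
                continue
        deduped.append((fam, h))

    loci = list(intact_loci)
    unreconciled = []
    counter = 0
    for fam, h in deduped:
        counter += 1
        status = classify_locus(
            h, refs[fam]["internal"], scaffolds, flank_window, params
        )
        locus = LtrLocus(
            element_id=f"{fam}_hit_{counter:04d}", scaffold=h.scaffold,
            start=h.start, end=h.end, strand=h.strand, family=fam,
            superfamily=refs[fam]["superfamily"], status=status,
        )
        if status == "intact-overlap":
            unreconciled.append(locus)
        else:
            loci.append(locus)
    return loci, unreconciled


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _counts(loci, keep=lambda l: True):
    c = {"intact": 0, "solo": 0, "truncated": 0}
    for l in loci:
        if l.status in c and keep(l):
            c[l.status] += 1
    return c["intact"], c["solo"], c["truncated"]


def run_census(
    loci: Sequence[LtrLocus],
    min_scaffold_length: int = 0,
    scaffold_lengths: Optional[dict] = None,
) -> CensusTable:
    """I/S/T counts and ratio statistics, with a scaffold-length filter.

    Loci on scaffolds shorter than ``min_scaffold_length`` are excluded
    from the filtered columns; unfiltered counts are always reported.
    """
    if min_scaffold_length > 0 and scaffold_lengths is None:
        raise ContractError("scaffold_lengths required when filtering by length")
    if scaffold_lengths is not None:
        missing = {l.scaffold for l in loci} - set(scaffold_lengths)
        if missing:
            raise ContractError(f"scaffold_lengths missing {sorted(missing)[:3]}")
    I, S, T = _counts(loci)
    fI = fS = fT = None
    if min_scaffold_length > 0:
        keep = lambda l: scaffold_lengths[l.scaffold] >= min_scaffold_length  # noqa: E731
        fI, fS, fT = _counts(loci, keep)
    return CensusTable.from_counts(
        I, S, T, min_scaffold_length=min_scaffold_length,
        filtered_I=fI, filtered_S=fS, filtered_T=fT,
    )


def family_census(loci: Sequence[LtrLocus]):
    """Per-family I/S/T with the proportion of S:I > 3 families.

    Families present only as solos/truncations (I = 0, S + T > 0) count as
    high-elimination: the ratio is effectively infinite, which is the
    extreme of the elimination signal the statistic measures.
    """
    fams = {}
    for l in loci:
        if l.status not in ("intact", "solo", "truncated"):
            continue
        rec = fams.setdefault(l.family, [0, 0, 0])
        rec[("intact", "solo", "truncated").index(l.status)] += 1
    table = [
        FamilyCensus(family_id=f, I=v[0], S=v[1], T=v[2])
        for f, v in sorted(fams.items())
    ]
    summary = FamilySummary(
        n_families=len(table), n_high=sum(fc.high_elimination for fc in table)
    )
    return table, summary


def stability_scan(
    loci: Sequence[LtrLocus],
    scaffold_lengths: dict,
    grid: Optional[Sequence[int]] = None,
    tolerance: float = 0.01,
    patience: int = 2,
) -> StabilityScan:
    """Scan scaffold-length filters until the S:I ratio stabilizes.

    The default grid is 0 plus the deciles of the scaffold-length
    distribution.  The selected threshold is the first grid point after
    which the relative change in S:I stays below ``tolerance`` for
    ``patience`` consecutive grid steps; if the ratio never stabilizes the
    scan selects 0 and reports ``stable=False``.  If some threshold
    removes every intact element the scan truncates there.
    """
    if tolerance <= 0:
        raise ParameterError("tolerance must be > 0")
    if patience < 1:
        raise ParameterError("patience must be >= 1")
    if grid is None:
        lens = np.array(sorted(scaffold_lengths.values()))
        deciles = np.quantile(lens, np.linspace(0.1, 0.9, 9), method="lower")
        grid = sorted({0, *[int(d) for d in deciles]})
    grid = list(grid)
    if grid[0] != 0 or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ParameterError("grid must be strictly increasing and start at 0")

    ratios = []
    truncated_at = None
    used = []
    for t in grid:
        keep = lambda l: scaffold_lengths[l.scaffold] >= t  # noqa: E731
        I, S, _ = _counts(loci, keep)
        if I == 0:
            truncated_at = t
            break
        used.append(t)
        ratios.append(S / I)
    if not used:
        return StabilityScan(
            thresholds=[], ratio_at_threshold=[], selected_threshold=0,
            tolerance=tolerance, stable=False, truncated_at=truncated_at,
        )

    n = len(used)
    rel = [
        abs(ratios[i + 1] - ratios[i]) / ratios[i] if ratios[i] > 0
        else float(ratios[i + 1] != ratios[i])
        for i in range(n - 1)
    ]
    selected, stable = 0, False
    if n == 1:
        selected, stable = used[0], True
    else:
        for i in range(n - 1):
            # a window shorter than `patience` counts only when it reaches
            # the end of the grid (the ratio stayed flat to the last point)
            window = rel[i : i + patience]
            if all(r < tolerance for r in window):
                selected, stable = used[i], True
                break
    return StabilityScan(
        thresholds=used, ratio_at_threshold=ratios,
        selected_threshold=selected, tolerance=tolerance, stable=stable,
        truncated_at=truncated_at,
    )


def loci_to_frame(loci: Sequence[LtrLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                element_id=l.element_id, scaffold=l.scaffold, start=l.start,
                end=l.end, strand=l.strand, family=l.family,
                superfamily=l.superfamily, status=l.status,
            )
            for l in loci
        ]
    )
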