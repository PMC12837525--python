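"""LTR-pair divergence and insertion-time estimation.

An LTR retrotransposon inserts with two identical LTRs; they then diverge
at the neutral rate, so the per-site distance K between the 5' and 3' LTR
of an intact element dates the insertion as

    T = K / (2 r)

with r the substitution rate per site per year (default 1.3e-8).  K is
estimated from a global alignment of the two LTRs under the Kimura
2-parameter model by default,

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

where P and Q are the transition and transversion proportions over
ungapped, unambiguous columns; Jukes-Cantor (JC69) and the raw proportion
P + Q are available alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import encode, require_acgt
from .errors import ParameterError, SaturationError

DEFAULT_RATE = 1.3e-8  # substitutions / site / year

_NEG = -(10**9)

# purine codes {A=0, G=2}; a substitution within purines or within
# pyrimidines is a transition, across is a transversion
_IS_PURINE = np.array([True, False, True, False, False])


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    n_ungapped: int
    n_transitions: int
    n_transversions: int


@dataclass
class DivergenceEstimate:
    P: float
    Q: float
    K: float
    model: str
    n_sites: int
    r: Optional[float] = None
    t_years: Optional[float] = None


def align_pair(
    a: str,
    b: str,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    match: float = 2.0,
    mismatch: float = -3.0,
) -> PairwiseAlignment:
    """Optimal global alignment under an affine gap scheme (Gotoh).

    A gap of length L scores ``gap_open + L * gap_extend``.  Traceback
    ties are broken deterministically preferring a diagonal step (match or
    substitution) over opening or extending a gap.
    """
    ca = require_acgt(a, "sequence a")
    cb = require_acgt(b, "sequence b")
    if gap_open > 0 or gap_extend > 0:
        raise ParameterError("gap penalties must be <= 0")
    n, m = len(ca), len(cb)
    oe = gap_open + gap_extend
    e = gap_extend

    M = np.full((n + 1, m + 1), _NEG, dtype=np.float64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.float64)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.float64)  # gap in a (consumes b)
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = oe + e * np.arange(n)
    if m:
        Y[0, 1:] = oe + e * np.arange(m)

    js = np.arange(1, m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        sub = np.where(cb == ca[i - 1], match, mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1, :m], X[i - 1, :m]), Y[i - 1, :m])
        M[i, 1:] = prev_best + sub
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] + oe, Y[i - 1, 1:] + oe), X[i - 1, 1:] + e
        )
        # Y via prefix scan over the current row:
        #   Y[i,j] = max_{k<j} max(M[i,k], X[i,k]) + oe + (j-1-k) e
        # which equals the recurrence max(M[i,j-1]+oe, X[i,j-1]+oe, Y[i,j-1]+e)
        B = np.maximum(M[i, :m], X[i, :m])
        Y[i, 1:] = np.maximum.accumulate(B + oe - e * js) + e * js

    # traceback, preferring a diagonal step (M) over X over Y at every tie
    out_a, out_b = [], []
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    score = float(max(M[n, m], X[n, m], Y[n, m]))
    while i > 0 or j > 0:
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            state = int(np.argmax([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]))
            i, j = i - 1, j - 1
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            val = X[i, j]
            cands = (M[i - 1, j] + oe, X[i - 1, j] + e, Y[i - 1, j] + oe)
            state = (0, 1, 2)[_first_eq(cands, val)]
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Y[i, j]
            cands = (M[i, j - 1] + oe, X[i, j - 1] + oe, Y[i, j - 1] + e)
            state = (0, 1, 2)[_first_eq(cands, val)]
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    al = _count_columns(aligned_a, aligned_b)
    return PairwiseAlignment(
        aligned_a=aligned_a, aligned_b=aligned_b, score=score,
        n_ungapped=al[0], n_transitions=al[1], n_transversions=al[2],
    )


def _first_eq(cands, val) -> int:
    for k, c in enumerate(cands):
        if c == val:
            return k
    # floating slack: fall back to the closest candidate
    return int(np.argmin([abs(c - val) for c in cands]))


def alignment_from_strings(aligned_a: str, aligned_b: str, score: float = 0.0) -> PairwiseAlignment:
    """Build a :class:`PairwiseAlignment` from pre-aligned strings."""
    if len(aligned_a) != len(aligned_b):
        raise ParameterError("aligned strings must have equal length")
    n_ungapped, ts, tv = _count_columns(aligned_a, aligned_b)
    return PairwiseAlignment(aligned_a, aligned_b, score, n_ungapped, ts, tv)


def _count_columns(aligned_a: str, aligned_b: str):
    """Count ungapped unambiguous columns, transitions and transversions."""
    n_ungapped = ts = tv = 0
    for x, y in zip(aligned_a, aligned_b):
        if x in "-N" or y in "-N":
            continue
        n_ungapped += 1
        if x == y:
            continue
        cx, cy = int(encode(x)[0]), int(encode(y)[0])
        if _IS_PURINE[cx] == _IS_PURINE[cy]:
            ts += 1
        else:
            tv += 1
    return n_ungapped, ts, tv


def estimate_divergence(alignment: PairwiseAlignment, model: str = "K2P") -> DivergenceEstimate:
    """Per-site distance K from an aligned LTR pair.

    Gapped and ambiguous columns are excluded from the P/Q denominators.
    Raises :class:`SaturationError` when the divergence lies outside the
    domain of the requested model's log transform.
    """
    if alignment.n_ungapped <= 0:
        raise ParameterError("alignment has no ungapped columns")
    n = alignment.n_ungapped
    P = alignment.n_transitions / n
    Q = alignment.n_transversions / n
    if model == "K2P":
        w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if w1 <= 0 or w2 <= 0:
            raise SaturationError(
                f"K2P distance undefined: 1-2P-Q={w1:.4f}, 1-2Q={w2:.4f}"
            )
        K = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    elif model == "JC69":
        p = P + Q
        w = 1.0 - 4.0 * p / 3.0
        if w <= 0:
            raise SaturationError(f"JC69 distance undefined: 1-4p/3={w:.4f}")
        K = -0.75 * np.log(w)
    elif model == "raw":
        K = P + Q
    else:
        raise ParameterError(f"unknown model {model!r}; use K2P, JC69 or raw")
    return DivergenceEstimate(P=P, Q=Q, K=float(K), model=model, n_sites=n)


def insertion_time(K: float, r: float = DEFAULT_RATE) -> float:
    """Years since insertion: T = K / (2 r)."""
    if r <= 0:
        raise ParameterError("substitution rate r must be > 0")
    if K < 0:
        raise ParameterError("divergence K must be >= 0")
    return K / (2.0 * r)


def date_elements(
    scaffolds: dict,
    intact_annotation: pd.DataFrame,
    model: str = "K2P",
    r: float = DEFAULT_RATE,
    **align_kw,
) -> pd.DataFrame:
    """Per-intact-element divergence and insertion time.

    ``intact_annotation`` holds part rows with LTR5/LTR3 intervals; the two
    LTR sequences are extracted in element orientation, globally aligned
    and dated.  Elements whose divergence saturates the model are reported
    with NaN K/T and a note.
    """
    from ._seq import revcomp

    rows = []
    for eid, grp in intact_annotation.groupby("element_id", sort=True):
        by_part = {p.part: p for p in grp.itertuples()}
        if "LTR5" not in by_part or "LTR3" not in by_part:
            continue
        recs = {}
        for part in ("LTR5", "LTR3"):
            rec = by_part[part]
            s = scaffolds[rec.scaffold][rec.start : rec.end]
            recs[part] = revcomp(s) if rec.strand == "-" else s
        aln = align_pair(recs["LTR5"], recs["LTR3"], **align_kw)
        row0 = grp.iloc[0]
        base = dict(
            element_id=eid, superfamily=getattr(row0, "superfamily", "unknown"),
            family=row0.family, n_sites=aln.n_ungapped,
        )
        try:
            est = estimate_divergence(aln, model)
            base.update(P=est.P, Q=est.Q, K=est.K, t_years=insertion_time(est.K, r))
        except SaturationError:
            n = aln.n_ungapped
            base.update(
                P=aln.n_transitions / n, Q=aln.n_transversions / n,
                K=np.nan, t_years=np.nan,
            )
        rows.append(base)
    cols = ["element_id", "family", "superfamily", "P", "Q", "K", "t_years", "n_sites"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


def insertion_profile(estimates: pd.DataFrame, bin_width: float) -> pd.DataFrame:
    """Histogram of insertion times per superfamily.

    Bins are half-open ``[k*w, (k+1)*w)``; rows with NaN times (saturated
    elements) are dropped.  Total counts over bins equal the number of
    dated elements.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    cols = ["superfamily", "bin_start", "bin_end", "count"]
    if estimates is None or not len(estimates):
        return pd.DataFrame(columns=cols)
    df = estimates.dropna(subset=["t_years"])
    if not len(df):
        return pd.DataFrame(columns=cols)
    binned = (df["t_years"] // bin_width).astype(int)
    out = (
        df.assign(_bin=binned)
        .groupby(["superfamily", "_bin"])
        .size()
        .reset_index(name="count")
    )
    out["bin_start"] = out["_bin"] * bin_width
    out["bin_end"] = (out["_bin"] + 1) * bin_width
    return out[cols].sort_values(["superfamily", "bin_start"]).reset_index(drop=True)
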