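"""Synthetic genomes with planted LTR-retrotransposon truth.

This module builds small genomes in which every quantity the analysis
modules estimate is known by construction: intact elements are planted as
TSD + 5'LTR + internal (Gag-Pol) + 3'LTR + TSD with the 3' LTR diverged
from the 5' LTR by an exact, recorded number of transition and
transversion substitutions; solo LTRs are single LTR copies with no
internal sequence anywhere near them; truncated elements keep one LTR and
a partial internal fragment on one side only.  Structural-variation region
classes (INV / SPE / SYN) partition the scaffolds with exact base
fractions, and element placement can be biased towards a class to plant an
enrichment signal.  A companion gene simulator plants tandem / proximal
duplicate pairs and pseudogene candidates straddling the filter
thresholds, and an expression simulator adds a configurable log-scale
offset to genes resident in species-specific (SPE) regions.

Mutations are placed at distinct sites (no multiple hits), so the planted
transition / transversion proportions are exactly recoverable from the
emitted sequences; this makes divergence-dating recovery an exact test
rather than a statistical one.

All coordinates are 0-based half-open internally; GFF3 output is 1-based
closed (see :mod:`ltrscape.io`).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import TRANSITION, decode, encode, random_seq, require_acgt, revcomp
from .errors import CapacityError, ParameterError

REGION_CLASSES = ("INV", "SPE", "SYN")

# transversion partners per base code (the two codes that are neither the
# base itself nor its transition partner)
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def mutate_sequence(seq: str, p_target: float, q_target: float, seed) -> str:
    """Apply exact numbers of transition/transversion substitutions.

    ``round(p_target * len)`` sites receive a transition (A<->G, C<->T) and
    ``round(q_target * len)`` sites a transversion, all at distinct
    positions, so the observed proportions equal the targets exactly.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    codes = require_acgt(seq, "input sequence")
    if p_target < 0 or q_target < 0:
        raise ParameterError("divergence targets must be non-negative")
    if p_target + q_target > 0.75:
        raise ParameterError(
            f"P + Q = {p_target + q_target:.3f} exceeds 0.75; sequences this "
            "diverged cannot be represented without multiple hits"
        )
    n = len(codes)
    n_ts = _round_half_up(p_target * n)
    n_tv = _round_half_up(q_target * n)
    if n_ts + n_tv > n:
        raise ParameterError(
            f"targets require {n_ts + n_tv} distinct sites but sequence has {n}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = codes.copy()
    sites = rng.choice(n, size=n_ts + n_tv, replace=False)
    ts_sites = sites[:n_ts]
    tv_sites = sites[n_ts:]
    out[ts_sites] = TRANSITION[codes[ts_sites]]
    if n_tv:
        pick = rng.integers(0, 2, size=n_tv)
        out[tv_sites] = _TV_PARTNERS[codes[tv_sites], pick]
    return decode(out)


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Defaults emulate a small diploid-plant-like repeat landscape: a ~2 Mb
    assembly in a dozen scaffolds whose lengths follow a truncated power
    law, six LTR-RT families split between Copia and Gypsy, LTR-pair
    divergence up to P=0.05 / Q=0.02 (young insertions, within the
    homology-search identity floor), and SPE/SYN/INV fractions inside the
    ranges reported for whole-genome comparisons of congeneric plants.
    """

    # scaffolds
    n_scaffolds: int = 12
    scaffold_length_min: int = 80_000
    scaffold_length_max: int = 500_000
    scaffold_length_alpha: float = 1.6

    # element complement
    n_families: int = 6
    n_intact: int = 50
    n_solo: int = 100
    n_truncated: int = 30
    ltr_length: int = 300
    internal_length: int = 2_000
    tsd_length: int = 5
    truncated_internal_fraction: float = 0.4
    min_element_gap: int = 4_000
    minus_strand_fraction: float = 0.5

    # LTR-pair divergence: explicit (P, Q) list cycled over intact
    # elements, or uniform draws bounded by the maxima below
    divergence_targets: Optional[Sequence[tuple[float, float]]] = None
    divergence_p_max: float = 0.05
    divergence_q_max: float = 0.02

    # region classes and placement bias
    region_fractions: dict = field(
        default_factory=lambda: {"INV": 0.14, "SPE": 0.38, "SYN": 0.42}
    )
    region_chunk_size: int = 10_000
    ltr_placement_bias: dict = field(
        default_factory=lambda: {"INV": 1.0, "SPE": 1.0, "SYN": 1.0}
    )

    # gene complement
    gene_count: int = 300
    gene_length: int = 1_500
    gene_spacing: int = 1_000
    td_clusters: int = 4
    pd_clusters: int = 4
    none_pairs: int = 4
    pseudogene_count: int = 12

    # expression
    n_stages: int = 5
    expression_effect: float = 0.0
    expression_baseline_log2: float = 6.0
    expression_sd_log2: float = 1.5

    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_scaffolds": self.n_scaffolds,
            "n_families": self.n_families,
            "n_intact": self.n_intact,
            "n_solo": self.n_solo,
            "n_truncated": self.n_truncated,
            "gene_count": self.gene_count,
            "td_clusters": self.td_clusters,
            "pd_clusters": self.pd_clusters,
            "pseudogene_count": self.pseudogene_count,
            "tsd_length": self.tsd_length,
        }
        for name, v in counts.items():
            if v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v}")
        if self.n_families < 1:
            raise ParameterError("n_families must be >= 1")
        if not 0 < self.scaffold_length_min <= self.scaffold_length_max:
            raise ParameterError("scaffold length bounds must satisfy 0 < min <= max")
        for cls, f in self.region_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ParameterError(f"region fraction for {cls} must be in [0, 1]")
        if sum(self.region_fractions.values()) > 1.0 + 1e-9:
            raise ParameterError("region fractions must sum to <= 1")
        if any(w < 0 for w in self.ltr_placement_bias.values()):
            raise ParameterError("placement bias weights must be >= 0")
        if self.n_stages < 1:
            raise ParameterError("n_stages must be >= 1")
        if not 0 <= self.minus_strand_fraction <= 1:
            raise ParameterError("minus_strand_fraction must be in [0, 1]")


@dataclass
class TruthTable:
    """Planted ground truth for one synthetic bundle."""

    elements: pd.DataFrame
    regions: pd.DataFrame
    genes: Optional[pd.DataFrame] = None
    pairs: Optional[pd.DataFrame] = None
    pseudogenes: Optional[pd.DataFrame] = None


@dataclass
class GenomeBundle:
    """A simulated genome with annotations and planted truth."""

    config: SimConfig
    scaffolds: dict
    elements: pd.DataFrame  # one row per element part (LTR5/internal/LTR3/LTR)
    regions: pd.DataFrame
    truth: TruthTable
    genes: Optional[pd.DataFrame] = None
    pairs: Optional[pd.DataFrame] = None
    pseudogenes: Optional[pd.DataFrame] = None
    expression: Optional[pd.DataFrame] = None

    @property
    def scaffold_lengths(self) -> dict:
        return {name: len(seq) for name, seq in self.scaffolds.items()}

    def intact_annotation(self) -> pd.DataFrame:
        """Part rows of intact elements, as an upstream annotator would supply."""
        return self.elements[self.elements["status"] == "intact"].reset_index(drop=True)

    def part_sequence(self, row) -> str:
        """Extract the planted (element-orientation) sequence of a part row."""
        s = self.scaffolds[row.scaffold][row.start : row.end]
        return revcomp(s) if row.strand == "-" else s

    def write(self, outdir) -> None:
        from . import io

        io.write_bundle(self, outdir)


def _scaffold_lengths(cfg: SimConfig, rng: np.random.Generator) -> dict:
    a = cfg.scaffold_length_alpha
    lo, hi = float(cfg.scaffold_length_min), float(cfg.scaffold_length_max)
    u = rng.random(cfg.n_scaffolds)
    if abs(a - 1.0) < 1e-12:
        lengths = lo * np.exp(u * np.log(hi / lo))
    else:
        # inverse CDF of a Pareto-like density ~ L^-a truncated to [lo, hi]
        b = 1.0 - a
        lengths = (lo**b + u * (hi**b - lo**b)) ** (1.0 / b)
    names = [f"scaffold_{i + 1}" for i in range(cfg.n_scaffolds)]
    return dict(zip(names, np.floor(lengths).astype(int).tolist()))


def simulate_regions(scaffold_lengths: dict, config: SimConfig, seed=None):
    """Partition scaffolds into labeled INV/SPE/SYN intervals.

    Scaffolds are chopped into chunks (``region_chunk_size``), the chunks
    shuffled genome-wide, and each class fills its exact base quota
    (``fraction * total_length``) from the shuffled stream, splitting the
    final chunk so realized fractions match the request to the base pair.
    Remaining chunks stay unlabeled.  Returns ``(regions, weights)`` where
    ``regions`` has columns scaffold/start/end/cls and ``weights`` is the
    normalized placement-bias map.
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    total = int(sum(scaffold_lengths.values()))
    chunks = []
    for name in scaffold_lengths:
        L = int(scaffold_lengths[name])
        for s in range(0, L, config.region_chunk_size):
            chunks.append((name, s, min(s + config.region_chunk_size, L)))
    order = rng.permutation(len(chunks))
    stream = [chunks[i] for i in order]

    records = []
    pos = 0
    for cls in REGION_CLASSES:
        quota = int(round(config.region_fractions.get(cls, 0.0) * total))
        while quota > 0 and pos < len(stream):
            name, s, e = stream[pos]
            take = min(e - s, quota)
            records.append((name, s, s + take, cls))
            if take < e - s:
                stream[pos] = (name, s + take, e)
            else:
                pos += 1
            quota -= take
    regions = pd.DataFrame(records, columns=["scaffold", "start", "end", "cls"])
    regions = regions.sort_values(["scaffold", "start"]).reset_index(drop=True)
    weights = dict(config.ltr_placement_bias)
    return regions, weights


class _RegionLookup:
    """Point query: which labeled class (or None) covers a position."""

    def __init__(self, regions: pd.DataFrame):
        self._by_scaffold = {}
        for name, grp in regions.groupby("scaffold"):
            grp = grp.sort_values("start")
            self._by_scaffold[name] = (
                grp["start"].to_numpy(),
                grp["end"].to_numpy(),
                grp["cls"].to_numpy(),
            )

    def cls_at(self, scaffold: str, pos: int):
        if scaffold not in self._by_scaffold:
            return None
        starts, ends, labels = self._by_scaffold[scaffold]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return labels[i]
        return None


def _draw_divergences(cfg: SimConfig, n: int, rng: np.random.Generator):
    if cfg.divergence_targets is not None:
        targets = list(cfg.divergence_targets)
        return [targets[i % len(targets)] for i in range(n)]
    p = rng.uniform(0.0, cfg.divergence_p_max, size=n)
    q = rng.uniform(0.0, cfg.divergence_q_max, size=n)
    return list(zip(p.tolist(), q.tolist()))


def simulate_genome(config: SimConfig) -> GenomeBundle:
    """Build scaffolds with planted intact / solo / truncated elements.

    Elements are placed uniformly (scaffold chosen proportional to length)
    subject to the region-class bias weights and a minimum gap of
    ``min_element_gap`` between planted elements, so no planted internal
    domain sits inside another element's classification flank window.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = _scaffold_lengths(config, rng)
    scaffold_names = list(lengths)
    backgrounds = {n: rng.integers(0, 4, size=lengths[n], dtype=np.uint8) for n in scaffold_names}

    regions, weights = simulate_regions(lengths, config, rng)
    lookup = _RegionLookup(regions)
    wmax = max(list(weights.values()) + [1.0])

    # family reference sequences
    families = []
    for f in range(config.n_families):
        families.append(
            {
                "family": f"fam_{f + 1}",
                "superfamily": "Copia" if f % 2 == 0 else "Gypsy",
                "ltr": random_seq(config.ltr_length, rng),
                "internal": random_seq(config.internal_length, rng),
            }
        )

    tsd_of = lambda: random_seq(config.tsd_length, rng)  # noqa: E731
    frag_len = int(round(config.truncated_internal_fraction * config.internal_length))

    specs = []
    div_intact = _draw_divergences(config, config.n_intact, rng)
    for i in range(config.n_intact):
        fam = families[i % config.n_families]
        p, q = div_intact[i]
        tsd = tsd_of()
        ltr5 = fam["ltr"]
        ltr3 = mutate_sequence(ltr5, p, q, rng)
        seq = tsd + ltr5 + fam["internal"] + ltr3 + tsd
        t = config.tsd_length
        L, Li = config.ltr_length, config.internal_length
        parts = [
            ("LTR5", t, t + L),
            ("internal", t + L, t + L + Li),
            ("LTR3", t + L + Li, t + 2 * L + Li),
        ]
        specs.append(dict(status="intact", fam=fam, seq=seq, parts=parts, p=p, q=q))
    div_solo = _draw_divergences(config, config.n_solo, rng)
    for i in range(config.n_solo):
        fam = families[i % config.n_families]
        p, q = div_solo[i]
        tsd = tsd_of()
        ltr = mutate_sequence(fam["ltr"], p, q, rng)
        seq = tsd + ltr + tsd
        t = config.tsd_length
        specs.append(
            dict(status="solo", fam=fam, seq=seq,
                 parts=[("LTR", t, t + config.ltr_length)], p=p, q=q)
        )
    div_trunc = _draw_divergences(config, config.n_truncated, rng)
    for i in range(config.n_truncated):
        fam = families[i % config.n_families]
        p, q = div_trunc[i]
        tsd = tsd_of()
        ltr = mutate_sequence(fam["ltr"], p, q, rng)
        seq = tsd + ltr + fam["internal"][:frag_len]
        t = config.tsd_length
        L = config.ltr_length
        parts = [("LTR", t, t + L), ("internal", t + L, t + L + frag_len)]
        specs.append(dict(status="truncated", fam=fam, seq=seq, parts=parts, p=p, q=q))

    total_len = sum(lengths.values())
    footprint = sum(len(s["seq"]) + config.min_element_gap for s in specs)
    if footprint > 0.8 * total_len:
        raise CapacityError(
            f"requested elements need ~{footprint} bp of spaced sequence but "
            f"scaffolds total {total_len} bp"
        )

    name_arr = np.array(scaffold_names)
    len_arr = np.array([lengths[n] for n in scaffold_names], dtype=float)
    probs = len_arr / len_arr.sum()
    placed = {n: [] for n in scaffold_names}  # sorted (start, end) per scaffold
    order = rng.permutation(len(specs))
    placements = [None] * len(specs)
    budget = 2_000 * max(len(specs), 1)
    for idx in order:
        spec = specs[idx]
        elen = len(spec["seq"])
        ok = False
        while budget > 0:
            budget -= 1
            sc = str(name_arr[rng.choice(len(name_arr), p=probs)])
            L = lengths[sc]
            if L < elen:
                continue
            start = int(rng.integers(0, L - elen + 1))
            cls = lookup.cls_at(sc, start + elen // 2)
            w = weights.get(cls, 1.0) if cls is not None else 1.0
            if w < wmax and rng.random() * wmax >= w:
                continue
            occ = placed[sc]
            j = bisect.bisect_left(occ, (start, start + elen))
            lo_ok = j == 0 or occ[j - 1][1] + config.min_element_gap <= start
            hi_ok = j == len(occ) or start + elen + config.min_element_gap <= occ[j][0]
            if lo_ok and hi_ok:
                occ.insert(j, (start, start + elen))
                placements[idx] = (sc, start)
                ok = True
                break
        if not ok:
            raise CapacityError(
                "could not place all elements under the gap/bias constraints; "
                "increase scaffold lengths or reduce element counts"
            )

    # write element sequences into the backgrounds and assemble tables
    truth_rows = []
    part_rows = []
    for i, spec in enumerate(specs):
        sc, start = placements[i]
        elen = len(spec["seq"])
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        seq = revcomp(spec["seq"]) if strand == "-" else spec["seq"]
        backgrounds[sc][start : start + elen] = encode(seq)
        eid = f"LTRRT_{i + 1:04d}"
        cls = lookup.cls_at(sc, start + elen // 2)
        truth_rows.append(
            dict(
                element_id=eid,
                scaffold=sc,
                start=start,
                end=start + elen,
                strand=strand,
                status=spec["status"],
                family=spec["fam"]["family"],
                superfamily=spec["fam"]["superfamily"],
                p_planted=spec["p"],
                q_planted=spec["q"],
                region_cls=cls if cls is not None else "none",
            )
        )
        for part, a, b in spec["parts"]:
            if strand == "+":
                gs, ge = start + a, start + b
            else:
                gs, ge = start + elen - b, start + elen - a
            part_rows.append(
                dict(
                    element_id=eid,
                    scaffold=sc,
                    start=gs,
                    end=ge,
                    strand=strand,
                    family=spec["fam"]["family"],
                    superfamily=spec["fam"]["superfamily"],
                    part=part,
                    status=spec["status"],
                )
            )

    truth_df = pd.DataFrame(truth_rows).sort_values(
        ["scaffold", "start"], kind="stable"
    ).reset_index(drop=True)
    parts_df = pd.DataFrame(part_rows).sort_values(
        ["scaffold", "start"], kind="stable"
    ).reset_index(drop=True)
    scaffolds = {n: decode(backgrounds[n]) for n in scaffold_names}
    truth = TruthTable(elements=truth_df, regions=regions)
    return GenomeBundle(
        config=config,
        scaffolds=scaffolds,
        elements=parts_df,
        regions=regions,
        truth=truth,
    )


def simulate_gene_set(config: SimConfig, seed=None, regions: Optional[pd.DataFrame] = None):
    """Plant gene arrays with TD/PD duplicate pairs and pseudogene candidates.

    Genes are laid out in order along a dedicated gene scaffold; homolog
    pairs are planted adjacent (TD truth), separated by 1-10 genes (PD
    truth) or by more than 10 (neither).  Pseudogene candidates carry
    identity/coverage values straddling the 30% / 50% filter thresholds,
    including exact-boundary cases.  Returns ``(genes, pairs, pseudogenes)``
    where ``genes`` includes the truth columns ``region_cls`` and ``rank``.
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    n = config.gene_count
    pitch = config.gene_length + config.gene_spacing
    lookup = _RegionLookup(regions) if regions is not None else None
    rows = []
    for i in range(n):
        start = i * pitch
        if lookup is not None:
            cls = lookup.cls_at("gene_scaffold_1", start + config.gene_length // 2)
            cls = cls if cls is not None else "none"
        else:
            cls = "SPE" if rng.random() < 0.5 else "SYN"
        rows.append(
            dict(
                gene_id=f"GENE_{i + 1:04d}",
                scaffold="gene_scaffold_1",
                start=start,
                end=start + config.gene_length,
                strand="+" if rng.random() < 0.5 else "-",
                rank=i + 1,
                region_cls=cls,
            )
        )
    genes = pd.DataFrame(rows)

    # pick non-colliding anchor indices; each cluster consumes <= 17 ranks
    need = config.td_clusters + config.pd_clusters + config.none_pairs
    span = 20
    if need * span > n:
        raise ParameterError(
            f"gene_count={n} too small for {need} planted pairs (need >= {need * span})"
        )
    anchors = rng.permutation(n // span)[:need] * span
    pair_rows = []
    k = 0
    for _ in range(config.td_clusters):
        a = int(anchors[k]); k += 1
        pair_rows.append((a, a + 1, "TD", 0))
    for j in range(config.pd_clusters):
        a = int(anchors[k]); k += 1
        intervening = 10 if j == 0 else int(rng.integers(1, 11))
        pair_rows.append((a, a + intervening + 1, "PD", intervening))
    for j in range(config.none_pairs):
        a = int(anchors[k]); k += 1
        intervening = 11 if j == 0 else int(rng.integers(11, 16))
        pair_rows.append((a, a + intervening + 1, "none", intervening))
    pairs = pd.DataFrame(
        [
            dict(
                gene_a=genes.iloc[a]["gene_id"],
                gene_b=genes.iloc[b]["gene_id"],
                dup_type=t,
                intervening=iv,
            )
            for a, b, t, iv in pair_rows
        ]
    )

    psg_rows = []
    for i in range(config.pseudogene_count):
        parent = genes.iloc[int(rng.integers(0, n))]["gene_id"]
        if i == 0:
            ident, cov, kept = 30.0, 90.0, False  # exact identity boundary
        elif i == 1:
            ident, cov, kept = 80.0, 50.0, False  # exact coverage boundary
        elif i == 2:
            ident, cov, kept = 31.0, 51.0, True  # just inside both
        else:
            kept = bool(rng.random() < 0.5)
            if kept:
                ident = float(rng.uniform(35, 95))
                cov = float(rng.uniform(55, 100))
            elif rng.random() < 0.5:
                ident = float(rng.uniform(5, 28))
                cov = float(rng.uniform(55, 100))
            else:
                ident = float(rng.uniform(35, 95))
                cov = float(rng.uniform(5, 48))
        start = int(rng.integers(0, n * pitch))
        psg_rows.append(
            dict(
                pseudo_id=f"PSG_{i + 1:03d}",
                scaffold="gene_scaffold_1",
                start=start,
                end=start + 500,
                parent_id=parent,
                identity=round(ident, 2),
                parent_coverage=round(cov, 2),
                kept_truth=kept,
            )
        )
    pseudogenes = pd.DataFrame(psg_rows) if psg_rows else pd.DataFrame(
        columns=["pseudo_id", "scaffold", "start", "end", "parent_id",
                 "identity", "parent_coverage", "kept_truth"]
    )
    return genes, pairs, pseudogenes


def simulate_expression(
    genes: pd.DataFrame,
    effect: float = 0.0,
    stages: int = 5,
    seed=0,
    baseline_log2: float = 6.0,
    sd_log2: float = 1.5,
) -> pd.DataFrame:
    """Stage-wise log-normal expression with an SPE-resident offset.

    log2 expression for gene g at any stage is N(baseline + effect * 1[g in
    SPE], sd); returned values are on the linear (TPM-like) scale with one
    column per stage.
    """
    if stages < 1:
        raise ParameterError("stages must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    is_spe = (genes["region_cls"] == "SPE").to_numpy()
    mu = baseline_log2 + effect * is_spe.astype(float)
    z = rng.normal(loc=mu[:, None], scale=sd_log2, size=(len(genes), stages))
    expr = pd.DataFrame(
        np.power(2.0, z),
        columns=[f"stage_{s + 1}" for s in range(stages)],
    )
    expr.insert(0, "gene_id", genes["gene_id"].to_numpy())
    return expr


def simulate_bundle(config: SimConfig) -> GenomeBundle:
    """Full study bundle: genome + regions + genes + pairs + expression.

    Child random streams are derived deterministically from ``config.seed``
    so the whole bundle is byte-reproducible.
    """
    bundle = simulate_genome(config)
    gene_rng = np.random.default_rng([config.seed, 1])
    genes, pairs, pseudogenes = simulate_gene_set(config, seed=gene_rng)
    expr_rng = np.random.default_rng([config.seed, 2])
    expression = simulate_expression(
        genes,
        effect=config.expression_effect,
        stages=config.n_stages,
        seed=expr_rng,
        baseline_log2=config.expression_baseline_log2,
        sd_log2=config.expression_sd_log2,
    )
    bundle.genes = genes
    bundle.pairs = pairs
    bundle.pseudogenes = pseudogenes
    bundle.expression = expression
    bundle.truth.genes = genes
    bundle.truth.pairs = pairs
    bundle.truth.pseudogenes = pseudogenes
    return bundle


def config_with(config: SimConfig, **overrides) -> SimConfig:
    """Return a copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
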