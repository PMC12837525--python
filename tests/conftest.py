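import numpy as np
import pytest

from ltrscape import census, simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimConfig(
        n_scaffolds=4,
        scaffold_length_min=40_000,
        scaffold_length_max=120_000,
        n_intact=6,
        n_solo=12,
        n_truncated=4,
        n_families=3,
        gene_count=300,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate.simulate_bundle(small_config)


@pytest.fixture(scope="session")
def small_loci(small_bundle):
    loci, unreconciled = census.classify_genome(
        small_bundle.scaffolds, small_bundle.intact_annotation()
    )
    assert not unreconciled
    return loci


def match_truth(truth, loci):
    """Count planted elements recovered with the correct status.

    A planted element counts as recovered when a classified locus overlaps
    its interval and carries the planted status.
    """
    frame = census.loci_to_frame(loci)
    hits = 0
    for t in truth.itertuples():
        sub = frame[
            (frame.scaffold == t.scaffold)
            & (frame.start < t.end)
            & (frame.end > t.start)
        ]
        if len(sub) and (sub["status"] == t.status).any():
            hits += 1
    return hits


def smith_waterman_present(query, subject, min_identity=0.8, min_length=100,
                           match=1, mismatch=-2, gap=-3):
    """Exhaustive local-alignment oracle: is there a homology of the
    required strength anywhere in the subject?

    Full Smith-Waterman matrix with linear gaps, both strands; homology is
    deemed present when the best local score reaches the score of a
    minimally acceptable hit (min_length columns at min_identity).
    """
    from ltrscape._seq import revcomp

    return any(
        _sw_present_forward(q, subject, min_identity, min_length, match, mismatch, gap)
        for q in (query, revcomp(query))
    )


def _sw_present_forward(query, subject, min_identity, min_length, match, mismatch, gap):
    from ltrscape._seq import encode

    q = encode(query)
    s = encode(subject)
    n, m = len(q), len(s)
    threshold = min_length * (min_identity * match + (1 - min_identity) * mismatch)
    prev = np.zeros(m + 1)
    best = 0.0
    for i in range(1, n + 1):
        sub = np.where(s == q[i - 1], float(match), float(mismatch))
        cur = np.empty(m + 1)
        cur[0] = 0.0
        diag = prev[:m] + sub
        up = prev[1:] + gap
        base = np.maximum(np.maximum(diag, up), 0.0)
        # left moves via prefix scan: cur[j] = max(base[j], max_k<j base[k] + (j-k) gap)
        js = np.arange(1, m + 1, dtype=float)
        run = np.maximum.accumulate(base - gap * js) + gap * js
        cur[1:] = np.maximum(base, run)
        best = max(best, float(cur.max()))
        prev = cur
        if best >= threshold:
            return True
    return best >= threshold
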