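"""Shared test fixtures/oracles, independent of the library code paths
they check."""

import numpy as np

from lungdens import PatientRecord


def make_binary_cohort(a, b, c, d, variable="heavy_smoker"):
    """Cohort whose (outcome, variable) cross-tabulation is (a,b,c,d):
    a exposed cases, b unexposed cases, c exposed controls, d unexposed
    controls."""
    records = []
    i = 0
    for outcome, exposed, n in [(1, 1, a), (1, 0, b), (0, 1, c), (0, 0, d)]:
        for _ in range(n):
            i += 1
            kw = dict(id=f"p{i:04d}", outcome=outcome, age=60.0,
                      heavy_smoker=0, ex_or_current_smoker=0, cea=1.0,
                      ca125=8.0, ca199=9.0, other_nodules=0,
                      focal_fibrosis=0, bulla=0, dist1_indicator=0,
                      dist2_indicator=0)
            kw[variable] = exposed
            records.append(PatientRecord(**kw))
    return records


def brute_force_counts(values, scheme):
    """Independent per-voxel tally with explicit half-open bin logic."""
    counts = np.zeros(scheme.n_bins, dtype=int)
    edges = scheme.bin_edges
    for v in values:
        for i in range(scheme.n_bins):
            lo, hi = edges[i], edges[i + 1]
            last = i == scheme.n_bins - 1
            if (lo <= v < hi) or (last and v == hi):
                counts[i] += 1
                break
    return counts


def brute_force_auc(y, scores):
    """Exhaustive pairwise concordance (ties count one half)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
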