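import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


# ---------------------------------------------------------------------------
# independent oracles shared across test modules
# ---------------------------------------------------------------------------

def brute_union_length(intervals, length):
    """Interval-union length by per-base marking (oracle)."""
    marked = [False] * length
    for s, e in intervals:
        for i in range(s, e):
            marked[i] = True
    return sum(marked)


def brute_levenshtein(a, b):
    """Full dynamic-programming edit distance (oracle)."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[n]


def brute_tandem_runs(seq, max_period, min_copies, min_len):
    """O(L^2 p) exact tandem-run scan (oracle).

    Returns the set of (start, end, minimal period) of maximal exact tandem
    regions meeting the thresholds, reported at the minimal period only.
    """
    found = set()
    n = len(seq)
    for p in range(1, max_period + 1):
        start = None
        for x in range(p, n + 1):
            ok = x < n and seq[x] == seq[x - p]
            if ok and start is None:
                start = x - p
            if not ok and start is not None:
                region = seq[start:x]
                q = _min_period(region)
                if (
                    q == p
                    and "N" not in region
                    and len(region) / p >= min_copies
                    and len(region) >= min_len
                ):
                    found.add((start, x, p))
                start = None
    return found


def _min_period(region):
    for q in range(1, len(region) + 1):
        if all(region[i] == region[i - q] for i in range(q, len(region))):
            return q
    return len(region)
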