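"""Independent brute-force reference for winnowing, used only by tests.

Re-derives everything from first principles: Pearson r via the raw formula
(scipy.stats.pearsonr where defined), and a collapse loop that re-scans all
surviving pairs from scratch every round.  Shares no code with the
production implementation.
"""

import itertools
import math

from scipy import stats


def pearson_brute(x, y):
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    den2 = (n * sxx - sx * sx) * (n * syy - sy * sy)
    if den2 <= 0:
        return 1.0 if list(x) == list(y) else None
    return (n * sxy - sx * sy) / math.sqrt(den2)


def pearson_scipy(x, y):
    if list(x) == list(y):
        return 1.0
    if len(set(x)) == 1 or len(set(y)) == 1:
        return None
    return float(stats.pearsonr(x, y).statistic)


def winnow_rescan(profiles, r_threshold=0.8):
    """Greedy winnow re-scanning every pair each round.

    ``profiles``: dict contig_id -> tuple of counts.  Returns
    (survivor ids sorted, ledger list of (dropped, kept, r)).
    """
    active = sorted(profiles)
    ledger = []
    while True:
        best = None
        for a, b in itertools.combinations(active, 2):
            r = pearson_brute(profiles[a], profiles[b])
            if r is None or r < r_threshold:
                continue
            combined = sum(profiles[a]) + sum(profiles[b])
            key = (r, combined)
            if best is None or key > best[0] or (key == best[0] and (a, b) < best[1]):
                best = (key, (a, b))
        if best is None:
            return active, ledger
        (r, _), (a, b) = best
        ta, tb = sum(profiles[a]), sum(profiles[b])
        if ta > tb or (ta == tb and a < b):
            keep, drop = a, b
        else:
            keep, drop = b, a
        ledger.append((drop, keep, r))
        active.remove(drop)
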