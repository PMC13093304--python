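"""Independent brute-force oracles, deliberately written as plain loops.

These re-derive the freeze-thaw event scan, the Mann-Kendall statistics,
the mean-rank percentile and the Shapley permutation average from their
definitions, sharing no code with the package implementation.
"""

from __future__ import annotations

import math
from itertools import permutations


def _code(v) -> str:
    """'f' frozen, 't' thawed, 'z' zero, 'm' missing."""
    if v is None or (isinstance(v, float) and v != v):
        return "m"
    if v < 0:
        return "f"
    if v > 0:
        return "t"
    return "z"


def oracle_detect(values, freeze_min: int = 5, thaw_min: int = 5):
    """Explicit state-machine scan over a daily temperature list.

    Returns (freeze_start, freeze_end, thaw_end, frozen_days) index tuples.
    Soil freezes after freeze_min consecutive sub-zero days and stays frozen
    (through shorter warm interludes and zero days) until thaw_min
    consecutive above-zero days; a missing day aborts an unconfirmed event.
    """
    codes = [_code(v) for v in values]
    n = len(codes)
    events = []
    i = 0
    while i < n:
        if codes[i] != "f":
            i += 1
            continue
        j = i
        while j < n and codes[j] == "f":
            j += 1
        if j - i < freeze_min:
            i = j
            continue
        freeze_start, freeze_end, frozen = i, j - 1, j - i
        k = j
        thaw_end = None
        aborted_at = None
        while k < n:
            c = codes[k]
            if c == "f":
                m = k
                while m < n and codes[m] == "f":
                    m += 1
                freeze_end = m - 1
                frozen += m - k
                k = m
            elif c == "t":
                m = k
                while m < n and codes[m] == "t":
                    m += 1
                if m - k >= thaw_min:
                    thaw_end = k + thaw_min - 1
                    break
                k = m
            elif c == "z":
                k += 1
            else:
                aborted_at = k
                break
        if thaw_end is not None:
            events.append((freeze_start, freeze_end, thaw_end, frozen))
            i = thaw_end + 1
        elif aborted_at is not None:
            i = aborted_at + 1
        else:
            i = n
    return events


def oracle_mann_kendall(x):
    """O(n^2) pair enumeration for S, tie-group loop for var(S), then z."""
    x = [float(v) for v in x]
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] > x[i]:
                s += 1
            elif x[j] < x[i]:
                s -= 1
    counts = {}
    for v in x:
        counts[v] = counts.get(v, 0) + 1
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in counts.values() if t > 1)
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if s > 0:
        z = (s - 1) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / math.sqrt(var_s)
    else:
        z = 0.0
    return s, var_s, z


def oracle_percentile(record, value) -> float:
    less = sum(1 for v in record if v < value)
    equal = sum(1 for v in record if v == value)
    return 100.0 * (less + 0.5 * equal) / len(record)


def oracle_permutation_shapley(predict_fn, background, instance, players):
    """Shapley values as the average marginal contribution over all n!
    feature orderings, with the interventional coalition value recomputed
    here from scratch."""
    names = list(players)
    n = len(names)

    def value(coalition: frozenset) -> float:
        X = background.copy()
        for name in coalition:
            for col in players[name]:
                X[col] = instance[col]
        return float(predict_fn(X).mean())

    cache: dict[frozenset, float] = {}

    def v(coalition: frozenset) -> float:
        if coalition not in cache:
            cache[coalition] = value(coalition)
        return cache[coalition]

    phi = {name: 0.0 for name in names}
    total = math.factorial(n)
    for order in permutations(names):
        so_far: frozenset = frozenset()
        for name in order:
            with_i = so_far | {name}
            phi[name] += (v(with_i) - v(so_far)) / total
            so_far = with_i
    return phi
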