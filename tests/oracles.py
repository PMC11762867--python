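"""Independent brute-force oracles used by the test suite.

Deliberately simple and slow: these enumerate rather than mirror the
production algorithms.
"""

from __future__ import annotations


def bruteforce_apportion(percentages: list[float], total: int) -> list[int]:
    """Enumerate every integer allocation of ``total`` over the categories
    and return the one minimizing the maximum absolute deviation from the
    exact shares (percent-of-total), breaking ties by minimum total
    deviation and then by preferring larger counts for earlier categories.

    Exhaustive search with exact pruning on the running max deviation.
    """
    shares = [p / 100.0 * total for p in percentages]
    n = len(shares)
    best_key: tuple | None = None
    best_alloc: list[int] | None = None
    counts = [0] * n

    def leaf_key(alloc: list[int]) -> tuple:
        devs = [abs(c - s) for c, s in zip(alloc, shares)]
        return (
            round(max(devs), 9),
            round(sum(devs), 9),
            tuple(-c for c in alloc),
        )

    def rec(i: int, remaining: int, running_max: float) -> None:
        nonlocal best_key, best_alloc
        if i == n - 1:
            counts[i] = remaining
            key = leaf_key(counts)
            if best_key is None or key < best_key:
                best_key = key
                best_alloc = counts.copy()
            return
        # try candidate counts nearest the exact share first so pruning
        # kicks in immediately
        for c in sorted(range(remaining + 1), key=lambda c: abs(c - shares[i])):
            dev = abs(c - shares[i])
            if best_key is not None and round(dev, 9) > best_key[0]:
                break  # every later candidate deviates even more
            counts[i] = c
            rec(i + 1, remaining - c, max(running_max, dev))

    rec(0, total, 0.0)
    assert best_alloc is not None
    return best_alloc


def naive_relative_counts(percentage: float, total: int) -> int:
    """Round a single percentage of a total, half away from zero."""
    exact = percentage / 100.0 * total
    return int(exact + 0.5)
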