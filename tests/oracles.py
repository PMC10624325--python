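"""Independent brute-force oracles for the diversity statistics.

These deliberately avoid the vectorised implementations in maitrep.stats:
Simpson clonality is computed by literally enumerating unordered cell
pairs, Morisita overlap by a plain-Python evaluation over the clone union.
"""

from __future__ import annotations

from itertools import combinations


def simpson_pair_enumeration(counts: list[int]) -> float:
    """Probability that two distinct cells share a clone, by exhaustive
    enumeration of all C(N,2) unordered cell pairs."""
    labels = [i for i, n in enumerate(counts) for _ in range(n)]
    pairs = list(combinations(range(len(labels)), 2))
    same = sum(1 for a, b in pairs if labels[a] == labels[b])
    return same / len(pairs)


def morisita_horn_bruteforce(a: dict[str, int], b: dict[str, int]) -> float:
    """Morisita-Horn index evaluated term by term over the clone union."""
    total_a = sum(a.values())
    total_b = sum(b.values())
    cross = pp = qq = 0.0
    for key in set(a) | set(b):
        p = a.get(key, 0) / total_a
        q = b.get(key, 0) / total_b
        cross += p * q
        pp += p * p
        qq += q * q
    return 2.0 * cross / (pp + qq)
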