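"""Brute-force Jonckheere-Terpstra oracle, independent of the package.

The statistic is counted with a naive double loop and the exact null
distribution is built by enumerating every *distinct* permutation of the
pooled values split into the observed group sizes — distinct multiset
permutations are equally likely under the null. Intentionally slow and
simple; used only to check the fast implementation on tiny inputs.
"""

from itertools import permutations


def naive_jt(groups) -> float:
    j = 0.0
    for k in range(len(groups)):
        for l in range(k + 1, len(groups)):
            for x in groups[k]:
                for y in groups[l]:
                    if x < y:
                        j += 1.0
                    elif x == y:
                        j += 0.5
    return j


def exact_null_distribution(groups) -> list[float]:
    pooled = tuple(v for g in groups for v in g)
    sizes = [len(g) for g in groups]
    stats = []
    for perm in set(permutations(pooled)):
        split, start = [], 0
        for s in sizes:
            split.append(perm[start: start + s])
            start += s
        stats.append(naive_jt(split))
    return stats


def exact_p(groups, alternative="increasing") -> float:
    obs = naive_jt(groups)
    null = exact_null_distribution(groups)
    tol = 1e-9
    p_ge = sum(s >= obs - tol for s in null) / len(null)
    p_le = sum(s <= obs + tol for s in null) / len(null)
    if alternative == "increasing":
        return p_ge
    if alternative == "decreasing":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))
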