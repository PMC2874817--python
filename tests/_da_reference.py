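"""Independent brute-force reference for architecture-conservation scores.

Kept free of any import from the package's domain_architecture module so it
can serve as an oracle: the three indices are recomputed from first
principles with plain set/loop code.
"""

import itertools


def reference_da_score(a: list[str], b: list[str]) -> float:
    set_a, set_b = set(a), set(b)
    if not set_a and not set_b:
        return 1.0
    shared = set_a & set_b
    if not shared:
        return 0.0
    jac = len(shared) / len(set_a | set_b)

    first_a = {d: a.index(d) for d in shared}
    first_b = {d: b.index(d) for d in shared}
    conc = disc = 0
    for d1, d2 in itertools.combinations(sorted(shared), 2):
        if (first_a[d1] - first_a[d2]) * (first_b[d1] - first_b[d2]) > 0:
            conc += 1
        else:
            disc += 1
    gamma = 1.0 if conc + disc == 0 else ((conc - disc) / (conc + disc) + 1) / 2

    mins = sum(min(a.count(d), b.count(d)) for d in shared)
    maxs = sum(max(a.count(d), b.count(d)) for d in shared)
    dup = mins / maxs
    return (jac + gamma + dup) / 3.0


def enumerate_architectures(max_distinct=4, max_copies=3, max_length=6):
    """Every copy-count multiset over up to four domain types, each laid
    out in several distinct orders (sorted, reversed, interleaved)."""
    pool = ["A", "B", "C", "D"][:max_distinct]
    archs = {()}
    for counts in itertools.product(range(max_copies + 1), repeat=len(pool)):
        if sum(counts) == 0 or sum(counts) > max_length:
            continue
        multiset = []
        for d, c in zip(pool, counts):
            multiset += [d] * c
        orders = {tuple(multiset), tuple(reversed(multiset))}
        present = [d for d, c in zip(pool, counts) if c]
        remaining = {d: c for d, c in zip(pool, counts)}
        inter = []
        while any(remaining.values()):
            for d in present:
                if remaining[d]:
                    inter.append(d)
                    remaining[d] -= 1
        orders.add(tuple(inter))
        archs |= orders
    return [list(t) for t in sorted(archs)]
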