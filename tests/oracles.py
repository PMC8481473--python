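"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: connected components
via union-find instead of BFS/sparse machinery, Fisher p by exhaustive
hypergeometric enumeration instead of scipy, consistency tallies by a
hand-rolled vote recount.
"""

from math import comb


def lcc_union_find(nodes, edges):
    """Largest-component size over ``nodes`` using plain union-find on the
    edges internal to the node set."""
    nodes = list(nodes)
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    keep = set(nodes)
    for u, v in edges:
        if u in keep and v in keep and u != v:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    sizes = {}
    for n in nodes:
        root = find(n)
        sizes[root] = sizes.get(root, 0) + 1
    return max(sizes.values()) if sizes else 0


def fisher_two_sided_enum(a, b, c, d):
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    return sum(p for x in range(0, c1 + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9))


def fisher_greater_enum(a, b, c, d):
    """One-sided (overrepresentation) Fisher p: upper hypergeometric tail."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    return sum(prob(x) for x in range(a, c1 + 1))
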