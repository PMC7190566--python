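"""Independent brute-force oracles for the agreement statistics.

Deliberately naive (explicit loops, direct textbook formulas) and independent
of the package implementation, so tests compare two distinct routes to the
same quantity.
"""

from collections import Counter


def naive_fleiss_kappa(counts):
    """Fleiss kappa from an objects x categories count table, by the book."""
    counts = [list(map(int, row)) for row in counts]
    big_n = len(counts)
    n = sum(counts[0])
    # per-object agreement
    p_i = []
    for row in counts:
        assert sum(row) == n
        p_i.append((sum(v * v for v in row) - n) / (n * (n - 1)))
    p_bar = sum(p_i) / big_n
    # category marginals
    p_j = [sum(row[j] for row in counts) / (big_n * n)
           for j in range(len(counts[0]))]
    p_e = sum(p * p for p in p_j)
    if p_bar == 1.0:
        return 1.0
    return (p_bar - p_e) / (1.0 - p_e)


def naive_cohen_kappa(a, b):
    """Cohen kappa via an explicit contingency table."""
    a, b = list(a), list(b)
    assert len(a) == len(b) and len(a) > 0
    n = len(a)
    cats = sorted(set(a) | set(b), key=str)
    table = {(x, y): 0 for x in cats for y in cats}
    for x, y in zip(a, b):
        table[(x, y)] += 1
    p_o = sum(table[(c, c)] for c in cats) / n
    row = Counter(a)
    col = Counter(b)
    p_e = sum((row[c] / n) * (col[c] / n) for c in cats)
    if p_o == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def random_count_matrix(rng, n_objects, n_raters, n_cats=3):
    """Random complete vote-count table with constant row sum."""
    rows = []
    for _ in range(n_objects):
        draws = rng.integers(0, n_cats, size=n_raters)
        rows.append([int((draws == j).sum()) for j in range(n_cats)])
    return rows
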