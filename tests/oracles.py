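"""Independent reference implementations used to cross-check the package.

Everything here is deliberately brute-force (path enumeration, exact
combinatorics with fractions, scipy's studentized-range distribution) and
shares no code with the implementations under test.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
from scipy.stats import studentized_range


def all_ancestor_paths(parents: dict[str, list[str]], node: str):
    """Every parent-edge path from ``node`` up to some root (inclusive)."""
    paths = []

    def walk(current, acc):
        acc = acc + [current]
        ps = parents.get(current, [])
        if not ps:
            paths.append(acc)
            return
        for p in ps:
            walk(p, acc)

    walk(node, [])
    return paths


def brute_ancestors(parents: dict[str, list[str]], node: str) -> set[str]:
    out = set()
    for path in all_ancestor_paths(parents, node):
        out.update(path)
    return out


def brute_level(parents: dict[str, list[str]], node: str) -> int:
    return min(len(path) - 1 for path in all_ancestor_paths(parents, node))


def brute_closure(pairs, parents: dict[str, list[str]]):
    out = set()
    for gene, term in pairs:
        for anc in brute_ancestors(parents, term):
            out.add((gene, anc))
    return out


def hypergeom_tail(a: int, universe: int, annotated: int, significant: int) -> float:
    """Exact P(X >= a) for X ~ Hypergeom(universe, annotated, significant)."""
    total = Fraction(0)
    denom = comb(universe, significant)
    hi = min(annotated, significant)
    for j in range(a, hi + 1):
        total += Fraction(comb(annotated, j) * comb(universe - annotated,
                                                    significant - j), denom)
    return float(total)


def fisher2x2_two_sided(table) -> float:
    """Full enumeration over 2x2 tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + Fraction(1, 10**9)):
            total += p
    return float(min(total, Fraction(1)))


def tukey_pairwise_p(groups: list[np.ndarray]):
    """Tukey HSD adjusted p per pair via scipy's studentized range.

    Returns {(i, j): p} for i < j over group indices, using the
    Tukey-Kramer standard error.
    """
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    df = n_total - k
    means = [g.mean() for g in groups]
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    mse = sse / df
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(mse * 0.5 * (1 / len(groups[i]) + 1 / len(groups[j])))
        q = abs(means[i] - means[j]) / se
        out[(i, j)] = float(studentized_range.sf(q, k, df))
    return out


def welch_t(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    return float((x.mean() - y.mean()) / np.sqrt(vx / len(x) + vy / len(y)))


def exhaustive_best_conjunctions(
    pairs: set[tuple[str, str]],
    universe: set[str],
    significant: set[str],
    parents: dict[str, list[str]],
    max_len: int = 2,
):
    """Best achievable ACC/AUC/F1 over all conjunctions of <= max_len terms.

    Coverage is computed directly from the closed (gene, term) pair set;
    redundant conjunctions (one term an ancestor of another) are excluded,
    matching the rule language.
    """
    terms = sorted({t for _, t in pairs})
    by_term = {t: {g for g, tt in pairs if tt == t} for t in terms}
    n_nonsig = len(universe) - len(significant)

    def scores(covered):
        tp = len(covered & significant)
        fp = len(covered) - tp
        fn = len(significant) - tp
        tn = len(universe) - tp - fp - fn
        acc = (tp + tn) / len(universe)
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        sens = tp / len(significant) if significant else 0.0
        spec = tn / n_nonsig if n_nonsig else 0.0
        return {"ACC": acc, "AUC": 0.5 * (sens + spec), "F1": f1}

    best = {"ACC": 0.0, "AUC": 0.0, "F1": 0.0}
    combos = [(t,) for t in terms]
    if max_len >= 2:
        for t1, t2 in itertools.combinations(terms, 2):
            if t1 in brute_ancestors(parents, t2):
                continue
            if t2 in brute_ancestors(parents, t1):
                continue
            combos.append((t1, t2))
    for combo in combos:
        covered = set(universe)
        for t in combo:
            covered &= by_term[t]
        s = scores(covered)
        for key in best:
            best[key] = max(best[key], s[key])
    return best
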