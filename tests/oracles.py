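"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives a pipeline quantity from first principles with a
different formulation than the implementation (direct formulas, exact
enumeration, exhaustive recursion), so agreement is a genuine check.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import combinations

from scipy import stats

# --- pooled two-sample t -------------------------------------------------

def pooled_t_oracle(x, y):
    """Textbook pooled-variance t and two-sided p, written longhand."""
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    ss1 = sum((v - m1) ** 2 for v in x)
    ss2 = sum((v - m2) ** 2 for v in y)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return t, p


# --- Pearson r and p -----------------------------------------------------

def pearson_oracle(x, y):
    """Direct product-moment formula plus the t-transform p."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    r = num / den
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * stats.t.sf(abs(t), df=n - 2)


# --- hypergeometric upper tail by exact enumeration ----------------------

def hypergeom_oracle(N, K, n, k):
    """P(X >= k) as a ratio of binomial-coefficient sums (exact integers)."""
    total = math.comb(N, n)
    hits = sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(k, min(K, n) + 1))
    return hits / total


def hypergeom_enumeration_oracle(N, K, n, k):
    """P(X >= k) by brute-force enumeration of every n-subset (tiny N only)."""
    universe = list(range(N))
    in_term = set(range(K))
    hits = sum(1 for draw in combinations(universe, n)
               if len(in_term.intersection(draw)) >= k)
    return hits / math.comb(N, n)


# --- exhaustive local duplex alignment -----------------------------------

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}


def best_local_score_oracle(mirna, target, scheme):
    """Maximum local alignment score over every start point and path.

    Top-down recursion over (reversed-miRNA index, target index, last
    move), maximising over all ways to extend or stop; the affine gap
    convention (first gap char = open, later = extend) matches the
    scoring model's definition.  Exhaustive for small inputs.
    """
    mr = mirna[::-1]
    L, T = len(mr), len(target)

    def col_score(i, j):
        m, t = mr[i], target[j]
        if _COMP[m] == t:
            s = scheme.match
        elif (m, t) in _WOBBLE:
            s = scheme.wobble
        else:
            s = scheme.mismatch
        pos = L - i  # 1-based 5'-anchored miRNA position
        if scheme.seed_start <= pos <= scheme.seed_end:
            s *= scheme.seed_weight
        return s

    @lru_cache(maxsize=None)
    def best_from(i, j, last):
        """Best score of any (possibly empty) alignment continuing at
        (i, j) given the previous column type ('d', 'gm', 'gt')."""
        options = [0.0]  # stop here
        if i < L and j < T:
            options.append(col_score(i, j) + best_from(i + 1, j + 1, "d"))
        if j < T:  # gap in miRNA, consume target
            cost = scheme.gap_extend if last == "gm" else scheme.gap_open
            options.append(cost + best_from(i, j + 1, "gm"))
        if i < L:  # gap in target, consume miRNA
            cost = scheme.gap_extend if last == "gt" else scheme.gap_open
            options.append(cost + best_from(i + 1, j, "gt"))
        return max(options)

    best = 0.0
    for i in range(L):
        for j in range(T):
            best = max(best, col_score(i, j) + best_from(i + 1, j + 1, "d"))
    return best


# --- triplet assembly by triple loop -------------------------------------

def assemble_oracle(strata, lnc_pairs, mrna_pairs, lnc_mrna_edges, stratum):
    """Triple loop applying the triplet predicate verbatim."""
    signs = {"UP": ("up", "down", "up"), "DOWN": ("down", "up", "down")}[stratum]
    lnc_ok = strata["lncRNA"][signs[0]]
    mir_ok = strata["miRNA"][signs[1]]
    mrna_ok = strata["mRNA"][signs[2]]
    lnc_pair_keys = {(p.mirna_id, p.target_id) for p, _ in lnc_pairs}
    mrna_pair_keys = {(p.mirna_id, p.target_id) for p, _ in mrna_pairs}
    edge_keys = {(e.a_id, e.b_id) for e in lnc_mrna_edges}
    out = set()
    for lnc in lnc_ok:
        for mir in mir_ok:
            for mrna in mrna_ok:
                if ((mir, lnc) in lnc_pair_keys and (mir, mrna) in mrna_pair_keys
                        and (lnc, mrna) in edge_keys):
                    out.add((lnc, mir, mrna))
    return out


# --- hub extraction by filter-and-induce ---------------------------------

def hub_oracle(triplets, threshold):
    """Triplets kept by the hub rule, computed from raw incidence counts."""
    edges = set()
    for t in triplets:
        edges.add((("lncRNA", t.lncrna_id), ("miRNA", t.mirna_id)))
        edges.add((("miRNA", t.mirna_id), ("mRNA", t.mrna_id)))
    degree: dict[tuple, int] = {}
    for a, b in edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    hubs = {fid for (cls, fid), d in degree.items() if cls == "lncRNA" and d > threshold}
    return {t.key() for t in triplets if t.lncrna_id in hubs}
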