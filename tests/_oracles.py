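"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorised code paths: plain dict
and loop arithmetic, so that agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


# ---------------------------------------------------------------------------
# MDR reference: naive cell labelling, fold evaluation and search
# ---------------------------------------------------------------------------

def naive_label_cells(genos, status, T):
    """Map genotype-combo -> 'high'/'low' from per-cell ratios (dict tally)."""
    cases = Counter()
    controls = Counter()
    for row, st in zip(genos, status):
        key = tuple(int(g) for g in row)
        if st == 1:
            cases[key] += 1
        else:
            controls[key] += 1
    n_cases = sum(cases.values())
    n_controls = sum(controls.values())
    labels = {}
    for key in set(cases) | set(controls):
        ca, co = cases[key], controls[key]
        if co == 0:
            labels[key] = "high" if ca > 0 else "low"
        else:
            ratio = (ca / n_cases) / (co / n_controls)
            labels[key] = "high" if ratio > T else "low"
    return labels


def naive_balanced_accuracy(genos, status, labels):
    tp = fn = tn = fp = 0
    for row, st in zip(genos, status):
        high = labels.get(tuple(int(g) for g in row), "low") == "high"
        if st == 1:
            tp += high
            fn += not high
        else:
            tn += not high
            fp += high
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return (sens + spec) / 2, sens, spec


def naive_search(genos, status, folds, snp_names, k_values, T):
    """Reference MDR search over given fold assignments.

    Returns {k: (modal_combo, consistency, mean_test_ba)} with the same
    winner rules as the engine: per-fold min training error, lexicographic
    tie-break, modal winner by count then order.
    """
    n_folds = max(folds) + 1
    out = {}
    for k in k_values:
        combos = list(itertools.combinations(range(len(snp_names)), k))
        winners = []
        fold_ba = {}
        for f in range(n_folds):
            tr = [i for i in range(len(status)) if folds[i] != f]
            te = [i for i in range(len(status)) if folds[i] == f]
            best, best_err = None, None
            for c in combos:
                g_tr = [[genos[i][j] for j in c] for i in tr]
                s_tr = [status[i] for i in tr]
                labels = naive_label_cells(g_tr, s_tr, T)
                ba, _, _ = naive_balanced_accuracy(g_tr, s_tr, labels)
                err = 1 - ba
                if best is None or err < best_err - 1e-15:
                    best, best_err = c, err
                g_te = [[genos[i][j] for j in c] for i in te]
                s_te = [status[i] for i in te]
                tba, _, _ = naive_balanced_accuracy(g_te, s_te, labels)
                fold_ba[(c, f)] = tba
            winners.append(best)
        counts = Counter(winners)
        modal = min(counts, key=lambda c: (-counts[c], c))
        mean_ba = sum(fold_ba[(modal, f)] for f in range(n_folds)) / n_folds
        out[k] = (
            tuple(snp_names[i] for i in modal),
            counts[modal],
            mean_ba,
        )
    return out


# ---------------------------------------------------------------------------
# entropy reference: triple-loop plug-in entropies
# ---------------------------------------------------------------------------

def _h(counter, n):
    h = 0.0
    for c in counter.values():
        p = c / n
        h -= p * math.log2(p)
    return h


def naive_mi_pct(a_codes, status):
    """100 * I(A;C) / H(C) from explicit joint tallies."""
    n = len(status)
    ha = _h(Counter(a_codes), n)
    hc = _h(Counter(status), n)
    hac = _h(Counter(zip(a_codes, status)), n)
    return 100.0 * (ha + hc - hac) / hc


def naive_ig_pct(a_codes, b_codes, status):
    joint = list(zip(a_codes, b_codes))
    return (
        naive_mi_pct(joint, status)
        - naive_mi_pct(list(a_codes), status)
        - naive_mi_pct(list(b_codes), status)
    )


# ---------------------------------------------------------------------------
# clustering reference: naive average linkage
# ---------------------------------------------------------------------------

def naive_average_linkage(names, dist):
    """Merge order of average-linkage agglomeration on a dict distance.

    ``dist`` maps frozenset({a, b}) -> dissimilarity. Returns a list of
    (merged_member_sets, height) in merge order.
    """
    clusters = [frozenset([n]) for n in names]
    merges = []
    while len(clusters) > 1:
        best = None
        for x, y in itertools.combinations(clusters, 2):
            d = sum(
                dist[frozenset([a, b])] for a in x for b in y
            ) / (len(x) * len(y))
            if best is None or d < best[0] - 1e-12:
                best = (d, x, y)
        d, x, y = best
        clusters.remove(x)
        clusters.remove(y)
        clusters.append(x | y)
        merges.append(({x, y}, d))
    return merges


# ---------------------------------------------------------------------------
# exact-test references
# ---------------------------------------------------------------------------

def enumerate_hwe_exact(n0, n1, n2):
    """Exact HWE p by direct summation over all heterozygote counts."""
    n = n0 + n1 + n2
    n_a = 2 * n0 + n1  # copies of one allele
    probs = {}
    for het in range(0, min(n_a, 2 * n - n_a) + 1):
        if (n_a - het) % 2:
            continue
        homa = (n_a - het) // 2
        homb = n - het - homa
        if homb < 0:
            continue
        logp = (
            het * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(het + 1)
            - math.lgamma(homa + 1)
            - math.lgamma(homb + 1)
        )
        probs[het] = logp
    mx = max(probs.values())
    total = sum(math.exp(v - mx) for v in probs.values())
    p_of = {k: math.exp(v - mx) / total for k, v in probs.items()}
    obs = p_of[n1]
    return min(1.0, sum(p for p in p_of.values() if p <= obs * (1 + 1e-9)))


def enumerate_fisher_2x3(counts):
    """Two-sided 2x3 Fisher p by exhaustive enumeration of tables."""
    row0 = sum(counts[0])
    col = [counts[0][j] + counts[1][j] for j in range(3)]
    n = row0 + sum(counts[1])

    def log_comb(a, b):
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    denom = log_comb(n, row0)

    def prob(x0, x1, x2):
        return math.exp(
            log_comb(col[0], x0) + log_comb(col[1], x1) + log_comb(col[2], x2) - denom
        )

    obs = prob(*counts[0])
    total = 0.0
    for x0 in range(0, min(col[0], row0) + 1):
        for x1 in range(0, min(col[1], row0 - x0) + 1):
            x2 = row0 - x0 - x1
            if 0 <= x2 <= col[2]:
                p = prob(x0, x1, x2)
                if p <= obs * (1 + 1e-9):
                    total += p
    return min(1.0, total)
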