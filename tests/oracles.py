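"""Naive, loop-based reference implementations used as independent oracles.

These deliberately avoid the package's vectorised code paths (and the
libraries standing behind them): explicit Python loops, explicit rank
assignment, explicit pair enumeration.  They are slow and only ever run on
tiny instances.
"""

import math


# ---------------------------------------------------------------------------
# patient weights: explicit if/elif chain over the 8 published bins
# ---------------------------------------------------------------------------

def naive_patient_weight(total):
    t = math.floor(total)
    if t <= 0:
        thr = 0.0
    elif t == 1:
        thr = 1.0
    elif t <= 3:
        thr = math.log(3)
    elif t <= 7:
        thr = math.log(7)
    elif t <= 20:
        thr = math.log(20)
    elif t <= 55:
        thr = math.log(55)
    elif t <= 148:
        thr = math.log(148)
    else:
        thr = 6.0
    return 2.0 ** thr


def naive_weighted_rmse(truth_terms, predicted_terms, patient_totals_per_term):
    """sqrt(sum w*d^2 / sum w) with d = ln(1+y) - ln(1+s), one loop pass.

    ``patient_totals_per_term`` carries, for every term, the ground-truth
    overall total of the patient the term belongs to.
    """
    num = 0.0
    den = 0.0
    for s, y, total in zip(truth_terms, predicted_terms, patient_totals_per_term):
        w = naive_patient_weight(total)
        d = math.log(1.0 + y) - math.log(1.0 + s)
        num += w * d * d
        den += w
    return math.sqrt(num / den)


# ---------------------------------------------------------------------------
# Spearman with midranks, via explicit rank assignment and Pearson loops
# ---------------------------------------------------------------------------

def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        midrank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    return ranks


def naive_spearman(a, b):
    ra, rb = _midranks(list(a)), _midranks(list(b))
    n = len(ra)
    ma = sum(ra) / n
    mb = sum(rb) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    va = sum((x - ma) ** 2 for x in ra)
    vb = sum((y - mb) ** 2 for y in rb)
    return cov / math.sqrt(va * vb)


# ---------------------------------------------------------------------------
# concordance index: pair enumeration; ties in `a` are non-comparable,
# ties only in `b` count half
# ---------------------------------------------------------------------------

def naive_concordance(a, b):
    concordant = 0.0
    comparable = 0
    n = len(a)
    for i in range(n):
        for j in range(i + 1, n):
            if a[i] == a[j]:
                continue
            comparable += 1
            if b[i] == b[j]:
                concordant += 0.5
            elif (a[i] < a[j]) == (b[i] < b[j]):
                concordant += 1.0
    return concordant / comparable


# ---------------------------------------------------------------------------
# bootstrap Bayes factor: explicit iteration counting, ties excluded
# ---------------------------------------------------------------------------

def naive_bayes_factor(ref_values, team_values):
    ref_wins = 0
    team_wins = 0
    for r, t in zip(ref_values, team_values):
        if r < t:
            ref_wins += 1
        elif t < r:
            team_wins += 1
    if ref_wins == 0 and team_wins == 0:
        return 1.0
    if team_wins == 0:
        return math.inf
    return ref_wins / team_wins


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up, by hand
# ---------------------------------------------------------------------------

def naive_bh(p_values):
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, p_values[i] * m / rank_from_end)
        q[i] = val
        prev = val
    return q


# ---------------------------------------------------------------------------
# inter-reader CV: per-pair sample SD over mean, averaged
# ---------------------------------------------------------------------------

def naive_reader_cv(a, b):
    cvs = []
    for x, y in zip(a, b):
        mean = (x + y) / 2.0
        if mean <= 0:
            continue
        sd = math.sqrt((x - mean) ** 2 + (y - mean) ** 2)  # ddof=1 for n=2
        cvs.append(sd / mean)
    return sum(cvs) / len(cvs)
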