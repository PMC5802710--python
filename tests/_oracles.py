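"""Independent brute-force oracles used to cross-check the package.

Everything here is written from first principles (pure Python / direct
numeric integration) and deliberately shares no code path with the
implementation under test.
"""

import math
from fractions import Fraction

import numpy as np
from scipy.integrate import quad


# -- goodness of fit --------------------------------------------------------

def gof_chi2_oracle(counts, proportions):
    """Pearson statistic as a literal sum over categories."""
    n = sum(counts)
    total = 0.0
    for obs, p in zip(counts, proportions):
        expected = n * p
        total += (obs - expected) ** 2 / expected
    return total


# -- chi-squared upper tail -------------------------------------------------

def chi2_sf_oracle(x, df):
    """Upper-tail probability by direct numeric integration of the
    hand-written chi-squared density."""

    def pdf(t):
        return (
            t ** (df / 2.0 - 1.0)
            * math.exp(-t / 2.0)
            / (2.0 ** (df / 2.0) * math.gamma(df / 2.0))
        )

    upper, _ = quad(pdf, x, np.inf, epsabs=1e-13, epsrel=1e-13)
    return upper


# -- CBC classification by direct enumeration -------------------------------

def cbc_oracle(control_values, subject_values, directions, q, k,
               inclusive=True):
    """Classify subjects by literally re-deriving nearest-rank cutoffs
    and counting deviant measures, all in exact arithmetic.

    Parameters
    ----------
    control_values : list of per-measure lists (control population)
    subject_values : list of per-animal lists (one value per measure)
    directions : list of "low"/"high" per measure
    """
    m = len(directions)
    q_exact = Fraction(q).limit_denominator(10**6)
    cutoffs = []
    for j in range(m):
        vals = sorted(control_values[j])
        n = len(vals)
        rank = -((-q_exact * n) // 1)  # ceil of an exact rational
        rank = int(min(max(int(rank), 1), n))
        if directions[j] == "low":
            cutoffs.append(vals[rank - 1])
        else:
            cutoffs.append(vals[n - rank])
    results = []
    for row in subject_values:
        hits = 0
        for j in range(m):
            v, c = row[j], cutoffs[j]
            if directions[j] == "low":
                hit = v <= c if inclusive else v < c
            else:
                hit = v >= c if inclusive else v > c
            hits += int(hit)
        results.append((hits, hits >= k))
    return cutoffs, results


# -- ANOVA sums of squares on balanced designs ------------------------------

def balanced_anova_oracle(y, a_labels, b_labels):
    """Two-way fixed-effects ANOVA for a balanced design by textbook
    sums of squares. Returns {effect: (ss, df, F)} plus the residual.

    Valid only when every (a, b) cell holds the same number of
    replicates (where Type I/II/III all coincide).
    """
    y = np.asarray(y, dtype=float)
    a_levels = sorted(set(a_labels))
    b_levels = sorted(set(b_labels))
    a_idx = {lvl: i for i, lvl in enumerate(a_levels)}
    b_idx = {lvl: i for i, lvl in enumerate(b_levels)}
    na, nb = len(a_levels), len(b_levels)
    cells = [[[] for _ in range(nb)] for _ in range(na)]
    for val, a, b in zip(y, a_labels, b_labels):
        cells[a_idx[a]][b_idx[b]].append(val)
    reps = {len(c) for row in cells for c in row}
    assert len(reps) == 1, "oracle requires a balanced design"
    r = reps.pop()

    grand = y.mean()
    cell_means = np.array([[np.mean(c) for c in row] for row in cells])
    a_means = cell_means.mean(axis=1)
    b_means = cell_means.mean(axis=0)

    ss_a = r * nb * float(((a_means - grand) ** 2).sum())
    ss_b = r * na * float(((b_means - grand) ** 2).sum())
    ss_ab = r * float(
        (
            (cell_means - a_means[:, None] - b_means[None, :] + grand) ** 2
        ).sum()
    )
    ss_e = float(
        sum(
            (val - cell_means[i][j]) ** 2
            for i, row in enumerate(cells)
            for j, c in enumerate(row)
            for val in c
        )
    )
    df_a, df_b = na - 1, nb - 1
    df_ab = df_a * df_b
    df_e = na * nb * (r - 1)
    mse = ss_e / df_e
    return {
        "a": (ss_a, df_a, (ss_a / df_a) / mse),
        "b": (ss_b, df_b, (ss_b / df_b) / mse),
        "ab": (ss_ab, df_ab, (ss_ab / df_ab) / mse),
        "residual": (ss_e, df_e, None),
    }


def oneway_f_oracle(groups):
    """Closed-form one-way ANOVA F from a list of per-group samples."""
    all_vals = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)
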