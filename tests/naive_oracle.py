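"""Independent naive-loop oracles for the posterior-moment machinery.

These follow the definitional summations step by step, with no
vectorization and no code shared with the package implementation, so
they can serve as an independent reference on small fixtures.
"""

import math


def naive_moments(counts, prior, codes, n_groups):
    """All moment quantities for an entities x samples count table.

    ``counts`` is a list of lists, ``prior`` a scalar, ``codes`` the group
    index per sample.  Returns a dict of plain Python structures.
    """
    m = len(counts)
    S = len(counts[0])
    alpha = [[counts[i][s] + prior for s in range(S)] for i in range(m)]
    atot = [sum(alpha[i][s] for i in range(m)) for s in range(S)]

    mean = [[alpha[i][s] / atot[s] for s in range(S)] for i in range(m)]
    var = [
        [
            alpha[i][s] * (atot[s] - alpha[i][s]) / (atot[s] ** 2 * (atot[s] + 1.0))
            for s in range(S)
        ]
        for i in range(m)
    ]

    members = [[s for s in range(S) if codes[s] == g] for g in range(n_groups)]
    group_mean = [
        [sum(mean[i][s] for s in members[g]) / len(members[g]) for g in range(n_groups)]
        for i in range(m)
    ]
    group_var = [
        [
            sum(var[i][s] for s in members[g]) / len(members[g]) ** 2
            for g in range(n_groups)
        ]
        for i in range(m)
    ]
    grand = [sum(group_mean[i]) / n_groups for i in range(m)]

    def pair_group_cov(i, j, g):
        # double sum over sample pairs; cross terms are zero by belief
        # independence and are written out explicitly to prove it
        total = 0.0
        for s in members[g]:
            for s2 in members[g]:
                if s == s2:
                    total += -alpha[i][s] * alpha[j][s] / (atot[s] ** 2 * (atot[s] + 1.0))
                else:
                    total += 0.0
        return total / len(members[g]) ** 2

    def total_var(i):
        cross = sum(
            (group_mean[i][g] - grand[i]) ** 2 for g in range(n_groups)
        ) / n_groups
        unc = sum(group_var[i][g] for g in range(n_groups)) / n_groups
        return cross + unc

    def total_cov(i, j, include_within):
        cross = sum(
            (group_mean[i][g] - grand[i]) * (group_mean[j][g] - grand[j])
            for g in range(n_groups)
        ) / n_groups
        if include_within:
            cross += sum(pair_group_cov(i, j, g) for g in range(n_groups)) / n_groups
        return cross

    def correlation(i, j, include_within):
        denom = math.sqrt(total_var(i) * total_var(j))
        return total_cov(i, j, include_within) / denom

    return {
        "alpha": alpha,
        "alpha_totals": atot,
        "mean": mean,
        "var": var,
        "group_mean": group_mean,
        "group_var": group_var,
        "grand_mean": grand,
        "pair_group_cov": pair_group_cov,
        "total_var": total_var,
        "total_cov": total_cov,
        "correlation": correlation,
    }


def naive_grouped_pearson(values, codes, n_groups):
    """Textbook grouped Pearson: correlate the n group-mean vectors."""
    m = len(values)
    members = [[s for s in range(len(codes)) if codes[s] == g] for g in range(n_groups)]
    gm = [
        [sum(values[i][s] for s in members[g]) / len(members[g]) for g in range(n_groups)]
        for i in range(m)
    ]

    def corr(i, j):
        mi = sum(gm[i]) / n_groups
        mj = sum(gm[j]) / n_groups
        num = sum((gm[i][g] - mi) * (gm[j][g] - mj) for g in range(n_groups))
        di = math.sqrt(sum((gm[i][g] - mi) ** 2 for g in range(n_groups)))
        dj = math.sqrt(sum((gm[j][g] - mj) ** 2 for g in range(n_groups)))
        return num / (di * dj)

    return gm, corr
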