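"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles with explicit loops and
textbook formulas, sharing no code with the package, so that agreement
between an oracle and the implementation is evidence rather than tautology.
"""

import math

import numpy as np


def brute_moving_average(profile, window):
    """Sliding mean by explicit summation: value j = mean(profile[j:j+window])."""
    profile = list(profile)
    out = []
    for j in range(len(profile) - window + 1):
        out.append(sum(profile[j : j + window]) / window)
    return np.array(out)


def brute_quotient_flags(profile, short_window=5, long_window=31, threshold=1.1):
    """Center-aligned short/long quotient flags by explicit loops.

    Returns (positions, quotients, flags) for every pixel where the long
    window fits entirely.
    """
    profile = list(profile)
    L = len(profile)
    hs, hl = short_window // 2, long_window // 2
    positions, quotients, flags = [], [], []
    for x in range(hl, L - hl):
        s = sum(profile[x - hs : x + hs + 1]) / short_window
        l = sum(profile[x - hl : x + hl + 1]) / long_window
        q = s / l
        positions.append(x)
        quotients.append(q)
        flags.append(q > threshold)
    return np.array(positions), np.array(quotients), np.array(flags, dtype=bool)


def brute_runs(flags):
    """Maximal runs of consecutive True values as (start, end) index pairs."""
    runs, start = [], None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(flags)))
    return runs


def brute_punctal_fluorescence(profile, regions):
    """Per-region summed intensity over frame total, by explicit slicing."""
    total = sum(profile)
    return np.array([sum(profile[a:b]) / total for a, b in regions])


def brute_split_plot_ss(Y, groups):
    """Split-plot sums of squares from cell/marginal means, definitionally.

    Y is subjects × times; groups labels each subject's condition.  Every
    mean below is computed by explicit loops over observations.
    """
    Y = np.asarray(Y, dtype=float)
    N, k = Y.shape
    conds = sorted(set(groups))
    grand = sum(Y[i, t] for i in range(N) for t in range(k)) / (N * k)

    subj_mean = [sum(Y[i, t] for t in range(k)) / k for i in range(N)]
    time_mean = [sum(Y[i, t] for i in range(N)) / N for t in range(k)]
    group_rows = {c: [i for i in range(N) if groups[i] == c] for c in conds}
    group_mean = {
        c: sum(Y[i, t] for i in group_rows[c] for t in range(k)) / (len(group_rows[c]) * k)
        for c in conds
    }
    cell_mean = {
        (c, t): sum(Y[i, t] for i in group_rows[c]) / len(group_rows[c])
        for c in conds
        for t in range(k)
    }

    ss_total = sum((Y[i, t] - grand) ** 2 for i in range(N) for t in range(k))
    ss_cond = k * sum(len(group_rows[c]) * (group_mean[c] - grand) ** 2 for c in conds)
    ss_subj = k * sum(
        (subj_mean[i] - group_mean[c]) ** 2 for c in conds for i in group_rows[c]
    )
    ss_time = N * sum((time_mean[t] - grand) ** 2 for t in range(k))
    ss_inter = sum(
        len(group_rows[c])
        * (cell_mean[(c, t)] - group_mean[c] - time_mean[t] + grand) ** 2
        for c in conds
        for t in range(k)
    )
    ss_err = ss_total - ss_cond - ss_subj - ss_time - ss_inter
    return {
        "condition": ss_cond,
        "subject_error": ss_subj,
        "time": ss_time,
        "condition_x_time": ss_inter,
        "time_error": ss_err,
        "total": ss_total,
    }


def box_epsilon_literal(S):
    """Box's epsilon via the classic elementwise Greenhouse–Geisser formula.

    eps = k^2 (mean-diagonal - grand-mean)^2
          / ((k-1) (sum s_ij^2 - 2k sum_i rbar_i^2 + k^2 m^2))
    """
    S = np.asarray(S, dtype=float)
    k = S.shape[0]
    diag_mean = sum(S[i, i] for i in range(k)) / k
    grand = sum(S[i, j] for i in range(k) for j in range(k)) / k**2
    row_means = [sum(S[i, j] for j in range(k)) / k for i in range(k)]
    num = k**2 * (diag_mean - grand) ** 2
    den = (k - 1) * (
        sum(S[i, j] ** 2 for i in range(k) for j in range(k))
        - 2 * k * sum(r**2 for r in row_means)
        + k**2 * grand**2
    )
    return num / den


def brute_levene_w(groups_of_obs):
    """Levene's W by definition: one-way ANOVA on |y - group mean|."""
    devs = []
    for g in groups_of_obs:
        m = sum(g) / len(g)
        devs.append([abs(y - m) for y in g])
    N = sum(len(d) for d in devs)
    G = len(devs)
    grand = sum(z for d in devs for z in d) / N
    ss_between = sum(len(d) * (sum(d) / len(d) - grand) ** 2 for d in devs)
    ss_within = sum((z - sum(d) / len(d)) ** 2 for d in devs for z in d)
    return (ss_between / (G - 1)) / (ss_within / (N - G))


def analytic_rel_fluor(
    profile_length,
    baseline,
    positions,
    puncta_width,
    amplitude_init,
    amplitude_max,
    t_half,
    tau_rise,
    times,
    short_window=5,
    long_window=31,
    threshold=1.1,
):
    """Closed-form end-to-end oracle for the noiseless translocation read-out.

    Builds the exact noiseless profile analytically for each frame
    (truncated-Gaussian puncta on a flat baseline, amplitude following the
    logistic closed form), then applies brute-force detection and
    quantification.  Bleaching is omitted: it is a per-frame scalar and
    cancels in the relative read-out.
    """
    values = []
    for t in times:
        amp = amplitude_init + (amplitude_max - amplitude_init) / (
            1.0 + math.exp(-(t - t_half) / tau_rise)
        )
        sigma = puncta_width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        profile = []
        for x in range(profile_length):
            v = baseline
            for p in positions:
                if abs(x - p) <= 2 * puncta_width:
                    v += baseline * amp * math.exp(-0.5 * ((x - p) / sigma) ** 2)
            profile.append(v)
        pos, _, flags = brute_quotient_flags(profile, short_window, long_window, threshold)
        regions = [(pos[a], pos[b - 1] + 1) for a, b in brute_runs(flags)]
        rel = brute_punctal_fluorescence(profile, regions)
        values.append(sum(rel) / len(rel))
    values = np.array(values)
    return values / values[0]
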