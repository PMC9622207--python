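"""Independent brute-force reference implementations used only by the tests.

Each function re-derives a pipeline quantity by the most literal possible
method (exhaustive scans, double loops, direct-summation DFT), deliberately
sharing no code with the package.
"""

from __future__ import annotations

import math



def run_scan_events(values, dt, threshold, min_duration, mode_ge, gap_after=None):
    """Exhaustive scanner: all maximal violating runs longer than min_duration.

    Returns a list of (start_index, end_index) inclusive pairs. ``gap_after[i]``
    marks a timestamp gap between samples i and i+1 (breaks a run).
    """
    n = len(values)
    if gap_after is None:
        gap_after = [False] * max(n - 1, 0)
    viol = [
        (not math.isnan(values[i]))
        and (values[i] >= threshold if mode_ge else values[i] <= threshold)
        for i in range(n)
    ]
    runs = []
    i = 0
    while i < n:
        if viol[i]:
            j = i
            while j + 1 < n and viol[j + 1] and not gap_after[j]:
                j += 1
            if (j - i + 1) * dt > min_duration:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def trend_stats(values, minutes):
    """The eight window statistics by direct formulas."""
    v = list(map(float, values))
    t = list(map(float, minutes))
    n = len(v)
    mean = sum(v) / n
    sv = sorted(v)
    median = sv[n // 2] if n % 2 else (sv[n // 2 - 1] + sv[n // 2]) / 2.0
    sd = math.sqrt(sum((x - mean) ** 2 for x in v) / (n - 1)) if n > 1 else 0.0
    auc = sum((v[i] + v[i + 1]) / 2.0 * (t[i + 1] - t[i]) for i in range(n - 1))
    return {
        "mean": mean,
        "median": median,
        "sd": sd,
        "min": min(v),
        "max": max(v),
        "diff_first_last": v[-1] - v[0],
        "diff_recent": v[-1] - v[-2],
        "auc": auc,
    }


def dft_psd(values, dt):
    """One-sided periodogram of the mean-removed series by direct-summation DFT.

    Matches the scipy periodogram density normalization: P_k = |X_k|^2 * dt / N
    with a factor 2 on non-edge bins. Returns (freqs, power) without the DC bin.
    """
    v = [float(x) for x in values]
    n = len(v)
    mean = sum(v) / n
    v = [x - mean for x in v]
    n_freq = n // 2 + 1
    freqs, power = [], []
    for k in range(1, n_freq):
        re = sum(v[j] * math.cos(2 * math.pi * k * j / n) for j in range(n))
        im = -sum(v[j] * math.sin(2 * math.pi * k * j / n) for j in range(n))
        p = (re * re + im * im) * dt / n
        if not (n % 2 == 0 and k == n_freq - 1):
            p *= 2.0
        freqs.append(k / (n * dt))
        power.append(p)
    return freqs, power


def psd_slope_and_spread(values, dt):
    """Spectral log-log OLS slope and spectral-spread variance from dft_psd."""
    freqs, power = dft_psd(values, dt)
    pairs = [(math.log10(f), math.log10(p)) for f, p in zip(freqs, power) if p > 0]
    if len(pairs) < 2:
        slope = float("nan")
    else:
        xs = [a for a, _ in pairs]
        ys = [b for _, b in pairs]
        n = len(pairs)
        mx, my = sum(xs) / n, sum(ys) / n
        slope = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / sum(
            (x - mx) ** 2 for x in xs
        )
    total = sum(power)
    if total <= 0:
        return slope, float("nan")
    probs = [p / total for p in power]
    centroid = sum(f * p for f, p in zip(freqs, probs))
    spread = sum((f - centroid) ** 2 * p for f, p in zip(freqs, probs))
    return slope, spread


def apen(values, m, r):
    """Pincus approximate entropy by the O(N^2) double-loop definition."""
    u = [float(x) for x in values]
    n = len(u)

    def phi(mm):
        count = n - mm + 1
        total = 0.0
        for i in range(count):
            matches = 0
            for j in range(count):
                d = max(abs(u[i + k] - u[j + k]) for k in range(mm))
                if d <= r:
                    matches += 1
            total += math.log(matches / count)
        return total / count

    return phi(m) - phi(m + 1)


def concordance_auroc(labels, risks):
    """AUROC as explicit pairwise concordance with ties counted 1/2."""
    pos = [r for y, r in zip(labels, risks) if y == 1]
    neg = [r for y, r in zip(labels, risks) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def delong_stat(labels, risks_a, risks_b):
    """Paired DeLong z statistic by the direct psi/covariance formulas."""
    labels = list(labels)
    pos_i = [i for i, y in enumerate(labels) if y == 1]
    neg_i = [i for i, y in enumerate(labels) if y == 0]
    m, n = len(pos_i), len(neg_i)

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    def components(risks):
        auc = sum(psi(risks[i], risks[j]) for i in pos_i for j in neg_i) / (m * n)
        v10 = [sum(psi(risks[i], risks[j]) for j in neg_i) / n for i in pos_i]
        v01 = [sum(psi(risks[i], risks[j]) for i in pos_i) / m for j in neg_i]
        return auc, v10, v01

    auc_a, v10_a, v01_a = components(list(risks_a))
    auc_b, v10_b, v01_b = components(list(risks_b))

    def cov(xs, ys, mx, my):
        return sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / (len(xs) - 1)

    s10 = [
        [cov(a, b, ma, mb) for b, mb in ((v10_a, auc_a), (v10_b, auc_b))]
        for a, ma in ((v10_a, auc_a), (v10_b, auc_b))
    ]
    s01 = [
        [cov(a, b, ma, mb) for b, mb in ((v01_a, auc_a), (v01_b, auc_b))]
        for a, ma in ((v01_a, auc_a), (v01_b, auc_b))
    ]
    var = (s10[0][0] + s10[1][1] - 2 * s10[0][1]) / m + (
        s01[0][0] + s01[1][1] - 2 * s01[0][1]
    ) / n
    return (auc_a - auc_b) / math.sqrt(var)


def horizon_labels(rep_minutes, onset_minutes, block_minutes):
    """Next-block outcome labels for block representatives, by direct scan.

    A representative whose block is [k*b, (k+1)*b) gets label 1 iff an onset
    falls in [(k+1)*b, (k+2)*b).
    """
    out = []
    for t in rep_minutes:
        k = int(t // block_minutes)
        lo, hi = (k + 1) * block_minutes, (k + 2) * block_minutes
        out.append(int(any(lo <= o < hi for o in onset_minutes)))
    return out
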