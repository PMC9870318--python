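"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: the spike
oracle is a per-sample scan, the Ward oracle recomputes cluster sums of
squares from scratch at every step (O(n^3) exhaustive agglomeration), and
the Tukey oracle builds the studentized-range statistic by hand.
"""

from __future__ import annotations

import numpy as np


def spike_oracle(v: np.ndarray, dt: float, threshold: float = 0.0,
                 min_interval: float = 2.0) -> list[float]:
    """Naive per-sample threshold-crossing scan with local-max refinement."""
    events = []
    i = 0
    n = len(v)
    while i < n:
        entered = (v[i] >= threshold) and (i == 0 or v[i - 1] < threshold)
        if entered:
            j = i
            best = i
            while j < n and v[j] >= threshold:
                if v[j] > v[best]:
                    best = j
                j += 1
            events.append(best)
            i = j
        else:
            i += 1
    merged: list[int] = []
    for pk in events:
        if merged and (pk - merged[-1]) * dt < min_interval:
            if v[pk] > v[merged[-1]]:
                merged[-1] = pk
        else:
            merged.append(pk)
    return [p * dt for p in merged]


def ward_oracle(X: np.ndarray) -> list[tuple[frozenset, float]]:
    """Exhaustive Ward (ward.D2) agglomeration.

    At each step, for every cluster pair, the increase in total
    within-cluster sum of squares is recomputed from the raw points; the
    minimizing pair merges (ties to the lowest index pair) at height
    sqrt(2 * increase).  Returns the merge list as (leaf set, height).
    """
    X = np.asarray(X, dtype=float)

    def ess(idx: list[int]) -> float:
        pts = X[idx]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    clusters: list[list[int]] = [[i] for i in range(X.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                inc = (ess(clusters[i] + clusters[j])
                       - ess(clusters[i]) - ess(clusters[j]))
                if best is None or inc < best[0] - 1e-15:
                    best = (inc, i, j)
        inc, i, j = best
        new = clusters[i] + clusters[j]
        merges.append((frozenset(new), float(np.sqrt(2.0 * inc))))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(new)
    return merges


def linkage_to_merges(Z: np.ndarray) -> list[tuple[frozenset, float]]:
    """Convert a scipy linkage matrix to (leaf set, height) merge records."""
    n = Z.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, h, _s) in enumerate(Z):
        new = members[int(a)] | members[int(b)]
        members[n + k] = new
        out.append((new, float(h)))
    return out


def tukey_oracle(groups: dict[str, np.ndarray]) -> dict[tuple, float]:
    """Adjusted p per pair from the studentized range distribution
    (Tukey-Kramer standard error for unequal n)."""
    from scipy.stats import studentized_range

    names = list(groups)
    arrs = [np.asarray(groups[g], dtype=float) for g in names]
    k = len(arrs)
    dof = sum(a.size for a in arrs) - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrs) / dof
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
            q = abs(arrs[i].mean() - arrs[j].mean()) / se
            out[(names[i], names[j])] = float(
                studentized_range.sf(q, k, dof))
    return out


def balanced_twoway_anova_oracle(y: np.ndarray) -> dict[str, tuple]:
    """Closed-form sums-of-squares decomposition for a balanced a×b×n array.

    ``y`` has shape (a, b, n).  Returns {effect: (F, df1, df2)}.
    """
    a, b, n = y.shape
    grand = y.mean()
    mean_a = y.mean(axis=(1, 2))
    mean_b = y.mean(axis=(0, 2))
    mean_ab = y.mean(axis=2)
    ss_a = b * n * ((mean_a - grand) ** 2).sum()
    ss_b = a * n * ((mean_b - grand) ** 2).sum()
    ss_ab = n * ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    ss_err = ((y - mean_ab[:, :, None]) ** 2).sum()
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_err = a * b * (n - 1)
    ms_err = ss_err / df_err
    return {
        "A": (ss_a / df_a / ms_err, df_a, df_err),
        "B": (ss_b / df_b / ms_err, df_b, df_err),
        "interaction": (ss_ab / df_ab / ms_err, df_ab, df_err),
    }


def bandlimited_traces(n_traces: int, n_samples: int, seed: int,
                       scale: float = 45.0, offset: float = -35.0):
    """Random smooth traces spanning the spike threshold (for detector tests)."""
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_traces, n_samples))
    smooth = gaussian_filter1d(raw, sigma=25.0, axis=1)
    smooth /= smooth.std(axis=1, keepdims=True)
    return smooth * scale + offset
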