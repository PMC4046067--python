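"""Group-comparison statistics: one-way random-effects ICC, per-bin
Kruskal-Wallis tests, SNK stepwise post hoc, and the paired
return-to-baseline test for accumulated slow-wave energy."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InputError


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    var_between: float
    var_within: float
    group_sizes: tuple


def _as_groups(values_by_group):
    if isinstance(values_by_group, dict):
        groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in values_by_group]
    if len(groups) < 2:
        raise InputError("need >= 2 groups")
    for g in groups:
        if len(g) < 2:
            raise InputError("every group needs >= 2 values")
    return groups


def icc_between_groups(values_by_group, alpha: float = 0.05) -> ICCResult:
    """One-way random-effects ICC by method of moments, with F-pivot CI.

    The between-group variance component is (MSB - MSW) / n0, truncated at
    zero; the ICC is its share of total variance.  The confidence interval
    uses the exact F pivot for the balanced one-way design (Searle), applied
    with the unbalanced n0 coefficient when group sizes differ.
    """
    groups = _as_groups(values_by_group)
    k = len(groups)
    sizes = np.array([len(g) for g in groups])
    n_total = sizes.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    msb = float(np.sum(sizes * (means - grand) ** 2) / (k - 1))
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    msw = ssw / (n_total - k)
    n0 = (n_total - np.sum(sizes**2) / n_total) / (k - 1)
    var_between = max(0.0, (msb - msw) / n0)
    total = var_between + msw
    icc = 0.0 if total == 0 else var_between / total
    # F-pivot confidence interval
    df1, df2 = k - 1, n_total - k
    if msw == 0:
        lo, hi = (icc, icc)
    else:
        f_obs = msb / msw
        fl = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + n0 - 1)
        hi = (fu - 1) / (fu + n0 - 1)
    lo = float(np.clip(lo, 0.0, 1.0))
    hi = float(np.clip(hi, 0.0, 1.0))
    lo, hi = min(lo, icc), max(hi, icc)
    return ICCResult(icc, lo, hi, var_between, msw, tuple(sizes))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and asymptotic chi-square p.

    All-identical values yield (0, 1) by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def per_bin_kruskal_wallis(spectra_by_group, bin_freqs) -> pd.DataFrame:
    """Kruskal-Wallis test at every frequency bin across groups.

    ``spectra_by_group`` maps group label to an (n_subjects, n_bins) array.
    Returns one row per bin keyed by bin frequency.
    """
    mats = {k: np.atleast_2d(np.asarray(v, dtype=float))
            for k, v in spectra_by_group.items()}
    if len(mats) < 2:
        raise InputError("need >= 2 groups")
    n_bins = len(bin_freqs)
    for k, m in mats.items():
        if m.shape[1] != n_bins:
            raise InputError(f"group {k!r} has {m.shape[1]} bins, expected {n_bins}")
    rows = []
    for j in range(n_bins):
        h, p = kruskal_wallis([m[:, j] for m in mats.values()])
        rows.append({"freq_hz": float(bin_freqs[j]), "H": h, "p": p})
    return pd.DataFrame(rows)


@dataclass
class SNKResult:
    order: list                 # group labels sorted by ascending mean
    means: dict                 # label -> (possibly rank-transformed) mean
    significant: set            # frozenset pairs of labels judged different
    alpha: float

    def is_significant(self, a, b) -> bool:
        return frozenset((a, b)) in self.significant


def snk_posthoc(values_by_group, alpha: float = 0.05, use_ranks: bool = True) -> SNKResult:
    """Student-Newman-Keuls stepwise range test.

    By default the test operates on jointly rank-transformed data (the
    companion of a Kruskal-Wallis omnibus test); ``use_ranks=False`` gives
    the parametric variant on raw values.  Critical values come from the
    studentized range with stretch-dependent span; a non-significant span
    blocks all comparisons nested inside it.
    """
    if isinstance(values_by_group, dict):
        labels = list(values_by_group.keys())
        raw = [np.asarray(values_by_group[l], dtype=float) for l in labels]
    else:
        raw = [np.asarray(v, dtype=float) for v in values_by_group]
        labels = list(range(len(raw)))
    if len(raw) < 2:
        raise InputError("need >= 2 groups")
    pooled = np.concatenate(raw)
    if use_ranks:
        ranks = sps.rankdata(pooled)
        data, start = [], 0
        for g in raw:
            data.append(ranks[start : start + len(g)])
            start += len(g)
    else:
        data = raw
    k = len(data)
    n_total = len(pooled)
    df = n_total - k
    if df < 1:
        raise InputError("not enough observations for a within-group error term")
    mse = sum(float(((g - g.mean()) ** 2).sum()) for g in data) / df
    means = np.array([g.mean() for g in data])
    sizes = np.array([len(g) for g in data])
    order = np.argsort(means, kind="stable")
    significant: set = set()

    def test_span(i: int, j: int) -> None:
        # i, j index into the sorted order; span r = j - i + 1
        if j <= i:
            return
        a, b = order[i], order[j]
        r = j - i + 1
        if mse == 0:
            diff_sig = means[b] != means[a]
        else:
            se = np.sqrt(mse / 2 * (1 / sizes[a] + 1 / sizes[b]))
            q_obs = (means[b] - means[a]) / se
            q_crit = sps.studentized_range.ppf(1 - alpha, r, df)
            diff_sig = q_obs > q_crit
        if diff_sig:
            significant.add(frozenset((labels[a], labels[b])))
            test_span(i, j - 1)
            test_span(i + 1, j)
        # non-significant span: inner comparisons stay non-significant

    test_span(0, k - 1)
    return SNKResult(
        order=[labels[i] for i in order],
        means={labels[i]: float(means[i]) for i in range(k)},
        significant=significant,
        alpha=alpha,
    )


def paired_return_to_baseline(accumulated_values, reference: float = 0.0):
    """One-sample t test of final accumulated differences against baseline.

    Used on per-subject final accumulated slow-wave-energy values to ask
    whether a cohort returned to its baseline level.  Returns (t, p).
    """
    x = np.asarray(accumulated_values, dtype=float)
    if len(x) < 2:
        raise InputError("need >= 2 subjects")
    if np.all(x == x[0]):
        if x[0] == reference:
            return 0.0, 1.0
        raise DegenerateDataError("zero variance with nonzero offset: t undefined")
    t, p = sps.ttest_1samp(x, popmean=reference)
    return float(t), float(p)
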