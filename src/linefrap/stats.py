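"""Statistical comparison of diffusion estimates across media/treatments.

Significance tiers follow the convention: ns for p > 0.05, * for 0.05–0.01,
** for 0.01–0.005, *** for 0.005–0.001 and **** for p < 0.0001.  The interval
[0.0001, 0.001] is not named by that convention; this module assigns it to
*** (the adjacent tier) so the mapping is total and monotone.

Summary-level contrasts (mean, SE) use a two-sided z-test — appropriate when
each mean pools ~20–30 cells.  Per-cell samples use Welch's t.  Many-to-one
comparisons use one-way ANOVA with Dunnett's multiple-comparison adjustment,
with a seeded max-t permutation fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import DconfocalResult, InvalidInputError

__all__ = [
    "ConditionComparison",
    "ManyComparisonResult",
    "significance_tier",
    "compare_two",
    "compare_many",
]


@dataclass
class ConditionComparison:
    condition_a: str
    condition_b: str
    delta_d: float
    z_or_t: float
    p_value: float
    tier: str
    test: str = "z"


@dataclass
class ManyComparisonResult:
    anova_f: float
    anova_p: float
    comparisons: list
    method: str = "dunnett"


def significance_tier(p: float) -> str:
    """Map a p-value to its printed significance tier."""
    if not (0.0 <= p <= 1.0):
        raise InvalidInputError(f"p-value must be in [0, 1], got {p}")
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.005:
        return "**"
    if p >= 0.0001:
        return "***"
    return "****"


def compare_two(
    a: DconfocalResult,
    b: DconfocalResult,
    samples_a=None,
    samples_b=None,
) -> ConditionComparison:
    """Two-condition contrast of D_confocal.

    With per-cell samples supplied, uses Welch's t; otherwise a two-sided
    z-test on the (mean, SE) summaries.  Two identical, error-free summaries
    compare as p = 1 (ns) rather than erroring.
    """
    if samples_a is not None and samples_b is not None:
        xa = np.asarray(samples_a, dtype=float)
        xb = np.asarray(samples_b, dtype=float)
        if np.array_equal(xa, xb):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(xa, xb, equal_var=False)
        delta = float(xa.mean() - xb.mean())
        test = "welch_t"
    else:
        delta = a.d_confocal - b.d_confocal
        pooled = np.hypot(a.se, b.se)
        if pooled == 0:
            if delta == 0:
                stat, p = 0.0, 1.0
            else:
                raise InvalidInputError(
                    "cannot compare unequal means with zero SEs"
                )
        else:
            stat = delta / pooled
            p = 2.0 * sps.norm.sf(abs(stat))
        test = "z"
    return ConditionComparison(
        condition_a=a.condition,
        condition_b=b.condition,
        delta_d=float(delta),
        z_or_t=float(stat),
        p_value=float(p),
        tier=significance_tier(float(p)),
        test=test,
    )


def compare_many(
    groups: dict,
    reference: str,
    method: str = "dunnett",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> ManyComparisonResult:
    """One-way ANOVA plus many-to-one contrasts against a reference group.

    ``groups`` maps condition labels to per-cell D samples.  Dunnett's test
    (multivariate-t critical values, via scipy) is the primary adjustment; a
    seeded max-|t| permutation test is available as ``method="permutation"``.
    Groups with zero variance and n < 3 are excluded with a warning.
    """
    if reference not in groups:
        raise InvalidInputError(f"reference condition {reference!r} not in groups")
    clean = {}
    for label, xs in groups.items():
        xs = np.asarray(xs, dtype=float)
        if xs.size < 3 and np.std(xs) == 0:
            import warnings

            warnings.warn(f"excluding group {label!r}: n < 3 with zero variance")
            continue
        clean[label] = xs
    if reference not in clean or len(clean) < 2:
        raise InvalidInputError("need >= 2 usable groups including the reference")

    labels = [k for k in clean if k != reference]
    ref = clean[reference]

    if len(clean) == 2 and labels and np.array_equal(clean[labels[0]], ref):
        # degenerate single-group-vs-itself comparison
        f_stat, anova_p = 0.0, 1.0
        comps = [
            ConditionComparison(labels[0], reference, 0.0, 0.0, 1.0, "ns", "dunnett")
        ]
        return ManyComparisonResult(f_stat, anova_p, comps, method)

    f_stat, anova_p = sps.f_oneway(*clean.values())

    if method == "dunnett":
        res = sps.dunnett(*[clean[k] for k in labels], control=ref)
        stats_, pvals = np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)
    elif method == "permutation":
        stats_, pvals = _permutation_dunnett(
            [clean[k] for k in labels], ref, n_permutations, seed
        )
    else:
        raise InvalidInputError(f"unknown method {method!r}")

    comps = []
    for label, t, p in zip(labels, stats_, pvals):
        p = float(min(max(p, 0.0), 1.0))
        comps.append(
            ConditionComparison(
                condition_a=label,
                condition_b=reference,
                delta_d=float(clean[label].mean() - ref.mean()),
                z_or_t=float(t),
                p_value=p,
                tier=significance_tier(p),
                test=method,
            )
        )
    return ManyComparisonResult(float(f_stat), float(anova_p), comps, method)


def _welch_t(x, y):
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    denom = np.sqrt(vx / nx + vy / ny)
    return (x.mean() - y.mean()) / denom if denom > 0 else 0.0


def _permutation_dunnett(treatments, control, n_permutations, seed):
    """Family-wise max-|t| permutation test for many-to-one comparisons."""
    rng = np.random.default_rng(seed)
    t_obs = np.array([_welch_t(x, control) for x in treatments])
    pooled = np.concatenate([control] + list(treatments))
    sizes = [control.size] + [x.size for x in treatments]
    cuts = np.cumsum(sizes)[:-1]
    exceed = np.zeros(len(treatments))
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        parts = np.split(perm, cuts)
        ctrl = parts[0]
        t_max = max(abs(_welch_t(x, ctrl)) for x in parts[1:])
        exceed += t_max >= np.abs(t_obs)
    pvals = (exceed + 1.0) / (n_permutations + 1.0)
    return t_obs, pvals
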