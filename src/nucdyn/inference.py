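"""Group comparison of movement coefficients and event rates.

The primary tool is a two-way ANOVA whose main-effect, interaction and post
hoc pairwise p-values come from Monte Carlo permutation rather than the F
distribution.  Null distributions for the ANOVA terms use residual
permutation under the reduced model (Freedman-Lane): for a tested term the
model without that term is fitted, its residuals are permuted and added
back to its fitted values, and the term's F statistic is recomputed on each
permuted response.  Post hoc pairwise contrasts permute group labels within
the margin of the contrasted factor.  All p-values use the add-one
estimator p = (1 + #{permuted >= observed}) / (B + 1), so the smallest
attainable p is 1/(B + 1) and p = 0 is impossible.

The experimental unit is the retina / experimental repeat, not the frame:
callers must aggregate to one value per unit before testing.

Routine pairwise tests (unpaired t, Mann-Whitney) are thin wrappers over
scipy so pipeline reports can mirror conventional reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import DesignError, InsufficientDataError

__all__ = [
    "PermutationResult",
    "permutation_two_way",
    "pairwise_tests",
]

DEFAULT_PERMUTATIONS = 9999


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistics and permutation p-values for one design."""

    observed_stats: dict
    p_values: dict
    n_permutations: int
    seed: int
    alpha: float = 0.05

    def significant(self, key: str) -> bool:
        return self.p_values[key] <= self.alpha


def _sum_coding(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding: L levels -> L-1 columns."""
    levels = sorted(set(labels.tolist()))
    L = len(levels)
    cols = np.zeros((labels.size, L - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[labels == lev, j] = 1.0
    cols[labels == levels[-1], :] = -1.0
    return cols, levels


def _proj(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q of the column space (projection = Q Q^T)."""
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def _rss(Q: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y under projection Q."""
    total = np.sum(Y * Y, axis=0)
    fitted = Q.T @ Y
    return total - np.sum(fitted * fitted, axis=0)


def _safe_f(rss_red, rss_full, df_num: int, df_den: int,
            tol: float = 0.0) -> np.ndarray:
    """F statistic with degenerate cases resolved deterministically.

    RSS values below ``tol`` (numerical noise around an exact fit) are
    treated as zero: a zero numerator gives F = 0, a zero denominator with
    a positive numerator gives F = inf."""
    rss_red = np.where(np.asarray(rss_red) < tol, 0.0, rss_red)
    rss_full = np.where(np.asarray(rss_full) < tol, 0.0, rss_full)
    num = np.maximum(rss_red - rss_full, 0.0) / df_num
    den = rss_full / df_den
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(
            den > 0,
            num / np.where(den > 0, den, 1.0),
            np.where(num > 0, np.inf, 0.0),
        )
    return np.maximum(f, 0.0)


def _add_one_p(perm: np.ndarray, observed: float) -> float:
    b = perm.size
    return float((1 + np.count_nonzero(perm >= observed - 1e-12)) / (b + 1))


def permutation_two_way(
    values,
    factor_a,
    factor_b,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    alpha: float = 0.05,
    posthoc: bool = True,
) -> PermutationResult:
    """Two-way ANOVA with Monte Carlo permutation p-values.

    Parameters
    ----------
    values
        One scalar per experimental unit (e.g. one coefficient of movement
        per retina).
    factor_a, factor_b
        Factor labels per unit (e.g. age and treatment); >= 2 levels each.
    n_permutations
        Monte Carlo sample size B (default 9999; < 999 triggers a warning).
    seed
        Mandatory seed; identical seeds and inputs give identical results.

    Returns
    -------
    PermutationResult with keys ``factor_a``, ``factor_b``, ``interaction``
    and, when ``posthoc`` is set, ``a:<l1>|<l2>`` / ``b:<l1>|<l2>`` for each
    level pair.
    """
    if seed is None:
        raise DesignError("a seed is required for reproducible permutation")
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise DesignError("values and factor labels differ in length")
    if len(set(fa.tolist())) < 2 or len(set(fb.tolist())) < 2:
        raise DesignError("each factor needs >= 2 levels")
    if n_permutations < 999:
        warnings.warn(
            f"n_permutations={n_permutations} < 999 gives coarse p-values",
            stacklevel=2,
        )

    n = y.size
    rng = np.random.default_rng(seed)
    a_cols, a_levels = _sum_coding(fa)
    b_cols, b_levels = _sum_coding(fb)
    ab_cols = np.einsum("ni,nj->nij", a_cols, b_cols).reshape(n, -1)
    intercept = np.ones((n, 1))

    terms = {
        "factor_a": a_cols,
        "factor_b": b_cols,
        "interaction": ab_cols,
    }
    X_full = np.hstack([intercept, a_cols, b_cols, ab_cols])
    Q_full = _proj(X_full)
    df_den = n - Q_full.shape[1]
    if df_den < 1:
        raise DesignError("no residual degrees of freedom in the full model")

    observed: dict[str, float] = {}
    p_values: dict[str, float] = {}
    B = int(n_permutations)
    rss_tol = 1e-10 * max(1.0, float(np.dot(y - y.mean(), y - y.mean())))
    for name, cols in terms.items():
        others = [intercept] + [c for k, c in terms.items() if k != name]
        Q_red = _proj(np.hstack(others))
        df_num = Q_full.shape[1] - Q_red.shape[1]
        rss_full = float(_rss(Q_full, y[:, None])[0])
        rss_red = float(_rss(Q_red, y[:, None])[0])
        f_obs = float(_safe_f(rss_red, rss_full, df_num, df_den, rss_tol))
        # Freedman-Lane: permute reduced-model residuals
        fitted_red = Q_red @ (Q_red.T @ y)
        resid_red = y - fitted_red
        perm_idx = rng.permuted(
            np.tile(np.arange(n), (B, 1)), axis=1
        ).T  # (n, B)
        Yp = fitted_red[:, None] + resid_red[perm_idx]
        f_perm = _safe_f(
            _rss(Q_red, Yp), _rss(Q_full, Yp), df_num, df_den, rss_tol
        )
        observed[name] = f_obs
        p_values[name] = _add_one_p(f_perm, f_obs)

    if posthoc:
        for tag, labels, levels in (("a", fa, a_levels), ("b", fb, b_levels)):
            for l1, l2 in combinations(levels, 2):
                m = (labels == l1) | (labels == l2)
                yy = y[m]
                g = labels[m] == l1
                n1 = int(np.count_nonzero(g))
                stat = abs(float(yy[g].mean() - yy[~g].mean()))
                idx = rng.permuted(
                    np.tile(np.arange(yy.size), (B, 1)), axis=1
                )
                perm_vals = yy[idx]  # (B, n_pair)
                m1 = perm_vals[:, :n1].mean(axis=1)
                m2 = perm_vals[:, n1:].mean(axis=1)
                key = f"{tag}:{l1}|{l2}"
                observed[key] = stat
                p_values[key] = _add_one_p(np.abs(m1 - m2), stat)

    return PermutationResult(
        observed_stats=observed,
        p_values=p_values,
        n_permutations=B,
        seed=int(seed),
        alpha=alpha,
    )


def pairwise_tests(
    group_x, group_y, kind: str = "auto"
) -> tuple[float, float, str]:
    """Two-sided two-sample test: unpaired t, Mann-Whitney, or automatic.

    ``kind='auto'`` routes on D'Agostino-Pearson normality of both groups
    (t test when neither rejects normality at 0.05, rank test otherwise;
    small groups where the normality test is undefined route to the rank
    test).  Returns (statistic, p_value, kind_used).
    """
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    if kind == "auto":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normal = (stats.normaltest(x).pvalue > 0.05
                          and stats.normaltest(y).pvalue > 0.05)
        except ValueError:  # too few observations for the normality test
            normal = False
        kind = "t" if normal else "rank"
    if kind == "t":
        res = stats.ttest_ind(x, y)
    elif kind == "rank":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    pvalue = float(res.pvalue)
    if np.isnan(pvalue):  # identical constant groups
        pvalue = 1.0
    return float(res.statistic), pvalue, kind
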