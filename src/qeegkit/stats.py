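"""Group comparisons, the r-significance criterion and polynomial fits.

``critical_r`` inverts the t statistic for a Pearson correlation,
``t = r·√(n−2)/√(1−r²)``, at the critical t with n−2 degrees of freedom, so
a fitted correlation can be declared significant by a single threshold
(0.4227 at n = 22, α = 0.05 two-sided).

``fit_polynomial`` performs ordinary least squares on powers of x and
summarizes fit quality as the Pearson correlation between fitted and
observed values; ``select_degree`` applies a parsimony rule: the lowest
degree whose r exceeds 75% of the best r over degrees 1–4.

``group_compare`` reproduces a routine clinical-statistics decision tree:
normality by Shapiro–Wilk and homoscedasticity by Brown–Forsythe gate the
parametric (Student t) versus rank (Wilcoxon / Mann–Whitney) paths; three or
more groups go to Kruskal–Wallis with Dunn's post-hoc z tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import DesignError, EstimatorError, FitError, ParameterError


def critical_r(n: int, alpha: float = 0.05, tail: str = "two-sided") -> float:
    """Smallest |r| significant at ``alpha`` for sample size ``n``.

    Default is the two-sided critical point; ``tail="one-sided"`` gives the
    one-tailed variant.
    """
    if n <= 3:
        raise EstimatorError("need n > 3 (at least 2 degrees of freedom)")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if tail not in ("two-sided", "one-sided"):
        raise ParameterError(f"unknown tail {tail!r}")
    q = 1 - alpha / 2 if tail == "two-sided" else 1 - alpha
    tcrit = sps.t.ppf(q, df=n - 2)
    return float(tcrit / np.sqrt((n - 2) + tcrit ** 2))


@dataclass
class RegressionFit:
    """Polynomial least-squares fit summarized by fitted-vs-observed r."""

    degree: int
    coefficients: np.ndarray  # constant first
    r: float
    significant: bool
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(
            np.asarray(x, dtype=float), self.coefficients)


def fit_polynomial(x, y, degree: int, alpha: float = 0.05) -> RegressionFit:
    """OLS fit of ``y`` on powers of ``x`` up to ``degree``.

    ``r`` is the Pearson correlation between fitted and observed values
    (equal to √R² for a least-squares fit with intercept); significance is
    assessed against :func:`critical_r`. A constant ``y`` has no defined
    correlation: ``r`` is reported missing and the fit non-significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("x and y must be 1-D of equal length")
    n = len(x)
    if not 1 <= degree <= 4:
        raise ParameterError("degree must be in 1..4")
    if n <= degree + 1:
        raise FitError(f"n={n} too small for degree {degree}")
    if len(np.unique(x)) <= degree:
        raise FitError("rank deficiency: too few distinct x values")
    V = np.vander(x, degree + 1, increasing=True)
    coefs, *_ = np.linalg.lstsq(V, y, rcond=None)
    fitted = V @ coefs
    if np.std(y) == 0 or np.std(fitted) == 0:
        return RegressionFit(degree, coefs, np.nan, False, n)
    r = float(np.corrcoef(fitted, y)[0, 1])
    return RegressionFit(degree, coefs, r,
                         bool(r > critical_r(n, alpha)), n)


def select_degree(x, y, degrees=range(1, 5), frac: float = 0.75) -> int:
    """Lowest polynomial degree whose r exceeds ``frac`` of the best r.

    Guards against overfitting: raising the degree always raises r, so the
    minimum degree reaching 75% of the degree-4 correlation is retained.
    Non-finite r values count as zero; if every fit fails a selection error
    is raised.
    """
    rs = {}
    for d in degrees:
        try:
            fit = fit_polynomial(x, y, d)
            rs[d] = fit.r if np.isfinite(fit.r) else 0.0
        except FitError:
            continue
    if not rs:
        raise FitError("no polynomial degree could be fitted")
    best = max(rs.values())
    for d in sorted(rs):
        if rs[d] >= frac * best:
            return d
    return max(rs)  # unreachable: the best degree satisfies the rule


@dataclass
class ComparisonReport:
    """Outcome of one group comparison."""

    design: str
    test: str
    statistic: float
    p: float
    normal: bool
    equal_var: bool
    n: tuple[int, ...]
    posthoc: list[dict] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return bool(self.p < 0.05)


def _normal(sample: np.ndarray, alpha: float) -> bool:
    if np.ptp(sample) == 0:
        return False  # degenerate; route to rank tests
    return sps.shapiro(sample).pvalue > alpha


def group_compare(a, b=None, *groups, design: str = "independent",
                  gate_alpha: float = 0.05) -> ComparisonReport:
    """Two-group or k-group comparison with normality/variance gating.

    ``design``:

    - ``"paired"``: paired Student t when both samples pass Shapiro–Wilk,
      Wilcoxon signed-rank otherwise;
    - ``"independent"``: Student t when both samples are normal and
      Brown–Forsythe finds equal variances, Mann–Whitney otherwise;
    - ``"k-group"``: Kruskal–Wallis over all samples with Dunn post-hoc.
    """
    samples = [np.asarray(s, dtype=float)
               for s in ([a] if b is None else [a, b]) + list(groups)]
    if any(len(s) < 3 for s in samples):
        raise DesignError("every group needs at least 3 observations")

    if design == "k-group" or len(samples) > 2:
        stat, p = sps.kruskal(*samples)
        return ComparisonReport(
            design="k-group", test="Kruskal-Wallis", statistic=float(stat),
            p=float(p), normal=False, equal_var=False,
            n=tuple(len(s) for s in samples),
            posthoc=dunn_test(samples))

    x, y = samples
    normal = _normal(x, gate_alpha) and _normal(y, gate_alpha)
    if design == "paired":
        if len(x) != len(y):
            raise DesignError("paired design requires equal lengths")
        equal_var = True  # not gated in the paired path
        if np.allclose(x, y):
            # zero differences break both paired tests; identical samples
            # are trivially not different
            return ComparisonReport("paired", "paired t", 0.0, 1.0,
                                    normal, equal_var, (len(x), len(y)))
        if normal:
            res = sps.ttest_rel(x, y)
            test = "paired t"
        else:
            res = sps.wilcoxon(x, y)
            test = "Wilcoxon"
    elif design == "independent":
        equal_var = bool(
            sps.levene(x, y, center="median").pvalue > gate_alpha)
        if normal and equal_var:
            res = sps.ttest_ind(x, y)
            test = "Student t"
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided")
            test = "Mann-Whitney"
    else:
        raise DesignError(f"unknown design {design!r}")
    return ComparisonReport(design, test, float(res.statistic),
                            float(res.pvalue), normal, equal_var,
                            (len(x), len(y)))


def dunn_test(samples: list[np.ndarray], correction: str = "bonferroni"
              ) -> list[dict]:
    """Dunn's post-hoc pairwise z tests after Kruskal–Wallis.

    Standard rank-sum z statistic with tie correction; p-values Bonferroni
    corrected over the pairs by default.
    """
    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie = counts[counts > 1]
    tie_term = (tie ** 3 - tie).sum() / (12 * (N - 1)) if len(tie) else 0.0
    mean_ranks, ns, idx = [], [], 0
    for s in samples:
        mean_ranks.append(ranks[idx:idx + len(s)].mean())
        ns.append(len(s))
        idx += len(s)
    out = []
    pairs = list(combinations(range(len(samples)), 2))
    for i, j in pairs:
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                     * (1.0 / ns[i] + 1.0 / ns[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * len(pairs)) if correction == "bonferroni" else p
        out.append({"groups": (i, j), "z": float(z), "p": float(p),
                    "p_adj": float(p_adj)})
    return out


def bonferroni(pvals) -> np.ndarray:
    """Bonferroni-corrected p values for one comparison family."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float),
                         method="bonferroni")[1]
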