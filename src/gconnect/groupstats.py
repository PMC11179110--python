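"""Case-control comparison of g and domain-specific measures.

Pooled-SD effect sizes, permutation tests in place of t-tests, a two-class
Fisher linear discriminant over the battery (the "can a weighted test
combination beat g?" comparison), g-adjustment of independent measures, and
generic g-covariate association.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from ._seeds import substream
from .psychometrics import ScoreTable

__all__ = [
    "EffectSizeRow",
    "LdaModel",
    "AssociationRow",
    "cohens_d",
    "permutation_test",
    "lda_fit",
    "lda_vs_g",
    "adjust_for_g",
    "associate",
    "effect_size_table",
]

#: cap on exact enumeration of group assignments in the permutation test
EXACT_PERM_LIMIT = 20_000


@dataclass
class EffectSizeRow:
    measure: str
    mean1: float
    sd1: float
    mean0: float
    sd0: float
    perm_p: float
    cohens_d: float


@dataclass
class LdaModel:
    """Two-class Fisher discriminant: w ∝ S_pooled⁻¹ (μ1 − μ0)."""

    direction: pd.Series        # discriminant weights, one per test
    threshold: float            # midpoint of projected group means
    scores: pd.Series           # standardized projections, all subjects
    ridge_used: bool = False


@dataclass
class AssociationRow:
    covariate: str
    method: str
    statistic: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def cohens_d(m1: float, s1: float, n1: int, m0: float, s0: float, n0: int) -> float:
    """Pooled-SD standardized mean difference, reported as a magnitude.

    d = |m1 − m0| / sqrt(((n1−1)s1² + (n0−1)s0²) / (n1+n0−2))
    """
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs at least 2 observations")
    if s1 <= 0 or s0 <= 0:
        raise ValueError("group SDs must be positive")
    pooled = math.sqrt(((n1 - 1) * s1**2 + (n0 - 1) * s0**2) / (n1 + n0 - 2))
    if pooled == 0:
        raise ValueError("pooled variance is zero")
    return abs(m1 - m0) / pooled


def permutation_test(
    values, groups, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Two-sided permutation p for a difference in group means.

    Exact enumeration of all group assignments when their number is at most
    20,000, otherwise Monte Carlo with the +1 correction
    p = (1 + #{|T*| >= |T|}) / (1 + n_draws).
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {len(labels)}")
    n1 = int(np.sum(g == labels[1]))
    n0 = int(np.sum(g == labels[0]))
    if min(n1, n0) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(x) == 0:
        warnings.warn("constant input; permutation p-value is 1", stacklevel=2)
        return 1.0

    total = x.sum()
    n = len(x)
    obs = abs(x[g == labels[1]].mean() - x[g == labels[0]].mean())

    def diff_from_sum1(s1: np.ndarray) -> np.ndarray:
        return np.abs(s1 / n1 - (total - s1) / n0)

    n_comb = math.comb(n, n1)
    if n_comb <= EXACT_PERM_LIMIT:
        sums = np.fromiter(
            (x[list(idx)].sum() for idx in combinations(range(n), n1)),
            dtype=float, count=n_comb,
        )
        perm = diff_from_sum1(sums)
        return float(np.sum(perm >= obs - 1e-12) / n_comb)
    rng = substream(seed, "permutation")
    hits = 0
    block = 2000
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)[:, :n1]
        sums = x[idx].sum(axis=1)
        hits += int(np.sum(diff_from_sum1(sums) >= obs - 1e-12))
        done += b
    return float((1 + hits) / (1 + n_perm))


def effect_size_table(
    table: ScoreTable,
    extra: dict[str, pd.Series] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-measure group means ± SD, permutation p and |d| for a battery.

    ``extra`` adds derived measures (g, the LDA score) as additional rows.
    """
    cols: dict[str, pd.Series] = {}
    if extra:
        cols.update(extra)
    for t in table.test_names:
        cols[t] = table.scores[t]
    g = table.group.to_numpy()
    rows = []
    for i, (name, v) in enumerate(cols.items()):
        x = v.to_numpy(dtype=float)
        x1, x0 = x[g == 1], x[g == 0]
        rows.append(
            EffectSizeRow(
                measure=name,
                mean1=x1.mean(), sd1=x1.std(ddof=1),
                mean0=x0.mean(), sd0=x0.std(ddof=1),
                perm_p=permutation_test(x, g, n_perm=n_perm, seed=seed + i),
                cohens_d=cohens_d(
                    x1.mean(), x1.std(ddof=1), len(x1),
                    x0.mean(), x0.std(ddof=1), len(x0),
                ),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("measure")


# ---------------------------------------------------------------------------
# linear discriminant
# ---------------------------------------------------------------------------

def lda_fit(table: ScoreTable) -> LdaModel:
    """Fisher two-class discriminant on the battery.

    w ∝ S_pooled⁻¹ (μ1 − μ0), scaled so the projected scores have unit
    pooled within-group SD and signed so controls (group 0) score higher.
    A small ridge (1e−8 · trace/p) is added if the pooled covariance is
    singular.
    """
    X = table.scores.to_numpy(dtype=float)
    g = table.group.to_numpy()
    X1, X0 = X[g == 1], X[g == 0]
    n1, n0 = len(X1), len(X0)
    p = X.shape[1]
    S = ((n1 - 1) * np.cov(X1, rowvar=False) + (n0 - 1) * np.cov(X0, rowvar=False)) / (
        n1 + n0 - 2
    )
    S = np.atleast_2d(S)
    ridge_used = False
    try:
        w = linalg.solve(S, X1.mean(axis=0) - X0.mean(axis=0), assume_a="pos")
    except linalg.LinAlgError:
        if min(n1, n0) <= p:
            warnings.warn(
                "singular pooled covariance (n <= p per group); using ridge",
                stacklevel=2,
            )
        S = S + 1e-8 * np.trace(S) / p * np.eye(p)
        w = linalg.solve(S, X1.mean(axis=0) - X0.mean(axis=0), assume_a="pos")
        ridge_used = True

    proj = X @ w
    pooled_sd = math.sqrt(
        (
            (n1 - 1) * proj[g == 1].var(ddof=1)
            + (n0 - 1) * proj[g == 0].var(ddof=1)
        )
        / (n1 + n0 - 2)
    )
    w = w / pooled_sd
    proj = proj / pooled_sd
    if proj[g == 0].mean() < proj[g == 1].mean():  # controls score higher
        w, proj = -w, -proj
    threshold = (proj[g == 1].mean() + proj[g == 0].mean()) / 2.0
    scores = (proj - proj.mean()) / proj.std(ddof=1)
    return LdaModel(
        direction=pd.Series(w, index=table.test_names, name="weight"),
        threshold=float(threshold),
        scores=pd.Series(scores, index=table.scores.index, name="lda"),
        ridge_used=ridge_used,
    )


def lda_vs_g(lda_scores: pd.Series, g: pd.Series, table: ScoreTable | None = None) -> dict:
    """Correlate the LDA discriminant with g and with each input test.

    Returns the g-LDA Pearson correlation and, when the battery is given,
    each test's correlation with the LDA score plus a ranking showing
    whether g outranks every individual test.
    """
    if not lda_scores.index.equals(g.index):
        raise ValueError("LDA scores and g must be over the same subjects")
    r_g = float(np.corrcoef(lda_scores, g)[0, 1])
    out = {"r_g_lda": r_g}
    if table is not None:
        r_tests = {
            t: float(np.corrcoef(lda_scores, table.scores[t])[0, 1])
            for t in table.test_names
        }
        out["r_test_lda"] = r_tests
        out["g_outranks_all_tests"] = bool(
            abs(r_g) > max(abs(v) for v in r_tests.values())
        )
    return out


# ---------------------------------------------------------------------------
# g-adjustment and association
# ---------------------------------------------------------------------------

def adjust_for_g(
    values, g, groups, n_perm: int = 10_000, seed: int = 0
) -> dict:
    """Residualize a measure on g (combined-sample OLS) and re-test groups.

    Returns the residuals and the permutation p before and after adjustment.
    """
    x = np.asarray(values, dtype=float)
    gv = np.asarray(g, dtype=float)
    if np.ptp(gv) == 0:
        raise ValueError("g is constant; cannot adjust")
    design = np.column_stack([np.ones_like(gv), gv])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ beta
    p_before = permutation_test(x, groups, n_perm=n_perm, seed=seed)
    if np.ptp(resid) < 1e-12:
        p_after = 1.0
    else:
        p_after = permutation_test(resid, groups, n_perm=n_perm, seed=seed + 1)
    return {
        "residuals": resid,
        "slope": float(beta[1]),
        "p_before": p_before,
        "p_after": p_after,
    }


def associate(g, covariate, kind: str) -> AssociationRow:
    """Associate g with one covariate using the declared method.

    kind: "pearson" or "spearman" for continuous covariates, "t" for a
    two-level category compared on g, "chi2" for two categorical variables
    (covariate vs. a second categorical passed as ``g``).
    """
    name = getattr(covariate, "name", None) or "covariate"
    if kind in ("pearson", "spearman"):
        x = np.asarray(g, dtype=float)
        y = np.asarray(covariate, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            raise ValueError("fewer than 3 complete pairs")
        if kind == "pearson":
            r, p = stats.pearsonr(x[ok], y[ok])
        else:
            r, p = stats.spearmanr(x[ok], y[ok])
        return AssociationRow(name, kind, float(r), float(p), int(ok.sum()))
    if kind == "t":
        cats = pd.Series(covariate)
        levels = cats.dropna().unique()
        if len(levels) != 2:
            raise ValueError("t association needs a two-level category")
        x = np.asarray(g, dtype=float)
        a = x[(cats == levels[0]).to_numpy()]
        b = x[(cats == levels[1]).to_numpy()]
        t, p = stats.ttest_ind(a, b)
        return AssociationRow(name, "t", float(t), float(p), len(a) + len(b))
    if kind == "chi2":
        tab = pd.crosstab(pd.Series(g), pd.Series(covariate))
        chi2, p, _, _ = stats.chi2_contingency(tab)
        return AssociationRow(name, "chi2", float(chi2), float(p), int(tab.to_numpy().sum()))
    raise ValueError(f"unknown association kind {kind!r}")
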