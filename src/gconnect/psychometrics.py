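"""Extraction of a general cognitive factor (Spearman's g) from a test battery.

The workflow mirrors standard exploratory-factor-analysis practice for
deriving g from a neuropsychological battery:

1. sampling adequacy (Kaiser-Meyer-Olkin measure, Bartlett sphericity test),
2. factor-count selection (Velicer's minimum-average-partial test, both the
   1976 squared and the 2000 fourth-power criteria),
3. minimum-residual (unweighted least squares) factor estimation with
   oblimin rotation via gradient projection for multi-factor solutions,
4. Thurstone regression factor scores with their validity and multiple R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from ._rotation import oblimin_rotate

__all__ = [
    "ScoreTable",
    "AdequacyReport",
    "FactorModel",
    "GScores",
    "kmo",
    "bartlett_sphericity",
    "map_test",
    "efa",
    "factor_scores",
    "extract_g",
]

#: floor applied to uniquenesses when a Heywood case is encountered
HEYWOOD_FLOOR = 0.005


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ScoreTable:
    """Subjects x tests score matrix with group labels and covariates.

    ``scores`` is indexed by subject id with one column per test;
    ``group`` is coded 0 = control, 1 = patient. ``latent_g`` carries the
    true latent factor when the table is synthetic (recovery tests).
    """

    scores: pd.DataFrame
    group: pd.Series
    covariates: pd.DataFrame | None = None
    latent_g: pd.Series | None = None

    def __post_init__(self) -> None:
        n, p = self.scores.shape
        if n <= p:
            raise ValueError(f"need more subjects ({n}) than tests ({p})")
        if self.scores.isna().any().any():
            raise ValueError("missing values in score table; complete cases required")
        if not self.group.index.equals(self.scores.index):
            raise ValueError("group labels must be indexed like the scores")

    @property
    def test_names(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def subject_ids(self) -> list:
        return list(self.scores.index)

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    def standardized(self) -> pd.DataFrame:
        """Z-scored test columns over the combined sample (ddof=1)."""
        s = self.scores
        return (s - s.mean()) / s.std(ddof=1)

    def correlation(self) -> pd.DataFrame:
        return self.scores.corr(method="pearson")

    def to_csv(self, path) -> None:
        out = self.scores.copy()
        out.insert(0, "group", self.group)
        if self.covariates is not None:
            out = out.join(self.covariates)
        if self.latent_g is not None:
            out["latent_g"] = self.latent_g
        out.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path, tests: list[str] | None = None) -> "ScoreTable":
        df = pd.read_csv(path, index_col="subject_id")
        if "group" not in df.columns:
            raise ValueError("score CSV must carry a 'group' column (0=control, 1=patient)")
        group = df.pop("group").astype(int)
        latent = df.pop("latent_g") if "latent_g" in df.columns else None
        if tests is None:
            tests = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
        covars = df.drop(columns=tests) if set(df.columns) - set(tests) else None
        return cls(scores=df[tests], group=group, covariates=covars, latent_g=latent)


@dataclass
class AdequacyReport:
    kmo_overall: float
    msa_per_item: pd.Series
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


@dataclass
class FactorModel:
    """A fitted exploratory factor model (minres/ULS, optionally oblimin-rotated)."""

    n_factors: int
    loadings: pd.DataFrame          # p x m, rotated pattern matrix
    uniquenesses: pd.Series         # psi, diagonal of the unique variances
    factor_corr: np.ndarray         # m x m factor correlation Phi
    rmsr: float                     # root mean square off-diagonal residual
    tli: float                      # Tucker-Lewis index (nan without n_obs)
    score_weights: pd.DataFrame     # p x m Thurstone regression weights
    score_validity: np.ndarray      # corr(estimated score, factor), per factor
    score_r2: np.ndarray            # squared validity, per factor
    corr: pd.DataFrame = field(repr=False)
    n_obs: int | None = None
    objective_path: list[float] = field(default_factory=list, repr=False)

    @property
    def test_names(self) -> list[str]:
        return list(self.loadings.index)

    def implied_correlation(self) -> np.ndarray:
        L = self.loadings.to_numpy()
        S = L @ self.factor_corr @ L.T
        np.fill_diagonal(S, 1.0)
        return S


@dataclass
class GScores:
    g: pd.Series
    method: str = "regression"


# ---------------------------------------------------------------------------
# adequacy diagnostics
# ---------------------------------------------------------------------------

def _as_corr(corr) -> tuple[np.ndarray, list[str]]:
    if isinstance(corr, pd.DataFrame):
        return corr.to_numpy(dtype=float), list(corr.columns)
    R = np.asarray(corr, dtype=float)
    return R, [f"v{i}" for i in range(R.shape[0])]


def _check_corr(R: np.ndarray) -> None:
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")


def kmo(corr) -> AdequacyReport:
    """Kaiser-Meyer-Olkin sampling adequacy from a correlation matrix.

    Overall KMO is sum(r²) / (sum(r²) + sum(q²)) over off-diagonal entries,
    where q are the anti-image partial correlations obtained from the
    inverse correlation matrix. Per-item MSA uses the same ratio row-wise.
    Bartlett fields are filled by :func:`bartlett_sphericity`; here they are
    returned as nan placeholders so the report can be built incrementally.
    """
    R, names = _as_corr(corr)
    _check_corr(R)
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < 1e-12:
        off = np.abs(R - np.eye(len(R)))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            f"correlation matrix is singular (min eigenvalue {eigmin:.3g}); "
            f"most collinear pair: {names[i]!r} and {names[j]!r} (r={R[i, j]:.4f})"
        )
    S = linalg.inv(R)
    d = np.sqrt(np.diag(S))
    Q = -S / np.outer(d, d)
    np.fill_diagonal(Q, 0.0)
    R_off = R - np.diag(np.diag(R))

    r2 = R_off**2
    q2 = Q**2
    overall = r2.sum() / (r2.sum() + q2.sum())
    with np.errstate(invalid="ignore"):
        msa = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
    return AdequacyReport(
        kmo_overall=float(overall),
        msa_per_item=pd.Series(msa, index=names, name="msa"),
        bartlett_chi2=float("nan"),
        bartlett_df=0,
        bartlett_p=float("nan"),
    )


def bartlett_sphericity(corr, n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi² = -(n - 1 - (2p+5)/6) ln|R| with p(p-1)/2 degrees of freedom.
    """
    R, _ = _as_corr(corr)
    _check_corr(R)
    p = R.shape[0]
    if n <= p:
        raise ValueError(f"sample size n={n} must exceed the number of tests p={p}")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def adequacy(corr, n: int) -> AdequacyReport:
    """KMO and Bartlett diagnostics in one report."""
    rep = kmo(corr)
    chi2, df, p = bartlett_sphericity(corr, n)
    rep.bartlett_chi2, rep.bartlett_df, rep.bartlett_p = chi2, df, p
    return rep


# ---------------------------------------------------------------------------
# factor-count selection: Velicer's minimum average partial
# ---------------------------------------------------------------------------

def map_test(corr, criterion: str = "1976") -> int:
    """Velicer's minimum-average-partial factor count.

    For m = 0..p-2 principal components partialled out of the correlation
    matrix, the average squared (1976) or fourth-power (2000) off-diagonal
    partial correlation is computed; the m minimising it is returned.
    """
    if criterion not in ("1976", "2000"):
        raise ValueError("criterion must be '1976' or '2000'")
    power = 2 if criterion == "1976" else 4
    R, _ = _as_corr(corr)
    _check_corr(R)
    p = R.shape[0]
    vals, vecs = linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals[-1] <= 0:
        raise ValueError("correlation matrix must be positive definite")

    offmask = ~np.eye(p, dtype=bool)
    avgs = np.empty(p - 1)
    avgs[0] = np.mean(np.abs(R[offmask]) ** power)
    for m in range(1, p - 1):
        L = vecs[:, :m] * np.sqrt(vals[:m])
        C = R - L @ L.T
        d = np.sqrt(np.clip(np.diag(C), 1e-12, None))
        P = C / np.outer(d, d)
        avgs[m] = np.mean(np.abs(P[offmask]) ** power)
    return int(np.argmin(avgs))


# ---------------------------------------------------------------------------
# minres factor estimation
# ---------------------------------------------------------------------------

def _loadings_given_psi(R: np.ndarray, psi: np.ndarray, m: int) -> np.ndarray:
    Rstar = R - np.diag(psi)
    vals, vecs = linalg.eigh(Rstar)
    order = np.argsort(vals)[::-1][:m]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _minres_objective(psi: np.ndarray, R: np.ndarray, m: int, offmask: np.ndarray) -> float:
    L = _loadings_given_psi(R, psi, m)
    resid = (R - np.diag(psi)) - L @ L.T
    return float(np.sum(resid[offmask] ** 2) / 2.0)


def efa(corr, n_factors: int, rotation: str = "oblique-GPA",
        n_obs: int | None = None, max_iter: int = 1000) -> FactorModel:
    """Fit a minres (unweighted least squares) exploratory factor model.

    The uniquenesses are optimised by L-BFGS-B; given uniquenesses, the
    loadings are the best rank-m spectral approximation of the reduced
    correlation matrix. A single factor is left unrotated (sign fixed so the
    loading sum is positive — the g convention); multi-factor solutions are
    rotated obliquely by quartimin/oblimin through gradient projection.
    """
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if rotation not in ("none", "oblique-GPA"):
        raise ValueError("rotation must be 'none' or 'oblique-GPA'")
    R, names = _as_corr(corr)
    _check_corr(R)
    p = R.shape[0]
    if n_factors > (p - 1):
        raise ValueError("n_factors must be at most p - 1")
    offmask = ~np.eye(p, dtype=bool)

    # start from squared-multiple-correlation communalities
    try:
        Rinv = linalg.inv(R)
        psi0 = np.clip(1.0 / np.diag(Rinv), 0.05, 1.0)
    except linalg.LinAlgError:
        psi0 = np.full(p, 0.5)

    path: list[float] = [_minres_objective(psi0, R, n_factors, offmask)]
    res = optimize.minimize(
        _minres_objective, psi0, args=(R, n_factors, offmask),
        method="L-BFGS-B", bounds=[(HEYWOOD_FLOOR, 1.0)] * p,
        callback=lambda xk: path.append(_minres_objective(xk, R, n_factors, offmask)),
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-10},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise RuntimeError(
            f"minres estimation failed to converge: {res.message} "
            f"(last objective {res.fun:.6g})"
        )
    psi = np.asarray(res.x)
    if np.any(psi <= HEYWOOD_FLOOR + 1e-12):
        warnings.warn(
            "Heywood case: uniqueness floored at "
            f"{HEYWOOD_FLOOR} for {int(np.sum(psi <= HEYWOOD_FLOOR + 1e-12))} test(s)",
            stacklevel=2,
        )
    L = _loadings_given_psi(R, psi, n_factors)

    if n_factors == 1:
        if L[:, 0].sum() < 0:
            L = -L
        Phi = np.ones((1, 1))
    elif rotation == "oblique-GPA":
        L, Phi = oblimin_rotate(L)
        flip = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
        L = L * flip
        Phi = Phi * np.outer(flip, flip)
    else:
        Phi = np.eye(n_factors)

    implied = L @ Phi @ L.T
    resid = R - implied
    rmsr = float(np.sqrt(np.mean(resid[np.triu_indices(p, 1)] ** 2)))
    tli = _tucker_lewis(R, implied + np.diag(psi), p, n_factors, n_obs)

    # Thurstone regression scores: W = R^-1 Lambda Phi
    Rinv = linalg.inv(R)
    W = Rinv @ L @ Phi
    cov_sf = Phi @ L.T @ Rinv @ L @ Phi  # cov(score, factor) = var(score)
    validity = np.sqrt(np.clip(np.diag(cov_sf), 0.0, None))

    return FactorModel(
        n_factors=n_factors,
        loadings=pd.DataFrame(L, index=names, columns=[f"F{k+1}" for k in range(n_factors)]),
        uniquenesses=pd.Series(psi, index=names, name="uniqueness"),
        factor_corr=Phi,
        rmsr=rmsr,
        tli=tli,
        score_weights=pd.DataFrame(W, index=names, columns=[f"F{k+1}" for k in range(n_factors)]),
        score_validity=validity,
        score_r2=validity**2,
        corr=pd.DataFrame(R, index=names, columns=names),
        n_obs=n_obs,
        objective_path=path,
    )


def _tucker_lewis(R: np.ndarray, implied: np.ndarray, p: int, m: int,
                  n_obs: int | None) -> float:
    """Tucker-Lewis index from the ML discrepancy evaluated at the ULS solution."""
    if n_obs is None:
        return float("nan")
    sign, logdet_sigma = np.linalg.slogdet(implied)
    if sign <= 0:
        return float("nan")
    _, logdet_r = np.linalg.slogdet(R)
    F = logdet_sigma - logdet_r + float(np.trace(R @ linalg.inv(implied))) - p
    scale = n_obs - 1 - (2 * p + 5) / 6.0 - 2 * m / 3.0
    chi2_m = max(F, 0.0) * scale
    df_m = ((p - m) ** 2 - p - m) / 2.0
    chi2_0, df_0, _ = bartlett_sphericity(R, n_obs)
    if df_m <= 0 or chi2_0 / df_0 <= 1:
        return float("nan")
    return float((chi2_0 / df_0 - chi2_m / df_m) / (chi2_0 / df_0 - 1.0))


# ---------------------------------------------------------------------------
# factor scores
# ---------------------------------------------------------------------------

def factor_scores(model: FactorModel, table: ScoreTable) -> GScores:
    """Thurstone regression scores for the first (general) factor.

    Scores are computed over the combined sample from z-scored tests and
    re-standardised to mean 0 / SD 1 on the estimation sample.
    """
    missing = set(model.test_names) - set(table.test_names)
    if missing:
        raise ValueError(f"tests missing from table: {sorted(missing)}")
    Z = table.standardized()[model.test_names].to_numpy()
    raw = Z @ model.score_weights.to_numpy()[:, 0]
    g = (raw - raw.mean()) / raw.std(ddof=1)
    return GScores(g=pd.Series(g, index=table.scores.index, name="g"))


def extract_g(table: ScoreTable, n_factors: int | None = None) -> dict:
    """Full g-extraction pipeline on a score table.

    Returns adequacy diagnostics, MAP factor counts under both criteria,
    the fitted one-factor (or overridden) model and per-subject g scores.
    """
    if len(table.test_names) < 3:
        raise ValueError("factor extraction needs at least 3 tests")
    R = table.correlation()
    n = table.n_subjects
    rep = adequacy(R, n)
    map1976 = map_test(R, "1976")
    map2000 = map_test(R, "2000")
    m = n_factors if n_factors is not None else max(map1976, 1)
    model = efa(R, m, n_obs=n)
    scores = factor_scores(model, table)
    return {
        "adequacy": rep,
        "map_1976": map1976,
        "map_2000": map2000,
        "model": model,
        "gscores": scores,
    }
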