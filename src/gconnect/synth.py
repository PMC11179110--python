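"""Synthetic cohorts with planted structure for the g/connectome analysis.

Three generators emulate the statistical structure the downstream analysis
assumes, so every stage can be exercised and validated without any scan or
test data:

* :func:`simulate_battery` — a cognitive battery driven by a single latent
  factor (the positive manifold), with a standardized group shift on the
  latent factor itself;
* :func:`simulate_connectomes` — per-subject modular correlation matrices
  with a group difference in within-module correlation (modular
  segregation), Fisher-z transformed;
* :func:`simulate_covariates` — clinical/sociodemographic covariates with
  chosen linear relationships to the latent factor, including a two-level
  neighbourhood-deprivation category.

Latent truths (the factor, the module labels) are always returned with the
data: recovery of planted structure is the package's validation surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import substream
from .connectome import ConnectivityMatrix, ParcellationScheme
from .psychometrics import ScoreTable

__all__ = [
    "BatterySpec",
    "NetworkSpec",
    "simulate_battery",
    "simulate_connectomes",
    "simulate_covariates",
]


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

@dataclass
class BatterySpec:
    """One-factor battery: scores x_ij = lambda_j f_i + eps_ij.

    Defaults emulate an 11-test neuropsychological battery with moderate
    general-factor loadings and a patient deficit of 0.85 pooled SD on the
    latent factor (the observed case-control effect size on g). When
    ``noise_sd`` is None, residual SDs are sqrt(1 - lambda²) so each test
    has unit population variance and inter-test correlations equal
    lambda_i * lambda_j.
    """

    n_per_group: int = 100
    loadings: np.ndarray = field(default_factory=lambda: np.full(11, 0.7))
    group_shift: float = -0.85
    noise_sd: np.ndarray | float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.loadings = np.atleast_1d(np.asarray(self.loadings, dtype=float))
        if np.any(self.loadings <= 0) or np.any(self.loadings >= 1):
            raise ValueError("loadings must be strictly between 0 and 1")
        if self.n_per_group < 3:
            raise ValueError("need at least 3 subjects per group")
        if self.noise_sd is None:
            self.noise_sd = np.sqrt(1.0 - self.loadings**2)
        else:
            self.noise_sd = np.broadcast_to(
                np.asarray(self.noise_sd, dtype=float), self.loadings.shape
            ).copy()
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be nonnegative")

    def implied_correlation(self) -> np.ndarray:
        """Population correlation matrix of the test scores."""
        lam = self.loadings
        cov = np.outer(lam, lam) + np.diag(self.noise_sd**2)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)


def simulate_battery(spec: BatterySpec) -> ScoreTable:
    """Draw a two-group battery from the one-factor model in ``spec``.

    Group 1 ("patient") has its latent factor mean shifted by
    ``spec.group_shift``. The true latent factor is stored on the returned
    table (``latent_g``) for recovery tests. Deterministic under the seed.
    """
    p = len(spec.loadings)
    implied = spec.implied_correlation()
    eigmin = float(np.linalg.eigvalsh(implied).min())
    if not np.isfinite(eigmin) or (p > 1 and eigmin <= 1e-10):
        raise ValueError(
            f"implied correlation matrix is not positive definite "
            f"(min eigenvalue {eigmin:.3g}); increase noise_sd"
        )
    rng = substream(spec.seed, "battery")
    n = 2 * spec.n_per_group
    group = np.repeat([0, 1], spec.n_per_group)
    f = rng.standard_normal(n) + spec.group_shift * group
    eps = rng.standard_normal((n, p)) * spec.noise_sd
    X = f[:, None] * spec.loadings + eps

    ids = pd.Index([f"s{i:04d}" for i in range(n)], name="subject_id")
    names = [f"test{j+1:02d}" for j in range(p)]
    return ScoreTable(
        scores=pd.DataFrame(X, index=ids, columns=names),
        group=pd.Series(group, index=ids, name="group"),
        latent_g=pd.Series(f, index=ids, name="latent_g"),
    )


# ---------------------------------------------------------------------------
# connectomes
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Modular correlation structure with a group segregation deficit.

    The population matrix has correlation ``within_corr`` inside modules and
    ``between_corr`` across them; the patient group's within-module
    correlation is reduced by ``group_delta`` (lower modular segregation,
    which raises participation and lowers clustering/modularity). Subject
    heterogeneity is i.i.d. symmetric noise on the off-diagonals followed by
    a positive-semidefinite repair.
    """

    n_nodes: int = 90
    module_sizes: np.ndarray = field(default_factory=lambda: np.full(6, 15))
    within_corr: float = 0.5
    between_corr: float = 0.1
    subject_noise_sd: float = 0.06
    group_delta: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_sizes = np.asarray(self.module_sizes, dtype=int)
        if int(self.module_sizes.sum()) != self.n_nodes:
            raise ValueError(
                f"module_sizes sum to {int(self.module_sizes.sum())}, "
                f"expected n_nodes={self.n_nodes}"
            )
        if not (0 <= self.between_corr < self.within_corr < 1):
            raise ValueError("require 0 <= between_corr < within_corr < 1")
        if self.within_corr - self.group_delta <= self.between_corr:
            raise ValueError("group_delta would erase the modular structure")

    def module_labels(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)

    def parcellation(self) -> ParcellationScheme:
        return ParcellationScheme(
            module_of=np.array([f"M{k}" for k in self.module_labels()])
        )

    def template(self, group: int) -> np.ndarray:
        """Population correlation matrix for a group (before Fisher z)."""
        within = self.within_corr - (self.group_delta if group == 1 else 0.0)
        labels = self.module_labels()
        same = labels[:, None] == labels[None, :]
        C = np.where(same, within, self.between_corr)
        np.fill_diagonal(C, 1.0)
        return C


def _nearest_psd_corr(C: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue clipping at ``eig_floor`` then renormalization to unit diagonal."""
    vals, vecs = np.linalg.eigh((C + C.T) / 2.0)
    vals = np.clip(vals, eig_floor, None)
    C2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(C2))
    C2 = C2 / np.outer(d, d)
    np.fill_diagonal(C2, 1.0)
    return C2


def _fisher_z(C: np.ndarray) -> np.ndarray:
    z = np.arctanh(np.clip(C, -0.999999, 0.999999))
    np.fill_diagonal(z, 0.0)
    return (z + z.T) / 2.0


def simulate_connectomes(
    spec: NetworkSpec, n_subjects_per_group: int
) -> list[ConnectivityMatrix]:
    """Per-subject Fisher-z connectivity matrices with planted modules.

    Each subject's correlation matrix is the group template plus symmetric
    off-diagonal noise, repaired to the nearest positive-semidefinite
    correlation matrix, then Fisher-z transformed with zero diagonal.
    """
    rng = substream(spec.seed, "connectomes")
    N = spec.n_nodes
    iu = np.triu_indices(N, 1)
    out: list[ConnectivityMatrix] = []
    for group in (0, 1):
        template = spec.template(group)
        for s in range(n_subjects_per_group):
            C = template.copy()
            if spec.subject_noise_sd > 0:
                noise = rng.standard_normal(len(iu[0])) * spec.subject_noise_sd
                C[iu] += noise
                C.T[iu] = C[iu]
                C = _nearest_psd_corr(C)
            z = _fisher_z(C)
            out.append(
                ConnectivityMatrix(
                    z=z, subject_id=f"g{group}s{s:03d}", group=group
                )
            )
    return out


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def simulate_covariates(
    g_true: pd.Series | np.ndarray,
    coeffs: dict[str, float],
    seed: int = 0,
    noise_sd: float = 1.0,
    adi_slope: float | None = None,
) -> pd.DataFrame:
    """Covariates with chosen linear dependence on the latent factor.

    Each entry of ``coeffs`` maps a covariate name to its slope on g; the
    covariate is slope * g + N(0, noise_sd). If ``adi_slope`` is given, a
    two-level neighbourhood-deprivation category ``adi`` is added
    ("advantaged"/"disadvantaged", split at the latent median), with a
    negative slope making low-g subjects more likely disadvantaged.
    """
    g = np.asarray(g_true, dtype=float)
    index = g_true.index if isinstance(g_true, pd.Series) else pd.RangeIndex(len(g))
    for name, slope in coeffs.items():
        if not np.isfinite(slope):
            raise ValueError(f"slope for {name!r} must be finite")
    rng = substream(seed, "covariates")
    cols = {}
    for name, slope in coeffs.items():
        cols[name] = slope * g + rng.standard_normal(len(g)) * noise_sd
    df = pd.DataFrame(cols, index=index)
    if adi_slope is not None:
        latent = adi_slope * g + rng.standard_normal(len(g)) * noise_sd
        df["adi"] = np.where(
            latent > np.median(latent), "disadvantaged", "advantaged"
        )
    return df
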