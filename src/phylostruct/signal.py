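"""Pagel's lambda phylogenetic signal for continuous traits.

Under Brownian motion the tree alone fixes the expected trait covariance:
``cov(x_i, x_j) = sigma^2 * C_ij`` with ``C_ij`` the shared root-to-MRCA
path length.  Pagel's lambda rescales the off-diagonal of ``C`` by a factor
``lambda in [0, 1]``: at 1 trait similarity tracks relatedness exactly
(niche conservatism); at 0 tips are phylogenetically independent.

The fit maximizes the profile log-likelihood over lambda; for fixed lambda
the root state ``mu`` and rate ``sigma^2`` have closed-form GLS solutions

    mu_hat     = (1' V^-1 x) / (1' V^-1 1)
    sigma2_hat = (x - mu_hat 1)' V^-1 (x - mu_hat 1) / n

with ``V = lambda_transform(C, lambda)``.  Significance is a likelihood-
ratio test of lambda_hat against lambda = 0 with a chi-square(1) reference,
halved because the null lies on the boundary of the parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import chi2

from phylostruct.tree import Phylogeny, PhyloCovariance, normalize_label

__all__ = [
    "SignalResult",
    "lambda_transform",
    "bm_loglik",
    "profile_loglik",
    "fit_lambda",
    "signal_report",
]

_GRID = np.linspace(0.0, 1.0, 21)


@dataclass(frozen=True)
class SignalResult:
    """Maximum-likelihood lambda fit for one trait."""

    trait: str
    lam: float
    sigma2: float
    mu: float
    loglik: float          # at lambda_hat
    loglik0: float         # at lambda = 0
    pvalue: float          # boundary-halved LRT
    n: int                 # species used

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda outside [0, 1]")
        if self.loglik < self.loglik0 - 1e-8:
            raise ValueError("profile optimum below the lambda=0 likelihood")


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal covariances by ``lam``; diagonal unchanged."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    V = C.values * lam
    np.fill_diagonal(V, np.diag(C.values))
    return PhyloCovariance(C.labels, V)


def _cho_factor_ridged(V: np.ndarray):
    """Cholesky with an escalating tiny ridge: trees with effectively
    duplicated tips (zero-length pendant edges) make C numerically
    singular at lambda near 1."""
    scale = float(np.mean(np.diag(V))) or 1.0
    for ridge in (0.0, 1e-12, 1e-10, 1e-8, 1e-6):
        try:
            return linalg.cho_factor(
                V + ridge * scale * np.eye(V.shape[0]), lower=True
            )
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance matrix is singular")


def _loglik_core(x: np.ndarray, V: np.ndarray) -> tuple[float, float, float]:
    """Profile out (mu, sigma2) for a fixed covariance structure V.

    Returns (loglik, mu_hat, sigma2_hat).  Raises on singular V or a
    zero-variance trait.
    """
    n = x.size
    cho = _cho_factor_ridged(V)
    ones = np.ones(n)
    Vi1 = linalg.cho_solve(cho, ones)
    Vix = linalg.cho_solve(cho, x)
    mu = float(ones @ Vix) / float(ones @ Vi1)
    r = x - mu
    q = float(r @ linalg.cho_solve(cho, r))
    if q <= 0:
        raise ValueError("zero-variance trait: likelihood degenerate")
    s2 = q / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    ll = -0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n)
    return ll, mu, s2


def bm_loglik(
    x: np.ndarray, C: PhyloCovariance, sigma2: float, mu: float
) -> float:
    """Log density of ``x`` under N(mu * 1, sigma2 * C)."""
    x = np.asarray(x, dtype=float)
    if x.size != len(C.labels):
        raise ValueError("trait vector length does not match covariance")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    n = x.size
    cho = linalg.cho_factor(sigma2 * C.values, lower=True)
    r = x - mu
    q = float(r @ linalg.cho_solve(cho, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + q)


def profile_loglik(lam: float, x: np.ndarray, C: PhyloCovariance) -> float:
    """Profile log-likelihood of lambda (mu, sigma2 profiled out)."""
    V = lambda_transform(C, lam)
    return _loglik_core(np.asarray(x, dtype=float), V.values)[0]


def fit_lambda(
    tree: Phylogeny | PhyloCovariance,
    x,
    trait_name: str = "trait",
) -> SignalResult:
    """ML fit of Pagel's lambda on [0, 1].

    ``x`` is a mapping/Series from species label to trait value; species
    absent from the tree are ignored, species with missing values dropped.
    A 21-point grid pre-scan guards the bounded scalar optimizer against
    local optima.
    """
    C_full = tree.covariance() if isinstance(tree, Phylogeny) else tree
    series = pd.Series(x, dtype=float)
    series.index = [normalize_label(i) for i in series.index]
    series = series.dropna()
    labels_norm = {normalize_label(l): l for l in C_full.labels}
    common = [l for l in series.index if l in labels_norm]
    if len(common) < 4:
        raise ValueError(
            f"need >= 4 species with trait values in the tree, got {len(common)}"
        )
    sub = C_full.submatrix([labels_norm[l] for l in common])
    xv = series.loc[common].to_numpy()
    if np.ptp(xv) == 0:
        raise ValueError("zero-variance trait")

    def negll(lam: float) -> float:
        return -profile_loglik(lam, xv, sub)

    grid_ll = np.array([-negll(l) for l in _GRID])
    i = int(np.argmax(grid_ll))
    lo = _GRID[max(i - 1, 0)]
    hi = _GRID[min(i + 1, len(_GRID) - 1)]
    best_lam, best_ll = float(_GRID[i]), float(grid_ll[i])
    if hi > lo:
        res = optimize.minimize_scalar(
            negll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        if -res.fun > best_ll:
            best_lam, best_ll = float(np.clip(res.x, 0.0, 1.0)), float(-res.fun)

    ll0 = float(grid_ll[0])
    V = lambda_transform(sub, best_lam)
    _, mu, s2 = _loglik_core(xv, V.values)
    lr = max(0.0, 2.0 * (best_ll - ll0))
    p = 1.0 if lr <= 1e-12 else float(0.5 * chi2.sf(lr, df=1))
    return SignalResult(
        trait=trait_name, lam=best_lam, sigma2=s2, mu=mu,
        loglik=best_ll, loglik0=ll0, pvalue=p, n=len(common),
    )


def signal_report(
    tree: Phylogeny,
    traits: pd.DataFrame,
    log_transform: bool = False,
) -> pd.DataFrame:
    """One lambda fit per trait column; returns a table with columns
    trait, lambda, p, sigma2, mu, loglik, loglik0, n.

    ``traits`` is indexed by species label.  With ``log_transform`` every
    trait is log-transformed (uniformly) before fitting; values must then
    be strictly positive.
    """
    C = tree.covariance()
    rows = []
    for col in traits.columns:
        x = traits[col].dropna()
        if log_transform:
            if (x <= 0).any():
                raise ValueError(
                    f"log transform requires positive values ({col})"
                )
            x = np.log(x)
        res = fit_lambda(C, x, trait_name=col)
        rows.append(
            {
                "trait": res.trait,
                "lambda": res.lam,
                "p": res.pvalue,
                "sigma2": res.sigma2,
                "mu": res.mu,
                "loglik": res.loglik,
                "loglik0": res.loglik0,
                "n": res.n,
            }
        )
    if not rows:
        raise ValueError("no traits to analyze")
    return pd.DataFrame(rows)
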