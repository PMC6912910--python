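"""Climate-table handling, aridity index, PCA habitat space, UPGMA
grouping, and Last Glacial Maximum (LGM) anomalies.

The climate table carries the 21 standard factors per plot: the 19
bioclimatic variables Bio1-Bio19 (temperatures in deg C, precipitation in
mm), potential evapotranspiration PET (mm/yr), and the aridity index
AI = Bio12 / PET (unitless; AI < 0.3 conventionally separates arid from
semiarid).  Habitat groups come from PCA on the standardized variables
(components kept until >= 85% cumulative variance) followed by UPGMA on
Euclidean distances in that component space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

__all__ = [
    "BIO_COLUMNS",
    "CLIMATE_COLUMNS",
    "LGM_COLUMNS",
    "aridity_index",
    "classify_aridity",
    "validate_climate_table",
    "read_climate",
    "PCAResult",
    "climate_pca",
    "select_components",
    "HabitatGroups",
    "upgma_groups",
    "linkage_to_newick",
    "climate_anomaly",
]

BIO_COLUMNS = [f"bio{i}" for i in range(1, 20)]
CLIMATE_COLUMNS = BIO_COLUMNS + ["pet", "ai"]
#: LGM counterparts of annual mean temperature (Bio1/AMT), mean temperature
#: of the driest quarter (Bio9/MTD) and annual precipitation (Bio12/AP).
LGM_COLUMNS = ["lgm_bio1", "lgm_bio9", "lgm_bio12"]
ANOMALY_NAMES = {"bio1": "d_amt", "bio9": "d_mtd", "bio12": "d_ap"}


def aridity_index(map_mm: float, pet_mm: float) -> float:
    """AI = mean annual precipitation / potential evapotranspiration."""
    if pet_mm <= 0:
        raise ValueError("PET must be positive")
    if map_mm < 0:
        raise ValueError("MAP must be nonnegative")
    return map_mm / pet_mm


def classify_aridity(ai: float) -> str:
    """Arid below 0.3; the boundary value itself counts as semiarid."""
    return "arid" if ai < 0.3 else "semiarid"


def validate_climate_table(df: pd.DataFrame) -> None:
    """Check the 21-column contract: all current-climate columns present,
    AI positive, Bio5 >= Bio6 and Bio7 = Bio5 - Bio6 (within 0.5 for
    source rounding)."""
    missing = [c for c in CLIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing climate columns: {missing}")
    if (df["ai"] <= 0).any():
        raise ValueError("AI must be positive")
    if (df["bio5"] < df["bio6"]).any():
        raise ValueError("Bio5 < Bio6: max warm-month temperature below "
                         "min cold-month temperature")
    resid = (df["bio7"] - (df["bio5"] - df["bio6"])).abs()
    if (resid > 0.5).any():
        raise ValueError("Bio7 inconsistent with Bio5 - Bio6 beyond 0.5")


def read_climate(path) -> pd.DataFrame:
    """Read a plot x climate CSV (plot id in the first column), validate
    the 21-variable contract, and return it indexed by plot."""
    df = pd.read_csv(path, comment="#")
    df = df.set_index(df.columns[0])
    df.index.name = "plot"
    df.columns = [c.lower() for c in df.columns]
    validate_climate_table(df)
    return df


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame        # plot x component, zero column means
    loadings: pd.DataFrame      # variable x component
    variance_fractions: np.ndarray

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.variance_fractions)


def climate_pca(table: pd.DataFrame, columns=None) -> PCAResult:
    """PCA of the climate table on standardized variables (correlation
    scale): the factors mix deg C, mm, and unitless quantities, so raw
    covariance would be dominated by precipitation variance.

    Constant columns are dropped with a warning; missing values refuse to
    fit (no silent imputation).
    """
    cols = list(columns) if columns is not None else [
        c for c in CLIMATE_COLUMNS if c in table.columns
    ]
    X = table[cols]
    if len(X) < 3:
        raise ValueError("need >= 3 plots for PCA")
    if X.isna().to_numpy().any():
        raise ValueError("missing values in climate table (imputation refused)")
    sd = X.std(ddof=1)
    const = sd.index[sd == 0].tolist()
    if const:
        warnings.warn(f"dropping constant climate columns: {const}",
                      stacklevel=2)
        X = X.drop(columns=const)
        sd = sd.drop(index=const)
    Z = (X - X.mean()) / sd
    n_comp = min(len(Z) - 1, Z.shape[1])
    fit = PCA(n_components=n_comp, svd_solver="full").fit(Z)
    scores = pd.DataFrame(
        fit.transform(Z), index=table.index,
        columns=[f"pc{k+1}" for k in range(n_comp)],
    )
    loadings = pd.DataFrame(
        fit.components_.T, index=X.columns, columns=scores.columns,
    )
    frac = fit.explained_variance_ratio_
    return PCAResult(scores=scores, loadings=loadings,
                     variance_fractions=frac)


def select_components(fractions, threshold: float = 0.85) -> int:
    """Smallest k whose cumulative variance fraction reaches ``threshold``."""
    f = np.asarray(fractions, dtype=float)
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    cum = np.cumsum(f)
    hit = np.nonzero(cum >= threshold - 1e-12)[0]
    if hit.size == 0:
        return int(np.count_nonzero(f > 0))
    return int(hit[0]) + 1


@dataclass(frozen=True)
class HabitatGroups:
    labels: pd.Series           # plot -> 1..k (1 = largest group)
    linkage: np.ndarray         # scipy linkage matrix (merge heights)
    k: int
    scores: pd.DataFrame        # the PCA scores clustered

    def __post_init__(self) -> None:
        if self.labels.isna().any():
            raise ValueError("every plot must be assigned a group")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def upgma_groups(scores: pd.DataFrame, n_groups: int = 3) -> HabitatGroups:
    """UPGMA (average linkage) on Euclidean distances between PCA scores,
    cut to exactly ``n_groups`` clusters.

    Labels are canonicalized (1..k by decreasing group size, ties broken
    by the smallest plot id), so they do not depend on input order.
    """
    scores = pd.DataFrame(scores)
    if n_groups > len(scores):
        raise ValueError("more groups than plots")
    # stable plot order so that scipy's tie-breaking is input-order free
    ordered = scores.sort_index(kind="stable")
    Z = linkage(pdist(ordered.to_numpy()), method="average")
    raw = fcluster(Z, t=n_groups, criterion="maxclust")
    lab = pd.Series(raw, index=ordered.index, name="group")
    order = sorted(
        lab.unique(),
        key=lambda g: (-(lab == g).sum(), min(lab.index[lab == g].astype(str))),
    )
    remap = {g: i + 1 for i, g in enumerate(order)}
    lab = lab.map(remap).reindex(scores.index)
    return HabitatGroups(labels=lab, linkage=Z, k=int(lab.nunique()),
                         scores=scores)


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Render a scipy linkage matrix as Newick with merge heights turned
    into branch lengths (dendrogram export)."""
    names = list(leaf_names)
    n = len(names)
    height = {i: 0.0 for i in range(n)}
    text = {i: str(names[i]) for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + k
        height[node] = float(h)
        la = height[node] - height[a]
        lb = height[node] - height[b]
        text[node] = f"({text[a]}:{la:.10g},{text[b]}:{lb:.10g})"
    return text[n + len(Z) - 1] + ";\n"


def climate_anomaly(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plot current-minus-LGM anomalies for AMT (Bio1), MTD (Bio9) and
    AP (Bio12), plus a mean +/- SD (n-1) summary per variable.

    A |delta AMT| above 30 deg C indicates mismatched units (e.g. deg C x 10
    dialect) and raises.
    """
    missing = [c for c in LGM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing LGM columns: {missing}")
    out = pd.DataFrame(index=table.index)
    for cur, name in ANOMALY_NAMES.items():
        out[name] = table[cur] - table[f"lgm_{cur}"]
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError("non-finite anomaly values")
    if (out["d_amt"].abs() > 30).any():
        raise ValueError("|delta AMT| > 30 deg C: probable unit mismatch "
                         "between current and LGM temperatures")
    summary = pd.DataFrame(
        {"mean": out.mean(), "sd": out.std(ddof=1)}
    )
    summary.index.name = "variable"
    return out, summary
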