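"""Mean pairwise distance, the randomization null, and the net relatedness
index (NRI).

For a plot with species weights ``w`` (importance values) and patristic
distances ``d_ij``, the abundance-weighted MPD is

    MPD = sum_{i<j} w_i w_j d_ij / sum_{i<j} w_i w_j

(unweighted: plain mean over unordered pairs).  The null model preserves
richness and the observed abundance multiset: each of ``n_rand`` draws
samples S species uniformly without replacement from the regional pool and
reassigns the observed importance values to them in random order.  Then

    NRI = -1 * (MPD_obs - mean(MPD_rand)) / SD(MPD_rand)

so NRI > 0 flags phylogenetic clustering (co-occurring species closer than
expected; habitat filtering), NRI < 0 overdispersion (limiting similarity).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from phylostruct.stats import wilcoxon_signed_rank
from phylostruct.tree import DistanceMatrix, Phylogeny, normalize_label

__all__ = [
    "NullDistribution",
    "NRIResult",
    "mpd",
    "null_mpd",
    "nri",
    "nri_batch",
    "pd_sr_table",
    "read_community",
    "write_community",
]


@dataclass(frozen=True)
class NullDistribution:
    """MPD values under the richness/abundance-preserving null."""

    values: np.ndarray
    n_rand: int
    seed: object
    model: str = "richness"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size != self.n_rand:
            raise ValueError("null distribution length != n_rand")
        if (v < 0).any():
            raise ValueError("negative MPD in null distribution")
        object.__setattr__(self, "values", v)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))


@dataclass(frozen=True)
class NRIResult:
    plot: object
    richness: int
    mpd_obs: float
    null_mean: float
    null_sd: float
    nri: Optional[float]
    classification: str  # clustered | overdispersed | random/undefined


def _mpd_core(D: np.ndarray, w: np.ndarray, weighted: bool) -> float:
    if weighted:
        num = float(w @ D @ w)            # = 2 * sum_{i<j} w_i w_j d_ij
        den = float(w.sum() ** 2 - (w ** 2).sum())
    else:
        num = float(D.sum())
        s = D.shape[0]
        den = float(s * (s - 1))
    return num / den


def mpd(
    weights: Mapping[str, float],
    D: DistanceMatrix,
    weighted: bool = True,
) -> float:
    """MPD of one community; ``weights`` maps species to importance value.

    Species with zero weight are ignored.  Invariant to rescaling all
    weights by a positive constant.
    """
    present = [(sp, w) for sp, w in weights.items() if w > 0]
    if any(w < 0 for w in weights.values()):
        raise ValueError("negative importance value")
    if len(present) < 2:
        raise ValueError("MPD undefined for fewer than 2 species")
    norm = {normalize_label(l): i for i, l in enumerate(D.labels)}
    try:
        idx = np.array([norm[normalize_label(sp)] for sp, _ in present])
    except KeyError as exc:
        raise KeyError(f"species not in distance matrix: {exc}") from exc
    w = np.array([v for _, v in present], dtype=float)
    return _mpd_core(D.values[np.ix_(idx, idx)], w, weighted)


def null_mpd(
    richness: int,
    weights: Sequence[float],
    pool: Sequence[str],
    D: DistanceMatrix,
    n_rand: int = 999,
    seed=None,
    weighted: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> NullDistribution:
    """Null MPD distribution: S species drawn uniformly without replacement
    from ``pool``, observed abundances reassigned in random order.

    Vectorized over draws; reproducible given ``seed`` (or a Generator).
    """
    S = int(richness)
    if S < 2:
        raise ValueError("richness must be >= 2")
    if S > len(pool):
        raise ValueError("richness exceeds pool size")
    w = np.asarray(list(weights), dtype=float)
    if w.size != S:
        raise ValueError("abundance multiset length != richness")
    if rng is None:
        rng = np.random.default_rng(seed)
    norm = {normalize_label(l): i for i, l in enumerate(D.labels)}
    pool_idx = np.array([norm[normalize_label(p)] for p in pool])
    # random S-subsets in random order: weights in fixed order against a
    # randomly ordered species draw == random abundance reassignment
    draws = np.argsort(rng.random((n_rand, pool_idx.size)), axis=1)[:, :S]
    sampled = pool_idx[draws]
    Dsub = D.values[sampled[:, :, None], sampled[:, None, :]]
    if weighted:
        num = np.einsum("rij,i,j->r", Dsub, w, w)
        den = w.sum() ** 2 - (w ** 2).sum()
    else:
        num = Dsub.sum(axis=(1, 2))
        den = S * (S - 1)
    return NullDistribution(num / den, n_rand=n_rand, seed=seed)


def nri(observed: float, null: NullDistribution, plot=None, richness: int = 0) -> NRIResult:
    """NRI = -1 * (MPD_obs - mean(MPD_rand)) / SD(MPD_rand); SD with n-1.

    SD = 0 (degenerate null) yields classification "random/undefined" with
    a missing NRI.
    """
    if null.values.size == 0:
        raise ValueError("empty null distribution")
    m, s = null.mean, null.sd
    if s <= 1e-12 * max(1.0, abs(m)):  # degenerate null (e.g. S = pool)
        return NRIResult(plot, richness, observed, m, s, None, "random/undefined")
    val = -1.0 * (observed - m) / s
    if val > 0:
        cls = "clustered"
    elif val < 0:
        cls = "overdispersed"
    else:
        cls = "random/undefined"
    return NRIResult(plot, richness, observed, m, s, val, cls)


def _community_wide(comm: pd.DataFrame) -> pd.DataFrame:
    if (comm.to_numpy() < 0).any():
        raise ValueError("negative importance values in community matrix")
    return comm


def nri_batch(
    comm: pd.DataFrame,
    tree: Phylogeny,
    n_rand: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Per-plot NRI for a wide plot x species matrix of importance values.

    The regional pool is the union of species observed with positive weight
    across all plots (all must be tree tips).  Each plot gets its own child
    seed derived from (master seed, row position), so results do not depend
    on evaluation order.  Plots with fewer than 2 species are skipped.

    Returns (per-plot table, summary dict with the clustered/overdispersed
    percentages and a Wilcoxon signed-rank test of NRI against zero).
    """
    comm = _community_wide(comm)
    if comm.empty:
        raise ValueError("empty community matrix")
    present_any = comm.columns[(comm > 0).any(axis=0)]
    tip_norms = {normalize_label(l) for l in tree.tip_labels}
    unknown = [s for s in present_any if normalize_label(s) not in tip_norms]
    if unknown:
        raise KeyError(f"community species not in tree: {sorted(unknown)}")
    D = tree.distances()
    pool = list(present_any)

    rows = []
    skipped = []
    root = np.random.SeedSequence(seed)
    for i, (plot, row) in enumerate(comm.iterrows()):
        w = row[row > 0]
        if w.size < 2:
            skipped.append(plot)
            continue
        obs = mpd(w.to_dict(), D, weighted=weighted)
        child = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        )
        null = null_mpd(
            w.size, w.to_numpy(), pool, D,
            n_rand=n_rand, seed=None, weighted=weighted, rng=child,
        )
        rows.append(nri(obs, null, plot=plot, richness=int(w.size)))
    _ = root  # master seed recorded via spawn keys above

    table = pd.DataFrame(
        {
            "plot": [r.plot for r in rows],
            "S": [r.richness for r in rows],
            "mpd_obs": [r.mpd_obs for r in rows],
            "null_mean": [r.null_mean for r in rows],
            "null_sd": [r.null_sd for r in rows],
            "nri": [r.nri for r in rows],
            "class": [r.classification for r in rows],
        }
    )
    defined = table.dropna(subset=["nri"])
    n_def = len(defined)
    summary = {
        "n_plots": int(len(comm)),
        "n_skipped": len(skipped),
        "skipped_plots": [str(p) for p in skipped],
        "n_defined": int(n_def),
        "pct_clustered": float(100.0 * (defined["nri"] > 0).sum() / n_def)
        if n_def else float("nan"),
        "pct_overdispersed": float(100.0 * (defined["nri"] < 0).sum() / n_def)
        if n_def else float("nan"),
        "mean_nri": float(defined["nri"].mean()) if n_def else float("nan"),
    }
    if n_def >= 3 and (defined["nri"] != 0).any():
        stat, p = wilcoxon_signed_rank(defined["nri"].to_numpy())
        summary["wilcoxon_vs_zero_p"] = float(p)
    else:
        summary["wilcoxon_vs_zero_p"] = float("nan")
    return table, summary


def pd_sr_table(comm: pd.DataFrame, tree: Phylogeny) -> pd.DataFrame:
    """Per-plot Faith's PD (root-inclusive) and species richness."""
    comm = _community_wide(comm)
    rows = []
    for plot, row in comm.iterrows():
        present = row[row > 0].index.tolist()
        pd_val = tree.faith_pd(present) if present else 0.0
        rows.append({"plot": plot, "pd": pd_val, "sr": len(present)})
    return pd.DataFrame(rows)


def read_community(path: str | Path) -> pd.DataFrame:
    """Read a community matrix CSV, long (plot,species,importance_value)
    or wide (plot index, one column per species).  Returns wide."""
    df = pd.read_csv(path, comment="#")
    cols = [c.lower() for c in df.columns]
    if cols[:3] == ["plot", "species", "importance_value"] or (
        len(df.columns) == 3 and "species" in cols
    ):
        df.columns = ["plot", "species", "importance_value"]
        wide = df.pivot_table(
            index="plot", columns="species",
            values="importance_value", aggfunc="sum", fill_value=0.0,
        )
        wide.columns.name = None
        return wide
    wide = df.set_index(df.columns[0])
    wide.index.name = "plot"
    return wide.astype(float)


def write_community(comm: pd.DataFrame, path: str | Path) -> None:
    """Write wide community matrix to CSV (plot index, species columns)."""
    out = comm.copy()
    out.index.name = "plot"
    out.to_csv(path, float_format="%.10g")
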