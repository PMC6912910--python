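"""Synthetic data with the statistical structure the analysis assumes.

The generators emulate the shape of a dryland shrub-community survey:
an ultrametric birth-death phylogeny (~47 angiosperm species, optional
distant gymnosperm outgroup), four positive functional traits evolved with
controllable Pagel's lambda, ~116 plots of richness 2-15 assembled
neutrally / by habitat filtering / by limiting similarity with log-normal
importance values, and 21 correlated bioclimatic variables driven by three
latent habitat factors (moisture, temperature, seasonality) plus LGM
offsets.  Everything is deterministic given a seed and the default fixture
is byte-stable.

Trees are rescaled to unit root-to-tip depth, so a Brownian rate of 1
gives tip trait SD ~= 1; filtering width tau and limiting radius delta are
expressed on that trait scale.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml
from dendropy.simulate import treesim

from phylostruct.tree import Phylogeny

__all__ = [
    "SynthConfig",
    "simulate_tree",
    "add_outgroup",
    "simulate_traits",
    "simulate_communities",
    "simulate_climate",
    "make_fixture",
]

#: study-scale habitat archetypes on the latent (moisture, temperature,
#: seasonality) axes: sandy = warm/humid, steppified = cold transition,
#: desert = warm/extremely arid
_GROUP_ARCHETYPES = {
    1: (1.0, 0.5, -0.3),
    2: (0.0, -1.0, 0.5),
    3: (-1.0, 0.5, 0.0),
}


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults mirror the survey scale that the
    analysis is designed for (47 species, 116 plots, 3 habitat groups with
    sizes 12/17/87, richness 2-15)."""

    seed: int = 0
    n_species: int = 47
    n_plots: int = 116
    birth_rate: float = 0.4          # Myr^-1
    death_rate: float = 0.1          # Myr^-1
    trait_lambdas: dict = field(
        default_factory=lambda: {
            "height_m": 0.05,
            "canopy_m2": 0.05,
            "leaf_length_mm": 0.5,
            "leaf_width_mm": 0.75,
        }
    )
    trait_sigma2: float = 0.25       # Brownian rate on the log scale
    trait_means: dict = field(
        default_factory=lambda: {
            "height_m": -0.2,        # ~0.8 m
            "canopy_m2": -0.7,       # ~0.5 m^2
            "leaf_length_mm": 2.3,   # ~10 mm
            "leaf_width_mm": 1.1,    # ~3 mm
        }
    )
    assembly_mode: str = "neutral"   # neutral | filtering | limiting
    filter_tau: float = 0.3          # filtering width, trait-SD units
    niche_dim: int = 5               # conserved niche axes for limiting
    limiting_delta: float = 2.0      # rejection radius in niche space
    richness_range: tuple = (2, 15)
    n_groups: int = 3
    group_sizes: Optional[tuple] = None   # default: 12/17/87 scaled
    climate_effect: float = 3.0      # latent-factor group separation (SD)
    lgm_offsets: dict = field(
        default_factory=lambda: {
            "d_amt": (6.37, 0.55),   # deg C since the LGM
            "d_mtd": (5.38, 2.20),   # deg C
            "d_ap": (41.05, 21.28),  # mm
        }
    )
    importance_sigma: float = 1.0    # log-normal importance values

    def __post_init__(self) -> None:
        if self.birth_rate <= self.death_rate or self.death_rate < 0:
            raise ValueError("need birth rate > death rate >= 0")
        for name, lam in self.trait_lambdas.items():
            if not 0 <= lam <= 1:
                raise ValueError(f"lambda for {name} outside [0, 1]")
        lo, hi = self.richness_range
        hi = min(hi, self.n_species)  # small pools cap plot richness
        self.richness_range = (lo, hi)
        if not (2 <= lo <= hi):
            raise ValueError("richness range must lie within [2, n_species]")


def _derive_seed(seed: int, *key: int) -> int:
    """Deterministic child seed below 2^31 for python/dendropy RNGs."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def simulate_tree(
    n_species: int = 47,
    birth_rate: float = 0.4,
    death_rate: float = 0.1,
    seed: int = 0,
    scale_depth: Optional[float] = 1.0,
    max_tries: int = 100,
) -> Phylogeny:
    """Ultrametric birth-death tree conditioned on ``n_species`` extant
    tips, rescaled to root-to-tip depth ``scale_depth`` (None keeps the
    simulated time scale).

    Total extinction triggers a bounded retry; tips are labelled sp001..
    in a reproducible order.
    """
    last: Exception | None = None
    for attempt in range(max_tries):
        rng = _pyrandom.Random(_derive_seed(seed, attempt))
        try:
            # general sampling approach: pick a random time at which the
            # process has exactly n tips, avoiding zero-length pendant
            # edges from stopping exactly at a birth event
            dtree = treesim.birth_death_tree(
                birth_rate=birth_rate,
                death_rate=death_rate,
                num_extant_tips=n_species,
                gsa_ntax=n_species + 2,
                rng=rng,
            )
            break
        except Exception as exc:  # total extinction
            last = exc
    else:
        raise RuntimeError(
            f"birth-death simulation failed after {max_tries} tries: {last}"
        )
    leaves = list(dtree.leaf_node_iter())
    for i, leaf in enumerate(leaves):
        label = f"sp{i + 1:03d}"
        if leaf.taxon is None:
            leaf.taxon = dtree.taxon_namespace.new_taxon(label)
        else:
            leaf.taxon.label = label
    dtree.seed_node.edge.length = None
    depth = max(
        leaf.distance_from_root() for leaf in dtree.leaf_node_iter()
    )
    if depth <= 0:
        raise RuntimeError("degenerate simulated tree")
    if scale_depth is not None:
        f = scale_depth / depth
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= f
    return Phylogeny(dtree)


def add_outgroup(
    tree: Phylogeny,
    labels: Sequence[str],
    depth_factor: float = 3.0,
    crown_fraction: float = 0.15,
) -> Phylogeny:
    """Attach a distant outgroup clade (e.g. gymnosperms) below a new root.

    The new root sits ``depth_factor`` x the ingroup depth above the tips;
    the outgroup crown diverges at ``crown_fraction`` of that depth.  The
    result stays ultrametric and ingroup patristic distances are unchanged.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("need at least one outgroup label")
    depths = tree.covariance()
    T = float(np.max(np.diag(depths.values)))
    F = depth_factor * T
    ingroup = tree.to_newick().strip().rstrip(";")
    crown = crown_fraction * F
    safe = [l.replace(" ", "_") for l in labels]
    if len(safe) == 1:
        og = f"{safe[0]}:{F:.12g}"
    else:
        tips = ",".join(f"{l}:{crown:.12g}" for l in safe)
        og = f"({tips}):{F - crown:.12g}"
    newick = f"({ingroup}:{F - T:.12g},{og});\n"
    return Phylogeny.from_newick(newick)


def simulate_traits(
    tree: Phylogeny,
    lam: float,
    sigma2: float = 1.0,
    mu: float = 0.0,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> pd.Series:
    """One draw from N(mu * 1, sigma2 * lambda_transform(C, lam))."""
    from phylostruct.signal import lambda_transform

    if not 0 <= lam <= 1:
        raise ValueError("lambda outside [0, 1]")
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    C = tree.covariance()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(C.labels)
    if sigma2 == 0:
        return pd.Series(np.full(n, mu), index=list(C.labels))
    V = sigma2 * lambda_transform(C, lam).values
    L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
    x = mu + L @ rng.standard_normal(n)
    return pd.Series(x, index=list(C.labels))


def simulate_niche(
    tree: Phylogeny,
    n_axes: int = 5,
    sigma2: float = 1.0,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Fully conserved (lambda = 1) multivariate niche: ``n_axes``
    independent Brownian axes.  With several axes the Euclidean niche
    distance between two species tracks their patristic distance closely
    (E[dist^2] = 2 * n_axes * sigma2 * (depth - C_ij)), which is what makes
    trait-based limiting similarity produce phylogenetic overdispersion."""
    if rng is None:
        rng = np.random.default_rng(seed)
    cols = {}
    for k in range(n_axes):
        cols[f"axis{k + 1}"] = simulate_traits(
            tree, 1.0, sigma2, 0.0, rng=rng
        )
    return pd.DataFrame(cols)


def _select_filtering(
    trait: np.ndarray, S: int, opt: float, tau: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Weighted sampling without replacement, inclusion weight
    proportional to exp(-(t - opt)^2 / (2 tau^2)) (Gumbel top-k)."""
    logw = -((trait - opt) ** 2) / (2.0 * tau ** 2)
    keys = logw + rng.gumbel(size=trait.size)
    return np.argsort(keys)[::-1][:S]


def _select_limiting(
    niche: np.ndarray, S: int, delta: float,
    rng: np.random.Generator, max_tries: int = 25,
) -> np.ndarray:
    """Sequential sampling rejecting candidates within Euclidean niche
    distance ``delta`` of an already-selected species; if infeasible after
    ``max_tries`` permutation scans, delta relaxes by 10% with a warning."""
    d = delta
    while True:
        for _ in range(max_tries):
            perm = rng.permutation(niche.shape[0])
            chosen: list[int] = []
            for cand in perm:
                if not chosen or np.min(
                    np.linalg.norm(niche[cand] - niche[chosen], axis=1)
                ) >= d:
                    chosen.append(int(cand))
                    if len(chosen) == S:
                        return np.array(chosen)
        d *= 0.9
        warnings.warn(
            f"limiting-similarity draw infeasible; relaxing delta to {d:.4g}",
            stacklevel=2,
        )
        if d < 1e-6:
            raise RuntimeError("limiting-similarity sampler cannot satisfy S")


def simulate_communities(
    tree: Phylogeny,
    trait: Optional[pd.Series | pd.DataFrame],
    n_plots: int = 116,
    mode: str | Sequence[str] = "neutral",
    richness_range: tuple = (2, 15),
    tau: float = 0.3,
    delta: float = 2.0,
    optima: Optional[Sequence[float]] = None,
    importance_sigma: float = 1.0,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    plot_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Assemble plots from the species pool; returns a wide plot x species
    importance-value matrix.

    ``mode`` is one of neutral / filtering / limiting, or a per-plot
    sequence.  ``trait`` is a species Series (one niche axis) or DataFrame
    (multivariate niche).  Filtering admits species near a plot niche
    optimum with Gaussian width ``tau``: given a scalar trait (or explicit
    per-plot ``optima``, which tie the optima to an environmental
    gradient) it acts on the first axis; given a multivariate niche the
    optimum is a random species' niche position (plus jitter), so the
    filter always targets occupied niche space.  Limiting similarity
    rejects candidates within Euclidean niche distance ``delta`` of an
    accepted species.  Importance values are log-normal (heavy-tailed
    dominance, as in shrub cover data).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    species = list(tree.tip_labels)
    n_sp = len(species)
    modes = [mode] * n_plots if isinstance(mode, str) else list(mode)
    if len(modes) != n_plots:
        raise ValueError("per-plot mode list length != n_plots")
    tvals = niche = None
    if any(m in ("filtering", "limiting") for m in modes):
        if trait is None:
            raise ValueError("trait required for non-neutral assembly")
        frame = trait.to_frame() if isinstance(trait, pd.Series) else trait
        niche = frame.reindex(species).to_numpy(dtype=float)
        if np.isnan(niche).any():
            raise ValueError("trait missing for some species")
        tvals = niche[:, 0]
    lo, hi = richness_range
    if plot_ids is None:
        plot_ids = [f"p{i + 1:03d}" for i in range(n_plots)]
    mat = np.zeros((n_plots, n_sp))
    for p in range(n_plots):
        S = int(rng.integers(lo, hi + 1))
        m = modes[p]
        if m == "neutral":
            idx = rng.choice(n_sp, size=S, replace=False)
        elif m == "filtering":
            if niche.shape[1] == 1 or optima is not None:
                opt = (
                    float(optima[p])
                    if optima is not None
                    else rng.uniform(tvals.min(), tvals.max())
                )
                idx = _select_filtering(tvals, S, opt, tau, rng)
            else:
                # multivariate niche: plot optimum anchored at a random
                # species' niche position (keeps it in occupied niche space)
                opt_vec = niche[rng.integers(n_sp)] + rng.normal(
                    0.0, tau / 2.0, size=niche.shape[1]
                )
                logw = -((niche - opt_vec) ** 2).sum(axis=1) / (
                    2.0 * tau ** 2
                )
                keys = logw + rng.gumbel(size=n_sp)
                idx = np.argsort(keys)[::-1][:S]
        elif m == "limiting":
            idx = _select_limiting(niche, S, delta, rng)
        else:
            raise ValueError(f"unknown assembly mode: {m}")
        mat[p, idx] = rng.lognormal(mean=0.0, sigma=importance_sigma, size=S)
    return pd.DataFrame(mat, index=pd.Index(plot_ids, name="plot"),
                        columns=species)


def simulate_climate(
    group_labels: Sequence[int],
    effect: float = 3.0,
    lgm_offsets: Optional[dict] = None,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    plot_ids: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """21 bioclimatic variables from 3 latent habitat factors, plus LGM
    columns.

    Groups are separated by ``effect`` latent-SD units along archetype
    directions; internal consistency is enforced (Bio7 = Bio5 - Bio6,
    Bio3 = Bio2*100/Bio7, AI = Bio12/PET > 0).  Returns (climate table,
    latent factor table with moisture/temperature/seasonality).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    groups = np.asarray(group_labels, dtype=int)
    n = groups.size
    if n == 0:
        raise ValueError("no plots")
    if lgm_offsets is None:
        lgm_offsets = SynthConfig().lgm_offsets
    arch = np.array(
        [
            _GROUP_ARCHETYPES.get(g, tuple(rng.standard_normal(3)))
            for g in groups
        ]
    )
    latent = effect * arch + rng.standard_normal((n, 3))
    m, t, s = latent[:, 0], latent[:, 1], latent[:, 2]

    def eps(scale: float) -> np.ndarray:
        return rng.normal(0.0, scale, size=n)

    df = pd.DataFrame(index=pd.Index(
        plot_ids if plot_ids is not None else [f"p{i+1:03d}" for i in range(n)],
        name="plot",
    ))
    df["bio1"] = 4.0 + 2.5 * t + eps(0.4)
    df["bio2"] = 14.0 + 1.0 * s + eps(0.15)
    df["bio4"] = 1200.0 + 150.0 * s + eps(20.0)
    df["bio5"] = 30.0 + 2.5 * t + 1.5 * s + eps(0.4)
    df["bio6"] = -22.0 + 3.0 * t - 2.0 * s + eps(0.4)
    df["bio7"] = df["bio5"] - df["bio6"]
    df["bio3"] = df["bio2"] * 100.0 / df["bio7"]
    df["bio8"] = 18.0 + 2.5 * t + eps(0.4)
    df["bio9"] = -12.0 + 3.0 * t - 1.5 * s + eps(0.4)
    df["bio10"] = 20.0 + 2.5 * t + eps(0.4)
    df["bio11"] = -15.0 + 3.0 * t - 1.5 * s + eps(0.4)
    ap = np.maximum(230.0 + 50.0 * m + eps(8.0), 5.0)
    df["bio12"] = ap
    df["bio13"] = 0.25 * ap * np.exp(eps(0.05))
    df["bio14"] = 0.012 * ap * np.exp(eps(0.08))
    df["bio15"] = 95.0 - 8.0 * m + eps(2.0)
    df["bio16"] = 0.55 * ap * np.exp(eps(0.04))
    df["bio17"] = 0.045 * ap * np.exp(eps(0.08))
    df["bio18"] = 0.50 * ap * np.exp(eps(0.04))
    df["bio19"] = 0.05 * ap * np.exp(eps(0.08))
    df["pet"] = 1100.0 - 60.0 * m + eps(15.0)
    df["ai"] = df["bio12"] / df["pet"]
    df["lgm_bio1"] = df["bio1"] - rng.normal(*lgm_offsets["d_amt"], size=n)
    df["lgm_bio9"] = df["bio9"] - rng.normal(*lgm_offsets["d_mtd"], size=n)
    df["lgm_bio12"] = df["bio12"] - rng.normal(*lgm_offsets["d_ap"], size=n)
    # column order: the 21-variable contract, then LGM
    from phylostruct.climate import CLIMATE_COLUMNS, LGM_COLUMNS

    df = df[CLIMATE_COLUMNS + LGM_COLUMNS]
    latents = pd.DataFrame(
        {"moisture": m, "temperature": t, "seasonality": s, "group": groups},
        index=df.index,
    )
    return df, latents


# ---------------------------------------------------------------------------
# Fixture assembly

_GYMNOSPERMS = ["Ephedra_przewalskii", "Ephedra_sinica"]
#: study-like group sizes (sandy / steppified / desert) for 116 plots
_GROUP_SIZE_RATIOS = (12, 17, 87)
#: per-habitat assembly: limiting similarity dominates in sandy and desert
#: habitats, habitat filtering in the steppified transition zone
_GROUP_MODES = {1: "limiting", 2: "filtering", 3: "limiting"}


def _group_sizes(n_plots: int, n_groups: int,
                 sizes: Optional[tuple]) -> np.ndarray:
    if sizes is not None:
        if len(sizes) != n_groups or sum(sizes) != n_plots:
            raise ValueError("group sizes must sum to n_plots")
        return np.asarray(sizes, dtype=int)
    ratios = np.asarray(_GROUP_SIZE_RATIOS[:n_groups], dtype=float)
    out = np.floor(ratios / ratios.sum() * n_plots).astype(int)
    out = np.maximum(out, 1)
    out[-1] += n_plots - out.sum()
    return out


def make_fixture(
    outdir: str | Path,
    seed: int = 0,
    config: Optional[SynthConfig] = None,
    gymnosperms: bool = True,
) -> dict[str, Path]:
    """Write a complete synthetic survey to ``outdir``: tree.nwk,
    community.csv (long), traits.csv, climate.csv, gymnosperms.txt,
    config.yaml.  Byte-identical across runs with the same seed.

    The angiosperm tree has ``n_species`` tips; a distant two-tip
    gymnosperm clade is grafted on and sprinkled into some plots so the
    clade-filtering step of the pipeline is exercised.  Habitat groups get
    study-like sizes and per-habitat assembly modes; filtering optima in
    the transition group track the latent moisture gradient, so
    NRI-climate correlations have a known sign.
    """
    cfg = config or SynthConfig(seed=seed)
    cfg.seed = seed
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    tree = simulate_tree(
        cfg.n_species, cfg.birth_rate, cfg.death_rate,
        seed=_derive_seed(seed, 1),
    )
    species = list(tree.tip_labels)

    # traits on the log scale (positivity by construction)
    traits_log = pd.DataFrame(index=pd.Index(species, name="species"))
    for k, (name, lam) in enumerate(sorted(cfg.trait_lambdas.items())):
        traits_log[name] = simulate_traits(
            tree, lam, cfg.trait_sigma2, cfg.trait_means[name],
            rng=np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(2, k))
            ),
        )
    traits = np.exp(traits_log)
    traits = traits[
        ["height_m", "canopy_m2", "leaf_length_mm", "leaf_width_mm"]
    ]

    # habitat truth and climate
    sizes = _group_sizes(cfg.n_plots, cfg.n_groups, cfg.group_sizes)
    groups = np.concatenate(
        [np.full(sz, g + 1, dtype=int) for g, sz in enumerate(sizes)]
    )
    plot_ids = [f"p{i + 1:03d}" for i in range(cfg.n_plots)]
    rng_clim = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(3,))
    )
    climate, latents = simulate_climate(
        groups, effect=cfg.climate_effect, lgm_offsets=cfg.lgm_offsets,
        rng=rng_clim, plot_ids=plot_ids,
    )
    rng_geo = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(4,))
    )
    lon = rng_geo.uniform(97.0, 112.0, size=cfg.n_plots)
    lat = rng_geo.uniform(37.0, 45.0, size=cfg.n_plots)

    # assembly: per-habitat mode on a latent conserved niche; filtering
    # optima on the first niche axis track the moisture gradient, giving
    # NRI-climate correlations a known sign
    modes = [_GROUP_MODES.get(g, cfg.assembly_mode) for g in groups]
    niche = simulate_niche(
        tree, n_axes=cfg.niche_dim,
        rng=np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(7,))
        ),
    )
    ax1 = niche.iloc[:, 0]
    mstd = (latents["moisture"] - latents["moisture"].mean()) / latents[
        "moisture"
    ].std(ddof=1)
    optima = ax1.mean() + ax1.std(ddof=1) * mstd.to_numpy()
    rng_comm = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(5,))
    )
    comm = simulate_communities(
        tree, niche, n_plots=cfg.n_plots, mode=modes,
        richness_range=cfg.richness_range, tau=cfg.filter_tau,
        delta=cfg.limiting_delta, optima=optima,
        importance_sigma=cfg.importance_sigma, rng=rng_comm,
        plot_ids=plot_ids,
    )

    full_tree = tree
    if gymnosperms:
        full_tree = add_outgroup(tree, _GYMNOSPERMS)
        rng_gym = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(6,))
        )
        for g in _GYMNOSPERMS:
            comm[g] = 0.0
        hosts = rng_gym.choice(
            cfg.n_plots, size=max(3, cfg.n_plots // 8), replace=False
        )
        for p in hosts:
            g = _GYMNOSPERMS[int(rng_gym.integers(len(_GYMNOSPERMS)))]
            comm.iloc[p, comm.columns.get_loc(g)] = rng_gym.lognormal(
                0.0, cfg.importance_sigma
            )

    paths = {
        "tree": out / "tree.nwk",
        "community": out / "community.csv",
        "traits": out / "traits.csv",
        "climate": out / "climate.csv",
        "clade_filter": out / "gymnosperms.txt",
        "config": out / "config.yaml",
        "truth": out / "truth.csv",
    }
    paths["tree"].write_text(full_tree.to_newick())
    long = (
        comm.stack()
        .rename("importance_value")
        .reset_index()
        .rename(columns={"level_1": "species"})
    )
    long = long[long["importance_value"] > 0]
    long.to_csv(paths["community"], index=False, float_format="%.10g")
    traits.to_csv(paths["traits"], float_format="%.10g")
    clim_out = climate.copy()
    clim_out.insert(0, "lat", lat)
    clim_out.insert(0, "lon", lon)
    clim_out.to_csv(paths["climate"], float_format="%.10g")
    paths["clade_filter"].write_text(
        "# gymnosperm taxa removed before phylogenetic analysis\n"
        + "".join(f"{g}\n" for g in _GYMNOSPERMS)
    )
    truth = pd.DataFrame(
        {"plot": plot_ids, "group": groups, "mode": modes}
    )
    truth.to_csv(paths["truth"], index=False)
    cfgdict = asdict(cfg)
    cfgdict["richness_range"] = list(cfg.richness_range)
    cfgdict["group_sizes"] = [int(x) for x in sizes]
    cfgdict["files"] = {k: v.name for k, v in paths.items()}
    paths["config"].write_text(
        yaml.safe_dump(cfgdict, sort_keys=True)
    )
    return paths
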