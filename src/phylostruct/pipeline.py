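"""Config-driven orchestration of the full analysis.

Stage order: trait signal -> clade filter -> NRI -> Faith's PD -> habitat
grouping (PCA + UPGMA) -> climate associations -> LGM anomaly.  Every
output CSV starts with a header comment carrying the seed and a hash of the
parameters that produced it; all randomness flows from the one master seed.
Results go to files, human-readable progress to stderr, so outputs stay
machine-readable.  Later stages re-read the CSVs written by earlier ones,
which makes ``run_all`` bitwise identical to running the subcommands in
sequence.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from phylostruct import climate as climod
from phylostruct import community as commod
from phylostruct import stats as statmod
from phylostruct.signal import signal_report
from phylostruct.tree import CladeFilter, Phylogeny

log = logging.getLogger("phylostruct")

__all__ = [
    "PipelineError",
    "RunConfig",
    "run_signal",
    "run_nri",
    "run_habitat",
    "run_associate",
    "run_all",
]

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """Stage-labelled pipeline failure."""


@dataclass
class RunConfig:
    """Paths and knobs for a full run."""

    tree: str
    community: str
    traits: str
    climate: str
    outdir: str
    clade_filter: Optional[str] = None
    n_rand: int = 999
    seed: int = 0
    n_groups: int = 3
    pca_threshold: float = 0.85
    weighted: bool = True
    log_transform_traits: bool = False
    pls_components: int = 3
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_rand < 1:
            raise ValueError("n_rand must be >= 1")
        if not (0 < self.pca_threshold <= 1):
            raise ValueError("PCA threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _param_hash(params: dict) -> str:
    """Stable short hash of stage parameters; path-like values reduce to
    their basename so reruns in different directories hash identically."""
    norm = {}
    for k, v in params.items():
        s = str(v)
        norm[k] = Path(s).name if ("/" in s or "\\" in s) else s
    blob = json.dumps(norm, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, seed: int, phash: str,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# phylostruct seed={seed} config={phash}\n")
        df.to_csv(fh, index=index, float_format=FLOAT_FMT)


def _load_tree(tree_path, clade_filter, stage: str) -> Phylogeny:
    p = Path(tree_path)
    if not p.exists():
        raise PipelineError(f"stage '{stage}': tree file not found: {p}")
    tree = Phylogeny.from_newick(p.read_text())
    if clade_filter:
        fp = Path(clade_filter)
        if not fp.exists():
            raise PipelineError(
                f"stage '{stage}': clade filter file not found: {fp}"
            )
        filt = CladeFilter.from_file(fp)
        before = len(tree)
        tree = tree.drop(filt)
        log.info("stage %s: clade filter removed %d of %d taxa",
                 stage, before - len(tree), before)
    return tree


def run_signal(
    tree_path, traits_path, outdir, seed: int = 0,
    clade_filter=None, log_transform: bool = False,
) -> Path:
    """Pagel's lambda per trait -> signal.csv."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    phash = _param_hash(dict(
        cmd="signal", tree=tree_path, traits=traits_path,
        clade_filter=clade_filter, log_transform=log_transform, seed=seed,
    ))
    try:
        tree = _load_tree(tree_path, clade_filter, "signal")
        tp = Path(traits_path)
        if not tp.exists():
            raise PipelineError(
                f"stage 'signal': trait file not found: {tp}"
            )
        traits = pd.read_csv(tp, index_col=0, comment="#")
        table = signal_report(tree, traits, log_transform=log_transform)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'signal': {exc}") from exc
    path = out / "signal.csv"
    _write_csv(table, path, seed, phash)
    log.info("stage signal: %d traits -> %s", len(table), path)
    return path


def run_nri(
    tree_path, community_path, outdir, seed: int = 0,
    clade_filter=None, n_rand: int = 999, weighted: bool = True,
) -> dict[str, Path]:
    """NRI per plot + summary + Faith's PD / richness tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    phash = _param_hash(dict(
        cmd="nri", tree=tree_path, community=community_path,
        clade_filter=clade_filter, n_rand=n_rand, weighted=weighted,
        seed=seed,
    ))
    try:
        tree = _load_tree(tree_path, clade_filter, "structure")
        cp = Path(community_path)
        if not cp.exists():
            raise PipelineError(
                f"stage 'structure': community file not found: {cp}"
            )
        comm = commod.read_community(cp)
        if clade_filter is not None:
            filt = {  # drop filtered taxa from the community as well
                commod.normalize_label(n)
                for n in CladeFilter.from_file(clade_filter).names
            }
            drop = [
                c for c in comm.columns
                if commod.normalize_label(c) in filt
            ]
            if drop:
                log.info(
                    "stage structure: dropping %d filtered taxa from "
                    "community matrix", len(drop),
                )
                comm = comm.drop(columns=drop)
        nri_df, summary = commod.nri_batch(
            comm, tree, n_rand=n_rand, seed=seed, weighted=weighted,
        )
        pdsr = commod.pd_sr_table(comm, tree)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'structure': {exc}") from exc
    paths = {
        "nri": out / "nri.csv",
        "pd_sr": out / "pd_sr.csv",
        "nri_summary": out / "nri_summary.json",
    }
    _write_csv(nri_df, paths["nri"], seed, phash)
    _write_csv(pdsr, paths["pd_sr"], seed, phash)
    paths["nri_summary"].write_text(
        json.dumps({"seed": seed, "config": phash, **summary},
                   indent=2, sort_keys=True) + "\n"
    )
    log.info(
        "stage structure: %d plots (%d skipped), %.1f%% clustered / "
        "%.1f%% overdispersed",
        summary["n_plots"], summary["n_skipped"],
        summary["pct_clustered"], summary["pct_overdispersed"],
    )
    return paths


def run_habitat(
    climate_path, outdir, seed: int = 0, n_groups: int = 3,
    pca_threshold: float = 0.85,
) -> dict[str, Path]:
    """Climate PCA, UPGMA habitat groups, and LGM anomalies."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    phash = _param_hash(dict(
        cmd="habitat", climate=climate_path, n_groups=n_groups,
        pca_threshold=pca_threshold, seed=seed,
    ))
    cp = Path(climate_path)
    if not cp.exists():
        raise PipelineError(
            f"stage 'habitat': climate file not found: {cp}"
        )
    try:
        clim = climod.read_climate(cp)
        pca = climod.climate_pca(clim)
        k = climod.select_components(
            pca.variance_fractions, pca_threshold
        )
        scores = pca.scores.iloc[:, :k]
        groups = climod.upgma_groups(scores, n_groups=n_groups)
        anomaly = None
        if all(c in clim.columns for c in climod.LGM_COLUMNS):
            anomaly = climod.climate_anomaly(clim)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'habitat': {exc}") from exc
    paths = {
        "pca_scores": out / "pca_scores.csv",
        "pca_variance": out / "pca_variance.csv",
        "groups": out / "groups.csv",
        "dendrogram": out / "dendrogram.nwk",
    }
    _write_csv(scores, paths["pca_scores"], seed, phash, index=True)
    var = pd.DataFrame({
        "component": [f"pc{i+1}" for i in
                      range(len(pca.variance_fractions))],
        "variance_fraction": pca.variance_fractions,
        "cumulative": pca.cumulative(),
    })
    _write_csv(var, paths["pca_variance"], seed, phash)
    gdf = groups.labels.rename("group").reset_index()
    _write_csv(gdf, paths["groups"], seed, phash)
    paths["dendrogram"].write_text(
        f"[phylostruct seed={seed} config={phash}]\n"
        + climod.linkage_to_newick(
            groups.linkage, scores.sort_index().index
        )
    )
    if anomaly is not None:
        table, summ = anomaly
        paths["anomaly"] = out / "anomaly.csv"
        paths["anomaly_summary"] = out / "anomaly_summary.csv"
        _write_csv(table, paths["anomaly"], seed, phash, index=True)
        _write_csv(summ, paths["anomaly_summary"], seed, phash, index=True)
    log.info("stage habitat: %d PCs kept (%.1f%% variance), %d groups",
             k, 100 * pca.cumulative()[k - 1], groups.k)
    return paths


def run_associate(
    nri_path, pd_sr_path, climate_path, groups_path, outdir,
    seed: int = 0, pls_components: int = 3,
) -> dict[str, Path]:
    """Spearman NRI-climate matrix, PLS report, per-group summaries."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    phash = _param_hash(dict(
        cmd="associate", nri=nri_path, pd_sr=pd_sr_path,
        climate=climate_path, groups=groups_path,
        pls_components=pls_components, seed=seed,
    ))
    try:
        for label, p in [("NRI table", nri_path), ("PD table", pd_sr_path),
                         ("climate table", climate_path),
                         ("groups table", groups_path)]:
            if not Path(p).exists():
                raise PipelineError(
                    f"stage 'associate': {label} not found: {p}"
                )
        nri_df = pd.read_csv(nri_path, comment="#").set_index("plot")
        pdsr = pd.read_csv(pd_sr_path, comment="#").set_index("plot")
        clim = climod.read_climate(climate_path)
        groups = (
            pd.read_csv(groups_path, comment="#")
            .set_index("plot")["group"]
        )
        nri_ser = nri_df["nri"].dropna()
        factors = clim[[c for c in climod.CLIMATE_COLUMNS
                        if c in clim.columns]]
        anomaly_cols = [c for c in climod.LGM_COLUMNS
                        if c in clim.columns]
        assoc_input = factors.copy()
        if len(anomaly_cols) == len(climod.LGM_COLUMNS):
            anom, _ = climod.climate_anomaly(clim)
            assoc_input = assoc_input.join(anom)
        assoc = statmod.nri_climate_spearman(
            nri_ser, assoc_input, groups
        )
        pls_rows = []
        for gname, idx in [("all", nri_ser.index)] + [
            (str(g), groups.index[groups == g]) for g in
            sorted(groups.unique())
        ]:
            idx = pd.Index(idx).intersection(nri_ser.index).intersection(
                factors.index
            )
            row = {"group": gname, "n": int(len(idx))}
            try:
                res = statmod.pls_regression(
                    factors.loc[idx], nri_ser.loc[idx],
                    n_components=pls_components,
                )
                for k in range(pls_components):
                    row[f"r2y_cum_{k+1}"] = res.r2y_cumulative[k]
                    row[f"r2x_cum_{k+1}"] = res.r2x_cumulative[k]
                row["skipped"] = False
            except ValueError as exc:
                row["skipped"] = True
                row["reason"] = str(exc)
            pls_rows.append(row)
        pls_df = pd.DataFrame(pls_rows)
        metrics = nri_df[["nri"]].join(pdsr[["pd", "sr"]])
        per_group, pairwise = statmod.group_summaries(
            metrics, groups
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'associate': {exc}") from exc
    paths = {
        "assoc": out / "assoc.csv",
        "pls": out / "pls.csv",
        "group_stats": out / "group_stats.csv",
        "group_pairwise": out / "group_pairwise.csv",
    }
    _write_csv(assoc, paths["assoc"], seed, phash)
    _write_csv(pls_df, paths["pls"], seed, phash)
    _write_csv(per_group, paths["group_stats"], seed, phash)
    _write_csv(pairwise, paths["group_pairwise"], seed, phash)
    log.info("stage associate: %d correlations, %d PLS fits",
             len(assoc), len(pls_df))
    return paths


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write a run manifest.

    Idempotent given the seed; rerunning with the same config reproduces
    every output byte for byte.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["signal"] = run_signal(
        config.tree, config.traits, out, seed=config.seed,
        clade_filter=config.clade_filter,
        log_transform=config.log_transform_traits,
    )
    paths.update(run_nri(
        config.tree, config.community, out, seed=config.seed,
        clade_filter=config.clade_filter, n_rand=config.n_rand,
        weighted=config.weighted,
    ))
    paths.update(run_habitat(
        config.climate, out, seed=config.seed,
        n_groups=config.n_groups, pca_threshold=config.pca_threshold,
    ))
    paths.update(run_associate(
        paths["nri"], paths["pd_sr"], config.climate, paths["groups"],
        out, seed=config.seed, pls_components=config.pls_components,
    ))
    cfgdict = asdict(config)
    manifest = {
        "seed": config.seed,
        "config": cfgdict,
        "config_hash": _param_hash(cfgdict),
        "outputs": {
            k: {
                "file": v.name,
                "sha256": hashlib.sha256(v.read_bytes()).hexdigest(),
            }
            for k, v in sorted(paths.items())
        },
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mpath
    log.info("run complete: %d outputs in %s", len(paths), out)
    return paths
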