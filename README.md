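# phylostruct

Community phylogenetic structure of dryland shrub vegetation: phylogenetic
signal of functional traits (Pagel's λ), net relatedness index (NRI)
against a richness- and abundance-preserving randomization null, Faith's
phylogenetic diversity, climate-based habitat grouping (PCA + UPGMA), and
the association of community structure with current climate and
paleoclimate change since the Last Glacial Maximum.

It is written for plant community ecologists working with plot surveys:
a plot × species matrix of importance values, a time-calibrated phylogeny
of the regional species pool, a species × trait table, and a plot ×
bioclimatic table (Bio1–Bio19, PET, AI).  Everything is also runnable end
to end on a built-in synthetic survey generator that mimics an arid-zone
shrub data set (47 species, 116 plots, three climate habitats), so the
whole pipeline is testable without any external data.

## The statistics at the core

**Pagel's λ.** Under Brownian motion a tree implies trait covariance
`cov(x_i, x_j) = σ²·C_ij`, `C_ij` the shared root-to-ancestor path
length.  λ rescales the off-diagonal of `C`; the ML fit profiles μ and σ²
out in closed form and maximizes over λ ∈ [0, 1].  λ ≈ 1: trait similarity
tracks relatedness (niche conservatism); λ ≈ 0: phylogenetic independence.
Significance is a boundary-halved likelihood-ratio test against λ = 0.

**NRI.** For each plot, the abundance-weighted mean pairwise patristic
distance

    MPD = Σ_{i<j} w_i w_j d_ij / Σ_{i<j} w_i w_j

is compared with a null that redraws the same number of species from the
regional pool (999×), keeping the observed abundance multiset:

    NRI = −1 × (MPD_obs − mean(MPD_rand)) / SD(MPD_rand)

NRI > 0 — phylogenetic clustering (habitat filtering); NRI < 0 —
overdispersion (limiting similarity).

**Habitats.** PCA on the 21 standardized climate variables, components
kept to ≥ 85% cumulative variance, UPGMA on Euclidean distances in that
space, dendrogram cut at k = 3 groups.  Group differences in NRI / PD /
richness use exact Wilcoxon tests; NRI–climate associations use Spearman
correlations and PLS regression (NIPALS, R²Y reported per component).

See `docs/methods.md` for conventions (root-inclusive PD, weighted-MPD
pair definition, null-model details) and the synthetic generator's design.

## Worked example

The numbered scripts under `analysis/` run the full study on the
synthetic survey (writing tables under `results/`):

```sh
python analysis/01_simulate_survey.py      # tree, traits, plots, climate
python analysis/02_trait_signal.py         # Pagel's lambda per trait
python analysis/03_community_structure.py  # NRI + PD + richness
python analysis/04_habitat_groups.py       # PCA + UPGMA + LGM anomalies
python analysis/05_climate_associations.py # Spearman + PLS + group tests
```

Step 02 prints the signal table (the generator evolves leaf traits
conserved, size traits labile — and the fit recovers that):

```
         trait   lambda            p  n
      height_m 0.052024 2.946806e-01 47
     canopy_m2 0.000000 1.000000e+00 47
leaf_length_mm 0.693214 1.685941e-04 47
 leaf_width_mm 0.789745 7.780244e-08 47

traits with significant phylogenetic signal (p < .05): ['leaf_length_mm', 'leaf_width_mm']
```

Step 03 summarizes the community structure after gymnosperm filtering
(the survey assembles desert and sandy plots by limiting similarity,
steppified plots by habitat filtering):

```
116 plots analyzed (0 skipped): 78.45% overdispersed, 21.55% clustered
mean NRI = -0.513, Wilcoxon vs zero p = 1.1e-08
```

Step 04 recovers the three climate habitats and the LGM warming signal
built into the generator:

```
2 components retained (cumulative variance 87.08%)
habitat group sizes: {1: 86, 2: 17, 3: 13}
climate change since the LGM (mean +/- SD):
  d_amt: 6.44 +/- 0.52
  d_mtd: 5.38 +/- 2.22
  d_ap: 42.02 +/- 20.94
```

and step 05 shows the interpretive layer: the large desert group and the
sandy group are significantly overdispersed (p < .01), the cold
steppified transition group trends toward clustering (median NRI +0.30,
p = .11), and pooled NRI correlates most strongly with winter-temperature
factors (Bio6/Bio9/Bio11).

The same stages are available as a console tool over your own files
(`phylostruct signal|nri|habitat|associate|all`), e.g.:

```sh
phylostruct all --tree tree.nwk --community community.csv \
    --traits traits.csv --climate climate.csv \
    --clade-filter gymnosperms.txt --outdir out --seed 1 --n-rand 999
```

Every output CSV carries a `# phylostruct seed=… config=…` header and a
rerun with the same seed is byte-for-byte identical.

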