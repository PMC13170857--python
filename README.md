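# zooarch

Quantitative analysis of archaeological faunal assemblages: assemblage
quantification, radiocarbon-based phasing, diversity diachronics,
fish-ecology ordination for palaeo-environmental reconstruction, and
optimal-foraging prey-choice models — as one tested Python pipeline.

The package is aimed at zooarchaeologists and statistical ecologists who
work with multi-site bone-count datasets (NISP/MNI tables) spanning long
time ranges, and who want every analytical step — from curation rules to
ordination eigenvalues — reproducible from the command line or a script.

## What it computes

**Quantification.** Long-format taxon × site count records (NISP = number
of identified specimens, MNI = minimum number of individuals) are
validated, curated (sites below a NISP threshold dropped, unidentifiable
material excluded, fish MNI set to 1 per taxon/site because fish skeletal
redundancy makes element-based MNI unreliable) and aggregated to count
matrices at species-group, family or class level.

**Chronology.** Radiocarbon determinations are calibrated against a
tabulated curve: `prob(t) ∝ N(age_bp; c14(t), √(σ_lab² + σ_curve²(t)))` on
a 1-year calendar grid. Sites are placed at the median of their dates'
medians and partitioned into chronological groups by *exact* 1-D k-means
(dynamic programming over contiguous partitions of the sorted ages).

**Diversity.** Simpson's index `D = 1 − Σ pᵢ²` per site at every
level/basis combination; family-level D regressed on class-level D with a
95% confidence band to flag assemblages dominated by single families;
LOESS (degree-1, tricube, span 0.75) trends of D against median age;
Welch t-tests between chronological slices.

**Environmental ordination.** Fish taxa are mapped to salinity and
sediment preference categories (configurable trait map, default
shipped); the binary site × category incidence matrix is ordinated by
correspondence analysis (chi-square-residual SVD), with segment-wise
detrending to remove the arch artefact.

**Prey choice.** Profitability as post-encounter return rate
`PERR = e/h × 60` (kcal/hour; e = caloric return per individual, h =
handling time in minutes). Model a: Pearson correlation of PERR with
%NISP. Model b: Spearman correlation of PERR and NISP ranks. Plus
habitat shares (marine/coastal/terrestrial) and diachronic energetics of
the fish catch with pairwise Welch tests.

**Synthetic data.** A seeded generator emulates the whole study design —
Dirichlet-multinomial site compositions, a planted declining diversity
trend, salinity-filtered fish communities, radiocarbon dates by inverse
curve lookup, and abundance ranks coupled to PERR at a tunable Spearman
strength — so every stage is testable without any downloads.

## Worked example

Generate a synthetic 17-site dataset and run the full pipeline:

```bash
zooarch simulate --seed 42 --outdir demo
cat > demo/config.yaml <<EOF
assemblage_csv: demo/assemblage.csv
c14_csv: demo/c14.csv
curve_path: demo/curve.14c
trait_map_path: demo/traits.yaml
nutrition_csv: demo/nutrition.csv
outdir: demo/run
seed: 42
EOF
zooarch all --config demo/config.yaml
```

`demo/run/summary.json` then contains (abridged):

```json
{
  "curation":   {"n_sites": 17, "total_nisp": 8075, "total_mni": 659},
  "chronology": {"n_sites_dated": 17, "k": 4},
  "feri": {
    "salinity": {"eigenvalues": [0.3, 0.025]},
    "sediment": {"eigenvalues": [0.228106, 0.045007]}
  },
  "diversity": {"d_group_nisp": {"SYN001": 0.74417, "SYN002": 0.867958}}
}
```

Reading this: 17 sites survived curation with 8075 identified specimens;
the k-means chronology found 4 groups; the salinity ordination has a
dominant first gradient (eigenvalue 0.30 vs 0.025 — most inter-site
structure is one salinity axis); per-site group-level Simpson diversity
is in the 0.74–0.87 range, i.e. moderately even assemblages. The same
JSON carries the family-level slice t-tests and per-site prey-choice
correlations (`model_b_rho`, `model_b_p`): a significant positive rho
means abundance tracks profitability at that site.

The packaged reference dataset (17 excavations from a former fjord on
Lolland, Denmark) is available via
`zooarch.datasets.load_fjord_overview()`; its totals are NISP 8767 and
MNI (excl. fish) 472, with class sums fish 4050, mammals 4355, birds 266.

## Layout

- `src/zooarch/assemblage.py` — data model, I/O, curation, aggregation
- `src/zooarch/chronology.py` — calibration, medians, k-means, time slices
- `src/zooarch/diversity.py` — Simpson D, regression, LOESS, Welch tests
- `src/zooarch/feri.py` — trait matrices, CA/DCA ordination
- `src/zooarch/prey_choice.py` — PERR, models a/b, habitat, energetics
- `src/zooarch/synthetic.py` — seeded scenario generators
- `src/zooarch/pipeline.py`, `cli.py` — orchestration and the `zooarch` command
- `docs/methods.md` — models, assumptions, parameter choices, limitations
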