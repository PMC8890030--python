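# richconn

Rich-club analysis of functional brain connectomes, packaged as a tested,
reproducible pipeline: from parcel-level BOLD time series to normalized
rich-club curves, rich / feeder / local edge classes, nodal efficiency,
edgewise group statistics with FDR control, and behavioral / radiomic
correlations.

## The problem

Resting-state fMRI connectomes of clinical cohorts — here modeled on a
three-group post-stroke cognitive impairment design (healthy controls,
hemorrhagic-stroke patients, infarct-stroke patients) — are commonly
analyzed through their *rich-club organization*: the tendency of
high-degree hub regions to be more densely interconnected than a
degree-matched random network would predict. The analysis asks which part
of the network a disease process disturbs: the hub core ("rich" edges),
the core-periphery links ("feeder" edges), or the periphery ("local"
edges), and how that disturbance relates to cognition scores and to
lesion radiomics.

## The statistics at the core

For a binary graph, the rich-club coefficient at degree level *k* is the
edge density among nodes of degree strictly greater than *k*:

    φ(k) = 2 E₍>k₎ / ( N₍>k₎ (N₍>k₎ − 1) )

Because hubs are interconnected by chance alone, φ(k) is normalized by
the mean coefficient of an ensemble of degree-preserving randomized
graphs (double-edge-swap rewiring):

    φ_norm(k) = φ(k) / ⟨φ_random(k)⟩ ,   φ_norm(k) > 1 ⇒ rich-club organization

Connectomes are built per subject as 116×116 (AAL atlas) Pearson
correlation matrices of detrended, band-passed (0.01–0.08 Hz) parcel
time series, binarized across a proportional sparsity sweep
(0.05–0.5, step 0.01). Group comparisons run per edge on Fisher-z values
(one-way ANOVA gate, patient-vs-control t tests, Benjamini–Hochberg FDR
per contrast), per k on subject-level φ_norm curves, and per node on
efficiency (mean inverse shortest-path length). Lesions contribute
first-order intensity statistics and 3D shape features (volume,
boundary-face surface area, sphericity, maximum 3D diameter, elongation,
flatness), with two-rater reliability summarized by the
absolute-agreement ICC(2,1).

Because public data for this design are unavailable, the package ships a
first-class synthetic cohort generator (`richconn.synthetic_cohort`) that
plants known ground truth — a dense 17-node core, attenuated
feeder/local coupling in patient groups, behavior scores linearly coupled
to the attenuation, lesion geometry coupled to it too — so every stage of
the pipeline can be validated by parameter recovery. Real data can be
supplied as parcels×time TSV matrices and NIfTI lesion volumes.

## Worked example

A reduced end-to-end run (17 subjects, 40 nodes with a planted 6-node
core, five sparsity levels, 100-graph null ensembles):

```bash
richconn run --test-profile --seed 1 --out demo_run
richconn report --run-dir demo_run
```

prints

```
richconn 0.1.0 (config b257c47e4560d5d1, seed 1)
subjects: {'HC': 6, 'hPSCI': 5, 'iPSCI': 6}
rich nodes: Parcel_000, Parcel_001, Parcel_002, Parcel_003, Parcel_004, Parcel_005
significant k windows: {'hPSCI': [3, 3], 'iPSCI': None}
significant decreased edges by class: {'hPSCI': {'feeder': 1, 'local': 9, 'rich': 0}, 'iPSCI': {'feeder': 4, 'local': 23, 'rich': 0}}
top aberrant nodes [hPSCI]: Parcel_032 (4), Parcel_008 (3)
top aberrant nodes [iPSCI]: Parcel_037 (7), Parcel_032 (6)
```

Reading this: the top-15% degree selection recovered exactly the six
planted core nodes; the significantly decreased connections are feeder
and local edges while the planted rich-club core shows zero significant
losses — the disturbance pattern the pipeline is designed to detect.
Every reported number is traceable to a TSV table in `demo_run/`
(`edge_stats.tsv`, `phinorm_stats.tsv`, `node_frequency.tsv`, ...), and
rerunning with the same config and seed reproduces `report.json`
byte for byte.

Library use mirrors the CLI:

```python
from richconn import planted_core_graph, BinaryGraph, normalized_rich_club

adj, core = planted_core_graph(n_nodes=116, density=0.10, core_size=17, seed=0)
profile = normalized_rich_club(BinaryGraph(adj), n_null=100, seed=0)
print(profile.as_frame().head(8))   # k, phi, null mean/sd, phi_norm
```

## Layout

| module | contents |
| --- | --- |
| `richconn.synthetic_cohort` | cohort spec, ground-truth weights, series/behavior/lesion generator, planted-core benchmark graph |
| `richconn.connectome` | panel preprocessing, correlation/Fisher-z matrices, sparsity thresholding and sweep |
| `richconn.richclub` | φ(k), degree-preserving rewiring, φ_norm(k), rich-node selection, edge classes, nodal efficiency |
| `richconn.group_analysis` | edgewise/curvewise ANOVA + t + BH-FDR, aberrant-node ranking, Pearson correlation tables, ICC(2,1) |
| `richconn.lesion_features` | ellipsoidal lesion simulator, first-order and 3D shape radiomics, NIfTI I/O |
| `richconn.pipeline` | `AnalysisConfig`, end-to-end `run()`, TSV/JSON outputs |
| `richconn.cli` | `richconn simulate / connectome / richclub / stats / run / report` |

See `docs/methods.md` for the model, parameter defaults, numerical
choices, and known limitations.
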