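# ivdkit

Analysis toolkit for studies of diabetic intervertebral-disc (IVD)
pathology in mouse models. Chronic type-2 diabetes fosters an inflammatory
microenvironment in the disc; characterizing it requires four distinct
computational pipelines that this package implements as one tested library:

1. **Cytokine screening** — multiplex panel preprocessing (median collapse
   of pseudo-replicates, exclusion of cytokines with >25% out-of-range
   readings), Welch's t-test differential screening, and per-animal fold
   changes over the control-group mean, compared across diabetic models.
2. **Correlation networks** — per-group Pearson matrices thresholded at
   |r| > 0.7 into undirected cytokine graphs; eigenvector and betweenness
   centrality, hub ranking, average shortest finite path length, Louvain
   communities with Newman–Girvan modularity Q, k-hop reachability
   (k = 1, 2), and Jaccard similarity between the reachability relations of
   two groups.
3. **Micro-CT morphometry** — Gaussian smoothing, whole-disc masks morphed
   from sparse perimeter contours by signed-distance interpolation, NP
   segmentation (Otsu + morphological close/open + largest component), and
   the NPVF (NP/disc volume fraction), NI/DI (NP/disc intensity ratio) and
   DHI (mid-sagittal height/width) metrics.
4. **Mechanics & phenotyping** — loading slope, loss tangent tan δ from the
   force-displacement phase delay, and hysteresis energy per cycle from
   sinusoidal compression records; glucose-tolerance AUC (mg·h/dl) with the
   435 mg·h/dl diabetic cutoff.

A synthetic-data module generates cytokine panels with planted
block-correlation structure and fold changes, disc phantoms with exact
ground-truth masks, phase-lagged loading traces, and GTT series — so every
stage is testable against known truth without any download. See
`docs/methods.md` for the models and conventions.

## Worked example

```python
from ivdkit import synthetic as syn, screen, network

design = syn.GroupDesign()          # db/+, db/db, Con+Veh, STZ-HFD; n=3/3/3/9
structure = syn.CorrelationStructure(
    blocks={"monocyte": ("CCL2", "CCL3", "CCL4", "CCL5"),
            "tcell": ("IL-2", "CXCL9", "CXCL10"),
            "other": ("IL-6", "CSF3", "VEGF")},
    upregulated={"STZ-HFD": {"CCL2": 3.0, "CCL3": 3.0, "IL-2": 2.5}},
    missing_rate=0.05,
)
panel, truth = syn.generate_cytokine_panel(design, structure, seed=42)
collapsed = screen.collapse_pseudoreplicates(panel)
filtered, excluded = screen.filter_missingness(collapsed)
table = screen.differential_screen(filtered, "STZ-HFD", "Con+Veh")
print(table.head(4).round(4).to_string(index=False))
```

```
cytokine  mean_case  mean_control      t     df      p  upregulated
    CCL2   675.4977      207.1550 4.3497 6.4039 0.0041         True
    CCL3   188.6823       54.3347 3.8880 8.2909 0.0043         True
    CCL5   165.1937      116.2817 2.5816 8.4753 0.0311         True
    IL-2    32.9517       14.0702 2.4798 8.1313 0.0377         True
```

The three planted cytokines surface with case means ~2.5–3× control (CCL5
rides along through its block correlation with CCL2/CCL3). Building the
diabetic-group network and comparing it to the control network:

```python
corr = network.correlation_matrix(filtered, "STZ-HFD")
net = network.threshold_network(corr, tau=0.7)
part = network.louvain_communities(net, seed=0)
print(f"edges={net.number_of_edges()}  Q={part.q:.3f}  "
      f"APL={network.average_path_length(net):.3f}")
r1 = network.khop_reachability(net, 1)
ctrl = network.threshold_network(network.correlation_matrix(filtered, "Con+Veh"))
j = network.jaccard_similarity(r1, network.khop_reachability(ctrl, 1))
print(f"Jaccard(STZ-HFD vs Con+Veh, k=1) = {j.jaccard:.3f}")
```

```
edges=15  Q=0.391  APL=1.286
Jaccard(STZ-HFD vs Con+Veh, k=1) = 0.227
```

Q = 0.391 reflects the planted modular structure; the low Jaccard index
says only ~23% of within-one-hop cytokine pairs are shared between the
diabetic and control networks — substantial rewiring of the inflammatory
architecture.

## Command line

Each stage is also a CLI (`ivdkit --help`), deterministic given its config
and seed:

```sh
ivdkit simulate panel --seed 3 --out sim/
ivdkit screen --panel sim/panel.csv --case STZ-HFD --control Con+Veh --out screen.csv
ivdkit network build --panel sim/panel.csv --group STZ-HFD --out net.graphml
ivdkit network metrics --graph net.graphml --seed 1 --out metrics/
ivdkit network compare --graph-a net.graphml --graph-b other.graphml --k 1 --k 2
ivdkit morphometry --volume vol.tif --contours contours.json --out morpho/
ivdkit mechanics --trace trace.csv --out mech.csv
ivdkit gtt --series gtt.csv
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the full synthetic study from the seed and runs every stage end
to end — screening and fold-change comparison on the four-group panel,
network construction/metrics/Jaccard comparison for the diabetic and
control groups, phantom morphometry (with recovered-vs-true NPVF), trace
viscoelasticity, and GTT classification — printing the pipeline summary it
computed.
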