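# modulon

Robust-ICA mining of **iModulons** — independently modulated gene sets — from
bacterial RNA-seq compendia, with downstream activity analysis, regulon
reconstitution, and secondary-metabolite biosynthetic gene cluster (smBGC)
boundary refinement.

## Who this is for

Microbial systems biologists with a compendium of RNA-seq profiles (tens to
hundreds of samples across diverse conditions) who want an unsupervised,
regulator-oriented decomposition of their expression data: which gene sets
move together, under which conditions, and which known regulators they
correspond to.  The package is aimed at actinomycete-style use cases —
condition-rich compendia of *Streptomyces* and relatives, where transcriptional
programs of secondary metabolism are of particular interest — but nothing in
it is organism-specific.

## The model

The centered log₂-TPM expression matrix **X** (genes × samples) is decomposed

```
X ≈ M · A
```

where the columns of **M** (genes × k) are statistically independent gene
weight vectors and the rows of **A** (k × samples) are the condition-dependent
activities of each component.  Because FastICA is a non-convex fixed-point
iteration, a single run is not trustworthy: the decomposition is repeated many
times with random initial conditions, all components are pooled, and the pool
is clustered with DBSCAN under the sign-invariant distance

```
d(x, y) = 1 − |ρ(x, y)|        (ρ = Pearson correlation)
```

so that a component and its sign-flip coincide.  Cluster centroids are the
*robust* independent components.  Gene membership of each iModulon is called
by 3-means clustering of the absolute gene weights (the top two clusters are
members), the fraction of data variance captured by any component subset S is

```
EV(S) = 1 − ‖X − M_S·A*_S‖²_F / ‖X‖²_F ,    A*_S = argmin‖X − M_S·A‖_F
```

and the ICA dimensionality is chosen by scanning a grid of dimensions and
taking the smallest one where the number of non-single-gene components equals
the number of components conserved (|ρ| > 0.7) at the largest scanned
dimension.  Details, defaults and caveats are in
[docs/methods.md](docs/methods.md).

Because the study-scale compendium is not shipped, the package includes a
first-class synthetic-compendium generator with planted ground truth (sparse
modules, replicate structure, regulons, genomically contiguous BGC blocks)
against which every pipeline stage is validated.

## Worked example

```python
import modulon as md
from modulon.preprocess import preprocess_counts

sim = md.simulate_compendium(n_genes=2000, k_true=12, n_conditions=20, seed=1)
X, qc = preprocess_counts(sim.counts, sim.genes, sim.design)
print(f"centered matrix: {X.shape[0]} genes x {X.shape[1]} samples, "
      f"{len(qc.removed)} samples removed by QC")

est = md.RobustICA(n_components=12, n_runs=20, random_state=1).fit(X)
print(f"robust components: {est.n_components_}")

ims = md.build_imodulons(est.to_component_set(), X, seed=0)
total_ev = md.explained_variance(X, est.gene_weights_)
print(f"iModulons: {len(ims)}, combined explained variance {total_ev:.1%}")
for im in ims[:3]:
    print(f"  {im.id}: {len(im.members)} genes, threshold {im.threshold:.3f}, "
          f"EV {im.explained_variance:.1%}")
```

Output:

```
centered matrix: 2000 genes x 60 samples, 0 samples removed by QC
robust components: 12
iModulons: 12, combined explained variance 94.4%
  IM008: 37 genes, threshold 0.068, EV 14.7%
  IM012: 36 genes, threshold 0.074, EV 10.3%
  IM005: 28 genes, threshold 0.076, EV 9.7%
```

All 12 planted modules are recovered: each true gene-weight vector matches a
robust component at |ρ| > 0.9, and the called memberships score a mean F1 of
0.91 against the planted gene sets.  `threshold` is the smallest absolute
gene weight among an iModulon's members; `EV` is that component's own
explained variance (components are not orthogonal, so single-component EVs
need not sum to the combined EV).

The same stages are available from a shell:

```sh
modulon simulate --genes 2000 --modules 12 --conditions 20 --seed 1 --outdir data/
modulon preprocess --counts data/counts.tsv --genes data/genes.tsv \
    --samples data/samples.tsv --out data/X.tsv
modulon ica --expr data/X.tsv --dim 12 --runs 100 --seed 1 --outdir data/ica/
modulon imodulons --m data/ica/M.tsv --a data/ica/A.tsv --expr data/X.tsv \
    --out data/imodulons.json
```

plus `optdim` (dimension scan), `enrich` (regulon enrichment) and
`bgc-refine` (cluster boundary refinement).

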