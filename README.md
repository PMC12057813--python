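# seedclust

De novo clustering of long transcriptomic reads (ONT, PacBio) into gene
families — no reference genome required.

Long-read transcriptome pipelines for organisms without good references
start by splitting the read set into clusters that each cover one gene or
gene family, so that error correction and isoform reconstruction can run
per cluster. seedclust implements a single-pass greedy clusterer built on
three ideas:

1. **Quality-aware seeds.** Each read is sketched with canonical
   (k, w)-minimizers. A seed spanning positions *i…i+k−1* gets a
   confidence *P = ∏ⱼ (1 − 10^(−qⱼ/10))* from its Phred base qualities —
   the probability that all *k* bases were called correctly. Seeds with
   *P > T1* are *high-confidence seeds* (HCS), the only seeds trusted to
   describe a cluster.
2. **Dynamically growing cluster representations.** Reads are sorted by
   decreasing HCS count and streamed once. A read joins the cluster whose
   HCS representation contains the largest number of its seed values,
   provided that number is at least a fraction T2 of the read's distinct
   seeds; its own HCS are then **added** to the representation. This lets
   a cluster follow a gene family across isoforms that only chain-overlap
   (new exons, SNVs), where founder-frozen representations fragment.
   Candidate clusters come from an inverted seed → cluster-id index, so
   each read is only compared against clusters it actually shares a seed
   with.
3. **Iterative cluster merging** (optional, `post_cluster`). Clusters are
   visited in ascending representation size; a cluster merges into a
   larger one when their HCS overlap exceeds a fraction T3 of the smaller
   representation, and sweeps repeat until a fixpoint. This repairs the
   fragmentation that noise causes in the greedy pass.

Presets: ONT `k=13, w=21, T1=0.95, T2=0.5, T3=0.5`; PacBio
`k=15, w=51, T1=0.98, T2=0.5, T3=0.8`.

The package also ships the standard external clustering metrics
(homogeneity, completeness, V-measure, Rand index, adjusted Rand index,
singleton/non-singleton summaries) and a synthetic long-read generator
with ground-truth labels for self-contained benchmarking.

## Worked example

```python
from seedclust import SimConfig, simulate, make_config, run, Labeling, evaluate

reads, truth = simulate(SimConfig(n_families=10, reads_per_family=(50, 50),
                                  error_rate=0.05, seed=1))
result = run(make_config("ont", post_cluster=True), reads=reads, write=False)
labeling = Labeling.from_sequences(
    [result.assignment[r.read_id] for r in reads],
    [truth.family[r.read_id] for r in reads])
print(result.n_clusters_initial, "->", result.n_clusters_final)
print(evaluate(labeling))
```

prints (see `examples/02_simulate_and_cluster.py`):

```
greedy pass: 31 clusters; after 2 merge sweeps: 10
  homogeneity: 1.0000
  completeness: 1.0000
  v_measure: 1.0000
  adjusted_rand_index: 1.0000
  pct_reads_in_nontrivial_clusters: 100.0000
```

500 simulated reads at 5% error from 10 gene families come out of the
greedy pass as 31 clusters (noise fragments some families); two merge
sweeps collapse them to exactly the 10 true families, and every external
metric against the ground truth is 1 — a perfect recovery. The
`examples/` directory holds one short script per capability: seed
confidence, the full pipeline, the dynamic-representation effect, and
cluster merging.

## Command line

```bash
seedclust simulate --out sim/ --n-families 10 --error-rate 0.05 --seed 1
seedclust cluster --fastq sim/reads.fastq --outfolder out/ --mode ont --post-cluster
seedclust evaluate --clusters out/final_clusters.tsv --classes sim/truth.tsv
```

`cluster` writes `final_clusters.tsv` (`cluster_id <tab> read_id`, ids
renumbered by decreasing cluster size) and one FASTQ per cluster with at
least `--min-size` members. Input FASTQ may be gzipped; malformed records
are skipped and counted.

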