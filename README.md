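# diffmod

Network diffusion-based detection of interactome regions ("modules")
differentially enriched in omics signal.

Molecular entities that participate in the same biological function or
disease process tend to be close in molecular interaction networks (the
*local hypothesis*). `diffmod` exploits this to interpret per-gene
statistics — somatic mutation frequencies, differential-expression
scores — in the context of a protein–protein interaction network:

1. **Network propagation.** An input statistic `x0` is smoothed over
   the network by the random-walk-with-restart iteration
   `x_{t+1} = αWx_t + (1−α)x0`, where `W = D^{-1/2} A D^{-1/2}` is the
   symmetrically normalised adjacency; the unique steady state `x*`
   solves `(I − αW)x* = (1−α)x0`.
2. **Network smoothing index.** `S_j = x*_j / (x0_j + ε)` jointly
   scores a gene's own signal and the signal in its network
   neighbourhood. For two sample groups the differential index
   `ΔS_j = S_j(cases) − S_j(controls)` cancels purely topological (hub)
   effects; for a single inferential statistic the permutation-adjusted
   `Sp_j = S_j (1 − p_j)` discounts genes whose S is reproduced by
   diffusing randomly relabelled inputs.
3. **Network resampling.** For genes ranked by ΔS or Sp, the
   non-decreasing objective `Ω(n) = Σ_{(i,j) interacting, i,j ≤ n} s_i s_j`
   is compared, rank by rank, with k degree-preserving rewirings of the
   network; low empirical p-values `p_nr(n)` indicate that the
   top-ranked genes are significantly interconnected, and the first
   contiguous significant run cuts out the module.
4. **Synthetic benchmark.** A generator plants connected modules with a
   controlled signal share ω (mountains/hills mutation landscape,
   margin-preserving permutations) in scale-free clustered networks and
   measures recovery (recall of S versus the network-free statistic,
   module-size estimation).

The package is aimed at computational biologists who have a network
(e.g. a STRING export filtered at confidence ≥ 700) and per-gene
statistics for one cohort or two contrasted groups, and want ranked
genes plus a significance-backed subnetwork rather than a flat gene
list.

## Library quick start

The core is exposed as scikit-learn style estimators: fit on a network,
transform per-gene statistic vectors.

```python
from diffmod import NetworkSmoother, ModuleDetector, simulate_dataset, recall_at_M

ds = simulate_dataset(n_nodes=500, M=30, m_pct=0.1, h=0.1, seed=11)
print(f"planted module: M={len(ds.module)}, omega={ds.omega:.3f}, density={ds.density:.3f}")

smoother = NetworkSmoother(alpha=0.7, epsilon=0.25).fit(ds.net)
table = smoother.smooth_scores(ds.f_sim)          # gene, x0, x_star, S
print(table.sort_values("S", ascending=False).head(5).to_string(index=False))

rec_S = recall_at_M(dict(zip(table.gene, table.S)), ds.module)
rec_f = recall_at_M(ds.f_sim, ds.module)
print(f"recall(S) = {rec_S.recall:.2f}   recall(f) = {rec_f.recall:.2f}")
```

prints

```
planted module: M=30, omega=0.329, density=0.161
 gene   x0   x_star        S
g0017 0.12 0.129901 0.351083
g0008 0.09 0.119284 0.350834
g0003 0.10 0.096288 0.275109
g0077 0.47 0.189608 0.263345
g0066 0.14 0.096180 0.246615
recall(S) = 0.57   recall(f) = 0.50
```

The planted module carries ω ≈ 0.33 of the total mutation signal. The
top of the S ranking mixes true sources (g0077, mutated in 47% of
samples) with genes like g0017 whose own frequency is modest but whose
neighbourhood is heavily mutated — exactly the joint prioritisation the
index is built for — and recalls more of the planted module than the
raw frequency ranking (0.57 vs 0.50 here; the gap widens with more
replicates, see the benchmark).

Module detection on the differential index against the unplanted
control of the same dataset:

```python
from diffmod import align_scores

x_sim, _ = align_scores(ds.f_sim, ds.net)
x_ctl, _ = align_scores(ds.f_control, ds.net)
delta = smoother.transform(x_sim) - smoother.transform(x_ctl)
detector = ModuleDetector(k=100, n_max=60, random_state=0).fit(ds.net, dict(zip(ds.net.nodes, delta)))
print(f"first significant rank = {detector.first_significant_rank_}, n* = {detector.n_star_}")
hit = len(set(detector.module_genes_) & set(ds.module))
print(f"detected module: {len(detector.module_genes_)} genes, {hit} from the planted module")
```

```
first significant rank = 8, n* = 60
detected module: 60 genes, 25 from the planted module
```

A significantly connected component is present from rank 8 onwards
(`p_nr ≤ 0.05`); the cut at n* = 60 recovers 25 of the 30 planted genes
(chance expectation ≈ 3.6). `detector.profile_` holds the full
`(n, Ω, p_nr)` table.

## Command line

Every stage is also a subcommand of the `diffmod` CLI, reading and
writing TSV (plus `.rnk` and SIF exports):

```bash
diffmod smooth --network edges.tsv --scores f.tsv --epsilon 0.25 --out S.tsv
diffmod delta  --network edges.tsv --cases f2.tsv --controls f1.tsv --out dS.tsv --rnk dS.rnk
diffmod sp     --network edges.tsv --scores lfcp.tsv --top-n 500 --n-perm 1000 --seed 1 --out Sp.tsv
diffmod resample --network edges.tsv --scores dS.tsv --k 100 --seed 1 --out profile.tsv
diffmod module --network edges.tsv --scores dS.tsv --k 100 --seed 1 \
               --out-genes module.tsv --out-sif module.sif
diffmod simulate --n-nodes 2000 -M 100 --seed 1 --out-prefix toy
diffmod benchmark --n-seeds 20 --seed 1 --out bench.tsv
diffmod run --config run.cfg            # full pipeline from a key=value config
```

Networks are whitespace/tab edge lists (first two columns = node IDs,
`#` comments skipped); `--score-column`/`--min-score` filter on an edge
confidence column with an inclusive threshold.

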