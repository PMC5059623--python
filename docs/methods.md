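# Methods

## Model

### Network propagation

An undirected molecular interaction network with adjacency matrix **A**
(binary, symmetric, zero diagonal) is normalised symmetrically,

    w_ij = a_ij / sqrt(k_i * k_j),

where `k_i` is the degree of node *i*; rows and columns of degree-0
nodes are identically zero. The spectral radius of **W** is at most 1,
so for any restart parameter `0 < alpha < 1` the propagation recurrence

    x_{t+1} = alpha * W @ x_t + (1 - alpha) * x0

is a contraction with a unique fixed point `x*` — the steady state of
the open-system Laplacian dynamics `(I - alpha*W) x* = (1 - alpha) x0`.
Both routes are implemented: a sparse fixed-point iteration
(`propagate_iterative`, max-norm update threshold `tol = 1e-6`,
element-wise, starting from `x0` itself — the fixed point is unique, so
the start only affects the iteration count) and a direct solve
(`propagate_closed_form`, sparse LU). `check_steady_state` returns the
max-norm residual of the linear balance and is the verification
contract tying the two together. `alpha` defaults to 0.7: more than
half of the mass circulates through the network, while convergence
remains fast (the iteration count grows as `alpha` approaches 1).

### Smoothing indices

The network smoothing index of gene *j* compares the diffused state
with the initial statistic:

    S_j = x*_j / (x0_j + epsilon),       epsilon > 0.

Small `epsilon` emphasises the *gain* of information relative to the
initial state (a gene with no signal of its own but well-connected to
sources scores high); as `epsilon` grows, the ranking by S converges to
the ranking by `x*`. Defaults follow the two input branches:
`epsilon = 0.25` for descriptive statistics (per-group mutation
frequencies) and `epsilon = 1` for inferential statistics (lfcp-like
scores), both user-settable.

Two hub-mitigation routes are provided on top of S:

* **dS** (descriptive inputs): `dS_j = S_j(cases) - S_j(controls)`,
  computed with the identical network, `alpha` and `epsilon` on both
  sides (enforced). Because the topology is shared, purely topological
  contributions cancel: a hub with the same signal in both groups has
  `dS = 0` exactly, and `dS_hub` depends only on the neighbourhood
  signal difference.
* **Sp** (inferential inputs): `Sp_j = S_j * (1 - p_j)` with

      p_j = (1 + #{perm : S_j^perm >= S_j}) / (n_perm + 1),

  where each permutation shuffles the input values across network
  genes and is re-diffused. The add-one correction counts the observed
  configuration as one of the permutations, so `0 < p_j <= 1` and
  `Sp_j <= S_j` always. The linear system is LU-factorised once and
  re-used for all permutations, which makes `n_perm = 1000` (default)
  cheap even on thousands of genes. An exhaustive mode enumerates all
  `n!` permutations on small vectors and is used as an exact oracle in
  the tests.

Genes absent from the network are excluded from diffusion and reported
with `dS = Sp = 0` in all outputs.

### Connectedness of top-ranked genes

For a gene list ranked by a non-negative score (positive dS or Sp), the
objective

    Omega(n) = sum over unordered interacting pairs (i,j) among the
               top-n genes of score_i * score_j

is non-decreasing in *n* (each unordered pair is counted once; a factor
of 2 would rescale every resample identically and leave the p-values
unchanged). Significance at each rank is assessed against `k = 100`
(default) degree-preserving rewirings of the whole network, generated
once and re-used across all ranks:

    p_nr(n) = (1 + #{r : Omega_r(n) >= Omega_real(n)}) / (k + 1).

The null is a double-edge-swap Markov chain with `10 * |E|` attempted
swaps; swaps creating self-loops or multi-edges are rejected, so the
degree sequence is conserved exactly and swap-rigid graphs (e.g. K4)
are returned unchanged. An alternative scope that rewires the induced
top-n subnetwork at every rank is available
(`rewire_scope="induced"`); it is strictly more conservative and much
slower, and is not the default.

The module cut takes the first contiguous run of ranks with
`p_nr <= 0.05` and returns the top-n* genes, where n* is the largest
rank of that run; the first significant rank is reported alongside. If
no rank is significant the module is empty.

## Synthetic benchmark

The generator plants a connected module inside a synthetic interactome
and measures whether network smoothing recovers it.

* **Substrate.** `generate_network(n, "scale_free")` draws a Holme–Kim
  powerlaw-cluster graph with `m = 3` edges per node and triangle
  probability 0.9, giving a heavy-tailed degree distribution, mean
  degree ~6 and clustering ~0.4 — the regime of sparse physical
  interactomes (a genome-scale binary PPI map has mean degree ~6.5).
  Clustering matters: on a clustering-free preferential-attachment
  graph, grown modules are tree-like and the within-module
  reinforcement that diffusion exploits largely disappears. An
  Erdős–Rényi generator is included as a homogeneous control.
* **Module sampling.** Seed-and-grow: a random seed gene, then
  repeatedly a random current member donates 1–5 of its non-member
  neighbours (uniform count, capped by availability and the remaining
  budget) until exactly M genes are collected; stalls restart from a
  fresh seed (bounded). The induced subgraph is connected by
  construction and spans a range of topological densities.
* **Signal.** A binary genes-by-samples mutation matrix is simulated
  with per-gene Bernoulli probabilities drawn from a clipped lognormal
  (log-mean −5.5, log-sd 2.0, cap 0.9) over 100 samples, giving the
  mountains-and-hills landscape of cancer cohorts: a few highly mutated
  genes, a long low-frequency tail, and — because frequencies are
  empirical fractions k/100 — heavy ties, which is where
  network-aware ranking has the most to add. The margin-preserving
  null permutes gene labels (rows), conserving per-patient sums exactly
  and the per-gene sum multiset exactly.
* **Planting.** `assign_module_signal` relabels the `ceil(m_pct * M)`
  globally largest frequencies onto random module genes (mountains) and
  fills the remaining module genes (hills) with values picked greedily
  from the residual pool so their mean approaches the target `h`
  (nearest-to-running-target selection; an unreachable `h` raises an
  error stating the achievable range). All remaining values are
  scattered randomly outside the module; the value multiset is
  conserved exactly. The module's signal share
  `omega = sum_module f / sum_all f` rises monotonically with `h` and
  with M at fixed `m_pct`.
* **Scoring.** Recall is the fraction of module genes among the top-M
  genes of a ranking (ties broken by gene identifier). The benchmark
  compares the ranking by S against the network-free ranking by the raw
  frequency f, optionally ranks by dS against an unplanted control
  dataset, and can estimate module size from the resampling profile.

Default problem sizes — 2,000-node networks with M = 100 for
prioritisation runs, 1,000 nodes with M = 50 for module-size runs, 10–20
replicate seeds — keep a full benchmark in the tens of seconds while
leaving the planted effects well clear of seed noise.

### What the generator does and does not emulate

It reproduces the degree heterogeneity, clustering and tie-heavy,
heavy-tailed frequency landscape that the method's behaviour depends
on, with exactly conserved margins. It does not emulate identifier
noise, interactome incompleteness or ascertainment bias (hub degree
correlating with study attention), patient subgroup structure, or
RNA-seq count noise for the inferential branch (binary/lfcp-like inputs
are modelled directly). Passing benchmarks therefore show that the
pipeline recovers planted, network-coherent signal under realistic
topology and signal shapes — not that any particular biological claim
holds on a given cohort.

## Numerical choices

* Node order is lexicographic and fixed at load; all vectors, matrices
  and outputs follow it, making runs bit-reproducible at fixed seed.
* Ranking ties: descending score, then ascending gene identifier
  (stable). `binarize_top` always emits exactly N ones.
* Convergence is declared on the element-wise max-norm of the update;
  the closed-form solve is preferred up to a configurable node-count
  cutoff (default 5,000) and the sparse iteration above it.
* Empirical p-values (Sp and p_nr) always carry the add-one
  correction, so they are never exactly 0 and the observed data counts
  as one resample.
* All stochastic steps take explicit seeds; a pipeline run records its
  parameters, seeds and unmapped genes in `run_metadata.json`.
* The rewiring kernel runs over a dense boolean adjacency (numba JIT),
  which is exact and fast for the network sizes this package targets
  (up to a few thousand nodes); the edge-array state is rebuilt per
  resample from the input network, so resamples are independent.

## Known limitations

* **Module-size estimation saturates on clustered networks.** The
  degree-preserving null destroys clustering. Once a genuine module has
  entered the ranking, its score-weighted links keep the observed
  Omega(n) above virtually every rewired value at *every* subsequent
  rank, so the significant run extends to the end of the profiled range
  and its last rank (n*) reflects the horizon, not the module. The
  *first* significant rank — the quantity the profile plots make
  visible — is the informative size signal, and both are reported by
  `extract_module` and the benchmark. On dense, low-clustering
  networks the run does terminate and n* becomes meaningful; on the
  sparse clustered substrate used here it should be read as "a
  significantly connected component is present from rank r onwards".
* The permutation null for Sp assumes exchangeable input values;
  strong covariate structure (e.g. gene length driving both mutation
  rate and degree) is not modelled by it.
* Multiple-testing correction across ranks of the p_nr profile is out
  of scope; the profile is a scan statistic, and the null-calibration
  test tracks (without correcting) the family-wise dip rate.
* Weighted diffusion on edge confidence scores is not implemented;
  confidence enters only through the edge filter threshold.
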