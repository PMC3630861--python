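# kbpbm

Design and analysis of **κB-site protein binding microarrays (PBMs)** —
the double-stranded DNA arrays used to compare the sequence preferences of
NF-κB family transcription factors across many binding-site variants in
parallel.

The package is aimed at researchers profiling protein–DNA binding
specificity with custom two-color arrays. It covers the whole computational
loop:

* **Probe design.** A degenerate IUPAC consensus (default: the generalized
  κB site `RGGRNNHHYYB`, 6,912 11-mers) is expanded into its k-mer space,
  embedded by classical principal coordinate analysis (PCoA) of pairwise
  Hamming distances, and reduced to a representative core subset with
  k-medoids (PAM). Cores are crossed with four flanking-arm variants and
  three technical replicates into the physical feature list, with
  array-capacity bookkeeping (803 cores × 4 flanks × 3 replicates = 9,636
  features on a 15K array sector).
* **Synthetic data.** A Boltzmann two-state occupancy simulator generates
  two-channel intensities from energy PWMs: probe occupancy is
  `Σ_windows σ(score − μ)` over both strands, the Cy5 (binding) channel is
  `δ·(β₀ + β₁·occ)·ε`, the Cy3 (double-stranding) channel is `γ·δ·ε′`, with
  a shared per-spot double-stranding factor `δ` and independent log-normal
  measurement noise. A default suite of four NF-κB-like dimers
  (`nv_p50_like`, `hs_p52_like`, `hs_p50_like`, `relA_like`) encodes a
  planted divergence structure.
* **Processing.** The array z-score chain: per-feature `Cy5/Cy3` ratio →
  `log2` → median over technical replicates (pooling flank variants) →
  `z = (log₂ value − median of array) / SD of array` (sample SD).
* **Comparison.** Pearson correlation of matched z-score profiles,
  complete-linkage hierarchical clustering (Euclidean distance on
  z-vectors, newick export), ordered heat-map matrices, and top-20
  "barcodes": the position frequency matrix and information content
  (`IC_j = 2 + Σ_b f_bj log₂ f_bj`) of a protein's highest-z probes, plus a
  half-site symmetry score comparing the 5′ GG and 3′ CC κB signatures.
* **Plate statistics.** LUMIER fold-binding
  (`(eluate/lysate) / (eluate/lysate)_control`), dual-luciferase reporter
  fold-induction (firefly/renilla over the mean control ratio), and
  ChIP-qPCR fold-enrichment over IgG (`efficiency^(Ct_IgG − Ct_Ab)`).

## Worked example

Design a 200-core array from the κB consensus (embedding a seeded
1,024-point subsample of the 6,912-mer space), simulate the four-dimer
suite, and compare the resulting binding profiles:

```python
import numpy as np
from kbpbm import (
    expand_iupac, hamming_matrix, pcoa, select_representatives,
    assemble_probes, default_dimer_suite, NoiseModel,
    simulate_intensities, profiles_from_intensities,
    correlation_matrix, cluster_profiles, top_n_probes,
    position_frequency_matrix, half_site_symmetry,
)
from kbpbm.probe_design import DEFAULT_FLANKS

space = expand_iupac("RGGRNNHHYYB")
print(len(space.kmers))                       # 6912

rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(1).spawn(1)[0]))
idx = np.sort(rng.choice(len(space.kmers), 1024, replace=False))
kmers = [space.kmers[i] for i in idx]
embedding = pcoa(hamming_matrix(kmers), retained_fraction=0.9)
cores = [kmers[i] for i in select_representatives(embedding, k=200, seed=1)]
design = assemble_probes(cores, DEFAULT_FLANKS, replicates=3, capacity=15_000)
print(design.n_features)                      # 2400

table = simulate_intensities(design, default_dimer_suite(), NoiseModel(seed=1))
profiles = profiles_from_intensities(table, design)
print(correlation_matrix(profiles).to_frame().round(2))
print(cluster_profiles(profiles).to_newick())
by = {p.protein: p for p in profiles}
for name in ("hs_p52_like", "hs_p50_like"):
    bc = position_frequency_matrix(top_n_probes(by[name], design, 20), protein=name)
    print(name, round(half_site_symmetry(bc), 3))
```

Output:

```text
6912
2400
             hs_p50_like  hs_p52_like  nv_p50_like  relA_like
hs_p50_like         1.00         0.69         0.58      -0.02
hs_p52_like         0.69         1.00         0.92       0.05
nv_p50_like         0.58         0.92         1.00       0.12
relA_like          -0.02         0.05         0.12       1.00
(relA_like:20.16735137,(hs_p50_like:12.93147368,(hs_p52_like:6.083177873,nv_p50_like:6.083177873):6.848295807):7.235877687);
hs_p52_like 0.765
hs_p50_like 0.562
```

Reading the numbers: the anemone-like p50 profile correlates most strongly
with the human p52-like profile (0.92), less with the human p50-like one
(0.58), and barely with RelA-like (0.12), and RelA-like joins the
dendrogram last — the planted cross-protein divergence structure is
recovered from the simulated arrays. The half-site symmetry scores show the
p50-like barcode (0.562) has lost the GG…CC balance that the p52-like
barcode retains (0.765), reflecting its asymmetric 3′ C-run preference.

## Command line

Every stage is also exposed as a subcommand of `kbpbm`:

```bash
kbpbm design   --consensus RGGRNNHHYYB --k 803 --replicates 3 --capacity 15000 --seed 1 --out design.tsv
kbpbm simulate --design design.tsv --suite default --noise-sd 0.05 --ds-sd 0.3 --seed 1 --out intensities.tsv
kbpbm process  --intensities intensities.tsv --design design.tsv --out zscores.tsv
kbpbm compare  --zscores zscores.tsv --out-prefix results/
kbpbm barcode  --zscores zscores.tsv --design design.tsv --protein nv_p50_like --n 20 --out-prefix results/
kbpbm quantify --mode lumier --in plate.tsv --out folds.tsv
kbpbm run-all  --config run.yaml
```

`run-all` executes the full chain from a flat YAML config and writes a
manifest with the SHA-256 of every artifact; identical config + seed gives
byte-identical outputs.

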