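# Methods

## Probe design

**K-mer space.** An IUPAC degenerate consensus is expanded into every
matching DNA string, emitted in lexicographic order. The package default is
the generalized κB-site 11-mer `RGGRNNHHYYB` (6,912 k-mers); the canonical
10-mer κB consensus `GGRRNNYYCC` has a degeneracy product of 2·2·4·4·2·2 =
256. All tie-breaks downstream (medoid ties, top-N ties) resolve on this
lexicographic order, so every stage is deterministic.

**Distance and embedding.** Cores are compared by Hamming distance — the
minimal defensible metric for fixed-length k-mers; the distance function is
pluggable for callers who want a weighted or biophysical alternative. The
space is embedded by classical (Gower) principal coordinate analysis:
double-center `−½ D∘D`, eigendecompose, keep positive-eigenvalue axes up to
a retained fraction (default 0.90) of the positive eigenvalue mass, and
scale eigenvectors by √λ. Hamming distances are not Euclidean-embeddable,
so negative eigenvalues occur; they are dropped in the classical manner and
the dropped-mass fraction is logged (≈0.43–0.45 of the positive mass for
κB k-mer spaces — substantial, which is why representative selection works
on the retained coordinates rather than on reconstructed distances).
Eigenvector signs are fixed (largest-magnitude loading positive) so
embeddings are reproducible across runs and BLAS builds.

**Representative selection.** k-medoids via PAM (greedy BUILD followed by
best-improvement SWAP sweeps) on Euclidean distances in the retained
coordinate space. PAM is deterministic here — ties resolve at the lowest
index, i.e. lexicographically smallest k-mer — and the `seed` parameter is
accepted for interface stability. On every random instance with n ≤ 8,
k ≤ 3 the heuristic is verified against exhaustive search (within 5% of the
optimum; in practice it attains it). The full-scale default is k = 803
cores; whether the original set was produced by fixed-count selection or
by thresholding is not recoverable, so the count is simply a parameter.

**Array assembly.** Features are the full factorial cores × flanks ×
replicates, refused outright if it exceeds the array capacity (default
15,000 features). Flank `fA` reproduces the constant arms of the
biotinylated κB pulldown oligonucleotide (`AGCTGGGCAT…AACTCT`); flanks
`fB`–`fD` are fixed GC-balanced 10/6-mers shipped as named constants, all
overridable. Probe sequences are stored 5′→3′ top strand; the k-mer space
is not reverse-complement-deduplicated (the consensus orientation defines
the space). The design TSV carries a `# capacity=N` comment line ahead of
the header so that write → read is an identity.

## Synthetic PBM model

**Occupancy.** Binding of a protein to a probe is modeled per window as a
Boltzmann two-state system: window score `s = Σ_j M[b_j, j]` against a 4 ×
width log-odds matrix, occupancy contribution `σ(s − μ)` with chemical
potential μ, summed over all windows on both strands. This makes noise-free
behavior analytically checkable (a flat matrix with μ = 0 gives exactly
half a unit per window; a single perfect match with everything else far
below μ gives occupancy → 1).

**Channels and noise.** Each core × flank spot family has one
double-stranding efficiency `δ ~ LogNormal(0, σ_ds²)` per protein, shared
between channels and replicates — it is a physical property of the spot.
Per row, `Cy3 = γ·δ·ε` and `Cy5 = δ·(β₀ + β₁·occ)·ε′` with independent
`ε, ε′ ~ LogNormal(0, σ_meas²)`. By construction the Cy3 normalization of
Cy5 is exactly the right correction: δ cancels in the ratio, so z-profiles
are invariant to σ_ds (verified exactly in tests). Defaults: σ_meas = 0.05,
σ_ds = 0.3, β₀ = 100, β₁ = 5000, γ = 500 — chosen once to give a log2
dynamic range of ~5–6 between background and saturated probes, which makes
the downstream comparisons discriminating; they are not calibrated to any
particular scanner. All randomness derives from one master seed through
deterministic `SeedSequence` substreams (one for δ, two per protein for the
channel noise).

**The four-dimer suite.** Width-10 log-odds matrices aligned to positions
1–10 of the 11-mer consensus (frame `RGGRNNHHYY`), so the canonical TNF κB
site `GGGAATTTCC` is the top-scoring k-mer of the anemone-like matrix.
Disfavored bases at constrained positions are penalized at 0.6× the
position's top bonus — without penalties the matrices degenerate into
homopolymer-run detectors whose off-frame and reverse-strand matches wash
out position structure. μ is 0.55 of each matrix's maximum score. The suite
encodes the structure the analysis should recover:

* `nv_p50_like` — symmetric canonical profile (GG…CC).
* `hs_p52_like` — mild perturbation of it (closest; Frobenius distance 3.0).
* `hs_p50_like` — 3′-biased C-run with a C/T-tolerant final constrained
  position, an asymmetric half-site preference (distance 6.1).
* `relA_like` — divergent A/T-shifted preferences (farthest; distance 6.5).

**What the simulator does not emulate.** Spot morphology, spatial
gradients, scanner saturation, sequence-dependent double-stranding bias,
probe secondary structure, or inter-array batch effects. Passing tests
therefore demonstrate that the analysis chain is correct and discriminating
under the stated noise model, not that it is robust to every artifact of
real scanner data.

## Processing chain

Order of operations: `Cy5/Cy3` ratio per (feature, protein, replicate) →
`log2` → median per probe core over replicates and flank variants (pooling
flanks is the symmetric default; per-flank profiles are available) →
`z = (x − median) / SD` across the array's cores, per protein. The sample
(n − 1) SD is used; at hundreds of probes the distinction from the
population SD is numerically immaterial, but it is documented and fixed.
Even-sized medians take the mean of the two middle values. Missing features
are a hard error — the design is a complete factorial by construction, so
imputation would only mask upstream problems. Profiles satisfy median(z) = 0
and sd(z) = 1 to machine precision, and the chain is invariant to
per-protein gain rescaling of either channel.

Z-score tables are read/written in the supplementary-table layout (probe
rows × protein columns, TSV or CSV with delimiter auto-detection).

## Profile comparison and barcodes

Pearson correlation on matched z-score vectors (equivalent to correlation
on the log2 summaries up to the affine standardization). Clustering is
agglomerative with complete linkage on Euclidean distances between
z-vectors — the two named, compatible choices — with correlation distance
(1 − r) available as a switch; merge heights are verified against a direct
O(n³) re-agglomeration. Heat-map matrices order columns by dendrogram leaf
order and rows by mean z, descending.

A protein's barcode is the exact position frequency matrix of its top-20
highest-z cores (no pseudocounts — twenty sequences define exact
frequencies), with per-position information content `2 + Σ f log₂ f` bits.
Half-site symmetry is `min(s_L, s_R)/max(s_L, s_R)` where `s_L` is the
product of G frequencies at the 5′ GG signature and `s_R` the product of C
frequencies at the 3′ CC signature (positions 2–3 and 9–10 of the 11-mer
consensus; both-zero is defined as 1). Because positions 2–3 are fixed G in
the consensus space, the score reduces there to the 3′ C-signature
strength, which is exactly where the p50-like asymmetry shows.

## Plate statistics

All three fold statistics normalize to an in-plate control and are
therefore invariant to instrument gain; controls map to exactly 1.0.
ChIP-qPCR enrichment uses `E^(ΔCt)` with a shared efficiency E ∈ (1, 2],
defaulting to perfect doubling (E = 2) — primer sets are assumed validated
for equal efficiency. Reporter SDs are computed on the per-replicate fold
scale with the control summarized by its mean ratio; per-condition mean
normalization is the documented alternative.

## Problem sizes and determinism

Simulation-driven tests and the acceptance script run a desk-scale study:
200 cores selected by the full PCoA + k-medoids path from a seeded
1,024-point subsample of the 6,912-member 11-mer space, 4 flanks × 3
replicates (2,400 features), 20 independent noise seeds. Full-space
embeddings (a dense 6,912² eigendecomposition) are supported for production
designs. The recovery properties — correlation ordering
corr(nv, p52) > corr(nv, p50) > corr(nv, relA), relA joining the dendrogram
last, and p50's barcode scoring below p52's on half-site symmetry — hold in
20/20 runs at the default noise level.

Every pipeline run is reproducible: one master seed feeds named
`SeedSequence` substreams, outputs are written with fixed float formats,
and the run manifest records the SHA-256 of every artifact. Known
limitations: the PCoA negative-eigenvalue mass means retained coordinates
underestimate long Hamming distances; PAM is a heuristic (near-optimal, not
certified beyond the small-instance oracle checks); and the simulator's
noise model is multiplicative-only.
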