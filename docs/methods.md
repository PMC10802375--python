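# Methods

## Pipeline and assumptions

`tensorparc` assumes per-subject BOLD series sampled on a shared
triangular hemisphere mesh, already spatially registered, and that
subjects share a common vertex-pair correlation structure up to an
orthogonal temporal transform. Under that assumption synchronization is
exact in the noiseless limit: if two normalized datasets have identical
correlation structure, the Procrustes-optimal orthogonal transform makes
every homologous-vertex pair perfectly correlated. Group alignment
alternates between the mean-of-aligned template and per-subject
closed-form Procrustes solves; each half-step cannot increase the total
squared error, so the objective trace is monotone non-increasing.

Subjects with two sessions are concatenated in time; a subject with one
session has it duplicated and concatenated, so every subject contributes
the same doubled time length to the group tensor.

The CP model is deliberately unconstrained — no orthogonality,
no independence — because functional networks overlap and correlate.
The solver is alternating least squares: each mode update solves the
exact normal equations (Khatri-Rao Gram products), so the reconstruction
error is non-increasing. Identifiability relies on the usual CP
conditions (distinct magnitudes, incoherent factors); on planted tensors
the solver reaches matched congruence > 0.99 noiselessly and > 0.9 for
spatial maps at 5 dB SNR.

Graph construction uses the feature-row Pearson matrix, a monotone
kernel, and a hop mask. Hops are unweighted edge counts (BFS), not
geodesic millimetres: the locality constraint only needs an ordering of
neighborhood sizes, and edge-count hops make the construction
independent of mesh units. The NetMF matrix is computed along the
sparse random-walk path (repeated sparse multiplication by the
row-stochastic walk matrix), which the tests pin against a dense
explicit-matrix-power oracle to 1e-10.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| σ (kernel width) | 0.5 | scale of the similarity kernel, dimensionless correlation units |
| nb (hop radius) | schedule | locality constraint, in mesh-edge hops at 32K-class resolution |
| T_win (walk window) | schedule | random-walk window of the NetMF matrix |
| b (negative samples) | 1 | NetMF negative-sampling constant |
| d (embedding dim) | 128 | number of singular triplets kept |
| n_init | 500 | k-means restarts; the min-cost labeling wins |
| k-means max_iter | 20000 | per-restart iteration cap |
| sync max_iter / tol | 10 / 1e-6 | group-template alternation stop rule |
| CP max_iter / tol | 200 / 1e-8 | ALS stop rule on the relative-error decrease |

The (nb, T_win) schedule is keyed by the *total* parcel count:
(0,200] → (55, 7); (200,300] → (40, 15); (300,400] → (35, 15). The
printed source intervals leave 301 unassigned; we close the gap as
(300,400] since any other reading orphans a valid parcel count. Counts
beyond 400 reuse the nearest interval with a warning.

Hop radii in the schedule are defined at ~32K-vertex resolution. On
coarser meshes `nb` is rescaled by the ratio of the mesh's hop diameter
(double BFS sweep estimate) to a reference diameter of 192 — the
measured hop diameter of an icosphere with 40962 vertices, the
sphere-mesh analogue of a 32K cortical surface. This preserves the
fraction of the surface each vertex may connect to; set
`nb_scale=1.0` to disable.

## Open design choices

- **Kernel form.** The similarity kernel defaults to
  `exp(A/(2σ²))`; variants `exp(A²/(2σ²))` and `exp(−(1−A)/(2σ²))` are
  selectable. All are monotone in similarity over the relevant range,
  which is the only property the downstream walk matrix uses; negative
  correlations map to small positive weights rather than being zeroed.
- **Embedding scaling.** Default `B = U_d Σ_d^{1/2}` (the NetMF
  factorization convention, since `M ≈ B Bᵀ` for symmetric PSD-like M);
  `B = U_d Σ_d` is available behind a flag. Natural log throughout —
  the base only rescales embeddings uniformly.
- **Feature scaling.** Spatial-map columns enter the feature matrix at
  unit norm by default; λ-scaled columns are available because the two
  give genuinely different vertex-pair correlations (verified in tests).
- **Sign and order conventions.** CP factors are unit-norm with
  magnitudes sorted descending; each spatial map's largest-magnitude
  entry is made positive (compensated in the time course). Parcel labels
  are renumbered by descending size, ties broken by the smaller original
  label. Both remove permutation/sign indeterminacy so identical inputs
  serialize identically.
- **Procrustes domain.** Transforms range over the full orthogonal
  group (reflections allowed) — the closed-form optimum of the
  squared-error objective; transforms act on time only.
- **Template start.** Group sync starts from the subject with the
  highest mean pairwise correlation to the others: deterministic, and it
  cannot produce the degenerate all-zero mean template that averaging
  unaligned subjects can.

## Degenerate inputs and numerical details

Constant vertex series are zeroed and flagged rather than normalized;
their correlations are excluded. Fisher z clips correlations at
1 − 1e-7 so duplicated sessions stay finite. Singleton parcels score
zero homogeneity with a warning; within-parcel task variance is the
population variance, which is well defined (0) for singletons. Zero
degree nodes abort the NetMF computation with the offending vertex
named. An all-zero tensor yields an all-zero factorization without NaNs.
k-means relies on the library's internal empty-cluster repair; the
winning restart's cost is retained alongside every trial's cost so the
argmin contract is auditable.

## What the synthetic generator emulates — and what it does not

The generator plants: smooth nonnegative spatial maps (sums of
hop-distance Gaussian bumps, width `smoothness` in hops, around
farthest-point-sampled centers assigned to networks so same-network
territories are maximally separated); controllable overlap between
adjacent networks (0 = disjoint supports, 1 = unrestricted bumps);
temporally autocorrelated unit-norm time courses (Gaussian-filtered
noise, filter width 4 samples); positive subject participation; Haar
orthogonal per-subject temporal mixing (QR of a Gaussian matrix); the
one/two-session concatenation rule; i.i.d. Gaussian noise whose sd is
specified *relative to the clean-signal sd* so noise levels are
resolution-independent; and task contrasts as noisy nonnegative
combinations of the planted maps grouped into named tasks. The planted
parcellation is each vertex's argmax network split into contiguous
pieces.

It does not model hemodynamics, scanner physics, motion, physiological
confounds, spatially correlated noise, inter-subject anatomical
misalignment, or a medial wall (though a validity mask is supported
throughout). Passing tests therefore demonstrate correctness of the
algorithms under the model's own assumptions — exact synchronizability
and a low-rank shared structure — not performance on real recordings,
where those assumptions hold only approximately.

One nuance the generator makes explicit: orthogonal temporal mixing
preserves the *uncentred* (cosine) vertex-pair similarity exactly, but
Pearson correlation only approximately, because per-vertex demeaning
does not commute with the temporal transform. The synchronizer operates
on demeaned, normalized series, where the distinction vanishes in the
noiseless limit.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so
the full suite completes in well under a minute while every recovery
property remains non-trivial: icosphere-3 hemispheres (642 vertices,
hop diameter 24, so the tuned nb = 55 rescales to 7), 10 planted parcels
per hemisphere driven by 6 overlapping networks, 8 subjects (two
single-session) at 60 time points per session, relative noise sd 0.3,
k-means with 50 restarts, 50 random-parcellation null draws per parcel
count, and CP recovery tensors of size 162×120×12.

## Known limitations

- ALS CP can need many iterations near-degenerate magnitude spectra; no
  line search or acceleration is implemented (desk-scale tensors do not
  need it), and rank selection is the caller's responsibility.
- No contiguity post-processing: parcels are usually connected because
  of the hop constraint, but connectivity is reported, not enforced.
- Dense |V|×|V| similarity and NetMF matrices bound the practical mesh
  size to a few thousand vertices per hemisphere in this implementation.
- The embedding/k-means stage is per hemisphere; no cross-hemisphere
  label correspondence is attempted.
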