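# tensorparc

Cortical parcellation from multi-subject resting-state surface fMRI via
unconstrained tensor decomposition and graph node embedding.

Group parcellations divide the cortical surface into disjoint, spatially
contiguous regions whose vertices behave alike — the working units for
connectivity and task-activation analyses. Most data-driven parcellations
start from features constrained to be orthogonal (PCA) or statistically
independent (ICA), assumptions that real functional networks, which
overlap and correlate, do not obey. `tensorparc` instead derives vertex
features from an *unconstrained* canonical-polyadic (CP) decomposition of
the group data and turns them into parcels with a random-walk graph
embedding, so the parcel boundaries follow the transitions of overlapping
functional networks.

## The model

Per-subject time series on a shared triangle mesh are first made
comparable: each vertex series is z-normalized and every subject is
temporally aligned to a group template by the orthogonal transform

    O_s = argmin_{O orthogonal} || template − O X_s ||_F²,

solved in closed form from an SVD and iterated against the mean of the
aligned subjects. The synchronized data form a tensor
`X ∈ R^{|V|×T×S}` (vertices × time × subjects) fitted by a rank-R CP model

    X ≈ Σ_{r=1..R} λ_r · a_r ∘ b_r ∘ c_r,

where each term is a "network": spatial map `a_r`, time course `b_r`,
subject participation `c_r`, magnitude `λ_r` — with **no** orthogonality
or independence imposed, so the maps `a_r` may overlap and correlate.
The maps give every vertex an R-dimensional participation feature.

Per hemisphere, the Pearson correlation `A = corr(X_features)` of these
feature vectors is kernelized, `Ã_ij = exp(A_ij / 2σ²)` with σ = 0.5, and
restricted to an `nb`-hop mesh neighborhood (long-range similarity is
discarded to keep parcels contiguous). The NetMF matrix

    M = log max{ vol(G)/(b·T_win) · (Σ_{r=1..T_win} (D⁻¹Ā)^r) D⁻¹ , 1 }

is the closed-form equivalent of DeepWalk skip-gram embeddings; its
truncated SVD gives `B = U_d Σ_d^{1/2}` (d = 128), and k-means over the
rows of `B` (best of many restarts) yields the parcellation. Tuned
`(nb, T_win)` values follow a schedule in the requested parcel count and
are rescaled to the mesh's hop diameter.

Parcellations are scored by Fisher-z RSFC homogeneity
`ρ = Σ_i ρ_i V_i/|V|`, within-parcel task-contrast variance
`σ² = Σ_i σ_i² V_i/|V|`, adjusted Rand index, Hungarian/Dice parcel
matching, and ratio curves against region-growing random parcellations.
A seeded synthetic generator plants overlapping networks, subject mixing
and a ground-truth parcellation on an icosphere so the whole chain is
testable without any data download.

## Worked example

```python
import numpy as np, tensorparc as tp

mesh = tp.build_icosphere(3)                      # 642-vertex hemisphere
truth = tp.make_ground_truth(mesh, n_parcels=10, R=6, n_timepoints=120,
                             n_subjects=8, noise_sd=0.3, seed=0)
subjects, _ = tp.make_dataset(truth, S=8, T_session=60,
                              sessions_per_subject=[2, 2, 2, 1, 2, 2, 1, 2], seed=1)

sync = tp.sync_group([tp.normalize_timeseries(s)[0] for s in subjects])
tensor = tp.GroupTensor(np.stack([a.T for a in sync.aligned], axis=2))
networks = tp.cp_decompose(tensor, R=6, seed=0)

parc = tp.parcellate_hemisphere(tp.feature_matrix(networks), mesh, k=10,
                                config=tp.ParcellateConfig(n_init=50, seed=0))

ari = tp.adjusted_rand_index(truth.parcellation.labels, parc.labels)
rho = np.mean([tp.homogeneity(tp.rsfc_z(s)[0], parc).weighted_average
               for s in subjects])
print(f"CP relative error:    {networks.rel_error:.3f}")
print(f"parcel sizes:         {parc.parcel_sizes}")
print(f"homogeneity (rho):    {rho:.4f}")
print(f"ARI vs planted truth: {ari:.3f}")
```

prints

```
CP relative error:    0.447
parcel sizes:         [91 84 76 76 71 67 50 45 42 40]
homogeneity (rho):    1.1409
ARI vs planted truth: 1.000
```

The CP fit stops at the injected noise floor (relative error ≈ the noise
fraction of the data), the ten recovered parcels cover all 642 vertices,
and the parcellation matches the planted truth exactly (ARI 1.0); the
mean homogeneity is the subject-average within-parcel Fisher-z
connectivity, which for random parcellations of the same size is
substantially lower.

The same chain is available from the shell:

```bash
tensorparc run --seed 0 --out demo_run -k 10 --n-init 50
```

which writes GIFTI label files, HDF5 audit bundles, a CSV/JSON
evaluation report and a reproducibility manifest into `demo_run/`.

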