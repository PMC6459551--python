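# amvml

Adaptive multi-view multi-label learning for miRNA–disease association
prediction.

MicroRNAs (miRNAs) regulate gene expression post-transcriptionally, and their
dysregulation is implicated in many human diseases, but experimentally
confirming which miRNAs drive which diseases is slow and expensive.  Given a
sparse binary catalogue of known disease–miRNA associations and several
heterogeneous similarity matrices per entity space (disease semantic
similarity from the MeSH hierarchy, miRNA sequence / functional / kernel
similarities), this package ranks the unobserved pairs so that likely true
associations surface at the top.  It is aimed at computational biologists who
want a reproducible, well-tested implementation of adaptive multi-view graph
learning for bipartite link prediction, complete with the standard
cross-validation protocols of the field.

## The model

Let `Y ∈ {0,1}^{q×p}` be the disease × miRNA association matrix, `AD^(v)`
(v = 1..m) disease similarity views and `AM^(u)` (u = 1..n) miRNA similarity
views.  AMVML jointly learns row-stochastic affinity graphs `SD` (q×q), `SM`
(p×p) and a score matrix `F ∈ R^{q×p}` by minimizing

    Ω = Σ_v w_D^(v) ‖SD − AD^(v)‖_F²  +  2α Tr(Fᵀ L_SD F)
      + Σ_u w_M^(u) ‖SM − AM^(u)‖_F²  +  2β Tr(F L_SM Fᵀ)
      + ‖F − Y‖_F²
    s.t.  SD_i 1 = 1, SD ≥ 0,   SM_i 1 = 1, SM ≥ 0,

where `L_S = D_S − (Sᵀ+S)/2` is the graph Laplacian and the view weights are
not free parameters but are re-estimated from the data as
`w^(v) = 1 / (2‖S − A^(v)‖_F)` — views closer to the learned consensus get
larger weight (self-conducted weight learning).  The alternating optimization
uses exact coordinate minimizers: a sorting-based Euclidean projection onto
the probability simplex for each row of `SD`/`SM`, and a Sylvester equation
for `F`, so the objective provably never increases within an inner loop.

## Worked example

```python
import numpy as np
from amvml import make_block_instance, fit_amvml, kfold_cv

# seeded synthetic benchmark: 60 diseases x 80 miRNAs in latent blocks,
# two similarity views per space (one faithful, one pure noise)
inst = make_block_instance(seed=7)
state = fit_amvml(inst.views_D, inst.views_M, inst.Y)
print("disease-view weights:", np.round(state.wD, 4))
print("miRNA-view weights:  ", np.round(state.wM, 4))

i = 0  # rank candidate miRNAs for the first disease
cand = np.flatnonzero(inst.Y.matrix[i] == 0)
top = cand[np.argsort(-state.F[i, cand])[:5]]
for rank, j in enumerate(top, 1):
    print(rank, inst.Y.mirna_ids[j], f"{state.F[i, j]:.4g}",
          "true propensity", inst.propensity[i, j])

report = kfold_cv(inst.views_D, inst.views_M, inst.Y, k=5, repeats=2, seed=7)
print(f"5-fold mean AUC: {report.auc:.3f} +/- {report.auc_sd:.3f}")
```

prints

```
disease-view weights: [0.0167 0.0162]
miRNA-view weights:   [0.0143 0.0118]
1 m64 0.0002706 true propensity 0.45
2 m63 0.0002548 true propensity 0.45
3 m69 0.0002536 true propensity 0.45
4 m65 0.0002081 true propensity 0.45
5 m12 0.0001929 true propensity 0.45
5-fold mean AUC: 0.829 +/- 0.010
```

The faithful view (first entry) receives the larger weight in both spaces,
all five top-ranked candidate miRNAs are true high-propensity pairs that were
simply not sampled into `Y`, and masked associations are recovered with a
mean AUC of 0.83.  The same pipeline is available from the shell:

```bash
amvml simulate --q 60 --p 80 --seed 7 --out-dir sim/
amvml fit --assoc sim/Y.csv --dense \
    --disease-view sim/ad1.csv --disease-view sim/ad2.csv \
    --mirna-view sim/am1.csv --mirna-view sim/am2.csv \
    --out F.csv --trace trace.tsv
amvml predict --assoc sim/Y.csv --dense --disease d0 --top 10 \
    --disease-view sim/ad1.csv --disease-view sim/ad2.csv \
    --mirna-view sim/am1.csv --mirna-view sim/am2.csv
```

`amvml build-sim` constructs the similarity views from raw inputs (a MeSH
parent→child edge list, mature sequences as FASTA, the association matrix
itself for interaction-profile kernels and functional similarity), and
`amvml evaluate` runs global leave-one-out, repeated k-fold,
leave-one-disease-out or temporal top-N validation and writes a JSON report.

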