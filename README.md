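# specmatch

Spectral template matching for topological signals in single-cell
expression data.

Single-cell RNA-seq profiles superimpose several biological signals —
cell cycle, circadian rhythm, spatial zonation, cell-type structure —
and the one you care about is often masked by the others.  `specmatch`
targets a signal through its *topology*: if cells are arranged along a
cycle (or a chain, clusters, several coupled cycles, or a 2D tissue),
the theoretical cell–cell covariance of that arrangement has a known
spectrum, and the data can be matched against it directly, without
low-dimensional embedding.  The package reconstructs the cell ordering
along the topology, scores genes by how much they carry the signal, and
either **enhances** the signal (keeping only the expression that
projects onto the template spectrum) or **filters** it out (removing
that projection), leaving a full-size expression matrix usable by any
downstream tool.

## The model

For cells on a cycle with neighbor correlation α ∈ (0,1), the expected
cell–cell covariance is the symmetric circulant matrix
C<sub>kj</sub> = α^min((j−k) mod n, (k−j) mod n).  Its eigenvalues are
the discrete cosine transform of the first row and its eigenvectors are
phase-shifted Fourier modes — both closed-form.  For a linear chain the
covariance is the Kac–Murdock–Szegő matrix α^|i−j| with a classical
eigenvalue approximation λ_i = (1−α²)/(1+α²−2α·cos((i+1)π/(n+1))).
Cluster, block-circulant, and spatial heat-kernel templates are
decomposed numerically.

All stages maximize or minimize the same spectral projection score

&nbsp;&nbsp;&nbsp;&nbsp;S(B) = Σ_i λ_i ‖Bᵀ v_i‖² = trace(C·BBᵀ),

with (λ_i, v_i) the retained template eigenpairs:

1. **Ordering** — argmax over permutations E of S(E·A), relaxed to the
   Birkhoff polytope of doubly stochastic matrices, solved by projected
   stochastic gradient ascent with Bregmanian bi-stochastication, and
   greedily rounded to a permutation.
2. **Gene inference** — argmin over diagonal 0 ≤ D ≤ I of
   S(A·D) − γ‖D‖₁; the complement I−D scores gene informativeness.
3. **Enhancement** — argmax over elementwise 0 ≤ F ≤ 1 of
   S(A∘F) − γ‖F‖₁ (projected stochastic ascent); A_enhanced = A∘F.
4. **Filtering** — argmin of the same objective (convex; deterministic
   projected descent); A_filtered = A∘F.

## Worked example

```python
import numpy as np
from specmatch import SpectralTemplateModel, simulate, evaluate as ev

ds = simulate.simulate_cyclic(simulate.SimulationParams(p=400, k=4, q=50, seed=0))
model = SpectralTemplateModel(ds.matrix, template="cyclic", alpha="auto")
res = model.fit(workflow="enhance")
print(res.summary())
print(ev.circular_rank_correlation(res.order_, ds.true_order))
```

```
Spectral template matching results
============================================
template kind           cyclic
cells (n)               84
genes (p)               400
alpha                   0.950
top component dropped   True
workflow                enhance
ordering source         reconstructed
relaxed objective       116.616
rounded objective       124.555
projection proportion   0.1519 (ordered)
                        0.5469 (enhanced)
gamma (genes)           0.6011
informative genes       152/400
============================================
0.998
```

The simulator plants a binary cyclic signal (each cell flips `k=4` of
`p=400` genes relative to its neighbor) and shuffles the rows.  The
fitted α is the neighbor correlation whose template spectrum best
matches the data.  The recovered ordering agrees with the planted one
at circular rank correlation 0.998 (orderings are identified up to
circular shift and reflection).  The projection proportion — the
fraction of total variance lying in the span of the retained template
eigenvectors — rises from 0.15 to 0.55 after enhancement;
`res.gene_scores_` ranks genes by informativeness for the cyclic
signal.

The same workflow is exposed as a CLI:

```bash
specmatch simulate --kind composite -p 200 -k 3 -q 40 --seed 1 -o mix.csv
specmatch reconstruct mix.csv --template cyclic -o rec/
specmatch infer-genes rec/ordered.csv --template cyclic -o scores.csv
specmatch filter rec/ordered.csv --template cyclic -o filtered/
specmatch evaluate rec/ordered.csv --template cyclic -o report.json
```

and as a declarative pipeline (`specmatch run config.yaml`) that writes
the ordered matrix, gene scores, masks, enhanced/filtered matrix, an
evaluation report, and a manifest with the config hash and seed.

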