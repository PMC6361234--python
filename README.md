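# smssvd

Adaptive noise-reducing low-rank matrix decomposition for wide
(variables ≫ samples) data, with the synthetic benchmark and evaluation
tooling used to characterize it.

Given a `P × N` data matrix `X` (variables in rows, samples in columns),
the method iteratively extracts orthogonal low-rank signals:

1. **Selection** — choose a variable subset by sweeping variance-filtering
   thresholds jointly with candidate dimensions, scored by the *projection
   score*: the top-`d` singular-mass fraction of the selected submatrix
   minus its expectation under a within-variable permutation null.
2. **SVD** — take the rank-`d` truncated SVD of the selected submatrix and
   keep its right-singular subspace `Π`.
3. **Expansion** — compute the SVD of `X` restricted to `Π`, which carries
   the signal back to *all* variables while leaving the selected rows
   intact.
4. **Signal removal** — deflate, `X ← (I − U Uᵀ) X`, and repeat.

The concatenated factors `U Σ Vᵀ` behave like an SVD (orthonormal `U`
and `V` columns across all signals) and coincide with the truncated SVD
when selection is disabled. The method is parameter-free: the threshold
and dimension of each signal are chosen automatically.

## Library use

```python
import numpy as np
from smssvd import DataMatrix, SMSSVDConfig, smssvd, reconstruct

X = DataMatrix(np.loadtxt("expr.txt"))       # or smssvd.read_matrix(...)
result = smssvd(X, target_dim=7, config=SMSSVDConfig(seed=1))
for k, sig in enumerate(result.signals, 1):
    print(k, sig.d, sig.threshold, sig.score, sig.selection.n_selected)
denoised = reconstruct(result)               # U diag(sigma) V^T
```

`target_dim=None` runs open-ended: iteration stops when no variable
subset beats the permutation null.

Synthetic benchmark data (orthogonal sparse-support signals with
geometric power decay `0.6^(k−1) 0.9^(i−1)` plus Gaussian noise):

```python
from smssvd import SyntheticConfig, generate_dataset, greedy_match
ds = generate_dataset(SyntheticConfig(P=5000, N=100, L=64, K=8, d=2,
                                      noise_sigma=0.05, seed=0))
```

## Command line

```sh
smssvd decompose --input X.tsv --dims 7 --seed 1 --out run1
smssvd simulate  -P 5000 -N 100 -L 64 -K 8 -d 2 --noise-sigma 0.05 \
                 --seed 0 --out sim0
smssvd fixture   --regime non_signal_only --noise-sigma 0.01 --out fig4
smssvd benchmark --grid grid.json --replicates 10 --seed 0 --out bench
smssvd score     --coords run1.V.tsv --labels labels.tsv
```

`decompose` writes `<out>.U.tsv`, `<out>.V.tsv`, `<out>.sigma.tsv`,
`<out>.signals.json` (per-signal dimension, threshold, score, selected
variables) and `<out>.scoregrid.<k>.tsv` (the projection-score grid of
each iteration, for threshold-sweep plots). Matrix inputs are TSV/CSV
(ids in first column/header row) or MatrixMarket with
`<stem>.rownames`/`<stem>.colnames` sidecars. Exit codes: 0 success,
1 data error, 2 usage error.

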