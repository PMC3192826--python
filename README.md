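# vbgen — virtual brain generator

`vbgen` reconstructs functional connectivity networks ("virtual brains")
whose dynamics reproduce a prescribed multi-band power spectrum, and analyses
what those networks have in common. It is aimed at computational
neuroscientists studying what brain rhythms — the frequency bands seen in
EEG/MEG recordings over a 1/f² background — imply about the *functional*
(not anatomical) coupling between recorded channels.

## The model

Channel activity is modeled as a multivariate Ornstein–Uhlenbeck process

    dx/dt = W x + σ ξ(t),

where `x(t)` holds the N channel signals, `ξ` is channel-wise white noise and
`W` (units 1/s) is the functional connectivity matrix: the sign of `W_ij` is
functional excitation or inhibition of node *i* by node *j*. The
channel-averaged power spectrum of this process is

    P(f) = (σ²/N) · ‖(i·2πf·I − W)⁻¹‖²_F ,

a superposition of Lorentzians: each complex eigenvalue pair a ± ib of `W`
produces a spectral peak at b/2π Hz with half width at half maximum |a|/2π Hz,
and the real eigenvalues build the non-oscillatory background. Prescribing the
peaks of a spectrum therefore prescribes the eigenvalues of `W`, and network
reconstruction becomes an **inverse eigenvalue problem** (IEP): find a real
matrix with those eigenvalues and a prescribed sparsity pattern (by default
35% of the off-diagonal entries forced to zero). `vbgen` solves it with an
isospectral gradient flow: the candidate `X = V Λ V⁻¹` has the prescribed
spectrum for every invertible `V`, and the matrix ODE
`dV/dt = −(X Rᵀ − Rᵀ X)ᵀ V⁻ᵀ` (with `R` the deviation from the prescribed
entries) drives the prescribed entries toward zero until the residual `‖R‖_F`
falls below a size-scaled threshold.

Five spectral scenarios are built in: **Normal** (peaks evenly spaced on a
logarithmic frequency axis), **Entrained** (peaks at exact rational ratios,
default 2.7 and 8.1 Hz, modeling cross-frequency phase-locking as seen in
epilepsy), **Incomplete** (high-frequency peaks missing, as in schizophrenia),
**Background** (no peaks, pure 1/f² control) and **Random** (peaks uniform on
the log-frequency axis). On top of the reconstruction, the package provides
the full forward/analysis stack: Euler–Maruyama simulation (white or low-pass
filtered drive), Welch spectra and spectrograms, analytic cross-spectrum /
coherence / phase, stationary covariance in closed form, Tononi–Sporns–Edelman
(TSE) neural complexity, the Total-Nodal-Strength (TNS) hierarchy,
node-removal spectral perturbation, a signed motif census among hub nodes and
a bootstrap test for group differences.

## Worked example

```python
import numpy as np
from vbgen import (PrescriptionConfig, build_prescription, solve_iep,
                   stationary_covariance, tse_complexity, tns_and_hierarchy,
                   eigenvalue_mismatch)

cfg = PrescriptionConfig(n_peaks=2, n_nodes=20)        # desk-scale Normal
presc = build_prescription("Normal", cfg, seed=1)       # peaks at 2 and 5.2 Hz
cm = solve_iep(presc, seed=1)
print(f"residual {cm.residual:.4f} (threshold {cm.threshold:.4f}), "
      f"converged={cm.converged}")
print(f"eigenvalue mismatch {eigenvalue_mismatch(cm.W, cm.eigenvalues):.2e}")
print(f"sparsity {100*np.mean(np.abs(cm.W) < 0.01*np.abs(cm.W).max()):.1f}%")
C = stationary_covariance(cm.W, 1.0)
_, hier = tns_and_hierarchy(cm.W, C)
print(f"TSE complexity {tse_complexity(C):.3f}, half-rank {hier.half_rank}")
```

prints

```
residual 0.6013 (threshold 0.6013), converged=True
eigenvalue mismatch 6.93e-16
sparsity 45.5%
TSE complexity 16.478, half-rank 6
```

The flow stopped exactly at the size-scaled residual threshold (0.6013 is the
80-node reference value 10 scaled by the number of prescribed entries); the
reconstructed matrix carries the prescribed eigenvalues to machine precision;
45.5% of its entries are negligible — sparser than the 35% lower bound
prescribed; and the network is hierarchical: the six strongest of twenty
nodes carry half the total nodal strength. The same pipeline on a Background
prescription yields a much flatter network (half-rank 9) with far lower TSE
complexity (1.905 versus 16.478) — rhythms imply hierarchy and complexity.

A command-line interface mirrors the pipeline:

```
vb prescribe --group Entrained --out presc.yaml
vb solve --prescription presc.yaml --seed 1 --out w.csv
vb simulate --w w.csv --duration 60 --out panel.csv
vb spectrum --panel panel.csv --out spectrum.csv
vb analyze --w w.csv --report report/
vb motifs --w w.csv --out motifs.csv
vb study --out study/          # full multi-group comparison
```

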