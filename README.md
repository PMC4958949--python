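# dicrecon

Quantitative reconstruction of differential interference contrast (DIC)
micrographs.

DIC microscopy is a label-free technique whose images show optical path
length (OPL) *differences* along the instrument's shear axis: objects appear
as bright/dark shadow-cast reliefs on a mid-gray background rather than as
quantitative intensity maps. That makes raw DIC images easy to read by eye
but hard to segment, threshold or measure. `dicrecon` inverts the image
formation and recovers the underlying OPL distribution, turning DIC into a
quantitative phase-imaging modality — useful for anyone doing label-free
high-content imaging of cells, tissue or micro-fabricated structures.

## The model and the algorithms

Under the linear image-formation model a DIC image `G` is the local
correlation of the OPL map `I` with a derivative-type point spread function
`K` oriented along the unit shear vector **u** = [u v]ᵀ (u² + v² = 1):

    G(x, y) = ∬_W K(ξ, η) I(x + ξ, y + η) dξ dη,     W = [−d, d]²,

with `K` a zero-sum kernel — the first derivative of a Gaussian, or the
difference of two Dirac deltas. The package's core algorithm reconstructs
`I` by minimizing a total-variation-regularized energy

    E(I) = ∬_Ω (K ∗ I − G)² dΩ + λ ∬_Ω |∇I| dΩ,

by explicit gradient descent on the Euler–Lagrange equations, with three
interchangeable discretizations of the data term (a bilinear Taylor scheme,
a piecewise-constant scheme for shear-symmetric kernels, and the default
kernel-side scheme that moves the derivative onto an integral kernel `K₀`
with vanishing boundary differences, supporting arbitrary PSFs). Six
baselines are included for comparison: Hilbert transform, Wiener filtering,
Yin inverse filtering, SEMU (nonnegative multiplicative updates), SOCP
(a TV + L1 cone program solved to global optimality by primal–dual
splitting), and the earlier Feineigle variational method.

Around the solvers the package provides:

* a forward simulator and a synthetic benchmark generator (20 geometric
  phantoms — 15 strictly two-valued, 5 multi-level — plus a spherical-bead
  phase phantom), so everything is testable without any downloads;
* evaluation: min-max normalization, MSE against grayscale ground truth,
  and threshold-sweep ROC/AUC against binary masks;
* bead-based calibration that converts reconstructed intensities into
  physical optical path length.

## Worked example

```python
import numpy as np
from dicrecon import (make_dirac_difference, ShearSpec, simulate_dic,
                      reconstruct_proposed, VariationalParams,
                      normalize_pair, mse, pearson)

shear = ShearSpec.from_degrees(45.0)          # diagonal shear
psf = make_dirac_difference(shear, offset=1.0)
truth = np.zeros((64, 64)); truth[20:44, 20:44] = 1.0
dic = simulate_dic(truth, psf)                # bipolar edge image
recon, trace = reconstruct_proposed(dic, psf, VariationalParams(lambda_tv=0.1))
a, b = normalize_pair(recon, truth)
print(f"converged after {len(trace)-1} iterations "
      f"(energy {trace.total[0]:.3f} -> {trace.total[-1]:.6f})")
print(f"normalized MSE vs truth: {mse(a, b):.2e}")
print(f"Pearson correlation:     {pearson(recon, truth):.5f}")
```

Output:

```
converged after 1965 iterations (energy 92.343 -> 9.197406)
normalized MSE vs truth: 3.07e-05
Pearson correlation:     0.99999
```

The energy falls monotonically from 92.3 to the TV floor of the recovered
square; an MSE of 3·10⁻⁵ on the [0, 1] scale means the flat interior and the
sharp edges of the object are both recovered, not just the edge doublets
visible in the raw DIC image.

The same pipeline is available from the shell:

```sh
dicrecon simulate --size 128 --seed 1 --out data/
dicrecon reconstruct data/dic_000.tif recon.tif \
    --algorithm proposed --psf data/psf.tif --lambda 0.1 --trace trace.csv
dicrecon benchmark --algorithms proposed,hilbert,wiener --out scores.csv
dicrecon calibrate bead_recon.tif --pixel-um 0.25 --out cal.yaml
```

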