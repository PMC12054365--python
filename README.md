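# sxcalib

Robust error calibration, merging and intensity diagnostics for serial
crystallography.

## The problem

In serial crystallography (SX), a data set is assembled from diffraction of
thousands of individual crystals ("lattices"), each measured once, with an
X-ray beam that varies shot to shot.  After integration and scaling, each
observation of a Miller index *h* carries an intensity *I<sub>hk</sub>* and a
counting-statistics uncertainty σ<sub>hk</sub> — but counting statistics is
only the *lower bound* of the real measurement error.  Before merging,
the counting sigmas must be *calibrated*: transformed empirically so that
they explain the observed spread of redundant, symmetry-equivalent
measurements.  Only then is inverse-variance weighted merging — the
maximum-likelihood estimate of the mean intensity — actually optimal, and
only then do downstream consumers of σ (outlier rejection, French–Wilson
conversion, refinement) behave as intended.

`sxcalib` implements two calibrations behind a statsmodels-style
model/results interface:

**Ev11** (baseline).  A single global transform

σ′<sub>hk</sub>² = s<sub>fac</sub>² (σ<sub>hk</sub>² + s<sub>B</sub>⟨I<sub>h</sub>⟩ + s<sub>add</sub>²⟨I<sub>h</sub>⟩²)

fitted so that the normalized leave-one-out deviations
δ<sub>hk</sub> = (I<sub>hk</sub> − ⟨I<sub>h</sub>⟩<sub>≠k</sub>) / sd have
unit RMS in each of 100 intensity bins, minimizing
Σ<sub>b</sub> √m<sub>b</sub> (RMS<sub>b</sub>(δ) − 1)².

**MM24** (robust, per-lattice).  Every lattice *l* carries a quality score
cc<sub>l</sub> — the Pearson correlation of its intensities to a scaling
reference — and receives its own error level through

s<sub>add</sub>(cc) = s<sub>add,0</sub> + s<sub>add,1</sub> exp(−s<sub>add,2</sub> cc),  σ′<sub>hk,l</sub>² = s<sub>fac</sub>² (σ<sub>hk</sub>² + s<sub>add</sub>(cc<sub>l</sub>)²⟨I<sub>h</sub>⟩²).

Instead of deviations from an estimated mean, the fit uses normalized
pairwise differences of symmetry mates,
ω<sub>hjk</sub> = |I<sub>hj</sub> − I<sub>hk</sub>| / (σ′<sub>hj</sub>² + σ′<sub>hk</sub>²)<sup>1/2</sup>,
which measure scale without assuming a mean, a symmetric distribution or
equal variances.  Parameters maximize the likelihood of the differences
under a half-normal kernel, or a half Student-*t* kernel with optimizable
degrees of freedom ν for robustness to heavy tails and outliers (ν = 1 is
half-Cauchy; ν → ∞ recovers the half-normal).  Memory is bounded by
subsampling at most 100 pairs per Miller index with a deterministic
per-index PCG64 generator seeded through Cantor's pairing function, so
results are bit-reproducible no matter how the data are partitioned.

The package also provides inverse-variance and unweighted merging,
per-resolution-shell CC<sub>1/2</sub> and ⟨I/σ⟩, the per-lattice
correlation filter, Wilson second-moment diagnostics (observed
⟨I²⟩/⟨I⟩² against the expectation 2 + ⟨σ<sub>Z</sub>²⟩ for acentric
data), rankit (normal-probability) profiles, and a fully model-conforming
synthetic-data generator with exact ground truth.

## Worked example

```python
from sxcalib import (SimulationConfig, simulate_experiment,
                     fit_mm24, merge, binned_stats)

config = SimulationConfig(n_miller=2000, mean_multiplicity=12,
                          n_lattices=100, seed=17)
table, truth = simulate_experiment(config)    # ~24k observations
res = fit_mm24(table, likelihood="half_t")
print(res.summary())
```

```
MM24 error calibration
======================
likelihood:         half_t
pairs (cap 100/index): 128439
s_fac:        1.19208
s_add_0:  0.000222936
s_add_1:     0.160195
s_add_2:      1.78121
nu:               200
NLL: 568602 -> 566639 in 50 iterations
```

The generator's true parameters were (s_fac=1.2, s_add_0=0.01,
s_add_1=0.15, s_add_2=2.0) with Gaussian noise: the fit recovers the
global scale within 1% and the s_add(cc) decay closely, and ν runs to its
upper bound of 200 — the half-*t* correctly collapsing to the half-normal
because the simulated noise has no excess tail.  Merging with the
calibrated sigmas then gives per-shell statistics:

```python
print(binned_stats(table, params=res.params, n_bins=6)
      [["d_max", "d_min", "n_unique", "i_over_sigma", "cc_half"]])
```

```
 d_max  d_min  n_unique  i_over_sigma  cc_half
22.400  2.906       353        28.721    0.998
 2.906  2.307       347        15.360    0.994
 2.307  2.016       312         9.603    0.983
 2.016  1.831       327         5.324    0.927
 1.831  1.700       318         2.891    0.832
 1.700  1.600       343         1.580    0.508
```

⟨I/σ⟩ falls and CC<sub>1/2</sub> decays toward the resolution limit, as
they should for Wilson-distributed intensities under increasing relative
noise.

The same pipeline is available from the shell:

```bash
sxcalib simulate --n-miller 2000 --seed 17 --out run/sim
sxcalib calibrate --reflections run/sim/reflections.tsv \
    --lattices run/sim/lattices.tsv --model mm24 --likelihood half_t \
    --out run/cal
sxcalib merge --reflections run/sim/reflections.tsv \
    --lattices run/sim/lattices.tsv --params run/cal/params.json \
    --out run/merged
sxcalib diagnose --reflections run/sim/reflections.tsv \
    --lattices run/sim/lattices.tsv --params run/cal/params.json \
    --out run/diag
```

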