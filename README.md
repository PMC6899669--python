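# diffct

Differentiable computed-tomography operators on the CPU: ray-driven forward
projectors and voxel-driven back projectors for parallel-, fan- and cone-beam
geometries, filtered backprojection (FBP) and Feldkamp–Davis–Kress (FDK)
reconstruction with Ram-Lak filtering and cosine/Parker short-scan weights,
analytic phantoms, and gradient-based iterative reconstruction — with every
operator carrying an analytic gradient so that whole reconstruction chains
are end-to-end differentiable.

## Who this is for

CT algorithm developers and researchers embedding reconstruction operators
inside gradient-based optimisation or learning pipelines ("known-operator"
or "precision-learning" setups): the projector and back projector are exposed
as layers whose registered gradients are their exact algebraic transposes,
so losses defined on reconstructions can be differentiated back through the
physics without an autodiff framework.

## The model

Data acquisition is the linear system

    A x = p

where `x` is the discretised attenuation volume, `p` the stack of measured
line integrals (the sinogram), and `A` the system matrix, far too large to
store and therefore applied on the fly: the forward projector marches one
ray per detector pixel through the volume (bi/trilinear sampling, step-length
weighting); the back projector projects each voxel onto every detector row
and interpolates (perspective division through 3×4 projection matrices for
cone beam, with the FDK distance weight 1/U² applied in the kernel).

FBP is the discrete realisation of the pseudoinverse factorisation

    x = Aᵀ Fᴴ K F p

with `F` the Fourier transform along detector rows and `K` the diagonal ramp
filter |ω|; divergent-beam scans additionally pre-weight rows by cos γ and,
for a short scan over π + 2γ_max, by Parker's sin² redundancy weights so
every ray carries unit total weight. Iterative reconstruction minimises

    ‖A x − p‖² + λ · TV_ε(x)

by gradient descent through the registered gradient operators, with
step-halving backtracking and a smoothed isotropic total-variation penalty.
The ramp filter itself can also be *learned*: `learn_fbp_filter` optimises
the per-frequency weights `K` of the FBP chain against reference volumes,
which is the classic sanity experiment for differentiable reconstruction —
the learned filter reproduces the analytic ramp discretisation.

## Worked example

```python
import numpy as np
from diffct import (DetectorGeometry, IterativeConfig, VolumeGeometry, fbp,
                    finite_difference_gradcheck, forward_project,
                    iterative_tv, parallel_beam, projector_layer, shepp_logan)

vol_geom = VolumeGeometry(shape=(256, 256), spacing=(1.0, 1.0))  # mm voxels
phantom = shepp_logan(vol_geom)

geom = parallel_beam(vol_geom, DetectorGeometry((363,), (1.0,)),
                     n_views=360, angular_range=np.pi)
sino = forward_project(phantom, geom)          # line integrals, value*mm
recon = fbp(sino, geom)                        # absolute attenuation values

dyn = phantom.values.max() - phantom.values.min()
rmse = np.sqrt(np.mean((recon.values - phantom.values) ** 2)) / dyn
print(f"parallel FBP, 360 views: relative RMSE = {rmse:.4f}")

sparse = parallel_beam(vol_geom, DetectorGeometry((363,), (1.0,)),
                       n_views=30, angular_range=np.pi)
p30 = forward_project(phantom, sparse)
fbp30 = fbp(p30, sparse)
cfg = IterativeConfig(lambda_tv=1.0, step_size=1e-3, iterations=60, init="fbp")
tv30, trace = iterative_tv(p30, sparse, cfg)
e_fbp = np.sqrt(np.mean((fbp30.values - phantom.values) ** 2)) / dyn
e_tv = np.sqrt(np.mean((tv30.values - phantom.values) ** 2)) / dyn
print(f"30-view FBP RMSE = {e_fbp:.4f};  30-view TV RMSE = {e_tv:.4f}")
print(f"objective: {trace[0,2]:.1f} -> {trace[-1,2]:.1f} over {len(trace)-1} steps")

op = projector_layer(geom)
dev = finite_difference_gradcheck(
    op, np.random.default_rng(0).standard_normal((256, 256)), seed=0)
print(f"projector gradcheck deviation = {dev:.2e}")
```

prints

```
parallel FBP, 360 views: relative RMSE = 0.0270
30-view FBP RMSE = 0.1255;  30-view TV RMSE = 0.0824
objective: 127425.5 -> 3421.2 over 60 steps
projector gradcheck deviation = 1.40e-10
```

Read: a 360-view scan reconstructs the phantom to 2.7% of its dynamic range
(discretisation error only — the data are noiseless); at 30 views the TV
prior recovers a third of the streak-artifact error that plain FBP leaves
behind while the objective falls monotonically; and the projector layer's
analytic gradient matches central finite differences to rounding.

The same pipelines are scriptable from the shell via the `diffct` command
(`phantom`, `project`, `fbp`, `iterative`, `gradcheck`, `learnfilter`
subcommands), with volumes and sinograms stored as MetaImage MHD/RAW,
geometries as YAML, and projection matrices as plain text.

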