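"""Known-operator layers: each forward map carries its registered gradient
operator so chains of projections, filters and reconstructions are
end-to-end differentiable.

The registered gradient of every layer is the exact algebraic transpose of
that layer's own forward kernel (ray-driven splatting for the ray-driven
projector, voxel-driven scattering for the voxel-driven backprojector), so a
finite-difference check of any layer converges to machine-level agreement.
The classic *unmatched* pairing — using the voxel-driven backprojector as a
stand-in for the projector's adjoint — remains available through the
projectors module and its discrepancy is quantified there; layers do not use
it because an inexact gradient caps every downstream optimisation at the
pairing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import ScanGeometry
from .phantoms import VolumeGrid
from .projectors import (ProjectionStack, ProjectorConfig, back_project,
                         back_project_transpose, forward_project,
                         forward_project_transpose)
from .filters import FrequencyFilter, filter_projections, pad_length_for

__all__ = [
    "DifferentiableOp",
    "projector_layer",
    "backprojector_layer",
    "finite_difference_gradcheck",
    "learn_fbp_filter",
]


@dataclass
class DifferentiableOp:
    """A forward map bundled with its registered gradient operator.

    ``forward`` maps an input array to an output array; ``gradient`` maps an
    upstream gradient (output-shaped) to an input-space gradient.
    """

    forward: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    name: str = "op"


def projector_layer(geom: ScanGeometry,
                    cfg: ProjectorConfig | None = None) -> DifferentiableOp:
    """Forward projection A with registered gradient A^T."""
    cfg = cfg or ProjectorConfig()

    def fwd(x: np.ndarray) -> np.ndarray:
        return forward_project(VolumeGrid(x, geom.volume), geom, cfg).values

    def grad(g: np.ndarray) -> np.ndarray:
        return forward_project_transpose(ProjectionStack(g, geom), geom, cfg).values

    return DifferentiableOp(fwd, grad, name=f"forward_project[{geom.beam}]")


def backprojector_layer(geom: ScanGeometry,
                        cfg: ProjectorConfig | None = None) -> DifferentiableOp:
    """Voxel-driven back projection B with registered gradient B^T."""
    cfg = cfg or ProjectorConfig()

    def fwd(p: np.ndarray) -> np.ndarray:
        return back_project(ProjectionStack(p, geom), geom, cfg).values

    def grad(g: np.ndarray) -> np.ndarray:
        return back_project_transpose(VolumeGrid(g, geom.volume), geom, cfg).values

    return DifferentiableOp(fwd, grad, name=f"back_project[{geom.beam}]")


def finite_difference_gradcheck(op: DifferentiableOp, x: np.ndarray,
                                seed: int = 0, n_coords: int = 32,
                                h_rel: float = 1e-4) -> float:
    """Central-difference check of a layer's registered gradient.

    A seeded random output weighting ``w`` scalarises the layer as
    ``L(x) = <w, forward(x)>`` so the analytic gradient is ``gradient(w)``.
    It is compared with central differences (step ``h = h_rel * scale``) on a
    seeded random subset of at least ``n_coords`` input coordinates; the
    return value is ``max |analytic - numeric| / max(max|numeric|, eps)``.
    """
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    y = op.forward(x)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"{op.name}: forward produced non-finite values")
    w = rng.standard_normal(y.shape)
    analytic = op.gradient(w)
    if analytic.shape != x.shape:
        raise ValueError(f"{op.name}: gradient shape {analytic.shape} "
                         f"!= input shape {x.shape}")
    if not np.all(np.isfinite(analytic)):
        raise FloatingPointError(f"{op.name}: gradient produced non-finite values")

    flat = x.ravel().copy()
    n = flat.size
    idx = rng.choice(n, size=min(n, max(n_coords, 32)), replace=False)
    scale = max(1.0, float(np.max(np.abs(flat))) if n else 1.0)
    h = h_rel * scale
    numeric = np.empty(idx.size)
    for j, i in enumerate(idx):
        orig = flat[i]
        flat[i] = orig + h
        lp = float(np.vdot(w, op.forward(flat.reshape(x.shape))))
        flat[i] = orig - h
        lm = float(np.vdot(w, op.forward(flat.reshape(x.shape))))
        flat[i] = orig
        numeric[j] = (lp - lm) / (2.0 * h)
    if not np.all(np.isfinite(numeric)):
        raise FloatingPointError(f"{op.name}: non-finite finite-difference values")
    ana = analytic.ravel()[idx]
    denom = max(float(np.max(np.abs(numeric))), 1e-12)
    return float(np.max(np.abs(ana - numeric)) / denom)


# ---------------------------------------------------------------------------
# learning the reconstruction filter through the differentiable chain


def _range_scale(geom: ScanGeometry) -> float:
    # parallel FBP integrates over [0, pi); longer ranges over-count views
    return min(1.0, np.pi / geom.angular_range)


def learn_fbp_filter(stacks: Sequence[ProjectionStack],
                     targets: Sequence[VolumeGrid],
                     init: np.ndarray | FrequencyFilter | None = None,
                     step_size: float | None = None,
                     iterations: int = 100,
                     seed: int = 0,
                     backtracking: bool = True,
                     cfg: ProjectorConfig | None = None
                     ) -> tuple[FrequencyFilter, np.ndarray]:
    """Learn the per-frequency filter weights K of x = B F^H K F p.

    Gradient descent on the quadratic loss ``1/2 sum ||x_hat - target||^2``
    over the training pairs, with the gradient of K flowing through the
    differentiable backprojection layer and the Fourier chain.  The loss is
    an exact convex quadratic in K, so by default (``step_size=None``) the
    descent directions are conjugate-gradient updates with the analytically
    optimal step length, computed from Hessian-vector products read off the
    affine gradient; plain steepest descent stalls on this badly conditioned
    problem.  Passing a numeric ``step_size`` selects plain fixed-step
    gradient descent with halving backtracking instead.  Starting from zero
    weights the iterates stay in the data-supported (Krylov) frequency
    subspace, which is the implicit regularisation that keeps data-starved
    frequencies near zero.  Returns the learned filter and the per-iteration
    loss trace (non-increasing; ``seed`` is unused by the deterministic
    pipeline but kept for interface stability).
    """
    if len(stacks) < 1 or len(stacks) != len(targets):
        raise ValueError("need >= 1 (sinogram, target) pair of equal counts")
    geom = stacks[0].geometry
    if geom.beam != "parallel2d":
        raise ValueError("filter learning operates on parallel2d geometry")
    for st, tg in zip(stacks, targets):
        if st.values.shape != geom.stack_shape or tg.values.shape != geom.volume.shape:
            raise ValueError("training pair shape mismatch")
    cfg = cfg or ProjectorConfig()
    n = geom.detector.shape[0]
    tau = geom.detector.spacing[0]
    n_pad = pad_length_for(n)
    n_freq = n_pad // 2 + 1
    if init is None:
        K = np.zeros(n_freq)
    elif isinstance(init, FrequencyFilter):
        if init.pad_length != n_pad:
            raise ValueError(f"init filter pad_length {init.pad_length} != {n_pad}")
        K = init.weights.copy()
    else:
        K = np.asarray(init, dtype=float).copy()
        if K.shape != (n_freq,):
            raise ValueError(f"init weights must have shape ({n_freq},)")

    scale = _range_scale(geom)
    bp = backprojector_layer(geom, cfg)
    spectra = [np.fft.rfft(st.values, n=n_pad, axis=-1) for st in stacks]
    tvals = [tg.values for tg in targets]
    # Parseval coefficients of the rfft half spectrum
    c = np.full(n_freq, 2.0)
    c[0] = 1.0
    if n_pad % 2 == 0:
        c[-1] = 1.0

    def loss_and_grad(K):
        loss = 0.0
        gK = np.zeros(n_freq)
        for Z, t in zip(spectra, tvals):
            filtered = np.fft.irfft(Z * K, n=n_pad, axis=-1)[..., :n]
            xh = bp.forward(filtered) * scale
            r = xh - t
            loss += 0.5 * float(np.sum(r * r))
            g_filt = bp.gradient(r) * scale           # d loss / d filtered rows
            U = np.fft.rfft(g_filt, n=n_pad, axis=-1)
            gK += np.sum((c / n_pad) * (U * np.conj(Z)).real, axis=0)
        return loss, gK

    loss, gK = loss_and_grad(K)
    losses = [loss]
    if step_size is None:
        # conjugate gradient on the quadratic: H d is read off the affine
        # gradient as grad(K + d) - grad(K), one pipeline pass per iteration
        r = -gK
        d = r.copy()
        for _ in range(iterations):
            rr = float(r @ r)
            if rr < 1e-28:
                break
            _, g_probe = loss_and_grad(K + d)
            Hd = g_probe - gK
            curv = float(d @ Hd)
            if curv <= 0:
                break
            alpha = rr / curv
            K = K + alpha * d
            # quadratic model update: f(K + a d) = f(K) - a r.d + a^2/2 d.H.d
            loss = loss - alpha * float(r @ d) + 0.5 * alpha * alpha * curv
            r = r - alpha * Hd
            d = r + (float(r @ r) / rr) * d
            gK = -r
            losses.append(loss)
    else:
        step = float(step_size)
        for _ in range(iterations):
            accepted = False
            for _try in range(40):
                K_new = K - step * gK
                new_loss, new_g = loss_and_grad(K_new)
                if (not backtracking) or new_loss <= loss:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            K, loss, gK = K_new, new_loss, new_g
            losses.append(loss)
    return FrequencyFilter(np.maximum(K, 0.0), n_pad, tau), np.asarray(losses)
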