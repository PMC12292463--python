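"""Plug-and-play ADMM restoration with a learned denoiser as the prior.

The restored image solves

    argmin_{x,z}  1/2 ||y - x||^2 + rho/2 ||x - z||^2,   z ~ D(x)

where ``y`` is the noisy slice and ``D`` the trained blind-spot denoiser.
The ADMM splitting alternates an exact quadratic x-update

    x = (y + rho (z - u)) / (1 + rho)

with a denoiser z-step and a dual update, for a fixed small number of
iterations (default 3, rho = 1). The data-fidelity term pulls the denoised
estimate back towards the measured image, restoring detail an aggressive
prior would remove.

Two textual ambiguities in this family of methods are resolved by config
flags rather than silently: whether rho multiplies the dual variable in the
x-update (``scaled_x_update``, default True = exact minimiser of the
x-subproblem) and whether the denoiser sees ``x + u`` or ``x`` in the z-step
(``z_from_shifted``, default True = standard scaled ADMM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import NoisyImage

__all__ = ["PnPConfig", "PnPResult", "x_update", "pnp_denoise"]


@dataclass(frozen=True)
class PnPConfig:
    rho: float = 1.0
    n_iters: int = 3
    seed: int = 0
    scaled_x_update: bool = True
    z_from_shifted: bool = True

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if not 1 <= self.n_iters <= 100:
            raise ValueError("n_iters must be in [1, 100]")


@dataclass
class PnPResult:
    """Final estimate plus the per-iteration primal residuals ||x - z||."""

    x: np.ndarray
    residual_history: list[float] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.residual_history)


def x_update(y: np.ndarray, z: np.ndarray, u: np.ndarray, rho: float,
             scaled: bool = True) -> np.ndarray:
    """Exact solution of the quadratic x-subproblem.

    ``scaled=True`` gives (y + rho (z - u)) / (1 + rho), the minimiser of
    1/2||y - x||^2 + rho/2||x - z + u||^2; ``scaled=False`` gives the literal
    reading (y + rho z - u) / (1 + rho).
    """
    if rho <= 0:
        raise ValueError("rho must be > 0")
    y, z, u = (np.asarray(a, dtype=np.float64) for a in (y, z, u))
    if not (y.shape == z.shape == u.shape):
        raise ValueError("y, z, u must share a shape")
    if scaled:
        return (y + rho * (z - u)) / (1.0 + rho)
    return (y + rho * z - u) / (1.0 + rho)


def pnp_denoise(y, model, config: PnPConfig | None = None) -> PnPResult:
    """Run the PnP-ADMM iteration.

    ``model`` is any object exposing ``denoise(image, seed=...) -> array``
    (typically :class:`lungperf.bsn.DenoiserResults`; tests use linear stubs).
    Initialisation: u = 0, z = D(y). Runs exactly ``n_iters`` iterations.
    """
    cfg = config or PnPConfig()
    y = np.asarray(y.pixels if isinstance(y, NoisyImage) else y, dtype=np.float64)
    # one deterministic inference seed per denoiser call
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_iters + 1) % (2**31)
    z = np.asarray(model.denoise(y, seed=int(seeds[0])), dtype=np.float64)
    u = np.zeros_like(y)
    residuals: list[float] = []
    x = z
    for k in range(1, cfg.n_iters + 1):
        x = x_update(y, z, u, cfg.rho, scaled=cfg.scaled_x_update)
        arg = x + u if cfg.z_from_shifted else x
        z = np.asarray(model.denoise(arg, seed=int(seeds[k])), dtype=np.float64)
        if not cfg.z_from_shifted:
            z = z + u  # literal reading: z = D(x) + u
        u = u + x - z
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(z))):
            raise RuntimeError(f"non-finite intermediate at PnP iteration {k}")
        residuals.append(float(np.linalg.norm(x - z)))
    return PnPResult(x=x.astype(np.float32), residual_history=residuals)
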