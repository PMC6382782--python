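"""Total-variation denoising of enface OCT images.

The extraction pipeline removes speckle noise from a grayscale slab image
``g`` by finding the image ``u`` that minimises the Rudin–Osher–Fatemi style
energy

    F(u) = sum_ij |grad u_ij|  +  (1 / 2 lambda) * sum_ij (u_ij - g_ij)^2

where ``grad`` is the forward-difference gradient with replicate (zero-flux)
boundary and ``lambda`` trades smoothing against fidelity: lambda = 0 returns
the input unchanged, larger lambda smooths more.  The minimiser is computed
with Chambolle's dual projection algorithm, which preserves the image mean
and removes speckle while keeping the step edges that delineate retinal
folds.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tv_energy", "tv_denoise"]

#: Dual time step.  Chambolle's convergence proof allows tau <= 1/8; in
#: practice 1/4 converges and is the value used throughout the literature.
_TAU = 0.25


def _forward_grad(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward differences with replicate boundary (last row/col slope 0)."""
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx[:-1, :] = u[1:, :] - u[:-1, :]
    gy[:, :-1] = u[:, 1:] - u[:, :-1]
    return gx, gy


def _divergence(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Discrete divergence, the negative adjoint of :func:`_forward_grad`."""
    div = np.zeros_like(p1)
    div[0, :] += p1[0, :]
    div[1:-1, :] += p1[1:-1, :] - p1[:-2, :]
    div[-1, :] += -p1[-2, :]
    div[:, 0] += p2[:, 0]
    div[:, 1:-1] += p2[:, 1:-1] - p2[:, :-2]
    div[:, -1] += -p2[:, -2]
    return div


def tv_energy(u: np.ndarray, g: np.ndarray, lam: float) -> float:
    """Energy F(u) = TV(u) + ||u - g||^2 / (2 lam).

    Parameters
    ----------
    u, g : ndarray
        Candidate output and original input image, same shape.
    lam : float
        Positive smoothing constant; divides the data-fidelity term.

    Returns
    -------
    float
        Total variation (isotropic, forward differences, replicate
        boundary) plus the scaled squared data misfit.
    """
    u = np.asarray(u, dtype=float)
    g = np.asarray(g, dtype=float)
    if u.shape != g.shape:
        raise ValueError(f"shape mismatch: u {u.shape} vs g {g.shape}")
    if lam <= 0:
        raise ValueError("lam must be positive")
    gx, gy = _forward_grad(u)
    tv = float(np.sum(np.hypot(gx, gy)))
    data = float(np.sum((u - g) ** 2)) / (2.0 * lam)
    return tv + data


def tv_denoise(
    g: np.ndarray,
    lam: float = 12.0,
    max_iter: int = 200,
    tol: float = 1e-4,
    full_output: bool = False,
):
    """Denoise ``g`` by minimising :func:`tv_energy` (Chambolle projection).

    The dual variable ``p`` is iterated as

        p <- (p + tau * grad(div p - g/lam)) / (1 + tau * |grad(...)|)

    and the primal image recovered as ``u = g - lam * div p``.  Iterates are
    only *accepted* when they do not increase the primal energy, so the
    returned trace is non-increasing by construction; the best iterate seen
    is returned.

    Parameters
    ----------
    g : ndarray
        Input grayscale image (any float/int dtype; processed as float64).
    lam : float
        Smoothing constant of the energy.  ``lam = 0`` is the documented
        special case and returns the input unchanged.
    max_iter : int
        Iteration cap.
    tol : float
        Stop when the relative change of ``u`` between iterations falls
        below this value.
    full_output : bool
        If True, also return a dict with the accepted-energy trace and the
        iteration count.

    Returns
    -------
    u : ndarray of float64
        Denoised image, same shape as ``g``; mean preserved.
    info : dict, optional
        Only with ``full_output``; keys ``energy_trace`` (non-increasing
        list starting at F(g)), ``n_iter``.
    """
    g = np.asarray(g, dtype=np.float64)
    if not np.all(np.isfinite(g)):
        raise ValueError("input image contains non-finite pixels")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0:
        u = g.copy()
        if full_output:
            return u, {"energy_trace": [], "n_iter": 0}
        return u

    p1 = np.zeros_like(g)
    p2 = np.zeros_like(g)
    u_best = g.copy()
    e_best = tv_energy(g, g, lam)
    trace = [e_best]
    n_done = 0
    for it in range(max_iter):
        div_p = _divergence(p1, p2)
        gx, gy = _forward_grad(div_p - g / lam)
        norm = np.hypot(gx, gy)
        denom = 1.0 + _TAU * norm
        p1 = (p1 + _TAU * gx) / denom
        p2 = (p2 + _TAU * gy) / denom
        u = g - lam * _divergence(p1, p2)
        n_done = it + 1
        e = tv_energy(u, g, lam)
        if e <= e_best:
            rel = np.linalg.norm(u - u_best) / max(np.linalg.norm(u_best), 1e-12)
            u_best = u
            e_best = e
            trace.append(e)
            if rel < tol and it > 0:
                break
    if full_output:
        return u_best, {"energy_trace": trace, "n_iter": n_done}
    return u_best
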