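"""Independent verification layer: homogeneous steady states, linear
(Turing) stability of the two-species subsystems, and high-accuracy ODE
trajectories of the diffusion-free kinetics.

The three pattern-forming subsystems are analysed as classical two-species
activator-inhibitor pairs with all cross-coupling species frozen at supplied
values: a Turing instability requires the homogeneous steady state to be
stable to uniform perturbations (Laplace-Beltrami eigenvalue lambda = 0) but
unstable in some band of lambda < 0, which on a sphere of radius R is probed
at the discrete eigenvalues lambda_l = -l(l+1)/R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from hydrapattern.model import (SPECIES, SPECIES_INDEX, ModelParameters,
                                reaction_rhs)

#: species pair and frozen set per analysable subsystem
SUBSYSTEMS = {
    "body_axis": ("beta_cat", "beta_cat_ant"),
    "organizer": ("wnt3", "wnt3_ant"),
    "tentacle": ("tent", "tent_ant"),
}


@dataclass
class DispersionResult:
    """Growth rates of a linearized 2-species subsystem over the sphere's
    Laplace-Beltrami spectrum."""

    subsystem: str
    degrees: np.ndarray          # spherical-harmonic degree l
    eigenvalue_grid: np.ndarray  # lambda_l = -l(l+1)/R^2
    growth_rates: np.ndarray     # leading real part per lambda
    unstable_band: np.ndarray    # degrees l with positive growth

    @property
    def turing_unstable(self) -> bool:
        """Stable to uniform perturbations, unstable at some lambda < 0."""
        at_zero = self.growth_rates[self.degrees == 0]
        stable_homogeneous = bool(at_zero.size and at_zero[0] <= 0)
        return stable_homogeneous and bool(
            (self.unstable_band > 0).any())


def _rhs_point(u: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Reaction right-hand side at a single spatial point (9-vector)."""
    return reaction_rhs(u.reshape(len(SPECIES), 1), params).ravel()


def homogeneous_steady_state(params: ModelParameters,
                             frozen: dict[str, float] | None = None,
                             n_starts: int = 24,
                             seed: int = 0,
                             residual_tol: float = 1e-10
                             ) -> list[dict[str, float]]:
    """Non-negative roots of the reaction system with some species frozen.

    Multi-start root finding over the free species (frozen species are held
    at the supplied values and their equations dropped).  Returns every
    distinct non-negative root found, each as a full species -> value map;
    an empty list (not an exception) when no root is located within the
    start budget.
    """
    frozen = dict(frozen or {})
    unknown = set(frozen) - set(SPECIES)
    if unknown:
        raise KeyError(f"unknown frozen species: {unknown}")
    free = [s for s in SPECIES if s not in frozen]
    if not free:
        raise ValueError("frozen species must be a strict subset")
    free_idx = np.array([SPECIES_INDEX[s] for s in free])

    base = np.zeros(len(SPECIES))
    for name, value in frozen.items():
        base[SPECIES_INDEX[name]] = value

    def residual(x):
        u = base.copy()
        u[free_idx] = x
        return _rhs_point(u, params)[free_idx]

    rng = np.random.default_rng(seed)
    starts = [np.zeros(len(free)), np.ones(len(free)),
              np.full(len(free), 0.1)]
    starts += [rng.uniform(0, 3, size=len(free))
               for _ in range(max(0, n_starts - len(starts)))]

    roots: list[np.ndarray] = []
    for x0 in starts:
        sol = root(residual, x0, method="hybr")
        if not sol.success:
            continue
        x = sol.x
        # polish and filter: exact non-negativity up to round-off
        x[np.abs(x) < 1e-13] = 0.0
        if np.any(x < 0):
            continue
        if np.max(np.abs(residual(x))) > residual_tol:
            continue
        if any(np.allclose(x, r, rtol=1e-6, atol=1e-9) for r in roots):
            continue
        roots.append(x)

    out = []
    for r in sorted(roots, key=lambda v: tuple(v)):
        full = base.copy()
        full[free_idx] = r
        out.append({s: float(full[SPECIES_INDEX[s]]) for s in SPECIES})
    return out


def subsystem_jacobian(params: ModelParameters, steady: dict[str, float],
                       subsystem: str, h: float = 1e-7) -> np.ndarray:
    """2x2 Jacobian of the subsystem's kinetics at a steady state,
    with all other species frozen (central finite differences)."""
    pair = SUBSYSTEMS[subsystem]
    idx = [SPECIES_INDEX[s] for s in pair]
    u0 = np.array([steady[s] for s in SPECIES])
    jac = np.zeros((2, 2))
    for j, col in enumerate(idx):
        up, dn = u0.copy(), u0.copy()
        step = h * max(1.0, abs(u0[col]))
        up[col] += step
        dn[col] -= step
        fp = _rhs_point(up, params)[idx]
        fm = _rhs_point(dn, params)[idx]
        jac[:, j] = (fp - fm) / (2 * step)
    return jac


def growth_rate(jac: np.ndarray, diffusion: np.ndarray,
                lam: float) -> float:
    """Leading real part of eig(J + diag(a) * lambda) for one eigenvalue."""
    m = jac + np.diag(diffusion) * lam
    return float(np.max(np.linalg.eigvals(m).real))


def dispersion_relation(params: ModelParameters, steady: dict[str, float],
                        subsystem: str, l_max: int = 30,
                        radius: float = 1.0,
                        residual_tol: float = 1e-8) -> DispersionResult:
    """Turing dispersion curve of one 2-species subsystem.

    For each spherical-harmonic degree l <= l_max the leading eigenvalue of
    ``J + diag(a_activator, a_inhibitor) * lambda_l`` is computed, with
    lambda_l = -l(l+1)/radius^2.  The supplied state must be steady for the
    subsystem pair (other species may be off-equilibrium: they are frozen
    parameters of the analysis).
    """
    if subsystem not in SUBSYSTEMS:
        raise KeyError(f"unknown subsystem {subsystem!r}; "
                       f"known: {sorted(SUBSYSTEMS)}")
    pair = SUBSYSTEMS[subsystem]
    idx = [SPECIES_INDEX[s] for s in pair]
    u0 = np.array([steady[s] for s in SPECIES])
    resid = np.abs(_rhs_point(u0, params)[idx])
    if resid.max() > residual_tol:
        raise ValueError(
            f"state is not steady for subsystem {subsystem!r}: residual "
            f"{resid.max():.3e} > {residual_tol:g}")
    diffusion = params.diffusion_coefficients()[idx]
    jac = subsystem_jacobian(params, steady, subsystem)

    degrees = np.arange(l_max + 1)
    lams = -degrees * (degrees + 1) / radius ** 2
    rates = np.array([growth_rate(jac, diffusion, lam) for lam in lams])
    band = degrees[rates > 0]
    return DispersionResult(subsystem=subsystem, degrees=degrees,
                            eigenvalue_grid=lams, growth_rates=rates,
                            unstable_band=band)


def assemble_linearized_operator(params: ModelParameters,
                                 steady: dict[str, float], subsystem: str,
                                 mesh) -> np.ndarray:
    """Dense 2N x 2N linearization of the subsystem on a mesh.

    Cross-check for the dispersion relation: because both species share the
    same discrete Laplace-Beltrami operator, the spectrum of this block
    operator is exactly the union over the operator's eigenvalues of the 2x2
    dispersion eigenvalues.  Intended for coarse meshes only.
    """
    pair = SUBSYSTEMS[subsystem]
    idx = [SPECIES_INDEX[s] for s in pair]
    jac = subsystem_jacobian(params, steady, subsystem)
    diffusion = params.diffusion_coefficients()[idx]
    a_op = mesh.lb_operator.toarray()
    n = a_op.shape[0]
    eye = np.eye(n)
    top = np.hstack([jac[0, 0] * eye + diffusion[0] * a_op, jac[0, 1] * eye])
    bot = np.hstack([jac[1, 0] * eye, jac[1, 1] * eye + diffusion[1] * a_op])
    return np.vstack([top, bot])


def integrate_ode_oracle(params: ModelParameters,
                         initial: dict[str, float] | np.ndarray,
                         t_end: float,
                         t_eval: np.ndarray | None = None,
                         rtol: float = 1e-9):
    """High-accuracy adaptive integration of the diffusion-free kinetics.

    Independent oracle for the PDE stepper (the reaction system is spatially
    local, so a uniform PDE state must follow this trajectory exactly).
    Returns the scipy ``OdeResult`` with ``y`` of shape (9, len(t)).
    """
    if isinstance(initial, dict):
        u0 = np.array([initial[s] for s in SPECIES], dtype=float)
    else:
        u0 = np.asarray(initial, dtype=float)
    sol = solve_ivp(lambda _, u: _rhs_point(u, params), (0.0, t_end), u0,
                    method="LSODA", rtol=rtol, atol=1e-12, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"ODE oracle failed at t={sol.t[-1]:g}: "
                           f"{sol.message}")
    return sol
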