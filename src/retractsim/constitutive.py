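"""Ogden hyper-viscoelastic constitutive model for brain parenchyma.

The parenchyma is modelled with a one-term Ogden strain-energy density in the
principal stretches,

    W_iso = (2*mu0 / alpha**2) * (lam1b**alpha + lam2b**alpha + lam3b**alpha - 3),

where ``lam_ib = J**(-1/3) * lam_i`` are the isochoric principal stretches,
``mu0`` is the instantaneous shear modulus and ``alpha`` the (sign-free)
material exponent.  Near-incompressibility is enforced by the volumetric
penalty ``W_vol = K/2 * (J - 1)**2``.

Stress relaxation follows a Prony series acting on the isochoric part of the
second Piola-Kirchhoff stress,

    mu(t) = mu0 * (1 - sum_k g_k * (1 - exp(-t / tau_k))),

integrated in time with the standard exponential recursion (exact for a
piecewise-linear stress path within each increment).  All stress routines are
vectorised over arbitrary leading axes so a whole mesh's quadrature points are
processed in single stacked calls.

Internal stress measure is second Piola-Kirchhoff (PK2); :func:`cauchy_from_pk2`
pushes forward for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OgdenPronyMaterial",
    "LinearElasticMaterial",
    "ViscoState",
    "cauchy_from_pk2",
]

_EYE = np.eye(3)


def cauchy_from_pk2(F: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Push a PK2 stress forward to Cauchy: sigma = F S F^T / det(F)."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    return np.einsum("...iI,...IJ,...jJ->...ij", F, S, F) / J[..., None, None]


@dataclass
class ViscoState:
    """Per-quadrature-point viscoelastic history.

    ``h`` holds one stress-like internal tensor per Prony term (the
    exponentially fading memory of the isochoric PK2 stress); ``s_iso_prev``
    is the instantaneous isochoric PK2 stress at the last committed step.
    Fresh states (all zeros) represent the undeformed, fully relaxed tissue.
    """

    n_terms: int
    shape: tuple  # leading (quadrature-point) shape
    h: np.ndarray = field(default=None)  # (n_terms, *shape, 3, 3)
    s_iso_prev: np.ndarray = field(default=None)  # (*shape, 3, 3)
    time: float = 0.0

    def __post_init__(self):
        if self.h is None:
            self.h = np.zeros((self.n_terms, *self.shape, 3, 3))
        if self.s_iso_prev is None:
            self.s_iso_prev = np.zeros((*self.shape, 3, 3))

    def copy(self) -> "ViscoState":
        return ViscoState(self.n_terms, self.shape, self.h.copy(),
                          self.s_iso_prev.copy(), self.time)


@dataclass(frozen=True)
class OgdenPronyMaterial:
    """One-term Ogden hyperelasticity with Prony-series stress relaxation.

    Parameters
    ----------
    mu0 : float
        Instantaneous shear modulus in the undeformed state, Pa.  Must be > 0.
    alpha : float
        Ogden exponent; any non-zero real value.
    prony : tuple of (tau_k, g_k)
        Characteristic times (s, > 0) and relaxation coefficients
        (dimensionless, >= 0, summing to < 1 so the long-term modulus stays
        positive).
    poisson : float
        Equivalent Poisson ratio setting the volumetric penalty; default 0.49
        (near-incompressible).  The bulk modulus is
        ``K = 2*mu0*(1+nu) / (3*(1-2*nu))``.

    Defaults are the swine-brain parameters used throughout the package:
    mu0 = 842 Pa, alpha = -4.7, (tau, g) = (0.5 s, 0.450), (50 s, 0.365).
    """

    mu0: float = 842.0
    alpha: float = -4.7
    prony: tuple = ((0.5, 0.450), (50.0, 0.365))
    poisson: float = 0.49

    def __post_init__(self):
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if self.alpha == 0:
            raise ValueError("alpha must be non-zero")
        taus = [t for t, _ in self.prony]
        gs = [g for _, g in self.prony]
        if any(t <= 0 for t in taus):
            raise ValueError("all Prony times tau_k must be positive")
        if any(g < 0 for g in gs):
            raise ValueError("all Prony coefficients g_k must be >= 0")
        if sum(gs) >= 1.0:
            raise ValueError("sum(g_k) must be < 1 (positive long-term modulus)")
        if not (0 <= self.poisson < 0.5):
            raise ValueError("poisson must lie in [0, 0.5)")

    # -- derived moduli -----------------------------------------------------

    @property
    def bulk_modulus(self) -> float:
        """Volumetric penalty modulus K, Pa."""
        nu = self.poisson
        return 2.0 * self.mu0 * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))

    @property
    def g_inf(self) -> float:
        """Long-term / instantaneous modulus ratio, 1 - sum(g_k)."""
        return 1.0 - sum(g for _, g in self.prony)

    def relaxation_modulus(self, t) -> np.ndarray:
        """Shear relaxation modulus mu(t) = mu0*(1 - sum_k g_k*(1 - e^(-t/tau_k)))."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        mu = np.full(t.shape, self.mu0)
        for tau, g in self.prony:
            mu = mu - self.mu0 * g * (1.0 - np.exp(-t / tau))
        return mu[()] if mu.ndim == 0 else mu

    def fresh_state(self, shape=()) -> ViscoState:
        return ViscoState(len(self.prony), tuple(np.atleast_1d(shape)) if shape else ())

    # -- energy -------------------------------------------------------------

    def energy_density(self, stretches) -> np.ndarray:
        """Instantaneous strain-energy density W at principal stretches, Pa.

        Includes the isochoric Ogden part and the volumetric penalty.
        """
        lam = np.asarray(stretches, dtype=float)
        if np.any(lam <= 0):
            raise ValueError("principal stretches must be positive")
        J = np.prod(lam, axis=-1)
        lamb = lam * J[..., None] ** (-1.0 / 3.0)
        w_iso = (2.0 * self.mu0 / self.alpha**2) * (
            np.sum(lamb**self.alpha, axis=-1) - 3.0
        )
        w_vol = 0.5 * self.bulk_modulus * (J - 1.0) ** 2
        return w_iso + w_vol

    # -- stress -------------------------------------------------------------

    def _pk2_parts(self, C: np.ndarray):
        """Instantaneous isochoric and volumetric PK2 stresses from C = F^T F.

        Works on stacked ``(..., 3, 3)`` tensors via eigendecomposition.
        """
        w, V = np.linalg.eigh(C)
        if np.any(w <= 0):
            raise ValueError("non-positive-definite C (inverted element)")
        lam = np.sqrt(w)
        J = np.prod(lam, axis=-1)[..., None]
        lamb = lam / J ** (1.0 / 3.0)
        sa = lamb**self.alpha
        # dW_iso/dlam_i = (2 mu/alpha)(1/lam_i)(lamb_i^a - mean_j lamb_j^a)
        dw_iso = (2.0 * self.mu0 / self.alpha) / lam * (
            sa - np.mean(sa, axis=-1, keepdims=True)
        )
        s_iso_p = dw_iso / lam  # principal PK2
        s_vol_p = self.bulk_modulus * (J - 1.0) * J / w  # K(J-1) * J / lam_i^2
        s_iso = np.einsum("...ai,...i,...bi->...ab", V, s_iso_p, V)
        s_vol = np.einsum("...ai,...i,...bi->...ab", V, s_vol_p, V)
        return s_iso, s_vol

    def pk2_update(self, C: np.ndarray, state: ViscoState, dt: float):
        """Viscoelastic PK2 stress for trial C after a step of length dt.

        Returns ``(S, h_new, s_iso)`` without mutating ``state``; callers
        commit via :meth:`commit`.  ``dt = 0`` gives the instantaneous
        (unrelaxed) response.
        """
        if dt < 0:
            raise ValueError("dt must be >= 0")
        s_iso, s_vol = self._pk2_parts(C)
        ds = s_iso - state.s_iso_prev
        h_new = np.empty_like(state.h)
        s_dev = self.g_inf * s_iso
        for k, (tau, g) in enumerate(self.prony):
            if dt == 0.0:
                e, c = 1.0, 1.0
            else:
                x = dt / tau
                e = np.exp(-x)
                c = (1.0 - e) / x
            h_new[k] = e * state.h[k] + c * ds
            s_dev = s_dev + g * h_new[k]
        return s_vol + s_dev, h_new, s_iso

    def commit(self, state: ViscoState, h_new, s_iso, dt: float) -> None:
        state.h[...] = h_new
        state.s_iso_prev[...] = s_iso
        state.time += dt

    def stress(self, F: np.ndarray, state: ViscoState | None = None,
               dt: float = 0.0, measure: str = "pk2", update: bool = False):
        """Stress for deformation gradient(s) F held over a step of length dt.

        Parameters
        ----------
        F : (..., 3, 3) array
            Deformation gradient(s); det F must be positive.
        state : ViscoState, optional
            History; a fresh (fully relaxed) state if omitted.
        dt : float
            Step duration, s; 0 gives the instantaneous response.
        measure : {"pk2", "cauchy"}
        update : bool
            Commit the internal-variable update into ``state``.

        Returns
        -------
        (stress, state) — the (possibly updated) state is always returned.
        """
        F = np.asarray(F, dtype=float)
        if np.any(np.linalg.det(F) <= 0):
            raise ValueError("det(F) must be positive (inverted element)")
        if state is None:
            state = self.fresh_state(F.shape[:-2])
        C = np.einsum("...ki,...kj->...ij", F, F)
        S, h_new, s_iso = self.pk2_update(C, state, dt)
        if update:
            self.commit(state, h_new, s_iso, dt)
        if measure == "cauchy":
            return cauchy_from_pk2(F, S), state
        return S, state

    def _iso_factor(self, dt: float) -> float:
        """Weight of the instantaneous isochoric stiffness in the update.

        The internal-variable recursion is linear in the isochoric stress,
        so dS/dC = dS_vol/dC + [g_inf + sum_k g_k c_k(dt)] dS_iso/dC with
        c_k = tau_k (1 - e^(-dt/tau_k)) / dt (-> 1 as dt -> 0).
        """
        f = self.g_inf
        for tau, g in self.prony:
            if dt == 0.0:
                f += g
            else:
                x = dt / tau
                f += g * (1.0 - np.exp(-x)) / x
        return f

    def tangent_dSdC(self, C: np.ndarray, state: ViscoState, dt: float,
                     h_rel: float = 1e-7) -> np.ndarray:
        """Algorithmic material tangent D = dS/dC, minor-symmetric in (K, L).

        Central differences of the exact elastic parts in the six symmetric
        components of C, batched into a single stacked eigendecomposition;
        the Prony recursion enters through its (linear) dt-dependent weight,
        so the result is exactly consistent with :meth:`pk2_update` to
        O(h^2).  ``dS = D : dC`` under full double contraction with a
        symmetric dC.
        """
        C = np.asarray(C, dtype=float)
        lead = C.shape[:-2]
        scale = h_rel * max(1.0, float(np.abs(C).max()))
        pairs = [(K, L) for K in range(3) for L in range(K, 3)]
        perts = [C]
        for K, L in pairs:
            dC = np.zeros((3, 3))
            dC[K, L] += 0.5
            dC[L, K] += 0.5
            perts.append(C + scale * dC)
        batch = np.stack(perts)                      # (7, ..., 3, 3)
        s_iso, s_vol = self._pk2_parts(batch)
        f_iso = self._iso_factor(dt)
        S_eff = s_vol + f_iso * s_iso
        D = np.empty(lead + (3, 3, 3, 3))
        for n, (K, L) in enumerate(pairs):
            dd = (S_eff[n + 1] - S_eff[0]) / scale
            D[..., K, L] = dd
            D[..., L, K] = dd
        # enforce the major symmetry the energy Hessian possesses
        lead_axes = tuple(range(D.ndim - 4))
        D = 0.5 * (D + D.transpose(lead_axes + (D.ndim - 2, D.ndim - 1,
                                                D.ndim - 4, D.ndim - 3)))
        return D


@dataclass(frozen=True)
class LinearElasticMaterial:
    """Small-strain isotropic elasticity exposing the same interface.

    Plug-in comparison material (constant tangent, no history).  Uses the
    Saint-Venant form S = lambda tr(E) I + 2 mu E with E = (C - I)/2, which
    reduces to classical linear elasticity for small strains.
    """

    mu: float = 842.0
    poisson: float = 0.49

    @property
    def lam(self) -> float:
        return 2.0 * self.mu * self.poisson / (1.0 - 2.0 * self.poisson)

    @property
    def bulk_modulus(self) -> float:
        return self.lam + 2.0 * self.mu / 3.0

    def relaxation_modulus(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        return np.broadcast_to(self.mu, t.shape).copy()[()] if t.ndim == 0 \
            else np.full(t.shape, self.mu)

    def fresh_state(self, shape=()) -> ViscoState:
        return ViscoState(0, tuple(np.atleast_1d(shape)) if shape else ())

    def energy_density(self, stretches):
        lam_s = np.asarray(stretches, dtype=float)
        if np.any(lam_s <= 0):
            raise ValueError("principal stretches must be positive")
        e = 0.5 * (lam_s**2 - 1.0)
        tr = np.sum(e, axis=-1)
        return 0.5 * self.lam * tr**2 + self.mu * np.sum(e**2, axis=-1)

    def pk2_update(self, C, state, dt):
        E = 0.5 * (C - _EYE)
        tr = np.trace(E, axis1=-2, axis2=-1)[..., None, None]
        S = self.lam * tr * _EYE + 2.0 * self.mu * E
        return S, state.h, np.zeros_like(S)

    def commit(self, state, h_new, s_iso, dt):
        state.time += dt

    def stress(self, F, state=None, dt=0.0, measure="pk2", update=False):
        F = np.asarray(F, dtype=float)
        if np.any(np.linalg.det(F) <= 0):
            raise ValueError("det(F) must be positive (inverted element)")
        if state is None:
            state = self.fresh_state(F.shape[:-2])
        C = np.einsum("...ki,...kj->...ij", F, F)
        S, _, _ = self.pk2_update(C, state, dt)
        if measure == "cauchy":
            return cauchy_from_pk2(F, S), state
        return S, state

    def tangent_dSdC(self, C, state, dt, h_rel=None):
        C = np.asarray(C, dtype=float)
        D = np.zeros(C.shape[:-2] + (3, 3, 3, 3))
        for i in range(3):
            for j in range(3):
                D[..., i, i, j, j] += 0.5 * self.lam
                D[..., i, j, i, j] += 0.5 * self.mu
                D[..., i, j, j, i] += 0.5 * self.mu
        return D


def uniaxial_incompressible_cauchy(mu: float, alpha: float, lam) -> np.ndarray:
    """Closed-form incompressible uniaxial Ogden Cauchy stress.

    sigma = (2 mu / alpha) * (lam^alpha - lam^(-alpha/2)); the classical
    virtual-test expression used as an oracle for the tensor implementation.
    """
    lam = np.asarray(lam, dtype=float)
    return (2.0 * mu / alpha) * (lam**alpha - lam ** (-alpha / 2.0))
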