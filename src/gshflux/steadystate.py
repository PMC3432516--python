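"""Steady-state computation for kinetic models.

The solver follows the strategy common to steady-state engines for
metabolic ODE models: integrate the ODEs toward stationarity, then polish
the algebraic system N.v(c) = 0 with a damped Newton iteration; if Newton
fails the integration result alone decides convergence.  Conserved moieties
(left-null vectors of the dynamic stoichiometric matrix, detected exactly
with rational arithmetic) make the Jacobian singular, so one ODE per moiety
is replaced by the conservation relation anchored at the starting
concentrations.

Non-convergence is reported through ``SteadyState.converged`` rather than
an exception, because the ensemble engine needs to count failed parameter
draws instead of aborting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import sympy
from scipy.integrate import solve_ivp
from scipy.linalg import lu_factor, lu_solve

from .model import KineticModel, evaluate_rates

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 1e-9  # mM/h, absolute, per dynamic species
DEFAULT_HORIZON = 1e6  # h of model time
_DIVERGENCE_CAP = 1e9  # mM; beyond this the trajectory is deemed unbounded


@dataclass
class SteadyState:
    """Result of a steady-state solve.

    ``residual_norm`` is max |dc/dt| over dynamic species (mM/h) at the
    returned concentrations; ``fluxes`` are the reaction rates there.
    """

    concentrations: Dict[str, float]
    fluxes: Dict[str, float]
    residual_norm: float
    converged: bool
    method_used: str
    conc_vector: np.ndarray
    flux_vector: np.ndarray


class SteadyStateSolver:
    """Reusable solver bound to one model (caches structure between solves)."""

    def __init__(self, model: KineticModel, tolerance: float = DEFAULT_TOLERANCE,
                 horizon: float = DEFAULT_HORIZON) -> None:
        if tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        self.model = model
        self.tolerance = tolerance
        self.horizon = horizon
        self._ev = model._get_evaluator()
        self.dyn = model.dynamic_index
        self.n_dyn = self.dyn.size
        self.stoich_dyn = self._ev.stoich[self.dyn, :]
        self.moieties = _conserved_moieties(self.stoich_dyn)
        # one pivot species per moiety: largest coefficient, distinct rows
        self._pivots: List[int] = []
        taken: set = set()
        for w in self.moieties:
            order = np.argsort(-np.abs(w))
            pivot = next(int(i) for i in order if int(i) not in taken and w[i] != 0)
            taken.add(pivot)
            self._pivots.append(pivot)

    # -- right-hand side ---------------------------------------------------

    def _rhs_dyn(self, x_dyn: np.ndarray, conc_full: np.ndarray,
                 vmax: np.ndarray) -> np.ndarray:
        conc_full[self.dyn] = x_dyn
        rates = self._ev.rates(conc_full, vmax)
        return self.stoich_dyn @ rates

    def _residual(self, x_dyn, conc_full, vmax) -> float:
        return float(np.max(np.abs(self._rhs_dyn(x_dyn, conc_full, vmax))))

    def _newton_system(self, x_dyn, conc_full, vmax, totals):
        """Residual with moiety rows replaced by conservation relations."""
        f = self._rhs_dyn(x_dyn, conc_full, vmax).copy()
        for w, pivot, total in zip(self.moieties, self._pivots, totals):
            f[pivot] = float(w @ x_dyn) - total
        return f

    def _jacobian(self, x_dyn, conc_full, vmax, totals) -> np.ndarray:
        n = self.n_dyn
        f0 = self._newton_system(x_dyn, conc_full, vmax, totals)
        jac = np.empty((n, n))
        for i in range(n):
            h = 1e-7 * max(abs(x_dyn[i]), 1e-3)
            xp = x_dyn.copy()
            xp[i] += h
            jac[:, i] = (self._newton_system(xp, conc_full, vmax, totals) - f0) / h
        return jac

    # -- solving -----------------------------------------------------------

    def solve(
        self,
        vmax_override: Optional[Dict[str, float]] = None,
        x0: Optional[np.ndarray] = None,
        newton_first: bool = False,
    ) -> SteadyState:
        """Full solve: (optional Newton from ``x0``), integrate, Newton polish.

        ``x0`` is a full concentration vector used as the starting point;
        with ``newton_first`` the solver attempts a direct Newton solve from
        it before falling back to time integration (the ensemble warm-start
        path).
        """
        vmax = self.model.vmax_vector(vmax_override)
        conc_full = (x0 if x0 is not None else self.model.initial_concentrations()).astype(
            float
        ).copy()
        x = conc_full[self.dyn].copy()
        totals = [float(w @ x) for w in self.moieties]

        if newton_first and x0 is not None:
            xn, ok = self._newton(x, conc_full.copy(), vmax, totals)
            if ok:
                return self._package(xn, conc_full, vmax, "newton")

        x_int, ok_int = self._integrate(x, conc_full.copy(), vmax)
        if not ok_int:
            return self._package(x, conc_full, vmax, "integration-diverged")
        xn, ok = self._newton(x_int, conc_full.copy(), vmax, totals)
        if ok:
            return self._package(xn, conc_full, vmax, "integration+newton")
        return self._package(x_int, conc_full, vmax, "integration")

    def _integrate(self, x, conc_full, vmax):
        """Advance toward stationarity in expanding time chunks."""
        t = 0.0
        target = max(self.tolerance * 0.01, 1e-13)
        chunk = 10.0
        while t < self.horizon:
            span = min(chunk, self.horizon - t)
            try:
                sol = solve_ivp(
                    lambda _t, y: self._rhs_dyn(np.maximum(y, 0.0), conc_full, vmax),
                    (0.0, span),
                    x,
                    method="LSODA",
                    rtol=1e-8,
                    atol=1e-12,
                )
            except Exception as exc:  # pragma: no cover - integrator failure
                logger.debug("integration failed: %s", exc)
                return x, False
            if not sol.success:
                return x, False
            x = np.maximum(sol.y[:, -1], 0.0)
            if np.any(~np.isfinite(x)) or np.max(x) > _DIVERGENCE_CAP:
                return x, False
            t += span
            if self._residual(x, conc_full, vmax) < target:
                return x, True
            chunk *= 10.0
        return x, True  # horizon reached; Newton (or residual check) decides

    def _newton(self, x, conc_full, vmax, totals, max_iter: int = 60):
        x = np.maximum(x.copy(), 0.0)
        f = self._newton_system(x, conc_full, vmax, totals)
        fnorm = np.max(np.abs(f))
        for _ in range(max_iter):
            if fnorm <= self.tolerance and np.all(x >= 0):
                return x, True
            jac = self._jacobian(x, conc_full, vmax, totals)
            try:
                dx = np.linalg.solve(jac, -f)
            except np.linalg.LinAlgError:
                return x, False
            lam, improved = 1.0, False
            for _bt in range(40):
                xn = x + lam * dx
                if np.all(xn >= 0):
                    fn = self._newton_system(xn, conc_full, vmax, totals)
                    fnn = np.max(np.abs(fn))
                    if np.all(np.isfinite(fn)) and fnn < fnorm * (1 - 1e-4 * lam) + 1e-300:
                        x, f, fnorm, improved = xn, fn, fnn, True
                        break
                lam *= 0.5
            if not improved:
                return x, fnorm <= self.tolerance
        return x, fnorm <= self.tolerance and bool(np.all(x >= 0))

    # -- chord iteration for ensemble warm starts --------------------------

    def factor_jacobian(self, conc_full: np.ndarray,
                        vmax_override: Optional[Dict[str, float]] = None):
        """LU-factored Newton Jacobian at a reference state, for chord solves."""
        vmax = self.model.vmax_vector(vmax_override)
        x = conc_full[self.dyn].copy()
        totals = [float(w @ x) for w in self.moieties]
        jac = self._jacobian(x, conc_full.copy(), vmax, totals)
        return lu_factor(jac)

    def solve_chord(self, vmax_override, x0: np.ndarray, lu,
                    max_iter: int = 40) -> SteadyState:
        """Chord-Newton solve from ``x0`` reusing a factored Jacobian.

        Converges for Vmax draws near the reference because the Jacobian
        varies slowly inside the sampled box; on failure the caller falls
        back to :meth:`solve`.
        """
        vmax = self.model.vmax_vector(vmax_override)
        conc_full = x0.astype(float).copy()
        x = conc_full[self.dyn].copy()
        totals = [float(w @ x) for w in self.moieties]
        f = self._newton_system(x, conc_full, vmax, totals)
        for _ in range(max_iter):
            fnorm = np.max(np.abs(f))
            if fnorm <= self.tolerance and np.all(x >= 0):
                return self._package(x, conc_full, vmax, "chord")
            xn = x + lu_solve(lu, -f)
            if np.any(~np.isfinite(xn)) or np.any(xn < -1e-9):
                break
            xn = np.maximum(xn, 0.0)
            fn = self._newton_system(xn, conc_full, vmax, totals)
            if not np.all(np.isfinite(fn)):
                break
            x, f = xn, fn
        return self._package(x, conc_full, vmax, "chord-failed", force_fail=True)

    # -- packaging ---------------------------------------------------------

    def _package(self, x_dyn, conc_full, vmax, method, force_fail=False) -> SteadyState:
        conc_full = conc_full.copy()
        conc_full[self.dyn] = np.maximum(x_dyn, 0.0)
        rates = self._ev.rates(conc_full, vmax)
        resid = float(np.max(np.abs(self.stoich_dyn @ rates))) if self.n_dyn else 0.0
        converged = (not force_fail) and resid <= self.tolerance and bool(
            np.all(conc_full >= 0)
        )
        sids = self.model.species_ids
        rids = self.model.reaction_ids
        return SteadyState(
            concentrations=dict(zip(sids, conc_full.tolist())),
            fluxes=dict(zip(rids, rates.tolist())),
            residual_norm=resid,
            converged=converged,
            method_used=method,
            conc_vector=conc_full,
            flux_vector=rates,
        )


def _conserved_moieties(stoich_dyn: np.ndarray) -> List[np.ndarray]:
    """Left-null vectors of the dynamic stoichiometric matrix, exact."""
    if stoich_dyn.size == 0:
        return []
    mat = sympy.Matrix(stoich_dyn.T.astype(int))
    return [
        np.array([float(v) for v in vec], dtype=float).ravel()
        for vec in mat.nullspace()
    ]


def solve_steady_state(
    model: KineticModel,
    vmax_override: Optional[Dict[str, float]] = None,
    tolerance: float = DEFAULT_TOLERANCE,
    horizon: float = DEFAULT_HORIZON,
    x0: Optional[np.ndarray] = None,
) -> SteadyState:
    """Compute a steady state of ``model`` under an optional Vmax assignment.

    Returns a :class:`SteadyState`; non-convergence (including trajectories
    that grow without bound, as when a drain Vmax is below a constant input
    rate) is flagged, not raised.
    """
    solver = SteadyStateSolver(model, tolerance=tolerance, horizon=horizon)
    return solver.solve(vmax_override=vmax_override, x0=x0)


def integrate_trajectory(
    model: KineticModel,
    t_end: float,
    vmax_override: Optional[Dict[str, float]] = None,
    x0: Optional[np.ndarray] = None,
    n_points: int = 50,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Brute-force time integration (independent of the steady-state path).

    Returns ``(t, conc)`` with ``conc`` of shape (n_points, n_species);
    boundary species stay clamped.  Used as the long-horizon oracle against
    which the steady-state solver is checked, and for moiety-drift tests.
    """
    vmax = model.vmax_vector(vmax_override)
    ev = model._get_evaluator()
    dyn = model.dynamic_index
    stoich_dyn = ev.stoich[dyn, :]
    conc_full = (x0 if x0 is not None else model.initial_concentrations()).astype(float).copy()

    def rhs(_t, y):
        conc_full[dyn] = y
        return stoich_dyn @ ev.rates(conc_full, vmax)

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), conc_full[dyn].copy(), method="LSODA",
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    out = np.tile(conc_full, (len(sol.t), 1))
    out[:, dyn] = sol.y.T
    return sol.t, out
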