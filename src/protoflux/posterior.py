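"""Truncated-Gaussian characterization of the steady-state flux polytope.

The feasible space ``L = {v : S v = mdot, v_inf <= v <= v_sup}`` is
approximated by Expectation Propagation (EP): the box constraint on each
flux is replaced by a univariate Gaussian site, the stoichiometric
constraint enters as a Boltzmann-like quadratic energy
``E(v) = 1/2 ||S v - mdot||^2`` with stiffness ``beta``, and site moments
are refined against exact truncated-Gaussian tilted moments until the
site parameters stop moving.  The result is a multivariate Gaussian
``N(mu, Sigma)`` whose restriction to the stoichiometric subspace,
truncated to the box, is the sampling distribution for fluxes.

The object model is statsmodels-like: :class:`FluxSpaceModel` holds the
problem, ``fit()`` returns a :class:`FluxPosterior` results object that
can ``sample()``, evaluate ``log_density()`` and print a ``summary()``.
A uniform Hit-and-Run sampler over the same polytope is provided as an
independent moment oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from ._truncnorm import truncnorm_moments, truncnorm_rvs
from .model_io import ConstraintSpec, MetabolicModel, apply_constraints
from .nullspace_modules import nullspace_of

__all__ = [
    "InfeasibleModelError",
    "FluxSpaceModel",
    "FluxPosterior",
    "SampleSet",
    "MomentComparison",
    "ep_fit",
    "condition_on_observed_flux",
    "hit_and_run",
    "moment_comparison",
]

#: max |S v - mdot| allowed for emitted samples
STOICH_TOL = 1e-6
#: box violation allowed for emitted samples
BOX_TOL = 1e-9


class InfeasibleModelError(RuntimeError):
    """The flux polytope is empty under the given bounds."""


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _particular_solution(S, mdot):
    if S.shape[0] == 0:
        return np.zeros(S.shape[1])
    vp, *_ = np.linalg.lstsq(S, mdot, rcond=None)
    return vp


def _interior_point(K, v_p, lo, hi):
    """LP for a maximal-margin interior point of {x : lo <= v_p + K x <= hi}.

    Returns ``(x0, margin)``; raises :class:`InfeasibleModelError` when the
    polytope is empty.  ``margin`` is 0 for polytopes of zero width in
    some direction.
    """
    N, d = K.shape
    norms = np.linalg.norm(K, axis=1)
    live = norms > 1e-12
    # rows with no kernel component must already satisfy their bounds at v_p
    dead = ~live
    if np.any((v_p[dead] < lo[dead] - 1e-9) | (v_p[dead] > hi[dead] + 1e-9)):
        raise InfeasibleModelError("bounds exclude the affine subspace")
    if d == 0:
        return np.zeros(0), 0.0
    A_rows = K[live]
    s = norms[live]
    l = lo[live] - v_p[live]
    u = hi[live] - v_p[live]
    # variables (x, t): maximize t s.t. A x - t s >= l, A x + t s <= u
    A_ub = np.vstack([
        np.hstack([-A_rows, s[:, None]]),
        np.hstack([A_rows, s[:, None]]),
    ])
    b_ub = np.concatenate([-l, u])
    c = np.zeros(d + 1)
    c[-1] = -1.0
    res = linprog(c, A_ub=A_ub, b_ub=b_ub,
                  bounds=[(None, None)] * d + [(0, None)], method="highs")
    if res.status != 0 or res.x is None:
        raise InfeasibleModelError("flux polytope is empty (LP infeasible)")
    margin = float(res.x[-1])
    if margin < -1e-9:
        raise InfeasibleModelError("flux polytope is empty")
    return res.x[:d], max(margin, 0.0)


def _chord_bounds(w, slack_lo, slack_hi):
    """Feasible step interval for moving along direction coefficients w.

    ``slack_lo = lo - v`` (<= 0) and ``slack_hi = hi - v`` (>= 0) are the
    current slacks per reaction; returns (t_lo, t_hi).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = w > 1e-14
        neg = w < -1e-14
        t_hi = np.inf
        t_lo = -np.inf
        if pos.any():
            t_hi = np.min(slack_hi[pos] / w[pos])
            t_lo = np.max(slack_lo[pos] / w[pos])
        if neg.any():
            t_hi = min(t_hi, np.min(slack_lo[neg] / w[neg]))
            t_lo = max(t_lo, np.max(slack_hi[neg] / w[neg]))
    return t_lo, t_hi


# ---------------------------------------------------------------------------
# sample container
# ---------------------------------------------------------------------------

@dataclass
class SampleSet:
    """Flux vectors drawn from the polytope with per-sample log-densities.

    ``log_density`` is unnormalized and comparable only within one set.
    Construction asserts the polytope invariants on every row.
    """

    fluxes: np.ndarray          # N_s x N
    log_density: np.ndarray     # N_s
    seed: Optional[int]
    source: str                 # "ep" | "hit_and_run"
    reaction_ids: Optional[List[str]] = None

    def __post_init__(self):
        self.fluxes = np.asarray(self.fluxes, dtype=float)
        self.log_density = np.asarray(self.log_density, dtype=float)
        if self.fluxes.ndim != 2:
            raise ValueError("fluxes must be a 2-D array (samples x reactions)")
        if self.log_density.shape != (self.fluxes.shape[0],):
            raise ValueError("log_density length must match the number of samples")
        if not np.all(np.isfinite(self.log_density)):
            raise ValueError("log densities must be finite")

    @property
    def n_samples(self) -> int:
        return self.fluxes.shape[0]

    def check_constraints(self, S, mdot, v_inf, v_sup,
                          stoich_tol=STOICH_TOL, box_tol=BOX_TOL) -> None:
        if S.shape[0]:
            resid = np.abs(S @ self.fluxes.T - np.asarray(mdot)[:, None]).max()
            if resid > stoich_tol:
                raise ValueError(f"samples violate S v = mdot (max residual {resid:.2e})")
        lo_violation = (v_inf[None, :] - self.fluxes).max(initial=0.0)
        hi_violation = (self.fluxes - v_sup[None, :]).max(initial=0.0)
        if max(lo_violation, hi_violation) > box_tol:
            raise ValueError("samples violate the flux bounds")

    def marginal_moments(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.fluxes.mean(axis=0), self.fluxes.var(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# EP model / results
# ---------------------------------------------------------------------------

class FluxSpaceModel:
    """EP characterization problem for a metabolic model's flux polytope.

    Parameters
    ----------
    model : MetabolicModel
        Stoichiometry and box bounds; any ``fixed_exchanges`` recorded on
        the model become soft Gaussian observations ``N(value, sigma^2)``.
    mdot : array-like, optional
        Metabolite input/output rates; defaults to the steady-state zero
        vector.
    beta : float
        Stiffness of the quadratic stoichiometric energy.  The default
        1e10 makes the constraint effectively hard; sampling then enforces
        ``S v = mdot`` exactly through the null-space parameterization.
    """

    def __init__(self, model: MetabolicModel, mdot=None, beta: float = 1e10):
        self.model = model
        self.mdot = np.zeros(model.n_metabolites) if mdot is None else np.asarray(mdot, float)
        if self.mdot.shape != (model.n_metabolites,):
            raise ValueError("mdot length must equal the number of metabolites")
        if beta <= 0:
            raise ValueError("beta must be positive")
        self.beta = float(beta)
        # soft flux observations
        N = model.n_reactions
        self.obs_prec = np.zeros(N)
        self.obs_val = np.zeros(N)
        for rid, (value, sigma) in model.fixed_exchanges.items():
            i = model.reaction_index(rid)
            self.obs_prec[i] = 1.0 / sigma**2
            self.obs_val[i] = value

    def fit(self, damping: float = 0.7, tol: float = 1e-6,
            max_iter: int = 2000) -> "FluxPosterior":
        """Run EP to convergence and return the posterior results object.

        ``damping`` is the weight on the freshly matched site parameters,
        ``tol`` the convergence threshold on site natural-parameter
        changes, ``max_iter`` the sweep budget.  Non-convergence returns a
        result flagged ``converged=False`` with a warning.
        """
        if not 0 < damping <= 1:
            raise ValueError("damping must be in (0, 1]")
        model = self.model
        S, lo, hi = model.S, model.v_inf, model.v_sup
        N = model.n_reactions
        mdot = self.mdot

        K, rank = nullspace_of(S)
        v_p = _particular_solution(S, mdot)
        if S.shape[0] and np.abs(S @ v_p - mdot).max() > 1e-8:
            raise InfeasibleModelError("S v = mdot has no solution")
        x0, _ = _interior_point(K, v_p, lo, hi)  # raises if polytope empty

        width = hi - lo
        scale = max(width.max(), 1.0)
        fixed = width < 1e-12
        lam_fixed = 1e14 / scale**2

        # site natural parameters (precision lam, shift r)
        lam = np.where(fixed, lam_fixed, 1.0 / np.maximum(width, 1e-12) ** 2 * 0.1)
        r = lam * np.where(fixed, lo, 0.5 * (lo + hi))

        BS = self.beta * (S.T @ S) if S.shape[0] else np.zeros((N, N))
        BSm = self.beta * (S.T @ mdot) if S.shape[0] else np.zeros(N)
        C = self.obs_prec
        Cc = self.obs_prec * self.obs_val

        def refresh():
            P = BS + np.diag(C + lam)
            try:
                Sigma = np.linalg.inv(P)
            except np.linalg.LinAlgError:
                Sigma = np.linalg.inv(P + np.eye(N) * (1e-10 * np.trace(P) / N))
            return 0.5 * (Sigma + Sigma.T)

        Sigma = refresh()
        h = BSm + Cc + r
        mu = Sigma @ h

        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            max_delta = 0.0
            for i in range(N):
                if fixed[i]:
                    continue
                sig_ii = Sigma[i, i]
                if sig_ii <= 0:
                    continue
                lam_cav = 1.0 / sig_ii - lam[i]
                if lam_cav < 1e-12 / scale**2:
                    # flat cavity: tilted distribution is uniform on the box
                    mt = 0.5 * (lo[i] + hi[i])
                    vt = width[i] ** 2 / 12.0
                    lam_cav = 0.0
                    mc = 0.0
                else:
                    mc = (mu[i] / sig_ii - r[i]) / lam_cav
                    mt, vt = truncnorm_moments(mc, 1.0 / np.sqrt(lam_cav), lo[i], hi[i])
                    mt, vt = float(mt), float(vt)
                vt = max(vt, 1e-14 * scale**2)
                lam_new = 1.0 / vt - lam_cav
                r_new = mt / vt - mc * lam_cav
                if lam_new < 1e-12:
                    lam_new = 1e-12
                    r_new = mt * lam_new
                d_lam = damping * (lam_new - lam[i])
                d_r = damping * (r_new - r[i])
                max_delta = max(max_delta,
                                abs(d_lam) * scale**2, abs(d_r) * scale)
                # rank-one (Sherman-Morrison) update of Sigma, then the mean
                denom = 1.0 + d_lam * sig_ii
                if denom <= 1e-12:
                    continue
                col = Sigma[:, i].copy()
                Sigma -= np.outer(col, col) * (d_lam / denom)
                lam[i] += d_lam
                r[i] += d_r
                h[i] += d_r
                mu = Sigma @ h
            if it % 20 == 0:
                Sigma = refresh()
                mu = Sigma @ h
            if max_delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"EP did not reach tol={tol} within {max_iter} sweeps "
                f"(last change {max_delta:.2e})", RuntimeWarning)

        Sigma = refresh()
        mu = Sigma @ h
        return FluxPosterior(
            mu=mu, Sigma=Sigma, bounds=(lo.copy(), hi.copy()), mdot=mdot.copy(),
            beta=self.beta, converged=converged, iterations=it,
            particular_solution=v_p, kernel=K,
            site_precision=lam, site_shift=r,
            obs_prec=C.copy(), obs_val=self.obs_val.copy(),
            S=S.copy(), reaction_ids=list(model.reaction_ids),
            _interior_x=x0,
        )


@dataclass
class FluxPosterior:
    """EP-fitted Gaussian over fluxes plus the exact polytope geometry.

    ``mu``/``Sigma`` are the moments of the EP Gaussian; ``kernel`` and
    ``particular_solution`` carry the exact affine subspace so that
    sampling and density evaluation live in null-space coordinates
    ``x = K^T (v - v_p)``.
    """

    mu: np.ndarray
    Sigma: np.ndarray
    bounds: Tuple[np.ndarray, np.ndarray]
    mdot: np.ndarray
    beta: float
    converged: bool
    iterations: int
    particular_solution: np.ndarray
    kernel: np.ndarray
    site_precision: np.ndarray
    site_shift: np.ndarray
    obs_prec: np.ndarray
    obs_val: np.ndarray
    S: np.ndarray
    reaction_ids: List[str]
    _interior_x: Optional[np.ndarray] = None

    # -- restricted (null-space) Gaussian ---------------------------------
    def _restricted(self):
        """Precision and mean of the EP Gaussian on the affine subspace."""
        K, v_p = self.kernel, self.particular_solution
        w = self.site_precision + self.obs_prec
        shift = self.site_shift + self.obs_prec * self.obs_val
        Lam = K.T @ (K * w[:, None])
        rhs = K.T @ (shift - w * v_p)
        d = K.shape[1]
        if d == 0:
            return Lam, np.zeros(0)
        xbar = np.linalg.solve(Lam + np.eye(d) * 1e-300, rhs)
        return Lam, xbar

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def kernel_dim(self) -> int:
        return self.kernel.shape[1]

    def log_density(self, v: np.ndarray) -> float:
        """Unnormalized log of the EP density in null-space coordinates.

        Returns ``-inf`` when ``v`` violates the box; raises when ``v``
        is off the stoichiometric subspace by more than the sample
        tolerance.  Values are comparable only within one posterior.
        """
        v = np.asarray(v, dtype=float)
        lo, hi = self.bounds
        if np.any(v < lo - BOX_TOL) or np.any(v > hi + BOX_TOL):
            return -np.inf
        if self.S.shape[0]:
            resid = np.abs(self.S @ v - self.mdot).max()
            if resid > STOICH_TOL:
                raise ValueError(
                    f"v is off the stoichiometric subspace (|Sv - mdot| = {resid:.2e})")
        x = self.kernel.T @ (v - self.particular_solution)
        Lam, xbar = self._restricted()
        dx = x - xbar
        return float(-0.5 * dx @ Lam @ dx)

    def _log_density_rows(self, X: np.ndarray) -> np.ndarray:
        Lam, xbar = self._restricted()
        dX = X - xbar[None, :]
        return -0.5 * np.einsum("ij,jk,ik->i", dX, Lam, dX)

    # -- sampling ----------------------------------------------------------
    def sample(self, n_samples: int, seed: int = 0, sweeps: int = 40) -> SampleSet:
        """Draw fluxes from the truncated EP Gaussian on the polytope.

        One Gibbs chain per requested sample is run in parallel from a
        common interior point for ``sweeps`` full coordinate sweeps; each
        chain's final state is emitted.  Deterministic given ``seed``.
        """
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        K, v_p = self.kernel, self.particular_solution
        lo, hi = self.bounds
        N, d = K.shape
        if d == 0:
            fluxes = np.tile(v_p, (n_samples, 1))
            return SampleSet(fluxes, np.zeros(n_samples), seed, "ep", self.reaction_ids)
        Lam, xbar = self._restricted()
        if self._interior_x is None:
            self._interior_x, _ = _interior_point(K, v_p, lo, hi)
        X = np.tile(self._interior_x, (n_samples, 1))
        V = X @ K.T  # v - v_p per chain
        cond_sd = 1.0 / np.sqrt(np.diag(Lam))
        l_rel = lo - v_p
        u_rel = hi - v_p

        for _ in range(sweeps):
            for j in range(d):
                w = K[:, j]
                active = np.abs(w) > 1e-14
                wa = w[active]
                R = V[:, active] - np.outer(X[:, j], wa)
                with np.errstate(divide="ignore", invalid="ignore"):
                    t_hi_cand = np.where(wa > 0, (u_rel[active] - R) / wa, np.inf)
                    t_hi_cand = np.where(wa < 0, (l_rel[active] - R) / wa, t_hi_cand)
                    t_lo_cand = np.where(wa > 0, (l_rel[active] - R) / wa, -np.inf)
                    t_lo_cand = np.where(wa < 0, (u_rel[active] - R) / wa, t_lo_cand)
                t_hi = t_hi_cand.min(axis=1)
                t_lo = t_lo_cand.max(axis=1)
                bad = t_lo > t_hi
                if bad.any():  # float noise on degenerate chords
                    mid = 0.5 * (t_lo[bad] + t_hi[bad])
                    t_lo[bad] = mid
                    t_hi[bad] = mid
                m_cond = xbar[j] - ((X - xbar[None, :]) @ Lam[:, j]
                                    - (X[:, j] - xbar[j]) * Lam[j, j]) / Lam[j, j]
                x_new = truncnorm_rvs(rng, m_cond, cond_sd[j], t_lo, t_hi)
                V[:, active] += np.outer(x_new - X[:, j], wa)
                X[:, j] = x_new

        fluxes = v_p[None, :] + X @ K.T
        np.clip(fluxes, lo[None, :] - 0.0, hi[None, :] + 0.0, out=fluxes)
        ss = SampleSet(fluxes, self._log_density_rows(X), seed, "ep", self.reaction_ids)
        ss.check_constraints(self.S, self.mdot, lo, hi)
        return ss

    # -- reporting ---------------------------------------------------------
    def marginal_moments(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.mu.copy(), np.diag(self.Sigma).copy()

    def summary(self) -> pd.DataFrame:
        """Per-reaction posterior means, standard deviations and bounds."""
        lo, hi = self.bounds
        return pd.DataFrame({
            "reaction": self.reaction_ids,
            "mean": self.mu,
            "sd": np.sqrt(np.clip(np.diag(self.Sigma), 0, None)),
            "lb": lo,
            "ub": hi,
        }).set_index("reaction")

    def plot_marginals(self, ax=None):
        """Error-bar plot of posterior flux means with +/- 1 sd whiskers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, 0.25 * self.n_reactions), 4))
        sd = np.sqrt(np.clip(np.diag(self.Sigma), 0, None))
        pos = np.arange(self.n_reactions)
        ax.errorbar(pos, self.mu, yerr=sd, fmt="o", ms=3, capsize=2)
        ax.set_xticks(pos)
        ax.set_xticklabels(self.reaction_ids, rotation=90, fontsize=7)
        ax.set_ylabel("flux")
        return ax

    def __repr__(self) -> str:
        return (f"<FluxPosterior: {self.n_reactions} reactions, "
                f"kernel dim {self.kernel_dim}, beta={self.beta:g}, "
                f"converged={self.converged} in {self.iterations} sweeps>")

    def save(self, directory: str) -> None:
        """Serialize mu/Sigma/meta to a directory of TSV + JSON files."""
        import json
        import os

        os.makedirs(directory, exist_ok=True)
        pd.DataFrame({"reaction": self.reaction_ids, "mean": self.mu}).to_csv(
            os.path.join(directory, "mu.tsv"), sep="\t", index=False)
        pd.DataFrame(self.Sigma, index=self.reaction_ids,
                     columns=self.reaction_ids).to_csv(
            os.path.join(directory, "sigma.tsv"), sep="\t")
        with open(os.path.join(directory, "meta.json"), "w") as fh:
            json.dump({"beta": self.beta, "converged": self.converged,
                       "iterations": self.iterations,
                       "kernel_dim": self.kernel_dim}, fh, indent=1)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def ep_fit(model: MetabolicModel, mdot=None, beta: float = 1e10,
           damping: float = 0.7, tol: float = 1e-6,
           max_iter: int = 2000) -> FluxPosterior:
    """Fit the EP posterior for a model's flux polytope (convenience)."""
    return FluxSpaceModel(model, mdot=mdot, beta=beta).fit(
        damping=damping, tol=tol, max_iter=max_iter)


def condition_on_observed_flux(model: MetabolicModel, spec: ConstraintSpec,
                               mdot=None, **fit_kwargs) -> FluxPosterior:
    """EP posterior conditioned on observed exchange fluxes.

    Each observed flux contributes a Gaussian factor ``N(v_obs, sigma^2)``
    to the target density before EP; observations must carry a nonempty
    ``fixed_exchanges`` map and lie inside the reaction bounds.
    """
    if not spec.fixed_exchanges:
        raise ValueError("spec.fixed_exchanges is empty")
    constrained = apply_constraints(model, spec)
    return ep_fit(constrained, mdot=mdot, **fit_kwargs)


def hit_and_run(model: MetabolicModel, mdot=None, n_samples: int = 10000,
                burn_in: int = 10000, jump: float = 0.5, seed: int = 0,
                max_retries: int = 50) -> SampleSet:
    """Uniform samples over the flux polytope by Hit-and-Run.

    The chain lives in null-space coordinates: a random direction is drawn
    in kernel coordinates, intersected with the box to get the feasible
    chord, and the step is drawn uniformly from the chord scaled by
    ``jump`` (the fraction of the chord used per step).  For ``jump < 1``
    a reversibility check rejects moves whose reverse step would fall
    outside the reverse proposal window, preserving exact uniform
    invariance.  Deterministic given ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 0 < jump <= 1:
        raise ValueError("jump must be in (0, 1]")
    mdot = np.zeros(model.n_metabolites) if mdot is None else np.asarray(mdot, float)
    S, lo, hi = model.S, model.v_inf, model.v_sup
    K, _ = nullspace_of(S)
    v_p = _particular_solution(S, mdot)
    x0, _ = _interior_point(K, v_p, lo, hi)
    N, d = K.shape
    rng = np.random.default_rng(seed)
    if d == 0:
        fluxes = np.tile(v_p, (n_samples, 1))
        return SampleSet(fluxes, np.zeros(n_samples), seed, "hit_and_run",
                         list(model.reaction_ids))

    x = x0.copy()
    v = v_p + K @ x
    out = np.empty((n_samples, N))
    kept = 0
    step = 0
    total = burn_in + n_samples
    while step < total:
        accepted = False
        for _ in range(max_retries):
            g = rng.standard_normal(d)
            g /= np.linalg.norm(g)
            w = K @ g
            t_lo, t_hi = _chord_bounds(w, lo - v, hi - v)
            if not np.isfinite(t_lo) or not np.isfinite(t_hi):
                continue
            if t_hi - t_lo < 1e-12:
                continue
            t = rng.uniform(jump * t_lo, jump * t_hi)
            # reverse window from the proposed point
            if not (jump * (t_lo - t) <= -t <= jump * (t_hi - t)):
                accepted = True  # proposal rejected: chain stays, step counts
                break
            x = x + t * g
            v = v + t * w
            accepted = True
            break
        if not accepted:
            raise RuntimeError(
                "degenerate chord: the polytope has no width along "
                f"{max_retries} random directions")
        if step % 1000 == 999:  # refresh against float drift
            v = v_p + K @ x
        if step >= burn_in:
            out[kept] = v
            kept += 1
        step += 1
    np.clip(out, lo[None, :], hi[None, :], out=out)
    ss = SampleSet(out, np.zeros(n_samples), seed, "hit_and_run",
                   list(model.reaction_ids))
    ss.check_constraints(S, mdot, lo, hi)
    return ss


@dataclass
class MomentComparison:
    """Correlation of marginal means and variances between two sources."""

    r_mean: float
    r_var: float
    max_abs_mean_gap: float
    n_reactions: int

    def __post_init__(self):
        for r in (self.r_mean, self.r_var):
            if np.isfinite(r) and not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
                raise ValueError("correlations must lie in [-1, 1]")


def _moments_of(obj) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, (SampleSet, FluxPosterior)):
        return obj.marginal_moments()
    raise TypeError(f"cannot extract marginal moments from {type(obj)!r}")


def moment_comparison(A, B) -> MomentComparison:
    """Pearson correlations of marginal means and variances across reactions.

    ``A`` may be a :class:`FluxPosterior` (EP moments) or a
    :class:`SampleSet`; ``B`` is a :class:`SampleSet` over the same
    reaction ordering.
    """
    mean_a, var_a = _moments_of(A)
    mean_b, var_b = _moments_of(B)
    if mean_a.shape != mean_b.shape:
        raise ValueError("sources cover different numbers of reactions")
    n = mean_a.size
    if n < 3:
        raise ValueError("moment comparison needs at least 3 reactions")

    def _corr(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])

    return MomentComparison(
        r_mean=_corr(mean_a, mean_b),
        r_var=_corr(var_a, var_b),
        max_abs_mean_gap=float(np.abs(mean_a - mean_b).max()),
        n_reactions=n,
    )
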