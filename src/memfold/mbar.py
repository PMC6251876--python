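"""Multistate Bennett acceptance ratio (MBAR) free-energy estimator.

Combines samples drawn from K states (umbrella windows × temperatures) into
dimensionless free energies f_k and per-frame weights for arbitrary target
states, given the reduced energy u_kn of every pooled frame n evaluated in
every sampling state k.  The estimating equations

    f_k = -log sum_n exp(-u_kn) / sum_l N_l exp(f_l - u_ln)

are solved by minimizing the equivalent convex objective with an analytic
gradient, then polished by self-consistent iteration.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


class MBARConvergenceError(RuntimeError):
    pass


class MBAR:
    """Solve the MBAR equations for a pooled sample.

    Parameters
    ----------
    u_kn : (K, N) array
        Reduced energy (V/kT, dimensionless) of frame n evaluated in state k.
    n_samples : (K,) array
        Number of frames drawn from each state; sum must equal N.
    tol : float
        Relative self-consistency tolerance on the free energies.
    """

    def __init__(self, u_kn: np.ndarray, n_samples: np.ndarray, tol: float = 1e-9):
        u_kn = np.asarray(u_kn, dtype=float)
        n_samples = np.asarray(n_samples, dtype=float)
        if u_kn.ndim != 2 or len(n_samples) != u_kn.shape[0]:
            raise ValueError("u_kn must be (K, N) with one count per state")
        if int(n_samples.sum()) != u_kn.shape[1]:
            raise ValueError("sample counts do not sum to the number of frames")
        if not np.all(np.isfinite(u_kn)):
            raise ValueError("non-finite reduced energies")
        self.u_kn = u_kn
        self.n_samples = n_samples
        self.log_n = np.log(np.maximum(n_samples, 1e-300))
        self._solve(tol)

    # -- solver ------------------------------------------------------------

    def _objective(self, f: np.ndarray):
        # Phi(f) = sum_n logsumexp_k(log N_k + f_k - u_kn) - sum_k N_k f_k
        log_mix = logsumexp(self.log_n[:, None] + f[:, None] - self.u_kn, axis=0)
        val = log_mix.sum() - float(self.n_samples @ f)
        w = np.exp(self.log_n[:, None] + f[:, None] - self.u_kn - log_mix[None, :])
        grad = w.sum(axis=1) - self.n_samples
        return val, grad

    def _solve(self, tol: float) -> None:
        k = self.u_kn.shape[0]
        f = np.zeros(k)
        if k > 1:
            res = minimize(
                self._objective, f, jac=True, method="L-BFGS-B",
                options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
            )
            f = res.x
        # self-consistent polish
        for _ in range(200):
            c = logsumexp(self.log_n[:, None] + f[:, None] - self.u_kn, axis=0)
            f_new = -logsumexp(-self.u_kn - c[None, :], axis=1)
            f_new -= f_new[0]
            delta = np.max(np.abs(f_new - f + f[0]))
            f = f_new
            if delta < tol * max(1.0, np.max(np.abs(f))):
                break
        else:
            raise MBARConvergenceError(
                "MBAR self-consistent iteration did not converge; the sampled "
                "states likely do not overlap (check window spacing)"
            )
        self.f_k = f
        self.log_denominator = logsumexp(
            self.log_n[:, None] + f[:, None] - self.u_kn, axis=0
        )

    # -- queries -----------------------------------------------------------

    def log_weights(self, u_target: np.ndarray) -> np.ndarray:
        """Unnormalized log weights of every frame in a target state."""
        u_target = np.asarray(u_target, dtype=float)
        return -u_target - self.log_denominator

    def weights(self, u_target: np.ndarray) -> np.ndarray:
        """Normalized frame weights of a target state (sum to 1)."""
        lw = self.log_weights(u_target)
        lw -= logsumexp(lw)
        return np.exp(lw)

    def free_energy(self, u_target: np.ndarray) -> float:
        """Dimensionless free energy of a target state relative to state 0."""
        return float(-logsumexp(self.log_weights(u_target)))

    def free_energy_difference(self, u_a: np.ndarray, u_b: np.ndarray) -> float:
        """f(b) - f(a), in kT."""
        return self.free_energy(u_b) - self.free_energy(u_a)
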