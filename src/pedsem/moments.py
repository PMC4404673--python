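"""Model-implied moments.

The SEM implies, per variance component c, a t x t trait covariance

    V_c(theta) = Lambda (I-B)^-1 Psi_c (I-B)^-T Lambda' + Theta_c,

and a mean structure mu = nu + Lambda (I-B)^-1 (alpha + Gamma_eta x)
+ Gamma_y x, linear in the covariates x.  The covariance of the stacked
trait vector of a pedigree with relationship matrices R_c is the Kronecker
sum  sum_c R_c (x) V_c  with individual-major blocks of size t.

The moment vector sigma(theta) stacks, in this fixed order:

1. per observed variable (model order): implied intercept, then implied
   coefficient on each covariate (model order);
2. per observed variable, per component (p, e, c, a order): implied variance;
3. per variable pair (i < j in model order), per component: implied
   covariance.

Stage 1 produces the empirical counterpart s in the same order, which is
what stage 2 matches against.
"""

from __future__ import annotations

import numpy as np

from .errors import NumericalError
from .model import ModelMatrices

__all__ = [
    "implied_component_covariance",
    "implied_mean",
    "implied_mean_coefficients",
    "assemble_pedigree_covariance",
    "moment_map",
    "moment_jacobian",
    "moment_labels",
]


def _effective_loadings(mats, n_latent):
    """Lambda (I-B)^-1, guarding against singular (I-B)."""
    B = mats["B"]
    I = np.eye(n_latent)
    try:
        IBinv = np.linalg.solve(I - B, I)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"(I - B) singular: {exc}") from exc
    if not np.all(np.isfinite(IBinv)):
        raise NumericalError("(I - B) inverse is non-finite")
    return mats["Lambda"] @ IBinv, IBinv


def implied_component_covariance(mm: ModelMatrices, theta: np.ndarray,
                                 component: str) -> np.ndarray:
    """V_c(theta) = Lambda (I-B)^-1 Psi_c (I-B)^-T Lambda' + Theta_c."""
    mats = mm.matrices(theta)
    return _component_cov_from_mats(mm, mats, component)


def _component_cov_from_mats(mm, mats, component):
    L_eff, _ = _effective_loadings(mats, mm.n_latent)
    Psi = mats[("Psi", component)]
    Theta = mats[("Theta", component)]
    V = L_eff @ Psi @ L_eff.T + Theta
    return 0.5 * (V + V.T)


def implied_mean_coefficients(mm: ModelMatrices, theta: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Implied intercepts (length t) and covariate slopes (t x n_cov).

    These are the mean-structure moments: evaluating the implied mean at
    x = 0 and at unit covariate vectors.
    """
    mats = mm.matrices(theta)
    L_eff, IBinv = _effective_loadings(mats, mm.n_latent)
    intercept = mats["nu"] + L_eff @ mats["alpha"]
    slopes = L_eff @ mats["Gamma_eta"] + mats["Gamma_y"]
    return intercept, slopes


def implied_mean(mm: ModelMatrices, theta: np.ndarray,
                 x: np.ndarray) -> np.ndarray:
    """Implied trait mean for one individual with covariate values ``x``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != (mm.n_covariates,):
        raise ValueError(f"expected {mm.n_covariates} covariate values")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing covariate values are not allowed in the mean model")
    intercept, slopes = implied_mean_coefficients(mm, theta)
    return intercept + slopes @ x


def assemble_pedigree_covariance(V: dict, R: dict) -> np.ndarray:
    """sum_c R_c (x) V_c with individual-major ordering (blocks of size t)."""
    if set(V) != set(R):
        raise ValueError(f"component keys differ: {sorted(V)} vs {sorted(R)}")
    total = None
    for c in V:
        Vc, Rc = np.asarray(V[c]), np.asarray(R[c])
        if Vc.ndim != 2 or Vc.shape[0] != Vc.shape[1]:
            raise ValueError(f"V[{c}] is not square")
        if Rc.ndim != 2 or Rc.shape[0] != Rc.shape[1]:
            raise ValueError(f"R[{c}] is not square")
        term = np.kron(Rc, Vc)
        total = term if total is None else total + term
    if total is None:
        raise ValueError("no components given")
    return total


def moment_labels(mm: ModelMatrices) -> list[str]:
    """Human-readable labels in moment-vector order."""
    labels = []
    for v in mm.observed_vars:
        labels.append(f"mean({v})")
        for x in mm.covariate_vars:
            labels.append(f"coef({x},{v})")
    for v in mm.observed_vars:
        for c in mm.components:
            labels.append(f"var({v},{c})")
    t = mm.n_observed
    for i in range(t):
        for j in range(i + 1, t):
            for c in mm.components:
                labels.append(
                    f"cov({mm.observed_vars[i]},{mm.observed_vars[j]},{c})")
    return labels


class _CompiledMomentMap:
    """Precompiled sigma(theta) evaluator (scatter indices, one solve)."""

    def __init__(self, mm: ModelMatrices):
        t, q, nc = mm.n_observed, mm.n_latent, mm.n_covariates
        C = len(mm.components)
        self.t, self.q, self.nc, self.C = t, q, nc, C
        shapes = {"Lambda": (t, q), "B": (q, q), "Gamma_eta": (q, nc),
                  "Gamma_y": (t, nc), "nu": (t,), "alpha": (q,)}
        for c in mm.components:
            shapes[("Psi", c)] = (q, q)
            shapes[("Theta", c)] = (t, t)
        self.base = {k: np.zeros(s) for k, s in shapes.items()}
        for p in mm.fixed:
            for (key, i, j) in p.slots:
                if j is None:
                    self.base[key][i] = p.value
                else:
                    self.base[key][i, j] = p.value
        # scatter lists per matrix: (param indices, flat positions)
        self.scatter = {}
        for pi, p in enumerate(mm.free):
            for (key, i, j) in p.slots:
                flat = i if j is None else i * shapes[key][1] + j
                self.scatter.setdefault(key, ([], []))
                self.scatter[key][0].append(pi)
                self.scatter[key][1].append(flat)
        self.scatter = {k: (np.array(a), np.array(b))
                        for k, (a, b) in self.scatter.items()}
        self.components = list(mm.components)
        self.n_free = len(mm.free)
        iu, ju = np.triu_indices(t, k=1)
        self.iu, self.ju = iu, ju
        self.n_out = t * (1 + nc) + t * C + iu.size * C
        # precomputed row-index arrays for the analytic jacobian
        k = 1 + nc
        var0, cov0 = t * k, t * k + t * C
        self._mean_rows = np.arange(t) * k
        self._var_rows = [var0 + np.arange(t) * C + ci for ci in range(C)]
        self._cov_rows = [cov0 + np.arange(iu.size) * C + ci
                          for ci in range(C)]

    def _mat(self, key, theta):
        M = self.base[key]
        if key in self.scatter:
            M = M.copy()
            pi, flat = self.scatter[key]
            M.ravel()[flat] = theta[pi]
        return M

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        t, q, nc, C = self.t, self.q, self.nc, self.C
        Lam = self._mat("Lambda", theta)
        B = self._mat("B", theta)
        try:
            E = np.linalg.solve((np.eye(q) - B).T, Lam.T).T if q else Lam
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"(I - B) singular: {exc}") from exc
        nu = self._mat("nu", theta)
        alpha = self._mat("alpha", theta)
        intercept = nu + E @ alpha
        slopes = E @ self._mat("Gamma_eta", theta) + self._mat("Gamma_y", theta)
        out = np.empty(self.n_out)
        out[:t * (1 + nc)] = np.concatenate(
            [intercept[:, None], slopes], axis=1).ravel()
        pos = t * (1 + nc)
        var_block = np.empty((t, C))
        cov_block = np.empty((self.iu.size, C))
        for ci, c in enumerate(self.components):
            V = E @ self._mat(("Psi", c), theta) @ E.T \
                + self._mat(("Theta", c), theta)
            var_block[:, ci] = np.diag(V)
            cov_block[:, ci] = 0.5 * (V[self.iu, self.ju] + V[self.ju, self.iu])
        out[pos:pos + t * C] = var_block.ravel()
        out[pos + t * C:] = cov_block.ravel()
        if not np.all(np.isfinite(out)):
            raise NumericalError("non-finite implied moments")
        return out


    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        """Analytic d sigma / d theta, (n_out, n_free).

        Coefficient slots in Lambda and B both perturb the effective
        loading matrix E = Lambda (I-B)^-1 by a rank-one update
        dE = u w', which is what all the chain-rule terms below use.
        """
        theta = np.asarray(theta, dtype=float)
        t, q, nc, C = self.t, self.q, self.nc, self.C
        Lam = self._mat("Lambda", theta)
        B = self._mat("B", theta)
        G = np.linalg.inv(np.eye(q) - B) if q else np.zeros((0, 0))
        E = Lam @ G
        alpha = self._mat("alpha", theta)
        Geta = self._mat("Gamma_eta", theta)
        Psi = {c: self._mat(("Psi", c), theta) for c in self.components}
        J = np.zeros((self.n_out, self.n_free))
        k = 1 + nc
        var0 = t * k
        cov0 = var0 + t * C
        iu, ju = self.iu, self.ju
        mean_rows = self._mean_rows
        cidx = {c: ci for ci, c in enumerate(self.components)}

        def add_coef(pi, u, w):
            # dE = outer(u, w); u length t, w length q
            if alpha.size and alpha.any():
                J[mean_rows, pi] += u * (w @ alpha)
            if nc:
                wG = w @ Geta  # (nc,)
                for x in range(nc):
                    J[mean_rows + 1 + x, pi] += u * wG[x]
            for ci, c in enumerate(self.components):
                b = E @ (Psi[c] @ w)  # (t,)
                J[self._var_rows[ci], pi] += 2.0 * u * b
                J[self._cov_rows[ci], pi] += u[iu] * b[ju] + b[iu] * u[ju]

        for key, (pis, flats) in self.scatter.items():
            if key == "nu":
                for pi, f in zip(pis, flats):
                    J[f * k, pi] += 1.0
            elif key == "alpha":
                for pi, f in zip(pis, flats):
                    J[mean_rows, pi] += E[:, f]
            elif key == "Gamma_y":
                for pi, f in zip(pis, flats):
                    v, x = divmod(f, nc)
                    J[v * k + 1 + x, pi] += 1.0
            elif key == "Gamma_eta":
                for pi, f in zip(pis, flats):
                    qi, x = divmod(f, nc)
                    J[mean_rows + 1 + x, pi] += E[:, qi]
            elif key == "Lambda":
                for pi, f in zip(pis, flats):
                    v, qi = divmod(f, q)
                    u = np.zeros(t)
                    u[v] = 1.0
                    add_coef(pi, u, G[qi, :])
            elif key == "B":
                for pi, f in zip(pis, flats):
                    bi, bj = divmod(f, q)
                    add_coef(pi, E[:, bi], G[bj, :])
            elif isinstance(key, tuple) and key[0] == "Theta":
                ci = cidx[key[1]]
                for pi, f in zip(pis, flats):
                    i, j = divmod(f, t)
                    if i > j:
                        continue  # symmetric mirror of a processed slot
                    if i == j:
                        J[var0 + i * C + ci, pi] += 1.0
                    else:
                        pr = np.nonzero((iu == i) & (ju == j))[0][0]
                        J[cov0 + pr * C + ci, pi] += 1.0
            elif isinstance(key, tuple) and key[0] == "Psi":
                ci = cidx[key[1]]
                for pi, f in zip(pis, flats):
                    i, j = divmod(f, q)
                    if i > j:
                        continue
                    Ei, Ej = E[:, i], E[:, j]
                    if i == j:
                        dvar = Ei * Ei
                        dcov = Ei[iu] * Ei[ju]
                    else:
                        dvar = 2.0 * Ei * Ej
                        dcov = Ei[iu] * Ej[ju] + Ej[iu] * Ei[ju]
                    J[self._var_rows[ci], pi] += dvar
                    J[self._cov_rows[ci], pi] += dcov
        return J


def _compiled_map(mm: ModelMatrices) -> _CompiledMomentMap:
    cm = getattr(mm, "_compiled_moment_map", None)
    if cm is None:
        cm = _CompiledMomentMap(mm)
        mm._compiled_moment_map = cm
    return cm


def moment_map(mm: ModelMatrices, theta: np.ndarray) -> np.ndarray:
    """sigma(theta): the implied moment vector (see module docstring)."""
    return _compiled_map(mm)(theta)


def moment_jacobian(mm: ModelMatrices, theta: np.ndarray) -> np.ndarray:
    """Central-difference Jacobian d sigma / d theta.

    Step per coordinate: h_j = 1e-6 * max(1, |theta_j|).
    """
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    cols = []
    for j in range(n):
        h = 1e-6 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        cols.append((moment_map(mm, tp) - moment_map(mm, tm)) / (2 * h))
    J = np.column_stack(cols) if cols else np.empty((moment_map(mm, theta).size, 0))
    if not np.all(np.isfinite(J)):
        raise NumericalError("non-finite entries in the moment Jacobian")
    return J
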