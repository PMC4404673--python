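"""Two-stage estimation for pedigree SEMs.

Stage 1 fits a *saturated* model by maximum likelihood: a univariate
variance-component model per observed variable (mean = intercept +
covariate slopes; covariance = sum_c sigma_c^2 R_c over the model's
components), then a bivariate model per variable pair estimating the
per-component cross-covariances with each variable's own parameters held
at the univariate estimates.  Variances are deliberately *not* constrained
to be positive; only positive-definiteness of the assembled covariance is
enforced, which keeps the estimator's asymptotic distribution regular.

The stacked stage-1 estimates s (intercepts, slopes, variances,
covariances in moment order) get a robust sandwich covariance

    Gamma_hat = A^-1 B A^-T / N,

where A is the Jacobian of the mean stacked per-pedigree score and B the
empirical covariance of the per-pedigree scores.  A is obtained by numeric
differentiation of the analytic scores, so the dependence of the bivariate
estimating equations on the univariate estimates is carried automatically.

Stage 2 minimizes Q(theta) = (s - sigma(theta))' W (s - sigma(theta)) with
W = diag(Gamma_hat)^-1 by default (or the pseudo-inverse of Gamma_hat),
polished by Levenberg-Marquardt from multiple starting values produced by
a small evolutionary search.  Standard errors come from the usual
minimum-distance sandwich.

Ascertainment correction (single ascertainment through a proband) replaces
each pedigree's likelihood by the likelihood conditional on the proband's
values of the variables in the current fit: log f(y_ped) - log f(y_proband).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from . import fit_indices as fi
from .errors import ConfigurationError, EstimationError, NumericalError
from .model import ModelMatrices, ModelSpec, build_model_matrices, parse_model
from .moments import moment_jacobian, moment_labels
from .pedigree import IbdStore, Pedigree, relationship_matrix

__all__ = [
    "SaturatedEstimates",
    "FittedModel",
    "RelationshipCache",
    "pedigree_loglik",
    "conditional_loglik_ascertained",
    "prepare_fit_data",
    "fit_univariate_vc",
    "fit_bivariate_vc",
    "saturated_estimates",
    "generate_starting_values",
    "minimum_distance_fit",
    "fit_model",
]

_LOG2PI = math.log(2.0 * math.pi)
_BIG = 1e12
_A_RE = re.compile(r"^a\((.+)\)$")


def component_marker(label: str) -> str | None:
    m = _A_RE.match(label)
    return m.group(1) if m else None


# ---------------------------------------------------------------------------
# reference likelihoods (small, readable; the engines below are vectorized)


def pedigree_loglik(y: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> float:
    """Multivariate normal log-density over the non-missing entries of y.

    Rows/columns of Sigma for missing (NaN) entries are deleted.  Returns
    -inf when Sigma is not positive definite on the observed entries.
    """
    y = np.asarray(y, dtype=float).ravel()
    mu = np.asarray(mu, dtype=float).ravel()
    obs = np.isfinite(y)
    if not obs.any():
        return 0.0
    r = y[obs] - mu[obs]
    S = np.asarray(Sigma, dtype=float)[np.ix_(obs, obs)]
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return -np.inf
    alpha = np.linalg.solve(L, r)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (obs.sum() * _LOG2PI + logdet + alpha @ alpha))


def conditional_loglik_ascertained(y, mu, Sigma, proband_entries) -> float:
    """log f(y) - log f(y_proband): likelihood conditional on the proband.

    ``proband_entries`` indexes the proband's entries within the stacked
    vector; entries that are missing in y contribute nothing.  With no
    proband entries the unconditional log-likelihood is returned.
    """
    full = pedigree_loglik(y, mu, Sigma)
    idx = np.atleast_1d(np.asarray(proband_entries, dtype=int))
    if idx.size == 0:
        return full
    y = np.asarray(y, dtype=float).ravel()
    keep = idx[np.isfinite(y[idx])]
    if keep.size == 0:
        warnings.warn("proband has no observed values for this fit; "
                      "using the unconditional likelihood", stacklevel=2)
        return full
    sub = pedigree_loglik(y[keep], np.asarray(mu).ravel()[keep],
                          np.asarray(Sigma)[np.ix_(keep, keep)])
    return full - sub


# ---------------------------------------------------------------------------
# data preparation


class RelationshipCache:
    """Per-family cache of structure-determined relationship matrices.

    Reuses kinship/household matrices and their eigendecompositions across
    replicate analyses of the same pedigree structures.  Marker IBD
    (linkage) matrices are data, not structure, and are never cached.
    """

    def __init__(self):
        self._rel: dict = {}
        self._eig: dict = {}

    @staticmethod
    def _key(ped: Pedigree, comp: str):
        sk = getattr(ped, "structure_key", None)
        return (("sk", sk) if sk is not None else ped.family_id, comp)

    def rel(self, ped: Pedigree, comp: str, ibd=None):
        marker = component_marker(comp)
        if marker is not None:
            if ibd is None:
                raise ConfigurationError(
                    f"linkage component {comp} requires IBD data")
            return ibd.matrix(ped, marker)
        key = self._key(ped, comp)
        if key not in self._rel:
            base = {"p": "polygenic", "e": "environment", "c": "household"}[comp]
            self._rel[key] = relationship_matrix(ped, base)
        return self._rel[key]

    def eigh(self, ped: Pedigree, comp: str, R: np.ndarray):
        if component_marker(comp) is not None:
            return np.linalg.eigh(R)
        key = self._key(ped, comp)
        if key not in self._eig:
            self._eig[key] = np.linalg.eigh(R)
        return self._eig[key]


@dataclass
class FitData:
    """Prepared inputs for stage-1 fitting."""

    peds: list
    traits: list
    covariates: list
    components: list
    Y: list            # per pedigree (n, t)
    X: list            # per pedigree (n, 1 + n_cov)
    R: list            # per pedigree dict comp -> (n, n)
    proband: list      # per pedigree member index or None
    complete: bool
    eigen: "EigenCache | None" = None

    @property
    def n_pedigrees(self) -> int:
        return len(self.peds)


@dataclass
class EigenCache:
    """Shared eigendecomposition of the single non-identity component.

    Applicable when the model has exactly two components, one of which is
    the identity ('e').  Rotating each pedigree by the eigenvectors of the
    other component's matrix diagonalizes every covariance the stage-1
    fits need, reducing all likelihood work to elementwise operations on
    flat arrays.
    """

    idx_R: int
    idx_I: int
    d: np.ndarray          # (ntot,) eigenvalues, pedigree-concatenated
    starts: np.ndarray     # (N+1,) offsets into the flat arrays
    Ytil: np.ndarray       # (ntot, t) rotated traits
    Xtil: np.ndarray       # (ntot, k) rotated design
    has_prob: np.ndarray   # (N,) bool
    yp: np.ndarray         # (N, t) proband raw trait values (nan if none)
    xp: np.ndarray         # (N, k)
    Rpp: np.ndarray        # (N,) non-identity diag at the proband


def prepare_fit_data(peds: list, mm: ModelMatrices, ibd: IbdStore | None = None,
                     cache: RelationshipCache | None = None) -> FitData:
    """Extract trait/covariate matrices and relationship matrices per pedigree."""
    cache = cache or RelationshipCache()
    traits = mm.observed_vars
    covs = mm.covariate_vars
    comps = mm.components
    Y, X, R, proband = [], [], [], []
    for ped in peds:
        Y.append(ped.data_matrix(traits))
        cols = [np.ones(ped.size)] + [ped.column(c) for c in covs]
        X.append(np.column_stack(cols))
        R.append({c: cache.rel(ped, c, ibd) for c in comps})
        proband.append(ped.proband_index)
    complete = all(np.all(np.isfinite(y)) and np.all(np.isfinite(x))
                   for y, x in zip(Y, X))
    fd = FitData(peds, traits, covs, comps, Y, X, R, proband, complete)
    if complete and len(comps) == 2 and "e" in comps:
        fd.eigen = _build_eigen_cache(fd, cache)
    return fd


def _build_eigen_cache(fd: FitData, cache: RelationshipCache) -> EigenCache:
    comps = fd.components
    idx_I = comps.index("e")
    idx_R = 1 - idx_I
    comp_R = comps[idx_R]
    N = fd.n_pedigrees
    t = len(fd.traits)
    k = fd.X[0].shape[1]
    sizes = [y.shape[0] for y in fd.Y]
    starts = np.concatenate([[0], np.cumsum(sizes)])
    ntot = starts[-1]
    d = np.empty(ntot)
    Ytil = np.empty((ntot, t))
    Xtil = np.empty((ntot, k))
    has_prob = np.zeros(N, dtype=bool)
    yp = np.full((N, t), np.nan)
    xp = np.zeros((N, k))
    Rpp = np.zeros(N)
    for i, ped in enumerate(fd.peds):
        Rm = fd.R[i][comp_R]
        dv, U = cache.eigh(ped, comp_R, Rm)
        a, b = starts[i], starts[i + 1]
        d[a:b] = dv
        Ytil[a:b] = U.T @ fd.Y[i]
        Xtil[a:b] = U.T @ fd.X[i]
        p = fd.proband[i]
        if p is not None:
            has_prob[i] = True
            yp[i] = fd.Y[i][p]
            xp[i] = fd.X[i][p]
            Rpp[i] = Rm[p, p]
    return EigenCache(idx_R, idx_I, d, starts, Ytil, Xtil,
                      has_prob, yp, xp, Rpp)


# ---------------------------------------------------------------------------
# stage-1 engines: eigendecomposition fast path


class _UniEigen:
    """Univariate variance-component likelihood on the rotated flat arrays."""

    def __init__(self, fd: FitData, trait: int, ascertained: bool):
        eg = fd.eigen
        self.eg = eg
        self.k = eg.Xtil.shape[1]
        self.C = len(fd.components)
        self.trait = trait
        self.y = eg.Ytil[:, trait]
        self.N = fd.n_pedigrees
        self.ntot = eg.d.size
        cond = ascertained & eg.has_prob & np.isfinite(eg.yp[:, trait])
        self.cond_rows = np.nonzero(cond)[0]
        self.ypc = eg.yp[self.cond_rows, trait]
        self.xpc = eg.xp[self.cond_rows]
        self.Rppc = eg.Rpp[self.cond_rows]

    def start(self) -> np.ndarray:
        X, y = self.eg.Xtil, self.y
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = float(resid @ resid) / max(1, resid.size - self.k)
        sigma = np.full(self.C, s2 / self.C)
        return np.concatenate([beta, sigma])

    def _core(self, x):
        eg = self.eg
        beta, sigma = x[:self.k], x[self.k:]
        w = sigma[eg.idx_R] * eg.d + sigma[eg.idx_I]
        if w.min() <= 0:
            return None
        r = self.y - eg.Xtil @ beta
        iw = 1.0 / w
        riw = r * iw
        return beta, sigma, w, r, iw, riw

    def value_grad(self, x):
        out = self._core(x)
        if out is None:
            return _BIG, np.zeros_like(x)
        beta, sigma, w, r, iw, riw = out
        eg = self.eg
        ll = -0.5 * (self.ntot * _LOG2PI + np.log(w).sum() + r @ riw)
        gb = eg.Xtil.T @ riw
        q = riw * riw
        gs = np.empty(self.C)
        diff = q - iw
        gs[eg.idx_R] = 0.5 * (diff @ eg.d)
        gs[eg.idx_I] = 0.5 * diff.sum()
        if self.cond_rows.size:
            sR, sI = sigma[eg.idx_R], sigma[eg.idx_I]
            spp = sR * self.Rppc + sI
            rp = self.ypc - self.xpc @ beta
            isp = 1.0 / spp
            llp = -0.5 * (self.cond_rows.size * _LOG2PI
                          + np.log(spp).sum() + (rp * rp * isp).sum())
            ll -= llp
            gb -= self.xpc.T @ (rp * isp)
            dq = rp * rp * isp * isp - isp
            gs[eg.idx_R] -= 0.5 * (dq @ self.Rppc)
            gs[eg.idx_I] -= 0.5 * dq.sum()
        grad = np.concatenate([gb, gs])
        return -ll, -grad

    def scores(self, x) -> np.ndarray:
        """Per-pedigree log-likelihood scores, (N, k + C)."""
        out = self._core(x)
        if out is None:
            raise NumericalError("non-PD covariance at stage-1 score evaluation")
        beta, sigma, w, r, iw, riw = out
        eg = self.eg
        cuts = eg.starts[:-1]
        S = np.empty((self.N, self.k + self.C))
        S[:, :self.k] = np.add.reduceat(eg.Xtil * riw[:, None], cuts, axis=0)
        diff = 0.5 * (riw * riw - iw)
        S[:, self.k + eg.idx_R] = np.add.reduceat(diff * eg.d, cuts)
        S[:, self.k + eg.idx_I] = np.add.reduceat(diff, cuts)
        if self.cond_rows.size:
            sR, sI = sigma[eg.idx_R], sigma[eg.idx_I]
            spp = sR * self.Rppc + sI
            rp = self.ypc - self.xpc @ beta
            isp = 1.0 / spp
            dq = 0.5 * (rp * rp * isp * isp - isp)
            S[self.cond_rows, :self.k] -= self.xpc * (rp * isp)[:, None]
            S[self.cond_rows, self.k + eg.idx_R] -= dq * self.Rppc
            S[self.cond_rows, self.k + eg.idx_I] -= dq
        return S


class _BivEigen:
    """Bivariate cross-covariance likelihood on the rotated flat arrays."""

    def __init__(self, fd: FitData, ti: int, tj: int, ascertained: bool):
        eg = fd.eigen
        self.eg = eg
        self.k = eg.Xtil.shape[1]
        self.C = len(fd.components)
        self.ti, self.tj = ti, tj
        self.N = fd.n_pedigrees
        cond = (ascertained & eg.has_prob
                & np.isfinite(eg.yp[:, ti]) & np.isfinite(eg.yp[:, tj]))
        self.cond_rows = np.nonzero(cond)[0]

    def _core(self, ui, uj, cross):
        eg = self.eg
        bi, si = ui[:self.k], ui[self.k:]
        bj, sj = uj[:self.k], uj[self.k:]
        wi = si[eg.idx_R] * eg.d + si[eg.idx_I]
        wj = sj[eg.idx_R] * eg.d + sj[eg.idx_I]
        c = cross[eg.idx_R] * eg.d + cross[eg.idx_I]
        det = wi * wj - c * c
        if det.min() <= 0 or wi.min() <= 0 or wj.min() <= 0:
            return None
        ri = eg.Ytil[:, self.ti] - eg.Xtil @ bi
        rj = eg.Ytil[:, self.tj] - eg.Xtil @ bj
        return bi, si, bj, sj, wi, wj, c, det, ri, rj

    def _dll_dc(self, wi, wj, c, det, ri, rj):
        Nq = wj * ri * ri - 2.0 * c * ri * rj + wi * rj * rj
        return c / det + ri * rj / det - c * Nq / (det * det)

    def _cond_terms(self, bi, si, bj, sj, cross):
        eg = self.eg
        rows = self.cond_rows
        sppi = si[eg.idx_R] * eg.Rpp[rows] + si[eg.idx_I]
        sppj = sj[eg.idx_R] * eg.Rpp[rows] + sj[eg.idx_I]
        cpp = cross[eg.idx_R] * eg.Rpp[rows] + cross[eg.idx_I]
        detp = sppi * sppj - cpp * cpp
        rpi = eg.yp[rows, self.ti] - eg.xp[rows] @ bi
        rpj = eg.yp[rows, self.tj] - eg.xp[rows] @ bj
        return sppi, sppj, cpp, detp, rpi, rpj

    def value_grad(self, ui, uj, cross):
        out = self._core(ui, uj, cross)
        if out is None:
            return _BIG, np.zeros(self.C)
        bi, si, bj, sj, wi, wj, c, det, ri, rj = out
        eg = self.eg
        quad = (wj * ri * ri - 2.0 * c * ri * rj + wi * rj * rj) / det
        ll = -0.5 * (2.0 * eg.d.size * _LOG2PI + np.log(det).sum() + quad.sum())
        dll = self._dll_dc(wi, wj, c, det, ri, rj)
        g = np.empty(self.C)
        g[eg.idx_R] = dll @ eg.d
        g[eg.idx_I] = dll.sum()
        if self.cond_rows.size:
            sppi, sppj, cpp, detp, rpi, rpj = self._cond_terms(bi, si, bj, sj, cross)
            if detp.min() <= 0:
                return _BIG, np.zeros(self.C)
            quadp = (sppj * rpi * rpi - 2.0 * cpp * rpi * rpj
                     + sppi * rpj * rpj) / detp
            llp = -0.5 * (2.0 * detp.size * _LOG2PI
                          + np.log(detp).sum() + quadp.sum())
            ll -= llp
            dllp = self._dll_dc(sppi, sppj, cpp, detp, rpi, rpj)
            g[eg.idx_R] -= dllp @ self.eg.Rpp[self.cond_rows]
            g[eg.idx_I] -= dllp.sum()
        return -ll, -g

    def scores(self, ui, uj, cross) -> np.ndarray:
        """Per-pedigree scores w.r.t. the cross-covariances, (N, C)."""
        out = self._core(ui, uj, cross)
        if out is None:
            raise NumericalError("non-PD covariance at stage-1 score evaluation")
        bi, si, bj, sj, wi, wj, c, det, ri, rj = out
        eg = self.eg
        dll = self._dll_dc(wi, wj, c, det, ri, rj)
        cuts = eg.starts[:-1]
        S = np.empty((self.N, self.C))
        S[:, eg.idx_R] = np.add.reduceat(dll * eg.d, cuts)
        S[:, eg.idx_I] = np.add.reduceat(dll, cuts)
        if self.cond_rows.size:
            sppi, sppj, cpp, detp, rpi, rpj = self._cond_terms(bi, si, bj, sj, cross)
            dllp = self._dll_dc(sppi, sppj, cpp, detp, rpi, rpj)
            S[self.cond_rows, eg.idx_R] -= dllp * eg.Rpp[self.cond_rows]
            S[self.cond_rows, eg.idx_I] -= dllp
        return S


# ---------------------------------------------------------------------------
# stage-1 engines: general dense path (any components, missing data)


def _group_by(keys):
    groups = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)
    return groups


class _UniDense:
    """Univariate likelihood with per-pedigree dense covariance matrices."""

    def __init__(self, fd: FitData, trait: int, ascertained: bool):
        self.C = len(fd.components)
        self.k = fd.X[0].shape[1]
        self.N = fd.n_pedigrees
        self.groups = []
        masks, sizes = [], []
        for i in range(fd.n_pedigrees):
            m = np.isfinite(fd.Y[i][:, trait]) & np.all(np.isfinite(fd.X[i]), axis=1)
            masks.append(np.nonzero(m)[0])
            sizes.append(int(m.sum()))
        for n, idxs in _group_by(sizes).items():
            if n == 0:
                continue
            idxs = np.array(idxs)
            Rg = np.stack([
                np.stack([fd.R[i][c][np.ix_(masks[i], masks[i])]
                          for c in fd.components])
                for i in idxs])
            Yg = np.stack([fd.Y[i][masks[i], trait] for i in idxs])
            Xg = np.stack([fd.X[i][masks[i], :] for i in idxs])
            ppos = np.full(len(idxs), -1)
            if ascertained:
                for row, i in enumerate(idxs):
                    p = fd.proband[i]
                    if p is not None and p in masks[i]:
                        ppos[row] = int(np.nonzero(masks[i] == p)[0][0])
            self.groups.append({"peds": idxs, "n": n, "R": Rg, "Y": Yg,
                                "X": Xg, "ppos": ppos})
        self._pooled = None

    def start(self) -> np.ndarray:
        Xs = np.concatenate([g["X"].reshape(-1, self.k) for g in self.groups])
        ys = np.concatenate([g["Y"].ravel() for g in self.groups])
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        resid = ys - Xs @ beta
        s2 = float(resid @ resid) / max(1, resid.size - self.k)
        return np.concatenate([beta, np.full(self.C, s2 / self.C)])

    def _eval(self, x, want_scores):
        beta, sigma = x[:self.k], x[self.k:]
        ll = 0.0
        gb = np.zeros(self.k)
        gs = np.zeros(self.C)
        S = np.zeros((self.N, self.k + self.C)) if want_scores else None
        for g in self.groups:
            n = g["n"]
            Sigma = np.einsum("c,mcij->mij", sigma, g["R"])
            try:
                chol = np.linalg.cholesky(Sigma)
            except np.linalg.LinAlgError:
                return None
            logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)),
                                  axis=1)
            r = g["Y"] - np.einsum("mnk,k->mn", g["X"], beta)
            alpha = np.linalg.solve(Sigma, r[..., None])[..., 0]
            inv = np.linalg.inv(Sigma)
            ll_m = -0.5 * (n * _LOG2PI + logdet + np.einsum("mn,mn->m", r, alpha))
            gb_m = np.einsum("mnk,mn->mk", g["X"], alpha)
            quad = np.einsum("mi,mcij,mj->mc", alpha, g["R"], alpha)
            tr = np.einsum("mij,mcij->mc", inv, g["R"])
            gs_m = 0.5 * (quad - tr)
            prow = np.nonzero(g["ppos"] >= 0)[0]
            if prow.size:
                pp = g["ppos"][prow]
                Rpp = g["R"][prow, :, pp, pp]              # (np, C)
                spp = Rpp @ sigma
                rp = r[prow, pp]
                xp = g["X"][prow, pp, :]
                isp = 1.0 / spp
                llp = -0.5 * (_LOG2PI + np.log(spp) + rp * rp * isp)
                ll_m[prow] -= llp
                gb_m[prow] -= xp * (rp * isp)[:, None]
                dq = 0.5 * (rp * rp * isp * isp - isp)
                gs_m[prow] -= dq[:, None] * Rpp
            ll += ll_m.sum()
            gb += gb_m.sum(axis=0)
            gs += gs_m.sum(axis=0)
            if want_scores:
                S[g["peds"], :self.k] = gb_m
                S[g["peds"], self.k:] = gs_m
        return ll, np.concatenate([gb, gs]), S

    def value_grad(self, x):
        out = self._eval(x, want_scores=False)
        if out is None:
            return _BIG, np.zeros_like(x)
        ll, grad, _ = out
        return -ll, -grad

    def scores(self, x) -> np.ndarray:
        out = self._eval(x, want_scores=True)
        if out is None:
            raise NumericalError("non-PD covariance at stage-1 score evaluation")
        return out[2]


class _BivDense:
    """Bivariate cross-covariance likelihood, dense per-pedigree covariances."""

    def __init__(self, fd: FitData, ti: int, tj: int, ascertained: bool):
        self.C = len(fd.components)
        self.k = fd.X[0].shape[1]
        self.N = fd.n_pedigrees
        self.groups = []
        oi, oj, shapes = [], [], []
        for i in range(fd.n_pedigrees):
            mx = np.all(np.isfinite(fd.X[i]), axis=1)
            a = np.nonzero(np.isfinite(fd.Y[i][:, ti]) & mx)[0]
            b = np.nonzero(np.isfinite(fd.Y[i][:, tj]) & mx)[0]
            oi.append(a)
            oj.append(b)
            shapes.append((a.size, b.size))
        for (ni, nj), idxs in _group_by(shapes).items():
            if ni == 0 or nj == 0:
                continue
            idxs = np.array(idxs)
            comps = range(self.C)
            g = {
                "peds": idxs, "ni": ni, "nj": nj,
                "Rii": np.stack([np.stack([fd.R[i][c][np.ix_(oi[i], oi[i])]
                                           for c in fd.components]) for i in idxs]),
                "Rjj": np.stack([np.stack([fd.R[i][c][np.ix_(oj[i], oj[i])]
                                           for c in fd.components]) for i in idxs]),
                "Rij": np.stack([np.stack([fd.R[i][c][np.ix_(oi[i], oj[i])]
                                           for c in fd.components]) for i in idxs]),
                "Yi": np.stack([fd.Y[i][oi[i], ti] for i in idxs]),
                "Yj": np.stack([fd.Y[i][oj[i], tj] for i in idxs]),
                "Xi": np.stack([fd.X[i][oi[i], :] for i in idxs]),
                "Xj": np.stack([fd.X[i][oj[i], :] for i in idxs]),
            }
            pi = np.full(len(idxs), -1)
            pj = np.full(len(idxs), -1)
            if ascertained:
                for row, i in enumerate(idxs):
                    p = fd.proband[i]
                    if p is not None:
                        if p in oi[i]:
                            pi[row] = int(np.nonzero(oi[i] == p)[0][0])
                        if p in oj[i]:
                            pj[row] = int(np.nonzero(oj[i] == p)[0][0])
            g["pi"], g["pj"] = pi, pj
            self.groups.append(g)

    def _eval(self, ui, uj, cross, want_scores):
        bi, si = ui[:self.k], ui[self.k:]
        bj, sj = uj[:self.k], uj[self.k:]
        ll = 0.0
        gc = np.zeros(self.C)
        S = np.zeros((self.N, self.C)) if want_scores else None
        for g in self.groups:
            ni, nj = g["ni"], g["nj"]
            n = ni + nj
            m = g["peds"].size
            Sigma = np.empty((m, n, n))
            Sigma[:, :ni, :ni] = np.einsum("c,mcij->mij", si, g["Rii"])
            Sigma[:, ni:, ni:] = np.einsum("c,mcij->mij", sj, g["Rjj"])
            Sij = np.einsum("c,mcij->mij", cross, g["Rij"])
            Sigma[:, :ni, ni:] = Sij
            Sigma[:, ni:, :ni] = np.swapaxes(Sij, 1, 2)
            try:
                chol = np.linalg.cholesky(Sigma)
            except np.linalg.LinAlgError:
                return None
            logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)),
                                  axis=1)
            r = np.concatenate([
                g["Yi"] - np.einsum("mnk,k->mn", g["Xi"], bi),
                g["Yj"] - np.einsum("mnk,k->mn", g["Xj"], bj)], axis=1)
            alpha = np.linalg.solve(Sigma, r[..., None])[..., 0]
            inv = np.linalg.inv(Sigma)
            ll_m = -0.5 * (n * _LOG2PI + logdet + np.einsum("mn,mn->m", r, alpha))
            ai, aj = alpha[:, :ni], alpha[:, ni:]
            quad = np.einsum("mi,mcij,mj->mc", ai, g["Rij"], aj)
            tr = np.einsum("mij,mcij->mc", inv[:, :ni, ni:], g["Rij"])
            gc_m = quad - tr
            prow = np.nonzero((g["pi"] >= 0) & (g["pj"] >= 0))[0]
            if prow.size:
                pi, pj = g["pi"][prow], g["pj"][prow]
                Rpp_i = g["Rii"][prow, :, pi, pi]
                Rpp_j = g["Rjj"][prow, :, pj, pj]
                Rpp_x = g["Rij"][prow, :, pi, pj]
                sppi = Rpp_i @ si
                sppj = Rpp_j @ sj
                cpp = Rpp_x @ cross
                detp = sppi * sppj - cpp * cpp
                if detp.min() <= 0:
                    return None
                rpi = r[prow, pi]
                rpj = r[prow, ni + pj]
                quadp = (sppj * rpi * rpi - 2 * cpp * rpi * rpj
                         + sppi * rpj * rpj) / detp
                llp = -0.5 * (2 * _LOG2PI + np.log(detp) + quadp)
                ll_m[prow] -= llp
                Nq = sppj * rpi * rpi - 2 * cpp * rpi * rpj + sppi * rpj * rpj
                dllp = cpp / detp + rpi * rpj / detp - cpp * Nq / (detp * detp)
                gc_m[prow] -= dllp[:, None] * Rpp_x
            ll += ll_m.sum()
            gc += gc_m.sum(axis=0)
            if want_scores:
                S[g["peds"]] = gc_m
        return ll, gc, S

    def value_grad(self, ui, uj, cross):
        out = self._eval(ui, uj, cross, want_scores=False)
        if out is None:
            return _BIG, np.zeros(self.C)
        ll, gc, _ = out
        return -ll, -gc

    def scores(self, ui, uj, cross) -> np.ndarray:
        out = self._eval(ui, uj, cross, want_scores=True)
        if out is None:
            raise NumericalError("non-PD covariance at stage-1 score evaluation")
        return out[2]


# ---------------------------------------------------------------------------
# stage-1 driver


def _optimize_ml(value_grad, x0, what, max_restarts=3, seed=0):
    rng = np.random.default_rng(seed + 911)
    best_x, best_f = None, np.inf
    x = np.asarray(x0, dtype=float)
    for _attempt in range(max_restarts + 1):
        res = optimize.minimize(value_grad, x, jac=True, method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 500})
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
        gnorm = float(np.max(np.abs(res.jac)))
        if best_f < _BIG / 10 and (res.success or gnorm < 1e-4):
            return best_x, True
        x = best_x + 0.1 * rng.standard_normal(x.size) * (1 + np.abs(best_x))
    if best_f >= _BIG / 10:
        raise EstimationError(f"stage-1 fit failed to converge for {what}")
    return best_x, False


class _MomentIndex:
    """Position of each stage-1 parameter inside the moment vector s."""

    def __init__(self, mm: ModelMatrices):
        self.t = mm.n_observed
        self.k = 1 + mm.n_covariates
        self.C = len(mm.components)
        t, k, C = self.t, self.k, self.C
        self.mean = [slice(v * k, (v + 1) * k) for v in range(t)]
        var0 = t * k
        self.var = [slice(var0 + v * C, var0 + (v + 1) * C) for v in range(t)]
        self.pairs = [(i, j) for i in range(t) for j in range(i + 1, t)]
        cov0 = var0 + t * C
        self.cov = {pair: slice(cov0 + p * C, cov0 + (p + 1) * C)
                    for p, pair in enumerate(self.pairs)}
        self.size = cov0 + len(self.pairs) * C

    def uni(self, v, s):
        """(beta, sigma) for trait v extracted from a moment vector."""
        return np.concatenate([s[self.mean[v]], s[self.var[v]]])


@dataclass
class SaturatedEstimates:
    """Stage-1 moment estimates with their robust sandwich covariance."""

    s: np.ndarray
    Gamma: np.ndarray
    scores: np.ndarray       # (N, len(s)) per-pedigree log-lik scores at s
    N: int
    labels: list
    ascertained: bool = False

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.Gamma), 0, None))


def fit_univariate_vc(fd: FitData, trait: int, ascertained: bool = False,
                      seed: int = 0):
    """ML fit of one trait's variance-component model; returns (params, engine)."""
    if fd.eigen is not None:
        eng = _UniEigen(fd, trait, ascertained)
    else:
        eng = _UniDense(fd, trait, ascertained)
    x0 = eng.start()
    x, _conv = _optimize_ml(eng.value_grad, x0, f"trait {fd.traits[trait]}",
                            seed=seed)
    return x, eng


def fit_bivariate_vc(fd: FitData, ti: int, tj: int, ui, uj,
                     uni_engines=None, ascertained: bool = False, seed: int = 0):
    """ML fit of the cross-covariances for one trait pair; returns (cross, engine)."""
    if fd.eigen is not None:
        eng = _BivEigen(fd, ti, tj, ascertained)
    else:
        eng = _BivDense(fd, ti, tj, ascertained)
    C = len(fd.components)
    # start at an equal split of the empirical residual cross-moment,
    # shrunk until the implied covariance is positive definite
    k = fd.X[0].shape[1]
    prods, var_i, var_j = [], [], []
    for Y, X in zip(fd.Y, fd.X):
        m = (np.isfinite(Y[:, ti]) & np.isfinite(Y[:, tj])
             & np.all(np.isfinite(X), axis=1))
        if m.any():
            ri = Y[m, ti] - X[m] @ ui[:k]
            rj = Y[m, tj] - X[m] @ uj[:k]
            prods.append(ri * rj)
    chat = float(np.mean(np.concatenate(prods))) if prods else 0.0
    cross = np.full(C, chat / C)
    for _ in range(12):
        f, _g = eng.value_grad(ui, uj, cross)
        if f < _BIG / 10:
            break
        cross *= 0.5
    x, _conv = _optimize_ml(lambda c: eng.value_grad(ui, uj, c), cross,
                            f"pair ({fd.traits[ti]},{fd.traits[tj]})", seed=seed)
    return x, eng


def saturated_estimates(peds, mm: ModelMatrices, ibd: IbdStore | None = None,
                        ascertained: bool = False,
                        cache: RelationshipCache | None = None,
                        fd: FitData | None = None,
                        seed: int = 0) -> SaturatedEstimates:
    """Stage 1: saturated moment estimates s and their sandwich covariance."""
    if fd is None:
        fd = prepare_fit_data(peds, mm, ibd, cache)
    if fd.n_pedigrees < 2:
        raise EstimationError("at least 2 pedigrees are required")
    idx = _MomentIndex(mm)
    t = idx.t
    N = fd.n_pedigrees

    uni_x, uni_eng = [], []
    for v in range(t):
        x, eng = fit_univariate_vc(fd, v, ascertained, seed=seed)
        uni_x.append(x)
        uni_eng.append(eng)
    biv_x, biv_eng = {}, {}
    for (i, j) in idx.pairs:
        x, eng = fit_bivariate_vc(fd, i, j, uni_x[i], uni_x[j],
                                  ascertained=ascertained, seed=seed)
        biv_x[(i, j)] = x
        biv_eng[(i, j)] = eng

    s = np.empty(idx.size)
    for v in range(t):
        s[idx.mean[v]] = uni_x[v][:idx.k]
        s[idx.var[v]] = uni_x[v][idx.k:]
    for pair in idx.pairs:
        s[idx.cov[pair]] = biv_x[pair]

    def stacked_scores(svec):
        S = np.zeros((N, idx.size))
        for v in range(t):
            sc = uni_eng[v].scores(idx.uni(v, svec))
            S[:, idx.mean[v]] = sc[:, :idx.k]
            S[:, idx.var[v]] = sc[:, idx.k:]
        for (i, j) in idx.pairs:
            S[:, idx.cov[(i, j)]] = biv_eng[(i, j)].scores(
                idx.uni(i, svec), idx.uni(j, svec), svec[idx.cov[(i, j)]])
        return S

    psi = stacked_scores(s)
    B = psi.T @ psi / N
    M = idx.size

    # which score blocks react to a perturbation of each s coordinate
    def affected_blocks(m):
        for v in range(t):
            if (idx.mean[v].start <= m < idx.mean[v].stop
                    or idx.var[v].start <= m < idx.var[v].stop):
                return ([v], [pr for pr in idx.pairs if v in pr])
        for pr in idx.pairs:
            if idx.cov[pr].start <= m < idx.cov[pr].stop:
                return ([], [pr])
        raise AssertionError(m)  # pragma: no cover

    def partial_sums(svec, unis, pairs):
        out = np.zeros(M)
        for v in unis:
            sc = uni_eng[v].scores(idx.uni(v, svec)).sum(axis=0)
            out[idx.mean[v]] = sc[:idx.k]
            out[idx.var[v]] = sc[idx.k:]
        for pr in pairs:
            out[idx.cov[pr]] = biv_eng[pr].scores(
                idx.uni(pr[0], svec), idx.uni(pr[1], svec),
                svec[idx.cov[pr]]).sum(axis=0)
        return out

    A = np.zeros((M, M))
    for m in range(M):
        h = 1e-5 * max(1.0, abs(s[m]))
        sp, sm = s.copy(), s.copy()
        sp[m] += h
        sm[m] -= h
        unis, pairs = affected_blocks(m)
        A[:, m] = (partial_sums(sp, unis, pairs)
                   - partial_sums(sm, unis, pairs)) / (2 * h * N)
    try:
        Ainv = np.linalg.solve(A, np.eye(M))
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            "singular stage-1 Hessian; consider simplifying the model"
        ) from exc
    Gamma = Ainv @ B @ Ainv.T / N
    Gamma = 0.5 * (Gamma + Gamma.T)
    evals, evecs = np.linalg.eigh(Gamma)
    floor = 1e-10 * max(evals.max(), 1e-30)
    if evals.min() < floor:
        evals = np.clip(evals, floor, None)
        Gamma = (evecs * evals) @ evecs.T
    return SaturatedEstimates(s=s, Gamma=Gamma, scores=psi, N=N,
                              labels=moment_labels(mm), ascertained=ascertained)


# ---------------------------------------------------------------------------
# stage 2: evolutionary multi-start + minimum-distance fit


def _heuristic_center(mm: ModelMatrices, s: np.ndarray) -> np.ndarray:
    """Coefficients 1, intercepts at stage-1 values, variances equal splits."""
    labels = {lab: i for i, lab in enumerate(moment_labels(mm))}
    idx = _MomentIndex(mm)
    C = idx.C
    obs_index = {v: i for i, v in enumerate(mm.observed_vars)}
    # total stage-1 variance per observed variable
    tot = {v: float(np.sum(s[idx.var[obs_index[v]]])) for v in mm.observed_vars}
    indicators = {lat: [o for (l, o) in mm.spec.measurement_edges if l == lat]
                  for lat in mm.latent_vars}
    center = np.empty(mm.n_free)
    for pi, p in enumerate(mm.free):
        if p.role == "CO":
            center[pi] = 1.0
        elif p.role == "IN":
            center[pi] = s[labels[p.name]] if p.name in labels else 0.0
        else:
            m = re.match(r"^var\(([^,]+),", p.name)
            if m is None:               # freed covariance
                center[pi] = 0.0
                continue
            v = m.group(1)
            if v in obs_index:
                n_comp = len(mm.spec.components_of(v))
                center[pi] = max(tot[v] / n_comp, 0.05)
            else:
                inds = indicators.get(v) or []
                base = np.mean([tot[o] for o in inds]) if inds else 1.0
                n_comp = len(mm.spec.components_of(v))
                center[pi] = max(base / n_comp, 0.05)
    return center


def generate_starting_values(mm: ModelMatrices, s: np.ndarray, Q,
                             n_population: int = 20, n_generations: int = 10,
                             seed: int = 0, n_top: int = 5) -> list[np.ndarray]:
    """Evolutionary search for stage-2 starting values.

    Tournament selection (size 3), blend crossover (alpha = 0.5), Gaussian
    mutation (sd = 0.1 x scale, rate 0.2), elitism.  Deterministic given
    the seed.  Returns the distinct top ``n_top`` individuals plus the
    heuristic center, best first.
    """
    rng = np.random.default_rng(seed)
    center = _heuristic_center(mm, s)
    scale = np.maximum(0.5, 0.5 * np.abs(center))
    n = mm.n_free

    def fitness(x):
        q = Q(x)
        return -q if np.isfinite(q) else -_BIG

    pop = [center] + [center + scale * rng.standard_normal(n)
                      for _ in range(n_population - 1)]
    fit = np.array([fitness(x) for x in pop])
    for _gen in range(n_generations):
        order = np.argsort(fit)[::-1]
        new = [pop[order[0]]]
        new_fit = [fit[order[0]]]
        while len(new) < n_population:
            parents = []
            for _ in range(2):
                cand = rng.integers(0, n_population, size=3)
                parents.append(pop[cand[np.argmax(fit[cand])]])
            u = rng.uniform(-0.5, 1.5, size=n)
            child = u * parents[0] + (1.0 - u) * parents[1]
            mut = rng.random(n) < 0.2
            child = np.where(mut, child + 0.1 * scale * rng.standard_normal(n),
                             child)
            new.append(child)
            new_fit.append(fitness(child))
        pop, fit = new, np.array(new_fit)
    order = np.argsort(fit)[::-1]
    out, seen = [], set()
    for i in order:
        key = tuple(np.round(pop[i], 6))
        if key not in seen:
            seen.add(key)
            out.append(pop[i])
        if len(out) >= n_top:
            break
    ckey = tuple(np.round(center, 6))
    if ckey not in seen:
        out.append(center)
    return out


@dataclass
class FittedModel:
    """Stage-2 result: estimates, sandwich covariance, Wald tests, fit indices."""

    mm: ModelMatrices
    theta: np.ndarray
    vcov: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    Q_min: float
    df: int
    weight: str
    converged: bool
    n_starts_used: int
    fit: fi.FitIndexBundle | None = None
    sat: SaturatedEstimates | None = None
    seed: int = 0

    @property
    def param_names(self):
        return self.mm.param_names

    @property
    def roles(self):
        return self.mm.roles

    def parameter_table(self):
        import pandas as pd

        rows = []
        for i, prm in enumerate(self.mm.free):
            rows.append({"name": prm.name, "role": prm.role,
                         "estimate": self.theta[i], "se": self.se[i],
                         "z": self.z[i], "p": self.p[i], "fixed": False})
        for prm in self.mm.fixed:
            rows.append({"name": prm.name, "role": prm.role,
                         "estimate": prm.value, "se": np.nan,
                         "z": np.nan, "p": np.nan, "fixed": True})
        return pd.DataFrame(
            rows, columns=["name", "role", "estimate", "se", "z", "p", "fixed"])

    def conf_int(self, level: float = 0.95):
        zq = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.theta - zq * self.se,
                                self.theta + zq * self.se])


def _weight_matrix(Gamma: np.ndarray, weight: str):
    """Return (W matrix, function mapping residual -> W^1/2 residual)."""
    if weight == "diag":
        wd = 1.0 / np.clip(np.diag(Gamma), 1e-12, None)
        sqw = np.sqrt(wd)
        return np.diag(wd), lambda r: sqw * r if r.ndim == 1 else sqw[:, None] * r
    if weight == "full":
        evals, evecs = np.linalg.eigh(Gamma)
        tol = max(evals.max(), 0.0) * 1e-12
        inv = np.where(evals > tol, 1.0 / np.clip(evals, tol, None), 0.0)
        W = (evecs * inv) @ evecs.T
        half = (evecs * np.sqrt(inv)) @ evecs.T
        return W, lambda r: half @ r
    raise ConfigurationError(f"unknown weight choice {weight!r}")


def minimum_distance_fit(sat: SaturatedEstimates, mm: ModelMatrices,
                         weight: str = "diag", seed: int = 0,
                         mc_reps: int = 100_000, n_polish: int = 3,
                         ea_population: int = 20, ea_generations: int = 10,
                         compute_indices: bool = True) -> FittedModel:
    """Stage 2: minimize (s - sigma(theta))' W (s - sigma(theta))."""
    from .moments import _compiled_map

    s, Gamma = sat.s, sat.Gamma
    M = s.size
    W, half = _weight_matrix(Gamma, weight)
    cmap = _compiled_map(mm)

    def resid(theta):
        try:
            return half(s - cmap(theta))
        except (NumericalError, np.linalg.LinAlgError):
            return np.full(M, 1e6)

    def resid_jac(theta):
        try:
            return -half(cmap.jacobian(theta))
        except (NumericalError, np.linalg.LinAlgError):
            return np.zeros((M, mm.n_free))

    def Q(theta):
        r = resid(theta)
        return float(r @ r)

    starts = generate_starting_values(mm, s, Q, n_population=ea_population,
                                      n_generations=ea_generations, seed=seed)
    # polish the best evolutionary candidates plus, always, the heuristic
    # center (last element): it lives in the sane region of parameter space
    # and guards against deceptive basins the population may drift into
    polish_list = list(starts[:max(1, n_polish - 1)])
    if not any(np.array_equal(starts[-1], x) for x in polish_list):
        polish_list.append(starts[-1])
    best = None
    n_used = 0
    method = "lm" if M >= mm.n_free else "trf"
    for x0 in polish_list:
        n_used += 1
        try:
            res = optimize.least_squares(resid, x0, jac=resid_jac,
                                         method=method,
                                         xtol=1e-8, ftol=1e-8, gtol=1e-8,
                                         max_nfev=200 * (mm.n_free + 1))
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise EstimationError("all stage-2 starts failed to converge")
    theta = best.x
    Q_min = 2.0 * best.cost  # least_squares cost is 0.5 * sum of squares
    converged = bool(best.status > 0)

    Delta = moment_jacobian(mm, theta)
    DW = Delta.T @ W
    Mmat = DW @ Delta
    try:
        Minv = np.linalg.inv(Mmat)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"singular Delta'W Delta at the optimum: {exc}") from exc
    vcov = Minv @ DW @ Gamma @ DW.T @ Minv
    vcov = 0.5 * (vcov + vcov.T)
    se = np.sqrt(np.clip(np.diag(vcov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, theta / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    df = M - mm.n_free

    bundle = None
    if compute_indices:
        if df >= 1:
            idx = _MomentIndex(mm)
            n_free_base = idx.t * idx.k + idx.t * idx.C
            E = np.zeros((M, n_free_base))
            E[np.arange(n_free_base), np.arange(n_free_base)] = 1.0
            EW = E.T @ W
            theta_b = np.linalg.solve(EW @ E, EW @ s)
            rb = s - E @ theta_b
            Q_b = float(rb @ W @ rb)
            df_b = M - n_free_base
            baseline = (Q_b, E, df_b) if df_b >= 1 else None
        else:
            baseline = None
        bundle = fi.compute_fit_indices(Q_min, W, Gamma, Delta, df,
                                        baseline=baseline,
                                        mc_reps=mc_reps, seed=seed)
    return FittedModel(mm=mm, theta=theta, vcov=vcov, se=se, z=z, p=p,
                       Q_min=Q_min, df=df, weight=weight, converged=converged,
                       n_starts_used=n_used, fit=bundle, sat=sat, seed=seed)


def fit_model(peds, model, ibd: IbdStore | None = None,
              ascertained: bool = False, weight: str = "diag", seed: int = 0,
              mc_reps: int = 100_000, compute_indices: bool = True,
              check_ident: bool = True,
              cache: RelationshipCache | None = None,
              **stage2_kwargs) -> FittedModel:
    """Full two-stage pipeline: parse/compile, stage 1, stage 2.

    ``model`` may be model-description text, a :class:`ModelSpec`, or
    compiled :class:`ModelMatrices`.
    """
    if isinstance(model, str):
        model = parse_model(model)
    if isinstance(model, ModelSpec):
        mm = build_model_matrices(model)
    else:
        mm = model
    if check_ident:
        from .model import check_identification

        ident = check_identification(mm)
        if not ident["identified"]:
            warnings.warn("model appears locally non-identified "
                          f"(df={ident['df']}); estimates may be unstable",
                          stacklevel=2)
    sat = saturated_estimates(peds, mm, ibd=ibd, ascertained=ascertained,
                              cache=cache, seed=seed)
    return minimum_distance_fit(sat, mm, weight=weight, seed=seed,
                                mc_reps=mc_reps,
                                compute_indices=compute_indices,
                                **stage2_kwargs)
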