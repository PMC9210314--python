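"""Genomic prediction models: RRBLUP, GBLUP and the Gaussian kernel.

All three reduce to the single-kernel mixed model y = 1μ + Zu + ε solved
by :class:`~tritigs.mixed.MixedModel`:

* RRBLUP — markers as random effects of equal variance, Z the centered
  dosage design; GEBVs are marker effects summed over a genotype.
* GBLUP — genotype effects covarying per VanRaden's additive relationship
  matrix A = WW′ / (2·Σ p_k(1−p_k)).
* GAUSS — kernel K(θ) = exp(−(D/θ)²) on mean-scaled Euclidean dosage
  distances, with the bandwidth θ profiled over a grid by restricted
  likelihood.

Prediction for unobserved genotypes uses the conditional-mean BLUP
extension K_test,train K_train,train⁻¹ û.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import GenotypeMatrix
from .mixed import MixedModel, MixedModelResults

__all__ = [
    "KernelSpec",
    "a_matrix",
    "gauss_kernel",
    "marker_design",
    "solve_mixed",
    "predict_gebv",
    "GSModel",
]

MODELS = ("rrblup", "gblup", "gauss")

#: default bandwidth grid after mean-distance normalization
DEFAULT_THETA_GRID = np.logspace(np.log10(0.1), np.log10(5.0), 20)


@dataclass
class KernelSpec:
    """A prediction kernel over the panel.

    ``kind`` is one of ``marker_identity`` (RRBLUP: Z = centered marker
    design, K implicit identity over markers), ``additive_A`` (GBLUP) or
    ``gauss``.  For ``gauss`` the scaled distance matrix is stored; the
    kernel matrix materializes once θ is chosen.
    """

    kind: str
    K: np.ndarray | None = None  # n x n kernel (additive_A / gauss)
    Z: np.ndarray | None = None  # n x m marker design (marker_identity)
    D: np.ndarray | None = field(default=None, repr=False)  # scaled distances
    theta: float | None = None
    theta_grid: np.ndarray | None = None
    grid_loglik: np.ndarray | None = None

    def materialize(self, theta: float | None = None) -> np.ndarray:
        """Kernel matrix; for gauss, at the given (or selected) bandwidth."""
        if self.kind == "gauss":
            th = self.theta if theta is None else theta
            if th is None:
                raise ValueError("gauss kernel bandwidth not selected yet")
            return np.exp(-((self.D / th) ** 2))
        if self.kind == "additive_A":
            return self.K
        raise ValueError(f"kernel {self.kind!r} has no n x n matrix")


def marker_design(g: GenotypeMatrix) -> KernelSpec:
    """RRBLUP design: dosages centered at 2p per marker (W of VanRaden)."""
    if g.has_missing():
        raise ValueError("impute before building kernels")
    p = g.allele_freq
    W = g.dosages - 2.0 * p[None, :]
    return KernelSpec(kind="marker_identity", Z=W)


def a_matrix(g: GenotypeMatrix) -> KernelSpec:
    """VanRaden additive relationship matrix A = WW′ / (2·Σ p(1−p)).

    Monomorphic markers contribute nothing to the denominator and are
    excluded with a warning.
    """
    if g.has_missing():
        raise ValueError("impute before building kernels")
    p = g.allele_freq
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic markers from A",
                      stacklevel=2)
    if not poly.any():
        raise ValueError("no polymorphic markers")
    pp = p[poly]
    W = g.dosages[:, poly] - 2.0 * pp[None, :]
    denom = 2.0 * float(np.sum(pp * (1.0 - pp)))
    return KernelSpec(kind="additive_A", K=(W @ W.T) / denom)


def gauss_kernel(g: GenotypeMatrix, theta_grid=None) -> KernelSpec:
    """Gaussian kernel spec on mean-scaled Euclidean dosage distances.

    The bandwidth θ is profiled against the restricted likelihood inside
    :func:`solve_mixed` / :class:`GSModel`; until then the spec carries the
    distance matrix and the candidate grid.
    """
    if g.has_missing():
        raise ValueError("impute before building kernels")
    D = squareform(pdist(g.dosages))
    mean_d = D[np.triu_indices_from(D, k=1)].mean() if g.n_accessions > 1 else 0.0
    if mean_d == 0:
        raise ValueError("zero mean distance: all accessions identical")
    grid = DEFAULT_THETA_GRID if theta_grid is None else np.asarray(theta_grid, float)
    if grid.size == 0:
        raise ValueError("empty theta grid")
    return KernelSpec(kind="gauss", D=D / mean_d, theta_grid=grid)


def _subset_spec(spec: KernelSpec, idx) -> KernelSpec:
    idx = np.asarray(idx)
    if spec.kind == "marker_identity":
        return KernelSpec("marker_identity", Z=spec.Z[idx])
    if spec.kind == "additive_A":
        return KernelSpec("additive_A", K=spec.K[np.ix_(idx, idx)])
    return KernelSpec("gauss", D=spec.D[np.ix_(idx, idx)], theta=spec.theta,
                      theta_grid=spec.theta_grid)


def solve_mixed(y, kernel: KernelSpec | np.ndarray | None = None, X=None) -> MixedModelResults:
    """REML fit of y = Xβ + Zu + ε for the given kernel.

    For a gauss spec without a selected θ, every grid bandwidth is fitted
    and the one maximizing the restricted likelihood wins (ties to the
    smallest θ); the choice is recorded on the result as ``theta``.
    """
    if kernel is None or isinstance(kernel, np.ndarray):
        res = MixedModel(y, X=X, K=kernel).fit()
        res.theta = None
        return res
    if kernel.kind == "marker_identity":
        res = MixedModel(y, X=X, Z=kernel.Z).fit()
        res.theta = None
        return res
    if kernel.kind == "additive_A":
        res = MixedModel(y, X=X, K=kernel.K).fit()
        res.theta = None
        return res
    if kernel.kind == "gauss":
        if kernel.theta is not None:
            res = MixedModel(y, X=X, K=kernel.materialize()).fit()
            res.theta = kernel.theta
            return res
        best = None
        logliks = []
        for th in kernel.theta_grid:
            r = MixedModel(y, X=X, K=np.exp(-((kernel.D / th) ** 2))).fit()
            logliks.append(r.loglik)
            if best is None or r.loglik > best[1].loglik:
                best = (float(th), r)
        kernel.grid_loglik = np.asarray(logliks)
        res = best[1]
        res.theta = best[0]
        return res
    raise ValueError(f"unknown kernel kind {kernel.kind!r}")


def predict_gebv(fit: MixedModelResults, spec_full: KernelSpec, train_idx, test_idx) -> np.ndarray:
    """GEBVs for test accessions from a fit on the training accessions.

    RRBLUP: GEBV = W_test û + μ̂.  Kernel models: the conditional-mean
    extension K_test,train K_train,train⁻¹ û_train + μ̂, with the training
    kernel inverted through its eigendecomposition (eigenvalue floor 1e-8).
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    mu = float(fit.beta[0])
    if spec_full.kind == "marker_identity":
        return spec_full.Z[test_idx] @ fit.u + mu
    theta = getattr(fit, "theta", None)
    K = spec_full.materialize(theta)
    if max(train_idx.max(), test_idx.max()) >= K.shape[0]:
        raise ValueError("accession index outside the kernel")
    K_tt = K[np.ix_(train_idx, train_idx)]
    w, U = np.linalg.eigh((K_tt + K_tt.T) / 2.0)
    w_inv = np.where(w > 1e-8, 1.0 / np.maximum(w, 1e-8), 0.0)
    alpha = U @ (w_inv * (U.T @ fit.u))
    return K[np.ix_(test_idx, train_idx)] @ alpha + mu


class GSModel:
    """Genomic prediction on a panel, statsmodels-style.

    Parameters
    ----------
    y : phenotypic estimates (PEBV), one per accession of ``geno``
    geno : imputed :class:`GenotypeMatrix`
    model : "rrblup" | "gblup" | "gauss"

    ``fit(train_idx)`` fits on a subset (default: all) and returns a
    :class:`GSResults` that predicts GEBVs for any accession subset.
    """

    def __init__(self, y, geno: GenotypeMatrix, model: str = "gblup", theta_grid=None):
        if model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        y = np.asarray(y, float).ravel()
        if len(y) != geno.n_accessions:
            raise ValueError("y length must match the panel")
        self.y = y
        self.geno = geno
        self.model = model
        if model == "rrblup":
            self.spec = marker_design(geno)
        elif model == "gblup":
            self.spec = a_matrix(geno)
        else:
            self.spec = gauss_kernel(geno, theta_grid)

    def fit(self, train_idx=None) -> "GSResults":
        n = self.geno.n_accessions
        train_idx = np.arange(n) if train_idx is None else np.asarray(train_idx)
        sub = _subset_spec(self.spec, train_idx)
        res = solve_mixed(self.y[train_idx], sub)
        return GSResults(self, res, train_idx)


@dataclass
class GSResults:
    """Fitted genomic prediction model."""

    gsmodel: GSModel
    mixed: MixedModelResults
    train_idx: np.ndarray

    @property
    def mu(self) -> float:
        return float(self.mixed.beta[0])

    @property
    def h2(self) -> float:
        return self.mixed.h2

    def predict(self, test_idx=None) -> np.ndarray:
        if test_idx is None:
            test_idx = np.arange(self.gsmodel.geno.n_accessions)
        spec = self.gsmodel.spec
        if spec.kind == "gauss":
            spec = KernelSpec("gauss", D=spec.D, theta=getattr(self.mixed, "theta", None),
                              theta_grid=spec.theta_grid)
        return predict_gebv(self.mixed, spec, self.train_idx, np.asarray(test_idx))

    def summary(self) -> str:
        head = f"Genomic prediction: {self.gsmodel.model.upper()}"
        th = getattr(self.mixed, "theta", None)
        extra = f"\ntheta            {th:>10.4g}" if th is not None else ""
        return head + "\n" + self.mixed.summary().split("\n", 1)[1] + extra
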