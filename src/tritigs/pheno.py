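"""Field-trial adjustment: lattice and spatial mixed models, H², combination.

Per environment, plot yields are adjusted two ways and compared:

* lattice — y = μ + replicate (fixed) + incomplete block (random) +
  genotype + ε, the classical resolvable-lattice recovery of
  inter-block information;
* spatial — a two-dimensional P-spline surface over the (row, column)
  grid: Y = Xβ + X_sβ_s + Z_sS + Z_uU + Z_gG + e, with the tensor-product
  cubic B-spline surface split into its unpenalized bilinear part (X_sβ_s)
  and a penalized random part (second-order difference penalties),
  independent random row and column effects U, and random genotype
  effects G for variance estimation.  Smoothing/variance parameters come
  from Schall's iterative REML; a companion fixed-genotype generalized
  least squares pass yields adjusted means.

Broad-sense heritability uses the entry-mean formula
H² = σ²_g / (σ²_g + σ²_e / n_reps).  Adjusted means from the environments
combine in a second stage (genotype fixed, environment random) into
per-genotype phenotypic estimates (PEBV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .mixed import MixedModel, fit_schall
from .simulate import FieldTrial

__all__ = [
    "TrialFit",
    "PhenoBLUE",
    "fit_lattice",
    "fit_spatial",
    "efficiency",
    "heritability",
    "combine_environments",
]


@dataclass
class TrialFit:
    """Per-environment adjusted analysis."""

    model: str  # "lattice" | "spatial"
    environment: str
    varcomps: dict  # includes sigma2_g and sigma2_e
    adjusted_means: pd.Series  # genotype -> adjusted mean (g/m²)
    n_reps: int
    surface: np.ndarray | None = None  # per plot, spatial only
    diagnostics: dict = field(default_factory=dict)

    @property
    def sigma2_g(self):
        return self.varcomps["sigma2_g"]

    @property
    def sigma2_e(self):
        return self.varcomps["sigma2_e"]

    def summary(self) -> str:
        lines = [f"{self.model} fit, {self.environment}", "-" * 30]
        for k, v in self.varcomps.items():
            lines.append(f"{k:<12} {v:>12.4g}")
        lines.append(f"H2 (entry-mean, {self.n_reps} reps) "
                     f"{heritability(self, self.n_reps):.3f}")
        return "\n".join(lines)


def _onehot(values):
    cats = pd.unique(values)
    idx = pd.Categorical(values, categories=cats).codes
    Z = np.zeros((len(values), len(cats)))
    Z[np.arange(len(values)), idx] = 1.0
    return Z, list(cats)


def _dummies_drop_first(values):
    Z, cats = _onehot(values)
    return Z[:, 1:], cats


def _gls(y, X, V):
    c, low = cho_factor(V)
    Vi_y = cho_solve((c, low), y)
    Vi_X = cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    return beta


def _adjusted_means(y, V, base_cols, geno_dummies, geno_cats):
    """Fixed-genotype GLS; means = mean fixed baseline + genotype effect."""
    X = np.hstack([base_cols, geno_dummies])
    beta = _gls(y, X, V)
    p0 = base_cols.shape[1]
    baseline = float((base_cols @ beta[:p0]).mean())
    coefs = np.concatenate([[0.0], beta[p0:]])
    return pd.Series(baseline + coefs, index=geno_cats).sort_index()


def fit_lattice(t: FieldTrial) -> TrialFit:
    """Incomplete-block (lattice) analysis of one environment.

    Variance components come from the genotype-random REML fit; adjusted
    genotype means from the companion genotype-fixed GLS at the estimated
    block variance.  A single-replicate trial is degenerate and returns
    raw genotype means with a warning.
    """
    df = t.plots
    for col in ("rep", "block"):
        if col not in df.columns:
            raise ValueError(f"trial lacks the {col!r} column")
    y = df["yield_g_m2"].to_numpy(float)
    n_reps = df["rep"].nunique()
    if n_reps == 1:
        warnings.warn("single-replicate trial: returning raw means", stacklevel=2)
        means = df.groupby("genotype")["yield_g_m2"].mean().sort_index()
        vc = {"sigma2_g": float(means.var(ddof=1)), "sigma2_b": float("nan"),
              "sigma2_e": float("nan")}
        return TrialFit("lattice", t.environment, vc, means, n_reps,
                        diagnostics={"degenerate": True})

    rep_d, _ = _dummies_drop_first(df["rep"].to_numpy())
    X = np.hstack([np.ones((len(df), 1)), rep_d])
    Z_b, _ = _onehot(df["block"].to_numpy())
    Z_g, geno_cats = _onehot(df["genotype"].to_numpy())
    fit = fit_schall(y, X, {"block": Z_b, "genotype": Z_g})
    s2_b, s2_g, s2_e = fit.sigma2["block"], fit.sigma2["genotype"], fit.sigma2_e

    V = s2_e * np.eye(len(df)) + s2_b * (Z_b @ Z_b.T)
    geno_dum = Z_g[:, 1:]
    means = _adjusted_means(y, V, X, geno_dum, geno_cats)
    missing = set(geno_cats) ^ set(means.index)
    if missing:  # pragma: no cover - all genotypes present by construction
        warnings.warn(f"non-estimable genotypes: {sorted(missing)}", stacklevel=2)
    vc = {"sigma2_g": float(s2_g), "sigma2_b": float(s2_b), "sigma2_e": float(s2_e)}
    return TrialFit("lattice", t.environment, vc, means, n_reps,
                    diagnostics={"n_iter": fit.n_iter, "converged": fit.converged})


def _bspline_basis(x, n_knots, degree=3):
    """Cubic B-spline design over [min(x), max(x)] with equally spaced knots."""
    x = np.asarray(x, float)
    x0, x1 = x.min(), x.max()
    if x1 == x0:
        raise ValueError("degenerate coordinate range")
    breaks = np.linspace(x0, x1, n_knots)
    t = np.concatenate([[x0] * degree, breaks, [x1] * degree])
    B = BSpline.design_matrix(x, t, degree).toarray()
    return B


def _diff_penalty(nb, order=2):
    D = np.diff(np.eye(nb), n=order, axis=0)
    return D.T @ D


def fit_spatial(t: FieldTrial, knots_r: int | None = None, knots_c: int | None = None,
                max_iter: int = 2000) -> TrialFit:
    """Two-dimensional P-spline spatial analysis of one environment.

    The tensor-product penalty P = D′D ⊗ I + I ⊗ D′D is eigen-reparametrized:
    its null space (bilinear in row and column) enters the fixed design,
    the penalized remainder becomes a single isotropic random spline
    component.  Default knot spacing is one knot per 2 grid units.
    """
    df = t.plots
    rows = df["row"].to_numpy()
    cols = df["col"].to_numpy()
    if not (np.equal(np.mod(rows, 1), 0).all() and np.equal(np.mod(cols, 1), 0).all()):
        raise ValueError("non-grid layout: row/col must be integer grid indices")
    y = df["yield_g_m2"].to_numpy(float)
    n = len(df)
    n_r, n_c = len(np.unique(rows)), len(np.unique(cols))
    if knots_r is None:
        knots_r = max(4, n_r // 2 + 1)
    if knots_c is None:
        knots_c = max(4, n_c // 2 + 1)
    if knots_r < 4 or knots_c < 4:
        raise ValueError("need at least 4 knots per dimension")

    B_r = _bspline_basis(rows, knots_r)
    B_c = _bspline_basis(cols, knots_c)
    nb_r, nb_c = B_r.shape[1], B_c.shape[1]
    # row-major tensor basis: column (i, j) = B_r[:, i] * B_c[:, j]
    B = (B_r[:, :, None] * B_c[:, None, :]).reshape(n, nb_r * nb_c)
    P = np.kron(_diff_penalty(nb_r), np.eye(nb_c)) + np.kron(np.eye(nb_r), _diff_penalty(nb_c))
    lam, U = np.linalg.eigh((P + P.T) / 2.0)
    pos = lam > 1e-8 * lam.max()
    Z_s = B @ (U[:, pos] / np.sqrt(lam[pos]))

    r_n = (rows - rows.mean()) / max(rows.std(), 1.0)
    c_n = (cols - cols.mean()) / max(cols.std(), 1.0)
    poly = np.column_stack([r_n, c_n, r_n * c_n])
    rep_d, _ = _dummies_drop_first(df["rep"].to_numpy())
    X = np.hstack([np.ones((n, 1)), rep_d, poly])
    Z_row, _ = _onehot(rows)
    Z_col, _ = _onehot(cols)
    Z_g, geno_cats = _onehot(df["genotype"].to_numpy())

    fit = fit_schall(y, X, {"spline": Z_s, "row": Z_row, "col": Z_col, "genotype": Z_g},
                     max_iter=max_iter)
    if not fit.converged:
        raise RuntimeError(
            f"spatial REML did not converge in {fit.n_iter} iterations "
            f"(varcomps {fit.sigma2}, sigma2_e {fit.sigma2_e:.4g})"
        )
    p_rep = 1 + rep_d.shape[1]
    beta_poly = fit.beta[p_rep:p_rep + 3]
    surface = poly @ beta_poly + Z_s @ fit.u["spline"]
    surface = surface - surface.mean()

    s2 = fit.sigma2
    V = (fit.sigma2_e * np.eye(n)
         + s2["spline"] * (Z_s @ Z_s.T)
         + s2["row"] * (Z_row @ Z_row.T)
         + s2["col"] * (Z_col @ Z_col.T))
    means = _adjusted_means(y, V, X, Z_g[:, 1:], geno_cats)
    vc = {"sigma2_g": float(s2["genotype"]), "sigma2_spline": float(s2["spline"]),
          "sigma2_r": float(s2["row"]), "sigma2_c": float(s2["col"]),
          "sigma2_e": float(fit.sigma2_e)}
    return TrialFit("spatial", t.environment, vc, means, df["rep"].nunique(),
                    surface=surface,
                    diagnostics={"n_iter": fit.n_iter, "converged": fit.converged,
                                 "effective_dims": fit.effective_dims})


def efficiency(spatial: TrialFit, lattice: TrialFit) -> float:
    """Percent reduction of residual variance of the spatial vs lattice fit.

    100 · (σ²_e,lattice − σ²_e,spatial) / σ²_e,lattice.  Scale-invariant.
    """
    if lattice.sigma2_e == 0 or not np.isfinite(lattice.sigma2_e):
        raise ValueError("lattice residual variance is zero or undefined")
    return 100.0 * (lattice.sigma2_e - spatial.sigma2_e) / lattice.sigma2_e


def heritability(fit: TrialFit, n_reps: int | None = None) -> float:
    """Entry-mean broad-sense heritability H² = σ²_g / (σ²_g + σ²_e/r)."""
    if n_reps is None:
        n_reps = fit.n_reps
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    s2g, s2e = fit.sigma2_g, fit.sigma2_e
    if s2g == 0 and s2e == 0:
        raise ValueError("all variance components are zero")
    return s2g / (s2g + s2e / n_reps)


@dataclass
class PhenoBLUE:
    """Across-environment phenotypic estimates (PEBV) per genotype."""

    pebv: pd.Series  # genotype -> estimate (g/m²)
    stage1: pd.DataFrame  # long: genotype, env, mean
    varcomps: dict  # sigma2_env, sigma2_ge_resid

    def align(self, accession_ids) -> np.ndarray:
        """PEBV vector in the order of the given accession ids."""
        return self.pebv.reindex(list(accession_ids)).to_numpy(float)

    def summary(self) -> str:
        return (
            "Combined-environment analysis\n"
            f"genotypes        {len(self.pebv):>8d}\n"
            f"environments     {self.stage1['env'].nunique():>8d}\n"
            f"sigma2_env       {self.varcomps['sigma2_env']:>8.4g}\n"
            f"sigma2_GE+resid  {self.varcomps['sigma2_ge_resid']:>8.4g}\n"
            f"PEBV mean        {self.pebv.mean():>8.2f} g/m2"
        )


def combine_environments(stage1) -> PhenoBLUE:
    """Combine per-environment adjusted means into PEBVs.

    ``stage1``: list of :class:`TrialFit` (or (env, Series) pairs, or a
    long DataFrame with genotype/env/mean columns).  Two-way mixed model
    on the stage-1 means: genotype fixed, environment random, GxE
    confounded with the residual.  PEBV = genotype BLUEs.
    """
    if isinstance(stage1, pd.DataFrame):
        long = stage1[["genotype", "env", "mean"]].copy()
    else:
        frames = []
        for item in stage1:
            if isinstance(item, TrialFit):
                env, means = item.environment, item.adjusted_means
            else:
                env, means = item
            frames.append(pd.DataFrame(
                {"genotype": means.index, "env": env, "mean": means.to_numpy()}
            ))
        long = pd.concat(frames, ignore_index=True)
    if long["env"].nunique() < 2:
        raise ValueError("need adjusted means from at least 2 environments")
    counts = long.groupby("genotype")["env"].nunique()
    single = counts[counts < 2]
    if len(single):
        warnings.warn(
            f"{len(single)} genotypes observed in a single environment", stacklevel=2
        )
    y = long["mean"].to_numpy(float)
    geno_dum, geno_cats = _dummies_drop_first(long["genotype"].to_numpy())
    X = np.hstack([np.ones((len(long), 1)), geno_dum])
    Z_env, _ = _onehot(long["env"].to_numpy())
    res = MixedModel(y, X=X, Z=Z_env).fit()
    coefs = np.concatenate([[0.0], res.beta[1:]])
    pebv = pd.Series(float(res.beta[0]) + coefs, index=geno_cats).sort_index()
    return PhenoBLUE(pebv, long,
                     {"sigma2_env": res.sigma2_u, "sigma2_ge_resid": res.sigma2_e})
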