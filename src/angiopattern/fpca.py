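"""Multivariate functional principal component analysis (MFPCA).

Each vessel contributes a pair of curves — μFR and minimal lumen diameter
— registered onto a common normalized abscissa in [0, 1].  The multivariate
Karhunen–Loève expansion is estimated in two stages: (1) univariate FPCA
per variable by eigendecomposition of the quadrature-weighted sample
covariance operator; (2) eigendecomposition of the covariance of the
stacked univariate score vectors, whose eigenvectors form the combination
matrix mapping univariate scores to multivariate scores.  The leading
multivariate scores (three by default) summarize the joint curve variation
and enter the downstream classifiers as features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .curves import VesselRecord


@dataclass(frozen=True)
class FunctionalSample:
    """Curves for n subjects on a shared grid: values has shape (n, G, V)."""

    grid: np.ndarray
    values: np.ndarray
    var_names: tuple[str, ...]

    def __post_init__(self):
        grid = np.asarray(self.grid, float)
        vals = np.asarray(self.values, float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", vals)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if vals.ndim != 3 or vals.shape[1] != grid.size or vals.shape[2] != len(self.var_names):
            raise ValueError("values must have shape (subjects, grid, variables)")
        if np.any(~np.isfinite(vals)):
            raise ValueError("registered curves must have no missing values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class UnivariateFPCA:
    mean: np.ndarray            # (G,)
    eigenfunctions: np.ndarray  # (k, G), orthonormal under the weighted inner product
    eigenvalues: np.ndarray     # (k,), non-increasing
    total_variance: float       # sum of all eigenvalues before truncation


@dataclass
class MFPCAModel:
    """Fitted MFPCA: means, univariate eigenpairs and the score-combination map."""

    grid: np.ndarray
    var_names: tuple[str, ...]
    univariate: list[UnivariateFPCA]
    combination_matrix: np.ndarray       # (M, K): stacked univariate -> multivariate scores
    multivariate_eigenvalues: np.ndarray  # (K,)
    n_components: int
    weights_scheme: str = "trapezoid"

    def multivariate_eigenfunctions(self) -> np.ndarray:
        """Shape (K, G, V): the combined eigenfunctions per variable."""
        G = self.grid.size
        V = len(self.var_names)
        K = self.n_components
        out = np.zeros((K, G, V))
        offset = 0
        for v, uni in enumerate(self.univariate):
            m = uni.eigenfunctions.shape[0]
            # (K, m) @ (m, G)
            out[:, :, v] = self.combination_matrix[offset:offset + m, :K].T @ uni.eigenfunctions
            offset += m
        return out


def quadrature_weights(grid: np.ndarray, scheme: str = "trapezoid") -> np.ndarray:
    """Integration weights on the grid: 'trapezoid' quadrature or 'uniform'
    (unit weight per point, i.e. the plain matrix inner product)."""
    if scheme == "uniform":
        return np.ones(grid.size)
    if scheme == "trapezoid":
        w = np.zeros(grid.size)
        d = np.diff(grid)
        w[:-1] += d / 2
        w[1:] += d / 2
        return w
    raise ValueError(f"unknown quadrature scheme {scheme!r}")


def register_curves(
    records: Sequence[VesselRecord],
    n_grid: int = 101,
    variables: tuple[str, ...] = ("mufr", "mld"),
    on_missing: str = "raise",
) -> FunctionalSample:
    """Rescale each vessel to the domain [0, 1] and interpolate onto a
    common grid.

    Vessels differ in physical length; MFPCA requires a shared abscissa, so
    each curve is linearly mapped to [0, 1] (shape registration — absolute
    length information stays available to the classifiers through PPGi and
    the disease-length terms).

    ``on_missing`` controls vessels lacking a requested diameter curve:
    'raise' fails, 'drop' silently removes them.
    """
    if on_missing not in ("raise", "drop"):
        raise ValueError("on_missing must be 'raise' or 'drop'")
    grid = np.linspace(0.0, 1.0, n_grid)
    rows = []
    for rec in records:
        c = rec.curve
        t = (c.positions - c.positions[0]) / (c.positions[-1] - c.positions[0])
        mat = np.empty((n_grid, len(variables)))
        ok = True
        for j, name in enumerate(variables):
            arr = getattr(c, name)
            if arr is None:
                if on_missing == "raise":
                    raise ValueError(f"vessel {rec.vessel_id} lacks a {name} curve")
                ok = False
                break
            mat[:, j] = np.interp(grid, t, arr)
        if ok:
            rows.append(mat)
    values = np.array(rows).reshape(len(rows), n_grid, len(variables))
    return FunctionalSample(grid=grid, values=values, var_names=tuple(variables))


def _fix_signs(eigenfunctions: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Sign convention: each eigenfunction has non-negative weighted
    integral; exact-zero integrals break ties toward a positive first
    nonzero loading."""
    out = eigenfunctions.copy()
    for i in range(out.shape[0]):
        integral = float(np.sum(w * out[i]))
        if abs(integral) > 1e-12:
            if integral < 0:
                out[i] = -out[i]
        else:
            nz = np.nonzero(np.abs(out[i]) > 1e-12)[0]
            if nz.size and out[i, nz[0]] < 0:
                out[i] = -out[i]
    return out


def fit_univariate_fpca(
    values: np.ndarray,
    grid: np.ndarray,
    pve: float = 0.99,
    weights: Optional[np.ndarray] = None,
) -> tuple[UnivariateFPCA, np.ndarray]:
    """Karhunen–Loève estimation for one variable.

    Centers by the pointwise mean, eigendecomposes the quadrature-weighted
    sample covariance (divisor n − 1) and retains the smallest number of
    components whose cumulative eigenvalue fraction reaches ``pve``.
    Returns the fitted eigenpairs and the (n, k) score matrix.
    """
    X = np.asarray(values, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("univariate FPCA needs at least 2 subjects")
    w = quadrature_weights(grid) if weights is None else np.asarray(weights, float)
    mean = X.mean(axis=0)
    Xc = X - mean
    sw = np.sqrt(w)
    B = Xc * sw  # (n, G); B^T B / (n-1) is the weighted covariance
    _, s, Vt = np.linalg.svd(B / np.sqrt(n - 1), full_matrices=False)
    eigvals = s**2
    total = float(eigvals.sum())
    if total <= 1e-14:
        phi = _fix_signs((Vt[:1] / sw), w)
        uni = UnivariateFPCA(mean=mean, eigenfunctions=phi, eigenvalues=np.zeros(1), total_variance=0.0)
        return uni, np.zeros((n, 1))
    frac = np.cumsum(eigvals) / total
    k = int(np.searchsorted(frac, pve - 1e-12) + 1)
    k = min(k, eigvals.size)
    phi = _fix_signs(Vt[:k] / sw, w)
    scores = (Xc * w) @ phi.T
    uni = UnivariateFPCA(
        mean=mean, eigenfunctions=phi, eigenvalues=eigvals[:k], total_variance=total
    )
    return uni, scores


def fit_mfpca(
    sample: FunctionalSample,
    n_components: int = 3,
    pve: float = 0.99,
    weights: str = "trapezoid",
) -> MFPCAModel:
    """Fit the two-stage multivariate FPCA.

    Univariate expansions are estimated per variable (truncated at
    ``pve``); the covariance of the stacked score vectors is then
    eigendecomposed to obtain the combination matrix and multivariate
    eigenvalues.  ``n_components`` beyond the available rank triggers a
    warning and truncation.
    """
    if sample.n_subjects < 2:
        raise ValueError("MFPCA needs at least 2 subjects")
    w = quadrature_weights(sample.grid, weights)
    fits, score_blocks = [], []
    for v in range(len(sample.var_names)):
        uni, scores = fit_univariate_fpca(sample.values[:, :, v], sample.grid, pve=pve, weights=w)
        fits.append(uni)
        score_blocks.append(scores)
    Z = np.hstack(score_blocks)  # (n, M)
    M = Z.shape[1]
    if n_components > M:
        warnings.warn(
            f"requested {n_components} components but only {M} univariate "
            f"directions are available; truncating",
            stacklevel=2,
        )
        n_components = M
    C = np.cov(Z, rowvar=False, ddof=1).reshape(M, M)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    U = evecs[:, order]
    # sign convention applied through the combined eigenfunctions
    model = MFPCAModel(
        grid=sample.grid,
        var_names=sample.var_names,
        univariate=fits,
        combination_matrix=U,
        multivariate_eigenvalues=evals[:n_components],
        n_components=n_components,
        weights_scheme=weights,
    )
    psi = model.multivariate_eigenfunctions()  # (K, G, V)
    for kk in range(n_components):
        integral = float(np.sum(w[None, :, None] * psi[kk][None]))
        flip = False
        if abs(integral) > 1e-12:
            flip = integral < 0
        else:
            flat = psi[kk].ravel(order="F")
            nz = np.nonzero(np.abs(flat) > 1e-12)[0]
            flip = bool(nz.size and flat[nz[0]] < 0)
        if flip:
            U[:, kk] = -U[:, kk]
    return model


def transform(model: MFPCAModel, sample: FunctionalSample) -> np.ndarray:
    """Project registered curves onto the multivariate eigenfunctions.

    Returns the (n, n_components) score matrix.  On the training sample
    the score columns are uncorrelated with variances equal to the
    multivariate eigenvalues.
    """
    if sample.grid.shape != model.grid.shape or not np.allclose(sample.grid, model.grid):
        raise ValueError("sample grid does not match the fitted model grid")
    if sample.var_names != model.var_names:
        raise ValueError("sample variables do not match the fitted model")
    w = quadrature_weights(model.grid, model.weights_scheme)
    blocks = []
    for v, uni in enumerate(model.univariate):
        Xc = sample.values[:, :, v] - uni.mean
        blocks.append((Xc * w) @ uni.eigenfunctions.T)
    Z = np.hstack(blocks)
    return Z @ model.combination_matrix[:, : model.n_components]


def reconstruct(model: MFPCAModel, scores: np.ndarray) -> np.ndarray:
    """Rebuild curves (n, G, V) from multivariate scores via the truncated
    Karhunen–Loève expansion."""
    psi = model.multivariate_eigenfunctions()  # (K, G, V)
    n = scores.shape[0]
    out = np.einsum("nk,kgv->ngv", scores[:, : model.n_components], psi)
    for v, uni in enumerate(model.univariate):
        out[:, :, v] += uni.mean
    return out


def save_model(model: MFPCAModel, path) -> None:
    """Serialize a fitted model to a single JSON file."""
    payload = {
        "grid": model.grid.tolist(),
        "var_names": list(model.var_names),
        "weights_scheme": model.weights_scheme,
        "n_components": model.n_components,
        "combination_matrix": model.combination_matrix.tolist(),
        "multivariate_eigenvalues": model.multivariate_eigenvalues.tolist(),
        "univariate": [
            {
                "mean": u.mean.tolist(),
                "eigenfunctions": u.eigenfunctions.tolist(),
                "eigenvalues": u.eigenvalues.tolist(),
                "total_variance": u.total_variance,
            }
            for u in model.univariate
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> MFPCAModel:
    with open(path) as fh:
        d = json.load(fh)
    return MFPCAModel(
        grid=np.array(d["grid"]),
        var_names=tuple(d["var_names"]),
        univariate=[
            UnivariateFPCA(
                mean=np.array(u["mean"]),
                eigenfunctions=np.array(u["eigenfunctions"]),
                eigenvalues=np.array(u["eigenvalues"]),
                total_variance=u["total_variance"],
            )
            for u in d["univariate"]
        ],
        combination_matrix=np.array(d["combination_matrix"]),
        multivariate_eigenvalues=np.array(d["multivariate_eigenvalues"]),
        n_components=d["n_components"],
        weights_scheme=d["weights_scheme"],
    )
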