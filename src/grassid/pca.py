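"""Varimax-rotated principal component model on standardized features.

The model is a correlation-matrix PCA: features are z-scored (sample SD,
n − 1 denominator), the sample correlation matrix is eigendecomposed, and
components with eigenvalue ≥ 1 − kaiser_tolerance are retained (the tolerance
admits borderline eigenvalues that round to 1.00, mirroring scree-plot
judgement). Retained loadings (eigenvectors × √eigenvalue) are rotated with
classical Varimax (Kaiser row normalization by default), and component score
coefficients are obtained by the regression method, C = R⁻¹·Λ, so scores of
the fitting set are standardized (mean 0, variance 1) and uncorrelated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateColumn, MissingFeature, NoComponents, SingularInput


@dataclass
class PcaModel:
    """A fitted (or bundled) rotated principal component model."""

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    eigenvalues: np.ndarray  # all of them, descending
    retained_k: int
    rotated_loadings: np.ndarray  # features × retained_k
    rotation: np.ndarray  # retained_k × retained_k orthogonal
    score_coefficients: np.ndarray  # features × retained_k
    explained_pct: np.ndarray  # per component, eigenvalue / p × 100
    provenance: str = "fitted"

    @property
    def component_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.retained_k)]

    def score(self, table: pd.DataFrame) -> pd.DataFrame:
        """Component scores of each row: standardize, then apply coefficients."""
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise MissingFeature(f"feature table lacks columns: {missing}")
        x = table[self.feature_names].to_numpy(dtype=float)
        z = (x - self.means) / self.sds
        scores = z @ self.score_coefficients
        return pd.DataFrame(scores, columns=self.component_names, index=table.index)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "retained_k": self.retained_k,
            "rotated_loadings": self.rotated_loadings.tolist(),
            "rotation": self.rotation.tolist(),
            "score_coefficients": self.score_coefficients.tolist(),
            "explained_pct": self.explained_pct.tolist(),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PcaModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            means=np.asarray(d["means"], float),
            sds=np.asarray(d["sds"], float),
            eigenvalues=np.asarray(d["eigenvalues"], float),
            retained_k=int(d["retained_k"]),
            rotated_loadings=np.asarray(d["rotated_loadings"], float),
            rotation=np.asarray(d["rotation"], float),
            score_coefficients=np.asarray(d["score_coefficients"], float),
            explained_pct=np.asarray(d["explained_pct"], float),
            provenance=d.get("provenance", "fitted"),
        )


def standardize(
    table: pd.DataFrame, feature_names: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score the feature columns; returns (matrix, means, sample SDs)."""
    missing = [f for f in feature_names if f not in table.columns]
    if missing:
        raise MissingFeature(f"feature table lacks columns: {missing}")
    x = table[feature_names].to_numpy(dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    if np.any(sds == 0):
        dead = [f for f, s in zip(feature_names, sds) if s == 0]
        raise DegenerateColumn(f"zero-variance feature(s): {dead}")
    return (x - means) / sds, means, sds


def fit_pca(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose the sample correlation matrix of a standardized matrix.

    Returns descending eigenvalues and the full loadings matrix (eigenvectors
    scaled by √eigenvalue; each column's largest-magnitude entry positive).
    """
    n, p = z.shape
    if n <= p:
        raise SingularInput(f"need more rows ({n}) than features ({p})")
    corr = (z.T @ z) / (n - 1)
    if not np.all(np.isfinite(corr)):
        raise SingularInput("correlation matrix contains non-finite entries")
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    dominant = np.abs(eigvecs).argmax(axis=0)
    signs = np.sign(eigvecs[dominant, np.arange(p)])
    signs[signs == 0] = 1.0
    loadings = eigvecs * signs * np.sqrt(eigvals)
    return eigvals, loadings


def retain_components(eigenvalues: np.ndarray, kaiser_tolerance: float = 0.05) -> int:
    """Kaiser retention with a small tolerance for borderline eigenvalues."""
    ev = np.asarray(eigenvalues, float)
    k = int(np.sum(ev >= 1.0 - kaiser_tolerance))
    if k == 0:
        raise NoComponents("no eigenvalue meets the retention criterion")
    return k


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax objective: summed column variance of squared loadings."""
    L2 = np.asarray(loadings, float) ** 2
    p = L2.shape[0]
    return float(np.sum(L2**2) - np.sum(L2.sum(axis=0) ** 2) / p)


def _order_and_sign(
    loadings: np.ndarray, rotation: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    # columns by decreasing sum of squared loadings; dominant entry positive
    ss = (loadings**2).sum(axis=0)
    order = np.argsort(-ss, kind="stable")
    loadings = loadings[:, order]
    rotation = rotation[:, order]
    dominant = np.abs(loadings).argmax(axis=0)
    signs = np.sign(loadings[dominant, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs, rotation * signs


def varimax(
    loadings: np.ndarray,
    row_normalize: bool = True,
    tol: float = 1e-8,
    max_sweeps: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Classical Varimax rotation by successive planar rotations.

    With ``row_normalize`` (Kaiser normalization), rows are scaled to unit
    communality before rotation and rescaled after — the convention used by
    the major statistics packages. Sweeps over all column pairs continue until
    the varimax criterion improves by less than ``tol``; if ``max_sweeps`` is
    reached first a RuntimeWarning is emitted and the best iterate returned.

    Returns ``(rotated_loadings, rotation)`` with the rotation orthogonal,
    columns ordered by decreasing sum of squared loadings, and each column's
    dominant entry positive. Communalities (row sums of squares) are
    preserved exactly up to floating point.
    """
    L = np.array(loadings, dtype=float)
    if L.ndim != 2:
        raise ValueError("loadings must be a 2-D array")
    p, k = L.shape
    if k == 1:
        out, rot = _order_and_sign(L, np.eye(1))
        return out, rot
    h = np.sqrt((L**2).sum(axis=1))
    if row_normalize:
        scale = np.where(h > 0, h, 1.0)
        L = L / scale[:, None]
    rotation = np.eye(k)
    last = varimax_criterion(L)
    converged = False
    for _ in range(max_sweeps):
        for i in range(k - 1):
            for j in range(i + 1, k):
                u = L[:, i] ** 2 - L[:, j] ** 2
                v = 2.0 * L[:, i] * L[:, j]
                a, b = u.sum(), v.sum()
                c = (u**2 - v**2).sum()
                d = 2.0 * (u * v).sum()
                num = d - 2.0 * a * b / p
                den = c - (a**2 - b**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-12:
                    continue
                g = np.array(
                    [[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]]
                )
                L[:, [i, j]] = L[:, [i, j]] @ g
                rotation[:, [i, j]] = rotation[:, [i, j]] @ g
        crit = varimax_criterion(L)
        if crit - last < tol:
            converged = True
            break
        last = crit
    if not converged:
        warnings.warn(
            f"varimax did not converge within {max_sweeps} sweeps; "
            "returning best iterate",
            RuntimeWarning,
        )
    if row_normalize:
        L = L * scale[:, None]
    return _order_and_sign(L, rotation)


def score_coefficients(corr: np.ndarray, rotated_loadings: np.ndarray) -> np.ndarray:
    """Regression-method score coefficients C = R⁻¹·Λ.

    Multiplying a standardized feature row by C gives component scores with
    unit variance over the fitting set.
    """
    corr = np.asarray(corr, float)
    try:
        return np.linalg.solve(corr, np.asarray(rotated_loadings, float))
    except np.linalg.LinAlgError as exc:
        raise SingularInput("correlation matrix is singular") from exc


def fit_model(
    table: pd.DataFrame,
    feature_names: list[str],
    kaiser_tolerance: float = 0.05,
    row_normalize: bool = True,
) -> PcaModel:
    """Fit the full rotated-PCA scoring model on a feature table."""
    z, means, sds = standardize(table, feature_names)
    eigvals, loadings = fit_pca(z)
    k = retain_components(eigvals, kaiser_tolerance)
    rotated, rotation = varimax(loadings[:, :k], row_normalize=row_normalize)
    # regression coefficients R⁻¹·Λ, computed through the retained eigenpairs
    # (V_k D_k^{-1/2} T): algebraically identical when R is invertible, and
    # stable when discarded eigenvalues are near zero
    coeffs = (loadings[:, :k] / eigvals[:k]) @ rotation
    p = len(feature_names)
    return PcaModel(
        feature_names=list(feature_names),
        means=means,
        sds=sds,
        eigenvalues=eigvals,
        retained_k=k,
        rotated_loadings=rotated,
        rotation=rotation,
        score_coefficients=coeffs,
        explained_pct=eigvals / p * 100.0,
        provenance="fitted",
    )


def score_standardized(coefficients: pd.DataFrame | np.ndarray, z_rows: np.ndarray) -> np.ndarray:
    """Score pre-standardized feature rows with a bare coefficient matrix.

    Useful with a bundled reference coefficient matrix whose standardization
    parameters are unknown.
    """
    c = coefficients.to_numpy() if isinstance(coefficients, pd.DataFrame) else np.asarray(coefficients)
    return np.atleast_2d(np.asarray(z_rows, float)) @ c
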