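"""Ridge marker-effect predictor (rrBLUP-style linear comparator).

The model is y = mu + X beta + e with X the column-centred additive 0/1/2
genotype matrix and a single shared shrinkage parameter lambda on the
marker effects:

    beta = (X'X + lambda I)^-1 X' (y - ybar),   mu = ybar.

With ``lam="reml"`` the shrinkage is the variance ratio
lambda = sigma_e^2 / sigma_u^2 of the equivalent random-effect model
(u ~ N(0, sigma_u^2 I), e ~ N(0, sigma_e^2 I)), estimated by restricted
maximum likelihood through the spectral decomposition of the genomic
kernel XX' — the same mechanics as rrBLUP's mixed-model solver. REML
optimisation is a golden-section search on log lambda (tolerance 1e-6).

Only the additive 0/1/2 coding is accepted: ridge effects have a per-copy
interpretation only for biallelic dosage codes, so a ten-state matrix is
an explicit error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geno import EncodedMatrix, MISSING_CODE

__all__ = ["RidgeModel", "fit_ridge", "predict_ridge"]


@dataclass
class RidgeModel:
    intercept: float
    effects: np.ndarray
    lam: float
    marker_ids: list[str] | None
    scheme: str | None
    col_means: np.ndarray
    reml: bool = False

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


def _resolve_additive(X) -> tuple[np.ndarray, list[str] | None, str | None]:
    if isinstance(X, EncodedMatrix):
        if X.scheme != "additive012":
            raise ValueError(
                f"ridge requires the additive012 coding, got {X.scheme!r}; "
                "re-encode with geno.encode_additive")
        return X.to_array(), list(X.marker_ids), X.scheme
    Xa = np.asarray(X, dtype=float)
    return Xa, None, None


def _reml_lambda(Z: np.ndarray, y: np.ndarray) -> float:
    """REML estimate of lambda = sigma_e^2/sigma_u^2 via eigendecomposition.

    Works in the (n-1)-dimensional complement of the intercept: with
    S = I - 11'/n, eigendecompose S Z Z' S and maximise the restricted
    log-likelihood of the rotated data over delta = lambda.
    """
    n = len(y)
    yc = y - y.mean()
    Zc = Z - Z.mean(axis=0)
    K = Zc @ Zc.T
    # K already lives in the centred space; 1 is a null eigenvector.
    theta, U = np.linalg.eigh(K)
    theta = np.clip(theta, 0.0, None)
    eta = U.T @ yc

    # yc is centred, so its component along the intercept null-direction of
    # K is zero: quadratic forms over all n eigendirections equal those over
    # the (n-1)-dim complement of the intercept, and one log(delta) term is
    # subtracted for the excluded direction.
    def neg_restricted_ll(log_delta: float) -> float:
        d = np.exp(log_delta)
        denom = theta + d
        ss = np.sum(eta**2 / denom)
        return float(np.sum(np.log(denom)) - log_delta + (n - 1) * np.log(ss))

    # golden-section search on log delta
    lo, hi = -12.0, 12.0
    invphi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d_ = a + invphi * (b - a)
    fc, fd = neg_restricted_ll(c), neg_restricted_ll(d_)
    while b - a > 1e-6:
        if fc < fd:
            b, d_, fd = d_, c, fc
            c = b - invphi * (b - a)
            fc = neg_restricted_ll(c)
        else:
            a, c, fc = c, d_, fd
            d_ = a + invphi * (b - a)
            fd = neg_restricted_ll(d_)
    return float(np.exp((a + b) / 2))


def fit_ridge(X, y, lam: float | str = 1.0) -> RidgeModel:
    """Fit ridge marker effects; ``lam`` is a number or ``"reml"``.

    Missing genotype codes are mean-imputed per marker before centring
    (the linear model has no native missing routing).
    """
    Xa, marker_ids, scheme = _resolve_additive(X)
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing phenotypes not allowed in fit_ridge")
    n, m = Xa.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    # mean-impute missing, then centre
    col_means = np.zeros(m)
    for j in range(m):
        col = Xa[:, j]
        miss = np.isnan(col)
        mu = col[~miss].mean() if (~miss).any() else 0.0
        col[miss] = mu
        col_means[j] = col.mean()
    Z = Xa - col_means

    reml = lam == "reml"
    if reml:
        lam_val = _reml_lambda(Z, y)
    else:
        lam_val = float(lam)
        if lam_val < 0:
            raise ValueError("lambda must be non-negative")

    yc = y - y.mean()
    A = Z.T @ Z + lam_val * np.eye(m)
    if lam_val == 0:
        # solve may be singular; detect and advise
        if np.linalg.matrix_rank(Z.T @ Z) < m:
            raise np.linalg.LinAlgError(
                "X'X is singular with lambda=0; use lambda > 0 (or 'reml')")
    effects = np.linalg.solve(A, Z.T @ yc)
    return RidgeModel(float(y.mean()), effects, lam_val, marker_ids, scheme,
                      col_means, reml=reml)


def predict_ridge(model: RidgeModel, X) -> np.ndarray:
    """intercept + (X - training column means) . effects"""
    Xa, marker_ids, scheme = _resolve_additive(X)
    if Xa.shape[1] != len(model.effects):
        raise ValueError("marker count mismatch")
    if model.marker_ids is not None and marker_ids is not None \
            and marker_ids != model.marker_ids:
        raise ValueError("marker ids/order differ from training")
    Xa = Xa.copy()
    for j in range(Xa.shape[1]):
        col = Xa[:, j]
        col[np.isnan(col)] = model.col_means[j]
    return model.intercept + (Xa - model.col_means) @ model.effects
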