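"""NIPALS PLS-DA: fit/predict, LOO-CV complexity, VIP, target projection, SR.

Two-class discriminant PLS regresses a +1/-1 coded class variable on the
autoscaled metabolite matrix.  With a single response the NIPALS weight
update is closed-form per component (w ∝ X'y), followed by score, loading
and deflation steps.  The regression vector b = W (P'W)^-1 q collapses the
A-component model into one linear predictor; class assignment thresholds
the predicted response at 0, the natural cut-off for a balanced model set.

Variable importance in projection (VIP) combines the squared, normalized
X-weights with the response variance captured per component; by
construction the mean of the squared VIP scores over all variables is 1,
which motivates cut-offs near 1 (0.8 in this workflow).  Target projection
collapses the A-component model onto the single predictive direction
b/||b||; the selectivity ratio (SR) of a variable is the ratio of its
variance explained by that predictive component to its residual variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .table import ScalingParams
from .preprocess import apply_scaling

__all__ = [
    "PLSDAModel",
    "TargetProjectionResult",
    "fit_plsda",
    "predict",
    "select_complexity_loo",
    "vip_scores",
    "target_projection",
    "selectivity_ratio",
]

_EPS = 1e-12


class RankDeficiencyError(ValueError):
    """X carries no further y-predictive variation at the requested complexity."""


@dataclass
class PLSDAModel:
    """Fitted NIPALS PLS-DA model.

    ``W`` holds the unit-norm X-weights (variables x A), ``P`` the X-loadings,
    ``T`` the training scores and ``q`` the y-loadings; ``b`` is the
    regression vector on the autoscaled variables.  ``y_coding`` maps the two
    class labels onto +1/-1; ``cutoff`` is the decision threshold on the
    predicted response (0).  ``scaling``, when present, is applied to new
    data inside :func:`predict`.
    """

    n_components: int
    W: np.ndarray
    P: np.ndarray
    T: np.ndarray
    q: np.ndarray
    b: np.ndarray
    y_coding: dict[str, int] | None = None
    cutoff: float = 0.0
    scaling: ScalingParams | None = None
    variable_names: list[str] | None = None

    @property
    def ssy_per_component(self) -> np.ndarray:
        """Response sum of squares captured by each component (q_a^2 t_a't_a)."""
        return self.q**2 * np.einsum("ia,ia->a", self.T, self.T)

    def to_json(self, path) -> None:
        """Serialize the model (matrices row-major with named dimensions)."""
        import json
        from pathlib import Path

        d = {
            "n_components": self.n_components,
            "cutoff": self.cutoff,
            "y_coding": self.y_coding,
            "variable_names": self.variable_names,
            "W": {"dims": ["variable", "component"], "data": self.W.tolist()},
            "P": {"dims": ["variable", "component"], "data": self.P.tolist()},
            "T": {"dims": ["sample", "component"], "data": self.T.tolist()},
            "q": {"dims": ["component"], "data": self.q.tolist()},
            "b": {"dims": ["variable"], "data": self.b.tolist()},
        }
        if self.scaling is not None:
            d["scaling"] = {
                "variable_names": self.scaling.variable_names,
                "mean": self.scaling.mean.tolist(),
                "sd": self.scaling.sd.tolist(),
            }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path) -> "PLSDAModel":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        scaling = None
        if "scaling" in d:
            s = d["scaling"]
            scaling = ScalingParams(
                s["variable_names"], np.array(s["mean"]), np.array(s["sd"])
            )
        return cls(
            n_components=d["n_components"],
            W=np.array(d["W"]["data"]),
            P=np.array(d["P"]["data"]),
            T=np.array(d["T"]["data"]),
            q=np.array(d["q"]["data"]),
            b=np.array(d["b"]["data"]),
            y_coding=d.get("y_coding"),
            cutoff=d.get("cutoff", 0.0),
            scaling=scaling,
            variable_names=d.get("variable_names"),
        )


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """One-response NIPALS with deflation; returns (W, P, T, q)."""
    n, p = X.shape
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    T = np.empty((n, n_components))
    q = np.empty(n_components)
    Xd = X.copy()
    y_scale = float(y @ y)
    for a in range(n_components):
        w = Xd.T @ y
        nw = float(np.linalg.norm(w))
        if nw <= _EPS * max(1.0, y_scale):
            raise RankDeficiencyError(
                f"component {a + 1} exceeds the predictive rank of X"
            )
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _EPS:
            raise RankDeficiencyError(
                f"component {a + 1} exceeds the predictive rank of X"
            )
        pa = Xd.T @ t / tt
        qa = float(y @ t) / tt
        Xd -= np.outer(t, pa)
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
    return W, P, T, q


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    return W @ np.linalg.solve(P.T @ W, q)


def fit_plsda(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scaling: ScalingParams | None = None,
    y_coding: dict[str, int] | None = None,
    variable_names: list[str] | None = None,
) -> PLSDAModel:
    """Fit a PLS-DA model of complexity ``n_components`` on autoscaled ``X``.

    ``y`` must be +1/-1 with both classes present.  ``scaling`` is stored for
    later prediction on raw data; it is not applied to ``X`` here.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be n x p and y of length n")
    if not (np.any(y > 0) and np.any(y < 0)):
        raise ValueError("both classes must be present in y")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(X.shape):
        raise RankDeficiencyError(
            f"n_components={n_components} exceeds min(n, p)={min(X.shape)}"
        )
    W, P, T, q = _nipals_pls1(X, y, n_components)
    b = _regression_vector(W, P, q)
    return PLSDAModel(
        n_components=n_components,
        W=W,
        P=P,
        T=T,
        q=q,
        b=b,
        y_coding=dict(y_coding) if y_coding else None,
        scaling=scaling,
        variable_names=list(variable_names) if variable_names else None,
    )


def predict(model: PLSDAModel, X_new: np.ndarray):
    """Continuous scores and hard class assignments for new samples.

    If the model carries scaling parameters they are applied to ``X_new``
    first (so raw concentration rows can be passed); otherwise ``X_new`` must
    already be autoscaled.  A score exactly at the cut-off is assigned to the
    negative-coded class.  Returns ``(scores, labels)`` where labels are +1/-1
    or, when a label coding is stored, the original class names.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.b.size:
        raise ValueError(
            f"variable mismatch: model has {model.b.size}, data has {X_new.shape[1]}"
        )
    if model.scaling is not None:
        X_new = apply_scaling(X_new, model.scaling)
    scores = X_new @ model.b
    signs = np.where(scores > model.cutoff, 1, -1)
    if model.y_coding:
        inv = {v: k for k, v in model.y_coding.items()}
        labels = np.array([inv[int(s)] for s in signs], dtype=object)
    else:
        labels = signs
    return scores, labels


def _cumulative_regression_vectors(W, P, q, A_max: int) -> np.ndarray:
    """Stack b_a for a = 1..A_max as columns (p x A_max).

    Exploits the NIPALS property that P'W is unit upper triangular, so each
    leading system (P'W)[:a,:a] x = q[:a] is solved by back substitution.
    """
    U = P.T @ W
    coeff = np.zeros((A_max, A_max))
    for a in range(A_max):
        coeff[a, a] = q[a]
        for k in range(a - 1, -1, -1):
            coeff[k, a] = q[k] - U[k, k + 1 : a + 1] @ coeff[k + 1 : a + 1, a]
    return W[:, :A_max] @ coeff


def _loo_misclassification(X: np.ndarray, y: np.ndarray, A_max: int) -> np.ndarray:
    """LOO misclassification counts for complexities 1..A_max, scaling refit per fold.

    All n leave-one-out folds are evaluated simultaneously.  For held-out row
    i the fold's autoscaling statistics follow from rank-one downdates of the
    full-data sums, and the fold's PLS components are extracted with the
    non-deflating kernel recursion: keeping r_a = w_a orthogonalized against
    the previous loadings, the score vector is t_a = Xs r_a, so
    ``tau_a = r_a' (Xs'Xs) r_a``, ``p_a = (Xs'Xs) r_a / tau_a`` and
    ``q_a = r_a' (Xs'y) / tau_a`` with the *undeflated* cross-product, and the
    cumulative regression vector is simply ``b_A = sum_a q_a r_a``.  The fold
    Gram products are never materialized: ``(Xs'Xs) r`` is reduced to one
    shared GEMM against the full-data Gram matrix plus rank-one corrections
    per fold.  Algebraically identical to refitting NIPALS on every explicit
    fold matrix.
    """
    n, p = X.shape
    nf = n - 1
    G = X.T @ X
    diag_G = np.diag(G).copy()
    S = X.sum(axis=0)
    Xy_all = X.T @ y
    y_sum = float(y.sum())

    m = (S[None, :] - X) / nf                      # fold means   (n, p)
    var = (diag_G[None, :] - X**2 - nf * m**2) / (nf - 1)
    s = np.sqrt(np.maximum(var, 0.0))
    s[s <= 0] = 1.0                                # degenerate fold column: no signal
    Xys = (Xy_all[None, :] - X * y[:, None] - m * (y_sum - y)[:, None]) / s
    xi_s = (X - m) / s                             # scaled held-out rows

    R = np.zeros((A_max, n, p))
    P = np.zeros((A_max, n, p))
    Sd = Xys.copy()                                # deflated Xs'y per fold
    scale = np.maximum(1.0, np.abs(Xys).max(axis=1))
    errors = np.zeros(A_max)
    b = np.zeros((n, p))
    for a in range(A_max):
        nw = np.sqrt((Sd * Sd).sum(axis=1))
        alive = nw > 1e-10 * scale
        w = np.where(alive[:, None], Sd / np.where(alive, nw, 1.0)[:, None], 0.0)
        r = w
        for k in range(a):                          # orthogonalize against loadings
            r = r - ((P[k] * w).sum(axis=1))[:, None] * R[k]
        # z = (Xs'Xs) r per fold, via the shared Gram matrix
        rt = r / s
        z = (rt @ G - X * (X * rt).sum(axis=1)[:, None]
             - (nf * m) * (m * rt).sum(axis=1)[:, None]) / s
        tau = (r * z).sum(axis=1)
        alive &= tau > _EPS
        tau_safe = np.where(alive, tau, 1.0)
        pa = np.where(alive[:, None], z / tau_safe[:, None], 0.0)
        qa = np.where(alive, (r * Xys).sum(axis=1) / tau_safe, 0.0)
        Sd = Sd - (tau_safe * qa)[:, None] * pa
        R[a], P[a] = r, pa
        b = b + qa[:, None] * r                    # dead folds keep their last b
        preds = np.where((xi_s * b).sum(axis=1) > 0, 1.0, -1.0)
        errors[a] = float((preds != y).sum())
    return errors


def select_complexity_loo(
    X: np.ndarray, y: np.ndarray, A_max: int, refit_scaling: bool = True
) -> int:
    """Smallest complexity minimizing the LOO-CV misclassification rate.

    Each fold refits the autoscaling on the n-1 training rows (when
    ``refit_scaling``, the leakage-safe default, in which case ``X`` should be
    the raw matrix), extracts up to ``A_max`` components, and classifies the
    held-out sample at every complexity.  Ties go to the smaller model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    A_max = min(A_max, n - 1, p)
    if refit_scaling:
        errors = _loo_misclassification(X, y, A_max)
    else:
        errors = np.zeros(A_max)
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            W, P, _T, q = _nipals_pls1(X[mask], y[mask], A_max)
            B = _cumulative_regression_vectors(W, P, q, A_max)
            preds = np.where(X[i] @ B > 0, 1.0, -1.0)
            errors += preds != y[i]
            mask[i] = True
    return int(np.argmin(errors)) + 1  # argmin takes the smallest index on ties


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection for every variable.

    ``VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a )`` with unit-norm
    weight vectors and SSY_a the response variance captured by component a.
    The mean of the squared VIPs equals 1 for any fitted model.
    """
    ssy = model.ssy_per_component
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model captured no response variance")
    p = model.W.shape[0]
    return np.sqrt(p * (model.W**2 @ ssy) / total)


@dataclass
class TargetProjectionResult:
    """Target-projected decomposition of an A-component PLS-DA model.

    ``explained + residual`` equals the per-variable total sum of squares of
    the projected matrix by construction; the selectivity ratio is their
    per-variable quotient.
    """

    w_tp: np.ndarray
    t_tp: np.ndarray
    p_tp: np.ndarray
    explained: np.ndarray
    residual: np.ndarray
    total: np.ndarray


def target_projection(
    model: PLSDAModel, X: np.ndarray, reconstructed: bool = True
) -> TargetProjectionResult:
    """Collapse the model onto its single predictive direction b/||b||.

    ``X`` is the autoscaled training matrix.  The target-projected score
    vector is computed on the A-component reconstruction ``T P'`` by default
    (the predictive score of the fitted model, free of variation the model
    never captured); with ``reconstructed=False`` it is ``X b/||b||``
    directly.  The per-variable loading ``p_TP = X' t_TP / t_TP't_TP`` is the
    least-squares slope of each variable on the target score — identical
    whether taken against ``X`` or its reconstruction, since the discarded
    residue is orthogonal to the score space — and the explained sum of
    squares ``t_TP't_TP p_TP_j^2`` is therefore each variable's regression
    SS on the target component, with ``residual = total - explained`` its
    lack of fit against the measured variable.
    """
    X = np.asarray(X, dtype=float)
    nb = float(np.linalg.norm(model.b))
    if nb <= _EPS:
        raise ValueError("regression vector has zero norm; target undefined")
    w_tp = model.b / nb
    t_tp = (model.T @ model.P.T if reconstructed else X) @ w_tp
    tt = float(t_tp @ t_tp)
    if tt <= _EPS:
        raise ValueError("target-projected scores are null")
    p_tp = X.T @ t_tp / tt
    explained = tt * p_tp**2
    total = np.einsum("ij,ij->j", X, X)
    residual = np.maximum(total - explained, 0.0)
    return TargetProjectionResult(
        w_tp=w_tp, t_tp=t_tp, p_tp=p_tp,
        explained=explained, residual=residual, total=total,
    )


def selectivity_ratio(tp: TargetProjectionResult) -> np.ndarray:
    """Per-variable explained/residual variance ratio after target projection.

    Variables whose residual falls below ``1e-12 * total`` are reported as
    ``+inf`` (fully explained); they sort above every finite ratio.
    """
    sr = np.empty_like(tp.explained)
    degenerate = tp.residual <= 1e-12 * np.maximum(tp.total, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        sr = np.where(degenerate, np.inf, tp.explained / np.where(degenerate, 1.0, tp.residual))
    sr[tp.total <= _EPS] = 0.0  # variable absent from the projected space
    return sr
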