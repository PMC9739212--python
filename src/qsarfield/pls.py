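"""Partial least squares by NIPALS, with leave-one-out cross-validation.

The descriptor block of a grid-based QSAR has thousands of collinear columns
and a few dozen rows; ordinary least squares is hopeless, PLS extracts a
small number of latent components ordered by covariance with the activity.
The NIPALS implementation here is deterministic — with a single response the
first weight vector is X'y, no random initialisation is involved — so
refitting is bit-reproducible.

Internal predictivity is measured by leave-one-out cross-validation:

    PRESS = sum (y_pred - y_obs)^2       over held-out predictions
    TSS   = sum (y_obs  - y_mean)^2      y_mean over the cross-validated set
    q^2   = 1 - PRESS / TSS

The optimal number of components (ONC) is the smallest component count whose
q^2 comes within a parsimony tolerance (default 5%) of the best q^2.  The
fitted (non-cross-validated) model is summarised by r^2, the standard error
of estimate SEE = sqrt(SSres / (n - c - 1)) and the Fisher statistic
F = (r^2/c) / ((1-r^2)/(n-c-1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import FieldBlock

__all__ = [
    "PLSModel",
    "CrossValReport",
    "fit_pls",
    "predict",
    "loo_q2",
    "select_onc",
    "fit_statistics",
    "field_contributions",
]


@dataclass
class PLSModel:
    n_components: int
    x_means: np.ndarray
    y_mean: float
    x_weights: np.ndarray  # (n_cols, A)
    x_loadings: np.ndarray  # (n_cols, A)
    y_loadings: np.ndarray  # (A,)
    coefficients: np.ndarray  # (n_cols,) regression vector on centered data
    scores: np.ndarray | None = None  # (n, A) training scores


@dataclass
class CrossValReport:
    q2_by_component: np.ndarray
    press_by_component: np.ndarray
    tss: float
    onc: int

    @property
    def q2(self) -> float:
        """q^2 at the selected number of components."""
        return float(self.q2_by_component[self.onc - 1])

    @property
    def press(self) -> float:
        return float(self.press_by_component[self.onc - 1])


def _nipals(xc: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS on centered data; returns weights, loadings and per-component
    cumulative coefficient vectors."""
    n, p = xc.shape
    ws, ps, cs, ts = [], [], [], []
    x = xc.copy()
    y = yc.copy()
    for _ in range(n_components):
        w = x.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = x @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p_vec = x.T @ t / tt
        c = float(y @ t) / tt
        ws.append(w)
        ps.append(p_vec)
        cs.append(c)
        ts.append(t)
        x = x - np.outer(t, p_vec)
        y = y - c * t
    if not ws:
        raise ValueError("NIPALS extracted no components (zero-variance problem)")
    w_mat = np.column_stack(ws)
    p_mat = np.column_stack(ps)
    c_vec = np.array(cs)
    t_mat = np.column_stack(ts)
    # B_a = W_a (P_a' W_a)^-1 c_a, computed cumulatively for every a
    coefs = []
    for a in range(1, w_mat.shape[1] + 1):
        pw = p_mat[:, :a].T @ w_mat[:, :a]
        coefs.append(w_mat[:, :a] @ np.linalg.solve(pw, c_vec[:a]))
    return w_mat, p_mat, c_vec, t_mat, coefs


def fit_pls(x, y, n_components: int) -> PLSModel:
    """Fit a NIPALS PLS model on column-centered X and centered y.

    ``x`` may be a :class:`FieldBlock` or a plain 2-D array.
    """
    xm = x.matrix if isinstance(x, FieldBlock) else np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = xm.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if len(y) != n:
        raise ValueError("X and y disagree in sample count")
    if float(np.var(y)) == 0.0:
        raise ValueError("zero-variance response")
    max_a = min(n - 1, p)
    if not 1 <= n_components <= max_a:
        raise ValueError(f"n_components must lie in [1, {max_a}]")
    x_means = xm.mean(axis=0)
    y_mean = float(y.mean())
    w_mat, p_mat, c_vec, t_mat, coefs = _nipals(xm - x_means, y - y_mean, n_components)
    return PLSModel(
        n_components=w_mat.shape[1],
        x_means=x_means,
        y_mean=y_mean,
        x_weights=w_mat,
        x_loadings=p_mat,
        y_loadings=c_vec,
        coefficients=coefs[-1],
        scores=t_mat,
    )


def predict(model: PLSModel, x_new) -> np.ndarray:
    """``y_hat = y_mean + (X_new - x_means) @ coefficients``."""
    xm = x_new.matrix if isinstance(x_new, FieldBlock) else np.asarray(x_new, dtype=float)
    xm = np.atleast_2d(xm)
    if xm.shape[1] != model.x_means.shape[0]:
        raise ValueError(
            f"column count {xm.shape[1]} does not match model ({model.x_means.shape[0]})"
        )
    return model.y_mean + (xm - model.x_means) @ model.coefficients


def select_onc(q2_by_component, parsimony_tol: float = 0.05) -> int:
    """Smallest component count whose q^2 reaches (1 - tol) * max q^2.

    With a non-positive best q^2 the parsimony band is meaningless and the
    argmax (smallest index on ties) is returned.
    """
    q2 = np.asarray(q2_by_component, dtype=float)
    if q2.size == 0:
        raise ValueError("empty q2 sequence")
    q_max = float(q2.max())
    threshold = (1.0 - parsimony_tol) * q_max
    if q_max <= 0:
        return int(np.argmax(q2)) + 1
    candidates = np.flatnonzero(q2 >= threshold)
    return int(candidates[0]) + 1 if candidates.size else int(np.argmax(q2)) + 1


def loo_q2(x, y, n_components: int, parsimony_tol: float = 0.05) -> CrossValReport:
    """Leave-one-out cross-validation over 1..n_components components.

    Each sample is held out in turn, the model refit on the remainder and the
    held-out activity predicted; PRESS accumulates the squared prediction
    errors per component count.  TSS is taken about the mean of the full
    cross-validated set.
    """
    xm = x.matrix if isinstance(x, FieldBlock) else np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = xm.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for LOO")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("constant response: TSS is zero")
    max_a = min(n_components, n - 2, xm.shape[1])
    press = np.zeros(max_a)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xt, yt = xm[mask], y[mask]
        x_means = xt.mean(axis=0)
        y_mean = float(yt.mean())
        try:
            _, _, _, _, coefs = _nipals(xt - x_means, yt - y_mean, max_a)
        except ValueError:
            continue
        xi = xm[i] - x_means
        for a in range(max_a):
            b = coefs[min(a, len(coefs) - 1)]
            press[a] += (y_mean + float(xi @ b) - y[i]) ** 2
    q2 = 1.0 - press / tss
    onc = select_onc(q2, parsimony_tol)
    return CrossValReport(q2_by_component=q2, press_by_component=press, tss=tss, onc=onc)


def fit_statistics(model: PLSModel, x, y) -> tuple[float, float, float]:
    """Non-cross-validated (r^2, SEE, F) of a fitted model on its data."""
    y = np.asarray(y, dtype=float)
    resid = y - predict(model, x)
    n, c = len(y), model.n_components
    dof = n - c - 1
    if dof <= 0:
        raise ValueError("non-positive degrees of freedom")
    ss_res = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / tss
    see = float(np.sqrt(ss_res / dof))
    f_value = float("inf") if r2 >= 1.0 else (r2 / c) / ((1.0 - r2) / dof)
    return r2, see, float(f_value)


def field_contributions(model: PLSModel, block: FieldBlock) -> dict[str, float]:
    """Fractional importance of each field kind.

    Per kind: sum over its columns of |coefficient| x column standard
    deviation (on the scaled block the model was fit to), normalised to sum
    to one across kinds.
    """
    sd = block.column_sd
    raw = {}
    for kind in block.kinds:
        idx = block.columns_of(kind)
        if idx.size == 0:
            raise ValueError(f"field kind {kind!r} has no kept columns")
        raw[kind] = float(np.sum(np.abs(model.coefficients[idx]) * sd[idx]))
    total = sum(raw.values())
    if total == 0:
        return {k: 1.0 / len(raw) for k in raw}
    return {k: v / total for k, v in raw.items()}
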