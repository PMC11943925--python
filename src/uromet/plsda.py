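"""Two-class PLS-DA: NIPALS fitting, cross-validated Q², VIP scores.

Class membership is encoded as a single response y (+1 study, -1 control)
and the bucket matrix X is regressed on it with PLS1.  For a single
response NIPALS reduces to a closed form per component a:

    w_a = X'y / ||X'y||        (weights)
    t_a = X w_a                (scores)
    p_a = X't_a / t_a't_a      (X loadings)
    c_a = y't_a / t_a't_a      (y loading)

after which X (and y) are deflated and the next component extracted.
Model quality is summarized by the cumulative fraction of class-label
variance explained, R²Y(cum), and by its cross-validated counterpart
Q²(cum) = 1 - PRESS/SS, computed by withholding 1/7 of the samples at a
time.  Per-bucket influence is summarized by VIP scores, whose squares
average to 1 over the K buckets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import CONTROL, STUDY, ValidationError

__all__ = [
    "PlsdaModel",
    "scale_matrix",
    "encode_labels",
    "fit_plsda",
    "cross_validate_q2",
    "vip_scores",
]

_RANK_TOL = 1e-10


def encode_labels(labels) -> np.ndarray:
    """Encode group labels as +1 (study) / -1 (control)."""
    y = np.empty(len(labels), dtype=float)
    for i, g in enumerate(labels):
        if g == STUDY:
            y[i] = 1.0
        elif g == CONTROL:
            y[i] = -1.0
        else:
            raise ValidationError(f"unknown group label {g!r}")
    if not (np.any(y > 0) and np.any(y < 0)):
        raise ValidationError("both groups must be present")
    return y


def scale_matrix(X, mode: str = "uv"):
    """Column-center X and scale per ``mode``.

    ``uv`` divides by the column SD (n-1 denominator, SIMCA-style
    unit-variance scaling), ``pareto`` by its square root, ``none`` leaves
    the scale at 1.  Zero-variance columns get scale 1 with a warning.

    Returns ``(X_scaled, centers, scales)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("X must be 2-D with >= 2 rows")
    if mode not in ("none", "uv", "pareto"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    centers = X.mean(axis=0)
    if mode == "none":
        scales = np.ones(X.shape[1])
    else:
        sd = X.std(axis=0, ddof=1)
        zero = sd == 0.0
        if np.any(zero):
            warnings.warn(
                f"{int(zero.sum())} zero-variance column(s); scale set to 1",
                stacklevel=2,
            )
            sd = np.where(zero, 1.0, sd)
        scales = sd if mode == "uv" else np.sqrt(sd)
    return (X - centers) / scales, centers, scales


@dataclass
class PlsdaModel:
    """A fitted two-class PLS-DA model.

    Shapes: K buckets, n samples, A components.  Scores are mutually
    orthogonal; the mean of squared VIP scores is 1.
    """

    n_components: int
    x_weights: np.ndarray      # (K, A)
    x_loadings: np.ndarray     # (K, A)
    x_scores: np.ndarray       # (n, A)
    y_loadings: np.ndarray     # (A,)
    x_mean: np.ndarray         # (K,)
    x_scale: np.ndarray        # (K,)
    y_mean: float
    scaling: str
    r2y_per_component: np.ndarray  # (A,)
    r2y_cum: float
    vip: np.ndarray            # (K,)
    q2_cum: float | None = None
    bucket_ids: list[str] | None = None

    def coefficients(self) -> np.ndarray:
        """Regression vector B on the scaled X: yhat = ym + Xs B."""
        w, p, c = self.x_weights, self.x_loadings, self.y_loadings
        return w @ np.linalg.solve(p.T @ w, c)

    def predict(self, X) -> np.ndarray:
        """Continuous class prediction for new samples (raw bucket scale)."""
        X = np.asarray(X, dtype=float)
        xs = (X - self.x_mean) / self.x_scale
        return self.y_mean + xs @ self.coefficients()

    def transform(self, X) -> np.ndarray:
        """Project new samples onto the model's score space."""
        X = np.asarray(X, dtype=float)
        xs = (X - self.x_mean) / self.x_scale
        w, p = self.x_weights, self.x_loadings
        r = w @ np.linalg.inv(p.T @ w)
        return xs @ r

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_components": self.n_components,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "x_scores": self.x_scores.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "scaling": self.scaling,
            "r2y_per_component": self.r2y_per_component.tolist(),
            "r2y_cum": self.r2y_cum,
            "q2_cum": self.q2_cum,
            "vip": self.vip.tolist(),
            "bucket_ids": self.bucket_ids,
        }
        return d

    def to_json(self, dest=None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        if dest is not None:
            with open(dest, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PlsdaModel":
        return cls(
            n_components=int(d["n_components"]),
            x_weights=np.asarray(d["x_weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            x_scores=np.asarray(d["x_scores"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_scale=np.asarray(d["x_scale"], dtype=float),
            y_mean=float(d["y_mean"]),
            scaling=str(d["scaling"]),
            r2y_per_component=np.asarray(d["r2y_per_component"], dtype=float),
            r2y_cum=float(d["r2y_cum"]),
            vip=np.asarray(d["vip"], dtype=float),
            q2_cum=None if d.get("q2_cum") is None else float(d["q2_cum"]),
            bucket_ids=d.get("bucket_ids"),
        )


def _nipals_pls1(Xs: np.ndarray, yc: np.ndarray, n_components: int):
    """Extract components from pre-scaled X and centered y.

    Returns (W, T, P, c).  The sign of each component is fixed so that the
    largest-magnitude weight entry is positive, making fits reproducible
    bit-for-bit.
    """
    X = Xs.copy()
    y = yc.copy()
    n, k = X.shape
    W = np.empty((k, n_components))
    P = np.empty((k, n_components))
    T = np.empty((n, n_components))
    c = np.empty(n_components)
    ref = float(np.linalg.norm(Xs.T @ yc))
    if ref == 0.0:
        raise ValidationError("X carries no covariance with the class labels")
    for a in range(n_components):
        xty = X.T @ y
        norm = float(np.linalg.norm(xty))
        if norm <= _RANK_TOL * ref:
            raise ValidationError(
                f"requested {n_components} components but the matrix supports "
                f"only {a} (rank exhausted)"
            )
        w = xty / norm
        t = X @ w
        tt = float(t @ t)
        if tt <= _RANK_TOL:
            raise ValidationError(
                f"requested {n_components} components but component {a + 1} "
                "has a degenerate score vector"
            )
        p = X.T @ t / tt
        ca = float(y @ t) / tt
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, t, p, ca = -w, -t, -p, -ca
        W[:, a], T[:, a], P[:, a], c[a] = w, t, p, ca
        X = X - np.outer(t, p)
        y = y - ca * t
    return W, T, P, c


def fit_plsda(
    X,
    labels,
    n_components: int = 2,
    scaling: str = "uv",
    bucket_ids=None,
) -> PlsdaModel:
    """Fit a two-class PLS-DA model by NIPALS.

    ``labels`` holds canonical group names (``control``/``study``).  The
    default of 2 components matches the two-dimensional score plots the
    separation test operates on; unit-variance scaling is the default.
    """
    X = np.asarray(X, dtype=float)
    y = encode_labels(labels)
    if X.shape[0] != y.size:
        raise ValidationError("X rows and labels length differ")
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        raise ValidationError(
            f"n_components={n_components} exceeds the maximum rank {max_rank}"
        )
    xs, centers, scales = scale_matrix(X, scaling)
    y_mean = float(y.mean())
    yc = y - y_mean
    ssy = float(yc @ yc)
    W, T, P, c = _nipals_pls1(xs, yc, n_components)
    ss_component = c**2 * np.einsum("na,na->a", T, T)
    r2y_per = ss_component / ssy
    model = PlsdaModel(
        n_components=n_components,
        x_weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=c,
        x_mean=centers,
        x_scale=scales,
        y_mean=y_mean,
        scaling=scaling,
        r2y_per_component=r2y_per,
        r2y_cum=float(r2y_per.sum()),
        vip=np.empty(X.shape[1]),
        bucket_ids=list(bucket_ids) if bucket_ids is not None else None,
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PlsdaModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_k = sqrt( K * sum_a SS_a (w_ak/||w_a||)^2 / sum_a SS_a ), where
    SS_a = c_a^2 t_a't_a is the label variance captured by component a.
    The mean of squared VIPs equals 1 exactly.
    """
    W = model.x_weights
    k = W.shape[0]
    ss = model.y_loadings**2 * np.einsum("na,na->a", model.x_scores, model.x_scores)
    wnorm2 = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(k * (wnorm2 @ ss) / ss.sum())


def _interleaved_folds(labels, n_folds: int) -> np.ndarray:
    """Deterministic venetian-blind fold assignment, balanced per class."""
    labels = list(labels)
    folds = np.empty(len(labels), dtype=int)
    for group in sorted(set(labels)):
        idx = [i for i, g in enumerate(labels) if g == group]
        if len(idx) < 2:
            raise ValidationError(
                f"group {group!r} has {len(idx)} sample(s); need >= 2 for "
                "cross-validation"
            )
        for pos, i in enumerate(idx):
            folds[i] = pos % n_folds
    return folds


def cross_validate_q2(
    X,
    labels,
    n_components: int = 2,
    n_folds: int = 7,
    scaling: str = "uv",
) -> float:
    """Cumulative Q² by repeatedly withholding 1/``n_folds`` of the samples.

    Folds are assigned deterministically by interleaving within each class
    (venetian blinds), which keeps classes balanced across folds without
    any randomness.  Centering and scaling are re-estimated on each
    training split so no information leaks from held-out samples.

    Q²(cum) = 1 - PRESS / SS, with PRESS the summed squared prediction
    errors of held-out class labels and SS the total (centered) label sum
    of squares.
    """
    X = np.asarray(X, dtype=float)
    y = encode_labels(labels)
    n = y.size
    if n < n_folds:
        raise ValidationError(f"need >= {n_folds} samples for {n_folds}-fold CV")
    folds = _interleaved_folds(labels, n_folds)
    press = 0.0
    for f in range(n_folds):
        test = folds == f
        if not np.any(test):
            continue
        train = ~test
        model = fit_plsda(
            X[train],
            [labels[i] for i in np.flatnonzero(train)],
            n_components=n_components,
            scaling=scaling,
        )
        yhat = model.predict(X[test])
        press += float(np.sum((y[test] - yhat) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss
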