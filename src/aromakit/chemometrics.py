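"""Multivariate chemometrics for replicate-level concentration matrices.

The supervised workflow is classical metabolomics discriminant analysis:

* preprocessing -- minimum-based imputation, probabilistic-quotient
  normalization against a designated reference sample, Pareto scaling
  ((x - mean) / sqrt(sd), a compromise between unit variance and no
  scaling that keeps large fold-changes influential without letting the
  most abundant compounds dominate);
* unsupervised views -- Spearman rank correlation between samples and
  principal coordinate analysis (Gower double-centering of a squared
  distance matrix followed by eigendecomposition);
* supervised models -- PLS-DA fitted by NIPALS with sequential deflation
  on a centered one-hot class matrix, and two-class OPLS-DA in which
  class-orthogonal variation is stripped from X before a single
  predictive component is fitted;
* model assessment -- R2 on the full fit, Q2 from stratified k-fold
  cross-validation, a label-permutation test with the add-one p-value
  estimator, and VIP scores

      VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )

  where SS_a is the Y sum of squares explained by component a; variables
  with VIP > 1 are the discriminant markers.

Rows are sample replicates throughout; replicates are never averaged
before modeling. Each transformation appends a tag to the frame's
``attrs["provenance"]`` list.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .errors import (ConfigurationError, ConvergenceError, ModelError,
                     StratificationError, ValidationError)

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 1000


def _tagged(frame: pd.DataFrame, parent: pd.DataFrame | None, tag: str) -> pd.DataFrame:
    prov = list(parent.attrs.get("provenance", [])) if parent is not None else []
    frame.attrs["provenance"] = prov + [tag]
    return frame


def replicate_matrix(records: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Pivot long concentration records to a replicates x compounds matrix."""
    wide = records.pivot_table(index="sample_id", columns="compound_id",
                               values="concentration", aggfunc="mean")
    wide = wide.reindex(meta["sample_id"])
    wide.columns.name = None
    return _tagged(wide, None, "replicate_matrix")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def impute_missing(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Replace missing cells by 1/5 of the column's minimum positive value.

    Columns with no observed value at all cannot be imputed; they are
    dropped and returned in the report list.
    """
    dropped = [c for c in matrix.columns if matrix[c].notna().sum() == 0]
    out = matrix.drop(columns=dropped)
    mins = out.where(out > 0).min(axis=0)
    fill = mins / 5.0
    out = out.fillna(fill)
    if out.isna().any().any():
        bad = [c for c in out.columns if out[c].isna().any()]
        raise ValidationError(f"columns without a positive minimum: {bad}")
    return _tagged(out, matrix, "impute_min5"), dropped


def normalize_to_reference(matrix: pd.DataFrame, reference_sample: str) -> pd.DataFrame:
    """Probabilistic-quotient normalization against one reference replicate.

    Each row is divided by the median of its element-wise quotients
    against the reference row, removing sample-to-sample dilution-style
    scale differences. The reference row itself is unchanged (its median
    quotient is 1).
    """
    if reference_sample not in matrix.index:
        raise ConfigurationError(
            f"reference sample {reference_sample!r} not in matrix rows")
    ref = matrix.loc[reference_sample]
    if (ref == 0).any() or ref.isna().any():
        raise ValidationError("reference row has zeros or missing values")
    factors = matrix.div(ref, axis=1).median(axis=1)
    out = matrix.div(factors, axis=0)
    return _tagged(out, matrix, f"pqn_reference={reference_sample}")


def pareto_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each column and divide by the square root of its SD.

    Constant columns carry no information at any scaling; they are set to
    0 and listed in ``attrs["constant_columns"]``.
    """
    if len(matrix) < 2:
        raise ValidationError("Pareto scaling needs at least two rows")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    constant = list(matrix.columns[sd == 0])
    scale = np.sqrt(sd.where(sd > 0, 1.0))
    out = (matrix - mean) / scale
    out[constant] = 0.0
    out = _tagged(out, matrix, "pareto_scale")
    out.attrs["constant_columns"] = constant
    return out


# ---------------------------------------------------------------------------
# unsupervised views
# ---------------------------------------------------------------------------

def spearman_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Spearman rank correlations (average ranks for ties)."""
    if matrix.shape[1] < 3:
        raise ValidationError("Spearman needs at least three compounds")
    ranks = np.apply_along_axis(rankdata, 1, matrix.to_numpy())
    rho = np.corrcoef(ranks)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=matrix.index, columns=matrix.index)


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a sample distance matrix."""
    eigenvalues: np.ndarray            # descending, positive axes only
    coordinates: pd.DataFrame          # samples x kept axes
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray   # reported, their axes are dropped
    metric: str


def pcoa(matrix: pd.DataFrame, metric: str = "braycurtis") -> PcoaResult:
    """Classical multidimensional scaling on the chosen distance metric.

    Gower-centers the squared distance matrix, B = -1/2 J D^2 J, and keeps
    the eigenvectors with positive eigenvalues scaled by sqrt(eigenvalue),
    so Euclidean distances among coordinates reproduce the input distances
    whenever those are Euclidean-embeddable. Non-embeddable metrics (e.g.
    Bray-Curtis) can produce negative eigenvalues; these are reported and
    their axes dropped.
    """
    if len(matrix) < 3:
        raise ValidationError("PCoA needs at least three samples")
    try:
        dist = pdist(matrix.to_numpy(float), metric=metric)
    except ValueError as exc:
        raise ConfigurationError(f"unknown distance metric {metric!r}") from exc
    d2 = squareform(dist) ** 2
    n = len(d2)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval).max(), 1.0) * 1e-12
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    axes = [f"PCo{i + 1}" for i in range(pos.sum())]
    return PcoaResult(
        eigenvalues=eigval[pos],
        coordinates=pd.DataFrame(coords, index=matrix.index, columns=axes),
        proportion_explained=eigval[pos] / eigval[pos].sum(),
        negative_eigenvalues=eigval[eigval < -tol],
        metric=metric,
    )


# ---------------------------------------------------------------------------
# latent-variable models
# ---------------------------------------------------------------------------

@dataclass
class LatentModel:
    """A fitted PLS-DA or OPLS-DA model in NIPALS parametrization.

    Weights ``w`` (unit norm), loadings ``p``, scores ``t`` and Y-loadings
    ``q`` are stored column-per-component; ``ss`` is the Y sum of squares
    explained by each predictive component (the VIP weights). OPLS-DA
    additionally stores the class-orthogonal triplets ``w_ortho`` /
    ``p_ortho`` / ``t_ortho`` that were stripped before the single
    predictive component was fitted.
    """
    kind: str
    classes: list
    feature_names: list
    x_mean: np.ndarray
    y_mean: np.ndarray
    w: np.ndarray
    p: np.ndarray
    t: np.ndarray
    q: np.ndarray
    ss: np.ndarray
    w_ortho: np.ndarray | None = None
    p_ortho: np.ndarray | None = None
    t_ortho: np.ndarray | None = None

    @property
    def n_predictive(self) -> int:
        return self.w.shape[1]

    @property
    def n_orthogonal(self) -> int:
        return 0 if self.w_ortho is None else self.w_ortho.shape[1]

    def _filter(self, xc: np.ndarray) -> np.ndarray:
        for a in range(self.n_orthogonal):
            w_o = self.w_ortho[:, a]
            t_o = xc @ w_o
            xc = xc - np.outer(t_o, self.p_ortho[:, a])
        return xc

    def predict_y(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predicted (possibly multi-column) class indicator values."""
        xv = x.to_numpy(float) if isinstance(x, pd.DataFrame) else np.asarray(x, float)
        xc = self._filter(xv - self.x_mean)
        # regression form of sequential NIPALS: B = W (P'W)^-1 Q'
        pw = self.p.T @ self.w
        beta = self.w @ np.linalg.solve(pw, self.q.T)
        return xc @ beta + self.y_mean

    def predict_classes(self, x) -> np.ndarray:
        yhat = self.predict_y(x)
        if yhat.shape[1] == 1:  # two-class indicator column
            return np.array([self.classes[int(v >= 0.5)] for v in yhat[:, 0]])
        return np.array([self.classes[i] for i in yhat.argmax(axis=1)])

    def scores_frame(self, index=None) -> pd.DataFrame:
        cols = [f"t{a + 1}" for a in range(self.n_predictive)]
        frame = pd.DataFrame(self.t, columns=cols, index=index)
        for a in range(self.n_orthogonal):
            frame[f"to{a + 1}"] = self.t_ortho[:, a]
        return frame


@dataclass
class ModelSpec:
    """How to fit the supervised model in validation loops."""
    kind: str = "plsda"
    n_components: int = 2
    n_orthogonal: int = 1

    def fit(self, x: pd.DataFrame, y) -> LatentModel:
        if self.kind == "plsda":
            return fit_plsda(x, y, n_components=self.n_components)
        if self.kind == "oplsda":
            return fit_oplsda(x, y, n_orthogonal=self.n_orthogonal)
        raise ConfigurationError(f"unknown model kind {self.kind!r}")


def _one_hot(y) -> tuple[np.ndarray, list]:
    y = np.asarray(y)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) < 2:
        raise ModelError("need at least two classes")
    hot = np.zeros((len(y), len(classes)))
    for j, c in enumerate(classes):
        hot[y == c, j] = 1.0
    return hot, classes


def _sign_fix(w: np.ndarray) -> float:
    """Sign so the largest-magnitude weight is positive (reproducible plots)."""
    return 1.0 if w[np.argmax(np.abs(w))] >= 0 else -1.0


def _nipals_component(xr: np.ndarray, yr: np.ndarray) -> tuple:
    """One NIPALS PLS2 component on residual matrices (both centered)."""
    u = yr[:, int(np.argmax(yr.var(axis=0)))].copy()
    if not np.any(u):
        u = yr[:, 0] + 1e-12
    t_old = None
    for _ in range(_NIPALS_MAX_ITER):
        w = xr.T @ u / (u @ u)
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ModelError("X residual carries no covariance with Y")
        w /= norm
        t = xr @ w
        tt = t @ t
        if tt == 0:
            raise ModelError("degenerate score vector (X residual is zero)")
        q = yr.T @ t / tt
        qq = q @ q
        if qq == 0:
            raise ModelError("Y residual carries no covariance with X")
        u = yr @ q / qq
        if t_old is not None and np.linalg.norm(t - t_old) <= _NIPALS_TOL * np.linalg.norm(t):
            break
        t_old = t
    else:
        raise ConvergenceError(
            f"NIPALS did not converge in {_NIPALS_MAX_ITER} iterations")
    sign = _sign_fix(w)
    w, t, q = sign * w, sign * t, sign * q
    p = xr.T @ t / (t @ t)
    return w, t, p, q


def fit_plsda(x: pd.DataFrame, y, n_components: int = 2) -> LatentModel:
    """NIPALS PLS-DA on a centered one-hot class matrix.

    Components are extracted sequentially with deflation of both X and Y;
    score vectors are mutually orthogonal. ``n_components`` may not exceed
    min(rows - 1, columns).
    """
    xv = x.to_numpy(float)
    hot, classes = _one_hot(y)
    cap = min(xv.shape[0] - 1, xv.shape[1])
    if not 1 <= n_components <= cap:
        raise ModelError(f"n_components must be in [1, {cap}], got {n_components}")
    x_mean = xv.mean(axis=0)
    y_mean = hot.mean(axis=0)
    xr = xv - x_mean
    yr = hot - y_mean

    ws, ts, ps, qs, ss = [], [], [], [], []
    for _ in range(n_components):
        w, t, p, q = _nipals_component(xr, yr)
        xr = xr - np.outer(t, p)
        yr = yr - np.outer(t, q)
        ws.append(w); ts.append(t); ps.append(p); qs.append(q)
        ss.append((t @ t) * (q @ q))
    return LatentModel(
        kind="plsda", classes=classes, feature_names=list(x.columns),
        x_mean=x_mean, y_mean=y_mean,
        w=np.column_stack(ws), p=np.column_stack(ps),
        t=np.column_stack(ts), q=np.column_stack(qs), ss=np.array(ss),
    )


def fit_oplsda(x: pd.DataFrame, y, n_orthogonal: int = 1) -> LatentModel:
    """Two-class OPLS-DA: strip class-orthogonal variation, then one
    predictive component.

    Each orthogonal component is the part of the X loading orthogonal to
    the class-covariance weight vector (Trygg-Wold orthogonal projection
    to latent structures); its scores are uncorrelated with the class
    vector by construction. With ``n_orthogonal=0`` this reduces to a
    1-component PLS-DA.
    """
    xv = x.to_numpy(float)
    hot, classes = _one_hot(y)
    if len(classes) != 2:
        raise ModelError(
            "OPLS-DA is defined for exactly two classes; use PLS-DA for more")
    if n_orthogonal < 0:
        raise ModelError("n_orthogonal must be >= 0")
    yvec = hot[:, 1]
    y_mean = yvec.mean()
    x_mean = xv.mean(axis=0)
    xr = xv - x_mean
    yc = yvec - y_mean

    w = xr.T @ yc / (yc @ yc)
    w /= np.linalg.norm(w)
    w_os, p_os, t_os = [], [], []
    for _ in range(n_orthogonal):
        t = xr @ w
        p = xr.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal structure left
        w_o /= norm
        sign = _sign_fix(w_o)
        w_o *= sign
        t_o = xr @ w_o
        p_o = xr.T @ t_o / (t_o @ t_o)
        xr = xr - np.outer(t_o, p_o)
        w_os.append(w_o); p_os.append(p_o); t_os.append(t_o)

    # single predictive component on the filtered X
    w, t, p, q = _nipals_component(xr, yc[:, None])
    ortho = len(w_os) > 0
    return LatentModel(
        kind="oplsda", classes=classes, feature_names=list(x.columns),
        x_mean=x_mean, y_mean=np.array([y_mean]),
        w=w[:, None], p=p[:, None], t=t[:, None], q=np.array([[q[0]]]),
        ss=np.array([(t @ t) * (q @ q)]),
        w_ortho=np.column_stack(w_os) if ortho else None,
        p_ortho=np.column_stack(p_os) if ortho else None,
        t_ortho=np.column_stack(t_os) if ortho else None,
    )


def compute_vip(model: LatentModel) -> pd.Series:
    """Variable importance in projection over the predictive components.

    Normalized so that the mean squared VIP is 1 (sum VIP^2 = number of
    variables); for OPLS-DA only the predictive component contributes.
    """
    if model.n_predictive < 1:
        raise ModelError("model has no predictive component")
    w = model.w / np.linalg.norm(model.w, axis=0, keepdims=True)
    ss = model.ss
    p = w.shape[0]
    vip = np.sqrt(p * (w ** 2 @ ss) / ss.sum())
    return pd.Series(vip, index=model.feature_names, name="vip")


def select_discriminants(vip: pd.Series, cutoff: float = 1.0) -> pd.Series:
    """Variables with VIP strictly above the cutoff, ranked descending."""
    return vip[vip > cutoff].sort_values(ascending=False, kind="mergesort")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Fit and predictivity metrics of a supervised model."""
    r2: float
    q2: float
    folds: int
    permutation_p: float | None = None
    n_permutations: int = 0
    permuted_q2: np.ndarray | None = field(default=None, repr=False)


def _fold_indices(y: np.ndarray, folds: int, seed: int):
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(len(y)), y))


def cross_validate(x: pd.DataFrame, y, model_spec: ModelSpec,
                   folds: int = 5, seed: int = 0) -> ValidationReport:
    """R2 on the full fit and Q2 from stratified k-fold cross-validation.

    R2 = 1 - RSS/TSS on the one-hot class matrix; Q2 = 1 - PRESS/TSS with
    PRESS accumulated over held-out folds (the held-out TSS uses the
    training fold's class means). Deterministic for a given seed.
    """
    if folds < 2:
        raise ValidationError("need at least 2 folds")
    y = np.asarray(y)
    hot, classes = _one_hot(y)
    model = model_spec.fit(x, y)
    target = hot[:, 1:2] if model.kind == "oplsda" else hot
    resid = target - model.predict_y(x)
    tss_full = ((target - target.mean(axis=0)) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / tss_full

    press = 0.0
    tss = 0.0
    for train, test in _fold_indices(y, folds, seed):
        if len(np.unique(y[train])) < len(classes):
            raise StratificationError("a training fold lost a class")
        sub = model_spec.fit(x.iloc[train], y[train])
        yhat = sub.predict_y(x.iloc[test])
        press += ((target[test] - yhat) ** 2).sum()
        tss += ((target[test] - target[train].mean(axis=0)) ** 2).sum()
    q2 = 1.0 - press / tss
    return ValidationReport(r2=float(r2), q2=float(q2), folds=folds)


def permutation_test(x: pd.DataFrame, y, model_spec: ModelSpec,
                     n_permutations: int = 100, folds: int = 5,
                     seed: int = 0) -> ValidationReport:
    """Label-permutation test on Q2.

    p = (1 + #{permuted Q2 >= observed Q2}) / (1 + B), so p is never below
    1/(B+1). Only y is shuffled; folds are re-stratified per permutation.
    """
    if n_permutations < 1:
        raise ValidationError("need at least one permutation")
    y = np.asarray(y)
    if len(pd.unique(y)) < 2:
        # a constant class vector is invariant under permutation
        return ValidationReport(r2=float("nan"), q2=float("nan"), folds=folds,
                                permutation_p=1.0, n_permutations=n_permutations)
    report = cross_validate(x, y, model_spec, folds=folds, seed=seed)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_permutations)
    for b in range(n_permutations):
        y_perm = rng.permutation(y)
        while np.array_equal(y_perm, y):
            # the observed labeling is already counted by the +1 of the
            # add-one estimator; drawing it again would double-count it
            y_perm = rng.permutation(y)
        try:
            permuted[b] = cross_validate(x, y_perm, model_spec,
                                         folds=folds, seed=seed).q2
        except (ModelError, StratificationError):
            permuted[b] = -np.inf
    exceed = int((permuted >= report.q2).sum())
    p = (1 + exceed) / (1 + n_permutations)
    return ValidationReport(r2=report.r2, q2=report.q2, folds=folds,
                            permutation_p=p, n_permutations=n_permutations,
                            permuted_q2=permuted)


def choose_n_components(x: pd.DataFrame, y, max_components: int = 5,
                        folds: int = 5, seed: int = 0) -> int:
    """Smallest component count maximizing Q2 over 1..max_components."""
    y = np.asarray(y)
    cap = min(max_components, len(x) - 1, x.shape[1])
    best_a, best_q2 = 1, -np.inf
    for a in range(1, cap + 1):
        try:
            q2 = cross_validate(x, y, ModelSpec("plsda", n_components=a),
                                folds=folds, seed=seed).q2
        except ModelError:
            break  # Y residual exhausted; richer models are unfittable
        if q2 > best_q2 + 1e-12:
            best_a, best_q2 = a, q2
    return best_a
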