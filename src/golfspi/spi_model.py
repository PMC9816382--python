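"""The Swing Performance Index model.

For a chosen subset of one to three rotational metrics the index is built
in five stages, each parameterised by the professional cohort only:

1. **Normalisation** — each metric is z-scored with the pro group's mean
   and population SD.
2. **Class balancing** — the amateur (minority) group is oversampled in
   the normalised subset space: a random amateur row and its single
   nearest neighbour (Euclidean) are joined by a uniformly random point on
   the connecting segment, repeated until group counts are equal.
3. **PCA** — principal axes are the eigenvectors of the pro covariance
   (population convention); all components are kept and every swing is
   projected onto them.
4. **Log distance** — each swing's Euclidean distance ``d`` to the mean
   pro PC vector is taken, then ``l = ln(max(d, epsilon))``.
5. **Scaling** — ``SPI = 100 - 10 * (l - mu_l) / sigma_l`` with ``mu_l``
   and ``sigma_l`` the pro population mean/SD of ``l``.  Pro swings score
   100 +/- 10 by construction; a swing further from the pro centroid
   scores lower.

Also provided here: the Kaiser-Meyer-Olkin measure of sampling adequacy
used to screen metric subsets for factorability, and lossless YAML
persistence of fitted models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .swing_metrics import METRIC_ORDER, MetricName, MetricVector

MODEL_SCHEMA = "spi-model/1"

#: Distance floor keeping ln finite for a swing at the pro centroid.
DEFAULT_EPSILON = 1e-6


class SPIModelError(ValueError):
    pass


@dataclass
class LabeledDataset:
    """Rows of swing feature vectors with pro/amateur labels.

    ``X`` may hold raw metric values (columns ordered as ``metric_names``)
    or, for fixtures, precomputed principal components.  ``synthetic``
    flags oversampled rows.
    """

    X: np.ndarray  # (n_rows, n_features)
    groups: np.ndarray  # (n_rows,) of {"pro", "amateur"}
    subject_ids: np.ndarray
    swing_ids: np.ndarray
    synthetic: np.ndarray  # (n_rows,) bool
    metric_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.groups = np.asarray(self.groups)
        self.subject_ids = np.asarray(self.subject_ids)
        self.swing_ids = np.asarray(self.swing_ids)
        self.synthetic = np.asarray(self.synthetic, dtype=bool)
        n = self.X.shape[0]
        for name, arr in (
            ("groups", self.groups),
            ("subject_ids", self.subject_ids),
            ("swing_ids", self.swing_ids),
            ("synthetic", self.synthetic),
        ):
            if arr.shape != (n,):
                raise SPIModelError(f"{name} length {arr.shape} != n_rows {n}")

    @classmethod
    def from_metric_vectors(cls, vectors: Sequence[MetricVector]) -> "LabeledDataset":
        X = np.array([mv.as_array() for mv in vectors])
        return cls(
            X=X,
            groups=np.array([mv.group for mv in vectors]),
            subject_ids=np.array([mv.subject_id for mv in vectors]),
            swing_ids=np.array([mv.swing_id for mv in vectors]),
            synthetic=np.zeros(len(vectors), dtype=bool),
            metric_names=tuple(m.value for m in METRIC_ORDER),
        )

    def select(self, subset: Sequence[MetricName | str]) -> "LabeledDataset":
        """Restrict columns to a metric subset (by name)."""
        names = [m.value if isinstance(m, MetricName) else m for m in subset]
        idx = [self.metric_names.index(n) for n in names]
        return replace(self, X=self.X[:, idx], metric_names=tuple(names))

    @property
    def is_pro(self) -> np.ndarray:
        return self.groups == "pro"


@dataclass
class SPIModel:
    """Fitted SPI artifact: everything needed to score a new swing."""

    subset: tuple[str, ...]
    pro_mean: np.ndarray  # per metric, deg/s
    pro_sd: np.ndarray  # per metric, deg/s (population)
    pca_components: np.ndarray  # (k, k), rows = components
    pro_pc_center: np.ndarray  # (k,)
    log_dist_mean: float
    log_dist_sd: float
    epsilon: float = DEFAULT_EPSILON
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pro_mean = np.asarray(self.pro_mean, dtype=float)
        self.pro_sd = np.asarray(self.pro_sd, dtype=float)
        self.pca_components = np.asarray(self.pca_components, dtype=float)
        self.pro_pc_center = np.asarray(self.pro_pc_center, dtype=float)
        if np.any(self.pro_sd <= 0):
            bad = [self.subset[i] for i in np.flatnonzero(self.pro_sd <= 0)]
            raise SPIModelError(f"non-positive pro SD for metrics: {bad}")
        if not self.log_dist_sd > 0:
            raise SPIModelError("log-distance SD must be positive")
        k = len(self.subset)
        gram = self.pca_components @ self.pca_components.T
        if not np.allclose(gram, np.eye(k), atol=1e-10):
            raise SPIModelError("pca_components not orthonormal")

    @classmethod
    def from_pc_scaling(
        cls,
        pro_pcs: np.ndarray,
        center: np.ndarray | None = None,
        epsilon: float = DEFAULT_EPSILON,
    ) -> "SPIModel":
        """Scaling-only model for rows that are already principal components.

        Fits the log-distance scaling on the given pro PC vectors;
        normalisation and PCA become identity stages.  ``center`` defaults
        to the zero vector (PC fixtures are centred by construction).
        """
        pro_pcs = np.asarray(pro_pcs, dtype=float)
        k = pro_pcs.shape[1]
        if center is None:
            center = np.zeros(k)
        center, mu, sd = fit_log_distance_scaling(pro_pcs, center=center, epsilon=epsilon)
        return cls(
            subset=tuple(f"pc{i + 1}" for i in range(k)),
            pro_mean=np.zeros(k),
            pro_sd=np.ones(k),
            pca_components=np.eye(k),
            pro_pc_center=center,
            log_dist_mean=mu,
            log_dist_sd=sd,
            epsilon=epsilon,
        )


# ---------------------------------------------------------------------------
# Stage 1: normalisation
# ---------------------------------------------------------------------------

def pro_stats(X: np.ndarray, is_pro: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pro-group per-column mean and population SD; zero spread is an error."""
    pro = X[is_pro]
    if pro.shape[0] < 2:
        raise SPIModelError("need at least 2 pro rows to estimate spread")
    mean = pro.mean(axis=0)
    sd = pro.std(axis=0)  # population convention
    if np.any(sd == 0):
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise SPIModelError(f"zero pro variance in metric(s): {bad}")
    return mean, sd


def normalize(X: np.ndarray, pro_mean: np.ndarray, pro_sd: np.ndarray) -> np.ndarray:
    """z = (x - pro_mean) / pro_sd, columnwise."""
    return (np.asarray(X, dtype=float) - pro_mean) / pro_sd


# ---------------------------------------------------------------------------
# Kaiser-Meyer-Olkin sampling adequacy
# ---------------------------------------------------------------------------

def kmo(data: np.ndarray) -> tuple[float, np.ndarray]:
    """KMO measure of sampling adequacy: (overall, per-variable).

    From the correlation matrix R and the anti-image partial correlations
    A (``a_ij = -Rinv_ij / sqrt(Rinv_ii * Rinv_jj)``):

        KMO_j = sum_{i!=j} r_ij^2 / (sum r_ij^2 + sum a_ij^2)

    and the overall value sums over all off-diagonal pairs.  Values lie in
    [0, 1]; higher means more shared variance, hence better factorability.
    Scale-invariant by construction.  A singular correlation matrix falls
    back to the pseudo-inverse with a warning, as does having fewer rows
    than variables.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if p < 2:
        raise SPIModelError("KMO needs at least 2 variables")
    if np.any(X.std(axis=0) == 0):
        raise SPIModelError("KMO undefined for a constant column")
    if n < p:
        warnings.warn("fewer rows than variables: correlation matrix is singular")
    R = np.corrcoef(X, rowvar=False)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix; using pseudo-inverse")
        Rinv = np.linalg.pinv(R)
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    A = -Rinv / d
    off = ~np.eye(p, dtype=bool)
    r2 = np.where(off, R**2, 0.0)
    a2 = np.where(off, A**2, 0.0)
    per_var = r2.sum(axis=1) / (r2.sum(axis=1) + a2.sum(axis=1))
    overall = r2.sum() / (r2.sum() + a2.sum())
    return float(overall), per_var


# ---------------------------------------------------------------------------
# Stage 2: minority oversampling (single-nearest-neighbour SMOTE)
# ---------------------------------------------------------------------------

def smote_balance(ds: LabeledDataset, seed: int | np.random.Generator) -> LabeledDataset:
    """Oversample the minority group until group counts are equal.

    Each synthetic row is ``p + u * (q - p)`` where ``p`` is a randomly
    chosen *original* minority row, ``q`` is its single nearest neighbour
    (Euclidean) among the other original minority rows, and
    ``u ~ Uniform(0, 1)``.  Deterministic given the seed.  Already-equal
    groups are returned unchanged; a minority of one row is an error.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = {g: int((ds.groups == g).sum()) for g in ("pro", "amateur")}
    if counts["pro"] == 0 or counts["amateur"] == 0:
        raise SPIModelError("both groups must be nonempty")
    if counts["pro"] == counts["amateur"]:
        return ds
    minority = min(counts, key=counts.get)
    deficit = abs(counts["pro"] - counts["amateur"])
    orig_idx = np.flatnonzero((ds.groups == minority) & ~ds.synthetic)
    if orig_idx.size < 2:
        raise SPIModelError("minority group needs at least 2 original rows for SMOTE")
    P = ds.X[orig_idx]
    # nearest original neighbour of each original minority row
    d2 = ((P[:, None, :] - P[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn = d2.argmin(axis=1)
    new_rows = []
    for i in range(deficit):
        j = rng.integers(len(orig_idx))
        u = rng.uniform()
        new_rows.append(P[j] + u * (P[nn[j]] - P[j]))
    m = len(new_rows)
    return LabeledDataset(
        X=np.vstack([ds.X, np.array(new_rows)]),
        groups=np.concatenate([ds.groups, [minority] * m]),
        subject_ids=np.concatenate([ds.subject_ids, ["synthetic"] * m]),
        swing_ids=np.concatenate([ds.swing_ids, [f"smote_{i}" for i in range(m)]]),
        synthetic=np.concatenate([ds.synthetic, np.ones(m, dtype=bool)]),
        metric_names=ds.metric_names,
    )


# ---------------------------------------------------------------------------
# Stage 3: PCA on the professional rows
# ---------------------------------------------------------------------------

def fit_pca_on_pros(z_pro: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal axes of the pro z-matrix: (components, eigenvalues, center).

    Eigen-decomposition of the population covariance; all components kept,
    ordered by decreasing eigenvalue; each component's sign fixed so its
    largest-|loading| entry is positive (backend-independent).  Returns
    the component matrix (rows = components), the eigenvalues, and the
    pro mean in PC space (analytically zero; stored as computed).
    """
    Z = np.asarray(z_pro, dtype=float)
    if Z.shape[0] < 2:
        raise SPIModelError("PCA needs at least 2 pro rows")
    Zc = Z - Z.mean(axis=0)
    cov = (Zc.T @ Zc) / Z.shape[0]  # population convention
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    W = evecs[:, order].T  # rows = components
    for r in range(W.shape[0]):
        a = np.abs(W[r])
        # tolerant tie-break: first entry within 1e-9 of the max magnitude,
        # so exact |loading| ties cannot flip the convention between fits
        j = int(np.flatnonzero(a >= a.max() - 1e-9)[0])
        if W[r, j] < 0:
            W[r] = -W[r]
    if np.any(evals < 1e-12):
        warnings.warn("rank-deficient pro covariance: some eigenvalues are ~0")
    center = (Z @ W.T).mean(axis=0)
    return W, evals, center


def pc_transform(z: np.ndarray, components: np.ndarray) -> np.ndarray:
    """Project z-scored rows onto the principal axes."""
    return np.asarray(z, dtype=float) @ components.T


# ---------------------------------------------------------------------------
# Stages 4-5: log distance and scaling
# ---------------------------------------------------------------------------

def log_distance(pcs: np.ndarray, center: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """ln of the Euclidean distance to the pro centroid, floored at epsilon."""
    pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
    d = np.linalg.norm(pcs - center, axis=1)
    return np.log(np.maximum(d, epsilon))


def fit_log_distance_scaling(
    pro_pcs: np.ndarray,
    center: np.ndarray | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[np.ndarray, float, float]:
    """Fit the scaling stage on pro PC vectors: (center, mu_l, sigma_l).

    ``center`` defaults to the mean pro PC vector — pass the zero vector
    to score fixture PCs that are already centred.  ``sigma_l`` uses the
    population convention; zero spread is an error.
    """
    pro_pcs = np.asarray(pro_pcs, dtype=float)
    if center is None:
        center = pro_pcs.mean(axis=0)
    ell = log_distance(pro_pcs, center, epsilon)
    mu, sd = float(ell.mean()), float(ell.std())
    if sd == 0:
        raise SPIModelError("pro log-distances have zero spread; cannot scale")
    return np.asarray(center, dtype=float), mu, sd


def spi_score(pcs: np.ndarray, model: SPIModel) -> np.ndarray:
    """SPI of PC vectors: 100 - 10 * (ln d - mu_l) / sigma_l.

    Larger distance from the pro centroid gives a lower score; the floor
    at ``epsilon`` caps the score for swings at the centroid itself.
    """
    ell = log_distance(pcs, model.pro_pc_center, model.epsilon)
    return 100.0 - 10.0 * (ell - model.log_dist_mean) / model.log_dist_sd


def score_metrics(model: SPIModel, X: np.ndarray, metric_names: Sequence[str]) -> np.ndarray:
    """Score raw metric rows through the full fitted pipeline."""
    idx = [list(metric_names).index(n) for n in model.subset]
    z = normalize(np.asarray(X, dtype=float)[:, idx], model.pro_mean, model.pro_sd)
    return spi_score(pc_transform(z, model.pca_components), model)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def fit_spi_model(
    ds: LabeledDataset,
    subset: Sequence[MetricName | str],
    seed: int | np.random.Generator,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[SPIModel, LabeledDataset, np.ndarray]:
    """Fit the SPI on a labelled dataset for one metric subset.

    Pipeline order: pro-normalise the subset columns; SMOTE-balance the
    minority group in that normalised space; fit PCA on the pro rows;
    project every row (original and synthetic); fit the log-distance
    scaling on the pro rows; score everything.  Returns the model, the
    balanced dataset (metric-space columns, synthetic rows appended) and
    the per-row SPI scores aligned with that dataset.

    Pro scores have mean 100 and population SD 10 exactly, by construction.
    """
    if not 1 <= len(list(subset)) <= 3:
        raise SPIModelError("subset must contain 1 to 3 metrics")
    sub = ds.select(subset) if ds.metric_names else ds
    names = list(sub.metric_names) if sub.metric_names else [str(s) for s in subset]

    mean, sd = pro_stats(sub.X, sub.is_pro, names)
    z_ds = replace(sub, X=normalize(sub.X, mean, sd))
    balanced = smote_balance(z_ds, seed)
    W, evals, center = fit_pca_on_pros(balanced.X[balanced.is_pro & ~balanced.synthetic])
    pcs = pc_transform(balanced.X, W)
    pro_orig = balanced.is_pro & ~balanced.synthetic
    _, mu, sigma = fit_log_distance_scaling(pcs[pro_orig], center=center, epsilon=epsilon)
    model = SPIModel(
        subset=tuple(names),
        pro_mean=mean,
        pro_sd=sd,
        pca_components=W,
        pro_pc_center=center,
        log_dist_mean=mu,
        log_dist_sd=sigma,
        epsilon=epsilon,
        provenance={
            "seed": int(seed) if not isinstance(seed, np.random.Generator) else None,
            "n_pro": int(pro_orig.sum()),
            "n_amateur_original": int((~balanced.is_pro & ~balanced.synthetic).sum()),
            "n_synthetic": int(balanced.synthetic.sum()),
            "pca_eigenvalues": [float(v) for v in evals],
        },
    )
    scores = spi_score(pcs, model)
    # hand back the balanced dataset in original metric units for reference
    metric_space = replace(balanced, X=balanced.X * sd + mean)
    return model, metric_space, scores


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: SPIModel, path: str | Path) -> None:
    """Write a fitted model as schema-versioned YAML (lossless)."""
    doc = {
        "schema": MODEL_SCHEMA,
        "subset": list(model.subset),
        "pro_mean": [float(v) for v in model.pro_mean],
        "pro_sd": [float(v) for v in model.pro_sd],
        "pca_components": [[float(v) for v in row] for row in model.pca_components],
        "pro_pc_center": [float(v) for v in model.pro_pc_center],
        "log_dist_mean": float(model.log_dist_mean),
        "log_dist_sd": float(model.log_dist_sd),
        "epsilon": float(model.epsilon),
        "provenance": model.provenance,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


_MODEL_FIELDS = {
    "schema", "subset", "pro_mean", "pro_sd", "pca_components",
    "pro_pc_center", "log_dist_mean", "log_dist_sd", "epsilon", "provenance",
}


def load_model(path: str | Path) -> SPIModel:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or doc.get("schema") != MODEL_SCHEMA:
        raise SPIModelError(
            f"unsupported model schema {doc.get('schema') if isinstance(doc, dict) else doc!r}; "
            f"expected {MODEL_SCHEMA}"
        )
    unknown = set(doc) - _MODEL_FIELDS
    missing = _MODEL_FIELDS - set(doc)
    if unknown or missing:
        raise SPIModelError(f"model file schema error: unknown={sorted(unknown)} missing={sorted(missing)}")
    return SPIModel(
        subset=tuple(doc["subset"]),
        pro_mean=np.array(doc["pro_mean"], dtype=float),
        pro_sd=np.array(doc["pro_sd"], dtype=float),
        pca_components=np.array(doc["pca_components"], dtype=float),
        pro_pc_center=np.array(doc["pro_pc_center"], dtype=float),
        log_dist_mean=float(doc["log_dist_mean"]),
        log_dist_sd=float(doc["log_dist_sd"]),
        epsilon=float(doc["epsilon"]),
        provenance=doc.get("provenance") or {},
    )
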