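"""Phase-locking states: coherence matrices, leading eigenvectors, clustering.

At each retained timepoint the pairwise phase coherence
``dFC(n, p, t) = cos(theta(n, t) - theta(p, t))`` forms a symmetric matrix
with unit diagonal; its leading eigenvector V1(t) summarises the dominant
phase-alignment pattern. Eigenvectors pooled across subjects are clustered
with k-means into recurrent phase-locking (PL) states, and the number of
clusters is selected by the Dunn validity index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans

__all__ = [
    "ClusterModel",
    "NetworkTemplate",
    "phase_coherence",
    "leading_eigenvector",
    "eigenvectors_for_phases",
    "concatenate_eigenvectors",
    "kmeans_states",
    "dunn_index",
    "select_optimal_k",
    "template_correlation",
]

DEFAULT_K_RANGE = range(3, 16)
DEFAULT_RESTARTS = 20
DEFAULT_DUNN_SUBSAMPLE = 8000


@dataclass
class ClusterModel:
    """A k-means partition of pooled leading eigenvectors into PL states.

    ``labels`` are 1-based (states 1..k), leaving 0 free as the downstream
    "other condition" mask label. ``index`` carries (subject_id, timepoint)
    provenance per pooled row.
    """

    k: int
    centroids: np.ndarray  # (k, n_regions)
    labels: np.ndarray  # (n_rows,), values 1..k
    inertia: float
    dunn: float = np.nan
    index: pd.DataFrame | None = field(default=None, repr=False)

    def labels_for(self, subject_id: str) -> np.ndarray:
        """State sequence (1..k) for one subject, ordered by timepoint."""
        if self.index is None:
            raise ValueError("model has no provenance index")
        mask = (self.index["subject_id"] == subject_id).to_numpy()
        if not mask.any():
            raise KeyError(subject_id)
        order = np.argsort(self.index.loc[mask, "timepoint"].to_numpy())
        return self.labels[mask][order]


@dataclass(frozen=True)
class NetworkTemplate:
    """A reference network map over regions (binary membership or weights)."""

    name: str
    map: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "map", np.asarray(self.map, dtype=float))


def phase_coherence(phases_at_t: np.ndarray) -> np.ndarray:
    """Pairwise phase-coherence matrix cos(theta_n - theta_p) at one timepoint.

    Entries lie in [-1, 1]: 1 for phase-locked regions, 0 for orthogonal
    phases, -1 for anti-phase. Symmetric with an exactly unit diagonal, and
    invariant to adding a global phase constant.
    """
    th = np.asarray(phases_at_t, dtype=float)
    if th.ndim != 1:
        raise ValueError("expected a 1-D phase vector for one timepoint")
    if not np.all(np.isfinite(th)):
        raise ValueError("non-finite phases")
    C = np.cos(th[:, None] - th[None, :])
    np.fill_diagonal(C, 1.0)
    return C


def _sign_normalize(v: np.ndarray) -> np.ndarray:
    """Orient an eigenvector so the strict majority of components is negative.

    On an exact negative/positive tie the first component is made <= 0. A
    fixed orientation is required because eigenvectors are sign-ambiguous and
    k-means would otherwise split one pattern into two antipodal clusters.
    """
    n_neg = int(np.sum(v < 0))
    n_pos = int(np.sum(v > 0))
    if n_neg < n_pos:
        return -v
    if n_neg == n_pos and v[0] > 0:
        return -v
    return v


def leading_eigenvector(C: np.ndarray) -> np.ndarray:
    """Unit-norm, sign-normalized eigenvector of the largest eigenvalue of C."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("C must be symmetric")
    n = C.shape[0]
    try:
        w, v = linalg.eigh(C, subset_by_index=[n - 1, n - 1])
    except linalg.LinAlgError as err:  # pragma: no cover - rare
        raise linalg.LinAlgError(f"eigensolver failed on coherence matrix: {err}")
    vec = v[:, 0]
    vec = vec / np.linalg.norm(vec)
    return _sign_normalize(vec)


def eigenvectors_for_phases(phases: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the coherence matrix at every timepoint.

    Parameters
    ----------
    phases : ndarray, shape (n_regions, n_volumes)

    Returns
    -------
    ndarray, shape (n_volumes, n_regions)
    """
    phases = np.asarray(phases, dtype=float)
    n_regions, n_vol = phases.shape
    out = np.empty((n_vol, n_regions))
    for t in range(n_vol):
        out[t] = leading_eigenvector(phase_coherence(phases[:, t]))
    return out


def concatenate_eigenvectors(
    sets: list[tuple[str, np.ndarray]],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack per-subject eigenvector matrices into one pooled matrix.

    Parameters
    ----------
    sets : list of (subject_id, ndarray of shape (timepoints, regions))

    Returns
    -------
    pooled : ndarray, shape (sum timepoints, regions)
    index : DataFrame with columns subject_id, timepoint, one row per pooled
        row, preserving provenance (42 subjects x 780 timepoints pool to a
        32,760-row matrix).
    """
    if not sets:
        raise ValueError("no eigenvector sets to concatenate")
    n_regions = {np.asarray(m).shape[1] for _, m in sets}
    if len(n_regions) != 1:
        raise ValueError(f"region-count mismatch across subjects: {sorted(n_regions)}")
    pooled = np.vstack([np.asarray(m, dtype=float) for _, m in sets])
    index = pd.DataFrame(
        {
            "subject_id": np.repeat(
                [sid for sid, _ in sets], [np.asarray(m).shape[0] for _, m in sets]
            ),
            "timepoint": np.concatenate(
                [np.arange(np.asarray(m).shape[0]) for _, m in sets]
            ),
        }
    )
    return pooled, index


def kmeans_states(
    pooled: np.ndarray,
    k: int,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int | None = 0,
    index: pd.DataFrame | None = None,
) -> ClusterModel:
    """Cluster pooled eigenvectors into k PL states (best of n_restarts).

    Euclidean k-means with k-means++ initialization; on unit-norm vectors
    Euclidean distance is monotone in cosine distance. Labels are returned
    1-based.
    """
    X = np.asarray(pooled, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} available rows")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels0 = km.fit_predict(X)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        labels=labels0 + 1,
        inertia=float(km.inertia_),
        index=index,
    )


def dunn_index(
    points: np.ndarray,
    labels: np.ndarray,
    subsample: int | None = None,
    seed: int | None = 0,
) -> float:
    """Dunn cluster-validity index (larger is better).

    Classic variant: the minimum single-linkage inter-cluster distance divided
    by the maximum complete-diameter intra-cluster distance, Euclidean. Exact
    computation is O(N^2); ``subsample`` caps the point count via a seeded
    uniform subsample (at least one point per cluster is retained).

    Returns ``inf`` when every cluster has zero diameter but clusters are
    distinct; raises on a single cluster.
    """
    X = np.asarray(points, dtype=float)
    lab = np.asarray(labels)
    if X.shape[0] != lab.shape[0]:
        raise ValueError("points/labels length mismatch")
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise ValueError("Dunn index requires at least 2 clusters")

    if subsample is not None and X.shape[0] > subsample:
        rng = np.random.default_rng(seed)
        keep = rng.choice(X.shape[0], size=subsample, replace=False)
        # guarantee every cluster survives the subsample
        present = np.unique(lab[keep])
        missing = np.setdiff1d(uniq, present)
        if missing.size:
            extra = [np.flatnonzero(lab == c)[0] for c in missing]
            keep = np.concatenate([keep, extra])
        X, lab = X[keep], lab[keep]

    groups = [X[lab == c] for c in uniq]
    max_diam = 0.0
    for g in groups:
        if g.shape[0] > 1:
            max_diam = max(max_diam, float(pdist(g).max()))
    min_inter = np.inf
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            min_inter = min(min_inter, float(cdist(groups[i], groups[j]).min()))
    if max_diam == 0.0:
        return np.inf
    return min_inter / max_diam


def select_optimal_k(
    pooled: np.ndarray,
    k_range=DEFAULT_K_RANGE,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int | None = 0,
    dunn_subsample: int | None = DEFAULT_DUNN_SUBSAMPLE,
    index: pd.DataFrame | None = None,
) -> tuple[ClusterModel, pd.DataFrame]:
    """Fit k-means over k_range and return the model maximising the Dunn index.

    Ties break toward the smallest k (parsimony). Returns the winning model
    and the full k -> Dunn table.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("empty k_range")
    models: dict[int, ClusterModel] = {}
    rows = []
    for k in ks:
        m = kmeans_states(pooled, k, n_restarts=n_restarts, seed=seed, index=index)
        m.dunn = dunn_index(pooled, m.labels, subsample=dunn_subsample, seed=seed)
        models[k] = m
        rows.append({"k": k, "dunn": m.dunn, "inertia": m.inertia})
    table = pd.DataFrame(rows)
    best_dunn = table["dunn"].max()
    best_k = int(table.loc[table["dunn"] == best_dunn, "k"].min())
    return models[best_k], table


def template_correlation(
    centroids: np.ndarray,
    templates: list[NetworkTemplate],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each PL centroid with each reference network map.

    Two-sided p-values come from the t-distribution with (regions - 2) df;
    significance is Bonferroni-corrected over all (state, template) tests at
    ``alpha``. Zero-variance centroids or templates yield NaN r with a flag.
    """
    cents = np.atleast_2d(np.asarray(centroids, dtype=float))
    n_regions = cents.shape[1]
    if n_regions < 3:
        raise ValueError("need at least 3 regions for a correlation test")
    for t in templates:
        if t.map.shape[0] != n_regions:
            raise ValueError(
                f"template {t.name!r} has {t.map.shape[0]} regions, expected {n_regions}"
            )
    n_tests = cents.shape[0] * len(templates)
    rows = []
    for s in range(cents.shape[0]):
        for t in templates:
            degenerate = np.std(cents[s]) == 0 or np.std(t.map) == 0
            if degenerate:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(cents[s], t.map)
            rows.append(
                {
                    "state": s + 1,
                    "template": t.name,
                    "r": r,
                    "p": p,
                    "significant": bool(p < alpha / n_tests) if not degenerate else False,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)
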