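"""Descriptor-space analysis: clustering and group-separability statistics.

Assembles per-spine descriptor vectors (optionally with the volume scalar)
into a feature matrix, reduces dimensionality (PCA / t-SNE / UMAP), clusters
with k-means (elbow + silhouette model selection), and scores how the
control and treated groups distribute over clusters: a per-cluster
one-vs-rest Agresti–Caffo two-proportion test (membership rate in control
vs treated) and an overall Pearson chi-squared test on the k x 2
cluster-by-group contingency table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureMatrix",
    "ClusterReport",
    "ACResult",
    "Chi2Result",
    "KSelection",
    "assemble_features",
    "reduce_dim",
    "kmeans_cluster",
    "choose_k",
    "agresti_caffo",
    "chi_square_groups",
    "best_separability_report",
    "cluster_group_report",
    "permutation_calibration",
    "representative_spines",
]

GROUPS = ("control", "treated")


@dataclass
class FeatureMatrix:
    """Aligned spine ids, feature rows and optional group labels."""

    spine_ids: list[str]
    X: np.ndarray
    feature_names: list[str]
    scaling: str = "none"
    group: np.ndarray | None = None  # per-spine "control"/"treated"
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2D")
        n, d = self.X.shape
        if d == 0:
            raise ValueError("feature matrix has no columns")
        if len(self.spine_ids) != n:
            raise ValueError("spine_ids and X rows must align")
        if len(self.feature_names) != d:
            raise ValueError("feature_names and X columns must align")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing values")
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)
            if len(self.group) != n:
                raise ValueError("group labels and X rows must align")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


class ACResult(NamedTuple):
    diff: float
    ci_low: float
    ci_high: float
    z: float
    p: float


class Chi2Result(NamedTuple):
    statistic: float
    dof: int
    p: float


@dataclass
class KSelection:
    table: pd.DataFrame  # columns k, inertia, silhouette
    elbow_k: int
    silhouette_k: int


@dataclass
class ClusterReport:
    """Cluster labels plus control/treated separability statistics."""

    k: int
    labels: np.ndarray
    reduction: str
    seed: int
    inertia: float
    silhouette: float
    space: np.ndarray  # matrix clustering was run in (for representatives)
    spine_ids: list[str]
    per_cluster: dict[int, dict] | None = None
    chi2: Chi2Result | None = None

    @property
    def chi2_p(self) -> float | None:
        return None if self.chi2 is None else self.chi2.p

    def significant_clusters(self, alpha: float = 0.05) -> list[int]:
        if self.per_cluster is None:
            return []
        return [c for c, row in self.per_cluster.items() if row["ac_p"] < alpha]

    def table1_row(self, label: str = "") -> dict:
        """One row shaped like the descriptor-comparison summary table."""
        sig = self.significant_clusters()
        ps = sorted(self.per_cluster[c]["ac_p"] for c in sig) if sig else []
        return {
            "dimension": label or self.reduction,
            "n_clusters": self.k,
            "n_significant": len(sig),
            "ac_p_values": "; ".join(f"{p:.3g}" for p in ps),
            "chi2_p": self.chi2_p,
        }

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "reduction": self.reduction,
            "seed": self.seed,
            "inertia": self.inertia,
            "silhouette": self.silhouette,
            "labels": {s: int(l) for s, l in zip(self.spine_ids, self.labels)},
            "per_cluster": {
                str(c): {k: (float(v) if isinstance(v, (int, float, np.floating)) else v) for k, v in row.items()}
                for c, row in (self.per_cluster or {}).items()
            },
            "chi2_p": self.chi2_p,
        }


# ---------------------------------------------------------------------------
# feature assembly


def assemble_features(
    descriptors: Mapping[str, np.ndarray],
    volumes: Mapping[str, float] | None = None,
    scaling: str = "zscore",
    groups: Mapping[str, str] | None = None,
    feature_names: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Stack per-spine descriptor vectors (+ optional volume column).

    Spines with a missing or non-finite descriptor (or missing volume when
    volumes are requested) are dropped and listed in ``dropped`` — the
    reduced-dataset semantics of descriptor chains that fail on some meshes.
    """
    if scaling not in ("none", "zscore"):
        raise ValueError(f"unknown scaling {scaling!r}")
    ids, rows, dropped = [], [], []
    length = None
    for sid, vec in descriptors.items():
        vec = np.asarray(vec, dtype=float).ravel()
        if length is None:
            length = len(vec)
        elif len(vec) != length:
            raise ValueError(f"descriptor length mismatch for {sid}")
        if not np.all(np.isfinite(vec)) or (volumes is not None and sid not in volumes):
            dropped.append(sid)
            continue
        if volumes is not None:
            vec = np.append(vec, float(volumes[sid]))
        ids.append(sid)
        rows.append(vec)
    if not rows:
        raise ValueError("no usable spines after filtering")
    X = np.vstack(rows)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(length)]
    names = list(feature_names)
    if volumes is not None:
        names = names + ["volume"]
    if len(names) != X.shape[1]:
        raise ValueError("feature_names length mismatch")
    if scaling == "zscore":
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    group = None
    if groups is not None:
        group = np.array([groups[s] for s in ids], dtype=object)
    return FeatureMatrix(
        spine_ids=ids, X=X, feature_names=names, scaling=scaling, group=group, dropped=dropped
    )


# ---------------------------------------------------------------------------
# dimensionality reduction


def reduce_dim(
    fm: FeatureMatrix, method: str = "none", dim: int = 3, seed: int = 0
) -> FeatureMatrix:
    """Embed the feature matrix with PCA, t-SNE or UMAP (seeded)."""
    if method == "none":
        return fm
    if dim >= fm.d:
        raise ValueError("dim must be smaller than the feature dimension")
    if method == "pca":
        from sklearn.decomposition import PCA

        emb = PCA(n_components=dim, random_state=seed).fit_transform(fm.X)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (fm.n - 1) / 3.0))
        emb = TSNE(
            n_components=dim,
            random_state=seed,
            perplexity=perplexity,
            init="pca",
        ).fit_transform(fm.X)
    elif method == "umap":
        import umap

        emb = umap.UMAP(
            n_components=dim, random_state=seed, n_neighbors=15, min_dist=0.1
        ).fit_transform(fm.X)
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    return replace(
        fm,
        X=np.asarray(emb, dtype=float),
        feature_names=[f"{method}{i + 1}" for i in range(dim)],
        scaling=fm.scaling,
    )


# ---------------------------------------------------------------------------
# k-means and model selection


def kmeans_cluster(
    fm: FeatureMatrix, k: int, seed: int = 0, restarts: int = 20
) -> ClusterReport:
    """Best-of-restarts k-means; labels, inertia and mean silhouette."""
    if not 2 <= k < fm.n:
        raise ValueError(f"k={k} out of range [2, n-1]")
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(fm.X)
    labels = km.labels_.astype(int)
    try:
        sil = float(silhouette_score(fm.X, labels))
    except ValueError:  # all points in one cluster (degenerate data)
        sil = float("nan")
    return ClusterReport(
        k=k,
        labels=labels,
        reduction="none",
        seed=seed,
        inertia=float(km.inertia_),
        silhouette=sil,
        space=fm.X,
        spine_ids=list(fm.spine_ids),
    )


def choose_k(
    fm: FeatureMatrix, k_range: Iterable[int], seed: int = 0, restarts: int = 20
) -> KSelection:
    """Per-k inertia (elbow) and silhouette diagnostics.

    The elbow is the k maximizing the second difference of inertia; the
    recommended k is the silhouette argmax.  Both are surfaced — they need
    not agree, and no silent tie-break is applied.
    """
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 or k >= fm.n for k in ks):
        raise ValueError("k_range must lie in [2, n-1]")
    rows = []
    for k in ks:
        rep = kmeans_cluster(fm, k, seed=seed, restarts=restarts)
        rows.append({"k": k, "inertia": rep.inertia, "silhouette": rep.silhouette})
    table = pd.DataFrame(rows)
    sil_k = int(table.loc[table["silhouette"].idxmax(), "k"])
    if len(ks) >= 3:
        second_diff = np.diff(table["inertia"].to_numpy(), 2)
        elbow_k = int(table["k"].iloc[int(np.argmax(second_diff)) + 1])
    else:
        elbow_k = sil_k
    return KSelection(table=table, elbow_k=elbow_k, silhouette_k=sil_k)


# ---------------------------------------------------------------------------
# separability statistics


def agresti_caffo(x1: int, n1: int, x2: int, n2: int) -> ACResult:
    """Agresti–Caffo adjusted-Wald two-proportion test.

    One success and one failure are added to each sample; the z statistic and
    the 95% CI use the adjusted proportions (x_i + 1) / (n_i + 2).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("trial counts must be >= 1")
        if not 0 <= x <= n:
            raise ValueError("successes must lie in [0, n]")
    p1 = (x1 + 1.0) / (n1 + 2.0)
    p2 = (x2 + 1.0) / (n2 + 2.0)
    se = np.sqrt(p1 * (1 - p1) / (n1 + 2.0) + p2 * (1 - p2) / (n2 + 2.0))
    diff = p1 - p2
    z = diff / se if se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * se
    return ACResult(diff=diff, ci_low=diff - half, ci_high=diff + half, z=float(z), p=p)


def chi_square_groups(counts: np.ndarray) -> Chi2Result:
    """Pearson chi-squared on a k x 2 cluster-by-group contingency table.

    Uncorrected (no Yates continuity correction), so on a 2 x 2 table the
    statistic equals the squared two-proportion z statistic.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("counts must be k x 2")
    if np.any(counts.sum(axis=0) == 0):
        raise ValueError("a group has zero total count")
    keep = counts.sum(axis=1) > 0
    counts = counts[keep]
    stat, p, dof, expected = stats.chi2_contingency(counts, correction=False)
    if np.any(expected < 5):
        warnings.warn(
            "chi-squared expected count below 5; p-value approximate", stacklevel=2
        )
    return Chi2Result(statistic=float(stat), dof=int(dof), p=float(p))


def _per_cluster_stats(
    labels: np.ndarray, group: np.ndarray, k: int
) -> tuple[dict[int, dict], Chi2Result]:
    is_ctrl = group == GROUPS[0]
    is_trt = group == GROUPS[1]
    n_ctrl, n_trt = int(is_ctrl.sum()), int(is_trt.sum())
    if n_ctrl == 0 or n_trt == 0:
        raise ValueError("both groups must be represented")
    per = {}
    pvals = []
    counts = np.zeros((k, 2))
    for c in range(k):
        in_c = labels == c
        x1 = int((in_c & is_ctrl).sum())
        x2 = int((in_c & is_trt).sum())
        counts[c] = (x1, x2)
        ac = agresti_caffo(x1, n_ctrl, x2, n_trt)
        per[c] = {
            "n_control": x1,
            "n_treated": x2,
            "pct_control": 100.0 * x1 / n_ctrl,
            "pct_treated": 100.0 * x2 / n_trt,
            "ac_p": ac.p,
            "ac_z": ac.z,
        }
        pvals.append(ac.p)
    # Holm adjustment reported alongside (the raw per-cluster p-values remain
    # the primary readout)
    order = np.argsort(pvals)
    m = len(pvals)
    holm = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        holm[idx] = min(1.0, running)
    for c in range(k):
        per[c]["ac_p_holm"] = float(holm[c])
    chi2 = chi_square_groups(counts)
    return per, chi2


def cluster_group_report(
    fm: FeatureMatrix,
    k: int,
    reduction: str = "none",
    seed: int = 0,
    dim: int = 3,
    restarts: int = 20,
) -> ClusterReport:
    """Reduce, cluster, and test control/treated separability per cluster.

    Each cluster's membership rate in the control group is compared with its
    rate in the treated group by the Agresti–Caffo test (one-vs-rest); the
    overall distribution difference is tested by Pearson chi-squared on the
    k x 2 table.
    """
    if fm.group is None:
        raise ValueError("feature matrix carries no group labels")
    emb = reduce_dim(fm, method=reduction, dim=dim, seed=seed)
    rep = kmeans_cluster(emb, k, seed=seed, restarts=restarts)
    per, chi2 = _per_cluster_stats(rep.labels, fm.group, k)
    rep.reduction = reduction
    rep.per_cluster = per
    rep.chi2 = chi2
    return rep


def best_separability_report(
    fm: FeatureMatrix,
    reductions: Sequence[str] = ("none", "pca", "tsne", "umap"),
    k_range: Iterable[int] = range(2, 9),
    seed: int = 0,
    dim: int = 3,
    restarts: int = 20,
) -> tuple[ClusterReport, pd.DataFrame]:
    """Best-performing clustering configuration by group separability.

    Mirrors the descriptor-comparison procedure: each reduction is clustered
    at its silhouette-selected k, and the configuration with the smallest
    overall chi-squared p (ties broken by more significant clusters) is
    returned together with the per-configuration summary table.
    """
    rows, reports = [], {}
    ks = list(k_range)
    for red in reductions:
        emb = reduce_dim(fm, method=red, dim=dim, seed=seed)
        sel = choose_k(emb, [k for k in ks if k < emb.n], seed=seed, restarts=restarts)
        rep = cluster_group_report(fm, k=sel.silhouette_k, reduction=red, seed=seed, dim=dim, restarts=restarts)
        reports[red] = rep
        rows.append(
            {
                "reduction": red,
                "k": rep.k,
                "silhouette": rep.silhouette,
                "n_significant": len(rep.significant_clusters()),
                "chi2_p": rep.chi2_p,
            }
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["chi2_p", "n_significant"], ascending=[True, False], kind="stable"
    )
    best = reports[order.iloc[0]["reduction"]]
    return best, table


def permutation_calibration(
    labels: np.ndarray,
    group: np.ndarray,
    k: int,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Per-cluster rejection rate of the Agresti–Caffo test under label shuffling.

    Group labels are permuted relative to a fixed clustering; with
    exchangeable groups the fraction of (cluster, permutation) tests with
    p < alpha estimates the test's realized size.
    """
    rng = np.random.default_rng(seed)
    group = np.asarray(group, dtype=object)
    rejections = 0
    total = 0
    for _ in range(n_perm):
        perm = group[rng.permutation(len(group))]
        per, _chi = _per_cluster_stats(labels, perm, k)
        for c in range(k):
            total += 1
            if per[c]["ac_p"] < alpha:
                rejections += 1
    return rejections / total


def representative_spines(
    report: ClusterReport, fm: FeatureMatrix | None = None, top: int = 3
) -> dict[int, list[str]]:
    """Per cluster, the ids of the spines nearest the cluster centroid.

    Distances are Euclidean in the space clustering was run in; ``top``
    larger than the cluster returns the whole cluster, sorted.
    """
    if top < 1:
        raise ValueError("top must be >= 1")
    X = report.space
    out: dict[int, list[str]] = {}
    ids = np.asarray(report.spine_ids, dtype=object)
    for c in range(report.k):
        mask = report.labels == c
        pts = X[mask]
        centroid = pts.mean(axis=0)
        d = np.linalg.norm(pts - centroid, axis=1)
        order = np.argsort(d, kind="stable")[:top]
        out[c] = list(ids[mask][order])
    return out
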