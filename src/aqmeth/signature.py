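"""Variance ranking, clustering, MDS and prognostic signature panels.

This module carries the unsupervised half of the pipeline: selection of
the most variably methylated probes, agglomerative clustering of samples
over a probe panel, classical (Torgerson) multidimensional scaling,
derivation of a differential signature panel between outcome groups
(e.g. salvaged vs enucleated eyes), two-group cluster assignment
("Cluster A" = salvage-enriched, "Cluster B" = enucleation-enriched) and
the exact cluster-vs-outcome association test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_is_fitted

from .containers import BetaMatrix, ProbeAnnotation
from .diffmeth import dm_table, select_dm

__all__ = [
    "top_variable_probes", "hcluster", "cut_k", "mds_embed",
    "derive_panel", "assign_clusters", "cluster_outcome_test",
    "LinkageTree", "SignaturePanel", "ClusterAssignment", "OutcomeTest",
    "TopVariableProbeSelector", "ClassicalMDS", "SignatureClusterer",
]

ENUCLEATED = frozenset({"PE", "SE"})


# ---------------------------------------------------------------------------
# variance ranking

def top_variable_probes(betas: BetaMatrix, samples: Sequence[str] | None = None,
                        k: int = 10000) -> list[str]:
    """The k probes with the largest beta standard deviation.

    SD is the unbiased (ddof=1) estimate over unmasked values; probes with
    fewer than two unmasked values are ineligible. Ties are broken by
    lexicographic probe id so the ranking is fully deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    sub = betas if samples is None else betas.select(samples=samples)
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = sub.beta.std(axis=1, ddof=1, skipna=True)
    sd = sd[sub.beta.notna().sum(axis=1) >= 2]
    if k > len(sd):
        warnings.warn(f"k={k} exceeds {len(sd)} eligible probes; returning all")
        k = len(sd)
    order = sorted(sd.index, key=lambda p: (-sd[p], p))
    return order[:k]


# ---------------------------------------------------------------------------
# distances / trees

def _pairwise_distances(X: np.ndarray, metric: str) -> np.ndarray:
    """Sample x sample distances, pairwise-complete over missing cells.

    Euclidean distances over incomplete pairs are rescaled to the full
    probe count so missingness does not shrink them.
    """
    if metric not in ("euclidean", "correlation"):
        raise ValueError("metric must be 'euclidean' or 'correlation'")
    n, p = X.shape
    nan = np.isnan(X)
    D = np.zeros((n, n))
    if not nan.any():
        if metric == "euclidean":
            diff = X[:, None, :] - X[None, :, :]
            return np.sqrt((diff ** 2).sum(axis=2))
        Xc = X - X.mean(axis=1, keepdims=True)
        norm = np.sqrt((Xc ** 2).sum(axis=1))
        norm[norm == 0] = np.nan
        r = (Xc @ Xc.T) / np.outer(norm, norm)
        return 1.0 - np.nan_to_num(r, nan=0.0)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(nan[i] | nan[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(f"samples {i} and {j} share no unmasked probes")
            xi, xj = X[i, ok], X[j, ok]
            if metric == "euclidean":
                d = np.sqrt(((xi - xj) ** 2).sum() * p / m)
            else:
                with np.errstate(invalid="ignore"):
                    r = np.corrcoef(xi, xj)[0, 1]
                d = 1.0 - (0.0 if np.isnan(r) else r)
            D[i, j] = D[j, i] = d
    return D


@dataclass
class LinkageTree:
    """Agglomerative tree: scipy linkage matrix plus the leaf order."""

    Z: np.ndarray
    leaves: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def merge_list(self) -> list[dict]:
        """Serializable merge list: child indices and merge heights."""
        return [{"left": int(a), "right": int(b), "height": float(h),
                 "size": int(s)} for a, b, h, s in self.Z]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"leaves": self.leaves, "merges": self.merge_list()},
                      fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "LinkageTree":
        with open(path) as fh:
            obj = json.load(fh)
        Z = np.array([[m["left"], m["right"], m["height"], m["size"]]
                      for m in obj["merges"]], dtype=float)
        return cls(Z=Z, leaves=list(obj["leaves"]))


def _panel_matrix(betas: BetaMatrix, probes, samples) -> tuple[np.ndarray, list[str]]:
    sub = betas.select(probes=probes, samples=samples)
    X = sub.beta.to_numpy().T  # samples x probes
    sample_ids = list(sub.sample_ids)
    frac_missing = np.isnan(X).mean(axis=1)
    bad = [s for s, f in zip(sample_ids, frac_missing) if f > 0.5]
    if bad:
        raise ValueError(f"samples with >50% missing over the panel: {bad}")
    return X, sample_ids


def hcluster(betas: BetaMatrix, probes: Sequence[str] | None = None,
             samples: Sequence[str] | None = None,
             metric: str = "euclidean",
             linkage: str = "complete") -> LinkageTree:
    """Agglomerative clustering of samples over a probe panel.

    Default Euclidean/complete; ``average`` and ``ward`` linkages and a
    Pearson-correlation distance are also available. Deterministic for a
    given input.
    """
    if linkage not in ("complete", "average", "ward"):
        raise ValueError("linkage must be complete, average or ward")
    X, sample_ids = _panel_matrix(betas, probes, samples)
    if len(sample_ids) < 2:
        raise ValueError("need at least 2 samples to cluster")
    D = _pairwise_distances(X, metric)
    condensed = D[np.triu_indices_from(D, k=1)]
    Z = hierarchy.linkage(condensed, method=linkage)
    return LinkageTree(Z=Z, leaves=sample_ids)


def cut_k(tree: LinkageTree, k: int) -> pd.Series:
    """Cut the tree into k flat clusters (labels 1..k, scipy numbering)."""
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must lie in [1, {tree.n_leaves}]")
    labels = hierarchy.fcluster(tree.Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=tree.leaves, name="cluster")


# ---------------------------------------------------------------------------
# classical MDS

def _classical_mds(D: np.ndarray, dims: int) -> np.ndarray:
    n = D.shape[0]
    if np.allclose(D, 0):
        warnings.warn("degenerate (all-equal) distances; returning zeros")
        return np.zeros((n, dims))
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[idx], 0.0, None)
    # axes with negligible spread carry only numerical noise
    lam[lam < lam.max() * 1e-12] = 0.0
    coords = v[:, idx] * np.sqrt(lam)
    # fix the sign convention: largest-|coordinate| sample positive per axis
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def mds_embed(betas: BetaMatrix, probes: Sequence[str] | None = None,
              samples: Sequence[str] | None = None,
              dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples on Euclidean panel distances.

    Coordinates are centered at the origin; exactly embeddable distance
    matrices are reproduced up to numerical precision.
    """
    X, sample_ids = _panel_matrix(betas, probes, samples)
    if len(sample_ids) < dims + 1:
        raise ValueError("need at least dims+1 samples")
    D = _pairwise_distances(X, "euclidean")
    coords = _classical_mds(D, dims)
    return pd.DataFrame(coords, index=sample_ids,
                        columns=[f"MDS{i+1}" for i in range(dims)])


# ---------------------------------------------------------------------------
# signature panels

@dataclass
class SignaturePanel:
    """Ordered probe panel with per-probe stats and its provenance."""

    label: str
    table: pd.DataFrame  # indexed by probe id: delta_beta, p_value, direction
    delta_thresh: float
    p_thresh: float
    arm_a: list[str] = field(default_factory=list)
    arm_b: list[str] = field(default_factory=list)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# panel={self.label}\n")
            fh.write(f"# delta_thresh={self.delta_thresh}\n")
            fh.write(f"# p_thresh={self.p_thresh}\n")
            fh.write(f"# arm_a={','.join(self.arm_a)}\n")
            fh.write(f"# arm_b={','.join(self.arm_b)}\n")
            self.table.to_csv(fh, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, path) -> "SignaturePanel":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            table = pd.read_csv(fh, sep="\t", index_col=0)
        split = lambda s: [x for x in s.split(",") if x]  # noqa: E731
        return cls(label=meta.get("panel", ""), table=table,
                   delta_thresh=float(meta.get("delta_thresh", 0.4)),
                   p_thresh=float(meta.get("p_thresh", 0.01)),
                   arm_a=split(meta.get("arm_a", "")),
                   arm_b=split(meta.get("arm_b", "")))


def derive_panel(betas: BetaMatrix, arm_a: Sequence[str], arm_b: Sequence[str],
                 delta_thresh: float = 0.4, p_thresh: float = 0.01,
                 probes: Sequence[str] | None = None,
                 annotation: ProbeAnnotation | None = None,
                 label: str = "signature") -> SignaturePanel:
    """Derive a differential signature panel between two outcome arms.

    Probes with |delta-beta| > ``delta_thresh`` and p < ``p_thresh``
    (strict, Welch's t) enter the panel. Composable: a second-round panel
    can be derived between previously assigned clusters the same way.
    """
    dm = dm_table(betas, arm_a, arm_b, probes=probes, annotation=annotation,
                  delta_thresh=delta_thresh, p_thresh=p_thresh, label=label)
    hyper, hypo = select_dm(dm)
    selected = sorted(hyper | hypo)
    if not selected:
        warnings.warn(f"panel '{label}' is empty at the given thresholds")
    table = dm.records.loc[selected, ["delta_beta", "p_value", "direction"]]
    table = table.sort_values(["p_value", "delta_beta"],
                              ascending=[True, False])
    return SignaturePanel(label=label, table=table, delta_thresh=delta_thresh,
                          p_thresh=p_thresh, arm_a=list(arm_a),
                          arm_b=list(arm_b))


# ---------------------------------------------------------------------------
# cluster assignment and outcome association

@dataclass
class ClusterAssignment:
    """Two-group cluster labels over a panel, with the linkage tree."""

    labels: pd.Series  # sample id -> "A"/"B" (or "1"/"2" without outcomes)
    tree: LinkageTree
    panel_label: str
    silhouette: float
    weak_separation: bool

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def assign_clusters(betas: BetaMatrix, panel: SignaturePanel,
                    samples: Sequence[str] | None = None,
                    outcomes: Mapping[str, str] | pd.Series | None = None,
                    metric: str = "euclidean", linkage: str = "complete",
                    weak_threshold: float = 0.1) -> ClusterAssignment:
    """Cluster samples over a signature panel and cut at k=2.

    With per-sample outcome annotations, the cluster holding the larger
    fraction of salvaged (SV) samples is labeled "A", the other "B"
    (ties broken toward the cluster containing the lexicographically first
    sample, so reports are stable). Without outcomes the labels are
    "1"/"2". A mean silhouette below ``weak_threshold`` flags weak
    separation (the forced 2-cut of a homogeneous cohort).
    """
    missing = [p for p in panel.probe_ids if p not in betas.probe_ids]
    if missing:
        raise KeyError(f"panel probes absent from the matrix: {missing[:10]}")
    tree = hcluster(betas, probes=panel.probe_ids, samples=samples,
                    metric=metric, linkage=linkage)
    raw = cut_k(tree, 2)
    X, sample_ids = _panel_matrix(betas, panel.probe_ids, samples)
    D = _pairwise_distances(X, metric)
    if raw.nunique() == 2:
        sil = float(silhouette_score(D, raw.to_numpy(), metric="precomputed"))
    else:  # pragma: no cover - k=2 cut of >=2 samples always yields 2 groups
        sil = 0.0

    groups = {g: set(raw.index[raw == g]) for g in raw.unique()}
    if outcomes is not None:
        outcomes = pd.Series(dict(outcomes)) if not isinstance(outcomes, pd.Series) \
            else outcomes

        def sv_frac(members: set[str]) -> float:
            vals = [outcomes.get(s) for s in members]
            known = [v for v in vals if v is not None and not pd.isna(v)]
            if not known:
                return 0.0
            return sum(v == "SV" for v in known) / len(known)

        g1, g2 = sorted(groups, key=lambda g: min(groups[g]))
        if sv_frac(groups[g1]) >= sv_frac(groups[g2]):
            name_of = {g1: "A", g2: "B"}
        else:
            name_of = {g1: "B", g2: "A"}
    else:
        g1, g2 = sorted(groups, key=lambda g: min(groups[g]))
        name_of = {g1: "1", g2: "2"}
    labels = raw.map(name_of)
    labels.name = "cluster"
    return ClusterAssignment(labels=labels, tree=tree,
                             panel_label=panel.label, silhouette=sil,
                             weak_separation=sil < weak_threshold)


@dataclass
class OutcomeTest:
    """2x2 cluster-by-outcome association."""

    table: pd.DataFrame
    odds_ratio: float
    p_value: float
    containment: tuple[bool, bool]


def _doubled_fisher(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided p as twice the smaller hypergeometric tail, capped at 1."""
    n = a + b + c + d
    rv = hypergeom(n, a + c, a + b)
    p_ge = float(rv.sf(a - 1))
    p_le = float(rv.cdf(a))
    return min(1.0, 2.0 * min(p_ge, p_le))


def cluster_outcome_test(assignment: ClusterAssignment | pd.Series,
                         outcomes: Mapping[str, str] | pd.Series) -> OutcomeTest:
    """Exact test of cluster membership against a binarized outcome.

    Clinical outcomes are binarized as salvaged (SV) versus enucleated
    (PE and SE merged); any other two-level labeling (e.g. external
    subtypes 1/2) is used as-is with the lexicographically first level as
    the positive column. The p-value is the doubled smaller exact
    hypergeometric tail. ``containment`` reports whether cluster A lies
    entirely within the positive level and cluster B within the negative
    one (the "full overlap" reading of a perfect correspondence).

    The odds ratio is (a*d)/(b*c); infinity is reported when a zero cell
    makes the association perfect.
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) \
        else assignment
    outcomes = pd.Series(dict(outcomes)) if not isinstance(outcomes, pd.Series) \
        else outcomes
    missing = [s for s in labels.index if s not in outcomes.index
               or pd.isna(outcomes[s])]
    if missing:
        raise ValueError(f"samples without outcome/subtype: {missing[:10]}")
    out = outcomes.loc[labels.index].astype(str)
    levels = sorted(out.unique())
    if set(levels) <= {"SV", "PE", "SE"}:
        pos_name, neg_name = "SV", "enucleated"
        binary = out.map(lambda v: "SV" if v == "SV" else "enucleated")
    else:
        if len(levels) != 2:
            raise ValueError(f"expected two outcome levels, got {levels}")
        pos_name, neg_name = levels
        binary = out
    cluster_names = sorted(labels.unique())
    if len(cluster_names) != 2:
        raise ValueError(f"expected two clusters, got {cluster_names}")
    for cname in cluster_names:
        if (labels == cname).sum() == 0:  # pragma: no cover
            raise ValueError(f"cluster {cname} has no members")
    ca, cb = cluster_names
    a = int(((labels == ca) & (binary == pos_name)).sum())
    b = int(((labels == ca) & (binary == neg_name)).sum())
    c = int(((labels == cb) & (binary == pos_name)).sum())
    d = int(((labels == cb) & (binary == neg_name)).sum())
    table = pd.DataFrame([[a, b], [c, d]], index=[ca, cb],
                         columns=[pos_name, neg_name])
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    p = _doubled_fisher(a, b, c, d)
    containment = (b == 0, c == 0)  # A subset of positive, B subset of negative
    return OutcomeTest(table=table, odds_ratio=float(odds), p_value=p,
                       containment=containment)


# ---------------------------------------------------------------------------
# scikit-learn estimators

class TopVariableProbeSelector(BaseEstimator, TransformerMixin):
    """Keep the k most variable probes (columns of samples x probes X)."""

    def __init__(self, k: int = 10000):
        self.k = k

    def fit(self, X, y=None) -> "TopVariableProbeSelector":
        X = pd.DataFrame(X)
        betas = BetaMatrix(X.T, validate=False)
        self.selected_ids_ = top_variable_probes(betas, k=self.k)
        self.sd_ = X.std(axis=0, ddof=1)
        sel = set(self.selected_ids_)
        self.support_ = np.array([c in sel for c in X.columns])
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "support_")
        return pd.DataFrame(X).loc[:, self.support_]


class ClassicalMDS(BaseEstimator, TransformerMixin):
    """Classical (Torgerson) multidimensional scaling transformer.

    ``dissimilarity="euclidean"`` computes sample distances from
    samples x probes input; ``"precomputed"`` takes a square distance
    matrix.
    """

    def __init__(self, n_components: int = 2,
                 dissimilarity: str = "euclidean"):
        self.n_components = n_components
        self.dissimilarity = dissimilarity

    def fit_transform(self, X, y=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.dissimilarity == "precomputed":
            D = X
        elif self.dissimilarity == "euclidean":
            D = _pairwise_distances(X, "euclidean")
        else:
            raise ValueError("dissimilarity must be euclidean or precomputed")
        self.dissimilarity_matrix_ = D
        self.embedding_ = _classical_mds(D, self.n_components)
        return self.embedding_

    def fit(self, X, y=None) -> "ClassicalMDS":
        self.fit_transform(X)
        return self


class SignatureClusterer(BaseEstimator, ClusterMixin):
    """Agglomerative two-group clusterer over a probe panel.

    Fitted attributes: ``labels_`` (ints), ``linkage_tree_``,
    ``silhouette_`` and ``weak_separation_``.
    """

    def __init__(self, n_clusters: int = 2, metric: str = "euclidean",
                 linkage: str = "complete", weak_threshold: float = 0.1):
        self.n_clusters = n_clusters
        self.metric = metric
        self.linkage = linkage
        self.weak_threshold = weak_threshold

    def fit(self, X, y=None) -> "SignatureClusterer":
        X = pd.DataFrame(X)
        betas = BetaMatrix(X.T, validate=False)
        tree = hcluster(betas, metric=self.metric, linkage=self.linkage)
        labels = cut_k(tree, self.n_clusters)
        self.linkage_tree_ = tree
        self.labels_ = labels.to_numpy()
        D = _pairwise_distances(X.to_numpy(dtype=float), self.metric)
        if 1 < len(set(self.labels_)) < len(self.labels_):
            self.silhouette_ = float(
                silhouette_score(D, self.labels_, metric="precomputed"))
        else:
            self.silhouette_ = 0.0
        self.weak_separation_ = self.silhouette_ < self.weak_threshold
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# plotting (optional, thin)

def plot_mds(coords: pd.DataFrame, groups: Mapping[str, str] | None = None,
             path=None):
    """Scatter the first two MDS axes, optionally colored by group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if groups is None:
        ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=25)
    else:
        groups = pd.Series(dict(groups)).reindex(coords.index)
        for g in sorted(groups.dropna().unique()):
            sub = coords[groups == g]
            ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=25, label=str(g))
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
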