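"""Co-expression clustering of differentially expressed features.

Normalized counts of DE features are turned into per-feature expression
proportions and arcsin(sqrt(p))-transformed; a diagonal-covariance Gaussian
mixture is fitted by EM (seeded k-means++ init, best of several restarts)
for a sweep of K; the model maximizing the integrated completed likelihood
(ICL = BIC-penalized log-likelihood minus the classification entropy) is
retained. Clusters are grouped into six families by expression tendency
(transient up/down, stable high up/down, stable low up/down), DE-lncTUs get
an average-linkage 1 - Pearson dendrogram with up/down/dynamic labels, and
annotated-term enrichment per cluster uses one-sided hypergeometric tests
with BH control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.cluster import kmeans_plusplus

from .diffexpr import bh_adjust

FAMILY_LABELS = ("CF1", "CF2", "CF3", "CF4", "CF5", "CF6")
FAMILY_TENDENCY = {
    "CF1": "transient-up",
    "CF2": "transient-down",
    "CF3": "stable-high-up",
    "CF4": "stable-low-up",
    "CF5": "stable-high-down",
    "CF6": "stable-low-down",
}


def profile_transform(counts: pd.DataFrame, eff_lib: Optional[pd.Series] = None
                      ) -> pd.DataFrame:
    """Arcsin-root transformed expression proportions.

    p_fs = normalized count of feature f in sample s / feature total;
    y = arcsin(sqrt(p)) in [0, pi/2]. Requires positive feature totals.
    """
    x = counts.to_numpy(dtype=float)
    if eff_lib is not None:
        lib = eff_lib.reindex(counts.columns).to_numpy(dtype=float)
        x = x * (lib.mean() / lib)
    totals = x.sum(axis=1)
    if (totals <= 0).any():
        bad = counts.index[totals <= 0].tolist()
        raise ValueError(f"zero-total features cannot be transformed: {bad[:5]}")
    p = x / totals[:, None]
    y = np.arcsin(np.sqrt(np.clip(p, 0.0, 1.0)))
    return pd.DataFrame(y, index=counts.index, columns=counts.columns)


@dataclass
class ClusterModel:
    """A fitted diagonal-covariance Gaussian mixture over profiles."""

    k: int
    weights: np.ndarray           # (K,)
    means: np.ndarray             # (K, d)
    variances: np.ndarray         # (K, d)
    responsibilities: np.ndarray  # (n, K)
    log_likelihood: float
    ll_trace: List[float] = field(default_factory=list)
    feature_ids: Optional[List[str]] = None

    @property
    def labels(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)

    @property
    def n_parameters(self) -> int:
        d = self.means.shape[1]
        return (self.k - 1) + 2 * self.k * d

    def bic(self, n: int) -> float:
        """BIC on the larger-is-better scale: LL - 0.5 p log n."""
        return self.log_likelihood - 0.5 * self.n_parameters * np.log(n)

    def icl(self) -> float:
        """ICL = BIC - posterior classification entropy."""
        tau = np.clip(self.responsibilities, 1e-300, 1.0)
        entropy = -np.sum(self.responsibilities * np.log(tau))
        return self.bic(self.responsibilities.shape[0]) - entropy

    def assignments(self) -> pd.DataFrame:
        idx = self.feature_ids if self.feature_ids is not None else list(range(len(self.labels)))
        return pd.DataFrame(
            {"feature": idx, "cluster": self.labels,
             "max_posterior": self.responsibilities.max(axis=1)}
        )


def _log_gauss_diag(y: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(n, K) log density matrix for a diagonal Gaussian mixture's components."""
    n, d = y.shape
    out = np.empty((n, means.shape[0]))
    for k in range(means.shape[0]):
        v = variances[k]
        out[:, k] = -0.5 * (np.sum((y - means[k]) ** 2 / v, axis=1)
                            + np.sum(np.log(2 * np.pi * v)))
    return out


_VAR_FLOOR = 1e-8


class _EmptyClusterCollapse(RuntimeError):
    """A mixture component lost all posterior mass during EM."""


def _em_once(y: np.ndarray, k: int, rng: np.random.Generator,
             tol: float, max_iter: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, List[float]]:
    n, d = y.shape
    seed = int(rng.integers(2**31 - 1))
    centers, _ = kmeans_plusplus(y, n_clusters=k, random_state=seed)
    means = centers.copy()
    global_var = y.var(axis=0) + _VAR_FLOOR
    variances = np.tile(global_var, (k, 1))
    weights = np.full(k, 1.0 / k)

    ll_prev = -np.inf
    trace: List[float] = []
    for _ in range(max_iter):
        logdens = _log_gauss_diag(y, means, variances) + np.log(weights)
        m = logdens.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logdens - m).sum(axis=1))
        ll = float(lse.sum())
        tau = np.exp(logdens - lse[:, None])
        trace.append(ll)

        nk = tau.sum(axis=0)
        if (nk < 1e-8).any():
            raise _EmptyClusterCollapse
        weights = nk / n
        means = (tau.T @ y) / nk[:, None]
        for kk in range(k):
            diff = y - means[kk]
            variances[kk] = (tau[:, kk] @ (diff**2)) / nk[kk] + _VAR_FLOOR

        if ll - ll_prev < tol * max(1.0, abs(ll)) and np.isfinite(ll_prev):
            break
        ll_prev = ll
    return weights, means, variances, tau, trace[-1], trace


_MAX_COLLAPSE_RETRIES = 10


def fit_gmm(profiles: pd.DataFrame, k: int, n_restarts: int = 10,
            seed: int = 0, tol: float = 1e-8, max_iter: int = 500) -> ClusterModel:
    """Best-of-restarts EM fit of a K-component diagonal Gaussian mixture.

    Restarts that hit an empty-cluster collapse are retried with a fresh
    perturbed initialization, up to a bounded number of attempts.
    """
    y = profiles.to_numpy(dtype=float)
    if k < 1:
        raise ValueError("K must be >= 1")
    if y.shape[0] < k:
        raise ValueError(f"need at least K={k} features, got {y.shape[0]}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        for _attempt in range(_MAX_COLLAPSE_RETRIES):
            try:
                weights, means, variances, tau, ll, trace = _em_once(y, k, rng, tol, max_iter)
                break
            except _EmptyClusterCollapse:
                continue
        else:
            raise RuntimeError(
                f"EM collapsed to an empty cluster {_MAX_COLLAPSE_RETRIES} times at K={k}"
            )
        if best is None or ll > best.log_likelihood:
            best = ClusterModel(k, weights, means, variances, tau, ll, trace,
                                feature_ids=list(profiles.index))
    return best


def select_k(profiles: pd.DataFrame, k_range: Sequence[int] = range(10, 41),
             n_restarts: int = 10, seed: int = 0) -> Tuple[ClusterModel, pd.DataFrame]:
    """Fit every K in the sweep and return the ICL-best model plus the table."""
    rows = []
    best = None
    for i, k in enumerate(k_range):
        model = fit_gmm(profiles, k, n_restarts=n_restarts, seed=seed + 7919 * i)
        icl = model.icl()
        rows.append({"k": k, "log_likelihood": model.log_likelihood,
                     "bic": model.bic(profiles.shape[0]), "icl": icl})
        if best is None or icl > best.icl():
            best = model
    return best, pd.DataFrame(rows)


def assign_families(model: ClusterModel, design_timepoints: Sequence[str],
                    sample_timepoints: Sequence[str],
                    theta: float = 0.05, theta_high: float = 0.15) -> pd.DataFrame:
    """Classify clusters into the six expression-tendency families.

    Cluster means are pooled per timepoint (arithmetic mean over replicate
    columns on the transformed scale); with d_t = centroid(T_t) -
    centroid(T0), a cluster is transient-up (CF1) if the peak deviation
    exceeds theta while the final deviation falls back within theta/2
    (mirrored for CF2), otherwise stable up/down by the sign of the final
    deviation, high vs low by |d_last| >= theta_high. Near-flat centroids
    default to the stable-low family of their sign and are flagged weak.
    """
    tps = list(design_timepoints)
    cols_per_tp = [
        [j for j, t in enumerate(sample_timepoints) if t == tp] for tp in tps
    ]
    rows = []
    for k in range(model.k):
        centroid = np.array([model.means[k][cols].mean() for cols in cols_per_tp])
        d = centroid - centroid[0]
        d_last = d[-1]
        peak = d[1:].max(initial=0.0)
        trough = d[1:].min(initial=0.0)
        weak = bool(np.max(np.abs(d)) < theta)
        if peak > theta and abs(d_last) <= theta / 2:
            fam = "CF1"
        elif trough < -theta and abs(d_last) <= theta / 2:
            fam = "CF2"
        elif d_last >= 0:
            fam = "CF3" if abs(d_last) >= theta_high else "CF4"
        else:
            fam = "CF5" if abs(d_last) >= theta_high else "CF6"
        margin = float(np.max(np.abs(d)))
        rows.append({"cluster": k, "family": fam,
                     "tendency": FAMILY_TENDENCY[fam], "margin": margin,
                     "weak": weak})
    return pd.DataFrame(rows)


def _pearson_distance(y: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance; zero-variance rows get distance 1."""
    sd = y.std(axis=1)
    z = np.zeros_like(y)
    ok = sd > 0
    z[ok] = (y[ok] - y[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    corr = (z @ z.T) / y.shape[1]
    dist = 1.0 - corr
    bad = ~ok
    dist[bad, :] = 1.0
    dist[:, bad] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, 2.0)
    n = y.shape[0]
    iu = np.triu_indices(n, k=1)
    return dist[iu]


def hclust_profiles(profiles: pd.DataFrame, de_table: pd.DataFrame
                    ) -> Tuple[np.ndarray, pd.DataFrame]:
    """Average-linkage dendrogram on 1 - Pearson plus regulation labels.

    A feature is labeled dynamic iff its significant contrasts include
    both positive and negative log2 fold changes, else up/down by sign.
    Returns the scipy linkage matrix and a per-feature label table.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 features for hierarchical clustering")
    y = profiles.to_numpy(dtype=float)
    condensed = _pearson_distance(y)
    linkage = hierarchy.linkage(condensed, method="average")

    sig = de_table.loc[de_table["call"]]
    labels = []
    for feat in profiles.index:
        lfc = sig.loc[sig["feature"] == feat, "log2fc"]
        if len(lfc) == 0:
            lab = "none"
        elif (lfc > 0).any() and (lfc < 0).any():
            lab = "dynamic"
        else:
            lab = "up" if (lfc > 0).any() else "down"
        labels.append(lab)
    zero_var = profiles.std(axis=1).to_numpy() == 0
    table = pd.DataFrame({"feature": profiles.index, "label": labels,
                          "zero_variance": zero_var})
    return linkage, table


def linkage_to_newick(linkage: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return str(leaf_names[node.id])
        ldist = node.dist - node.left.dist
        rdist = node.dist - node.right.dist
        return f"({walk(node.left)}:{ldist:g},{walk(node.right)}:{rdist:g})"

    return walk(tree) + ";"


def term_enrichment(cluster_members: Sequence[str],
                    term_map: pd.DataFrame,
                    background: Sequence[str],
                    min_entries: int = 10, fdr: float = 0.01) -> pd.DataFrame:
    """One-sided hypergeometric term enrichment of a cluster vs background.

    ``term_map`` is a two-column frame (feature, term). Terms with fewer
    than ``min_entries`` members in the cluster are dropped before testing;
    BH is applied within the cluster and rows with padj < fdr are flagged.
    """
    background = set(background)
    members = set(cluster_members)
    if not members <= background:
        missing = sorted(members - background)
        raise ValueError(f"cluster members absent from background: {missing[:5]}")
    tm = term_map[term_map["feature"].isin(background)]
    n_bg = len(background)
    n_cl = len(members)
    rows = []
    for term, grp in tm.groupby("term"):
        feats = set(grp["feature"])
        k_bg = len(feats)
        k_cl = len(feats & members)
        if k_cl < min_entries:
            continue
        # P(X >= k_cl) drawing n_cl from n_bg with k_bg successes
        p = float(stats.hypergeom.sf(k_cl - 1, n_bg, k_bg, n_cl))
        rows.append({"term": term, "count_cluster": k_cl, "count_background": k_bg,
                     "pvalue": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term", "count_cluster", "count_background", "pvalue"])
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
        out["enriched"] = out["padj"] < fdr
        out = out.sort_values("pvalue", kind="stable").reset_index(drop=True)
    else:
        out["padj"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
    return out
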