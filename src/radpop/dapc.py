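"""PCA, k-means/BIC cluster discovery, and discriminant analysis of
principal components (DAPC).

DAPC first reduces the dosage matrix with PCA (mean-imputing missing calls
with per-locus means), then finds, in retained-PC space, the linear
combinations maximizing the between-group to within-group variance ratio.
Membership posteriors for new individuals use an isotropic Gaussian around
each group centroid in discriminant space with equal priors. Per-SNP
"variable contributions" (normalized squared loadings through PCA rotation
and discriminant coefficients) rank markers by discriminatory value.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.cluster import KMeans

from .panel import GenotypePanel

logger = logging.getLogger(__name__)


class DapcError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PcaModel:
    means: np.ndarray              # per-locus centering means (= imputation values)
    rotation: np.ndarray           # loci x components, orthonormal columns
    eigenvalues: np.ndarray
    explained_var_ratio: np.ndarray
    snp_ids: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project dosages (NaN = missing, imputed with training means)."""
        Xi = np.where(np.isnan(X), self.means[None, :], X)
        return (Xi - self.means[None, :]) @ self.rotation


def _dosage_imputed(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    X = panel.dosage()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        means = np.nanmean(X, axis=0)
    means = np.nan_to_num(means, nan=0.0)
    X = np.where(np.isnan(X), means[None, :], X)
    return X, means


def fit_pca(
    panel: GenotypePanel, n_components: int | None = None
) -> tuple[PcaModel, np.ndarray]:
    """PCA of the mean-centered, mean-imputed dosage matrix via SVD."""
    if panel.n_samples < 2 or panel.n_loci < 2:
        raise DapcError("PCA needs at least 2 individuals and 2 loci")
    X, means = _dosage_imputed(panel)
    Xc = X - means[None, :]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig_all = s**2 / (panel.n_samples - 1)
    total = float(eig_all.sum())
    if n_components is None:
        n_components = len(s)
    n_components = min(n_components, len(s))
    rotation = Vt[:n_components].T
    eig = eig_all[:n_components]
    evr = eig / total if total > 0 else np.zeros_like(eig)
    model = PcaModel(
        means=means,
        rotation=rotation,
        eigenvalues=eig,
        explained_var_ratio=evr,
        snp_ids=panel.snp_ids,
    )
    scores = Xc @ rotation
    return model, scores


# ---------------------------------------------------------------------------
# find.clusters: k-means + BIC elbow
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClusterScan:
    table: pd.DataFrame            # K, WSS, BIC
    selected_k: int
    assignments: dict[int, np.ndarray]


def find_clusters(
    panel: GenotypePanel,
    k_max: int,
    n_pca: int | None = None,
    n_starts: int = 10,
    seed: int | None = None,
) -> ClusterScan:
    """k-means over 1..k_max on retained PC scores, scored by BIC.

    BIC(K) = n ln(WSS_K / n) + K ln(n). The selected K is the elbow: the
    first K whose single-step BIC decrease falls below 5% of the largest
    single-step decrease (K = 1 when BIC never decreases meaningfully).
    """
    if k_max >= panel.n_samples:
        raise DapcError("k_max must be smaller than the number of individuals")
    _, scores = fit_pca(panel)
    if n_pca is not None:
        scores = scores[:, :n_pca]
    n = scores.shape[0]
    rng = np.random.default_rng(seed)
    wss_list, assignments = [], {}
    for k in range(1, k_max + 1):
        km = KMeans(
            n_clusters=k,
            n_init=n_starts,
            algorithm="lloyd",
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(scores)
        wss_list.append(float(km.inertia_))
        assignments[k] = km.labels_.copy()
    wss = np.asarray(wss_list)
    with np.errstate(divide="ignore"):
        bic = n * np.log(wss / n) + np.arange(1, k_max + 1) * np.log(n)
    # decrease achieved by moving K -> K+1; NaN (all clusterings perfect,
    # BIC = -inf throughout) counts as no improvement
    drops = np.nan_to_num(bic[:-1] - bic[1:], nan=0.0, neginf=0.0)
    if len(drops) == 0 or np.nanmax(drops) <= 0:
        selected = 1
    else:
        max_drop = np.nanmax(drops)
        selected = k_max
        for i, d in enumerate(drops):
            if d < 0.05 * max_drop:
                selected = i + 1   # K at which improvement stalls
                break
    table = pd.DataFrame({"K": np.arange(1, k_max + 1), "WSS": wss, "BIC": bic})
    return ClusterScan(table=table, selected_k=int(selected), assignments=assignments)


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

def default_n_pca(n_samples: int, n_groups: int) -> int:
    """Conservative retained-PC default limiting overfitting."""
    return max(1, min(n_samples // 3, n_samples - n_groups - 1))


@dataclasses.dataclass
class DapcModel:
    pca: PcaModel
    n_pca: int
    coef: np.ndarray               # PC-space -> discriminant-space (n_pca x n_da)
    centroids: np.ndarray          # groups x n_da
    groups: list[str]
    var_contrib: pd.Series         # per-SNP normalized squared loadings

    @property
    def n_da(self) -> int:
        return self.coef.shape[1]

    def discriminant_scores(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(X)[:, : self.n_pca] @ self.coef

    def save(self, path) -> None:
        """Serialize to a single versioned JSON file (documented schema:
        schema_version, groups, n_pca, snp_ids, means, rotation, coef,
        centroids, var_contrib)."""
        import json

        payload = {
            "schema_version": 1,
            "groups": self.groups,
            "n_pca": self.n_pca,
            "snp_ids": [str(s) for s in self.pca.snp_ids],
            "means": self.pca.means.tolist(),
            "rotation": self.pca.rotation[:, : self.n_pca].tolist(),
            "eigenvalues": self.pca.eigenvalues[: self.n_pca].tolist(),
            "explained_var_ratio":
                self.pca.explained_var_ratio[: self.n_pca].tolist(),
            "coef": self.coef.tolist(),
            "centroids": self.centroids.tolist(),
            "var_contrib": self.var_contrib.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "DapcModel":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema_version") != 1:
            raise DapcError(
                f"unsupported DapcModel schema {payload.get('schema_version')!r}"
            )
        snp_ids = np.asarray(payload["snp_ids"], dtype=object)
        pca = PcaModel(
            means=np.asarray(payload["means"]),
            rotation=np.asarray(payload["rotation"]),
            eigenvalues=np.asarray(payload["eigenvalues"]),
            explained_var_ratio=np.asarray(payload["explained_var_ratio"]),
            snp_ids=snp_ids,
        )
        return cls(
            pca=pca,
            n_pca=int(payload["n_pca"]),
            coef=np.asarray(payload["coef"]),
            centroids=np.asarray(payload["centroids"]),
            groups=list(payload["groups"]),
            var_contrib=pd.Series(
                np.asarray(payload["var_contrib"]), index=snp_ids,
                name="contribution",
            ),
        )


def fit_dapc(
    panel: GenotypePanel,
    labels=None,
    n_pca: int | None = None,
    n_da: int | None = None,
) -> DapcModel:
    """Fit DAPC on a panel with the given group labels (default: populations).

    Discriminant axes solve the generalized eigenproblem B v = λ W v in
    retained-PC space, with the pooled within-group scatter W ridge-
    stabilized when near-singular.
    """
    if labels is None:
        labels = panel.populations.to_numpy()
    labels = np.asarray(labels, dtype=object)
    groups, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        small = groups[counts < 2].tolist()
        raise DapcError(f"group(s) {small} have fewer than 2 members")
    G = len(groups)
    pca_model, scores = fit_pca(panel)
    if n_pca is None:
        n_pca = default_n_pca(panel.n_samples, G)
    n_pca = min(n_pca, scores.shape[1])
    S = scores[:, :n_pca]

    max_da = min(G - 1, n_pca)
    if n_da is None:
        n_da = max_da
    elif n_da > max_da:
        warnings.warn(f"n_da={n_da} clipped to {max_da} (at most K-1 axes)")
        n_da = max_da

    grand = S.mean(axis=0)
    W = np.zeros((n_pca, n_pca))
    B = np.zeros((n_pca, n_pca))
    for g in groups:
        rows = S[labels == g]
        mu = rows.mean(axis=0)
        dev = rows - mu
        W += dev.T @ dev
        d = (mu - grand)[:, None]
        B += len(rows) * (d @ d.T)
    W /= max(panel.n_samples - G, 1)
    B /= max(G - 1, 1)
    ridge = 1e-8 * np.trace(W) / n_pca if np.trace(W) > 0 else 1e-8
    W_reg = W + ridge * np.eye(n_pca)
    eigval, eigvec = linalg.eigh(B, W_reg)
    order = np.argsort(eigval)[::-1][:n_da]
    coef = eigvec[:, order]

    disc = S @ coef
    centroids = np.vstack([disc[labels == g].mean(axis=0) for g in groups])

    loadings = pca_model.rotation[:, :n_pca] @ coef     # loci x n_da
    contrib = (loadings**2).sum(axis=1)
    total = contrib.sum()
    contrib = contrib / total if total > 0 else contrib
    return DapcModel(
        pca=pca_model,
        n_pca=n_pca,
        coef=coef,
        centroids=centroids,
        groups=[str(g) for g in groups],
        var_contrib=pd.Series(contrib, index=pca_model.snp_ids, name="contribution"),
    )


def predict_membership(
    model: DapcModel, panel: GenotypePanel
) -> tuple[pd.DataFrame, pd.Series]:
    """Membership posteriors and hard assignments for new individuals.

    The new panel is matched to the model's locus set by snp_id; model loci
    absent from the panel are imputed with the training means, extra panel
    loci are ignored (with a warning). Posterior for group g is proportional
    to exp(-d_g^2 / 2) with d_g the Euclidean distance to the group centroid
    in discriminant space (equal priors).
    """
    pos = {s: i for i, s in enumerate(panel.snp_ids)}
    model_ids = model.pca.snp_ids
    shared = [s for s in model_ids if s in pos]
    if not shared:
        raise DapcError("new panel shares no loci with the model")
    extra = len(pos) - len(shared)
    if extra > 0:
        warnings.warn(f"ignoring {extra} panel loci unknown to the model")
    X = np.full((panel.n_samples, len(model_ids)), np.nan)
    dos = panel.dosage()
    for j, s in enumerate(model_ids):
        if s in pos:
            X[:, j] = dos[:, pos[s]]
    disc = model.discriminant_scores(X)
    d2 = ((disc[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    logw = -0.5 * (d2 - d2.min(axis=1, keepdims=True))
    w = np.exp(logw)
    post = w / w.sum(axis=1, keepdims=True)
    post_df = pd.DataFrame(post, index=panel.samples, columns=model.groups)
    best = post.argmax(axis=1)
    ties = (post == post.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.warning(
            "%d individual(s) had tied posteriors; first group in order kept",
            int(ties.sum()),
        )
    hard = pd.Series(
        [model.groups[b] for b in best], index=panel.samples, name="assigned"
    )
    return post_df, hard
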