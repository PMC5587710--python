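"""Bootstrap-stabilised NMF signature extraction.

The extraction step follows the resampling scheme popularised by the
WTSI mutational-signature framework: each bootstrap multinomially
resamples every sample's mutations, NMF with multiplicative updates
under the generalized Kullback-Leibler divergence factorises the
resampled catalog, and the pooled bootstrap signatures are clustered by
cosine distance under a one-signature-per-run matching constraint.
The average silhouette width of that clustering is the *stability*
s(k); the number of signatures K is chosen as the largest k whose
stability clears the cutoff (0.85 by default).
Exposures are then refit on the original catalog by fixed-signature
multiplicative KL updates, the loss that matches count noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import silhouette_score

from .catalog import CLASS_LABELS, N_CLASSES

_FLOOR = 1e-12

DEFAULT_CATEGORY_MAP = {
    "APOBEC": ("Signature 2", "Signature 13", "SBS2like", "SBS13like"),
    "aging": ("Signature 1A", "Signature 1B", "SBS1Alike", "SBS1Blike"),
    "smoking": ("Signature 4", "Signature 5", "SBS4like", "SBS5like"),
}


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _FLOOR)
    mask = V > 0
    return float(np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum())


def kl_nmf(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 10000,
    tol: float = 1e-8,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Multiplicative-update NMF minimising generalized KL divergence.

    Starts from random nonnegative factors (or the factors in ``init``);
    entries are floored at 1e-12 to keep the updates well-defined.  The
    objective is non-increasing under these updates; iteration stops
    when the relative improvement over a 10-iteration window falls below
    ``tol``.  Returns (W, H, divergence) with W of shape (96, k).
    """
    V = np.asarray(V, dtype=float)
    m, n = V.shape
    if init is not None:
        W = np.maximum(np.asarray(init[0], dtype=float).copy(), _FLOOR)
        H = np.maximum(np.asarray(init[1], dtype=float).copy(), _FLOOR)
    else:
        W = np.maximum(rng.random((m, k)), _FLOOR)
        H = np.maximum(rng.random((k, n)), _FLOOR)
    prev = _kl_divergence(V, W @ H)
    for it in range(max_iter):
        WH = np.maximum(W @ H, _FLOOR)
        W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1), _FLOOR)
        W = np.maximum(W, _FLOOR)
        WH = np.maximum(W @ H, _FLOOR)
        H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0)[:, None], _FLOOR)
        H = np.maximum(H, _FLOOR)
        if (it + 1) % 10 == 0:
            cur = _kl_divergence(V, W @ H)
            if prev - cur <= tol * max(abs(prev), 1.0):
                break
            prev = cur
    return W, H, _kl_divergence(V, W @ H)


def _kl_refit_exposures(
    V: np.ndarray, P: np.ndarray, max_iter: int = 10000, tol: float = 1e-8
) -> np.ndarray:
    """H-only multiplicative KL updates with the signatures held fixed."""
    rng = np.random.default_rng(0)
    k, n = P.shape[1], V.shape[1]
    H = np.maximum(np.full((k, n), V.sum() / max(k * n, 1)), _FLOOR)
    prev = _kl_divergence(V, P @ H)
    for it in range(max_iter):
        WH = np.maximum(P @ H, _FLOOR)
        H *= P.T @ (V / WH) / np.maximum(P.sum(axis=0)[:, None], _FLOOR)
        H = np.maximum(H, _FLOOR)
        if (it + 1) % 10 == 0:
            cur = _kl_divergence(V, P @ H)
            if prev - cur <= tol * max(abs(prev), 1.0):
                break
            prev = cur
    return H


def _cosine_distance_matrix(X: np.ndarray) -> np.ndarray:
    D = cdist(X, X, metric="cosine")
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _matched_clusters(X: np.ndarray, k: int, n_runs: int, max_iter: int = 100) -> np.ndarray:
    """Partition bootstrap signatures with one-per-run cluster matching.

    ``X`` stacks the k signatures of each of ``n_runs`` NMF runs
    (run-major).  Each run's k vectors are assigned to the k clusters
    bijectively (Hungarian matching on cosine distance to the current
    centroids), so a cluster can never absorb two signatures from the
    same run — a spurious extra component then collects each run's
    unstable leftover vector and its silhouette collapses, which is
    what makes the stability criterion discriminate.
    """
    from scipy.optimize import linear_sum_assignment

    centroids = X[:k].copy()  # first run's signatures seed the clusters
    labels = np.zeros(len(X), dtype=int)
    for _ in range(max_iter):
        new_labels = np.empty_like(labels)
        for r in range(n_runs):
            block = X[r * k : (r + 1) * k]
            D = cdist(block, centroids, metric="cosine")
            rows, cols = linear_sum_assignment(np.nan_to_num(D, nan=1.0))
            new_labels[r * k + rows] = cols
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for c in range(k):
            members = X[labels == c]
            if len(members):
                centroids[c] = members.mean(axis=0)
    return labels


@dataclass
class StabilityResult:
    k: int
    stability: float
    reconstruction_error: float


@dataclass
class ExtractionResult:
    """Signatures P (96 x k, column-stochastic), exposures E (k x S),
    stability diagnostics and the pooled bootstrap signatures."""

    signatures: pd.DataFrame
    exposures: pd.DataFrame
    stability: StabilityResult
    bootstrap_signatures: np.ndarray = field(repr=False)
    cluster_labels: np.ndarray = field(repr=False)


def _as_catalog(M) -> tuple[np.ndarray, list]:
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float), list(M.columns)
    M = np.asarray(M, dtype=float)
    return M, [f"S{j}" for j in range(M.shape[1])]


def nmf_extract(
    M,
    k: int,
    n_restarts: int = 10,
    n_bootstraps: int = 100,
    seed: int = 0,
    max_iter: int = 10000,
    tol: float = 1e-8,
) -> ExtractionResult:
    """Bootstrap NMF at a fixed number of signatures ``k``.

    Every bootstrap resamples each catalog column multinomially (sample
    totals preserved), factorises it keeping the best of ``n_restarts``
    random initialisations, and contributes k unit-sum signature
    vectors.  The pooled vectors are partition-clustered on cosine
    distance with one signature per run per cluster; stability is the
    average silhouette width of that clustering (for k = 1, the mean
    cosine similarity to the centroid).
    """
    V, samples = _as_catalog(M)
    if V.shape[0] != N_CLASSES:
        raise ValueError(f"catalog must have {N_CLASSES} rows")
    S = V.shape[1]
    if k < 1 or k > min(N_CLASSES, S):
        raise ValueError(f"k={k} outside 1..min(96, {S})")
    if (V.sum(axis=0) > 0).sum() < k:
        raise ValueError("fewer nonzero samples than signatures requested")
    rng = np.random.default_rng(seed)
    boot_sigs = []
    for _ in range(n_bootstraps):
        Vb = np.empty_like(V)
        for j in range(S):
            tot = V[:, j].sum()
            if tot <= 0:
                Vb[:, j] = 0.0
                continue
            p = V[:, j] / tot
            Vb[:, j] = rng.multinomial(int(round(tot)), p)
        best = None
        for _ in range(n_restarts):
            W, H, d = kl_nmf(Vb, k, rng, max_iter=max_iter, tol=tol)
            if best is None or d < best[2]:
                best = (W, H, d)
        W = best[0]
        boot_sigs.append(W / np.maximum(W.sum(axis=0), _FLOOR))
    X = np.hstack(boot_sigs).T  # (k * n_bootstraps, 96)

    D = _cosine_distance_matrix(X)
    if k == 1:
        centroid = X.mean(axis=0)
        centroid /= max(centroid.sum(), _FLOOR)
        sims = 1.0 - cdist(X, centroid[None, :], metric="cosine").ravel()
        labels = np.zeros(len(X), dtype=int)
        stability = float(sims.mean())
    else:
        labels = _matched_clusters(X, k, n_bootstraps)
        if len(np.unique(labels)) < 2:
            stability = 0.0
        else:
            stability = float(silhouette_score(D, labels, metric="precomputed"))

    P = np.zeros((N_CLASSES, k))
    for c in range(k):
        members = X[labels == c]
        P[:, c] = members.mean(axis=0) if len(members) else _FLOOR
    P /= np.maximum(P.sum(axis=0), _FLOOR)
    sig_names = [f"extracted_{c + 1}" for c in range(k)]
    Pdf = pd.DataFrame(P, index=list(CLASS_LABELS), columns=sig_names)
    # exposures: Poisson/KL refit with the consensus signatures held
    # fixed — the loss that matches count noise, unlike least squares
    # which misweights the many low-count classes of diffuse signatures
    E_arr = _kl_refit_exposures(V, P, max_iter=max_iter, tol=tol)
    E = pd.DataFrame(E_arr, index=sig_names, columns=samples)
    recon = float(np.linalg.norm(V - P @ E.to_numpy()) / max(np.linalg.norm(V), _FLOOR))
    return ExtractionResult(
        signatures=Pdf,
        exposures=E,
        stability=StabilityResult(k=k, stability=stability, reconstruction_error=recon),
        bootstrap_signatures=X,
        cluster_labels=labels,
    )


@dataclass
class SelectionResult:
    chosen_k: int
    below_cutoff: bool
    diagnostics: pd.DataFrame
    results: dict

    @property
    def best(self) -> ExtractionResult:
        return self.results[self.chosen_k]


def select_signature_number(
    M,
    k_range,
    stability_cutoff: float = 0.85,
    **kwargs,
) -> SelectionResult:
    """Pick the number of signatures by bootstrap stability.

    K is the largest k in ``k_range`` with stability >= cutoff; when no
    k qualifies the argmax-stability k is returned flagged
    ``below_cutoff``.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    results = {k: nmf_extract(M, k, **kwargs) for k in ks}
    diag = pd.DataFrame(
        {
            "k": ks,
            "stability": [results[k].stability.stability for k in ks],
            "reconstruction_error": [results[k].stability.reconstruction_error for k in ks],
        }
    )
    passing = [k for k in ks if results[k].stability.stability >= stability_cutoff]
    if passing:
        return SelectionResult(max(passing), False, diag, results)
    best_k = ks[int(np.argmax(diag.stability.to_numpy()))]
    return SelectionResult(best_k, True, diag, results)


def match_to_reference(P, reference_catalog: pd.DataFrame) -> pd.DataFrame:
    """Best cosine match of each extracted signature in the reference set.

    Returns a frame (one row per extracted signature) with the matched
    name and cosine similarity; the full similarity matrix is attached
    as ``.attrs['similarity']``.
    """
    Pdf = P if isinstance(P, pd.DataFrame) else pd.DataFrame(P)
    if Pdf.shape[0] != N_CLASSES or reference_catalog.shape[0] != N_CLASSES:
        raise ValueError(f"signatures and reference must have {N_CLASSES} rows")
    ref = reference_catalog / reference_catalog.sum(axis=0)
    A = Pdf.to_numpy(dtype=float).T
    B = ref.to_numpy(dtype=float).T
    sim = 1.0 - cdist(A, B, metric="cosine")
    sim = np.nan_to_num(sim, nan=0.0)
    best = sim.argmax(axis=1)
    out = pd.DataFrame(
        {
            "extracted": list(Pdf.columns),
            "matched": [ref.columns[j] for j in best],
            "cosine": sim[np.arange(len(best)), best],
        }
    )
    out.attrs["similarity"] = pd.DataFrame(sim, index=list(Pdf.columns), columns=list(ref.columns))
    return out


def summarize_categories(
    matches: pd.DataFrame,
    E: pd.DataFrame,
    category_map: dict | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum per-sample exposures of signatures within functional categories.

    Exposures are normalised per sample before summing; the cohort-wide
    value is the mutation-count-weighted mean of the per-sample
    fractions (weights = exposure column totals).
    """
    cmap = category_map or DEFAULT_CATEGORY_MAP
    name_to_cat = {}
    for cat, names in cmap.items():
        for n in names:
            name_to_cat[n] = cat
    cats = list(cmap) + ["other"]
    sig_cat = [name_to_cat.get(m, "other") for m in matches["matched"]]
    En = E.to_numpy(dtype=float)
    totals = En.sum(axis=0)
    frac = np.divide(En, totals, out=np.zeros_like(En), where=totals > 0)
    per_sample = pd.DataFrame(0.0, index=E.columns, columns=cats)
    for cat, row in zip(sig_cat, frac):
        per_sample[cat] += row
    w = totals / totals.sum() if totals.sum() > 0 else np.full(len(totals), 1.0 / len(totals))
    cohort = pd.Series(per_sample.to_numpy().T @ w, index=cats, name="cohort_fraction")
    return per_sample, cohort


def refit_exposures_nnls(M, P) -> pd.DataFrame:
    """Nonnegative least-squares refit of each sample on fixed signatures."""
    V, samples = _as_catalog(M)
    Pm = P.to_numpy(dtype=float) if isinstance(P, pd.DataFrame) else np.asarray(P, float)
    names = list(P.columns) if isinstance(P, pd.DataFrame) else [f"sig{j}" for j in range(Pm.shape[1])]
    E = np.zeros((Pm.shape[1], V.shape[1]))
    resid = np.zeros(V.shape[1])
    for j in range(V.shape[1]):
        E[:, j], resid[j] = nnls(Pm, V[:, j])
    out = pd.DataFrame(E, index=names, columns=samples)
    out.attrs["residual"] = resid
    return out


def correlate_exposure_expression(
    exposures,
    tpm,
    sample_subset=None,
) -> dict:
    """Spearman correlation between a per-sample exposure vector and a
    per-sample expression vector over an optional sample subset.

    Uses average ranks for ties and the t-approximation p-value; a
    constant input leaves rho undefined (flagged)."""
    from scipy import stats

    x = pd.Series(exposures)
    y = pd.Series(tpm)
    common = x.index.intersection(y.index)
    if sample_subset is not None:
        common = common.intersection(pd.Index(sample_subset))
    x, y = x.loc[common].astype(float), y.loc[common].astype(float)
    if len(common) < 3:
        raise ValueError("need at least 3 paired observations")
    if x.nunique() <= 1 or y.nunique() <= 1:
        return {"rho": float("nan"), "p": float("nan"), "n": len(common), "constant_input": True}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": len(common), "constant_input": False}


class BootstrapSignatureNMF(BaseEstimator, TransformerMixin):
    """Scikit-learn style wrapper around bootstrap signature extraction.

    Follows the decomposition API: ``X`` has shape (n_samples, 96) with
    per-class mutation counts in COSMIC class order.  ``fit`` extracts
    signatures (choosing k by stability when ``k_range`` is given),
    ``transform`` returns NNLS exposures of shape (n_samples, k).

    Attributes
    ----------
    components_ : ndarray of shape (k, 96)
        Extracted column-stochastic signatures (rows sum to 1).
    stability_ : float
        Silhouette stability of the retained k.
    n_signatures_ : int
        The retained number of signatures.
    selection_ : SelectionResult or None
        Full per-k diagnostics when ``k_range`` was used.
    """

    def __init__(
        self,
        k: int | None = None,
        k_range=None,
        stability_cutoff: float = 0.85,
        n_restarts: int = 10,
        n_bootstraps: int = 100,
        max_iter: int = 10000,
        tol: float = 1e-8,
        random_state: int = 0,
    ):
        self.k = k
        self.k_range = k_range
        self.stability_cutoff = stability_cutoff
        self.n_restarts = n_restarts
        self.n_bootstraps = n_bootstraps
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _catalog(self, X) -> pd.DataFrame:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_CLASSES:
            raise ValueError(f"X must be (n_samples, {N_CLASSES})")
        return pd.DataFrame(X.T, index=list(CLASS_LABELS))

    def fit(self, X, y=None):
        if (self.k is None) == (self.k_range is None):
            raise ValueError("specify exactly one of k or k_range")
        M = self._catalog(X)
        kwargs = dict(
            n_restarts=self.n_restarts,
            n_bootstraps=self.n_bootstraps,
            seed=self.random_state,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        if self.k_range is not None:
            sel = select_signature_number(
                M, self.k_range, stability_cutoff=self.stability_cutoff, **kwargs
            )
            res, self.selection_ = sel.best, sel
        else:
            res, self.selection_ = nmf_extract(M, self.k, **kwargs), None
        self.result_ = res
        self.components_ = res.signatures.to_numpy().T
        self.n_signatures_ = res.signatures.shape[1]
        self.stability_ = res.stability.stability
        self.reconstruction_err_ = res.stability.reconstruction_error
        return self

    def transform(self, X):
        if not hasattr(self, "components_"):
            raise ValueError("estimator is not fitted")
        M = self._catalog(X)
        E = refit_exposures_nnls(M, pd.DataFrame(self.components_.T, index=list(CLASS_LABELS)))
        return E.to_numpy().T
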