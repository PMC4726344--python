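"""De novo mutational-signature extraction by KL-NMF with bootstrap stability.

A cohort's samples x 96 catalog ``V`` is modelled as a non-negative mixture
``V ~ E P`` of ``k`` signature profiles (rows of ``P``, each a normalized
96-vector) weighted by per-sample exposures ``E``. Profiles and exposures
are estimated by non-negative matrix factorization under the generalized
Kullback-Leibler divergence with Lee-Seung multiplicative updates.

Because NMF solutions depend on the realized counts, the number of
signatures is chosen by a stability criterion: each sample's catalog row is
re-drawn from a multinomial (a parametric bootstrap that preserves the
sample's mutation load), NMF is run on each replicate, the pooled replicate
profiles are clustered under cosine distance, and the mean silhouette width
of the clustering measures how reproducibly ``k`` signatures are recovered.
The selected ``k`` is the largest one whose stability clears a threshold.

The estimators follow scikit-learn conventions (``fit``, ``transform``,
``get_params``; fitted attributes carry a trailing underscore) and accept
either a :class:`~platsig.catalog.Catalog96` or a plain array.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_samples

from .catalog import Catalog96
from .channels import CHANNEL_LABELS, PLATINUM_CHANNELS

_EPS = np.finfo(float).tiny


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, Catalog96):
        return np.asarray(X.counts, dtype=float), list(X.sample_ids)
    X = np.asarray(X, dtype=float)
    return X, [f"S{i}" for i in range(X.shape[0])]


def _sample_key(sample_id: str) -> int:
    """Stable 32-bit key for a sample id, used to seed per-sample streams."""
    return zlib.crc32(sample_id.encode())


def generalized_kl(V: np.ndarray, WH: np.ndarray) -> float:
    """D(V || WH) = sum v*log(v/wh) - v + wh, with 0*log(0) = 0."""
    WH = np.maximum(WH, _EPS)
    pos = V > 0
    d = WH.sum() - V.sum()
    d += float((V[pos] * np.log(V[pos] / WH[pos])).sum())
    return float(d)


def cosine_similarity(a, b) -> float:
    """Cosine similarity between two non-negative profiles (1 iff proportional)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def platinum_score(profile) -> float:
    """Weight a normalized profile places on the platinum-diagnostic channels.

    The platinum process concentrates C>A transversions at CpCpA and CpCpG
    (CCR) contexts; the score is the summed weight of those two channels.
    """
    profile = np.asarray(profile, dtype=float).ravel()
    idx = [CHANNEL_LABELS.index(c) for c in PLATINUM_CHANNELS]
    return float(profile[idx].sum())


def bootstrap_catalog(catalog: Catalog96, seed: int) -> Catalog96:
    """Multinomial bootstrap of each sample's 96-vector.

    Each row is redrawn from Multinomial(n = row sum, p = normalized row),
    so per-sample totals are preserved exactly. Draws are keyed by sample id
    (not row position), making the resample invariant to row order.
    """
    counts = np.empty_like(np.asarray(catalog.counts, dtype=float))
    for i, sid in enumerate(catalog.sample_ids):
        row = catalog.counts[i]
        total = row.sum()
        if total <= 0:
            warnings.warn(f"sample {sid!r} has zero mutations; returned unchanged")
            counts[i] = row
            continue
        rng = np.random.default_rng([int(seed), _sample_key(sid)])
        counts[i] = rng.multinomial(int(round(total)), row / total)
    return Catalog96(counts, list(catalog.sample_ids))


class KLNMF(BaseEstimator, TransformerMixin):
    """Non-negative factorization V ~ W H under generalized KL divergence.

    Multiplicative (Lee-Seung) updates; the objective is non-increasing at
    every iteration and the run stops when its relative change falls below
    ``tol`` or after ``max_iter`` iterations. After fitting, rows of
    ``components_`` are L1-normalized signature profiles with the exposure
    matrix rescaled so the product ``W H`` is unchanged.

    Random initialization is drawn from ``random_state``; when per-sample
    keys are supplied to :meth:`fit`, each exposure row is initialized from
    a stream keyed by its sample id so that permuting input rows permutes
    the solution's exposure rows while leaving the profiles unchanged.
    """

    def __init__(
        self,
        n_components: int = 2,
        max_iter: int = 10_000,
        tol: float = 1e-9,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- initialization -------------------------------------------------
    def _init_W(self, V, sample_keys, seed_tags):
        n, k = V.shape[0], self.n_components
        scale = max(V.mean(), 1.0) / k
        if sample_keys is None:
            rng = np.random.default_rng([*seed_tags, 0])
            return scale * (0.5 + rng.random((n, k)))
        W = np.empty((n, k))
        for i, key in enumerate(sample_keys):
            rng = np.random.default_rng([*seed_tags, 0, key])
            W[i] = scale * (0.5 + rng.random(k))
        return W

    def _init_H(self, V, seed_tags):
        rng = np.random.default_rng([*seed_tags, 1])
        return 0.5 + rng.random((self.n_components, V.shape[1]))

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y=None, sample_keys: Sequence[int] | None = None):
        V, _ = _as_matrix(X)
        self._validate(V)
        seed_tags = (0 if self.random_state is None else int(self.random_state),)
        W = self._init_W(V, sample_keys, seed_tags)
        H = self._init_H(V, seed_tags)
        W, H, curve = self._iterate(V, W, H, update_W=True, update_H=True)
        self.components_, self.exposures_ = self._normalize(W, H)
        self.objective_curve_ = curve
        self.reconstruction_err_ = curve[-1]
        self.n_iter_ = len(curve) - 1
        return self

    def fit_transform(self, X, y=None, **kw):
        self.fit(X, **kw)
        return self.exposures_

    def transform(self, X, sample_keys: Sequence[int] | None = None) -> np.ndarray:
        """Non-negative KL fit of exposures with fitted profiles held fixed."""
        V, _ = _as_matrix(X)
        self._validate(V)
        H = self.components_
        seed_tags = (0 if self.random_state is None else int(self.random_state), 2)
        W = self._init_W(V, sample_keys, seed_tags)
        W, _, _ = self._iterate(V, W, H.copy(), update_W=True, update_H=False)
        return W

    def _validate(self, V: np.ndarray) -> None:
        if not np.isfinite(V).all():
            raise ValueError("input matrix contains non-finite entries")
        if (V < 0).any():
            raise ValueError("input matrix must be non-negative")
        if self.n_components > min(V.shape):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(matrix shape)={min(V.shape)}"
            )
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

    def _iterate(self, V, W, H, update_W: bool, update_H: bool):
        WH = W @ H
        curve = [generalized_kl(V, WH)]
        for _ in range(self.max_iter):
            if update_W:
                np.maximum(WH, _EPS, out=WH)
                W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1), _EPS)
                WH = W @ H
            if update_H:
                np.maximum(WH, _EPS, out=WH)
                H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0)[:, None], _EPS)
                WH = W @ H
            obj = generalized_kl(V, WH)
            prev = curve[-1]
            curve.append(obj)
            if obj > prev + 1e-9 * max(abs(prev), 1.0):
                raise AssertionError(
                    f"KL objective increased: {prev} -> {obj}"
                )
            if abs(prev - obj) <= self.tol * max(abs(prev), 1e-300):
                break
        return W, H, curve

    @staticmethod
    def _normalize(W, H):
        scale = H.sum(axis=1)
        scale = np.maximum(scale, _EPS)
        return H / scale[:, None], W * scale[None, :]


@dataclass
class ReferenceSignatures:
    """A named collection of normalized 96-channel reference profiles."""

    names: list[str]
    profiles: np.ndarray  # (n_refs, 96), rows sum to 1

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        sums = self.profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("reference profiles must be normalized")
        self.profiles = self.profiles / sums[:, None]  # exact renormalization

    def __getitem__(self, name: str) -> np.ndarray:
        return self.profiles[self.names.index(name)]


def load_reference_signatures(path: str | Path | None = None) -> ReferenceSignatures:
    """Load the bundled (or a user-supplied) reference-signature TSV.

    The bundled set consists of synthetic idealized profiles — a platinum
    profile concentrated on C>A at CpCpA/CpCpG plus APOBEC-, age-, UV- and
    smoking-like profiles — constructed for annotation and testing, not
    taken from any external catalog. Layout: first column channel label,
    one column per named signature.
    """
    if path is None:
        ref = resources.files("platsig.data") / "reference_signatures_synthetic.tsv"
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t", index_col=0)
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    frame = frame.reindex(list(CHANNEL_LABELS))
    if frame.isna().any().any():
        raise ValueError("reference table does not cover all 96 channels")
    return ReferenceSignatures(list(frame.columns), frame.to_numpy().T)


class SignatureExtractor(BaseEstimator):
    """Bootstrap-stabilized signature extraction at a fixed ``k``.

    Fitting runs KL-NMF on ``n_bootstrap`` multinomial resamples of the
    catalog, pools the resulting ``n_bootstrap * k`` profiles, and
    partitions them into ``k`` clusters under cosine distance with the
    constraint that every bootstrap replicate contributes exactly one
    profile to each cluster (an average-linkage hierarchical partition
    refined by per-replicate optimal matching to the cluster centroids).
    The constraint is what makes the stability measure honest: with more
    clusters than real mutational processes, a replicate's redundant
    near-duplicate profiles must be forced into different clusters, mixing
    them and collapsing the silhouette. The mean silhouette width of the
    partition is reported as the stability of the ``k``-signature solution. Consensus profiles are the normalized
    cluster centroids; exposures are refit to the original catalog with the
    consensus profiles held fixed.

    Attributes (after ``fit``)
    --------------------------
    profiles_ : (k, 96) array, rows normalized to 1
    exposures_ : (n_samples, k) array, mutation counts attributed per signature
    stability_ : float, mean silhouette width in [-1, 1]
    per_signature_stability_ : (k,) array
    reconstruction_err_ : float, generalized KL of the consensus fit
    degenerate_ : bool, True if clustering could not fill all k clusters
    """

    def __init__(
        self,
        n_signatures: int = 5,
        n_bootstrap: int = 100,
        random_state: int | None = None,
        max_iter: int = 10_000,
        tol: float = 1e-9,
    ):
        self.n_signatures = n_signatures
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        V, sample_ids = _as_matrix(X)
        catalog = X if isinstance(X, Catalog96) else Catalog96(V, sample_ids)
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be >= 2")
        k = self.n_signatures
        seed = 0 if self.random_state is None else int(self.random_state)
        keys = [_sample_key(s) for s in sample_ids]

        pooled = np.empty((self.n_bootstrap * k, 96))
        for b in range(self.n_bootstrap):
            boot = bootstrap_catalog(catalog, seed=self._boot_seed(seed, b))
            nmf = KLNMF(
                k, self.max_iter, self.tol, random_state=self._nmf_seed(seed, b)
            ).fit(boot.counts, sample_keys=keys)
            pooled[b * k : (b + 1) * k] = nmf.components_

        labels, centroids, degenerate = self._cluster(pooled)
        self.degenerate_ = degenerate
        self.per_signature_stability_, self.stability_ = self._silhouette(
            pooled, labels, k, degenerate
        )
        self.profiles_ = centroids / np.maximum(centroids.sum(axis=1)[:, None], _EPS)

        refit = KLNMF(k, self.max_iter, self.tol, random_state=seed)
        refit.components_ = self.profiles_
        self.exposures_ = refit.transform(V, sample_keys=keys)
        self.reconstruction_err_ = generalized_kl(V, self.exposures_ @ self.profiles_)
        self.sample_ids_ = sample_ids
        self.n_bootstrap_profiles_ = pooled.shape[0]
        return self

    @staticmethod
    def _boot_seed(seed: int, b: int) -> int:
        return int(np.random.default_rng([seed, 10, b]).integers(2**31))

    @staticmethod
    def _nmf_seed(seed: int, b: int) -> int:
        return int(np.random.default_rng([seed, 11, b]).integers(2**31))

    def _cluster(self, pooled):
        """Partition pooled bootstrap profiles into k clusters (cosine).

        Average-linkage hierarchical clustering gives a deterministic,
        initialization-free starting partition; it is then refined by
        repeatedly matching each replicate's k profiles one-to-one onto the
        current centroids (Hungarian assignment on cosine distance) until
        the labelling is stable. Every cluster ends with exactly one member
        per replicate, so no cluster can be empty.
        """
        k = self.n_signatures
        unit = pooled / np.maximum(np.linalg.norm(pooled, axis=1, keepdims=True), _EPS)
        if k == 1:
            labels = np.zeros(len(pooled), dtype=int)
            return labels, pooled.mean(axis=0, keepdims=True), False
        labels = AgglomerativeClustering(
            n_clusters=k, metric="cosine", linkage="average"
        ).fit_predict(unit)
        for _ in range(100):
            # agglomerative clusters are non-empty, and matched clusters have
            # exactly one member per replicate, so every mean is well defined
            centroids = np.vstack([pooled[labels == j].mean(axis=0) for j in range(k)])
            cu = centroids / np.maximum(
                np.linalg.norm(centroids, axis=1, keepdims=True), _EPS
            )
            new_labels = np.empty_like(labels)
            for b in range(self.n_bootstrap):
                block = slice(b * k, (b + 1) * k)
                cost = 1.0 - unit[block] @ cu.T
                rows, cols = linear_sum_assignment(cost)
                new_labels[block][rows] = cols
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        centroids = np.vstack([pooled[labels == j].mean(axis=0) for j in range(k)])
        return labels, centroids, False

    def _silhouette(self, pooled, labels, k, degenerate):
        if degenerate:
            return np.full(k, np.nan), -1.0
        if k == 1:
            # silhouette is undefined for one cluster; report the mean cosine
            # similarity to the centroid instead (1 = perfectly reproducible)
            c = pooled.mean(axis=0)
            sims = np.array([cosine_similarity(p, c) for p in pooled])
            return np.array([float(sims.mean())]), float(sims.mean())
        sil = silhouette_samples(pooled, labels, metric="cosine")
        per = np.array([float(sil[labels == j].mean()) for j in range(k)])
        return per, float(sil.mean())


def extract_signatures(
    catalog: Catalog96,
    k: int,
    n_bootstrap: int = 100,
    seed: int | None = None,
    **kw,
) -> SignatureExtractor:
    """Functional wrapper over :class:`SignatureExtractor`."""
    if not 1 <= k <= 10:
        raise ValueError("k must be in 1..10")
    return SignatureExtractor(
        n_signatures=k, n_bootstrap=n_bootstrap, random_state=seed, **kw
    ).fit(catalog)


class SignatureSelector(BaseEstimator):
    """Choose the number of signatures by the stability criterion.

    Runs :class:`SignatureExtractor` for each ``k`` in ``[k_min, k_max]``
    and selects the largest ``k`` whose stability is at least
    ``stability_min``. If no ``k`` clears the threshold, the argmax of
    stability is selected and ``flagged_`` is set.
    """

    def __init__(
        self,
        k_min: int = 1,
        k_max: int = 10,
        stability_min: float = 0.8,
        n_bootstrap: int = 100,
        random_state: int | None = None,
        max_iter: int = 10_000,
        tol: float = 1e-9,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.stability_min = stability_min
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        V, _ = _as_matrix(X)
        if not (1 <= self.k_min <= self.k_max <= min(V.shape[0], 96)):
            raise ValueError(
                f"k range [{self.k_min}, {self.k_max}] invalid for matrix {V.shape}"
            )
        self.extractions_ = {}
        rows = []
        for k in range(self.k_min, self.k_max + 1):
            ext = SignatureExtractor(
                n_signatures=k,
                n_bootstrap=self.n_bootstrap,
                random_state=self.random_state,
                max_iter=self.max_iter,
                tol=self.tol,
            ).fit(X)
            self.extractions_[k] = ext
            rows.append((k, ext.stability_, ext.reconstruction_err_))
        self.curve_ = pd.DataFrame(
            rows, columns=["k", "stability", "reconstruction_error"]
        )
        ok = self.curve_[self.curve_["stability"] >= self.stability_min]
        if len(ok):
            self.k_ = int(ok["k"].max())
            self.flagged_ = False
        else:
            self.k_ = int(self.curve_.loc[self.curve_["stability"].idxmax(), "k"])
            self.flagged_ = True
            warnings.warn(
                f"no k in [{self.k_min}, {self.k_max}] reached stability "
                f">= {self.stability_min}; selected argmax k={self.k_}"
            )
        self.best_ = self.extractions_[self.k_]
        return self


def select_k(
    catalog: Catalog96,
    k_range: Sequence[int] = range(1, 11),
    stability_min: float = 0.8,
    n_bootstrap: int = 100,
    seed: int | None = None,
) -> SignatureSelector:
    """Functional wrapper over :class:`SignatureSelector`."""
    ks = list(k_range)
    return SignatureSelector(
        k_min=min(ks),
        k_max=max(ks),
        stability_min=stability_min,
        n_bootstrap=n_bootstrap,
        random_state=seed,
    ).fit(catalog)


def annotate_signatures(
    profiles,
    refs: ReferenceSignatures,
    min_cos: float = 0.8,
) -> list[tuple[str, float]]:
    """Label each extracted profile with its best-matching reference.

    A profile gets the name of the reference with the highest cosine
    similarity provided that similarity is at least ``min_cos``; otherwise
    it is labeled ``"novel"``. Ties break toward the first reference in
    bundled order. Accepts a fitted :class:`SignatureExtractor` or a
    (k, 96) array; returns ``(label, cosine)`` pairs.
    """
    if isinstance(profiles, SignatureExtractor):
        profiles = profiles.profiles_
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if len(refs.names) == 0:
        raise ValueError("reference set is empty")
    out = []
    for p in profiles:
        sims = np.array([cosine_similarity(p, r) for r in refs.profiles])
        j = int(np.argmax(sims))
        if sims[j] >= min_cos:
            out.append((refs.names[j], float(sims[j])))
        else:
            out.append(("novel", float(sims[j])))
    return out
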