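"""Selection of consistent reconstructions by convolutional-feature clustering.

Independent phase-retrieval runs differ by a rigid translation, a possible
Friedel twin (point inversion), and — in noisy data — outright failures
(stagnated or wrong-branch iterates). The pipeline here registers the runs to
a common frame, embeds each image with a fixed multi-scale convolutional
feature bank, reduces with PCA, partitions with k-means++, picks the cluster
with the best data fidelity (lowest mean Fourier R-factor) and averages its
best members. Averaging only mutually consistent runs is what turns a noisy
ensemble into a reliable image and a meaningful PRTF.

The feature backbone is deliberately training-free: a seeded, fixed bank of
zero-mean random convolution kernels at several scales, a rectifying
nonlinearity and coarse average pooling. Any callable mapping an image to a
1-D vector can be registered as an alternative backbone (e.g. a pretrained
CNN feature layer).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import fftconvolve
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .types import ClusterResult, FeatureMatrix, Reconstruction, ReconstructionSet

__all__ = [
    "ReconstructionClusterer",
    "register_reconstructions",
    "align_to_reference",
    "point_invert",
    "extract_features",
    "register_backbone",
    "cluster_reconstructions",
    "select_and_average",
    "baseline_cluster",
]

_BANK_SEED = 20831  # fixed: part of the backbone definition, not a tunable
_BANK_SCALES = (3, 5, 9, 15)
_BANK_KERNELS_PER_SCALE = 8
_BANK_POOL = 4


def point_invert(image: np.ndarray) -> np.ndarray:
    """Friedel twin: point inversion about the array origin (index 0).

    For complex images the twin solution is the conjugate of the inversion.
    """
    inv = np.roll(image[::-1, ::-1], (1, 1), axis=(0, 1))
    return np.conj(inv) if np.iscomplexobj(inv) else inv


def _mag(image: np.ndarray) -> np.ndarray:
    return np.abs(image) if np.iscomplexobj(image) else np.asarray(image, dtype=float)


def _best_shift(ref_mag: np.ndarray, img_mag: np.ndarray) -> tuple[tuple[int, int], float]:
    """Integer shift maximizing the circular cross-correlation, plus its score."""
    cc = np.fft.ifft2(np.fft.fft2(ref_mag) * np.conj(np.fft.fft2(img_mag))).real
    idx = int(np.argmax(cc))
    shift = np.unravel_index(idx, cc.shape)
    return (int(shift[0]), int(shift[1])), float(cc.flat[idx])


def align_to_reference(
    image: np.ndarray, reference: np.ndarray, allow_twin: bool = True
) -> np.ndarray:
    """Shift (and possibly twin) ``image`` onto ``reference``.

    The better-matching of {image, its Friedel twin} is cyclically shifted by
    the integer offset maximizing real-space cross-correlation of magnitudes.
    The original orientation wins ties, which makes the operation idempotent.
    """
    ref_mag = _mag(reference)
    cands = [image]
    if allow_twin:
        cands.append(point_invert(image))
    best_score, best_cand, best_shift = None, None, None
    for cand in cands:
        shift, score = _best_shift(ref_mag, _mag(cand))
        # strict > : the untwinned orientation wins ties (idempotence)
        if best_score is None or score > best_score:
            best_score, best_cand, best_shift = score, cand, shift
    return np.roll(best_cand, best_shift, axis=(0, 1))


def register_reconstructions(rset: ReconstructionSet) -> ReconstructionSet:
    """Register every member onto member 0 (translation + Friedel twin).

    For complex-mode images the global phase is additionally rotated so the
    support-mean phase is zero.
    """
    if len(rset) < 2:
        raise ValueError("need at least two members to register")
    ref = rset[0]
    out = [ref.copy()]
    for member in rset.members[1:]:
        aligned = align_to_reference(member.image, ref.image)
        if np.iscomplexobj(aligned):
            mean_phase = np.angle(aligned[member.support].mean())
            aligned = aligned * np.exp(-1j * mean_phase)
        out.append(
            Reconstruction(aligned, member.support, member.error_history, member.seed)
        )
    return ReconstructionSet(members=out, pattern=rset.pattern)


def _conv_bank() -> list[np.ndarray]:
    rng = np.random.default_rng(_BANK_SEED)
    kernels = []
    for scale in _BANK_SCALES:
        for _ in range(_BANK_KERNELS_PER_SCALE):
            k = rng.normal(size=(scale, scale))
            k -= k.mean()  # zero response to constants; zero bias
            k /= np.linalg.norm(k)
            kernels.append(k)
    return kernels


_BANK_CACHE: list[np.ndarray] | None = None


def _random_conv_features(image: np.ndarray) -> np.ndarray:
    global _BANK_CACHE
    if _BANK_CACHE is None:
        _BANK_CACHE = _conv_bank()
    img = _mag(image)
    norm = np.linalg.norm(img)
    if norm > 0:
        img = img / norm
    feats = []
    for k in _BANK_CACHE:
        resp = np.maximum(fftconvolve(img, k, mode="same"), 0.0)
        blocks = [
            np.array([b.mean() for b in np.array_split(row_band, _BANK_POOL, axis=1)])
            for row_band in np.array_split(resp, _BANK_POOL, axis=0)
        ]
        feats.append(np.concatenate(blocks))
    return np.concatenate(feats)


_BACKBONES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "random-conv": _random_conv_features,
}


def register_backbone(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Plug in an alternative image -> feature-vector backbone."""
    _BACKBONES[name] = fn


def extract_features(image: np.ndarray, backbone: str = "random-conv") -> np.ndarray:
    """Deterministic fixed-length embedding of a registered image."""
    try:
        fn = _BACKBONES[backbone]
    except KeyError:
        raise ValueError(
            f"unknown backbone {backbone!r}; registered: {sorted(_BACKBONES)}"
        ) from None
    vec = np.asarray(fn(image), dtype=float).ravel()
    if not np.all(np.isfinite(vec)):
        raise ValueError("backbone produced non-finite features")
    return vec


def cluster_reconstructions(
    features: FeatureMatrix | np.ndarray,
    n_components: int = 10,
    k: int = 4,
    seed: int = 0,
    rfactors: np.ndarray | None = None,
) -> ClusterResult:
    """PCA + k-means++ partition of the feature vectors.

    The selected cluster is the one with the lowest mean Fourier R-factor
    among its members (ties broken toward the larger cluster, then the lower
    index); without R-factors the largest cluster is selected.
    """
    X = features.vectors if isinstance(features, FeatureMatrix) else np.asarray(features)
    n_members, n_feat = X.shape
    if not 2 <= k <= n_members:
        raise ValueError("k must satisfy 2 <= k <= number of members")
    if n_components > n_feat:
        raise ValueError("n_components exceeds the feature length")
    eff = min(n_components, n_members, n_feat)
    Z = PCA(n_components=eff, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(Z)
    selected = _select_cluster(labels, k, rfactors)
    chosen = np.flatnonzero(labels == selected)
    return ClusterResult(labels=labels, selected=selected, chosen_members=chosen)


def _select_cluster(labels: np.ndarray, k: int, rfactors: np.ndarray | None) -> int:
    sizes = np.bincount(labels, minlength=k)
    present = np.flatnonzero(sizes > 0)
    if rfactors is None:
        return int(present[np.argmax(sizes[present])])
    rf = np.asarray(rfactors, dtype=float)
    key = sorted(
        present, key=lambda c: (rf[labels == c].mean(), -int(sizes[c]), int(c))
    )
    return int(key[0])


def select_and_average(
    rset: ReconstructionSet,
    cluster_result: ClusterResult,
    n_best: int = 24,
) -> tuple[np.ndarray, dict]:
    """Average the ``n_best`` lowest-R members of the selected cluster.

    Members are re-registered against the running mean as they are folded in,
    which keeps slowly drifting solutions coherent. Returns the pixel-wise
    mean image and a report with the member indices and their mean R-factor.
    """
    rf = rset.rfactors()
    chosen = list(cluster_result.chosen_members)
    chosen.sort(key=lambda i: rf[i])
    chosen = chosen[: max(1, n_best)]
    mean = np.array(rset[chosen[0]].image, copy=True)
    for count, idx in enumerate(chosen[1:], start=2):
        aligned = align_to_reference(rset[idx].image, mean)
        mean = mean + (aligned - mean) / count
    report = {
        "members": [int(i) for i in chosen],
        "mean_rfactor": float(rf[chosen].mean()),
        "n_averaged": len(chosen),
        "selected_cluster": int(cluster_result.selected),
    }
    return mean, report


def baseline_cluster(
    rset: ReconstructionSet, method: str = "pairwise-cc", cut: float = 0.7
) -> ClusterResult:
    """Comparator: hierarchical grouping on pairwise real-space correlations.

    ``cut`` is the correlation level at which the dendrogram is cut (distance
    threshold ``1 - cut``, average linkage). Provided only as a baseline
    against the feature-clustering path.
    """
    if method != "pairwise-cc":
        raise ValueError(f"unknown baseline method: {method!r}")
    if len(rset) < 2:
        raise ValueError("need at least two members")
    reg = register_reconstructions(rset)
    flat = np.stack([_mag(m.image).ravel() for m in reg.members])
    corr = np.corrcoef(flat)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform((dist + dist.T) / 2, checks=False), method="average")
    labels = fcluster(Z, t=1.0 - cut, criterion="distance") - 1
    k = int(labels.max()) + 1
    selected = _select_cluster(labels, k, reg.rfactors())
    chosen = np.flatnonzero(labels == selected)
    return ClusterResult(labels=labels, selected=selected, chosen_members=chosen)


class ReconstructionClusterer(BaseEstimator):
    """Full selection pipeline as a fit-shaped estimator.

    ``fit`` registers the ensemble, embeds every member with the configured
    backbone, clusters (PCA -> k-means++), selects the lowest-mean-R cluster
    and averages its ``n_best`` best members.

    Attributes (after ``fit``): ``registered_set_``, ``features_``,
    ``labels_``, ``selected_``, ``chosen_members_``, ``average_image_``,
    ``report_``.
    """

    def __init__(
        self,
        backbone: str = "random-conv",
        n_components: int = 10,
        k: int = 4,
        n_best: int = 24,
        random_state: int = 0,
    ):
        self.backbone = backbone
        self.n_components = n_components
        self.k = k
        self.n_best = n_best
        self.random_state = random_state

    def fit(self, rset: ReconstructionSet) -> "ReconstructionClusterer":
        reg = register_reconstructions(rset)
        X = np.stack([extract_features(m.image, self.backbone) for m in reg.members])
        self.features_ = FeatureMatrix(X, backbone=self.backbone)
        result = cluster_reconstructions(
            self.features_,
            n_components=self.n_components,
            k=self.k,
            seed=self.random_state,
            rfactors=reg.rfactors(),
        )
        avg, report = select_and_average(reg, result, n_best=self.n_best)
        self.registered_set_ = reg
        self.cluster_result_ = result
        self.labels_ = result.labels
        self.selected_ = result.selected
        self.chosen_members_ = result.chosen_members
        self.average_image_ = avg
        self.report_ = report
        return self

    def fit_predict(self, rset: ReconstructionSet) -> np.ndarray:
        return self.fit(rset).labels_
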