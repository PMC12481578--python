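"""Context-representative interpretable model explanations (CRIME).

A trained quantifier may reach the same prediction through different
rationales on different inputs: the target analyte's own peaks, a
correlated confounder's peaks, or measurement artifacts.  CRIME surfaces
these rationales as *contexts*:

1. a LIME explanation (weighted ridge surrogate over segment on/off
   perturbations) is computed for every instance;
2. all explanations — weights plus observed perturbation limits — are
   flattened and embedded in the 2-D latent space of a variational
   autoencoder;
3. K-means over the latent space yields the contexts; each context is
   summarized by the mean of its member explanations;
4. within a context, segments are placed in a 3-D space (mean spectral
   intensity, normalized explanation weight, position z-score), clustered
   into 15 groups, and the five groups with the highest weight x intensity
   score become the context's top peak regions;
5. the mean context spectrum, intensity-weighted by the explanation
   profile, is matched to weighted analyte reference spectra by cosine
   similarity to name the likely rationale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.linear_model import Ridge
from sklearn.metrics import silhouette_score

from .nn import Adam, Dense, Module, Tensor
from .spectra import Spectrum

__all__ = [
    "LimeExplanation",
    "VAESpec",
    "ContextReport",
    "segment_map_for",
    "lime_explain",
    "flatten_explanations",
    "fit_latent",
    "cluster_contexts",
    "context_regions",
    "cosine_similarity",
    "match_context",
    "crime_analysis",
]

#: Default segment width in grid points — about half a SERS peak.
SEGMENT_WIDTH = 25


@dataclass
class LimeExplanation:
    """Per-segment surrogate weights and observed perturbation limits."""

    feature_weights: np.ndarray  # (S,)
    perturbation_limits: tuple[np.ndarray, np.ndarray]  # lower, upper (S,)
    intercept: float
    segment_map: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        lo, hi = self.perturbation_limits
        S = len(self.segment_map)
        if not (self.feature_weights.size == lo.size == hi.size == S):
            raise ValueError("inconsistent explanation lengths")
        if np.any(lo > hi + 1e-12):
            raise ValueError("perturbation limits must satisfy lower <= upper")


def segment_map_for(length: int, width: int = SEGMENT_WIDTH) -> tuple[tuple[int, int], ...]:
    """Contiguous fixed-width segments covering [0, length); the last
    segment absorbs the remainder."""
    edges = list(range(0, length, width))
    segs = [(a, min(a + width, length)) for a in edges]
    if len(segs) >= 2 and segs[-1][1] - segs[-1][0] < width // 2:
        a, _ = segs.pop()
        segs[-1] = (segs[-1][0], length)
    return tuple(segs)


def _predict_fn(model) -> Callable[[np.ndarray], np.ndarray]:
    if callable(model) and not hasattr(model, "predict"):
        return model
    return model.predict


def lime_explain(
    model,
    s: Spectrum | np.ndarray,
    n_segments: int | None = None,
    n_samples: int = 256,
    seed: int = 0,
    kernel_width: float = 0.75,
    ridge_alpha: float = 1.0,
) -> LimeExplanation:
    """LIME explanation of one spectrum under a quantification model.

    The spectrum is divided into contiguous equal-width segments (default
    width 25 points).  Perturbed neighbors are built by switching random
    segment subsets "off" — replacing them with the spectrum's global
    baseline level (its minimum).  A ridge surrogate is fit to the model
    outputs with exponential kernel weights on the perturbation distance,
    and the per-segment min/max values observed across the perturbation
    sample are recorded as the perturbation limits.
    """
    y = s.intensities if isinstance(s, Spectrum) else np.asarray(s, float)
    L = y.size
    if n_segments is None:
        segs = segment_map_for(L)
    else:
        bounds = np.linspace(0, L, n_segments + 1).astype(int)
        segs = tuple((int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:]))
    S = len(segs)
    if n_samples < S:
        raise ValueError(
            f"n_samples ({n_samples}) must be >= number of segments ({S}) "
            "for a determined surrogate"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x117E]))
    off_value = float(y.min())

    masks = rng.integers(0, 2, size=(n_samples, S))
    masks[0, :] = 1  # include the unperturbed instance
    X_pert = np.repeat(y[None, :], n_samples, axis=0)
    for j, (a, b) in enumerate(segs):
        off = masks[:, j] == 0
        X_pert[np.ix_(off, np.arange(a, b))] = off_value
    predict = _predict_fn(model)
    preds = np.asarray(predict(X_pert), float).reshape(n_samples)

    # exponential kernel on the fraction of switched-off segments
    d = 1.0 - masks.mean(axis=1)
    w = np.exp(-((d / kernel_width) ** 2))
    ridge = Ridge(alpha=ridge_alpha)
    ridge.fit(masks, preds, sample_weight=w)

    seg_means = np.stack([X_pert[:, a:b].mean(axis=1) for (a, b) in segs], axis=1)
    lower = seg_means.min(axis=0)
    upper = seg_means.max(axis=0)
    return LimeExplanation(
        feature_weights=np.asarray(ridge.coef_, float),
        perturbation_limits=(lower, upper),
        intercept=float(ridge.intercept_),
        segment_map=segs,
    )


def flatten_explanations(explanations: Sequence[LimeExplanation]) -> np.ndarray:
    """Stack explanations into an (n, 3S) matrix: [weights | lower | upper],
    each column min-max normalized across the dataset (constant columns
    map to zero)."""
    if not explanations:
        raise ValueError("no explanations")
    seg0 = explanations[0].segment_map
    for e in explanations[1:]:
        if e.segment_map != seg0:
            raise ValueError("explanations have inconsistent segment maps")
    rows = np.stack(
        [
            np.concatenate(
                [e.feature_weights, e.perturbation_limits[0], e.perturbation_limits[1]]
            )
            for e in explanations
        ]
    )
    lo = rows.min(axis=0)
    hi = rows.max(axis=0)
    span = hi - lo
    out = np.zeros_like(rows)
    nz = span > 0
    out[:, nz] = (rows[:, nz] - lo[nz]) / span[nz]
    return out


@dataclass(frozen=True)
class VAESpec:
    """Variational autoencoder used to embed flattened explanations.

    The latent dimension is fixed at 2 so contexts can be inspected in a
    plane.  ``beta`` weights the KL term against the (per-sample summed)
    reconstruction error; the modest default keeps the embedding
    informative on small explanation sets.
    """

    latent_dim: int = 2
    encoder_widths: tuple[int, ...] = (64, 32)
    beta: float = 0.1
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.latent_dim != 2:
            raise ValueError("latent_dim is fixed at 2")


class _VAENet(Module):
    def __init__(self, d_in: int, spec: VAESpec, rng: np.random.Generator):
        widths = list(spec.encoder_widths)
        self.enc = []
        prev = d_in
        for w in widths:
            self.enc.append(Dense(prev, w, rng))
            prev = w
        self.mu = Dense(prev, spec.latent_dim, rng)
        self.logvar = Dense(prev, spec.latent_dim, rng)
        self.dec = []
        prev = spec.latent_dim
        for w in reversed(widths):
            self.dec.append(Dense(prev, w, rng))
            prev = w
        self.out = Dense(prev, d_in, rng)

    def parameters(self):
        params = []
        for l in self.enc + [self.mu, self.logvar] + self.dec + [self.out]:
            params.extend(l.parameters())
        return params

    def encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = x
        for l in self.enc:
            h = l(h).relu()
        return self.mu(h), self.logvar(h)

    def decode(self, z: Tensor) -> Tensor:
        h = z
        for l in self.dec:
            h = l(h).relu()
        return self.out(h).sigmoid()


def fit_latent(
    matrix: np.ndarray, spec: VAESpec = VAESpec(), seed: int = 0
) -> np.ndarray:
    """Train the VAE on flattened explanations; return the (n, 2) encoder
    means.  Degenerate all-identical inputs yield collapsed coordinates
    with a warning rather than an error."""
    X = np.asarray(matrix, float)
    n, d = X.shape
    if n < 10:
        raise ValueError("need at least 10 instances")
    if np.allclose(X, X[0]):
        warnings.warn("all explanation rows identical; latent space collapses")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7AE]))
    net = _VAENet(d, spec, rng)
    opt = Adam(net.parameters(), lr=spec.learning_rate)
    for _ in range(spec.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = perm[start : start + spec.batch_size]
            xb = Tensor(X[idx])
            opt.zero_grad()
            mu, logvar = net.encode(xb)
            eps = Tensor(rng.standard_normal(mu.shape))
            z = mu + (logvar * 0.5).exp() * eps
            recon = net.decode(z)
            rec_loss = ((recon - xb) ** 2).sum(axis=1).mean()
            kl = ((mu**2 + logvar.exp() - logvar - 1.0) * 0.5).sum(axis=1).mean()
            (rec_loss + spec.beta * kl).backward()
            opt.step()
    mu, _ = net.encode(Tensor(X))
    return mu.data


def cluster_contexts(
    latent: np.ndarray, k: int | str = "auto", seed: int = 0
) -> np.ndarray:
    """K-means context labels over the 2-D latent coordinates.

    ``k="auto"`` scans k in [2, 10] and keeps the silhouette-maximizing
    choice — a programmatic stand-in for visual inspection of the latent
    plane; an explicit k overrides it.
    """
    Z = np.asarray(latent, float)
    n = Z.shape[0]
    if k == "auto":
        best_k, best_score = None, -np.inf
        for kk in range(2, min(10, n - 1) + 1):
            labels = KMeans(kk, n_init=10, random_state=seed).fit_predict(Z)
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(Z, labels)
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    k = int(k)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, n={n}]")
    return KMeans(k, n_init=10, random_state=seed).fit_predict(Z)


@dataclass
class ContextReport:
    """Summary of one prediction context."""

    context_id: str
    member_indices: np.ndarray
    mean_explanation: LimeExplanation
    mean_spectrum: np.ndarray
    top_regions: list[tuple[int, int, float]]  # (start, end, score)
    reference_matches: list[tuple[str, float]] = field(default_factory=list)


def context_regions(
    explanations: Sequence[LimeExplanation],
    spectra: np.ndarray,
    context_id: str = "A",
    member_indices: np.ndarray | None = None,
    n_region_clusters: int = 15,
    n_top: int = 5,
    seed: int = 0,
) -> ContextReport:
    """Mean explanation and top peak regions of one context.

    Each segment becomes a 3-D point (mean spectral intensity, normalized
    absolute explanation weight, position z-score); the points are
    K-means-clustered into 15 groups ranked by mean weight x mean
    intensity, and the five best groups are merged into contiguous index
    regions.  Ranking uses absolute weights; signed weights stay in the
    report's mean explanation.
    """
    if not explanations:
        raise ValueError("context has no members")
    segs = explanations[0].segment_map
    S = len(segs)
    W = np.stack([e.feature_weights for e in explanations])
    lo = np.stack([e.perturbation_limits[0] for e in explanations])
    hi = np.stack([e.perturbation_limits[1] for e in explanations])
    mean_expl = LimeExplanation(
        feature_weights=W.mean(axis=0),
        perturbation_limits=(lo.mean(axis=0), hi.mean(axis=0)),
        intercept=float(np.mean([e.intercept for e in explanations])),
        segment_map=segs,
    )
    spectra = np.atleast_2d(np.asarray(spectra, float))
    mean_spec = spectra.mean(axis=0)

    seg_intensity = np.array([mean_spec[a:b].mean() for (a, b) in segs])
    absw = np.abs(mean_expl.feature_weights)
    norm_w = absw / absw.max() if absw.max() > 0 else absw
    pos = np.arange(S, dtype=float)
    pos_z = (pos - pos.mean()) / (pos.std() if pos.std() > 0 else 1.0)
    pts = np.stack([seg_intensity, norm_w, pos_z], axis=1)

    kk = n_region_clusters
    if S < kk:
        warnings.warn(f"only {S} segments; reducing region clusters to {S}")
        kk = S
    labels = KMeans(kk, n_init=10, random_state=seed).fit_predict(pts)
    scores = np.array(
        [norm_w[labels == c].mean() * seg_intensity[labels == c].mean() for c in range(kk)]
    )
    top_clusters = np.argsort(scores)[::-1][:n_top]

    regions: list[tuple[int, int, float]] = []
    for c in top_clusters:
        seg_idx = np.sort(np.flatnonzero(labels == c))
        # merge consecutive segments of one cluster into index regions
        run_start = seg_idx[0]
        prev = seg_idx[0]
        for i in list(seg_idx[1:]) + [None]:
            if i is not None and i == prev + 1:
                prev = i
                continue
            regions.append((segs[run_start][0], segs[prev][1], float(scores[c])))
            if i is not None:
                run_start = prev = i
    if member_indices is None:
        member_indices = np.arange(len(explanations))
    return ContextReport(
        context_id=context_id,
        member_indices=np.asarray(member_indices),
        mean_explanation=mean_expl,
        mean_spectrum=mean_spec,
        top_regions=regions,
    )


def cosine_similarity(A: np.ndarray, B: np.ndarray) -> float:
    """S_cos = A.B / (||A|| ||B||): 1 identical, 0 orthogonal, -1 opposite."""
    A = np.asarray(A, float).ravel()
    B = np.asarray(B, float).ravel()
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(A @ B / (na * nb))


def _weight_profile(expl: LimeExplanation, length: int) -> np.ndarray:
    """Broadcast normalized absolute segment weights to grid positions."""
    absw = np.abs(expl.feature_weights)
    if absw.max() > 0:
        absw = absw / absw.max()
    profile = np.zeros(length)
    for w, (a, b) in zip(absw, expl.segment_map):
        profile[a:b] = w
    return profile


def match_context(
    report: ContextReport, references: Sequence[tuple[str, Spectrum]]
) -> list[tuple[str, float]]:
    """Rank analyte references against a context by weighted cosine.

    Both the mean context spectrum and each reference are scaled
    elementwise by the context's explanation-weight profile before the
    cosine is taken, emphasizing the spectral locations the model used.
    """
    L = report.mean_spectrum.size
    profile = _weight_profile(report.mean_explanation, L)
    if profile.max() == 0:
        profile = np.ones(L)
    weighted_ctx = report.mean_spectrum * profile
    matches = []
    for name, ref in references:
        if len(ref) != L:
            raise ValueError(f"reference {name!r} grid length {len(ref)} != {L}")
        matches.append((name, cosine_similarity(weighted_ctx, ref.intensities * profile)))
    matches.sort(key=lambda t: t[1], reverse=True)
    report.reference_matches = matches
    return matches


def crime_analysis(
    model,
    spectra: np.ndarray,
    references: Sequence[tuple[str, Spectrum]],
    n_samples: int = 256,
    k: int | str = "auto",
    vae_spec: VAESpec = VAESpec(),
    seed: int = 0,
) -> tuple[list[ContextReport], np.ndarray, np.ndarray]:
    """Run the full CRIME pipeline on a matrix of spectra.

    Returns (context reports, latent coordinates, context labels).
    """
    X = np.atleast_2d(np.asarray(spectra, float))
    explanations = [
        lime_explain(model, X[i], n_samples=n_samples, seed=seed + i)
        for i in range(X.shape[0])
    ]
    flat = flatten_explanations(explanations)
    latent = fit_latent(flat, vae_spec, seed=seed)
    labels = cluster_contexts(latent, k=k, seed=seed)
    reports = []
    for ci, c in enumerate(np.unique(labels)):
        idx = np.flatnonzero(labels == c)
        rep = context_regions(
            [explanations[i] for i in idx],
            X[idx],
            context_id=chr(ord("A") + ci),
            member_indices=idx,
            seed=seed,
        )
        match_context(rep, references)
        reports.append(rep)
    return reports, latent, labels
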