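"""Evoked-activity decoding: binning, PCA, multinomial logistic regression.

Each 2-s trial is converted to a feature vector by discarding spikes
within 10 ms of any stimulation pulse (artifact blanking), counting the
remaining spikes in ten 200-ms windows per recording channel, and
concatenating channel-major. PCA reduces the dimensionality, and a
multinomial logistic regression with a reference class — fitted by a
Newton-type iteratively reweighted least squares (IRLS) on the
ridge-stabilized cross-entropy — assigns each trial to one of the k
firing patterns (nine image-evoked patterns plus spontaneous).

The staged protocol trains one decoder per training stage on that
stage's 15 trials per pattern and evaluates on the 5 held-out trials per
pattern that follow the stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .simulator import SpikeEventTable

__all__ = [
    "DecodingConfig",
    "ResponseFeatureVector",
    "PcaBasis",
    "TrainedDecoder",
    "StageResult",
    "extract_response_features",
    "pca_fit",
    "pca_transform",
    "fit_multinomial_logit",
    "predict",
    "evaluate_protocol",
]

#: label used for the spontaneous firing pattern (reference class).
SPONTANEOUS_LABEL = 9


@dataclass(frozen=True)
class DecodingConfig:
    blank_after_stim: float = 0.010  # s discarded after every pulse
    n_windows: int = 10
    window_len: float = 0.200  # s
    pca_variance_kept: float = 0.95
    n_components: int | None = None  # fixed override of the variance rule
    ridge: float = 1e-6
    max_iter: int = 100
    tol: float = 1e-8
    refit_per_stage: bool = True

    def __post_init__(self) -> None:
        if self.blank_after_stim >= self.window_len:
            raise ValueError("blanking window must be shorter than a count window")
        if not 0 < self.pca_variance_kept <= 1:
            raise ValueError("pca_variance_kept must lie in (0, 1]")

    @property
    def trial_duration(self) -> float:
        return self.n_windows * self.window_len


@dataclass
class ResponseFeatureVector:
    """Concatenated per-channel window counts for one trial."""

    x: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.x)
        if (arr < 0).any():
            raise ValueError("window counts must be non-negative")
        self.x = arr.astype(float)


@dataclass
class PcaBasis:
    """Fitted PCA (or its degenerate bypass for zero-variance data)."""

    mean: np.ndarray
    components: np.ndarray  # (n_kept, n_features)
    explained_variance_ratio: np.ndarray
    bypass: bool = False

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass
class TrainedDecoder:
    pca: PcaBasis
    coef: np.ndarray  # (k-1, d+1): intercept first
    classes: np.ndarray
    loss_trace: list[float] = field(default_factory=list)
    converged: bool = True


@dataclass
class StageResult:
    stage: int
    accuracy: float
    confusion: np.ndarray  # (k, k): rows true, cols predicted
    n_test: int
    decoder: TrainedDecoder


def extract_response_features(
    st: SpikeEventTable,
    stim_onsets: Sequence[float] | None = None,
    cfg: DecodingConfig = DecodingConfig(),
    label: int | None = None,
) -> ResponseFeatureVector:
    """Blank stimulation artifacts, bin in 200-ms windows, concatenate.

    ``stim_onsets`` defaults to the pulse times stored in the table's
    metadata; spikes within ``blank_after_stim`` after any pulse are
    discarded before counting.
    """
    if abs(st.duration - cfg.trial_duration) > 1e-9:
        raise ValueError(
            f"trial duration {st.duration} s does not equal "
            f"{cfg.n_windows} x {cfg.window_len} s"
        )
    onsets = stim_onsets
    if onsets is None:
        onsets = st.metadata.get("stim_onsets", [])
    onsets = np.sort(np.asarray(list(onsets), dtype=float))
    t, ch = st.times, st.channels
    if onsets.size and t.size:
        prev = np.searchsorted(onsets, t, side="right") - 1
        has_prev = prev >= 0
        dt = np.where(has_prev, t - onsets[np.clip(prev, 0, None)], np.inf)
        keep = ~(has_prev & (dt < cfg.blank_after_stim))
        t, ch = t[keep], ch[keep]
    win = np.minimum((t / cfg.window_len).astype(int), cfg.n_windows - 1)
    flat = ch * cfg.n_windows + win
    counts = np.bincount(flat, minlength=st.n_channels * cfg.n_windows)
    return ResponseFeatureVector(x=counts, label=label)


def pca_fit(xs: np.ndarray, cfg: DecodingConfig = DecodingConfig()) -> PcaBasis:
    """Fit PCA keeping the smallest component count reaching the kept-variance
    target, capped at n_samples - 1. Zero-variance data bypass PCA with an
    empty (constant) embedding so downstream fitting degenerates cleanly."""
    X = np.asarray(xs, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a samples x features matrix")
    mean = X.mean(axis=0)
    if np.allclose(X, mean, atol=1e-12):
        return PcaBasis(
            mean=mean, components=np.empty((0, X.shape[1])),
            explained_variance_ratio=np.empty(0), bypass=True,
        )
    cap = min(X.shape[0] - 1, X.shape[1])
    if cfg.n_components is not None:
        n_comp = min(cfg.n_components, cap)
        pca = PCA(n_components=n_comp, svd_solver="full").fit(X)
    elif cfg.pca_variance_kept >= 1.0:
        pca = PCA(n_components=cap, svd_solver="full").fit(X)
    else:
        pca = PCA(n_components=cap, svd_solver="full").fit(X)
        csum = np.cumsum(pca.explained_variance_ratio_)
        n_comp = int(np.searchsorted(csum, cfg.pca_variance_kept - 1e-12) + 1)
        pca.components_ = pca.components_[:n_comp]
        pca.explained_variance_ratio_ = pca.explained_variance_ratio_[:n_comp]
    return PcaBasis(
        mean=pca.mean_, components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def pca_transform(x: np.ndarray, basis: PcaBasis) -> np.ndarray:
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if basis.bypass or basis.n_components == 0:
        return np.zeros((X.shape[0], 0))
    return (X - basis.mean) @ basis.components.T


def _probabilities(coef: np.ndarray, Xa: np.ndarray) -> np.ndarray:
    """Class probabilities; the reference class has an implicit zero logit."""
    z = Xa @ coef.T  # (n, k-1)
    z = np.hstack([z, np.zeros((z.shape[0], 1))])
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss(coef, Xa, Y, ridge):
    P = _probabilities(coef, Xa)
    n = Xa.shape[0]
    ll = -np.log(np.clip(P[Y.astype(bool)], 1e-300, None)).sum() / n
    pen = 0.5 * ridge * (coef[:, 1:] ** 2).sum()  # intercepts unpenalized
    return ll + pen


def fit_multinomial_logit(
    X: np.ndarray, y: np.ndarray, cfg: DecodingConfig = DecodingConfig(),
    pca: PcaBasis | None = None,
) -> TrainedDecoder:
    """Fit the reference-class multinomial logit by Newton/IRLS.

    Minimizes the mean cross-entropy plus a small ridge penalty on the
    non-intercept coefficients (the penalty keeps separable data from
    driving the MLE to infinity). Step-halving enforces a monotone
    non-increasing loss trace; convergence is declared when the loss
    change falls below ``cfg.tol``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    k = classes.size
    if k < 2:
        raise ValueError("at least two classes required")
    n, d = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    Y = (y[:, None] == classes[None, :]).astype(float)  # (n, k)
    coef = np.zeros((k - 1, d + 1))
    ridge_mask = np.ones(d + 1)
    ridge_mask[0] = 0.0
    trace = [_loss(coef, Xa, Y, cfg.ridge)]
    converged = False
    for _ in range(cfg.max_iter):
        P = _probabilities(coef, Xa)
        R = P[:, :-1] - Y[:, :-1]  # (n, k-1)
        grad = (Xa.T @ R).T / n + cfg.ridge * coef * ridge_mask
        # Hessian over the vectorized (k-1, d+1) coefficient block
        W = -P[:, :-1, None] * P[:, None, :-1]
        idx = np.arange(k - 1)
        W[:, idx, idx] += P[:, :-1]
        H = np.einsum("na,njl,nb->jalb", Xa, W, Xa, optimize=True) / n
        dim = (k - 1) * (d + 1)
        H = H.reshape(dim, dim)
        H[np.arange(dim), np.arange(dim)] += cfg.ridge * np.tile(ridge_mask, k - 1)
        H[np.arange(dim), np.arange(dim)] += 1e-10  # numerical floor
        step = np.linalg.solve(H, grad.ravel()).reshape(k - 1, d + 1)
        t, new_loss = 1.0, np.inf
        for _half in range(30):
            cand = coef - t * step
            new_loss = _loss(cand, Xa, Y, cfg.ridge)
            if new_loss <= trace[-1] + 1e-15:
                break
            t *= 0.5
        if new_loss > trace[-1]:
            converged = True  # no descent direction left: at the optimum
            break
        coef = coef - t * step
        trace.append(new_loss)
        if trace[-2] - trace[-1] < cfg.tol:
            converged = True
            break
    basis = pca if pca is not None else PcaBasis(
        mean=np.zeros(d), components=np.eye(d),
        explained_variance_ratio=np.ones(d) / max(d, 1),
    )
    return TrainedDecoder(
        pca=basis, coef=coef, classes=classes, loss_trace=trace, converged=converged
    )


def predict(
    decoder: TrainedDecoder, x: np.ndarray, reduce: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted pattern id(s) and full probability vector(s).

    The argmax tie-break is deterministic toward the lowest class index.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if reduce:
        X = pca_transform(X, decoder.pca)
    Xa = np.hstack([np.ones((X.shape[0], 1)), X])
    P = _probabilities(decoder.coef, Xa)
    labels = decoder.classes[P.argmax(axis=1)]
    if np.isscalar(x) or np.asarray(x).ndim == 1:
        return labels[0], P[0]
    return labels, P


def _trial_label(md: dict) -> int:
    return SPONTANEOUS_LABEL if md.get("stimulus") is None else int(md["stimulus"])


def evaluate_protocol(
    session: Sequence[SpikeEventTable], cfg: DecodingConfig = DecodingConfig()
) -> list[StageResult]:
    """Staged train/test evaluation over the 10 firing patterns.

    For each stage: train on the stage's training trials (15 per image
    pattern plus spontaneous), PCA + IRLS; test on the 5 held-out
    post-stage trials per pattern. With ``cfg.refit_per_stage`` False a
    single decoder is trained on all stages pooled and evaluated on each
    stage's test trials.
    """
    feats = {}
    for i, st in enumerate(session):
        feats[i] = extract_response_features(st, cfg=cfg, label=_trial_label(st.metadata))
    stages = sorted(
        {st.metadata.get("train_stage") for st in session} - {None}
    )
    if not stages:
        raise ValueError("session carries no stage annotations")
    all_classes = np.unique([f.label for f in feats.values()])
    results = []
    pooled_decoder = None
    if not cfg.refit_per_stage:
        idx = [i for i, st in enumerate(session) if st.metadata.get("train_stage")]
        Xtr = np.stack([feats[i].x for i in idx])
        ytr = np.array([feats[i].label for i in idx])
        basis = pca_fit(Xtr, cfg)
        pooled_decoder = fit_multinomial_logit(
            pca_transform(Xtr, basis), ytr, cfg, pca=basis
        )
    for s in stages:
        if cfg.refit_per_stage:
            idx = [
                i for i, st in enumerate(session)
                if st.metadata.get("train_stage") == s
            ]
            Xtr = np.stack([feats[i].x for i in idx])
            ytr = np.array([feats[i].label for i in idx])
            basis = pca_fit(Xtr, cfg)
            decoder = fit_multinomial_logit(
                pca_transform(Xtr, basis), ytr, cfg, pca=basis
            )
        else:
            decoder = pooled_decoder
        tidx = [
            i for i, st in enumerate(session) if st.metadata.get("test_stage") == s
        ]
        if not tidx:
            raise ValueError(f"no test trials for stage {s}")
        Xte = np.stack([feats[i].x for i in tidx])
        yte = np.array([feats[i].label for i in tidx])
        pred, _ = predict(decoder, Xte)
        k = all_classes.size
        conf = np.zeros((k, k), dtype=int)
        lut = {c: j for j, c in enumerate(all_classes)}
        for yt, yp in zip(yte, pred):
            conf[lut[int(yt)], lut[int(yp)]] += 1
        results.append(StageResult(
            stage=s, accuracy=float((pred == yte).mean()),
            confusion=conf, n_test=len(yte), decoder=decoder,
        ))
    return results
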