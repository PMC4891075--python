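"""Signature discovery by probe-pair quadratic discriminant analysis.

The algorithm ranks every probe couple by leave-one-out (LOO) cross-validated
performance of a two-class Gaussian quadratic discriminant (class-specific
mean and covariance), merges the top-scoring couples into a graph whose
connected components and greedily grown variants form candidate
low-dimensional signatures, picks the best candidate by the same LOO score,
and summarizes the chosen signature with repeated stratified 3-fold
cross-validation (accuracy, sensitivity, specificity, PPV, NPV as median and
min–max range over repeats).

Modelling choices that matter:

* Class priors default to *equal* (0.5/0.5). With a 15-vs-103 class split,
  empirical priors make the discriminant collapse onto the majority class
  and the minority class is never called; equal priors keep sensitivity
  meaningful. ``priors="empirical"`` is available.
* The per-class covariance is regularized as ``S + lam * (trace(S)/d) * I``
  with ``lam`` doubled until the matrix is positive-definite (cap 1e-2,
  beyond which the fit errors out as irreparably singular).
* The pair-ranking score defaults to balanced accuracy,
  ``(sensitivity + specificity) / 2`` — robust to the class imbalance;
  plain accuracy is selectable.
* Discriminant ties are broken toward the positive class, and signature
  ties toward the smaller then lexicographically earlier probe set, so every
  run is deterministic given its seed.

Scored pair enumeration is vectorized over all pairs at once (closed-form
2x2 covariance downdates per held-out sample); ``loo_score`` provides the
plain fit-per-fold path and the two are held equal by tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import BinaryContrast

logger = logging.getLogger("mmresponse")

LAMBDA_CAP = 1e-2

# how enumerate_pairs behaves when prefilter_m="auto"
AUTO_PREFILTER_THRESHOLD = 2000
AUTO_PREFILTER_M = 200


# ---------------------------------------------------------------------------
# quadratic discriminant model
# ---------------------------------------------------------------------------

@dataclass
class QDAModel:
    """Two-class QDA fit: per class k, discriminant
    g_k(x) = ln pi_k - 1/2 ln det S_k - 1/2 (x-mu_k)' S_k^-1 (x-mu_k)."""

    feature_names: tuple[str, ...]
    mu_neg: np.ndarray
    mu_pos: np.ndarray
    cov_neg: np.ndarray          # regularized
    cov_pos: np.ndarray          # regularized
    prior_pos: float
    lam: float                   # final regularization weight after escalation

    @property
    def prior_neg(self) -> float:
        return 1.0 - self.prior_pos


def _regularize(cov: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Add ``lam * (trace/d) * I``, doubling lam until positive-definite."""
    d = cov.shape[0]
    scale = np.trace(cov) / d
    while lam <= LAMBDA_CAP:
        reg = cov + lam * scale * np.eye(d)
        try:
            np.linalg.cholesky(reg)
            return reg, lam
        except np.linalg.LinAlgError:
            lam *= 2
    raise np.linalg.LinAlgError(
        f"covariance irreparably singular (lambda escalation exceeded {LAMBDA_CAP})"
    )


def fit_qda(
    X: np.ndarray,
    y: np.ndarray,
    lam: float = 1e-6,
    priors: str = "equal",
) -> QDAModel:
    """Fit the two-class QDA on samples ``X`` (n x d) with 0/1 labels ``y``.

    Each class needs at least d+1 samples so the class covariance has full
    rank before regularization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    counts = np.bincount(y, minlength=2)
    if counts[0] < d + 1 or counts[1] < d + 1:
        raise ValueError(
            f"each class needs >= d+1 = {d + 1} samples, got {counts[0]} / {counts[1]}"
        )
    Xn, Xp = X[y == 0], X[y == 1]
    mu_neg, mu_pos = Xn.mean(axis=0), Xp.mean(axis=0)
    cov_neg = np.atleast_2d(np.cov(Xn, rowvar=False, ddof=1))
    cov_pos = np.atleast_2d(np.cov(Xp, rowvar=False, ddof=1))
    cov_neg, lam_n = _regularize(cov_neg, lam)
    cov_pos, lam_p = _regularize(cov_pos, lam)
    if priors == "equal":
        prior_pos = 0.5
    elif priors == "empirical":
        prior_pos = counts[1] / n
    else:
        raise ValueError(f"priors must be 'equal' or 'empirical', got {priors!r}")
    return QDAModel(
        feature_names=tuple(f"f{i}" for i in range(d)),
        mu_neg=mu_neg, mu_pos=mu_pos, cov_neg=cov_neg, cov_pos=cov_pos,
        prior_pos=prior_pos, lam=max(lam_n, lam_p),
    )


def decision_values(model: QDAModel, X: np.ndarray) -> np.ndarray:
    """g_pos(x) - g_neg(x) per row of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != len(model.mu_pos):
        raise ValueError(
            f"feature dimension mismatch: model has {len(model.mu_pos)}, X has {X.shape[1]}"
        )

    def g(mu, cov, prior):
        sign, logdet = np.linalg.slogdet(cov)
        diff = X - mu
        mahal = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
        return np.log(prior) - 0.5 * logdet - 0.5 * mahal

    return g(model.mu_pos, model.cov_pos, model.prior_pos) - g(
        model.mu_neg, model.cov_neg, model.prior_neg
    )


def predict_qda(model: QDAModel, X: np.ndarray) -> np.ndarray:
    """0/1 class labels; an exact discriminant tie goes to the positive class."""
    return (decision_values(model, X) >= 0.0).astype(int)


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV, NPV from a confusion table.

    A zero denominator yields NaN for that metric (undefined)."""

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(tp + tn, tp + fp + tn + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def implied_npv(sensitivity: float, specificity: float, n_pos: int, n_neg: int) -> float:
    """NPV implied by sensitivity/specificity at a given class split."""
    tn = specificity * n_neg
    fn = (1.0 - sensitivity) * n_pos
    return tn / (tn + fn)


def implied_ppv(sensitivity: float, specificity: float, n_pos: int, n_neg: int) -> float:
    tp = sensitivity * n_pos
    fp = (1.0 - specificity) * n_neg
    return tp / (tp + fp)


def _score_from_confusion(tp, fp, tn, fn, metric: str):
    """Ranking score; works on scalars or aligned arrays."""
    tp, fp, tn, fn = (np.asarray(a, dtype=float) for a in (tp, fp, tn, fn))
    if metric == "balanced":
        with np.errstate(invalid="ignore", divide="ignore"):
            sens = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
            spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
        return (sens + spec) / 2.0
    if metric == "accuracy":
        return (tp + tn) / (tp + fp + tn + fn)
    raise ValueError(f"metric must be 'balanced' or 'accuracy', got {metric!r}")


# ---------------------------------------------------------------------------
# leave-one-out scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairScore:
    """LOO confusion and ranking score of a probe set (usually a couple)."""

    probes: tuple[str, ...]
    tp: int
    fp: int
    tn: int
    fn: int
    score: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _contrast_data(matrix: pd.DataFrame, contrast: BinaryContrast, probes) -> tuple[np.ndarray, np.ndarray]:
    missing = [p for p in probes if p not in matrix.index]
    if missing:
        raise KeyError(f"probes absent from matrix: {missing[:5]}")
    X = matrix.loc[list(probes), list(contrast.samples)].to_numpy(dtype=float).T
    return X, contrast.labels()


def _reg_batched(covs: np.ndarray, lam0: float) -> np.ndarray:
    """Regularize a stack of covariance matrices exactly like ``_regularize``
    (lam doubled per matrix until positive-definite, shared cap)."""
    d = covs.shape[-1]
    scale = np.trace(covs, axis1=-2, axis2=-1) / d
    lam = np.full(covs.shape[0], lam0)
    eye = np.eye(d)
    reg = covs + (lam * scale)[:, None, None] * eye
    bad = np.linalg.eigvalsh(reg)[:, 0] <= 0
    while bad.any():
        if lam[bad].min() > LAMBDA_CAP / 2:
            raise np.linalg.LinAlgError(
                f"covariance irreparably singular (lambda escalation exceeded {LAMBDA_CAP})"
            )
        lam = np.where(bad, lam * 2, lam)
        reg = covs + (lam * scale)[:, None, None] * eye
        bad = np.linalg.eigvalsh(reg)[:, 0] <= 0
    return reg


def _loo_predictions(X: np.ndarray, y: np.ndarray, lam: float, priors: str) -> np.ndarray:
    """Per-sample LOO prediction via closed-form downdates of the held-out
    sample's class mean/covariance, batched over folds."""
    n, d = X.shape
    counts = np.bincount(y, minlength=2)
    if counts.min() - 1 < d + 1:
        raise ValueError(
            f"each class needs >= d+2 = {d + 2} samples for LOO with {d} features, "
            f"got {counts[0]} / {counts[1]}"
        )
    mus, scatters = {}, {}
    for k in (0, 1):
        Xk = X[y == k]
        mus[k] = Xk.mean(axis=0)
        diff = Xk - mus[k]
        scatters[k] = diff.T @ diff

    # full-class regularized models (used as the 'other' class in each fold)
    full_cov = {k: _reg_batched((scatters[k] / (counts[k] - 1))[None], lam)[0] for k in (0, 1)}
    full_inv = {k: np.linalg.inv(full_cov[k]) for k in (0, 1)}
    full_logdet = {k: np.linalg.slogdet(full_cov[k])[1] for k in (0, 1)}

    preds = np.empty(n, dtype=int)
    for k in (0, 1):
        idx = np.flatnonzero(y == k)
        nk = counts[k]
        Xk = X[idx]
        dev = Xk - mus[k]
        mu_down = (nk * mus[k] - Xk) / (nk - 1)                       # (nk, d)
        scat_down = scatters[k][None] - (nk / (nk - 1)) * np.einsum(
            "ni,nj->nij", dev, dev
        )
        cov_down = _reg_batched(scat_down / (nk - 2), lam)
        inv_down = np.linalg.inv(cov_down)
        logdet_down = np.linalg.slogdet(cov_down)[1]

        diff_own = Xk - mu_down
        g_own = -0.5 * logdet_down - 0.5 * np.einsum(
            "ni,nij,nj->n", diff_own, inv_down, diff_own
        )
        other = 1 - k
        diff_other = Xk - mus[other]
        g_other = -0.5 * full_logdet[other] - 0.5 * np.einsum(
            "ni,ij,nj->n", diff_other, full_inv[other], diff_other
        )
        if priors == "equal":
            logprior = 0.0
        else:
            n_pos_tr = counts[1] - (1 if k == 1 else 0)
            n_neg_tr = counts[0] - (1 if k == 0 else 0)
            logprior = np.log(n_pos_tr) - np.log(n_neg_tr)
        g_pos_minus_neg = (g_own - g_other if k == 1 else g_other - g_own) + logprior
        preds[idx] = (g_pos_minus_neg >= 0.0).astype(int)
    return preds


def loo_score(
    matrix: pd.DataFrame,
    contrast: BinaryContrast,
    probe_set,
    metric: str = "balanced",
    lam: float = 1e-6,
    priors: str = "equal",
) -> PairScore:
    """Leave-one-out confusion of a QDA restricted to ``probe_set``.

    Each sample is predicted by a model fit on the remaining n-1; the
    aggregated confusion is scored by balanced accuracy (default) or plain
    accuracy. Implemented by closed-form fold downdates; equivalent to
    refitting per fold with :func:`fit_qda`.
    """
    X, y = _contrast_data(matrix, contrast, probe_set)
    n = len(y)
    if n < 3:
        raise ValueError("LOO needs at least 3 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    pred = _loo_predictions(X, y, lam, priors)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    score = float(_score_from_confusion(tp, fp, tn, fn, metric))
    return PairScore(tuple(probe_set), tp, fp, tn, fn, score)


# ---------------------------------------------------------------------------
# vectorized all-pairs LOO enumeration
# ---------------------------------------------------------------------------

def _pair_stats(X: np.ndarray, iu: np.ndarray, ju: np.ndarray):
    """Per-class sufficient statistics for downdating: sums, squared sums,
    pairwise cross-products restricted to the enumerated pairs."""
    S = X.sum(axis=1)                       # (m,)
    Q = (X * X).sum(axis=1)                 # (m,)
    Gp = (X[iu] * X[ju]).sum(axis=1)        # (P,) cross-product per pair
    return S, Q, Gp


def _reg_2x2(a, b, c, lam0):
    """Vectorized regularization of 2x2 covariances [[a,b],[b,c]]; returns
    regularized (a, c, det, valid mask)."""
    t = (a + c) / 2.0
    lam = np.full_like(a, lam0)
    a_r = a + lam * t
    c_r = c + lam * t
    det = a_r * c_r - b * b
    bad = ~((det > 0) & (a_r > 0))
    while bad.any() and lam[bad].min() <= LAMBDA_CAP / 2:
        lam = np.where(bad, lam * 2, lam)
        a_r = np.where(bad, a + lam * t, a_r)
        c_r = np.where(bad, c + lam * t, c_r)
        det = np.where(bad, a_r * c_r - b * b, det)
        bad = ~((det > 0) & (a_r > 0))
    return a_r, c_r, det, ~bad


def _pairs_loo_confusions(
    X: np.ndarray, y: np.ndarray, iu: np.ndarray, ju: np.ndarray,
    lam: float, priors: str,
):
    """LOO confusion counts for every probe pair (iu[k], ju[k]) at once.

    X is (m_probes, n_samples). For each held-out sample the held-out
    class's mean/covariance is downdated in closed form; the other class
    keeps its full-data statistics. Returns (tp, fp, tn, fn, valid) arrays
    of length n_pairs; ``valid`` is False where regularization could not
    rescue a singular covariance in some fold.
    """
    n = len(y)
    P = len(iu)
    stats_by_class = {}
    for k in (0, 1):
        Xk = X[:, y == k]
        stats_by_class[k] = (_pair_stats(Xk, iu, ju), Xk.shape[1])

    def full_cov(k):
        (S, Q, Gp), nk = stats_by_class[k]
        mu_i, mu_j = S[iu] / nk, S[ju] / nk
        a = (Q[iu] - nk * mu_i**2) / (nk - 1)
        c = (Q[ju] - nk * mu_j**2) / (nk - 1)
        b = (Gp - nk * mu_i * mu_j) / (nk - 1)
        return mu_i, mu_j, a, b, c

    full = {k: full_cov(k) for k in (0, 1)}
    reg_full = {}
    for k in (0, 1):
        mu_i, mu_j, a, b, c = full[k]
        a_r, c_r, det, ok = _reg_2x2(a, b, c, lam)
        reg_full[k] = (mu_i, mu_j, a_r, b, c_r, det, ok)

    tp = np.zeros(P, dtype=int)
    fp = np.zeros(P, dtype=int)
    tn = np.zeros(P, dtype=int)
    fn = np.zeros(P, dtype=int)
    valid = np.ones(P, dtype=bool)

    n_by_class = {k: stats_by_class[k][1] for k in (0, 1)}

    for s in range(n):
        k = int(y[s])
        other = 1 - k
        (S, Q, Gp), nk = stats_by_class[k]
        xi, xj = X[iu, s], X[ju, s]
        nk1 = nk - 1
        mu_i = (S[iu] - xi) / nk1
        mu_j = (S[ju] - xj) / nk1
        a = (Q[iu] - xi**2 - nk1 * mu_i**2) / (nk1 - 1)
        c = (Q[ju] - xj**2 - nk1 * mu_j**2) / (nk1 - 1)
        b = (Gp - xi * xj - nk1 * mu_i * mu_j) / (nk1 - 1)
        a_r, c_r, det, ok = _reg_2x2(a, b, c, lam)
        valid &= ok

        mo_i, mo_j, ao, bo, co, deto, ok_o = reg_full[other]
        valid &= ok_o

        if priors == "equal":
            logprior = 0.0
        else:
            # empirical priors over the training fold of size n-1
            n_pos_tr = n_by_class[1] - (1 if k == 1 else 0)
            n_neg_tr = n_by_class[0] - (1 if k == 0 else 0)
            logprior = np.log(n_pos_tr) - np.log(n_neg_tr)

        def quad(dx, dy, a_r, b, c_r, det):
            return (c_r * dx * dx - 2.0 * b * dx * dy + a_r * dy * dy) / det

        if k == 1:
            g_pos = -0.5 * np.log(det) - 0.5 * quad(xi - mu_i, xj - mu_j, a_r, b, c_r, det)
            g_neg = -0.5 * np.log(deto) - 0.5 * quad(xi - mo_i, xj - mo_j, ao, bo, co, deto)
        else:
            g_neg = -0.5 * np.log(det) - 0.5 * quad(xi - mu_i, xj - mu_j, a_r, b, c_r, det)
            g_pos = -0.5 * np.log(deto) - 0.5 * quad(xi - mo_i, xj - mo_j, ao, bo, co, deto)
        pred_pos = (g_pos - g_neg + logprior) >= 0.0
        if k == 1:
            tp += pred_pos
            fn += ~pred_pos
        else:
            fp += pred_pos
            tn += ~pred_pos
    return tp, fp, tn, fn, valid


def enumerate_pairs(
    matrix: pd.DataFrame,
    contrast: BinaryContrast,
    prefilter_m: int | str | None = "auto",
    top_k: int = 50,
    metric: str = "balanced",
    lam: float = 1e-6,
    priors: str = "equal",
) -> list[PairScore]:
    """Score every unordered probe couple by LOO QDA and return the ranking.

    ``prefilter_m`` limits the candidate probes to the top m by univariate
    Welch p — a desk-scale deviation from scoring all couples, applied
    automatically above 2000 probes (``"auto"``); pass ``None`` to score all
    couples regardless of size. Order is deterministic: score descending,
    then lexicographic probe-id pairs. ``top_k`` only controls how the
    caller typically consumes the list; the full ranking is returned.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 probes to enumerate couples")
    probes = list(matrix.index.astype(str))
    if prefilter_m == "auto":
        prefilter_m = AUTO_PREFILTER_M if len(probes) > AUTO_PREFILTER_THRESHOLD else None
    if prefilter_m is not None and prefilter_m < len(probes):
        logger.info(
            "prefiltering %d probes to top %d by univariate Welch p before pair enumeration",
            len(probes), prefilter_m,
        )
        pos = matrix[list(contrast.positive)].to_numpy(dtype=float)
        neg = matrix[list(contrast.negative)].to_numpy(dtype=float)
        p = stats.ttest_ind(pos, neg, axis=1, equal_var=False).pvalue
        p = np.where(np.isfinite(p), p, 1.0)
        order = np.lexsort((np.array(probes), p))[:prefilter_m]
        keep = sorted(order)
        matrix = matrix.iloc[keep]
        probes = list(matrix.index.astype(str))

    X, y = _contrast_data(matrix, contrast, probes)
    m = len(probes)
    iu, ju = np.triu_indices(m, k=1)
    tp, fp, tn, fn, valid = _pairs_loo_confusions(X.T, y, iu, ju, lam, priors)
    score = _score_from_confusion(tp, fp, tn, fn, metric)
    score = np.where(valid, score, -np.inf)

    pair_ids = [(probes[i], probes[j]) for i, j in zip(iu, ju)]
    order = sorted(range(len(pair_ids)), key=lambda k: (-score[k], pair_ids[k]))
    return [
        PairScore(pair_ids[k], int(tp[k]), int(fp[k]), int(tn[k]), int(fn[k]), float(score[k]))
        for k in order
    ]


# ---------------------------------------------------------------------------
# network merging of top couples into candidate signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Signature:
    """A candidate probe set with a note on how it was assembled."""

    probes: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.probes) < 2:
            raise ValueError("a signature needs at least 2 probes")

    @property
    def size(self) -> int:
        return len(self.probes)


def _greedy_grow(
    matrix, contrast, graph, seed_nodes, max_size, metric, lam, priors
) -> tuple[tuple[str, ...], float]:
    current = sorted(seed_nodes)
    best = loo_score(matrix, contrast, current, metric=metric, lam=lam, priors=priors).score
    while len(current) < max_size:
        neighbors = sorted(
            {nb for node in current for nb in graph.neighbors(node)} - set(current)
        )
        if not neighbors:
            break
        scores = [
            (loo_score(matrix, contrast, sorted(current + [nb]),
                       metric=metric, lam=lam, priors=priors).score, nb)
            for nb in neighbors
        ]
        top_score, top_nb = max(scores, key=lambda t: (t[0], t[1]))
        if top_score <= best:
            break
        current = sorted(current + [top_nb])
        best = top_score
    return tuple(current), best


def build_network_signatures(
    matrix: pd.DataFrame,
    contrast: BinaryContrast,
    ranked_pairs: list[PairScore],
    top_k: int = 50,
    max_size: int = 10,
    metric: str = "balanced",
    lam: float = 1e-6,
    priors: str = "equal",
    ladder: bool = True,
    hubs: bool = True,
) -> list[Signature]:
    """Merge the top-k couples into candidate signatures via a probe graph.

    Probes are nodes, the top-k couples are edges. The exact rule turning a
    couple network into a signature is underdetermined, so several labelled
    variants are generated and the selection step arbitrates:

    * ``component``: the node set of each connected component of the full
      top-k graph (components larger than ``max_size`` reduced by greedy
      growth from their best edge, labelled ``component-reduced``);
    * ``component@k``: with ``ladder=True``, components of every prefix
      graph built from the top 1..k couples — tight clusters around the
      strongest couples that the full graph may have merged away;
    * ``greedy``: per component, start from its best couple and repeatedly
      add the neighboring probe giving the largest LOO ranking-score
      improvement, stopping at no improvement or ``max_size``;
    * ``hub-n``: with ``hubs=True``, the n highest-degree probes of the
      top-k graph for n = 2..max_size — probes that recur across many top
      couples are the likeliest true signal.

    Duplicates are removed; output order is deterministic.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    edges = ranked_pairs[:top_k]
    graph = nx.Graph()
    for ps in edges:
        graph.add_edge(ps.probes[0], ps.probes[1], score=ps.score)

    candidates: dict[tuple[str, ...], Signature] = {}

    def add(probes, provenance: str) -> None:
        key = tuple(sorted(probes))
        if 2 <= len(key) <= max_size and key not in candidates:
            candidates[key] = Signature(key, provenance)

    if ladder:
        prefix = nx.Graph()
        for k, ps in enumerate(edges, 1):
            prefix.add_edge(*ps.probes)
            for comp in nx.connected_components(prefix):
                add(tuple(comp), f"component@k={k}")

    for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        comp = set(comp)
        best_edge = min(
            (ps for ps in edges if set(ps.probes) <= comp),
            key=lambda ps: (-ps.score, ps.probes),
        )
        if len(comp) <= max_size:
            add(tuple(comp), "component")
        grown, _ = _greedy_grow(
            matrix, contrast, graph.subgraph(comp), best_edge.probes,
            max_size, metric, lam, priors,
        )
        add(grown, "greedy" if len(comp) <= max_size else "component-reduced")

    if hubs:
        by_degree = sorted(graph.degree, key=lambda t: (-t[1], t[0]))
        names = [node for node, _ in by_degree]
        for size in range(2, max_size + 1):
            if size <= len(names):
                add(tuple(names[:size]), f"hub-{size}")
    return list(candidates.values())


def select_best_signature(
    matrix: pd.DataFrame,
    contrast: BinaryContrast,
    candidates: list[Signature],
    metric: str = "balanced",
    lam: float = 1e-6,
    priors: str = "equal",
) -> Signature:
    """Pick the candidate with the highest LOO ranking score.

    Ties go to the smaller signature, then the lexicographically earlier
    probe tuple.
    """
    if not candidates:
        raise ValueError("no candidate signatures")
    scored = [
        (loo_score(matrix, contrast, sig.probes, metric=metric, lam=lam, priors=priors).score, sig)
        for sig in candidates
    ]
    return min(scored, key=lambda t: (-t[0], t[1].size, t[1].probes))[1]


def discover_signature(
    matrix: pd.DataFrame,
    contrast: BinaryContrast,
    prefilter_m: int | str | None = "auto",
    top_k: int = 50,
    max_size: int = 10,
    metric: str = "balanced",
    lam: float = 1e-6,
    priors: str = "equal",
) -> tuple[list[PairScore], list[Signature], Signature]:
    """Full discovery chain: rank couples, build candidate signatures from
    the couple network, select the best by LOO score.

    Returns (ranked pairs, candidate signatures, selected signature).
    """
    pairs = enumerate_pairs(
        matrix, contrast, prefilter_m=prefilter_m, top_k=top_k,
        metric=metric, lam=lam, priors=priors,
    )
    candidates = build_network_signatures(
        matrix, contrast, pairs, top_k=top_k, max_size=max_size,
        metric=metric, lam=lam, priors=priors,
    )
    signature = select_best_signature(
        matrix, contrast, candidates, metric=metric, lam=lam, priors=priors
    )
    return pairs, candidates, signature


# ---------------------------------------------------------------------------
# repeated k-fold evaluation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-repeat pooled-confusion metrics of a signature under repeated
    stratified k-fold cross-validation. Undefined metrics (zero denominator
    in a repeat) are stored as NaN and excluded from that metric's summary."""

    signature: tuple[str, ...]
    k: int
    n_repeats: int
    seed: int
    accuracy: np.ndarray = field(repr=False, default=None)
    sensitivity: np.ndarray = field(repr=False, default=None)
    specificity: np.ndarray = field(repr=False, default=None)
    ppv: np.ndarray = field(repr=False, default=None)
    npv: np.ndarray = field(repr=False, default=None)

    METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "npv")

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for name in self.METRICS:
            vals = getattr(self, name)
            defined = vals[~np.isnan(vals)]
            if defined.size == 0:
                out[name] = {"median": float("nan"), "min": float("nan"),
                             "max": float("nan"), "n_defined": 0}
            else:
                out[name] = {
                    "median": float(np.median(defined)),
                    "min": float(defined.min()),
                    "max": float(defined.max()),
                    "n_defined": int(defined.size),
                }
        return out

    def balanced_accuracy(self) -> np.ndarray:
        return (self.sensitivity + self.specificity) / 2.0

    def to_dict(self) -> dict:
        return {
            "signature": list(self.signature),
            "k": self.k,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "summary": self.summary(),
        }


def evaluate_signature(
    matrix: pd.DataFrame,
    contrast: BinaryContrast,
    signature: Signature | tuple[str, ...],
    k: int = 3,
    n_repeats: int = 1000,
    stratified: bool = True,
    seed: int = 0,
    lam: float = 1e-6,
    priors: str = "equal",
) -> CVReport:
    """Repeated k-fold cross-validation of a fixed signature.

    Each repeat randomly partitions the cohort into k folds (stratified by
    class by default — with few positives an unstratified split can produce
    positive-free test folds), trains on k-1 folds, predicts the held-out
    fold, and pools all n predictions into one confusion table, from which
    accuracy, sensitivity, specificity, PPV and NPV are taken. The report
    summarizes each metric as median and (min, max) over repeats.
    """
    probes = signature.probes if isinstance(signature, Signature) else tuple(signature)
    X, y = _contrast_data(matrix, contrast, probes)
    n = len(y)
    counts = np.bincount(y, minlength=2)
    if stratified and (counts[0] < k or counts[1] < k):
        raise ValueError(
            f"stratified {k}-fold needs >= {k} samples per class, got {counts[0]} / {counts[1]}"
        )
    rng = np.random.default_rng(seed)
    metrics = {name: np.empty(n_repeats) for name in CVReport.METRICS}
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    for r in range(n_repeats):
        if stratified:
            folds = [[] for _ in range(k)]
            for idx in (pos_idx, neg_idx):
                perm = rng.permutation(idx)
                for f, chunk in enumerate(np.array_split(perm, k)):
                    folds[f].extend(chunk.tolist())
        else:
            perm = rng.permutation(n)
            folds = [chunk.tolist() for chunk in np.array_split(perm, k)]
        tp = fp = tn = fn = 0
        for fold in folds:
            fold = np.array(fold, dtype=int)
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            model = fit_qda(X[mask], y[mask], lam=lam, priors=priors)
            pred = predict_qda(model, X[fold])
            truth = y[fold]
            tp += int(((pred == 1) & (truth == 1)).sum())
            fp += int(((pred == 1) & (truth == 0)).sum())
            tn += int(((pred == 0) & (truth == 0)).sum())
            fn += int(((pred == 0) & (truth == 1)).sum())
        vals = confusion_metrics(tp, fp, tn, fn)
        for name in CVReport.METRICS:
            metrics[name][r] = vals[name]
    return CVReport(
        signature=probes, k=k, n_repeats=n_repeats, seed=seed, **metrics
    )


# ---------------------------------------------------------------------------
# cross-cohort application
# ---------------------------------------------------------------------------

def standardize_probes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-probe standardization (mean 0, sd 1 across samples); constant
    probes are centred only."""
    values = matrix.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((values - mu) / sd, index=matrix.index, columns=matrix.columns)


def fit_signature_model(
    matrix: pd.DataFrame,
    contrast: BinaryContrast,
    signature: Signature | tuple[str, ...],
    gene_names: dict[str, str] | None = None,
    lam: float = 1e-6,
    priors: str = "equal",
) -> QDAModel:
    """Fit the final QDA on per-probe standardized signature features so the
    model can be transported to another cohort with ``apply_signature``.

    ``gene_names`` optionally renames probe features to gene symbols, the
    namespace used for cross-platform probe mapping.
    """
    probes = signature.probes if isinstance(signature, Signature) else tuple(signature)
    Z = standardize_probes(matrix.loc[list(probes)])
    X = Z[list(contrast.samples)].to_numpy(dtype=float).T
    model = fit_qda(X, contrast.labels(), lam=lam, priors=priors)
    names = tuple(gene_names.get(p, p) for p in probes) if gene_names else probes
    model.feature_names = names
    return model


def apply_signature(
    model: QDAModel,
    external_matrix: pd.DataFrame,
    probe_map: dict[str, list[str]],
) -> tuple[pd.Series, dict[str, list[str]]]:
    """Predict an external cohort with a transported signature model.

    Features are rebuilt per signature gene by averaging that gene's probes
    after per-matrix standardization (every probe of the external matrix is
    scaled to mean 0, sd 1), which absorbs platform-level location/scale
    differences. Every signature gene must map to at least one probe present
    in the external matrix; otherwise an error lists the unmapped genes.
    Returns per-sample 0/1 predictions and the gene -> probes mapping used.
    """
    unmapped = [
        g for g in model.feature_names
        if not [p for p in probe_map.get(g, []) if p in external_matrix.index]
    ]
    if unmapped:
        raise KeyError(f"signature genes with no mapped probe in external matrix: {unmapped}")
    Z = standardize_probes(external_matrix)
    used: dict[str, list[str]] = {}
    features = []
    for gene in model.feature_names:
        probes = [p for p in probe_map[gene] if p in Z.index]
        used[gene] = probes
        features.append(Z.loc[probes].to_numpy(dtype=float).mean(axis=0))
    X = np.column_stack(features)
    pred = predict_qda(model, X)
    return pd.Series(pred, index=external_matrix.columns, name="prediction"), used
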