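"""Constrained parallel infomax ICA and model-order selection.

Each modality ``X`` (subjects x variables) is modeled as ``X = A @ S`` with
``W = A^{-1}`` in the PCA-reduced subject space. Infomax maximizes the joint
entropy of ``Y = logistic(W X + W0)`` via the natural-gradient rule

    dW  = eta * (I + (1 - 2Y) U^T / N) @ W,     U = W X + W0
    dW0 = eta * mean(1 - 2Y, axis=samples)

which separates super-Gaussian sources. The parallel variant adds a
cross-modality objective term: the squared Pearson correlation between one
column of the FA loading matrix and one column of the SNP loading matrix.
At each sweep the maximally correlated loading pair is found; if its |r|
exceeds a threshold (default 0.3), a gradient-ascent step on corr^2 is
applied to those two subject-space loading columns and propagated back to
the unmixing matrices through W = A^{-1}. A negative "endurance" bound on
the per-iteration entropy change suspends the constraint (and halves its
step size) when the entropy term degrades too fast, guarding against the
correlation term overwhelming source separation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .datatypes import DecompositionConfig, DecompositionResult, ModalityMatrix


# ---------------------------------------------------------------------------
# PCA reduction / whitening
# ---------------------------------------------------------------------------

def pca_reduce(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Whiten along the subject dimension to ``k`` components.

    Rows of ``X`` (subjects) are the channels; columns (voxels/SNPs) are the
    samples. Each row is centered, the subject-space covariance is
    eigendecomposed, and the top-k whitened representation is returned with
    the whitening map ``K`` (k x n_subjects) and dewhitening map ``D``
    (n_subjects x k) such that ``D @ X_white`` approximates the centered data
    and ``K @ D = I``.
    """
    X = np.asarray(X, dtype=float)
    n_sub, n_var = X.shape
    if k > min(n_sub, n_var):
        raise ValueError(f"k={k} exceeds min(subjects, variables)")
    Xc = X - X.mean(axis=1, keepdims=True)
    C = Xc @ Xc.T / (n_var - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1][:k]
    lam = evals[order]
    if lam[-1] <= 1e-12 * max(lam[0], 1.0):
        raise ValueError(f"k={k} exceeds numerical rank of the data")
    E = evecs[:, order]
    K = (E / np.sqrt(lam)).T          # whitening, k x n_sub
    D = E * np.sqrt(lam)              # dewhitening, n_sub x k
    return K @ Xc, K, D


# ---------------------------------------------------------------------------
# Infomax machinery
# ---------------------------------------------------------------------------

def infomax_update(W: np.ndarray, W0: np.ndarray, X_batch: np.ndarray,
                   learning_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One natural-gradient infomax step on a (whitened) batch.

    Raises FloatingPointError when the step produces non-finite values, as
    an annealing signal to the caller.
    """
    k, n = X_batch.shape
    with np.errstate(over="ignore", invalid="ignore"):
        U = W @ X_batch + W0[:, None]
        Y = expit(U)
        dW = learning_rate * (np.eye(k) + (1.0 - 2.0 * Y) @ U.T / n) @ W
        dW0 = learning_rate * (1.0 - 2.0 * Y).mean(axis=1)
        W_new, W0_new = W + dW, W0 + dW0
    if not (np.isfinite(W_new).all() and np.isfinite(W0_new).all()):
        raise FloatingPointError("infomax step diverged")
    return W_new, W0_new


def infomax_entropy(W: np.ndarray, W0: np.ndarray, X: np.ndarray) -> float:
    """Entropy surrogate H(Y) = ln|det W| + E[sum_i ln y_i(1-y_i)] (+const)."""
    U = W @ X + W0[:, None]
    Y = expit(U)
    ly = np.log(np.clip(Y * (1.0 - Y), 1e-300, None))
    sign, logdet = np.linalg.slogdet(W)
    if sign <= 0:
        return -np.inf
    return float(logdet + ly.sum(axis=0).mean())


def _run_infomax(Xw: np.ndarray, config: DecompositionConfig,
                 rng: np.random.Generator,
                 max_iterations: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Plain (unconstrained) infomax on whitened data; used standalone for
    model-order consistency scoring."""
    k = Xw.shape[0]
    W = _random_orthogonal(k, rng)
    W0 = np.zeros(k)
    lr = config.learning_rate
    prev_h = -np.inf
    iters = max_iterations or config.max_iterations
    for _ in range(iters):
        W_old = W
        try:
            W, W0 = infomax_update(W, W0, Xw, lr)
        except FloatingPointError:
            lr *= 0.5
            continue
        h = infomax_entropy(W, W0, Xw)
        if h < prev_h:
            lr *= config.anneal_factor
        prev_h = h
        if np.linalg.norm(W - W_old) / np.linalg.norm(W_old) < config.convergence_tol:
            break
    return W, W0


def _random_orthogonal(k: int, rng: np.random.Generator) -> np.ndarray:
    Q, R = np.linalg.qr(rng.standard_normal((k, k)))
    return Q * np.sign(np.diag(R))


# ---------------------------------------------------------------------------
# Correlation-enhancement constraint
# ---------------------------------------------------------------------------

def constraint_update(A1_col: np.ndarray, A2_col: np.ndarray,
                      learning_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Gradient-ascent deltas on corr(A1_col, A2_col)^2.

    With centered columns a, b: rho = a.b/(|a||b|) and

        d(rho^2)/da = 2 rho (b/(|a||b|) - rho a/|a|^2)

    (the centering projector leaves this vector fixed, so it is also the
    gradient with respect to the raw column). Increasing rho^2 pushes |rho|
    toward 1 while preserving the sign of rho.
    """
    a = np.asarray(A1_col, float)
    b = np.asarray(A2_col, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("columns must share length >= 3")
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance loading column")
    rho = float(ac @ bc / (na * nb))
    ga = 2.0 * rho * (bc / (na * nb) - rho * ac / na**2)
    gb = 2.0 * rho * (ac / (na * nb) - rho * bc / nb**2)
    return learning_rate * ga, learning_rate * gb


def _loading_corr_matrix(A1: np.ndarray, A2: np.ndarray) -> np.ndarray:
    A1c = A1 - A1.mean(axis=0)
    A2c = A2 - A2.mean(axis=0)
    n1 = np.linalg.norm(A1c, axis=0)
    n2 = np.linalg.norm(A2c, axis=0)
    return (A1c.T @ A2c) / np.outer(n1, n2)


# ---------------------------------------------------------------------------
# Parallel ICA driver
# ---------------------------------------------------------------------------

def run_parallel_ica(X1, X2, config: DecompositionConfig) -> DecompositionResult:
    """Joint decomposition of two subject-aligned modality matrices.

    Accepts :class:`ModalityMatrix` or plain arrays. Alternates full-batch
    infomax sweeps on both modalities with a correlation-enhancement step on
    the maximally correlated loading pair (when above the threshold),
    annealing the ICA learning rate on entropy decreases and suspending the
    constraint when the entropy drop exceeds the endurance bound. Components
    are returned standardized (unit-variance rows, largest-|weight| element
    positive) with the scale and sign absorbed into the loadings.
    """
    subjects1, M1 = _as_matrix(X1)
    subjects2, M2 = _as_matrix(X2)
    if M1.shape[0] != M2.shape[0]:
        raise ValueError("modalities must share the subject dimension")
    if subjects1 and subjects2 and subjects1 != subjects2:
        raise ValueError("modalities must share subject order")

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    Xw1, K1, D1 = pca_reduce(M1, cfg.n_comp_fa)
    Xw2, K2, D2 = pca_reduce(M2, cfg.n_comp_snp)

    W1 = _random_orthogonal(cfg.n_comp_fa, rng)
    W2 = _random_orthogonal(cfg.n_comp_snp, rng)
    W0_1 = np.zeros(cfg.n_comp_fa)
    W0_2 = np.zeros(cfg.n_comp_snp)
    lr1 = lr2 = cfg.learning_rate
    crate = cfg.constraint_rate

    h1_hist: list[float] = []
    h2_hist: list[float] = []
    corr_hist: list[float] = []
    pair: tuple[int, int] | None = None
    constraint_suspended = False
    converged = False
    it = 0

    for it in range(1, cfg.max_iterations + 1):
        W1_old, W2_old = W1.copy(), W2.copy()

        try:
            W1, W0_1 = infomax_update(W1, W0_1, Xw1, lr1)
        except FloatingPointError:
            W1, lr1 = W1_old, lr1 * 0.5
        try:
            W2, W0_2 = infomax_update(W2, W0_2, Xw2, lr2)
        except FloatingPointError:
            W2, lr2 = W2_old, lr2 * 0.5

        h1 = infomax_entropy(W1, W0_1, Xw1)
        h2 = infomax_entropy(W2, W0_2, Xw2)
        if h1_hist and h1 < h1_hist[-1]:
            lr1 *= cfg.anneal_factor
        if h2_hist and h2 < h2_hist[-1]:
            lr2 *= cfg.anneal_factor

        # endurance guard: entropy falling faster than the bound suspends
        # the constraint for this iteration and halves its step size
        drop = 0.0
        if h1_hist:
            drop = min(h1 - h1_hist[-1], h2 - h2_hist[-1])
        constraint_suspended = bool(h1_hist) and drop < cfg.endurance
        if constraint_suspended:
            crate *= 0.5
        h1_hist.append(h1)
        h2_hist.append(h2)

        # cross-modality constraint on subject-space loadings
        A1r, A2r = np.linalg.inv(W1), np.linalg.inv(W2)
        A1, A2 = D1 @ A1r, D2 @ A2r
        R = _loading_corr_matrix(A1, A2)
        i, j = np.unravel_index(np.argmax(np.abs(R)), R.shape)
        top_r = float(R[i, j])
        corr_hist.append(top_r)
        if abs(top_r) > cfg.constraint_threshold and not constraint_suspended:
            pair = (int(i), int(j))
            for _ in range(cfg.max_constrained_pairs):  # one pair by default
                d1, d2 = constraint_update(A1[:, i], A2[:, j], crate)
                a1_new = A1[:, i] + d1 * np.linalg.norm(A1[:, i])
                a2_new = A2[:, j] + d2 * np.linalg.norm(A2[:, j])
                # propagate to reduced space and re-derive W = A^{-1}
                A1r[:, i] = np.linalg.lstsq(D1, a1_new, rcond=None)[0]
                A2r[:, j] = np.linalg.lstsq(D2, a2_new, rcond=None)[0]
                break
            W1, W2 = np.linalg.inv(A1r), np.linalg.inv(A2r)

        dw = max(
            np.linalg.norm(W1 - W1_old) / np.linalg.norm(W1_old),
            np.linalg.norm(W2 - W2_old) / np.linalg.norm(W2_old),
        )
        if dw < cfg.convergence_tol:
            converged = True
            break

    S1 = W1 @ Xw1
    S2 = W2 @ Xw2
    A1 = D1 @ np.linalg.inv(W1)
    A2 = D2 @ np.linalg.inv(W2)
    A1, S1 = _standardize(A1, S1)
    A2, S2 = _standardize(A2, S2)

    return DecompositionResult(
        A1=A1, A2=A2, S1=S1, S2=S2,
        W1=W1, W2=W2, W0_1=W0_1, W0_2=W0_2,
        entropy_history_1=np.array(h1_hist),
        entropy_history_2=np.array(h2_hist),
        constrained_pair=pair,
        constraint_corr_history=np.array(corr_hist),
        converged=converged,
        n_iterations=it,
        config=cfg,
        subjects=subjects1 or subjects2 or [],
    )


def _as_matrix(X) -> tuple[list[str], np.ndarray]:
    if isinstance(X, ModalityMatrix):
        return list(X.subjects), X.values
    return [], np.asarray(X, dtype=float)


def _standardize(A: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance component rows, largest-|weight| element positive;
    scale/sign absorbed into A so A @ S is unchanged."""
    A = A.copy()
    S = S.copy()
    for c in range(S.shape[0]):
        sd = S[c].std()
        if sd > 0:
            S[c] /= sd
            A[:, c] *= sd
        sgn = np.sign(S[c, np.argmax(np.abs(S[c]))])
        if sgn < 0:
            S[c] *= -1
            A[:, c] *= -1
    return A, S


# ---------------------------------------------------------------------------
# Model-order selection
# ---------------------------------------------------------------------------

def mdl_criterion(eigenvalues: np.ndarray, n_samples: int) -> np.ndarray:
    """MDL value for each candidate order k = 0..p-1 (Wax-Kailath form).

    MDL(k) = -n (p-k) ln( GM(lam_{k+1..p}) / AM(lam_{k+1..p}) )
             + 0.5 k (2p - k) ln n
    """
    lam = np.sort(np.asarray(eigenvalues, float))[::-1]
    lam = np.clip(lam, 1e-300, None)
    p = len(lam)
    out = np.empty(p)
    for k in range(p):
        tail = lam[k:]
        gm = np.exp(np.mean(np.log(tail)))
        am = np.mean(tail)
        out[k] = -n_samples * (p - k) * np.log(gm / am) \
            + 0.5 * k * (2 * p - k) * np.log(n_samples)
    return out


def estimate_ncomp_mdl(X: np.ndarray) -> int:
    """Model order of the subject-space covariance by minimum description
    length; ties go to the smallest k."""
    X = np.asarray(X, float)
    n_sub, n_var = X.shape
    if n_var <= n_sub:
        raise ValueError("need more variables (samples) than subjects (channels)")
    Xc = X - X.mean(axis=1, keepdims=True)
    lam = np.linalg.eigvalsh(Xc @ Xc.T / (n_var - 1))
    crit = mdl_criterion(lam, n_var)
    return int(np.argmin(crit))


def estimate_ncomp_consistency(X: np.ndarray, candidate_ks, n_runs: int = 10,
                               seed: int = 0, max_iterations: int = 128,
                               consistency_min: float = 0.85) -> int:
    """Pick the largest order whose components stay reproducible across
    random restarts (run-to-run matching by absolute correlation;
    ICASSO-style).

    For each candidate k the whitened data are decomposed ``n_runs`` times
    from random initial unmixing matrices; every pair of runs is greedily
    matched on |corr| of component rows and the mean matched |corr| is the
    consistency score. Scores stay high up to the true order and drop
    sharply beyond it, while small k are trivially stable — so the rule is
    the largest candidate scoring at least ``consistency_min`` (falling
    back to the global maximum, smaller k on ties, if none qualifies).
    """
    if n_runs < 2:
        raise ValueError("consistency is undefined for n_runs < 2")
    X = np.asarray(X, float)
    cfg = DecompositionConfig(seed=seed, max_iterations=max_iterations)
    rng = np.random.default_rng(seed)
    ks = sorted(candidate_ks)
    scores = {}
    for k in ks:
        Xw, _, _ = pca_reduce(X, k)
        comps = []
        for _ in range(n_runs):
            W, W0 = _run_infomax(Xw, cfg, rng, max_iterations=max_iterations)
            comps.append(W @ Xw)
        pair_scores = [_greedy_match_score(comps[a], comps[b])
                       for a in range(n_runs) for b in range(a + 1, n_runs)]
        scores[k] = float(np.mean(pair_scores))
    eligible = [k for k in ks if scores[k] >= consistency_min]
    if eligible:
        return int(max(eligible))
    best = max(scores.values())
    return int(min(k for k in ks if scores[k] >= best - 1e-12))


def _greedy_match_score(Sa: np.ndarray, Sb: np.ndarray) -> float:
    k = Sa.shape[0]
    c = np.abs(np.corrcoef(Sa, Sb)[:k, k:]).copy()
    total = 0.0
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(c), c.shape)
        total += c[i, j]
        c[i, :] = -1
        c[:, j] = -1
    return total / k


# ---------------------------------------------------------------------------
# Component post-processing
# ---------------------------------------------------------------------------

def zscore_component(s: np.ndarray) -> np.ndarray:
    """(s - mean) / sd over the component row."""
    s = np.asarray(s, float)
    sd = s.std()
    if sd == 0:
        raise ValueError("constant component row cannot be z-scored")
    return (s - s.mean()) / sd


def threshold_component(z: np.ndarray, z_min: float = 3.5) -> np.ndarray:
    """Indices with |z| strictly above the threshold."""
    return np.flatnonzero(np.abs(np.asarray(z, float)) > z_min)


def top_fraction(weights: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Indices of the floor(fraction * len) largest |weights|.

    Ties across the cut are broken by ascending index (stable sort on
    descending magnitude), so the selection is deterministic.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    w = np.abs(np.asarray(weights, float))
    k = int(np.floor(fraction * len(w)))
    order = np.argsort(-w, kind="stable")
    return np.sort(order[:k])


def amari_index(W: np.ndarray, A: np.ndarray) -> float:
    """Permutation/scale-invariant separation error of unmixing W vs mixing A
    (0 = perfect). Standard normalized row/column-max form of P = W @ A."""
    P = np.abs(W @ A)
    k = P.shape[0]
    row = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1
    col = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1
    return float((row.sum() + col.sum()) / (2 * k * (k - 1)))
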