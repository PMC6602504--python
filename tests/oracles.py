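"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force (path enumeration, sign
enumeration, plain gradient descent) and share no code with the package's
implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from gcoupler.constants import AA_INDEX


def enumerate_alignment_score(hmm, query: str) -> float:
    """Best glocal alignment score by exhaustive enumeration of all paths.

    A path is a sequence of moves through the (node, residue) lattice:
    match (consume column + residue), delete (column only), insert (residue
    only, staying at the current node).  Scores are accumulated exactly as
    the model defines them: match emissions in log2-odds against the
    background, insert emissions zero, all transitions log2 of their
    probability, and a final transition into the end state.
    """
    L, n = hmm.n_columns, len(query)
    t = {k: np.log2(v) for k, v in hmm.transitions.items()}
    logodds = np.log2(hmm.emissions / hmm.background)

    def esc(j: int, i: int) -> float:
        ch = query[i]
        if ch not in AA_INDEX:
            return 0.0
        return float(logodds[j - 1, AA_INDEX[ch]])

    best = -math.inf

    def walk(state: str, j: int, i: int, score: float) -> None:
        nonlocal best
        if j == L and i == n:
            total = score + t[state + "m"][L]
            if total > best:
                best = total
            # inserts may still follow at node L before ending
        if j < L:
            if i < n:  # match consumes query[i] at column j+1
                walk("m", j + 1, i + 1, score + t[state + "m"][j] + esc(j + 1, i))
            walk("d", j + 1, i, score + t[state + "d"][j])
        if i < n:
            # insert at current node (emits background: 0 bits)
            walk("i", j, i + 1, score + t[state + "i"][j])

    walk("m", 0, 0, 0.0)
    return best


def exact_signed_rank_pvalue(diff: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p by 2^n sign enumeration.

    Requires non-zero differences with tie-free absolute values.
    """
    d = np.asarray(diff, dtype=float)
    d = d[d != 0.0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = float(ranks[d > 0].sum())
    w_all = np.array([
        float(np.sum(ranks[np.array(signs, dtype=bool)]))
        for signs in itertools.product([0, 1], repeat=n)
    ])
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def gd_logistic(X: np.ndarray, y_pm: np.ndarray, C: float,
                sample_weight: np.ndarray | None = None,
                max_iter: int = 50_000, tol: float = 1e-12):
    """Plain gradient descent with Armijo backtracking on the penalised
    logistic cost (1/2)wᵀw + C Σ sᵢ log(1 + exp(-yᵢ(xᵢᵀw + c)))."""
    n, p = X.shape
    s = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    w = np.zeros(p)
    c = 0.0

    def fval(w, c):
        m = -y_pm * (X @ w + c)
        return 0.5 * w @ w + C * float(np.sum(s * np.logaddexp(0.0, m)))

    def grad(w, c):
        z = y_pm * (X @ w + c)
        sig = 1.0 / (1.0 + np.exp(z))  # sigmoid(-margin)
        coef = -C * s * y_pm * sig
        return w + X.T @ coef, float(np.sum(coef))

    f = fval(w, c)
    for _ in range(max_iter):
        gw, gc = grad(w, c)
        gnorm2 = gw @ gw + gc * gc
        if gnorm2 < tol**0.5 * 1e-6:
            break
        step = 1.0
        while step > 1e-16:
            w2, c2 = w - step * gw, c - step * gc
            f2 = fval(w2, c2)
            if f2 <= f - 1e-4 * step * gnorm2:
                break
            step *= 0.5
        if abs(f - f2) < tol and gnorm2 < 1e-12:
            w, c, f = w2, c2, f2
            break
        w, c, f = w2, c2, f2
    return w, c, f


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the positive/negative pair-win rate with ties counted 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))
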