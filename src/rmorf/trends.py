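"""Coverage-trend decomposition of the (ORF length, read count) cloud.

In an enriched community, ORFs from genomes at a similar abundance fall
on a common line through the origin in the (length L, read count n)
plane; the slope s of that line times the read length r is the genomes'
fold coverage (c = s*r).  This module formalises those visually apparent
trends as a K-component Gaussian mixture on log per-ORF coverage
log(n*r/L), fitted by EM, with each component's slope refined as the
origin-constrained weighted least-squares slope over its
responsibilities.  K is chosen by BIC over a small range.

ORFs with zero mapped reads are excluded from fitting (their log
coverage is undefined) and reported separately.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError

log = logging.getLogger(__name__)

_VAR_FLOOR = 1e-6
_TOL = 1e-8
_MAX_ITER = 300


@dataclass(frozen=True)
class OrfCoveragePoint:
    """One ORF's point on the coverage plot: length L, read count n, c_hat = n*r/L."""

    orf_id: str
    L: int
    n: int
    c_hat: float

    @classmethod
    def make(cls, orf_id: str, L: int, n: int, r: int) -> "OrfCoveragePoint":
        return cls(orf_id=orf_id, L=L, n=n, c_hat=per_orf_coverage(n, L, r))


@dataclass
class CoverageTrendModel:
    """K coverage trends: slopes (reads/nt), fold coverages c_k = s_k * r,
    mixing weights, per-ORF membership, and the fit's log-likelihood/BIC.

    Components are sorted by strictly decreasing coverage.
    """

    K: int
    read_length: int
    slopes: np.ndarray           # reads per nt, shape (K,)
    coverages: np.ndarray        # fold, == slopes * read_length
    weights: np.ndarray          # mixing proportions, sum to 1
    mus: np.ndarray              # component means on log c_hat
    sigmas: np.ndarray           # component sds on log c_hat
    membership: dict[str, int]   # orf_id -> trend index (0 = highest coverage)
    log_likelihood: float
    bic: float
    n_points: int
    converged: bool = True

    def to_json(self, path) -> None:
        payload = {
            "K": self.K,
            "read_length": self.read_length,
            "slopes": self.slopes.tolist(),
            "coverages": self.coverages.tolist(),
            "weights": self.weights.tolist(),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_points": self.n_points,
            "converged": self.converged,
            "membership": self.membership,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def per_orf_coverage(n: int, L: int, r: int) -> float:
    """Fold coverage of one ORF: n reads of length r over L nt -> n*r/L."""
    if L <= 0:
        raise InputError(f"ORF length must be positive, got {L}")
    if r <= 0:
        raise InputError(f"read length must be positive, got {r}")
    if n < 0:
        raise InputError(f"read count must be >= 0, got {n}")
    return n * r / L


def _em_once(
    x: np.ndarray,
    v: np.ndarray,
    K: int,
    mu0: np.ndarray,
    sigma0: np.ndarray,
    w0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, bool]:
    """One EM run on 1-D data x with known per-point noise variances v.

    Component density: N(x_i; mu_k, sigma_k^2 + v_i), where v_i is the
    known counting-noise variance (~1/n for Poisson read counts on the
    log scale), so sigma_k carries only the excess dispersion beyond
    counting noise; without this the mixture buys extra components just
    to mimic the per-ORF heteroscedasticity.  M step: mu_k is the
    precision-weighted mean; sigma_k^2 follows a fixed-point
    reweighting update accepted only when it improves the EM Q-function
    (falling back to the previous value otherwise), so the observed
    log-likelihood stays monotone (asserted every iteration).
    Returns (mu, sigma, w, responsibilities, loglik, converged).
    """
    N = x.size
    s_lo = np.sqrt(_VAR_FLOOR)
    s_hi = max(float(x.max() - x.min()), 1.0)
    mu, sigma, w = mu0.copy(), np.clip(sigma0, s_lo, s_hi), w0.copy()
    prev_ll = -np.inf
    converged = False
    gamma = np.full((N, K), 1.0 / K)

    def neg_q_k(s: float, g: np.ndarray, mu_k: float) -> float:
        tot = s * s + v
        return float((g * (0.5 * np.log(tot) + 0.5 * (x - mu_k) ** 2 / tot)).sum())

    for _ in range(_MAX_ITER):
        # E step: responsibilities under total variance sigma_k^2 + v_i
        tot = sigma[None, :] ** 2 + v[:, None]
        logp = (
            np.log(np.maximum(w, 1e-300))[None, :]
            - 0.5 * np.log(2 * np.pi * tot)
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / tot
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        # EM guarantees monotone likelihood; a violation means a numerical bug
        assert ll >= prev_ll - 1e-6 * max(1.0, abs(prev_ll)), "EM log-likelihood decreased"
        gamma = np.exp(logp - lse[:, None])
        if ll - prev_ll < _TOL * max(1.0, abs(ll)) and np.isfinite(prev_ll):
            prev_ll = ll
            converged = True
            break
        prev_ll = ll
        # M step: coordinate ascent on Q per component
        nk = np.maximum(gamma.sum(axis=0), 1e-12)
        w = nk / N
        for k in range(K):
            g = gamma[:, k]
            for _inner in range(3):
                prec = g / (sigma[k] ** 2 + v)
                mu[k] = float((prec * x).sum() / np.maximum(prec.sum(), 1e-300))
                # fixed point of dQ/dsigma^2 = 0 under the current weights
                u2 = g / (sigma[k] ** 2 + v) ** 2
                num = float((u2 * ((x - mu[k]) ** 2 - v)).sum())
                den = float(np.maximum(u2.sum(), 1e-300))
                s_new = float(np.sqrt(np.clip(num / den, _VAR_FLOOR, s_hi ** 2)))
                if neg_q_k(s_new, g, mu[k]) <= neg_q_k(sigma[k], g, mu[k]):
                    sigma[k] = s_new
                else:
                    break
    return mu, sigma, w, gamma, prev_ll, converged


def fit_trend_mixture(
    points: Sequence[OrfCoveragePoint],
    K: int,
    read_length: int = 100,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 5,
) -> CoverageTrendModel:
    """Fit a K-trend model to nonzero-count coverage points.

    EM on log(c_hat) under a K-component Gaussian mixture; afterwards
    each component's slope is re-estimated as the origin-constrained
    weighted least-squares slope sum(gamma*n*L)/sum(gamma*L^2) over its
    responsibilities, and membership is the argmax responsibility.
    """
    if K < 1:
        raise InputError(f"K must be >= 1, got {K}")
    pts = [p for p in points if p.n > 0]
    if any(p.n == 0 for p in points):
        log.info("excluded %d zero-count ORFs from trend fit", len(points) - len(pts))
    if not pts:
        raise InputError("no points with nonzero read counts")
    x = np.log(np.array([p.c_hat for p in pts]))
    # counting-noise variance of log coverage: Var(log n) ~ 1/n for Poisson counts
    v = 1.0 / np.array([p.n for p in pts], dtype=float)
    n_distinct = np.unique(x).size
    if K > n_distinct:
        raise InputError(f"K={K} exceeds the {n_distinct} distinct coverage values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    span = x.max() - x.min()
    best = None
    for restart in range(max(1, n_restarts)):
        # K evenly spaced quantiles, jittered on restarts after the first
        q = (np.arange(K) + 0.5) / K
        if restart > 0:
            q = np.clip(q + rng.uniform(-0.5 / K, 0.5 / K, size=K), 0.0, 1.0)
        mu0 = np.quantile(x, q)
        sigma0 = np.full(K, max(span / max(K, 1), 0.05))
        w0 = np.full(K, 1.0 / K)
        fit = _em_once(x, v, K, mu0, sigma0, w0)
        if best is None or fit[4] > best[4]:
            best = fit
    mu, sigma, w, gamma, ll, converged = best
    if not converged:
        warnings.warn("EM did not converge within the iteration cap; best iterate returned")

    # origin-constrained WLS slope per component over responsibilities
    L = np.array([p.L for p in pts], dtype=float)
    n = np.array([p.n for p in pts], dtype=float)
    slopes = (gamma * (n * L)[:, None]).sum(axis=0) / np.maximum(
        (gamma * (L * L)[:, None]).sum(axis=0), 1e-300
    )
    coverages = slopes * read_length

    order = np.argsort(-coverages)
    slopes, coverages = slopes[order], coverages[order]
    mu, sigma, w = mu[order], sigma[order], w[order]
    gamma = gamma[:, order]
    labels = gamma.argmax(axis=1)
    membership = {p.orf_id: int(lab) for p, lab in zip(pts, labels)}

    p_free = 3 * K - 1
    bic = -2.0 * ll + p_free * np.log(len(pts))
    return CoverageTrendModel(
        K=K, read_length=read_length, slopes=slopes, coverages=coverages,
        weights=w, mus=mu, sigmas=sigma, membership=membership,
        log_likelihood=ll, bic=float(bic), n_points=len(pts), converged=converged,
    )


def select_num_trends(
    points: Sequence[OrfCoveragePoint],
    K_range: Sequence[int] = range(1, 6),
    read_length: int = 100,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 5,
) -> CoverageTrendModel:
    """Fit each K in the range and return the model minimising BIC."""
    pts = [p for p in points if p.n > 0]
    if len(pts) < 10:
        warnings.warn(f"only {len(pts)} nonzero points; capping K at 1")
        K_range = [1]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_distinct = np.unique([p.c_hat for p in pts]).size
    best: CoverageTrendModel | None = None
    for K in K_range:
        if K > n_distinct:
            break
        model = fit_trend_mixture(points, K, read_length=read_length,
                                  seed=rng, n_restarts=n_restarts)
        log.info("K=%d: loglik=%.2f BIC=%.2f", K, model.log_likelihood, model.bic)
        if best is None or model.bic < best.bic:
            best = model
    assert best is not None
    return best


def trend_taxonomy_summary(
    model: CoverageTrendModel, orf_taxa: Mapping[str, str]
) -> dict[int, dict[str, float]]:
    """Per-trend taxon composition: fraction of member ORFs per taxon.

    ORFs missing from ``orf_taxa`` are labelled 'unassigned'.  Fractions
    sum to 1 within each non-empty trend; empty trends yield empty
    tables.
    """
    totals: dict[int, int] = {k: 0 for k in range(model.K)}
    counts: dict[int, dict[str, int]] = {k: {} for k in range(model.K)}
    for orf_id, trend in model.membership.items():
        taxon = orf_taxa.get(orf_id, "unassigned")
        totals[trend] += 1
        counts[trend][taxon] = counts[trend].get(taxon, 0) + 1
    return {
        k: {t: c / totals[k] for t, c in sorted(counts[k].items())} if totals[k] else {}
        for k in range(model.K)
    }


def plot_trends(points: Sequence[OrfCoveragePoint], model: CoverageTrendModel, path) -> None:
    """Scatter of (L, n) coloured by trend membership, with the fitted lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    colors = plt.cm.tab10.colors
    pts = [p for p in points if p.orf_id in model.membership]
    L = np.array([p.L for p in pts])
    n = np.array([p.n for p in pts])
    lab = np.array([model.membership[p.orf_id] for p in pts])
    for k in range(model.K):
        sel = lab == k
        ax.scatter(L[sel], n[sel], s=6, color=colors[k % 10],
                   label=f"trend {k + 1}: {model.coverages[k]:.0f}x")
    xs = np.linspace(0, L.max() if L.size else 1, 50)
    for k in range(model.K):
        ax.plot(xs, model.slopes[k] * xs, color=colors[k % 10], lw=1)
    ax.set_xlabel("ORF length (nt)")
    ax.set_ylabel("reads aligned to ORF")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
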