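"""Absolute integer copy-number inference from segment copy ratios.

The segment copy ratios R_j of a cell subgroup are modeled by a mixture over
integer CN states Q = {1, ..., I}:

    P(R_j | mu, sigma^2, theta, w_j) =
        sum_q P(q | theta_q, w_j) * N(R_j | mu_q, sigma^2)

with a maximum-entropy prior over states,

    P(q | theta_q, w_j) = exp(-theta_q * q# * w_j) / sum_k exp(-theta_k * k# * w_j)

(q# is the 1-based rank of q in Q and w_j the genomic fraction of segment j).
theta is estimated by Nelder-Mead so that each theta_q matches the expected
genomic fraction of state q.  The expected ratio per state is constrained to
a line mu_q = mu_1 + (q - 1) * Delta; a small set of candidate spacings Delta
(from density modes of the ratio histogram, always including the diploid
anchor ratio 1 <-> CN 2) is fit by maximum likelihood, and the candidate with
minimum AIC gives the final integer CN states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.signal import find_peaks
from scipy.special import logsumexp
from scipy.stats import gaussian_kde

from clonecn.segmentation import Segmentation

logger = logging.getLogger(__name__)

SIGMA2_FLOOR = 1e-6
#: mass of the uniform outlier component in the emission mixture
OUTLIER_EPS = 0.01
#: fallback spacing grid when the ratio histogram shows a single mode
FALLBACK_DELTAS = (0.25, 1.0 / 3.0, 0.5)


@dataclass
class Candidate:
    """One linear-spacing hypothesis: mu_q = mu1 + (q-1) * delta."""

    mu1: float
    delta: float

    def mu(self, n_states: int) -> np.ndarray:
        return self.mu1 + np.arange(n_states) * self.delta


@dataclass
class CNModel:
    """A fitted candidate: state means, shared variance, prior and fit stats."""

    Q: np.ndarray  # integer CN states, ascending
    theta: np.ndarray  # theta_q per state
    mu: np.ndarray  # expected ratio per state (strictly increasing)
    sigma2: float
    candidate: Candidate
    logL: float
    aic: float
    n_params: int

    def prior(self, w: np.ndarray) -> np.ndarray:
        return prior_prob(self.theta, w)


@dataclass
class CloneCNProfile:
    """Integer CN per segment with posteriors, ploidy and reliability."""

    cn: np.ndarray  # argmax-posterior integer CN per segment
    posterior: np.ndarray  # segments x |Q|
    ploidy: float
    reliability: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# prior and theta estimation
# ---------------------------------------------------------------------------


def prior_prob(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Maximum-entropy prior P(q | theta_q, w_j) for every segment.

    Returns an (n_segments, n_states) matrix; each row sums to 1.  The state
    rank q# is 1-based.  Overflow is guarded by max-subtraction.
    """
    theta = np.asarray(theta, dtype=np.float64)
    w = np.atleast_1d(np.asarray(w, dtype=np.float64))
    rank = np.arange(1, len(theta) + 1)
    logits = -np.outer(w, theta * rank)  # (l, |Q|)
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def _theta_loss(theta: np.ndarray, w: np.ndarray) -> float:
    """sqrt( sum_q ( sum_j w_j P(q|theta,w_j) - theta_q )^2 )."""
    p = prior_prob(theta, w)
    expected_frac = w @ p
    return float(np.sqrt(np.sum((expected_frac - theta) ** 2)))


def _theta_init(
    w: np.ndarray, Q: np.ndarray, ratios: np.ndarray | None
) -> np.ndarray:
    """Deterministic start: genomic fraction of each state under the
    diploid-anchored Delta = 0.5 nearest-state map (uniform if no ratios)."""
    if ratios is None:
        return np.full(len(Q), 1.0 / len(Q))
    mu = 1.0 + (Q - 2) * 0.5
    nearest = np.argmin(np.abs(ratios[:, None] - mu[None, :]), axis=1)
    init = np.bincount(nearest, weights=w, minlength=len(Q))
    return init / init.sum()


def estimate_theta(
    w: np.ndarray,
    Q: np.ndarray,
    ratios: np.ndarray | None = None,
    maxiter: int = 5000,
) -> tuple[np.ndarray, float]:
    """Estimate theta by Nelder-Mead from a fixed deterministic start.

    Returns (theta_hat, achieved_loss).  Non-convergence returns the best
    point found, with a warning.
    """
    w = np.asarray(w, dtype=np.float64)
    x0 = _theta_init(w, np.asarray(Q), ratios)
    res = minimize(
        _theta_loss,
        x0,
        args=(w,),
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-10},
    )
    if not res.success:
        logger.warning("theta estimation did not converge: %s", res.message)
    return res.x, float(res.fun)


# ---------------------------------------------------------------------------
# candidate construction
# ---------------------------------------------------------------------------


def density_modes(
    ratios: np.ndarray, w: np.ndarray, grid_size: int = 512, max_bw: float = 0.08
) -> np.ndarray:
    """Modes of the w-weighted Gaussian-KDE density of segment ratios.

    Bandwidth is Silverman's rule capped at ``max_bw`` ratio units: segment
    medians cluster tightly (sd ~0.05) around state means >= 0.2 apart, and
    an uncapped bandwidth merges adjacent states into one mode.
    """
    ratios = np.asarray(ratios, dtype=np.float64)
    if len(ratios) < 2 or np.ptp(ratios) < 1e-9:
        return np.array([float(np.median(ratios))])
    try:
        kde = gaussian_kde(ratios, bw_method="silverman", weights=w)
        data_sd = np.sqrt(kde.covariance[0, 0]) / kde.factor
        if data_sd > 0:
            kde.set_bandwidth(min(kde.factor, max_bw / data_sd))
    except np.linalg.LinAlgError:
        return np.array([float(np.median(ratios))])
    pad = 0.25 * np.ptp(ratios) + 0.05
    grid = np.linspace(ratios.min() - pad, ratios.max() + pad, grid_size)
    dens = kde(grid)
    peaks = find_peaks(dens)[0]  # plateau-aware local maxima
    if len(peaks) == 0:
        return np.array([float(grid[np.argmax(dens)])])
    return grid[peaks]


def build_candidates(
    ratios: np.ndarray,
    w: np.ndarray,
    max_cn: int = 8,
    max_candidates: int = 60,
) -> list[Candidate]:
    """Candidate (mu1, Delta) pairs from the ratio histogram.

    The Delta pool combines (a) pairwise distances between adjacent KDE modes
    together with their halves and thirds (adjacent observed modes may be more
    than one copy apart), and (b) proportional placements Delta = mode / q
    that put a density mode exactly on integer state q.  Single-mode profiles
    fall back to the grid {0.25, 1/3, 0.5}.

    Since accessibility scales with copy number, the expected ratio ladder
    passes through the origin: mu_q ~= q * Delta.  Each Delta therefore gets
    a proportional anchor mu1 = Delta, plus the diploid anchor mu1 = 1 - Delta
    (ratio 1 <-> CN 2; identical to the proportional anchor at Delta = 0.5).
    All candidates satisfy 0 < Delta < 1.
    """
    ratios = np.asarray(ratios, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    modes = density_modes(ratios, w)

    # the state ladder must be able to reach the largest observed ratio
    delta_min = ratios.max() / (max_cn + 0.5)
    deltas: set[float] = set()

    def add_delta(d: float, lo: float = 0.0, hi: float = 1.0) -> None:
        if d >= delta_min and lo < d < hi:
            deltas.add(round(float(d), 6))

    # raw adjacent-mode gaps; spacings below 0.2 are "unrealistically small"
    # for a single-copy step (the reliability score penalizes them too)
    for g in np.diff(np.sort(modes)):
        add_delta(g, lo=0.2)
    # derived spacings (gap subdivisions for modes >1 copy apart, and
    # proportional placements mode/q): restricted to the physically
    # plausible per-copy range — the diploid reference pins the ratio
    # scale near CN/2, so the true spacing sits near 0.5
    for g in np.diff(np.sort(modes)):
        for div in (2, 3):
            add_delta(g / div, lo=0.3, hi=0.8)
    for m in modes:
        for q in range(1, max_cn + 1):
            add_delta(m / q, lo=0.3, hi=0.8)
    if len(modes) < 2 and not deltas:
        for d in FALLBACK_DELTAS:
            add_delta(d)
    if not deltas:  # pathological scale: fall back unconditionally
        deltas = {d for d in FALLBACK_DELTAS}

    seen: set[tuple[float, float]] = set()
    candidates: list[Candidate] = []

    def add(mu1: float, delta: float) -> None:
        if mu1 <= 0:
            return
        key = (round(mu1, 3), round(delta, 3))
        if key in seen:
            return
        seen.add(key)
        candidates.append(Candidate(mu1=float(mu1), delta=float(delta)))

    for delta in sorted(deltas, reverse=True):
        add(delta, delta)  # proportional anchor: mu_q = q * Delta
        add(1.0 - delta, delta)  # diploid anchor: ratio 1 <-> CN 2
    return candidates[:max_candidates]


# ---------------------------------------------------------------------------
# likelihood fitting and model selection
# ---------------------------------------------------------------------------


def _log_lik(
    ratios: np.ndarray,
    w: np.ndarray,
    mu: np.ndarray,
    sigma2: float,
    theta: np.ndarray,
) -> float:
    """Mixture log-likelihood of segment ratios, weighted by genomic fraction.

    Per-segment terms are weighted by l * w_j (mean weight 1): long segments
    carry precise median ratios while short ones are noisy, so
    fraction-weighting approximates inverse-variance weighting and stops
    many tiny noisy segments from dominating the fit.
    """
    prior = prior_prob(theta, w)
    resid2 = (ratios[:, None] - mu[None, :]) ** 2
    log_norm = -0.5 * (np.log(2 * np.pi * sigma2) + resid2 / sigma2)
    per_seg = logsumexp(np.log(prior + 1e-300) + log_norm, axis=1)
    # small uniform outlier component: a lone noisy segment stranded between
    # states must not dominate sigma^2 or the spacing selection
    unif = OUTLIER_EPS / (mu.max() + 1.0)
    per_seg = np.logaddexp(np.log1p(-OUTLIER_EPS) + per_seg, np.log(unif))
    omega = len(w) * w / w.sum()
    return float(np.sum(omega * per_seg))


def fit_model(
    segments: Segmentation,
    candidate: Candidate,
    theta_hat: np.ndarray,
    max_cn: int = 8,
    refine_mu1: bool = True,
) -> CNModel:
    """Maximum-likelihood fit of sigma^2 (and a local mu1 refinement within
    +/- Delta/4 of the anchor) for one candidate spacing."""
    ratios, w = segments.ratios, segments.w
    Q = np.arange(1, max_cn + 1)
    theta_hat = np.asarray(theta_hat, dtype=np.float64)

    def unpack(x: np.ndarray) -> tuple[np.ndarray, float]:
        mu1 = x[0]
        sigma2 = max(np.exp(x[1]), SIGMA2_FLOOR)
        return Candidate(mu1, candidate.delta).mu(max_cn), sigma2

    def neg(x: np.ndarray) -> float:
        mu, sigma2 = unpack(x)
        return -_log_lik(ratios, w, mu, sigma2, theta_hat)

    mu0 = candidate.mu(max_cn)
    nearest = np.argmin(np.abs(ratios[:, None] - mu0[None, :]), axis=1)
    resid = ratios - mu0[nearest]
    s2_init = max(float(np.average(resid**2, weights=w)), SIGMA2_FLOOR)
    x0 = np.array([candidate.mu1, np.log(s2_init)])
    half = candidate.delta / 4.0 if refine_mu1 else 0.0
    bounds = [
        (candidate.mu1 - half, candidate.mu1 + half),
        (np.log(SIGMA2_FLOOR), 5.0),
    ]
    res = minimize(
        neg, x0, method="Nelder-Mead", bounds=bounds,
        options={"maxiter": 500, "xatol": 1e-8, "fatol": 1e-10},
    )
    mu, sigma2 = unpack(res.x)
    logL = -float(res.fun)
    # free continuous params (sigma2, refined mu1) + |Q| theta components
    n_params = (2 if refine_mu1 else 1) + max_cn
    return CNModel(
        Q=Q,
        theta=theta_hat,
        mu=mu,
        sigma2=sigma2,
        candidate=Candidate(float(mu[0]), candidate.delta),
        logL=logL,
        aic=2 * n_params - 2 * logL,
        n_params=n_params,
    )


def select_by_aic(
    fits: list[CNModel],
    segments: Segmentation | None = None,
    aic_tol: float = 2.0,
) -> CNModel:
    """Minimum-AIC candidate, with a parsimony rule for near-ties.

    A spacing Delta and its half (or double) fit the same ratio levels
    equally well — the ladders only relabel the states — so AIC differences
    between them are optimizer noise.  Among fits within ``aic_tol`` of the
    minimum (the conventional "substantial support" window) the diploid
    reference breaks the tie: the state carrying the dominant genomic
    fraction should be CN 2, since reference cells are diploid and most of a
    tumor genome is copy-neutral.  Remaining ties go to lower implied
    ploidy, then smaller Delta.  Without ``segments`` plain minimum AIC
    applies.
    """
    if not fits:
        raise ValueError("no fitted candidates")
    best_aic = min(m.aic for m in fits)
    if segments is None:
        return min(
            fits, key=lambda m: (round(m.aic, 9), m.candidate.delta, -m.mu[0])
        )
    near = [m for m in fits if m.aic <= best_aic + aic_tol]
    w = segments.w

    def key(m: CNModel):
        prof = posterior_cn(m, segments)
        state_w = np.bincount(
            np.searchsorted(m.Q, prof.cn), weights=w, minlength=len(m.Q)
        )
        dominant = int(m.Q[np.argmax(state_w)])
        return (
            abs(dominant - 2),
            round(prof.ploidy, 6),
            m.candidate.delta,
            m.mu[0],
        )

    return min(near, key=key)


def posterior_cn(model: CNModel, segments: Segmentation) -> CloneCNProfile:
    """Posterior P(CN = q | segment_j) ∝ prior * N(R_j | mu_q, sigma^2).

    The CN call is the argmax; exact ties resolve to the lower state.
    """
    ratios, w = segments.ratios, segments.w
    prior = model.prior(w)
    resid2 = (ratios[:, None] - model.mu[None, :]) ** 2
    log_post = np.log(prior + 1e-300) - 0.5 * resid2 / model.sigma2
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post)
    cn = model.Q[np.argmax(post, axis=1)]  # argmax picks first (lowest q) on ties
    ploidy = compute_ploidy(cn, w)
    return CloneCNProfile(cn=cn, posterior=post, ploidy=ploidy)


def compute_ploidy(cn: np.ndarray, w: np.ndarray) -> float:
    """Length-weighted average integer CN: ploidy = sum_j w_j * q_hat_j."""
    return float(np.sum(np.asarray(w) * np.asarray(cn)))


def reliability_score(
    profile: CloneCNProfile,
    model: CNModel,
    segments: Segmentation,
    mse_scale: float = 5.0,
    delta_floor: float = 0.2,
    max_segments: int = 100,
    ploidy_range: tuple[float, float] = (1.5, 5.0),
) -> float:
    """Composite [0, 1] reliability of a clone CN profile.

    Combines (a) the w-weighted MSE of segment ratios around their assigned
    state means (via exp(-mse_scale * MSE), monotone decreasing in MSE) and
    (b) the genome fraction "well explained" — residual within Delta/2 of the
    assigned state.  Multiplicative penalties for an unrealistically small
    single-copy spacing (Delta < delta_floor), excessive segmentation, and
    extreme ploidy.  A perfect diploid-like fit scores 1.0.
    """
    ratios, w = segments.ratios, segments.w
    idx = np.searchsorted(model.Q, profile.cn)
    resid = ratios - model.mu[idx]
    mse = float(np.sum(w * resid**2))
    delta = model.candidate.delta
    explained = float(np.sum(w[np.abs(resid) < delta / 2.0]))
    score = explained * np.exp(-mse_scale * mse)
    if delta < delta_floor:
        score *= 0.5
    if len(segments) > max_segments:
        score *= 0.8
    if not (ploidy_range[0] <= profile.ploidy <= ploidy_range[1]):
        score *= 0.5
    return float(np.clip(score, 0.0, 1.0))


def infer_clone_cn(
    segments: Segmentation,
    max_cn: int = 8,
    refine_mu1: bool = True,
) -> tuple[CNModel, CloneCNProfile]:
    """Full per-subgroup inference: theta, candidates, MLE fits, AIC pick,
    posterior CN, ploidy and reliability."""
    ratios, w = segments.ratios, segments.w
    Q = np.arange(1, max_cn + 1)
    theta_hat, _ = estimate_theta(w, Q, ratios)
    candidates = build_candidates(ratios, w, max_cn=max_cn)
    fits = [
        fit_model(segments, c, theta_hat, max_cn=max_cn, refine_mu1=refine_mu1)
        for c in candidates
    ]
    model = select_by_aic(fits, segments)
    profile = posterior_cn(model, segments)
    profile.reliability = reliability_score(profile, model, segments)
    return model, profile


def model_to_dict(model: CNModel) -> dict:
    """JSON-serializable dump of a fitted model."""
    return {
        "Q": model.Q.tolist(),
        "theta": model.theta.tolist(),
        "mu": model.mu.tolist(),
        "sigma2": model.sigma2,
        "delta": model.candidate.delta,
        "mu1": model.candidate.mu1,
        "logL": model.logL,
        "aic": model.aic,
        "n_params": model.n_params,
    }
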