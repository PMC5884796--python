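"""Two-component mixture-model footprint calling on motif-anchored,
strand-specific Tn5 cut-count matrices.

Model for a motif occurrence l with count row X_l (length S = 2(2L+1)) and
row total R_l:

    Z_l ~ Bernoulli(pi_l),      logit(pi_l) = beta . (1, score_l)
    Z = 1 (bound):   R_l ~ NegBin(mu1, phi1),  X_l | R_l ~ Mult(R_l, tau)
    Z = 0 (unbound): R_l ~ NegBin(mu0, phi0),  uniform spatial profile 1/S

NegBin uses the mean/dispersion parameterization, variance mu + mu^2/phi.
EM alternates exact posteriors with blockwise-maximizing M-steps (weighted
means for mu, bounded 1-D likelihood maximization for phi, IRLS for beta,
closed-form smoothed tau), each guarded to never decrease the objective, so
the recorded trace is non-decreasing.  The trace is the observed-data log
likelihood plus the Dirichlet smoothing term for tau (pseudocount 1 per
column); the constant multinomial coefficient is omitted from both
components, where it cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, gammaln, logsumexp

from .core import CutSiteTrack, GenomicInterval, PeakSet
from .motif_scan import MotifOccurrence


@dataclass
class CutCountMatrix:
    """N occurrences x S = 2(2L+1) strand-specific insertion counts.

    Columns 0..2L are the motif-forward strand 5'->3' in the motif frame;
    columns 2L+1..S-1 are the opposite strand.  Rows for '-' occurrences
    were coordinate-reversed and strand-swapped at construction so every
    row shares the motif-relative frame.
    """

    motif_id: str
    occurrences: List[MotifOccurrence]
    counts: np.ndarray
    L: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        S = 2 * (2 * self.L + 1)
        if self.counts.ndim != 2 or self.counts.shape[1] != S:
            raise ValueError(f"counts must have S = {S} columns")
        if len(self.occurrences) != self.counts.shape[0]:
            raise ValueError("occurrences/counts length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def S(self) -> int:
        return self.counts.shape[1]

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def build_cut_matrix(occurrences: Sequence[MotifOccurrence], track: CutSiteTrack,
                     L: int = 100) -> CutCountMatrix:
    """Assemble the +/- L bp strand-specific count matrix around motif centers.

    The window anchor is the motif center start + floor(width/2) (the
    left-of-center base for even widths).  Occurrences whose window does
    not fit inside the chromosome coordinates available are dropped with a
    warning.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if not occurrences:
        raise ValueError("need at least one occurrence")
    motif_id = occurrences[0].motif_id
    rows = []
    kept = []
    dropped = 0
    for occ in occurrences:
        iv = occ.interval
        center = iv.start + iv.length // 2
        lo, hi = center - L, center + L + 1
        if lo < 0:
            dropped += 1
            continue
        plus = track.window_counts(iv.chrom, "+", lo, hi)
        minus = track.window_counts(iv.chrom, "-", lo, hi)
        if iv.strand == "-":
            row = np.concatenate([minus[::-1], plus[::-1]])
        else:
            row = np.concatenate([plus, minus])
        rows.append(row)
        kept.append(occ)
    if dropped:
        warnings.warn(f"dropped {dropped} occurrences with windows off the chromosome edge")
    if not kept:
        raise ValueError("no occurrence windows fit inside the chromosomes")
    return CutCountMatrix(motif_id, kept, np.vstack(rows), L)


@dataclass
class CentipedeFit:
    tau: np.ndarray  # length-S bound spatial profile, sums to 1
    mu1: float
    phi1: float
    mu0: float
    phi0: float
    beta: np.ndarray  # logistic prior coefficients (intercept, score)
    posterior: np.ndarray  # per-occurrence P(bound | data)
    loglik_trace: List[float]
    converged: bool
    n_iter: int

    def to_dict(self) -> Dict:
        return {
            "tau": self.tau.tolist(), "mu1": self.mu1, "phi1": self.phi1,
            "mu0": self.mu0, "phi0": self.phi0, "beta": self.beta.tolist(),
            "posterior": self.posterior.tolist(),
            "loglik_trace": self.loglik_trace,
            "converged": self.converged, "n_iter": self.n_iter,
        }


def log_negbin(r: np.ndarray, mu: float, phi: float) -> np.ndarray:
    """log pmf of NegBin with mean mu, dispersion phi (var = mu + mu^2/phi)."""
    r = np.asarray(r, dtype=float)
    return (gammaln(r + phi) - gammaln(phi) - gammaln(r + 1)
            + phi * np.log(phi / (phi + mu)) + r * np.log(mu / (phi + mu)))


def _component_loglik(counts: np.ndarray, totals: np.ndarray, tau: np.ndarray,
                      mu1: float, phi1: float, mu0: float, phi0: float
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-row log P(X | Z=1) and log P(X | Z=0), multinomial coeff omitted."""
    S = counts.shape[1]
    log_tau = np.log(tau)
    l1 = log_negbin(totals, mu1, phi1) + counts @ log_tau
    l0 = log_negbin(totals, mu0, phi0) - totals * np.log(S)
    return l1, l0


def _observed_loglik(l1: np.ndarray, l0: np.ndarray, eta: np.ndarray,
                     tau: np.ndarray, eps: float) -> float:
    # log(pi) = -log(1 + e^-eta), log(1-pi) = -log(1 + e^eta); stable forms
    log_pi = -np.logaddexp(0.0, -eta)
    log_1mpi = -np.logaddexp(0.0, eta)
    ll = logsumexp(np.stack([log_pi + l1, log_1mpi + l0]), axis=0).sum()
    return float(ll + eps * np.log(tau).sum())


def _weighted_nb_fit(r: np.ndarray, w: np.ndarray, mu_old: float,
                     phi_old: float) -> Tuple[float, float]:
    """Posterior-weighted NegBin MLE: exact weighted mean; phi by bounded
    1-D maximization with a keep-better safeguard against the old value."""
    wsum = w.sum()
    if wsum <= 1e-12:
        return mu_old, phi_old
    mu = float(np.clip((w * r).sum() / wsum, 1e-6, None))

    def nll(log_phi: float) -> float:
        return -float((w * log_negbin(r, mu, np.exp(log_phi))).sum())

    res = minimize_scalar(nll, bounds=(np.log(1e-2), np.log(1e6)), method="bounded")
    phi = float(np.exp(res.x))
    if nll(np.log(phi_old)) < res.fun:
        phi = phi_old
    return mu, phi


def _logistic_irls(x: np.ndarray, gamma: np.ndarray, beta0: np.ndarray,
                   max_iter: int = 50, ridge: float = 1e-8) -> np.ndarray:
    """Maximize sum gamma*log(sigma(eta)) + (1-gamma)*log(1-sigma(eta))."""
    beta = beta0.copy()

    def obj(b):
        eta = x @ b
        return float((gamma * (-np.logaddexp(0, -eta))
                      + (1 - gamma) * (-np.logaddexp(0, eta))).sum())

    best, best_obj = beta0.copy(), obj(beta0)
    for _ in range(max_iter):
        eta = x @ beta
        p = expit(eta)
        wdiag = np.clip(p * (1 - p), 1e-10, None)
        grad = x.T @ (gamma - p)
        hess = (x * wdiag[:, None]).T @ x + ridge * np.eye(x.shape[1])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        beta = np.clip(beta, -30, 30)  # separation guard
        if np.max(np.abs(step)) < 1e-10:
            break
    if obj(beta) > best_obj:
        best = beta
    return best


def fit_centipede(matrix: CutCountMatrix, covariates: Optional[np.ndarray] = None,
                  max_iter: int = 200, tol: float = 1e-6,
                  tau_pseudocount: float = 1.0, seed: int = 0) -> CentipedeFit:
    """EM fit of the two-component footprint mixture.

    ``covariates`` is the per-occurrence PWM score (defaults to the stored
    occurrence scores); the logistic prior uses (intercept, score).
    Initialization puts posterior 0.9 on rows in the top quartile of
    totals and 0.1 elsewhere, which breaks symmetry deterministically.  If
    the bound mean drops below the unbound mean after an M-step the
    components are swapped to keep mu1 >= mu0.
    """
    counts = matrix.counts.astype(float)
    n, S = counts.shape
    if n < 20:
        raise ValueError(f"need >= 20 occurrences for a stable fit, got {n}")
    totals = counts.sum(axis=1)
    if totals.sum() == 0:
        raise ValueError("all-zero count matrix: no signal to fit")
    if covariates is None:
        covariates = np.array([occ.score for occ in matrix.occurrences], dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    x = np.column_stack([np.ones(n), covariates])
    eps = tau_pseudocount

    q75 = np.quantile(totals, 0.75)
    gamma = np.where(totals >= q75, 0.9, 0.1)

    def m_step(gamma, mu1, phi1, mu0, phi0, beta):
        tau = (gamma @ counts + eps) / ((gamma * totals).sum() + eps * S)
        mu1, phi1 = _weighted_nb_fit(totals, gamma, mu1, phi1)
        mu0, phi0 = _weighted_nb_fit(totals, 1.0 - gamma, mu0, phi0)
        beta = _logistic_irls(x, gamma, beta)
        return tau, mu1, phi1, mu0, phi0, beta

    mu1 = float(max(totals[totals >= q75].mean(), 1e-3))
    mu0 = float(max(totals[totals < q75].mean() if np.any(totals < q75) else mu1 / 2, 1e-3))
    phi1 = phi0 = 10.0
    beta = np.zeros(2)
    tau, mu1, phi1, mu0, phi0, beta = m_step(gamma, mu1, phi1, mu0, phi0, beta)

    trace: List[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        l1, l0 = _component_loglik(counts, totals, tau, mu1, phi1, mu0, phi0)
        eta = x @ beta
        gamma = expit(eta + l1 - l0)
        trace.append(_observed_loglik(l1, l0, eta, tau, eps))
        if len(trace) > 1:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) < tol * (abs(prev) + 1e-12):
                converged = True
                break
        tau, mu1, phi1, mu0, phi0, beta = m_step(gamma, mu1, phi1, mu0, phi0, beta)
        if mu1 < mu0:  # identifiability: bound component has the larger mean
            mu1, phi1, mu0, phi0 = mu0, phi0, mu1, phi1
            gamma = 1.0 - gamma
            beta = -beta
            tau = (gamma @ counts + eps) / ((gamma * totals).sum() + eps * S)
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations")

    l1, l0 = _component_loglik(counts, totals, tau, mu1, phi1, mu0, phi0)
    posterior = expit(x @ beta + l1 - l0)
    return CentipedeFit(tau=tau, mu1=mu1, phi1=phi1, mu0=mu0, phi0=phi0,
                        beta=beta, posterior=posterior, loglik_trace=trace,
                        converged=converged, n_iter=it)


@dataclass
class FootprintCall:
    occurrence: MotifOccurrence
    posterior: float
    bound: bool
    containing_peak: Optional[GenomicInterval] = None


def call_footprints(fit: CentipedeFit, matrix: CutCountMatrix, peaks: PeakSet,
                    posterior_threshold: float = 0.99) -> List[FootprintCall]:
    """Bound iff posterior strictly exceeds the threshold (default 0.99) and
    the motif interval is entirely contained within a peak."""
    calls = []
    merged = peaks.merged()
    for occ, post in zip(matrix.occurrences, fit.posterior):
        iv = occ.interval
        containing = None
        if merged.contains_interval(iv):
            for peak in merged.intervals:
                if peak.contains(iv):
                    containing = peak
                    break
        bound = bool(post > posterior_threshold and containing is not None)
        calls.append(FootprintCall(occ, float(post), bound, containing))
    return calls


@dataclass
class OccupancyProfile:
    motif_id: str
    sample: str
    cluster: str
    signal: np.ndarray  # length S, bound aggregate / unbound aggregate
    n_bound: int
    n_unbound: int


def occupancy_profile(matrix: CutCountMatrix, fit: CentipedeFit, peaks: PeakSet,
                      cluster_regions: Optional[Sequence[GenomicInterval]] = None,
                      seed: int = 0, sample: str = "", cluster: str = "all",
                      posterior_threshold: float = 0.99) -> OccupancyProfile:
    """Bound-over-unbound aggregate insertion signal in the motif frame.

    Bound set: footprint calls inside *cluster_regions* (all peaks when
    None).  Unbound set: a seeded simple random sample, of equal size, from
    occurrences with posterior <= 0.5 that do not intersect any peak.  The
    signal is (sum bound + 1) / (sum unbound + 1) per column; when the
    unbound pool is smaller than the bound set the whole pool is used.
    """
    calls = call_footprints(fit, matrix, peaks, posterior_threshold)
    region_set = None if cluster_regions is None else PeakSet(list(cluster_regions)).merged()
    bound_idx = [i for i, c in enumerate(calls)
                 if c.bound and (region_set is None
                                 or region_set.contains_interval(c.occurrence.interval))]
    if not bound_idx:
        return OccupancyProfile(matrix.motif_id, sample, cluster,
                                np.ones(matrix.S), 0, 0)
    merged = peaks.merged()
    pool = [i for i, c in enumerate(calls)
            if c.posterior <= 0.5 and not merged.overlaps_interval(c.occurrence.interval)]
    if not pool:
        raise ValueError("unbound pool is empty: no posterior <= 0.5 occurrences off peaks")
    rng = np.random.default_rng(seed)
    if len(pool) > len(bound_idx):
        unbound_idx = sorted(rng.choice(pool, size=len(bound_idx), replace=False).tolist())
    else:
        unbound_idx = pool
    bound_sum = matrix.counts[bound_idx].sum(axis=0).astype(float)
    unbound_sum = matrix.counts[unbound_idx].sum(axis=0).astype(float)
    signal = (bound_sum + 1.0) / (unbound_sum + 1.0)
    return OccupancyProfile(matrix.motif_id, sample, cluster, signal,
                            len(bound_idx), len(unbound_idx))
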