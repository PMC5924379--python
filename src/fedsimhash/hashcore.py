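"""Supervised multi-domain hashing by damped-Newton block coordinate descent.

The model learns, for each feature domain k, a linear hash function
``f_k(P) = W_k^T P`` whose sign gives ``b_k``-bit patient codes. Because
``sign`` is non-differentiable, each site's code block is relaxed to a real
matrix ``Q_k^i`` passed through the smooth surrogate
``S_L(q) = q / sqrt(q^2 + xi)``; the objective

    f(W, Q) =  sum_{i,k} || W_k^T P_k^i - S_L(Q_k^i) ||_F^2
             + lambda * sum_{i,k} tr( -S_L(Q_k^i) R^i S_L(Q_k^i)^T )
             + eta * sum_{i,k} || Q_k^i ||_F^2

couples a reconfiguration (projection-vs-code) error, a supervised loss
that pushes same-label patients toward similar codes and different-label
patients apart (``R^i`` is the +-1 label-agreement matrix), and a Frobenius
regularizer that pins down Q. Every term is additive over sites, which is
what makes the federated W update exact: sites only contribute d_k x d_k
and d_k x b_k aggregates.

Blocks are visited as W_1..W_K then every Q_k^i; each takes one Newton
step damped by step-halving so the objective never increases. The W
Hessian is block-diagonal across the b_k columns of W_k with identical
d_k x d_k blocks (exact: the first term separates over columns); the Q
Hessian is block-diagonal across bits with N_i x N_i blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from fedsimhash.errors import ConfigurationError, DimensionError, NumericError
from fedsimhash.features import FeatureDomainSpec, SiteDataset

MAX_HALVINGS = 20


@dataclass(frozen=True)
class HashConfig:
    """Hyperparameters of the hashing objective and its solver.

    ``bits_per_domain=None`` applies the study defaults: 2 bits for the
    demographics domain and 10 bits for every coded domain (52 bits total
    for the six-domain configuration). ``lambda_sup`` and ``eta`` default
    to 0.5 and 1e-3; ``xi`` controls the sharpness of the surrogate sign.
    """

    bits_per_domain: tuple[int, ...] | None = None
    lambda_sup: float = 0.5
    eta: float = 1e-3
    xi: float = 0.5
    max_iter: int = 100
    rel_tol: float = 1e-6
    hessian_ridge: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.xi <= 0:
            raise ConfigurationError(f"xi must be > 0, got {self.xi}")
        if self.lambda_sup < 0 or self.eta < 0 or self.hessian_ridge < 0:
            raise ConfigurationError("lambda_sup, eta, hessian_ridge must be >= 0")
        if self.bits_per_domain is not None and any(b < 1 for b in self.bits_per_domain):
            raise ConfigurationError("all b_k must be >= 1")

    def bits_for(self, spec: FeatureDomainSpec) -> tuple[int, ...]:
        """Resolve per-domain code lengths b_k for a feature spec."""
        if self.bits_per_domain is None:
            return tuple(2 if tag == "demo" else 10 for tag in spec.tags)
        if len(self.bits_per_domain) != spec.K:
            raise DimensionError(
                f"bits_per_domain has length {len(self.bits_per_domain)}, spec has K={spec.K}"
            )
        return tuple(self.bits_per_domain)


@dataclass
class HashModel:
    """Shared hash-function coefficients, one d_k x b_k block per domain."""

    spec: FeatureDomainSpec
    W: dict[str, np.ndarray]

    @property
    def bits(self) -> tuple[int, ...]:
        return tuple(self.W[tag].shape[1] for tag in self.spec.tags)

    @property
    def total_bits(self) -> int:
        return sum(self.bits)

    def copy(self) -> "HashModel":
        return HashModel(self.spec, {t: w.copy() for t, w in self.W.items()})


@dataclass
class SiteAux:
    """Per-site relaxation variables Q_k^i (b_k x N_i) whose signs are the codes."""

    site_index: int
    Q: dict[str, np.ndarray]

    def copy(self) -> "SiteAux":
        return SiteAux(self.site_index, {t: q.copy() for t, q in self.Q.items()})


@dataclass
class HashCodes:
    """Per-domain +-1 code matrices H_k^i (b_k x N_i); column j = patient j."""

    codes: dict[str, np.ndarray]
    patient_ids: list[str] = field(default_factory=list)

    def concatenated(self, tags: Sequence[str]) -> np.ndarray:
        """Stack per-domain codes into a (sum b_k) x N matrix."""
        return np.concatenate([self.codes[t] for t in tags], axis=0)


# ---------------------------------------------------------------------------
# surrogate sign and its derivatives

def surrogate_sign(Q: np.ndarray, xi: float) -> np.ndarray:
    """Smooth elementwise sign: q -> q / sqrt(q^2 + xi), in (-1, 1)."""
    if xi <= 0:
        raise ConfigurationError(f"xi must be > 0, got {xi}")
    Q = np.asarray(Q, dtype=float)
    return Q / np.sqrt(Q * Q + xi)


def _surrogate_d1(Q: np.ndarray, xi: float) -> np.ndarray:
    # d/dq [q (q^2+xi)^{-1/2}] = xi (q^2+xi)^{-3/2}
    return xi * np.power(Q * Q + xi, -1.5)


def _surrogate_d2(Q: np.ndarray, xi: float) -> np.ndarray:
    # second derivative: -3 xi q (q^2+xi)^{-5/2}
    return -3.0 * xi * Q * np.power(Q * Q + xi, -2.5)


# ---------------------------------------------------------------------------
# objective

def _site_domain_terms(
    W: np.ndarray, Q: np.ndarray, P: np.ndarray, R: np.ndarray, cfg: HashConfig
) -> float:
    S = surrogate_sign(Q, cfg.xi)
    resid = W.T @ P - S
    t1 = float(np.sum(resid * resid))
    t2 = -cfg.lambda_sup * float(np.sum((S @ R) * S))
    t3 = cfg.eta * float(np.sum(Q * Q))
    return t1 + t2 + t3


def site_objective(model: HashModel, aux: SiteAux, site: SiteDataset, cfg: HashConfig) -> float:
    """One site's additive contribution to the objective."""
    total = 0.0
    for tag in model.spec.tags:
        W, Q, P = model.W[tag], aux.Q[tag], site.P[tag]
        if W.shape[0] != P.shape[0] or Q.shape != (W.shape[1], P.shape[1]):
            raise DimensionError(
                f"site {site.site_index} domain {tag!r}: W {W.shape}, P {P.shape}, Q {Q.shape}"
            )
        total += _site_domain_terms(W, Q, P, site.R, cfg)
    return total


def objective_value(
    model: HashModel, aux: Sequence[SiteAux], sites: Sequence[SiteDataset], cfg: HashConfig
) -> float:
    """Total objective, additive over sites and domains."""
    return sum(site_objective(model, a, s, cfg) for a, s in zip(aux, sites))


# ---------------------------------------------------------------------------
# analytic derivatives

def w_statistics(site: SiteDataset, aux: SiteAux, tag: str, cfg: HashConfig):
    """One site's sufficient statistics for the W_k Newton step.

    Returns ``(G2, C, snorm)`` with ``G2 = P P^T`` (d_k x d_k),
    ``C = P S_L(Q)^T`` (d_k x b_k) and ``snorm = ||S_L(Q)||_F^2``; the
    site's contributions to gradient and Hessian are ``2 (G2 W - C)`` and
    ``2 G2`` per column. Nothing patient-level appears in any of them.
    """
    P = site.P[tag]
    S = surrogate_sign(aux.Q[tag], cfg.xi)
    return P @ P.T, P @ S.T, float(np.sum(S * S))


def derivatives_W(
    tag: str, model: HashModel, aux: SiteAux, site: SiteDataset, cfg: HashConfig
):
    """Gradient (d_k x b_k) and full Hessian (d_k b_k square) of one site's
    objective with respect to W_k, everything else fixed.

    Only the reconfiguration term involves W, so the Hessian is exactly
    block-diagonal: ``kron(I_{b_k}, 2 P P^T)`` in column-major block order.
    """
    W = model.W[tag]
    G2, C, _ = w_statistics(site, aux, tag, cfg)
    grad = 2.0 * (G2 @ W - C)
    if not np.all(np.isfinite(grad)):
        raise NumericError(f"non-finite W gradient for domain {tag!r}")
    b_k = W.shape[1]
    hess = np.kron(np.eye(b_k), 2.0 * G2)
    return grad, hess


def derivatives_Q(
    site_index: int,
    tag: str,
    model: HashModel,
    aux: SiteAux,
    site: SiteDataset,
    cfg: HashConfig,
):
    """Gradient (b_k x N_i) and full Hessian (b_k N_i square) with respect
    to Q_k^i, chain-ruled through the surrogate sign.

    With ``S = S_L(Q)``, ``A = W_k^T P_k^i``, ``s' = dS/dq``:

        grad = 2 (S - A) o s'  -  2 lambda (S R) o s'  +  2 eta Q

    The Hessian is block-diagonal across the b_k bits; each N_i x N_i
    block couples patients only through R (flattening order is row-major:
    bit-major, patient-minor).
    """
    W, Q, P, R = model.W[tag], aux.Q[tag], site.P[tag], site.R
    b_k, n = Q.shape
    S = surrogate_sign(Q, cfg.xi)
    s1 = _surrogate_d1(Q, cfg.xi)
    s2 = _surrogate_d2(Q, cfg.xi)
    A = W.T @ P
    SR = S @ R
    lam, eta = cfg.lambda_sup, cfg.eta

    grad = 2.0 * (S - A) * s1 - 2.0 * lam * SR * s1 + 2.0 * eta * Q
    if not np.all(np.isfinite(grad)):
        raise NumericError(f"non-finite Q gradient for site {site_index} domain {tag!r}")

    hess = np.zeros((b_k * n, b_k * n))
    diag_R = np.diag(R)
    for a in range(b_k):
        block = -2.0 * lam * np.outer(s1[a], s1[a]) * R
        diag = (
            2.0 * (s1[a] ** 2 + (S[a] - A[a]) * s2[a])
            + 2.0 * eta
            - 2.0 * lam * (SR[a] * s2[a] + diag_R * s1[a] ** 2)
        )
        np.fill_diagonal(block, diag)
        hess[a * n : (a + 1) * n, a * n : (a + 1) * n] = block
    return grad, hess


# ---------------------------------------------------------------------------
# damped Newton block updates

def _ridge_for(H: np.ndarray, cfg: HashConfig) -> float:
    scale = np.trace(H) / H.shape[0] if H.shape[0] else 0.0
    return cfg.hessian_ridge * scale if scale > 0 else cfg.hessian_ridge


def newton_step_W(
    W: np.ndarray, G2: np.ndarray, C: np.ndarray, cfg: HashConfig, block_id: str = "W"
) -> np.ndarray:
    """One damped Newton step on W given aggregated statistics.

    The W-dependent part of the objective is the exact quadratic
    ``phi(W) = tr(W^T G2 W) - 2 tr(W^T C)``, so step-halving can use it
    directly; the step is rejected outright if no halving decreases phi.
    """
    H = 2.0 * G2
    grad = 2.0 * (G2 @ W - C)
    Hr = H + _ridge_for(H, cfg) * np.eye(H.shape[0])
    try:
        direction = np.linalg.solve(Hr, grad)
    except np.linalg.LinAlgError as exc:
        raise NumericError(f"singular Hessian in block {block_id}") from exc

    def phi(M: np.ndarray) -> float:
        return float(np.sum(M * (G2 @ M)) - 2.0 * np.sum(M * C))

    f0 = phi(W)
    step = 1.0
    for _ in range(MAX_HALVINGS):
        cand = W - step * direction
        if phi(cand) <= f0:
            return cand
        step *= 0.5
    return W.copy()


def _relationship_components(R: np.ndarray) -> list[np.ndarray]:
    """Column groups that the relationship graph actually couples.

    Given W, the Q subproblem separates over connected components of the
    nonzero pattern of R (patients in different components never interact),
    so Newton damping can — and for site-decomposability must — be applied
    per component.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    ncomp, labels = connected_components(csr_matrix(R != 0), directed=False)
    if ncomp == 1:
        return [np.arange(R.shape[0])]
    return [np.flatnonzero(labels == c) for c in range(ncomp)]


def _newton_q_component(
    Q: np.ndarray, A: np.ndarray, R: np.ndarray, cfg: HashConfig, block_id: str
) -> np.ndarray:
    """Damped Newton step on one coupled column group of a Q block."""
    b_k, n = Q.shape
    S = surrogate_sign(Q, cfg.xi)
    s1 = _surrogate_d1(Q, cfg.xi)
    s2 = _surrogate_d2(Q, cfg.xi)
    SR = S @ R
    lam, eta = cfg.lambda_sup, cfg.eta
    grad = 2.0 * (S - A) * s1 - 2.0 * lam * SR * s1 + 2.0 * eta * Q

    direction = np.empty_like(Q)
    for a in range(b_k):
        block = -2.0 * lam * np.outer(s1[a], s1[a]) * R
        diag = 2.0 * (s1[a] ** 2 + (S[a] - A[a]) * s2[a]) + 2.0 * eta - 2.0 * lam * SR[a] * s2[a]
        np.fill_diagonal(block, diag)
        block = block + _ridge_for(block, cfg) * np.eye(n)
        try:
            direction[a] = np.linalg.solve(block, grad[a])
        except np.linalg.LinAlgError as exc:
            raise NumericError(f"singular Hessian in block {block_id}, bit={a}") from exc

    def psi(Qc: np.ndarray) -> float:
        S_c = surrogate_sign(Qc, cfg.xi)
        resid = A - S_c
        return (
            float(np.sum(resid * resid))
            - lam * float(np.sum((S_c @ R) * S_c))
            + eta * float(np.sum(Qc * Qc))
        )

    f0 = psi(Q)
    step = 1.0
    for _ in range(MAX_HALVINGS):
        cand = Q - step * direction
        if psi(cand) <= f0:
            return cand
        step *= 0.5
    return Q.copy()


def newton_step_Q(
    model: HashModel, aux: SiteAux, site: SiteDataset, tag: str, cfg: HashConfig
) -> np.ndarray:
    """One damped Newton step on Q_k^i, solved per bit (N_i x N_i blocks).

    Step-halving uses the local objective contribution of each coupled
    column group, which is the only part of the global objective that
    depends on it.
    """
    W, Q, P, R = model.W[tag], aux.Q[tag], site.P[tag], site.R
    if Q.shape[1] == 0:
        return Q.copy()
    A = W.T @ P
    Qnew = Q.copy()
    for idx in _relationship_components(R):
        block_id = f"Q[site={site.site_index}, domain={tag!r}]"
        Qnew[:, idx] = _newton_q_component(
            Q[:, idx], A[:, idx], R[np.ix_(idx, idx)], cfg, block_id
        )
    return Qnew


# ---------------------------------------------------------------------------
# initialization and the full fit

def init_model(spec: FeatureDomainSpec, cfg: HashConfig) -> HashModel:
    """Seeded small-Gaussian initialization of every W_k (sigma = 0.1)."""
    rng = np.random.default_rng(cfg.seed)
    bits = cfg.bits_for(spec)
    W = {}
    for (tag, vocab), b_k in zip(spec.domains, bits):
        W[tag] = 0.1 * rng.standard_normal((len(vocab), b_k))
    return HashModel(spec, W)


def init_aux(model: HashModel, site: SiteDataset) -> SiteAux:
    """Q_k^i starts at the model's own projection W_k^T P_k^i."""
    return SiteAux(site.site_index, {tag: model.W[tag].T @ site.P[tag] for tag in model.spec.tags})


def aggregate_w_stats(stats: Sequence[tuple]) -> tuple:
    """Sum per-site (G2, C, snorm) statistics in site order."""
    G2 = sum(s[0] for s in stats)
    C = sum(s[1] for s in stats)
    snorm = sum(s[2] for s in stats)
    return G2, C, snorm


def fit_hash_model(
    sites: Sequence[SiteDataset], cfg: HashConfig
) -> tuple[HashModel, list[SiteAux], list[float]]:
    """Block coordinate descent over W_1..W_K and every Q_k^i.

    Each outer iteration updates every W_k from aggregated per-site
    statistics, then every Q_k^i locally; stops when the relative change
    of the objective falls below ``rel_tol`` or after ``max_iter``
    iterations. The returned trace (one value per completed iteration,
    starting at the initial objective) is non-increasing.
    """
    if not sites:
        raise ConfigurationError("need at least one site")
    import logging

    log = logging.getLogger(__name__)
    for s in sites:
        if s.n_patients < 2 or len(np.unique(s.labels)) < 2:
            log.warning("site %d has <2 patients or a single class", s.site_index)
    spec = sites[0].spec
    model = init_model(spec, cfg)
    aux = [init_aux(model, s) for s in sites]
    trace = [objective_value(model, aux, sites, cfg)]
    if math.isinf(cfg.rel_tol):
        return model, aux, trace
    for _ in range(cfg.max_iter):
        for tag in spec.tags:
            stats = [w_statistics(s, a, tag, cfg) for s, a in zip(sites, aux)]
            G2, C, _ = aggregate_w_stats(stats)
            model.W[tag] = newton_step_W(model.W[tag], G2, C, cfg, block_id=f"W[{tag}]")
        for s, a in zip(sites, aux):
            for tag in spec.tags:
                a.Q[tag] = newton_step_Q(model, a, s, tag, cfg)
        f = objective_value(model, aux, sites, cfg)
        prev = trace[-1]
        trace.append(f)
        if abs(prev - f) <= cfg.rel_tol * max(abs(prev), 1e-12):
            break
    return model, aux, trace


def encode(model: HashModel, P: dict[str, np.ndarray], patient_ids: list[str] | None = None) -> HashCodes:
    """Hash a site's feature matrices: H_k = sign(W_k^T P_k), sign(0) = +1."""
    codes = {}
    n = None
    for tag in model.spec.tags:
        W = model.W[tag]
        mat = P[tag]
        if mat.shape[0] != W.shape[0]:
            raise DimensionError(
                f"domain {tag!r}: features have d={mat.shape[0]}, model expects {W.shape[0]}"
            )
        if n is None:
            n = mat.shape[1]
        elif mat.shape[1] != n:
            raise DimensionError(f"domain {tag!r}: inconsistent patient count")
        proj = W.T @ mat
        codes[tag] = np.where(proj >= 0, 1, -1).astype(int)
    return HashCodes(codes, patient_ids or [])


def encode_site(model: HashModel, site: SiteDataset) -> HashCodes:
    return encode(model, site.P, list(site.patient_ids))
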