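"""Federated orchestration of the hashing fit behind a strict message boundary.

M data custodians each hold one SiteDataset. A coordinator broadcasts the
current hash-function coefficients; for each W_k update, every site returns
a DerivativeBundle containing only d_k x b_k / d_k x d_k aggregates and
scalars — never a matrix with a patient axis. The relaxation variables
Q_k^i (and the resulting codes) are updated locally and never leave their
site. Because every exchanged statistic is an exact sum over sites, the
federated model sequence is identical to a centralized fit on the same
partition; that equivalence is this module's correctness anchor.

Transport is an in-process call-and-log queue; every message is recorded in
an audit log whose payload shapes can be checked after the fact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from fedsimhash.errors import ConfigurationError, ProtocolError
from fedsimhash.features import SiteDataset
from fedsimhash.hashcore import (
    HashCodes,
    HashConfig,
    HashModel,
    SiteAux,
    aggregate_w_stats,
    encode_site,
    init_aux,
    init_model,
    newton_step_Q,
    newton_step_W,
    site_objective,
    w_statistics,
)


@dataclass(frozen=True)
class FederationConfig:
    """Federation shape: M sites, synchronous rounds, in-process transport."""

    M: int = 3
    schedule: str = "synchronous"
    rounds_cap: int = 1000
    transport: str = "queue"

    def __post_init__(self):
        if self.M < 1:
            raise ConfigurationError("M must be >= 1")
        if self.schedule not in ("synchronous", "asynchronous"):
            raise ConfigurationError(f"unknown schedule {self.schedule!r}")
        if self.schedule == "asynchronous":
            raise NotImplementedError(
                "asynchronous updates are an interface stub; only the "
                "synchronous schedule is supported"
            )


@dataclass
class DerivativeBundle:
    """A site's aggregate statistics for one W_k Newton step.

    ``gradient`` is the site's d_k x b_k contribution 2 (G2 W - C);
    ``hessian`` the shared per-column d_k x d_k block 2 G2; ``cross`` the
    d_k x b_k statistic C = P S_L(Q)^T (needed for exact step-halving);
    ``snorm`` the scalar ||S_L(Q)||_F^2. No patient-level payloads.
    """

    site: int
    k: str
    gradient: np.ndarray
    hessian: np.ndarray
    cross: np.ndarray
    n_patients: int
    snorm: float
    model_version: int


def validate_bundle(bundle: DerivativeBundle, d_k: int, b_k: int, n_patients_forbidden: int) -> None:
    """Schema guard: only (d_k, b_k) and (d_k, d_k) arrays plus scalars.

    Rejects any array payload carrying a patient axis.
    """
    allowed = {(d_k, b_k), (d_k, d_k)}
    for name in ("gradient", "hessian", "cross"):
        arr = getattr(bundle, name)
        if not isinstance(arr, np.ndarray) or arr.shape not in allowed:
            raise ProtocolError(
                f"bundle field {name!r} has disallowed shape "
                f"{getattr(arr, 'shape', None)}; only {sorted(allowed)} permitted"
            )
        if n_patients_forbidden > 0 and n_patients_forbidden in arr.shape and arr.shape not in allowed:
            raise ProtocolError(f"bundle field {name!r} carries a patient axis")
    if not np.isscalar(bundle.snorm) and not isinstance(bundle.snorm, float):
        raise ProtocolError("snorm must be a scalar")


class SiteNode:
    """A data custodian: answers statistic requests, keeps Q and codes local."""

    def __init__(self, site: SiteDataset, cfg: HashConfig):
        self.site = site
        self.cfg = cfg
        self.model: HashModel | None = None
        self.aux: SiteAux | None = None
        self.model_version = -1

    def receive_model(self, model: HashModel, version: int) -> None:
        self.model = model.copy()
        self.model_version = version
        if self.aux is None:
            self.aux = init_aux(self.model, self.site)

    def w_bundle(self, tag: str, version: int) -> DerivativeBundle:
        if version != self.model_version:
            raise ProtocolError(
                f"site {self.site.site_index}: stale model version "
                f"{self.model_version}, coordinator at {version}"
            )
        G2, C, snorm = w_statistics(self.site, self.aux, tag, self.cfg)
        W = self.model.W[tag]
        return DerivativeBundle(
            site=self.site.site_index,
            k=tag,
            gradient=2.0 * (G2 @ W - C),
            hessian=2.0 * G2,
            cross=C,
            n_patients=self.site.n_patients,
            snorm=snorm,
            model_version=version,
        )

    def update_W(self, tag: str, W_new: np.ndarray, version: int) -> None:
        self.model.W[tag] = W_new.copy()
        self.model_version = version

    def update_local_Q(self) -> None:
        for tag in self.model.spec.tags:
            self.aux.Q[tag] = newton_step_Q(self.model, self.aux, self.site, tag, self.cfg)

    def local_objective(self) -> float:
        return site_objective(self.model, self.aux, self.site, self.cfg)

    def local_codes(self) -> HashCodes:
        """Codes for this site's own patients; computed and kept locally."""
        return encode_site(self.model, self.site)


def local_W_statistics(
    site: SiteDataset, model: HashModel, aux: SiteAux, tag: str, cfg: HashConfig, version: int = 0
) -> DerivativeBundle:
    """One site's derivative bundle for W_k (functional form of SiteNode.w_bundle)."""
    node = SiteNode(site, cfg)
    node.model = model.copy()
    node.aux = aux
    node.model_version = version
    return node.w_bundle(tag, version)


def aggregate_and_update_W(
    bundles: Sequence[DerivativeBundle], model: HashModel, tag: str, cfg: HashConfig
) -> np.ndarray:
    """Sum site bundles and take the damped Newton step on W_k.

    Hessians are summed before inversion (the pooled Newton step); the
    sufficient statistics (G2, C) come straight from the bundles, so the
    step is bit-identical to the centralized one.
    """
    if not bundles:
        raise ProtocolError("no bundles to aggregate")
    versions = {b.model_version for b in bundles}
    ks = {b.k for b in bundles}
    if len(versions) != 1 or len(ks) != 1 or ks != {tag}:
        raise ProtocolError("bundles disagree on domain or model version")
    W = model.W[tag]
    stats = [(b.hessian / 2.0, b.cross, b.snorm) for b in bundles]
    G2, C, _ = aggregate_w_stats(stats)
    return newton_step_W(W, G2, C, cfg, block_id=f"W[{tag}]")


def federated_fit(
    sites: Sequence[SiteDataset],
    cfg: HashConfig,
    fed: FederationConfig | None = None,
    message_log: list | None = None,
) -> tuple[HashModel, list[SiteNode], list[float]]:
    """Run the full block coordinate descent over the message boundary.

    Returns the broadcast model, the site nodes (whose Q and codes never
    left them), and the objective trace. If ``message_log`` is given,
    every exchanged message is appended as a dict recording its type and
    payload shapes for a privacy audit.
    """
    fed = fed or FederationConfig(M=len(sites))
    if fed.M != len(sites):
        raise ProtocolError(f"FederationConfig.M={fed.M} but {len(sites)} sites supplied")
    spec = sites[0].spec
    bits = cfg.bits_for(spec)
    dims = dict(zip(spec.tags, spec.dims))
    b_of = dict(zip(spec.tags, bits))

    def log(msg: dict) -> None:
        if message_log is not None:
            message_log.append(msg)

    nodes = [SiteNode(s, cfg) for s in sites]
    model = init_model(spec, cfg)
    version = 0
    for node in nodes:
        node.receive_model(model, version)
        log({"type": "model", "version": version, "site": node.site.site_index,
             "payload_dims": {t: list(model.W[t].shape) for t in spec.tags}})

    def global_objective() -> float:
        vals = [node.local_objective() for node in nodes]
        for node, v in zip(nodes, vals):
            log({"type": "objective", "version": version, "site": node.site.site_index,
                 "payload_dims": "scalar"})
        return sum(vals)

    trace = [global_objective()]
    if math.isinf(cfg.rel_tol):
        return model, nodes, trace

    for _ in range(min(cfg.max_iter, fed.rounds_cap)):
        for tag in spec.tags:
            bundles = []
            for node in nodes:
                b = node.w_bundle(tag, version)
                validate_bundle(b, dims[tag], b_of[tag], node.site.n_patients)
                log({"type": "bundle", "version": version, "site": b.site, "k": tag,
                     "payload_dims": {"gradient": list(b.gradient.shape),
                                      "hessian": list(b.hessian.shape)}})
                bundles.append(b)
            W_new = aggregate_and_update_W(bundles, model, tag, cfg)
            model.W[tag] = W_new
            version += 1
            for node in nodes:
                node.update_W(tag, W_new, version)
                log({"type": "model", "version": version, "site": node.site.site_index,
                     "k": tag, "payload_dims": list(W_new.shape)})
        for node in nodes:
            node.update_local_Q()
            log({"type": "ack", "version": version, "site": node.site.site_index,
                 "payload_dims": None})
        f = global_objective()
        prev = trace[-1]
        trace.append(f)
        if abs(prev - f) <= cfg.rel_tol * max(abs(prev), 1e-12):
            break
    return model, nodes, trace
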