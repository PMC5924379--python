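"""Synthetic event-sequence cohorts with a planted label signal.

Emulates the structure of a multi-site EHR study: each patient has 1-5
hospital admissions holding coded events drawn from per-domain
vocabularies (lab tests, prescriptions, diagnoses, conditions, symptoms)
plus static demographics. Positive patients receive the target diagnosis
code in exactly one admission (never the first, so every positive retains
a pre-outcome history) and draw their other events from a distribution
enriched for a designated "signal" subset of each coded vocabulary; the
log-odds enrichment is the tunable separability of the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from fedsimhash.errors import ConfigurationError, PartitionError
from fedsimhash.features import CODED_PREFIXES, EventSequence

#: fraction of each coded vocabulary designated as label-signal codes
SIGNAL_FRACTION = 0.2


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    ``signal_strength`` is the log-odds enrichment of signal codes in
    positive patients: their sampling weight is multiplied by
    ``exp(signal_strength)``, so 0 plants no signal at all.
    """

    n_patients: int
    domain_specs: tuple[tuple[str, int], ...] = (
        ("demo", 3),
        ("l", 30),
        ("p", 30),
        ("d", 30),
        ("c", 20),
        ("s", 20),
    )
    positive_fraction: float = 0.5
    signal_strength: float = 2.0
    events_per_patient: tuple[int, int] = (80, 120)
    target_code: str = "d_TARGET"
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ConfigurationError(
                f"positive_fraction must lie in [0, 1], got {self.positive_fraction}"
            )
        if self.signal_strength < 0:
            raise ConfigurationError("signal_strength must be >= 0")
        tags = [t for t, _ in self.domain_specs]
        if len(tags) != len(set(tags)):
            raise ConfigurationError("domain tags must be unique")
        coded = [t for t in tags if t != "demo"]
        if not coded:
            raise ConfigurationError("at least one coded domain is required")
        for tag, size in self.domain_specs:
            if size < 1:
                raise ConfigurationError(f"vocab_size for {tag!r} must be >= 1")
            if tag != "demo" and tag not in CODED_PREFIXES:
                raise ConfigurationError(f"unknown domain tag {tag!r}")
        lo, hi = self.events_per_patient
        if lo < 1 or hi < lo:
            raise ConfigurationError("events_per_patient must be a positive range")


def _vocab(tag: str, size: int) -> list[str]:
    return [f"{tag}_{i:04d}" for i in range(size)]


def signal_codes(config: CohortConfig) -> dict[str, list[str]]:
    """The designated signal subset of each coded vocabulary (first 20%)."""
    out = {}
    for tag, size in config.domain_specs:
        if tag == "demo":
            continue
        n_sig = max(1, int(np.ceil(SIGNAL_FRACTION * size)))
        out[tag] = _vocab(tag, size)[:n_sig]
    return out


def generate_cohort(config: CohortConfig) -> list[EventSequence]:
    """Generate a cohort of event sequences with the planted signal.

    Deterministic given ``config.seed``: identical configs give
    byte-identical serialized cohorts.
    """
    rng = np.random.default_rng(config.seed)
    n_pos = int(round(config.n_patients * config.positive_fraction))
    labels = np.array([1] * n_pos + [0] * (config.n_patients - n_pos))
    rng.shuffle(labels)

    coded = [(t, s) for t, s in config.domain_specs if t != "demo"]
    vocabs = {t: _vocab(t, s) for t, s in coded}
    n_sig = {t: max(1, int(np.ceil(SIGNAL_FRACTION * s))) for t, s in coded}

    # per-domain sampling weights: uniform for negatives, signal codes
    # up-weighted by exp(signal_strength) for positives
    weights = {}
    for t, s in coded:
        w_neg = np.ones(s)
        w_pos = np.ones(s)
        w_pos[: n_sig[t]] *= np.exp(config.signal_strength)
        weights[t] = (w_neg / w_neg.sum(), w_pos / w_pos.sum())

    tags = [t for t, _ in coded]
    cohort: list[EventSequence] = []
    for j in range(config.n_patients):
        label = int(labels[j])
        # positives need >= 2 admissions so the target never lands first
        n_adm = int(rng.integers(2 if label else 1, 6))
        n_events = int(rng.integers(config.events_per_patient[0], config.events_per_patient[1] + 1))
        ev_tags = rng.choice(tags, size=n_events)
        events = [""] * n_events
        for t in tags:
            pos = np.flatnonzero(ev_tags == t)
            if pos.size == 0:
                continue
            w = weights[t][label]
            draws = rng.choice(len(w), size=pos.size, p=w)
            for where, code_idx in zip(pos, draws):
                events[where] = vocabs[t][int(code_idx)]
        # deal events into admissions, keeping temporal order
        bounds = np.sort(rng.integers(0, n_events + 1, size=n_adm - 1))
        admissions = [
            list(events[a:b])
            for a, b in zip(np.r_[0, bounds], np.r_[bounds, n_events])
        ]
        if label:
            target_adm = int(rng.integers(1, n_adm))
            admissions[target_adm].append(config.target_code)
        cohort.append(
            EventSequence(
                pid=f"pt{j:05d}",
                admissions=tuple(tuple(a) for a in admissions),
                gender="M" if rng.random() < 0.5 else "F",
                age=float(np.round(rng.uniform(20, 90), 1)),
                label=label,
            )
        )
    return cohort


@dataclass(frozen=True)
class SitePartitionPlan:
    """How to split a cohort across M sites.

    ``per_site_positive_fraction`` is either the string ``"inherit"`` (use
    the cohort's own positive rate at every site) or a list of per-site
    fractions; per-site positive counts are rounded down, with the
    remainder filled by negatives.
    """

    M: int
    per_site_sizes: tuple[int, ...]
    per_site_positive_fraction: object = "inherit"

    def __post_init__(self):
        if self.M < 1 or len(self.per_site_sizes) != self.M:
            raise ConfigurationError("per_site_sizes must have length M >= 1")
        if self.per_site_positive_fraction != "inherit":
            fracs = tuple(self.per_site_positive_fraction)
            if len(fracs) != self.M:
                raise ConfigurationError("need one positive fraction per site")
            if any(not (0.0 <= f <= 1.0) for f in fracs):
                raise ConfigurationError("per-site positive fractions must lie in [0, 1]")


def partition_sites(
    cohort: Sequence[EventSequence], plan: SitePartitionPlan, seed: int
) -> list[list[EventSequence]]:
    """Disjointly assign patients to sites with exact per-site class counts.

    Raises PartitionError naming the first site whose requested positive or
    negative count cannot be met.
    """
    if sum(plan.per_site_sizes) > len(cohort):
        raise PartitionError(
            f"plan requests {sum(plan.per_site_sizes)} patients but cohort has {len(cohort)}"
        )
    rng = np.random.default_rng(seed)
    pos = [s for s in cohort if s.label == 1]
    neg = [s for s in cohort if s.label == 0]
    rng.shuffle(pos)
    rng.shuffle(neg)
    global_rate = len(pos) / len(cohort) if cohort else 0.0
    if plan.per_site_positive_fraction == "inherit":
        fracs = [global_rate] * plan.M
    else:
        fracs = list(plan.per_site_positive_fraction)

    sites: list[list[EventSequence]] = []
    ip = im = 0
    for i, (size, frac) in enumerate(zip(plan.per_site_sizes, fracs)):
        n_pos = int(np.floor(size * frac))
        if ip + n_pos > len(pos):
            raise PartitionError(
                f"site {i}: needs {n_pos} positives but only {len(pos) - ip} remain"
            )
        n_neg = size - n_pos
        avail_neg = len(neg) - im
        if n_neg > avail_neg:
            # floor rounding can exhaust negatives at the tail even when the
            # plan is feasible in total; cover the deficit with positives
            deficit = n_neg - avail_neg
            if ip + n_pos + deficit > len(pos):
                raise PartitionError(
                    f"site {i}: needs {n_neg} negatives but only {avail_neg} remain"
                )
            logging.getLogger(__name__).warning(
                "site %d: negative shortfall of %d filled with positives", i, deficit
            )
            n_pos += deficit
            n_neg = avail_neg
        chunk = pos[ip : ip + n_pos] + neg[im : im + n_neg]
        ip += n_pos
        im += n_neg
        order = rng.permutation(len(chunk))
        sites.append([chunk[int(o)] for o in order])
    return sites
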