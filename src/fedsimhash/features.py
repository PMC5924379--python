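"""Per-domain feature construction from coded event sequences.

Each patient is an ordered sequence of hospital admissions holding coded
events (lab tests ``l_``, prescriptions ``p_``, diagnoses ``d_``,
conditions ``c_``, symptoms ``s_``) plus static demographics. A patient's
domain-k feature vector is the sum of one-hot event indicators weighted by
the exponential decay ``exp(-gamma * t)``, where ``t`` counts event steps
backward from the most recent retained event (events are taken as equally
spaced). Recent events therefore carry more weight than old ones;
demographics are copied without decay.

For supervised hashing, patients whose history contains the target
diagnosis are truncated to the admissions strictly before the first
admission containing it, so the features never encode the outcome itself.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from fedsimhash.errors import AssemblyError, ConfigurationError, FormatError

logger = logging.getLogger(__name__)

#: canonical feature-domain order: demographics first, then coded domains
DOMAIN_ORDER = ("demo", "l", "p", "d", "c", "s")

#: coded-event prefixes mapped to their domain tag
CODED_PREFIXES = {"l": "l_", "p": "p_", "d": "d_", "c": "c_", "s": "s_"}

#: fixed demographics vocabulary: gender one-hot plus raw age
DEMO_VOCAB = ("gender_M", "gender_F", "age")


@dataclass(frozen=True)
class EventSequence:
    """One patient: ordered admissions of coded events, demographics, label."""

    pid: str
    admissions: tuple[tuple[str, ...], ...]
    gender: str
    age: float
    label: int

    def coded_events(self) -> list[str]:
        """All coded events flattened in temporal order."""
        return [code for adm in self.admissions for code in adm]

    def to_json(self) -> str:
        return json.dumps(
            {
                "pid": self.pid,
                "label": self.label,
                "admissions": [list(adm) for adm in self.admissions],
                "demographics": {"gender": self.gender, "age": self.age},
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "EventSequence":
        obj = json.loads(line)
        demo = obj.get("demographics", {})
        return cls(
            pid=str(obj["pid"]),
            admissions=tuple(tuple(adm) for adm in obj["admissions"]),
            gender=str(demo.get("gender", "M")),
            age=float(demo.get("age", 0.0)),
            label=int(obj["label"]),
        )


def write_jsonl(cohort: Iterable[EventSequence], path) -> None:
    with open(path, "w") as fh:
        for seq in cohort:
            fh.write(seq.to_json() + "\n")


def read_jsonl(path) -> list[EventSequence]:
    with open(path) as fh:
        return [EventSequence.from_json(line) for line in fh if line.strip()]


def domain_of_code(code: str) -> str:
    """Domain tag of a coded event, from its prefix."""
    head = code.split("_", 1)[0]
    if head not in CODED_PREFIXES:
        raise FormatError(f"unknown domain prefix on code {code!r}")
    return head


@dataclass(frozen=True)
class FeatureDomainSpec:
    """Ordered feature domains with canonical (sorted) code vocabularies."""

    domains: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self):
        tags = [t for t, _ in self.domains]
        if len(tags) != len(set(tags)):
            raise ConfigurationError("duplicate domain tags in spec")
        if not tags:
            raise ConfigurationError("spec needs at least one domain")

    @property
    def K(self) -> int:
        return len(self.domains)

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.domains)

    @property
    def dims(self) -> tuple[int, ...]:
        """Per-domain dimensionalities d_k."""
        return tuple(len(v) for _, v in self.domains)

    def vocabulary(self, tag: str) -> tuple[str, ...]:
        for t, v in self.domains:
            if t == tag:
                return v
        raise KeyError(tag)

    def to_json(self) -> str:
        return json.dumps({t: list(v) for t, v in self.domains})

    @classmethod
    def from_json(cls, text: str) -> "FeatureDomainSpec":
        obj = json.loads(text)
        return cls(tuple((t, tuple(v)) for t, v in obj.items()))


def build_domain_vocabulary(cohort: Sequence[EventSequence]) -> FeatureDomainSpec:
    """Scan a cohort and build sorted per-domain code vocabularies.

    The demographics domain is fixed at ``(gender_M, gender_F, age)``; coded
    domains get the lexicographically sorted set of observed codes, which
    fixes a canonical column order for the hash-function coefficients.
    """
    if not cohort:
        raise ConfigurationError("cannot build vocabularies from an empty cohort")
    seen: dict[str, set[str]] = {}
    for seq in cohort:
        for code in seq.coded_events():
            seen.setdefault(domain_of_code(code), set()).add(code)
    domains: list[tuple[str, tuple[str, ...]]] = [("demo", DEMO_VOCAB)]
    for tag in DOMAIN_ORDER[1:]:
        if tag in seen:
            domains.append((tag, tuple(sorted(seen[tag]))))
    return FeatureDomainSpec(tuple(domains))


@dataclass(frozen=True)
class SliceResult:
    """Outcome of truncating a sequence at the first target-disease admission."""

    sequence: EventSequence
    label: int
    no_history: bool = False


def slice_at_first_target(seq: EventSequence, target_code: str) -> SliceResult:
    """Truncate a patient's history at the first target-disease admission.

    If the target code occurs, only admissions strictly before its first
    occurrence are kept and the label is 1; the retained feature stream
    therefore never contains the outcome. If the first admission already
    holds the target, the patient has no usable history and is flagged so
    the caller can exclude them. Patients without the target keep all
    admissions and get label 0.
    """
    for idx, adm in enumerate(seq.admissions):
        if target_code in adm:
            kept = seq.admissions[:idx]
            sliced = EventSequence(seq.pid, kept, seq.gender, seq.age, label=1)
            return SliceResult(sliced, label=1, no_history=(idx == 0))
    return SliceResult(
        EventSequence(seq.pid, seq.admissions, seq.gender, seq.age, label=0),
        label=0,
        no_history=False,
    )


def vectorize_patient(
    seq: EventSequence, spec: FeatureDomainSpec, gamma: float = 0.01
) -> dict[str, np.ndarray]:
    """Time-decayed one-hot feature vectors, one per domain.

    Coded events are flattened across admissions in temporal order; the
    event at step ``t`` back from the sequence end contributes
    ``exp(-gamma*t)`` to its code's entry (the most recent event has weight
    1). Demographics are encoded without decay. Codes absent from the
    vocabulary are dropped with a warning so a frozen spec can be applied
    to new cohorts.
    """
    if gamma < 0:
        raise ConfigurationError(f"decay constant gamma must be >= 0, got {gamma}")
    index = {
        tag: {code: i for i, code in enumerate(vocab)}
        for tag, vocab in spec.domains
        if tag != "demo"
    }
    out = {tag: np.zeros(len(vocab)) for tag, vocab in spec.domains}
    events = seq.coded_events()
    n = len(events)
    for pos, code in enumerate(events):
        tag = domain_of_code(code)
        if tag not in index:
            logger.warning("code %s from unknown domain %s dropped", code, tag)
            continue
        col = index[tag].get(code)
        if col is None:
            logger.warning("code %s not in vocabulary; dropped", code)
            continue
        t = n - 1 - pos  # steps back from the most recent event
        out[tag][col] += np.exp(-gamma * t)
    if "demo" in out:
        vec = out["demo"]
        vocab = spec.vocabulary("demo")
        lut = {c: i for i, c in enumerate(vocab)}
        gender_key = f"gender_{seq.gender}"
        if gender_key in lut:
            vec[lut[gender_key]] = 1.0
        if "age" in lut:
            vec[lut["age"]] = seq.age
    return out


def relationship_matrix(labels: np.ndarray) -> np.ndarray:
    """Pairwise label-agreement matrix: +1 same class, -1 different, 0 on the diagonal."""
    labels = np.asarray(labels)
    R = np.where(labels[:, None] == labels[None, :], 1.0, -1.0)
    np.fill_diagonal(R, 0.0)
    return R


@dataclass
class SiteDataset:
    """One site's per-domain feature matrices, labels, and relationships.

    ``P[tag]`` has shape (d_k, N_i) with patients as columns in a fixed
    order shared across domains; ``R`` is the symmetric +-1 label-agreement
    matrix with a zero diagonal (self-pairs are excluded from the
    supervised loss).
    """

    site_index: int
    spec: FeatureDomainSpec
    P: dict[str, np.ndarray]
    labels: np.ndarray
    patient_ids: list[str] = field(default_factory=list)
    R: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.labels.shape[0]
        for tag, mat in self.P.items():
            d_k = len(self.spec.vocabulary(tag))
            if mat.shape != (d_k, n):
                raise AssemblyError(
                    f"site {self.site_index} domain {tag!r}: matrix shape "
                    f"{mat.shape} != ({d_k}, {n})"
                )
        if self.R is None:
            self.R = relationship_matrix(self.labels)
        if not self.patient_ids:
            self.patient_ids = [f"s{self.site_index}_p{j}" for j in range(n)]

    @property
    def n_patients(self) -> int:
        return int(self.labels.shape[0])

    def subset(self, cols: np.ndarray) -> "SiteDataset":
        """A new SiteDataset restricted to the given patient columns."""
        cols = np.asarray(cols)
        return SiteDataset(
            site_index=self.site_index,
            spec=self.spec,
            P={t: m[:, cols] for t, m in self.P.items()},
            labels=self.labels[cols],
            patient_ids=[self.patient_ids[int(c)] for c in cols],
        )


def assemble_site(
    cohort: Sequence[EventSequence],
    spec: FeatureDomainSpec,
    gamma: float,
    target_code: str,
    site_index: int = 0,
) -> SiteDataset:
    """Slice, vectorize, and stack a cohort into a SiteDataset.

    Patients whose first admission already contains the target code carry
    no usable history and are dropped (with a logged count).
    """
    cols: dict[str, list[np.ndarray]] = {tag: [] for tag, _ in spec.domains}
    labels: list[int] = []
    pids: list[str] = []
    dropped = 0
    for seq in cohort:
        res = slice_at_first_target(seq, target_code)
        if res.no_history:
            dropped += 1
            continue
        vecs = vectorize_patient(res.sequence, spec, gamma)
        for tag in cols:
            cols[tag].append(vecs[tag])
        labels.append(res.label)
        pids.append(seq.pid)
    if dropped:
        logger.warning(
            "site %d: dropped %d patient(s) with target disease in first admission",
            site_index,
            dropped,
        )
    if not labels:
        raise AssemblyError(f"site {site_index}: no usable patients after slicing")
    P = {tag: np.column_stack(vs) for tag, vs in cols.items()}
    return SiteDataset(site_index=site_index, spec=spec, P=P, labels=np.array(labels), patient_ids=pids)


def concatenate_sites(sites: Sequence[SiteDataset], site_index: int = 0) -> SiteDataset:
    """Pool several sites into one, keeping the supervised loss unchanged.

    Cross-site relationship entries are zero, so the pooled objective is
    identical to the sum of the per-site objectives; this is the pooled
    dataset used to check that the distributed fit matches a central one.
    """
    spec = sites[0].spec
    P = {tag: np.concatenate([s.P[tag] for s in sites], axis=1) for tag, _ in spec.domains}
    labels = np.concatenate([s.labels for s in sites])
    n = labels.shape[0]
    R = np.zeros((n, n))
    off = 0
    for s in sites:
        m = s.n_patients
        R[off : off + m, off : off + m] = s.R
        off += m
    pids = [pid for s in sites for pid in s.patient_ids]
    return SiteDataset(site_index=site_index, spec=spec, P=P, labels=labels, patient_ids=pids, R=R)


def pool_sites(sites: Sequence[SiteDataset], site_index: int = 0) -> SiteDataset:
    """Pool sites as a genuinely open system: relationships span all pairs."""
    pooled = concatenate_sites(sites, site_index=site_index)
    pooled.R = relationship_matrix(pooled.labels)
    return pooled


def as_uni_domain(site: SiteDataset, tag: str = "uni") -> SiteDataset:
    """Collapse all feature domains into one stacked matrix (uni-hash view)."""
    stacked = np.concatenate([site.P[t] for t, _ in site.spec.domains], axis=0)
    vocab = tuple(
        f"{t}:{code}" for t, v in site.spec.domains for code in v
    )
    spec = FeatureDomainSpec(((tag, vocab),))
    return SiteDataset(
        site_index=site.site_index,
        spec=spec,
        P={tag: stacked},
        labels=site.labels.copy(),
        patient_ids=list(site.patient_ids),
        R=site.R.copy(),
    )
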