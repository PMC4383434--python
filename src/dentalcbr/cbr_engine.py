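"""The case-based reasoning cycle: retrieve, reuse, revise, retain.

The knowledge base organizes the case memory with an EM mixture over the
problem descriptors; a Bayesian-network classifier trained on the hard EM
labels assigns each new probe to a cluster.  Retrieval returns the m most
similar cases inside that cluster (per-attribute match score: equality for
categoricals, 1 - |d|/range for continuous attributes, equal weights).
Reuse adapts the retrieved knowledge through the cluster's mixture of
experts, which is trained lazily on first use and cached.  Revision clamps
the raw estimate into the cluster's per-type confidence limits
(mean +/- z sd of same-type longevities, z = 2 by default), and retention
appends the solved case, invalidates the affected caches and periodically
retrains the clustering.

Two longevity estimates are reported side by side for each candidate
material: the mean longevity of the retrieved same-type cases (the
headline estimate by default) and the revised mixture output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import em_clustering as em
from .bayes_net import BayesNet, DiscreteData, bn_posterior, fit_cpts, learn_structure
from .case_model import (
    RESTORATION_TYPES,
    Case,
    CaseBase,
    CaseEncoder,
    EncodedFrame,
    validate_case,
    _case_to_row,
    _row_to_case,
)
from .mixture import MixtureConfig, MixtureModel, mixture_predict, train_mixture

MODEL_SCHEMA_VERSION = 1


class DuplicateCaseError(ValueError):
    pass


class ModelVersionError(ValueError):
    pass


@dataclass
class EngineConfig:
    """All tunable knobs of the reasoning cycle, with study-scale defaults."""

    m: int = 20                      # retrieved cases per probe
    z: float = 2.0                   # confidence-limit half-width in sd units
    headline: str = "average"        # "average" or "mixture"
    refresh_threshold: int = 50      # retains before EM/classifier retrain
    k_fixed: int | None = None       # bypass cluster-count selection
    k_max: int = 6
    cv_folds: int = 10
    cv_threshold: float = 1e-6
    select_restarts: int = 3
    em_restarts: int = 5
    em_tol: float = 1e-6
    em_max_iter: int = 200
    em_alpha: float = 1.0
    var_floor: float = 1e-6
    classifier_alpha: float = 0.05
    classifier_max_cond: int = 1
    classifier_laplace: float = 1.0
    mixture: MixtureConfig = field(default_factory=MixtureConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EngineConfig":
        d = dict(d)
        if "mixture" in d and isinstance(d["mixture"], dict):
            d["mixture"] = MixtureConfig(**d["mixture"])
        return cls(**d)


@dataclass
class Prediction:
    """Outcome of one pass through the reasoning cycle."""

    recommended_type: str
    longevity_by_type: dict[str, float]          # the configured headline estimate
    average_by_type: dict[str, float]            # mean of retrieved same-type cases
    mixture_by_type: dict[str, float] | None     # revised mixture output (if computed)
    confidence_interval: dict[str, tuple[float, float]]
    retrieved_ids: list[tuple]
    retrieved_indices: list[int]
    cluster_id: int
    flags: dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "recommended_type": self.recommended_type,
            "longevity_by_type": self.longevity_by_type,
            "average_by_type": self.average_by_type,
            "mixture_by_type": self.mixture_by_type,
            "confidence_interval": {
                t: list(ci) for t, ci in self.confidence_interval.items()
            },
            "retrieved_ids": [[k[0], k[1], k[2].isoformat()] for k in self.retrieved_ids],
            "cluster_id": int(self.cluster_id),
            "flags": self.flags,
        }


@dataclass
class KnowledgeBase:
    cb: CaseBase
    config: EngineConfig
    seed: int
    encoder: CaseEncoder
    em_model: em.EMModel
    labels: np.ndarray                       # hard cluster label per case
    classifier: BayesNet
    em_frame: EncodedFrame                   # descriptor encoding of every case
    cv_table: object = None
    mixtures: dict[int, MixtureModel] = field(default_factory=dict)
    limits: dict = field(default_factory=dict)        # (cluster, type) -> (mean, sd)
    global_limits: dict = field(default_factory=dict)  # type -> (mean, sd)
    mixture_train_count: dict[int, int] = field(default_factory=dict)
    em_build_count: int = 1
    retains_since_build: int = 0

    @property
    def n_clusters(self) -> int:
        return self.em_model.n_clusters


# ---------------------------------------------------------------------------
# Building
# ---------------------------------------------------------------------------

def _fan_seed(seed: int, *tags: int) -> int:
    return int(np.random.default_rng(np.random.SeedSequence([seed, *tags])).integers(0, 2**31 - 1))


def _classifier_data(kb_or_frame, encoder: CaseEncoder, cases, labels: np.ndarray, K: int) -> DiscreteData:
    frame = encoder.encode_frame(cases, target="bn")
    dd = DiscreteData.from_frame(frame)
    # cluster label goes first so it is the first candidate separating set
    codes = np.hstack([labels.reshape(-1, 1).astype(np.int64), dd.codes])
    return DiscreteData(codes, ["cluster"] + dd.names, [K] + dd.levels)


def _compute_limits(kb: "KnowledgeBase") -> None:
    lons = kb.cb.longevities()
    types = kb.cb.types()
    kb.limits = {}
    for t in RESTORATION_TYPES:
        mask = types == t
        if mask.any():
            kb.global_limits[t] = (float(lons[mask].mean()), float(lons[mask].std()))
    for k in range(kb.n_clusters):
        for t in RESTORATION_TYPES:
            mask = (kb.labels == k) & (types == t)
            if mask.sum() >= 2:
                kb.limits[(k, t)] = (float(lons[mask].mean()), float(lons[mask].std()))


def build_knowledge_base(cb: CaseBase, config: EngineConfig | None = None, seed: int = 0) -> KnowledgeBase:
    """Organize the case memory: cluster, train the classifier, set limits."""
    if len(cb) == 0:
        raise ValueError("case-base is empty")
    config = config or EngineConfig()
    encoder = CaseEncoder.fit(cb)
    frame = encoder.encode_frame(cb.cases, target="em")
    cv_table = None
    if config.k_fixed is not None:
        K = config.k_fixed
    else:
        K, cv_table = em.select_k(
            frame,
            k_max=config.k_max,
            threshold=config.cv_threshold,
            folds=config.cv_folds,
            seed=_fan_seed(seed, 1),
            restarts=config.select_restarts,
            alpha=config.em_alpha,
            var_floor=config.var_floor,
        )
    model = em.em_fit(
        frame,
        K,
        tol=config.em_tol,
        max_iter=config.em_max_iter,
        seed=_fan_seed(seed, 2),
        restarts=config.em_restarts,
        alpha=config.em_alpha,
        var_floor=config.var_floor,
    )
    labels = em.hard_labels(model, frame)
    cls_data = _classifier_data(None, encoder, cb.cases, labels, K)
    classifier = learn_structure(
        cls_data, alpha=config.classifier_alpha, max_cond=config.classifier_max_cond
    )
    fit_cpts(classifier, cls_data, config.classifier_laplace)
    kb = KnowledgeBase(
        cb=cb,
        config=config,
        seed=seed,
        encoder=encoder,
        em_model=model,
        labels=labels,
        classifier=classifier,
        em_frame=frame,
        cv_table=cv_table,
    )
    _compute_limits(kb)
    return kb


# ---------------------------------------------------------------------------
# Retrieve
# ---------------------------------------------------------------------------

def classify(kb: KnowledgeBase, case: Case) -> int:
    """Cluster assignment by the Bayesian-network classifier.

    Ties are broken by the EM responsibility and then by the lower index.
    """
    frame = kb.encoder.encode_frame([case], target="bn")
    ev = {name: int(frame.cat[0, j]) for j, name in enumerate(frame.cat_names)}
    ev = {k: v for k, v in ev.items() if k in kb.classifier.levels}
    post = bn_posterior(kb.classifier, ev, "cluster")
    best = post.max()
    tied = np.where(post >= best - 1e-12)[0]
    if len(tied) == 1:
        return int(tied[0])
    resp = em.responsibilities(kb.em_model, kb.encoder.encode_frame([case], target="em"))[0]
    tied = sorted(tied, key=lambda k: (-resp[k], k))
    return int(tied[0])


def _similarity(kb: KnowledgeBase, case: Case, candidate_idx: np.ndarray) -> np.ndarray:
    probe = kb.encoder.encode_frame([case], target="em")
    cand = kb.em_frame.select(candidate_idx)
    n_cat = len(kb.em_frame.cat_names)
    n_real = len(kb.em_frame.real_names)
    score = (cand.cat == probe.cat[0][None, :]).sum(axis=1).astype(float)
    if n_real:
        ranges = kb.encoder.real_ranges
        diff = np.abs(cand.real - probe.real[0][None, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            close = np.where(
                ranges[None, :] > 0,
                np.clip(1.0 - diff / np.where(ranges == 0, 1.0, ranges)[None, :], 0.0, 1.0),
                (diff == 0).astype(float),
            )
        score += close.sum(axis=1)
    return score / (n_cat + n_real)


def retrieve(
    kb: KnowledgeBase, case: Case, m: int | None = None, exclude=None
) -> tuple[int, list[int], dict]:
    """Cluster assignment plus the indices of the m most similar cases."""
    m = m if m is not None else kb.config.m
    if m < 1:
        raise ValueError("m must be >= 1")
    exclude = set(exclude or ())
    cluster = classify(kb, case)
    flags = {"fallback_global_pool": False}
    candidates = np.array(
        [i for i in np.where(kb.labels == cluster)[0] if i not in exclude], dtype=int
    )
    if len(candidates) == 0:
        flags["fallback_global_pool"] = True
        candidates = np.array([i for i in range(len(kb.cb)) if i not in exclude], dtype=int)
        if len(candidates) == 0:
            return cluster, [], flags
    scores = _similarity(kb, case, candidates)
    order = np.lexsort((candidates, -scores))  # score desc, then stable by index
    top = candidates[order[:m]]
    return cluster, top.tolist(), flags


# ---------------------------------------------------------------------------
# Reuse / revise / retain
# ---------------------------------------------------------------------------

def reuse(kb: KnowledgeBase, cluster: int, case: Case) -> tuple[dict[str, float], dict]:
    """Raw longevity estimate per candidate material, via the cluster mixture.

    Clusters below the training floor fall back to the per-type average of
    the cluster's cases (flagged).
    """
    flags = {"average_fallback": False}
    member_idx = np.where(kb.labels == cluster)[0]
    if len(member_idx) < kb.config.mixture.min_cases:
        flags["average_fallback"] = True
        return _per_type_average(kb, member_idx), flags
    if cluster not in kb.mixtures:
        model = train_mixture(
            [kb.cb.cases[i] for i in member_idx],
            kb.encoder,
            kb.config.mixture,
            seed=_fan_seed(kb.seed, 3, cluster, kb.em_build_count),
        )
        model.cluster_id = cluster
        kb.mixtures[cluster] = model
        kb.mixture_train_count[cluster] = kb.mixture_train_count.get(cluster, 0) + 1
    model = kb.mixtures[cluster]
    return {t: mixture_predict(model, case, t) for t in RESTORATION_TYPES}, flags


def _per_type_average(kb: KnowledgeBase, idx: np.ndarray) -> dict[str, float]:
    lons = kb.cb.longevities()
    types = kb.cb.types()
    out = {}
    for t in RESTORATION_TYPES:
        mask = np.zeros(len(kb.cb), dtype=bool)
        mask[idx] = True
        mask &= types == t
        if mask.any():
            out[t] = float(lons[mask].mean())
        elif t in kb.global_limits:
            out[t] = kb.global_limits[t][0]
        else:
            out[t] = float(lons.mean()) if len(lons) else 0.0
    return out


def revise(
    kb: KnowledgeBase, cluster: int, restoration_type: str, raw: float
) -> tuple[float, tuple[float, float], dict]:
    """Clamp a raw estimate into the cluster/type confidence limits."""
    flags = {"global_limits": False}
    if (cluster, restoration_type) in kb.limits:
        mean, sd = kb.limits[(cluster, restoration_type)]
    elif restoration_type in kb.global_limits:
        mean, sd = kb.global_limits[restoration_type]
        flags["global_limits"] = True
    else:
        return raw, (raw, raw), {"global_limits": True}
    lo, hi = mean - kb.config.z * sd, mean + kb.config.z * sd
    return float(np.clip(raw, lo, hi)), (lo, hi), flags


def retain(kb: KnowledgeBase, case: Case) -> KnowledgeBase:
    """Store a solved case; invalidate caches; periodically retrain."""
    validate_case(case, kb.cb.reference_date)
    if any(c.key == case.key for c in kb.cb.cases):
        raise DuplicateCaseError(f"case key {case.key} already stored")
    cluster = classify(kb, case)
    kb.cb.cases.append(case)
    row = kb.encoder.encode_frame([case], target="em")
    kb.em_frame = EncodedFrame(
        np.vstack([kb.em_frame.cat, row.cat]),
        kb.em_frame.cat_names,
        kb.em_frame.cat_levels,
        np.vstack([kb.em_frame.real, row.real]),
        kb.em_frame.real_names,
    )
    kb.labels = np.append(kb.labels, cluster)
    kb.mixtures.pop(cluster, None)
    _compute_limits(kb)
    kb.retains_since_build += 1
    if kb.retains_since_build >= kb.config.refresh_threshold:
        _rebuild(kb)
    return kb


def _rebuild(kb: KnowledgeBase) -> None:
    kb.em_build_count += 1
    kb.encoder = CaseEncoder.fit(kb.cb)
    kb.em_frame = kb.encoder.encode_frame(kb.cb.cases, target="em")
    K = kb.n_clusters if kb.config.k_fixed is None else kb.config.k_fixed
    kb.em_model = em.em_fit(
        kb.em_frame,
        K,
        tol=kb.config.em_tol,
        max_iter=kb.config.em_max_iter,
        seed=_fan_seed(kb.seed, 2, kb.em_build_count),
        restarts=kb.config.em_restarts,
        alpha=kb.config.em_alpha,
        var_floor=kb.config.var_floor,
    )
    kb.labels = em.hard_labels(kb.em_model, kb.em_frame)
    cls_data = _classifier_data(None, kb.encoder, kb.cb.cases, kb.labels, K)
    kb.classifier = learn_structure(
        cls_data, alpha=kb.config.classifier_alpha, max_cond=kb.config.classifier_max_cond
    )
    fit_cpts(kb.classifier, cls_data, kb.config.classifier_laplace)
    kb.mixtures.clear()
    _compute_limits(kb)
    kb.retains_since_build = 0


# ---------------------------------------------------------------------------
# Full cycle
# ---------------------------------------------------------------------------

def predict_restoration(
    kb: KnowledgeBase, case: Case, exclude=None, with_mixture: bool = True
) -> Prediction:
    """Run retrieve -> reuse -> revise for both candidate materials."""
    cluster, retrieved, flags = retrieve(kb, case, exclude=exclude)
    lons = kb.cb.longevities()
    types = kb.cb.types()

    average_by_type: dict[str, float] = {}
    flags["average_from_cluster"] = False
    flags["average_from_global"] = False
    for t in RESTORATION_TYPES:
        same = [i for i in retrieved if types[i] == t]
        if same:
            average_by_type[t] = float(lons[same].mean())
        elif (cluster, t) in kb.limits:
            average_by_type[t] = kb.limits[(cluster, t)][0]
            flags["average_from_cluster"] = True
        elif t in kb.global_limits:
            average_by_type[t] = kb.global_limits[t][0]
            flags["average_from_global"] = True
        else:
            average_by_type[t] = float(lons.mean()) if len(lons) else 0.0

    mixture_by_type = None
    intervals: dict[str, tuple[float, float]] = {}
    if with_mixture:
        raw_by_type, reuse_flags = reuse(kb, cluster, case)
        flags.update(reuse_flags)
        mixture_by_type = {}
        for t, raw in raw_by_type.items():
            revised, interval, rev_flags = revise(kb, cluster, t, raw)
            mixture_by_type[t] = revised
            intervals[t] = interval
            flags["global_limits"] = flags.get("global_limits", False) or rev_flags["global_limits"]
    else:
        for t in RESTORATION_TYPES:
            _, interval, _ = revise(kb, cluster, t, average_by_type[t])
            intervals[t] = interval

    headline = (
        mixture_by_type
        if (kb.config.headline == "mixture" and mixture_by_type is not None)
        else average_by_type
    )
    recommended = max(RESTORATION_TYPES, key=lambda t: headline[t])
    return Prediction(
        recommended_type=recommended,
        longevity_by_type=dict(headline),
        average_by_type=average_by_type,
        mixture_by_type=mixture_by_type,
        confidence_interval=intervals,
        retrieved_ids=[kb.cb.cases[i].key for i in retrieved],
        retrieved_indices=list(retrieved),
        cluster_id=cluster,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_knowledge_base(kb: KnowledgeBase, path) -> None:
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "kind": "knowledge_base",
        "seed": kb.seed,
        "config": kb.config.to_dict(),
        "reference_date": kb.cb.reference_date.isoformat(),
        "cases": [_case_to_row(c) for c in kb.cb.cases],
        "em_model": kb.em_model.to_dict(),
        "labels": kb.labels.tolist(),
        "classifier": kb.classifier.to_dict(),
        "mixtures": {str(k): m.to_dict() for k, m in kb.mixtures.items()},
        "em_build_count": kb.em_build_count,
        "retains_since_build": kb.retains_since_build,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_knowledge_base(path) -> KnowledgeBase:
    import datetime as dt

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ModelVersionError(
            f"model file schema {payload.get('schema_version')} != {MODEL_SCHEMA_VERSION}"
        )
    ref = dt.date.fromisoformat(payload["reference_date"])
    cases = [_row_to_case(r, ref, row=i + 1) for i, r in enumerate(payload["cases"])]
    cb = CaseBase(cases, ref)
    config = EngineConfig.from_dict(payload["config"])
    encoder = CaseEncoder.fit(cb)
    kb = KnowledgeBase(
        cb=cb,
        config=config,
        seed=payload["seed"],
        encoder=encoder,
        em_model=em.EMModel.from_dict(payload["em_model"]),
        labels=np.asarray(payload["labels"], dtype=int),
        classifier=BayesNet.from_dict(payload["classifier"]),
        em_frame=encoder.encode_frame(cb.cases, target="em"),
        em_build_count=payload["em_build_count"],
        retains_since_build=payload["retains_since_build"],
    )
    for k, md in payload["mixtures"].items():
        kb.mixtures[int(k)] = MixtureModel.from_dict(md, encoder=encoder)
    _compute_limits(kb)
    return kb
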