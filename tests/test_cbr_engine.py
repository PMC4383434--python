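import dataclasses
import datetime as dt

import numpy as np
import pytest

from dentalcbr.case_model import CaseBase
from dentalcbr.cbr_engine import (
    DuplicateCaseError,
    EngineConfig,
    build_knowledge_base,
    classify,
    load_knowledge_base,
    predict_restoration,
    retain,
    retrieve,
    reuse,
    revise,
    save_knowledge_base,
    _similarity,
)
from dentalcbr.mixture import MixtureConfig
from dentalcbr.synthetic_data import default_paper_like_config, generate_casebase

FAST_MIX = MixtureConfig(epochs=40, patience=8, combiner_epochs=60)


def fast_config(**kw):
    base = dict(k_fixed=3, mixture=FAST_MIX)
    base.update(kw)
    return EngineConfig(**base)


@pytest.fixture(scope="module")
def kb_and_truth():
    cb, labels = generate_casebase(default_paper_like_config(13, n_cases=500))
    kb = build_knowledge_base(cb, fast_config(), seed=13)
    return kb, labels


class TestBuild:
    def test_classifier_agrees_with_em_labels(self, kb_and_truth):
        kb, _ = kb_and_truth
        agree = np.mean(
            [classify(kb, kb.cb.cases[i]) == kb.labels[i] for i in range(0, len(kb.cb), 5)]
        )
        assert agree >= 0.9

    def test_deterministic_given_seed(self, kb_and_truth):
        kb, _ = kb_and_truth
        kb2 = build_knowledge_base(kb.cb, fast_config(), seed=13)
        assert np.array_equal(kb.labels, kb2.labels)
        assert np.allclose(kb.em_model.weights, kb2.em_model.weights)

    def test_empty_casebase_rejected(self):
        with pytest.raises(ValueError):
            build_knowledge_base(CaseBase([], dt.date(2014, 6, 30)), fast_config(), seed=0)

    def test_confidence_limits_are_mean_and_sd(self, kb_and_truth):
        kb, _ = kb_and_truth
        lons = kb.cb.longevities()
        types = kb.cb.types()
        (k, t), (mean, sd) = next(iter(kb.limits.items()))
        mask = (kb.labels == k) & (types == t)
        assert mean == pytest.approx(lons[mask].mean())
        assert sd == pytest.approx(lons[mask].std())


class TestRetrieve:
    def test_identical_probe_ranked_first(self, kb_and_truth):
        kb, _ = kb_and_truth
        probe = kb.cb.cases[42]
        cluster, retrieved, _ = retrieve(kb, probe, m=5)
        assert retrieved[0] == 42

    def test_m_larger_than_cluster_returns_all(self, kb_and_truth):
        kb, _ = kb_and_truth
        probe = kb.cb.cases[0]
        cluster, retrieved, _ = retrieve(kb, probe, m=10**6)
        assert len(retrieved) == int((kb.labels == classify(kb, probe)).sum())

    def test_matches_exhaustive_scan_oracle(self, kb_and_truth):
        kb, _ = kb_and_truth
        probe = kb.cb.cases[7]
        cluster, retrieved, _ = retrieve(kb, probe, m=8)
        pool = np.where(kb.labels == cluster)[0]
        scores = _similarity(kb, probe, pool)
        order = np.lexsort((pool, -scores))
        assert retrieved == pool[order[:8]].tolist()

    def test_exclusion_respected(self, kb_and_truth):
        kb, _ = kb_and_truth
        probe = kb.cb.cases[42]
        _, retrieved, _ = retrieve(kb, probe, m=5, exclude={42})
        assert 42 not in retrieved

    def test_invalid_m(self, kb_and_truth):
        kb, _ = kb_and_truth
        with pytest.raises(ValueError):
            retrieve(kb, kb.cb.cases[0], m=0)


class TestReuseReviseRetain:
    def test_mixture_cached_after_first_reuse(self, kb_and_truth):
        kb, _ = kb_and_truth
        probe = kb.cb.cases[3]
        cluster = classify(kb, probe)
        reuse(kb, cluster, probe)
        assert kb.mixture_train_count.get(cluster) == 1
        reuse(kb, cluster, probe)
        assert kb.mixture_train_count.get(cluster) == 1  # cache hit, no retrain

    def test_small_cluster_average_fallback(self):
        cb, _ = generate_casebase(default_paper_like_config(41, n_cases=60))
        kb = build_knowledge_base(
            cb, fast_config(k_fixed=2, mixture=MixtureConfig(min_cases=10**6)), seed=1
        )
        est, flags = reuse(kb, 0, cb.cases[0])
        assert flags["average_fallback"]
        assert set(est) == {"amalgam", "composite"}

    def test_revise_passes_through_inside_limits(self, kb_and_truth):
        kb, _ = kb_and_truth
        (k, t), (mean, sd) = next(iter(kb.limits.items()))
        value, (lo, hi), _ = revise(kb, k, t, mean)
        assert value == pytest.approx(mean)
        assert (lo, hi) == pytest.approx((mean - 2 * sd, mean + 2 * sd))

    def test_revise_clamps_outliers(self, kb_and_truth):
        kb, _ = kb_and_truth
        (k, t), (mean, sd) = next(iter(kb.limits.items()))
        value, _, _ = revise(kb, k, t, mean + 10 * sd)
        assert value == pytest.approx(mean + 2 * sd)

    def test_retain_then_retrieve_finds_new_case(self):
        cb, _ = generate_casebase(default_paper_like_config(43, n_cases=150))
        kb = build_knowledge_base(cb, fast_config(k_fixed=2), seed=2)
        new = dataclasses.replace(cb.cases[0], patient_number=77777)
        retain(kb, new)
        _, retrieved, _ = retrieve(kb, new, m=3)
        assert len(kb.cb) == 151
        assert 150 in retrieved

    def test_retain_duplicate_rejected(self):
        cb, _ = generate_casebase(default_paper_like_config(47, n_cases=50))
        kb = build_knowledge_base(cb, fast_config(k_fixed=1), seed=0)
        with pytest.raises(DuplicateCaseError):
            retain(kb, dataclasses.replace(cb.cases[0]))

    def test_retain_invalidates_mixture_cache(self):
        cb, _ = generate_casebase(default_paper_like_config(53, n_cases=150))
        kb = build_knowledge_base(cb, fast_config(k_fixed=1), seed=3)
        probe = cb.cases[0]
        reuse(kb, 0, probe)
        assert kb.mixture_train_count[0] == 1
        retain(kb, dataclasses.replace(probe, patient_number=88888))
        assert 0 not in kb.mixtures
        reuse(kb, 0, probe)
        assert kb.mixture_train_count[0] == 2  # retrained after invalidation

    def test_refresh_threshold_triggers_rebuild(self):
        cb, _ = generate_casebase(default_paper_like_config(59, n_cases=120))
        kb = build_knowledge_base(cb, fast_config(k_fixed=2, refresh_threshold=3), seed=4)
        donors, _ = generate_casebase(default_paper_like_config(61, n_cases=3))
        fresh = [
            dataclasses.replace(c, patient_number=90000 + i) for i, c in enumerate(donors.cases)
        ]
        retain(kb, fresh[0])
        retain(kb, fresh[1])
        assert kb.em_build_count == 1  # below threshold: no retrain
        retain(kb, fresh[2])
        assert kb.em_build_count == 2  # threshold reached: EM retrained
        assert kb.retains_since_build == 0

    def test_default_refresh_threshold_is_fifty(self):
        assert EngineConfig().refresh_threshold == 50


class TestPredict:
    def test_average_of_uniform_retrieved_cases(self):
        cb, _ = generate_casebase(default_paper_like_config(67, n_cases=40))
        cases = [
            dataclasses.replace(c, restoration_type="composite", restoration_longevity=10.0)
            for c in cb.cases
        ]
        cb = CaseBase(cases, cb.reference_date)
        kb = build_knowledge_base(
            cb, fast_config(k_fixed=1, mixture=MixtureConfig(min_cases=10**6)), seed=5
        )
        pred = predict_restoration(kb, cb.cases[0])
        assert pred.average_by_type["composite"] == pytest.approx(10.0)

    def test_average_of_two_retrieved_cases(self):
        cb, _ = generate_casebase(default_paper_like_config(71, n_cases=2))
        cases = [
            dataclasses.replace(c, restoration_type="composite", restoration_longevity=lon)
            for c, lon in zip(cb.cases, (8.0, 12.0))
        ]
        cb = CaseBase(cases, cb.reference_date)
        kb = build_knowledge_base(
            cb, fast_config(k_fixed=1, m=2, mixture=MixtureConfig(min_cases=10**6)), seed=6
        )
        probe = dataclasses.replace(cases[0], patient_number=555)
        pred = predict_restoration(kb, probe)
        assert pred.average_by_type["composite"] == pytest.approx(10.0)

    def test_recommended_type_maximizes_headline(self, kb_and_truth):
        kb, _ = kb_and_truth
        pred = predict_restoration(kb, kb.cb.cases[10], with_mixture=False)
        best = max(pred.longevity_by_type, key=pred.longevity_by_type.get)
        assert pred.recommended_type == best

    def test_prediction_deterministic(self, kb_and_truth):
        kb, _ = kb_and_truth
        a = predict_restoration(kb, kb.cb.cases[11], with_mixture=False)
        b = predict_restoration(kb, kb.cb.cases[11], with_mixture=False)
        assert a.average_by_type == b.average_by_type
        assert a.retrieved_indices == b.retrieved_indices


class TestSerialization:
    def test_save_load_round_trip(self, kb_and_truth, tmp_path):
        kb, _ = kb_and_truth
        path = tmp_path / "kb.json"
        save_knowledge_base(kb, path)
        kb2 = load_knowledge_base(path)
        assert np.array_equal(kb2.labels, kb.labels)
        probe = kb.cb.cases[5]
        a = predict_restoration(kb, probe, with_mixture=False)
        b = predict_restoration(kb2, probe, with_mixture=False)
        assert a.average_by_type == pytest.approx(b.average_by_type)
        assert a.cluster_id == b.cluster_id

    def test_version_mismatch_rejected(self, kb_and_truth, tmp_path):
        import json

        from dentalcbr.cbr_engine import ModelVersionError

        kb, _ = kb_and_truth
        path = tmp_path / "kb.json"
        save_knowledge_base(kb, path)
        payload = json.loads(path.read_text())
        payload["schema_version"] = 999
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelVersionError):
            load_knowledge_base(path)
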