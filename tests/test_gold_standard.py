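"""Merge rule, detection pooling, consensus classification and session QC."""

import math

import networkx as nx
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coughval.gold_standard import (
    ExclusionReason,
    GoldClass,
    AnalysisSecond,
    DeviceSecond,
    annotator_tier_map,
    build_analysis_seconds,
    cluster_events,
    consensus_classify,
    merge_events_to_seconds,
    pool_detections,
    session_qc,
)
from coughval.io_formats import AnnotationLabel, Detection


def _labels(ann, time_tier_pairs):
    return [AnnotationLabel(ann, t, t, tier, str(tier)) for t, tier in time_tier_pairs]


def oracle_clusters(times, merge_gap):
    """Connected components of the 'closer than merge_gap' chain graph."""
    g = nx.Graph()
    g.add_nodes_from(range(len(times)))
    ts = sorted(times)
    for i in range(len(ts)):
        for j in range(i + 1, len(ts)):
            if ts[j] - ts[i] < merge_gap:
                g.add_edge(i, j)
    return sorted(
        sorted(ts[i] for i in comp) for comp in nx.connected_components(g)
    )


@pytest.mark.parametrize(
    "times, expected",
    [
        ([10.2, 10.8], {10}),
        ([45.0], {45}),
        ([10.0, 10.9, 11.7, 14.0], {10, 14}),
        ([], set()),
    ],
)
def test_merge_events_examples(times, expected):
    assert merge_events_to_seconds(times) == expected


@given(st.lists(st.floats(0, 100), max_size=25))
def test_clustering_matches_component_oracle(times):
    ours = sorted(sorted(c) for c in cluster_events(times, 1.0))
    assert ours == oracle_clusters(times, 1.0)


@given(st.lists(st.floats(0, 600), max_size=40))
def test_merge_size_and_idempotence(times):
    secs = merge_events_to_seconds(times)
    assert len(secs) <= len(times)
    # re-merging the representative times changes nothing
    assert merge_events_to_seconds(sorted(float(s) for s in secs)) == secs


def _det(t, score, device="phone1"):
    return Detection(device, t, score)


def test_pool_takes_max_score_within_second():
    pooled = pool_detections([_det(40.2, 0.30), _det(40.7, 0.91)])
    assert pooled == {40: DeviceSecond(True, 0.91)}


def test_pool_threshold_is_inclusive():
    pooled = pool_detections([_det(10.0, 0.85)])
    assert pooled[10].detected


def test_pool_below_threshold_not_detected():
    pooled = pool_detections([_det(10.0, 0.2), _det(10.4, 0.5)])
    assert pooled[10] == DeviceSecond(False, 0.5)


@given(
    st.lists(
        st.tuples(st.floats(0, 300), st.floats(0, 1)),
        max_size=30,
        unique_by=lambda row: row[0],
    )
)
def test_pool_scores_match_brute_force_max(rows):
    """Each pooled second carries the max score over its member detections."""
    dets = [_det(t, s) for t, s in rows]
    pooled = pool_detections(dets)
    expected: dict[int, float] = {}
    for t, s in rows:
        sec = int(math.floor(t))
        expected[sec] = max(s, expected.get(sec, 0.0))
    assert {sec: ds.max_score for sec, ds in pooled.items()} == expected


@pytest.mark.parametrize(
    "tiers, expected",
    [
        ((3, 3, 3), GoldClass.TRUE_COUGH),
        ((0, 0, 0), GoldClass.NON_COUGH),
        ((0, None, None), GoldClass.NON_COUGH),
        ((3, 3, 2), GoldClass.DISPUTED),
        ((2, 2, 2), GoldClass.COUGH_LIKE_NONCONSENSUS),
        ((1, 1, 1), GoldClass.COUGH_LIKE_NONCONSENSUS),
        ((3, 3, None), GoldClass.DISPUTED),  # silent annotator counts as tier 0
        ((0, 0, 1), GoldClass.DISPUTED),
    ],
)
def test_consensus_rule(tiers, expected):
    labels = {
        f"ann{i}": ([] if t is None else _labels(f"ann{i}", [(100.5, t)]))
        for i, t in enumerate(tiers, start=1)
    }
    assert consensus_classify(labels, 100) == expected


def test_consensus_outside_universe_raises():
    labels = {f"ann{i}": _labels(f"ann{i}", [(10.0, 3)]) for i in (1, 2, 3)}
    with pytest.raises(ValueError, match="universe"):
        consensus_classify(labels, 500)


def test_identical_tracks_never_disputed(small_cohort):
    track = small_cohort.sessions[0].labels["ann1"]
    labels = {f"ann{i}": track for i in (1, 2, 3)}
    secs, _ = build_analysis_seconds("s", labels, {})
    assert all(s.gold_class is not GoldClass.DISPUTED for s in secs)


def test_partition_of_labeled_seconds(small_cohort):
    """Every labeled second gets exactly one gold class."""
    ses = small_cohort.sessions[0]
    secs, _ = build_analysis_seconds(ses.session_id, ses.labels, {})
    universe = set()
    for track in ses.labels.values():
        universe |= {int(math.floor(lab.start)) for lab in track}
    classified = {s.second_index for s in secs}
    # merging can only move cough-like seconds onto cluster representatives
    assert classified <= universe
    n = len(secs)
    by_class = {
        c: sum(1 for s in secs if s.gold_class is c) for c in GoldClass
    }
    assert sum(by_class.values()) == n


def test_interval_labels_cover_overlapped_seconds():
    tiers = annotator_tier_map(
        [AnnotationLabel("a", 30.5, 32.2, 2, "2")]
    )
    assert set(tiers) == {30, 31, 32}
    tiers = annotator_tier_map([AnnotationLabel("a", 30.0, 31.0, 2, "2")])
    assert set(tiers) == {30}  # half-open bins: touching 31.0 does not enter [31, 32)


def test_out_of_universe_detections_counted_separately():
    labels = {f"ann{i}": _labels(f"ann{i}", [(10.0, 3)]) for i in (1, 2, 3)}
    dets = {"phone1": [_det(10.2, 0.95), _det(300.0, 0.99), _det(400.0, 0.2)]}
    secs, oou = build_analysis_seconds("s", labels, dets)
    assert len(secs) == 1 and secs[0].devices["phone1"].detected
    assert oou == {"phone1": 1}  # the 0.99 in silence; the 0.2 is sub-threshold


def _seconds(n_cough, n_non=5, session="s"):
    secs = [
        AnalysisSecond(session, i, GoldClass.TRUE_COUGH, {}) for i in range(n_cough)
    ]
    secs += [
        AnalysisSecond(session, 100 + i, GoldClass.NON_COUGH, {}) for i in range(n_non)
    ]
    return secs


@pytest.mark.parametrize(
    "n_coughs, synchronizable, included, reason",
    [
        (9, True, False, ExclusionReason.TOO_FEW_COUGHS),
        (10, True, True, ExclusionReason.NONE),
        (25, False, False, ExclusionReason.SYNC_FAILURE),
    ],
)
def test_session_qc_rules(n_coughs, synchronizable, included, reason):
    qc = session_qc(_seconds(n_coughs), synchronizable)
    assert qc.included == included
    assert qc.exclusion_reason is reason
    assert qc.n_unanimous_coughs == n_coughs
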