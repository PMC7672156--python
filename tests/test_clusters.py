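import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsite import (Region, Transcript, compaction_degree, find_clusters,
                     percent_of, span_length, transcript_report)
from mirsite.clusters import SiteInterval, clusters_from_table, clusters_to_frame
from mirsite.errors import ContractError


def make_sites(items, tid="tx"):
    """items: iterable of (start, length) or (start, length, mirna_id)."""
    out = []
    for i, item in enumerate(items):
        start, length = item[0], item[1]
        mid = item[2] if len(item) > 2 else f"m{i}"
        out.append(SiteInterval(mirna_id=mid, transcript_id=tid,
                                start=start, length=length))
    return out


def oracle_components(sites, min_overlap=1):
    """Connected components of the pairwise interval-overlap graph."""
    g = nx.Graph()
    g.add_nodes_from(range(len(sites)))
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            a, b = sites[i], sites[j]
            overlap = min(a.end, b.end) - max(a.start, b.start) + 1
            if overlap >= min_overlap:
                g.add_edge(i, j)
    return {frozenset((sites[i].start, sites[i].end) for i in comp)
            for comp in nx.connected_components(g)}


class TestSpanAndCompaction:
    @pytest.mark.parametrize("start,end,expected", [
        (11, 49, 39),        # 5'UTR cluster bounded at 11 and 49
        (2586, 2626, 41),    # CDS cluster bounded at 2586 and 2626
        (438, 482, 45),
        (99, 136, 38),
        (7, 7, 1),
    ])
    def test_span_length_inclusive(self, start, end, expected):
        assert span_length(start, end) == expected

    def test_span_inverted_bounds(self):
        with pytest.raises(ContractError):
            span_length(10, 9)

    @pytest.mark.parametrize("total,span,expected", [
        (824, 39, 21),
        (669, 45, 15),
        (735, 38, 19),
        (305, 33, 9),
        (170, 29, 6),
        (100, 100, 1),
    ])
    def test_compaction_degree(self, total, span, expected):
        assert compaction_degree(total, span) == expected

    def test_compaction_rounds_half_away_from_zero(self):
        assert compaction_degree(5, 2) == 3   # 2.5 -> 3
        assert compaction_degree(49, 20) == 2  # 2.45 -> 2

    def test_compaction_zero_span_rejected(self):
        with pytest.raises(ContractError):
            compaction_degree(100, 0)

    def test_percent_precisions(self):
        assert percent_of(1607, 4017, 0) == 40
        assert percent_of(110, 4017, 1) == 2.7


class TestFindClusters:
    def test_two_overlapping_sites_merge(self):
        clusters = find_clusters(make_sites([(11, 22), (30, 25)]))
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.span_start, c.span_end) == (11, 54)
        assert c.total_bs_length == 47

    def test_disjoint_sites_are_singletons(self):
        clusters = find_clusters(make_sites([(1, 20), (100, 20)]))
        assert len(clusters) == 2
        assert all(c.singleton for c in clusters)

    def test_transitive_chain_is_one_cluster(self):
        clusters = find_clusters(make_sites([(1, 10), (8, 10), (15, 10)]))
        assert len(clusters) == 1
        assert clusters[0].n_sites == 3

    def test_abutting_sites_do_not_merge(self):
        # [1,10] and [11,20] share no nucleotide
        clusters = find_clusters(make_sites([(1, 10), (11, 10)]))
        assert len(clusters) == 2

    def test_min_overlap_gate(self):
        # [1,10] and [10,19] overlap by exactly 1 nt
        sites = make_sites([(1, 10), (10, 10)])
        assert len(find_clusters(sites, min_overlap=1)) == 1
        assert len(find_clusters(sites, min_overlap=2)) == 2

    def test_mixed_transcripts_rejected(self):
        sites = make_sites([(1, 10)], tid="a") + make_sites([(1, 10)], tid="b")
        with pytest.raises(ContractError):
            find_clusters(sites)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=1, max_value=50))
    def test_matches_graph_components_oracle(self, seed, n_sites):
        rng = np.random.default_rng(seed)
        sites = make_sites(
            (int(rng.integers(1, 500)), int(rng.integers(15, 30)))
            for _ in range(n_sites))
        clusters = find_clusters(sites)
        got = {frozenset((s.start, s.end) for s in c.sites) for c in clusters}
        assert got == oracle_components(sites)
        # partition: every site in exactly one cluster
        assert sum(c.n_sites for c in clusters) == n_sites

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        sites = make_sites(
            (int(rng.integers(1, 300)), int(rng.integers(15, 30)))
            for _ in range(20))
        base = clusters_to_frame(find_clusters(sites))
        perm = [sites[i] for i in rng.permutation(len(sites))]
        shuffled = clusters_to_frame(find_clusters(perm))
        pd.testing.assert_frame_equal(base, shuffled)

    def test_compaction_at_least_one(self):
        for c in find_clusters(make_sites([(1, 20), (5, 20), (200, 22)])):
            assert c.compaction >= 1
            if c.singleton:
                assert c.compaction == 1


class TestClusterTableModes:
    def test_external_table_clustering(self):
        df = pd.DataFrame({
            "mirna_id": ["m1", "m2", "m3"],
            "transcript_id": ["tx", "tx", "tx"],
            "start": [11, 30, 100],
            "length": [22, 25, 20],
        })
        clusters = clusters_from_table(df)
        assert [c.n_sites for c in clusters] == [2, 1]

    def test_member_summary_notation(self):
        sites = make_sites([(17, 22, "m1"), (20, 22, "m1"), (23, 22, "m1")])
        frame = clusters_to_frame(find_clusters(sites))
        assert frame.loc[0, "members"] == "m1:17÷23 (3)"


class TestTranscriptReport:
    def _sites(self, tx):
        from mirsite import MiRNA, reverse_complement, scan
        mirna = MiRNA("m1", "ACGUACGUACGUACGUACGU")
        seq = (tx.seq[:4] + reverse_complement(mirna.seq)
               + tx.seq[24:44] + reverse_complement(mirna.seq) + tx.seq[64:])
        planted = Transcript(tx.id, seq, cds_start=tx.cds_start,
                             cds_end=tx.cds_end)
        return planted, scan(mirna, planted, min_ratio_pct=100)

    def test_report_rows_and_region_percent(self, annotated_transcript):
        planted, sites = self._sites(annotated_transcript)
        report = transcript_report(planted, sites)
        totals = report[report.row_type == "region_total"]
        assert not totals.empty
        for _, row in totals.iterrows():
            assert row["total_bs_pct_of_region"] == percent_of(
                row["total_bs_length"], row["region_length"], 1)

    def test_empty_sites_empty_report(self, annotated_transcript):
        assert transcript_report(annotated_transcript, []).empty

    def test_clusters_respect_region_grouping(self, annotated_transcript):
        planted, sites = self._sites(annotated_transcript)
        report = transcript_report(planted, sites)
        cluster_rows = report[report.row_type == "cluster"]
        # sites land in distinct regions -> no cluster mixes regions
        assert set(cluster_rows["region"]) <= {"5'UTR", "CDS", "3'UTR"}
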