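import numpy as np
import pandas as pd
import pytest

from relnet.correlation import CorrelationResult
from relnet.network import (
    RelevanceNetwork,
    annotate_locality,
    build_network,
    difference_network,
    export_network,
    match_link_count,
    read_mirbase_gff3,
    read_transcript_gtf,
)


def _corr(r, ids=None, undefined=None):
    r = np.asarray(r, dtype=float)
    return CorrelationResult(r, "bayesian", entity_ids=ids, undefined_entities=undefined)


def _random_corr(rng, m):
    a = rng.uniform(-1, 1, size=(m, m))
    r = (a + a.T) / 2
    np.fill_diagonal(r, 1.0)
    return _corr(r)


class TestBuildNetwork:
    def test_above_one_threshold_empty(self, rng):
        net = build_network(_random_corr(rng, 5), 1.0 + 1e-9)
        assert net.n_links == 0
        assert net.nodes == []

    def test_threshold_counting(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.97
        r[0, 2] = r[2, 0] = 0.95
        r[1, 2] = r[2, 1] = 0.99
        net = build_network(_corr(r), 0.96)
        assert net.n_links == 2
        assert net.edge_set() == {frozenset({"e0", "e1"}), frozenset({"e1", "e2"})}

    def test_matches_brute_force_scan(self, rng):
        corr = _random_corr(rng, 50)
        t = 0.4
        net = build_network(corr, t)
        count = sum(
            1
            for i in range(50)
            for j in range(i + 1, 50)
            if corr.r[i, j] >= t
        )
        assert net.n_links == count
        assert (net.edges["r"] >= t).all()

    def test_edge_count_nonincreasing_in_threshold(self, rng):
        corr = _random_corr(rng, 20)
        counts = [build_network(corr, t).n_links for t in np.linspace(-1, 1, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_masked_entities_never_linked(self, rng):
        corr = _random_corr(rng, 4)
        corr.r[2, :] = np.nan
        corr.r[:, 2] = np.nan
        corr.undefined_entities = np.array([False, False, True, False])
        net = build_network(corr, -1.0)
        assert "e2" not in net.nodes


class TestMatchLinkCount:
    def test_extremes(self, rng):
        corr = _random_corr(rng, 10)
        vals = corr.defined_upper_values()
        t_all, n_all = match_link_count(corr, len(vals))
        assert t_all == pytest.approx(vals.min())
        assert n_all == len(vals)
        t_one, n_one = match_link_count(corr, 1)
        assert t_one == pytest.approx(vals.max())
        assert n_one == 1

    def test_matches_sort_oracle(self, rng):
        corr = _random_corr(rng, 30)
        vals = sorted(corr.defined_upper_values(), reverse=True)
        for target in (3, 57, 200):
            t, achieved = match_link_count(corr, target)
            assert t == pytest.approx(vals[target - 1])
            assert achieved >= target
            assert build_network(corr, t).n_links == achieved

    def test_unreachable_target(self, rng):
        corr = _random_corr(rng, 5)
        with pytest.raises(ValueError):
            match_link_count(corr, 11)  # only 10 pairs


class TestDifferenceNetwork:
    def _net(self, pairs):
        edges = pd.DataFrame(
            [{"entity_i": i, "entity_j": j, "r": r} for i, j, r in pairs]
        )
        return RelevanceNetwork(edges, 0.9)

    def test_identical_networks_all_shared(self):
        net = self._net([("a", "b", 0.95), ("b", "c", 0.97)])
        edges, nodes = difference_network(net, net)
        assert (edges["label"] == "shared").all()
        assert set(nodes.values()) == {"shared"}

    def test_disjoint_networks_share_nothing(self):
        na = self._net([("a", "b", 0.95)])
        nb = self._net([("c", "d", 0.97)])
        edges, nodes = difference_network(na, nb)
        assert set(edges["label"]) == {"A-only", "B-only"}
        assert nodes == {"a": "A-only", "b": "A-only", "c": "B-only", "d": "B-only"}

    def test_label_counts_match_set_algebra(self, rng):
        ids = [f"v{k}" for k in range(12)]
        def random_net():
            pairs = set()
            while len(pairs) < 15:
                i, j = rng.choice(12, size=2, replace=False)
                pairs.add(frozenset((ids[i], ids[j])))
            return self._net([(min(p, key=str), max(p, key=str), 0.9) for p in pairs])
        na, nb = random_net(), random_net()
        edges, _ = difference_network(na, nb)
        ea, eb = na.edge_set(), nb.edge_set()
        counts = edges["label"].value_counts().to_dict()
        assert counts.get("shared", 0) == len(ea & eb)
        assert counts.get("A-only", 0) == len(ea - eb)
        assert counts.get("B-only", 0) == len(eb - ea)
        # swap symmetry up to relabeling
        swapped, _ = difference_network(nb, na)
        sc = swapped["label"].value_counts().to_dict()
        assert sc.get("A-only", 0) == counts.get("B-only", 0)
        assert sc.get("B-only", 0) == counts.get("A-only", 0)
        assert sc.get("shared", 0) == counts.get("shared", 0)


GFF3 = """##gff-version 3
chr1\t.\tmiRNA_primary_transcript\t100\t180\t.\t+\t.\tID=MI0000001;Name=hsa-mir-1
chr1\t.\tmiRNA\t105\t125\t.\t+\t.\tID=MIMAT0000001;Alias=MIMAT0000001;Name=hsa-miR-1-5p;Derives_from=MI0000001
chr1\t.\tmiRNA\t150\t170\t.\t+\t.\tID=MIMAT0000002;Alias=MIMAT0000002;Name=hsa-miR-1-3p;Derives_from=MI0000001
chr1\t.\tmiRNA_primary_transcript\t201000\t201100\t.\t+\t.\tID=MI0000002;Name=hsa-mir-2
chr1\t.\tmiRNA\t201000\t201020\t.\t+\t.\tID=MIMAT0000003;Alias=MIMAT0000003;Name=hsa-miR-2;Derives_from=MI0000002
chr1\t.\tmiRNA_primary_transcript\t205000\t205100\t.\t+\t.\tID=MI0000003;Name=hsa-mir-3
chr1\t.\tmiRNA\t205000\t205020\t.\t+\t.\tID=MIMAT0000004;Alias=MIMAT0000004;Name=hsa-miR-3;Derives_from=MI0000003
chr1\t.\tmiRNA\t50000\t50020\t.\t+\t.\tID=MIMAT0000005;Alias=MIMAT0000005;Name=hsa-miR-5;Derives_from=MI0000005
chr1\t.\tmiRNA\t59000\t59020\t.\t+\t.\tID=MIMAT0000006;Alias=MIMAT0000006;Name=hsa-miR-6;Derives_from=MI0000006
chr1\t.\tmiRNA\t68000\t68020\t.\t+\t.\tID=MIMAT0000007;Alias=MIMAT0000007;Name=hsa-miR-7;Derives_from=MI0000007
chr2\t.\tmiRNA\t500\t520\t.\t+\t.\tID=MIMAT0000008;Alias=MIMAT0000008;Name=hsa-miR-8;Derives_from=MI0000008
chr1\t.\tmiRNA\t400000\t400020\t.\t+\t.\tID=MIMAT0000010\t;Alias=MIMAT0000010;Name=hsa-miR-10;Derives_from=MI0000010
chr2\t.\tmiRNA\t1000\t1020\t.\t+\t.\tID=MIMAT0000010_2;Alias=MIMAT0000010;Name=hsa-miR-10;Derives_from=MI0000010_2
chr2\t.\tmiRNA\t5000\t5020\t.\t+\t.\tID=MIMAT0000011;Alias=MIMAT0000011;Name=hsa-miR-11;Derives_from=MI0000011
"""

GTF = (
    'chr1\ttest\ttranscript\t200000\t210000\t.\t+\t.\t'
    'gene_id "g1"; transcript_id "t1";\n'
)


@pytest.fixture(scope="module")
def annotation_inputs(tmp_path_factory):
    d = tmp_path_factory.mktemp("anno")
    gff = d / "mirnas.gff3"
    gff.write_text(GFF3.replace("ID=MIMAT0000010\t;", "ID=MIMAT0000010;"))
    gtf = d / "transcripts.gtf"
    gtf.write_text(GTF)
    mature, stemloop = read_mirbase_gff3(gff)
    transcripts = read_transcript_gtf(gtf)
    return mature, stemloop, transcripts


class TestLocality:
    def _edges(self, pairs):
        return RelevanceNetwork(
            pd.DataFrame(
                [{"entity_i": a, "entity_j": b, "r": 0.99} for a, b in pairs]
            ),
            0.96,
        )

    def test_parsers(self, annotation_inputs):
        mature, stemloop, transcripts = annotation_inputs
        assert stemloop["MIMAT0000001"] == {"MI0000001"}
        assert len(mature["MIMAT0000010"]) == 2  # multi-locus, suffix stripped
        assert transcripts[0][3] == "t1"

    def test_categories_in_priority_order(self, annotation_inputs):
        mature, stemloop, transcripts = annotation_inputs
        net = self._edges(
            [
                ("MIMAT0000001", "MIMAT0000002"),  # same stem-loop (also near)
                ("MIMAT0000003", "MIMAT0000004"),  # same transcript (also near)
                ("MIMAT0000005", "MIMAT0000006"),  # within 10 kb
                ("MIMAT0000005", "MIMAT0000007"),  # linked only transitively
                ("MIMAT0000001", "MIMAT0000008"),  # different chromosomes
            ]
        )
        cats = annotate_locality(net, stemloop, mature, transcripts)
        assert cats.tolist() == ["stem-loop", "transcript", "near", "cluster", "non-local"]

    def test_multi_locus_near_via_any_occurrence(self, annotation_inputs):
        mature, stemloop, transcripts = annotation_inputs
        net = self._edges([("MIMAT0000010", "MIMAT0000011")])
        cats = annotate_locality(net, stemloop, mature, transcripts)
        assert cats.tolist() == ["near"]

    def test_missing_genomic_record_is_non_local(self, annotation_inputs, caplog):
        mature, stemloop, transcripts = annotation_inputs
        net = self._edges([("MIMAT0000001", "MIMAT9999999")])
        with caplog.at_level("WARNING"):
            cats = annotate_locality(net, stemloop, mature, transcripts)
        assert cats.tolist() == ["non-local"]
        assert any("no genomic record" in r.message for r in caplog.records)

    def test_categories_partition_edges(self, annotation_inputs):
        mature, stemloop, transcripts = annotation_inputs
        ids = sorted(mature)
        net = self._edges([(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]])
        cats = annotate_locality(net, stemloop, mature, transcripts)
        assert len(cats) == net.n_links
        assert set(cats) <= {"stem-loop", "transcript", "near", "cluster", "non-local"}


class TestExport:
    def _net(self):
        return RelevanceNetwork(
            pd.DataFrame(
                [
                    {"entity_i": "a", "entity_j": "b", "r": 0.97},
                    {"entity_i": "b", "entity_j": "c", "r": 0.99},
                ]
            ),
            0.96,
        )

    def test_sif_lines(self, tmp_path):
        path = tmp_path / "n.sif"
        export_network(self._net(), path, "sif")
        lines = path.read_text().strip().split("\n")
        assert lines == ["a\tbayesian\tb", "b\tbayesian\tc"]

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        path = tmp_path / "n.graphml"
        net = self._net()
        export_network(net, path, "graphml")
        back = nx.read_graphml(path)
        assert {frozenset(e) for e in back.edges()} == net.edge_set()
        assert back.edges["a", "b"]["r"] == pytest.approx(0.97)

    def test_empty_network_valid_documents(self, tmp_path):
        empty = RelevanceNetwork(pd.DataFrame(columns=["entity_i", "entity_j", "r"]), 2.0)
        for fmt, name in [("sif", "e.sif"), ("graphml", "e.graphml"), ("tsv", "e.tsv")]:
            export_network(empty, tmp_path / name, fmt)
            assert (tmp_path / name).exists()
        assert (tmp_path / "e.sif").read_text() == ""

    def test_tsv_includes_locality(self, tmp_path):
        path = tmp_path / "n.tsv"
        export_network(self._net(), path, "tsv", annotation=pd.Series(["near", "cluster"]))
        df = pd.read_csv(path, sep="\t")
        assert df["locality"].tolist() == ["near", "cluster"]

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(self._net(), tmp_path / "x", "dot")
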