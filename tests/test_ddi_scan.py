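import numpy as np
import networkx as nx
import pytest

from ddikit.ddi_scan import (
    DEFAULT_EXCLUDED_PFAMS,
    DomainMatch,
    PLDDTProfile,
    ddi_enrichment,
    degree_preserving_randomize,
    export_fragment_pairs,
    load_domain_matches,
    parse_fragment_header,
    predict_ddis,
    refine_boundaries,
    write_domain_matches,
)
from ddikit.errors import CoverageError, FlatParseError

DOMTBL_ROW = (
    "{pfam_name}  {acc}  100  {protein}  -  {plen}  1e-20  55.0  0.1  1  1  "
    "2e-20  1e-19  50.0  0.1  1  95  {ali_from}  {ali_to}  {env_from}  {env_to}  0.9  desc"
)


def domtbl_file(tmp_path):
    rows = [
        "# comment line",
        DOMTBL_ROW.format(pfam_name="Ras", acc="PF00071.22", protein="P01112",
                          plen=189, ali_from=5, ali_to=160, env_from=2, env_to=165),
        DOMTBL_ROW.format(pfam_name="zf-RING", acc="PF13639.6", protein="Q9Y4K3",
                          plen=500, ali_from=20, ali_to=100, env_from=17, env_to=102),
        DOMTBL_ROW.format(pfam_name="Ub-con", acc="PF00179.26", protein="P51668",
                          plen=150, ali_from=10, ali_to=140, env_from=8, env_to=145),
    ]
    path = tmp_path / "hits.domtblout"
    path.write_text("\n".join(rows) + "\n")
    return path


class TestMatchIO:
    def test_domtblout_rows_become_matches(self, tmp_path):
        matches = load_domain_matches(domtbl_file(tmp_path))
        assert len(matches) == 3
        assert {m.pfam for m in matches} == {"PF00071", "PF13639", "PF00179"}

    def test_envelope_coordinates_used(self, tmp_path):
        matches = load_domain_matches(domtbl_file(tmp_path))
        ring = next(m for m in matches if m.pfam == "PF13639")
        assert (ring.start, ring.end) == (17, 102)

    def test_simple_tsv_roundtrip(self, tmp_path):
        matches = load_domain_matches(domtbl_file(tmp_path))
        path = tmp_path / "matches.tsv"
        write_domain_matches(matches, path)
        assert load_domain_matches(path) == matches

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("protein\tpfam\tstart\tend\nP1\tPF1\tx\t9\n")
        with pytest.raises(FlatParseError) as err:
            load_domain_matches(path)
        assert err.value.line_number == 2

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            DomainMatch(protein="P1", pfam="PF00001", start=10, end=5)


def simple_case():
    net = nx.Graph([("A", "B")])
    matches = [
        DomainMatch("A", "PF13639", 17, 102),
        DomainMatch("B", "PF00179", 8, 145),
    ]
    hc = {("PF00179", "PF13639")}
    return net, matches, hc


class TestPrediction:
    def test_complementary_matches_yield_one_prediction(self):
        net, matches, hc = simple_case()
        preds = predict_ddis(net, matches, hc)
        assert len(preds) == 1
        assert preds[0].ddi_type == ("PF00179", "PF13639")
        assert preds[0].n_types_on_edge == 1

    def test_rod_domain_pairs_dropped_by_default(self):
        net = nx.Graph([("K1", "K2")])
        matches = [DomainMatch("K1", "PF00038", 1, 300),
                   DomainMatch("K2", "PF00038", 1, 300)]
        assert predict_ddis(net, matches, {("PF00038", "PF00038")}) == []
        assert "PF00038" in DEFAULT_EXCLUDED_PFAMS

    def test_invariant_to_edge_orientation_and_pair_order(self):
        matches = [
            DomainMatch("A", "PF13639", 17, 102),
            DomainMatch("B", "PF00179", 8, 145),
        ]
        variants = [
            (nx.Graph([("A", "B")]), {("PF00179", "PF13639")}),
            (nx.Graph([("B", "A")]), {("PF13639", "PF00179")}),
        ]
        results = [
            [(p.ddi_type, p.protein_a, p.protein_b)
             for p in predict_ddis(net, matches, hc)]
            for net, hc in variants
        ]
        assert results[0] == results[1]

    def test_self_edge_needs_both_domains_on_one_protein(self):
        net = nx.Graph()
        net.add_edge("A", "A")
        hc = {("PF00001", "PF00002")}
        only_one = [DomainMatch("A", "PF00001", 1, 50)]
        both = only_one + [DomainMatch("A", "PF00002", 60, 120)]
        assert predict_ddis(net, only_one, hc) == []
        assert len(predict_ddis(net, both, hc)) == 1

    def test_homotypic_pair_needs_match_on_both_partners(self):
        net = nx.Graph([("A", "B")])
        hc = {("PF00005", "PF00005")}
        one_side = [DomainMatch("A", "PF00005", 1, 50)]
        assert predict_ddis(net, one_side, hc) == []
        both = one_side + [DomainMatch("B", "PF00005", 1, 50)]
        assert len(predict_ddis(net, both, hc)) == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_per_edge_multiplicity_matches_cross_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        proteins = [f"P{i}" for i in range(8)]
        pfams = [f"PF0000{i}" for i in range(6)]
        net = nx.gnm_random_graph(8, 12, seed=seed)
        net = nx.relabel_nodes(net, dict(enumerate(proteins)))
        matches = [
            DomainMatch(p, f, 1, 50)
            for p in proteins for f in pfams if rng.random() < 0.4
        ]
        hc = {tuple(sorted((pfams[0], pfams[1]))),
              tuple(sorted((pfams[2], pfams[3]))),
              tuple(sorted((pfams[4], pfams[4])))}
        preds = predict_ddis(net, matches, hc)
        # brute-force oracle over all edge x type combinations
        pf_by_prot = {}
        for m in matches:
            pf_by_prot.setdefault(m.protein, set()).add(m.pfam)
        expected = set()
        for u, v in net.edges():
            for x, y in hc:
                pu = pf_by_prot.get(u, set())
                pv = pf_by_prot.get(v, set())
                if u == v:
                    ok = x in pu and y in pu
                else:
                    ok = (x in pu and y in pv) or (y in pu and x in pv)
                if ok:
                    expected.add((tuple(sorted((u, v))), (x, y)))
        got = {((p.protein_a, p.protein_b) if p.protein_a <= p.protein_b
                else (p.protein_b, p.protein_a), p.ddi_type) for p in preds}
        assert got == expected
        for p in preds:
            edge = tuple(sorted((p.protein_a, p.protein_b)))
            assert p.n_types_on_edge == sum(e == edge for e, _ in expected)


class TestRandomization:
    def test_degree_sequence_exactly_preserved(self):
        g = nx.gnm_random_graph(50, 120, seed=1)
        r = degree_preserving_randomize(g, seed=7)
        assert dict(g.degree()) == dict(r.degree())

    def test_four_cycle_stays_a_valid_wiring(self):
        g = nx.cycle_graph(4)
        r = degree_preserving_randomize(g, seed=0)
        assert sorted(d for _, d in r.degree()) == [2, 2, 2, 2]
        assert r.number_of_edges() == 4

    def test_seeded_reproducibility_and_actual_shuffling(self):
        g = nx.gnm_random_graph(100, 300, seed=2)
        r1 = degree_preserving_randomize(g, seed=11)
        r2 = degree_preserving_randomize(g, seed=11)
        assert set(r1.edges()) == set(r2.edges())
        overlap = len(set(map(frozenset, r1.edges()))
                      & set(map(frozenset, g.edges())))
        assert overlap / g.number_of_edges() < 0.5

    def test_too_small_network_rejected(self):
        with pytest.raises(ValueError):
            degree_preserving_randomize(nx.Graph([("A", "B")]))


class TestEnrichment:
    def test_no_matches_means_no_signal(self):
        g = nx.gnm_random_graph(20, 40, seed=3)
        res = ddi_enrichment(g, [], {("PF00001", "PF00002")}, n_random=10, seed=0)
        assert res.observed == 0
        assert all(c == 0 for c in res.null_counts)
        assert res.p_value == 1.0

    def test_saturated_signal_is_rewiring_invariant(self):
        # every protein carries both domains: every wiring predicts every
        # edge, so observed equals each null count and p is exactly 1
        g = nx.gnm_random_graph(12, 20, seed=4)
        matches = []
        for node in g.nodes():
            matches.append(DomainMatch(str(node), "PF00001", 1, 50))
            matches.append(DomainMatch(str(node), "PF00002", 60, 110))
        g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes()})
        res = ddi_enrichment(g, matches, {("PF00001", "PF00002")},
                             n_random=10, seed=1)
        assert res.observed == g.number_of_edges()
        assert set(res.null_counts) == {res.observed}
        assert res.p_value == 1.0


def plateau_profile(length=300, start=20, end=120, high=95.0, low=40.0):
    values = np.full(length, low)
    values[start - 1 : end] = high
    return PLDDTProfile("P1", values)


def oracle_refine(values, start, end, cutoff=80.0, window=10):
    """Direct step-by-step simulation of the extension rule."""
    n = len(values)
    while start > 1 and np.mean(values[start - 1 : min(start - 1 + window, n)]) >= cutoff:
        start -= 1
    while end < n and np.mean(values[max(0, end - window) : end]) >= cutoff:
        end += 1
    return start, end


class TestBoundaryRefinement:
    def test_low_confidence_boundaries_unchanged(self):
        prof = PLDDTProfile("P1", np.full(200, 70.0))
        m = DomainMatch("P1", "PF00001", 50, 120)
        assert refine_boundaries(m, prof) == (50, 120)

    def test_expansion_stops_in_low_confidence_stretch(self):
        prof = plateau_profile()
        m = DomainMatch("P1", "PF00001", 40, 100)
        start, end = refine_boundaries(m, prof)
        assert start <= 40 and end >= 100
        # expansion reaches the plateau edges but halts within one window
        assert abs(start - 20) <= 10 and abs(end - 120) <= 10
        assert (start, end) == oracle_refine(prof.values, 40, 100)

    def test_terminus_clamps_extension(self):
        prof = PLDDTProfile("P1", np.full(100, 95.0))
        m = DomainMatch("P1", "PF00001", 10, 95)
        assert refine_boundaries(m, prof) == (1, 100)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_rule_simulation_on_noisy_profiles(self, seed):
        rng = np.random.default_rng(seed)
        values = np.clip(
            np.where(np.arange(300) % 97 < 50, 90.0, 45.0)
            + rng.normal(0, 8, 300),
            0, 100,
        )
        prof = PLDDTProfile("P1", values)
        start = int(rng.integers(30, 150))
        end = int(rng.integers(start + 10, 280))
        m = DomainMatch("P1", "PF00001", start, end)
        got = refine_boundaries(m, prof)
        assert got == oracle_refine(values, start, end)
        assert got[0] <= start and got[1] >= end  # containment invariant

    def test_raising_cutoff_never_widens(self):
        prof = plateau_profile(high=85.0)
        m = DomainMatch("P1", "PF00001", 40, 100)
        lo = refine_boundaries(m, prof, cutoff=75)
        hi = refine_boundaries(m, prof, cutoff=90)
        assert hi[0] >= lo[0] and hi[1] <= lo[1]

    def test_profile_shorter_than_match_is_coverage_error(self):
        prof = PLDDTProfile("P1", np.full(50, 90.0))
        with pytest.raises(CoverageError):
            refine_boundaries(DomainMatch("P1", "PF00001", 10, 80), prof)


class TestFragmentExport:
    def test_exported_length_and_roundtrip(self, tmp_path):
        from Bio import SeqIO

        net, matches, hc = simple_case()
        preds = predict_ddis(net, matches, hc)
        rng = np.random.default_rng(0)
        seqs = {
            "A": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200)),
            "B": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200)),
        }
        paths = export_fragment_pairs(preds, seqs, tmp_path / "frag")
        assert len(paths) == 1
        records = list(SeqIO.parse(paths[0], "fasta"))
        assert len(records) == 2
        for rec in records:
            acc, pfam, start, end = parse_fragment_header(rec.id)
            assert len(rec.seq) == end - start + 1
            assert str(rec.seq) == seqs[acc][start - 1 : end]

    def test_out_of_bounds_coordinates_rejected(self, tmp_path):
        net, matches, hc = simple_case()
        preds = predict_ddis(net, matches, hc)
        seqs = {"A": "ACDEF", "B": "ACDEF"}
        with pytest.raises(IndexError):
            export_fragment_pairs(preds, seqs, tmp_path / "frag")

    def test_missing_sequence_rejected(self, tmp_path):
        net, matches, hc = simple_case()
        preds = predict_ddis(net, matches, hc)
        with pytest.raises(KeyError):
            export_fragment_pairs(preds, {"A": "A" * 200}, tmp_path / "frag")
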