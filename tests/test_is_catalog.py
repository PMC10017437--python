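"""TIR/DR detection, transposase identity, clustering and catalog assembly."""

import numpy as np
import pytest

from iskit.genome_io import CdsFeature, FlankWindow, TpaseCandidate
from iskit.is_catalog import (
    CatalogConfig,
    DegenerateInputError,
    build_catalog,
    assign_family,
    cluster_subtypes,
    find_dr,
    find_tir,
    load_family_exemplars,
    pairwise_identity,
    revcomp,
)
from iskit.transposition_sim import (
    DEFAULT_IS_SPECS,
    _mutate_protein,
    plant_element,
    synth_genome,
)
from _helpers import brute_force_tir, gotoh_score, make_tir_window, rand_dna

# TIR arms characteristic of the emulated mobilome families
PRINTED_TIRS = [
    "CTCTGTACCGGACAACT",      # IS4, 17 nt
    "CTCGGTAGCTGACAACTTCA",   # IS4, 20 nt
    "AGGCTG",                 # IS5, 6 nt
    "TACGGACTCCGATTAA",       # IS630, 16 nt
]


class TestFindTir:
    @pytest.mark.parametrize("tir", PRINTED_TIRS[:2] + PRINTED_TIRS[3:])
    def test_recovers_planted_arm_exactly(self, tir):
        w = make_tir_window(tir, stub_len=1000, flank=50, seed=11)
        t = find_tir(w)
        assert t is not None
        assert t.left_seq == tir
        assert t.right_seq == revcomp(tir)
        assert t.mismatches == 0

    def test_short_arm_recovered_in_quiet_window(self):
        # a 6-nt arm is below the default noise floor; it is only findable
        # with exact matching and a lowered floor in a short, quiet window
        tir = "AGGCTG"
        w = make_tir_window(tir, stub_len=40, flank=8, seed=3)
        t = find_tir(w, max_mismatch=0, min_score=6)
        assert t is not None and (t.left_seq, t.mismatches) == (tir, 0)

    def test_homopolymer_window_has_no_arms(self):
        cand = TpaseCandidate(CdsFeature("T", 20, 80, "+", "transposase"), "t")
        w = FlankWindow("g", cand, (1, 100), "A" * 100, (20, 80))
        assert find_tir(w) is None

    def test_window_too_short_raises(self):
        cand = TpaseCandidate(CdsFeature("T", 2, 6, "+", "transposase"), "t")
        w = FlankWindow("g", cand, (1, 8), "ACGTACGT", (2, 6))
        with pytest.raises(DegenerateInputError):
            find_tir(w, min_arm=6)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(80, 160))
        seq = rand_dna(n, rng, gc=0.6)
        ts = n // 3
        te = 2 * n // 3
        cand = TpaseCandidate(CdsFeature("T", ts, te, "+", "transposase"), "t")
        w = FlankWindow("g", cand, (1, n), seq, (ts, te))
        got = find_tir(w, min_score=6)
        expect = brute_force_tir(w, min_score=6)
        if expect is None:
            assert got is None
        else:
            a, mism, i, u = expect
            assert got is not None
            assert (got.arm_length, got.mismatches) == (a, mism)
            assert got.left_span == (i + 1, i + a)
            assert got.right_span == (u - a + 2, u + 1)

    def test_bruteforce_agreement_on_planted_window(self):
        w = make_tir_window("CTCTGTACCGGACAACT", stub_len=120, flank=30, seed=5)
        got = find_tir(w)
        a, mism, i, u = brute_force_tir(w)
        assert (got.arm_length, got.mismatches, got.left_span[0] - 1) == (a, mism, i)


class TestFindDr:
    def _window_with_dr(self, dr, tir="CTCTGTACCGGACAACT", seed=0):
        from iskit.is_catalog import TIRPair

        rng = np.random.default_rng(seed)
        left = list(rand_dna(40, rng))
        right = list(rand_dna(40, rng))
        left[-len(dr):] = list(dr)
        right[: len(dr)] = list(dr)
        # stop chance extension of the duplication
        while left[-len(dr) - 1] == right[len(dr)]:
            right[len(dr)] = "ACGT"[int(rng.integers(4))]
        stub = rand_dna(60, rng)
        seq = "".join(left) + tir + stub + revcomp(tir) + "".join(right)
        cand = TpaseCandidate(CdsFeature("T", 41 + len(tir), 40 + len(tir) + 60, "+", "t"), "t")
        w = FlankWindow("g", cand, (1, len(seq)), seq, cand.feature.span)
        nt = len(tir)
        t = TIRPair(
            left_span=(41, 40 + nt), left_seq=tir,
            right_span=(41 + nt + 60, 40 + 2 * nt + 60), right_seq=revcomp(tir),
            mismatches=0,
        )
        assert seq[40 : 40 + nt] == tir
        assert seq[40 + nt + 60 : 40 + 2 * nt + 60] == revcomp(tir)
        return w, t

    @pytest.mark.parametrize("dr", ["GCCGTGATC", "ACCCGCCCC", "TAG"])
    def test_recovers_planted_duplication(self, dr):
        w, t = self._window_with_dr(dr)
        d = find_dr(w, t)
        assert d is not None
        assert d.sequence == dr
        assert d.length == len(dr)

    def test_unrelated_contexts_give_none(self):
        tir = "CTCTGTACCGGACAACT"
        seq = "A" * 20 + tir + "G" * 60 + revcomp(tir) + "C" * 20
        cand = TpaseCandidate(CdsFeature("T", 38, 97, "+", "t"), "t")
        w = FlankWindow("g", cand, (1, len(seq)), seq, (38, 97))
        t = find_tir(w)
        assert t is not None
        assert find_dr(w, t) is None

    def test_truncated_context_flag(self):
        # arms almost at the window edge: fewer than max_dr nt of context
        rng = np.random.default_rng(4)
        tir = "CTCTGTACCGGACAACT"
        dr = "TAGC"
        stub = rand_dna(60, rng)
        seq = dr + tir + stub + revcomp(tir) + dr + "G"
        while seq[-1] == seq[3]:
            seq = seq[:-1] + "ACGT"[int(rng.integers(4))]
        cand = TpaseCandidate(CdsFeature("T", 5 + len(tir), 4 + len(tir) + 60, "+", "t"), "t")
        w = FlankWindow("g", cand, (1, len(seq)), seq, cand.feature.span)
        t = find_tir(w)
        d = find_dr(w, t)
        assert d is not None and d.sequence == dr
        assert d.truncated_context


class TestPairwiseIdentity:
    def test_frozen_example(self):
        assert pairwise_identity("MKVLH", "MRVLH") == pytest.approx(0.8)

    def test_self_identity_and_symmetry(self):
        rng = np.random.default_rng(9)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aas, size=80).tolist())
        b = "".join(rng.choice(aas, size=95).tolist())
        assert pairwise_identity(a, a) == 1.0
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))
        assert 0.0 <= pairwise_identity(a, b) <= 1.0

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MKV")

    def test_shorter_sequence_denominator(self):
        # appending residues to one sequence cannot reduce the numerator,
        # and the denominator stays at the shorter length
        a = "MKVLHAGWQERTYIPASDFG"
        assert pairwise_identity(a, a + "AAAAA") == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_alignment_score_matches_gotoh_oracle(self, seed):
        rng = np.random.default_rng(seed)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aas, size=int(rng.integers(10, 30))).tolist())
        b = "".join(rng.choice(aas, size=int(rng.integers(10, 30))).tolist())
        from iskit.is_catalog import _ALIGNER

        assert _ALIGNER.score(a, b) == pytest.approx(gotoh_score(a, b))


def _cand(tag, start, translation):
    return TpaseCandidate(
        CdsFeature(tag, start, start + 3 * len(translation) + 2, "+",
                   "transposase", translation),
        "transposase",
    )


class TestClustering:
    def test_low_identity_pair_splits(self):
        rng = np.random.default_rng(2)
        ex = load_family_exemplars()["IS4"]
        a = _mutate_protein(ex, 0.80, rng)
        b = _mutate_protein(ex, 0.60, rng)  # a vs b well below 0.90
        clusters, _ = cluster_subtypes([_cand("A", 100, a), _cand("B", 5000, b)])
        assert len(clusters) == 2

    def test_high_identity_trio_merges(self):
        rng = np.random.default_rng(3)
        base = load_family_exemplars()["IS630"]
        members = [
            _cand(f"M{i}", 1000 * (i + 1), _mutate_protein(base, 0.99, np.random.default_rng(i)))
            for i in range(3)
        ]
        clusters, _ = cluster_subtypes(members)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_locus_tags) == ["M0", "M1", "M2"]

    def test_singleton(self):
        clusters, _ = cluster_subtypes([_cand("S", 10, "M" + "AGWQ" * 30)])
        assert len(clusters) == 1 and clusters[0].member_locus_tags == ["S"]

    def test_order_invariance_and_matrix_properties(self):
        rng = np.random.default_rng(7)
        ex = load_family_exemplars()["IS5"]
        cands = [
            _cand("X", 100, _mutate_protein(ex, 0.95, rng)),
            _cand("Y", 900, _mutate_protein(ex, 0.94, rng)),
            _cand("Z", 5000, "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200).tolist())),
        ]
        c1, _ = cluster_subtypes(cands)
        c2, _ = cluster_subtypes(cands[::-1])
        assert [sorted(c.member_locus_tags) for c in c1] == [sorted(c.member_locus_tags) for c in c2]
        for cl in c1:
            m = cl.identity_matrix
            assert np.allclose(m, m.T) and np.allclose(np.diag(m), 1.0)

    def test_missing_translation_reported_separately(self):
        c = TpaseCandidate(CdsFeature("NT", 10, 100, "+", "transposase"), "t")
        clusters, excluded = cluster_subtypes([c])
        assert clusters == [] and [e.feature.locus_tag for e in excluded] == ["NT"]


class TestAssignFamily:
    def test_exact_exemplar_match(self):
        ex = load_family_exemplars()
        clusters, _ = cluster_subtypes([_cand("A", 1, ex["IS4"])])
        assert assign_family(clusters[0], ex, ex["IS4"]) == "IS4"

    def test_remote_sequence_unclassified(self):
        ex = load_family_exemplars()
        rng = np.random.default_rng(0)
        junk = "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 300).tolist())
        clusters, _ = cluster_subtypes([_cand("A", 1, junk)])
        assert assign_family(clusters[0], ex, junk) == "unclassified"

    @pytest.mark.parametrize("family", ["IS1", "IS4", "IS5", "IS66", "IS630", "IS701"])
    def test_mutated_exemplars_recover_family(self, family):
        ex = load_family_exemplars()
        rng = np.random.default_rng(hash(family) % 2**31)
        mutant = _mutate_protein(ex[family], 0.40, rng)
        clusters, _ = cluster_subtypes([_cand("A", 1, mutant)])
        assert assign_family(clusters[0], ex, mutant) == family


class TestBuildCatalog:
    def test_planted_elements_recovered_exactly(self):
        g = synth_genome(n_genes=12, seed=21)
        specs = [DEFAULT_IS_SPECS[i] for i in (0, 1, 4, 5, 6)]  # long-TIR blueprints
        truths = []
        for i, spec in enumerate(specs):
            f = g.features[2 * i + 1]
            g, tr = plant_element(g, spec, locus=f.end + 60, seed=i)
            truths.append(tr)
        cat = build_catalog(g)
        assert cat.n_full == 5 and cat.n_partial == 0
        by_tag = {el.locus_tag: el for el in cat.elements}
        for tr in truths:
            el = by_tag[tr.locus_tag]
            assert el.element_span == tr.element_span
            assert el.tir.left_seq == tr.tir.left_seq
            assert (el.dr.sequence if el.dr else None) == (tr.dr.sequence if tr.dr else None)
            assert el.family == tr.family
        assert sum(cat.family_counts.values()) == len(cat.elements)

    def test_tpase_fragment_is_partial(self):
        from dataclasses import replace

        g = synth_genome(n_genes=6, seed=8)
        g, _ = plant_element(g, DEFAULT_IS_SPECS[0], locus=g.features[1].end + 50, seed=0)
        # declare an ordinary gene a transposase fragment: no TIRs around it
        feats = list(g.features)
        for i, f in enumerate(feats):
            if f.product == "hypothetical protein":
                feats[i] = replace(f, product="IS1 family transposase (fragment)")
                break
        g = replace(g, features=tuple(feats))
        cat = build_catalog(g)
        assert cat.n_full == 1 and cat.n_partial == 1
        partial = [el for el in cat.elements if el.completeness == "partial"][0]
        assert partial.tir is None and partial.dr is None

    def test_no_transposase_annotation_empty_catalog(self):
        g = synth_genome(n_genes=4, seed=2)
        cat = build_catalog(g)
        assert cat.elements == [] and cat.family_counts == {}

    def test_identical_copies_share_cluster_and_name(self):
        g = synth_genome(n_genes=10, seed=31)
        spec = DEFAULT_IS_SPECS[1]
        g, t1 = plant_element(g, spec, locus=g.features[1].end + 60, seed=0)
        g, t2 = plant_element(g, spec, locus=g.features[7].end + 60, seed=0)
        cat = build_catalog(g)
        assert len(cat.clusters) == 1
        assert len(cat.clusters[0].member_locus_tags) == 2
        names = {el.name for el in cat.elements}
        assert len(names) == 1

    def test_strand_symmetry(self):
        g = synth_genome(n_genes=8, seed=41)
        g, _ = plant_element(g, DEFAULT_IS_SPECS[0], locus=g.features[2].end + 60, seed=0)
        g, _ = plant_element(g, DEFAULT_IS_SPECS[1], locus=g.features[6].end + 60, seed=0)
        cat_f = build_catalog(g)
        cat_r = build_catalog(g.reverse_complement())
        L = len(g)
        fwd = sorted(el.element_span for el in cat_f.elements)
        rev_mapped = sorted((L - e + 1, L - s + 1) for s, e in
                            (el.element_span for el in cat_r.elements))
        assert fwd == rev_mapped
        assert cat_f.family_counts == cat_r.family_counts
        strands_f = sorted(el.tpase.feature.strand for el in cat_f.elements)
        strands_r = sorted({"+": "-", "-": "+"}[el.tpase.feature.strand] for el in cat_r.elements)
        assert strands_f == strands_r

    def test_exports(self, tmp_path, planted_catalog):
        import json

        import pandas as pd

        cat = planted_catalog
        cat.write_tsv(tmp_path / "cat.tsv", header_lines=["iskit test"])
        cat.write_gff3(tmp_path / "cat.gff3")
        cat.write_cluster_json(tmp_path / "cl.json")
        df = pd.read_csv(tmp_path / "cat.tsv", sep="\t", comment="#")
        assert list(df["name"]) == [el.name for el in cat.elements]
        doc = json.loads((tmp_path / "cl.json").read_text())
        assert doc["n_full"] == cat.n_full
        gff = (tmp_path / "cat.gff3").read_text().splitlines()
        assert gff[0] == "##gff-version 3"
        assert len(gff) == 1 + len(cat.elements)

    def test_config_validation(self):
        cfg = CatalogConfig(min_arm=0)
        with pytest.raises(ValueError):
            cfg.validate()
        cfg = CatalogConfig(subtype_threshold=1.5)
        with pytest.raises(ValueError):
            cfg.validate()
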