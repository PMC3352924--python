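"""Motif scanning, NBS localization, two-round search, domain typing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nbsarch.domains import (
    MotifHit,
    coiled_coil_scan,
    collapse_redundant,
    detect_lrr,
    iterative_search,
    iterative_search_detail,
    locate_nbs,
    nucleotide_identity,
    scan_motifs,
    type_n_terminal,
    DomainAnnotation,
)
from nbsarch.errors import InputError
from nbsarch.genemodel import ProteinRecord
from nbsarch.profiles import (
    AMINO_ACIDS,
    ANCHOR_MOTIFS,
    MOTIF_BLOCKS,
    MOTIF_ORDER,
    domain_template,
    nbs_anchor_spans,
    nbs_template,
)

_ORDER_INDEX = {name: i + 1 for i, name in enumerate(MOTIF_ORDER)}


def _hit(name, start, score=20.0):
    width = len(MOTIF_BLOCKS[name][0])
    return MotifHit(name, start, start + width, score, _ORDER_INDEX[name])


def _random_protein(length, seed):
    rng = np.random.default_rng(seed)
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))


class TestScanMotifs:
    def test_exact_exemplar_found_at_offset(self):
        prefix = _random_protein(30, 1)
        seq = prefix + MOTIF_BLOCKS["P-loop"][0] + _random_protein(30, 2)
        hits = [h for h in scan_motifs(seq) if h.name == "P-loop"]
        assert [h.start for h in hits] == [30]

    def test_random_sequence_has_no_hits(self):
        assert scan_motifs(_random_protein(200, 11)) == []

    def test_two_copies_give_two_hits(self):
        block = MOTIF_BLOCKS["P-loop"][0]
        seq = block + _random_protein(40, 3) + block
        hits = [h for h in scan_motifs(seq) if h.name == "P-loop"]
        assert [h.start for h in hits] == [0, 49]

    def test_empty_profile_list_rejected(self):
        with pytest.raises(InputError):
            scan_motifs("MKV", profiles=())

    def test_position_equivariance(self):
        """Prepending k residues shifts every hit start by exactly k."""
        k = 17
        base = nbs_template()
        shifted = "P" * k + base
        original = {(h.name, h.start) for h in scan_motifs(base)}
        moved = {(h.name, h.start - k) for h in scan_motifs(shifted)}
        assert original == moved


class TestLocateNbs:
    def test_anchor_chain_accepted(self):
        hits = [_hit("P-loop", 10), _hit("Kinase-2", 60), _hit("GLPL", 150)]
        nbs = locate_nbs(hits)
        assert nbs is not None
        assert nbs.start == 10
        assert nbs.end == 150 + len(MOTIF_BLOCKS["GLPL"][0])

    def test_wrong_order_rejected(self):
        hits = [_hit("GLPL", 10), _hit("P-loop", 150), _hit("Kinase-2", 200)]
        assert locate_nbs(hits) is None

    def test_missing_anchor_rejected(self):
        assert locate_nbs([_hit("P-loop", 10)]) is None

    @given(st.lists(st.sampled_from(MOTIF_ORDER), max_size=8), st.integers(0, 10_000))
    def test_never_violates_canonical_order(self, names, seed):
        """Brute-force check: any returned chain has anchors present and the
        best-per-motif hits in strictly increasing canonical order."""
        rng = np.random.default_rng(seed)
        hits = [
            _hit(name, int(rng.integers(0, 300)), float(rng.integers(15, 40)))
            for name in names
        ]
        result = locate_nbs(hits)
        best = {}
        for hit in hits:
            cur = best.get(hit.name)
            if cur is None or (hit.score, -hit.start) > (cur.score, -cur.start):
                best[hit.name] = hit
        anchors = sorted(
            (best[m] for m in ANCHOR_MOTIFS if m in best),
            key=lambda h: h.order_index,
        )
        expected_some = len(anchors) == 3 and all(
            a.start < b.start for a, b in zip(anchors, anchors[1:])
        )
        assert (result is not None) == expected_some


class TestIterativeSearch:
    def test_low_divergence_family_found_in_round_one(self):
        from nbsarch.profiles import _mutate

        rng = np.random.default_rng(0)
        proteome = [
            ProteinRecord(f"g{i}", _mutate(nbs_template(), 0.05, rng))
            for i in range(10)
        ]
        detail = iterative_search_detail(proteome, seed=1, n_shuffles=300)
        assert detail.round1 == [f"g{i}" for i in range(10)]

    def test_zero_expectation_threshold_returns_nothing(self):
        proteome = [ProteinRecord("g", nbs_template())]
        assert iterative_search(proteome, e_threshold=0.0, n_shuffles=100) == []

    def test_divergent_subfamily_recovered_in_round_two(self):
        """A subfamily sharing lineage-specific anchor variants scores below
        the seed threshold but above the adapted one after refinement."""
        spans = nbs_anchor_spans()

        def variant(seq, positions, shift):
            out = list(seq)
            for name in ("P-loop", "Kinase-2", "GLPL"):
                start, _ = spans[name]
                for p in positions:
                    i = start + p
                    out[i] = AMINO_ACIDS[
                        (AMINO_ACIDS.index(out[i]) + shift) % 20
                    ]
            return "".join(out)

        lineage = variant(nbs_template(), [1, 4, 7], shift=1)
        divergent = variant(lineage, [2, 5, 6], shift=3)
        proteome = [ProteinRecord(f"main{i}", lineage) for i in range(6)] + [
            ProteinRecord(f"div{i}", divergent) for i in range(3)
        ]
        detail = iterative_search_detail(proteome, seed=0, n_shuffles=300)
        assert all(g.startswith("main") for g in detail.round1)
        assert {"div0", "div1", "div2"} <= set(detail.accepted)
        # query refinement never loses a round-1 gene
        assert set(detail.round1) <= set(detail.accepted)

    def test_empty_proteome_rejected(self):
        with pytest.raises(InputError):
            iterative_search([])


class TestCoiledCoil:
    def test_heptad_repeats_detected(self):
        assert coiled_coil_scan("LQELEKE" * 5) is not None

    def test_polyproline_not_detected(self):
        assert coiled_coil_scan("P" * 40) is None

    def test_threshold_one_never_met(self):
        assert coiled_coil_scan("LQELEKE" * 5, threshold=1.0) is None

    def test_short_sequence_skipped(self):
        assert coiled_coil_scan("LQELEKE", window=28) is None


class TestTypeNTerminal:
    @pytest.mark.parametrize("kind", ["TIR", "PK", "HYDROLASE"])
    def test_template_typed_correctly(self, kind):
        seq = domain_template(kind) + nbs_template()
        nbs = DomainAnnotation("NBS", len(domain_template(kind)), len(seq), 1.0, "")
        assert type_n_terminal(seq, nbs) == kind

    def test_cc_template_typed_cc(self):
        seq = domain_template("CC") * 2 + nbs_template()
        nbs = DomainAnnotation("NBS", 112, len(seq), 1.0, "")
        assert type_n_terminal(seq, nbs) == "CC"

    def test_tiny_region_is_none(self):
        seq = "MKVAE" + nbs_template()
        nbs = DomainAnnotation("NBS", 5, len(seq), 1.0, "")
        assert type_n_terminal(seq, nbs) == "NONE"

    def test_no_region_is_none(self):
        nbs = DomainAnnotation("NBS", 0, 100, 1.0, "")
        assert type_n_terminal(nbs_template(), nbs) == "NONE"


class TestDetectLrr:
    def test_six_repeats_after_nbs_detected(self):
        nbs_seq = nbs_template()
        seq = nbs_seq + "LRELNLSGN" * 6
        nbs = DomainAnnotation("NBS", 0, len(nbs_seq), 1.0, "")
        ann = detect_lrr(seq, nbs)
        assert ann is not None
        assert ann.start == len(nbs_seq)

    def test_two_repeats_not_enough(self):
        nbs_seq = nbs_template()
        seq = nbs_seq + "LRELNLSGN" * 2 + "PPPPPPPP"
        nbs = DomainAnnotation("NBS", 0, len(nbs_seq), 1.0, "")
        assert detect_lrr(seq, nbs) is None

    def test_repeats_before_nbs_ignored(self):
        nbs_seq = nbs_template()
        seq = "LRELNLSGN" * 6 + nbs_seq
        nbs = DomainAnnotation("NBS", 54, 54 + len(nbs_seq), 1.0, "")
        assert detect_lrr(seq, nbs) is None


class TestCollapseRedundant:
    def test_identical_pair_collapses(self):
        assert collapse_redundant({"a": "ATGCATGC" * 10, "b": "ATGCATGC" * 10}) == ["a"]

    def test_ninety_percent_identity_stays_separate(self):
        rng = np.random.default_rng(5)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        b = list(a)
        for pos in range(0, 100, 10):  # 10 substitutions -> 90% identity
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        b = "".join(b)
        assert nucleotide_identity(a, b) < 0.97
        assert len(collapse_redundant({"a": a, "b": b})) == 2

    def test_single_linkage_chains_transitively(self):
        rng = np.random.default_rng(6)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))

        def subs(seq, positions):
            out = list(seq)
            for pos in positions:
                out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
            return "".join(out)

        b = subs(a, range(0, 4))  # 2% from a
        c = subs(b, range(100, 104))  # 2% from b, 4% from a
        assert nucleotide_identity(a, c) < 0.97 <= nucleotide_identity(a, b)
        assert len(collapse_redundant({"a": a, "b": b, "c": c})) == 1

    def test_representative_is_longest(self):
        seqs = {"short": "ATGC" * 25, "long": "ATGC" * 25 + "AT"}
        assert collapse_redundant(seqs) == ["long"]
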