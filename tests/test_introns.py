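"""Intron offsets, phases, region labels and class signatures."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nbsarch.domains import DomainAnnotation
from nbsarch.errors import InputError
from nbsarch.genemodel import GeneModel
from nbsarch.introns import (
    CLASS_SIGNATURES,
    IntronRecord,
    Region,
    conserved_introns,
    intron_offsets,
    intron_phase,
    intron_records,
    label_region,
    match_signature,
)
from nbsarch.pipeline import run_survey
from nbsarch.simulate import SyntheticFamilySpec, make_family


def _gene_with_lengths(lengths, strand="+", start=1):
    segments = []
    pos = start
    for length in lengths:
        segments.append((pos, pos + length - 1))
        pos += length + 50  # 50 nt introns
    if strand == "-":
        segments = segments[::-1]
    return GeneModel("g", "s", strand, tuple(segments))


class TestIntronOffsets:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([12], []), ([9, 6], [9]), ([7, 5, 9], [7, 12])],
        ids=["intronless", "two-exon", "three-exon"],
    )
    def test_cumulative_lengths(self, lengths, expected):
        assert intron_offsets(_gene_with_lengths(lengths)) == expected

    def test_exon_length_sum_property(self):
        lengths = [13, 22, 7, 31]
        gene = _gene_with_lengths(lengths)
        offsets = intron_offsets(gene)
        assert max(offsets) + lengths[-1] == sum(lengths)

    def test_strand_invariance(self):
        """A gene and its minus-strand mirror have identical intron records."""
        plus = _gene_with_lengths([14, 22, 9], "+")
        scaffold_len = 500
        mirror_segments = tuple(
            (scaffold_len - end + 1, scaffold_len - start + 1)
            for start, end in plus.cds_segments
        )
        minus = GeneModel("g", "s", "-", mirror_segments)
        assert intron_records(plus) == intron_records(minus)


class TestIntronPhase:
    @pytest.mark.parametrize("offset,phase", [(300, 0), (301, 1), (299, 2)])
    def test_examples(self, offset, phase):
        assert intron_phase(offset) == phase

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            intron_phase(-1)

    def test_agrees_with_codon_counting_oracle(self):
        """Brute-force oracle: strip complete codons 5' of the junction and
        count the leftover bases."""

        def oracle(offset):
            remaining = offset
            while remaining >= 3:
                remaining -= 3
            return remaining

        rng = np.random.default_rng(123)
        offsets = rng.integers(0, 100_000, size=10_000)
        assert all(intron_phase(int(o)) == oracle(int(o)) for o in offsets)


_DOMAINS = [
    DomainAnnotation("PK", 10, 150, 50.0, "PK profile"),
    DomainAnnotation("NBS", 160, 420, 90.0, "chain"),
    DomainAnnotation("LRR", 430, 520, 6.0, "LRR repeat count"),
]


def _intron_at(pos, phase=0):
    return IntronRecord(0, 3 * pos + phase, phase, pos)


class TestLabelRegion:
    @pytest.mark.parametrize(
        "pos,region",
        [
            (80, Region.WITHIN_NTERM),
            (155, Region.NTERM_NBS_BOUNDARY),  # midway PK end / NBS start
            (300, Region.WITHIN_NBS),
            (425, Region.NBS_LRR_BOUNDARY),
            (470, Region.WITHIN_LRR),
            (570, Region.OTHER),  # 50 residues past the LRR end
        ],
    )
    def test_examples(self, pos, region):
        assert label_region(_intron_at(pos), _DOMAINS) == region

    def test_requires_nbs(self):
        with pytest.raises(InputError):
            label_region(_intron_at(5), [_DOMAINS[0]])


class TestMatchSignature:
    def test_tnl_fingerprint(self):
        introns = [
            IntronRecord(0, 2, 2, 0, Region.NTERM_NBS_BOUNDARY),
            IntronRecord(1, 900, 0, 300, Region.NBS_LRR_BOUNDARY),
        ]
        assert match_signature(introns, CLASS_SIGNATURES["TNL"])
        assert not match_signature(introns, CLASS_SIGNATURES["PNL"])
        assert not match_signature(introns, CLASS_SIGNATURES["CNL"])

    def test_cnl_is_absence_of_boundary_introns(self):
        no_boundary = [IntronRecord(0, 301, 1, 100, Region.WITHIN_NBS)]
        assert match_signature(no_boundary, CLASS_SIGNATURES["CNL"])
        assert match_signature([], CLASS_SIGNATURES["CNL"])
        boundary = [IntronRecord(0, 300, 0, 100, Region.NTERM_NBS_BOUNDARY)]
        assert not match_signature(boundary, CLASS_SIGNATURES["CNL"])

    def test_generator_round_trip_zero_divergence(self, zero_divergence_families):
        """Each class's zero-divergence genes match their own fingerprint;
        cross-matches only where one required set contains another (the HNL
        fingerprint strictly extends the PNL one)."""
        for cls, family in zero_divergence_families.items():
            result = run_survey(
                family.genome, family.genes, seed=0, n_shuffles=200
            )
            for gene_id in result.accepted:
                introns = result.introns[gene_id]
                assert match_signature(introns, CLASS_SIGNATURES[cls]), cls
                for other in CLASS_SIGNATURES:
                    if other == cls or (cls, other) == ("HNL", "PNL"):
                        continue
                    assert not match_signature(
                        introns, CLASS_SIGNATURES[other]
                    ), (cls, other)


class TestConservedIntrons:
    def test_hnl_family_has_three_conserved_phase0_locations(self):
        spec = SyntheticFamilySpec("HNL", {"HNL": 10}, divergence=0.2, seed=21)
        family = make_family(spec)
        result = run_survey(family.genome, family.genes, seed=1, n_shuffles=300)
        nbs_starts = {
            g: next(d for d in result.domains[g] if d.kind == "NBS").start
            for g in result.accepted
        }
        found = conserved_introns(
            [(g, result.introns[g]) for g in result.accepted],
            nbs_starts=nbs_starts,
        )
        assert len(found) == 3
        assert all(phase == 0 for _, phase, _ in found)

    def test_intronless_family_reports_nothing(self):
        family = [("a", []), ("b", [])]
        assert conserved_introns(family) == []

    def test_support_below_threshold_excluded(self):
        family = [(f"g{i}", [_intron_at(100)]) for i in range(7)]
        family += [(f"g{i}", []) for i in range(7, 10)]
        assert conserved_introns(family, min_fraction=0.8) == []
        assert len(conserved_introns(family, min_fraction=0.7)) == 1


@given(st.integers(0, 2**31 - 1))
def test_phase_matches_record_invariant(seed):
    """phase == cds_offset % 3 and protein_pos == cds_offset // 3 for the
    records produced from arbitrary exon structures."""
    rng = np.random.default_rng(seed)
    lengths = rng.integers(3, 500, size=rng.integers(2, 6)).tolist()
    gene = _gene_with_lengths(lengths)
    for rec in intron_records(gene):
        assert rec.phase == rec.cds_offset % 3
        assert rec.protein_pos == rec.cds_offset // 3
        assert 0 < rec.cds_offset < sum(lengths)
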