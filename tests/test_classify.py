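"""Architecture strings, the classification cascade, survey tabulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nbsarch.classify import (
    PPATENS_SURVEY,
    ClassCall,
    SurveyTable,
    architecture_string,
    assign_class,
    intact_count,
    tabulate,
)
from nbsarch.domains import DomainAnnotation, protein_identity
from nbsarch.errors import InputError, ValidationError
from nbsarch.introns import IntronRecord, Region
from nbsarch.profiles import _mutate
from nbsarch.simulate import class_nbs_founder


def _domains(*kinds):
    out = []
    pos = 0
    for kind in kinds:
        width = 260 if kind == "NBS" else 120
        out.append(DomainAnnotation(kind, pos, pos + width, 50.0, "test"))
        pos += width + 10
    return out


class TestArchitectureString:
    @pytest.mark.parametrize(
        "kinds,form",
        [
            (("PK", "NBS", "LRR"), "PNL"),
            (("NBS",), "N"),
            (("TIR", "NBS"), "TN"),
            (("CC", "NBS", "LRR"), "CNL"),
            (("HYDROLASE", "NBS"), "HN"),
            (("NBS", "LRR"), "NL"),
        ],
    )
    def test_forms(self, kinds, form):
        assert architecture_string(_domains(*kinds)) == form

    def test_requires_nbs(self):
        with pytest.raises(InputError):
            architecture_string(_domains("PK", "LRR"))


class TestAssignClass:
    def test_nterm_domain_decides_class(self):
        call = assign_class("g", _domains("PK", "NBS", "LRR"), [])
        assert (call.class_name, call.form, call.evidence) == (
            "PNL",
            "PNL",
            "ARCHITECTURE",
        )

    def test_truncation_classified_by_nbs_similarity(self):
        founder = class_nbs_founder("PNL")
        rng = np.random.default_rng(3)
        query = _mutate(founder, 0.15, rng)  # ~85% identity to the reference
        assert protein_identity(query, founder) > 0.40
        domains = [DomainAnnotation("NBS", 0, len(query), 80.0, "chain")]
        call = assign_class(
            "g",
            domains,
            [],
            references={"PNL": [founder], "TNL": [class_nbs_founder("TNL")]},
            protein=query,
        )
        assert (call.class_name, call.form, call.evidence) == (
            "PNL",
            "N",
            "NBS_SIMILARITY",
        )

    def test_intron_signature_rescues_divergent_gene(self):
        """A gene below the similarity threshold but carrying the phase-2
        boundary intron (plus the shared phase-0 NBS/LRR boundary intron)
        lands in the TNL class through the intron channel."""
        introns = [
            IntronRecord(0, 29, 2, 9, Region.NTERM_NBS_BOUNDARY),
            IntronRecord(1, 900, 0, 300, Region.NBS_LRR_BOUNDARY),
        ]
        call = assign_class("g", _domains("NBS"), introns, references={})
        assert (call.class_name, call.evidence) == ("TNL", "INTRON_SIGNATURE")

    def test_hnl_fingerprint_beats_its_pnl_subset(self):
        introns = [
            IntronRecord(0, 150, 0, 50, Region.WITHIN_NTERM),
            IntronRecord(1, 450, 0, 150, Region.NTERM_NBS_BOUNDARY),
            IntronRecord(2, 1500, 0, 500, Region.NBS_LRR_BOUNDARY),
        ]
        call = assign_class("g", _domains("NBS"), introns, references={})
        assert call.class_name == "HNL"

    def test_cascade_precedence(self):
        """When the N-terminal domain fires, later channels cannot change
        the call, whatever references or introns say."""
        domains = _domains("TIR", "NBS", "LRR")
        confusing_refs = {"PNL": [class_nbs_founder("PNL")]}
        introns = [IntronRecord(0, 450, 0, 150, Region.NTERM_NBS_BOUNDARY)]
        call = assign_class(
            "g", domains, introns, confusing_refs, protein="A" * 700
        )
        assert (call.class_name, call.evidence) == ("TNL", "ARCHITECTURE")

    def test_unclassifiable_gene(self):
        introns = [
            IntronRecord(0, 29, 2, 9, Region.NTERM_NBS_BOUNDARY),
            IntronRecord(1, 31, 1, 10, Region.NTERM_NBS_BOUNDARY),
        ]
        # boundary introns of both phases: no signature matches uniquely
        call = assign_class("g", _domains("NBS"), introns, references={})
        assert call.class_name == "UNCLASSIFIED"
        assert call.evidence is None


def _calls_from_counts(counts):
    calls = []
    for (cls, form), n in counts.items():
        for i in range(n):
            calls.append(ClassCall(f"{cls}_{form}_{i}", cls, form, "ARCHITECTURE"))
    return calls


class TestTabulate:
    def test_survey_table_arithmetic(self):
        table = tabulate(_calls_from_counts(PPATENS_SURVEY))
        assert table.class_totals == {"TNL": 9, "PNL": 45, "CNL": 11}
        assert table.grand_total == 65
        assert intact_count(table) == 18

    def test_empty_input_gives_zero_table(self):
        table = tabulate([])
        assert table.grand_total == 0
        assert intact_count(table) == 0

    def test_duplicate_gene_ids_rejected(self):
        call = ClassCall("g1", "PNL", "PN", "ARCHITECTURE")
        with pytest.raises(ValidationError, match="duplicate"):
            tabulate([call, call])

    def test_two_domain_forms_not_intact(self):
        table = SurveyTable.from_counts({("PNL", "PN"): 7})
        assert intact_count(table) == 0

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["TNL", "PNL", "CNL", "HNL", "UNCLASSIFIED"]),
                st.sampled_from(["TNL", "PNL", "CNL", "HNL", "TN", "PN", "CN", "HN", "NL", "N"]),
            ),
            max_size=60,
        )
    )
    def test_totals_invariants(self, pairs):
        """Class totals sum the per-form counts; the grand total sums the
        class totals; UNCLASSIFIED never enters either."""
        calls = [
            ClassCall(f"g{i}", cls, form, None if cls == "UNCLASSIFIED" else "ARCHITECTURE")
            for i, (cls, form) in enumerate(pairs)
        ]
        table = tabulate(calls)
        assert sum(table.counts.values()) == table.grand_total
        for cls, total in table.class_totals.items():
            assert total == sum(
                n for (c, _), n in table.counts.items() if c == cls
            )
        n_unclassified = sum(1 for c in calls if c.class_name == "UNCLASSIFIED")
        assert table.unclassified == n_unclassified
        assert table.grand_total == len(calls) - n_unclassified


class TestClassCallInvariants:
    def test_form_must_contain_nbs(self):
        with pytest.raises(ValidationError):
            ClassCall("g", "PNL", "PL", "ARCHITECTURE")

    def test_classified_call_needs_evidence(self):
        with pytest.raises(ValidationError):
            ClassCall("g", "PNL", "PNL", None)
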