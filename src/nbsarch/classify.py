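"""Class assignment and survey tabulation.

Each NBS-positive gene receives a class (TNL / CNL / PNL / HNL) and an
architecture form — the string of present domains in N-to-C order, e.g.
"PNL" for protein-kinase + NBS + LRR, "PN" for a gene lacking the LRR, "N"
for an NBS-only fragment.  Classification is a fixed-precedence cascade:

1. ARCHITECTURE — a recognizable N-terminal domain determines the class
   directly (TIR -> TNL, PK -> PNL, hydrolase -> HNL, coiled-coil -> CNL);
2. NBS_SIMILARITY — otherwise the NBS domain is globally aligned to every
   classified reference and takes the class of the best hit when identity
   reaches the similarity threshold (default 0.40);
3. INTRON_SIGNATURE — otherwise a uniquely matching class intron fingerprint
   decides;
4. UNCLASSIFIED.

Pseudogenes (internal stop codon) are classified from their conceptual
translation, with stops treated as wildcards, and flagged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .domains import DomainAnnotation, protein_identity
from .errors import InputError, ValidationError
from .introns import CLASS_SIGNATURES, IntronRecord, match_signature

__all__ = [
    "CLASS_OF_NTERM",
    "NTERM_LETTER",
    "ClassCall",
    "SurveyTable",
    "architecture_string",
    "assign_class",
    "tabulate",
    "intact_count",
    "PPATENS_SURVEY",
    "calls_to_frame",
]

CLASS_OF_NTERM = {"TIR": "TNL", "PK": "PNL", "HYDROLASE": "HNL", "CC": "CNL"}
NTERM_LETTER = {"TIR": "T", "PK": "P", "HYDROLASE": "H", "CC": "C"}

CLASS_NAMES = ("TNL", "PNL", "CNL", "HNL")

#: Per-form gene counts reported for the Physcomitrella patens genome survey
#: (reference input for the tabulation arithmetic; UNCLASSIFIED absent).
PPATENS_SURVEY: dict[tuple[str, str], int] = {
    ("TNL", "TNL"): 3,
    ("TNL", "TN"): 0,
    ("TNL", "NL"): 5,
    ("TNL", "N"): 1,
    ("PNL", "PNL"): 6,
    ("PNL", "PN"): 18,
    ("PNL", "NL"): 2,
    ("PNL", "N"): 19,
    ("CNL", "CNL"): 9,
    ("CNL", "CN"): 2,
    ("CNL", "NL"): 0,
    ("CNL", "N"): 0,
}

#: Form mixture used for synthetic HNL families, patterned on the liverwort
#: survey: 36 HNL-class genes of which at least three are intact and several
#: more retain only the N-terminal hydrolase domain.
MPOLYMORPHA_HNL: dict[tuple[str, str], int] = {
    ("HNL", "HNL"): 3,
    ("HNL", "HN"): 6,
    ("HNL", "N"): 27,
}


@dataclass(frozen=True)
class ClassCall:
    gene_id: str
    class_name: str
    form: str
    evidence: str | None
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if "N" not in self.form:
            raise ValidationError(f"{self.gene_id}: form {self.form!r} lacks N")
        if self.class_name != "UNCLASSIFIED" and not self.evidence:
            raise ValidationError(f"{self.gene_id}: classified call needs evidence")


@dataclass
class SurveyTable:
    """Class-by-architecture count table with totals."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    unclassified: int = 0

    @property
    def class_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for (cls, _), n in self.counts.items():
            totals[cls] = totals.get(cls, 0) + n
        return totals

    @property
    def grand_total(self) -> int:
        return sum(self.class_totals.values())

    @classmethod
    def from_counts(cls, counts: Mapping[tuple[str, str], int]) -> "SurveyTable":
        return cls(counts=dict(counts))

    def to_frame(self) -> pd.DataFrame:
        totals = self.class_totals
        rows = [
            {"class": c, "form": f, "count": n, "class_total": totals[c]}
            for (c, f), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["class", "form", "count", "class_total"])


def architecture_string(domains: Sequence[DomainAnnotation]) -> str:
    """Domain-letter form in N-to-C order (e.g. "PNL", "TN", "N")."""
    if not any(d.kind == "NBS" for d in domains):
        raise InputError("architecture requires an NBS annotation")
    letters = []
    nterm = next((d for d in domains if d.kind in NTERM_LETTER), None)
    if nterm is not None:
        letters.append(NTERM_LETTER[nterm.kind])
    letters.append("N")
    if any(d.kind == "LRR" for d in domains):
        letters.append("L")
    return "".join(letters)


def _similarity_class(
    nbs_seq: str,
    references: Mapping[str, Sequence[str]],
    threshold: float,
) -> tuple[str | None, float]:
    """Best class by global NBS identity; ties resolved to None (never guess)."""
    best: list[tuple[float, str]] = []
    for cls, seqs in references.items():
        for ref in seqs:
            best.append((protein_identity(nbs_seq, ref), cls))
    if not best:
        return None, 0.0
    best.sort(key=lambda t: -t[0])
    top_identity, top_class = best[0]
    if top_identity < threshold:
        return None, top_identity
    rivals = {cls for ident, cls in best if ident == top_identity}
    if len(rivals) > 1:
        return None, top_identity
    return top_class, top_identity


def assign_class(
    gene_id: str,
    domains: Sequence[DomainAnnotation],
    introns: Sequence[IntronRecord],
    references: Mapping[str, Sequence[str]] | None = None,
    *,
    protein: str | None = None,
    similarity_threshold: float = 0.40,
    pseudogene: bool = False,
) -> ClassCall:
    """Run the classification cascade for one NBS-positive gene.

    ``references`` maps class name to classified NBS-domain sequences;
    ``protein`` is needed for the similarity channel (to slice out the NBS).
    """
    form = architecture_string(domains)
    nterm = next((d for d in domains if d.kind in CLASS_OF_NTERM), None)
    if nterm is not None:
        return ClassCall(
            gene_id, CLASS_OF_NTERM[nterm.kind], form, "ARCHITECTURE", pseudogene
        )
    if references and protein:
        nbs = next(d for d in domains if d.kind == "NBS")
        cls, _ = _similarity_class(
            protein[nbs.start : nbs.end], references, similarity_threshold
        )
        if cls is not None:
            return ClassCall(gene_id, cls, form, "NBS_SIMILARITY", pseudogene)
    matching = [
        name
        for name, sig in CLASS_SIGNATURES.items()
        if match_signature(introns, sig)
    ]
    if len(matching) > 1:
        # prefer the most specific fingerprint (largest required set); the
        # HNL fingerprint strictly extends the PNL one, so a gene carrying
        # all three HNL introns also satisfies PNL's requirements
        most = max(len(CLASS_SIGNATURES[m].required) for m in matching)
        matching = [
            m for m in matching if len(CLASS_SIGNATURES[m].required) == most
        ]
    if len(matching) == 1:
        return ClassCall(gene_id, matching[0], form, "INTRON_SIGNATURE", pseudogene)
    return ClassCall(gene_id, "UNCLASSIFIED", form, None, pseudogene)


def tabulate(calls: Iterable[ClassCall]) -> SurveyTable:
    """Count calls per (class, form); UNCLASSIFIED kept out of class totals."""
    calls = list(calls)
    ids = Counter(c.gene_id for c in calls)
    dupes = [g for g, n in ids.items() if n > 1]
    if dupes:
        raise ValidationError(f"duplicate gene ids in call list: {dupes[:5]}")
    table = SurveyTable()
    for call in calls:
        if call.class_name == "UNCLASSIFIED":
            table.unclassified += 1
            continue
        key = (call.class_name, call.form)
        table.counts[key] = table.counts.get(key, 0) + 1
    return table


def intact_count(table: SurveyTable) -> int:
    """Genes with all three domains present (three-letter forms)."""
    return sum(n for (_, form), n in table.counts.items() if len(form) == 3)


def calls_to_frame(calls: Iterable[ClassCall]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "class": c.class_name,
            "form": c.form,
            "evidence": c.evidence or "",
            "pseudogene": c.pseudogene,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "class", "form", "evidence", "pseudogene"]
    )
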