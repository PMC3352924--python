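"""End-to-end survey driver: genome + gene models -> classified survey table.

Orchestrates the module chain: spliced-CDS translation, two-round NBS motif
search, domain annotation, intron labeling, reference building from
architecture-classified genes, cascade classification, and tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .classify import (
    CLASS_OF_NTERM,
    ClassCall,
    SurveyTable,
    assign_class,
    tabulate,
)
from .domains import DomainAnnotation, annotate_protein, iterative_search_detail
from .genemodel import GeneModel, ProteinRecord, spliced_cds, translate
from .introns import IntronRecord, intron_records

__all__ = ["SurveyResult", "run_survey", "build_references"]


@dataclass
class SurveyResult:
    calls: list[ClassCall]
    table: SurveyTable
    accepted: list[str]
    proteins: dict[str, ProteinRecord] = field(repr=False)
    domains: dict[str, list[DomainAnnotation]] = field(repr=False)
    introns: dict[str, list[IntronRecord]] = field(repr=False)
    references: dict[str, list[str]] = field(repr=False)


def build_references(
    proteins: Mapping[str, ProteinRecord],
    domains: Mapping[str, Sequence[DomainAnnotation]],
    max_per_class: int = 5,
) -> dict[str, list[str]]:
    """NBS-domain sequences of genes classified by their N-terminal domain.

    These architecture-anchored genes serve as the reference panel for the
    similarity channel; at most ``max_per_class`` per class, longest first.
    """
    refs: dict[str, list[str]] = {}
    for gene_id, anns in domains.items():
        nterm = next((d for d in anns if d.kind in CLASS_OF_NTERM), None)
        nbs = next((d for d in anns if d.kind == "NBS"), None)
        if nterm is None or nbs is None:
            continue
        seq = proteins[gene_id].sequence[nbs.start : nbs.end].replace("*", "X")
        refs.setdefault(CLASS_OF_NTERM[nterm.kind], []).append(seq)
    return {
        cls: sorted(seqs, key=lambda s: (-len(s), s))[:max_per_class]
        for cls, seqs in refs.items()
    }


def run_survey(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    *,
    seed: int = 0,
    e_threshold: float = 1.0,
    cc_threshold: float = 0.9,
    similarity_threshold: float = 0.40,
    boundary_slack: int = 10,
    max_refs_per_class: int = 5,
    n_shuffles: int = 1000,
) -> SurveyResult:
    """Run the full survey on an annotated genome."""
    gene_index = {g.gene_id: g for g in genes}
    proteins = {
        g.gene_id: translate(spliced_cds(g, genome), g.gene_id) for g in genes
    }
    search = iterative_search_detail(
        list(proteins.values()),
        e_threshold=e_threshold,
        seed=seed,
        n_shuffles=n_shuffles,
    )
    domains: dict[str, list[DomainAnnotation]] = {}
    introns: dict[str, list[IntronRecord]] = {}
    for gene_id in search.accepted:
        anns = annotate_protein(
            proteins[gene_id], search.hits[gene_id], cc_threshold=cc_threshold
        )
        domains[gene_id] = anns
        introns[gene_id] = intron_records(
            gene_index[gene_id], anns, boundary_slack=boundary_slack
        )
    references = build_references(proteins, domains, max_refs_per_class)
    calls = [
        assign_class(
            gene_id,
            domains[gene_id],
            introns[gene_id],
            references,
            protein=proteins[gene_id].sequence,
            similarity_threshold=similarity_threshold,
            pseudogene=proteins[gene_id].has_internal_stop,
        )
        for gene_id in search.accepted
    ]
    return SurveyResult(
        calls=calls,
        table=tabulate(calls),
        accepted=search.accepted,
        proteins=proteins,
        domains=domains,
        introns=introns,
        references=references,
    )
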