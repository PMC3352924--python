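"""Intron positions and phases on the spliced CDS, and class signatures.

Intron phase follows the standard codon-relative definition: phase 0 introns
fall before the first base of a codon, phase 1 after the first base, phase 2
after the second.  Because offsets are taken on the spliced CDS (not genomic
coordinates), phase and protein position are strand-free.

The four NBS-gene classes carry distinctive intron fingerprints:

* TNL — an intron at the TIR/NBS boundary, phase 2, plus a phase-0 intron at
  the NBS/LRR boundary;
* PNL — an intron at the PK/NBS boundary, phase 0, plus a phase-0 NBS/LRR
  boundary intron;
* HNL — three conserved phase-0 locations: one inside the hydrolase domain,
  one at the hydrolase/NBS boundary, one at the NBS/LRR boundary;
* CNL — no conserved domain-boundary introns at all (its distinguishing
  character is the absence).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import StrEnum
from typing import Iterable, Sequence

import pandas as pd

from .domains import DomainAnnotation
from .errors import InputError
from .genemodel import GeneModel

__all__ = [
    "Region",
    "IntronRecord",
    "ClassSignature",
    "CLASS_SIGNATURES",
    "intron_offsets",
    "intron_phase",
    "label_region",
    "intron_records",
    "match_signature",
    "conserved_introns",
    "introns_to_frame",
]


class Region(StrEnum):
    WITHIN_NTERM = "WITHIN_NTERM"
    NTERM_NBS_BOUNDARY = "NTERM_NBS_BOUNDARY"
    WITHIN_NBS = "WITHIN_NBS"
    NBS_LRR_BOUNDARY = "NBS_LRR_BOUNDARY"
    WITHIN_LRR = "WITHIN_LRR"
    OTHER = "OTHER"


@dataclass(frozen=True)
class IntronRecord:
    """One intron, located on the spliced CDS.

    ``cds_offset`` is the 0-based offset of the first base after the intron;
    ``phase == cds_offset % 3`` and ``protein_pos == cds_offset // 3`` by
    construction.
    """

    index: int
    cds_offset: int
    phase: int
    protein_pos: int
    region: Region = Region.OTHER


@dataclass(frozen=True)
class ClassSignature:
    class_name: str
    required: tuple[tuple[Region, int], ...]
    forbidden_boundary_introns: bool = False


#: Class-specific intron fingerprints (see module docstring).
CLASS_SIGNATURES: dict[str, ClassSignature] = {
    "TNL": ClassSignature(
        "TNL",
        ((Region.NTERM_NBS_BOUNDARY, 2), (Region.NBS_LRR_BOUNDARY, 0)),
    ),
    "PNL": ClassSignature(
        "PNL",
        ((Region.NTERM_NBS_BOUNDARY, 0), (Region.NBS_LRR_BOUNDARY, 0)),
    ),
    "HNL": ClassSignature(
        "HNL",
        (
            (Region.WITHIN_NTERM, 0),
            (Region.NTERM_NBS_BOUNDARY, 0),
            (Region.NBS_LRR_BOUNDARY, 0),
        ),
    ),
    "CNL": ClassSignature("CNL", (), forbidden_boundary_introns=True),
}


def intron_offsets(gene: GeneModel) -> list[int]:
    """Spliced-CDS offsets of the introns: cumulative segment lengths."""
    lengths = gene.segment_lengths
    offsets, total = [], 0
    for length in lengths[:-1]:
        total += length
        offsets.append(total)
    return offsets


def intron_phase(cds_offset: int) -> int:
    """Phase of an intron at a spliced-CDS offset (offset mod 3)."""
    if cds_offset < 0:
        raise InputError(f"negative CDS offset {cds_offset}")
    return cds_offset % 3


def label_region(
    intron: IntronRecord,
    domains: Sequence[DomainAnnotation],
    boundary_slack: int = 10,
) -> Region:
    """Locate an intron relative to the domain architecture.

    A position inside a domain interval labels WITHIN_*; a position within
    ``boundary_slack`` residues of the NBS start (outside any domain) labels
    NTERM_NBS_BOUNDARY, and analogously NBS_LRR_BOUNDARY around the NBS end.
    """
    nbs = next((d for d in domains if d.kind == "NBS"), None)
    if nbs is None:
        raise InputError("domain list lacks an NBS annotation")
    pos = intron.protein_pos
    nterm = next(
        (d for d in domains if d.kind in {"TIR", "CC", "PK", "HYDROLASE"}), None
    )
    lrr = next((d for d in domains if d.kind == "LRR"), None)
    if nterm is not None and nterm.start <= pos < nterm.end:
        return Region.WITHIN_NTERM
    if nbs.start <= pos < nbs.end:
        return Region.WITHIN_NBS
    if lrr is not None and lrr.start <= pos < lrr.end:
        return Region.WITHIN_LRR
    # boundary zones: the inter-domain gap widened by the slack on both sides
    nterm_gap_lo = nterm.end if nterm is not None else nbs.start - boundary_slack
    if nterm_gap_lo - boundary_slack <= pos < nbs.start + boundary_slack:
        return Region.NTERM_NBS_BOUNDARY
    lrr_gap_hi = lrr.start if lrr is not None else nbs.end + boundary_slack
    if nbs.end - boundary_slack <= pos < lrr_gap_hi + boundary_slack:
        return Region.NBS_LRR_BOUNDARY
    return Region.OTHER


def intron_records(
    gene: GeneModel,
    domains: Sequence[DomainAnnotation] | None = None,
    boundary_slack: int = 10,
) -> list[IntronRecord]:
    """All introns of a gene, labeled when domains are supplied."""
    records = []
    for i, offset in enumerate(intron_offsets(gene)):
        rec = IntronRecord(
            index=i,
            cds_offset=offset,
            phase=intron_phase(offset),
            protein_pos=offset // 3,
        )
        if domains:
            rec = IntronRecord(
                index=rec.index,
                cds_offset=rec.cds_offset,
                phase=rec.phase,
                protein_pos=rec.protein_pos,
                region=label_region(rec, domains, boundary_slack),
            )
        records.append(rec)
    return records


def match_signature(
    introns: Sequence[IntronRecord], sig: ClassSignature
) -> bool:
    """Does a labeled intron set satisfy one class fingerprint?

    For boundary-forbidding signatures (CNL) the test is the absence of any
    N-terminal/NBS boundary intron; otherwise every required (region, phase)
    pair must be present.
    """
    if sig.forbidden_boundary_introns:
        return not any(r.region == Region.NTERM_NBS_BOUNDARY for r in introns)
    present = {(r.region, r.phase) for r in introns}
    return all(req in present for req in sig.required)


def conserved_introns(
    family: Iterable[tuple[object, Sequence[IntronRecord]]],
    nbs_starts: dict[object, int] | None = None,
    position_tolerance: int = 5,
    min_fraction: float = 0.8,
) -> list[tuple[Region, int, float]]:
    """Conserved intron locations across a gene family.

    Introns are expressed as protein positions relative to each gene's NBS
    start (pass ``nbs_starts``; default 0, i.e. absolute positions), then
    single-linkage clustered: two introns join when their relative positions
    differ by at most ``position_tolerance`` and their phases are equal.
    Clusters supported by at least ``min_fraction`` of the family are
    reported as (region, phase, support) with support in [0, 1].
    """
    family = list(family)
    if len(family) < 2:
        raise InputError("family must contain at least two genes")
    entries = []  # (relative position, phase, region, gene index)
    for gi, (gene_id, introns) in enumerate(family):
        offset = (nbs_starts or {}).get(gene_id, 0)
        for rec in introns:
            entries.append((rec.protein_pos - offset, rec.phase, rec.region, gi))
    if not entries:
        return []
    parent = list(range(len(entries)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            if (
                entries[i][1] == entries[j][1]
                and abs(entries[i][0] - entries[j][0]) <= position_tolerance
            ):
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(entries)):
        clusters.setdefault(find(i), []).append(i)
    results = []
    n_genes = len(family)
    for members in clusters.values():
        support = len({entries[i][3] for i in members}) / n_genes
        if support >= min_fraction:
            regions = [entries[i][2] for i in members]
            region = max(set(regions), key=regions.count)
            phase = entries[members[0]][1]
            mean_pos = sum(entries[i][0] for i in members) / len(members)
            results.append((region, phase, support, mean_pos))
    results.sort(key=lambda r: r[3])
    return [(region, phase, support) for region, phase, support, _ in results]


def introns_to_frame(per_gene: dict[str, Sequence[IntronRecord]]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": gene_id,
            "index": rec.index,
            "cds_offset": rec.cds_offset,
            "phase": rec.phase,
            "protein_pos": rec.protein_pos,
            "region": str(rec.region),
        }
        for gene_id, records in per_gene.items()
        for rec in records
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "index", "cds_offset", "phase", "protein_pos", "region"],
    )
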