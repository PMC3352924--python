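"""Synthetic labelled genomes for benchmarking the survey pipeline.

Each synthetic family emulates one NBS-gene class.  A class *founder* is
derived from the packaged NBS template by substituting non-anchor positions
at a fixed between-class divergence (the anchor motifs P-loop, Kinase-2 and
GLPL are left intact, as they are in real lineages), so the NBS domain
carries the class signal the similarity channel relies on.  Family members
are then drawn from the founder by independent per-site substitution at the
requested within-family divergence.

Genes are emitted as a genome FASTA plus GFF3 gene models: proteins are
reverse-translated with uniformly random synonymous codons, class-signature
introns (random 80-300 nt, GT...AG) are inserted at fixed template offsets
with the class's phases, half of the genes are placed on the minus strand,
and a chosen fraction receives one internal stop codon (pseudogenes).
Decoy genes are composition-matched random proteins carrying none of the
templates.  All output is byte-deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .genemodel import GeneModel, write_gff3
from .profiles import (
    AMINO_ACIDS,
    ANCHOR_MOTIFS,
    _mutate,
    domain_template,
    nbs_anchor_spans,
    nbs_template,
)

__all__ = [
    "SyntheticFamilySpec",
    "SyntheticFamily",
    "CLASS_DIVERGENCE",
    "make_templates",
    "class_nbs_founder",
    "make_family",
    "combine_families",
    "bryophyte_survey_specs",
    "mutate",
]

LEADER = "MGSSAE"
LINKER = "AGSTAGST"
TAIL = "GKDE"

#: Between-class divergence applied once to the NBS template (non-anchor
#: positions) to derive each class founder.
CLASS_DIVERGENCE = 0.30
_FOUNDER_SEEDS = {"TNL": 311001, "PNL": 311002, "CNL": 311003, "HNL": 311004}
_NTERM_KIND = {"T": "TIR", "C": "CC", "P": "PK", "H": "HYDROLASE"}

_NUCLEOTIDES = "ACGT"
_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Recipe for one synthetic gene family.

    ``n_per_form`` maps architecture forms (e.g. "PNL", "PN", "NL", "N") to
    gene counts; ``divergence`` is the within-family per-site substitution
    probability.
    """

    class_name: str
    n_per_form: dict[str, int]
    divergence: float = 0.2
    intron_signature: bool = True
    n_decoy_genes: int = 0
    pseudogene_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_name not in _FOUNDER_SEEDS:
            raise InputError(f"unknown class {self.class_name!r}")
        if not 0.0 <= self.divergence < 1.0:
            raise InputError("divergence must lie in [0, 1)")
        for form, n in self.n_per_form.items():
            if n < 0:
                raise InputError(f"negative count for form {form!r}")
            if "N" not in form:
                raise InputError(f"form {form!r} lacks the NBS letter")
        if not 0.0 <= self.pseudogene_fraction <= 1.0:
            raise InputError("pseudogene_fraction must lie in [0, 1]")


@dataclass
class SyntheticFamily:
    """Generator output: genome, gene models and the truth table."""

    genome: dict[str, str]
    genes: list[GeneModel]
    truth: pd.DataFrame = field(repr=False)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "genome.fa", "w") as out:
            for sid, seq in self.genome.items():
                out.write(f">{sid}\n")
                for i in range(0, len(seq), 70):
                    out.write(seq[i : i + 70] + "\n")
        write_gff3(
            self.genes,
            out_dir / "genes.gff3",
            scaffold_lengths={s: len(q) for s, q in self.genome.items()},
        )
        self.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)


def make_templates() -> dict[str, str]:
    """The fixed, versioned domain templates used to assemble genes."""
    return {
        kind: domain_template(kind)
        for kind in ("TIR", "PK", "HYDROLASE", "CC", "NBS", "LRR")
    }


@lru_cache(maxsize=None)
def class_nbs_founder(class_name: str) -> str:
    """Class-specific NBS founder: template diverged outside the anchors."""
    if class_name not in _FOUNDER_SEEDS:
        raise InputError(f"unknown class {class_name!r}")
    protected = frozenset(
        i
        for name, (start, end) in nbs_anchor_spans().items()
        if name in ANCHOR_MOTIFS
        for i in range(start, end)
    )
    rng = np.random.default_rng(_FOUNDER_SEEDS[class_name])
    return _mutate(nbs_template(), CLASS_DIVERGENCE, rng, protected=protected)


def mutate(seq: str, rate: float, seed: int) -> str:
    """Independent per-site substitution; alphabet inferred from content."""
    rng = np.random.default_rng(seed)
    letters = set(seq.upper())
    if letters <= set("ACGTU"):
        alphabet = _NUCLEOTIDES if "U" not in letters else "ACGU"
    else:
        alphabet = AMINO_ACIDS
    return _mutate(seq.upper(), rate, rng, alphabet=alphabet)


# ---------------------------------------------------------------------------
# Gene assembly.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Layout:
    """Protein-coordinate landmarks of one assembled gene."""

    nterm: tuple[int, int] | None
    nbs: tuple[int, int]  # full template span
    nbs_obs: tuple[int, int]  # motif-delimited (observable) span
    lrr: tuple[int, int] | None
    length: int


def _assemble_protein(class_name: str, form: str) -> tuple[str, _Layout]:
    parts = [LEADER]
    pos = len(LEADER)
    nterm_span = None
    if form[0] in _NTERM_KIND:
        template = domain_template(_NTERM_KIND[form[0]])
        nterm_span = (pos, pos + len(template))
        parts.append(template)
        pos += len(template)
        parts.append(LINKER)
        pos += len(LINKER)
    nbs = class_nbs_founder(class_name)
    spans = nbs_anchor_spans()
    nbs_span = (pos, pos + len(nbs))
    nbs_obs = (pos + spans["P-loop"][0], pos + spans["MHDV"][1])
    parts.append(nbs)
    pos += len(nbs)
    lrr_span = None
    if form.endswith("L"):
        parts.append(LINKER)
        pos += len(LINKER)
        template = domain_template("LRR")
        lrr_span = (pos, pos + len(template))
        parts.append(template)
        pos += len(template)
    parts.append(TAIL)
    pos += len(TAIL)
    return "".join(parts), _Layout(nterm_span, nbs_span, nbs_obs, lrr_span, pos)


def _intron_plan(
    class_name: str, form: str, layout: _Layout
) -> list[tuple[int, int, str]]:
    """(protein position, phase, truth region) per intron, 5' to 3'.

    Signature introns sit at fixed template offsets so that conserved-location
    detection across a family is meaningful; divergence never moves them.
    """
    plan: list[tuple[int, int, str]] = []
    if layout.nterm is not None:
        boundary_pos = (layout.nterm[1] + layout.nbs_obs[0]) // 2
    else:
        boundary_pos = layout.nbs_obs[0] - 6
    if layout.lrr is not None:
        lrr_boundary_pos = (layout.nbs_obs[1] + layout.lrr[0]) // 2
    else:
        lrr_boundary_pos = layout.nbs_obs[1] + 5
    if class_name == "TNL":
        plan = [
            (boundary_pos, 2, "NTERM_NBS_BOUNDARY"),
            (lrr_boundary_pos, 0, "NBS_LRR_BOUNDARY"),
        ]
    elif class_name == "PNL":
        plan = [
            (boundary_pos, 0, "NTERM_NBS_BOUNDARY"),
            (lrr_boundary_pos, 0, "NBS_LRR_BOUNDARY"),
        ]
    elif class_name == "HNL":
        plan = []
        if layout.nterm is not None:
            mid = (layout.nterm[0] + layout.nterm[1]) // 2
            plan.append((mid, 0, "WITHIN_NTERM"))
        plan += [
            (boundary_pos, 0, "NTERM_NBS_BOUNDARY"),
            (lrr_boundary_pos, 0, "NBS_LRR_BOUNDARY"),
        ]
    elif class_name == "CNL":
        # no conserved boundary introns: one noise intron deep inside the NBS
        plan = [(layout.nbs_obs[0] + 60, 1, "WITHIN_NBS")]
    return plan


@lru_cache(maxsize=1)
def _codon_map() -> dict[str, tuple[str, ...]]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    by_aa["*"] = list(_STOP_CODONS)
    return {aa: tuple(sorted(codons)) for aa, codons in by_aa.items()}


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codon_map = _codon_map()
    parts = []
    for aa in protein:
        options = codon_map[aa]
        parts.append(options[rng.integers(0, len(options))])
    return "".join(parts)


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(_NUCLEOTIDES[i] for i in rng.integers(0, 4, size=length))


def _intron_seq(rng: np.random.Generator) -> str:
    length = int(rng.integers(80, 301))
    return "GT" + _random_dna(length - 4, rng) + "AG"


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@lru_cache(maxsize=1)
def _template_composition() -> tuple[np.ndarray, str]:
    pool = "".join(make_templates().values())
    freqs = np.array([pool.count(a) for a in AMINO_ACIDS], dtype=float)
    return freqs / freqs.sum(), AMINO_ACIDS


@dataclass
class _GeneDraft:
    gene_id: str
    cds: str
    intron_offsets: list[int]
    truth: dict


def _place_genes(
    drafts: list[_GeneDraft], scaffold_id: str, rng: np.random.Generator
) -> tuple[str, list[GeneModel]]:
    pieces: list[str] = []
    cursor = 0
    models = []
    for i, draft in enumerate(drafts):
        spacer = _random_dna(int(rng.integers(150, 400)), rng)
        pieces.append(spacer)
        cursor += len(spacer)
        bounds = [0] + sorted(draft.intron_offsets) + [len(draft.cds)]
        exons = [draft.cds[a:b] for a, b in zip(bounds, bounds[1:])]
        chunks: list[tuple[str, bool]] = []
        for j, exon in enumerate(exons):
            chunks.append((exon, True))
            if j < len(exons) - 1:
                chunks.append((_intron_seq(rng), False))
        gene_seq = "".join(seq for seq, _ in chunks)
        strand = "+" if i % 2 == 0 else "-"
        length = len(gene_seq)
        segments = []
        local = 0
        for seq, coding in chunks:
            if coding:
                if strand == "+":
                    segments.append((cursor + local + 1, cursor + local + len(seq)))
                else:
                    segments.append(
                        (cursor + length - (local + len(seq)) + 1,
                         cursor + length - local)
                    )
            local += len(seq)
        if strand == "-":
            gene_seq = gene_seq.translate(_COMPLEMENT)[::-1]
        pieces.append(gene_seq)
        cursor += length
        models.append(
            GeneModel(
                gene_id=draft.gene_id,
                scaffold_id=scaffold_id,
                strand=strand,
                cds_segments=tuple(segments),
            )
        )
        draft.truth["strand"] = strand
    tail = _random_dna(int(rng.integers(150, 400)), rng)
    pieces.append(tail)
    return "".join(pieces), models


def make_family(
    spec: SyntheticFamilySpec, scaffold_id: str | None = None
) -> SyntheticFamily:
    """Generate one labelled family (genome FASTA dict, GFF3 models, truth)."""
    rng = np.random.default_rng(spec.seed)
    scaffold_id = scaffold_id or f"scf_{spec.class_name}"
    drafts: list[_GeneDraft] = []
    counter = 0
    for form, count in spec.n_per_form.items():
        for _ in range(count):
            gene_id = f"{spec.class_name}_{form}_{counter:03d}"
            counter += 1
            protein, layout = _assemble_protein(spec.class_name, form)
            protein = protein[0] + _mutate(
                protein[1:], spec.divergence, rng
            )  # start methionine preserved
            plan = _intron_plan(spec.class_name, form, layout) if spec.intron_signature else []
            offsets = [3 * pos + phase for pos, phase, _ in plan]
            if any(not 0 < off < 3 * (layout.length + 1) for off in offsets):
                raise ValidationError(f"{gene_id}: intron offset outside CDS")
            drafts.append(
                _GeneDraft(
                    gene_id=gene_id,
                    cds="",  # filled after optional pseudogene injection
                    intron_offsets=offsets,
                    truth={
                        "gene_id": gene_id,
                        "class_name": spec.class_name,
                        "form": form,
                        "pseudogene": False,
                        "introns": ";".join(
                            f"{region}:{phase}" for _, phase, region in plan
                        ),
                        "_protein": protein,
                        "_layout": layout,
                    },
                )
            )
    n_pseudo = round(spec.pseudogene_fraction * len(drafts))
    pseudo_idx = set(
        rng.choice(len(drafts), size=n_pseudo, replace=False).tolist()
    ) if n_pseudo else set()
    for i, draft in enumerate(drafts):
        protein = draft.truth.pop("_protein")
        layout: _Layout = draft.truth.pop("_layout")
        if i in pseudo_idx:
            stop_pos = layout.nbs[1] + 1  # linker/tail residue after the NBS
            protein = protein[:stop_pos] + "*" + protein[stop_pos + 1 :]
            draft.truth["pseudogene"] = True
        stop = _STOP_CODONS[rng.integers(0, len(_STOP_CODONS))]
        draft.cds = _reverse_translate(protein, rng) + stop
    probs, alphabet = _template_composition()
    for d in range(spec.n_decoy_genes):
        length = int(rng.integers(200, 321))
        protein = "M" + "".join(
            rng.choice(list(alphabet), size=length - 1, p=probs)
        )
        cds = _reverse_translate(protein, rng) + _STOP_CODONS[
            rng.integers(0, len(_STOP_CODONS))
        ]
        n_introns = int(rng.integers(0, 3))
        offsets = sorted(
            set(int(o) for o in rng.integers(30, len(cds) - 30, size=n_introns))
        )
        drafts.append(
            _GeneDraft(
                gene_id=f"DECOY_{spec.class_name}_{d:03d}",
                cds=cds,
                intron_offsets=offsets,
                truth={
                    "gene_id": f"DECOY_{spec.class_name}_{d:03d}",
                    "class_name": "DECOY",
                    "form": "",
                    "pseudogene": False,
                    "introns": "",
                },
            )
        )
    sequence, models = _place_genes(drafts, scaffold_id, rng)
    truth = pd.DataFrame(
        [d.truth for d in drafts],
        columns=["gene_id", "class_name", "form", "pseudogene", "introns", "strand"],
    )
    return SyntheticFamily(
        genome={scaffold_id: sequence}, genes=models, truth=truth
    )


def combine_families(families: list[SyntheticFamily]) -> SyntheticFamily:
    """Merge family outputs into one multi-scaffold genome."""
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    truths = []
    for fam in families:
        for sid, seq in fam.genome.items():
            if sid in genome:
                raise ValidationError(f"duplicate scaffold id {sid!r}")
            genome[sid] = seq
        genes.extend(fam.genes)
        truths.append(fam.truth)
    return SyntheticFamily(
        genome=genome, genes=genes, truth=pd.concat(truths, ignore_index=True)
    )


def bryophyte_survey_specs(
    divergence: float = 0.2,
    seed: int = 0,
    n_decoy_genes: int = 5,
    pseudogene_fraction: float = 0.0,
    include_hnl: bool = True,
) -> list[SyntheticFamilySpec]:
    """Family specs whose form mixtures mirror the bryophyte surveys.

    The TNL/PNL/CNL compositions follow the moss genome survey table; with
    ``include_hnl`` a liverwort-style HNL family is added.
    """
    from .classify import MPOLYMORPHA_HNL, PPATENS_SURVEY

    source = dict(PPATENS_SURVEY)
    if include_hnl:
        source.update(MPOLYMORPHA_HNL)
    per_class: dict[str, dict[str, int]] = {}
    for (cls, form), n in source.items():
        if n > 0:
            per_class.setdefault(cls, {})[form] = n
    specs = []
    for i, (cls, forms) in enumerate(sorted(per_class.items())):
        specs.append(
            SyntheticFamilySpec(
                class_name=cls,
                n_per_form=forms,
                divergence=divergence,
                n_decoy_genes=n_decoy_genes if i == 0 else 0,
                pseudogene_fraction=pseudogene_fraction,
                seed=seed + 101 * (i + 1),
            )
        )
    return specs
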