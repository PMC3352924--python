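"""Packaged scoring profiles and reference sequence blocks.

The NBS (NB-ARC) domain of plant disease-resistance proteins carries a series
of short conserved motifs appearing, N- to C-terminus, in the canonical order
P-loop, RNBS-A, Kinase-2, RNBS-B, RNBS-C, GLPL, RNBS-D, MHDV.  Each motif is
packaged here as a block of aligned exemplar peptides from which a fixed-width
position-specific score matrix (PSSM) is built.  P-loop, Kinase-2, GLPL and
RNBS-D are the motifs conserved across all classes and get tight blocks; the
class-variable motifs (RNBS-A/B/C, MHDV) get looser ones.

The same machinery types N-terminal domains: TIR, protein-kinase (PK) and
alpha/beta-hydrolase regions are scored with wide PSSMs built from packaged
domain templates, while coiled-coil detection uses a separate heptad
heuristic (see :mod:`nbsarch.domains`).

Scores are log-odds in bits against a uniform residue background, floored per
cell so that a single substitution cannot veto an otherwise strong match.
Each profile's acceptance threshold is calibrated empirically: the maximum
score of 1,000 random windows plus a one-bit margin.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import InputError

__all__ = [
    "AMINO_ACIDS",
    "MOTIF_ORDER",
    "ANCHOR_MOTIFS",
    "MOTIF_BLOCKS",
    "MotifProfile",
    "build_profile",
    "default_motif_profiles",
    "nterm_profiles",
    "encode_protein",
    "window_scores",
    "nbs_template",
    "nbs_anchor_spans",
    "domain_template",
    "LRR_UNITS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_N_AA = len(AMINO_ACIDS)
_BACKGROUND = 1.0 / _N_AA
_SCORE_FLOOR = -1.0  # bits; also the score of any non-standard letter
_CALIBRATION_SEED = 90731
_CALIBRATION_WINDOWS = 1000
_DEFAULT_MARGIN = 1.0  # bits above the empirical null maximum

MOTIF_ORDER = (
    "P-loop",
    "RNBS-A",
    "Kinase-2",
    "RNBS-B",
    "RNBS-C",
    "GLPL",
    "RNBS-D",
    "MHDV",
)

#: Motifs whose joint, ordered presence defines an NBS domain call.  RNBS-D is
#: well conserved too but lost in C-terminally truncated genes, so it is
#: scored without being required.
ANCHOR_MOTIFS = frozenset({"P-loop", "Kinase-2", "GLPL"})

# Aligned exemplar peptides per motif.  The first row of each block doubles as
# the motif instance embedded in the packaged NBS template below.
MOTIF_BLOCKS: dict[str, tuple[str, ...]] = {
    "P-loop": (
        "GMGGVGKTT",
        "GMGGLGKTT",
        "GPGGVGKST",
        "GMGGSGKTT",
        "GESGVGKTT",
        "GMPGIGKTT",
    ),
    "RNBS-A": (
        "FDLKAWVCVS",
        "FDLRAWITVS",
        "LDLKAWVCIS",
        "FNLQAWVSVS",
        "FDVPAWICVS",
        "YDLKTWVCVP",
    ),
    "Kinase-2": (
        "KRFLLVLDDV",
        "KRYLIVLDDV",
        "KRFLLVLDDI",
        "KKFLLVLDDV",
        "SRFLIVLDDV",
        "KRCLIVIDDV",
    ),
    "RNBS-B": (
        "GSRIIITTRD",
        "GSRIIVTTRN",
        "GSKILITTRD",
        "GCRVIITTRS",
        "SSRIIFTSRD",
        "GSRIVLTTRE",
    ),
    "RNBS-C": (
        "YEVKPLSEDE",
        "YKVEPLSEDN",
        "FEVKPLSDDE",
        "YEVELLSEDD",
        "YEVGPLSHEE",
        "HEVKPLSQED",
    ),
    "GLPL": (
        "GGLPLALKV",
        "GGLPLALKV",
        "GGLPLALIT",
        "CGLPLALKV",
        "GGLPLTLKV",
        "AGLPLALVT",
    ),
    "RNBS-D": (
        "CFLYCALFP",
        "CFLYCSLFP",
        "CFLYCALYP",
        "CGLYCALFP",
        "CFLYCCLFP",
        "CFLYSALFP",
    ),
    "MHDV": (
        "MHDVVREM",
        "MHDLLREM",
        "MHDVIREF",
        "MHDLVRDM",
        "IHDVVREM",
        "MHDVVHEL",
    ),
}


@dataclass(frozen=True)
class MotifProfile:
    """A fixed-width PSSM with a calibrated acceptance threshold.

    ``matrix`` has shape (width, 21): one column per standard residue plus a
    trailing floor column used for X, stop (*) and other non-standard letters.
    """

    name: str
    order_index: int
    matrix: np.ndarray
    min_score: float

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def max_score(self) -> float:
        return float(self.matrix[:, :_N_AA].max(axis=1).sum())


def encode_protein(sequence: str) -> np.ndarray:
    """Map a protein string to integer codes; non-standard letters -> 20."""
    return np.array(
        [_AA_INDEX.get(ch, _N_AA) for ch in sequence.upper()], dtype=np.int64
    )


def _pssm(block: tuple[str, ...], pseudocount: float = 1.0) -> np.ndarray:
    width = len(block[0])
    if any(len(row) != width for row in block):
        raise InputError("exemplar block rows must share one width")
    counts = np.zeros((width, _N_AA))
    for row in block:
        for j, ch in enumerate(row.upper()):
            counts[j, _AA_INDEX[ch]] += 1.0
    n = len(block)
    probs = (counts + pseudocount * _BACKGROUND) / (n + pseudocount)
    scores = np.log2(probs / _BACKGROUND)
    scores = np.maximum(scores, _SCORE_FLOOR)
    matrix = np.full((width, _N_AA + 1), _SCORE_FLOOR)
    matrix[:, :_N_AA] = scores
    return matrix


def window_scores(profile: MotifProfile, encoded: np.ndarray) -> np.ndarray:
    """Score every window of ``encoded``; empty array if the sequence is short."""
    w = profile.width
    n = encoded.size - w + 1
    if n <= 0:
        return np.empty(0)
    out = np.zeros(n)
    for j in range(w):
        out += profile.matrix[j, encoded[j : j + n]]
    return out


def _calibrate_min_score(
    matrix: np.ndarray, margin: float, seed: int = _CALIBRATION_SEED
) -> float:
    """Empirical null: max score over random uniform windows, plus a margin."""
    rng = np.random.default_rng(seed)
    width = matrix.shape[0]
    windows = rng.integers(0, _N_AA, size=(_CALIBRATION_WINDOWS, width))
    scores = matrix[np.arange(width), windows].sum(axis=1)
    return float(scores.max() + margin)


def build_profile(
    name: str,
    order_index: int,
    block: tuple[str, ...],
    *,
    pseudocount: float = 1.0,
    margin: float = _DEFAULT_MARGIN,
) -> MotifProfile:
    matrix = _pssm(tuple(block), pseudocount=pseudocount)
    return MotifProfile(
        name=name,
        order_index=order_index,
        matrix=matrix,
        min_score=_calibrate_min_score(matrix, margin),
    )


@lru_cache(maxsize=None)
def default_motif_profiles() -> tuple[MotifProfile, ...]:
    """The eight packaged NBS motif profiles in canonical order."""
    return tuple(
        build_profile(name, i + 1, MOTIF_BLOCKS[name])
        for i, name in enumerate(MOTIF_ORDER)
    )


# ---------------------------------------------------------------------------
# Reference templates: the fixed, versioned sequences behind both the
# N-terminal typing profiles and the synthetic-genome generator.
# ---------------------------------------------------------------------------

# Filler composition loosely resembling globular protein interiors/surfaces.
_FILLER_AA = "AAVVLLIIGGSSTTEEKKDDRRNNQQPFYMHWC"


def _filler(length: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(_FILLER_AA), size=length)
    return "".join(_FILLER_AA[i] for i in idx)


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            alphabet: str = AMINO_ACIDS,
            protected: frozenset[int] = frozenset()) -> str:
    """Independent per-site substitution to a uniformly-chosen other letter."""
    if not 0.0 <= rate < 1.0:
        raise InputError(f"substitution rate {rate} outside [0, 1)")
    out = list(seq)
    hit = rng.random(len(seq)) < rate
    # draw replacements for every site so the random stream is rate-independent
    draws = rng.integers(0, len(alphabet) - 1, size=len(seq))
    for i, flag in enumerate(hit):
        if not flag or i in protected:
            continue
        current = alphabet.find(out[i])
        j = draws[i]
        if current >= 0 and j >= current:
            j += 1
        out[i] = alphabet[j % len(alphabet)]
    return "".join(out)


def _assemble_nbs() -> tuple[str, dict[str, tuple[int, int]]]:
    rng = np.random.default_rng(424243)
    gaps_before = {
        "P-loop": 14,
        "RNBS-A": 22,
        "Kinase-2": 12,
        "RNBS-B": 25,
        "RNBS-C": 28,
        "GLPL": 30,
        "RNBS-D": 24,
        "MHDV": 20,
    }
    parts: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    for name in MOTIF_ORDER:
        filler = _filler(gaps_before[name], rng)
        parts.append(filler)
        pos += len(filler)
        instance = MOTIF_BLOCKS[name][0]
        spans[name] = (pos, pos + len(instance))
        parts.append(instance)
        pos += len(instance)
    parts.append(_filler(12, rng))
    return "".join(parts), spans


_NBS_TEMPLATE, _NBS_SPANS = _assemble_nbs()


def nbs_template() -> str:
    """The packaged NBS domain template (all eight motifs in order)."""
    return _NBS_TEMPLATE


def nbs_anchor_spans() -> dict[str, tuple[int, int]]:
    """0-based half-open spans of every motif instance within the template."""
    return dict(_NBS_SPANS)


def _embed(length: int, inserts: dict[int, str], seed: int) -> str:
    seq = list(_filler(length, np.random.default_rng(seed)))
    for offset, peptide in inserts.items():
        seq[offset : offset + len(peptide)] = peptide
    return "".join(seq)


# TIR: Toll/Interleukin-1-receptor homology region.
_TIR_TEMPLATE = _embed(
    120,
    {0: "WIYDVFLSFRGEDT", 44: "KIVIPIFYDVDPSDVRHQ", 90: "FGEAFAKHE"},
    seed=515001,
)

# PK: protein-kinase catalytic core (glycine loop, catalytic loop, DFG).
_PK_TEMPLATE = _embed(
    150,
    {6: "GSGGFGEVYK", 58: "IHRDLKPSNILL", 102: "DFGLARLI", 128: "APEVLR"},
    seed=515002,
)

# Alpha/beta-hydrolase fold (nucleophile elbow GxSxG, oxyanion HGGG).
_HYD_TEMPLATE = _embed(
    130,
    {8: "VLLLHGWPG", 52: "IAPDLRGYG", 88: "GHSMGGMIA", 116: "DLAAFLN"},
    seed=515003,
)

# Coiled coil: eight heptads, hydrophobic a/d positions, charged flanks.
_CC_TEMPLATE = (
    "LQELEKE" "IESLKQK" "LEDLKEE" "MKSLEQK"
    "LEELAKE" "LQSLNEK" "VEDLKQE" "LKELEDK"
)

#: Leucine-rich-repeat units; each 9-mer starts on the LxxLxLxx consensus
#: (L at offsets 0, 3, 5 with L in {L, I, V, F}).
LRR_UNITS = (
    "LRELNLSGN",
    "LKSLDLSNN",
    "LTELYLDGN",
    "LPNLRVLNA",
    "LESLILSNN",
    "LKELDLSRN",
    "LTSLNLSGN",
    "LRELILDNN",
    "LQSLDLSEN",
    "LKELNLSQN",
)

_DOMAIN_TEMPLATES = {
    "TIR": _TIR_TEMPLATE,
    "PK": _PK_TEMPLATE,
    "HYDROLASE": _HYD_TEMPLATE,
    "CC": _CC_TEMPLATE,
    "NBS": _NBS_TEMPLATE,
    "LRR": "".join(LRR_UNITS),
}


def domain_template(kind: str) -> str:
    """Packaged template sequence for one domain kind."""
    try:
        return _DOMAIN_TEMPLATES[kind]
    except KeyError:
        raise InputError(f"unknown domain kind {kind!r}") from None


@lru_cache(maxsize=None)
def nterm_profiles() -> dict[str, MotifProfile]:
    """Wide typing profiles for the three sequence-profiled N-terminal kinds.

    Each block is the packaged template plus two 10%-divergent variants, so
    the profile tolerates substantial lineage divergence while staying far
    above the random-window null.
    """
    out: dict[str, MotifProfile] = {}
    for i, kind in enumerate(("TIR", "PK", "HYDROLASE")):
        template = _DOMAIN_TEMPLATES[kind]
        rng = np.random.default_rng(77000 + i)
        block = (
            template,
            _mutate(template, 0.10, rng),
            _mutate(template, 0.10, rng),
        )
        out[kind] = build_profile(kind, 100 + i, block)
    return out
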