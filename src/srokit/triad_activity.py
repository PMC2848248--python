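"""Catalytic triad extraction and PARP/mART/inactive activity prediction.

The catalytic triad of the PARP fold sits at three structural landmarks: the
C-terminal residue of beta-strand 1, the middle residue of beta-strand 2 and
the N-terminal residue of beta-strand 5 (H, Y, E in active poly-ADP-ribose
polymerases; H and Y contact NAD, E is catalytic).  A query catalytic core
is anchored to a packaged fold-annotated reference by global pairwise
alignment with free end gaps; the query residues in the landmark columns,
together with the length of the beta4-beta5 loop (long in classical PARPs,
short in mono-ART-fold enzymes with open active sites), drive a rule cascade:

1. catalytic E at landmark 3 with a long loop        -> PARP
2. NAD-contacting H and Y at landmarks 1 and 2       -> mART
3. Y retained and experimental NAD binding positive  -> mART
   (the substrate-assisted mechanism, where the substrate supplies the
   catalytic glutamate)
4. otherwise                                         -> inactive
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from ._refdata import fold_reference_raw

__all__ = [
    "FoldReference",
    "AnchorAlignment",
    "TriadCall",
    "default_reference",
    "anchor_align",
    "extract_triad",
    "classify_activity",
    "call_protein",
]

#: beta4-beta5 loop length from which rule 1 treats the loop as "long";
#: observed loop lengths are bimodal (5-6 vs 36-38), any cutoff between
#: those bands behaves identically.
LONG_LOOP_MIN = 30


@dataclass
class FoldReference:
    """Fold-annotated PARP-core reference with triad landmark columns."""

    sequence: str
    spans: dict[str, tuple[int, int]]   # 1-based inclusive, core coordinates
    offset: int = 0                     # full-protein position of core residue 1 is offset+1
    name: str = "PARP_core_reference"

    def __post_init__(self) -> None:
        last = 0
        for key in ("beta1", "beta2", "beta3", "beta4", "beta5", "beta6"):
            a, b = self.spans[key]
            if not (last < a <= b <= len(self.sequence)):
                raise ValueError(f"span {key} out of order or out of bounds")
            last = b

    @property
    def landmarks(self) -> tuple[int, int, int]:
        """Triad landmark positions in core coordinates."""
        b2s, b2e = self.spans["beta2"]
        mid = b2s + math.ceil((b2e - b2s + 1) / 2) - 1
        return (self.spans["beta1"][1], mid, self.spans["beta5"][0])

    @property
    def landmarks_full(self) -> tuple[int, int, int]:
        return tuple(self.offset + p for p in self.landmarks)

    @property
    def loop_bounds(self) -> tuple[int, int]:
        """Core positions of the beta4 C-terminus and beta5 N-terminus."""
        return (self.spans["beta4"][1], self.spans["beta5"][0])


def default_reference() -> FoldReference:
    raw = fold_reference_raw()
    return FoldReference(
        sequence=raw["sequence"],
        spans={k: tuple(v) for k, v in raw["spans"].items()},
        offset=raw["offset"],
        name=raw["name"],
    )


@dataclass
class AnchorAlignment:
    """Query anchored to the reference core with a column map."""

    query: str
    reference: FoldReference
    ref_to_query: dict[int, int | None]  # core position -> 1-based query position
    score: float

    def map_position(self, core_pos: int) -> int | None:
        return self.ref_to_query.get(core_pos)


@dataclass
class TriadCall:
    """Triad residues, positions, loop length and the activity class."""

    residues: tuple[str, str, str]
    positions: tuple[int | None, int | None, int | None]
    loop_len: int | None
    nad_evidence: str = "ND"
    activity: str | None = None
    gapped: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def motif(self) -> str:
        parts = []
        for res, pos in zip(self.residues, self.positions):
            parts.append(f"{res}{pos}" if pos is not None else "-")
        return " ".join(parts)


def _make_aligner(open_gap: float = -11.0, extend_gap: float = -1.0,
                  matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    # free end gaps on both sides: the core may sit anywhere in the query
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    aligner.mode = "global"
    return aligner


def anchor_align(
    query: str,
    ref: FoldReference | None = None,
    open_gap: float = -11.0,
    extend_gap: float = -1.0,
    matrix: str = "BLOSUM62",
) -> AnchorAlignment:
    """Globally align a query to the fold reference and map its columns.

    Every reference core position is mapped to a 1-based query position, or
    to None where the query has a gap in that column.
    """
    query = query.upper()
    if len(query) < 50:
        raise ValueError("query too short to anchor a PARP core (< 50 residues)")
    ref = ref or default_reference()
    aligner = _make_aligner(open_gap, extend_gap, matrix)
    best = aligner.align(ref.sequence, query)[0]
    mapping: dict[int, int | None] = {p: None for p in range(1, len(ref.sequence) + 1)}
    target_blocks, query_blocks = best.aligned
    for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
        for k in range(te - ts):
            mapping[ts + k + 1] = qs + k + 1
    return AnchorAlignment(
        query=query, reference=ref, ref_to_query=mapping, score=float(best.score)
    )


def _nearest_mapped(aln: AnchorAlignment, span: tuple[int, int], from_end: bool):
    positions = range(span[1], span[0] - 1, -1) if from_end else range(span[0], span[1] + 1)
    for p in positions:
        q = aln.map_position(p)
        if q is not None:
            return q
    return None


def extract_triad(aln: AnchorAlignment, nad_evidence: str = "ND") -> TriadCall:
    """Read the triad residues and beta4-beta5 loop length off an anchoring.

    A landmark column that aligns to a gap in the query yields residue '-'
    and flags the call; downstream the activity is forced to inactive.  The
    loop length counts query residues strictly between the columns aligned
    to the beta4 C-terminus and the beta5 N-terminus; if either endpoint is
    gapped, the nearest aligned position inside the strand is used as a
    fallback (reported in the warnings).
    """
    ref = aln.reference
    residues: list[str] = []
    positions: list[int | None] = []
    warnings: list[str] = []
    gapped = False
    for i, core_pos in enumerate(ref.landmarks, start=1):
        q = aln.map_position(core_pos)
        if q is None:
            residues.append("-")
            positions.append(None)
            warnings.append(f"landmark {i} aligned to a gap")
            gapped = True
        else:
            residues.append(aln.query[q - 1])
            positions.append(q)

    b4_end, b5_start = ref.loop_bounds
    q4 = aln.map_position(b4_end)
    q5 = aln.map_position(b5_start)
    if q4 is None:
        q4 = _nearest_mapped(aln, ref.spans["beta4"], from_end=True)
        if q4 is not None:
            warnings.append("beta4 end gapped; nearest aligned strand position used")
    if q5 is None:
        q5 = _nearest_mapped(aln, ref.spans["beta5"], from_end=False)
        if q5 is not None:
            warnings.append("beta5 start gapped; nearest aligned strand position used")
    if q4 is None or q5 is None or q5 <= q4:
        loop_len = None
        warnings.append("beta4-beta5 loop could not be measured")
        gapped = True
    else:
        loop_len = q5 - q4 - 1

    return TriadCall(
        residues=tuple(residues),
        positions=tuple(positions),
        loop_len=loop_len,
        nad_evidence=nad_evidence,
        gapped=gapped,
        warnings=warnings,
    )


def classify_activity(
    triad: tuple[str, str, str],
    loop_len: int | None,
    nad_evidence: str = "ND",
    long_loop_min: int = LONG_LOOP_MIN,
) -> str:
    """Predicted activity class from triad residues, loop length and NAD data.

    Total function over single-letter residues (or '-') and non-negative
    loop lengths; ``nad_evidence`` is "yes", "no" or "ND".
    """
    r1, r2, r3 = (r.upper() for r in triad)
    loop = -1 if loop_len is None else loop_len
    if r3 == "E" and loop >= long_loop_min:
        return "PARP"
    if r1 == "H" and r2 == "Y":
        return "mART"
    if r2 == "Y" and nad_evidence == "yes":
        return "mART"
    return "inactive"


def call_protein(
    seq: str,
    nad_evidence: str = "ND",
    ref: FoldReference | None = None,
    long_loop_min: int = LONG_LOOP_MIN,
    **align_kwargs,
) -> TriadCall:
    """Anchor, extract and classify one protein sequence."""
    aln = anchor_align(seq, ref, **align_kwargs)
    call = extract_triad(aln, nad_evidence)
    if call.gapped:
        call.activity = "inactive"
    else:
        call.activity = classify_activity(
            call.residues, call.loop_len, nad_evidence, long_loop_min
        )
    return call
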