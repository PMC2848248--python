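"""Domain architecture: profile scanning, structural typing, nomenclature
and alignment-conservation annotation.

SRO-family proteins are typed by which of three signatures they carry and in
what order: an N-terminal WWE protein-protein interaction domain, the PARP
catalytic core, and the plant-specific C-terminal RST domain.  Type A
carries all three (WWE first); type B lacks the WWE domain; records missing
the PARP core or RST are flagged incomplete (typically truncated gene
models).  Detection uses packaged position-weight-matrix mini-profiles
rather than live domain-database services.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._refdata import miniprofile_raw

__all__ = [
    "MiniProfile",
    "DomainHit",
    "ArchitectureCall",
    "ConservationRow",
    "default_profiles",
    "scan_domains",
    "classify_architecture",
    "assign_names",
    "annotate_conservation",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_BACKGROUND = 1.0 / 20.0

# Clustal-convention residue similarity groups (progressive-alignment
# defaults packaged as data; ':' for strong groups, '.' for weak groups).
STRONG_GROUPS = [
    "STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW",
]
WEAK_GROUPS = [
    "CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK", "NDEQHK",
    "NEQHRK", "FVLIM", "HFY",
]

# Biochemical-property palette for conservation rows.
_PROPERTY_CLASSES = [
    ("tyrosine", set("Y")),
    ("glycine", set("G")),
    ("positive", set("KRH")),
    ("acidic", set("DE")),
    ("hydrophobic", set("AVLIMFW")),
    ("polar-noncharged", set("STNQC")),
]


@dataclass
class MiniProfile:
    """Ungapped position weight matrix with consensus and threshold.

    ``pwm`` is length x 20 with rows summing to one; scoring is log-odds
    against a uniform background.  A window is a hit when its score reaches
    ``threshold`` times the maximum attainable score.
    """

    name: str
    pwm: np.ndarray
    consensus: str
    threshold: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        if not np.allclose(self.pwm.sum(axis=1), 1.0):
            raise ValueError("profile weights must sum to 1 per column")

    @classmethod
    def from_consensus(
        cls, name: str, consensus: str, match_weight: float = 0.7, threshold: float = 0.8
    ) -> "MiniProfile":
        length = len(consensus)
        pwm = np.full((length, 20), (1.0 - match_weight) / 19.0)
        for i, aa in enumerate(consensus):
            pwm[i, _AA_INDEX[aa]] = match_weight
        return cls(name=name, pwm=pwm, consensus=consensus, threshold=threshold)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log(self.pwm / _BACKGROUND)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def score_window(self, window: str) -> float:
        return float(self.scan_scores(window)[0])

    def scan_scores(self, seq: str) -> np.ndarray:
        """Log-odds score of every window of the profile's width in seq.

        X (or any non-standard letter) scores as background, log-odds 0.
        """
        width = len(self.consensus)
        if len(seq) < width:
            return np.empty(0)
        # 21st column: background score for X / unknown letters
        lo = np.hstack([self.log_odds, np.zeros((width, 1))])
        enc = np.array([_AA_INDEX.get(aa, 20) for aa in seq])
        windows = np.lib.stride_tricks.sliding_window_view(enc, width)
        return lo[np.arange(width), windows].sum(axis=1)


@dataclass
class DomainHit:
    name: str
    start: int   # 1-based inclusive
    end: int
    score: float


@dataclass
class ArchitectureCall:
    record_id: str
    domains: list[DomainHit]
    structural_type: str        # "A" | "B" | "incomplete"
    group_hint: str = "unassigned"
    group: str | None = None    # filled in from phylogeny when available


@dataclass
class ConservationRow:
    symbols: str                 # per column: '*', ':', '.' or ' '
    property_classes: list[str]  # per column palette class


def default_profiles() -> dict[str, MiniProfile]:
    """The packaged WWE / PARP_core / RST mini-profiles."""
    raw = miniprofile_raw()
    return {
        name: MiniProfile.from_consensus(
            name, consensus, raw["match_weight"], raw["threshold"]
        )
        for name, consensus in raw["profiles"].items()
    }


def scan_domains(
    seq: str, profiles: dict[str, MiniProfile] | None = None
) -> list[DomainHit]:
    """Scan a sequence with every profile; greedy non-overlapping placement.

    All windows scoring at least threshold x max score are candidate hits;
    they are placed best-scoring-first, discarding overlaps, and returned in
    coordinate (N to C) order.
    """
    profiles = profiles if profiles is not None else default_profiles()
    seq = seq.upper()
    if not seq:
        return []
    bad = set(seq) - set(_AA) - {"X"}
    if bad:
        raise ValueError(f"sequence contains non-amino-acid letters: {sorted(bad)}")

    candidates: list[DomainHit] = []
    for profile in profiles.values():
        width = len(profile.consensus)
        cutoff = profile.threshold * profile.max_score
        scores = profile.scan_scores(seq)
        for start in np.flatnonzero(scores >= cutoff):
            candidates.append(
                DomainHit(profile.name, int(start) + 1, int(start) + width, float(scores[start]))
            )
    candidates.sort(key=lambda h: (-h.score, h.start, h.name))
    placed: list[DomainHit] = []
    for hit in candidates:
        if all(hit.end < p.start or hit.start > p.end for p in placed):
            placed.append(hit)
    placed.sort(key=lambda h: h.start)
    return placed


def classify_architecture(
    annotations: list[DomainHit], record_id: str = ""
) -> ArchitectureCall:
    """Structural type from domain presence and order.

    Type A: WWE, PARP core and RST present in N-to-C order.  Type B: PARP
    core and RST but no WWE.  Anything missing the PARP core or the RST
    domain is "incomplete" (the convention for truncated gene models).
    WWE-bearing full architectures hint at phylogenetic group I; the hint
    stays "unassigned" otherwise because group membership is a tree
    property, not an architecture one.
    """
    order = [h.name for h in sorted(annotations, key=lambda h: h.start)]
    has = set(order)
    if {"PARP_core", "RST"} <= has and "WWE" in has:
        ordered = (
            order.index("WWE") < order.index("PARP_core") < order.index("RST")
        )
        stype = "A" if ordered else "incomplete"
    elif {"PARP_core", "RST"} <= has:
        stype = "B" if order.index("PARP_core") < order.index("RST") else "incomplete"
    else:
        stype = "incomplete"
    hint = "I" if stype == "A" else "unassigned"
    return ArchitectureCall(
        record_id=record_id,
        domains=sorted(annotations, key=lambda h: h.start),
        structural_type=stype,
        group_hint=hint,
    )


def assign_names(
    species_abbr: str,
    calls: list[ArchitectureCall],
    existing: dict[str, str] | None = None,
) -> dict[str, str]:
    """Assign SRO-family names by the unified nomenclature rules.

    (i) records present in the ``existing`` registry (the A. thaliana
    proteins) retain their current names; (ii) every other family member is
    named SRO prefixed with the two-letter species abbreviation; (iii) the
    number is 1 for phylogenetic group I and 2 for group II; (iv) when
    several records within a species share a number they get letter
    suffixes a, b, c... in order of discovery (input order).
    """
    if not species_abbr:
        raise ValueError("species abbreviation must be non-empty")
    existing = existing or {}
    number_for = {"I": "1", "II": "2"}
    by_group: dict[str, list[ArchitectureCall]] = {"I": [], "II": []}
    names: dict[str, str] = {}
    for call in calls:
        if call.record_id in existing:
            names[call.record_id] = existing[call.record_id]
            continue
        if call.group not in number_for:
            raise ValueError(
                f"record {call.record_id!r} has no group I/II assignment"
            )
        by_group[call.group].append(call)
    for group, members in by_group.items():
        if len(members) > 26:
            raise ValueError(f"more than 26 group {group} members; suffixes exhausted")
        for idx, call in enumerate(members):
            suffix = "" if len(members) == 1 else chr(ord("a") + idx)
            names[call.record_id] = f"{species_abbr}SRO{number_for[group]}{suffix}"
    return names


def annotate_conservation(msa: list[tuple[str, str]] | list[str]) -> ConservationRow:
    """Clustal-style conservation symbols and property classes per column.

    '*' marks columns with a single residue across all sequences, ':' columns
    whose residues all fall in one strong similarity group, '.' one weak
    group, blank otherwise; any gap voids the column's symbol.  The property
    class reports the biochemical palette category shared by the whole
    column (tyrosine, glycine, positive, acidic, hydrophobic or
    polar-noncharged), or "none".
    """
    seqs = [s[1] if isinstance(s, tuple) else s for s in msa]
    if not seqs:
        raise ValueError("empty alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")

    symbols = []
    classes = []
    for col in range(length):
        residues = {s[col].upper() for s in seqs}
        if "-" in residues or "." in residues:
            symbols.append(" ")
            classes.append("none")
            continue
        if len(residues) == 1:
            symbols.append("*")
        elif any(residues <= set(g) for g in STRONG_GROUPS):
            symbols.append(":")
        elif any(residues <= set(g) for g in WEAK_GROUPS):
            symbols.append(".")
        else:
            symbols.append(" ")
        for cname, members in _PROPERTY_CLASSES:
            if residues <= members:
                classes.append(cname)
                break
        else:
            classes.append("none")
    return ConservationRow(symbols="".join(symbols), property_classes=classes)
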