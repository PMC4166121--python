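"""SP/TP proline-directed kinase motif logic for phosphosite assignment.

MAPKs (ERK, p38, JNK) phosphorylate serine or threonine residues that are
immediately followed by proline.  When mass spectrometry localizes a
phosphate only to a set of candidate S/T residues within a peptide, the
motif constraint often disambiguates the site: candidates not followed by
proline cannot be MAPK targets, and if the number of motif-consistent
candidates equals the number of observed phosphates the assignment is
unique.  An in-silico tryptic digest supports building peptide-level
evidence from a protein sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "PhosphoPeptide",
    "SiteCall",
    "Peptide",
    "scan_motif",
    "resolve_ambiguity",
    "tryptic_digest",
    "count_unique_sites",
]

_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
_ALPHABET = _AMINO_ACIDS | {"X"}  # X allowed, never part of a motif


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = sorted(set(seq) - _ALPHABET)
    if bad:
        raise ValueError(f"invalid amino-acid symbols: {', '.join(bad)}")
    return seq


@dataclass(frozen=True)
class PhosphoPeptide:
    """A peptide with MS phospho-localization evidence.

    ``candidate_positions`` are 1-based indices of S/T residues the spectra
    flag as possibly phosphorylated; ``n_phospho`` is the observed number of
    phosphates on the peptide; ``parent_offset`` shifts positions into the
    parent protein's numbering (0 when the peptide stands alone).
    """

    sequence: str
    candidate_positions: frozenset[int]
    n_phospho: int = 1
    parent_offset: int = 0

    def __post_init__(self) -> None:
        seq = _validate_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(
            self, "candidate_positions", frozenset(self.candidate_positions)
        )
        for pos in self.candidate_positions:
            if not (1 <= pos <= len(seq)):
                raise ValueError(f"candidate position {pos} outside peptide")
            if seq[pos - 1] not in "ST":
                raise ValueError(
                    f"candidate position {pos} is {seq[pos - 1]}, not S/T"
                )
        if not (0 <= self.n_phospho <= len(self.candidate_positions)):
            raise ValueError(
                f"n_phospho={self.n_phospho} exceeds the "
                f"{len(self.candidate_positions)} candidate positions"
            )


@dataclass(frozen=True)
class SiteCall:
    """Motif-resolved status of one candidate phosphosite.

    ``position`` is 1-based in the parent protein when the peptide carries a
    ``parent_offset``; ``status`` is ``unique`` (single consistent
    assignment), ``ambiguous`` (more motif-consistent candidates than
    phosphates), or ``none`` (no motif-consistent assignment);
    ``inconsistent`` flags evidence that cannot be explained by the motif
    (fewer consistent candidates than observed phosphates).
    """

    position: int
    residue: str
    status: str
    inconsistent: bool = False

    def __post_init__(self) -> None:
        if self.residue not in "ST":
            raise ValueError(f"residue must be S or T, got {self.residue!r}")
        if self.status not in ("unique", "ambiguous", "none"):
            raise ValueError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class Peptide:
    """A digest product with 1-based inclusive parent coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0


def scan_motif(sequence: str) -> list[int]:
    """1-based positions of S/T residues immediately followed by P.

    The last residue can never match (no following residue).  Raises for
    symbols outside the 20-letter alphabet plus X; X never matches.
    """
    seq = _validate_sequence(sequence)
    return [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "ST" and seq[i + 1] == "P"
    ]


def resolve_ambiguity(peptide: PhosphoPeptide) -> list[SiteCall]:
    """Resolve candidate phosphosites against the SP/TP motif.

    Intersects the candidates with the peptide's motif positions.  If the
    intersection size equals ``n_phospho`` every intersecting site is
    called ``unique``; if larger, all are ``ambiguous``; if smaller, the
    observation cannot be explained by proline-directed phosphorylation and
    every candidate is returned with status ``none`` and the
    ``inconsistent`` flag set.  Positions are reported in parent-protein
    coordinates via ``parent_offset``.
    """
    motif = set(scan_motif(peptide.sequence))
    consistent = sorted(peptide.candidate_positions & motif)
    off = peptide.parent_offset

    if len(consistent) < peptide.n_phospho:
        return [
            SiteCall(
                position=pos + off,
                residue=peptide.sequence[pos - 1],
                status="none",
                inconsistent=True,
            )
            for pos in sorted(peptide.candidate_positions)
        ]
    status = "unique" if len(consistent) == peptide.n_phospho else "ambiguous"
    return [
        SiteCall(
            position=pos + off,
            residue=peptide.sequence[pos - 1],
            status=status,
        )
        for pos in consistent
    ]


def tryptic_digest(sequence: str, missed_cleavages: int = 0) -> list[Peptide]:
    """In-silico trypsin digest: cleave C-terminal to K/R except before P.

    Returns peptides with 1-based inclusive coordinates on the input.  With
    ``missed_cleavages`` up to 2, products spanning that many skipped
    cleavage sites are appended after the fully cleaved set.
    """
    seq = _validate_sequence(sequence)
    if not seq:
        raise ValueError("empty sequence")
    if not (0 <= missed_cleavages <= 2):
        raise ValueError("missed_cleavages must be in 0..2")

    cut_after = [
        i
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    starts = [0] + [i + 1 for i in cut_after]
    ends = [i + 1 for i in cut_after] + [len(seq)]

    peptides = [
        Peptide(sequence=seq[s:e], start=s + 1, end=e, missed_cleavages=0)
        for s, e in zip(starts, ends)
    ]
    for mc in range(1, missed_cleavages + 1):
        for i in range(len(starts) - mc):
            s, e = starts[i], ends[i + mc]
            peptides.append(
                Peptide(sequence=seq[s:e], start=s + 1, end=e, missed_cleavages=mc)
            )
    return peptides


def count_unique_sites(calls: Iterable[SiteCall] | Sequence[SiteCall]) -> int:
    """Number of distinct positions carrying a ``unique`` call."""
    return len({c.position for c in calls if c.status == "unique"})
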