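"""Phospho-annotated peptide parsing and 14-3-3 binding-mode classification.

14-3-3 proteins recognize phosphorylated Ser/Thr within three canonical
sequence contexts:

* mode I   — ``R-X-X-pS/pT-X-P``  (Arg at −3, Pro at +2)
* mode II  — ``R-X-(Y/F)-X-pS/pT-X-P``  (Arg at −5, aromatic at −3, Pro at +2)
* mode III — C-terminal ``X-X-pS/pT-X-COOH`` (phosphosite penultimate, free
  acid C-terminus)

Peptides are written in a simple text dialect: uppercase one-letter codes
with each phosphosite tagged as ``pS``/``pT``, an optional ``Ac-`` or
``FAM-Ahx-`` prefix and an optional ``-NH2`` or ``-OH`` suffix, e.g.
``Ac-DCRRTIpSAPVVRPK-NH2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AMINO_ACIDS",
    "PeptideRecord",
    "MotifMatch",
    "NotationError",
    "parse_phosphopeptide",
    "scan_modes",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_N_TERM = {"Ac-": "acetyl", "FAM-Ahx-": "FAM-Ahx", "X-": "acetyl"}
_C_TERM = {"-NH2": "amide", "-OH": "free-acid"}


class NotationError(ValueError):
    """Malformed phosphopeptide notation (bad phospho tag or unknown letter)."""


@dataclass(frozen=True)
class PeptideRecord:
    """A phospho-annotated peptide with terminal chemistry.

    ``phospho_positions`` are 1-based local indices into ``residues``;
    ``protein_offset`` maps local index 1 onto full-protein numbering
    (e.g. 361 for hDMX residues 361-374) and is reporting-only.
    """

    id: str
    residues: str
    phospho_positions: tuple[int, ...] = ()
    protein_offset: int = 1
    n_terminus: str = "free"
    c_terminus: str = "free-acid"

    def __post_init__(self):
        if not self.residues:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise NotationError(f"unknown residue letter(s) {sorted(bad)} in {self.id!r}")
        if self.n_terminus not in {"acetyl", "FAM-Ahx", "free"}:
            raise ValueError(f"invalid n_terminus {self.n_terminus!r}")
        if self.c_terminus not in {"amide", "free-acid"}:
            raise ValueError(f"invalid c_terminus {self.c_terminus!r}")
        prev = 0
        for pos in self.phospho_positions:
            if not 1 <= pos <= len(self.residues):
                raise ValueError(f"phospho position {pos} outside sequence of length {len(self.residues)}")
            if pos <= prev:
                raise ValueError("phospho positions must be strictly increasing")
            if self.residues[pos - 1] not in "ST":
                raise NotationError(
                    f"phospho position {pos} is {self.residues[pos - 1]!r}, not S/T"
                )
            prev = pos

    def protein_position(self, local_pos: int) -> int:
        """Full-protein residue number for a 1-based local index."""
        return self.protein_offset + local_pos - 1


@dataclass(frozen=True)
class MotifMatch:
    """Mode classification of one phosphosite.

    ``anchor_offsets`` maps each individually satisfied anchor (by name,
    e.g. ``'Arg'`` for Arg at −3) to its signed offset relative to the
    phospho residue, whether or not a full mode matched.
    """

    phospho_position: int
    mode: str  # one of "I", "II", "III", "none"
    anchor_offsets: dict = field(default_factory=dict)


def parse_phosphopeptide(notation: str, *, id: str | None = None, protein_offset: int = 1) -> PeptideRecord:
    """Parse the phosphopeptide text dialect into a :class:`PeptideRecord`.

    Examples
    --------
    >>> p = parse_phosphopeptide("Ac-DCRRTIpSAPVVRPK-NH2", protein_offset=361)
    >>> p.residues, p.phospho_positions, p.n_terminus, p.c_terminus
    ('DCRRTISAPVVRPK', (7,), 'acetyl', 'amide')
    """
    text = notation.strip()
    n_term = "free"
    for prefix, name in _N_TERM.items():
        if text.startswith(prefix):
            n_term = name
            text = text[len(prefix):]
            break
    c_term = "free-acid"
    for suffix, name in _C_TERM.items():
        if text.endswith(suffix):
            c_term = name
            text = text[: -len(suffix)]
            break

    residues = []
    phospho = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "p":
            if i + 1 >= len(text) or text[i + 1] not in "ST":
                nxt = text[i + 1] if i + 1 < len(text) else "<end>"
                raise NotationError(f"phospho tag 'p' before {nxt!r}; only pS/pT allowed")
            residues.append(text[i + 1])
            phospho.append(len(residues))
            i += 2
            continue
        if ch not in AMINO_ACIDS:
            raise NotationError(f"unknown residue letter {ch!r} in {notation!r}")
        residues.append(ch)
        i += 1

    return PeptideRecord(
        id=id if id is not None else notation,
        residues="".join(residues),
        phospho_positions=tuple(phospho),
        protein_offset=protein_offset,
        n_terminus=n_term,
        c_terminus=c_term,
    )


def _residue_at(seq: str, pos: int, offset: int) -> str | None:
    """Residue at signed *offset* from 1-based *pos*, or None if outside."""
    i = pos + offset
    if 1 <= i <= len(seq):
        return seq[i - 1]
    return None


def scan_modes(p: PeptideRecord) -> list[MotifMatch]:
    """Classify every phosphosite of *p* into binding mode I, II, III or none.

    Mode II is tested before mode I (its anchor set is the more specific
    superset), and mode III last; mode III additionally requires a free-acid
    C-terminus with the phosphosite penultimate. One :class:`MotifMatch` is
    returned per phosphosite; sites matching no full mode report whichever
    individual anchors they do satisfy.
    """
    matches = []
    seq = p.residues
    for pos in p.phospho_positions:
        anchors = {}
        if _residue_at(seq, pos, -3) == "R":
            anchors["Arg"] = -3
        if _residue_at(seq, pos, +2) == "P":
            anchors["Pro"] = +2
        if _residue_at(seq, pos, -5) == "R":
            anchors["Arg-5"] = -5
        if _residue_at(seq, pos, -3) in ("Y", "F"):
            anchors["Aromatic"] = -3
        c_terminal = pos == len(seq) - 1 and p.c_terminus == "free-acid"
        if c_terminal:
            anchors["C-terminal"] = +1

        full_window_ii = pos - 5 >= 1 and pos + 2 <= len(seq)
        full_window_i = pos - 3 >= 1 and pos + 2 <= len(seq)
        if full_window_ii and "Arg-5" in anchors and "Aromatic" in anchors and "Pro" in anchors:
            mode = "II"
        elif full_window_i and "Arg" in anchors and "Pro" in anchors:
            mode = "I"
        elif c_terminal:
            mode = "III"
        else:
            mode = "none"
        matches.append(MotifMatch(phospho_position=pos, mode=mode, anchor_offsets=anchors))
    return matches
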