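"""Germline V/J segment model on IMGT unique numbering.

The IMGT unique numbering assigns every variable-domain residue a fixed
position (1..104 for the V region up to the conserved Cys, 105..117 for
CDR3, 118.. for FR4 starting at the conserved Phe/Trp) by padding each
germline sequence with alignment gaps at scheme-defined positions.  A
:class:`GermlineSegment` stores the gapped nucleotide sequence, so the
IMGT position of any residue is recoverable by codon counting, and the
anchor residues (Cys-104 on V, Phe-118 / F-G-X-G on J) as offsets into
the ungapped sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

GAP = "."

#: IMGT position of the conserved V-region cysteine (junction 5' anchor).
CYS104 = 104
#: IMGT position of the conserved J-region phenylalanine/tryptophan
#: (junction 3' anchor, first residue of the F-G-X-G motif).
PHE118 = 118

#: Number of codon slots in the gapped V region (IMGT positions 1..104).
V_REGION_POSITIONS = 104

#: Standard hydrophobic/nonpolar residues (used by the signature rule).
NONPOLAR_AA = frozenset("GAVLIPFMW")


@dataclass(frozen=True)
class GermlineSegment:
    """A named germline V or J allele with IMGT-gapped sequence.

    Parameters
    ----------
    name:
        Allele identifier, e.g. ``"IGLV1-44*01"`` or ``"IGLJ3*02"``.
    gapped_seq:
        Nucleotide string over ``{A,C,G,T,.}``; ``.`` marks IMGT gaps.
        For V segments the string is framed in codons from IMGT position
        1, so slot ``i`` (0-based codon index) is IMGT position ``i+1``.
        J segments carry no gaps.
    segment_class:
        ``"V"`` or ``"J"``.
    anchors:
        Map from anchor role (``"CYS104"`` for V; ``"PHE118"`` and
        ``"FGXG"`` for J) to the 0-based nucleotide offset of the anchor
        codon start within the *ungapped* sequence.
    """

    name: str
    gapped_seq: str
    segment_class: str
    anchors: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.segment_class not in ("V", "J"):
            raise ValueError(f"segment_class must be V or J, got {self.segment_class!r}")
        if set(self.gapped_seq) - set("ACGT" + GAP):
            raise ValueError(f"{self.name}: invalid characters in gapped sequence")
        if self.segment_class == "V" and len(self.gapped_seq) % 3 != 0:
            raise ValueError(f"{self.name}: gapped V sequence not codon-framed")

    @property
    def seq(self) -> str:
        """Ungapped nucleotide sequence."""
        return self.gapped_seq.replace(GAP, "")

    @property
    def gene(self) -> str:
        """Gene name with the allele suffix stripped (``IGLV1-44*01`` -> ``IGLV1-44``)."""
        return self.name.split("*")[0]

    @property
    def locus(self) -> str:
        """Chain locus inferred from the name prefix (IGH, IGL or IGK)."""
        return self.name[:3]

    # ---- IMGT coordinate bookkeeping (V segments) -------------------

    def imgt_positions(self) -> dict[int, int]:
        """Map IMGT position -> 0-based ungapped nt offset of its codon start.

        Only defined for V segments; gap slots are absent from the map.
        """
        if self.segment_class != "V":
            raise ValueError("IMGT positions are defined on V segments only")
        out: dict[int, int] = {}
        offset = 0
        for slot in range(len(self.gapped_seq) // 3):
            codon = self.gapped_seq[3 * slot : 3 * slot + 3]
            if codon == GAP * 3:
                continue
            if GAP in codon:
                raise ValueError(f"{self.name}: partial gap codon at slot {slot}")
            out[slot + 1] = offset
            offset += 3
        return out

    def imgt_aa(self) -> dict[int, str]:
        """Translate the gapped V template: IMGT position -> germline amino acid."""
        seq = self.seq
        return {
            pos: str(Seq(seq[off : off + 3]).translate())
            for pos, off in self.imgt_positions().items()
            if off + 3 <= len(seq)
        }


def index_by_name(refs: list[GermlineSegment]) -> dict[str, GermlineSegment]:
    return {r.name: r for r in refs}


def select_class(refs: list[GermlineSegment], segment_class: str, locus: str | None = None) -> list[GermlineSegment]:
    """Subset a reference list by segment class and (optionally) locus."""
    out = [r for r in refs if r.segment_class == segment_class]
    if locus is not None:
        out = [r for r in out if r.locus == locus]
    return out
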