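"""Per-cell Ig transcript annotation.

Each transcript is assigned its best germline V and J segment by local
affine-gap alignment, the CDR3/junction is delineated from the conserved
anchors (Cys-104 on V, Phe-118 on J) mapped through the alignments, and
the V region is projected onto IMGT unique numbering so substitutions
can be called in a fixed coordinate system.

Scoring scheme (nucleotide): match +2, mismatch -2, gap open -6, gap
extend -1, configurable via :class:`AlignmentConfig`.  Candidate
references can be prescreened by edit distance (edlib) before the affine
alignment — the reported alignment and score always come from the affine
aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
from Bio import Align
from Bio.Seq import Seq

from .germline import CYS104, PHE118, GermlineSegment, select_class
from .synthetic_data import SimulatedCohort

UNASSIGNED = "unassigned"

#: Minimum transcript length for a V / J segment search.
MIN_V_QUERY = 50
MIN_J_QUERY = 15


@dataclass(frozen=True)
class AlignmentConfig:
    match: int = 2
    mismatch: int = -2
    gap_open: int = -6
    gap_extend: int = -1
    #: Minimum percent identity (0..1) for a segment call.
    identity_floor: float = 0.80
    #: Edit-distance slack when prescreening candidate references; any
    #: reference within ``prescreen_margin`` edits of the best candidate
    #: is still affine-aligned.
    prescreen_margin: int = 20

    def aligner(self) -> Align.PairwiseAligner:
        return Align.PairwiseAligner(
            mode="local",
            match_score=self.match,
            mismatch_score=self.mismatch,
            open_gap_score=self.gap_open,
            extend_gap_score=self.gap_extend,
        )


DEFAULT_ALIGN = AlignmentConfig()


@dataclass
class SegmentAlignment:
    """Local alignment of a transcript against one germline segment."""

    query_id: str
    segment_name: str
    score: int
    query_start: int
    query_end: int
    segment_start: int
    segment_end: int
    identity: float
    #: CIGAR-like edit string over {=, X, I, D}; I = insertion in the
    #: query relative to the segment, D = deletion.
    edit_string: str
    #: Aligned blocks [((qstart, qend), (sstart, send)), ...], gap-free.
    blocks: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)

    def map_segment_interval(self, start: int, end: int) -> tuple[int, int] | None:
        """Map a gap-free segment interval onto query coordinates.

        Returns the query interval, or None when the interval is not
        covered contiguously inside a single aligned block.
        """
        for (qs, _qe), (ss, se) in self.blocks:
            if ss <= start and end <= se:
                off = qs - ss
                return start + off, end + off
        return None


def _edit_string(query: str, seg: str, blocks) -> tuple[str, int, int]:
    """Build the edit string; returns (edits, n_match, n_columns)."""
    ops: list[str] = []
    matches = columns = 0
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in blocks:
        if prev_q is not None:
            dq, ds = qs - prev_q, ss - prev_s
            if dq:
                ops.append(f"{dq}I")
                columns += dq
            if ds:
                ops.append(f"{ds}D")
                columns += ds
        run_op, run_len = None, 0
        for i in range(qe - qs):
            op = "=" if query[qs + i] == seg[ss + i] else "X"
            if op == run_op:
                run_len += 1
            else:
                if run_op:
                    ops.append(f"{run_len}{run_op}")
                run_op, run_len = op, 1
            matches += op == "="
            columns += 1
        if run_op:
            ops.append(f"{run_len}{run_op}")
        prev_q, prev_s = qe, se
    return "".join(ops), matches, columns


def score_edit_string(edits: str, cfg: AlignmentConfig = DEFAULT_ALIGN) -> int:
    """Re-compute the alignment score implied by an edit string."""
    score = 0
    num = ""
    for ch in edits:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            score += n * cfg.match
        elif ch == "X":
            score += n * cfg.mismatch
        else:  # I or D
            score += cfg.gap_open + (n - 1) * cfg.gap_extend
    return score


def align_pair(
    transcript: str,
    ref: GermlineSegment,
    cfg: AlignmentConfig = DEFAULT_ALIGN,
    query_id: str = "query",
) -> SegmentAlignment:
    """Optimal local affine-gap alignment of a transcript to one segment."""
    aln = cfg.aligner().align(transcript, ref.seq)[0]
    t_blocks, s_blocks = aln.aligned
    blocks = [((int(t[0]), int(t[1])), (int(s[0]), int(s[1]))) for t, s in zip(t_blocks, s_blocks)]
    edits, matches, columns = _edit_string(transcript, ref.seq, blocks)
    return SegmentAlignment(
        query_id=query_id,
        segment_name=ref.name,
        score=int(aln.score),
        query_start=blocks[0][0][0],
        query_end=blocks[-1][0][1],
        segment_start=blocks[0][1][0],
        segment_end=blocks[-1][1][1],
        identity=matches / columns if columns else 0.0,
        edit_string=edits,
        blocks=blocks,
    )


def align_to_segments(
    transcript: str,
    refs: list[GermlineSegment],
    segment_class: str,
    cfg: AlignmentConfig = DEFAULT_ALIGN,
    query_id: str = "query",
    prescreen: bool = False,
) -> list[SegmentAlignment]:
    """Rank germline segments of one class against a transcript.

    Returns affine local alignments sorted by score descending, ties
    broken lexicographically by allele name.  With ``prescreen``, only
    references within ``prescreen_margin`` edlib edit distance of the
    best candidate are affine-aligned (the others cannot win).
    """
    candidates = [r for r in refs if r.segment_class == segment_class]
    min_len = MIN_V_QUERY if segment_class == "V" else MIN_J_QUERY
    if len(transcript) < min_len:
        raise ValueError(
            f"transcript too short for a {segment_class} search ({len(transcript)} < {min_len} nt)"
        )
    if prescreen and len(candidates) > 1:
        dists = [
            edlib.align(r.seq, transcript, mode="HW", task="distance")["editDistance"]
            for r in candidates
        ]
        best = min(dists)
        candidates = [r for r, d in zip(candidates, dists) if d <= best + cfg.prescreen_margin]
    alns = [align_pair(transcript, r, cfg, query_id) for r in candidates]
    alns.sort(key=lambda a: (-a.score, a.segment_name))
    return alns


def best_call(alns: list[SegmentAlignment], cfg: AlignmentConfig = DEFAULT_ALIGN) -> SegmentAlignment | None:
    """Top-ranked alignment, or None when the best identity is below the floor."""
    if not alns or alns[0].identity < cfg.identity_floor:
        return None
    return alns[0]


# --------------------------------------------------------------------
# IMGT numbering and CDR3 extraction
# --------------------------------------------------------------------

def imgt_number(transcript: str, v_aln: SegmentAlignment, ref: GermlineSegment) -> dict[int, str]:
    """Project the transcript onto IMGT positions via its V alignment.

    Each germline codon covered contiguously by the alignment donates its
    IMGT position to the transcript codon aligned to it; insertions in
    the transcript are excluded, deletions leave positions absent.
    """
    if v_aln.segment_name != ref.name:
        raise ValueError(f"alignment is against {v_aln.segment_name}, not {ref.name}")
    out: dict[int, str] = {}
    for pos, off in ref.imgt_positions().items():
        q = v_aln.map_segment_interval(off, off + 3)
        if q is None:
            continue
        aa = str(Seq(transcript[q[0] : q[1]]).translate())
        out[pos] = aa
    return out


class Cdr3Error(ValueError):
    """CDR3 delineation failed (anchor not covered or frame broken)."""


def extract_cdr3(
    transcript: str,
    v_aln: SegmentAlignment,
    j_aln: SegmentAlignment,
    v_ref: GermlineSegment,
    j_ref: GermlineSegment,
) -> tuple[str, str, str, str]:
    """Delineate the CDR3 between the Cys-104 and Phe-118 anchors.

    Returns ``(cdr3_nt, cdr3_aa, junction_nt, junction_aa)``; the CDR3
    spans IMGT 105..117, the junction additionally includes both anchor
    codons.  Raises :class:`Cdr3Error` when an anchor codon is not
    covered by its alignment or the junction is out of frame.
    """
    cys = v_ref.anchors["CYS104"]
    q_cys = v_aln.map_segment_interval(cys, cys + 3)
    if q_cys is None:
        raise Cdr3Error("Cys-104 codon not covered by the V alignment")
    phe = j_ref.anchors["PHE118"]
    q_phe = j_aln.map_segment_interval(phe, phe + 3)
    if q_phe is None:
        raise Cdr3Error("Phe/Trp-118 codon not covered by the J alignment")
    if q_phe[0] < q_cys[1]:
        raise Cdr3Error("J anchor precedes the end of the V region")
    junction_nt = transcript[q_cys[0] : q_phe[1]]
    if len(junction_nt) % 3 != 0:
        raise Cdr3Error("junction out of frame")
    junction_aa = str(Seq(junction_nt).translate())
    cdr3_nt = transcript[q_cys[1] : q_phe[0]]
    cdr3_aa = junction_aa[1:-1]
    return cdr3_nt, cdr3_aa, junction_nt, junction_aa


# --------------------------------------------------------------------
# Cell-level annotation
# --------------------------------------------------------------------

@dataclass
class ChainAnnotation:
    """One cell's reconstructed chain on IMGT coordinates."""

    barcode: str
    locus: str
    v_call: str
    j_call: str
    cdr3_nt: str = ""
    cdr3_aa: str = ""
    junction: str = ""
    junction_aa: str = ""
    imgt_aa: dict[int, str] = field(default_factory=dict)
    productive: bool = False
    v_score: int = 0
    v_identity: float = 0.0
    flags: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str, str]:
        """Clonotype key: (V call, J call, junction nt)."""
        return (self.v_call, self.j_call, self.junction)


@dataclass
class CellAnnotation:
    barcode: str
    chains: dict[str, ChainAnnotation] = field(default_factory=dict)
    is_doublet: bool = False
    no_chain: bool = False

    @property
    def light(self) -> ChainAnnotation | None:
        for locus in ("IGL", "IGK"):
            if locus in self.chains:
                return self.chains[locus]
        return None

    @property
    def heavy(self) -> ChainAnnotation | None:
        return self.chains.get("IGH")


def annotate_transcript(
    transcript: str,
    refs: list[GermlineSegment],
    locus: str,
    cfg: AlignmentConfig = DEFAULT_ALIGN,
    barcode: str = "",
    prescreen: bool = True,
) -> ChainAnnotation | None:
    """Annotate one transcript against the references of one locus."""
    v_refs = select_class(refs, "V", locus)
    j_refs = select_class(refs, "J", locus)
    if not v_refs or not j_refs or len(transcript) < MIN_V_QUERY:
        return None
    v_alns = align_to_segments(transcript, v_refs, "V", cfg, prescreen=prescreen)
    v_top = best_call(v_alns, cfg)
    if v_top is None:
        return None
    j_alns = align_to_segments(transcript, j_refs, "J", cfg, prescreen=prescreen)
    j_top = best_call(j_alns, cfg)
    v_ref = next(r for r in v_refs if r.name == v_top.segment_name)
    ann = ChainAnnotation(
        barcode=barcode,
        locus=locus,
        v_call=v_top.segment_name,
        j_call=j_top.segment_name if j_top else UNASSIGNED,
        imgt_aa=imgt_number(transcript, v_top, v_ref),
        v_score=v_top.score,
        v_identity=v_top.identity,
    )
    if j_top is None:
        ann.flags.append("no_j")
        return ann
    j_ref = next(r for r in j_refs if r.name == j_top.segment_name)
    try:
        cdr3_nt, cdr3_aa, junction, junction_aa = extract_cdr3(transcript, v_top, j_top, v_ref, j_ref)
    except Cdr3Error as exc:
        ann.flags.append(f"cdr3_fail:{exc}")
        return ann
    ann.cdr3_nt, ann.cdr3_aa = cdr3_nt, cdr3_aa
    ann.junction, ann.junction_aa = junction, junction_aa
    if not cdr3_aa:
        ann.flags.append("empty_cdr3")
    in_frame = len(junction) % 3 == 0
    no_stop = "*" not in junction_aa and "*" not in ann.imgt_aa.values()
    ann.productive = in_frame and no_stop and ann.imgt_aa.get(CYS104) == "C"
    return ann


def annotate_cell(
    barcode: str,
    transcripts: dict[str, list[str]],
    refs: list[GermlineSegment],
    cfg: AlignmentConfig = DEFAULT_ALIGN,
    _cache: dict | None = None,
) -> CellAnnotation:
    """Annotate all of one cell's transcripts.

    ``transcripts`` maps locus -> candidate transcript list.  When a
    locus has several candidates the highest V-score one wins (ties:
    longest transcript, then lexicographic); a cell with two distinct
    productive light-chain junctions is flagged as a suspected doublet.
    """
    cell = CellAnnotation(barcode=barcode)
    for locus, seqs in transcripts.items():
        anns = []
        for seq in seqs:
            if _cache is not None and (locus, seq) in _cache:
                base = _cache[(locus, seq)]
                ann = replace(base, barcode=barcode) if base is not None else None
            else:
                ann = annotate_transcript(seq, refs, locus, cfg, barcode=barcode)
                if _cache is not None:
                    _cache[(locus, seq)] = ann
            if ann is not None:
                anns.append((ann, seq))
        if not anns:
            continue
        anns.sort(key=lambda t: (-t[0].v_score, -len(t[1]), t[1]))
        cell.chains[locus] = anns[0][0]
        if locus in ("IGL", "IGK"):
            productive_junctions = {a.junction for a, _ in anns if a.productive and a.junction}
            if len(productive_junctions) > 1:
                cell.is_doublet = True
    if not cell.chains:
        cell.no_chain = True
    return cell


def annotate_cohort(
    cohort: SimulatedCohort,
    cfg: AlignmentConfig = DEFAULT_ALIGN,
    loci: tuple[str, ...] | None = None,
) -> list[CellAnnotation]:
    """Annotate every cell of a simulated cohort (with transcript dedupe)."""
    cache: dict = {}
    out = []
    for cell in cohort.cells:
        transcripts: dict[str, list[str]] = {}
        for locus, seq in cell.transcripts.items():
            if loci is None or locus in loci:
                transcripts.setdefault(locus, []).append(seq)
        for locus, seq in cell.extra_transcripts.items():
            if loci is None or locus in loci:
                transcripts.setdefault(locus, []).append(seq)
        out.append(annotate_cell(cell.barcode, transcripts, cohort.reference, cfg, _cache=cache))
    return out


def to_airr_table(cells: list[CellAnnotation]):
    """AIRR-style rearrangement table (one row per annotated chain)."""
    import pandas as pd

    rows = []
    for cell in cells:
        for locus, ann in sorted(cell.chains.items()):
            rows.append(
                {
                    "cell_id": cell.barcode,
                    "locus": locus,
                    "v_call": ann.v_call,
                    "j_call": ann.j_call,
                    "junction": ann.junction,
                    "junction_aa": ann.junction_aa,
                    "cdr3_aa": ann.cdr3_aa,
                    "productive": ann.productive,
                    "doublet": cell.is_doublet,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "locus", "v_call", "j_call", "junction",
            "junction_aa", "cdr3_aa", "productive", "doublet",
        ],
    )
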