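"""Germline substitution calling and the POEMS light-chain signature.

POEMS clones carry a characteristic lambda light chain: the V segment
comes from one of four IGLV1 families (1-36, 1-40, 1-44, 1-47), the J
segment is always IGLJ3*02, and two amino-acid substitutions relative to
germline sit at IMGT positions 38 (CDR1) and 40 (FR2): position 40 is
always changed to asparagine, while position 38 changes to a variable
but always nonpolar residue.  This module calls substitutions on IMGT
coordinates and classifies chains against that signature, including the
rescue of signature-positive singleton cells as putative clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .clonotypes import CloneCall, CloneCallResult, Clonotype
from .germline import NONPOLAR_AA, GermlineSegment
from .repertoire import CellAnnotation, ChainAnnotation

#: Lambda V families recurrently used by POEMS clones (gene level).
POEMS_V_GENES = frozenset({"IGLV1-36", "IGLV1-40", "IGLV1-44", "IGLV1-47"})

#: The J allele used by all POEMS clones (exact allele match).
POEMS_J_ALLELE = "IGLJ3*02"

#: Signature positions: 38 in CDR1, 40 in FR2 (IMGT unique numbering).
POS_38 = 38
POS_40 = 40


@dataclass
class SubstitutionProfile:
    """Amino-acid differences from germline on IMGT coordinates."""

    cell_id: str
    locus: str
    v_call: str
    j_call: str
    #: (IMGT position, germline aa, observed aa), germline != observed.
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    #: IMGT positions covered by both chain and germline template.
    covered: frozenset[int] = frozenset()

    def at(self, pos: int) -> tuple[str, str] | None:
        for p, germ, obs in self.substitutions:
            if p == pos:
                return germ, obs
        return None


@dataclass
class SignatureCall:
    cell_id: str
    verdict: bool
    v_family_ok: bool
    j_ok: bool
    pos38_nonpolar: bool
    pos40_asn: bool
    rule_mode: str
    coverage_warning: bool = False


def call_substitutions(chain: ChainAnnotation, ref: GermlineSegment) -> SubstitutionProfile:
    """Positions where the chain's residue differs from germline.

    Only positions covered by both the chain's IMGT map and the germline
    template are compared; partial coverage is recorded, not an error.
    """
    if chain.v_call != ref.name:
        raise ValueError(f"chain V call {chain.v_call} does not match reference {ref.name}")
    germ = ref.imgt_aa()
    covered = frozenset(chain.imgt_aa) & frozenset(germ)
    subs = [
        (pos, germ[pos], chain.imgt_aa[pos])
        for pos in sorted(covered)
        if chain.imgt_aa[pos] != germ[pos]
    ]
    return SubstitutionProfile(
        cell_id=chain.barcode,
        locus=chain.locus,
        v_call=chain.v_call,
        j_call=chain.j_call,
        substitutions=subs,
        covered=covered,
    )


def classify_poems_signature(profile: SubstitutionProfile, rule_mode: str = "strict") -> SignatureCall:
    """Classify a substitution profile against the POEMS signature.

    strict (default): positive iff V family and J allele match AND
    position 40 is substituted to Asn AND position 38 is substituted to a
    nonpolar residue.  either: positive iff V/J match and at least one of
    the two position criteria holds.  Missing coverage at 38/40 leaves
    the corresponding flag false and sets a coverage warning.
    """
    if rule_mode not in ("strict", "either"):
        raise ValueError(f"unknown rule mode {rule_mode!r}")
    v_family_ok = profile.v_call.split("*")[0] in POEMS_V_GENES
    j_ok = profile.j_call == POEMS_J_ALLELE
    s38 = profile.at(POS_38)
    s40 = profile.at(POS_40)
    pos38_nonpolar = s38 is not None and s38[1] in NONPOLAR_AA
    pos40_asn = s40 is not None and s40[1] == "N"
    if rule_mode == "strict":
        verdict = v_family_ok and j_ok and pos38_nonpolar and pos40_asn
    else:
        verdict = v_family_ok and j_ok and (pos38_nonpolar or pos40_asn)
    return SignatureCall(
        cell_id=profile.cell_id,
        verdict=verdict,
        v_family_ok=v_family_ok,
        j_ok=j_ok,
        pos38_nonpolar=pos38_nonpolar,
        pos40_asn=pos40_asn,
        rule_mode=rule_mode,
        coverage_warning=not ({POS_38, POS_40} <= profile.covered),
    )


def signature_calls_for_cohort(
    cells: list[CellAnnotation],
    refs: list[GermlineSegment],
    rule_mode: str = "strict",
) -> dict[str, SignatureCall]:
    """Per-cell signature calls on the light chain (by barcode)."""
    by_name = {r.name: r for r in refs}
    out: dict[str, SignatureCall] = {}
    for cell in cells:
        light = cell.light
        if light is None or light.v_call not in by_name:
            continue
        profile = call_substitutions(light, by_name[light.v_call])
        out[cell.barcode] = classify_poems_signature(profile, rule_mode)
    return out


def rescue_singletons(
    clone_result: CloneCallResult,
    signature_calls: dict[str, SignatureCall],
) -> CloneCallResult:
    """Promote signature-positive singleton cells to putative clones.

    A clonotype of one cell whose member is signature-positive is
    reported as a clone at fraction 1/total; cells already inside a
    flagged clone are untouched (no double counting).
    """
    calls = []
    for call in clone_result.calls:
        if (
            not call.is_clone
            and call.clonotype.size == 1
            and signature_calls.get(call.clonotype.members[0], None) is not None
            and signature_calls[call.clonotype.members[0]].verdict
        ):
            calls.append(replace(call, is_clone=True, rescued=True))
        else:
            calls.append(call)
    return CloneCallResult(calls=calls, n_cells=clone_result.n_cells, min_cells=clone_result.min_cells)
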