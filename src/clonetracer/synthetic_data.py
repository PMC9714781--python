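"""Synthetic cohorts with a planted plasma cell clone.

Generates everything the downstream stages consume, with known ground
truth: IMGT-gapped germline V/J scaffolds, per-cell Ig transcripts in
which one clonotype is planted at a configurable fraction, bulk
repertoire reads drawn from the same cells, and a gene-by-cell count
matrix with clone-specific marker shifts (CD19 down, HLA-DR down, CD38
low, MYC/CCND1 low-to-normal — the immunophenotype reported for POEMS
clones).

The germline scaffolds are randomly generated sequences that *conform*
to the IMGT conventions (gapped V alignment of identical length, Cys at
position 104, J with an F-G-X-G motif) but are not real database
alleles; only the names and the anchor structure follow the convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .germline import (
    CYS104,
    GAP,
    PHE118,
    V_REGION_POSITIONS,
    GermlineSegment,
    index_by_name,
    select_class,
)

# --------------------------------------------------------------------
# Genetic code helpers
# --------------------------------------------------------------------

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.items():
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)

_AMINO_ACIDS = sorted(set(_CODON_TABLE.values()) - {"*"})
_NT = "ACGT"


def _codon_for(aa: str, rng: np.random.Generator) -> str:
    codons = _AA_TO_CODONS[aa]
    return codons[rng.integers(len(codons))]


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(_AMINO_ACIDS[i] for i in rng.integers(len(_AMINO_ACIDS), size=n))


def _encode_aa(aa_seq: str, rng: np.random.Generator) -> str:
    return "".join(_codon_for(a, rng) for a in aa_seq)


# --------------------------------------------------------------------
# Germline scaffold construction
# --------------------------------------------------------------------

#: Codon slots of the gapped V region left as IMGT gaps.  Shared by every
#: scaffold so all gapped V sequences have identical length, as in a real
#: IMGT alignment.  Kept away from the conserved anchors (23, 41, 89, 104)
#: and the signature positions 38/40.
V_GAP_SLOTS = frozenset({10, 31, 32, 33, 60, 61, 73, 82})

#: Conserved residues forced onto every V scaffold (IMGT position -> aa).
V_CONSERVED = {23: "C", 41: "W", 89: "L", CYS104: "C"}

#: Germline residues at the signature positions 38/40 for the lambda
#: V families recurrently used by POEMS clones.  The 38/40 entries match
#: the germline side of the substitutions reported for each family
#: (IGLV1-40: D38/H40, IGLV1-44: T38/H40, IGLV1-47: Y38/Y40).
POEMS_V_FAMILIES = {
    "IGLV1-36": {38: "S", 40: "H"},
    "IGLV1-40": {38: "D", 40: "H"},
    "IGLV1-44": {38: "T", 40: "H"},
    "IGLV1-47": {38: "Y", 40: "Y"},
}

#: Number of codons a J scaffold contributes before the Phe-118 anchor.
J_TAIL_CODONS = 2


def _build_v_scaffold(name: str, fixed_aa: dict[int, str], rng: np.random.Generator) -> GermlineSegment:
    codons = []
    ungapped_offset = 0
    anchors = {}
    for pos in range(1, V_REGION_POSITIONS + 1):
        if pos in V_GAP_SLOTS:
            codons.append(GAP * 3)
            continue
        aa = fixed_aa.get(pos) or _AMINO_ACIDS[rng.integers(len(_AMINO_ACIDS))]
        codons.append(_codon_for(aa, rng))
        if pos == CYS104:
            anchors["CYS104"] = ungapped_offset
        ungapped_offset += 3
    return GermlineSegment(name=name, gapped_seq="".join(codons), segment_class="V", anchors=anchors)


def _build_j_scaffold(name: str, rng: np.random.Generator) -> GermlineSegment:
    # tail codons (3' end of CDR3 in a natural rearrangement), then the
    # conserved F-G-X-G motif starting at IMGT 118, then a short FR4.
    tail = _encode_aa(_random_aa(rng, J_TAIL_CODONS), rng)
    fgxg = (
        _codon_for("F", rng)
        + _codon_for("G", rng)
        + _codon_for(_AMINO_ACIDS[rng.integers(len(_AMINO_ACIDS))], rng)
        + _codon_for("G", rng)
    )
    fr4 = _encode_aa(_random_aa(rng, 3), rng)
    anchor = len(tail)
    return GermlineSegment(
        name=name,
        gapped_seq=tail + fgxg + fr4,
        segment_class="J",
        anchors={"PHE118": anchor, "FGXG": anchor},
    )


def build_germline_reference(
    v_count: int = 4,
    j_alleles: list[str] | None = None,
    seed: int = 0,
    locus: str = "IGL",
) -> list[GermlineSegment]:
    """Build a synthetic germline reference for one locus.

    For the lambda locus the first four V alleles are the POEMS-relevant
    families (IGLV1-36/-40/-44/-47, allele *01) with their germline
    residues fixed at IMGT positions 38 and 40; additional alleles get
    synthetic names.  Deterministic for a fixed seed.

    Parameters
    ----------
    v_count:
        Number of V alleles (>= 4 for the lambda locus, so the signature
        families are all present).
    j_alleles:
        J allele names; defaults to ``["IGLJ3*02", "IGLJ2*01"]`` for IGL
        and ``["IGHJ4*01"]`` for IGH.
    """
    if locus == "IGL" and v_count < 4:
        raise ValueError("v_count must be >= 4: the four POEMS lambda V families are required")
    if v_count < 1:
        raise ValueError("v_count must be >= 1")
    if j_alleles is None:
        j_alleles = ["IGLJ3*02", "IGLJ2*01"] if locus == "IGL" else ["IGHJ4*01"]

    rng = np.random.default_rng(seed)
    refs: list[GermlineSegment] = []
    names: list[str] = []
    if locus == "IGL":
        names.extend(f"{fam}*01" for fam in POEMS_V_FAMILIES)
    while len(names) < v_count:
        names.append(f"{locus}V{2 + len(names) % 6}-{10 + len(names)}*01")
    names = names[:v_count]
    for name in names:
        fixed = dict(V_CONSERVED)
        fixed.update(POEMS_V_FAMILIES.get(name.split("*")[0], {}))
        refs.append(_build_v_scaffold(name, fixed, rng))
    for jname in j_alleles:
        refs.append(_build_j_scaffold(jname, rng))
    return refs


# --------------------------------------------------------------------
# Simulation configuration
# --------------------------------------------------------------------

#: Default clone-specific marker shifts (log2 fold change in clone cells):
#: CD19 negative, HLA-DR low, CD38 lower, MYC/CCND1 low-to-normal.
DEFAULT_MARKER_EFFECTS = {
    "CD19": -5.0,
    "HLA-DRA": -4.0,
    "HLA-DRB1": -4.0,
    "CD38": -1.5,
    "MYC": -1.0,
    "CCND1": -1.0,
}

#: Marker genes always present in simulated count matrices.
MARKER_GENES = [
    "CD19", "SDC1", "CD38", "HLA-DRA", "HLA-DRB1",
    "MYC", "CCND1", "CCND2", "IRF4", "VEGFA", "IL6",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, fully determined by ``seed``."""

    n_cells: int = 100
    clone_fraction: float = 0.2
    clone_v_allele: str = "IGLV1-44*01"
    clone_j_allele: str = "IGLJ3*02"
    #: (IMGT position, germline aa, mutant aa) applied to every clone cell's
    #: light chain.  Defaults plant the POEMS signature on IGLV1-44.
    planted_substitutions: list[tuple[int, str, str]] = field(
        default_factory=lambda: [(38, "T", "P"), (40, "H", "N")]
    )
    #: CDR3 length in residues (IMGT 105..117).
    cdr3_length: int = 11
    #: Fixed clone CDR3 amino-acid sequence; random (seeded) when None.
    clone_cdr3_aa: str | None = None
    per_base_error_rate: float = 0.001
    include_heavy: bool = True
    #: Number of artificial doublets appended to the cohort (two nonclone
    #: cells' chains merged under one barcode).
    n_doublets: int = 0
    marker_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MARKER_EFFECTS))
    n_genes: int = 2000
    nb_dispersion: float = 0.3
    #: sdlog of the log-normal per-cell library-size multiplier.
    library_size_sdlog: float = 0.3
    bulk_read_depth: int = 10000
    bulk_read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.clone_fraction <= 1.0:
            raise ValueError("clone_fraction must lie in [0, 1]")
        if not 0.0 <= self.per_base_error_rate <= 0.05:
            raise ValueError("per_base_error_rate must lie in [0, 0.05]")
        if self.cdr3_length < 3:
            raise ValueError("cdr3_length must be >= 3 residues")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for pos, germ, mut in self.planted_substitutions:
            if germ == mut:
                raise ValueError(f"planted substitution at {pos} does not change the residue")

    @property
    def n_clone_cells(self) -> int:
        return int(math.floor(self.n_cells * self.clone_fraction + 0.5))


@dataclass
class CellRecord:
    """One simulated cell: barcode, truth label, transcripts per locus."""

    barcode: str
    is_clone: bool
    transcripts: dict[str, str]
    is_doublet: bool = False
    #: Extra chains carried by a doublet (locus -> second transcript).
    extra_transcripts: dict[str, str] = field(default_factory=dict)


@dataclass
class CohortTruth:
    """Planted ground truth, recorded before error injection."""

    clone_key: tuple[str, str, str] | None  # (v_call, j_call, junction nt)
    clone_junction_aa: str | None
    clone_cdr3_aa: str | None
    substitutions: list[tuple[int, str, str]]
    heavy_key: tuple[str, str, str] | None = None


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    reference: list[GermlineSegment]
    cells: list[CellRecord]
    truth: CohortTruth
    counts: "object | None" = None  # CountMatrix, filled by simulate_expression
    bulk_reads: list[str] | None = None

    @property
    def clone_barcodes(self) -> list[str]:
        return [c.barcode for c in self.cells if c.is_clone]


# --------------------------------------------------------------------
# Repertoire simulation
# --------------------------------------------------------------------

def _recombine(
    v: GermlineSegment,
    j: GermlineSegment,
    cdr3_aa: str,
    rng: np.random.Generator,
    substitutions: list[tuple[int, str, str]] | None = None,
) -> tuple[str, str, str]:
    """Assemble a transcript V + CDR3 codons + J(from Phe-118).

    Returns ``(transcript, junction_nt, junction_aa)`` where the junction
    spans Cys-104 .. Phe-118 inclusive.  Planted substitutions replace V
    codons at the given IMGT positions.
    """
    v_seq = v.seq
    if substitutions:
        pos_map = v.imgt_positions()
        germ_aa = v.imgt_aa()
        for pos, germ, mut in substitutions:
            if pos not in pos_map:
                raise ValueError(f"IMGT position {pos} is a gap slot in {v.name}")
            if germ_aa[pos] != germ:
                raise ValueError(
                    f"germline residue at IMGT {pos} of {v.name} is {germ_aa[pos]}, not {germ}"
                )
            off = pos_map[pos]
            v_seq = v_seq[:off] + _codon_for(mut, rng) + v_seq[off + 3 :]
    cdr3_nt = _encode_aa(cdr3_aa, rng)
    j_part = j.seq[j.anchors["PHE118"] :]
    transcript = v_seq + cdr3_nt + j_part
    cys = v_seq[v.anchors["CYS104"] : v.anchors["CYS104"] + 3]
    phe = j_part[:3]
    junction_nt = cys + cdr3_nt + phe
    junction_aa = _CODON_TABLE[cys] + cdr3_aa + _CODON_TABLE[phe]
    return transcript, junction_nt, junction_aa


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        base = chr(arr[i])
        alt = _NT[rng.integers(4)]
        while alt == base:
            alt = _NT[rng.integers(4)]
        arr[i] = ord(alt)
    return arr.tobytes().decode()


def simulate_repertoire(cfg: SimulationConfig, ref: list[GermlineSegment]) -> SimulatedCohort:
    """Simulate per-cell Ig transcripts with a planted clone.

    Clone cells share one light-chain (and, when ``include_heavy``, one
    heavy-chain) V-J recombination with a fixed CDR3 and carry the
    configured substitutions; nonclone cells draw independent V, J and a
    random CDR3.  Per-base substitution errors are applied last; truth is
    recorded before error injection.
    """
    rng = np.random.default_rng(cfg.seed)
    by_name = index_by_name(ref)
    vl = select_class(ref, "V", "IGL")
    jl = select_class(ref, "J", "IGL")
    if not vl or not jl:
        raise ValueError("reference must contain IGL V and J segments")
    if cfg.clone_v_allele not in by_name or cfg.clone_j_allele not in by_name:
        raise ValueError(
            f"clone alleles {cfg.clone_v_allele}/{cfg.clone_j_allele} not in the reference"
        )
    vh = select_class(ref, "V", "IGH")
    jh = select_class(ref, "J", "IGH")
    heavy = cfg.include_heavy and bool(vh) and bool(jh)

    n_clone = cfg.n_clone_cells
    clone_v = by_name[cfg.clone_v_allele]
    clone_j = by_name[cfg.clone_j_allele]
    clone_cdr3 = cfg.clone_cdr3_aa or _random_aa(rng, cfg.cdr3_length)
    if len(clone_cdr3) != cfg.cdr3_length:
        raise ValueError("clone_cdr3_aa length must equal cdr3_length")

    clone_tx, clone_junction, clone_junction_aa = _recombine(
        clone_v, clone_j, clone_cdr3, rng, cfg.planted_substitutions
    )
    truth = CohortTruth(
        clone_key=(clone_v.name, clone_j.name, clone_junction) if n_clone else None,
        clone_junction_aa=clone_junction_aa if n_clone else None,
        clone_cdr3_aa=clone_cdr3 if n_clone else None,
        substitutions=list(cfg.planted_substitutions),
    )
    if heavy:
        hv, hj = vh[0], jh[0]
        clone_htx, clone_hjunc, _ = _recombine(hv, hj, _random_aa(rng, cfg.cdr3_length), rng)
        truth.heavy_key = (hv.name, hj.name, clone_hjunc) if n_clone else None

    def random_light() -> str:
        v = vl[rng.integers(len(vl))]
        j = jl[rng.integers(len(jl))]
        tx, _, _ = _recombine(v, j, _random_aa(rng, cfg.cdr3_length), rng)
        return tx

    def random_heavy() -> str:
        v = vh[rng.integers(len(vh))]
        j = jh[rng.integers(len(jh))]
        tx, _, _ = _recombine(v, j, _random_aa(rng, cfg.cdr3_length), rng)
        return tx

    cells: list[CellRecord] = []
    for i in range(cfg.n_cells):
        is_clone = i < n_clone
        tx = {"IGL": clone_tx if is_clone else random_light()}
        if heavy:
            tx["IGH"] = clone_htx if is_clone else random_heavy()
        cells.append(CellRecord(barcode=f"CELL{i:04d}", is_clone=is_clone, transcripts=tx))
    for d in range(cfg.n_doublets):
        tx = {"IGL": random_light()}
        extra = {"IGL": random_light()}
        if heavy:
            tx["IGH"] = random_heavy()
        cells.append(
            CellRecord(
                barcode=f"DBLT{d:04d}",
                is_clone=False,
                transcripts=tx,
                is_doublet=True,
                extra_transcripts=extra,
            )
        )

    err_rng = np.random.default_rng(rng.integers(2**31))
    for cell in cells:
        cell.transcripts = {
            loc: _inject_errors(s, cfg.per_base_error_rate, err_rng)
            for loc, s in cell.transcripts.items()
        }
        cell.extra_transcripts = {
            loc: _inject_errors(s, cfg.per_base_error_rate, err_rng)
            for loc, s in cell.extra_transcripts.items()
        }
    return SimulatedCohort(config=cfg, reference=ref, cells=cells, truth=truth)


# --------------------------------------------------------------------
# Expression simulation
# --------------------------------------------------------------------

def simulate_expression(cfg: SimulationConfig, cohort: SimulatedCohort):
    """Draw a gene-by-cell NB count matrix with clone-specific marker shifts.

    Counts follow NB(mean = base_mean * libsize * 2^effect, dispersion
    ``nb_dispersion``); the marker effect applies in clone cells only.
    Returns a :class:`~clonetracer.expression.CountMatrix` (also stored on
    the cohort).
    """
    from .expression import CountMatrix  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed + 1)
    genes = list(MARKER_GENES)
    for g in cfg.marker_effects:
        if g not in genes:
            raise ValueError(f"marker gene {g!r} absent from the simulated gene index")
    while len(genes) < cfg.n_genes:
        genes.append(f"GENE{len(genes):05d}")
    genes = genes[: max(cfg.n_genes, len(MARKER_GENES))]

    cells = [c.barcode for c in cohort.cells]
    labels = np.array([c.is_clone for c in cohort.cells])
    base = rng.lognormal(mean=np.log(20.0), sigma=1.2, size=len(genes))
    # markers get solid expression so planted shifts are detectable
    base[: len(MARKER_GENES)] = rng.uniform(40.0, 120.0, size=len(MARKER_GENES))
    libsize = rng.lognormal(mean=0.0, sigma=cfg.library_size_sdlog, size=len(cells))

    log2fc = np.zeros((len(genes), len(cells)))
    gidx = {g: i for i, g in enumerate(genes)}
    for g, eff in cfg.marker_effects.items():
        log2fc[gidx[g], labels] = eff
    mu = base[:, None] * libsize[None, :] * np.exp2(log2fc)
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix.from_arrays(
        counts, genes, cells,
        groups={c.barcode: ("clone" if c.is_clone else "nonclone") for c in cohort.cells},
    )
    cohort.counts = cm
    return cm


# --------------------------------------------------------------------
# Bulk repertoire simulation
# --------------------------------------------------------------------

def simulate_bulk_reads(cfg: SimulationConfig, cohort: SimulatedCohort) -> list[str]:
    """Sample bulk repertoire reads from the cells' light-chain transcripts.

    Cells contribute uniformly, so the expected clonal read fraction
    equals the clone fraction.  Each read is a window of
    ``bulk_read_length`` nt centred on the junction (so V anchor,
    junction and J anchor are all covered), with fresh sequencing errors.
    """
    if cfg.bulk_read_depth < 1000:
        raise ValueError("bulk_read_depth must be >= 1000")
    rng = np.random.default_rng(cfg.seed + 2)
    by_name = index_by_name(cohort.reference)
    v_len = len(by_name[cfg.clone_v_allele].seq)  # all scaffolds share gapped structure

    # pre-error transcripts are not kept per cell; reads sample the stored
    # (post-error) transcripts and add fresh per-read errors on top.
    transcripts = [c.transcripts["IGL"] for c in cohort.cells if not c.is_doublet]
    reads: list[str] = []
    for idx in rng.integers(len(transcripts), size=cfg.bulk_read_depth):
        tx = transcripts[idx]
        centre = v_len  # junction starts 3 nt before the end of V
        start = max(0, min(centre - cfg.bulk_read_length // 2, len(tx) - cfg.bulk_read_length))
        read = tx[start : start + cfg.bulk_read_length]
        reads.append(_inject_errors(read, cfg.per_base_error_rate, rng))
    cohort.bulk_reads = reads
    return reads


def simulate_cohort(cfg: SimulationConfig, ref: list[GermlineSegment] | None = None) -> SimulatedCohort:
    """Convenience: repertoire + expression + bulk reads in one call."""
    if ref is None:
        ref = build_germline_reference(seed=cfg.seed) + (
            build_germline_reference(v_count=3, seed=cfg.seed + 7, locus="IGH")
            if cfg.include_heavy
            else []
        )
    cohort = simulate_repertoire(cfg, ref)
    simulate_expression(cfg, cohort)
    simulate_bulk_reads(cfg, cohort)
    return cohort
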