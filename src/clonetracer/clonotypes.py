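"""Clonotype grouping, clone calling and single-cell vs bulk concordance.

Cells sharing identical V and J calls and junction nucleotide sequence
form a clonotype; a clonotype with at least ``min_cells`` members is a
clone, and its fraction of all assignable (non-doublet) cells is the
clone size.  Bulk repertoire reads are annotated with the same machinery
and clonal read frequencies are compared with the single-cell fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .germline import GermlineSegment
from .repertoire import (
    DEFAULT_ALIGN,
    AlignmentConfig,
    CellAnnotation,
    annotate_transcript,
)

Key = tuple[str, str, str]


@dataclass
class Clonotype:
    clonotype_id: str
    key: Key  # light chain (v_call, j_call, junction nt)
    heavy_key: Key | None
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CloneCall:
    clonotype: Clonotype
    fraction: float
    is_clone: bool
    #: True for a singleton promoted by the signature rule.
    rescued: bool = False


@dataclass
class CloneCallResult:
    calls: list[CloneCall]
    n_cells: int  # assignable, non-doublet denominator
    min_cells: int

    @property
    def clones(self) -> list[CloneCall]:
        return [c for c in self.calls if c.is_clone]

    def by_key(self, key: Key) -> CloneCall | None:
        for c in self.calls:
            if c.clonotype.key == key:
                return c
        return None


def group_clonotypes(
    cells: list[CellAnnotation],
    require_both_chains: bool = False,
) -> list[Clonotype]:
    """Partition assignable cells into exact-key clonotypes.

    Doublets and cells without a productive light chain are excluded.
    Default mode groups on the light-chain key alone and, within a
    light-chain group, subdivides by heavy-chain key when heavy chains
    are present (cells lacking a heavy chain stay with the light-chain
    group).  With ``require_both_chains`` cells must carry both chains
    and both keys define the group.
    """
    groups: dict[tuple, list[str]] = {}
    heavy_keys: dict[tuple, Key | None] = {}
    for cell in cells:
        if cell.is_doublet or cell.no_chain:
            continue
        light = cell.light
        if light is None or not light.productive or not light.junction:
            continue
        heavy = cell.heavy
        hkey = heavy.key if heavy is not None and heavy.junction else None
        if require_both_chains and hkey is None:
            continue
        # heavy chain must match when available: subdivide by heavy key;
        # absent heavy keys are merged into an unambiguous group below
        gkey = (light.key, hkey)
        groups.setdefault(gkey, []).append(cell.barcode)
        heavy_keys[gkey] = hkey

    # merge heavy-absent members into the (unique) matching light group
    merged: dict[tuple, list[str]] = {}
    hk: dict[tuple, Key | None] = {}
    if not require_both_chains:
        light_to_gkeys: dict[Key, list[tuple]] = {}
        for gkey in groups:
            light_to_gkeys.setdefault(gkey[0], []).append(gkey)
        for lkey, gkeys in light_to_gkeys.items():
            with_heavy = [g for g in gkeys if g[1] is not None]
            without = [g for g in gkeys if g[1] is None]
            if len(with_heavy) == 1 and without:
                # unambiguous: heavy-less cells join the single heavy group
                target = with_heavy[0]
                merged[target] = groups[target] + groups[without[0]]
                hk[target] = target[1]
            else:
                for g in gkeys:
                    merged[g] = groups[g]
                    hk[g] = g[1]
    else:
        merged, hk = groups, heavy_keys

    ordered = sorted(merged.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        Clonotype(
            clonotype_id=f"CT{i:04d}",
            key=gkey[0],
            heavy_key=hk[gkey],
            members=sorted(cells_),
        )
        for i, (gkey, cells_) in enumerate(ordered, start=1)
    ]


def call_clones(
    clonotypes: list[Clonotype],
    min_cells: int = 2,
    n_cells: int | None = None,
) -> CloneCallResult:
    """Flag clones (size >= min_cells) and compute clone fractions.

    The denominator defaults to the number of cells in the partition
    (assignable, non-doublet); pass ``n_cells`` to override.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    total = n_cells if n_cells is not None else sum(c.size for c in clonotypes)
    calls = [
        CloneCall(
            clonotype=ct,
            fraction=ct.size / total if total else 0.0,
            is_clone=ct.size >= min_cells,
        )
        for ct in clonotypes
    ]
    return CloneCallResult(calls=calls, n_cells=total, min_cells=min_cells)


# --------------------------------------------------------------------
# Bulk repertoire
# --------------------------------------------------------------------

def bulk_repertoire_frequencies(
    reads: list[str],
    refs: list[GermlineSegment],
    locus: str = "IGL",
    cfg: AlignmentConfig = DEFAULT_ALIGN,
) -> dict[Key, float]:
    """Clonotype-key read frequencies in a bulk repertoire.

    Every read is annotated (V, J, junction) with the single-cell
    machinery; the frequency of a key is its read count over all
    key-assignable reads.  Identical reads are annotated once.
    """
    counts: dict[Key, int] = {}
    cache: dict[str, Key | None] = {}
    n_assignable = 0
    for read in reads:
        if read in cache:
            key = cache[read]
        else:
            ann = annotate_transcript(read, refs, locus, cfg, prescreen=True)
            key = ann.key if ann is not None and ann.junction else None
            cache[read] = key
        if key is None:
            continue
        n_assignable += 1
        counts[key] = counts.get(key, 0) + 1
    if n_assignable == 0:
        raise ValueError("no assignable reads in the bulk repertoire")
    return {k: v / n_assignable for k, v in counts.items()}


# --------------------------------------------------------------------
# Single-cell vs bulk concordance
# --------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    #: (key, single-cell fraction, bulk read fraction)
    pairs: list[tuple[Key, float, float]] = field(default_factory=list)
    pearson_r: float | None = None

    def extend(self, other: "ConcordanceReport") -> "ConcordanceReport":
        return concordance_from_pairs(self.pairs + other.pairs)


def concordance_from_pairs(pairs: list[tuple[Key, float, float]]) -> ConcordanceReport:
    rep = ConcordanceReport(pairs=list(pairs))
    if len(pairs) >= 3:
        sc = np.array([p[1] for p in pairs])
        bk = np.array([p[2] for p in pairs])
        if np.std(sc) > 0 and np.std(bk) > 0:
            rep.pearson_r = float(stats.pearsonr(sc, bk)[0])
    return rep


def compare_sc_bulk(
    sc: CloneCallResult,
    bulk: dict[Key, float],
    clones_only: bool = True,
) -> ConcordanceReport:
    """Pair single-cell clone fractions with bulk read frequencies.

    By default only flagged clones are paired (singleton fractions are
    dominated by sampling noise on both sides); bulk keys missing from
    the map pair with frequency 0.  Pearson r is reported when at least
    three pairs exist, and can be pooled across cohorts with
    :meth:`ConcordanceReport.extend`.
    """
    calls = sc.clones if clones_only else sc.calls
    pairs = [(c.clonotype.key, c.fraction, bulk.get(c.clonotype.key, 0.0)) for c in calls]
    return concordance_from_pairs(pairs)
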