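"""Readers and writers for the pipeline's on-disk formats.

Per-cell transcripts go to FASTA with barcode-tagged headers, bulk reads
to FASTQ (Phred 33), counts to TSV and MatrixMarket, truth/clonotype
tables to TSV, configs to YAML, and germline references to a gapped
FASTA whose headers carry the segment class and anchor offsets.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .clonotypes import CloneCallResult
from .expression import CountMatrix
from .germline import GermlineSegment
from .synthetic_data import SimulatedCohort, SimulationConfig


# ---- germline reference -------------------------------------------

def write_germline_fasta(refs: list[GermlineSegment], path: str | Path) -> None:
    records = []
    for r in refs:
        anchors = ",".join(f"{k}:{v}" for k, v in sorted(r.anchors.items()))
        records.append(
            SeqRecord(Seq(r.gapped_seq), id=r.name, description=f"class={r.segment_class} anchors={anchors}")
        )
    SeqIO.write(records, str(path), "fasta")


def read_germline_fasta(path: str | Path) -> list[GermlineSegment]:
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(kv.split("=", 1) for kv in rec.description.split()[1:])
        anchors = {}
        if fields.get("anchors"):
            anchors = {k: int(v) for k, v in (kv.split(":") for kv in fields["anchors"].split(","))}
        refs.append(
            GermlineSegment(
                name=rec.id,
                gapped_seq=str(rec.seq),
                segment_class=fields["class"],
                anchors=anchors,
            )
        )
    return refs


# ---- cells and bulk reads -----------------------------------------

def write_cell_fasta(cohort: SimulatedCohort, path: str | Path) -> None:
    """All cell transcripts in one FASTA, headers ``<barcode>|<locus>[|extra]``."""
    records = []
    for cell in cohort.cells:
        for locus, seq in sorted(cell.transcripts.items()):
            records.append(SeqRecord(Seq(seq), id=f"{cell.barcode}|{locus}", description=""))
        for locus, seq in sorted(cell.extra_transcripts.items()):
            records.append(SeqRecord(Seq(seq), id=f"{cell.barcode}|{locus}|extra", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_cell_fasta(path: str | Path) -> dict[str, dict[str, list[str]]]:
    """Barcode -> locus -> transcript list."""
    cells: dict[str, dict[str, list[str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        barcode, locus = rec.id.split("|")[:2]
        cells.setdefault(barcode, {}).setdefault(locus, []).append(str(rec.seq))
    return cells


def write_bulk_fastq(reads: list[str], path: str | Path, quality: int = 30) -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i:06d}\n{read}\n+\n{chr(quality + 33) * len(read)}\n")


def read_bulk_fastq(path: str | Path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


# ---- counts and tables --------------------------------------------

def write_counts_tsv(m: CountMatrix, path: str | Path) -> None:
    m.counts.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path, labels: str | Path | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    groups = {}
    if labels is not None:
        lab = pd.read_csv(labels, sep="\t", index_col=0)
        groups = lab.iloc[:, 0].to_dict()
    return CountMatrix.from_arrays(df.to_numpy(), df.index, df.columns, groups)


def write_counts_mtx(m: CountMatrix, prefix: str | Path) -> None:
    """MatrixMarket triplet plus gene/cell index sidecars."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(m.counts.to_numpy()))
    prefix.with_name(prefix.name + ".genes.txt").write_text("\n".join(m.genes) + "\n")
    prefix.with_name(prefix.name + ".cells.txt").write_text("\n".join(m.cells) + "\n")


def read_counts_mtx(prefix: str | Path) -> CountMatrix:
    prefix = Path(prefix)
    mat = np.asarray(mmread(str(prefix.with_suffix(".mtx"))).todense())
    genes = prefix.with_name(prefix.name + ".genes.txt").read_text().splitlines()
    cells = prefix.with_name(prefix.name + ".cells.txt").read_text().splitlines()
    return CountMatrix.from_arrays(mat, genes, cells)


def write_truth_tsv(cohort: SimulatedCohort, path: str | Path) -> None:
    rows = [
        {"cell_id": c.barcode, "is_clone": c.is_clone, "is_doublet": c.is_doublet}
        for c in cohort.cells
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_labels_tsv(cohort: SimulatedCohort, path: str | Path) -> None:
    """Group labels (clone/nonclone) keyed by cell, for ``profile``-style runs."""
    rows = [
        {"cell_id": c.barcode, "group": "clone" if c.is_clone else "nonclone"}
        for c in cohort.cells
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_clonotype_tsv(result: CloneCallResult, path: str | Path) -> None:
    rows = [
        {
            "clonotype_id": c.clonotype.clonotype_id,
            "v_call": c.clonotype.key[0],
            "j_call": c.clonotype.key[1],
            "junction": c.clonotype.key[2],
            "n_cells": c.clonotype.size,
            "fraction": c.fraction,
            "is_clone": c.is_clone,
            "rescued": c.rescued,
        }
        for c in result.calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def clone_summary_json(result: CloneCallResult, path: str | Path | None = None) -> dict:
    summary = {
        "n_cells": result.n_cells,
        "min_cells": result.min_cells,
        "n_clonotypes": len(result.calls),
        "n_clones": len(result.clones),
        "clone_fractions": {c.clonotype.clonotype_id: c.fraction for c in result.clones},
    }
    if path is not None:
        Path(path).write_text(json.dumps(summary, indent=2) + "\n")
    return summary


# ---- config -------------------------------------------------------

def write_config_yaml(cfg: SimulationConfig, path: str | Path) -> None:
    data = {k: v for k, v in cfg.__dict__.items()}
    data["planted_substitutions"] = [list(t) for t in data["planted_substitutions"]]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_config_yaml(path: str | Path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text())
    if "planted_substitutions" in data:
        data["planted_substitutions"] = [tuple(t) for t in data["planted_substitutions"]]
    return SimulationConfig(**data)
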