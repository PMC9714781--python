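# clonetracer

Identification and profiling of monoclonal plasma cell populations from
single-cell transcriptomes.

Full-length single-cell RNA-seq of plasma cells captures the complete
immunoglobulin transcript of every cell, so clonality can be read
directly from the data: cells sharing the same V-(D)-J rearrangement and
CDR3 sequence belong to one clone. `clonetracer` implements that
analysis end to end, aimed at disorders where the clone is *small* —
the motivating case is POEMS syndrome, where the pathogenic clone is
often only 1–30% of plasma cells (vs ~100% in multiple myeloma) and
carries a restricted lambda light chain: IGLV1-36/-40/-44/-47 rearranged
to IGLJ3\*02, with amino-acid substitutions at IMGT positions 38 (CDR1)
and 40 (FR2) — position 40 always to asparagine, position 38 to a
nonpolar residue. That signature allows even a single-cell clone to be
recognized.

The package provides:

- **Repertoire reconstruction** — per-cell V/J assignment by local
  affine-gap alignment (match +2, mismatch −2, gap −6/−1), CDR3/junction
  delineation between the conserved Cys-104 and Phe-118 anchors, and
  projection onto IMGT unique numbering.
- **Clonotype calling** — exact-key grouping on (V, J, junction nt),
  clone flags at ≥ 2 cells, clone fractions, and concordance of
  single-cell fractions with bulk repertoire read frequencies.
- **Signature analysis** — germline substitution calling on IMGT
  coordinates, the POEMS light-chain signature rule, and rescue of
  signature-positive singleton cells as putative clones.
- **Expression profiling** — median-of-ratios normalization, an NB Wald
  differential-expression test, top-30 gene pooling + K-means,
  pre-ranked GSEA (weighted KS running sum, gene-set permutation null),
  marker phenotyping and an in-silico CD19⁻HLA-DR⁻/lo sorting gate.
- **Synthetic cohorts** — a fully seeded generator planting a clone at
  configurable fraction with signature substitutions, sequencing error,
  bulk reads and marker-shifted NB count matrices, so every stage is
  testable with known ground truth.

## Worked example

```python
import clonetracer as ct

cfg = ct.SimulationConfig(n_cells=120, clone_fraction=0.1, seed=42)
cohort = ct.simulate_cohort(cfg)              # repertoire + counts + bulk reads

annotations = ct.annotate_cohort(cohort)
result = ct.call_clones(ct.group_clonotypes(annotations))
top = result.clones[0]
print(f"clone: {top.clonotype.key[0]} / {top.clonotype.key[1]}")
print(f"cells: {top.clonotype.size}/{result.n_cells}  fraction: {top.fraction:.3f}")

bulk = ct.bulk_repertoire_frequencies(cohort.bulk_reads, cohort.reference)
print(f"bulk clonal read fraction: {bulk[top.clonotype.key]:.3f}")

sigs = ct.signature_calls_for_cohort(annotations, cohort.reference)
print(f"signature-positive cells: {sum(s.verdict for s in sigs.values())}")

m = ct.size_factor_normalize(cohort.counts)
gate = ct.gate_clones_by_markers(m)
print(f"CD19-/HLA-DR-lo gate: purity {gate.purity:.2f}, recall {gate.recall:.2f}")
```

Output:

```
clone: IGLV1-44*01 / IGLJ3*02
cells: 10/115  fraction: 0.087
bulk clonal read fraction: 0.077
signature-positive cells: 12
CD19-/HLA-DR-lo gate: purity 0.92, recall 1.00
```

Reading it: 12 clone cells were planted (10% of 120). Two of them lose
their exact junction to the simulated 0.1% per-base sequencing error, so
the clonotype contains 10 of the 115 assignable cells (fraction 8.7%,
truth 10%), and the bulk RNA-seq reads of the same cells give a
concordant 7.7%. The signature rule recovers all 12 planted cells —
including the two that fell out of the junction-identity group — because
the 38/40 substitutions are read from the IMGT-numbered V region, not
the junction. The expression gate (CD19 and HLA-DRA below the
nonclone mean − 2 SD) captures every clone cell at 92% purity.

A CLI mirrors the library (`clonetracer simulate / annotate / clones /
signature / profile`); see `clonetracer --help`.

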