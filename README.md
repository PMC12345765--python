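# sfdkit

Scaffold-free functional deconvolution (SFD) of extracellular-vesicle (EV)
proteomes: a provenance-tracked presence/absence pipeline for prioritizing
disease-specific, functionally relevant EV cargo.

## The problem

EVs released by tumor cells carry protein cargo with diagnostic and
therapeutic potential, but the bulk of any EV proteome is *scaffold* — the
constitutive vesicle machinery also present in vesicles from healthy serum,
fibroblasts, melanocytes and dozens of other normal sources. Abundance-based
differential analysis struggles here because EV proteomics is largely a
presence/absence measurement. SFD embraces that: it treats proteomes as sets
and refines a disease EV protein list `x` by

1. **subtracting** healthy-EV references (scaffold and serum-contaminant
   removal), giving the non-scaffold remainder `y`, then
2. **intersecting** `y` with function-specific databases (metastasis
   association, cell-surface accessibility, immunosuppression, ...), giving
   function-specific candidates `z`, iterating for sub-functions,

and finally classifies survivors into four functional categories
(metabolic/acidification, immune modulation, oncogenic driver,
metastasis-associated/unknown) and ranks them by a univariate Cox
proportional-hazards screen — per gene `g`, the model
`h(t | x_g) = h0(t) · exp(β_g · x_g)` on continuous (log2, z-scored)
expression against overall and disease-free survival, with Wald CIs,
Benjamini–Hochberg q-values and a Schoenfeld-residual proportionality check.

Because every step is an irreversible discard, each set carries a provenance
chain and every cascade emits a funnel report recording per-step
retained/removed counts *and the removed members* — so you can audit why a
known marker fell out (e.g. because it was also detected, even faintly, in a
healthy source).

A seeded synthetic-data generator produces complete worlds — scaffold core,
per-source healthy extras, disease-unique cargo, detection dropout, and a
survival cohort with planted hazard genes — so the entire pipeline is
testable end-to-end with known ground truth and no external downloads.

## Worked example

```python
from sfdkit import (SyntheticConfig, generate_proteomes, build_reference,
                    run_cascade, CascadeStep, StepKind, classify,
                    default_rules, screen, ProteinSet)

config = SyntheticConfig(seed=11, n_scaffold=300, n_sources=6,
                         n_source_specific=20, n_disease_unique=40,
                         frac_function_annotated=0.4, n_patients=300)
world = generate_proteomes(config)

healthy = build_reference(world.healthy_sources)     # union of 6 sources
report = run_cascade(
    world.disease,
    [CascadeStep(StepKind.SUBTRACT, "healthy"),
     CascadeStep(StepKind.INTERSECT, "function")],
    {"healthy": healthy, "function": world.function_reference},
)
print("funnel:", " -> ".join(map(str, report.counts)))

result = classify(report.final_set, world.annotations, default_rules())
print("categories:", result.counts)

out = screen(ProteinSet.from_symbols("cand",
             world.planted_genes + [f"NULL{i:05d}" for i in range(5)]),
             world.expression, world.clinical, "OS")
top = out.results[0]
print(f"top gene {top.gene}: HR={top.hr:.2f} [{top.ci_low:.2f}, "
      f"{top.ci_high:.2f}], p={top.p:.1e}, q={top.q:.1e}, PH p={top.prop_p:.2f}")
```

prints

```
funnel: 340 -> 40 -> 16
categories: {'metabolic_acidification': 3, 'immune_modulation': 5, 'oncogenic_driver': 4, 'metastasis_unknown': 4}
top gene DISU00000: HR=1.95 [1.67, 2.28], p=1.4e-17, q=8.6e-17, PH p=0.57
```

Reading the numbers: the disease proteome holds 340 proteins (300 scaffold +
40 disease-unique). Subtracting the healthy union removes all 300 scaffold
proteins (no dropout here), and the function intersect keeps the 16
function-annotated disease-unique proteins — exactly the planted truth. The
classifier splits them 3/5/4/4 across the four categories, and the Cox
screen puts the planted hazard gene on top with a hazard ratio of 1.95 per
SD of log2 expression (generative β = 0.7 ⇒ HR = e^0.7 ≈ 2.01) and no
proportionality violation (Schoenfeld p = 0.57).

## Command line

The same stages are exposed as subcommands:

```bash
sfdkit simulate --seed 4 --out world/          # write a synthetic world
sfdkit build-reference world/healthy_manifest.tsv --out healthy.txt
sfdkit run-cascade disease.txt \
    --step subtract:serum --step intersect:metastasis \
    --reference serum=serum.txt --reference metastasis=hcmdb.txt \
    --out funnel.json
sfdkit classify candidates.txt --annotations ann.tsv --out assignments.tsv
sfdkit survival-screen candidates.txt --expression expr.tsv \
    --clinical clinical.tsv --endpoint DFS --sample-type primary --out cox.tsv
sfdkit run-preset --config run.yaml            # full pipeline + run manifest
```

Shipped presets (`metastasis`, `surface_immunosuppression`, `meta_analysis`)
encode the three standard cascade recipes; `custom` takes explicit ordered
steps. Every `run-preset` invocation writes a machine-readable run manifest
(input SHA-256 hashes, seed, rule-file identity) sufficient to re-execute
the run bit-identically.

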