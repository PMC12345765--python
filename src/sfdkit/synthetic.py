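"""Synthetic EV proteomes and survival cohorts with known ground truth.

Real disease-EV proteomics data carry three structural ingredients that the
deconvolution cascade must navigate: a *scaffold* core of constitutive
vesicle proteins shared with healthy sources, *source-specific* cargo unique
to each healthy sample type, and *disease-unique* cargo, a fraction of which
carries function annotations.  Detection dropout — a truly present protein
missed in one sample's proteome — is the mechanism behind presence/absence
false negatives, so each scaffold protein appears in each healthy source
independently with probability ``1 - dropout``.

The generator emulates exactly that structure, plus a survival cohort with
planted hazard genes: patient event times are exponential with hazard
``h0 * exp(beta_planted * z)`` for a standard-normal per-patient latent
``z``, under uniform censoring calibrated to a requested censoring fraction.
Everything is driven by one seeded NumPy generator, so identical config +
seed reproduces identical worlds.

Disease-side dropout defaults to 0 so presence/absence truth is exact and
the cascade's set logic can be tested in isolation; switch it on to emulate
the false-negative regime in which genuinely disease-associated proteins are
lost because they were (also) detected in a healthy source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .compendium import SourceList
from .identifiers import Namespace, ProteinID
from .setalgebra import ProteinSet

#: baseline hazard, events/month; median survival ~14 months at z = 0
BASELINE_HAZARD = 0.05

#: fixed offset making expression = 2**(z + shift) - 1 strictly positive
#: while keeping log2(x+1) an exact affine image of the latent z
_EXPR_LOG_SHIFT = 8.0

_TERM_POOL = {
    "immune": ["antigen processing", "cytokine binding"],
    "metabolic": ["glycolysis", "lactate transport"],
    "oncogenic": ["protein kinase activity", "cell cycle regulation"],
    "none": [],
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; the defaults emulate a desk-scale disease-EV study.

    A shared scaffold of ~1000 proteins across 24 healthy sample types with
    ~150 disease-unique proteins mirrors (at reduced size) the composition
    of a melanoma-style EV proteome of a few thousand identifications
    against a multi-source healthy compendium.  Dropout defaults to 0 on
    both sides: noiseless presence/absence, exact recovery.
    """

    seed: int
    n_scaffold: int = 1000
    n_sources: int = 24
    n_source_specific: int = 40
    n_disease_unique: int = 150
    frac_function_annotated: float = 0.4
    frac_scaffold_decoy: float = 0.1
    dropout: float = 0.0
    disease_dropout: float = 0.0
    n_patients: int = 500
    n_null_genes: int = 20
    beta_planted: float = 0.7
    censoring: float = 0.3
    frac_dfs_missing: float = 0.15

    def __post_init__(self) -> None:
        counts = {
            "n_scaffold": self.n_scaffold,
            "n_sources": self.n_sources,
            "n_source_specific": self.n_source_specific,
            "n_disease_unique": self.n_disease_unique,
            "n_patients": self.n_patients,
            "n_null_genes": self.n_null_genes,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        probs = {
            "frac_function_annotated": self.frac_function_annotated,
            "frac_scaffold_decoy": self.frac_scaffold_decoy,
            "dropout": self.dropout,
            "disease_dropout": self.disease_dropout,
            "censoring": self.censoring,
            "frac_dfs_missing": self.frac_dfs_missing,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")


@dataclass
class SyntheticWorld:
    """Generated inputs plus the truth labels the tests check against."""

    config: SyntheticConfig
    healthy_sources: list[SourceList]
    disease: ProteinSet
    function_reference: ProteinSet
    annotations: dict[ProteinID, frozenset[str]]
    truth: dict[str, frozenset[ProteinID]]  # scaffold/source_specific/disease_unique/function_positive
    expression: Optional[pd.DataFrame] = None
    clinical: Optional[pd.DataFrame] = None
    planted_genes: list[str] = field(default_factory=list)


def _symbol(prefix: str, i: int) -> ProteinID:
    return ProteinID(Namespace.GENE_SYMBOL, f"{prefix}{i:05d}")


def generate_proteomes(config: SyntheticConfig, with_survival: bool = True) -> SyntheticWorld:
    """Generate a full synthetic world (proteomes; optionally a cohort).

    Construction, in order:

    1. universe = scaffold ∪ per-source-specific ∪ disease-unique ids
       (disjoint by construction; this partition is the truth labeling);
    2. each healthy source holds each scaffold id with probability
       ``1 - dropout`` plus its own ``n_source_specific`` ids;
    3. disease proteome = scaffold ∪ disease-unique, each member kept with
       probability ``1 - disease_dropout``;
    4. the function reference holds a ``frac_function_annotated`` fraction
       of disease-unique ids (these are the planted positives) plus a
       disjoint ``frac_scaffold_decoy`` fraction of scaffold ids (decoys
       that must be removed by subtraction, not by the function filter);
    5. annotated proteins receive trigger-style functional terms.
    """
    rng = np.random.default_rng(config.seed)

    scaffold = [_symbol("SCAF", i) for i in range(config.n_scaffold)]
    disease_unique = [_symbol("DISU", i) for i in range(config.n_disease_unique)]
    source_specific: dict[str, list[ProteinID]] = {}
    sample_types = _sample_type_names(config.n_sources)
    for si, stype in enumerate(sample_types):
        source_specific[stype] = [
            ProteinID(Namespace.GENE_SYMBOL, f"SRC{si:02d}N{i:04d}")
            for i in range(config.n_source_specific)
        ]

    sources = []
    for stype in sample_types:
        if config.dropout > 0:
            keep = rng.random(len(scaffold)) >= config.dropout
            held = [p for p, k in zip(scaffold, keep) if k]
        else:
            held = list(scaffold)
        sources.append(
            SourceList(
                name=f"healthy_{stype}",
                sample_type=stype,
                proteins=ProteinSet.from_ids(
                    f"healthy_{stype}", held + source_specific[stype]
                ),
            )
        )

    disease_members = scaffold + disease_unique
    if config.disease_dropout > 0:
        keep = rng.random(len(disease_members)) >= config.disease_dropout
        disease_members = [p for p, k in zip(disease_members, keep) if k]
    disease = ProteinSet.from_ids("disease_ev", disease_members)

    n_pos = round(config.frac_function_annotated * config.n_disease_unique)
    function_positive = list(
        rng.choice(len(disease_unique), size=n_pos, replace=False)
    ) if n_pos else []
    positives = [disease_unique[i] for i in sorted(function_positive)]
    n_decoy = round(config.frac_scaffold_decoy * config.n_scaffold)
    decoy_idx = rng.choice(len(scaffold), size=n_decoy, replace=False) if n_decoy else []
    decoys = [scaffold[i] for i in sorted(decoy_idx)]
    function_reference = ProteinSet.from_ids("function_reference", positives + decoys)

    annotations: dict[ProteinID, frozenset[str]] = {}
    kinds = list(_TERM_POOL)
    for pid in positives + decoys:
        kind = kinds[rng.integers(len(kinds))]
        terms = _TERM_POOL[kind]
        if terms:
            annotations[pid] = frozenset(terms)

    world = SyntheticWorld(
        config=config,
        healthy_sources=sources,
        disease=disease,
        function_reference=function_reference,
        annotations=annotations,
        truth={
            "scaffold": frozenset(scaffold),
            "source_specific": frozenset(
                p for ids in source_specific.values() for p in ids
            ),
            "disease_unique": frozenset(disease_unique),
            "function_positive": frozenset(positives),
        },
    )
    if with_survival and config.n_patients > 0:
        planted = [p.value for p in positives[:1]] or ["HAZARD00001"]
        expr, clinical = generate_survival(config, planted_genes=planted, rng=rng)
        world.expression, world.clinical, world.planted_genes = expr, clinical, planted
    return world


def generate_survival(
    config: SyntheticConfig,
    planted_genes: Optional[list[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an expression matrix and clinical table with planted hazards.

    For each planted gene, a standard-normal latent ``z`` per patient drives
    exponential event times with hazard ``BASELINE_HAZARD * exp(beta * z)``;
    null genes are independent of survival.  Expression is stored as
    ``2**(z + 8) - 1``, so the screen's log2(x+1) transform recovers the
    latent exactly (up to the affine shift the per-gene z-scoring removes).
    Censoring times are uniform on ``[0, m]`` with ``m`` calibrated by
    bisection so the realized censoring fraction approximates the request.
    DFS is an independent draw from the same hazard model, with a fraction
    of records jointly missing both DFS fields.
    """
    if config.n_patients < 10:
        raise ValueError("n_patients must be >= 10 for a meaningful cohort")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    planted = planted_genes or ["HAZARD00001"]
    n = config.n_patients
    patients = [f"PT{i:04d}" for i in range(n)]

    rows: dict[str, np.ndarray] = {}
    hazard_z = None
    for g in planted:
        z = rng.standard_normal(n)
        hazard_z = z if hazard_z is None else hazard_z  # first planted gene drives risk
        rows[g] = np.maximum(2.0 ** (z + _EXPR_LOG_SHIFT) - 1.0, 0.0)
    for i in range(config.n_null_genes):
        w = rng.standard_normal(n)
        rows[f"NULL{i:05d}"] = np.maximum(2.0 ** (w + _EXPR_LOG_SHIFT) - 1.0, 0.0)

    os_time, os_event = _draw_endpoint(rng, hazard_z, config.beta_planted, config.censoring)
    dfs_time, dfs_event = _draw_endpoint(rng, hazard_z, config.beta_planted, config.censoring)
    dfs_time = dfs_time.astype(object)
    dfs_event = dfs_event.astype(object)
    if config.frac_dfs_missing > 0:
        miss = rng.random(n) < config.frac_dfs_missing
        dfs_time[miss] = np.nan
        dfs_event[miss] = np.nan

    expression = pd.DataFrame(rows, index=patients).T
    expression.index.name = "gene"
    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "sample_type": "primary",
            "os_time": os_time,
            "os_event": os_event.astype(int),
            "dfs_time": pd.to_numeric(pd.Series(dfs_time), errors="coerce"),
            "dfs_event": pd.to_numeric(pd.Series(dfs_event), errors="coerce"),
        }
    )
    return expression, clinical


def _draw_endpoint(
    rng: np.random.Generator, z: np.ndarray, beta: float, censoring: float
) -> tuple[np.ndarray, np.ndarray]:
    n = len(z)
    rate = BASELINE_HAZARD * np.exp(beta * z)
    t = rng.exponential(1.0 / rate)
    if censoring <= 0:
        return t, np.ones(n)
    u = rng.random(n)

    def censored_frac(m: float) -> float:
        return float(np.mean(u * m < t))

    lo, hi = 1e-6, float(10 * t.max())
    # censored fraction decreases in m; bisect to the requested level
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if censored_frac(mid) > censoring:
            lo = mid
        else:
            hi = mid
    c = u * hi
    event = (t <= c).astype(float)
    return np.minimum(t, c), event


def _sample_type_names(n: int) -> list[str]:
    base = [
        "serum", "plasma", "fibroblast", "melanocyte", "csf", "breast_milk",
        "aqueous_humor", "saliva", "urine", "keratinocyte", "endothelial",
        "platelet", "erythrocyte", "tcell", "bcell", "nkcell", "monocyte",
        "hepatocyte", "astrocyte", "neuron", "adipocyte", "myocyte",
        "osteoblast", "chondrocyte",
    ]
    if n <= len(base):
        return base[:n]
    return base + [f"sample_type_{i}" for i in range(len(base), n)]
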