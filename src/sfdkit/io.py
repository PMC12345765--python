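"""Readers, writers, run configuration and the preset pipeline runner.

File dialects
-------------
* ``plain`` — one identifier per line, ``#`` comments ignored;
* ``tabular`` — TSV/CSV with a declared identifier column;
* ``compendium_export`` — tab-delimited export with declared gene-symbol and
  sample-type columns (column names are declared, never assumed, because
  public EV-compendium export schemas vary by release).

The three shipped cascade presets mirror the standard deconvolution
recipes: ``metastasis`` (serum subtraction → metastasis-database intersect →
healthy-cell subtraction), ``surface_immunosuppression`` (serum and healthy
subtraction → surfaceome intersect → immunosuppression sub-function) and
``meta_analysis`` (healthy-compendium subtraction → metastasis intersect).
``run_preset`` chains cascade → classification → optional survival screen
and drops a machine-readable run manifest (input hashes, seed, versions) so
a run can be re-executed bit-identically.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .classification import (
    CategoryRule,
    ClassificationResult,
    classify,
    default_rules,
    normalize_terms,
    rules_from_yaml,
)
from .compendium import SourceList, build_reference
from .identifiers import (
    IdMapping,
    InvalidIdentifierError,
    Namespace,
    ProteinID,
    canonicalize,
    translate,
)
from .setalgebra import CascadeStep, FunnelReport, ProteinSet, StepKind, run_cascade
from .survival import Endpoint, ScreenOutput, filter_cohort, screen, validate_clinical

logger = logging.getLogger(__name__)

PRESETS: dict[str, list[tuple[StepKind, str]]] = {
    "metastasis": [
        (StepKind.SUBTRACT, "serum"),
        (StepKind.INTERSECT, "metastasis"),
        (StepKind.SUBTRACT, "healthy"),
    ],
    "surface_immunosuppression": [
        (StepKind.SUBTRACT, "serum"),
        (StepKind.SUBTRACT, "healthy"),
        (StepKind.INTERSECT, "surfaceome"),
        (StepKind.SUBFUNCTION, "immunosuppression"),
    ],
    "meta_analysis": [
        (StepKind.SUBTRACT, "healthy"),
        (StepKind.INTERSECT, "metastasis"),
    ],
}


class UnknownPresetError(ValueError):
    pass


class MissingColumnError(ValueError):
    pass


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# readers


def read_protein_list(
    path: str | Path,
    dialect: str = "plain",
    namespace: Namespace = Namespace.GENE_SYMBOL,
    column: Optional[str] = None,
    sample_type_column: Optional[str] = None,
    sample_type: Optional[str] = None,
    label: Optional[str] = None,
) -> ProteinSet:
    """Read a protein list in any supported dialect into a canonical set.

    Duplicate identifiers (after canonicalization) and unparsable lines are
    counted and logged, never silently dropped from the accounting.
    """
    path = Path(path)
    label = label or path.stem
    raw: list[str] = []
    if dialect == "plain":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    raw.append(line)
    elif dialect in ("tabular", "compendium_export"):
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
        col = column or ("gene_symbol" if dialect == "compendium_export" else None)
        if col is None:
            raise ValueError("tabular dialect requires a declared id column")
        if col not in df.columns:
            raise MissingColumnError(
                f"{path}: declared column {col!r} absent (have {list(df.columns)})"
            )
        if dialect == "compendium_export" and sample_type is not None:
            st_col = sample_type_column or "sample_type"
            if st_col not in df.columns:
                raise MissingColumnError(
                    f"{path}: declared sample-type column {st_col!r} absent"
                )
            df = df[df[st_col] == sample_type]
        raw = df[col].dropna().tolist()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    ids: list[ProteinID] = []
    unparsable = 0
    for token in raw:
        try:
            ids.append(canonicalize(token, namespace))
        except InvalidIdentifierError:
            unparsable += 1
    members = frozenset(ids)
    duplicates = len(ids) - len(members)
    if not members:
        logger.warning("protein list %s is empty", path)
    if duplicates or unparsable:
        logger.info(
            "%s: %d duplicate and %d unparsable entries dropped from %d lines",
            path, duplicates, unparsable, len(raw),
        )
    return ProteinSet.from_ids(label, members)


def write_protein_list(pset: ProteinSet, path: str | Path) -> None:
    """Write a plain one-id-per-line list (sorted, canonical)."""
    Path(path).write_text("\n".join(pset.values()) + "\n", encoding="utf-8")


def read_manifest(
    path: str | Path, namespace: Namespace = Namespace.GENE_SYMBOL
) -> list[SourceList]:
    """Read a compendium manifest: TSV of (source, sample_type, path).

    List-file paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    sources = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"source", "sample_type", "path"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise MissingColumnError(
                f"{path}: manifest requires columns {sorted(required)}"
            )
        for row in reader:
            list_path = path.parent / row["path"]
            sources.append(
                SourceList(
                    name=row["source"],
                    sample_type=row["sample_type"],
                    proteins=read_protein_list(
                        list_path, namespace=namespace, label=row["source"]
                    ),
                )
            )
    return sources


def read_annotations(path: str | Path) -> dict[ProteinID, frozenset[str]]:
    """Annotation TSV: columns (protein, terms), terms semicolon-joined."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("protein", "terms"):
        if col not in df.columns:
            raise MissingColumnError(f"{path}: annotation column {col!r} absent")
    out: dict[ProteinID, frozenset[str]] = {}
    for _, row in df.iterrows():
        pid = canonicalize(row["protein"], Namespace.GENE_SYMBOL)
        terms = normalize_terms(str(row["terms"]).split(";")) if pd.notna(row["terms"]) else frozenset()
        out[pid] = out.get(pid, frozenset()) | terms
    return out


def write_annotations(
    annotations: dict[ProteinID, frozenset[str]], path: str | Path
) -> None:
    lines = ["protein\tterms"]
    for pid in sorted(annotations):
        lines.append(f"{pid.value}\t{';'.join(sorted(annotations[pid]))}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column gene ids, remaining columns patients."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [canonicalize(g, Namespace.GENE_SYMBOL).value for g in df.index]
    if pd.Index(df.index).duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids after canonicalization")
    return df


def read_clinical(
    path: str | Path, column_map: Optional[dict[str, str]] = None
) -> pd.DataFrame:
    """Clinical TSV with a declared mapping from standard names to columns.

    ``column_map`` maps standard names (patient_id, sample_type, os_time,
    os_event, dfs_time, dfs_event) to the file's column names; omitted
    entries default to the standard name itself.
    """
    df = pd.read_csv(path, sep="\t")
    column_map = column_map or {}
    rename = {}
    from .survival import CLINICAL_COLUMNS

    for std in CLINICAL_COLUMNS:
        src = column_map.get(std, std)
        if src not in df.columns:
            raise MissingColumnError(f"{path}: clinical column {src!r} absent")
        rename[src] = std
    return validate_clinical(df.rename(columns=rename)[list(CLINICAL_COLUMNS)])


# ---------------------------------------------------------------------------
# synthetic-world export (same formats the pipeline reads)


def write_world(world, outdir: str | Path) -> dict[str, Path]:
    """Write a :class:`~sfdkit.synthetic.SyntheticWorld` as pipeline inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    manifest_rows = ["source\tsample_type\tpath"]
    for src in world.healthy_sources:
        fname = f"{src.name}.txt"
        write_protein_list(src.proteins, outdir / fname)
        manifest_rows.append(f"{src.name}\t{src.sample_type}\t{fname}")
    paths["manifest"] = outdir / "healthy_manifest.tsv"
    paths["manifest"].write_text("\n".join(manifest_rows) + "\n", encoding="utf-8")

    paths["disease"] = outdir / "disease.txt"
    write_protein_list(world.disease, paths["disease"])
    paths["function_reference"] = outdir / "function_reference.txt"
    write_protein_list(world.function_reference, paths["function_reference"])
    paths["annotations"] = outdir / "annotations.tsv"
    write_annotations(world.annotations, paths["annotations"])

    if world.expression is not None:
        paths["expression"] = outdir / "expression.tsv"
        world.expression.to_csv(paths["expression"], sep="\t")
        paths["clinical"] = outdir / "clinical.tsv"
        world.clinical.to_csv(paths["clinical"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(
        json.dumps(
            {k: sorted(p.value for p in v) for k, v in world.truth.items()}
            | {"planted_genes": world.planted_genes},
            indent=2,
        ),
        encoding="utf-8",
    )
    return paths


# ---------------------------------------------------------------------------
# run configuration and the preset runner


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    input_path: Path
    references: dict[str, Path]
    preset: str = "custom"
    steps: list[CascadeStep] = field(default_factory=list)
    namespace: Namespace = Namespace.GENE_SYMBOL
    mapping_path: Optional[Path] = None
    annotations_path: Optional[Path] = None
    rules_path: Optional[Path] = None
    expression_path: Optional[Path] = None
    clinical_path: Optional[Path] = None
    compendium_manifest: Optional[Path] = None
    min_sources: int = 1
    sample_type: Optional[str] = None
    endpoints: list[Endpoint] = field(default_factory=lambda: [Endpoint.OS, Endpoint.DFS])
    seed: int = 0
    outdir: Path = Path("sfd_out")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        base = path.parent

        def p(key: str) -> Optional[Path]:
            return base / doc[key] if doc.get(key) else None

        preset = doc.get("preset", "custom")
        steps = [
            CascadeStep(StepKind(s["kind"]), s["reference"])
            for s in doc.get("steps", [])
        ]
        cfg = cls(
            input_path=base / doc["input"],
            references={k: base / v for k, v in doc.get("references", {}).items()},
            preset=preset,
            steps=steps,
            namespace=Namespace(doc.get("namespace", "gene_symbol")),
            mapping_path=p("mapping"),
            annotations_path=p("annotations"),
            rules_path=p("rules"),
            expression_path=p("expression"),
            clinical_path=p("clinical"),
            compendium_manifest=p("compendium_manifest"),
            min_sources=int(doc.get("min_sources", 1)),
            sample_type=doc.get("sample_type"),
            endpoints=[Endpoint(e) for e in doc.get("endpoints", ["OS", "DFS"])],
            seed=int(doc.get("seed", 0)),
            outdir=base / doc.get("outdir", "sfd_out"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.preset != "custom" and self.preset not in PRESETS:
            raise UnknownPresetError(
                f"unknown preset {self.preset!r}; valid presets: "
                f"{sorted(PRESETS) + ['custom']}"
            )
        for path in [
            self.input_path, self.mapping_path, self.annotations_path,
            self.rules_path, self.expression_path, self.clinical_path,
            self.compendium_manifest, *self.references.values(),
        ]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured path does not exist: {path}")

    def cascade_steps(self) -> list[CascadeStep]:
        if self.preset == "custom":
            if not self.steps:
                raise ValueError("custom preset requires explicit steps")
            return self.steps
        return [CascadeStep(kind, ref) for kind, ref in PRESETS[self.preset]]


@dataclass
class RunResult:
    funnel: FunnelReport
    classification: ClassificationResult
    screens: dict[str, ScreenOutput]
    network_genes: list[str]
    manifest: dict


def run_preset(config: RunConfig, write: bool = True) -> RunResult:
    """Execute cascade → classification → (optional) survival screen.

    Outputs, when ``write`` is set, land in ``config.outdir``: the funnel as
    JSON and TSV, category assignments as TSV with a JSON count summary, one
    Cox table per endpoint, the network-ready gene list (final candidates
    annotated with their category), and a run manifest with input hashes.
    Stage failures propagate wrapped in :class:`StageError` naming the stage.
    """
    try:
        disease = read_protein_list(
            config.input_path, namespace=config.namespace, label="disease_input"
        )
        references = {
            name: read_protein_list(path, namespace=config.namespace, label=name)
            for name, path in config.references.items()
        }
        if config.compendium_manifest is not None:
            sources = read_manifest(config.compendium_manifest, config.namespace)
            references["healthy"] = build_reference(
                sources, min_sources=config.min_sources, label="healthy"
            )
        if config.mapping_path is not None and config.namespace is Namespace.UNIPROT_ACCESSION:
            mapping = IdMapping.from_tsv(config.mapping_path)
            tr = translate(disease.members, mapping)
            if tr.unmapped:
                logger.info("%d unmapped accessions retained aside", len(tr.unmapped))
            disease = ProteinSet.from_ids("disease_input", tr.translated)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("load", exc) from exc

    try:
        funnel = run_cascade(disease, config.cascade_steps(), references)
    except Exception as exc:
        raise StageError("cascade", exc) from exc

    try:
        annotations = (
            read_annotations(config.annotations_path)
            if config.annotations_path is not None
            else {}
        )
        rules: list[CategoryRule] = (
            rules_from_yaml(config.rules_path)
            if config.rules_path is not None
            else default_rules()
        )
        classification = classify(funnel.final_set, annotations, rules)
    except Exception as exc:
        raise StageError("classification", exc) from exc

    screens: dict[str, ScreenOutput] = {}
    if config.expression_path is not None and config.clinical_path is not None:
        try:
            expression = read_expression(config.expression_path)
            clinical = read_clinical(config.clinical_path)
            if config.sample_type:
                clinical = filter_cohort(clinical, config.sample_type)
            for endpoint in config.endpoints:
                screens[endpoint.value] = screen(
                    funnel.final_set, expression, clinical, endpoint
                )
        except Exception as exc:
            raise StageError("survival", exc) from exc

    category_of = {a.protein.value: a.category.value for a in classification.assignments}
    network_genes = [f"{g}\t{category_of[g]}" for g in funnel.final_members]

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "steps": [
            {"kind": s.kind.value, "reference": s.reference}
            for s in config.cascade_steps()
        ],
        "rules": str(config.rules_path) if config.rules_path else "<default>",
        "inputs": {
            str(p): _sha256(p)
            for p in [
                config.input_path, *config.references.values(),
                config.mapping_path, config.annotations_path, config.rules_path,
                config.expression_path, config.clinical_path,
                config.compendium_manifest,
            ]
            if p is not None
        },
    }
    result = RunResult(funnel, classification, screens, network_genes, manifest)
    if write:
        _write_outputs(result, config.outdir)
    return result


def _write_outputs(result: RunResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "funnel.json").write_text(result.funnel.to_json(), encoding="utf-8")
    (outdir / "funnel.tsv").write_text(result.funnel.to_tsv(), encoding="utf-8")
    (outdir / "assignments.tsv").write_text(
        result.classification.to_tsv(), encoding="utf-8"
    )
    (outdir / "category_counts.json").write_text(
        json.dumps(result.classification.counts, indent=2), encoding="utf-8"
    )
    for endpoint, out in result.screens.items():
        out.to_frame().to_csv(outdir / f"cox_{endpoint}.tsv", sep="\t", index=False)
    (outdir / "network_genes.txt").write_text(
        "\n".join(result.network_genes) + ("\n" if result.network_genes else ""),
        encoding="utf-8",
    )
    (outdir / "run_manifest.json").write_text(
        json.dumps(result.manifest, indent=2), encoding="utf-8"
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
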