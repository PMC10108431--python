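"""Batch orchestration: scan a directory of models, classify, report.

Per model the pipeline runs dominant-knot typing; unknotted chains
short-circuit (no fingerprint), knotted chains get knot-core
localization, the clash heuristic, optional homolog-conservation and
second-model agreement, and a verdict.  The report is one TSV row per
model plus a census table (knot type x verdict counts).  Per-model
failures are recorded in the row, never aborting the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .classification import (
    ClassificationConfig,
    ConservationSummary,
    HomologTable,
    clash_check,
    classify,
    conservation_summary,
    read_homolog_table,
)
from .detection import (
    CLOSURE_RADIUS_FACTOR,
    DEFAULT_N_CLOSURES,
    UNKNOT,
    dominant_knot,
)
from .fingerprint import (
    DEFAULT_CLOSURES_PER_CELL,
    DEFAULT_COARSE_STEP,
    detect_slipknot,
    fingerprint,
    knot_core,
)
from .structures_io import BackboneChain, StructureParseError, parse_backbone

__all__ = [
    "PipelineConfig",
    "ModelResult",
    "ScanReport",
    "analyze_model",
    "scan_directory",
    "census",
    "load_config",
]

logger = logging.getLogger("knotscan")

#: chains longer than this are processed with a warning flag: full-length
#: giants are fragment-stitched in the source database and artifact-prone
LARGE_CHAIN_WARNING = 3000

REPORT_COLUMNS = [
    "model_id", "n_residues", "dominant_knot", "nontrivial_fraction",
    "core_start", "core_end", "core_mean_plddt", "n_tail", "c_tail",
    "depth_class", "slipknots", "verdict", "rule_flags",
    "needs_visual_inspection", "warnings", "error",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the scan in one record (echoed into reports)."""

    n_closures: int = DEFAULT_N_CLOSURES
    closures_per_cell: int = DEFAULT_CLOSURES_PER_CELL
    coarse_step: int = DEFAULT_COARSE_STEP
    closure_radius_factor: float = CLOSURE_RADIUS_FACTOR
    crossing_cap: int = 24
    seed: int = 0
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)

    def as_text(self) -> str:
        cls = self.classification
        pairs = [
            ("n_closures", self.n_closures),
            ("closures_per_cell", self.closures_per_cell),
            ("coarse_step", self.coarse_step),
            ("closure_radius_factor", self.closure_radius_factor),
            ("crossing_cap", self.crossing_cap),
            ("seed", self.seed),
            ("plddt_min", cls.plddt_min),
            ("conservation_min", cls.conservation_min),
            ("close_identity_min", cls.close_identity_min),
            ("clash_distance", cls.clash_distance),
        ]
        return "\n".join(f"# {k} = {v}" for k, v in pairs)


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Config from a key = value text file, with keyword overrides."""
    values: dict[str, str] = {}
    if path is not None:
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            values[key] = val
    values.update({k: v for k, v in overrides.items() if v is not None})

    cls_fields = {"plddt_min", "conservation_min", "close_identity_min",
                  "clash_distance", "min_sequence_span"}
    cls_kwargs, pipe_kwargs = {}, {}
    for key, val in values.items():
        if key in cls_fields:
            cls_kwargs[key] = float(val) if key != "min_sequence_span" else int(val)
        elif key in ("n_closures", "closures_per_cell", "coarse_step",
                     "crossing_cap", "seed"):
            pipe_kwargs[key] = int(val)
        elif key == "closure_radius_factor":
            pipe_kwargs[key] = float(val)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return PipelineConfig(
        classification=ClassificationConfig(**cls_kwargs), **pipe_kwargs
    )


@dataclass(frozen=True)
class ModelResult:
    """Full per-model analysis record (one report row)."""

    model_id: str
    row: Mapping[str, object]


@dataclass(frozen=True)
class ScanReport:
    """Per-model rows plus the effective configuration."""

    frame: pd.DataFrame
    config: PipelineConfig

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(self.config.as_text() + "\n")
            self.frame.to_csv(fh, sep="\t", index=False)


def analyze_model(
    chain: BackboneChain,
    config: PipelineConfig | None = None,
    homologs: HomologTable | None = None,
    second_model_label: str | None = None,
    model_id: str = "model",
) -> dict[str, object]:
    """Run the full per-structure pipeline and return one report row."""
    config = config or PipelineConfig()
    warnings = list(chain.warnings)
    if len(chain) > LARGE_CHAIN_WARNING:
        warnings.append(
            f"chain has {len(chain)} residues (> {LARGE_CHAIN_WARNING}); "
            "source models of this size are stitched from overlapping "
            "fragments and artifact-prone"
        )
    row: dict[str, object] = {c: "" for c in REPORT_COLUMNS}
    row.update(model_id=model_id, n_residues=len(chain))

    spectrum = dominant_knot(
        chain, n_closures=config.n_closures, seed=config.seed,
        radius_factor=config.closure_radius_factor,
        crossing_cap=config.crossing_cap,
    )
    row["dominant_knot"] = spectrum.dominant
    row["nontrivial_fraction"] = round(spectrum.nontrivial_fraction, 4)

    if spectrum.dominant == UNKNOT:
        verdict = classify(spectrum, None, None, None, None, config.classification)
        row.update(verdict=verdict.category, rule_flags="",
                   needs_visual_inspection=False,
                   warnings="; ".join(warnings))
        return row

    fp = fingerprint(
        chain, coarse_step=config.coarse_step,
        closures_per_cell=config.closures_per_cell,
        seed=config.seed, full_spectrum=spectrum,
    )
    core = knot_core(fp, chain)
    clash_ok, offenders = clash_check(chain, core, config.classification)
    conservation: ConservationSummary | None = None
    if homologs is not None:
        conservation = conservation_summary(
            homologs, spectrum.dominant, config.classification
        )
    verdict = classify(spectrum, core, clash_ok, conservation,
                       second_model_label, config.classification)
    slipknots = detect_slipknot(fp)
    if not clash_ok:
        warnings.append(f"{len(offenders)} core clash pair(s)")

    row.update(
        core_start=core.start, core_end=core.end,
        core_mean_plddt=round(core.mean_plddt, 2),
        n_tail=core.n_tail, c_tail=core.c_tail,
        depth_class=core.depth_class,
        slipknots="; ".join(
            f"{motif}@{s}-{e}" for (s, e), _, motif in slipknots
        ),
        verdict=verdict.category,
        rule_flags=",".join(f"{k}={v}" for k, v in verdict.rule_flags.items()),
        needs_visual_inspection=verdict.needs_visual_inspection,
        warnings="; ".join(warnings),
    )
    return row


def _iter_model_files(input_dir: Path) -> list[Path]:
    exts = {".pdb", ".ent", ".cif", ".mmcif"}
    return sorted(p for p in input_dir.iterdir()
                  if p.is_file() and p.suffix.lower() in exts)


def scan_directory(
    input_dir: str | Path,
    config: PipelineConfig | None = None,
    homolog_dir: str | Path | None = None,
    second_model_labels: Mapping[str, str] | None = None,
) -> ScanReport:
    """Analyse every model file in a directory into one report.

    Homolog tables, when given, are matched by file stem:
    ``<homolog_dir>/<model stem>.tsv``.  Per-model errors land in the
    row's error column.
    """
    config = config or PipelineConfig()
    input_dir = Path(input_dir)
    files = _iter_model_files(input_dir)
    if not files:
        raise FileNotFoundError(f"no model files (.pdb/.cif) in {input_dir}")
    rows = []
    for path in files:
        model_id = path.stem
        logger.info("scanning %s", model_id)
        try:
            chain = parse_backbone(path)
            homologs = None
            if homolog_dir is not None:
                hpath = Path(homolog_dir) / f"{model_id}.tsv"
                if hpath.exists():
                    homologs = read_homolog_table(hpath)
            second = None
            if second_model_labels is not None:
                second = second_model_labels.get(model_id)
            row = analyze_model(chain, config, homologs, second, model_id)
        except (StructureParseError, ValueError, RuntimeError) as exc:
            row = {c: "" for c in REPORT_COLUMNS}
            row.update(model_id=model_id, error=str(exc))
            logger.warning("model %s failed: %s", model_id, exc)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return ScanReport(frame, config)


def census(report: ScanReport | pd.DataFrame) -> pd.DataFrame:
    """Knot-type x verdict counts with an "All" margin row.

    Mirrors the published census layout: one row per knot type, columns
    for knotted / potentially knotted / artifact counts.
    """
    frame = report.frame if isinstance(report, ScanReport) else report
    if frame.empty:
        raise ValueError("census of an empty report")
    cats = ["knotted", "potentially_knotted", "artifact"]
    sub = frame[frame["verdict"].isin(cats)]
    types = sorted(set(sub["dominant_knot"])) if not sub.empty else []
    data = {}
    for cat in cats:
        counts = sub[sub["verdict"] == cat]["dominant_knot"].value_counts()
        data[cat] = [int(counts.get(t, 0)) for t in types]
    table = pd.DataFrame(data, index=pd.Index(types, name="knot_type"))
    table.loc["All"] = table.sum(axis=0)
    return table
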