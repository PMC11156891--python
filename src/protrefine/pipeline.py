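"""End-to-end refinement pipeline over a directory of models.

For every native AI model found, the pipeline produces a refined
(trimmed) version; when a homology donor for the same accession is
present, it additionally produces a ligand-integrated relaxed model
(transplant, optional external minimizer hook) and its refined version
(trim plus ligand-retention filter).  Stage order is fixed: transplant ->
relax (hook) -> trim -> retention.  A JSON-serializable manifest records
every file produced and every per-model failure; a single bad model never
aborts the run.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ProtrefineError
from .model_io import (
    MODEL_TYPE_TOKEN,
    StructureModel,
    dataset_filename,
    read_model,
    write_model,
)
from .transplant import TransplantPolicy, run_minimizer_hook, transplant_all
from .trim import TrimPolicy, trim_model

logger = logging.getLogger(__name__)

_TOKEN_TO_TYPE = {tok: mt for mt, tok in MODEL_TYPE_TOKEN.items()}
_NATIVE_RE = re.compile(
    rf"^({'|'.join(MODEL_TYPE_TOKEN.values())})_(.+)\.pdb$"
)
_HM_RE = re.compile(r"^HM_(.+)\.pdb$")


@dataclass
class PipelineConfig:
    input_dir: Path
    output_dir: Path
    trim_policy: TrimPolicy = field(default_factory=TrimPolicy)
    transplant_policy: TransplantPolicy = field(default_factory=TransplantPolicy)
    minimizer_hook: str | None = None
    stages: tuple[str, ...] = ("refined", "relaxed_ligand", "refined_ligand")

    def __post_init__(self):
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)


def discover_inputs(input_dir: Path) -> tuple[list[tuple[str, str, Path]], dict[str, Path]]:
    """Find native AI models [(model_type, accession, path)] and homology
    donors {accession: path} by the dataset naming convention."""
    ai_models, donors = [], {}
    for path in sorted(Path(input_dir).glob("*.pdb")):
        m = _NATIVE_RE.match(path.name)
        if m:
            ai_models.append((_TOKEN_TO_TYPE[m.group(1)], m.group(2), path))
            continue
        m = _HM_RE.match(path.name)
        if m:
            donors[m.group(1)] = path
    return ai_models, donors


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all requested stages; returns the manifest."""
    config.output_dir.mkdir(parents=True, exist_ok=True)
    ai_models, donors = discover_inputs(config.input_dir)
    manifest: dict = {
        "categories": {stage: [] for stage in config.stages},
        "dropped": [],
        "failures": [],
        "counts": {},
    }

    for model_type, accession, path in ai_models:
        try:
            _process_one(config, model_type, accession, path,
                         donors.get(accession), manifest)
        except ProtrefineError as exc:
            logger.warning("model %s (%s) failed: %s", accession, model_type, exc)
            manifest["failures"].append(
                {"accession": accession, "model_type": model_type, "error": str(exc)}
            )
    manifest["counts"] = {
        stage: len(files) for stage, files in manifest["categories"].items()
    }
    manifest["counts"]["dropped"] = len(manifest["dropped"])
    manifest["counts"]["failures"] = len(manifest["failures"])
    return manifest


def _emit(config: PipelineConfig, manifest: dict, model: StructureModel,
          stage: str) -> None:
    name = dataset_filename(model.model_type, model.accession, stage)
    write_model(model, config.output_dir / name)
    manifest["categories"][stage].append(name)


def _process_one(config, model_type: str, accession: str, path: Path,
                 donor_path: Path | None, manifest: dict) -> None:
    model = read_model(path, model_type=model_type)
    if not model.accession:
        model.accession = accession

    if "refined" in config.stages:
        relaxed = (run_minimizer_hook(model, config.minimizer_hook)
                   if config.minimizer_hook else model)
        trimmed, report = trim_model(relaxed, config.trim_policy)
        if trimmed is None:
            manifest["dropped"].append(
                {"accession": accession, "model_type": model_type,
                 "stage": "refined", "reason": "below_min_residues"}
            )
        else:
            _emit(config, manifest, trimmed, "refined")

    if donor_path is not None and (
        {"relaxed_ligand", "refined_ligand"} & set(config.stages)
    ):
        donor = read_model(donor_path, model_type="homology")
        if not donor.accession:
            donor.accession = accession
        with_ligands, t_report = transplant_all(
            model, donor, config.transplant_policy,
            minimizer_hook=config.minimizer_hook,
        )
        if "relaxed_ligand" in config.stages:
            _emit(config, manifest, with_ligands, "relaxed_ligand")
        if "refined_ligand" in config.stages:
            trimmed, report = trim_model(with_ligands, config.trim_policy)
            if trimmed is None:
                manifest["dropped"].append(
                    {"accession": accession, "model_type": model_type,
                     "stage": "refined_ligand", "reason": "below_min_residues"}
                )
            else:
                _emit(config, manifest, trimmed, "refined_ligand")
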