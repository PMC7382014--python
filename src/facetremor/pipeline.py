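"""End-to-end orchestration of the analysis stages.

A single YAML-able :class:`RunConfig` drives synth/import ->
normalize -> features -> screen -> select -> classify -> seqtrain.
Every stage writes its artifact into the run directory and is logged;
reruns with the same config and seed reproduce all deterministic
outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diagnosis_models import evaluate_classifiers
from .feature_selection import DEFAULT_ALPHA_GRID, lasso_sweep
from .landmark_io import load_dataset, save_cohort
from .relative_coords import to_relative_sequence
from .sequence_model import difference, train_sequence_classifier
from .significance_screen import count_significant
from .synthetic_faces import SyntheticConfig, generate_cohort
from .trajectory_features import build_feature_table

logger = logging.getLogger("facetremor")

STAGES = ("synth", "import", "normalize", "features", "screen", "select",
          "classify", "seqtrain")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ("synth", "normalize", "features", "screen",
                               "select", "classify", "seqtrain")
    manifest: str | None = None              # required for the import stage
    synth: dict = field(default_factory=dict)
    basis_policy: str = "per_frame"
    alphas: tuple[float, ...] = (0.05, 0.005)
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    algorithms: tuple[str, ...] = ("lr", "svm", "dt", "rf")
    n_splits: int = 5
    seq_arch: str = "lstm"
    seq_epochs: int = 60
    seq_splits: int = 3

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise PipelineError(f"unknown stage name(s): {unknown}")
        if "synth" in self.stages and "import" in self.stages:
            raise PipelineError("choose either 'synth' or 'import', not both")
        if "import" in self.stages and not self.manifest:
            raise PipelineError("the 'import' stage requires a manifest path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "alphas", "alpha_grid", "algorithms"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the configured stages; return the machine-readable summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "seed": config.seed, "artifacts": {},
                     "hashes": {}}

    def _record(name: str, path: Path) -> None:
        summary["artifacts"][name] = str(path)
        summary["hashes"][name] = _sha256(path)

    try:
        cohort = None
        if "synth" in config.stages:
            logger.info("stage synth: generating cohort")
            cfg = SyntheticConfig(seed=config.seed, **config.synth)
            cohort = generate_cohort(cfg)
            manifest = save_cohort(cohort, out / "landmarks")
            _record("manifest", manifest)
        elif "import" in config.stages:
            logger.info("stage import: loading %s", config.manifest)
            cohort = load_dataset(config.manifest)
            manifest = save_cohort(cohort, out / "landmarks")
            _record("manifest", manifest)
        elif config.manifest:
            cohort = load_dataset(config.manifest)

        rels = None
        if "normalize" in config.stages or "features" in config.stages:
            if cohort is None:
                raise PipelineError("normalize/features need a cohort (synth, import or manifest)")
            logger.info("stage normalize: basis policy %s", config.basis_policy)
            rels = [to_relative_sequence(s, basis_policy=config.basis_policy)
                    for s in cohort]

        table = None
        if "features" in config.stages:
            logger.info("stage features: extracting per-record features")
            table = build_feature_table(cohort, rels)
            fpath = out / "features.csv"
            table.to_csv(fpath, index=False, float_format="%.17g")
            _record("features", fpath)

        if "screen" in config.stages:
            if table is None:
                raise PipelineError("screen needs the features stage")
            logger.info("stage screen: alphas %s", config.alphas)
            report = count_significant(table, alphas=config.alphas)
            spath = out / "screen.csv"
            report.counts.to_csv(spath)
            report.p_values.to_csv(out / "p_values.csv")
            _record("screen", spath)

        if "select" in config.stages:
            if table is None:
                raise PipelineError("select needs the features stage")
            logger.info("stage select: %d-point alpha grid", len(config.alpha_grid))
            sweep = lasso_sweep(table, alpha_grid=config.alpha_grid,
                                n_splits=config.n_splits, seed=config.seed)
            wpath = out / "sweep.csv"
            sweep.table.to_csv(wpath, index=False)
            _record("select", wpath)

        if "classify" in config.stages:
            if table is None:
                raise PipelineError("classify needs the features stage")
            logger.info("stage classify: %s", ",".join(config.algorithms))
            creport = evaluate_classifiers(table, algorithms=config.algorithms,
                                           n_splits=config.n_splits, seed=config.seed)
            cpath = out / "classify.json"
            cpath.write_text(json.dumps(creport.to_dict(), indent=2))
            _record("classify", cpath)

        if "seqtrain" in config.stages:
            if rels is None:
                raise PipelineError("seqtrain needs the normalize stage")
            logger.info("stage seqtrain: arch %s", config.seq_arch)
            data = [difference(r) for r in rels]
            _, sreport = train_sequence_classifier(
                data, arch=config.seq_arch, seed=config.seed,
                n_splits=config.seq_splits, epochs=config.seq_epochs, refit=False,
            )
            qpath = out / "seqtrain.json"
            qpath.write_text(json.dumps(sreport.to_dict(), indent=2))
            _record("seqtrain", qpath)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage failure: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
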