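"""End-to-end orchestration: simulate -> describe -> train -> predict -> report.

A single JSON-serialisable configuration drives every stage; one global
seed is fanned out deterministically to the sub-stages through
``numpy.random.SeedSequence.spawn``, so rerunning the same configuration
reproduces every per-cell label exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ann import (
    Stage1Config,
    Stage2Config,
    multi_restart_select,
    predict_pipeline,
    save_model,
)
from .augment import (
    LabeledSpectrum,
    augment_classification,
    augment_regression,
    split_before_augmentation,
)
from .descriptor import DescriptorConfig, build_descriptor, descriptor_table, save_descriptors
from .reporting import build_confusion, build_sample_report, results_to_frame, write_report
from .sde import NON_SDE_CLASSES, SDE_CLASSES, STAGE1_LABELS
from .shapes import default_specs, generate_dataset

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the failing stage name when a stage aborts."""


@dataclass
class RunConfig:
    seed: int = 0
    classes: tuple[str, ...] = SDE_CLASSES + NON_SDE_CLASSES
    n_per_class_sde: int = 50
    n_per_class_other: int = 25
    split_fraction: float = 0.8
    augment_per_class: int = 2000
    augment_regression_total: int = 14000
    restarts: int = 3
    stage1_epochs: int = 100
    stage2_epochs: int = 40
    descriptor: DescriptorConfig = field(default_factory=DescriptorConfig)
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["classes"] = list(self.classes)
        d["descriptor"] = self.descriptor.to_dict()
        return d

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "descriptor" in d:
            d["descriptor"] = DescriptorConfig(**d["descriptor"])
        if "classes" in d:
            d["classes"] = tuple(d["classes"])
        return cls(**d)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full synthetic pipeline and write all artifacts to *out_dir*.

    Returns the manifest dictionary (also written as manifest.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    seeds = _spawn_seeds(config.seed, 6)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "sub_seeds": seeds,
        "stages": {},
    }

    def _stage(name):
        log.info("stage: %s", name)
        manifest["stages"][name] = {"started": time.time()}

    try:
        _stage("simulate")
        sde_classes = [c for c in config.classes if c in SDE_CLASSES]
        other_classes = [c for c in config.classes if c not in SDE_CLASSES]
        data = []
        if sde_classes:
            data += generate_dataset(default_specs(sde_classes), config.n_per_class_sde, seed=seeds[0])
        if other_classes:
            data += generate_dataset(default_specs(other_classes), config.n_per_class_other, seed=seeds[0] + 1)
        mesh_dir = out / "meshes"
        mesh_dir.mkdir(exist_ok=True)
        for k, (mesh, spec) in enumerate(data):
            mesh.save_ply(mesh_dir / f"cell{k:05d}.ply")
    except Exception as exc:
        raise PipelineError(f"stage simulate failed: {exc}") from exc

    try:
        _stage("describe")
        spectra = []
        for k, (mesh, spec) in enumerate(data):
            d = build_descriptor(mesh, config.descriptor)
            spectra.append(
                LabeledSpectrum(d.normalized_vector, spec.shape_class, spec.sde_score, uid=f"cell{k:05d}")
            )
        import pandas as pd

        table = pd.DataFrame(
            [s.vector for s in spectra],
            index=[s.uid for s in spectra],
            columns=[f"v{i:03d}" for i in range(config.descriptor.vector_length)],
        )
        table.index.name = "cell_id"
        save_descriptors(table, out / "descriptors.tsv", config.descriptor)
        labels_frame = pd.DataFrame(
            {
                "shape_class": [s.shape_class for s in spectra],
                "sde_score": [s.sde_score for s in spectra],
            },
            index=[s.uid for s in spectra],
        )
        labels_frame.index.name = "cell_id"
        labels_frame.to_csv(out / "labels.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(f"stage describe failed: {exc}") from exc

    try:
        _stage("train")
        split = split_before_augmentation(spectra, config.split_fraction, seed=seeds[1])
        aug1 = augment_classification(split, config.augment_per_class, seed=seeds[2])
        lab2idx = {l: i for i, l in enumerate(STAGE1_LABELS)}
        X1 = np.array([s.vector for s in aug1.train])
        y1 = np.array([lab2idx[s.label] for s in aug1.train])
        X1v = np.array([s.vector for s in aug1.validation])
        y1v = np.array([lab2idx[s.label] for s in aug1.validation])
        cfg1 = Stage1Config(epochs=config.stage1_epochs, restarts=config.restarts)
        stage1, log1 = multi_restart_select(cfg1, X1, y1, X1v, y1v, base_seed=seeds[3])
        stage2 = None
        if set(SDE_CLASSES).issubset(set(config.classes)):
            aug2 = augment_regression(split, config.augment_regression_total, seed=seeds[2] + 1)
            X2 = np.array([s.vector for s in aug2.train])
            y2 = np.array([s.sde_score for s in aug2.train])
            X2v = np.array([s.vector for s in aug2.validation])
            y2v = np.array([s.sde_score for s in aug2.validation])
            cfg2 = Stage2Config(epochs=config.stage2_epochs, restarts=config.restarts)
            stage2, log2 = multi_restart_select(cfg2, X2, y2, X2v, y2v, base_seed=seeds[4])
        dh = config.descriptor.hash()
        save_model(stage1, out / "stage1_model.npz", descriptor_hash=dh)
        if stage2 is not None:
            save_model(stage2, out / "stage2_model.npz", descriptor_hash=dh)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage train failed: {exc}") from exc

    try:
        _stage("predict")
        val_spectra = split.validation
        Xval = np.array([s.vector for s in val_spectra])
        results = predict_pipeline(stage1, stage2, Xval, [s.uid for s in val_spectra])
        frame = results_to_frame(results)
        frame.to_csv(out / "results.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(f"stage predict failed: {exc}") from exc

    try:
        _stage("report")
        report = build_sample_report(results, sample_id="synthetic")
        manual = {s.uid: s.shape_class for s in val_spectra}
        confusion = build_confusion(results, manual)
        write_report(report, out / "report", confusion=confusion)
        diag = confusion.accuracy_per_class()
        manifest["stages"]["report"]["diagonal"] = diag
    except Exception as exc:
        raise PipelineError(f"stage report failed: {exc}") from exc

    manifest["n_cells"] = len(data)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
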