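"""Reproducible pipelines: YAML-configured stages with run manifests.

A pipeline config names some of the stages ``simulate``, ``train``,
``predict``, ``evaluate`` and their parameters; stages execute in that
fixed order, each writing its artifacts plus a JSON run manifest (command,
config snapshot, seeds, input digests, output paths, version, timestamp)
into the declared output directory.  Inputs are never mutated.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, io
from .evaluation import sweep_to_frame, threshold_sweep
from .model import (ModelConfig, build_model, load_model, save_model,
                    score_sequence, train_model)
from .simulator import (BenchmarkConfig, build_benchmark, synthetic_cohort)

__all__ = ["RunManifest", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = ""

    def write(self, path: Path) -> None:
        self.timestamp = self.timestamp or time.strftime("%Y-%m-%dT%H:%M:%S")
        path.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(outdir: Path, stage: str, cfg: dict, seed: int,
              inputs: list[Path], outputs: list[Path]) -> None:
    RunManifest(
        command=stage, config=cfg, seed=seed,
        inputs={str(p): _digest(p) for p in inputs},
        outputs=[str(p) for p in outputs],
    ).write(outdir / f"manifest_{stage}.json")


def _stage_simulate(cfg: dict, outdir: Path, seed: int) -> None:
    genomes = synthetic_cohort(
        cfg.get("n_per_class_per_split", 2),
        n_hosts=cfg.get("n_hosts", 2),
        divergence=cfg.get("divergence", 1.0),
        seed=seed,
        n_genes=cfg.get("n_genes", 20),
        gene_len_codons=tuple(cfg.get("gene_len_codons", (100, 300))),
        intergenic_frac=cfg.get("intergenic_frac", 0.10),
        mixing=cfg.get("mixing", "codon"),
    )
    bench = BenchmarkConfig(
        n_train_per_class=cfg.get("n_train_per_class", 1000),
        n_test_per_class=dict(cfg.get("n_test_per_class", {"A": 200})),
        seed=seed,
    )
    train, test, manifest = build_benchmark(genomes, bench)
    outputs = []
    genomes_path = outdir / "genomes.gbk"
    io.write_genomes(genomes, genomes_path, "genbank")
    outputs.append(genomes_path)
    labels = outdir / "labels.tsv"
    with open(labels, "w") as fh:
        fh.write("genome_id\tlabel\tsplit\n")
        for rec in genomes:
            fh.write(f"{rec.id}\t{rec.annotations['transmissibility']}"
                     f"\t{rec.annotations['split']}\n")
    outputs.append(labels)
    train_path = outdir / "train.fasta"
    io.write_fragments_fasta(train, train_path)
    outputs.append(train_path)
    for group, frags in test.items():
        p = outdir / f"test_{group}.fasta"
        io.write_fragments_fasta(frags, p)
        outputs.append(p)
    manifest_path = outdir / "fragments.tsv"
    io.write_manifest(manifest, manifest_path)
    outputs.append(manifest_path)
    logger.info("simulate: %d genomes, %d train fragments, %d test fragments",
                len(genomes), len(train), sum(len(v) for v in test.values()))
    _manifest(outdir, "simulate", cfg, seed, [], outputs)


def _stage_train(cfg: dict, outdir: Path, seed: int) -> None:
    train_path = Path(cfg.get("train", outdir / "train.fasta"))
    fragments = list(io.read_fragments_fasta(train_path))
    mcfg = ModelConfig(seed=seed, **{
        k: v for k, v in cfg.items()
        if k in ModelConfig.__dataclass_fields__ and k != "seed"
    })
    model = train_model(build_model(mcfg), fragments)
    model_path = outdir / "model.npz"
    save_model(model, model_path)
    logger.info("train: %d fragments, %d epochs, final val loss %.4f",
                len(fragments), len(model.history["val_loss"]),
                model.history["val_loss"][-1])
    _manifest(outdir, "train", cfg, seed, [train_path], [model_path])


def _stage_predict(cfg: dict, outdir: Path, seed: int) -> None:
    model_path = Path(cfg.get("model", outdir / "model.npz"))
    model = load_model(model_path)
    t = float(cfg.get("t", 0.0))
    inputs = cfg.get("inputs")
    if inputs is None:
        inputs = sorted(str(p) for p in outdir.glob("test_*.fasta"))
    rows = []
    in_paths = []
    for path in inputs:
        in_paths.append(Path(path))
        for frag in io.read_fragments_fasta(path):
            rec = score_sequence(model, frag.sequence, frag.fragment_id, t=t)
            rows.append((rec.sequence_id, len(frag.sequence),
                         len(rec.window_scores), rec.score, rec.label,
                         frag.label, frag.group))
    pred_path = outdir / "predictions.tsv"
    with open(pred_path, "w") as fh:
        fh.write("sequence_id\tlength\tn_windows\tscore\tlabel\ttruth\tgroup\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    logger.info("predict: %d sequences scored (t=%.3g)", len(rows), t)
    _manifest(outdir, "predict", cfg, seed, in_paths + [model_path], [pred_path])


def _stage_evaluate(cfg: dict, outdir: Path, seed: int) -> None:
    import pandas as pd

    from .model import PredictionRecord, classify_score

    pred_path = Path(cfg.get("pred", outdir / "predictions.tsv"))
    df = pd.read_csv(pred_path, sep="\t")
    t_values = [float(t) for t in cfg.get("t_values", [0.0])]
    frames = []
    for group, sub in df.groupby("group"):
        preds = [
            PredictionRecord(r.sequence_id, float(r.score), [],
                             classify_score(float(r.score), 0.0), 0.0)
            for r in sub.itertuples()
        ]
        truth = dict(zip(sub["sequence_id"], sub["truth"]))
        frames.append(sweep_to_frame(
            threshold_sweep(preds, truth, t_values, group=str(group))
        ))
    report = pd.concat(frames, ignore_index=True)
    report_path = outdir / "report.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    logger.info("evaluate: %d report rows", len(report))
    _manifest(outdir, "evaluate", cfg, seed, [pred_path], [report_path])


_STAGES = [
    ("simulate", _stage_simulate),
    ("train", _stage_train),
    ("predict", _stage_predict),
    ("evaluate", _stage_evaluate),
]


def run_pipeline(config: str | Path | dict, outdir: str | Path | None = None,
                 seed: int | None = None) -> Path:
    """Execute the configured stages in order; returns the output directory.

    ``config`` is a YAML path or an equivalent dict with optional top-level
    keys ``outdir``, ``seed`` and one section per stage.  A stage failure
    raises :class:`PipelineError` naming the stage.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    if not isinstance(cfg, dict):
        raise PipelineError("pipeline config must be a mapping")
    unknown = set(cfg) - {"outdir", "seed"} - {name for name, _ in _STAGES}
    if unknown:
        raise PipelineError(f"unknown config sections: {sorted(unknown)}")
    out = Path(outdir or cfg.get("outdir", "plastrans_out"))
    out.mkdir(parents=True, exist_ok=True)
    run_seed = int(seed if seed is not None else cfg.get("seed", 0))
    for name, fn in _STAGES:
        if name not in cfg:
            continue
        stage_cfg = cfg[name] or {}
        if not isinstance(stage_cfg, dict):
            raise PipelineError(f"stage {name!r}: config must be a mapping")
        logger.info("stage %s: start", name)
        try:
            fn(stage_cfg, out, run_seed)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return out
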