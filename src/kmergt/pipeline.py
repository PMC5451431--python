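"""End-to-end pipeline: build-db -> count -> call [-> evaluate].

One call produces a run directory with every intermediate artifact in its
plain-text format (marker database, count table, fitted model parameters,
calls, optional metrics) plus a manifest recording package version, seed,
configuration and SHA-256 hashes of all inputs.  Re-running with the same
inputs and seed reproduces the calls file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__, genotyper, kmercount, simgen, variantdb
from .variantdb import AUTOSOME, CHRX

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    ref: str
    variants: str
    fastq: list[str]
    outdir: str
    k: int = 25
    max_pairs: int = 3
    sex: str = "auto"          # auto | male | female
    seed: int = 0
    truth: str | None = None   # enables the evaluate stage
    min_posterior: float | None = None
    full_output: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if not 16 <= self.k <= 32:
            raise ValueError(f"k must be in [16, 32], got {self.k}")
        if self.sex not in ("auto", "male", "female"):
            raise ValueError(f"sex must be auto/male/female, got {self.sex!r}")
        if not self.fastq:
            raise ValueError("at least one FASTQ file is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _stage(name: str, manifest: dict, fn):
    t0 = time.perf_counter()
    logger.info("stage %s: starting", name)
    try:
        result = fn()
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(name, str(exc)) from exc
    dt = time.perf_counter() - t0
    manifest["stages"][name] = {"seconds": round(dt, 3)}
    logger.info("stage %s: done in %.1fs", name, dt)
    return result


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages into ``config.outdir``; returns the run directory."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for path in [config.ref, config.variants, *config.fastq] + (
            [config.truth] if config.truth else []):
        if not Path(path).exists():
            raise PipelineError("config", f"input path does not exist: {path}")

    manifest: dict = {
        "kmergt_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
        "inputs": {str(p): _sha256(p)
                   for p in [config.ref, config.variants, *config.fastq]},
        "stages": {},
    }

    def build_db():
        reference = variantdb.read_reference(config.ref)
        variants, indels = variantdb.read_variants(config.variants)
        dbconf = variantdb.DBConfig(k=config.k, max_pairs=config.max_pairs)
        markers, report = variantdb.build_marker_db(
            reference, variants, indels, dbconf)
        variantdb.write_db(markers, outdir / "db.txt")
        manifest["db_report"] = {
            k: (len(v) if isinstance(v, list) else v)
            for k, v in report.items()}
        return markers

    markers = _stage("build-db", manifest, build_db)

    def count():
        index = kmercount.build_index(markers)
        kmercount.count_reads(index, config.fastq)
        table = kmercount.extract_counts(index, markers)
        kmercount.write_counts(table, outdir / "counts.txt")
        return table

    table = _stage("count", manifest, count)

    def call():
        classes = np.array([m.variant.chrom_class for m in markers])
        auto_table = table.subset(classes == AUTOSOME)
        params = genotyper.estimate_params(auto_table, seed=config.seed)
        params.save(outdir / "params.txt")

        if config.sex == "auto":
            sex = genotyper.detect_sex(table, classes).sex
        else:
            sex = config.sex
        manifest["sex"] = sex

        haploid_params = None
        if sex == "male":
            try:
                haploid_params = genotyper.fit_haploid_model(
                    table.subset(classes == CHRX), params, sex=sex,
                    seed=config.seed)
                haploid_params.save(outdir / "params_haploid.txt")
            except ValueError as exc:
                logger.warning(
                    "haploid fit unavailable (%s); using diploid "
                    "parameters for sex chromosomes", exc)

        calls = genotyper.call_all(
            table, markers, params, sex, haploid_params=haploid_params,
            output_mode="full" if config.full_output else "default",
            min_posterior=config.min_posterior)
        genotyper.write_calls(calls, outdir / "calls.txt")
        return calls

    calls = _stage("call", manifest, call)

    if config.truth:
        def evaluate():
            truth = read_truth(config.truth)
            metrics = simgen.evaluate_calls(calls, truth)
            metrics["confusion"] = {
                str(t): {str(c): int(n) for c, n in row.items()}
                for t, row in metrics["confusion"].iterrows()}
            with open(outdir / "metrics.json", "w") as fh:
                json.dump(metrics, fh, indent=2, sort_keys=True)
            return metrics

        _stage("evaluate", manifest, evaluate)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return outdir


# ---------------------------------------------------------------------------
# truth-set text format (written by `kmergt simulate`)

TRUTH_MAGIC = "#kmergt-truth v1"


def write_truth(truth: simgen.TruthSet, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"{TRUTH_MAGIC} sex={truth.sex}\n")
        for vid in sorted(truth.genotypes):
            fh.write(f"{vid}\t{truth.genotypes[vid]}\n")


def read_truth(path) -> simgen.TruthSet:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(TRUTH_MAGIC):
            raise ValueError(f"{path}: not a kmergt truth file")
        sex = header.split("sex=")[1].strip()
        genotypes = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                vid, g = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line") from exc
            genotypes[vid] = g
    return simgen.TruthSet(genotypes, sex)
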