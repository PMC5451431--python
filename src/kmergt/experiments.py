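"""Scaled-down simulation studies of genotyping accuracy.

Reproduces, on a desk-scale synthetic genome, the two classic experiments
used to characterize k-mer genotyping: (1) reads simulated from an
individual identical to the reference (every marker truly AA), which
measures how often the caller invents variation, and (2) reads from an
individual with planted heterozygous/homozygous-alternative genotypes,
which measures sensitivity and specificity as a function of coverage.

Study conditions follow the standard protocol: 2 x 100 nt paired reads,
per-base substitution error 0.005, insert 500 +/- 50, coverages from the
{5, 10, 20, 30, 40}x series; the default system is a 2 Mb genome (two
autosomes, a small chrX and chrY) carrying ~12,000 well-spaced k=25
markers, >= 10,000 of them autosomal.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import genotyper, kmercount, simgen, variantdb
from .variantdb import AUTOSOME, MarkerRecord, Variant

#: default 2 Mb study genome
STUDY_CHROMOSOMES = {"1": 900_000, "2": 900_000, "X": 150_000, "Y": 50_000}
COVERAGE_SERIES = (5, 10, 20, 30, 40)
HOMOZYGOUS_REF = {"AA": 1.0}
PLANTED_FREQS = {"AA": 0.6, "AB": 0.3, "BB": 0.1}


def _child_seed(seed: int, tag: int) -> int:
    """Derive a deterministic sub-seed (kept below 2**31)."""
    return (seed * 1_000_003 + tag) % (2**31 - 1)


@dataclass
class StudySystem:
    """A fixed reference + marker database shared by all simulated runs."""

    reference: dict[str, str]
    variants: list[Variant]
    markers: list[MarkerRecord]
    classes: np.ndarray  # chrom_class per marker
    k: int


def make_study_system(seed: int,
                      chromosomes: dict[str, int] | None = None,
                      n_markers: int = 12_000, k: int = 25) -> StudySystem:
    """Generate the reference, plant marker positions and compile the db."""
    chroms = dict(chromosomes or STUDY_CHROMOSOMES)
    reference = simgen.generate_reference(chroms, _child_seed(seed, 1))
    variants = simgen.place_markers(reference, n_markers,
                                    _child_seed(seed, 2), k=k)
    markers, _ = variantdb.build_marker_db(
        reference, variants, [], variantdb.DBConfig(k=k))
    classes = np.array([m.variant.chrom_class for m in markers])
    return StudySystem(reference, variants, markers, classes, k)


def run_individual(system: StudySystem, genotype_frequencies: dict,
                   coverage: float, seed: int,
                   base_error_rate: float = 0.005,
                   sex: str = "female", workdir=None) -> dict:
    """Simulate one individual at one coverage and score the calls.

    Draws genotypes, simulates paired reads, counts database k-mers, fits
    the empirical-Bayes model on autosomal markers, infers sex, calls all
    markers and returns the evaluation metrics (plus the fitted depth
    under key ``lambda_``).
    """
    truth = simgen.assign_genotypes(system.variants, genotype_frequencies,
                                    _child_seed(seed, 3), sex=sex)
    haps = simgen.build_haplotypes(system.reference, system.variants, truth)
    config = simgen.SimConfig(
        chromosomes={n: len(s) for n, s in system.reference.items()},
        n_markers=len(system.variants), coverage=coverage,
        base_error_rate=base_error_rate, seed=_child_seed(seed, 4))

    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        r1, r2 = Path(tmp) / "r1.fq", Path(tmp) / "r2.fq"
        simgen.simulate_reads(haps, config, r1, r2,
                              reference_length=config.genome_length)
        index = kmercount.build_index(system.markers)
        kmercount.count_reads(index, [r1, r2])
    table = kmercount.extract_counts(index, system.markers)

    params = genotyper.estimate_params(
        table.subset(system.classes == AUTOSOME), seed=_child_seed(seed, 5))
    sex_call = genotyper.detect_sex(table, system.classes)
    calls = genotyper.call_all(table, system.markers, params, sex_call.sex)
    metrics = simgen.evaluate_calls(calls, truth)
    metrics["lambda_"] = params.lambda_
    metrics["detected_sex"] = sex_call.sex
    return metrics
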