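"""Synthetic references, individuals and paired reads, plus call scoring.

The generator emulates the classic whole-genome-shotgun simulation used to
benchmark genotype callers: a uniform-random reference with planted
bi-allelic SNVs of known genotype, and paired-end reads with substitution
errors drawn at a fixed per-base rate, a fixed read length and a normal
insert-size distribution (defaults: error 0.005, 2 x 100 nt, insert
500 +/- 50).  Indel errors, quality-score structure, GC bias and repeat
content of real genomes are deliberately not modeled; the simulator's job
is to provide a fully known truth set for the counting and calling stack.

Scoring follows the usual definitions for known-variant genotyping:
sensitivity is the fraction of truth-AB/BB markers called correctly,
specificity the fraction of truth-AA markers called AA, both over
autosomal markers only; no-calls are tallied separately.
"""

from __future__ import annotations

import gzip
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dna
from .variantdb import AUTOSOME, CHRX, CHRY, Variant, classify_chrom

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)

DIPLOID_LABELS = ("AA", "AB", "BB")


@dataclass
class SimConfig:
    """Parameters of one simulated sequencing experiment."""

    chromosomes: dict[str, int]
    n_markers: int = 1000
    base_error_rate: float = 0.005
    read_length: int = 100
    insert_mean: int = 500
    insert_sd: int = 50
    coverage: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("at least one chromosome is required")
        if any(l <= 0 for l in self.chromosomes.values()):
            raise ValueError("chromosome lengths must be positive")
        if not 0 <= self.base_error_rate < 1:
            raise ValueError("base_error_rate must be in [0, 1)")
        if min(self.read_length, self.insert_mean, self.insert_sd,
               self.n_markers) <= 0:
            raise ValueError("read/insert/marker parameters must be positive")

    @property
    def genome_length(self) -> int:
        return sum(self.chromosomes.values())


@dataclass
class TruthSet:
    """Planted genotypes of one individual (AA/AB/BB diploid, A/B haploid)."""

    genotypes: dict[str, str]
    sex: str = "female"


def generate_reference(chromosomes: Mapping[str, int],
                       seed: int) -> dict[str, str]:
    """Uniform-random ACGT reference; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, length in chromosomes.items():
        codes = rng.integers(0, 4, size=int(length), dtype=np.uint8)
        out[name] = _ASCII[codes].tobytes().decode("ascii")
    return out


def place_markers(reference: Mapping[str, str], n_markers: int, seed: int,
                  k: int = 25) -> list[Variant]:
    """Plant well-spaced SNV positions (spacing >= 2k) with random alleles.

    Marker counts are allocated to chromosomes proportionally to length.
    Raises when the requested density cannot keep markers 2k apart.
    """
    rng = np.random.default_rng(seed)
    total = sum(len(s) for s in reference.values())
    variants: list[Variant] = []
    serial = 0
    for name in reference:
        seq = reference[name]
        length = len(seq)
        n_c = max(1, round(n_markers * length / total))
        span = length - 2 * k
        step = span / n_c
        if span <= 0 or step < 2 * k:
            raise ValueError(
                f"{name}: cannot place {n_c} markers {2 * k} bases apart "
                f"in {length} bases")
        jmax = max(0, int(step) - 2 * k - 2)
        codes = dna.seq_to_codes(seq)
        for i in range(n_c):
            pos = k + 1 + int(i * step)
            if jmax:
                pos += int(rng.integers(0, jmax + 1))
            refc = int(codes[pos - 1])
            altc = (refc + int(rng.integers(1, 4))) % 4
            serial += 1
            variants.append(Variant(f"m{serial:06d}", name, pos,
                                    "ACGT"[refc], "ACGT"[altc]))
    return sorted(variants)


def assign_genotypes(variants: Sequence[Variant],
                     genotype_frequencies: Mapping[str, float],
                     seed: int, sex: str = "female") -> TruthSet:
    """Draw a truth genotype per marker from diploid class frequencies.

    Hemizygous markers (male chrX, chrY) draw a single allele with the
    implied allele frequency; females carry no chrY genotype at all.
    """
    freqs = {g: float(genotype_frequencies.get(g, 0.0))
             for g in DIPLOID_LABELS}
    total = sum(freqs.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"genotype frequencies must sum to 1, got {total}")
    p_alt = freqs["BB"] + freqs["AB"] / 2  # implied alternative-allele freq
    rng = np.random.default_rng(seed)
    genotypes: dict[str, str] = {}
    probs = [freqs[g] for g in DIPLOID_LABELS]
    for v in variants:
        if v.chrom_class == CHRY and sex == "female":
            continue
        if v.chrom_class == CHRY or (v.chrom_class == CHRX and sex == "male"):
            genotypes[v.id] = "B" if rng.random() < p_alt else "A"
        else:
            genotypes[v.id] = DIPLOID_LABELS[
                int(rng.choice(3, p=probs))]
    return TruthSet(genotypes, sex)


def build_haplotypes(reference: Mapping[str, str],
                     variants: Sequence[Variant],
                     truth: TruthSet) -> list[tuple[str, str]]:
    """Apply planted alleles to per-chromosome haplotype copies.

    Autosomes and female chrX get two copies, male chrX/chrY one; female
    genomes carry no chrY sequence.
    """
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    haplotypes: list[tuple[str, str]] = []
    for name, seq in reference.items():
        cclass = classify_chrom(name)
        if cclass == CHRY and truth.sex == "female":
            continue
        n_copies = 1 if (cclass == CHRY or
                         (cclass == CHRX and truth.sex == "male")) else 2
        copies = [bytearray(seq, "ascii") for _ in range(n_copies)]
        for v in by_chrom.get(name, ()):
            g = truth.genotypes.get(v.id)
            if g is None:
                continue
            alt = ord(v.alt)
            if n_copies == 1:
                if g == "B":
                    copies[0][v.pos - 1] = alt
            else:
                if g == "AB":
                    copies[1][v.pos - 1] = alt
                elif g == "BB":
                    copies[0][v.pos - 1] = alt
                    copies[1][v.pos - 1] = alt
        for h, copy in enumerate(copies, start=1):
            haplotypes.append((f"{name}_h{h}", copy.decode("ascii")))
    return haplotypes


def plant_variants(reference: Mapping[str, str], n_markers: int,
                   genotype_frequencies: Mapping[str, float], seed: int,
                   k: int = 25, sex: str = "female"
                   ) -> tuple[list[Variant], TruthSet, list[tuple[str, str]]]:
    """Place markers, draw genotypes and build the carrier haplotypes."""
    variants = place_markers(reference, n_markers, seed, k=k)
    truth = assign_genotypes(variants, genotype_frequencies, seed + 1,
                             sex=sex)
    return variants, truth, build_haplotypes(reference, variants, truth)


# ---------------------------------------------------------------------------
# read simulation


def _open_out(path):
    p = str(path)
    if p.endswith(".gz"):
        # fixed mtime so identical simulations give identical bytes
        return gzip.GzipFile(filename="", mode="wb", fileobj=open(p, "wb"),
                             mtime=0, compresslevel=4)
    return open(p, "wb")


def simulate_reads(haplotypes: Sequence[tuple[str, str]],
                   config: SimConfig, out1, out2,
                   reference_length: int | None = None) -> int:
    """Write paired-end reads from the haplotypes; returns the pair count.

    Fragments are placed uniformly on each haplotype (counts proportional
    to haplotype length), with insert sizes ~ Normal(insert_mean,
    insert_sd) truncated to [2 * read_length, haplotype length]; read 1 is
    the fragment start on the forward strand, read 2 the reverse
    complement of the fragment end.  Every base is substituted by one of
    the other three with probability ``base_error_rate``.  The pair count
    is ``coverage * genome_length / (2 * read_length)``, with
    ``genome_length`` the haploid reference length (so each haplotype copy
    is sampled at about half the nominal coverage).  Deterministic given
    ``config.seed``.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    L = config.read_length
    lengths = np.array([len(s) for _, s in haplotypes], dtype=np.int64)
    if (lengths <= config.insert_mean).any():
        raise ValueError("every haplotype must be longer than the mean "
                         "insert size")
    ref_len = int(reference_length if reference_length is not None
                  else lengths.sum() // 2)
    n_pairs = int(round(config.coverage * ref_len / (2 * L)))
    rng = np.random.default_rng(config.seed)
    per_hap = rng.multinomial(n_pairs, lengths / lengths.sum())

    f1, f2 = _open_out(out1), _open_out(out2)
    serial = 0
    try:
        for (name, seq), n_h in zip(haplotypes, per_hap):
            if n_h == 0:
                continue
            codes = dna.seq_to_codes(seq)
            if (codes > 3).any():
                raise ValueError(f"haplotype {name} contains non-ACGT bases")
            for lo in range(0, int(n_h), 200_000):
                n = min(200_000, int(n_h) - lo)
                serial = _emit_batch(codes, name, n, serial, config, rng,
                                     f1, f2)
    finally:
        f1.close()
        f2.close()
    return n_pairs


def _emit_batch(codes: np.ndarray, hap_name: str, n: int, serial: int,
                config: SimConfig, rng: np.random.Generator,
                f1, f2) -> int:
    L = config.read_length
    hap_len = codes.shape[0]
    insert = np.rint(rng.normal(config.insert_mean, config.insert_sd,
                                size=n)).astype(np.int64)
    np.clip(insert, 2 * L, hap_len, out=insert)
    start = (rng.random(n) * (hap_len - insert + 1)).astype(np.int64)

    offs = np.arange(L, dtype=np.int64)
    r1 = codes[start[:, None] + offs].astype(np.uint8)
    r2 = (3 - codes[(start + insert - 1)[:, None] - offs]).astype(np.uint8)

    e = config.base_error_rate
    if e > 0:
        for r in (r1, r2):
            mask = rng.random((n, L)) < e
            shift = rng.integers(1, 4, size=(n, L), dtype=np.uint8)
            r += np.where(mask, shift, 0).astype(np.uint8)
            r %= 4

    qual = b"I" * L
    for fh, reads, mate in ((f1, r1, 1), (f2, r2, 2)):
        ascii_mat = _ASCII[reads]
        parts = []
        for i in range(n):
            parts.append(b"@%s_p%d/%d\n" % (hap_name.encode(),
                                            serial + i + 1, mate))
            parts.append(ascii_mat[i].tobytes())
            parts.append(b"\n+\n")
            parts.append(qual)
            parts.append(b"\n")
        fh.write(b"".join(parts))
    return serial + n


# ---------------------------------------------------------------------------
# scoring


def evaluate_calls(calls: pd.DataFrame, truth: TruthSet) -> dict:
    """Score called genotypes against the planted truth.

    Sensitivity (truth AB/BB called correctly) and specificity (truth AA
    called AA) are computed over autosomal markers only; the per-label
    fractions and the confusion table cover every evaluated marker.
    Raises when a called marker has no truth genotype.
    """
    missing = [vid for vid in calls["id"] if vid not in truth.genotypes]
    if missing:
        raise ValueError(
            f"{len(missing)} called markers have no truth genotype "
            f"(first: {missing[0]!r})")

    df = calls.copy()
    df["truth"] = [truth.genotypes[vid] for vid in df["id"]]
    df["cclass"] = [classify_chrom(c) for c in df["chrom"]]

    auto = df[df["cclass"] == AUTOSOME]
    pos = auto[auto["truth"].isin(["AB", "BB"])]
    neg = auto[auto["truth"] == "AA"]
    sensitivity = (float((pos["label"] == pos["truth"]).mean())
                   if len(pos) else None)
    specificity = (float((neg["label"] == "AA").mean())
                   if len(neg) else None)

    fractions = {lab: float((df["label"] == lab).mean())
                 for lab in ("AA", "AB", "BB", "NC", "A", "B")}
    confusion = (
        df.groupby(["truth", "label"]).size().unstack(fill_value=0))
    return {
        "n_markers": int(len(df)),
        "n_autosomal": int(len(auto)),
        "n_truth_positive": int(len(pos)),
        "n_truth_negative": int(len(neg)),
        "sensitivity": sensitivity,
        "specificity": specificity,
        "concordance": float((df["label"] == df["truth"]).mean()),
        "nc_fraction": float((df["label"] == "NC").mean()),
        "fractions": fractions,
        "counts": {lab: int((df["label"] == lab).sum())
                   for lab in ("AA", "AB", "BB", "NC", "A", "B")},
        "confusion": confusion,
    }
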