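"""Marker database: unique k-mer pairs for known bi-allelic SNVs.

A genotyping marker is an SNV together with up to ``max_pairs`` k-mer pairs,
where the two members of a pair are identical except at the variant base
(one carries the reference allele, the other the alternative allele).  The
database is compiled from a reference genome and a variant list in three
filtering steps:

1. *neighbor filter* -- drop SNVs that have another variant or indel base
   within k bases on either side, so at least one k-mer covering the SNV
   overlaps no other variant;
2. *uniqueness filter* -- drop pairs whose members occur more than once in
   the "expanded reference" (all reference k-mers plus every alternative
   k-mer of known SNVs/indels), counted in canonical (strand-neutral)
   space; pairs that stay unique even under one mismatch are flagged and
   preferred during selection;
3. *panel filter* (optional) -- drop markers that behave abnormally in a
   panel of sequenced individuals (female chrY signal, counts far above an
   individual's median depth, recurrent non-canonical genotypes).

Indels in the variant input are used only for window exclusion and for
expanded-reference construction; they are never emitted as markers.
Coordinates are 1-based and fully closed (VCF convention) throughout.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left, bisect_right
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np

from . import dna

logger = logging.getLogger(__name__)

AUTOSOME = "autosome"
CHRX = "chrX"
CHRY = "chrY"

_VALID_BASES = frozenset("ACGT")


def classify_chrom(name: str) -> str:
    """Map a chromosome name to autosome / chrX / chrY."""
    short = name.lower().removeprefix("chr")
    if short in ("x",):
        return CHRX
    if short in ("y",):
        return CHRY
    return AUTOSOME


@dataclass(frozen=True, order=True)
class Variant:
    """A known bi-allelic SNV (1-based position, single-base alleles)."""

    chrom: str
    pos: int
    id: str = field(compare=False)
    ref: str = field(compare=False)
    alt: str = field(compare=False)
    chrom_class: str = field(compare=False, default="")

    def __init__(self, id: str, chrom: str, pos: int, ref: str, alt: str,
                 chrom_class: str | None = None):
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", int(pos))
        object.__setattr__(self, "ref", ref.upper())
        object.__setattr__(self, "alt", alt.upper())
        object.__setattr__(
            self, "chrom_class",
            chrom_class if chrom_class is not None else classify_chrom(chrom))
        if self.pos < 1:
            raise ValueError(f"{id}: position must be >= 1, got {self.pos}")
        if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
            raise ValueError(
                f"{id}: alleles must be single bases A/C/G/T, "
                f"got {self.ref!r}/{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"{id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class Indel:
    """An insertion/deletion used only for k-mer exclusion, never as marker."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def occupied(self) -> tuple[int, int]:
        """1-based closed interval of reference bases touched by the indel."""
        return self.pos, self.pos + max(len(self.ref), 1) - 1


@dataclass(frozen=True)
class KmerPair:
    """Two k-mers differing only at the variant base."""

    ref_kmer: str
    alt_kmer: str
    snv_offset: int
    mismatch_unique: bool = False

    def __post_init__(self):
        if len(self.ref_kmer) != len(self.alt_kmer):
            raise ValueError("pair members must have equal length")
        diff = [i for i, (a, b) in enumerate(zip(self.ref_kmer, self.alt_kmer))
                if a != b]
        if diff != [self.snv_offset]:
            raise ValueError(
                f"pair members must differ exactly at snv_offset "
                f"{self.snv_offset}, differ at {diff}")

    @property
    def k(self) -> int:
        return len(self.ref_kmer)


@dataclass(frozen=True)
class MarkerRecord:
    """A variant plus its selected k-mer pairs (1-3)."""

    variant: Variant
    pairs: tuple[KmerPair, ...]

    def __post_init__(self):
        if not 1 <= len(self.pairs) <= 3:
            raise ValueError(
                f"{self.variant.id}: a marker carries 1-3 pairs, "
                f"got {len(self.pairs)}")


@dataclass(frozen=True)
class DBConfig:
    """Database build parameters (k defaults to 25)."""

    k: int = 25
    prefer_mismatch_unique: bool = True
    max_pairs: int = 3

    def __post_init__(self):
        if not 16 <= self.k <= 32:
            raise ValueError(f"k must be in [16, 32], got {self.k}")
        if self.max_pairs < 1:
            raise ValueError("max_pairs must be >= 1")


class ExpandedReference:
    """Multiset of canonical k-mers: reference plus all alternative alleles.

    Stored as a sorted array of canonical codes with occurrence counts, so
    membership and count queries are vectorized binary searches.
    """

    def __init__(self, k: int, codes: np.ndarray, counts: np.ndarray):
        self.k = k
        self.codes = codes
        self.counts = counts

    @property
    def total_kmers(self) -> int:
        return int(self.counts.sum())

    @property
    def distinct_kmers(self) -> int:
        return int(self.codes.shape[0])

    def count_codes(self, canonical: np.ndarray) -> np.ndarray:
        """Occurrence counts for already-canonical codes (vectorized)."""
        canonical = np.asarray(canonical, dtype=np.uint64)
        idx = np.searchsorted(self.codes, canonical)
        idx_c = np.minimum(idx, len(self.codes) - 1) if len(self.codes) else idx
        if len(self.codes) == 0:
            return np.zeros(canonical.shape, dtype=np.int64)
        hit = self.codes[idx_c] == canonical
        out = np.where(hit, self.counts[idx_c], 0)
        return out.astype(np.int64)

    def count(self, kmer: str) -> int:
        """Occurrence count of one k-mer (canonicalized internally)."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        code = dna.canonical_codes(dna.encode_kmer(kmer), self.k)
        return int(self.count_codes(np.array([code], dtype=np.uint64))[0])


@dataclass
class PanelObservation:
    """Counts of one panel individual used by filtering step 3.

    ``counts`` maps marker id -> ((ref_count, alt_count), ...) per pair in
    database order; ``median_autosomal`` is the individual's median
    per-pair autosomal total count.
    """

    individual_id: str
    sex: str  # "male" | "female"
    counts: Mapping[str, tuple[tuple[int, int], ...]]
    median_autosomal: float


# ---------------------------------------------------------------------------
# filtering step 1: neighborhood


def _check_sorted(variants: Sequence[Variant]) -> None:
    for a, b in zip(variants, variants[1:]):
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            raise ValueError(
                f"variants must be sorted by (chrom, pos): "
                f"{a.chrom}:{a.pos} precedes {b.chrom}:{b.pos}")
        if (a.chrom, a.pos) == (b.chrom, b.pos):
            raise ValueError(
                f"duplicate variant position {a.chrom}:{a.pos} "
                f"({a.id}, {b.id})")


def neighbor_filter(variants: Sequence[Variant], k: int,
                    indels: Iterable[Indel] = ()) -> list[Variant]:
    """Keep SNVs with a variant-free flank of >= k bases on each side.

    A variant is removed iff another SNV position or indel-occupied base
    lies within k bases on either side, i.e. whenever no k-mer covering the
    SNV can avoid all other variants with a full flank.  Input must be
    sorted by (chrom, pos); duplicate positions are an error.
    """
    variants = list(variants)
    _check_sorted(variants)

    by_chrom_pos: dict[str, list[int]] = {}
    for v in variants:
        by_chrom_pos.setdefault(v.chrom, []).append(v.pos)
    # indel occupied intervals, sorted per chromosome
    iv_by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for ind in indels:
        iv_by_chrom.setdefault(ind.chrom, ([], []))
        s, e = ind.occupied
        iv_by_chrom[ind.chrom][0].append(s)
        iv_by_chrom[ind.chrom][1].append(e)
    for chrom, (starts, ends) in iv_by_chrom.items():
        order = sorted(range(len(starts)), key=starts.__getitem__)
        iv_by_chrom[chrom] = ([starts[i] for i in order],
                              [ends[i] for i in order])

    kept = []
    for v in variants:
        positions = by_chrom_pos[v.chrom]
        i = bisect_left(positions, v.pos)
        if i > 0 and v.pos - positions[i - 1] <= k:
            continue
        if i + 1 < len(positions) and positions[i + 1] - v.pos <= k:
            continue
        starts, ends = iv_by_chrom.get(v.chrom, ([], []))
        # any indel interval intersecting [pos-k, pos+k]?
        j = bisect_right(starts, v.pos + k)
        if j > 0 and ends[j - 1] >= v.pos - k:
            # nearest interval starting at or left of pos+k reaches pos-k;
            # intervals are not nested in practice (indels are short), but
            # scan leftwards to be safe
            hit = False
            for jj in range(j - 1, -1, -1):
                if ends[jj] >= v.pos - k:
                    hit = True
                    break
                if v.pos - k - starts[jj] > 10_000:
                    break
            if hit:
                continue
        kept.append(v)
    return kept


# ---------------------------------------------------------------------------
# pair enumeration


def _free_flanks(variant: Variant, chrom_len: int,
                 positions: Sequence[int],
                 intervals: tuple[Sequence[int], Sequence[int]]) -> tuple[int, int]:
    """Variant-free bases immediately left/right of the SNV (within chrom)."""
    pos = variant.pos
    left_bound = 0  # rightmost occupied base strictly left of pos (0 = none)
    right_bound = chrom_len + 1
    i = bisect_left(positions, pos)  # positions exclude pos itself
    if i > 0:
        left_bound = positions[i - 1]
    if i < len(positions):
        right_bound = positions[i]
    starts, ends = intervals
    for s, e in zip(starts, ends):
        if e < pos:
            left_bound = max(left_bound, e)
        elif s > pos:
            right_bound = min(right_bound, s)
            break
        else:  # interval covers the SNV itself: no variant-free window
            return -1, -1
    return pos - left_bound - 1, right_bound - pos - 1


def enumerate_pairs(reference: str, variant: Variant,
                    neighbor_variants: Iterable[Variant | Indel],
                    config: DBConfig) -> list[KmerPair]:
    """All candidate k-mer pairs inside the variant-free window of an SNV.

    Pairs are ordered by ``snv_offset`` ascending (window start sliding from
    the SNV leftwards).  Windows containing non-ACGT reference bases are
    skipped.  With >= k-1 variant-free bases on both sides the SNV is
    covered by exactly k pairs.
    """
    k = config.k
    pos = variant.pos
    if not 1 <= pos <= len(reference):
        raise ValueError(f"{variant.id}: position {pos} outside reference "
                         f"of length {len(reference)}")
    refbase = reference[pos - 1].upper()
    if refbase != variant.ref:
        raise ValueError(
            f"{variant.id}: reference mismatch at {variant.chrom}:{pos} "
            f"(reference has {refbase!r}, variant declares {variant.ref!r})")

    positions = []
    starts: list[int] = []
    ends: list[int] = []
    for nb in neighbor_variants:
        if nb.chrom != variant.chrom:
            continue
        if isinstance(nb, Indel):
            s, e = nb.occupied
            starts.append(s)
            ends.append(e)
        elif nb.pos != pos:
            positions.append(nb.pos)
    positions.sort()
    order = sorted(range(len(starts)), key=starts.__getitem__)
    starts = [starts[i] for i in order]
    ends = [ends[i] for i in order]

    gl, gr = _free_flanks(variant, len(reference), positions, (starts, ends))
    lo = max(0, k - 1 - gr)
    hi = min(k - 1, gl)
    pairs = []
    for offset in range(lo, hi + 1):
        start0 = pos - 1 - offset
        window = reference[start0 : start0 + k].upper()
        if len(window) < k or any(b not in _VALID_BASES for b in window):
            continue
        alt_kmer = window[:offset] + variant.alt + window[offset + 1 :]
        pairs.append(KmerPair(window, alt_kmer, offset))
    return pairs


# ---------------------------------------------------------------------------
# filtering step 2: uniqueness in the expanded reference


def build_expanded_reference(reference: Mapping[str, str],
                             all_variants: Iterable[Variant],
                             indels: Iterable[Indel] = (),
                             k: int = 25) -> ExpandedReference:
    """Canonical k-mer multiset of the reference plus all alternative alleles.

    Contains every positional k-mer of every reference sequence (counted
    with multiplicity) plus, for each SNV/indel, every k-mer overlapping
    its alternative allele.  Windows containing non-ACGT bases are skipped
    and logged.
    """
    chunks: list[np.ndarray] = []
    skipped = 0
    for name, seq in reference.items():
        codes = dna.seq_to_codes(seq)
        win, valid = dna.kmer_codes(codes, k)
        skipped += int((~valid).sum())
        chunks.append(dna.canonical_codes(win[valid], k))

    # alternative-allele k-mers: build one long sequence with 'N' sentinels
    # between windows so a single rolling pass can encode them all
    alt_parts: list[str] = []
    for v in all_variants:
        seq = reference.get(v.chrom)
        if seq is None:
            raise KeyError(f"variant {v.id}: unknown chromosome {v.chrom!r}")
        p0 = v.pos - 1
        left = seq[max(0, p0 - (k - 1)) : p0]
        right = seq[p0 + 1 : p0 + k]
        alt_parts.append((left + v.alt + right).upper())
    for ind in indels:
        seq = reference.get(ind.chrom)
        if seq is None:
            raise KeyError(f"indel at {ind.chrom}:{ind.pos}: unknown chromosome")
        p0 = ind.pos - 1
        left = seq[max(0, p0 - (k - 1)) : p0]
        right = seq[p0 + len(ind.ref) : p0 + len(ind.ref) + k - 1]
        window = (left + ind.alt + right).upper()
        # keep only k-mers overlapping the replaced segment
        fl = len(left)
        lo = max(0, fl - k + 1)
        hi = min(len(window) - k, fl + len(ind.alt) - 1)
        if hi >= lo:
            alt_parts.append(window[lo : hi + k])

    if alt_parts:
        joined = "N".join(alt_parts)
        codes = dna.seq_to_codes(joined)
        win, valid = dna.kmer_codes(codes, k)
        skipped += sum(
            1 for part in alt_parts for b in part if b not in _VALID_BASES)
        chunks.append(dna.canonical_codes(win[valid], k))

    if skipped:
        logger.info("expanded reference: skipped %d windows containing "
                    "non-ACGT bases", skipped)
    allcodes = (np.concatenate(chunks) if chunks
                else np.empty(0, dtype=np.uint64))
    codes, counts = np.unique(allcodes, return_counts=True)
    return ExpandedReference(k, codes, counts)


def _pair_codes(pairs: Sequence[KmerPair], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes of (ref, alt) members for a list of pairs."""
    n = len(pairs)
    ref = np.empty(n, dtype=np.uint64)
    alt = np.empty(n, dtype=np.uint64)
    if n:
        mat = dna.BASE_CODES[
            np.frombuffer(
                "".join(p.ref_kmer + p.alt_kmer for p in pairs).encode(),
                dtype=np.uint8,
            )
        ].reshape(n * 2, k)
        codes = dna.encode_kmer_matrix(mat)
        ref = dna.canonical_codes(codes[0::2], k)
        alt = dna.canonical_codes(codes[1::2], k)
    return ref, alt


def _hamming1_total(codes: np.ndarray, k: int,
                    expref: ExpandedReference) -> np.ndarray:
    """Summed expanded-reference counts over all HD-1 neighbors of each code.

    ``codes`` are plain (non-canonical) k-mer codes; neighbors are
    canonicalized before lookup.
    """
    n = codes.shape[0]
    total = np.zeros(n, dtype=np.int64)
    if n == 0:
        return total
    chunk = max(1, 4_000_000 // (3 * k))
    for lo in range(0, n, chunk):
        sub = codes[lo : lo + chunk]
        nb = dna.hamming1_neighbor_codes(sub, k)
        canon = dna.canonical_codes(nb.ravel(), k)
        cnt = expref.count_codes(canon).reshape(nb.shape)
        total[lo : lo + chunk] = cnt.sum(axis=1)
    return total


def uniqueness_filter(pairs: Sequence[KmerPair], expref: ExpandedReference,
                      config: DBConfig) -> list[KmerPair]:
    """Keep pairs whose members occur at most once in the expanded reference.

    The single allowed occurrence is the variant's own locus.  Surviving
    pairs get ``mismatch_unique=True`` iff no *other* expanded-reference
    k-mer lies within Hamming distance 1 of either member (each member's
    partner at the same locus is not "other": ref and alt differ by exactly
    one base by construction).
    """
    if not pairs:
        return []
    k = pairs[0].k
    if any(p.k != k for p in pairs):
        raise ValueError("pairs have mixed k-mer lengths")
    if k != expref.k:
        raise ValueError(
            f"pair length k={k} does not match expanded reference "
            f"k={expref.k}")

    ref_c, alt_c = _pair_codes(pairs, k)
    ref_counts = expref.count_codes(ref_c)
    alt_counts = expref.count_codes(alt_c)
    keep = (ref_counts <= 1) & (alt_counts <= 1)

    # 1-mismatch uniqueness for the survivors
    idx = np.nonzero(keep)[0]
    kept_pairs = [pairs[i] for i in idx]
    ref_plain = np.array(
        [dna.encode_kmer(p.ref_kmer) for p in kept_pairs], dtype=np.uint64)
    alt_plain = np.array(
        [dna.encode_kmer(p.alt_kmer) for p in kept_pairs], dtype=np.uint64)
    ref_nb = _hamming1_total(ref_plain, k, expref)
    alt_nb = _hamming1_total(alt_plain, k, expref)
    # discount the partner's own occurrence (it is an HD-1 neighbor)
    ref_other = ref_nb - alt_counts[idx]
    alt_other = alt_nb - ref_counts[idx]
    out = []
    for j, p in enumerate(kept_pairs):
        out.append(replace(p, mismatch_unique=bool(
            ref_other[j] == 0 and alt_other[j] == 0)))
    return out


# ---------------------------------------------------------------------------
# pair selection


def select_pairs(candidates: Sequence[KmerPair],
                 config: DBConfig) -> list[KmerPair]:
    """Deterministically pick up to ``max_pairs`` pairs.

    Mismatch-unique pairs first (soft preference), then by distance of the
    variant base from the k-mer center (most centered first), ties broken
    by the smaller offset.  Pure function of the candidate *set*: the
    result does not depend on input order.
    """
    center = (config.k - 1) / 2

    def key(p: KmerPair):
        pref = 0 if (p.mismatch_unique or not config.prefer_mismatch_unique) \
            else 1
        return (pref, abs(p.snv_offset - center), p.snv_offset)

    ranked = sorted(candidates, key=key)
    return ranked[: config.max_pairs]


# ---------------------------------------------------------------------------
# filtering step 3: panel


def panel_filter(markers: Sequence[MarkerRecord],
                 panel: Sequence[PanelObservation],
                 caller) -> list[MarkerRecord]:
    """Drop markers that misbehave in a panel of sequenced individuals.

    Removes (1) chrY markers with any k-mer count > 3 in more than one
    woman, (2) markers with a k-mer count > 3x the individual's median
    autosomal count in more than one individual, and (3) markers whose
    called genotype is non-canonical (allele copies != 2 on autosomes /
    female chrX, != 1 on male chrX/chrY) in more than one individual.

    ``caller(pair_counts, chrom_class, sex) -> (cA, cB)`` supplies the
    genotype for criterion 3.  Sex-chromosome criteria use male panel
    members only; an empty panel passes everything through with a warning.
    """
    if not panel:
        warnings.warn("panel filter skipped: empty panel", stacklevel=2)
        return list(markers)

    kept = []
    for m in markers:
        mid = m.variant.id
        cclass = m.variant.chrom_class

        # criterion 1: chrY signal in women
        if cclass == CHRY:
            n_women = sum(
                1 for obs in panel
                if obs.sex == "female" and mid in obs.counts
                and any(c > 3 for rc in obs.counts[mid] for c in rc))
            if n_women > 1:
                continue

        # criterion 2: counts far above the individual's median depth
        n_high = 0
        for obs in panel:
            if mid not in obs.counts:
                continue
            lim = 3 * obs.median_autosomal
            if any(c > lim for rc in obs.counts[mid] for c in rc):
                n_high += 1
        if n_high > 1:
            continue

        # criterion 3: recurrent non-canonical genotypes
        expected = 2
        use = panel
        if cclass in (CHRX, CHRY):
            use = [obs for obs in panel if obs.sex == "male"]
            expected = 1
        n_noncanon = 0
        for obs in use:
            if mid not in obs.counts:
                continue
            ca, cb = caller(obs.counts[mid], cclass, obs.sex)
            if ca + cb != expected:
                n_noncanon += 1
        if n_noncanon > 1:
            continue

        kept.append(m)
    return kept


# ---------------------------------------------------------------------------
# whole-database compilation


def build_marker_db(reference: Mapping[str, str],
                    variants: Sequence[Variant],
                    indels: Sequence[Indel] = (),
                    config: DBConfig = DBConfig(),
                    panel: Sequence[PanelObservation] | None = None,
                    caller=None) -> tuple[list[MarkerRecord], dict]:
    """Run the full database compilation and return (markers, report).

    The report counts variants surviving each stage and lists variants
    dropped for lack of unique pairs.
    """
    k = config.k
    variants = sorted(variants)
    _check_sorted(variants)
    report: dict = {"input": len(variants)}

    step1 = neighbor_filter(variants, k, indels)
    report["after_neighbor_filter"] = len(step1)

    expref = build_expanded_reference(reference, variants, indels, k)
    report["expanded_reference_kmers"] = expref.total_kmers

    # enumerate candidates for all surviving variants, then run one
    # vectorized uniqueness pass over the whole batch
    neighbors_by_chrom: dict[str, list] = {}
    for v in variants:
        neighbors_by_chrom.setdefault(v.chrom, []).append(v)
    for ind in indels:
        neighbors_by_chrom.setdefault(ind.chrom, []).append(ind)

    per_variant: list[tuple[Variant, list[KmerPair]]] = []
    flat: list[KmerPair] = []
    spans: list[tuple[int, int]] = []
    for v in step1:
        cands = enumerate_pairs(reference[v.chrom], v,
                                neighbors_by_chrom.get(v.chrom, ()), config)
        spans.append((len(flat), len(flat) + len(cands)))
        flat.extend(cands)
        per_variant.append((v, cands))

    filtered_flat = _bulk_uniqueness(flat, expref, config) if flat else []

    markers: list[MarkerRecord] = []
    dropped: list[str] = []
    pos = 0
    for (v, cands), (lo, hi) in zip(per_variant, spans):
        survivors = [p for p in filtered_flat[lo:hi] if p is not None]
        chosen = select_pairs(survivors, config)
        if chosen:
            markers.append(MarkerRecord(v, tuple(chosen)))
        else:
            dropped.append(v.id)
    report["after_uniqueness_filter"] = len(markers)
    report["dropped_no_unique_pairs"] = dropped
    if dropped:
        logger.info("%d variants dropped: no unique k-mer pairs", len(dropped))

    if panel:
        markers = panel_filter(markers, panel, caller)
        report["after_panel_filter"] = len(markers)
    return markers, report


def _bulk_uniqueness(pairs: Sequence[KmerPair], expref: ExpandedReference,
                     config: DBConfig) -> list[KmerPair | None]:
    """Vectorized uniqueness pass preserving positions (None = removed)."""
    k = config.k
    if k != expref.k:
        raise ValueError("k mismatch between pairs and expanded reference")
    ref_c, alt_c = _pair_codes(pairs, k)
    ref_counts = expref.count_codes(ref_c)
    alt_counts = expref.count_codes(alt_c)
    keep = (ref_counts <= 1) & (alt_counts <= 1)

    n = len(pairs)
    mat = dna.BASE_CODES[
        np.frombuffer(
            "".join(p.ref_kmer + p.alt_kmer for p in pairs).encode(),
            dtype=np.uint8,
        )
    ].reshape(n * 2, k)
    plain = dna.encode_kmer_matrix(mat)
    idx = np.nonzero(keep)[0]
    ref_nb = _hamming1_total(plain[0::2][idx], k, expref)
    alt_nb = _hamming1_total(plain[1::2][idx], k, expref)
    mm = (ref_nb - alt_counts[idx] == 0) & (alt_nb - ref_counts[idx] == 0)

    out: list[KmerPair | None] = [None] * n
    for j, i in enumerate(idx):
        out[i] = replace(pairs[i], mismatch_unique=bool(mm[j]))
    return out


# ---------------------------------------------------------------------------
# flat-file formats

DB_MAGIC = "#kmergt-db v1"


def write_db(markers: Sequence[MarkerRecord], path) -> None:
    """Write the marker database (versioned TSV; byte-deterministic)."""
    if markers:
        k = markers[0].pairs[0].k
    else:
        k = DBConfig().k
    with open(path, "w", newline="\n") as fh:
        fh.write(f"{DB_MAGIC} k={k}\n")
        for m in markers:
            v = m.variant
            fields = [v.id, v.chrom, str(v.pos), v.ref, v.alt,
                      str(len(m.pairs))]
            for p in m.pairs:
                fields += [p.ref_kmer, p.alt_kmer, str(p.snv_offset),
                           "1" if p.mismatch_unique else "0"]
            fh.write("\t".join(fields) + "\n")


def read_db(path) -> list[MarkerRecord]:
    """Read a marker database written by :func:`write_db`."""
    markers = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(DB_MAGIC):
            raise ValueError(f"{path}: not a kmergt marker database "
                             f"(bad header {header!r})")
        try:
            k = int(header.split("k=")[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: malformed header {header!r}") from exc
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                vid, chrom, pos, ref, alt, npairs = fields[:6]
                npairs = int(npairs)
                if len(fields) != 6 + 4 * npairs:
                    raise ValueError(
                        f"expected {6 + 4 * npairs} fields, got {len(fields)}")
                pairs = []
                for i in range(npairs):
                    rk, ak, off, mm = fields[6 + 4 * i : 10 + 4 * i]
                    for km in (rk, ak):
                        if len(km) != k or any(b not in _VALID_BASES
                                               for b in km):
                            raise ValueError(
                                f"invalid {k}-mer {km!r}")
                    pairs.append(KmerPair(rk, ak, int(off), mm == "1"))
                variant = Variant(vid, chrom, int(pos), ref, alt)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed marker line "
                                 f"({exc})") from exc
            if vid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate marker id "
                                 f"{vid!r}")
            seen.add(vid)
            markers.append(MarkerRecord(variant, tuple(pairs)))
    return markers


# ---------------------------------------------------------------------------
# external inputs: FASTA reference, VCF / TSV variant lists


def read_reference(path) -> dict[str, str]:
    """Read a (multi-)FASTA reference into {name: uppercase sequence}."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_reference(reference: Mapping[str, str], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_variants(path) -> tuple[list[Variant], list[Indel]]:
    """Read SNVs (and indels, for exclusion only) from VCF or 5-column TSV.

    TSV columns: ``id chrom pos ref alt``.  VCF records with multiple ALT
    alleles are skipped with a warning (markers are strictly bi-allelic);
    length-changing records become exclusion indels.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_vcf(path)
    variants: list[Variant] = []
    indels: list[Indel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns "
                                 f"`id chrom pos ref alt`, got {len(fields)}")
            vid, chrom, pos, ref, alt = fields[:5]
            try:
                if len(ref) == 1 and len(alt) == 1:
                    variants.append(Variant(vid, chrom, int(pos), ref, alt))
                else:
                    indels.append(Indel(chrom, int(pos), ref.upper(),
                                        alt.upper()))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return variants, indels


def _read_vcf(path: str) -> tuple[list[Variant], list[Indel]]:
    import pysam

    variants: list[Variant] = []
    indels: list[Indel] = []
    skipped_multi = 0
    with pysam.VariantFile(path) as vcf:
        for i, rec in enumerate(vcf):
            alts = rec.alts or ()
            if len(alts) != 1:
                skipped_multi += 1
                continue
            alt = alts[0]
            vid = rec.id or f"var{i + 1}"
            if len(rec.ref) == 1 and len(alt) == 1 and \
                    rec.ref.upper() in _VALID_BASES and \
                    alt.upper() in _VALID_BASES:
                variants.append(
                    Variant(vid, rec.chrom, rec.pos, rec.ref, alt))
            else:
                indels.append(Indel(rec.chrom, rec.pos, rec.ref.upper(),
                                    alt.upper()))
    if skipped_multi:
        warnings.warn(
            f"{path}: skipped {skipped_multi} multi-allelic records "
            "(markers are strictly bi-allelic)", stacklevel=2)
    return variants, indels


def write_variants_tsv(variants: Iterable[Variant], path,
                       indels: Iterable[Indel] = ()) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("#id\tchrom\tpos\tref\talt\n")
        rows = [(v.chrom, v.pos, v.id, v.ref, v.alt) for v in variants]
        rows += [(d.chrom, d.pos, f"indel_{d.chrom}_{d.pos}", d.ref, d.alt)
                 for d in indels]
        for chrom, pos, vid, ref, alt in sorted(rows):
            fh.write(f"{vid}\t{chrom}\t{pos}\t{ref}\t{alt}\n")
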