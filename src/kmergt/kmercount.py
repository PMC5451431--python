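"""Counting database k-mers directly in FASTQ reads.

The counter holds *only* the k-mers of interest (every pair member of every
marker) in a fixed-size structure: a dense first-level index on the first
``min(14, k)`` bases and, per prefix, a sorted array of packed suffixes
sharing one 16-bit saturating counter slot per k-mer.  Memory is therefore
proportional to the number of database k-mers and never to the size of the
read set -- counting a 1x and a 40x genome uses the identical structure.

Reads are streamed in batches; every length-k window over {A,C,G,T} is
canonicalized and, when present in the index, its counter is incremented
(saturating at 65535).  Windows containing non-ACGT characters are skipped,
lowercase bases are upcased, quality strings are ignored, and reads shorter
than k contribute nothing.  Counts are invariant under reverse-complementing
reads and under splitting the input across files.
"""

from __future__ import annotations

import gzip
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np

from . import dna
from .variantdb import MarkerRecord

logger = logging.getLogger(__name__)

COUNTER_MAX = 65535  # two bytes per k-mer
COUNTS_MAGIC = "#kmergt-counts v1"


def saturating_increment(counter: int) -> int:
    """Increment a 16-bit counter, saturating at 65535."""
    if counter < 0 or counter > COUNTER_MAX:
        raise ValueError(f"counter out of range: {counter}")
    return min(counter + 1, COUNTER_MAX)


class KmerIndex:
    """Sparse canonical-k-mer -> saturating 16-bit counter map."""

    #: k-mer lengths the counter itself accepts (the marker database is
    #: stricter and enforces 16-32)
    MIN_K, MAX_K = 14, 32

    def __init__(self, k: int, codes: np.ndarray):
        if not self.MIN_K <= k <= self.MAX_K:
            raise ValueError(f"k must be in [{self.MIN_K}, {self.MAX_K}], "
                             f"got {k}")
        self.k = k
        self.prefix_len = min(14, k)
        self.codes = np.sort(np.unique(codes)).astype(np.uint64)
        self.counters = np.zeros(len(self.codes), dtype=np.uint16)
        # dense-by-construction first level: prefix -> slice of the sorted
        # suffix-ordered code array (sorted codes group by prefix)
        shift = np.uint64(2 * (k - self.prefix_len))
        prefixes = self.codes >> shift
        self._prefix_table: dict[int, tuple[int, int]] = {}
        if len(prefixes):
            bounds = np.flatnonzero(np.diff(prefixes)) + 1
            starts = np.concatenate(([0], bounds))
            stops = np.concatenate((bounds, [len(prefixes)]))
            for p, lo, hi in zip(prefixes[starts], starts, stops):
                self._prefix_table[int(p)] = (int(lo), int(hi))

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def nbytes(self) -> int:
        """Memory held by code + counter storage (read-set independent)."""
        return int(self.codes.nbytes + self.counters.nbytes)

    def _find(self, canonical_code: int) -> int:
        """Slot of a canonical code, or -1 when absent (O(k) + O(log s))."""
        shift = 2 * (self.k - self.prefix_len)
        span = self._prefix_table.get(int(canonical_code) >> shift)
        if span is None:
            return -1
        lo, hi = span
        i = int(np.searchsorted(self.codes[lo:hi],
                                np.uint64(canonical_code))) + lo
        if i < hi and int(self.codes[i]) == int(canonical_code):
            return i
        return -1

    def lookup(self, kmer: str) -> int | None:
        """Counter value for a k-mer, or None when it is not in the index."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)}")
        i = self._find(dna.canonical_codes(dna.encode_kmer(kmer), self.k))
        return int(self.counters[i]) if i >= 0 else None

    def add_counts(self, canonical_codes: np.ndarray) -> None:
        """Add one occurrence per code (vectorized, saturating)."""
        idx = np.searchsorted(self.codes, canonical_codes)
        if len(self.codes) == 0:
            return
        idx_c = np.minimum(idx, len(self.codes) - 1)
        hit = self.codes[idx_c] == canonical_codes
        inc = np.bincount(idx_c[hit], minlength=len(self.codes))
        total = self.counters.astype(np.uint32) + inc.astype(np.uint32)
        np.minimum(total, COUNTER_MAX, out=total)
        self.counters = total.astype(np.uint16)


def build_index(markers: Sequence[MarkerRecord]) -> KmerIndex:
    """Index the canonical form of every pair member of every marker.

    Duplicate k-mers across markers share a counter slot and are reported
    (uniqueness filtering should have prevented them).
    """
    if not markers:
        raise ValueError("cannot build an index from zero markers")
    ks = {p.k for m in markers for p in m.pairs}
    if len(ks) != 1:
        raise ValueError(f"markers carry mixed k-mer lengths: {sorted(ks)}")
    k = ks.pop()
    if not 16 <= k <= 32:
        raise ValueError(f"database k must be in [16, 32], got {k}")

    kmers = [km for m in markers for p in m.pairs
             for km in (p.ref_kmer, p.alt_kmer)]
    mat = dna.BASE_CODES[
        np.frombuffer("".join(kmers).encode(), dtype=np.uint8)
    ].reshape(len(kmers), k)
    if (mat > 3).any():
        raise ValueError("database k-mers contain non-ACGT characters")
    codes = dna.canonical_codes(dna.encode_kmer_matrix(mat), k)
    n_dup = len(codes) - len(np.unique(codes))
    if n_dup:
        logger.warning("%d duplicate k-mers across markers share counter "
                       "slots", n_dup)
    index = KmerIndex(k, codes)
    index.n_duplicates = n_dup
    return index


# ---------------------------------------------------------------------------
# FASTQ streaming


def _open_maybe_gzip(path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rb")
    return open(p, "rb")


def _iter_fastq_seq_batches(path, batch_bases: int) -> Iterable[list[bytes]]:
    """Yield batches of raw sequence lines from one FASTQ file.

    Validates the 4-line record structure and raises with the file name and
    record number on truncation or malformed records.
    """
    pending: list[bytes] = []
    seqs: list[bytes] = []
    nbases = 0
    recno = 0

    def handle(group: list[bytes]):
        nonlocal recno, nbases
        recno += 1
        head, seq, plus, qual = group
        if not head.startswith(b"@") or not plus.startswith(b"+") \
                or len(seq) != len(qual):
            raise ValueError(
                f"{path}: malformed FASTQ record {recno}")
        seqs.append(seq)
        nbases += len(seq)

    with _open_maybe_gzip(path) as fh:
        carry = b""
        while True:
            block = fh.read(8 << 20)
            if not block:
                break
            lines = (carry + block).split(b"\n")
            carry = lines.pop()
            pending.extend(lines)
            ngroups = len(pending) // 4
            for g in range(ngroups):
                handle(pending[4 * g : 4 * g + 4])
                if nbases >= batch_bases:
                    yield seqs
                    seqs = []
                    nbases = 0
            del pending[: 4 * ngroups]
        if carry:
            pending.append(carry)
        while pending and pending[-1] == b"":
            pending.pop()
        if pending:
            if len(pending) % 4:
                raise ValueError(
                    f"{path}: truncated FASTQ record {recno + 1} "
                    f"(dangling {len(pending) % 4} line(s) at end of file)")
            for g in range(len(pending) // 4):
                handle(pending[4 * g : 4 * g + 4])
    if seqs:
        yield seqs


def count_reads(index: KmerIndex, fastq_paths: Sequence,
                batch_bases: int = 8_000_000) -> KmerIndex:
    """Count canonical window k-mers of all reads into the index.

    Multiple files may be given in any order; final counts are
    order-independent.  Returns the same index with counters updated.
    """
    if not fastq_paths:
        raise ValueError("no FASTQ files given")
    k = index.k
    for path in fastq_paths:
        for seqs in _iter_fastq_seq_batches(path, batch_bases):
            # join with an N sentinel: windows crossing read boundaries
            # contain an invalid base and are dropped by the validity mask
            joined = b"N".join(seqs)
            codes = dna.BASE_CODES[np.frombuffer(joined, dtype=np.uint8)]
            win, valid = dna.kmer_codes(codes, k)
            if not len(win):
                continue
            index.add_counts(dna.canonical_codes(win[valid], k))
    return index


# ---------------------------------------------------------------------------
# per-marker count table


@dataclass
class CountTable:
    """Per-marker, per-pair (ref_count, alt_count) in database order."""

    ids: list[str]
    npairs: np.ndarray  # (n,) int
    counts: np.ndarray  # (n, 3, 2) int64; rows padded with zeros

    def __post_init__(self):
        self.npairs = np.asarray(self.npairs, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.ids), 3, 2):
            raise ValueError(
                f"counts must have shape (n, 3, 2), got {self.counts.shape}")

    def __len__(self) -> int:
        return len(self.ids)

    def pair_counts(self, i: int) -> tuple[tuple[int, int], ...]:
        n = int(self.npairs[i])
        return tuple((int(r), int(a)) for r, a in self.counts[i, :n])

    def subset(self, mask: np.ndarray) -> "CountTable":
        mask = np.asarray(mask)
        ids = [vid for vid, keep in zip(self.ids, mask) if keep]
        return CountTable(ids, self.npairs[mask], self.counts[mask])


def extract_counts(index: KmerIndex,
                   markers: Sequence[MarkerRecord]) -> CountTable:
    """Read the counters of every marker's pairs out of the index."""
    n = len(markers)
    counts = np.zeros((n, 3, 2), dtype=np.int64)
    npairs = np.zeros(n, dtype=np.int64)
    for i, m in enumerate(markers):
        npairs[i] = len(m.pairs)
        for j, p in enumerate(m.pairs):
            r = index.lookup(p.ref_kmer)
            a = index.lookup(p.alt_kmer)
            if r is None or a is None:
                raise ValueError(
                    f"marker {m.variant.id}: k-mer missing from index "
                    "(index was built from different markers)")
            counts[i, j] = (r, a)
    return CountTable([m.variant.id for m in markers], npairs, counts)


def write_counts(table: CountTable, path) -> None:
    """Write a count table (TSV, marker order preserved, LF endings)."""
    with open(path, "w", newline="\n") as fh:
        fh.write(COUNTS_MAGIC + "\n")
        for i, vid in enumerate(table.ids):
            n = int(table.npairs[i])
            fields = [vid, str(n)]
            for j in range(n):
                fields += [str(int(table.counts[i, j, 0])),
                           str(int(table.counts[i, j, 1]))]
            fh.write("\t".join(fields) + "\n")


def read_counts(path, markers: Sequence[MarkerRecord] | None = None
                ) -> CountTable:
    """Read a count table; verify marker ids/order when markers are given."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    npairs: list[int] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(COUNTS_MAGIC):
            raise ValueError(f"{path}: not a kmergt count table "
                             f"(bad header {header!r})")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                vid = fields[0]
                n = int(fields[1])
                if not 1 <= n <= 3 or len(fields) != 2 + 2 * n:
                    raise ValueError("bad pair count")
                row = np.zeros((3, 2), dtype=np.int64)
                for j in range(n):
                    row[j, 0] = int(fields[2 + 2 * j])
                    row[j, 1] = int(fields[3 + 2 * j])
                if (row < 0).any():
                    raise ValueError("negative count")
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed count line ({exc})") from exc
            ids.append(vid)
            npairs.append(n)
            rows.append(row)
    table = CountTable(ids, np.array(npairs, dtype=np.int64),
                       np.stack(rows) if rows
                       else np.zeros((0, 3, 2), dtype=np.int64))
    if markers is not None:
        if len(markers) != len(table) or any(
                m.variant.id != vid for m, vid in zip(markers, table.ids)):
            raise ValueError(
                f"{path}: marker ids do not match the database")
    return table
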