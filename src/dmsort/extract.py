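"""Anchored barcode extraction and per-bin counting.

The barcode sits between two constant anchor sequences in every amplicon
read, so extraction is anchored matching under a Hamming (substitution-only)
tolerance: scan for the leftmost position where the 5' anchor fits with at
most ``max_anchor_mismatches`` mismatches, take the next 15 bases as the
candidate barcode, and require the 3' anchor immediately after within the
same tolerance.  Candidates are then assigned to manifest barcodes within
``max_barcode_mismatches``; assignment is provably unambiguous because the
manifest's minimum pairwise barcode distance must exceed twice that
tolerance (disjoint Hamming balls).

Base qualities are ignored throughout: the fixed-length, constant-flank
design plus the manifest distance guarantee already bound misassignment.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import library as lib
from ._seq import encode, mismatches_upto
from .simulate import ReadLayout

REJECT_NO_ANCHOR5 = "no-anchor5"
REJECT_NO_ANCHOR3 = "no-anchor3"
REJECT_SHORT_READ = "short-read"
UNASSIGNED = "unassigned-barcode"


class ExtractionError(ValueError):
    """Invalid extraction configuration or unreadable input."""


@dataclass(frozen=True)
class ExtractionConfig:
    layout: ReadLayout = field(default_factory=ReadLayout)
    max_anchor_mismatches: int = 1
    max_barcode_mismatches: int = 1
    min_read_length: int | None = None  # defaults to the full cassette length

    def __post_init__(self) -> None:
        if self.max_anchor_mismatches < 0 or self.max_barcode_mismatches < 0:
            raise ExtractionError("mismatch allowances must be nonnegative")
        if self.min_read_length is None:
            object.__setattr__(self, "min_read_length", self.layout.read_len)


class ExtractionResult(NamedTuple):
    barcode: str | None
    reject_reason: str | None


def extract_barcode(read_seq: str, cfg: ExtractionConfig) -> ExtractionResult:
    """Locate the barcode in one read, or reject with a reason code.

    The 5' anchor is searched at every offset where the full cassette still
    fits; the leftmost offset at which both anchors match wins (deterministic
    tie-break, robust to spurious near-anchor sequence upstream).  Returns
    ``(barcode, None)`` on success, ``(None, reason)`` otherwise with reason
    one of ``short-read``, ``no-anchor5``, ``no-anchor3``.
    """
    layout = cfg.layout
    seq = read_seq.upper()
    if len(seq) < cfg.min_read_length or len(seq) < layout.read_len:
        return ExtractionResult(None, REJECT_SHORT_READ)
    a5, a3 = layout.anchor5, layout.anchor3
    la5 = len(a5)
    tol = cfg.max_anchor_mismatches
    last_offset = len(seq) - layout.read_len
    saw_anchor5 = False
    for i in range(last_offset + 1):
        if mismatches_upto(seq[i : i + la5], a5, tol) <= tol:
            saw_anchor5 = True
            bc_start = i + la5
            bc_end = bc_start + layout.barcode_len
            if mismatches_upto(seq[bc_end : bc_end + len(a3)], a3, tol) <= tol:
                return ExtractionResult(seq[bc_start:bc_end], None)
    return ExtractionResult(None, REJECT_NO_ANCHOR3 if saw_anchor5 else REJECT_NO_ANCHOR5)


class BarcodeIndex:
    """Mismatch-tolerant lookup from candidate barcodes to manifest clones.

    Exact matches and (for tolerance >= 1) all single-mismatch neighbours are
    resolved by dictionary; larger tolerances fall back to a vectorised
    Hamming scan.  Construction verifies that twice the tolerance is below
    the manifest's minimum pairwise barcode distance, so every candidate has
    at most one manifest barcode in range.
    """

    def __init__(self, manifest: lib.LibraryManifest, max_mismatches: int = 1):
        self.manifest = manifest
        self.max_mismatches = max_mismatches
        self._barcodes = list(manifest.barcodes)
        self._codes = (
            np.stack([encode(b) for b in self._barcodes])
            if self._barcodes
            else np.empty((0, lib.BARCODE_LEN), dtype=np.uint8)
        )
        if max_mismatches > 0 and len(self._barcodes) > 1:
            min_dist = self._min_pairwise_distance()
            if 2 * max_mismatches >= min_dist:
                raise ExtractionError(
                    f"max_barcode_mismatches={max_mismatches} is ambiguous for a "
                    f"manifest with minimum pairwise barcode distance {min_dist}; "
                    f"require 2*max_barcode_mismatches < min distance"
                )
        self._exact = {b: i for i, b in enumerate(self._barcodes)}
        self._one_off: dict[str, int] = {}
        if max_mismatches >= 1:
            for i, b in enumerate(self._barcodes):
                for pos in range(len(b)):
                    for base in "ACGT":
                        if base != b[pos]:
                            self._one_off[b[:pos] + base + b[pos + 1 :]] = i

    def _min_pairwise_distance(self, chunk: int = 512) -> int:
        codes = self._codes
        best = codes.shape[1]
        for start in range(0, len(codes), chunk):
            block = codes[start : start + chunk]
            d = (block[:, None, :] != codes[None, :, :]).sum(axis=2)
            iu = np.arange(start, start + len(block))
            d[np.arange(len(block)), iu] = codes.shape[1]  # mask self-distance
            best = min(best, int(d.min()))
        return best

    def lookup(self, candidate: str) -> int | None:
        """Manifest index of the unique barcode within tolerance, else None."""
        idx = self._exact.get(candidate)
        if idx is not None:
            return idx
        if self.max_mismatches >= 1:
            idx = self._one_off.get(candidate)
            if idx is not None:
                return idx
        if self.max_mismatches >= 2 and len(self._codes):
            d = (self._codes != encode(candidate)).sum(axis=1)
            j = int(d.argmin())
            if d[j] <= self.max_mismatches:
                return j
        return None


def assign_barcode(
    candidate: str,
    index: BarcodeIndex | lib.LibraryManifest,
    cfg: ExtractionConfig | None = None,
) -> lib.BarcodeClone | None:
    """Assign a 15-nt candidate to its manifest clone, or None if unassigned."""
    if len(candidate) != lib.BARCODE_LEN:
        raise ExtractionError(f"candidate barcode must have length {lib.BARCODE_LEN}")
    if isinstance(index, lib.LibraryManifest):
        tol = cfg.max_barcode_mismatches if cfg is not None else 1
        index = BarcodeIndex(index, tol)
    i = index.lookup(candidate)
    return None if i is None else index.manifest.clones[i]


@dataclass
class BinCounts:
    """Per-barcode read counts for one sorted bin, plus conservation totals."""

    counts: dict[str, int]
    reads_seen: int
    reads_assigned: int
    reads_unassigned: int
    reject_reasons: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.reads_assigned + self.reads_unassigned != self.reads_seen:
            raise ExtractionError("read conservation violated: assigned + unassigned != seen")
        if sum(self.counts.values()) != self.reads_assigned:
            raise ExtractionError("assigned counts do not sum to reads_assigned")

    def summary(self) -> dict:
        return {
            "reads_seen": self.reads_seen,
            "reads_assigned": self.reads_assigned,
            "reads_unassigned": self.reads_unassigned,
            "reject_reasons": dict(self.reject_reasons),
        }


def count_bin(
    fastq_path,
    manifest: lib.LibraryManifest,
    cfg: ExtractionConfig | None = None,
    index: BarcodeIndex | None = None,
) -> BinCounts:
    """Count manifest barcodes in one bin's FASTQ.

    Extraction and assignment are memoised per unique read sequence, which
    makes counting effectively linear in the number of distinct error
    patterns rather than reads.  Gzip input is handled by extension.
    """
    cfg = cfg or ExtractionConfig()
    index = index or BarcodeIndex(manifest, cfg.max_barcode_mismatches)
    barcodes = manifest.barcodes
    counts = {b: 0 for b in barcodes}
    reasons: Counter = Counter()
    cache: dict[str, tuple[str | None, str | None]] = {}
    seen = assigned = 0
    path = str(fastq_path)
    if path.endswith(".gz"):
        import gzip

        handle = gzip.open(path, "rt")
    else:
        handle = open(path)
    with handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                item = next(iterator, None)
            except ValueError as exc:
                raise ExtractionError(
                    f"{path}: malformed FASTQ near record {seen + 1}: {exc}"
                ) from exc
            if item is None:
                break
            _title, seq, _qual = item
            seen += 1
            hit = cache.get(seq)
            if hit is None:
                barcode, reason = extract_barcode(seq, cfg)
                if barcode is None:
                    hit = (None, reason)
                else:
                    i = index.lookup(barcode)
                    hit = (None, UNASSIGNED) if i is None else (barcodes[i], None)
                cache[seq] = hit
            target, reason = hit
            if target is None:
                reasons[reason] += 1
            else:
                counts[target] += 1
                assigned += 1
    return BinCounts(
        counts=counts,
        reads_seen=seen,
        reads_assigned=assigned,
        reads_unassigned=seen - assigned,
        reject_reasons=reasons,
    )


def merge_bins(
    low: BinCounts, high: BinCounts, manifest: lib.LibraryManifest
) -> pd.DataFrame:
    """Merge two bins into the counts table keyed by manifest barcode."""
    return pd.DataFrame(
        {
            "barcode": [c.barcode for c in manifest.clones],
            "clone_id": [c.clone_id for c in manifest.clones],
            "count_low": [low.counts.get(c.barcode, 0) for c in manifest.clones],
            "count_high": [high.counts.get(c.barcode, 0) for c in manifest.clones],
        }
    )


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "clone_id": str})
    required = {"barcode", "count_low", "count_high"}
    missing = required - set(df.columns)
    if missing:
        raise ExtractionError(f"{path}: missing counts columns {sorted(missing)}")
    return df


def write_summary(low: BinCounts, high: BinCounts, path) -> None:
    with open(path, "w") as fh:
        json.dump({"low": low.summary(), "high": high.summary()}, fh, indent=2)
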