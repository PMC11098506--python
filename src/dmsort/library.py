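"""Barcoded saturation-mutagenesis library model.

The screen couples every clone of a variant library to a unique 15-nt
barcode in the 3' UTR.  The scanned window covers sixteen residues of the
human VDAC2 beta10-11 loop (positions 165-180, human numbering).  Clones
fall into exactly one of three classes:

* ``wt_syn``   — wild-type or synonymous coding sequence (the test's null),
* ``missense`` — a single amino-acid substitution at one window position,
* ``stop``     — a premature stop codon at one window position.

This module builds manifests matching a :class:`LibraryDesign`, validates
their composition, and round-trips them through a plain TSV format.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._seq import ALPHABET, decode

#: The twenty proteinogenic amino acids, alphabetical one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Marker used in ``sub_aa`` for premature stop codons.
STOP = "*"
#: Marker used in ``sub_aa`` for wild-type/synonymous clones.
WT = "WT"

CLASS_WT_SYN = "wt_syn"
CLASS_MISSENSE = "missense"
CLASS_STOP = "stop"
CLASSES = (CLASS_WT_SYN, CLASS_MISSENSE, CLASS_STOP)

#: First and last scanned residue (human VDAC2 numbering).
WINDOW_START = 165
WINDOW_END = 180
WINDOW_LEN = WINDOW_END - WINDOW_START + 1

#: Wild-type amino acids of the scanned human VDAC2 window Q165..F180.
#: Overridable wherever a ``reference_segment`` argument is accepted.
DEFAULT_REFERENCE_SEGMENT = "QMTFDTAKSKLSQNNF"

BARCODE_LEN = 15


class LibraryError(ValueError):
    """Invalid library design, manifest, or manifest file."""


class BarcodeCapacityError(LibraryError):
    """The requested number of barcodes cannot satisfy the Hamming constraint."""


@dataclass(frozen=True, order=True)
class Variant:
    """A single library variant in human VDAC2 numbering.

    ``sub_aa`` is a one-letter amino acid for missense variants, ``"*"`` for a
    premature stop, or ``"WT"`` for wild-type/synonymous coding sequence.
    """

    position: int
    wt_aa: str
    sub_aa: str

    def __post_init__(self) -> None:
        if not (WINDOW_START <= self.position <= WINDOW_END):
            raise LibraryError(
                f"position {self.position} outside scanned window "
                f"[{WINDOW_START}, {WINDOW_END}]"
            )
        if self.wt_aa not in AA20:
            raise LibraryError(f"invalid wild-type amino acid {self.wt_aa!r}")
        if self.sub_aa not in (STOP, WT) and self.sub_aa not in AA20:
            raise LibraryError(f"invalid substitution {self.sub_aa!r}")
        if self.sub_aa == self.wt_aa:
            raise LibraryError(
                f"missense variant at position {self.position} must differ from "
                f"wild type {self.wt_aa!r}; use sub_aa={WT!r} for wild-type clones"
            )

    @property
    def clazz(self) -> str:
        if self.sub_aa == WT:
            return CLASS_WT_SYN
        if self.sub_aa == STOP:
            return CLASS_STOP
        return CLASS_MISSENSE

    @property
    def label(self) -> str:
        """Human-readable label, e.g. ``A171L``, ``A171*`` or ``WT``."""
        if self.sub_aa == WT:
            return WT
        return f"{self.wt_aa}{self.position}{self.sub_aa}"

    def key(self) -> tuple[int, str]:
        """Grouping key: WT clones pool into one group regardless of position."""
        if self.sub_aa == WT:
            return (0, WT)
        return (self.position, self.sub_aa)


@dataclass(frozen=True)
class BarcodeClone:
    """One sequence-verified clone: a barcode tied to a coding variant."""

    barcode: str
    variant: Variant
    clone_id: str

    def __post_init__(self) -> None:
        if len(self.barcode) != BARCODE_LEN:
            raise LibraryError(
                f"barcode {self.barcode!r} has length {len(self.barcode)}, "
                f"expected {BARCODE_LEN}"
            )
        if any(b not in ALPHABET for b in self.barcode):
            raise LibraryError(f"barcode {self.barcode!r} contains non-ACGT bases")


@dataclass(frozen=True)
class LibraryManifest:
    """Ordered collection of barcoded clones plus the scanned reference window."""

    clones: tuple[BarcodeClone, ...]
    reference_segment: str = DEFAULT_REFERENCE_SEGMENT

    def __post_init__(self) -> None:
        _check_reference(self.reference_segment)
        seen: dict[str, str] = {}
        dups = []
        for c in self.clones:
            if c.barcode in seen:
                dups.append(c.barcode)
            seen[c.barcode] = c.clone_id
            wt = self.reference_segment[c.variant.position - WINDOW_START]
            if c.variant.wt_aa != wt:
                raise LibraryError(
                    f"clone {c.clone_id}: wt_aa {c.variant.wt_aa!r} at position "
                    f"{c.variant.position} does not match reference {wt!r}"
                )
        if dups:
            raise LibraryError(f"duplicate barcodes in manifest: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def barcodes(self) -> tuple[str, ...]:
        return tuple(c.barcode for c in self.clones)

    def by_class(self, clazz: str) -> tuple[BarcodeClone, ...]:
        return tuple(c for c in self.clones if c.variant.clazz == clazz)


@dataclass(frozen=True)
class LibraryDesign:
    """Per-class clone counts and the barcode-allocation rule.

    Defaults reproduce the screen's stated composition: 4,920 clones in total,
    289 wild-type/synonymous, 247 premature stops, and 4,384 missense clones
    allocated over all 16 x 19 = 304 single substitutions with a median of 11
    unique barcodes per substitution.
    """

    n_wt_syn: int = 289
    n_stop: int = 247
    n_missense_clones: int = 4384
    median_barcodes_per_missense: int = 11
    barcode_spread: float = 0.0
    barcodes_per_missense: Mapping[tuple[int, str], int] | None = None
    min_barcode_hamming: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_wt_syn", "n_stop", "n_missense_clones"):
            if getattr(self, name) < 0:
                raise LibraryError(f"{name} must be nonnegative")
        if self.min_barcode_hamming < 1:
            raise LibraryError("min_barcode_hamming must be >= 1")
        if self.barcode_spread < 0:
            raise LibraryError("barcode_spread must be nonnegative")
        if self.barcodes_per_missense is not None:
            if any(n < 1 for n in self.barcodes_per_missense.values()):
                raise LibraryError("explicit barcode allocation must be >= 1 per substitution")


@dataclass(frozen=True)
class CompositionReport:
    """Tallied manifest composition (direct counts, no modelling)."""

    n_clones: int
    n_wt_syn: int
    n_stop: int
    n_missense_clones: int
    n_distinct_missense: int
    median_barcodes_per_missense: float

    def __post_init__(self) -> None:
        if self.n_clones != self.n_wt_syn + self.n_stop + self.n_missense_clones:
            raise LibraryError("class counts do not sum to n_clones")


def random_barcodes(
    n: int,
    length: int = BARCODE_LEN,
    min_hamming: int = 1,
    rng: np.random.Generator | None = None,
    max_rejections: int = 5000,
) -> list[str]:
    """Draw ``n`` distinct random barcodes with pairwise Hamming >= ``min_hamming``.

    Rejection sampling over the uniform {A,C,G,T}^length space; with 15-mers and
    the default distance 3 the acceptance rate is essentially 1.  Raises
    :class:`BarcodeCapacityError` after ``max_rejections`` consecutive failures,
    which is how an infeasible request (e.g. more codewords than the space
    admits) surfaces.
    """
    rng = np.random.default_rng(rng)
    codes = np.empty((n, length), dtype=np.uint8)
    k = 0
    rejections = 0
    while k < n:
        cand = rng.integers(0, 4, size=length, dtype=np.uint8)
        if k > 0:
            dmin = int((codes[:k] != cand).sum(axis=1).min())
            if dmin < min_hamming:
                rejections += 1
                if rejections >= max_rejections:
                    raise BarcodeCapacityError(
                        f"could not place barcode {k + 1}/{n} at length {length} with "
                        f"min pairwise Hamming distance {min_hamming} after "
                        f"{max_rejections} rejections"
                    )
                continue
        codes[k] = cand
        k += 1
        rejections = 0
    return [decode(c) for c in codes]


def _check_reference(reference_segment: str) -> None:
    if len(reference_segment) != WINDOW_LEN:
        raise LibraryError(
            f"reference segment must have length {WINDOW_LEN} "
            f"(positions {WINDOW_START}-{WINDOW_END}), got {len(reference_segment)}"
        )
    bad = [a for a in reference_segment if a not in AA20]
    if bad:
        raise LibraryError(f"reference segment contains invalid residues {bad}")


def allocate_missense(
    n_substitutions: int,
    total: int,
    target_median: int,
    spread: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-substitution barcode counts with an exact median and an exact total.

    Counts start from ``target_median`` (plus optional rounded-normal spread,
    with the middle order statistics pinned to the median), then the surplus or
    deficit against ``total`` is distributed over the strict upper (resp. lower)
    half of the sorted counts so the median is untouched.
    """
    if n_substitutions <= 0:
        raise LibraryError("need at least one substitution to allocate")
    if total < n_substitutions:
        raise LibraryError(
            f"cannot place {total} missense clones over {n_substitutions} "
            "substitutions with >= 1 barcode each"
        )
    mid = (n_substitutions - 1) // 2
    n_medians = 2 if n_substitutions % 2 == 0 else 1  # order statistics pinned
    if total < mid + (n_substitutions - mid) * target_median:
        # target median unattainable at this total: split as evenly as possible
        counts = np.full(n_substitutions, total // n_substitutions, dtype=int)
        counts[: total % n_substitutions] += 1
        rng.shuffle(counts)
        return counts
    if spread > 0:
        counts = np.rint(rng.normal(target_median, spread, n_substitutions)).astype(int)
        counts = np.maximum(counts, 1)
        counts.sort()
        # pin the middle order statistic(s) so the median is exact
        counts[: mid + n_medians] = np.minimum(counts[: mid + n_medians], target_median)
        counts[mid:] = np.maximum(counts[mid:], target_median)
    else:
        counts = np.full(n_substitutions, target_median, dtype=int)
    diff = total - int(counts.sum())
    upper = np.arange(mid + n_medians, n_substitutions)
    lower = np.arange(0, mid)
    i = 0
    while diff > 0:
        if len(upper) == 0:
            raise LibraryError("cannot reach the requested total at this median")
        counts[upper[i % len(upper)]] += 1
        diff -= 1
        i += 1
    i = 0
    guard = 0
    while diff < 0:
        if len(lower) == 0 or guard > 10 * total:
            raise LibraryError("cannot reach the requested total at this median")
        j = lower[i % len(lower)]
        if counts[j] > 1:
            counts[j] -= 1
            diff += 1
        i += 1
        guard += 1
    rng.shuffle(counts)
    return counts


def build_manifest(
    design: LibraryDesign,
    reference_segment: str = DEFAULT_REFERENCE_SEGMENT,
) -> LibraryManifest:
    """Construct a manifest matching ``design`` over the scanned window.

    Reproducible: the same ``design`` (including ``rng_seed``) yields an
    identical manifest.  Barcodes are uniform random 15-mers with pairwise
    Hamming distance >= ``design.min_barcode_hamming``.
    """
    _check_reference(reference_segment)
    rng = np.random.default_rng(design.rng_seed)
    positions = list(range(WINDOW_START, WINDOW_END + 1))

    substitutions: list[tuple[int, str]] = [
        (pos, aa)
        for pos in positions
        for aa in AA20
        if aa != reference_segment[pos - WINDOW_START]
    ]

    variants: list[Variant] = []
    # wild-type/synonymous clones, positions cycled for bookkeeping only
    for i in range(design.n_wt_syn):
        pos = positions[i % len(positions)]
        variants.append(Variant(pos, reference_segment[pos - WINDOW_START], WT))
    # premature stops spread as evenly as possible over the window
    for i in range(design.n_stop):
        pos = positions[i % len(positions)]
        variants.append(Variant(pos, reference_segment[pos - WINDOW_START], STOP))
    # missense allocation
    if design.barcodes_per_missense is not None:
        alloc = dict(design.barcodes_per_missense)
        unknown = set(alloc) - set(substitutions)
        if unknown:
            raise LibraryError(f"allocation names unknown substitutions: {sorted(unknown)}")
    elif design.n_missense_clones > 0:
        # allocate over as many substitutions as the total supports at the
        # target median, chosen round-robin across positions so the scanned
        # window stays covered whenever the total allows it
        n_used = min(
            len(substitutions),
            max(1, design.n_missense_clones // max(design.median_barcodes_per_missense, 1)),
        )
        by_pos: dict[int, list[tuple[int, str]]] = {}
        for sub in substitutions:
            by_pos.setdefault(sub[0], []).append(sub)
        by_round = [
            by_pos[pos][k]
            for k in range(max(len(v) for v in by_pos.values()))
            for pos in positions
            if k < len(by_pos[pos])
        ]
        used = sorted(by_round[:n_used])
        counts = allocate_missense(
            len(used),
            design.n_missense_clones,
            design.median_barcodes_per_missense,
            design.barcode_spread,
            rng,
        )
        alloc = dict(zip(used, (int(c) for c in counts)))
    else:
        alloc = {}
    for (pos, aa), n in sorted(alloc.items()):
        wt = reference_segment[pos - WINDOW_START]
        variants.extend(Variant(pos, wt, aa) for _ in range(n))

    barcodes = random_barcodes(
        len(variants), BARCODE_LEN, design.min_barcode_hamming, rng
    )
    clones = tuple(
        BarcodeClone(barcode=bc, variant=v, clone_id=f"clone{i:05d}")
        for i, (bc, v) in enumerate(zip(barcodes, variants), start=1)
    )
    return LibraryManifest(clones=clones, reference_segment=reference_segment)


def validate_manifest(manifest: LibraryManifest) -> CompositionReport:
    """Tally manifest composition.

    The median barcodes-per-missense-substitution uses the midpoint of the two
    middle values for an even number of substitutions.  An empty manifest
    reports all-zero counts.
    """
    n_wt_syn = n_stop = 0
    per_sub: dict[tuple[int, str], set[str]] = {}
    for c in manifest.clones:
        clazz = c.variant.clazz
        if clazz == CLASS_WT_SYN:
            n_wt_syn += 1
        elif clazz == CLASS_STOP:
            n_stop += 1
        else:
            per_sub.setdefault(c.variant.key(), set()).add(c.barcode)
    n_missense = sum(len(s) for s in per_sub.values())
    median = float(np.median([len(s) for s in per_sub.values()])) if per_sub else 0.0
    return CompositionReport(
        n_clones=len(manifest),
        n_wt_syn=n_wt_syn,
        n_stop=n_stop,
        n_missense_clones=n_missense,
        n_distinct_missense=len(per_sub),
        median_barcodes_per_missense=median,
    )


def coverage_fold(n_infected_cells: int, manifest: LibraryManifest) -> float:
    """Library coverage: infected cells per clone."""
    if n_infected_cells <= 0:
        raise LibraryError("n_infected_cells must be positive")
    if len(manifest) == 0:
        raise LibraryError("cannot compute coverage of an empty manifest")
    return n_infected_cells / len(manifest)


_MANIFEST_COLUMNS = ["barcode", "position", "wt_aa", "sub_aa", "class"]


def write_manifest(manifest: LibraryManifest, path) -> None:
    df = pd.DataFrame(
        {
            "barcode": [c.barcode for c in manifest.clones],
            "position": [c.variant.position for c in manifest.clones],
            "wt_aa": [c.variant.wt_aa for c in manifest.clones],
            "sub_aa": [c.variant.sub_aa for c in manifest.clones],
            "class": [c.variant.clazz for c in manifest.clones],
            "clone_id": [c.clone_id for c in manifest.clones],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path, reference_segment: str = DEFAULT_REFERENCE_SEGMENT) -> LibraryManifest:
    """Read a manifest TSV, reporting the 1-based file line of any bad row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryError(f"{path}: missing manifest columns {missing}")
    df = df.rename(columns={"class": "clazz"})
    clones = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            position = int(row.position)
        except ValueError:
            raise LibraryError(f"{path}:{line}: non-integer position {row.position!r}") from None
        if row.clazz not in CLASSES:
            raise LibraryError(f"{path}:{line}: unknown class label {row.clazz!r}")
        try:
            variant = Variant(position, row.wt_aa, row.sub_aa)
            clone_id = getattr(row, "clone_id", None)
            if not isinstance(clone_id, str):
                clone_id = f"clone{i + 1:05d}"
            clone = BarcodeClone(row.barcode, variant, clone_id)
        except LibraryError as exc:
            raise LibraryError(f"{path}:{line}: {exc}") from None
        if variant.clazz != row.clazz:
            raise LibraryError(
                f"{path}:{line}: class label {row.clazz!r} inconsistent "
                f"with variant {variant.label}"
            )
        clones.append(clone)
    try:
        return LibraryManifest(tuple(clones), reference_segment)
    except LibraryError as exc:
        raise LibraryError(f"{path}: {exc}") from None
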