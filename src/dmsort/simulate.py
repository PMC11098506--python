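"""Generative model for a two-bin sort-seq screen.

The chain mirrors how the real experiment produces data:

1. **Infection / expansion** — clone abundances are drawn once from a
   symmetric Dirichlet (pooled libraries are never perfectly uniform), and
   each of ``n_cells`` cells carries exactly one clone (single integration,
   the low-MOI regime).
2. **Phenotype** — a cell's log-fluorescence is Normal(baseline + variant
   effect, ``cell_sigma``); effects come from an :class:`EffectTable` in the
   same log units.
3. **Sorting** — the bottom and top ``gate_fraction`` of the fluorescence
   distribution become the low and high bins.
4. **Sequencing** — within a bin, each barcode's expected read share is its
   cell count times a log-normal PCR jitter; ``reads_per_bin`` reads are
   drawn multinomially and emitted as anchored amplicon reads with i.i.d.
   per-base substitution errors.

Every stage is reproducible from one seed, and the intermediate truth
(cells and reads per clone per bin) is kept alongside the FASTQ output.
"""

from __future__ import annotations

import dataclasses
import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from . import library as lib
from ._seq import ALPHABET, decode, encode, reverse_complement

# Annealing segments of the screen's two-step PCR, read orientation:
# the 5' anchor is the forward annealing sequence, the 3' anchor the
# reverse complement of the reverse annealing sequence.
DEFAULT_ANCHOR5 = "CTGGAGGCCACAAGGTTG"
DEFAULT_ANCHOR3 = reverse_complement("GGTGGATGTGGAATGTGTG")  # CACACATTCCACATCCACC

QUALITY_CHAR = "I"


class SimulationError(ValueError):
    """Invalid simulation configuration or inputs."""


class EffectCoverageError(SimulationError):
    """The effect table does not cover every manifest variant."""


@dataclass(frozen=True)
class ReadLayout:
    """Amplicon architecture: constant flanks around the 15-nt barcode."""

    anchor5: str = DEFAULT_ANCHOR5
    anchor3: str = DEFAULT_ANCHOR3
    barcode_len: int = lib.BARCODE_LEN

    def __post_init__(self) -> None:
        if not self.anchor5 or not self.anchor3:
            raise SimulationError("anchors must be non-empty")
        if self.anchor5 == self.anchor3:
            raise SimulationError("anchors must be distinct")
        if self.barcode_len != lib.BARCODE_LEN:
            raise SimulationError(f"barcode_len must be {lib.BARCODE_LEN}")

    @property
    def read_len(self) -> int:
        return len(self.anchor5) + self.barcode_len + len(self.anchor3)

    def template(self, barcode: str) -> str:
        return self.anchor5 + barcode + self.anchor3


@dataclass(frozen=True)
class SimConfig:
    """Tunable screen parameters; defaults are the modelled study conditions.

    ``n_cells`` matches the stated infected-cell number (1.5e6, >300X
    coverage of 4,920 clones); ``moi_max`` records the low-MOI regime the
    single-integration assumption rests on.  Gate placement, depth and the
    noise scales are not reported for the study and carry documented
    defaults.
    """

    n_cells: int = 1_500_000
    moi_max: float = 0.3
    abundance_dispersion: float = 10.0
    cell_sigma: float = 1.0
    gate_fraction: float = 0.25
    reads_per_bin: int = 2_000_000
    pcr_log_jitter_sd: float = 0.3
    seq_error_rate: float = 0.001
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise SimulationError("n_cells must be nonnegative")
        if not (0 < self.moi_max <= 1):
            raise SimulationError("moi_max must be in (0, 1]")
        if self.abundance_dispersion < 0:
            raise SimulationError("abundance_dispersion must be nonnegative")
        if self.cell_sigma < 0 or self.pcr_log_jitter_sd < 0:
            raise SimulationError("noise scales must be nonnegative")
        if not (0 < self.gate_fraction <= 0.5):
            raise SimulationError("gate_fraction must be in (0, 0.5]")
        if not (0 <= self.seq_error_rate <= 1):
            raise SimulationError("seq_error_rate must be in [0, 1]")
        if self.reads_per_bin < 0:
            raise SimulationError("reads_per_bin must be nonnegative")


class EffectTable:
    """Mapping from variant group (position, sub_aa) to a phenotype shift.

    Effects are shifts of the mean cell log-fluorescence, in units of the
    (natural-log-scale) fluorescence model; wild-type/synonymous entries are
    0 by construction.
    """

    def __init__(self, effects: Mapping[tuple[int, str], float] | None = None):
        self._effects: dict[tuple[int, str], float] = {(0, lib.WT): 0.0}
        for key, value in (effects or {}).items():
            if key[1] == lib.WT:
                if value != 0.0:
                    raise SimulationError("wild-type effects are 0 by construction")
                continue
            self._effects[key] = float(value)

    @classmethod
    def null(cls, manifest: lib.LibraryManifest) -> "EffectTable":
        """All-zero effect table covering every manifest variant."""
        return cls({c.variant.key(): 0.0 for c in manifest.clones})

    def with_effects(self, effects: Mapping[str, float]) -> "EffectTable":
        """Copy with effects set by variant label, e.g. ``{"A171L": 2.0}``."""
        out = EffectTable()
        out._effects = dict(self._effects)
        for label, value in effects.items():
            pos, sub = int(label[1:-1]), label[-1]
            out._effects[(pos, sub)] = float(value)
        return out

    def effect(self, variant: lib.Variant) -> float:
        key = variant.key()
        try:
            return self._effects[key]
        except KeyError:
            raise EffectCoverageError(
                f"no effect entry for variant {variant.label}"
            ) from None

    def items(self):
        return self._effects.items()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"position": pos, "sub_aa": sub, "effect": eff}
            for (pos, sub), eff in sorted(self._effects.items())
        ]
        return pd.DataFrame(rows, columns=["position", "sub_aa", "effect"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "EffectTable":
        df = pd.read_csv(path, sep="\t", dtype={"position": int, "sub_aa": str, "effect": float})
        table = cls()
        for row in df.itertuples(index=False):
            if row.sub_aa == lib.WT:
                continue
            table._effects[(int(row.position), row.sub_aa)] = float(row.effect)
        return table


@dataclass
class Population:
    """Per-cell records: clone index into the manifest plus log-fluorescence."""

    clone_index: np.ndarray
    log_fluorescence: np.ndarray

    def __len__(self) -> int:
        return len(self.clone_index)


@dataclass
class GroundTruth:
    """Simulation truth: per-clone cells and reads in each bin, plus effects."""

    manifest: lib.LibraryManifest
    cells_low: np.ndarray
    cells_high: np.ndarray
    reads_low: np.ndarray
    reads_high: np.ndarray
    expected_frac_low: np.ndarray
    expected_frac_high: np.ndarray
    effects: EffectTable

    def to_frame(self) -> pd.DataFrame:
        clones = self.manifest.clones
        return pd.DataFrame(
            {
                "barcode": [c.barcode for c in clones],
                "clone_id": [c.clone_id for c in clones],
                "position": [c.variant.position for c in clones],
                "wt_aa": [c.variant.wt_aa for c in clones],
                "sub_aa": [c.variant.sub_aa for c in clones],
                "class": [c.variant.clazz for c in clones],
                "effect": [self.effects.effect(c.variant) for c in clones],
                "cells_low": self.cells_low,
                "cells_high": self.cells_high,
                "expected_frac_low": self.expected_frac_low,
                "expected_frac_high": self.expected_frac_high,
                "reads_low": self.reads_low,
                "reads_high": self.reads_high,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _clone_effects(manifest: lib.LibraryManifest, effects: EffectTable) -> np.ndarray:
    return np.array([effects.effect(c.variant) for c in manifest.clones], dtype=float)


def simulate_population(
    manifest: lib.LibraryManifest,
    effects: EffectTable,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> Population:
    """Draw the infected, expanded cell population.

    Clone abundances come from one symmetric Dirichlet draw with
    concentration ``abundance_dispersion`` (uniform abundances if 0); each
    cell's log-fluorescence is Normal(effect of its clone, ``cell_sigma``).
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    k = len(manifest)
    if k == 0:
        raise SimulationError("manifest is empty")
    per_clone_effect = _clone_effects(manifest, effects)
    if cfg.abundance_dispersion > 0:
        abundance = rng.dirichlet(np.full(k, cfg.abundance_dispersion))
    else:
        abundance = np.full(k, 1.0 / k)
    cells_per_clone = rng.multinomial(cfg.n_cells, abundance)
    clone_index = np.repeat(np.arange(k), cells_per_clone)
    noise = rng.normal(0.0, cfg.cell_sigma, cfg.n_cells) if cfg.cell_sigma > 0 else 0.0
    log_f = per_clone_effect[clone_index] + noise
    return Population(clone_index=clone_index, log_fluorescence=np.asarray(log_f))


def sort_bins(population: Population, gate_fraction: float) -> tuple[Population, Population]:
    """Split the population into (low, high) tail bins of the gate fraction.

    Each bin holds ``floor(gate_fraction * n)`` cells; ties in fluorescence
    break by stable input order, so the split is deterministic.
    """
    if not (0 < gate_fraction <= 0.5):
        raise SimulationError("gate_fraction must be in (0, 0.5]")
    n = len(population)
    n_bin = int(np.floor(gate_fraction * n))
    order = np.argsort(population.log_fluorescence, kind="stable")
    low_idx, high_idx = order[:n_bin], order[n - n_bin :]
    return (
        Population(population.clone_index[low_idx], population.log_fluorescence[low_idx]),
        Population(population.clone_index[high_idx], population.log_fluorescence[high_idx]),
    )


def _bin_cell_counts(bin_pop: Population, n_clones: int) -> np.ndarray:
    return np.bincount(bin_pop.clone_index, minlength=n_clones)


def _bin_read_counts(
    cell_counts: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial read counts per clone; returns (counts, expected fractions)."""
    weights = cell_counts.astype(float)
    if cfg.pcr_log_jitter_sd > 0:
        weights = weights * np.exp(rng.normal(0.0, cfg.pcr_log_jitter_sd, len(weights)))
    total = weights.sum()
    if total == 0:
        raise SimulationError("cannot draw reads from an empty bin")
    probs = weights / total
    return rng.multinomial(cfg.reads_per_bin, probs), probs


def _mutate_chunk(
    codes: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply i.i.d. per-base substitution errors to a (n_reads, read_len) array."""
    if error_rate <= 0:
        return codes
    mask = rng.random(codes.shape) < error_rate
    # a uniform shift in {1,2,3} mod 4 is uniform over the three other bases
    shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
    out = codes.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def _read_records(
    read_counts: np.ndarray,
    manifest: lib.LibraryManifest,
    layout: ReadLayout,
    error_rate: float,
    rng: np.random.Generator,
    name_prefix: str,
    chunk_size: int = 100_000,
) -> Iterator[tuple[str, str, str]]:
    qual = QUALITY_CHAR * layout.read_len
    serial = 0
    for clone, n_reads in zip(manifest.clones, read_counts):
        n_reads = int(n_reads)
        if n_reads == 0:
            continue
        template = encode(layout.template(clone.barcode))
        for start in range(0, n_reads, chunk_size):
            n = min(chunk_size, n_reads - start)
            chunk = np.tile(template, (n, 1))
            chunk = _mutate_chunk(chunk, error_rate, rng)
            for row in chunk:
                serial += 1
                yield f"{name_prefix}_{serial:08d}", decode(row), qual
    del serial


def simulate_reads(
    bin_pop: Population,
    manifest: lib.LibraryManifest,
    layout: ReadLayout,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    name_prefix: str = "read",
) -> tuple[np.ndarray, Iterator[tuple[str, str, str]]]:
    """Sequence one sorted bin.

    Returns the per-clone read counts (manifest order) and an iterator of
    FASTQ records ``(name, sequence, quality)``.  Read shares are cell counts
    modulated by log-normal PCR jitter; each emitted read is the anchored
    barcode template with i.i.d. substitution errors.
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    if len(bin_pop) == 0 and cfg.reads_per_bin > 0:
        raise SimulationError("cannot draw reads from an empty bin")
    cell_counts = _bin_cell_counts(bin_pop, len(manifest))
    read_counts, _ = _bin_read_counts(cell_counts, cfg, rng)
    records = _read_records(read_counts, manifest, layout, cfg.seq_error_rate, rng, name_prefix)
    return read_counts, records


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> int:
    """Write 4-line FASTQ records (gzip if the path ends in .gz); returns count."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    n = 0
    with opener(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def simulate_counts(
    manifest: lib.LibraryManifest,
    effects: EffectTable,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Run the generative chain down to per-clone read counts in both bins."""
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    population = simulate_population(manifest, effects, cfg, rng)
    low, high = sort_bins(population, cfg.gate_fraction)
    cells_low = _bin_cell_counts(low, len(manifest))
    cells_high = _bin_cell_counts(high, len(manifest))
    reads_low, frac_low = _bin_read_counts(cells_low, cfg, rng)
    reads_high, frac_high = _bin_read_counts(cells_high, cfg, rng)
    return GroundTruth(
        manifest=manifest,
        cells_low=cells_low,
        cells_high=cells_high,
        reads_low=reads_low,
        reads_high=reads_high,
        expected_frac_low=frac_low,
        expected_frac_high=frac_high,
        effects=effects,
    )


def simulate_screen(
    manifest: lib.LibraryManifest,
    effects: EffectTable,
    cfg: SimConfig,
    layout: ReadLayout | None = None,
    fastq_low="low.fastq",
    fastq_high="high.fastq",
) -> GroundTruth:
    """Full screen: population, sorting, sequencing of both bins to FASTQ.

    Byte-identical outputs for identical seeds.  The returned
    :class:`GroundTruth` carries the exact read counts behind both files.
    """
    layout = layout or ReadLayout()
    rng = np.random.default_rng(cfg.rng_seed)
    truth = simulate_counts(manifest, effects, cfg, rng)
    for counts, path, prefix in (
        (truth.reads_low, fastq_low, "low"),
        (truth.reads_high, fastq_high, "high"),
    ):
        records = _read_records(counts, manifest, layout, cfg.seq_error_rate, rng, prefix)
        write_fastq(records, path)
    return truth
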