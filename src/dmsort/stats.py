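"""Enrichment scores and variant-level Mann-Whitney statistics.

Per-barcode enrichment is the log2 difference of read counts between the
high and low bins (with a symmetric pseudocount so zero counts stay
finite).  Each coding substitution is then tested against the pooled
wild-type/synonymous barcode scores with a two-sided Mann-Whitney U test;
the result is summarised as a signed log10 p-value (positive when the
variant skews to the high bin) and the usual star categories.  The screen's
headline output is the position x substitution heatmap of signed log p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import library as lib

#: Star categories by raw two-sided p (strict upper bounds).
STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))

#: Smallest p reported on the asymptotic path, so signed log p stays finite.
P_FLOOR = 1e-300

HEATMAP_ROWS = list(lib.AA20) + ["STOP"]


class StatsError(ValueError):
    """Invalid statistical configuration or inputs."""


@dataclass(frozen=True)
class StatsConfig:
    pseudocount: float = 0.5
    min_total_reads: int = 0  # drop barcodes with count_low+count_high below this
    method: str = "auto"  # mann-whitney path: exact | approx | auto
    min_barcodes: int = 2  # below this a variant is flagged low-confidence
    p_floor: float = P_FLOOR
    include_bh: bool = True  # optional Benjamini-Hochberg column (never alters stars)

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise StatsError("pseudocount must be > 0")
        if self.method not in ("exact", "approx", "auto"):
            raise StatsError(f"unknown method {self.method!r}")
        if self.min_total_reads < 0 or self.min_barcodes < 0:
            raise StatsError("count floors must be nonnegative")
        if not (0 < self.p_floor < 1):
            raise StatsError("p_floor must be in (0, 1)")


@dataclass(frozen=True)
class VariantResult:
    variant: lib.Variant
    n_barcodes: int
    u_statistic: float
    p_two_sided: float
    direction: int
    signed_logp: float
    stars: str
    flags: str = ""


def barcode_scores(
    counts: pd.DataFrame,
    manifest: lib.LibraryManifest,
    pseudocount: float = 0.5,
    min_total_reads: int = 0,
) -> pd.DataFrame:
    """Per-barcode enrichment scores log2(high + c) - log2(low + c).

    Every manifest barcode receives a score (zero-count barcodes score 0
    through the symmetric pseudocount); barcodes with total reads below
    ``min_total_reads`` are dropped.  A counts row whose barcode is not in
    the manifest is a consistency error.
    """
    if pseudocount <= 0:
        raise StatsError("pseudocount must be > 0")
    known = set(manifest.barcodes)
    unknown = set(counts["barcode"]) - known
    if unknown:
        raise StatsError(f"counts contain barcodes absent from manifest: {sorted(unknown)[:5]}")
    by_barcode = counts.set_index("barcode")
    clones = manifest.clones
    low = np.array(
        [by_barcode["count_low"].get(c.barcode, 0) for c in clones], dtype=float
    )
    high = np.array(
        [by_barcode["count_high"].get(c.barcode, 0) for c in clones], dtype=float
    )
    df = pd.DataFrame(
        {
            "barcode": [c.barcode for c in clones],
            "clone_id": [c.clone_id for c in clones],
            "position": [c.variant.position for c in clones],
            "wt_aa": [c.variant.wt_aa for c in clones],
            "sub_aa": [c.variant.sub_aa for c in clones],
            "class": [c.variant.clazz for c in clones],
            "count_low": low.astype(int),
            "count_high": high.astype(int),
            "score": np.log2(high + pseudocount) - np.log2(low + pseudocount),
        }
    )
    if min_total_reads > 0:
        df = df[df["count_low"] + df["count_high"] >= min_total_reads].reset_index(drop=True)
    return df


def mann_whitney_two_sided(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of ``x`` versus ``y``.

    ``exact`` enumerates the permutation null (valid without ties);
    ``approx`` is the normal approximation with tie and continuity
    corrections; ``auto`` picks exact when there are no ties and the smaller
    sample has at most 10 observations.  Returns ``(U, p)`` with U the
    statistic of ``x`` and p clipped into (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise StatsError("both samples must be non-empty")
    if method == "auto":
        pooled = np.concatenate([x, y])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (not has_ties and min(len(x), len(y)) <= 10) else "approx"
    scipy_method = {"exact": "exact", "approx": "asymptotic"}[method]
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=scipy_method)
    p = float(min(res.pvalue, 1.0))
    return float(res.statistic), max(p, P_FLOOR)


def _stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def variant_test(
    variant: lib.Variant,
    variant_scores: Sequence[float],
    null_scores: Sequence[float],
    config: StatsConfig | None = None,
) -> VariantResult:
    """Test one variant's barcode scores against the wild-type null.

    The direction is the sign of the median difference (falling back to the
    mean difference on a median tie, then to 0); the signed log p is
    direction times -log10(p).
    """
    config = config or StatsConfig()
    variant_scores = np.asarray(variant_scores, dtype=float)
    null_scores = np.asarray(null_scores, dtype=float)
    if len(null_scores) == 0:
        raise StatsError("null (wild-type/synonymous) score set is empty")
    if len(variant_scores) == 0:
        raise StatsError(f"variant {variant.label} has no barcode scores")
    u, p = mann_whitney_two_sided(variant_scores, null_scores, config.method)
    p = max(p, config.p_floor)
    delta = float(np.median(variant_scores) - np.median(null_scores))
    if delta == 0:
        delta = float(np.mean(variant_scores) - np.mean(null_scores))
    direction = 0 if delta == 0 else (1 if delta > 0 else -1)
    signed_logp = 0.0 if direction == 0 else direction * -math.log10(p)
    flags = "low_n" if len(variant_scores) < config.min_barcodes else ""
    return VariantResult(
        variant=variant,
        n_barcodes=len(variant_scores),
        u_statistic=u,
        p_two_sided=p,
        direction=direction,
        signed_logp=signed_logp,
        stars=_stars(p),
        flags=flags,
    )


def run_screen(
    counts: pd.DataFrame,
    manifest: lib.LibraryManifest,
    config: StatsConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score and test every non-wild-type variant in the manifest.

    Returns ``(results, heatmap)``: one results row per distinct variant
    (missense substitutions and premature stops) tested against the pooled
    wild-type/synonymous barcode scores, and the position x substitution
    matrix of signed log10 p (NaN where a variant is absent or is the
    wild-type identity).
    """
    config = config or StatsConfig()
    scores = barcode_scores(counts, manifest, config.pseudocount, config.min_total_reads)
    null_scores = scores.loc[scores["class"] == lib.CLASS_WT_SYN, "score"].to_numpy()
    if len(scores) and len(null_scores) == 0:
        raise StatsError("no wild-type/synonymous barcodes available as the null set")

    variant_lookup = {
        c.variant.key(): c.variant
        for c in manifest.clones
        if c.variant.clazz != lib.CLASS_WT_SYN
    }
    rows = []
    non_wt = scores[scores["class"] != lib.CLASS_WT_SYN]
    for (position, sub_aa), group in non_wt.groupby(["position", "sub_aa"], sort=True):
        variant = variant_lookup[(int(position), sub_aa)]
        res = variant_test(variant, group["score"].to_numpy(), null_scores, config)
        rows.append(
            {
                "position": variant.position,
                "wt_aa": variant.wt_aa,
                "sub_aa": variant.sub_aa,
                "class": variant.clazz,
                "n_barcodes": res.n_barcodes,
                "U": res.u_statistic,
                "p": res.p_two_sided,
                "direction": res.direction,
                "signed_logp": res.signed_logp,
                "stars": res.stars,
                "flags": res.flags,
            }
        )
    columns = [
        "position", "wt_aa", "sub_aa", "class", "n_barcodes", "U", "p",
        "direction", "signed_logp", "stars", "flags",
    ]
    results = pd.DataFrame(rows, columns=columns)
    if config.include_bh and len(results):
        from statsmodels.stats.multitest import multipletests

        results["q_bh"] = multipletests(results["p"], method="fdr_bh")[1]
    return results, heatmap_matrix(results, manifest.reference_segment)


def heatmap_matrix(
    results: pd.DataFrame,
    reference_segment: str = lib.DEFAULT_REFERENCE_SEGMENT,
) -> pd.DataFrame:
    """Signed log p as rows = substitutions (A..Y then STOP), columns = positions.

    Wild-type identity cells and untested variants are NaN.
    """
    positions = list(range(lib.WINDOW_START, lib.WINDOW_END + 1))
    matrix = pd.DataFrame(np.nan, index=HEATMAP_ROWS, columns=positions)
    for row in results.itertuples(index=False):
        key = "STOP" if row.sub_aa == lib.STOP else row.sub_aa
        matrix.loc[key, row.position] = row.signed_logp
    return matrix


def write_heatmap(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="substitution", na_rep="")


def plot_heatmap(matrix: pd.DataFrame, path, vmax: float | None = None) -> None:
    """Diverging heatmap (blue = skew to low bin, red = skew to high bin)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix.to_numpy(dtype=float)
    if vmax is None:
        finite = np.abs(values[np.isfinite(values)])
        vmax = float(finite.max()) if finite.size else 1.0
    fig, ax = plt.subplots(figsize=(8, 6))
    masked = np.ma.masked_invalid(values)
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("0.85")
    im = ax.imshow(masked, cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(matrix.columns)), labels=[str(c) for c in matrix.columns])
    ax.set_yticks(range(len(matrix.index)), labels=list(matrix.index))
    ax.set_xlabel("position")
    ax.set_ylabel("substitution")
    fig.colorbar(im, ax=ax, label="signed log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def crosslink_fraction(
    intensity_crosslinked: float, intensity_total_components: Iterable[float]
) -> float:
    """Cross-linked fraction (%): crosslinked intensity over summed total intensity."""
    components = [float(v) for v in intensity_total_components]
    if intensity_crosslinked < 0 or any(v < 0 for v in components):
        raise StatsError("intensities must be nonnegative")
    total = sum(components)
    if total <= 0:
        raise StatsError("total intensity must be positive")
    return 100.0 * intensity_crosslinked / total
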