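"""Barcode-gap analysis: stratify pairwise distances by taxonomic rank.

Every unordered pair of sequences is coded as *intraspecific* (same genus,
same epithet, neither name carrying an sp./cf./aff. qualifier),
*intrageneric* (same genus but not conspecific -- where pairs involving
sp./cf./aff. specimens land, since those can only be compared at genus
level), or *other* (different genera). A usable barcode locus shows a gap
between the intraspecific distance distribution and the rest; the overlap
fraction quantifies its absence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .distances import FLAG_MISSING, FLAG_OK, FLAG_SATURATED, DistanceMatrix
from .errors import LabelParseError, UndefinedDistanceError
from .seqio import TaxonName, parse_taxon_label, write_tsv

CATEGORIES = ("intraspecific", "intrageneric", "other")

DEFAULT_TRUNCATION = 0.05
# fallback kernel bandwidth (substitutions/site) when a stratum has zero
# spread and Silverman's rule degenerates
_MIN_BANDWIDTH = 1e-4


def classify_pair(name_a: TaxonName, name_b: TaxonName) -> str:
    """Taxonomic stratum of a pair of parsed names (symmetric, total).

    Genus and epithet comparison is case-insensitive. A name with an
    sp./cf./aff. qualifier never forms an intraspecific pair, even against
    an identical label: such specimens are comparable at genus level only.
    """
    if name_a.genus.lower() != name_b.genus.lower():
        return "other"
    conspecific = (
        name_a.epithet is not None
        and name_b.epithet is not None
        and name_a.epithet.lower() == name_b.epithet.lower()
        and name_a.qualifier == "none"
        and name_b.qualifier == "none"
    )
    return "intraspecific" if conspecific else "intrageneric"


@dataclass(frozen=True)
class PairContrast:
    label_a: str
    label_b: str
    category: str
    d: float  # finite distance or +inf for a saturated pair
    n: int


@dataclass
class ContrastTable:
    """All classifiable pairwise contrasts plus exclusion bookkeeping.

    The identity  finite-category counts + missing + saturated + skipped
    = N(N-1)/2  is asserted on construction: every pair of the input matrix
    is accounted for exactly once.
    """

    contrasts: list[PairContrast]
    n_sequences: int
    missing_pairs: int
    saturated_pairs: int
    skipped_labels: list[str]
    skipped_pairs: int

    def finite_contrasts(self) -> list[PairContrast]:
        return [c for c in self.contrasts if math.isfinite(c.d)]

    def category_counts(self) -> dict[str, int]:
        counts = {cat: 0 for cat in CATEGORIES}
        for c in self.finite_contrasts():
            counts[c.category] += 1
        return counts

    def total_pairs(self) -> int:
        return self.n_sequences * (self.n_sequences - 1) // 2

    def assert_bookkeeping(self) -> None:
        counted = (
            sum(self.category_counts().values())
            + self.missing_pairs
            + self.saturated_pairs
            + self.skipped_pairs
        )
        if counted != self.total_pairs():
            raise AssertionError(
                f"pair bookkeeping broken: {counted} accounted for, "
                f"expected N(N-1)/2 = {self.total_pairs()}"
            )

    def to_tsv(self, path) -> None:
        rows = [
            (c.label_a, c.label_b, c.category, c.n,
             "inf" if math.isinf(c.d) else f"{c.d:.8g}",
             "saturated" if math.isinf(c.d) else "ok")
            for c in self.contrasts
        ]
        write_tsv(rows, path, header=("labelA", "labelB", "category", "n", "d", "flag"))


def contrast_table(
    matrix: DistanceMatrix,
    names: Optional[dict[str, TaxonName]] = None,
) -> ContrastTable:
    """Classify every pair of a distance matrix by taxonomic relationship.

    Labels that cannot be parsed are collected in a skip report and their
    pairs excluded; the run continues. ``names`` may supply pre-parsed
    taxon names keyed by label (ground truth from a simulator, say),
    bypassing label parsing.
    """
    parsed: dict[str, TaxonName] = {}
    skipped: list[str] = []
    for label in matrix.labels:
        if names is not None and label in names:
            parsed[label] = names[label]
            continue
        try:
            parsed[label] = parse_taxon_label(label)
        except LabelParseError:
            skipped.append(label)

    contrasts: list[PairContrast] = []
    skipped_set = set(skipped)
    missing = saturated = skipped_pairs = 0
    for i, j, a, b in matrix.pairs():
        if a in skipped_set or b in skipped_set:
            skipped_pairs += 1
            continue
        flag = int(matrix.flags[i, j])
        if flag == FLAG_MISSING:
            missing += 1
            continue
        category = classify_pair(parsed[a], parsed[b])
        contrasts.append(
            PairContrast(label_a=a, label_b=b, category=category,
                         d=float(matrix.d[i, j]), n=int(matrix.sites[i, j]))
        )
        if flag == FLAG_SATURATED:
            saturated += 1

    table = ContrastTable(
        contrasts=contrasts,
        n_sequences=len(matrix.labels),
        missing_pairs=missing,
        saturated_pairs=saturated,
        skipped_labels=skipped,
        skipped_pairs=skipped_pairs,
    )
    table.assert_bookkeeping()
    return table


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb, guarded against zero spread."""
    n = len(x)
    if n < 2:
        return _MIN_BANDWIDTH
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    scale = min(s for s in (sd, iqr / 1.34) if s > 0) if (sd > 0 or iqr > 0) else 0.0
    h = 0.9 * scale * n ** (-0.2)
    return h if h > 0 else _MIN_BANDWIDTH


def reflected_kde(
    x: np.ndarray,
    grid: np.ndarray,
    bandwidth: Optional[float] = None,
    chunk: int = 4096,
) -> np.ndarray:
    """Gaussian kernel density on [0, inf), reflected at the 0 boundary.

    Reflection returns the kernel mass that would leak below zero back to
    the positive half-line, so the density integrates to 1 over [0, inf).
    """
    x = np.asarray(x, dtype=float)
    h = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    dens = np.zeros_like(grid, dtype=float)
    norm = 1.0 / (len(x) * h * math.sqrt(2.0 * math.pi))
    for lo in range(0, len(x), chunk):
        block = x[lo : lo + chunk]
        z1 = (grid[:, None] - block[None, :]) / h
        z2 = (grid[:, None] + block[None, :]) / h
        dens += norm * (np.exp(-0.5 * z1 * z1).sum(axis=1)
                        + np.exp(-0.5 * z2 * z2).sum(axis=1))
    return dens


@dataclass
class CategoryStats:
    count: int
    min: Optional[float] = None
    max: Optional[float] = None
    mean: Optional[float] = None
    median: Optional[float] = None
    bandwidth: Optional[float] = None


@dataclass
class ContrastSummary:
    """Per-stratum order statistics and display densities.

    The truncation bound affects only the exported density grid (mirroring
    a plot cut "for clarity"); every statistic is computed over the full
    range of finite distances. Saturated pairs are counted in totals but
    excluded from statistics and densities.
    """

    stats: dict[str, CategoryStats]
    grid: np.ndarray
    densities: dict[str, Optional[np.ndarray]]
    truncation: float
    saturated_pairs: int = 0
    overlap: Optional[float] = None
    settings: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "categories": {
                cat: {
                    "count": st.count,
                    "min": st.min, "max": st.max,
                    "mean": st.mean, "median": st.median,
                    "kde_bandwidth": st.bandwidth,
                }
                for cat, st in self.stats.items()
            },
            "saturated_pairs": self.saturated_pairs,
            "overlap_fraction": self.overlap,
            "truncation": self.truncation,
            "settings": self.settings,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def density_tsv(self, path) -> None:
        header = ["d"] + [cat for cat in CATEGORIES if self.densities.get(cat) is not None]
        rows = []
        for k, x in enumerate(self.grid):
            rows.append([f"{x:.6g}"] + [
                f"{self.densities[cat][k]:.8g}" for cat in header[1:]
            ])
        write_tsv(rows, path, header=header)


def summarize_contrasts(
    contrasts: Iterable[PairContrast],
    truncation: float = DEFAULT_TRUNCATION,
    bandwidth: Optional[float] = None,
    grid_points: int = 512,
    saturated_pairs: Optional[int] = None,
) -> ContrastSummary:
    """Order statistics and reflected-Gaussian KDEs per stratum."""
    contrasts = list(contrasts)
    finite: dict[str, np.ndarray] = {
        cat: np.array([c.d for c in contrasts
                       if c.category == cat and math.isfinite(c.d)])
        for cat in CATEGORIES
    }
    n_saturated = (
        sum(1 for c in contrasts if math.isinf(c.d))
        if saturated_pairs is None else saturated_pairs
    )

    grid = np.linspace(0.0, truncation, grid_points)
    stats: dict[str, CategoryStats] = {}
    densities: dict[str, Optional[np.ndarray]] = {}
    for cat, x in finite.items():
        if len(x) == 0:
            stats[cat] = CategoryStats(count=0)
            densities[cat] = None
            continue
        h = bandwidth if bandwidth is not None else silverman_bandwidth(x)
        stats[cat] = CategoryStats(
            count=len(x),
            min=float(x.min()), max=float(x.max()),
            mean=float(x.mean()), median=float(np.median(x)),
            bandwidth=h,
        )
        densities[cat] = reflected_kde(x, grid, bandwidth=h)

    overlap: Optional[float] = None
    if len(finite["intraspecific"]) and (
        len(finite["intrageneric"]) or len(finite["other"])
    ):
        overlap = overlap_fraction(contrasts)

    return ContrastSummary(
        stats=stats, grid=grid, densities=densities, truncation=truncation,
        saturated_pairs=n_saturated, overlap=overlap,
        settings={"bandwidth": bandwidth or "silverman", "grid_points": grid_points},
    )


def overlap_fraction(contrasts: Iterable[PairContrast]) -> float:
    """Fraction of non-intraspecific distances at or below the largest
    intraspecific distance. 0 means a clean barcode gap; values near 1 mean
    the strata are indistinguishable."""
    intra, rest = [], []
    for c in contrasts:
        if not math.isfinite(c.d):
            continue
        (intra if c.category == "intraspecific" else rest).append(c.d)
    if not intra:
        raise UndefinedDistanceError(
            "overlap fraction undefined without finite intraspecific contrasts"
        )
    if not rest:
        raise UndefinedDistanceError(
            "overlap fraction undefined without finite non-intraspecific contrasts"
        )
    ceiling = max(intra)
    return sum(1 for d in rest if d <= ceiling) / len(rest)
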