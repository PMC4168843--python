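"""Pairwise site counting and Kimura 2-parameter (K2P) distances.

The K2P model corrects observed divergence for multiple hits with separate
transition and transversion proportions: with P = transitions/sites and
Q = transversions/sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)   [substitutions/site]

Sites are compared under *pairwise deletion*: a column contributes to a
pair's comparison only when both characters are unambiguous bases (A, C, G,
T); gaps, N, ? and all IUPAC ambiguity codes are excluded per pair, not per
column. When divergence is high enough that a log argument is non-positive
the distance is *saturated*: it is reported as ``math.inf`` and flagged, so
one saturated pair cannot abort a large matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .errors import AlignmentShapeError, UndefinedDistanceError
from .seqio import SequenceAlignment, SequenceRecord, write_tsv

#: default minimum comparable sites for a pair to be reported at all;
#: below this the pair is recorded as missing rather than given a wild value
DEFAULT_MIN_SITES = 100

# per-pair status codes in DistanceMatrix.flags
FLAG_OK = 0
FLAG_MISSING = 1    # fewer comparable sites than the minimum
FLAG_SATURATED = 2  # K2P log argument non-positive

FLAG_NAMES = {FLAG_OK: "ok", FLAG_MISSING: "missing", FLAG_SATURATED: "saturated"}

# byte -> base code lookup: A=0 C=1 G=2 T=3, everything else -1.
# XOR with 2 maps a base to its transition partner (A<->G, C<->T).
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a sequence string to int8 codes (non-ACGT -> -1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


@dataclass(frozen=True)
class SiteCounts:
    """Comparable sites and observed transition/transversion counts."""

    n: int
    ts: int
    tv: int

    def __post_init__(self):
        if min(self.n, self.ts, self.tv) < 0 or self.ts + self.tv > self.n:
            raise ValueError(f"inconsistent site counts {self}")


def count_site_differences(
    seq_a: Union[str, SequenceRecord], seq_b: Union[str, SequenceRecord]
) -> SiteCounts:
    """Classify aligned columns into comparable / transition / transversion."""
    a = seq_a.sequence if isinstance(seq_a, SequenceRecord) else seq_a
    b = seq_b.sequence if isinstance(seq_b, SequenceRecord) else seq_b
    if len(a) != len(b):
        raise AlignmentShapeError(
            f"sequences have different lengths ({len(a)} vs {len(b)})"
        )
    ca, cb = encode_sequence(a), encode_sequence(b)
    comparable = (ca >= 0) & (cb >= 0)
    diff = comparable & (ca != cb)
    ts = diff & ((ca ^ cb) == 2)
    return SiteCounts(
        n=int(comparable.sum()), ts=int(ts.sum()), tv=int(diff.sum() - ts.sum())
    )


def k2p_distance(counts: SiteCounts) -> float:
    """K2P distance from site counts.

    Returns ``math.inf`` (the saturation sentinel) when the observed
    proportions fall outside the model's domain. Raises
    :class:`UndefinedDistanceError` when there are no comparable sites at
    all, which is a different situation from saturation.
    """
    if counts.n == 0:
        raise UndefinedDistanceError("no comparable sites: distance undefined")
    p = counts.ts / counts.n
    q = counts.tv / counts.n
    return k2p_from_proportions(p, q)


def k2p_from_proportions(p: float, q: float) -> float:
    """K2P distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return d + 0.0  # normalize -0.0 for identical sequences


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair bookkeeping.

    ``d`` holds distances (NaN where a pair is missing, +inf where
    saturated); ``sites``, ``ts`` and ``tv`` hold per-pair counts and
    ``flags`` the per-pair status code.
    """

    labels: list[str]
    d: np.ndarray
    sites: np.ndarray
    ts: np.ndarray
    tv: np.ndarray
    flags: np.ndarray
    min_sites: int = DEFAULT_MIN_SITES

    def __post_init__(self):
        n = len(self.labels)
        for name in ("d", "sites", "ts", "tv", "flags"):
            arr = getattr(self, name)
            if arr.shape != (n, n):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, n)}")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_array(cls, labels: list[str], d: np.ndarray) -> "DistanceMatrix":
        """Wrap a plain symmetric distance array (site counts unknown)."""
        d = np.asarray(d, dtype=float)
        n = len(labels)
        flags = np.zeros((n, n), dtype=np.int8)
        flags[np.isnan(d)] = FLAG_MISSING
        flags[np.isinf(d)] = FLAG_SATURATED
        zeros = np.zeros((n, n), dtype=np.int64)
        return cls(labels=list(labels), d=d, sites=zeros.copy(), ts=zeros.copy(),
                   tv=zeros.copy(), flags=flags, min_sites=0)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def pairs(self):
        """Yield (i, j, labelA, labelB) over unordered pairs, i < j."""
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                yield i, j, self.labels[i], self.labels[j]

    def incomplete_pairs(self) -> list[tuple[str, str]]:
        """Label pairs whose distance is missing or saturated."""
        return [
            (a, b) for i, j, a, b in self.pairs() if self.flags[i, j] != FLAG_OK
        ]

    def submatrix(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in keep]
        ix = np.ix_(idx, idx)
        return DistanceMatrix(
            labels=list(keep),
            d=self.d[ix].copy(),
            sites=self.sites[ix].copy(),
            ts=self.ts[ix].copy(),
            tv=self.tv[ix].copy(),
            flags=self.flags[ix].copy(),
            min_sites=self.min_sites,
        )

    # -- export -----------------------------------------------------------

    def to_phylip(self, path) -> None:
        """Write the square PHYLIP distance format (missing/saturated as
        NaN/inf, which PHYLIP proper does not accept; export a complete
        matrix for downstream PHYLIP tools)."""
        with Path(path).open("w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, label in enumerate(self.labels):
                row = " ".join(f"{v:.8f}" for v in self.d[i])
                fh.write(f"{label.replace(' ', '_')[:50]}  {row}\n")

    def to_long_tsv(self, path) -> None:
        rows = [
            (
                a,
                b,
                int(self.sites[i, j]),
                int(self.ts[i, j]),
                int(self.tv[i, j]),
                "" if math.isnan(self.d[i, j]) else f"{self.d[i, j]:.8g}",
                FLAG_NAMES[int(self.flags[i, j])],
            )
            for i, j, a, b in self.pairs()
        ]
        write_tsv(rows, path, header=("labelA", "labelB", "n", "ts", "tv", "d", "flag"))


def read_phylip_distances(path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix (counts unavailable -> zeros)."""
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    d = np.asarray(rows, dtype=float)
    if d.shape != (n, n):
        raise ValueError(f"expected {n}x{n} matrix, got {d.shape}")
    zeros = np.zeros((n, n))
    flags = np.zeros((n, n), dtype=np.int8)
    flags[np.isnan(d)] = FLAG_MISSING
    flags[np.isinf(d)] = FLAG_SATURATED
    return DistanceMatrix(labels=labels, d=d, sites=zeros.copy(), ts=zeros.copy(),
                          tv=zeros.copy(), flags=flags, min_sites=0)


def pairwise_distance_matrix(
    alignment: SequenceAlignment, min_sites: int = DEFAULT_MIN_SITES
) -> DistanceMatrix:
    """All-pairs K2P distances under pairwise deletion.

    Pairs with fewer than ``min_sites`` comparable sites are recorded as
    missing (NaN + flag), not zero; saturated pairs carry the +inf sentinel.
    Per-pair problems never abort the matrix.
    """
    n = len(alignment)
    codes = np.vstack([encode_sequence(rec.sequence) for rec in alignment])
    valid = codes >= 0

    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    ts_m = np.zeros((n, n), dtype=np.int64)
    tv_m = np.zeros((n, n), dtype=np.int64)
    flags = np.zeros((n, n), dtype=np.int8)

    for i in range(n):
        ci, vi = codes[i], valid[i]
        for j in range(i + 1, n):
            comparable = vi & valid[j]
            nc = int(comparable.sum())
            diff = comparable & (ci != codes[j])
            nts = int((diff & ((ci ^ codes[j]) == 2)).sum())
            ntv = int(diff.sum()) - nts
            sites[i, j] = sites[j, i] = nc
            ts_m[i, j] = ts_m[j, i] = nts
            tv_m[i, j] = tv_m[j, i] = ntv
            if nc < max(min_sites, 1):
                d[i, j] = d[j, i] = np.nan
                flags[i, j] = flags[j, i] = FLAG_MISSING
                continue
            dist = k2p_from_proportions(nts / nc, ntv / nc)
            d[i, j] = d[j, i] = dist
            if math.isinf(dist):
                flags[i, j] = flags[j, i] = FLAG_SATURATED

    return DistanceMatrix(
        labels=alignment.labels, d=d, sites=sites, ts=ts_m, tv=tv_m,
        flags=flags, min_sites=min_sites,
    )
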