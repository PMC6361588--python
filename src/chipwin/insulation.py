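"""Capture Hi-C insulation scores and TAD strength.

A capture experiment yields contacts restricted to one genomic region; only
pairs with both ends inside the region are analyzed.  Contacts are binned
into a symmetric matrix (default 25 kb resolution), optionally normalized by
the square root of bin coverage, and an insulation score is computed by
sliding a square along the diagonal: for bin i the contacts between the
``w`` bins upstream and the ``w`` bins downstream are summed (the bin itself
is excluded) and expressed as a log2 ratio to the regional mean.  Local
insulation minima flanked by a negative-to-positive swing of the delta
vector are domain boundaries; a TAD's score is the mean strength of its two
boundaries.  Defaults follow the procedure this package reimplements:
insulation square 125 kb, delta span 75 kb, ``sum`` metric, at 25 kb
resolution (a 5x5 square).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ContactMatrix:
    """Symmetric contact counts over the fixed-resolution bins of one region."""

    region: tuple[str, int, int]
    resolution_bp: int
    matrix: np.ndarray
    total_reads: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("contact matrix must be square")
        finite = np.isfinite(self.matrix)
        sym_ok = np.allclose(self.matrix[finite & finite.T],
                             self.matrix.T[finite & finite.T], atol=1e-9)
        if not sym_ok:
            raise ValueError("contact matrix must be symmetric")
        if self.total_reads < 0:
            raise ValueError("total_reads must be >= 0")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


@dataclass
class InsulationTrack:
    """Per-bin insulation values (log2 ratio to the regional mean).

    ``values`` is NaN at masked bins; ``valid`` marks bins that are neither
    within the insulation span of a region edge nor over an empty square.
    ``raw`` holds the unlogged square sums.
    """

    values: np.ndarray
    valid: np.ndarray
    raw: np.ndarray
    resolution_bp: int
    is_bp: int = 125_000
    ids_bp: int = 75_000
    metric: str = "sum"

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.values[self.valid])):
            raise ValueError("valid insulation values must be finite")


@dataclass(frozen=True)
class Boundary:
    bin: int
    strength: float

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("boundary strength must be >= 0")


@dataclass(frozen=True)
class TADInterval:
    left_bin: int
    right_bin: int
    tad_score: float

    def __post_init__(self) -> None:
        if self.left_bin >= self.right_bin:
            raise ValueError("left boundary must precede right boundary")
        if self.tad_score < 0:
            raise ValueError("TAD score must be >= 0")


# ---------------------------------------------------------------------------
# operations


def build_contact_matrix(tag_pairs, region: tuple[str, int, int],
                         resolution_bp: int = 25_000) -> ContactMatrix:
    """Bin tag pairs with both ends inside the region into a symmetric matrix.

    ``tag_pairs`` is an iterable of (chrom1, pos1, chrom2, pos2) with 0-based
    positions.  Pairs with either end outside the region are discarded.  Each
    retained pair adds one count to [i, j] and [j, i] (once on the diagonal).
    """
    chrom, start, end = region
    n = -(-(end - start) // resolution_bp)
    if n < 3:
        raise ValueError("region must span at least 3 bins")
    m = np.zeros((n, n))
    total = 0
    for c1, p1, c2, p2 in tag_pairs:
        if c1 != chrom or c2 != chrom:
            continue
        if not (start <= p1 < end and start <= p2 < end):
            continue
        i = (int(p1) - start) // resolution_bp
        j = (int(p2) - start) // resolution_bp
        m[i, j] += 1
        if i != j:
            m[j, i] += 1
        total += 1
    return ContactMatrix(region, resolution_bp, m, total)


def sqrt_coverage_normalize(cm: ContactMatrix) -> ContactMatrix:
    """Divide entries by the square root of both bins' coverage (row sums),
    rescaled so the mean over unmasked entries is preserved.

    Bins with zero coverage are masked (NaN rows/columns).
    """
    m = cm.matrix
    if not np.any(m > 0):
        raise ValueError("all-zero contact matrix")
    cov = m.sum(axis=1)
    v = np.sqrt(cov)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = m / (v[:, None] * v[None, :])
    mask = (cov > 0)[:, None] & (cov > 0)[None, :]
    norm[~mask] = np.nan
    scale = m[mask].mean() / norm[mask].mean()
    norm[mask] *= scale
    return ContactMatrix(cm.region, cm.resolution_bp, norm, cm.total_reads)


def insulation_score(cm: ContactMatrix, is_bp: int = 125_000,
                     ids_bp: int = 75_000) -> InsulationTrack:
    """Insulation track of a contact matrix.

    With w = is_bp / resolution, raw(i) sums the square of contacts between
    the w bins strictly upstream and the w bins strictly downstream of bin i;
    value(i) = log2(raw(i) / mean of raw over valid bins).  Bins within w of
    either edge, or whose square is empty, are masked.
    """
    res = cm.resolution_bp
    if is_bp % res or ids_bp % res:
        raise ValueError("is_bp and ids_bp must be multiples of the resolution")
    w = is_bp // res
    n = cm.n_bins
    if n < 2 * w + 1:
        raise ValueError(f"matrix of {n} bins too small for a {w}-bin square")
    m = np.nan_to_num(cm.matrix, nan=0.0)
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        raw[i] = m[i - w:i, i + 1:i + 1 + w].sum()
    valid = np.isfinite(raw) & (raw > 0)
    values = np.full(n, np.nan)
    if valid.any():
        mean_raw = raw[valid].mean()
        values[valid] = np.log2(raw[valid] / mean_raw)
    return InsulationTrack(values, valid, raw, res, is_bp, ids_bp)


def region_read_normalize(raw_track: np.ndarray, total_reads: int) -> np.ndarray:
    """Scale raw square sums to per-million capture-region reads.

    Cross-sample comparison of raw insulation requires depth normalization by
    the reads inside the capture region; the log2-ratio track is invariant to
    this scaling.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    return np.asarray(raw_track, dtype=float) / (total_reads / 1e6)


def boundary_strength(track: InsulationTrack, i: int) -> float:
    """Strength of a boundary placed at bin i: mean of the maxima of the
    insulation value over the d-bin spans to the left and right, minus the
    value at i.  Negative differences are clamped at zero."""
    d = track.ids_bp // track.resolution_bp
    v = track.values
    if not track.valid[i]:
        raise ValueError(f"bin {i} is masked")
    left = v[max(i - d, 0):i]
    right = v[i + 1:i + 1 + d]
    left = left[np.isfinite(left)]
    right = right[np.isfinite(right)]
    if len(left) == 0 or len(right) == 0:
        raise ValueError(f"bin {i} lacks valid flanking bins")
    return max(0.0, float((left.max() + right.max()) / 2.0 - v[i]))


def delta_and_boundaries(track: InsulationTrack, ids_bp: int | None = None,
                         strength_floor: float = 0.1) -> list[Boundary]:
    """Boundaries: insulation minima where the delta vector swings from
    negative to positive.

    delta(i) = mean(value[i+1 .. i+d]) - mean(value[i-d .. i-1]) with
    d = ids_bp / resolution.  A boundary is placed at the smaller-valued of
    two consecutive bins where delta changes sign from negative to
    non-negative, provided it is a local minimum of the insulation value;
    boundaries weaker than ``strength_floor`` are discarded.
    """
    d = (ids_bp if ids_bp is not None else track.ids_bp) // track.resolution_bp
    v = track.values
    n = len(v)
    if int(track.valid.sum()) < 2 * d + 1:
        return []
    delta = np.full(n, np.nan)
    for i in range(n):
        left = v[max(i - d, 0):i]
        right = v[i + 1:i + 1 + d]
        left = left[np.isfinite(left)]
        right = right[np.isfinite(right)]
        if len(left) and len(right):
            delta[i] = right.mean() - left.mean()
    boundaries: list[Boundary] = []
    for i in range(n - 1):
        if not (np.isfinite(delta[i]) and np.isfinite(delta[i + 1])):
            continue
        if delta[i] < 0 <= delta[i + 1]:
            cand = i if (track.valid[i] and (not track.valid[i + 1]
                                             or v[i] <= v[i + 1])) else i + 1
            if not track.valid[cand]:
                continue
            lo, hi = max(cand - 1, 0), min(cand + 2, n)
            neighborhood = v[lo:hi]
            if v[cand] > np.nanmin(neighborhood) + 1e-12:
                continue
            s = boundary_strength(track, cand)
            if s >= strength_floor:
                boundaries.append(Boundary(cand, s))
    return boundaries


def tad_score(track: InsulationTrack, left_bin: int, right_bin: int) -> TADInterval:
    """TAD strength: mean of the boundary strengths evaluated at the two
    given bins (whether or not they were auto-detected)."""
    if left_bin >= right_bin:
        raise ValueError("left_bin must be < right_bin")
    s_left = boundary_strength(track, left_bin)
    s_right = boundary_strength(track, right_bin)
    return TADInterval(left_bin, right_bin, (s_left + s_right) / 2.0)
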