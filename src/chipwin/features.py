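"""Peak-set comparison suite.

Everything needed to compare two ChIP peak sets: interval intersection with
single-overlap (bedtools ``-u``) semantics, per-peak tag coverage, ordinary
least-squares R², PWM motif scanning with an exact tail-probability score
threshold, per-interval conservation averages, Wilcoxon rank-sum tests,
genomic-feature annotation, metagene profiles, and a small utility that
classifies RNA reads over a single codon.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .peakcalling import PeakSet, TagTrack, _window_sums

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Floor applied to PWM probabilities when forming log-odds, so that an
# impossible base scores very negatively but remains finite.
_PROB_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# PWM and motif scanning


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities over ACGT.

    ``probs`` has shape (w, 4) with rows summing to 1; ``background`` is the
    base composition the log-odds are taken against (uniform by default).
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must have shape (w, 4)")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """log2 odds against background, probabilities floored at 1e-6."""
        p = np.clip(self.probs, _PROB_FLOOR, None)
        return np.log2(p / self.background)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.probs, axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), self.background[::-1].copy(),
                   name=self.name)

    @classmethod
    def from_counts(cls, counts: np.ndarray, background=None,
                    pseudocount: float = 0.5, name: str = "motif") -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(probs, bg, name=name)


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int
    end: int
    strand: str
    score: float


def ctcf_like_pwm(width: int = 15, consensus_prob: float = 0.85) -> PWM:
    """A moderately informative PWM over the zinc-finger core consensus
    CCACCAGGGGGCGCT, for simulations and examples."""
    consensus = "CCACCAGGGGGCGCT"[:width]
    if width > len("CCACCAGGGGGCGCT"):
        raise ValueError("width must be <= 15")
    probs = np.full((width, 4), (1.0 - consensus_prob) / 3.0)
    for i, b in enumerate(consensus):
        probs[i, _CODE[b]] = consensus_prob
    return PWM(probs, name="ctcf_like")


def score_distribution(pwm: PWM, grid: float = 1e-3) -> tuple[int, np.ndarray]:
    """Exact distribution of the log-odds score of a random w-mer drawn from
    the PWM background.

    Per-cell log-odds are rounded to integer multiples of ``grid`` and the
    distribution is built by dynamic programming (convolution of the four
    per-position score atoms).  Returns ``(min_score, probs)`` where
    ``probs[i]`` is the probability of integer score ``min_score + i``.
    """
    s = np.rint(pwm.log_odds / grid).astype(np.int64)  # (w, 4) integer scores
    lo = int(s.min(axis=1).sum())
    hi = int(s.max(axis=1).sum())
    cur_lo = int(s[0].min())
    cur = np.zeros(int(s[0].max()) - cur_lo + 1)
    for b in range(4):
        cur[s[0, b] - cur_lo] += pwm.background[b]
    for j in range(1, pwm.width):
        new_lo = cur_lo + int(s[j].min())
        new = np.zeros(len(cur) + int(s[j].max()) - int(s[j].min()))
        for b in range(4):
            off = s[j, b] - int(s[j].min())
            new[off:off + len(cur)] += pwm.background[b] * cur
        cur, cur_lo = new, new_lo
    full = np.zeros(hi - lo + 1)
    full[cur_lo - lo:cur_lo - lo + len(cur)] = cur
    return lo, full


def pwm_tail_probability(pwm: PWM, threshold: float, grid: float = 1e-3) -> float:
    """P(score of a random background w-mer >= threshold), on the DP grid."""
    lo, probs = score_distribution(pwm, grid)
    t_int = int(math.ceil(threshold / grid - 1e-9))
    idx = max(t_int - lo, 0)
    if idx >= len(probs):
        return 0.0
    return float(probs[idx:].sum())


def pwm_threshold(pwm: PWM, p_cutoff: float = 3e-5, grid: float = 1e-3) -> float:
    """Minimal log-odds threshold t with background tail P(score >= t) <= p_cutoff.

    Computed by exact dynamic programming over per-cell scores discretized on
    ``grid`` (default 1e-3 log2-odds units).  When no achievable score has a
    small enough tail (e.g. a PWM identical to background), the cutoff is
    unreachable: a threshold just above the maximal score is returned (zero
    hits downstream) with a warning flag.
    """
    if not (0.0 < p_cutoff < 1.0):
        raise ValueError("p_cutoff must be in (0, 1)")
    lo, probs = score_distribution(pwm, grid)
    tail = np.cumsum(probs[::-1])[::-1]
    ok = np.flatnonzero(tail <= p_cutoff)
    if len(ok):
        t_int = lo + int(ok[0])
    else:
        t_int = lo + len(probs)  # above the maximal achievable score
        warnings.warn("p_cutoff unreachable below the maximal PWM score; "
                      "returning a threshold that admits no hits")
    return t_int * grid


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(len(arr), 4, dtype=np.int8)
    for b, i in _CODE.items():
        codes[arr == ord(b)] = i
    return codes


def _scan_one_strand(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    w = pwm.width
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    lo = np.concatenate([pwm.log_odds, np.full((w, 1), -np.inf)], axis=1)
    scores = np.zeros(n)
    for j in range(w):
        scores += lo[j, codes[j:j + n]]
    return scores


def scan_motifs(sequence: str, pwm: PWM, threshold: float,
                both_strands: bool = True, chrom: str = "chr1") -> list[MotifHit]:
    """All motif occurrences with log-odds >= threshold.

    N positions score -inf.  With ``both_strands`` the reverse complement is
    scanned as well; hits are reported in forward coordinates, sorted by
    start.  Overlapping hits are retained.
    """
    codes = _encode(sequence)
    hits: list[MotifHit] = []
    fwd = _scan_one_strand(codes, pwm)
    for i in np.flatnonzero(fwd >= threshold):
        hits.append(MotifHit(chrom, int(i), int(i) + pwm.width, "+", float(fwd[i])))
    if both_strands:
        rev = _scan_one_strand(codes, pwm.reverse_complement())
        for i in np.flatnonzero(rev >= threshold):
            hits.append(MotifHit(chrom, int(i), int(i) + pwm.width, "-", float(rev[i])))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# interval operations


def _by_chrom(intervals) -> dict[str, list]:
    d: dict[str, list] = {}
    for iv in intervals:
        d.setdefault(iv.chrom, []).append(iv)
    return d


def _overlaps_any(start: int, end: int, starts: np.ndarray, ends: np.ndarray) -> bool:
    """Any overlap of [start, end) with sorted, non-overlapping intervals."""
    i = np.searchsorted(starts, end)  # intervals with start < end
    j = np.searchsorted(ends, start, side="right")  # intervals with end <= start
    return i > j


def intersect_peaks(set_a: PeakSet, set_b: PeakSet) -> tuple[PeakSet, float]:
    """Peaks of A overlapping >= 1 bp of any peak of B, and the fraction of A.

    Single-overlap semantics: each A peak is reported at most once no matter
    how many B peaks it touches.  An empty A yields fraction ``nan``.
    """
    b_by = {c: (np.array([p.start for p in ps]), np.array([p.end for p in ps]))
            for c, ps in _by_chrom(set_b).items()}
    shared = []
    for p in set_a:
        if p.chrom in b_by and _overlaps_any(p.start, p.end, *b_by[p.chrom]):
            shared.append(p)
    frac = len(shared) / len(set_a) if len(set_a) else float("nan")
    return PeakSet(f"{set_a.label}_shared", list(shared)), frac


def peak_coverage(track: TagTrack, peaks: PeakSet | list) -> np.ndarray:
    """Tag count per peak: sum of tags on [start, end), in input peak order."""
    csums = {c: np.concatenate([[0], np.cumsum(a, dtype=np.int64)])
             for c, a in track.counts.items()}
    res = track.resolution
    out = np.zeros(len(list(peaks)), dtype=np.int64)
    for i, p in enumerate(peaks):
        if p.chrom not in csums:
            raise KeyError(f"track has no chromosome {p.chrom!r}")
        cs = csums[p.chrom]
        lo = min(p.start // res, len(cs) - 1)
        hi = min(-(-p.end // res), len(cs) - 1)
        out[i] = cs[hi] - cs[lo]
    return out


def count_motifs_in_peaks(motifs: list[MotifHit], peaks: PeakSet | list) -> np.ndarray:
    """Number of motif hits overlapping >= 1 bp of each peak.

    A motif overlapping two peaks counts for both.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c, ms in _by_chrom(motifs).items():
        ms.sort(key=lambda m: m.start)
        by_chrom[c] = (np.array([m.start for m in ms]),
                       np.array([m.end for m in ms]))
    peaks = list(peaks)
    out = np.zeros(len(peaks), dtype=np.int64)
    for i, p in enumerate(peaks):
        if p.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[p.chrom]
        # motif overlaps iff motif.start < p.end and motif.end > p.start
        lo = np.searchsorted(starts, p.end)
        out[i] = int(np.sum(ends[:lo] > p.start))
    return out


def average_conservation(score_track: dict[str, np.ndarray],
                         intervals) -> np.ndarray:
    """Mean per-bp score over the covered bases of each interval.

    ``score_track`` maps chromosome to a per-bp float array with NaN at
    uncovered positions; a fully uncovered interval yields NaN (flagged
    missing).
    """
    out = []
    for iv in intervals:
        arr = score_track.get(iv.chrom)
        if arr is None:
            out.append(float("nan"))
            continue
        seg = arr[iv.start:iv.end]
        with np.errstate(invalid="ignore"):
            out.append(float(np.nanmean(seg)) if np.any(~np.isnan(seg)) else float("nan"))
    return np.array(out)


# ---------------------------------------------------------------------------
# statistics


def linear_r2(x, y) -> float:
    """R² of ordinary least squares of y on x, with intercept.

    Returns NaN (flagged undefined) when y has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(y) == 0 or np.allclose(np.var(y), 0):
        return float("nan")
    if np.ptp(x) == 0:
        return float("nan")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2)


@dataclass(frozen=True)
class WilcoxonResult:
    u: float
    pvalue: float
    method: str  # "exact" or "asymptotic"


_ALTERNATIVES = {"two_sided": "two-sided", "two-sided": "two-sided",
                 "less": "less", "greater": "greater"}


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> WilcoxonResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test of two independent samples.

    Uses the exact null enumeration when the combined sample size is <= 20
    and there are no ties; otherwise the normal approximation with tie and
    continuity correction.  The result records which path was used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    alt = _ALTERNATIVES[alternative]
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alt, method=method,
                             use_continuity=True)
    return WilcoxonResult(float(res.statistic), float(res.pvalue), method)


# ---------------------------------------------------------------------------
# gene annotation and metagene


@dataclass
class GeneModel:
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: list[tuple[int, int]]
    name: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError("exon outside transcript bounds")
            if prev_end is not None and s < prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


CATEGORIES = ("promoter", "utr5", "utr3", "exon", "intron",
              "downstream", "intergenic")


@dataclass
class FeatureDistribution:
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("fractions must sum to 1")


def _classify_point(chrom: str, pos: int, genes: list[GeneModel],
                    promoter_bp: int) -> str:
    best = len(CATEGORIES) - 1  # intergenic
    for g in genes:
        if g.chrom != chrom:
            continue
        cats = []
        if abs(pos - g.tss) <= promoter_bp:
            cats.append("promoter")
        if g.tx_start <= pos < g.tx_end:
            in_exon = any(s <= pos < e for s, e in g.exons)
            if in_exon:
                if g.strand == "+":
                    if pos < g.cds_start:
                        cats.append("utr5")
                    elif pos >= g.cds_end:
                        cats.append("utr3")
                    else:
                        cats.append("exon")
                else:
                    if pos >= g.cds_end:
                        cats.append("utr5")
                    elif pos < g.cds_start:
                        cats.append("utr3")
                    else:
                        cats.append("exon")
            else:
                cats.append("intron")
        else:
            down = (g.tx_end <= pos < g.tx_end + promoter_bp) if g.strand == "+" \
                else (g.tx_start - promoter_bp <= pos < g.tx_start)
            if down:
                cats.append("downstream")
        for c in cats:
            best = min(best, CATEGORIES.index(c))
    return CATEGORIES[best]


def annotate_peaks(peaks: PeakSet | list, genes: list[GeneModel],
                   promoter_bp: int = 1000,
                   chrom_lengths: dict[str, int] | None = None,
                   probe_step: int = 1000,
                   ) -> tuple[FeatureDistribution, FeatureDistribution | None]:
    """Genomic-feature distribution of peaks, each assigned by its midpoint.

    Priority: promoter > 5'UTR > 3'UTR > exon > intron > downstream >
    intergenic.  When ``chrom_lengths`` is given, the genome-background
    distribution over uniformly spaced probe points is returned as well.
    """
    peaks = list(peaks)
    if not peaks:
        raise ValueError("empty peak set")
    counts = {c: 0 for c in CATEGORIES}
    for p in peaks:
        mid = (p.start + p.end) // 2
        counts[_classify_point(p.chrom, mid, genes, promoter_bp)] += 1
    dist = FeatureDistribution({c: counts[c] / len(peaks) for c in CATEGORIES})
    background = None
    if chrom_lengths is not None:
        bg = {c: 0 for c in CATEGORIES}
        n = 0
        for chrom, length in chrom_lengths.items():
            for pos in range(probe_step // 2, length, probe_step):
                bg[_classify_point(chrom, pos, genes, promoter_bp)] += 1
                n += 1
        background = FeatureDistribution({c: bg[c] / n for c in CATEGORIES})
    return dist, background


def metagene_profile(coverage_track: dict[str, np.ndarray],
                     genes: list[GeneModel], n_body_bins: int = 60,
                     flank_bp: int = 2000, flank_bins: int = 20,
                     ) -> tuple[np.ndarray, int]:
    """Average coverage over genes: fixed-width flanks plus a rescaled body.

    Each gene body is rescaled to ``n_body_bins`` bins; flanks are binned at
    ``flank_bp / flank_bins`` bp.  Minus-strand genes are reversed so the
    profile reads 5'→3' left to right.  Genes shorter than ``n_body_bins``
    bp are skipped; the skip count is returned.
    """
    width = n_body_bins + 2 * flank_bins
    rows = []
    skipped = 0
    fw = flank_bp / flank_bins
    for g in genes:
        cov = coverage_track.get(g.chrom)
        if cov is None or g.tx_end - g.tx_start < n_body_bins:
            skipped += 1
            continue
        row = np.full(width, np.nan)
        # upstream flank (genomic left), body, downstream flank
        for k in range(flank_bins):
            s = int(g.tx_start - flank_bp + k * fw)
            e = int(g.tx_start - flank_bp + (k + 1) * fw)
            s, e = max(s, 0), min(e, len(cov))
            if e > s:
                row[k] = float(np.mean(cov[s:e]))
        length = g.tx_end - g.tx_start
        edges = g.tx_start + np.floor(
            np.arange(n_body_bins + 1) * length / n_body_bins).astype(int)
        for k in range(n_body_bins):
            row[flank_bins + k] = float(np.mean(cov[edges[k]:edges[k + 1]]))
        for k in range(flank_bins):
            s = int(g.tx_end + k * fw)
            e = int(g.tx_end + (k + 1) * fw)
            s, e = max(s, 0), min(e, len(cov))
            if e > s:
                row[flank_bins + n_body_bins + k] = float(np.mean(cov[s:e]))
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
    if not rows:
        return np.full(width, np.nan), skipped
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.vstack(rows), axis=0), skipped


# ---------------------------------------------------------------------------
# codon-read classification


@dataclass
class CodonTally:
    """Per-position base counts over a three-base codon, plus the fraction of
    reads spelling a glutamate codon (GAA/GAG) among reads with no N."""

    counts: pd.DataFrame  # index A,C,G,T,N; columns pos1..pos3
    glutamate_fraction: float
    n_reads: int


GLUTAMATE_CODONS = ("GAA", "GAG")


def classify_codon_reads(read_bases) -> CodonTally:
    """Tally base calls at the three positions of a codon.

    ``read_bases`` is an iterable of 3-character strings, or a DataFrame
    with columns ``base1..base3``.  Any character outside ACGT counts as N.
    """
    if isinstance(read_bases, pd.DataFrame):
        codons = (read_bases["base1"].astype(str) + read_bases["base2"].astype(str)
                  + read_bases["base3"].astype(str)).tolist()
    else:
        codons = [str(c) for c in read_bases]
    letters = "ACGTN"
    counts = np.zeros((5, 3), dtype=np.int64)
    n_glu = 0
    n_clean = 0
    for codon in codons:
        codon = codon.upper()
        norm = "".join(c if c in "ACGT" else "N" for c in codon[:3].ljust(3, "N"))
        for j, c in enumerate(norm):
            counts[letters.index(c), j] += 1
        if "N" not in norm:
            n_clean += 1
            if norm in GLUTAMATE_CODONS:
                n_glu += 1
    frac = n_glu / n_clean if n_clean else float("nan")
    df = pd.DataFrame(counts, index=list(letters),
                      columns=["pos1", "pos2", "pos3"])
    return CodonTally(df, frac, len(codons))
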