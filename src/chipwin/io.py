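"""Readers and writers for the plain-text formats shared across modules.

Conventions: BED and bedGraph coordinates are 0-based half-open; tag-pair
files carry 1-based positions (converted to 0-based on read); dense contact
matrices are TSV with a header row and column of bin start coordinates.
Malformed lines raise :class:`FileFormatError` with the line number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import PWM
from .insulation import ContactMatrix
from .peakcalling import Peak, PeakSet, TagTrack


class FileFormatError(ValueError):
    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# BED


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


def read_bed(path) -> list[BedRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FileFormatError(path, lineno, "BED needs >= 3 fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise FileFormatError(path, lineno, "non-integer coordinates")
            if end <= start or start < 0:
                raise FileFormatError(path, lineno, f"bad interval [{start}, {end})")
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 else 0.0
            strand = f[5] if len(f) > 5 else "."
            records.append(BedRecord(f[0], start, end, name, score, strand))
    return records


def write_bed(path, records) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\n")


def write_peaks_bed(path, peaks: PeakSet) -> None:
    """BED6 peaks: name = peak id, score = min(1000, round(100 * z_max))."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = int(min(1000, round(100 * p.z_max)))
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{peaks.label}_{i}\t{score}\t.\n")


def read_peaks_bed(path, label: str = "peaks") -> PeakSet:
    recs = sorted(read_bed(path), key=lambda r: (r.chrom, r.start))
    return PeakSet(label, [Peak(r.chrom, r.start, r.end, r.score / 100.0)
                           for r in recs])


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph as a DataFrame (chrom, start, end, value); intervals must be
    sorted and non-overlapping within each chromosome."""
    rows = []
    last: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise FileFormatError(path, lineno, "bedGraph needs 4 fields")
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError:
                raise FileFormatError(path, lineno, "malformed bedGraph fields")
            if end <= start:
                raise FileFormatError(path, lineno, f"bad interval [{start}, {end})")
            if f[0] in last and start < last[f[0]]:
                raise FileFormatError(path, lineno,
                                      "overlapping or unsorted intervals")
            last[f[0]] = end
            rows.append((f[0], start, end, value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(path, track: dict[str, np.ndarray] | TagTrack,
                   resolution: int = 1) -> None:
    """Write a per-position track run-length encoded as bedGraph."""
    if isinstance(track, TagTrack):
        resolution = track.resolution
        track = track.counts
    with open(path, "w") as fh:
        for chrom in sorted(track):
            arr = np.asarray(track[chrom])
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s * resolution}\t{e * resolution}\t{arr[s]:g}\n")


def track_from_bedgraph(df: pd.DataFrame, chrom_lengths: dict[str, int],
                        resolution: int = 1, dtype=np.int64) -> TagTrack:
    """Expand a bedGraph DataFrame to a dense per-position TagTrack."""
    counts = {c: np.zeros(-(-L // resolution), dtype=dtype)
              for c, L in chrom_lengths.items()}
    for chrom, start, end, value in df.itertuples(index=False):
        counts[chrom][start // resolution:-(-end // resolution)] = dtype(value)
    return TagTrack(counts, resolution)


# ---------------------------------------------------------------------------
# FASTA (via Biopython)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PWM (JASPAR-style text)


def read_pwm(path, pseudocount: float = 0.5) -> PWM:
    """JASPAR-style PWM text: optional ``>`` header, then four rows
    ``A  [ 1 2 3 ]`` (brackets optional) in A/C/G/T order."""
    name = "motif"
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else name
                continue
            parts = line.replace("[", " ").replace("]", " ").split()
            if parts[0].upper() not in "ACGT":
                raise FileFormatError(path, lineno, f"unexpected row {parts[0]!r}")
            try:
                rows[parts[0].upper()] = [float(x) for x in parts[1:]]
            except ValueError:
                raise FileFormatError(path, lineno, "non-numeric PWM entry")
    if set(rows) != set("ACGT"):
        raise FileFormatError(path, 0, "PWM must have A, C, G and T rows")
    counts = np.array([rows[b] for b in "ACGT"]).T
    if np.allclose(counts.sum(axis=1), 1.0, atol=1e-6):
        # already a probability matrix: no count-scale smoothing
        return PWM(counts / counts.sum(axis=1, keepdims=True), name=name)
    return PWM.from_counts(counts, pseudocount=pseudocount, name=name)


def write_pwm(path, pwm: PWM) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for bi, base in enumerate("ACGT"):
            vals = " ".join(f"{v:.6f}" for v in pwm.probs[:, bi])
            fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# dense contact matrix TSV


def write_matrix(path, cm: ContactMatrix) -> None:
    chrom, start, _ = cm.region
    coords = [start + i * cm.resolution_bp for i in range(cm.n_bins)]
    df = pd.DataFrame(cm.matrix, index=coords, columns=coords)
    with open(path, "w") as fh:
        fh.write(f"# region={chrom}:{cm.region[1]}-{cm.region[2]} "
                 f"resolution={cm.resolution_bp} total_reads={cm.total_reads}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def read_matrix(path) -> ContactMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# region="):
            raise FileFormatError(path, 1, "missing matrix header line")
        fields = dict(kv.split("=") for kv in header[2:].split())
        chrom, span = fields["region"].split(":")
        start, end = (int(x) for x in span.split("-"))
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return ContactMatrix((chrom, start, end), int(fields["resolution"]),
                         df.to_numpy(), int(fields["total_reads"]))


# ---------------------------------------------------------------------------
# tag pairs, DE table, JSON


def read_pairs(path) -> list[tuple[str, int, str, int]]:
    """Tab-delimited tag pairs: chrom1 pos1 strand1 chrom2 pos2 strand2
    (strands ignored, positions 1-based on disk, 0-based in memory)."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FileFormatError(path, lineno, "pair line needs 6 fields")
            try:
                pairs.append((f[0], int(f[1]) - 1, f[3], int(f[4]) - 1))
            except ValueError:
                raise FileFormatError(path, lineno, "non-integer position")
    return pairs


def write_pairs(path, pairs) -> None:
    with open(path, "w") as fh:
        for c1, p1, c2, p2 in pairs:
            fh.write(f"{c1}\t{p1 + 1}\t+\t{c2}\t{p2 + 1}\t+\n")


_DE_ALIASES = {"gene_id": ("gene_id", "gene", "id"),
               "log2fc": ("log2fc", "log2foldchange", "lfc"),
               "padj": ("padj", "adj_pvalue", "adjusted_pvalue", "fdr")}


def read_de_table(path) -> pd.DataFrame:
    """Differential-expression table (TSV) with gene id, log2 fold change and
    adjusted p-value columns under common namings."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    out = {}
    for canon, aliases in _DE_ALIASES.items():
        found = next((cols[a] for a in aliases if a in cols), None)
        if found is None:
            raise FileFormatError(path, 1, f"missing column for {canon}")
        out[canon] = df[found]
    result = pd.DataFrame(out)
    if result["gene_id"].duplicated().any():
        raise FileFormatError(path, 0, "duplicate gene ids")
    return result


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
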