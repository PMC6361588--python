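"""Synthetic-data generators for the full analysis bench.

Everything the pipeline consumes can be generated at desk scale with known
ground truth: a random genome with planted PWM binding sites of graded
affinity, negative-binomially dispersed ChIP and input tag tracks, a
capture-region contact matrix with power-law distance decay and depleted
contacts across domain boundaries, RNA reads over a single codon, simple
gene models, and a differential-expression table to threshold.

The phospho-bound subset of planted sites is drawn from the top of the
affinity distribution and carries at least the median motif count of the
remaining sites, reproducing the structure the downstream comparisons are
designed to detect (stronger binding signal and more motifs at the
phospho-marked subset).  This is a simulation convention describing the
observed structure, not a causal claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import PWM, GeneModel
from .insulation import ContactMatrix
from .peakcalling import TagTrack

_BASES = np.array(list("ACGT"))


class PlacementError(ValueError):
    """Raised when requested sites cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GenomeModel:
    chrom_names: list[str]
    chrom_lengths: list[int]
    sequence: dict[str, str] | None = None
    resolution: int = 1

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        for n, L in zip(self.chrom_names, self.chrom_lengths):
            if L <= 0:
                raise ValueError(f"{n}: chromosome length must be > 0")
            if self.sequence is not None and len(self.sequence[n]) != L:
                raise ValueError(f"{n}: sequence length != chrom_length")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))


@dataclass(frozen=True)
class PlantedSite:
    chrom: str
    start: int
    end: int
    affinity: float
    n_motifs: int
    phospho: bool

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("site end must exceed start")
        if self.affinity < 1:
            raise ValueError("affinity must be >= 1")
        if self.n_motifs < 1:
            raise ValueError("n_motifs must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic bench.

    ``depth_chip`` / ``depth_input`` are expected background tags per bp
    (the input is sequenced deeper than the ChIP, as is standard);
    ``nb_size`` is the per-bp NB dispersion size of simulated counts;
    ``affinity_range`` spans the enrichment multipliers of planted sites;
    ``phospho_fraction`` of sites form the phospho-bound subset.  Contact
    maps decay as (distance+1)^-decay_exponent with contacts crossing a
    domain boundary multiplied by ``boundary_depletion``.
    """

    seed: int = 0
    depth_chip: float = 0.5
    depth_input: float = 2.0
    nb_size: float = 10.0
    n_sites: int = 50
    phospho_fraction: float = 0.2
    affinity_range: tuple[float, float] = (8.0, 15.0)
    site_width: int = 400
    tad_boundaries: tuple[int, ...] = (20, 38)
    boundary_depletion: float = 0.25
    decay_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.depth_chip <= 0 or self.depth_input <= 0:
            raise ValueError("depths must be > 0")
        if self.nb_size <= 0:
            raise ValueError("nb_size must be > 0")
        if not (0.0 < self.boundary_depletion <= 1.0):
            raise ValueError("boundary_depletion must be in (0, 1]")
        if not (0.0 <= self.phospho_fraction <= 1.0):
            raise ValueError("phospho_fraction must be in [0, 1]")
        if self.affinity_range[0] < 1 or self.affinity_range[1] < self.affinity_range[0]:
            raise ValueError("affinity_range must satisfy 1 <= lo <= hi")


# ---------------------------------------------------------------------------
# genome and binding sites


def generate_genome(n_chroms: int, length_bp: int, gc_fraction: float = 0.5,
                    seed: int = 0) -> GenomeModel:
    """I.i.d. random genome of ``n_chroms`` chromosomes of ``length_bp`` each."""
    if length_bp <= 0:
        raise ValueError("length_bp must be > 0")
    if n_chroms <= 0:
        raise ValueError("n_chroms must be > 0")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    names = [f"chr{i + 1}" for i in range(n_chroms)]
    seqs = {n: "".join(_BASES[rng.choice(4, size=length_bp, p=p)]) for n in names}
    return GenomeModel(names, [length_bp] * n_chroms, seqs)


def plant_sites(genome: GenomeModel, pwm: PWM, config: SimulationConfig,
                motif_spacer: int = 8) -> tuple[GenomeModel, list[PlantedSite]]:
    """Plant non-overlapping binding sites and return the ground truth.

    Each site's sequence is overwritten with ``n_motifs`` copies of the PWM
    consensus.  Affinities are uniform over ``affinity_range``; the
    ``phospho_fraction`` of sites with the highest affinities are flagged
    phospho and receive at least the median motif count of the rest.
    Sites are returned sorted by coordinate.
    """
    if genome.sequence is None:
        raise ValueError("genome must carry sequence to plant motifs")
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_sites
    w = pwm.width
    if w > min(genome.chrom_lengths):
        raise ValueError("motif longer than the shortest chromosome")
    site_w = max(config.site_width, 4 * (w + motif_spacer))
    margin = 2 * site_w  # keep sites apart so merged peaks stay distinct

    # allocate sites to chromosomes proportional to length, slot placement
    slots: list[tuple[str, int]] = []
    for name, L in zip(genome.chrom_names, genome.chrom_lengths):
        n_slots = max((L - margin) // (site_w + margin), 0)
        slots.extend((name, margin + i * (site_w + margin)) for i in range(n_slots))
    if len(slots) < n:
        raise PlacementError(
            f"cannot place {n} non-overlapping sites (only {len(slots)} slots)")
    chosen = [slots[i] for i in sorted(rng.choice(len(slots), size=n, replace=False))]

    affinity = rng.uniform(*config.affinity_range, size=n)
    n_phospho = int(round(n * config.phospho_fraction))
    order = np.argsort(affinity)
    phospho = np.zeros(n, dtype=bool)
    if n_phospho > 0:
        phospho[order[-n_phospho:]] = True
    n_motifs = rng.integers(1, 4, size=n)  # 1..3 for non-phospho
    med = int(np.median(n_motifs[~phospho])) if (~phospho).any() else 2
    n_motifs[phospho] = np.maximum(rng.integers(2, 5, size=int(phospho.sum())), med)

    consensus = pwm.consensus()
    seqs = {name: list(genome.sequence[name]) for name in genome.chrom_names}
    sites: list[PlantedSite] = []
    for i, (chrom, start) in enumerate(chosen):
        end = start + site_w
        pos = start + motif_spacer  # motifs sit inside the enriched footprint
        for _ in range(int(n_motifs[i])):
            seqs[chrom][pos:pos + w] = consensus
            pos += w + motif_spacer
        sites.append(PlantedSite(chrom, start, end, float(affinity[i]),
                                 int(n_motifs[i]), bool(phospho[i])))
    sites.sort(key=lambda s: (s.chrom, s.start))
    new_genome = GenomeModel(genome.chrom_names, list(genome.chrom_lengths),
                             {n_: "".join(s) for n_, s in seqs.items()})
    return new_genome, sites


# ---------------------------------------------------------------------------
# tag tracks


def _nb_draw(rng: np.random.Generator, mean, size_param: float, n: int) -> np.ndarray:
    """NB(mean, size) samples via numpy's (n, p) parameterization."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def simulate_tags(genome: GenomeModel, sites: list[PlantedSite],
                  config: SimulationConfig) -> tuple[TagTrack, TagTrack]:
    """Per-bp ChIP and input tag counts.

    Input counts are NB(depth_input, nb_size) everywhere; ChIP counts are
    NB(depth_chip * affinity, nb_size) inside planted sites and
    NB(depth_chip, nb_size) elsewhere.  Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed + 2)
    chip: dict[str, np.ndarray] = {}
    inp: dict[str, np.ndarray] = {}
    for name, L in zip(genome.chrom_names, genome.chrom_lengths):
        c = _nb_draw(rng, config.depth_chip, config.nb_size, L)
        for s in sites:
            if s.chrom == name:
                c[s.start:s.end] = _nb_draw(
                    rng, config.depth_chip * s.affinity, config.nb_size,
                    s.end - s.start)
        chip[name] = c.astype(np.int64)
        inp[name] = _nb_draw(rng, config.depth_input, config.nb_size, L).astype(np.int64)
    return TagTrack(chip), TagTrack(inp)


# ---------------------------------------------------------------------------
# contact matrices


def expected_contacts(n_bins: int, tad_boundaries, boundary_depletion: float,
                      decay_exponent: float, depth: float) -> np.ndarray:
    """Expected contact matrix: power-law distance decay with a depletion
    factor for every boundary strictly between the two bins."""
    i = np.arange(n_bins)
    dist = np.abs(i[:, None] - i[None, :])
    expect = depth * (dist + 1.0) ** (-decay_exponent)
    for b in tad_boundaries:
        lo = np.minimum(i[:, None], i[None, :])
        hi = np.maximum(i[:, None], i[None, :])
        crossed = (lo < b) & (hi >= b)
        expect = np.where(crossed, expect * boundary_depletion, expect)
    return expect


def simulate_contact_matrix(n_bins: int, resolution_bp: int, tad_boundaries,
                            boundary_depletion: float, decay_exponent: float,
                            depth: float, seed: int = 0,
                            chrom: str = "chrX", start: int = 0) -> ContactMatrix:
    """Poisson-sampled symmetric contact matrix of one capture region.

    E[i,j] = depth * (|i-j|+1)^(-decay_exponent), multiplied by
    ``boundary_depletion`` once per boundary strictly between i and j.
    """
    if n_bins < 12:
        raise ValueError("n_bins must be >= 12")
    for b in tad_boundaries:
        if not (1 <= b <= n_bins - 1):
            raise ValueError(f"boundary {b} outside [1, n_bins-1]")
    rng = np.random.default_rng(seed)
    expect = expected_contacts(n_bins, tad_boundaries, boundary_depletion,
                               decay_exponent, depth)
    upper = np.triu(rng.poisson(expect))
    m = upper + np.triu(upper, 1).T
    total = int(np.triu(m).sum())
    region = (chrom, start, start + n_bins * resolution_bp)
    return ContactMatrix(region, resolution_bp, m.astype(float), total)


# ---------------------------------------------------------------------------
# codon reads and auxiliary tables


def simulate_codon_reads(n_reads: int, mutant_fraction: float = 0.14,
                         error_rate: float = 0.0, seed: int = 0,
                         mutant_codon: str = "GAG",
                         ref_codon: str = "TCC") -> pd.DataFrame:
    """Reads over a single codon: a deterministic round(n * mutant_fraction)
    of them carry the glutamate codon, the rest the serine reference codon,
    then each base is independently flipped with ``error_rate``."""
    if not (0.0 <= mutant_fraction <= 1.0):
        raise ValueError("mutant_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_mut = int(round(n_reads * mutant_fraction))
    codons = np.array([mutant_codon] * n_mut + [ref_codon] * (n_reads - n_mut))
    rng.shuffle(codons)
    bases = np.array([list(c) for c in codons]) if n_reads else np.empty((0, 3), dtype="<U1")
    if error_rate > 0 and n_reads:
        flip = rng.random(bases.shape) < error_rate
        for i, j in zip(*np.nonzero(flip)):
            alternatives = [b for b in "ACGT" if b != bases[i, j]]
            bases[i, j] = alternatives[rng.integers(3)]
    return pd.DataFrame({
        "read_id": [f"read{i}" for i in range(n_reads)],
        "base1": bases[:, 0] if n_reads else [],
        "base2": bases[:, 1] if n_reads else [],
        "base3": bases[:, 2] if n_reads else [],
    })


def simulate_genes(genome: GenomeModel, n_genes: int, seed: int = 0,
                   min_len: int = 2000, max_len: int = 8000) -> list[GeneModel]:
    """Simple non-overlapping gene models (2-4 exons, random strand) for
    annotation and metagene exercises."""
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    spacing = max_len + 4000
    slots = []
    for name, L in zip(genome.chrom_names, genome.chrom_lengths):
        slots.extend((name, s) for s in range(3000, L - max_len - 3000, spacing))
    if len(slots) < n_genes:
        raise PlacementError(f"cannot place {n_genes} genes in this genome")
    keep = sorted(rng.choice(len(slots), size=n_genes, replace=False))
    for gi, idx in enumerate(keep):
        chrom, tx_start = slots[idx]
        length = int(rng.integers(min_len, max_len))
        tx_end = tx_start + length
        n_ex = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(200, length - 200), size=2 * n_ex - 2,
                                  replace=False))
        bounds = np.concatenate([[0], cuts, [length]])
        exons = [(tx_start + int(bounds[2 * k]), tx_start + int(bounds[2 * k + 1]))
                 for k in range(n_ex)]
        cds_start = exons[0][0] + min(150, exons[0][1] - exons[0][0] - 1)
        cds_end = exons[-1][1] - min(150, exons[-1][1] - exons[-1][0] - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(chrom, strand, tx_start, tx_end,
                               cds_start, cds_end, exons, name=f"gene{gi}"))
    return genes


def simulate_de_table(n_up: int = 118, n_down: int = 257, n_null: int = 12000,
                      seed: int = 0, alpha: float = 0.01) -> pd.DataFrame:
    """Differential-expression table with a planted number of up- and
    downregulated genes below the adjusted-p threshold; model fitting itself
    is out of scope, only thresholding of the table is exercised.

    Defaults plant 118 upregulated and 257 downregulated significant genes,
    the tally this bench's report stage reproduces.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_up):
        rows.append((f"up{i}", float(rng.uniform(0.3, 3.0)),
                     float(rng.uniform(0, alpha * 0.99))))
    for i in range(n_down):
        rows.append((f"down{i}", float(-rng.uniform(0.3, 3.0)),
                     float(rng.uniform(0, alpha * 0.99))))
    for i in range(n_null):
        rows.append((f"ns{i}", float(rng.normal(0, 0.2)),
                     float(rng.uniform(alpha * 1.5, 1.0))))
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"])
    return df.sample(frac=1.0, random_state=int(seed) % (2**32 - 1)).reset_index(drop=True)
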