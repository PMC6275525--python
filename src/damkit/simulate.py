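"""Synthetic genomes, annotations, and DamID fragment counts with planted
truth, so every analysis stage can be exercised without external data.

The generative model mirrors the assay design: for each cell type a
Dam-only control and a Dam-fusion sample, plus a TF-Dam pair.  A latent
per-fragment log2 occupancy surface (0 baseline, +delta on fragments of
expressed genes, +peak height on planted TF peaks) multiplies the fusion
sample's negative-binomial mean; Dam-only accessibility is flat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .reference import (
    GATCFragmentMap,
    assign_fragments_to_genes,
    GENE_COLUMNS,
)
from .signal import FragmentCounts

CELL_TYPES = ("A", "B")
SAMPLES = ("dam_A", "fusion_A", "dam_B", "fusion_B", "dam_TF", "fusion_TF")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset; defaults give a dataset on which all
    downstream callers run end-to-end in well under five minutes."""

    chrom_lengths: tuple[int, ...] = (6_000_000, 6_000_000)
    motif_rate_per_kb: float = 8.0  # planted, on top of background occurrences
    n_genes: int = 2000
    gene_length_median: float = 2000.0
    gene_length_sigma: float = 0.3
    expressed_fraction: float = 0.15
    effect_size: float = 2.0  # delta, log2 shift on expressed-gene fragments
    n_peaks: int = 50
    peak_width_fragments: int = 5
    peak_height: float = 3.0  # log2
    depth: float = 20.0  # NB mean reads per fragment
    dispersion: float = 0.2  # NB: var = mu + dispersion * mu^2
    accessibility_sigma: float = 0.0  # shared log2 bias field on both samples

    def validate(self) -> "SimulationConfig":
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not 0 < self.expressed_fraction < 1:
            raise ValueError("expressed_fraction must lie in (0, 1)")
        for name in ("motif_rate_per_kb", "gene_length_median", "gene_length_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_genes < 1 or self.n_peaks < 0 or self.peak_width_fragments < 1:
            raise ValueError("invalid gene/peak configuration")
        return self


@dataclass
class SimulationTruth:
    """Planted ground truth emitted alongside the noisy counts."""

    expressed: dict[str, set[str]]
    peaks: pd.DataFrame  # chrom, start, end, frag_lo, frag_hi
    occupancy: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


# ---------------------------------------------------------------------------
# Reference simulation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MOTIF_BYTES = np.frombuffer(b"GATC", dtype=np.uint8)


def _simulate_chromosome(length: int, motif_rate_per_kb: float,
                         rng: np.random.Generator) -> str:
    seq = _BASES[rng.integers(0, 4, size=length, dtype=np.uint8)].copy()
    n_plant = rng.poisson(motif_rate_per_kb * length / 1000.0)
    if n_plant and length >= 4:
        pos = rng.integers(0, length - 3, size=n_plant)
        for p in np.sort(pos):  # later plants may overwrite earlier ones
            seq[p : p + 4] = _MOTIF_BYTES
    return seq.tobytes().decode("ascii")


def _layout_genes(
    chrom: str,
    chrom_length: int,
    n: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[str, int, int, str]]:
    """Non-overlapping gene spans on one chromosome: lengths are log-normal,
    the leftover space is split into random inter-gene gaps."""
    if n == 0:
        return []
    lengths = rng.lognormal(
        mean=math.log(config.gene_length_median), sigma=config.gene_length_sigma, size=n
    ).astype(np.int64)
    lengths = np.maximum(lengths, 100)
    total = int(lengths.sum())
    if total > 0.85 * chrom_length:
        raise ValueError(
            f"chromosome {chrom}: genome too small for {n} genes "
            f"({total} bp of genes in {chrom_length} bp)"
        )
    free = chrom_length - total
    gaps = np.floor(rng.dirichlet(np.ones(n + 1)) * free).astype(np.int64)
    spans = []
    cursor = 0
    for i in range(n):
        cursor += int(gaps[i])
        start = cursor
        end = start + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        spans.append((chrom, start, end, strand))
        cursor = end
    return spans


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate a genome (i.i.d. background + Poisson-planted GATC motifs)
    and a set of non-overlapping gene spans.  Fully reproducible from the
    generator state."""
    config.validate()
    genomes = {}
    for c, length in enumerate(config.chrom_lengths):
        genomes[f"chr{c + 1}"] = _simulate_chromosome(
            length, config.motif_rate_per_kb, rng
        )
    # allocate genes to chromosomes proportionally to length
    lengths = np.asarray(config.chrom_lengths, dtype=np.float64)
    alloc = np.floor(config.n_genes * lengths / lengths.sum()).astype(int)
    for i in range(config.n_genes - alloc.sum()):
        alloc[i % alloc.size] += 1
    spans: list[tuple[str, int, int, str]] = []
    for c, (chrom, n_c) in enumerate(zip(genomes, alloc)):
        spans.extend(
            _layout_genes(chrom, config.chrom_lengths[c], int(n_c), config, rng)
        )
    genes = pd.DataFrame(
        [
            (f"gene{i:05d}", f"gene{i:05d}", chrom, start, end, strand)
            for i, (chrom, start, end, strand) in enumerate(spans)
        ],
        columns=GENE_COLUMNS,
    )
    return genomes, genes


# ---------------------------------------------------------------------------
# Count simulation


def _negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = mu + a mu^2);
    dispersion 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=np.float64)
    if dispersion <= 0:
        return rng.poisson(mean).astype(np.int64)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(np.int64)


def _plant_peaks(
    fmap: GATCFragmentMap, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample non-overlapping runs of ``peak_width_fragments`` consecutive
    internal fragments, uniformly over all feasible starts."""
    width = config.peak_width_fragments
    candidates = []
    for chrom in fmap.chrom_names:
        lo, hi = fmap.chrom_slice(chrom)
        internal = np.arange(lo, hi)[fmap.internal[lo:hi]]
        if internal.size < width:
            continue
        # internal fragments of one chromosome are contiguous in map order
        for s in range(internal.size - width + 1):
            candidates.append((chrom, int(internal[s]), int(internal[s]) + width))
    if config.n_peaks == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "frag_lo", "frag_hi"])
    if not candidates:
        raise ValueError("no chromosome can host a peak of the requested width")
    order = rng.permutation(len(candidates))
    chosen: list[tuple[str, int, int]] = []
    occupied: set[int] = set()
    for i in order:
        chrom, flo, fhi = candidates[i]
        frags = range(flo - 1, fhi + 1)  # keep a 1-fragment buffer between peaks
        if any(f in occupied for f in frags):
            continue
        chosen.append(candidates[i])
        occupied.update(frags)
        if len(chosen) == config.n_peaks:
            break
    if len(chosen) < config.n_peaks:
        raise ValueError(
            f"could only place {len(chosen)} of {config.n_peaks} peaks"
        )
    rows = [
        (chrom, int(fmap.starts[flo]), int(fmap.ends[fhi - 1]), flo, fhi)
        for chrom, flo, fhi in sorted(chosen, key=lambda t: (t[0], t[1]))
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "frag_lo", "frag_hi"])


def simulate_damid_counts(
    fmap: GATCFragmentMap,
    genes: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, FragmentCounts], SimulationTruth]:
    """Draw per-fragment counts for all six samples and emit planted truth.

    Truth (expressed sets, peak placement) is drawn before any count noise,
    so changing depth or dispersion under a fixed seed changes counts but
    never the truth tables.
    """
    config.validate()
    assignments, _ = assign_fragments_to_genes(fmap, genes)
    scorable = sorted(assignments)
    # fraction applies to the full annotation, but planted genes must be
    # scorable for the truth to be recoverable
    n_expressed = min(
        int(round(config.expressed_fraction * len(genes))), len(scorable)
    )

    expressed: dict[str, set[str]] = {}
    occupancy: dict[str, np.ndarray] = {}
    for cell in CELL_TYPES:
        chosen = rng.choice(len(scorable), size=n_expressed, replace=False)
        gene_ids = {scorable[i] for i in chosen}
        lam = np.zeros(fmap.n_fragments)
        for gid in gene_ids:
            lam[assignments[gid]] = config.effect_size
        expressed[cell] = gene_ids
        occupancy[cell] = lam

    peaks = _plant_peaks(fmap, config, rng)
    lam_tf = np.zeros(fmap.n_fragments)
    for p in peaks.itertuples(index=False):
        lam_tf[p.frag_lo : p.frag_hi] = config.peak_height
    occupancy["TF"] = lam_tf

    if config.accessibility_sigma > 0:
        bias = 2.0 ** rng.normal(0.0, config.accessibility_sigma, fmap.n_fragments)
    else:
        bias = np.ones(fmap.n_fragments)

    samples: dict[str, FragmentCounts] = {}
    for cell, lam in (("A", occupancy["A"]), ("B", occupancy["B"]), ("TF", lam_tf)):
        dam_mu = config.depth * bias
        fusion_mu = config.depth * bias * 2.0**lam
        samples[f"dam_{cell}"] = FragmentCounts(
            f"dam_{cell}", _negative_binomial(rng, dam_mu, config.dispersion)
        )
        samples[f"fusion_{cell}"] = FragmentCounts(
            f"fusion_{cell}", _negative_binomial(rng, fusion_mu, config.dispersion)
        )
    return samples, SimulationTruth(expressed=expressed, peaks=peaks, occupancy=occupancy)


def simulate_dataset(
    config: SimulationConfig, seed: int
) -> tuple[dict[str, str], pd.DataFrame, GATCFragmentMap, dict[str, FragmentCounts], SimulationTruth]:
    """One-call simulation: genome, genes, fragment map, counts, truth."""
    rng = np.random.default_rng(seed)
    genomes, genes = simulate_reference(config, rng)
    fmap = GATCFragmentMap.from_sequences(genomes)
    samples, truth = simulate_damid_counts(fmap, genes, config, rng)
    return genomes, genes, fmap, samples, truth


# ---------------------------------------------------------------------------
# Writers


def write_fasta(genomes: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Gene features only, converting back to 1-based closed coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.sort_values(["chrom", "start"]).itertuples(index=False):
            fh.write(
                f"{g.chrom}\tdamkit_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};Name={g.symbol}\n"
            )


def write_truth(truth: SimulationTruth, outdir) -> dict[str, str]:
    """Write expressed-gene and peak truth tables; returns name -> path."""
    from pathlib import Path

    outdir = Path(outdir)
    written = {}
    for cell, gene_ids in truth.expressed.items():
        path = outdir / f"truth_expressed_{cell}.tsv"
        pd.DataFrame({"gene_id": sorted(gene_ids)}).to_csv(path, sep="\t", index=False)
        written[f"truth_expressed_{cell}"] = str(path)
    peak_path = outdir / "truth_peaks.tsv"
    truth.peaks.to_csv(peak_path, sep="\t", index=False)
    written["truth_peaks"] = str(peak_path)
    return written


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["chrom_lengths"] = list(d["chrom_lengths"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "chrom_lengths" in d:
        d["chrom_lengths"] = tuple(int(x) for x in d["chrom_lengths"])
    return SimulationConfig(**d).validate()
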