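"""Per-fragment read counting and normalized log2 occupancy tracks.

The occupancy statistic is the log2 ratio of a Dam-fusion library over its
matched Dam-only control, computed on GATC fragments after library-size
scaling with a pseudocount and median-centering over internal fragments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import GATCFragmentMap

READ_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass
class FragmentCounts:
    """Integer read counts aligned to fragment-map order."""

    sample_id: str
    counts: np.ndarray
    n_dropped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError(f"negative counts in sample {self.sample_id!r}")

    @property
    def library_size(self) -> int:
        return int(self.counts.sum())


@dataclass
class OccupancyTrack:
    """Normalized log2(fusion/control) values aligned to fragment-map order."""

    values: np.ndarray
    pseudocount: float
    fusion_id: str
    control_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("occupancy track contains non-finite values")


# ---------------------------------------------------------------------------
# Read loading


def read_bed_reads(path) -> pd.DataFrame:
    """Load BED6 read intervals (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    return df[READ_COLUMNS]


def read_bam_reads(path) -> pd.DataFrame:
    """Load mapped reads from BAM/SAM as intervals with strand."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            rows.append(
                (
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                )
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def count_reads_per_fragment(
    reads: pd.DataFrame, fmap: GATCFragmentMap, sample_id: str = "sample"
) -> FragmentCounts:
    """Assign each read to the single fragment containing its 5' end.

    The 5' end is ``start`` for + strand reads and ``end - 1`` for - strand.
    Reads on unknown chromosomes (or with a 5' end off the chromosome) are
    dropped and tallied in ``n_dropped``.  An empty read set yields all-zero
    counts with a warning.
    """
    counts = np.zeros(fmap.n_fragments, dtype=np.int64)
    if len(reads) == 0:
        warnings.warn(f"sample {sample_id!r}: empty read set, all-zero counts")
        return FragmentCounts(sample_id, counts)
    dropped = 0
    for chrom, grp in reads.groupby("chrom", sort=False):
        five_prime = np.where(
            grp["strand"].to_numpy() == "-",
            grp["end"].to_numpy() - 1,
            grp["start"].to_numpy(),
        )
        idx = fmap.locate(chrom, five_prime)
        hit = idx >= 0
        dropped += int((~hit).sum())
        np.add.at(counts, idx[hit], 1)
    return FragmentCounts(sample_id, counts, n_dropped=dropped)


# ---------------------------------------------------------------------------
# Occupancy


def normalize_frequencies(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """Smoothed library-size normalization: (c_i + psi) / (sum c + m * psi)."""
    counts = np.asarray(counts, dtype=np.float64)
    m = counts.size
    return (counts + pseudocount) / (counts.sum() + m * pseudocount)


def compute_occupancy_track(
    fusion: FragmentCounts,
    control: FragmentCounts,
    fmap: GATCFragmentMap,
    pseudocount: float = 0.5,
    center: bool = True,
) -> OccupancyTrack:
    """log2 ratio of smoothed fusion over control frequencies, then
    median-centered over internal fragments (scaling-normalization stand-in).

    Raises on length mismatch, non-positive pseudocount, or an all-zero
    library (named in the error).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    for fc in (fusion, control):
        if fc.counts.size != fmap.n_fragments:
            raise ValueError(
                f"sample {fc.sample_id!r}: {fc.counts.size} counts for "
                f"{fmap.n_fragments} fragments"
            )
        if fc.library_size == 0:
            raise ValueError(f"sample {fc.sample_id!r} has zero total counts")
    r = np.log2(
        normalize_frequencies(fusion.counts, pseudocount)
        / normalize_frequencies(control.counts, pseudocount)
    )
    if center:
        internal = fmap.internal
        med = np.median(r[internal]) if internal.any() else np.median(r)
        r = r - med
    return OccupancyTrack(
        values=r,
        pseudocount=pseudocount,
        fusion_id=fusion.sample_id,
        control_id=control.sample_id,
    )


# ---------------------------------------------------------------------------
# Serialization


def write_bedgraph(track: OccupancyTrack, fmap: GATCFragmentMap, path) -> None:
    """Write the track as 4-column bedGraph, one line per fragment."""
    chroms = fmap.chrom_of()
    with open(path, "w") as fh:
        for i in range(fmap.n_fragments):
            fh.write(
                f"{chroms[i]}\t{fmap.starts[i]}\t{fmap.ends[i]}"
                f"\t{track.values[i]:.6f}\n"
            )


def read_bedgraph(path, fmap: GATCFragmentMap, fusion_id="fusion", control_id="control",
                  pseudocount: float = 0.5) -> OccupancyTrack:
    """Read a bedGraph written by :func:`write_bedgraph`; coordinates must
    match the fragment map line-for-line."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    if len(df) != fmap.n_fragments:
        raise ValueError(
            f"{path}: {len(df)} rows for {fmap.n_fragments} fragments"
        )
    if not (
        np.array_equal(df["start"].to_numpy(), fmap.starts)
        and np.array_equal(df["end"].to_numpy(), fmap.ends)
    ):
        raise ValueError(f"{path}: coordinates do not match fragment map")
    return OccupancyTrack(
        values=df["value"].to_numpy(dtype=np.float64),
        pseudocount=pseudocount,
        fusion_id=fusion_id,
        control_id=control_id,
    )


def write_counts(fc: FragmentCounts, path) -> None:
    """Write counts as TSV (fragment_id, count)."""
    with open(path, "w") as fh:
        fh.write(f"# sample={fc.sample_id}\n")
        fh.write("fragment_id\tcount\n")
        for i, c in enumerate(fc.counts):
            fh.write(f"frag{i:07d}\t{c}\n")


def read_counts(path, sample_id: str | None = None) -> FragmentCounts:
    sid = sample_id
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# sample=") and sid is None:
        sid = first.rstrip("\n").split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    return FragmentCounts(sid or "sample", df["count"].to_numpy(dtype=np.int64))
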