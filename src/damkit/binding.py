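"""Binding-peak calling on occupancy tracks and target-gene assignment.

Candidate peaks are maximal runs of at least ``min_run`` consecutive
internal fragments whose occupancy exceeds the track's upper percentile
threshold; a candidate's score is (mean occupancy) x (run length in
fragments).  Significance comes from an empirical null built by permuting
fragment values within each chromosome: FDR(s) is the ratio of the mean
null candidate count at score >= s to the observed count, monotonized to be
non-increasing in s.  A target gene is any gene whose body is overlapped by
a retained peak by >= 1 bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import GATCFragmentMap

PEAK_COLUMNS = ["chrom", "start", "end", "peak_id", "score", "fdr",
                "frag_lo", "frag_hi"]


@dataclass
class TargetGeneSet:
    """Genes overlapped by at least one significant binding peak."""

    tf_name: str
    genes: set[str]
    support: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.tf_name, g, ",".join(self.support.get(g, [])))
            for g in sorted(self.genes)
        ]
        return pd.DataFrame(rows, columns=["tf", "gene_id", "peak_ids"])


def _candidate_runs(above: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_run, as local [lo, hi) pairs."""
    if above.size == 0:
        return []
    padded = np.concatenate(([False], above, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_run]


def _extract_scores(
    values_by_chrom: list[np.ndarray], threshold: float, min_run: int
) -> list[float]:
    scores = []
    for v in values_by_chrom:
        for lo, hi in _candidate_runs(v > threshold, min_run):
            scores.append(float(v[lo:hi].mean() * (hi - lo)))
    return scores


def call_binding_peaks(
    track,
    fmap: GATCFragmentMap,
    fdr_threshold: float = 0.01,
    n_shuffles: int = 100,
    seed: int = 0,
    min_run: int = 2,
    percentile: float = 95.0,
) -> pd.DataFrame:
    """Call peaks with an empirical permutation FDR.

    Returns a DataFrame (chrom, start, end, peak_id, score, fdr, frag_lo,
    frag_hi) of peaks with FDR < ``fdr_threshold``, sorted by position.
    frag_lo/frag_hi are global fragment indices [lo, hi).
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must lie in (0, 1)")
    if n_shuffles < 100:
        warnings.warn(f"n_shuffles={n_shuffles} < 100: FDR estimates unstable")
    rng = np.random.default_rng(seed)

    # internal fragments per chromosome, in map order
    per_chrom: list[tuple[str, np.ndarray, np.ndarray]] = []
    for chrom in fmap.chrom_names:
        lo, hi = fmap.chrom_slice(chrom)
        idx = np.arange(lo, hi)[fmap.internal[lo:hi]]
        per_chrom.append((chrom, idx, track.values[idx]))

    if all(v.size < min_run for _, _, v in per_chrom):
        warnings.warn("no chromosome has enough internal fragments; no peaks")
        return pd.DataFrame(columns=PEAK_COLUMNS)

    all_internal = np.concatenate([v for _, _, v in per_chrom])
    threshold = float(np.percentile(all_internal, percentile))

    # observed candidates
    observed = []  # (chrom, frag_lo, frag_hi, score)
    for chrom, idx, v in per_chrom:
        for lo, hi in _candidate_runs(v > threshold, min_run):
            score = float(v[lo:hi].mean() * (hi - lo))
            observed.append((chrom, int(idx[lo]), int(idx[hi - 1]) + 1, score))
    if not observed:
        return pd.DataFrame(columns=PEAK_COLUMNS)

    # null candidates from within-chromosome permutations
    null_scores: list[float] = []
    for _ in range(n_shuffles):
        shuffled = [rng.permutation(v) for _, _, v in per_chrom]
        null_scores.extend(_extract_scores(shuffled, threshold, min_run))
    null = np.sort(np.asarray(null_scores))

    obs_scores = np.asarray([o[3] for o in observed])
    order = np.argsort(-obs_scores)  # descending score
    fdr = np.empty(obs_scores.size)
    for rank, i in enumerate(order, start=1):
        s = obs_scores[i]
        mean_null_ge = (null.size - np.searchsorted(null, s, side="left")) / n_shuffles
        obs_ge = int((obs_scores >= s).sum())
        fdr[i] = mean_null_ge / obs_ge
    # monotonize: FDR non-increasing in score
    running = 0.0
    for i in order:
        running = max(running, fdr[i])
        fdr[i] = min(running, 1.0)

    rows = []
    for (chrom, flo, fhi, score), q in zip(observed, fdr):
        if q < fdr_threshold:
            rows.append(
                (
                    chrom,
                    int(fmap.starts[flo]),
                    int(fmap.ends[fhi - 1]),
                    "",
                    score,
                    float(q),
                    flo,
                    fhi,
                )
            )
    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    peaks = peaks.sort_values(["chrom", "start"], ignore_index=True)
    peaks["peak_id"] = [f"peak{i:05d}" for i in range(len(peaks))]
    return peaks


def assign_peak_targets(
    peaks: pd.DataFrame, genes: pd.DataFrame, tf_name: str
) -> TargetGeneSet:
    """Genes whose span is overlapped (>= 1 bp, half-open) by any peak."""
    support: dict[str, list[str]] = {}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in peaks.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        by_chrom[chrom] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["peak_id"].to_numpy(),
        )
    for gene in genes.itertuples(index=False):
        entry = by_chrom.get(gene.chrom)
        if entry is None:
            continue
        starts, ends, ids = entry
        # retained peaks never overlap each other, so ends are sorted too
        i0 = np.searchsorted(ends, gene.start, side="right")
        i1 = np.searchsorted(starts, gene.end, side="left")
        if i1 > i0:
            support[gene.gene_id] = list(ids[i0:i1])
    return TargetGeneSet(tf_name=tf_name, genes=set(support), support=support)


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """BED6+1: chrom, start, end, peak_id, score, '.', fdr."""
    with open(path, "w") as fh:
        for p in peaks.itertuples(index=False):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}"
                f"\t{p.score:.4f}\t.\t{p.fdr:.6g}\n"
            )


def read_peaks_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "peak_id", "score", "strand", "fdr"],
    )
    return df.drop(columns=["strand"])
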