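"""Gene-level occupancy scoring, expression calling, and cell-type comparison.

A gene's occupancy ``g`` is the length-weighted mean of the log2 track over
its assigned internal fragments.  Expression is called against a permutation
null: for each gene, random sets of the same number of internal fragments
are drawn genome-wide (without replacement within a draw) and scored
identically; p = (1 + #{null >= g}) / (M + 1), with Benjamini-Hochberg FDR
across genes and the extra requirement g > 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .reference import GATCFragmentMap
from .signal import OccupancyTrack

CALL_COLUMNS = ["gene_id", "n", "g", "p", "q", "expressed"]

SPECIFICITY_CLASSES = (
    "A_specific",
    "B_specific",
    "shared",
    "neither",
    "A_enriched",
    "B_enriched",
    "unscorable",
)


def score_gene_occupancy(
    track: OccupancyTrack,
    fmap: GATCFragmentMap,
    assignments: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Length-weighted mean occupancy per gene.

    Returns a DataFrame (gene_id, n, g) sorted by gene_id; genes absent
    from ``assignments`` (unscorable) simply do not appear.
    """
    lengths = fmap.lengths.astype(np.float64)
    values = track.values
    rows = []
    for gene_id, idx in assignments.items():
        w = lengths[idx]
        rows.append((gene_id, idx.size, float((w * values[idx]).sum() / w.sum())))
    df = pd.DataFrame(rows, columns=["gene_id", "n", "g"])
    return df.sort_values("gene_id", ignore_index=True)


def _null_means(
    vals: np.ndarray,
    lens: np.ndarray,
    n: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """M length-weighted means of n fragments drawn without replacement."""
    pool = vals.size
    out = np.empty(n_permutations)
    for j in range(n_permutations):
        pick = rng.choice(pool, size=n, replace=False)
        w = lens[pick]
        out[j] = (w * vals[pick]).sum() / w.sum()
    return out


def call_expressed_genes(
    scores: pd.DataFrame,
    track: OccupancyTrack,
    fmap: GATCFragmentMap,
    fdr_threshold: float = 0.01,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill p, q and the expressed flag on a (gene_id, n, g) score table.

    Genes sharing a fragment count n share one null sample.  Deterministic
    for a fixed seed.  ``n_permutations`` below 1000 triggers a warning
    (small p-values become unstable).
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must lie in (0, 1)")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if n_permutations < 1000:
        warnings.warn(
            f"n_permutations={n_permutations} < 1000: small p-values unstable"
        )
    internal = np.flatnonzero(fmap.internal)
    vals = track.values[internal]
    lens = fmap.lengths[internal].astype(np.float64)
    rng = np.random.default_rng(seed)

    df = scores.sort_values("gene_id", ignore_index=True).copy()
    p = np.empty(len(df))
    # one null distribution per distinct n, in sorted order for determinism
    for n in sorted(df["n"].unique()):
        null = np.sort(_null_means(vals, lens, int(n), n_permutations, rng))
        sel = df["n"].to_numpy() == n
        g = df.loc[sel, "g"].to_numpy()
        n_ge = n_permutations - np.searchsorted(null, g, side="left")
        p[sel] = (1.0 + n_ge) / (n_permutations + 1.0)
    df["p"] = p
    df["q"] = stats.false_discovery_control(p, method="bh")
    df["expressed"] = (df["q"] < fdr_threshold) & (df["g"] > 0)
    return df


def compare_cell_types(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    fdr_threshold: float = 0.01,
    fold_min: float = 2.0,
) -> pd.DataFrame:
    """Classify genes by where they are expressed.

    Classes: A_specific (q_A < theta, q_B >= theta), B_specific (symmetric),
    shared (both below), neither (both at/above).  Shared genes with fold
    F = 2**(g_A - g_B) >= fold_min are sub-labelled A_enriched (and
    B_enriched for F <= 1/fold_min).  Genes present on one side only are
    "unscorable".  F is reported for every two-sided gene.
    """
    a = records_a[["gene_id", "g", "q"]].rename(columns={"g": "g_A", "q": "q_A"})
    b = records_b[["gene_id", "g", "q"]].rename(columns={"g": "g_B", "q": "q_B"})
    df = a.merge(b, on="gene_id", how="outer").sort_values(
        "gene_id", ignore_index=True
    )
    df["F"] = 2.0 ** (df["g_A"] - df["g_B"])

    cls = np.full(len(df), "unscorable", dtype=object)
    both = df["q_A"].notna() & df["q_B"].notna()
    in_a = df["q_A"] < fdr_threshold
    in_b = df["q_B"] < fdr_threshold
    cls[(both & in_a & ~in_b).to_numpy()] = "A_specific"
    cls[(both & ~in_a & in_b).to_numpy()] = "B_specific"
    shared = both & in_a & in_b
    cls[shared.to_numpy()] = "shared"
    cls[(shared & (df["F"] >= fold_min)).to_numpy()] = "A_enriched"
    cls[(shared & (df["F"] <= 1.0 / fold_min)).to_numpy()] = "B_enriched"
    cls[(both & ~in_a & ~in_b).to_numpy()] = "neither"
    df["class"] = cls
    return df


def rank_correlation(records: pd.DataFrame, external: pd.DataFrame) -> float:
    """Spearman correlation of gene occupancy g against an external
    expression table (columns gene_id, value), mid-ranked ties.

    Raises if fewer than 3 genes are shared.
    """
    merged = records[["gene_id", "g"]].merge(
        external[["gene_id", "value"]], on="gene_id"
    )
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} genes shared with external table (need >= 3)"
        )
    rho, _ = stats.spearmanr(merged["g"], merged["value"])
    return float(rho)


def write_gene_calls(df: pd.DataFrame, path, symbols: pd.DataFrame | None = None) -> None:
    """Write the per-gene call table as TSV, stable-ordered by gene id."""
    out = df.copy()
    if symbols is not None:
        out = out.merge(symbols[["gene_id", "symbol"]], on="gene_id", how="left")
        cols = ["gene_id", "symbol"] + [c for c in out.columns if c not in ("gene_id", "symbol")]
        out = out[cols]
    out.sort_values("gene_id").to_csv(path, sep="\t", index=False, float_format="%.6g")
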