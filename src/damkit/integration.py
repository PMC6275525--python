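"""Set integration and small statistics: Venn regions, TF ranking,
candidate reports, hypergeometric enrichment, and 2x2 chi-square tests."""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def venn_counts(sets: dict[str, set]) -> tuple[dict[tuple[str, ...], int], pd.DataFrame]:
    """Exact membership-region counts for 2-4 named sets, plus ordered
    pairwise overlap fractions.

    Returns (regions, pairwise): ``regions`` maps each non-empty combination
    of set names (as a sorted tuple) to the count of elements belonging to
    exactly those sets; ``pairwise`` has one row per ordered pair (x, y)
    with |x & y|, the fraction |x & y| / |x|, and that fraction as a
    percentage rounded to the nearest integer.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError(f"venn_counts supports 2-4 sets, got {len(names)}")
    universe = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            regions[tuple(sorted(combo))] = 0
    for element in universe:
        membership = tuple(sorted(n for n in names if element in sets[n]))
        regions[membership] += 1

    rows = []
    for x in names:
        for y in names:
            if x == y:
                continue
            inter = len(sets[x] & sets[y])
            if sets[x]:
                frac = inter / len(sets[x])
                pct = _round_half_up(100.0 * frac)
            else:
                frac, pct = float("nan"), float("nan")
            rows.append((x, y, inter, frac, pct))
    pairwise = pd.DataFrame(
        rows, columns=["set_x", "set_y", "intersection", "fraction", "pct"]
    )
    return regions, pairwise


def rank_specific_tfs(
    specificity: pd.DataFrame,
    tf_list: set[str] | list[str],
    fold_min: float = 2.0,
    cls: str = "A_specific",
) -> pd.DataFrame:
    """A-specific TFs with fold >= fold_min, sorted by descending fold
    (ties broken by gene id); fold reported to one decimal."""
    tf_set = set(tf_list)
    if not tf_set:
        raise ValueError("tf list is empty")
    sel = specificity[
        (specificity["class"] == cls)
        & specificity["gene_id"].isin(tf_set)
        & (specificity["F"] >= fold_min)
    ].copy()
    sel = sel.sort_values(["F", "gene_id"], ascending=[False, True], ignore_index=True)
    sel["F_display"] = sel["F"].round(1)
    return sel[["gene_id", "F", "F_display", "class"]]


def candidate_report(
    specificity: pd.DataFrame,
    target_sets: dict[str, "object"],
    curated: list[str],
    cls: str = "A_specific",
) -> tuple[pd.DataFrame, list[str]]:
    """Curated genes that are A-specific and present in *every* target set.

    ``target_sets`` maps TF name -> TargetGeneSet.  Returns (report,
    not_scored): the report has class, fold and per-TF supporting peak ids;
    ``not_scored`` lists curated ids absent from the scored universe.
    """
    if not target_sets:
        raise ValueError("at least one target set is required")
    universe = set(specificity["gene_id"])
    not_scored = sorted(set(curated) - universe)
    by_gene = specificity.set_index("gene_id")
    rows = []
    for gene in sorted(set(curated) & universe):
        if by_gene.loc[gene, "class"] != cls:
            continue
        if not all(gene in ts.genes for ts in target_sets.values()):
            continue
        row = {
            "gene_id": gene,
            "class": by_gene.loc[gene, "class"],
            "F": by_gene.loc[gene, "F"],
        }
        for tf, ts in target_sets.items():
            row[f"peaks_{tf}"] = ",".join(ts.support.get(gene, []))
        rows.append(row)
    cols = ["gene_id", "class", "F"] + [f"peaks_{tf}" for tf in target_sets]
    report = pd.DataFrame(rows, columns=cols)
    return report, not_scored


def enrichment_test(
    query: set[str],
    universe: set[str],
    terms: dict[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a query set in each term.

    Terms are intersected with the universe first; terms with zero universe
    members are skipped with a warning.  Returns a DataFrame (term, k, K,
    n, N, p, q) with Benjamini-Hochberg q across tested terms, sorted by p.
    """
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for term, members in terms.items():
        K = len(members & universe)
        if K == 0:
            warnings.warn(f"term {term!r} has no members in the universe; skipped")
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    else:
        df["q"] = pd.Series(dtype=float)
    return df.sort_values(["p", "term"], ignore_index=True)


def contingency_chisq(
    table, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table (df = 1).

    Yates continuity correction is applied when requested.  Raises on a
    zero marginal (the statistic is undefined).
    """
    obs = np.asarray(table, dtype=np.float64)
    if obs.shape != (2, 2):
        raise ValueError("contingency table must be 2x2")
    if (obs < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if total < 1 or (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal: chi-square statistic undefined")
    expected = np.outer(row, col) / total
    dev = np.abs(obs - expected)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def write_venn(regions: dict, pairwise: pd.DataFrame, tsv_path, text_path=None) -> None:
    """Write Venn regions + pairwise overlaps as TSV, optionally a text digest."""
    with open(tsv_path, "w") as fh:
        fh.write("region\tcount\n")
        for combo in sorted(regions, key=lambda c: (len(c), c)):
            fh.write("&".join(combo) + f"\t{regions[combo]}\n")
        fh.write("\n")
        pairwise.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write("Membership regions (exclusive counts)\n")
            for combo in sorted(regions, key=lambda c: (len(c), c)):
                fh.write(f"  {' & '.join(combo):<40s} {regions[combo]}\n")
            fh.write("\nOrdered pairwise overlap\n")
            for r in pairwise.itertuples(index=False):
                fh.write(
                    f"  {r.set_x} with {r.set_y}: {r.intersection} ({r.pct}%)\n"
                )
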