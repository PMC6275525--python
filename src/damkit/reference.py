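"""Genome ingestion, GATC fragment maps, and gene-model handling.

DamID signal has a native resolution of one GATC restriction fragment: the
interval between two adjacent DpnI cleavage points (GA^TC, i.e. motif start
+ 2).  This module builds that coordinate backbone from a genome, loads gene
models from GFF3, and assigns fragments to gene bodies by >= 1 bp overlap.

All internal coordinates are 0-based half-open.  GFF3 (1-based closed) is
converted on read; BED is native.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MOTIF = "GATC"
CUT_OFFSET = 2  # DpnI cleaves GA^TC
_DNA_ALPHABET = frozenset("ACGTN")

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand"]


class GenomeError(ValueError):
    """Raised for sequences containing non-DNA characters."""


def validate_sequence(name: str, seq: str) -> str:
    """Upper-case a sequence and reject characters outside {A,C,G,T,N}."""
    seq = seq.upper()
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise GenomeError(
            f"sequence {name!r} contains non-DNA characters: {sorted(bad)}"
        )
    return seq


def load_genome(path) -> dict[str, str]:
    """Read a (multi-record, possibly line-wrapped) FASTA into a dict.

    Returns an insertion-ordered mapping of chromosome id -> upper-case
    residues, validated against the DNA alphabet.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    return {name: validate_sequence(name, str(fa[name][:])) for name in fa.keys()}


@dataclass
class GATCFragmentMap:
    """Ordered GATC fragments tiling each chromosome exactly.

    Fragments are stored in flat arrays ordered by chromosome (insertion
    order) then position; ``_slices`` maps a chromosome to its [lo, hi)
    range of global fragment indices.  ``terminal`` flags the fragments
    touching a chromosome end; a motif-free chromosome is one terminal
    fragment spanning its whole length.
    """

    chrom_names: list[str]
    chrom_sizes: dict[str, int]
    starts: np.ndarray
    ends: np.ndarray
    terminal: np.ndarray
    _slices: dict[str, tuple[int, int]] = field(repr=False)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_sequences(cls, genomes: Mapping[str, str]) -> "GATCFragmentMap":
        """Scan forward-strand GATC occurrences (the motif is palindromic)
        and cut at motif start + 2."""
        if not genomes:
            raise ValueError("empty genome")
        names, sizes, slices = [], {}, {}
        starts, ends, terminal = [], [], []
        offset = 0
        for name, seq in genomes.items():
            seq = validate_sequence(name, seq)
            length = len(seq)
            cuts = [m.start() + CUT_OFFSET for m in re.finditer(MOTIF, seq)]
            bounds = [0, *cuts, length]
            n = len(bounds) - 1
            for i in range(n):
                starts.append(bounds[i])
                ends.append(bounds[i + 1])
                terminal.append(i == 0 or i == n - 1)
            names.append(name)
            sizes[name] = length
            slices[name] = (offset, offset + n)
            offset += n
        return cls(
            chrom_names=names,
            chrom_sizes=sizes,
            starts=np.asarray(starts, dtype=np.int64),
            ends=np.asarray(ends, dtype=np.int64),
            terminal=np.asarray(terminal, dtype=bool),
            _slices=slices,
        )

    @classmethod
    def from_fasta(cls, path) -> "GATCFragmentMap":
        return cls.from_sequences(load_genome(path))

    # -- basic accessors --------------------------------------------------

    @property
    def n_fragments(self) -> int:
        return self.starts.size

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def internal(self) -> np.ndarray:
        """Boolean mask of non-terminal fragments."""
        return ~self.terminal

    def chrom_slice(self, chrom: str) -> tuple[int, int]:
        return self._slices[chrom]

    def chrom_of(self) -> np.ndarray:
        """Per-fragment chromosome name array (object dtype)."""
        out = np.empty(self.n_fragments, dtype=object)
        for name, (lo, hi) in self._slices.items():
            out[lo:hi] = name
        return out

    # -- queries ----------------------------------------------------------

    def locate(self, chrom: str, positions) -> np.ndarray:
        """Global fragment index containing each position; -1 if the
        position is outside [0, chrom length) or the chromosome is unknown."""
        positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        if chrom not in self._slices:
            return np.full(positions.shape, -1, dtype=np.int64)
        lo, hi = self._slices[chrom]
        local = np.searchsorted(self.starts[lo:hi], positions, side="right") - 1
        valid = (positions >= 0) & (positions < self.chrom_sizes[chrom])
        return np.where(valid, lo + local, -1)

    def overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of fragments overlapping [start, end) by >= 1 bp."""
        if chrom not in self._slices or end <= start:
            return np.empty(0, dtype=np.int64)
        lo, hi = self._slices[chrom]
        i0 = np.searchsorted(self.ends[lo:hi], start, side="right")
        i1 = np.searchsorted(self.starts[lo:hi], end, side="left")
        return np.arange(lo + i0, lo + i1, dtype=np.int64)

    # -- serialization ----------------------------------------------------

    def to_bed(self, path) -> None:
        """Write BED4: chrom, start, end, name=frag<idx>_<T|I>."""
        chroms = self.chrom_of()
        with open(path, "w") as fh:
            for i in range(self.n_fragments):
                flag = "T" if self.terminal[i] else "I"
                fh.write(
                    f"{chroms[i]}\t{self.starts[i]}\t{self.ends[i]}"
                    f"\tfrag{i:07d}_{flag}\n"
                )

    @classmethod
    def from_bed(cls, path) -> "GATCFragmentMap":
        """Rebuild a map written by :meth:`to_bed` (fragments must tile
        each chromosome; chromosome size is the last fragment end)."""
        names, sizes, slices = [], {}, {}
        starts, ends, terminal = [], [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, s, e, name = line.rstrip("\n").split("\t")[:4]
                if chrom not in sizes:
                    names.append(chrom)
                    sizes[chrom] = 0
                    slices[chrom] = [len(starts), len(starts)]
                starts.append(int(s))
                ends.append(int(e))
                terminal.append(name.endswith("_T"))
                sizes[chrom] = int(e)
                slices[chrom][1] = len(starts)
        return cls(
            chrom_names=names,
            chrom_sizes=sizes,
            starts=np.asarray(starts, dtype=np.int64),
            ends=np.asarray(ends, dtype=np.int64),
            terminal=np.asarray(terminal, dtype=bool),
            _slices={k: tuple(v) for k, v in slices.items()},
        )


# ---------------------------------------------------------------------------
# Gene models


def _parse_gff_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def load_gene_models(path, chrom_sizes: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Load gene spans from GFF3 into a gene table.

    ``gene`` features define records (1-based closed coordinates converted
    to 0-based half-open); ``mRNA`` features extend their parent gene's span
    to the union over transcripts.  Malformed records (end < start) and
    records on chromosomes absent from ``chrom_sizes`` (when given) are
    skipped with a warning.

    Returns a DataFrame with columns gene_id, symbol, chrom, start, end,
    strand, sorted by gene_id.
    """
    genes: dict[str, dict] = {}
    transcripts: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                warnings.warn(f"{path}:{lineno}: short GFF3 record skipped")
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, raw = fields[:9]
            if ftype not in ("gene", "mRNA"):
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                warnings.warn(
                    f"{path}:{lineno}: end < start ({end_i} < {start_i}), record skipped"
                )
                continue
            if chrom_sizes is not None and chrom not in chrom_sizes:
                warnings.warn(
                    f"{path}:{lineno}: unknown chromosome {chrom!r}, record skipped"
                )
                continue
            attrs = _parse_gff_attributes(raw)
            if ftype == "gene":
                gid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
                if gid is None:
                    warnings.warn(f"{path}:{lineno}: gene without ID skipped")
                    continue
                span = (start_i - 1, end_i)
                if gid in genes:  # multiple gene lines: union
                    rec = genes[gid]
                    rec["start"] = min(rec["start"], span[0])
                    rec["end"] = max(rec["end"], span[1])
                else:
                    genes[gid] = {
                        "gene_id": gid,
                        "symbol": attrs.get("Name", gid),
                        "chrom": chrom,
                        "start": span[0],
                        "end": span[1],
                        "strand": strand if strand in "+-" else ".",
                    }
            else:  # mRNA
                parent = attrs.get("Parent")
                if parent:
                    transcripts.append((parent, start_i - 1, end_i))
    for parent, t_start, t_end in transcripts:
        rec = genes.get(parent)
        if rec is None:
            continue
        rec["start"] = min(rec["start"], t_start)
        rec["end"] = max(rec["end"], t_end)
    df = pd.DataFrame(list(genes.values()), columns=GENE_COLUMNS)
    return df.sort_values("gene_id", ignore_index=True)


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Check the gene-table invariants: unique ids, start < end."""
    if genes["gene_id"].duplicated().any():
        dupes = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    bad = genes["start"] >= genes["end"]
    if bad.any():
        raise ValueError(f"{int(bad.sum())} genes with start >= end")
    return genes


def assign_fragments_to_genes(
    fmap: GATCFragmentMap,
    genes: pd.DataFrame,
    include_terminal: bool = False,
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Map each gene to the fragments overlapping its span by >= 1 bp.

    Terminal fragments are excluded unless ``include_terminal``; a fragment
    may belong to several genes; assignment ignores strand.  Returns
    (assignments, unscorable) where ``unscorable`` lists genes with zero
    assigned fragments (including genes on chromosomes absent from the map).
    """
    assignments: dict[str, np.ndarray] = {}
    unscorable: list[str] = []
    for row in genes.itertuples(index=False):
        idx = fmap.overlapping(row.chrom, int(row.start), int(row.end))
        if not include_terminal and idx.size:
            idx = idx[~fmap.terminal[idx]]
        if idx.size:
            assignments[row.gene_id] = idx
        else:
            unscorable.append(row.gene_id)
    return assignments, unscorable
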