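"""Stage-wise expression quantification of candidate genes.

Reads are counted against candidate gene sequences with a naive exact/near
matcher (both strands, best match wins, multi-gene ties discarded as
ambiguous) and normalized to RPKM — reads per kilobase of gene length per
million mapped library reads, the denominator following the mapped-read
convention. Stage summaries report the extreme stages and fold ranges that
characterize stage-structured expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from Bio.Seq import Seq

from xenoscan.io_core import SequenceRecord, logger

__all__ = ["ExpressionTable", "naive_map_counts", "rpkm_table", "stage_summary"]


@dataclass
class ExpressionTable:
    """Gene x stage counts and RPKM with the library sizes that produced them."""

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    library_sizes: pd.Series
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.rpkm.to_numpy() < 0).any():
            raise ValueError("rpkm must be non-negative")
        zero_mismatch = (self.rpkm.to_numpy() == 0) != (self.counts.to_numpy() == 0)
        if zero_mismatch.any():
            raise ValueError("rpkm must be zero exactly where counts are zero")


def _min_mismatches(read: str, gene: str, max_mismatch: int) -> int | None:
    """Fewest mismatches of read against any same-length window of gene."""
    if len(read) > len(gene):
        return None
    if max_mismatch == 0:
        return 0 if read in gene else None
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    g = np.frombuffer(gene.encode(), dtype=np.uint8)
    n_win = len(g) - len(r) + 1
    windows = np.lib.stride_tricks.sliding_window_view(g, len(r))[:n_win]
    mism = (windows != r).sum(axis=1)
    best = int(mism.min())
    return best if best <= max_mismatch else None


def naive_map_counts(
    reads: Sequence[SequenceRecord],
    gene_seqs: Sequence[SequenceRecord],
    max_mismatch: int = 0,
) -> tuple[pd.Series, int]:
    """Count reads per gene by naive substring matching on both strands.

    A read counts for a gene when it matches some window of the gene or its
    reverse complement with at most ``max_mismatch`` mismatches; a read
    matching several genes goes to the best (fewest mismatches) and is
    discarded as ambiguous on a tie. Returns (per-gene counts, ambiguous
    read count).
    """
    if not gene_seqs:
        raise ValueError("empty gene set")
    counts = {g.id: 0 for g in gene_seqs}
    ambiguous = 0

    if max_mismatch == 0:
        # Exact matching: index every read-length window of every gene
        # (both strands) once, then count by dictionary lookup.
        read_lengths = {len(r.residues) for r in reads}
        index: dict[int, dict[str, set[str]]] = {}
        for L in read_lengths:
            idx: dict[str, set[str]] = {}
            for g in gene_seqs:
                for strand_seq in (g.residues, str(Seq(g.residues).reverse_complement())):
                    for i in range(len(strand_seq) - L + 1):
                        idx.setdefault(strand_seq[i : i + L], set()).add(g.id)
            index[L] = idx
        for read in reads:
            genes = index[len(read.residues)].get(read.residues)
            if not genes:
                continue
            if len(genes) == 1:
                counts[next(iter(genes))] += 1
            else:
                ambiguous += 1
    else:
        targets = {
            g.id: (g.residues, str(Seq(g.residues).reverse_complement())) for g in gene_seqs
        }
        for read in reads:
            best_genes: list[str] = []
            best_m: int | None = None
            for gid, (fwd, rev) in targets.items():
                ms = [
                    m
                    for m in (
                        _min_mismatches(read.residues, fwd, max_mismatch),
                        _min_mismatches(read.residues, rev, max_mismatch),
                    )
                    if m is not None
                ]
                if not ms:
                    continue
                m = min(ms)
                if best_m is None or m < best_m:
                    best_m, best_genes = m, [gid]
                elif m == best_m:
                    best_genes.append(gid)
            if len(best_genes) == 1:
                counts[best_genes[0]] += 1
            elif len(best_genes) > 1:
                ambiguous += 1
    if ambiguous:
        logger.info("naive_map_counts: %d ambiguous multi-gene reads discarded", ambiguous)
    return pd.Series(counts, name="count"), ambiguous


def rpkm_table(
    counts: pd.DataFrame | Mapping[str, Mapping[str, int]],
    gene_lengths: Mapping[str, int] | pd.Series,
    library_sizes: Mapping[str, int] | pd.Series,
) -> ExpressionTable:
    """RPKM = 1e9 * count / (gene length in nt * library size in reads).

    ``counts`` is genes x stages; ``library_sizes`` gives the mapped-read
    total per stage. Lengths and library sizes must be positive.
    """
    counts = pd.DataFrame(counts)
    lengths = pd.Series(gene_lengths, dtype=float).reindex(counts.index)
    libs = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("every stage needs a positive library size")
    rpkm = 1e9 * counts.div(lengths, axis=0).div(libs, axis=1)
    return ExpressionTable(
        counts=counts, rpkm=rpkm, library_sizes=libs, gene_lengths=lengths
    )


def stage_summary(table: ExpressionTable) -> pd.DataFrame:
    """Per-gene extreme stages and fold range of the RPKM profile.

    Reports argmin/argmax stages (ties broken by stage order), the max/min
    fold ratio (infinite-flag when the minimum stage is zero), and log10
    values for plotting.
    """
    rpkm = table.rpkm
    if rpkm.shape[1] < 2:
        raise ValueError("stage summary needs at least 2 stages")
    rows = []
    for gene, prof in rpkm.iterrows():
        vals = prof.to_numpy(dtype=float)
        i_min, i_max = int(vals.argmin()), int(vals.argmax())
        infinite = vals[i_min] == 0 and vals[i_max] > 0
        fold = np.inf if infinite else (vals[i_max] / vals[i_min] if vals[i_min] > 0 else 1.0)
        rows.append(
            {
                "gene": gene,
                "min_stage": rpkm.columns[i_min],
                "max_stage": rpkm.columns[i_max],
                "fold": fold,
                "infinite_fold": infinite,
                **{f"log10_{s}": (np.log10(v) if v > 0 else -np.inf) for s, v in prof.items()},
            }
        )
    return pd.DataFrame(rows).set_index("gene")
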