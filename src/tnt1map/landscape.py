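"""Insertion-landscape statistics.

Turns called insertion sites into the downstream summaries used to describe
a Tnt1 mutant population: per-chromosome distribution tables, per-gene
insertion tallies with frequency classes, selection of frequently inserted
genes, fixed-width genomic bins with GC content, and per-synteny-block
tallies.

Counting is FST-level by default (each mapped read counts once, matching
how the population tables are reported); a line-deduplicated view can be
produced upstream with :func:`tnt1map.mapper.deduplicate_sites`.  All
printed percents are round-half-up at the precision of the table they
appear in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io import GeneModel, ReferenceGenome
from .mapper import InsertionSite
from .rounding import percent_of, round_half_up

logger = logging.getLogger("tnt1map")


# ---------------------------------------------------------------------------
# per-gene tallies

@dataclass
class GeneTally:
    gene_id: str
    insertion_count: int
    fst_ids: list[str] = field(default_factory=list)


def assign_to_genes(
    sites: Sequence[InsertionSite], genes: Sequence[GeneModel]
) -> tuple[list[GeneTally], list[str]]:
    """Assign each site to every gene whose span contains it (inclusive ends).

    Overlapping genes each receive the insertion.  Returns (tallies for genes
    with >= 1 insertion, ids of genes with none).
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree is half-open; +1 makes the gene end inclusive
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    hits: dict[str, list[str]] = {g.gene_id: [] for g in genes}
    n_overlap_assignments = 0
    for s in sites:
        tree = trees.get(s.chrom)
        if tree is None:
            continue
        overlapping = tree[s.position]
        if len(overlapping) > 1:
            n_overlap_assignments += 1
        for iv in overlapping:
            hits[iv.data].append(s.fst_id)
    if n_overlap_assignments:
        logger.info(
            "assign_to_genes: %d sites fell in overlapping genes (counted in each)",
            n_overlap_assignments,
        )
    tallies = [
        GeneTally(gene_id=g.gene_id, insertion_count=len(hits[g.gene_id]), fst_ids=hits[g.gene_id])
        for g in genes
        if hits[g.gene_id]
    ]
    zero_genes = [g.gene_id for g in genes if not hits[g.gene_id]]
    return tallies, zero_genes


# ---------------------------------------------------------------------------
# per-chromosome distribution table

def chromosome_table(
    chrom_counts: Mapping[str, int],
    n_highconf_total: int,
    anchored: Sequence[str],
) -> pd.DataFrame:
    """Per-chromosome FST distribution with percents of the high-confidence
    total, plus total/unanchored/mean summary rows.

    ``anchored`` lists the chromosome-length scaffolds in display order;
    counts on any other sequence are pooled as unanchored.  Percents are
    count / n_highconf_total * 100, round-half-up to 2 decimals; the
    per-chromosome mean is rounded half-up to an integer.
    """
    if n_highconf_total <= 0:
        raise ValueError("n_highconf_total must be > 0")
    anchored = list(anchored)
    unknown = [c for c in chrom_counts if c not in anchored]
    if unknown:
        logger.warning(
            "chromosome_table: %d sequences treated as unanchored: %s",
            len(unknown),
            unknown[:5],
        )
    rows = []
    for chrom in anchored:
        n = int(chrom_counts.get(chrom, 0))
        rows.append(
            {
                "category": f"FSTs mapped to {chrom}",
                "fst_count": n,
                "percent_of_total": percent_of(n, n_highconf_total, 2),
            }
        )
    total_anchored = sum(int(chrom_counts.get(c, 0)) for c in anchored)
    total_unanchored = sum(int(chrom_counts[c]) for c in unknown)
    rows.append(
        {
            "category": f"Total mapped to {len(anchored)} chromosomes",
            "fst_count": total_anchored,
            "percent_of_total": percent_of(total_anchored, n_highconf_total, 2),
        }
    )
    rows.append(
        {
            "category": "Total mapped to unanchored scaffolds",
            "fst_count": total_unanchored,
            "percent_of_total": percent_of(total_unanchored, n_highconf_total, 2),
        }
    )
    rows.append(
        {
            "category": "Mean per chromosome",
            "fst_count": int(round_half_up(total_anchored / len(anchored), 0)),
            "percent_of_total": float("nan"),
        }
    )
    return pd.DataFrame(rows)


def sites_to_chrom_counts(sites: Sequence[InsertionSite]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in sites:
        counts[s.chrom] = counts.get(s.chrom, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# frequency classes

@dataclass
class FrequencyClassSummary:
    """How often genes are hit: counts at >=1, >1 and >=4 insertions.

    Two means are reported because the natural denominator is ambiguous:
    per gene *with* an insertion, and per annotated gene.
    """

    n_annotated_genes: int
    n_genes_ge1: int
    n_genes_gt1: int
    n_genes_ge4: int
    total_genic_insertions: int
    mean_per_inserted_gene: float
    mean_per_annotated_gene: float

    def percent(self, which: str, decimals: int = 1) -> float:
        counts = {"ge1": self.n_genes_ge1, "gt1": self.n_genes_gt1, "ge4": self.n_genes_ge4}
        return percent_of(counts[which], self.n_annotated_genes, decimals)


def frequency_classes(
    tallies: Sequence[GeneTally], n_annotated_genes: int
) -> FrequencyClassSummary:
    if n_annotated_genes < len(tallies):
        raise ValueError("more tallied genes than annotated genes")
    counts = [t.insertion_count for t in tallies]
    total = sum(counts)
    ge1 = sum(1 for c in counts if c >= 1)
    return FrequencyClassSummary(
        n_annotated_genes=n_annotated_genes,
        n_genes_ge1=ge1,
        n_genes_gt1=sum(1 for c in counts if c > 1),
        n_genes_ge4=sum(1 for c in counts if c >= 4),
        total_genic_insertions=total,
        mean_per_inserted_gene=total / ge1 if ge1 else 0.0,
        mean_per_annotated_gene=total / n_annotated_genes if n_annotated_genes else 0.0,
    )


def select_frequent_genes(
    tallies: Sequence[GeneTally], mean_threshold: float | None = None
) -> list[GeneTally]:
    """Genes hit strictly more often than the mean insertion number,
    sorted by count descending then gene id."""
    if mean_threshold is None:
        summary = frequency_classes(tallies, n_annotated_genes=len(tallies))
        mean_threshold = summary.mean_per_inserted_gene
    if mean_threshold < 0:
        raise ValueError("mean_threshold must be >= 0")
    selected = [t for t in tallies if t.insertion_count > mean_threshold]
    selected.sort(key=lambda t: (-t.insertion_count, t.gene_id))
    return selected


# ---------------------------------------------------------------------------
# fixed-width bins

@dataclass
class GenomicBin:
    chrom: str
    bin_start: int  # 1-based inclusive
    bin_end: int  # 1-based inclusive
    insertion_count: int
    gc_fraction: float
    all_n: bool = False


def bin_landscape(
    sites: Sequence[InsertionSite],
    genome: ReferenceGenome,
    bin_width: int = 500_000,
) -> list[GenomicBin]:
    """Tile each chromosome with fixed-width bins (terminal bin truncated),
    count contained sites, and compute the N-excluded GC fraction per bin."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    site_bins: dict[tuple[str, int], int] = {}
    for s in sites:
        site_bins[(s.chrom, (s.position - 1) // bin_width)] = (
            site_bins.get((s.chrom, (s.position - 1) // bin_width), 0) + 1
        )
    bins: list[GenomicBin] = []
    for chrom, seq in genome.sequences.items():
        length = len(seq)
        for b in range((length + bin_width - 1) // bin_width):
            start = b * bin_width + 1
            end = min((b + 1) * bin_width, length)
            window = seq[start - 1 : end]
            gc = window.count("G") + window.count("C")
            at = window.count("A") + window.count("T")
            all_n = (gc + at) == 0
            bins.append(
                GenomicBin(
                    chrom=chrom,
                    bin_start=start,
                    bin_end=end,
                    insertion_count=site_bins.get((chrom, b), 0),
                    gc_fraction=0.0 if all_n else gc / (gc + at),
                    all_n=all_n,
                )
            )
    return bins


def bins_to_dataframe(bins: Sequence[GenomicBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "bin_start": b.bin_start,
                "bin_end": b.bin_end,
                "insertion_count": b.insertion_count,
                "gc_fraction": round(b.gc_fraction, 6),
                "all_n": b.all_n,
            }
            for b in bins
        ]
    )


def plot_landscape(bins: Sequence[GenomicBin], path: str) -> None:
    """Per-chromosome tracks of binned insertion density and GC fraction."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({b.chrom for b in bins})
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 1.8 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        cb = [b for b in bins if b.chrom == chrom]
        mids = [(b.bin_start + b.bin_end) / 2 / 1e6 for b in cb]
        ax.bar(mids, [b.insertion_count for b in cb], width=0.45, color="#4878a8")
        ax2 = ax.twinx()
        ax2.plot(mids, [b.gc_fraction * 100 for b in cb], color="#b0413e", lw=1)
        ax2.set_ylabel("GC %", fontsize=7)
        ax.set_ylabel(f"{chrom}\ninsertions", fontsize=7)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# synteny blocks

def synteny_tally(
    tallies: Sequence[GeneTally],
    blocks: Mapping[str, Sequence[str]],
    annotated_gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per collinear block: member genes, members with >= 1 insertion, and
    summed insertions; sorted by genes-with-insertions descending.

    A gene listed in several blocks counts in each (logged).  Members that
    do not resolve against the annotation are logged and kept in n_genes.
    """
    if not blocks:
        raise ValueError("empty synteny block table")
    by_gene = {t.gene_id: t.insertion_count for t in tallies}
    known = set(annotated_gene_ids) if annotated_gene_ids is not None else None
    membership: dict[str, int] = {}
    n_unresolved = 0
    rows = []
    for block_id, members in blocks.items():
        genes_with = 0
        total = 0
        for g in members:
            membership[g] = membership.get(g, 0) + 1
            if known is not None and g not in known:
                n_unresolved += 1
            c = by_gene.get(g, 0)
            if c:
                genes_with += 1
                total += c
        rows.append(
            {
                "block_id": block_id,
                "n_genes": len(members),
                "genes_with_insertions": genes_with,
                "total_insertions": total,
            }
        )
    n_multi = sum(1 for c in membership.values() if c > 1)
    if n_multi:
        logger.info("synteny_tally: %d genes occur in more than one block", n_multi)
    if n_unresolved:
        logger.warning("synteny_tally: %d block members missing from the annotation", n_unresolved)
    df = pd.DataFrame(rows).sort_values(
        ["genes_with_insertions", "block_id"], ascending=[False, True]
    )
    return df.reset_index(drop=True)


def gene_tallies_to_dataframe(tallies: Sequence[GeneTally]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": t.gene_id,
                "insertion_count": t.insertion_count,
                "fst_ids": ",".join(t.fst_ids),
            }
            for t in tallies
        ]
    )
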