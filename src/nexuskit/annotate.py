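"""Gene-relative annotation of peaks and gene-level binding multiplicity.

A peak overlapping a gene body by >= 1 bp is ``within_gene``; otherwise, if
its nearest gene edge lies within the flank (5 kb default, boundary
inclusive) it is ``upstream_5kb`` or ``downstream_5kb`` resolved by the
gene's strand; anything farther is ``intergenic``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .config import PipelineConfig
from .intervals import GenomicInterval
from .peaks import Peak

CATEGORIES = ("within_gene", "upstream_5kb", "downstream_5kb", "intergenic")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    interval: GenomicInterval
    strand: str


def read_gene_models(path) -> List[GeneModel]:
    """Gene models from 6-column BED (chrom, start, end, gene_id, score,
    strand) or from GTF/GFF ``gene`` features."""
    path = str(path)
    if path.endswith((".gtf", ".gff", ".gff3")):
        return _read_gtf_genes(path)
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id", "score",
                            "strand"],
                     dtype={"chrom": str, "gene_id": str})
    return [GeneModel(r["gene_id"], r["chrom"],
                      GenomicInterval(r["chrom"], int(r["start"]),
                                      int(r["end"])), r["strand"])
            for _, r in df.iterrows()]


def _read_gtf_genes(path) -> List[GeneModel]:
    import gffutils
    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True, disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        genes.append(GeneModel(gid, feat.seqid,
                               GenomicInterval(feat.seqid, feat.start - 1,
                                               feat.end), feat.strand))
    return genes


def _gene_trees(genes: List[GeneModel]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g)
    return trees


def annotate_peaks(peaks: List[Peak], genes: List[GeneModel],
                   config: PipelineConfig) -> pd.DataFrame:
    """Assign each peak a gene-relative category and gene.

    Overlapping two genes -> the gene with the larger overlap, ties to the
    smaller gene_id.  Non-overlapping peaks within ``flank`` of a gene edge
    (inclusive) are upstream/downstream by gene strand; ties across genes
    go to the smallest distance then smallest gene_id.  Peaks on
    chromosomes absent from the gene models are marked
    ``intergenic-unplaced``.
    """
    trees = _gene_trees(genes)
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for pk in peaks:
        row = {"chrom": pk.chrom, "start": pk.start, "end": pk.end,
               "name": pk.name, "summit": pk.summit,
               "category": "intergenic", "gene_id": ".", "distance": -1}
        if pk.chrom not in trees:
            row["category"] = ("intergenic-unplaced"
                               if pk.chrom not in by_chrom else "intergenic")
            rows.append(row)
            continue
        hits = trees[pk.chrom].overlap(pk.start, pk.end)
        if hits:
            # larger overlap wins; ties go to the smaller gene_id
            best = min(
                hits, key=lambda iv: (
                    -iv.data.interval.intersection_length(pk.interval),
                    iv.data.gene_id))
            row["category"] = "within_gene"
            row["gene_id"] = best.data.gene_id
            row["distance"] = 0
            rows.append(row)
            continue
        # nearest gene edge among non-overlapping genes
        best_gene, best_dist = None, None
        for g in by_chrom[pk.chrom]:
            if pk.end <= g.interval.start:
                dist = g.interval.start - pk.end
                side = "left"
            elif g.interval.end <= pk.start:
                dist = pk.start - g.interval.end
                side = "right"
            else:               # safety: tree should have caught overlaps
                dist, side = 0, "left"
            key = (dist, g.gene_id)
            if best_dist is None or key < best_dist:
                best_dist, best_gene = key, (g, side)
        if best_gene is not None and best_dist[0] <= config.flank:
            g, side = best_gene
            # peak left of a + gene (or right of a - gene) is upstream
            upstream = (side == "left") == (g.strand == "+")
            row["category"] = "upstream_5kb" if upstream else "downstream_5kb"
            row["gene_id"] = g.gene_id
            row["distance"] = best_dist[0]
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "summit", "category", "gene_id",
                                       "distance"])


def category_counts(annotated: pd.DataFrame) -> pd.Series:
    counts = annotated["category"].value_counts()
    return counts.reindex(CATEGORIES, fill_value=0)


def genes_with_peaks(annotated: pd.DataFrame
                     ) -> Tuple[pd.Series, Tuple[int, int]]:
    """Per-gene peak counts over gene-linked categories and the
    (single-peak genes, multi-peak genes) summary."""
    linked = annotated[annotated["category"].isin(
        ("within_gene", "upstream_5kb", "downstream_5kb"))]
    per_gene = linked.groupby("gene_id").size().sort_index()
    single = int((per_gene == 1).sum())
    multiple = int((per_gene >= 2).sum())
    return per_gene, (single, multiple)
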