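"""TSS classification against a gene annotation.

Each TSS is assigned exactly one of four categories:

* ``InterS`` — intergenic, downstream gene in the same orientation;
* ``InterA`` — intergenic, downstream gene in the opposite orientation;
* ``IntraS`` — inside a gene of the same orientation;
* ``IntraA`` — inside a gene of the opposite orientation.

Distances follow the published convention: from the TSS to the gene's
translation start for InterS/IntraS/IntraA, and from the TSS to the gene's
stop (3' end) for InterA. The primary TSS of a gene is its InterS TSS with
the most reads; the 5' UTR runs from the primary TSS to the start codon.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import Annotation, Gene, OperonTable
from .tss_calling import Tss

TSS_CLASSES = ("InterS", "IntraS", "InterA", "IntraA")


@dataclass
class ClassifiedTss:
    tss: Tss
    tss_class: str
    gene_id: str
    gene_start: int | None
    distance: int | None
    product: str = ""
    is_primary_global: bool = False
    primary_conditions: set[str] = field(default_factory=set)


@dataclass
class UtrRecord:
    gene_id: str
    primary_tss_position: int
    utr_length: int
    leaderless: bool


class _GeneIndex:
    """Containment and nearest-downstream lookups over an annotation."""

    def __init__(self, annotation: Annotation):
        self.annotation = annotation
        self.tree = IntervalTree()
        for g in annotation.genes:
            # interval tree uses half-open [start, end+1)
            self.tree[g.start:g.end + 1] = g
        self.starts = np.array([g.start for g in annotation.genes])
        self.ends_sorted_idx = np.argsort([g.end for g in annotation.genes],
                                          kind="stable")
        self.ends_sorted = np.array(
            [annotation.genes[i].end for i in self.ends_sorted_idx])

    def containing(self, pos: int) -> list[Gene]:
        return [iv.data for iv in self.tree[pos]]

    def next_downstream(self, strand: str, pos: int) -> tuple[Gene | None, int | None]:
        """Nearest gene in transcription direction from an intergenic position.

        Returns the gene and the wrap-aware distance from ``pos`` to the
        gene's nearest boundary in the travel direction.
        """
        genes = self.annotation.genes
        L = self.annotation.genome_length
        circular = self.annotation.circular
        if not genes:
            return None, None
        if strand == "+":
            i = int(np.searchsorted(self.starts, pos, side="left"))
            if i < len(genes):
                g = genes[i]
                return g, g.start - pos
            if circular:
                g = genes[0]
                return g, g.start + L - pos
            return None, None
        # minus strand: travel toward decreasing coordinates; nearest gene
        # whose right end is < pos
        i = int(np.searchsorted(self.ends_sorted, pos, side="left")) - 1
        if i >= 0:
            g = genes[self.ends_sorted_idx[i]]
            return g, pos - g.end
        if circular:
            g = genes[self.ends_sorted_idx[-1]]
            return g, pos + L - g.end
        return None, None


def _circular_distance(a: int, b: int, length: int, circular: bool) -> int:
    d = abs(a - b)
    if circular:
        d = min(d, length - d)
    return d


def classify_tss(tss_list: list[Tss], annotation: Annotation) -> list[ClassifiedTss]:
    """Assign each TSS its category, gene, and signed-convention distance.

    A TSS inside at least one gene is intragenic: a same-strand containing
    gene is preferred (IntraS beats IntraA when genes overlap); among several
    containing genes on the chosen strand, the one whose transcription start
    is nearest upstream of the TSS wins. Intergenic TSS are assigned the
    nearest gene in the TSS's transcription direction (wrapping on circular
    genomes) and classified InterS/InterA by that gene's strand.
    """
    if not annotation.genes:
        raise ValueError("annotation is empty")
    index = _GeneIndex(annotation)
    L = annotation.genome_length
    out: list[ClassifiedTss] = []
    for tss in tss_list:
        if not (1 <= tss.position <= L):
            raise ValueError(f"TSS position {tss.position} outside genome [1, {L}]")
        hits = index.containing(tss.position)
        if hits:
            same = [g for g in hits if g.strand == tss.strand]
            pool = same if same else hits
            # nearest-upstream transcription start: smallest distance from
            # gene tx_start forward to the TSS along the gene's direction
            def upstream_dist(g: Gene) -> int:
                return (tss.position - g.start if g.strand == "+"
                        else g.end - tss.position)
            gene = min(pool, key=lambda g: (upstream_dist(g), g.gene_id))
            cls = "IntraS" if gene.strand == tss.strand else "IntraA"
            dist = _circular_distance(tss.position, gene.tx_start, L,
                                      annotation.circular)
        else:
            gene, travel = index.next_downstream(tss.strand, tss.position)
            if gene is None:
                out.append(ClassifiedTss(tss=tss, tss_class="InterS",
                                         gene_id="none", gene_start=None,
                                         distance=None))
                continue
            cls = "InterS" if gene.strand == tss.strand else "InterA"
            anchor = gene.tx_start if cls == "InterS" else gene.tx_stop
            dist = _circular_distance(tss.position, anchor, L, annotation.circular)
        out.append(ClassifiedTss(tss=tss, tss_class=cls, gene_id=gene.gene_id,
                                 gene_start=gene.tx_start, distance=dist,
                                 product=gene.product))
    return out


def assign_primary(classified: list[ClassifiedTss], mode: str = "global"
                   ) -> list[ClassifiedTss]:
    """Flag each gene's primary TSS: the InterS TSS with the most reads.

    ``global`` mode ranks InterS TSS of a gene by mean RPM summed over all
    conditions and sets ``is_primary_global`` on the winner. ``per_condition``
    mode ranks, per condition, among TSS detected in that condition and
    records winners in ``primary_conditions``. Ties break toward the TSS
    nearer the translation start.
    """
    if mode not in ("global", "per_condition"):
        raise ValueError(f"unknown mode {mode!r}")
    by_gene: dict[str, list[ClassifiedTss]] = defaultdict(list)
    for c in classified:
        if c.tss_class == "InterS" and c.gene_id != "none":
            by_gene[c.gene_id].append(c)
    if mode == "global":
        for c in classified:
            c.is_primary_global = False
        for gene_id, group in by_gene.items():
            winner = min(group, key=lambda c: (-c.tss.total_mean_rpm(),
                                               c.distance, c.tss.position))
            winner.is_primary_global = True
    else:
        conditions: set[str] = set()
        for c in classified:
            c.primary_conditions = set()
            conditions |= set(c.tss.mean_rpm_by_condition)
        for gene_id, group in by_gene.items():
            for cond in sorted(conditions):
                detected = [c for c in group if cond in c.tss.detected_conditions]
                if not detected:
                    continue
                winner = min(detected,
                             key=lambda c: (-c.tss.mean_rpm_by_condition.get(cond, 0.0),
                                            c.distance, c.tss.position))
                winner.primary_conditions.add(cond)
    return classified


def utr_lengths(classified: list[ClassifiedTss], leaderless_cutoff: int = 10,
                bin_width: int = 20) -> tuple[list[UtrRecord], pd.DataFrame]:
    """Per-gene 5' UTR lengths from global primary TSS, plus a binned summary.

    The UTR length is the primary InterS TSS's distance to the start codon.
    A transcript is flagged leaderless when that length is below
    ``leaderless_cutoff`` (too short to hold a ribosome binding site).
    Also returns a histogram of UTR lengths in ``bin_width`` bp bins with the
    mean TSS strength (total mean RPM) per bin.
    """
    pairs = []
    for c in classified:
        if c.is_primary_global and c.distance is not None:
            rec = UtrRecord(
                gene_id=c.gene_id, primary_tss_position=c.tss.position,
                utr_length=c.distance,
                leaderless=c.distance < leaderless_cutoff)
            pairs.append((rec, c.tss.total_mean_rpm()))
    pairs.sort(key=lambda p: p[0].gene_id)
    records = [p[0] for p in pairs]
    strengths = [p[1] for p in pairs]
    if records:
        lengths = np.array([r.utr_length for r in records])
        strengths = np.array(strengths)
        bins = lengths // bin_width
        rows = []
        for b in sorted(set(bins.tolist())):
            mask = bins == b
            rows.append({
                "bin_start": int(b) * bin_width,
                "bin_end": (int(b) + 1) * bin_width,
                "n_genes": int(mask.sum()),
                "mean_tss_strength": float(strengths[mask].mean()),
            })
        hist = pd.DataFrame(rows)
    else:
        hist = pd.DataFrame(columns=["bin_start", "bin_end", "n_genes",
                                     "mean_tss_strength"])
    return records, hist


def operon_start_fraction(classified: list[ClassifiedTss],
                          operon_table: OperonTable,
                          singletons_count_as_start: bool = False
                          ) -> tuple[int, int, float]:
    """Fraction of InterS-covered genes that begin a predicted operon.

    Counts distinct genes with at least one InterS TSS; of those, genes that
    are the first member of an operon in its transcription direction. Genes
    absent from the operon table count as operon starts only when
    ``singletons_count_as_start`` is set (a gene not in any predicted operon
    is its own single-gene transcription unit under that reading).
    """
    genes_with_inters = {c.gene_id for c in classified
                         if c.tss_class == "InterS" and c.gene_id != "none"}
    starts = operon_table.start_genes()
    members = operon_table.member_genes()
    n_start = 0
    for g in genes_with_inters:
        if g in starts:
            n_start += 1
        elif g not in members and singletons_count_as_start:
            n_start += 1
    n = len(genes_with_inters)
    return n, n_start, (n_start / n if n else float("nan"))


def class_counts(classified: list[ClassifiedTss]) -> dict[str, int]:
    counts = {k: 0 for k in TSS_CLASSES}
    for c in classified:
        counts[c.tss_class] += 1
    return counts
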