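import numpy as np
import pytest

from cappswitch.genome_io import Annotation, Gene, StartCountTrack
from cappswitch.tss_calling import Tss


@pytest.fixture
def toy_annotation():
    """Three genes on a 10 kb linear-friendly toy chromosome."""
    return Annotation(
        genes=[
            Gene("gA", "+", 1000, 2000, "alpha"),
            Gene("gB", "-", 3000, 4000, "beta"),
            Gene("gC", "+", 6000, 7000, "gamma"),
        ],
        genome_length=10_000,
        circular=True,
    )


@pytest.fixture
def track_factory():
    def make(counts, library_size=1_000_000, label="c/r", genome_length=None):
        return StartCountTrack(counts=dict(counts), library_size=library_size,
                               label=label, genome_length=genome_length)
    return make


@pytest.fixture
def tss_factory():
    def make(strand, position, rpm_by_condition, detected=None):
        detected = (set(rpm_by_condition) if detected is None else set(detected))
        return Tss(strand=strand, position=position,
                   mean_rpm_by_condition=dict(rpm_by_condition),
                   detected_conditions=detected)
    return make


def random_track(rng, n_positions=200, span=5000, max_count=50,
                 library_size=1_000_000):
    """A random strand-specific read-start track for oracle comparisons."""
    counts = {}
    for _ in range(n_positions):
        strand = "+" if rng.random() < 0.5 else "-"
        pos = int(rng.integers(1, span + 1))
        counts[(strand, pos)] = counts.get((strand, pos), 0) + int(
            rng.integers(1, max_count))
    return StartCountTrack(counts=counts, library_size=library_size,
                           label="rand", genome_length=span)


def oracle_cluster(counts, window):
    """Independent brute-force of greedy window clustering: rescan the whole
    unassigned set for the maximum at every step."""
    half = (window - 1) // 2
    out = []
    for strand in "+-":
        items = {p: c for (s, p), c in counts.items() if s == strand and c > 0}
        unassigned = set(items)
        while unassigned:
            if strand == "+":
                peak = min(unassigned, key=lambda p: (-items[p], p))
            else:
                peak = min(unassigned, key=lambda p: (-items[p], -p))
            members = sorted(p for p in unassigned if abs(p - peak) <= half)
            unassigned -= set(members)
            out.append((strand, peak, tuple(members),
                        sum(items[p] for p in members)))
    return sorted(out)


def mirror_annotation(annotation: Annotation) -> Annotation:
    """Reverse-complement an annotation: coordinates flip around the genome."""
    L = annotation.genome_length
    genes = [Gene(g.gene_id, "-" if g.strand == "+" else "+",
                  L - g.end + 1, L - g.start + 1, g.product)
             for g in annotation.genes]
    return Annotation(genes=genes, genome_length=L, circular=annotation.circular)


def mirror_tss(t: Tss, genome_length: int) -> Tss:
    return Tss(strand="-" if t.strand == "+" else "+",
               position=genome_length - t.position + 1,
               mean_rpm_by_condition=dict(t.mean_rpm_by_condition),
               detected_conditions=set(t.detected_conditions),
               pooled_count=t.pooled_count)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
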