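"""Window-clustering TSS calling from strand-specific read-start tracks.

The calling model: read 5' ends pile up within a few bases of the true
initiation site, so per-strand counts are clustered within a short sliding
window (default 5 bp) and each cluster is represented by the position with
the most reads. A position becomes a called TSS for a condition only when
both (all) replicate cultures show a cluster there exceeding the expression
threshold (default >10 read starts per million mapped reads), which controls
for spurious single-library pileups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import StartCountTrack


@dataclass
class CandidateCluster:
    """A read-start cluster: peak position plus absorbed neighbours."""

    strand: str
    peak_position: int
    member_positions: list[int]
    cluster_count: float
    peak_count: float
    rpm: float


@dataclass
class Tss:
    """A called transcription start site with per-condition expression."""

    strand: str
    position: int
    rpm_by_condition_replicate: dict[tuple[str, str], float] = field(default_factory=dict)
    mean_rpm_by_condition: dict[str, float] = field(default_factory=dict)
    detected_conditions: set[str] = field(default_factory=set)
    pooled_count: float = 0.0

    @property
    def key(self) -> tuple[str, int]:
        return (self.strand, self.position)

    def total_mean_rpm(self) -> float:
        return sum(self.mean_rpm_by_condition.values())


def normalize_rpm(track: StartCountTrack) -> StartCountTrack:
    """Scale every count to read starts per million mapped reads (RPM)."""
    if track.library_size <= 0:
        raise ValueError(f"track {track.label!r}: library_size must be > 0")
    factor = 1e6 / track.library_size
    return StartCountTrack(
        counts={k: c * factor for k, c in track.counts.items()},
        library_size=track.library_size,
        label=track.label,
        genome_length=track.genome_length,
    )


def _tie_sort_key(strand: str):
    """Greedy selection order: count desc, then 5'-most in transcription
    direction (smaller coordinate on +, larger on -)."""
    if strand == "+":
        return lambda item: (-item[1], item[0])
    return lambda item: (-item[1], -item[0])


def cluster_read_starts(track: StartCountTrack, window: int = 5) -> list[CandidateCluster]:
    """Greedy peak-seeded clustering of read starts within a sliding window.

    Repeatedly selects the unassigned position with the highest count (ties
    broken 5'-most in transcription direction), absorbs all unassigned
    positions within +/-(window-1)//2 of it, and records the summed count at
    the peak. Every counted position ends up in exactly one cluster.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = (window - 1) // 2
    clusters: list[CandidateCluster] = []
    for strand in ("+", "-"):
        items = [(p, c) for (s, p), c in track.counts.items() if s == strand and c > 0]
        items.sort(key=_tie_sort_key(strand))
        count_at = dict(items)
        assigned: set[int] = set()
        for pos, cnt in items:
            if pos in assigned:
                continue
            members = [q for q in range(pos - half, pos + half + 1)
                       if q in count_at and q not in assigned]
            assigned.update(members)
            total = sum(count_at[q] for q in members)
            clusters.append(CandidateCluster(
                strand=strand, peak_position=pos,
                member_positions=sorted(members),
                cluster_count=total, peak_count=cnt,
                rpm=total * 1e6 / track.library_size))
    clusters.sort(key=lambda c: (c.strand, c.peak_position))
    return clusters


def call_tss(replicate_tracks: list[StartCountTrack], condition: str,
             threshold_rpm: float = 10.0, window: int = 5,
             match_window: int = 5, count_mode: str = "cluster_sum",
             replicate_names: list[str] | None = None) -> list[Tss]:
    """Call TSS for one condition from raw replicate read-start tracks.

    A TSS is emitted where every replicate has a cluster whose peak lies
    within +/-(match_window-1)//2 of the others and whose RPM is strictly
    greater than ``threshold_rpm``. The reported position is the peak of
    the replicate-pooled count profile within the matched window.

    ``count_mode`` selects what the threshold applies to: ``"cluster_sum"``
    (the summed count of the whole cluster, the default) or ``"peak_only"``
    (the peak position's own count).
    """
    if len(replicate_tracks) < 2:
        raise ValueError("call_tss requires at least two replicate tracks")
    if count_mode not in ("cluster_sum", "peak_only"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    lengths = {t.genome_length for t in replicate_tracks if t.genome_length}
    if len(lengths) > 1:
        raise ValueError(f"replicate tracks disagree on genome length: {lengths}")
    if replicate_names is None:
        replicate_names = [f"rep{i + 1}" for i in range(len(replicate_tracks))]
    half = (match_window - 1) // 2

    per_rep_clusters = [cluster_read_starts(t, window=window) for t in replicate_tracks]

    def rpm_of(cl: CandidateCluster, track: StartCountTrack) -> float:
        count = cl.cluster_count if count_mode == "cluster_sum" else cl.peak_count
        return count * 1e6 / track.library_size

    # index clusters of replicates 2..n by peak position for window lookup
    lookup = []
    for clusters in per_rep_clusters[1:]:
        lookup.append({(c.strand, c.peak_position): c for c in clusters})

    pooled: dict[tuple[str, int], float] = {}
    for t in replicate_tracks:
        for k, c in t.counts.items():
            pooled[k] = pooled.get(k, 0) + c

    called: list[Tss] = []
    used: list[set[tuple[str, int]]] = [set() for _ in lookup]
    # seed from replicate-1 clusters in descending strength for deterministic,
    # strongest-first matching
    seeds = sorted(per_rep_clusters[0],
                   key=lambda c: (-c.cluster_count, c.strand, c.peak_position))
    for seed in seeds:
        track0 = replicate_tracks[0]
        if rpm_of(seed, track0) <= threshold_rpm:
            continue
        partners = []
        ok = True
        for ri, table in enumerate(lookup):
            best = None
            for off in sorted(range(-half, half + 1), key=abs):
                cand = table.get((seed.strand, seed.peak_position + off))
                if cand is None or (cand.strand, cand.peak_position) in used[ri]:
                    continue
                if rpm_of(cand, replicate_tracks[ri + 1]) > threshold_rpm:
                    best = cand
                    break
            if best is None:
                ok = False
                break
            partners.append(best)
        if not ok:
            continue
        for ri, cand in enumerate(partners):
            used[ri].add((cand.strand, cand.peak_position))
        peaks = [seed.peak_position] + [c.peak_position for c in partners]
        lo, hi = min(peaks) - half, max(peaks) + half
        region = [(q, pooled.get((seed.strand, q), 0.0)) for q in range(lo, hi + 1)]
        region = [(q, c) for q, c in region if c > 0]
        region.sort(key=_tie_sort_key(seed.strand))
        position = region[0][0] if region else seed.peak_position
        pooled_count = sum(c for _, c in region)
        rpms = {}
        all_clusters = [seed] + partners
        for name, cl, tr in zip(replicate_names, all_clusters, replicate_tracks):
            rpms[(condition, name)] = rpm_of(cl, tr)
        mean_rpm = sum(rpms.values()) / len(rpms)
        called.append(Tss(
            strand=seed.strand, position=position,
            rpm_by_condition_replicate=rpms,
            mean_rpm_by_condition={condition: mean_rpm},
            detected_conditions={condition},
            pooled_count=pooled_count))
    called.sort(key=lambda t: (t.strand, t.position))
    return called


def merge_tss_across_conditions(per_condition_tss: dict[str, list[Tss]],
                                merge_window: int = 5) -> list[Tss]:
    """Merge per-condition TSS lists into one cross-condition TSS set.

    TSS on the same strand whose positions lie within +/-(merge_window-1)//2
    are merged; the representative position is the member position with the
    greatest pooled read support, detected conditions are unioned, and
    per-condition expression is carried over (0 where a condition did not
    call the site).
    """
    half = (merge_window - 1) // 2
    all_tss: list[Tss] = [t for lst in per_condition_tss.values() for t in lst]
    # strongest-first greedy merge for determinism
    all_tss.sort(key=lambda t: (-t.pooled_count, -t.total_mean_rpm(),
                                t.strand, t.position))
    index: dict[tuple[str, int], Tss] = {}
    merged: list[Tss] = []
    for t in all_tss:
        target = None
        for off in sorted(range(-half, half + 1), key=lambda x: (abs(x), x)):
            target = index.get((t.strand, t.position + off))
            if target is not None:
                break
        if target is None:
            rep = Tss(strand=t.strand, position=t.position,
                      rpm_by_condition_replicate=dict(t.rpm_by_condition_replicate),
                      mean_rpm_by_condition=dict(t.mean_rpm_by_condition),
                      detected_conditions=set(t.detected_conditions),
                      pooled_count=t.pooled_count)
            merged.append(rep)
            index[(t.strand, t.position)] = rep
        else:
            target.rpm_by_condition_replicate.update(t.rpm_by_condition_replicate)
            for cond, rpm in t.mean_rpm_by_condition.items():
                target.mean_rpm_by_condition[cond] = max(
                    target.mean_rpm_by_condition.get(cond, 0.0), rpm)
            target.detected_conditions |= t.detected_conditions
            target.pooled_count += t.pooled_count
    conditions = list(per_condition_tss)
    for t in merged:
        for cond in conditions:
            t.mean_rpm_by_condition.setdefault(cond, 0.0)
    merged.sort(key=lambda t: (t.strand, t.position))
    return merged


def attach_subthreshold_rpm(merged_tss: list[Tss],
                            tracks_by_condition: dict[str, list[StartCountTrack]],
                            window: int = 5) -> list[Tss]:
    """Record sub-threshold expression at merged TSS positions.

    A TSS called on one substrate often has real but sub-threshold signal on
    others; fold-change and clustering analyses need those low values rather
    than zeros. For every condition in which a TSS was NOT detected, the mean
    replicate RPM summed over the TSS's +/-(window-1)//2 neighbourhood is
    written into ``mean_rpm_by_condition`` (detected conditions keep their
    called values)."""
    half = (window - 1) // 2
    for t in merged_tss:
        for cond, reps in tracks_by_condition.items():
            if cond in t.detected_conditions or not reps:
                continue
            rpms = []
            for tr in reps:
                count = sum(tr.counts.get((t.strand, t.position + off), 0)
                            for off in range(-half, half + 1))
                rpms.append(count * 1e6 / tr.library_size)
            t.mean_rpm_by_condition[cond] = sum(rpms) / len(rpms)
    return merged_tss
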