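"""Promoter window extraction and position-weight-matrix operator scanning.

Window offsets are expressed in the anchored feature's transcription
direction: negative offsets are upstream of the anchor, 0 is the anchor base
itself. "5-20 bp upstream" therefore means offsets -20..-5, a 16 bp window.
On the minus strand the mirror-image genomic interval is taken and
reverse-complemented, so every returned sequence reads 5'->3' along the
transcript.

Scanning is log-odds against a mononucleotide background:
score = sum over columns of log2(p_col(base) / background(base)); a hit is
any offset scoring at least ``threshold_fraction`` of the maximal attainable
score. This replaces an external motif-search engine for regulon
enumeration; it does not compute E-values.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .genome_io import reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class WindowSpec:
    """Anchored sequence window in transcription-direction coordinates."""

    anchor: str  # "tss" or "start_codon"
    from_offset: int
    to_offset: int
    name: str = ""

    def __post_init__(self):
        if self.anchor not in ("tss", "start_codon"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.from_offset > self.to_offset:
            raise ValueError("from_offset must be <= to_offset")

    @property
    def length(self) -> int:
        return self.to_offset - self.from_offset + 1


# the fixed windows used for promoter-element and operator searches
MINUS35_WINDOW = WindowSpec("tss", -50, -25, "minus35")
MINUS10_WINDOW = WindowSpec("tss", -20, -5, "minus10")
TSS_MOTIF_WINDOW = WindowSpec("tss", -100, 10, "tss_context")
START_CODON_WINDOW = WindowSpec("start_codon", -250, 50, "start_context")


@dataclass
class SeqWindow:
    feature_id: str
    window_name: str
    strand: str
    genomic_start: int  # 1-based inclusive, leftmost
    genomic_end: int
    sequence: str


def extract_windows(features: list[tuple[str, str, int]], genome: str,
                    spec: WindowSpec, circular: bool = True
                    ) -> list[SeqWindow]:
    """Extract the spec's window around each ``(feature_id, strand, anchor_pos)``.

    For a plus-strand anchor at p the genomic interval is
    [p+from_offset, p+to_offset] read forward; for a minus-strand anchor it
    is [p-to_offset, p-from_offset] reverse-complemented. On a linear genome
    windows are clipped at the ends and fully off-genome windows are skipped;
    on a circular genome they wrap.
    """
    L = len(genome)
    out: list[SeqWindow] = []
    for fid, strand, pos in features:
        if strand == "+":
            lo, hi = pos + spec.from_offset, pos + spec.to_offset
        else:
            lo, hi = pos - spec.to_offset, pos - spec.from_offset
        if circular:
            seq = "".join(genome[(i - 1) % L] for i in range(lo, hi + 1))
            glo, ghi = ((lo - 1) % L) + 1, ((hi - 1) % L) + 1
        else:
            clo, chi = max(lo, 1), min(hi, L)
            if clo > chi:
                continue  # entirely off the genome
            seq = genome[clo - 1:chi]
            glo, ghi = clo, chi
        if strand == "-":
            seq = reverse_complement(seq)
        out.append(SeqWindow(feature_id=fid, window_name=spec.name,
                             strand=strand, genomic_start=glo,
                             genomic_end=ghi, sequence=seq))
    return out


@dataclass
class Pwm:
    """Position weight matrix (rows A,C,G,T) with background frequencies."""

    probabilities: np.ndarray  # (4, W), columns sum to 1
    background: np.ndarray     # (4,)
    pseudocount: float

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A,C,G,T)")
        if not np.allclose(self.probabilities.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if (self.probabilities <= 0).any() and self.pseudocount > 0:
            raise ValueError("PWM probabilities must be > 0 after pseudocount")

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probabilities / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def score(self, seq: str) -> float:
        if len(seq) != self.width:
            raise ValueError("sequence length must equal PWM width")
        lo = self.log_odds
        return float(sum(lo[_BASE_INDEX[b], j] for j, b in enumerate(seq)))


def genome_background(genome: str) -> np.ndarray:
    """Mononucleotide frequencies of the genome (N excluded)."""
    counts = Counter(b for b in genome if b in _BASE_INDEX)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("genome contains no A/C/G/T bases")
    return np.array([counts[b] / total for b in BASES])


def build_pwm(aligned_sites: list[str], background=None,
              pseudocount: float = 0.25) -> Pwm:
    """Build a PWM from equal-length aligned binding sites.

    Column probabilities are (count + pseudocount) / (n + 4*pseudocount).
    The background defaults to uniform; pass genome mononucleotide
    frequencies for genome-aware log-odds.
    """
    if len(aligned_sites) < 2:
        raise ValueError("need at least 2 aligned sites")
    sites = [s.upper() for s in aligned_sites]
    width = len(sites[0])
    for s in sites:
        if len(s) != width:
            raise ValueError("aligned sites must have equal length")
        if set(s) - set(BASES):
            raise ValueError(f"non-ACGT character in site {s!r}")
    n = len(sites)
    counts = np.zeros((4, width))
    for s in sites:
        for j, b in enumerate(s):
            counts[_BASE_INDEX[b], j] += 1
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    if background is None:
        background = np.full(4, 0.25)
    return Pwm(probabilities=probs, background=np.asarray(background, float),
               pseudocount=pseudocount)


@dataclass
class PwmHit:
    position: int  # 1-based position of the matched window's leftmost base
    strand: str
    score: float
    offset: int | None = None  # offset of the match start in the scanned window
    feature_id: str | None = None


def scan_sequence(seq: str, pwm: Pwm, score_threshold_fraction: float = 0.8,
                  both_strands: bool = True, origin: int = 1) -> list[PwmHit]:
    """Exhaustively score every offset of ``seq`` against the PWM.

    ``origin`` is the 1-based genomic coordinate of ``seq``'s first base, so
    hit positions are genomic. Minus-strand hits are reported at the leftmost
    forward-strand coordinate of the matched window.
    """
    if not (0 < score_threshold_fraction <= 1):
        raise ValueError("score_threshold_fraction must be in (0, 1]")
    W = pwm.width
    threshold = score_threshold_fraction * pwm.max_score()
    hits: list[PwmHit] = []
    seq = seq.upper()
    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", reverse_complement(seq)))
    n = len(seq)
    for strand, s in strands:
        if n < W:
            continue
        for i in range(n - W + 1):
            window = s[i:i + W]
            if set(window) - set(BASES):
                continue
            score = pwm.score(window)
            if score >= threshold:
                left = i if strand == "+" else n - W - i
                hits.append(PwmHit(position=origin + left, strand=strand,
                                   score=score, offset=left))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_gene_windows(windows: list[SeqWindow], pwm: Pwm, window_spec: WindowSpec,
                      score_threshold_fraction: float = 0.8,
                      both_strands: bool = True) -> list[PwmHit]:
    """Scan extracted per-gene windows; hit offsets are reported relative to
    the window's anchor (e.g. distance from the translation start)."""
    hits: list[PwmHit] = []
    for w in windows:
        for h in scan_sequence(w.sequence, pwm,
                               score_threshold_fraction=score_threshold_fraction,
                               both_strands=both_strands, origin=1):
            h.feature_id = w.feature_id
            h.offset = window_spec.from_offset + (h.position - 1)
            hits.append(h)
    hits.sort(key=lambda h: (h.feature_id or "", h.offset or 0, h.strand))
    return hits
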