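"""Binding-site annotation of regulatory regions.

Predicts transcription-factor binding sites (TFBSs) by scanning regulatory
sequences with positional weight matrices (PWMs), thresholds each PWM at
mean + 3 s.d. of its exact k-mer score distribution, and partitions a region
into model sites (inside accessible chromatin), non-model sites, and
non-functional sequence (accessible / non-accessible, coding excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PWM",
    "RegulatoryRegion",
    "BindingSite",
    "RegionPartition",
    "pwm_score",
    "pwm_threshold",
    "scan_sites",
    "partition_regions",
    "revcomp",
]

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Per-position nucleotide log-odds matrix (natural log) for one TF.

    ``logodds`` has shape (k, 4) with columns ordered A, C, G, T;
    ``background`` is the genomic nucleotide distribution the odds are
    taken against.
    """

    tf_name: str
    logodds: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        lo = np.asarray(self.logodds, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if lo.ndim != 2 or lo.shape[1] != 4 or lo.shape[0] < 1:
            raise ValueError("logodds must be a k x 4 matrix with k >= 1")
        if not np.all(np.isfinite(lo)):
            raise ValueError("logodds entries must be finite")
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 positive entries summing to 1")
        object.__setattr__(self, "logodds", lo)
        object.__setattr__(self, "background", bg)

    @property
    def k(self) -> int:
        return self.logodds.shape[0]

    @property
    def max_score(self) -> float:
        """Best achievable score: sum of per-column maxima."""
        return float(self.logodds.max(axis=1).sum())

    @classmethod
    def from_counts(cls, tf_name, counts, background=None, pseudocount=0.5):
        """Build from a count matrix with a pseudocount.

        Log-odds are ln(freq / background) with
        freq = (count + pseudocount) / (total + 4*pseudocount).
        """
        counts = np.asarray(counts, dtype=float)
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        freqs = counts + pseudocount
        freqs /= freqs.sum(axis=1, keepdims=True)
        return cls(tf_name, np.log(freqs / background), background)

    def score(self, window: str, strand: str = "+") -> float:
        """PWM score P_s of a k-mer; '-' scores the reverse complement."""
        return pwm_score(window, self, strand)

    def threshold(self, background_weighted: bool = False) -> float:
        """mean + 3 s.d. of the exact k-mer score distribution."""
        return pwm_threshold(self, background_weighted=background_weighted)


def pwm_score(window: str, pwm: PWM, strand: str = "+") -> float:
    """Sum of log-odds entries of the (strand-oriented) window nucleotides.

    Raises on length mismatch or any character outside A/C/G/T (N included:
    callers are expected to skip N-containing windows).
    """
    if len(window) != pwm.k:
        raise ValueError(
            f"window length {len(window)} != PWM length {pwm.k}"
        )
    if strand == "-":
        window = revcomp(window)
    elif strand != "+":
        raise ValueError(f"invalid strand {strand!r}")
    try:
        idx = [_INDEX[c] for c in window.upper()]
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in window") from None
    return float(pwm.logodds[np.arange(pwm.k), idx].sum())


def pwm_threshold(pwm: PWM, background_weighted: bool = False) -> float:
    """Score threshold: mean + 3 s.d. over all 4^k k-mers.

    Positions are independent, so the full-enumeration mean and variance
    equal sums of per-column moments; k-mers are equally weighted unless
    ``background_weighted`` draws nucleotides from the PWM background.
    """
    w = pwm.background if background_weighted else np.full(4, 0.25)
    col_mean = pwm.logodds @ w
    col_var = (pwm.logodds**2) @ w - col_mean**2
    return float(col_mean.sum() + 3.0 * np.sqrt(col_var.sum()))


def _as_intervals(intervals):
    out = []
    for s, e in intervals:
        s, e = int(s), int(e)
        if e <= s:
            raise ValueError(f"degenerate interval [{s}, {e})")
        out.append((s, e))
    return sorted(out)


@dataclass
class RegulatoryRegion:
    """A gene's regulatory sequence with accessibility and CDS annotation.

    Coordinates are 0-based half-open relative to the region start;
    ``genome_offset`` records the 1-based genomic start used in file I/O.
    """

    gene: str
    sequence: str
    genome_offset: int = 1
    accessible: list = field(default_factory=list)
    cds: list = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"invalid characters in sequence: {bad}")
        self.accessible = _as_intervals(self.accessible)
        self.cds = _as_intervals(self.cds)
        n = len(self.sequence)
        for name, ivs in (("accessible", self.accessible), ("cds", self.cds)):
            for s, e in ivs:
                if s < 0 or e > n:
                    raise ValueError(
                        f"{name} interval [{s}, {e}) outside region of length {n}"
                    )

    def __len__(self):
        return len(self.sequence)

    def with_sequence(self, sequence: str) -> "RegulatoryRegion":
        return RegulatoryRegion(
            self.gene, sequence, self.genome_offset,
            list(self.accessible), list(self.cds),
        )


@dataclass(frozen=True)
class BindingSite:
    """A located, scored, TF-labeled interval on a regulatory region."""

    tf_name: str
    gene: str
    start: int
    end: int
    strand: str
    score: float
    is_model: bool

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("site interval must be non-degenerate")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "BindingSite") -> bool:
        return self.start < other.end and other.start < self.end

    def gap_to(self, other: "BindingSite") -> int:
        """Gap in bp between two site intervals; 0 when they touch/overlap."""
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


def _contained(start, end, intervals):
    return any(s <= start and end <= e for s, e in intervals)


def _midpoint_in(start, end, intervals):
    mid = (start + end) // 2
    return any(s <= mid < e for s, e in intervals)


def scan_sites(region, pwms, thresholds, accessibility_rule="containment"):
    """Scan both strands of a region with each PWM; keep windows >= threshold.

    Sites may overlap each other and sites of other TFs.  A site is flagged
    ``is_model`` when its interval lies in accessible chromatin under the
    chosen rule ('containment': fully contained in one accessible interval;
    'midpoint': midpoint inside one).  Duplicate same-TF same-interval hits
    on both strands keep the higher-scoring strand.  Windows containing N
    are skipped (count logged).
    """
    if accessibility_rule == "containment":
        in_access = lambda s, e: _contained(s, e, region.accessible)
    elif accessibility_rule == "midpoint":
        in_access = lambda s, e: _midpoint_in(s, e, region.accessible)
    else:
        raise ValueError(f"unknown accessibility rule {accessibility_rule!r}")

    seq = region.sequence
    sites = []
    n_skipped = 0
    for tf, pwm in pwms.items():
        thr = thresholds[tf]
        k = pwm.k
        if k > len(seq):
            if len(seq) == 0:
                continue
            raise ValueError(
                f"PWM {tf} (length {k}) longer than region {region.gene}"
            )
        for start in range(len(seq) - k + 1):
            window = seq[start : start + k]
            if "N" in window:
                n_skipped += 1
                continue
            best = None
            for strand in "+-":
                s = pwm_score(window, pwm, strand)
                if s >= thr and (best is None or s > best[1]):
                    best = (strand, s)
            if best is not None:
                strand, s = best
                sites.append(
                    BindingSite(
                        tf_name=tf, gene=region.gene, start=start,
                        end=start + k, strand=strand, score=s,
                        is_model=in_access(start, start + k),
                    )
                )
    if n_skipped:
        logger.info(
            "scan_sites(%s): skipped %d windows containing N",
            region.gene, n_skipped,
        )
    sites.sort(key=lambda s: (s.start, s.end, s.tf_name))
    return sites


def rescore_sites(sites, region, pwms):
    """Re-score existing sites against a (possibly mutated) region sequence.

    Site inventory is kept fixed: no sites are created or removed, only P_s
    is recomputed, so mutations cannot create novel TFBSs.
    """
    seq = region.sequence
    out = []
    for s in sites:
        window = seq[s.start : s.end]
        out.append(replace(s, score=pwm_score(window, pwms[s.tf_name], s.strand)))
    return out


def _gc_fraction(sequence, positions):
    if not positions:
        return 0.0
    sub = [sequence[p] for p in positions]
    return sum(c in "GC" for c in sub) / len(sub)


@dataclass
class RegionPartition:
    """Disjoint position classes of a regulatory region, with GC content."""

    model_bp: frozenset
    nonmodel_bp: frozenset
    nonfunctional_accessible_bp: frozenset
    nonfunctional_nonaccessible_bp: frozenset
    cds_bp: frozenset
    gc_content: dict

    @property
    def classes(self):
        return {
            "model": self.model_bp,
            "nonmodel": self.nonmodel_bp,
            "nonfunctional_accessible": self.nonfunctional_accessible_bp,
            "nonfunctional_nonaccessible": self.nonfunctional_nonaccessible_bp,
        }


def partition_regions(region, sites):
    """Partition region positions into model / non-model / non-functional.

    Model class: union of model-site positions.  Non-model class: union of
    non-model-site positions minus the model class.  The remainder, minus
    CDS, is non-functional, split by accessibility.
    """
    n = len(region)
    model = set()
    nonmodel = set()
    for s in sites:
        target = model if s.is_model else nonmodel
        target.update(range(s.start, s.end))
    nonmodel -= model
    cds = set()
    for s, e in region.cds:
        cds.update(range(s, e))
    accessible = set()
    for s, e in region.accessible:
        accessible.update(range(s, e))
    rest = set(range(n)) - model - nonmodel - cds
    nf_acc = rest & accessible
    nf_nonacc = rest - accessible
    seq = region.sequence
    gc = {
        "model": _gc_fraction(seq, sorted(model)),
        "nonmodel": _gc_fraction(seq, sorted(nonmodel)),
        "nonfunctional_accessible": _gc_fraction(seq, sorted(nf_acc)),
        "nonfunctional_nonaccessible": _gc_fraction(seq, sorted(nf_nonacc)),
    }
    return RegionPartition(
        frozenset(model), frozenset(nonmodel), frozenset(nf_acc),
        frozenset(nf_nonacc), frozenset(cds - model - nonmodel), gc,
    )
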