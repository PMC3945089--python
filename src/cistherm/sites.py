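"""PWM scanning: annotating candidate TF binding sites in a sequence.

A site's raw score is the log-likelihood ratio (LLR, in nats) of the k-mer
under the motif versus the background; its relative affinity is
``exp(llr - llr_max)`` where ``llr_max`` is the best score the motif can
achieve, so the consensus word scores exactly 1. Both strands are scanned;
at one (position, TF) only the better strand is kept. Windows containing N
are skipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ALPHABET, PWM, Sequence

logger = logging.getLogger(__name__)

_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE["N"] = -1
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def encode(residues: str) -> np.ndarray:
    """Map residues to integer codes (A=0 .. T=3, N=-1)."""
    return np.array([_CODE[c] for c in residues], dtype=np.int8)


@dataclass(frozen=True)
class Site:
    """One annotated TF binding site (0-based half-open on the + strand)."""

    tf_index: int
    start: int
    length: int
    strand: str  # '+' or '-'
    llr: float
    rel_affinity: float

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SiteAnnotation:
    """All candidate sites of one sequence, sorted by (start, strand)."""

    sequence_id: str
    sites: list[Site]
    tf_names: list[str]
    llr_max: dict[int, float]
    seq_length: int
    _arrays: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.sites = sorted(self.sites, key=lambda s: (s.start, s.strand))

    def __len__(self) -> int:
        return len(self.sites)

    def arrays(self):
        """Columnar view (starts, ends, tf_idx, rel_affinity) for fast math."""
        if not self._arrays:
            self._arrays = {
                "starts": np.array([s.start for s in self.sites], dtype=np.int64),
                "ends": np.array([s.end for s in self.sites], dtype=np.int64),
                "tf": np.array([s.tf_index for s in self.sites], dtype=np.int64),
                "aff": np.array([s.rel_affinity for s in self.sites], dtype=float),
            }
        return (
            self._arrays["starts"],
            self._arrays["ends"],
            self._arrays["tf"],
            self._arrays["aff"],
        )

    def subset(self, start: int, end: int) -> "SiteAnnotation":
        """Sites lying entirely inside [start, end) of the sequence."""
        kept = [s for s in self.sites if s.start >= start and s.end <= end]
        return SiteAnnotation(
            f"{self.sequence_id}:{start}-{end}",
            kept,
            self.tf_names,
            self.llr_max,
            self.seq_length,
        )

    def with_sites(self, sites: list[Site]) -> "SiteAnnotation":
        return SiteAnnotation(
            self.sequence_id, sites, self.tf_names, self.llr_max, self.seq_length
        )


def llr_score(pwm: PWM, kmer: str, strand: str = "+") -> float:
    """Log-likelihood ratio of one k-mer under the motif vs the background."""
    if len(kmer) != len(pwm):
        raise ValueError(
            f"k-mer length {len(kmer)} != motif length {len(pwm)}"
        )
    if strand == "-":
        kmer = revcomp(kmer)
    codes = encode(kmer)
    if np.any(codes < 0):
        raise ValueError("k-mer contains N; unscored")
    pos = np.arange(len(pwm))
    return float(
        np.sum(np.log(pwm.probs[pos, codes]) - np.log(pwm.background[codes]))
    )


def pwm_llr_max(pwm: PWM) -> float:
    """The best LLR the motif can achieve (its consensus word's score)."""
    return float(np.sum(np.max(np.log(pwm.probs) - np.log(pwm.background), axis=1)))


def _scan_one_strand(codes: np.ndarray, logratio: np.ndarray) -> np.ndarray:
    """LLR at every start position (NaN where the window contains N)."""
    L = logratio.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = np.all(win >= 0, axis=1)
    scores = np.full(n, np.nan)
    if valid.any():
        idx = win[valid]
        scores[valid] = logratio[np.arange(L)[None, :], idx].sum(axis=1)
    return scores


def scan_sites(
    seq: Sequence,
    pwms: list[PWM],
    rel_affinity_threshold: float = 0.01,
) -> SiteAnnotation:
    """Annotate all sites with relative affinity >= threshold, both strands."""
    if not 0 < rel_affinity_threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    codes = encode(seq.residues)
    if seq.has_n:
        logger.info("sequence %s contains N; windows with N are unscored", seq.id)
    sites: list[Site] = []
    llr_max: dict[int, float] = {}
    for t, pwm in enumerate(pwms):
        L = len(pwm)
        lmax = pwm_llr_max(pwm)
        llr_max[t] = lmax
        if L > len(seq):
            warnings.warn(
                f"motif {pwm.tf_name!r} is longer than sequence {seq.id!r}; "
                "no sites annotated"
            )
            continue
        logratio = np.log(pwm.probs) - np.log(pwm.background)[None, :]
        fwd = _scan_one_strand(codes, logratio)
        # Reverse strand: score the reverse complement of each window, which
        # equals scanning with the reverse-complemented motif on the forward
        # strand (rows reversed, columns in complement order).
        rc_logratio = logratio[::-1, ::-1]
        rev = _scan_one_strand(codes, rc_logratio)
        cutoff = lmax + np.log(rel_affinity_threshold)
        with np.errstate(invalid="ignore"):
            take_f = fwd >= cutoff - 1e-12
            take_r = rev >= cutoff - 1e-12
        for pos in np.nonzero(take_f | take_r)[0]:
            f, r = fwd[pos], rev[pos]
            # at one (position, TF) keep only the better strand; tie -> '+'
            if take_f[pos] and (not take_r[pos] or f >= r):
                strand, llr = "+", f
            else:
                strand, llr = "-", r
            sites.append(
                Site(t, int(pos), L, strand, float(llr),
                     float(min(np.exp(llr - lmax), 1.0)))
            )
    return SiteAnnotation(
        seq.id, sites, [p.tf_name for p in pwms], llr_max, len(seq)
    )


def shuffle_site_positions(
    annotation: SiteAnnotation, seq_length: int, rng_seed: int
) -> SiteAnnotation:
    """Relocate every site to a uniformly random position within the locus.

    The multiset of (TF, strand, LLR, affinity, length) is conserved; only
    start coordinates are redrawn. Same-TF sites never land on the exact
    same position twice.
    """
    sites = annotation.sites
    if sites and seq_length < max(s.length for s in sites):
        raise ValueError("sequence shorter than the longest site")
    rng = np.random.default_rng(rng_seed)
    taken: dict[int, set[int]] = {}
    new_sites: list[Site] = []
    for s in sites:
        n_positions = seq_length - s.length + 1
        used = taken.setdefault(s.tf_index, set())
        if len(used) >= n_positions:
            raise ValueError(
                f"cannot place {len(used) + 1} sites of TF {s.tf_index} "
                f"in {n_positions} positions without duplicates"
            )
        while True:
            start = int(rng.integers(0, n_positions))
            if start not in used:
                break
        used.add(start)
        new_sites.append(
            Site(s.tf_index, start, s.length, s.strand, s.llr, s.rel_affinity)
        )
    return SiteAnnotation(
        annotation.sequence_id + "|shuffled",
        new_sites,
        annotation.tf_names,
        annotation.llr_max,
        seq_length,
    )


def write_sites_tsv(path, annotation: SiteAnnotation) -> None:
    """Dump sites as TSV (0-based half-open coordinates)."""
    with open(path, "w") as fh:
        fh.write("sequence_id\ttf\tstart\tend\tstrand\tllr\trel_affinity\n")
        for s in annotation.sites:
            fh.write(
                f"{annotation.sequence_id}\t{annotation.tf_names[s.tf_index]}\t"
                f"{s.start}\t{s.end}\t{s.strand}\t{s.llr:.6g}\t{s.rel_affinity:.6g}\n"
            )
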