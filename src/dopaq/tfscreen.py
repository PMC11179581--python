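"""Promoter PWM scanning and the four-criterion transcription-factor filter.

The candidate screen keeps a transcription factor when it (1) ranks within the
top slice of a differential-target enrichment list (TFT rank <= 50 by
default), (2) has annotated homologs in both mouse and worm, (3) is expressed
in dopaminergic neurons per a single-cell atlas annotation, and (4) has at
least one predicted binding site in the promoter window (4 kb upstream of the
transcription start site). Site prediction is an explicit, reproducible PWM
log-odds scan over both strands with a documented default threshold (80% of
each motif's maximum achievable score); PWMs are supplied as JASPAR-style
count matrices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

__all__ = [
    "Pwm",
    "PromoterWindow",
    "read_jaspar",
    "scan_pwm",
    "count_promoter_sites",
    "filter_tf_candidates",
    "read_promoter_fasta",
]

_ALPHABET = "ACGT"
_INDEX = {c: i for i, c in enumerate(_ALPHABET)}
_COMPLEMENT_ROWS = [3, 2, 1, 0]  # A<->T, C<->G


@dataclass
class Pwm:
    """Position count matrix with log-odds scoring.

    ``counts`` is 4 x W over rows A, C, G, T. Scoring adds ``pseudocount`` to
    every cell, normalizes columns to probabilities, and scores log2 odds
    against ``background`` (uniform by default).
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.25
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError("counts must be 4 x W with W >= 4")
        if (self.counts < 0).any() or (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("counts must be nonnegative with positive column sums")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        padded = self.counts + self.pseudocount
        probs = padded / padded.sum(axis=0, keepdims=True)
        return np.log2(probs / self.background[:, None])

    @property
    def max_score(self) -> float:
        # accumulated column-by-column, in the same order the scanner sums a
        # window, so a consensus match scores exactly max_score
        lo = self.log_odds
        total = 0.0
        for j in range(lo.shape[1]):
            total += float(lo[:, j].max())
        return total

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.counts.argmax(axis=0))

    def reverse_complement(self) -> "Pwm":
        rc = self.counts[_COMPLEMENT_ROWS, ::-1]
        return Pwm(self.name, rc, self.pseudocount, self.background[_COMPLEMENT_ROWS].copy())


@dataclass
class PromoterWindow:
    """Sequence immediately upstream of a gene's transcription start site."""

    gene: str
    tss: int  # 1-based
    strand: str
    seq: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        bad = set(self.seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence has non-nucleotide characters: {sorted(bad)}")
        self.seq = self.seq.upper()


def read_jaspar(source) -> list[Pwm]:
    """Read JASPAR-format count matrices (path, file object or text)."""
    if isinstance(source, str) and "\n" in source:
        handle = io.StringIO(source)
    elif hasattr(source, "read"):
        handle = source
    else:
        handle = open(source)
    with handle:
        parsed = bio_motifs.parse(handle, "jaspar")
        out = []
        for m in parsed:
            counts = np.array([m.counts[base] for base in _ALPHABET], dtype=float)
            out.append(Pwm(name=m.name or m.matrix_id or "motif", counts=counts))
    return out


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, -1, dtype=np.int64)
    for base, idx in _INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(enc: np.ndarray, lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every window plus a validity mask (no N inside)."""
    w = lo.shape[1]
    n_win = enc.size - w + 1
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(enc < 0, 0, enc)
    for j in range(w):
        col = enc[j : j + n_win]
        valid &= col >= 0
        scores += lo[:, j][safe[j : j + n_win]]
    return scores, valid


def scan_pwm(seq: str, pwm: Pwm, score_threshold: float) -> list[tuple[int, int, str, float]]:
    """All PWM hits on both strands of ``seq`` at or above ``score_threshold``.

    Returns (start, end, strand, score) tuples with 0-based half-open
    coordinates on the forward orientation of the given sequence; a "-" hit
    means the reverse complement of that window matches. Windows containing N
    are skipped. Output is sorted by start, then strand.
    """
    w = pwm.width
    if len(seq) < w:
        raise ValueError(f"sequence shorter than motif width ({len(seq)} < {w})")
    enc = _encode(seq)
    hits: list[tuple[int, int, str, float]] = []
    for strand, matrix in (("+", pwm.log_odds), ("-", pwm.reverse_complement().log_odds)):
        scores, valid = _window_scores(enc, matrix)
        for pos in np.flatnonzero(valid & (scores >= score_threshold)):
            hits.append((int(pos), int(pos) + w, strand, float(scores[pos])))
    hits.sort(key=lambda h: (h[0], h[2]))
    return hits


def resolve_threshold(pwm: Pwm, threshold_rule) -> float:
    """Absolute score threshold from a rule.

    A float in (0, 1] is a fraction of the PWM's maximum achievable score
    (default convention, 0.8); a ("abs", value) pair is an absolute log-odds
    score.
    """
    if isinstance(threshold_rule, tuple):
        kind, value = threshold_rule
        if kind != "abs":
            raise ValueError(f"unknown threshold rule {kind!r}")
        return float(value)
    frac = float(threshold_rule)
    if not 0.0 < frac <= 1.0:
        raise ValueError("fractional threshold must be in (0, 1]")
    return frac * pwm.max_score


def count_promoter_sites(
    window: PromoterWindow,
    pwms: Sequence[Pwm],
    threshold_rule=0.8,
) -> dict[str, int]:
    """Per-TF count of PWM hits (both strands) in a promoter window."""
    if not pwms:
        raise ValueError("empty PWM list")
    counts: dict[str, int] = {}
    for pwm in pwms:
        thr = resolve_threshold(pwm, threshold_rule)
        counts[pwm.name] = len(scan_pwm(window.seq, pwm, thr))
    return counts


def read_promoter_fasta(path, window_bp: int = 4000) -> list[PromoterWindow]:
    """Read promoter windows from FASTA with ``gene|tss|strand`` headers."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(f"FASTA id {rec.id!r} is not gene|tss|strand")
        gene, tss, strand = parts
        seq = str(rec.seq)
        out.append(
            PromoterWindow(
                gene=gene,
                tss=int(tss),
                strand=strand,
                seq=seq,
                truncated=len(seq) < window_bp,
            )
        )
    return out


_CRITERIA = ("tft_rank", "mouse_homolog", "worm_homolog", "dopaminergic_expression", "binding_site")


def filter_tf_candidates(annotations: pd.DataFrame, rank_cutoff: int = 50) -> pd.DataFrame:
    """Apply the four-criterion candidate filter and rank the survivors.

    A TF passes iff its TFT rank is within ``rank_cutoff`` AND it has mouse
    and worm homologs AND it is expressed in dopaminergic neurons AND it has
    at least one predicted promoter binding site. Survivors are ranked by
    site_count descending, ties broken by TFT rank ascending; ``rank_score``
    encodes that total order as a single number. Failure reasons are recorded
    per non-passer.
    """
    required = {
        "tf",
        "tft_rank",
        "has_mouse_homolog",
        "has_worm_homolog",
        "dopaminergic_expressed",
        "site_count",
    }
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    if annotations["tft_rank"].duplicated().any():
        dup = annotations.loc[annotations["tft_rank"].duplicated(), "tft_rank"].iloc[0]
        raise ValueError(f"duplicate TFT rank {int(dup)}")

    df = annotations.copy()
    checks = {
        "tft_rank": df["tft_rank"] <= rank_cutoff,
        "mouse_homolog": df["has_mouse_homolog"].astype(bool),
        "worm_homolog": df["has_worm_homolog"].astype(bool),
        "dopaminergic_expression": df["dopaminergic_expressed"].astype(bool),
        "binding_site": df["site_count"] >= 1,
    }
    passed = np.logical_and.reduce(list(checks.values()))
    df["passed"] = passed
    df["failure_reasons"] = [
        ";".join(name for name, ok in checks.items() if not ok.iloc[i]) for i in range(len(df))
    ]
    # deterministic total order: more sites first, then better (smaller) rank
    df["rank_score"] = df["site_count"] - df["tft_rank"] / (df["tft_rank"].max() + 1.0)
    df = df.sort_values(["passed", "site_count", "tft_rank"], ascending=[False, False, True])
    return df.reset_index(drop=True)
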