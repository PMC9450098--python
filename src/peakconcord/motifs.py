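"""PWM motif scanning and the fractional-change motif enrichment score.

Scanning computes, per peak sequence, the best log2 odds of any window
(both strands) under the motif versus a background base composition.
The enrichment score for a motif is the percent change of summed
normalized fragment counts at motif-containing peaks, treatment versus
control, with a percentile bootstrap over peaks for the interval. This is
the bias-uncorrected fractional-change statistic: no GC/accessibility-
matched background peak sampling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .types import CountMatrix

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "EnrichmentScore",
    "read_jaspar_pwms",
    "scan_pwm",
    "motif_enrichment_score",
]

_BASES = "ACGT"
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G on encoded rows
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class PositionWeightMatrix:
    """4 x L base probabilities (rows A, C, G, T), pseudo-floored.

    Cells are floored at ``pseudo`` and columns renormalized, so log-odds
    are always finite on ACGT windows.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudo: float = 1e-3

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != 4:
            raise ValueError("matrix must be 4 x L")
        if mat.shape[1] < 4:
            raise ValueError("motif length must be >= 4")
        mat = np.maximum(mat, self.pseudo)
        mat = mat / mat.sum(axis=0, keepdims=True)
        object.__setattr__(self, "matrix", mat)
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """log2(P(base|motif) / P(base|background)) per cell."""
        return np.log2(self.matrix / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            self.motif_id,
            self.matrix[_COMPLEMENT][:, ::-1],
            self.background[_COMPLEMENT],
            self.pseudo,
        )

    @classmethod
    def from_counts(
        cls, motif_id: str, counts: np.ndarray, **kwargs
    ) -> "PositionWeightMatrix":
        counts = np.asarray(counts, dtype=float)
        return cls(motif_id, counts / counts.sum(axis=0, keepdims=True), **kwargs)


def read_jaspar_pwms(path: str, pseudo: float = 1e-3) -> list[PositionWeightMatrix]:
    """Read JASPAR-format motif count matrices into floored PWMs."""
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in _BASES], dtype=float)
            out.append(
                PositionWeightMatrix.from_counts(
                    m.matrix_id or m.name, counts, pseudo=pseudo
                )
            )
    return out


@dataclass(frozen=True)
class MotifHit:
    peak_id: str
    score: float
    match: bool


def _best_window_score(encoded: np.ndarray, lods: np.ndarray) -> float:
    """Best score over all windows of one strand; N-containing windows
    score -inf."""
    L = lods.shape[1]
    n = encoded.size
    if n < L:
        return -np.inf
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return -np.inf
    w = windows[valid]
    scores = lods[w, np.arange(L)].sum(axis=1)
    return float(scores.max())


def scan_pwm(
    pwm: PositionWeightMatrix,
    peak_sequences: Mapping[str, str],
    threshold: float | None = None,
) -> dict[str, MotifHit]:
    """Best log-odds per peak over both strands, with match flags.

    ``threshold`` defaults to 80% of the motif's maximum attainable score.
    Sequences shorter than the motif (or all-N) score -inf and never match.
    """
    if threshold is None:
        threshold = 0.8 * pwm.max_score
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    fwd = pwm.log_odds
    rev = pwm.reverse_complement().log_odds
    out = {}
    for peak_id, seq in peak_sequences.items():
        enc = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        score = max(_best_window_score(enc, fwd), _best_window_score(enc, rev))
        out[peak_id] = MotifHit(peak_id, score, bool(score >= threshold))
    return out


@dataclass(frozen=True)
class EnrichmentScore:
    motif_id: str
    score: float  # percent change, treatment vs control
    ci_low: float
    ci_high: float
    n_motif_peaks: int


def motif_enrichment_score(
    normalized: CountMatrix,
    motif_peaks: Sequence[str],
    control_samples: Sequence[str],
    treatment_samples: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
    motif_id: str = "",
) -> EnrichmentScore:
    """Percent change of summed normalized counts at motif-containing peaks.

    Per-peak counts are summed over the motif peak set, averaged across
    control and (dose-pooled) treatment samples, and compared:
    score = 100 * (mean_treatment - mean_control) / mean_control. The CI is
    a 2.5/97.5 percentile bootstrap over peaks.
    """
    motif_peaks = list(motif_peaks)
    if not motif_peaks:
        raise ValueError("motif peak set is empty")
    rows = normalized.row_indexer(motif_peaks)
    col_of = {s: i for i, s in enumerate(normalized.sample_ids)}
    try:
        ctrl = np.array([col_of[s] for s in control_samples], dtype=int)
        trt = np.array([col_of[s] for s in treatment_samples], dtype=int)
    except KeyError as exc:
        raise KeyError(f"unknown sample id {exc.args[0]!r}") from None
    sub_c = normalized.values[np.ix_(rows, ctrl)]
    sub_t = normalized.values[np.ix_(rows, trt)]

    def _score(c: np.ndarray, t: np.ndarray) -> float:
        m_c = c.sum(axis=0).mean()
        m_t = t.sum(axis=0).mean()
        return 100.0 * (m_t - m_c) / m_c

    if sub_c.sum(axis=0).mean() == 0:
        raise ValueError("zero control signal at motif peaks")
    score = _score(sub_c, sub_t)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(motif_peaks)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        c = sub_c[idx]
        if c.sum(axis=0).mean() == 0:
            boots[b] = np.nan
            continue
        boots[b] = _score(c, sub_t[idx])
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return EnrichmentScore(motif_id, float(score), float(lo), float(hi), n)
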