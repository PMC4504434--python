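"""Plant-style miRNA target prediction by ungapped complementarity.

Each transcript window of miRNA length is scored against the miRNA in the
antiparallel register: Watson-Crick pair 0, G:U wobble 0.5, mismatch 1.0,
with penalties doubled inside the seed-proximal region (miRNA positions
2-13 from the 5' end). Sites at or under the penalty threshold (default
3.0) are reported; a mismatch at the central positions 9-11 marks the site
as translational inhibition rather than cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import normalize
from .config import TargetConfig

__all__ = [
    "TargetPrediction",
    "score_alignment",
    "classify_inhibition",
    "scan_targets",
    "scan_transcriptome",
]

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U in RNA


@dataclass
class TargetPrediction:
    mirna_id: str
    transcript_id: str
    start: int          # 0-based half-open on the transcript
    end: int
    score: float
    inhibition: str     # 'cleavage' | 'translation'
    mirna_seq: str
    site_seq: str

    @property
    def alignment(self) -> tuple[str, str, str]:
        """(miRNA 3'->5', bond line, target 5'->3').

        In this antiparallel display, column i aligns miRNA base
        ``mirna[L-1-i]`` with target base ``site[i]``.
        """
        m_rev = self.mirna_seq[::-1]
        bonds = []
        for mb, tb in zip(m_rev, self.site_seq):
            if (mb, tb) in _WC:
                bonds.append("|")
            elif (mb, tb) in _WOBBLE:
                bonds.append("o")
            else:
                bonds.append(" ")
        return m_rev, "".join(bonds), self.site_seq


def _pair_kind(mirna_base: str, target_base: str) -> str:
    """'wc', 'wobble' or 'mismatch' for an antiparallel pairing."""
    if (mirna_base, target_base) in _WC:
        return "wc"
    if (mirna_base, target_base) in _WOBBLE:
        return "wobble"
    return "mismatch"


def score_alignment(
    mirna: str, target_window: str, cfg: TargetConfig | None = None
) -> float:
    """Penalty score of an ungapped miRNA/target duplex.

    ``target_window`` is the transcript site 5'->3'; miRNA position i
    (1-based from its 5' end) pairs target position L-i. Penalties are
    doubled within miRNA positions [seed_start, seed_end].
    """
    cfg = cfg or TargetConfig()
    m = normalize(mirna)
    t = normalize(target_window)
    if len(m) != len(t):
        raise ValueError("miRNA and target window must have equal length")
    if set(m + t) - set("ACGT"):
        raise ValueError("non-ACGT/U symbol in alignment")
    L = len(m)
    score = 0.0
    for i in range(1, L + 1):  # miRNA position, 1-based from 5' end
        kind = _pair_kind(m[i - 1], t[L - i])
        if kind == "wc":
            penalty = 0.0
        elif kind == "wobble":
            penalty = cfg.wobble_penalty
        else:
            penalty = cfg.mismatch_penalty
        if cfg.seed_start <= i <= cfg.seed_end:
            penalty *= 2.0
        score += penalty
    return score


def classify_inhibition(
    mirna: str, target_window: str, cfg: TargetConfig | None = None
) -> str:
    """'translation' iff a true mismatch (wobble excluded) falls at the
    central miRNA positions (default 9-11); else 'cleavage'."""
    cfg = cfg or TargetConfig()
    m = normalize(mirna)
    t = normalize(target_window)
    if len(m) != len(t):
        raise ValueError("miRNA and target window must have equal length")
    L = len(m)
    for i in range(cfg.central_start, cfg.central_end + 1):
        if i < 1 or i > L:
            continue
        if _pair_kind(m[i - 1], t[L - i]) == "mismatch":
            return "translation"
    return "cleavage"


def scan_targets(
    mirna: str,
    transcript: str,
    cfg: TargetConfig | None = None,
    mirna_id: str = "miRNA",
    transcript_id: str = "transcript",
) -> list[TargetPrediction]:
    """Score every ungapped transcript window against the miRNA.

    Windows with penalty <= ``cfg.max_score`` are reported; runs of
    overlapping qualifying windows are reduced to their local score
    minimum (leftmost on ties).
    """
    cfg = cfg or TargetConfig()
    m = normalize(mirna)
    t = normalize(transcript)
    L = len(m)
    if len(t) < L:
        return []
    qualifying: list[tuple[int, float]] = []
    for s in range(len(t) - L + 1):
        window = t[s : s + L]
        if "N" in window:
            continue
        sc = score_alignment(m, window, cfg)
        if sc <= cfg.max_score:
            qualifying.append((s, sc))

    # collapse overlapping windows to the best-scoring representative
    out: list[TargetPrediction] = []
    group: list[tuple[int, float]] = []

    def _flush() -> None:
        if not group:
            return
        s, sc = min(group, key=lambda x: (x[1], x[0]))
        window = t[s : s + L]
        out.append(
            TargetPrediction(
                mirna_id=mirna_id,
                transcript_id=transcript_id,
                start=s,
                end=s + L,
                score=sc,
                inhibition=classify_inhibition(m, window, cfg),
                mirna_seq=m,
                site_seq=window,
            )
        )
        group.clear()

    last_end = -1
    for s, sc in qualifying:
        if group and s >= last_end:
            _flush()
        group.append((s, sc))
        last_end = max(last_end, s + L)
    _flush()
    return out


def scan_transcriptome(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    cfg: TargetConfig | None = None,
) -> list[TargetPrediction]:
    """All-vs-all target scan."""
    cfg = cfg or TargetConfig()
    out: list[TargetPrediction] = []
    for mid in sorted(mirnas):
        for tid in sorted(transcripts):
            out.extend(
                scan_targets(mirnas[mid], transcripts[tid], cfg, mid, tid)
            )
    return out
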