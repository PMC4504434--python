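"""Digital differential expression for unreplicated small-RNA libraries.

Counts are normalised to transcripts per million (TPM = count / clean
library total * 1e6); changes are summarised as log2 fold change and
tested with the exact Poisson-based (Audic-Claverie) test, which
conditions on the summed count of a tag across two libraries. A mature is
called up or down in a genotype when it clears the 1-TPM detection floor,
|log2FC| >= 1 and p <= alpha; the two-genotype pattern is then categorised
(up in both, down in both, or opposite between the tolerant and
susceptible genotype).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import ExpressionConfig

__all__ = [
    "ExpressionRecord",
    "DEResult",
    "tpm_normalize",
    "log2_fold_change",
    "audic_claverie_pvalue",
    "classify_de",
]

CATEGORIES = ("up_both", "down_both", "up_T_down_S", "down_T_up_S", "mixed_or_unchanged")


@dataclass
class ExpressionRecord:
    """Raw counts and library sizes for one miRNA in one genotype."""

    mirna_id: str
    genotype: str
    x_ctrl: int
    y_stress: int
    n_ctrl: int     # clean-read total of the control library
    n_stress: int   # clean-read total of the stress library

    @property
    def tpm_ctrl(self) -> float:
        return tpm_normalize(self.x_ctrl, self.n_ctrl)

    @property
    def tpm_stress(self) -> float:
        return tpm_normalize(self.y_stress, self.n_stress)


@dataclass
class DEResult:
    mirna_id: str
    log2fc: dict[str, float | None] = field(default_factory=dict)
    pvalue: dict[str, float | None] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)   # up|down|unchanged|ND
    tpm: dict[str, tuple[float, float]] = field(default_factory=dict)
    category: str = "mixed_or_unchanged"


def tpm_normalize(count: int, library_clean_total: int) -> float:
    """Reads-per-million normalisation against the clean-read total."""
    if library_clean_total < 1:
        raise ValueError("library_clean_total must be >= 1")
    if count < 0:
        raise ValueError("negative count")
    return count / library_clean_total * 1e6


def log2_fold_change(tpm_stress: float, tpm_ctrl: float, pseudo: float = 0.0) -> float:
    """log2(stress / control) in TPM; ``pseudo`` is added to both sides
    only when either TPM is zero (the caller chooses a pseudo equivalent
    to one raw read in the relevant library)."""
    if tpm_stress < 0 or tpm_ctrl < 0:
        raise ValueError("negative TPM")
    if tpm_stress == 0 or tpm_ctrl == 0:
        if pseudo <= 0:
            raise ValueError("zero TPM requires a positive pseudocount")
        tpm_stress += pseudo
        tpm_ctrl += pseudo
    return math.log2(tpm_stress / tpm_ctrl)


def audic_claverie_pvalue(
    x: int,
    y: int,
    n1: int,
    n2: int,
    alternative: str = "two_sided",
) -> float:
    """Exact Poisson-model significance of a count difference.

    Conditional on x reads in a library of n1 clean reads, the count y in a
    library of n2 clean reads follows
    ``p(y|x) = (n2/n1)^y (x+y)! / (x! y! (1+n2/n1)^(x+y+1))``, a negative
    binomial with x+1 successes and failure probability n2/(n1+n2). Tails
    are computed from that law in a numerically stable form; the two-sided
    p doubles the smaller tail (capped at 1), which is monotone in |x-y|.
    """
    if x < 0 or y < 0:
        raise ValueError("negative counts")
    if n1 < 1 or n2 < 1:
        raise ValueError("library sizes must be >= 1")
    q = n2 / (n1 + n2)     # failure probability; successes have prob n1/(n1+n2)
    dist = stats.nbinom(x + 1, 1 - q)
    upper = float(dist.sf(y - 1))   # P(Y >= y)
    lower = float(dist.cdf(y))      # P(Y <= y)
    if alternative == "greater":
        return min(1.0, upper)
    if alternative == "less":
        return min(1.0, lower)
    if alternative == "two_sided":
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"unknown alternative {alternative!r}")


def audic_claverie_pvalues(
    x: np.ndarray, y: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Vectorised two-sided Audic-Claverie p-values."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    q = n2 / (n1 + n2)
    upper = stats.nbinom.sf(y - 1, x + 1, 1 - q)
    lower = stats.nbinom.cdf(y, x + 1, 1 - q)
    return np.minimum(1.0, 2.0 * np.minimum(upper, lower))


def _status(
    rec: ExpressionRecord, cfg: ExpressionConfig
) -> tuple[str, float | None, float | None]:
    """Per-genotype status with detection floor, fold-change and p gates."""
    t_ctrl, t_stress = rec.tpm_ctrl, rec.tpm_stress
    if max(t_ctrl, t_stress) < cfg.min_tpm:
        return "ND", None, None
    # pseudo equivalent to one raw read in the zero-count library
    pseudo = 0.0
    if rec.x_ctrl == 0 or rec.y_stress == 0:
        n_zero = rec.n_ctrl if rec.x_ctrl == 0 else rec.n_stress
        pseudo = tpm_normalize(1, n_zero)
    fc = log2_fold_change(t_stress, t_ctrl, pseudo)
    p = audic_claverie_pvalue(rec.x_ctrl, rec.y_stress, rec.n_ctrl, rec.n_stress)
    if fc >= cfg.min_abs_log2fc and p <= cfg.alpha:
        return "up", fc, p
    if fc <= -cfg.min_abs_log2fc and p <= cfg.alpha:
        return "down", fc, p
    return "unchanged", fc, p


def categorize(status_t: str, status_s: str) -> str:
    """Cross-genotype drought-response category (T = tolerant, S =
    susceptible genotype)."""
    if status_t == "up" and status_s == "up":
        return "up_both"
    if status_t == "down" and status_s == "down":
        return "down_both"
    if status_t == "up" and status_s == "down":
        return "up_T_down_S"
    if status_t == "down" and status_s == "up":
        return "down_T_up_S"
    return "mixed_or_unchanged"


def classify_de(
    records: list[ExpressionRecord],
    cfg: ExpressionConfig | None = None,
    genotype_order: tuple[str, str] | None = None,
) -> list[DEResult]:
    """Per-miRNA DE call across two genotypes.

    ``records`` holds one ExpressionRecord per (miRNA, genotype);
    ``genotype_order`` names the (tolerant, susceptible) pair — defaults to
    the sorted genotype labels.
    """
    cfg = cfg or ExpressionConfig()
    by_mirna: dict[str, dict[str, ExpressionRecord]] = {}
    for rec in records:
        by_mirna.setdefault(rec.mirna_id, {})[rec.genotype] = rec
    if genotype_order is None:
        genos = sorted({rec.genotype for rec in records})
        if len(genos) != 2:
            raise ValueError(f"expected exactly 2 genotypes, got {genos}")
        genotype_order = (genos[0], genos[1])
    g_t, g_s = genotype_order

    results = []
    for mirna_id in sorted(by_mirna):
        recs = by_mirna[mirna_id]
        res = DEResult(mirna_id=mirna_id)
        for g in genotype_order:
            if g not in recs:
                res.status[g] = "ND"
                res.log2fc[g] = None
                res.pvalue[g] = None
                res.tpm[g] = (0.0, 0.0)
                continue
            status, fc, p = _status(recs[g], cfg)
            res.status[g] = status
            res.log2fc[g] = fc
            res.pvalue[g] = p
            res.tpm[g] = (recs[g].tpm_ctrl, recs[g].tpm_stress)
        res.category = categorize(res.status[g_t], res.status[g_s])
        results.append(res)
    return results
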