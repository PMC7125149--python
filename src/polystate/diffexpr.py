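"""Per-fraction differential abundance between the two developmental stages.

Each isoform is tested with Welch's t on log2(abundance + pseudocount)
across replicates, two-sided, and the resulting p-values are corrected by
Benjamini–Hochberg within the fraction. A direction (up / down / none) is
assigned at q <= alpha; "up" means higher at stage B (the later stage).
Detection flags record whether the mean abundance in a stage reaches the
detection threshold — low-expressed transcripts can be confidently seen in
the polysome pool while sitting below detection in total RNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .fractions import _welch_from_stats
from .io import FRACTIONS, AbundanceMatrix

#: Default pseudocount added before log2; stabilises the ratio at low
#: FPKM-like abundances.
DEFAULT_PSEUDOCOUNT = 1.0

#: Default detection threshold: mean abundance >= 1.0 in a stage. The
#: threshold is a configurable stand-in (see docs/methods.md).
DEFAULT_DETECTION_THRESHOLD = 1.0

CONTRAST_COLUMNS = (
    "log2_fold_change", "statistic", "p_value", "q_value",
    "detected_A", "detected_B", "direction", "degenerate",
)


@dataclass
class ContrastResult:
    """Differential statistics for one fraction, stage B vs stage A.

    ``table`` is indexed by isoform id with columns log2_fold_change,
    statistic (Welch t), p_value, q_value (BH within this fraction),
    detected_A, detected_B, direction, degenerate.
    """

    fraction: str
    stage_a: str
    stage_b: str
    alpha: float
    table: pd.DataFrame = field(repr=False)

    def directions(self, alpha: float | None = None) -> pd.Series:
        """Direction calls at a (possibly different) FDR level."""
        alpha = self.alpha if alpha is None else alpha
        sig = self.table["q_value"] <= alpha
        up = sig & (self.table["log2_fold_change"] > 0)
        down = sig & (self.table["log2_fold_change"] < 0)
        out = pd.Series("none", index=self.table.index, name="direction")
        out[up] = "up"
        out[down] = "down"
        return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def global_correction(contrasts: list[ContrastResult]) -> list[ContrastResult]:
    """Recompute q-values jointly across several fraction contrasts.

    The default analysis corrects within each fraction (the three contrasts
    are separate families); this opt-in mode pools all p-values into one BH
    family and reassigns directions at each contrast's alpha.
    """
    if not contrasts:
        return []
    sizes = [len(c.table) for c in contrasts]
    pooled = np.concatenate([c.table["p_value"].to_numpy() for c in contrasts])
    q_all = bh_adjust(pooled)
    out = []
    offset = 0
    for c, size in zip(contrasts, sizes):
        table = c.table.copy()
        table["q_value"] = q_all[offset:offset + size]
        offset += size
        res = ContrastResult(fraction=c.fraction, stage_a=c.stage_a,
                             stage_b=c.stage_b, alpha=c.alpha, table=table)
        table["direction"] = res.directions(c.alpha)
        res.table = table[list(CONTRAST_COLUMNS)]
        out.append(res)
    return out


def detection_filter(matrix: AbundanceMatrix, fraction: str,
                     threshold: float = DEFAULT_DETECTION_THRESHOLD) -> pd.DataFrame:
    """Per-isoform detection flags per stage.

    Detected at a stage iff the mean abundance over that stage's replicates
    of ``fraction`` is >= threshold.
    """
    if threshold < 0:
        raise ValidationError("detection threshold must be >= 0")
    if fraction not in FRACTIONS:
        raise ValidationError(f"unknown fraction {fraction!r}")
    stage_a, stage_b = matrix.stages
    mean_a = matrix.fraction_values(fraction, stage_a).mean(axis=1)
    mean_b = matrix.fraction_values(fraction, stage_b).mean(axis=1)
    return pd.DataFrame(
        {"detected_A": mean_a >= threshold, "detected_B": mean_b >= threshold},
        index=matrix.isoform_ids,
    )


def test_contrast(matrix: AbundanceMatrix, fraction: str, alpha: float = 0.05,
                  pseudocount: float = DEFAULT_PSEUDOCOUNT,
                  detection_threshold: float = DEFAULT_DETECTION_THRESHOLD) -> ContrastResult:
    """Test every isoform for differential abundance in one fraction.

    Welch's t on log2(x + pseudocount), stage B vs stage A, two-sided;
    BH correction within this fraction's isoform list. Isoforms with zero
    variance and equal means in both stages get p = 1 by convention and are
    flagged ``degenerate``.
    """
    if fraction not in FRACTIONS:
        raise ValidationError(f"unknown fraction {fraction!r}; expected one of {FRACTIONS}")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    stage_a, stage_b = matrix.stages
    va = matrix.fraction_values(fraction, stage_a).to_numpy(dtype=float)
    vb = matrix.fraction_values(fraction, stage_b).to_numpy(dtype=float)
    if va.shape[1] < 2 or vb.shape[1] < 2:
        raise ValidationError(
            f"fraction {fraction!r} needs >= 2 replicates per stage "
            f"(found {va.shape[1]} at {stage_a}, {vb.shape[1]} at {stage_b})"
        )
    la = np.log2(va + pseudocount)
    lb = np.log2(vb + pseudocount)
    # t on (B − A) so a positive statistic means higher at the later stage
    t, df, p, degenerate = _welch_from_stats(
        lb.mean(axis=1), lb.var(axis=1, ddof=1), lb.shape[1],
        la.mean(axis=1), la.var(axis=1, ddof=1), la.shape[1],
    )
    log2fc = lb.mean(axis=1) - la.mean(axis=1)
    q = bh_adjust(p)
    detected = detection_filter(matrix, fraction, detection_threshold)
    table = pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "statistic": t,
            "p_value": p,
            "q_value": q,
            "detected_A": detected["detected_A"].to_numpy(),
            "detected_B": detected["detected_B"].to_numpy(),
            "degenerate": degenerate,
        },
        index=matrix.isoform_ids,
    )
    res = ContrastResult(fraction=fraction, stage_a=stage_a, stage_b=stage_b,
                         alpha=alpha, table=table)
    table["direction"] = res.directions(alpha)
    res.table = table[list(CONTRAST_COLUMNS)]
    return res


def contrast_to_frame(result: ContrastResult) -> pd.DataFrame:
    """Flatten a ContrastResult for TSV export."""
    out = result.table.reset_index(names="isoform_id")
    out.insert(1, "fraction", result.fraction)
    return out
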