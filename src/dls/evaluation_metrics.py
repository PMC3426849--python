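"""Precision / recall / F-beta counts shared across modules.

Kept separate from the evaluation harness so the classifier can use the
metric without a circular import.
"""

from __future__ import annotations


def precision_recall_fbeta(
    tp: float, fp: float, fn: float, beta: float = 2.0
) -> tuple[float, float, float]:
    """Precision, recall and the precision-weighted F-beta.

    ``f_beta = (1 + beta^2) * P * R / (beta^2 * R + P)`` — beta > 1
    up-weights *precision* (favouring accurate models over high-recall
    ones), which is the mirror image of the common recall-weighted
    convention.  Degenerate denominators yield 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    denom = beta**2 * recall + precision
    f_beta = (1 + beta**2) * precision * recall / denom if denom > 0 else 0.0
    return precision, recall, f_beta
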