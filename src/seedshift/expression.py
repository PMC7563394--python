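"""Tissue-expression normalization and brain-enrichment ranking.

Raw TPM-like values are normalized as ``10 * log10(x + pseudocount)``;
with the default pseudocount of 1 a raw 0 maps to exactly 0 and the scale
is decibel-like (9 TPM -> 10, 99 TPM -> 20).  Brain enrichment per gene is
the ratio of pseudocount-stabilized mean expression in brain tissues to the
mean elsewhere, computed on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

#: GTEx-style brain tissue labels (13 of the 53 sampled tissues).
DEFAULT_BRAIN_TISSUES: tuple[str, ...] = (
    "Brain - Amygdala",
    "Brain - Anterior cingulate cortex (BA24)",
    "Brain - Caudate (basal ganglia)",
    "Brain - Cerebellar Hemisphere",
    "Brain - Cerebellum",
    "Brain - Cortex",
    "Brain - Frontal Cortex (BA9)",
    "Brain - Hippocampus",
    "Brain - Hypothalamus",
    "Brain - Nucleus accumbens (basal ganglia)",
    "Brain - Putamen (basal ganglia)",
    "Brain - Spinal cord (cervical c-1)",
    "Brain - Substantia nigra",
)


@dataclass
class NormalizedMatrix(ExpressionMatrix):
    """An ExpressionMatrix on the 10*log10(x + pseudocount) scale."""

    pseudocount: float = 1.0

    def __post_init__(self):
        # values may legitimately be 0 (raw 0, pseudocount 1) but never NaN
        if self.values.isna().any().any():
            raise ValueError("normalized matrix contains NaN")


def normalize_expression(m: ExpressionMatrix, pseudocount: float = 1.0
                         ) -> NormalizedMatrix:
    """Elementwise ``10 * log10(x + pseudocount)``; labels preserved."""
    arr = m.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("expression values must be non-negative")
    norm = 10.0 * np.log10(arr + pseudocount)
    return NormalizedMatrix(
        values=pd.DataFrame(norm, index=m.values.index, columns=m.values.columns),
        brain_tissues=m.brain_tissues, pseudocount=pseudocount,
    )


def brain_enrichment_rank(m: ExpressionMatrix, pseudocount: float = 1.0
                          ) -> pd.DataFrame:
    """Rank genes by mean brain / mean non-brain expression ratio.

    Returns a DataFrame indexed by gene with columns ``mean_brain``,
    ``mean_nonbrain`` and ``ratio``, sorted by descending ratio with ties
    broken by gene label.  Means are computed on the raw scale;
    ``ratio = (mean_brain + eps) / (mean_nonbrain + eps)`` with
    ``eps = pseudocount``.
    """
    if not m.brain_tissues:
        raise ValueError("no brain tissue flags present")
    brain = list(m.brain_tissues)
    nonbrain = [t for t in m.tissues if t not in m.brain_tissues]
    if not nonbrain:
        raise ValueError("ranking requires at least one non-brain tissue")
    mean_brain = m.values[brain].mean(axis=1)
    mean_nonbrain = m.values[nonbrain].mean(axis=1)
    ratio = (mean_brain + pseudocount) / (mean_nonbrain + pseudocount)
    out = pd.DataFrame({"mean_brain": mean_brain,
                        "mean_nonbrain": mean_nonbrain,
                        "ratio": ratio})
    out = out.sort_values(["ratio"], ascending=False, kind="mergesort")
    # deterministic tie-break by gene label within equal ratios
    out["_gene"] = out.index
    out = (out.sort_values(["ratio", "_gene"], ascending=[False, True],
                           kind="mergesort").drop(columns="_gene"))
    return out
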