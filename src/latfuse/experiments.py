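"""Reusable layer-sweep harness.

Re-runs the fusion pipeline over a range of decomposition depths N and
reports the four quality metrics per N, together with the mechanical
conservation error of each decomposition.  The qualitative trends (e.g.
whether information transfer keeps improving beyond two layers) are
data-dependent and are reported, not asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .features import FeatureExtractor
from .fusion import FusionConfig, fuse_pair
from .metrics import evaluate_all

__all__ = ["SweepRow", "layer_sweep"]


@dataclass(frozen=True)
class SweepRow:
    """Metrics for one (pair, N) cell of the sweep."""

    pair_index: int
    layers: int
    q_te: float
    q_g: float
    q_c: float
    q_cb: float
    conservation_error: float  # relative Frobenius error of each stack, maxed over the two sources


def layer_sweep(
    pairs: "list[tuple[np.ndarray, np.ndarray]]",
    n_values: "list[int]" = (1, 2, 3, 4),
    cfg: FusionConfig | None = None,
    extractor: FeatureExtractor | None = None,
) -> "list[SweepRow]":
    """Fuse every grayscale pair at every decomposition depth.

    Returns one row per (pair, N) with the four metrics computed on the
    unclipped fused matrix and the decomposition conservation error.
    """
    if cfg is None:
        cfg = FusionConfig()
    rows: list[SweepRow] = []
    for idx, (a, b) in enumerate(pairs):
        for n in n_values:
            res = fuse_pair(a, b, replace(cfg, layers=n), extractor=extractor)
            report = evaluate_all(a, b, res.fused_raw)
            cons = max(
                float(np.linalg.norm(st.reconstruct() - src) / max(np.linalg.norm(src), 1e-300))
                for st, src in ((res.stack_a, np.asarray(a, float)), (res.stack_b, np.asarray(b, float)))
            )
            rows.append(
                SweepRow(
                    pair_index=idx,
                    layers=n,
                    q_te=report.q_te,
                    q_g=report.q_g,
                    q_c=report.q_c,
                    q_cb=report.q_cb,
                    conservation_error=cons,
                )
            )
    return rows
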