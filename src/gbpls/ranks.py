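"""SNP ranking by outer-weight magnitude, shared by both GBPLS variants."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["rank_abs_weights", "snp_ranks"]


def rank_abs_weights(weights: np.ndarray) -> np.ndarray:
    """Rank 1 = largest |weight|; ties get the mean of the tied ranks."""
    return rankdata(-np.abs(np.asarray(weights, dtype=float)), method="average")


def snp_ranks(weights: dict[str, np.ndarray],
              snp_ids: dict[str, list[str]],
              selected: list[str]) -> dict[str, dict[str, float]]:
    """Per selected gene, map each member SNP to its outer-weight rank."""
    out: dict[str, dict[str, float]] = {}
    for gid in selected:
        if gid not in weights:
            raise KeyError(f"gene {gid!r} was not fitted")
        r = rank_abs_weights(weights[gid])
        out[gid] = {sid: float(rk) for sid, rk in zip(snp_ids[gid], r)}
    return out
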