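"""Cross-tissue eQTL sharing: Storey's pi1 and fixed-pair replication.

Given the (feature, variant) pairs significant in a discovery tissue, the
replication tissue's nominal p-values at those exact pairs estimate how many
are true associations there: pi1 = 1 - pi0, with pi0 from Storey's
lambda-grid smoother. Fixed-pair replication instead re-declares
significance within the restricted pair set at a chosen FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cis_eqtl import LAMBDA_GRID, qvalues, storey_pi0

log = logging.getLogger(__name__)

__all__ = ["SharingEstimate", "pi1", "replicate_at_fixed_pairs"]


@dataclass
class SharingEstimate:
    pi1: float
    pi0: float
    n_pairs: int
    lambda_grid: np.ndarray = field(default_factory=lambda: LAMBDA_GRID.copy(), repr=False)


def pi1(replication_ps: np.ndarray) -> SharingEstimate:
    """Estimated fraction of shared (true) associations among replication p-values."""
    p = np.asarray(replication_ps, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) < 50:
        warnings.warn(f"only {len(p)} pairs: pi1 has wide uncertainty", stacklevel=2)
    pi0 = storey_pi0(p)
    return SharingEstimate(pi1=float(np.clip(1.0 - pi0, 0.0, 1.0)), pi0=pi0, n_pairs=len(p))


def replicate_at_fixed_pairs(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Significance re-evaluation at the discovery-significant pairs.

    Both frames need feature_id, variant_id; ``replication`` additionally
    p_nominal. Pairs are joined on (feature_id, variant_id); duplicate pair
    keys are an alignment error, unmatched pairs are logged and excluded.
    FDR correction runs within the restricted pair set only.
    """
    for name, df in (("discovery", discovery), ("replication", replication)):
        if df.duplicated(["feature_id", "variant_id"]).any():
            raise ValueError(f"duplicate (feature, variant) pairs in {name} set")
    merged = discovery[["feature_id", "variant_id"]].merge(
        replication, on=["feature_id", "variant_id"], how="left", indicator=True
    )
    unmatched = merged["_merge"] != "both"
    if unmatched.any():
        log.info("%d discovery pair(s) absent from the replication set; excluded", int(unmatched.sum()))
    merged = merged[~unmatched].drop(columns="_merge").reset_index(drop=True)
    if merged.empty:
        return merged.assign(q_value=pd.Series(dtype=float))
    merged["q_value"] = qvalues(merged["p_nominal"].to_numpy())
    return merged[merged["q_value"] < fdr].reset_index(drop=True)
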