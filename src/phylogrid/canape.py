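"""CANAPE: categorical analysis of neo- and paleo-endemism.

Two-step decision tree over the empirical quantiles from the structured
null:

1. Candidacy — a cell is endemism-significant if PE on the original tree
   OR PE on the equal-branch-length comparison tree sits in the upper
   one-tailed alpha (default 0.05) of its null distribution; otherwise
   ``not_significant``.
2. Among candidates, the RPE quantile decides the flavor: upper tail
   (default per-tail 0.025) → ``paleo`` (range-restricted long branches),
   lower tail → ``neo`` (range-restricted short branches), else ``mixed``.
   Mixed cells whose PE is extreme on both trees (both quantiles ≥
   1 - alpha_super, default 0.01) are promoted to ``super``.

Per-cell randomization quantiles are used as-is (no multiple-testing
correction across cells — the convention for these maps).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .randomization import CellSignificance

__all__ = ["classify_canape", "classify_q", "CATEGORIES"]

CATEGORIES = ("not_significant", "neo", "paleo", "mixed", "super")


def classify_q(
    q_pe_orig: np.ndarray, q_pe_alt: np.ndarray, q_rpe: np.ndarray,
    alpha_one_tail: float = 0.05, alpha_rpe_tail: float = 0.025,
    alpha_super: float = 0.01, collapse_super: bool = False,
) -> np.ndarray:
    """Vectorized CANAPE categories from the three quantile arrays.

    A pure function of the q-values and thresholds. NaN in any quantile of
    a candidate cell is fatal (the decision would be undefined).
    """
    q_pe_orig = np.asarray(q_pe_orig, dtype=float)
    q_pe_alt = np.asarray(q_pe_alt, dtype=float)
    q_rpe = np.asarray(q_rpe, dtype=float)
    candidate = (q_pe_orig >= 1 - alpha_one_tail) | (q_pe_alt >= 1 - alpha_one_tail)
    if np.isnan(q_rpe[candidate]).any() or np.isnan(q_pe_orig[candidate]).any() \
            or np.isnan(q_pe_alt[candidate]).any():
        raise ValueError("missing quantile for a candidate cell")
    cat = np.full(q_rpe.shape, "not_significant", dtype=object)
    paleo = candidate & (q_rpe >= 1 - alpha_rpe_tail)
    neo = candidate & (q_rpe <= alpha_rpe_tail)
    mixed = candidate & ~paleo & ~neo
    super_ = mixed & (q_pe_orig >= 1 - alpha_super) & (q_pe_alt >= 1 - alpha_super)
    cat[mixed] = "mixed"
    cat[paleo] = "paleo"
    cat[neo] = "neo"
    if not collapse_super:
        cat[super_] = "super"
    return cat


def classify_canape(
    sig: CellSignificance,
    alpha_one_tail: float = 0.05, alpha_rpe_tail: float = 0.025,
    alpha_super: float = 0.01, collapse_super: bool = False,
) -> pd.DataFrame:
    """CANAPE classification of every analyzable cell.

    Returns a DataFrame indexed by cell_id with the category and the three
    quantiles it was derived from (q_PE_orig, q_PE_alt, q_RPE).
    """
    qf = sig.q_frame
    for col in ("PE_orig", "PE_alt", "RPE"):
        if col not in qf.columns:
            raise ValueError(f"significance table lacks {col}")
    cats = classify_q(
        qf["PE_orig"].to_numpy(), qf["PE_alt"].to_numpy(), qf["RPE"].to_numpy(),
        alpha_one_tail=alpha_one_tail, alpha_rpe_tail=alpha_rpe_tail,
        alpha_super=alpha_super, collapse_super=collapse_super,
    )
    return pd.DataFrame(
        {"category": cats,
         "q_PE_orig": qf["PE_orig"], "q_PE_alt": qf["PE_alt"],
         "q_RPE": qf["RPE"]},
        index=qf.index,
    )
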