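"""Random-gene null-ratio enrichment.

Given a gene list (e.g. the PLS1+ set) and labelled gene classes
(synthetic cell types or cortical layers), the enrichment statistic for a
class is the fraction of the list falling in the class.  The null is the
same fraction for size-matched random draws from the background universe;
enrichment and depletion p-values use the +1 permutation convention and
are BH-FDR corrected across classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mindgrad.group_contrast import bh_fdr


def null_ratio_enrichment(
    gene_set,
    classes: pd.DataFrame,
    background,
    n_null: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-class enrichment of ``gene_set`` against random gene draws.

    ``classes`` is a DataFrame with columns ``gene_id`` and ``class_id``
    (a gene may carry several class memberships across rows).  Returns a
    DataFrame per class with the observed ratio, the null mean/quantiles,
    and enrichment/depletion p and q values.
    """
    gene_set = list(dict.fromkeys(gene_set))
    background = list(dict.fromkeys(background))
    if not gene_set:
        raise ValueError("gene_set is empty")
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    missing = set(gene_set) - set(background)
    if missing:
        raise ValueError(f"gene_set not contained in background: {sorted(missing)[:5]}")

    bg_index = {g: i for i, g in enumerate(background)}
    n_bg = len(background)
    class_ids = sorted(classes["class_id"].unique())
    # indicator matrix: background genes x classes
    member = np.zeros((n_bg, len(class_ids)), dtype=bool)
    col_of = {c: j for j, c in enumerate(class_ids)}
    for gid, cid in zip(classes["gene_id"], classes["class_id"]):
        if gid in bg_index:
            member[bg_index[gid], col_of[cid]] = True

    set_idx = np.array([bg_index[g] for g in gene_set])
    m = len(set_idx)
    observed = member[set_idx].sum(axis=0) / m

    rng = np.random.default_rng(seed)
    null = np.empty((n_null, len(class_ids)))
    for b in range(n_null):
        draw = rng.choice(n_bg, size=m, replace=False)
        null[b] = member[draw].sum(axis=0) / m

    p_enrich = (1.0 + np.sum(null >= observed[None, :], axis=0)) / (1.0 + n_null)
    p_deplete = (1.0 + np.sum(null <= observed[None, :], axis=0)) / (1.0 + n_null)
    return pd.DataFrame(
        {
            "class_id": class_ids,
            "ratio": observed,
            "null_mean": null.mean(axis=0),
            "null_q025": np.quantile(null, 0.025, axis=0),
            "null_q975": np.quantile(null, 0.975, axis=0),
            "p_enrich": p_enrich,
            "q_enrich": bh_fdr(p_enrich),
            "p_deplete": p_deplete,
            "q_deplete": bh_fdr(p_deplete),
        }
    )
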