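"""Validation against an independent individual-level expression cohort.

The pooled-array calls are compared with a large individual-level cohort
(253 males / 212 females in the original validation set): per-gene log2
male/female mean-expression ratios with Welch t-tests, the Pearson
correlation of log2 ratios between cohorts, a 16-vs-16 subsampling
permutation null for that correlation, and a directional concordance count
among the genes significant in the validation cohort.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MALE = "male"
FEMALE = "female"


def _split_by_sex(values: pd.DataFrame, sex_labels: pd.Series):
    males = values.loc[:, sex_labels[values.columns] == MALE]
    females = values.loc[:, sex_labels[values.columns] == FEMALE]
    return males, females


def mf_ratio_table(
    values: pd.DataFrame,
    sex_labels: pd.Series,
    gene_symbols: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene log2 male/female mean ratio with Welch two-tailed t p-values.

    ``values`` is a genes x individuals matrix on the linear scale; means are
    taken per sex before the log2 ratio.  When ``gene_symbols`` maps probes
    to (possibly duplicated) symbols, only the probe with the lowest p-value
    is kept per symbol.
    """
    males, females = _split_by_sex(values, sex_labels)
    if males.shape[1] < 2 or females.shape[1] < 2:
        raise ValueError("need at least 2 individuals per sex")
    m = males.to_numpy(dtype=float)
    f = females.to_numpy(dtype=float)
    ratio = np.log2(m.mean(axis=1) / f.mean(axis=1))
    t, p = stats.ttest_ind(m, f, axis=1, equal_var=False)
    out = pd.DataFrame(
        {"log2_ratio": ratio, "p_value": p},
        index=pd.Index(values.index, name="gene"),
    )
    if gene_symbols is not None:
        out["gene"] = gene_symbols.reindex(out.index)
        out = (
            out.sort_values("p_value")
            .drop_duplicates("gene", keep="first")
            .set_index("gene")
            .sort_index()
        )
    return out


def cohort_correlation(
    ratios_a: pd.DataFrame,
    ratios_b: pd.DataFrame,
    gene_subset: Sequence[str] | None = None,
    exclude: Sequence[str] | None = None,
) -> float:
    """Pearson correlation of two cohorts' log2 ratios over common genes."""
    common = ratios_a.index.intersection(ratios_b.index)
    if gene_subset is not None:
        common = common.intersection(pd.Index(gene_subset))
    if exclude:
        common = common.difference(pd.Index(exclude))
    if len(common) < 3:
        raise ValueError("need at least 3 common genes")
    a = ratios_a.loc[common, "log2_ratio"]
    b = ratios_b.loc[common, "log2_ratio"]
    return float(stats.pearsonr(a, b)[0])


def correlation_permutation_null(
    values: pd.DataFrame,
    sex_labels: pd.Series,
    n_sub_male: int = 16,
    n_sub_female: int = 16,
    genes: Sequence[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Within-cohort subsampling null for the cross-cohort correlation.

    Each round draws n_sub_male + n_sub_female random individuals, computes
    log2 male/female ratios from the subsample and, separately, from all
    remaining individuals, and records their Pearson correlation over the
    gene set.  Returns the n_perm correlation coefficients.
    """
    if genes is not None:
        values = values.loc[list(genes)]
    males, females = _split_by_sex(values, sex_labels)
    if n_sub_male >= males.shape[1] - 1 or n_sub_female >= females.shape[1] - 1:
        raise ValueError("subsample must leave at least 2 individuals per sex")
    m = males.to_numpy(dtype=float)
    f = females.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    for i in range(n_perm):
        mi = rng.choice(m.shape[1], size=n_sub_male, replace=False)
        fi = rng.choice(f.shape[1], size=n_sub_female, replace=False)
        m_mask = np.zeros(m.shape[1], dtype=bool)
        f_mask = np.zeros(f.shape[1], dtype=bool)
        m_mask[mi] = True
        f_mask[fi] = True
        sub = np.log2(m[:, m_mask].mean(axis=1) / f[:, f_mask].mean(axis=1))
        rest = np.log2(m[:, ~m_mask].mean(axis=1) / f[:, ~f_mask].mean(axis=1))
        out[i] = np.corrcoef(sub, rest)[0, 1]
    return out


def concordance(
    calls: pd.DataFrame,
    ratios: pd.DataFrame,
    p_thresh: float = 0.05,
) -> dict:
    """Directional agreement with the validation cohort.

    Among genes significant in the validation cohort (ratio p < p_thresh),
    counts those whose log2-ratio sign matches the call direction.  ``calls``
    is indexed or keyed by gene symbol with a ``direction`` column.
    """
    c = calls.set_index("gene_symbol") if "gene_symbol" in calls.columns else calls
    common = c.index.intersection(ratios.index)
    if len(common) == 0:
        raise ValueError("no genes in common")
    sig = ratios.loc[common]
    sig = sig[sig["p_value"] < p_thresh]
    call_dir = c.loc[sig.index, "direction"]
    cohort_dir = np.where(sig["log2_ratio"] > 0, "male", "female")
    same = (call_dir.to_numpy() == cohort_dir)
    n_sig = int(len(sig))
    n_same = int(same.sum())
    return {
        "n_common": int(len(common)),
        "n_significant": n_sig,
        "n_same_direction": n_same,
        "percent_concordant": round(100.0 * n_same / n_sig) if n_sig else float("nan"),
    }
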