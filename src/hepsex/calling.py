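"""Sex-bias calling: signed fold-changes, composite scores, thresholds, FDRs.

A gene is called sex-biased when it jointly satisfies three criteria on the
16 replicate arrays: mean |fold change| > 1.15, p < 0.005, and a composite
array score >= 14 (relaxable to 13 or 12).  The composite score is the
number of arrays, out of 16, agreeing on the direction of the male/female
ratio.  Apparent false-discovery rates come from two nulls: a one-sided
binomial tail on the score among fold-change passers, and the p-value
threshold applied to the tested probe count.
"""

from __future__ import annotations

from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCORE_LEVELS = (14, 13, 12)

#: annotation categories, highest priority first
CATEGORY_PRIORITY = ("RefSeq", "mRNA", "Ensembl", "spliced_EST", "unspliced_EST", "unmapped")


def signed_fold_change(ratio):
    """Signed fold change of a positive male/female linear ratio.

    Ratios > 1 map to themselves (male-biased, positive); ratios < 1 map to
    the negative inverse (female-biased); a ratio of exactly 1 maps to 1 by
    convention.  Satisfies FC(1/r) = -FC(r) for r != 1 and |FC| >= 1.
    """
    arr = np.asarray(ratio, dtype=float)
    if (arr <= 0).any():
        raise ValueError("ratio must be positive")
    out = np.where(arr >= 1.0, arr, -1.0 / arr)
    return float(out) if np.isscalar(ratio) or arr.ndim == 0 else out


def composite_score(ratios: Sequence[float], log_scale: bool = False) -> tuple[int, str]:
    """Replicate sign-agreement score and direction for one probe.

    ``score = max(n_up, n_down)`` where n_up counts arrays with ratio > 1
    (log ratio > 0 when ``log_scale``); ratios exactly at 1 (0) and missing
    values count for neither side.  Direction is male when n_up > n_down,
    female when n_down > n_up, tied otherwise.
    """
    arr = np.asarray(ratios, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no usable ratios")
    null = 0.0 if log_scale else 1.0
    n_up = int((arr > null).sum())
    n_down = int((arr < null).sum())
    score = max(n_up, n_down)
    direction = "male" if n_up > n_down else "female" if n_down > n_up else "tied"
    return score, direction


def composite_score_frame(ratios: pd.DataFrame, log_scale: bool = False) -> pd.DataFrame:
    """Vectorised composite scores for a probes x arrays ratio matrix."""
    arr = ratios.to_numpy(dtype=float)
    null = 0.0 if log_scale else 1.0
    with np.errstate(invalid="ignore"):
        n_up = (arr > null).sum(axis=1)
        n_down = (arr < null).sum(axis=1)
    score = np.maximum(n_up, n_down)
    direction = np.where(n_up > n_down, "male", np.where(n_down > n_up, "female", "tied"))
    return pd.DataFrame(
        {"score": score, "direction": direction, "n_up": n_up, "n_down": n_down},
        index=ratios.index,
    )


# ---------------------------------------------------------------------------
# threshold calling
# ---------------------------------------------------------------------------


def call_sex_biased(
    stats: pd.DataFrame,
    fc_thresh: float = 1.15,
    p_thresh: float = 0.005,
    score_levels: Iterable[int] = SCORE_LEVELS,
    min_arrays: int = 14,
) -> pd.DataFrame:
    """Apply the combined calling criteria at nested score levels.

    ``stats`` needs fold_change, p_value, composite_score and direction
    columns (n_arrays optional).  A probe passes a level s when
    |FC| > fc_thresh, p < p_thresh and score >= s; ``pass_level`` records
    the most stringent level satisfied ("none" otherwise).  Probes observed
    on fewer than ``min_arrays`` arrays are never called.
    """
    if fc_thresh <= 0 or p_thresh <= 0:
        raise ValueError("thresholds must be positive")
    levels = sorted(set(score_levels), reverse=True)
    out = stats.copy()
    base = (out["fold_change"].abs() > fc_thresh) & (out["p_value"] < p_thresh)
    if "n_arrays" in out:
        base &= out["n_arrays"] >= min_arrays
    pass_level = np.full(len(out), "none", dtype=object)
    for level in sorted(levels):  # ascending so stricter levels overwrite
        hit = base & (out["composite_score"] >= level)
        pass_level[hit.to_numpy()] = f"score{level}"
    out["pass_level"] = pass_level
    return out


def annotate_and_deduplicate(
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    max_genome_hits: int = 3,
) -> pd.DataFrame:
    """Attach probe annotations and collapse to one probe per gene/direction.

    Rules: when a probe has several annotation rows the highest-priority
    category wins (RefSeq > mRNA > Ensembl > spliced EST > unspliced EST);
    probes that are unmapped, or hit more than ``max_genome_hits`` genomic
    sites without an mRNA-level match, are dropped; per gene symbol and
    direction only the probe with the highest composite score is retained
    (ties: lowest p, then probe id) while opposite-direction probes of the
    same gene are all kept.  Probes with more than one genome hit stay in the
    calls but are flagged ``single_hit=False`` for chromosome analyses.
    """
    required = {"probe_id", "gene_symbol", "category", "n_genome_hits"}
    if not required <= set(annotation.columns):
        raise ValueError(f"annotation lacks columns: {sorted(required - set(annotation.columns))}")
    unknown = set(calls.index) - set(annotation["probe_id"])
    if unknown:
        raise ValueError(f"no annotation for probes: {sorted(unknown)[:5]}")

    rank = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}
    ann = annotation.copy()
    ann["_rank"] = ann["category"].map(rank)
    if ann["_rank"].isna().any():
        bad = sorted(set(ann.loc[ann["_rank"].isna(), "category"]))
        raise ValueError(f"unknown annotation categories: {bad}")
    ann = ann.sort_values(["probe_id", "_rank"]).drop_duplicates("probe_id", keep="first")

    df = calls.merge(ann.set_index("probe_id"), left_index=True, right_index=True, how="left")
    df.index.name = "probe_id"
    df = df.reset_index()

    mapped = df["category"] != "unmapped"
    mrna_level = df["category"].isin(("RefSeq", "mRNA"))
    df = df[mapped & ~((df["n_genome_hits"] > max_genome_hits) & ~mrna_level)]

    df = df.copy()
    df["single_hit"] = df["n_genome_hits"] <= 1
    # fall back to the accession (or probe id) when no gene symbol is assigned
    key = df["gene_symbol"].where(
        df["gene_symbol"].notna() & (df["gene_symbol"] != "-"),
        df.get("accession", df["probe_id"]),
    )
    df["_gene_key"] = key
    df = df.sort_values(
        ["_gene_key", "direction", "composite_score", "p_value", "probe_id"],
        ascending=[True, True, False, True, True],
    )
    df = df.drop_duplicates(["_gene_key", "direction"], keep="first")
    return df.drop(columns=["_rank", "_gene_key"]).set_index("probe_id")


# ---------------------------------------------------------------------------
# apparent FDRs
# ---------------------------------------------------------------------------


def binomial_score_tail(n_arrays: int, score_thresh: int) -> float:
    """One-sided null probability of a score >= threshold: sum C(n,k)/2^n."""
    if score_thresh > n_arrays:
        raise ValueError("score_thresh cannot exceed n_arrays")
    return sum(comb(n_arrays, k) for k in range(max(score_thresh, 0), n_arrays + 1)) / 2**n_arrays


def apparent_fdr_binomial(
    n_fc_passing: int, n_arrays: int, score_thresh: int, n_observed_passing: int
) -> tuple[int, float]:
    """Expected-by-chance count and apparent FDR under the binomial score null.

    expected = round(n_fc_passing * P(score >= threshold)) with the one-sided
    binomial tail; FDR = expected / n_observed_passing.  With the study's
    numbers (4,734 fold-change passers, score >= 14 of 16, 1,295 observed)
    this gives 10 expected and an FDR of 0.77%.
    """
    if n_fc_passing <= 0 or n_arrays <= 0:
        raise ValueError("counts must be positive")
    if n_observed_passing <= 0:
        raise ValueError("n_observed_passing must be positive")
    expected = round(n_fc_passing * binomial_score_tail(n_arrays, score_thresh))
    return expected, expected / n_observed_passing


def apparent_fdr_pvalue(
    n_tested: int, p_thresh: float, n_observed_passing: int
) -> tuple[int, float]:
    """Expected-by-chance count and apparent FDR under the p-value null.

    expected = round(n_tested * p_thresh); FDR = expected / observed.
    """
    if not 0 < p_thresh < 1:
        raise ValueError("p_thresh must lie in (0, 1)")
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if n_observed_passing <= 0:
        raise ValueError("n_observed_passing must be positive")
    expected = round(n_tested * p_thresh)
    return expected, expected / n_observed_passing


def direction_summary(calls: pd.DataFrame) -> dict:
    """Counts and integer-rounded percentages of male- vs female-biased calls."""
    if len(calls) == 0:
        raise ValueError("empty call table")
    if "pass_level" in calls:
        calls = calls[calls["pass_level"] != "none"]
    if len(calls) == 0:
        raise ValueError("no passing calls to summarise")
    n_male = int((calls["direction"] == "male").sum())
    n_female = int((calls["direction"] == "female").sum())
    total = n_male + n_female
    return {
        "n_male": n_male,
        "n_female": n_female,
        "n_total": total,
        "percent_male": round(100.0 * n_male / total),
        "percent_female": round(100.0 * n_female / total),
    }
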