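"""Chromosomal distribution of sex-biased genes and X-inactivation escape.

Per-chromosome enrichment is tested with a 2x2 chi-square (this chromosome
vs the rest x male- vs female-biased), without continuity correction and
with an automatic switch to Fisher's exact test when an expected cell drops
below 5; a goodness-of-fit mode against the genome-wide split is also
provided since the study describes its test only as a comparison "to the
overall distribution".  Only genes whose probes hit a single genomic site
enter these analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

TIERS = ((0.001, "0.001"), (0.01, "0.01"), (0.05, "0.05"))


def _tier(p: float) -> str:
    for cut, label in TIERS:
        if p < cut:
            return label
    return "ns"


def chrom_test_from_counts(
    n_male: int, n_female: int, total_male: int, total_female: int, mode: str = "two_by_two"
) -> tuple[float, float]:
    """Chi-square statistic and p-value for one chromosome's male/female split.

    ``two_by_two`` contrasts the chromosome against the rest of the genome;
    ``goodness_of_fit`` compares the chromosome's counts with the
    genome-wide male/female proportions.  Fisher's exact test replaces the
    2x2 chi-square when any expected cell is below 5 (statistic NaN).
    """
    if mode == "two_by_two":
        rest_m, rest_f = total_male - n_male, total_female - n_female
        table = np.array([[n_male, n_female], [rest_m, rest_f]])
        if (table < 0).any():
            raise ValueError("chromosome counts exceed genome totals")
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            return float("nan"), float("nan")
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            return float("nan"), float(stats.fisher_exact(table)[1])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    if mode == "goodness_of_fit":
        n = n_male + n_female
        if n == 0:
            return float("nan"), float("nan")
        pm = total_male / (total_male + total_female)
        expected = np.array([n * pm, n * (1 - pm)])
        if (expected < 5).any():
            p = float(stats.binomtest(n_male, n, pm).pvalue)
            return float("nan"), p
        chi2, p = stats.chisquare([n_male, n_female], expected)
        return float(chi2), float(p)
    raise ValueError(f"unknown mode: {mode}")


def chrom_distribution_test(
    calls: pd.DataFrame, mode: str = "two_by_two"
) -> pd.DataFrame:
    """Per-chromosome sex-bias counts with enrichment tests.

    ``calls`` needs ``chrom`` and ``direction`` columns; rows flagged
    ``single_hit=False`` are excluded.  Returns one row per chromosome with
    counts, the female/male ratio, the test statistic, p-value, significance
    tier and the enriched direction (relative to the genome-wide split).
    """
    df = calls
    if "single_hit" in df:
        df = df[df["single_hit"].astype(bool)]
    df = df[df["direction"].isin(("male", "female")) & df["chrom"].notna()]
    if len(df) == 0:
        raise ValueError("no mapped sex-biased calls")
    total_m = int((df["direction"] == "male").sum())
    total_f = int((df["direction"] == "female").sum())

    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        n_m = int((sub["direction"] == "male").sum())
        n_f = int((sub["direction"] == "female").sum())
        if n_m + n_f == 0:
            rows.append(
                {"chrom": chrom, "n_male_biased": 0, "n_female_biased": 0,
                 "female_to_male_ratio": np.nan, "chi2": np.nan, "p_value": np.nan,
                 "tier": "ns", "enriched_direction": "none"}
            )
            continue
        chi2, p = chrom_test_from_counts(n_m, n_f, total_m, total_f, mode=mode)
        frac_f = n_f / (n_m + n_f)
        genome_frac_f = total_f / (total_m + total_f)
        rows.append(
            {
                "chrom": chrom,
                "n_male_biased": n_m,
                "n_female_biased": n_f,
                "female_to_male_ratio": n_f / n_m if n_m else np.inf,
                "chi2": chi2,
                "p_value": p,
                "tier": _tier(p) if np.isfinite(p) else "ns",
                "enriched_direction": "female" if frac_f > genome_frac_f else
                                      "male" if frac_f < genome_frac_f else "none",
            }
        )
    out = pd.DataFrame(rows).set_index("chrom")
    out.attrs["total_male"] = total_m
    out.attrs["total_female"] = total_f
    return out


def escape_concordance(
    panel: pd.DataFrame, required_score: int = 16
) -> tuple[int, list[str]]:
    """Count panel genes concordant with escape from X inactivation.

    A gene is concordant when its liver expression is female-biased
    (negative signed fold-change) with a composite array score at or above
    ``required_score``.  ``panel`` needs gene_symbol, fold_change and
    composite_score columns; returns the count and the concordant symbols.
    """
    required_cols = {"gene_symbol", "fold_change", "composite_score"}
    if not required_cols <= set(panel.columns):
        raise ValueError(f"panel lacks columns: {sorted(required_cols - set(panel.columns))}")
    hit = (panel["fold_change"] < 0) & (panel["composite_score"] >= required_score)
    return int(hit.sum()), list(panel.loc[hit, "gene_symbol"])
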