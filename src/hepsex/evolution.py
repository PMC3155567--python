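"""Protein evolutionary-rate analysis for sex-biased vs non-sex-biased genes.

dN/dS for pairwise codon alignments is estimated by Nei-Gojobori (1986)
counting with Jukes-Cantor multiple-hit correction: synonymous and
non-synonymous site counts are averaged over the two sequences, observed
differences at multi-substitution codons are averaged over all substitution
orderings that avoid stop-codon intermediates, and the two proportions are
corrected with d = -3/4 ln(1 - 4p/3).  Externally computed maximum-likelihood
ratios can be substituted via a plain ``gene_id, dnds`` table.

Group comparisons (male-biased vs female-biased vs non-sex-biased orthologs)
use a difference-of-medians permutation test that resamples two disjoint gene
sets of the observed sizes from a pooled background; the one-sided p-value is
Nd / n_perm, the fraction of resampled differences at or above the observed
one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gencode import CODON_TO_AA, NUCLEOTIDES, codon_site_counts, is_stop

_VALID_NT = set(NUCLEOTIDES)


@dataclass
class DnDsRecord:
    """Per ortholog pair: substitution rates and their ratio.

    ``ratio`` is present iff ``valid`` (dS > 0 and both Jukes-Cantor
    corrections defined).  ``n_skipped_codons`` counts codons dropped for
    ambiguous characters or gaps.
    """

    gene_id: str
    dn: float
    ds: float
    ratio: float | None
    valid: bool
    group: str | None = None
    n_skipped_codons: int = 0


@dataclass
class PermutationResult:
    observed_median_difference: float
    nd: int
    n_perm: int
    seed: int

    @property
    def p_value(self) -> float:
        return self.nd / self.n_perm


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/non-synonymous difference counts for one codon pair.

    For codons differing at more than one position, counts are averaged with
    equal weight over the substitution orderings whose intermediate codons
    are not stops; if every ordering passes through a stop, all orderings are
    used.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        sd = nd = 0.0
        cur = c1
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if is_stop(nxt) and nxt != c2:
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # all orderings hit a stop; fall back to unrestricted paths
        for order in permutations(diff):
            sd = nd = 0.0
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                    sd += 1.0
                else:
                    nd += 1.0
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Multiple-hit corrected distance d = -3/4 ln(1 - 4p/3); NaN for p >= 3/4."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_counts(seq_a: str, seq_b: str) -> tuple[float, float, float, float, int]:
    """Raw NG86 totals (S, N, Sd, Nd, skipped codons) for an aligned pair."""
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("alignment length must be divisible by 3")
    s_sites = n_sites = s_diff = n_diff = 0.0
    skipped = 0
    for i in range(0, len(seq_a), 3):
        c1, c2 = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (_VALID_NT >= set(c1) and _VALID_NT >= set(c2)):
            skipped += 1  # ambiguous nucleotides or gaps: flagged, not fatal
            continue
        if is_stop(c1) or is_stop(c2):
            if i + 3 == len(seq_a) and c1 == c2:
                continue  # shared terminal stop codon is ignored
            raise ValueError(f"internal stop codon at position {i}")
        s1, n1 = codon_site_counts(c1)
        s2, n2 = codon_site_counts(c2)
        s_sites += 0.5 * (s1 + s2)
        n_sites += 0.5 * (n1 + n2)
        sd, nd = _codon_differences(c1, c2)
        s_diff += sd
        n_diff += nd
    return s_sites, n_sites, s_diff, n_diff, skipped


def ng86_dnds(
    seq_a: str,
    seq_b: str,
    gene_id: str = "",
    group: str | None = None,
) -> DnDsRecord:
    """NG86 dN and dS with Jukes-Cantor correction for one aligned codon pair."""
    s_sites, n_sites, s_diff, n_diff, skipped = ng86_counts(seq_a, seq_b)
    if s_sites == 0 or n_sites == 0:
        raise ValueError("alignment has no usable codons")
    ps = s_diff / s_sites
    pn = n_diff / n_sites
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    valid = math.isfinite(dn) and math.isfinite(ds) and ds > 0.0
    return DnDsRecord(
        gene_id=gene_id,
        dn=dn,
        ds=ds,
        ratio=dn / ds if valid else None,
        valid=valid,
        group=group,
        n_skipped_codons=skipped,
    )


def dnds_table(pairs: Iterable, precomputed: pd.DataFrame | None = None) -> pd.DataFrame:
    """DnDs records for a CodonPairSet, as a DataFrame.

    ``precomputed``, a (gene_id, dnds) table such as codeml output, bypasses
    the NG86 estimator for the genes it covers.
    """
    pre = {}
    if precomputed is not None:
        pre = dict(zip(precomputed["gene_id"], precomputed["dnds"]))
    rows = []
    for pair in pairs.pairs if hasattr(pairs, "pairs") else pairs:
        if pair.gene_id in pre:
            r = float(pre[pair.gene_id])
            rows.append(
                {"gene_id": pair.gene_id, "group": pair.group, "dn": np.nan,
                 "ds": np.nan, "dnds": r, "valid": True, "n_skipped_codons": 0}
            )
            continue
        rec = ng86_dnds(pair.seq_a, pair.seq_b, gene_id=pair.gene_id, group=pair.group)
        rows.append(
            {"gene_id": rec.gene_id, "group": rec.group, "dn": rec.dn, "ds": rec.ds,
             "dnds": rec.ratio if rec.valid else np.nan, "valid": rec.valid,
             "n_skipped_codons": rec.n_skipped_codons}
        )
    return pd.DataFrame(rows)


def aggregate_gene_ratio(
    records: pd.DataFrame, gene_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-gene dN/dS: the median over each gene's valid accession ratios.

    ``gene_map`` maps accession (``gene_id`` in ``records``) to gene symbol;
    without it each record is its own gene.  Genes whose accessions are all
    invalid are excluded and reported with ``valid=False``.
    """
    df = records.copy()
    df["gene"] = (
        df["gene_id"].map(lambda a: gene_map.get(a, a)) if gene_map else df["gene_id"]
    )
    rows = []
    for gene, sub in df.groupby("gene", sort=False):
        valid = sub.loc[sub["valid"].astype(bool), "dnds"].dropna()
        rows.append(
            {
                "gene": gene,
                "dnds": float(valid.median()) if len(valid) else np.nan,
                "n_accessions": len(sub),
                "n_valid": len(valid),
                "valid": len(valid) > 0,
                "group": sub["group"].iloc[0] if "group" in sub else None,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene-set selection and permutation testing
# ---------------------------------------------------------------------------


def select_non_sex_biased(
    human_stats: pd.DataFrame,
    ortholog_stats: pd.DataFrame,
    intensity_min: float = 100.0,
    fc_max: float = 1.01,
) -> list[str]:
    """Liver-expressed genes with no appreciable sex bias in either species.

    Requires signal intensity above ``intensity_min`` in the human data and
    |fold-change| below ``fc_max`` in both species.  Tables must carry
    ``gene``, ``fold_change`` and (human) ``intensity`` columns.
    """
    h = human_stats.set_index("gene")
    o = ortholog_stats.set_index("gene")
    common = h.index.intersection(o.index)
    h, o = h.loc[common], o.loc[common]
    keep = (
        (h["intensity"] > intensity_min)
        & (h["fold_change"].abs() < fc_max)
        & (o["fold_change"].abs() < fc_max)
    )
    return list(common[keep.to_numpy()])


def median_permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    background: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """One-sided difference-of-medians permutation test.

    Each round draws two disjoint random gene sets of sizes |a| and |b| from
    the pooled ``background`` and records the difference of their medians;
    Nd counts rounds with difference >= the observed median(a) - median(b),
    and p = Nd / n_perm (no +1 correction).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    bg = np.asarray(background, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(bg) < len(a) + len(b):
        raise ValueError("background smaller than combined group sizes")
    observed = float(np.median(a) - np.median(b))
    rng = np.random.default_rng(seed)
    na, nb = len(a), len(b)
    nd = 0
    for _ in range(n_perm):
        pick = rng.choice(len(bg), size=na + nb, replace=False)
        diff = np.median(bg[pick[:na]]) - np.median(bg[pick[na:]])
        if diff >= observed:
            nd += 1
    return PermutationResult(
        observed_median_difference=observed, nd=nd, n_perm=n_perm, seed=seed
    )
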