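"""Synthetic cohorts, pooled designs, simulated two-color arrays, and codon pairs.

The generator emulates the study design the rest of the package analyses: a
cohort of 112 male and 112 female liver donors, each sex randomly partitioned
twice into 8 pools of 14, and the 16 pool pairs hybridised on dye-swapped
two-color arrays.  Sex effects are planted on the log10 scale, mostly small
(1.15- to 2-fold) and ~70% female-biased, and per-array measurement noise is
calibrated so the replicate scatter of log10 ratios is about 0.0896.

Nothing here requires external data; every downstream stage of the pipeline
can be exercised against the planted truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gencode import (
    CODON_TO_AA,
    NONSTOP_CODONS,
    codon_site_counts,
    neighbours,
)

MALE = "male"
FEMALE = "female"

#: log10 fold-change range covering the bulk of the effects seen in liver
DEFAULT_EFFECT_RANGE = (math.log10(1.15), math.log10(2.0))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class IndividualExpressionMatrix:
    """Linear-scale expression per gene per individual, with sex labels.

    ``values`` is a genes x samples DataFrame of strictly positive
    fluorescence-scale intensities.  ``truth``, when present, holds one row
    per gene with the planted ``true_log10_sex_effect`` (log10 male/female)
    and an ``is_sex_biased`` flag.
    """

    values: pd.DataFrame
    sex_labels: pd.Series
    truth: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, sex: str) -> list[str]:
        return list(self.sex_labels.index[self.sex_labels == sex])

    def validate(self) -> None:
        if (self.values.values <= 0).any():
            raise ValueError("expression values must be strictly positive")
        if not self.values.columns.equals(self.sex_labels.index):
            raise ValueError("sex_labels must be indexed by sample_ids")
        bad = set(self.sex_labels) - {MALE, FEMALE}
        if bad:
            raise ValueError(f"unknown sex labels: {sorted(bad)}")
        if self.truth is not None:
            if not self.truth.index.equals(self.values.index):
                raise ValueError("truth must have exactly one record per gene")


@dataclass
class PoolDesign:
    """Random partition of each sex into equal-size RNA pools.

    ``members`` maps a pool id (M1..M16, F1..F16 by convention) to the ordered
    sample ids it contains; ``replicate_set`` tags each pool as belonging to
    the first or second independent partition of the same individuals.
    """

    members: dict[str, list[str]]
    pool_size: int
    replicate_set: dict[str, str]

    @property
    def pool_ids(self) -> list[str]:
        return list(self.members)

    def sex_of(self, pool_id: str) -> str:
        return MALE if pool_id.startswith("M") else FEMALE

    def pools_of(self, sex: str, replicate_set: str | None = None) -> list[str]:
        prefix = "M" if sex == MALE else "F"
        out = [p for p in self.members if p.startswith(prefix)]
        if replicate_set is not None:
            out = [p for p in out if self.replicate_set[p] == replicate_set]
        return out


@dataclass
class NoiseSpec:
    """Measurement-noise model for simulated two-color arrays.

    channel_sd_log10
        sd of the lognormal multiplicative noise applied to each channel
        (log10 scale).  The default 0.0617 is calibrated so that, with
        pool-composition variation from the default cohort (individual sd
        0.15, pools of 14) and the additive background, the mean replicate
        scatter of normalized log10 ratios is ~0.0896.
    background
        additive background intensity (fluorescence units) on both channels.
    dye_bias_amplitude
        full range (log10) of the smooth intensity-dependent dye bias applied
        to channel A; 0 disables it.
    dye_bias_center, dye_bias_width
        midpoint and scale (log10 intensity) of the sigmoidal bias curve.
    """

    channel_sd_log10: float = 0.0617
    background: float = 30.0
    dye_bias_amplitude: float = 0.15
    dye_bias_center: float = 2.5
    dye_bias_width: float = 0.5

    def dye_bias_log10(self, mean_intensity: np.ndarray) -> np.ndarray:
        """Monotone-decreasing log10 bias of channel A vs mean intensity."""
        if self.dye_bias_amplitude == 0:
            return np.zeros_like(np.asarray(mean_intensity, dtype=float))
        x = (np.log10(np.asarray(mean_intensity, dtype=float)) - self.dye_bias_center)
        return self.dye_bias_amplitude * (0.5 - 1.0 / (1.0 + np.exp(-x / self.dye_bias_width)))


@dataclass
class TwoColorArraySet:
    """Per-array two-channel probe intensities with pool pairing metadata.

    ``arrays`` has one row per array (array_id, male_pool_id, female_pool_id,
    dye_orientation in {male_in_A, male_in_B}); ``channel_a``/``channel_b``
    are probes x arrays intensity matrices.
    """

    arrays: pd.DataFrame
    channel_a: pd.DataFrame
    channel_b: pd.DataFrame
    background: float = 0.0

    @property
    def probe_ids(self) -> pd.Index:
        return self.channel_a.index

    @property
    def array_ids(self) -> list[str]:
        return list(self.arrays["array_id"])

    def validate(self) -> None:
        if (self.channel_a.values < 0).any() or (self.channel_b.values < 0).any():
            raise ValueError("intensities must be non-negative")
        if not set(self.arrays["dye_orientation"]) <= {"male_in_A", "male_in_B"}:
            raise ValueError("dye_orientation must be male_in_A or male_in_B")


@dataclass
class CodonPair:
    gene_id: str
    seq_a: str
    seq_b: str
    group: str
    flagged: bool = False  # True when a sequence contains ambiguous characters


@dataclass
class CodonPairSet:
    pairs: list[CodonPair] = field(default_factory=list)
    provenance: str = ""

    def by_group(self, group: str) -> list[CodonPair]:
        return [p for p in self.pairs if p.group == group]


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    n_male: int = 112,
    n_female: int = 112,
    n_genes: int = 1000,
    frac_biased: float = 0.05,
    frac_female_biased_of_biased: float = 0.70,
    effect_range_log10: tuple[float, float] = DEFAULT_EFFECT_RANGE,
    indiv_sd_log10: float = 0.15,
    baseline_mean_log10: float = 2.5,
    baseline_sd_log10: float = 0.5,
    seed: int = 0,
) -> IndividualExpressionMatrix:
    """Generate an individual-level expression cohort with planted sex effects.

    A fixed number round(frac_biased * n_genes) of genes receives a sex
    effect whose magnitude is uniform on ``effect_range_log10`` (log10
    male/female); round(frac_female_biased_of_biased * n_biased) of those are
    female-biased (negative effect).  Half the effect is added to males and
    subtracted from females on the log10 scale, keeping the grand mean
    sex-invariant.  Individual biological variability is Gaussian on log10
    with sd ``indiv_sd_log10``.
    """
    if n_male <= 0 or n_female <= 0 or n_genes <= 0:
        raise ValueError("counts must be positive")
    if not 0.0 <= frac_biased <= 1.0:
        raise ValueError("frac_biased must be within [0, 1]")
    if frac_biased > 0:
        if not 0.0 <= frac_female_biased_of_biased <= 1.0:
            raise ValueError("frac_female_biased_of_biased must be within [0, 1]")
        lo, hi = effect_range_log10
        if lo <= 0 or hi < lo:
            raise ValueError("effect_range_log10 must be a positive interval")

    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    samples = [f"M{i + 1:03d}" for i in range(n_male)] + [
        f"F{i + 1:03d}" for i in range(n_female)
    ]
    sex = pd.Series([MALE] * n_male + [FEMALE] * n_female, index=samples, name="sex")

    n_biased = round(frac_biased * n_genes)
    n_female_biased = round(frac_female_biased_of_biased * n_biased)
    biased_idx = rng.choice(n_genes, size=n_biased, replace=False)
    female_idx = rng.choice(biased_idx, size=n_female_biased, replace=False) if n_biased else []

    effect = np.zeros(n_genes)
    if n_biased:
        lo, hi = effect_range_log10
        magnitude = rng.uniform(lo, hi, size=n_biased)
        effect[biased_idx] = magnitude
        effect[np.asarray(female_idx, dtype=int)] *= -1.0

    baseline = rng.normal(baseline_mean_log10, baseline_sd_log10, size=n_genes)
    sex_sign = np.where(np.asarray(sex) == MALE, 0.5, -0.5)  # +effect/2 in males
    log_values = (
        baseline[:, None]
        + effect[:, None] * sex_sign[None, :]
        + rng.normal(0.0, indiv_sd_log10, size=(n_genes, n_male + n_female))
    )
    values = pd.DataFrame(
        10.0 ** log_values, index=pd.Index(genes, name="gene_id"), columns=samples
    )

    truth = pd.DataFrame(
        {
            "true_log10_sex_effect": effect,
            "is_sex_biased": effect != 0.0,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    matrix = IndividualExpressionMatrix(values=values, sex_labels=sex, truth=truth)
    matrix.validate()
    return matrix


def build_pool_design(
    matrix: IndividualExpressionMatrix,
    pool_size: int = 14,
    n_replicate_sets: int = 2,
    seed: int = 0,
) -> PoolDesign:
    """Randomly partition each sex into pools, independently per replicate set.

    Within a replicate set, the pools of one sex are disjoint and exhaustive
    over that sex's samples.  Pool ids follow the M1..M8 (set 1) / M9..M16
    (set 2) convention.
    """
    rng = np.random.default_rng(seed)
    members: dict[str, list[str]] = {}
    replicate_set: dict[str, str] = {}
    for sex, prefix in ((MALE, "M"), (FEMALE, "F")):
        samples = matrix.samples_of(sex)
        if not samples:
            raise ValueError(f"no {sex} samples to pool")
        if len(samples) % pool_size:
            raise ValueError(
                f"{len(samples)} {sex} samples are not divisible by pool_size={pool_size}"
            )
        pools_per_set = len(samples) // pool_size
        counter = 0
        for s in range(n_replicate_sets):
            order = rng.permutation(samples)
            for p in range(pools_per_set):
                counter += 1
                pid = f"{prefix}{counter}"
                members[pid] = list(order[p * pool_size : (p + 1) * pool_size])
                replicate_set[pid] = f"set{s + 1}"
    return PoolDesign(members=members, pool_size=pool_size, replicate_set=replicate_set)


def pool_signal(matrix: IndividualExpressionMatrix, design: PoolDesign) -> pd.DataFrame:
    """Linear-scale pool expression: arithmetic mean over members (equal RNA mass)."""
    missing = {s for m in design.members.values() for s in m} - set(matrix.sample_ids)
    if missing:
        raise ValueError(f"pool members absent from matrix: {sorted(missing)[:5]}")
    return pd.DataFrame(
        {pid: matrix.values[m].mean(axis=1) for pid, m in design.members.items()}
    )


def simulate_arrays(
    matrix: IndividualExpressionMatrix,
    design: PoolDesign,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> TwoColorArraySet:
    """Simulate dye-swapped male-vs-female two-color arrays from a pool design.

    Male pool i is paired with female pool i.  Channel intensity is
    ``pool signal x dye-bias(mean intensity) x lognormal noise + background``
    with the dye bias attached to channel A only; dye orientation alternates
    so that half the arrays are swapped.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    signal = pool_signal(matrix, design)

    male_pools = sorted(design.pools_of(MALE), key=lambda p: int(p[1:]))
    female_pools = sorted(design.pools_of(FEMALE), key=lambda p: int(p[1:]))
    if len(male_pools) != len(female_pools):
        raise ValueError("need equal numbers of male and female pools to pair")

    meta_rows = []
    chan_a: dict[str, np.ndarray] = {}
    chan_b: dict[str, np.ndarray] = {}
    for i, (mp, fp) in enumerate(zip(male_pools, female_pools)):
        array_id = f"A{i + 1:02d}"
        orientation = "male_in_A" if i % 2 == 0 else "male_in_B"
        sig_m = signal[mp].to_numpy()
        sig_f = signal[fp].to_numpy()
        sig_a, sig_b = (sig_m, sig_f) if orientation == "male_in_A" else (sig_f, sig_m)
        mean_int = 0.5 * (sig_a + sig_b)
        bias = 10.0 ** noise.dye_bias_log10(mean_int)
        n = len(sig_a)
        a = sig_a * bias * 10.0 ** rng.normal(0.0, noise.channel_sd_log10, n)
        b = sig_b * 10.0 ** rng.normal(0.0, noise.channel_sd_log10, n)
        chan_a[array_id] = a + noise.background
        chan_b[array_id] = b + noise.background
        meta_rows.append(
            {
                "array_id": array_id,
                "male_pool_id": mp,
                "female_pool_id": fp,
                "dye_orientation": orientation,
            }
        )

    arrays = pd.DataFrame(meta_rows)
    probe_index = signal.index.rename("probe_id")
    out = TwoColorArraySet(
        arrays=arrays,
        channel_a=pd.DataFrame(chan_a, index=probe_index),
        channel_b=pd.DataFrame(chan_b, index=probe_index),
        background=noise.background,
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# codon-pair generation
# ---------------------------------------------------------------------------


def _jc_inverse(d: float) -> float:
    """Proportion of differing sites giving Jukes-Cantor distance ``d``."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _random_ancestor(rng: np.random.Generator, n_codons: int) -> list[str]:
    idx = rng.integers(0, len(NONSTOP_CODONS), size=n_codons)
    return [NONSTOP_CODONS[i] for i in idx]


def _apply_changes(
    rng: np.random.Generator, codons: list[str], n_changes: int, synonymous: bool
) -> None:
    """Apply single-nucleotide substitutions of the requested class in place.

    Changes producing stop codons are never applied.  Positions are drawn at
    random with replacement; a draw with no available change of the requested
    class is redrawn.
    """
    applied = 0
    attempts = 0
    while applied < n_changes:
        attempts += 1
        if attempts > 200 * max(n_changes, 1):
            raise RuntimeError("could not place requested substitutions")
        ci = int(rng.integers(0, len(codons)))
        options = [
            alt
            for alt in neighbours(codons[ci])
            if (CODON_TO_AA[alt] == CODON_TO_AA[codons[ci]]) == synonymous
        ]
        if not options:
            continue
        codons[ci] = options[int(rng.integers(0, len(options)))]
        applied += 1


def generate_codon_pairs(
    n_per_group: int,
    seq_len_codons: int,
    target_dnds: dict[str, float] | float,
    target_ds: float = 0.35,
    seed: int = 0,
) -> CodonPairSet:
    """Generate ortholog-like codon pairs whose NG86 dN/dS centres near a target.

    For each pair, a random stop-free ancestor is copied and one copy is
    mutated with synonymous and non-synonymous single-nucleotide substitution
    counts chosen so that the NG86 estimates of dS and dN/dS are centred near
    ``target_ds`` and the group's ``target_dnds``.  ``target_ds=0`` gives
    identical pairs (dN = dS = 0).
    """
    if n_per_group <= 0:
        raise ValueError("n_per_group must be positive")
    if seq_len_codons < 10:
        raise ValueError("seq_len_codons must be at least 10")
    if isinstance(target_dnds, (int, float)):
        target_dnds = {"non_sex_biased": float(target_dnds)}
    for g, w in target_dnds.items():
        if w < 0:
            raise ValueError(f"target dN/dS for {g} must be non-negative")

    rng = np.random.default_rng(seed)
    pairs: list[CodonPair] = []
    for group, omega in target_dnds.items():
        for k in range(n_per_group):
            anc = _random_ancestor(rng, seq_len_codons)
            derived = list(anc)
            if target_ds > 0:
                s_sites = sum(codon_site_counts(c)[0] for c in anc)
                n_sites = 3 * seq_len_codons - s_sites
                n_syn = round(_jc_inverse(target_ds) * s_sites)
                n_nonsyn = round(_jc_inverse(omega * target_ds) * n_sites)
                _apply_changes(rng, derived, n_syn, synonymous=True)
                _apply_changes(rng, derived, n_nonsyn, synonymous=False)
            pairs.append(
                CodonPair(
                    gene_id=f"{group}_{k + 1:04d}",
                    seq_a="".join(anc),
                    seq_b="".join(derived),
                    group=group,
                )
            )
    return CodonPairSet(pairs=pairs, provenance=f"synthetic codon pairs, seed={seed}")
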