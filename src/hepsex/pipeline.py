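"""End-to-end pipeline: simulate -> normalize -> call -> summarise.

``run_pipeline`` executes the enabled stages on a synthetic cohort, writes
every stage's table to a run directory, and produces a JSON report whose
numbers are all re-derivable from those tables.  Outputs are stamped with
the seed and a hash of the configuration; reruns with the same configuration
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, chromosomes, evolution, io, normalize, synthetic
from .fixtures import load_fixture

log = logging.getLogger("hepsex")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults are the study's values."""

    seed: int = 0
    # cohort
    n_male: int = 112
    n_female: int = 112
    n_genes: int = 1000
    frac_biased: float = 0.05
    frac_female_biased_of_biased: float = 0.70
    indiv_sd_log10: float = 0.15
    # pools and arrays
    pool_size: int = 14
    n_replicate_sets: int = 2
    channel_sd_log10: float = 0.0617
    background: float = 30.0
    dye_bias_amplitude: float = 0.15
    # normalization
    span: float = 0.4
    # calling thresholds
    fc_thresh: float = 1.15
    p_thresh: float = 0.005
    score_levels: tuple[int, ...] = (14, 13, 12)
    # permutation counts
    n_perm_correlation: int = 1000
    n_perm_median: int = 10_000
    # stage switches
    run_calling: bool = True
    run_chromosomes: bool = True
    run_evolution: bool = False

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the enabled stages, write all outputs under ``outdir``, return the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    io.dump_config({**asdict(config), "config_hash": chash}, outdir / "config.yaml")
    report: dict = {"seed": config.seed, "config_hash": chash}

    # --- simulate ---------------------------------------------------------
    matrix = _stage("simulate")(synthetic.generate_cohort)(
        n_male=config.n_male,
        n_female=config.n_female,
        n_genes=config.n_genes,
        frac_biased=config.frac_biased,
        frac_female_biased_of_biased=config.frac_female_biased_of_biased,
        indiv_sd_log10=config.indiv_sd_log10,
        seed=config.seed,
    )
    design = synthetic.build_pool_design(
        matrix, pool_size=config.pool_size,
        n_replicate_sets=config.n_replicate_sets, seed=config.seed + 1,
    )
    noise = synthetic.NoiseSpec(
        channel_sd_log10=config.channel_sd_log10,
        background=config.background,
        dye_bias_amplitude=config.dye_bias_amplitude,
    )
    arrays = synthetic.simulate_arrays(matrix, design, noise=noise, seed=config.seed + 2)
    io.write_cohort(matrix, outdir / "cohort.tsv")
    io.write_arrays(arrays, outdir / "arrays.tsv")
    log.info("stage=simulate hash=%s seed=%d genes=%d arrays=%d",
             chash, config.seed, config.n_genes, len(arrays.array_ids))

    # --- normalize --------------------------------------------------------
    ratios, amean = _stage("normalize")(normalize.lowess_normalize)(arrays, span=config.span)
    errors = normalize.estimate_replicate_errors(ratios, amean, span=config.span)
    stats = normalize.combine_replicates(ratios, errors)
    io.write_probe_stats(stats, ratios, outdir / "probe_stats.tsv")
    log.info("stage=normalize hash=%s probes=%d", chash, len(stats))
    report["n_probes"] = int(len(stats))

    if not config.run_calling:
        (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        return report

    # --- call -------------------------------------------------------------
    calls = _stage("call")(calling.call_sex_biased)(
        stats, fc_thresh=config.fc_thresh, p_thresh=config.p_thresh,
        score_levels=config.score_levels,
    )
    io.write_calls(calls, outdir / "calls.tsv")
    passing = calls[calls["pass_level"] != "none"]
    n_fc = int((stats["fold_change"].abs() > config.fc_thresh).sum())
    top = max(config.score_levels)
    n_obs = int((passing["composite_score"] >= top).sum())
    report["n_fc_passing"] = n_fc
    report["n_called"] = {
        f"score{s}": int((passing["composite_score"] >= s).sum()) for s in config.score_levels
    }
    if n_obs:
        expected, fdr = calling.apparent_fdr_binomial(n_fc, ratios.shape[1], top, n_obs)
        report["fdr_binomial"] = {"expected": expected, "fdr_percent": 100 * fdr}
        report["direction_summary"] = calling.direction_summary(passing)
    if matrix.truth is not None:
        truth = matrix.truth.loc[passing.index[passing["composite_score"] >= top]]
        report["true_positive_calls"] = int(truth["is_sex_biased"].sum())
        report["false_positive_calls"] = int((~truth["is_sex_biased"]).sum())
    log.info("stage=call hash=%s called=%d", chash, int(len(passing)))

    # --- chromosome summary (synthetic genes carry no coordinates; report
    # the fixture-based escape concordance instead) -------------------------
    if config.run_chromosomes:
        panel = load_fixture("escape_panel")
        n_escape, genes = chromosomes.escape_concordance(panel, required_score=16)
        report["escape_panel"] = {"n_concordant": n_escape, "n_panel": int(len(panel)),
                                  "genes": genes}
        log.info("stage=chromosomes hash=%s escape=%d/%d", chash, n_escape, len(panel))

    # --- evolution (optional, synthetic codon pairs) -----------------------
    if config.run_evolution:
        pairs = synthetic.generate_codon_pairs(
            n_per_group=100, seq_len_codons=300,
            target_dnds={"male_biased": 0.128, "female_biased": 0.104,
                         "non_sex_biased": 0.074},
            seed=config.seed + 3,
        )
        table = evolution.dnds_table(pairs)
        table.to_csv(outdir / "dnds.tsv", sep="\t", index=False)
        med = table.groupby("group")["dnds"].median()
        report["dnds_medians"] = {k: float(v) for k, v in med.items()}
        mb = table.loc[table["group"] == "male_biased", "dnds"].dropna()
        nb = table.loc[table["group"] == "non_sex_biased", "dnds"].dropna()
        res = evolution.median_permutation_test(
            mb, nb, background=pd.concat([mb, nb]),
            n_perm=config.n_perm_median, seed=config.seed + 4,
        )
        report["dnds_permutation"] = {
            "observed_median_difference": res.observed_median_difference,
            "nd": res.nd, "n_perm": res.n_perm, "p_value": res.p_value,
        }
        log.info("stage=evolution hash=%s pairs=%d", chash, len(table))

    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def desk_summary() -> dict:
    """The desk-scale reproducible quantities, computed from formulas and fixtures.

    These need no simulation: the binomial and p-value apparent FDRs from
    the study's probe counts, the power analysis, the escape-panel
    concordance, and the direction-split percentages.
    """
    expected14, fdr14 = calling.apparent_fdr_binomial(4734, 16, 14, 1295)
    expected_p, fdr_p = calling.apparent_fdr_pvalue(4734, 0.005, 2575)
    expected_all, fdr_all = calling.apparent_fdr_pvalue(41000, 0.005, 6902)
    fc = normalize.detectable_fold_change(
        normalize.PowerSpec(sd_log10=0.0896, n_arrays=16, alpha=0.05, power=0.8)
    )
    panel = load_fixture("escape_panel")
    n_escape, _ = chromosomes.escape_concordance(panel, required_score=16)
    summary = calling.direction_summary(
        pd.DataFrame({"direction": ["female"] * 873 + ["male"] * 376})
    )
    return {
        "binomial_expected_by_chance": expected14,
        "binomial_fdr_percent": 100 * fdr14,
        "pvalue_fdr_expected": expected_p,
        "pvalue_fdr_percent": 100 * fdr_p,
        "allprobe_fdr_expected": expected_all,
        "allprobe_fdr_percent": 100 * fdr_all,
        "detectable_fold_change": round(fc, 2),
        "escape_concordant": n_escape,
        "escape_panel_size": int(len(panel)),
        "percent_female_biased": summary["percent_female"],
        "percent_male_biased": summary["percent_male"],
    }
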