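"""Plain-text readers and writers for the pipeline's tables and sequences.

All tabular formats are TSV with one header row and the probe/gene id in the
first column.  Cohort matrices carry a second header row of sex labels;
codon pairs travel as interleaved FASTA with ``gene|a`` / ``gene|b`` headers
plus a gene-to-group map TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import CodonPair, CodonPairSet, IndividualExpressionMatrix, TwoColorArraySet


# ---------------------------------------------------------------------------
# cohort matrices
# ---------------------------------------------------------------------------


def write_cohort(matrix: IndividualExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        fh.write("sex\t" + "\t".join(matrix.sex_labels[matrix.sample_ids]) + "\n")
        matrix.values.to_csv(fh, sep="\t", header=False)
    if matrix.truth is not None:
        matrix.truth.to_csv(path.with_suffix(".truth.tsv"), sep="\t")


def read_cohort(path: str | Path) -> IndividualExpressionMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sexrow = fh.readline().rstrip("\n").split("\t")
        if sexrow[0] != "sex":
            raise ValueError("second header row must carry sex labels")
        values = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    samples = header[1:]
    values.columns = samples
    values.index.name = "gene_id"
    sex = pd.Series(sexrow[1:], index=samples, name="sex")
    truth_path = path.with_suffix(".truth.tsv")
    truth = pd.read_csv(truth_path, sep="\t", index_col=0) if truth_path.exists() else None
    m = IndividualExpressionMatrix(values=values, sex_labels=sex, truth=truth)
    m.validate()
    return m


# ---------------------------------------------------------------------------
# two-color arrays (long format)
# ---------------------------------------------------------------------------


def write_arrays(array_set: TwoColorArraySet, path: str | Path) -> None:
    frames = []
    for _, row in array_set.arrays.iterrows():
        aid = row["array_id"]
        frames.append(
            pd.DataFrame(
                {
                    "array_id": aid,
                    "male_pool_id": row["male_pool_id"],
                    "female_pool_id": row["female_pool_id"],
                    "dye_orientation": row["dye_orientation"],
                    "probe_id": array_set.probe_ids,
                    "intensity_a": array_set.channel_a[aid].to_numpy(),
                    "intensity_b": array_set.channel_b[aid].to_numpy(),
                }
            )
        )
    long = pd.concat(frames, ignore_index=True)
    with Path(path).open("w") as fh:
        fh.write(f"# background={array_set.background!r}\n")
        long.to_csv(fh, sep="\t", index=False)


def read_arrays(path: str | Path) -> TwoColorArraySet:
    background = 0.0
    with Path(path).open() as fh:
        first = fh.readline()
        if first.startswith("# background="):
            background = float(first.split("=", 1)[1])
        else:
            fh.seek(0)
        long = pd.read_csv(fh, sep="\t")
    meta = (
        long[["array_id", "male_pool_id", "female_pool_id", "dye_orientation"]]
        .drop_duplicates("array_id")
        .reset_index(drop=True)
    )
    chan_a = long.pivot(index="probe_id", columns="array_id", values="intensity_a")
    chan_b = long.pivot(index="probe_id", columns="array_id", values="intensity_b")
    chan_a.columns.name = None
    chan_b.columns.name = None
    order = list(meta["array_id"])
    out = TwoColorArraySet(
        arrays=meta, channel_a=chan_a[order], channel_b=chan_b[order], background=background
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# probe statistics and calls
# ---------------------------------------------------------------------------


def write_probe_stats(
    stats: pd.DataFrame, ratios: pd.DataFrame, path: str | Path
) -> None:
    """ProbeStatTable TSV: probe_id, ratio_1..n, then the combined statistics."""
    named = ratios.copy()
    named.columns = [f"ratio_{i + 1}" for i in range(ratios.shape[1])]
    out = named.join(stats)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.6e")


def read_probe_stats(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    ratio_cols = [c for c in df.columns if c.startswith("ratio_")]
    return df.drop(columns=ratio_cols), df[ratio_cols]


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", float_format="%.6e")


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """BED-like probe annotation: chrom, start, end, probe_id, score, strand + extras."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "probe_id"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation lacks columns: {sorted(required - set(df.columns))}")
    return df


# ---------------------------------------------------------------------------
# codon pairs
# ---------------------------------------------------------------------------


def write_codon_pairs(pairs: CodonPairSet, fasta_path: str | Path, group_path: str | Path) -> None:
    records = []
    for p in pairs.pairs:
        records.append(SeqRecord(Seq(p.seq_a), id=f"{p.gene_id}|a", description=""))
        records.append(SeqRecord(Seq(p.seq_b), id=f"{p.gene_id}|b", description=""))
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        [{"gene_id": p.gene_id, "group": p.group} for p in pairs.pairs]
    ).to_csv(group_path, sep="\t", index=False)


def read_codon_pairs(fasta_path: str | Path, group_path: str | Path | None = None) -> CodonPairSet:
    groups = {}
    if group_path is not None:
        gm = pd.read_csv(group_path, sep="\t")
        groups = dict(zip(gm["gene_id"], gm["group"]))
    seqs: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gene, _, which = rec.id.rpartition("|")
        if which not in ("a", "b") or not gene:
            raise ValueError(f"FASTA header {rec.id!r} is not of the form gene|a / gene|b")
        seqs.setdefault(gene, {})[which] = str(rec.seq).upper()
    pairs = []
    valid_nt = set("ACGT")
    for gene, d in seqs.items():
        if set(d) != {"a", "b"}:
            raise ValueError(f"gene {gene} lacks one of its two sequences")
        flagged = not (valid_nt >= set(d["a"]) and valid_nt >= set(d["b"]))
        pairs.append(
            CodonPair(
                gene_id=gene, seq_a=d["a"], seq_b=d["b"],
                group=groups.get(gene, "unlabelled"), flagged=flagged,
            )
        )
    return CodonPairSet(pairs=pairs, provenance=str(fasta_path))


# ---------------------------------------------------------------------------
# GSEA export and configuration
# ---------------------------------------------------------------------------


def write_rank_file(ratios: pd.DataFrame, path: str | Path) -> None:
    """Two-column rank file (gene, log2 ratio) for external GSEA runs."""
    ratios["log2_ratio"].to_csv(path, sep="\t", header=False)


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path, description: str = "hepsex") -> None:
    with Path(path).open("w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
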