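"""Readers and writers for the package's file dialects.

All tabular formats are UTF-8, tab-delimited:

* expression / specificity matrix — first column ``gene``, header row of
  sample or tissue labels;
* tissue-group map — two columns ``sample``, ``group``;
* variant table — ``chrom pos ref alt gene clinvar maf_<cohort>... score_<name>...``;
* term-gene map — two columns ``term_id``, ``gene``;
* per-term metrics, comparison summaries and score tables mirror the objects
  they serialise.

Exome samples are written as minimal single-sample VCF v4.2 plus a sidecar
annotation TSV keyed by ``chrom:pos:ref:alt`` (gene, MAFs, scores); reading
joins the VCF records back to that annotation.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohorts import TermGeneSet, variant_ids
from .evaluation import ComparisonSummary, TermPerformance
from .spikein import SpikeInResult, SpikeInSkip
from .synthetic import ExomeSample

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_group_map",
    "write_group_map",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_term_genes",
    "write_term_genes",
    "write_scores_tsv",
    "write_performance_tsv",
    "write_comparison_tsv",
    "write_spikein_results_tsv",
    "write_exome_vcf",
    "read_exome_vcf",
    "sha256_file",
]


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except (pd.errors.ParserError, ValueError) as exc:
        # pandas parser errors carry the offending line number
        raise ValueError(f"malformed TSV {path}: {exc}") from exc


def read_expression_tsv(path) -> pd.DataFrame:
    matrix = _read_tsv(path, index_col=0)
    matrix.index.name = "gene"
    matrix = matrix.astype(float)
    if matrix.isna().any().any():
        bad = matrix.index[matrix.isna().any(axis=1)]
        # 1-based data line: header occupies line 1
        line = matrix.index.get_loc(bad[0]) + 2
        raise ValueError(f"malformed TSV {path}: missing value at line {line} (gene {bad[0]})")
    return matrix


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("gene").to_csv(path, sep="\t")


def read_group_map(path) -> dict[str, str]:
    table = _read_tsv(path, dtype=str)
    if list(table.columns[:2]) != ["sample", "group"]:
        raise ValueError(f"{path}: expected columns 'sample', 'group'")
    if table["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample labels")
    return dict(zip(table["sample"], table["group"]))


def write_group_map(groups: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"sample": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    table = _read_tsv(path, dtype={"chrom": str, "ref": str, "alt": str, "gene": str})
    required = ["chrom", "pos", "ref", "alt", "gene", "clinvar"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing variant columns {missing}")
    table["pos"] = table["pos"].astype(int)
    if (table["pos"] < 1).any():
        raise ValueError(f"{path}: positions must be 1-based (>= 1)")
    for col in table.columns:
        if col.startswith(("maf_", "score_")):
            vals = table[col].astype(float)
            bad = vals.notna() & ((vals < 0) | (vals > 1))
            if bad.any():
                raise ValueError(f"{path}: {col} outside [0, 1] at rows {list(table.index[bad][:3])}")
            table[col] = vals
    return table


def write_variants_tsv(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_term_genes(path) -> list[TermGeneSet]:
    table = _read_tsv(path, dtype=str)
    if list(table.columns[:2]) != ["term_id", "gene"]:
        raise ValueError(f"{path}: expected columns 'term_id', 'gene'")
    return [
        TermGeneSet(term_id, frozenset(group["gene"]))
        for term_id, group in table.groupby("term_id", sort=True)
    ]


def write_term_genes(terms: Sequence[TermGeneSet], path) -> None:
    rows = [
        {"term_id": t.term_id, "gene": g} for t in terms for g in sorted(t.genes)
    ]
    pd.DataFrame(rows, columns=["term_id", "gene"]).to_csv(path, sep="\t", index=False)


def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    """Variant scores: variant_id, probability (empty if unscored), n_votes."""
    scores.rename_axis("variant_id").to_csv(path, sep="\t")


def write_performance_tsv(perfs: Sequence[TermPerformance], path) -> None:
    rows = []
    for p in perfs:
        row = {
            "term_id": p.term_id,
            "method": p.method,
            "auprc": p.auprc,
            "n_scored": p.n_scored,
            "n_unscored": p.n_unscored,
        }
        for k in sorted(p.ppk):
            row[f"pp{k}"] = p.ppk[k]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_comparison_tsv(summaries: Sequence[ComparisonSummary], path) -> None:
    pd.DataFrame(
        [
            {
                "metric": s.metric,
                "n_terms": s.n_terms,
                "n_improved": s.n_improved,
                "mean_difference": s.mean_difference,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "t_statistic": s.t_statistic,
                "df": s.df,
                "p_value": s.p_value,
            }
            for s in summaries
        ]
    ).to_csv(path, sep="\t", index=False)


def write_spikein_results_tsv(
    results: Sequence[Union[SpikeInResult, SpikeInSkip]], path
) -> None:
    rows = []
    for r in results:
        if isinstance(r, SpikeInSkip):
            rows.append({"sample_id": r.sample_id, "status": f"skipped: {r.reason}"})
        else:
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "status": "ok",
                    "spike": r.spike_id,
                    "rank_varpp": r.rank_varpp,
                    "rank_baseline": r.rank_baseline,
                    "n_ranked_varpp": r.n_ranked_varpp,
                    "n_ranked_baseline": r.n_ranked_baseline,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SPIKE,Number=0,Type=Flag,Description="Spiked-in pathogenic variant">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_exome_vcf(sample: ExomeSample, vcf_path, annotation_path=None) -> None:
    """Write one exome as a single-sample VCF plus an annotation TSV.

    The spike-in record carries the ``SPIKE`` INFO flag.  The annotation TSV
    (``variant_id`` plus gene, clinvar, MAF and score columns) restores the
    fields VCF does not carry.
    """
    table = sample.all_variants()
    spike_idx = len(table) - 1
    order = np.lexsort((table["pos"].to_numpy(), table["chrom"].to_numpy()))
    lines = [_VCF_HEADER]
    for chrom in sorted(set(table["chrom"])):
        lines.append(f"##contig=<ID={chrom}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample.sample_id + "\n"
    )
    ids = variant_ids(table)
    for i in order:
        row = table.iloc[i]
        info = "SPIKE" if i == spike_idx else "."
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{ids[i]}\t{row['ref']}\t"
            f"{row['alt']}\t.\t.\t{info}\tGT\t0/1\n"
        )
    Path(vcf_path).write_text("".join(lines))
    if annotation_path is not None:
        ann = table.copy()
        ann.insert(0, "variant_id", ids)
        ann.to_csv(annotation_path, sep="\t", index=False)


def read_exome_vcf(
    vcf_path, annotation: pd.DataFrame, term_ids: Optional[Sequence[str]] = None
) -> ExomeSample:
    """Read a single-sample VCF and join each record to its annotation row.

    ``annotation`` must carry a ``variant_id`` column (``chrom:pos:ref:alt``)
    plus the variant-table fields.  Records without annotation are dropped.
    The spike is identified by the ``SPIKE`` INFO flag.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_id = vcf.samples[0] if vcf.samples else Path(str(vcf_path)).stem
    ann = annotation.set_index("variant_id")
    rows = []
    spike_ids = []
    for record in vcf:
        for alt in record.ALT:
            vid = f"{record.CHROM}:{record.POS}:{record.REF}:{alt}"
            if vid not in ann.index:
                continue
            rows.append(vid)
            if record.INFO.get("SPIKE") is not None:
                spike_ids.append(vid)
    vcf.close()
    if not spike_ids:
        raise ValueError(f"{vcf_path}: no record carries the SPIKE flag")
    if len(spike_ids) > 1:
        raise ValueError(f"{vcf_path}: multiple SPIKE records")
    table = ann.loc[rows].reset_index(drop=True)
    spike_mask = pd.Index(rows) == spike_ids[0]
    spike = table.loc[spike_mask].iloc[0]
    background = table.loc[~spike_mask].reset_index(drop=True)
    return ExomeSample(
        sample_id=sample_id,
        variants=background,
        spike=spike,
        spike_term_ids=list(term_ids or []),
    )


def sha256_file(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()
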