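"""Readers and writers for the pipeline's on-disk formats.

Dialects: TSV with explicit headers for matrices and tables; GFF3 (1-based,
inclusive) or BED (0-based, half-open) for gene coordinates, both normalized
to the internal 1-based inclusive convention; JSON for planted truth and run
logs. Output files written by :func:`write_with_header` carry ``#``-prefixed
provenance lines (package version, config hash, seed) which every reader
skips, so each output re-parses through the package's own readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .data import ExpressionDataset, GeneLocus, RateSeries
from .simulate import SyntheticDataset


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample log2 matrix from TSV (first column gene_id)."""
    matrix = _read_tsv(path, index_col=0)
    matrix.index.name = "gene_id"
    if matrix.isna().any().any():
        rows, cols = np.nonzero(matrix.isna().to_numpy())
        raise ValueError(
            "missing expression value at gene "
            f"{matrix.index[rows[0]]!r}, sample {matrix.columns[cols[0]]!r}"
        )
    return matrix


def read_design(path: str | Path) -> pd.DataFrame:
    design = _read_tsv(path)
    required = {"sample_id", "substrate", "time_h", "replicate", "role"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return design.set_index("sample_id")


def read_dataset(expression_path: str | Path, design_path: str | Path) -> ExpressionDataset:
    return ExpressionDataset(
        matrix=read_expression(expression_path), design=read_design(design_path)
    )


def read_gff3(path: str | Path, featuretype: str = "gene") -> list[GeneLocus]:
    """Gene loci from GFF3 (1-based inclusive, kept as-is internally)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    loci = []
    for feat in db.features_of_type(featuretype):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        loci.append(
            GeneLocus(
                gene_id=gene_id,
                scaffold=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else ".",
            )
        )
    return loci


def write_gff3(loci: list[GeneLocus], path: str | Path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines or []:
            fh.write(f"#{line}\n")
        for g in loci:
            fh.write(
                f"{g.scaffold}\tregscreen\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_bed(path: str | Path) -> list[GeneLocus]:
    """Gene loci from BED (0-based half-open), converted to 1-based inclusive."""
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs >=4 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            loci.append(
                GeneLocus(
                    gene_id=fields[3],
                    scaffold=fields[0],
                    start=start + 1,
                    end=end,
                    strand=strand,
                )
            )
    return loci


def write_regions_bed(regions, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Region calls as BED6 (0-based half-open; name=cluster:kind, score=size)."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"#{line}\n")
        for r in regions:
            fh.write(
                f"{r.scaffold}\t{r.bp_span[0] - 1}\t{r.bp_span[1]}\t"
                f"cluster{r.cluster_id}:{r.kind}\t{len(r.member_gene_ids)}\t.\n"
            )


def read_annotations(path: str | Path) -> pd.DataFrame:
    annot = _read_tsv(path)
    required = {"gene_id", "class_label", "domain_id"}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return annot


def read_rates(rates_path: str | Path, expression_path: str | Path) -> RateSeries:
    rates = _read_tsv(rates_path)
    if not {"condition", "rate"} <= set(rates.columns):
        raise ValueError("rates table needs columns condition, rate")
    expr = read_expression(expression_path)
    return RateSeries(
        rates=rates.set_index("condition")["rate"], expression=expr
    )


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def read_proteome_flags(path: str | Path) -> pd.Series:
    flags = _read_tsv(path)
    if not {"gene_id", "proteome_flag"} <= set(flags.columns):
        raise ValueError("proteome table needs columns gene_id, proteome_flag")
    out = flags.set_index("gene_id")["proteome_flag"].astype(int)
    bad = set(out.unique()) - {-1, 0, 1}
    if bad:
        raise ValueError(f"proteome flags must be -1/0/+1, got {sorted(bad)}")
    return out


def write_with_header(
    frame: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None,
    index: bool = True,
) -> None:
    """TSV with ``#``-prefixed provenance header lines."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic study as the pipeline's standard input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "design": outdir / "design.tsv",
        "genome": outdir / "genome.gff3",
        "annotations": outdir / "annotations.tsv",
        "reference_genes": outdir / "reference_genes.txt",
        "rates": outdir / "rates.tsv",
        "chemostat_expression": outdir / "chemostat_expression.tsv",
        "proteome": outdir / "proteome_flags.tsv",
        "truth": outdir / "truth.json",
    }
    dataset.expression.matrix.to_csv(paths["expression"], sep="\t")
    dataset.expression.design.to_csv(paths["design"], sep="\t")
    write_gff3(dataset.loci, paths["genome"])
    dataset.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    paths["reference_genes"].write_text(
        "\n".join(dataset.reference_genes) + "\n"
    )
    dataset.chemostat.rates.rename("rate").rename_axis("condition").reset_index().to_csv(
        paths["rates"], sep="\t", index=False
    )
    dataset.chemostat.expression.to_csv(paths["chemostat_expression"], sep="\t")
    dataset.proteome_flags.rename("proteome_flag").rename_axis("gene_id").reset_index().to_csv(
        paths["proteome"], sep="\t", index=False
    )
    truth = dataset.truth
    paths["truth"].write_text(
        json.dumps(
            {
                "cluster_labels": {
                    g: int(c) for g, c in truth.cluster_labels.items()
                },
                "region_extents": truth.region_extents,
                "regulator_ids": truth.regulator_ids,
                "correlated_ids": truth.correlated_ids,
                "reference_ids": truth.reference_ids,
                "roles": {g: str(r) for g, r in truth.roles.items()},
            },
            indent=1,
        )
    )
    return paths


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
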