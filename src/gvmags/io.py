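"""Readers and writers for the pipeline's tabular dialects.

Gene tables travel as TSV (and GFF3 with ``rbs_motif=``/``rbs_spacer=``
attributes; GFF3 coordinates are 1-based inclusive while the in-memory
convention is 0-based half-open).  Similarity-search hits use a BLAST
outfmt-6-like TSV extended with database and taxon-group columns.  Marker
tables are long-format (genome_id, ncvog_id, count) TSV; score matrices are
wide TSV; planted truths serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .hgt import HitRecord
from .rbs import FEATURE_NAMES, FeatureVector, GeneRecord
from .synth import GENE_TABLE_COLUMNS, PlantedTruth

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "write_gene_table_gff3",
    "genes_from_table",
    "read_hits",
    "write_hits",
    "read_marker_tables",
    "write_marker_tables",
    "read_score_matrix",
    "write_score_matrix",
    "write_truth",
    "feature_vector_frame",
]


def write_gene_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=list(GENE_TABLE_COLUMNS))


def read_gene_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    missing = set(GENE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return table


def genes_from_table(table: pd.DataFrame) -> list[GeneRecord]:
    """Materialise :class:`~gvmags.rbs.GeneRecord` objects from a table."""
    return [
        GeneRecord(
            contig_id=str(r.contig_id),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            rbs_motif=str(r.rbs_motif) or None,
            rbs_spacer_bp=int(r.rbs_spacer_bp),
            confidence=float(r.confidence),
            score=float(r.score),
            gene_id=str(r.gene_id),
        )
        for r in table.itertuples()
    ]


def write_gene_table_gff3(table: pd.DataFrame, path: str | Path) -> None:
    """Emit genes as GFF3 CDS features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in table.itertuples():
            attrs = [f"ID={r.gene_id}", f"conf={r.confidence}"]
            if r.rbs_motif:
                attrs.append(f"rbs_motif={r.rbs_motif}")
                attrs.append(f"rbs_spacer={r.rbs_spacer_bp}")
            fh.write(
                "\t".join(
                    [
                        str(r.contig_id),
                        "gvmags",
                        "CDS",
                        str(int(r.start) + 1),
                        str(int(r.end)),
                        str(r.score),
                        str(r.strand),
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


HIT_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "evalue",
    "bitscore",
    "qlen",
    "database",
    "taxon_group",
    "query_lineage",
)


def write_hits(records: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits as outfmt-6-style TSV (alignment length is reconstructed
    from the alignment fraction against a nominal 100-residue query)."""
    rows = []
    for r in records:
        qlen = 100
        rows.append(
            {
                "qseqid": r.query_protein,
                "sseqid": r.subject_id,
                "pident": r.pct_identity,
                "length": int(round(r.alignment_fraction / 100.0 * qlen)),
                "evalue": r.evalue,
                "bitscore": 0.0,
                "qlen": qlen,
                "database": r.database,
                "taxon_group": r.subject_taxon_group,
                "query_lineage": r.query_lineage,
            }
        )
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path) -> list[HitRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        HitRecord(
            query_protein=str(r.qseqid),
            query_lineage=str(r.query_lineage),
            subject_id=str(r.sseqid),
            database=str(r.database),
            subject_taxon_group=str(r.taxon_group),
            evalue=float(r.evalue),
            pct_identity=float(r.pident),
            alignment_fraction=100.0 * float(r.length) / float(r.qlen),
        )
        for r in df.itertuples()
    ]


def write_marker_tables(
    tables: Mapping[str, Mapping[str, int]], path: str | Path
) -> None:
    rows = [
        {"genome_id": g, "ncvog_id": m, "count": c}
        for g in sorted(tables)
        for m, c in sorted(tables[g].items())
    ]
    pd.DataFrame(rows, columns=["genome_id", "ncvog_id", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_marker_tables(path: str | Path) -> dict[str, dict[str, int]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, int]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.genome_id), {})[str(r.ncvog_id)] = int(r.count)
    return out


def write_score_matrix(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index_label="protein_id")


def read_score_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein_id")


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)


def feature_vector_frame(
    vectors: Sequence[FeatureVector], ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """One row per feature vector, columns in canonical 14-feature order."""
    rows = [dict(zip(FEATURE_NAMES, v.as_array())) for v in vectors]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if ids is not None:
        df.insert(0, "genome_id", list(ids))
    return df
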