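"""File formats: GMT gene sets, TSV matrices and tables, JSON truth/config.

All tabular artefacts are plain TSV so runs are diffable; floats are
written with repr-level precision, which keeps write -> read round trips
exact to 1e-12 and fixed-seed runs byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .finemap import EQTL_COLUMNS, VARIANT_COLUMNS, LDMatrix
from .genesets import GeneSetDB
from .ranking import ExpressionCompendium, RankedGeneMatrix
from .simulate import PlantedTruth

log = logging.getLogger("drugsea.io")

__all__ = [
    "ParseError",
    "read_gmt",
    "write_gmt",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_compendium",
    "write_compendium",
    "read_variant_table",
    "read_eqtl_table",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_ranked_gene_matrix",
    "write_truth",
    "read_truth",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    pass


def read_gmt(path) -> GeneSetDB:
    """Read a GMT file: one pathway per line (ID, description, genes...).

    Duplicate pathway IDs raise; duplicate genes within a line are
    deduplicated with a warning; an empty file yields an empty database
    with a warning.
    """
    path = Path(path)
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pid, desc, *genes = fields
            genes = [g for g in genes if g]
            if pid in pathways:
                raise ParseError(f"{path.name}:{lineno}: duplicate pathway ID {pid!r}")
            unique = frozenset(genes)
            if len(unique) < len(genes):
                log.warning(
                    "%s:%d: %d duplicate gene(s) in pathway %s",
                    path.name, lineno, len(genes) - len(unique), pid,
                )
            pathways[pid] = (desc, unique)
    if not pathways:
        log.warning("%s: empty GMT file", path.name)
    return GeneSetDB(db_name=path.stem, pathways=pathways)


def write_gmt(db: GeneSetDB, path) -> None:
    with Path(path).open("w") as fh:
        for pid, (desc, genes) in db.pathways.items():
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Labelled real matrix from TSV (header row + label column).

    Ragged rows, non-numeric or non-finite cells raise with coordinates.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header) - 1
        labels, rows = [], []
        for lineno, raw in enumerate(fh, start=2):
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != ncol + 1:
                raise ParseError(
                    f"{path.name}:{lineno}: expected {ncol + 1} fields, "
                    f"got {len(fields)}"
                )
            labels.append(fields[0])
            row = np.empty(ncol)
            for j, cell in enumerate(fields[1:]):
                try:
                    row[j] = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path.name}:{lineno}: non-numeric cell in column "
                        f"{header[j + 1]!r}: {cell!r}"
                    ) from None
                if not np.isfinite(row[j]):
                    raise ParseError(
                        f"{path.name}:{lineno}: non-finite value in column "
                        f"{header[j + 1]!r}: {cell!r}"
                    )
            rows.append(row)
    values = np.vstack(rows) if rows else np.empty((0, ncol))
    return pd.DataFrame(values, index=pd.Index(labels, name=header[0]),
                        columns=header[1:])


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_compendium(comp: ExpressionCompendium, expr_path, samples_path) -> None:
    write_matrix_tsv(comp.expression, expr_path)
    comp.samples.to_csv(samples_path, sep="\t")


def read_compendium(expr_path, samples_path) -> ExpressionCompendium:
    expr = read_matrix_tsv(expr_path)
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id", dtype=str)
    return ExpressionCompendium(expression=expr, samples=samples)


def read_variant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "locus_id": str})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"variant table lacks column(s): {sorted(missing)}")
    return df


def read_eqtl_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"eqtl_set_id": str, "variant_id": str,
                                            "gene_id": str})
    missing = set(EQTL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"eQTL table lacks column(s): {sorted(missing)}")
    return df


def write_ld_matrix(ld: LDMatrix, path) -> None:
    df = pd.DataFrame(ld.r2, index=ld.variants, columns=ld.variants)
    df.index.name = "variant_id"
    # positions ride along as a second header line comment-free format is
    # kept simple: a sibling .pos.tsv carries variant positions
    write_matrix_tsv(df, path)
    pos = pd.DataFrame({"variant_id": ld.variants, "position": ld.positions})
    pos.to_csv(Path(path).with_suffix(".pos.tsv"), sep="\t", index=False)


def read_ld_matrix(path, locus_id: str | None = None) -> LDMatrix:
    df = read_matrix_tsv(path)
    pos = pd.read_csv(Path(path).with_suffix(".pos.tsv"), sep="\t",
                      dtype={"variant_id": str})
    pos = pos.set_index("variant_id")["position"]
    variants = list(df.index)
    return LDMatrix(
        locus_id=locus_id or Path(path).stem,
        variants=variants,
        positions=pos.loc[variants].to_numpy(),
        r2=df.to_numpy(),
    )


def write_ranked_gene_matrix(rgm: RankedGeneMatrix, path) -> None:
    rgm.ranks.to_csv(path, sep="\t")


def read_ranked_gene_matrix(path) -> RankedGeneMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RankedGeneMatrix(ranks=df.astype(np.int64))


def write_truth(truth: PlantedTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))


def read_truth(path) -> PlantedTruth:
    return PlantedTruth.from_dict(json.loads(Path(path).read_text()))
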