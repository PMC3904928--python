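"""Readers and writers: VCF/TSV genotypes, phenotype tables, pools, results.

Coordinates are 1-based inclusive as in VCF.  Sample ids join the genotype,
phenotype and covariate tables (inner join; mismatches are logged).
"""

from __future__ import annotations

import logging
import os
import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .popgen_sim import HaplotypePool
from .score_core import GenotypeMatrix, InvalidInputError, prepare_genotypes

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_table",
    "read_phenotype",
    "read_partition_labels",
    "write_results",
    "read_results",
    "write_pool",
    "read_pool",
]

_POS_SUFFIX = re.compile(r".*[:_](\d+)$")


def _impute_missing(values: np.ndarray, samples: list[str], policy: str) -> tuple:
    missing = np.isnan(values)
    if not missing.any():
        return values, samples
    if policy == "error":
        raise InvalidInputError("missing genotypes present and policy is 'error'")
    if policy == "drop-sample":
        keep = ~missing.any(axis=1)
        if not keep.any():
            raise InvalidInputError("all samples carry missing genotypes")
        dropped = [s for s, k in zip(samples, keep) if not k]
        logger.warning("dropping %d sample(s) with missing genotypes: %s", len(dropped), dropped)
        return values[keep], [s for s, k in zip(samples, keep) if k]
    if policy != "impute":
        raise InvalidInputError(f"unknown missing-genotype policy {policy!r}")
    # mean imputation per variant, rounded back to allele counts
    col_mean = np.nanmean(values, axis=0)
    idx = np.where(missing)
    values[idx] = np.rint(col_mean[idx[1]])
    return values, samples


def _read_vcf(path: str, annotation_key: Optional[str]) -> tuple:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    ids, positions, annotations, columns = [], [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping multi-allelic site %s:%d", variant.CHROM, variant.POS
            )
            continue
        gt = np.asarray(variant.gt_types, dtype=float)
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        counts = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        columns.append(counts)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        positions.append(variant.POS)
        ann = None
        if annotation_key is not None:
            ann = variant.INFO.get(annotation_key)
        annotations.append(str(ann) if ann is not None else "unknown")
    if not columns:
        raise InvalidInputError(f"no usable biallelic variants in {path}")
    values = np.column_stack(columns)
    has_ann = annotation_key is not None
    return samples, values, ids, positions, (annotations if has_ann else None)


def _read_tsv_genotypes(path: str) -> tuple:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise InvalidInputError(f"no variant columns in {path}")
    ids = [str(c) for c in df.columns]
    positions = []
    for i, vid in enumerate(ids):
        m = _POS_SUFFIX.match(vid)
        positions.append(int(m.group(1)) if m else i + 1)
    samples = [str(s) for s in df.index]
    return samples, df.to_numpy(dtype=float), ids, positions, None


def read_genotypes(
    path: str,
    fmt: Optional[str] = None,
    annotation_key: Optional[str] = None,
    missing: str = "impute",
    prepare: bool = True,
) -> tuple[list[str], GenotypeMatrix]:
    """Load a genotype matrix from VCF or headered TSV.

    Returns ``(sample_ids, GenotypeMatrix)``.  VCF sites must be biallelic
    (others are skipped with a warning) and GT fields are converted to
    alt-allele counts; TSV rows are samples and columns variants, with the
    position parsed from a ``name:pos`` / ``name_pos`` column suffix when
    present (column order otherwise).  After loading, variants are
    minor-allele recoded, monomorphic sites dropped and columns sorted by
    position unless ``prepare=False``.  Missing genotypes follow the
    ``missing`` policy: ``impute`` (per-variant mean), ``drop-sample`` or
    ``error``.
    """
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if fmt == "vcf":
        samples, values, ids, positions, annotations = _read_vcf(path, annotation_key)
    elif fmt == "tsv":
        samples, values, ids, positions, annotations = _read_tsv_genotypes(path)
    else:
        raise InvalidInputError(f"unknown genotype format {fmt!r}")
    values, samples = _impute_missing(values, samples, missing)
    gm = GenotypeMatrix(
        values=values.astype(np.int64),
        variant_ids=ids,
        positions=np.asarray(positions),
        annotations=annotations,
    )
    if prepare:
        gm = prepare_genotypes(gm)
    return samples, gm


def read_table(path: str) -> pd.DataFrame:
    """Headered TSV keyed by sample id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_phenotype(path: str, column: Optional[str] = None) -> pd.Series:
    df = read_table(path)
    if column is None:
        column = df.columns[0]
    if column not in df.columns:
        raise InvalidInputError(f"phenotype column {column!r} not in {path}")
    return df[column].astype(float)


def read_partition_labels(path: str, variant_ids: list[str]) -> list[str]:
    """Two-column TSV (variant_id, group_label) mapped onto ``variant_ids``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["variant_id", "label"], dtype=str)
    mapping = dict(zip(df["variant_id"], df["label"]))
    missing = [v for v in variant_ids if v not in mapping]
    if missing:
        raise InvalidInputError(f"partition file lacks labels for variants: {missing[:5]}")
    return [mapping[v] for v in variant_ids]


def write_results(results: pd.DataFrame, path: str, config: Optional[dict] = None, force: bool = False) -> None:
    """Write a results table as TSV with a reproducibility header.

    Header lines start with ``#key=value`` and carry the full run
    configuration; an existing file is only overwritten with ``force``.
    """
    if os.path.exists(path) and not force:
        raise FileExistsError(f"{path} exists; pass force=True (or --force) to overwrite")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (config or {}).items():
            fh.write(f"#{key}={val}\n")
        results.to_csv(fh, sep="\t", index=False)


def read_results(path: str) -> tuple[pd.DataFrame, dict]:
    """Read back a results TSV written by :func:`write_results`."""
    header = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].rstrip("\n").partition("=")
            header[key] = val
            skip += 1
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    return df, header


def write_pool(pool: HaplotypePool, path: str) -> None:
    """Rectangular 0/1 pool file: a ``#positions`` header row, one haplotype per line."""
    with open(path, "w") as fh:
        fh.write("#positions\t" + "\t".join(map(str, pool.positions)) + "\n")
        np.savetxt(fh, pool.haplotypes, fmt="%d", delimiter="\t")


def read_pool(path: str) -> HaplotypePool:
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
        if first[0] != "#positions":
            raise InvalidInputError("pool file must start with a '#positions' header row")
        positions = np.asarray(first[1:], dtype=np.int64)
        hap = np.loadtxt(fh, dtype=np.int8, delimiter="\t", ndmin=2)
    return HaplotypePool(haplotypes=hap, positions=positions)
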