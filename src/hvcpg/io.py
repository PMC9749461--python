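"""Readers and writers for the pipeline's plain-text formats.

Conventions: Beta matrices are TSV with the CpG id as first column and a
sample-id header; covariates are TSV (sample, age, sex); probe annotation
is a 4-column BED (0-based half-open single-base intervals) with a TSV
sidecar for the reliability flag, or a single annotation TSV; feature
tracks are BED; CpG sets are one id per line; mQTL tables are TSV with
columns cpg, snp, beta, maf, kind, p.  Missing values are written as "NA".
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .core import InputError, MethylationDataset, ProbeAnnotation

NA_TOKENS = ["NA", "NaN", ""]
PathLike = Union[str, Path]


def _read_tsv(path: PathLike, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=NA_TOKENS, keep_default_na=False, **kw)
    except (pd.errors.ParserError, ValueError) as exc:
        raise InputError(f"{path}: {exc}") from exc


def read_beta_matrix(path: PathLike) -> pd.DataFrame:
    """CpG x sample Beta matrix from TSV; duplicate CpG ids are an error."""
    df = _read_tsv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{path}: duplicate CpG id {dup!r}")
    bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(bad):
        for col in bad:
            culprit = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(culprit):
                line = df.index.get_loc(culprit.index[0]) + 2  # header + 1-based
                raise InputError(f"{path}: non-numeric cell {culprit.iloc[0]!r} near line {line}")
        df = df.astype(float)
    df.index.name = "cpg"
    return df.astype(float)


def write_beta_matrix(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label="cpg")


def read_covariates(path: PathLike) -> pd.DataFrame:
    return _read_tsv(path, index_col=0)


def write_covariates(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label="sample")


def read_dataset(
    beta_path: PathLike,
    covariates_path: PathLike = None,
    detection_p_path: PathLike = None,
    dataset_id: str = None,
    tissue: str = "",
    ethnicity: str = "",
) -> MethylationDataset:
    beta = read_beta_matrix(beta_path)
    cov = read_covariates(covariates_path) if covariates_path else pd.DataFrame(index=beta.columns)
    det = read_beta_matrix(detection_p_path) if detection_p_path else None
    return MethylationDataset(
        dataset_id=dataset_id or Path(beta_path).stem,
        beta=beta, covariates=cov, detection_p=det, tissue=tissue, ethnicity=ethnicity,
    )


def write_dataset(ds: MethylationDataset, outdir: PathLike) -> dict:
    """Write one dataset's matrices under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"beta": outdir / f"{ds.dataset_id}.beta.tsv",
             "covariates": outdir / f"{ds.dataset_id}.covariates.tsv"}
    write_beta_matrix(ds.beta, paths["beta"])
    write_covariates(ds.covariates, paths["covariates"])
    if ds.detection_p is not None:
        paths["detection_p"] = outdir / f"{ds.dataset_id}.detection_p.tsv"
        write_beta_matrix(ds.detection_p, paths["detection_p"])
    return {k: str(v) for k, v in paths.items()}


def read_annotation(path: PathLike) -> ProbeAnnotation:
    """Annotation TSV with columns cpg, chrom, pos (1-based), reliable."""
    df = _read_tsv(path)
    if "cpg" not in df.columns:
        raise InputError(f"{path}: annotation needs a 'cpg' column")
    df = df.set_index("cpg")
    if "reliable" not in df.columns:
        df["reliable"] = True
    df["reliable"] = df["reliable"].astype(bool)
    return ProbeAnnotation(df[["chrom", "pos", "reliable"]])


def write_annotation(annotation: ProbeAnnotation, tsv_path: PathLike, bed_path: PathLike = None) -> None:
    annotation.table.to_csv(tsv_path, sep="\t", index_label="cpg")
    if bed_path:
        tab = annotation.table
        bed = pd.DataFrame(
            {"chrom": tab["chrom"], "start": tab["pos"] - 1, "end": tab["pos"], "name": tab.index}
        )
        bed.to_csv(bed_path, sep="\t", header=False, index=False)


def read_bed(path: PathLike) -> pd.DataFrame:
    """Feature track: BED (chrom, start, end[, name]); 0-based half-open."""
    df = _read_tsv(path, header=None)
    if df.shape[1] < 3:
        raise InputError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df.columns:
        df["name"] = [f"iv{i}" for i in range(len(df))]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(intervals: pd.DataFrame, path: PathLike) -> None:
    intervals[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", header=False, index=False)


def read_id_list(path: PathLike) -> set:
    """One CpG id per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_id_list(ids: Iterable[str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for i in sorted(set(ids)):
            fh.write(f"{i}\n")


MQTL_COLUMNS = ["cpg", "snp", "beta", "maf", "kind", "p"]


def read_mqtl_table(path: PathLike) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = set(MQTL_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: mQTL table missing columns {sorted(missing)}")
    return df[MQTL_COLUMNS]


def write_mqtl_table(df: pd.DataFrame, path: PathLike) -> None:
    df[MQTL_COLUMNS].to_csv(path, sep="\t", index=False)


def write_hvcpg_result(result: pd.DataFrame, annotation: ProbeAnnotation, tsv_path: PathLike,
                       bed_path: PathLike = None) -> None:
    """hvCpG calls as a TSV report plus optional single-base BED of calls."""
    result.to_csv(tsv_path, sep="\t", na_rep="NA", index_label="cpg")
    if bed_path:
        hv = result.index[result["is_hvcpg"]]
        pos = annotation.positions(hv.intersection(annotation.cpgs))
        bed = pd.DataFrame(
            {"chrom": pos["chrom"], "start": pos["pos"] - 1, "end": pos["pos"], "name": pos.index}
        )
        bed.to_csv(bed_path, sep="\t", header=False, index=False)


def write_cluster_set(clusterset, annotation: ProbeAnnotation, bed_path: PathLike,
                      membership_path: PathLike) -> None:
    """Cluster spans as BED plus a TSV membership table."""
    rows, bed_rows = [], []
    for k, members in enumerate(clusterset.clusters):
        pos = annotation.positions(pd.Index(members))
        bed_rows.append(
            {"chrom": pos["chrom"].iloc[0], "start": int(pos["pos"].min()) - 1,
             "end": int(pos["pos"].max()), "name": f"cluster{k:05d}"}
        )
        rows += [{"cpg": m, "cluster": f"cluster{k:05d}"} for m in members]
    rows += [{"cpg": s, "cluster": "singleton"} for s in clusterset.singletons]
    pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name"]).to_csv(
        bed_path, sep="\t", header=False, index=False
    )
    pd.DataFrame(rows, columns=["cpg", "cluster"]).to_csv(membership_path, sep="\t", index=False)
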