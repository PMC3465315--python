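"""Readers and writers for the pipeline's plain-text formats.

Formats: PLINK text PED/MAP for genotypes, a SNP metadata TSV (locus and
external replication statistics), probes as BED (0-based half-open), sample
covariates and expression matrices as TSV, a sparse long-format flag sidecar,
and a YAML run configuration. MAP/metadata positions are 1-based; BED is
0-based half-open; the conversion happens only here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    FLAG_NAMES,
    GenotypeMatrix,
    ProbeAnnotation,
    RawExpression,
    SampleTable,
    ValidationError,
)

MISSING_TOKEN = "."
SNP_META_FILE_COLUMNS = [
    "snp_id", "chromosome", "position", "minor_allele", "major_allele",
    "locus", "replication_p", "risk_or", "discovery_direction",
]


# ---------------------------------------------------------------------------
# genotypes: PED/MAP + metadata TSV
# ---------------------------------------------------------------------------

def read_snp_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = set(SNP_META_FILE_COLUMNS) - set(meta.columns)
    if missing:
        raise ValidationError(f"SNP metadata missing columns: {sorted(missing)}")
    if meta["snp_id"].duplicated().any():
        dups = meta.loc[meta["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValidationError(f"duplicate SNP ids in metadata: {dups}")
    return meta.set_index("snp_id")


def read_genotypes(ped_path, map_path, metadata_path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP plus the SNP metadata TSV into dosages.

    Alleles are converted to minor-allele counts using the metadata's
    minor/major labels; "0 0" is a missing call. Errors carry line numbers.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValidationError(f"{map_path}:{lineno}: expected 4 MAP fields")
            chrom, snp_id, _cm, pos = parts
            map_rows.append((chrom, snp_id, int(pos)))
    snp_ids = [r[1] for r in map_rows]
    if len(set(snp_ids)) != len(snp_ids):
        raise ValidationError(f"{map_path}: duplicate SNP ids")

    meta = read_snp_metadata(metadata_path)
    unknown = [s for s in snp_ids if s not in meta.index]
    if unknown:
        raise ValidationError(f"SNPs in MAP absent from metadata: {unknown[:5]}")
    meta = meta.loc[snp_ids].copy()
    meta["chromosome"] = [r[0] for r in map_rows]
    meta["position"] = [r[2] for r in map_rows]

    sample_ids: list[str] = []
    phenos: list[str] = []
    rows: list[np.ndarray] = []
    minor = meta["minor_allele"].to_numpy()
    major = meta["major_allele"].to_numpy()
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(snp_ids):
                raise ValidationError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * len(snp_ids)} fields, "
                    f"got {len(parts)} (PED/MAP mismatch?)"
                )
            iid = parts[1]
            if iid in sample_ids:
                raise ValidationError(f"{ped_path}:{lineno}: duplicate sample id {iid!r}")
            sample_ids.append(iid)
            phenos.append(parts[5])
            alleles = np.array(parts[6:], dtype=object).reshape(-1, 2)
            dose = np.zeros(len(snp_ids))
            for k in range(len(snp_ids)):
                a, b = alleles[k]
                if a == "0" and b == "0":
                    dose[k] = np.nan
                    continue
                for allele in (a, b):
                    if allele == minor[k]:
                        dose[k] += 1
                    elif allele != major[k]:
                        raise ValidationError(
                            f"{ped_path}:{lineno}: allele {allele!r} at SNP "
                            f"{snp_ids[k]} not in {{{minor[k]}, {major[k]}, 0}}"
                        )
            rows.append(dose)
    dosages = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"),
                           columns=snp_ids)
    return GenotypeMatrix(dosages, meta)


def write_genotypes(genotypes: GenotypeMatrix, samples: SampleTable,
                    ped_path, map_path, metadata_path) -> None:
    snps = genotypes.snps
    with open(map_path, "w") as fh:
        for snp_id, row in snps.iterrows():
            fh.write(f"{row['chromosome']}\t{snp_id}\t0\t{int(row['position'])}\n")
    minor = snps["minor_allele"].to_numpy()
    major = snps["major_allele"].to_numpy()
    status = samples.status
    with open(ped_path, "w") as fh:
        for sample_id, dose_row in genotypes.dosages.iterrows():
            pheno = "2" if status.loc[sample_id] == "case" else "1"
            fields = [str(sample_id), str(sample_id), "0", "0", "1", pheno]
            for k, d in enumerate(dose_row.to_numpy(dtype=float)):
                if np.isnan(d):
                    fields += ["0", "0"]
                else:
                    n_minor = int(d)
                    fields += [minor[k]] * n_minor + [major[k]] * (2 - n_minor)
            fh.write(" ".join(fields) + "\n")
    out = snps.reset_index()
    out = out.rename(columns={out.columns[0]: "snp_id"})
    out[SNP_META_FILE_COLUMNS].to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# probes: BED
# ---------------------------------------------------------------------------

def read_probe_bed(path) -> ProbeAnnotation:
    """Probe intervals from BED: chrom, start, end, name[, gene]. 0-based
    half-open; the name column is the probe id; strand, if present, ignored."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4 or not parts[3].strip():
                raise ValidationError(f"{path}:{lineno}: BED needs a name (4th) field")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3].strip()
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end")
            gene = parts[4].strip() if len(parts) > 4 else ""
            rows.append({"probe_id": name, "chromosome": chrom, "start": start,
                         "end": end, "gene": gene})
    frame = pd.DataFrame(rows).set_index("probe_id")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate probe ids: {dups}")
    return ProbeAnnotation(frame)


def write_probe_bed(annotation: ProbeAnnotation, path) -> None:
    with open(path, "w") as fh:
        for probe_id, row in annotation.data.iterrows():
            gene = row.get("gene", "")
            fh.write(
                f"{row['chromosome']}\t{int(row['start'])}\t{int(row['end'])}"
                f"\t{probe_id}\t{gene}\n"
            )


# ---------------------------------------------------------------------------
# samples & expression TSV
# ---------------------------------------------------------------------------

def read_samples(path) -> SampleTable:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    return SampleTable(frame)


def write_samples(samples: SampleTable, path) -> None:
    samples.data.to_csv(path, sep="\t", index_label="sample_id")


def read_expression(path) -> pd.DataFrame:
    """Expression TSV: first column probe id, remaining columns samples,
    '.' for missing. Duplicate probe ids (replicates) are allowed."""
    frame = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN])
    frame = frame.set_index(frame.columns[0])
    frame.index.name = "probe_id"
    return frame.astype(float)


def write_expression(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="probe_id",
                  na_rep=MISSING_TOKEN, float_format="%.17g")


def read_flags(path, values: pd.DataFrame) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Sparse long-format sidecar (probe, sample, flag, value) -> dense masks.

    Returns (flags, detectable). Unlisted (probe, sample, flag) triples default
    to flag off; unlisted detectability defaults to detectable.
    """
    long = pd.read_csv(path, sep="\t", dtype={"value": int})
    required = {"probe", "sample", "flag", "value"}
    if set(long.columns) != required:
        raise ValidationError(f"flag sidecar must have columns {sorted(required)}")
    flags = {
        name: pd.DataFrame(False, index=values.index, columns=values.columns)
        for name in FLAG_NAMES
    }
    detectable = pd.DataFrame(True, index=values.index, columns=values.columns)
    known = set(FLAG_NAMES) | {"detectable"}
    for _, row in long.iterrows():
        if row["flag"] not in known:
            raise ValidationError(f"unknown flag {row['flag']!r} in {path}")
        if row["flag"] == "detectable":
            detectable.loc[row["probe"], row["sample"]] = bool(row["value"])
        else:
            flags[row["flag"]].loc[row["probe"], row["sample"]] = bool(row["value"])
    return flags, detectable


def write_flags(flags: dict[str, pd.DataFrame], detectable: pd.DataFrame, path) -> None:
    """Write only the non-default entries (flag on, or non-detectable)."""
    rows = []
    for name, table in flags.items():
        arr = table.to_numpy(dtype=bool)
        for i, j in zip(*np.nonzero(arr)):
            rows.append((table.index[i], table.columns[j], name, 1))
    nondet = ~detectable.to_numpy(dtype=bool)
    for i, j in zip(*np.nonzero(nondet)):
        rows.append((detectable.index[i], detectable.columns[j], "detectable", 0))
    frame = pd.DataFrame(rows, columns=["probe", "sample", "flag", "value"])
    frame.to_csv(path, sep="\t", index=False)


def read_raw_expression(expr_path, flags_path, samples: SampleTable) -> RawExpression:
    values = read_expression(expr_path)
    missing = [s for s in values.columns if s not in samples.sample_ids]
    if missing:
        raise ValidationError(f"expression arrays without sample records: {missing[:5]}")
    flags, detectable = read_flags(flags_path, values)
    group = samples.status.loc[values.columns]
    return RawExpression(values, flags, detectable, group)


# ---------------------------------------------------------------------------
# planted effects, config, dataset bundle
# ---------------------------------------------------------------------------

EFFECT_FILE_COLUMNS = ["snp_id", "probe_id", "beta_case", "beta_control", "mode"]


def write_effects(effects, path) -> None:
    frame = pd.DataFrame(
        [(e.snp_id, e.probe_id, e.beta_case, e.beta_control, e.mode) for e in effects],
        columns=EFFECT_FILE_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_effects(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dataset_files(dataset, outdir) -> dict[str, str]:
    """Write the complete synthetic input file set; see esnp.simulate."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".esnp_write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ValidationError(f"cannot write to {outdir}: {exc}") from exc
    paths = {
        "ped": outdir / "genotypes.ped",
        "map": outdir / "genotypes.map",
        "snp_metadata": outdir / "snps.tsv",
        "samples": outdir / "samples.tsv",
        "expression": outdir / "expression.tsv",
        "flags": outdir / "expression_flags.tsv",
        "probe_bed": outdir / "probes.bed",
        "effects": outdir / "planted_effects.tsv",
    }
    write_genotypes(dataset.genotypes, dataset.samples,
                    paths["ped"], paths["map"], paths["snp_metadata"])
    write_samples(dataset.samples, paths["samples"])
    write_expression(dataset.raw.values, paths["expression"])
    write_flags(dataset.raw.flags, dataset.raw.detectable, paths["flags"])
    write_probe_bed(dataset.annotation, paths["probe_bed"])
    write_effects(dataset.spec.effects, paths["effects"])
    return {k: str(v) for k, v in paths.items()}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg
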