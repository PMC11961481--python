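"""Readers and writers for the external formats the pipeline touches.

Supported formats: VCF 4.x (GT field only, via cyvcf2), a plain TSV genotype
matrix (header row of SNP ids, one row per participant, with an optional
``<name>.meta.tsv`` sidecar carrying chrom/pos/ref metadata), ASCII PLY / OBJ
triangle meshes (via trimesh), NIfTI-1 volumes (via nibabel), BED4 gene
annotations, and TSV covariate / phenotype tables.

All genomic positions are converted to the internal 0-based half-open
convention on read and back to 1-based on write.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .types import (
    MISSING,
    FormatError,
    GenotypeMatrix,
    SurfaceMesh,
    ValidationError,
    VolumeImage,
    validate_covariates,
    validate_gene_annotation,
)

_VALID_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | os.PathLike, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or TSV.

    ``fmt`` is inferred from the extension when not given ("vcf" or "tsv").
    Calls are reference-allele counts; ``./.`` becomes the missing marker.
    """
    path = Path(path)
    if fmt is None:
        suffixes = "".join(path.suffixes).lower()
        fmt = "vcf" if ".vcf" in suffixes else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv_genotypes(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise FormatError(f"{path}: cannot open as VCF: {exc}") from exc
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    meta_rows = []
    # header line count so parse errors can name a line number
    n_header = sum(1 for line in open(path, "rt") if line.startswith("#"))
    for i, variant in enumerate(vcf):
        lineno = n_header + i + 1
        gts = variant.genotypes
        calls = np.empty(len(samples), dtype=np.int8)
        for j, gt in enumerate(gts):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 2:
                raise FormatError(
                    f"{path}:{lineno}: non-diploid GT for sample {samples[j]}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                calls[j] = MISSING
            else:
                calls[j] = int(alleles[0] == 0) + int(alleles[1] == 0)
        has_id = variant.ID is not None and variant.ID != "."
        ref = variant.REF or ""
        meta_rows.append(
            {
                "id": variant.ID if has_id else f"__noid_{i}",
                "chrom": str(variant.CHROM),
                "pos": int(variant.POS) - 1,  # to 0-based
                "ref_allele": ref,
                "has_ref_id": has_id,
                "ref_allele_valid": ref in _VALID_BASES,
            }
        )
        columns.append(calls)
    if not columns:
        raise FormatError(f"{path}: VCF contains no variant records")
    calls = np.stack(columns, axis=1)
    return GenotypeMatrix(calls=calls, snp_meta=pd.DataFrame(meta_rows), participant_ids=samples)


def _read_tsv_genotypes(path: Path) -> GenotypeMatrix:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: expected participant id column plus SNP columns")
    snp_ids = list(table.columns[1:])
    participant_ids = table.iloc[:, 0].astype(str).tolist()
    raw = table.iloc[:, 1:].to_numpy()
    calls = np.empty(raw.shape, dtype=np.int8)
    for (r, c), value in np.ndenumerate(raw):
        text = "" if value is None else str(value).strip()
        if text in ("", "NA", "nan", ".", str(MISSING)):
            calls[r, c] = MISSING
        elif text in ("0", "1", "2"):
            calls[r, c] = int(text)
        else:
            raise FormatError(f"{path}: line {r + 2}: invalid genotype {text!r}")
    side = Path(str(path) + ".meta.tsv")
    if side.exists():
        meta = pd.read_csv(side, sep="\t", dtype={"chrom": str})
        meta["has_ref_id"] = meta["has_ref_id"].astype(bool)
        meta["ref_allele_valid"] = meta["ref_allele_valid"].astype(bool)
        if list(meta["id"]) != snp_ids:
            raise FormatError(f"{side}: SNP ids do not match {path}")
    else:
        meta = pd.DataFrame(
            {
                "id": snp_ids,
                "chrom": "0",
                "pos": np.arange(len(snp_ids)),
                "ref_allele": "A",
                "has_ref_id": True,
                "ref_allele_valid": True,
            }
        )
    return GenotypeMatrix(calls=calls, snp_meta=meta, participant_ids=participant_ids)


def write_genotypes_tsv(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a genotype TSV plus a ``.meta.tsv`` sidecar with SNP metadata."""
    path = Path(path)
    table = pd.DataFrame(g.calls, columns=g.snp_meta["id"])
    table = table.astype(object).mask(table == MISSING, "NA")
    table.insert(0, "participant_id", g.participant_ids)
    table.to_csv(path, sep="\t", index=False)
    g.snp_meta.to_csv(str(path) + ".meta.tsv", sep="\t", index=False)


_GT_STRING = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
_ALT_FOR = {"A": "G", "C": "T", "G": "A", "T": "C"}


def write_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF 4.2 with GT fields (positions printed 1-based)."""
    path = Path(path)
    meta = g.snp_meta
    order = np.lexsort((meta["pos"].to_numpy(), meta["chrom"].to_numpy()))
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(meta["chrom"].to_numpy()[order]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(p) for p in g.participant_ids)
            + "\n"
        )
        for j in order:
            row = meta.iloc[j]
            ref = row["ref_allele"] if row["ref_allele_valid"] else "N"
            alt = _ALT_FOR.get(ref, "A")
            snp_id = row["id"] if row["has_ref_id"] else "."
            gts = "\t".join(_GT_STRING[int(v)] for v in g.calls[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t{snp_id}\t{ref}\t{alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def _check_triangular_text(path: Path) -> None:
    """Reject quad/polygon faces in ASCII PLY or OBJ before loading.

    trimesh silently triangulates polygons, so the arity check has to look at
    the file itself.  Binary PLY is left to trimesh.
    """
    suffix = path.suffix.lower()
    if suffix == ".obj":
        for lineno, line in enumerate(open(path, "rt"), start=1):
            if line.startswith("f "):
                n = len(line.split()) - 1
                if n != 3:
                    raise FormatError(f"{path}:{lineno}: non-triangular face ({n} vertices)")
    elif suffix == ".ply":
        with open(path, "rb") as fh:
            header = fh.readline()
            if not header.startswith(b"ply"):
                raise FormatError(f"{path}: not a PLY file")
            fmt_line = fh.readline()
            if b"ascii" not in fmt_line:
                return  # binary PLY: rely on the parsed faces
        lines = open(path, "rt", errors="replace").read().splitlines()
        n_vertex = n_face = 0
        end = 0
        current = None
        for i, line in enumerate(lines):
            parts = line.split()
            if parts[:1] == ["element"]:
                current = parts[1]
                if current == "vertex":
                    n_vertex = int(parts[2])
                elif current == "face":
                    n_face = int(parts[2])
            if line.strip() == "end_header":
                end = i
                break
        face_lines = lines[end + 1 + n_vertex : end + 1 + n_vertex + n_face]
        for k, line in enumerate(face_lines):
            arity = int(line.split()[0])
            if arity != 3:
                raise FormatError(
                    f"{path}: face {k}: non-triangular face ({arity} vertices)"
                )


def read_mesh(path: str | os.PathLike, name: str | None = None) -> SurfaceMesh:
    """Read a triangle mesh from PLY or OBJ.  Non-triangular faces are errors."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_triangular_text(path)
    try:
        tm = trimesh.load_mesh(str(path), process=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse mesh: {exc}") from exc
    if name is None:
        name = path.stem
    return SurfaceMesh(vertices=np.asarray(tm.vertices, dtype=np.float64),
                       faces=np.asarray(tm.faces, dtype=np.int64), name=name)


def write_mesh(mesh: SurfaceMesh, path: str | os.PathLike) -> None:
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if path.suffix.lower() == ".ply":
        data = tm.export(file_type="ply", encoding="ascii")
        mode = "wb" if isinstance(data, bytes) else "wt"
        with open(path, mode) as fh:
            fh.write(data)
    else:
        tm.export(str(path))


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike, labels_path: str | os.PathLike | None = None) -> VolumeImage:
    img = nib.load(str(path))
    labels = None
    if labels_path is not None:
        lab_img = nib.load(str(labels_path))
        labels = np.asarray(lab_img.get_fdata(), dtype=np.int16)
    return VolumeImage(
        intensities=np.asarray(img.get_fdata(), dtype=np.float64),
        affine=np.asarray(img.affine, dtype=np.float64),
        labels=labels,
    )


def write_volume(vol: VolumeImage, path: str | os.PathLike,
                 labels_path: str | os.PathLike | None = None) -> None:
    nib.save(nib.Nifti1Image(vol.intensities.astype(np.float64), vol.affine), str(path))
    if labels_path is not None and vol.labels is not None:
        nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), vol.affine), str(labels_path))


# ---------------------------------------------------------------------------
# BED gene annotations
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED4+ annotation into a sorted (chrom, start) gene table.

    BED is already 0-based half-open, so intervals are stored verbatim.
    """
    path = Path(path)
    rows = []
    for lineno, line in enumerate(open(path, "rt"), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}:{lineno}: BED4 needs at least 4 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer interval bounds") from exc
        rows.append({"chrom": parts[0], "start": start, "end": end, "gene_name": parts[3]})
    if not rows:
        raise FormatError(f"{path}: empty BED file")
    try:
        return validate_gene_annotation(pd.DataFrame(rows))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_bed(ann: pd.DataFrame, path: str | os.PathLike) -> None:
    ann = validate_gene_annotation(ann)
    ann[["chrom", "start", "end", "gene_name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# covariates / phenotypes
# ---------------------------------------------------------------------------

def read_covariates(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    return validate_covariates(table)


def write_covariates(covars: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_covariates(covars)
    covars.to_csv(path, sep="\t", index_label="participant_id")


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Phenotype TSV: one row per participant, one column per location."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    return table


def write_phenotypes(pheno: pd.DataFrame, path: str | os.PathLike) -> None:
    pheno.to_csv(path, sep="\t", index_label="participant_id", float_format="%.10g")


def validate_file(path: str | os.PathLike) -> str:
    """Best-effort validation used by ``cortmapgen io validate``.

    Returns a short description of the recognized content; raises on failure.
    """
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if ".vcf" in suffix or (path.suffix in (".tsv", ".txt") and "geno" in path.stem):
        g = read_genotypes(path)
        return f"genotypes: {g.n_participants} participants x {g.n_snps} SNPs"
    if path.suffix.lower() in (".ply", ".obj"):
        mesh = read_mesh(path)
        return f"mesh: {len(mesh.vertices)} vertices, {len(mesh.faces)} faces"
    if ".nii" in suffix:
        vol = read_volume(path)
        return f"volume: shape {vol.intensities.shape}"
    if path.suffix.lower() == ".bed":
        ann = read_bed(path)
        return f"annotation: {len(ann)} genes"
    if path.suffix.lower() in (".tsv", ".txt"):
        table = pd.read_csv(path, sep="\t")
        return f"table: {table.shape[0]} rows x {table.shape[1]} columns"
    raise FormatError(f"{path}: unrecognized format")
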