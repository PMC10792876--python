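"""Readers and writers for the pipeline's file formats.

Variants travel either as an uncompressed VCF (v4.x, annotations in INFO
keys) or as a canonical tab-separated dialect with the column names of
:data:`sdyburden.datatypes.VARIANT_COLUMNS`.  Universe, manifest, panel,
and damage-score tables are plain TSV.  Malformed variant rows are
collected into a line-numbered parse report rather than aborting the
whole read; a missing mandatory column aborts immediately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .datatypes import (
    VARIANT_COLUMNS,
    CohortManifest,
    DamageCallSet,
    GenePanel,
    GeneUniverse,
    VariantRecord,
    variants_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "VariantReadResult",
    "VcfInfoMap",
    "read_variants",
    "write_variants",
    "read_panel",
    "write_panel",
    "read_universe",
    "write_universe",
    "read_manifest",
    "write_manifest",
    "read_damage_scores",
    "write_damage_scores",
]


@dataclass(frozen=True)
class ParseError:
    """One rejected input row."""

    line: int
    field: str
    message: str


@dataclass
class VariantReadResult:
    """Parsed records plus the rejection report."""

    records: list[VariantRecord]
    errors: list[ParseError] = field(default_factory=list)

    def raise_if_errors(self) -> "VariantReadResult":
        if self.errors:
            first = self.errors[0]
            raise ValueError(
                f"{len(self.errors)} malformed variant rows; first at line "
                f"{first.line} ({first.field}): {first.message}"
            )
        return self


@dataclass(frozen=True)
class VcfInfoMap:
    """Which INFO keys carry each annotation in the VCF dialect."""

    gene: str = "GENE"
    consequence: str = "CONSEQ"
    aa_change: str = "AACHANGE"
    af_global: str = "AF"
    af_ancestry: str = "AF_ANC"
    clinvar: str = "CLNSIG"
    acmg: str = "ACMG"
    mcap: str = "MCAP"


_MANDATORY_TSV = [
    "sample_id",
    "gene",
    "contig",
    "position",
    "ref",
    "alt",
    "consequence_class",
    "af_global",
]


def read_variants(
    path: str | Path,
    dialect: str = "tsv",
    info_map: Optional[VcfInfoMap] = None,
) -> VariantReadResult:
    """Read sample-level variant records from a TSV or VCF file.

    Multi-allelic VCF rows are split into one record per alternate
    allele.  Rows violating a record invariant (frequency out of range,
    ref == alt, ...) are rejected with their line number; the remaining
    rows still parse.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"variant file not found: {path}")
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path, info_map or VcfInfoMap())
    raise ValueError(f"unknown variant dialect {dialect!r}")


def _read_variants_tsv(path: Path) -> VariantReadResult:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_TSV if c not in table.columns]
    if missing:
        raise ValueError(
            f"variant TSV {path} missing mandatory column(s): {missing}"
        )
    records: list[VariantRecord] = []
    errors: list[ParseError] = []
    for i, row in enumerate(table.to_dict("records")):
        line = i + 2  # header is line 1
        try:
            records.append(
                VariantRecord(
                    sample_id=row["sample_id"],
                    gene=row["gene"],
                    contig=row["contig"],
                    position=int(row["position"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    consequence_class=row["consequence_class"],
                    af_global=float(row["af_global"]),
                    aa_change=row.get("aa_change") or None,
                    af_ancestry=(
                        float(row["af_ancestry"])
                        if row.get("af_ancestry")
                        else None
                    ),
                    clinvar_class=row.get("clinvar_class") or "absent",
                    acmg_class=row.get("acmg_class") or "unclassified",
                    mcap_score=(
                        float(row["mcap_score"]) if row.get("mcap_score") else None
                    ),
                    zygosity=row.get("zygosity") or "het",
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(
                ParseError(line=line, field=_offending_field(exc, row), message=str(exc))
            )
    if errors:
        logger.warning("rejected %d of %d rows in %s", len(errors), len(table), path)
    return VariantReadResult(records=records, errors=errors)


def _offending_field(exc: Exception, row: dict) -> str:
    msg = str(exc)
    for col in VARIANT_COLUMNS:
        if col in msg:
            return col
    return "row"


def _info_scalar(value, alt_index: int):
    """INFO values may be per-site scalars or per-alt tuples."""
    if isinstance(value, tuple):
        return value[alt_index] if alt_index < len(value) else None
    return value


def _get_info(info, key: str):
    """INFO lookup tolerant of keys absent from the header."""
    try:
        return info.get(key)
    except (KeyError, ValueError):
        return None


def _read_variants_vcf(path: Path, info_map: VcfInfoMap) -> VariantReadResult:
    records: list[VariantRecord] = []
    errors: list[ParseError] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            for alt_index, alt in enumerate(rec.alts or ()):
                allele_code = alt_index + 1
                info = rec.info
                af = _info_scalar(_get_info(info, info_map.af_global), alt_index)
                mcap = _info_scalar(_get_info(info, info_map.mcap), alt_index)
                af_anc = _info_scalar(_get_info(info, info_map.af_ancestry), alt_index)
                for sample in samples:
                    gt = rec.samples[sample].get("GT")
                    if gt is None:
                        continue
                    calls = [a for a in gt if a is not None]
                    n_alt = sum(1 for a in calls if a == allele_code)
                    if n_alt == 0:
                        continue
                    zygosity = "hom" if (calls and n_alt == len(calls)) else "het"
                    try:
                        records.append(
                            VariantRecord(
                                sample_id=sample,
                                gene=str(_info_scalar(_get_info(info, info_map.gene), alt_index)),
                                contig=str(rec.contig),
                                position=int(rec.pos),
                                ref=str(rec.ref),
                                alt=str(alt),
                                consequence_class=str(
                                    _info_scalar(_get_info(info, info_map.consequence), alt_index)
                                ),
                                af_global=float(af) if af is not None else 0.0,
                                aa_change=(
                                    str(_info_scalar(_get_info(info, info_map.aa_change), alt_index))
                                    if _get_info(info, info_map.aa_change) is not None
                                    else None
                                ),
                                af_ancestry=(
                                    float(af_anc) if af_anc is not None else None
                                ),
                                clinvar_class=str(
                                    _info_scalar(_get_info(info, info_map.clinvar), alt_index)
                                    or "absent"
                                ),
                                acmg_class=str(
                                    _info_scalar(_get_info(info, info_map.acmg), alt_index)
                                    or "unclassified"
                                ),
                                mcap_score=float(mcap) if mcap is not None else None,
                                zygosity=zygosity,
                            )
                        )
                    except ValueError as exc:
                        errors.append(
                            ParseError(
                                line=-1,
                                field="record",
                                message=f"{rec.contig}:{rec.pos} {exc}",
                            )
                        )
    return VariantReadResult(records=records, errors=errors)


def write_variants(
    variants,
    path: str | Path,
    dialect: str = "tsv",
    info_map: Optional[VcfInfoMap] = None,
    reference_label: str = "unknown",
) -> Path:
    """Write records in the TSV or VCF dialect (round-trip safe)."""
    path = Path(path)
    frame = (
        variants if isinstance(variants, pd.DataFrame) else variants_to_frame(variants)
    )
    if dialect == "tsv":
        frame.to_csv(path, sep="\t", index=False)
        return path
    if dialect == "vcf":
        _write_variants_vcf(frame, path, info_map or VcfInfoMap(), reference_label)
        return path
    raise ValueError(f"unknown variant dialect {dialect!r}")


def _write_variants_vcf(
    frame: pd.DataFrame, path: Path, info_map: VcfInfoMap, reference_label: str
) -> None:
    header = pysam.VariantHeader()
    header.add_line(f"##reference={reference_label}")
    for contig in pd.unique(frame["contig"].astype(str)):
        header.contigs.add(contig)
    for key, number, vtype, descr in [
        (info_map.gene, 1, "String", "Gene symbol"),
        (info_map.consequence, 1, "String", "Consequence class"),
        (info_map.aa_change, 1, "String", "Protein-level change"),
        (info_map.af_global, "A", "Float", "Global allele frequency"),
        (info_map.af_ancestry, "A", "Float", "Ancestry-specific allele frequency"),
        (info_map.clinvar, 1, "String", "ClinVar class"),
        (info_map.acmg, 1, "String", "ACMG class"),
        (info_map.mcap, "A", "Float", "M-CAP score"),
    ]:
        header.info.add(key, number, vtype, descr)
    header.formats.add("GT", 1, "String", "Genotype")
    samples = sorted(pd.unique(frame["sample_id"].astype(str)))
    for sample in samples:
        header.add_sample(sample)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        keys = ["contig", "position", "ref", "alt"]
        for (contig, pos, ref, alt), group in frame.groupby(keys, sort=True):
            first = group.iloc[0]
            rec = out.new_record(
                contig=str(contig), start=int(pos) - 1, alleles=(str(ref), str(alt))
            )
            rec.info[info_map.gene] = str(first["gene"])
            rec.info[info_map.consequence] = str(first["consequence_class"])
            if pd.notna(first.get("aa_change")) and first.get("aa_change"):
                rec.info[info_map.aa_change] = str(first["aa_change"])
            rec.info[info_map.af_global] = (float(first["af_global"]),)
            if pd.notna(first.get("af_ancestry")):
                rec.info[info_map.af_ancestry] = (float(first["af_ancestry"]),)
            rec.info[info_map.clinvar] = str(first["clinvar_class"])
            rec.info[info_map.acmg] = str(first["acmg_class"])
            if pd.notna(first.get("mcap_score")):
                rec.info[info_map.mcap] = (float(first["mcap_score"]),)
            carriers = group.set_index("sample_id")["zygosity"].to_dict()
            for sample in samples:
                zyg = carriers.get(sample)
                if zyg is None:
                    rec.samples[sample]["GT"] = (0, 0)
                elif zyg == "hom":
                    rec.samples[sample]["GT"] = (1, 1)
                else:
                    rec.samples[sample]["GT"] = (0, 1)
            out.write(rec)


def read_panel(path: str | Path, name: Optional[str] = None) -> GenePanel:
    """Read a gene panel: one symbol per line, '#' comments allowed."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"panel file not found: {path}")
    symbols: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        symbols.append(line)
    unique = set(symbols)
    n_dupes = len(symbols) - len(unique)
    if n_dupes:
        logger.info("panel %s: %d duplicate symbol(s) collapsed", path.name, n_dupes)
    if not unique:
        raise ValueError(f"panel file {path} contains no gene symbols")
    return GenePanel(name=name or path.stem, genes=frozenset(unique))


def write_panel(panel: GenePanel, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"# panel: {panel.name} ({len(panel)} genes)"]
    lines += sorted(panel.genes)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_universe(path: str | Path) -> GeneUniverse:
    table = pd.read_csv(path, sep="\t")
    return GeneUniverse(table)


def write_universe(universe: GeneUniverse, path: str | Path) -> Path:
    path = Path(path)
    universe.frame.to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | Path) -> CohortManifest:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=True)
    if "exclusion_reasons" in table.columns:
        table["exclusion_reasons"] = table["exclusion_reasons"].fillna("")
    return CohortManifest(table)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    manifest.frame.to_csv(path, sep="\t", index=False)
    return path


def read_damage_scores(path: str | Path, threshold: float = 0.69) -> DamageCallSet:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
    return DamageCallSet(table, threshold=threshold)


def write_damage_scores(calls: DamageCallSet, path: str | Path) -> Path:
    path = Path(path)
    calls.frame[["sample_id", "gene", "score"]].to_csv(path, sep="\t", index=False)
    return path
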