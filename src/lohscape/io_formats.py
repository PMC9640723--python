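"""Readers and writers for every on-disk format the pipeline touches.

All internal coordinates are 1-based inclusive.  BED gene models are the one
0-based half-open format and are converted on read/write.  Chromosome names
are normalized to a ``chr`` prefix; ``strict_chroms=True`` rejects input that
mixes prefixed and unprefixed names instead of normalizing silently.

The variant TSV dialect is defined by this package (columns below) so the
pipeline does not depend on any single caller's VCF INFO conventions; a
minimal VCF 4.2 subset is also supported via pysam.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    UNKNOWN,
    Effect,
    GeneModel,
    GenomeAnnotation,
    Segment,
    SegmentProfile,
    SomaticVariant,
    ValidationError,
)

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["chromosome", "start", "end", "cn_total", "cn_major", "cn_minor"]
VARIANT_COLUMNS = [
    "sample_id", "chromosome", "position", "ref", "alt", "gene", "effect",
    "aaf", "alt_depth", "n_callers_pass", "exonic", "pop_freq_max", "revel",
]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def normalize_chrom(name: str, strict: bool = False, saw: set[str] | None = None) -> str:
    name = str(name).strip()
    prefixed = name.startswith("chr")
    if saw is not None:
        saw.add("chr" if prefixed else "bare")
        if strict and len(saw) > 1:
            raise ParseError("mixed chromosome naming (chr-prefixed and bare) with strict_chroms=True")
    return name if prefixed else f"chr{name}"


# ---------------------------------------------------------------------------
# segments (seqz-like TSV)
# ---------------------------------------------------------------------------

def read_segments(path: str | Path, strict_chroms: bool = False) -> SegmentProfile:
    """Read one sample's allele-specific segments from a seqz-like TSV.

    Leading ``#key=value`` comment lines carry sample_id/purity/ploidy
    metadata.  Coordinates are 1-based inclusive.  Overlapping segments and
    inconsistent allele counts are rejected with the offending line named.
    """
    path = Path(path)
    meta = {"sample_id": path.stem, "purity": 1.0, "ploidy": 2.0}
    header_line = 0
    lines = path.read_text().splitlines()
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if key in ("purity", "ploidy"):
                meta[key] = float(value)
            elif key == "sample_id":
                meta["sample_id"] = value.strip()
        else:
            header_line = i
            break
    header = lines[header_line].split("\t") if lines else []
    missing = [c for c in SEGMENT_COLUMNS if c not in header]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    idx = {c: header.index(c) for c in SEGMENT_COLUMNS}
    saw: set[str] = set()
    segments = []
    for lineno, line in enumerate(lines[header_line + 1:], start=header_line + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            seg = Segment(
                chrom=normalize_chrom(fields[idx["chromosome"]], strict_chroms, saw),
                start=int(fields[idx["start"]]),
                end=int(fields[idx["end"]]),
                cn_total=int(fields[idx["cn_total"]]),
                cn_major=int(fields[idx["cn_major"]]),
                cn_minor=int(fields[idx["cn_minor"]]),
            )
        except (IndexError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            raise ParseError(f"{path}:{lineno}: malformed segment row: {line!r}") from None
        segments.append(seg)
    try:
        return SegmentProfile(meta["sample_id"], segments, purity=meta["purity"], ploidy=meta["ploidy"])
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_segments(profile: SegmentProfile, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#sample_id={profile.sample_id}\n")
        fh.write(f"#purity={profile.purity:g}\n")
        fh.write(f"#ploidy={profile.ploidy:g}\n")
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for seg in profile.segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.cn_total}\t{seg.cn_major}\t{seg.cn_minor}\n")


# ---------------------------------------------------------------------------
# somatic variants (flat TSV dialect, plus a minimal VCF subset)
# ---------------------------------------------------------------------------

def _parse_optional(value: str) -> float | str:
    value = value.strip()
    if value in ("", ".", "NA", UNKNOWN):
        return UNKNOWN
    return float(value)


def read_variants(path: str | Path, strict_chroms: bool = False) -> list[SomaticVariant]:
    """Read somatic variants from the package TSV dialect or a minimal VCF.

    Missing optional annotations (REVEL, PopFreqMax) become the explicit
    ``unknown`` sentinel, never silent defaults.  An empty file yields an
    empty list with a logged warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_variants_vcf(path, strict_chroms)
    text = path.read_text()
    if not text.strip():
        logger.warning("variant file %s is empty", path)
        return []
    lines = text.splitlines()
    header = lines[0].split("\t")
    missing = [c for c in VARIANT_COLUMNS if c not in header]
    if missing:
        raise ParseError(f"{path}: missing mandatory columns {missing}")
    idx = {c: header.index(c) for c in VARIANT_COLUMNS}
    saw: set[str] = set()
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        f = line.split("\t")
        try:
            out.append(SomaticVariant(
                chrom=normalize_chrom(f[idx["chromosome"]], strict_chroms, saw),
                pos=int(f[idx["position"]]),
                ref=f[idx["ref"]],
                alt=f[idx["alt"]],
                gene=f[idx["gene"]],
                effect=Effect(f[idx["effect"]]),
                aaf=float(f[idx["aaf"]]),
                alt_depth=int(f[idx["alt_depth"]]),
                n_callers_pass=int(f[idx["n_callers_pass"]]),
                exonic=f[idx["exonic"]].strip().lower() in ("1", "true", "yes"),
                pop_freq_max=_parse_optional(f[idx["pop_freq_max"]]),
                revel=_parse_optional(f[idx["revel"]]),
                sample_id=f[idx["sample_id"]],
            ))
        except (IndexError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            raise ParseError(f"{path}:{lineno}: malformed variant row: {line!r}") from None
    if not out:
        logger.warning("variant file %s contains no records", path)
    return out


def _read_variants_vcf(path: Path, strict_chroms: bool = False) -> list[SomaticVariant]:
    """Minimal VCF 4.2 subset: single-sample, INFO keys GENE/EFFECT/AAF/
    ALT_DP/NCALL/EXONIC and optional POPFREQ/REVEL."""
    import pysam

    out = []
    saw: set[str] = set()
    with pysam.VariantFile(str(path)) as vcf:
        sample = next(iter(vcf.header.samples), "")
        for rec in vcf:
            info = rec.info
            for req in ("GENE", "EFFECT", "AAF", "ALT_DP", "NCALL"):
                if req not in info:
                    raise ParseError(f"{path}: record {rec.chrom}:{rec.pos} lacks INFO/{req}")
            out.append(SomaticVariant(
                chrom=normalize_chrom(rec.chrom, strict_chroms, saw),
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alts[0] if rec.alts else ".",
                gene=str(info["GENE"]),
                effect=Effect(str(info["EFFECT"])),
                aaf=float(info["AAF"]),
                alt_depth=int(info["ALT_DP"]),
                n_callers_pass=int(info["NCALL"]),
                exonic=bool(info.get("EXONIC", False)),
                pop_freq_max=float(info["POPFREQ"]) if "POPFREQ" in info else UNKNOWN,
                revel=float(info["REVEL"]) if "REVEL" in info else UNKNOWN,
                sample_id=sample,
            ))
    if not out:
        logger.warning("VCF %s contains no records", path)
    return out


def write_variants(variants: Iterable[SomaticVariant], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for v in variants:
            pf = v.pop_freq_max if v.pop_freq_max == UNKNOWN else f"{v.pop_freq_max:g}"
            rv = v.revel if v.revel == UNKNOWN else f"{v.revel:g}"
            fh.write(
                f"{v.sample_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.gene}\t"
                f"{v.effect.value}\t{v.aaf:g}\t{v.alt_depth}\t{v.n_callers_pass}\t"
                f"{int(v.exonic)}\t{pf}\t{rv}\n"
            )


# ---------------------------------------------------------------------------
# gene models (BED4), .rnk, results
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, strict_chroms: bool = False) -> list[GeneModel]:
    """Read BED4 gene models (0-based half-open) into 1-based inclusive loci."""
    out = []
    saw: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise ParseError(f"{path}:{lineno}: BED4 requires 4 columns")
        try:
            start0, end0 = int(f[1]), int(f[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed BED coordinates") from None
        if start0 >= end0:
            raise ValidationError(f"{path}:{lineno}: BED start >= end")
        out.append(GeneModel(gene=f[3], chrom=normalize_chrom(f[0], strict_chroms, saw),
                             start=start0 + 1, end=end0))
    return out


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene}\n")


def write_rnk(ranked: Sequence[tuple[str, float]], path: str | Path) -> None:
    """Two-column tab-separated (gene, score), no header, order preserved."""
    with Path(path).open("w") as fh:
        for gene, score in ranked:
            fh.write(f"{gene}\t{score:g}\n")


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  summary: dict | None = None) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    if summary is not None:
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# genome annotation (arm/centromere TSV)
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> GenomeAnnotation:
    """Arm/centromere TSV: columns chromosome, length, region (p/q/centromere),
    start, end; 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"chromosome", "length", "region", "start", "end"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: annotation TSV requires columns {sorted(required)}")
    lengths: dict[str, int] = {}
    parts: dict[str, dict[str, tuple[int, int]]] = {}
    for row in df.itertuples():
        chrom = normalize_chrom(row.chromosome)
        lengths[chrom] = int(row.length)
        parts.setdefault(chrom, {})[str(row.region)] = (int(row.start), int(row.end))
    arms, cens = {}, {}
    for chrom, regions in parts.items():
        if set(regions) != {"p", "q", "centromere"}:
            raise ParseError(f"{path}: chromosome {chrom} needs p, q and centromere rows")
        arms[chrom] = (*regions["p"], *regions["q"])
        cens[chrom] = regions["centromere"]
    return GenomeAnnotation(chrom_lengths=lengths, arms=arms, centromeres=cens)


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    rows = []
    for chrom in annotation.chroms():
        length = annotation.chrom_lengths[chrom]
        ps, pe, qs, qe = annotation.arms[chrom]
        cs, ce = annotation.centromeres[chrom]
        rows += [
            (chrom, length, "p", ps, pe),
            (chrom, length, "centromere", cs, ce),
            (chrom, length, "q", qs, qe),
        ]
    pd.DataFrame(rows, columns=["chromosome", "length", "region", "start", "end"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort metadata
# ---------------------------------------------------------------------------

TISSUES = ("breast", "ovarian")
GROUPS = ("primary", "recurrent")


@dataclass
class CohortMetadata:
    """Per-sample cohort table with validated pairing structure.

    One row per sample: patient, tissue, timepoint (0 = primary), group,
    germline BRCA1/2 gene and pathogenic-variant locus, free-text treatments.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"sample_id", "patient_id", "tissue", "timepoint", "group",
                    "germline_gene", "germline_chrom", "germline_pos"}
        if not required.issubset(df.columns):
            raise ParseError(f"cohort metadata requires columns {sorted(required)}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        bad_tissue = set(df["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValidationError(f"unknown tissue values {sorted(bad_tissue)}")
        primary_mismatch = (df["timepoint"].astype(int) == 0) != (df["group"] == "primary")
        if primary_mismatch.any():
            sid = df.loc[primary_mismatch, "sample_id"].iloc[0]
            raise ValidationError(f"sample {sid}: timepoint 0 must coincide with group 'primary'")
        for patient, sub in df.groupby("patient_id"):
            for col in ("germline_gene", "germline_chrom", "germline_pos"):
                if sub[col].nunique() > 1:
                    raise ValidationError(f"patient {patient}: inconsistent {col} across samples")

    @property
    def patients(self) -> list[str]:
        return sorted(self.table["patient_id"].unique())

    def samples_of(self, patient_id: str) -> pd.DataFrame:
        sub = self.table[self.table["patient_id"] == patient_id]
        return sub.sort_values("timepoint")

    def germline_locus(self, patient_id: str) -> tuple[str, str, int]:
        row = self.table[self.table["patient_id"] == patient_id].iloc[0]
        return str(row["germline_gene"]), str(row["germline_chrom"]), int(row["germline_pos"])


def read_metadata(path: str | Path) -> CohortMetadata:
    df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str, "germline_chrom": str})
    if "treatments" not in df.columns:
        df["treatments"] = ""
    df["treatments"] = df["treatments"].fillna("")
    df["germline_chrom"] = df["germline_chrom"].map(normalize_chrom)
    return CohortMetadata(df)


def write_metadata(meta: CohortMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# isoform counts and survival tables
# ---------------------------------------------------------------------------

def read_isoform_counts(path: str | Path) -> pd.DataFrame:
    """TSV: sample_id, isoform_long, isoform_short (expression units >= 0)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "isoform_long", "isoform_short"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: isoform TSV requires columns {sorted(required)}")
    if (df[["isoform_long", "isoform_short"]] < 0).any().any():
        raise ValidationError(f"{path}: negative isoform counts")
    return df


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """CSV: patient_id, os_months, event (0/1) plus optional covariates."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "os_months", "event"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: survival CSV requires columns {sorted(required)}")
    if (df["os_months"] <= 0).any():
        raise ValidationError(f"{path}: os_months must be > 0")
    return df
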