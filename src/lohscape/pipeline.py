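"""End-to-end orchestration of the analysis stages on a cohort directory.

Expected cohort layout (what the simulator emits and the readers accept):

    cohort/
      genome.tsv        arm/centromere annotation
      metadata.csv      per-sample cohort table
      segments/*.tsv    per-sample allele-specific segments
      variants/*.tsv    per-sample somatic variant tables
      isoforms.tsv      two-isoform counts (optional)
      survival.csv      per-patient survival (optional)
      genes.bed         gene models (optional)

Stages run in order loh -> scarring -> cnv -> somatic variants -> isoform /
survival; stages whose inputs are missing are skipped with an explicit
notice.  Every output is written atomically (temp file + rename) and listed
with a content hash in MANIFEST.json; a summary.json aggregates the
per-patient results.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cnv, io_formats, isoform_survival, loh, scarring, somatic_variants
from .model import ScarConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort_dir: Path
    out_dir: Path
    seed: int = 0
    capture_size_mbp: float = 50.0
    scar_config: ScarConfig = field(default_factory=ScarConfig)
    both_threshold: float = isoform_survival.BOTH_THRESHOLD
    dif_threshold: float = isoform_survival.DIF_THRESHOLD
    aaf_share_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        scar = ScarConfig(**raw.pop("scar_config", {}))
        return cls(cohort_dir=Path(raw.pop("cohort_dir")), out_dir=Path(raw.pop("out_dir")),
                   scar_config=scar, **raw)


def _atomic_write_df(df: pd.DataFrame, path: Path, sep: str = "\t") -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep=sep, index=False)
    tmp.rename(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs exist; return the summary dict.

    A stage failure raises after the MANIFEST records which stages
    completed, so partial outputs remain inspectable.
    """
    cdir, odir = Path(config.cohort_dir), Path(config.out_dir)
    for required in ("genome.tsv", "metadata.csv"):
        if not (cdir / required).exists():
            raise FileNotFoundError(f"cohort input missing: {cdir / required}")
    odir.mkdir(parents=True, exist_ok=True)
    annotation = io_formats.read_annotation(cdir / "genome.tsv")
    metadata = io_formats.read_metadata(cdir / "metadata.csv")
    manifest: dict[str, dict] = {"stages": {}, "outputs": {}}
    summary: dict = {"n_patients": len(metadata.patients),
                     "n_samples": len(metadata.table)}

    def record(stage: str, status: str) -> None:
        manifest["stages"][stage] = status
        _write_manifest()

    def _write_manifest() -> None:
        for p in sorted(odir.glob("*.tsv")) + sorted(odir.glob("*.json")):
            if p.name != "MANIFEST.json":
                manifest["outputs"][p.name] = _sha256(p)
        (odir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        profiles = {p.stem: io_formats.read_segments(p)
                    for p in sorted((cdir / "segments").glob("*.tsv"))}

        # --- LOH stage -----------------------------------------------------
        calls, trajectories = loh.call_cohort_loh(profiles, metadata)
        _atomic_write_df(calls, odir / "loh_calls.tsv")
        _atomic_write_df(trajectories, odir / "loh_trajectories.tsv")
        summary["trajectories"] = dict(zip(trajectories.get("patient_id", []),
                                           trajectories.get("trajectory", [])))
        for group in ("primary", "recurrent"):
            n_loh, n_det = loh.loh_fraction(calls, group)
            summary[f"loh_{group}"] = {"loh": n_loh, "determinate": n_det}
        record("loh", "completed")

        # --- somatic variants (needed for TMB) -----------------------------
        variant_files = sorted((cdir / "variants").glob("*.tsv")) if (cdir / "variants").exists() else []
        filtered: dict[str, list] = {}
        if variant_files:
            cosmic = somatic_variants.load_cosmic_set()
            cgc = somatic_variants.load_cgc_table()
            call_rows = []
            sample_group = metadata.table.set_index("sample_id")
            for vf in variant_files:
                sample = vf.stem
                kept = somatic_variants.filter_somatic(io_formats.read_variants(vf))
                filtered[sample] = kept
                if sample not in sample_group.index:
                    continue
                for v in kept:
                    fc = somatic_variants.classify_functional(v, cosmic, cgc)
                    call_rows.append({
                        "sample_id": sample,
                        "patient_id": sample_group.loc[sample, "patient_id"],
                        "group": sample_group.loc[sample, "group"],
                        "gene": v.gene, "effect": v.effect.value, "aaf": v.aaf,
                        "is_lof": fc.is_lof, "is_gof": fc.is_gof,
                        "rationale": fc.rationale})
            func_calls = pd.DataFrame(call_rows)
            _atomic_write_df(func_calls, odir / "functional_calls.tsv")
            for group in ("primary", "recurrent"):
                ranked = somatic_variants.rank_genes_by_lof_prevalence(func_calls, group)
                io_formats.write_rnk(ranked, odir / f"lof_prevalence_{group}.rnk")
            record("variants", "completed")
        else:
            record("variants", "skipped: no variants directory")

        # --- scarring ------------------------------------------------------
        scores = []
        for sample, profile in sorted(profiles.items()):
            n_nonsyn = sum(1 for v in filtered.get(sample, [])
                           if v.effect.value != "synonymous")
            scores.append(scarring.score_profile(
                profile, annotation, config.scar_config,
                n_nonsyn=n_nonsyn, capture_size_mbp=config.capture_size_mbp))
        score_df = scarring.scores_table(scores)
        _atomic_write_df(score_df, odir / "scar_scores.tsv")
        try:
            report, pairing = scarring.compare_paired_scores(score_df, metadata, seed=config.seed)
            _atomic_write_df(report, odir / "paired_score_tests.tsv")
            _atomic_write_df(pairing, odir / "paired_score_pairing.tsv")
            summary["paired_tests"] = {r["metric"]: r["p_value"]
                                       for _, r in report.iterrows()}
        except ValueError as exc:
            logger.warning("paired score comparison skipped: %s", exc)
        record("scarring", "completed")

        # --- gene-level CNV ------------------------------------------------
        genes_bed = cdir / "genes.bed"
        if genes_bed.exists():
            genes = io_formats.read_gene_models(genes_bed)
            sample_group = metadata.table.set_index("sample_id")
            rows = []
            for sample, profile in sorted(profiles.items()):
                if sample not in sample_group.index:
                    continue
                for gene in genes:
                    call = cnv.annotate_gene_cn(gene, profile)
                    rows.append({
                        "sample_id": sample,
                        "patient_id": sample_group.loc[sample, "patient_id"],
                        "group": sample_group.loc[sample, "group"],
                        "gene": call.gene, "min_cn": call.min_cn,
                        "category": call.category.value if call.category else "no_call",
                        "covered_fraction": call.covered_fraction,
                        "qualifies_deleted": call.qualifies_deleted,
                        "qualifies_amplified": call.qualifies_amplified})
            gene_df = pd.DataFrame(rows)
            _atomic_write_df(gene_df, odir / "gene_cn.tsv")
            for group in ("primary", "recurrent"):
                for event in ("gain_or_amp", "loss_or_del"):
                    ranked = cnv.rank_genes_by_cn_event(gene_df, event, group)
                    io_formats.write_rnk(ranked, odir / f"cn_{event}_{group}.rnk")
            record("cnv", "completed")
        else:
            record("cnv", "skipped: no genes.bed")

        # --- isoform usage and survival ------------------------------------
        iso_path = cdir / "isoforms.tsv"
        exposure_by_pid: dict[str, bool] = {}
        if iso_path.exists():
            usage = isoform_survival.compute_usage(
                io_formats.read_isoform_counts(iso_path), config.both_threshold)
            _atomic_write_df(usage, odir / "isoform_usage.tsv")
            sample_pid = metadata.table.set_index("sample_id")["patient_id"]
            tumor_usage = usage[usage["sample_id"].isin(sample_pid.index)].copy()
            tumor_usage["patient_id"] = tumor_usage["sample_id"].map(sample_pid)
            for pid, sub in tumor_usage.groupby("patient_id"):
                exp = isoform_survival.exposure_by_patient(sub)
                if exp is not None:
                    exposure_by_pid[pid] = exp
            if "group" in usage.columns:
                grp = usage[usage["group"].isin(["primary", "recurrent"])]
                a = grp[grp["group"] == "primary"]["if_short"]
                b = grp[grp["group"] == "recurrent"]["if_short"]
                try:
                    sw = isoform_survival.detect_isoform_switch(a, b, config.dif_threshold)
                    summary["isoform_switch"] = {
                        "dif": sw.dif, "p": sw.p_value, "switch": sw.is_switch}
                except ValueError as exc:
                    logger.warning("isoform switch test skipped: %s", exc)
            record("isoform", "completed")
        else:
            record("isoform", "skipped: no isoforms.tsv")

        surv_path = cdir / "survival.csv"
        if surv_path.exists():
            surv = io_formats.read_survival_table(surv_path)
            if "exposure" not in surv.columns:
                surv["exposure"] = surv["patient_id"].map(exposure_by_pid)
                surv = surv.dropna(subset=["exposure"])
            summary["survival"] = {}
            try:
                terms = isoform_survival.fit_cox(surv, covariates=("exposure",))
                summary["survival"]["cox"] = [t.__dict__ for t in terms]
            except Exception as exc:  # non-convergence / degenerate exposure
                logger.warning("Cox fit skipped: %s", exc)
                summary["survival"]["cox"] = f"skipped: {exc}"
            try:
                medians = isoform_survival.km_medians(surv)
                summary["survival"]["km_medians"] = [m.__dict__ for m in medians]
            except ValueError as exc:
                logger.warning("KM medians skipped: %s", exc)
                summary["survival"]["km_medians"] = f"skipped: {exc}"
            record("survival", "completed")
        else:
            record("survival", "skipped: no survival.csv")
    except Exception:
        _write_manifest()
        raise

    (odir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    _write_manifest()
    return summary
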