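"""Synthetic paired primary/recurrent cohorts with full ground truth.

The generator emulates the inputs of a paired BRCA1/2 tumor study: per-sample
allele-specific copy-number profiles with a controllable LOH state at the
germline pathogenic locus, injectable genomic-scar events, clonal/private
somatic variants with purity-scaled allele fractions, mutually exclusive
two-isoform expression, and exponential survival times with a configurable
hazard ratio between isoform-exposure groups.

Scar events are constructed to be unambiguous under the documented scoring
thresholds, so scoring a generated profile recovers the injected counts
*exactly* — this is the central oracle for the scoring code.  The
construction relies on sub-10 Mb "buffer" segments around each event (so no
unintended large-scale state transition qualifies), >=5 Mb spacing between
events (so smoothing cannot fuse them), and a uniformly diploid (1+1)
background.  Everything is deterministic under a fixed seed, with
independent random streams per component.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import CohortMetadata
from .model import GenomeAnnotation, ScarConfig, Segment, SegmentProfile, SomaticVariant, Effect, UNKNOWN

MB = 1_000_000


class CapacityError(ValueError):
    """Requested scar events exceed genome capacity."""


# ---------------------------------------------------------------------------
# genome presets and germline loci
# ---------------------------------------------------------------------------

def genome_preset(name: str = "toy") -> GenomeAnnotation:
    """Reduced genomes for simulation.

    ``toy``: 3 chromosomes, 200 Mb total — fast, fits a handful of events.
    ``medium``: 8 chromosomes x 160 Mb — enough telomeres/arm capacity for
    up to ~10 events of each scar class per sample.
    """
    if name == "toy":
        spec = {"chr1": (90, 25, 29), "chr2": (75, 25, 29), "chr3": (35, 10, 14)}
    elif name == "medium":
        spec = {f"chr{i}": (160, 75, 85) for i in range(1, 9)}
    else:
        raise ValueError(f"unknown genome preset {name!r}")
    lengths, arms, cens = {}, {}, {}
    for chrom, (length, cen_s, cen_e) in spec.items():
        lengths[chrom] = length * MB
        arms[chrom] = (1, cen_s * MB, cen_e * MB + 1, length * MB)
        cens[chrom] = (cen_s * MB + 1, cen_e * MB)
    return GenomeAnnotation(chrom_lengths=lengths, arms=arms, centromeres=cens)


#: Germline pathogenic loci in the synthetic genome (both on p arms).
GERMLINE_LOCI = {"BRCA1": ("chr1", 15 * MB), "BRCA2": ("chr2", 15 * MB)}


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; every probability in [0, 1].

    A fixed ``seed`` makes the full output byte-for-byte reproducible.
    Random streams are drawn per component (cohort structure, scars,
    variants, isoforms, survival), so changing one block of the
    configuration does not perturb the draws of the others.
    """

    n_patients: int = 12
    # distribution of recurrence counts per patient
    recurrences_per_patient: dict[int, float] = field(default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2})
    tissue_mix: dict[str, float] = field(default_factory=lambda: {"breast": 0.5, "ovarian": 0.5})
    purity_range: tuple[float, float] = (0.4, 0.9)
    # LOH model: Bernoulli for the primary, Markov transitions along recurrences
    p_loh_primary: float = 0.8
    p_nonloh_to_loh: float = 0.1
    p_loh_to_nonloh: float = 0.1
    # injected scar counts per sample, drawn uniformly from inclusive ranges
    n_ntai_range: tuple[int, int] = (0, 1)
    n_lst_range: tuple[int, int] = (0, 1)
    n_hrd_loh_range: tuple[int, int] = (0, 1)
    n_arm_range: tuple[int, int] = (0, 1)
    # variant model
    n_clonal_shared: int = 8
    n_private_per_tumor: int = 4
    n_decoys_per_tumor: int = 3
    p_tp53_driver: float = 0.8
    aaf_noise_sd: float = 0.02
    # isoform model
    p_short_dominant: dict[str, float] = field(default_factory=lambda: {
        "normal": 0.1, "primary": 0.25, "recurrent": 0.6})
    mutual_exclusivity_prob: float = 0.97
    isoform_mean_counts: float = 200.0
    both_threshold: float = 0.2
    n_normals: int = 6
    # survival model
    baseline_hazard: float = 0.01  # per month
    true_hr: float = 2.5
    censor_rate: float = 0.2
    # genome / sequencing
    genome: str = "toy"
    capture_size_mbp: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.p_loh_primary, self.p_nonloh_to_loh, self.p_loh_to_nonloh,
                 self.p_tp53_driver, self.mutual_exclusivity_prob,
                 *self.recurrences_per_patient.values(), *self.tissue_mix.values(),
                 *self.p_short_dominant.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_patients < 0 or self.n_clonal_shared < 0 or self.n_private_per_tumor < 0:
            raise ValueError("counts must be >= 0")
        if not self.true_hr > 0:
            raise ValueError("true_hr must be > 0")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must be in [0, 1)")


@dataclass
class CohortTruth:
    """Ground truth emitted alongside the cohort, one record per entity."""

    samples: pd.DataFrame   # sample_id, patient_id, group, loh, ntai, lst, hrd_loh, arm_events, n_pass_nonsyn, dominant_isoform
    patients: pd.DataFrame  # patient_id, trajectory, exposure, true_hr
    variants: pd.DataFrame  # sample_id, chromosome, position, ref, alt, gene, clonal, passes_filter


@dataclass
class CohortData:
    """In-memory cohort: everything `generate_cohort` writes to disk."""

    annotation: GenomeAnnotation
    metadata: CohortMetadata
    profiles: dict[str, SegmentProfile]
    variants: dict[str, list[SomaticVariant]]
    isoforms: pd.DataFrame
    survival: pd.DataFrame
    truth: CohortTruth
    capture_size_mbp: float


# ---------------------------------------------------------------------------
# scar-event injection
# ---------------------------------------------------------------------------

@dataclass
class _Arm:
    chrom: str
    name: str
    start: int
    end: int
    cursor: int = 0       # next free position (left edge)
    usable_end: int = 0   # last free position (right edge)
    altered: int = 0      # bp deviating from diploid placed so far

    def __post_init__(self) -> None:
        self.cursor = self.start
        self.usable_end = self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def free(self) -> int:
        return self.usable_end - self.cursor + 1


_SPACING = 5 * MB          # minimum background between events
_BUFFER = 4 * MB           # sub-LST-flank shoulder around events
_NTAI_LEN = 8 * MB         # telomeric allelic-imbalance block
_LST_BLOCK = 11 * MB       # large-scale-transition block (>= 10 Mb)
_LST_CLEAR = 12 * MB       # background clearance after a chain (>= 10 Mb flank)
_HRD_CORE = 18 * MB        # LOH core (> 15 Mb, < chromosome)
_LOCUS_CORE = 10 * MB      # germline-locus LOH core (< 15 Mb: not an HRD-LOH event)
_MAX_CHAIN = 3             # LST blocks per chain (caps per-arm altered length)


def _arm_budget_ok(arm: _Arm, add_altered: int) -> bool:
    # keep deviant coverage clear of the 80% aneuploidy-call threshold
    return (arm.altered + add_altered) <= 0.75 * arm.length


def inject_scar_events(sample_id: str, n_ntai: int, n_lst: int, n_hrd_loh: int,
                       annotation: GenomeAnnotation, n_arm_events: int = 0,
                       loh_at_locus: bool = False,
                       locus: tuple[str, int] | None = None,
                       reserved_loci: tuple[tuple[str, int], ...] = (),
                       purity: float = 1.0, verify: bool = True) -> SegmentProfile:
    """Build a diploid profile carrying exactly the requested scar events.

    Events are placed deterministically with >=5 Mb spacing on a (1,1)
    background; arms containing ``reserved_loci`` (the germline loci) host
    only the optional germline LOH block.  Raises :class:`CapacityError`
    naming the exhausted resource before any profile is returned.
    """
    reserved = set()
    for chrom, pos in (*reserved_loci, *( [locus] if locus else [] )):
        for arm_name, s, e in annotation.arm_intervals(chrom):
            if s <= pos <= e:
                reserved.add((chrom, arm_name))
    arms = []
    for chrom in annotation.chroms():
        chrom_len = annotation.chrom_lengths[chrom]
        for arm_name, s, e in annotation.arm_intervals(chrom):
            if (chrom, arm_name) in reserved:
                continue
            arm = _Arm(chrom, arm_name, s, e)
            # keep interior events clear of the telomere so their allelic
            # imbalance can never masquerade as an NtAI event
            if arm.start == 1:
                arm.cursor = arm.start + _SPACING
            if arm.end == chrom_len:
                arm.usable_end = arm.end - _SPACING
            arms.append(arm)
    placed: list[Segment] = []

    def put(chrom: str, start: int, end: int, major: int, minor: int) -> None:
        placed.append(Segment(chrom, start, end, major + minor, major, minor))

    # germline-locus LOH block (reserved arm)
    if loh_at_locus:
        if locus is None:
            raise ValueError("loh_at_locus requires a locus")
        chrom, pos = locus
        cs, ce = pos - _LOCUS_CORE // 2 + 1, pos + _LOCUS_CORE // 2
        put(chrom, cs - _BUFFER, cs - 1, 2, 1)
        put(chrom, cs, ce, 1, 0)
        put(chrom, ce + 1, ce + _BUFFER, 2, 1)

    # whole-arm events, consuming arms from the end of the list
    if n_arm_events > len(arms):
        raise CapacityError(
            f"{sample_id}: {n_arm_events} arm events requested but only {len(arms)} free arms")
    for _ in range(n_arm_events):
        arm = arms.pop()
        # margins sized so the altered footprint stays safely above the 80%
        # arm-coverage rule even on small arms
        margin = int(0.09 * arm.length)
        inner = arm.length - 2 * _BUFFER - 2 * margin
        if inner < 3 * MB:  # must survive LST smoothing as a real block
            raise CapacityError(f"{sample_id}: arm {arm.chrom}{arm.name} too small for an arm event")
        s = arm.start + margin
        put(arm.chrom, s, s + _BUFFER - 1, 3, 3)
        put(arm.chrom, s + _BUFFER, s + _BUFFER + inner - 1, 2, 2)
        put(arm.chrom, s + _BUFFER + inner, s + 2 * _BUFFER + inner - 1, 3, 3)

    # telomeric allelic-imbalance events, one telomere each
    if n_ntai > len(arms):
        raise CapacityError(
            f"{sample_id}: {n_ntai} NtAI events requested but only {len(arms)} free telomeres")
    for i in range(n_ntai):
        arm = arms[i]
        chrom_len = annotation.chrom_lengths[arm.chrom]
        if arm.start == 1:  # p arm: telomere on the left
            put(arm.chrom, 1, _NTAI_LEN, 2, 1)
            arm.cursor = _NTAI_LEN + 1 + _SPACING
        elif arm.end == chrom_len:  # q arm: telomere on the right
            put(arm.chrom, chrom_len - _NTAI_LEN + 1, chrom_len, 2, 1)
            arm.usable_end = chrom_len - _NTAI_LEN - _SPACING
        else:
            raise CapacityError(f"{sample_id}: arm {arm.chrom}{arm.name} has no telomere")
        arm.altered += _NTAI_LEN

    def find_arm(footprint: int, altered: int, clearance: int) -> tuple[_Arm, int] | None:
        # clearance doubles as the inter-event spacing behind the footprint
        need = footprint + max(clearance, _SPACING)
        for arm in arms:
            if arm.free() >= need and _arm_budget_ok(arm, altered):
                return arm, need
        return None

    # HRD-LOH events: buffered interstitial LOH cores
    for _ in range(n_hrd_loh):
        footprint = 2 * _BUFFER + _HRD_CORE
        found = find_arm(footprint, 2 * _BUFFER, 0)
        if found is None:
            raise CapacityError(f"{sample_id}: no arm can host a {footprint // MB} Mb LOH event")
        arm, need = found
        s = arm.cursor
        put(arm.chrom, s, s + _BUFFER - 1, 3, 1)
        put(arm.chrom, s + _BUFFER, s + _BUFFER + _HRD_CORE - 1, 2, 0)
        put(arm.chrom, s + _BUFFER + _HRD_CORE, s + footprint - 1, 3, 1)
        arm.cursor = s + need
        arm.altered += 2 * _BUFFER  # the (2,0) core matches diploid total

    # LST events: chains of alternating balanced blocks behind one shoulder;
    # a chain of m blocks contributes exactly m qualifying breakpoints
    remaining = n_lst
    while remaining > 0:
        placed_chain = False
        for m in range(min(remaining, _MAX_CHAIN), 0, -1):
            footprint = _BUFFER + m * _LST_BLOCK
            found = find_arm(footprint, footprint, _LST_CLEAR)
            if found is None:
                continue
            arm, need = found
            s = arm.cursor
            put(arm.chrom, s, s + _BUFFER - 1, 5, 4)
            for k in range(m):
                bs = s + _BUFFER + k * _LST_BLOCK
                major = 2 if k % 2 == 0 else 3
                put(arm.chrom, bs, bs + _LST_BLOCK - 1, major, major)
            arm.cursor = s + need
            arm.altered += footprint
            remaining -= m
            placed_chain = True
            break
        if not placed_chain:
            raise CapacityError(f"{sample_id}: no arm can host further LST chains "
                                f"({remaining} breakpoints unplaced)")

    # diploid background fills every remaining basepair
    by_chrom: dict[str, list[Segment]] = {}
    for seg in placed:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    segments: list[Segment] = []
    for chrom in annotation.chroms():
        chrom_len = annotation.chrom_lengths[chrom]
        pos = 1
        for seg in sorted(by_chrom.get(chrom, []), key=lambda s: s.start):
            if seg.start > pos:
                segments.append(Segment(chrom, pos, seg.start - 1, 2, 1, 1))
            segments.append(seg)
            pos = seg.end + 1
        if pos <= chrom_len:
            segments.append(Segment(chrom, pos, chrom_len, 2, 1, 1))

    profile = SegmentProfile(sample_id, segments, purity=purity, ploidy=2.0)
    if verify:
        from . import scarring
        cfg = ScarConfig()
        got = (scarring.compute_ntai(profile, annotation, cfg),
               scarring.compute_lst(profile, cfg),
               scarring.compute_hrd_loh(profile, annotation, cfg),
               scarring.compute_aneuploidy(profile, annotation))
        want = (n_ntai, n_lst, n_hrd_loh, n_arm_events)
        if got != want:
            raise RuntimeError(
                f"{sample_id}: injected scar events not recovered exactly "
                f"(wanted ntai/lst/hrd_loh/arm {want}, scored {got})")
    return profile


# ---------------------------------------------------------------------------
# survival simulation
# ---------------------------------------------------------------------------

def simulate_survival(patient_ids: list[str], exposure: list[bool], true_hr: float,
                      baseline_hazard: float, censor_rate: float,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Exponential event times with hazard multiplied by ``true_hr`` for
    exposed patients, under independent exponential censoring calibrated so
    the expected censored fraction is ``censor_rate`` in the baseline arm."""
    if not true_hr > 0:
        raise ValueError("true_hr must be > 0")
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError("censor_rate must be in [0, 1)")
    rows = []
    cens_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
    for pid, exposed in zip(patient_ids, exposure):
        hazard = baseline_hazard * (true_hr if exposed else 1.0)
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.exponential(1.0 / cens_rate) if cens_rate > 0 else np.inf
        os_months = min(t_event, t_cens)
        rows.append({"patient_id": pid, "os_months": round(max(os_months, 0.01), 3),
                     "event": int(t_event <= t_cens), "exposure": bool(exposed)})
    return pd.DataFrame(rows, columns=["patient_id", "os_months", "event", "exposure"])


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_EFFECTS = [Effect.MISSENSE, Effect.NONSENSE, Effect.FRAMESHIFT,
            Effect.SYNONYMOUS, Effect.SPLICE, Effect.OTHER]
_EFFECT_P = [0.50, 0.10, 0.10, 0.20, 0.05, 0.05]


def _truth_trajectory(statuses: list[bool]) -> str:
    """Trajectory label from planted LOH statuses (primary first).

    Written independently of the classifier: recurrences that disagree among
    themselves are mixed; otherwise the direction against the primary wins.
    """
    primary, recs = statuses[0], statuses[1:]
    if len(set(recs)) > 1:
        return "mixed"
    if all(s == statuses[0] for s in statuses):
        return "concordant_LOH" if primary else "concordant_nonLOH"
    return "nonLOH_to_LOH" if not primary else "LOH_to_nonLOH"


@dataclass(frozen=True)
class _VariantSpec:
    """Sample-independent identity of a simulated mutation."""

    gene: str
    chrom: str
    pos: int
    effect: Effect
    pop_freq_max: float | str
    revel: float | str


def _spec_variant(rng, gene, chrom, pos, forced_effect: Effect | None = None) -> _VariantSpec:
    effect = forced_effect or _EFFECTS[rng.choice(len(_EFFECTS), p=_EFFECT_P)]
    pop = UNKNOWN if rng.random() < 0.2 else round(float(rng.uniform(0, 0.005)), 5)
    revel = round(float(rng.uniform(0, 1)), 3) if effect is Effect.MISSENSE else UNKNOWN
    return _VariantSpec(gene, chrom, pos, effect, pop, revel)


def _realize_variant(rng, sample_id, spec: _VariantSpec, purity, clonal,
                     cfg) -> tuple[SomaticVariant, bool]:
    """Instantiate a mutation in one tumor: clonal variants sit at AAF ~
    purity/2 (heterozygous, diploid locus); private ones are subclonal."""
    scale = 1.0 if clonal else rng.uniform(0.2, 0.6)
    aaf = round(float(np.clip(purity / 2.0 * scale + rng.normal(0.0, cfg.aaf_noise_sd),
                              0.01, 0.99)), 6)
    v = SomaticVariant(chrom=spec.chrom, pos=spec.pos, ref="A", alt="T", gene=spec.gene,
                       effect=spec.effect, aaf=aaf, alt_depth=max(int(round(aaf * 100)), 1),
                       n_callers_pass=int(rng.integers(1, 5)), exonic=True,
                       pop_freq_max=spec.pop_freq_max, revel=spec.revel, sample_id=sample_id)
    passes = (v.alt_depth >= 5
              and (v.pop_freq_max == UNKNOWN or float(v.pop_freq_max) < 0.01))
    return v, passes and spec.effect is not Effect.SYNONYMOUS


def _draw_decoy(rng, sample_id, gene, chrom, pos) -> SomaticVariant:
    kind = rng.choice(["depth", "popfreq", "nonexonic"])
    return SomaticVariant(
        chrom=chrom, pos=pos, ref="G", alt="C", gene=gene, effect=Effect.MISSENSE,
        aaf=0.05, alt_depth=4 if kind == "depth" else 30,
        n_callers_pass=1, exonic=kind != "nonexonic",
        pop_freq_max=0.05 if kind == "popfreq" else 0.001, revel=0.9, sample_id=sample_id)


def generate_cohort(config: SimulationConfig, out_dir: str | Path | None = None) -> CohortData:
    """Generate a full cohort (optionally writing it to ``out_dir``).

    Output layout under ``out_dir``: ``genome.tsv``, ``metadata.csv``,
    ``segments/<sample>.tsv``, ``variants/<sample>.tsv``, ``isoforms.tsv``,
    ``survival.csv`` and ``truth/*.tsv``.  Infeasible scar configurations
    raise before any file is written.
    """
    annotation = genome_preset(config.genome)
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_scars, rng_vars, rng_iso, rng_surv = (
        np.random.default_rng(s) for s in ss.spawn(5))

    meta_rows, truth_sample_rows, truth_patient_rows, truth_variant_rows = [], [], [], []
    profiles: dict[str, SegmentProfile] = {}
    variants: dict[str, list[SomaticVariant]] = {}
    iso_rows = []
    surv_patients: list[str] = []
    surv_exposure: list[bool] = []

    rec_counts = sorted(config.recurrences_per_patient)
    rec_probs = [config.recurrences_per_patient[k] for k in rec_counts]
    tissues = sorted(config.tissue_mix)
    tissue_probs = [config.tissue_mix[t] for t in tissues]
    gene_pool = [f"GENE{i:03d}" for i in range(1, 61)]
    reserved = tuple(GERMLINE_LOCI.values())

    for pi in range(config.n_patients):
        patient = f"P{pi + 1:03d}"
        tissue = tissues[rng_struct.choice(len(tissues), p=tissue_probs)]
        gene = "BRCA1" if rng_struct.random() < 0.5 else "BRCA2"
        locus_chrom, locus_pos = GERMLINE_LOCI[gene]
        n_rec = rec_counts[rng_struct.choice(len(rec_counts), p=rec_probs)]

        statuses = [bool(rng_struct.random() < config.p_loh_primary)]
        for _ in range(n_rec):
            prev = statuses[-1]
            flip = config.p_loh_to_nonloh if prev else config.p_nonloh_to_loh
            statuses.append(bool(not prev) if rng_struct.random() < flip else bool(prev))

        # clonal variants shared across all of the patient's tumors
        pos_counter = [int(rng_vars.integers(1, 10_000)) * 1000 + 1]

        def next_pos() -> int:
            pos_counter[0] += 997  # co-prime stride keeps positions unique
            return pos_counter[0]

        clonal_specs = []
        if rng_struct.random() < config.p_tp53_driver:
            clonal_specs.append(_spec_variant(rng_vars, "TP53", "chr3", next_pos(),
                                              forced_effect=Effect.NONSENSE))
        for _ in range(config.n_clonal_shared):
            clonal_specs.append(_spec_variant(
                rng_vars, gene_pool[rng_vars.integers(len(gene_pool))], "chr3", next_pos()))

        dominances = []
        for t in range(n_rec + 1):
            sample = f"{patient}-T{t}"
            group = "primary" if t == 0 else "recurrent"
            purity = round(float(rng_struct.uniform(*config.purity_range)), 4)
            meta_rows.append({
                "sample_id": sample, "patient_id": patient, "tissue": tissue,
                "timepoint": t, "group": group, "germline_gene": gene,
                "germline_chrom": locus_chrom, "germline_pos": locus_pos,
                "treatments": "platinum" if group == "recurrent" else "",
            })
            n_ntai = int(rng_scars.integers(config.n_ntai_range[0], config.n_ntai_range[1] + 1))
            n_lst = int(rng_scars.integers(config.n_lst_range[0], config.n_lst_range[1] + 1))
            n_hrd = int(rng_scars.integers(config.n_hrd_loh_range[0], config.n_hrd_loh_range[1] + 1))
            n_arm = int(rng_scars.integers(config.n_arm_range[0], config.n_arm_range[1] + 1))
            profiles[sample] = inject_scar_events(
                sample, n_ntai, n_lst, n_hrd, annotation, n_arm_events=n_arm,
                loh_at_locus=statuses[t], locus=(locus_chrom, locus_pos),
                reserved_loci=reserved, purity=purity)

            sample_variants: list[SomaticVariant] = []
            n_pass_nonsyn = 0
            private_specs = [
                _spec_variant(rng_vars, gene_pool[rng_vars.integers(len(gene_pool))],
                              "chr3", next_pos())
                for _ in range(config.n_private_per_tumor)]
            for spec, clonal in ([(s, True) for s in clonal_specs]
                                 + [(s, False) for s in private_specs]):
                v, counts = _realize_variant(rng_vars, sample, spec, purity, clonal, config)
                sample_variants.append(v)
                n_pass_nonsyn += int(counts)
                truth_variant_rows.append({
                    "sample_id": sample, "chromosome": v.chrom, "position": v.pos,
                    "ref": v.ref, "alt": v.alt, "gene": v.gene, "clonal": clonal,
                    "passes_filter": bool(counts or (
                        v.effect is Effect.SYNONYMOUS and v.alt_depth >= 5
                        and (v.pop_freq_max == UNKNOWN or float(v.pop_freq_max) < 0.01)))})
            for _ in range(config.n_decoys_per_tumor):
                sample_variants.append(_draw_decoy(
                    rng_vars, sample, gene_pool[rng_vars.integers(len(gene_pool))],
                    "chr3", next_pos()))
            variants[sample] = sample_variants

            dom, counts_pair = _draw_isoform(rng_iso, config, group)
            dominances.append(dom)
            iso_rows.append({"sample_id": sample, "isoform_long": counts_pair[0],
                             "isoform_short": counts_pair[1], "group": group})
            truth_sample_rows.append({
                "sample_id": sample, "patient_id": patient, "group": group,
                "loh": statuses[t], "ntai": n_ntai, "lst": n_lst, "hrd_loh": n_hrd,
                "arm_events": n_arm, "n_pass_nonsyn": n_pass_nonsyn,
                "dominant_isoform": dom})

        exposure = any(d in ("short", "both") for d in dominances)
        surv_patients.append(patient)
        surv_exposure.append(exposure)
        truth_patient_rows.append({
            "patient_id": patient, "trajectory": _truth_trajectory(statuses),
            "exposure": exposure, "true_hr": config.true_hr})

    for k in range(config.n_normals):
        dom, counts_pair = _draw_isoform(rng_iso, config, "normal")
        iso_rows.append({"sample_id": f"N{k + 1:03d}", "isoform_long": counts_pair[0],
                         "isoform_short": counts_pair[1], "group": "normal"})

    survival = simulate_survival(surv_patients, surv_exposure, config.true_hr,
                                 config.baseline_hazard, config.censor_rate, rng_surv)
    meta_cols = ["sample_id", "patient_id", "tissue", "timepoint", "group",
                 "germline_gene", "germline_chrom", "germline_pos", "treatments"]
    metadata = CohortMetadata(pd.DataFrame(meta_rows, columns=meta_cols))
    truth = CohortTruth(
        samples=pd.DataFrame(truth_sample_rows, columns=[
            "sample_id", "patient_id", "group", "loh", "ntai", "lst", "hrd_loh",
            "arm_events", "n_pass_nonsyn", "dominant_isoform"]),
        patients=pd.DataFrame(truth_patient_rows, columns=[
            "patient_id", "trajectory", "exposure", "true_hr"]),
        variants=pd.DataFrame(truth_variant_rows, columns=[
            "sample_id", "chromosome", "position", "ref", "alt", "gene", "clonal",
            "passes_filter"]),
    )
    iso_cols = ["sample_id", "isoform_long", "isoform_short", "group"]
    cohort = CohortData(
        annotation=annotation, metadata=metadata, profiles=profiles, variants=variants,
        isoforms=pd.DataFrame(iso_rows, columns=iso_cols), survival=survival,
        truth=truth, capture_size_mbp=config.capture_size_mbp)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _draw_isoform(rng: np.random.Generator, config: SimulationConfig,
                  group: str) -> tuple[str, tuple[int, int]]:
    short_dom = rng.random() < config.p_short_dominant.get(group, 0.0)
    dominant = max(int(rng.poisson(config.isoform_mean_counts)), 20)
    if rng.random() < config.mutual_exclusivity_prob:
        minor_if = rng.uniform(0.0, config.both_threshold * 0.75)
    else:
        minor_if = rng.uniform(config.both_threshold + 0.05, 0.5)
    minor = int(round(dominant * minor_if / (1.0 - minor_if)))
    long_c, short_c = (minor, dominant) if short_dom else (dominant, minor)
    total = long_c + short_c
    if total == 0:
        dom = "none"
    elif min(short_c, long_c) / total >= config.both_threshold:
        dom = "both"
    else:
        dom = "short" if short_c > long_c else "long"
    return dom, (long_c, short_c)


def _write_cohort(cohort: CohortData, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    io_formats.write_annotation(cohort.annotation, out_dir / "genome.tsv")
    io_formats.write_metadata(cohort.metadata, out_dir / "metadata.csv")
    (out_dir / "segments").mkdir(exist_ok=True)
    for sample, profile in sorted(cohort.profiles.items()):
        io_formats.write_segments(profile, out_dir / "segments" / f"{sample}.tsv")
    (out_dir / "variants").mkdir(exist_ok=True)
    for sample, vs in sorted(cohort.variants.items()):
        io_formats.write_variants(vs, out_dir / "variants" / f"{sample}.tsv")
    cohort.isoforms.to_csv(out_dir / "isoforms.tsv", sep="\t", index=False)
    cohort.survival.to_csv(out_dir / "survival.csv", index=False)
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    cohort.truth.samples.to_csv(truth_dir / "samples.tsv", sep="\t", index=False)
    cohort.truth.patients.to_csv(truth_dir / "patients.tsv", sep="\t", index=False)
    cohort.truth.variants.to_csv(truth_dir / "variants.tsv", sep="\t", index=False)


def read_cohort(out_dir: str | Path) -> CohortData:
    """Load a cohort previously written by :func:`generate_cohort`."""
    out_dir = Path(out_dir)
    annotation = io_formats.read_annotation(out_dir / "genome.tsv")
    metadata = io_formats.read_metadata(out_dir / "metadata.csv")
    profiles = {p.stem: io_formats.read_segments(p)
                for p in sorted((out_dir / "segments").glob("*.tsv"))}
    variants = {p.stem: io_formats.read_variants(p)
                for p in sorted((out_dir / "variants").glob("*.tsv"))}
    isoforms = pd.read_csv(out_dir / "isoforms.tsv", sep="\t", dtype={"sample_id": str})
    survival = io_formats.read_survival_table(out_dir / "survival.csv")
    truth_dir = out_dir / "truth"
    truth = CohortTruth(
        samples=pd.read_csv(truth_dir / "samples.tsv", sep="\t", dtype={"sample_id": str}),
        patients=pd.read_csv(truth_dir / "patients.tsv", sep="\t", dtype={"patient_id": str}),
        variants=pd.read_csv(truth_dir / "variants.tsv", sep="\t", dtype={"sample_id": str}),
    )
    return CohortData(annotation=annotation, metadata=metadata, profiles=profiles,
                      variants=variants, isoforms=isoforms, survival=survival,
                      truth=truth, capture_size_mbp=50.0)
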