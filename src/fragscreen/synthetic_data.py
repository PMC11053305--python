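"""Synthetic cfDNA fragment cohorts with known ground truth.

The generator emulates the statistical structure the screening analysis
assumes:

* per-bin fragment counts proportional to bin spans (multinomial over
  bins), with a nucleosome-peaked size distribution;
* a case-specific enrichment of short (100–167 nt) fragments in a small
  set of affected bins, with enrichment ratios in the empirically
  observed 1.50–2.38 range;
* a tumor signal that grows exponentially toward diagnosis with a
  configurable volume doubling time (default 4.6 months), so samples
  drawn years before diagnosis carry a diluted signal:
  ``tau_eff = tau * 2**(-months_before_dx / doubling_time)``;
* per-bin short-fragment probability
  ``p_b = p0_b * (1 + (r_b - 1) * tau_eff)`` for affected bins and
  ``p0_b`` otherwise, clipped to [0, 1];
* survival outcomes whose hazard is multiplied by a programmed hazard
  ratio for the latent high-burden half of the cases.

Every latent parameter is recorded in a truth dictionary so tests can
verify recovery.  Identical seed and config give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fragmentation_profile import ProfileMatrix
from .genome_binning import BinSet, GenomicBin, SourceBin

MONTHS_PER_YEAR = 12.0


@dataclass
class CohortConfig:
    """Parameters of a simulated screening cohort.

    Defaults describe a reduced-scale cohort (50 bins, 1e5 fragments per
    sample) that preserves the signal structure of a full-scale study
    while remaining fast to simulate; the QC threshold is scaled
    accordingly by the caller.
    """

    seed: int = 0
    n_cases: int = 30
    n_controls: int = 30
    n_bins: int = 50
    n_arms: int = 5
    source_span: int = 100_000
    bins_per_window: int = 50           # -> 5-Mb windows
    fragments_per_sample: int = 100_000
    baseline_short_proportion: float = 0.2
    baseline_spread_sd: float = 0.02
    n_affected_bins: int = 5
    enrichment_range: tuple[float, float] = (1.50, 2.38)
    tumor_fraction: float = 0.5
    burden_sigma: float = 0.6           # per-case lognormal tumor-burden spread
    sample_noise_sd: float = 0.01       # per-sample per-bin probability jitter
    global_noise_sd: float = 0.05       # per-sample global short-fraction scaling
    control_background_sd: float = 0.08  # per-subject benign background signal
    doubling_time_months: float = 4.6
    sampling_times_years: tuple[float, ...] = (0.0,)
    baseline_median_survival_months: float = 22.0
    hr_high: float = 2.41
    followup_cap_months: float = 36.0
    qc_fail_fraction: float = 0.0
    decoy_fraction: float = 0.0
    decoy_mapq: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if not 0.0 <= self.baseline_short_proportion <= 1.0:
            raise ValueError("baseline_short_proportion must be in [0, 1]")
        if not 0.0 <= self.qc_fail_fraction <= 1.0:
            raise ValueError("qc_fail_fraction must be in [0, 1]")
        lo, hi = self.enrichment_range
        if lo < 1.0 or hi < lo:
            raise ValueError("enrichment ratios must satisfy 1 <= lo <= hi")
        if self.n_affected_bins > self.n_bins:
            raise ValueError("more affected bins than bins")
        if self.doubling_time_months <= 0:
            raise ValueError("doubling time must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["enrichment_range"] = list(d["enrichment_range"])
        d["sampling_times_years"] = list(d["sampling_times_years"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["enrichment_range"] = tuple(d["enrichment_range"])
        d["sampling_times_years"] = tuple(d["sampling_times_years"])
        return cls(**d)


# ---------------------------------------------------------------------------
# bin scheme
# ---------------------------------------------------------------------------

def make_binset(config: CohortConfig) -> BinSet:
    """Synthetic arm layout: ``n_bins`` consecutive windows spread as evenly
    as possible over ``n_arms`` arms, with global sequential labels."""
    if config.n_bins < 1:
        raise ValueError("need at least one bin")
    window_span = config.bins_per_window * config.source_span
    per_arm = np.full(config.n_arms, config.n_bins // config.n_arms, dtype=int)
    per_arm[: config.n_bins % config.n_arms] += 1
    bins: list[GenomicBin] = []
    label_idx = 1
    for a, count in enumerate(per_arm, start=1):
        chrom, arm = f"chr{a}", f"{a}q"
        for w in range(count):
            start = w * window_span
            bins.append(
                GenomicBin(
                    chrom=chrom,
                    start=start,
                    end=start + window_span,
                    arm=arm,
                    label=f"{arm}_{label_idx}",
                    n_source_bins=config.bins_per_window,
                )
            )
            label_idx += 1
    return BinSet(bins=bins, genome_build="synthetic")


def write_source_bed(config: CohortConfig, path: str | Path) -> int:
    """Write the constituent 100-kb source bins as BED4 (chrom start end arm),
    suitable for ``genome_binning.load_source_bins`` + ``merge_to_windows``.
    Returns the number of source bins written."""
    binset = make_binset(config)
    n = 0
    with open(path, "w") as fh:
        for b in binset:
            for k in range(b.n_source_bins):
                s = b.start + k * config.source_span
                fh.write(f"{b.chrom}\t{s}\t{s + config.source_span}\t{b.arm}\n")
                n += 1
    return n


# ---------------------------------------------------------------------------
# latent truth and per-sample counts
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Latent parameters of a generated cohort."""

    p0: np.ndarray                    # per-bin baseline short proportion
    affected_bins: np.ndarray         # indices of enriched bins
    enrichment: np.ndarray            # ratio r_b per affected bin
    bin_labels: list[str]
    sample_tau_eff: dict[str, float] = field(default_factory=dict)
    high_burden_subjects: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "p0": self.p0.tolist(),
            "affected_bins": self.affected_bins.tolist(),
            "affected_bin_labels": [self.bin_labels[i] for i in self.affected_bins],
            "enrichment": self.enrichment.tolist(),
            "bin_labels": self.bin_labels,
            "sample_tau_eff": self.sample_tau_eff,
            "high_burden_subjects": self.high_burden_subjects,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def draw_truth(config: CohortConfig, binset: BinSet, rng: np.random.Generator) -> CohortTruth:
    p0 = np.clip(
        rng.normal(config.baseline_short_proportion, config.baseline_spread_sd, len(binset)),
        0.01, 0.95,
    )
    affected = np.sort(rng.choice(len(binset), size=config.n_affected_bins, replace=False))
    lo, hi = config.enrichment_range
    enrichment = rng.uniform(lo, hi, size=config.n_affected_bins) if hi > lo else np.full(
        config.n_affected_bins, lo
    )
    return CohortTruth(
        p0=p0, affected_bins=affected, enrichment=enrichment, bin_labels=binset.labels
    )


def effective_tumor_fraction(
    tumor_fraction: float, months_before_dx: float, doubling_time_months: float
) -> float:
    """Exponential-growth dilution of the tumor signal before diagnosis."""
    return tumor_fraction * 2.0 ** (-months_before_dx / doubling_time_months)


def bin_short_probabilities(truth: CohortTruth, tau_eff: float) -> np.ndarray:
    """Per-bin short-fragment probability at effective tumor fraction tau_eff."""
    p = truth.p0.copy()
    r = truth.enrichment
    p[truth.affected_bins] = truth.p0[truth.affected_bins] * (1.0 + (r - 1.0) * tau_eff)
    return np.clip(p, 0.0, 1.0)


def sample_profile_counts(
    config: CohortConfig,
    truth: CohortTruth,
    binset: BinSet,
    rng: np.random.Generator,
    tumor_fraction: float | None = None,
    months_before_dx: float = 0.0,
    n_fragments: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin (short, total) fragment counts for one sample.

    Total counts are multinomial over bins with probabilities proportional
    to bin spans; short counts are binomial with the enrichment-adjusted
    per-bin probability.  Inter-individual and technical variability is
    emulated by a per-sample global scaling of the short-fragment
    probability (``global_noise_sd``) plus independent per-bin jitter
    (``sample_noise_sd``); set both to zero for purely binomial sampling.
    """
    tau = config.tumor_fraction if tumor_fraction is None else tumor_fraction
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tumor fraction must be in [0, 1]")
    tau_eff = effective_tumor_fraction(tau, months_before_dx, config.doubling_time_months)
    p = bin_short_probabilities(truth, tau_eff)
    g = rng.normal(1.0, config.global_noise_sd) if config.global_noise_sd else 1.0
    jitter = (
        rng.normal(0.0, config.sample_noise_sd, len(p)) if config.sample_noise_sd else 0.0
    )
    p = np.clip(p * g + jitter, 0.0, 1.0)
    spans = np.array([b.span for b in binset], dtype=float)
    n = config.fragments_per_sample if n_fragments is None else n_fragments
    total = rng.multinomial(n, spans / spans.sum())
    short = rng.binomial(total, p)
    return short, total


# ---------------------------------------------------------------------------
# fragment emission
# ---------------------------------------------------------------------------

def emit_fragments(
    short_counts: np.ndarray,
    total_counts: np.ndarray,
    binset: BinSet,
    rng: np.random.Generator,
    path: str | Path,
    decoy_fraction: float = 0.0,
    decoy_mapq: int = 10,
) -> int:
    """Write one sample's fragments as BED5 (chrom start end name mapq).

    Short-class fragments have lengths uniform on [100, 167]; long-class
    fragments are drawn from the mononucleosome peak (normal, mean 167,
    sd 10) truncated above the short window so that recomputing the
    profile reproduces the generating counts exactly.  A ``decoy_fraction``
    of extra records with sub-threshold MAPQ and out-of-class lengths is
    appended to exercise the filters.  Returns the number of records
    written.
    """
    short_counts = np.asarray(short_counts, dtype=np.int64)
    total_counts = np.asarray(total_counts, dtype=np.int64)
    if np.any(short_counts > total_counts):
        raise ValueError("short counts exceed totals")
    chroms: list[np.ndarray] = []
    starts_all: list[np.ndarray] = []
    ends_all: list[np.ndarray] = []
    for b, ns, nt in zip(binset, short_counts, total_counts):
        nl = int(nt - ns)
        short_len = rng.integers(100, 168, size=int(ns))
        long_len = _truncated_peak_lengths(rng, nl, low=168)
        lengths = np.concatenate([short_len, long_len])
        starts = b.start + rng.integers(
            0, np.maximum(b.span - lengths, 1), size=len(lengths)
        )
        chroms.append(np.full(len(lengths), b.chrom))
        starts_all.append(starts)
        ends_all.append(starts + lengths)
    n_decoys = int(round(decoy_fraction * total_counts.sum()))
    mapqs_tail = np.empty(0, dtype=np.int64)
    if n_decoys and len(binset):
        bidx = rng.integers(0, len(binset), size=n_decoys)
        dlen = rng.integers(1100, 1500, size=n_decoys)
        bstarts = np.array([binset.bins[int(i)].start for i in bidx])
        bspans = np.array([binset.bins[int(i)].span for i in bidx])
        dstart = bstarts + (rng.random(n_decoys) * np.maximum(bspans - dlen, 1)).astype(np.int64)
        chroms.append(np.array([binset.bins[int(i)].chrom for i in bidx]))
        starts_all.append(dstart)
        ends_all.append(dstart + dlen)
        mapqs_tail = np.full(n_decoys, decoy_mapq, dtype=np.int64)
    chrom_arr = np.concatenate(chroms) if chroms else np.empty(0, dtype=object)
    start_arr = np.concatenate(starts_all) if starts_all else np.empty(0, dtype=np.int64)
    end_arr = np.concatenate(ends_all) if ends_all else np.empty(0, dtype=np.int64)
    n_real = len(start_arr) - len(mapqs_tail)
    mapq_arr = np.concatenate([np.full(n_real, 60, dtype=np.int64), mapqs_tail])
    names = np.char.add("frag", np.arange(len(start_arr)).astype(str))
    pd.DataFrame(
        {"chrom": chrom_arr, "start": start_arr, "end": end_arr,
         "name": names, "mapq": mapq_arr}
    ).to_csv(path, sep="\t", index=False, header=False)
    return len(start_arr)


def _truncated_peak_lengths(
    rng: np.random.Generator, n: int, mean: float = 167.0, sd: float = 10.0, low: int = 168
) -> np.ndarray:
    """Rejection-sample rounded normal lengths >= ``low``."""
    out = np.empty(0, dtype=np.int64)
    while len(out) < n:
        draw = np.rint(rng.normal(mean, sd, size=max(2 * (n - len(out)), 16)))
        out = np.concatenate([out, draw[draw >= low].astype(np.int64)])
    return out[:n]


# ---------------------------------------------------------------------------
# whole-cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """In-memory cohort: profile matrix plus metadata and latent truth."""

    config: CohortConfig
    binset: BinSet
    truth: CohortTruth
    matrix: ProfileMatrix              # one row per sample
    metadata: pd.DataFrame             # sample_id, subject_id, label, years_before_dx, ...
    survival: pd.DataFrame             # per case subject
    counts: dict[str, tuple[np.ndarray, np.ndarray]]  # sample_id -> (short, total)


def make_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> Cohort:
    """Generate a full synthetic cohort.

    Cases contribute one sample per configured pre-diagnosis sampling time
    (years before diagnosis; 0 means a sample at clinical diagnosis);
    controls are sampled at the same offsets with zero tumor fraction.
    Every subject additionally carries a persistent benign background
    signal in the affected bins (half-normal effective fraction with scale
    ``control_background_sd``), emulating non-malignant processes — e.g.
    chronic hepatitis in an HBV-seropositive screening population — that
    shift fragmentation in the same genomic compartments.  A
    ``qc_fail_fraction`` of samples is under-sequenced (1% of the normal
    fragment yield).  Case survival is exponential with the hazard
    multiplied by ``hr_high`` for the latent high-burden half of subjects
    (those with above-median per-subject tumor burden), administratively
    censored at the follow-up cap.

    When ``out_dir`` is given, also writes per-sample fragment BEDs, the
    bin manifest, metadata CSV, survival CSV, truth JSON and a config echo.
    """
    rng = np.random.default_rng(config.seed)
    binset = make_binset(config)
    truth = draw_truth(config, binset, rng)

    # per-case burden multiplier links profile signal, score and survival
    burden = rng.lognormal(mean=0.0, sigma=config.burden_sigma, size=config.n_cases)
    case_ids = [f"case{str(i + 1).zfill(3)}" for i in range(config.n_cases)]
    ctrl_ids = [f"ctrl{str(i + 1).zfill(3)}" for i in range(config.n_controls)]
    if config.n_cases:
        median_burden = float(np.median(burden))
        truth.high_burden_subjects = [
            sid for sid, b in zip(case_ids, burden) if b >= median_burden
        ]

    rows, meta_rows = [], []
    counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    sample_ids: list[str] = []
    n_samples_total = (config.n_cases + config.n_controls) * len(config.sampling_times_years)
    qc_fail = rng.random(n_samples_total) < config.qc_fail_fraction
    k = 0
    for subject_ids, is_case in ((case_ids, True), (ctrl_ids, False)):
        for j, sid in enumerate(subject_ids):
            tau_subject = (
                min(1.0, config.tumor_fraction * burden[j]) if is_case else 0.0
            )
            background = abs(rng.normal(0.0, config.control_background_sd))
            for t_years in config.sampling_times_years:
                months = t_years * MONTHS_PER_YEAR
                n_frag = config.fragments_per_sample
                if qc_fail[k]:
                    n_frag = max(1, n_frag // 100)
                tau_total = min(
                    1.0,
                    effective_tumor_fraction(
                        tau_subject, months, config.doubling_time_months
                    )
                    + background,
                )
                short, total = sample_profile_counts(
                    config, truth, binset, rng,
                    tumor_fraction=tau_total, months_before_dx=0.0,
                    n_fragments=n_frag,
                )
                sample_id = f"{sid}_t{t_years:g}"
                counts[sample_id] = (short, total)
                sample_ids.append(sample_id)
                with np.errstate(invalid="ignore"):
                    rows.append(np.where(total > 0, short / total, np.nan))
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "subject_id": sid,
                        "label": "case" if is_case else "control",
                        "years_before_dx": t_years,
                        "n_fragments": int(total.sum()),
                        "qc_fail_intended": bool(qc_fail[k]),
                    }
                )
                truth.sample_tau_eff[sample_id] = tau_total
                k += 1

    matrix = ProfileMatrix(
        sample_ids=sample_ids, bin_labels=binset.labels, values=np.vstack(rows)
    )
    metadata = pd.DataFrame(meta_rows)
    metadata = _attach_clinical_covariates(metadata, rng)
    survival = _make_case_survival(config, case_ids, truth.high_burden_subjects, rng)

    cohort = Cohort(
        config=config, binset=binset, truth=truth, matrix=matrix,
        metadata=metadata, survival=survival, counts=counts,
    )
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir), rng)
    return cohort


def _attach_clinical_covariates(metadata: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Per-subject age/sex/BCLC/AFP covariates, independent of outcome."""
    subjects = metadata["subject_id"].unique()
    cov = pd.DataFrame(
        {
            "subject_id": subjects,
            "age": rng.normal(55.0, 8.0, len(subjects)).round(1),
            "sex": rng.choice(["M", "F"], size=len(subjects), p=[0.85, 0.15]),
            "bclc": rng.choice(["0A", "BC"], size=len(subjects)),
            "afp_status": rng.choice(["positive", "negative"], size=len(subjects), p=[0.3, 0.7]),
        }
    )
    return metadata.merge(cov, on="subject_id", how="left")


def _make_case_survival(
    config: CohortConfig,
    case_ids: list[str],
    high_subjects: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    if not case_ids:
        return pd.DataFrame(
            columns=["subject_id", "time_months", "event", "high_burden"]
        )
    high = np.array([sid in set(high_subjects) for sid in case_ids])
    base_rate = np.log(2.0) / config.baseline_median_survival_months
    rate = base_rate * np.where(high, config.hr_high, 1.0)
    t = rng.exponential(1.0 / rate)
    event = (t <= config.followup_cap_months).astype(int)
    t = np.minimum(t, config.followup_cap_months)
    return pd.DataFrame(
        {
            "subject_id": case_ids,
            "time_months": np.round(t, 3),
            "event": event,
            "high_burden": high.astype(int),
        }
    )


def make_survival_cohort(
    n_subjects: int,
    hr_high: float = 2.41,
    baseline_median_months: float = 22.0,
    cap_months: float = 36.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Standalone survival cohort for hazard-ratio recovery experiments.

    Half the subjects are in the high-score group with hazard multiplied
    by ``hr_high``; clinical covariates (age group, sex, BCLC, AFP) are
    generated independently of outcome (null adjustment covariates).
    """
    rng = np.random.default_rng(seed)
    high = np.zeros(n_subjects, dtype=int)
    high[: n_subjects // 2] = 1
    rng.shuffle(high)
    base_rate = np.log(2.0) / baseline_median_months
    t = rng.exponential(1.0 / (base_rate * np.where(high, hr_high, 1.0)))
    event = (t <= cap_months).astype(int)
    t = np.minimum(t, cap_months)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n_subjects)],
            "time_months": t,
            "event": event,
            "score_high": high,
            "age_ge55": rng.integers(0, 2, n_subjects),
            "sex": rng.integers(0, 2, n_subjects),
            "bclc": rng.integers(0, 2, n_subjects),
            "afp_status": rng.integers(0, 2, n_subjects),
        }
    )


def _write_cohort(cohort: Cohort, out_dir: Path, rng: np.random.Generator) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    frag_dir = out_dir / "fragments"
    frag_dir.mkdir(exist_ok=True)
    cfg = cohort.config
    for sample_id in cohort.matrix.sample_ids:
        short, total = cohort.counts[sample_id]
        emit_fragments(
            short, total, cohort.binset, rng, frag_dir / f"{sample_id}.bed",
            decoy_fraction=cfg.decoy_fraction, decoy_mapq=cfg.decoy_mapq,
        )
    cohort.binset.write_manifest(out_dir / "bins.tsv")
    cohort.metadata.to_csv(out_dir / "metadata.csv", index=False)
    cohort.survival.to_csv(out_dir / "survival.csv", index=False)
    cohort.truth.to_json(out_dir / "truth.json")
    cfg.to_yaml(out_dir / "config.yaml")
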