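"""End-to-end pipeline: simulate/ingest -> preprocess -> per-subject AAHC ->
group templates -> backfit -> parameters/transitions -> group statistics.

A single integer seed fans out deterministically to per-subject seeds, so a
cohort is reproducible subject by subject. Every stage writes its outputs
under the run directory and the run report links them with content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .backfit import compute_parameters, segment_and_parameterize, transition_matrix
from .containers import EpochedData, MicrostateSegmentation, TemplateSet
from .maps import align_subject_maps, group_mean_templates, label_canonical, subject_templates
from .montage import channel_positions, default_channels
from .preprocess import preprocess_recording
from .simulate import GeneratorConfig, make_template_maps, sample_state_sequence, synthesize_recording
from .stats import CLASS_NAMES, SubjectRecord, group_comparison_report

__all__ = [
    "EffectSpec",
    "PipelineConfig",
    "make_demo_cohort",
    "simulate_cohort_records",
    "run_pipeline",
]


@dataclass
class EffectSpec:
    """Plantable group effects on the microstate generator.

    ``duration_scale`` multiplies the affected group's per-class mean
    segment duration (e.g. {"D": 0.85} shortens D segments by 15%);
    ``transition_bias`` multiplies the probability of transitions *into* a
    class (rows renormalised), raising that class's occurrence and coverage
    without touching its segment-length law.
    """

    duration_scale: dict[str, float] = field(default_factory=dict)
    transition_bias: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.duration_scale, self.transition_bias):
            bad = set(d) - set(CLASS_NAMES)
            if bad:
                raise ValueError(f"unknown class names in effect spec: {sorted(bad)}")

    @classmethod
    def default_rbd(cls) -> "EffectSpec":
        """Effect pattern emulating the reported RBD findings: shorter A and
        D segments, more traffic into B and C."""
        return cls(
            duration_scale={"A": 0.92, "D": 0.85},
            transition_bias={"B": 1.3, "C": 1.15},
        )


def _apply_effects(
    base_means_ms: np.ndarray, base_T: np.ndarray, spec: EffectSpec
) -> tuple[np.ndarray, np.ndarray]:
    means = base_means_ms.copy()
    for cname, scale in spec.duration_scale.items():
        means[CLASS_NAMES.index(cname)] *= scale
    T = base_T.copy()
    for cname, bias in spec.transition_bias.items():
        T[:, CLASS_NAMES.index(cname)] *= bias
    np.fill_diagonal(T, 0.0)
    T /= T.sum(axis=1, keepdims=True)
    return means, T


def _subject_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n)


def _metadata(
    n_rbd: int, n_hc: int, seed: int
) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    rows = []
    for i in range(n_rbd + n_hc):
        is_rbd = i < n_rbd
        rows.append(
            {
                "subject_id": f"{'rbd' if is_rbd else 'hc'}{i:03d}",
                "group": "RBD" if is_rbd else "HC",
                # severity questionnaire: screening threshold is 17
                "rbdqhk": int(rng.integers(17, 81)) if is_rbd else int(rng.integers(0, 13)),
                "age": float(np.round(rng.normal(57.0 if is_rbd else 55.0, 5.0), 1)),
                "sex": "F" if rng.random() < 0.75 else "M",
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort_records(
    n_rbd: int = 22,
    n_hc: int = 46,
    effect_spec: Optional[EffectSpec] = None,
    seed: int = 0,
    duration_s: float = 60.0,
    sampling_rate: float = 250.0,
    mean_segment_ms: float = 80.0,
    between_subject_cv: float = 0.10,
    epoch_s: float = 2.0,
    n_states: int = 4,
) -> list[SubjectRecord]:
    """Simulate a cohort at the label-sequence level and parameterize it.

    The microstate label process (per-class geometric segments driven by a
    transition matrix) is sampled per subject, chopped into epochs exactly
    as the EEG route does, and fed to the same parameter and transition
    extraction — the quantities group statistics consume are functions of
    the label sequence alone. Between-subject variability enters as a
    lognormal jitter (coefficient of variation ``between_subject_cv``) on
    each subject's mean segment durations.
    """
    if effect_spec is None:
        effect_spec = EffectSpec.default_rbd()
    meta = _metadata(n_rbd, n_hc, seed)
    seeds = _subject_seeds(seed, n_rbd + n_hc)
    base_means = np.full(n_states, mean_segment_ms)
    base_T = np.full((n_states, n_states), 1.0 / (n_states - 1))
    np.fill_diagonal(base_T, 0.0)
    sigma = np.sqrt(np.log(1.0 + between_subject_cv**2))

    records = []
    n_per_epoch = int(round(epoch_s * sampling_rate))
    for row, subj_seed in zip(meta.itertuples(index=False), seeds):
        if row.group == "RBD":
            means, T = _apply_effects(base_means, base_T, effect_spec)
        else:
            means, T = base_means.copy(), base_T.copy()
        rng = np.random.default_rng(int(subj_seed))
        if sigma > 0:
            means = means * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_states)
        cfg = GeneratorConfig(
            n_channels=2,  # irrelevant at label level
            n_states=n_states,
            sampling_rate=sampling_rate,
            duration=duration_s,
            mean_segment_duration=means,
            transition_matrix=T,
            seed=int(subj_seed),
        )
        gt = sample_state_sequence(cfg)
        n_epochs = len(gt.label_sequence) // n_per_epoch
        labels = [
            gt.label_sequence[k * n_per_epoch : (k + 1) * n_per_epoch] for k in range(n_epochs)
        ]
        seg = MicrostateSegmentation(
            labels=labels,
            assignment_corr=[np.ones(n_per_epoch) for _ in range(n_epochs)],
            gfp=[np.ones(n_per_epoch) for _ in range(n_epochs)],
            sampling_rate=sampling_rate,
            n_classes=n_states,
        )
        records.append(
            SubjectRecord(
                subject_id=row.subject_id,
                group=row.group,
                rbdqhk_score=row.rbdqhk,
                age=row.age,
                sex=row.sex,
                parameters=compute_parameters(seg),
                transitions=transition_matrix(seg),
            )
        )
    return records


def make_demo_cohort(
    output_dir: str | Path,
    n_rbd: int = 22,
    n_hc: int = 46,
    effect_spec: Optional[EffectSpec] = None,
    seed: int = 0,
    duration_s: float = 60.0,
    n_channels: int = 64,
    sampling_rate: float = 1000.0,
    mean_segment_ms: float = 80.0,
    noise_sigma: float = 0.1,
    between_subject_cv: float = 0.10,
) -> Path:
    """Write a full synthetic cohort: BrainVision triplets + metadata CSV.

    Returns the manifest (metadata) CSV path. All subjects share one set of
    generating templates (the cohort's 'true' microstate maps); planted
    effects act on the per-subject label process.
    """
    output_dir = Path(output_dir)
    (output_dir / "recordings").mkdir(parents=True, exist_ok=True)
    if effect_spec is None:
        effect_spec = EffectSpec.default_rbd()
    meta = _metadata(n_rbd, n_hc, seed)
    seeds = _subject_seeds(seed, n_rbd + n_hc)
    templates = make_template_maps(n_channels, 4, seed=seed, min_separation=0.4)
    names = list(default_channels(n_channels))
    positions = channel_positions(names)
    base_means = np.full(4, mean_segment_ms)
    base_T = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(base_T, 0.0)
    sigma = np.sqrt(np.log(1.0 + between_subject_cv**2))

    files = []
    for row, subj_seed in zip(meta.itertuples(index=False), seeds):
        if row.group == "RBD":
            means, T = _apply_effects(base_means, base_T, effect_spec)
        else:
            means, T = base_means.copy(), base_T.copy()
        rng = np.random.default_rng(int(subj_seed))
        if sigma > 0:
            means = means * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=4)
        cfg = GeneratorConfig(
            n_channels=n_channels,
            n_states=4,
            sampling_rate=sampling_rate,
            duration=duration_s,
            mean_segment_duration=means,
            transition_matrix=T,
            noise_sigma=noise_sigma,
            seed=int(subj_seed),
        )
        gt = sample_state_sequence(cfg)
        gt = dataclasses.replace(gt, templates=templates)
        rec = synthesize_recording(templates, gt, cfg, channel_names=names, positions=positions)
        vhdr = eio.write_brainvision(rec, output_dir / "recordings" / row.subject_id)
        eio.write_ground_truth(gt, output_dir / "ground_truth", row.subject_id)
        files.append(str(vhdr))
    meta["file"] = files
    manifest = output_dir / "metadata.csv"
    meta.to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# Pipeline configuration and runner
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with protocol defaults."""

    seed: int = 0
    output_dir: str = "eegstates_run"
    manifest: Optional[str] = None  # existing cohort; None -> simulate

    # simulation (used when manifest is None)
    n_rbd: int = 22
    n_hc: int = 46
    duration_s: float = 60.0
    n_channels: int = 64
    sampling_rate: float = 1000.0
    mean_segment_ms: float = 80.0
    noise_sigma: float = 0.1
    effect_duration_scale: dict = field(default_factory=lambda: {"A": 0.92, "D": 0.85})
    effect_transition_bias: dict = field(default_factory=lambda: {"B": 1.3, "C": 1.15})

    # preprocessing
    target_rate: float = 250.0
    low: float = 1.0
    high: float = 40.0
    notch: float = 50.0
    flatline_s: float = 5.0
    noise_sd: float = 4.0
    min_corr: float = 0.8
    window_s: float = 0.5
    sd_cut: float = 20.0
    epoch_s: float = 2.0

    # microstate analysis
    n_classes: int = 4
    min_distance_ms: float = 10.0
    min_segment_ms: float = 0.0

    # statistics
    alpha: float = 0.05
    adjust: str = "holm"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run report (also written to
    ``output_dir/run_report.json``)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline_log.jsonl"
    log_f = log_path.open("w")

    def log(stage: str, subject: str = "", **kw) -> None:
        log_f.write(json.dumps({"stage": stage, "subject": subject, **kw}) + "\n")

    try:
        if config.manifest is None:
            manifest = make_demo_cohort(
                out,
                n_rbd=config.n_rbd,
                n_hc=config.n_hc,
                effect_spec=EffectSpec(
                    duration_scale=dict(config.effect_duration_scale),
                    transition_bias=dict(config.effect_transition_bias),
                ),
                seed=config.seed,
                duration_s=config.duration_s,
                n_channels=config.n_channels,
                sampling_rate=config.sampling_rate,
                mean_segment_ms=config.mean_segment_ms,
                noise_sigma=config.noise_sigma,
            )
            log("simulate", n_subjects=config.n_rbd + config.n_hc)
        else:
            manifest = Path(config.manifest)
        meta = pd.read_csv(manifest)
        missing = [f for f in meta["file"] if not Path(f).exists()]
        if missing:
            raise FileNotFoundError(f"manifest references missing files: {missing}")

        epochs_by_subject: dict[str, EpochedData] = {}
        for row in meta.itertuples(index=False):
            try:
                rec = eio.read_recording(row.file)
                epochs, report = preprocess_recording(
                    rec,
                    target_rate=config.target_rate,
                    low=config.low,
                    high=config.high,
                    notch=config.notch,
                    flatline_s=config.flatline_s,
                    noise_sd=config.noise_sd,
                    min_corr=config.min_corr,
                    window_s=config.window_s,
                    sd_cut=config.sd_cut,
                    epoch_s=config.epoch_s,
                )
            except Exception as exc:
                raise RuntimeError(f"stage=preprocess subject={row.subject_id}: {exc}") from exc
            epochs_by_subject[row.subject_id] = epochs
            log(
                "preprocess",
                row.subject_id,
                bad_channel_pct=report.bad_channel_pct,
                bad_channels=[b.name for b in report.bad_channels],
                rejected_pct=report.rejected_pct,
                n_epochs=report.n_epochs,
            )

        subject_sets: dict[str, TemplateSet] = {}
        for sid, ep in epochs_by_subject.items():
            ts = subject_templates(
                ep, k=config.n_classes, min_distance_ms=config.min_distance_ms, source=sid
            )
            subject_sets[sid] = ts
            log("aahc", sid, gev_total=ts.gev_total)

        group_templates: dict[str, TemplateSet] = {}
        for gname in meta["group"].unique():
            sids = meta.loc[meta["group"] == gname, "subject_id"]
            aligned, _ = align_subject_maps([subject_sets[s] for s in sids])
            mean_ts = group_mean_templates(aligned, source=str(gname))
            if config.n_classes == 4:
                mean_ts = label_canonical(mean_ts).ordered_by_label()
            group_templates[gname] = mean_ts
            eio.write_templates(mean_ts, out / f"templates_{gname}.csv")
            log("group_templates", gname)

        records: list[SubjectRecord] = []
        params_by_subject, tables_by_subject = {}, {}
        for row in meta.itertuples(index=False):
            seg, params, table = segment_and_parameterize(
                epochs_by_subject[row.subject_id],
                group_templates[row.group],
                min_segment_ms=config.min_segment_ms,
            )
            params_by_subject[row.subject_id] = params
            tables_by_subject[row.subject_id] = table
            records.append(
                SubjectRecord(
                    subject_id=row.subject_id,
                    group=row.group,
                    rbdqhk_score=row.rbdqhk,
                    age=row.age,
                    sex=row.sex,
                    parameters=params,
                    transitions=table,
                )
            )
            log("backfit", row.subject_id, gev_total=params.gev_total)

        params_csv = out / "parameters.csv"
        eio.parameters_to_frame(params_by_subject).to_csv(params_csv, index=False)
        trans_csv = out / "transitions.csv"
        eio.transitions_to_frame(tables_by_subject).to_csv(trans_csv, index=False)

        report = group_comparison_report(records, alpha=config.alpha, adjust=config.adjust)
        stats_files = {}
        for name, df in (
            ("parameter_tests", report.parameters),
            ("correlations", report.correlations),
            ("regressions", report.regressions),
            ("ancova", report.ancova),
        ):
            p = out / f"stats_{name}.csv"
            df.to_csv(p, index=False)
            stats_files[name] = str(p)
        if report.transitions_between_groups is not None:
            p = out / "stats_transitions_between_groups.csv"
            report.transitions_between_groups.to_csv(p, index=False)
            stats_files["transitions_between_groups"] = str(p)
            for gname, df in report.transitions_vs_expected.items():
                p = out / f"stats_transitions_vs_expected_{gname}.csv"
                df.to_csv(p, index=False)
                stats_files[f"transitions_vs_expected_{gname}"] = str(p)
        log("stats")

        artifacts = {
            "parameters": str(params_csv),
            "transitions": str(trans_csv),
            **stats_files,
        }
        run_report = {
            "seed": config.seed,
            "n_subjects": len(records),
            "artifacts": {k: {"path": v, "sha256": _sha256(Path(v))} for k, v in artifacts.items()},
            "group_gev": {
                g: float(np.mean([r.parameters.gev_total for r in records if r.group == g]))
                for g in meta["group"].unique()
            },
        }
        (out / "run_report.json").write_text(json.dumps(run_report, indent=2))
        return run_report
    finally:
        log_f.close()
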