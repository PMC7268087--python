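"""End-to-end orchestration: synthesize -> envelope -> fit -> decode ->
metrics -> group stats -> gene association, from a single validated config.

The pipeline is a pure function of (inputs, config): every random stage
draws from a seed derived deterministically from ``config.seed``, and
re-running the same config reproduces outputs bit for bit. Stage outputs
and a provenance record (parameters, derived seeds, output digests) are
written under the run's output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genes as genes_mod
from . import synthetic
from .envelope import concatenate_subjects, envelope_pipeline, normalize_subject
from .groupstats import compare_all
from .hmm import HMMParams, StateTimeCourses, fit_hmm, state_spatial_maps, viterbi_decode
from .metrics import compute_metrics, group_summary
from .synthetic import CohortSpec, make_ground_truth, simulate_cohort

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """All stage toggles and parameters for one pipeline run."""

    # stage toggles / modes
    synthesize: bool = True
    envelope_stage: bool = False  # raw oscillatory input -> envelope chain
    decode_mode: str = "hmm"  # "hmm" | "true_paths"
    genes_stage: bool = True
    protocol: str = "rest"

    # synthetic generator
    n_states: int = 8
    n_parcels: int = 38
    self_persistence: float = 0.9
    separation: float = 3.0
    n_subjects_per_group: tuple[int, int] = (7, 8)
    samples_per_subject: int = 3000
    group_effect: dict[int, float] = field(default_factory=dict)
    expression_coupling: float = 0.0
    expression_noise_sd: float = 1.0

    # envelope stage
    band_low_hz: float = 4.0
    band_high_hz: float = 30.0
    fs_raw: float = 250.0
    window_width_ms: float = 100.0
    window_overlap: float = 0.75
    orthogonalize: bool = False

    # HMM stage
    n_restarts: int = 2
    max_iter: int = 50
    tol: float = 1e-3
    cov_reg: float = 1e-4

    # group statistics
    n_permutations: int = 10_000
    q: float = 0.05
    fdr_family: str = "all"

    # gene association
    top_k: int = 20
    n_null_iterations: int = 10_000

    # inputs (used when synthesize is False)
    data_dir: str | None = None
    expression_csv: str | None = None

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "group_effect" in raw and raw["group_effect"] is not None:
            raw["group_effect"] = {int(k): float(v) for k, v in raw["group_effect"].items()}
        if "n_subjects_per_group" in raw:
            raw["n_subjects_per_group"] = tuple(raw["n_subjects_per_group"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_subjects_per_group"] = list(self.n_subjects_per_group)
        d["group_effect"] = {str(k): v for k, v in self.group_effect.items()}
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of precondition violations (empty means valid)."""
    v: list[str] = []
    if config.decode_mode not in ("hmm", "true_paths"):
        v.append(f"decode_mode: must be 'hmm' or 'true_paths', got {config.decode_mode!r}")
    if config.fdr_family not in ("all", "per_measure"):
        v.append(f"fdr_family: must be 'all' or 'per_measure', got {config.fdr_family!r}")
    if config.n_states < 1:
        v.append("n_states: must be >= 1")
    if config.n_parcels < 1:
        v.append("n_parcels: must be >= 1")
    if not 0.0 < config.self_persistence < 1.0:
        v.append("self_persistence: must lie strictly between 0 and 1")
    if config.separation < 0:
        v.append("separation: must be >= 0")
    if any(n < 1 for n in config.n_subjects_per_group):
        v.append("n_subjects_per_group: each group needs >= 1 subject")
    if config.samples_per_subject < 1:
        v.append("samples_per_subject: must be >= 1")
    if not 0.0 < config.band_low_hz < config.band_high_hz < config.fs_raw / 2.0:
        v.append("band: need 0 < band_low_hz < band_high_hz < fs_raw / 2")
    if config.window_width_ms <= 0:
        v.append("window_width_ms: must be > 0")
    if not 0.0 <= config.window_overlap < 1.0:
        v.append("window_overlap: must lie in [0, 1)")
    if config.n_restarts < 1:
        v.append("n_restarts: must be >= 1")
    if config.max_iter < 1:
        v.append("max_iter: must be >= 1")
    if config.n_permutations < 1:
        v.append("n_permutations: must be >= 1")
    if not 0.0 < config.q < 1.0:
        v.append("q: must lie in (0, 1)")
    if not 1 <= config.top_k <= 68:
        v.append("top_k: must lie in [1, 68] (68 expression regions)")
    if config.n_null_iterations < 1:
        v.append("n_null_iterations: must be >= 1")
    if not config.synthesize and config.data_dir is None:
        v.append("data_dir: required when synthesize is disabled")
    return v


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns a run report dict.

    The report carries the main tables (metrics, summary, group report,
    expression results, association) plus provenance. When ``out_dir`` is
    given, every table is also written as CSV alongside a
    ``provenance.json``.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config:\n  " + "\n  ".join(violations))

    root = np.random.default_rng(config.seed)
    seeds = {name: int(root.integers(2**31)) for name in
             ("cohort", "expression", "hmm", "stats", "genes")}
    report: dict = {"config": config.to_dict(), "seeds": seeds, "stages": []}

    # --- inputs -----------------------------------------------------------
    if config.synthesize:
        truth = make_ground_truth(
            n_states=config.n_states,
            n_parcels=config.n_parcels,
            self_persistence=config.self_persistence,
            separation=config.separation,
            seed=seeds["cohort"],
        )
        cohort = simulate_cohort(
            truth,
            CohortSpec(
                n_subjects_per_group=config.n_subjects_per_group,
                samples_per_subject=config.samples_per_subject,
                group_effect=config.group_effect,
                expression_coupling=config.expression_coupling,
                expression_noise_sd=config.expression_noise_sd,
                seed=seeds["cohort"],
            ),
        )
        subject_mats = cohort.envelopes
        subject_ids = cohort.subject_ids
        labels = dict(zip(cohort.subject_ids, cohort.group_labels))
        fs = truth.sampling_rate
        report["stages"].append("synthesize")
    else:
        from .io import load_subject_matrices

        data_dir = Path(config.data_dir)
        if not data_dir.exists():
            raise FileNotFoundError(f"input directory not found: {data_dir}")
        subject_mats, subject_ids = load_subject_matrices(data_dir)
        labels_df = pd.read_csv(data_dir / "labels.csv")
        labels = dict(zip(labels_df["subject_id"].astype(str), labels_df["group"]))
        cohort = None
        truth = None
        fs = config.fs_raw if config.envelope_stage else 40.0
        report["stages"].append("load")

    # --- envelope ---------------------------------------------------------
    if config.envelope_stage:
        dataset = envelope_pipeline(
            subject_mats,
            subject_ids,
            fs=config.fs_raw,
            low_hz=config.band_low_hz,
            high_hz=config.band_high_hz,
            width_ms=config.window_width_ms,
            overlap_fraction=config.window_overlap,
            orthogonalize=config.orthogonalize,
        )
        report["stages"].append("envelope")
    else:
        dataset = concatenate_subjects(
            [normalize_subject(m) for m in subject_mats], subject_ids, sampling_rate=fs
        )

    # --- state decomposition ---------------------------------------------
    if config.decode_mode == "hmm":
        params = fit_hmm(
            dataset,
            n_states=config.n_states,
            n_restarts=config.n_restarts,
            max_iter=config.max_iter,
            tol=config.tol,
            seed=seeds["hmm"],
            cov_reg=config.cov_reg,
        )
        stc = viterbi_decode(params, dataset)
        report["stages"].append("fit+decode")
        report["log_likelihood"] = params.log_likelihood
    else:
        if cohort is None:
            raise ValueError("decode_mode='true_paths' requires synthesized data")
        act = np.zeros((config.n_states, dataset.n_samples), dtype=np.int8)
        for (sid, s, e), path in zip(dataset.subject_boundaries, cohort.true_paths):
            act[path, np.arange(s, e)] = 1
        stc = StateTimeCourses(activations=act, subject_boundaries=dataset.subject_boundaries)
        params = HMMParams(
            n_states=config.n_states,
            means=cohort.truth_a.state_means,
            covariances=cohort.truth_a.state_covariances,
            transition_matrix=cohort.truth_a.transition_matrix,
            initial_distribution=cohort.truth_a.initial_distribution,
        )
        report["stages"].append("true-path decode")

    # --- temporal metrics and group statistics ----------------------------
    metrics = compute_metrics(stc, dataset.sampling_rate)
    summary = group_summary(metrics, labels)
    group_report = compare_all(
        metrics,
        labels,
        n_permutations=config.n_permutations,
        seed=seeds["stats"],
        q=config.q,
        family=config.fdr_family,
    )
    report["stages"] += ["metrics", "stats"]

    # --- gene association --------------------------------------------------
    expression_results = None
    association = None
    if config.genes_stage:
        maps = state_spatial_maps(stc, dataset)
        P = dataset.n_parcels
        projection = (
            genes_mod.identity_projection()
            if P == 68
            else genes_mod.uniform_overlap_projection(P)
        )
        if config.expression_csv is not None:
            expr = genes_mod.ExpressionMap.from_csv(config.expression_csv)
        elif config.synthesize:
            parcel_profile = synthetic.effect_region_profile(truth, config.group_effect)
            region_profile = genes_mod.project_state_map(parcel_profile, projection)
            values = synthetic.simulate_expression(
                region_profile,
                coupling=config.expression_coupling,
                noise_sd=config.expression_noise_sd,
                rng=np.random.default_rng(seeds["expression"]),
            )
            expr = genes_mod.ExpressionMap(list(genes_mod.DK_REGIONS), values)
        else:
            raise ValueError("genes stage needs expression_csv when not synthesizing")

        null = genes_mod.null_scores(
            expr, k=config.top_k, n_iterations=config.n_null_iterations, seed=seeds["genes"]
        )
        rows = []
        expr_p = np.empty(config.n_states)
        for k_state in range(config.n_states):
            activity = genes_mod.project_state_map(maps[k_state], projection)
            score = genes_mod.state_expression_score(activity, expr, k=config.top_k)
            p = genes_mod.expression_pvalue(score, null)
            expr_p[k_state] = p
            rows.append({"state": k_state, "score": score, "p": p})
        expression_results = pd.DataFrame(rows)
        association = genes_mod.association_report({"synthetic": expr_p}, group_report)
        report["stages"].append("genes")

    report["metrics"] = metrics
    report["summary"] = summary
    report["group_report"] = group_report
    report["expression_results"] = expression_results
    report["association"] = association

    # --- outputs -----------------------------------------------------------
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        group_report.to_csv(out / "group_report.csv", index=False)
        written = ["metrics.csv", "summary.csv", "group_report.csv"]
        if expression_results is not None:
            expression_results.to_csv(out / "expression_results.csv", index=False)
            association.to_csv(out / "association.csv", index=False)
            written += ["expression_results.csv", "association.csv"]
        provenance = {
            "config": config.to_dict(),
            "seeds": seeds,
            "stages": report["stages"],
            "outputs": {name: _digest(out / name) for name in written},
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        report["out_dir"] = str(out)
    return report
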