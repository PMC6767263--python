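"""Configuration-driven grid experiments over beta, cost and classifier.

Reproduces the study design: every combination of ADASYN balance level
(beta in {0, 0.2, 0.5, 1}), FoG misclassification cost (C_FoG in
{1, 2, 3}) and classifier, under the patient-dependent (chronological
60/40 within subject) and/or patient-independent (leave-one-subject-out)
protocol, repeated over seeds.  Results come back as a tidy DataFrame —
one row per grid cell per seed per subject — plus best-per-metric
summary tables in the shape (classifier, C_NG, C_FoG, beta,
sensitivity, specificity, F1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adasyn import AdasynConfig, adasyn_oversample
from .ensemble import CLASSIFIER_NAMES, CostSpec, train_classifier
from .evaluation import (
    evaluate_model,
    latency_profile,
    loocv_patient_independent,
    split_patient_dependent,
)
from .gait_synth import SignalRecording, SynthConfig, generate_recording, read_recording
from .sample_builder import SampleSet, samples_from_recording

__all__ = ["GridConfig", "run_grid", "summarize_best", "plot_trends", "plot_latency_histogram"]


@dataclass
class GridConfig:
    betas: list[float] = field(default_factory=lambda: [0.0, 0.2, 0.5, 1.0])
    fog_costs: list[float] = field(default_factory=lambda: [1.0, 2.0, 3.0])
    classifiers: list[str] = field(default_factory=lambda: ["clsf_bagging"])
    protocol: str = "dependent"          # dependent | independent | both
    seeds: list[int] = field(default_factory=lambda: [0])
    n_subjects: int = 3
    synth: SynthConfig = field(default_factory=SynthConfig)
    recording_paths: list[str] | None = None  # one file per subject, overrides synth
    target_rate: float = 64.0
    pre_fog_seconds: float = 1.0
    k_neighbors: int = 5
    with_latency: bool = True

    def validate(self) -> None:
        if not (self.betas and self.fog_costs and self.classifiers and self.seeds):
            raise ValueError("grid axes must be non-empty")
        for c in self.classifiers:
            if c not in CLASSIFIER_NAMES:
                raise ValueError(f"unknown classifier {c!r}")
        if self.protocol not in ("dependent", "independent", "both"):
            raise ValueError("protocol must be dependent, independent or both")

    @staticmethod
    def from_dict(d: dict) -> "GridConfig":
        d = dict(d)
        if "synth" in d and isinstance(d["synth"], dict):
            d["synth"] = SynthConfig(**d["synth"])
        return GridConfig(**d)


def _load_subjects(cfg: GridConfig, seed: int) -> dict[str, SignalRecording]:
    if cfg.recording_paths:
        return {f"s{i}": read_recording(p) for i, p in enumerate(cfg.recording_paths)}
    recs = {}
    for i in range(cfg.n_subjects):
        sc = replace(cfg.synth, seed=int((seed * 10_007 + i) % 2**31))
        recs[f"s{i}"] = generate_recording(sc)
    return recs


_ROW_COLS = [
    "classifier", "c_ng", "c_fog", "beta", "protocol", "seed", "subject",
    "sensitivity", "specificity", "f1",
    "predicted_fraction", "detected_fraction", "identified_fraction",
    "mean_latency", "status",
]


def run_grid(cfg: GridConfig) -> pd.DataFrame:
    """Run the full beta x cost x classifier grid.

    Patient-dependent cells train one model per subject on that
    subject's chronological 60 % (with ADASYN on the training side) and
    evaluate on the remaining 40 %; patient-independent cells run
    leave-one-subject-out.  A failed cell is recorded with
    ``status='failed'`` and the grid continues.
    """
    cfg.validate()
    rows = []
    protocols = ["dependent", "independent"] if cfg.protocol == "both" else [cfg.protocol]
    for seed in cfg.seeds:
        recordings = _load_subjects(cfg, seed)
        per_subject: dict[str, tuple[SampleSet, SignalRecording]] = {}
        for subj, rec in recordings.items():
            samples, rec_rs = samples_from_recording(
                rec, cfg.target_rate, cfg.pre_fog_seconds
            )
            samples.subject = np.full(len(samples), subj)
            per_subject[subj] = (samples, rec_rs)

        for name in cfg.classifiers:
            for beta in cfg.betas:
                for c_fog in cfg.fog_costs:
                    cost = CostSpec(c_fog=c_fog)
                    acfg = AdasynConfig(beta=beta, k_neighbors=cfg.k_neighbors, seed=seed)
                    for protocol in protocols:
                        try:
                            rows.extend(
                                _run_cell(
                                    per_subject, name, cost, acfg, protocol, seed, cfg
                                )
                            )
                        except Exception as exc:
                            rows.append(
                                dict.fromkeys(_ROW_COLS)
                                | {
                                    "classifier": name,
                                    "c_ng": cost.c_ng,
                                    "c_fog": c_fog,
                                    "beta": beta,
                                    "protocol": protocol,
                                    "seed": seed,
                                    "status": f"failed: {exc}",
                                }
                            )
    return pd.DataFrame(rows, columns=_ROW_COLS)


def _run_cell(per_subject, name, cost, acfg, protocol, seed, cfg) -> list[dict]:
    base = {
        "classifier": name,
        "c_ng": cost.c_ng,
        "c_fog": cost.c_fog,
        "beta": acfg.beta,
        "protocol": protocol,
        "seed": seed,
        "status": "ok",
    }
    rows = []
    if protocol == "dependent":
        for subj, (samples, rec_rs) in per_subject.items():
            train, test = split_patient_dependent(samples)
            if acfg.beta > 0:
                train = adasyn_oversample(train, acfg)
            model = train_classifier(name, train, cost=cost, seed=seed)
            report = evaluate_model(model, test)
            row = base | {
                "subject": subj,
                "sensitivity": report.metrics.sensitivity,
                "specificity": report.metrics.specificity,
                "f1": report.metrics.f1,
            }
            if cfg.with_latency:
                pred = model.predict(test.X)
                prof = latency_profile(
                    test.t, pred, rec_rs.labels, cfg.target_rate
                )
                row |= {
                    "predicted_fraction": prof.predicted_fraction,
                    "detected_fraction": prof.detected_fraction,
                    "identified_fraction": prof.identified_fraction,
                    "mean_latency": prof.mean_latency,
                }
            rows.append(row)
    else:
        samples_by_subject = {s: p[0] for s, p in per_subject.items()}
        reports, _ = loocv_patient_independent(
            samples_by_subject, classifier=name, cost=cost, adasyn_cfg=acfg, seed=seed
        )
        for subj, report in reports.items():
            rows.append(
                base
                | {
                    "subject": subj,
                    "sensitivity": report.metrics.sensitivity,
                    "specificity": report.metrics.specificity,
                    "f1": report.metrics.f1,
                }
            )
    return rows


def summarize_best(results: pd.DataFrame, top: int = 5) -> dict[str, pd.DataFrame]:
    """Best-performing grid cells per metric.

    Rows are first averaged over subjects and seeds within each
    (classifier, C_NG, C_FoG, beta, protocol) cell, then the ``top``
    cells per metric are reported, highest first.
    """
    ok = results[results["status"] == "ok"]
    keys = ["classifier", "c_ng", "c_fog", "beta", "protocol"]
    cell = ok.groupby(keys, as_index=False)[["sensitivity", "specificity", "f1"]].mean()
    out = {}
    for metric_name in ("sensitivity", "specificity", "f1"):
        out[metric_name] = (
            cell.sort_values(metric_name, ascending=False)
            .head(top)
            .reset_index(drop=True)
        )
    return out


def plot_trends(results: pd.DataFrame, metric: str = "f1", ax=None):
    """Metric vs beta, one line per C_FoG, averaged over subjects/seeds."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = results[results["status"] == "ok"]
    for c_fog, grp in ok.groupby("c_fog"):
        trend = grp.groupby("beta")[metric].mean()
        ax.plot(trend.index, trend.values, marker="o", label=f"$C_{{FoG}}$ = {c_fog:g}")
    ax.set_xlabel(r"ADASYN balance level $\beta$")
    ax.set_ylabel(f"{metric} (%)")
    ax.legend()
    return ax


def plot_latency_histogram(profile, ax=None):
    """Episode-count histogram over the latency search window."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    edges, counts = profile.histogram()
    ax.bar(edges, counts, width=0.4)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("latency relative to FoG onset (s)")
    ax.set_ylabel("episodes")
    return ax
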