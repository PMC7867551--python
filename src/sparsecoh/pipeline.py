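"""End-to-end orchestration: simulate -> preprocess -> features ->
validate -> transfer -> correlate.

A single master seed fans out to stage-specific seeds through a counter
scheme (`SeedSequence(master, spawn_key=stage_index)`), so stages are
reproducible independently and the whole run is byte-deterministic for a
fixed config. Every artifact written is listed in a checksum manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as io_mod
from .association import model_symptom_associations
from .preprocess import (
    DEFAULT_AMP_THRESHOLD_UV,
    DEFAULT_DRIFT_THRESHOLD_UV,
    MIN_USABLE_EPOCHS,
    BipolarMontage,
    RawSession,
    preprocess_session,
)
from .simulate import CohortSpec, simulate_cohort
from .spectral import BAND_BY_NAME, extract_features, pair_labels
from .validation import (
    CVConfig,
    contrast_arrays,
    refit_and_metrics,
    run_contrasts,
    transfer_apply,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage (and session)."""


#: stage indices for the seed fan-out
STAGES = ("simulate", "validate", "permute", "metrics")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the master seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(master_seed, spawn_key=(idx,))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """Full-run configuration; round-trips losslessly through YAML."""

    seed: int = 0
    out_dir: str = "run"
    # cohort (None -> read an existing manifest instead)
    manifest: str | None = None
    n_active: int = 19
    n_sham: int = 16
    effect_magnitude: float = 0.6
    duration: float = 408.0
    # preprocessing
    amp_threshold: float = DEFAULT_AMP_THRESHOLD_UV
    drift_threshold: float = DEFAULT_DRIFT_THRESHOLD_UV
    min_epochs: int = MIN_USABLE_EPOCHS
    montage_file: str | None = None
    # validation
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta")
    contrasts: tuple[str, ...] = (
        "active-vs-sham-post", "active-vs-sham-pre",
        "pre-vs-post-active", "pre-vs-post-sham",
    )
    primary_contrast: str = "active-vs-sham-post"
    primary_band: str = "delta"
    n_iterations: int = 500
    n_permutations: int = 1000
    perm_n_iterations: int | None = None
    reduced: bool = False  # desk-scale preset override

    def cv_config(self, seed: int) -> CVConfig:
        if self.reduced:
            return CVConfig.reduced(seed=seed)
        return CVConfig(
            n_iterations=self.n_iterations,
            n_permutations=self.n_permutations,
            perm_n_iterations=self.perm_n_iterations,
            seed=seed,
        )

    def montage(self) -> BipolarMontage:
        if self.montage_file:
            return BipolarMontage.from_file(self.montage_file)
        return BipolarMontage()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(
                f"config: unknown key(s): {', '.join(sorted(unknown))}"
            )
        for key in ("bands", "contrasts"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        data = asdict(self)
        data["bands"] = list(self.bands)
        data["contrasts"] = list(self.contrasts)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path


def cohort_features(
    sessions: list[RawSession],
    montage: BipolarMontage | None = None,
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta"),
    amp_threshold: float = DEFAULT_AMP_THRESHOLD_UV,
    drift_threshold: float = DEFAULT_DRIFT_THRESHOLD_UV,
    min_epochs: int = MIN_USABLE_EPOCHS,
) -> tuple[pd.DataFrame, list[str], list[dict]]:
    """Preprocess and featurize a cohort.

    Returns the long-format feature table (one row per included session
    and band), the 28 coherence column names, and the per-session
    inclusion log (including excluded sessions with reasons).
    """
    montage = montage or BipolarMontage()
    band_defs = [BAND_BY_NAME[b] for b in bands]
    rows: list[dict] = []
    log: list[dict] = []
    cols: list[str] | None = None
    for s in sessions:
        try:
            epochs, decision = preprocess_session(
                s, montage, amp_threshold=amp_threshold,
                drift_threshold=drift_threshold, min_epochs=min_epochs,
            )
        except Exception as exc:  # noqa: BLE001 - stage failure context
            raise PipelineError(
                f"preprocess failed for session {s.participant_id}-"
                f"{s.timepoint}: {exc}"
            ) from exc
        log.append(
            {
                "participant": s.participant_id,
                "timepoint": s.timepoint,
                "arm": s.arm,
                "included": decision.passed,
                "reason": decision.reason,
                "n_epochs": decision.n_epochs,
            }
        )
        if not decision.passed:
            continue
        feats = extract_features(epochs, band_defs)
        if cols is None:
            cols = list(feats[bands[0]].pair_names)
        for b in bands:
            row = {
                "participant": s.participant_id,
                "arm": s.arm,
                "timepoint": s.timepoint,
                "band": b,
                "n_epochs": epochs.n_epochs,
            }
            row.update(dict(zip(cols, feats[b].values)))
            row.update(s.symptoms)
            rows.append(row)
    if cols is None:
        cols = list(pair_labels(montage.site_names))
    return pd.DataFrame(rows), cols, log


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute the full analysis; returns the report dict.

    Writes: cohort files + manifest, feature table, model file, JSON
    report, human-readable summary, and a checksum manifest of every
    artifact.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = config.montage()
    artifacts: list[Path] = []

    # --- stage 1: cohort ---------------------------------------------------
    if config.manifest:
        sessions = io_mod.read_cohort(config.manifest)
    else:
        spec = CohortSpec(
            n_active=config.n_active,
            n_sham=config.n_sham,
            effect_magnitude=config.effect_magnitude,
            duration=config.duration,
            seed=stage_seed(config.seed, "simulate"),
            montage=montage,
        )
        sessions = simulate_cohort(spec)
        artifacts.append(io_mod.write_cohort(sessions, out / "cohort"))

    # --- stage 2+3: preprocess & features ---------------------------------
    features, feature_cols, inclusion_log = cohort_features(
        sessions, montage, config.bands,
        amp_threshold=config.amp_threshold,
        drift_threshold=config.drift_threshold,
        min_epochs=config.min_epochs,
    )
    if not len(features):
        raise PipelineError("features: no session passed inclusion")
    artifacts.append(io_mod.write_features(features, out / "features.tsv"))

    # --- stage 4: contrasts ------------------------------------------------
    cv_cfg = config.cv_config(stage_seed(config.seed, "validate"))
    results = run_contrasts(
        features, cv_cfg, feature_cols,
        bands=config.bands, contrasts=config.contrasts,
        with_permutation=True,
    )

    # --- stage 5: refit metrics on the primary contrast --------------------
    key = (config.primary_contrast, config.primary_band)
    primary_cv = results[key]["cv"]
    sub = features[features.band == config.primary_band]
    X, y, _ = contrast_arrays(sub, config.primary_contrast, feature_cols)
    metrics = refit_and_metrics(
        X, y, primary_cv.best_C, cv_cfg, feature_names=feature_cols,
        rng=np.random.default_rng(stage_seed(config.seed, "metrics")),
    )
    artifacts.append(io_mod.save_model(metrics.model, out / "model.txt"))

    # --- stage 6: transfer to pretreatment sessions ------------------------
    pre = features[
        (features.band == config.primary_band)
        & (features.timepoint == "pre")
    ]
    transfer = transfer_apply(
        metrics.model, pre[feature_cols].to_numpy(dtype=float)
    )

    # --- stage 7: symptom associations -------------------------------------
    active_post = features[
        (features.band == config.primary_band)
        & (features.timepoint == "post")
        & (features.arm == "active")
    ]
    associations = model_symptom_associations(
        metrics.model, active_post, feature_cols
    )

    # --- report -------------------------------------------------------------
    report = {
        "config": {**asdict(config), "bands": list(config.bands),
                   "contrasts": list(config.contrasts)},
        "inclusion": inclusion_log,
        "contrasts": {
            f"{c}|{b}": {
                "cv": cell["cv"].to_dict(),
                "permutation": cell["permutation"].to_dict(),
            }
            for (c, b), cell in results.items()
        },
        "primary": {
            "contrast": config.primary_contrast,
            "band": config.primary_band,
            "best_C": primary_cv.best_C,
            "cv_accuracy": primary_cv.best_accuracy,
            **metrics.to_dict(),
            "nonzero_connections": metrics.model.nonzero_connections(),
            "transfer": transfer.to_dict(),
        },
        "associations": [a.to_dict() for a in associations],
    }
    artifacts.append(io_mod.write_json_report(report, out / "report.json"))
    artifacts.append(_write_summary(report, out / "report.txt"))

    manifest = {
        str(p.relative_to(out)): io_mod.sha256_of(p)
        for p in artifacts if p.is_file()
    }
    # include per-session files written under cohort/
    for p in sorted(out.rglob("*")):
        if p.is_file() and str(p.relative_to(out)) not in manifest:
            if p.name == "artifact_manifest.json":
                continue
            manifest[str(p.relative_to(out))] = io_mod.sha256_of(p)
    io_mod.write_json_report(manifest, out / "artifact_manifest.json")
    return report


def _write_summary(report: dict, path: Path) -> Path:
    lines = ["sparsecoh run summary", "=" * 21, ""]
    prim = report["primary"]
    lines.append(
        f"primary contrast: {prim['contrast']} ({prim['band']} band)"
    )
    lines.append(
        f"  best C = {prim['best_C']:.3g}, CV accuracy = "
        f"{prim['cv_accuracy']:.3f}"
    )
    lines.append(
        f"  refit AUC = {prim['auc']:.3f} "
        f"(95% CI {prim['auc_ci'][0]:.3f}-{prim['auc_ci'][1]:.3f}), "
        f"sensitivity = {prim['sensitivity']:.3f}, "
        f"specificity = {prim['specificity']:.3f}"
    )
    tr = prim["transfer"]
    lines.append(
        f"  transfer: {tr['n_negative']}/{tr['n_negative'] + tr['n_positive']}"
        f" pretreatment sessions assigned sham "
        f"({100 * tr['fraction_negative']:.1f}%)"
    )
    lines.append("")
    lines.append("contrast p-values (permutation, smoothed):")
    for key, cell in sorted(report["contrasts"].items()):
        lines.append(
            f"  {key}: acc={cell['cv']['best_accuracy']:.3f} "
            f"p={cell['permutation']['p_value']:.4f}"
        )
    lines.append("")
    if report["associations"]:
        lines.append("coherence-symptom associations (active, post):")
        for a in report["associations"]:
            lines.append(
                f"  {a['connection']} vs {a['instrument']}: "
                f"r={a['r']:.3f} p={a['p']:.4f} (n={a['n']})"
            )
    path.write_text("\n".join(lines) + "\n")
    return path
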