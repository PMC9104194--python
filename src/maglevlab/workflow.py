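"""End-to-end orchestration: generate -> extract -> classify -> report.

A :class:`RunConfig` fully determines a run; the report payload is a
deterministic function of (config, seed) so reruns are byte-identical
(timestamps are deliberately excluded from the payload).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cohorts import (
    ClassSpec,
    cohort_from_replicates,
    default_class_specs,
    generate_fingerprint_cohort,
)
from .stats import (
    Cohort,
    blind_validation,
    classify,
    confidence_ellipse,
    lda_fit,
    metrics,
    pairwise_pvalue_matrix,
)

__all__ = ["RunConfig", "ConfigError", "run_full", "make_report"]

REPORT_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    seed: int
    output_dir: str
    n_nop: int = 15
    n_per_cancer: int = 5
    n_pdac: int = 15
    positive_classes: tuple = ("breast", "prostate", "colorectal", "PDAC")
    negative_class: str = "NOP"
    ellipse_level: float = 0.95
    holdout_per_class: int = 5
    holdout_positive_class: str = "PDAC"
    make_figures: bool = True

    REQUIRED = ("seed", "output_dir")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        missing = [k for k in cls.REQUIRED if k not in d]
        if missing:
            raise ConfigError(f"missing required config field(s): {missing}")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown config field(s): {unknown}")
        cfg = cls(**{k: v for k, v in d.items() if k in known})
        if isinstance(cfg.positive_classes, list):
            cfg.positive_classes = tuple(cfg.positive_classes)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["positive_classes"] = list(self.positive_classes)
        return d

    def digest(self) -> str:
        # output_dir is a deployment detail, not part of the analysis identity
        d = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _holdout_cohort(config: RunConfig, specs: list[ClassSpec]) -> Cohort:
    """Fresh donors (distinct ids, derived seed) for blind validation."""
    wanted = {config.negative_class, config.holdout_positive_class}
    ho_specs = []
    for s in specs:
        if s.class_name in wanted:
            ho_specs.append(
                ClassSpec(
                    class_name=s.class_name,
                    fingerprint_mean=s.fingerprint_mean,
                    fingerprint_cov=s.fingerprint_cov,
                    n_donors=config.holdout_per_class,
                    n_replicates=s.n_replicates,
                    replicate_cov_scale=s.replicate_cov_scale,
                    density_mixture=s.density_mixture,
                    n_particles=s.n_particles,
                )
            )
    table = generate_fingerprint_cohort(ho_specs, seed=config.seed + 10_000)
    table["donor_id"] = "holdout-" + table["donor_id"]
    return cohort_from_replicates(table)


def run_full(config: RunConfig) -> dict:
    """Run the complete synthetic workflow and write the report bundle.

    Returns the in-memory artifact dictionary; side effects are the
    files written by :func:`make_report` under ``config.output_dir``.
    """
    specs = default_class_specs(
        n_nop=config.n_nop,
        n_per_cancer=config.n_per_cancer,
        n_pdac=config.n_pdac,
    )
    try:
        table = generate_fingerprint_cohort(specs, seed=config.seed)
        cohort = cohort_from_replicates(table)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'generate' failed: {exc}") from exc

    comparisons = {}
    for pos in config.positive_classes:
        try:
            sub = cohort.subset([config.negative_class, pos])
            model = lda_fit(sub, positive_class=pos, negative_class=config.negative_class)
            _, counts = classify(model, sub.points, sub.labels)
            m = metrics(counts)
            ellipses = {
                name: confidence_ellipse(
                    sub.points[sub.labels == name], level=config.ellipse_level
                )
                for name in (config.negative_class, pos)
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'classify[{pos}]' failed: {exc}") from exc
        comparisons[pos] = {
            "model": model,
            "confusion": counts,
            "metrics": m,
            "ellipses": ellipses,
        }

    pmat = pairwise_pvalue_matrix(cohort, feature_index=0)

    holdout = _holdout_cohort(config, specs)
    bv = blind_validation(
        comparisons[config.holdout_positive_class]["model"],
        holdout,
        training_donor_ids=cohort.donor_ids,
    )

    artifacts = {
        "config": config,
        "replicate_table": table,
        "cohort": cohort,
        "comparisons": comparisons,
        "pvalue_matrix": pmat,
        "blind_validation": bv,
    }
    make_report(artifacts, Path(config.output_dir), figures=config.make_figures)
    return artifacts


def _ellipse_payload(e) -> dict:
    return {
        "center": [float(x) for x in e.center],
        "semi_axes": [float(x) for x in e.semi_axes],
        "orientation_rad": float(e.orientation),
        "level": e.level,
    }


def report_payload(artifacts: dict) -> dict:
    """Deterministic JSON-serializable report body."""
    config: RunConfig = artifacts["config"]
    comparisons = {}
    for pos, c in artifacts["comparisons"].items():
        model = c["model"]
        counts = c["confusion"]
        comparisons[pos] = {
            "weight_vector": [float(x) for x in model.weight_vector],
            "threshold": float(model.threshold),
            "confusion": {
                "true_negative": counts.true_negative,
                "false_positive": counts.false_positive,
                "false_negative": counts.false_negative,
                "true_positive": counts.true_positive,
            },
            "metrics": c["metrics"],
            "ellipses": {k: _ellipse_payload(v) for k, v in c["ellipses"].items()},
        }
    pmat = artifacts["pvalue_matrix"]
    bv = artifacts["blind_validation"]
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "n_donors": len(artifacts["cohort"]),
        "comparisons": comparisons,
        "pvalue_matrix": {
            "classes": list(pmat.columns),
            "values": [[float(v) for v in row] for row in pmat.to_numpy()],
        },
        "blind_validation": {
            "metrics": bv["metrics"],
            "confusion": {
                "true_negative": bv["confusion"].true_negative,
                "false_positive": bv["confusion"].false_positive,
                "false_negative": bv["confusion"].false_negative,
                "true_positive": bv["confusion"].true_positive,
            },
            "provenance": bv["provenance"],
        },
    }


def make_report(artifacts: dict, out_dir: Path, figures: bool = True) -> Path:
    """Write report.json, the fingerprint CSV and the figures.

    The JSON payload is written with sorted keys and no timestamps so a
    rerun with the same config and seed is byte-identical.
    """
    required = ("config", "cohort", "comparisons", "pvalue_matrix")
    missing = [k for k in required if k not in artifacts]
    if missing:
        raise ValueError(f"missing artifacts: {missing}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    payload = report_payload(artifacts)
    (out_dir / "report.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n"
    )
    artifacts["cohort"].to_frame().to_csv(out_dir / "fingerprints.csv", index=False)
    if "replicate_table" in artifacts:
        artifacts["replicate_table"].to_csv(out_dir / "replicates.csv", index=False)
    if figures:
        _write_figures(artifacts, out_dir)
    return out_dir / "report.json"


def _write_figures(artifacts: dict, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    config: RunConfig = artifacts["config"]
    cohort: Cohort = artifacts["cohort"]
    neg = config.negative_class

    # scatter panels with LDA boundary and ellipses
    comps = artifacts["comparisons"]
    n = len(comps)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    for ax, (pos, c) in zip(axes[0], comps.items()):
        for name, color in ((neg, "tab:blue"), (pos, "tab:orange")):
            pts = cohort.points[cohort.labels == name]
            ax.scatter(pts[:, 0], pts[:, 1], s=18, color=color, label=name)
            ax.scatter(*pts.mean(axis=0), marker="x", s=80, color=color)
            e = c["ellipses"][name]
            ax.add_patch(
                MplEllipse(
                    e.center,
                    2 * e.semi_axes[0],
                    2 * e.semi_axes[1],
                    angle=np.degrees(e.orientation),
                    fill=False,
                    color=color,
                )
            )
        w, t = c["model"].weight_vector, c["model"].threshold
        xs = np.linspace(*ax.get_xlim(), 50)
        if abs(w[1]) > 1e-12:
            ax.plot(xs, (t - w[0] * xs) / w[1], "k-", lw=1)
        else:
            ax.axvline(t / w[0], color="k", lw=1)
        ax.set_xlabel("starting position (mm)")
        ax.set_ylabel("levitating fraction area")
        ax.set_title(pos)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "scatter.png", dpi=120)
    plt.close(fig)

    # boxplots of the two features
    classes = cohort.classes
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, (idx, label) in zip(
        axes, ((0, "starting position (mm)"), (1, "levitating fraction area"))
    ):
        ax.boxplot(
            [cohort.feature(idx, cl) for cl in classes], tick_labels=classes
        )
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(out_dir / "boxplots.png", dpi=120)
    plt.close(fig)

    # p-value heatmap
    pmat = artifacts["pvalue_matrix"]
    fig, ax = plt.subplots(figsize=(5, 4))
    with np.errstate(divide="ignore"):
        logp = np.log10(pmat.to_numpy())
    im = ax.imshow(logp, cmap="viridis")
    ax.set_xticks(range(len(pmat.columns)), pmat.columns, rotation=45)
    ax.set_yticks(range(len(pmat.index)), pmat.index)
    fig.colorbar(im, label="log10 p")
    fig.tight_layout()
    fig.savefig(out_dir / "heatmap.png", dpi=120)
    plt.close(fig)
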