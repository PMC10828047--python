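"""End-to-end experiment orchestration.

One config drives the whole protocol: generate the paired dataset, train
multi- and single-mode seed ensembles, score reconstruction / cross
generation, compute latent metrics, run the arithmetic probe, and compare
the two training modes with Welch tests.  Every stage writes its artifacts
under the output directory and is individually invokable and resumable.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arithmetic import arithmetic_success_rate, build_expression_set
from .classifiers import one_sample_ttest, score_generation, train_classifier
from .datasets import DatasetConfig, PairedDataset, build_paired_dataset
from .latent_metrics import (
    MetricRecord,
    centroid_distance_correlation,
    compare_conditions,
    compute_latents,
    embed_2d,
    silhouette,
)
from .mmvae import MODALITIES, MultimodalModel
from .training import TrainConfig, train_ensemble

__all__ = ["ExperimentConfig", "run_experiment", "make_report", "CHANCE_LEVEL"]

CHANCE_LEVEL = 1.0 / 9.0  # 9 balanced number classes


@dataclass
class ExperimentConfig:
    out_dir: str = "results/experiment"
    seed: int = 0
    n_pairs: int = 2700
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    train_multi: TrainConfig = field(default_factory=lambda: TrainConfig(mode="multi"))
    train_single: TrainConfig = field(default_factory=lambda: TrainConfig(mode="single"))
    classifier_floor: float = 0.95
    expressions_per_answer: int | None = 8
    stimuli_per_expression: int = 5

    # -- round-trip --------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["train_multi"]["seeds"] = list(d["train_multi"]["seeds"])
        d["train_single"]["seeds"] = list(d["train_single"]["seeds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["dataset"] = DatasetConfig(**d.get("dataset", {}))
        for key in ("train_multi", "train_single"):
            sub = d.get(key, {})
            if "seeds" in sub:
                sub["seeds"] = tuple(sub["seeds"])
            d[key] = TrainConfig(**sub)
        return cls(**d)


def _out(config: ExperimentConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# --------------------------------------------------------------------------
# stages


def stage_generate(config: ExperimentConfig) -> PairedDataset:
    out = _out(config) / "dataset"
    if (out / "labels.tsv").exists():
        return PairedDataset.load(out, config.dataset)
    ds = build_paired_dataset(config.n_pairs, seed=config.seed, config=config.dataset)
    ds.save(out)
    return ds


def stage_train(config: ExperimentConfig, dataset: PairedDataset, verbose: bool = False):
    ck = _out(config) / "checkpoints"
    multi = train_ensemble(config.train_multi, dataset, out_dir=ck, verbose=verbose)
    single = train_ensemble(config.train_single, dataset, out_dir=ck, verbose=verbose)
    return multi, single


def _classifiers(config: ExperimentConfig, dataset: PairedDataset):
    return {
        m: train_classifier(dataset, m, "number", seed=config.seed, floor=config.classifier_floor)
        for m in MODALITIES
    }


def stage_eval_generation(config, dataset, multi, single, clfs) -> pd.DataFrame:
    """Classifier-scored accuracies for recon (both modes) and cross (multi)."""
    rows = []
    for ens, mode in ((multi, "multi"), (single, "single")):
        for seed, model, _ in ens.members:
            for m in MODALITIES:
                other = "cmnist" if m == "oscn" else "oscn"
                rec = score_generation(model, clfs[m], "recon", m, dataset)
                row = dict(seed=seed, mode=mode, modality=m, recon_accuracy=rec.mean_accuracy)
                if mode == "multi":
                    cro = score_generation(model, clfs[other], "cross", m, dataset)
                    row["cross_accuracy"] = cro.mean_accuracy
                    np.savetxt(
                        _out(config) / f"confusion_recon_{m}_seed{seed}.tsv",
                        rec.confusion.counts, fmt="%d", delimiter="\t",
                    )
                    np.savetxt(
                        _out(config) / f"confusion_cross_{m}to{other}_seed{seed}.tsv",
                        cro.confusion.counts, fmt="%d", delimiter="\t",
                    )
                rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(_out(config) / "generation_scores.tsv", sep="\t", index=False)
    return df


def stage_eval_latent(config, dataset, multi, single) -> pd.DataFrame:
    rows = []
    for ens, mode in ((multi, "multi"), (single, "single")):
        for seed, model, _ in ens.members:
            for m in MODALITIES:
                lab = compute_latents(model, m, dataset, split="test")
                rec = MetricRecord(seed=seed, mode=mode, modality=m)

                def safe_sil(factor):
                    y = lab.factor(factor)
                    _, counts = np.unique(y, return_counts=True)
                    if len(counts) < 2 or counts.min() < 2:
                        return float("nan")  # factor not evaluable at this split size
                    return silhouette(lab, factor)

                rec.silhouette_number = safe_sil("number")
                rec.silhouette_color = safe_sil("color")
                if m == "oscn":
                    rec.silhouette_shape = safe_sil("shape")
                rec.centroid_corr_linear = centroid_distance_correlation(lab, "linear")
                rec.centroid_corr_log = centroid_distance_correlation(lab, "log")
                rows.append(asdict(rec))
    df = pd.DataFrame(rows)
    df.to_csv(_out(config) / "latent_metrics.tsv", sep="\t", index=False)
    return df


def stage_eval_arithmetic(config, dataset, multi, single, clfs) -> pd.DataFrame:
    exprs = build_expression_set(n_per_answer=config.expressions_per_answer, seed=config.seed)
    rows = []
    for ens, mode in ((multi, "multi"), (single, "single")):
        for seed, model, _ in ens.members:
            for m in MODALITIES:
                rng = np.random.default_rng(config.seed * 1000 + seed)
                score = arithmetic_success_rate(
                    model, clfs[m], exprs, dataset, m,
                    stimuli_per_expression=config.stimuli_per_expression, rng=rng,
                )
                rows.append(dict(seed=seed, mode=mode, modality=m, arithmetic_success=score.rate))
                if mode == "multi":
                    np.savetxt(
                        _out(config) / f"confusion_arithmetic_{m}_seed{seed}.tsv",
                        score.confusion.counts, fmt="%d", delimiter="\t",
                    )
    df = pd.DataFrame(rows)
    df.to_csv(_out(config) / "arithmetic_scores.tsv", sep="\t", index=False)
    return df


def stage_stats(config, gen_df, lat_df, arith_df) -> dict:
    """Chance-level t-tests plus multi-vs-single Welch comparisons."""
    stats: dict = {"chance_level": CHANCE_LEVEL, "tests": []}

    def chance_test(name, values):
        if len(values) >= 2:
            r = one_sample_ttest(values, CHANCE_LEVEL)
            stats["tests"].append(
                dict(name=name, kind="one_sample_vs_chance", t=r.t, df=r.df, p=r.p,
                     mean=float(np.mean(values)))
            )

    def welch(name, a, b):
        if len(a) >= 2 and len(b) >= 2:
            r = compare_conditions(a, b)
            stats["tests"].append(
                dict(name=name, kind="welch_multi_vs_single", t=r.t, df=r.df, p=r.p,
                     mean_multi=r.mean_a, mean_single=r.mean_b)
            )

    for m in MODALITIES:
        gm = gen_df[(gen_df["mode"] == "multi") & (gen_df["modality"] == m)]
        chance_test(f"recon_{m}_vs_chance", gm["recon_accuracy"].to_numpy())
        if "cross_accuracy" in gm:
            chance_test(f"cross_from_{m}_vs_chance", gm["cross_accuracy"].dropna().to_numpy())
        for col in ("silhouette_number", "centroid_corr_linear"):
            a = lat_df[(lat_df["mode"] == "multi") & (lat_df["modality"] == m)][col].to_numpy()
            b = lat_df[(lat_df["mode"] == "single") & (lat_df["modality"] == m)][col].to_numpy()
            welch(f"{col}_{m}", a, b)
        a = arith_df[(arith_df["mode"] == "multi") & (arith_df["modality"] == m)][
            "arithmetic_success"].to_numpy()
        b = arith_df[(arith_df["mode"] == "single") & (arith_df["modality"] == m)][
            "arithmetic_success"].to_numpy()
        chance_test(f"arithmetic_{m}_vs_chance", a)
        welch(f"arithmetic_success_{m}", a, b)
    (_out(config) / "stats.json").write_text(json.dumps(stats, indent=2))
    return stats


def run_experiment(config: ExperimentConfig, verbose: bool = False) -> dict:
    """Run the full protocol; returns the stats summary.

    Stage order: generate -> train -> eval-generation -> eval-latent ->
    eval-arithmetic -> stats.  A stage failure is re-raised with the stage
    name attached.
    """
    out = _out(config)
    config.to_yaml(out / "config.yaml")
    timings = {}
    artifacts = {}

    def run(name, fn, *args, **kw):
        t0 = time.time()
        try:
            res = fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"experiment stage {name!r} failed") from exc
        timings[name] = round(time.time() - t0, 2)
        return res

    dataset = run("generate", stage_generate, config)
    multi, single = run("train", stage_train, config, dataset, verbose)
    clfs = run("classifiers", _classifiers, config, dataset)
    gen_df = run("eval_generation", stage_eval_generation, config, dataset, multi, single, clfs)
    lat_df = run("eval_latent", stage_eval_latent, config, dataset, multi, single)
    arith_df = run("eval_arithmetic", stage_eval_arithmetic, config, dataset, multi, single, clfs)
    stats = run("stats", stage_stats, config, gen_df, lat_df, arith_df)

    # merged per-seed metric table
    merged = lat_df.merge(gen_df, on=["seed", "mode", "modality"], how="left", suffixes=("", "_g"))
    merged = merged.drop(columns=[c for c in ("recon_accuracy_g", "cross_accuracy_g") if c in merged])
    for c in ("recon_accuracy", "cross_accuracy"):
        if c in gen_df.columns and c in merged.columns:
            merged[c] = gen_df.set_index(["seed", "mode", "modality"]).reindex(
                merged.set_index(["seed", "mode", "modality"]).index)[c].to_numpy()
    merged["arithmetic_success"] = arith_df.set_index(["seed", "mode", "modality"]).reindex(
        merged.set_index(["seed", "mode", "modality"]).index)["arithmetic_success"].to_numpy()
    merged.to_csv(out / "metrics.tsv", sep="\t", index=False)
    (out / "timings.json").write_text(json.dumps(timings, indent=2))
    artifacts["stats"] = stats
    artifacts["metrics"] = merged
    return artifacts


# --------------------------------------------------------------------------
# report


def make_report(results_dir: str | Path) -> list[Path]:
    """Figures from a finished (or partial) experiment directory.

    Produces confusion heatmaps, bar charts of silhouettes / correlations /
    arithmetic success with per-seed points, and t-SNE panels when
    checkpoints are present.  Missing stages are noted and skipped.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = Path(results_dir)
    figdir = res / "figures"
    figdir.mkdir(exist_ok=True)
    written: list[Path] = []
    notes: list[str] = []

    for tsv in sorted(res.glob("confusion_*.tsv")):
        counts = np.loadtxt(tsv, delimiter="\t")
        fig, ax = plt.subplots(figsize=(4, 3.5))
        row_sums = counts.sum(axis=1, keepdims=True)
        frac = np.divide(counts, row_sums, out=np.zeros_like(counts, dtype=float), where=row_sums > 0)
        im = ax.imshow(frac, cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks(range(9), [str(i) for i in range(1, 10)])
        ax.set_yticks(range(9), [str(i) for i in range(1, 10)])
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(tsv.stem.replace("confusion_", ""), fontsize=9)
        fig.colorbar(im, ax=ax)
        p = figdir / f"{tsv.stem}.png"
        fig.savefig(p, dpi=110, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    metrics_path = res / "metrics.tsv"
    if metrics_path.exists():
        df = pd.read_csv(metrics_path, sep="\t")
        for col in ("silhouette_number", "centroid_corr_linear", "arithmetic_success",
                    "recon_accuracy"):
            if col not in df.columns:
                continue
            fig, ax = plt.subplots(figsize=(4.5, 3))
            xticks, xlabels = [], []
            for i, (m, mode) in enumerate(
                [(m, md) for m in ("oscn", "cmnist") for md in ("multi", "single")]
            ):
                vals = df[(df["modality"] == m) & (df["mode"] == mode)][col].dropna()
                if len(vals) == 0:
                    continue
                ax.bar(i, vals.mean(), color="tab:blue" if mode == "multi" else "tab:orange",
                       alpha=0.7)
                ax.scatter(np.full(len(vals), i), vals, color="k", s=12, zorder=3)
                xticks.append(i)
                xlabels.append(f"{m}\n{mode}")
            ax.set_xticks(xticks, xlabels, fontsize=8)
            ax.set_ylabel(col)
            if col in ("arithmetic_success", "recon_accuracy"):
                ax.axhline(CHANCE_LEVEL, color="r", ls="--", lw=1, label="chance 1/9")
                ax.legend(fontsize=8)
            p = figdir / f"bars_{col}.png"
            fig.savefig(p, dpi=110, bbox_inches="tight")
            plt.close(fig)
            written.append(p)
    else:
        notes.append("metrics.tsv missing: latent/arithmetic stages not run")

    # t-SNE panels from the first multi checkpoint, if data + checkpoints exist
    ck = sorted((res / "checkpoints").glob("multi_seed*.npz")) if (res / "checkpoints").exists() else []
    if ck and (res / "dataset" / "labels.tsv").exists():
        from .latent_metrics import compute_latents as _cl

        model = MultimodalModel.load(ck[0])
        ds = PairedDataset.load(res / "dataset")
        for m in MODALITIES:
            lab = _cl(model, m, ds, split="test")
            if len(lab.z) >= 35:
                xy = embed_2d(lab.z, seed=0, perplexity=min(30.0, (len(lab.z) - 1) / 3))
                factors = ["number", "color"] + (["shape"] if m == "oscn" else [])
                fig, axes = plt.subplots(1, len(factors), figsize=(4 * len(factors), 3.5))
                axes = np.atleast_1d(axes)
                for ax, fct in zip(axes, factors):
                    y = lab.factor(fct)
                    for v in np.unique(y):
                        pts = xy[y == v]
                        ax.scatter(pts[:, 0], pts[:, 1], s=8, label=str(v))
                    ax.set_title(f"{m}: colored by {fct}", fontsize=9)
                    ax.legend(fontsize=6, markerscale=0.8)
                p = figdir / f"tsne_{m}.png"
                fig.savefig(p, dpi=110, bbox_inches="tight")
                plt.close(fig)
                written.append(p)
    else:
        notes.append("checkpoints or dataset missing: t-SNE panels skipped")

    stats_path = res / "stats.json"
    summary_lines = ["# Report summary", ""]
    if stats_path.exists():
        stats = json.loads(stats_path.read_text())
        for t in stats.get("tests", []):
            summary_lines.append(
                f"- {t['name']} ({t['kind']}): t={t['t']:.3f}, df={t['df']:.2f}, p={t['p']:.4g}"
            )
    else:
        notes.append("stats.json missing: no statistical summary")
    if notes:
        summary_lines += ["", "## Missing stages"] + [f"- {n}" for n in notes]
    (res / "report_summary.md").write_text("\n".join(summary_lines) + "\n")
    written.append(res / "report_summary.md")
    return written
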