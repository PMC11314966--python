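"""End-to-end experiment orchestration.

An :class:`ExperimentSpec` resolves an input source (a directory of
one-column ASCII records, a list of EDF channels, or a synthetic
recipe), preprocessing parameters, a training configuration, similarity
weights, and seeded repetitions.  :func:`run_experiment` runs
preprocess -> train -> cluster -> evaluate, freezing the resolved
configuration and all artifacts under a run directory;
:func:`ablate_similarity` re-clusters one trained model under several
weight modes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import synthetic
from .clustering import SimilarityWeights, cluster_dataset
from .io import read_signal_ascii, read_signal_edf
from .metrics import ari, contingency, nmi, purity
from .model import save_checkpoint
from .preprocess import SegmentationConfig, bandpass_filter, cwt_scalogram, segment_signal
from .training import TrainConfig, train

__all__ = ["ExperimentSpec", "run_experiment", "ablate_similarity",
           "iteration_sweep", "preprocess_records", "load_records"]

#: weight modes used in the similarity ablation
ABLATION_MODES = {
    "latent": SimilarityWeights(1.0, 0.0, 0.0),
    "latent+image": SimilarityWeights(0.5, 0.5, 0.0),
    "compositive": SimilarityWeights(1 / 3, 1 / 3, 1 / 3),
}


@dataclass
class ExperimentSpec:
    """Everything needed to reproduce one clustering experiment."""

    name: str = "experiment"
    source: dict = field(default_factory=lambda: {"kind": "synthetic"})
    n_clusters: int = 3
    fs: float = 173.61
    band: tuple = (0.5, 40.0)
    window_s: float = 2.88
    overlap_frac: float = 0.5
    image_size: int = 64
    width_scale: float = 1.0
    train: TrainConfig = field(default_factory=TrainConfig)
    weights: SimilarityWeights = field(default_factory=SimilarityWeights)
    repetitions: int = 1
    base_seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.repetitions < 1:
            raise ValueError("need at least 1 repetition")

    @classmethod
    def from_file(cls, path) -> "ExperimentSpec":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        if "train" in data:
            data["train"] = TrainConfig(**data["train"])
        if "weights" in data:
            data["weights"] = SimilarityWeights(*data["weights"])
        if "band" in data:
            data["band"] = tuple(data["band"])
        return cls(**data)

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        out["train"]["adam_betas"] = list(out["train"]["adam_betas"])
        return out


def load_records(spec: ExperimentSpec):
    """Resolve the input source into labeled signal records."""
    src = dict(spec.source)
    kind = src.pop("kind", "synthetic")
    if kind == "synthetic":
        return synthetic.generate_dataset(
            ratios=tuple(src.get("ratios", (2, 2, 1))),
            n_total=int(src.get("n_total", 300)),
            fs=spec.fs,
            duration=float(src.get("duration", spec.window_s)),
            seed=int(src.get("seed", spec.base_seed)),
        )
    if kind == "ascii_dir":
        root = Path(src["path"])
        labels = {}
        labels_csv = root / src.get("labels_csv", "labels.csv")
        if labels_csv.exists():
            import pandas as pd

            for row in pd.read_csv(labels_csv).itertuples():
                labels[row.file] = str(row.label) if str(row.label) != "nan" else None
        files = sorted(root.glob(src.get("pattern", "*.txt")))
        if not files:
            raise FileNotFoundError(f"no ASCII records under {root}")
        return [
            read_signal_ascii(f, fs=spec.fs, label=labels.get(f.name)) for f in files
        ]
    if kind == "edf":
        return [
            read_signal_edf(item["path"], item["channel"], label=item.get("label"))
            for item in src["files"]
        ]
    raise ValueError(f"unknown input source kind {kind!r}")


def preprocess_records(records, spec: ExperimentSpec):
    """Filter, segment and render scalograms; labels ride along."""
    cfg = SegmentationConfig(spec.window_s, spec.overlap_frac)
    scalograms = []
    for rec in records:
        filtered = bandpass_filter(rec, *spec.band)
        for seg in segment_signal(filtered, cfg):
            scalograms.append(
                cwt_scalogram(seg, *spec.band, out_size=spec.image_size)
            )
    return scalograms


def _evaluate(labels, assignments):
    t = contingency(labels, assignments)
    return {"purity": purity(t), "ari": ari(t), "nmi": nmi(t)}


def _stage(name):
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _ctx()


class _StageError(RuntimeError):
    pass


def run_experiment(spec: ExperimentSpec, outdir, progress: bool = False):
    """Preprocess, train, cluster, and (with labels) evaluate.

    One model is trained per repetition with seed ``base_seed + r``; the
    per-repetition indexes plus mean +/- sd land in ``report.csv`` and
    ``summary.json`` under ``outdir``.  Returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(spec.to_jsonable(), indent=2))

    with _stage("preprocess"):
        records = load_records(spec)
        scalograms = preprocess_records(records, spec)
    labels = [s.label for s in scalograms]
    have_labels = all(lbl is not None for lbl in labels)

    rows = []
    for rep in range(spec.repetitions):
        seed = spec.base_seed + rep
        cfg = dataclasses.replace(spec.train, seed=seed)
        with _stage(f"train[rep{rep}]"):
            bundle, gmm, report = train(
                scalograms,
                cfg,
                n_components=spec.n_clusters,
                image_size=spec.image_size,
                width_scale=spec.width_scale,
                progress=progress,
            )
            report.save_csv(outdir / f"losses_rep{rep}.csv")
            save_checkpoint(outdir / f"model_rep{rep}.npz", bundle, gmm)
        with _stage(f"cluster[rep{rep}]"):
            assignments, probs, results = cluster_dataset(
                scalograms, bundle, gmm, spec.weights
            )
            _write_assignments(
                outdir / f"assignments_rep{rep}.csv", scalograms, assignments,
                probs, results,
            )
        row = {"group": spec.name, "rep": rep, "seed": seed}
        if have_labels:
            with _stage(f"evaluate[rep{rep}]"):
                row.update(_evaluate(labels, assignments))
        row["p"] = np.round(gmm.p, 4).tolist()
        sizes = np.bincount(assignments, minlength=spec.n_clusters + 1)[1:]
        row["cluster_sizes"] = sizes.tolist()
        rows.append(row)

    summary = _summarize(spec, rows, have_labels)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    _write_report_csv(outdir / "report.csv", rows, have_labels)
    return summary


def ablate_similarity(spec: ExperimentSpec, outdir, modes=None,
                      progress: bool = False):
    """Cluster one trained model per repetition under several weight modes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    modes = {k: ABLATION_MODES[k] for k in (modes or ABLATION_MODES)}
    with _stage("preprocess"):
        records = load_records(spec)
        scalograms = preprocess_records(records, spec)
    labels = [s.label for s in scalograms]
    have_labels = all(lbl is not None for lbl in labels)

    rows = []
    for rep in range(spec.repetitions):
        seed = spec.base_seed + rep
        cfg = dataclasses.replace(spec.train, seed=seed)
        with _stage(f"train[rep{rep}]"):
            bundle, gmm, _ = train(
                scalograms, cfg, n_components=spec.n_clusters,
                image_size=spec.image_size, width_scale=spec.width_scale,
                progress=progress,
            )
        for mode, w in modes.items():
            with _stage(f"cluster[{mode},rep{rep}]"):
                assignments, _, _ = cluster_dataset(scalograms, bundle, gmm, w)
            row = {"group": spec.name, "mode": mode, "rep": rep, "seed": seed}
            if have_labels:
                row.update(_evaluate(labels, assignments))
            rows.append(row)
    import pandas as pd

    df = pd.DataFrame(rows)
    df.to_csv(outdir / "ablation.csv", index=False)
    return df


def _summarize(spec, rows, have_labels):
    summary = {"group": spec.name, "repetitions": rows}
    if have_labels:
        for key in ("purity", "ari", "nmi"):
            vals = np.array([r[key] for r in rows], dtype=float)
            summary[key] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
    return summary


def _write_report_csv(path, rows, have_labels):
    import pandas as pd

    df = pd.DataFrame(
        [{k: v for k, v in r.items() if k not in ("p", "cluster_sizes")}
         for r in rows]
    )
    if have_labels and len(df) > 1:
        means = df[["purity", "ari", "nmi"]].mean()
        sds = df[["purity", "ari", "nmi"]].std(ddof=1)
        extra = {"group": "mean+/-sd", "rep": "", "seed": ""}
        extra.update(
            {k: f"{means[k]:.4f}+/-{sds[k]:.4f}" for k in ("purity", "ari", "nmi")}
        )
        df = pd.concat([df, pd.DataFrame([extra])], ignore_index=True)
    df.to_csv(path, index=False)


def _write_assignments(path, scalograms, assignments, probs, results):
    """Per-item CSV: probabilities plus raw and combined per-level scores."""
    with open(path, "w") as fh:
        n = probs.shape[1]
        cols = [f"prob{k + 1}" for k in range(n)]
        for level in ("latent", "image", "dfm", "com"):
            cols += [f"s_{level}{k + 1}" for k in range(n)]
        fh.write("item,label,cluster," + ",".join(cols) + "\n")
        for s, a, p, r in zip(scalograms, assignments, probs, results):
            values = list(p) + list(r.s_latent) + list(r.s_image) + \
                list(r.s_dfm) + list(r.s_com)
            txt = ",".join(f"{x:.6g}" for x in values)
            fh.write(f"{s.meta},{s.label or ''},{a},{txt}\n")


def iteration_sweep(spec: ExperimentSpec, outdir, every: int,
                    progress: bool = False):
    """Cluster and score checkpoints taken every ``every`` iterations.

    Trains once (single repetition at ``base_seed``), snapshotting the
    model on a regular grid, then evaluates each snapshot with the
    configured similarity weights.  Returns a DataFrame (also written to
    ``sweep.csv``) tracking the indexes against training progress.
    """
    from .model import load_checkpoint

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with _stage("preprocess"):
        records = load_records(spec)
        scalograms = preprocess_records(records, spec)
    labels = [s.label for s in scalograms]
    have_labels = all(lbl is not None for lbl in labels)
    cfg = dataclasses.replace(spec.train, seed=spec.base_seed)
    ckpt_dir = outdir / "checkpoints"
    with _stage("train"):
        train(
            scalograms, cfg, n_components=spec.n_clusters,
            image_size=spec.image_size, width_scale=spec.width_scale,
            checkpoint_dir=ckpt_dir, checkpoint_every=every,
            progress=progress,
        )
    rows = []
    for ckpt in sorted(ckpt_dir.glob("checkpoint_*.npz")):
        step = int(ckpt.stem.split("_")[1])
        bundle, gmm = load_checkpoint(ckpt)
        assignments, _, _ = cluster_dataset(scalograms, bundle, gmm,
                                            spec.weights)
        row = {"iteration": step}
        if have_labels:
            row.update(_evaluate(labels, assignments))
        rows.append(row)
    import pandas as pd

    df = pd.DataFrame(rows)
    df.to_csv(outdir / "sweep.csv", index=False)
    return df
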