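"""End-to-end experiment orchestration.

Runs generate -> detect/extract -> select (four algorithms, perturbation
voting) -> accuracy-vs-k curves -> classification at fixed subset sizes ->
t-SNE projections, and emits a machine-readable JSON report plus a
human-readable summary table (four ranking columns with the classification
accuracy of each method's selected subset).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import RFParams, SVMParams, accuracy_vs_k, cross_validate
from .embedding import scatter_plot, tsne_project
from .features import build_design_matrix
from .selection import METHODS, stability_protocol
from .spectral import SpectrogramConfig
from .synth import generate_corpus

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    # generator block
    n_per_class: int = 25
    seed: int = 42
    snr_db: float = 20.0
    # spectrogram block
    spectrogram: SpectrogramConfig = field(default_factory=SpectrogramConfig)
    # selection block
    methods: tuple[str, ...] = METHODS
    selection_runs: int = 100
    k_max: int = 15
    # classification block
    model: str = "rf"
    folds: int = 10
    repetitions: int = 10
    n_trees: int = 500
    mtry: int | None = None
    report_k: tuple[int, ...] = (8, 15)
    # embedding block
    perplexity: float = 30.0
    # output
    out_dir: str = "usvkit_experiment"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        spec_cfg = SpectrogramConfig(**data.pop("spectrogram", {}))
        for key in ("methods", "report_k"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(spectrogram=spec_cfg, **data)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _config_hash(cfg: ExperimentConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the full pipeline per the config; returns the report dict.

    Writes ``report.json``, ``summary.txt``, the feature table CSV, t-SNE
    coordinate CSVs and scatter plots into ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    logger.info("stage generate: %d calls/class, seed %d", cfg.n_per_class, cfg.seed)
    corpus = generate_corpus(cfg.n_per_class, cfg.seed, snr_db=cfg.snr_db)

    logger.info("stage extract: %d calls", len(corpus))
    dm = build_design_matrix(corpus, cfg.spectrogram)
    dm.to_csv(out / "features.csv")

    model_spec = (
        RFParams(n_trees=cfg.n_trees, n_candidate_features=cfg.mtry)
        if cfg.model == "rf"
        else SVMParams()
    )

    report: dict = {
        "provenance": {
            "config": cfg.to_dict(),
            "config_hash": _config_hash(cfg),
            "version": __version__,
            "n_calls": len(corpus),
        },
        "rankings": {},
        "accuracy_vs_k": {},
        "accuracy_at_k": {},
    }

    ss = np.random.SeedSequence(cfg.seed)
    method_seeds = {m: s for m, s in zip(cfg.methods, ss.spawn(len(cfg.methods)))}
    rankings = {}
    for method in cfg.methods:
        logger.info("stage select: %s x %d runs", method, cfg.selection_runs)
        rng = np.random.default_rng(method_seeds[method])
        rk = stability_protocol(dm.X, dm.y, method, runs=cfg.selection_runs, rng=rng)
        rk.feature_names = [dm.feature_names[i] for i in rk.order]
        rankings[method] = rk
        report["rankings"][method] = rk.feature_names[: cfg.k_max]

        curve = accuracy_vs_k(
            dm.X,
            dm.y,
            rk,
            k_max=cfg.k_max,
            model_spec=model_spec,
            folds=cfg.folds,
            repetitions=cfg.repetitions,
            seed=cfg.seed,
        )
        report["accuracy_vs_k"][method] = [
            {"k": k, "mean": m, "sd": s} for k, m, s in curve
        ]

        report["accuracy_at_k"][method] = {}
        for k in cfg.report_k:
            res = cross_validate(
                dm.X[:, rk.top(k)],
                dm.y,
                model_spec,
                folds=cfg.folds,
                repetitions=cfg.repetitions,
                seed=cfg.seed,
            )
            report["accuracy_at_k"][method][str(k)] = res.to_dict()
            logger.info(
                "%s k=%d: %.3f +/- %.3f", method, k, res.mean, res.sd
            )

    # t-SNE on the full feature space and on the top-8 SIMBA subset
    for tag, X in {
        "all_features": dm.X,
        "top8_simba": dm.X[:, rankings.get("simba", rankings[cfg.methods[0]]).top(8)],
    }.items():
        try:
            emb = tsne_project(X, perplexity=cfg.perplexity, seed=cfg.seed)
        except ValueError as exc:  # corpus smaller than 3 x perplexity
            logger.warning("skipping t-SNE (%s): %s", tag, exc)
            continue
        coords_path = out / f"tsne_{tag}.csv"
        with open(coords_path, "w") as fh:
            fh.write("call_id,x,y,label\n")
            for cid, (x, ycoord), lab in zip(dm.call_ids, emb.coords, dm.y):
                fh.write(f"{cid},{x:.6f},{ycoord:.6f},{lab}\n")
        scatter_plot(emb, dm.y, out / f"tsne_{tag}.png")

    report["elapsed_s"] = round(time.time() - t0, 1)
    (out / "report.json").write_text(
        json.dumps({k: v for k, v in report.items() if k != "elapsed_s"}, indent=1)
    )
    (out / "summary.txt").write_text(_summary_table(report, cfg))
    return report


def _summary_table(report: dict, cfg: ExperimentConfig) -> str:
    """Four ranking columns plus an accuracy row, one line per rank step."""
    methods = list(cfg.methods)
    width = 28
    lines = ["".join(m.ljust(width) for m in methods)]
    for i in range(cfg.k_max):
        row = []
        for m in methods:
            names = report["rankings"][m]
            row.append((names[i] if i < len(names) else "").ljust(width))
        lines.append("".join(row))
    accs = []
    k = str(max(cfg.report_k))
    for m in methods:
        r = report["accuracy_at_k"][m][k]
        accs.append(f"{100 * r['mean']:.1f} +/- {100 * r['sd']:.1f}".ljust(width))
    lines.append("".join(accs))
    return "\n".join(lines) + "\n"
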