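"""End-to-end orchestration: simulate -> quantify -> differential screen ->
classifier bench -> 3-class net -> clinical association -> cross-reactivity.

A single declarative :class:`RunConfig` (YAML/JSON-friendly) drives a run;
all stage defaults equal the published analysis values (P < 0.05, FC >= 2,
AUC gate 0.96, top-10 consensus from >= 2 models, 5-fold binary CV, 3-fold
net CV, lr 0.001, 150 epochs, batch 16, cross-reactivity rho > 0.5).  All
randomness flows from one master seed through named per-stage substreams
(crc32 of the stage name), so stages are independently reproducible and an
identical config + seed reproduces byte-identical artifacts.  The manifest
records per-stage parameters, seeds and output-file SHA-256 hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from zlib import crc32

import pandas as pd

from .align import crossreact_screen, read_fasta, write_fasta
from .bench import ClassifierBench
from .clinical import TraitAssociation, adjusted_regression
from .net import DementiaNet, NetConfig
from .quantify import build_au_matrix
from .screen import DifferentialScreen
from .simulate import SimConfig, generate_cohort, generate_sequences, write_fluorescence_tsv

__all__ = ["RunConfig", "run_all", "stage_seed", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "diff", "bench", "net", "clinical", "crossreact")


def stage_seed(master_seed: int, stage: str) -> int:
    """Named substream: deterministic per-stage seed below 2**31."""
    return (int(master_seed) + crc32(stage.encode())) % 2**31


@dataclass
class RunConfig:
    """Declarative pipeline configuration (defaults = the published values)."""

    seed: int = 0
    stages: tuple = STAGES
    sim: dict = field(default_factory=dict)  # overrides for SimConfig
    fluorescence_tsv: str | None = None  # user-supplied inputs instead of simulate
    subjects_csv: str | None = None
    sequences_fasta: str | None = None
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    bench_folds: int = 5
    net_folds: int = 3
    auc_gate: float = 0.96
    top_k: int = 10
    min_models: int = 2
    tune_budget: int = 0
    epochs: int = 150
    learning_rate: float = 0.001
    batch_size: int = 16
    hidden: tuple = (8, 4)
    r_threshold: float = 0.5

    _SIM_KEYS = frozenset(f.name for f in dataclasses.fields(SimConfig)) - {"trait_model"}

    def __post_init__(self):
        self.stages = tuple(self.stages)
        self.hidden = tuple(self.hidden)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        bad = set(self.sim) - self._SIM_KEYS
        if bad:
            raise ValueError(f"unknown sim keys: {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["hidden"] = list(self.hidden)
        return d

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=stage_seed(self.seed, "simulate"), **self.sim)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, outdir) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    Every output file is named in the manifest with its SHA-256.  A stage
    failure raises, naming the stage; artifacts from completed stages are
    retained in ``outdir``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": config.to_dict(), "stages": {}}
    ctx: dict = {}

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "params": params,
            "outputs": {p.name: _sha256(p) for p in files},
        }
        log.info("stage=%s seed=%d params=%s", stage, stage_seed(config.seed, stage), params)

    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            files = _run_stage(stage, config, out, ctx)
        except Exception as exc:
            _write_manifest(manifest, out)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        record(stage, _stage_params(stage, config), files)

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _stage_params(stage: str, c: RunConfig) -> dict:
    return {
        "simulate": dict(c.sim),
        "quantify": {},
        "diff": {"p_threshold": c.p_threshold, "fc_threshold": c.fc_threshold},
        "bench": {"folds": c.bench_folds, "auc_gate": c.auc_gate, "top_k": c.top_k,
                  "min_models": c.min_models, "tune_budget": c.tune_budget},
        "net": {"folds": c.net_folds, "epochs": c.epochs, "lr": c.learning_rate,
                "batch": c.batch_size, "hidden": list(c.hidden)},
        "clinical": {},
        "crossreact": {"r_threshold": c.r_threshold},
    }[stage]


def _run_stage(stage: str, c: RunConfig, out: Path, ctx: dict) -> list[Path]:
    if stage == "simulate":
        fluor, subjects, truth = generate_cohort(c.sim_config())
        seqs = generate_sequences(truth.latent_au.columns,
                                  seed=stage_seed(c.seed, "sequences"))
        write_fluorescence_tsv(fluor, out / "fluorescence.tsv")
        subjects.to_csv(out / "subjects.csv", index=False)
        truth.to_json(out / "truth.json")
        write_fasta(seqs, out / "sequences.fasta")
        ctx.update(fluorescence=fluor, subjects=subjects, truth=truth,
                   sequences={r.id: str(r.seq) for r in seqs})
        return [out / n for n in ("fluorescence.tsv", "subjects.csv", "truth.json",
                                  "sequences.fasta")]

    if stage == "quantify":
        fluor = ctx.get("fluorescence")
        if fluor is None:
            from .simulate import read_fluorescence_tsv

            fluor = read_fluorescence_tsv(c.fluorescence_tsv)
        au = build_au_matrix(fluor)
        au.to_csv(out / "au_matrix.csv")
        au.sal_to_csv(out / "sal.csv")
        ctx["au"] = au
        return [out / "au_matrix.csv", out / "sal.csv"]

    subjects = ctx.get("subjects")
    if subjects is None and c.subjects_csv:
        subjects = pd.read_csv(c.subjects_csv)
        ctx["subjects"] = subjects
    diagnosis = pd.Series(subjects["diagnosis"].to_numpy(),
                          index=subjects["subject_id"].to_numpy())

    if stage == "diff":
        res = DifferentialScreen(ctx["au"], diagnosis, c.p_threshold, c.fc_threshold).fit()
        res.to_csv(out / "differential_table.csv")
        res.volcano("AD").to_csv(out / "volcano_ad.csv", index_label="antigen_id")
        res.volcano("DLB").to_csv(out / "volcano_dlb.csv", index_label="antigen_id")
        (out / "selected_antigens.txt").write_text("\n".join(res.selected_union) + "\n")
        files = [out / n for n in ("differential_table.csv", "volcano_ad.csv",
                                   "volcano_dlb.csv", "selected_antigens.txt")]
        if res.selected_union:
            scores, evr, _ = res.pca()
            scores.assign(diagnosis=diagnosis.reindex(scores.index)).to_csv(
                out / "pca_scores.csv", index_label="subject_id")
            files.append(out / "pca_scores.csv")
        ctx["screen"] = res
        return files

    selected = ctx["screen"].selected_union if "screen" in ctx else list(ctx["au"].antigens)
    panel = selected or list(ctx["au"].antigens)

    if stage == "bench":
        bench = ClassifierBench.from_diagnosis(ctx["au"].values, diagnosis,
                                               case="AD", features=panel)
        res = bench.fit(k=c.bench_folds, seed=stage_seed(c.seed, "bench"),
                        tune_budget=c.tune_budget)
        res.summary().to_csv(out / "bench_table.csv", index_label="model")
        res.importances_frame().to_csv(out / "importances.csv", index_label="feature")
        consensus = res.consensus(c.auc_gate, c.top_k, c.min_models)
        with open(out / "consensus.json", "w") as fh:
            json.dump(consensus.to_dict(), fh, indent=2, sort_keys=True)
        ctx["bench"] = res
        ctx["consensus"] = consensus
        return [out / n for n in ("bench_table.csv", "importances.csv", "consensus.json")]

    # features highlighted by the consensus; fall back to the best model's
    # top-k when no model clears the gate
    highlighted = None
    if "consensus" in ctx and ctx["consensus"].selected:
        highlighted = ctx["consensus"].selected
    elif "bench" in ctx:
        imp = ctx["bench"].best.importances
        highlighted = list(imp.sort_values(ascending=False, kind="stable").index[: c.top_k])
    if not highlighted:
        highlighted = panel[: c.top_k]

    if stage == "net":
        X = ctx["au"].values[panel]
        cfg = NetConfig(input_dim=len(panel), hidden=c.hidden, epochs=c.epochs,
                        learning_rate=c.learning_rate, batch_size=c.batch_size,
                        seed=stage_seed(c.seed, "net"))
        report = DementiaNet(X, diagnosis.to_numpy(), cfg).fit(
            k=c.net_folds, seed=stage_seed(c.seed, "net"))
        report.loss_curves.to_csv(out / "net_loss_curves.csv", index=False)
        pd.DataFrame(report.confusion,
                     index=[f"true_{n}" for n in ("CNI", "AD", "DLB")],
                     columns=[f"pred_{n}" for n in ("CNI", "AD", "DLB")],
                     ).to_csv(out / "net_confusion.csv")
        with open(out / "net_class_metrics.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        ctx["net"] = report
        return [out / n for n in ("net_loss_curves.csv", "net_confusion.csv",
                                  "net_class_metrics.json")]

    if stage == "clinical":
        X = ctx["au"].values[highlighted]
        assoc = TraitAssociation(X, subjects).fit()
        assoc.to_csv(str(out / "assoc"))
        reg_rows = []
        for ab in highlighted:
            try:
                reg = adjusted_regression("MMSE", X[ab], subjects)
            except (ValueError, KeyError):
                continue
            for model_name in ("univariate", "multivariate"):
                frame = reg[model_name]
                for term, row in frame.iterrows():
                    reg_rows.append({"antibody": ab, "model": model_name, "term": term,
                                     **row.to_dict()})
        pd.DataFrame(reg_rows).to_csv(out / "regressions_mmse.csv", index=False)
        ctx["assoc"] = assoc
        return [out / n for n in ("assoc_rho.csv", "assoc_p.csv", "assoc_stars.csv",
                                  "regressions_mmse.csv")]

    if stage == "crossreact":
        sequences = ctx.get("sequences")
        if sequences is None and c.sequences_fasta:
            sequences = read_fasta(c.sequences_fasta)
        report = crossreact_screen(highlighted, ctx["au"], sequences or {},
                                   c.r_threshold)
        report.correlations.to_csv(out / "crossreact_correlations.csv",
                                   index_label="autoantibody")
        report.to_tsv(out / "crossreact_pairs.tsv")
        ctx["crossreact"] = report
        return [out / "crossreact_correlations.csv", out / "crossreact_pairs.tsv"]

    raise ValueError(f"unknown stage {stage!r}")
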