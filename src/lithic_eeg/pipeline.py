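"""End-to-end orchestration: simulate/ingest -> preprocess -> clean ->
epoch -> spectra -> paired comparisons, with a reproducible run
directory, a manifest of stage hashes, and a markdown report."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .epochs import (
    DEFAULT_EXCLUDED_CONDITIONS,
    align_markers,
    baseline_correct,
    extract_step_epochs,
    reject_epochs,
    segment_trials,
)
from .ica import fit_infomax, remove_components, score_components
from .inference import BetaPowerTable, PairedComparison
from .io import read_recording, write_result_table
from .preprocess import (
    FilterSpec,
    apply_filter,
    detect_bad_channels,
    downsample,
    interpolate_channels,
    rereference_average,
    rereference_rest,
)
from .recording import Recording
from .simulate import EffectMap, SimulationConfig, simulate_cohort
from .spectral import SpectralConfig, band_mean_table
from .topomap import render_topomap

__all__ = ["PipelineConfig", "DEFAULT_COMPARISONS", "run_pipeline",
           "generate_report", "process_recording"]

# the full set of paired comparisons of the staged-tool-use design
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("nutcrack.hold", "cut.hold"),
    ("nutcrack.aim", "cut.aim"),
    ("control.movement", "nutcrack.hold"),
    ("control.movement", "nutcrack.aim"),
    ("nutcrack.hold", "nutcrack.aim"),
    ("control.movement", "cut.hold"),
    ("control.movement", "cut.aim"),
    ("control.movement", "cut.execute"),
    ("cut.hold", "cut.aim"),
    ("cut.aim", "cut.execute"),
    ("cut.hold", "cut.execute"),
)


@dataclass
class PipelineConfig:
    """Serializable configuration of a full run (YAML round-trip)."""

    out_dir: str = "run"
    seed: int = 0
    input_dir: str | None = None          # ingest instead of simulate
    tasks: tuple[str, ...] = ("nutcrack", "cut", "control")
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    effects: dict = field(default_factory=dict)      # "channel:condition" -> mult
    target_hz: float = 250.0
    band: tuple[float, float] = (1.0, 40.0)
    notch_hz: float = 50.0
    reference: str = "rest"               # {"rest", "avg"}
    run_ica: bool = True
    eye_threshold: float = 0.6
    muscle_threshold: float = 0.6
    tolerance_ms: float = 250.0
    amp_uv: float = 100.0
    grad_uv: float = 50.0
    excluded_conditions: tuple[str, ...] = tuple(sorted(DEFAULT_EXCLUDED_CONDITIONS))
    allow_excluded_in_comparisons: bool = False
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    alpha: float = 0.05
    k_iqr: float = 1.5
    taper_fraction: float = 0.10
    band_lo_hz: float = 12.5
    band_hi_hz: float = 30.0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["tasks"] = list(self.tasks)
        d["comparisons"] = [list(c) for c in self.comparisons]
        d["excluded_conditions"] = list(self.excluded_conditions)
        d["band"] = list(self.band)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["tasks"] = tuple(d.get("tasks", ("nutcrack", "cut", "control")))
        d["comparisons"] = tuple(tuple(c) for c in d.get("comparisons",
                                                         DEFAULT_COMPARISONS))
        d["excluded_conditions"] = tuple(d.get(
            "excluded_conditions", tuple(sorted(DEFAULT_EXCLUDED_CONDITIONS))))
        d["band"] = tuple(d.get("band", (1.0, 40.0)))
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if self.reference not in ("rest", "avg"):
            raise ValueError("reference must be 'rest' or 'avg'")
        if not self.allow_excluded_in_comparisons:
            banned = set(self.excluded_conditions)
            for a, b in self.comparisons:
                hit = {a, b} & banned
                if hit:
                    raise ValueError(
                        f"comparison ({a}, {b}) uses excluded condition(s) "
                        f"{sorted(hit)}; set allow_excluded_in_comparisons "
                        "to override"
                    )


def process_recording(rec: Recording, cfg: PipelineConfig, subject: str,
                      seed: int = 0, log: list | None = None) -> pd.DataFrame:
    """Signal chain for one recording; returns beta-table rows."""
    steps = log if log is not None else []
    if rec.rate > cfg.target_hz:
        rec = downsample(rec, cfg.target_hz)
        steps.append(f"downsample -> {cfg.target_hz} Hz")
    rec = apply_filter(rec, FilterSpec("notch", notch_hz=cfg.notch_hz))
    rec = apply_filter(rec, FilterSpec("bandpass", low_hz=cfg.band[0],
                                       high_hz=cfg.band[1]))
    steps.append(f"IIR band-pass {cfg.band[0]}-{cfg.band[1]} Hz, "
                 f"notch {cfg.notch_hz} Hz (zero-phase)")
    bad = detect_bad_channels(rec)
    if bad:
        steps.append(f"bad channels: {sorted(bad)}")
    rec = rec.copy_with(bad_channels=bad)
    if cfg.run_ica:
        dec = fit_infomax(rec, seed=seed)
        dec = score_components(dec, rec.montage)
        rec = remove_components(rec, dec, cfg.eye_threshold, cfg.muscle_threshold)
        steps.append(f"ICA removed components: {sorted(dec.removed)}")
    if bad:
        rec = interpolate_channels(rec, bad)
        steps.append("interpolated bad channels")
    rec = rereference_average(rec)
    if cfg.reference == "rest":
        rec = rereference_rest(rec)
    steps.append(f"reference: {cfg.reference}")
    rec = align_markers(rec, cfg.tolerance_ms)
    trials = segment_trials(rec)
    trials.subject = subject
    trials = baseline_correct(trials)
    eps = extract_step_epochs(trials, set(cfg.excluded_conditions))
    eps = reject_epochs(eps, cfg.amp_uv, cfg.grad_uv)
    steps.append(f"epochs: {eps.n_retained}/{eps.n_epochs} retained")
    scfg = SpectralConfig(cfg.taper_fraction, cfg.band_lo_hz, cfg.band_hi_hz)
    return band_mean_table(eps, subject, scfg)


def _comparison_slug(a: str, b: str) -> str:
    return f"{a}_vs_{b}".replace(".", "-")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    Re-running with an identical configuration on an existing complete
    run directory is a no-op.
    """
    config.validate()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = run_dir / "manifest.json"
    chash = config.config_hash()
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash and old.get("complete"):
            (run_dir / "run.log").open("a").write("up to date; nothing to do\n")
            return run_dir

    log: list[str] = [f"lithic-eeg {__version__}", f"seed {config.seed}"]
    sim_kwargs = dict(config.simulation)
    sim_kwargs.setdefault("seed", config.seed)
    sim_cfg = SimulationConfig(**sim_kwargs)
    effects = EffectMap(
        {tuple(k.split(":")): float(v) for k, v in config.effects.items()}
    )

    if config.input_dir:
        in_dir = Path(config.input_dir)
        recs = {}
        for p in sorted(in_dir.glob("*.json")):
            stem = p.stem
            if "_" not in stem:
                continue
            subject, task = stem.rsplit("_", 1)
            if task in config.tasks:
                recs[(subject, task)] = p.with_suffix("")
        log.append(f"ingested {len(recs)} recordings from {in_dir}")
    else:
        recs, manifest = simulate_cohort(sim_cfg, effects, config.tasks)
        log.append(f"simulated cohort: {sim_cfg.n_subjects} subjects x "
                   f"{config.tasks}")

    rows = []
    for (subject, task), rec in sorted(recs.items()):
        if isinstance(rec, (str, Path)):
            rec = read_recording(rec, dialect="portable")
        stage_log: list[str] = []
        rows.append(process_recording(rec, config, subject, seed=config.seed,
                                      log=stage_log))
        log.append(f"[{subject}/{task}] " + "; ".join(stage_log))
    beta = pd.concat(rows, ignore_index=True)
    beta_rows = beta[["subject", "condition", "channel", "beta_uv"]]
    table = BetaPowerTable(beta_rows)
    write_result_table(beta, run_dir / "beta_table.tsv")

    for a, b in config.comparisons:
        res = PairedComparison(table, a, b, alpha=config.alpha,
                               k_iqr=config.k_iqr).fit()
        slug = _comparison_slug(a, b)
        cdir = run_dir / slug
        write_result_table(res.channel_frame(), cdir / "channels.tsv")
        write_result_table(res.pca.loadings.reset_index(names="channel"),
                           cdir / "loadings.tsv")
        write_result_table(res.pca.scores.reset_index(), cdir / "scores.tsv")
        write_result_table(res.pc_frame(), cdir / "pc_tests.tsv")
        (cdir / "run.json").write_text(json.dumps({
            "comparison": res.comparison,
            "selected_channels": list(res.selection.channels),
            "rule_used": res.selection.rule_used,
            "outliers_removed": list(res.outliers_removed),
            "rerun": res.rerun,
        }, indent=1))
        diff = res.mean_abs_difference()
        render_topomap(diff.to_dict(), table_montage(effects),
                       cdir / "difference_topomap.png",
                       title=f"|{a} - {b}| beta (uV)")
        _pca_scatter(res, cdir / "pca_scores.png")
        log.append(f"comparison {slug}: selected {res.selection.channels} "
                   f"({res.selection.rule_used}), rerun={res.rerun}")

    (run_dir / "run.log").write_text("\n".join(log) + "\n")
    hashes = {
        str(p.relative_to(run_dir)): hashlib.sha256(p.read_bytes()).hexdigest()[:12]
        for p in sorted(run_dir.rglob("*.tsv"))
    }
    manifest_path.write_text(json.dumps({
        "config_hash": chash, "complete": True, "stage_hashes": hashes,
        "version": __version__,
    }, indent=1))
    config.to_yaml(run_dir / "config.yaml")
    return run_dir


def table_montage(effects: EffectMap):
    return effects.montage


def _pca_scatter(res, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sc = res.pca.scores
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for cond, color in zip((res.model.cond_a, res.model.cond_b), ("C0", "C3")):
        sub = sc.xs(cond, level="condition")
        ax.scatter(sub["PC1"], sub["PC2"] if "PC2" in sub else 0 * sub["PC1"],
                   s=18, label=cond, color=color, alpha=0.8)
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    v = res.pca.var_explained
    ax.set_xlabel(f"PC1 ({v[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({v[1]:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=110)
    plt.close(fig)


def generate_report(run_dir) -> Path:
    """Markdown report: one section per comparison."""
    run_dir = Path(run_dir)
    comp_dirs = sorted(d for d in run_dir.iterdir()
                       if d.is_dir() and (d / "run.json").exists())
    if not comp_dirs:
        raise FileNotFoundError(f"no completed comparisons under {run_dir}")
    lines = ["# Beta-power paired-comparison report", ""]
    for d in comp_dirs:
        info = json.loads((d / "run.json").read_text())
        lines += [f"## {info['comparison']}", ""]
        lines += [f"- selected channels: {', '.join(info['selected_channels'])} "
                  f"({info['rule_used']})"]
        if info["outliers_removed"]:
            lines += [f"- outliers removed, chain re-run: "
                      f"{', '.join(info['outliers_removed'])}"]
        pc = pd.read_csv(d / "pc_tests.tsv", sep="\t")
        for r in pc.itertuples():
            lines += [f"- {r.axis}: var {r.var_explained_pct:.1f}%, "
                      f"Z = {r.Z:.2f}, p = {r.p:.4g}"]
        lines += [f"- channel table: `{d.name}/channels.tsv`",
                  f"- figures: `{d.name}/pca_scores.png`, "
                  f"`{d.name}/difference_topomap.png`", ""]
    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
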