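"""Scripted synthetic reproduction of the study grid.

Builds the default desk-scale benchmark (simulated victim and perpetrator
machines, a trained victim model behind the black-box interface, a calibrated
transfer function, and unlabeled perpetrator data), runs migration cells over
the experiment factors (transfer function on/off, label-percentile prior,
noise-rate prior, unlabeled-data size, transducer mismatch), and provides
B-mode rendering for visual before/after checks.

Absolute full-scale scores depend on the real machines and real data; the
synthetic harness therefore asserts orderings and trends (calibrated beats
uncalibrated, robustness bands), not absolute table values.
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .blackbox import VictimInterface
from .iterlnl import (
    IterLNLConfig,
    IterLNLMigrator,
    accuracy_score_pct,
    auc_score,
    evaluate,
)
from .models import (
    ClassifierSpec,
    PatchCNNClassifier,
    TrainConfig,
    perpetrator_spec,
    victim_spec,
)
from .preprocess import (
    PatchConfig,
    PatchSet,
    extract_patches_dataset,
    resample_rate,
    split_frames,
    zscore,
)
from .rf_sim import (
    MachineProfile,
    RFFrame,
    perpetrator_machine,
    phantom_calibration,
    phantom_liver_like,
    phantom_low_attenuation,
    simulate_calibration_views,
    simulate_dataset,
    victim_machine,
)
from .transfer_function import DepthGrid, WienerTransferFunction

__all__ = [
    "BenchmarkConfig",
    "Benchmark",
    "make_benchmark",
    "migrate_once",
    "ExperimentGrid",
    "run_grid",
    "transducer_mismatch_config",
    "render_bmode",
]


def _seed_for(master: int, *tags) -> int:
    words = [int(master)] + [
        int(t) if isinstance(t, (int, np.integer)) else zlib.crc32(str(t).encode())
        for t in tags
    ]
    return int(np.random.SeedSequence([w & 0x7FFFFFFF for w in words]).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Desk-scale study conditions: reduced geometry, frame counts, and
    training protocol sized for a single CPU while preserving the study's
    structure (full scale: 2080 x 256 frames, 1000 frames per phantom,
    10 denoising cycles)."""

    victim_frames_per_class: int = 50
    perp_frames_per_class: int = 24
    axial_samples: int = 1040  # victim-grid frame height
    lateral_lines: int = 128
    n_cal_views: int = 10
    cal_mode: str = "stable"
    patch: PatchConfig = field(default_factory=PatchConfig)
    depth_grid: DepthGrid = field(default_factory=DepthGrid)
    train: TrainConfig = field(default_factory=TrainConfig)
    victim_arch: ClassifierSpec = field(default_factory=victim_spec)
    perp_arch: ClassifierSpec = field(default_factory=perpetrator_spec)
    n_cycles: int = 2


def _rate_factors(fs_from: float, fs_to: float) -> tuple[int, int]:
    from fractions import Fraction

    r = Fraction(str(fs_to)) / Fraction(str(fs_from))
    return r.numerator, r.denominator


@dataclass
class Benchmark:
    """One fully prepared synthetic study: victim behind its interface, the
    fitted transfer function, and perpetrator patch sets (true labels retained
    only for measurement)."""

    config: BenchmarkConfig
    seed: int
    victim_machine: MachineProfile
    perp_machine: MachineProfile
    victim_clf: PatchCNNClassifier
    victim_iface: VictimInterface
    victim_val_metrics: dict
    tfw: WienerTransferFunction
    X_unlabeled: PatchSet  # raw perpetrator patches at the victim rate
    test_set: PatchSet  # labeled raw perpetrator patches at the victim rate


def _perp_frames_at_victim_rate(
    perp: MachineProfile,
    victim: MachineProfile,
    phantoms,
    n_per_class: int,
    seed: int,
    cfg: BenchmarkConfig,
) -> tuple[list[RFFrame], np.ndarray]:
    up, down = _rate_factors(perp.sampling_rate, victim.sampling_rate)
    n_ax_perp = int(round(cfg.axial_samples * down / up))
    frames, labels = simulate_dataset(
        perp,
        phantoms,
        n_per_class,
        seed=seed,
        axial_samples=n_ax_perp,
        lateral_lines=cfg.lateral_lines,
    )
    return [resample_rate(f, up, down) for f in frames], labels


def make_benchmark(
    seed: int,
    cfg: BenchmarkConfig = BenchmarkConfig(),
    perp: MachineProfile | None = None,
) -> Benchmark:
    """Build the default synthetic two-machine benchmark."""
    victim = victim_machine()
    perp = perp or perpetrator_machine()
    phantoms = [phantom_liver_like(), phantom_low_attenuation()]

    # victim side: simulate, split 80/20 at frame level, train, validate
    v_frames, v_labels = simulate_dataset(
        victim,
        phantoms,
        cfg.victim_frames_per_class,
        seed=_seed_for(seed, "victim-data"),
        axial_samples=cfg.axial_samples,
        lateral_lines=cfg.lateral_lines,
    )
    splits = split_frames(v_labels, "victim", seed=_seed_for(seed, "victim-split"))
    train_ps = extract_patches_dataset(
        [v_frames[i] for i in splits["train"]], v_labels[splits["train"]], cfg.patch
    )
    val_ps = extract_patches_dataset(
        [v_frames[i] for i in splits["val"]], v_labels[splits["val"]], cfg.patch
    )
    clf = PatchCNNClassifier(cfg.victim_arch, cfg.train, seed=_seed_for(seed, "victim-train"))
    clf.fit(zscore(train_ps.patches), train_ps.labels)
    val_scores = clf.decision_function(zscore(val_ps.patches))
    victim_val = {
        "accuracy_pct": accuracy_score_pct(val_scores, val_ps.labels),
        "auc": auc_score(val_scores, val_ps.labels),
        "n": len(val_ps),
    }
    iface = VictimInterface(clf.model_, expected_shape=(cfg.patch.patch_height, cfg.patch.patch_width))

    # transfer function from paired calibration views
    cal_v, cal_p = simulate_calibration_views(
        victim,
        perp,
        phantom_calibration(),
        n_views=cfg.n_cal_views,
        mode=cfg.cal_mode,
        seed=_seed_for(seed, "calibration"),
        axial_samples=cfg.axial_samples,
        lateral_lines=cfg.lateral_lines,
    )
    up, down = _rate_factors(perp.sampling_rate, victim.sampling_rate)
    cal_p = [resample_rate(f, up, down) for f in cal_p]
    tfw = WienerTransferFunction(cfg.depth_grid).fit(cal_v, cal_p)

    # perpetrator side: rate-matched frames, 50% held-out test
    p_frames, p_labels = _perp_frames_at_victim_rate(
        perp, victim, phantoms, cfg.perp_frames_per_class, _seed_for(seed, "perp-data"), cfg
    )
    p_splits = split_frames(p_labels, "perpetrator", seed=_seed_for(seed, "perp-split"))
    unlab_idx = np.sort(np.concatenate([p_splits["train"], p_splits["val"]]))
    X_unlab = extract_patches_dataset(
        [p_frames[i] for i in unlab_idx], p_labels[unlab_idx], cfg.patch
    )
    test_set = extract_patches_dataset(
        [p_frames[i] for i in p_splits["test"]], p_labels[p_splits["test"]], cfg.patch
    )
    return Benchmark(
        config=cfg,
        seed=seed,
        victim_machine=victim,
        perp_machine=perp,
        victim_clf=clf,
        victim_iface=iface,
        victim_val_metrics=victim_val,
        tfw=tfw,
        X_unlabeled=X_unlab,
        test_set=test_set,
    )


def migrate_once(
    bench: Benchmark,
    seed: int,
    use_tf: bool = True,
    label_percentile: float = 50.0,
    noise_rate: float = 0.20,
    n_cycles: int | None = None,
) -> dict:
    """Run one migration on a prepared benchmark and measure it end to end.

    Returns initial pseudo-label accuracy (victim scores vs withheld ground
    truth), final patch-wise test accuracy and AUC, and the query count.
    """
    cfg = IterLNLConfig(
        noise_rate=noise_rate,
        label_percentile=label_percentile,
        n_cycles=bench.config.n_cycles if n_cycles is None else n_cycles,
        seed=seed,
    )
    mig = IterLNLMigrator(
        bench.victim_iface,
        bench.tfw.tf_ if use_tf else None,
        bench.config.perp_arch,
        cfg,
        bench.config.train,
    )
    mig.fit(bench.X_unlabeled)
    true = bench.X_unlabeled.labels
    initial_acc = float(np.mean(mig.state_.initial_labels == true) * 100.0)
    final = evaluate(mig.model_, bench.test_set)
    return {
        "seed": seed,
        "tf": "on" if use_tf else "off",
        "percentile": label_percentile,
        "epsilon": noise_rate,
        "n_cycles": cfg.n_cycles,
        "initial_pseudo_label_accuracy_pct": initial_acc,
        "final_label_accuracy_pct": float(np.mean(mig.state_.labels == true) * 100.0),
        "accuracy_pct": final["accuracy_pct"],
        "auc": final["auc"],
        "query_count": mig.state_.query_count,
    }


@dataclass(frozen=True)
class ExperimentGrid:
    """Factor grid over migration cells. Factors absent from a dict default
    to the benchmark settings."""

    tf: tuple = ("on",)
    percentile: tuple = (50.0,)
    epsilon: tuple = (0.20,)
    n_frames: tuple = (None,)  # perpetrator frames per class; None = default
    transducer: tuple = ("matched",)
    n_cycles: tuple = (None,)
    n_seeds: int = 5

    def cells(self):
        for combo in itertools.product(
            self.tf, self.percentile, self.epsilon, self.n_frames, self.transducer, self.n_cycles
        ):
            yield dict(
                zip(("tf", "percentile", "epsilon", "n_frames", "transducer", "n_cycles"), combo)
            )


def transducer_mismatch_config(
    base: MachineProfile, center_shift_mhz: float = 1.5, bandwidth_scale: float = 1.2
) -> MachineProfile:
    """Variant perpetrator profile emulating a different transducer: shifted
    center frequency and widened bandwidth, imaging configuration unchanged."""
    new_fc = base.center_frequency + center_shift_mhz
    if new_fc >= base.sampling_rate / 2:
        raise ValueError("shifted center frequency reaches or exceeds Nyquist")
    return replace(
        base,
        center_frequency=new_fc,
        fractional_bandwidth=min(1.0, base.fractional_bandwidth * bandwidth_scale),
        machine_id=base.machine_id + "-altxdcr",
        transducer_id=base.transducer_id + "-alt",
    )


def _cell_id(cell: dict) -> str:
    return "_".join(f"{k}={cell[k]}" for k in sorted(cell))


def run_grid(
    grid: ExperimentGrid,
    base_config: BenchmarkConfig = BenchmarkConfig(),
    master_seed: int = 0,
    out_dir: str | Path | None = None,
    resume: bool = False,
) -> pd.DataFrame:
    """Run every (cell, seed) migration; returns per-run rows plus per-cell
    aggregates (mean +- std). Benchmarks are cached per simulation-relevant
    factor combination; when ``out_dir`` is set, results and a manifest are
    written and completed cells are skipped on resume."""
    out_path = Path(out_dir) if out_dir is not None else None
    manifest: dict = {"master_seed": master_seed, "cells": {}}
    rows: list[dict] = []
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        mf = out_path / "manifest.json"
        if mf.exists():
            if not resume:
                raise FileExistsError(f"{out_path} already holds a run (use resume)")
            manifest = json.loads(mf.read_text())
            done = pd.read_csv(out_path / "results.csv")
            rows = done.to_dict("records")

    bench_cache: dict[tuple, Benchmark] = {}
    for cell in grid.cells():
        cid = _cell_id(cell)
        if cid in manifest["cells"]:
            continue
        perp = perpetrator_machine()
        if cell["transducer"] == "mismatched":
            perp = transducer_mismatch_config(perp)
        cfg = base_config
        if cell["n_frames"] is not None:
            cfg = replace(cfg, perp_frames_per_class=int(cell["n_frames"]))
        key = (cell["transducer"], cell["n_frames"])
        if key not in bench_cache:
            bench_cache[key] = make_benchmark(_seed_for(master_seed, "bench", *key), cfg, perp)
        bench = bench_cache[key]
        seeds = [_seed_for(master_seed, cid, r) for r in range(grid.n_seeds)]
        for s in seeds:
            row = migrate_once(
                bench,
                s,
                use_tf=cell["tf"] == "on",
                label_percentile=cell["percentile"],
                noise_rate=cell["epsilon"],
                n_cycles=cell["n_cycles"],
            )
            row.update({"cell": cid, "transducer": cell["transducer"], "n_frames": cell["n_frames"]})
            rows.append(row)
        manifest["cells"][cid] = {"seeds": seeds, "query_counts": [r["query_count"] for r in rows[-len(seeds):]]}
        if out_path is not None:
            pd.DataFrame(rows).to_csv(out_path / "results.csv", index=False)
            (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    df = pd.DataFrame(rows)
    return df


def aggregate_grid(df: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean and std of accuracy and AUC."""
    return (
        df.groupby("cell")[["accuracy_pct", "auc", "initial_pseudo_label_accuracy_pct"]]
        .agg(["mean", "std"])
        .reset_index()
    )


def render_bmode(frame: RFFrame, dynamic_range: float = 50.0) -> np.ndarray:
    """Log-compressed envelope image: analytic-signal magnitude along the
    axial axis, normalized to 0 dB at the frame maximum and clamped to
    [-dynamic_range, 0] dB."""
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    env = np.abs(hilbert(frame.samples, axis=0))
    peak = env.max()
    if peak == 0:
        raise ValueError("cannot render an all-zero frame")
    img = 20.0 * np.log10(np.maximum(env, peak * 10 ** (-dynamic_range / 20.0 - 2)) / peak)
    return np.clip(img, -dynamic_range, 0.0)
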