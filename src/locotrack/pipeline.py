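"""End-to-end pipeline driver: simulate -> (render -> detect) -> track ->
kinematics -> statistics, with a run manifest for reproducibility.

Every stage writes a TSV so the pipeline can be resumed or audited from any
intermediate.  All randomness flows from the single config seed, split per
stage, so a fixed config yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .detection import detect_stack, detections_to_xy
from .kinematics import (
    TrackTooShortError,
    interpolate_gaps,
    raw_speed,
    smooth_speed,
    stats_table,
    track_stats,
)
from .stats import bin_tracks_by_avg_speed, speed_histogram, t_test, two_way_anova, speed_bin_of
from .synthetic import generate_dataset, render_stack
from .tracking import Track, filter_tracks, link_tracks
from . import io as lio

__all__ = ["RunManifest", "run_pipeline", "annotate_genotypes", "tracks_smoothed_speeds"]


@dataclass
class RunManifest:
    config: dict
    seed: int
    versions: dict
    outputs: dict[str, str]  # filename -> sha256
    counts: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def annotate_genotypes(tracks: list[Track], ground_truth) -> None:
    """Label each track with the genotype of the ground-truth animal whose
    true path it follows (nearest true position, majority vote over the
    track's observed frames)."""
    pos = ground_truth.positions  # (n_animals, n_frames, 2)
    for t in tracks:
        votes = np.empty(len(t.frames), dtype=int)
        for i, (f, x, y) in enumerate(zip(t.frames, t.xs, t.ys)):
            d2 = (pos[:, f, 0] - x) ** 2 + (pos[:, f, 1] - y) ** 2
            votes[i] = int(np.argmin(d2))
        winner = np.bincount(votes).argmax()
        t.genotype = ground_truth.genotypes[int(winner)]


def tracks_smoothed_speeds(tracks: list[Track], window: int = 5) -> list[np.ndarray]:
    """Smoothed speed series per track (gaps interpolated); tracks too short
    to fill one window are skipped."""
    out = []
    for t in tracks:
        try:
            out.append(smooth_speed(raw_speed(interpolate_gaps(t)), window))
        except TrackTooShortError:
            continue
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Run the full pipeline and write all outputs under ``outdir``.

    Outputs: ground_truth.tsv, detections.tsv, tracks.tsv,
    track_stats.tsv, histogram_<genotype>.tsv, binned_<field>.tsv,
    tests.tsv, manifest.json (and frames.tif when rendering).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # --- simulate ---------------------------------------------------------
    frames, gt = generate_dataset(config.sim_config(), config.genotype_params())
    gt.to_tsv(outdir / "ground_truth.tsv")
    outputs["ground_truth.tsv"] = outdir / "ground_truth.tsv"

    # --- detect (optional rendering round-trip) ---------------------------
    if config.render:
        stack = render_stack(
            frames,
            arena_size=tuple(config.arena_size),
            blob_sigma=config.blob_sigma_px,
            intensity=config.intensity,
            mm_per_px=config.mm_per_px,
        )
        lio.write_stack(stack, outdir / "frames.tif")
        outputs["frames.tif"] = outdir / "frames.tif"
        dets = detect_stack(stack, config.threshold, config.min_area, config.mm_per_px)
        centroids = [detections_to_xy(d) for d in dets]
        lio.write_detections(dets, outdir / "detections.tsv", dt=config.dt)
    else:
        # centroid lists straight from the generator (dropout applied)
        centroids = frames
        from .detection import Detection

        dets = [
            [Detection(i, x, y, 0) for x, y in frame]
            for i, frame in enumerate(frames)
        ]
        lio.write_detections(dets, outdir / "detections.tsv", dt=config.dt)
    outputs["detections.tsv"] = outdir / "detections.tsv"

    # --- track ------------------------------------------------------------
    tracks, diag = link_tracks(
        centroids, config.max_disp, config.max_gap, config.dt, with_diagnostics=True
    )
    annotate_genotypes(tracks, gt)
    n_before = len(tracks)
    kept = filter_tracks(tracks, config.min_track_s)
    lio.write_tracks(kept, outdir / "tracks.tsv")
    outputs["tracks.tsv"] = outdir / "tracks.tsv"

    # --- kinematics -------------------------------------------------------
    stats = [track_stats(t, config.window, config.min_track_s) for t in kept]
    table = stats_table(stats)
    table.to_csv(outdir / "track_stats.tsv", sep="\t", index=False, float_format="%.6f")
    outputs["track_stats.tsv"] = outdir / "track_stats.tsv"

    # --- statistics -------------------------------------------------------
    genotypes = sorted(table["genotype"].dropna().unique()) if len(table) else []
    for g in genotypes:
        sub = [t for t in kept if t.genotype == g]
        hist = speed_histogram(tracks_smoothed_speeds(sub, config.window), config.hist_bin_width)
        p = outdir / f"histogram_{g}.tsv"
        hist.to_frame().to_csv(p, sep="\t", index=False, float_format="%.6f")
        outputs[p.name] = p

    for g in genotypes:
        summ = bin_tracks_by_avg_speed(
            table[table["genotype"] == g], config.field_name, config.curve_bin_width, label=g
        )
        p = outdir / f"binned_{config.field_name}_{g}.tsv"
        summ.table.assign(genotype=g).to_csv(p, sep="\t", index=False, float_format="%.6f")
        outputs[p.name] = p

    test_rows = []
    if len(genotypes) == 2:
        a = table[table["genotype"] == genotypes[0]]
        b = table[table["genotype"] == genotypes[1]]
        if len(a) >= 2 and len(b) >= 2:
            bins = speed_bin_of(table["avg_speed"].to_numpy(), config.curve_bin_width)
            try:
                res = two_way_anova(
                    table[config.field_name].to_numpy(),
                    table["genotype"].to_numpy(),
                    bins,
                )
                test_rows.append(
                    {
                        "comparison": f"{config.field_name}~genotype+speed_bin",
                        "test": "two_way_anova",
                        "statistic": res.f["genotype"],
                        "df": res.df["genotype"],
                        "p": res.p["genotype"],
                    }
                )
            except ValueError:
                pass
            t, p = t_test(a["avg_speed"].to_numpy(), b["avg_speed"].to_numpy())
            test_rows.append(
                {
                    "comparison": f"avg_speed:{genotypes[0]}-vs-{genotypes[1]}",
                    "test": "student_t",
                    "statistic": t,
                    "df": len(a) + len(b) - 2,
                    "p": p,
                }
            )
    pd.DataFrame(test_rows, columns=["comparison", "test", "statistic", "df", "p"]).to_csv(
        outdir / "tests.tsv", sep="\t", index=False, float_format="%.6g"
    )
    outputs["tests.tsv"] = outdir / "tests.tsv"

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        versions={"locotrack": __version__, "python": platform.python_version()},
        outputs={name: _sha256(p) for name, p in outputs.items()},
        counts={
            "n_detections": diag["n_detections"],
            "n_tracks_linked": n_before,
            "n_tracks_kept": len(kept),
            "n_singletons": diag["n_singletons"],
        },
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
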