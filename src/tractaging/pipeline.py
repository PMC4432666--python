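"""End-to-end orchestration: simulate -> fit -> track -> extract -> profile -> stats.

Each stage reads the previous stage's files and writes its own, so any
prefix of the pipeline is resumable from cached outputs.  A manifest
(JSON-lines) records package version, seed, stage parameters and input
checksums.  Report TSVs are written with fixed float formatting, so a rerun
with identical configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .core import DWISeries, FAVolume, Geometry, GradientScheme, LabelVolume
from .dti import brain_mask, fa_volume, fit_tensor, tensor_eigensystem
from .phantom import (
    CurveBundleSpec,
    PhantomCohortSpec,
    default_bundles,
    simulate_cohort,
    write_cohort,
)
from .stats import change_table_frame, connection_change_table, segmentwise_longitudinal_test
from .toi import (
    Bundle,
    DetectionMatrix,
    bundle_passes_threshold,
    extract_bundle,
    tract_mean_fa,
)
from .tracking import TrackingParams, fact_track, load_trk, save_trk
from .tract_param import orient_bundle, profile_two_roi, profiles_to_tsv

logger = logging.getLogger("tractaging")

STAGES = ["simulate", "fit", "track", "extract", "profile", "stats"]
FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Reproducible run configuration; a plain `key = value` file on disk."""

    outdir: str = "tractaging_run"
    n_subjects: int = 10
    waves: int = 2
    rng_seed: int = 0
    snr: float = 25.0
    baseline_fa: float = 0.45
    decline_mean: float = 1.5  # % per year
    decline_sd: float = 0.5
    interval_mean: float = 3.6  # years
    interval_jitter: float = 0.4
    fa_stop: float = 0.15
    angle_stop: float = 35.0
    min_fibers: int = 20
    detection_fraction: float = 0.9
    n_segments: int = 100
    alpha: float = 0.05
    log_level: str = "INFO"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"str": str, "int": int, "float": float}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line or "=" not in line:
                    continue
                key, value = (s.strip() for s in line.split("=", 1))
                if key in types:
                    kwargs[key] = casts.get(str(types[key]), str)(value)
        return cls(**kwargs)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_append(outdir, stage: str, config: RunConfig, inputs: list[str]) -> None:
    record = {
        "stage": stage,
        "version": __version__,
        "seed": config.rng_seed,
        "parameters": dataclasses.asdict(config),
        "input_checksums": {os.path.basename(p): _sha256(p) for p in sorted(inputs)},
    }
    with open(os.path.join(outdir, "manifest.jsonl"), "a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")


def _participants_path(outdir):
    return os.path.join(outdir, "sim", "participants.tsv")


def _list_subject_waves(outdir) -> pd.DataFrame:
    return pd.read_csv(_participants_path(outdir), sep="\t")


def stage_simulate(config: RunConfig,
                   bundles: list[CurveBundleSpec] | None = None,
                   grid: Geometry | None = None) -> None:
    simdir = os.path.join(config.outdir, "sim")
    if os.path.exists(_participants_path(config.outdir)):
        logger.info("simulate: cached outputs found, skipping")
        return
    os.makedirs(simdir, exist_ok=True)
    if bundles is None:
        bundles = default_bundles()
    spec = PhantomCohortSpec(
        n_subjects=config.n_subjects, waves=config.waves,
        interval_years=(config.interval_mean, config.interval_jitter),
        baseline_fa=config.baseline_fa,
        annual_decline_pct=(config.decline_mean, config.decline_sd),
        snr=config.snr, rng_seed=config.rng_seed,
    )
    subject_waves, truths = simulate_cohort(spec, bundles, grid)
    write_cohort(subject_waves, truths, simdir)
    rows = [
        {"subject": sw.subject, "wave": sw.wave, "age": round(sw.age, 2),
         "interval_years": round(sw.interval_since_previous, 3)}
        for sw in subject_waves
    ]
    pd.DataFrame(rows).to_csv(_participants_path(config.outdir), sep="\t",
                              index=False, float_format=FLOAT_FMT)
    with open(os.path.join(simdir, "bundles.json"), "w") as fh:
        json.dump(
            [
                {"name": b.name, "seed_label": b.seed_label,
                 "target_label": b.target_label, "radius": b.radius,
                 "centerline": np.asarray(b.centerline).tolist(),
                 "n_streamlines": b.n_streamlines}
                for b in bundles
            ],
            fh, indent=1,
        )
    _manifest_append(config.outdir, "simulate", config, [])
    logger.info("simulate: wrote %d subject-waves", len(subject_waves))


def _load_bundle_specs(outdir) -> list[CurveBundleSpec]:
    with open(os.path.join(outdir, "sim", "bundles.json")) as fh:
        raw = json.load(fh)
    return [
        CurveBundleSpec(
            centerline=np.asarray(b["centerline"]), radius=b["radius"],
            n_streamlines=b["n_streamlines"], seed_label=b["seed_label"],
            target_label=b["target_label"], name=b["name"],
        )
        for b in raw
    ]


def _sw_stem(outdir, sub, wave, sub_dir):
    return os.path.join(outdir, sub_dir, f"{sub}_wave-{wave}")


def stage_fit(config: RunConfig) -> None:
    fadir = os.path.join(config.outdir, "fa")
    os.makedirs(fadir, exist_ok=True)
    table = _list_subject_waves(config.outdir)
    inputs = []
    for _, row in table.iterrows():
        sim_stem = _sw_stem(config.outdir, row.subject, row.wave, "sim")
        out_stem = _sw_stem(config.outdir, row.subject, row.wave, "fa")
        if os.path.exists(out_stem + "_fa.nii.gz"):
            continue
        scheme = GradientScheme.from_files(sim_stem + ".bval", sim_stem + ".bvec")
        dwi = DWISeries.from_nifti(sim_stem + "_dwi.nii.gz", scheme)
        inputs.append(sim_stem + "_dwi.nii.gz")
        tensors = fit_tensor(dwi)
        mask = brain_mask(dwi)
        fa = fa_volume(tensors, mask)
        _, evecs, _ = tensor_eigensystem(tensors)
        fa.to_nifti(out_stem + "_fa.nii.gz")
        np.save(out_stem + "_evecs.npy", evecs.astype(np.float32))
        np.save(out_stem + "_mask.npy", mask)
    if inputs:
        _manifest_append(config.outdir, "fit", config, inputs)
    logger.info("fit: done")


def _load_fa(config, sub, wave) -> FAVolume:
    import nibabel as nib

    stem = _sw_stem(config.outdir, sub, wave, "fa")
    img = nib.load(stem + "_fa.nii.gz")
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.load(stem + "_mask.npy")
    geom = Geometry(data.shape, tuple(float(z) for z in img.header.get_zooms()[:3]),
                    np.asarray(img.affine))
    return FAVolume(np.where(mask, data, np.nan), geom, mask)


def stage_track(config: RunConfig) -> None:
    trkdir = os.path.join(config.outdir, "trk")
    os.makedirs(trkdir, exist_ok=True)
    params = TrackingParams(fa_stop=config.fa_stop, angle_stop=config.angle_stop)
    table = _list_subject_waves(config.outdir)
    done_any = False
    for _, row in table.iterrows():
        out = _sw_stem(config.outdir, row.subject, row.wave, "trk") + ".trk"
        if os.path.exists(out):
            continue
        fa = _load_fa(config, row.subject, row.wave)
        evecs = np.load(
            _sw_stem(config.outdir, row.subject, row.wave, "fa") + "_evecs.npy"
        ).astype(float)
        streamlines = fact_track(evecs, fa, params)
        save_trk(out, [s.astype(np.float32) for s in streamlines], fa.geometry)
        done_any = True
    if done_any:
        _manifest_append(config.outdir, "track", config, [])
    logger.info("track: done")


def stage_extract(config: RunConfig) -> None:
    outpath = os.path.join(config.outdir, "cohort_fa.tsv")
    if os.path.exists(outpath):
        logger.info("extract: cached outputs found, skipping")
        return
    bundles = _load_bundle_specs(config.outdir)
    table = _list_subject_waves(config.outdir)
    os.makedirs(os.path.join(config.outdir, "bundles"), exist_ok=True)
    rows = []
    for _, row in table.iterrows():
        labels = LabelVolume.from_nifti(
            _sw_stem(config.outdir, row.subject, row.wave, "sim") + "_labels.nii.gz"
        )
        fa = _load_fa(config, row.subject, row.wave)
        streamlines = load_trk(
            _sw_stem(config.outdir, row.subject, row.wave, "trk") + ".trk", fa.geometry
        )
        for spec in bundles:
            bundle = extract_bundle(
                streamlines, labels, spec.seed_label, spec.target_label,
                name=spec.name,
            )
            detected = bundle_passes_threshold(bundle, config.min_fibers)
            mean_fa = tract_mean_fa(bundle, fa) if detected else np.nan
            rows.append(
                {"subject": row.subject, "wave": row.wave, "connection": spec.name,
                 "fa": mean_fa, "n_fibers": bundle.n_fibers,
                 "detected": detected, "age": row.age,
                 "interval_years": row.interval_years}
            )
            if detected:
                save_trk(
                    os.path.join(config.outdir, "bundles",
                                 f"{row.subject}_wave-{row.wave}_{spec.name}.trk"),
                    [s.astype(np.float32) for s in bundle.streamlines], fa.geometry,
                )
    df = pd.DataFrame(rows)
    df.to_csv(outpath, sep="\t", index=False, float_format=FLOAT_FMT)

    # detection matrix: subjects in whom each connection was detected at all waves
    det = (
        df.groupby(["connection", "subject"])["detected"].all().groupby("connection").sum()
    )
    counts = det.astype(float).to_frame().T
    counts.index = ["n_subjects"]
    mat = DetectionMatrix(counts, cohort_size=int(table["subject"].nunique()))
    mat.to_tsv(os.path.join(config.outdir, "detection_matrix.tsv"))
    _manifest_append(config.outdir, "extract", config, [])
    logger.info("extract: wrote %s", outpath)


def stage_profile(config: RunConfig) -> None:
    outpath = os.path.join(config.outdir, "profiles.tsv")
    if os.path.exists(outpath):
        logger.info("profile: cached outputs found, skipping")
        return
    bundles = _load_bundle_specs(config.outdir)
    table = _list_subject_waves(config.outdir)
    frames = []
    for _, row in table.iterrows():
        labels = LabelVolume.from_nifti(
            _sw_stem(config.outdir, row.subject, row.wave, "sim") + "_labels.nii.gz"
        )
        fa = _load_fa(config, row.subject, row.wave)
        for spec in bundles:
            trk_path = os.path.join(
                config.outdir, "bundles",
                f"{row.subject}_wave-{row.wave}_{spec.name}.trk",
            )
            if not os.path.exists(trk_path):
                continue
            streamlines = load_trk(trk_path, fa.geometry)
            bundle = Bundle(spec.seed_label, spec.target_label, streamlines,
                            name=spec.name)
            oriented = orient_bundle(bundle, labels.mask_for(spec.seed_label),
                                     fa.geometry)
            prof = profile_two_roi(oriented, fa, n=config.n_segments)
            frames.append(
                prof.to_frame(connection=spec.name, subject=row.subject,
                              wave=row.wave)
            )
    profiles_to_tsv(frames, outpath)
    _manifest_append(config.outdir, "profile", config, [])
    logger.info("profile: wrote %s", outpath)


def stage_stats(config: RunConfig) -> None:
    statsdir = os.path.join(config.outdir, "stats")
    change_path = os.path.join(statsdir, "change_table.tsv")
    if os.path.exists(change_path):
        logger.info("stats: cached outputs found, skipping")
        return
    os.makedirs(statsdir, exist_ok=True)
    cohort = pd.read_csv(os.path.join(config.outdir, "cohort_fa.tsv"), sep="\t")
    cohort = cohort[cohort["detected"] & np.isfinite(cohort["fa"])]
    waves = sorted(cohort["wave"].unique())
    results = connection_change_table(cohort, waves=waves)
    change_table_frame(results).to_csv(change_path, sep="\t", index=False,
                                       float_format=FLOAT_FMT)

    profiles = pd.read_csv(os.path.join(config.outdir, "profiles.tsv"), sep="\t")
    participants = _list_subject_waves(config.outdir)
    for conn, group in profiles.groupby("connection"):
        pivot = group.pivot_table(index=["subject", "wave"], columns="segment",
                                  values="mean_fa")
        subjects = sorted({s for s, _ in pivot.index})
        complete = [
            s for s in subjects
            if all((s, w) in pivot.index for w in waves)
        ]
        if len(complete) < 3:
            continue
        arr = np.stack(
            [np.stack([pivot.loc[(s, w)].to_numpy() for w in waves]) for s in complete]
        )
        iv = participants.set_index(["subject", "wave"])["interval_years"]
        intervals = np.stack(
            [[float(iv.loc[(s, w)]) for w in waves[1:]] for s in complete]
        )
        seg = segmentwise_longitudinal_test(arr, intervals=intervals, waves=waves)
        seg.to_frame().to_csv(
            os.path.join(statsdir, f"segment_tests_{conn}.tsv"), sep="\t",
            index=False, float_format=FLOAT_FMT,
        )
    _manifest_append(config.outdir, "stats", config, [])
    logger.info("stats: wrote %s", change_path)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "track": stage_track,
    "extract": stage_extract,
    "profile": stage_profile,
    "stats": stage_stats,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> str:
    """Run the requested stages in order (all by default); returns outdir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.outdir, exist_ok=True)
    config.save(os.path.join(config.outdir, "config.txt"))
    for stage in stages or STAGES:
        try:
            _STAGE_FUNCS[stage](config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return config.outdir
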