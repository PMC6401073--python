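"""End-to-end orchestration: simulate -> preprocess -> isc -> slopes/anova
-> spectral, with a manifest for reproducible, resumable runs."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, io, preprocess, spectral, synthetic
from .config import RunConfig
from .corrca import summed_isc
from .datatypes import Annotation, SegmentStack

__all__ = ["run_pipeline", "preprocess_study", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "isc", "slopes", "anova", "spectral"]


# ---------------------------------------------------------------------------
# preprocessing driver (stage order fixed here)
# ---------------------------------------------------------------------------

def preprocess_study(
    recordings: dict, annotations: list, cfg: RunConfig
) -> list[SegmentStack]:
    """Run the full cleaning chain and return scalp-only segment stacks.

    Order: high-pass -> notch -> robust PCA (scalp channels, whole
    recording) -> low-pass -> downsample -> bad-channel interpolation ->
    segmentation -> per-segment EOG regression -> per-channel outlier
    zeroing. Interpolation is applied to the continuous recording; it is a
    per-sample linear map, so it commutes with segmentation.
    """
    p = cfg.preprocess
    cleaned = {}
    for subj, rec in recordings.items():
        t0 = time.perf_counter()
        out = preprocess.highpass(rec, p.hp_cutoff_hz)
        out = preprocess.notch(out, p.notch_hz)
        if p.run_rpca:
            scalp_idx = out.indices(out.scalp_labels)
            low, _ = preprocess.robust_pca_clean(
                out.data[scalp_idx], lam=p.rpca_lambda, tol=p.rpca_tol
            )
            data = out.data.copy()
            data[scalp_idx] = low
            out = out.copy_with(data=data)
        out = preprocess.lowpass(out, p.lp_cutoff_hz)
        out = preprocess.downsample(out, p.target_rate_hz)
        out = preprocess.interpolate_bad_channels(out)
        cleaned[subj] = out
        logger.info(
            "preprocessed %s in %.1f s (rate %g Hz)",
            subj,
            time.perf_counter() - t0,
            out.rate,
        )

    subjects = list(cleaned)
    first = cleaned[subjects[0]]
    scalp_labels = first.scalp_labels
    stacks = []
    for ann in annotations:
        tensors, masks = [], []
        for subj in subjects:
            rec = cleaned[subj]
            (_, seg), = preprocess.segment(rec, [ann])
            scalp = seg[rec.indices(scalp_labels)]
            if rec.eog_labels:
                eog = seg[rec.indices(rec.eog_labels)]
                scalp = preprocess.regress_out_eog(scalp, eog)
            mask = np.ones(scalp.shape[1], dtype=bool)
            for c in range(scalp.shape[0]):
                scalp[c], zeroed = preprocess.zero_outlier_samples(
                    scalp[c],
                    rec.rate,
                    iqr_multiplier=p.outlier_iqr_multiplier,
                    pad_s=p.outlier_pad_ms / 1000.0,
                )
                mask &= ~zeroed
            tensors.append(scalp)
            masks.append(mask)
        stacks.append(
            SegmentStack(
                tensor=np.stack(tensors),
                rate=first.rate,
                annotation=ann,
                subjects=subjects,
                channel_labels=scalp_labels,
                mask=np.stack(masks),
            )
        )
    return stacks


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    s = cfg.simulate
    design = synthetic.StudyDesign(
        n_subjects=s.n_subjects,
        n_pieces=s.n_pieces,
        n_repeats=s.n_repeats,
        segment_s=s.segment_s,
        rate=s.rate_hz,
        n_channels=s.n_channels,
        include_distract=s.include_distract,
    )
    study = synthetic.simulate_study(
        design,
        k=s.k,
        signal_amp=s.signal_amp_uv,
        noise_sd=s.noise_sd_uv,
        eog_strength=s.eog_strength,
        n_bad_channels=s.n_bad_channels,
        outlier_rate=s.outlier_rate_per_min,
        outlier_amp=s.outlier_amp_sd,
        seed=seed,
    )
    study_dir = out / "study"
    study.save(study_dir)
    audio_dir = out / "audio"
    audio_dir.mkdir(parents=True, exist_ok=True)
    for i, piece in enumerate(design.pieces):
        depth = 0.4 + 0.5 * (i % 2)  # alternate calm / dynamic pieces
        wav, rate = synthetic.simulate_audio(
            min(design.segment_s, 30.0), modulation_depth=depth, seed=seed + i
        )
        io.write_wav(audio_dir / f"{piece}.wav", wav, rate)
    return sorted(study_dir.glob("*")) + sorted(audio_dir.glob("*.wav"))


def _save_stacks(stacks: list, path: Path) -> None:
    arrays = {}
    meta = []
    for i, st in enumerate(stacks):
        arrays[f"tensor_{i}"] = st.tensor.astype(np.float32)
        arrays[f"mask_{i}"] = st.mask
        meta.append(
            {
                "annotation": st.annotation.to_dict(),
                "rate": st.rate,
                "subjects": list(st.subjects),
                "channel_labels": list(st.channel_labels),
            }
        )
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def _load_stacks(path: Path) -> list:
    out = []
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        for i, m in enumerate(meta):
            out.append(
                SegmentStack(
                    tensor=z[f"tensor_{i}"].astype(float),
                    mask=z[f"mask_{i}"],
                    rate=m["rate"],
                    annotation=Annotation(**m["annotation"]),
                    subjects=m["subjects"],
                    channel_labels=m["channel_labels"],
                )
            )
    return out


def _stage_preprocess(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    recordings, annotations, _ = io.load_study_dir(out / "study")
    stacks = preprocess_study(recordings, annotations, cfg)
    path = out / "stacks.npz"
    _save_stacks(stacks, path)
    return [path]


def _stage_isc(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    stacks = _load_stacks(out / "stacks.npz")
    with open(out / "study" / "annotations.json") as fh:
        subject_meta = json.load(fh)["subject_meta"]
    loo = inference.loo_crossval(
        stacks,
        k_max=cfg.corrca.k_max,
        shrinkage=cfg.corrca.shrinkage,
        subject_meta=subject_meta,
    )
    test_isc = inference.component_test_isc(loo)
    attend_comps = [
        loo.test_components[key]
        for key in sorted(loo.test_components)
        if key[2] == "attend"
    ]
    null = inference.circular_shift_null(
        attend_comps, n_shuffles=cfg.inference.n_shuffles, seed=seed
    )
    significant = inference.select_significant(test_isc, null)
    summed = summed_isc(loo.table, significant)

    loo.table.to_csv(out / "isc_table.csv", index=False)
    summed.to_csv(out / "isc_summed.csv", index=False)
    report = {
        "n_components": int(test_isc.size),
        "test_isc_per_component": test_isc.tolist(),
        "null_threshold": null.threshold,
        "n_shuffles": cfg.inference.n_shuffles,
        "significant_components": significant,
        "no_significant_components": bool(not significant),
    }
    with open(out / "isc_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    with open(out / "corrca_models.json", "w") as fh:
        json.dump({p: m.to_dict() for p, m in loo.models.items()}, fh)
    return [
        out / "isc_table.csv",
        out / "isc_summed.csv",
        out / "isc_report.json",
        out / "corrca_models.json",
    ]


def _stage_slopes(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    summed = pd.read_csv(out / "isc_summed.csv")
    att = summed[summed["attention"] == "attend"]
    scale = cfg.report.slope_scale
    rows = []
    for (piece, training), sub in att.groupby(["piece", "training"]):
        by_rep = sub.groupby("repeat")["isc_sum"].mean().sort_index()
        rec = inference.isc_slope(by_rep.to_numpy(), piece=piece, group=training)
        rows.append(
            {
                "piece": piece,
                "training": training,
                "familiarity": sub["familiarity"].iloc[0],
                "slope": rec.slope,
                "slope_scaled": rec.slope * scale,
                "intercept": rec.intercept,
            }
        )
    slopes = pd.DataFrame(rows)
    slopes.to_csv(out / "slopes.csv", index=False)

    stats = {}
    for training, sub in slopes.groupby("training"):
        fam = sub.loc[sub["familiarity"] == "familiar", "slope"]
        unf = sub.loc[sub["familiarity"] == "unfamiliar", "slope"]
        if len(fam) >= 2 and len(unf) >= 2:
            t, df, pval = inference.slope_group_test(fam, unf)
            stats[training] = {"t": t, "df": df, "p": pval}
    with open(out / "slope_tests.json", "w") as fh:
        json.dump(stats, fh, indent=1)
    return [out / "slopes.csv", out / "slope_tests.json"]


def _stage_anova(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    summed = pd.read_csv(out / "isc_summed.csv")
    att = summed[summed["attention"] == "attend"]
    report = {}

    agg = inference.aggregate_cells(att, "isc_sum", factors=["repeat", "familiarity"])
    two = inference.rm_anova(agg, "isc_sum", within=["repeat", "familiarity"])
    report["two_way"] = two.to_dict(orient="records")

    agg3 = att.groupby(
        ["subject", "repeat", "familiarity", "training"], as_index=False
    )["isc_sum"].mean()
    counts = agg3.drop_duplicates("subject").groupby("training").size()
    if len(counts) == 2 and counts.nunique() == 1:
        three = inference.rm_anova(
            agg3,
            "isc_sum",
            within=["repeat", "familiarity"],
            between="training",
        )
        report["three_way"] = three.to_dict(orient="records")

    if (summed["attention"] == "distract").any():
        delta = inference.attend_distract_delta(summed)
        delta.to_csv(out / "attend_distract_delta.csv", index=False)
        report["attend_distract_mean_delta"] = (
            delta.groupby("familiarity")["delta"].mean().to_dict()
        )
        att1 = summed[
            ((summed["attention"] == "attend") & (summed["repeat"] == 1))
            | (summed["attention"] == "distract")
        ]
        agg_att = att1.groupby(
            ["subject", "attention", "familiarity"], as_index=False
        )["isc_sum"].mean()
        att_anova = inference.rm_anova(
            agg_att, "isc_sum", within=["attention", "familiarity"]
        )
        report["attention_two_way"] = att_anova.to_dict(orient="records")

    with open(out / "anova.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return [out / "anova.json"]


def _stage_spectral(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    audio_dir = Path(cfg.paths.audio_dir) if cfg.paths.audio_dir else out / "audio"
    wavs = sorted(audio_dir.glob("*.wav"))
    if not wavs:
        logger.warning("no audio in %s; spectral stage skipped", audio_dir)
        return []
    n_pieces = len(wavs)
    dyns = []
    rows = []
    for i, wav in enumerate(wavs):
        audio, rate = io.read_wav(wav)
        category = "familiar" if i < n_pieces // 2 else "unfamiliar"
        d = spectral.piece_dynamics(audio, rate, piece=wav.stem, category=category)
        dyns.append(d)
        rows.append(
            {
                "piece": wav.stem,
                "category": category,
                "median_aggregated_flux": float(np.median(d.aggregated)),
                "mean_aggregated_flux": float(d.aggregated.mean()),
            }
        )
    pd.DataFrame(rows).to_csv(out / "spectral_dynamics.csv", index=False)
    try:
        t, dof, pval = spectral.balance_test(dyns)
        balance = {"t": t, "df": dof, "p": pval}
    except ValueError as exc:
        logger.warning("balance test not computed: %s", exc)
        balance = {"t": None, "df": None, "p": None, "note": str(exc)}
    with open(out / "spectral_balance.json", "w") as fh:
        json.dump(balance, fh, indent=1)
    return [out / "spectral_dynamics.csv", out / "spectral_balance.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "isc": _stage_isc,
    "slopes": _stage_slopes,
    "anova": _stage_anova,
    "spectral": _stage_spectral,
}


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(
    cfg: RunConfig, stages: list[str] | None = None, seed: int | None = None
) -> dict:
    """Execute the requested stages in order and update the run manifest.

    Completed stages (same config hash and seed, outputs still present) are
    skipped on re-runs. Returns the manifest dict.
    """
    cfg.validate()
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    seed = cfg.seed if seed is None else seed
    out = Path(cfg.paths.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cfg_hash = hashlib.sha256(cfg.to_yaml().encode()).hexdigest()[:16]
    manifest_path = out / "manifest.json"
    manifest = {"config_hash": cfg_hash, "seed": seed, "stages": {}}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == cfg_hash and old.get("seed") == seed:
            manifest = old

    # stage-level substreams: independent reruns get identical stage seeds
    stage_seed = {
        name: int(np.random.SeedSequence(seed).spawn(len(STAGES))[i].generate_state(1)[0] % (2**31))
        for i, name in enumerate(STAGES)
    }

    for name in STAGES:
        if name not in stages:
            continue
        done = manifest["stages"].get(name)
        if done and all(Path(p).exists() for p in done["outputs"]):
            logger.info("stage %s already complete; skipped", name)
            continue
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[name](cfg, out, stage_seed[name])
        except Exception:
            manifest_path.write_text(json.dumps(manifest, indent=1))
            logger.error("stage %s failed; partial state persisted", name)
            raise
        manifest["stages"][name] = {
            "outputs": [str(p) for p in outputs],
            "checksums": {Path(p).name: _checksum(Path(p)) for p in outputs},
            "wall_s": round(time.perf_counter() - t0, 2),
        }
        manifest_path.write_text(json.dumps(manifest, indent=1))
        logger.info("stage %s done in %.1f s", name, time.perf_counter() - t0)
    return manifest
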