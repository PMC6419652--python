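"""End-to-end driver: cohort of phantoms -> gated/ungated images -> VOIs ->
features -> paired comparison and survival analysis.

Each subject gets an independent, reproducible RNG substream derived from the
global seed and the subject index (counter-based spawn), so a subject's data
do not depend on cohort size or order.  All numeric outputs are CSV at 9
significant digits; a manifest records the resolved configuration, seed and
library versions so every output is regenerable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .features import FEATURE_NAMES, extract_all
from .gating import optimal_amplitude_window, select_frames
from .io import FLOAT_FORMAT, write_table
from .phantom import (
    PhantomImage,
    default_phantom_spec,
    lujan_waveform,
    make_phantom,
    simulate_acquisition,
    sum_frames,
)
from .segmentation import isocontour_voi, seed_mask_from_truth
from .survival import simulate_survival, standard_scale, table2_analysis, wilcoxon_paired

logger = logging.getLogger("orgpet")

__all__ = ["PipelineError", "simulate_subject", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and subject id."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed for subject '{subject_id}': {cause}")
        self.stage = stage
        self.subject_id = subject_id


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, subject_index)))


def simulate_subject(
    config: RunConfig, subject_index: int
) -> Dict[str, Dict[str, float]]:
    """One synthetic patient: returns {'nonORG': features, 'ORG': features}.

    Subject-level variability: lesion peak SUV is log-normal around 8,
    lesion radius and motion amplitude Gaussian around their cohort means.
    """
    rng = _subject_rng(config.seed, subject_index)
    subject_id = f"S{subject_index:03d}"
    coh = config.cohort
    mot = config.motion

    try:
        peak = 8.0 * float(np.exp(coh.peak_suv_logsd * rng.standard_normal()))
        radius = float(np.clip(16.0 + coh.radius_sd_mm * rng.standard_normal(), 10.0, 24.0))
        amplitude = float(
            np.clip(mot.amplitude_mm + coh.amplitude_sd_mm * rng.standard_normal(), 0.0, 25.0)
        )
        spec = default_phantom_spec(
            seed=int(rng.integers(2**31)),
            noise_scale=config.noise_scale,
            lesion_peak_suv=peak,
            lesion_radius_mm=radius,
        )
        truth = make_phantom(spec)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("phantom", subject_id, exc) from exc

    try:
        trace = lujan_waveform(
            period_s=mot.period_s,
            amplitude_mm=amplitude,
            exponent_n=mot.exponent_n,
            duration_s=mot.duration_s,
            dt_s=mot.dt_s,
            drift_mm_per_min=mot.drift_mm_per_min,
            jitter=mot.cycle_jitter,
            seed=int(rng.integers(2**31)),
        )
        stack = simulate_acquisition(
            truth,
            trace,
            background_suv=spec.background_suv,
            motion_axis=mot.motion_axis,
            noise_scale=config.noise_scale,
            seed=int(rng.integers(2**31)),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("acquisition", subject_id, exc) from exc

    try:
        ungated = sum_frames(stack, np.arange(len(stack)))
        window = optimal_amplitude_window(trace, config.duty)
        gated = sum_frames(stack, select_frames(trace, window))
        logger.debug(
            "%s window L=%.2f U=%.2f W=%.2f duty=%.3f",
            subject_id,
            window.lower_L_mm,
            window.upper_U_mm,
            window.width_W_mm,
            window.achieved_duty,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("gating", subject_id, exc) from exc

    try:
        seed_mask = seed_mask_from_truth(
            truth,
            spec.background_suv,
            dilate_voxels=2,
            motion_axis=mot.motion_axis,
            max_shift_mm=float(trace.amplitudes_mm.max(initial=0.0)),
        )
        out = {}
        for name, img in (("nonORG", ungated), ("ORG", gated)):
            voi = isocontour_voi(img, seed_mask, fraction=config.isocontour_fraction)
            out[name] = dict(extract_all(img, voi, n_bins=config.n_bins))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("segmentation/features", subject_id, exc) from exc
    return out


def _feature_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["subject_id", "reconstruction", *FEATURE_NAMES])


def run_pipeline(config: RunConfig, output_dir: Optional[str] = None) -> Dict[str, Path]:
    """Run the full study simulation and write all outputs.

    Writes features.csv (tidy per subject x reconstruction), survival.csv,
    wilcoxon.csv (paired nonORG vs ORG per feature), table2.csv (univariate
    Cox per feature x reconstruction), cutoffs.csv and manifest.json into
    the output directory; returns the paths.
    """
    config.validate()
    out_dir = Path(output_dir if output_dir is not None else config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for s in range(config.cohort.n_subjects):
        feats = simulate_subject(config, s)
        for recon in ("nonORG", "ORG"):
            rows.append({"subject_id": f"S{s:03d}", "reconstruction": recon, **feats[recon]})
    features_df = _feature_frame(rows)

    # paired comparison per feature
    non = features_df[features_df["reconstruction"] == "nonORG"].set_index("subject_id")
    org = features_df[features_df["reconstruction"] == "ORG"].set_index("subject_id")
    wil_rows = []
    n_subj = config.cohort.n_subjects
    for name in FEATURE_NAMES:
        x = non[name].to_numpy(dtype=float)
        y = org.loc[non.index, name].to_numpy(dtype=float)
        if n_subj >= 6:
            res = wilcoxon_paired(x, y)
            stat, p, flag = res.statistic, res.p, res.degenerate
        else:
            stat, p, flag = float("nan"), float("nan"), True
        wil_rows.append(
            {
                "feature": name,
                "median_nonORG": float(np.median(x)),
                "median_ORG": float(np.median(y)),
                "statistic": stat,
                "p_value": p,
                "degenerate": flag,
            }
        )
    wilcoxon_df = pd.DataFrame(wil_rows)

    # survival generation tied to planted standardized features
    coh = config.cohort
    planted_src = (
        org if coh.planted_reconstruction == "ORG" else non
    ).loc[non.index]
    lin_pred = np.zeros(n_subj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fname, beta in coh.planted_effects.items():
            lin_pred = lin_pred + beta * standard_scale(
                planted_src[fname].to_numpy(dtype=float)
            )
    surv_seed = int(
        np.random.default_rng(np.random.SeedSequence((config.seed, 999983))).integers(2**31)
    )
    times, events = simulate_survival(
        lin_pred,
        lambda0=coh.lambda0_per_week,
        censor_frac=coh.censor_frac,
        seed=surv_seed,
    )
    survival_df = pd.DataFrame(
        {"subject_id": non.index, "time_weeks": times, "event": events}
    )

    paths = {
        "features": out_dir / "features.csv",
        "survival": out_dir / "survival.csv",
        "wilcoxon": out_dir / "wilcoxon.csv",
        "manifest": out_dir / "manifest.json",
    }
    write_table(features_df, paths["features"])
    write_table(survival_df, paths["survival"])
    write_table(wilcoxon_df, paths["wilcoxon"])

    if n_subj >= 3 and events.sum() >= 2:
        cox_df, cut_df = table2_analysis(features_df, survival_df, FEATURE_NAMES)
        paths["table2"] = out_dir / "table2.csv"
        paths["cutoffs"] = out_dir / "cutoffs.csv"
        write_table(cox_df, paths["table2"])
        write_table(cut_df, paths["cutoffs"])

    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "orgpet_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": sorted(p.name for p in paths.values() if p.name != "manifest.json"),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
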