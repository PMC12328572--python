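"""Config-driven experiment recipes reproducing each figure-level analysis
end to end, writing results tables plus a reproducibility manifest."""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd

from . import __version__, periphery, psychophysics, spike_analysis, stats_util
from . import stimuli, synthetic_data
from .periphery import FiberParams
from .stimuli import NotchedNoiseSpec

RECIPES = (
    "level_series", "population_sweep", "notch_population", "notch_grid",
    "shift_curves", "staircase_thresholds", "condition_blocks",
)


@dataclass
class ExperimentConfig:
    recipe: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.recipe not in RECIPES:
            raise ValueError(f"unknown recipe {self.recipe!r}; "
                             f"choose from {RECIPES}")


def _sam_factory(cf, f_m, level, duration, ramp, fs, noise_spec=None):
    """Stimulus factory: SAM tone plus (optionally) fresh notched noise per
    repetition (running noise)."""
    def make(seed: int):
        sam = stimuli.synth_sam(cf, f_m, level, duration, ramp, fs)
        if noise_spec is None:
            return sam
        from dataclasses import replace
        nspec = replace(noise_spec, seed=seed, interaural="diotic")
        nz = stimuli.synth_noise(nspec, duration, fs)
        return replace(sam, waveform=sam.waveform + nz.channel(0))
    return make


def level_series(
    fiber: Optional[FiberParams] = None,
    levels=None,
    noise_spectral_level: Optional[float] = None,
    w: float = 20.0,
    f_m: float = 128.0,
    duration: float = 3.0,
    ramp: float = 0.02,
    fs: float = stimuli.FS_MODEL,
    n_reps: int = 10,
    noise_band=(1.0, 8500.0),
    seed: int = 0,
) -> spike_analysis.LevelFunction:
    """Rate- and VS-level functions of one on-CF fiber, in quiet or in
    fixed-level notched noise."""
    fiber = fiber or FiberParams()
    if levels is None:
        levels = np.arange(0.0, 91.0, 5.0)
    noise_spec = None
    if noise_spectral_level is not None:
        noise_spec = NotchedNoiseSpec(
            f_c=fiber.cf, w=w, spectral_level=noise_spectral_level,
            f_lo=noise_band[0], f_hi=min(noise_band[1], 0.45 * fs))
    ss = np.random.SeedSequence(seed)
    sets = {}
    for lv, child in zip(levels, ss.spawn(len(levels))):
        stim = _sam_factory(fiber.cf, f_m, float(lv), duration, ramp, fs,
                            noise_spec)
        if noise_spec is None:
            stim = stim(0)  # deterministic stimulus; one cascade evaluation
        sets[float(lv)] = periphery.simulate_fiber_response(
            stim, fiber, n_reps=n_reps,
            seed=int(child.generate_state(1)[0] % 2**31))
    return spike_analysis.level_functions(sets, f_m=f_m)


def population_sweep(
    level: float,
    cfs=None,
    fiber_template: Optional[FiberParams] = None,
    noise_spectral_level: Optional[float] = None,
    w: float = 20.0,
    f_c: float = 4000.0,
    f_m: float = 128.0,
    duration: float = 3.0,
    fs: float = stimuli.FS_MODEL,
    n_reps: int = 10,
    noise_band=(1.0, 8500.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Rate and VS across a CF grid for a fixed SAM tone (optionally in
    notched noise around f_c)."""
    cfs = periphery.cf_grid() if cfs is None else np.asarray(cfs, float)
    noise_spec = None
    if noise_spectral_level is not None:
        noise_spec = NotchedNoiseSpec(
            f_c=f_c, w=w, spectral_level=noise_spectral_level,
            f_lo=noise_band[0], f_hi=min(noise_band[1], 0.45 * fs))
    stim = _sam_factory(f_c, f_m, level, duration, 0.02, fs, noise_spec)
    if noise_spec is None:
        stim = stim(0)
    sets = periphery.simulate_population(
        stim, cfs, fiber_template, n_reps=n_reps, seed=seed)
    rows = []
    for cf, st in sets.items():
        s = spike_analysis.summarize_set(st)
        rows.append({"cf": cf, "level_db_spl": level,
                     "rate": s.rate_mean, "rate_sd": s.rate_sd,
                     "vs": s.vs_mean, "vs_sd": s.vs_sd,
                     "significant": s.significant})
    return pd.DataFrame(rows)


def notch_grid(
    n_fibers: int = 17,
    sam_level: float = 60.0,
    cohort: Optional[synthetic_data.CohortSpec] = None,
    seed: int = 0,
    **session_kwargs,
) -> Dict[str, pd.DataFrame]:
    """Six-condition notched-noise grid on a fiber cohort: per-fiber VS with
    and without noise, paired tests with Holm correction, and the
    delta-VS-vs-SR correlation."""
    spec = cohort or synthetic_data.CohortSpec(n_fibers=n_fibers,
                                               master_seed=seed)
    fibers = synthetic_data.sample_fiber_population(spec)
    rows = []
    for i, fiber in enumerate(fibers):
        sess = synthetic_data.generate_recording_session(
            fiber, seed=seed + 1000 + i, sam_level=sam_level,
            **session_kwargs)
        tab = synthetic_data.session_delta_vs(sess)
        tab.insert(0, "fiber_id", f"F{i:02d}")
        tab.insert(1, "sr", fiber.sr)
        tab.insert(2, "sr_class", fiber.sr_class)
        tab.insert(3, "cf", fiber.cf)
        rows.append(tab)
    table = pd.concat(rows, ignore_index=True)

    tests = []
    for (w, g), grp in table.groupby(["w_percent", "g_db_hz"]):
        grp = grp.dropna(subset=["vs_quiet", "vs_noise"])
        if len(grp) >= 2:
            res = stats_util.paired_t(grp["vs_noise"], grp["vs_quiet"])
            tests.append({"w_percent": w, "g_db_hz": g, "n": len(grp),
                          "mean_delta_vs": float(grp["delta_vs"].mean()),
                          "t": res.statistic, "df": res.df, "p": res.p})
    tests = pd.DataFrame(tests)
    if len(tests):
        tests["p_holm"] = stats_util.holm_correction(tests["p"].to_numpy())

    sub = table[(table.w_percent == 30) & (table.g_db_hz == -35)].dropna(
        subset=["delta_vs"])
    corr = None
    if len(sub) >= 3 and sub["sr"].nunique() > 1:
        corr = stats_util.pearson_corr(sub["delta_vs"], sub["sr"])
    corr_df = pd.DataFrame([{
        "rho": corr.statistic if corr else math.nan,
        "p": corr.p if corr else math.nan,
        "n": len(sub),
    }])
    return {"delta_vs": table, "paired_tests": tests, "sr_correlation": corr_df}


def shift_curves(
    fiber: Optional[FiberParams] = None,
    noise_spectral_level: float = 25.0,
    **kwargs,
) -> pd.DataFrame:
    """VS-level functions in quiet vs fixed-level notched noise, with the
    level of maximal (significant) VS in each."""
    fiber = fiber or FiberParams()
    quiet = level_series(fiber, **kwargs)
    noisy = level_series(fiber, noise_spectral_level=noise_spectral_level,
                         **kwargs)
    rows = []
    for name, lf in (("quiet", quiet), ("notched_noise", noisy)):
        df = lf.as_frame()
        df.insert(0, "condition", name)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def vs_peak_level(lf: spike_analysis.LevelFunction,
                  significant_only: bool = True) -> float:
    """Stimulus level of maximal VS (significant values only by default)."""
    vs = lf.vs_mean.copy()
    if significant_only:
        vs[~lf.significant] = np.nan
    if np.all(np.isnan(vs)):
        raise ValueError("no defined VS values")
    return float(lf.levels[int(np.nanargmax(vs))])


def staircase_thresholds(
    cohort: Optional[synthetic_data.CohortSpec] = None,
    n_tracks: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-observer geometric-mean envelope-IPD thresholds over repeated
    adaptive tracks."""
    spec = cohort or synthetic_data.CohortSpec(master_seed=seed)
    observers = synthetic_data.sample_observer_cohort(spec)
    rows = []
    for i, obs in enumerate(observers):
        gmean, gsd, tracks = psychophysics.repeated_thresholds(
            obs, n_tracks=n_tracks, seed=seed + 17 * i)
        rows.append({
            "observer": f"S{i + 1}", "alpha": obs.alpha, "lapse": obs.lapse,
            "threshold_gmean": gmean, "threshold_gsd": gsd,
            "threshold_itd_ms": stimuli.ipd_to_itd(gmean, 128.0) * 1e3
            if not math.isnan(gmean) else math.nan,
            "n_converged": sum(t.converged for t in tracks),
        })
    return pd.DataFrame(rows)


def condition_blocks(
    model: Optional[psychophysics.BinauralModel] = None,
    delta_ipd: float = psychophysics.START_DELTA_IPD,
    conditions=("Q", "Mon_left", "Bin"),
    n_trials: int = 100,
    sam_level: float = 65.0,
    noise_g: float = -35.0,
    w: float = 20.0,
    fs: float = 32000.0,
    seed: int = 0,
) -> Dict[str, pd.DataFrame]:
    """Fixed-level condition blocks through the binaural decision model,
    with exact binomial CIs and chi-square contrasts against Bin."""
    model = model or psychophysics.BinauralModel()
    noise = NotchedNoiseSpec(
        f_c=4000.0, w=w,
        spectral_level=stimuli.spectral_level_from_relative(noise_g, sam_level),
        f_lo=1.0, f_hi=min(8500.0, 0.45 * fs))
    trial_spec = stimuli.BinauralTrialSpec(delta_ipd_env=delta_ipd, fs=fs)
    blocks = {}
    rows = []
    for i, cond in enumerate(conditions):
        responder = model.responder(cond, sam_level=sam_level, noise=noise,
                                    trial_spec=trial_spec)
        blk = psychophysics.constant_stimuli_block(
            responder, delta_ipd, n_trials=n_trials, seed=seed + 101 * i)
        blocks[cond] = blk
        rows.append({"condition": cond, "n_correct": blk.n_correct,
                     "n_trials": blk.n_trials, "proportion": blk.proportion,
                     "ci_low": blk.ci_low, "ci_high": blk.ci_high,
                     "p_vs_chance": blk.p_vs_chance})
    props = pd.DataFrame(rows)

    contrasts = []
    if "Bin" in blocks:
        ref = blocks["Bin"]
        for cond, blk in blocks.items():
            if cond == "Bin":
                continue
            res = stats_util.chi_square_2x2([
                [blk.n_correct, blk.n_trials - blk.n_correct],
                [ref.n_correct, ref.n_trials - ref.n_correct],
            ])
            contrasts.append({"condition": cond, "vs": "Bin",
                              "chi2": res.statistic, "p": res.p})
    return {"proportions": props, "chi2_contrasts": pd.DataFrame(contrasts)}


# ---------------------------------------------------------------------------
# dispatch + manifest
# ---------------------------------------------------------------------------

_DISPATCH: Dict[str, Callable] = {
    "level_series": lambda p: {"level_function": level_series(**p).as_frame()},
    "population_sweep": lambda p: {"population": population_sweep(**p)},
    "notch_population": lambda p: (lambda level, nsl: {
        "quiet": population_sweep(level=level, **p),
        "notched_noise": population_sweep(
            level=level, noise_spectral_level=nsl, **p),
    })(p.pop("level", 65.0), p.pop("noise_spectral_level", 30.0)),
    "notch_grid": lambda p: notch_grid(**p),
    "shift_curves": lambda p: {"curves": shift_curves(**p)},
    "staircase_thresholds": lambda p: {"thresholds": staircase_thresholds(**p)},
    "condition_blocks": lambda p: condition_blocks(**p),
}


def run_experiment(config: ExperimentConfig) -> Dict[str, pd.DataFrame]:
    """Run a named recipe; write per-table CSVs and a manifest when
    ``config.out_dir`` is set."""
    params = dict(config.params)
    params.setdefault("seed", config.seed)
    tables = _DISPATCH[config.recipe](params)
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(os.path.join(config.out_dir, f"{name}.csv"), index=False)
        manifest = {
            "recipe": config.recipe,
            "params": {k: _jsonable(v) for k, v in config.params.items()},
            "seed": config.seed,
            "package_version": __version__,
        }
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return tables


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if hasattr(v, "__dict__"):
        return {k: _jsonable(x) for k, x in v.__dict__.items()}
    return v
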