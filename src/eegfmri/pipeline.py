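"""End-to-end orchestration: cohort -> metrics (pre/post correction) ->
association grid -> FDR -> paired r-squared comparison -> polarity matrix.

The per-participant path mirrors the study design: initial frames are
dropped, the macrovascular correction (when applied) precedes nuisance
regression and band-pass filtering (the venous reference is broadband), and
metric extraction runs separately on the uncorrected ("pre") and corrected
("post") series.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from .correction import correct_volume
from .eeg_metrics import EEG_METRICS, MseParams, eeg_network_metrics
from .fmri_metrics import (BandLimits, EntropyParams, FMRI_METRICS,
                           drop_initial_frames, fmri_network_metrics,
                           preprocess_bold)
from .synth import COUPLED_PAIR, Cohort, SimulationConfig, make_cohort

log = logging.getLogger(__name__)

__all__ = ["AnalysisOptions", "participant_tables", "cohort_tables",
           "run_full_analysis", "coupled_pair_replicate"]


class AnalysisOptions:
    """Stage parameters for a full run (serializable to JSON)."""

    def __init__(self, band=(0.01, 0.1), drop_initial: int = 5,
                 fc_threshold: float = 0.6, entropy_m: int = 3,
                 entropy_r: float = 0.6, mse_m: int = 2, mse_r: float = 0.5,
                 max_lag: int = 3, q: float = 0.05, iqr_k: float = 1.5,
                 random_network: bool = False,
                 fmri_metrics: tuple = FMRI_METRICS,
                 eeg_metrics: tuple = EEG_METRICS):
        self.band = BandLimits(*band)
        self.drop_initial = drop_initial
        self.fc_threshold = fc_threshold
        self.entropy = EntropyParams(entropy_m, entropy_r)
        self.mse = MseParams(mse_m, mse_r)
        self.max_lag = max_lag
        self.q = q
        self.iqr_k = iqr_k
        self.random_network = random_network
        self.fmri_metrics = tuple(fmri_metrics)
        self.eeg_metrics = tuple(eeg_metrics)

    def to_dict(self) -> dict:
        return {"band": [self.band.low_hz, self.band.high_hz],
                "drop_initial": self.drop_initial,
                "fc_threshold": self.fc_threshold,
                "entropy": asdict(self.entropy), "mse": asdict(self.mse),
                "max_lag": self.max_lag, "q": self.q, "iqr_k": self.iqr_k,
                "random_network": self.random_network,
                "fmri_metrics": list(self.fmri_metrics),
                "eeg_metrics": list(self.eeg_metrics)}


def participant_tables(participant, atlas: np.ndarray,
                       opts: AnalysisOptions) -> tuple:
    """Pre- and post-correction fMRI network metrics plus EEG network metrics
    for one participant."""
    v = drop_initial_frames(participant.volume, opts.drop_initial)

    pre = preprocess_bold(v, band=opts.band)
    f_pre = fmri_network_metrics(pre, atlas, threshold=opts.fc_threshold,
                                 entropy_params=opts.entropy,
                                 metrics=opts.fmri_metrics).assign(state="pre")

    corrected, _ = correct_volume(v, max_lag=opts.max_lag)
    post = preprocess_bold(corrected, band=opts.band)
    f_post = fmri_network_metrics(post, atlas, threshold=opts.fc_threshold,
                                  entropy_params=opts.entropy,
                                  metrics=opts.fmri_metrics).assign(state="post")

    eeg = eeg_network_metrics(participant.eeg, params=opts.mse,
                              metrics=opts.eeg_metrics).assign(state="pre")
    pid = participant.pid
    return (pd.concat([f_pre, f_post], ignore_index=True).assign(participant=pid),
            eeg.assign(participant=pid))


def cohort_tables(cohort: Cohort, opts: AnalysisOptions) -> tuple:
    """Metric tables for every participant of a cohort."""
    fmri, eeg = [], []
    for part in cohort.participants:
        f, e = participant_tables(part, cohort.atlas, opts)
        fmri.append(f)
        eeg.append(e)
    sex = pd.DataFrame({"participant": [p.pid for p in cohort.participants],
                        "sex": cohort.truth.sex})
    return pd.concat(fmri, ignore_index=True), pd.concat(eeg, ignore_index=True), sex


def run_full_analysis(cohort: Cohort, opts: AnalysisOptions | None = None,
                      out_dir: str | Path | None = None) -> dict:
    """Execute the whole analysis on a cohort and optionally persist TSVs.

    Returns a dict with the metric tables, the association results, the
    paired r-squared comparison, and the signed polarity matrix.  When
    ``out_dir`` is given, writes ``fmri_metrics.tsv``, ``eeg_metrics.tsv``,
    ``associations.tsv``, ``r2_comparison.tsv``, ``polarity_matrix.tsv`` and
    the resolved options as ``options.json``.
    """
    opts = opts or AnalysisOptions()
    fmri, eeg, sex = cohort_tables(cohort, opts)
    y_metrics = tuple(m for m in assoc.DEFAULT_Y_METRICS if m in opts.fmri_metrics)
    x_metrics = tuple(m for m in assoc.DEFAULT_X_METRICS if m in opts.eeg_metrics)
    results = assoc.association_grid(fmri, eeg, sex, q=opts.q,
                                     y_metrics=y_metrics, x_metrics=x_metrics,
                                     random_network=opts.random_network)
    pre = results[results["state"] == "pre"].set_index(["y", "x"])["adj_r2"]
    post = results[results["state"] == "post"].set_index(["y", "x"])["adj_r2"]
    common = pre.index.intersection(post.index)
    if len(common) >= 6:
        stat, p, degenerate = assoc.compare_r2(pre.loc[common].to_numpy(),
                                               post.loc[common].to_numpy())
    else:
        stat, p, degenerate = np.nan, np.nan, True
    r2_cmp = pd.DataFrame([{"n_pairs": len(common), "wilcoxon_stat": stat,
                            "p_value": p, "degenerate": degenerate,
                            "median_pre": float(pre.loc[common].median()),
                            "median_post": float(post.loc[common].median())}])
    polarity = assoc.polarity_matrix(results, state="post")
    out = {"fmri_table": fmri, "eeg_table": eeg, "sex": sex,
           "associations": results, "r2_comparison": r2_cmp, "polarity": polarity}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fmt = dict(sep="\t", index=False, float_format="%.10g")
        fmri.to_csv(out_dir / "fmri_metrics.tsv", **fmt)
        eeg.to_csv(out_dir / "eeg_metrics.tsv", **fmt)
        results.to_csv(out_dir / "associations.tsv", **fmt)
        r2_cmp.to_csv(out_dir / "r2_comparison.tsv", **fmt)
        polarity.to_csv(out_dir / "polarity_matrix.tsv", sep="\t",
                        float_format="%.10g")
        (out_dir / "options.json").write_text(json.dumps(opts.to_dict(), indent=2))
        log.info("analysis written to %s", out_dir)
    return out


def coupled_pair_replicate(config: SimulationConfig, seed: int,
                           opts: AnalysisOptions | None = None) -> dict:
    """One synthetic replicate of the headline comparison: generate a
    confounded cohort, compute the coupled metric pair pre and post
    correction, fit the mixed model, and return both adjusted r-squared
    values plus the fitted X effects."""
    cfg = SimulationConfig(**{**asdict_config(config), "master_seed": seed})
    y_m, x_m = COUPLED_PAIR
    opts = opts or AnalysisOptions(fmri_metrics=(y_m,), eeg_metrics=(x_m,))
    cohort = make_cohort(cfg)
    fmri, eeg, sex = cohort_tables(cohort, opts)
    res = {}
    for state in ("pre", "post"):
        grid = assoc.build_grid(fmri[fmri["state"] == state], eeg, sex,
                                y_metrics=(y_m,), x_metrics=(x_m,))
        fit = assoc.fit_pair(grid[(y_m, x_m, state)], y=y_m, x=x_m, state=state)
        res[f"r2_{state}"] = fit.adj_r2
        res[f"beta_x_{state}"] = fit.beta_x
    return res


def asdict_config(config: SimulationConfig) -> dict:
    from dataclasses import asdict as _asdict
    return _asdict(config)
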