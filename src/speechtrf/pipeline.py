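"""Config-driven orchestration of the encoding analyses.

``run_model`` fits one of the named encoding models per participant and
condition of a dataset, returning fitted TRFs, tidy prediction tables and
— for the multivariate models — the residual-r comparison against the
documented univariate baseline (the spectrogram for the phonetic-feature
model, the envelope for the surprisal model).  ``report`` summarizes a
completed run directory into machine-readable JSON.

Model registry (feature sets and lag windows):

========== ============================== ================= =========
name       features                       lag window (ms)   baseline
========== ============================== ================= =========
Env        envelope                       [-200, 600]       —
Sgram      8 spectrogram bands            [-200, 600]       —
PhFSgram   19 phonetic features + Sgram   [-200, 600]       Sgram
SemEnv     surprisal + envelope           [-200, 700]       Env
========== ============================== ================= =========
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inventory import FEATURE_LABELS
from .simulate import SimulatedDataset
from .trf import CVResult, PredictionResult, cv_lambda_search, residual_r

__all__ = ["RunConfig", "MODEL_SPECS", "run_model", "report"]

_SGRAM = tuple(f"sgram{b}" for b in range(8))

MODEL_SPECS: dict[str, dict] = {
    "Env": {"features": ("env",), "window": (-200.0, 600.0), "baseline": None},
    "Sgram": {"features": _SGRAM, "window": (-200.0, 600.0), "baseline": None},
    "PhFSgram": {
        "features": FEATURE_LABELS + _SGRAM,
        "window": (-200.0, 600.0),
        "baseline": "Sgram",
    },
    "SemEnv": {
        "features": ("surprisal", "env"),
        "window": (-200.0, 700.0),
        "baseline": "Env",
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings; the defaults reproduce the documented pipeline
    (100 Hz analysis rate, 1-8 Hz band, 5 folds, lambda grid 1e-2..1e8,
    [-200, 600] ms acoustic/phonetic windows, [-200, 700] ms semantic)."""

    fs: float = 100.0
    band: tuple[float, float] = (1.0, 8.0)
    filter_order: int = 2
    n_folds: int = 5
    lambda_exponents: tuple[float, float, int] = (-2.0, 8.0, 11)
    scale_features: bool = True
    n1p2_window: tuple[float, float] = (30.0, 180.0)
    n400_window: tuple[float, float] = (440.0, 640.0)
    cbpt_cluster_alpha: float = 0.05
    cbpt_n_permutations: int = 5000
    cbpt_adjacency_threshold: float = 0.6
    seed: int = 0

    @property
    def lambda_grid(self) -> np.ndarray:
        lo, hi, n = self.lambda_exponents
        return np.logspace(lo, hi, int(n))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        for key in ("band", "n1p2_window", "n400_window"):
            if key in d:
                d[key] = tuple(d[key])
        if "lambda_exponents" in d:
            d["lambda_exponents"] = tuple(d["lambda_exponents"])
        return cls(**d)


@dataclass(frozen=True)
class RunResult:
    """Per-(participant, condition) fits and tidy summaries of one model."""

    model_name: str
    fits: dict  # (participant, condition) -> CVResult
    predictions: pd.DataFrame  # participant, condition, channel, fold, r
    baseline_fits: dict | None = None
    residual_tests: dict | None = None  # condition -> ResidualRResult
    residual_test_pooled: object | None = None


def _fit_one(
    dataset: SimulatedDataset, participant, condition, spec, config: RunConfig
) -> CVResult:
    stim = dataset.stimuli[condition]
    feats = stim.features.select(list(spec["features"]))
    rec = dataset.recordings[(participant, condition)]
    return cv_lambda_search(
        feats,
        rec,
        lag_window=spec["window"],
        n_folds=config.n_folds,
        lambda_grid=config.lambda_grid,
        scale=config.scale_features,
    )


def run_model(
    config: RunConfig,
    model_name: str,
    dataset: SimulatedDataset,
    out_dir=None,
) -> RunResult:
    """Fit ``model_name`` for every participant and condition.

    For models with a univariate baseline the baseline is fit on the same
    data and the residual-r cohort test (one-tailed, multivariate minus
    baseline prediction r) is computed per condition and pooled over all
    participant-condition observations.
    """
    if model_name not in MODEL_SPECS:
        raise KeyError(
            f"unknown model {model_name!r}; choose from {sorted(MODEL_SPECS)}"
        )
    spec = MODEL_SPECS[model_name]
    missing = [
        f
        for cond in dataset.conditions
        for f in spec["features"]
        if f not in dataset.stimuli[cond].features.feature_labels
    ]
    if missing:
        raise ValueError(f"dataset stimuli lack features: {sorted(set(missing))}")

    fits: dict = {}
    rows = []
    for p in dataset.participants:
        for cond in dataset.conditions:
            cv = _fit_one(dataset, p, cond, spec, config)
            fits[(p, cond)] = cv
            labels = dataset.recordings[(p, cond)].channel_labels
            for k in range(cv.prediction.r.shape[0]):
                for c, lab in enumerate(labels):
                    rows.append(
                        {
                            "participant": p,
                            "condition": cond,
                            "channel": lab,
                            "fold": k,
                            "r": cv.prediction.r[k, c],
                            "lambda": cv.best_lambda,
                        }
                    )
    predictions = pd.DataFrame(rows)

    baseline_fits = residual_tests = pooled = None
    if spec["baseline"] is not None:
        base_spec = MODEL_SPECS[spec["baseline"]]
        baseline_fits = {
            key: _fit_one(dataset, key[0], key[1], base_spec, config)
            for key in fits
        }
        residual_tests = {}
        for cond in dataset.conditions:
            multi = [fits[(p, cond)].prediction for p in dataset.participants]
            uni = [baseline_fits[(p, cond)].prediction for p in dataset.participants]
            residual_tests[cond] = residual_r(multi, uni)
        pooled = residual_r(
            [fits[k].prediction for k in sorted(fits)],
            [baseline_fits[k].prediction for k in sorted(fits)],
        )

    result = RunResult(model_name, fits, predictions, baseline_fits,
                       residual_tests, pooled)
    if out_dir is not None:
        _write_run(result, config, dataset, Path(out_dir))
    return result


def _write_run(
    result: RunResult, config: RunConfig, dataset: SimulatedDataset, out: Path
) -> None:
    from .io import save_trf

    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    result.predictions.to_csv(out / f"{result.model_name}_predictions.csv",
                              index=False)
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    for (p, cond), cv in result.fits.items():
        save_trf(cv.model, models_dir / f"{result.model_name}_p{p}_{cond}.h5")
    summary = {
        "model": result.model_name,
        "participants": dataset.participants,
        "conditions": dataset.conditions,
        "mean_r_by_condition": {
            cond: float(
                result.predictions.query("condition == @cond")["r"].mean()
            )
            for cond in dataset.conditions
        },
        "chosen_lambda": {
            f"p{p}_{cond}": cv.best_lambda for (p, cond), cv in result.fits.items()
        },
    }
    if result.residual_tests is not None:
        summary["residual_r"] = {
            cond: {"t": res.t, "df": res.df, "p": res.p,
                   "mean_delta": float(res.delta_per_participant.mean())}
            for cond, res in result.residual_tests.items()
        }
        pooled = result.residual_test_pooled
        summary["residual_r_pooled"] = {"t": pooled.t, "df": pooled.df,
                                        "p": pooled.p}
    with open(out / f"{result.model_name}_summary.json", "w") as f:
        json.dump(summary, f, indent=2)


def report(run_dir) -> dict:
    """Summarize a completed run directory into ``report.json``.

    Collects every ``*_summary.json`` and ``*_predictions.csv`` the model
    runs wrote, computes per-condition mean prediction correlations, and
    writes the merged report next to them.  Raises if the directory holds
    no run artifacts, listing what was expected.
    """
    run_dir = Path(run_dir)
    summaries = sorted(run_dir.glob("*_summary.json"))
    predictions = sorted(run_dir.glob("*_predictions.csv"))
    if not summaries and not predictions:
        raise FileNotFoundError(
            f"no run artifacts in {run_dir}: expected *_summary.json and "
            f"*_predictions.csv written by run_model"
        )
    rep: dict = {"run_dir": str(run_dir), "models": {}}
    for s in summaries:
        with open(s) as f:
            rep["models"][s.stem.replace("_summary", "")] = json.load(f)
    for p in predictions:
        name = p.stem.replace("_predictions", "")
        df = pd.read_csv(p)
        rep["models"].setdefault(name, {})["mean_r_by_condition"] = (
            df.groupby("condition")["r"].mean().to_dict()
        )
    with open(run_dir / "report.json", "w") as f:
        json.dump(rep, f, indent=2)
    return rep
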