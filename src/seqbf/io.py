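"""CSV/JSON/YAML interfaces and the end-to-end pipeline.

All file formats are plain text.  The participant CSV is the pipeline's
exchange format::

    participant_id,lab,collection_order,n_trials,negative_count

``run_replication_analysis`` chains every stage — sequential curve, prior
robustness, per-lab meta-analysis, anomaly statistics with Monte-Carlo null
calibration — and writes one JSON summary plus per-stage tables, fully
deterministic for a given configuration (seed included).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes
from .anomaly import build_null, combined_exceedance, empirical_p
from .bayes import BFConfig
from .meta import LabMeta, LabSummary
from .sequential import SequentialBF

__all__ = [
    "PARTICIPANT_COLUMNS",
    "load_participants",
    "write_participants",
    "write_trials",
    "write_curve",
    "load_lab_summaries",
    "RunConfig",
    "run_replication_analysis",
    "get_logger",
]

PARTICIPANT_COLUMNS = [
    "participant_id",
    "lab",
    "collection_order",
    "n_trials",
    "negative_count",
]

_logger = logging.getLogger("seqbf")


def get_logger(verbosity: str = "info") -> logging.Logger:
    """Package logger on stderr; levels quiet / info / debug."""
    levels = {"quiet": logging.WARNING, "info": logging.INFO, "debug": logging.DEBUG}
    if verbosity not in levels:
        raise ValueError(f"verbosity must be one of {sorted(levels)}")
    if not _logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        _logger.addHandler(handler)
    _logger.setLevel(levels[verbosity])
    return _logger


class ValidationError(ValueError):
    """A malformed input file; the message names the offending row."""


def load_participants(path) -> pd.DataFrame:
    """Read, validate and order a participant CSV.

    Rows are checked (counts within [0, n_trials], unique collection_order)
    and returned sorted by collection_order.
    """
    frame = pd.read_csv(path)
    missing = [c for c in PARTICIPANT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    for col in ("collection_order", "n_trials", "negative_count"):
        if not np.issubdtype(frame[col].dtype, np.number):
            raise ValidationError(f"{path}: column {col!r} must be numeric")
    bad = frame[(frame.negative_count < 0) | (frame.negative_count > frame.n_trials)]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"{path}: row {int(row.name)} (participant "
            f"{row.participant_id!r}): negative_count={int(row.negative_count)} "
            f"outside [0, {int(row.n_trials)}]"
        )
    dupes = frame.collection_order[frame.collection_order.duplicated()]
    if len(dupes):
        raise ValidationError(
            f"{path}: duplicate collection_order value {int(dupes.iloc[0])}"
        )
    return frame.sort_values("collection_order").reset_index(drop=True)


def write_participants(records_or_frame, path) -> None:
    if isinstance(records_or_frame, pd.DataFrame):
        frame = records_or_frame
    else:
        from .cohort import cohort_to_frame

        frame = cohort_to_frame(records_or_frame)
    frame.to_csv(path, index=False)


def write_trials(trials_or_frame, path) -> None:
    if isinstance(trials_or_frame, pd.DataFrame):
        frame = trials_or_frame
    else:
        from .cohort import trials_to_frame

        frame = trials_to_frame(trials_or_frame)
    frame.to_csv(path, index=False)


def write_curve(results, path) -> None:
    """Per-step curve CSV: cumulative_n, mean, sd, t, bf10, bf01."""
    results.to_frame().to_csv(path, index=False)


def load_lab_summaries(path) -> list[LabSummary]:
    """Read a lab-summary CSV with columns label, n, mean, sd."""
    frame = pd.read_csv(path)
    missing = [c for c in ("label", "n", "mean", "sd") if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return [
        LabSummary(str(r.label), int(r.n), float(r.mean), float(r.sd))
        for r in frame.itertuples()
    ]


@dataclass
class RunConfig:
    """Configuration of the end-to-end pipeline."""

    input: str
    outdir: str
    seed: int = 0
    mu0: float = 30.0
    prior_scale: float = 0.1
    direction: str = "less"
    min_n: int = 2
    stop_bf: float = 10.0
    r_grid: tuple = bayes.DEFAULT_R_GRID
    n_sims: int = 1000
    fft_scaling: str = "coefficient"
    fft_include_dc: bool = True
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError(f"n_sims must be >= 1, got {self.n_sims}")
        self.r_grid = tuple(float(r) for r in self.r_grid)
        self.bf_config  # validate BFConfig fields eagerly

    @property
    def bf_config(self) -> BFConfig:
        return BFConfig(
            mu0=self.mu0,
            prior_scale=self.prior_scale,
            direction=self.direction,
            min_n=self.min_n,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**payload)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _dump_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_replication_analysis(config: RunConfig) -> dict:
    """Run every stage on a participant CSV and write the report bundle.

    Outputs in ``config.outdir``: curve.csv, robustness.csv, labs_meta.json,
    anomaly.json, null_distribution.csv and summary.json.  Returns the
    summary payload.  Deterministic given the configuration.
    """
    log = get_logger(config.verbosity)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bf_config = config.bf_config

    log.info("[load] reading cohort from %s", config.input)
    cohort = load_participants(config.input)

    log.info("[sequential] fitting curve for %d participants", len(cohort))
    res = SequentialBF.from_cohort(cohort, bf_config).fit()
    write_curve(res, outdir / "curve.csv")
    stopping = res.stopping(config.stop_bf)

    log.info("[robustness] prior scales %s", config.r_grid)
    sweep = res.robustness(config.r_grid)
    pd.DataFrame(
        {"prior_scale": list(sweep), "bf10": [sweep[r] for r in sweep]}
    ).to_csv(outdir / "robustness.csv", index=False)

    log.info("[meta] per-lab Bayes factors and random-effects pooling")
    labs = [
        LabSummary(
            str(label),
            int(len(group)),
            float(group.negative_count.mean()),
            float(group.negative_count.std(ddof=1)),
        )
        for label, group in cohort.groupby("lab", sort=True)
    ]
    meta_payload = None
    if len(labs) >= 2 and all(s.sd > 0 for s in labs):
        meta_payload = LabMeta(labs, bf_config).fit().to_dict()
        _dump_json(meta_payload, outdir / "labs_meta.json")
    else:
        log.info("[meta] skipped: fewer than 2 labs with positive sd")

    log.info(
        "[anomaly] %d null simulations of %d participants (seed %d)",
        config.n_sims,
        len(cohort),
        config.seed,
    )
    null = build_null(
        config.n_sims,
        n_participants=len(cohort),
        n_trials=int(cohort.n_trials.iloc[0]),
        config=bf_config,
        seed=config.seed,
        fft_scaling=config.fft_scaling,
        fft_include_dc=config.fft_include_dc,
    )
    null.to_frame().to_csv(outdir / "null_distribution.csv", index=False)
    observed = res.anomaly(
        scaling=config.fft_scaling, include_dc=config.fft_include_dc
    )
    anomaly_payload = {
        "observed": dataclasses.asdict(observed),
        "null": {
            "n_sims": null.n_sims,
            "n_participants": null.n_participants,
            "n_trials": null.n_trials,
            "seed": null.seed,
            "mean_energy": float(null.energy.mean()),
            "sd_energy": float(null.energy.std(ddof=1)),
        },
        "p_max_bf": empirical_p(observed.max_bf, null.max_bf),
        "p_energy": empirical_p(observed.energy, null.energy),
        "p_amp_sum": empirical_p(observed.amp_sum, null.amp_sum),
        "p_combined": combined_exceedance(
            (observed.max_bf, observed.energy), null
        ),
    }
    _dump_json(anomaly_payload, outdir / "anomaly.json")

    summary = {
        "config": {
            **dataclasses.asdict(config),
            "r_grid": list(config.r_grid),
        },
        "n_participants": len(cohort),
        "mean": res.summary_stats.mean,
        "sd": res.summary_stats.sd,
        "t": res.summary_stats.t,
        "final_bf10": res.bf10,
        "final_bf01": res.bf01,
        "stopping": dataclasses.asdict(stopping),
        "robustness": {str(r): v for r, v in sweep.items()},
        "labs_meta": meta_payload,
        "anomaly": anomaly_payload,
    }
    _dump_json(summary, outdir / "summary.json")
    log.info("[done] summary written to %s", outdir / "summary.json")
    return summary
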