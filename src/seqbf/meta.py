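"""Per-lab Bayes factors and random-effects meta-analysis.

Each lab contributes a summary row (n, mean, sd) from which a one-sided
Bayes factor and a standardized effect size are computed.  The effect sizes
are pooled with a DerSimonian-Laird random-effects model; heterogeneity is
described by Cochran's Q, I² and the between-lab variance tau².

Sign convention: an *avoidance* effect (mean negative count below chance) is
positive, d = (mu0 - mean) / sd, with the standard one-sample sampling
variance v = 1/n + d²/(2n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.meta_analysis import combine_effects

from . import bayes
from .bayes import BFConfig

__all__ = [
    "LabSummary",
    "MetaResult",
    "bf_from_summary",
    "effect_size",
    "random_effects_meta",
    "LabMeta",
    "LabMetaResults",
]


@dataclass(frozen=True)
class LabSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"lab {self.label!r}: need n >= 2, got {self.n}")
        if not self.sd > 0:
            raise ValueError(f"lab {self.label!r}: sd must be positive, got {self.sd}")


@dataclass(frozen=True)
class MetaResult:
    """Random-effects pooling output.

    I² is the Q-based definition max(0, (Q - df)/Q) * 100; for the
    DerSimonian-Laird estimator it coincides with the tau²-based form.
    """

    es: float  # pooled effect (random-effects weights)
    se: float  # its standard error
    tau2: float  # between-lab variance (DerSimonian-Laird)
    I2: float  # percent heterogeneity
    Q: float  # Cochran statistic
    df: int
    p_Q: float
    k: int

    @property
    def tau(self) -> float:
        return math.sqrt(self.tau2)


def bf_from_summary(summary: LabSummary, config: BFConfig | None = None) -> float:
    """One-sided BF10 recomputed from a lab's (n, mean, sd) row."""
    config = config or BFConfig()
    t = (summary.mean - config.mu0) / (summary.sd / math.sqrt(summary.n))
    return bayes.bf10(
        t, summary.n, prior_scale=config.prior_scale, direction=config.direction
    )


def effect_size(summary: LabSummary, mu0: float = 30.0) -> tuple[float, float]:
    """Standardized avoidance effect d and its sampling variance v."""
    d = (mu0 - summary.mean) / summary.sd
    v = 1.0 / summary.n + d * d / (2.0 * summary.n)
    return d, v


def random_effects_meta(studies) -> MetaResult:
    """DerSimonian-Laird random-effects meta-analysis.

    ``studies`` is a sequence of (d, v) or (d, v, n) tuples.  Pooling uses
    inverse-variance weights 1/(v + tau²) with the method-of-moments tau²;
    Q, I² and p_Q describe heterogeneity of the fixed-effect fit.
    """
    studies = [tuple(s) for s in studies]
    if len(studies) < 2:
        raise ValueError("meta-analysis requires at least 2 studies")
    d = np.array([s[0] for s in studies], dtype=float)
    v = np.array([s[1] for s in studies], dtype=float)
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")

    with np.errstate(divide="ignore", invalid="ignore"):
        res = combine_effects(d, v, method_re="dl")
    q = float(res.test_homogeneity().statistic)
    df = len(studies) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    # the method-of-moments tau2 goes negative for under-dispersed studies;
    # truncate at 0 (as rma and most implementations do) and re-pool
    tau2 = max(0.0, float(res.tau2))
    w = 1.0 / (v + tau2)
    es = float(np.sum(w * d) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return MetaResult(
        es=es,
        se=se,
        tau2=tau2,
        I2=i2,
        Q=q,
        df=df,
        p_Q=float(_sps.chi2.sf(q, df)),
        k=len(studies),
    )


class LabMeta:
    """Meta-analytic model over per-lab summary rows (statsmodels-style)."""

    def __init__(self, summaries, config: BFConfig | None = None):
        self.summaries = list(summaries)
        if len(self.summaries) < 2:
            raise ValueError("need at least 2 labs")
        self.config = config or BFConfig()

    @classmethod
    def from_frame(cls, frame, config: BFConfig | None = None) -> "LabMeta":
        """Build from a DataFrame with columns label, n, mean, sd."""
        rows = [
            LabSummary(str(r.label), int(r.n), float(r.mean), float(r.sd))
            for r in frame.itertuples()
        ]
        return cls(rows, config)

    def fit(self) -> "LabMetaResults":
        per_lab_bf = {
            s.label: bf_from_summary(s, self.config) for s in self.summaries
        }
        effects = [
            effect_size(s, self.config.mu0) + (s.n,) for s in self.summaries
        ]
        meta = random_effects_meta(effects)
        return LabMetaResults(self, per_lab_bf, effects, meta)


class LabMetaResults:
    def __init__(self, model: LabMeta, per_lab_bf, effects, meta: MetaResult):
        self.model = model
        self.per_lab_bf = per_lab_bf
        self.effects = effects
        self.meta = meta

    def to_frame(self):
        import pandas as pd

        rows = []
        for s, (d, v, _) in zip(self.model.summaries, self.effects):
            rows.append(
                {
                    "label": s.label,
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                    "d": d,
                    "v": v,
                    "bf10": self.per_lab_bf[s.label],
                    "bf01": 1.0 / self.per_lab_bf[s.label],
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        m = self.meta
        return {
            "per_lab_bf10": {k: float(v) for k, v in self.per_lab_bf.items()},
            "pooled_es": m.es,
            "pooled_se": m.se,
            "tau2": m.tau2,
            "tau": m.tau,
            "I2_percent": m.I2,
            "Q": m.Q,
            "df": m.df,
            "p_Q": m.p_Q,
            "k": m.k,
        }

    def summary(self) -> str:
        m = self.meta
        lines = [
            "Random-effects meta-analysis (DerSimonian-Laird)",
            "=" * 50,
            f"{'lab':<10}{'n':>6}{'mean':>8}{'sd':>7}{'d':>9}{'BF10':>9}",
        ]
        for s, (d, _, _) in zip(self.model.summaries, self.effects):
            lines.append(
                f"{s.label:<10}{s.n:>6}{s.mean:>8.2f}{s.sd:>7.2f}"
                f"{d:>9.4f}{self.per_lab_bf[s.label]:>9.3f}"
            )
        lines += [
            "-" * 50,
            f"pooled ES {m.es:.4f} (SE {m.se:.4f})",
            f"tau^2 {m.tau2:.6f}  I^2 {m.I2:.2f}%  "
            f"Q({m.df}) = {m.Q:.3f}, p = {m.p_Q:.3f}",
        ]
        return "\n".join(lines)
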